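"""Small shared helpers."""

from __future__ import annotations

__all__ = ["split_counts"]


def split_counts(n_total: int, ratios=(0.7, 0.2, 0.1)) -> tuple[int, ...]:
    """Dataset split sizes for a ratio partition, rounding half up.

    All but the last subset get round(n * ratio); the last takes the
    remainder so the sizes always sum to ``n_total``.  A 7:2:1 split of 7077
    images yields (4954, 1415, 708).
    """
    if n_total < 0:
        raise ValueError("n_total must be non-negative")
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError(f"ratios must sum to 1, got {ratios}")
    counts = [int(n_total * r + 0.5) for r in ratios[:-1]]
    counts.append(n_total - sum(counts))
    if counts[-1] < 0:
        raise ValueError("rounding overflow: ratios incompatible with n_total")
    return tuple(counts)
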