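"""Object keypoint similarity (OKS) and the derived detection metrics.

OKS plays the role IoU plays for boxes: for a prediction/ground-truth pair it
is the visibility-weighted mean of per-keypoint Gaussian similarities,

    OKS = sum_i exp(-d_i^2 / (2 s^2 sigma_i^2)) * [v_i > 0] / sum_i [v_i > 0],

where d_i is the pixel distance between predicted and true keypoint i, s is
the object scale and sigma_i a per-landmark labeling-noise constant.  Under
the standard convention s = sqrt(bbox_area) (``sqrt_area``); the alternative
``raw_area`` mode squares the bounding-box area itself, for literal
reproduction of formulations that write s as the area.

AP at a threshold T is the fraction of instances whose OKS strictly exceeds
T; mAP averages AP over categories (or over the 0.50:0.05:0.95 threshold
grid); precision and recall follow the usual TP/FP/FN definitions.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .frames import LANDMARK_NAMES, KeypointSet

__all__ = [
    "OKSConfig",
    "EvalSummary",
    "oks",
    "oks_terms",
    "ap_at_threshold",
    "mean_ap",
    "precision_recall",
    "match_predictions",
    "evaluate",
    "ap_improvement_pp",
    "DEFAULT_THRESHOLDS",
]

DEFAULT_THRESHOLDS = tuple(np.round(np.arange(0.50, 0.951, 0.05), 2))


@dataclass(frozen=True)
class OKSConfig:
    sigmas: tuple = (0.05,) * len(LANDMARK_NAMES)
    thresholds: tuple = DEFAULT_THRESHOLDS
    area_convention: str = "sqrt_area"

    def __post_init__(self) -> None:
        if len(self.sigmas) != len(LANDMARK_NAMES) or any(s <= 0 for s in self.sigmas):
            raise ValueError(f"need {len(LANDMARK_NAMES)} positive sigmas, got {self.sigmas}")
        t = np.asarray(self.thresholds, dtype=np.float64)
        if t.size == 0 or np.any(np.diff(t) <= 0) or np.any(t <= 0) or np.any(t >= 1):
            raise ValueError("thresholds must be strictly increasing within (0, 1)")
        if self.area_convention not in ("sqrt_area", "raw_area"):
            raise ValueError(f"unknown area convention {self.area_convention!r}")

    def scale(self, bbox_area: float) -> float:
        """The normalizing object scale s for a given bounding-box area."""
        if bbox_area <= 0:
            raise ValueError(f"bbox_area must be positive, got {bbox_area}")
        return float(np.sqrt(bbox_area)) if self.area_convention == "sqrt_area" else float(bbox_area)


class UndefinedOKSError(ValueError):
    """OKS is undefined when the ground truth has no visible keypoint."""


def oks_terms(pred: KeypointSet, gt: KeypointSet, config: OKSConfig) -> np.ndarray:
    """Per-keypoint similarity terms exp(-d_i^2/(2 s^2 sigma_i^2)), NaN where invisible."""
    s = config.scale(gt.bbox_area)
    terms = np.full(len(LANDMARK_NAMES), np.nan)
    p, g = pred.as_array(), gt.as_array()
    d2 = np.sum((p - g) ** 2, axis=1)
    for i, kp in enumerate(gt.keypoints):
        if kp.visible:
            terms[i] = np.exp(-d2[i] / (2.0 * s**2 * config.sigmas[i] ** 2))
    return terms


def oks(pred: KeypointSet, gt: KeypointSet, config: OKSConfig | None = None) -> float:
    """Object keypoint similarity in [0, 1] between a prediction and its ground truth."""
    config = config or OKSConfig()
    if gt.visible_count() == 0:
        raise UndefinedOKSError("ground truth has no visible keypoint; OKS is undefined")
    terms = oks_terms(pred, gt, config)
    visible = ~np.isnan(terms)
    return float(np.mean(terms[visible]))


def ap_at_threshold(oks_values, T: float) -> float:
    """Fraction of instances whose OKS strictly exceeds the threshold T."""
    vals = np.asarray(oks_values, dtype=np.float64)
    if vals.size == 0:
        raise ValueError("AP is undefined for an empty OKS list")
    return float(np.mean(vals > T))


def mean_ap(per_category_ap) -> float:
    """Arithmetic mean of per-category (or per-threshold) AP values."""
    vals = np.asarray(per_category_ap, dtype=np.float64)
    if vals.size == 0:
        raise ValueError("mAP is undefined for an empty AP list")
    return float(np.mean(vals))


def precision_recall(tp: int, fp: int, fn: int) -> tuple[float, float, dict]:
    """P = TP/(TP+FP), R = TP/(TP+FN); 0/0 is defined as 0 and flagged."""
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be non-negative")
    flags = {}
    if tp + fp == 0:
        p, flags["precision_undefined"] = 0.0, True
    else:
        p = tp / (tp + fp)
    if tp + fn == 0:
        r, flags["recall_undefined"] = 0.0, True
    else:
        r = tp / (tp + fn)
    return p, r, flags


def _instance_confidence(ks: KeypointSet) -> float:
    vis = [k.confidence for k in ks.keypoints if k.visible]
    return float(np.mean(vis)) if vis else 0.0


@dataclass
class MatchResult:
    oks_values: list[float]
    pairs: list[tuple[int, int]]      # (pred index, gt index)
    tp: int = 0                       # keypoint-level true positives
    fp: int = 0
    fn: int = 0
    unmatched_preds: list[int] = field(default_factory=list)
    unmatched_gts: list[int] = field(default_factory=list)


def match_predictions(preds: list[KeypointSet], gts: list[KeypointSet],
                      config: OKSConfig | None = None,
                      decision_threshold: float = 0.5) -> MatchResult:
    """Greedy one-to-one matching of predictions to ground truths by OKS.

    Predictions are visited in descending instance confidence; each takes the
    still-unmatched ground truth with the highest (strictly positive) OKS.
    Unmatched predictions count as instance false positives and unmatched
    ground truths as false negatives.  At keypoint level every visible
    ground-truth keypoint becomes exactly one TP (its matched per-keypoint
    OKS term exceeds ``decision_threshold``) or one FN (term at/below the
    threshold, or its instance was never matched), so TP + FN equals the
    number of visible ground-truth keypoints; a matched keypoint below the
    threshold is additionally a false detection (FP), as are the keypoints of
    unmatched predictions.
    """
    config = config or OKSConfig()
    order = sorted(range(len(preds)), key=lambda i: -_instance_confidence(preds[i]))
    available = set(range(len(gts)))
    result = MatchResult(oks_values=[], pairs=[])
    for pi in order:
        best_gi, best_oks = None, 0.0
        for gi in available:
            try:
                val = oks(preds[pi], gts[gi], config)
            except UndefinedOKSError:
                continue
            if val > best_oks:
                best_gi, best_oks = gi, val
        if best_gi is None:
            result.unmatched_preds.append(pi)
            continue
        available.discard(best_gi)
        result.pairs.append((pi, best_gi))
        result.oks_values.append(best_oks)
        terms = oks_terms(preds[pi], gts[best_gi], config)
        vis = ~np.isnan(terms)
        hits = int(np.count_nonzero(terms[vis] > decision_threshold))
        misses = int(np.count_nonzero(vis)) - hits
        result.tp += hits
        result.fn += misses
        result.fp += misses
    result.unmatched_gts = sorted(available)
    for gi in result.unmatched_gts:
        result.fn += gts[gi].visible_count()
    for pi in result.unmatched_preds:
        result.fp += preds[pi].visible_count()
    return result


@dataclass
class EvalSummary:
    ap_per_threshold: dict[float, float]
    map_thresholds: float
    precision: float
    recall: float
    tp: int
    fp: int
    fn: int
    n_instances: int
    flags: dict = field(default_factory=dict)

    @property
    def ap50(self) -> float:
        return self.ap_per_threshold[min(self.ap_per_threshold)]


def evaluate(preds: list[KeypointSet], gts: list[KeypointSet],
             config: OKSConfig | None = None,
             decision_threshold: float = 0.5) -> EvalSummary:
    """Full OKS evaluation: matching, per-threshold AP, mAP, precision, recall."""
    config = config or OKSConfig()
    res = match_predictions(preds, gts, config, decision_threshold=decision_threshold)
    # Unmatched ground truths enter the AP pool with OKS 0 (missed instances);
    # unmatched predictions likewise (spurious instances).
    pool = list(res.oks_values) + [0.0] * (len(res.unmatched_gts) + len(res.unmatched_preds))
    if not pool:
        raise ValueError("nothing to evaluate: no predictions and no ground truths")
    ap = {float(t): ap_at_threshold(pool, t) for t in config.thresholds}
    p, r, flags = precision_recall(res.tp, res.fp, res.fn)
    return EvalSummary(ap_per_threshold=ap, map_thresholds=mean_ap(list(ap.values())),
                       precision=p, recall=r, tp=res.tp, fp=res.fp, fn=res.fn,
                       n_instances=len(pool), flags=flags)


def ap_improvement_pp(ap_new: float, ap_base: float) -> float:
    """Absolute AP improvement in percentage points, to two decimals."""
    return round((ap_new - ap_base) * 100.0, 2)


def exhaustive_best_matching(preds: list[KeypointSet], gts: list[KeypointSet],
                             config: OKSConfig | None = None) -> float:
    """Total OKS of the best one-to-one assignment, by exhaustive enumeration.

    Intended for small instance counts; serves as the reference the greedy
    matcher is compared against in tests.
    """
    config = config or OKSConfig()
    n, m = len(preds), len(gts)
    best = 0.0
    k = min(n, m)
    for pred_subset in itertools.permutations(range(n), k):
        for gt_subset in itertools.combinations(range(m), k):
            total = 0.0
            for pi, gi in zip(pred_subset, gt_subset):
                try:
                    total += oks(preds[pi], gts[gi], config)
                except UndefinedOKSError:
                    pass
            best = max(best, total)
    return best
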