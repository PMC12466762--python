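"""Batch orchestration: frames + annotations in, report CSV + per-animal JSON out.

``run_measure`` walks a directory laid out as ``<id>_color.png``,
``<id>_depth.png`` and ``<id>_keypoints.json`` (the layout the ``synth``
subcommand emits), runs the measurement chain on each animal, and writes:

* ``report.csv`` — one row per animal with the four traits (and relative
  errors when a ``truth.csv`` is present);
* ``<id>.json`` — per-animal traits, flags and stage diagnostics;
* ``log.jsonl`` — one JSON-lines record per pipeline stage per animal
  (completion fill fraction, pass-through kept/removed counts, ground-plane
  support, every fallback flag).

A failure in one animal is recorded and the batch continues; the exit status
reported to the CLI is non-zero if any animal failed.  Reports are written
with fixed float formatting and contain no wall-clock fields, so re-running
on identical inputs yields byte-identical output.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .completion import complete_depth, hole_statistics
from .config import extrinsics_from_config, intrinsics_from_config
from .frames import TRAIT_COLUMNS, RGBDFrame, read_frame, read_keypoints, write_report
from .geometry import FilterRange, frame_to_cloud, passthrough_filter
from .measure import BodyMeasurements, GroundConfig, measure_animal, relative_error

__all__ = ["run_measure"]


def _discover_animals(frames_dir: Path) -> list[str]:
    ids = sorted(p.name[: -len("_color.png")] for p in frames_dir.glob("*_color.png"))
    if not ids:
        raise FileNotFoundError(f"no '<id>_color.png' frames found in {frames_dir}")
    return ids


def _load_truth(path: Path) -> dict[str, BodyMeasurements]:
    df = pd.read_csv(path, dtype={"animal_id": str})
    truth = {}
    for _, row in df.iterrows():
        truth[str(row["animal_id"])] = BodyMeasurements(
            **{c: (None if pd.isna(row[c]) else float(row[c])) for c in TRAIT_COLUMNS}
        )
    return truth


def run_measure(config: dict, frames_dir, out_dir, annotation_dialect: str = "labelme") -> int:
    """Measure every animal under ``frames_dir``; returns the number of failures."""
    frames_dir, out_dir = Path(frames_dir), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    intrinsics = intrinsics_from_config(config)
    extrinsics = extrinsics_from_config(config)
    filt = FilterRange(config["passthrough"]["z1"], config["passthrough"]["z2"])
    gcfg = GroundConfig(radius=config["ground"]["radius"],
                        min_support=config["ground"]["min_support"],
                        stride=config["ground"]["stride"])
    truth_path = frames_dir / "truth.csv"
    truth = _load_truth(truth_path) if truth_path.exists() else None

    log_records: list[dict] = []
    results: list[tuple[str, BodyMeasurements]] = []
    errors: list[dict] = []
    for animal_id in _discover_animals(frames_dir):
        try:
            ext_path = frames_dir / f"{animal_id}_extrinsics.json"
            animal_ext = extrinsics
            if ext_path.exists():
                with open(ext_path) as fh:
                    doc = json.load(fh)
                from .frames import Extrinsics
                animal_ext = Extrinsics(doc["R"], doc["T"])
            frame = read_frame(frames_dir / f"{animal_id}_color.png",
                               frames_dir / f"{animal_id}_depth.png",
                               intrinsics, depth_scale=config["depth_scale"])
            kp_path = frames_dir / f"{animal_id}_keypoints.json"
            keypoints = read_keypoints(kp_path, dialect=annotation_dialect,
                                       aliases=config["landmark_aliases"])[0]

            completed = complete_depth(frame.depth, max_passes=config["completion"]["max_passes"])
            stats = hole_statistics(frame.depth, completed)
            completed_frame = RGBDFrame(frame.color, completed, frame.intrinsics)
            kept, removed = passthrough_filter(
                frame_to_cloud(completed_frame, stride=gcfg.stride), filt)
            log_records.append({"animal_id": animal_id, "stage": "completion",
                                "missing_before": stats.missing_before,
                                "missing_after": stats.missing_after,
                                "fill_fraction": round(stats.fill_fraction, 6)})
            log_records.append({"animal_id": animal_id, "stage": "passthrough",
                                "kept": len(kept), "removed": len(removed)})

            bm = measure_animal(completed_frame, keypoints, animal_ext, gcfg,
                                complete=False, filter_range=filt,
                                depth_lookup=config["depth_lookup"])
            log_records.append({"animal_id": animal_id, "stage": "traits",
                                "flags": bm.flags})
            results.append((animal_id, bm))

            per_animal = {"animal_id": animal_id, "flags": bm.flags}
            for col in TRAIT_COLUMNS:
                val = getattr(bm, col)
                per_animal[col] = None if val is None else round(val, 2)
                if truth and animal_id in truth:
                    gt = getattr(truth[animal_id], col)
                    if val is not None and gt is not None:
                        per_animal[col.replace("_cm", "_re_pct")] = relative_error(gt, val)
            with open(out_dir / f"{animal_id}.json", "w") as fh:
                json.dump(per_animal, fh, indent=1, sort_keys=True)
        except Exception as exc:  # per-animal isolation: record and continue
            errors.append({"animal_id": animal_id, "stage": "pipeline",
                           "error": f"{type(exc).__name__}: {exc}"})
            log_records.append(errors[-1])

    with open(out_dir / "log.jsonl", "w") as fh:
        for rec in log_records:
            fh.write(json.dumps(rec, sort_keys=True) + "\n")
    if results:
        gt_list = [truth.get(aid) if truth else None for aid, _ in results]
        if truth and all(g is not None for g in gt_list):
            write_report(results, out_dir / "report.csv", ground_truth=gt_list)
        else:
            write_report(results, out_dir / "report.csv")
    if errors:
        with open(out_dir / "errors.json", "w") as fh:
            json.dump(errors, fh, indent=1, sort_keys=True)
    return len(errors)
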