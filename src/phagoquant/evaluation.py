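"""Detection validation against ground truth.

Detected peaks are matched one-to-one to ground-truth peaks within a distance
radius (3 px by default, Euclidean), greedily in ascending distance.  Matched
detections are true positives; unmatched detections false positives; unmatched
truth false negatives.  Metrics follow the standard definitions, with one
caveat: spot detection has no true-negative count, so the "false-positive
rate" reported here is FP / (TP + FP), i.e. 1 - precision.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import hypot

import numpy as np
import pandas as pd

Point = tuple[float, float]

H_GRID_DEFAULT = (5.0, 15.0, 25.0, 50.0, 100.0)
PROMINENCE_GRID_DEFAULT = (5.0, 10.0, 20.0, 40.0, 80.0)


@dataclass
class MatchResult:
    """One-to-one matching of detections to ground truth."""

    tp: int
    fp: int
    fn: int
    matched_pairs: list[tuple[int, int, float]]  # (detected idx, truth idx, distance px)


@dataclass
class MetricSet:
    """Precision, sensitivity, F1 and FP-rate; None flags an undefined value."""

    precision: float | None
    sensitivity: float | None
    f1: float | None
    fpr: float | None


def match_peaks(
    detected: list[Point], truth: list[Point], radius_px: float = 3.0
) -> MatchResult:
    """Greedy ascending-distance one-to-one matching within ``radius_px``.

    Ties in distance are broken by lower detected index, then lower truth
    index, so the matching is deterministic.
    """
    if not radius_px > 0:
        raise ValueError("radius_px must be positive")
    candidates = []
    for i, (dr, dc) in enumerate(detected):
        for j, (tr, tc) in enumerate(truth):
            d = hypot(dr - tr, dc - tc)
            if d <= radius_px:
                candidates.append((d, i, j))
    candidates.sort()
    used_det: set[int] = set()
    used_truth: set[int] = set()
    pairs: list[tuple[int, int, float]] = []
    for d, i, j in candidates:
        if i in used_det or j in used_truth:
            continue
        used_det.add(i)
        used_truth.add(j)
        pairs.append((i, j, d))
    tp = len(pairs)
    return MatchResult(
        tp=tp, fp=len(detected) - tp, fn=len(truth) - tp, matched_pairs=pairs
    )


def compute_metrics(m: MatchResult) -> MetricSet:
    """Precision, sensitivity, F1, FP-rate from TP/FP/FN counts.

    A metric whose denominator is zero is returned as None, never as a
    silent 0.
    """
    precision = m.tp / (m.tp + m.fp) if (m.tp + m.fp) > 0 else None
    sensitivity = m.tp / (m.tp + m.fn) if (m.tp + m.fn) > 0 else None
    if precision is not None and sensitivity is not None and (precision + sensitivity) > 0:
        f1 = 2 * precision * sensitivity / (precision + sensitivity)
    elif precision is not None and sensitivity is not None:
        f1 = 0.0
    else:
        f1 = None
    fpr = m.fp / (m.tp + m.fp) if (m.tp + m.fp) > 0 else None
    return MetricSet(precision=precision, sensitivity=sensitivity, f1=f1, fpr=fpr)


def parameter_sweep(
    sections,
    h_grid=H_GRID_DEFAULT,
    prominence_grid=PROMINENCE_GRID_DEFAULT,
    radius_px: float = 3.0,
    sigma: float = 1.0,
) -> pd.DataFrame:
    """Pooled detection metrics over a grid of (h, prominence) settings.

    ``sections`` is an iterable of synthetic sections (or any objects exposing
    ``stack``, ``truth_peaks`` and a ``true_mask``).  TP/FP/FN are pooled
    (micro-averaged) over sections per parameter combination; rows are sorted
    by (h, prominence).
    """
    from .detection import DetectionParams, detect_spots
    from .imaging import gaussian_denoise, max_project
    from .segmentation import RpeMask

    h_grid = tuple(h_grid)
    prominence_grid = tuple(prominence_grid)
    if not h_grid or not prominence_grid:
        raise ValueError("parameter grids must be non-empty")
    sections = list(sections)
    if not sections:
        raise ValueError("at least one section with ground truth is required")

    prepared = []
    for section in sections:
        img = gaussian_denoise(max_project(section.stack, "photoreceptor"), sigma=sigma)
        mask = RpeMask(mask=section.true_mask, threshold_value=float("nan"))
        prepared.append((img, mask, [tuple(p) for p in section.truth_peaks]))

    rows = []
    for h in h_grid:
        for prom in prominence_grid:
            tp = fp = fn = 0
            for img, mask, truth in prepared:
                peaks = detect_spots(img, DetectionParams(h=h, prominence=prom), mask)
                m = match_peaks([p.position for p in peaks], truth, radius_px)
                tp, fp, fn = tp + m.tp, fp + m.fp, fn + m.fn
            metrics = compute_metrics(MatchResult(tp, fp, fn, []))
            rows.append(
                {
                    "h": h,
                    "prominence": prom,
                    "TP": tp,
                    "FP": fp,
                    "FN": fn,
                    "precision": metrics.precision,
                    "sensitivity": metrics.sensitivity,
                    "f1": metrics.f1,
                    "fpr": metrics.fpr,
                }
            )
    return pd.DataFrame(rows).sort_values(["h", "prominence"]).reset_index(drop=True)


def percent_difference(manual_count: int, auto_count: int) -> float:
    """Absolute manual-vs-automated count difference as % of the manual count."""
    if manual_count <= 0:
        raise ValueError("manual_count must be positive")
    return abs(auto_count - manual_count) / manual_count * 100.0
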