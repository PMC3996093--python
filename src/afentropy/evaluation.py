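"""Beat-level evaluation: confusion counts, Se/Sp/PPV/ACC, ROC sweep.

A beat counts as true positive when both the reference and the detector call
it AF; warm-up predictions count as non-AF (conservative). The four metrics
are reported as percentages:

    Se  = TP / (TP + FN)          Sp  = TN / (TN + FP)
    PPV = TP / (TP + FP)          ACC = (TP + TN) / total

A metric whose denominator is zero (e.g. Se on a record with no AF beats) is
reported as missing (None), not as 0.

The ROC sweep re-classifies the per-beat H'' values over a threshold grid
(default 0.0 to 1.0 inclusive in steps of 0.001, 1001 points) with the
detector's strict-greater rule, and the operating threshold is chosen as the
point of the curve closest (Euclidean, in percent units) to the perfect
classifier at Se = Sp = 100%.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Sequence

import numpy as np

from .rr_io import AF, NONAF, WARMUP, RhythmReference

__all__ = [
    "ConfusionCounts",
    "MetricSet",
    "ROCPoint",
    "confusion_counts",
    "metrics",
    "roc_sweep",
    "optimal_threshold",
    "write_roc_csv",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """Beat-level confusion-matrix tallies."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricSet:
    """Se / Sp / PPV / ACC as percentages; None where undefined."""

    se: Optional[float]
    sp: Optional[float]
    ppv: Optional[float]
    acc: Optional[float]


@dataclass(frozen=True)
class ROCPoint:
    threshold: float
    se: Optional[float]
    sp: Optional[float]
    one_minus_sp: Optional[float]
    ppv: Optional[float]
    acc: Optional[float]


def confusion_counts(
    predicted: Sequence[str], reference: RhythmReference
) -> ConfusionCounts:
    """Tally TP/TN/FP/FN; WARMUP predictions are counted as non-AF."""
    pred = np.asarray(predicted, dtype=object)
    ref = reference.labels
    if pred.size != ref.size:
        raise ValueError(
            f"predicted has {pred.size} beats but reference has {ref.size}"
        )
    pred_af = pred == AF
    ref_af = ref == AF
    tp = int(np.sum(pred_af & ref_af))
    fp = int(np.sum(pred_af & ~ref_af))
    fn = int(np.sum(~pred_af & ref_af))
    tn = int(np.sum(~pred_af & ~ref_af))
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def _ratio(num: int, den: int) -> Optional[float]:
    return None if den == 0 else 100.0 * num / den


def metrics(c: ConfusionCounts) -> MetricSet:
    """The four beat-level metrics of a confusion tally, in percent."""
    if c.total == 0:
        raise ValueError("all confusion counts are zero")
    return MetricSet(
        se=_ratio(c.tp, c.tp + c.fn),
        sp=_ratio(c.tn, c.tn + c.fp),
        ppv=_ratio(c.tp, c.tp + c.fp),
        acc=_ratio(c.tp + c.tn, c.total),
    )


def roc_sweep(
    h_values: Sequence[float],
    reference: RhythmReference,
    start: float = 0.0,
    stop: float = 1.0,
    step: float = 0.001,
) -> List[ROCPoint]:
    """Re-classify per-beat H'' over a threshold grid (endpoints inclusive).

    ``h_values`` holds one value per beat, NaN (or None) where H'' is
    undefined; undefined beats are non-AF at every threshold, matching the
    warm-up convention. Classification is AF iff ``h > threshold``.
    """
    h = np.array(
        [math.nan if v is None else float(v) for v in h_values], dtype=float
    )
    ref = reference.labels
    if h.size != ref.size:
        raise ValueError(f"{h.size} H'' values but {ref.size} reference beats")
    defined = ~np.isnan(h)
    if not defined.any():
        raise ValueError("no defined H'' values to sweep")

    ref_af = ref == AF
    n_af = int(ref_af.sum())
    n_nonaf = int((~ref_af).sum())
    af_h = np.sort(h[defined & ref_af])
    nonaf_h = np.sort(h[defined & ~ref_af])

    n_steps = int(round((stop - start) / step))
    thresholds = start + step * np.arange(n_steps + 1)
    # counts of defined values strictly above each threshold
    tp = af_h.size - np.searchsorted(af_h, thresholds, side="right")
    fp = nonaf_h.size - np.searchsorted(nonaf_h, thresholds, side="right")
    fn = n_af - tp
    tn = n_nonaf - fp

    points: List[ROCPoint] = []
    for i, thr in enumerate(thresholds):
        m = metrics(ConfusionCounts(int(tp[i]), int(tn[i]), int(fp[i]), int(fn[i])))
        points.append(
            ROCPoint(
                threshold=float(thr),
                se=m.se,
                sp=m.sp,
                one_minus_sp=None if m.sp is None else 100.0 - m.sp,
                ppv=m.ppv,
                acc=m.acc,
            )
        )
    return points


def optimal_threshold(points: Sequence[ROCPoint]) -> float:
    """Threshold of the ROC point nearest the perfect classifier.

    Distance is Euclidean in the (1 - Sp, 100 - Se) percent plane; ties are
    broken toward the larger threshold. Points with undefined Se or Sp are
    ignored.
    """
    best: Optional[tuple[float, float]] = None  # (distance, threshold)
    for p in points:
        if p.se is None or p.sp is None:
            continue
        d = math.hypot(100.0 - p.se, 100.0 - p.sp)
        if best is None or d < best[0] or (d == best[0] and p.threshold > best[1]):
            best = (d, p.threshold)
    if best is None:
        raise ValueError("no ROC points with defined Se and Sp")
    return best[1]


def write_roc_csv(points: Sequence[ROCPoint], path: str | Path) -> None:
    """Write the sweep as threshold,se,sp,one_minus_sp,ppv,acc rows."""
    points = list(points)
    if not points:
        raise ValueError("no ROC points to write")
    with Path(path).open("w") as fh:
        fh.write("threshold,se,sp,one_minus_sp,ppv,acc\n")
        for p in points:
            row = [
                f"{p.threshold:.3f}",
                *("" if v is None else repr(v)
                  for v in (p.se, p.sp, p.one_minus_sp, p.ppv, p.acc)),
            ]
            fh.write(",".join(row) + "\n")
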