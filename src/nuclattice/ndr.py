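"""Reference-occupancy transforms, NDR annotation, and prediction scoring.

Reference nucleosome-occupancy data often come as per-bp log-ratios Y_L.
They are mapped to absolute occupancy Y = c * exp(gamma * Y_L) by choosing
(c, gamma) so that the genome mean equals a target (default 0.80, the
near-saturating in vivo nucleosome density) while Y stays within [0, 1];
gamma is taken as large as the ceiling allows, stretching the dynamic range.

NDRs (nucleosome depleted regions) are called on the absolute track with a
discretisation scheme: horizontal lines at 80%, 73.2%, 66.4%, ... descending
in constant steps of 6.78% (one SD of the reference data).  A candidate dip
(a maximal run below the 80% line) becomes an NDR iff

1. its width at the 73.2% line — outermost crossings, interior bumps
   included — exceeds 110 bp,
2. it is steep: on at least one flank the distance dx between the 80%
   crossing and the crossing of the lowest line the dip reaches is < 100 bp,
3. NDRs whose centers lie closer than 125 bp are merged.

The NDR interval spans the lowest crossing points on each side; its length
is the extent below the 66.43% line (the mean-minus-2-SD occupancy cutoff
also used to score predictions).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from sklearn.metrics import roc_auc_score

logger = logging.getLogger("nuclattice")

#: Default genome-mean occupancy the transform enforces.
TARGET_MEAN = 0.80
#: Spacing of the discretisation lines (one SD of reference occupancy).
LINE_STEP = 0.0678
#: Occupancy cutoff (mean - 2 SD) below which a position counts as depleted.
NDR_CUTOFF = 0.6643

_WIDTH_LINE = TARGET_MEAN - LINE_STEP  # 73.22%
_MIN_WIDTH = 110  # bp, rule 1
_MAX_DX = 100  # bp, rule 2
_MERGE_DIST = 125  # bp, rule 3


@dataclass
class ReferenceTrack:
    """Absolute per-bp occupancy in [0, 1] plus its transform provenance."""

    y: np.ndarray
    ylog: np.ndarray | None = None
    c: float | None = None
    gamma: float | None = None
    target_mean: float = TARGET_MEAN

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        if self.y.ndim != 1:
            raise ValueError("occupancy track must be 1-D")

    @property
    def L(self) -> int:
        return self.y.size

    def copy(self) -> "ReferenceTrack":
        return ReferenceTrack(
            self.y.copy(),
            None if self.ylog is None else self.ylog.copy(),
            self.c,
            self.gamma,
            self.target_mean,
        )


@dataclass(frozen=True)
class NDR:
    """A nucleosome-depleted interval, 0-based half-open coordinates."""

    start: int
    end: int
    center: float
    length: int

    def __post_init__(self) -> None:
        if self.end < self.start or self.length < 0:
            raise ValueError("malformed NDR interval")


NDRSet = list  # list[NDR]


@dataclass
class EvalReport:
    """Agreement between a predicted occupancy track and reference NDRs."""

    rmsd: float
    p_ndr: float
    fpr: float
    auc: float
    hits: list[NDR]
    missed: list[NDR]
    false_positive_intervals: list[tuple[int, int]]


# ---------------------------------------------------------------------------
# occupancy transform
# ---------------------------------------------------------------------------


def _solve_transform(
    ylog: np.ndarray,
    target_mean: float,
    gamma_max: float,
    n_total: int | None = None,
) -> tuple[float, float]:
    """Find (c, gamma): mean of c*exp(gamma*ylog) over `n_total` positions
    equals target_mean, max <= 1, gamma as large as possible.

    `n_total` > len(ylog) models positions pinned at zero occupancy (they
    enter the mean but not the max constraint).
    """
    if n_total is None:
        n_total = ylog.size
    ymax = float(ylog.max())

    def ceiling(gamma: float) -> float:
        # max Y - 1 given c is set by the mean constraint
        c = target_mean * n_total / np.sum(np.exp(gamma * (ylog - ymax)))
        # c above is scaled by e^{gamma*ymax}: maxY = c
        return c - 1.0

    if ceiling(0.0) > 0:
        raise ValueError(
            "no feasible transform: mean constraint already violates the ceiling"
        )
    if ceiling(gamma_max) <= 0:
        gamma = gamma_max
    else:
        gamma = brentq(ceiling, 0.0, gamma_max, xtol=1e-12)
    c = target_mean * n_total / float(np.sum(np.exp(gamma * ylog)))
    return float(c), float(gamma)


def transform_occupancy(
    ylog: np.ndarray,
    target_mean: float = TARGET_MEAN,
    gamma_max: float = 10.0,
) -> ReferenceTrack:
    """Map a log-ratio track to absolute occupancy Y = c * exp(gamma * Y_L)
    with genome mean `target_mean`, Y <= 1, and gamma maximised (capped at
    `gamma_max` when the ceiling never binds, e.g. a constant track)."""
    ylog = np.asarray(ylog, dtype=float)
    if not np.all(np.isfinite(ylog)):
        raise ValueError("log track must be finite (remove outliers upstream)")
    c, gamma = _solve_transform(ylog, target_mean, gamma_max)
    y = c * np.exp(gamma * ylog)
    return ReferenceTrack(y, ylog=ylog.copy(), c=c, gamma=gamma, target_mean=target_mean)


# ---------------------------------------------------------------------------
# NDR annotation
# ---------------------------------------------------------------------------


def _runs_below(y: np.ndarray, level: float) -> list[tuple[int, int]]:
    """Maximal half-open runs where y < level."""
    below = y < level
    if not below.any():
        return []
    d = np.diff(below.astype(np.int8))
    starts = list(np.flatnonzero(d == 1) + 1)
    ends = list(np.flatnonzero(d == -1) + 1)
    if below[0]:
        starts.insert(0, 0)
    if below[-1]:
        ends.append(y.size)
    return list(zip(starts, ends))


def _lines(lowest: float) -> np.ndarray:
    n = int(np.floor((TARGET_MEAN - lowest) / LINE_STEP)) + 2
    return TARGET_MEAN - LINE_STEP * np.arange(max(n, 1))


def annotate_ndrs(
    ref: ReferenceTrack | np.ndarray,
    *,
    min_width: int = _MIN_WIDTH,
    max_dx: int = _MAX_DX,
    merge_dist: int = _MERGE_DIST,
    cutoff: float = NDR_CUTOFF,
) -> list[NDR]:
    """Call NDRs on an absolute occupancy track with the three
    discretisation rules (width at the 73.2% line, flank steepness dx,
    center merging).  Returns intervals bounded by the crossings of the
    lowest discretisation line each dip reaches."""
    y = ref.y if isinstance(ref, ReferenceTrack) else np.asarray(ref, dtype=float)
    if y.size < 147:
        msg = f"track of {y.size} bp is shorter than one nucleosome; no NDRs called"
        logger.warning(msg)
        warnings.warn(msg, stacklevel=2)
        return []

    accepted: list[NDR] = []
    for a, b in _runs_below(y, TARGET_MEAN):
        seg = y[a:b]
        lowest = float(seg.min())
        lines = _lines(lowest)
        reached = lines[lines > lowest]
        if reached.size < 2:
            continue  # never crosses the 73.2% line
        # rule 1: outermost extent below the 73.2% line (bumps included)
        below1 = np.flatnonzero(seg < _WIDTH_LINE)
        width = int(below1[-1] - below1[0] + 1)
        if width <= min_width:
            continue
        # lowest line the dip reaches, and its outermost crossings
        low_line = float(reached[-1])
        below_low = np.flatnonzero(seg < low_line)
        lo, hi = int(below_low[0]), int(below_low[-1]) + 1  # half-open in seg
        # rule 2: dx from the 80% crossing (run edge) to the lowest crossing,
        # per flank; the steeper flank must be < max_dx
        dx_left = lo
        dx_right = (b - a) - hi
        if min(dx_left, dx_right) >= max_dx:
            continue
        start, end = a + lo, a + hi
        length = _extent_below(y, start, end, cutoff)
        accepted.append(NDR(start, end, (start + end - 1) / 2.0, length))

    return _merge_ndrs(accepted, merge_dist, y, cutoff)


def _extent_below(y: np.ndarray, start: int, end: int, cutoff: float) -> int:
    """Length of the contiguous sub-cutoff region containing the dip's
    minimum (it extends beyond [start, end), which is bounded by the lowest
    discretisation line rather than the cutoff)."""
    idx = np.flatnonzero(y[start:end] < cutoff)
    if idx.size == 0:
        return 0
    lo = start + int(idx[0])
    hi = start + int(idx[-1]) + 1
    while lo > 0 and y[lo - 1] < cutoff:
        lo -= 1
    while hi < y.size and y[hi] < cutoff:
        hi += 1
    return hi - lo


def _merge_ndrs(
    ndrs: list[NDR], merge_dist: int, y: np.ndarray, cutoff: float
) -> list[NDR]:
    if not ndrs:
        return []
    ndrs = sorted(ndrs, key=lambda n: n.center)
    merged: list[NDR] = [ndrs[0]]
    for n in ndrs[1:]:
        prev = merged[-1]
        if n.center - prev.center < merge_dist:
            start, end = prev.start, max(prev.end, n.end)
            merged[-1] = NDR(
                start, end, (start + end - 1) / 2.0, _extent_below(y, start, end, cutoff)
            )
        else:
            merged.append(n)
    return merged


def zero_ndrs_and_rescale(
    ref: ReferenceTrack, ndrs: list[NDR], gamma_max: float = 10.0
) -> ReferenceTrack:
    """Produce the modified reference: occupancy pinned to 0 inside each NDR
    interval, then the remaining track re-transformed so the genome mean is
    restored to the target."""
    if not ndrs:
        return ref.copy()
    mask = np.zeros(ref.L, dtype=bool)
    for n in ndrs:
        if n.start < 0 or n.end > ref.L:
            raise ValueError("NDR outside track bounds")
        mask[n.start : n.end] = True
    if ref.ylog is not None:
        ylog = ref.ylog
    else:
        # recover a log track from the absolute one (c=1, gamma=1 convention)
        ylog = np.log(np.maximum(ref.y, 1e-12))
    keep = ylog[~mask]
    c, gamma = _solve_transform(keep, ref.target_mean, gamma_max, n_total=ref.L)
    y = np.where(mask, 0.0, c * np.exp(gamma * ylog))
    return ReferenceTrack(y, ylog=ylog.copy(), c=c, gamma=gamma, target_mean=ref.target_mean)


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------


def rmsd(pred: np.ndarray, ref: np.ndarray) -> float:
    """Root-mean-square per-bp deviation between two occupancy tracks."""
    pred = np.asarray(pred, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if pred.shape != ref.shape:
        raise ValueError(f"length mismatch: {pred.shape} vs {ref.shape}")
    return float(np.sqrt(np.mean((pred - ref) ** 2)))


def predicted_ndr_intervals(
    pred: np.ndarray, cutoff: float = NDR_CUTOFF, min_run: int = 50
) -> list[tuple[int, int]]:
    """Maximal sub-cutoff runs of length >= `min_run` in a predicted track."""
    return [(a, b) for a, b in _runs_below(np.asarray(pred, float), cutoff) if b - a >= min_run]


def evaluate_prediction(
    pred: np.ndarray,
    ref_ndrs: list[NDR],
    *,
    ref: ReferenceTrack | np.ndarray | None = None,
    cutoff: float = NDR_CUTOFF,
    min_run: int = 50,
) -> EvalReport:
    """Score a predicted occupancy track against reference NDRs.

    A reference NDR is a hit iff a contiguous sub-cutoff run of >= `min_run`
    bp in the prediction overlaps it.  FPR is the per-bp fraction of non-NDR
    positions predicted below the cutoff; AUC scores (1 - predicted
    occupancy) against per-bp NDR labels.  RMSD is reported when `ref` is
    given (NaN otherwise).
    """
    pred = np.asarray(pred, dtype=float)
    if len(ref_ndrs) == 0:
        raise ValueError("no reference NDRs: P_NDR undefined")
    runs = predicted_ndr_intervals(pred, cutoff, min_run)
    hits, missed = [], []
    for n in ref_ndrs:
        if any(a < n.end and b > n.start for a, b in runs):
            hits.append(n)
        else:
            missed.append(n)
    labels = np.zeros(pred.size, dtype=bool)
    for n in ref_ndrs:
        labels[n.start : n.end] = True
    fp_intervals = [
        (a, b) for a, b in runs if not any(a < n.end and b > n.start for n in ref_ndrs)
    ]
    non_ndr = ~labels
    fpr = float(np.mean(pred[non_ndr] < cutoff)) if non_ndr.any() else 0.0
    auc = float(roc_auc_score(labels, 1.0 - pred)) if labels.any() and non_ndr.any() else np.nan
    if ref is not None:
        refy = ref.y if isinstance(ref, ReferenceTrack) else np.asarray(ref, float)
        r = rmsd(pred, refy)
    else:
        r = float("nan")
    return EvalReport(r, len(hits) / len(ref_ndrs), fpr, auc, hits, missed, fp_intervals)


__all__ = [
    "TARGET_MEAN",
    "LINE_STEP",
    "NDR_CUTOFF",
    "ReferenceTrack",
    "NDR",
    "EvalReport",
    "transform_occupancy",
    "annotate_ndrs",
    "zero_ndrs_and_rescale",
    "rmsd",
    "predicted_ndr_intervals",
    "evaluate_prediction",
]
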