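"""Sorting statistics for pair-matching: comparison design, threshold
classification, threshold sweep, distribution testing, and repeatability.

The experimental design compares every left element against every right
element within a group (all-against-all superimposition), yielding an RMS
value per cell.  Cells belonging to the same individual are *matches*, all
others *mismatches*; a pair is predicted a match when its RMS does not
exceed a threshold (inclusive rule — a match sitting exactly on the
threshold still counts as detected).

Repeatability follows the anthropometric convention: the technical error of
measurement TEM = sqrt(Σ d_i² / 2n) over paired repeated measurements, and
its relative form rTEM = 100·TEM / grand mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin

from .errors import ValidationError


# ---------------------------------------------------------------------------
# comparison matrix


@dataclass(frozen=True)
class ComparisonMatrix:
    """Left×right grid of RMS values with ground-truth pairing.

    ``rms_mm`` holds NaN for cells that were never compared (a pooled
    two-group matrix has no cross-group cells); every non-NaN cell is a
    performed superimposition.  Each left id and each right id belongs to at
    most one truth pair.
    """

    left_ids: tuple
    right_ids: tuple
    rms_mm: np.ndarray
    truth: frozenset
    group: str = "combined"

    def __post_init__(self):
        object.__setattr__(self, "left_ids", tuple(self.left_ids))
        object.__setattr__(self, "right_ids", tuple(self.right_ids))
        m = np.asarray(self.rms_mm, dtype=np.float64)
        object.__setattr__(self, "rms_mm", m)
        object.__setattr__(self, "truth", frozenset(tuple(p) for p in self.truth))
        if m.shape != (len(self.left_ids), len(self.right_ids)):
            raise ValidationError("rms_mm shape does not match id lists")
        valid = ~np.isnan(m)
        if not valid.any():
            raise ValidationError("comparison matrix has no cells")
        if np.any(m[valid] < 0) or np.any(np.isinf(m[valid])):
            raise ValidationError("RMS values must be finite and non-negative")
        li, ri = {}, {}
        for l, r in self.truth:
            if l not in self.left_ids or r not in self.right_ids:
                raise ValidationError(f"truth pair ({l}, {r}) has no matrix cell")
            if np.isnan(m[self.left_ids.index(l), self.right_ids.index(r)]):
                raise ValidationError(f"truth pair ({l}, {r}) was never compared")
            li[l] = li.get(l, 0) + 1
            ri[r] = ri.get(r, 0) + 1
        if any(c > 1 for c in li.values()) or any(c > 1 for c in ri.values()):
            raise ValidationError("an id appears in more than one truth pair")

    # -- flat views -------------------------------------------------------

    def cells(self) -> pd.DataFrame:
        """Long-format table of performed comparisons:
        columns left_id, right_id, rms_mm, is_match."""
        li, ri = np.nonzero(~np.isnan(self.rms_mm))
        rows = {"left_id": [self.left_ids[i] for i in li],
                "right_id": [self.right_ids[j] for j in ri],
                "rms_mm": self.rms_mm[li, ri]}
        df = pd.DataFrame(rows)
        truth = self.truth
        df["is_match"] = [(l, r) in truth
                          for l, r in zip(df["left_id"], df["right_id"])]
        return df

    @property
    def n_cells(self) -> int:
        return int((~np.isnan(self.rms_mm)).sum())

    @property
    def n_matches(self) -> int:
        return len(self.truth)

    @property
    def n_mismatches(self) -> int:
        return self.n_cells - self.n_matches

    def match_values(self) -> np.ndarray:
        df = self.cells()
        return df.loc[df.is_match, "rms_mm"].to_numpy()

    def mismatch_values(self) -> np.ndarray:
        df = self.cells()
        return df.loc[~df.is_match, "rms_mm"].to_numpy()

    # -- construction / IO ------------------------------------------------

    @classmethod
    def pooled(cls, matrices: Sequence["ComparisonMatrix"],
               group: str = "combined") -> "ComparisonMatrix":
        """Union of several (disjoint-id) matrices, e.g. the two per-sex
        matrices pooled into the combined analysis.  Cross-matrix cells stay
        absent: pooling adds no new superimpositions."""
        left_ids, right_ids, truth = [], [], set()
        for m in matrices:
            if set(m.left_ids) & set(left_ids) or set(m.right_ids) & set(right_ids):
                raise ValidationError("pooled matrices must have disjoint ids")
            left_ids += list(m.left_ids)
            right_ids += list(m.right_ids)
            truth |= set(m.truth)
        grid = np.full((len(left_ids), len(right_ids)), np.nan)
        r0 = c0 = 0
        for m in matrices:
            nr, nc = m.rms_mm.shape
            grid[r0:r0 + nr, c0:c0 + nc] = m.rms_mm
            r0 += nr
            c0 += nc
        return cls(left_ids, right_ids, grid, truth, group=group)

    def to_csv(self, path) -> None:
        pd.DataFrame(self.rms_mm, index=list(self.left_ids),
                     columns=list(self.right_ids)).to_csv(Path(path))

    @classmethod
    def from_csv(cls, matrix_path, truth_path, group: str = "combined"
                 ) -> "ComparisonMatrix":
        df = pd.read_csv(matrix_path, index_col=0)
        truth_df = pd.read_csv(truth_path)
        truth = set(zip(truth_df["left_id"].astype(str),
                        truth_df["right_id"].astype(str)))
        return cls(tuple(df.index.astype(str)), tuple(df.columns.astype(str)),
                   df.to_numpy(), truth, group=group)


def build_comparison_matrix(superimpositions: Iterable[tuple],
                            truth: Iterable[tuple],
                            group: str = "combined") -> ComparisonMatrix:
    """Assemble a ComparisonMatrix from ``(left_id, right_id, rms_mm)``
    records.  Every provided cell must appear exactly once; every truth pair
    must have a cell."""
    seen = set()
    left_ids, right_ids = [], []
    records = []
    for l, r, v in superimpositions:
        if (l, r) in seen:
            raise ValidationError(f"duplicate comparison cell ({l}, {r})")
        seen.add((l, r))
        if l not in left_ids:
            left_ids.append(l)
        if r not in right_ids:
            right_ids.append(r)
        records.append((l, r, float(v)))
    grid = np.full((len(left_ids), len(right_ids)), np.nan)
    li = {l: i for i, l in enumerate(left_ids)}
    ri = {r: j for j, r in enumerate(right_ids)}
    for l, r, v in records:
        grid[li[l], ri[r]] = v
    return ComparisonMatrix(left_ids, right_ids, grid, set(truth), group=group)


# ---------------------------------------------------------------------------
# classification


@dataclass(frozen=True)
class ClassificationReport:
    """Confusion counts and rates at one RMS threshold (inclusive rule)."""

    threshold_mm: float
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def sensitivity_raw(self) -> float:
        if self.tp + self.fn == 0:
            raise ValidationError("sensitivity undefined: no true pairs")
        return self.tp / (self.tp + self.fn)

    @property
    def specificity_raw(self) -> float:
        if self.tn + self.fp == 0:
            raise ValidationError("specificity undefined: no true non-pairs")
        return self.tn / (self.tn + self.fp)

    @property
    def sensitivity_pct(self) -> float:
        """Percent, rounded to one decimal (reporting convention)."""
        return round(100.0 * self.sensitivity_raw, 1)

    @property
    def specificity_pct(self) -> float:
        return round(100.0 * self.specificity_raw, 1)

    def to_dict(self) -> dict:
        doc = {"threshold_mm": self.threshold_mm,
               "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn}
        for key in ("sensitivity_pct", "specificity_pct",
                    "sensitivity_raw", "specificity_raw"):
            try:
                doc[key] = getattr(self, key)
            except ValidationError:        # degenerate design: rate undefined
                doc[key] = None
        return doc


def confusion_stats(tp: int, fp: int, tn: int, fn: int) -> tuple[float, float]:
    """(sensitivity %, specificity %) rounded to one decimal."""
    if min(tp, fp, tn, fn) < 0:
        raise ValidationError("confusion counts must be non-negative")
    rep = ClassificationReport(threshold_mm=np.nan, tp=tp, fp=fp, tn=tn, fn=fn)
    return rep.sensitivity_pct, rep.specificity_pct


def _confusion_at(rms: np.ndarray, is_match: np.ndarray,
                  threshold: float) -> tuple[int, int, int, int]:
    pred = rms <= threshold       # inclusive: a match at the threshold counts
    tp = int(np.sum(pred & is_match))
    fp = int(np.sum(pred & ~is_match))
    fn = int(np.sum(~pred & is_match))
    tn = int(np.sum(~pred & ~is_match))
    return tp, fp, tn, fn


def classify(matrix: ComparisonMatrix, threshold_mm: float) -> ClassificationReport:
    """Classify every cell: predicted match iff RMS ≤ threshold."""
    if not threshold_mm > 0:
        raise ValidationError("threshold must be > 0 mm")
    df = matrix.cells()
    tp, fp, tn, fn = _confusion_at(df["rms_mm"].to_numpy(),
                                   df["is_match"].to_numpy(), threshold_mm)
    return ClassificationReport(threshold_mm=float(threshold_mm),
                                tp=tp, fp=fp, tn=tn, fn=fn)


@dataclass(frozen=True)
class SweepResult:
    reports: tuple                      # (threshold, ClassificationReport) pairs
    recommended_threshold_mm: float
    recommended: ClassificationReport = field(repr=False, default=None)


def sweep_thresholds(matrix: ComparisonMatrix) -> SweepResult:
    """One classification report per unique observed RMS value used as the
    threshold, plus a recommended operating point: among thresholds with
    zero false negatives, those with the fewest false positives, and the
    largest of these (the max-match-RMS choice when separation allows it).
    """
    df = matrix.cells()
    rms = df["rms_mm"].to_numpy()
    is_match = df["is_match"].to_numpy()
    thresholds = np.unique(rms)
    reports = []
    for t in thresholds:
        tp, fp, tn, fn = _confusion_at(rms, is_match, t)
        reports.append((float(t), ClassificationReport(
            threshold_mm=float(t), tp=tp, fp=fp, tn=tn, fn=fn)))
    no_fn = [(t, r) for t, r in reports if r.fn == 0]
    if no_fn:
        min_fp = min(r.fp for _, r in no_fn)
        best_t, best_r = max((tr for tr in no_fn if tr[1].fp == min_fp),
                             key=lambda tr: tr[0])
    else:   # no truth pairs at all: fall back to the largest threshold
        best_t, best_r = reports[-1]
    return SweepResult(reports=tuple(reports), recommended_threshold_mm=best_t,
                       recommended=best_r)


class RMSThresholdClassifier(BaseEstimator, ClassifierMixin):
    """Threshold rule over RMS values as a scikit-learn classifier.

    ``fit(X, y)`` takes RMS values (n,) or (n, 1) and binary labels
    (1 = match).  With ``threshold_mm=None`` the fitted threshold is the
    sweep recommendation (largest threshold with zero false negatives and
    minimal false positives); otherwise the given threshold is used as-is.
    ``predict`` applies the inclusive rule ``rms <= threshold_``.
    """

    def __init__(self, threshold_mm: float | None = None):
        self.threshold_mm = threshold_mm

    @staticmethod
    def _to_1d(X) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if X.ndim == 2 and X.shape[1] == 1:
            X = X[:, 0]
        if X.ndim != 1:
            raise ValidationError("X must be (n,) or (n, 1) RMS values")
        return X

    def fit(self, X, y=None) -> "RMSThresholdClassifier":
        X = self._to_1d(X)
        if self.threshold_mm is not None:
            self.threshold_ = float(self.threshold_mm)
        else:
            if y is None:
                raise ValidationError("labels are required to fit a threshold")
            y = np.asarray(y).astype(bool)
            mat = build_comparison_matrix(
                [(f"L{i}", f"R{i}", v) for i, v in enumerate(X)],
                {(f"L{i}", f"R{i}") for i in np.flatnonzero(y)})
            self.threshold_ = sweep_thresholds(mat).recommended_threshold_mm
        self.classes_ = np.array([0, 1])
        return self

    def predict(self, X) -> np.ndarray:
        X = self._to_1d(X)
        return (X <= self.threshold_).astype(int)

    def decision_function(self, X) -> np.ndarray:
        """Higher = more match-like (threshold margin in mm)."""
        return self.threshold_ - self._to_1d(X)


# ---------------------------------------------------------------------------
# distribution test


def rank_sum_test(match_rms, mismatch_rms) -> tuple[float, float]:
    """Mann–Whitney U between match and mismatch RMS samples.

    Exact null distribution when the combined sample size is ≤ 20 and
    tie-free; otherwise the normal approximation with tie correction.
    Returns (U of the first sample, two-sided p).
    """
    x = np.asarray(match_rms, dtype=np.float64).reshape(-1)
    y = np.asarray(mismatch_rms, dtype=np.float64).reshape(-1)
    if len(x) == 0 or len(y) == 0:
        raise ValidationError("rank-sum test needs two non-empty samples")
    combined = np.concatenate([x, y])
    exact = (len(combined) <= 20
             and len(np.unique(combined)) == len(combined))
    res = stats.mannwhitneyu(x, y, alternative="two-sided",
                             method="exact" if exact else "asymptotic")
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# repeatability (TEM / rTEM)


@dataclass(frozen=True)
class RepeatabilityReport:
    tem_mm: float
    rtem_percent: float
    n_pairs: int
    mode: str = "intra"        # intra- or inter-observer


def tem(run1, run2, mode: str = "intra") -> RepeatabilityReport:
    """Technical error of measurement between two measurement runs.

    TEM = sqrt(Σ (run1_i − run2_i)² / 2n); rTEM = 100·TEM / grand mean of
    all 2n measurements.  Symmetric in its runs; scaling both runs by c > 0
    scales TEM by c and leaves rTEM unchanged.
    """
    a = np.asarray(run1, dtype=np.float64).reshape(-1)
    b = np.asarray(run2, dtype=np.float64).reshape(-1)
    if len(a) != len(b):
        raise ValidationError(f"run lengths differ: {len(a)} vs {len(b)}")
    if len(a) == 0:
        raise ValidationError("TEM needs at least one measurement pair")
    if mode not in ("intra", "inter"):
        raise ValidationError(f"unknown repeatability mode {mode!r}")
    t = float(np.sqrt(np.sum((a - b) ** 2) / (2 * len(a))))
    grand = float(np.mean(np.concatenate([a, b])))
    if abs(grand) < 1e-300:
        raise ValidationError("rTEM undefined: grand mean is zero")
    return RepeatabilityReport(tem_mm=t, rtem_percent=100.0 * t / grand,
                               n_pairs=len(a), mode=mode)


#: default qualitative bands for rTEM (%), configurable — upper bound → label
DEFAULT_RTEM_BANDS = ((1.0, "excellent"), (5.0, "very good"),
                      (10.0, "good"), (float("inf"), "poor"))


def rate_rtem(rtem_percent: float,
              bands=DEFAULT_RTEM_BANDS) -> str:
    """Qualitative rating of an rTEM value against configurable bands
    (ordered (upper_bound_percent, label) pairs)."""
    if rtem_percent < 0:
        raise ValidationError("rTEM cannot be negative")
    for bound, label in bands:
        if rtem_percent <= bound:
            return label
    raise ValidationError("bands do not cover the value")
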