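from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.base import clone

from osteopair import (ComparisonMatrix, RMSThresholdClassifier,
                       build_comparison_matrix, classify, confusion_stats,
                       rank_sum_test, sweep_thresholds, tem)
from osteopair.errors import ValidationError
from osteopair.pairmatch_stats import rate_rtem


def _design(n_left_extra, n_pairs, rng, group="g", match_lo=0.4, match_hi=0.9,
            mismatch_lo=1.0, mismatch_hi=5.0):
    """A synthetic all-against-all design: n_pairs paired individuals plus
    unpaired lefts, match RMS drawn low, mismatch RMS drawn high."""
    lefts = [f"{group}L{i}" for i in range(n_pairs + n_left_extra)]
    rights = [f"{group}R{i}" for i in range(n_pairs)]
    cells = []
    truth = {(f"{group}L{i}", f"{group}R{i}") for i in range(n_pairs)}
    for l in lefts:
        for r in rights:
            if (l, r) in truth:
                v = rng.uniform(match_lo, match_hi)
            else:
                v = rng.uniform(mismatch_lo, mismatch_hi)
            cells.append((l, r, v))
    return cells, truth


# --- comparison design -------------------------------------------------


def test_per_sex_design_counts():
    """22 lefts (20 paired + 2 unpaired) × 20 rights per sex: 440 cells,
    20 matches, 420 mismatches."""
    rng = np.random.default_rng(0)
    cells, truth = _design(2, 20, rng)
    m = build_comparison_matrix(cells, truth, group="males")
    assert m.n_cells == 440
    assert m.n_matches == 20
    assert m.n_mismatches == 420


def test_pooled_design_counts():
    """Two sexes pooled: 880 superimpositions, 40 matches, 840 mismatches."""
    rng = np.random.default_rng(1)
    mats = []
    for g in ("m", "f"):
        cells, truth = _design(2, 20, rng, group=g)
        mats.append(build_comparison_matrix(cells, truth, group=g))
    pooled = ComparisonMatrix.pooled(mats)
    assert pooled.n_cells == 880
    assert pooled.n_matches == 40
    assert pooled.n_mismatches == 840


def test_single_cell_matrix():
    m = build_comparison_matrix([("L", "R", 0.5)], {("L", "R")})
    assert (m.n_cells, m.n_matches, m.n_mismatches) == (1, 1, 0)


def test_duplicate_cell_rejected():
    with pytest.raises(ValidationError, match="duplicate"):
        build_comparison_matrix([("L", "R", 0.5), ("L", "R", 0.6)], set())


def test_truth_pair_without_cell_rejected():
    with pytest.raises(ValidationError):
        build_comparison_matrix([("L1", "R1", 0.5)], {("L2", "R1")})


def test_id_in_two_truth_pairs_rejected():
    cells = [("L1", "R1", 0.5), ("L1", "R2", 0.6), ("L2", "R1", 0.7),
             ("L2", "R2", 0.4)]
    with pytest.raises(ValidationError, match="more than one"):
        build_comparison_matrix(cells, {("L1", "R1"), ("L1", "R2")})


def test_matrix_csv_round_trip(tmp_path):
    rng = np.random.default_rng(2)
    cells, truth = _design(1, 3, rng)
    m = build_comparison_matrix(cells, truth)
    m.to_csv(tmp_path / "m.csv")
    (tmp_path / "t.csv").write_text(
        "left_id,right_id\n" + "\n".join(f"{l},{r}" for l, r in sorted(truth)))
    back = ComparisonMatrix.from_csv(tmp_path / "m.csv", tmp_path / "t.csv")
    np.testing.assert_allclose(back.rms_mm, m.rms_mm)
    assert back.truth == m.truth


# --- classification ----------------------------------------------------


def test_inclusive_threshold_rule():
    """A match sitting exactly on the threshold counts as detected, and a
    mismatch below the threshold is a false positive."""
    cells = [("L1", "R1", 0.91),     # match at exactly the threshold
             ("L1", "R2", 2.0), ("L2", "R1", 0.87),   # mismatch below t
             ("L2", "R2", 0.55)]
    m = build_comparison_matrix(cells, {("L1", "R1"), ("L2", "R2")})
    rep = classify(m, 0.91)
    assert rep.fn == 0
    assert rep.tp == 2
    assert rep.fp == 1            # the 0.87 mismatch
    assert rep.sensitivity_pct == 100.0


def test_threshold_below_minimum():
    cells = [("L1", "R1", 0.5), ("L1", "R2", 1.0), ("L2", "R1", 1.2),
             ("L2", "R2", 0.6)]
    m = build_comparison_matrix(cells, {("L1", "R1"), ("L2", "R2")})
    rep = classify(m, 0.01)
    assert rep.tp == 0 and rep.fp == 0
    assert rep.specificity_pct == 100.0


@pytest.mark.parametrize("counts,expected", [
    ((20, 1, 419, 0), (100.0, 99.8)),
    ((20, 5, 415, 0), (100.0, 98.8)),
    ((40, 6, 834, 0), (100.0, 99.3)),
])
def test_confusion_stats_reference_rows(counts, expected):
    """Sensitivity/specificity arithmetic on the reference confusion rows,
    exact after one-decimal rounding."""
    assert confusion_stats(*counts) == expected


def test_confusion_stats_undefined():
    with pytest.raises(ValidationError, match="sensitivity"):
        confusion_stats(0, 0, 10, 0)
    with pytest.raises(ValidationError, match="specificity"):
        confusion_stats(5, 0, 0, 0)


def test_report_count_invariants():
    rng = np.random.default_rng(3)
    cells, truth = _design(2, 5, rng)
    m = build_comparison_matrix(cells, truth)
    rep = classify(m, 0.9)
    assert rep.tp + rep.fn == m.n_matches
    assert rep.tn + rep.fp == m.n_mismatches
    assert rep.tp + rep.fp + rep.tn + rep.fn == m.n_cells


# --- sweep -------------------------------------------------------------


def test_sweep_recommends_max_match_rms():
    """With the max match RMS at 0.91 and overlapping mismatches below it,
    the recommended threshold is 0.91 (zero FN, minimal FP)."""
    cells = [("L1", "R1", 0.41), ("L2", "R2", 0.91),
             ("L1", "R2", 0.87), ("L2", "R1", 2.0)]
    m = build_comparison_matrix(cells, {("L1", "R1"), ("L2", "R2")})
    res = sweep_thresholds(m)
    assert res.recommended_threshold_mm == 0.91
    assert res.recommended.fn == 0 and res.recommended.fp == 1
    # idempotence: re-applying classify at the recommendation reproduces it
    assert classify(m, res.recommended_threshold_mm) == res.recommended


def test_sweep_perfect_separation():
    rng = np.random.default_rng(4)
    cells, truth = _design(1, 4, rng)      # matches < 0.9 < 1.0 < mismatches
    m = build_comparison_matrix(cells, truth)
    res = sweep_thresholds(m)
    assert res.recommended.sensitivity_pct == 100.0
    assert res.recommended.specificity_pct == 100.0


def test_sweep_all_equal_cells():
    cells = [("L1", "R1", 1.0), ("L1", "R2", 1.0), ("L2", "R1", 1.0),
             ("L2", "R2", 1.0)]
    m = build_comparison_matrix(cells, {("L1", "R1"), ("L2", "R2")})
    res = sweep_thresholds(m)
    assert len(res.reports) == 1
    assert res.recommended.sensitivity_pct == 100.0
    assert res.recommended.specificity_pct == 0.0


def test_sweep_monotone():
    """Sensitivity is non-decreasing and specificity non-increasing in the
    threshold."""
    rng = np.random.default_rng(5)
    cells, truth = _design(2, 8, rng, match_hi=2.0, mismatch_lo=0.5)
    m = build_comparison_matrix(cells, truth)
    reports = [r for _, r in sweep_thresholds(m).reports]
    sens = [r.sensitivity_raw for r in reports]
    spec = [r.specificity_raw for r in reports]
    assert all(a <= b + 1e-12 for a, b in zip(sens, sens[1:]))
    assert all(a >= b - 1e-12 for a, b in zip(spec, spec[1:]))


# --- rank-sum test -----------------------------------------------------


def exact_mw_p(x, y):
    """Enumeration oracle: exact two-sided p of the Mann–Whitney U under
    the permutation null (tie-free samples)."""
    pooled = np.concatenate([x, y])
    n = len(x)

    def u_of(idx):
        xs = pooled[list(idx)]
        ys = np.delete(pooled, list(idx))
        return np.sum(xs[:, None] > ys[None, :]) + 0.5 * np.sum(
            xs[:, None] == ys[None, :])

    u_obs = u_of(range(n))
    mean_u = n * (len(pooled) - n) / 2
    us = [u_of(c) for c in combinations(range(len(pooled)), n)]
    extreme = sum(abs(u - mean_u) >= abs(u_obs - mean_u) - 1e-12 for u in us)
    return extreme / len(us)


def test_rank_sum_complete_separation():
    u, p = rank_sum_test([1, 2, 3], [4, 5, 6])
    assert u == 0
    assert p == pytest.approx(0.1)        # 2 / C(6,3) = 2/20


def test_rank_sum_identical_samples():
    _, p = rank_sum_test([1.0, 2.0], [1.0, 2.0])
    assert p >= 0.99


@pytest.mark.parametrize("seed", range(4))
def test_rank_sum_matches_enumeration(seed):
    """Exact p-values agree with brute-force enumeration for small
    tie-free samples."""
    rng = np.random.default_rng(seed)
    x = rng.normal(0, 1, rng.integers(2, 5))
    y = rng.normal(0.8, 1, rng.integers(2, 5))
    _, p = rank_sum_test(x, y)
    assert p == pytest.approx(exact_mw_p(x, y), abs=1e-12)


def test_rank_sum_empty_sample():
    with pytest.raises(ValidationError):
        rank_sum_test([], [1.0])


# --- TEM / rTEM --------------------------------------------------------


def test_tem_closed_forms():
    rep = tem([1.0], [1.1])
    assert rep.tem_mm == pytest.approx(np.sqrt(0.01 / 2))
    assert rep.rtem_percent == pytest.approx(100 * np.sqrt(0.005) / 1.05,
                                             abs=1e-4)
    rep2 = tem([0.70, 0.50], [0.73, 0.47])
    assert rep2.tem_mm == pytest.approx(np.sqrt((0.0009 + 0.0009) / 4))
    assert tem([1.0, 2.0], [1.0, 2.0]).tem_mm == 0.0


def test_tem_errors():
    with pytest.raises(ValidationError):
        tem([1.0, 2.0], [1.0])
    with pytest.raises(ValidationError, match="grand mean"):
        tem([1.0], [-1.0])


@settings(deadline=None, derandomize=True)
@given(st.lists(st.floats(0.1, 10), min_size=1, max_size=20),
       st.floats(0.1, 10))
def test_tem_symmetry_and_scaling(values, c):
    """TEM is symmetric in its runs; scaling both runs by c scales TEM by c
    and leaves rTEM unchanged."""
    a = np.asarray(values)
    b = a[::-1]
    r1, r2 = tem(a, b), tem(b, a)
    assert r1.tem_mm == pytest.approx(r2.tem_mm)
    scaled = tem(c * a, c * b)
    assert scaled.tem_mm == pytest.approx(c * r1.tem_mm, rel=1e-9)
    assert scaled.rtem_percent == pytest.approx(r1.rtem_percent, rel=1e-9)


def test_rate_rtem_bands():
    assert rate_rtem(4.3) == "very good"
    assert rate_rtem(5.5, bands=((5.0, "tight"), (float("inf"), "loose"))) \
        == "loose"


# --- estimator surface -------------------------------------------------


def test_threshold_classifier_fit_predict():
    rng = np.random.default_rng(6)
    cells, truth = _design(2, 10, rng)
    m = build_comparison_matrix(cells, truth)
    df = m.cells()
    X = df["rms_mm"].to_numpy()
    y = df["is_match"].to_numpy().astype(int)
    clf = RMSThresholdClassifier().fit(X, y)
    assert clf.threshold_ == sweep_thresholds(m).recommended_threshold_mm
    pred = clf.predict(X)
    assert np.all(pred[y == 1] == 1)            # zero false negatives
    # fixed threshold passes through fit untouched
    fixed = RMSThresholdClassifier(threshold_mm=0.91).fit(X)
    assert fixed.threshold_ == 0.91
    assert clone(fixed).get_params()["threshold_mm"] == 0.91
    np.testing.assert_array_equal(fixed.predict([[0.91], [0.92]]), [1, 0])
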