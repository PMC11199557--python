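"""Inference chain against brute-force normal-equation and residual oracles."""

import numpy as np
import pytest
import scipy.stats

from striamap.stats import (
    DegenerateTestError, RankDeficientError, age_match, chi_squared_table,
    compute_lateralized_scores, encode_sex, run_group_ancova,
    run_paired_side_comparison, run_partial_correlation, subscore_item_codes,
)


# ---------------------------------------------------------------------------
# oracles (independent normal-equation / residual implementations)
# ---------------------------------------------------------------------------

def ancova_oracle(y, group, cov):
    """General-linear-model group F and partial eta^2 from normal equations."""
    y = np.asarray(y, float)
    levels = sorted(set(group))
    dummies = np.column_stack([(np.asarray(group) == g).astype(float)
                               for g in levels[1:]])
    X_full = np.column_stack([np.ones(len(y)), dummies] +
                             ([cov] if cov is not None else []))
    X_red = np.column_stack([np.ones(len(y))] +
                            ([cov] if cov is not None else []))

    def sse(X):
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        r = y - X @ beta
        return float(r @ r)

    sse_f, sse_r = sse(X_full), sse(X_red)
    q = len(levels) - 1
    dfe = len(y) - X_full.shape[1]
    F = ((sse_r - sse_f) / q) / (sse_f / dfe)
    eta = (sse_r - sse_f) / sse_r
    p = scipy.stats.f.sf(F, q, dfe)
    return F, p, eta


def partial_r_oracle(x, y, cov):
    Z = np.column_stack([np.ones(len(x)), cov])
    hat = Z @ np.linalg.solve(Z.T @ Z, Z.T)
    rx, ry = x - hat @ x, y - hat @ y
    return float(rx @ ry / np.sqrt((rx @ rx) * (ry @ ry)))


@pytest.fixture
def fixture_20():
    rng = np.random.default_rng(17)
    n = 20
    group = np.repeat(["a", "b"], n // 2)
    cov = np.column_stack([rng.normal(60, 8, n), rng.integers(0, 2, n)])
    y = (1.0 + 0.5 * (group == "b") + 0.03 * cov[:, 0]
         + rng.normal(0, 1, n))
    return y, group, cov


# ---------------------------------------------------------------------------
# ANCOVA
# ---------------------------------------------------------------------------

def test_identical_groups_give_null_f():
    y = np.tile(np.arange(10.0), 2)
    group = np.repeat(["a", "b"], 10)
    res = run_group_ancova(y, group)
    assert res.statistic == pytest.approx(0.0, abs=1e-12)
    assert res.p == pytest.approx(1.0)


def test_ancova_matches_normal_equation_oracle(fixture_20):
    y, group, cov = fixture_20
    res = run_group_ancova(y, group, cov)
    F, p, eta = ancova_oracle(y, group, cov)
    assert res.statistic == pytest.approx(F, abs=1e-9)
    assert res.p == pytest.approx(p, abs=1e-9)
    assert res.effect_size == pytest.approx(eta, abs=1e-10)


def test_three_group_ancova_with_posthoc(fixture_20):
    rng = np.random.default_rng(2)
    n = 30
    group = np.repeat(["a", "b", "c"], 10)
    cov = rng.normal(size=(n, 2))
    y = rng.normal(size=n) + (group == "c") * 2.0
    res = run_group_ancova(y, group, cov)
    F, p, eta = ancova_oracle(y, group, cov)
    assert res.statistic == pytest.approx(F, abs=1e-9)
    ph = res.posthoc
    assert len(ph) == 3                                  # all unordered pairs
    assert set(ph.columns) >= {"a", "b", "diff", "t", "p"}
    # LSD contrast for a vs c must flag the built-in shift
    p_ac = float(ph[(ph.a == "a") & (ph.b == "c")].p.iloc[0])
    assert p_ac < 0.01


def test_two_group_f_equals_squared_pooled_t():
    rng = np.random.default_rng(4)
    y = np.concatenate([rng.normal(0, 1, 12), rng.normal(0.7, 1, 15)])
    group = np.array(["a"] * 12 + ["b"] * 15)
    res = run_group_ancova(y, group)
    t, _ = scipy.stats.ttest_ind(y[:12], y[12:], equal_var=True)
    assert res.statistic == pytest.approx(t ** 2, abs=1e-9)


def test_collinear_design_raises_with_term_name():
    y = np.arange(10.0)
    group = np.repeat(["a", "b"], 5)
    cov = np.column_stack([np.ones(10), np.ones(10) * 2])   # both ~ intercept
    with pytest.raises(RankDeficientError, match="collinear"):
        run_group_ancova(y, group, cov)


# ---------------------------------------------------------------------------
# partial correlation
# ---------------------------------------------------------------------------

def test_constant_covariate_reduces_to_pearson():
    rng = np.random.default_rng(6)
    x, y = rng.normal(size=25), rng.normal(size=25)
    plain = scipy.stats.pearsonr(x, y)
    res = run_partial_correlation(x, y, np.full((25, 1), 3.0))
    assert res.statistic == pytest.approx(plain.statistic, abs=1e-10)


def test_outcome_linear_in_covariates_has_zero_partial_r():
    rng = np.random.default_rng(7)
    cov = rng.normal(size=(30, 2))
    x = rng.normal(size=30)
    y = 2.0 + cov @ np.array([1.5, -0.7])
    res = run_partial_correlation(x, y, cov)
    assert res.statistic == pytest.approx(0.0, abs=1e-9)


def test_partial_r_matches_residual_oracle_and_pingouin(fixture_20):
    y, _, cov = fixture_20
    rng = np.random.default_rng(9)
    x = y * 0.5 + rng.normal(0, 1, len(y))
    res = run_partial_correlation(x, y, cov)
    assert res.statistic == pytest.approx(partial_r_oracle(x, y, cov), abs=1e-10)

    pingouin = pytest.importorskip("pingouin")
    import pandas as pd
    df = pd.DataFrame({"x": x, "y": y, "c1": cov[:, 0], "c2": cov[:, 1]})
    pg = pingouin.partial_corr(df, x="x", y="y", covar=["c1", "c2"])
    assert res.statistic == pytest.approx(float(pg["r"].iloc[0]), abs=1e-8)
    assert res.p == pytest.approx(float(pg["p_val"].iloc[0]), abs=1e-8)


def test_partial_r_invariant_to_affine_covariate_transform(fixture_20):
    y, _, cov = fixture_20
    rng = np.random.default_rng(10)
    x = rng.normal(size=len(y))
    base = run_partial_correlation(x, y, cov)
    warped = cov @ np.array([[2.0, 0.3], [0.0, -5.0]]) + np.array([7.0, 1.0])
    res = run_partial_correlation(x, y, warped)
    assert res.statistic == pytest.approx(base.statistic, abs=1e-9)


def test_constant_residuals_rejected():
    x = np.full(10, 2.0)
    y = np.arange(10.0)
    with pytest.raises(DegenerateTestError):
        run_partial_correlation(x, y, None)


# ---------------------------------------------------------------------------
# paired side comparison
# ---------------------------------------------------------------------------

def test_identical_sides_give_null_t():
    v = np.arange(8.0)
    res = run_paired_side_comparison(v, v)
    assert res.statistic == 0.0 and res.p == 1.0 and res.effect_size == 0.0


def test_paired_t_matches_hand_computation():
    lo = np.array([3.0, 4.0, 6.0, 5.0, 7.0])
    hi = np.array([2.0, 4.5, 4.0, 4.0, 5.0])
    res = run_paired_side_comparison(lo, hi)
    d = lo - hi
    t_hand = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
    p_hand = 2 * scipy.stats.t.sf(abs(t_hand), len(d) - 1)
    assert res.statistic == pytest.approx(t_hand, abs=1e-12)
    assert res.p == pytest.approx(p_hand, abs=1e-12)
    assert res.effect_size == pytest.approx(d.mean() / d.std(ddof=1), abs=1e-12)


def test_swapping_sides_negates_t_and_d():
    rng = np.random.default_rng(12)
    lo, hi = rng.normal(size=9), rng.normal(size=9)
    a = run_paired_side_comparison(lo, hi)
    b = run_paired_side_comparison(hi, lo)
    assert a.statistic == pytest.approx(-b.statistic, abs=1e-12)
    assert a.effect_size == pytest.approx(-b.effect_size, abs=1e-12)
    assert a.p == pytest.approx(b.p, abs=1e-12)


def test_constant_nonzero_differences_rejected():
    with pytest.raises(DegenerateTestError):
        run_paired_side_comparison(np.array([2.0, 3.0]), np.array([1.0, 2.0]))


# ---------------------------------------------------------------------------
# lateralized MDS-UPDRS III scores
# ---------------------------------------------------------------------------

def test_equal_sides_flagged_excluded():
    items = {"4R": 2, "4L": 2, "15R": 1, "15L": 1}
    lat = compute_lateralized_scores(items)
    assert lat.excluded and lat.low_side is None


def test_non_lateralized_items_never_contribute():
    # item 3a (neck rigidity) and 17e (lip/jaw) are in the exclusion list
    lat = compute_lateralized_scores({"3a": 4, "17e": 3, "1": 2})
    assert lat.left == 0 and lat.right == 0 and lat.excluded


def test_right_sided_tremor_fixture():
    # rest/postural/kinetic tremor on the right limbs only
    items = {"15R": 1, "16R": 1, "17a": 1, "17c": 1, "18": 3, "17e": 2}
    lat = compute_lateralized_scores(items, "tremor")
    assert lat.right == 4 and lat.left == 0
    assert lat.low_side == "L"


def test_item9_overlap_switch():
    assert "9" in subscore_item_codes("bradykinesia")
    assert "9" not in subscore_item_codes("bradykinesia", drop_overlap=True)
    assert "9" in subscore_item_codes("axial", drop_overlap=True)


def test_unknown_item_code_rejected():
    with pytest.raises(ValueError, match="unknown"):
        compute_lateralized_scores({"99x": 1})


def test_exclusion_count_matches_equal_side_subjects():
    rng = np.random.default_rng(13)
    n_excluded = 0
    n = 40
    for _ in range(n):
        r = int(rng.integers(0, 3))
        l = int(rng.integers(0, 3))
        lat = compute_lateralized_scores({"4R": r, "4L": l})
        n_excluded += lat.excluded
        assert lat.excluded == (r == l)
    assert 0 < n_excluded < n


# ---------------------------------------------------------------------------
# age matching
# ---------------------------------------------------------------------------

def test_disjoint_age_ranges_yield_no_matches(rng):
    assert age_match([25, 27, 29], [71, 75], rng=rng) == []


def test_identical_age_lists_match_fully(rng):
    ages = [50.0, 55.0, 60.0, 65.0]
    pairs = age_match(ages, ages, rng=rng)
    assert len(pairs) == 4
    assert all(ages[i] == ages[j] for i, j in pairs)


def test_greedy_matching_equals_exhaustive_oracle_for_fixed_order():
    cases = np.array([60.0, 52.0, 47.0, 71.0, 64.0, 58.0, 55.0, 49.0, 66.0, 62.0])
    controls = np.array([59.0, 50.0, 73.0, 61.0, 56.0])
    seed = 99
    pairs = age_match(cases, controls, tolerance_years=5.0,
                      rng=np.random.default_rng(seed))
    # oracle: replay the greedy procedure explicitly for the same seed
    order = np.random.default_rng(seed).permutation(len(cases))
    used = set()
    expected = []
    for ci in order:
        best, best_gap = None, np.inf
        for j, c in enumerate(controls):
            if j in used:
                continue
            gap = abs(c - cases[ci])
            if gap < best_gap:
                best, best_gap = j, gap
        if best is not None and best_gap <= 5.0:
            used.add(best)
            expected.append((int(ci), best))
    assert pairs == expected
    assert 0 < len(pairs) <= len(controls)


# ---------------------------------------------------------------------------
# chi-squared
# ---------------------------------------------------------------------------

def test_proportional_table_is_null():
    res = chi_squared_table([[10, 20], [5, 10], [20, 40]])
    assert res.statistic == pytest.approx(0.0, abs=1e-12)
    assert res.p == pytest.approx(1.0)
    assert res.df == 2


def test_two_by_two_matches_hand_computation():
    table = np.array([[12.0, 8.0], [5.0, 15.0]])
    exp = np.outer(table.sum(1), table.sum(0)) / table.sum()
    chi_hand = ((table - exp) ** 2 / exp).sum()
    res = chi_squared_table(table)
    assert res.statistic == pytest.approx(chi_hand, abs=1e-12)


def test_zero_marginal_rejected():
    with pytest.raises(ValueError, match="marginal"):
        chi_squared_table([[0, 0], [3, 4]])


def test_encode_sex_binary():
    np.testing.assert_array_equal(encode_sex(["M", "F", "M"]), [1.0, 0.0, 1.0])
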