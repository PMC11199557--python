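"""Cohort inference: ANCOVA, partial correlations, paired side comparisons.

The chain mirrors a conventional neuroimaging-cohort analysis: one-way
ANCOVA (Type-III group effect with age/sex covariates, partial eta squared,
unadjusted least-significant-difference post-hoc contrasts on the
covariate-adjusted means), two-tailed partial correlations by the residual
method, paired Student's t-tests between hemispheres stratified by putaminal
SBR or by lateralized MDS-UPDRS III scores (Cohen's d on the paired
differences), greedy randomized age matching, and Pearson's chi-squared for
sex distributions.  No multiple-testing correction is applied anywhere: the
post-hoc contrasts are deliberately unadjusted LSD tests and the analysis
reports raw two-tailed p values.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.stats
import statsmodels.api as sm

# ---------------------------------------------------------------------------
# MDS-UPDRS III item catalogue
# ---------------------------------------------------------------------------

#: side of the body each lateralized item code scores (right body side is
#: contralateral to the left hemisphere)
ITEM_SIDE: dict[str, str] = {
    "3b": "R", "3c": "L", "3d": "R", "3e": "L",
    "4R": "R", "4L": "L", "5R": "R", "5L": "L", "6R": "R", "6L": "L",
    "7R": "R", "7L": "L", "8R": "R", "8L": "L",
    "15R": "R", "15L": "L", "16R": "R", "16L": "L",
    "17a": "R", "17b": "L", "17c": "R", "17d": "L",
}

#: items with no lateralization, excluded from lateralized score sums
#: (items 1, 2, 3a, 9-14, 17e and 18)
NON_LATERALIZED: tuple[str, ...] = (
    "1", "2", "3a", "9", "10", "11", "12", "13", "14", "17e", "18",
)

ALL_ITEM_CODES: tuple[str, ...] = NON_LATERALIZED + tuple(ITEM_SIDE)

#: motor subscore families as printed: tremor (items 15-18), bradykinesia
#: (items 2, 4-9 and 14), rigidity (item 3), axial (items 1 and 9-13).
#: Item 9 appears in both the bradykinesia and the axial listing; it is kept
#: in both (see ``subscore_item_codes`` for the switch dropping the overlap).
SUBSCORE_ITEM_CODES: dict[str, tuple[str, ...]] = {
    "tremor": ("15R", "15L", "16R", "16L", "17a", "17b", "17c", "17d", "17e", "18"),
    "bradykinesia": ("2", "4R", "4L", "5R", "5L", "6R", "6L", "7R", "7L",
                     "8R", "8L", "9", "14"),
    "rigidity": ("3a", "3b", "3c", "3d", "3e"),
    "axial": ("1", "9", "10", "11", "12", "13"),
    "total": ALL_ITEM_CODES,
}


def subscore_item_codes(name: str, drop_overlap: bool = False) -> tuple[str, ...]:
    """Item codes of a subscore; ``drop_overlap`` removes the duplicated
    item 9 from bradykinesia (it then counts only toward axial)."""
    codes = SUBSCORE_ITEM_CODES[name]
    if drop_overlap and name == "bradykinesia":
        codes = tuple(c for c in codes if c != "9")
    return codes


class DegenerateTestError(ValueError):
    pass


class RankDeficientError(ValueError):
    pass


@dataclass
class AnalysisResult:
    name: str
    statistic: float
    df: tuple[float, float] | float
    p: float
    effect_name: str = ""
    effect_size: float = float("nan")
    n: int = 0
    terms: tuple[str, ...] = ()
    posthoc: pd.DataFrame | None = None


# ---------------------------------------------------------------------------
# ANCOVA
# ---------------------------------------------------------------------------

def _as_covariate_matrix(covariates) -> tuple[np.ndarray, tuple[str, ...]]:
    if covariates is None:
        return np.empty((0, 0)), ()
    if isinstance(covariates, pd.DataFrame):
        names = tuple(str(c) for c in covariates.columns)
        mat = covariates.to_numpy(dtype=float)
    else:
        mat = np.asarray(covariates, dtype=float)
        if mat.ndim == 1:
            mat = mat[:, None]
        names = tuple(f"cov{i}" for i in range(mat.shape[1]))
    return mat, names


def encode_sex(sex: Sequence[str]) -> np.ndarray:
    """Two-level sex factor as a single 0/1 covariate (male = 1)."""
    return np.asarray([1.0 if s in ("M", "m", "male", 1) else 0.0 for s in sex])


def run_group_ancova(outcome, group, covariates=None, name: str = "ancova") -> AnalysisResult:
    """One-way ANCOVA: Type-III F for the group factor.

    partial eta^2 = SS_group / (SS_group + SS_error); the post-hoc table
    holds unadjusted pairwise LSD contrasts on the covariate-adjusted group
    means, using the pooled error term of the full model.
    """
    y = np.asarray(outcome, dtype=float)
    group = np.asarray(group)
    levels = sorted(pd.unique(group).tolist())
    if len(levels) < 2:
        raise ValueError("need >= 2 groups")
    for lev in levels:
        if (group == lev).sum() < 2:
            raise ValueError(f"group {lev!r} has fewer than 2 subjects")
    cov, cov_names = _as_covariate_matrix(covariates)
    n = y.size

    dummies = np.column_stack([(group == lev).astype(float) for lev in levels[1:]])
    parts = [np.ones((n, 1)), dummies]
    if cov.size:
        parts.append(cov)
    X = np.column_stack(parts)
    colnames = ["intercept"] + [f"group[{lev}]" for lev in levels[1:]] + list(cov_names)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify a dependent column via QR column pivoting
        _, r, piv = scipy.linalg.qr(X, pivoting=True)
        bad = [colnames[j] for j in piv[rank:]]
        raise RankDeficientError(f"design is rank deficient; collinear term(s): {bad}")

    full = sm.OLS(y, X).fit()
    X_red = np.delete(X, np.s_[1:len(levels)], axis=1)
    red = sm.OLS(y, X_red).fit()
    q = len(levels) - 1
    ss_group = float(red.ssr - full.ssr)
    df_err = float(full.df_resid)
    f_stat = (ss_group / q) / (full.ssr / df_err)
    p = float(scipy.stats.f.sf(f_stat, q, df_err))
    eta = ss_group / (ss_group + float(full.ssr))

    rows = []
    k = len(levels)
    for i in range(k):
        for j in range(i + 1, k):
            c = np.zeros(X.shape[1])
            if i > 0:
                c[i] = 1.0
            if j > 0:
                c[j] = -1.0
            tt = full.t_test(c)
            rows.append({
                "a": levels[i], "b": levels[j],
                "diff": float(np.atleast_1d(tt.effect)[0]),
                "t": float(np.atleast_1d(tt.tvalue).ravel()[0]),
                "p": float(np.atleast_1d(tt.pvalue).ravel()[0]),
            })
    posthoc = pd.DataFrame(rows)
    return AnalysisResult(
        name=name, statistic=float(f_stat), df=(float(q), df_err), p=p,
        effect_name="partial_eta_sq", effect_size=float(eta), n=n,
        terms=tuple(colnames), posthoc=posthoc,
    )


# ---------------------------------------------------------------------------
# partial correlation
# ---------------------------------------------------------------------------

def run_partial_correlation(x, y, covariates=None, name: str = "partial_r") -> AnalysisResult:
    """Two-tailed partial correlation by the residual method.

    r is the Pearson correlation of the residuals of x and y after OLS on
    the covariates; p from t = r * sqrt((n - k - 2) / (1 - r^2)).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    cov, _ = _as_covariate_matrix(covariates)
    n = x.size
    k = cov.shape[1] if cov.size else 0
    if n <= k + 2:
        raise ValueError(f"need n > k + 2 (n={n}, k={k})")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateTestError("constant variable: partial r undefined")
    Z = np.column_stack([np.ones(n)] + ([cov] if cov.size else []))
    rx = x - Z @ np.linalg.lstsq(Z, x, rcond=None)[0]
    ry = y - Z @ np.linalg.lstsq(Z, y, rcond=None)[0]
    sx, sy = np.sqrt((rx ** 2).sum()), np.sqrt((ry ** 2).sum())
    dof = n - k - 2
    if sx < 1e-12 * max(1.0, np.abs(x).max()) or sy < 1e-12 * max(1.0, np.abs(y).max()):
        # a variable perfectly explained by the covariates carries no
        # residual association: r = 0 by convention
        return AnalysisResult(name=name, statistic=0.0, df=float(dof), p=1.0,
                              effect_name="partial_r", effect_size=0.0, n=n)
    r = float((rx * ry).sum() / (sx * sy))
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) >= 1.0:
        t = np.inf * np.sign(r)
        p = 0.0
    else:
        t = r * np.sqrt(dof / (1.0 - r ** 2))
        p = float(2.0 * scipy.stats.t.sf(abs(t), dof))
    return AnalysisResult(name=name, statistic=float(r), df=float(dof), p=p,
                          effect_name="partial_r", effect_size=float(r), n=n)


# ---------------------------------------------------------------------------
# paired side comparison
# ---------------------------------------------------------------------------

def run_paired_side_comparison(values_low, values_high, name: str = "paired") -> AnalysisResult:
    """Two-tailed paired Student's t (low side minus high side).

    Cohen's d = mean(diff) / SD(diff) on the paired differences.
    """
    lo = np.asarray(values_low, dtype=float)
    hi = np.asarray(values_high, dtype=float)
    if lo.shape != hi.shape or lo.ndim != 1 or lo.size < 2:
        raise ValueError("paired vectors must be equal-length 1-D with n >= 2")
    diff = lo - hi
    sd = diff.std(ddof=1)
    if sd == 0 and diff.mean() != 0:
        raise DegenerateTestError("zero-variance nonzero differences")
    if sd == 0:
        # identical vectors: no evidence of a difference
        return AnalysisResult(name=name, statistic=0.0, df=float(lo.size - 1),
                              p=1.0, effect_name="cohen_d", effect_size=0.0,
                              n=lo.size)
    t, p = scipy.stats.ttest_rel(lo, hi)
    d = float(diff.mean() / sd)
    return AnalysisResult(name=name, statistic=float(t), df=float(lo.size - 1),
                          p=float(p), effect_name="cohen_d", effect_size=d,
                          n=lo.size)


# ---------------------------------------------------------------------------
# lateralized MDS-UPDRS III scores
# ---------------------------------------------------------------------------

@dataclass
class LateralizedScore:
    left: int
    right: int
    excluded: bool               # equal sides: excluded from paired tests
    items_used: tuple[str, ...] = ()

    @property
    def low_side(self) -> str | None:
        if self.excluded:
            return None
        return "L" if self.left < self.right else "R"


def compute_lateralized_scores(
    items: Mapping[str, int], subscore: str = "total", drop_overlap: bool = False
) -> LateralizedScore:
    """Left/right sums of the lateralized items of a (sub)score.

    Only items with left/right versions contribute; the non-lateralized
    items (1, 2, 3a, 9-14, 17e, 18) never enter either side.  Subjects with
    identical sums on both sides are flagged excluded.
    """
    for code in items:
        if code not in ALL_ITEM_CODES:
            raise ValueError(f"unknown MDS-UPDRS III item code: {code!r}")
    codes = [c for c in subscore_item_codes(subscore, drop_overlap)
             if c in ITEM_SIDE]
    left = sum(int(items.get(c, 0)) for c in codes if ITEM_SIDE[c] == "L")
    right = sum(int(items.get(c, 0)) for c in codes if ITEM_SIDE[c] == "R")
    return LateralizedScore(left=left, right=right, excluded=(left == right),
                            items_used=tuple(codes))


# ---------------------------------------------------------------------------
# age matching
# ---------------------------------------------------------------------------

def age_match(
    case_ages,
    control_ages,
    tolerance_years: float = 5.0,
    rng: np.random.Generator | None = None,
) -> list[tuple[int, int]]:
    """Greedy randomized 1:1 age matching.

    Cases are visited in randomized order; each is matched to the nearest
    unused control within the tolerance (ties to the lower index).
    Unmatched cases are dropped.  Returns (case_index, control_index) pairs.
    """
    rng = rng or np.random.default_rng()
    cases = np.asarray(case_ages, dtype=float)
    controls = np.asarray(control_ages, dtype=float)
    order = rng.permutation(cases.size)
    used = np.zeros(controls.size, dtype=bool)
    pairs: list[tuple[int, int]] = []
    for ci in order:
        gap = np.abs(controls - cases[ci])
        gap[used] = np.inf
        j = int(np.argmin(gap))
        if gap[j] <= tolerance_years:
            used[j] = True
            pairs.append((int(ci), j))
    return pairs


# ---------------------------------------------------------------------------
# chi-squared
# ---------------------------------------------------------------------------

def chi_squared_table(counts, name: str = "chi2") -> AnalysisResult:
    """Pearson chi-squared on an r x c contingency table (no continuity
    correction), df = (r - 1)(c - 1)."""
    table = np.asarray(counts, dtype=float)
    if table.ndim != 2:
        raise ValueError("contingency table must be 2-D")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("zero marginal: expected counts undefined")
    chi2, p, dof, _ = scipy.stats.chi2_contingency(table, correction=False)
    return AnalysisResult(name=name, statistic=float(chi2), df=float(dof),
                          p=float(p), effect_name="", n=int(table.sum()))
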