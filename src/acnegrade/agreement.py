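"""Inter-rater agreement machinery for ordinal severity ratings.

Implements linear weighted Cohen's kappa (agreement form), pairwise-kappa
rater ranking and panel selection, median consensus labels, the two-way
random-effects absolute-agreement average-measures intraclass correlation
ICC(2,k) with an F-based 95% CI, and confusion matrices.

Rating matrices are pandas DataFrames: subjects as rows (index = subject
ids), raters as columns, entries ordinal grades 1..n_levels; NaN marks a
missing rating. Missing entries are dropped pairwise for kappa and
complete-case for the ICC.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AcnegradeError, InvalidGradeError, UndefinedStatisticError
from .scale import N_GRADES

logger = logging.getLogger(__name__)


def _as_grade_array(a, n_levels: int) -> np.ndarray:
    arr = np.asarray(a, dtype=float)
    finite = arr[np.isfinite(arr)]
    if ((finite < 1) | (finite > n_levels) | (finite != np.round(finite))).any():
        raise InvalidGradeError(f"grades must be integers in 1..{n_levels}")
    return arr


def linear_weighted_kappa(a, b, n_levels: int = N_GRADES) -> float:
    """Cohen's kappa with linear weights between two raters.

    With agreement weights ``w(i, j) = 1 - |i - j| / (n_levels - 1)``,

        kappa = (sum(w * O) - sum(w * E)) / (n - sum(w * E))

    where O is the observed contingency table and E the outer product of
    its marginals divided by n. Disagreements are penalized in proportion
    to their ordinal distance; the result lies in [-1, 1].

    Pairs with a missing entry are dropped. Two identical constant raters
    return 1.0 by convention (logged); any other zero-expected-disagreement
    case raises :class:`UndefinedStatisticError`.
    """
    a = _as_grade_array(a, n_levels)
    b = _as_grade_array(b, n_levels)
    if a.shape != b.shape:
        raise AcnegradeError("rating vectors must have equal length")
    keep = np.isfinite(a) & np.isfinite(b)
    a, b = a[keep].astype(int), b[keep].astype(int)
    n = a.size
    if n < 2:
        raise AcnegradeError("need >= 2 complete rating pairs")

    obs = np.zeros((n_levels, n_levels))
    np.add.at(obs, (a - 1, b - 1), 1.0)
    exp = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / n
    levels = np.arange(n_levels)
    w = 1.0 - np.abs(levels[:, None] - levels[None, :]) / (n_levels - 1)

    denom = n - (w * exp).sum()
    if abs(denom) < 1e-12:
        if np.array_equal(a, b):
            logger.warning("identical constant raters: kappa defined as 1.0 by convention")
            return 1.0
        raise UndefinedStatisticError("zero expected disagreement; kappa undefined")
    return float(((w * obs).sum() - (w * exp).sum()) / denom)


def pairwise_kappa_matrix(ratings: pd.DataFrame, n_levels: int = N_GRADES) -> pd.DataFrame:
    """Symmetric rater x rater matrix of linear weighted kappas.

    Diagonal is NaN (excluded from per-rater means by convention); an
    undefined pair is flagged NaN rather than raising.
    """
    raters = list(ratings.columns)
    if len(raters) < 2:
        raise AcnegradeError("need >= 2 raters")
    out = pd.DataFrame(np.nan, index=raters, columns=raters, dtype=float)
    for i, ri in enumerate(raters):
        for rj in raters[i + 1 :]:
            try:
                k = linear_weighted_kappa(ratings[ri], ratings[rj], n_levels)
            except UndefinedStatisticError:
                k = np.nan
            out.loc[ri, rj] = out.loc[rj, ri] = k
    return out


def mean_pairwise_kappa(ratings: pd.DataFrame, n_levels: int = N_GRADES) -> pd.Series:
    """Per-rater mean of off-diagonal pairwise kappas, descending order."""
    km = pairwise_kappa_matrix(ratings, n_levels)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        means = km.mean(axis=1, skipna=True)
    return means.sort_values(ascending=False, kind="stable")


def select_top_raters(ratings: pd.DataFrame, k: int = 3, n_levels: int = N_GRADES) -> list:
    """The k raters with the highest mean pairwise kappa.

    Ties are broken by column order of the rating matrix (stable sort).
    """
    if k < 1:
        raise AcnegradeError("k must be >= 1")
    if k > ratings.shape[1]:
        raise AcnegradeError(f"k={k} exceeds the {ratings.shape[1]} raters")
    means = mean_pairwise_kappa(ratings, n_levels)
    return list(means.index[:k])


def median_true_label(ratings: pd.DataFrame) -> pd.Series:
    """Per-subject median grade over an odd-sized selected rater panel.

    With integer grades and an odd rater count the median is itself an
    integer grade.
    """
    if ratings.shape[1] % 2 == 0:
        raise AcnegradeError("median consensus requires an odd number of raters")
    med = ratings.median(axis=1)
    return med.astype(int)


# ---------------------------------------------------------------------------
# ICC


def _anova_mean_squares(x: np.ndarray) -> tuple[float, float, float]:
    """(MSR, MSC, MSE): subject, rater, residual mean squares of a complete
    two-way subjects x raters layout with one observation per cell."""
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((x - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    return ss_rows / (n - 1), ss_cols / (k - 1), ss_err / ((n - 1) * (k - 1))


def icc_agreement(
    ratings: pd.DataFrame, confidence: float = 0.95, average_measures: bool = True
) -> tuple[float, tuple[float, float]]:
    """Two-way random-effects, absolute-agreement ICC with an F-based CI.

    Average-measures (``ICC(2,k)``, the default) treats the panel's mean
    rating as the measurement, matching a consensus-of-raters design;
    ``average_measures=False`` gives the single-measures ICC(2,1). Rows
    with any missing rating are dropped (complete-case).

    Returns ``(icc, (ci_lower, ci_upper))``.
    """
    x = ratings.dropna(axis=0, how="any").to_numpy(dtype=float)
    n, k = x.shape
    if n < 2 or k < 2:
        raise AcnegradeError("ICC needs >= 2 complete subjects and >= 2 raters")
    msr, msc, mse = _anova_mean_squares(x)
    denom_k = msr + (msc - mse) / n
    if abs(denom_k) < 1e-12 or np.isclose(msr, 0.0):
        raise UndefinedStatisticError("zero between-subject variance; ICC undefined")
    icc_k = (msr - mse) / denom_k
    icc_1 = (msr - mse) / (msr + (k - 1) * mse + (k / n) * (msc - mse))
    if mse < 1e-12 * msr:  # perfect agreement: the F interval degenerates
        if average_measures:
            return float(icc_k), (float(icc_k), float(icc_k))
        return float(icc_1), (float(icc_1), float(icc_1))

    # Satterthwaite F-based interval for ICC(2,1), Spearman-Brown stepped
    # up to the average-measures form.
    alpha = 1.0 - confidence
    fj = msc / mse if mse > 0 else np.inf
    r = icc_1
    vn = (k - 1) * (n - 1) * (k * r * fj + n * (1 + (k - 1) * r) - k * r) ** 2
    vd = (n - 1) * k**2 * r**2 * fj**2 + (n * (1 + (k - 1) * r) - k * r) ** 2
    v = vn / vd
    f1 = stats.f.ppf(1 - alpha / 2, n - 1, v)
    f2 = stats.f.ppf(1 - alpha / 2, v, n - 1)
    l1 = n * (msr - f1 * mse) / (f1 * (k * msc + (k * n - k - n) * mse) + n * msr)
    u1 = n * (f2 * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f2 * msr)

    def step_up(r1: float) -> float:
        return k * r1 / (1 + (k - 1) * r1)

    if average_measures:
        return float(icc_k), (float(step_up(l1)), float(step_up(u1)))
    return float(icc_1), (float(l1), float(u1))


# ---------------------------------------------------------------------------
# confusion matrix


def confusion_matrix(pred, truth, n_levels: int = N_GRADES) -> np.ndarray:
    """n_levels x n_levels counts; entry (t-1, p-1) counts truth t predicted p."""
    p = _as_grade_array(pred, n_levels)
    t = _as_grade_array(truth, n_levels)
    if p.shape != t.shape:
        raise AcnegradeError("pred and truth must have equal length")
    if not (np.isfinite(p).all() and np.isfinite(t).all()):
        raise InvalidGradeError("confusion matrix requires complete grades")
    cm = np.zeros((n_levels, n_levels), dtype=int)
    np.add.at(cm, (t.astype(int) - 1, p.astype(int) - 1), 1)
    return cm


def agreement_report(ratings: pd.DataFrame, k_select: int = 3, n_levels: int = N_GRADES) -> dict:
    """Full panel report: pairwise matrix, ranking, selection, ICC."""
    km = pairwise_kappa_matrix(ratings, n_levels)
    means = mean_pairwise_kappa(ratings, n_levels)
    icc, ci = icc_agreement(ratings)
    return {
        "pairwise_kappa": km.to_dict(),
        "mean_pairwise_kappa": {str(k): float(v) for k, v in means.items()},
        "ranking": [str(r) for r in means.index],
        "selected": [str(r) for r in select_top_raters(ratings, k_select, n_levels)],
        "icc": {"value": icc, "ci95": [ci[0], ci[1]]},
    }
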