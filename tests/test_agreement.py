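"""Agreement statistics: weighted kappa, rater selection, consensus, ICC."""

import numpy as np
import pandas as pd
import pytest

from acnegrade.agreement import (
    _anova_mean_squares,
    agreement_report,
    confusion_matrix,
    icc_agreement,
    linear_weighted_kappa,
    mean_pairwise_kappa,
    median_true_label,
    pairwise_kappa_matrix,
    select_top_raters,
)
from acnegrade.errors import AcnegradeError, InvalidGradeError, UndefinedStatisticError

# ---------------------------------------------------------------------------
# independent oracles


def oracle_kappa(a, b, n_levels):
    """Disagreement-form linear weighted kappa by explicit double loops."""
    a, b = list(a), list(b)
    n = len(a)
    obs = [[0.0] * n_levels for _ in range(n_levels)]
    for x, y in zip(a, b):
        obs[x - 1][y - 1] += 1
    row = [sum(obs[i]) for i in range(n_levels)]
    col = [sum(obs[i][j] for i in range(n_levels)) for j in range(n_levels)]
    num = den = 0.0
    for i in range(n_levels):
        for j in range(n_levels):
            d = abs(i - j) / (n_levels - 1)
            num += d * obs[i][j]
            den += d * row[i] * col[j] / n
    return 1.0 - num / den


def oracle_icc2k(x):
    """ICC(2,k) from an explicitly assembled two-way ANOVA table."""
    x = np.asarray(x, float)
    n, k = x.shape
    grand = x.mean()
    msr = k * sum((x[i].mean() - grand) ** 2 for i in range(n)) / (n - 1)
    msc = n * sum((x[:, j].mean() - grand) ** 2 for j in range(k)) / (k - 1)
    sse = sum(
        (x[i, j] - x[i].mean() - x[:, j].mean() + grand) ** 2
        for i in range(n)
        for j in range(k)
    )
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (msc - mse) / n)


# ---------------------------------------------------------------------------
# kappa


class TestLinearWeightedKappa:
    def test_perfect_agreement(self):
        assert linear_weighted_kappa([1, 3, 5, 8], [1, 3, 5, 8]) == pytest.approx(1.0)

    def test_hand_case_half(self):
        # 2 levels: po = 0.75, pe = 0.5 -> kappa = 0.5
        assert linear_weighted_kappa([1, 1, 2, 2], [1, 2, 2, 2], n_levels=2) == pytest.approx(0.5, abs=1e-12)

    def test_hand_case_minus_one(self):
        assert linear_weighted_kappa([1, 2], [2, 1], n_levels=2) == pytest.approx(-1.0, abs=1e-12)

    def test_identical_constant_convention(self):
        assert linear_weighted_kappa([4, 4, 4], [4, 4, 4]) == 1.0

    def test_different_constants_give_zero(self):
        # expected disagreement is nonzero here, so kappa is defined: 0
        assert linear_weighted_kappa([4, 4, 4], [5, 5, 5]) == pytest.approx(0.0, abs=1e-12)

    def test_missing_dropped_pairwise(self):
        a = [1, 2, np.nan, 4, 5]
        b = [1, 2, 3, np.nan, 5]
        assert linear_weighted_kappa(a, b) == pytest.approx(
            linear_weighted_kappa([1, 2, 5], [1, 2, 5])
        )

    def test_out_of_range_rejected(self):
        with pytest.raises(InvalidGradeError):
            linear_weighted_kappa([0, 1], [1, 2])

    def test_brute_force_oracle_equivalence(self, rng):
        for _ in range(300):
            n = int(rng.integers(5, 60))
            a = rng.integers(1, 9, n)
            b = np.clip(a + rng.integers(-2, 3, n), 1, 8)
            if len(set(a)) == 1 and np.array_equal(a, b):
                continue
            k_impl = linear_weighted_kappa(a, b)
            assert abs(k_impl - oracle_kappa(a, b, 8)) < 1e-12

    def test_matches_sklearn(self, rng):
        from sklearn.metrics import cohen_kappa_score

        for _ in range(50):
            a = rng.integers(1, 9, 40)
            b = rng.integers(1, 9, 40)
            k_impl = linear_weighted_kappa(a, b)
            k_skl = cohen_kappa_score(a, b, labels=list(range(1, 9)), weights="linear")
            assert k_impl == pytest.approx(k_skl, abs=1e-10)

    def test_symmetry_bounds_and_permutation_invariance(self, rng):
        for _ in range(100):
            n = int(rng.integers(5, 40))
            a, b = rng.integers(1, 9, n), rng.integers(1, 9, n)
            k = linear_weighted_kappa(a, b)
            assert k == pytest.approx(linear_weighted_kappa(b, a), abs=1e-14)
            assert -1.0 - 1e-12 <= k <= 1.0 + 1e-12
            perm = rng.permutation(n)
            assert linear_weighted_kappa(a[perm], b[perm]) == pytest.approx(k, abs=1e-12)

    def test_independence_null_centered_on_zero(self):
        """Mean kappa of independent uniform raters stays within +-0.02 of 0."""
        rng = np.random.default_rng(77)
        vals = [
            linear_weighted_kappa(rng.integers(1, 9, 500), rng.integers(1, 9, 500))
            for _ in range(200)
        ]
        assert abs(float(np.mean(vals))) < 0.02


# ---------------------------------------------------------------------------
# panel machinery


class TestPanel:
    def test_identical_raters_all_ones(self):
        m = pd.DataFrame({"A": [1, 3, 5], "B": [1, 3, 5], "C": [1, 3, 5]})
        km = pairwise_kappa_matrix(m)
        off = km.values[~np.eye(3, dtype=bool)]
        assert np.allclose(off, 1.0)

    def test_two_raters_consistency_and_symmetry(self, rng):
        m = pd.DataFrame(rng.integers(1, 9, (40, 7)), columns=list("ABCDEFG"))
        km = pairwise_kappa_matrix(m)
        assert np.allclose(km.values, km.values.T, equal_nan=True)
        assert km.loc["A", "B"] == pytest.approx(linear_weighted_kappa(m["A"], m["B"]))

    def test_full_ranking_and_anticorrelated_rater_last(self):
        base = np.tile(np.arange(1, 9), 5)
        m = pd.DataFrame({
            "A": base, "B": base, "C": base,
            "D": 9 - base,  # anti-correlated
        })
        ranking = select_top_raters(m, k=4)
        assert ranking[-1] == "D"
        assert set(ranking[:3]) == {"A", "B", "C"}

    def test_select_validates_k(self):
        m = pd.DataFrame({"A": [1, 2], "B": [1, 2]})
        with pytest.raises(AcnegradeError):
            select_top_raters(m, k=0)
        with pytest.raises(AcnegradeError):
            select_top_raters(m, k=3)

    def test_median_true_label(self):
        m = pd.DataFrame({"A": [3, 2, 4], "B": [4, 5, 4], "C": [4, 3, 4]})
        med = median_true_label(m)
        assert med.tolist() == [4, 3, 4]
        with pytest.raises(AcnegradeError):
            median_true_label(m[["A", "B"]])

    def test_report_contains_selection_and_icc(self, rng):
        from acnegrade.datasets import simulate_raters

        grades = rng.integers(1, 9, 40)
        m = simulate_raters(grades, seed=1)
        rep = agreement_report(m, k_select=3)
        assert len(rep["selected"]) == 3
        assert 0.0 < rep["icc"]["value"] <= 1.0
        lo, hi = rep["icc"]["ci95"]
        assert lo <= rep["icc"]["value"] <= hi


# ---------------------------------------------------------------------------
# ICC


class TestICC:
    def test_identical_raters_unity(self):
        m = pd.DataFrame({"A": [1, 3, 5, 7], "B": [1, 3, 5, 7]})
        icc, _ = icc_agreement(m)
        assert icc == pytest.approx(1.0)

    def test_worked_3x4_matrix_matches_anova_oracle(self):
        x = np.array([[2, 3, 4], [4, 5, 5], [6, 6, 7], [1, 2, 2]], dtype=float)
        m = pd.DataFrame(x, columns=["A", "B", "C"])
        icc, _ = icc_agreement(m)
        assert icc == pytest.approx(oracle_icc2k(x), abs=1e-10)

    def test_matches_pingouin(self):
        import pingouin as pg

        rng = np.random.default_rng(5)
        x = rng.normal(0, 1.5, (12, 1)) + rng.normal(0, 0.6, (12, 4))
        m = pd.DataFrame(x, columns=list("ABCD"))
        icc, (lo, hi) = icc_agreement(m)
        long = m.reset_index().melt(id_vars="index", var_name="rater", value_name="y")
        res = pg.intraclass_corr(long, targets="index", raters="rater", ratings="y")
        row = res[res["Type"].isin(["ICC2k", "ICC(A,k)"])].iloc[0]
        ci_col = "CI95%" if "CI95%" in res.columns else "CI95"
        assert icc == pytest.approx(row["ICC"], abs=1e-8)
        assert lo == pytest.approx(row[ci_col][0], abs=0.01)  # pingouin rounds its CI
        assert hi == pytest.approx(row[ci_col][1], abs=0.01)

    def test_closed_form_variance_ratio_recovery(self):
        """500 subjects, 3 raters: ICC(2,k) near sigma_s^2/(sigma_s^2+sigma_e^2/k)."""
        rng = np.random.default_rng(99)
        sigma_s, sigma_e, k = 1.5, 0.8, 3
        subj = rng.normal(0, sigma_s, (500, 1))
        x = subj + rng.normal(0, sigma_e, (500, k))
        icc, _ = icc_agreement(pd.DataFrame(x))
        target = sigma_s**2 / (sigma_s**2 + sigma_e**2 / k)
        assert abs(icc - target) < 0.05

    def test_average_measures_at_least_single(self, rng):
        x = rng.normal(0, 1, (20, 1)) + rng.normal(0, 1, (20, 4))
        m = pd.DataFrame(x)
        icc_k, _ = icc_agreement(m, average_measures=True)
        icc_1, _ = icc_agreement(m, average_measures=False)
        assert icc_k >= icc_1

    def test_zero_between_subject_variance_undefined(self):
        m = pd.DataFrame({"A": [3.0, 3.0, 3.0], "B": [3.0, 3.0, 3.0]})
        with pytest.raises(UndefinedStatisticError):
            icc_agreement(m)

    def test_mean_squares_partition(self, rng):
        x = rng.normal(0, 1, (6, 4))
        msr, msc, mse = _anova_mean_squares(x)
        n, k = x.shape
        total = ((x - x.mean()) ** 2).sum()
        assert msr * (n - 1) + msc * (k - 1) + mse * (n - 1) * (k - 1) == pytest.approx(total)


# ---------------------------------------------------------------------------
# confusion matrix


class TestConfusionMatrix:
    def test_diagonal_when_equal(self):
        cm = confusion_matrix([1, 2, 2, 8], [1, 2, 2, 8])
        assert cm.sum() == 4 and np.trace(cm) == 4

    def test_single_subject_and_conservation(self, rng):
        cm = confusion_matrix([5], [2])
        assert cm[1, 4] == 1 and cm.sum() == 1
        p, t = rng.integers(1, 9, 30), rng.integers(1, 9, 30)
        assert confusion_matrix(p, t).sum() == 30
        assert (confusion_matrix(p, t).sum(axis=1) == np.bincount(t, minlength=9)[1:]).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(InvalidGradeError):
            confusion_matrix([9], [1])
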