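"""Trait normalization, the burden regression, FDR, and effect-scale maps."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from funburd.assoc import (
    fdr_correct,
    fit_funburd,
    irnt,
    liability_transform,
    outlier_filter,
    pleiotropy,
    proportion_compare,
)


def make_covariates(n, seed=0):
    rng = np.random.default_rng(seed)
    data = {"age": rng.uniform(40, 70, n), "sex": rng.integers(0, 2, n).astype(float)}
    for i in range(10):
        data[f"PC{i + 1}"] = rng.standard_normal(n)
    return pd.DataFrame(data)


class TestOutlierFilter:
    def test_small_sample_keeps_large_value(self):
        # oracle: mean 25, SD 50 -> |100-25| = 75 < 6*50
        values = np.array([0.0, 0.0, 0.0, 100.0])
        assert outlier_filter(values, k=6).all()

    def test_extreme_value_dropped(self):
        values = np.concatenate([np.zeros(100), [1000.0]])
        mean, sd = values.mean(), values.std(ddof=1)
        assert abs(1000 - mean) > 6 * sd  # oracle confirms it is an outlier
        mask = outlier_filter(values, k=6)
        assert not mask[-1] and mask[:-1].all()

    def test_constant_vector_warns_and_keeps_all(self):
        with pytest.warns(UserWarning, match="constant"):
            assert outlier_filter(np.ones(5)).all()

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            outlier_filter(np.array([np.nan, 1.0]))


class TestIrnt:
    def test_three_values_closed_form(self):
        out = irnt(np.array([10.0, 20.0, 30.0]))
        expected = stats.norm.ppf([1 / 6, 3 / 6, 5 / 6])
        np.testing.assert_allclose(out, expected)
        assert out[1] == pytest.approx(0.0)
        assert out[2] == pytest.approx(0.9674216, abs=1e-6)

    def test_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=101)
        np.testing.assert_allclose(irnt(x), irnt(np.exp(x)))

    def test_all_ties_rejected(self):
        with pytest.raises(ValueError):
            irnt(np.full(10, 3.0))


class TestFitFunburd:
    def test_matches_normal_equations_on_small_design(self):
        rng = np.random.default_rng(2)
        n = 50
        cov = make_covariates(n, seed=2)
        x1 = rng.poisson(1.0, n).astype(float)
        x2 = rng.poisson(2.0, n).astype(float)
        y = 0.3 * x1 - 0.1 * x2 + rng.normal(0, 1, n)
        res = fit_funburd(y, x1, x2, cov, "continuous")
        X = np.column_stack([np.ones(n), x1, x2, cov.to_numpy()])
        beta_oracle = np.linalg.solve(X.T @ X, X.T @ y)[1]
        assert res.beta == pytest.approx(beta_oracle, abs=1e-8)

    def test_recovers_planted_slope(self):
        rng = np.random.default_rng(3)
        n = 2000
        cov = make_covariates(n, seed=3)
        x1 = rng.poisson(0.5, n).astype(float)
        x2 = rng.poisson(1.0, n).astype(float)
        y = 0.5 * x1 + rng.normal(0, 0.1, n)
        res = fit_funburd(y, x1, x2, cov, "continuous")
        assert abs(res.beta - 0.5) < 3 * res.se

    def test_no_carriers_gives_non_estimable_cell(self):
        n = 30
        cov = make_covariates(n)
        res = fit_funburd(
            np.random.default_rng(0).normal(size=n),
            np.zeros(n),
            np.zeros(n),
            cov,
            "continuous",
        )
        assert not res.estimable
        assert res.p == 1.0 and res.beta == 0.0

    def test_logistic_beta_is_log_odds(self):
        rng = np.random.default_rng(4)
        n = 3000
        cov = make_covariates(n, seed=4)
        x1 = rng.poisson(0.8, n).astype(float)
        logit = -2.0 + 0.8 * x1
        y = (rng.uniform(size=n) < 1 / (1 + np.exp(-logit))).astype(float)
        res = fit_funburd(y, x1, np.zeros(n), cov, "binary")
        assert abs(res.beta - 0.8) < 3 * res.se

    def test_irrelevant_noise_covariate_barely_moves_beta(self):
        rng = np.random.default_rng(5)
        n = 1000
        cov = make_covariates(n, seed=5)
        x1 = rng.poisson(0.5, n).astype(float)
        y = 0.5 * x1 + rng.normal(0, 1, n)
        res1 = fit_funburd(y, x1, np.zeros(n), cov, "continuous")
        cov2 = cov.copy()
        cov2["PC10"] = rng.standard_normal(n)  # swap in fresh pure noise
        res2 = fit_funburd(y, x1, np.zeros(n), cov2, "continuous")
        assert abs(res1.beta - res2.beta) < res1.se


def _bh_oracle(p):
    """Independent step-up implementation."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p)
    q = np.empty(m)
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        prev = min(prev, p[i] * m / rank)
        q[i] = prev
    return q


class TestFdr:
    def test_example_grid(self):
        np.testing.assert_allclose(
            fdr_correct([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_degenerate_cases(self):
        np.testing.assert_allclose(fdr_correct([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])
        np.testing.assert_allclose(fdr_correct([0.037]), [0.037])

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_independent_step_up(self, seed):
        p = np.random.default_rng(seed).uniform(size=500)
        np.testing.assert_allclose(fdr_correct(p), _bh_oracle(p), atol=1e-12)

    def test_q_monotone_in_p(self):
        p = np.sort(np.random.default_rng(9).uniform(size=200))
        q = fdr_correct(p)
        assert (np.diff(q) >= -1e-12).all()


class TestPleiotropy:
    def test_counts_and_percentage(self):
        traits = [f"t{i}" for i in range(43)]
        rows = []
        for dtype in ("DEL", "DUP"):
            for t in traits:
                rows.append(
                    {
                        "gene_set": "S",
                        "trait": t,
                        "dosage_type": dtype,
                        "q": 0.01 if (dtype == "DEL" and t in traits[:5]) else 0.9,
                    }
                )
        out = pleiotropy(pd.DataFrame(rows))
        del_row = out[(out.gene_set == "S") & (out.dosage_type == "DEL")].iloc[0]
        assert del_row.n_traits_significant == 5
        assert del_row.pct_traits_significant == pytest.approx(100 * 5 / 43)
        dup_row = out[(out.gene_set == "S") & (out.dosage_type == "DUP")].iloc[0]
        assert dup_row.n_traits_significant == 0

    def test_count_bounded_by_traits(self, grid):
        out = pleiotropy(grid)
        assert (out.n_traits_significant <= grid["trait"].nunique()).all()


class TestProportionCompare:
    def test_equal_proportions_p_one(self):
        assert proportion_compare(10, 100, 20, 200) == 1.0

    def test_large_difference_significant(self):
        assert proportion_compare(568, 2580, 352, 2580) < 1e-10

    def test_symmetric_in_group_order(self):
        assert proportion_compare(30, 100, 10, 100) == pytest.approx(
            proportion_compare(10, 100, 30, 100)
        )

    def test_zero_totals_rejected(self):
        with pytest.raises(ValueError):
            proportion_compare(0, 0, 1, 10)


class TestLiabilityTransform:
    def test_zero_beta_maps_to_zero(self):
        assert liability_transform(0.0, 0.37) == 0.0

    def test_half_prevalence_factor(self):
        # t = 0, phi(0)/0.25 = 1.59577
        assert liability_transform(1.0, 0.5) == pytest.approx(1.5957691, abs=1e-6)

    def test_symmetric_in_prevalence(self):
        assert liability_transform(1.0, 0.1) == pytest.approx(
            liability_transform(1.0, 0.9)
        )

    def test_invalid_prevalence(self):
        with pytest.raises(ValueError):
            liability_transform(1.0, 1.0)


def test_grid_is_rectangular_with_joint_fdr(cohort, grid):
    n_sets = len(cohort.burden.set_names)
    n_traits = cohort.phenotypes.shape[1]
    assert len(grid) == n_sets * n_traits * 2
    assert (grid["q"] >= grid["p"] - 1e-12).all()
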