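"""Burden correlation machinery: residualization, selection, shrinkage, rg."""

import numpy as np
import pandas as pd
import pytest

from funburd.correlation import (
    burden_rg,
    fold_ratio,
    filter_genesets,
    lasso_selection,
    residualize,
    shrinkage_profile,
    sign_concordance,
    variance_explained,
)


def covariates(n, seed=0):
    rng = np.random.default_rng(seed)
    data = {"age": rng.uniform(40, 70, n), "sex": rng.integers(0, 2, n).astype(float)}
    for i in range(10):
        data[f"PC{i + 1}"] = rng.standard_normal(n)
    return pd.DataFrame(data)


class TestResidualize:
    def test_exact_linear_trait_gives_zero_residuals(self):
        cov = covariates(200, seed=1)
        y = 2.0 + 0.5 * cov["age"].to_numpy() - 1.2 * cov["PC3"].to_numpy()
        resid = residualize(y, cov, "continuous")
        np.testing.assert_allclose(resid, 0, atol=1e-8)

    def test_residuals_orthogonal_to_covariates(self):
        rng = np.random.default_rng(2)
        cov = covariates(300, seed=2)
        y = rng.standard_normal(300) + 0.3 * cov["sex"].to_numpy()
        resid = residualize(y, cov, "continuous")
        for col in cov.columns:
            r = np.corrcoef(resid, cov[col].to_numpy())[0, 1]
            assert abs(r) < 1e-8

    def test_binary_residuals_are_response_scale(self):
        rng = np.random.default_rng(3)
        cov = covariates(500, seed=3)
        y = (rng.uniform(size=500) < 0.3).astype(float)
        resid = residualize(y, cov, "binary")
        assert np.all(np.abs(resid) <= 1.0)
        assert abs(resid.mean()) < 0.05


class TestLassoSelection:
    def test_zero_burden_column_never_selected(self):
        rng = np.random.default_rng(4)
        n = 300
        X = pd.DataFrame(
            {
                "live": rng.poisson(1.0, n).astype(float),
                "dead": np.zeros(n),
            }
        )
        resid = pd.DataFrame({"t": 0.5 * X["live"] + rng.normal(0, 0.5, n)})
        selected, removal = lasso_selection(resid, X, seed=0)
        assert not selected.loc["t", "dead"]
        assert removal["dead"] == 1.0

    def test_infinite_penalty_selects_nothing(self):
        rng = np.random.default_rng(5)
        X = pd.DataFrame(rng.poisson(1.0, size=(200, 4)).astype(float),
                         columns=list("abcd"))
        resid = pd.DataFrame({"t": rng.standard_normal(200)})
        selected, removal = lasso_selection(resid, X, alpha=1e9)
        assert not selected.to_numpy().any()
        assert (removal == 1.0).all()

    def test_planted_single_set_effect_is_selected(self):
        hits = 0
        reps = 10
        for rep in range(reps):
            rng = np.random.default_rng(100 + rep)
            n = 400
            X = pd.DataFrame(
                rng.poisson(0.8, size=(n, 6)).astype(float),
                columns=[f"S{j}" for j in range(6)],
            )
            resid = pd.DataFrame({"t": 0.6 * X["S2"] + rng.normal(0, 1, n)})
            selected, _ = lasso_selection(resid, X, seed=rep)
            if selected.loc["t", "S2"]:
                hits += 1
        assert hits >= 9  # >= 95% support recovery allowing one miss at 10 reps

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            lasso_selection(pd.DataFrame({"t": [1.0, 2.0]}), pd.DataFrame(index=[0, 1]))


class TestFilterGenesets:
    def test_no_set_meets_both_conditions_all_retained(self):
        jac = pd.DataFrame(
            [[1.0, 0.1], [0.1, 1.0]], index=["A", "B"], columns=["A", "B"]
        )
        removal = pd.Series({"A": 0.0, "B": 0.5})  # neither removed often enough
        assert filter_genesets(jac, removal) == ["A", "B"]

    def test_duplicated_set_always_removed_is_excluded(self):
        names = ["A", "B", "C", "D"]
        jac = pd.DataFrame(np.eye(4) * 0.9 + 0.1, index=names, columns=names)
        jac.loc["A", "B"] = jac.loc["B", "A"] = 1.0  # B duplicates A
        jac.loc["C", "D"] = jac.loc["D", "C"] = 0.05
        removal = pd.Series({"A": 0.0, "B": 1.0, "C": 1.0, "D": 0.0})
        retained = filter_genesets(jac, removal, pct_threshold=0.2, freq_threshold=0.8)
        assert "B" not in retained
        assert set(retained) >= {"A", "D"}


class TestShrinkageProfile:
    def test_near_zero_penalty_orthonormal_equals_ols(self):
        rng = np.random.default_rng(6)
        n = 400
        X = pd.DataFrame(rng.standard_normal((n, 3)), columns=list("abc"))
        X = (X - X.mean()) / X.std()
        y = 0.4 * X["a"].to_numpy() - 0.2 * X["c"].to_numpy() + rng.normal(0, 0.3, n)
        prof = shrinkage_profile(y, X, alpha=1e-8)
        ols = np.linalg.lstsq(
            np.column_stack([np.ones(n), X.to_numpy()]), y, rcond=None
        )[0][1:]
        np.testing.assert_allclose(prof.to_numpy() * X.std().to_numpy(), ols, atol=1e-4)

    def test_huge_penalty_shrinks_to_zero(self):
        rng = np.random.default_rng(7)
        X = pd.DataFrame(rng.poisson(1.0, size=(200, 3)).astype(float),
                         columns=list("abc"))
        y = X["a"].to_numpy() + rng.normal(0, 0.2, 200)
        prof = shrinkage_profile(y, X, alpha=1e12)
        np.testing.assert_allclose(prof.to_numpy(), 0, atol=1e-6)

    def test_collinear_sets_split_coefficient_equally(self):
        rng = np.random.default_rng(8)
        n = 300
        base = rng.poisson(1.0, n).astype(float)
        X = pd.DataFrame({"twin1": base, "twin2": base})
        y = 0.6 * base + rng.normal(0, 0.2, n)
        prof = shrinkage_profile(y, X, alpha=1.0)
        assert prof["twin1"] == pytest.approx(prof["twin2"], rel=1e-8)


class TestVarianceExplained:
    def test_exact_linear_gives_one(self):
        rng = np.random.default_rng(9)
        X = pd.DataFrame(rng.poisson(1.0, size=(100, 2)).astype(float),
                         columns=["a", "b"])
        y = 1.0 + 2.0 * X["a"].to_numpy() - 0.5 * X["b"].to_numpy()
        assert variance_explained(y, X) == pytest.approx(1.0)

    def test_null_r2_near_p_over_n(self):
        rng = np.random.default_rng(10)
        n, p = 1000, 8
        X = pd.DataFrame(rng.poisson(1.0, size=(n, p)).astype(float))
        r2 = np.mean(
            [
                variance_explained(np.random.default_rng(s).standard_normal(n), X)
                for s in range(20)
            ]
        )
        assert r2 == pytest.approx(p / n, abs=3 * p / n)

    def test_r2_non_decreasing_in_sets(self):
        rng = np.random.default_rng(11)
        X = pd.DataFrame(rng.poisson(1.0, size=(200, 4)).astype(float),
                         columns=list("abcd"))
        y = X["a"].to_numpy() + rng.normal(0, 1, 200)
        assert variance_explained(y, X) >= variance_explained(y, X[list("abc")]) - 1e-12

    def test_underdetermined_rejected(self):
        X = pd.DataFrame(np.ones((3, 5)))
        with pytest.raises(ValueError):
            variance_explained(np.zeros(3), X)


class TestBurdenRg:
    def test_orthogonal_profiles_zero(self):
        p1 = np.array([1.0, -1.0, 1.0, -1.0])
        p2 = np.array([1.0, 1.0, -1.0, -1.0])
        assert burden_rg(p1, p2, 0.1, 0.1).rg == pytest.approx(0.0)

    def test_negation_flips_sign(self):
        rng = np.random.default_rng(12)
        p1 = rng.standard_normal(20)
        p2 = 0.5 * p1 + rng.normal(0, 0.2, 20)
        est = burden_rg(p1, p2, 0.05, 0.05)
        neg = burden_rg(p1, -p2, 0.05, 0.05)
        assert neg.rg == pytest.approx(-est.rg)

    def test_homogeneity_scaling_profiles_and_h2_consistently(self):
        # scaling both profiles by c while scaling both h2 by c**2 leaves rg fixed
        rng = np.random.default_rng(13)
        p1 = rng.standard_normal(15)
        p2 = rng.standard_normal(15)
        base = burden_rg(p1, p2, 0.2, 0.3).rg
        c = 7.3
        scaled = burden_rg(c * p1, c * p2, c**2 * 0.2, c**2 * 0.3).rg
        assert scaled == pytest.approx(base)

    def test_out_of_range_flagged_not_clamped(self):
        p1 = np.array([1.0, 2.0, 3.0])
        est = burden_rg(p1, p1, 1e-4, 1e-4)
        assert est.rg > 1 and est.out_of_range

    def test_zero_h2_rejected(self):
        with pytest.raises(ValueError):
            burden_rg(np.ones(3), np.ones(3), 0.0, 0.1)


def square(values, names):
    return pd.DataFrame(values, index=names, columns=names)


class TestMatrixComparisons:
    names = list("xyz")

    def test_sign_concordance_extremes(self):
        a = square([[np.nan, 0.5, -0.2], [0.5, np.nan, 0.1],
                    [-0.2, 0.1, np.nan]], self.names)
        assert sign_concordance(a, a) == 100.0
        assert sign_concordance(a, -a) == 0.0

    def test_fold_ratio_values(self):
        a = square([[np.nan, 0.4, -0.2], [0.4, np.nan, 0.6],
                    [-0.2, 0.6, np.nan]], self.names)
        assert fold_ratio(2 * a, a) == pytest.approx(2.0)
        assert fold_ratio(a, a) == pytest.approx(1.0)
        b = square([[np.nan, 0.1, 0.1], [0.1, np.nan, 0.2],
                    [0.1, 0.2, np.nan]], self.names)
        # hand oracle: mean|a| = (0.4+0.2+0.6)/3, mean|b| = (0.1+0.1+0.2)/3
        assert fold_ratio(a, b) == pytest.approx((1.2 / 3) / (0.4 / 3))

    def test_zero_denominator_rejected(self):
        a = square(np.zeros((3, 3)), self.names)
        with pytest.raises(ValueError):
            fold_ratio(a, a)


def test_duplication_channel_independent_of_deletion_channel(cohort, trait_types):
    """Permuting duplication labels leaves the deletion matrix untouched."""
    del_before = cohort.burden.x1("DEL").to_numpy().copy()
    from funburd.burden import CNVCall, aggregate_burden

    rng = np.random.default_rng(0)
    dels = [c for c in cohort.cnvs if c.dosage_type == "DEL"]
    dups = [c for c in cohort.cnvs if c.dosage_type == "DUP"]
    perm = rng.permutation(len(dups))
    shuffled = [
        CNVCall(dups[i].sample_id, dups[j].chrom, dups[j].start, dups[j].end, "DUP")
        for i, j in enumerate(perm)
    ]
    table = aggregate_burden(
        dels + shuffled,
        cohort.gene_models,
        cohort.marker_sets,
        sample_ids=list(cohort.samples),
    )
    np.testing.assert_array_equal(table.x1("DEL").to_numpy(), del_before)
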