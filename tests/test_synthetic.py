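"""Generator behaviour: structure, determinism, and self-consistency."""

import numpy as np
import pandas as pd
import pytest

from funburd.assoc import association_grid
from funburd.burden import aggregate_burden, genes_fully_encompassed
from funburd.synthetic import (
    PlantedEffect,
    SyntheticConfig,
    TraitSpec,
    generate_gene_models,
    simulate_cohort,
)


def small_config(**kw):
    base = dict(
        n_samples=200,
        n_genes=120,
        n_chroms=2,
        chrom_length=20_000_000,
        n_contexts=4,
        marker_genes_per_context=10,
        cnv_rate=0.5,
        planted_effects=[],
        trait_specs=[TraitSpec("t1", "continuous")],
        seed=1,
    )
    base.update(kw)
    return SyntheticConfig(**base)


class TestGeneModels:
    def test_disjoint_and_sorted_per_chromosome(self):
        rng = np.random.default_rng(0)
        genes = generate_gene_models(
            small_config(n_genes=10, n_chroms=1, marker_genes_per_context=2), rng
        )
        assert len(genes) == 10
        starts = [g.start for g in genes]
        assert starts == sorted(starts)
        for a, b in zip(genes, genes[1:]):
            assert a.end < b.start  # non-overlapping, left to right

    def test_deterministic_given_seed(self):
        cfg = small_config()
        g1 = generate_gene_models(cfg, np.random.default_rng(5))
        g2 = generate_gene_models(cfg, np.random.default_rng(5))
        assert g1 == g2

    def test_zero_genes_gives_empty_list(self):
        cfg = small_config(n_genes=0, marker_genes_per_context=0)
        assert generate_gene_models(cfg, np.random.default_rng(0)) == []

    def test_chromosome_too_small_raises(self):
        cfg = small_config(chrom_length=100_000)
        with pytest.raises(ValueError, match="too small"):
            generate_gene_models(cfg, np.random.default_rng(0))


class TestExpression:
    def test_marker_genes_concentrated_in_their_context(self, cohort):
        prop = cohort.expression.div(cohort.expression.sum(axis=1), axis=0)
        for gene, ctx in cohort.truth.marker_assignment.items():
            assert prop.loc[gene, ctx] > 0.9

    def test_background_genes_near_uniform(self):
        c = simulate_cohort(small_config(seed=3))
        prop = c.expression.div(c.expression.sum(axis=1), axis=0)
        background = [
            g for g in c.expression.index if g not in c.truth.marker_assignment
        ]
        sub = prop.loc[background]
        assert np.all(np.abs(sub.to_numpy() - 0.25) < 0.2)  # 4 contexts


class TestCnvs:
    def test_zero_rate_means_no_cnvs_and_zero_burden(self):
        c = simulate_cohort(small_config(cnv_rate=0.0))
        assert c.cnvs == []
        assert (c.burden.x1("DEL").to_numpy() == 0).all()
        assert (c.burden.x2("DUP").to_numpy() == 0).all()

    def test_mean_count_matches_poisson_rate(self, cohort):
        # mean CNVs/sample/type within 3 SE of the configured rate
        rate = cohort.config.cnv_rate
        n = cohort.config.n_samples
        for dtype in ("DEL", "DUP"):
            count = sum(1 for c in cohort.cnvs if c.dosage_type == dtype)
            se = np.sqrt(rate / n)
            assert abs(count / n - rate) < 3 * se

    def test_cnvs_encompass_contiguous_gene_runs(self, cohort):
        genes = cohort.gene_models
        by_id = {g.gene_id: g for g in genes}
        for cnv in cohort.cnvs[:50]:
            hit = genes_fully_encompassed(cnv, genes)
            assert len(hit) >= 1
            # boundaries coincide with the first/last gene of the run
            assert min(by_id[g].start for g in hit) == cnv.start
            assert max(by_id[g].end for g in hit) == cnv.end


class TestTraits:
    def test_binary_prevalence_half_thresholds_at_median(self):
        cfg = small_config(
            n_samples=500,
            trait_specs=[TraitSpec("b", "binary", prevalence=0.5)],
        )
        c = simulate_cohort(cfg)
        assert abs(c.phenotypes["b"].mean() - 0.5) < 0.05

    def test_unknown_gene_set_in_planted_effect_rejected(self):
        with pytest.raises(ValueError, match="unknown gene set"):
            small_config(
                planted_effects=[PlantedEffect("ctx99", "t1", "DEL", 0.5)]
            ).validate()


class TestCohortInvariants:
    def test_determinism_byte_identical(self):
        cfg = small_config(seed=11)
        a = simulate_cohort(cfg)
        b = simulate_cohort(cfg)
        pd.testing.assert_frame_equal(a.expression, b.expression)
        pd.testing.assert_frame_equal(a.phenotypes, b.phenotypes)
        assert a.cnvs == b.cnvs
        assert a.truth.constraint_labels == b.truth.constraint_labels

    def test_burden_self_consistency(self, cohort):
        regenerated = aggregate_burden(
            cohort.cnvs,
            cohort.gene_models,
            cohort.marker_sets,
            sample_ids=list(cohort.samples),
        )
        assert regenerated.equals(cohort.burden)

    def test_constraint_labels_enriched_in_effect_contexts(self, cohort):
        labels = cohort.truth.constraint_labels
        effect_ctx = {e.gene_set for e in cohort.config.planted_effects}
        marker = cohort.truth.marker_assignment
        in_effect = [
            labels[g] for g, ctx in marker.items() if ctx in effect_ctx
        ]
        background = [
            labels[g] for g in labels if marker.get(g) not in effect_ctx
        ]
        assert np.mean(in_effect) > np.mean(background)


def test_strong_planted_effect_flagged_with_high_power():
    """An effect with |beta|/SE well above 4 is FDR-flagged in most replicates."""
    detected = 0
    reps = 25
    for rep in range(reps):
        cfg = SyntheticConfig(
            n_samples=1500,
            n_genes=600,
            n_chroms=2,
            n_contexts=6,
            marker_genes_per_context=60,
            cnv_rate=0.8,
            trait_specs=[
                TraitSpec("a", "continuous"),
                TraitSpec("b", "continuous"),
            ],
            planted_effects=[PlantedEffect("ctx00", "a", "DEL", 0.6)],
            seed=1000 + rep,
        )
        c = simulate_cohort(cfg)
        g = association_grid(
            c.burden, c.phenotypes, c.covariates, {"a": "continuous", "b": "continuous"}
        )
        cell = g[
            (g.gene_set == "ctx00") & (g.trait == "a") & (g.dosage_type == "DEL")
        ].iloc[0]
        if cell.q < 0.05:
            detected += 1
    assert detected / reps > 0.8
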