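"""End-to-end pipeline orchestration.

Runs the full analysis on a synthetic cohort (or user-supplied input
files): gene-set construction → burden aggregation → the association grid
with joint FDR → pleiotropy → constraint correlation and normative bands
→ between-trait burden correlations → dosage-response classification.
Each stage logs timing; a manifest records input checksums, seeds, grid
dimensions and package versions so a run can be reproduced exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Callable, Dict, Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from . import io as fio
from .assoc import association_grid, fdr_correct, fit_funburd, irnt, outlier_filter, pleiotropy
from .burden import CnvGeneHits, aggregate_burden, index_cnv_gene_hits
from .correlation import (
    burden_correlation_matrix,
    effect_profiles,
    filter_genesets,
    lasso_selection,
    residualize,
)
from .dosage import classify_responses, monotonic_fraction_by_group
from .genesets import GeneSetCollection, build_tdep_sets, expression_proportion, jaccard_matrix, mean_overlap
from .normative import constrained_fraction, constraint_pleiotropy_correlation, normalized_pleiotropy, normative_model
from .synthetic import SyntheticConfig, simulate_cohort

logger = logging.getLogger("funburd")

__all__ = ["burden_pleiotropy_runner", "run_pipeline", "synthetic_config_from_dict"]


def burden_pleiotropy_runner(
    hits: CnvGeneHits,
    phenotypes: pd.DataFrame,
    covariates: pd.DataFrame,
    trait_types: Dict[str, str],
    q_threshold: float = 0.05,
    outlier_k: float = 6.0,
) -> Callable[[Sequence[str]], float]:
    """Build a function evaluating burden pleiotropy for an arbitrary gene set.

    Used by the normative resampling model: given member gene ids, it
    computes x1/x2 (x2 as non-members across all the sample's CNVs, the
    fast whole-sample scope), fits the burden model for every trait and
    dosage type, applies BH within the set's own cells, and returns the
    number of significant (trait, dosage type) associations.
    """
    gene_pos = {g: i for i, g in enumerate(hits.gene_ids)}
    samples = list(hits.samples)
    cov = covariates.loc[samples]
    processed = {}
    for trait in phenotypes.columns:
        y = phenotypes[trait].to_numpy(dtype=float)
        if trait_types[trait] == "continuous":
            keep = outlier_filter(y, k=outlier_k)
            processed[trait] = (irnt(y[keep]), keep)
        else:
            keep = ~np.isnan(y)
            processed[trait] = (y[keep], keep)
    # per sample/type: total distinct genes hit (x2 = total - x1)
    totals = {
        d: np.array([hits.union_hits(s, d).size for s in samples]) for d in ("DEL", "DUP")
    }

    def runner(member_genes: Sequence[str]) -> float:
        mask = np.zeros(len(hits.gene_ids), dtype=bool)
        for g in member_genes:
            if g in gene_pos:
                mask[gene_pos[g]] = True
        pvals = []
        for dtype in ("DEL", "DUP"):
            x1 = hits.x1_counts(mask, dtype)
            x2 = totals[dtype] - x1
            for trait in phenotypes.columns:
                y, keep = processed[trait]
                res = fit_funburd(
                    y, x1[keep], x2[keep], cov.loc[keep], trait_types[trait]
                )
                pvals.append(res.p)
        q = fdr_correct(np.array(pvals))
        return float(np.sum(q < q_threshold))

    return runner


def synthetic_config_from_dict(d: dict) -> SyntheticConfig:
    from .synthetic import PlantedEffect, TraitSpec

    d = dict(d)
    if "planted_effects" in d:
        d["planted_effects"] = [PlantedEffect(**e) for e in d["planted_effects"]]
    if "trait_specs" in d:
        d["trait_specs"] = [TraitSpec(**t) for t in d["trait_specs"]]
    return SyntheticConfig(**d)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: dict, output_dir: Optional[str] = None) -> Path:
    """Execute all stages and write results + manifest to ``output_dir``.

    ``config`` mirrors the YAML schema: a ``synthetic`` section (cohort
    parameters) or an ``inputs`` section (file paths), plus optional
    ``thresholds``, ``permutations``, ``normative`` sections and
    ``output_dir``.
    """
    t0 = time.time()
    out = Path(output_dir or config.get("output_dir", "funburd_results"))
    out.mkdir(parents=True, exist_ok=True)
    thresholds = {
        "q": 0.05,
        "decile": 0.10,
        "jaccard_percentile": 0.2,
        "lasso_removal_freq": 0.8,
        **config.get("thresholds", {}),
    }
    perms = {"n_perm": 200, "seed": 0, **config.get("permutations", {})}
    x2_scope = config.get("x2_scope", "same_cnv")
    manifest: dict = {
        "version": __version__,
        "thresholds": thresholds,
        "permutations": perms,
        "x2_scope": x2_scope,
        "stages": {},
        "outputs": {},
    }

    def stage(name):
        logger.info("stage %s", name)
        manifest["stages"][name] = {"started": time.time() - t0}

    def done(name):
        manifest["stages"][name]["seconds"] = round(
            time.time() - t0 - manifest["stages"][name]["started"], 3
        )

    try:
        # ------------------------------------------------------------- inputs
        stage("inputs")
        if "synthetic" in config or "inputs" not in config:
            syn_cfg = synthetic_config_from_dict(config.get("synthetic", {}))
            cohort = simulate_cohort(syn_cfg)
            genes = cohort.gene_models
            cnvs = cohort.cnvs
            expression = cohort.expression
            phenotypes = cohort.phenotypes
            covariates = cohort.covariates
            trait_types = {t.name: t.kind for t in syn_cfg.trait_specs}
            trait_groups = {t.name: t.category for t in syn_cfg.trait_specs}
            constraint_flags = pd.Series(cohort.truth.constraint_labels)
            manifest["synthetic_seed"] = syn_cfg.seed
            fio.write_gene_models(genes, out / "gene_models.tsv", out / "gene_models.bed")
            fio.write_cnv_tsv(cnvs, out / "cnvs.tsv")
            fio.write_tsv(expression, out / "expression.tsv")
            fio.write_tsv(phenotypes.rename_axis("sample_id"), out / "phenotypes.tsv")
            fio.write_tsv(covariates.rename_axis("sample_id"), out / "covariates.tsv")
            (out / "truth.json").write_text(
                json.dumps(cohort.truth.to_json_dict(), indent=1)
            )
        else:
            inputs = config["inputs"]
            genes = (
                fio.read_bed(inputs["genes"])
                if str(inputs["genes"]).endswith(".bed")
                else fio.read_gene_tsv(inputs["genes"])
            )
            cnvs = fio.read_cnv_tsv(inputs["cnvs"])
            expression = fio.read_expression_tsv(inputs["expression"])
            pheno_df = pd.read_csv(inputs["phenotypes"], sep="\t", index_col=0)
            covariates = pd.read_csv(inputs["covariates"], sep="\t", index_col=0)
            meta = pd.read_csv(inputs["traits"], sep="\t")
            trait_types = dict(zip(meta["trait"], meta["kind"]))
            trait_groups = dict(zip(meta["trait"], meta["category"]))
            phenotypes = pheno_df[list(trait_types)]
            constraint_flags = (
                fio.read_constraint_tsv(inputs["constraint"])
                if "constraint" in inputs
                else None
            )
        done("inputs")

        # ---------------------------------------------------------- gene sets
        stage("genesets")
        prop = expression_proportion(expression)
        collection = build_tdep_sets(prop, decile=thresholds["decile"])
        fio.write_gmt(collection, out / "gene_sets.gmt")
        jac = jaccard_matrix(collection)
        fio.write_tsv(jac, out / "jaccard.tsv")
        manifest["mean_overlap"] = mean_overlap(collection)
        done("genesets")

        # ------------------------------------------------------------- burden
        stage("burden")
        samples = list(phenotypes.index)
        burden = aggregate_burden(
            cnvs, genes, collection, sample_ids=samples, x2_scope=x2_scope
        )
        fio.write_tsv(burden.to_long(), out / "burden.tsv", index=False)
        done("burden")

        # ------------------------------------------------------- associations
        stage("associations")
        grid = association_grid(burden, phenotypes, covariates, trait_types)
        fio.write_tsv(grid, out / "association_grid.tsv", index=False)
        manifest["grid_dimensions"] = {
            "gene_sets": len(collection),
            "traits": phenotypes.shape[1],
            "dosage_types": 2,
            "cells": int(len(grid)),
        }
        pleio = pleiotropy(grid, q_threshold=thresholds["q"])
        fio.write_tsv(pleio, out / "pleiotropy.tsv", index=False)
        done("associations")

        # --------------------------------------------------------- constraint
        if constraint_flags is not None:
            stage("constraint")
            top = {g for g, v in constraint_flags.items() if v == 1}
            fractions = pd.Series(
                {n: constrained_fraction(collection[n], top) for n in collection.names}
            )
            rows = []
            for dtype in ("DEL", "DUP"):
                counts = (
                    pleio[pleio["dosage_type"] == dtype]
                    .set_index("gene_set")["n_traits_significant"]
                    .reindex(list(collection.names))
                )
                if counts.std() > 0 and fractions.std() > 0:
                    res = constraint_pleiotropy_correlation(
                        fractions.to_numpy(),
                        counts.to_numpy(),
                        collection,
                        constraint_flags,
                        n_perm=perms["n_perm"],
                        seed=perms["seed"],
                    )
                    r = float(np.corrcoef(fractions, counts)[0, 1])
                    rows.append(
                        {"dosage_type": dtype, "r": r, "p_jaccard": res.p}
                    )
            fio.write_tsv(pd.DataFrame(rows), out / "constraint_correlation.tsv", index=False)
            done("constraint")

            # -------------------------------------------------- normative model
            stage("normative")
            ncfg = {
                "set_size": 50,
                "n_reps": 30,
                "fraction_grid": [0.0, 0.1, 0.2, 0.3, 0.4],
                **config.get("normative", {}),
            }
            hits = index_cnv_gene_hits(cnvs, genes, sample_ids=samples)
            runner = burden_pleiotropy_runner(
                hits, phenotypes, covariates, trait_types, q_threshold=thresholds["q"]
            )
            bands = normative_model(
                [g.gene_id for g in genes],
                constraint_flags,
                runner,
                fraction_grid=ncfg["fraction_grid"],
                set_size=ncfg["set_size"],
                n_reps=ncfg["n_reps"],
                seed=perms["seed"],
            )
            band_rows = bands.centiles.rename_axis("fraction").reset_index().melt(
                id_vars="fraction", var_name="centile", value_name="value"
            )
            fio.write_tsv(band_rows, out / "normative_bands.tsv", index=False)
            grid_lo, grid_hi = min(bands.fractions), max(bands.fractions)
            norm_rows = []
            for name in collection.names:
                frac = fractions[name]
                if not (grid_lo <= frac <= grid_hi):
                    continue
                obs = float(runner(collection[name]))
                score = normalized_pleiotropy(obs, frac, bands)
                norm_rows.append(
                    {"gene_set": name, "constrained_fraction": frac,
                     "observed_pleiotropy": obs, **score}
                )
            fio.write_tsv(pd.DataFrame(norm_rows), out / "normalized_pleiotropy.tsv", index=False)
            done("normative")

        # ------------------------------------------------- burden correlations
        stage("correlations")
        rg_written = False
        if phenotypes.shape[1] >= 2 and len(collection) >= 3:
            for dtype in ("DEL", "DUP"):
                x1 = burden.x1(dtype)
                resid = pd.DataFrame(
                    {
                        t: residualize(
                            phenotypes[t].to_numpy(dtype=float),
                            covariates.loc[samples],
                            trait_types[t],
                        )
                        for t in phenotypes.columns
                    },
                    index=samples,
                )
                _, removal = lasso_selection(resid, x1, seed=perms["seed"])
                retained = filter_genesets(
                    jac,
                    removal,
                    pct_threshold=thresholds["jaccard_percentile"],
                    freq_threshold=thresholds["lasso_removal_freq"],
                )
                if len(retained) < 2:
                    # redundancy filter is too aggressive for a tiny panel;
                    # profiles need at least two sets to define a covariance
                    logger.warning("filter retained <2 sets; keeping all")
                    retained = list(collection.names)
                profiles, h2 = effect_profiles(
                    phenotypes,
                    covariates.loc[samples],
                    x1[retained],
                    trait_types,
                    seed=perms["seed"],
                )
                if (h2 <= 0).any():
                    continue
                rg, pmat = burden_correlation_matrix(
                    profiles, h2, collection, n_perm=perms["n_perm"], seed=perms["seed"]
                )
                fio.write_tsv(rg, out / f"rg_{dtype.lower()}.tsv")
                if pmat is not None:
                    fio.write_tsv(pmat, out / f"rg_{dtype.lower()}_p.tsv")
                fio.write_tsv(h2.to_frame(), out / f"h2_{dtype.lower()}.tsv")
                rg_written = True
        manifest["rg_computed"] = rg_written
        done("correlations")

        # ---------------------------------------------------- dosage responses
        stage("dosage")
        responses = classify_responses(grid, q_threshold=thresholds["q"])
        fio.write_tsv(responses, out / "dosage_responses.tsv", index=False)
        non_null = responses[responses["evidence_class"] != "null"]
        summary = {
            "n_responses": int(len(responses)),
            "n_non_null": int(len(non_null)),
            "pct_monotonic": (
                float(100 * (non_null["sign_class"] == "monotonic").mean())
                if len(non_null)
                else float("nan")
            ),
        }
        table, p_group = monotonic_fraction_by_group(responses, trait_groups)
        if len(table):
            fio.write_tsv(table, out / "monotonic_fractions.tsv", index=False)
        summary["group_p"] = None if np.isnan(p_group) else float(p_group)
        manifest["dosage_summary"] = summary
        done("dosage")
    except Exception as exc:
        failed = [k for k, v in manifest["stages"].items() if "seconds" not in v]
        raise RuntimeError(
            f"pipeline failed at stage {failed[-1] if failed else '?'}: {exc}"
        ) from exc

    for f in sorted(out.iterdir()):
        if f.name != "manifest.json" and f.is_file():
            manifest["outputs"][f.name] = _sha256(f)
    manifest["total_seconds"] = round(time.time() - t0, 3)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return out
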