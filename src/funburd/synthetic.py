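"""Synthetic cohort generator with known ground truth.

Emulates the inputs of a biobank-scale CNV burden study at desk scale: a
toy genome of non-overlapping genes, context-specific expression in which
each context has planted marker genes, sparse multigenic deletion and
duplication calls, per-gene constraint labels correlated with planted
effects, and continuous/binary traits generated from planted gene-set
burden effects plus age/sex/PC covariates and Gaussian (or liability)
noise.

Every stochastic step consumes a single :class:`numpy.random.Generator`
seeded from the config, in the fixed order: gene models → expression →
CNVs → constraint labels → covariates → traits. Identical config and seed
therefore give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .burden import BurdenTable, CNVCall, DOSAGE_TYPES, GeneModel, aggregate_burden
from .genesets import GeneSetCollection

__all__ = [
    "TraitSpec",
    "PlantedEffect",
    "SyntheticConfig",
    "SyntheticTruth",
    "SyntheticCohort",
    "default_trait_specs",
    "default_planted_effects",
    "correlated_effect_pair",
    "generate_gene_models",
    "generate_expression",
    "generate_cnvs",
    "generate_constraint_labels",
    "generate_covariates",
    "generate_traits",
    "simulate_cohort",
]

# fixed covariate effects entering every simulated trait
AGE_BETA = 0.01
SEX_BETA = 0.10
PC_BETA_SD = 0.05
N_PCS = 10


@dataclass(frozen=True)
class TraitSpec:
    name: str
    kind: str  # "continuous" | "binary"
    prevalence: Optional[float] = None  # K, binary only
    category: str = "non-brain"  # "brain" | "non-brain"

    def __post_init__(self):
        if self.kind not in ("continuous", "binary"):
            raise ValueError(f"unknown trait kind {self.kind!r}")
        if self.kind == "binary":
            if self.prevalence is None or not (0 < self.prevalence < 1):
                raise ValueError(
                    f"binary trait {self.name!r} needs prevalence in (0,1)"
                )
        if self.category not in ("brain", "non-brain"):
            raise ValueError(f"unknown trait category {self.category!r}")


@dataclass(frozen=True)
class PlantedEffect:
    """A true effect of x1 burden in `gene_set` on `trait` for one dosage type."""

    gene_set: str
    trait: str
    dosage_type: str
    beta: float

    def __post_init__(self):
        if self.dosage_type not in DOSAGE_TYPES:
            raise ValueError(f"unknown dosage type {self.dosage_type!r}")


def default_trait_specs() -> List[TraitSpec]:
    return [
        TraitSpec("fluid_intelligence", "continuous", category="brain"),
        TraitSpec("neuroticism", "continuous", category="brain"),
        TraitSpec("bmi", "continuous", category="non-brain"),
        TraitSpec("hdl", "continuous", category="non-brain"),
        TraitSpec("depression", "binary", prevalence=0.10, category="brain"),
        TraitSpec("diabetes", "binary", prevalence=0.05, category="non-brain"),
    ]


def default_planted_effects() -> List[PlantedEffect]:
    # mix of monotonic (opposing DEL/DUP signs) and non-monotonic effects
    return [
        PlantedEffect("ctx00", "fluid_intelligence", "DEL", -0.5),
        PlantedEffect("ctx00", "fluid_intelligence", "DUP", 0.35),
        PlantedEffect("ctx01", "neuroticism", "DEL", 0.45),
        PlantedEffect("ctx01", "neuroticism", "DUP", 0.40),
        PlantedEffect("ctx02", "bmi", "DEL", 0.5),
        PlantedEffect("ctx03", "hdl", "DUP", -0.45),
        PlantedEffect("ctx00", "depression", "DEL", 0.5),
        PlantedEffect("ctx04", "diabetes", "DEL", 0.45),
    ]


@dataclass
class SyntheticConfig:
    """Study conditions for one synthetic cohort.

    Defaults describe a sparse multigenic CNV cohort: ~0.8 deletions and
    ~0.8 duplications per sample on average, each spanning ~3 consecutive
    genes, with ten expression contexts of 60 marker genes each.
    """

    n_samples: int = 2000
    n_genes: int = 1200
    n_chroms: int = 4
    chrom_length: int = 60_000_000
    n_contexts: int = 10
    marker_genes_per_context: int = 60
    cnv_rate: float = 0.8  # mean CNVs per sample per dosage type
    cnv_gene_span_mean: float = 3.0  # mean genes per CNV (>= 1)
    planted_effects: List[PlantedEffect] = field(default_factory=default_planted_effects)
    trait_specs: List[TraitSpec] = field(default_factory=default_trait_specs)
    pairwise_trait_rg: Dict[Tuple[str, str], float] = field(default_factory=dict)
    constraint_fraction: float = 0.10
    x2_beta: float = 0.0
    noise_sd: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        for name, value in {
            "n_samples": self.n_samples,
            "n_chroms": self.n_chroms,
            "chrom_length": self.chrom_length,
            "n_contexts": self.n_contexts,
        }.items():
            if value <= 0:
                raise ValueError(f"{name} must be positive, got {value}")
        if self.n_genes < 0 or self.marker_genes_per_context < 0:
            raise ValueError("n_genes and marker_genes_per_context must be >= 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.cnv_rate < 0:
            raise ValueError("cnv_rate must be >= 0")
        if self.cnv_gene_span_mean < 1:
            raise ValueError("cnv_gene_span_mean must be >= 1")
        if not (0 <= self.constraint_fraction <= 1):
            raise ValueError("constraint_fraction must be in [0, 1]")
        if self.marker_genes_per_context * self.n_contexts > self.n_genes:
            raise ValueError("marker_genes_per_context × n_contexts exceeds n_genes")
        trait_names = {t.name for t in self.trait_specs}
        if len(trait_names) != len(self.trait_specs):
            raise ValueError("duplicate trait names")
        contexts = {f"ctx{i:02d}" for i in range(self.n_contexts)}
        for eff in self.planted_effects:
            if eff.trait not in trait_names:
                raise ValueError(f"planted effect on unknown trait {eff.trait!r}")
            if eff.gene_set not in contexts:
                raise ValueError(f"planted effect on unknown gene set {eff.gene_set!r}")

    def context_names(self) -> List[str]:
        return [f"ctx{i:02d}" for i in range(self.n_contexts)]

    def trait(self, name: str) -> TraitSpec:
        for t in self.trait_specs:
            if t.name == name:
                return t
        raise KeyError(name)


@dataclass
class SyntheticTruth:
    """Ground truth planted into a cohort, for parameter-recovery tests."""

    marker_assignment: Dict[str, str]  # gene -> context
    planted_effects: List[PlantedEffect]
    constraint_labels: Dict[str, int]  # gene -> {0,1}
    pairwise_trait_rg: Dict[Tuple[str, str], float]

    def marker_sets(self) -> Dict[str, List[str]]:
        sets: Dict[str, List[str]] = {}
        for gene, ctx in self.marker_assignment.items():
            sets.setdefault(ctx, []).append(gene)
        return {k: sorted(v) for k, v in sets.items()}

    def to_json_dict(self) -> dict:
        return {
            "marker_assignment": self.marker_assignment,
            "planted_effects": [asdict(e) for e in self.planted_effects],
            "constraint_labels": self.constraint_labels,
            "pairwise_trait_rg": {
                f"{a}|{b}": r for (a, b), r in self.pairwise_trait_rg.items()
            },
        }


def correlated_effect_pair(
    contexts: Sequence[str],
    trait_a: str,
    trait_b: str,
    rho: float,
    dosage_type: str = "DEL",
    scale: float = 0.4,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[List[PlantedEffect], Dict[Tuple[str, str], float]]:
    """Plant per-set effect vectors for two traits with correlation ``rho``.

    Draws one (beta_a, beta_b) pair per context from a bivariate normal
    with correlation rho and standard deviation ``scale``, which makes the
    between-trait burden correlation recoverable against a planned truth.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    cov = scale**2 * np.array([[1.0, rho], [rho, 1.0]])
    betas = rng.multivariate_normal([0.0, 0.0], cov, size=len(contexts))
    effects = []
    for ctx, (ba, bb) in zip(contexts, betas):
        effects.append(PlantedEffect(ctx, trait_a, dosage_type, float(ba)))
        effects.append(PlantedEffect(ctx, trait_b, dosage_type, float(bb)))
    return effects, {(trait_a, trait_b): rho}


# ---------------------------------------------------------------------------
# generation stages


def generate_gene_models(
    config: SyntheticConfig, rng: np.random.Generator
) -> List[GeneModel]:
    """Non-overlapping genes laid left-to-right on each chromosome."""
    config.validate()
    if config.n_genes == 0:
        return []
    per_chrom = np.full(config.n_chroms, config.n_genes // config.n_chroms)
    per_chrom[: config.n_genes % config.n_chroms] += 1
    genes: List[GeneModel] = []
    gid = 0
    for c in range(config.n_chroms):
        n = int(per_chrom[c])
        if n == 0:
            continue
        lengths = rng.integers(5_000, 100_000, size=n)
        gaps = rng.integers(10_000, 50_000, size=n)
        if int(lengths.sum() + gaps.sum()) > config.chrom_length:
            raise ValueError(
                f"chrom_length {config.chrom_length} too small to place {n} genes "
                f"on chromosome chr{c + 1}"
            )
        pos = 1
        for i in range(n):
            start = pos + int(gaps[i])
            end = start + int(lengths[i]) - 1
            genes.append(
                GeneModel(f"g{gid:05d}", f"chr{c + 1}", start, end)
            )
            pos = end + 1
            gid += 1
    return genes


def _assign_markers(
    config: SyntheticConfig, genes: Sequence[GeneModel], rng: np.random.Generator
) -> Dict[str, str]:
    gene_ids = [g.gene_id for g in genes]
    chosen = rng.choice(
        len(gene_ids),
        size=config.marker_genes_per_context * config.n_contexts,
        replace=False,
    )
    assignment: Dict[str, str] = {}
    contexts = config.context_names()
    for k, idx in enumerate(chosen):
        assignment[gene_ids[int(idx)]] = contexts[k % config.n_contexts]
    return assignment


def generate_expression(
    config: SyntheticConfig,
    genes: Sequence[GeneModel],
    marker_assignment: Dict[str, str],
    rng: np.random.Generator,
) -> pd.DataFrame:
    """nTPM-like genes × contexts matrix with planted marker structure.

    Marker genes concentrate >90% of their total expression in their
    assigned context; background genes are near-uniform (concentrated
    Dirichlet), so TDEP recovers the planted sets.
    """
    contexts = config.context_names()
    k = len(contexts)
    n = len(genes)
    totals = rng.lognormal(mean=3.0, sigma=1.0, size=n)
    values = np.zeros((n, k))
    ctx_index = {c: j for j, c in enumerate(contexts)}
    for i, g in enumerate(genes):
        ctx = marker_assignment.get(g.gene_id)
        if ctx is not None:
            p = rng.uniform(0.92, 0.98)
            rest = rng.dirichlet(np.ones(k - 1)) * (1 - p)
            row = np.insert(rest, ctx_index[ctx], p)
        else:
            row = rng.dirichlet(np.full(k, 25.0))
        values[i] = row * totals[i]
    return pd.DataFrame(
        values, index=[g.gene_id for g in genes], columns=contexts
    )


def generate_cnvs(
    config: SyntheticConfig, genes: Sequence[GeneModel], rng: np.random.Generator
) -> List[CNVCall]:
    """Sparse multigenic CNV calls fully encompassing contiguous gene runs.

    Per sample and dosage type the CNV count is Poisson(cnv_rate); each
    CNV covers ``1 + Poisson(cnv_gene_span_mean - 1)`` consecutive genes
    of one chromosome, with breakpoints at the boundary genes' ends, so
    exactly that run is fully encompassed.
    """
    by_chrom: Dict[str, List[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    chroms = sorted(by_chrom)
    if not chroms:
        return []
    weights = np.array([len(by_chrom[c]) for c in chroms], dtype=float)
    weights /= weights.sum()
    calls: List[CNVCall] = []
    for s in range(config.n_samples):
        sample = f"S{s:06d}"
        for dtype in DOSAGE_TYPES:
            n_cnv = rng.poisson(config.cnv_rate)
            for _ in range(n_cnv):
                chrom = chroms[rng.choice(len(chroms), p=weights)]
                chrom_genes = by_chrom[chrom]
                span = 1 + rng.poisson(config.cnv_gene_span_mean - 1)
                start_idx = int(rng.integers(0, len(chrom_genes)))
                run = chrom_genes[start_idx : start_idx + span]
                calls.append(
                    CNVCall(sample, chrom, run[0].start, run[-1].end, dtype)
                )
    return calls


def generate_constraint_labels(
    config: SyntheticConfig,
    genes: Sequence[GeneModel],
    marker_assignment: Dict[str, str],
    rng: np.random.Generator,
) -> Dict[str, int]:
    """Binary top-decile constraint flags correlated with planted effects.

    Genes whose context carries larger total planted |beta| are sampled
    preferentially into the constrained decile, emulating the empirical
    coupling between constraint and effect size.
    """
    context_weight: Dict[str, float] = {}
    for eff in config.planted_effects:
        context_weight[eff.gene_set] = context_weight.get(eff.gene_set, 0.0) + abs(
            eff.beta
        )
    gene_ids = [g.gene_id for g in genes]
    w = np.ones(len(gene_ids))
    for i, gid in enumerate(gene_ids):
        ctx = marker_assignment.get(gid)
        if ctx is not None and ctx in context_weight:
            w[i] += 4.0 * context_weight[ctx]
    n_constrained = int(round(config.constraint_fraction * len(gene_ids)))
    labels = {gid: 0 for gid in gene_ids}
    if n_constrained > 0 and len(gene_ids) > 0:
        chosen = rng.choice(
            len(gene_ids), size=n_constrained, replace=False, p=w / w.sum()
        )
        for idx in chosen:
            labels[gene_ids[int(idx)]] = 1
    return labels


def generate_covariates(
    config: SyntheticConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Age ~ U(40,70), sex ~ Bernoulli(0.5), 10 iid standard-normal PCs."""
    samples = [f"S{s:06d}" for s in range(config.n_samples)]
    data = {
        "age": rng.uniform(40, 70, size=config.n_samples),
        "sex": rng.integers(0, 2, size=config.n_samples).astype(float),
    }
    for i in range(N_PCS):
        data[f"PC{i + 1}"] = rng.standard_normal(config.n_samples)
    return pd.DataFrame(data, index=samples)


def generate_traits(
    config: SyntheticConfig,
    truth: SyntheticTruth,
    burden: BurdenTable,
    covariates: pd.DataFrame,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Simulate traits from planted burden effects plus covariates and noise.

    Continuous trait: sum of planted beta·x1 terms, x2_beta·x2 nuisance
    terms, fixed covariate effects, and N(0, noise_sd²) noise. Binary
    trait: the same construction is standardized as a liability and
    thresholded at the (1 − K) standard-normal quantile.
    """
    samples = list(burden.samples)
    if list(covariates.index) != samples:
        raise ValueError("covariates must be indexed by the burden samples")
    pc_cols = [f"PC{i + 1}" for i in range(N_PCS)]
    pc_betas = {
        t.name: rng.normal(0.0, PC_BETA_SD, size=N_PCS) for t in config.trait_specs
    }
    cov_part_base = (
        AGE_BETA * covariates["age"].to_numpy()
        + SEX_BETA * covariates["sex"].to_numpy()
    )
    out = {}
    for spec in config.trait_specs:
        signal = np.zeros(len(samples))
        for eff in config.planted_effects:
            if eff.trait != spec.name:
                continue
            if eff.gene_set not in burden.set_names:
                raise ValueError(
                    f"planted effect references unknown gene set {eff.gene_set!r}"
                )
            signal += eff.beta * burden.x1(eff.dosage_type)[eff.gene_set].to_numpy()
            if config.x2_beta:
                signal += (
                    config.x2_beta
                    * burden.x2(eff.dosage_type)[eff.gene_set].to_numpy()
                )
        cov_part = cov_part_base + covariates[pc_cols].to_numpy() @ pc_betas[spec.name]
        y = signal + cov_part + rng.normal(0.0, config.noise_sd, size=len(samples))
        if spec.kind == "binary":
            z = (y - y.mean()) / y.std()
            thresh = stats.norm.ppf(1 - spec.prevalence)
            out[spec.name] = (z > thresh).astype(int)
        else:
            out[spec.name] = y
    return pd.DataFrame(out, index=samples)


@dataclass
class SyntheticCohort:
    """A fully generated cohort plus its ground truth."""

    config: SyntheticConfig
    gene_models: List[GeneModel]
    expression: pd.DataFrame
    marker_sets: GeneSetCollection  # the planted (true) sets
    cnvs: List[CNVCall]
    covariates: pd.DataFrame
    burden: BurdenTable  # burden on the true marker sets
    phenotypes: pd.DataFrame
    truth: SyntheticTruth

    @property
    def samples(self) -> Tuple[str, ...]:
        return self.burden.samples


def simulate_cohort(config: SyntheticConfig) -> SyntheticCohort:
    """Run all generation stages in their documented RNG order."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    genes = generate_gene_models(config, rng)
    marker_assignment = _assign_markers(config, genes, rng)
    expression = generate_expression(config, genes, marker_assignment, rng)
    cnvs = generate_cnvs(config, genes, rng)
    constraint = generate_constraint_labels(config, genes, marker_assignment, rng)
    covariates = generate_covariates(config, rng)
    truth = SyntheticTruth(
        marker_assignment=marker_assignment,
        planted_effects=list(config.planted_effects),
        constraint_labels=constraint,
        pairwise_trait_rg=dict(config.pairwise_trait_rg),
    )
    marker_sets = GeneSetCollection(
        truth.marker_sets(), universe=[g.gene_id for g in genes]
    )
    samples = [f"S{s:06d}" for s in range(config.n_samples)]
    burden = aggregate_burden(cnvs, genes, marker_sets, sample_ids=samples)
    phenotypes = generate_traits(config, truth, burden, covariates, rng)
    return SyntheticCohort(
        config=config,
        gene_models=genes,
        expression=expression,
        marker_sets=marker_sets,
        cnvs=cnvs,
        covariates=covariates,
        burden=burden,
        phenotypes=phenotypes,
        truth=truth,
    )
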