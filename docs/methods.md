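# Methods

## The functional burden model

Copy number variants (CNVs) — deletions and duplications of genomic
segments — change the dosage of every gene they fully encompass. Rather
than testing individual loci (which is underpowered for rare CNVs), the
functional burden test aggregates CNVs over *gene sets* that share a
biological context, and regresses each trait on the per-sample burden:

    trait = b0 + b1*x1 + b2*x2 + b3*age + b4*sex + sum_{i=1..10} c_i*PC_i + e

where, for one gene set and one dosage type (deletions and duplications
are always analyzed separately),

- `x1` — number of **distinct set-member** genes fully encompassed by the
  sample's CNVs of that type,
- `x2` — number of **distinct non-member** genes encompassed, the
  adjustment for the multigenic nature of CNVs. By default x2 only counts
  non-members on CNVs that also hit the set (`same_cnv` scope); the
  whole-sample scope (`all_cnvs`) is selectable because the per-sample
  semantics of "the same CNV" is ambiguous once several CNVs contribute.

Continuous traits are outlier-filtered (±6 SD around the sample mean,
computed on non-missing values) and inverse-rank-normal transformed,
IRNT: `Phi^{-1}((rank - 0.5)/n)` with average ranks for ties. The offset
convention is ours (it is the common one); it makes the result invariant
to strictly monotone transforms of the raw trait. `b1` is then in trait-SD
units per in-set disrupted gene. Binary traits are fitted by logistic
regression on the raw 0/1 outcome with the identical design, giving `b1`
on the log-odds scale; where cross-trait comparability is needed it is
moved to the liability scale by `b_liab = b_logit * phi(t) / (K(1-K))`
with `t = Phi^{-1}(1-K)` and `K` the prevalence.

Cells with constant x1 (no carriers) are *non-estimable*: they carry
`beta = 0, p = 1` and stay in the grid, because multiple-testing
correction (Benjamini–Hochberg) is applied jointly over the complete
gene-set × trait × dosage-type rectangle. **Functional pleiotropy** of a
gene set is the number (and percentage) of traits with q < 0.05.

## Gene sets: top decile expression proportion (TDEP)

Each gene's expression in a context (tissue or cell type) is divided by
its total across contexts; per context, the set holds the
`ceil(0.10 * n_eligible)` genes with the highest proportion. Genes with
zero total expression are excluded before the decile is taken (their
proportion is undefined). Ties at the boundary are broken by (proportion
descending, gene identifier ascending) — a deterministic choice we fixed
since no convention is standard. TDEP is scale-invariant per gene row,
which the tests assert.

## Overlap-conditioned permutation p-values (P-Jaccard)

TDEP sets overlap; statistics computed across sets (e.g. a correlation
between per-set constrained fraction and per-set pleiotropy) are
therefore not based on independent observations, and naive permutation
nulls are anti-conservative. Our null permutes the *gene-level* attribute
across the universe and re-derives the per-set statistic through the
unchanged memberships, so every null replicate carries exactly the
observed Jaccard matrix. This is the strongest form of conditioning on
overlap that admits a deterministic algorithm. p-values use the add-one
estimator `(1 + #{|null| >= |obs|})/(n_perm + 1)`, never below
`1/(n_perm+1)`. The calibration suite checks that with iid attributes and
heavily overlapping sets, the rejection rate at 0.05 stays inside the
binomial 95% envelope over 500 datasets.

For the covariance between two traits' effect-size profiles there is no
pre-existing gene-level attribute. We construct one: the second profile
is spread onto genes (each gene takes the mean profile value over the
sets containing it), and that per-gene score is what gets permuted. This
keeps the overlap structure fixed while randomizing which genes carry the
second trait's signal.

## Between-trait burden correlations

Per trait and dosage type:

1. covariates are regressed out (OLS for continuous traits; logistic fit
   with response-scale residuals `y - p̂` for binary traits, treated as
   continuous downstream);
2. redundant gene sets are dropped: a set is excluded when the rank
   percentile of its maximum pairwise Jaccard similarity exceeds 0.2 AND
   LASSO (10-fold CV, 1-SE rule, standardized predictors) removes it in
   at least 80% of traits. "Jaccard similarity percentile" is concretized
   as the rank percentile of each set's maximum off-diagonal similarity —
   redundancy against a best partner;
3. a joint ridge regression (penalty by 10-fold CV, fixed fold seed) of
   the residuals on all retained-set burdens gives the shrinkage-adjusted
   effect profile, reported back on the burden-count scale; binary-trait
   profiles are liability-rescaled;
4. the R² of an ordinary multiple regression of the residuals on the same
   burdens is the trait's h² proxy.

The burden correlation is `rg = Cov(profile_1, profile_2) /
sqrt(h²_1 * h²_2)` with the sample covariance across retained sets. rg is
reported unclamped with an out-of-range flag: the numerator and
denominator are estimated from different regressions and nothing
constrains the ratio to [-1, 1], especially when the h² proxies are
small. For the same reason the *magnitude* of rg is not scale-matched to
a planted effect-vector correlation; the recovery tests assert
monotonicity in the planted correlation and correct bracketing of zero,
which is what the estimator can promise. Sign concordance and fold ratios
between matrices (deletions vs duplications, or vs external SNP/LoF
matrices supplied as read-only inputs) are computed on upper-triangle
off-diagonal entries, excluding zero and missing cells.

## Constraint and the normative model

Constraint metrics (LOEUF, pLI, missense-Z, CDS, pHaplo, pTriplo, s-het,
gene length) enter only as per-gene binary top-decile flags supplied as
input files; the per-set *constrained fraction* is the share of members
flagged. The normative model asks how much pleiotropy a random gene set
with the same constrained fraction would show: for each fraction f on a
grid (default 0 to 0.6 in steps of 0.05) it draws `floor(f*set_size)`
constrained plus unconstrained genes without replacement, evaluates the
burden pleiotropy of that set, and repeats (default 100 per grid point —
we read the resample count as per-fraction). Centile curves
(5/10/25/50/75/90/95) summarize the null; an observed set is scored by
the midrank centile of its pleiotropy within the matched-fraction null,
flagged when outside the 5th–95th band; fractions outside the grid are
refused rather than extrapolated. The default documented set size is
1,298 genes; tests and the bundled pipeline use 50–100 genes with
proportionally reduced grids, which preserves the construction while
keeping simulations small. The resampling runner computes x2 on the
whole-sample (`all_cnvs`) scope, which is vectorizable; the main grid
keeps the `same_cnv` default.

## Gene dosage responses

For each (gene set, trait): if neither dosage type is FDR-significant the
response is `null`. Otherwise the *sign class* is monotonic when the
deletion and duplication effects have opposite signs (a zero product
counts as non-monotonic — a determinate rule for a degenerate case), and
the *evidence class* is `truly_monotonic`/`truly_non_monotonic` when both
types are significant, else `undetermined_del`/`undetermined_dup`, named
for the significant side. Undetermined responses still carry a sign class
so monotonic/non-monotonic proportions can be computed over all non-null
responses. The functional overlap between CNV-associated sets and a fixed
external reference list (e.g. common-variant enrichments) is tested by
redrawing the CNV side uniformly from the gene-set universe (1000
permutations, one-sided); on small universes this agrees with the
hypergeometric tail, which a test asserts.

## The synthetic cohort generator

The generator emulates the *structure* of a biobank CNV study at desk
scale, with full ground truth:

- **Genome** — non-overlapping genes (5–100 kb, 10–50 kb gaps) laid left
  to right on a few chromosomes. No LD, no array-probe noise, no calling
  artifacts (deliberately: those are properties of upstream calling
  pipelines, not of the analysis under test).
- **Expression** — each context has planted marker genes holding 92–98%
  of their total expression in that context; background genes are
  near-uniform (concentrated Dirichlet). TDEP must recover the markers.
- **CNVs** — per sample and dosage type, counts are Poisson(cnv_rate);
  each CNV spans `1 + Poisson(span_mean - 1)` consecutive genes with
  breakpoints at the run's boundary genes, so exactly that run is fully
  encompassed. Defaults: rate 0.8 per type, mean span 3 genes — sparse
  multigenic CNVs with enough carriers (~200 per set at n = 2000) that a
  planted |beta| of 0.5 sits well clear of its standard error.
- **Traits** — continuous traits are the planted linear burden signal
  plus fixed covariate effects (age 0.01/year, sex 0.1, small
  random-but-seeded PC loadings) plus N(0, noise_sd²); binary traits
  threshold the standardized liability at `Phi^{-1}(1-K)`. The x2
  nuisance coefficient defaults to 0 so that null configurations are
  exactly null. Correlated trait pairs are planted by drawing per-set
  effect vectors from a bivariate normal with the requested correlation.
- **Constraint** — a configurable fraction of genes is flagged
  top-decile, sampled preferentially from contexts carrying large planted
  effects, emulating the empirical coupling of constraint and effect
  size.

One `numpy.random.Generator` seeded from the config drives all stages in
a documented order, so identical configs give byte-identical cohorts.
What passing tests on this cohort do **not** show: robustness to CNV
call errors, to expression normalization choices across real atlases, to
ancestry structure beyond iid PCs, or to the sparsity regime of a
half-million-sample biobank (real per-sample CNV rates after filtering
are lower and sample sizes far larger; the defaults trade realism of the
rate for statistical power at n ≈ 2000).

## Numerical and design choices

- Coordinates are 1-based inclusive internally; BED input is converted on
  read (start + 1). Containment queries use per-chromosome sorted arrays;
  tests compare against an all-pairs scan oracle.
- BH-FDR and the two-proportion z-test go through statsmodels; LASSO and
  ridge through scikit-learn; the test suite keeps independent
  hand-written oracles for BH and the normal equations.
- Logistic fits that separate fall back to a lightly L2-penalized fit
  with a warning; in the association grid such cells are flagged
  non-estimable rather than dropped.
- Tabular outputs are TSV, floats at 6 significant digits; the pipeline
  manifest records input checksums, seeds, grid dimensions and versions,
  and a rerun from the same config is bit-identical.
- Simulation sizes in the tests (n = 1000–2000 samples, 600–1200 genes,
  12–25 replicates per recovery check, 100 normative resamples of
  60-gene sets) were chosen as the smallest cohorts at which the planted
  signals are comfortably identifiable; the acceptance script uses the
  same scales.

## Known limitations

- The redundancy filter can empty a small gene-set panel; the pipeline
  then falls back to the unfiltered panel with a warning (at realistic
  panel sizes the filter removes a small minority).
- h² proxies from R² are upward-biased at small n (≈ p/n under the null),
  which propagates into rg magnitudes; rg should be read comparatively,
  not as an absolute genetic correlation.
- The P-Jaccard construction fixes overlap exactly by permuting gene
  attributes; other readings of "conditioning on the Jaccard distance"
  (e.g. resampling sets at matched distances) exist and could give
  different nulls.
- Binary-trait machinery (logistic fit, response-scale residuals,
  liability rescaling of ridge coefficients) follows the stated analysis
  plan; the liability factor applied to a linear-model coefficient is an
  approximation inherited from that plan.
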