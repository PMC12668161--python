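"""Functional burden association testing.

The burden association model regresses a trait on the number of gene-set
member genes disrupted by CNVs (x1), adjusting for non-member disrupted
genes (x2) and age, sex, and ten ancestry principal components:

    trait = b0 + b1*x1 + b2*x2 + b3*age + b4*sex + sum_i c_i*PC_i + e

Continuous traits are outlier-filtered and inverse-rank-normal-transformed
(IRNT) before fitting by ordinary least squares, so b1 is in trait-SD
units per in-set disrupted gene. Binary traits are fitted by logistic
regression on the raw 0/1 outcome with the same design; b1 is then on the
log-odds scale and can be moved to the liability scale given prevalence.
The full grid of (gene set × trait × dosage type) associations is FDR
corrected jointly by Benjamini–Hochberg, and functional pleiotropy is the
number of traits significantly associated with a gene set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.proportion import proportions_ztest

from .burden import BurdenTable, DOSAGE_TYPES

__all__ = [
    "AssociationResult",
    "outlier_filter",
    "irnt",
    "fit_funburd",
    "fdr_correct",
    "association_grid",
    "pleiotropy",
    "proportion_compare",
    "liability_transform",
]

COVARIATE_COLUMNS = ["age", "sex"] + [f"PC{i + 1}" for i in range(10)]


@dataclass
class AssociationResult:
    gene_set: str
    trait: str
    dosage_type: str
    beta: float
    se: float
    p: float
    n_carriers: int
    estimable: bool = True
    q: Optional[float] = None


def outlier_filter(values: np.ndarray, k: float = 6.0) -> np.ndarray:
    """Mask of retained values: non-missing and within ±k SD of the mean.

    Mean and SD are computed on the non-missing values. A constant vector
    has SD 0; everything is retained with a warning.
    """
    values = np.asarray(values, dtype=float)
    if np.sum(~np.isnan(values)) < 2:
        raise ValueError("need at least two non-missing values")
    finite = ~np.isnan(values)
    mean = values[finite].mean()
    sd = values[finite].std(ddof=1)
    if sd == 0:
        warnings.warn("constant trait vector; no outliers to remove", stacklevel=2)
        return finite
    return finite & (np.abs(values - mean) <= k * sd)


def irnt(values: np.ndarray) -> np.ndarray:
    """Inverse rank normal transform: ranks to standard-normal quantiles.

    Uses the offset (rank − 0.5)/n with average ranks for ties, so the
    result depends only on the ordering of the input (invariant to any
    strictly monotone transform).
    """
    values = np.asarray(values, dtype=float)
    if np.unique(values).size < 2:
        raise ValueError("IRNT undefined for fewer than two distinct values")
    ranks = stats.rankdata(values, method="average")
    return stats.norm.ppf((ranks - 0.5) / len(values))


def _design(
    x1: np.ndarray, x2: np.ndarray, covariates: pd.DataFrame
) -> pd.DataFrame:
    X = pd.DataFrame({"x1": x1, "x2": x2}, index=covariates.index)
    for col in COVARIATE_COLUMNS:
        if col not in covariates.columns:
            raise ValueError(f"missing covariate column {col!r}")
        X[col] = covariates[col].to_numpy()
    return sm.add_constant(X, has_constant="add")


def fit_funburd(
    y: np.ndarray,
    x1: np.ndarray,
    x2: np.ndarray,
    covariates: pd.DataFrame,
    trait_type: str = "continuous",
    gene_set: str = "",
    trait: str = "",
    dosage_type: str = "",
) -> AssociationResult:
    """Fit the burden model for one (gene set, trait, dosage type) cell.

    Continuous traits: OLS on the (already IRNT-scaled) outcome. Binary
    traits: logistic regression on the raw 0/1 outcome, same design. When
    x1 is constant (no carriers, or all carriers identical) the cell is
    non-estimable and carries beta=0, p=1 so the grid stays rectangular
    for joint FDR.
    """
    y = np.asarray(y, dtype=float)
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    n_carriers = int(np.sum(x1 > 0))
    if np.all(x1 == x1[0]):
        return AssociationResult(
            gene_set, trait, dosage_type, 0.0, np.nan, 1.0, n_carriers, estimable=False
        )
    X = _design(x1, x2, covariates)
    constant = [
        c for c in X.columns if c not in ("const", "x1") and X[c].nunique() == 1
    ]
    if constant:
        warnings.warn(
            f"dropping constant design column(s) {constant}", stacklevel=2
        )
        X = X.drop(columns=constant)
    if trait_type == "continuous":
        fit = sm.OLS(y, X).fit()
    elif trait_type == "binary":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
                if not np.isfinite(fit.bse["x1"]):
                    raise ValueError("non-finite standard error")
            except Exception:
                # quasi-separation: fall back to a lightly L2-penalized fit
                warnings.warn(
                    "logistic fit failed or separated; using penalized fallback",
                    stacklevel=2,
                )
                fit = sm.GLM(y, X, family=sm.families.Binomial()).fit_regularized(
                    alpha=1e-4, L1_wt=0.0
                )
                beta = float(fit.params["x1"])
                return AssociationResult(
                    gene_set, trait, dosage_type, beta, np.nan, 1.0,
                    n_carriers, estimable=False,
                )
    else:
        raise ValueError(f"unknown trait_type {trait_type!r}")
    beta = float(fit.params["x1"])
    se = float(fit.bse["x1"])
    p = float(fit.pvalues["x1"])
    return AssociationResult(gene_set, trait, dosage_type, beta, se, p, n_carriers)


def fdr_correct(p_values: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values over the whole grid jointly."""
    p_values = np.asarray(p_values, dtype=float)
    return multipletests(p_values, method="fdr_bh")[1]


def association_grid(
    burden: BurdenTable,
    phenotypes: pd.DataFrame,
    covariates: pd.DataFrame,
    trait_types: Dict[str, str],
    outlier_k: float = 6.0,
) -> pd.DataFrame:
    """Fit the complete sets × traits × {DEL,DUP} association grid.

    Continuous traits are outlier-filtered (±outlier_k SD) then IRNT
    scaled on the analyzed samples; binary traits are used raw. Returns a
    long DataFrame with one row per cell and joint BH q-values; the grid
    is always rectangular (|sets| × |traits| × 2 rows).
    """
    results = []
    samples = list(burden.samples)
    cov = covariates.loc[samples]
    for trait in phenotypes.columns:
        ttype = trait_types[trait]
        y_raw = phenotypes[trait].to_numpy(dtype=float)
        if ttype == "continuous":
            keep = outlier_filter(y_raw, k=outlier_k)
            y = irnt(y_raw[keep])
        else:
            keep = ~np.isnan(y_raw)
            y = y_raw[keep]
        cov_t = cov.loc[keep]
        for dtype in DOSAGE_TYPES:
            x1_all = burden.x1(dtype).to_numpy()
            x2_all = burden.x2(dtype).to_numpy()
            for j, name in enumerate(burden.set_names):
                res = fit_funburd(
                    y, x1_all[keep, j], x2_all[keep, j], cov_t, ttype,
                    gene_set=name, trait=trait, dosage_type=dtype,
                )
                results.append(res)
    grid = pd.DataFrame(
        {
            "gene_set": [r.gene_set for r in results],
            "trait": [r.trait for r in results],
            "dosage_type": [r.dosage_type for r in results],
            "beta": [r.beta for r in results],
            "se": [r.se for r in results],
            "p": [r.p for r in results],
            "n_carriers": [r.n_carriers for r in results],
            "estimable": [r.estimable for r in results],
        }
    )
    grid["q"] = fdr_correct(grid["p"].to_numpy())
    expected = len(burden.set_names) * phenotypes.shape[1] * 2
    assert len(grid) == expected, "association grid is not rectangular"
    return grid


def pleiotropy(grid: pd.DataFrame, q_threshold: float = 0.05) -> pd.DataFrame:
    """Functional pleiotropy: per (gene set, dosage type), the number and
    percentage of traits with q below threshold."""
    n_traits = grid["trait"].nunique()
    sig = grid.assign(sig=grid["q"] < q_threshold)
    out = (
        sig.groupby(["gene_set", "dosage_type"], sort=True)["sig"]
        .sum()
        .rename("n_traits_significant")
        .reset_index()
    )
    out["pct_traits_significant"] = 100.0 * out["n_traits_significant"] / n_traits
    return out


def proportion_compare(count_a: int, n_a: int, count_b: int, n_b: int) -> float:
    """Two-sided two-proportion z-test p-value."""
    if n_a <= 0 or n_b <= 0:
        raise ValueError("group totals must be positive")
    if count_a > n_a or count_b > n_b:
        raise ValueError("counts cannot exceed totals")
    if count_a / n_a == count_b / n_b:
        return 1.0
    _, p = proportions_ztest([count_a, count_b], [n_a, n_b], alternative="two-sided")
    return float(p)


def liability_transform(beta_logistic: float, prevalence: float) -> float:
    """Rescale a log-odds effect to the liability scale.

    With t = Phi^{-1}(1 - K) the threshold for prevalence K, the factor is
    phi(t) / (K (1 - K)), phi the standard normal density. Symmetric in
    K vs 1 - K.
    """
    if not (0 < prevalence < 1):
        raise ValueError("prevalence must be in (0, 1)")
    t = stats.norm.ppf(1 - prevalence)
    return float(beta_logistic * stats.norm.pdf(t) / (prevalence * (1 - prevalence)))
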