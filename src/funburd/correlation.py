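"""Between-trait CNV burden correlations.

Analogue of genetic correlation for gene-set CNV burden: for each trait,
covariates are regressed out, a shrinkage-adjusted (ridge) effect-size
profile over a redundancy-filtered panel of gene sets is estimated, and
the variance explained (R²) by the panel serves as an h² proxy. The
burden correlation between two traits is then

    rg(T1, T2) = Cov(profile_T1, profile_T2) / sqrt(h²_T1 · h²_T2)

computed separately for deletions and duplications. Binary-trait profiles
are moved to the liability scale before the covariance so mixed trait
pairs are comparable. Redundant gene sets are dropped beforehand: a set is
excluded when its maximum pairwise Jaccard similarity sits above a rank
percentile threshold AND LASSO removes it in most traits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from sklearn.linear_model import Lasso, LassoCV, Ridge, RidgeCV
from sklearn.model_selection import KFold

from .assoc import liability_transform
from .genesets import GeneSetCollection
from .pjaccard import PermutationNull, _empirical_p

__all__ = [
    "RgEstimate",
    "residualize",
    "lasso_selection",
    "filter_genesets",
    "shrinkage_profile",
    "variance_explained",
    "burden_rg",
    "rg_pjaccard",
    "effect_profiles",
    "burden_correlation_matrix",
    "sign_concordance",
    "fold_ratio",
]


@dataclass
class RgEstimate:
    rg: float
    out_of_range: bool  # |rg| > 1, reported as-is with this flag


def residualize(
    y: np.ndarray, covariates: pd.DataFrame, trait_type: str = "continuous"
) -> np.ndarray:
    """Residuals of a trait after regressing out covariates.

    Continuous: OLS residuals. Binary: logistic regression, residuals on
    the response scale (observed − fitted probability), treated as a
    continuous outcome downstream. Separation triggers a warning and a
    lightly penalized fallback fit.
    """
    y = np.asarray(y, dtype=float)
    X = sm.add_constant(covariates, has_constant="add")
    if trait_type == "continuous":
        return np.asarray(sm.OLS(y, X).fit().resid)
    if trait_type == "binary":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
                if not np.all(np.isfinite(fit.bse)):
                    raise ValueError("separation")
                fitted = np.asarray(fit.predict(X))
            except Exception:
                warnings.warn(
                    "logistic covariate fit separated; penalized fallback",
                    stacklevel=2,
                )
                fit = sm.GLM(y, X, family=sm.families.Binomial()).fit_regularized(
                    alpha=1e-4, L1_wt=0.0
                )
                fitted = np.asarray(fit.predict(X))
        return y - fitted
    raise ValueError(f"unknown trait_type {trait_type!r}")


def _standardize(X: np.ndarray) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale_safe = np.where(scale == 0, 1.0, scale)
    return (X - mean) / scale_safe, mean, scale_safe


def lasso_selection(
    residuals: pd.DataFrame,
    burden_x1: pd.DataFrame,
    alpha: Optional[float] = None,
    seed: int = 0,
) -> Tuple[pd.DataFrame, pd.Series]:
    """LASSO variable selection of gene sets, per trait.

    Burden predictors are standardized; the penalty is chosen per trait by
    10-fold cross-validation at the 1-SE rule unless ``alpha`` is given.
    Returns (selected indicator traits × sets, removal frequency per set =
    fraction of traits in which the coefficient is exactly zero).
    """
    if burden_x1.shape[1] == 0:
        raise ValueError("empty burden matrix")
    Xs, _, _ = _standardize(burden_x1.to_numpy(dtype=float))
    selected = {}
    for trait in residuals.columns:
        y = residuals[trait].to_numpy(dtype=float)
        if alpha is None:
            cv = KFold(n_splits=10, shuffle=True, random_state=seed)
            lcv = LassoCV(cv=cv, max_iter=20000).fit(Xs, y)
            mean_mse = lcv.mse_path_.mean(axis=1)
            se_mse = lcv.mse_path_.std(axis=1, ddof=1) / np.sqrt(
                lcv.mse_path_.shape[1]
            )
            best = int(np.argmin(mean_mse))
            limit = mean_mse[best] + se_mse[best]
            # alphas_ are descending; take the largest alpha within 1 SE
            ok = np.nonzero(mean_mse <= limit)[0]
            alpha_t = float(lcv.alphas_[ok.min()])
        else:
            alpha_t = alpha
        model = Lasso(alpha=alpha_t, max_iter=20000).fit(Xs, y)
        selected[trait] = model.coef_ != 0
    indicator = pd.DataFrame(selected, index=burden_x1.columns).T
    removal_freq = 1.0 - indicator.mean(axis=0)
    return indicator, removal_freq


def filter_genesets(
    jaccard: pd.DataFrame,
    removal_freq: pd.Series,
    pct_threshold: float = 0.2,
    freq_threshold: float = 0.8,
) -> List[str]:
    """Drop redundant gene sets; return the retained set names.

    A set is excluded when BOTH hold: (i) the rank percentile, among all
    sets, of its maximum off-diagonal Jaccard similarity exceeds
    ``pct_threshold``; (ii) LASSO removed it in at least ``freq_threshold``
    of traits.
    """
    names = list(jaccard.index)
    jac = jaccard.to_numpy().copy()
    np.fill_diagonal(jac, -np.inf)
    max_sim = jac.max(axis=1)
    percentile = stats.rankdata(max_sim, method="average") / len(names)
    excluded = set()
    for i, name in enumerate(names):
        if percentile[i] > pct_threshold and removal_freq.get(name, 0.0) >= freq_threshold:
            excluded.add(name)
    return [n for n in names if n not in excluded]


def shrinkage_profile(
    residuals: np.ndarray,
    burden_x1: pd.DataFrame,
    alpha: Optional[float] = None,
    seed: int = 0,
) -> pd.Series:
    """Joint ridge regression effect-size profile over retained gene sets.

    Predictors are standardized for the penalized fit; coefficients are
    reported back on the original burden-count scale.
    """
    y = np.asarray(residuals, dtype=float)
    Xs, _, scale = _standardize(burden_x1.to_numpy(dtype=float))
    if alpha is None:
        cv = KFold(n_splits=10, shuffle=True, random_state=seed)
        model = RidgeCV(alphas=np.logspace(-3, 5, 25), cv=cv).fit(Xs, y)
        coef = model.coef_
    else:
        coef = Ridge(alpha=alpha).fit(Xs, y).coef_
    return pd.Series(coef / scale, index=burden_x1.columns)


def variance_explained(residuals: np.ndarray, burden_x1: pd.DataFrame) -> float:
    """R² of the residualized trait on the retained-set burdens (h² proxy)."""
    y = np.asarray(residuals, dtype=float)
    n, p = burden_x1.shape
    if n <= p:
        raise ValueError(f"need n_samples > n_sets ({n} <= {p}); proxy undefined")
    X = sm.add_constant(burden_x1.to_numpy(dtype=float), has_constant="add")
    return float(sm.OLS(y, X).fit().rsquared)


def burden_rg(
    profile1: np.ndarray, profile2: np.ndarray, h1_sq: float, h2_sq: float
) -> RgEstimate:
    """Burden correlation: Cov(profiles) / sqrt(h1² · h2²), unclamped."""
    if h1_sq <= 0 or h2_sq <= 0:
        raise ValueError("heritability proxies must be positive")
    p1 = np.asarray(profile1, dtype=float)
    p2 = np.asarray(profile2, dtype=float)
    if p1.shape != p2.shape:
        raise ValueError("profiles must be aligned over the same gene sets")
    cov = float(np.cov(p1, p2, ddof=1)[0, 1])
    rg = cov / float(np.sqrt(h1_sq * h2_sq))
    return RgEstimate(rg=rg, out_of_range=abs(rg) > 1)


def rg_pjaccard(
    profile1: pd.Series,
    profile2: pd.Series,
    collection: GeneSetCollection,
    n_perm: int = 1000,
    seed: Optional[int] = None,
) -> PermutationNull:
    """Overlap-conditioned permutation p for a profile covariance.

    The second trait's per-set profile is spread onto genes (each gene
    gets the mean profile value of the sets containing it); null
    replicates permute that gene attribute and re-derive per-set means
    through the fixed memberships, preserving the Jaccard structure.
    """
    names = [n for n in collection.names if n in profile1.index]
    sub = GeneSetCollection(
        {n: collection.sets[n] for n in names}, universe=collection.universe
    )
    mat, _, genes = sub.membership_matrix()
    p1 = profile1.loc[list(names)].to_numpy(dtype=float)
    p2 = profile2.loc[list(names)].to_numpy(dtype=float)
    sizes = mat.sum(axis=1).astype(float)
    counts = mat.sum(axis=0).astype(float)  # sets per gene
    in_any = counts > 0
    attr = np.zeros(mat.shape[1])
    attr[in_any] = (mat.T @ p2)[in_any] / counts[in_any]
    observed = float(np.cov(p1, (mat @ attr) / sizes, ddof=1)[0, 1])
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for r in range(n_perm):
        perm = rng.permutation(attr)
        null[r] = float(np.cov(p1, (mat @ perm) / sizes, ddof=1)[0, 1])
    p = _empirical_p(observed, null, two_sided=True)
    return PermutationNull(observed, null, p, seed, n_perm)


def effect_profiles(
    phenotypes: pd.DataFrame,
    covariates: pd.DataFrame,
    burden_x1: pd.DataFrame,
    trait_types: Dict[str, str],
    prevalences: Optional[Dict[str, float]] = None,
    alpha: Optional[float] = None,
    seed: int = 0,
) -> Tuple[pd.DataFrame, pd.Series]:
    """Shrinkage effect profiles and h² proxies for every trait.

    Returns (profiles: sets × traits, h²: per trait). Binary-trait
    profiles are converted to the liability scale using the observed
    prevalence unless one is supplied.
    """
    prevalences = prevalences or {}
    profiles = {}
    h2 = {}
    for trait in phenotypes.columns:
        ttype = trait_types[trait]
        y = phenotypes[trait].to_numpy(dtype=float)
        resid = residualize(y, covariates, ttype)
        prof = shrinkage_profile(resid, burden_x1, alpha=alpha, seed=seed)
        if ttype == "binary":
            k = prevalences.get(trait, float(np.mean(y)))
            factor = liability_transform(1.0, k)
            prof = prof * factor
        profiles[trait] = prof
        h2[trait] = variance_explained(resid, burden_x1)
    return pd.DataFrame(profiles), pd.Series(h2, name="h2")


def burden_correlation_matrix(
    profiles: pd.DataFrame,
    h2: pd.Series,
    collection: Optional[GeneSetCollection] = None,
    n_perm: int = 1000,
    seed: Optional[int] = None,
) -> Tuple[pd.DataFrame, Optional[pd.DataFrame]]:
    """Trait × trait rg matrix (and P-Jaccard p-values when a collection
    is supplied). The diagonal is set to NaN — it is not reported."""
    traits = list(profiles.columns)
    rg = pd.DataFrame(np.nan, index=traits, columns=traits)
    pvals = (
        pd.DataFrame(np.nan, index=traits, columns=traits)
        if collection is not None
        else None
    )
    for i, a in enumerate(traits):
        for b in traits[i + 1 :]:
            est = burden_rg(
                profiles[a].to_numpy(), profiles[b].to_numpy(), h2[a], h2[b]
            )
            rg.loc[a, b] = rg.loc[b, a] = est.rg
            if collection is not None:
                res = rg_pjaccard(
                    profiles[a], profiles[b], collection, n_perm=n_perm, seed=seed
                )
                pvals.loc[a, b] = pvals.loc[b, a] = res.p
    return rg, pvals


def _offdiag_upper(matrix: pd.DataFrame) -> np.ndarray:
    m = matrix.to_numpy(dtype=float)
    iu = np.triu_indices_from(m, k=1)
    return m[iu]


def sign_concordance(matrix_a: pd.DataFrame, matrix_b: pd.DataFrame) -> float:
    """Percentage of upper-triangle trait pairs with matching rg sign
    (pairs where either value is zero or missing are excluded)."""
    a = _offdiag_upper(matrix_a)
    b = _offdiag_upper(matrix_b)
    keep = (a != 0) & (b != 0) & np.isfinite(a) & np.isfinite(b)
    if keep.sum() == 0:
        raise ValueError("no comparable nonzero pairs")
    return float(100.0 * np.mean(np.sign(a[keep]) == np.sign(b[keep])))


def fold_ratio(matrix_a: pd.DataFrame, matrix_b: pd.DataFrame) -> float:
    """Ratio of mean absolute off-diagonal correlations, A over B."""
    a = _offdiag_upper(matrix_a)
    b = _offdiag_upper(matrix_b)
    denom = np.nanmean(np.abs(b))
    if denom == 0 or not np.isfinite(denom):
        raise ValueError("zero or undefined denominator matrix")
    return float(np.nanmean(np.abs(a)) / denom)
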