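"""Constraint summaries and the normative resampling model.

Pleiotropy (the number of traits a gene set associates with) correlates
with genetic constraint: sets richer in top-decile constrained genes tend
to hit more traits. To express a gene set's pleiotropy relative to what
*any* set with the same constrained fraction would show, the normative
model resamples random gene sets at a grid of constrained fractions —
``floor(f · set_size)`` constrained genes plus unconstrained genes, drawn
without replacement — runs the burden association machinery on each, and
records centile bands of the resulting pleiotropy. An observed set is
then scored as a centile within the matched-fraction null; falling
outside the 5th–95th band flags higher (or lower) pleiotropy than its
constraint level explains.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, Iterable, List, Optional, Sequence, Set

import numpy as np
import pandas as pd
from scipy import stats

from .genesets import GeneSetCollection
from .pjaccard import PermutationNull, pjaccard_correlation

__all__ = [
    "CENTILES",
    "NormativeBands",
    "constrained_fraction",
    "constraint_pleiotropy_correlation",
    "normative_model",
    "normalized_pleiotropy",
    "group_difference",
]

CENTILES = (5, 10, 25, 50, 75, 90, 95)


def constrained_fraction(gene_set: Iterable[str], top_decile_genes: Set[str]) -> float:
    """Fraction of set members in the constrained top decile."""
    members = set(gene_set)
    if not members:
        raise ValueError("empty gene set")
    return len(members & set(top_decile_genes)) / len(members)


def constraint_pleiotropy_correlation(
    fractions: np.ndarray,
    pleiotropy_counts: np.ndarray,
    collection: GeneSetCollection,
    constraint_flags: pd.Series,
    n_perm: int = 1000,
    seed: Optional[int] = None,
) -> PermutationNull:
    """Pearson r between per-set constrained fraction and pleiotropy, with
    an overlap-conditioned (P-Jaccard) permutation p-value.

    The constrained fraction is exactly the per-set mean of the binary
    constraint flags, so the flags serve as the permuted gene attribute.
    """
    fractions = np.asarray(fractions, dtype=float)
    counts = np.asarray(pleiotropy_counts, dtype=float)
    if np.std(fractions) == 0 or np.std(counts) == 0:
        raise ValueError("constant vector; correlation undefined")
    return pjaccard_correlation(
        constraint_flags, counts, collection, n_perm=n_perm, seed=seed
    )


@dataclass
class NormativeBands:
    """Centile curves of null pleiotropy on a grid of constrained fractions."""

    fractions: List[float]
    centiles: pd.DataFrame  # rows: fraction, columns: centile, values
    null_draws: Dict[float, np.ndarray]
    set_size: int
    n_reps: int
    seed: Optional[int]
    skipped: List[float] = field(default_factory=list)

    def band(self, fraction: float, low: int = 5, high: int = 95):
        row = self._nearest(fraction)
        return float(row[low]), float(row[high])

    def _nearest(self, fraction: float) -> pd.Series:
        grid = np.asarray(self.fractions)
        if fraction < grid.min() - 1e-9 or fraction > grid.max() + 1e-9:
            raise ValueError(
                f"fraction {fraction:.3f} outside the normative grid "
                f"[{grid.min():.2f}, {grid.max():.2f}]; extrapolation refused"
            )
        return self.centiles.loc[self.fractions[int(np.argmin(np.abs(grid - fraction)))]]


def normative_model(
    universe: Sequence[str],
    constraint_flags: pd.Series,
    pleiotropy_fn: Callable[[Sequence[str]], float],
    fraction_grid: Sequence[float] = tuple(np.round(np.arange(0, 0.65, 0.05), 2)),
    set_size: int = 1298,
    n_reps: int = 100,
    seed: Optional[int] = None,
) -> NormativeBands:
    """Null pleiotropy bands from resampled gene sets at matched constraint.

    For each fraction f in the grid and each of ``n_reps`` replicates, a
    gene set of ``set_size`` genes is drawn without replacement with
    ``floor(f · set_size)`` constrained and the remainder unconstrained
    genes; ``pleiotropy_fn`` evaluates the burden pleiotropy of that set.
    Grid points that request more constrained (or unconstrained) genes
    than exist are skipped with a warning entry in ``skipped``.
    """
    rng = np.random.default_rng(seed)
    universe = list(universe)
    flags = constraint_flags.reindex(universe)
    if flags.isna().any():
        raise ValueError("constraint flags undefined for part of the universe")
    constrained = np.array([g for g in universe if flags[g] == 1])
    unconstrained = np.array([g for g in universe if flags[g] != 1])
    rows = {}
    draws: Dict[float, np.ndarray] = {}
    skipped: List[float] = []
    for f in fraction_grid:
        n_con = int(np.floor(f * set_size))
        n_unc = set_size - n_con
        if n_con > len(constrained) or n_unc > len(unconstrained):
            skipped.append(float(f))
            continue
        values = np.empty(n_reps)
        for r in range(n_reps):
            pick_c = rng.choice(constrained, size=n_con, replace=False)
            pick_u = rng.choice(unconstrained, size=n_unc, replace=False)
            values[r] = float(pleiotropy_fn(np.concatenate([pick_c, pick_u])))
        draws[float(f)] = values
        rows[float(f)] = {c: float(np.percentile(values, c)) for c in CENTILES}
    if not rows:
        raise ValueError("every grid point was skipped; universe too small")
    centiles = pd.DataFrame(rows).T.sort_index()
    centiles.columns = list(CENTILES)
    return NormativeBands(
        fractions=list(centiles.index),
        centiles=centiles,
        null_draws=draws,
        set_size=set_size,
        n_reps=n_reps,
        seed=seed,
        skipped=skipped,
    )


def normalized_pleiotropy(
    observed: float, fraction: float, bands: NormativeBands
) -> Dict[str, float]:
    """Centile of an observed pleiotropy within the matched-fraction null.

    Uses the midrank convention, centile = 100·(#{null < obs} + 0.5·#{null
    = obs} + 0.5)/(n+1), which avoids hard 0/100 saturation at small rep
    counts. ``outlier`` is 1.0 when the observation falls outside the
    5th–95th band of the nearest grid point.
    """
    bands._nearest(fraction)  # validates range
    grid = np.asarray(bands.fractions)
    key = bands.fractions[int(np.argmin(np.abs(grid - fraction)))]
    null = bands.null_draws[key]
    less = int(np.sum(null < observed))
    equal = int(np.sum(null == observed))
    centile = 100.0 * (less + 0.5 * equal + 0.5) / (len(null) + 1)
    lo, hi = bands.band(fraction)
    outlier = float(observed < lo or observed > hi)
    return {"centile": centile, "outlier": outlier, "band_low": lo, "band_high": hi}


def group_difference(values_a: Sequence[float], values_b: Sequence[float]) -> float:
    """Two-sided Wilcoxon rank-sum p-value (exact where feasible)."""
    a = np.asarray(list(values_a), dtype=float)
    b = np.asarray(list(values_b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    return float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
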