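"""Expression-defined gene sets via Top Decile Expression Proportion (TDEP).

A gene's expression proportion in a context (tissue or cell type) is its
expression there divided by its total expression across all contexts. For
each context, the gene set is the top decile of genes ranked by that
proportion — genes whose expression is most concentrated in the context.
Sets built this way partially overlap; the pairwise Jaccard structure is
computed here because downstream permutation tests condition on it.
"""

from __future__ import annotations

import math
from typing import Dict, Iterable, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "GeneSetCollection",
    "expression_proportion",
    "build_tdep_sets",
    "jaccard_matrix",
    "mean_overlap",
]


class GeneSetCollection:
    """Named gene sets over a common gene universe.

    Parameters
    ----------
    sets
        Mapping of set name to member gene identifiers. Members are stored
        sorted; no set may be empty.
    universe
        All gene identifiers sets may draw from. Defaults to the union of
        the members. Every member must belong to the universe.
    annotations
        Optional mapping of set name to a dict with keys ``brain`` (bool)
        and ``level`` (``tissue`` | ``body-cell`` | ``brain-cell``).
        Annotations are curated metadata, never inferred.
    """

    def __init__(
        self,
        sets: Mapping[str, Iterable[str]],
        universe: Optional[Iterable[str]] = None,
        annotations: Optional[Mapping[str, dict]] = None,
    ):
        stored: Dict[str, Tuple[str, ...]] = {}
        for name, members in sets.items():
            members = tuple(sorted(set(members)))
            if not members:
                raise ValueError(f"gene set {name!r} is empty")
            stored[name] = members
        self.sets = stored
        if universe is None:
            universe = sorted({g for m in stored.values() for g in m})
        self.universe: Tuple[str, ...] = tuple(sorted(set(universe)))
        uni = set(self.universe)
        for name, members in stored.items():
            missing = set(members) - uni
            if missing:
                raise ValueError(
                    f"gene set {name!r} has members outside the universe: "
                    f"{sorted(missing)[:5]}"
                )
        self.annotations = dict(annotations) if annotations else {}

    @property
    def names(self) -> Tuple[str, ...]:
        return tuple(self.sets.keys())

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> Tuple[str, ...]:
        return self.sets[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def __eq__(self, other) -> bool:
        if not isinstance(other, GeneSetCollection):
            return NotImplemented
        return (
            self.sets == other.sets
            and self.universe == other.universe
            and self.annotations == other.annotations
        )

    def membership_matrix(
        self, gene_order: Optional[Sequence[str]] = None
    ) -> Tuple[np.ndarray, Tuple[str, ...], Tuple[str, ...]]:
        """Boolean sets × genes indicator matrix.

        Returns ``(matrix, set_names, gene_order)``. The matrix is the
        fixed overlap structure that overlap-conditioned permutations keep
        bit-identical across null replicates.
        """
        genes = tuple(gene_order) if gene_order is not None else self.universe
        index = {g: j for j, g in enumerate(genes)}
        mat = np.zeros((len(self.sets), len(genes)), dtype=bool)
        for i, members in enumerate(self.sets.values()):
            for g in members:
                if g in index:
                    mat[i, index[g]] = True
        return mat, self.names, genes

    def brain_names(self) -> Tuple[str, ...]:
        return tuple(
            n for n in self.names if self.annotations.get(n, {}).get("brain", False)
        )


def expression_proportion(expr: pd.DataFrame) -> pd.DataFrame:
    """Per-gene expression proportions across contexts.

    Each gene's row is divided by its row total so that rows sum to 1.
    Genes with zero total expression have an undefined proportion and are
    returned as all-NaN rows; callers exclude them from the eligible
    universe before taking deciles.

    Raises
    ------
    ValueError
        If any expression value is negative, or gene/context identifiers
        are duplicated.
    """
    if expr.index.has_duplicates:
        raise ValueError("duplicate gene identifiers in expression matrix")
    if expr.columns.has_duplicates:
        raise ValueError("duplicate context identifiers in expression matrix")
    values = expr.to_numpy(dtype=float)
    if np.any(values < 0):
        raise ValueError("expression values must be non-negative")
    totals = values.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        prop = values / totals[:, None]
    prop[totals == 0] = np.nan
    return pd.DataFrame(prop, index=expr.index, columns=expr.columns)


def build_tdep_sets(
    prop: pd.DataFrame,
    decile: float = 0.10,
    annotations: Optional[Mapping[str, dict]] = None,
) -> GeneSetCollection:
    """Top-decile expression-proportion gene sets, one per context.

    For each context the set holds the ``ceil(decile * n_eligible)`` genes
    with the highest proportion there. Eligible genes are those with a
    defined proportion (non-zero total expression). Ties at the decile
    boundary are broken deterministically by (proportion descending, gene
    identifier ascending).
    """
    if not (0 < decile <= 1):
        raise ValueError(f"decile must be in (0, 1], got {decile}")
    eligible = prop.dropna(how="any")
    n_eligible = len(eligible)
    if n_eligible == 0:
        raise ValueError("no eligible genes (all have zero total expression)")
    size = math.ceil(decile * n_eligible)
    # stable two-key sort: gene id ascending, then proportion descending
    by_id = eligible.sort_index(kind="mergesort")
    sets = {}
    for context in prop.columns:
        order = np.argsort(-by_id[context].to_numpy(), kind="stable")
        sets[str(context)] = list(by_id.index[order[:size]])
    return GeneSetCollection(sets, universe=eligible.index, annotations=annotations)


def jaccard_matrix(collection: GeneSetCollection) -> pd.DataFrame:
    """Pairwise Jaccard similarity J(A,B) = |A∩B| / |A∪B| between sets.

    Symmetric with unit diagonal; the Jaccard *distance* is ``1 - J``.
    """
    if len(collection) < 2:
        raise ValueError("need at least two gene sets")
    mat, names, _ = collection.membership_matrix()
    m = mat.astype(np.int64)
    inter = m @ m.T
    sizes = m.sum(axis=1)
    union = sizes[:, None] + sizes[None, :] - inter
    with np.errstate(invalid="ignore"):
        jac = inter / union
    return pd.DataFrame(jac, index=list(names), columns=list(names))


def mean_overlap(collection: GeneSetCollection) -> float:
    """Mean off-diagonal pairwise Jaccard similarity across the sets."""
    jac = jaccard_matrix(collection).to_numpy()
    n = jac.shape[0]
    off = ~np.eye(n, dtype=bool)
    return float(jac[off].mean())
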