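"""CNV-to-gene annotation and per-sample gene-set burden aggregation.

A gene counts as disrupted by a CNV only when it is *fully encompassed*
(gene interval contained in the CNV interval on the same chromosome), since
full deletion or duplication is what guarantees a large dosage change.
Burden for a (sample, gene set, dosage type) cell is the pair

    x1 = number of distinct set-member genes fully encompassed
    x2 = number of distinct non-member genes fully encompassed

x2 is the multigenicity adjustment; by default it only counts non-members
carried by CNVs that also hit the set ("same_cnv" scope). Deletions and
duplications are never pooled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .genesets import GeneSetCollection

__all__ = [
    "DOSAGE_TYPES",
    "GeneModel",
    "CNVCall",
    "BurdenTable",
    "CnvGeneHits",
    "genes_fully_encompassed",
    "index_cnv_gene_hits",
    "aggregate_burden",
]

DOSAGE_TYPES: Tuple[str, str] = ("DEL", "DUP")


@dataclass(frozen=True)
class GeneModel:
    """A gene as a 1-based inclusive genomic interval."""

    gene_id: str
    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if self.start < 0 or self.end < 0:
            raise ValueError(f"negative coordinate in gene {self.gene_id}")
        if self.start > self.end:
            raise ValueError(f"start > end in gene {self.gene_id}")


@dataclass(frozen=True)
class CNVCall:
    """A deletion or duplication call, 1-based inclusive coordinates."""

    sample_id: str
    chrom: str
    start: int
    end: int
    dosage_type: str

    def __post_init__(self):
        if self.start < 0 or self.end < 0:
            raise ValueError(f"negative coordinate in CNV for {self.sample_id}")
        if self.start > self.end:
            raise ValueError(f"start > end in CNV for {self.sample_id}")
        if self.dosage_type not in DOSAGE_TYPES:
            raise ValueError(f"unknown dosage type {self.dosage_type!r}")


class _GeneIndex:
    """Per-chromosome sorted arrays for containment queries."""

    def __init__(self, genes: Sequence[GeneModel]):
        self.gene_ids = np.array([g.gene_id for g in genes], dtype=object)
        self.by_chrom: Dict[str, Tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        chroms: Dict[str, List[int]] = {}
        for i, g in enumerate(genes):
            chroms.setdefault(g.chrom, []).append(i)
        for chrom, idx in chroms.items():
            idx = np.asarray(idx)
            starts = np.array([genes[i].start for i in idx])
            ends = np.array([genes[i].end for i in idx])
            order = np.argsort(starts, kind="stable")
            self.by_chrom[chrom] = (starts[order], ends[order], idx[order])

    def contained(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Indices (into the original gene list) fully inside [start, end]."""
        if chrom not in self.by_chrom:
            return np.empty(0, dtype=int)
        starts, ends, idx = self.by_chrom[chrom]
        lo = np.searchsorted(starts, start, side="left")
        hi = np.searchsorted(starts, end, side="right")
        sel = ends[lo:hi] <= end
        return idx[lo:hi][sel]


def genes_fully_encompassed(cnv: CNVCall, genes: Sequence[GeneModel]) -> List[str]:
    """Identifiers of genes fully contained in the CNV interval."""
    index = _GeneIndex(genes)
    hit = index.contained(cnv.chrom, cnv.start, cnv.end)
    return sorted(index.gene_ids[hit])


@dataclass
class CnvGeneHits:
    """Pre-resolved CNV→gene containment, reusable across many gene sets.

    ``per_cnv[sample_id][dosage_type]`` is a list of integer gene-index
    arrays, one per CNV of that type carried by the sample. Gene indices
    refer to ``gene_ids`` order.
    """

    gene_ids: Tuple[str, ...]
    samples: Tuple[str, ...]
    per_cnv: Dict[str, Dict[str, List[np.ndarray]]]

    def union_hits(self, sample: str, dosage_type: str) -> np.ndarray:
        arrays = self.per_cnv.get(sample, {}).get(dosage_type, [])
        if not arrays:
            return np.empty(0, dtype=int)
        return np.unique(np.concatenate(arrays))

    def x1_counts(self, member_mask: np.ndarray, dosage_type: str) -> np.ndarray:
        """Distinct in-set genes hit, per sample, for one dosage type."""
        out = np.zeros(len(self.samples), dtype=int)
        for s, sample in enumerate(self.samples):
            hits = self.union_hits(sample, dosage_type)
            if hits.size:
                out[s] = int(member_mask[hits].sum())
        return out


def index_cnv_gene_hits(
    cnvs: Sequence[CNVCall],
    genes: Sequence[GeneModel],
    sample_ids: Optional[Sequence[str]] = None,
) -> CnvGeneHits:
    """Resolve every CNV to the gene indices it fully encompasses."""
    index = _GeneIndex(genes)
    if sample_ids is None:
        sample_ids = sorted({c.sample_id for c in cnvs})
    samples = tuple(sample_ids)
    known = set(samples)
    per_cnv: Dict[str, Dict[str, List[np.ndarray]]] = {}
    for cnv in cnvs:
        if cnv.sample_id not in known:
            raise ValueError(f"CNV sample {cnv.sample_id!r} not in sample_ids")
        hit = index.contained(cnv.chrom, cnv.start, cnv.end)
        per_cnv.setdefault(cnv.sample_id, {}).setdefault(cnv.dosage_type, []).append(
            np.sort(hit)
        )
    gene_ids = tuple(g.gene_id for g in genes)
    return CnvGeneHits(gene_ids=gene_ids, samples=samples, per_cnv=per_cnv)


class BurdenTable:
    """Per-sample, per-gene-set, per-dosage-type burden counts.

    Stores dense samples × sets matrices of x1 and x2 per dosage type;
    ``to_long`` serializes to the exchanged long TSV layout.
    """

    def __init__(
        self,
        samples: Sequence[str],
        set_names: Sequence[str],
        x1: Dict[str, np.ndarray],
        x2: Dict[str, np.ndarray],
        x2_scope: str,
    ):
        self.samples = tuple(samples)
        self.set_names = tuple(set_names)
        self._x1 = x1
        self._x2 = x2
        self.x2_scope = x2_scope

    def x1(self, dosage_type: str) -> pd.DataFrame:
        return pd.DataFrame(
            self._x1[dosage_type], index=list(self.samples), columns=list(self.set_names)
        )

    def x2(self, dosage_type: str) -> pd.DataFrame:
        return pd.DataFrame(
            self._x2[dosage_type], index=list(self.samples), columns=list(self.set_names)
        )

    def to_long(self) -> pd.DataFrame:
        rows = []
        for dtype in DOSAGE_TYPES:
            x1 = self._x1[dtype]
            x2 = self._x2[dtype]
            for j, name in enumerate(self.set_names):
                rows.append(
                    pd.DataFrame(
                        {
                            "sample_id": list(self.samples),
                            "gene_set": name,
                            "dosage_type": dtype,
                            "x1": x1[:, j],
                            "x2": x2[:, j],
                        }
                    )
                )
        return pd.concat(rows, ignore_index=True)

    def equals(self, other: "BurdenTable") -> bool:
        return (
            self.samples == other.samples
            and self.set_names == other.set_names
            and all(np.array_equal(self._x1[d], other._x1[d]) for d in DOSAGE_TYPES)
            and all(np.array_equal(self._x2[d], other._x2[d]) for d in DOSAGE_TYPES)
        )


def aggregate_burden(
    cnvs: Sequence[CNVCall],
    genes: Sequence[GeneModel],
    collection: GeneSetCollection,
    sample_ids: Optional[Sequence[str]] = None,
    x2_scope: str = "same_cnv",
) -> BurdenTable:
    """Aggregate per-sample burden (x1, x2) for every gene set and dosage type.

    Parameters
    ----------
    x2_scope
        ``"same_cnv"`` (default): x2 counts distinct non-member genes on
        CNVs that encompass at least one set member — the multigenic
        adjustment local to contributing CNVs. ``"all_cnvs"``: distinct
        non-members across all the sample's CNVs of that type.

    Gene-set members absent from the gene models are ignored with a
    warning; counting is over distinct genes (a gene hit by two same-type
    CNVs counts once).
    """
    if x2_scope not in ("same_cnv", "all_cnvs"):
        raise ValueError(f"unknown x2_scope {x2_scope!r}")
    hits = index_cnv_gene_hits(cnvs, genes, sample_ids=sample_ids)
    gene_pos = {g: i for i, g in enumerate(hits.gene_ids)}
    n_genes = len(hits.gene_ids)

    masks = np.zeros((len(collection), n_genes), dtype=bool)
    for j, (name, members) in enumerate(collection.sets.items()):
        unknown = [g for g in members if g not in gene_pos]
        if unknown:
            warnings.warn(
                f"gene set {name!r}: {len(unknown)} member(s) missing from gene "
                "models; ignored",
                stacklevel=2,
            )
        for g in members:
            if g in gene_pos:
                masks[j, gene_pos[g]] = True

    n_samples = len(hits.samples)
    n_sets = len(collection)
    x1 = {d: np.zeros((n_samples, n_sets), dtype=int) for d in DOSAGE_TYPES}
    x2 = {d: np.zeros((n_samples, n_sets), dtype=int) for d in DOSAGE_TYPES}
    for s, sample in enumerate(hits.samples):
        for dtype in DOSAGE_TYPES:
            arrays = hits.per_cnv.get(sample, {}).get(dtype, [])
            if not arrays:
                continue
            all_hit = np.unique(np.concatenate(arrays))
            for j in range(n_sets):
                mask = masks[j]
                x1[dtype][s, j] = int(mask[all_hit].sum())
                if x2_scope == "all_cnvs":
                    x2[dtype][s, j] = int((~mask[all_hit]).sum())
                else:
                    contributing = [a for a in arrays if mask[a].any()]
                    if contributing:
                        cg = np.unique(np.concatenate(contributing))
                        x2[dtype][s, j] = int((~mask[cg]).sum())
    return BurdenTable(hits.samples, collection.names, x1, x2, x2_scope)
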