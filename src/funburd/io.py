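"""Readers and writers for the exchanged plain-text formats.

Internal coordinates are 1-based inclusive (annotation-style); BED input
(0-based half-open) is converted on read. All tabular outputs are TSV
with a single header row and floats at six significant digits.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Optional, Union

import numpy as np
import pandas as pd
import yaml

from .burden import BurdenTable, CNVCall, GeneModel
from .genesets import GeneSetCollection

__all__ = [
    "read_gmt",
    "write_gmt",
    "read_annotations",
    "write_annotations",
    "read_bed",
    "read_gene_tsv",
    "write_gene_models",
    "read_cnv_tsv",
    "write_cnv_tsv",
    "read_expression_tsv",
    "write_tsv",
    "read_constraint_tsv",
    "load_config",
]

PathLike = Union[str, Path]


def read_gmt(path: PathLike) -> GeneSetCollection:
    """Read a tab-delimited GMT file (name, description, members...)."""
    sets: Dict[str, List[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: line {lineno} has fewer than 3 fields")
            name = fields[0]
            if name in sets:
                raise ValueError(f"{path}: duplicate set name {name!r} at line {lineno}")
            sets[name] = [g for g in fields[2:] if g]
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: PathLike) -> None:
    with open(path, "w") as fh:
        for name, members in collection.sets.items():
            fh.write("\t".join([name, "na", *members]) + "\n")


def read_annotations(path: PathLike) -> Dict[str, dict]:
    df = pd.read_csv(path, sep="\t")
    return {
        str(r["gene_set"]): {"brain": bool(r["brain"]), "level": str(r["level"])}
        for _, r in df.iterrows()
    }


def write_annotations(annotations: Dict[str, dict], path: PathLike) -> None:
    rows = [
        {"gene_set": name, "brain": meta.get("brain", False), "level": meta.get("level", "")}
        for name, meta in annotations.items()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_bed(path: PathLike) -> List[GeneModel]:
    """BED (0-based half-open) → gene models (1-based inclusive)."""
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 4:
                raise ValueError(f"{path}: line {lineno} needs chrom,start,end,name")
            chrom, start, end, name = fields[0], int(fields[1]), int(fields[2]), fields[3]
            if start < 0 or end <= start:
                raise ValueError(f"{path}: invalid interval at line {lineno}")
            genes.append(GeneModel(name, chrom, start + 1, end))
    return genes


def read_gene_tsv(path: PathLike) -> List[GeneModel]:
    """TSV with 1-based inclusive gene_id, chrom, start, end columns."""
    df = pd.read_csv(path, sep="\t")
    return [
        GeneModel(str(r["gene_id"]), str(r["chrom"]), int(r["start"]), int(r["end"]))
        for _, r in df.iterrows()
    ]


def write_gene_models(genes: List[GeneModel], tsv_path: PathLike, bed_path: Optional[PathLike] = None) -> None:
    df = pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "chrom": [g.chrom for g in genes],
            "start": [g.start for g in genes],
            "end": [g.end for g in genes],
        }
    )
    df.to_csv(tsv_path, sep="\t", index=False)
    if bed_path is not None:
        with open(bed_path, "w") as fh:
            for g in genes:
                fh.write(f"{g.chrom}\t{g.start - 1}\t{g.end}\t{g.gene_id}\n")


def read_cnv_tsv(path: PathLike) -> List[CNVCall]:
    df = pd.read_csv(path, sep="\t")
    calls = []
    for _, r in df.iterrows():
        calls.append(
            CNVCall(
                str(r["sample_id"]), str(r["chrom"]), int(r["start"]), int(r["end"]),
                str(r["type"]),
            )
        )
    return calls


def write_cnv_tsv(cnvs: List[CNVCall], path: PathLike) -> None:
    pd.DataFrame(
        {
            "sample_id": [c.sample_id for c in cnvs],
            "chrom": [c.chrom for c in cnvs],
            "start": [c.start for c in cnvs],
            "end": [c.end for c in cnvs],
            "type": [c.dosage_type for c in cnvs],
        }
    ).to_csv(path, sep="\t", index=False)


def read_expression_tsv(path: PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_tsv(df: pd.DataFrame, path: PathLike, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.6g")


def read_constraint_tsv(path: PathLike, metric: Optional[str] = None) -> pd.Series:
    """Constraint annotations: gene_id, metric, top_decile_flag columns."""
    df = pd.read_csv(path, sep="\t")
    if metric is not None:
        df = df[df["metric"] == metric]
    return df.set_index("gene_id")["top_decile_flag"].astype(int)


def load_config(path: PathLike) -> dict:
    """Load a YAML or JSON pipeline/simulation config file."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)
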