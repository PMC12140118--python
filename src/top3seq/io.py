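"""Readers and writers for the pipeline's plain-text table formats.

Counts are TSV with the feature id in the first column and sample ids in
the header; the sample sheet is TSV with sample_id, condition, replicate.
Gene sets are one-id-per-line text or GMT; ortholog maps are 3-column
TSV (source_id, target_id, score).  Undefined values are written "NA".
"""

from __future__ import annotations

import os

import pandas as pd

from .diffexpr import CountMatrix
from .overlap import GeneSet

__all__ = [
    "read_counts",
    "read_sample_sheet",
    "load_count_matrix",
    "read_gene_set",
    "read_gene_sets_gmt",
    "read_ortholog_map",
    "write_table",
]


def _require(path: str) -> str:
    if not os.path.exists(path):
        raise FileNotFoundError(f"input file does not exist: {path}")
    return path


def read_counts(path: str) -> pd.DataFrame:
    df = pd.read_csv(_require(path), sep="\t", index_col=0)
    df.index.name = "feature_id"
    return df


def read_sample_sheet(path: str) -> pd.DataFrame:
    df = pd.read_csv(_require(path), sep="\t")
    required = {"sample_id", "condition"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(
            f"sample sheet {path} lacks columns {sorted(missing)}; "
            f"found {list(df.columns)}"
        )
    return df


def load_count_matrix(counts_path: str, sheet_path: str) -> CountMatrix:
    counts = read_counts(counts_path)
    sheet = read_sample_sheet(sheet_path)
    condition = sheet.set_index("sample_id")["condition"]
    return CountMatrix(counts=counts, condition=condition)


def read_gene_set(path: str, name: str | None = None) -> GeneSet:
    """One gene id per line; blank lines and '#' comments ignored."""
    members = []
    with open(_require(path)) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                members.append(line)
    return GeneSet(name=name or os.path.splitext(os.path.basename(path))[0],
                   members=frozenset(members))


def read_gene_sets_gmt(path: str) -> list[GeneSet]:
    """GMT: name <tab> description <tab> member1 <tab> member2 ..."""
    sets = []
    with open(_require(path)) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets.append(GeneSet(name=parts[0], members=frozenset(parts[2:])))
    return sets


def read_ortholog_map(path: str) -> pd.DataFrame:
    df = pd.read_csv(_require(path), sep="\t")
    required = {"source_id", "target_id"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(
            f"ortholog map {path} lacks columns {sorted(missing)}; "
            f"found {list(df.columns)}"
        )
    return df.drop_duplicates(subset=["source_id", "target_id"])


def write_table(df: pd.DataFrame, path: str, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index, na_rep="NA")
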