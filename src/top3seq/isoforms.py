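"""Reciprocal isoform-pair detection and start-site classification.

A gene is "reciprocal" in a mutant-vs-wild-type contrast when at least
one of its transcript isoforms is significantly downregulated and at
least one other significantly upregulated — the pattern expected when
loss of the enzyme shifts expression between promoters, splice forms, or
3'-end variants of the same gene.  For each qualifying gene all down x up
pairs are emitted, with the single best pair (most negative x most
positive log2fc) flagged, and the transcription-start relation of the
up- versus the down-regulated isoform is classified in gene orientation.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .annotation import TranscriptModel

__all__ = ["find_reciprocal_genes", "classify_start_relation", "reciprocal_pair_table"]


def find_reciprocal_genes(
    de: pd.DataFrame,
    tx2gene: pd.Series,
    alpha: float = 0.05,
    lfc: float = 1.0,
    comparator: str = "inclusive",
) -> pd.DataFrame:
    """Genes with >= 1 significant down and >= 1 significant up isoform.

    ``de`` is a transcript-level result table (index transcript_id, with
    log2fc and adjp); ``tx2gene`` maps transcript -> gene.  Returns one
    row per (gene, down_tx, up_tx) pair with a ``best_pair`` flag and a
    combined-effect rank.  Duplicate result rows are deduplicated;
    transcripts without a gene mapping are dropped with a warning count.
    """
    de = de[~de.index.duplicated(keep="first")]
    tx2gene = tx2gene[~tx2gene.index.duplicated(keep="first")]
    unmapped = [t for t in de.index if t not in tx2gene.index]
    if unmapped:
        warnings.warn(
            f"{len(unmapped)} transcripts lack a gene mapping and were excluded",
            stacklevel=2,
        )
    de = de.loc[[t for t in de.index if t in tx2gene.index]]
    genes = tx2gene.loc[de.index]

    adjp = de["adjp"].values
    fc = de["log2fc"].values
    sig = np.isfinite(adjp) & (adjp < alpha)
    if comparator == "inclusive":
        down = sig & (fc <= -lfc)
        up = sig & (fc >= lfc)
    elif comparator == "strict":
        down = sig & (fc < -lfc)
        up = sig & (fc > lfc)
    else:
        raise ValueError("comparator must be 'inclusive' or 'strict'")

    rows = []
    table = pd.DataFrame(
        {"gene_id": genes.values, "log2fc": fc, "adjp": adjp,
         "down": down, "up": up},
        index=de.index,
    )
    for gene_id, grp in table.groupby("gene_id", sort=True):
        down_tx = grp[grp["down"]].sort_values(["log2fc", "adjp"])
        up_tx = grp[grp["up"]].sort_values(["log2fc", "adjp"], ascending=[False, True])
        if down_tx.empty or up_tx.empty:
            continue
        for d_id, d in down_tx.iterrows():
            for u_id, u in up_tx.iterrows():
                rows.append(
                    {
                        "gene_id": gene_id,
                        "down_tx": d_id,
                        "up_tx": u_id,
                        "down_log2fc": d["log2fc"],
                        "up_log2fc": u["log2fc"],
                        "down_adjp": d["adjp"],
                        "up_adjp": u["adjp"],
                        "best_pair": d_id == down_tx.index[0] and u_id == up_tx.index[0],
                    }
                )
    out = pd.DataFrame(
        rows,
        columns=[
            "gene_id", "down_tx", "up_tx", "down_log2fc", "up_log2fc",
            "down_adjp", "up_adjp", "best_pair",
        ],
    )
    if len(out):
        out["pair_score"] = out["up_log2fc"] - out["down_log2fc"]
        out = out.sort_values(
            ["pair_score", "gene_id", "down_tx", "up_tx"],
            ascending=[False, True, True, True],
            kind="mergesort",
        ).reset_index(drop=True)
    return out


def tss(model: TranscriptModel) -> int:
    """Transcription start coordinate: first exon start on +, last exon
    end on -."""
    if model.strand == "+":
        return model.exons[0].start
    return model.exons[-1].end


def classify_start_relation(
    up_tx: TranscriptModel,
    down_tx: TranscriptModel,
    tolerance: int = 0,
) -> str:
    """Start-site relation of the upregulated isoform versus the
    downregulated one, in gene orientation.

    Returns "upstream" when the up isoform starts more 5', "downstream"
    when more 3', "same" when the TSS coordinates agree within
    ``tolerance`` nt (default exact).  Isoforms of one gene must share a
    strand.
    """
    if up_tx.strand != down_tx.strand:
        raise ValueError(
            f"isoforms of gene {up_tx.gene_id} are annotated on different strands"
        )
    t_up, t_down = tss(up_tx), tss(down_tx)
    if abs(t_up - t_down) <= tolerance:
        return "same"
    if up_tx.strand == "+":
        return "upstream" if t_up < t_down else "downstream"
    return "upstream" if t_up > t_down else "downstream"


def reciprocal_pair_table(
    pairs: pd.DataFrame,
    models: dict[str, TranscriptModel],
    tolerance: int = 0,
) -> pd.DataFrame:
    """Attach the start-site relation to a reciprocal-pair table."""
    relations = []
    for _, row in pairs.iterrows():
        up = models.get(row["up_tx"])
        down = models.get(row["down_tx"])
        if up is None or down is None:
            relations.append("NA")
        else:
            relations.append(classify_start_relation(up, down, tolerance=tolerance))
    out = pairs.copy()
    out["start_relation"] = relations
    return out
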