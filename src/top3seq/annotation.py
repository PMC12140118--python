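"""Gene models and transcript feature extraction.

Parses GTF/GFF3 gene annotations into per-transcript exon/CDS models and
derives the length features used throughout the analysis: spliced mRNA
length, genomic (pre-mRNA) span, CDS and UTR lengths, exon and intron
counts.  Coordinates are 1-based and fully closed, as in GTF/GFF3; all
emitted tables use the same convention.

UTR lengths are measured in spliced (exonic) coordinates on the
transcript's own strand: the 5'UTR is the exonic sequence strictly 5' of
the first CDS base, the 3'UTR the exonic sequence strictly 3' of the last
CDS base.  CDS intervals are taken at face value (no stop-codon
adjustment); transcripts without an annotated CDS have undefined UTRs and
cds_len = 0 but keep their mRNA/pre-mRNA/exon statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd

__all__ = [
    "GenomicInterval",
    "TranscriptModel",
    "TranscriptFeatures",
    "AnnotationError",
    "parse_annotation",
    "compute_transcript_features",
    "compute_gene_features",
    "write_features_tsv",
    "features_frame",
    "write_gtf",
]


class AnnotationError(ValueError):
    """Raised on malformed annotation input."""


@dataclass(frozen=True)
class GenomicInterval:
    """A closed 1-based interval on a chromosome strand."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise AnnotationError(
                f"interval start {self.start} > end {self.end} on {self.chrom}"
            )
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"unknown strand symbol {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class TranscriptModel:
    """One transcript: sorted non-overlapping exons plus optional CDS."""

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[GenomicInterval] = field(default_factory=list)
    cds: list[GenomicInterval] = field(default_factory=list)

    def validate(self) -> None:
        for prev, cur in zip(self.exons, self.exons[1:]):
            if cur.start <= prev.end:
                raise AnnotationError(
                    f"{self.transcript_id}: exons overlap or are unsorted"
                )
        exon_spans = [(e.start, e.end) for e in self.exons]
        for c in self.cds:
            if not any(s <= c.start and c.end <= e for s, e in exon_spans):
                raise AnnotationError(
                    f"CDS interval {c.start}-{c.end} of transcript "
                    f"{self.transcript_id} is not contained in any exon"
                )


@dataclass
class TranscriptFeatures:
    """Per-transcript length/count features (nt).

    UTR lengths are ``None`` when the transcript has no annotated CDS.
    """

    transcript_id: str
    gene_id: str
    mrna_len: int
    pre_mrna_len: int
    cds_len: int
    utr5_len: Optional[int]
    utr3_len: Optional[int]
    exon_count: int
    intron_count: int
    intron_len_total: int


def _merge_intervals(
    ivs: list[GenomicInterval],
) -> list[GenomicInterval]:
    """Sort and merge abutting or overlapping intervals (defensive against
    redundant annotation lines)."""
    if not ivs:
        return []
    ivs = sorted(ivs, key=lambda x: (x.start, x.end))
    merged = [ivs[0]]
    for iv in ivs[1:]:
        last = merged[-1]
        if iv.start <= last.end + 1:
            if iv.end > last.end:
                merged[-1] = GenomicInterval(last.chrom, last.start, iv.end, last.strand)
        else:
            merged.append(iv)
    return merged


def _parse_attributes(raw: str) -> dict[str, str]:
    """Parse the 9th column in either GTF (`key "value";`) or GFF3
    (`key=value`) dialect."""
    attrs: dict[str, str] = {}
    raw = raw.strip()
    if "=" in raw and '"' not in raw:
        for part in raw.split(";"):
            part = part.strip()
            if not part:
                continue
            key, _, value = part.partition("=")
            attrs[key.strip()] = value.strip()
    else:
        for part in raw.split(";"):
            part = part.strip()
            if not part:
                continue
            key, _, value = part.partition(" ")
            attrs[key.strip()] = value.strip().strip('"')
    return attrs


_TX_KEYS = ("transcript_id", "ID", "Parent")
_GENE_KEYS = ("gene_id", "gene", "Parent")


def parse_annotation(path: str) -> list[TranscriptModel]:
    """Read a GTF or GFF3 file into a list of :class:`TranscriptModel`.

    Only ``exon`` and ``CDS`` records are used; each must carry a
    transcript and a gene identifier in its attributes.  Exons of a
    transcript are merged when they abut or overlap and stored sorted by
    start.  Malformed lines (wrong column count), CDS intervals outside
    the exons, and unknown strand symbols raise :class:`AnnotationError`.
    """
    exons: dict[str, list[GenomicInterval]] = {}
    cdss: dict[str, list[GenomicInterval]] = {}
    meta: dict[str, tuple[str, str, str]] = {}

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise AnnotationError(
                    f"{path}:{lineno}: expected 9 tab-separated columns, "
                    f"got {len(fields)}"
                )
            chrom, _source, ftype, start_s, end_s, _score, strand, _frame, attr_s = fields
            if ftype not in ("exon", "CDS"):
                continue
            if strand not in ("+", "-"):
                raise AnnotationError(
                    f"{path}:{lineno}: unknown strand symbol {strand!r}"
                )
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise AnnotationError(
                    f"{path}:{lineno}: non-integer coordinates"
                ) from exc
            attrs = _parse_attributes(attr_s)
            tx_id = next((attrs[k] for k in _TX_KEYS if k in attrs), None)
            gene_id = next((attrs[k] for k in _GENE_KEYS if k in attrs), None)
            if tx_id is None:
                raise AnnotationError(
                    f"{path}:{lineno}: {ftype} record lacks a transcript identifier"
                )
            iv = GenomicInterval(chrom, start, end, strand)
            store = exons if ftype == "exon" else cdss
            store.setdefault(tx_id, []).append(iv)
            if tx_id not in meta:
                meta[tx_id] = (gene_id or tx_id, chrom, strand)

    models: list[TranscriptModel] = []
    for tx_id in sorted(exons):
        gene_id, chrom, strand = meta[tx_id]
        model = TranscriptModel(
            transcript_id=tx_id,
            gene_id=gene_id,
            chrom=chrom,
            strand=strand,
            exons=_merge_intervals(exons[tx_id]),
            cds=sorted(cdss.get(tx_id, []), key=lambda x: x.start),
        )
        model.validate()
        models.append(model)
    return models


def compute_transcript_features(t: TranscriptModel) -> TranscriptFeatures:
    """Derive length/count features from a transcript model.

    Invariants guaranteed for CDS-bearing transcripts:
    ``utr5 + cds + utr3 == mrna_len`` and
    ``pre_mrna_len == mrna_len + intron_len_total``.
    """
    t.validate()
    if not t.exons:
        raise AnnotationError(f"{t.transcript_id}: transcript has no exons")

    mrna_len = sum(e.length for e in t.exons)
    pre_mrna_len = t.exons[-1].end - t.exons[0].start + 1
    exon_count = len(t.exons)
    intron_count = exon_count - 1
    intron_len_total = pre_mrna_len - mrna_len

    if not t.cds:
        return TranscriptFeatures(
            t.transcript_id, t.gene_id, mrna_len, pre_mrna_len,
            cds_len=0, utr5_len=None, utr3_len=None,
            exon_count=exon_count, intron_count=intron_count,
            intron_len_total=intron_len_total,
        )

    cds_len = sum(c.length for c in t.cds)
    cds_min = min(c.start for c in t.cds)
    cds_max = max(c.end for c in t.cds)
    # exonic bases strictly left/right of the genomic CDS span
    left = sum(
        max(0, min(e.end, cds_min - 1) - e.start + 1) for e in t.exons
    )
    right = sum(
        max(0, e.end - max(e.start, cds_max + 1) + 1) for e in t.exons
    )
    if t.strand == "+":
        utr5, utr3 = left, right
    else:
        utr5, utr3 = right, left
    return TranscriptFeatures(
        t.transcript_id, t.gene_id, mrna_len, pre_mrna_len,
        cds_len=cds_len, utr5_len=utr5, utr3_len=utr3,
        exon_count=exon_count, intron_count=intron_count,
        intron_len_total=intron_len_total,
    )


def features_frame(models: Iterable[TranscriptModel]) -> pd.DataFrame:
    """Feature table for a collection of transcripts, one row each."""
    rows = []
    for m in models:
        f = compute_transcript_features(m)
        rows.append(
            {
                "transcript_id": f.transcript_id,
                "gene_id": f.gene_id,
                "mrna_len": f.mrna_len,
                "pre_mrna_len": f.pre_mrna_len,
                "cds_len": f.cds_len,
                "utr5_len": f.utr5_len,
                "utr3_len": f.utr3_len,
                "exon_count": f.exon_count,
                "intron_len_total": f.intron_len_total,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "transcript_id", "gene_id", "mrna_len", "pre_mrna_len",
            "cds_len", "utr5_len", "utr3_len", "exon_count",
            "intron_len_total",
        ],
    )
    return df


def compute_gene_features(models: Sequence[TranscriptModel]) -> pd.DataFrame:
    """Per-gene isoform count and representative-isoform features.

    The representative isoform is the one with the longest pre-mRNA
    (genomic span); ties break toward the lexicographically smallest
    transcript_id.  Gene "length" throughout the package means the
    representative pre_mrna_len.
    """
    if not models:
        return pd.DataFrame(
            columns=[
                "gene_id", "isoform_count", "transcript_id", "mrna_len",
                "pre_mrna_len", "cds_len", "utr5_len", "utr3_len",
                "exon_count", "intron_len_total",
            ]
        )
    feats = features_frame(models)
    feats = feats.sort_values(
        ["gene_id", "pre_mrna_len", "transcript_id"],
        ascending=[True, False, True],
    )
    rep = feats.groupby("gene_id", sort=True).first().reset_index()
    counts = (
        feats.groupby("gene_id")["transcript_id"].nunique().rename("isoform_count")
    )
    out = rep.merge(counts, on="gene_id")
    cols = ["gene_id", "isoform_count"] + [
        c for c in feats.columns if c != "gene_id"
    ]
    return out[cols]


def write_features_tsv(df: pd.DataFrame, path: str) -> None:
    """Write a feature table as TSV; undefined UTRs become "NA".

    Coordinates underlying these lengths are 1-based fully closed.
    """
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def write_gtf(models: Iterable[TranscriptModel], path: str) -> None:
    """Serialize transcript models as a minimal well-formed GTF."""
    with open(path, "w") as fh:
        for m in models:
            attrs = f'gene_id "{m.gene_id}"; transcript_id "{m.transcript_id}";'
            for e in m.exons:
                fh.write(
                    f"{m.chrom}\ttop3seq\texon\t{e.start}\t{e.end}\t.\t"
                    f"{m.strand}\t.\t{attrs}\n"
                )
            for c in m.cds:
                fh.write(
                    f"{m.chrom}\ttop3seq\tCDS\t{c.start}\t{c.end}\t.\t"
                    f"{m.strand}\t0\t{attrs}\n"
                )
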