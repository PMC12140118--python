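"""Gene-model parsing and transcript feature extraction."""

import numpy as np
import pytest

from top3seq.annotation import (
    AnnotationError,
    GenomicInterval,
    TranscriptModel,
    compute_gene_features,
    compute_transcript_features,
    features_frame,
    parse_annotation,
    write_gtf,
)


def iv(start, end, strand="+", chrom="chr1"):
    return GenomicInterval(chrom, start, end, strand)


def model(exons, cds=(), strand="+", tx="t1", gene="g1"):
    return TranscriptModel(
        transcript_id=tx, gene_id=gene, chrom="chr1", strand=strand,
        exons=[iv(s, e, strand) for s, e in exons],
        cds=[iv(s, e, strand) for s, e in cds],
    )


def brute_force_features(m: TranscriptModel):
    """Per-base classifier: label each genomic base exon/intron, walk the
    exonic bases in transcript orientation and split them UTR5/CDS/UTR3."""
    exonic = sorted({b for e in m.exons for b in range(e.start, e.end + 1)})
    cds_bases = {b for c in m.cds for b in range(c.start, c.end + 1)}
    walk = exonic if m.strand == "+" else exonic[::-1]
    mrna = len(exonic)
    pre = exonic[-1] - exonic[0] + 1
    out = {
        "mrna_len": mrna,
        "pre_mrna_len": pre,
        "intron_len_total": pre - mrna,
        "exon_count": len(m.exons),
        "cds_len": len(cds_bases),
    }
    if cds_bases:
        positions = [i for i, b in enumerate(walk) if b in cds_bases]
        out["utr5_len"] = positions[0]
        out["utr3_len"] = mrna - positions[-1] - 1
    else:
        out["utr5_len"] = out["utr3_len"] = None
    return out


class TestComputeFeatures:
    def test_fully_coding_single_exon(self):
        f = compute_transcript_features(model([(1, 100)], [(1, 100)]))
        assert (f.utr5_len, f.cds_len, f.utr3_len) == (0, 100, 0)
        assert f.mrna_len == f.pre_mrna_len == 100
        assert f.intron_count == 0

    @pytest.mark.parametrize("strand,utr5,utr3", [("+", 50, 50), ("-", 50, 50)])
    def test_two_exon_split_cds(self, strand, utr5, utr3):
        f = compute_transcript_features(
            model([(101, 200), (301, 400)], [(151, 200), (301, 350)], strand)
        )
        assert f.utr5_len == utr5 and f.utr3_len == utr3
        assert f.cds_len == 100 and f.mrna_len == 200
        assert f.intron_len_total == 100 and f.pre_mrna_len == 300

    def test_minus_strand_utr_identity(self):
        # on -, the 5'UTR is the high-coordinate side
        f = compute_transcript_features(
            model([(101, 200), (301, 400)], [(151, 200), (301, 350)], "-")
        )
        plus = compute_transcript_features(
            model([(101, 200), (301, 400)], [(151, 200), (301, 350)], "+")
        )
        assert f.utr5_len == plus.utr3_len and f.utr3_len == plus.utr5_len

    def test_noncoding_transcript(self):
        f = compute_transcript_features(model([(1, 100), (201, 260)]))
        assert f.cds_len == 0
        assert f.utr5_len is None and f.utr3_len is None
        assert f.mrna_len == 160

    def test_matches_per_base_classifier_on_random_models(self, default_annotation):
        models, _ = default_annotation
        rng = np.random.default_rng(5)
        sample = rng.choice(len(models), size=200, replace=False)
        for i in sample:
            m = models[i]
            f = compute_transcript_features(m)
            b = brute_force_features(m)
            got = {
                "mrna_len": f.mrna_len, "pre_mrna_len": f.pre_mrna_len,
                "intron_len_total": f.intron_len_total,
                "exon_count": f.exon_count, "cds_len": f.cds_len,
                "utr5_len": f.utr5_len, "utr3_len": f.utr3_len,
            }
            assert got == b, m.transcript_id

    def test_length_identities_hold_on_all_synthetic_models(self, default_annotation):
        models, _ = default_annotation
        for m in models:
            f = compute_transcript_features(m)
            if m.cds:
                assert f.utr5_len + f.cds_len + f.utr3_len == f.mrna_len
            assert f.pre_mrna_len == f.mrna_len + f.intron_len_total
            assert f.intron_count == f.exon_count - 1

    def test_strand_reversal_swaps_utrs_only(self, small_annotation):
        models, _ = small_annotation
        for m in models[:50]:
            if not m.cds:
                continue
            flipped = TranscriptModel(
                m.transcript_id, m.gene_id, m.chrom,
                "-" if m.strand == "+" else "+",
                [GenomicInterval(e.chrom, e.start, e.end,
                                 "-" if m.strand == "+" else "+") for e in m.exons],
                [GenomicInterval(c.chrom, c.start, c.end,
                                 "-" if m.strand == "+" else "+") for c in m.cds],
            )
            a = compute_transcript_features(m)
            b = compute_transcript_features(flipped)
            assert (a.utr5_len, a.utr3_len) == (b.utr3_len, b.utr5_len)
            assert a.mrna_len == b.mrna_len and a.cds_len == b.cds_len


class TestParse:
    def test_identity_single_record_set(self, tmp_path):
        p = tmp_path / "a.gtf"
        p.write_text(
            'chr1\tx\texon\t1\t100\t.\t+\t.\tgene_id "g"; transcript_id "t";\n'
            'chr1\tx\tCDS\t1\t100\t.\t+\t0\tgene_id "g"; transcript_id "t";\n'
        )
        (m,) = parse_annotation(str(p))
        assert len(m.exons) == 1 and len(m.cds) == 1
        assert m.gene_id == "g" and m.transcript_id == "t"

    def test_exons_stored_sorted(self, tmp_path):
        p = tmp_path / "a.gtf"
        p.write_text(
            'chr1\tx\texon\t301\t400\t.\t+\t.\tgene_id "g"; transcript_id "t";\n'
            'chr1\tx\texon\t101\t200\t.\t+\t.\tgene_id "g"; transcript_id "t";\n'
        )
        (m,) = parse_annotation(str(p))
        assert [(e.start, e.end) for e in m.exons] == [(101, 200), (301, 400)]

    def test_gff3_dialect(self, tmp_path):
        p = tmp_path / "a.gff3"
        p.write_text(
            "chr1\tx\texon\t1\t50\t.\t-\t.\tID=t;Parent=g;gene_id=g;transcript_id=t\n"
        )
        (m,) = parse_annotation(str(p))
        assert m.transcript_id == "t" and m.strand == "-"

    def test_round_trip_synthetic_annotation(self, tmp_path, small_annotation):
        models, truth = small_annotation
        path = tmp_path / "sim.gtf"
        write_gtf(models, str(path))
        reparsed = parse_annotation(str(path))
        got = features_frame(reparsed)
        want = truth[got.columns].sort_values("transcript_id").reset_index(drop=True)
        got = got.sort_values("transcript_id").reset_index(drop=True)
        assert got.fillna(-1).equals(want.fillna(-1))

    def test_malformed_line_reports_line_number(self, tmp_path):
        p = tmp_path / "bad.gtf"
        p.write_text(
            'chr1\tx\texon\t1\t100\t.\t+\t.\tgene_id "g"; transcript_id "t";\n'
            "chr1\texon\t1\t100\n"
        )
        with pytest.raises(AnnotationError, match="bad.gtf:2"):
            parse_annotation(str(p))

    def test_cds_outside_exons_names_transcript(self, tmp_path):
        p = tmp_path / "bad.gtf"
        p.write_text(
            'chr1\tx\texon\t1\t100\t.\t+\t.\tgene_id "g"; transcript_id "tX";\n'
            'chr1\tx\tCDS\t150\t200\t.\t+\t0\tgene_id "g"; transcript_id "tX";\n'
        )
        with pytest.raises(AnnotationError, match="tX"):
            parse_annotation(str(p))

    def test_unknown_strand_rejected(self, tmp_path):
        p = tmp_path / "bad.gtf"
        p.write_text('chr1\tx\texon\t1\t100\t.\t*\t.\tgene_id "g"; transcript_id "t";\n')
        with pytest.raises(AnnotationError, match="strand"):
            parse_annotation(str(p))


class TestGeneFeatures:
    def test_single_isoform(self):
        df = compute_gene_features([model([(1, 100)], [(1, 100)])])
        assert df.loc[0, "isoform_count"] == 1
        assert df.loc[0, "transcript_id"] == "t1"

    def test_longest_pre_mrna_wins_with_tiebreak(self):
        a = model([(1, 300)], tx="tB")
        b = model([(1, 100), (401, 500)], tx="tA")  # span 500
        c = model([(1, 100), (401, 500)], tx="tC")  # same span, larger id
        df = compute_gene_features([a, b, c])
        assert df.loc[0, "transcript_id"] == "tA"
        assert df.loc[0, "pre_mrna_len"] == 500
        assert df.loc[0, "isoform_count"] == 3

    def test_empty_input_gives_empty_table(self):
        assert len(compute_gene_features([])) == 0

    def test_recovers_planted_isoform_counts(self, small_annotation):
        models, truth = small_annotation
        df = compute_gene_features(models).set_index("gene_id")
        planted = truth.groupby("gene_id")["isoform_count"].first()
        assert (df["isoform_count"] == planted.loc[df.index]).all()
        planted_max = truth.groupby("gene_id")["pre_mrna_len"].max()
        assert (df["pre_mrna_len"] == planted_max.loc[df.index]).all()
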