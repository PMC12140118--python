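"""Seeded synthetic data with the statistical structure the analyses assume.

Every generator is a pure function of a :class:`SimConfig`: fixed seed in,
byte-identical files out.  Each generator draws from its own child stream
of the master seed (fixed block offsets), so adding one block never
perturbs another's output.  Truth tables accompany every dataset so that
recovery metrics (FDR, power, recall, planted fold) can be computed
without re-deriving hidden state.

What is emulated, by block:

* annotation — multi-isoform gene models: isoforms per gene distributed
  1 + Poisson(1) (capped at 6; the fly average is about two isoforms per
  gene), log-normal spliced lengths (log10 mean 3.3, sd 0.35, i.e. a
  median mRNA of ~2 kb) partitioned into 5'UTR/CDS/3'UTR by a
  Dirichlet(1, 6, 3), log-normal intron lengths, and a small fraction of
  non-coding transcripts.
* expression — NB counts for wild type plus three mutants (a null, a
  catalytic-dead point mutant, an RNA-binding-motif deletion) with
  planted effects: 10% affected transcripts, 67% of them down, effect
  probability increasing with 3'UTR length, nested mutant effect sets,
  and a block of genes carrying reciprocally regulated isoform pairs.
  Gene-level counts are exact sums of the gene's transcript counts.
* ip — immunoprecipitation counts (signal vs catalytic-dead control)
  with ~3% planted covalent targets whose binding probability increases
  with log10 mRNA length and whose enrichment is Normal(2, 0.5) in log2.
* disease sets — human-namespace gene lists with a planted 2.5-fold
  enrichment toward the focal downregulated set, plus a mostly-1:1
  ortholog map with 10% one-to-two records.
* climbing — multinomial zone counts whose mean climbing index follows
  genotype-specific decline curves that separate only after week 5.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import binom

from .annotation import GenomicInterval, TranscriptModel
from .overlap import GeneSet

__all__ = [
    "SimConfig",
    "gen_annotation",
    "gen_expression",
    "gen_ip",
    "gen_disease_sets",
    "gen_climbing",
]

_CHROMS = ("chr2L", "chr2R", "chr3L", "chr3R", "chrX")
_BLOCK = {"annotation": 1, "expression": 2, "ip": 3, "disease": 4, "climbing": 5}

MUTANTS = ("null26", "y332f", "drgg")
WT = "wt"


@dataclass
class SimConfig:
    """Generator parameters; defaults define the study conditions."""

    seed: int = 0
    n_genes: int = 2000

    # annotation block
    isoform_poisson_mean: float = 1.0
    max_isoforms: int = 6
    mrna_log10_mean: float = 3.3
    mrna_log10_sd: float = 0.35
    utr_cds_dirichlet: tuple[float, float, float] = (1.0, 6.0, 3.0)
    exon_poisson_mean: float = 3.0
    intron_log10_mean: float = 2.0
    intron_log10_sd: float = 0.4
    noncoding_fraction: float = 0.05

    # expression block
    replicates: int = 3
    baseline_log_mean: float = 4.0
    baseline_log_sd: float = 1.2
    dispersion_log_mean: float = -2.5
    dispersion_log_sd: float = 0.8
    libsize_log_sd: float = 0.15
    de_fraction: float = 0.10
    down_fraction: float = 0.67
    effect_size_mean: float = 2.0
    effect_size_sd: float = 0.5
    effect_size_min: float = 0.5
    length_bias: float = 1.0
    p_y332f_given_null: float = 0.43
    p_null_given_y332f: float = 0.92
    drgg_fraction_of_null: float = 0.10
    p_drgg_overlap: float = 0.11
    reciprocal_gene_count: int = 30
    reciprocal_lfc: float = 2.0
    reciprocal_min_mean: float = 150.0

    # ip block
    ip_target_fraction: float = 0.03
    ip_length_coef: float = 1.0
    ip_lfc_mean: float = 2.0
    ip_lfc_sd: float = 0.5
    ip_lfc_min: float = 0.25

    # disease block
    n_disease_sets: int = 7
    disease_set_min: int = 200
    disease_set_max: int = 600
    disease_fold: float = 2.5
    multi_ortholog_fraction: float = 0.10

    # climbing block
    climbing_weeks: int = 7
    climbing_batches: int = 3
    climbing_trials_per_batch: int = 3
    climbing_flies: int = 10
    climbing_ci_curves: dict = field(default_factory=lambda: {
        "wt":     [4.2, 4.2, 4.2, 4.2, 4.0, 3.8, 3.6],
        "drgg":   [4.2, 4.2, 4.2, 4.2, 4.0, 3.6, 3.3],
        "y332f":  [4.2, 4.2, 4.2, 4.2, 4.0, 2.9, 2.2],
        "null26": [4.2, 4.2, 4.2, 4.2, 4.0, 2.7, 2.0],
    })


def _rng(cfg: SimConfig, block: str) -> np.random.Generator:
    return np.random.default_rng([_BLOCK[block], cfg.seed])


# ---------------------------------------------------------------------------
# annotation


def _spliced_to_genomic(
    exons: Sequence[GenomicInterval], strand: str, s_start: int, s_end: int
) -> list[GenomicInterval]:
    """Map a spliced-coordinate interval [s_start, s_end] (1-based, in
    transcript orientation) onto genomic intervals within the exons."""
    order = exons if strand == "+" else list(reversed(exons))
    out = []
    pos = 1
    for e in order:
        e_len = e.length
        lo = max(s_start, pos)
        hi = min(s_end, pos + e_len - 1)
        if lo <= hi:
            if strand == "+":
                g_lo = e.start + (lo - pos)
                g_hi = e.start + (hi - pos)
            else:
                g_hi = e.end - (lo - pos)
                g_lo = e.end - (hi - pos)
            out.append(GenomicInterval(e.chrom, g_lo, g_hi, strand))
        pos += e_len
    return sorted(out, key=lambda iv: iv.start)


def gen_annotation(cfg: SimConfig) -> tuple[list[TranscriptModel], pd.DataFrame]:
    """Generate gene models and the matching truth feature table."""
    rng = _rng(cfg, "annotation")
    cursors = {c: 1000 for c in _CHROMS}
    models: list[TranscriptModel] = []
    truth_rows = []

    for gi in range(cfg.n_genes):
        gene_id = f"G{gi:05d}"
        chrom = _CHROMS[gi % len(_CHROMS)]
        strand = "+" if rng.random() < 0.5 else "-"
        n_iso = 1 + min(int(rng.poisson(cfg.isoform_poisson_mean)),
                        cfg.max_isoforms - 1)
        anchor = cursors[chrom]
        gene_max_end = anchor

        for ti in range(n_iso):
            tx_id = f"{gene_id}.T{ti:02d}"
            mrna_len = max(200, int(round(10 ** rng.normal(
                cfg.mrna_log10_mean, cfg.mrna_log10_sd))))
            n_exons = 1 + int(rng.poisson(cfg.exon_poisson_mean))
            n_exons = min(n_exons, mrna_len // 60)
            n_exons = max(n_exons, 1)
            if n_exons > 1:
                cuts = np.sort(rng.choice(
                    np.arange(1, mrna_len), size=n_exons - 1, replace=False))
                exon_lens = np.diff(np.concatenate([[0], cuts, [mrna_len]]))
            else:
                exon_lens = np.array([mrna_len])
            intron_lens = 30 + np.round(
                10 ** rng.normal(cfg.intron_log10_mean, cfg.intron_log10_sd,
                                 size=n_exons - 1)
            ).astype(int)

            start = anchor + int(rng.integers(0, 500))
            exons = []
            pos = start
            for k, el in enumerate(exon_lens):
                exons.append(GenomicInterval(chrom, pos, pos + int(el) - 1, strand))
                pos += int(el)
                if k < n_exons - 1:
                    pos += int(intron_lens[k])
            gene_max_end = max(gene_max_end, exons[-1].end)

            coding = rng.random() >= cfg.noncoding_fraction
            cds_ivs: list[GenomicInterval] = []
            utr5 = utr3 = None
            cds_len = 0
            if coding:
                frac = rng.dirichlet(cfg.utr_cds_dirichlet)
                utr5 = int(round(frac[0] * mrna_len))
                cds_len = int(round(frac[1] * mrna_len))
                cds_len = max(3, min(cds_len, mrna_len - utr5 - 1))
                if utr5 + cds_len > mrna_len:
                    utr5 = mrna_len - cds_len - 1
                utr3 = mrna_len - utr5 - cds_len
                cds_ivs = _spliced_to_genomic(
                    exons, strand, utr5 + 1, utr5 + cds_len)

            model = TranscriptModel(
                transcript_id=tx_id, gene_id=gene_id, chrom=chrom,
                strand=strand, exons=exons, cds=cds_ivs,
            )
            models.append(model)
            truth_rows.append({
                "transcript_id": tx_id,
                "gene_id": gene_id,
                "mrna_len": mrna_len,
                "pre_mrna_len": exons[-1].end - exons[0].start + 1,
                "cds_len": cds_len,
                "utr5_len": utr5,
                "utr3_len": utr3,
                "exon_count": n_exons,
                "intron_len_total": int(intron_lens.sum()),
                "isoform_count": n_iso,
            })

        cursors[chrom] = gene_max_end + 1500

    truth = pd.DataFrame(truth_rows)
    return models, truth


# ---------------------------------------------------------------------------
# expression


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """NB counts with mean mu and Var = mu + alpha mu^2."""
    r = 1.0 / np.maximum(alpha, 1e-12)
    p = r / (r + mu)
    return rng.negative_binomial(r, p)


def gen_expression(
    cfg: SimConfig, truth_features: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Transcript counts, gene counts, sample sheet and truth labels.

    Returns ``(tx_counts, gene_counts, sample_sheet, truth)``; counts are
    features x samples with the wild type and the three mutants at
    ``cfg.replicates`` each.  ``truth`` carries the per-transcript true
    log2 fold change under every mutant and the reciprocal-gene flags.
    """
    rng = _rng(cfg, "expression")
    feats = truth_features.sort_values("transcript_id").reset_index(drop=True)
    n = len(feats)

    baseline = np.exp(rng.normal(cfg.baseline_log_mean, cfg.baseline_log_sd, n))
    alpha = np.exp(rng.normal(cfg.dispersion_log_mean, cfg.dispersion_log_sd, n))

    # effect probability increases with 3'UTR length (standardized log10)
    utr3 = feats["utr3_len"].to_numpy(dtype=float)
    log_u = np.log10(np.where(np.isfinite(utr3) & (utr3 > 0), utr3, np.nan) + 1)
    z = (log_u - np.nanmean(log_u)) / np.nanstd(log_u)
    z = np.nan_to_num(z, nan=0.0)

    if cfg.de_fraction > 0:
        p_de = expit(logit(cfg.de_fraction) + cfg.length_bias * z)
        is_de_null = rng.random(n) < p_de
    else:
        is_de_null = np.zeros(n, dtype=bool)
    sign = np.where(rng.random(n) < cfg.down_fraction, -1.0, 1.0)
    magnitude = np.maximum(
        rng.normal(cfg.effect_size_mean, cfg.effect_size_sd, n),
        cfg.effect_size_min,
    )
    lfc_null = np.where(is_de_null, sign * magnitude, 0.0)

    # nested mutant effect sets
    null_idx = np.flatnonzero(is_de_null)
    keep = rng.random(len(null_idx)) < cfg.p_y332f_given_null
    y332f_idx = list(null_idx[keep])
    n_extra = int(round(len(y332f_idx) * (1.0 / cfg.p_null_given_y332f - 1.0)))
    non_null = np.flatnonzero(~is_de_null)
    if n_extra > 0 and len(non_null):
        y332f_idx += list(rng.choice(non_null, size=min(n_extra, len(non_null)),
                                     replace=False))
    lfc_y332f = np.zeros(n)
    for i in y332f_idx:
        if lfc_null[i] != 0:
            lfc_y332f[i] = lfc_null[i]
        else:
            s = -1.0 if rng.random() < cfg.down_fraction else 1.0
            lfc_y332f[i] = s * max(rng.normal(cfg.effect_size_mean,
                                              cfg.effect_size_sd),
                                   cfg.effect_size_min)

    n_drgg = max(1, int(round(cfg.drgg_fraction_of_null * len(null_idx))))
    n_from_y = min(int(round(cfg.p_drgg_overlap * len(y332f_idx))), n_drgg)
    drgg_idx = list(rng.choice(y332f_idx, size=n_from_y, replace=False)) if n_from_y else []
    pool = np.setdiff1d(np.arange(n), np.array(drgg_idx, dtype=int))
    drgg_idx += list(rng.choice(pool, size=n_drgg - len(drgg_idx), replace=False))
    lfc_drgg = np.zeros(n)
    for i in drgg_idx:
        if lfc_y332f[i] != 0:
            lfc_drgg[i] = lfc_y332f[i]
        else:
            s = -1.0 if rng.random() < cfg.down_fraction else 1.0
            lfc_drgg[i] = s * max(rng.normal(cfg.effect_size_mean,
                                             cfg.effect_size_sd),
                                  cfg.effect_size_min)

    # reciprocal isoform pairs: one isoform down, another up, null + y332f
    iso_counts = feats.groupby("gene_id")["transcript_id"].count()
    multi_genes = np.array(sorted(iso_counts.index[iso_counts >= 2]))
    n_recip = min(cfg.reciprocal_gene_count, len(multi_genes))
    recip_genes = rng.choice(multi_genes, size=n_recip, replace=False)
    recip_flag = np.zeros(n, dtype=bool)
    tx_pos = {t: i for i, t in enumerate(feats["transcript_id"])}
    for g in recip_genes:
        txs = feats.loc[feats["gene_id"] == g, "transcript_id"].tolist()
        picked = rng.choice(txs, size=2, replace=False)
        i_down, i_up = tx_pos[picked[0]], tx_pos[picked[1]]
        for i, s in ((i_down, -1.0), (i_up, +1.0)):
            lfc_null[i] = s * cfg.reciprocal_lfc
            lfc_y332f[i] = s * cfg.reciprocal_lfc
            baseline[i] = max(baseline[i], cfg.reciprocal_min_mean)
            recip_flag[i] = True

    # samples and counts
    conditions = [WT] + list(MUTANTS)
    sample_ids, cond_labels, reps = [], [], []
    for cond in conditions:
        for r in range(1, cfg.replicates + 1):
            sample_ids.append(f"{cond}_{r}")
            cond_labels.append(cond)
            reps.append(r)
    libsize = np.exp(rng.normal(0.0, cfg.libsize_log_sd, len(sample_ids)))

    lfc_by_cond = {WT: np.zeros(n), "null26": lfc_null,
                   "y332f": lfc_y332f, "drgg": lfc_drgg}
    counts = np.empty((n, len(sample_ids)), dtype=np.int64)
    for j, (sid, cond) in enumerate(zip(sample_ids, cond_labels)):
        mu = baseline * libsize[j] * 2.0 ** lfc_by_cond[cond]
        counts[:, j] = _nb_draw(rng, mu, alpha)

    tx_counts = pd.DataFrame(counts, index=feats["transcript_id"],
                             columns=sample_ids)
    tx_counts.index.name = "feature_id"
    gene_counts = tx_counts.groupby(feats.set_index("transcript_id")["gene_id"]).sum()
    gene_counts.index.name = "feature_id"
    sample_sheet = pd.DataFrame({
        "sample_id": sample_ids, "condition": cond_labels, "replicate": reps,
    })
    truth = pd.DataFrame({
        "transcript_id": feats["transcript_id"],
        "gene_id": feats["gene_id"],
        "baseline_mean": baseline,
        "dispersion": alpha,
        "true_lfc_null26": lfc_null,
        "true_lfc_y332f": lfc_y332f,
        "true_lfc_drgg": lfc_drgg,
        "reciprocal_isoform": recip_flag,
    })
    return tx_counts, gene_counts, sample_sheet, truth


# ---------------------------------------------------------------------------
# ip


def gen_ip(
    cfg: SimConfig, truth_features: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """IP counts (signal vs catalytic-dead control) plus target truth.

    Binding probability increases with log10 mRNA length; planted
    enrichment is log2 Normal(ip_lfc_mean, ip_lfc_sd) applied to the
    signal condition.  Non-targets are exchangeable between conditions.
    """
    rng = _rng(cfg, "ip")
    feats = truth_features.sort_values("transcript_id").reset_index(drop=True)
    n = len(feats)

    log_len = np.log10(feats["mrna_len"].to_numpy(dtype=float))
    z = (log_len - log_len.mean()) / log_len.std()
    p_target = expit(logit(cfg.ip_target_fraction) + cfg.ip_length_coef * z)
    is_target = rng.random(n) < p_target
    enrich = np.where(
        is_target,
        np.maximum(rng.normal(cfg.ip_lfc_mean, cfg.ip_lfc_sd, n), cfg.ip_lfc_min),
        0.0,
    )

    baseline = np.exp(rng.normal(cfg.baseline_log_mean, cfg.baseline_log_sd, n))
    alpha = np.exp(rng.normal(cfg.dispersion_log_mean, cfg.dispersion_log_sd, n))

    sample_ids, cond_labels, reps = [], [], []
    for cond in ("signal_ip", "dead_ip"):
        for r in range(1, cfg.replicates + 1):
            sample_ids.append(f"{cond}_{r}")
            cond_labels.append(cond)
            reps.append(r)
    libsize = np.exp(rng.normal(0.0, cfg.libsize_log_sd, len(sample_ids)))

    counts = np.empty((n, len(sample_ids)), dtype=np.int64)
    for j, cond in enumerate(cond_labels):
        mu = baseline * libsize[j]
        if cond == "signal_ip":
            mu = mu * 2.0 ** enrich
        counts[:, j] = _nb_draw(rng, mu, alpha)

    ip_counts = pd.DataFrame(counts, index=feats["transcript_id"],
                             columns=sample_ids)
    ip_counts.index.name = "feature_id"
    sheet = pd.DataFrame({
        "sample_id": sample_ids, "condition": cond_labels, "replicate": reps,
    })
    truth = pd.DataFrame({
        "transcript_id": feats["transcript_id"],
        "gene_id": feats["gene_id"],
        "is_target": is_target,
        "true_log2_enrichment": enrich,
    })
    return ip_counts, sheet, truth


# ---------------------------------------------------------------------------
# disease sets


def gen_disease_sets(
    cfg: SimConfig,
    universe: Sequence[str],
    focal_down: Sequence[str],
) -> tuple[list[GeneSet], pd.DataFrame, pd.DataFrame]:
    """Human-namespace disease gene lists with a planted overlap fold.

    Each list of size m drawn from [disease_set_min, disease_set_max]
    contains round(fold * m * |focal| / N) focal fly genes (via their
    human counterparts); the rest are non-focal.  The ortholog map is
    1:1 with an extra second fly target for 10% of human genes.
    Returns (sets, ortholog_map, truth).
    """
    if not len(focal_down):
        raise ValueError("focal set is empty")
    rng = _rng(cfg, "disease")
    universe = sorted(universe)
    n_univ = len(universe)
    focal = sorted(set(focal_down) & set(universe))
    non_focal = sorted(set(universe) - set(focal))

    fly2hs = {g: f"HS{i:05d}" for i, g in enumerate(universe)}
    map_rows = [{"source_id": fly2hs[g], "target_id": g, "score": 1.0}
                for g in universe]
    n_multi = int(round(cfg.multi_ortholog_fraction * n_univ))
    multi_src = rng.choice(universe, size=n_multi, replace=False)
    for g in sorted(multi_src):
        extra = universe[int(rng.integers(0, n_univ))]
        if extra != g:
            map_rows.append({"source_id": fly2hs[g], "target_id": extra,
                             "score": 0.5})
    ortholog_map = pd.DataFrame(map_rows).drop_duplicates(
        subset=["source_id", "target_id"]).reset_index(drop=True)

    sets, truth_rows = [], []
    for si in range(cfg.n_disease_sets):
        m = int(rng.integers(cfg.disease_set_min, cfg.disease_set_max + 1))
        m = min(m, n_univ)
        k_in = int(round(cfg.disease_fold * m * len(focal) / n_univ))
        k_in = min(k_in, len(focal), m)
        m = min(m, k_in + len(non_focal))
        chosen_focal = rng.choice(focal, size=k_in, replace=False)
        chosen_other = rng.choice(non_focal, size=m - k_in, replace=False)
        fly_members = sorted(set(chosen_focal) | set(chosen_other))
        hs_members = frozenset(fly2hs[g] for g in fly_members)
        sets.append(GeneSet(name=f"disease_{si}", members=hs_members))
        truth_rows.append({
            "set_name": f"disease_{si}", "size": m,
            "planted_focal_overlap": k_in,
            "planted_fold": cfg.disease_fold,
        })
    return sets, ortholog_map, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# climbing


def gen_climbing(cfg: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Zone-count climbing trials and the truth table of weekly mean CIs.

    Each fly's zone is Binomial(5, mu/5), so trial CIs are unbiased for
    the genotype's target mean mu; zone counts per trial are the
    resulting multinomial.
    """
    rng = _rng(cfg, "climbing")
    rows = []
    truth_rows = []
    for genotype in sorted(cfg.climbing_ci_curves):
        curve = cfg.climbing_ci_curves[genotype]
        for week in range(1, cfg.climbing_weeks + 1):
            mu = curve[min(week, len(curve)) - 1]
            probs = binom.pmf(np.arange(6), 5, mu / 5.0)
            probs = probs / probs.sum()
            truth_rows.append({"genotype": genotype, "week": week,
                               "true_mean_ci": mu})
            rep = 0
            for batch in range(1, cfg.climbing_batches + 1):
                for _trial in range(cfg.climbing_trials_per_batch):
                    rep += 1
                    zones = rng.multinomial(cfg.climbing_flies, probs)
                    rows.append({
                        "genotype": genotype, "week": week,
                        "replicate": rep, "batch": batch,
                        **{f"n{k}": int(zones[k]) for k in range(6)},
                    })
    return pd.DataFrame(rows), pd.DataFrame(truth_rows)
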