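"""End-to-end orchestration and the supplementary-table recount harness.

``run_full`` runs every stage on a directory of inputs (typically the
output of the synthetic generators) and writes stage TSVs plus a JSON
manifest with checksums, thresholds, and the seed, sufficient to verify
a bit-identical re-run.  The recount functions re-apply the published
filter criteria (adjp and log2 fold-change thresholds, reciprocal-pair
detection, target selection) to user-exported result sheets so that the
printed headline counts can be checked from the journal's tables.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, asdict, field

import pandas as pd

from . import __version__
from .annotation import parse_annotation, features_frame, compute_gene_features
from .diffexpr import CountMatrix, run_de
from .enrichment import compare_feature_table, select_top_reduced
from .io import (
    load_count_matrix,
    read_gene_set,
    read_ortholog_map,
    write_table,
)
from .isoforms import find_reciprocal_genes, reciprocal_pair_table
from .overlap import map_orthologs, overlap_stats
from .behavior import summarize_climbing
from .targets import call_targets, top_k, length_enrichment_correlation
from .simulate import MUTANTS, WT

__all__ = [
    "RunConfig",
    "run_full",
    "recount_isoform_table",
    "recount_reciprocal_table",
    "recount_target_table",
    "recount_supplement",
]


@dataclass
class RunConfig:
    """Paths and thresholds for a full run; thresholds are echoed into
    every output so no result table is ambiguous about its criteria."""

    annotation: str
    tx_counts: str
    gene_counts: str
    sample_sheet: str
    outdir: str
    ip_counts: str | None = None
    ip_sample_sheet: str | None = None
    gene_sets: list[str] = field(default_factory=list)
    ortholog_map: str | None = None
    climbing: str | None = None
    alpha: float = 0.05
    stringent_alpha: float = 0.0002
    lfc: float = 1.0
    comparator: str = "inclusive"
    top_n: int = 50
    top_targets: int = 46
    filter_quantile: float | str = "auto"
    seed: int = 0


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_full(cfg: RunConfig) -> dict:
    """Run every configured stage; returns the manifest dict."""
    for path in [cfg.annotation, cfg.tx_counts, cfg.gene_counts, cfg.sample_sheet]:
        if not os.path.exists(path):
            raise FileNotFoundError(f"input file does not exist: {path}")
    os.makedirs(cfg.outdir, exist_ok=True)
    outputs: dict[str, str] = {}

    def emit(df: pd.DataFrame, name: str, index: bool = True) -> None:
        path = os.path.join(cfg.outdir, name)
        write_table(df, path, index=index)
        outputs[name] = path

    # stage: annotation features
    models = parse_annotation(cfg.annotation)
    feats = features_frame(models)
    gene_feats = compute_gene_features(models)
    emit(feats, "transcript_features.tsv", index=False)
    emit(gene_feats, "gene_features.tsv", index=False)
    model_by_id = {m.transcript_id: m for m in models}
    tx2gene = feats.set_index("transcript_id")["gene_id"]

    # stage: differential expression, per mutant, both levels
    de_results = {}
    for level, counts_path in (("tx", cfg.tx_counts), ("gene", cfg.gene_counts)):
        m = load_count_matrix(counts_path, cfg.sample_sheet)
        for mutant in MUTANTS:
            if mutant not in set(m.condition):
                continue
            res = run_de(
                m, (WT, mutant), alpha=cfg.alpha, lfc=cfg.lfc,
                comparator=cfg.comparator, filter_quantile=cfg.filter_quantile,
            )
            de_results[(level, mutant)] = res
            emit(res, f"de_{level}_{mutant}.tsv")

    # stage: top-reduced feature enrichment (null mutant isoforms)
    if ("tx", "null26") in de_results:
        de_null = de_results[("tx", "null26")]
        top_ids = select_top_reduced(de_null, n=cfg.top_n, alpha=cfg.alpha)
        cmp_tab = compare_feature_table(top_ids, feats)
        emit(cmp_tab, "top_reduced_feature_enrichment.tsv", index=False)

        # stage: reciprocal isoform pairs
        pairs = find_reciprocal_genes(
            de_null, tx2gene, alpha=cfg.alpha, lfc=cfg.lfc,
            comparator=cfg.comparator,
        )
        pairs = reciprocal_pair_table(pairs, model_by_id)
        emit(pairs, "reciprocal_pairs.tsv", index=False)

    # stage: covalent targets
    if cfg.ip_counts:
        ip = load_count_matrix(cfg.ip_counts, cfg.ip_sample_sheet or cfg.sample_sheet)
        calls = call_targets(ip, alpha=cfg.alpha, lfc=cfg.lfc,
                             filter_quantile=cfg.filter_quantile)
        emit(top_k(calls, cfg.top_targets), "top_targets.tsv")
        emit(calls, "target_calls.tsv")
        r, p, n_corr = length_enrichment_correlation(calls.attrs["de"], feats)
        corr = pd.DataFrame([{"r": r, "p": p, "n": n_corr,
                              "length_field": "mrna_len", "scale": "log10"}])
        emit(corr, "length_enrichment_correlation.tsv", index=False)

    # stage: disease-set overlap
    if cfg.gene_sets and cfg.ortholog_map and ("tx", "null26") in de_results:
        omap = read_ortholog_map(cfg.ortholog_map)
        de_null = de_results[("tx", "null26")]
        down_tx = de_null.index[de_null["call"] == "down"]
        focal_genes = sorted(set(tx2gene.loc[[t for t in down_tx if t in tx2gene.index]]))
        universe_n = tx2gene.nunique()
        from .overlap import GeneSet

        focal = GeneSet(name="top3b_down", members=frozenset(focal_genes))
        rows = []
        for path in cfg.gene_sets:
            disease = read_gene_set(path)
            mapped = map_orthologs(disease, omap)
            mapped = GeneSet(mapped.name,
                             frozenset(mapped.members) & set(tx2gene.unique()))
            rows.append(vars(overlap_stats(focal, mapped, universe_n)))
        emit(pd.DataFrame(rows), "disease_overlap.tsv", index=False)

    # stage: climbing
    if cfg.climbing:
        trials = pd.read_csv(cfg.climbing)
        emit(summarize_climbing(trials), "climbing_summary.tsv", index=False)
        if "batch" in trials.columns:
            emit(summarize_climbing(trials, by_batch=True),
                 "climbing_summary_by_batch.tsv", index=False)

    manifest = {
        "package_version": __version__,
        "seed": cfg.seed,
        "thresholds": {
            "alpha": cfg.alpha, "stringent_alpha": cfg.stringent_alpha,
            "lfc": cfg.lfc, "comparator": cfg.comparator,
            "top_n": cfg.top_n, "top_targets": cfg.top_targets,
            "filter_quantile": cfg.filter_quantile,
        },
        "config": asdict(cfg),
        "inputs": {
            os.path.basename(p): _sha256(p)
            for p in [cfg.annotation, cfg.tx_counts, cfg.gene_counts,
                      cfg.sample_sheet, cfg.ip_counts, cfg.ip_sample_sheet,
                      cfg.ortholog_map, cfg.climbing, *cfg.gene_sets]
            if p and os.path.exists(p)
        },
        "outputs": {name: _sha256(path) for name, path in sorted(outputs.items())},
    }
    with open(os.path.join(cfg.outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


# ---------------------------------------------------------------------------
# recount harness


_RECOUNT_COLUMNS = ("log2fc", "adjp")


def _check_columns(df: pd.DataFrame, required: tuple[str, ...], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(
            f"{what}: missing required columns {missing}; "
            f"found {list(df.columns)}"
        )


def recount_isoform_table(
    df: pd.DataFrame,
    alpha: float = 0.05,
    lfc: float = 1.0,
) -> pd.DataFrame:
    """Apply the published DE filters to an exported result sheet.

    Requires columns log2fc and adjp.  Reports total/down/up counts and
    the down percentage under both the inclusive (|log2fc| >= lfc) and
    strict (|log2fc| > lfc) comparator, side by side.
    """
    _check_columns(df, _RECOUNT_COLUMNS, "isoform table")
    rows = []
    for comparator in ("inclusive", "strict"):
        if comparator == "inclusive":
            down = (df["adjp"] < alpha) & (df["log2fc"] <= -lfc)
            up = (df["adjp"] < alpha) & (df["log2fc"] >= lfc)
        else:
            down = (df["adjp"] < alpha) & (df["log2fc"] < -lfc)
            up = (df["adjp"] < alpha) & (df["log2fc"] > lfc)
        n_down, n_up = int(down.sum()), int(up.sum())
        total = n_down + n_up
        rows.append({
            "comparator": comparator, "alpha": alpha, "lfc": lfc,
            "total": total, "down": n_down, "up": n_up,
            "down_pct": 100.0 * n_down / total if total else float("nan"),
        })
    return pd.DataFrame(rows)


def recount_reciprocal_table(
    df: pd.DataFrame,
    alpha: float = 0.05,
    lfc: float = 1.0,
    comparator: str = "inclusive",
) -> int:
    """Number of genes with at least one significant down and one
    significant up isoform in an exported sheet (columns feature_id,
    gene_id, log2fc, adjp)."""
    _check_columns(df, ("feature_id", "gene_id") + _RECOUNT_COLUMNS,
                   "reciprocal table")
    de = df.set_index("feature_id")[["log2fc", "adjp"]]
    tx2gene = df.set_index("feature_id")["gene_id"]
    pairs = find_reciprocal_genes(de, tx2gene, alpha=alpha, lfc=lfc,
                                  comparator=comparator)
    return int(pairs["gene_id"].nunique()) if len(pairs) else 0


def recount_target_table(
    df: pd.DataFrame,
    alpha: float = 0.05,
    lfc: float = 1.0,
) -> int:
    """Number of IP enrichment rows passing adjp < alpha and
    log2fc > lfc (strict, as the target selection is printed)."""
    _check_columns(df, _RECOUNT_COLUMNS, "target table")
    return int(((df["adjp"] < alpha) & (df["log2fc"] > lfc)).sum())


def recount_supplement(
    tables: dict[str, str],
    alpha: float = 0.05,
    stringent_alpha: float = 0.0002,
    lfc: float = 1.0,
) -> pd.DataFrame:
    """Recount headline numbers from exported supplementary sheets.

    ``tables`` maps logical names to TSV paths; recognized names:
    ``isoforms_null``, ``isoforms_y332f``, ``isoforms_drgg`` (transcript
    DE sheets, recounted under both comparators and both alpha levels),
    ``reciprocal`` (transcript sheet with gene ids), ``targets`` (IP
    sheet).  Unknown names raise.  Returns a tidy report, one row per
    recomputed quantity.
    """
    rows = []
    for name, path in sorted(tables.items()):
        df = pd.read_csv(path, sep="\t")
        if name.startswith("isoforms_"):
            for a in (alpha, stringent_alpha):
                rec = recount_isoform_table(df, alpha=a, lfc=lfc)
                for _, r in rec.iterrows():
                    rows.append({
                        "table": name, "quantity": "de_counts",
                        "alpha": a, "comparator": r["comparator"],
                        "total": r["total"], "down": r["down"],
                        "up": r["up"], "down_pct": r["down_pct"],
                    })
        elif name == "reciprocal":
            n = recount_reciprocal_table(df, alpha=alpha, lfc=lfc)
            rows.append({"table": name, "quantity": "reciprocal_genes",
                         "alpha": alpha, "total": n})
        elif name == "targets":
            n = recount_target_table(df, alpha=alpha, lfc=lfc)
            rows.append({"table": name, "quantity": "targets_called",
                         "alpha": alpha, "total": n})
        else:
            raise ValueError(f"unrecognized table name {name!r}")
    return pd.DataFrame(rows)
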