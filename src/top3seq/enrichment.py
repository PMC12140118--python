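"""Transcript-feature enrichment of a focal gene set against a background.

Compares length/count features (UTR lengths, CDS length, pre-mRNA
length, exon and isoform counts) of a focal set — e.g. the top covalent
targets, or the most strongly reduced transcripts in a mutant — against
a background distribution, reporting a two-sided Mann-Whitney test with
the conventional star labels.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FeatureComparison",
    "select_top_reduced",
    "compare_feature",
    "stars",
    "compare_feature_table",
]

EXACT_MAX_N = 8
_STAR_LEVELS = ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (5e-2, "*"))


@dataclass
class FeatureComparison:
    feature_name: str
    n_focal: int
    n_background: int
    focal_median: float
    background_median: float
    direction: str  # higher / lower / none
    p: float
    stars: str


def select_top_reduced(
    de: pd.DataFrame,
    n: int,
    alpha: float = 0.05,
) -> list[str]:
    """The n most strongly reduced significant features.

    Among features with adjp < alpha and negative log2fc, takes the n
    most negative log2fc; ties break by ascending adjp then feature id.
    Returns fewer than n (with a warning) when fewer qualify.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    qual = de[(de["adjp"] < alpha) & (de["log2fc"] < 0)].copy()
    qual = qual.reset_index().sort_values(
        ["log2fc", "adjp", "feature_id"], kind="mergesort"
    )
    if len(qual) < n:
        import warnings

        warnings.warn(
            f"only {len(qual)} features qualify (requested {n})", stacklevel=2
        )
    return qual["feature_id"].head(n).tolist()


def _mannwhitney_exact(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney by enumerating all group assignments
    of the pooled sample (handles ties correctly).  Two-sided p is the
    probability of a U at least as far from its null mean n1*n2/2 as the
    observed one."""
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    mid = n1 * n2 / 2.0
    dev = abs(u_obs - mid)
    total = comb(n1 + n2, n1)
    hits = 0
    idx_all = range(n1 + n2)
    for chosen in combinations(idx_all, n1):
        u = ranks[list(chosen)].sum() - n1 * (n1 + 1) / 2.0
        if abs(u - mid) >= dev - 1e-9:
            hits += 1
    return float(u_obs), hits / total


def compare_feature(
    focal,
    background,
    feature_name: str = "feature",
    method: str = "mannwhitney",
) -> FeatureComparison:
    """Two-sided comparison of a focal value set against a background.

    Mann-Whitney U by default (exact enumeration when both n <= 8,
    normal approximation with tie correction otherwise); a Welch t-test
    on log1p values is available with ``method="welch_log"`` for users
    who prefer a location test on log lengths.
    """
    x = np.asarray(focal, dtype=float)
    y = np.asarray(background, dtype=float)
    if len(x) < 3 or len(y) < 3:
        raise ValueError("need at least 3 values in each group")

    med_x, med_y = float(np.median(x)), float(np.median(y))
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        p = 1.0
    elif method == "welch_log":
        p = float(stats.ttest_ind(np.log1p(x), np.log1p(y), equal_var=False).pvalue)
    elif method == "mannwhitney":
        if len(x) <= EXACT_MAX_N and len(y) <= EXACT_MAX_N:
            _, p = _mannwhitney_exact(x, y)
        else:
            p = float(
                stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").pvalue
            )
    else:
        raise ValueError(f"unknown method {method!r}")

    if med_x > med_y:
        direction = "higher"
    elif med_x < med_y:
        direction = "lower"
    else:
        direction = "none"
    return FeatureComparison(
        feature_name=feature_name,
        n_focal=len(x),
        n_background=len(y),
        focal_median=med_x,
        background_median=med_y,
        direction=direction,
        p=float(min(p, 1.0)),
        stars=stars(min(p, 1.0)),
    )


def stars(p: float) -> str:
    """Significance label: **** < 1e-4, *** < 1e-3, ** < 0.01, * < 0.05,
    else "ns" (thresholds strict)."""
    if not 0 <= p <= 1:
        raise ValueError("p must be in [0, 1]")
    for threshold, label in _STAR_LEVELS:
        if p < threshold:
            return label
    return "ns"


def compare_feature_table(
    focal_ids: list[str],
    features: pd.DataFrame,
    background_ids: list[str] | None = None,
    feature_columns: tuple[str, ...] = (
        "mrna_len", "pre_mrna_len", "cds_len", "utr5_len", "utr3_len",
        "exon_count", "intron_len_total",
    ),
    method: str = "mannwhitney",
    with_bh: bool = True,
) -> pd.DataFrame:
    """One comparison row per feature column, focal vs background.

    ``background_ids=None`` uses every transcript in the table that is
    not focal.  Transcripts with undefined values (e.g. UTRs of
    non-coding transcripts) are dropped per column.  Raw p-values carry
    the star labels; a BH column is appended for rigor.
    """
    idx_col = "transcript_id" if "transcript_id" in features.columns else "gene_id"
    feats = features.set_index(idx_col)
    focal_ids = [i for i in focal_ids if i in feats.index]
    if background_ids is None:
        background_ids = [i for i in feats.index if i not in set(focal_ids)]
    rows = []
    for col in feature_columns:
        if col not in feats.columns:
            continue
        fx = feats.loc[focal_ids, col].dropna().astype(float)
        bx = feats.loc[background_ids, col].dropna().astype(float)
        if len(fx) < 3 or len(bx) < 3:
            continue
        cmp = compare_feature(fx.values, bx.values, feature_name=col, method=method)
        rows.append(vars(cmp))
    out = pd.DataFrame(rows)
    if with_bh and len(out):
        from .diffexpr import bh_adjust

        out["adjp_bh"] = bh_adjust(out["p"].values)
    return out
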