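"""Negative-geotaxis climbing index.

In the climbing assay startled flies climb a graduated cylinder divided
into six zones (0 = bottom to 5 = top).  The climbing index of one trial
is the zone-weighted mean position,

    CI = (0*n0 + 1*n1 + 2*n2 + 3*n3 + 4*n4 + 5*n5) / n_total,

bounded in [0, 5].  Summaries report mean CI and SEM per genotype and
week, both at trial level and averaged per batch first; the downstream
two-way ANOVA is left to any standard stats package.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["climbing_index", "summarize_climbing", "ZONE_COLUMNS"]

ZONE_COLUMNS = ["n0", "n1", "n2", "n3", "n4", "n5"]
_WEIGHTS = np.arange(6)


def climbing_index(zone_counts) -> float:
    """CI of one trial from its zone counts (n0..n5)."""
    n = np.asarray(zone_counts, dtype=float)
    if n.shape[-1] != 6:
        raise ValueError("expected 6 zone counts n0..n5")
    if (n < 0).any():
        raise ValueError("zone counts must be nonnegative")
    total = n.sum()
    if total == 0:
        raise ValueError("n_total is zero; CI undefined")
    return float((n * _WEIGHTS).sum() / total)


def summarize_climbing(trials: pd.DataFrame, by_batch: bool = False) -> pd.DataFrame:
    """Mean CI and SEM per (genotype, week).

    ``trials`` columns: genotype, week, replicate (and optionally batch),
    n0..n5.  SEM is sample SD / sqrt(n), 0 for a single trial.  With
    ``by_batch`` trials are first averaged within each batch and the SEM
    is computed across batch means.
    """
    df = trials.copy()
    df["ci"] = [
        climbing_index(row) for row in df[ZONE_COLUMNS].values
    ]
    if by_batch:
        if "batch" not in df.columns:
            raise ValueError("by_batch summaries need a 'batch' column")
        df = (
            df.groupby(["genotype", "week", "batch"], as_index=False)["ci"].mean()
        )
    grouped = df.groupby(["genotype", "week"])["ci"]
    out = grouped.agg(
        mean_ci="mean",
        sem=lambda s: s.std(ddof=1) / np.sqrt(len(s)) if len(s) > 1 else 0.0,
        n_trials="count",
    ).reset_index()
    return out
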