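"""Gene-set overlap statistics against a random-overlap expectation.

Quantifies how strongly a focal fly gene set (e.g. transcripts that
depend on the topoisomerase for normal expression) overlaps
ortholog-mapped human disease gene lists.  The random expectation of the
intersection of sets of sizes n_a and n_b drawn from a universe of N
genes is n_a*n_b/N; the observed intersection is reported as a fold over
that expectation together with the exact hypergeometric upper-tail
probability P(X >= k).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd
from scipy import stats

__all__ = ["GeneSet", "OverlapResult", "map_orthologs", "overlap_stats", "multiway_membership"]


@dataclass
class GeneSet:
    name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        self.members = frozenset(self.members)

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class OverlapResult:
    name_a: str
    name_b: str
    n_a: int
    n_b: int
    universe_n: int
    observed_k: int
    expected_k: float
    fold: float
    random_overlap_pct: float  # expected_k as % of n_b
    observed_pct: float        # observed_k as % of n_b
    p: float                   # hypergeometric P(X >= observed_k)


def map_orthologs(
    src: GeneSet,
    mapping: pd.DataFrame,
    min_score: float | None = None,
) -> GeneSet:
    """Translate a gene set through an ortholog table.

    ``mapping`` has columns source_id, target_id and optionally score;
    all targets of every mapped member are kept (no best-hit collapse),
    deduplicated.  Unmapped members are counted in ``.attrs``-style
    metadata via a warning when the result is empty.
    """
    m = mapping
    if min_score is not None and "score" in m.columns:
        m = m[m["score"] >= min_score]
    hits = m[m["source_id"].isin(src.members)]
    targets = frozenset(hits["target_id"])
    n_unmapped = len(src.members - set(hits["source_id"]))
    if not targets:
        warnings.warn(
            f"no member of set {src.name!r} mapped ({n_unmapped} unmapped)",
            stacklevel=2,
        )
    out = GeneSet(name=src.name, members=targets)
    out.n_unmapped = n_unmapped  # type: ignore[attr-defined]
    return out


def overlap_stats(a: GeneSet, b: GeneSet, universe_n: int) -> OverlapResult:
    """Two-set overlap with hypergeometric expectation and tail p.

    Members outside a supplied universe collection should be dropped by
    the caller; here the universe enters only through its size.  The
    boundary P(X >= 0) = 1 holds for disjoint sets.
    """
    union = a.members | b.members
    if universe_n < len(union):
        raise ValueError(
            f"universe_n={universe_n} smaller than |a union b|={len(union)}"
        )
    n_a, n_b = len(a), len(b)
    k = len(a.members & b.members)
    expected = n_a * n_b / universe_n if universe_n else 0.0
    fold = k / expected if expected > 0 else float("nan")
    p = float(stats.hypergeom.sf(k - 1, universe_n, n_a, n_b))
    return OverlapResult(
        name_a=a.name, name_b=b.name,
        n_a=n_a, n_b=n_b, universe_n=universe_n,
        observed_k=k, expected_k=expected, fold=fold,
        random_overlap_pct=100.0 * expected / n_b if n_b else float("nan"),
        observed_pct=100.0 * k / n_b if n_b else float("nan"),
        p=min(p, 1.0),
    )


def multiway_membership(sets: list[GeneSet]) -> pd.DataFrame:
    """Venn-region counts for 2-7 sets, keyed by membership bitmask.

    Every gene of the union is assigned the pattern of sets containing
    it (one character per set, '1' = member, in input order).  Genes
    present in all sets are listed explicitly in the all-ones row.
    Region counts always sum to |union|.
    """
    if not 2 <= len(sets) <= 7:
        raise ValueError("multiway_membership handles 2-7 sets")
    union = sorted(set().union(*(s.members for s in sets)))
    patterns: dict[str, list[str]] = {}
    for g in union:
        pat = "".join("1" if g in s.members else "0" for s in sets)
        patterns.setdefault(pat, []).append(g)
    rows = []
    for pat in sorted(patterns):
        genes = patterns[pat]
        rows.append(
            {
                "pattern": pat,
                "count": len(genes),
                "genes": ";".join(genes) if pat == "1" * len(sets) else "",
            }
        )
    df = pd.DataFrame(rows, columns=["pattern", "count", "genes"])
    df.attrs["set_names"] = [s.name for s in sets]
    df.attrs["union_size"] = len(union)
    return df
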