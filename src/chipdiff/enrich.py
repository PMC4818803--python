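"""Gene-set enrichment of up/down gene lists over a term->genes annotation.

Replaces a web enrichment service with the two classic one-tailed overlap
statistics computed locally: the plain hypergeometric tail (Fisher's exact
one-sided p) and its conservative EASE variant, which removes one gene from
the overlap before taking the tail and thus penalizes terms supported by a
single gene.  Benjamini-Hochberg q-values are computed across tested terms.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import FrozenSet, Iterable, List, Sequence, Set

import numpy as np
import pandas as pd
from scipy import stats

from chipdiff._stats import bh_adjust

__all__ = [
    "TermAnnotation",
    "hypergeom_sf",
    "ease_score",
    "enrich_terms",
    "read_gmt",
    "write_gmt",
]


@dataclass(frozen=True)
class TermAnnotation:
    """A named gene set (GO/KEGG-like term)."""

    term_id: str
    name: str
    category: str
    genes: FrozenSet[str]

    def __post_init__(self) -> None:
        if not self.term_id:
            raise ValueError("term_id must be non-empty")
        if not self.genes:
            raise ValueError(f"term {self.term_id!r} has no member genes")


def _check_sizes(k: int, n: int, K: int, N: int) -> None:
    if N <= 0:
        raise ValueError("universe size N must be positive")
    if not (0 <= n <= N and 0 <= K <= N):
        raise ValueError("list size n and term size K must lie in [0, N]")
    if not (0 <= k <= min(n, K)):
        raise ValueError("overlap k must lie in [0, min(n, K)]")


def hypergeom_sf(k: int, n: int, K: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N population, K successes, n draws)."""
    _check_sizes(k, n, K, N)
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def ease_score(k: int, n: int, K: int, N: int) -> float:
    """EASE variant: hypergeometric tail with the overlap reduced by one.

    Always at least as large as the plain hypergeometric p; returns 1.0 for
    k = 0 (and for k = 1, since P(X >= 0) = 1).
    """
    _check_sizes(k, n, K, N)
    if k == 0:
        return 1.0
    return hypergeom_sf(k - 1, n, K, N)


def enrich_terms(
    gene_list: Iterable[str],
    annotation: Sequence[TermAnnotation],
    universe: Iterable[str],
    method: str = "ease",
) -> pd.DataFrame:
    """Test every term with at least one list member against the universe.

    Term memberships and the gene list are intersected with the universe
    before counting.  Returns a table sorted by ascending p-value with
    columns mirroring the usual enrichment-report layout (category, term,
    overlap count, p-value) plus the contingency sizes, both statistics and
    BH q-values over the chosen ``method`` ("fisher" or "ease").
    """
    if method not in ("fisher", "ease"):
        raise ValueError("method must be 'fisher' or 'ease'")
    universe_set: Set[str] = set(universe)
    if not universe_set:
        raise ValueError("universe must be non-empty")
    genes = set(gene_list) & universe_set
    N = len(universe_set)
    n = len(genes)

    rows = []
    for term in annotation:
        members = term.genes & universe_set
        K = len(members)
        if K == 0:
            continue
        k = len(genes & members)
        if k == 0:
            continue
        p_fisher = hypergeom_sf(k, n, K, N)
        p_ease = ease_score(k, n, K, N)
        rows.append(
            {
                "category": term.category,
                "term_id": term.term_id,
                "name": term.name,
                "count": k,
                "n": n,
                "K": K,
                "N": N,
                "p_fisher": p_fisher,
                "p_ease": p_ease,
                "pvalue": p_ease if method == "ease" else p_fisher,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "category",
            "term_id",
            "name",
            "count",
            "n",
            "K",
            "N",
            "p_fisher",
            "p_ease",
            "pvalue",
        ],
    )
    if len(df):
        df["qvalue"] = bh_adjust(df["pvalue"].to_numpy())
        df = df.sort_values(
            ["pvalue", "term_id"], kind="stable", ignore_index=True
        )
    else:
        df["qvalue"] = pd.Series(dtype=float)
    return df


def read_gmt(path: str | Path, category: str = "GO") -> List[TermAnnotation]:
    """Read a GMT-like annotation: term_id <TAB> name <TAB> gene1 <TAB> ...

    ``category`` labels every term from the file (e.g. "GO" or "KEGG").
    """
    terms: List[TermAnnotation] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}: line {lineno}: expected term_id, name and members"
                )
            members = frozenset(f for f in fields[2:] if f)
            if not members:
                raise ValueError(f"{path}: line {lineno}: term has no member genes")
            terms.append(TermAnnotation(fields[0], fields[1], category, members))
    return terms


def write_gmt(terms: Sequence[TermAnnotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        for t in terms:
            members = "\t".join(sorted(t.genes))
            fh.write(f"{t.term_id}\t{t.name}\t{members}\n")
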