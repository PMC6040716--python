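"""Hypergeometric set statistics with Benjamini-Hochberg control.

Three flavours of the same exact test are provided: enrichment of each
miRNA's associated genes (targets plus regulator TFs) within a differential
expression gene set, a single overlap test between two gene sets (e.g. the
DE set against a curated disease-gene list), and a generic per-term
over-representation analysis (ORA) for annotation collections.

All tests use the inclusive upper tail P(X >= k) of the hypergeometric
distribution.  The universe is always applied by intersection before testing,
and it matters: p-values are only comparable for a stated universe.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "EnrichmentTest",
    "hypergeom_tail",
    "bh_adjust",
    "mirna_enrichment",
    "geneset_overlap_test",
    "ora",
    "read_gmt",
    "write_gmt",
]


@dataclass
class EnrichmentTest:
    """One hypergeometric test: overlap k of a query (n) with an annotation
    set (K) inside a universe (N)."""

    term: str
    k: int
    K: int
    n: int
    N: int
    p: float
    q: float | None = None
    members: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not (0 <= self.k <= min(self.n, self.K) and self.n <= self.N and self.K <= self.N):
            raise ValueError(
                f"inconsistent counts for {self.term!r}: k={self.k} K={self.K} "
                f"n={self.n} N={self.N}"
            )


def hypergeom_tail(k: int, K: int, n: int, N: int) -> float:
    """Exact upper tail P(X >= k) for X ~ Hypergeometric(N, K, n).

    ``N`` universe size, ``K`` annotated in the universe, ``n`` drawn
    (query size), ``k`` annotated among the drawn.
    """
    if K > N or n > N:
        raise ValueError(f"K={K} and n={n} must not exceed N={N}")
    if k < 0 or k > min(n, K):
        raise ValueError(f"k={k} outside [0, min(n={n}, K={K})]")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def bh_adjust(pvals: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(list(pvals), dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return list(multipletests(p, method="fdr_bh")[1])


def _as_table(tests: list[EnrichmentTest], alpha: float, by: str) -> pd.DataFrame:
    qs = bh_adjust([t.p for t in tests])
    for t, q in zip(tests, qs):
        t.q = q
    df = pd.DataFrame(
        {
            "term": [t.term for t in tests],
            "k": [t.k for t in tests],
            "K": [t.K for t in tests],
            "n": [t.n for t in tests],
            "N": [t.N for t in tests],
            "p": [t.p for t in tests],
            "q": [t.q for t in tests],
            "members": [",".join(sorted(t.members)) for t in tests],
        }
    )
    df["significant"] = df[by] <= alpha
    return df.sort_values(["q", "p", "term"], kind="mergesort").reset_index(drop=True)


def mirna_enrichment(
    de_genes: set[str],
    associations: Mapping[str, set[str]],
    universe: set[str],
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Test each miRNA's associated gene set for enrichment in the DE set.

    ``associations`` maps miRNA id -> associated genes (targets united with
    regulator TFs); sets are intersected with the universe before testing.
    Enriched miRNAs are those with BH-adjusted q <= alpha (default 0.01).
    """
    if not universe:
        raise ValueError("empty universe")
    if not de_genes:
        raise ValueError("empty DE gene set")
    de = set(de_genes) & universe
    if de != set(de_genes):
        raise ValueError("de_genes must be a subset of the universe")
    tests = []
    for mirna in sorted(associations):
        assoc = associations[mirna] & universe
        overlap = assoc & de
        tests.append(
            EnrichmentTest(
                term=mirna,
                k=len(overlap),
                K=len(assoc),
                n=len(de),
                N=len(universe),
                p=hypergeom_tail(len(overlap), len(assoc), len(de), len(universe)),
                members=tuple(sorted(overlap)),
            )
        )
    return _as_table(tests, alpha, by="q")


def geneset_overlap_test(set_a: set[str], set_b: set[str], universe: set[str]) -> EnrichmentTest:
    """Single upper-tail hypergeometric test on the overlap of two sets."""
    if not (set_a <= universe and set_b <= universe):
        raise ValueError("both sets must be subsets of the universe")
    k = len(set_a & set_b)
    test = EnrichmentTest(
        term="overlap",
        k=k,
        K=len(set_b),
        n=len(set_a),
        N=len(universe),
        p=hypergeom_tail(k, len(set_b), len(set_a), len(universe)),
        members=tuple(sorted(set_a & set_b)),
    )
    return test


def ora(
    query: set[str],
    annotation_sets: Mapping[str, set[str]],
    universe: set[str],
    min_annotated: int = 2,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Generic over-representation analysis over an annotation collection.

    Terms overlapping the query in fewer than ``min_annotated`` ids are
    skipped.  Significance is on the raw p (p <= alpha); the BH-adjusted
    column ``q`` is reported alongside for modern practice.
    """
    if not query:
        raise ValueError("empty query set")
    if not universe:
        raise ValueError("empty universe")
    q_ids = set(query) & universe
    tests = []
    for term in sorted(annotation_sets):
        ann = annotation_sets[term] & universe
        overlap = ann & q_ids
        if len(overlap) < min_annotated:
            continue
        tests.append(
            EnrichmentTest(
                term=term,
                k=len(overlap),
                K=len(ann),
                n=len(q_ids),
                N=len(universe),
                p=hypergeom_tail(len(overlap), len(ann), len(q_ids), len(universe)),
                members=tuple(sorted(overlap)),
            )
        )
    if not tests:
        return pd.DataFrame(
            columns=["term", "k", "K", "n", "N", "p", "q", "members", "significant"]
        )
    return _as_table(tests, alpha, by="p")


# ---------------------------------------------------------------------------
# GMT input/output


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT file (term, description, members...) into term -> id set."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{line_no}: GMT line needs >= 3 tab-separated fields")
            name = fields[0]
            if name in sets:
                raise ValueError(f"{path}:{line_no}: duplicate gene-set name {name!r}")
            sets[name] = {g for g in fields[2:] if g}
    return sets


def write_gmt(sets: Mapping[str, Iterable[str]], path: str | Path, description: str = "") -> None:
    with open(path, "w") as fh:
        for name in sorted(sets):
            members = "\t".join(sorted(set(sets[name])))
            fh.write(f"{name}\t{description}\t{members}\n")
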