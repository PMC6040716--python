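"""GO semantic-similarity validation of motif functional homogeneity.

Gene-pair functional similarity is computed with Wang's graph-based term
measure combined by best-match averaging (BMA).  For Wang's measure each term
contributes an S-value to every ancestor: 1 for the term itself and, for an
ancestor reached through an edge of weight w, w times the child's S-value
(maximized over paths).  The similarity of two terms is the summed S-values
over their shared ancestors (terms included) divided by the sum of all their
S-values, which is 1 exactly for identical terms and decays with distance in
the ontology.

Motif validation compares the pairwise similarities of a motif's co-regulated
genes against a permutation null (random annotated gene sets of the same
size) with a one-sided two-sample Kolmogorov-Smirnov test of stochastic
dominance.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "GODag",
    "AnnotationMap",
    "SemSimResult",
    "read_obo",
    "write_obo",
    "read_annotations",
    "write_annotations",
    "term_similarity",
    "gene_similarity",
    "motif_homogeneity",
    "permutation_null",
    "ks_greater",
    "validate_motif_homogeneity",
]

logger = logging.getLogger(__name__)

DEFAULT_EDGE_WEIGHTS = {"is_a": 0.8, "part_of": 0.6}


@dataclass
class GODag:
    """Rooted, acyclic ontology with weighted child->parent edges.

    ``parents`` maps a term to its ``(parent, weight)`` pairs; weights encode
    the semantic contribution of the relationship (0.8 for is_a, 0.6 for
    part_of by default).
    """

    parents: dict[str, list[tuple[str, float]]]
    namespace: dict[str, str]
    _svalue_cache: dict[str, dict[str, float]] = field(default_factory=dict, repr=False)
    _termsim_cache: dict[tuple[str, str], float] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        g = nx.DiGraph()
        g.add_nodes_from(self.parents)
        for child, ps in self.parents.items():
            for parent, w in ps:
                if not 0 < w < 1:
                    raise ValueError(f"edge weight {w} for {child}->{parent} not in (0,1)")
                if parent not in self.parents:
                    raise ValueError(f"parent {parent!r} of {child!r} is not a term")
                g.add_edge(child, parent)
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("ontology contains a cycle")

    @property
    def terms(self) -> set[str]:
        return set(self.parents)

    @property
    def roots(self) -> set[str]:
        return {t for t, ps in self.parents.items() if not ps}

    def svalues(self, term: str) -> dict[str, float]:
        """Wang S-values of ``term`` over its ancestor closure (term included)."""
        if term not in self.parents:
            raise KeyError(f"unknown term {term!r}")
        cached = self._svalue_cache.get(term)
        if cached is not None:
            return cached
        s: dict[str, float] = {term: 1.0}
        stack = [term]
        while stack:
            t = stack.pop()
            for parent, w in self.parents[t]:
                v = w * s[t]
                if v > s.get(parent, 0.0):
                    s[parent] = v
                    stack.append(parent)
        self._svalue_cache[term] = s
        return s


@dataclass
class AnnotationMap:
    """Gene id -> set of ontology term ids."""

    gene_terms: dict[str, set[str]]

    def annotated(self, dag: GODag | None = None) -> list[str]:
        """Genes with at least one (known) annotation, sorted."""
        if dag is None:
            return sorted(g for g, ts in self.gene_terms.items() if ts)
        return sorted(g for g, ts in self.gene_terms.items() if ts & dag.terms)

    def terms_of(self, gene: str, dag: GODag) -> set[str]:
        terms = self.gene_terms.get(gene, set())
        known = terms & dag.terms
        if terms - known:
            logger.debug("gene %s has %d terms outside the DAG", gene, len(terms - known))
        return known


# ---------------------------------------------------------------------------
# similarity


def term_similarity(t1: str, t2: str, dag: GODag) -> float:
    """Wang semantic similarity of two terms of the same namespace."""
    ns1, ns2 = dag.namespace.get(t1), dag.namespace.get(t2)
    if t1 not in dag.parents or t2 not in dag.parents:
        missing = t1 if t1 not in dag.parents else t2
        raise KeyError(f"unknown term {missing!r}")
    if ns1 != ns2:
        raise ValueError(f"cross-namespace pair: {t1} ({ns1}) vs {t2} ({ns2})")
    if t1 == t2:
        return 1.0
    key = (t1, t2) if t1 <= t2 else (t2, t1)
    cached = dag._termsim_cache.get(key)
    if cached is not None:
        return cached
    s1 = dag.svalues(t1)
    s2 = dag.svalues(t2)
    common = s1.keys() & s2.keys()
    num = sum(s1[t] + s2[t] for t in common)
    den = sum(s1.values()) + sum(s2.values())
    sim = num / den if den > 0 else 0.0
    dag._termsim_cache[key] = sim
    return sim


def gene_similarity(
    g1: str, g2: str, ann: AnnotationMap, dag: GODag, combine: str = "BMA"
) -> float:
    """Best-match-average similarity of two annotated genes.

    BMA averages, over both genes' term sets, each term's best match in the
    other set: (sum of row maxima + sum of column maxima) / (n1 + n2).
    """
    if combine != "BMA":
        raise ValueError(f"unsupported combine rule {combine!r}")
    terms1 = sorted(ann.terms_of(g1, dag))
    terms2 = sorted(ann.terms_of(g2, dag))
    if not terms1 or not terms2:
        raise ValueError(f"gene without usable annotations: {g1 if not terms1 else g2!r}")
    sims = np.array([[term_similarity(a, b, dag) for b in terms2] for a in terms1])
    return float((sims.max(axis=1).sum() + sims.max(axis=0).sum()) / (len(terms1) + len(terms2)))


def motif_homogeneity(
    coregulated: Iterable[str], ann: AnnotationMap, dag: GODag, motif_id: str = "motif"
) -> list[float]:
    """Pairwise similarities of a motif's co-regulated genes.

    Unannotated genes are skipped with a log message; fewer than 2 annotated
    genes is an error naming the motif.
    """
    genes = sorted(set(coregulated))
    usable = [g for g in genes if ann.terms_of(g, dag)]
    skipped = set(genes) - set(usable)
    if skipped:
        logger.info("%s: skipping unannotated genes %s", motif_id, sorted(skipped))
    if len(usable) < 2:
        raise ValueError(f"{motif_id}: fewer than 2 annotated co-regulated genes")
    return [
        gene_similarity(a, b, ann, dag) for a, b in itertools.combinations(usable, 2)
    ]


def permutation_null(
    m: int,
    ann: AnnotationMap,
    dag: GODag,
    n_perm: int = 100,
    seed: int | None = 0,
) -> list[float]:
    """Pooled pairwise similarities of ``n_perm`` random annotated gene sets.

    Each permutation draws ``m`` annotated genes uniformly without
    replacement and contributes all C(m, 2) pairwise scores.
    """
    universe = ann.annotated(dag)
    if m > len(universe):
        raise ValueError(f"m={m} exceeds the annotated universe of {len(universe)} genes")
    if m < 2:
        raise ValueError("need m >= 2 genes per permutation")
    rng = np.random.default_rng(seed)
    scores: list[float] = []
    for _ in range(n_perm):
        picked = rng.choice(len(universe), size=m, replace=False)
        genes = [universe[i] for i in picked]
        scores.extend(
            gene_similarity(a, b, ann, dag) for a, b in itertools.combinations(genes, 2)
        )
    return scores


# ---------------------------------------------------------------------------
# one-sided two-sample KS


def ks_greater(observed: Sequence[float], null: Sequence[float]) -> tuple[float, float]:
    """One-sided two-sample KS test that ``observed`` is stochastically larger.

    The statistic is D = sup_x (F_null(x) - F_obs(x)), evaluated over the
    pooled sample support; the p-value is the one-sided asymptotic
    exp(-2 D^2 mn/(m+n)), capped at 1.
    """
    obs = np.asarray(observed, dtype=float)
    nul = np.asarray(null, dtype=float)
    if obs.size == 0 or nul.size == 0:
        raise ValueError("both samples must be non-empty")
    obs_sorted = np.sort(obs)
    nul_sorted = np.sort(nul)
    support = np.concatenate([obs_sorted, nul_sorted])
    f_obs = np.searchsorted(obs_sorted, support, side="right") / obs.size
    f_nul = np.searchsorted(nul_sorted, support, side="right") / nul.size
    d = float(np.max(f_nul - f_obs))
    d = max(d, 0.0)
    m, n = obs.size, nul.size
    p = min(1.0, math.exp(-2.0 * d * d * m * n / (m + n)))
    return d, p


@dataclass
class SemSimResult:
    """KS comparison of one motif's (or the pooled) similarity scores."""

    motif_id: str
    observed: list[float]
    null: list[float]
    n_perm: int
    D: float
    p: float

    def cdf_table(self) -> pd.DataFrame:
        """Empirical CDFs on the pooled support, for external plotting."""
        support = np.unique(np.concatenate([self.observed, self.null]))
        obs = np.sort(self.observed)
        nul = np.sort(self.null)
        return pd.DataFrame(
            {
                "x": support,
                "F_obs": np.searchsorted(obs, support, side="right") / len(obs),
                "F_null": np.searchsorted(nul, support, side="right") / len(nul),
            }
        )


def validate_motif_homogeneity(
    motif_genes: Mapping[str, Iterable[str]],
    ann: AnnotationMap,
    dag: GODag,
    n_perm: int = 100,
    seed: int | None = 0,
    pooled: bool = True,
) -> list[SemSimResult]:
    """Per-motif (and pooled) KS validation against the permutation null.

    ``motif_genes`` maps motif id -> co-regulated gene set.  Each motif's
    null resamples its own number of annotated genes.  When ``pooled`` a
    combined result over all motifs' scores is appended under id "pooled".
    """
    results: list[SemSimResult] = []
    all_obs: list[float] = []
    all_null: list[float] = []
    ss = np.random.SeedSequence(seed)
    seeds = ss.generate_state(len(motif_genes)).tolist()
    for child_seed, (motif_id, genes) in zip(seeds, sorted(motif_genes.items())):
        obs = motif_homogeneity(genes, ann, dag, motif_id=motif_id)
        m = len([g for g in set(genes) if ann.terms_of(g, dag)])
        null = permutation_null(m, ann, dag, n_perm=n_perm, seed=child_seed)
        d, p = ks_greater(obs, null)
        results.append(SemSimResult(motif_id, obs, null, n_perm, d, p))
        all_obs.extend(obs)
        all_null.extend(null)
    if pooled and results:
        d, p = ks_greater(all_obs, all_null)
        results.append(SemSimResult("pooled", all_obs, all_null, n_perm, d, p))
    return results


# ---------------------------------------------------------------------------
# input/output


def read_obo(
    path: str | Path,
    weights: Mapping[str, float] = DEFAULT_EDGE_WEIGHTS,
) -> GODag:
    """Read an OBO subset (id, namespace, is_a, relationship: part_of)."""
    import obonet

    graph = obonet.read_obo(path)
    parents: dict[str, list[tuple[str, float]]] = {t: [] for t in graph.nodes}
    namespace = {
        t: data.get("namespace", "biological_process") for t, data in graph.nodes(data=True)
    }
    # obonet edges run child -> parent with the relationship as the key
    for child, parent, rel in graph.edges(keys=True):
        w = weights.get(rel)
        if w is None:
            continue
        parents[child].append((parent, w))
    for child in parents:
        parents[child].sort()
    return GODag(parents=parents, namespace=namespace)


def write_obo(dag: GODag, path: str | Path, ontology_name: str = "synthetic-go") -> None:
    """Write the DAG in minimal OBO 1.2 format (is_a / part_of only)."""
    with open(path, "w") as fh:
        fh.write(f"format-version: 1.2\nontology: {ontology_name}\n")
        for term in sorted(dag.parents):
            fh.write(f"\n[Term]\nid: {term}\nname: {term}\n")
            fh.write(f"namespace: {dag.namespace.get(term, 'biological_process')}\n")
            for parent, w in dag.parents[term]:
                if w == DEFAULT_EDGE_WEIGHTS["part_of"]:
                    fh.write(f"relationship: part_of {parent}\n")
                else:
                    fh.write(f"is_a: {parent}\n")


def read_annotations(path: str | Path) -> AnnotationMap:
    """Read a GAF-like two-column TSV (gene, term) with a header row."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"gene", "term"} <= set(df.columns):
        raise ValueError("annotation file needs columns: gene, term")
    mapping: dict[str, set[str]] = {}
    for gene, term in zip(df["gene"], df["term"]):
        mapping.setdefault(gene, set()).add(term)
    return AnnotationMap(mapping)


def write_annotations(ann: AnnotationMap, path: str | Path) -> None:
    rows = [
        {"gene": g, "term": t}
        for g in sorted(ann.gene_terms)
        for t in sorted(ann.gene_terms[g])
    ]
    pd.DataFrame(rows, columns=["gene", "term"]).to_csv(path, sep="\t", index=False)
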