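"""Typed regulatory-interaction databases, GRN construction, and hub calling.

The interaction database is a table of directed, typed regulatory edges
between transcription factors (TFs), miRNAs and target genes, each carrying
an evidence label (experimental or predicted).  The disease-specific gene
regulatory network (GRN) is built by seeding the database with the
differentially expressed genes and the enriched miRNAs, optionally pulling in
their first-neighbour regulators and targets.  Hubs are the top fraction of
nodes by total degree, ranked separately for the pooled TF/gene class and for
miRNAs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

__all__ = [
    "EDGE_CLASSES",
    "InteractionDB",
    "GRN",
    "HubSet",
    "InteractionSchemaError",
    "load_interaction_db",
    "build_grn",
    "degree_centrality",
    "identify_hubs",
    "write_sif",
    "write_graphml",
]

logger = logging.getLogger(__name__)

#: Admissible (source kind, target kind) -> edge class.
EDGE_CLASSES: dict[tuple[str, str], str] = {
    ("TF", "gene"): "TF->gene",
    ("TF", "TF"): "TF->gene",  # a TF is a gene with regulatory function
    ("TF", "miRNA"): "TF->miRNA",
    ("miRNA", "gene"): "miRNA->gene",
    ("miRNA", "TF"): "miRNA->TF",
}

_EVIDENCE = ("experimental", "predicted")


class InteractionSchemaError(ValueError):
    """Raised for rows violating the interaction-table schema."""


@dataclass
class InteractionDB:
    """Deduplicated table of typed regulatory edges.

    ``edges`` has columns source, source_kind, target, target_kind,
    edge_class, evidence, provenance; one row per (source, target,
    edge_class) triple.
    """

    edges: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"source", "source_kind", "target", "target_kind", "edge_class", "evidence"}
        missing = required - set(self.edges.columns)
        if missing:
            raise InteractionSchemaError(f"missing columns: {sorted(missing)}")
        if "provenance" not in self.edges.columns:
            self.edges = self.edges.assign(provenance="")
        if self.edges.duplicated(["source", "target", "edge_class"]).any():
            raise InteractionSchemaError("duplicate (source, target, edge_class) rows")

    @property
    def node_kinds(self) -> dict[str, str]:
        """Node id -> kind; a node acting anywhere as TF is classed TF."""
        kinds: dict[str, str] = {}
        rows = self.edges
        for node, kind in zip(
            pd.concat([rows["source"], rows["target"]]),
            pd.concat([rows["source_kind"], rows["target_kind"]]),
        ):
            prev = kinds.get(node)
            if prev is None or (kind == "TF" and prev == "gene"):
                kinds[node] = kind
            elif {prev, kind} == {"miRNA", "TF"} or {prev, kind} == {"miRNA", "gene"}:
                raise InteractionSchemaError(f"node {node!r} is both {prev} and {kind}")
        return kinds

    @property
    def nodes(self) -> set[str]:
        return set(self.edges["source"]) | set(self.edges["target"])

    def to_graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        kinds = self.node_kinds
        for node, kind in kinds.items():
            g.add_node(node, kind=kind)
        for row in self.edges.itertuples(index=False):
            g.add_edge(
                row.source, row.target,
                edge_class=row.edge_class, evidence=row.evidence, provenance=row.provenance,
            )
        return g


def _validate_rows(df: pd.DataFrame) -> pd.DataFrame:
    errors = []
    classes = []
    for i, row in enumerate(df.itertuples(index=False)):
        if row.source == row.target:
            errors.append(f"row {i}: self-loop on {row.source!r}")
            classes.append(None)
            continue
        key = (row.source_kind, row.target_kind)
        cls = EDGE_CLASSES.get(key)
        if cls is None:
            errors.append(f"row {i}: no edge class for {row.source_kind}->{row.target_kind}")
        elif row.evidence not in _EVIDENCE:
            errors.append(f"row {i}: unknown evidence {row.evidence!r}")
        classes.append(cls)
    if errors:
        raise InteractionSchemaError("; ".join(errors[:20]))
    return df.assign(edge_class=classes)


def load_interaction_db(
    path: str | Path, evidence_filter: str | None = "experimental"
) -> InteractionDB:
    """Read an interaction TSV, validate kinds, filter by evidence, dedup.

    Duplicate (source, target, class) rows are collapsed with their
    provenance strings merged.  ``evidence_filter=None`` keeps everything.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"source", "source_kind", "target", "target_kind", "evidence"}
    missing = required - set(df.columns)
    if missing:
        raise InteractionSchemaError(f"missing columns: {sorted(missing)}")
    if "provenance" not in df.columns:
        df["provenance"] = ""
    df = _validate_rows(df)
    if evidence_filter is not None:
        df = df[df["evidence"] == evidence_filter]
    merged = (
        df.groupby(["source", "target", "edge_class"], as_index=False, sort=True)
        .agg(
            source_kind=("source_kind", "first"),
            target_kind=("target_kind", "first"),
            evidence=("evidence", "first"),
            provenance=("provenance", lambda s: ";".join(sorted({x for x in s if x}))),
        )
    )
    cols = ["source", "source_kind", "target", "target_kind", "edge_class", "evidence", "provenance"]
    return InteractionDB(merged[cols].reset_index(drop=True))


@dataclass
class GRN:
    """Disease-specific gene regulatory network.

    ``graph`` is a directed networkx graph whose nodes carry ``kind``
    (TF/gene/miRNA) and ``origin`` (DE / enriched-miRNA / neighbor)
    attributes and whose edges carry ``edge_class`` and ``evidence``.
    """

    graph: nx.DiGraph
    name: str = "GRN"

    @property
    def nodes_by_kind(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {"TF": set(), "gene": set(), "miRNA": set()}
        for n, data in self.graph.nodes(data=True):
            out[data["kind"]].add(n)
        return out

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


def build_grn(
    de_genes: set[str],
    enriched_mirnas: set[str],
    db: InteractionDB,
    scope: str = "expanded",
    name: str = "D-EPC-GRN",
) -> GRN:
    """Build the GRN around the DE genes and enriched miRNAs.

    ``scope="core"`` keeps only edges with both endpoints in the seed set;
    ``scope="expanded"`` (default) additionally includes every database edge
    touching a seed node, bringing in first-neighbour regulators and targets
    flagged ``origin="neighbor"``.  Seed ids absent from the database or left
    without edges are retained as isolated nodes and logged.
    """
    if scope not in ("core", "expanded"):
        raise ValueError(f"unknown scope {scope!r}")
    if not de_genes and not enriched_mirnas:
        raise ValueError("both seed sets are empty")
    seeds = set(de_genes) | set(enriched_mirnas)
    kinds = db.node_kinds

    g = nx.DiGraph(name=name)
    df = db.edges
    src_in = df["source"].isin(seeds)
    tgt_in = df["target"].isin(seeds)
    keep = (src_in & tgt_in) if scope == "core" else (src_in | tgt_in)
    for row in df[keep].itertuples(index=False):
        g.add_edge(
            row.source, row.target,
            edge_class=row.edge_class, evidence=row.evidence, provenance=row.provenance,
        )
    # seed nodes with no retained edges stay in the network, isolated
    isolated = []
    for s in sorted(seeds):
        if s not in g:
            g.add_node(s)
            isolated.append(s)
    if isolated:
        logger.warning("%s: %d isolated seed nodes (no qualifying edges)", name, len(isolated))
    if g.number_of_edges() == 0:
        logger.warning("%s: empty edge set", name)
    for n in g.nodes:
        kind = kinds.get(n)
        if kind is None:
            # seed id unknown to the database: miRNA naming convention, else gene
            kind = "miRNA" if n in enriched_mirnas else "gene"
        if n in de_genes:
            origin = "DE"
        elif n in enriched_mirnas:
            origin = "enriched-miRNA"
        else:
            origin = "neighbor"
        g.nodes[n]["kind"] = kind
        g.nodes[n]["origin"] = origin
    return GRN(graph=g, name=name)


def degree_centrality(grn: GRN) -> dict[str, int]:
    """Total degree (in + out) per node."""
    return {n: d for n, d in grn.graph.degree()}


@dataclass
class HubSet:
    """Top-degree nodes per class (TF/gene pooled vs miRNA)."""

    tf_gene_hubs: list[str]
    mirna_hubs: list[str]
    fraction: float
    degrees: dict[str, int] = field(default_factory=dict)

    @property
    def all_hubs(self) -> set[str]:
        return set(self.tf_gene_hubs) | set(self.mirna_hubs)


def _top_fraction(nodes: list[str], degrees: Mapping[str, int], fraction: float) -> list[str]:
    if not nodes:
        return []
    ranked = sorted(nodes, key=lambda n: (-degrees[n], n))
    n_top = math.ceil(fraction * len(ranked))
    cutoff = degrees[ranked[n_top - 1]]
    hubs = [n for n in ranked if degrees[n] >= cutoff]
    if len(hubs) > n_top:
        logger.info("tie at degree %d widened hub set from %d to %d", cutoff, n_top, len(hubs))
    return hubs


def identify_hubs(grn: GRN, fraction: float = 0.10) -> HubSet:
    """Select the top ``fraction`` of nodes by total degree within each class.

    TFs and target genes are pooled into one ranking; miRNAs form their own.
    The hub count per class is ceil(fraction x class size); nodes tied with
    the last selected degree are included.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    deg = degree_centrality(grn)
    by_kind = grn.nodes_by_kind
    tf_gene = sorted(by_kind["TF"] | by_kind["gene"])
    mirnas = sorted(by_kind["miRNA"])
    return HubSet(
        tf_gene_hubs=_top_fraction(tf_gene, deg, fraction),
        mirna_hubs=_top_fraction(mirnas, deg, fraction),
        fraction=fraction,
        degrees=deg,
    )


# ---------------------------------------------------------------------------
# exports (Cytoscape-compatible)


def write_sif(grn: GRN, path: str | Path) -> None:
    """Write the network as SIF: source <edge_class> target, one per line."""
    with open(path, "w") as fh:
        for u, v, data in sorted(grn.graph.edges(data=True)):
            fh.write(f"{u}\t{data['edge_class']}\t{v}\n")
        for n in sorted(nx.isolates(grn.graph)):
            fh.write(f"{n}\n")


def write_graphml(grn: GRN, path: str | Path, hubs: HubSet | None = None) -> None:
    """Write GraphML with kind/origin/degree/hub node attributes."""
    g = grn.graph.copy()
    deg = degree_centrality(grn)
    hub_ids = hubs.all_hubs if hubs is not None else set()
    for n in g.nodes:
        g.nodes[n]["degree"] = deg[n]
        g.nodes[n]["hub"] = n in hub_ids
    nx.write_graphml(g, path)
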