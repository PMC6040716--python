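"""Ground-truth synthetic data for every stage of the co-regulatory pipeline.

Three generators emulate the statistical structure the analysis assumes:

* :func:`simulate_expression` — a four-group (cell type x disease)
  log2-intensity microarray experiment with genes differentially expressed
  exclusively in the diabetic-EPC contrast, plus confounding genes shared
  with the reference comparisons;
* :func:`simulate_interaction_db` — a typed TF/miRNA/gene interaction table
  with planted high-degree hubs and planted feed-forward loops on a sparse
  random background;
* :func:`simulate_go` — a tree-shaped ontology with functionally homogeneous
  gene clusters annotated inside single subtrees against a uniformly
  annotated background.

:func:`simulate_study` wires the three together on a shared gene universe so
the full pipeline (differential expression -> enrichment -> network -> motifs
-> semantic validation) can be scored against a recorded
:class:`SyntheticTruth`.  All generators are deterministic under a fixed
seed.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .expression import DEFAULT_GROUPS, ExpressionMatrix, GroupDesign
from .network import EDGE_CLASSES, InteractionDB
from .semsim import AnnotationMap, GODag

__all__ = [
    "SyntheticTruth",
    "simulate_expression",
    "simulate_interaction_db",
    "simulate_go",
    "simulate_study",
    "StudyBundle",
]

logger = logging.getLogger(__name__)


@dataclass
class SyntheticTruth:
    """Planted ground truth recorded by the generators.

    Only the fields relevant to the generator(s) that produced the truth are
    populated; :func:`simulate_study` merges the three.
    """

    #: exclusive-DE gene -> signed log2 effect in the diabetic-EPC group
    exclusive_genes: dict[str, float] = field(default_factory=dict)
    #: shared (non-exclusive) DE gene -> pattern label
    shared_genes: dict[str, str] = field(default_factory=dict)
    hub_tfs: list[str] = field(default_factory=list)
    hub_mirnas: list[str] = field(default_factory=list)
    #: motif type -> list of planted (tf, mirna, target) triples
    planted_motifs: dict[str, list[tuple[str, str, str]]] = field(default_factory=dict)
    #: planted enriched miRNA -> its planted associated gene set
    enriched_mirnas: dict[str, set[str]] = field(default_factory=dict)
    #: cluster anchor term -> functionally homogeneous member genes
    go_clusters: dict[str, set[str]] = field(default_factory=dict)
    config: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# expression


def simulate_expression(
    n_genes: int = 1000,
    samples_per_group: int = 9,
    effect: float = 2.0,
    sigma: float = 0.5,
    n_exclusive: int = 80,
    n_shared: int = 120,
    baseline_mean: float = 8.0,
    baseline_sd: float = 1.0,
    groups: Sequence[str] = DEFAULT_GROUPS,
    heavy_tails: bool = False,
    seed: int | None = 0,
) -> tuple[ExpressionMatrix, GroupDesign, SyntheticTruth]:
    """Simulate the four-group microarray experiment with planted truth.

    Exclusive genes are shifted by ``+-effect`` (log2 units) in the
    diabetic-EPC group only; shared genes are shifted in two or more groups
    so that they are differentially expressed in the reference comparisons
    as well (half follow a general diabetes pattern — shifted in both
    diabetic groups — and half are shifted in the non-diabetic EPC group
    only).  Remaining genes are pure noise.  Noise is i.i.d. Gaussian on the
    log2 scale (Student t with 5 df when ``heavy_tails``).
    """
    if n_exclusive + n_shared > n_genes:
        raise ValueError("n_exclusive + n_shared must not exceed n_genes")
    if len(groups) != 4:
        raise ValueError("exactly 4 groups are required")
    if samples_per_group < 2:
        raise ValueError("need at least 2 samples per group")
    rng = np.random.default_rng(seed)

    gene_ids = [f"G{i + 1:04d}" for i in range(n_genes)]
    sample_ids = [f"{g}_{i + 1:02d}" for g in groups for i in range(samples_per_group)]
    sample_to_group = {s: g for g in groups for s in sample_ids if s.startswith(f"{g}_")}

    baseline = rng.normal(baseline_mean, baseline_sd, size=n_genes)
    # group-mean shift matrix: genes x 4 groups
    shifts = np.zeros((n_genes, 4))
    signs = rng.choice([-1.0, 1.0], size=n_genes)

    exclusive = gene_ids[:n_exclusive]
    n_diab = n_shared // 2
    shared_diabetes = gene_ids[n_exclusive : n_exclusive + n_diab]
    shared_ndepc = gene_ids[n_exclusive + n_diab : n_exclusive + n_shared]

    # group order: (ND-Lin+, D-Lin+, ND-EPC, D-EPC) = columns 0..3
    for i in range(n_exclusive):
        shifts[i, 3] = signs[i] * effect  # diabetic EPCs only
    for i in range(n_exclusive, n_exclusive + n_diab):
        shifts[i, 1] = signs[i] * effect  # both diabetic groups: general
        shifts[i, 3] = signs[i] * effect  # diabetes response
    for i in range(n_exclusive + n_diab, n_exclusive + n_shared):
        shifts[i, 2] = signs[i] * effect  # non-diabetic EPCs only

    means = baseline[:, None] + shifts  # genes x groups
    per_sample = np.repeat(means, samples_per_group, axis=1)
    if heavy_tails:
        noise = rng.standard_t(5, size=per_sample.shape) * sigma
    else:
        noise = rng.normal(0.0, sigma, size=per_sample.shape)
    values = pd.DataFrame(per_sample + noise, index=gene_ids, columns=sample_ids)

    matrix = ExpressionMatrix(values, scale="log2")
    design = GroupDesign(sample_to_group=sample_to_group, groups=tuple(groups))
    truth = SyntheticTruth(
        exclusive_genes={g: float(signs[i] * effect) for i, g in enumerate(exclusive)},
        shared_genes={
            **{g: "diabetes-general" for g in shared_diabetes},
            **{g: "control-EPC" for g in shared_ndepc},
        },
        config={
            "n_genes": n_genes,
            "samples_per_group": samples_per_group,
            "effect": effect,
            "sigma": sigma,
            "n_exclusive": n_exclusive,
            "n_shared": n_shared,
            "seed": seed,
        },
    )
    return matrix, design, truth


# ---------------------------------------------------------------------------
# interaction database


def _edge(source: str, s_kind: str, target: str, t_kind: str, evidence: str = "experimental",
          provenance: str = "synthetic") -> dict:
    return {
        "source": source,
        "source_kind": s_kind,
        "target": target,
        "target_kind": t_kind,
        "edge_class": EDGE_CLASSES[(s_kind, t_kind)],
        "evidence": evidence,
        "provenance": provenance,
    }


def _dedup(edges: list[dict]) -> list[dict]:
    seen: set[tuple[str, str, str]] = set()
    out = []
    for e in edges:
        key = (e["source"], e["target"], e["edge_class"])
        if key not in seen:
            seen.add(key)
            out.append(e)
    return out


def simulate_interaction_db(
    n_tfs: int = 4,
    n_genes: int = 16,
    n_mirnas: int = 10,
    background_density: float = 0.04,
    n_hub_tfs: int = 2,
    n_hub_mirnas: int = 1,
    hub_degree_multiplier: float = 3.0,
    n_planted_ffls: Mapping[str, int] | None = None,
    predicted_fraction: float = 0.0,
    gene_ids: Sequence[str] | None = None,
    verify_hub_gap: bool = True,
    seed: int | None = 0,
) -> tuple[InteractionDB, SyntheticTruth]:
    """Simulate a typed interaction database with planted hubs and FFLs.

    Background edges are drawn independently per edge class at
    ``background_density``.  Hub nodes then receive enough extra out-edges to
    exceed the maximum background degree by ``hub_degree_multiplier``; with
    ``verify_hub_gap`` the generator checks that planted hubs strictly
    dominate every other node of their class and raises if the configuration
    cannot guarantee it.  Planted FFLs are wired with exactly the edges their
    type requires.  All planted edges carry experimental evidence; a random
    ``predicted_fraction`` of background edges is labelled predicted.
    """
    rng = np.random.default_rng(seed)
    if n_planted_ffls is None:
        # the default configuration is sized for exact hub recovery
        # (ceil(0.1 x class size) == planted hubs); FFL planting would raise
        # non-hub degrees against the 3x gap, so it is opt-in
        n_planted_ffls = {}
    unknown = set(n_planted_ffls) - {"TF-FFL", "miRNA-FFL", "composite-FFL"}
    if unknown:
        raise ValueError(f"unknown motif types {sorted(unknown)}")
    if n_hub_tfs > n_tfs or n_hub_mirnas > n_mirnas:
        raise ValueError("more hubs requested than nodes available")

    tfs = [f"TF{i + 1:02d}" for i in range(n_tfs)]
    mirnas = [f"mir-{i + 1:03d}" for i in range(n_mirnas)]
    if gene_ids is None:
        genes = [f"G{i + 1:04d}" for i in range(n_genes)]
    else:
        genes = list(gene_ids)
        n_genes = len(genes)
    if len({*tfs} & {*genes} or {*mirnas} & {*genes}):
        raise ValueError("gene ids collide with TF/miRNA ids")

    hub_tfs = tfs[:n_hub_tfs]
    hub_mirnas = mirnas[:n_hub_mirnas]

    edges: list[dict] = []

    def _background(sources: list[str], s_kind: str, targets: list[str], t_kind: str) -> None:
        for s in sources:
            for t in targets:
                if s == t:
                    continue
                if rng.random() < background_density:
                    ev = "predicted" if rng.random() < predicted_fraction else "experimental"
                    edges.append(_edge(s, s_kind, t, t_kind, evidence=ev))

    non_hub_tfs = tfs[n_hub_tfs:]
    non_hub_mirnas = mirnas[n_hub_mirnas:]
    _background(non_hub_tfs, "TF", genes, "gene")
    _background(non_hub_tfs, "TF", non_hub_mirnas, "miRNA")
    _background(non_hub_mirnas, "miRNA", genes, "gene")
    _background(non_hub_mirnas, "miRNA", non_hub_tfs, "TF")

    def _degrees(edge_list: list[dict]) -> dict[str, int]:
        deg: dict[str, int] = {}
        for e in edge_list:
            deg[e["source"]] = deg.get(e["source"], 0) + 1
            deg[e["target"]] = deg.get(e["target"], 0) + 1
        return deg

    # planted feed-forward loops.  Plant before the hubs so the hub degree
    # can be sized against the final non-hub degrees.  The regulator pair of
    # a planted triple keeps one consistent TF<->miRNA wiring (a background
    # edge in the opposite direction would silently change the motif type).
    planted: dict[str, list[tuple[str, str, str]]] = {t: [] for t in n_planted_ffls}
    used_triples: set[tuple[str, str, str]] = set()
    pair_type: dict[tuple[str, str], str] = {}
    existing_pairs = {(e["source"], e["target"]) for e in edges}
    plant_tfs = non_hub_tfs or tfs
    plant_mirnas = non_hub_mirnas or mirnas
    # round-robin regulator choice spreads planted degree evenly, keeping the
    # hub degree gap attainable on small configurations
    tf_rr = itertools.cycle(plant_tfs)
    mi_rr = itertools.cycle(plant_mirnas)
    for mtype, count in n_planted_ffls.items():
        attempts = 0
        while len(planted[mtype]) < count:
            attempts += 1
            if attempts > 500 * max(count, 1) * len(plant_tfs):
                raise ValueError(
                    f"could not place {count} fresh {mtype} triples; "
                    "configuration too dense for planting"
                )
            tf = next(tf_rr)
            mi = next(mi_rr)
            tg = genes[rng.integers(n_genes)]
            if (tf, mi, tg) in used_triples:
                continue
            if pair_type.get((tf, mi), mtype) != mtype:
                continue
            # reject pairs whose pre-existing TF<->miRNA edges contradict the type
            if mtype == "TF-FFL" and (mi, tf) in existing_pairs:
                continue
            if mtype == "miRNA-FFL" and (tf, mi) in existing_pairs:
                continue
            used_triples.add((tf, mi, tg))
            pair_type[(tf, mi)] = mtype
            if mtype in ("TF-FFL", "composite-FFL"):
                edges.append(_edge(tf, "TF", mi, "miRNA"))
                existing_pairs.add((tf, mi))
            if mtype in ("miRNA-FFL", "composite-FFL"):
                edges.append(_edge(mi, "miRNA", tf, "TF"))
                existing_pairs.add((mi, tf))
            edges.append(_edge(tf, "TF", tg, "gene"))
            edges.append(_edge(mi, "miRNA", tg, "gene"))
            existing_pairs.update([(tf, tg), (mi, tg)])
            planted[mtype].append((tf, mi, tg))

    if hub_tfs or hub_mirnas:
        deg = _degrees(edges)
        n_hubs = len(hub_tfs) + len(hub_mirnas)

        def _hub_degree(class_nodes: list[str]) -> int:
            cls_max = max([deg.get(n, 0) for n in class_nodes], default=0)
            # strictly dominate the class even after hub edges raise gene
            # in-degrees by at most one per hub
            need = max(
                int(np.ceil(hub_degree_multiplier * max(cls_max, 1))),
                cls_max + n_hubs + 1,
                3,
            )
            if need > n_genes:
                raise ValueError(
                    f"hub degree {need} exceeds the {n_genes} available gene "
                    "targets; lower background_density or raise n_genes"
                )
            return need

        if hub_tfs:
            tf_hub_degree = _hub_degree(non_hub_tfs + genes)
            for h in hub_tfs:
                targets = rng.choice(n_genes, size=tf_hub_degree, replace=False)
                for t in targets:
                    edges.append(_edge(h, "TF", genes[t], "gene"))
        if hub_mirnas:
            mi_hub_degree = _hub_degree(non_hub_mirnas)
            for h in hub_mirnas:
                targets = rng.choice(n_genes, size=mi_hub_degree, replace=False)
                for t in targets:
                    edges.append(_edge(h, "miRNA", genes[t], "gene"))

    columns = ["source", "source_kind", "target", "target_kind", "edge_class",
               "evidence", "provenance"]
    db = InteractionDB(pd.DataFrame(_dedup(edges), columns=columns))

    if verify_hub_gap and (hub_tfs or hub_mirnas):
        deg = _degrees(db.edges.to_dict("records"))
        kinds = db.node_kinds
        tg_class = [n for n, k in kinds.items() if k in ("TF", "gene")]
        mi_class = [n for n, k in kinds.items() if k == "miRNA"]
        for hubs, cls in ((hub_tfs, tg_class), (hub_mirnas, mi_class)):
            if not hubs:
                continue
            min_hub = min(deg.get(h, 0) for h in hubs)
            others = [deg.get(n, 0) for n in cls if n not in hubs]
            if others and min_hub <= max(others):
                raise ValueError(
                    f"planted hub degree gap violated (min hub {min_hub} <= "
                    f"max background {max(others)}); adjust the configuration"
                )

    truth = SyntheticTruth(
        hub_tfs=hub_tfs,
        hub_mirnas=hub_mirnas,
        planted_motifs=planted,
        config={
            "n_tfs": n_tfs,
            "n_genes": n_genes,
            "n_mirnas": n_mirnas,
            "background_density": background_density,
            "n_hub_tfs": n_hub_tfs,
            "n_hub_mirnas": n_hub_mirnas,
            "hub_degree_multiplier": hub_degree_multiplier,
            "seed": seed,
        },
    )
    return db, truth


# ---------------------------------------------------------------------------
# ontology


def simulate_go(
    depth: int = 4,
    branching: int = 3,
    n_clusters: int = 2,
    genes_per_cluster: int = 8,
    annotations_per_gene: int = 3,
    n_background_genes: int = 60,
    cluster_gene_sets: Sequence[Iterable[str]] | None = None,
    background_gene_ids: Sequence[str] | None = None,
    namespace: str = "biological_process",
    seed: int | None = 0,
) -> tuple[GODag, AnnotationMap, SyntheticTruth]:
    """Simulate a tree ontology with functionally homogeneous gene clusters.

    The DAG is a complete ``branching``-ary is_a tree of the given depth
    (``(branching^(depth+1) - 1) / (branching - 1)`` terms).  Each cluster is
    anchored at a distinct depth-2 term and its member genes are annotated
    only with terms from that anchor's leaf descendants; background genes are
    annotated uniformly over all leaves.  Cluster membership can be imposed
    with ``cluster_gene_sets`` (e.g. the target sets of planted motifs).
    """
    if depth < 2:
        raise ValueError("depth must be >= 2 so cluster anchors exist")
    rng = np.random.default_rng(seed)

    # build the complete tree level by level
    parents: dict[str, list[tuple[str, float]]] = {}
    namespaces: dict[str, str] = {}
    counter = itertools.count(1)

    def _new_term() -> str:
        return f"GO:{next(counter):07d}"

    root = _new_term()
    parents[root] = []
    namespaces[root] = namespace
    levels: list[list[str]] = [[root]]
    for _ in range(depth):
        level = []
        for parent in levels[-1]:
            for _ in range(branching):
                t = _new_term()
                parents[t] = [(parent, 0.8)]
                namespaces[t] = namespace
                level.append(t)
        levels.append(level)
    dag = GODag(parents=parents, namespace=namespaces)

    anchors = levels[2]
    if cluster_gene_sets is not None:
        n_clusters = len(cluster_gene_sets)
    if n_clusters > len(anchors):
        raise ValueError(f"{n_clusters} clusters requested but only {len(anchors)} anchors")

    # leaf descendants per anchor: the complete tree is built depth-first per
    # parent, so each anchor owns a contiguous block of leaves
    leaves = levels[-1]
    per_anchor = branching ** (depth - 2)
    anchor_leaves = {
        a: leaves[i * per_anchor : (i + 1) * per_anchor] for i, a in enumerate(anchors)
    }

    gene_terms: dict[str, set[str]] = {}
    clusters: dict[str, set[str]] = {}
    chosen = rng.choice(len(anchors), size=n_clusters, replace=False)
    for c, a_idx in enumerate(chosen):
        anchor = anchors[a_idx]
        pool = anchor_leaves[anchor]
        if cluster_gene_sets is not None:
            members = sorted(set(cluster_gene_sets[c]))
        else:
            members = [f"CLG{c + 1}_{i + 1:02d}" for i in range(genes_per_cluster)]
        for g in members:
            n_ann = min(annotations_per_gene, len(pool))
            picked = rng.choice(len(pool), size=n_ann, replace=False)
            gene_terms[g] = {pool[i] for i in picked}
        clusters[anchor] = set(members)

    if background_gene_ids is None:
        background = [f"BGG{i + 1:03d}" for i in range(n_background_genes)]
    else:
        background = [g for g in background_gene_ids if g not in gene_terms]
    for g in background:
        picked = rng.choice(len(leaves), size=min(annotations_per_gene, len(leaves)),
                            replace=False)
        gene_terms[g] = {leaves[i] for i in picked}

    ann = AnnotationMap(gene_terms)
    truth = SyntheticTruth(
        go_clusters=clusters,
        config={
            "depth": depth,
            "branching": branching,
            "n_clusters": n_clusters,
            "annotations_per_gene": annotations_per_gene,
            "seed": seed,
        },
    )
    return dag, ann, truth


# ---------------------------------------------------------------------------
# coherent whole-study bundle


@dataclass
class StudyBundle:
    """All synthetic inputs of one simulated study, on a shared gene universe."""

    expression: ExpressionMatrix
    design: GroupDesign
    db: InteractionDB
    dag: GODag
    annotations: AnnotationMap
    truth: SyntheticTruth


def simulate_study(
    seed: int | None = 0,
    n_genes: int = 1000,
    samples_per_group: int = 9,
    effect: float = 2.0,
    sigma: float = 0.5,
    n_exclusive: int = 80,
    n_shared: int = 120,
    n_tfs: int = 15,
    n_mirnas: int = 20,
    n_enriched_mirnas: int = 5,
    targets_per_enriched: int = 12,
    ffl_group_sizes: Mapping[str, tuple[int, int]] | None = None,
) -> StudyBundle:
    """Simulate a coherent study: expression, interactions and ontology.

    The interaction database is laid over the expression gene universe:

    * hub TFs (TF01, TF02) regulate many exclusive-DE genes;
    * planted enriched miRNAs target mostly exclusive-DE genes, background
      miRNAs target non-DE genes;
    * planted FFL groups wire a (TF, miRNA) regulator pair to several shared
      exclusive-DE targets per motif type (``ffl_group_sizes`` maps type ->
      (number of pairs, targets per pair));
    * the first two planted TF-FFL pairs' co-regulated gene sets become the
      functionally homogeneous ontology clusters.
    """
    ss = np.random.SeedSequence(seed)
    s_expr, s_db, s_go, s_misc = (int(x) for x in ss.generate_state(4) % (2**31 - 1))
    rng = np.random.default_rng(s_misc)

    if ffl_group_sizes is None:
        ffl_group_sizes = {"TF-FFL": (2, 6), "miRNA-FFL": (1, 6), "composite-FFL": (1, 4)}
    total_ffl_targets = sum(n * t for n, t in ffl_group_sizes.values())
    if total_ffl_targets > n_exclusive:
        raise ValueError(
            f"planted FFL groups need {total_ffl_targets} exclusive-DE targets "
            f"but only {n_exclusive} are planted"
        )
    n_pairs_needed = sum(n for n, _ in ffl_group_sizes.values())
    if n_pairs_needed > (n_enriched_mirnas - 1) + (n_mirnas - n_enriched_mirnas):
        raise ValueError("not enough miRNAs for the planted FFL regulator pairs")

    matrix, design, truth = simulate_expression(
        n_genes=n_genes,
        samples_per_group=samples_per_group,
        effect=effect,
        sigma=sigma,
        n_exclusive=n_exclusive,
        n_shared=n_shared,
        seed=s_expr,
    )
    gene_ids = matrix.feature_ids
    exclusive = sorted(truth.exclusive_genes)
    non_de = [g for g in gene_ids if g not in truth.exclusive_genes
              and g not in truth.shared_genes]

    tfs = [f"TF{i + 1:02d}" for i in range(n_tfs)]
    mirnas = [f"mir-{i + 1:03d}" for i in range(n_mirnas)]
    edges: list[dict] = []

    # reserve one dedicated TF per planted FFL regulator pair, so a pair's
    # co-regulated gene set is exactly its planted targets plus the paired
    # miRNA's association set (needed below for the ontology clusters)
    n_pairs_total = sum(n for n, _ in ffl_group_sizes.values())
    hub_tfs = tfs[:2]
    pair_tfs = tfs[2 : 2 + n_pairs_total]
    background_tfs = tfs[2 + n_pairs_total :]
    if not background_tfs:
        raise ValueError("n_tfs too small for hub + planted-pair TFs")

    # hub TFs regulate a large slice of the exclusive-DE genes
    for h in hub_tfs:
        picked = rng.choice(len(exclusive), size=min(25, len(exclusive)), replace=False)
        for i in picked:
            edges.append(_edge(h, "TF", exclusive[i], "gene"))

    # planted enriched miRNAs target exclusive-DE genes (plus a little noise)
    enriched = mirnas[:n_enriched_mirnas]
    enriched_targets: dict[str, set[str]] = {}
    for mi in enriched:
        de_picked = rng.choice(len(exclusive), size=targets_per_enriched, replace=False)
        bg_picked = rng.choice(len(non_de), size=2, replace=False)
        targets = {exclusive[i] for i in de_picked} | {non_de[i] for i in bg_picked}
        for t in sorted(targets):
            edges.append(_edge(mi, "miRNA", t, "gene"))
        enriched_targets[mi] = targets
    # one hub miRNA: the first enriched miRNA additionally targets many DE genes
    hub_mirna = enriched[0]
    extra = rng.choice(len(exclusive), size=min(20, len(exclusive)), replace=False)
    for i in extra:
        edges.append(_edge(hub_mirna, "miRNA", exclusive[i], "gene"))
        enriched_targets[hub_mirna].add(exclusive[i])

    # background miRNAs avoid DE genes so their enrichment stays null
    for mi in mirnas[n_enriched_mirnas:]:
        picked = rng.choice(len(non_de), size=8, replace=False)
        for i in picked:
            edges.append(_edge(mi, "miRNA", non_de[i], "gene"))

    # background TFs regulate a mix of genes and the occasional miRNA
    for tf in background_tfs:
        picked = rng.choice(len(gene_ids), size=10, replace=False)
        for i in picked:
            edges.append(_edge(tf, "TF", gene_ids[i], "gene"))
        if rng.random() < 0.5:
            mi = mirnas[int(rng.integers(n_enriched_mirnas, n_mirnas))]
            edges.append(_edge(tf, "TF", mi, "miRNA"))

    # planted FFL groups: one regulator pair shares several DE targets
    planted: dict[str, list[tuple[str, str, str]]] = {}
    free_tfs = iter(pair_tfs)
    free_mirnas = iter(enriched[1:] + mirnas[n_enriched_mirnas:])
    cluster_sets: list[set[str]] = []
    target_pool = list(exclusive)
    rng.shuffle(target_pool)
    pool_iter = iter(target_pool)
    for mtype in ("TF-FFL", "miRNA-FFL", "composite-FFL"):
        n_pairs, n_targets = ffl_group_sizes.get(mtype, (0, 0))
        planted[mtype] = []
        for _ in range(n_pairs):
            tf = next(free_tfs)
            mi = next(free_mirnas)
            if mtype in ("TF-FFL", "composite-FFL"):
                edges.append(_edge(tf, "TF", mi, "miRNA"))
            if mtype in ("miRNA-FFL", "composite-FFL"):
                edges.append(_edge(mi, "miRNA", tf, "TF"))
            targets = [next(pool_iter) for _ in range(n_targets)]
            for tg in targets:
                edges.append(_edge(tf, "TF", tg, "gene"))
                edges.append(_edge(mi, "miRNA", tg, "gene"))
                planted[mtype].append((tf, mi, tg))
            if mtype == "TF-FFL":
                # the pair's full co-regulated set: planted targets plus
                # everything the paired miRNA is associated with
                cluster_sets.append(
                    set(targets) | enriched_targets.get(mi, set())
                )

    db = InteractionDB(pd.DataFrame(_dedup(edges)))

    # ontology clusters = the co-regulated gene sets of the planted TF-FFL pairs
    clustered = set().union(*cluster_sets) if cluster_sets else set()
    annotated_bg = sorted(
        (set(str(g) for g in rng.choice(non_de, size=120, replace=False)) | set(exclusive))
        - clustered
    )
    dag, ann, truth_go = simulate_go(
        cluster_gene_sets=cluster_sets,
        background_gene_ids=annotated_bg,
        seed=s_go,
    )

    truth.hub_tfs = hub_tfs
    truth.hub_mirnas = [hub_mirna]
    truth.planted_motifs = planted
    truth.enriched_mirnas = enriched_targets
    truth.go_clusters = truth_go.go_clusters
    truth.config.update(
        {
            "n_tfs": n_tfs,
            "n_mirnas": n_mirnas,
            "n_enriched_mirnas": n_enriched_mirnas,
            "targets_per_enriched": targets_per_enriched,
            "seed": seed,
        }
    )
    return StudyBundle(
        expression=matrix, design=design, db=db, dag=dag, annotations=ann, truth=truth
    )
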