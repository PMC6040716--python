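"""End-to-end orchestration of the co-regulatory network analysis.

Stages: normalization -> differential expression over the six comparisons ->
exclusivity filter -> miRNA enrichment -> GRN construction -> hub calling ->
FFL motif census and randomization significance -> GO semantic validation ->
optional over-representation / disease-overlap tests.  Every stage writes a
TSV table and the run ends with a manifest (parameters, seeds, stage counts,
input checksums).

The exclusivity filter defaults to subtracting the comparisons that do not
involve the diabetic-EPC group (the internal-reference logic of the study
design: a change also seen among the reference populations is not specific
to the diseased EPCs).  ``exclusivity="all"`` subtracts every non-focal
comparison instead.
"""

from __future__ import annotations

import hashlib
import json
import logging
import pickle
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .diffexpr import DECallSet, exclusive_de, run_all_comparisons
from .enrichment import geneset_overlap_test, mirna_enrichment, ora, read_gmt
from .expression import (
    ExpressionMatrix,
    GroupDesign,
    ProbeMap,
    merge_probes,
    quantile_normalize,
    read_expression,
)
from .motifs import MotifCensus, MotifSignificance, enumerate_motifs, motif_significance
from .network import (
    GRN,
    HubSet,
    InteractionDB,
    build_grn,
    degree_centrality,
    identify_hubs,
    load_interaction_db,
    write_graphml,
    write_sif,
)
from .semsim import AnnotationMap, GODag, SemSimResult, read_annotations, read_obo, \
    validate_motif_homogeneity

__all__ = ["PipelineParams", "PipelineConfig", "PipelineResult", "run_study", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineParams:
    """All thresholds and seeds of the pipeline, with study defaults."""

    sam_target_fdr: float = 0.05
    modt_alpha: float = 0.05
    auc_lower: float = 0.1
    auc_upper: float = 0.9
    min_methods: int = 2
    de_n_perm: int = 100
    mirna_alpha: float = 0.01
    ora_alpha: float = 0.05
    ora_min_annotated: int = 2
    hub_fraction: float = 0.10
    motif_nr: int = 100
    motif_alpha: float = 0.05
    swaps_per_edge: int = 10
    semsim_n_perm: int = 100
    n_examined_motifs: int = 6
    exclusivity: str = "reference"  # or "all"
    grn_scope: str = "expanded"
    normalize: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for name, lo, hi in (
            ("sam_target_fdr", 0, 1), ("modt_alpha", 0, 1), ("mirna_alpha", 0, 1),
            ("ora_alpha", 0, 1), ("motif_alpha", 0, 1), ("hub_fraction", 0, 1),
            ("auc_lower", 0, 1), ("auc_upper", 0, 1),
        ):
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise ValueError(f"{name}={v} outside [{lo}, {hi}]")
        if self.exclusivity not in ("reference", "all"):
            raise ValueError("exclusivity must be 'reference' or 'all'")
        if self.grn_scope not in ("core", "expanded"):
            raise ValueError("grn_scope must be 'core' or 'expanded'")


@dataclass
class PipelineConfig:
    """Paths plus parameters; round-trips through YAML."""

    expression: str
    design: str
    interactions: str
    obo: str
    annotations: str
    probe_map: str | None = None
    gene_sets: str | None = None  # GMT for ORA
    disease_genes: str | None = None  # GMT with one disease gene list
    outdir: str = "coregnet-results"
    expression_scale: str = "log2"
    params: PipelineParams = field(default_factory=PipelineParams)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        params = PipelineParams(**raw.pop("params", {}))
        return cls(params=params, **raw)

    def to_yaml(self, path: str | Path) -> None:
        raw = asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=True)


@dataclass
class PipelineResult:
    """In-memory bundle of every stage output."""

    de: dict[str, DECallSet]
    consensus_sets: dict[str, set[str]]
    exclusive_genes: set[str]
    mirna_table: pd.DataFrame
    enriched_mirnas: set[str]
    grn: GRN
    hubs: HubSet
    census: MotifCensus
    significance: MotifSignificance
    semsim: list[SemSimResult]
    examined_motifs: dict[str, set[str]]
    ora_table: pd.DataFrame | None = None
    disease_overlap: Any = None
    manifest: dict = field(default_factory=dict)


def _hash_inputs(*parts: Any) -> str:
    h = hashlib.sha256()
    for p in parts:
        h.update(repr(p).encode())
    return h.hexdigest()


class _StageCache:
    """Checksum-gated per-stage cache: unchanged inputs make a stage a no-op."""

    def __init__(self, outdir: Path | None):
        self.dir = outdir / "cache" if outdir is not None else None
        if self.dir is not None:
            self.dir.mkdir(parents=True, exist_ok=True)

    def get_or_run(self, name: str, key: str, fn):
        if self.dir is None:
            return fn()
        meta = self.dir / f"{name}.json"
        blob = self.dir / f"{name}.pkl"
        if meta.exists() and blob.exists():
            recorded = json.loads(meta.read_text())
            if recorded.get("key") == key:
                logger.info("stage %s: inputs unchanged, reusing cached result", name)
                with open(blob, "rb") as fh:
                    return pickle.load(fh)
        result = fn()
        with open(blob, "wb") as fh:
            pickle.dump(result, fh)
        meta.write_text(json.dumps({"key": key}))
        return result


def coregulated_genes(grn: GRN, tf: str, mirna: str) -> set[str]:
    """Genes regulated by the TF or the miRNA of a motif, within the GRN."""
    g = grn.graph
    out: set[str] = set()
    for reg in (tf, mirna):
        for succ in g.successors(reg):
            if g.nodes[succ].get("kind") in ("gene", "TF") and succ not in (tf, mirna):
                out.add(succ)
    return out


def run_study(
    matrix: ExpressionMatrix,
    design: GroupDesign,
    db: InteractionDB,
    dag: GODag,
    annotations: AnnotationMap,
    params: PipelineParams | None = None,
    outdir: str | Path | None = None,
    gene_sets: Mapping[str, set[str]] | None = None,
    disease_genes: set[str] | None = None,
) -> PipelineResult:
    """Run the full analysis on in-memory inputs.

    With ``outdir`` every stage output is written as TSV (plus SIF/GraphML
    for the network) and a ``manifest.json`` records parameters, seeds and
    stage counts; stage results are cached there keyed by an input checksum,
    so re-running with unchanged inputs skips recomputation.
    """
    params = params or PipelineParams()
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    cache = _StageCache(out)
    manifest: dict[str, Any] = {
        "version": __version__,
        "params": asdict(params),
        "stages": {},
    }

    # --- stage 1: normalization -------------------------------------------
    if params.normalize:
        matrix = quantile_normalize(matrix)
    focal = design.focal_id
    if focal not in design.comparison_ids:
        raise ValueError(f"focal comparison {focal} missing from the design")

    # --- stage 2: differential expression ---------------------------------
    de_key = _hash_inputs("de", params, matrix.values.to_numpy().tobytes(),
                          sorted(design.sample_to_group.items()))
    de = cache.get_or_run(
        "de",
        de_key,
        lambda: run_all_comparisons(
            matrix,
            design,
            seed=params.seed,
            sam_target_fdr=params.sam_target_fdr,
            modt_alpha=params.modt_alpha,
            auc_lower=params.auc_lower,
            auc_upper=params.auc_upper,
            min_methods=params.min_methods,
            n_perm=params.de_n_perm,
        ),
    )
    consensus_sets = {cid: cs.consensus for cid, cs in de.items()}
    exclude = design.reference_comparisons() if params.exclusivity == "reference" else None
    exclusive = exclusive_de(consensus_sets, focal, exclude=exclude)
    manifest["stages"]["diffexpr"] = {
        "comparisons": len(de),
        "consensus_sizes": {c: len(s) for c, s in consensus_sets.items()},
        "exclusive": len(exclusive),
        "exclusivity_subtracted": sorted(exclude) if exclude is not None
        else [c for c in consensus_sets if c != focal],
    }

    # --- stage 3: miRNA enrichment ----------------------------------------
    kinds = db.node_kinds
    universe = {n for n, k in kinds.items() if k in ("gene", "TF")}
    mirna_ids = sorted(n for n, k in kinds.items() if k == "miRNA")
    g_db = db.to_graph()
    assoc = {
        mi: ({s for s in g_db.successors(mi)} | {p for p in g_db.predecessors(mi)}) & universe
        for mi in mirna_ids
    }
    de_in_universe = exclusive & universe
    if not de_in_universe:
        raise ValueError("no exclusive DE gene appears in the interaction database")
    mirna_table = mirna_enrichment(de_in_universe, assoc, universe, alpha=params.mirna_alpha)
    enriched = set(mirna_table.loc[mirna_table["significant"], "term"])
    manifest["stages"]["mirna_enrichment"] = {
        "universe": len(universe),
        "de_in_universe": len(de_in_universe),
        "tested": len(assoc),
        "enriched": len(enriched),
    }

    # --- stage 4: GRN + hubs ----------------------------------------------
    grn = build_grn(exclusive, enriched, db, scope=params.grn_scope, name="D-EPC-GRN")
    hubs = identify_hubs(grn, fraction=params.hub_fraction)
    manifest["stages"]["network"] = {
        "nodes": grn.graph.number_of_nodes(),
        "edges": grn.n_edges,
        "tf_gene_hubs": len(hubs.tf_gene_hubs),
        "mirna_hubs": len(hubs.mirna_hubs),
    }

    # --- stage 5: motifs ---------------------------------------------------
    census = enumerate_motifs(grn)
    sig_key = _hash_inputs("motifs", params, sorted(grn.graph.edges))
    significance = cache.get_or_run(
        "motif_significance",
        sig_key,
        lambda: motif_significance(
            grn,
            nr=params.motif_nr,
            seed=params.seed + 101,
            alpha=params.motif_alpha,
            swaps_per_edge=params.swaps_per_edge,
        ),
    )
    sig_types = significance.significant_types
    manifest["stages"]["motifs"] = {
        "counts": census.counts,
        "significant_types": sorted(sig_types),
        "significant_instances": sum(census.counts[t] for t in sig_types),
    }

    # --- stage 6: semantic validation -------------------------------------
    pairs: dict[tuple[str, str], int] = {}
    for inst in census.instances:
        if inst.motif_type in sig_types:
            pairs[(inst.tf, inst.mirna)] = pairs.get((inst.tf, inst.mirna), 0) + 1
    examined: dict[str, set[str]] = {}
    ranked = sorted(pairs, key=lambda p: (-len(coregulated_genes(grn, *p)), p))
    for tf, mi in ranked[: params.n_examined_motifs]:
        genes = coregulated_genes(grn, tf, mi)
        annotated = [g for g in genes if annotations.terms_of(g, dag)]
        if len(annotated) >= 2:
            examined[f"{tf}|{mi}"] = genes
    semsim_results = (
        validate_motif_homogeneity(
            examined, annotations, dag, n_perm=params.semsim_n_perm,
            seed=params.seed + 211,
        )
        if examined
        else []
    )
    manifest["stages"]["semsim"] = {
        "examined_motifs": len(examined),
        "pooled_p": next((r.p for r in semsim_results if r.motif_id == "pooled"), None),
    }

    # --- stage 7: optional set-level validation ---------------------------
    ora_table = None
    if gene_sets:
        expr_universe = set(matrix.feature_ids)
        ora_table = ora(
            exclusive & expr_universe, gene_sets, expr_universe,
            min_annotated=params.ora_min_annotated, alpha=params.ora_alpha,
        )
        manifest["stages"]["ora"] = {"tested": len(ora_table)}
    disease_overlap = None
    if disease_genes is not None:
        expr_universe = set(matrix.feature_ids)
        disease_overlap = geneset_overlap_test(
            exclusive & expr_universe, disease_genes & expr_universe, expr_universe
        )
        manifest["stages"]["disease_overlap"] = {
            "k": disease_overlap.k, "p": disease_overlap.p,
        }

    result = PipelineResult(
        de=de,
        consensus_sets=consensus_sets,
        exclusive_genes=exclusive,
        mirna_table=mirna_table,
        enriched_mirnas=enriched,
        grn=grn,
        hubs=hubs,
        census=census,
        significance=significance,
        semsim=semsim_results,
        examined_motifs=examined,
        ora_table=ora_table,
        disease_overlap=disease_overlap,
        manifest=manifest,
    )
    if out is not None:
        _write_outputs(result, out)
    return result


def _write_outputs(res: PipelineResult, out: Path) -> None:
    for cid, cs in res.de.items():
        cs.table().to_csv(out / f"de_{cid}.tsv", sep="\t")
    pd.Series(sorted(res.exclusive_genes), name="gene").to_csv(
        out / "exclusive_genes.tsv", sep="\t", index=False
    )
    res.mirna_table.to_csv(out / "mirna_enrichment.tsv", sep="\t", index=False)
    deg = degree_centrality(res.grn)
    hub_ids = res.hubs.all_hubs
    pd.DataFrame(
        {
            "node": sorted(res.grn.graph.nodes),
            "kind": [res.grn.graph.nodes[n]["kind"] for n in sorted(res.grn.graph.nodes)],
            "origin": [res.grn.graph.nodes[n]["origin"] for n in sorted(res.grn.graph.nodes)],
            "degree": [deg[n] for n in sorted(res.grn.graph.nodes)],
            "hub": [n in hub_ids for n in sorted(res.grn.graph.nodes)],
        }
    ).to_csv(out / "grn_nodes.tsv", sep="\t", index=False)
    write_sif(res.grn, out / "grn.sif")
    write_graphml(res.grn, out / "grn.graphml", hubs=res.hubs)
    census_table = res.census.table()
    sig_types = res.significance.significant_types
    census_table["type_p"] = [res.significance.p_value(t) if t in res.significance.n_real
                              else float("nan")
                              for t in census_table["motif_type"]]
    census_table["significant"] = census_table["motif_type"].isin(sig_types)
    census_table.to_csv(out / "motifs.tsv", sep="\t", index=False)
    res.significance.table().to_csv(out / "motif_significance.tsv", sep="\t", index=False)
    rows = [
        {"motif_id": r.motif_id, "n_scores": len(r.observed), "D": r.D, "p": r.p}
        for r in res.semsim
    ]
    pd.DataFrame(rows, columns=["motif_id", "n_scores", "D", "p"]).to_csv(
        out / "semsim.tsv", sep="\t", index=False
    )
    for r in res.semsim:
        if r.motif_id == "pooled":
            r.cdf_table().to_csv(out / "semsim_cdf_pooled.tsv", sep="\t", index=False)
    if res.ora_table is not None:
        res.ora_table.to_csv(out / "ora.tsv", sep="\t", index=False)
    with open(out / "manifest.json", "w") as fh:
        json.dump(res.manifest, fh, indent=2, sort_keys=True, default=str)


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """Load every input named in the config and run the full analysis."""
    for attr in ("expression", "design", "interactions", "obo", "annotations"):
        path = getattr(cfg, attr)
        if not Path(path).exists():
            raise FileNotFoundError(f"{attr} input does not exist: {path}")
    matrix = read_expression(cfg.expression, scale=cfg.expression_scale)
    design = GroupDesign.from_tsv(cfg.design)
    if cfg.probe_map:
        matrix = merge_probes(matrix, ProbeMap.from_tsv(cfg.probe_map))
    db = load_interaction_db(cfg.interactions)
    dag = read_obo(cfg.obo)
    ann = read_annotations(cfg.annotations)
    gene_sets = read_gmt(cfg.gene_sets) if cfg.gene_sets else None
    disease = None
    if cfg.disease_genes:
        sets = read_gmt(cfg.disease_genes)
        disease = set().union(*sets.values())
    return run_study(
        matrix, design, db, dag, ann,
        params=cfg.params, outdir=cfg.outdir,
        gene_sets=gene_sets, disease_genes=disease,
    )
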