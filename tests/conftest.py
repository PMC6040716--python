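import numpy as np
import pandas as pd
import pytest

from coregnet.expression import ExpressionMatrix, GroupDesign
from coregnet.network import EDGE_CLASSES, GRN, InteractionDB

import networkx as nx


@pytest.fixture
def tiny_matrix() -> ExpressionMatrix:
    values = pd.DataFrame(
        [[1.0, 4.0], [2.0, 5.0], [3.0, 6.0]],
        index=["f1", "f2", "f3"],
        columns=["s1", "s2"],
    )
    return ExpressionMatrix(values, scale="log2")


@pytest.fixture
def small_design() -> GroupDesign:
    groups = ("ND-Lin+", "D-Lin+", "ND-EPC", "D-EPC")
    mapping = {f"{g}_{i}": g for g in groups for i in range(3)}
    return GroupDesign(sample_to_group=mapping, groups=groups)


def make_db(rows: list[tuple]) -> InteractionDB:
    """rows: (source, source_kind, target, target_kind[, evidence])"""
    records = []
    for row in rows:
        source, s_kind, target, t_kind = row[:4]
        evidence = row[4] if len(row) > 4 else "experimental"
        records.append(
            {
                "source": source,
                "source_kind": s_kind,
                "target": target,
                "target_kind": t_kind,
                "edge_class": EDGE_CLASSES[(s_kind, t_kind)],
                "evidence": evidence,
                "provenance": "test",
            }
        )
    return InteractionDB(pd.DataFrame(records))


def make_grn(edges: list[tuple[str, str]], kinds: dict[str, str], name: str = "test") -> GRN:
    """Build a GRN directly from (source, target) pairs and a kind map."""
    g = nx.DiGraph(name=name)
    for n, k in kinds.items():
        g.add_node(n, kind=k, origin="DE")
    for u, v in edges:
        g.add_edge(
            u, v,
            edge_class=EDGE_CLASSES[(kinds[u], kinds[v])],
            evidence="experimental",
            provenance="test",
        )
    return GRN(graph=g, name=name)


def random_grn(rng: np.random.Generator, n_tf=5, n_mi=4, n_gene=10, p=0.18) -> GRN:
    """Random typed GRN with edges drawn per legal edge class."""
    kinds = {f"T{i}": "TF" for i in range(n_tf)}
    kinds.update({f"m{i}": "miRNA" for i in range(n_mi)})
    kinds.update({f"g{i}": "gene" for i in range(n_gene)})
    edges = []
    for u, ku in kinds.items():
        for v, kv in kinds.items():
            if u == v or (ku, kv) not in EDGE_CLASSES:
                continue
            if ku == "gene":
                continue
            if rng.random() < p:
                edges.append((u, v))
    return make_grn(edges, kinds)
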