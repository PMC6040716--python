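"""Expression-matrix preprocessing for a four-group microarray design.

This module covers the preprocessing path of a two-factor (cell type x
disease) microarray experiment: reading a feature x sample intensity table,
background correction and log2 transformation, quantile normalization, and
collapsing probe-level rows to gene level by averaging.

The in-memory container is :class:`ExpressionMatrix`, a thin wrapper around a
pandas DataFrame (rows = features, columns = samples) that tracks whether the
values are raw intensities or log2 intensities.  :class:`GroupDesign` captures
the four sample groups and the six pairwise comparisons between them, with the
focal comparison (non-diabetic EPC vs diabetic EPC) marked.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "GroupDesign",
    "ProbeMap",
    "ExpressionFormatError",
    "read_expression",
    "write_expression",
    "background_correct_log2",
    "quantile_normalize",
    "merge_probes",
    "DEFAULT_GROUPS",
    "DEFAULT_COMPARISONS",
]

#: Default group labels: (non-diabetic / diabetic) x (Lin+ cells / Lin-VEGF-R2+ EPCs).
DEFAULT_GROUPS: tuple[str, ...] = ("ND-Lin+", "D-Lin+", "ND-EPC", "D-EPC")

#: Default six pairwise comparisons as (reference, case) index pairs into the
#: group list.  Comparison 4 (1-based) is ND-EPC vs D-EPC, the focal contrast.
DEFAULT_COMPARISONS: tuple[tuple[int, int], ...] = (
    (0, 1),  # comp1: ND-Lin+ vs D-Lin+   (internal Lin+ reference)
    (0, 2),  # comp2: ND-Lin+ vs ND-EPC
    (1, 3),  # comp3: D-Lin+  vs D-EPC
    (2, 3),  # comp4: ND-EPC  vs D-EPC    (focal)
    (0, 3),  # comp5: ND-Lin+ vs D-EPC
    (1, 2),  # comp6: D-Lin+  vs ND-EPC
)


class ExpressionFormatError(ValueError):
    """Raised for malformed expression/design/probe-map inputs."""


@dataclass
class ExpressionMatrix:
    """Feature x sample intensity matrix with a declared scale.

    Parameters
    ----------
    values
        DataFrame with unique feature ids as the index and unique sample ids
        as columns.
    scale
        Either ``"raw"`` (positive intensities) or ``"log2"``.
    """

    values: pd.DataFrame
    scale: str = "log2"

    def __post_init__(self) -> None:
        if self.scale not in ("raw", "log2"):
            raise ExpressionFormatError(f"unknown scale {self.scale!r}")
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ExpressionFormatError(f"duplicate feature ids: {dups[:10]}")
        if self.values.columns.has_duplicates:
            dups = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ExpressionFormatError(f"duplicate sample ids: {dups[:10]}")
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ExpressionFormatError("expression values must be finite (no NaN/inf)")

    @property
    def feature_ids(self) -> list[str]:
        return [str(f) for f in self.values.index]

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.values.columns]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        missing = [s for s in samples if s not in self.values.columns]
        if missing:
            raise KeyError(f"samples not in matrix: {missing}")
        return ExpressionMatrix(self.values.loc[:, list(samples)].copy(), self.scale)


@dataclass
class GroupDesign:
    """Assignment of samples to the four experimental groups.

    ``comparisons`` is an ordered list of (reference group, case group)
    pairs; ``focal`` is the 1-based index of the focal comparison, by default
    4 = non-diabetic EPC vs diabetic EPC.  Log fold changes downstream are
    case minus reference, so a positive value means up in the case (diabetic)
    group of that comparison.
    """

    sample_to_group: dict[str, str]
    groups: tuple[str, ...] = DEFAULT_GROUPS
    comparisons: tuple[tuple[str, str], ...] = ()
    focal: int = 4

    def __post_init__(self) -> None:
        if not self.comparisons:
            self.comparisons = tuple(
                (self.groups[i], self.groups[j]) for i, j in DEFAULT_COMPARISONS
            )
        seen_groups = set(self.groups)
        for s, g in self.sample_to_group.items():
            if g not in seen_groups:
                raise ExpressionFormatError(f"sample {s!r} maps to unknown group {g!r}")
        for ref, case in self.comparisons:
            if ref == case:
                raise ExpressionFormatError(f"degenerate comparison {ref!r} vs {ref!r}")
            if ref not in seen_groups or case not in seen_groups:
                raise ExpressionFormatError(f"comparison ({ref!r}, {case!r}) uses unknown group")
        n_pairs = len(self.groups) * (len(self.groups) - 1) // 2
        if len(self.comparisons) != n_pairs:
            raise ExpressionFormatError(
                f"expected {n_pairs} pairwise comparisons, got {len(self.comparisons)}"
            )
        if not (1 <= self.focal <= len(self.comparisons)):
            raise ExpressionFormatError(f"focal comparison index {self.focal} out of range")

    @property
    def comparison_ids(self) -> list[str]:
        return [f"comp{i + 1}" for i in range(len(self.comparisons))]

    @property
    def focal_id(self) -> str:
        return f"comp{self.focal}"

    def comparison(self, comp_id: str) -> tuple[str, str]:
        """Return (reference group, case group) for a ``compN`` id."""
        try:
            idx = int(comp_id.removeprefix("comp")) - 1
            return self.comparisons[idx]
        except (ValueError, IndexError) as exc:
            raise KeyError(f"unknown comparison id {comp_id!r}") from exc

    def samples_of(self, group: str) -> list[str]:
        if group not in self.groups:
            raise KeyError(f"unknown group {group!r}")
        return sorted(s for s, g in self.sample_to_group.items() if g == group)

    def reference_comparisons(self) -> list[str]:
        """Comparison ids that do not involve the focal case group.

        These are the comparisons among the internal-reference populations
        (e.g. the Lin+ fractions and the non-diabetic EPCs): a change seen
        there is, by the study logic, not specific to the diabetic EPCs.
        """
        _, case = self.comparisons[self.focal - 1]
        return [
            cid
            for cid, (r, c) in zip(self.comparison_ids, self.comparisons)
            if case not in (r, c) and cid != self.focal_id
        ]

    @classmethod
    def from_tsv(cls, path: str | Path, **kwargs) -> "GroupDesign":
        df = pd.read_csv(path, sep="\t", dtype=str)
        if not {"sample_id", "group"} <= set(df.columns):
            raise ExpressionFormatError("design file needs columns: sample_id, group")
        if df["sample_id"].duplicated().any():
            raise ExpressionFormatError("duplicate sample_id rows in design file")
        mapping = dict(zip(df["sample_id"], df["group"]))
        groups = kwargs.pop("groups", None)
        if groups is None:
            # preserve first-appearance order of groups in the file
            groups = tuple(dict.fromkeys(df["group"]))
        return cls(sample_to_group=mapping, groups=tuple(groups), **kwargs)

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"sample_id": list(self.sample_to_group), "group": list(self.sample_to_group.values())}
        ).to_csv(path, sep="\t", index=False)


@dataclass
class ProbeMap:
    """Many-to-one probe -> gene mapping."""

    probe_to_gene: dict[str, str]

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ProbeMap":
        df = pd.read_csv(path, sep="\t", dtype=str)
        if not {"probe_id", "gene_id"} <= set(df.columns):
            raise ExpressionFormatError("probe map needs columns: probe_id, gene_id")
        if df["probe_id"].duplicated().any():
            dups = df.loc[df["probe_id"].duplicated(), "probe_id"].tolist()
            raise ExpressionFormatError(f"probe mapped to more than one gene: {dups[:10]}")
        return cls(dict(zip(df["probe_id"], df["gene_id"])))

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"probe_id": list(self.probe_to_gene), "gene_id": list(self.probe_to_gene.values())}
        ).to_csv(path, sep="\t", index=False)


def read_expression(path: str | Path, scale: str = "raw") -> ExpressionMatrix:
    """Read a TSV expression table (first column feature id, header = samples)."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    seen: set[str] = set()
    dups = sorted({h for h in header if h in seen or seen.add(h)})
    if dups:
        raise ExpressionFormatError(f"duplicated sample columns: {dups}")
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & raw.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ExpressionFormatError(
            f"non-numeric cell at feature {raw.index[r]!r}, sample {raw.columns[c]!r}: "
            f"{raw.iat[r, c]!r}"
        )
    if numeric.isna().to_numpy().any():
        r, c = np.argwhere(numeric.isna().to_numpy())[0]
        raise ExpressionFormatError(
            f"missing value at feature {raw.index[r]!r}, sample {raw.columns[c]!r}"
        )
    return ExpressionMatrix(numeric.astype(float), scale=scale)


def write_expression(m: ExpressionMatrix, path: str | Path) -> None:
    out = m.values.copy()
    out.index.name = "feature_id"
    out.to_csv(path, sep="\t", float_format="%.10g")


def background_correct_log2(
    m: ExpressionMatrix, offset: float = 0.0, floor: float = 1.0
) -> ExpressionMatrix:
    """Subtract a constant background and move to the log2 scale.

    ``values' = log2(max(value - offset, floor))`` with ``floor > 0`` so the
    logarithm is always defined.  Monotone in the input.
    """
    if m.scale != "raw":
        raise ValueError("matrix is already on the log2 scale")
    if offset < 0:
        raise ValueError("offset must be >= 0")
    if floor <= 0:
        raise ValueError("floor must be > 0")
    corrected = np.maximum(m.values.to_numpy(dtype=float) - offset, floor)
    out = pd.DataFrame(np.log2(corrected), index=m.values.index, columns=m.values.columns)
    return ExpressionMatrix(out, scale="log2")


def quantile_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample column onto the common per-rank-mean distribution.

    After normalization ``sorted(col_i) == sorted(col_j)`` for all column
    pairs of tie-free data.  Ties within a column receive the mean of the
    rank-means their positions span (the usual average-ties convention);
    tied columns therefore deviate from the common distribution exactly
    where the ranks are ambiguous.  Rank order within every column is
    preserved, and on tie-free data the operation is idempotent.
    """
    X = m.values.to_numpy(dtype=float)
    n_feat, n_samp = X.shape
    if n_samp < 2:
        raise ValueError("quantile normalization needs at least 2 samples")
    order = np.argsort(X, axis=0, kind="mergesort")
    rank_means = np.mean(np.take_along_axis(X, order, axis=0), axis=1)
    out = np.empty_like(X)
    for j in range(n_samp):
        idx = order[:, j]
        xs = X[idx, j]
        # tied runs in the sorted column share the mean of their span of rank-means
        starts = np.flatnonzero(np.r_[True, xs[1:] != xs[:-1]])
        sums = np.add.reduceat(rank_means, starts)
        lengths = np.diff(np.r_[starts, n_feat])
        col_sorted = np.repeat(sums / lengths, lengths)
        out[idx, j] = col_sorted
    return ExpressionMatrix(
        pd.DataFrame(out, index=m.values.index, columns=m.values.columns), scale=m.scale
    )


def merge_probes(m: ExpressionMatrix, pm: ProbeMap) -> ExpressionMatrix:
    """Collapse probe rows to gene rows by the per-sample arithmetic mean."""
    unmapped = [p for p in m.feature_ids if p not in pm.probe_to_gene]
    if unmapped:
        raise ExpressionFormatError(f"probes without gene mapping: {unmapped[:10]}")
    genes = pd.Index([pm.probe_to_gene[p] for p in m.feature_ids], name="gene_id")
    merged = m.values.groupby(genes, sort=True).mean()
    return ExpressionMatrix(merged, scale=m.scale)
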