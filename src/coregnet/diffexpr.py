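"""Consensus differential expression over six pairwise group comparisons.

Three callers are run per comparison — the SAM statistic with a permutation
FDR, an empirical-Bayes moderated t-test, and the ROC AUC of each gene as a
classifier of the two groups — and a gene is accepted as differentially
expressed when at least two of the three call it.  The focal comparison's
consensus set is then reduced to the genes not called in a chosen set of
reference comparisons (exclusivity filter).

Statistics are computed on the log2 scale; log fold change is the case-group
mean minus the reference-group mean, so positive values are up in the case
(diabetic) group.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

from .enrichment import bh_adjust
from .expression import ExpressionMatrix, GroupDesign

__all__ = [
    "SamResult",
    "ModeratedTResult",
    "AucResult",
    "DECallSet",
    "sam_statistic",
    "sam_permutation_fdr",
    "moderated_t",
    "auc_roc",
    "consensus_de",
    "exclusive_de",
    "run_comparison",
    "run_all_comparisons",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# result containers


@dataclass
class SamResult:
    """Per-gene SAM statistics for one two-group comparison.

    ``d`` is the regularized t-like statistic (mean difference over pooled
    standard error plus fudge factor ``s0``); ``q`` and ``called`` are filled
    in by :func:`sam_permutation_fdr`.
    """

    d: pd.Series
    s: pd.Series
    s0: float
    delta: float | None = None
    fdr: float | None = None
    q: pd.Series | None = None
    called: pd.Series | None = None

    @property
    def called_genes(self) -> set[str]:
        if self.called is None:
            raise ValueError("run sam_permutation_fdr before asking for calls")
        return set(self.called.index[self.called])


@dataclass
class ModeratedTResult:
    """Per-gene moderated t statistics with the fitted variance prior."""

    t: pd.Series
    p: pd.Series
    q: pd.Series
    called: pd.Series
    df_prior: float
    s2_prior: float
    df_residual: float

    @property
    def called_genes(self) -> set[str]:
        return set(self.called.index[self.called])


@dataclass
class AucResult:
    """Per-gene ROC AUC for separating the two groups."""

    auc: pd.Series
    called: pd.Series
    lower: float
    upper: float

    @property
    def called_genes(self) -> set[str]:
        return set(self.called.index[self.called])


@dataclass
class DECallSet:
    """Calls for one comparison: per-method sets, consensus, LFC, direction."""

    comparison: str
    reference: str
    case: str
    method_calls: dict[str, set[str]]
    consensus: set[str]
    lfc: pd.Series
    min_methods: int = 2

    @property
    def direction(self) -> pd.Series:
        """'up'/'down' in the case group, by the sign of the log fold change."""
        return pd.Series(
            np.where(self.lfc >= 0, "up", "down"), index=self.lfc.index, name="direction"
        )

    def table(self) -> pd.DataFrame:
        votes = pd.Series(0, index=self.lfc.index, dtype=int)
        for genes in self.method_calls.values():
            votes[votes.index.isin(genes)] += 1
        return pd.DataFrame(
            {
                "lfc": self.lfc,
                "direction": self.direction,
                "votes": votes,
                "consensus": votes.index.isin(self.consensus),
            }
        )


# ---------------------------------------------------------------------------
# helpers


def _group_arrays(
    m: ExpressionMatrix, group_a: Sequence[str], group_b: Sequence[str]
) -> tuple[np.ndarray, np.ndarray]:
    if len(group_a) == 0 or len(group_b) == 0:
        raise ValueError("both groups must be non-empty")
    if set(group_a) & set(group_b):
        raise ValueError("groups share samples")
    a = m.values.loc[:, list(group_a)].to_numpy(dtype=float)
    b = m.values.loc[:, list(group_b)].to_numpy(dtype=float)
    return a, b


def _pooled_se(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pooled standard error of the mean difference, per gene."""
    na, nb = a.shape[1], b.shape[1]
    pooled_var = ((na - 1) * a.var(axis=1, ddof=1) + (nb - 1) * b.var(axis=1, ddof=1)) / (
        na + nb - 2
    )
    return np.sqrt(pooled_var * (1.0 / na + 1.0 / nb))


# ---------------------------------------------------------------------------
# SAM


def sam_statistic(
    m: ExpressionMatrix,
    group_a: Sequence[str],
    group_b: Sequence[str],
    s0: float | str = "auto",
    s0_percentile: float = 50.0,
) -> SamResult:
    """SAM regularized t statistic d = (mean_b - mean_a) / (s + s0).

    ``s`` is the pooled standard error of the mean difference.  With
    ``s0="auto"`` the fudge factor is the given percentile (default: median)
    of the gene-wise standard errors — a simple, widely used stand-in for the
    coefficient-of-variation search of the original procedure.
    """
    a, b = _group_arrays(m, group_a, group_b)
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValueError("SAM needs at least 2 samples per group")
    s = _pooled_se(a, b)
    if s0 == "auto":
        s0_val = float(np.percentile(s, s0_percentile))
    else:
        s0_val = float(s0)
    if s0_val < 0:
        raise ValueError("s0 must be >= 0")
    denom = s + s0_val
    if np.any(denom == 0):
        raise ZeroDivisionError(
            "zero variance in both groups with s0=0: SAM statistic undefined"
        )
    d = (b.mean(axis=1) - a.mean(axis=1)) / denom
    idx = m.values.index
    return SamResult(
        d=pd.Series(d, index=idx, name="d"),
        s=pd.Series(s, index=idx, name="s"),
        s0=s0_val,
    )


def _permutation_d(
    X: np.ndarray, na: int, n_perm: int, s0: float, rng: np.random.Generator
) -> np.ndarray:
    """Sorted SAM statistics for label permutations; rows = permutations.

    When the number of distinct labelings C(n, na) does not exceed ``n_perm``
    all of them are enumerated (the identity labeling included), otherwise
    ``n_perm`` labelings are sampled uniformly at random.
    """
    n = X.shape[1]
    total = math.comb(n, na)
    if total <= n_perm:
        combos = [np.array(c) for c in itertools.combinations(range(n), na)]
        if total < n_perm:
            logger.warning(
                "n_perm=%d exceeds %d distinct labelings; enumerating all", n_perm, total
            )
    else:
        combos = [rng.permutation(n)[:na] for _ in range(n_perm)]
    out = np.empty((len(combos), X.shape[0]))
    all_idx = np.arange(n)
    for i, ca in enumerate(combos):
        mask = np.zeros(n, dtype=bool)
        mask[ca] = True
        a, b = X[:, mask], X[:, ~mask]
        d = (b.mean(axis=1) - a.mean(axis=1)) / (_pooled_se(a, b) + s0)
        out[i] = np.sort(d)
    return out


def sam_permutation_fdr(
    res: SamResult,
    m: ExpressionMatrix,
    group_a: Sequence[str],
    group_b: Sequence[str],
    delta: float | None = None,
    target_fdr: float = 0.05,
    n_perm: int = 100,
    seed: int | None = 0,
    n_delta_grid: int = 50,
) -> SamResult:
    """Tusher-style permutation FDR for the SAM statistic.

    The observed statistics are ordered and compared rank-by-rank with the
    mean order statistics over label permutations; gene at rank i is called
    when ``|d_(i) - dbar_(i)| > delta``.  The false-call count for a given
    delta is the median, across permutations, of permuted statistics falling
    beyond the calling thresholds; FDR = median false calls / calls (pi0 = 1).
    With ``delta=None`` the smallest grid delta achieving ``target_fdr`` is
    chosen.  Per-gene q-values are the smallest FDR at which the gene is
    called, made monotone in |d|.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    a, b = _group_arrays(m, group_a, group_b)
    X = np.concatenate([a, b], axis=1)
    rng = np.random.default_rng(seed)
    perm = _permutation_d(X, a.shape[1], n_perm, res.s0, rng)
    dbar = perm.mean(axis=0)

    d = res.d.to_numpy()
    order = np.argsort(d, kind="mergesort")
    dsorted = d[order]
    diff = dsorted - dbar

    def _eval(dlt: float) -> tuple[np.ndarray, float]:
        called_sorted = np.abs(diff) > dlt
        n_called = int(called_sorted.sum())
        if n_called == 0:
            return called_sorted, 0.0
        up = called_sorted & (diff > 0)
        low = called_sorted & (diff < 0)
        cut_up = dsorted[up].min() if up.any() else np.inf
        cut_low = dsorted[low].max() if low.any() else -np.inf
        n_false = (perm >= cut_up).sum(axis=1) + (perm <= cut_low).sum(axis=1)
        fdr = min(float(np.median(n_false)) / n_called, 1.0)
        return called_sorted, fdr

    abs_diff = np.abs(diff)
    grid = np.unique(np.quantile(abs_diff, np.linspace(0.0, 1.0, n_delta_grid)))
    fdr_at = {}
    for dlt in grid:
        _, fdr_at[dlt] = _eval(float(dlt))

    if delta is None:
        feasible = [dlt for dlt in grid if fdr_at[dlt] <= target_fdr and np.any(abs_diff > dlt)]
        delta_val = float(min(feasible)) if feasible else float(abs_diff.max())
    else:
        delta_val = float(delta)
    called_sorted, fdr = _eval(delta_val)

    # q per gene: smallest FDR over grid deltas at which the gene is called
    q_sorted = np.ones_like(dsorted)
    for dlt in sorted(grid):
        mask = abs_diff > dlt
        q_sorted[mask] = np.minimum(q_sorted[mask], fdr_at[dlt])
    q = np.ones_like(d)
    q[order] = q_sorted
    called = np.zeros_like(d, dtype=bool)
    called[order] = called_sorted
    # enforce q monotone non-increasing in |d|
    by_absd = np.argsort(-np.abs(d), kind="mergesort")
    q[by_absd] = np.minimum.accumulate(q[by_absd])

    idx = res.d.index
    return SamResult(
        d=res.d,
        s=res.s,
        s0=res.s0,
        delta=delta_val,
        fdr=fdr,
        q=pd.Series(q, index=idx, name="q"),
        called=pd.Series(called, index=idx, name="called"),
    )


# ---------------------------------------------------------------------------
# moderated t


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    if x <= 0:
        raise ValueError("trigamma inverse needs x > 0")
    if x > 1e7:
        return 1.0 / math.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(75):
        tri = float(special.polygamma(1, y))
        dif = tri * (1.0 - tri / x) / float(special.polygamma(2, y))
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return y


def _fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments fit of the scaled-F model for sample variances.

    Under the hierarchical model s2 ~ s2_prior * chi2_df / df with
    1/sigma^2 ~ chi2_d0 scaling, log sample variances follow a shifted
    log-F distribution; matching mean and variance of log(s2) yields
    (d0, s2_prior).  Returns (inf, geometric-mean variance) when the observed
    spread is no larger than expected from sampling alone.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if ok.sum() < 2:
        raise ValueError("need at least 2 genes with positive variance to fit the prior")
    z = np.log(s2[ok])
    e = z - float(special.digamma(df / 2.0)) + math.log(df / 2.0)
    e_mean = float(e.mean())
    e_var = float(e.var(ddof=1)) - float(special.polygamma(1, df / 2.0))
    if e_var <= 0:
        return math.inf, math.exp(e_mean)
    d0 = 2.0 * _trigamma_inverse(e_var)
    s2_prior = math.exp(
        e_mean + float(special.digamma(d0 / 2.0)) - math.log(d0 / 2.0)
    )
    return d0, s2_prior


def moderated_t(
    m: ExpressionMatrix,
    group_a: Sequence[str],
    group_b: Sequence[str],
    alpha: float = 0.05,
    prior_df: float | None = None,
) -> ModeratedTResult:
    """Empirical-Bayes moderated t-test for one two-group comparison.

    Gene-wise sample variances are shrunk toward a fitted prior variance
    ``s2_prior`` with prior degrees of freedom ``d0`` (estimated by method of
    moments on log variances); the moderated statistic is tested on
    ``d0 + df_residual`` degrees of freedom and calls are BH-adjusted
    p <= alpha.  ``prior_df=0`` disables shrinkage and reproduces the plain
    pooled t-test.
    """
    a, b = _group_arrays(m, group_a, group_b)
    na, nb = a.shape[1], b.shape[1]
    if na < 2 or nb < 2:
        raise ValueError("moderated t needs at least 2 samples per group")
    if m.values.shape[0] < 2 and prior_df is None:
        raise ValueError(
            "cannot estimate a variance prior from fewer than 2 genes; use a plain t-test"
        )
    df_res = float(na + nb - 2)
    s2 = ((na - 1) * a.var(axis=1, ddof=1) + (nb - 1) * b.var(axis=1, ddof=1)) / df_res

    if prior_df is None:
        d0, s2_prior = _fit_variance_prior(s2, df_res)
    else:
        d0 = float(prior_df)
        if d0 < 0:
            raise ValueError("prior_df must be >= 0")
        s2_prior = float(np.exp(np.mean(np.log(s2[s2 > 0])))) if np.any(s2 > 0) else 0.0

    if math.isinf(d0):
        s2_post = np.full_like(s2, s2_prior)
        df_total = 1e9
    else:
        s2_post = (d0 * s2_prior + df_res * s2) / (d0 + df_res) if d0 > 0 else s2
        df_total = d0 + df_res
    t = (b.mean(axis=1) - a.mean(axis=1)) / np.sqrt(s2_post * (1.0 / na + 1.0 / nb))
    p = 2.0 * stats.t.sf(np.abs(t), df_total)
    q = np.asarray(bh_adjust(list(p)))
    idx = m.values.index
    return ModeratedTResult(
        t=pd.Series(t, index=idx, name="t"),
        p=pd.Series(p, index=idx, name="p"),
        q=pd.Series(q, index=idx, name="q"),
        called=pd.Series(q <= alpha, index=idx, name="called"),
        df_prior=d0,
        s2_prior=s2_prior,
        df_residual=df_res,
    )


# ---------------------------------------------------------------------------
# AUC


def auc_roc(
    m: ExpressionMatrix,
    group_a: Sequence[str],
    group_b: Sequence[str],
    lower: float = 0.1,
    upper: float = 0.9,
) -> AucResult:
    """Per-gene ROC AUC of group B vs group A via the Mann-Whitney identity.

    AUC is the fraction of (a in A, b in B) sample pairs with value_b >
    value_a, ties counted one half.  A gene is called when its AUC is at or
    beyond either cutoff (complete or near-complete separation in either
    direction).
    """
    a, b = _group_arrays(m, group_a, group_b)
    na, nb = a.shape[1], b.shape[1]
    combined = np.concatenate([a, b], axis=1)
    ranks = stats.rankdata(combined, axis=1)
    r_b = ranks[:, na:].sum(axis=1)
    auc = (r_b - nb * (nb + 1) / 2.0) / (na * nb)
    idx = m.values.index
    called = (auc >= upper) | (auc <= lower)
    return AucResult(
        auc=pd.Series(auc, index=idx, name="auc"),
        called=pd.Series(called, index=idx, name="called"),
        lower=lower,
        upper=upper,
    )


# ---------------------------------------------------------------------------
# consensus and exclusivity


def consensus_de(
    method_calls: Mapping[str, set[str]] | Sequence[set[str]], min_methods: int = 2
) -> set[str]:
    """Genes called by at least ``min_methods`` of exactly three methods."""
    sets = list(method_calls.values()) if isinstance(method_calls, Mapping) else list(method_calls)
    if len(sets) != 3:
        raise ValueError(f"expected exactly 3 method call sets, got {len(sets)}")
    if not 1 <= min_methods <= 3:
        raise ValueError("min_methods must be in 1..3")
    votes: dict[str, int] = {}
    for s in sets:
        for g in s:
            votes[g] = votes.get(g, 0) + 1
    return {g for g, v in votes.items() if v >= min_methods}


def exclusive_de(
    all_comparisons: Mapping[str, set[str]],
    focal: str,
    exclude: Iterable[str] | None = None,
) -> set[str]:
    """Focal consensus set minus the union of the excluded comparisons' sets.

    ``exclude`` defaults to every non-focal comparison present.
    """
    if focal not in all_comparisons:
        raise KeyError(f"focal comparison {focal!r} not among {sorted(all_comparisons)}")
    if len(all_comparisons) < 2:
        raise ValueError("need at least 2 comparisons for an exclusivity filter")
    if exclude is None:
        exclude = [c for c in all_comparisons if c != focal]
    others: set[str] = set()
    for cid in exclude:
        if cid == focal:
            continue
        try:
            others |= all_comparisons[cid]
        except KeyError as exc:
            raise KeyError(f"excluded comparison {cid!r} not among computed sets") from exc
    return set(all_comparisons[focal]) - others


# ---------------------------------------------------------------------------
# per-comparison driver


def run_comparison(
    m: ExpressionMatrix,
    design: GroupDesign,
    comp_id: str,
    sam_target_fdr: float = 0.05,
    modt_alpha: float = 0.05,
    auc_lower: float = 0.1,
    auc_upper: float = 0.9,
    min_methods: int = 2,
    n_perm: int = 100,
    seed: int | None = 0,
) -> DECallSet:
    """Run the three callers and the consensus vote for one comparison."""
    ref, case = design.comparison(comp_id)
    samples_ref = design.samples_of(ref)
    samples_case = design.samples_of(case)

    sam = sam_statistic(m, samples_ref, samples_case)
    sam = sam_permutation_fdr(
        sam, m, samples_ref, samples_case,
        target_fdr=sam_target_fdr, n_perm=n_perm, seed=seed,
    )
    modt = moderated_t(m, samples_ref, samples_case, alpha=modt_alpha)
    auc = auc_roc(m, samples_ref, samples_case, lower=auc_lower, upper=auc_upper)

    calls = {
        "sam": sam.called_genes,
        "moderated_t": modt.called_genes,
        "auc": auc.called_genes,
    }
    consensus = consensus_de(calls, min_methods=min_methods)

    lfc = (
        m.values.loc[:, samples_case].mean(axis=1)
        - m.values.loc[:, samples_ref].mean(axis=1)
    ).rename("lfc")

    # flag direction-discordant consensus votes (counted, but surfaced in logs)
    up_sam = set(sam.d.index[(sam.d > 0) & sam.called])
    down_sam = set(sam.d.index[(sam.d < 0) & sam.called])
    up_t = set(modt.t.index[(modt.t > 0) & modt.called])
    down_t = set(modt.t.index[(modt.t < 0) & modt.called])
    discordant = (up_sam & down_t) | (down_sam & up_t)
    if discordant & consensus:
        logger.warning(
            "%s: %d consensus genes have discordant directions between methods",
            comp_id, len(discordant & consensus),
        )

    return DECallSet(
        comparison=comp_id,
        reference=ref,
        case=case,
        method_calls=calls,
        consensus=consensus,
        lfc=lfc,
        min_methods=min_methods,
    )


def run_all_comparisons(
    m: ExpressionMatrix,
    design: GroupDesign,
    seed: int | None = 0,
    **kwargs,
) -> dict[str, DECallSet]:
    """Run every comparison of the design; per-comparison seeds are derived."""
    results: dict[str, DECallSet] = {}
    for i, comp_id in enumerate(design.comparison_ids):
        comp_seed = None if seed is None else (seed + 1009 * i) % (2**31 - 1)
        results[comp_id] = run_comparison(m, design, comp_id, seed=comp_seed, **kwargs)
    return results
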