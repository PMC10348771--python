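"""Wilcoxon rank-sum differential expression with fold-change/percentage filters.

Genes are screened before testing: a gene is tested only if it is detected
in at least ``min_pct`` of cells in one of the groups and its absolute
log2 fold change is at least ``logfc_threshold`` (1 by default, i.e. a
two-fold change of de-logged means).  P-values come from a two-sided
Wilcoxon rank-sum test — exact enumeration over all C(n, n1) group
assignments when the smaller group has ≤ 8 cells, a tie-corrected normal
approximation with continuity correction otherwise — and are adjusted over
the full gene universe (Bonferroni by default, Benjamini–Hochberg
available).  Significance is adjusted p < 0.05.

Fold change follows the single-cell convention for log-normalized data:
``log2((mean(expm1(x1)) + 1) / (mean(expm1(x2)) + 1))``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Literal, Sequence

import numpy as np
import scipy.sparse as sp
from scipy import stats

from .tenx import CountMatrix

__all__ = ["DEGRecord", "rank_sum_test", "fold_change", "find_markers", "adjust_pvalues",
           "EXACT_MAX_N"]

logger = logging.getLogger(__name__)

EXACT_MAX_N = 8  # per-group size at or below which the exact test is used


@dataclass
class DEGRecord:
    gene: str
    log_fc: float
    pct_1: float
    pct_2: float
    p_value: float
    p_adjusted: float
    significant: bool


def rank_sum_test(values_1: Sequence[float], values_2: Sequence[float]) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact regime (min group size ≤ 8): the rank-sum of group 1 is compared
    against its full permutation distribution over all C(n1+n2, n1)
    assignments of the pooled (tie-averaged) ranks; the two-sided p-value
    is the fraction of assignments at least as far from the mean rank-sum
    as observed.  Larger groups use the tie-corrected normal approximation
    with continuity correction.
    """
    x = np.asarray(values_1, dtype=float)
    y = np.asarray(values_2, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("rank_sum_test: both groups must be nonempty")
    n1, n2 = x.size, y.size
    if min(n1, n2) <= EXACT_MAX_N:
        pooled = np.concatenate([x, y])
        ranks = stats.rankdata(pooled)
        w_obs = ranks[:n1].sum()
        mu = n1 * (n1 + n2 + 1) / 2.0
        d_obs = abs(w_obs - mu)
        n_extreme = 0
        n_total = 0
        for combo in combinations(range(n1 + n2), n1):
            w = ranks[list(combo)].sum()
            n_extreme += abs(w - mu) >= d_obs - 1e-12
            n_total += 1
        return n_extreme / n_total
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic",
                             use_continuity=True)
    return float(res.pvalue)


def fold_change(
    normalized: CountMatrix,
    group1: Sequence[str],
    group2: Sequence[str],
    gene: str,
) -> tuple[float, float, float]:
    """(log2 fold change, pct_1, pct_2) for one gene between two cell groups."""
    lfc, p1, p2 = _fold_change_all(normalized, group1, group2)
    gi = normalized.gene_index(gene)
    return float(lfc[gi]), float(p1[gi]), float(p2[gi])


def _group_columns(normalized: CountMatrix, group1, group2) -> tuple[np.ndarray, np.ndarray]:
    pos = {bc: j for j, bc in enumerate(normalized.barcodes)}
    missing = [bc for bc in list(group1) + list(group2) if bc not in pos]
    if missing:
        raise ValueError(f"{len(missing)} group barcodes not in matrix")
    c1 = np.array([pos[bc] for bc in group1], dtype=int)
    c2 = np.array([pos[bc] for bc in group2], dtype=int)
    if c1.size == 0 or c2.size == 0:
        raise ValueError("both groups must be nonempty")
    if set(c1) & set(c2):
        raise ValueError("groups must be disjoint")
    return c1, c2


def _fold_change_all(normalized: CountMatrix, group1, group2):
    c1, c2 = _group_columns(normalized, group1, group2)
    X = sp.csc_matrix(normalized.counts)
    X1, X2 = X[:, c1], X[:, c2]
    pct1 = np.asarray((X1 > 0).sum(axis=1)).ravel() / c1.size
    pct2 = np.asarray((X2 > 0).sum(axis=1)).ravel() / c2.size
    m1 = np.asarray(X1.expm1().sum(axis=1)).ravel() / c1.size
    m2 = np.asarray(X2.expm1().sum(axis=1)).ravel() / c2.size
    lfc = np.log2(m1 + 1.0) - np.log2(m2 + 1.0)
    return lfc, pct1, pct2


def adjust_pvalues(
    p_list: Sequence[float],
    method: Literal["bonferroni", "bh"] = "bonferroni",
    m: int | None = None,
) -> list[float]:
    """Multiple-testing adjustment over ``m`` tests (default: len(p_list)).

    Bonferroni: min(1, p·m).  BH: step-up with monotonicity enforcement,
    ``p·m/rank`` cummin-ed from the largest p.
    """
    p = np.asarray(p_list, dtype=float)
    if p.size and (p.min() < 0 or p.max() > 1):
        raise ValueError("p-values must lie in [0, 1]")
    m = int(m) if m is not None else p.size
    if m < p.size:
        raise ValueError("m must be at least the number of p-values")
    if method == "bonferroni":
        return list(np.minimum(1.0, p * m))
    if method == "bh":
        order = np.argsort(p, kind="stable")
        ranked = p[order] * m / np.arange(1, p.size + 1)
        adj = np.minimum.accumulate(ranked[::-1])[::-1]
        out = np.empty_like(p)
        out[order] = np.minimum(1.0, adj)
        return list(out)
    raise ValueError(f"unknown adjustment method {method!r}")


def find_markers(
    normalized: CountMatrix,
    group1: Sequence[str],
    group2: Sequence[str],
    logfc_threshold: float = 1.0,
    min_pct: float = 0.2,
    alpha: float = 0.05,
    adjust: Literal["bonferroni", "bh"] = "bonferroni",
    adjust_over: Literal["all_genes", "tested"] = "all_genes",
) -> list[DEGRecord]:
    """Differential expression between two cell groups.

    A gene is tested only if ``max(pct_1, pct_2) ≥ min_pct`` and
    ``|log_fc| ≥ logfc_threshold``; p-values come from
    :func:`rank_sum_test` and are adjusted over the number of genes in the
    matrix (``adjust_over="all_genes"``, the usual tool convention) or over
    the tested set.  Records are sorted by p-value, then |log_fc|
    descending, then gene id.  Returns an empty list (logged) if no gene
    passes the filters.
    """
    lfc, pct1, pct2 = _fold_change_all(normalized, group1, group2)
    passing = np.flatnonzero(
        (np.maximum(pct1, pct2) >= min_pct) & (np.abs(lfc) >= logfc_threshold)
    )
    if passing.size == 0:
        logger.info("find_markers: no genes pass the pct/log_fc filters")
        return []
    c1, c2 = _group_columns(normalized, group1, group2)
    X = sp.csr_matrix(normalized.counts)
    pvals = []
    for gi in passing:
        row = np.asarray(X[gi, :].todense()).ravel()
        pvals.append(rank_sum_test(row[c1], row[c2]))
    m = normalized.n_genes if adjust_over == "all_genes" else passing.size
    padj = adjust_pvalues(pvals, method=adjust, m=m)
    records = [
        DEGRecord(
            gene=normalized.genes[gi],
            log_fc=float(lfc[gi]),
            pct_1=float(pct1[gi]),
            pct_2=float(pct2[gi]),
            p_value=float(p),
            p_adjusted=float(pa),
            significant=bool(pa < alpha),
        )
        for gi, p, pa in zip(passing, pvals, padj)
    ]
    records.sort(key=lambda r: (r.p_value, -abs(r.log_fc), r.gene))
    return records
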