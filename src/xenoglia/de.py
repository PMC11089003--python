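"""Normalization and Wilcoxon rank-sum marker detection.

Counts are library-size normalized to counts-per-10k and log1p transformed
(the transform is recorded in the matrix provenance tag). Marker genes
between two cell groups are prefiltered on detection fraction (default 1% in
either group) and mean log fold change (default 0.1 on the natural-log
scale), then tested with a two-sided Wilcoxon rank-sum test; P values are
Bonferroni-corrected with the total number of genes in the matrix as the
multiplier.

The rank-sum test itself is implemented here in two modes: an exact mode
that enumerates all group assignments (used automatically for small
samples), and a normal approximation with midranks, tie-corrected variance
and continuity correction.
"""

from __future__ import annotations

import warnings
from itertools import combinations
from math import comb, log

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import norm, rankdata

from .containers import CountMatrix, NormalizedMatrix

EXACT_MAX_N = 12  # total sample size up to which exact enumeration is used


def normalize_log(counts: CountMatrix, scale: float = 10_000) -> NormalizedMatrix:
    """log1p counts-per-``scale`` normalization.

    value = log1p(count / cell_total * scale). Zero counts stay exactly
    zero. All-zero cells are rejected; filter them first.
    """
    m = counts.matrix.tocsc().astype(float)
    totals = np.asarray(m.sum(axis=0)).ravel()
    if (totals == 0).any():
        raise ValueError(
            "matrix contains all-zero cells; run qc.filter_cells before normalizing"
        )
    m = m.multiply(scale / totals[None, :]).tocsr()
    m.data = np.log1p(m.data)
    return NormalizedMatrix(
        matrix=m,
        genes=counts.genes,
        barcodes=counts.barcodes,
        transform={"scheme": "log1p_cp", "scale": scale},
    )


def log_fold_change(norm: NormalizedMatrix, cells_a, cells_b) -> pd.Series:
    """Per-gene log2 fold change of mean de-logged expression, pseudocount 1.

    log2FC = log2((mu_a + 1) / (mu_b + 1)) where mu is the group mean of
    expm1 of the normalized values. Swapping the groups negates the result
    exactly.
    """
    ia, ib = _group_indices(norm, cells_a, cells_b)
    m = norm.matrix.tocsc()
    mu = []
    for idx in (ia, ib):
        sub = m[:, idx].copy()
        sub.data = np.expm1(sub.data)
        mu.append(np.asarray(sub.sum(axis=1)).ravel() / len(idx))
    return pd.Series(np.log2(mu[0] + 1.0) - np.log2(mu[1] + 1.0), index=norm.genes)


def _group_indices(norm, cells_a, cells_b):
    ia = norm.barcodes.get_indexer(pd.Index(cells_a))
    ib = norm.barcodes.get_indexer(pd.Index(cells_b))
    if (ia < 0).any() or (ib < 0).any():
        raise KeyError("unknown barcode in group definition")
    if len(ia) == 0 or len(ib) == 0:
        raise ValueError("both cell groups must be nonempty")
    if len(np.intersect1d(ia, ib)):
        raise ValueError("cell groups overlap")
    return ia, ib


def _exact_ranksum_p(values_a, values_b) -> float:
    """Two-sided rank-sum p by enumeration of all group assignments.

    Works with ties (it is a permutation test on the midrank statistic).
    """
    pooled = np.concatenate([values_a, values_b])
    n_a = len(values_a)
    ranks = rankdata(pooled)
    w_obs = ranks[:n_a].sum()
    mu = n_a * (len(pooled) + 1) / 2.0
    n_extreme = 0
    n_total = comb(len(pooled), n_a)
    for idx in combinations(range(len(pooled)), n_a):
        w = ranks[list(idx)].sum()
        if abs(w - mu) >= abs(w_obs - mu) - 1e-12:
            n_extreme += 1
    return n_extreme / n_total


def _normal_ranksum_p(values_a, values_b) -> float:
    """Two-sided rank-sum p: normal approximation, tie-corrected variance,
    continuity correction."""
    pooled = np.concatenate([values_a, values_b])
    n_a, n_b = len(values_a), len(values_b)
    n = n_a + n_b
    ranks = rankdata(pooled)
    w = ranks[:n_a].sum()
    mu = n_a * (n + 1) / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum()
    var = n_a * n_b / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:  # everything tied
        return 1.0
    z = max(abs(w - mu) - 0.5, 0.0) / np.sqrt(var)
    return min(1.0, 2.0 * norm.sf(z))


def wilcoxon_test(values_a, values_b, mode: str = "auto") -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    ``mode`` is ``"exact"`` (full enumeration, feasible for
    n_a + n_b <= 12), ``"normal"`` (midrank normal approximation with tie
    correction and continuity correction) or ``"auto"`` (exact when
    feasible, else normal — the convention of standard statistical
    software). Samples entirely tied across both groups give p = 1.
    """
    values_a = np.asarray(values_a, dtype=float)
    values_b = np.asarray(values_b, dtype=float)
    if len(values_a) == 0 or len(values_b) == 0:
        raise ValueError("both samples must be nonempty")
    if np.ptp(np.concatenate([values_a, values_b])) == 0:
        return 1.0
    if mode == "auto":
        mode = "exact" if len(values_a) + len(values_b) <= EXACT_MAX_N else "normal"
    if mode == "exact":
        return _exact_ranksum_p(values_a, values_b)
    if mode == "normal":
        return _normal_ranksum_p(values_a, values_b)
    raise ValueError("mode must be 'auto', 'exact' or 'normal'")


def _ranksum_p_matrix(dense_a: np.ndarray, dense_b: np.ndarray) -> np.ndarray:
    """Row-wise normal-approximation rank-sum p for genes x cells blocks."""
    n_a, n_b = dense_a.shape[1], dense_b.shape[1]
    n = n_a + n_b
    pooled = np.hstack([dense_a, dense_b])
    ranks = rankdata(pooled, axis=1)
    w = ranks[:, :n_a].sum(axis=1)
    mu = n_a * (n + 1) / 2.0
    # tie correction per gene
    srt = np.sort(pooled, axis=1)
    tie_term = np.zeros(pooled.shape[0])
    for g in range(pooled.shape[0]):
        _, cnt = np.unique(srt[g], return_counts=True)
        tie_term[g] = (cnt**3 - cnt).sum()
    var = n_a * n_b / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    p = np.ones(pooled.shape[0])
    ok = var > 0
    z = np.maximum(np.abs(w[ok] - mu) - 0.5, 0.0) / np.sqrt(var[ok])
    p[ok] = np.minimum(1.0, 2.0 * norm.sf(z))
    return p


def find_markers(
    norm: NormalizedMatrix,
    cells_a,
    cells_b,
    min_pct: float = 0.01,
    logfc_threshold: float = 0.1,
    bonferroni_multiplier: int | None = None,
    group_a: str = "A",
    group_b: str = "B",
) -> pd.DataFrame:
    """Differential expression between two cell groups.

    A gene is tested only when it is detected in at least ``min_pct`` of
    cells in either group and its mean fold change is at least
    ``logfc_threshold`` on the natural-log scale (equivalently
    ``|log2FC| >= logfc_threshold / ln 2``). P values come from the
    rank-sum normal approximation and are Bonferroni-adjusted with the
    total number of genes in the matrix by default.
    """
    ia, ib = _group_indices(norm, cells_a, cells_b)
    multiplier = norm.matrix.shape[0] if bonferroni_multiplier is None else bonferroni_multiplier

    m = norm.matrix.tocsc()
    sub_a = m[:, ia]
    sub_b = m[:, ib]
    pct_a = np.asarray((sub_a > 0).sum(axis=1)).ravel() / len(ia)
    pct_b = np.asarray((sub_b > 0).sum(axis=1)).ravel() / len(ib)
    lfc = log_fold_change(norm, cells_a, cells_b).to_numpy()

    log2_cut = logfc_threshold / log(2.0)
    tested = (np.maximum(pct_a, pct_b) >= min_pct) & (np.abs(lfc) >= log2_cut)
    idx = np.flatnonzero(tested)
    if idx.size == 0:
        return pd.DataFrame(
            columns=["gene", "log2FC", "pct_a", "pct_b", "p", "p_adj", "group_a", "group_b"]
        )
    p = _ranksum_p_matrix(sub_a[idx].toarray(), sub_b[idx].toarray())
    out = pd.DataFrame(
        {
            "gene": norm.genes[idx],
            "log2FC": lfc[idx],
            "pct_a": pct_a[idx],
            "pct_b": pct_b[idx],
            "p": p,
            "p_adj": np.minimum(1.0, p * multiplier),
            "group_a": group_a,
            "group_b": group_b,
        }
    )
    return out.sort_values("p", kind="stable").reset_index(drop=True)


def find_all_markers(norm: NormalizedMatrix, labels, **kwargs) -> dict[str, pd.DataFrame]:
    """One-vs-rest markers for every cluster label.

    ``labels`` is a per-cell series aligned to the matrix barcodes. Each
    cluster's table is exactly ``find_markers(cluster, complement)``.
    """
    labels = pd.Series(np.asarray(labels), index=norm.barcodes)
    uniq = labels.unique()
    if len(uniq) < 2:
        raise ValueError("need at least 2 clusters")
    tables = {}
    for cl in uniq:
        in_cl = norm.barcodes[labels == cl]
        rest = norm.barcodes[labels != cl]
        if len(in_cl) == 1:
            warnings.warn(f"cluster {cl!r} is a singleton")
        tables[cl] = find_markers(
            norm, in_cl, rest, group_a=str(cl), group_b="rest", **kwargs
        )
    return tables
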