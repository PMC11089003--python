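"""Droplet quality control and hashtag demultiplexing.

The filtering rules mirror a standard droplet pipeline: hard per-cell cutoffs
(minimum reads, minimum detected genes, maximum mitochondrial fraction)
followed by a per-library outlier rule that removes cells whose total counts
or detected genes lie more than ``sd_k`` standard deviations from the library
mean, then a gene filter dropping genes detected in fewer than ``min_cells``
cells. Demultiplexing thresholds each hashtag independently by 2-means
clustering of log1p counts and classifies droplets by how many hashes they
are positive for.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .containers import CountMatrix, HashMatrix


def compute_cell_qc(counts: CountMatrix, mito_genes) -> pd.DataFrame:
    """Per-droplet QC records: totals, detected genes, mitochondrial fraction.

    ``mito_genes`` may be a collection of gene names or a prefix string
    (e.g. ``"MT-"``). Genes not present in the matrix are ignored with a
    warning. A droplet with zero counts gets mito_fraction 0 by convention.
    """
    if isinstance(mito_genes, str):
        mito_mask = counts.genes.str.startswith(mito_genes)
    else:
        mito_genes = pd.Index(mito_genes)
        missing = mito_genes.difference(counts.genes)
        if len(missing):
            warnings.warn(f"{len(missing)} mitochondrial genes absent from matrix")
        mito_mask = counts.genes.isin(mito_genes)

    m = counts.matrix.tocsc()
    total = np.asarray(m.sum(axis=0)).ravel()
    n_genes = np.asarray((m > 0).sum(axis=0)).ravel()
    mito = np.asarray(m[np.flatnonzero(mito_mask)].sum(axis=0)).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(total > 0, mito / np.maximum(total, 1), 0.0)
    rec = pd.DataFrame(
        {
            "barcode": counts.barcodes,
            "library_id": counts.library_ids.to_numpy()
            if counts.library_ids is not None
            else "lib_0",
            "total_counts": total,
            "n_genes": n_genes,
            "mito_fraction": mito_frac,
        }
    )
    return rec


def filter_cells(
    records: pd.DataFrame,
    min_counts: float = 1000,
    min_genes: float = 100,
    max_mito: float = 0.15,
    sd_k: float = 3.0,
    sd_side: str = "both",
) -> tuple[pd.Index, pd.DataFrame]:
    """Two-stage cell filter.

    Stage 1 removes cells with fewer than ``min_counts`` reads OR fewer than
    ``min_genes`` detected genes OR more than ``max_mito`` mitochondrial
    fraction (boundaries strict: exactly 1000 reads or exactly 15% mito is
    kept). Stage 2, per library on the survivors, removes cells whose total
    counts or detected genes deviate from the library mean by more than
    ``sd_k`` sample standard deviations; ``sd_side`` is ``"both"`` (default)
    or ``"upper"``. Libraries with fewer than 3 survivors skip stage 2.

    Returns (kept barcodes, removal ledger with the first triggered reason
    per removed cell).
    """
    if sd_side not in ("both", "upper"):
        raise ValueError("sd_side must be 'both' or 'upper'")
    rec = records.reset_index(drop=True)
    reasons = []

    low_counts = rec["total_counts"] < min_counts
    low_genes = rec["n_genes"] < min_genes
    high_mito = rec["mito_fraction"] > max_mito
    stage1 = low_counts | low_genes | high_mito
    for i in np.flatnonzero(stage1):
        if low_counts.iat[i]:
            reason = "low_counts"
        elif low_genes.iat[i]:
            reason = "low_genes"
        else:
            reason = "high_mito"
        reasons.append((rec["barcode"].iat[i], reason))

    surv = rec[~stage1]
    removed2 = pd.Series(False, index=surv.index)
    for lib, grp in surv.groupby("library_id", sort=False):
        if len(grp) < 3:
            warnings.warn(
                f"library {lib!r}: fewer than 3 surviving cells, s.d. rule skipped"
            )
            continue
        for col, reason in (("total_counts", "outlier_counts"), ("n_genes", "outlier_genes")):
            x = grp[col].to_numpy(dtype=float)
            mu, sd = x.mean(), x.std(ddof=1)
            dev = (x - mu) if sd_side == "upper" else np.abs(x - mu)
            out = dev > sd_k * sd
            for i in grp.index[out]:
                if not removed2.loc[i]:
                    removed2.loc[i] = True
                    reasons.append((rec["barcode"].iat[i], reason))

    kept = surv.index[~removed2.loc[surv.index]]
    ledger = pd.DataFrame(reasons, columns=["barcode", "reason"])
    return pd.Index(rec["barcode"].iloc[kept]), ledger


def filter_genes(counts: CountMatrix, min_cells: int = 3) -> pd.Index:
    """Genes detected (nonzero) in at least ``min_cells`` cells."""
    n_cells = np.asarray((counts.matrix > 0).sum(axis=1)).ravel()
    return counts.genes[n_cells >= min_cells]


def _two_means_1d(x: np.ndarray, max_iter: int = 100) -> tuple[float, float] | None:
    """Deterministic Lloyd 2-means on a 1-D sample, seeded at min/max.

    Returns the two cluster centers, or None when the split is degenerate
    (all values equal or one cluster empties).
    """
    lo, hi = float(x.min()), float(x.max())
    if lo == hi:
        return None
    c = np.array([lo, hi])
    for _ in range(max_iter):
        assign = np.abs(x[:, None] - c[None, :]).argmin(axis=1)
        if assign.all() or not assign.any():
            return None
        new = np.array([x[assign == 0].mean(), x[assign == 1].mean()])
        if np.allclose(new, c):
            break
        c = new
    return float(c[0]), float(c[1])


def hash_thresholds(hash_counts: HashMatrix) -> pd.Series:
    """Per-hash positivity threshold on the log1p scale.

    Midpoint of the two centers from 2-means clustering of log1p counts;
    falls back to the 99th percentile of the lower half when clustering
    degenerates. An all-zero hash gets an infinite threshold (never
    positive).
    """
    thresholds = {}
    for i, h in enumerate(hash_counts.hashes):
        x = np.log1p(hash_counts.matrix[i].astype(float))
        if not x.any():
            warnings.warn(f"hash {h!r} has all-zero counts; never positive")
            thresholds[h] = np.inf
            continue
        centers = _two_means_1d(x)
        if centers is None:
            lower = np.sort(x)[: max(1, len(x) // 2)]
            thresholds[h] = float(np.percentile(lower, 99))
        else:
            thresholds[h] = 0.5 * (centers[0] + centers[1])
    return pd.Series(thresholds, name="threshold")


def demultiplex_hashes(hash_counts: HashMatrix) -> pd.DataFrame:
    """Classify droplets as singlet / doublet / negative from hashtag counts.

    A droplet is positive for a hash when log1p(count) exceeds that hash's
    threshold; zero positive hashes is a negative, one a singlet (assigned to
    that hash's sample), two or more a doublet.
    """
    if len(hash_counts.hashes) < 1 or len(hash_counts.barcodes) < 2:
        raise ValueError("need at least 1 hash and 2 droplets to demultiplex")
    t = hash_thresholds(hash_counts).to_numpy()
    logc = np.log1p(hash_counts.matrix.astype(float))
    positive = logc > t[:, None]
    n_pos = positive.sum(axis=0)
    call = np.where(n_pos == 0, "negative", np.where(n_pos == 1, "singlet", "doublet"))
    hash_arr = hash_counts.hashes.to_numpy()
    assigned = [
        hash_arr[positive[:, j]][0] if n_pos[j] == 1 else None
        for j in range(positive.shape[1])
    ]
    pos_sets = [";".join(hash_arr[positive[:, j]]) for j in range(positive.shape[1])]
    return pd.DataFrame(
        {
            "barcode": hash_counts.barcodes,
            "call": call,
            "assigned_sample": assigned,
            "positive_hashes": pos_sets,
        }
    )
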