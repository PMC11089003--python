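"""Gene-set module scoring with expression-bin-matched control genes.

A module score for a gene set is the per-cell mean expression of the set
minus the mean of a pooled control set: for every set gene, ``n_ctrl``
control genes are sampled from the same average-expression bin, so the score
is centred against genes of comparable abundance. Scores are shift-invariant
(adding a constant to the whole matrix cancels out).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import NormalizedMatrix


@dataclass
class GeneSet:
    name: str
    genes: tuple

    def __post_init__(self):
        if len(self.genes) == 0:
            raise ValueError("gene set must be nonempty")


def _expression_bins(norm: NormalizedMatrix, n_bins: int) -> np.ndarray:
    """Equal-frequency bins of genes by average expression across cells."""
    avg = np.asarray(norm.matrix.mean(axis=1)).ravel()
    order = np.argsort(avg, kind="stable")
    bins = np.empty(len(avg), dtype=int)
    for b, chunk in enumerate(np.array_split(order, n_bins)):
        bins[chunk] = b
    return bins


def module_score(
    norm: NormalizedMatrix,
    gene_set: GeneSet,
    n_bins: int = 25,
    n_ctrl: int = 100,
    seed: int = 0,
) -> pd.Series:
    """Per-cell module score for one gene set.

    Genes are binned into ``n_bins`` equal-frequency bins of average
    expression; each set gene contributes ``n_ctrl`` control genes sampled
    with replacement from its bin. Score = mean over set genes minus mean
    over the pooled control draws. Sampling is seeded, so identical inputs
    give identical scores. Set genes absent from the matrix are dropped with
    a warning; an empty set after dropping is an error.
    """
    if norm.matrix.shape[0] < n_bins:
        raise ValueError("need at least n_bins genes in the matrix")
    present = pd.Index(gene_set.genes).intersection(norm.genes)
    n_missing = len(gene_set.genes) - len(present)
    if n_missing:
        warnings.warn(f"{n_missing} genes of set {gene_set.name!r} absent from matrix")
    if len(present) == 0:
        raise ValueError(f"gene set {gene_set.name!r} has no genes in the matrix")

    rng = np.random.default_rng(seed)
    bins = _expression_bins(norm, n_bins)
    set_idx = norm.genes.get_indexer(present)

    ctrl_idx = []
    for gi in set_idx:
        pool = np.flatnonzero(bins == bins[gi])
        ctrl_idx.append(rng.choice(pool, size=n_ctrl, replace=True))
    ctrl_idx = np.concatenate(ctrl_idx)

    dense = norm.matrix.tocsr()
    set_mean = np.asarray(dense[set_idx].mean(axis=0)).ravel()
    ctrl_mean = np.asarray(dense[ctrl_idx].mean(axis=0)).ravel()
    return pd.Series(
        set_mean - ctrl_mean,
        index=norm.barcodes,
        name=gene_set.name,
    )


def score_state_panel(
    norm: NormalizedMatrix,
    panels: list[GeneSet],
    n_bins: int = 25,
    n_ctrl: int = 100,
    seed: int = 0,
    assign: bool = False,
):
    """Score a list of state panels; optionally hard-label cells by argmax.

    Returns a cells x panels score frame, or ``(scores, labels)`` when
    ``assign`` is true. Argmax ties break by panel order.
    """
    if len(panels) == 0:
        raise ValueError("need at least one panel")
    cols = {
        p.name: module_score(norm, p, n_bins=n_bins, n_ctrl=n_ctrl, seed=seed + i)
        for i, p in enumerate(panels)
    }
    scores = pd.DataFrame(cols)
    if not assign:
        return scores
    labels = scores.columns[np.argmax(scores.to_numpy(), axis=1)]
    return scores, pd.Series(labels, index=scores.index, name="state")


def read_gene_sets(path) -> list[GeneSet]:
    """Read panels from a GMT file or a two-column (set, gene) TSV."""
    from pathlib import Path

    path = Path(path)
    sets: dict[str, list] = {}
    if path.suffix.lower() == ".gmt":
        for line in path.read_text().splitlines():
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                sets[parts[0]] = parts[2:]
    else:
        df = pd.read_csv(path, sep="\t", header=None, names=["set", "gene"])
        for name, grp in df.groupby("set", sort=False):
            sets[name] = grp["gene"].tolist()
    return [GeneSet(name, tuple(genes)) for name, genes in sets.items()]
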