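"""Per-mouse cell-state composition statistics.

Cell-state proportions are computed per sample (mouse) and compared between
groups with an unpaired two-tailed Welch t-test (two groups) or one-way
ANOVA with Tukey HSD post hoc (three or more). Embedding density is a
per-group Gaussian kernel density in which every sample contributes equal
total weight regardless of how many cells it has; pseudotime distributions
are per-sample proportions over equal-width bins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class GroupTestResult:
    state: str
    statistic: float
    df: float
    p: float
    test: str
    group_means: dict = field(default_factory=dict)
    pairwise_adjusted_p: dict | None = None


def proportions(labels, samples, groups) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample state proportions.

    ``labels`` and ``samples`` are aligned per-cell vectors; ``groups``
    maps each sample to its experimental group. Returns (table, meta):
    rows of the table are samples, columns states, every row sums to 1;
    meta carries the group label and cell count per sample.
    """
    labels = pd.Series(np.asarray(labels, dtype=object), name="state")
    samples = pd.Series(np.asarray(samples, dtype=object), name="sample")
    if len(labels) != len(samples):
        raise ValueError("labels and samples must align per cell")
    groups = pd.Series(groups)
    tally = pd.crosstab(samples, labels)
    n_cells = tally.sum(axis=1)
    empty = n_cells == 0
    if empty.any():
        warnings.warn(f"{int(empty.sum())} samples with zero cells excluded")
        tally = tally[~empty]
        n_cells = n_cells[~empty]
    missing = pd.Index(tally.index).difference(groups.index)
    if len(missing):
        raise ValueError(f"samples without a group: {list(missing)}")
    table = tally.div(n_cells, axis=0)
    meta = pd.DataFrame({"group": groups.loc[table.index], "n_cells": n_cells})
    return table, meta


def _arcsine_sqrt(x):
    return np.arcsin(np.sqrt(np.clip(x, 0.0, 1.0)))


def welch_test(
    table: pd.DataFrame,
    meta: pd.DataFrame,
    state: str,
    group_a: str,
    group_b: str,
    transform: str | None = None,
) -> GroupTestResult:
    """Welch two-sample t-test on per-mouse proportions of one state.

    Satterthwaite degrees of freedom, two-sided p. ``transform`` may be
    ``"arcsine_sqrt"`` to variance-stabilize the proportions first. Two
    groups with zero variance and equal means give t = 0, p = 1.
    """
    xa = table.loc[meta["group"] == group_a, state].to_numpy(dtype=float)
    xb = table.loc[meta["group"] == group_b, state].to_numpy(dtype=float)
    if len(xa) < 2 or len(xb) < 2:
        raise ValueError("need at least 2 samples per group")
    if transform == "arcsine_sqrt":
        xa, xb = _arcsine_sqrt(xa), _arcsine_sqrt(xb)
    va, vb = xa.var(ddof=1), xb.var(ddof=1)
    na, nb = len(xa), len(xb)
    se2 = va / na + vb / nb
    if se2 == 0:
        t_stat, df, p = 0.0, float(na + nb - 2), 1.0
    else:
        t_stat = (xa.mean() - xb.mean()) / np.sqrt(se2)
        df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
        p = 2.0 * stats.t.sf(abs(t_stat), df)
    return GroupTestResult(
        state=state,
        statistic=float(t_stat),
        df=float(df),
        p=float(p),
        test="welch_t",
        group_means={group_a: float(xa.mean()), group_b: float(xb.mean())},
    )


def anova_tukey(
    table: pd.DataFrame,
    meta: pd.DataFrame,
    state: str,
    groups: list[str],
    transform: str | None = None,
) -> GroupTestResult:
    """One-way ANOVA across groups with Tukey HSD pairwise adjusted p.

    With exactly two groups this defers to :func:`welch_test` with a
    warning. Groups of a single sample are an error.
    """
    if len(groups) == 2:
        warnings.warn("two groups: deferring to Welch t-test")
        return welch_test(table, meta, state, groups[0], groups[1], transform=transform)
    xs = []
    for g in groups:
        x = table.loc[meta["group"] == g, state].to_numpy(dtype=float)
        if len(x) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 samples")
        if transform == "arcsine_sqrt":
            x = _arcsine_sqrt(x)
        xs.append(x)
    if all(x.var(ddof=1) == 0 for x in xs) and len({x.mean() for x in xs}) == 1:
        f_stat, p = 0.0, 1.0
        pairwise = {(a, b): 1.0 for i, a in enumerate(groups) for b in groups[i + 1 :]}
    else:
        f_stat, p = stats.f_oneway(*xs)
        hsd = stats.tukey_hsd(*xs)
        pairwise = {
            (groups[i], groups[j]): float(hsd.pvalue[i, j])
            for i in range(len(groups))
            for j in range(i + 1, len(groups))
        }
    n = sum(len(x) for x in xs)
    return GroupTestResult(
        state=state,
        statistic=float(f_stat),
        df=float(len(groups) - 1),
        p=float(p),
        test="anova_f",
        group_means={g: float(x.mean()) for g, x in zip(groups, xs)},
        pairwise_adjusted_p=pairwise,
    )


def embedding_density(
    embedding: np.ndarray,
    samples,
    groups,
    grid_size: int = 100,
    pad_frac: float = 0.25,
) -> dict[str, dict]:
    """Per-group 2-D kernel density with sample-size normalization.

    Every sample contributes total weight 1 / (number of samples in its
    group), i.e. per-cell weight 1 / (n_samples_in_group * n_cells_in_sample),
    so a tiny and a huge mouse carry the same mass. Bandwidth is Scott's
    rule per group. Returns, per group, the density grid, its axes and the
    grid cell area; each grid integrates to ~1 over the padded bounding box.
    """
    embedding = np.asarray(embedding, dtype=float)
    if not np.isfinite(embedding).all():
        raise ValueError("embedding coordinates must be finite")
    samples = pd.Series(np.asarray(samples, dtype=object))
    groups = pd.Series(groups)

    out = {}
    for g in groups.unique():
        g_samples = groups.index[groups == g]
        in_group = samples.isin(g_samples).to_numpy()
        present = [s for s in g_samples if (samples == s).any()]
        if not present:
            continue
        w = np.zeros(in_group.sum())
        sub_samples = samples[in_group].to_numpy()
        for s in present:
            mask = sub_samples == s
            w[mask] = 1.0 / (len(present) * mask.sum())
        kde = stats.gaussian_kde(embedding[in_group].T, weights=w)
        # grid bounds: data extent padded by the larger of a fixed fraction
        # of the span and 4 kernel bandwidths, so the grid captures ~all mass
        sub = embedding[in_group]
        span = sub.max(axis=0) - sub.min(axis=0)
        bw = np.sqrt(np.diag(kde.covariance))
        pad = np.maximum(pad_frac * span, 4.0 * bw)
        lo, hi = sub.min(axis=0) - pad, sub.max(axis=0) + pad
        xg = np.linspace(lo[0], hi[0], grid_size)
        yg = np.linspace(lo[1], hi[1], grid_size)
        xx, yy = np.meshgrid(xg, yg, indexing="ij")
        dens = kde(np.vstack([xx.ravel(), yy.ravel()])).reshape(grid_size, grid_size)
        out[g] = {
            "density": dens,
            "x": xg,
            "y": yg,
            "cell_area": (xg[1] - xg[0]) * (yg[1] - yg[0]),
        }
    return out


def bin_pseudotime(
    pseudotime,
    samples,
    groups,
    n_bins: int = 20,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Per-sample pseudotime distributions over equal-width bins.

    Bins are equal width over the observed pseudotime range. Returns
    (per-sample bin proportions, per-group mean curves, per-bin Welch tests
    between each pair of groups). Per-sample proportions sum to 1; empty
    bins are 0.
    """
    pt = np.asarray(pseudotime, dtype=float)
    if not np.isfinite(pt).all():
        raise ValueError("pseudotime values must be finite")
    samples = pd.Series(np.asarray(samples, dtype=object))
    groups = pd.Series(groups)
    edges = np.linspace(pt.min(), pt.max(), n_bins + 1)
    binned = np.clip(np.searchsorted(edges, pt, side="right") - 1, 0, n_bins - 1)

    per_sample = (
        pd.crosstab(samples, pd.Series(binned, name="bin"))
        .reindex(columns=range(n_bins), fill_value=0)
        .pipe(lambda d: d.div(d.sum(axis=1), axis=0))
    )
    meta = pd.DataFrame(
        {"group": groups.loc[per_sample.index], "n_cells": samples.value_counts()}
    )
    group_curves = per_sample.groupby(meta["group"]).mean()

    tests: dict = {}
    uniq = list(group_curves.index)
    for i, a in enumerate(uniq):
        for b in uniq[i + 1 :]:
            if (meta["group"] == a).sum() < 2 or (meta["group"] == b).sum() < 2:
                continue
            tests[(a, b)] = [
                welch_test(per_sample, meta, bin_idx, a, b)
                for bin_idx in range(n_bins)
            ]
    return per_sample, group_curves, tests
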