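"""Modified Sholl analysis of marker intensity around amyloid plaques.

Plaques are detected in a dedicated staining channel by thresholding and
connected components. Around every plaque center, marker intensity is
averaged over concentric annuli (default 24 annuli of width 10/3 um,
covering 0-80 um); pixels are assigned to their nearest plaque center only,
so overlapping neighborhoods are never double counted. Channel intensities
are z-scored across the whole profile table for comparability, smoothed
with LOESS for display, and the near (inner three annuli, 0-10 um) versus
distant (outer three annuli, 70-80 um) means are compared with a one-tailed
unpaired t-test in a user-declared direction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_N_ANNULI = 24
DEFAULT_ANNULUS_WIDTH_UM = 10.0 / 3.0


@dataclass
class NearFarResult:
    channel: str
    alternative: str
    near_means: np.ndarray
    far_means: np.ndarray
    t: float
    df: float
    p: float


def detect_plaques(
    plaque_channel: np.ndarray,
    pixel_size_um: float,
    threshold="otsu",
    min_area_um2: float = 10.0,
) -> pd.DataFrame:
    """Detect plaques by thresholding and 8-connected components.

    ``threshold`` is ``"otsu"`` or an absolute intensity value. Components
    below ``min_area_um2`` are dropped. Returns one row per plaque with a
    sub-pixel centroid (intensity-unweighted) and area in um^2; a blank
    image yields an empty table.
    """
    from skimage.filters import threshold_otsu
    from skimage.measure import label, regionprops

    img = np.asarray(plaque_channel, dtype=float)
    if img.size == 0:
        raise ValueError("empty plaque channel")
    if threshold == "otsu":
        if np.ptp(img) == 0:
            return pd.DataFrame(columns=["id", "row_px", "col_px", "area_um2"])
        thr = threshold_otsu(img)
    else:
        thr = float(threshold)
    mask = img > thr
    labeled = label(mask, connectivity=2)
    rows = []
    for k, prop in enumerate(regionprops(labeled)):
        area = prop.area * pixel_size_um**2
        if area < min_area_um2:
            continue
        rows.append((len(rows), prop.centroid[0], prop.centroid[1], area))
    return pd.DataFrame(rows, columns=["id", "row_px", "col_px", "area_um2"])


def annulus_means(
    channels: dict[str, np.ndarray],
    centers: np.ndarray,
    pixel_size_um: float,
    n_annuli: int = DEFAULT_N_ANNULI,
    annulus_width_um: float = DEFAULT_ANNULUS_WIDTH_UM,
    exclude_channels: tuple = (),
) -> pd.DataFrame:
    """Mean intensity per plaque, annulus and channel.

    ``centers`` is an (n_plaques, 2) array of (row, col) pixel coordinates.
    Each pixel is assigned to its NEAREST center; its annulus index is
    ``floor(d / width)`` of the center-of-pixel distance d in um, for
    d < n_annuli * width. Annuli that fall outside the image simply have
    fewer (possibly zero) pixels; no padding is applied. Returns rows
    (plaque_id, annulus_index, inner_radius_um, outer_radius_um, channel,
    mean_intensity, n_pixels) with NaN means where n_pixels is 0.
    """
    centers = np.atleast_2d(np.asarray(centers, dtype=float))
    if centers.shape[0] == 0:
        raise ValueError("need at least one plaque center")
    names = [n for n in channels if n not in exclude_channels]
    shape = channels[names[0]].shape
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    d2 = (rr[..., None] - centers[:, 0]) ** 2 + (cc[..., None] - centers[:, 1]) ** 2
    nearest = d2.argmin(axis=-1)
    dist_um = np.sqrt(d2.min(axis=-1)) * pixel_size_um
    annulus = np.floor(dist_um / annulus_width_um).astype(int)
    in_range = annulus < n_annuli

    # bin identifier combining plaque and annulus for one-pass bincount
    bin_id = np.where(in_range, nearest * n_annuli + annulus, -1).ravel()
    valid = bin_id >= 0
    n_bins = centers.shape[0] * n_annuli
    n_pix = np.bincount(bin_id[valid], minlength=n_bins)

    rows = []
    for name in names:
        vals = np.asarray(channels[name], dtype=float).ravel()
        sums = np.bincount(bin_id[valid], weights=vals[valid], minlength=n_bins)
        with np.errstate(invalid="ignore"):
            means = np.where(n_pix > 0, sums / np.maximum(n_pix, 1), np.nan)
        for pk in range(centers.shape[0]):
            for a in range(n_annuli):
                b = pk * n_annuli + a
                rows.append(
                    (
                        pk,
                        a,
                        a * annulus_width_um,
                        (a + 1) * annulus_width_um,
                        name,
                        means[b],
                        int(n_pix[b]),
                    )
                )
    return pd.DataFrame(
        rows,
        columns=[
            "plaque_id",
            "annulus_index",
            "inner_radius_um",
            "outer_radius_um",
            "channel",
            "mean_intensity",
            "n_pixels",
        ],
    )


def zscore_profiles(table: pd.DataFrame, within: str | None = None) -> pd.DataFrame:
    """Z-score annulus means per channel (sample s.d., n-1).

    By default the mean and s.d. are taken over all (plaque, annulus) rows
    of a channel across the whole table; pass ``within`` (a column name,
    e.g. an image or mouse id) to z-score inside each group instead. A
    zero-s.d. channel gets zeros with a warning.
    """
    out = table.copy()
    out["z"] = np.nan
    keys = ["channel"] if within is None else ["channel", within]
    for _, idx in out.groupby(keys).groups.items():
        x = out.loc[idx, "mean_intensity"]
        defined = x.notna()
        if defined.sum() < 2:
            raise ValueError("need at least 2 defined values per channel to z-score")
        mu, sd = x[defined].mean(), x[defined].std(ddof=1)
        if sd == 0:
            warnings.warn("zero s.d. channel; z-scores set to 0")
            out.loc[idx[defined], "z"] = 0.0
        else:
            out.loc[idx[defined], "z"] = (x[defined] - mu) / sd
    return out


def loess_curve(
    distances,
    values,
    span: float = 0.75,
    degree: int = 1,
    eval_x=None,
) -> pd.DataFrame:
    """LOESS fit with tricube weights and pointwise standard errors.

    At every evaluation point a weighted least-squares polynomial of the
    given degree is fitted over the ``ceil(span * n)`` nearest points with
    tricube weights on scaled distance. The standard error combines the
    residual variance estimate (RSS over residual degrees of freedom,
    n minus the trace of the smoother matrix) with the smoother row norm,
    the usual linear-smoother variance formula.
    """
    x = np.asarray(distances, dtype=float)
    y = np.asarray(values, dtype=float)
    if not (0 < span <= 1):
        raise ValueError("span must lie in (0, 1]")
    n = len(x)
    if n < max(4, degree + 2):
        raise ValueError("too few points for a LOESS fit")
    if np.ptp(x) == 0:
        raise ValueError("degenerate design: all x equal")
    eval_x = x if eval_x is None else np.asarray(eval_x, dtype=float)
    k = max(int(np.ceil(span * n)), degree + 1)

    def smoother_row(x0):
        d = np.abs(x - x0)
        idx = np.argsort(d, kind="stable")[:k]
        dmax = d[idx].max()
        if dmax == 0:
            w = np.ones(len(idx))
        else:
            w = (1 - (d[idx] / dmax) ** 3) ** 3
            w = np.clip(w, 0.0, None)
        X = np.vander(x[idx] - x0, degree + 1, increasing=True)
        WX = X * w[:, None]
        beta_map = np.linalg.pinv(X.T @ WX) @ WX.T  # rows -> coefficients
        row = np.zeros(n)
        row[idx] = beta_map[0]  # intercept at x0 = fitted value
        return row

    L_eval = np.array([smoother_row(x0) for x0 in eval_x])
    fitted_eval = L_eval @ y

    # residual variance from the fit at the data points themselves
    L_data = (
        L_eval
        if eval_x is x or (len(eval_x) == n and np.array_equal(eval_x, x))
        else np.array([smoother_row(x0) for x0 in x])
    )
    resid = y - L_data @ y
    df_resid = max(n - np.trace(L_data), 1.0)
    sigma2 = float(resid @ resid) / df_resid
    se = np.sqrt(sigma2 * (L_eval**2).sum(axis=1))
    return pd.DataFrame({"x": eval_x, "fitted": fitted_eval, "se": se})


def near_far_test(
    table: pd.DataFrame,
    channel: str,
    replicate_unit: str = "plaque_id",
    near_annuli: int = 3,
    far_annuli: int = 3,
    alternative: str = "near_greater",
    value_column: str = "z",
    equal_var: bool = True,
) -> NearFarResult:
    """One-tailed comparison of near-plaque vs distant annulus means.

    Per replicate (plaque or a coarser unit such as mouse, named by a
    table column), the near value is the mean over the innermost
    ``near_annuli`` annuli and the far value the mean over the outermost
    ``far_annuli``; replicates with missing annuli in either window are
    dropped with a warning. Near and far values are then compared with an
    unpaired one-tailed t-test in the declared direction
    (``near_greater`` or ``far_greater``). Identical near and far values
    give t = 0, p = 0.5.
    """
    if alternative not in ("near_greater", "far_greater"):
        raise ValueError("alternative must be 'near_greater' or 'far_greater'")
    sub = table[table["channel"] == channel]
    if len(sub) == 0:
        raise ValueError(f"channel {channel!r} not in table")
    n_annuli = int(sub["annulus_index"].max()) + 1
    near_idx = set(range(near_annuli))
    far_idx = set(range(n_annuli - far_annuli, n_annuli))

    near_vals, far_vals = [], []
    for rep, grp in sub.groupby(replicate_unit):
        ok = grp["n_pixels"] > 0
        have = set(grp.loc[ok, "annulus_index"])
        if not (near_idx <= have and far_idx <= have):
            warnings.warn(f"replicate {rep!r} dropped: missing near/far annuli")
            continue
        g = grp.set_index("annulus_index")
        near_vals.append(g.loc[sorted(near_idx), value_column].mean())
        far_vals.append(g.loc[sorted(far_idx), value_column].mean())
    near_vals, far_vals = np.asarray(near_vals), np.asarray(far_vals)
    if len(near_vals) < 2:
        raise ValueError("need at least 2 replicates per side")

    df = float(len(near_vals) + len(far_vals) - 2)
    if near_vals.var(ddof=1) == 0 and far_vals.var(ddof=1) == 0:
        # degenerate: no spread on either side
        if near_vals.mean() == far_vals.mean():
            t_stat, p = 0.0, 0.5
        else:
            diff = near_vals.mean() - far_vals.mean()
            favored = (diff > 0) == (alternative == "near_greater")
            t_stat = np.inf if diff > 0 else -np.inf
            p = 0.0 if favored else 1.0
    else:
        res = stats.ttest_ind(
            near_vals,
            far_vals,
            equal_var=equal_var,
            alternative="greater" if alternative == "near_greater" else "less",
        )
        t_stat, p, df = float(res.statistic), float(res.pvalue), float(res.df)
    return NearFarResult(
        channel=channel,
        alternative=alternative,
        near_means=near_vals,
        far_means=far_vals,
        t=t_stat,
        df=df,
        p=p,
    )


def fit_exponential_decay(radii_um, means, direction: str = "up_near_plaque"):
    """Recover (amplitude, decay length, baseline) from a radial profile.

    Fits ``b + A * exp(-r / lam)`` ("up" channels) or
    ``b + A * (1 - exp(-r / lam))`` ("down" channels) by nonlinear least
    squares. Returns the parameter dict.
    """
    from scipy.optimize import curve_fit

    r = np.asarray(radii_um, dtype=float)
    y = np.asarray(means, dtype=float)
    ok = np.isfinite(y)
    r, y = r[ok], y[ok]

    if direction == "up_near_plaque":
        f = lambda r, A, lam, b: b + A * np.exp(-r / lam)
        p0 = (y.max() - y.min(), r.max() / 4, y.min())
    else:
        f = lambda r, A, lam, b: b + A * (1.0 - np.exp(-r / lam))
        p0 = (y.max() - y.min(), r.max() / 4, y.min())
    popt, _ = curve_fit(f, r, y, p0=p0, maxfev=20_000)
    return {"amplitude": float(popt[0]), "decay_length_um": float(popt[1]), "baseline": float(popt[2])}
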