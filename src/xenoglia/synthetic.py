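"""Synthetic cohorts, plaque images and ortholog tables with planted truth.

Every downstream stage of the pipeline (QC, demultiplexing, marker finding,
state mapping, composition statistics, radial profiling) is exercised on the
outputs of this module, so each generator records the ground truth it planted:
per-droplet state / sample / droplet type for cohorts, plaque centers and
gradient parameters for images, relation classes for ortholog tables.

The count model is the standard single-cell negative binomial: gene g in a
cell of state s has mean ``mu_g * 2**effect`` when g belongs to state s's
marker program and ``mu_g`` otherwise, with variance ``mu + mu**2 / theta``.
Doublets are sums of two independently drawn parent cells and carry hashtag
signal on both parents' hashes. Mouse-to-mouse variability in state
composition is Dirichlet around the group means, which is what gives the
between-mouse variance the composition t-tests need.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .containers import CountMatrix, HashMatrix

DEFAULT_STATES = ("HM", "RM", "tCRM", "CRM-1", "CRM-2", "IRM", "DAM", "HLA")

# Baseline composition of a control (amyloid-free) cohort and the enriched
# composition of a plaque-bearing cohort: DAM, HLA and CRM-1 are doubled and
# the remaining states are scaled down to keep the vector on the simplex.
_CONTROL_PROPS = (0.40, 0.15, 0.10, 0.08, 0.04, 0.05, 0.10, 0.08)


def _enriched_props(base=_CONTROL_PROPS, enriched=("CRM-1", "DAM", "HLA"), factor=2.0):
    base = np.asarray(base, dtype=float)
    out = base.copy()
    idx = [DEFAULT_STATES.index(s) for s in enriched]
    out[idx] = base[idx] * factor
    rest = [i for i in range(len(base)) if i not in idx]
    out[rest] = base[rest] * (1.0 - out[idx].sum()) / base[rest].sum()
    return tuple(out)


@dataclass
class SimCohortConfig:
    """Parameters of the hashed-droplet cohort simulator.

    Defaults emulate a two-genotype transplantation cohort in which the
    reactive DAM, HLA and CRM-1 states double their share in the
    plaque-bearing group.
    """

    group_names: tuple = ("AppWT", "AppNLGF")
    mice_per_group: int = 6
    cells_per_mouse: int = 500
    n_genes: int = 2000
    n_mito_genes: int = 13
    state_names: tuple = DEFAULT_STATES
    state_proportions_per_group: tuple = (_CONTROL_PROPS, _enriched_props())
    program_size: int = 20
    program_log2_effect: float = 1.0
    nb_dispersion: float = 2.0
    baseline_mean_range: tuple = (0.02, 2.0)
    doublet_rate: float = 0.05
    negative_rate: float = 0.02
    hash_signal_mean: float = 200.0
    hash_background_mean: float = 10.0
    mito_fraction_beta_params: tuple = (2.0, 30.0)
    dirichlet_concentration: float = 150.0
    seed: int = 0

    @property
    def n_groups(self) -> int:
        return len(self.group_names)

    def validate(self) -> None:
        props = np.asarray(self.state_proportions_per_group, dtype=float)
        if props.shape != (self.n_groups, len(self.state_names)):
            raise ValueError("state_proportions_per_group must be n_groups x n_states")
        if not np.allclose(props.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("every state-proportion vector must sum to 1")
        if (props < 0).any():
            raise ValueError("state proportions must be nonnegative")
        if not (0 <= self.doublet_rate < 1):
            raise ValueError("doublet_rate must lie in [0, 1)")
        if not (0 <= self.negative_rate < 1):
            raise ValueError("negative_rate must lie in [0, 1)")
        for name in ("mice_per_group", "cells_per_mouse", "n_genes", "program_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        # programs are planted on the top quartile of baseline expression
        n_programmable = (self.n_genes - self.n_mito_genes) // 4
        if self.program_size * len(self.state_names) > n_programmable:
            raise ValueError(
                "state programs do not fit: program_size x n_states exceeds the "
                "number of eligible (moderately expressed, non-mitochondrial) genes"
            )


@dataclass
class CohortTruth:
    """Planted ground truth for one simulated cohort.

    ``cells`` has one record per emitted droplet (barcode, library, droplet
    type, true sample / state, parents for doublets, realized mito fraction);
    ``programs`` maps each state to its marker-program genes; ``mice`` maps
    samples to groups and hashes.
    """

    cells: pd.DataFrame
    programs: dict
    mice: pd.DataFrame
    baseline_means: pd.Series


def _nb_draw(rng, mean, theta):
    # numpy parameterizes NB by (n, p); mean/dispersion form: p = theta/(theta+mu)
    mean = np.asarray(mean, dtype=float)
    p = theta / (theta + mean)
    return rng.negative_binomial(theta, p)


def draw_mouse_state_proportions(config: SimCohortConfig, rng=None) -> pd.DataFrame:
    """Per-mouse state proportions: Dirichlet around the group means.

    The concentration parameter sets the between-mouse coefficient of
    variation; the returned frame has one row per mouse with ``group``
    metadata attached.
    """
    config.validate()
    rng = np.random.default_rng(config.seed) if rng is None else rng
    rows, meta = [], []
    for g, gname in enumerate(config.group_names):
        alpha = (
            np.asarray(config.state_proportions_per_group[g], dtype=float)
            * config.dirichlet_concentration
        )
        # Dirichlet with a zero component is degenerate; keep zero states zero.
        pos = alpha > 0
        for m in range(config.mice_per_group):
            p = np.zeros(len(alpha))
            p[pos] = rng.dirichlet(alpha[pos])
            rows.append(p)
            meta.append((f"{gname}_m{m + 1}", gname))
    df = pd.DataFrame(rows, columns=list(config.state_names))
    df.index = [s for s, _ in meta]
    df.insert(0, "group", [g for _, g in meta])
    return df


def _assign_programs(config: SimCohortConfig, rng, baseline):
    """Disjoint marker-program gene sets, one per state.

    Programs are planted on the top quartile of baseline expression (among
    non-mitochondrial genes): cell-state marker panels consist of robustly
    detected genes — a program on genes seen in a small minority of cells
    would not emulate a real transcriptional state signature.
    """
    n_regular = config.n_genes - config.n_mito_genes
    order = np.argsort(baseline[:n_regular], kind="stable")
    eligible = order[n_regular - n_regular // 4 :]  # top quartile by baseline mean
    chosen = rng.permutation(eligible)
    programs = {}
    for i, state in enumerate(config.state_names):
        sel = chosen[i * config.program_size : (i + 1) * config.program_size]
        programs[state] = np.sort(sel)
    return programs


def simulate_cohort(config: SimCohortConfig) -> tuple[CountMatrix, HashMatrix, CohortTruth]:
    """Simulate a hashed droplet cohort with planted cell states.

    Returns the raw gene x droplet count matrix, the hashtag count matrix
    (one hash per mouse) and the ground truth. Droplets are singlets,
    doublets (sum of two parent cells from the same library, hash signal on
    both parents' hashes) or negative-like (a real cell whose hash staining
    failed: background counts on every hash). The same config and seed give
    byte-identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    n_states = len(config.state_names)
    n_regular = config.n_genes - config.n_mito_genes
    gene_names = pd.Index(
        [f"GENE{i + 1:05d}" for i in range(n_regular)]
        + [f"MT-{i + 1}" for i in range(config.n_mito_genes)]
    )
    mito_idx = np.arange(n_regular, config.n_genes)

    lo, hi = config.baseline_mean_range
    baseline = np.exp(rng.uniform(np.log(lo), np.log(hi), size=config.n_genes))
    programs = _assign_programs(config, rng, baseline)

    # per-state mean vectors over non-mito genes
    state_means = np.tile(baseline[:n_regular], (n_states, 1))
    for i, state in enumerate(config.state_names):
        state_means[i, programs[state]] *= 2.0 ** config.program_log2_effect
    mito_weights = baseline[mito_idx] / baseline[mito_idx].sum()

    mouse_props = draw_mouse_state_proportions(config, rng)
    mice = mouse_props.index.to_numpy()
    mouse_group = mouse_props["group"]
    hash_names = pd.Index([f"HTO-{m}" for m in mice])
    mouse_hash = {m: i for i, m in enumerate(mice)}
    # one sequencing library per group: mice of a group are pooled
    mouse_library = {m: f"lib_{mouse_group[m]}" for m in mice}

    def draw_parent(mouse: str, n: int):
        """State indices and count rows for n cells of one mouse."""
        p = mouse_props.loc[mouse, list(config.state_names)].to_numpy(dtype=float)
        states = rng.choice(n_states, size=n, p=p)
        counts = np.zeros((n, config.n_genes), dtype=np.int64)
        for s in np.unique(states):
            m = states == s
            counts[np.ix_(m, np.arange(n_regular))] = _nb_draw(
                rng, np.tile(state_means[s], (m.sum(), 1)), config.nb_dispersion
            )
        # mitochondrial block: Beta-distributed share of each cell's reads
        f = rng.beta(*config.mito_fraction_beta_params, size=n)
        t_nm = counts.sum(axis=1)
        m_tot = np.rint(f / (1.0 - f) * t_nm).astype(np.int64)
        for i in range(n):
            if m_tot[i] > 0:
                counts[i, mito_idx] = rng.multinomial(m_tot[i], mito_weights)
        return states, counts

    blocks, truth_rows, hash_cols = [], [], []
    barcode_counter = 0
    for lib in dict.fromkeys(mouse_library.values()):
        lib_mice = [m for m in mice if mouse_library[m] == lib]
        n_droplets = config.cells_per_mouse * len(lib_mice)
        u = rng.random(n_droplets)
        is_doublet = u < config.doublet_rate
        is_negative = (~is_doublet) & (u < config.doublet_rate + config.negative_rate)
        # nominal mouse of each droplet (first parent for doublets)
        owner = rng.choice(lib_mice, size=n_droplets)
        partner = rng.choice(lib_mice, size=n_droplets)

        lib_counts = np.zeros((n_droplets, config.n_genes), dtype=np.int64)
        lib_states = np.empty(n_droplets, dtype=object)
        lib_partner_states = np.empty(n_droplets, dtype=object)
        for m in lib_mice:
            sel = np.flatnonzero(owner == m)
            if sel.size:
                st, ct = draw_parent(m, sel.size)
                lib_counts[sel] = ct
                lib_states[sel] = np.asarray(config.state_names, dtype=object)[st]
            sel2 = np.flatnonzero(is_doublet & (partner == m))
            if sel2.size:
                st2, ct2 = draw_parent(m, sel2.size)
                lib_counts[sel2] += ct2
                lib_partner_states[sel2] = np.asarray(config.state_names, dtype=object)[st2]

        hashes = rng.poisson(config.hash_background_mean, size=(len(mice), n_droplets))
        for j in range(n_droplets):
            barcode = f"BC{barcode_counter + j + 1:06d}"
            if is_doublet[j]:
                dtype_ = "doublet"
                for m in (owner[j], partner[j]):
                    hashes[mouse_hash[m], j] += rng.poisson(config.hash_signal_mean)
                true_sample = owner[j]  # first parent; second in parent_sample_2
            elif is_negative[j]:
                dtype_ = "negative-like"
                true_sample = owner[j]
            else:
                dtype_ = "singlet"
                hashes[mouse_hash[owner[j]], j] = rng.poisson(config.hash_signal_mean)
                true_sample = owner[j]
            tot = lib_counts[j].sum()
            mito = lib_counts[j, mito_idx].sum()
            truth_rows.append(
                {
                    "barcode": barcode,
                    "library_id": lib,
                    "droplet_type": dtype_,
                    "true_sample": true_sample,
                    "true_state": lib_states[j],
                    "parent_sample_2": partner[j] if is_doublet[j] else None,
                    "parent_state_2": lib_partner_states[j] if is_doublet[j] else None,
                    "mito_fraction": mito / tot if tot > 0 else 0.0,
                }
            )
        barcode_counter += n_droplets
        blocks.append(sp.csr_matrix(lib_counts.T))
        hash_cols.append(hashes)

    truth_cells = pd.DataFrame(truth_rows)
    barcodes = pd.Index(truth_cells["barcode"])
    counts = CountMatrix(
        matrix=sp.hstack(blocks, format="csr"),
        genes=gene_names,
        barcodes=barcodes,
        library_ids=truth_cells["library_id"].to_numpy(),
    )
    hash_matrix = HashMatrix(
        matrix=np.hstack(hash_cols), hashes=hash_names, barcodes=barcodes
    )
    mice_df = pd.DataFrame(
        {
            "sample": mice,
            "group": [mouse_group[m] for m in mice],
            "hash": [hash_names[mouse_hash[m]] for m in mice],
            "library_id": [mouse_library[m] for m in mice],
        }
    ).set_index("sample")
    truth = CohortTruth(
        cells=truth_cells,
        programs={s: gene_names[programs[s]].tolist() for s in config.state_names},
        mice=mice_df,
        baseline_means=pd.Series(baseline, index=gene_names),
    )
    return counts, hash_matrix, truth


# ---------------------------------------------------------------------------
# plaque images
# ---------------------------------------------------------------------------


@dataclass
class ChannelModel:
    """Radial intensity model of one fluorescence channel.

    ``up_near_plaque`` channels follow ``b + A * exp(-d / lam)`` of the
    distance d to the nearest plaque center; ``down_near_plaque`` channels
    follow ``b + A * (1 - exp(-d / lam))``; the ``plaque`` channel is a set
    of uniform disks blurred by the point-spread function.
    """

    direction: str  # {"plaque", "up_near_plaque", "down_near_plaque"}
    amplitude: float = 100.0
    decay_length_um: float = 20.0
    baseline: float = 10.0


@dataclass
class SimImageConfig:
    image_size_px: tuple = (256, 256)
    pixel_size_um: float = 1.0
    n_plaques: int = 5
    plaque_radius_um: tuple = (4.0, 8.0)
    channel_models: dict = field(
        default_factory=lambda: {
            "X34": ChannelModel("plaque", amplitude=255.0, baseline=5.0),
            "CD9": ChannelModel("up_near_plaque"),
            "P2RY12": ChannelModel("down_near_plaque"),
        }
    )
    noise_sd: float = 5.0
    psf_sigma_um: float = 1.0
    margin_um: float = 10.0
    min_separation_um: float = 25.0
    seed: int = 0

    def validate(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.n_plaques < 0:
            raise ValueError("n_plaques must be nonnegative")
        if self.plaque_radius_um[0] > self.plaque_radius_um[1]:
            raise ValueError("plaque_radius_um range inverted")


@dataclass
class ImageTruth:
    """Planted plaque geometry and per-channel gradient parameters."""

    plaques: pd.DataFrame  # id, row_px, col_px, radius_um
    channels: pd.DataFrame  # channel, direction, amplitude, decay_length_um, baseline
    pixel_size_um: float


def simulate_plaque_image(config: SimImageConfig) -> tuple[dict, ImageTruth]:
    """Simulate a multi-channel plaque image with radial marker gradients.

    Returns ``(channels, truth)`` where ``channels`` maps channel name to a
    2D float array. With zero plaques, distance-dependent channels reduce to
    baseline plus noise.
    """
    from scipy.ndimage import gaussian_filter

    config.validate()
    rng = np.random.default_rng(config.seed)
    h, w = config.image_size_px
    px = config.pixel_size_um

    # rejection-sample centers so plaques stay distinct objects
    margin = config.margin_um / px
    min_sep = config.min_separation_um / px
    centers_list: list = []
    tries = 0
    while len(centers_list) < config.n_plaques:
        cand = np.array(
            [rng.uniform(margin, h - 1 - margin), rng.uniform(margin, w - 1 - margin)]
        )
        if all(np.linalg.norm(cand - c) >= min_sep for c in centers_list):
            centers_list.append(cand)
        tries += 1
        if tries > 10_000 * max(config.n_plaques, 1):
            raise ValueError("cannot place plaques: image too small for separation")
    centers = np.array(centers_list) if centers_list else np.empty((0, 2))
    radii = rng.uniform(*config.plaque_radius_um, size=config.n_plaques)

    rr, cc = np.mgrid[0:h, 0:w]
    if len(centers):
        d2 = (rr[..., None] - centers[:, 0]) ** 2 + (cc[..., None] - centers[:, 1]) ** 2
        dist_um = np.sqrt(d2.min(axis=-1)) * px
        dist_each_um = np.sqrt(d2) * px
    else:
        dist_um = None

    channels = {}
    for name, cm in config.channel_models.items():
        if cm.direction == "plaque":
            img = np.full((h, w), cm.baseline, dtype=float)
            for k in range(len(centers)):
                img[dist_each_um[..., k] <= radii[k]] = cm.baseline + cm.amplitude
            if config.psf_sigma_um > 0:
                img = gaussian_filter(img, config.psf_sigma_um / px)
        elif dist_um is None:
            img = np.full((h, w), cm.baseline, dtype=float)
        elif cm.direction == "up_near_plaque":
            img = cm.baseline + cm.amplitude * np.exp(-dist_um / cm.decay_length_um)
        elif cm.direction == "down_near_plaque":
            img = cm.baseline + cm.amplitude * (1.0 - np.exp(-dist_um / cm.decay_length_um))
        else:
            raise ValueError(f"unknown channel direction {cm.direction!r}")
        if config.noise_sd > 0:
            img = img + rng.normal(0.0, config.noise_sd, size=img.shape)
        channels[name] = np.clip(img, 0.0, None)

    truth = ImageTruth(
        plaques=pd.DataFrame(
            {
                "id": np.arange(len(centers)),
                "row_px": centers[:, 0],
                "col_px": centers[:, 1],
                "radius_um": radii,
            }
        ),
        channels=pd.DataFrame(
            {
                "channel": list(config.channel_models),
                "direction": [c.direction for c in config.channel_models.values()],
                "amplitude": [c.amplitude for c in config.channel_models.values()],
                "decay_length_um": [
                    c.decay_length_um for c in config.channel_models.values()
                ],
                "baseline": [c.baseline for c in config.channel_models.values()],
            }
        ),
        pixel_size_um=px,
    )
    return channels, truth


# ---------------------------------------------------------------------------
# ortholog tables and genotyping arithmetic
# ---------------------------------------------------------------------------


def make_ortholog_table(
    n_pairs: int,
    fractions: dict,
    seed: int = 0,
) -> pd.DataFrame:
    """Mouse-human ortholog table with a controlled relation-class mix.

    ``fractions`` gives the share of mouse genes in each relation class
    (``one_to_one``, ``one_to_many``, ``many_to_one``, ``unmapped``) and must
    sum to 1. Class counts follow the largest-remainder rounding of
    ``fraction * n_pairs``; many-to-one mouse genes share human targets in
    pairs (plus one triple when the class count is odd), one-to-many mouse
    genes get two human targets each.
    """
    keys = ("one_to_one", "one_to_many", "many_to_one", "unmapped")
    fr = np.array([float(fractions.get(k, 0.0)) for k in keys])
    if (fr < 0).any():
        raise ValueError("fractions must be nonnegative")
    if abs(fr.sum() - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    raw = fr * n_pairs
    counts = np.floor(raw).astype(int)
    rem = n_pairs - counts.sum()
    order = np.argsort(-(raw - counts))
    counts[order[:rem]] += 1
    n11, n1m, nm1, _ = counts
    if nm1 == 1:
        warnings.warn("a single many_to_one gene cannot share a target; made one_to_one")
        nm1, n11 = 0, n11 + 1

    rng = np.random.default_rng(seed)
    mouse = [f"m_gene{i + 1:05d}" for i in range(n_pairs)]
    rng.shuffle(mouse)
    rows = []
    h = 0
    i = 0
    for _ in range(n11):
        h += 1
        rows.append((mouse[i], f"H_GENE{h:05d}", "one_to_one"))
        i += 1
    for _ in range(n1m):
        g = mouse[i]
        for _ in range(2):
            h += 1
            rows.append((g, f"H_GENE{h:05d}", "one_to_many"))
        i += 1
    # many-to-one genes share targets in pairs, plus one triple when odd
    group_sizes = [2] * (nm1 // 2)
    if nm1 % 2 == 1:
        group_sizes[-1] = 3
    for size in group_sizes:
        h += 1
        target = f"H_GENE{h:05d}"
        for _ in range(size):
            rows.append((mouse[i], target, "many_to_one"))
            i += 1
    table = pd.DataFrame(rows, columns=["mouse_gene", "human_gene", "relation"])
    return table.sample(frac=1.0, random_state=int(rng.integers(2**31))).reset_index(
        drop=True
    )


def predict_genotyping_amplicons(
    wt_amplicon_bp: int, deletion_segments_bp: list[int]
) -> tuple[int, int]:
    """PCR amplicon lengths for a wild-type and a deletion allele.

    The mutant amplicon is the wild-type amplicon minus the summed deleted
    segments; the deletion must fit strictly inside the amplicon or the
    primer sites would be lost.
    """
    if wt_amplicon_bp <= 0:
        raise ValueError("wild-type amplicon length must be positive")
    if any(s < 0 for s in deletion_segments_bp):
        raise ValueError("deletion segment lengths must be nonnegative")
    total = sum(deletion_segments_bp)
    if total >= wt_amplicon_bp:
        raise ValueError("deletion spans the whole amplicon; primers would be lost")
    return wt_amplicon_bp, wt_amplicon_bp - total
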