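"""Seeded forward simulators for the downstream kinetic and transcriptomic analyses.

Three generators live here:

* :func:`simulate_tracks` — 2D nuclear single-molecule trajectories from a
  multi-state kinetic model (two bound-lifetime classes, slow and free diffusion),
  sampled stroboscopically with photobleaching, blinking and localization noise.
* :func:`simulate_frap_curve` — double-exponential fluorescence recovery curves
  with additive Gaussian noise.
* :func:`simulate_counts_and_peaks` — negative-binomial expression counts with
  condition-specific fold-change effects, plus a matched gene annotation and
  promoter peak table.

Every generator consumes a single integer seed through one
:class:`numpy.random.Generator` stream, so identical configs give identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "SmtSimConfig",
    "FrapSimConfig",
    "CountsSimConfig",
    "simulate_tracks",
    "simulate_frap_curve",
    "simulate_counts_and_peaks",
    "simulate_displacements",
]

_STATE_NAMES = {0: "bound_fast", 1: "bound_slow", 2: "slow_diff", 3: "free"}


@dataclass(frozen=True)
class SmtSimConfig:
    """Ground truth and acquisition settings for the trajectory simulator.

    Distances are in micrometres, times in seconds, diffusivities in um^2/s.
    The camera cycle is ``dt = t_int + t_gap``; the 5 ms exposure is treated as
    instantaneous at the cycle start (dwell times are much longer than t_int,
    so motion blur is ignored).
    """

    n_molecules: int = 1000
    nucleus_size: float = 10.0
    d_bound: float = 0.04        # chromatin jitter of "immobile" molecules
    d_slow: float = 0.5
    d_free: float = 5.0
    frac_bound: float = 0.4
    frac_slow: float = 0.2
    frac_free: float = 0.4
    t_fast: float = 0.53         # mean dwell of short-lived binding events
    t_slow: float = 4.13         # mean dwell of long-lived binding events
    frac_slow_bound: float = 0.043  # P(binding event is long-lived)
    p_bleach: float = 0.01       # per-exposure, permanent
    p_blink: float = 0.05        # per-exposure, reversible dark state
    max_blink: int = 3           # longest run of consecutive dark frames
    sigma_loc: float = 0.03      # localization noise SD per axis
    t_int: float = 0.005
    t_gap: float = 0.095
    n_frames: int = 400
    rebind_rate: float = 0.0     # 1/s, free -> bound re-association within a track
    seed: int = 0

    @property
    def dt(self) -> float:
        return self.t_int + self.t_gap

    def __post_init__(self) -> None:
        fields = (
            self.nucleus_size, self.d_bound, self.d_slow, self.d_free,
            self.frac_bound, self.frac_slow, self.frac_free,
            self.t_fast, self.t_slow, self.frac_slow_bound,
            self.p_bleach, self.p_blink, self.sigma_loc, self.t_int, self.t_gap,
            self.rebind_rate,
        )
        for v in fields:
            if not math.isfinite(v) and not (v == math.inf and v in (self.t_fast, self.t_slow)):
                raise ValueError(f"non-finite config value: {v!r}")
            if v < 0:
                raise ValueError(f"negative config value: {v!r}")
        if self.n_molecules <= 0 or self.n_frames <= 0:
            raise ValueError("n_molecules and n_frames must be positive")
        if abs(self.frac_bound + self.frac_slow + self.frac_free - 1.0) > 1e-9:
            raise ValueError("frac_bound + frac_slow + frac_free must equal 1")
        if not self.dt > 0:
            raise ValueError("frame cycle t_int + t_gap must be positive")
        for p in (self.frac_slow_bound, self.p_bleach, self.p_blink):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability outside [0, 1]: {p!r}")


@dataclass(frozen=True)
class FrapSimConfig:
    """Ground truth for a simulated FRAP recovery: I(t) = I1(1-e^-t/tau1) + I2(1-e^-t/tau2)."""

    i1: float = 0.4
    i2: float = 0.4
    tau1: float = 0.3
    tau2: float = 3.0
    noise_sd: float = 0.01
    dt: float = 0.069            # frame delay of the confocal acquisition
    n_pre: int = 50
    n_post: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tau1 <= 0 or self.tau2 <= 0:
            raise ValueError("tau1 and tau2 must be positive")
        if self.i1 < 0 or self.i2 < 0:
            raise ValueError("amplitudes must be non-negative")
        if self.i1 + self.i2 > 1.0 + 1e-12:
            raise ValueError("I1 + I2 must not exceed 1")
        if self.noise_sd < 0 or self.dt <= 0:
            raise ValueError("noise_sd must be >= 0 and dt > 0")
        if self.n_pre < 0 or self.n_post < 1:
            raise ValueError("need n_pre >= 0 and n_post >= 1")


@dataclass(frozen=True)
class CountsSimConfig:
    """Negative-binomial count matrix with per-condition log2 fold-change effects.

    ``n_de_genes`` genes respond to transfection (the injected log2FC applies to
    them in every non-reference condition, scaled by that condition's effect);
    ``n_peak_genes`` of those additionally carry a promoter-window peak in the
    matched BED3 table.
    """

    n_genes: int = 5000
    n_de_genes: int = 1080
    n_peak_genes: int = 215
    samples: tuple = ("NT", "WT")
    effects: dict = field(default_factory=dict)   # condition -> log2FC multiplier for DE genes
    dispersion: float = 0.05
    lib_size: int = 1_000_000
    n_replicates: int = 1
    promoter_pad: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.n_peak_genes <= self.n_de_genes <= self.n_genes):
            raise ValueError("need n_peak_genes <= n_de_genes <= n_genes")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if self.lib_size <= 0:
            raise ValueError("lib_size must be positive")
        if "NT" not in self.samples:
            raise ValueError("samples must include the reference condition 'NT'")


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------

def simulate_tracks(config: SmtSimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate stroboscopic 2D single-molecule movies.

    Molecules are assigned a mobility state (bound / slow / free) with the
    configured fractions. Bound molecules jitter with ``d_bound`` and unbind
    after an exponential dwell whose mean is ``t_slow`` with probability
    ``frac_slow_bound`` and ``t_fast`` otherwise; after unbinding they diffuse
    freely. Positions evolve by Brownian steps with reflecting boundaries in
    the square nucleus and are read out every ``dt`` seconds. Each exposure a
    visible molecule bleaches permanently with ``p_bleach``, otherwise it may
    enter a dark (blinking) state with ``p_blink`` for at most ``max_blink``
    consecutive frames. Localization noise is added per axis.

    Returns
    -------
    localizations : DataFrame
        Columns ``frame, x_um, y_um, track_truth_id, state_truth``.
    events : DataFrame
        Ground-truth binding events, columns ``event_id, t_true_s, class``
        (true exponential dwell, uncensored by bleaching or the movie end).
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_molecules
    dt = cfg.dt

    def draw_dwells(rng, size):
        """Dwell times and classes for `size` new binding events."""
        slow = rng.random(size) < cfg.frac_slow_bound
        means = np.where(slow, cfg.t_slow, cfg.t_fast)
        dwell = np.where(
            np.isfinite(means), rng.exponential(np.where(np.isfinite(means), means, 1.0)), np.inf
        )
        return dwell, slow

    # initial mobility: 0 = bound, 1 = slow diffusion, 2 = free
    mobility = rng.choice(3, size=n, p=[cfg.frac_bound, cfg.frac_slow, cfg.frac_free])
    bound_now = mobility == 0
    slow_class = np.zeros(n, dtype=bool)
    dwell_end = np.full(n, -np.inf)
    ev_id, ev_t, ev_class = [], [], []
    d0, s0 = draw_dwells(rng, int(bound_now.sum()))
    idx0 = np.flatnonzero(bound_now)
    dwell_end[idx0] = d0
    slow_class[idx0] = s0
    ev_id.extend(idx0.tolist())
    ev_t.extend(d0.tolist())
    ev_class.extend(np.where(s0, "slow", "fast").tolist())

    p_rebind = 1.0 - math.exp(-cfg.rebind_rate * dt) if cfg.rebind_rate > 0 else 0.0

    pos = rng.uniform(0.0, cfg.nucleus_size, size=(n, 2))
    alive = np.ones(n, dtype=bool)
    dark_run = np.zeros(n, dtype=np.int64)

    frames_out, xs, ys, ids, states = [], [], [], [], []
    mol_ids = np.arange(n)

    for k in range(cfg.n_frames):
        t_k = k * dt
        # unbinding: bound molecules whose dwell has elapsed diffuse freely
        expired = bound_now & (t_k >= dwell_end)
        mobility[expired] = 2
        bound_now &= ~expired
        # optional re-association of free molecules (a fresh, independent event)
        if p_rebind > 0:
            free = (mobility == 2) & alive
            rebind = free & (rng.random(n) < p_rebind)
            if rebind.any():
                idx = np.flatnonzero(rebind)
                d_new, s_new = draw_dwells(rng, idx.size)
                mobility[idx] = 0
                bound_now[idx] = True
                dwell_end[idx] = t_k + d_new
                slow_class[idx] = s_new
                ev_id.extend(idx.tolist())
                ev_t.extend(d_new.tolist())
                ev_class.extend(np.where(s_new, "slow", "fast").tolist())

        diff = np.where(bound_now, cfg.d_bound,
                        np.where(mobility == 1, cfg.d_slow, cfg.d_free))

        # photophysics: bleach first, then blink (dark runs capped at max_blink)
        alive &= rng.random(n) >= cfg.p_bleach
        want_dark = rng.random(n) < cfg.p_blink
        dark = want_dark & (dark_run < cfg.max_blink)
        dark_run = np.where(dark, dark_run + 1, 0)

        visible = alive & ~dark
        if visible.any():
            noise = rng.normal(0.0, cfg.sigma_loc, size=(int(visible.sum()), 2))
            obs = pos[visible] + noise
            frames_out.append(np.full(int(visible.sum()), k))
            xs.append(obs[:, 0])
            ys.append(obs[:, 1])
            ids.append(mol_ids[visible])
            st = np.where(bound_now[visible] & slow_class[visible], 1,
                          np.where(bound_now[visible], 0,
                                   np.where(mobility[visible] == 1, 2, 3)))
            states.append(st)

        if not alive.any():
            break

        # advance positions to the next exposure (reflecting boundaries);
        # molecules unbinding mid-interval diffuse bound for the residual dwell
        # and freely for the remainder, so the variance is split accordingly
        var = 2.0 * diff * dt
        mid = bound_now & (dwell_end < t_k + dt)
        if mid.any():
            tb = np.clip(dwell_end[mid] - t_k, 0.0, dt)
            var[mid] = 2.0 * (cfg.d_bound * tb + cfg.d_free * (dt - tb))
        # zero-step axes keep their exact coordinate
        step = rng.normal(0.0, 1.0, size=(n, 2)) * np.sqrt(var)[:, None]
        moved = pos + step
        moved = np.abs(moved)
        moved = cfg.nucleus_size - np.abs(cfg.nucleus_size - moved)
        np.clip(moved, 0.0, cfg.nucleus_size, out=moved)
        pos = np.where(step == 0.0, pos, moved)

    if frames_out:
        locs = pd.DataFrame({
            "frame": np.concatenate(frames_out).astype(np.int64),
            "x_um": np.concatenate(xs),
            "y_um": np.concatenate(ys),
            "track_truth_id": np.concatenate(ids).astype(np.int64),
        })
        locs["state_truth"] = pd.Series(np.concatenate(states)).map(_STATE_NAMES).to_numpy()
        locs = locs.sort_values(["frame", "track_truth_id"], kind="stable").reset_index(drop=True)
    else:
        locs = pd.DataFrame(columns=["frame", "x_um", "y_um", "track_truth_id", "state_truth"])

    events = pd.DataFrame({
        "event_id": np.asarray(ev_id, dtype=np.int64),
        "t_true_s": np.asarray(ev_t, dtype=float),
        "class": np.asarray(ev_class, dtype=object),
    })
    return locs, events


def simulate_displacements(
    fractions, diffusivities, dt: float, n: int, seed: int = 0
) -> np.ndarray:
    """Draw single-step displacements from a mixture of 2D Brownian species.

    Step lengths for species *i* are Rayleigh with scale sqrt(2 D_i dt); the
    mixture weights are ``fractions`` (must sum to 1). Used for fast-acquisition
    displacement experiments where full trajectories are not needed.
    """
    f = np.asarray(fractions, dtype=float)
    d = np.asarray(diffusivities, dtype=float)
    if f.shape != d.shape:
        raise ValueError("fractions and diffusivities must have the same length")
    if abs(f.sum() - 1.0) > 1e-9 or (f < 0).any():
        raise ValueError("fractions must be non-negative and sum to 1")
    if (d < 0).any() or dt <= 0:
        raise ValueError("diffusivities must be >= 0 and dt > 0")
    rng = np.random.default_rng(seed)
    comp = rng.choice(len(f), size=n, p=f)
    scale = np.sqrt(2.0 * d[comp] * dt)
    return rng.rayleigh(scale=np.where(scale > 0, scale, 1e-300))


# ---------------------------------------------------------------------------
# FRAP
# ---------------------------------------------------------------------------

def simulate_frap_curve(config: FrapSimConfig) -> pd.DataFrame:
    """Simulate a normalized FRAP trace.

    Pre-bleach frames sit at 1.0; from the first post-bleach frame (t = 0) the
    mean recovery follows I1(1-e^-t/tau1) + I2(1-e^-t/tau2) with iid Gaussian
    noise of SD ``noise_sd`` added to every frame.

    Returns a DataFrame with columns ``time_s, intensity_norm`` where pre-bleach
    frames carry negative times.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    t_pre = -cfg.dt * np.arange(cfg.n_pre, 0, -1)
    t_post = cfg.dt * np.arange(cfg.n_post)
    mean_pre = np.ones(cfg.n_pre)
    mean_post = frap_model(t_post, cfg.i1, cfg.tau1, cfg.i2, cfg.tau2)
    t = np.concatenate([t_pre, t_post])
    y = np.concatenate([mean_pre, mean_post])
    if cfg.noise_sd > 0:
        y = y + rng.normal(0.0, cfg.noise_sd, size=y.size)
    return pd.DataFrame({"time_s": t, "intensity_norm": y})


def frap_model(t, i1, tau1, i2, tau2):
    """Double-exponential recovery I1(1-e^-t/tau1) + I2(1-e^-t/tau2)."""
    t = np.asarray(t, dtype=float)
    return i1 * (1.0 - np.exp(-t / tau1)) + i2 * (1.0 - np.exp(-t / tau2))


# ---------------------------------------------------------------------------
# counts, genes and peaks
# ---------------------------------------------------------------------------

def simulate_counts_and_peaks(
    config: CountsSimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate an expression count matrix with a matched annotation and peak set.

    Counts are negative binomial with gene-specific baselines, library-size
    scaling and var = mu + dispersion * mu^2. The first ``n_de_genes`` genes are
    differentially expressed: in condition ``c`` their expected expression is
    multiplied by 2**(effect_c * beta_g) where beta_g is the gene's injected
    log2FC (drawn once, sign and magnitude fixed across conditions) and
    effect_c is the per-condition multiplier from ``config.effects``
    (default 1 for every non-reference condition, 0 for NT).

    Genes are laid out on one synthetic chromosome with alternating strands;
    exactly ``n_peak_genes`` DE genes receive one peak inside their
    strand-extended promoter window (upstream ``promoter_pad`` bp through the
    gene body).

    Returns ``(counts, genes, peaks, truth)`` — counts indexed by gene id with
    one column per sample (replicates suffixed ``_r<j>`` when n_replicates > 1),
    genes as BED6-style records, peaks as BED3, truth with per-gene DE flag,
    injected log2FC and peak flag.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    gene_ids = np.array([f"gene{i:05d}" for i in range(cfg.n_genes)])

    base = rng.lognormal(mean=np.log(200.0), sigma=1.0, size=cfg.n_genes)
    is_de = np.zeros(cfg.n_genes, dtype=bool)
    is_de[: cfg.n_de_genes] = True
    beta = np.zeros(cfg.n_genes)
    beta[is_de] = rng.normal(0.0, 1.0, size=cfg.n_de_genes) + np.where(
        rng.random(cfg.n_de_genes) < 0.5, 1.0, -1.0
    )

    cols, mats = [], []
    r = 1.0 / cfg.dispersion
    cpm_mu = {}
    for cond in cfg.samples:
        eff = 0.0 if cond == "NT" else float(cfg.effects.get(cond, 1.0))
        mu_gene = base * 2.0 ** (eff * beta)
        mu = mu_gene / mu_gene.sum() * cfg.lib_size
        cpm_mu[cond] = mu / cfg.lib_size * 1e6
        for j in range(cfg.n_replicates):
            p = r / (r + mu)
            mats.append(rng.negative_binomial(r, p))
            cols.append(cond if cfg.n_replicates == 1 else f"{cond}_r{j + 1}")
    counts = pd.DataFrame(np.column_stack(mats), index=gene_ids, columns=cols)
    counts.index.name = "gene_id"

    # annotation: genes tiled on one chromosome, alternating strand
    gene_len = 8000
    spacing = 20000
    starts = 10000 + spacing * np.arange(cfg.n_genes)
    strands = np.where(np.arange(cfg.n_genes) % 2 == 0, "+", "-")
    genes = pd.DataFrame({
        "chrom": "chrS",
        "start": starts,
        "end": starts + gene_len,
        "gene_id": gene_ids,
        "score": 0,
        "strand": strands,
    })

    peak_genes = rng.choice(np.flatnonzero(is_de), size=cfg.n_peak_genes, replace=False)
    has_peak = np.zeros(cfg.n_genes, dtype=bool)
    has_peak[peak_genes] = True
    peak_rows = []
    for g in np.sort(peak_genes):
        s, e, strand = starts[g], starts[g] + gene_len, strands[g]
        lo = max(s - cfg.promoter_pad, 0) if strand == "+" else s
        hi = e if strand == "+" else e + cfg.promoter_pad
        centre = int(rng.integers(lo + 50, hi - 50))
        peak_rows.append(("chrS", centre - 50, centre + 50))
    peaks = pd.DataFrame(peak_rows, columns=["chrom", "start", "end"])

    truth = pd.DataFrame({
        "gene_id": gene_ids,
        "is_de": is_de,
        "log2fc_injected": beta,
        "has_peak": has_peak,
    })
    # realized expected log2FC on the CPM scale (library renormalization makes
    # this differ from the raw injected effect by a small compositional shift)
    for cond in cfg.samples:
        if cond != "NT":
            truth[f"log2fc_cpm_{cond}"] = np.log2(cpm_mu[cond] / cpm_mu["NT"])
    return counts, genes, peaks, truth
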