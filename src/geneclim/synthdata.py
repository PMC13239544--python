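"""Synthetic landscapes, occurrences and genotypes with known ground truth.

The generator emulates the data structure the pipeline consumes: spatially
auto-correlated environmental gradients with a prescribed future shift,
presence records drawn from a known suitability surface, and SNP genotypes
combining (a) discrete neutral clusters at a target Fst (Balding-Nichols
allele frequencies), (b) isolation-by-distance induced by smooth spatial
factors acting on logit allele frequencies, and (c) a planted subset of
adaptive loci whose alt-allele probability follows a logistic cline on a
chosen environmental driver.

All randomness flows from one ``numpy.random.default_rng`` (PCG64) seeded
from ``SimConfig.seed``; independent streams for landscape, genotypes and
occurrences are split with ``SeedSequence.spawn`` so stages are reproducible
in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .geo_io import MISSING, EnvStack, GenotypeMatrix, GridSpec, OccurrenceSet

__all__ = ["SimConfig", "TruthSet", "gen_landscape", "gen_genotypes",
           "gen_occurrences", "simulate"]


@dataclass
class SimConfig:
    """Study-condition parameters for the synthetic generator.

    Defaults give the desk-scale fixture: a 60x60 grid of 100 m cells with
    six climate variables, 40 individuals in 5 demes, 2000 loci of which 40
    are adaptive with logistic-cline slope 4, between-cluster Fst 0.15 and
    5% missing genotypes.
    """

    seed: int = 0
    nrow: int = 60
    ncol: int = 60
    cellsize: float = 100.0
    n_env: int = 6
    corr_length: float = 800.0         # Gaussian-kernel autocorrelation length (m)
    gradient_weight: float = 1.0       # strength of the deterministic W-E/N-S gradient
    future_shift: dict = field(default_factory=lambda: {"2070": 1.5})
    future_noise_sd: float = 0.0
    n_individuals: int = 40
    n_pops: int = 5
    n_loci: int = 2000
    n_adaptive_loci: int = 40
    cline_intercept: float = 0.0       # a in p = logistic(a + b z)
    cline_slope: float = 4.0           # b
    fst_target: float = 0.08
    ibd_strength: float = 0.3          # spatial-factor scale on logit frequencies
    missing_rate: float = 0.05
    n_occurrences: int = 28
    suit_optimum: float = 0.0          # optimum on the standardized variable scale
    suit_breadth: float = 0.5

    def __post_init__(self):
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.n_adaptive_loci > self.n_loci:
            raise ValueError("n_adaptive_loci cannot exceed n_loci")
        for v in (self.nrow, self.ncol, self.n_env, self.n_individuals,
                  self.n_pops, self.n_loci):
            if v <= 0:
                raise ValueError("counts must be positive")

    @property
    def grid(self) -> GridSpec:
        return GridSpec(self.nrow, self.ncol, xmin=700_000.0, ymin=7_500_000.0,
                        cellsize=self.cellsize)

    def streams(self):
        """Named child RNGs split from the master seed."""
        seqs = np.random.SeedSequence(self.seed).spawn(4)
        names = ("landscape", "genotypes", "occurrences", "missing")
        return {n: np.random.default_rng(s) for n, s in zip(names, seqs)}


@dataclass
class TruthSet:
    """Ground truth recorded by the generator for downstream validation."""

    adaptive_locus_ids: list[str] = field(default_factory=list)
    driver_variable: dict = field(default_factory=dict)  # locus id -> var name
    cluster_labels: np.ndarray | None = None             # per-individual deme
    suitability: dict = field(default_factory=dict)      # period -> raster


def gaussian_random_field(shape, sigma_cells, rng) -> np.ndarray:
    """Unit-variance field: Gaussian-kernel smoothing of white noise."""
    z = rng.standard_normal(shape)
    f = ndimage.gaussian_filter(z, sigma=sigma_cells, mode="reflect")
    return (f - f.mean()) / f.std()


def gen_landscape(cfg: SimConfig, rng=None):
    """Generate per-period environment stacks and the true suitability.

    Each variable is a smoothed Gaussian random field plus a linear
    west-east (even bands) or north-south (odd bands) gradient.  A future
    period adds the configured constant shift (and optional noise) to every
    variable.  True suitability is the product of Gaussian response curves
    on the standardized variables, rescaled to [0, 1].
    """
    if rng is None:
        rng = cfg.streams()["landscape"]
    grid = cfg.grid
    extent = min(grid.nrow, grid.ncol) * grid.cellsize
    if cfg.corr_length >= extent:
        raise ValueError("autocorrelation length must be below the grid extent")
    sigma = cfg.corr_length / cfg.cellsize
    rr, cc = np.meshgrid(np.linspace(-1, 1, grid.nrow),
                         np.linspace(-1, 1, grid.ncol), indexing="ij")
    bands = []
    for k in range(cfg.n_env):
        f = gaussian_random_field(grid.shape, sigma, rng)
        # each variable gets its own gradient direction so the predictor
        # set resembles one that already passed a collinearity screen
        theta = rng.uniform(0, 2 * np.pi)
        grad = np.cos(theta) * cc + np.sin(theta) * rr
        v = f + cfg.gradient_weight * grad
        bands.append((v - v.mean()) / v.std())
    current = EnvStack(np.stack(bands), [f"env{k + 1}" for k in range(cfg.n_env)],
                       grid, period="current")
    stacks = {"current": current}
    truth = TruthSet()
    truth.suitability["current"] = _true_suitability(current, cfg)
    for period, shift in cfg.future_shift.items():
        vals = current.values + float(shift)
        if cfg.future_noise_sd > 0:
            vals = vals + cfg.future_noise_sd * rng.standard_normal(vals.shape)
        fut = EnvStack(vals, list(current.var_names), grid, period=period)
        stacks[period] = fut
        truth.suitability[period] = _true_suitability(fut, cfg)
    return stacks, truth


def _true_suitability(stack: EnvStack, cfg: SimConfig) -> np.ndarray:
    logs = -0.5 * ((stack.values - cfg.suit_optimum) / cfg.suit_breadth) ** 2
    s = np.exp(logs.sum(axis=0))
    rng_ = s[np.isfinite(s)]
    lo, hi = rng_.min(), rng_.max()
    return (s - lo) / (hi - lo) if hi > lo else np.zeros_like(s)


def _logistic(x):
    return 1.0 / (1.0 + np.exp(-x))


def gen_genotypes(cfg: SimConfig, env: EnvStack, rng=None, rng_missing=None):
    """Simulate genotypes for individuals placed on the landscape.

    Individuals are assigned to ``n_pops`` demes clustered around random
    deme centers.  Neutral allele frequencies follow the Balding-Nichols
    model around a shared ancestral frequency at the configured Fst, with
    smooth spatial factors added on the logit scale to induce
    isolation-by-distance.  Adaptive loci ignore deme structure: each
    individual's alt-allele probability is logistic(a + b z) with z the
    standardized value of the locus' driver variable at the individual's
    cell.  Genotypes are Binomial(2, p); missing entries are masked at
    ``missing_rate``.
    """
    streams = cfg.streams()
    if rng is None:
        rng = streams["genotypes"]
    if rng_missing is None:
        rng_missing = streams["missing"]
    grid = env.grid
    n, L, P = cfg.n_individuals, cfg.n_loci, cfg.n_pops
    # deme centers and individual placement (clipped into the grid)
    centers = np.column_stack([
        rng.uniform(grid.xmin + 2 * grid.cellsize, grid.xmax - 2 * grid.cellsize, P),
        rng.uniform(grid.ymin + 2 * grid.cellsize, grid.ymax - 2 * grid.cellsize, P),
    ])
    # individuals scattered over the landscape; deme = nearest center, so
    # demes are spatially coherent (Voronoi) yet every deme samples a range
    # of environments -- individual-based sampling along gradients
    xy = np.column_stack([
        rng.uniform(grid.xmin + grid.cellsize / 2, grid.xmax - grid.cellsize / 2, n),
        rng.uniform(grid.ymin + grid.cellsize / 2, grid.ymax - grid.cellsize / 2, n),
    ])
    d2c = ((xy[:, None, :] - centers[None]) ** 2).sum(-1)
    deme = np.argmin(d2c, axis=1)
    # re-index demes to 0..P'-1 in case a center captured no individual
    uniq = np.unique(deme)
    deme = np.searchsorted(uniq, deme)

    n_ad = cfg.n_adaptive_loci
    n_neut = L - n_ad
    # neutral loci: Balding-Nichols deme frequencies
    p_anc = rng.uniform(0.1, 0.9, n_neut)
    F = cfg.fst_target
    if F > 0:
        a = p_anc * (1 - F) / F
        b = (1 - p_anc) * (1 - F) / F
        deme_freq = rng.beta(a, b, size=(P, n_neut))
    else:
        deme_freq = np.tile(p_anc, (P, 1))
    logit = np.log(deme_freq / (1 - deme_freq))
    p_ind = logit[deme]  # (n, n_neut) on logit scale
    if cfg.ibd_strength > 0:
        # low-rank smooth spatial factors -> per-locus loadings
        n_fac = 3
        factors = np.stack([
            gaussian_random_field(grid.shape, cfg.corr_length / cfg.cellsize, rng)
            for _ in range(n_fac)
        ])
        row, col = grid.cell_of(xy[:, 0], xy[:, 1])
        fac_at_ind = factors[:, row, col].T  # (n, n_fac)
        loadings = rng.normal(0, cfg.ibd_strength / np.sqrt(n_fac), (n_fac, n_neut))
        p_ind = p_ind + fac_at_ind @ loadings
    p_neut = _logistic(p_ind)

    # adaptive loci: logistic clines on round-robin driver variables
    env_at_ind = env.values_at(xy[:, 0], xy[:, 1])  # (n, n_env)
    mu, sd = np.nanmean(env.values, axis=(1, 2)), np.nanstd(env.values, axis=(1, 2))
    z = (env_at_ind - mu) / sd
    drivers = np.arange(n_ad) % cfg.n_env
    if n_ad and cfg.cline_slope == 0:
        import warnings
        warnings.warn("cline_slope = 0: adaptive loci are undetectable")
    p_adapt = _logistic(cfg.cline_intercept + cfg.cline_slope * z[:, drivers])

    p_all = np.concatenate([p_neut, p_adapt], axis=1)
    g = rng.binomial(2, p_all).astype(np.int8)
    if cfg.missing_rate > 0:
        miss = rng_missing.random(g.shape) < cfg.missing_rate
        g[miss] = MISSING

    locus_ids = [f"neut_{i}" for i in range(n_neut)] + [f"adapt_{i}" for i in range(n_ad)]
    gm = GenotypeMatrix(
        g, [f"ind_{i}" for i in range(n)], locus_ids, coords=xy,
        pop_labels=[f"pop{d + 1}" for d in deme],
    )
    truth = TruthSet(
        adaptive_locus_ids=[f"adapt_{i}" for i in range(n_ad)],
        driver_variable={f"adapt_{i}": env.var_names[drivers[i]] for i in range(n_ad)},
        cluster_labels=deme.copy(),
    )
    return gm, truth


def gen_occurrences(suitability: np.ndarray, grid: GridSpec, n: int,
                    seed_or_rng=0) -> OccurrenceSet:
    """Sample occurrence cells without replacement, probability ∝ suitability.

    One record per cell, placed at the cell center.
    """
    rng = (seed_or_rng if isinstance(seed_or_rng, np.random.Generator)
           else np.random.default_rng(seed_or_rng))
    s = np.nan_to_num(np.asarray(suitability, float), nan=0.0).ravel()
    if (s < 0).any() or (s > 1).any():
        raise ValueError("suitability must lie in [0, 1]")
    pos = np.nonzero(s > 0)[0]
    if n > pos.size:
        raise ValueError(f"requested {n} occurrences but only {pos.size} "
                         "cells have positive suitability")
    idx = rng.choice(s.size, size=n, replace=False, p=s / s.sum())
    row, col = np.unravel_index(idx, grid.shape)
    xc, yc = grid.cell_centers()
    return OccurrenceSet([f"occ_{i}" for i in range(n)],
                         xc[row, col], yc[row, col], grid)


def simulate(cfg: SimConfig):
    """Full synthetic study: environments, truth, genotypes, occurrences."""
    streams = cfg.streams()
    stacks, truth = gen_landscape(cfg, streams["landscape"])
    gm, gtruth = gen_genotypes(cfg, stacks["current"], streams["genotypes"],
                               streams["missing"])
    truth.adaptive_locus_ids = gtruth.adaptive_locus_ids
    truth.driver_variable = gtruth.driver_variable
    truth.cluster_labels = gtruth.cluster_labels
    occ = gen_occurrences(truth.suitability["current"], cfg.grid,
                          cfg.n_occurrences, streams["occurrences"])
    return stacks, gm, occ, truth
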