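"""Experiment drivers: persistence, abundance vs. mean field, synchrony.

Three seed-controlled Monte-Carlo analyses of the individual-based model:

* **Persistence** — mean time to global extinction over replicate runs,
  each capped at a terminal generation (censored replicates enter the mean
  at the cap and the censored fraction is reported alongside).  A paired
  variant reruns the same replicates on the habitat-aggregated landscape to
  isolate the effect of habitat configuration (fragmentation per se).
* **Abundance** — replicate trajectories of global population size over a
  fixed horizon, with a matching stochastic Beverton-Holt mean-field
  comparator driven by the same fecundity statistics.
* **Synchrony** — the landscape is tiled into m x m sampling sites; across
  surviving replicates, final-generation local occupancy and local
  abundance are correlated between site pairs and grouped by intersite
  distance (a spatial correlogram).  Mean fecundity is first calibrated so
  the mean global population size sits in a standard window, keeping
  occupancy informative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._rng import child_rng
from .dynamics import (
    EnvParams,
    Metapopulation,
    Population,
    SpeciesParams,
    init_population,
    mean_field_trajectory,
)
from .landscape import Landscape, aggregate
from .random_fields import INF, torus_distance

__all__ = [
    "PersistenceResult",
    "PairedPersistenceResult",
    "AbundanceSeries",
    "SiteGrid",
    "SynchronyResult",
    "CalibrationResult",
    "CalibrationError",
    "run_persistence",
    "run_persistence_aggregated",
    "run_abundance",
    "build_site_grid",
    "local_occupancy",
    "local_abundance",
    "synchrony_correlogram",
    "calibrate_mu0",
]


# ---------------------------------------------------------------------------
# Persistence


@dataclass(frozen=True)
class PersistenceResult:
    """Extinction generations per replicate, censored at ``t_max``."""

    times: np.ndarray
    censored: np.ndarray
    t_max: int
    config: dict = field(default_factory=dict)

    @property
    def n_reps(self) -> int:
        return self.times.size

    @property
    def mean_time(self) -> float:
        return float(self.times.mean())

    @property
    def censored_fraction(self) -> float:
        return float(self.censored.mean())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "replicate": np.arange(self.n_reps),
                "extinction_generation": self.times,
                "censored": self.censored,
            }
        )


def run_persistence(
    landscape: Landscape,
    species: SpeciesParams,
    env: EnvParams,
    reps: int,
    t_max: int,
    seed: int,
    *,
    init_density: float = 1000 / 3600,
) -> PersistenceResult:
    """Mean time to global extinction over ``reps`` independent replicates.

    Each replicate is freshly initialized with spatially randomized
    individuals at ``init_density`` per unit area and run until no
    individual remains or generation ``t_max`` is reached (censored).
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    meta = Metapopulation(landscape, species, env)
    times = np.empty(reps, dtype=np.int64)
    censored = np.zeros(reps, dtype=bool)
    for k in range(reps):
        rng = child_rng(seed, k)
        pop = init_population(landscape, init_density, rng)
        t_ext = t_max
        if pop.n == 0:
            t_ext = 1  # sterile initial state collapses immediately
        else:
            for t in range(1, t_max + 1):
                pop = meta.step(pop, rng, generation=t)
                if pop.n == 0:
                    t_ext = t
                    break
            else:
                censored[k] = True
        times[k] = t_ext
    config = {
        "reps": reps,
        "t_max": t_max,
        "seed": seed,
        "init_density": init_density,
        "species": species,
        "env": env,
        "landscape": landscape.provenance,
    }
    return PersistenceResult(times, censored, t_max, config)


@dataclass(frozen=True)
class PairedPersistenceResult:
    """Persistence on a landscape and on its habitat-aggregated counterpart,
    run with paired replicate seeds."""

    original: PersistenceResult
    aggregated: PersistenceResult

    @property
    def ratio(self) -> float:
        """Aggregated mean persistence over original mean persistence."""
        return self.aggregated.mean_time / self.original.mean_time


def run_persistence_aggregated(
    landscape: Landscape,
    species: SpeciesParams,
    env: EnvParams,
    reps: int,
    t_max: int,
    seed: int,
    **kwargs,
) -> PairedPersistenceResult:
    """Paired persistence with and without habitat aggregation (equal cover)."""
    original = run_persistence(landscape, species, env, reps, t_max, seed, **kwargs)
    agg = run_persistence(aggregate(landscape), species, env, reps, t_max, seed, **kwargs)
    return PairedPersistenceResult(original, agg)


# ---------------------------------------------------------------------------
# Abundance and the mean-field comparator


@dataclass(frozen=True)
class AbundanceSeries:
    """Replicate abundance trajectories plus the mean-field comparator.

    ``sim`` holds individual counts, shape (reps, T+1) including the
    initial state; ``mean_field`` holds the stochastic Beverton-Holt
    trajectories on the same count scale (density times L^2).
    """

    sim: np.ndarray
    mean_field: np.ndarray
    config: dict = field(default_factory=dict)

    @property
    def n_reps(self) -> int:
        return self.sim.shape[0]

    def quasistationary_mean(self, last: int = 50) -> float:
        """Mean simulated abundance over the final ``last`` generations."""
        return float(self.sim[:, -last:].mean())

    def mean_field_quasistationary_mean(self, last: int = 50) -> float:
        return float(self.mean_field[:, -last:].mean())

    def to_frame(self) -> pd.DataFrame:
        reps, T1 = self.sim.shape
        return pd.DataFrame(
            {
                "replicate": np.repeat(np.arange(reps), T1),
                "generation": np.tile(np.arange(T1), reps),
                "n": self.sim.ravel(),
                "mean_field": self.mean_field.ravel(),
            }
        )


def run_abundance(
    landscape: Landscape,
    species: SpeciesParams,
    env: EnvParams,
    reps: int,
    generations: int,
    seed: int,
    *,
    init_count: int = 5000,
) -> AbundanceSeries:
    """Replicate abundance trajectories with a mean-field comparator.

    Under globally synchronized noise (alpha_r = inf) the comparator is
    driven by the very fecundity draws the simulation realized, giving a
    paired comparison; otherwise it draws its own global log-normal
    fecundity sequence with the same (mu0, sigma_r2).
    """
    if generations < 1:
        raise ValueError("generations must be >= 1")
    area = landscape.grid.n_cells
    h = landscape.cover
    meta = Metapopulation(landscape, species, env)
    sim = np.empty((reps, generations + 1), dtype=np.int64)
    mf = np.empty((reps, generations + 1))
    density0 = init_count / area
    for k in range(reps):
        rng = child_rng(seed, k)
        pop = init_population(landscape, density0, rng)
        counts, _, mus = meta.run(pop, generations, rng, record_mu=True)
        sim[k] = counts
        if env.alpha_r == INF:
            mu_seq = mus
        else:
            mf_rng = child_rng(seed, 10_000_000 + k)
            mu_seq = np.exp(
                env.mu0 + math.sqrt(env.sigma_r2) * mf_rng.standard_normal(generations)
            )
        mf[k] = area * mean_field_trajectory(
            density0, generations, env, h, species.b, mu_sequence=mu_seq
        )
    config = {
        "reps": reps,
        "generations": generations,
        "seed": seed,
        "init_count": init_count,
        "species": species,
        "env": env,
        "landscape": landscape.provenance,
    }
    return AbundanceSeries(sim, mf, config)


# ---------------------------------------------------------------------------
# Sampling sites, local statistics, synchrony


@dataclass(frozen=True)
class SiteGrid:
    """Partition of the lattice into contiguous m x m sampling sites."""

    m: int
    L: int
    habitat_counts: np.ndarray  # (n_side, n_side) habitat cells per site

    @property
    def n_side(self) -> int:
        return self.L // self.m

    @property
    def n_sites(self) -> int:
        return self.n_side**2

    def centers(self) -> np.ndarray:
        """(n_sites, 2) site-center coordinates on the torus."""
        c = np.arange(self.n_side) * self.m + self.m / 2.0
        rr, cc = np.meshgrid(c, c, indexing="ij")
        return np.column_stack([rr.ravel(), cc.ravel()])

    def habitat_site_mask(self) -> np.ndarray:
        """Flat boolean mask of sites containing at least one habitat cell."""
        return self.habitat_counts.ravel() > 0


def build_site_grid(landscape: Landscape, m: int) -> SiteGrid:
    """Tile the landscape into (L/m)^2 sampling sites; m must divide L."""
    L = landscape.L
    if L % m != 0:
        raise ValueError(f"site side {m} must divide landscape side {L}")
    n_side = L // m
    counts = (
        landscape.mask.reshape(n_side, m, n_side, m).sum(axis=(1, 3)).astype(np.int64)
    )
    return SiteGrid(m=m, L=L, habitat_counts=counts)


def _per_site(values: np.ndarray, m: int) -> np.ndarray:
    n_side = values.shape[0] // m
    return values.reshape(n_side, m, n_side, m).sum(axis=(1, 3))


def _cell_counts(pop: Population, L: int) -> np.ndarray:
    counts = np.zeros((L, L))
    if pop.n:
        rows = np.floor(pop.positions[:, 0]).astype(np.intp) % L
        cols = np.floor(pop.positions[:, 1]).astype(np.intp) % L
        np.add.at(counts, (rows, cols), 1.0)
    return counts


def local_occupancy(pop: Population, sites: SiteGrid, landscape: Landscape) -> np.ndarray:
    """Fraction of habitat cells occupied, per site (flat, NaN where no habitat)."""
    occupied = (_cell_counts(pop, landscape.L) > 0) & landscape.mask
    occ = _per_site(occupied.astype(float), sites.m).ravel()
    hab = sites.habitat_counts.ravel().astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(hab > 0, occ / hab, np.nan)


def local_abundance(pop: Population, sites: SiteGrid, landscape: Landscape) -> np.ndarray:
    """Occupants per habitat cell, per site (flat, NaN where no habitat).

    Satisfies sum(value * habitat cells) = N over habitat-bearing sites.
    """
    counts = _per_site(_cell_counts(pop, landscape.L), sites.m).ravel()
    hab = sites.habitat_counts.ravel().astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(hab > 0, counts / hab, np.nan)


@dataclass(frozen=True)
class SynchronyResult:
    """Distance-binned cross-replicate correlations of local statistics.

    ``pairs`` has one row per site pair falling inside a requested distance
    bin: intersite distance, occupancy correlation, abundance correlation.
    ``summary`` aggregates the bin means.  Correlations are computed across
    surviving replicates at the final generation; sites with no habitat or
    no variation across replicates are excluded.
    """

    pairs: pd.DataFrame
    summary: pd.DataFrame
    n_surviving: int
    config: dict = field(default_factory=dict)


def _pairwise_correlations(X: np.ndarray) -> np.ndarray:
    """Column-by-column Pearson correlations across rows; NaN for constant
    columns."""
    n = X.shape[0]
    Z = X - X.mean(axis=0)
    sd = Z.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        Z = np.where(sd > 0, Z / sd, np.nan)
    return (Z.T @ Z) / n


def synchrony_correlogram(
    landscape: Landscape,
    species: SpeciesParams,
    env: EnvParams,
    reps: int,
    generations: int,
    m: int,
    distance_bins: tuple[float, ...] = (2.0, 20.0),
    seed: int = 0,
    *,
    init_count: int = 5000,
    bin_halfwidth: float = 0.5,
) -> SynchronyResult:
    """Spatial correlogram of final-generation occupancy and abundance.

    Runs ``reps`` replicates for ``generations`` generations, drops those
    extinct at the end (synchrony is conditional on persistence), computes
    per-site occupancy and abundance, and correlates every habitat-bearing
    site pair across the surviving replicates.  Pairs are grouped into the
    distance bins ``[l - hw, l + hw]`` around each requested intersite
    distance.
    """
    sites = build_site_grid(landscape, m)
    meta = Metapopulation(landscape, species, env)
    density0 = init_count / landscape.grid.n_cells
    occ_rows, abd_rows = [], []
    for k in range(reps):
        rng = child_rng(seed, k)
        pop = init_population(landscape, density0, rng)
        for t in range(1, generations + 1):
            pop = meta.step(pop, rng, generation=t)
            if pop.n == 0:
                break
        if pop.n == 0:
            continue
        occ_rows.append(local_occupancy(pop, sites, landscape))
        abd_rows.append(local_abundance(pop, sites, landscape))
    n_surviving = len(occ_rows)
    if n_surviving < 2:
        raise RuntimeError(
            f"only {n_surviving} replicate(s) survived to generation "
            f"{generations}; correlations need at least 2"
        )
    keep = sites.habitat_site_mask()
    occ = np.asarray(occ_rows)[:, keep]
    abd = np.asarray(abd_rows)[:, keep]
    centers = sites.centers()[keep]

    corr_occ = _pairwise_correlations(occ)
    corr_abd = _pairwise_correlations(abd)
    dist = torus_distance(centers[:, None, :], centers[None, :, :], landscape.grid)

    i_idx, j_idx = np.triu_indices(centers.shape[0], k=1)
    d = dist[i_idx, j_idx]
    records = []
    for target in distance_bins:
        sel = np.abs(d - target) <= bin_halfwidth
        records.append(
            pd.DataFrame(
                {
                    "bin": target,
                    "site_i": i_idx[sel],
                    "site_j": j_idx[sel],
                    "distance": d[sel],
                    "occupancy_corr": corr_occ[i_idx[sel], j_idx[sel]],
                    "abundance_corr": corr_abd[i_idx[sel], j_idx[sel]],
                }
            )
        )
    pairs = pd.concat(records, ignore_index=True)
    summary = (
        pairs.groupby("bin")
        .agg(
            n_pairs=("distance", "size"),
            mean_occupancy_corr=("occupancy_corr", "mean"),
            mean_abundance_corr=("abundance_corr", "mean"),
        )
        .reset_index()
    )
    config = {
        "reps": reps,
        "generations": generations,
        "m": m,
        "distance_bins": tuple(distance_bins),
        "seed": seed,
        "init_count": init_count,
        "species": species,
        "env": env,
        "landscape": landscape.provenance,
    }
    return SynchronyResult(pairs, summary, n_surviving, config)


# ---------------------------------------------------------------------------
# Fecundity calibration


class CalibrationError(RuntimeError):
    pass


@dataclass(frozen=True)
class CalibrationResult:
    """Calibrated mean log-fecundity and the pilot mean it achieved."""

    mu0: float
    achieved_n: float
    history: tuple  # (mu0, achieved) pairs in evaluation order

    def __float__(self) -> float:
        return self.mu0


def calibrate_mu0(
    landscape: Landscape,
    species: SpeciesParams,
    env: EnvParams,
    target_n: float = 1000.0,
    band: float = 200.0,
    pilot_reps: int = 100,
    generations: int = 50,
    seed: int = 0,
    *,
    init_count: int = 5000,
    mu0_range: tuple[float, float] = (-3.0, 4.0),
    max_iter: int = 14,
    settle_frac: float = 0.5,
) -> CalibrationResult:
    """Adjust mu0 so the pilot mean final population size hits target_n +/- band.

    The pilot objective (mean of N at the final generation over
    ``pilot_reps`` replicates) is evaluated under common random numbers, so
    it is monotone increasing in mu0 over the viable range; the search is
    bracket-and-bisect.  The initial guess inverts the mean-field fixed
    point (mu = 1 / (h (1 - b n*)) at target density n*), exact under mass
    action and a serviceable starting point otherwise.

    Bisection settles only when the pilot mean is within ``settle_frac *
    band`` of the target, leaving headroom so that fresh replicates at the
    returned mu0 still land inside the full band despite pilot estimation
    error.  If bisection exhausts ``max_iter`` the best evaluation inside
    the full band is returned; failing that, a :class:`CalibrationError`
    with the evaluation history is raised.
    """
    if band <= 0:
        raise ValueError("band must be > 0")
    if not (0 < settle_frac <= 1):
        raise ValueError("settle_frac must be in (0, 1]")
    settle = settle_frac * band
    area = landscape.grid.n_cells
    density0 = init_count / area
    meta_cache: dict[float, Metapopulation] = {}
    history: list[tuple[float, float]] = []

    def achieved(mu0: float) -> float:
        env_k = replace(env, mu0=mu0)
        meta = meta_cache.setdefault(mu0, Metapopulation(landscape, species, env_k))
        total = 0.0
        for k in range(pilot_reps):
            rng = child_rng(seed, k)
            pop = init_population(landscape, density0, rng)
            for t in range(1, generations + 1):
                pop = meta.step(pop, rng, generation=t)
                if pop.n == 0:
                    break
            total += pop.n
        value = total / pilot_reps
        history.append((mu0, value))
        return value

    def done(mu0: float, value: float) -> CalibrationResult:
        return CalibrationResult(mu0, value, tuple(history))

    lo, hi = mu0_range
    f_current = achieved(env.mu0)
    if abs(f_current - target_n) <= settle:
        return done(env.mu0, f_current)

    # Mean-field inversion for a starting guess.
    h, b = landscape.cover, species.b
    n_star = target_n / area
    guess = None
    if h > 0 and 0 < b * n_star < 1:
        guess = math.log(1.0 / (h * (1.0 - b * n_star)))
        guess = min(max(guess, lo), hi)

    evals = {env.mu0: f_current}
    if guess is not None and guess not in evals:
        evals[guess] = achieved(guess)
        if abs(evals[guess] - target_n) <= settle:
            return done(guess, evals[guess])

    below = {m: v for m, v in evals.items() if v < target_n}
    above = {m: v for m, v in evals.items() if v > target_n}
    step = 0.5
    probe = max(evals) if not above else min(evals)
    while not (below and above):
        if not above:
            probe = probe + step
            if probe > hi:
                raise CalibrationError(
                    f"could not bracket target {target_n} below mu0={hi}; "
                    f"evaluations: {history}"
                )
        else:
            probe = probe - step
            if probe < lo:
                raise CalibrationError(
                    f"could not bracket target {target_n} above mu0={lo}; "
                    f"evaluations: {history}"
                )
        value = achieved(probe)
        if abs(value - target_n) <= settle:
            return done(probe, value)
        (below if value < target_n else above)[probe] = value
        step *= 1.6

    lo_b = max(below)
    hi_b = min(above)
    for _ in range(max_iter):
        mid = 0.5 * (lo_b + hi_b)
        value = achieved(mid)
        if abs(value - target_n) <= settle:
            return done(mid, value)
        if value < target_n:
            lo_b = mid
        else:
            hi_b = mid
    best_mu0, best_val = min(history, key=lambda mv: abs(mv[1] - target_n))
    if abs(best_val - target_n) <= band:
        return done(best_mu0, best_val)
    raise CalibrationError(
        f"bisection did not reach {target_n} +/- {band} in {max_iter} steps; "
        f"evaluations: {history}"
    )
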