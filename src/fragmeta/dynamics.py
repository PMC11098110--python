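"""One-generation update of the individual-based metapopulation model.

Each nonoverlapping generation proceeds through five stages, all operating
on individuals with continuous positions on the torus:

1. a fecundity field is (re)sampled: log fecundity is a Gaussian random
   field with mean ``mu0``, variance ``sigma_r2`` and spatial scale
   ``alpha_r`` (regional stochasticity; independent between generations);
2. every adult produces a Poisson(mu at its cell) number of propagules and
   dies (semelparity);
3. propagules disperse by a bivariate Gaussian kernel with covariance
   ``alpha_d^2 I`` (``alpha_d = inf`` means uniform redistribution);
4. propagules landing in the matrix die immediately;
5. survivors experience density-dependent establishment with probability
   ``e_i = 1 / (1 + b * n_i)``, where the local propagule density ``n_i``
   is the propagule count field convolved (circularly) with a discretized
   Gaussian competition kernel of scale ``alpha_c`` normalized to sum 1.

With ``alpha = inf`` the model collapses to mass action and its expected
dynamics follow the stochastic Beverton-Holt map
``N_{t+1} = N_t mu_t h / (1 + b N_t mu_t h)`` (densities per unit area),
implemented here as :func:`mean_field_step`.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .landscape import Landscape
from .random_fields import INF, CovarianceSpec, GRFSampler, TorusGrid

__all__ = [
    "SpeciesParams",
    "EnvParams",
    "Population",
    "FecundityField",
    "Metapopulation",
    "sample_fecundity_field",
    "reproduce",
    "disperse",
    "filter_matrix",
    "local_density",
    "establish",
    "step_generation",
    "init_population",
    "mean_field_step",
    "mean_field_trajectory",
    "simulate",
]


@dataclass(frozen=True)
class SpeciesParams:
    """Species traits: dispersal scale, competition scale, competition strength.

    ``alpha_c`` defaults to ``alpha_d`` (one spatial scale alpha governs both
    dispersal and competition); they can be decoupled for sensitivity work.
    Small alpha = "resident", large alpha = "migrant".
    """

    alpha_d: float = 1.0
    alpha_c: float | None = None
    b: float = 0.2

    def __post_init__(self) -> None:
        if self.alpha_c is None:
            object.__setattr__(self, "alpha_c", self.alpha_d)
        if not (self.alpha_d > 0):
            raise ValueError(f"alpha_d must be > 0 (or inf), got {self.alpha_d!r}")
        if not (self.alpha_c > 0):
            raise ValueError(f"alpha_c must be > 0 (or inf), got {self.alpha_c!r}")
        if not (self.b >= 0):
            raise ValueError(f"b must be >= 0, got {self.b!r}")


@dataclass(frozen=True)
class EnvParams:
    """Regional stochasticity: log-fecundity mean, variance and spatial scale.

    ``mu0`` is the mean of log fecundity (so median fecundity is
    exp(mu0) = 1.1 at the default); no -sigma^2/2 correction is applied.
    ``alpha_r = inf`` is globally synchronized noise: one shared draw per
    generation.  ``sigma_r2 = 0`` is a deterministic environment.
    """

    mu0: float = math.log(1.1)
    sigma_r2: float = 0.5
    alpha_r: float = INF

    def __post_init__(self) -> None:
        if not (self.sigma_r2 >= 0):
            raise ValueError(f"sigma_r2 must be >= 0, got {self.sigma_r2!r}")
        if not (self.alpha_r > 0):
            raise ValueError(f"alpha_r must be > 0 (or inf), got {self.alpha_r!r}")


@dataclass(frozen=True)
class Population:
    """Adults as continuous positions (N, 2) in [0, L)^2 on the torus."""

    positions: np.ndarray

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float).reshape(-1, 2)
        pos.setflags(write=False)
        object.__setattr__(self, "positions", pos)

    @property
    def n(self) -> int:
        return self.positions.shape[0]

    @classmethod
    def empty(cls) -> "Population":
        return cls(np.empty((0, 2)))


@dataclass(frozen=True)
class FecundityField:
    """Per-cell fecundity mu(x) > 0, resampled each generation."""

    mu: np.ndarray
    generation: int = 0

    @property
    def global_mean(self) -> float:
        return float(self.mu.mean())


def _cells(positions: np.ndarray, L: int) -> tuple[np.ndarray, np.ndarray]:
    rows = np.floor(positions[:, 0]).astype(np.intp) % L
    cols = np.floor(positions[:, 1]).astype(np.intp) % L
    return rows, cols


def sample_fecundity_field(
    env: EnvParams, grid: TorusGrid, rng: np.random.Generator, generation: int = 0
) -> FecundityField:
    """log mu(x) = mu0 + g(x) with g a zero-mean GRF(sigma_r2, alpha_r)."""
    g = GRFSampler(CovarianceSpec(scale=env.alpha_r, variance=env.sigma_r2), grid).sample(rng)
    return FecundityField(np.exp(env.mu0 + g), generation)


def reproduce(
    pop: Population, fec: FecundityField, grid: TorusGrid, rng: np.random.Generator
) -> np.ndarray:
    """Poisson offspring per adult; returns propagule start positions (P, 2).

    Each adult draws Poisson(mu at its own cell) propagules, all initially
    at the parent position; the semelparous adult then dies.
    """
    if pop.n == 0:
        return np.empty((0, 2))
    rows, cols = _cells(pop.positions, grid.L)
    counts = rng.poisson(fec.mu[rows, cols])
    return np.repeat(pop.positions, counts, axis=0)


def disperse(
    propagules: np.ndarray, alpha_d: float, grid: TorusGrid, rng: np.random.Generator
) -> np.ndarray:
    """Bivariate Gaussian displacement of scale alpha_d, wrapped on the torus.

    ``alpha_d = inf`` redistributes every propagule uniformly over the
    whole landscape (mass-action dispersal).
    """
    P = propagules.shape[0]
    if P == 0:
        return propagules.reshape(0, 2)
    if alpha_d == INF:
        return rng.uniform(0.0, grid.L, size=(P, 2))
    return np.mod(propagules + rng.normal(0.0, alpha_d, size=(P, 2)), grid.L)


def filter_matrix(positions: np.ndarray, landscape: Landscape) -> np.ndarray:
    """Keep only propagules whose containing cell is habitat."""
    if positions.shape[0] == 0:
        return positions.reshape(0, 2)
    rows, cols = _cells(positions, landscape.L)
    return positions[landscape.mask[rows, cols]]


def _competition_kernel(alpha_c: float, grid: TorusGrid) -> np.ndarray:
    """Gaussian kernel discretized at cell centers on min-image lags, sum 1."""
    L = grid.L
    k = np.arange(L)
    axis = np.minimum(k, L - k).astype(float)
    sq = axis[:, None] ** 2 + axis[None, :] ** 2
    kernel = np.exp(-sq / (2.0 * alpha_c**2))
    return kernel / kernel.sum()


def local_density(
    positions: np.ndarray,
    alpha_c: float,
    landscape: Landscape,
    *,
    _kernel_fft: np.ndarray | None = None,
) -> np.ndarray:
    """Per-propagule local density n_i (propagules per unit area).

    Propagules are binned to cells; the count field is circularly convolved
    with the normalized competition kernel and read back at each propagule's
    cell.  ``alpha_c = inf`` is global density: total survivors divided by
    the landscape area L^2 (the exact limit of the normalized kernel, and
    the convention under which the mass-action model reproduces the
    Beverton-Holt mean-field map for any habitat cover).
    """
    P = positions.shape[0]
    L = landscape.L
    if P == 0:
        return np.empty(0)
    if alpha_c == INF:
        return np.full(P, P / landscape.grid.n_cells)
    rows, cols = _cells(positions, L)
    counts = np.zeros((L, L))
    np.add.at(counts, (rows, cols), 1.0)
    if _kernel_fft is None:
        _kernel_fft = np.fft.rfft2(_competition_kernel(alpha_c, landscape.grid))
    density = np.fft.irfft2(np.fft.rfft2(counts) * _kernel_fft, s=(L, L))
    return density[rows, cols]


def establish(
    positions: np.ndarray, densities: np.ndarray, b: float, rng: np.random.Generator
) -> Population:
    """Independent Bernoulli establishment with e_i = 1 / (1 + b * n_i)."""
    if positions.shape[0] == 0:
        return Population.empty()
    e = 1.0 / (1.0 + b * densities)
    keep = rng.random(positions.shape[0]) < e
    return Population(positions[keep])


class Metapopulation:
    """Bound simulator: landscape + species + environment with precomputed
    kernels, exposing the one-generation update and full runs.

    All randomness comes from the single generator passed to each call,
    consumed in a fixed stage order (fecundity field, Poisson reproduction,
    dispersal, establishment), so runs are bit-reproducible from the seed.
    """

    def __init__(self, landscape: Landscape, species: SpeciesParams, env: EnvParams):
        self.landscape = landscape
        self.species = species
        self.env = env
        self.grid = landscape.grid
        self._fec_sampler = GRFSampler(
            CovarianceSpec(scale=env.alpha_r, variance=env.sigma_r2), self.grid
        )
        if species.alpha_c != INF:
            self._kernel_fft = np.fft.rfft2(
                _competition_kernel(species.alpha_c, self.grid)
            )
        else:
            self._kernel_fft = None
        self.last_mu: float = math.nan  # realized spatial-mean fecundity

    def sample_fecundity(self, rng: np.random.Generator, generation: int = 0) -> FecundityField:
        g = self._fec_sampler.sample(rng)
        return FecundityField(np.exp(self.env.mu0 + g), generation)

    def step(self, pop: Population, rng: np.random.Generator, generation: int = 0) -> Population:
        fec = self.sample_fecundity(rng, generation)
        self.last_mu = fec.global_mean
        if pop.n == 0:
            return Population.empty()  # extinction is absorbing
        props = reproduce(pop, fec, self.grid, rng)
        props = disperse(props, self.species.alpha_d, self.grid, rng)
        props = filter_matrix(props, self.landscape)
        dens = local_density(
            props, self.species.alpha_c, self.landscape, _kernel_fft=self._kernel_fft
        )
        return establish(props, dens, self.species.b, rng)

    def run(
        self,
        pop: Population,
        generations: int,
        rng: np.random.Generator,
        *,
        stop_on_extinction: bool = False,
        record_mu: bool = False,
    ):
        """Iterate ``step``; returns (abundance series, final population[, mu series]).

        The abundance series has length generations + 1 and starts with the
        initial count.  With ``stop_on_extinction`` the loop ends at the
        first extinct generation (the series is truncated there).
        """
        counts = [pop.n]
        mus = []
        for t in range(1, generations + 1):
            pop = self.step(pop, rng, generation=t)
            counts.append(pop.n)
            if record_mu:
                mus.append(self.last_mu)
            if stop_on_extinction and pop.n == 0:
                break
        out = (np.array(counts), pop)
        return out + (np.array(mus),) if record_mu else out


def step_generation(
    pop: Population,
    landscape: Landscape,
    species: SpeciesParams,
    env: EnvParams,
    rng: np.random.Generator,
) -> Population:
    """One generation: fecundity -> reproduce -> disperse -> matrix filter ->
    local density -> establish.  Extinction (N=0) is absorbing."""
    return Metapopulation(landscape, species, env).step(pop, rng)


def init_population(
    landscape: Landscape, density: float, rng: np.random.Generator
) -> Population:
    """Spatially randomized initial adults at a given density per unit area.

    The count is round(density * L^2); individuals are placed on uniformly
    chosen habitat cells (matrix placement would be instant death), uniform
    within each cell.
    """
    if density < 0:
        raise ValueError("density must be >= 0")
    n = int(round(density * landscape.grid.n_cells))
    if n == 0:
        return Population.empty()
    cells = landscape.habitat_cells()
    if cells.shape[0] == 0:
        warnings.warn("landscape has no habitat; returning an empty population")
        return Population.empty()
    picks = cells[rng.integers(0, cells.shape[0], size=n)]
    return Population(picks + rng.random((n, 2)))


def mean_field_step(N: float, mu_t: float, h: float, b: float) -> float:
    """Stochastic Beverton-Holt map N_{t+1} = N mu h / (1 + b N mu h).

    ``N`` is the global population density per unit area; ``mu_t`` the
    realized fecundity of generation t; ``h`` the habitat cover.
    """
    g = N * mu_t * h
    return g / (1.0 + b * g)


def mean_field_trajectory(
    N0: float,
    generations: int,
    env: EnvParams,
    h: float,
    b: float,
    rng: np.random.Generator | None = None,
    mu_sequence: np.ndarray | None = None,
) -> np.ndarray:
    """Iterate the stochastic mean-field map for ``generations`` steps.

    Either pass a realized fecundity sequence (for paired comparison with a
    simulation) or a generator from which log mu_t ~ Normal(mu0, sigma_r2)
    is drawn per step.  Returns densities of length generations + 1.
    """
    if mu_sequence is None:
        if rng is None:
            raise ValueError("provide either mu_sequence or rng")
        mu_sequence = np.exp(
            env.mu0 + math.sqrt(env.sigma_r2) * rng.standard_normal(generations)
        )
    out = np.empty(generations + 1)
    out[0] = N = N0
    for t in range(generations):
        N = mean_field_step(N, float(mu_sequence[t]), h, b)
        out[t + 1] = N
    return out


def mean_field_fixed_point(mu: float, h: float, b: float) -> float:
    """Positive equilibrium density (mu h - 1) / (b mu h); 0 if mu h <= 1."""
    g = mu * h
    return max(0.0, (g - 1.0) / (b * g)) if g > 0 else 0.0


def simulate(
    landscape: Landscape,
    species: SpeciesParams,
    env: EnvParams,
    generations: int,
    rng: np.random.Generator,
    *,
    init_density: float = 1000 / 3600,
    stop_on_extinction: bool = False,
    record_mu: bool = False,
):
    """Initialize and run one replicate; see :meth:`Metapopulation.run`."""
    meta = Metapopulation(landscape, species, env)
    pop = init_population(landscape, init_density, rng)
    return meta.run(
        pop,
        generations,
        rng,
        stop_on_extinction=stop_on_extinction,
        record_mu=record_mu,
    )
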