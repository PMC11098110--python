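"""Individual-based one-generation update and the mean-field map."""

import math

import numpy as np
import pytest
from scipy.stats import chisquare

from fragmeta import (
    EnvParams,
    Metapopulation,
    Population,
    SpeciesParams,
    TorusGrid,
    disperse,
    establish,
    filter_matrix,
    init_population,
    local_density,
    make_fragmented,
    make_homogeneous,
    mean_field_fixed_point,
    mean_field_step,
    reproduce,
    sample_fecundity_field,
    step_generation,
)
from fragmeta.dynamics import FecundityField, _competition_kernel

LOG11 = math.log(1.1)


class TestFecundityField:
    def test_noise_free_limit_is_constant(self, rng):
        f = sample_fecundity_field(EnvParams(mu0=LOG11, sigma_r2=0.0), TorusGrid(10), rng)
        np.testing.assert_allclose(f.mu, 1.1)

    def test_global_noise_shares_one_draw_with_lognormal_moments(self, rng):
        env = EnvParams(mu0=LOG11, sigma_r2=0.5, alpha_r=math.inf)
        grid = TorusGrid(8)
        logs = []
        for _ in range(2000):
            f = sample_fecundity_field(env, grid, rng)
            assert np.ptp(f.mu) == 0.0
            logs.append(math.log(f.mu[0, 0]))
        logs = np.array(logs)
        assert abs(logs.mean() - LOG11) < 4 * math.sqrt(0.5 / 2000)
        assert logs.var() == pytest.approx(0.5, rel=0.1)

    def test_spatial_covariance_of_log_fecundity(self):
        env = EnvParams(mu0=LOG11, sigma_r2=0.5, alpha_r=1.5)
        grid = TorusGrid(16)
        rng = np.random.default_rng(9)
        fields = np.array(
            [np.log(sample_fecundity_field(env, grid, rng).mu) - LOG11 for _ in range(1500)]
        )
        cov_axis3 = (fields * np.roll(fields, 3, axis=2)).mean()
        cov_diag = (fields * np.roll(np.roll(fields, 1, axis=1), 1, axis=2)).mean()
        assert cov_axis3 == pytest.approx(0.5 * math.exp(-3 / 1.5), abs=0.05)
        assert cov_diag == pytest.approx(0.5 * math.exp(-math.sqrt(2) / 1.5), abs=0.05)


class TestReproduce:
    def test_empty_population_no_propagules(self, rng):
        grid = TorusGrid(6)
        field = FecundityField(np.full((6, 6), 1.1))
        assert reproduce(Population.empty(), field, grid, rng).shape == (0, 2)

    def test_poisson_mean_matches_fecundity(self, rng):
        grid = TorusGrid(10)
        n = 100_000
        pop = Population(rng.uniform(0, 10, size=(n, 2)))
        field = FecundityField(np.full((10, 10), 1.1))
        props = reproduce(pop, field, grid, rng)
        se = math.sqrt(1.1 / n)
        assert props.shape[0] / n == pytest.approx(1.1, abs=3 * se)

    def test_vanishing_fecundity_sterilizes(self, rng):
        grid = TorusGrid(10)
        pop = Population(rng.uniform(0, 10, size=(1000, 2)))
        field = FecundityField(np.full((10, 10), 1e-12))
        assert reproduce(pop, field, grid, rng).shape[0] == 0


class TestDisperse:
    def test_degenerate_kernel_keeps_positions(self, rng):
        grid = TorusGrid(20)
        start = rng.uniform(0, 20, size=(500, 2))
        moved = disperse(start, 1e-12, grid, rng)
        np.testing.assert_allclose(moved, start, atol=1e-9)

    def test_displacement_variance(self, rng):
        grid = TorusGrid(60)
        n = 100_000
        start = rng.uniform(0, 60, size=(n, 2))
        moved = disperse(start, 2.0, grid, rng)
        delta = (moved - start + 30) % 60 - 30  # unwrapped displacement
        assert delta.var() == pytest.approx(4.0, rel=0.02)

    def test_infinite_scale_is_uniform(self, rng):
        grid = TorusGrid(60)
        moved = disperse(np.zeros((100_000, 2)), math.inf, grid, rng)
        cells = np.floor(moved[:, 0]).astype(int) * 60 + np.floor(moved[:, 1]).astype(int)
        counts = np.bincount(cells, minlength=3600)
        assert chisquare(counts).pvalue > 0.01


class TestFilterMatrix:
    def test_homogeneous_keeps_all(self, rng):
        land = make_homogeneous(12)
        pts = rng.uniform(0, 12, size=(400, 2))
        assert filter_matrix(pts, land).shape[0] == 400

    def test_no_habitat_keeps_none(self, rng):
        from fragmeta import Landscape

        land = Landscape(TorusGrid(12), np.zeros((12, 12), dtype=bool))
        pts = rng.uniform(0, 12, size=(400, 2))
        assert filter_matrix(pts, land).shape[0] == 0

    def test_matches_per_propagule_lookup(self, rng):
        land = make_fragmented(16, 2.0, 0.5, rng)
        pts = rng.uniform(0, 16, size=(1000, 2))
        kept = filter_matrix(pts, land)
        expected = [p for p in pts if land.mask[int(p[0]) % 16, int(p[1]) % 16]]
        assert kept.shape[0] == len(expected)
        np.testing.assert_allclose(kept, np.array(expected).reshape(-1, 2))


def brute_force_density(positions, alpha_c, landscape):
    """O(P^2) pairwise kernel sum over propagule cells (oracle)."""
    L = landscape.L
    kernel = _competition_kernel(alpha_c, landscape.grid)
    cells = np.floor(positions).astype(int) % L
    out = np.empty(len(positions))
    for i, (ri, ci) in enumerate(cells):
        lags_r = (cells[:, 0] - ri) % L
        lags_c = (cells[:, 1] - ci) % L
        out[i] = kernel[lags_r, lags_c].sum()
    return out


class TestLocalDensity:
    def test_single_propagule_sees_lag_zero_weight(self):
        land = make_homogeneous(16)
        pts = np.array([[4.5, 9.5]])
        kernel = _competition_kernel(2.0, land.grid)
        assert local_density(pts, 2.0, land)[0] == pytest.approx(kernel[0, 0])

    @pytest.mark.parametrize("alpha_c", [1.0, 2.0, 5.0])
    def test_fft_matches_brute_force(self, alpha_c, rng):
        land = make_homogeneous(16)
        pts = rng.uniform(0, 16, size=(300, 2))
        fft_density = local_density(pts, alpha_c, land)
        np.testing.assert_allclose(
            fft_density, brute_force_density(pts, alpha_c, land), atol=1e-8
        )

    def test_uniform_one_per_cell_gives_unit_density(self):
        land = make_homogeneous(12)
        pts = np.stack(np.meshgrid(np.arange(12) + 0.5, np.arange(12) + 0.5), -1).reshape(-1, 2)
        np.testing.assert_allclose(local_density(pts, 3.0, land), 1.0)

    def test_infinite_scale_is_global_density(self):
        land = make_homogeneous(10)
        pts = np.zeros((37, 2)) + 0.5
        np.testing.assert_allclose(local_density(pts, math.inf, land), 37 / 100)


class TestEstablish:
    def test_zero_density_always_establishes(self, rng):
        pts = rng.uniform(0, 10, size=(500, 2))
        pop = establish(pts, np.zeros(500), 0.2, rng)
        assert pop.n == 500

    def test_expected_survivors(self, rng):
        n = 10_000
        pts = rng.uniform(0, 10, size=(n, 2))
        dens = np.full(n, 5.0)
        pop = establish(pts, dens, 0.2, rng)  # e_i = 1/(1+0.2*5) = 0.5
        se = math.sqrt(n * 0.5 * 0.5)
        assert abs(pop.n - 0.5 * n) < 3 * se


class TestStepGeneration:
    def test_extinction_is_absorbing(self, rng):
        land = make_homogeneous(8)
        out = step_generation(
            Population.empty(), land, SpeciesParams(), EnvParams(), rng
        )
        assert out.n == 0

    def test_branching_mean_without_competition(self):
        # b=0, sigma=0, homogeneous: E[N1] = N0 * exp(mu0)
        land = make_homogeneous(20)
        species = SpeciesParams(alpha_d=1.0, b=0.0)
        env = EnvParams(mu0=LOG11, sigma_r2=0.0)
        meta = Metapopulation(land, species, env)
        n0, reps = 2000, 200
        totals = []
        rng = np.random.default_rng(21)
        pop0 = init_population(land, n0 / 400, rng)
        for _ in range(reps):
            totals.append(meta.step(pop0, rng).n)
        se = math.sqrt(n0 * 1.1 / reps)  # Poisson-sum variance
        assert np.mean(totals) == pytest.approx(n0 * 1.1, abs=3 * se)

    def test_mass_action_one_step_matches_mean_field(self):
        land = make_homogeneous(30)
        species = SpeciesParams(alpha_d=math.inf, b=0.2)
        env = EnvParams(mu0=LOG11, sigma_r2=0.0)
        meta = Metapopulation(land, species, env)
        area = 900
        rng = np.random.default_rng(33)
        pop0 = init_population(land, 500 / area, rng)
        outcomes = np.array([meta.step(pop0, rng).n for _ in range(500)])
        expected = area * mean_field_step(500 / area, 1.1, 1.0, 0.2)
        se = outcomes.std(ddof=1) / math.sqrt(500)
        assert outcomes.mean() == pytest.approx(expected, abs=3 * se)

    def test_pipeline_counts_monotone_and_on_habitat(self, fragmented60):
        from fragmeta.dynamics import _cells

        species = SpeciesParams(alpha_d=2.0, b=0.2)
        env = EnvParams(mu0=1.0, sigma_r2=0.5, alpha_r=6.0)
        meta = Metapopulation(fragmented60, species, env)
        rng = np.random.default_rng(4)
        pop = init_population(fragmented60, 0.5, rng)
        fec = meta.sample_fecundity(rng)
        props = reproduce(pop, fec, fragmented60.grid, rng)
        landed = disperse(props, species.alpha_d, fragmented60.grid, rng)
        survivors = filter_matrix(landed, fragmented60)
        dens = local_density(survivors, species.alpha_c, fragmented60)
        nxt = establish(survivors, dens, species.b, rng)
        assert nxt.n <= survivors.shape[0] <= landed.shape[0] == props.shape[0]
        rows, cols = _cells(nxt.positions, 60)
        assert fragmented60.mask[rows, cols].all()

    def test_bit_reproducible_from_seed(self, fragmented60):
        species = SpeciesParams(alpha_d=2.0, b=0.2)
        env = EnvParams(mu0=1.0, sigma_r2=0.5, alpha_r=6.0)
        runs = []
        for _ in range(2):
            rng = np.random.default_rng(99)
            pop = init_population(fragmented60, 0.5, rng)
            pop = step_generation(pop, fragmented60, species, env, rng)
            runs.append(pop.positions)
        assert np.array_equal(runs[0], runs[1])


class TestInitPopulation:
    def test_counts_scale_with_total_area(self, rng, fragmented60):
        assert init_population(make_homogeneous(60), 1000 / 3600, rng).n == 1000
        assert init_population(fragmented60, 5000 / 3600, rng).n == 5000

    def test_zero_density_empty(self, rng):
        assert init_population(make_homogeneous(10), 0.0, rng).n == 0

    def test_no_habitat_warns_and_returns_empty(self, rng):
        from fragmeta import Landscape

        land = Landscape(TorusGrid(6), np.zeros((6, 6), dtype=bool))
        with pytest.warns(UserWarning):
            pop = init_population(land, 1.0, rng)
        assert pop.n == 0

    def test_individuals_placed_on_habitat_only(self, rng, fragmented60):
        from fragmeta.dynamics import _cells

        pop = init_population(fragmented60, 0.3, rng)
        rows, cols = _cells(pop.positions, 60)
        assert fragmented60.mask[rows, cols].all()


class TestMeanField:
    def test_extinction_fixed_point(self):
        assert mean_field_step(0.0, 1.1, 1.0, 0.2) == 0.0

    def test_positive_fixed_point(self):
        n_star = mean_field_fixed_point(1.1, 1.0, 0.2)
        assert n_star == pytest.approx((1.1 - 1) / (0.2 * 1.1))
        assert mean_field_step(n_star, 1.1, 1.0, 0.2) == pytest.approx(n_star)

    def test_subcritical_growth_decays_monotonically(self):
        n = 0.5
        for _ in range(50):
            nxt = mean_field_step(n, 1.1, 0.5, 0.2)  # mu*h = 0.55 <= 1
            assert nxt < n
            n = nxt
        assert n < 1e-6


class TestParamValidation:
    @pytest.mark.parametrize(
        "kwargs", [{"alpha_d": 0}, {"alpha_d": -1}, {"b": -0.1}, {"alpha_c": -2}]
    )
    def test_species_params(self, kwargs):
        with pytest.raises(ValueError):
            SpeciesParams(**kwargs)

    @pytest.mark.parametrize("kwargs", [{"sigma_r2": -1}, {"alpha_r": 0}])
    def test_env_params(self, kwargs):
        with pytest.raises(ValueError):
            EnvParams(**kwargs)

    def test_alpha_c_defaults_to_alpha_d(self):
        assert SpeciesParams(alpha_d=3.0).alpha_c == 3.0
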