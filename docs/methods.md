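# Methods

## The model

`fragmeta` simulates a metapopulation of sessile, semelparous individuals
with continuous positions on an L × L lattice with periodic boundaries
(a torus; cell spacing and cell area are 1). The landscape is a boolean
habitat mask; everything outside habitat is hostile matrix. Each
nonoverlapping generation applies, in order:

1. **Environment.** A fecundity field is resampled: log μ(x) = μ₀ + g(x),
   where g is a zero-mean Gaussian random field with variance σ²ᵣ and
   exponential correlation exp(−d/αᵣ) in the minimum-image distance d
   ("regional stochasticity"). αᵣ = ∞ means one global draw per
   generation (fully synchronized environments); σ²ᵣ = 0 means a constant
   environment. Noise is independent between generations.
2. **Reproduction.** Each adult produces Poisson(μ at its cell) propagules
   at its own position, then dies.
3. **Dispersal.** Each propagule is displaced by an isotropic bivariate
   Gaussian with per-axis standard deviation α_d, wrapped on the torus.
   α_d = ∞ redistributes propagules uniformly over the landscape.
4. **Matrix mortality.** Propagules whose landing cell is matrix die.
5. **Establishment.** Each survivor establishes with probability
   eᵢ = 1/(1 + b·nᵢ), where nᵢ is the local propagule density: the
   per-cell propagule counts circularly convolved with a discretized
   Gaussian kernel of scale α_c normalized to sum 1 (so nᵢ is propagules
   per unit area). By default α_c = α_d ≡ α: one spatial scale governs
   both dispersal and competition; the two can be decoupled for
   sensitivity analyses.

Extinction (N = 0) is absorbing. With α = ∞ the model is mass action and
its expected dynamics follow the stochastic Beverton–Holt map

    N_{t+1} = N_t μ_t h / (1 + b N_t μ_t h),

with N the global density per unit area, h the habitat cover, and
log μ_t ~ Normal(μ₀, σ²ᵣ). This map is implemented as the mean-field
comparator for the abundance analysis.

## Key parameters

| parameter | meaning | unit | default |
|---|---|---|---|
| L | lattice side | cells | 60 |
| h | habitat cover | proportion | by construction |
| α_e | landscape correlation scale | cells | 3 |
| α_d, α_c | dispersal / competition scale | cells | 1 (= "resident"); ∞ = "migrant" |
| b | competition strength | per unit density | 0.2 |
| μ₀ | mean log fecundity | — | ln(1.1) |
| σ²ᵣ | environmental-noise variance | — | 0.5 |
| αᵣ | noise correlation scale | cells | ∞ |

μ₀ is the mean of **log** fecundity, so exp(μ₀) = 1.1 is the median
fecundity; no −σ²/2 correction is applied. The alternative reading (μ₀ as
the arithmetic mean of μ) would make the default mean fecundity ≈ 0.095,
which cannot sustain any population; the log-scale convention is the only
ecologically coherent one.

## Gaussian random fields

Landscape heterogeneity and regional stochasticity share one sampler.
On a torus the exponential-covariance field is a circulant Gaussian
process, so it is sampled *exactly* by spectral synthesis: the 2-D DFT of
the covariance at all minimum-image lags is the eigenvalue spectrum;
white noise filtered through its square root has exactly the target
covariance, at O(L² log L) per draw. Wrapping can in principle make the
covariance indefinite; any negative eigenvalues are clamped to zero. At
the scales used here (α = 1.5–9 on L ≥ 32) the clamped mass is zero to
machine precision, so no approximation is actually incurred; the test
suite records this as a regression value. α = ∞ is a dedicated branch
(one global Normal(0, σ²) draw), not a large-scale approximation.

## Landscapes

* **Homogeneous** — all habitat.
* **Fragmented** — habitat where a unit-variance GRF with scale α_e
  exceeds a threshold; expected cover 1 − Φ(threshold) (≈ 0.136 at 1.1,
  ≈ 0.309 at 0.5). The inequality direction is exposed as an argument
  (default ">"), since the upper tail is what yields covers in the 0.10–0.30
  range at these thresholds.
* **Regular grid** — one patch_side² patch per spacing² block; spacing
  must divide L so patches stay equidistant under wrap. (1, 3) on L = 60
  gives 400 unit patches and 11.1% cover.
* **Subsample** — a size × size window at a uniform (wrapping) offset,
  returned as a fresh torus; used to study landscape-area effects.
* **Aggregate** — all H habitat cells re-packed row-major into a block of
  side ⌈√H⌉ anchored at (0, 0), last row partial: deterministic,
  area-preserving, compact up to one partial row. On a torus any
  placement is equivalent up to translation. Comparing a landscape
  with its aggregated counterpart isolates habitat *configuration*
  (fragmentation per se) at fixed habitat amount.

## Conventions and numerical choices

* **Fecundity is evaluated at the parent's cell** (reproduction precedes
  dispersal); the landing-site alternative would entangle dispersal with
  environment sampling.
* **Global density denominator.** For α_c = ∞ the density is
  (surviving propagules)/L², i.e. per unit of *total* landscape area.
  This is the exact limit of the normalized competition kernel as
  α_c → ∞, and it makes the mass-action simulation reproduce the
  Beverton–Holt map above for any cover h, not only h = 1 (with a
  habitat-area denominator the map's h would appear in the numerator but
  not the denominator). The equivalence is verified by a paired test at
  500 replicates.
* **Initial populations** are spatially randomized on habitat cells only
  (matrix placement would be death at t = 0), uniform within the cell;
  the count is round(density × L²), so the printed per-unit-area
  densities (1,000/3,600 and 5,000/3,600 on L = 60) give exactly 1,000
  and 5,000 individuals.
* **Establishment draws** are independent Bernoulli given the realized
  densities; eᵢ depends only on nᵢ, with no sequential depletion.
* **RNG.** One `numpy` generator per replicate, derived as
  `SeedSequence((seed, k))` for replicate k, consumed in a fixed stage
  order; every run is bit-reproducible from (config, seed) and any
  replicate can be regenerated in isolation.

## Experiment drivers

* **Persistence** (`run_persistence`): replicates run until extinction or
  a terminal generation T_max (default 5 × 10⁵). Censored replicates
  enter the mean at T_max and the censored fraction is always reported
  alongside — the mean is therefore a lower bound when censoring occurs.
  The paired variant reruns the same replicate seeds on the aggregated
  landscape and reports both means and their ratio.
* **Abundance** (`run_abundance`): full trajectories plus the stochastic
  mean-field comparator. Under αᵣ = ∞ the comparator consumes the very
  fecundity sequence the simulation realized (a paired design that
  removes environmental variance from the comparison); otherwise it draws
  its own global log-normal sequence with the same (μ₀, σ²ᵣ).
  Quasistationary summaries use the final 50 generations.
* **Synchrony** (`synchrony_correlogram`): the landscape is tiled into
  contiguous m × m sites; per site, local occupancy is occupied habitat
  cells / habitat cells and local abundance is occupants / habitat cells
  (so abundance × habitat cells sums to N). Site values at the final
  generation are correlated across surviving replicates (replicates
  extinct at the horizon are dropped — an all-zero replicate carries no
  synchrony information); pairs are grouped into distance bins
  [l − ½, l + ½] around the requested intersite distances, with
  distances measured between site centers on the torus. Sites without
  habitat, and sites constant across replicates, are excluded.
* **Calibration** (`calibrate_mu0`): adjusts μ₀ so the pilot mean final
  population size lands in target ± band (default 1,000 ± 200). The
  objective is evaluated under common random numbers (monotone in μ₀),
  bracketed by expanding steps and bisected. The initial guess inverts
  the mean-field fixed point: μ = 1/(h(1 − b n\*)) at the target density
  n\*. Bisection settles only once the pilot mean is within
  `settle_frac × band` (default ½) of the target, leaving headroom so
  fresh replicates at the returned μ₀ still fall inside the full band
  despite pilot estimation error.

## What the generator emulates — and what it does not

The synthetic landscapes and noise fields reproduce the *statistical*
structure assumed by the model: exponentially correlated heterogeneity,
sharp habitat/matrix dichotomy, stationary isotropic noise without
temporal autocorrelation. Real landscapes have anisotropy, matrix-quality
gradients, non-Euclidean dispersal barriers and temporally autocorrelated
climate, none of which are modeled. Passing tests therefore demonstrate
internal consistency of the model and faithful implementation of its
assumptions — not predictions for any particular real landscape.

## Problem sizes

Monte-Carlo sizes in the test suite and the reproduction script are
desk-scale choices that keep every statistical check comfortably powered:
500 landscape realizations per cover distribution, 2,000 field samples
for covariance checks, 500 paired replicates for the mean-field
equivalence, 300 replicates (cap 10⁴) for the noise-ordering regression,
100 pilot + 200 fresh replicates of 50 generations for calibration.
Full-scale figure replication (3,000–5,000 iterations, cap 5 × 10⁵) is
available through the same drivers by raising `reps`/`t_max` in the
config.

## Known limitations

* Persistence means under heavy censoring reflect the cap, not the true
  expectation; interpret alongside `censored_fraction`.
* The thresholded-GRF cover is random across realizations (SD ≈ 0.03 at
  L = 60, α_e = 3); analyses conditioned on a narrow cover range should
  generate and select landscapes accordingly.
* The aggregated block is anchored rather than centred on the habitat's
  mass centroid; on a torus this is immaterial, but it would matter if
  boundary conditions were changed.
* Correlations across few surviving replicates are noisy; the driver
  refuses to correlate fewer than 2 survivors and reports the surviving
  count so users can judge precision.
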