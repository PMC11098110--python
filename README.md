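# fragmeta

Individual-based metapopulation simulation on arbitrarily fragmented
lattice landscapes.

## The problem

Classical metapopulation theory predicts how spatially disjunct
populations persist through a balance of local extinctions and
recolonizations — but it was mostly built on simple networks of discrete,
identical patches. Real fragmentation produces irregular assemblies of
variably sized, possibly contiguous habitat parcels, and conclusions
drawn from simple patch networks (e.g. that localized dispersal is bad
for persistence, or that fragmentation always desynchronizes
populations) do not necessarily carry over. `fragmeta` is for ecologists
and modellers who want to test metapopulation predictions — persistence
time, abundance, spatial synchrony — on landscape structures spanning
the whole range from homogeneous habitat to heavily fragmented mosaics,
with an individual-based model that keeps density dependence and
spatially correlated environmental stochasticity in the picture.

## The model

On an L × L lattice with periodic boundaries, each generation:
adults produce Poisson(μ(x)) propagules and die; propagules disperse by a
bivariate Gaussian kernel of scale α; those landing in the matrix die;
survivors establish with probability eᵢ = 1/(1 + b·nᵢ), where nᵢ is the
propagule density from convolution with a Gaussian competition kernel of
the same scale α. Fecundity is log-normal with mean log μ₀ and spatial
correlation σ²ᵣ·exp(−d/αᵣ) (regional stochasticity), resampled every
generation. Fragmented landscapes are built by thresholding a Gaussian
random field with correlation exp(−d/α_e). In the mass-action limit
(α = ∞) the expected dynamics reduce to the stochastic Beverton–Holt map
N_{t+1} = N_t μ_t h / (1 + b N_t μ_t h), which the package also provides
as the mean-field comparator.

Species with small α ("residents") disperse and compete locally; species
with large α ("migrants") interact over long distances. The analyses ask
which does better as fragmentation intensifies.

## Worked example

```python
import math
import numpy as np
import fragmeta as fm

# a highly fragmented landscape: unit-variance GRF, scale 3, threshold 1.1
land = fm.make_fragmented(60, alpha_e=3.0, threshold=1.1, rng=np.random.default_rng(11))
print(f"habitat cover: {land.cover:.3f}")

env = fm.EnvParams(mu0=math.log(1.1), sigma_r2=0.5, alpha_r=math.inf)
resident = fm.SpeciesParams(alpha_d=1.0, b=0.2)
migrant = fm.SpeciesParams(alpha_d=math.inf, b=0.2)

for name, sp in [("resident (alpha=1)", resident), ("migrant (alpha=inf)", migrant)]:
    res = fm.run_persistence(land, sp, env, reps=100, t_max=5000, seed=0)
    print(f"{name}: mean extinction time {res.mean_time:.1f} generations "
          f"(censored {res.censored_fraction:.0%})")

pair = fm.run_persistence_aggregated(land, resident, env, reps=100, t_max=5000, seed=0)
print(f"with habitat aggregated into one block: {pair.aggregated.mean_time:.1f} "
      f"(x{pair.ratio:.1f} longer)")
```

prints

```
habitat cover: 0.172
resident (alpha=1): mean extinction time 22.3 generations (censored 0%)
migrant (alpha=inf): mean extinction time 4.9 generations (censored 0%)
with habitat aggregated into one block: 71.2 (x3.2 longer)
```

Three readings: on this heavily fragmented landscape the locally
interacting resident persists about four times longer than the
long-ranging migrant at equal fecundity (migrants waste most propagules
in the matrix); and collecting the same amount of habitat into one
compact block (the opposite of fragmentation per se) more than triples
resident persistence. Censoring 0% means every replicate went extinct
before the cap, so the means are exact.

The same library surface drives abundance comparisons against the
mean-field model (`run_abundance`), spatial synchrony correlograms over
m × m sampling sites (`synchrony_correlogram`), and fecundity
calibration to a standard population size (`calibrate_mu0`). A CLI
mirrors it:

```sh
fragmeta generate-landscape --type fragmented --size 60 --threshold 1.1 --seed 11 --out mask.txt
fragmeta persistence --reps 100 --t-max 5000 --out persistence.csv
```

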