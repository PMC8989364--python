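# moranlottery

Individual-based Moran-lottery models of competition in temporally varying
environments: how much does it matter whether environmental variation is
periodic (seasonal) or stochastic, and whether competition is global
(supporting the storage effect) or local (not)?

The package is aimed at community ecologists and population geneticists who
want quantitative, mechanistic answers about stochasticity-induced
coexistence: mean times to extinction for two competitors, and species
richness / evenness for diverse communities limited by a finite number of
temporal niches.

## Models

**Two-species chain.** A zero-sum community of `N` individuals evolves by
elementary birth–death events (one generation = `N` events). The
log-fitness difference between the species is dichotomous,
`Δs = s0 ± γ`, switching either every `Nδ` steps (periodic) or with
per-step probability `1/(Nδ)` (stochastic; mean dwell `δ` generations).
Under **local** competition two random individuals duel, the first winning
with probability `e^{s1}/(e^{s1}+e^{s2})`; under **global** competition a
random individual dies and the slot is recruited through the
abundance-weighted lottery `n1 e^{s1}/(n1 e^{s1}+n2 e^{s2})`. Persistence
is the mean time `T(x)` until absorption at `n ∈ {0, N}`.

**Diffusion approximation.** In the annealed regime (switching much faster
than fixation) `T(x)` solves the backward equation

```
σ²(x)/2 · T″(x) + μ(x) · T′(x) = −1,   T(0) = T(1) = 0,
```

with scenario-specific drift and variance, e.g. global–stochastic
`μ = x(1−x)/N·[s0 + (g + γ²/2)(1−2x)]`,
`σ² = 2x(1−x)/N²·[1 + gNx(1−x)]` where `g ≡ δγ²/2`. The solver uses the
integrating-factor double quadrature and yields the four growth laws of
`T(N)`: `ln²N` (local–stochastic), linear (local–periodic), `N^{1/δ}`
(global–stochastic), exponential (global–periodic).

**Diverse communities.** Each species carries `Q` per-niche selection
parameters (uniform on `[−γ/2, γ/2]`, centered), new species arrive with
per-death probability `ν`, and the environment cycles (or uniformly
resamples) the niche every `Nδ` steps. Species richness `SR` and Shannon
entropy `SE = −Σ (n_j/N) ln(n_j/N)` are tracked every generation. When `Q`
exceeds the number of species, global competition and periodic forcing both
raise diversity; when species outnumber niches, global competition instead
concentrates dominance in one specialist per niche and *lowers* `SR` and
`SE`.

## Worked example

```python
from moranlottery import TwoSpeciesConfig, mte_profile, mean_absorption_time

cfg = TwoSpeciesConfig(N=600, gamma=0.25, delta=0.55, s0=0.0,
                       competition="global", environment="periodic", seed=3)
sol = mte_profile(cfg)                     # diffusion theory
mc, sem = mean_absorption_time(cfg, x0=0.5, replicates=100)  # simulation
print(f"T_GP(1/2): theory {sol.T_half:.0f}, simulation {mc:.0f} +- {sem:.0f}")
```

prints

```
T_GP(1/2): theory 3706, simulation 3271 +- 284
```

i.e. starting from equal abundances, a global-competition community of 600
individuals under seasonal forcing persists for ~3.7 thousand generations —
against ~416 for local–periodic, ~572 for global–stochastic and ~228 for
local–stochastic at the same `γ = 0.25`, `δ = 0.55` (the
`T_GP > T_GS > T_LP > T_LS` hierarchy; the Monte-Carlo mean here is within
1.5 standard errors of the theory curve).

The same machinery from the shell:

```
moranlottery mte-theory --N 600 --gamma 0.25 --delta 0.55 --scenario GP --out out/gp
moranlottery community --N 10000 --nu 0.0001 --Q 3 --gamma 0.4 --delta 0.2 \
    --generations 5000 --burn-in 1000 --seed 1 --out out/q3
moranlottery scaling --scenario GS --source theory --out out/gs-scaling
```

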