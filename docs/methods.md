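# Methods

## The two-species chain

The chain is a continuous-time Moran/lottery hybrid: the community always
holds exactly `N` individuals, time advances in elementary birth–death
events of duration `1/N` generations, and fitness of an individual with
selection parameter `s` is `e^s`. The selection difference between the two
species is dichotomous, `Δs(t) = s0 ± γ`; only the difference matters,
since both the duel probability `e^{s1}/(e^{s1}+e^{s2})` and the lottery
`n1 e^{s1}/(n1 e^{s1}+n2 e^{s2})` are invariant under a common shift of
`(s1, s2)`. The intended regime is weak mean selection, `|s0| ≪ γ`; the
engine runs for any `s0`.

Elementary step, local competition: with probability `2x(1−x)` the two
sampled individuals are heterospecific and duel; the focal species gains or
loses one individual according to the duel outcome, otherwise nothing
changes. This Bernoulli formulation reproduces the one-step expectation
`E[Δx] = 2x(1−x)(1/N)·(e^{Δs}−1)/(e^{Δs}+1)` exactly and sidesteps the
with/without-replacement ambiguity of drawing labelled individuals
(conspecific duels are abundance no-ops either way).

Elementary step, global competition: a uniform individual dies; the slot is
filled by the focal species with probability given by the lottery evaluated
at **pre-death** abundances (the lottery is written in terms of the full
community frequency), so the net transition probabilities are
`(1−x)·P1` up and `x·(1−P1)` down.

Environment: the periodic switch period is `round(Nδ)` elementary steps and
must be ≥ 1 (a dwell shorter than one elementary event is outside the
model). Stochastic dwells are geometric with per-step flip probability
`1/(Nδ)` — the discrete mechanism whose large-`Nδ` limit is the exponential
dwell law with mean `δ` generations. The environment advances *after* the
birth–death event. Replicates average over the initial environmental state:
stochastic runs start in either state with probability 1/2; periodic runs
start at a uniformly random phase of the cycle (a fixed-phase option exists
for debugging). Replicate `r` uses seed `seed + r`, so every estimate is
reproducible from its configuration.

## Drift, variance and the mean time to extinction

In the annealed regime the frequency obeys a one-dimensional diffusion. Per
elementary step:

| scenario | μ(x) | σ²(x) |
|---|---|---|
| local–periodic | `s0·x(1−x)/N` | `2x(1−x)/N²` |
| global–periodic | `x(1−x)/N·[s0 + (γ²/2)(1−2x)]` | `2x(1−x)/N²` |
| local–stochastic | `x(1−x)/N·[s0 + g(1−2x)]` | `2x(1−x)/N²·[1 + gNx(1−x)]` |
| global–stochastic | `x(1−x)/N·[s0 + (g+γ²/2)(1−2x)]` | as local–stochastic |

with `g ≡ δγ²/2`. Periodic forcing contributes nothing to the variance
(every positive half-cycle is exactly cancelled), and under local
competition the apparent `g(1−2x)` restoring drift is exactly offset by
diffusive trapping, so the net stochastic-environment effect there is purely
destabilizing. Only under global competition does the `γ²/2` term survive as
a genuine bias toward `x = 1/2` — the storage effect.

The backward equation `σ²/2·T″ + μT′ = −1`, `T(0)=T(1)=0`, is solved by the
integrating-factor double quadrature. Numerical choices:

* cell-centered grid with half-cell offsets from the endpoints (first node
  at `1/(2M)`), because `2/σ²` diverges like `1/x` there; the divergence is
  integrable and trapezoidal quadrature on the offset grid converges under
  refinement;
* the integrating-factor reference point is `x = 1/2`, keeping the
  exponentials bounded even when the `γ²/2` drift makes them grow like
  `e^{Nγ²/8}` toward the boundaries;
* one integration constant is fixed by integrating from 0 (so `T(0)=0`
  holds by construction) and the other by a single linear condition from
  `T(1)=0`; both integrals share one quadrature grid so discretization bias
  cancels in the ratio;
* grids are doubled until the interior solution changes by < 1 % in
  relative terms. "Interior" means `x ∈ [1/N, 1−1/N]`: below one-individual
  resolution the continuum `T` has no discrete counterpart and the local
  quadrature error there is self-similar under refinement, while the
  physical interior converges to ~1e−7 against the neutral closed form
  `T = −N[x ln x + (1−x) ln(1−x)]`.

For small systems the diffusion approximation carries a finite-`N` error of
a few percent (≈ 3–4 % at `N = 20`); the test suite pins it against an
exact linear solve on the product chain of abundance × environmental state.

## T-vs-N scaling classification

Four transformed-linear regressions (`T` vs `ln²N`, `T` vs `N`, `ln T` vs
`ln N`, `ln T` vs `N`) are fitted and the family with maximal r² wins; ties
within 1e−6 resolve to the simpler family (linear < log-squared < power law
< exponential), since e.g. an exactly linear series is also a perfect power
law with exponent 1. Classification is invariant under rescaling `T`.

The four asymptotic classes emerge only once environmental noise dominates
demographic noise, i.e. `gN ≫ 1`. At `δ = 0.2`, `γ = 0.4` a geometric grid
`N = 500 … 16000` (6 points, factor 2) classifies all four scenarios
correctly and recovers the global–stochastic exponent `≈ 1/δ` to within
~12 %; on smaller grids (e.g. `N ≤ 3200`) the local–stochastic curve is
still pre-asymptotic and misclassifies as a shallow power law. The solver
is used for these studies (deterministic, fast at large `N`).

## The Q-niche community model

Each species carries `Q` selection parameters drawn uniformly on
`[−γ/2, γ/2]` and centered, so all species share zero mean log-fitness
across the niche cycle (entries therefore lie in `[−γ, γ]`, with per-entry
variance `γ²/12·(1−1/Q)`; for `Q = 1` the vector is identically zero).
New species enter with abundance 1 on a per-death probability `ν` — in
local mode the replacement rule applies to every duel outcome, conspecific
pairs included, and in global mode to every death. The recruitment lottery
uses pre-death abundances, mirroring the two-species convention. Extinct
species are removed; identifiers increase monotonically and are never
reused.

The environment here holds each niche for a **fixed** `round(Nδ)` steps in
both modes; periodic forcing cycles `1 … Q` in order while stochastic
forcing resamples the niche uniformly, the current niche included. (The
two-species chain, by contrast, uses geometric dwells in stochastic mode;
the two definitions are kept deliberately distinct, as each is the natural
discrete mechanism for its model.) Runs start from a single monodominant
species, and `SR`/`SE` are recorded at every generation boundary (`N`
elementary events); post-burn-in means and variances use a default
1000-generation burn-in.

Equilibration of a run is defined as the first generation at which the
trailing 200-generation mean of `SR` enters the band of ±2 long-run
standard deviations around the long-run mean *and stays there for a full
window*. The bounded look-ahead matters: excursions beyond a 2-SD band
recur indefinitely in the stationary state, so "stays inside forever" would
grow with the length of the record instead of measuring the approach to
stationarity.

## Reduced-size study conditions

The reference community experiment (global–periodic, `Q = 3`,
`N = 10000`, `γ = 0.4`, `δ = 0.2`, `ν = 1/N`) is run as a 3-seed ensemble
with a 1000-generation burn-in and a 4000-generation averaging window —
long enough that the ensemble mean of `SR` is stable to a few percent,
short enough for desk-scale runtimes.

Qualitative contrasts are checked at `N = 2000`. Because the strength of
environmental relative to demographic noise scales as `gN`, shrinking `N`
five-fold at fixed `γ` leaves the local periodic-vs-stochastic persistence
gap inside Monte-Carlo noise (measured `ΔSR = −0.01 ± 0.02` at `γ = 0.4`,
`νN = 0.05`). The low-colonization hierarchy test therefore uses `γ = 0.8`,
which restores `gN` (and the pairwise fitness spread between random
species) to the full-size regime; the large-`νN` global-vs-local crossover
and the neutral dwell-time invariance are insensitive to this and run at
`γ = 0.4` and `γ = 0`.

## What the simulations do and do not show

The generators emulate idealized communities: strictly zero-sum dynamics,
dichotomous or `Q`-state environments with a single dwell timescale,
i.i.d. uniform fitness vectors, and no spatial structure, age structure,
frequency-dependent interactions beyond the lottery, or mixtures of
periodic and stochastic forcing. Passing tests show the implementation
reproduces the mathematical models' behavior — hierarchies, scaling laws,
niche-saturation effects — not that any particular natural community obeys
them. The quenched regime (dwell times comparable to fixation times) is
outside the diffusion solver's validity; the simulation engines still run
there, but the theory curves should not be trusted in that regime.
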