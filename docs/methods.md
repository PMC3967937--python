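# Methods

## Model

A panmictic haploid Wright–Fisher population of size `N`.  Each individual
carries one linear chromosome (positions on `[0,1)`) accumulating selected
mutations at total rate `U` per genome per generation, with effects drawn
from a discrete distribution of fitness effects (DFE) `{(s_j, U_j)}`
(deleterious `s > 0` by convention); fitness is multiplicative,
`W = Π(1 - s_j)`, and log fitness is the working variable throughout.
Crossover recombination occurs at total map length `R` per genome per
generation.  Diversity is measured at an unconstrained infinite-sites locus
at the exact center of the chromosome and summarized by the site frequency
spectrum `ξ_i` for a sample of `n` individuals, with statistics `π`,
Tajima's `D`, mean minor allele frequency (MAF), and a U-shape statistic.
All predictions are functions of the population-scaled parameters `Ns`,
`NU`, `NR`; `N` enters only where absolute time matters.

Expectations and observations share one spectrum type; Tajima's `D` on an
expected spectrum uses `S = Σξ_i` with the standard sample-variance
constants (a plug-in approximation).  The U-shape statistic is the top-bin
to mid-bin ratio normalized by its neutral value,
`[ξ_{n-1}/ξ_m]/[m/(n-1)]` with `m = ⌈(n-1)/2⌉`: 1 under neutrality, > 1
when the spectrum turns up at high frequency.  The precise functional form
of such a statistic is a convention; this one was chosen because it is
computable from expected spectra, scale-free, and sign-calibrated.

## Background selection and the structured coalescent

With `R = 0` and a single effect, class-`k` frequencies are Poisson,
`h_k = e^{-λ}λ^k/k!`, `λ = U/s`.  Backward in time a lineage in class `k`
moves to `k-1` at rate `k s` (the generic rate `U h_{k-1}/h_k` simplified
under Poisson weights), and two lineages sharing a class vector coalesce at
rate `1/(N Π_j h_{k_j})`.  The Monte-Carlo engine (numba kernel) supports
any number of effect classes, samples initial class vectors from the
truncated Poisson weights (truncation tail < 1e-8, out-of-range draws
clamped with a logged warning), resolves competing events by
probability-proportional selection with the waiting time replaced by its
expectation `1/(total rate)`, and accumulates branch lengths subtending
each descendant count.  Replicate `r` of a run with seed `s` uses the
deterministic stream `s + 7919 r`, so results are bitwise reproducible.
Reported spectra are mean branch lengths in generations (multiply by a
neutral mutation rate for mutation counts); `T₂` is recovered from the
`i(n-i)`-weighted spectrum sum and `π/π₀ = T₂/N`.

The corrected pairwise reduction `π/π₀` is computed *exactly* for the
two-lineage case by the backward recursion

    T(k₁,k₂) = [1 + k₁Ns·T(k₁-1,k₂) + k₂Ns·T(k₁,k₂-1)] / ρ,
    ρ = (k₁+k₂)Ns + 1{k₁=k₂}/h_{k₁},

solved along anti-diagonals in O(k_max²) — deterministic, smooth in the
parameters, and in agreement with the Monte-Carlo kernel to Monte-Carlo
precision.  The closed-form strong-selection approximation
`e^{-λ} + (2/Ns)(γ + ln λ + E₁(λ))` (descent delay plus class-0
coalescence) is retained for fast brackets; it overshoots near the critical
line, which is why the exact recursion is the quantitative prediction.
With recombination, the independent-sites reduction for a centered neutral
site on a uniform chromosome is `π/π₀ = exp[-U/(s + R/2)]`, obtained by
integrating the classical per-site factor `exp[-u s/(s+r)²]` over map
positions.

## The fitness-variance map

In the infinitesimal limit (`Ns → 0`, `NU → ∞` at fixed `ζ = (Ns)²(NU)`),
diversity depends only on the scaled fitness standard deviation `Nσ`.  The
map `Nσ(ζ)` is the self-consistency relation `σ² = U⟨s²⟩·T₂(σ)`: variance
accumulates like neutral fitness diffusion over the pairwise coalescence
timescale, while the scaled coalescence rate crosses over from neutral
(`N/T₂ = 1`) to the multiple-merger regime (`∝ σN/ln(Nσ)`):

    ζ = x²·(1 + c·x³/((1+x)²·ln(1+x))),   x = Nσ.

This is strictly increasing and closed-form invertible in `ζ(x)`; `x` is
recovered by bracketed Brent iteration.  Asymptotics: `x² → ζ` as `ζ → 0`
(the variance accumulated neutrally over `N` generations, constant
`c₀ = 1`), and `T₂ ∝ ln(Nσ)/σ` at large `ζ`, so `σ` grows far more slowly
than either the deterministic mutation–selection-balance value
`σ²_det = U s` or the neutral-accumulation value — interference wastes most
of the injected variance.  The single order-one constant `c = 1.65678` is
fixed once so that the map reproduces the fitness variance of the
dot-chromosome reference regime (`Ns = 30`, `NU = 300` → `Nσ ≈ 90`) and is
frozen; forward simulations at an independent parameter set
(`Ns = 10`, `NU = 100`, `N = 10³`) then agree with the map within a few
percent (measured `Nσ ≈ 26.8` vs. predicted 27.2), which is the real check
of the crossover shape.

For multi-atom DFEs, the infinitesimal limit depends on the DFE only
through `U⟨s²⟩`, so an arbitrary discrete DFE maps to the equivalent
single-effect model `(s_eff = ⟨s²⟩^{1/2}, U_total)` before coarse-graining.
Beneficial atoms (`s < 0`) are accepted by the rms map and the forward
simulator only.

## Critical line and coarse-graining

For each `Nσ`, the corrected reduction has an interior minimum as a
function of `Ns` along the constraint `ζ = const`; these minima — where the
fitness-class description starts to fail and Muller's ratchet turns over —
form the critical line separating the regimes.  The solver seeds from the
closed-form stationarity condition `3λe^{-λ}Ns = 2A(λ) + 6(1-e^{-λ})`
(`A = γ + ln λ + E₁(λ)`), then root-finds the exact log-log derivative
(central differences, step 1e-4 in `ln Ns`) with Illinois-safeguarded false
position to a relative residual below 1e-6 (typically 1e-8).  As `ζ → 0`
the boundary tends to `Ns* = 8/3`.

Classification: a point is *interference* iff `Ns < Ns*(ζ)`, with ties
classified as background so the map is the identity there.  Interference
points map to `(Ns*, NU* = ζ/Ns*²)`; background points map to themselves.
`π/π₀` is reported from the exact corrected formula at the mapped point and
the spectrum shape from the Monte-Carlo run there; because the formula is
the exact pair solution of the same process, the two agree within
Monte-Carlo error everywhere, not just at the boundary.

The two-effect hybrid (weak interference atom + strong background atom)
first reduces the population size felt by the weak mutations,
`Nₑ = N e^{-λ_st}`, maps the weak atom to the critical line at `Nₑ`, and
runs the two-class structured coalescent at the original `N` with the
strong atom explicit and the coarse-grained weak atom converted back to
per-generation units with `Nₑ`; the reported reduction is
`e^{-λ_st} × π/π₀(weak at Nₑ)`.  Only a single strong atom is supported
(the harmonic-mean generalization for several strong atoms is out of
scope).

## Linkage blocks

For `R > 0` the chromosome is treated as a row of effectively asexual
blocks.  The block fraction solves

    f_b · NR · [T₂(f_b·NU)/N] = c · (1 - f_b)

by Brent's method on `(0, 1]`, with `T₂` the deterministic coarse-grained
pair time at `(Ns, f_b·NU)` (keeping the solve smooth and seed-free);
`f_b = 1` exactly at `NR = 0`, and `f_b → 0` with `u_eff = f_b·NU → 0` as
`NR → ∞`.  The constant `c = 7.19` was calibrated once against the forward
simulator at `Ns = 10`, `NU = 100`, `NR = 100`, `N = 10³` (pooled 17
replicate populations, `π/π₀ = 0.321 ± 0.009`) and frozen; the
monotonicity of the prediction in `NR` and both limits are independent of
`c`.  The prediction for the recombining genome is then the asexual
coarse-grained prediction at `(Ns, f_b·NU)`.  The additional effective
population-size reduction from *unlinked* blocks is deliberately neglected;
this logarithmic correction can matter for extremely long genomes dense
with selected sites.

## Forward-time simulator

Discrete generations: (1) multinomial resampling weighted by relative
fitness (log fitness recentered each generation to avoid underflow, with
the offset tracked so absolute trajectories survive); (2) `Poisson(NR)`
recombination events, each replacing one of two random individuals with a
single-crossover recombinant (the neutral locus follows the parent whose
segment covers position 0.5); (3) `Poisson(NU)` selected mutations at
uniform random individuals and positions; (4) `Poisson(N·U_neutral)`
neutral mutations at the center locus, recorded as nodes in a
parent-pointer haplotype forest from which sampled spectra are read off.
Defaults follow the study protocol: `20N` total generations, burn-in until
the neutral locus reaches its most recent common ancestor (tracked by
inherited ancestry labels; capped at half the run with a logged warning),
then 100 samples of `n` individuals (drawn without replacement) every
burn-in-length epoch.  `N·U_neutral = 1` by default — reported quantities
are `π/π₀` and normalized spectra, which are insensitive to this choice
under infinite sites.

When `R = 0` the simulator tracks only per-individual log fitness and the
neutral haplotype — exact for this model, since equally fit genotypes are
interchangeable — which makes desk-scale runs cheap even at `NU` in the
thousands.  The genome-based engine (explicit sorted mutation tuples,
copy-on-write across generations, fixed mutations pruned every 500
generations) is used whenever `R > 0` and is statistically
indistinguishable from the fast path at `R = 0` (tested).

Fitness variance is estimated two ways: *direct* (time-averaged
instantaneous variance of log fitness after burn-in) and *Fisher*
(`σ² = v - U·E[δ]`, where `v` is the regression slope of mean log fitness
and `E[δ]` the mean log-fitness effect of new mutations, so selection
balances mutation pressure at steady state and any residual slope is
Muller's ratchet).  The two agree within sampling error on equilibrated
runs; at the small scaled population sizes used for fixtures, effects can
be large enough that `ln(1-s) ≠ -s` matters, so comparisons are made in
log-fitness units throughout.

Fixture presets pin the study's printed parameter sets (e.g.
`dot_chromosome`: `Ns = 30, NU = 300, NR = 0`) at a base size `N = 10⁴`
scaled down by a factor in `(0, 1]` with all scaled parameters held fixed;
identical preset/scale/seed return a cached, bitwise-identical result.

## What the synthetic data does and does not emulate

The simulator realizes the model exactly, so passing tests demonstrate
internal consistency of theory and simulation *under the model's
assumptions*: free recombination outside the focal chromosome, constant
`N`, no epistasis, a constant DFE, infinite sites at the neutral locus.
They do not probe demographic change, spatial structure, direct selection
on the focal locus, or finite-sites reversions (a finite-chromosome mode is
not included).  Problem sizes are scaled down (typically `N = 10³`, 4–8
replicate populations, samples of 20–50) from the original protocol
(`N = 10⁴`, 300 replicates, `n = 100`); population-scaled parameters are
held fixed so the comparisons remain valid, at the price of larger
Monte-Carlo intervals and mildly stronger finite-`N` corrections.

## Numerical choices and degenerate inputs

- Poisson class truncation: tail mass < 1e-8; `λ > 2000` is refused.
- `NU = 0` short-circuits every prediction to the neutral limit; atoms with
  `U_j = 0` are dropped before the coalescent kernel, making degenerate
  multi-effect calls bitwise identical to their reduced forms.
- The corrected reduction is clamped at 1; its validity degrades for
  `Ns` below the critical line, which is precisely where the coarse-grained
  map replaces it.
- Root solves: Brent (`Nσ` inversion, block fraction, both to ~1e-12) and
  Illinois false position (critical line, residual < 1e-6 guaranteed,
  typically 1e-8).  All are deterministic.
- Monte-Carlo error: `T₂` standard errors are computed across replicates
  and reported (`mc_se_pi`); the expected-waiting-time substitution removes
  most of the exponential waiting-time variance, so these errors reflect
  only event-order and initial-class randomness.

## Known limitations

- At very large `Nσ` the mapped structured coalescent retains a star-like
  mutational-descent phase, so while the predicted *diversity decay*
  follows the asymptotic `ln(Nσ)/Nσ` scaling of the multiple-merger limit
  and the spectrum carries the same qualitative signatures (singleton
  excess, high-frequency uptick), its singleton-normalized shape does not
  converge bin-by-bin to the Bolthausen–Sznitman spectrum.
- Continuous DFEs are supported only through user-side discretization; the
  self-consistent weak/strong partition of a broad DFE and multi-atom
  strong components are out of scope.
- Predictions are population-averaged; no linkage disequilibrium,
  position-dependent diversity along the chromosome, or variable
  recombination maps.
- The unlinked-block `Nₑ` correction is neglected (see above), and the
  block-condition constant is an empirical calibration pending a sharper
  theory of the block boundary.
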