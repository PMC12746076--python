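# Methods

This note documents the models and procedures the package implements, the
choices made where the design was genuinely open, and what the synthetic
data do and do not establish about real measurements.

## Ankle lever model

The ankle is treated as a quasi-static, single-joint, third-class lever.
The inlever FA runs from the intertarsal joint to the centre of the
m. tibialis cranialis tubercle; the outlever RA from the joint to the
point where prey resists, taken as the distal end of the tarsometatarsus.
For prey mass *m* (kg) and g = 9.81 m s⁻² (configurable per scenario):
RP = m·g, F = RP·RA/FA, MA = FA/RA.

Two torque conventions are offered. The default, `"outlever"`, is
τ = F·RA — the product of required muscle force and outlever length, which
is how the published comparison tables this package reproduces were
computed. The physically standard joint moment, τ = F·FA = RP·RA, is
available as `"joint"`; the two differ by a factor of 1/MA. The
convention in effect is logged with every pipeline run.

The bundled lever arms are the published species values in metres. They
equal the species-mean skeletal measurements divided by 1000 (RA from
total bone length, FA from tubercle distance), except for the eastern
screech-owl, whose published outlever (0.0312 m) disagrees in the third
digit with its own skeletal mean (32.12 mm); the lever-table value is kept
verbatim so the published rows reproduce.

Not modelled: dynamic (accelerating) lifts, muscle architecture (PCSA,
pennation), multi-joint chains.

## Morphometrics

Per-specimen measurements (bone length, midpoint width, tubercle distance,
all mm) are averaged into a representative individual per species; derived
ratios use the averaged raw metrics (mean length / mean width), not means
of per-specimen ratios. Sample SDs use the n−1 denominator; a single
specimen reports SD 0 with a flag.

Group contrasts use the Mann–Whitney U test. U counts pairs with
x_i > y_j plus half-ties; W = min(U, n₁n₂−U) is also reported because the
orientation-free form is what comparative studies usually print. The p
value is exact (full U distribution) when n₁·n₂ ≤ 400 and the pooled data
are tie-free, and otherwise uses the tie-corrected normal approximation.
The exact path is verified against a complete enumeration oracle for all
n₁, n₂ ≤ 6. Normality and homogeneity pretests are deliberately out of
scope: the pipeline takes the nonparametric route as given for the focal
samples.

## Tensile-trace processing

A trace is one tensometer export: time, load (N), displacement (mm) at a
nominal 50 Hz, with resting length L₀ and junction cross-sectional area A₀
as sidecar metadata. The per-leg procedure:

1. **Segmentation.** Apexes are local maxima of displacement separated by
   at least half the nominal cycle period; troughs are the minima between
   apexes. Exactly five cycles are required, else a segmentation error
   with diagnostics.
2. **Zeroing.** The zero-load point is the mean of the per-trough minimum
   load over the last three cycles (`trough-min`, the default). An
   alternative reading — the three lowest samples pooled over those
   troughs (`global-min`) — is exposed as an option; the two coincide on
   clean data.
3. **Final load.** Mean of the cycle-2, -3 and -4 peak loads minus the
   zero offset. Cycle 1 is a pre-stress cycle and cycle 5 is excluded, so
   the per-cycle maxima of cycles 2–4 are also the three highest
   informative peaks; the two published phrasings of this rule coincide
   under that reading and are implemented once.
4. **Stress–strain.** σ = (load − offset)/A₀ in MPa, ε = displacement/L₀.
   The apex sample belongs to the rising curve; the falling curve starts
   at the next sample.
5. **Regional moduli.** The rising curve is split into three contiguous
   regions equal in sample count (remainder to the earlier regions — equal
   count, not equal strain span; the distinction matters only for
   nonuniform sampling and is configurable). In each region the OLS slope
   of the central five points (equal weights, free intercept) gives the
   toe, early-linear and late-linear moduli; the late ("end") slope is the
   working Young's modulus E. Regions shorter than five points fall back
   to all their points and set a degraded flag; fewer than six points
   total is an error.
6. **Loop areas and resilience.** Trapezoidal integration of σ(ε) under
   each curve; resilience = falling/rising area. For integration the loop
   is closed by prepending the apex sample to the falling curve —
   otherwise a one-sample sliver of falling area is lost, biasing
   resilience low by about 3 % at 50 Hz.
7. **Species aggregation.** Final load is the mean of the (usually two)
   leg loads; species modulus and resilience are means over the pooled
   cycle-by-leg values (six for two legs), and the reported SDs are across
   those six values — whether published SDs are across cycles, legs or
   both is not stated, so the pooled convention is documented here. Peak
   stress is recomputed from the species load.

All internal arithmetic is full precision; rounding happens only in
formatting helpers and report copies.

## Synthetic tensometer traces

The generator emulates the test protocol with a closed-form constitutive
model chosen so every downstream quantity has an exact oracle:

* loading (rising) stress: σ_up(ε) = a·(exp(b·ε) − 1), strictly increasing
  and convex — a J-curve with toe;
* unloading (falling) stress: σ_down(ε) = σ_m·(ε/ε_max)^q with
  σ_m = σ_up(ε_max).

Both areas are closed-form, so q is solved from the requested resilience
r: q = σ_m·ε_max/(r·A_up) − 1. q ≥ 1 is enforced and the unloading curve
is checked on a 1000-point grid never to exceed the loading curve;
r close to 1 can violate this (the loop would have to bulge above the
loading curve) and is refused as infeasible rather than silently clipped.

Displacement is a train of triangular ramps 0 → ε_max·L₀ → 0 at the
programmed crosshead rate, with a sample placed exactly at every apex and
trough so peak detection is deterministic at any sampling rate. Load is
σ·A₀ plus a constant pre-tension offset (exercising the zeroing rule) and
iid Gaussian noise. Defaults follow the study protocol: ε_max = 0.10,
50 mm min⁻¹, 50 Hz, five cycles. The default noise SD is 0.005 N — a few
times the gauge's 0.001 N resolution; with five-point OLS windows at this
sampling density, error propagation puts the per-cycle late-slope noise
near 0.5 %, comfortably inside the 1 % recovery band the tests assert.

The model is deliberately cycle-stationary: no creep, rate dependence, or
damage accumulation, so all five cycles share one curve pair. Real tendon
shows moduli drifting downward from cycle 2 to cycle 4; passing recovery
tests on synthetic traces therefore demonstrates the correctness of the
extraction arithmetic, not that real cyclic data are stationary. Likewise
the Gaussian load noise does not emulate grip slippage or drift.

Morphometric populations are truncated-Gaussian draws (redrawn until
positive, and until the tubercle lies proximal to the bone's end) around
species means — the published tables report only mean ± SD, so no
between-metric correlation is imposed.

## Phylogenetic comparative statistics

Trees are parsed from Newick (dendropy) and pruned with unifurcation
collapse; a stem edge left at the root after pruning counts toward every
depth, so root-to-tip distances are conserved. The Brownian
variance–covariance matrix has C_ii = root-to-tip distance and C_ij = the
depth of the most recent common ancestor, filled by a single depth-first
pass and verified against an explicit path-walk oracle.

**Pagel's λ** multiplies the off-diagonals of C; λ is restricted to [0, 1]
(the theoretical upper bound above 1 that some trees admit is not used).
The ML estimate profiles the mean and rate analytically by GLS at each λ
(μ̂ = (1ᵀC⁻¹1)⁻¹1ᵀC⁻¹y, σ̂² = GLS residual quadratic form / n) and
optimizes λ by a 0.01-step grid followed by bounded refinement around the
grid optimum. A flat profile (star tree) sets an unidentifiability flag.
Constant traits are refused.

**PGLS ANOVA/MANOVA with RRPP.** Data are whitened by the symmetric
inverse square root of C (eigendecomposition; near-singular matrices are
refused), then an ordinary linear model of whitened data on the whitened
intercept-plus-group design is fitted via orthonormal bases. The statistic
is the trace-form SS ratio summed over traits, which reduces exactly to
the classical one-way F for a single trait and is invariant under trait
duplication; Wilks/Pillai forms are out of scope. The permutation null
randomizes the reduced-model (intercept-only) whitened residuals — the
default of the residual-randomization framework; full-model residual
permutation is not offered. p = (1 + #{F* ≥ F})/(n_perm + 1), so p > 0
always and p ∈ [1/(n_perm+1), 1]. Non-ultrametric trees are accepted and C
is not normalized.

The published 62-species comparative result is not desk-reproducible (its
trait table and pruned tree live in external supplements), so the module
is validated by simulation instead: λ recovery on Brownian data (mean λ̂
above 0.9 at 64 tips — the signal regime the published analysis reports),
type-I error calibration of the RRPP ANOVA at the nominal 5 % level, and
the exact classical-F identity at C = I.

## Problem sizes and determinism

Every random quantity takes an explicit integer seed; there is no global
random state, and the demo pipeline derives per-stage substreams from one
base seed so reruns are byte-identical. Validation sweeps use 20 seeds for
tensile recovery, 50 replicates for λ recovery, and 500 null simulations
at 199 permutations for the type-I check — sizes at which the binomial
error of the checked rates is well inside the asserted bands while the
whole suite runs in seconds.

## Known limitations

* The constitutive family is one convex exponential; tendons with plateau
  or damage behaviour are outside it, and requested resilience near 1 is
  infeasible by construction.
* The exact Mann–Whitney path refuses ties (falls back to the corrected
  normal approximation); small tied samples therefore get approximate p.
* λ and the RRPP tests assume a correctly specified tree; measurement
  error in tips is not modelled.
* The lever model is static: reported forces are what equilibrium demands,
  not what the muscle can produce.
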