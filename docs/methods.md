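# Methods

This note documents the models, parameter choices and numerical decisions
behind `bkcav`, in the order the pipeline runs: the synthetic-data
generator, idealization, i–v fitting, cluster statistics, junction
potentials and the resting-potential model, and the Fura-2/colocalization
utilities.  It also states what the generator does and does not emulate,
and therefore what a passing test suite does and does not show about real
recordings.

## The gating simulator (synthetic-data generator)

### BK channels

Each BK channel is a two-state C⇌O Markov chain.  Rates are Boltzmann in
voltage with a Ca²⁺-dependent half-activation voltage:

- `α(V,Ca) = a₀ exp(+(V−V½(Ca))/s)`, `β(V,Ca) = b₀ exp(−(V−V½(Ca))/s)`,
  `V½(Ca) = V½,ref − d·log₁₀(Ca/Ca_ref)`.
- Defaults: γ = 186 pS (symmetric K⁺, E_rev 0 mV); `V½,ref = +20 mV` at
  `Ca_ref = 10 nM`; `s = 16 mV` per e-fold per rate, i.e. an effective
  activation slope of 8 mV; `d = 40 mV/decade`; `a₀ = b₀ = 0.0025 ms⁻¹`.

The stationary curve places open probability below 0.05 at −20 mV and
above 0.99 at +60 mV with ~10 nM Ca²⁺ (strong EGTA buffering), so whole-
cell currents first appear near −10 mV; 400 nM Ca²⁺ shifts activation
64 mV leftward.  These three facts — activation threshold at strong
buffering, the leftward shift with Ca²⁺, and the tens-of-ms latency of
the coupled ensemble Po peak (below) — are the calibration constraints;
no rate constants are available to fit directly, so the defaults are
declared calibrated values, not measurements.

The base rates deserve a comment: `a₀ = b₀ = 0.0025 ms⁻¹` gives *slow
envelope* kinetics (hundreds of ms at V½).  A two-state scheme cannot
simultaneously carry the millisecond intraburst flicker of a real BK
channel and the slow Ca²⁺-binding-limited envelope of its activation; we
keep the envelope, because every analysis in the package (ensemble Po,
NPo, subtraction currents) averages over flicker anyway.  Where tests
need dense transitions (idealization fidelity, amplitude estimation) they
use a fast-flicker variant (`a₀ = b₀ = 0.5 ms⁻¹`) whose stationary curve
is identical.

Integration uses a fixed step (default 0.05 ms) with the *exact*
two-state propagator per step: `P(C→O) = p∞·w`, `P(O→C) = (1−p∞)·w`,
`w = 1 − exp(−(α+β)Δt)`, `p∞ = α/(α+β)`.  Unlike the naive pair
`1 − exp(−rate·Δt)`, this keeps the chain's stationary distribution exact
at any step size (the naive scheme biases it by ~1% once `rate·Δt ≈ 1`);
the two coincide as Δt → 0.  Channels start in their stationary
distribution at the first sample.

### Cav3.2 channels

Macroscopic currents integrate the Hodgkin–Huxley `m²h` gates by
exponential relaxation toward `m∞, h∞` (exact for piecewise-constant
voltage): activation V½ −45 mV / slope 6 mV / τ 3 ms; inactivation V½
−72 mV / slope 5 mV / τ 25 ms; `I = g·m²h·(V−E_rev)`.  These values give
an activation threshold near −50 mV and `h∞(−40 mV) < 0.002` — the
"fully inactivated at −40 mV" behaviour that the paired-holding-potential
protocols exploit — and are free parameters otherwise.  The constructor
rejects parameter sets with `h∞(−40) ≥ 0.05`.

Single-channel mode simulates each channel as three independent binary
gates (two activation, one inactivation) with on/off rates
`x∞/τ, (1−x∞)/τ`, so the ensemble open fraction relaxes exactly to
`m∞²h∞`.  The unitary conductance default is 7 pS, the value appropriate
to ~100 mM external divalent, where the reversal sits near +120 mV and
the unitary current at −20 mV is ≈ −1 pA.

### Nanodomain coupling

The local Ca²⁺ seen by the BK channels of a patch is instantaneous and
algebraic: `Ca_loc(t) = Ca_bulk + κ·N_T,open(t)` with κ = 2 µM per open
channel by default — the micromolar scale expected within tens of nm of
an open Ca²⁺ channel.  No diffusion PDE is solved; all the evidence the
package reproduces is at ensemble/steady-state level, where an algebraic
rule with an EGTA attenuation factor (×0.05 for 10 mM EGTA, which
collapses bulk Ca²⁺ accumulation but spares nothing in this lumped model)
is sufficient.  `Ca_bulk` defaults to 10 nM for excised/strongly buffered
settings and 100 nM for intact-cell models.

The paired protocol helper reproduces the cell-attached experiment: test
pulses to −20 mV from holding at −80 mV versus after 10 s at −40 mV.  The
10 s conditioning is implemented by starting all gates at their steady
state for the holding level, which is equivalent at steady state and
avoids integrating dead time.  In the cell-attached geometry the patch
sees a 5/150 mM K⁺ gradient, so BK unitary currents reverse near
−86.5 mV (large outward events at −20 mV), and the default patch carries
4 BK and 4 T channels — the mean BK count reported for coupled patches,
with a matching handful of T channels consistent with their colocalization
in BK clusters.  With the default calibration the subtraction Po(t) peaks
21–25 ms after the step (seed-to-seed), within the tens-of-ms coupling
window, and early Po from HP −80 exceeds the HP −40 arm by far more than
the three-fold calibration floor.

### Patch placement and Fura-2 synthesis

Uniform placement draws per-patch counts as Binomial(n, x/y) — the exact
law for independent uniform placement of n channels on area y sampled
with patches of area x.  Clustered placement is a compound Poisson
(Neyman–Scott-like) process: cluster centres Poisson(`cluster_rate·x`)
per patch, Poisson(`mean_cluster_size`) channels per cluster, co-located
within one patch footprint.  Fura-2 ratios follow
`R = (Rmin + (Ca/(Kd·β))·Rmax)/(1 + Ca/(Kd·β))` plus optional Gaussian
noise — the exact inverse of the ratiometric conversion below.

### What the generator does not emulate

Filter/electrode artifacts, 1/f noise, series-resistance errors, BK
flicker-burst substructure, multi-state allosteric BK gating, IK/SK
channels, Ca²⁺ diffusion and buffering kinetics.  Passing tests therefore
show that the *analysis operations* are correct against a faithful but
idealized data-generating process; they do not certify performance on
recordings whose noise or kinetics violate these idealizations.

## Idealization and ensemble Po

Traces are idealized by half-amplitude threshold crossing: the level at a
sample is the rounded multiple of the unitary amplitude above baseline,
a switch requires crossing `(k ± 0.5)·amplitude` with a 5% hysteresis
margin, and events shorter than the dead time (default 0.3 ms) are merged
into their longer neighbour.  The baseline defaults to the median of the
holding segment.  On noiseless synthetic traces idealization inverts the
generator exactly; at SNR 5 the recovered time-averaged level stays
within 5% of ground truth.

Channels per patch are counted as the maximum simultaneous open level
across records at the maximal-Po potential.  The estimator is biased
downward for short records (a channel that never opens is invisible);
the bias is documented, not corrected, because that is the counting rule
whose outputs feed the cluster statistics.

The subtraction Po is `(⟨i₋₈₀⟩(t) − ⟨i₋₄₀⟩(t))/(N·i_unit)`; negative
samples are clipped to zero (the quantity is a probability) with the
clipped count logged and reported on the result object.  The composite
sweeps also contain the small inward T current (~1 pA against ~12 pA BK
events in the cell-attached geometry), a real contamination of the
subtraction method that the tests bound rather than remove.

## i–v analysis

Conductance/reversal fits are ordinary least squares on the i–v points in
a window, by default (−10, 60) mV — the linear region of the asymmetric-K⁺
single-channel curve.  Nernst potentials use RT/zF at 295 K (room
temperature; the recording temperature is not otherwise specified).
Boltzmann G/Gmax, single-exponential inactivation and Hill inhibition
fits are nonlinear least squares with three data-driven starts,
tie-broken by residual norm; non-convergence and non-decaying input are
flagged on the result object rather than raised.  Peak statistics for
transient currents take the largest-|i| sample in the window (the first
~100 ms of the step for T currents).

## Cluster statistics

The channel-weighted cluster-size distribution is
`w(k) = k·P(K=k)/E[K]` — the probability that a *channel* (not a patch)
sits in a patch of k channels — matching the "proportion of channels as a
function of cluster size" reading; it sums to 1 over k ≥ 1 and the empty-
patch fraction is reported separately.  The placement null takes K ~
Binomial(n, x/y), or Poisson(λ) when parameterized by mean occupancy;
both parameterizations are exposed and agree to ~3·10⁻⁶ (sup-norm) by
n = 10⁵, scaling as 1/n.

A note on the headline tail number: with 311 channels in 137 patches the
exact mean occupancy is 2.2701 and the closed-form channel-weighted tail
Σ_{k≥6} is 8.03%; with the legend-style n·x/y = 2.0 it is 5.26%; with the
*rounded published mean* of 2.3 channels per patch (Binomial, n = 6500) it
is 8.37%.  Only the last reproduces the published 8.3% to one decimal
unit, so `published_cluster_null()` adopts the rounded-mean
parameterization and the alternatives are computable through
`PlacementNullParams` directly.

Observed tables are tested against the null by parametric Monte Carlo:
the statistic is the total-variation distance between channel-weighted
distributions, null tables are resampled at the observed patch count, and
`p = (1 + #{TV* ≥ TV})/(n_boot + 1)` with n_boot ≥ 999.  Monte Carlo is
used instead of a chi-square because tail bins have small expected
counts.  Fisher's exact test is the standard hypergeometric two-sided
test (checked exhaustively against an enumeration oracle for N ≤ 30).

Density bookkeeping: density = mean channels per patch / patch area
(2 µm², the pipette-tip estimate); membrane area = capacitance / specific
capacitance (0.01 pF/µm², the classic 1 µF/cm²); the whole-cell total
supports a rounded density override so that "≈1 µm⁻² over a 65 pF cell"
yields 6500 channels.

## Junction potentials and the RMP model

Liquid junction potentials use the generalized Henderson equation over an
arbitrary ion list, with mobilities `λᵢ/|zᵢ|` from a pinned table of
limiting equivalent conductances (Na⁺ 50.1, K⁺ 73.5, Cl⁻ 76.3,
gluconate⁻ 24.3, Mg²⁺ 53.1, Ca²⁺ 59.5, HEPES⁻ 22.1 S·cm²·eq⁻¹; shipped
as `data/mobilities.csv`).  HEPES is carried at 50% of nominal as the
anion (its ionization near pH 7.2–7.4).  Concentrations stand in for
activities, a ≲0.3 mV approximation.  The sign convention is "bath
relative to pipette": a K-gluconate pipette against a NaCl bath reads
+15 mV.  The closed form is verified in the tests against an independent
numerical integration of the junction ODE along the linear mixing path.

The *bath-exchange* LJP change is computed as the Henderson potential of
the new bath against the original bath — the junction that physically
forms at the uncorrected reference electrode once the pipette is sealed
and the offset has been zeroed in the original bath.  For the
145 Na⁺/5 K⁺ → 0 Na⁺/150 K⁺ exchange at constant chloride this gives
−3.99 mV.  Computing instead the difference of two pipette-referenced
junction potentials gives −5.9 mV; both are available
(`bath_exchange_ljp_change` vs two calls to `henderson_ljp`), and the
bath-junction reading is the one consistent with the published −3.7 mV.

The RMP model solves `I_BK,∞ + I_T,window + I_leak = 0` on [−100, +20] mV
by sign-change bracketing and Brent refinement; a root is stable when the
net i–v slope is positive, and *all* stable roots are returned
(bistability is reported, never collapsed).  BK steady activation is the
stationary Boltzmann at the local Ca²⁺ of the coupling rule evaluated at
the expected open T-channel count `(g_T/γ_T)·m∞²h∞`.  Calibrated
parameters: g_BK = 1.8 nS, g_leak = 0.5 nS (E_leak = 0 mV, a lumped
nonselective background), E_K = −81 mV (tail-current reversal),
Ca_bulk = 100 nM, and g_T = 0 / 0.5 / 3.0 nS for the control-like,
neuroendocrine-like and Cav3.2-overexpressing models.  These rest at
−32.0, −41.7 and −54.4 mV: the window current hyperpolarizes through BK
recruitment (the direct inward T current is ≪ 1 pA), removing BK
depolarizes the control model by 32 mV to E_leak, and the high-EGTA
regime collapses the coupled models back to the control value.
Perturbations report the stable root nearest the unperturbed one
(continuation of the physiological state); the baseline is the most
negative stable root.

## Calcium tools

The ratiometric conversion is `Ca = Kd·β·(R − Rmin)/(Rmax − R)`, strictly
increasing on [Rmin, Rmax); ratios outside that interval are flagged and
returned as NaN (saturated dye or noise undershoot) so downstream
statistics exclude them.  Default calibration constants (Rmin 0.3,
Rmax 6.0, Kd 224 nM, β 5) are typical bench values supplied explicitly in
any non-default use.  Colocalization is the plain Pearson correlation of
two equal-shape rasters over an optional mask — no background
subtraction, thresholding or Manders coefficients — and is invariant to
affine intensity rescaling of either channel.

## Problem sizes and tolerances in the test suite

Monte-Carlo checks run at sizes chosen to put their standard errors well
inside the asserted bands while keeping the default suite under a minute:
10⁵–10⁶ patches for placement statistics, 500 sweeps per arm for the
coupling signature, 200 null datasets at n_boot = 999 for the type-I
error of the clustering test, and 40–60 replicates for fit-recovery
checks.  All stochastic tests are seeded and bit-reproducible; stationary
comparisons use 3σ bands computed from the chain's correlation time, and
the acceptance cross-check between closed-form and Monte-Carlo cluster
tails is held to 0.1 percentage points.

## Known limitations

- The BK scheme is minimal; it reproduces stationary curves and ensemble
  latencies, not dwell-time histograms or burst structure, and the
  Ca-independent (LRRC26-like) activation is folded into V½,ref.
- The coupling rule is lumped; it cannot distinguish coupling
  stoichiometry from Ca²⁺-handling differences (e.g. why T-activated BK
  decay τ differs by 30× between cell lines) — the relevant τ parameters
  are exposed without a mechanistic claim.
- The RMP model reproduces orderings and magnitudes of perturbations, not
  exact published means; leak parameters are effective values.
- The channel-count estimator's downward bias is documented, not
  corrected; cluster statistics inherit it exactly as the original
  counting rule does.
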