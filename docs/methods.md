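# Methods

## Reaction schemes and their assumptions

A scheme is a list of states (bound complex, docked-ligand sites,
pentacoordinated and bis-histidyl hexacoordinated deoxy species, ligand
pool, and for the NOD mechanism a ferric intermediate and product) plus
first-order and bimolecular transitions.  The default cytoglobin scheme
makes these physical assumptions:

* **Photolysis is an initial condition, not a transition.**  At t = 0 a
  fraction φ of the hemes (default 1.0) has its CO placed in the primary
  docking site P1; the rest remain bound.
* **The bound state is absorbing** on the ≤10 s observation window:
  thermal CO dissociation (~s⁻¹·10⁻³ scale) is negligible, so the default
  scheme carries no dissociation step.  This is also what makes the
  survival signal provably non-increasing.
* **One ligand pool.**  Bimolecular steps consume a free ligand
  (rate × [CO]); first-order escape steps (`k_2` from P1, `k_2p` from P5)
  release one.  The convention used to mark release is a first-order
  transition that names the pool as `ligand_partner`.
* **H6 is reached from P5 concurrently with His coordination**, as a
  reversible first-order step (`k_h`/`k_-h`); the docked ligand in H6
  cannot exchange with the solvent directly.  Topology is data-driven
  (states/transitions are declarative), so alternatives are configuration,
  not code.
* **HE7Q** (the distal-His mutant) removes Cygb_h and H6 together with
  their transitions; requesting H6 for HE7Q is an error, not a silent fix.

One printed constant requires a units decision: the innermost rebinding
rate is published as 1.5×10⁷ "M⁻¹ s⁻¹" although the step is geminate
(first order).  It is treated as s⁻¹ throughout, consistently with its
role in the scheme and in the on-rate branching formula.

## Integration

`integrate_network` solves the mass-action kinetics on a log-spaced grid
(default 100 points/decade, 10⁻⁹–10 s, the experimental span).  With the
ligand pool held fixed (pseudo-first-order conditions, the default) the
system is linear and is propagated exactly by eigendecomposition of the
rate matrix; the propagator falls back to the stiff integrator if the
eigenvector matrix is ill-conditioned (condition number > 10¹⁰).  With
explicit pool depletion (needed for stopped-flow mixing, where ligand and
protein are within a factor of a few) the nonlinear system is integrated
with BDF, analytic Jacobian, rtol 10⁻¹⁰ and atol 10⁻¹⁴.  Those tolerances
keep the BDF solution within ~10⁻¹⁰ of an independent matrix-exponential
solution on first-order networks; the exact-propagator and BDF routes are
cross-checked against each other and against `scipy.linalg.expm` in the
test suite, so the three routes are mutually independent checks.

The CO concentration is derived from partial pressure through a Henry-law
table anchored at 1.0×10⁻³ M/atm at 20 °C with approximate temperature
nodes from 0–45 °C (linear interpolation, clamped at the edges).  The
mapping is a convention shared by generator and fitter, so recovery tests
are insensitive to its absolute accuracy.

Under pseudo-first-order conditions the normalized survival signal is
mathematically independent of the photolysis yield φ (it cancels in the
t = 0 normalization).  φ is therefore held fixed in fits by default and
only the per-dataset scale is a free nuisance; φ matters, and is
honored, in explicit-pool simulations.

At exactly CO = 100× photolyzed heme, explicit-pool and fixed-pool
trajectories differ by ~1.3×10⁻³ (escaped ligand raises the free pool by
~1%); the two treatments converge as the excess grows (~10⁻⁴ at 1000×).

## Observable

The survival signal is Σᵢ wᵢ·xᵢ(t) normalized to 1 at t = 0, with default
weight 1 for every unliganded heme state (docked ligand, penta- and
hexacoordinated deoxy, ferric intermediate) and 0 for the ligand-bound
complex and the reaction product.  Whether penta- and hexacoordinated
species contribute with different extinction weights at the monitoring
wavelength is not established; equal weights are the default and per-state
weights are configurable.

## Maximum-entropy lifetime inversion

The decay is modeled as N(t) = Σₖ gₖ·exp(−t/τₖ) on a uniform log₁₀τ grid
(default 12 points/decade).  Amplitudes maximize the Skilling
positive-additive entropy S = Σₖ [gₖ − mₖ − gₖ ln(gₖ/mₖ)] relative to a
flat prior m (default 10⁻⁴ × signal amplitude / grid size) subject to a
per-point χ² target (default 1.0).  The constrained problem is solved as
min λχ²/2 − S with λ adjusted by log-space bisection until χ²/N lands in
(target·0.95, target·1.01]; the inner problem runs in u = ln g with
L-BFGS-B, which keeps amplitudes strictly positive by construction (the
non-negativity is exact, not clipped).  The Skilling form is used instead
of the bare Shannon cross-entropy because the amplitudes are an
unnormalized positive distribution; at stationarity it gives the standard
MEM fixed point gₖ = mₖ·exp(−λ·∂χ²/∂gₖ).

Practical safeguards: when σ is absent it is estimated from the median
absolute deviation of second differences (floored at 10⁻⁶ of the signal
amplitude); a grid narrower than the data span warns; a trace shorter than
twice the grid is rejected.  Because the amplitudes are constrained
non-negative, the best achievable χ²/N has a floor that can sit slightly
above 1.0 for a given noise realization — the floor is computed up front
by weighted NNLS and an unreachable target raises immediately, carrying
the floor, rather than iterating forever.  When the floor binds, a target
of ~1.05–1.1 is the robust choice; equivalence with any particular
published MEM implementation is not claimed, only the properties tested
(peak recovery, χ² control, entropy monotonicity in the target, exact
non-negativity).

## Global fitting

Rate constants are estimated by weighted least squares over several
datasets simultaneously (the two CO concentrations of one temperature, by
default), with the free rates shared across datasets and optimization in
log₁₀ space (rates span eight orders of magnitude).  Weights are the
per-point σ when present, else uniform.  A seeded multi-start (default 8
starts, log-uniform jitter ±0.5 around the initial guess) guards against
local minima; given the same spec and seed the result is bit-identical.
Standard errors come from the Gauss–Newton covariance at the optimum;
residual-resampling bootstrap quantiles are available separately.
Temperature series are fitted independently per temperature and the
fitted rates passed to the Eyring stage; no globally Eyring-constrained
fit is attempted.

A fit in which the bimolecular entry rate is free while no dataset covers
the bimolecular time window (t_max < 1/(k·[CO])) triggers an
identifiability warning.

Goodness of fit is reported per dataset as χ²/N plus a Wald–Wolfowitz
runs test on residual signs, which flags systematic misfit (long
same-sign stretches) that χ² alone can hide.

## Eyring analysis and energetics

`eyring_fit` is a linear regression of ln(k/T) on 1/T with
ΔH‡ = −slope·R and ΔS‡ = R·(intercept − ln(k_B/h)); constants are
R = 8.314462618 J/(mol·K) and k_B/h = 2.08366×10¹⁰ K⁻¹s⁻¹, transmission
coefficient 1.  ΔG‡ = ΔH‡ − T·ΔS‡, reported at 20 °C = 293.15 K by
convention.  The free-energy profile converts each forward/reverse rate
pair of a well chain into barrier heights via ΔG‡ = −RT ln(k·h/(k_B·T))
and propagates well levels by path consistency
(ΔG(i+1) = ΔG(i) − RT ln(k_fwd/k_rev)) from a reference well pinned at
exactly 0; the result is independent of traversal direction by
construction.

The on-rate formula k_ON = k₋₂·k₋₁/(k₋₁ + k₂ + k_c) is an
interpretation: it is the solvent entry rate times the probability that a
ligand in the primary site binds rather than escapes or migrates onward,
it reproduces the quoted 6.3×10⁶ M⁻¹s⁻¹ from the quoted microscopic
constants, and it agrees within 5% with the effective bimolecular rate of
a full simulation with deep migration disabled (tested).  Return from
deeper sites delays rebinding without changing the entry flux, so it is
deliberately excluded.

## Synthetic data: what it emulates and what it does not

The generator reproduces the study conditions: survival curves at 1 atm
and 0.1 atm CO (Henry mapping, exact 10:1 molarity ratio), temperatures
10–45 °C (via Eyring-parameterized ground truth when a temperature series
is requested), solution/gel/mutant regimes, and stopped-flow NOD decays
(6 µM oxy protein + 18 µM NO syringe concentrations, halved by 1:1
mixing, sampled linearly after a 1 ms instrument dead time).  Noise is
Gaussian and independent per point: 1% multiplicative plus 10⁻³ additive
by default, with the per-point σ stored alongside the signal.  Every
trace embeds its generating rates, seed and conditions in metadata, and
is bit-exactly reproducible from (config, seed).

Preset rate constants carry provenance markers: "printed" for published
microscopic constants (k₋₁ = 1.5×10⁷ s⁻¹, k₂ = 4.2×10⁷ s⁻¹,
k_c = 1.5×10⁷ s⁻¹, k₋₂ = 3.04×10⁷ M⁻¹s⁻¹, k_b = 149 s⁻¹,
k₋b = 1.8 s⁻¹, gel-phase k₂ = 2.1×10⁷ s⁻¹), "derived" for values computed
from published quantities (gel-phase His-release rates from the published
equilibrium constants 0.9 and 170; the mutant entry rate from the
published mutant on-rate 2.96×10⁷ M⁻¹s⁻¹ via the branching formula), and
"placeholder" for the deep-site rates, which are not available in the
published record.  Placeholders are chosen once: each deeper site an
order of magnitude slower, forward exceeding reverse so the docked ligand
is progressively stabilized along the pathway, and the site-5 solvent
exit sized to a ~11% branching fraction.

What the synthetic data does **not** emulate: instrument response /
laser-pulse convolution, detector-specific noise structure (shot vs
digitizer), spectral (Soret band) modeling, baseline drift, and any
systematic mismatch between the true mechanism and the assumed scheme.
Passing recovery tests therefore demonstrates that the pipeline is
self-consistent and well-conditioned under the stated noise model — not
that the scheme is the correct description of any particular measured
dataset.

The stopped-flow round trip is exact only in the fast-association limit:
at k_a = 10⁸ M⁻¹s⁻¹ (the published lower limit) the pseudo-first-order
association at 9 µM NO is ~900 s⁻¹, only ~2.4× the 370 s⁻¹ decay, and the
formation lag visible after the dead time biases a single-exponential
refit low by ~19%.  From k_a ≈ 3×10⁸ upward — the regime implied by
formation completing within the dead time — the refit returns the decay
rate within 2%.  Both behaviors are asserted in the tests.

## Problem sizes

Default test and acceptance workloads: 1001-point traces (100
points/decade over 10 decades) for fitting, 600-point traces for MEM
benchmarks, 100 random rate sets for the invariant sweep, 8-start global
fits, 20–50 bootstrap replicates.  These sizes keep the whole suite in
the tens of seconds on one CPU while leaving every recovery margin wide
(fit recovery errors ~0.01–0.04 log₁₀ units against a ±0.1 criterion).

## Known limitations

* The fitter's covariance assumes local quadratic behavior in log-space;
  strongly correlated deep-site rates are not identifiable from a single
  two-concentration pair and must be fixed or constrained.
* The MEM variant is this package's own (entropy form, prior, stopping
  rule documented above); distributions from other MEM codes may differ
  in width and baseline even when peak positions agree.
* Gel-phase presets adjust only the rates the published record pins down
  (escape rate, His equilibrium); other gel effects (e.g. on deep-site
  rates) are not modeled.
* The free-energy profile treats each step with transition-state theory
  and transmission coefficient 1; absolute barrier heights inherit that
  convention.
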