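# Methods notes

This note records the models, conventions and numerical choices behind
`gapscale`, in the spirit of the methods documentation of simulation
packages: what is computed, which knobs matter, and what the synthetic
data do and do not establish.

## Coordinate and measurement conventions

* AP positions are fractional embryo length ξ = x/L ∈ [0, 1], anterior = 0.
  Model-space positions are in EL units on the simulated interval
  [0.35, 0.92].
* Profiles live on 50 equal AP bins; bin *i* covers [i/50, (i+1)/50) and is
  represented by its centre (i + 0.5)/50.
* Background subtraction removes the mean of a declared non-expression
  window from every bin and clips at zero (intensities are non-negative
  arbitrary units).  The per-gene default windows ship as configuration
  because non-expression regions are gene-specific and not canonical.
* Domain normalization divides by the mean of the domain's three highest
  bins.  For the posterior *tll* domain the last three bins are excluded
  from both normalization and boundary search, so pole-cell signal cannot
  set the scale.
* A boundary is the 0.5 crossing of the normalized profile, linearly
  interpolated between bin centres on the declared side of the domain peak.
  With several crossings on one side the crossing nearest the peak wins —
  a deliberate robustness choice against distal noise.  A profile that
  never falls below 0.5 on the queried side raises a
  "boundary undetectable" error: real gap domains genuinely lack some
  boundaries at some times, so callers must treat absence as data.

## Staging

nc13 vs nc14 is decided by the dorsal nucleus count with a configurable
threshold (default 120; counts roughly double per cleavage division, and
the synthetic generator draws nc13 counts well below and nc14 counts well
above it).  nc14 time classes use the membrane-invagination ratio with
left-closed intervals [15, 25) → T3 through [65, 75) → T8 and ≥ 75 → T9;
the cut-off list itself carries no closure convention, so left-closed was
frozen here.  Embryos under 15% are split T1/T2 at the median of their
nuclear lengths (below median → T1).  A ranking-based split point is known
to be used but the exact quantile is not; the median is the natural choice
and is isolated in one function.  The direction — longer nuclei = later
(T2) — is likewise a convention, exposed as the `long_nuclei_late` flag of
the generator.

## The synthetic cohort generator

The generator emulates the statistical structure of a two-line FISH study:

* **Lengths**: Normal per line (482.0 ± 20.9 µm, 408.6 ± 16.8 µm by
  default), truncated at zero by redrawing (irrelevant at these
  parameters).
* **Profiles**: each domain is a product of a logistic rise and fall;
  the edge midpoint at length L is ξ₀ + S·(L/L_ref − 1), which makes the
  population regression of measured boundary on L/⟨L⟩ have slope S by
  construction — the generative truth the estimators must recover.
  Logistic edges were chosen because their half-maximum crossing is
  analytically known; default steepness 0.015 ξ-units keeps edges sharp on
  the 0.02-wide bins without aliasing.
* **Noise**: i.i.d. additive Gaussian per bin (default s.d. 3 a.u. against
  default amplitudes of ~80–100) plus a per-embryo constant background
  (default 20 a.u.), mirroring embryo-specific background subtraction.
* **Staging features** are drawn uniformly inside the target class's
  invagination interval, so the staging round-trip is exact for T3–T9.

What the generator does **not** emulate: spatial noise correlations along
the AP axis, embryo-to-embryo amplitude variability beyond the line-level
factor, pole-cell artefacts (except an explicit posterior-spike pattern
used in tests), asymmetric or non-logistic edge shapes, and any
within-line covariance between length and expression level.  Passing
recovery tests therefore demonstrate estimator correctness under the
stated model, not robustness to every imaging artefact.

## Scaling statistics

The scaling coefficient is ordinary least squares of ξ on L/⟨L⟩ with a
t-based 95% CI on the slope; ⟨L⟩ is the mean of the two line means, so
pooled cohorts are centred near L/⟨L⟩ = 1.  The estimator-recovery study
(200 replicate cohorts of 60 + 60 embryos, ξ-noise s.d. 0.01) shows bias
below 0.01 and empirical CI coverage inside [0.92, 0.98] for slopes in
{−0.19, 0, 0.33}.  Level comparisons use the equal-variance two-sample
two-tailed t-test (Welch variant behind a flag), with star coding
p < 0.05 → \*, p < 0.01 → \*\*.  Threshold-crossing positions are measured
on *unnormalized* group-mean profiles; a threshold the profile never
reaches is reported as missing rather than an error so that time-series
tables stay rectangular.  No multiple-testing correction is applied across
boundaries or time classes.

## Gene-circuit model

State variables are per-nucleus concentrations of Hb, Kr, Gt and Kni.
The regulation function is the standard gene-circuit sigmoid
g(u) = (u/√(1+u²)+1)/2 (a logistic alternative could be slotted in; the
algebraic form is the field's default and has analytically convenient
symmetry g(−u) = 1 − g(u)).  Diffusion is nearest-neighbour exchange with
zero-flux ends (absorbing ends were the alternative; zero-flux conserves
mass in the diffusion-only limit, which the tests exploit).

* **Grid**: nc14 nuclei at the centres of 58 equal bins on [0.35, 0.92] EL
  (~1% EL spacing); nc13 uses 29 bins; at division each mother splits into
  the two daughters occupying its bin halves, both inheriting her
  concentrations.
* **Schedule**: nc13 interphase 16 min, mitosis 5 min with synthesis gated
  off, instantaneous division at 21 min, nc14 interphase 50 min — 71 min
  total.  Observation clocks are quoted as minutes after the thirteenth
  division.  The sub-durations are conventions isolated in the `Schedule`
  config; only the ~71 min total is anchored.
* **Inputs**: Bcd is a static exponential A e^(−x/λ).  Cad and Tll are
  tabulated inputs interpolated bilinearly in time and position; the
  shipped tables are *synthetic stand-ins* (broad posterior Cad decaying
  through nc14; sharp posterior Tll sigmoid ramping up) — any table of the
  same layout replaces them.
* **Solver**: `scipy.integrate.solve_ivp` with LSODA, rtol = atol = 10⁻⁶
  by default, integrated piecewise over the three phases so the mitotic
  synthesis gate never presents a discontinuity to the adaptive stepper.
  The tests pin the integrator against a dt = 10⁻⁴ forward-Euler oracle
  (max abs difference < 10⁻³ a.u. over 1 min on a small instance) and
  against closed forms for pure decay, diffusion-only mass conservation
  and self-consistent steady states.

### The default parameter set

The historical parameter sets of fitted gap gene circuits are not
redistributable here, so the shipped defaults are the package's own
hand-tuned set.  The design uses the canonical regulatory logic: anterior
Hb maintained by autoactivation from its maternal initial step; Hb⊣Kr
setting Kr1; mutual Kr⊣kni setting the Kr2/Kni2 interface; kni/gt mutual
repression biased posteriorly by the much stronger Tll repression of kni;
posterior Hb driven by Tll; Kr, kni and gt reading Bcd directly (m = 0.18,
0.12, 0.04).  This yields the canonical trunk pattern (anterior Hb to
~0.48 EL, central Kr ~0.50–0.61, abdominal Kni ~0.63–0.73, posterior Gt
~0.73–0.78, posterior Hb from ~0.79) and the expected response to the
size-scaled Bcd input (A×1.6, λ×0.8): a lower Kr peak at every output time
and anterior displacement of the Kr2, Kni2, Kni3 and Gt5 boundaries.
Initial conditions are likewise synthetic: an anterior Hb step at 0.47 EL,
zygotic Kr/Gt/Kni starting at zero.  Any well-formed parameter set of the
documented schema runs unchanged.

## Experiment measurement

Model output is measured like embryo data: a cubic smoothing spline
(`scipy.interpolate.make_smoothing_spline`, penalty λ = 10⁻⁸ by default —
small enough that a noiseless single-bump profile's boundary is recovered
to well under 0.5% EL) is fitted per profile; its extrema are located in
spatial order (endpoint values serve as extrema for monotone profiles) and
the boundary between two consecutive extrema is where the spline equals
their mean.  Domain peak levels are spline maxima inside per-gene AP
windows shipped as configuration (posterior Hb 0.70–0.92, central Kr
0.40–0.66, posterior Gt 0.62–0.88, abdominal Kni 0.52–0.82).  The critical
position of two exponential gradients is evaluated in closed form,
ξ\* = ln k / (1/λ_s − 1/λ_c), and cross-checked against numeric
root-finding to 10⁻⁹.

## Problem sizes

The replication studies run 200 cohorts of 120 embryos (seconds on one
core); gene-circuit experiments integrate 232 ODEs for 71 min of model
time (sub-second per run).  These sizes give standard errors comfortably
below the effects being measured while keeping the full suite fast.

## Known limitations

* The generator's boundary placement is linear in L/⟨L⟩; curvature in the
  true scaling relation would not be detected by construction.
* T1/T2 assignment depends on the analysed cohort (median split), so a
  cohort heavily skewed toward one sub-stage will misassign; T3–T9 are
  cohort-independent.
* The circuit's default parameters are a demonstration set reproducing
  qualitative signatures, not a fit to embryo data; quantitative boundary
  positions from the default set should not be compared to measured
  embryos.
* The ΔW and movement statistics assume independent groups and report the
  plain difference-of-means standard error; no correction for multiple
  boundaries or time classes is made anywhere in the package.
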