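# Methods

## The physical model

A torsionally constrained DNA tether carries a rotor bead whose in-plane
angle θ tracks DNA twist.  Enzyme-induced unwinding of n base pairs
changes the equilibrium twist by n/10.5 turns (B-DNA helicity
10.5 bp/turn); traces are stored in bp unwound with unwinding positive,
i.e. bp = −Δturns × 10.5.  Conformational dynamics are modelled as a
continuous-time Markov chain over three states with twist levels 0 bp
(closed, C), 10 bp (R-loop intermediate, I) and 20 bp (open R-loop, O).
The closed→intermediate rate depends on RNP concentration through one of
two laws:

* linear: k_CI = kon_eff·[RNP] — bimolecular capture far from saturation;
* hyperbolic: k_CI = kopen·[RNP]/(Kd,init + [RNP]) — the lumped observable
  of a two-step scheme Cfree ⇌ Cbound → I under rapid equilibrium of the
  initial binding step.  Kd,init is the dissociation constant of the
  initial complex and kopen the unwinding rate out of it.

All other rates (k_IC, k_IO, k_OI, and the optional direct C↔O rates,
default 0 because direct closed↔open transitions are rare) are
concentration independent.  Free [RNP] is approximated by total [RNP]
(DNA is present at trace amounts relative to enzyme); concentrations are
in nM throughout.

The bead angle around a fixed twist level is an Ornstein–Uhlenbeck
process with relaxation rate κ and stationary SD σ.  Sampled at interval
Δt this is exactly AR(1):

    θ_{n+1} = μ + (θ_n − μ)·a + σ√(1 − a²)·ε_n,   a = e^{−κΔt},

which the simulator uses directly (no Euler discretisation error).  The
instrument's true stiffness/coupling values are not published; the
package defaults, κ = 200 s⁻¹ and σ = 1.5 bp, are chosen so that 1-bp
steps are resolvable at the 500 Hz analysis rate while leaving visible
sample-to-sample correlation (a ≈ 0.67).  They are package defaults, not
measured values, and are configurable.

Non-specific binding produces a prolonged baseline twist shift that
saturates with concentration; it is modelled as a constant per-trace
Langmuir offset ΔΘ([RNP]) = ΔΘ_sat·[RNP]/(K_D + [RNP]).  Dynamic
off-target binding kinetics are deliberately out of scope — the
observable in the assay is the persistent shift, and the re-zeroing step
(below) both removes it from the state analysis and measures it for the
binding isotherm.

### Enzyme presets

`dspry_config()` uses the hyperbolic law with kopen = 0.06 s⁻¹ and
Kd,init = 10 nM — the two-step parameters of the kinetically trapped
enzyme — with k_IC = 0.5 s⁻¹, k_IO = k_OI = 0.2 s⁻¹.
`dcas9_config()` uses the linear law with k_IC = 0.1 s⁻¹ and the same
I↔O rates.  The C↔I asymmetry (5-fold faster collapse for the trapped
enzyme) and the shared I↔O kinetics reflect the qualitative comparison
between the enzymes; the I↔O magnitudes themselves are package defaults
chosen to give intermediate dwells (~1.5 s) long enough to segment
reliably at 500 Hz yet short enough to accumulate hundreds of events per
hour.

## Trace preparation

Raw (x, y) bead positions are drift-corrected by fitting an algebraic
least-squares conic (ellipse) to each 1-s window and subtracting the
fitted center; non-elliptical or ill-conditioned windows fall back to a
Kåsa circle fit, and degenerate windows (< 5 points or collinear) to the
window centroid with a logged warning.  Angles are four-quadrant
arctangents, unwrapped with period one turn; samples at the exact origin
carry no angle and propagate the previous sample's value.  Spurious
integer-rotation jumps (bead passing through the origin) are repaired
automatically: a jump of ≥ 0.75 turns undone by an equal-and-opposite
jump is treated as an artifact and offset away, with a log record for
review — replacing the manual curation step of the original workflow.

Filtering to the analysis rate uses a boxcar mean over non-overlapping
blocks (10 samples for 5 kHz → 500 Hz).  The kernel is a stated
assumption — the published description fixes only the target rate — and
was chosen because it preserves level means exactly and smears a step
over at most one output sample.  Simulated analysis-rate data are
generated directly at 500 Hz.

After segmentation and clustering, traces are re-zeroed so the dominant
closed state sits at Δθ₀ = 0: the lifetime-weighted mean level of the
closed cluster is subtracted and recorded.  That recorded offset is
itself the non-specific baseline shift consumed by the Langmuir binding
analysis.

## Change-point segmentation

Within a segment the data are OU around a constant mean; the only free
parameters are the per-segment mean and the change-point times (the
level slope is fixed to zero).  Conditioning each segment's likelihood
on its first sample turns the model into independent Gaussian
innovations z_i = x_i − a·x_{i−1} with mean (1−a)μ and variance
σ²(1−a²); the innovation at a segment boundary belongs to neither
segment and is dropped.  The conditional MLE of a segment mean is
mean(z)/(1−a), and the residual-sum-of-squares improvement of a split,
divided by the innovation variance, is the generalized likelihood-ratio
(GLR) statistic.

Segmentation is recursive binary splitting: the best split of an
interval is accepted iff its GLR exceeds a threshold, then both sides
are re-scanned.  Full optimal partitioning was not used because the
referenced tool's internals are unpublished; binary segmentation with a
calibrated null threshold is auditable, fast (each scan is a vectorized
O(n) pass over prefix sums), and its single-split placement is verified
against a brute-force scan in the tests.

Because the null statistic depends only on the innovation count and the
minimum segment length — not on κ or σ — thresholds are calibrated by
Monte Carlo on standard normal draws (200 replicates, cached) to a
target expected false change-point rate per 100 s (default 0.1).
Calibration traces are capped at 100 s of samples; for longer traces
the per-100-s target is slightly conservative in aggregate because the
maximum statistic grows slowly with length.  The minimum segment length
defaults to 5 samples (10 ms at 500 Hz): dwell analysis later censors
at 100 ms, so shorter events need not be resolved reliably.

Noise calibration (κ from the lag-1 autocorrelation, σ from the sample
SD, both with asymptotic SEs) uses an event-free stretch recorded before
protein is introduced, mirroring the experimental procedure of fixing
global parameters on a pre-RNP baseline.

## States, merging and dwell times

Segments become states in two modes.  Short-match (3-bp seed)
experiments use a signed 1-bp threshold: unwound above +1 bp, overwound
below −1 bp (retained as its own label, excluded from C/I/O kinetics),
closed otherwise; exactly ±1 bp does not exceed the threshold.
Full-match experiments cluster levels into C (≤ 4 bp), I (4–15 bp] and
O (> 15 bp).  The printed level clusters sit at ~0, ~8–10 and ~20–21 bp;
the boundaries (4, 15) are package defaults placed midway between them
(the originally inherited numeric boundaries are unpublished) and are
configurable.  Boundary ties go to the lower cluster for determinism.

Consecutive same-label states merge: Δθ₀ is the dwell-weighted mean of
the contributors, dwells add.  Merging is idempotent and conserves total
dwell (property-tested).  Population histograms weight each 0.5-bp twist
bin by total dwell.

Dwell-time distributions are fit by maximum likelihood to a 1- or
2-component exponential mixture, left-censored at 100 ms: the
log-likelihood is Σ log f(t_i) − n log S(t_min), dwells below t_min are
excluded, and the 2-component optimisation is multistart Nelder–Mead in
(logit p, log k₁, log k₂).  A mixture pinned at p → 0/1, or one that
fails to beat the single-exponential likelihood, collapses to the
closed-form single-exponential fit (k = 1/(mean − t_min)).

## Rates and capture-model fits

Transition rates use the occupancy estimator k_ij = N_ij/T_i with
Poisson SE √N_ij/T_i (one-sided 1/T_i when no transitions were seen).
Counting starts after the first transition event, so the initial waiting
time — which begins before enzyme arrives — is excluded.

k_CI versus concentration is fit by weighted nonlinear least squares.
Two weighting modes exist.  With externally supplied errors, weights are
1/se² as given.  When the rates are count-based estimates, weighting by
the *observed* Poisson errors is biased: a point whose count happened to
come out low also gets a smaller error bar and hence more weight,
systematically pulling saturation fits toward larger Kd (about +30% in
this package's validation runs).  Supplying per-point occupancy times
switches to iteratively reweighted least squares with *model-expected*
counts (se_i = √(k_model(c_i)/T_i), four iterations), which is
asymptotically the Poisson maximum-likelihood fit; the pipeline uses
this mode.  Model selection in auto mode is an extra-sum-of-squares
F-test at α = 0.05, with per-model override supported (and used in
reproduction configurations, where the model per enzyme is fixed).  A
hyperbolic fit whose Kd exceeds 10× the largest measured concentration
is flagged: saturation was not observed, only the low-concentration
slope is identifiable and kopen is reported as a lower bound.

The two-step interpretation of a hyperbolic fit reports Kd,init, kopen,
koff_init = kon_init·Kd,init at an assumed kon_init (default
0.1 nM⁻¹s⁻¹, configurable) and the effective low-concentration on-rate
kopen/Kd,init, under the rapid-equilibrium assumption for the initial
binding step.

Langmuir isotherm fits of baseline shifts use weighted least squares
with parameters ΔΘ_sat and K_D; all-zero shifts are rejected as
unidentifiable.

## Free-energy landscapes

Apparent equilibrium constants are rate ratios K_ij = k_ij/k_ji and free
energies ΔG_ij = −ln K_ij in k_BT units (temperature enters nowhere
else).  Landscapes over Cfree → Cbound → I → O at a stated concentration
(default 100 nM) accumulate well energies along the pathway, with the
binding step contributing −ln([RNP]/Kd,init) by mass action.  Barrier
heights are −ln k_forward + C above the preceding well with C = 7 k_BT,
an explicitly arbitrary offset: rate ratios determine well depths but
not absolute barrier heights, so only barrier *differences* between
conditions are meaningful.  The Cfree well coordinate (−5 bp) is
illustrative.  Antisymmetry ΔG_ij = −ΔG_ji and loop closure under
detailed balance are asserted in tests.

## Bulk-assay fits

Cleavage time courses (fraction cut vs minutes) are fit to
Y = A(1 − e^{−k t}) (mono) or the two-component analogue (double, with
k_fast ≥ k_slow by convention).  The auto rule fits double first and
falls back to mono when the second phase is poorly defined,
operationalised as: Aslow < 0.05 ("amplitude close to zero"), or the
double model failing an extra-sum-of-squares F-test against mono at
α = 0.05.  An inflated SE of Aslow alone is not grounds for fallback —
in curves whose slow phase has not saturated by the last time point,
Aslow and kslow trade off strongly and the amplitude SE blows up even
when the two phases are unmistakable; the F-test separates that benign
degeneracy from a genuinely absent phase.  Exponential rates are bounded
above by 2/t_first (a phase completing before the first sample is
unresolvable — the assay's kinetic detection limit), and the multistart
optimiser prefers solutions whose component amplitudes are ≥ 0.05 when
they are RSS-equivalent (within 20%) to the unconstrained optimum,
rejecting degenerate vanishing-amplitude optima.  Both thresholds are
configurable.  Replicates can be fit independently with parameters
reported as mean ± SD, or averaged first and fit once; both modes are
provided because published practice uses each in different places.

2AP fluorescence fits fix Y0 to the mean of a non-targeting control and
fit only Ymax and kobs.  The active fraction is the 2-h cleavage
endpoint, recorded as an identity with provenance.  %DSB is
100·(1 − N_target/N_reference) from droplet counts; negative values
(sampling noise) are reported raw with a warning.  Permanganate
footprinting normalises each lane's band volumes to cleavage
probabilities and subtracts the no-permanganate control; per-lane
probabilities sum to 1 and oxidation probabilities to 0 by construction.

## What the generator does and does not emulate

The synthetic module reproduces the statistical structure the analysis
assumes: Markovian state switching, exact OU observation noise,
concentration laws, Langmuir baseline shifts, and the closed-form bulk
expectations with Gaussian (tables) or Poisson (droplet counts) noise —
the noise models themselves are package choices where no published noise
model exists.  It does not emulate instrument drift, tracking artifacts,
bead-size variability, force fluctuations, supercoiling, photophysics,
or non-Markovian kinetics.  Passing recovery tests therefore
demonstrates the correctness and calibration of the analysis chain under
its own model assumptions, not robustness to every failure mode of real
recordings (drift correction and artifact repair are tested on their own
synthetic corruptions).

## Problem sizes and reproducibility

Validation runs use sizes chosen to make estimator scatter small
relative to the quantities tested: the capture-model recovery simulates
120 min per concentration at 7 concentrations (1–100 nM, 500 Hz), giving
~40 closed→intermediate events at 1 nM and ~400 at saturation
(validated recovery across seeds: kopen within ~10%, Kd within ~±20%);
level recovery uses a 30-min three-state trace with ≥ 50 visits per
state; isotherm and cleavage recoveries use the stated designs (5
tethers at 0.3 bp noise; triplicates at 0.02 noise, 12 time points).
Every stochastic stage takes an explicit seed and reproduces
bit-for-bit; pipeline runs emit a manifest with SHA-256 hashes of every
output.

## Known limitations

* Binary segmentation is not exact optimal partitioning; near-threshold
  events at the minimum segment length can be merged or split
  differently than a global optimiser would.  Missed sub-resolution
  intermediate dwells bias estimated rates downward by a few percent at
  the default settings.
* The null-threshold calibration targets the false-positive rate of the
  first split; subsequent recursive scans inherit the same threshold,
  which is slightly conservative.
* Rate estimation includes the final (right-censored) dwell in
  occupancy, a small downward bias that vanishes with event count.
* The hyperbolic Kd estimator remains slightly upward-biased at small
  event counts even with expected-count weighting (nonlinear
  small-sample bias); the chosen problem sizes keep it within a few
  percent.
* The Langmuir baseline shift is static per trace; true off-target
  binding dynamics are out of scope.
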