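# Methods

This note documents the models, numerical choices and synthetic-data
conditions behind `ssbdyn`, and what the test suite does and does not
establish.

## Polymer mechanics

The extensible freely jointed chain relates force to extension as
L(F) = Lc·[coth(x) − 1/x]·(1 + F/S) with x = 2·F·Lp/kBT. The Langevin
bracket is evaluated with a series expansion (x/3 − x³/45) below x = 10⁻⁴
to avoid catastrophic cancellation; F ≤ 0 is a domain error and callers use
the analytic limit L(0⁺) = 0. Constants: S = 800 pN for ssDNA,
kBT = 4.11 pN·nm at 25 °C, kB = 1.380649×10⁻² pN·nm/K for general
temperature conversion (so 4.1 pN·nm ≈ 1 kBT at 25 °C).

Fitting minimises distance residuals (L predicted from F): force is the
controlled variable in an acoustic-force ramp. Free parameters default to
(Lc, Lp) with S fixed; bounds Lc ∈ (0, 100 μm], Lp ∈ (0, 100 nm] keep the
Langevin argument well conditioned, and the initial guess is
Lc = max observed distance, Lp = 1 nm. The force window is clipped to the
data's force support and the effective window reported rather than silently
extrapolated; fewer than 5 in-window samples is an error. Retraction curves
are the default fitting input (extension phases can be contaminated by
surface sticking at low force). Phase monotonicity is checked on a
5-sample median-filtered force series and violations only warn, since
measurement noise legitimately breaks strict monotonicity.

Energies between curves are trapezoid integrals of the force difference on
the union of the two distance grids restricted to their overlapping
support, with linear interpolation; μm·pN areas are converted to pN·nm and
kBT. The trapezoid-on-union-grid scheme agrees with adaptive quadrature to
better than 0.5% at ≥ 200 samples (regression-tested). Note that for
synthetic curves generated on a common force grid, the overlapping distance
support itself depends on the parameters, so cross-condition ΔE magnitudes
are comparable only over a shared support.

## Compaction kinetics

L0 and I0 are means over the first three movie frames. The salt-onset time
t0\* uses an invented, parameterised rule (the original criterion is not
published): the trailing 3-frame rolling mean of L/L0 must fall below
1 − δ (δ = 0.05) and stay there for 3 consecutive frames; the onset is then
refined backwards to the last frame whose raw normalised length is within
δ/2 of the plateau, which cancels the rolling-window lag and is exact to
±1 frame on noiseless traces. A pre-onset plateau shorter than 5 frames
warns. The refinement conditions the onset frame on being near the plateau,
which biases the ensemble's t\* = 0 point slightly above 1 under noise
(by less than the per-frame noise SD); tests account for this.

Ensembles are built on a common t\* grid at the movie frame interval with
linear interpolation and no extrapolation — a molecule contributes only
inside its own time support, and the per-point molecule count is reported.
The decay β·exp(−kc·t\*) + Lf/L0 is fitted to the ensemble mean
(unweighted by default; √n weighting optional), with 95% confidence
intervals as 1.96 σ from the fit covariance. A per-molecule fitting mode
exists but ensemble-mean fitting is the default.

Generator conditions: 60 molecules per ensemble; per-molecule L0 lognormal
(CV 0.15) around the regime median (2.56 μm WT-like, 4.14 μm mutant-like);
plateau of 10 frames plus 0–3 frames of onset jitter; frame interval 5 s;
additive noise SD 0.05 in normalised units. Amplitudes follow the measured
salt dependence (β = 0.63 at 100 mM, 0.80 at 400 mM). Compaction rates are
not printed in the source figures, so defaults encode the reported
ordering — kc = 0.02 s⁻¹ (WT, high salt) halving per condition step (2×
slower at low salt, 2× slower for the variant) — chosen once as realistic
for decays completing within a few-minute movie.

## Dissociation kinetics

The two-state scheme W → B → free (dissociation only from B, no rebinding)
has the closed form w(t) = w0·e^(−k₋w t),
b(t) = b0·e^(−k₋b t) + w0·k₋w/(k₋b − k₋w)·(e^(−k₋w t) − e^(−k₋b t)),
switching to the degenerate form (b0 + w0·k·t)·e^(−k·t) when the rates
agree to a relative 10⁻⁹; the closed form matches RK-integrated ODEs to
10⁻⁸ of the initial pool, including across the degenerate diagonal.

Counts are real-valued (intensity / single-fluorophore intensity /
labelling efficiency), never rounded. Fitting is unweighted least squares
(Poisson weighting optional) with non-negativity bounds and a small
multi-start over rate guesses taken from the head and tail slopes of the
log-trace. A single-exponential comparison fit is always reported with AIC,
and rate pairs within a factor 2 are flagged as weakly identifiable: the
model's two pools are then nearly indistinguishable.

Photobleaching multiplies the observed intensity of either pool by
e^(−k_bleach t), so both apparent rates exceed the true ones by exactly
k_bleach; correction subtracts it from both rates (floored at zero with a
warning) and refuses to run twice. The bleach rate itself is estimated from
a no-dissociation control as a single-exponential rate; controls whose
first-decile endpoint rate and tail rate differ more than 3-fold warn that
the trace is not single-exponential. The amplitude redistribution caused by
bleaching (the fast pool's effective amplitude shrinks) raises the variance
of k₋b estimates, so the correction-bias test uses a 400-molecule ensemble
to separate the systematic from sampling noise.

The Gillespie generator draws exact exponential waiting times per tetramer
(W-dwell, then B-dwell), gives each of the 4 subunits an independent
fluorophore (present with the labelling-efficiency probability, bleaching
at k_bleach), and samples the visible-fluorophore count at the camera
interval. Bleached-but-attached tetramers remain attached and invisible —
deliberately reproducing the confound that rate subtraction corrects, so
tests can measure the correction's residual bias. Regime presets: WT-like
= 112 tetramers, 2/3 wrapped (w0 ≈ 300, b0 ≈ 150 monomers), k₋w = 0.004,
k₋b = 0.03 s⁻¹; R107Q-like = 550 tetramers, half wrapped
(w0 ≈ b0 ≈ 1100 monomers), k₋w = 0.012 (3× faster), k₋b = 0.03 s⁻¹;
k_bleach = 5.9×10⁻³ s⁻¹; 5-s sampling over 900 s.

Coverage: (tetramers_binding×30 + tetramers_wrapping×60) / template_nt,
with tetramers = monomers × mode fraction / 4 and a 48,502-nt default
template; capped at 1 with an over-saturation warning.

## Competition

Classification thresholds default to 3× the per-channel background SD
(the original thresholds are unstated) and are fully configurable.
Molecules below both thresholds cannot be distinguished from uncoated DNA
by fluorescence and are excluded from the percentage base (their count is
reported) — percentages therefore sum to 100 over visible molecules.
Channel cross-talk is assumed zero. Composition on co-coated molecules is
the calibrated-count ratio, invariant to common rescaling of the two
calibrations. Real-time exchange summaries interpolate each channel's
traces onto that channel's first time base and report mean ± SD plus the
sign of a linear trend.

## Bulk assays

The 1:1 Langmuir model is fitted globally (shared k_on, k_off, R_max across
all phases and concentrations) in log-parameter space, which keeps rates
positive and well scaled across decades; dissociation phases start from the
association model's value at the association end time, coupling the phases
through a shared k_off. Single-concentration panels fit but warn about
k_on/K_d identifiability. Mass-photometry fits are histogram-free: the
single-component MLE is the sample mean and SD (floored at
bin_width/√12 = 0.58 kDa for degenerate samples), and multi-component fits
use an EM Gaussian mixture; the component count is user-chosen, never
auto-selected. The monomer mass is taken as 16.8 kDa where concentrations
are computed, while the tag-inclusive tetramer is usually quoted as
~65 kDa (4 × 16.8 = 67.2); both constants are kept and the discrepancy
documented rather than resolved.

## TIRF quantification

An explicit stand-in for an undescribed manual/vendor measurement, valid
only on synthetic images. Background is the per-frame median with a
MAD-derived sigma; pixels above median + k·σ (k = 3) form connected
components, and components smaller than 4 pixels are discarded as noise.
Length is the full-width-at-half-maximum extent of the component's
per-column peak profile along the flow axis (columns by convention): the
half-max crossing of a PSF-blurred uniform filament sits at the true edge,
making the measure PSF-width independent (≤ 1 px error on synthetic
filaments). Photometry sums background-subtracted intensity over the
component dilated by 3 px, recovering PSF tails below the threshold (≤ 2%
error at the default PSF). Frames with a majority of pixels at the
intensity ceiling, or with >50% above threshold, are rejected as
saturated. Tethered molecules have stationary anchors, so frames link by
nearest-anchor matching within 3 px; tracks shorter than 3 frames are
dropped. The movie generator deposits per-frame line sources blurred by an
isotropic Gaussian PSF on a constant background with Gaussian read noise —
no EMCCD gain, drift, or illumination-field structure.

## Synthetic data and what passing tests show

Generators define the study conditions (sample sizes, pool sizes, rates,
noise levels listed above); each emits a ground-truth sidecar, and all
recovery tests compare generated data only against that sidecar. Fixed
seeds make outputs bit-identical (regression-tested). The generators
emulate the statistical structure each stage assumes — exponential decays,
Markov dwell times, multinomial class draws, Langmuir responses, Gaussian
PSFs — but not instrument systematics (drift, illumination fields,
cross-talk, force-calibration error, secondary-structure effects). Passing
tests therefore demonstrate the estimators' correctness and calibration
under their own model assumptions, not robustness to real-data artifacts.

Statistical test design: ensemble-vs-model comparisons use 3-SE bands on a
thinned checkpoint grid (a per-point 3-SE criterion over hundreds of
correlated points would fail by chance); bias checks for stochastic fits
use a large ensemble or a median over seeds rather than a single draw.

## Pipeline

All randomness flows from one top-level seed via
`numpy.random.SeedSequence(seed).spawn` in stage order. Run configurations
are validated before execution (unknown keys rejected); every run directory
carries the config hash, a parameter echo and package version, and reruns
with the same config and seed are bit-identical for deterministic stages.
Results are JSON, tables CSV, images TIFF — diff-able, language-neutral
artifacts. Problem sizes in the analysis scripts (50–60-molecule ensembles,
5,000 mass events, 300-molecule two-color tables, 20-seed Monte-Carlo
loops) are the regime sizes stated above; each script runs in seconds to a
minute on one CPU.

## Known limitations

- The salt-onset rule is a stand-in; its δ and persistence parameters
  should be recalibrated against any real supplementary criterion.
- The two-state fit treats molecules independently; a shared-rate global
  mode across molecules of a condition is available only via the
  ensemble-mean path.
- No rebinding term: the model cannot describe conditions where free
  protein re-associates during the salt wash.
- Heterotetramers (mixed WT/variant subunits) are out of scope for the
  competition analysis.
- The TIRF module measures axis-aligned extent, not arc length; it is
  only meaningful for flow-straightened filaments.
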