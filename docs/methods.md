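# Methods

## Scope

`pulsedecode` implements an end-to-end analysis of single-cell
fluorescence experiments in which p53 expression dynamics are modulated by
square-wave Nutlin-3 dosing and decoded at target gene promoters. The
package covers regimen definition, synthetic data generation, trace
processing, promoter-model fitting, activation metrics, clustering and
frequency-filter classification, and geminin-based cell-cycle scoring.
Image segmentation is out of scope: inputs are per-cell mean-fluorescence
traces in long-format tables (`cell_id, channel, time_h, value_au,
division`), sampled every 20 min over 24 h (40 h for cell-cycle movies).

## Dosing regimens

A regimen is a square wave: `dose` μM for `t_on` hours, drug-free for
`t_off` hours, repeating until `total_time` (truncated mid-phase at the
end). The six canonical schedules are natural (10 μM, 3/2.5 h; period
5.5 h), low frequency (3/8 h), high frequency (2.5/2 h), long duration
(8/3 h), and low/high amplitude (5 or 15 μM at natural timing). Values at
switch instants are right-continuous, which makes sampling on the 20-min
grid unambiguous. Regimens are data (YAML-serializable), not code.

## Promoter model

Reporter accumulation follows a delayed Hill ODE,
d[mCherry]/dt = k_max·p(t−τ_d)ʰ/(Kʰ + p(t−τ_d)ʰ) − γ·[mCherry], with
τ_d = 2 h (transcription + translation + fluorophore maturation) and
γ = 6.7 × 10⁻⁴ min⁻¹ (converted internally to 0.0402 h⁻¹). Integration is
fixed-step classical RK4 with 20 sub-steps per 20-min frame; halving the
step changes trajectories by < 0.1%. The delayed signal is linearly
interpolated on the sampling grid, with pre-history (t < τ_d) clamped to
the t = 0 value.

Dose–response curves pair p53(t − τ_d) with the reporter production rate
(finite-difference derivative: central in the interior, one-sided at the
ends) frame by frame over the first 15 h; later times can be confounded by
promoter refractoriness, and γ is negligible on that window so no decay
correction is applied. Venus-tagged p53 is converted to a total-p53 scale
by dividing by `venus_fraction` (default 1 for synthetic data, which is
already on total scale; a real-data value must come from quantitative
blotting).

Fitting minimizes the sum of squared rate residuals over (k_max, h, K)
with bounds k_max ∈ (0, 10·max rate], h ∈ [0.5, 20], K ∈ (0, 2·max p53],
multi-started from a coarse log-spaced grid of initial guesses. A
brute-force oracle (`fit_hill_grid`, 20³ lattice refined once around the
incumbent) cross-checks the optimizer. Because the three parameters are
correlated along a flat loss valley, lattice points within one coarse
cell can have nearly identical loss; agreement between optimizer and
oracle is therefore asserted at the coarse-cell scale together with a
direct loss comparison, not at fine-lattice resolution.

### Parameter recovery

The recovery experiment (also run by `scripts/acceptance.py`) simulates
the reporter under a noiseless long-duration p53 input that sweeps
~20–700 normalized AU, rebuilds the dose–response, and refits. The input
is sampled at 2-min resolution: on the microscopy 20-min grid the steep
Hill transition (h ≈ 7–7.5) is crossed in about two frames and the
finite-difference production rate biases the fitted Hill coefficient by
roughly 13%; at 2-min spacing every parameter is recovered to < 0.2%.
With 5% multiplicative rate noise on 45 points (one seeded draw), recovery
stays within 15%. Fits of noisy population means at 20-min sampling
underestimate k_max and h for the same reason and because amplitude
heterogeneity convolves the Hill curve; such fits should be read as
effective, not mechanistic, parameters.

## Synthetic data

The generator emulates the statistical structure of the measured traces,
not p53 biochemistry. Each on-phase triggers one pulse: linear rise at a
fixed accumulation timescale (`rise_time` = 3 h, the natural on-duration),
capped at the pulse amplitude for the remainder of the on-phase, then
exponential decay (half-life 1 h) after washout. Because the rise
timescale belongs to p53 stabilization kinetics rather than to the
schedule, on-phases shorter than 3 h reach proportionally lower peaks —
reproducing the reduced pulse amplitude seen under high-frequency dosing.
Pulse amplitude scales linearly with dose relative to 10 μM (matching the
observed ordering low < natural < high amplitude without inventing a
binding curve) and varies per pulse as a unit-mean lognormal with
CV = 0.70, the amplitude variability reported for damage-induced pulses.
Measurement noise is additive Gaussian (sd 5 AU on a ~600-AU signal). All
randomness flows through one seeded generator recorded in the output
metadata; identical seeds give bit-identical outputs.

Default scale: basal 20 AU, mean pulse amplitude 580 AU at 10 μM, so the
natural pulse peaks near 600 normalized AU — between and above the two
reference half-activation thresholds (407 and 490), which is what makes
amplitude thresholding visible across regimens.

What the generator does *not* emulate: cell-to-cell baseline variation,
photobleaching, segmentation/tracking errors, pulse-timing jitter, and
promoter-intrinsic adaptation. Passing tests therefore demonstrate the
pipeline's correctness on data with the assumed structure, not robustness
to every artifact of real movies.

Geminin traces: arrested cells stay at basal for the whole 40 h;
progressing cells start an elevated episode at a random G1/S time,
either sustained to trace end or ending in an annotated division
(pulsatile). The feedback emulator is a two-variable ODE (p53 produced at
a constant rate and degraded by MDM2, with Nutlin inhibiting that
degradation; MDM2 induced by delayed p53 through a Hill term) started at
its drug-free fixed point. It is deliberately qualitative: only
directions are asserted (elevated MDM2 at 5.5/11 h and a suppressed
second p53 pulse under long-duration input), never magnitudes.

## Trace processing

Background is estimated as the mode of the intensity histogram (tallest
bin center) and subtracted with flooring at zero. Missing frames are
linearly interpolated (nearest-value extension at the ends); frames
around annotated divisions are marked missing and re-interpolated.
Smoothing defaults to a centered 3-frame (1-h) moving average with edge
shrinkage; the smoother is pluggable since the original study's exact
filter is not identifiable from its description. Traces are normalized to
the cross-cell mean at t = 0 when lamp-condition correction is wanted.
QC keeps cells whose pulse count (prominence ≥ 0.2 of trace range)
equals the regimen's number of completed on-phases and whose largest
frame-to-frame jump stays below half the trace range (spike rejection);
both thresholds are exposed.

## Activation metrics

A cell *responds* if its final reporter level is at least twice its trace
minimum (traces with non-positive minima fall back to a dynamic-range
floor and are flagged). For responders: baseline = mean of the first
3 frames (1 h), peak = trace max, magnitude = baseline + (peak −
baseline)/2, timing = first crossing of that level (linear interpolation
between frames), rate = least-squares slope between activation onset
(baseline + 10% of dynamic range) and the timing point. The baseline
window and onset fraction are configurable; directional conclusions are
tested for robustness to ±1 frame and ±5% threshold.

The matched-exposure comparison fixes C* = cumulative p53 of the
long-duration reference at its first pulse peak, finds the earliest time
t_X at which a comparison regimen's cumulative p53 reaches C*, and
measures the mean reporter slope between the comparison's first p53 peak
and t_X + 5.5 h (the natural pulse period). Self-comparison reduces
exactly to the plain interval slope. Group differences use equal-variance
two-sample t-tests with significance at P < 0.05.

Note on per-trace-normalized metrics: because magnitude and timing are
defined relative to each trace's own dynamic range, a regimen that keeps
accumulating (long duration) raises its own half-max and can show a
*later* own-range timing despite activating faster in absolute terms.
Duration comparisons therefore also report the fixed-level crossing time
and the matched-exposure rate, which are the readouts in which stronger
activation by longer pulses expresses unambiguously.

## Clustering and frequency filters

Activation traces are clustered by k-means (k = 4, 5 restarts, seeded)
under correlation distance (1 − Pearson r). Each trace is standardized to
zero mean and unit norm — correlation distance is then half the squared
Euclidean distance — and centroids are re-standardized after every mean
update. Ties go to the lowest-index centroid; an emptied cluster is
reseeded with the farthest member of the largest cluster. The best of
five restarts (lowest total distance) is kept.

Frequency-response profiles evaluate one metric at the low, natural and
high pulse frequencies and classify with margin δ = 0.2 (configurable):
band-pass if the natural response exceeds both neighbors by more than δ;
low-pass if low ≈ natural (within δ) and both exceed high; all-pass if
all three are within δ of their maximum; otherwise unclassified.

Readout choice matters, and the package is explicit about it. In a
feedforward Hill simulation any cumulative readout (e.g. activation
magnitude over 24 h) grows with the number of pulses delivered, so the
low-frequency response is necessarily about half the natural one; in that
readout a low-threshold/high-gain promoter (MDM2-like) classifies as
band-pass — natural beats low on pulse count and beats high on amplitude
thresholding (short on-phases yield sub-threshold pulses) — but a
high-threshold promoter cannot appear low-pass. Normalizing the same
metric by cumulative p53 exposure (the matched-exposure logic applied to
frequency) compares regimens per unit input; there the high-threshold
CDKN1A-like promoter classifies as low-pass (low ≈ natural per exposure,
high suppressed by thresholding), while the MDM2-like promoter's
natural-vs-low separation vanishes by construction. No single readout of
this model reproduces both assignments simultaneously; the in-vivo
band-pass/low-pass phenomenology additionally involves promoter-level
adaptation that a memoryless Hill function does not capture.
`frequency_response_profile(..., normalize_by_exposure=...)` exposes both
readouts, and the integration tests assert each promoter's class in the
readout where its mechanism expresses.

## Cell-cycle scoring

The elevated-geminin threshold is 1.5 × the cell's own first-hour
baseline (scale-invariant; factor configurable). A cell progresses if it
shows a contiguous elevated episode of ≥ 5 h (S/G2 accumulation;
`min_episode_h` configurable) — *pulsatile* if an episode returns to
basal before trace end, *sustained* otherwise. A cell is arrested if it
has no qualifying episode and spends more than 25 of the 40 hours at
basal (the cutoff is prorated for shorter traces when scoring is forced).
Divisions are counted from annotations only; automatic drop detection is
out of scope. Population summaries report percent divided, percent
geminin-positive (= progressing), and the per-status breakdown.

## Problem sizes and determinism

Default test and example sizes — tens of cells, 73–121 frames, 2-min
grids only for the recovery experiment — were chosen so every analysis
runs in seconds on a laptop while leaving the statistical checks
(amplitude CV, arrest-fraction recovery, cluster recovery) well
separated from their tolerances. Every stochastic path takes an explicit
seed, and rerunning any stage with the same inputs and seed is
bit-identical.

## Known limitations

- The promoter model is memoryless; refractory and adaptation phenomena
  are emulated qualitatively (feedback module) or not at all.
- Per-cell Hill fits on noisy 20-min traces are ill-conditioned and
  should be treated as descriptive; population-mean fits at microscope
  sampling systematically underestimate k_max and h (see Parameter
  recovery).
- The original study's printed effect sizes (fold-changes, division
  percentages) are properties of its deposited datasets; the pipeline
  computes the same quantities from any supplied trace tables but does
  not ship those data.
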