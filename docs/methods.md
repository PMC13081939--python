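# Methods

`omnquant` quantifies two sides of one biological question — how the
developmental origin of zebrafish extraocular motor neurons (nIII, nIV)
maps onto vertical/torsional eye-movement behavior — as a fully synthetic,
testable pipeline: tilt-stimulus kinematics, torsional video-oculography,
vestibulo-ocular reflex (VOR) gain with genotype statistics,
photoconversion birthdating with topographic soma counts, and
transcriptomic candidate selection.  Every stage consumes inputs the
package can generate itself with known ground truth.

## Stimulus model

The tilt protocol is a trapezoidal velocity profile: constant acceleration
`a` up to peak velocity `v`, a constant-velocity plateau, and a symmetric
deceleration.  For a step of amplitude `A` the duration is
`t = 2 v/a + (A − v²/a)/v`; a trapezoid exists only when `A ≥ v²/a`,
otherwise construction fails loudly (triangle profiles are rejected, not
approximated).  Defaults follow the published assay: `A = 15°`,
`v = 35 °/s`, `a = 150 °/s²`, 50 cycles of four steps (nose-up toward the
ceiling, back to horizon, nose-down, back), sampled at 200 Hz.  With these
values the plateau lasts 195 ms (39 samples).

Choices the protocol description leaves open:

- **Step order within a cycle** (up-toward, up-away, down-toward,
  down-away) is a configurable permutation; the default is arbitrary but
  fixed.
- **Dwell between steps** (`hold_duration`, default 7.5 s) is long enough
  for responses to settle; analyses in this repository use 1.5 s dwells
  and 2 cycles where only step kinematics matter, purely to keep arrays
  small — the per-step waveform is identical at any cycle count.
- The continuous-time profile is evaluated exactly at grid times (no
  band-limiting), matching how a motion controller tracks a commanded
  profile.

Segmentation recovers steps from a platform trace as upward crossings of
|velocity| through a threshold (default 5 °/s — far above numerical
noise, far below the 35 °/s peak), then walks each onset back to the
first moving sample so onsets align with the true start of motion within
±2 samples.  Direction (nose-up/nose-down) and phase (toward/away from
the horizon) come from the start/end angles.

## Synthetic eye plant

The simulated eye counter-rotates against the platform (compensatory sign
convention; gains are reported as positive magnitudes).  Two plant modes:
**proportional** (`eye = −g·platform`, with direction-specific gains
applied to the nose-up and nose-down parts of the trajectory) and
**first-order lag** (the same target filtered through
`dy/dt = (x − y)/τ`, discretized exactly).  The real larval plant's
dynamics are unknown at this level of detail; all tests score estimates
against recorded truth, never against plant realism.  Saccades are
injected as single-sample persistent position jumps from a Poisson
process — the simplest event that produces the "rapid deviation in eye
position" an exclusion rule must catch — and measurement noise is
additive Gaussian on the angle (default experiments use 0.1°).

## Torsion tracking

Torsional angle per frame is estimated by rotational registration: the
reference frame is rotated (bilinear interpolation) through a candidate
grid (±20° in 0.5° steps by default), each candidate is compared with the
frame by normalized cross-correlation over a circular mask, and the peak
is refined by a least-squares parabola fitted to the five grid points
around the argmax (`refine_points = 5`; 3 gives the classic exact
three-point parabola).  The five-point fit is the default because the
three-point parabola is noise-limited: its noiseless error (~0.002° RMSE
at these image sizes) is pure interpolation bias, so frame noise at
SNR 10 inflates error roughly three-fold, whereas the five-point fit
averages correlation noise and degrades only ~1.5× from a slightly higher
(still ~0.006°) noiseless floor.  Ties in correlation break toward the
smallest |angle|; refined angles never leave the searched range;
zero-variance frames get score 0 and carry the previous angle.
`track_session` warm-starts each frame's search ±2° around the previous
estimate (snapped to the global grid so rotated references are shared)
and falls back to the full range when the local peak sits on the window
edge, making it equivalent to the full search on slow traces.

The synthetic video is band-limited Gaussian noise (σ = 2 px smoothing)
inside a circular mask, rotated per frame — rotation-estimation
difficulty is controllable and no real eye images are needed.  The
tracker is an explicit stand-in for the original on-line pattern-matching
instrument, whose algorithm is not described; nothing here claims
bit-for-bit replication.

## VOR gain

Per step, the response is the peak compensatory eye velocity over the
first second after onset; per direction, gain = mean over retained steps
÷ peak platform velocity (measured from the trace by default, ≈35 °/s).
Velocity is the Savitzky–Golay first derivative (quadratic fit).  The
window default is **31 samples (155 ms)**: it fits inside the 195 ms
velocity plateau, so commanded peaks are exactly preserved (noiseless
gain recovery error is 0 to machine precision), while shrinking the
standard deviation of differentiated 0.1° noise from ~6.3 °/s (5-sample
window) to ~0.45 °/s.  Because the statistic is a windowed *maximum*,
differentiation noise biases it upward by roughly its own magnitude; at
the 5-sample window that bias is ~0.4 gain units, at 31 samples ~0.015 —
the wider window is what makes peak-based gain a usable estimator at this
noise level.

Artifact exclusion replaces the original manual curation with two
deterministic rules applied inside each response window: any
single-sample position jump > 3° (saccade) or |velocity| > 120 °/s
(tracking failure) rejects the step.  Exclusion and measurement are
independent — changing ceilings never changes a retained step's value.
Only "toward" steps count toward a direction's gain by default ("away"
steps return to the horizon and probe the opposite otolith drive);
unsigned-peak and away-inclusive modes are configurable.  A direction
with no retained steps reports a missing gain with a reason, never 0 and
never an imputation.

## Group statistics

Gains are compared across genotypes with one-way fixed-effects ANOVA and
all-pairs Tukey HSD.  The Tukey p is
`sf_studentized_range(q; k, N−k)` with the Tukey–Kramer standard error
`sqrt(MSE/2·(1/nᵢ+1/nⱼ))` for unequal group sizes.  Degenerate inputs
(zero variance everywhere, equal means) return the p = 1 family.  Tests
cross-check this path against `scipy.stats.tukey_hsd` and against an
independent 10⁵-permutation max-q family-wise oracle; at k = 2 the Tukey
p collapses to the pooled t-test p (verified to 1e-6).  Note the
permutation and studentized-range procedures are distinct tests that
agree only approximately at small n; the suite allows combined
Monte-Carlo plus small-sample slack.  Subnucleus counts use Welch's
t-test by default (robust to unequal variance; Mann–Whitney optional),
reporting the mean difference alongside p.

## Birthdating and counting

A cell is classified born-before-conversion iff its red intensity
**strictly exceeds** the threshold set from non-converted control fish —
`max(controls)` by default (the most conservative rule; a quantile rule
with numpy's linear interpolation is available for outlier-contaminated
controls).  Dorsoventral region assignment places a cell on a cut point
into the **dorsal-side** interval; both conventions are fixed and
documented because the source workflow is silent on them.  Cut-point
values are user configuration (the anatomical subdivision follows a
published scheme), never inferred.  Cumulative birthdate curves report
the fraction born per conversion timepoint (18–54 hpf) per region;
monotonicity violations are flagged, not corrected.  Count tables always
conserve the input cell total.

## Candidate selection

- **DE filter**: pass iff |log2FC| > 1 (fold change strictly greater
  than 2, on either side) and adjusted p strictly < 0.01; sign routes to
  early- vs late-enriched lists; genes with missing adjusted p are
  excluded with a warning.  P-value adjustment itself is upstream of this
  package.
- **GO over-representation**: per term with ≥1 selected gene,
  p = P(X ≥ k) for X ~ Binomial(n, K/N) — one-sided, upper tail only —
  with Bonferroni over the number of terms actually tested.  The
  background set is explicit user input.  The annotation is a flat
  gene→terms map; no ontology-graph propagation.
- **Single-cell QC**: the printed rules are exclusions (<1,100 genes,
  >15,000 genes, >4% mitochondrial counts), so boundary cells are
  retained.  Idempotent by construction.
- **Pattern summaries** partition probes over the 7 non-empty subsets of
  {dorsal nIII, ventral nIII, nIV} (counts always sum to the number of
  genes) and score agreement with the bulk/cluster prediction through an
  explicit category→regions map.  Defaults: early→dorsal nIII,
  late→ventral nIII or nIV, cluster0→ventral nIII or nIV, cluster1→nIV,
  cluster2→dorsal nIII, mirroring where each class's markers are found
  in situ; the map is an argument, not a constant.

## Synthetic-data fidelity and limits

Generators are pure functions of their parameters including the seed.
They emulate: trapezoidal platform motion; a compensatory plant with
direction-specific gain, saccade jumps and angle noise; rotating
band-limited eye texture; bimodal red fluorescence (converted cells
shifted by `separation` = 8 baseline SDs by default — cleanly separable,
as a successful conversion should be); DE tables whose null genes cannot
pass the filter by construction (padj ≥ 0.2) and spiked genes always do;
and QC tables whose failure classes each violate exactly one rule.  They
do **not** emulate: pupil/iris structure or illumination changes,
translation or scale drift in the video, plant nonlinearity or
habituation, fluorescence bleed-through or depth-dependent attenuation,
or realistic p-value/fold-change joint distributions.  Passing tests
therefore demonstrate correctness of the *quantification machinery* under
controlled conditions, not robustness to every failure mode of real
recordings.

## Problem sizes and numerical choices

Test and analysis runs use 2-cycle sessions with 1.5 s dwells (the
per-step waveform is identical to the 50-cycle protocol), 100–500-frame
100×100 px videos, 10⁵-permutation oracles at n ≤ 10 per group, and a
200-replicate null calibration (3 genotypes × 8 fish) — all chosen as the
smallest designs that exercise each property.  Ties, degenerate inputs
and boundary conventions are covered above; seeds are fixed everywhere
randomness enters, and identical seeds give bit-identical outputs.

## Known limitations

- The torsion tracker is rotation-only; translation of the eye within the
  window is not modeled or corrected.
- Automated artifact thresholds (3° jump, 120 °/s) are stated defaults,
  not a replication of any curator's judgment.
- Tukey HSD assumes normal within-group errors; with n of 6–10 fish per
  genotype the permutation cross-check is the more assumption-free read.
- The GO test treats genes as exchangeable draws (binomial), ignoring
  gene length or expression-level bias, matching the PANTHER-style test
  it mirrors.
- Saccades are single-sample jumps; real saccades have finite dynamics
  and post-saccadic drift, so the rejection rule's real-data sensitivity
  is untested here.
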