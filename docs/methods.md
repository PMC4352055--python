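# Methods

## The forward model

A module's activity is a 0–1 demand function of time: 1 while the module is
serving a request, 0 otherwise. Intervals are half-open `[onset, offset)`
in seconds, and intervals within a module never overlap (modules are serial
resources; concurrency exists only *across* modules). The predicted BOLD
signal is the convolution of the demand function with a hemodynamic
response function — equivalently, one HRF per activity period, summed. The
HRF is the conventional difference of two gamma densities: shape 6 for the
peak, shape 16 for the undershoot, unit rates, undershoot ratio 1/6, 32 s
support. With these defaults the kernel peaks at 5.0 s. The source names
this parameterization only by the analysis software that popularized it;
the numbers here are that software's long-standing defaults.

Demand functions are sampled on a `dt = 0.1 s` grid, convolved discretely
(scaled by `dt` to approximate the continuous integral) and read out at
scan times by nearest-sample lookup, without interpolation. Halving `dt`
changes scan-sampled predictions by well under 1 % (tested). Predictions
are in arbitrary amplitude units; a per-module scalar gain is fitted by
least squares whenever a prediction is compared against
percent-signal-change data, because the amplitude mapping between demand
and percent signal is not part of the model.

## Task models

These are *schedule-level* simulations: they reproduce the timing structure
of the two experiments, not a production-rule architecture. There is no
subsymbolic activation, no learning, and no conflict resolution beyond the
scheduler below.

**Pyramid algebra.** A problem `base $ height = value` is solved by
repeated addition starting at the base with terms decreasing by one
(4 $ 3 = 4 + 3 + 2 = 9), i.e. `height − 1` additions. The prose description
of the original model ("as many additions as the height") conflicts with
its own worked chain; the chain wins here. Solving for the height runs the
same chain until the accumulator matches the value; solving for the base is
a single guess-and-check step that evaluates one guessed base and reports
guess, guess + 1 or guess − 1 depending on whether the result was right,
too small, or too big. The initial guess is the upper midpoint of the
allowed base range 4–9 (i.e. 7); the guessing policy was not specified at
the source and the upper midpoint makes the procedure exact on the worked
solve-for-base problem. An addition carries when the units digits of its
operands sum to ten or more; each carry appends one extra problem-state
interval (`carry_extra`, default 0.2 s).

A trial's trace is strictly sequential: three visual encodes (base, height,
value slots; `encode_step` 0.3 s each), then per addition one declarative
retrieval and one problem-state update (`ps_step` 0.2 s), then one
right-manual interval per answer digit plus one for the submit click
(`motor_step` 0.5 s each, a mouse aiming + click cycle). The simulated RT
is the offset of the last manual interval. Retrieval durations are drawn
from a gamma distribution with mean 483 ms — the latency estimated from
behavior in the source dataset — and shape 2 (right-skewed, strictly
positive; the source states only the mean). Setting
`retrieval_shape = None` makes retrievals a 483 ms constant. A session is
72 trials, 18 per condition (small/large base 4–6/7–9 crossed with
small/large height 2–3/4–5), one per 51 s slot (30 s problem window plus
feedback, repetition detection and fixation).

**Threaded multitasking.** Three tasks — visual tracking, a 12-letter
2-back stream at 1000 ms on + 1500 ms blank, and counting the high tones
among 20 tones over 30 s (10–17 high per trial) — run alone or in pairs.
Each task is a thread of ordered resource requests; a greedy scheduler
assigns requests to module timelines. A module serves one request at a
time; competing threads queue first-come-first-served, with ties broken by
the earlier previous completion and then by a fixed task order (track <
nback < count). Stimulus-locked steps (tone onsets, letter onsets,
tracking samples) carry anchors and cannot start early. Whenever the
problem state changes hands between threads, a declarative store and a
declarative retrieve (0.3 s each) are inserted first — the swap. This
fires only in the tone-counting + 2-back condition, the only pairing in
which both threads hold state; it is how the model predicts that
condition's cost. Counting responses (one key press per counted tone) are
appended after the 30 s trial within the 10 s response window, with the
hand assignment of the original design (right hand alone and with 2-back,
left hand with tracking). Step durations not fixed by the design — letter
encode 0.185 s, tone encode 0.3 s, problem-state update 0.2 s, key press
0.25 s, tracking sample 0.2 s / press 0.15 s — were chosen once as
plausible perceptual/motor cycle times and are all configurable. A session
is 72 trials, 12 per condition, in 40 s slots. Mouse motion during problem
solving ("keeping the cursor on the gaze") is not modeled.

## Voxelwise regression and group maps

The design matrix holds one regressor per active module — the convolved
demand, mean-centered and scaled to unit standard deviation — plus
polynomial drift terms (order 1 by default) and an intercept. Unit-sd
scaling makes first-level coefficients directly comparable across modules
with very different demand duty cycles, and makes the synthetic generator's
injected amplitudes (below) the exact estimand of the regression. Modules
with empty or constant demand are dropped with a warning; rank deficiency
raises an error naming the most collinear column pair.

First-level fits are ordinary least squares per voxel (`t = β/SE`,
`df = scans − columns`); voxels with zero temporal variance are excluded.
The group map is a one-sample t across subjects per voxel
(`df = n − 1`, two-sided p, p floored at the smallest positive double and
t capped so zero-variance voxels remain finite). Thresholding keeps voxels
with `p < p_thresh` (default 10⁻⁷, uncorrected, as in the source
procedure), labels connected components (26-neighborhood by default; 6 and
18 selectable — the choice changes cluster counts and is therefore
explicit), removes components below `min_extent` (default 250 voxels), and
relabels survivors by descending peak |t|.

The dissociation (exclusive-variance) contrast for a regressor pair
computes, per subject and voxel, the difference of squared semipartial
correlations — R²(full) − R²(without A), minus the same for B — and takes
a group one-sample t over the differences; the positive tail is
A-exclusive. The exact statistic used in the original meta-analysis is not
published; the semipartial-r² difference is this package's stand-in.
Regressor pairs correlated above |r| = 0.99 are rejected.

## Region growing, restriction, mirroring

Growth starts at the most significant suprathreshold voxel (|t| by
default; a signed option exists) and repeatedly adds the most significant
suprathreshold voxel bordering the current region until `target_size`
voxels (default 100) or exhaustion of the component, in which case the
smaller region is returned with a warning — mirroring the source's
80-voxel manual region. Ties are broken by lowest linear voxel index, so
growth is fully deterministic. Anatomical restriction intersects the
*growth domain* with a label set before growing (as done for the manual
module, restricted to the precentral gyrus). Hemispheric mirroring
reflects member voxels through the world plane x = 0 mm and maps them to
nearest voxels — robust to affines whose midline falls between voxel
columns — dropping (with a count) any reflection that leaves the grid.
Centers of mass are unweighted means of member-voxel world coordinates.

## Evaluation

ROI time courses are unweighted spatial means. Event-locked curves take a
fixed window of scans from the scan nearest each trial onset, convert to
percent change relative to the onset-scan value (the baseline rule;
nothing else is implemented), and average within condition, then across
subjects. Aggregate fit statistics (TCC, R², RMSD) are computed on the
concatenation of all condition curves — one number per module × mapping,
matching the summary-table convention; whether the original aggregate was
concatenated or averaged per condition is not stated, and concatenation is
the choice here. The model is scaled by its fitted gain before RMSD; TCC
and R² are scale-invariant. Individual TCCs are computed per subject on
that subject's concatenated curves and summarized as mean, sd, min, max.

Behavioral filtering drops subjects whose accuracy does not exceed 85 %
(the retained boundary in the source is "> 85 %"), restricts to correct
trials, and removes trials with RT above mean + 2 sd of their subject ×
condition cell (one-sided: slow outliers are the stated concern; sample
sd; cells with fewer than two correct trials are left unfiltered and
logged). The trim is applied once, as in the source; re-applying it to the
filtered data can remove further trials because the cell statistics
shrink, so the filter is idempotent only once no surviving value exceeds
its own cell's cutoff.

## Synthetic data generator

The generator emulates a group study on a 40 × 48 × 40 grid at 4 mm
isotropic with an MNI-like affine (x negative = left) — small enough for
desk-scale tests while containing all published module centers, which are
shipped as constants (data-driven and original mappings) and used only as
generator defaults, never by any algorithm. True regions are spheres
(default radius 12 mm ≈ 113 voxels) around the data-driven centers, the
left-manual region mirrored to the right hemisphere. Each in-region
voxel's series is baseline (100) + amplitude × subject multiplier ×
(convolved demand of its module, normalized to unit temporal sd) + drift +
noise; other voxels get baseline + drift + noise. Normalizing the injected
response to unit sd makes `amplitude` the signal standard deviation in
scanner units, so `amplitude / sigma` is the temporal signal-to-noise
ratio independent of how sparse a module's demand is — without it,
brief-event modules (a 0.2 s problem-state update every few seconds) would
carry vanishing variance and no finite desk-scale study could localize
them. Defaults: amplitude 1, noise sd 1 (SNR 1), between-subject amplitude
multipliers with mean 1 and sd 0.2, white noise; an AR(1) option
(`x_t = ρ·x_{t−1} + e_t`, stationary sd `sigma`) and a linear drift are
available. Every subject gets fresh task traces, own multipliers and
independent noise from seeds spawned deterministically off one master
seed.

What the generator does *not* emulate: spatial noise correlation and
smoothing, physiological (cardiac/respiratory) noise, motion, susceptibility
artifacts, non-spherical and inhomogeneous activation, BOLD saturation and
other nonlinearities. Passing recovery tests therefore show that the
pipeline's statistics and geometry are correct under the stated noise
model, not that the procedure is robust to real scanner physics.

## Study sizes and scaled thresholds

The recovery self-check (`cogmap.pipeline.recovery_study`) uses 18
subjects, 12 multitask trials per subject (2 per condition, 40 s slots,
TR 2 s, 256 scans), and scores each grown 100-voxel ROI against its true
region by Dice overlap. Two thresholds scale with the synthetic grid: the
published 250-voxel cluster extent refers to acquisition-resolution
(≈ 2 mm) voxels, i.e. ≈ 2 mL; on the 4 mm grid the volume-equivalent
extent is 50 voxels (`RECOVERY_MIN_EXTENT`), while the API default remains
250 as printed. Small-group unit tests also lower the voxelwise p
threshold, because a one-sample t at 4–7 degrees of freedom cannot reach
p < 10⁻⁷ at any realistic effect size; the full-size study runs at the
published threshold. At these settings each module's expected group t is
≈ 15–30 and recovery Dice is ≈ 0.90–0.97 per seed.

## Numerical details and edge cases

- p-values are clipped to (tiny, 1]; t is capped at 10¹² where the
  between-subject sd is exactly zero.
- Boxcar sampling treats sample k as active iff `k·dt ∈ [onset, offset)`,
  with a 10⁻⁹ guard against float boundary error.
- `threshold_clusters` on an empty suprathreshold set returns an all-zero
  labeling; region growing on an exhausted component warns rather than
  fails.
- Toy stat maps place blobs as the `size` nearest voxels to a center
  (connected by construction) with t decaying linearly to half the peak at
  the rim, over a standard-normal background; blob collision (including
  adjacency, which would merge components) is an error.
- All file formats are exercised by round-trip tests: NIfTI volumes
  (float32), masks (uint8, exact), label images (int32), tab-separated
  traces/events/curves, JSON sidecars.
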