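# Methods

This note records the statistical model, the numerical choices, and the
design decisions behind `mosslif`, including what the synthetic-data
generator does and does not emulate.

## Data model

The unit of acquisition is an 8-bit RGB frame of a fluorescing moss tray.
Frames are indexed by trial (treatment group), day (1…7), session (am/pm)
and within-session position/side (five tray positions, front and back —
ten frames per session). Every frame carries a fixed spatial brightness
gradient from the camera sitting close to the laser; because the gradient
is identical across frames, it cancels from any histogram comparison made
over the same pixel rectangle. The pipeline therefore applies one ROI, with
identical coordinates, to every image of a run (default: full frame), and
performs no flat-field correction. ROI coordinates are 0-based with
half-open upper bounds. Pixel values are never rescaled, gamma-mapped or
clipped anywhere in the analysis.

Each channel of a frame is reduced to a 256-bin density histogram
(count of pixels at each code value divided by total pixel count). All
pixels inside the ROI are counted, including 0 and 255. Densities are
stored as fractions summing to 1 (validated to 1e-9); plots may scale by
100 for display.

## Distances

**Intersection density difference.** `1 − Σ_v min(x_v, y_v)` over the 256
code values; symmetric, bounded in [0, 1], zero iff the curves are bin-wise
equal. Inputs are validated to sum to 1 within 1e-6, and the result is
clamped into [0, 1] to shed float residue of order 1e-16.

**Dynamic time warping.** The standard boundary-anchored dynamic program
over the full 256-point curves, with step set
{(i−1, j), (i−1, j−1), (i, j−1)}, no warping window and no slope
constraint, and no path-length normalization: compared curves always have
equal length, and the cumulative cost is the quantity summarized
downstream. DTW operates on the normalized densities, consistent with the
density difference. The kernel is compiled with numba; the dynamic program
accumulates costs front-to-back along paths, so its result is exactly
(bit-for-bit) the minimum over all monotone paths — the test suite asserts
exact equality against a recursive path-enumeration oracle on short
sequences.

**Two-color DTW.** For the combinations RvG, GvB and RvB, the two channel
curves are stacked into a sequence of 2-vectors and warped jointly with a
Euclidean local cost in density space. This joint-cost formulation is a
declared design choice (recorded in every run's metadata JSON): it
preserves the property that a color shift *common* to both channels can be
absorbed by the warp while a *relative* shift between the channels cannot.

One geometric consequence, established during design and relied on by the
synthetic scenarios: when the two channels' histogram bumps are disjoint
along the code axis, the warp can absorb a bump shift that *widens* the gap
to its partner (the index offset changes inside near-zero-density regions
at negligible cost), but it cannot absorb a shift that *compresses* the gap
— monotone paths cannot reverse an index offset — so gap-compressing shifts
produce sharply rising cost. Sensitivity is therefore directional, not a
function of shift magnitude alone.

## Session statistics and the control band

All images of a trial session are compared against all images of the
control pool (the per-pair values are the default unit of replication;
per-image means are available via `replication_unit`). Session summaries
report mean, sample SD (n−1) and SE = SD/√n.

When the control is compared against its own pool, pairs are excluded at
two levels. The `all_pairs_differences` primitive always drops
identical-image self-pairs (distance 0 would bias the null downward). The
pipeline additionally drops *within-session* pairs when building the
control band (leave-session-out): images of one session share that
session's acquisition state, so within-session pairs are systematically
closer than between-session pairs, and retaining them deflates the control
session means relative to an independent trial whose sessions never appear
in the pool. With leave-session-out, control session means are exchangeable
with those of an independent control-like trial, which is exactly the null
the band must represent. (Measured effect during design: without the
exclusion, marginal false flags appeared on untreated days of independent
trials against the tightest bands.)

The control band for each metric/combination is computed from the control's
session means: center = their mean, and the `ci99` bounds are the t-based
interval `center ± t_{(1+level)/2, n−1} · s · √(1 + 1/n)` with `s` the SD of
the session means — the interval that contains a *new* control session mean
with probability `level`. This population-coverage form (rather than a
confidence interval of the mean, which shrinks with n and would reject far
more than 1% of genuine control sessions) is what makes "outside the 99%
band" mean "not a control sample with high certainty", and it is what the
coverage and false-positive-rate tests verify. A 3σ envelope
(`center ± 3s`) is reported alongside; for large n it strictly contains the
99% interval (t → 2.576 < 3).

A session deviates iff its mean lies strictly outside the band (a mean
exactly on a bound does not deviate). Welch's unequal-variance t-test
(two-sided by default; Satterthwaite degrees of freedom) compares each
trial session's per-pair values against the pooled control-vs-control
values and is reported with its own `p < 1 − level` flag. No
multiple-testing correction is applied; the run metadata records the number
of simultaneous combination tests so users can apply their own.

## Ratios and stressor classification

Per session, the three single-channel density-difference means are
normalized to fractions of their sum (`R_D/(R_D+G_D+B_D)` etc.), giving each
channel's share of the total color change; the triple sums to 1 and is
invariant to rescaling all three inputs.

Deviation flags feed an explicit, ordered rule table. Single channels are
flagged from the density-difference band (the single-color method), pair
combinations from the two-color DTW band:

| order | condition | label |
|---|---|---|
| a | ≥ 2 two-color combinations deviate | metal |
| b | exactly one deviating combination, containing B | environmental |
| c | exactly one deviating combination, containing G | photoperiod |
| d | no deviation anywhere | none |
| e | otherwise (single-channel-only deviation) | ambiguous |

A lone GvB deviation is genuinely ambiguous between environmental and
photoperiod stress; rule order (b before c) resolves it to environmental,
and every call lists the rules that fired so the resolution is visible
rather than hidden. The mapping is total and deterministic over all 64 flag
patterns (exhaustively tested). Per-metal identification (Cu vs Pb vs Zn)
is deliberately not attempted.

Calls are emitted at two granularities: per session, and per day, where a
combination counts as deviating only if **every** session of that day
exceeds the band. The am/pm sessions are replicate observations of one
treatment state, so requiring agreement damps isolated marginal
exceedances; the day-level table is the recommended basis for attribution
and is what the end-to-end tests assert.

## Synthetic data generator

Each synthetic pixel is
`clip(base_mean + day-scaled shift + session offset + image offset +
gradient(x, y) + N(0, noise_sd²))`, rounded to 8-bit codes. Defaults mirror
the acquisition design the package targets: 7 days × 2 sessions × 10 frames,
treatments on days 2/4/6 (constant amplitude on each dosing day), 64×64
frames. Channel base means (105, 175, 40) place three well-separated
unimodal bumps on the code axis; `noise_sd = 8` sets their width;
`gradient_amplitude = 10` reproduces the fixed corner-to-corner acquisition
ramp (shared by every frame of a run, so it cancels under a shared ROI —
one test deliberately mismatches ROIs to show the inflated differences);
`session_sd = 2` draws a per-channel intensity offset for each imaging
session, modeling the drift in laser power, moisture and tray placement
that gives the control band its width; `image_sd = 1` adds frame-level
brightness jitter. Noise is Gaussian-on-codes and clipped — the simplest
model that produces realistic unimodal histograms. Everything is determined
by the seed (per-trial streams are derived from seed + trial id, so trials
are independent but reproducible).

Scenario presets plant the three response classes through the directional
sensitivity described above, with signs chosen to express each class's
dominant channel response:

* `metal_like` (ΔR, ΔG, ΔB) = (0, −28, +22): strong shifts in both G and B,
  each compressing its gap toward R → RvG and RvB deviate (≥ 2
  combinations → metal);
* `environmental_like` (0, +11, +22): B-dominant rise → only RvB deviates;
* `photoperiod_like` (0, −28, −10): G-dominant drop → only RvG deviates;
* `control`: zero shifts.

The magnitudes and the generator's variability scales were fixed once,
during a design study that measured deviation margins across multiple seeds
(flagged combinations exceed the band by ≥ 1 half-width on every treated
session; unflagged ones stay below ~0.9), and are not tuned per run.

**What the generator does not emulate** — and hence what passing tests do
not establish about real data: real fluorescence spectra and their
multimodal or skewed histograms, pixel-to-pixel spatial correlation (moss
texture), dose–response dynamics within and across treatment days,
biological drift of the control over a week, and any coupling between
channels beyond shared brightness offsets. Recovery results on synthetic
scenarios demonstrate that the pipeline's statistics and decision rules
behave as designed, not that real stressors separate with these margins.

## Numerical and interface choices

* Degenerate inputs raise typed errors: empty image lists, fewer than two
  observations, non-normalized curves, both Welch samples constant,
  all-zero ratio inputs, ROI outside bounds, unknown combos/metrics.
* DTW tie-breaks among step directions do not affect the returned cost; no
  path is reported.
* Images with an alpha channel are accepted with the alpha dropped and a
  logged warning; non-RGB modes and bit depths over 8 are rejected.
* Manifest CSV (`path,trial_id,day,session,position,side`) and the
  `<trial>/day<D>/<session>/<position>_<side>.png` directory layout are
  both accepted; relative manifest paths resolve against the manifest file.
* The pipeline is deterministic given configuration and inputs; report
  CSVs are byte-identical across reruns, with fixed sort orders and no
  timestamps.
* Problem sizes in the test-suite and acceptance runs (64×64 default
  frames, a 140-image control pool, miniature 24×24 studies for structural
  tests) were chosen so histogram sampling noise stays realistic while the
  full study remains cheap to regenerate; the batch-structure check uses
  128×128 frames and a 193-image pool to match the acquisition protocol's
  image counts.
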