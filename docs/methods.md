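# Methods

This note documents the models, rules and numerical choices behind
`glowtrack`, in pipeline order.  Nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Recording model and conventions

Frames are 16-bit photon-count images integrated over 300 s, 1024×1024 px in
the nominal rig (any size works; tests use smaller images for speed).  Time
is hours since the start of recording, taken to be subjective dusk (CT12):
hours 0–12 of each cycle are subjective night.  Coordinates are 0-based,
row-major, y increasing downward; the tube long axis is y; rectangles are
closed pixel-index intervals.  A tube rectangle is 17 px wide and 184 px
long, divided into 46 bins of 4 px.

## Synthetic stacks (`simulate`)

The simulator's defaults define the study conditions under which the
pipeline's guarantees are demonstrated; they are fixed, not tuned per test.

**Clock.** Photon rate
`rate(t) = base · 2^(−t/halflife) · (1 + A·cos(2π(t−φ)/τ))`, peaking at dusk
and lowest at dawn (φ = 0 with t = 0 at dusk).  Defaults: base 10 counts/s,
A = 0.5, half-life 96 h (≈3.4-fold decay over a week, emulating luciferin
depletion), τ = 24 h per fly.

**Behaviour.** An alternating semi-Markov chain of exponentially distributed
active and rest bouts.  Mean bout lengths are modulated on a log scale in the
`control` scenario: rest-bout means follow a 24-h cosine peaking 6 h after
dusk (base 730 s, modulation 1.4, so night means reach ≈50 min and day means
fall to ≈3 min — long consolidated night sleep, short day naps), and
active-bout means follow a 12-h cosine (base 90 s, modulation 1.0), giving
the bimodal activity peaks near dusk and dawn.  `clock_only` freezes the
behavioural modulation at zero while the clock still cycles; `arrhythmic`
additionally forces the clock modulation to zero.  Within active bouts the
fly performs a reflected *persistent* random walk along the 46 bins (1
step/s, direction flip probability 0.03): persistence reproduces the flat
rectangular smear of a fly running along the tube, whereas a diffusive walk
piles dwell time into rest-like lumps that no peak rule can distinguish from
genuine rests.  Randomness derives from one `default_rng([seed, fly_id,
stream])` per fly, so flies are independent and stacks bit-reproducible.

**Ground-truth sleep.** Rest bouts longer than 300 s are sleep.  Bouts that
occupy the majority (≥150 s) of at least two frames are exported as
`sleep_episodes` — the recoverable targets for sensitivity scoring.  Bouts
\>300 s that only clip frame edges have no stable-position signature at
300-s resolution; they are exported separately (`sleep_bouts_any`) and count
toward the truth union used for precision, since flagging them is correct,
not spurious.

**Camera.** Per frame: a multiplicative radial vignette on a flat background
(5 counts/px/frame, gain 0.3), a faint uniform in-tube glow
(0.12 counts/px/frame, modelling scatter from the tube glass and food plug —
without it the in-tube residual after local background subtraction is
exactly zero-mean and half of all fully-resting frames would flag as
negative-mean; the default lands that rate near the ~8% seen in practice),
three bright corner markers (2×10⁴ counts each), Poisson shot noise,
Gaussian read noise (σ = 1), clipping to [0, 65535].  Fly spots are
Gaussians (σ = 2 px) renormalised over a ±4σ window, so photons are conserved
exactly in the float path; Poisson sampling digitizes without bias, but
noise-free uint16 rendering loses ~2% of sub-count tails to rounding — use
`quantize=False` for photon accounting.  Saturation above 16 bits warns and
sets a flag.

**What the simulator does not emulate:** optical PSF structure beyond a
Gaussian, EM-gain register noise, grooming and other micro-behaviours,
position preferences (food-end sleep), light–dark cycles.  Passing tests
therefore demonstrate correctness of the *computational* pipeline under a
plausible photon budget, not performance on any particular camera.

## Preprocessing (`preprocess`)

Global background: mean of the bottom-right 64×64 patch, estimated and
subtracted per frame (tracks slow dark-signal drift).  Alignment: three
corner markers (approximate locations supplied; sub-pixel centres by
intensity-weighted centre of mass in a ±10 px window) form a right triangle;
each marker pair's angle is folded into (−45°, 45°] mod 90°, the two legs
agree on the tray tilt and the closest pair of folded angles is averaged —
making the estimate order-invariant.  Rotation uses bilinear interpolation
about the image centre; one rotation per stack.  Negative pixels after
subtraction are retained on the quantitative path; only the enhancement path
clips at zero.

Tube detection runs on the per-pixel mean of the first 24 h of aligned
frames (averages out fly positions).  Column centres are `find_peaks` maxima
of the x-profile after subtracting a median-filter baseline (window twice
the minimum column separation), which removes the vignette dome.  Row bands
use a boxcar matched filter of tube length on a y-profile built from in-tube
columns minus neighbouring gap columns — the local subtraction cancels the
vignette, and the matched filter is robust to however the flies' light is
distributed inside the tube.  A count mismatch with the configured layout
raises an error listing the peaks found.

Local (inter-tube) background: a 5-px-wide, tube-length strip centred midway
to the neighbouring column (edge tubes use their single inner midpoint).
Quantification uses two refinements over the plain strip mean: (i) the two
flanking strips are averaged where both exist, cancelling the first-order
vignette gradient across the tube (a single-sided strip sits ~8 px off-centre
and is biased by slope×offset); (ii) the strip is averaged per *row* and
smoothed along y (σ = 8 px), so the vignette's along-tube gradient is removed
too — left in place it masquerades as intensity peaks at the tube ends; and
(iii) estimates are smoothed over 25 frames in time, since the vignette is
static and a 5-px strip's per-frame noise is large enough to flip the sign of
the peak-free tube mean.

## Per-frame quantification (`quantify`)

Contrast enhancement is a percentile-clipped linear stretch (1st–99th) onto
the 16-bit range, applied **per tube rectangle**: fly pixels are far fewer
than 1% of a whole frame, so a whole-frame stretch would be set by the noise
quantile and saturate every fly pixel while amplifying background noise into
the profile.  Enhancement feeds peak detection only; all quantities come
from raw background-adjusted data.

A bin is part of a resting-fly peak when its summed intensity strictly
exceeds the tube's mean + 1 SD of the 46 enhanced bin sums (like compared
with like; a single-pixel maximum cannot meaningfully be compared against
moments of 68-pixel sums).  Runs of adjacent flagged bins merge into one
peak (no gap tolerance); the anchor is the run's intensity-weighted centroid.

Time partition per frame: with `m` = mean of raw bin sums excluding peak
bins ("mean without peaks"), the activity area is `max(0, m) × 46` (the
rectangle spans all 46 bins, matching the shading of the assay's schematic),
and the rest area is the summed positive excess of peak bins over `m`.
Exposure time is split proportionally, so `time_active + time_rest = 300 s`
exactly for every ok frame.  `m < 0` flags `negative_mean`; a zero total
area flags `too_dim`; flagged frames keep their detected peaks but their
times and bioluminescence are linearly interpolated from the nearest ok
neighbours (edge runs take the nearest value).  Bioluminescence is the raw
background-adjusted sum over the tube rectangle — the molecular-clock
signal.

## Sleep (`sleep`)

An episode starts at a frame with exactly one peak and extends while a peak
stays within ±1 bin (4 px ≈ one fly length) of the first frame's anchor,
until the resting peak is lost.  By default continuation frames may contain
additional peaks (the initiation-only reading): the first/last frames of a
genuine episode regularly carry a second real peak from the preceding or
following rest, and requiring single peaks throughout caps sensitivity near
0.8 on synthetic truth.  The stricter every-frame-single-peak reading is
available via `strict_single_peak=True`.  A run of ≥2 frames whose summed
rest time exceeds 300 s is sleep: every frame gets 1 in the binary array and
carries the episode's total duration (minutes) in the consolidation array.

Binning to 30 min (6 frames): sums for time and bioluminescence (time
reported as percent of 1800 s), mean of non-zero entries for consolidation
(0 for an all-zero bin); a trailing partial bin is dropped.

## Rhythm analysis (`rhythm`)

Detrending: second-order Butterworth low-pass, cutoff 1/72 h⁻¹, applied
forward-and-backward (`filtfilt`, even-reflection padding) to get a
zero-phase trend; the series is divided by the trend and renormalised to
mean exactly 1.  A non-positive trend raises an error naming the first
offending time.  Behavioural series are detrended with the same filter for
symmetry; when ratio detrending is impossible (e.g. a consolidation series
with long all-zero stretches) the raw series is analysed instead — the
correlogram removes the mean, so only slow trends are at stake.

Correlogram: mean-removed autocorrelation over lags 0..n/2, biased
normalisation (divide by n), ACF(0) = 1.  The biased estimator tapers the
circadian peak by (1 − k/n) — at 24 h lag on a 7-day series, a factor 0.857
— which damps the noisy long-lag tail; the taper also biases the peak lag
early by ≲0.15 h, well inside the ±0.5 h recovery target, and the parabolic
three-point interpolation around the peak supplies sub-bin period
resolution.

RS is the height of the tallest positive local maximum of the ACF in the
14–38 h lag window divided by `2/√n`, with n the number of 30-min samples
(336 for 7 days); no qualifying peak gives RS = 0 and an undefined (NaN)
period.  The tallest (rather than first) local maximum is used because noise
wiggles on the rising flank of the circadian peak can create small earlier
maxima; for a clean correlogram the two coincide (the "third peak" of the
two-sided correlogram).  The flat `2/√n` line is used rather than a
lag-dependent band; at circadian lags and n = 336 the difference is a few
percent, but absolute RS values consequently depend on this convention.
RS > 1.5 defines rhythmicity; on white noise (n = 336) the false-positive
rate of this rule measures ≈2–3%, inside the 5% budget, as the acceptance
suite verifies.  Series shorter than 2 days (96 bins) are rejected.

## Cohort statistics (`cohort`)

Pairwise RS and period Pearson correlations include only flies rhythmic
(RS > 1.5) in both tested signals; fewer than 3 qualifying flies yields an
explicitly undefined result.  p-values use the exact t-transform
`t = r√((n−2)/(1−r²))`, two-sided (sidedness is a convention; two-sided is
the conservative choice).  Period comparisons add a paired two-sided t-test
on the per-fly period difference (t = 0 for identical vectors).  The
three-way time partition counts frames: sleep = frames inside detected
episodes, rest = non-sleep frames with ≥150 s immobility, active = the rest;
cohorts are compared with the textbook chi-square (no continuity correction)
on the pooled cohort × {sleep, rest, active} frame-count table.  Population
traces report per-bin mean ± SEM.

For period-coupling studies the simulator draws each fly's clock period from
N(24 h, 0.8 h) and either shares it with the behavioural oscillator
(coupled) or draws the behavioural period independently (uncoupled).  Clock
period estimates carry ≈0.03 h noise and behavioural estimates ≈0.6 h, so
the shared 0.8-h per-fly spread dominates and a coupled cohort of 30 flies
shows r ≈ 0.8.

## Problem sizes used in tests

The shared test stack is 12 flies × 2 days at 256×480 px (the tube geometry,
17×184 px at 32 px pitch, is full-scale; only the empty margins shrink);
rhythm and cohort studies run at ground-truth level (no rendering) with 7-day
series, 20–30 flies and 5–10 replicate cohorts.  These sizes were chosen so
the full suite completes in a few minutes while every rule still operates in
its intended regime.

## Known limitations

- Sub-bin position tracking and multiple flies per tube are out of scope.
- The partition slightly underestimates rest (the in-tube glow and PSF tails
  inflate the activity rectangle by a roughly constant amount); recovered
  activity correlates with truth at r ≥ 0.8–0.9 but the slope is below 1.
- Bioluminescence dips when a fly sleeps within ~2σ of a tube end (part of
  the PSF leaves the rectangle).
- A fly pacing tightly in place produces a dwell peak indistinguishable from
  rest; such frames are scored as resting.
- Absolute RS values depend on the biased-ACF and flat-confidence-line
  conventions above; comparisons across implementations should compare
  classifications, not raw RS.
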