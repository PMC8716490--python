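# Methods

## The coupling estimator

`pacfield` quantifies phase–amplitude coupling (PAC) with the entropy-based
Modulation Index. For a phase band f_p and an amplitude band f_A, both
traces are band-limited with a zero-phase 4th-order Butterworth filter
(applied forward–backward, so the effective rolloff is 8th-order and group
delay cancels), and the Hilbert analytic signal provides the instantaneous
phase φ_fp(t) of the slow trace and amplitude envelope A_fA(t) of the fast
trace. The phase axis [−π, π) is divided into N equal bins (default N = 18,
20° per bin; bins are left-closed, right-open, the first starting at
−180°). The mean envelope per bin, normalised by its sum, is a probability
distribution P(i); the Modulation Index is the normalised entropy deficit

    MI = (log N − H(P)) / log N,  H(P) = −Σ P(i) log P(i),  0·log 0 := 0.

MI is 0 when P is uniform, 1 when P is Dirac-like, and is invariant to the
logarithm base, to any positive rescaling of the amplitude trace, and to
permutations of the bins. Natural logarithms are used internally; the
ratio form makes the choice irrelevant.

Assumptions: the phase band must be narrow enough that instantaneous phase
is meaningful, and the amplitude band wide enough to contain the modulation
side peaks at f_A ± f_p. The default headline pair is theta (4–12 Hz) phase
against high-gamma (70–120 Hz) amplitude.

### Edge margins

Zero-phase IIR filtering and the Hilbert transform distort both ends of a
finite trace. Every filtered series therefore carries an *edge margin* of
max(1 s, 3 cycles of the band's lower edge); estimators mask those samples
rather than trimming them silently. A segment must retain at least 3 cycles
of the phase band's lower edge after masking, or an insufficient-data error
is raised. Empty phase bins raise a flagged error — interpolating over them
would bias the entropy downward.

### Estimator bias

For finite data, sampling noise in the bin means inflates MI above zero
even without coupling. The bias scales roughly as (N − 1)/(2 · n_eff ·
log N), where n_eff ≈ 2 · bandwidth · duration is the number of independent
envelope samples. This is why null-coupling validation uses longer segments
for narrow amplitude bands (60 s sessions for the full comodulogram grid,
whose narrowest amplitude bands are 10 Hz wide), and why zone-averaged MI
is computed on the full 4 s zone segment per trial rather than by averaging
windowed estimates (a `method="windowed"` flag provides the alternative).

## Comodulograms

MI is evaluated over a grid of band pairs: phase centres 2–20 Hz in 1 Hz
steps with 2 Hz bandwidth, amplitude centres 20–120 Hz in 5 Hz steps with
an adaptive bandwidth max(10 Hz, 2 × phase centre), which keeps the phase
estimate narrow-band while including the modulation side peaks. Cells whose
band would reach DC or the Nyquist frequency, and cells whose estimate
fails, are recorded as missing (NaN), never as zero. Band decompositions
are cached per grid sweep; a single-cell grid is bit-identical to a direct
`compute_mi` call.

## Preprocessing chain

The conditioning chain mirrors a standard acquisition pipeline: broadband
band-pass 0.3–120 Hz, a 50 Hz powerline notch (2nd-order IIR, Q = 30,
forward–backward, ≥ 20 dB attenuation at 50 Hz and < 3 dB at 40/60 Hz), and
least-squares polynomial baseline removal (default order 3; the order is a
package decision — drift-removal details are rarely reported and a cubic
tracks slow electrode drift without touching band-limited content). The
chain is applied to the continuous recording *before* segmentation into
trials; narrow-band extraction for PAC is then done per padded trial
segment, so each segment's filter margin is explicit.

## Open-field behaviour

The arena is a 100 cm square with a concentric 60 cm central zone; the zone
boundary is closed (a point on the boundary is central), a single
convention asserted by test. An exploration trial is a peripheral→central
entry with at least 4 s of continuous peripheral residence immediately
before it; the entry is the reference point (RP). Trials with central dwell
under 4 s are retained but flagged invalid; trials whose [−4, +4] s window
leaves the recording are dropped. Zone flickers shorter than 0.2 s are
debounced (tracking jitter at the boundary would otherwise fragment
residence runs); the raw, undebounced transition count is what the
behavioural *entries* metric reports, so the trial count can never exceed
it. Entry detection is centroid-based — a trajectory file carries only the
tracked centre of mass, so "entry" means the centroid crossing, not all
paws. Time in the centre integrates sample intervals whose midpoint is
central; speed uses central differences smoothed with a 0.5 s boxcar.

LFP segments are cut at sample precision around each valid RP (alignment
error at most half a sample period), optionally padded so that windowed
estimators have their filter margins outside the analysis span. The MI time
course uses 1 s windows stepped by 0.1 s over −4…+4 s, computed per trial
and then averaged across trials (mean ± SEM); across-trial averaging is
chosen because the across-trial spread is itself a reported quantity.

## Synthetic sessions

The generator implements the standard PAC test construction:

    driver  = a_p · sin(2π f_p t) + ε₁
    carrier = a_A · [(1 − χ) + χ · (sin(2π f_p t) + 1)/2] · sin(2π f_A t) + ε₂

with defaults f_p = 8 Hz, f_A = 80 Hz, a_p = 100 µV, a_A = 30 µV, white
Gaussian noise of SD 10 µV per channel, 2 kHz sampling. The coupling depth
χ ∈ [0, 1] maps monotonically to MI and is analytically transparent: χ = 0
leaves the carrier envelope constant, χ = 1 drives it over its full range
once per driver cycle, with the envelope maximum at driver phase 0. χ may
be a per-sample array, producing non-stationary coupling for time-course
validation. Noise is white by default (1/f-coloured noise is available but
off by default, to keep the closed-form examples exact). The noise level is
a package choice — per-trial signal quality of in vivo recordings is not
something the generator calibrates to; it is set so that coupling contrasts
are detectable at single-trial length while the χ = 0 null stays at
estimator-bias level.

Trajectories are Ornstein–Uhlenbeck-style smoothed random walks with
reflecting arena walls. Central-zone excursions are scripted: each visit is
approached by steering the walk toward an entry point on the zone boundary,
and every sample is projected into its scheduled zone, so a session built
with k visits produces exactly k extractable trials with known dwell times
drawn from the requested range (each preceded by ≥ 4 s peripheral
residence). Group datasets derive per-subject seeds deterministically from
a master seed, so any subject re-runs identically in isolation; the two
groups ("control", coupling χ_control; "cums", χ_cums ≤ χ_control) differ
only in coupling depth.

What the generator does **not** emulate: 1/f background spectra (by
default), non-sinusoidal rhythms and waveform asymmetry, multiple or
drifting coupling frequencies, volume conduction between regions,
movement or chewing artefacts, and any dependence of coupling on behaviour
beyond what a per-sample χ schedule encodes. Passing tests therefore
demonstrate estimator correctness and pipeline integrity under the stated
signal model, not robustness to every property of in vivo LFPs.

## Statistics

The summary-based t-test, t = (m₁ − m₂)/√(sem₁² + sem₂²) with pooled df =
n₁ + n₂ − 2, coincides exactly with the pooled-variance two-sample t when
group sizes are equal, which is what makes published mean ± SEM values
recomputable; Welch's df is available behind a flag. Raw-sample t-tests and
Pearson correlation delegate to scipy behind the module surface. The
two-way and mixed-design (split-plot) ANOVAs are written from explicit sums
of squares for balanced designs — unbalanced designs and missing cells are
rejected, not imputed — so each decomposition is verifiable against
brute-force enumeration (and is cross-checked against pingouin in the test
suite). When the residual mean square is exactly zero, an effect with zero
sum of squares reports F = 0, p = 1. Bonferroni adjustment is min(1, m·p)
over the m tested contrasts; the pipeline's headline contrasts are
(control periphery vs control centre), (control periphery vs stressed
periphery) and (control centre vs stressed centre). Significance markers
follow the ** p < 0.01 / *** p < 0.001 convention. No sphericity
corrections or effect sizes are computed.

## Pipeline and reproducibility

`run_pipeline` chains simulate → preprocess → behaviour → PAC → stats and
writes every output with a SHA-256 hash into a manifest together with the
config echo, software version and warnings (dropped trials, skipped
stages), so an identical configuration and master seed reproduces identical
files. Interchange formats are comma-delimited UTF-8 text with header rows;
numeric output is serialised at full double precision.

## Package shape

The core estimator is exposed in two equivalent forms: functional
(`compute_mi`, `comodulogram`, `mi_timecourse`) and as a model/results pair
(`PhaseAmplitudeCoupling(...).fit() → PACResults` with `summary()` and
plotting), the latter for interactive work where the intermediate
phase–amplitude distribution is of interest. Generation, behaviour and
statistics are plain functions — they are data transformations, not fitted
models.

## Problem sizes used in validation

The validation suite runs on synthetic data sized for desk-scale
verification: 8 s sessions for single MI estimates, 20–30 s for
comodulogram peak recovery, 60 s for full-grid null calibration, and group
studies of 5 subjects × 10 trials per group (scaled-down stand-ins for a
10-rat, 200-trial study). These sizes were chosen so that each check
isolates one property at adequate statistical power.

## Known limitations

* Only the entropy-based MI is implemented — no mean-vector-length or
  GLM-based PAC estimators, and no surrogate/permutation significance
  testing of MI values.
* The absolute MI magnitude depends on recording noise and segment length;
  MI values are comparable within a study design, not across pipelines.
* Balanced designs only in the ANOVA routines.
* Rearing counts cannot be derived from trajectories and only pass through
  from an external source.
* No support for proprietary acquisition formats; inputs are delimited
  text.
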