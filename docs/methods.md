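# Methods

`speechmood` implements a desk-scale version of a smartphone speech-analysis
chain for longitudinal mood monitoring in bipolar disorder: a recording is
reduced on the "device" side to a compact per-frame text file of pitch
estimates, and all downstream analysis — voiced segmentation, prosodic
features, session summaries, mood correlation — re-runs from that file.

## Pitch estimation by sawtooth-spectrum matching

The tracker belongs to the SWIPE′ family of spectral-matching estimators.
For each frame (centred at t = i·hop, hop 10 ms by default, windows
zero-padded at the signal edges):

1. The magnitude spectrum is square-root compressed and resampled on an
   ERB-spaced grid (step 0.1 ERB, from a quarter of the lowest candidate to
   Nyquist), where ERBs(f) = 21.4·log10(1 + 0.00437·f). The compression
   and auditory spacing emphasise low harmonics the way the ear does.
2. Each pitch candidate on a log2-spaced grid (default 1/96 octave over
   75–500 Hz) owns a matching kernel: positive cosine lobes on the first
   and prime-numbered harmonics (skipping non-prime multiples suppresses
   sub-harmonic octave errors), negative half-lobes in the valleys between
   lobes, each lobe weighted by 1/√i to mirror a sawtooth's compressed
   spectrum. The kernel's support begins at the first lobe (0.75 × the
   candidate).
3. *Pitch strength* is the cosine similarity between the unit-normalised
   kernel and the unit-normalised sampled spectrum, hence bounded in
   [−1, 1] and invariant to amplitude scaling of the input. On clean
   synthetic sawtooth material voiced frames score ≈ 0.5–0.6; white noise
   scores ≈ 0.0–0.1.
4. Each candidate is analysed with a window of about eight of its pitch
   periods. Only power-of-two window sizes are computed; a candidate's
   strength is the log-distance-weighted blend of the two bracketing sizes.
5. F0 for the frame is the strength-maximising candidate, refined by
   parabolic interpolation on the log2 candidate grid and clipped to the
   search range. Frames with no spectral energy at any window size carry
   F0 = missing and strength 0 — they are kept, not dropped, so the frame
   grid stays uniform.

A note on normalisation: normalising the kernel by its full Euclidean norm
(rather than by the norm of its positive part, as some reference
implementations do) makes strength a true cosine similarity and guarantees
the [−1, 1] bound. Absolute strength values are therefore a monotone
rescaling of such implementations'; since operating thresholds are always
selected from a sweep rather than hard-coded, behaviour is unchanged.

## Voiced segmentation

Two detectors:

* **Strength thresholding** (the device method): a frame is voiced when
  its pitch strength strictly exceeds the threshold; maximal voiced runs
  become segments. A frame centred at t covers [t − hop/2, t + hop/2], so
  an n-frame segment has length n·hop; starts are clipped at 0, which
  shortens a segment that begins at frame 0 by half a hop. Runs shorter
  than `min_segment` (default 0.02 s, the minimum on which variability
  features exist) are dropped.
* **Intensity + zero-crossing rate** (the reference method): 30-ms frames
  stepped by the hop are voiced when RMS energy strictly exceeds the 0.3
  quantile of all frame energies and ZCR stays below 3000 crossings/s.
  The energy gate is deliberately permissive — it rejects silence, which
  rarely exceeds a third of a running-speech timeline — while the ZCR gate
  rejects fricative-like noise (white noise at 48 kHz crosses zero about
  24 000 times/s, voiced speech a few hundred). Boundary frames whose
  30-ms window straddles an event edge lose energy, so this method
  resolves segment lengths to about one energy frame.

The operating threshold is chosen from a specificity/sensitivity sweep
against a reference segmentation: among thresholds with specificity > 0.9
and sensitivity > 0.6 (frame-level, reference as truth), the most
sensitive one wins; ties go to the smaller threshold. Because voiced-frame
sets are nested across thresholds, sensitivity is non-increasing and
specificity non-decreasing in the threshold — the sweep is monotone by
construction.

## Features and summaries

Per voiced segment, from the frame-wise F0:

* mean F0 (Hz);
* stdF0: sample standard deviation (n−1 denominator);
* jitter (local, relative): mean |T(i+1) − T(i)| / mean T(i) over frame
  periods T(i) = 1/F0(i). Defined from the exported track, which is the
  only construction available once raw audio is discarded.

Variability features require at least two frames and are missing
otherwise. Across the segments of one recording, each feature is
summarised by its median, unscaled MAD (median absolute deviation — a
descriptive "median ± MAD" companion, not a σ estimate, hence no 1.4826
factor) and moment skewness g1 = m3/m2^1.5 (missing below three segments
or for constant data). MAD of mean F0 ("MAD_meanF0") is the headline
longitudinal marker.

### Jitter transfer of the frame-based chain

The chain's jitter measurement is linear with an essentially zero noise
floor (≈ 3·10⁻⁵ measured on unjittered synthetic vowels) but attenuates
iid period-level jitter by a factor of roughly 2–5 (gain ≈ 0.2–0.5 across
75–500 Hz, ≈ 0.38 at 200 Hz). The cause is structural: period-level jitter
is white in the period index, and each frame's F0 is estimated from a
Hann window spanning ~8 periods, stepped by a hop much shorter than the
window, so consecutive frame periods are heavily smoothed, overlapping
averages. Relative comparisons of jitter across sessions (the monitoring
use case) are unaffected; absolute calibration against waveform-level
jitter is not attempted, and tests assert the true properties (zero
floor, monotone linear transfer) rather than unit gain.

## Agreement evaluation

* **Frame confusion**: both segment lists are rasterised to a common 1-ms
  grid (finer than any hop, so boundary rounding cannot dominate counts);
  a cell is voiced if its centre lies in a segment; sensitivity and
  specificity use the reference as truth.
* **Segment matching**: greedy pairing by descending temporal overlap,
  each segment on either side used at most once, pairs below 0.02 s of
  overlap (two frames — the minimum for variability features) discarded.
* **Feature agreement**: the named feature is recomputed on each pair's
  intersection interval, from the frames whose centres fall inside it, in
  both tracks; Pearson correlation across pairs with a two-sided t-test
  p-value (n−2 df). Pearson (not rank) correlation is used here; rank
  correlation is reserved for the ordinal mood analysis.
* **Distribution comparison**: two-sample Kolmogorov–Smirnov.
  D = sup |ECDF_a − ECDF_b|; the p-value is exact (full enumeration of
  all C(n_a+n_b, n_a) label assignments) for pooled sizes ≤ 12 and
  otherwise asymptotic via the Kolmogorov distribution with effective
  size n_a·n_b/(n_a+n_b).

## Mood scale and longitudinal correlation

Clinician scores: QID ≥ 8 marks a depressive state, YMRS ≥ 6 a hypomanic
state, both a mixed state, neither euthymia. Non-mixed states are ranked
hypomanic (1) < euthymic (2) < depressive (3); any strictly increasing
coding gives identical rank correlations. The mixed state does not fit a
one-dimensional mood model and is excluded from ordinal analysis (with a
logged warning) rather than coded.

Spearman correlation is the Pearson correlation of mid-ranks (average
ranks on ties). The two-sided p-value is an exact full-permutation
enumeration for n ≤ 9 (cheap below 10!) and the t-approximation with n−2
df above. `longitudinal_report` correlates each of the nine summary
statistics (median/MAD/skewness × meanF0/stdF0/jitter) with the session
ordinals.

## Synthetic speech generator

Scripts alternate voiced, unvoiced and silence events. Voiced events are
harmonic series with 1/k amplitudes (ten harmonics by default, capped
below Nyquist) — a sawtooth-like positive control for a sawtooth-matching
estimator — with a linear F0 contour integrated into phase. Jitter is
injected at the period level: each period's instantaneous F0 is multiplied
by (1 + ε), ε ~ N(0, jitter_level²), seeded, which is exactly the
perturbation local jitter measures. Unvoiced events are white Gaussian
noise at RMS 0.25 × amplitude (comparable intensity to the voiced events,
as fricatives are); silence is zeros. Rendering is bit-reproducible for a
given (script, rate, seed).

The standard 30-s fixture tiles a pattern of four voiced events per cycle
(level and gliding contours over 120–320 Hz), noise bursts and pauses,
about 62% voiced — emulating the voiced fraction and F0 range of read
adult speech at the study's 48-kHz acquisition rate. What it does *not*
emulate: formants and vocal-tract colouring, consonant structure, room
acoustics, additive environmental noise, amplitude modulation and
microphone response. Passing tests therefore demonstrate the correctness
of the algorithm chain under ideal harmonic excitation, not robustness to
real-world recording conditions.

## Numerical and design choices

* Frame times start at 0; all frame/segment conventions are closed-form so
  every hand-traceable example is testable exactly.
* Strict inequalities at both gates (strength > threshold,
  energy > quantile) so "higher than a given threshold" has one meaning.
* Missing F0 is NaN in memory and `NA` in track files; strength 0.
* Track files print time/F0/strength at 3/2/3 decimals — enough for 0.5-ms
  /5-mHz/5·10⁻⁴ round-trip fidelity while keeping a 30-s file under
  60 kB.
* Exact-p switchovers: KS at pooled n = 12, Spearman at n = 9; both
  enumerations are vectorised and run in well under a second at the
  switchover.
* Problem sizes in the test suite: the shared fixture is a single 30-s
  rendering; recovery experiments use 1–2-s events over ≤ 20 seeds; the
  longitudinal experiment uses 200 replicates of 15-session cohorts.

## Known limitations

* Absolute jitter is attenuated (see the transfer analysis above).
* The intensity/ZCR reference constants are plain defaults, not fitted to
  any corpus; on real recordings they will need adjustment.
* The pitch-strength scale differs from positive-part-normalised SWIPE′
  implementations by a monotone rescaling, so thresholds quoted for those
  implementations do not transfer numerically.
* No noise robustness is claimed or tested; the generator is clean by
  design.
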