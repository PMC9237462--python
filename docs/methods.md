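# Methods

## The problem

When listeners hear a stream of consonant–vowel (CV) syllables presented at
a fixed 4 Hz rate, EEG activity phase-locks to the stream: spectra of the
inter-trial phase coherence (ITPC) show peaks at 4 Hz and its harmonics.
How strongly the brain locks depends on the shape of each syllable's
amplitude envelope — in particular on its "edges", the rapid rises at
syllable onset and at the consonant–vowel transition. This package
implements the full analysis that links envelope edge descriptors to ITPC,
plus generators that synthesize the stimuli and EEG so the whole chain can
be exercised and validated without any recordings.

## Envelope extraction (`audio_envelope`)

A syllable waveform is passed through 32 log-spaced 4th-order gammatone
filters spanning 80–8000 Hz (FIR realization; the transfer-function IIR
form is numerically unstable at low center frequencies). Narrowband
envelopes are magnitudes of the analytic signal (Hilbert transform); their
sum is the cochlear-style envelope. The summed envelope is decimated
(default 1000 Hz for display, 250 Hz for marker extraction) with a
polyphase anti-alias resampler.

A separate smoothing stage applies a zero-phase order-350 FIR bandpass
(2–10 Hz, Kaiser window β = 5, ≈ −50 dB sidelobes). The filter's order is
fixed; its behavior therefore depends on the rate it runs at. At 1000 Hz a
351-tap kernel spans only 0.35 s and cannot separate 2 Hz from DC (measured
−9 dB at 0.5 Hz), so the stage resamples internally to a fixed 250 Hz
processing rate, filters, and resamples back. Measured response: 0 dB at
4–8 Hz, −6 dB at the 2/10 Hz edges, −56 dB at 0.5 Hz, −59 dB at DC, −99 dB
at 40 Hz. Signals are zero-padded by one kernel length before filtering;
syllables begin and end in silence, so zero continuation adds no spurious
boundary edges (reflection padding does, and moved the maximum-derivative
latency to the syllable end in early versions).

## Edge markers (`edge_markers`)

Eight scalars per syllable: sharpness (mean positive forward difference ×
rate), maximum amplitude (MA) and its latency, latency to 80% of MA,
plateau width (first ascending 0.8·MA crossing to the first descent below
it after the peak), maximum derivative (MD) and its latency, and the Gini
index G = ΣᵢΣⱼ|xᵢ−xⱼ| / (2n Σxᵢ), computed by the sorted O(n log n)
identity and checked against the O(n²) double loop in tests. Latencies use
first-occurrence tie-breaking with a 1e-9 relative tolerance so exact ties
on constant slopes resolve to the first sample rather than rounding noise.
Signed (bandpassed) envelopes have their minimum subtracted before the Gini
computation, which requires non-negative values.

Markers default to the summed envelope decimated to 250 Hz rather than the
2–10 Hz smoothed one. Two reasons. First, the decimation's anti-alias
filter (Nyquist 125 Hz) already removes the pitch-beat ripple that
motivates smoothing, while leaving even a 10 ms attack intact. Second, the
2–10 Hz passband clips any rise faster than ~50 ms, which blunts — and for
very fast attacks inverts — exactly the contrast the sharpness and MD
markers exist to measure. The smoothed variant remains available
(`stage='bandpassed'`).

Note a structural property of "sharpness": for a unimodal envelope the mean
positive derivative equals (peak − start)/duration, so across
equal-loudness syllables it is largely a proxy for envelope peak height —
peaked envelopes (much silence, fast decay) score high, flat ones score
low. This is why the generator controls it through duty cycle, not rise
time (see below).

## EEG preprocessing (`eeg_preprocess`)

Zero-phase 1–50 Hz Butterworth (order 6, forward–backward), average
re-reference, epoching into 5 s windows at stream-onset events, and removal
of the first 500 ms of each epoch (auditory onset transient). Ocular
components: given any blind-source-separation decomposition (mixing:
components × channels; sources: components × samples), a component is
removed when the fraction of its back-projected broadband power that falls
in the frontal channels (default Fp1, Fp2, F7, F8) exceeds 12%. The
per-component frontal share is the only scale-free reading of that
criterion; the decomposition itself is deliberately out of scope and
injected by the caller or the tests.

## ITPC (`itpc`)

Epoch phases come from Hann-tapered FFTs; 4.5 s epochs give 2/9 Hz bins, so
4/8/12/16 Hz land exactly on bins 18/36/54/72. The coherence statistic is
the squared mean resultant R = (Σcosθ/K)² + (Σsinθ/K)² of the K = 10 trials
of one (electrode, stream) cell. The squared form is deliberate: its
expectation under uniform random phases is exactly 1/K = 0.1, matching the
reference level the analysis is calibrated to; an unsquared variant is
available behind a flag. R(f, a) averages cells over streams and
electrodes, R(f) further over participants; condition-level views restrict
the stream average to a condition's own streams.

Significance: fictive participants are built by pushing uniform random
phases through the identical averaging structure (default 45 × 32 cells).
With 1440 averaged cells the null mean is 0.1 with a standard deviation of
~0.0025, putting the 95th percentile near 0.104; real participants are
compared to 5000 fictive ones by a one-sided Mann–Whitney U-test (exact for
tiny samples, tie-corrected normal approximation otherwise; an all-tied
degenerate input returns p = 1).

## Group statistics (`group_stats`)

- ITPC PCA: participant × condition rows of the four harmonic values,
  covariance PCA (shared units); signs fixed so each component's largest
  loading is positive. The first component is expected to be a positive,
  4 Hz-dominant weighting; the code warns when a fitted dataset disagrees
  rather than failing, since small simulations legitimately violate it.
- Marker PCA: z-scored (units are 1/s, ms and unitless; covariance PCA
  would be dominated by millisecond-scale latencies). Default marker set:
  MD latency, MA latency, sharpness, Gini, plateau.
- One-way repeated-measures ANOVA implemented directly (numpy): the
  Greenhouse–Geisser ε comes from the double-centered condition covariance
  and is applied only when Mauchly's test rejects sphericity at α = 0.05.
  The implementation is cross-checked against pingouin in the test suite;
  it exists as code rather than a pingouin call because the calibration
  simulations fit thousands of small tables.
- Bonferroni post-hocs (paired two-tailed t, family = all pairs in the
  tested partition), Pearson correlations with the t-transform p, and
  seeded Lloyd k-means (best of 100 restarts) for condition clustering.
- Phoneme partitions: stops {b d g k p t}, fricatives/sibilants {f v s z},
  nasals/liquids {m n l r}; the five-group refinement; and the voicing
  splits {b d g} vs {k p t} and {v z} vs {f s}. The vowel-only condition is
  excluded from consonant partitions.

## Synthetic data (`synthetic_data`)

The schedule reproduces the experiment's bookkeeping: 15 conditions (14
CV + vowel-only), 3 streams per condition whose 20-vowel orders avoid
immediate repeats and are shared across conditions (the three printed
five-vowel openings are embedded; the remainder is seed-generated under the
constraint), 10 repetitions per stream, 5 blocks of 3 conditions × 30
presentations plus 10 unique fillers each (450 target + 50 filler
presentations), 2 s inter-stimulus interval. Filler deviants sit uniformly
in syllable positions 11–20 and take a consonant from a different phoneme
class. Syllable durations draw from a truncated normal (mean 249.05 ms,
SD 2.42 ms, bounds 242–255 ms).

Syllables are acoustic caricatures validated only through their
envelope/edge statistics: a class-dependent onset (brief gap + burst for
stops; murmur for nasals/liquids; frication for fricatives/sibilants)
followed by a five-harmonic vowel (f0 220 Hz) with a raised-cosine attack
whose duration orders the classes (stops ~10–15 ms < nasals/liquids
~25–30 ms < fricatives/sibilants ~60–80 ms), a class-specific post-attack
decay, and a 50 ms release; tokens are RMS-equalized (the stand-in for
equal-SPL presentation). Frication uses a dense random-phase tone complex
rather than true noise so its envelope is steady (noise envelope
fluctuations would add spurious slow edges), and it crossfades into the
vowel so the envelope's main rise is the consonant–vowel transition.
Because sharpness tracks peak height (above), classes are separated by duty
cycle: plosive-like tokens decay fast from a tall onset peak, fricated ones
sustain. The resulting condition table has MD latency increasing and
sharpness broadly decreasing from stops through nasals/liquids to
fricatives/sibilants — the sign structure the group-level correlations
probe.

EEG is generated by an edge-triggered evoked model: every syllable's MD
latency triggers a damped 10 Hz oscillation kernel (300 ms, ~5 µV), with a
per-syllable per-presentation Gaussian latency jitter whose condition SD is
base (5 ms) + coupling × (condition MD latency above the minimum). Channels
share the evoked time course scaled by zero-mean random gains (so it
survives average referencing) plus independent 1/f noise (15 µV RMS).
Jitter is the single knob that degrades phase locking, so condition-level
ITPC falls monotonically with jittered MD latency — the relationship the
pipeline must recover. With these levels a jitter-free condition yields
4 Hz ITPC ≈ 0.2 at participant level, in the range real studies report,
and an 80 ms-jitter condition approaches the 0.1 noise floor.

What the generator does *not* emulate: real phoneme acoustics (formants,
coarticulation), electrode geometry and volume conduction, non-stationary
or non-Gaussian EEG artifacts, and behavioral responses. Passing tests
therefore demonstrate that the pipeline's bookkeeping, statistics and
sensitivity are correct, not that the acoustic-class effects of real speech
are reproduced.

## Problem sizes and numerical choices

Simulation-based tests run a scaled-down study — 5 participants, 5
conditions spanning the phoneme classes, 10 trials per stream — which keeps
the full end-to-end run to a couple of minutes while leaving the
condition-level correlation well determined; the ANOVA calibration uses
2000 Gaussian null tables. Audio synthesizes at 44.1 kHz (keeps the 8 kHz
band below Nyquist); EEG at 1 kHz with 32 channels. Seeds are explicit
everywhere; participant- and stage-level generators derive from one root
seed, and equal configurations produce byte-identical CSV outputs.

## Known limitations

- The frontal-power ICA rule is implemented; the decomposition quality is
  whatever the caller supplies.
- `sharpness` inherits its peak-height sensitivity from its definition;
  interpret it jointly with MA.
- BrainVision support covers the IEEE-float multiplexed core layout (reader
  via MNE, minimal writer for round-trips); EDF/FIF are out of scope.
- The 24-bit PCM WAV variant is not readable (scipy backend); use 16-bit or
  float.
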