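"""Synthetic stimuli and EEG emulating the syllable-stream experiment.

The generator reproduces the study's structure: 15 conditions (14 CV
consonants + one vowel-only), 3 streams per condition of 20 near-isochronous
syllables (4 Hz rate, durations ~249 ms +/- 2.4 ms), each stream repeated 10
times, plus 50 single-presentation fillers whose deviant syllable sits in
the second half of the stream; 5 blocks of 3 conditions each with a 2 s
inter-stimulus interval.

Syllables are caricatures: a class-dependent onset segment (burst, noise
ramp or murmur) followed by a harmonic vowel with a raised-cosine attack
whose duration orders the classes (stops sharpest, fricatives/sibilants
slowest), so the envelope edge markers vary across conditions the way the
phoneme classes do.

EEG is generated by an edge-triggered evoked model: each syllable's
maximum-derivative latency triggers a damped-oscillation kernel, jittered
per syllable per trial with a condition-specific SD (optionally coupled to
the condition's MD latency), on top of 1/f noise — so inter-trial phase
coherence at 4 Hz is directly controlled by the jitter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .audio_envelope import Waveform
from .eeg_preprocess import EEGRecording

#: 32-channel actiCAP-style montage.
CHANNELS_32 = [
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8", "FC5", "FC1", "FC2", "FC6",
    "T7", "C3", "Cz", "C4", "T8", "TP9", "CP5", "CP1", "CP2", "CP6", "TP10",
    "P7", "P3", "Pz", "P4", "P8", "PO9", "O1", "Oz", "O2", "PO10",
]

VOWELS = ("a", "e", "i", "o", "u")

DEFAULT_CONDITIONS = (
    "b", "d", "g", "k", "p", "t", "f", "v", "s", "z", "m", "n", "l", "r", "V",
)

CONSONANT_CLASS = {
    "b": "stop-voiced", "d": "stop-voiced", "g": "stop-voiced",
    "k": "stop-unvoiced", "p": "stop-unvoiced", "t": "stop-unvoiced",
    "f": "fricative", "v": "fricative",
    "s": "sibilant", "z": "sibilant",
    "m": "nasal", "n": "nasal",
    "l": "liquid", "r": "liquid",
    "V": "none",
}

#: Vowel-attack time (ms) per consonant class; ordered so that
#: stops < nasals/liquids < fricatives/sibilants.
CLASS_ATTACK_MS = {
    "stop-voiced": 10.0,
    "stop-unvoiced": 15.0,
    "none": 20.0,
    "nasal": 25.0,
    "liquid": 30.0,
    "fricative": 60.0,
    "sibilant": 80.0,
}

#: Onset-prefix length (ms) and type per class. Stop prefixes are the brief
#: voice-onset gap before the burst; fricated prefixes are the frication
#: noise itself.
CLASS_ONSET = {
    "stop-voiced": (15.0, "silence+burst"),
    "stop-unvoiced": (25.0, "silence+burst"),
    "none": (0.0, "none"),
    "nasal": (40.0, "murmur"),
    "liquid": (30.0, "murmur"),
    "fricative": (70.0, "noise-ramp"),
    "sibilant": (90.0, "noise-ramp"),
}

#: Post-attack amplitude decay rate (fraction of peak per second, floored at
#: 15% of peak). Plosive and plain-vowel syllables decay fast from a
#: prominent onset peak; continuously voiced/fricated classes sustain, which
#: spreads their energy and lowers their equal-loudness envelope peak.
CLASS_DECAY_RATE = {
    "stop-voiced": 3.0,
    "stop-unvoiced": 3.0,
    "none": 4.0,
    "nasal": 2.5,
    "liquid": 2.5,
    "fricative": 0.5,
    "sibilant": 0.3,
}

#: Frication level for noise-ramp classes, as a fraction of the vowel's RMS.
CLASS_NOISE_LEVEL = {"fricative": 0.55, "sibilant": 0.62}

#: Frication carrier bands (Hz): sibilants are high-frequency, fricatives
#: broader and lower.
CLASS_FRICATION_BAND = {"fricative": (800.0, 5000.0), "sibilant": (1500.0, 7500.0)}

#: Murmur amplitude as a fraction of the vowel RMS (nasals/liquids).
MURMUR_LEVEL = 0.15

#: Per-consonant attack-time offsets (ms) within a class, so conditions that
#: share a class still differ slightly, as real consonants do.
CONSONANT_ATTACK_OFFSET = {
    "b": -2.0, "d": 0.0, "g": 2.0, "k": -2.0, "p": 0.0, "t": 2.0,
    "f": -3.0, "v": 3.0, "s": -3.0, "z": 3.0,
    "m": -2.0, "n": 2.0, "l": -2.0, "r": 2.0, "V": 0.0,
}

#: The two printed stream-order openings (first five vowels of each stream);
#: the remaining fifteen syllables are seed-generated under the no-repeat
#: constraint.
PRINTED_VOWEL_PREFIXES = (
    ("a", "u", "e", "a", "i"),
    ("e", "a", "i", "u", "e"),
    ("i", "o", "u", "o", "a"),
)

#: Syllable-duration distribution (ms): truncated normal.
DURATION_MEAN_MS = 249.05
DURATION_SD_MS = 2.42
DURATION_LO_MS = 242.0
DURATION_HI_MS = 255.0


@dataclass
class SyllableRecipe:
    """Everything needed to synthesize one syllable token."""

    consonant: str  # condition label; "V" means vowel-only
    vowel: str
    duration_ms: float = 250.0
    attack_ms: float | None = None  # default: class attack time
    f0: float = 220.0

    def __post_init__(self) -> None:
        if self.vowel not in VOWELS:
            raise ValueError(f"unknown vowel {self.vowel!r}")
        cls = CONSONANT_CLASS.get(self.consonant)
        if cls is None:
            raise ValueError(f"unknown consonant {self.consonant!r}")
        if self.attack_ms is None:
            self.attack_ms = (CLASS_ATTACK_MS[cls]
                              + CONSONANT_ATTACK_OFFSET.get(self.consonant, 0.0))
        if self.attack_ms >= self.duration_ms:
            raise ValueError("attack time must be shorter than the syllable")

    @property
    def phoneme_class(self) -> str:
        return CONSONANT_CLASS[self.consonant]


@dataclass
class Presentation:
    block: int
    slot: int  # order within block
    stream_id: str
    condition: str
    is_filler: bool
    onset_time: float  # seconds from experiment start
    deviant_position: int | None = None  # 1-based syllable index
    deviant_consonant: str | None = None


@dataclass
class StimulusSchedule:
    """The full experiment plan."""

    presentations: list[Presentation]
    vowel_orders: list[tuple[str, ...]]  # one 20-vowel order per stream index
    conditions: list[str]
    streams_per_condition: int
    reps: int
    n_syllables: int = 20
    stream_slot: float = 5.0  # nominal stream duration, s
    isi: float = 2.0

    @property
    def targets(self) -> list[Presentation]:
        return [p for p in self.presentations if not p.is_filler]

    @property
    def fillers(self) -> list[Presentation]:
        return [p for p in self.presentations if p.is_filler]

    @property
    def filler_stream_ids(self) -> set[str]:
        return {p.stream_id for p in self.fillers}

    def stream_vowels(self, stream_index: int) -> tuple[str, ...]:
        return self.vowel_orders[stream_index]

    def validate(self) -> None:
        """Check every structural invariant; raises on violation."""
        for order in self.vowel_orders:
            if len(order) != self.n_syllables:
                raise AssertionError("vowel order has wrong length")
            for a, b in zip(order, order[1:]):
                if a == b:
                    raise AssertionError(f"consecutive vowel repeat in {order}")
        n_target = len(self.conditions) * self.streams_per_condition * self.reps
        if len(self.targets) != n_target:
            raise AssertionError(
                f"expected {n_target} target presentations, got {len(self.targets)}"
            )
        from collections import Counter

        filler_ids = Counter(p.stream_id for p in self.fillers)
        if filler_ids and max(filler_ids.values()) > 1:
            raise AssertionError("a filler stream was presented more than once")
        for p in self.fillers:
            if not (self.n_syllables // 2 < p.deviant_position <= self.n_syllables):
                raise AssertionError("filler deviant outside the second half")
            if p.deviant_consonant is not None and p.condition != "V":
                if CONSONANT_CLASS[p.deviant_consonant] == CONSONANT_CLASS[p.condition]:
                    raise AssertionError("filler deviant shares the phoneme class")
        blocks = sorted({p.block for p in self.presentations})
        for b in blocks:
            in_block = [p for p in self.presentations if p.block == b]
            n_fill = sum(p.is_filler for p in in_block)
            if len(in_block) - n_fill != len(self.targets) // len(blocks):
                raise AssertionError(f"block {b} has a wrong target count")
        # target stream repetition counts
        target_ids = Counter(p.stream_id for p in self.targets)
        if set(target_ids.values()) != {self.reps}:
            raise AssertionError("unequal repetition counts across target streams")


def _extend_vowel_order(prefix: tuple[str, ...], n: int, rng: np.random.Generator) -> tuple[str, ...]:
    order = list(prefix)
    while len(order) < n:
        choices = [v for v in VOWELS if v != order[-1]]
        order.append(choices[rng.integers(len(choices))])
    return tuple(order[:n])


def build_schedule(
    conditions: tuple[str, ...] | None = None,
    streams_per_condition: int = 3,
    reps: int = 10,
    fillers: int = 50,
    blocks: int = 5,
    seed: int | None = None,
    isi: float = 2.0,
    n_syllables: int = 20,
    stream_slot: float = 5.0,
) -> StimulusSchedule:
    """Build the full pseudo-randomized schedule.

    Conditions are split evenly across blocks (3 per block at defaults); each
    block holds every repetition of its conditions' streams plus its share of
    the unique fillers, in shuffled order.
    """
    conditions = list(conditions or DEFAULT_CONDITIONS)
    if len(conditions) % blocks != 0:
        raise ValueError("conditions must divide evenly across blocks")
    if fillers % blocks != 0:
        raise ValueError("fillers must divide evenly across blocks")
    rng = np.random.default_rng(seed)

    orders = []
    for j in range(streams_per_condition):
        prefix = PRINTED_VOWEL_PREFIXES[j % len(PRINTED_VOWEL_PREFIXES)]
        orders.append(_extend_vowel_order(prefix, n_syllables, rng))

    cond_perm = [conditions[i] for i in rng.permutation(len(conditions))]
    per_block = len(conditions) // blocks
    fill_per_block = fillers // blocks
    presentations: list[Presentation] = []
    t = 0.0
    filler_counter = 0
    for b in range(blocks):
        block_conditions = cond_perm[b * per_block : (b + 1) * per_block]
        entries: list[Presentation] = []
        for cond in block_conditions:
            for j in range(streams_per_condition):
                sid = f"{cond}-s{j}"
                for _ in range(reps):
                    entries.append(Presentation(b, 0, sid, cond, False, 0.0))
        for i in range(fill_per_block):
            cond = block_conditions[i % len(block_conditions)]
            j = int(rng.integers(streams_per_condition))
            pos = int(rng.integers(n_syllables // 2 + 1, n_syllables + 1))
            own_class = CONSONANT_CLASS[cond]
            others = [c for c in CONSONANT_CLASS
                      if c != "V" and CONSONANT_CLASS[c] != own_class]
            dev = others[rng.integers(len(others))]
            entries.append(Presentation(
                b, 0, f"{cond}-s{j}-f{filler_counter}", cond, True, 0.0,
                deviant_position=pos, deviant_consonant=dev,
            ))
            filler_counter += 1
        order = rng.permutation(len(entries))
        for slot, idx in enumerate(order):
            p = entries[idx]
            p.slot = slot
            p.onset_time = t
            t += stream_slot + isi
            presentations.append(p)
    return StimulusSchedule(
        presentations, orders, conditions, streams_per_condition, reps,
        n_syllables=n_syllables, stream_slot=stream_slot, isi=isi,
    )


def draw_durations(n: int, rng: np.random.Generator) -> np.ndarray:
    """Syllable durations (ms): truncated normal, mean ~249, sd ~2.4."""
    a = (DURATION_LO_MS - DURATION_MEAN_MS) / DURATION_SD_MS
    b = (DURATION_HI_MS - DURATION_MEAN_MS) / DURATION_SD_MS
    return stats.truncnorm.rvs(
        a, b, loc=DURATION_MEAN_MS, scale=DURATION_SD_MS, size=n, random_state=rng
    )


#: Per-vowel harmonic amplitude profiles (crude spectral identities).
_VOWEL_HARMONICS = {
    "a": (1.0, 0.9, 0.7, 0.5, 0.3, 0.2),
    "e": (1.0, 0.6, 0.8, 0.4, 0.3, 0.1),
    "i": (1.0, 0.4, 0.3, 0.7, 0.5, 0.2),
    "o": (1.0, 0.8, 0.4, 0.2, 0.1, 0.1),
    "u": (1.0, 0.7, 0.3, 0.1, 0.1, 0.05),
}


def _frication_carrier(n: int, rate: float, rng: np.random.Generator,
                       f_lo: float, f_hi: float,
                       spacing: float = 220.0) -> np.ndarray:
    """Noise-like frication carrier with a steady cochlear envelope.

    A dense equal-spaced tone complex with random phases sounds noisy but,
    unlike true white noise, its envelope fluctuates only at the component
    spacing (beat) frequency, which the envelope decimation removes — so
    frication does not leak spurious slow "edges" into the markers.
    Unit RMS.
    """
    freqs = np.arange(f_lo, f_hi, spacing)
    t = np.arange(n) / rate
    x = np.zeros(n)
    for f, ph in zip(freqs, rng.uniform(0, 2 * np.pi, freqs.size)):
        x += np.sin(2 * np.pi * f * t + ph)
    rms = np.sqrt(np.mean(x**2))
    return x / rms if rms > 0 else x


def synth_syllable(recipe: SyllableRecipe, rate: float = 44100.0,
                   seed: int | None = None) -> Waveform:
    """One syllable token: class-dependent onset + vowel with shaped attack.

    Plosive-like tokens are silence + burst + a prominent vowel peak decaying
    through the syllable; fricated tokens ramp steady noise up to a fraction
    of the vowel level so the envelope's main rise is the (slow) consonant-
    vowel transition. The waveform is RMS-normalized to a common reference
    level (the synthetic stand-in for equal-SPL presentation). Deterministic
    per seed.
    """
    rng = np.random.default_rng(seed)
    n_total = int(round(recipe.duration_ms * rate / 1000.0))
    cls = recipe.phoneme_class
    onset_ms, onset_type = CLASS_ONSET[cls]
    n_onset = min(int(round(onset_ms * rate / 1000.0)), n_total - 2)
    t_on = np.arange(n_onset) / rate

    amps = _VOWEL_HARMONICS[recipe.vowel]
    vowel_rms = np.sqrt(sum(a * a for a in amps) / 2.0)
    if onset_type == "silence+burst":
        onset = np.zeros(n_onset)
        n_burst = min(int(round(0.005 * rate)), n_onset)
        if n_burst:
            onset[-n_burst:] = 0.5 * rng.standard_normal(n_burst)
    elif onset_type == "murmur":
        onset = MURMUR_LEVEL * vowel_rms * np.sin(2 * np.pi * recipe.f0 * t_on) \
            * np.linspace(0.3, 1.0, n_onset)
    else:
        onset = np.zeros(n_onset)

    n_vowel = n_total - n_onset
    t = np.arange(n_vowel) / rate
    vowel = np.zeros(n_vowel)
    for h, amp in enumerate(amps, start=1):
        vowel += amp * np.sin(2 * np.pi * recipe.f0 * h * t)
    n_attack = max(2, int(round(recipe.attack_ms * rate / 1000.0)))
    n_attack = min(n_attack, n_vowel)
    ramp = np.ones(n_vowel)
    ramp[:n_attack] = 0.5 * (1 - np.cos(np.pi * np.arange(n_attack) / n_attack))
    if n_vowel > n_attack:
        t_dec = np.arange(n_vowel - n_attack) / rate
        ramp[n_attack:] *= np.maximum(1.0 - CLASS_DECAY_RATE[cls] * t_dec, 0.15)
    n_rel = min(int(round(0.05 * rate)), n_vowel)
    if n_rel:
        ramp[-n_rel:] *= 0.5 * (1 + np.cos(np.pi * np.arange(n_rel) / n_rel))
    vowel *= ramp

    x = np.concatenate([onset, vowel])
    if onset_type == "noise-ramp":
        # frication rises through the prefix and crossfades out during the
        # vowel attack, so the cochlear envelope climbs monotonically from
        # frication level to the vowel peak (the consonant-vowel transition)
        level = CLASS_NOISE_LEVEL[cls] * vowel_rms * np.sqrt(2.0)
        n_noise = min(n_onset + n_attack, n_total)
        carrier = _frication_carrier(n_noise, rate, rng, *CLASS_FRICATION_BAND[cls])
        gate = np.concatenate([
            np.linspace(0.0, 1.0, n_onset),
            np.linspace(1.0, 0.0, n_noise - n_onset),
        ])
        x[:n_noise] += level * gate * carrier
    rms = np.sqrt(np.mean(x**2))
    if rms > 0:
        x = 0.05 * x / rms
    return Waveform(x, rate, label=f"{recipe.consonant}{recipe.vowel}")


def condition_recipes(condition: str, stream_vowels: tuple[str, ...],
                      durations_ms: np.ndarray | None = None) -> list[SyllableRecipe]:
    """Recipes for one stream of a condition, following its vowel order."""
    out = []
    for i, v in enumerate(stream_vowels):
        d = 250.0 if durations_ms is None else float(durations_ms[i])
        out.append(SyllableRecipe(condition, v, duration_ms=d))
    return out


def render_stream(recipes: list[SyllableRecipe], rate: float = 44100.0,
                  seed: int | None = None,
                  deviant_position: int | None = None,
                  deviant_consonant: str | None = None) -> Waveform:
    """Concatenate syllable tokens into a ~5 s stream.

    A filler entry substitutes the deviant consonant at the stored 1-based
    position (vowel kept).
    """
    if not recipes:
        raise ValueError("empty stream: no syllable recipes")
    rng = np.random.default_rng(seed)
    pieces = []
    for i, r in enumerate(recipes, start=1):
        if deviant_position is not None and i == deviant_position:
            r = SyllableRecipe(deviant_consonant, r.vowel, duration_ms=r.duration_ms)
        pieces.append(synth_syllable(r, rate, seed=int(rng.integers(2**31))).samples)
    label = recipes[0].consonant
    return Waveform(np.concatenate(pieces), rate, label=label)


@dataclass
class EEGSimConfig:
    """Parameters of the edge-triggered evoked EEG model."""

    n_channels: int = 32
    rate: float = 1000.0
    evoked_gain_uv: float = 5.0  # kernel peak scale, microvolts
    kernel_freq: float = 10.0  # damped-oscillation frequency, Hz
    kernel_decay: float = 0.05  # decay time constant, s
    kernel_duration: float = 0.30  # s
    noise_rms_uv: float = 15.0  # per-channel 1/f noise RMS
    noise_exponent: float = 1.0
    base_jitter_ms: float = 5.0
    coupling: float = 0.0  # extra jitter SD per ms of condition MD latency
    syllable_period: float = 0.25  # s
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.base_jitter_ms < 0 or self.noise_rms_uv < 0:
            raise ValueError("jitter SD and noise amplitude must be non-negative")


def _evoked_kernel(cfg: EEGSimConfig) -> np.ndarray:
    t = np.arange(int(round(cfg.kernel_duration * cfg.rate))) / cfg.rate
    return cfg.evoked_gain_uv * np.sin(2 * np.pi * cfg.kernel_freq * t) * np.exp(-t / cfg.kernel_decay)


def _pink_noise(n: int, exponent: float, rng: np.random.Generator) -> np.ndarray:
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    f[0] = f[1] if n > 1 else 1.0
    spec *= f ** (-exponent / 2.0)
    x = np.fft.irfft(spec, n)
    sd = x.std()
    return x / sd if sd > 0 else x


def jitter_sd_ms(md_latency_ms: float, cfg: EEGSimConfig,
                 md_ref_ms: float = 0.0) -> float:
    """Condition jitter SD: base + coupling x (MD latency above reference)."""
    return max(0.0, cfg.base_jitter_ms + cfg.coupling * (md_latency_ms - md_ref_ms))


def simulate_eeg(
    schedule: StimulusSchedule,
    condition_md_latency_ms: dict[str, float],
    cfg: EEGSimConfig,
    include_fillers: bool = False,
) -> EEGRecording:
    """Continuous EEG: jittered edge-triggered evoked kernels + 1/f noise.

    Every syllable of every presentation triggers the evoked kernel at
    (stream onset + syllable onset + MD latency + jitter), where the jitter
    is drawn per syllable per presentation with the condition's SD. All
    channels share the evoked time course scaled by a fixed per-channel gain
    (zero-mean across channels, so it survives average referencing);
    channel noise is independent 1/f. Stream-onset events are attached.
    """
    rng = np.random.default_rng(cfg.seed)
    pres = schedule.presentations if include_fillers else schedule.targets
    if not pres:
        raise ValueError("schedule has no presentations to simulate")
    t_end = max(p.onset_time for p in pres) + schedule.stream_slot + 1.0
    n = int(round(t_end * cfg.rate))
    kernel = _evoked_kernel(cfg)
    md_ref = min(condition_md_latency_ms.values())

    evoked = np.zeros(n)
    events = []
    for p in sorted(pres, key=lambda q: q.onset_time):
        onset_sample = int(round(p.onset_time * cfg.rate))
        events.append((onset_sample, p.stream_id))
        md = condition_md_latency_ms[p.condition]
        sd = jitter_sd_ms(md, cfg, md_ref)
        for s_idx in range(schedule.n_syllables):
            t_edge = (p.onset_time + s_idx * cfg.syllable_period
                      + md / 1000.0 + rng.normal(0.0, sd) / 1000.0)
            i0 = int(round(t_edge * cfg.rate))
            if i0 < 0 or i0 >= n:
                continue
            i1 = min(n, i0 + kernel.size)
            evoked[i0:i1] += kernel[: i1 - i0]

    gains = rng.standard_normal(cfg.n_channels)
    gains -= gains.mean()  # survive average referencing
    data = gains[:, None] * evoked[None, :]
    if cfg.noise_rms_uv > 0:
        for ch in range(cfg.n_channels):
            data[ch] += cfg.noise_rms_uv * _pink_noise(n, cfg.noise_exponent, rng)
    names = CHANNELS_32[: cfg.n_channels]
    if len(names) < cfg.n_channels:
        names = names + [f"Ch{i}" for i in range(len(names), cfg.n_channels)]
    return EEGRecording(data, cfg.rate, names, events)


@dataclass
class SyntheticStudy:
    """A full synthetic dataset with stored ground truth."""

    schedule: StimulusSchedule
    condition_markers: "object"  # pandas DataFrame, one row per condition
    condition_jitter_sd_ms: dict[str, float]
    cfg: EEGSimConfig
    participant_seeds: list[int]

    @property
    def participants(self) -> list[str]:
        return [f"p{i}" for i in range(len(self.participant_seeds))]

    def participant_recording(self, i: int) -> EEGRecording:
        """Simulate participant i's recording (lazy, seeded)."""
        from dataclasses import replace

        cfg = replace(self.cfg, seed=self.participant_seeds[i])
        md = dict(zip(self.condition_markers["condition"],
                      self.condition_markers["md_latency"]))
        return simulate_eeg(self.schedule, md, cfg)


def condition_marker_table(conditions, schedule: StimulusSchedule,
                           audio_rate: float = 44100.0, seed: int | None = None):
    """Edge markers per condition: synthesize the five vowel tokens, run the
    envelope+marker pipeline, and average fieldwise."""
    import pandas as pd

    from .edge_markers import condition_average, markers_from_waveform

    rng = np.random.default_rng(seed)
    rows = []
    for cond in conditions:
        sets = []
        for v in VOWELS:
            w = synth_syllable(SyllableRecipe(cond, v), rate=audio_rate,
                               seed=int(rng.integers(2**31)))
            sets.append(markers_from_waveform(w))
        avg = condition_average(sets)
        rows.append({"condition": cond, **avg.as_dict()})
    return pd.DataFrame(rows)


def make_study(
    n_participants: int = 25,
    conditions: tuple[str, ...] | None = None,
    reps: int = 10,
    blocks: int = 5,
    fillers: int = 50,
    cfg: EEGSimConfig | None = None,
    coupling: float | None = None,
    seed: int | None = None,
) -> SyntheticStudy:
    """Assemble a complete synthetic study (schedule, markers, ground truth).

    Recordings are generated lazily per participant to keep memory bounded.
    ``coupling`` (ms of jitter SD per ms of MD latency) overrides the config
    field when given.
    """
    from dataclasses import replace

    rng = np.random.default_rng(seed)
    cfg = cfg or EEGSimConfig()
    if coupling is not None:
        cfg = replace(cfg, coupling=coupling)
    conditions = tuple(conditions or DEFAULT_CONDITIONS)
    schedule = build_schedule(conditions, reps=reps, fillers=fillers,
                              blocks=blocks, seed=int(rng.integers(2**31)))
    markers = condition_marker_table(conditions, schedule,
                                     seed=int(rng.integers(2**31)))
    md_ref = float(markers["md_latency"].min())
    jitter = {
        row["condition"]: jitter_sd_ms(row["md_latency"], cfg, md_ref)
        for _, row in markers.iterrows()
    }
    part_seeds = [int(rng.integers(2**31)) for _ in range(n_participants)]
    return SyntheticStudy(schedule, markers, jitter, cfg, part_seeds)
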