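"""Raw multichannel EEG -> cleaned, trimmed epochs.

Pipeline order: 1–50 Hz zero-phase bandpass, average re-reference, epoching
on stream-onset events (5 s epochs), optional ocular component rejection
(the 12% frontal-power rule applied to a supplied blind-source-separation
decomposition), and removal of the first 500 ms of each epoch to avoid the
transient auditory onset response.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

log = logging.getLogger(__name__)

#: Default frontal channels for the ocular rejection rule.
DEFAULT_FRONTAL = ("Fp1", "Fp2", "F7", "F8")


@dataclass
class EEGRecording:
    """Continuous EEG: channels x samples in microvolts.

    ``events`` is a list of (sample_index, stream_id) marking stream onsets.
    """

    data: np.ndarray
    rate: float
    channel_names: list[str]
    events: list[tuple[int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be channels x samples")
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError("channel_names length must match data rows")
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        for idx, _sid in self.events:
            if not (0 <= idx < self.data.shape[1]):
                raise ValueError(f"event sample {idx} outside the recording")


@dataclass
class EpochedEEG:
    """Epochs: trials x channels x samples, with per-trial labels."""

    data: np.ndarray
    rate: float
    channel_names: list[str]
    condition: np.ndarray  # per trial
    stream: np.ndarray  # per trial
    trial: np.ndarray  # repetition index per trial
    participant: np.ndarray  # per trial

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("epochs must be trials x channels x samples")
        n = self.data.shape[0]
        for name in ("condition", "stream", "trial", "participant"):
            arr = np.asarray(getattr(self, name))
            if arr.shape != (n,):
                raise ValueError(f"label {name!r} must have one entry per trial")
            setattr(self, name, arr)

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]


def bandpass_eeg(rec: EEGRecording, lo: float = 1.0, hi: float = 50.0) -> EEGRecording:
    """Zero-phase Butterworth bandpass (defaults 1–50 Hz); removes DC."""
    if rec.rate <= 2 * hi:
        raise ValueError(f"rate {rec.rate} Hz too low for hi={hi} Hz")
    sos = signal.butter(6, [lo, hi], btype="bandpass", fs=rec.rate, output="sos")
    out = signal.sosfiltfilt(sos, rec.data, axis=1)
    return EEGRecording(out, rec.rate, list(rec.channel_names), list(rec.events))


def average_reference(rec: EEGRecording) -> EEGRecording:
    """Subtract the cross-channel mean at every sample."""
    if rec.data.shape[0] < 2:
        raise ValueError("average reference needs at least 2 channels")
    out = rec.data - rec.data.mean(axis=0, keepdims=True)
    return EEGRecording(out, rec.rate, list(rec.channel_names), list(rec.events))


def reject_eye_components(
    rec: EEGRecording,
    mixing: np.ndarray,
    sources: np.ndarray,
    frontal_channels: tuple[str, ...] = DEFAULT_FRONTAL,
    threshold: float = 0.12,
) -> EEGRecording:
    """Zero components whose frontal share of back-projected power exceeds 12%.

    ``mixing`` is components x channels (back-projection weights), ``sources``
    components x samples. For component c the back-projection onto channel ch
    is mixing[c, ch] * sources[c]; its broadband power summed over the frontal
    channels, divided by the power summed over all channels, is the frontal
    share. Components with share > ``threshold`` are dropped and the signal is
    rebuilt from the rest. Ocular activity projects almost entirely to the
    frontal row, so this is a scale-free eye-artifact criterion.
    """
    mixing = np.asarray(mixing, dtype=float)
    sources = np.asarray(sources, dtype=float)
    n_comp, n_chan = mixing.shape
    if sources.shape[0] != n_comp or n_chan != rec.data.shape[0]:
        raise ValueError("mixing/sources shapes inconsistent with the recording")
    if sources.shape[1] != rec.data.shape[1]:
        raise ValueError("sources length inconsistent with the recording")
    frontal_idx = [i for i, nm in enumerate(rec.channel_names) if nm in frontal_channels]
    src_power = np.sum(sources**2, axis=1)  # per component
    gain2 = mixing**2
    total = src_power * gain2.sum(axis=1)
    frontal = src_power * gain2[:, frontal_idx].sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        share = np.where(total > 0, frontal / np.where(total > 0, total, 1.0), 0.0)
    keep = share <= threshold
    if not np.all(keep):
        log.info("rejecting %d/%d components (frontal share > %.0f%%)",
                 np.count_nonzero(~keep), n_comp, 100 * threshold)
    out = mixing[keep].T @ sources[keep]
    return EEGRecording(out, rec.rate, list(rec.channel_names), list(rec.events))


def epoch(rec: EEGRecording, schedule=None, duration: float = 5.0,
          participant: str = "p0") -> EpochedEEG:
    """Cut one epoch per stream-onset event.

    Stream/condition labels come from ``schedule`` (a StimulusSchedule) when
    given, else the stream id doubles as the condition. Events without
    ``duration`` seconds of data after them are skipped with a warning.
    """
    n = int(round(duration * rec.rate))
    chunks, conds, streams, trials = [], [], [], []
    counter: dict[str, int] = {}
    stream_condition = {}
    if schedule is not None:
        stream_condition = {p.stream_id: p.condition for p in schedule.presentations}
    for idx, sid in rec.events:
        if idx + n > rec.data.shape[1]:
            warnings.warn(
                f"event for stream {sid!r} at sample {idx} is truncated; skipped",
                stacklevel=2,
            )
            continue
        chunks.append(rec.data[:, idx : idx + n])
        streams.append(sid)
        conds.append(stream_condition.get(sid, sid))
        k = counter.get(sid, 0)
        trials.append(k)
        counter[sid] = k + 1
    data = np.stack(chunks) if chunks else np.empty((0, rec.data.shape[0], n))
    m = len(chunks)
    return EpochedEEG(
        data, rec.rate, list(rec.channel_names),
        np.asarray(conds, dtype=object), np.asarray(streams, dtype=object),
        np.asarray(trials), np.asarray([participant] * m, dtype=object),
    )


def trim_onset(ep: EpochedEEG, trim: float = 0.5) -> EpochedEEG:
    """Drop the first ``trim`` seconds of every epoch (default 500 ms)."""
    k = int(round(trim * ep.rate))
    if k >= ep.data.shape[-1]:
        raise ValueError(f"trim {trim} s is not shorter than the epochs")
    return EpochedEEG(
        ep.data[:, :, k:], ep.rate, list(ep.channel_names),
        ep.condition, ep.stream, ep.trial, ep.participant,
    )


def preprocess(
    rec: EEGRecording,
    schedule=None,
    lo: float = 1.0,
    hi: float = 50.0,
    duration: float = 5.0,
    trim: float = 0.5,
    participant: str = "p0",
    ica: tuple[np.ndarray, np.ndarray] | None = None,
    frontal_channels: tuple[str, ...] = DEFAULT_FRONTAL,
) -> EpochedEEG:
    """Full chain: filter -> re-reference -> (ocular rejection) -> epoch -> trim."""
    rec = bandpass_eeg(rec, lo, hi)
    rec = average_reference(rec)
    if ica is not None:
        mixing, sources = ica
        rec = reject_eye_components(rec, mixing, sources, frontal_channels)
    ep = epoch(rec, schedule, duration=duration, participant=participant)
    return trim_onset(ep, trim)
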