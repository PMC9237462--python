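"""Scalar "edge" descriptors of a syllable's amplitude envelope.

Eight markers quantify how sharp and how prominent the envelope rise is:

- sharpness: mean of the positive part of the discrete derivative (amp/s)
- MA, MA latency: maximum amplitude and the time of its first occurrence
- 80%-MA latency: first time the envelope reaches 80% of MA
- plateau: width of the region above 80% of MA around the peak
- MD, MD latency: maximum derivative (steepest rise) and its first time —
  commonly read as marking the consonant–vowel transition
- Gini index: inequality of the envelope values; 0 for a flat envelope,
  approaching 1 for a single dominant spike.

All latencies are in milliseconds with t = 0 at the envelope onset and use
first-occurrence tie-breaking. Derivatives are forward differences scaled by
the sampling rate, with the latency assigned to the left sample.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np

from .audio_envelope import Envelope


@dataclass
class EdgeMarkerSet:
    """Edge-marker values for one syllable (or a condition average)."""

    sharpness: float  # amplitude / s
    ma: float  # amplitude
    ma_latency: float  # ms
    ma80_latency: float  # ms
    plateau: float  # ms
    md: float  # amplitude / s
    md_latency: float  # ms
    gini: float  # unitless, [0, 1)

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def _first_max(x: np.ndarray) -> int:
    """Index of the first occurrence of the maximum, tolerant of float noise.

    Ties within a relative 1e-9 of the maximum count as maxima, so a
    constant-slope rise reports its first sample rather than whichever
    rounding error argmax happens to prefer.
    """
    m = float(np.max(x))
    tol = 1e-9 * max(abs(m), float(np.max(np.abs(x))))
    return int(np.flatnonzero(x >= m - tol)[0])


def sharpness(e: Envelope) -> float:
    """Mean positive derivative of the envelope, in amplitude units per second."""
    d = np.diff(e.values) * e.rate
    if d.size == 0:
        raise ValueError("envelope too short for a derivative")
    return float(np.mean(np.maximum(d, 0.0)))


def max_amplitude(e: Envelope) -> tuple[float, float]:
    """Maximum amplitude and the latency (ms) of its first occurrence."""
    if e.values.size == 0:
        raise ValueError("empty envelope")
    i = _first_max(e.values)
    return float(e.values[i]), 1000.0 * i / e.rate


def latency_80(e: Envelope) -> float:
    """Latency (ms) of the first sample at or above 80% of the maximum."""
    ma, _ = max_amplitude(e)
    idx = np.flatnonzero(e.values >= 0.8 * ma)
    return 1000.0 * int(idx[0]) / e.rate


def plateau(e: Envelope) -> float:
    """Width (ms) of the envelope's stay above 80% of MA around the peak.

    Measured from the first ascending crossing of 0.8*MA to the first sample
    after the MA latency that falls back below it; runs to the envelope end if
    the value never falls back.
    """
    ma, ma_lat = max_amplitude(e)
    thresh = 0.8 * ma
    i_up = int(np.flatnonzero(e.values >= thresh)[0])
    i_peak = int(round(ma_lat * e.rate / 1000.0))
    after = np.flatnonzero(e.values[i_peak:] < thresh)
    i_down = i_peak + int(after[0]) if after.size else e.values.size
    return 1000.0 * (i_down - i_up) / e.rate


def max_derivative(e: Envelope) -> tuple[float, float]:
    """Maximum forward-difference derivative (amp/s) and its first latency (ms)."""
    d = np.diff(e.values) * e.rate
    if d.size == 0:
        raise ValueError("envelope too short for a derivative")
    i = _first_max(d)
    return float(d[i]), 1000.0 * i / e.rate


def gini_index(e: Envelope) -> float:
    """Gini index G = sum_ij |x_i - x_j| / (2 n sum_i x_i) of the envelope.

    Bandpassed envelopes are signed, so the minimum is subtracted first to
    restore the non-negative values the index is defined on. A constant
    envelope returns 0 (the degenerate limit). Computed via the sorted
    O(n log n) identity; the double-loop form is kept as a test oracle.
    """
    x = e.values - e.values.min()
    n = x.size
    total = x.sum()
    if total == 0.0:
        return 0.0
    xs = np.sort(x)
    i = np.arange(1, n + 1)
    return float(2.0 * np.sum(i * xs) / (n * total) - (n + 1.0) / n)


def compute_markers(e: Envelope) -> EdgeMarkerSet:
    """All eight markers of one envelope."""
    ma, ma_lat = max_amplitude(e)
    md, md_lat = max_derivative(e)
    return EdgeMarkerSet(
        sharpness=sharpness(e),
        ma=ma,
        ma_latency=ma_lat,
        ma80_latency=latency_80(e),
        plateau=plateau(e),
        md=md,
        md_latency=md_lat,
        gini=gini_index(e),
    )


def condition_average(sets: list[EdgeMarkerSet]) -> EdgeMarkerSet:
    """Fieldwise arithmetic mean over syllables of one condition."""
    if not sets:
        raise ValueError("cannot average an empty marker list")
    return EdgeMarkerSet(
        **{
            f.name: float(np.mean([getattr(s, f.name) for s in sets]))
            for f in fields(EdgeMarkerSet)
        }
    )


def markers_from_waveform(
    w, spec=None, env_rate: float = 250.0, stage: str = "summed"
) -> EdgeMarkerSet:
    """Cochlear envelope chain + markers for one syllable waveform.

    By default the markers are computed on the summed narrowband envelope,
    anti-alias decimated to ``env_rate`` (250 Hz removes pitch-beat ripple
    while leaving even a 10 ms attack intact). ``stage='bandpassed'`` computes
    them on the 2–10 Hz smoothed envelope instead; that stage clips the rise
    of attacks faster than its passband, which blunts the very contrast the
    sharpness and MD markers exist to capture, so it is not the default.
    """
    from .audio_envelope import syllable_envelope

    env = syllable_envelope(w, spec=spec, env_rate=env_rate,
                            bandpass=(stage == "bandpassed"))
    return compute_markers(env)
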