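"""Inter-trial phase coherence (ITPC) at the syllable rate and harmonics.

Phases come from Hann-tapered FFTs of the trimmed epochs. The coherence
statistic is the *squared* mean resultant of the K unit phasors of one
(electrode, stream) cell,

    R = (mean cos theta)^2 + (mean sin theta)^2,

which is 1 for identical phases and has expectation 1/K for uniform random
phases (0.1 at K = 10). The participant-level view R(f, a) averages cells
over streams and electrodes; R(f) further averages participants. Peak
significance compares real participants to "fictive" participants built by
pushing uniform random phases through the identical averaging structure, via
a one-sided Mann–Whitney U-test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .eeg_preprocess import EpochedEEG


@dataclass
class PhaseSpectrum:
    """Per-epoch Fourier phases up to an analysis ceiling.

    ``phases`` has shape (n_trials, n_channels, n_bins); ``freqs`` are the
    bin frequencies (spacing 1/epoch-duration). Trial labels are carried
    through from the epochs.
    """

    phases: np.ndarray
    freqs: np.ndarray
    condition: np.ndarray
    stream: np.ndarray
    participant: np.ndarray

    def bin_of(self, f: float, tol: float | None = None) -> int:
        """Index of the bin nearest ``f``; error if above the ceiling."""
        if f > self.freqs[-1] + 1e-9:
            raise ValueError(f"{f} Hz above the analysis ceiling {self.freqs[-1]} Hz")
        i = int(np.argmin(np.abs(self.freqs - f)))
        df = self.freqs[1] - self.freqs[0] if self.freqs.size > 1 else np.inf
        if tol is None:
            tol = df / 2
        if abs(self.freqs[i] - f) > tol + 1e-12:
            raise ValueError(
                f"requested {f} Hz is {abs(self.freqs[i] - f):.3f} Hz from the "
                f"nearest bin ({self.freqs[i]:.3f} Hz)"
            )
        return i


@dataclass
class ITPCTable:
    """R(f, x) indexed frequency x electrode x stream x participant."""

    R: np.ndarray  # (n_freqs, n_electrodes, n_streams, n_participants)
    freqs: np.ndarray
    streams: list
    stream_condition: dict
    participants: list
    K: int


@dataclass
class SurrogateNull:
    """Fictive-participant null distribution of R(f, a) at one bin."""

    values: np.ndarray
    n_streams: int
    n_electrodes: int
    K: int
    seed: int | None

    def percentile(self, q: float) -> float:
        return float(np.percentile(self.values, q))


def phase_spectrum(ep: EpochedEEG, ceiling: float = 26.0) -> PhaseSpectrum:
    """Hann-windowed FFT phases of every epoch/channel up to ``ceiling`` Hz."""
    data = ep.data
    n = data.shape[-1]
    if n == 0 or ep.data.ndim != 3:
        raise ValueError("need trials x channels x samples epochs")
    win = np.hanning(n)
    spec = np.fft.rfft(data * win, axis=-1)
    freqs = np.fft.rfftfreq(n, d=1.0 / ep.rate)
    keep = freqs <= ceiling + 1e-9
    return PhaseSpectrum(
        phases=np.angle(spec[..., keep]),
        freqs=freqs[keep],
        condition=np.asarray(ep.condition),
        stream=np.asarray(ep.stream),
        participant=np.asarray(ep.participant),
    )


def itpc_cell(phases: np.ndarray, squared: bool = True) -> float:
    """Coherence of K phases (radians): squared mean resultant by default."""
    phases = np.asarray(phases, dtype=float)
    if phases.size < 2:
        raise ValueError("need at least K = 2 phases")
    c = np.mean(np.cos(phases))
    s = np.mean(np.sin(phases))
    r2 = c * c + s * s
    return float(r2 if squared else np.sqrt(r2))


def itpc_table(ps: PhaseSpectrum, squared: bool = True) -> ITPCTable:
    """Group epochs by (participant, stream) and compute R per cell.

    Every (participant, stream) cell must hold the same number of trials K.
    """
    participants = sorted(set(ps.participant.tolist()))
    streams = sorted(set(ps.stream.tolist()))
    stream_condition = {}
    n_f = ps.freqs.size
    n_e = ps.phases.shape[1]
    R = np.full((n_f, n_e, len(streams), len(participants)), np.nan)
    K = None
    for ai, a in enumerate(participants):
        for si, s in enumerate(streams):
            sel = (ps.participant == a) & (ps.stream == s)
            k = int(np.count_nonzero(sel))
            if k == 0:
                raise ValueError(f"missing cell: participant {a}, stream {s}")
            if K is None:
                K = k
            elif k != K:
                raise ValueError(
                    f"unbalanced trials: participant {a}, stream {s} has {k}, expected {K}"
                )
            stream_condition[s] = ps.condition[sel][0]
            th = ps.phases[sel]  # (K, n_e, n_f)
            c = np.mean(np.cos(th), axis=0)
            sn = np.mean(np.sin(th), axis=0)
            r2 = c * c + sn * sn
            R[:, :, si, ai] = (r2 if squared else np.sqrt(r2)).T
    return ITPCTable(R, ps.freqs, streams, stream_condition, participants, K)


def average_hierarchy(tab: ITPCTable):
    """R(f, a), R(f) and per-condition R(f, condition, a) averages.

    R(f, a) is the mean over streams and electrodes; R(f) the further mean
    over participants; the condition-level view restricts the stream average
    to each condition's own streams.
    """
    if np.any(np.isnan(tab.R)):
        bad = np.argwhere(np.isnan(tab.R))
        raise ValueError(f"ITPC table has {bad.shape[0]} missing cells")
    R_fa = tab.R.mean(axis=(1, 2))  # (n_freqs, n_participants)
    R_f = R_fa.mean(axis=1)
    conditions = sorted({str(c) for c in tab.stream_condition.values()})
    R_cond = np.empty((tab.freqs.size, len(conditions), len(tab.participants)))
    for ci, cond in enumerate(conditions):
        idx = [i for i, s in enumerate(tab.streams) if str(tab.stream_condition[s]) == cond]
        R_cond[:, ci, :] = tab.R[:, :, idx, :].mean(axis=(1, 2))
    return R_fa, R_f, (conditions, R_cond)


def random_phase_itpc(
    n: int, K: int = 10, rng: np.random.Generator | None = None, squared: bool = True
) -> np.ndarray:
    """n independent ITPC values from K uniform random phases each (vectorized)."""
    rng = rng or np.random.default_rng()
    th = rng.uniform(-np.pi, np.pi, size=(n, K))
    c = np.mean(np.cos(th), axis=1)
    s = np.mean(np.sin(th), axis=1)
    r2 = c * c + s * s
    return r2 if squared else np.sqrt(r2)


def surrogate_null(
    n_streams: int = 45,
    n_electrodes: int = 32,
    K: int = 10,
    n_fictive: int = 5000,
    seed: int | None = None,
    squared: bool = True,
    chunk: int = 200,
) -> SurrogateNull:
    """Fictive participants: mean over streams x electrodes of random-phase ITPC."""
    rng = np.random.default_rng(seed)
    cells = n_streams * n_electrodes
    out = np.empty(n_fictive)
    done = 0
    while done < n_fictive:
        m = min(chunk, n_fictive - done)
        vals = random_phase_itpc(m * cells, K=K, rng=rng, squared=squared)
        out[done : done + m] = vals.reshape(m, cells).mean(axis=1)
        done += m
    return SurrogateNull(out, n_streams, n_electrodes, K, seed)


def peak_significance(real: np.ndarray, null: SurrogateNull) -> tuple[float, float]:
    """One-sided Mann–Whitney U-test of real R(f, a) values against the null.

    Returns (U, p) for the alternative "real participants exceed fictive
    ones". Degenerate all-tied input returns p = 1.
    """
    real = np.asarray(real, dtype=float)
    if real.size < 2:
        raise ValueError("need at least 2 real participant values")
    pooled = np.concatenate([real, null.values])
    if np.all(pooled == pooled[0]):
        return float(real.size * null.values.size / 2.0), 1.0
    method = "exact" if (real.size < 8 and null.values.size < 8) else "asymptotic"
    res = stats.mannwhitneyu(real, null.values, alternative="greater", method=method)
    return float(res.statistic), float(res.pvalue)


def harmonic_extract(
    R: np.ndarray,
    freqs: np.ndarray,
    base: float = 4.0,
    harmonics: tuple[float, ...] = (4.0, 8.0, 12.0, 16.0),
) -> np.ndarray:
    """Values of R at the bins nearest the requested harmonic frequencies.

    ``R``'s first axis must be frequency. A requested frequency above the
    covered range is an error; one that does not land on a bin (the epoch
    duration and the frequency are incommensurate) triggers a warning.
    """
    import warnings

    freqs = np.asarray(freqs)
    idx = []
    for f in harmonics:
        if f > freqs[-1] + 1e-9:
            raise ValueError(f"harmonic {f} Hz above analysis ceiling {freqs[-1]} Hz")
        i = int(np.argmin(np.abs(freqs - f)))
        if abs(freqs[i] - f) > 1e-6:
            warnings.warn(
                f"harmonic {f} Hz does not land on a bin (nearest {freqs[i]:.4f} Hz)",
                stacklevel=2,
            )
        idx.append(i)
    return np.asarray(R)[idx]
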