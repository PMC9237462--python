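"""End-to-end orchestration and file formats.

Stages are tied together as: synthesize (optional) -> preprocess -> ITPC ->
edge markers -> group statistics, with tidy CSV interchange, a JSON report
and explicit seeds everywhere. EEG comes in as BrainVision Core
(.vhdr/.eeg/.vmrk) or as a raw float32 binary with a JSON sidecar; audio as
WAV (PCM 16/32-bit or float; 24-bit PCM is not supported by the reader).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .eeg_preprocess import EEGRecording, preprocess
from .itpc import (
    average_hierarchy,
    harmonic_extract,
    itpc_table,
    peak_significance,
    phase_spectrum,
    surrogate_null,
)

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# file formats

def read_wav(path) -> "object":
    """Read a WAV file into a Waveform (int PCM rescaled to [-1, 1])."""
    from scipy.io import wavfile

    from .audio_envelope import Waveform

    rate, data = wavfile.read(path)
    data = np.asarray(data)
    if data.ndim > 1:
        data = data.mean(axis=1)
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(float) / np.iinfo(data.dtype).max
    return Waveform(data.astype(float), float(rate), label=Path(path).stem)


def write_wav(path, w) -> None:
    from scipy.io import wavfile

    wavfile.write(path, int(w.rate), w.samples.astype(np.float32))


def write_raw_binary(path, rec: EEGRecording) -> None:
    """Raw float32 little-endian channels x samples + JSON sidecar."""
    path = Path(path)
    rec.data.astype("<f4").tofile(path)
    sidecar = {
        "rate": rec.rate,
        "channel_names": list(rec.channel_names),
        "events": [[int(i), str(s)] for i, s in rec.events],
        "n_channels": rec.data.shape[0],
        "n_samples": rec.data.shape[1],
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar))


def read_raw_binary(path) -> EEGRecording:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    data = np.fromfile(path, dtype="<f4").reshape(
        sidecar["n_channels"], sidecar["n_samples"]
    )
    events = [(int(i), str(s)) for i, s in sidecar["events"]]
    return EEGRecording(data.astype(float), float(sidecar["rate"]),
                        list(sidecar["channel_names"]), events)


def write_brainvision(basename, rec: EEGRecording) -> Path:
    """Minimal BrainVision Core writer (.vhdr/.eeg/.vmrk, IEEE float32).

    Intended for tests and for exporting synthetic recordings; events are
    written as Stimulus markers whose description is the stream id.
    """
    base = Path(basename)
    vhdr, eeg, vmrk = (base.with_suffix(s) for s in (".vhdr", ".eeg", ".vmrk"))
    n_ch = rec.data.shape[0]
    sampling_interval_us = 1e6 / rec.rate
    lines = [
        "Brain Vision Data Exchange Header File Version 1.0",
        "", "[Common Infos]", "Codepage=UTF-8",
        f"DataFile={eeg.name}", f"MarkerFile={vmrk.name}",
        "DataFormat=BINARY", "DataOrientation=MULTIPLEXED",
        f"NumberOfChannels={n_ch}",
        f"SamplingInterval={sampling_interval_us:.6f}",
        "", "[Binary Infos]", "BinaryFormat=IEEE_FLOAT_32",
        "", "[Channel Infos]",
    ]
    for i, name in enumerate(rec.channel_names, start=1):
        lines.append(f"Ch{i}={name},,1,µV")
    vhdr.write_text("\n".join(lines) + "\n", encoding="utf-8")
    rec.data.T.astype("<f4").tofile(eeg)  # multiplexed: sample-major
    mlines = [
        "Brain Vision Data Exchange Marker File, Version 1.0",
        "", "[Common Infos]", "Codepage=UTF-8", f"DataFile={eeg.name}",
        "", "[Marker Infos]",
        "Mk1=New Segment,,1,1,0,00000000000000000000",
    ]
    for j, (idx, sid) in enumerate(rec.events, start=2):
        mlines.append(f"Mk{j}=Stimulus,{sid},{idx + 1},1,0")
    vmrk.write_text("\n".join(mlines) + "\n", encoding="utf-8")
    return vhdr


def read_brainvision(path) -> EEGRecording:
    """Read a BrainVision Core triplet via MNE; Stimulus markers -> events."""
    import mne

    raw = mne.io.read_raw_brainvision(path, preload=True, verbose="error")
    data = raw.get_data() * 1e6  # volts -> microvolts
    events = []
    for onset, desc in zip(raw.annotations.onset, raw.annotations.description):
        if desc.startswith("Stimulus"):
            sid = desc.split("/", 1)[-1].strip()
            events.append((int(round(onset * raw.info["sfreq"])), sid))
    return EEGRecording(data, float(raw.info["sfreq"]),
                        list(raw.ch_names), events)


# ---------------------------------------------------------------------------
# pipeline

@dataclass
class RunConfig:
    """All stage parameters of one reproducible end-to-end run."""

    schema: str = "sylentrain-run/1"
    out_dir: str = "run_out"
    seed: int = 0
    # synthesis
    n_participants: int = 3
    conditions: tuple[str, ...] = ("b", "t", "n", "f", "s")
    reps: int = 10
    blocks: int = 5
    fillers: int = 0
    coupling: float = 0.6
    # preprocessing
    eeg_lo: float = 1.0
    eeg_hi: float = 50.0
    epoch_duration: float = 5.0
    trim: float = 0.5
    # itpc
    base_freq: float = 4.0
    harmonics: tuple[float, ...] = (4.0, 8.0, 12.0, 16.0)
    n_surrogates: int = 1000
    alpha: float = 0.05

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        d = dict(d)
        for key in ("conditions", "harmonics"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def config_hash(self) -> str:
        """Hash of the scientific parameters (output location excluded)."""
        d = dataclasses.asdict(self)
        d.pop("out_dir")
        blob = json.dumps(d, sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute synth -> preprocess -> ITPC -> markers -> stats; write outputs.

    Returns the report dict (also written as report.json). All CSV/JSON
    artifacts carry the config hash, so identical configs give identical
    outputs.
    """
    from . import group_stats, synthetic_data

    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = cfg.config_hash()
    log.info("run %s -> %s", chash, out)

    study = synthetic_data.make_study(
        n_participants=cfg.n_participants, conditions=cfg.conditions,
        reps=cfg.reps, blocks=cfg.blocks, fillers=cfg.fillers,
        coupling=cfg.coupling, seed=cfg.seed,
    )
    markers = study.condition_markers

    specs = []
    for i, pid in enumerate(study.participants):
        rec = study.participant_recording(i)
        ep = preprocess(rec, study.schedule, lo=cfg.eeg_lo, hi=cfg.eeg_hi,
                        duration=cfg.epoch_duration, trim=cfg.trim,
                        participant=pid)
        specs.append(phase_spectrum(ep))
    phases = np.concatenate([s.phases for s in specs])
    ps = dataclasses.replace(
        specs[0],
        phases=phases,
        condition=np.concatenate([s.condition for s in specs]),
        stream=np.concatenate([s.stream for s in specs]),
        participant=np.concatenate([s.participant for s in specs]),
    )
    tab = itpc_table(ps)
    R_fa, R_f, (cond_names, R_cond) = average_hierarchy(tab)

    null = surrogate_null(
        n_streams=len(tab.streams), n_electrodes=tab.R.shape[1], K=tab.K,
        n_fictive=cfg.n_surrogates, seed=cfg.seed + 1,
    )
    peaks = {}
    for f in cfg.harmonics:
        i = int(np.argmin(np.abs(tab.freqs - f)))
        U, p = peak_significance(R_fa[i], null)
        peaks[f] = {"frequency": f, "bin": i, "R": float(R_f[i]),
                    "U": U, "p": p, "significant": bool(p < cfg.alpha)}

    # tidy ITPC table: participant x condition x harmonic
    rows = []
    for ci, cond in enumerate(cond_names):
        vals = harmonic_extract(R_cond[:, ci, :], tab.freqs,
                                base=cfg.base_freq, harmonics=cfg.harmonics)
        for ai, pid in enumerate(tab.participants):
            for f, v in zip(cfg.harmonics, vals[:, ai]):
                rows.append({"participant": pid, "condition": cond,
                             "frequency": f, "R": float(v)})
    itpc_df = pd.DataFrame(rows)
    wide = itpc_df.pivot_table(index=["participant", "condition"],
                               columns="frequency", values="R").reset_index()
    scored, cs = group_stats.itpc_components(wide, tuple(cfg.harmonics))
    cond_scores = scored.groupby("condition", as_index=False)[["ITPC1", "ITPC2"]].mean()

    merged = cond_scores.merge(markers, on="condition")
    correlations = {}
    r4 = itpc_df[itpc_df.frequency == cfg.base_freq].groupby(
        "condition", as_index=False)["R"].mean().merge(markers, on="condition")
    if len(merged) >= 3:
        for m in ("sharpness", "ma", "ma_latency", "ma80_latency", "plateau",
                  "md", "md_latency", "gini"):
            r, p = group_stats.pearson(merged[m], merged["ITPC1"])
            correlations[m] = {"r": r, "p": p}
        r_md, p_md = group_stats.pearson(r4["md_latency"], r4["R"])
    else:
        log.warning("fewer than 3 conditions: condition-level correlations skipped")
        r_md = p_md = float("nan")

    anova_tab = scored.pivot_table(index="participant", columns="condition",
                                   values="ITPC1").to_numpy()
    anova = group_stats.rm_anova_gg(anova_tab)

    report = {
        "config_hash": chash,
        "config": dataclasses.asdict(cfg),
        "peaks": {str(k): v for k, v in peaks.items()},
        "itpc_pca_explained": cs.explained[:2].tolist(),
        "condition_anova_itpc1": {
            "F": anova.F, "df1": anova.df1, "df2": anova.df2,
            "epsilon": anova.epsilon, "p": anova.p,
        },
        "marker_itpc1_correlations": correlations,
        "md_latency_vs_4hz_itpc": {"r": r_md, "p": p_md},
        "ground_truth_jitter_sd_ms": study.condition_jitter_sd_ms,
    }
    for name, df in (("itpc.csv", itpc_df), ("markers.csv", markers),
                     ("condition_scores.csv", cond_scores)):
        df = df.copy()
        df.insert(0, "config_hash", chash)
        df.to_csv(out / name, index=False, float_format="%.10g")
    (out / "report.json").write_text(json.dumps(report, indent=2, default=float))
    return report
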