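"""Synthetic motor-imagery EEG sessions with class-dependent ERD.

A calibration session consists of six runs, one per binary class pairing
(LR, FR, LF, LX, FX, XR), separated by 90 s rest gaps.  Every trial is 8 s:
a 2 s cue pause followed by a 6 s task period.  Class labels are L (left
hand), F (feet), R (right hand), and X (relax).

The generated EEG is a sum of
  * per-channel 1/f^alpha pink background noise, and
  * narrow-band mu (8-12 Hz) and beta (18-28 Hz) oscillations shared within
    each sensorimotor channel group (left hemisphere, right hemisphere,
    midline).
Event-related desynchronization (ERD) is injected by multiplying a group's
oscillation amplitude by ``1 - erd_depth`` during the task window of trials
whose class maps to that group (left-hand imagery -> right hemisphere,
right-hand -> left hemisphere, feet -> midline), starting ``erd_latency_s``
after the task cue.  Relax (X) trials and inter-trial pauses keep baseline
amplitudes, so the rhythm is ongoing and the task-locked power *decrease*
is the only class-discriminative structure, as in real sensorimotor EEG.

All randomness flows through a single integer seed; a fixed seed yields
bit-identical output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps

from . import edf as edfio
from .montage import CHANNELS_32, CLASS_CHANNEL_GROUPS

RUN_TYPES = ("LR", "FR", "LF", "LX", "FX", "XR")
CLASSES = ("L", "F", "R", "X")

PAUSE_DUR_S = 2.0
TASK_DUR_S = 6.0
TRIAL_DUR_S = PAUSE_DUR_S + TASK_DUR_S
INTER_RUN_GAP_S = 90.0


@dataclass(frozen=True)
class Trial:
    onset_s: float
    label: str
    pause_dur_s: float = PAUSE_DUR_S
    task_dur_s: float = TASK_DUR_S


@dataclass(frozen=True)
class TrialSchedule:
    """Timing and labels of one run (one class pair)."""

    trials: tuple[Trial, ...]
    class_pair: str
    run_id: int = 0
    session_id: int = 0

    @property
    def duration_s(self) -> float:
        return len(self.trials) * TRIAL_DUR_S

    def __post_init__(self) -> None:
        labels = [t.label for t in self.trials]
        counts = {c: labels.count(c) for c in set(labels)}
        if len(set(counts.values())) > 1:
            raise ValueError("unequal per-class trial counts in run")
        onsets = [t.onset_s for t in self.trials]
        if any(b - a < TRIAL_DUR_S - 1e-9 for a, b in zip(onsets, onsets[1:])):
            raise ValueError("overlapping or unordered trials")


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator parameters; defaults are the standard study conditions."""

    n_channels: int = 32
    fs_hz: float = 250.0
    channel_labels: tuple[str, ...] = CHANNELS_32
    pink_exponent: float = 1.0
    background_rms_uv: float = 10.0
    # baseline oscillation RMS amplitude (uV) per band, applied at every
    # sensorimotor group; band edges are the mu and high-beta filter bands
    osc_amplitude_uv: dict = field(
        default_factory=lambda: {(8.0, 12.0): 6.0, (18.0, 28.0): 4.0}
    )
    erd_depth: float = 0.5
    erd_latency_s: float = 0.4
    class_groups: dict = field(default_factory=lambda: dict(CLASS_CHANNEL_GROUPS))

    def __post_init__(self) -> None:
        if not 0.0 <= self.erd_depth <= 1.0:
            raise ValueError("erd_depth must be in [0, 1]")
        if self.erd_latency_s < 0:
            raise ValueError("erd_latency_s must be >= 0")
        if self.fs_hz <= 0:
            raise ValueError("fs_hz must be positive")
        if len(self.channel_labels) != self.n_channels:
            raise ValueError("channel_labels length must equal n_channels")


@dataclass
class EEGRecording:
    """Continuous multichannel record plus its event table.

    ``events`` columns: sample (index at fs_hz), label, run_id, session_id.
    """

    labels: tuple[str, ...]
    fs_hz: float
    data: np.ndarray  # channels x samples, uV
    events: pd.DataFrame

    def __post_init__(self) -> None:
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("channel labels must be unique")
        if self.fs_hz <= 0:
            raise ValueError("fs_hz must be positive")
        if len(self.events) and self.events["sample"].max() >= self.data.shape[1]:
            raise ValueError("event sample index outside record")


def make_trial_schedule(
    n_trials: int,
    class_pair: str,
    seed: int | None = None,
    run_id: int = 0,
    session_id: int = 0,
) -> TrialSchedule:
    """Build one run's schedule: ``n_trials`` back-to-back 8 s trials with
    equal per-class counts, label order shuffled with ``seed``."""
    if class_pair not in RUN_TYPES:
        raise ValueError(f"class_pair must be one of {RUN_TYPES}")
    if n_trials < 2 or n_trials % 2 != 0:
        raise ValueError("n_trials must be even and >= 2")
    a, b = class_pair[0], class_pair[1]
    labels = [a] * (n_trials // 2) + [b] * (n_trials // 2)
    rng = np.random.default_rng(seed)
    rng.shuffle(labels)
    trials = tuple(
        Trial(onset_s=TRIAL_DUR_S * k, label=lab) for k, lab in enumerate(labels)
    )
    return TrialSchedule(
        trials=trials, class_pair=class_pair, run_id=run_id, session_id=session_id
    )


def make_session_schedules(
    n_trials_per_run: int, seed: int | None = None, session_id: int = 0
) -> list[TrialSchedule]:
    """Schedules for the six standard runs, independently seeded per run."""
    ss = np.random.SeedSequence(seed)
    seeds = ss.generate_state(len(RUN_TYPES))
    return [
        make_trial_schedule(
            n_trials_per_run, pair, seed=int(s), run_id=i, session_id=session_id
        )
        for i, (pair, s) in enumerate(zip(RUN_TYPES, seeds))
    ]


def _pink_noise(rng: np.random.Generator, n: int, exponent: float) -> np.ndarray:
    """Unit-RMS 1/f^exponent (power) noise via frequency-domain shaping."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n)
    shaping = np.ones_like(freqs)
    nz = freqs > 0
    shaping[nz] = freqs[nz] ** (-exponent / 2.0)
    shaping[0] = 0.0  # no DC
    out = np.fft.irfft(spec * shaping, n)
    return out / out.std()


def _narrowband(
    rng: np.random.Generator, n: int, band: tuple[float, float], fs: float
) -> np.ndarray:
    """Unit-RMS band-limited Gaussian noise (an ongoing rhythm)."""
    ntaps = 501
    taps = sps.firwin(ntaps, band, pass_zero=False, fs=fs)
    x = sps.fftconvolve(rng.standard_normal(n + ntaps), taps, mode="same")
    x = x[ntaps // 2 : ntaps // 2 + n]
    return x / x.std()


def generate_session(
    config: SyntheticConfig,
    schedules: list[TrialSchedule],
    seed: int | None = None,
    lead_in_s: float = 10.0,
    lead_out_s: float = 5.0,
) -> EEGRecording:
    """Render one six-run session to a continuous EEG record.

    Runs are concatenated in schedule order with 90 s gaps, preceded by a
    ``lead_in_s`` rest baseline (so the first trial has pre-cue history)
    and followed by ``lead_out_s`` of rest.  The event table holds one row
    per trial at its onset sample.
    """
    pairs = {s.class_pair for s in schedules}
    if pairs != set(RUN_TYPES):
        missing = set(RUN_TYPES) - pairs
        raise ValueError(f"schedules must cover all six run types; missing {missing}")

    fs = config.fs_hz
    run_starts: list[float] = []
    t = lead_in_s
    for sched in schedules:
        run_starts.append(t)
        t += sched.duration_s + INTER_RUN_GAP_S
    total_s = t - INTER_RUN_GAP_S + lead_out_s
    n = int(round(total_s * fs))

    rng = np.random.default_rng(seed)
    n_ch = config.n_channels
    data = np.empty((n_ch, n), dtype=np.float64)
    for c in range(n_ch):
        data[c] = config.background_rms_uv * _pink_noise(rng, n, config.pink_exponent)

    # per-group ERD envelopes: 1 at baseline, 1-erd_depth in task windows
    envelopes = {cls: np.ones(n) for cls in config.class_groups}
    events = []
    for sched, start in zip(schedules, run_starts):
        for tr in sched.trials:
            onset = start + tr.onset_s
            events.append(
                {
                    "sample": int(round(onset * fs)),
                    "label": tr.label,
                    "run_id": sched.run_id,
                    "session_id": sched.session_id,
                }
            )
            if tr.label in envelopes and config.erd_depth > 0:
                lo = int(round((onset + tr.pause_dur_s + config.erd_latency_s) * fs))
                hi = int(round((onset + tr.pause_dur_s + tr.task_dur_s) * fs))
                envelopes[tr.label][lo:hi] = 1.0 - config.erd_depth

    label_index = {lab: i for i, lab in enumerate(config.channel_labels)}
    for cls, group in config.class_groups.items():
        env = envelopes[cls]
        for band, amp in config.osc_amplitude_uv.items():
            osc = _narrowband(rng, n, band, fs)
            for ch in group:
                data[label_index[ch]] += amp * env * osc

    return EEGRecording(
        labels=tuple(config.channel_labels),
        fs_hz=fs,
        data=data,
        events=pd.DataFrame(events, columns=["sample", "label", "run_id", "session_id"]),
    )


def write_fixture(
    recording: EEGRecording,
    schedules: list[TrialSchedule],
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write an EDF signal file, a CSV event table, and a JSON schedule
    manifest under ``out_dir``; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if recording.data.size == 0:
        raise ValueError("cannot write an empty recording")
    paths = {
        "edf": out_dir / "recording.edf",
        "events": out_dir / "events.csv",
        "schedules": out_dir / "schedules.json",
    }
    edfio.write_edf(paths["edf"], recording.data, list(recording.labels), recording.fs_hz)
    recording.events.to_csv(paths["events"], index=False)
    manifest = [
        {
            "class_pair": s.class_pair,
            "run_id": s.run_id,
            "session_id": s.session_id,
            "trials": [
                {"onset_s": t.onset_s, "label": t.label} for t in s.trials
            ],
        }
        for s in schedules
    ]
    paths["schedules"].write_text(json.dumps(manifest, indent=1))
    return paths


def read_fixture(in_dir: str | Path) -> tuple[EEGRecording, list[TrialSchedule]]:
    """Inverse of :func:`write_fixture` (up to 16-bit EDF quantization)."""
    in_dir = Path(in_dir)
    data, labels, fs = edfio.read_edf(in_dir / "recording.edf")
    events = pd.read_csv(in_dir / "events.csv")
    manifest = json.loads((in_dir / "schedules.json").read_text())
    schedules = [
        TrialSchedule(
            trials=tuple(Trial(onset_s=t["onset_s"], label=t["label"]) for t in m["trials"]),
            class_pair=m["class_pair"],
            run_id=m["run_id"],
            session_id=m["session_id"],
        )
        for m in manifest
    ]
    rec = EEGRecording(labels=tuple(labels), fs_hz=fs, data=data, events=events)
    return rec, schedules


def config_from_json(path: str | Path) -> SyntheticConfig:
    """Load a SyntheticConfig from a JSON file (band keys as "lo-hi")."""
    raw = json.loads(Path(path).read_text())
    if "osc_amplitude_uv" in raw:
        raw["osc_amplitude_uv"] = {
            tuple(float(x) for x in k.split("-")): float(v)
            for k, v in raw["osc_amplitude_uv"].items()
        }
    if "channel_labels" in raw:
        raw["channel_labels"] = tuple(raw["channel_labels"])
    return SyntheticConfig(**raw)
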