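"""Filter-bank decomposition, decimation, epoching, and run pooling.

The calibration front-end band-passes 250 Hz EEG into four non-overlapping
bands — 8-12 Hz (mu), 12-18 Hz (low beta), 18-28 Hz (high beta), and
28-40 Hz (low gamma) — decimates to 125 Hz, and cuts trials into
[-2, +8] s epochs relative to the cue-pause onset (task onset at +2 s) on a
21-channel sensorimotor subset.  Trials of the same class from different
runs are then pooled into a restructured dataset with the derived
T = L u F u R class for the task-vs-relax classifier.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from .montage import CALIBRATION_21
from .synthetic import EEGRecording

DEFAULT_BANDS = ((8.0, 12.0), (12.0, 18.0), (18.0, 28.0), (28.0, 40.0))
ACQ_FS_HZ = 250.0
EPOCH_FS_HZ = 125.0
EPOCH_WINDOW_S = (-2.0, 8.0)
TASK_ONSET_S = 2.0  # relative to pause onset


@dataclass(frozen=True)
class FilterBankConfig:
    """FIR band-pass bank: >=60 dB stop attenuation, ~2 Hz transitions."""

    bands: tuple[tuple[float, float], ...] = DEFAULT_BANDS
    transition_hz: float = 2.0
    stop_atten_db: float = 60.0
    zero_phase: bool = True  # offline calibration; False gives the causal path

    def __post_init__(self) -> None:
        for (l1, h1), (l2, h2) in zip(self.bands, self.bands[1:]):
            if l2 < h1 or l1 >= h1:
                raise ValueError("bands must be ascending and non-overlapping")


def _design_fir(band: tuple[float, float], fs: float, cfg: FilterBankConfig) -> np.ndarray:
    ntaps, beta = sps.kaiserord(cfg.stop_atten_db, cfg.transition_hz / (0.5 * fs))
    ntaps |= 1  # odd length -> integer group delay, exact zero-phase via 'same'
    return sps.firwin(ntaps, band, pass_zero=False, window=("kaiser", beta), fs=fs)


def apply_filter_bank(
    data: np.ndarray, fs_hz: float, config: FilterBankConfig | None = None
) -> np.ndarray:
    """Band-pass ``data`` (channels x samples) into each bank band.

    Returns an array (bands x channels x samples).  With ``zero_phase``
    (default) the symmetric FIR is applied centred, so all band outputs are
    time-aligned with the input; the causal variant delays by the filter
    group delay as an online implementation would.
    """
    config = config or FilterBankConfig()
    if fs_hz != ACQ_FS_HZ:
        raise ValueError(f"expected fs = {ACQ_FS_HZ} Hz, got {fs_hz}")
    data = np.atleast_2d(np.asarray(data, dtype=float))
    out = np.empty((len(config.bands), *data.shape), dtype=float)
    for i, band in enumerate(config.bands):
        taps = _design_fir(band, fs_hz, config)
        if config.zero_phase:
            out[i] = sps.fftconvolve(data, taps[None, :], mode="same", axes=-1)
        else:
            out[i] = sps.lfilter(taps, 1.0, data, axis=-1)
    return out


def downsample(signal: np.ndarray, fs_from: float = 250.0, fs_to: float = 125.0) -> np.ndarray:
    """Decimate band-limited signal by an integer factor (250 -> 125 Hz).

    The filter bank already confines content below 40 Hz < 62.5 Hz, so plain
    sample dropping is alias-free in-band.
    """
    if fs_from != ACQ_FS_HZ:
        raise ValueError(f"expected input fs = {ACQ_FS_HZ} Hz, got {fs_from}")
    factor = fs_from / fs_to
    if factor != int(factor) or factor < 1:
        raise ValueError("downsampling factor must be a positive integer")
    return np.asarray(signal)[..., :: int(factor)]


@dataclass
class EpochSet:
    """Per-trial band-decomposed epochs.

    ``data``: trials x channels x bands x samples (uV, 125 Hz), time axis
    ``times`` spanning -2..+8 s relative to pause onset (task onset +2 s).
    """

    data: np.ndarray
    times: np.ndarray
    channels: tuple[str, ...]
    bands: tuple[tuple[float, float], ...]
    labels: np.ndarray  # str per trial
    run_ids: np.ndarray
    session_ids: np.ndarray
    n_skipped: int = 0

    def __post_init__(self) -> None:
        if self.data.shape[0] != len(self.labels):
            raise ValueError("one label per trial required")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]


def epoch(
    band_signals: np.ndarray,
    channel_labels: tuple[str, ...] | list[str],
    events: pd.DataFrame,
    fs_hz: float = EPOCH_FS_HZ,
    window_s: tuple[float, float] = EPOCH_WINDOW_S,
    channel_subset: tuple[str, ...] = CALIBRATION_21,
    bands: tuple[tuple[float, float], ...] = DEFAULT_BANDS,
    event_fs_hz: float = ACQ_FS_HZ,
) -> EpochSet:
    """Cut [-2, +8] s trials from band-decomposed 125 Hz signals.

    ``band_signals``: bands x channels x samples at ``fs_hz``; event sample
    indices are given at the acquisition rate ``event_fs_hz`` and converted.
    Trials too close to the record edge are skipped with a warning.
    """
    band_signals = np.asarray(band_signals)
    n_bands, n_ch, n_samp = band_signals.shape
    if n_ch != len(channel_labels):
        raise ValueError("channel_labels must match band_signals channel axis")
    missing = [c for c in channel_subset if c not in channel_labels]
    if missing:
        raise ValueError(f"channel subset not in record: {missing}")
    picks = [list(channel_labels).index(c) for c in channel_subset]

    lo_off = int(round(window_s[0] * fs_hz))
    hi_off = int(round(window_s[1] * fs_hz))
    n_out = hi_off - lo_off  # 1250 samples for 10 s at 125 Hz
    ratio = event_fs_hz / fs_hz

    kept, labels, runs, sessions = [], [], [], []
    n_skipped = 0
    for _, ev in events.iterrows():
        center = int(round(ev["sample"] / ratio))
        lo, hi = center + lo_off, center + hi_off
        if lo < 0 or hi > n_samp:
            n_skipped += 1
            continue
        kept.append(band_signals[:, picks, lo:hi])
        labels.append(ev["label"])
        runs.append(ev["run_id"])
        sessions.append(ev["session_id"])
    if n_skipped:
        warnings.warn(f"skipped {n_skipped} trial(s) too close to record edge")
    data = (
        np.stack(kept).transpose(0, 2, 1, 3)
        if kept
        else np.empty((0, len(picks), n_bands, n_out))
    )
    times = window_s[0] + np.arange(n_out) / fs_hz
    return EpochSet(
        data=data,
        times=times,
        channels=tuple(channel_subset),
        bands=tuple(bands),
        labels=np.asarray(labels, dtype=object),
        run_ids=np.asarray(runs, dtype=int),
        session_ids=np.asarray(sessions, dtype=int),
        n_skipped=n_skipped,
    )


def preprocess_recording(
    recording: EEGRecording, config: FilterBankConfig | None = None, **epoch_kw
) -> EpochSet:
    """Convenience front-end: filter bank -> decimate -> epoch."""
    banded = apply_filter_bank(recording.data, recording.fs_hz, config)
    banded = downsample(banded, recording.fs_hz, EPOCH_FS_HZ)
    return epoch(banded, recording.labels, recording.events, **epoch_kw)


@dataclass
class RestructuredDataset:
    """Class-pooled trials from the six runs (optionally many sessions).

    Holds a single epoch tensor plus label/provenance arrays; the derived
    T class (task = L u F u R) is materialized on demand.
    """

    data: np.ndarray  # trials x channels x bands x samples
    times: np.ndarray
    channels: tuple[str, ...]
    bands: tuple[tuple[float, float], ...]
    labels: np.ndarray
    run_ids: np.ndarray
    session_ids: np.ndarray

    def class_indices(self, cls: str) -> np.ndarray:
        if cls == "T":
            return np.flatnonzero(np.isin(self.labels, ("L", "F", "R")))
        return np.flatnonzero(self.labels == cls)

    def class_counts(self) -> dict[str, int]:
        return {c: len(self.class_indices(c)) for c in ("L", "F", "R", "X", "T")}

    def pair_arrays(
        self,
        pair: str,
        balance_seed: int | None = 0,
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Trial tensor, binary labels (1 = first class of ``pair``), and
        original trial indices for one binary classifier.

        For the TX classifier the T pool (3x the size of X for balanced
        runs) is randomly subsampled to |X| with ``balance_seed``.
        """
        a, b = pair[0], pair[1]
        ia, ib = self.class_indices(a), self.class_indices(b)
        if a == "T" and balance_seed is not None and len(ia) > len(ib):
            rng = np.random.default_rng(balance_seed)
            ia = np.sort(rng.choice(ia, size=len(ib), replace=False))
        idx = np.concatenate([ia, ib])
        y = np.concatenate([np.ones(len(ia), dtype=int), np.zeros(len(ib), dtype=int)])
        return self.data[idx], y, idx


def restructure_runs(epoch_sets: list[EpochSet]) -> RestructuredDataset:
    """Pool same-class trials across runs (and sessions) into one dataset.

    L trials come from the LR/LF/LX runs, and analogously for F, R, X; the
    T class is the union of L, F, R.  Per-trial provenance (session, run)
    is preserved.
    """
    if not epoch_sets:
        raise ValueError("no epoch sets to pool")
    ref = epoch_sets[0]
    data = np.concatenate([e.data for e in epoch_sets], axis=0)
    labels = np.concatenate([e.labels for e in epoch_sets])
    runs = np.concatenate([e.run_ids for e in epoch_sets])
    sessions = np.concatenate([e.session_ids for e in epoch_sets])
    ds = RestructuredDataset(
        data=data,
        times=ref.times,
        channels=ref.channels,
        bands=ref.bands,
        labels=labels,
        run_ids=runs,
        session_ids=sessions,
    )
    for cls in ("L", "F", "R", "X"):
        if len(ds.class_indices(cls)) == 0:
            raise ValueError(f"class {cls} has zero pooled trials")
    return ds
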