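"""CSP spatial filtering, sliding log-variance features, and quantized-MI
feature ranking for one binary classifier.

Per band, common spatial patterns (CSP) filters jointly diagonalize the two
class-average normalized spatial covariances; the three most extreme filter
pairs are kept (6 filters x 4 bands = 24 features).  Features are the log
variance of the CSP-projected signal in a 1 s trailing window sliding at
40 ms steps (25 Hz frame rate), window end-points spanning -1..+8 s
relative to pause onset.  Features are ranked by the mutual information
between their quantized values and the class label.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import linalg as sla

FRAME_RATE_HZ = 25.0
FRAME_SPAN_S = (-1.0, 8.0)
LOGVAR_FLOOR = 1e-12
TASK_INTERVAL_S = (2.4, 8.0)  # event-related period re pause onset


@dataclass
class CSPModel:
    """Per-band CSP filter bank for one class pair.

    ``filters``: bands x 2m x channels, rows ordered by descending
    class-1 variance ratio, so rows 1..m and 2m..m+1 are the paired
    extremes.  ``eigvals`` holds the corresponding generalized eigenvalues
    (class-1 variance fraction, in (0, 1)).
    """

    filters: np.ndarray
    eigvals: np.ndarray
    class_pair: str = ""
    n_pairs: int = 3

    @property
    def n_features(self) -> int:
        return self.filters.shape[0] * self.filters.shape[1]


def _normalized_covariance(trials: np.ndarray, normalize: str | None = "trace") -> np.ndarray:
    """Average spatial covariance over trials (trials x channels x samples).

    ``normalize="trace"`` (the standard estimate) divides each trial's
    covariance by its trace, equalizing per-trial broadband power before
    averaging; ``None`` averages raw covariances, which makes CSP exactly
    invariant to joint channel-wise rescaling of both classes.
    """
    covs = np.einsum("tcs,tds->tcd", trials, trials)
    if normalize == "trace":
        covs = covs / np.trace(covs, axis1=1, axis2=2)[:, None, None]
    elif normalize is not None:
        raise ValueError("normalize must be 'trace' or None")
    return covs.mean(axis=0)


def fit_csp(
    trials_a: np.ndarray,
    trials_b: np.ndarray,
    n_pairs: int = 3,
    ridge: float = 1e-10,
    normalize: str | None = "trace",
) -> tuple[np.ndarray, np.ndarray]:
    """CSP filters for one band: generalized eigenvectors of (Ca, Ca+Cb).

    Returns (filters 2m x channels, eigvals 2m) with rows ordered by
    descending eigenvalue; the first m maximize class-a variance, the last
    m maximize class-b variance (row 2m most extreme).  Rank-deficient
    composite covariances are ridge-regularized with a warning.
    """
    if len(trials_a) < 2 or len(trials_b) < 2:
        raise ValueError("need >= 2 trials per class")
    ca = _normalized_covariance(np.asarray(trials_a, dtype=float), normalize)
    cb = _normalized_covariance(np.asarray(trials_b, dtype=float), normalize)
    comp = ca + cb
    try:
        vals, vecs = sla.eigh(ca, comp)
    except sla.LinAlgError:
        warnings.warn("rank-deficient covariance; applying ridge regularization")
        comp = comp + ridge * np.trace(comp) * np.eye(comp.shape[0])
        vals, vecs = sla.eigh(ca, comp)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    n_ch = ca.shape[0]
    if 2 * n_pairs > n_ch:
        raise ValueError("n_pairs too large for channel count")
    sel = np.r_[np.arange(n_pairs), np.arange(n_ch - n_pairs, n_ch)]
    return vecs[:, sel].T.copy(), vals[sel].copy()


def fit_csp_bank(
    trials_a: np.ndarray,
    trials_b: np.ndarray,
    n_pairs: int = 3,
    class_pair: str = "",
    task_slice: slice | None = None,
) -> CSPModel:
    """Fit CSP independently in each band.

    ``trials_*``: trials x channels x bands x samples.  ``task_slice``
    restricts the covariance estimate to the task interval samples.
    """
    sl = task_slice if task_slice is not None else slice(None)
    n_bands = trials_a.shape[2]
    filters, eigvals = [], []
    for b in range(n_bands):
        w, lam = fit_csp(trials_a[:, :, b, sl], trials_b[:, :, b, sl], n_pairs)
        filters.append(w)
        eigvals.append(lam)
    return CSPModel(
        filters=np.stack(filters),
        eigvals=np.stack(eigvals),
        class_pair=class_pair,
        n_pairs=n_pairs,
    )


def task_slice_for(times: np.ndarray, interval_s: tuple[float, float] = TASK_INTERVAL_S) -> slice:
    """Sample slice of an epoch time axis covering the task interval."""
    idx = np.flatnonzero((times >= interval_s[0] - 1e-9) & (times <= interval_s[1] + 1e-9))
    return slice(int(idx[0]), int(idx[-1]) + 1)


def frame_times(
    span_s: tuple[float, float] = FRAME_SPAN_S, rate_hz: float = FRAME_RATE_HZ
) -> np.ndarray:
    """Window end-point times: -1..+8 s at 25 Hz -> 226 frames."""
    n = int(round((span_s[1] - span_s[0]) * rate_hz)) + 1
    return span_s[0] + np.arange(n) / rate_hz


def extract_logvar(
    trials: np.ndarray,
    csp: CSPModel,
    fs_hz: float = 125.0,
    epoch_start_s: float = -2.0,
    win_s: float = 1.0,
    span_s: tuple[float, float] = FRAME_SPAN_S,
    rate_hz: float = FRAME_RATE_HZ,
) -> tuple[np.ndarray, np.ndarray]:
    """Sliding-window log-variance of the CSP-projected trials.

    Returns (features trials x (bands*2m) x frames, frame end times).
    feature(f, t) = log var of the projection over [t - win_s, t]; windows
    with zero variance are clamped to log(1e-12) with a warning.
    """
    trials = np.asarray(trials, dtype=float)
    n_tr, n_ch, n_bands, n_samp = trials.shape
    t_frames = frame_times(span_s, rate_hz)
    win = int(round(win_s * fs_hz))
    step = fs_hz / rate_hz
    ends = np.round((t_frames - epoch_start_s) * fs_hz).astype(int)
    if ends[0] - win < 0 or ends[-1] > n_samp:
        raise ValueError("epoch does not cover the sliding-window span")
    if abs(step - round(step)) > 1e-9:
        raise ValueError("frame rate must divide the sampling rate")

    feats = np.empty((n_tr, n_bands * csp.filters.shape[1], len(t_frames)))
    for b in range(n_bands):
        proj = np.einsum("fc,tcs->tfs", csp.filters[b], trials[:, :, b, :])
        csum = np.concatenate(
            [np.zeros_like(proj[..., :1]), np.cumsum(proj, axis=-1)], axis=-1
        )
        csum2 = np.concatenate(
            [np.zeros_like(proj[..., :1]), np.cumsum(proj**2, axis=-1)], axis=-1
        )
        s1 = csum[..., ends] - csum[..., ends - win]
        s2 = csum2[..., ends] - csum2[..., ends - win]
        var = s2 / win - (s1 / win) ** 2
        var = np.maximum(var, 0.0)
        if np.any(var <= LOGVAR_FLOOR):
            warnings.warn("zero-variance window(s) clamped to the log floor")
        m = csp.filters.shape[1]
        feats[:, b * m : (b + 1) * m, :] = np.log(np.maximum(var, LOGVAR_FLOOR))
    return feats, t_frames


@dataclass
class MIRanking:
    """Mutual-information scores and descending feature ranking.

    ``mi_per_frame``: features x frames (bits); ``mi``: the pooled summary
    per feature used for ranking; ``ranking``: permutation of feature
    indices, best first, ties broken toward the lower index.
    """

    mi_per_frame: np.ndarray
    mi: np.ndarray
    ranking: np.ndarray
    n_bins: int
    summary: str


def quantized_mi(values: np.ndarray, labels: np.ndarray, n_bins: int = 8) -> float:
    """MI (bits) between one feature and a binary label after equal-frequency
    quantization of the feature into ``n_bins`` bins."""
    return float(
        _mi_frames(np.asarray(values, float).reshape(-1, 1, 1), np.asarray(labels), n_bins)[0, 0]
    )


def _mi_frames(feats: np.ndarray, y: np.ndarray, n_bins: int) -> np.ndarray:
    """Vectorized quantized MI for a trials x features x frames tensor."""
    n, f, t = feats.shape
    classes, yc = np.unique(y, return_inverse=True)
    if len(classes) < 2:
        raise ValueError("labels must contain two classes")
    qs = np.linspace(0, 1, n_bins + 1)[1:-1]
    edges = np.quantile(feats, qs, axis=0)  # (n_bins-1, f, t)
    bins = (feats[None] > edges[:, None]).sum(axis=0)  # (n, f, t) in 0..n_bins-1
    ft = (np.arange(f)[:, None] * t + np.arange(t)[None, :])[None]  # (1,f,t)
    flat = (ft * n_bins + bins) * len(classes) + yc[:, None, None]
    counts = np.bincount(flat.ravel(), minlength=f * t * n_bins * len(classes))
    joint = counts.reshape(f, t, n_bins, len(classes)) / n
    pb = joint.sum(axis=3, keepdims=True)
    py = joint.sum(axis=2, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = joint * np.log2(joint / (pb * py))
    return np.nansum(term, axis=(2, 3))


def mi_rank(
    feats: np.ndarray,
    labels: np.ndarray,
    n_bins: int = 8,
    frame_times_s: np.ndarray | None = None,
    task_interval_s: tuple[float, float] = TASK_INTERVAL_S,
    summary: str = "max",
) -> MIRanking:
    """Rank features by quantized MI with the class label.

    MI is estimated per frame from the joint (quantized feature, label)
    histogram and summarized over the task-interval frames (``max`` by
    default, ``mean`` optional) for ranking.
    """
    feats = np.asarray(feats, dtype=float)
    if feats.ndim == 2:
        feats = feats[:, :, None]
    mi_ft = _mi_frames(feats, np.asarray(labels), n_bins)
    if frame_times_s is not None:
        mask = (frame_times_s >= task_interval_s[0] - 1e-9) & (
            frame_times_s <= task_interval_s[1] + 1e-9
        )
    else:
        mask = np.ones(mi_ft.shape[1], dtype=bool)
    pooled = mi_ft[:, mask]
    if summary == "max":
        mi = pooled.max(axis=1)
    elif summary == "mean":
        mi = pooled.mean(axis=1)
    else:
        raise ValueError("summary must be 'max' or 'mean'")
    ranking = np.lexsort((np.arange(len(mi)), -mi))
    return MIRanking(
        mi_per_frame=mi_ft, mi=mi, ranking=ranking, n_bins=n_bins, summary=summary
    )


def select_features(ranking: MIRanking, k: int) -> np.ndarray:
    """Indices of the top-``k`` MI-ranked features (ties -> lower index)."""
    if k > len(ranking.ranking):
        raise ValueError(f"k={k} exceeds feature count {len(ranking.ranking)}")
    if k < 1:
        raise ValueError("k must be >= 1")
    return ranking.ranking[:k].copy()
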