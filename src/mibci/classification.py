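"""Regularized LDA, TSD computation, and time-resolved decoding accuracy.

Each binary classifier (LR, FR, LF, TX) is a shrinkage-regularized linear
discriminant on MI-selected FBCSP log-variance features.  Its continuous
output is the time-varying signed distance (TSD) from the hyperplane,

    TSD_{n,t} = w^F . x_{F,n,t} - a0,

positive for the first class of the pair.  Decoding accuracy (DA) is the
frame-wise correct-rate of held-out trials in a six-fold cross-validation;
the operating feature count k in {6, 10, 14, 18} is the one whose DA peaks
highest in the 2.4-8 s event-related interval of the trial.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import linalg as sla
from sklearn.covariance import ledoit_wolf

from .features import (
    TASK_INTERVAL_S,
    CSPModel,
    MIRanking,
    extract_logvar,
    fit_csp_bank,
    mi_rank,
    select_features,
    task_slice_for,
)
from .preprocessing import RestructuredDataset

PAIRS = ("LR", "FR", "LF", "TX")
FEATURE_COUNTS = (6, 10, 14, 18)


@dataclass
class RLDAModel:
    """Discriminant hyperplane w^F, a0 for one class pair.

    ``polarity`` names the TSD-positive class (first letter of the pair).
    """

    weights: np.ndarray
    bias: float
    gamma: float | str
    class_pair: str = ""
    polarity: str = ""

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("non-finite discriminant weights")


def fit_rlda(
    X: np.ndarray, y: np.ndarray, gamma: float | str = "lw", class_pair: str = ""
) -> RLDAModel:
    """Fit the regularized LDA on feature vectors ``X`` with binary ``y``.

    ``gamma='lw'`` uses Ledoit-Wolf automatic shrinkage of the pooled
    within-class covariance toward a scaled identity; a float in [0, 1]
    applies that shrinkage strength directly (1 = pure scaled identity,
    giving w proportional to the class-mean difference).  The bias places
    the boundary midway between the projected class means (equal priors).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("exactly two classes required")
    pos, neg = classes.max(), classes.min()
    mu1, mu0 = X[y == pos].mean(axis=0), X[y == neg].mean(axis=0)
    centered = np.concatenate([X[y == pos] - mu1, X[y == neg] - mu0])
    d = X.shape[1]
    if gamma == "lw":
        sigma, _ = ledoit_wolf(centered, assume_centered=True)
    else:
        g = float(gamma)
        if not 0.0 <= g <= 1.0:
            raise ValueError("gamma must be in [0, 1] or 'lw'")
        S = centered.T @ centered / len(centered)
        sigma = (1.0 - g) * S + g * (np.trace(S) / d) * np.eye(d)
    try:
        w = sla.solve(sigma, mu1 - mu0, assume_a="pos")
    except (sla.LinAlgError, ValueError) as err:
        raise np.linalg.LinAlgError(
            "singular pooled covariance; increase gamma"
        ) from err
    a0 = float(w @ (mu1 + mu0) / 2.0)
    polarity = class_pair[0] if class_pair else str(pos)
    return RLDAModel(weights=w, bias=a0, gamma=gamma, class_pair=class_pair, polarity=polarity)


def tsd(model: RLDAModel, x: np.ndarray) -> np.ndarray | float:
    """Signed distance of feature vector(s) from the hyperplane.

    Accepts a single vector (returns a float) or an array whose last
    axis is the feature dimension.
    """
    x = np.asarray(x, dtype=float)
    if x.shape[-1] != len(model.weights):
        raise ValueError(
            f"feature dimension {x.shape[-1]} != model dimension {len(model.weights)}"
        )
    out = np.tensordot(x, model.weights, axes=([-1], [0])) - model.bias
    return float(out) if out.ndim == 0 else out


@dataclass
class DAProfile:
    """Time-varying decoding accuracy (%) with its fold spread."""

    times: np.ndarray
    da: np.ndarray  # percent, mean over folds
    std: np.ndarray
    classifier: str = ""
    k: int = 0

    def peak(self, interval_s: tuple[float, float] = TASK_INTERVAL_S) -> tuple[float, float]:
        """(peak DA %, peak time s) within the event-related interval."""
        mask = (self.times >= interval_s[0] - 1e-9) & (self.times <= interval_s[1] + 1e-9)
        i = np.argmax(self.da[mask])
        return float(self.da[mask][i]), float(self.times[mask][i])

    def mean_in(self, interval_s: tuple[float, float]) -> float:
        mask = (self.times >= interval_s[0] - 1e-9) & (self.times <= interval_s[1] + 1e-9)
        return float(self.da[mask].mean())


@dataclass
class ClassifierBundle:
    """One fitted binary classifier: CSP bank + feature selection + RLDA."""

    pair: str
    csp: CSPModel
    ranking: MIRanking
    selected: np.ndarray
    rlda: RLDAModel
    frame_times: np.ndarray

    def tsd_trace(self, trials: np.ndarray) -> np.ndarray:
        """TSD for each trial and frame (trials x frames)."""
        feats, _ = extract_logvar(trials, self.csp)
        return tsd(self.rlda, feats[:, self.selected, :].transpose(0, 2, 1))

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        np.savetxt(out / "csp_filters.csv", self.csp.filters.reshape(-1, self.csp.filters.shape[-1]), delimiter=",")
        np.savetxt(out / "rlda_weights.csv", self.rlda.weights[None], delimiter=",")
        meta = {
            "pair": self.pair,
            "n_pairs": self.csp.n_pairs,
            "n_bands": int(self.csp.filters.shape[0]),
            "n_channels": int(self.csp.filters.shape[-1]),
            "eigvals": self.csp.eigvals.tolist(),
            "mi": self.ranking.mi.tolist(),
            "ranking": self.ranking.ranking.tolist(),
            "mi_bins": self.ranking.n_bins,
            "mi_summary": self.ranking.summary,
            "selected": self.selected.tolist(),
            "bias": self.rlda.bias,
            "gamma": self.rlda.gamma,
            "polarity": self.rlda.polarity,
            "frame_times": self.frame_times.tolist(),
        }
        (out / "meta.json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, in_dir: str | Path) -> "ClassifierBundle":
        out = Path(in_dir)
        meta = json.loads((out / "meta.json").read_text())
        filt = np.loadtxt(out / "csp_filters.csv", delimiter=",")
        filt = filt.reshape(meta["n_bands"], -1, meta["n_channels"])
        weights = np.atleast_1d(np.loadtxt(out / "rlda_weights.csv", delimiter=","))
        csp = CSPModel(
            filters=filt,
            eigvals=np.asarray(meta["eigvals"]),
            class_pair=meta["pair"],
            n_pairs=meta["n_pairs"],
        )
        ranking = MIRanking(
            mi_per_frame=np.zeros((len(meta["mi"]), 0)),
            mi=np.asarray(meta["mi"]),
            ranking=np.asarray(meta["ranking"], dtype=int),
            n_bins=meta["mi_bins"],
            summary=meta["mi_summary"],
        )
        rlda = RLDAModel(
            weights=weights,
            bias=meta["bias"],
            gamma=meta["gamma"],
            class_pair=meta["pair"],
            polarity=meta["polarity"],
        )
        return cls(
            pair=meta["pair"],
            csp=csp,
            ranking=ranking,
            selected=np.asarray(meta["selected"], dtype=int),
            rlda=rlda,
            frame_times=np.asarray(meta["frame_times"]),
        )


def _task_frame_mask(t_frames: np.ndarray) -> np.ndarray:
    return (t_frames >= TASK_INTERVAL_S[0] - 1e-9) & (t_frames <= TASK_INTERVAL_S[1] + 1e-9)


def _fit_stage(
    X: np.ndarray,
    y: np.ndarray,
    times: np.ndarray,
    pair: str,
    k: int,
    n_pairs: int,
    mi_bins: int,
    gamma: float | str,
) -> ClassifierBundle:
    """Fit CSP + MI ranking + RLDA on one training split."""
    task_sl = task_slice_for(times)
    csp = fit_csp_bank(X[y == 1], X[y == 0], n_pairs, class_pair=pair, task_slice=task_sl)
    feats, t_frames = extract_logvar(X, csp)
    ranking = mi_rank(feats, y, n_bins=mi_bins, frame_times_s=t_frames)
    selected = select_features(ranking, k)
    fmask = _task_frame_mask(t_frames)
    train = feats[:, selected, :][:, :, fmask]  # trials x k x frames
    samples = train.transpose(0, 2, 1).reshape(-1, k)
    labels = np.repeat(y, fmask.sum())
    rlda = fit_rlda(samples, labels, gamma=gamma, class_pair=pair)
    return ClassifierBundle(
        pair=pair, csp=csp, ranking=ranking, selected=selected, rlda=rlda, frame_times=t_frames
    )


def fit_pipeline(
    dataset: RestructuredDataset,
    pair: str,
    k: int = 10,
    n_pairs: int = 3,
    mi_bins: int = 8,
    gamma: float | str = "lw",
    balance_seed: int = 0,
) -> ClassifierBundle:
    """Calibrate one binary classifier on a full dataset (no held-out CV)."""
    X, y, _ = dataset.pair_arrays(pair, balance_seed=balance_seed)
    return _fit_stage(X, y, dataset.times, pair, k, n_pairs, mi_bins, gamma)


def evaluate_da(bundle: ClassifierBundle, X: np.ndarray, y: np.ndarray) -> DAProfile:
    """Frame-wise DA of a fitted classifier on held-out trials."""
    traces = bundle.tsd_trace(X)  # trials x frames
    correct = (traces > 0) == (np.asarray(y)[:, None] == 1)
    da = correct.mean(axis=0) * 100.0
    return DAProfile(
        times=bundle.frame_times,
        da=da,
        std=np.zeros_like(da),
        classifier=bundle.pair,
        k=len(bundle.selected),
    )


def _stratified_blocks(y: np.ndarray, n_folds: int, seed: int) -> list[np.ndarray]:
    """Contiguous-in-time per-class blocks, stratified over classes.

    Trials keep their dataset order (chronological within runs), so each
    fold holds temporally contiguous trials of each class, limiting
    train/test leakage from slowly varying background state.
    """
    folds: list[list[int]] = [[] for _ in range(n_folds)]
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        for f, block in enumerate(np.array_split(idx, n_folds)):
            folds[f].extend(block.tolist())
    return [np.asarray(sorted(f)) for f in folds]


def timevarying_da(
    dataset: RestructuredDataset,
    pair: str,
    n_folds: int = 6,
    feature_counts: tuple[int, ...] = FEATURE_COUNTS,
    n_pairs: int = 3,
    mi_bins: int = 8,
    gamma: float | str = "lw",
    seed: int = 0,
) -> tuple[dict[int, DAProfile], int]:
    """Six-fold cross-validated time-varying DA for one classifier.

    For every fold the full stage (CSP, MI ranking, RLDA) is fitted on the
    training split only; held-out trials are classified at every frame.
    Returns one profile per candidate feature count and the selected k*
    (highest event-related DA peak, ties to the smaller k).
    """
    X, y, _ = dataset.pair_arrays(pair, balance_seed=seed)
    for cls in (0, 1):
        if (y == cls).sum() < n_folds:
            raise ValueError("need at least n_folds trials per class")
    folds = _stratified_blocks(y, n_folds, seed)
    per_k_folds: dict[int, list[np.ndarray]] = {k: [] for k in feature_counts}
    kmax = max(feature_counts)
    for test_idx in folds:
        train_mask = np.ones(len(y), dtype=bool)
        train_mask[test_idx] = False
        bundle = _fit_stage(
            X[train_mask], y[train_mask], dataset.times, pair, kmax, n_pairs, mi_bins, gamma
        )
        feats_te, _ = extract_logvar(X[test_idx], bundle.csp)
        for k in feature_counts:
            sel = select_features(bundle.ranking, k)
            sub = feats_te[:, sel, :].transpose(0, 2, 1)
            samples = sub.reshape(-1, k)
            labels = np.repeat(y[test_idx], feats_te.shape[2])
            rl = bundle.rlda if k == kmax else _refit_rlda(bundle, X[train_mask], y[train_mask], sel, gamma, pair)
            traces = tsd(rl, sub)
            correct = (traces > 0) == (y[test_idx][:, None] == 1)
            per_k_folds[k].append(correct.mean(axis=0) * 100.0)
    profiles = {}
    t_frames = None
    for k in feature_counts:
        stack = np.stack(per_k_folds[k])
        if t_frames is None:
            from .features import frame_times

            t_frames = frame_times()
        profiles[k] = DAProfile(
            times=t_frames,
            da=stack.mean(axis=0),
            std=stack.std(axis=0),
            classifier=pair,
            k=k,
        )
    return profiles, select_feature_count(profiles)


def _refit_rlda(
    bundle: ClassifierBundle,
    X_train: np.ndarray,
    y_train: np.ndarray,
    selected: np.ndarray,
    gamma: float | str,
    pair: str,
) -> RLDAModel:
    feats, t_frames = extract_logvar(X_train, bundle.csp)
    fmask = _task_frame_mask(t_frames)
    train = feats[:, selected, :][:, :, fmask]
    samples = train.transpose(0, 2, 1).reshape(-1, len(selected))
    labels = np.repeat(y_train, fmask.sum())
    return fit_rlda(samples, labels, gamma=gamma, class_pair=pair)


def select_feature_count(profiles: dict[int, DAProfile]) -> int:
    """k* = argmax of the event-related DA peak; ties -> smaller k."""
    if not profiles:
        raise ValueError("no candidate profiles")
    best_k, best_peak = None, -np.inf
    for k in sorted(profiles):
        peak, _ = profiles[k].peak()
        if peak > best_peak + 1e-12:
            best_k, best_peak = k, peak
    return best_k


def pool_datasets(datasets: list[RestructuredDataset]) -> RestructuredDataset:
    """Concatenate restructured datasets from multiple sessions."""
    ref = datasets[0]
    return RestructuredDataset(
        data=np.concatenate([d.data for d in datasets]),
        times=ref.times,
        channels=ref.channels,
        bands=ref.bands,
        labels=np.concatenate([d.labels for d in datasets]),
        run_ids=np.concatenate([d.run_ids for d in datasets]),
        session_ids=np.concatenate([d.session_ids for d in datasets]),
    )


def search_calibration_sessions(
    sessions: dict[int, RestructuredDataset],
    holdout: list[int],
    subset_sizes: tuple[int, ...] = (2, 3, 4),
    pairs: tuple[str, ...] = PAIRS,
    k: int = 10,
    gamma: float | str = "lw",
    balance_seed: int = 0,
) -> tuple[tuple[int, ...], list[dict]]:
    """Find the calibration-session subset with the best cross-session DA.

    Every subset of the candidate (non-holdout) sessions of an admissible
    size is pooled and calibrated; its score is the mean over classifiers
    and holdout sessions of the held-out event-related DA peak.  Returns
    the winning subset and the full ranking report.
    """
    candidates = sorted(s for s in sessions if s not in holdout)
    if set(holdout) & set(candidates):
        raise ValueError("holdout sessions must be disjoint from candidates")
    if not holdout:
        raise ValueError("at least one holdout session required")
    if len(candidates) < min(subset_sizes):
        raise ValueError("too few candidate sessions")
    report = []
    for size in subset_sizes:
        for subset in itertools.combinations(candidates, size):
            pooled = pool_datasets([sessions[s] for s in subset])
            peaks = []
            for pair in pairs:
                bundle = fit_pipeline(pooled, pair, k=k, gamma=gamma, balance_seed=balance_seed)
                for h in holdout:
                    Xh, yh, _ = sessions[h].pair_arrays(pair, balance_seed=balance_seed)
                    prof = evaluate_da(bundle, Xh, yh)
                    peaks.append(prof.peak()[0])
            report.append({"subset": subset, "mean_holdout_peak_da": float(np.mean(peaks))})
    report.sort(key=lambda r: (-r["mean_holdout_peak_da"], r["subset"]))
    return report[0]["subset"], report
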