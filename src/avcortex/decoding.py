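"""Pseudo-population decoding with a linear maximum-margin classifier.

Neurons recorded in separate sessions are combined into a pseudo
population: for each resample, a fixed number of correct trials per cue
(default 30) is drawn per neuron and concatenated across neurons with
random within-class pairing, destroying any (here absent) noise
correlations.  Spike counts are taken in a sliding window (default
100 ms, stepped 10 ms); a linear-kernel SVM with unit cost is trained
and tested independently per window under stratified 10-fold
cross-validation, the resampling is repeated (default 100 times), and
chance level is estimated by shuffling trial labels (default 1000
iterations) at the most informative window.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .io_model import SessionConfig
from .selectivity import _correct_trials

Sessions = "list[tuple[pd.DataFrame, pd.DataFrame]]"


def _as_sessions(sessions):
    if isinstance(sessions, tuple) and len(sessions) == 2 and isinstance(
            sessions[0], pd.DataFrame):
        return [sessions]
    return list(sessions)


def _binned(spikes_one: pd.DataFrame, trial_ids: np.ndarray,
            edges: np.ndarray) -> np.ndarray:
    """Counts matrix (trials x bins) for the given trials of one neuron."""
    pos = {tid: i for i, tid in enumerate(trial_ids)}
    m = spikes_one["trial_id"].isin(pos)
    rows = spikes_one.loc[m, "trial_id"].map(pos).to_numpy()
    t = spikes_one.loc[m, "spike_time_ms"].to_numpy()
    mat, _, _ = np.histogram2d(
        rows, t, bins=[np.arange(len(trial_ids) + 1) - 0.5, edges])
    return mat


def _sliding(mat: np.ndarray, k: int) -> np.ndarray:
    """Sum of k consecutive bins, stepped one bin (trials x windows)."""
    c = np.concatenate(
        [np.zeros((mat.shape[0], 1)), np.cumsum(mat, axis=1)], axis=1)
    return c[:, k:] - c[:, :-k]


def _prepare(sessions, class_a: str, class_b: str, config: SessionConfig,
             t_range=None, strict: bool = True):
    """Per-neuron sliding-window count matrices for eligible neurons.

    A neuron is eligible when it has more than ``decode_trials_per_cue``
    correct trials for both cues (``strict=False`` relaxes to >=).
    Returns (neuron data list, window centers in ms).
    """
    lo, hi = t_range if t_range is not None else config.epoch_ms
    step = config.decode_step_ms
    k = int(round(config.decode_window_ms / step))
    edges = np.arange(lo, hi + step / 2, step)
    starts = edges[: len(edges) - k]
    centers = starts + config.decode_window_ms / 2.0
    need = config.decode_trials_per_cue
    data = []
    for s_idx, (spikes, trials) in enumerate(_as_sessions(sessions)):
        for cue in (class_a, class_b):
            if not (trials["cue"] == cue).any():
                raise ValueError(f"cue {cue!r} absent from session {s_idx}")
        ids_a = _correct_trials(trials, class_a).to_numpy()
        ids_b = _correct_trials(trials, class_b).to_numpy()
        for nid, grp in spikes.groupby("neuron_id", sort=True):
            ok = (len(ids_a) > need and len(ids_b) > need) if strict else (
                len(ids_a) >= need and len(ids_b) >= need)
            if not ok:
                continue
            data.append({
                "session": s_idx, "neuron_id": nid,
                "a": _sliding(_binned(grp, ids_a, edges), k),
                "b": _sliding(_binned(grp, ids_b, edges), k),
                "ids_a": ids_a, "ids_b": ids_b})
    if not data:
        raise ValueError(
            f"no neuron has more than {need} correct trials for both "
            f"{class_a!r} and {class_b!r}")
    return data, centers


@dataclasses.dataclass
class PseudoPopulation:
    """One resample's trial-by-neuron-by-window count array."""

    X: np.ndarray                 # M x N x T
    y: np.ndarray                 # M class labels (cue names)
    window_centers_ms: np.ndarray
    neurons: list                 # (session, neuron_id) per column
    provenance: np.ndarray        # M x N source trial ids


def _draw(data, class_a, class_b, config, rng) -> PseudoPopulation:
    n_per = config.decode_trials_per_cue
    cols_a, cols_b, prov_a, prov_b = [], [], [], []
    for d in data:
        ia = rng.choice(len(d["ids_a"]), size=n_per, replace=False)
        ib = rng.choice(len(d["ids_b"]), size=n_per, replace=False)
        cols_a.append(d["a"][ia])
        cols_b.append(d["b"][ib])
        prov_a.append(d["ids_a"][ia])
        prov_b.append(d["ids_b"][ib])
    X = np.concatenate([np.stack(cols_a, axis=1), np.stack(cols_b, axis=1)])
    y = np.array([class_a] * n_per + [class_b] * n_per)
    prov = np.concatenate([np.stack(prov_a, axis=1), np.stack(prov_b, axis=1)])
    # fetch centers lazily: caller attaches them
    return X, y, prov


def build_pseudopopulation(sessions, class_a: str, class_b: str,
                           config: SessionConfig | None = None,
                           rng: np.random.Generator | int | None = None,
                           t_range=None, strict: bool = True
                           ) -> PseudoPopulation:
    """Assemble one pseudo-population resample."""
    config = config or SessionConfig()
    rng = np.random.default_rng(rng)
    data, centers = _prepare(sessions, class_a, class_b, config, t_range, strict)
    X, y, prov = _draw(data, class_a, class_b, config, rng)
    return PseudoPopulation(
        X=X, y=y, window_centers_ms=centers,
        neurons=[(d["session"], d["neuron_id"]) for d in data],
        provenance=prov)


def _cv_accuracy(X: np.ndarray, y: np.ndarray, folds: int,
                 rng: np.random.Generator) -> float:
    """Stratified k-fold accuracy of a unit-cost linear SVM."""
    skf = StratifiedKFold(n_splits=folds, shuffle=True,
                          random_state=int(rng.integers(2**31)))
    correct = 0
    for tr, te in skf.split(X, y):
        clf = SVC(kernel="linear", C=1.0)
        clf.fit(X[tr], y[tr])
        correct += int((clf.predict(X[te]) == y[te]).sum())
    return correct / len(y)


@dataclasses.dataclass
class DecodingResult:
    class_a: str
    class_b: str
    window_centers_ms: np.ndarray
    mean_accuracy: np.ndarray          # per window, over resamples
    sd_accuracy: np.ndarray
    n_resamples: int
    n_neurons: int
    null_window_ms: float              # window where the null was computed
    null_mean: float
    null_band: tuple[float, float]     # 2.5th-97.5th percentile of shuffles
    null_accuracies: np.ndarray


def decode_time_resolved(sessions, class_a: str, class_b: str,
                         config: SessionConfig | None = None,
                         rng: np.random.Generator | int | None = None,
                         t_range=None, strict: bool = True
                         ) -> DecodingResult:
    """Cross-validated accuracy per sliding window, with a shuffled null.

    Per resample a fresh pseudo population is drawn and a linear SVM is
    trained and tested independently for each window.  The shuffled
    null permutes trial labels at the single most informative window
    (the per-window null is prohibitively costly and chance level is
    window-independent for balanced classes).
    """
    config = config or SessionConfig()
    rng = np.random.default_rng(rng)
    data, centers = _prepare(sessions, class_a, class_b, config, t_range, strict)
    T = len(centers)
    acc = np.empty((config.decode_resamples, T))
    for r in range(config.decode_resamples):
        X, y, _ = _draw(data, class_a, class_b, config, rng)
        for t in range(T):
            acc[r, t] = _cv_accuracy(X[:, :, t], y, config.decode_folds, rng)
    mean = acc.mean(axis=0)
    best = int(np.argmax(mean))
    Xb, yb, _ = _draw(data, class_a, class_b, config, rng)
    null = np.empty(config.decode_shuffles)
    for i in range(config.decode_shuffles):
        null[i] = _cv_accuracy(Xb[:, :, best], rng.permutation(yb),
                               config.decode_folds, rng)
    return DecodingResult(
        class_a=class_a, class_b=class_b, window_centers_ms=centers,
        mean_accuracy=mean, sd_accuracy=acc.std(axis=0, ddof=0),
        n_resamples=config.decode_resamples, n_neurons=len(data),
        null_window_ms=float(centers[best]), null_mean=float(null.mean()),
        null_band=(float(np.percentile(null, 2.5)),
                   float(np.percentile(null, 97.5))),
        null_accuracies=null)


def first_crossing_time(result: DecodingResult,
                        level: float = 0.9) -> float | None:
    """Earliest window center whose mean accuracy reaches ``level``."""
    above = np.flatnonzero(result.mean_accuracy >= level)
    if len(above) == 0:
        return None
    return float(result.window_centers_ms[above[0]])


def pairwise_decoding_matrix(sessions, cue_set,
                             window_ms: tuple[float, float] = (0.0, 150.0),
                             config: SessionConfig | None = None,
                             rng: np.random.Generator | int | None = None,
                             strict: bool = True) -> pd.DataFrame:
    """Single-window decoding accuracy for every unordered cue pair.

    Returns a symmetric cue-by-cue DataFrame with 0.5 on the diagonal.
    """
    config = config or SessionConfig()
    rng = np.random.default_rng(rng)
    cue_set = list(cue_set)
    sess = _as_sessions(sessions)
    present = set()
    for _, trials in sess:
        present |= set(trials["cue"].unique())
    missing = [c for c in cue_set if c not in present]
    if missing:
        raise ValueError(f"cues absent from sessions: {missing}")
    # one-window config: reuse the sliding machinery with a single window
    one = dataclasses.replace(
        config, decode_window_ms=window_ms[1] - window_ms[0],
        decode_step_ms=window_ms[1] - window_ms[0])
    mat = pd.DataFrame(0.5, index=cue_set, columns=cue_set, dtype=float)
    for i, ca in enumerate(cue_set):
        for cb in cue_set[i + 1:]:
            data, _ = _prepare(sess, ca, cb, one, t_range=window_ms,
                               strict=strict)
            accs = np.empty(config.decode_resamples)
            for r in range(config.decode_resamples):
                X, y, _ = _draw(data, ca, cb, one, rng)
                accs[r] = _cv_accuracy(X[:, :, 0], y, config.decode_folds, rng)
            mat.loc[ca, cb] = mat.loc[cb, ca] = float(accs.mean())
    return mat
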