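"""ROC-based cue selectivity and the multisensory interactive index.

The selectivity index between two cue conditions is ``SI = 2*(auROC -
0.5)``, in [-1, 1]: 0 means the response distributions are
indistinguishable, +1 (-1) that cue-A responses are always above
(below) cue-B responses.  The multisensory interactive index (MSI)
applies the same machinery with cue A = the audiovisual pairing and cue
B = the stronger of its two unisensory components; MSI > 0 denotes
multisensory enhancement, MSI < 0 inhibition.

Two auROC estimators are provided.  ``exact_rank`` is the exact
Mann-Whitney statistic, (wins + 0.5*ties) over all cross pairs, and is
the default.  ``discretized12`` reproduces the classical construction:
12 linearly spaced criterion levels spanning the pooled range of firing
rates; at each criterion the fraction of cue-A trials exceeding it
(strictly) is plotted against the fraction of cue-B trials exceeding
it, and the area is taken by the trapezoid rule with (0,0) and (1,1)
anchors.  Significance comes from a two-tailed permutation test that
reassigns trial labels and recomputes the index; p-values use the
(r+1)/(n+1) estimator so they are never exactly zero.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats

from .io_model import PAIRING_COMPONENTS, SessionConfig
from .psth import count_in_window


# ---------------------------------------------------------------- auROC

def auroc_exact(a: np.ndarray, b: np.ndarray) -> float:
    """(wins + 0.5*ties) / (n_a * n_b) over all cross pairs, via ranks."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n_a, n_b = len(a), len(b)
    ranks = stats.rankdata(np.concatenate([a, b]))
    r_a = ranks[:n_a].sum()
    u = r_a - n_a * (n_a + 1) / 2.0
    return float(u / (n_a * n_b))


def auroc_discretized(a: np.ndarray, b: np.ndarray, n_levels: int = 12) -> float:
    """Criterion-level ROC with linearly spaced thresholds over the pooled range."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    pooled = np.concatenate([a, b])
    lo, hi = pooled.min(), pooled.max()
    if hi == lo:
        return 0.5
    crit = np.linspace(lo, hi, n_levels)
    # strict exceedance; descending criteria give monotone increasing fractions
    tpr = (a[:, None] > crit[None, :]).mean(axis=0)[::-1]
    fpr = (b[:, None] > crit[None, :]).mean(axis=0)[::-1]
    fpr = np.concatenate([[0.0], fpr, [1.0]])
    tpr = np.concatenate([[0.0], tpr, [1.0]])
    order = np.argsort(fpr, kind="stable")
    return float(np.trapezoid(tpr[order], fpr[order]))


def compute_auroc(samples_a, samples_b, method: str = "exact_rank") -> float:
    """auROC between two per-trial response samples.

    Identical pooled values give 0.5 by convention.
    """
    a = np.asarray(samples_a, dtype=float)
    b = np.asarray(samples_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 samples per side")
    if method == "exact_rank":
        return auroc_exact(a, b)
    if method == "discretized12":
        return auroc_discretized(a, b)
    raise ValueError(f"unknown auROC method {method!r}")


# --------------------------------------------- permutation significance

def _null_si_exact(pooled: np.ndarray, n_a: int, n_perm: int,
                   rng: np.random.Generator) -> np.ndarray:
    """Vectorized permutation null of SI for the rank-based estimator.

    Pooled ranks are invariant under label reassignment, so each
    permutation only needs the rank-sum of a random size-n_a subset.
    """
    n = len(pooled)
    n_b = n - n_a
    ranks = stats.rankdata(pooled)
    # random subset of size n_a per permutation via argpartition of noise
    noise = rng.random((n_perm, n))
    idx = np.argpartition(noise, n_a - 1, axis=1)[:, :n_a]
    r_a = ranks[idx].sum(axis=1)
    u = r_a - n_a * (n_a + 1) / 2.0
    return 2.0 * (u / (n_a * n_b) - 0.5)


def permutation_si_test(samples_a, samples_b, n_perm: int = 2000,
                        rng: np.random.Generator | int | None = None,
                        method: str = "exact_rank"
                        ) -> tuple[float, float, np.ndarray]:
    """Observed SI, two-tailed permutation p-value, and the null sample."""
    rng = np.random.default_rng(rng)
    a = np.asarray(samples_a, dtype=float)
    b = np.asarray(samples_b, dtype=float)
    obs = 2.0 * (compute_auroc(a, b, method) - 0.5)
    pooled = np.concatenate([a, b])
    if method == "exact_rank":
        null = _null_si_exact(pooled, len(a), n_perm, rng)
    else:
        null = np.empty(n_perm)
        n_a = len(a)
        for i in range(n_perm):
            perm = rng.permutation(pooled)
            null[i] = 2.0 * (auroc_discretized(perm[:n_a], perm[n_a:]) - 0.5)
    hi = int(np.sum(null >= obs))
    lo = int(np.sum(null <= obs))
    p = min(1.0, 2.0 * (min(hi, lo) + 1) / (n_perm + 1))
    return float(obs), float(p), null


# ------------------------------------------------------------- results

@dataclasses.dataclass
class SelectivityResult:
    cue_a: str
    cue_b: str
    auroc: float
    si: float
    p_value: float
    n_permutations: int
    significant: bool
    window_ms: tuple[float, float]
    method: str
    n_a: int
    n_b: int
    degenerate: bool = False


@dataclasses.dataclass
class MSIResult:
    pairing: str
    stronger_unisensory: str          # "auditory" or "visual"
    stronger_cue: str
    msi: float
    p_value: float
    n_permutations: int
    significant: bool
    classification: str               # enhanced / inhibited / null
    window_ms: tuple[float, float]
    n_multi: int
    n_uni: int


def _correct_trials(trials: pd.DataFrame, cue: str) -> pd.Series:
    """Trial ids of correct trials for a cue ('either' trials count)."""
    m = (trials["cue"] == cue) & (trials["correct"].isin([True, "either"]))
    return trials.loc[m, "trial_id"]


def _window_counts(spikes_one, trials, cue, window, config, trial_ids=None):
    sel = _correct_trials(trials, cue) if trial_ids is None else trial_ids
    if len(sel) < config.min_trials:
        raise ValueError(
            f"cue {cue!r}: {len(sel)} usable trials < minimum {config.min_trials}")
    return count_in_window(spikes_one, sel, window).to_numpy()


def selectivity_index(spikes_one: pd.DataFrame, trials: pd.DataFrame,
                      cue_a: str, cue_b: str,
                      window_ms: tuple[float, float] | None = None,
                      config: SessionConfig | None = None,
                      rng: np.random.Generator | int | None = None
                      ) -> SelectivityResult:
    """SI between two cues on correct-trial analysis-window counts."""
    config = config or SessionConfig()
    window = window_ms or config.analysis_window_ms
    a = _window_counts(spikes_one, trials, cue_a, window, config)
    b = _window_counts(spikes_one, trials, cue_b, window, config)
    degenerate = len(np.unique(np.concatenate([a, b]))) == 1
    si, p, _ = permutation_si_test(a, b, config.n_permutations, rng,
                                   config.auroc_method)
    return SelectivityResult(
        cue_a=cue_a, cue_b=cue_b, auroc=si / 2 + 0.5, si=si, p_value=p,
        n_permutations=config.n_permutations, significant=p < config.alpha,
        window_ms=tuple(window), method=config.auroc_method,
        n_a=len(a), n_b=len(b), degenerate=degenerate)


def stronger_unisensory_cue(spikes_one, trials, pairing,
                            window_ms=None, config=None,
                            trial_ids_by_cue=None) -> tuple[str, str]:
    """Component cue with the higher mean analysis-window rate.

    Ties break toward the auditory component.  Returns (modality, cue).
    """
    config = config or SessionConfig()
    window = window_ms or config.analysis_window_ms
    a_cue, v_cue = PAIRING_COMPONENTS[pairing]
    ids = trial_ids_by_cue or {}
    a = _window_counts(spikes_one, trials, a_cue, window, config, ids.get(a_cue))
    v = _window_counts(spikes_one, trials, v_cue, window, config, ids.get(v_cue))
    if a.mean() >= v.mean():
        return "auditory", a_cue
    return "visual", v_cue


def msi(spikes_one: pd.DataFrame, trials: pd.DataFrame, pairing: str,
        window_ms: tuple[float, float] | None = None,
        config: SessionConfig | None = None,
        rng: np.random.Generator | int | None = None,
        trial_ids_by_cue: dict | None = None,
        stronger: tuple[str, str] | None = None) -> MSIResult:
    """Multisensory interactive index for one audiovisual pairing.

    Compares the pairing's analysis-window responses against the
    stronger unisensory component by the same ROC + permutation
    machinery; labels are permuted between these two conditions only.
    """
    config = config or SessionConfig()
    window = window_ms or config.analysis_window_ms
    ids = trial_ids_by_cue or {}
    if stronger is None:
        stronger = stronger_unisensory_cue(spikes_one, trials, pairing,
                                           window, config, trial_ids_by_cue)
    modality, uni_cue = stronger
    av = _window_counts(spikes_one, trials, pairing, window, config,
                        ids.get(pairing))
    uni = _window_counts(spikes_one, trials, uni_cue, window, config,
                         ids.get(uni_cue))
    value, p, _ = permutation_si_test(av, uni, config.n_permutations, rng,
                                      config.auroc_method)
    if p < config.alpha and value > 0:
        cls = "enhanced"
    elif p < config.alpha and value < 0:
        cls = "inhibited"
    else:
        cls = "null"
    return MSIResult(pairing=pairing, stronger_unisensory=modality,
                     stronger_cue=uni_cue, msi=value, p_value=p,
                     n_permutations=config.n_permutations,
                     significant=p < config.alpha, classification=cls,
                     window_ms=tuple(window), n_multi=len(av), n_uni=len(uni))


def msi_by_choice(spikes_one: pd.DataFrame, trials: pd.DataFrame, pairing: str,
                  config: SessionConfig | None = None,
                  rng: np.random.Generator | int | None = None,
                  window_ms: tuple[float, float] | None = None
                  ) -> tuple[MSIResult, MSIResult]:
    """MSI computed separately on correct- and incorrect-choice trials.

    Requires the configured minimum (default 9) trials per choice for
    the pairing and both component cues; otherwise the neuron is
    excluded with a ValueError stating the reason.  The stronger
    unisensory component is fixed from correct trials and reused for
    the incorrect subset so both indices compare the same conditions.
    """
    config = config or SessionConfig()
    rng = np.random.default_rng(rng)
    window = window_ms or config.analysis_window_ms
    a_cue, v_cue = PAIRING_COMPONENTS[pairing]
    subsets = {}
    for label, ok in (("correct", True), ("incorrect", False)):
        ids = {}
        for cue in (pairing, a_cue, v_cue):
            m = (trials["cue"] == cue) & (trials["correct"] == ok)
            sel = trials.loc[m, "trial_id"]
            if len(sel) < config.min_trials_per_choice:
                raise ValueError(
                    f"excluded: cue {cue!r} has {len(sel)} {label} trials "
                    f"< minimum {config.min_trials_per_choice}")
            ids[cue] = sel
        subsets[label] = ids
    stronger = stronger_unisensory_cue(
        spikes_one, trials, pairing, window, config,
        trial_ids_by_cue=subsets["correct"])
    res = {}
    for label in ("correct", "incorrect"):
        res[label] = msi(spikes_one, trials, pairing, window, config, rng,
                         trial_ids_by_cue=subsets[label], stronger=stronger)
    return res["correct"], res["incorrect"]


def delta_msi_vs_delta_selectivity(
        msi_pref, msi_null, si_multi, si_aud
) -> tuple[np.ndarray, float, float]:
    """Per-neuron change in MSI against change in selectivity.

    x = MSI(preferred pairing) - MSI(null pairing); y = multisensory SI
    - auditory SI.  Returns the (x, y) pairs, Pearson r and its p-value.
    """
    x = np.asarray(msi_pref, dtype=float) - np.asarray(msi_null, dtype=float)
    y = np.asarray(si_multi, dtype=float) - np.asarray(si_aud, dtype=float)
    if len(x) != len(y):
        raise ValueError("mismatched lengths")
    if len(x) < 3:
        raise ValueError("need at least 3 neurons")
    r, p = stats.pearsonr(x, y)
    return np.column_stack([x, y]), float(r), float(p)
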