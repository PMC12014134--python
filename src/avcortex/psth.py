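"""Window counting, PSTHs, baseline normalization, responsiveness.

Rates are in spikes/s throughout; windows are half-open ``[start, end)``
milliseconds relative to cue onset.  PSTHs are binned at the configured
resolution (default 10 ms), smoothed with a Gaussian kernel (default
sigma 50 ms, truncated at three sigma and renormalized at the edges so
the smoothed curve preserves the spike-count integral), and converted
to a Z-score against the mean and SD of the 400 ms pre-cue baseline.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats

from .io_model import (
    AUDITORY_CUES,
    MATCHED_PAIRINGS,
    MULTISENSORY_CUES,
    SessionConfig,
    VISUAL_CUES,
)

CATEGORIES = ("A-only", "V-only", "AV(both)", "AV-only", "unresponsive")


def window_rate(count, window_ms) -> float:
    """Convert a spike count in a window to a rate in spikes/s."""
    start, end = window_ms
    return np.asarray(count) * 1000.0 / (end - start)


def count_in_window(spikes: pd.DataFrame, trial_ids, window_ms) -> pd.Series:
    """Spike count per trial within a half-open window.

    ``spikes`` is typically one neuron's rows.  Trials with no spikes in
    the window get an explicit zero.  Raises on an empty selection.
    """
    trial_ids = list(trial_ids)
    if not trial_ids:
        raise ValueError("empty trial selection")
    start, end = window_ms
    m = (spikes["spike_time_ms"] >= start) & (spikes["spike_time_ms"] < end)
    counts = spikes.loc[m, "trial_id"].value_counts()
    return counts.reindex(trial_ids, fill_value=0).astype(int)


def neuron_spikes(spikes: pd.DataFrame, neuron_id: str) -> pd.DataFrame:
    """Rows of one neuron (empty frame with the right columns if absent)."""
    return spikes[spikes["neuron_id"] == str(neuron_id)]


def mean_rate(spikes_one: pd.DataFrame, trials: pd.DataFrame,
              config: SessionConfig) -> float:
    """Whole-epoch mean firing rate of one neuron across all trials."""
    lo, hi = config.epoch_ms
    n_trials = len(trials)
    if n_trials == 0:
        raise ValueError("empty trial table")
    return len(spikes_one) * 1000.0 / ((hi - lo) * n_trials)


def gaussian_smooth(values: np.ndarray, sigma_bins: float) -> np.ndarray:
    """Gaussian smoothing with a +/-3 sigma kernel, edge-renormalized."""
    if sigma_bins <= 0:
        return np.asarray(values, dtype=float)
    half = int(np.ceil(3 * sigma_bins))
    x = np.arange(-half, half + 1)
    kernel = np.exp(-0.5 * (x / sigma_bins) ** 2)
    kernel /= kernel.sum()
    num = np.convolve(values, kernel, mode="same")
    den = np.convolve(np.ones_like(values, dtype=float), kernel, mode="same")
    return num / den


@dataclasses.dataclass
class PSTH:
    """Trial-averaged firing rate of one neuron for one cue."""

    cue: str
    bin_edges_ms: np.ndarray            # len T+1, uniform
    rate: np.ndarray                    # spikes/s per bin
    smoothed: np.ndarray
    z_rate: np.ndarray | None           # None when baseline SD is 0
    n_trials: int
    baseline_mean: float
    baseline_sd: float
    degenerate: bool = False

    @property
    def bin_centers_ms(self) -> np.ndarray:
        return 0.5 * (self.bin_edges_ms[:-1] + self.bin_edges_ms[1:])


def make_psth(spikes_one: pd.DataFrame, trials: pd.DataFrame, cue: str,
              config: SessionConfig | None = None) -> PSTH:
    """Binned, smoothed, baseline-normalized PSTH for one neuron and cue."""
    config = config or SessionConfig()
    sel = trials.loc[trials["cue"] == cue, "trial_id"]
    if len(sel) == 0:
        raise ValueError(f"no trials for cue {cue!r}")
    lo, hi = config.epoch_ms
    edges = np.arange(lo, hi + config.bin_ms / 2, config.bin_ms)
    m = spikes_one["trial_id"].isin(set(sel))
    hist, _ = np.histogram(spikes_one.loc[m, "spike_time_ms"], bins=edges)
    rate = hist * 1000.0 / (config.bin_ms * len(sel))
    smoothed = gaussian_smooth(rate, config.smooth_sigma_ms / config.bin_ms)
    b0, b1 = config.baseline_window_ms
    centers = 0.5 * (edges[:-1] + edges[1:])
    base = smoothed[(centers >= b0) & (centers < b1)]
    b_mean, b_sd = float(base.mean()), float(base.std(ddof=0))
    if b_sd > 0:
        z = (smoothed - b_mean) / b_sd
        degenerate = False
    else:
        z = None
        degenerate = True
    return PSTH(cue=cue, bin_edges_ms=edges, rate=rate, smoothed=smoothed,
                z_rate=z, n_trials=int(len(sel)), baseline_mean=b_mean,
                baseline_sd=b_sd, degenerate=degenerate)


@dataclasses.dataclass
class ResponsivenessCall:
    """Per-cue responsiveness of one neuron and its response category.

    A cue counts as driving the neuron only if the baseline-subtracted
    evoked rate exceeds the threshold (default 2 spikes/s in the 0-300 ms
    window) AND the per-trial window rates are significantly above the
    per-trial baseline rates (one-sided Wilcoxon signed-rank, p < alpha).
    """

    evoked_rate: dict        # cue -> mean evoked rate above baseline (spikes/s)
    p_value: dict            # cue -> signed-rank p (nan if degenerate)
    responsive: dict         # cue -> bool
    category: str
    degenerate: dict         # cue -> True when all paired differences were 0


def classify_responsiveness(spikes_one: pd.DataFrame, trials: pd.DataFrame,
                            config: SessionConfig | None = None,
                            cues: tuple[str, ...] | None = None
                            ) -> ResponsivenessCall:
    """Test each cue's evoked response against baseline and categorize."""
    config = config or SessionConfig()
    if cues is None:
        cues = tuple(c for c in AUDITORY_CUES + VISUAL_CUES + MATCHED_PAIRINGS
                     if (trials["cue"] == c).any())
    evoked, pvals, resp, degen = {}, {}, {}, {}
    w = config.responsiveness_window_ms
    b = config.baseline_window_ms
    for cue in cues:
        sel = trials.loc[trials["cue"] == cue, "trial_id"]
        if len(sel) < config.min_trials:
            raise ValueError(f"fewer than {config.min_trials} trials for cue {cue!r}")
        ev = window_rate(count_in_window(spikes_one, sel, w).to_numpy(), w)
        ba = window_rate(count_in_window(spikes_one, sel, b).to_numpy(), b)
        diff = ev - ba
        evoked[cue] = float(diff.mean())
        degen[cue] = bool(np.all(diff == 0))
        if degen[cue]:
            pvals[cue] = float("nan")
            resp[cue] = False
            continue
        p = float(stats.wilcoxon(ev, ba, alternative="greater",
                                 zero_method="wilcox").pvalue)
        pvals[cue] = p
        resp[cue] = (evoked[cue] > config.responsive_rate_threshold_hz
                     and p < config.alpha)
    aud = any(resp.get(c, False) for c in AUDITORY_CUES)
    vis = any(resp.get(c, False) for c in VISUAL_CUES)
    multi = any(resp.get(c, False) for c in MULTISENSORY_CUES)
    if aud and vis:
        cat = "AV(both)"
    elif aud:
        cat = "A-only"
    elif vis:
        cat = "V-only"
    elif multi:
        cat = "AV-only"
    else:
        cat = "unresponsive"
    return ResponsivenessCall(evoked_rate=evoked, p_value=pvals,
                              responsive=resp, category=cat, degenerate=degen)


def psth_table(spikes_one: pd.DataFrame, trials: pd.DataFrame,
               config: SessionConfig | None = None) -> pd.DataFrame:
    """Long-format PSTH table (bin, cue, rate, smoothed, z) for one neuron."""
    config = config or SessionConfig()
    frames = []
    for cue in trials["cue"].unique():
        p = make_psth(spikes_one, trials, cue, config)
        frames.append(pd.DataFrame({
            "bin_center_ms": p.bin_centers_ms, "cue": cue, "rate": p.rate,
            "smoothed": p.smoothed,
            "z": p.z_rate if p.z_rate is not None else np.nan}))
    return pd.concat(frames, ignore_index=True)
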