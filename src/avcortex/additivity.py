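"""Bootstrap test of the additive model of multisensory combination.

The additive model predicts the multisensory response as the sum of the
two unisensory responses (optionally scaled by a coefficient).  A
benchmark distribution of predicted responses is built by repeatedly
resampling trials from the auditory and visual conditions, averaging
each draw, and summing the two means; the observed multisensory mean is
expressed as a Z-score against that distribution.  The Z denominator
combines the benchmark SD with the observed mean's own standard error:
both the prediction and the observation carry sampling noise, and
omitting the latter would inflate the score by sqrt(2) under true
additivity.  With the combined denominator the Z is approximately
standard normal for an additive neuron, so |Z| >= 1.96 flags a genuine
departure: positive = superadditive, negative = subadditive.

Responses are baseline-subtracted analysis-window rates on correct
trials, so the additive model is applied to evoked activity and the
baseline is not double-counted.  Resampling draws min(n_AV, pool)
trials per modality without replacement; when the draw would consume
the whole pool (which would make every draw identical and the
benchmark degenerate) the draw is made with replacement instead — the
ordinary bootstrap.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .io_model import PAIRING_COMPONENTS, SessionConfig
from .psth import count_in_window, window_rate
from .selectivity import _correct_trials

Z_CRIT = 1.96


@dataclasses.dataclass
class AdditivityResult:
    pairing: str
    observed_mean: float              # evoked spikes/s in the analysis window
    predicted_mean: float
    predicted_sd: float
    n_bootstrap: int
    coefficient: float
    z_score: float | None             # None when the benchmark is degenerate
    classification: str               # superadditive / additive / subadditive / degenerate
    scaling_coefficient: float | None  # observed / (A + V); None if undefined
    n_trials: dict


def evoked_rates(spikes_one: pd.DataFrame, trials: pd.DataFrame, cue: str,
                 config: SessionConfig, window_ms=None) -> np.ndarray:
    """Per-trial baseline-subtracted rate (spikes/s) on correct trials."""
    window = window_ms or config.analysis_window_ms
    sel = _correct_trials(trials, cue)
    if len(sel) < config.min_trials:
        raise ValueError(
            f"cue {cue!r}: {len(sel)} usable trials < minimum {config.min_trials}")
    ev = window_rate(count_in_window(spikes_one, sel, window).to_numpy(), window)
    ba = window_rate(count_in_window(
        spikes_one, sel, config.baseline_window_ms).to_numpy(),
        config.baseline_window_ms)
    return ev - ba


def _bootstrap_means(values: np.ndarray, n_draw: int, n_boot: int,
                     rng: np.random.Generator) -> np.ndarray:
    """Means of repeated draws; with replacement iff the draw spans the pool."""
    n = len(values)
    if n_draw >= n:
        idx = rng.integers(0, n, size=(n_boot, n))
    else:
        noise = rng.random((n_boot, n))
        idx = np.argpartition(noise, n_draw - 1, axis=1)[:, :n_draw]
    return values[idx].mean(axis=1)


def estimate_scaling_coefficient(spikes_one: pd.DataFrame,
                                 trials: pd.DataFrame, pairing: str,
                                 config: SessionConfig | None = None
                                 ) -> float | None:
    """Observed AV mean over (A mean + V mean), on evoked rates.

    Returns None (undefined) when the summed unisensory evoked means
    are not positive.
    """
    config = config or SessionConfig()
    a_cue, v_cue = PAIRING_COMPONENTS[pairing]
    av = evoked_rates(spikes_one, trials, pairing, config).mean()
    a = evoked_rates(spikes_one, trials, a_cue, config).mean()
    v = evoked_rates(spikes_one, trials, v_cue, config).mean()
    denom = a + v
    if denom <= 0:
        return None
    return float(av / denom)


def bootstrap_additivity(av_values, a_values, v_values,
                         coefficient: float = 1.0, n_boot: int = 5000,
                         rng: np.random.Generator | int | None = None,
                         pairing: str = "") -> AdditivityResult:
    """Core additive-model test on per-trial response values.

    ``av_values`` are the observed multisensory responses; ``a_values``
    and ``v_values`` the unisensory responses, all in the same units
    (typically evoked spikes/s in the analysis window).
    """
    rng = np.random.default_rng(rng)
    av = np.asarray(av_values, dtype=float)
    a = np.asarray(a_values, dtype=float)
    v = np.asarray(v_values, dtype=float)
    observed = float(av.mean())
    n_av = len(av)
    pred = coefficient * (
        _bootstrap_means(a, min(n_av, len(a)), n_boot, rng)
        + _bootstrap_means(v, min(n_av, len(v)), n_boot, rng))
    p_mean, p_sd = float(pred.mean()), float(pred.std(ddof=0))
    obs_se = float(av.std(ddof=1) / np.sqrt(n_av)) if n_av > 1 else 0.0
    denom = float(a.mean() + v.mean())
    c_hat = float(observed / denom) if denom > 0 else None
    if p_sd == 0:
        z, cls = None, "degenerate"
    else:
        z = (observed - p_mean) / np.sqrt(p_sd**2 + obs_se**2)
        cls = ("superadditive" if z >= Z_CRIT
               else "subadditive" if z <= -Z_CRIT else "additive")
    return AdditivityResult(
        pairing=pairing, observed_mean=observed, predicted_mean=p_mean,
        predicted_sd=p_sd, n_bootstrap=n_boot,
        coefficient=coefficient, z_score=None if z is None else float(z),
        classification=cls, scaling_coefficient=c_hat,
        n_trials={"AV": n_av, "A": len(a), "V": len(v)})


def additivity_test(spikes_one: pd.DataFrame, trials: pd.DataFrame,
                    pairing: str, config: SessionConfig | None = None,
                    rng: np.random.Generator | int | None = None,
                    coefficient: float = 1.0) -> AdditivityResult:
    """Compare the observed multisensory mean to the bootstrap benchmark."""
    config = config or SessionConfig()
    a_cue, v_cue = PAIRING_COMPONENTS[pairing]
    av = evoked_rates(spikes_one, trials, pairing, config)
    a = evoked_rates(spikes_one, trials, a_cue, config)
    v = evoked_rates(spikes_one, trials, v_cue, config)
    return bootstrap_additivity(av, a, v, coefficient, config.n_bootstrap,
                                rng, pairing)
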