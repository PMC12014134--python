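"""Population summaries, behavioral metrics, and the study's group tests.

Paired comparisons follow a normality gate: a Shapiro-Wilk test on the
paired differences selects the paired t-test (normal) or the Wilcoxon
signed-rank test (non-normal) at alpha = 0.05; both the gate p-value
and the chosen test are reported.  Proportions are compared with a
Pearson chi-square on the 2x2 table, uncorrected by default.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats

from .io_model import (
    AUDITORY_CUES,
    MATCHED_PAIRINGS,
    SessionConfig,
    VISUAL_CUES,
)
from .psth import CATEGORIES, classify_responsiveness, mean_rate, neuron_spikes
from .selectivity import msi, selectivity_index
from .synthdata import cue_modality


def correct_rate(trials: pd.DataFrame, cue: str) -> float:
    """Percentage of correct trials for a cue.

    Unmatched cues reward either port, so correctness is undefined and
    their trials are excluded; selecting such a cue is an error.
    """
    sel = trials.loc[(trials["cue"] == cue) & (trials["correct"] != "either")]
    if len(sel) == 0:
        raise ValueError(f"no scorable trials for cue {cue!r}")
    return 100.0 * float(sel["correct"].astype(bool).mean())


@dataclasses.dataclass
class BehaviorSummary:
    correct_rate_by_cue: dict          # cue -> %
    rt_mean_ms: dict                   # modality -> mean over correct trials
    rt_sd_ms: dict
    rt_n: dict
    rt_missing: list                   # modalities with no usable correct RT
    cumulative: pd.DataFrame           # modality, rt_ms, cum_fraction


def reaction_time_summary(trials: pd.DataFrame) -> BehaviorSummary:
    """Per-modality reaction-time statistics over correct trials."""
    rates = {}
    for cue in trials["cue"].unique():
        if (trials.loc[trials["cue"] == cue, "correct"] != "either").any():
            rates[cue] = correct_rate(trials, cue)
    mean_ms, sd_ms, n_ms, missing, rows = {}, {}, {}, [], []
    mods = trials["cue"].map(cue_modality)
    for mod in sorted(mods.unique()):
        m = (mods == mod) & (trials["correct"] == True)  # noqa: E712
        rt = trials.loc[m, "reaction_time_ms"].dropna()
        if len(rt) == 0:
            missing.append(mod)
            continue
        mean_ms[mod] = float(rt.mean())
        sd_ms[mod] = float(rt.std(ddof=1)) if len(rt) > 1 else 0.0
        n_ms[mod] = int(len(rt))
        srt = np.sort(rt.to_numpy())
        rows.append(pd.DataFrame({
            "modality": mod, "rt_ms": srt,
            "cum_fraction": np.arange(1, len(srt) + 1) / len(srt)}))
    cum = (pd.concat(rows, ignore_index=True) if rows
           else pd.DataFrame(columns=["modality", "rt_ms", "cum_fraction"]))
    return BehaviorSummary(correct_rate_by_cue=rates, rt_mean_ms=mean_ms,
                           rt_sd_ms=sd_ms, rt_n=n_ms, rt_missing=missing,
                           cumulative=cum)


@dataclasses.dataclass
class GroupComparison:
    test: str                 # "paired-t" | "signed-rank" | "none"
    statistic: float | None
    p_value: float | None
    n: int
    shapiro_p: float | None
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    degenerate: bool = False


def compare_paired(values_a, values_b, alpha: float = 0.05) -> GroupComparison:
    """Paired comparison with a Shapiro-Wilk normality gate on differences."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) != len(b):
        raise ValueError("paired samples must have equal length")
    if len(a) < 3:
        raise ValueError("need at least 3 pairs")
    base = dict(n=len(a), mean_a=float(a.mean()), sd_a=float(a.std(ddof=1)),
                mean_b=float(b.mean()), sd_b=float(b.std(ddof=1)))
    d = a - b
    if np.all(d == 0):
        return GroupComparison(test="none", statistic=None, p_value=None,
                               shapiro_p=None, degenerate=True, **base)
    sw_p = float(stats.shapiro(d).pvalue)
    if sw_p >= alpha:
        res = stats.ttest_rel(a, b)
        return GroupComparison(test="paired-t", statistic=float(res.statistic),
                               p_value=float(res.pvalue), shapiro_p=sw_p, **base)
    res = stats.wilcoxon(a, b, zero_method="wilcox")
    return GroupComparison(test="signed-rank", statistic=float(res.statistic),
                           p_value=float(res.pvalue), shapiro_p=sw_p, **base)


def proportion_test(k1: int, n1: int, k2: int, n2: int,
                    correction: bool = False) -> tuple[float, float]:
    """Pearson chi-square on the 2x2 table of two proportions.

    Returns (chi2, p).  Records a warning flag via ValueError only for
    invalid inputs; small expected cells are the caller's concern.
    """
    if n1 <= 0 or n2 <= 0 or not (0 <= k1 <= n1) or not (0 <= k2 <= n2):
        raise ValueError("counts must satisfy 0 <= k <= n, n > 0")
    table = np.array([[k1, n1 - k1], [k2, n2 - k2]], dtype=float)
    if (table.sum(axis=1) == 0).any() or (table.sum(axis=0) == 0).any():
        return 0.0, 1.0
    res = stats.chi2_contingency(table, correction=correction)
    return float(res.statistic), float(res.pvalue)


def population_report(spikes: pd.DataFrame, trials: pd.DataFrame,
                      config: SessionConfig | None = None,
                      rng: np.random.Generator | int | None = None,
                      preferred_pairing: str = "A10kVvt",
                      null_pairing: str = "A3kVhz") -> dict:
    """Session-level summary composing the single-neuron analyses.

    For every neuron passing the whole-epoch 2 Hz rate filter:
    responsiveness category; auditory, visual and multisensory
    selectivity; and the MSI for both matched pairings among
    audiovisual neurons.  Aggregates counts of significantly selective
    neurons by preferred cue, enhanced/inhibited counts per pairing,
    mean absolute selectivity, and mean MSI per pairing.
    """
    config = config or SessionConfig()
    rng = np.random.default_rng(rng)
    neuron_ids = sorted(spikes["neuron_id"].unique())
    report = {
        "n_neurons": len(neuron_ids), "n_included": 0,
        "categories": {c: 0 for c in CATEGORIES},
        "preferred_counts": {"A10k": 0, "A3k": 0, "Vvt": 0, "Vhz": 0},
        "msi": {p: [] for p in MATCHED_PAIRINGS},
        "enhanced": {p: 0 for p in MATCHED_PAIRINGS},
        "inhibited": {p: 0 for p in MATCHED_PAIRINGS},
        "abs_si": {"auditory": [], "visual": [], "multisensory": []},
        "neurons": {},
    }
    for nid in neuron_ids:
        sp = neuron_spikes(spikes, nid)
        if mean_rate(sp, trials, config) < config.min_rate_hz:
            continue
        report["n_included"] += 1
        call = classify_responsiveness(sp, trials, config)
        report["categories"][call.category] += 1
        rec = {"category": call.category}
        contrasts = {"auditory": AUDITORY_CUES, "visual": VISUAL_CUES,
                     "multisensory": ("A3kVhz", "A10kVvt")}
        aud_resp = any(call.responsive.get(c, False) for c in AUDITORY_CUES)
        vis_resp = any(call.responsive.get(c, False) for c in VISUAL_CUES)
        for name, (c1, c2) in contrasts.items():
            tested = (name == "auditory" and aud_resp) or (
                name == "visual" and vis_resp) or (
                name == "multisensory" and call.category != "unresponsive")
            if not tested:
                continue
            res = selectivity_index(sp, trials, c2, c1, None, config, rng)
            rec[f"si_{name}"] = res.si
            report["abs_si"][name].append(abs(res.si))
            if res.significant:
                pref = c2 if res.si > 0 else c1
                if pref in report["preferred_counts"]:
                    report["preferred_counts"][pref] += 1
        if call.category in ("AV(both)", "AV-only"):
            for pairing in MATCHED_PAIRINGS:
                r = msi(sp, trials, pairing, None, config, rng)
                rec[f"msi_{pairing}"] = r.msi
                report["msi"][pairing].append(r.msi)
                if r.classification == "enhanced":
                    report["enhanced"][pairing] += 1
                elif r.classification == "inhibited":
                    report["inhibited"][pairing] += 1
        report["neurons"][nid] = rec
    for key in ("msi", "abs_si"):
        report[f"mean_{key}"] = {
            k: (float(np.mean(v)) if v else None)
            for k, v in report[key].items()}
    both = [(report["neurons"][n][f"msi_{preferred_pairing}"],
             report["neurons"][n][f"msi_{null_pairing}"])
            for n in report["neurons"]
            if f"msi_{preferred_pairing}" in report["neurons"][n]
            and f"msi_{null_pairing}" in report["neurons"][n]]
    if len(both) >= 3:
        pref, null = map(np.asarray, zip(*both))
        cmp_ = compare_paired(pref, null)
        report["msi_pairing_comparison"] = dataclasses.asdict(cmp_)
    report["behavior"] = dataclasses.asdict(reaction_time_summary(trials)) | {
        "cumulative": None}
    return report
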