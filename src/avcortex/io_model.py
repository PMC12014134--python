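"""Data model and on-disk formats for trial-aligned spike sessions.

A session is a pair of comma-separated tables:

``spikes.csv``
    one row per spike: ``neuron_id,trial_id,spike_time_ms`` with spike
    times in milliseconds relative to cue onset (negative = pre-cue).

``trials.csv``
    one row per trial: ``trial_id,cue,choice,correct,reaction_time_ms``.
    ``correct`` is ``true``/``false``, or ``either`` for unmatched
    audiovisual cues where both reward ports are valid.  A missing
    reaction time is an empty field, distinct from zero.

All analysis windows are half-open ``[start, end)`` in milliseconds so
that adjacent windows partition the epoch without double-counting.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

#: The 6 task cues plus the 2 unmatched audiovisual pairings.
CUES = ("A3k", "A10k", "Vhz", "Vvt", "A3kVhz", "A10kVvt", "A10kVhz", "A3kVvt")

AUDITORY_CUES = ("A3k", "A10k")
VISUAL_CUES = ("Vhz", "Vvt")
MULTISENSORY_CUES = ("A3kVhz", "A10kVvt", "A10kVhz", "A3kVvt")
#: Pairings whose auditory and visual components indicate the same port.
MATCHED_PAIRINGS = ("A3kVhz", "A10kVvt")
UNMATCHED_PAIRINGS = ("A10kVhz", "A3kVvt")

#: Components of each audiovisual pairing.
PAIRING_COMPONENTS = {
    "A3kVhz": ("A3k", "Vhz"),
    "A10kVvt": ("A10k", "Vvt"),
    "A10kVhz": ("A10k", "Vhz"),
    "A3kVvt": ("A3k", "Vvt"),
}

#: Rewarded port for each informative cue (unmatched cues reward either).
CUE_SIDE = {
    "A3k": "left",
    "Vhz": "left",
    "A3kVhz": "left",
    "A10k": "right",
    "Vvt": "right",
    "A10kVvt": "right",
}

CHOICES = ("left", "right", "none")

SPIKE_COLUMNS = ["neuron_id", "trial_id", "spike_time_ms"]
TRIAL_COLUMNS = ["trial_id", "cue", "choice", "correct", "reaction_time_ms"]


class SchemaError(ValueError):
    """A table is missing a required column or has an unparseable value."""


class IntegrityError(ValueError):
    """Cross-table references are broken (e.g. spike cites unknown trial)."""


class ValidationError(ValueError):
    """A field value falls outside its documented domain."""


@dataclasses.dataclass
class SessionConfig:
    """Analysis constants shared by every stage of the pipeline.

    Defaults follow the study conventions: 10 ms PSTH bins smoothed by a
    50 ms Gaussian, a 400 ms pre-cue baseline, a 0-150 ms analysis
    window, a 150-300 ms late window, 0-300 ms responsiveness window,
    2000 permutations for selectivity nulls and 5000 bootstrap
    iterations for the additive-model test.
    """

    epoch_ms: tuple[float, float] = (-700.0, 1500.0)
    baseline_window_ms: tuple[float, float] = (-400.0, 0.0)
    analysis_window_ms: tuple[float, float] = (0.0, 150.0)
    late_window_ms: tuple[float, float] = (150.0, 300.0)
    responsiveness_window_ms: tuple[float, float] = (0.0, 300.0)
    bin_ms: float = 10.0
    smooth_sigma_ms: float = 50.0
    n_permutations: int = 2000
    n_bootstrap: int = 5000
    # pseudo-population decoding
    decode_window_ms: float = 100.0
    decode_step_ms: float = 10.0
    decode_trials_per_cue: int = 30
    decode_folds: int = 10
    decode_resamples: int = 100
    decode_shuffles: int = 1000
    # inclusion thresholds
    responsive_rate_threshold_hz: float = 2.0
    min_rate_hz: float = 2.0
    alpha: float = 0.05
    min_trials: int = 5
    min_trials_per_choice: int = 9
    auroc_method: str = "exact_rank"
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.epoch_ms
        for name in ("baseline_window_ms", "analysis_window_ms",
                     "late_window_ms", "responsiveness_window_ms"):
            w = tuple(getattr(self, name))
            setattr(self, name, w)
            if not (lo <= w[0] < w[1] <= hi):
                raise ValidationError(f"{name}={w} not within epoch {self.epoch_ms}")
        self.epoch_ms = (float(lo), float(hi))
        for name in ("n_permutations", "n_bootstrap", "decode_trials_per_cue",
                     "decode_folds", "decode_resamples", "decode_shuffles",
                     "min_trials", "min_trials_per_choice"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.auroc_method not in ("exact_rank", "discretized12"):
            raise ValidationError(f"unknown auroc_method {self.auroc_method!r}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SessionConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise SchemaError(f"unknown config keys: {sorted(unknown)}")
        kwargs = {k: tuple(v) if isinstance(v, list) else v for k, v in d.items()}
        return cls(**kwargs)

    @classmethod
    def from_file(cls, path: str | Path) -> "SessionConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(data or {})

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix == ".json":
            path.write_text(json.dumps(self.to_dict(), indent=2))
        else:
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


def _parse_correct(value):
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    s = str(value).strip().lower()
    if s in ("true", "1"):
        return True
    if s in ("false", "0"):
        return False
    if s == "either":
        return "either"
    raise ValidationError(f"correct must be true/false/either, got {value!r}")


def validate_trials(trials: pd.DataFrame) -> pd.DataFrame:
    """Validate a trial table in place and return it.

    Checks column presence, trial-id uniqueness, cue/choice enumerations
    and non-negative reaction times.
    """
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise SchemaError(f"trial table missing columns: {missing}")
    trials = trials[TRIAL_COLUMNS].copy()
    trials["trial_id"] = trials["trial_id"].astype(int)
    if trials["trial_id"].duplicated().any():
        dupes = trials.loc[trials["trial_id"].duplicated(), "trial_id"].tolist()
        raise ValidationError(f"duplicate trial_ids: {dupes}")
    if (trials["trial_id"] <= 0).any():
        raise ValidationError("trial_ids must be positive integers")
    bad_cue = set(trials["cue"]) - set(CUES)
    if bad_cue:
        raise ValidationError(f"unknown cues: {sorted(bad_cue)}")
    bad_choice = set(trials["choice"]) - set(CHOICES)
    if bad_choice:
        raise ValidationError(f"unknown choices: {sorted(bad_choice)}")
    trials["correct"] = trials["correct"].map(_parse_correct)
    rt = pd.to_numeric(trials["reaction_time_ms"], errors="coerce")
    had = trials["reaction_time_ms"].notna() & (
        trials["reaction_time_ms"].astype(str).str.strip() != "")
    if (had & rt.isna()).any():
        raise SchemaError("non-numeric reaction_time_ms values present")
    if (rt.dropna() < 0).any():
        raise ValidationError("reaction_time_ms must be >= 0 when present")
    trials["reaction_time_ms"] = rt
    return trials


def validate_spikes(spikes: pd.DataFrame, trials: pd.DataFrame,
                    epoch_ms: tuple[float, float] = (-700.0, 1500.0)) -> pd.DataFrame:
    """Validate a spike table against its companion trial table."""
    missing = [c for c in SPIKE_COLUMNS if c not in spikes.columns]
    if missing:
        raise SchemaError(f"spike table missing columns: {missing}")
    spikes = spikes[SPIKE_COLUMNS].copy()
    spikes["neuron_id"] = spikes["neuron_id"].astype(str)
    spikes["trial_id"] = spikes["trial_id"].astype(int)
    t = pd.to_numeric(spikes["spike_time_ms"], errors="coerce")
    if t.isna().any():
        lines = (np.flatnonzero(t.isna()) + 2).tolist()  # +2: header + 1-based
        raise SchemaError(f"non-numeric spike_time_ms at file lines {lines[:10]}")
    spikes["spike_time_ms"] = t.astype(float)
    known = set(trials["trial_id"])
    dangling = sorted(set(spikes["trial_id"]) - known)
    if dangling:
        raise IntegrityError(f"spikes reference unknown trial_ids: {dangling[:20]}")
    lo, hi = epoch_ms
    out = spikes["spike_time_ms"]
    if ((out < lo) | (out > hi)).any():
        raise ValidationError(f"spike times outside epoch [{lo}, {hi}] ms")
    return spikes


def read_session(spike_path: str | Path, trial_path: str | Path,
                 config: SessionConfig | None = None
                 ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read and validate a (spikes, trials) session from CSV files."""
    config = config or SessionConfig()
    trials = validate_trials(pd.read_csv(trial_path))
    spikes = validate_spikes(pd.read_csv(spike_path), trials, config.epoch_ms)
    return spikes, trials


def write_session(spikes: pd.DataFrame, trials: pd.DataFrame,
                  spike_path: str | Path, trial_path: str | Path,
                  config: SessionConfig | None = None) -> None:
    """Write validated tables to CSV, re-readable to equal tables."""
    config = config or SessionConfig()
    trials = validate_trials(trials)
    spikes = validate_spikes(spikes, trials, config.epoch_ms)
    out = trials.copy()
    out["correct"] = out["correct"].map(
        lambda v: v if v == "either" else ("true" if v else "false"))
    out.to_csv(trial_path, index=False, float_format="%.6g")
    spikes.to_csv(spike_path, index=False, float_format="%.6f")
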