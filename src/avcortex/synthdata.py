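"""Synthetic two-alternative forced-choice sessions with Poisson spiking.

The generator emulates the trial and response structure the analysis
assumes: six task cues (two tones, two visual stimuli, two matched
audiovisual pairings) plus optional unmatched pairings; per-neuron
baseline rates; modality-specific onset latencies (auditory earlier
than visual); cue tuning; and a pairing-specific multiplicative
interaction applied to the summed evoked rates,

    rate(t) = baseline + c_pair * (evoked_A(t) + evoked_V(t))

so c = 1 is additive, c > 1 enhancement, c < 1 suppression.  On
incorrect-choice trials the interaction is shrunk toward additivity:
c -> 1 + shrink * (c - 1), leaving unisensory responses untouched.

Spiking is an inhomogeneous Poisson process with a piecewise-constant
rate; the analyses only ever use window counts, so no renewal structure
is modelled, and neurons are conditionally independent (no noise
correlations) — the assumption pseudo-population decoding makes anyway.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .io_model import (
    AUDITORY_CUES,
    CUE_SIDE,
    MATCHED_PAIRINGS,
    MULTISENSORY_CUES,
    PAIRING_COMPONENTS,
    SessionConfig,
    UNMATCHED_PAIRINGS,
    VISUAL_CUES,
)

RESPONSE_CLASSES = ("auditory-only", "visual-only", "audiovisual",
                    "audiovisual-only", "unresponsive")


@dataclasses.dataclass
class NeuronSpec:
    """Ground-truth firing model of one synthetic neuron.

    Gains are evoked rates in spikes/s added on top of baseline during
    the response window of the corresponding modality.  ``av_only_gain``
    is an extra evoked rate present only on multisensory trials, giving
    the small audiovisual-only response class.
    """

    baseline_rate: float = 5.0
    auditory_gain: dict = dataclasses.field(
        default_factory=lambda: {"A3k": 0.0, "A10k": 0.0})
    visual_gain: dict = dataclasses.field(
        default_factory=lambda: {"Vhz": 0.0, "Vvt": 0.0})
    auditory_latency_ms: float = 20.0
    visual_latency_ms: float = 50.0
    response_duration_ms: float = 130.0
    interaction: dict = dataclasses.field(
        default_factory=lambda: {p: 1.0 for p in MULTISENSORY_CUES})
    av_only_gain: float = 0.0
    incorrect_interaction_shrink: float = 1.0

    def __post_init__(self) -> None:
        if self.baseline_rate < 0:
            raise ValueError("baseline_rate must be >= 0")
        for d in (self.auditory_gain, self.visual_gain):
            if any(v < 0 for v in d.values()):
                raise ValueError("gains must be >= 0")
        if any(c < 0 for c in self.interaction.values()):
            raise ValueError("interaction factors must be >= 0")
        if not 0.0 <= self.incorrect_interaction_shrink <= 1.0:
            raise ValueError("incorrect_interaction_shrink must be in [0,1]")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclasses.dataclass
class BehaviorSpec:
    """Behavioral statistics of the simulated animal.

    Correct-choice probabilities default to the qualitative pattern of
    trained rats (multisensory > unisensory); reaction times are shifted
    lognormals with multisensory responses fastest.
    """

    p_correct: dict = dataclasses.field(default_factory=lambda: {
        "auditory": 0.82, "visual": 0.82, "multisensory": 0.90})
    # modality -> (log-mean, log-sd, shift_ms) of a shifted lognormal
    reaction_time: dict = dataclasses.field(default_factory=lambda: {
        "auditory": (5.56, 0.35, 150.0),
        "visual": (5.53, 0.35, 150.0),
        "multisensory": (5.32, 0.35, 150.0)})
    p_right_unmatched: float = 0.5

    def __post_init__(self) -> None:
        for k, v in self.p_correct.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"p_correct[{k}] outside [0,1]")
        if not 0.0 <= self.p_right_unmatched <= 1.0:
            raise ValueError("p_right_unmatched outside [0,1]")


@dataclasses.dataclass
class PopulationSpec:
    """Composition of a synthetic population and its tuning statistics."""

    n_neurons: int = 100
    trials_per_cue: int = 40
    weights: dict = dataclasses.field(default_factory=lambda: {
        "auditory-only": 0.35, "visual-only": 0.08, "audiovisual": 0.40,
        "audiovisual-only": 0.03, "unresponsive": 0.14})
    include_unmatched: bool = False
    # tuning: which cue of each modality most neurons prefer (None = symmetric)
    pref_auditory: str | None = "A10k"
    pref_visual: str | None = "Vvt"
    pref_prob: float = 0.8
    gain_pref_range: tuple[float, float] = (6.0, 14.0)
    gain_nonpref_range: tuple[float, float] = (0.0, 4.0)
    gain_nonpref_zero_prob: float = 0.7
    visual_gain_pref_range: tuple[float, float] = (4.0, 10.0)
    visual_gain_nonpref_range: tuple[float, float] = (0.0, 3.0)
    baseline_range: tuple[float, float] = (2.0, 8.0)
    interaction_mean: dict = dataclasses.field(
        default_factory=lambda: {p: 1.0 for p in MULTISENSORY_CUES})
    interaction_sd: dict = dataclasses.field(
        default_factory=lambda: {p: 0.0 for p in MULTISENSORY_CUES})
    incorrect_interaction_shrink: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_neurons <= 0 or self.trials_per_cue <= 0:
            raise ValueError("counts must be positive")
        total = sum(self.weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class weights must sum to 1, got {total}")
        unknown = set(self.weights) - set(RESPONSE_CLASSES)
        if unknown:
            raise ValueError(f"unknown response classes: {sorted(unknown)}")


def cue_modality(cue: str) -> str:
    """Classify a cue as auditory / visual / multisensory / unmatched."""
    if cue in AUDITORY_CUES:
        return "auditory"
    if cue in VISUAL_CUES:
        return "visual"
    if cue in MATCHED_PAIRINGS:
        return "multisensory"
    if cue in UNMATCHED_PAIRINGS:
        return "unmatched"
    raise ValueError(f"unknown cue {cue!r}")


def poisson_counts(rate_hz: float, duration_ms: float, n_trials: int,
                   rng: np.random.Generator) -> np.ndarray:
    """Per-trial Poisson spike counts for a constant rate over a window."""
    lam = rate_hz * duration_ms / 1000.0
    return rng.poisson(lam, size=n_trials)


def generate_trials(pop: PopulationSpec, behavior: BehaviorSpec,
                    rng: np.random.Generator) -> pd.DataFrame:
    """Draw the trial table: cues, choices, correctness, reaction times."""
    cues = list(AUDITORY_CUES + VISUAL_CUES + MATCHED_PAIRINGS)
    if pop.include_unmatched:
        cues += list(UNMATCHED_PAIRINGS)
    rows = []
    for cue in cues:
        mod = cue_modality(cue)
        for _ in range(pop.trials_per_cue):
            if mod == "unmatched":
                choice = "right" if rng.random() < behavior.p_right_unmatched else "left"
                correct = "either"
                mu, sd, shift = behavior.reaction_time["multisensory"]
            else:
                ok = rng.random() < behavior.p_correct[mod]
                side = CUE_SIDE[cue]
                choice = side if ok else ("left" if side == "right" else "right")
                correct = bool(ok)
                mu, sd, shift = behavior.reaction_time[mod]
            rt = shift + float(rng.lognormal(mu, sd))
            rows.append((cue, choice, correct, rt))
    order = rng.permutation(len(rows))
    trials = pd.DataFrame(
        [rows[i] for i in order],
        columns=["cue", "choice", "correct", "reaction_time_ms"])
    trials.insert(0, "trial_id", np.arange(1, len(trials) + 1))
    return trials


def sample_neuron_spec(cls: str, pop: PopulationSpec,
                       rng: np.random.Generator) -> NeuronSpec:
    """Draw one neuron's ground-truth parameters for a response class."""

    def _gain(pref_range, nonpref_range, prefers):
        hi = float(rng.uniform(*pref_range))
        lo = 0.0 if rng.random() < pop.gain_nonpref_zero_prob else float(
            rng.uniform(*nonpref_range))
        return (hi, lo) if prefers else (lo, hi)

    a_gain = {"A3k": 0.0, "A10k": 0.0}
    v_gain = {"Vhz": 0.0, "Vvt": 0.0}
    has_a = cls in ("auditory-only", "audiovisual")
    has_v = cls in ("visual-only", "audiovisual")
    if has_a:
        if pop.pref_auditory is None:
            pref = "A10k" if rng.random() < 0.5 else "A3k"
        else:
            pref = pop.pref_auditory if rng.random() < pop.pref_prob else (
                "A3k" if pop.pref_auditory == "A10k" else "A10k")
        other = "A3k" if pref == "A10k" else "A10k"
        g_pref, g_other = _gain(pop.gain_pref_range, pop.gain_nonpref_range, True)
        a_gain[pref], a_gain[other] = g_pref, g_other
    if has_v:
        if pop.pref_visual is None:
            pref = "Vvt" if rng.random() < 0.5 else "Vhz"
        else:
            pref = pop.pref_visual if rng.random() < pop.pref_prob else (
                "Vhz" if pop.pref_visual == "Vvt" else "Vvt")
        other = "Vhz" if pref == "Vvt" else "Vvt"
        g_pref, g_other = _gain(pop.visual_gain_pref_range,
                                pop.visual_gain_nonpref_range, True)
        v_gain[pref], v_gain[other] = g_pref, g_other
    interaction = {}
    for p in MULTISENSORY_CUES:
        c = pop.interaction_mean.get(p, 1.0)
        sd = pop.interaction_sd.get(p, 0.0)
        if sd > 0:
            c = float(rng.normal(c, sd))
        interaction[p] = max(c, 0.0)
    av_only = float(rng.uniform(4.0, 10.0)) if cls == "audiovisual-only" else 0.0
    return NeuronSpec(
        baseline_rate=float(rng.uniform(*pop.baseline_range)),
        auditory_gain=a_gain, visual_gain=v_gain,
        interaction=interaction, av_only_gain=av_only,
        incorrect_interaction_shrink=pop.incorrect_interaction_shrink)


def _rate_segments(spec: NeuronSpec, cue: str, correct,
                   epoch_ms: tuple[float, float]):
    """Piecewise-constant rate of one trial as (edges, rates) arrays."""
    lo, hi = epoch_ms
    a_on = spec.auditory_latency_ms
    a_off = a_on + spec.response_duration_ms
    v_on = spec.visual_latency_ms
    v_off = v_on + spec.response_duration_ms
    mod = cue_modality(cue)
    gA = gV = gX = 0.0
    c_eff = 1.0
    if mod == "auditory":
        gA = spec.auditory_gain[cue]
    elif mod == "visual":
        gV = spec.visual_gain[cue]
    else:
        a_cue, v_cue = PAIRING_COMPONENTS[cue]
        gA = spec.auditory_gain[a_cue]
        gV = spec.visual_gain[v_cue]
        gX = spec.av_only_gain
        c = spec.interaction.get(cue, 1.0)
        if correct is False:
            c = 1.0 + spec.incorrect_interaction_shrink * (c - 1.0)
        c_eff = c
    edges = np.unique(np.clip([lo, a_on, a_off, v_on, v_off, hi], lo, hi))
    rates = np.empty(len(edges) - 1)
    for i, (s, e) in enumerate(zip(edges[:-1], edges[1:])):
        mid = 0.5 * (s + e)
        evoked = ((gA + gX) if a_on <= mid < a_off else 0.0) + (
            gV if v_on <= mid < v_off else 0.0)
        rates[i] = spec.baseline_rate + c_eff * evoked
    return edges, rates


def generate_spikes(specs: list[NeuronSpec], trials: pd.DataFrame,
                    config: SessionConfig, rng: np.random.Generator,
                    neuron_ids: list[str] | None = None) -> pd.DataFrame:
    """Sample Poisson spike trains for every neuron on every trial."""
    if neuron_ids is None:
        neuron_ids = [f"n{i:04d}" for i in range(len(specs))]
    trial_info = list(trials[["trial_id", "cue", "correct"]].itertuples(index=False))
    nid_out, tid_out, t_out = [], [], []
    for nid, spec in zip(neuron_ids, specs):
        seg_cache = {}
        for trial_id, cue, correct in trial_info:
            key = (cue, correct is False)
            if key not in seg_cache:
                seg_cache[key] = _rate_segments(spec, cue, correct, config.epoch_ms)
            edges, rates = seg_cache[key]
            for s, e, r in zip(edges[:-1], edges[1:], rates):
                if r <= 0:
                    continue
                n = rng.poisson(r * (e - s) / 1000.0)
                if n:
                    times = rng.uniform(s, e, size=n)
                    nid_out.extend([nid] * n)
                    tid_out.extend([trial_id] * n)
                    t_out.extend(times)
    spikes = pd.DataFrame({
        "neuron_id": pd.Series(nid_out, dtype=str),
        "trial_id": pd.Series(tid_out, dtype=int),
        "spike_time_ms": pd.Series(t_out, dtype=float)})
    spikes = spikes.sort_values(
        ["neuron_id", "trial_id", "spike_time_ms"]).reset_index(drop=True)
    return spikes


def generate_session(pop: PopulationSpec, behavior: BehaviorSpec | None = None,
                     config: SessionConfig | None = None,
                     seed: int | None = None
                     ) -> tuple[pd.DataFrame, pd.DataFrame, list[NeuronSpec]]:
    """Generate one full session: spikes, trials, and per-neuron truth."""
    behavior = behavior or BehaviorSpec()
    config = config or SessionConfig()
    rng = np.random.default_rng(pop.seed if seed is None else seed)
    trials = generate_trials(pop, behavior, rng)
    classes = rng.choice(RESPONSE_CLASSES, size=pop.n_neurons,
                         p=[pop.weights.get(c, 0.0) for c in RESPONSE_CLASSES])
    specs = [sample_neuron_spec(c, pop, rng) for c in classes]
    spikes = generate_spikes(specs, trials, config, rng)
    return spikes, trials, specs


PRESETS = ("trained_right_AC", "trained_left_AC", "free_choice",
           "unisensory_trained", "unmatched_cues")


def preset_scenarios(name: str) -> tuple[PopulationSpec, BehaviorSpec]:
    """Parameter bundles mirroring the study's training conditions.

    ``trained_right_AC``: most neurons prefer the cues guiding the
    contralateral (right) choice, with enhancement specific to the
    matched preferred pairing.  ``trained_left_AC`` is its mirror under
    cue relabeling.  ``free_choice`` has symmetric preferences and
    purely additive interactions; ``unisensory_trained`` keeps mild
    preference but no multisensory interaction; ``unmatched_cues`` adds
    the two unmatched pairings to the trial set.
    """
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {PRESETS}")
    behavior = BehaviorSpec()
    if name == "trained_right_AC":
        pop = PopulationSpec(
            pref_auditory="A10k", pref_visual="Vvt",
            interaction_mean={"A10kVvt": 1.5, "A3kVhz": 1.0,
                              "A10kVhz": 1.0, "A3kVvt": 1.0},
            interaction_sd={"A10kVvt": 0.25, "A3kVhz": 0.0,
                            "A10kVhz": 0.0, "A3kVvt": 0.0},
            incorrect_interaction_shrink=0.5)
    elif name == "trained_left_AC":
        pop = PopulationSpec(
            pref_auditory="A3k", pref_visual="Vhz",
            interaction_mean={"A3kVhz": 1.5, "A10kVvt": 1.0,
                              "A10kVhz": 1.0, "A3kVvt": 1.0},
            interaction_sd={"A3kVhz": 0.25, "A10kVvt": 0.0,
                            "A10kVhz": 0.0, "A3kVvt": 0.0},
            incorrect_interaction_shrink=0.5)
    elif name == "free_choice":
        pop = PopulationSpec(pref_auditory=None, pref_visual=None)
        behavior = BehaviorSpec(p_correct={
            "auditory": 0.5, "visual": 0.5, "multisensory": 0.5})
    elif name == "unisensory_trained":
        pop = PopulationSpec(pref_auditory="A10k", pref_visual=None,
                             pref_prob=0.6)
    else:  # unmatched_cues
        pop = PopulationSpec(
            include_unmatched=True,
            pref_auditory="A10k", pref_visual="Vvt",
            interaction_mean={"A10kVvt": 1.5, "A3kVhz": 1.0,
                              "A10kVhz": 1.0, "A3kVvt": 1.0},
            interaction_sd={"A10kVvt": 0.25, "A3kVhz": 0.0,
                            "A10kVhz": 0.0, "A3kVvt": 0.0},
            incorrect_interaction_shrink=0.5)
    return pop, behavior


def write_truth(specs: list[NeuronSpec], path: str | Path,
                neuron_ids: list[str] | None = None) -> None:
    """Dump ground-truth neuron parameters as JSON."""
    if neuron_ids is None:
        neuron_ids = [f"n{i:04d}" for i in range(len(specs))]
    payload = {nid: s.to_dict() for nid, s in zip(neuron_ids, specs)}
    Path(path).write_text(json.dumps(payload, indent=1))
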