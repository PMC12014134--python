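import numpy as np
import pandas as pd
import pytest

from avcortex.io_model import SessionConfig
from avcortex.psth import count_in_window, neuron_spikes
from avcortex.selectivity import compute_auroc
from avcortex.synthdata import (
    BehaviorSpec,
    NeuronSpec,
    PopulationSpec,
    generate_session,
    generate_spikes,
    generate_trials,
    poisson_counts,
    preset_scenarios,
)

from conftest import make_trials


def test_same_seed_identical_outputs():
    pop = PopulationSpec(n_neurons=4, trials_per_cue=10, seed=3)
    s1, t1, _ = generate_session(pop, BehaviorSpec())
    s2, t2, _ = generate_session(pop, BehaviorSpec())
    pd.testing.assert_frame_equal(s1, s2)
    pd.testing.assert_frame_equal(t1, t2)


def test_baseline_poisson_mean():
    """Baseline-only neuron: count in a 1 s window matches rate * duration."""
    cfg = SessionConfig()
    trials = make_trials(["A3k"], 200)
    spec = NeuronSpec(baseline_rate=5.0)
    rng = np.random.default_rng(0)
    spikes = generate_spikes([spec], trials, cfg, rng)
    counts = count_in_window(neuron_spikes(spikes, "n0000"),
                             trials["trial_id"], (0.0, 1000.0)).to_numpy()
    se = np.sqrt(5.0 / len(counts))
    assert abs(counts.mean() - 5.0) < 3 * se


def test_poisson_variance_over_mean_near_one():
    """Counts on a constant-rate segment are Poisson: Fano factor ~ 1."""
    counts = poisson_counts(20.0, 500.0, 4000, np.random.default_rng(1))
    fano = counts.var(ddof=1) / counts.mean()
    # var of Fano estimate under Poisson is ~2/n
    assert abs(fano - 1.0) < 3 * np.sqrt(2 / len(counts))


def test_additive_null_population_msi_near_zero():
    """With c=1 everywhere and equal component gains the rank index
    comparing AV to the stronger unisensory component is centered near
    its small positive additive offset, not at enhancement levels."""
    cfg = SessionConfig()
    trials = make_trials(["A10k", "Vvt", "A10kVvt"], 30, rng=0)
    rng = np.random.default_rng(2)
    vals = []
    for _ in range(120):
        spec = NeuronSpec(baseline_rate=5.0,
                          auditory_gain={"A3k": 0.0, "A10k": 8.0},
                          visual_gain={"Vhz": 0.0, "Vvt": 0.0})
        spikes = generate_spikes([spec], trials, cfg, rng)
        sp = neuron_spikes(spikes, "n0000")
        av = count_in_window(sp, trials.loc[trials.cue == "A10kVvt", "trial_id"],
                             cfg.analysis_window_ms).to_numpy()
        a = count_in_window(sp, trials.loc[trials.cue == "A10k", "trial_id"],
                            cfg.analysis_window_ms).to_numpy()
        vals.append(2 * (compute_auroc(av, a) - 0.5))
    vals = np.asarray(vals)
    se = vals.std(ddof=1) / np.sqrt(len(vals))
    assert abs(vals.mean()) < 3 * se


def test_zero_trials_for_cue_rejected():
    with pytest.raises(ValueError):
        PopulationSpec(trials_per_cue=0)


def test_preset_trained_right_prefers_high_tone():
    pop, _ = preset_scenarios("trained_right_AC")
    pop.n_neurons, pop.seed = 150, 5
    _, _, specs = generate_session(pop)
    hi = sum(s.auditory_gain["A10k"] > s.auditory_gain["A3k"] for s in specs)
    lo = sum(s.auditory_gain["A3k"] > s.auditory_gain["A10k"] for s in specs)
    assert hi > lo


def test_preset_free_choice_additive():
    pop, behavior = preset_scenarios("free_choice")
    assert all(v == 1.0 for v in pop.interaction_mean.values())
    assert behavior.p_correct["multisensory"] == 0.5


def test_preset_left_mirrors_right():
    right, _ = preset_scenarios("trained_right_AC")
    left, _ = preset_scenarios("trained_left_AC")
    assert left.pref_auditory == "A3k" and right.pref_auditory == "A10k"
    assert left.interaction_mean["A3kVhz"] == right.interaction_mean["A10kVvt"]
    assert left.interaction_mean["A10kVvt"] == right.interaction_mean["A3kVhz"]


def test_unknown_preset_rejected():
    with pytest.raises(ValueError, match="unknown preset"):
        preset_scenarios("nope")


def test_incorrect_trials_shrink_interaction():
    """shrink=0 removes the multisensory boost on incorrect trials."""
    cfg = SessionConfig()
    rng = np.random.default_rng(7)
    trials = make_trials(["A10kVvt"], 120, p_correct=0.5, rng=3)
    spec = NeuronSpec(baseline_rate=0.0,
                      auditory_gain={"A3k": 0.0, "A10k": 20.0},
                      visual_gain={"Vhz": 0.0, "Vvt": 20.0},
                      interaction={"A10kVvt": 2.0, "A3kVhz": 1.0,
                                   "A10kVhz": 1.0, "A3kVvt": 1.0},
                      incorrect_interaction_shrink=0.0)
    spikes = generate_spikes([spec], trials, cfg, rng)
    sp = neuron_spikes(spikes, "n0000")
    w = (50.0, 150.0)  # both modalities active
    ok = trials.loc[trials["correct"] == True, "trial_id"]  # noqa: E712
    bad = trials.loc[trials["correct"] == False, "trial_id"]  # noqa: E712
    r_ok = count_in_window(sp, ok, w).mean() * 10
    r_bad = count_in_window(sp, bad, w).mean() * 10
    # correct: 2*(20+20)=80 spikes/s; incorrect: 40 spikes/s
    assert r_ok > 60 > r_bad


def test_reaction_times_and_behavior_ranges():
    pop, behavior = preset_scenarios("trained_right_AC")
    pop.n_neurons, pop.trials_per_cue, pop.seed = 1, 200, 9
    _, trials, _ = generate_session(pop, behavior)
    assert (trials["reaction_time_ms"] >= 150).all()
    multi = trials["cue"].isin(["A3kVhz", "A10kVvt"])
    aud = trials["cue"].isin(["A3k", "A10k"])
    m_ok = trials.loc[multi & (trials["correct"] != "either"), "correct"]
    assert 0.8 < m_ok.astype(bool).mean() <= 1.0
    assert (trials.loc[multi, "reaction_time_ms"].mean()
            < trials.loc[aud, "reaction_time_ms"].mean())
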