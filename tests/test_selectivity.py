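import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from avcortex.io_model import SessionConfig
from avcortex.psth import neuron_spikes
from avcortex.selectivity import (
    compute_auroc,
    delta_msi_vs_delta_selectivity,
    msi,
    msi_by_choice,
    permutation_si_test,
    selectivity_index,
    stronger_unisensory_cue,
)
from avcortex.synthdata import NeuronSpec, generate_spikes

from conftest import make_spike_frame, make_trials

counts = st.lists(st.integers(0, 30), min_size=2, max_size=25)


def test_auroc_examples():
    assert compute_auroc([1, 1, 1], [1, 1, 1]) == 0.5
    assert compute_auroc([10, 11, 12], [0, 1, 2]) == 1.0
    assert compute_auroc([1, 2, 3], [0, 1, 2]) == pytest.approx(7 / 9)
    assert compute_auroc([1, 1, 1], [1, 1, 1], "discretized12") == 0.5


@given(a=counts, b=counts)
@settings(max_examples=100, deadline=None)
def test_auroc_antisymmetric_and_bounded(a, b):
    r = compute_auroc(a, b)
    assert 0.0 <= r <= 1.0
    assert compute_auroc(b, a) == pytest.approx(1.0 - r)


@given(a=counts, b=counts)
@settings(max_examples=100, deadline=None)
def test_auroc_invariant_under_monotone_transform(a, b):
    f = lambda x: [v**3 + 2 * v for v in x]  # strictly monotone on counts
    assert compute_auroc(a, b) == pytest.approx(compute_auroc(f(a), f(b)))


def test_discretized_close_to_exact_on_count_data():
    """The 12-level ROC tracks the exact rank statistic on Poisson-like
    spike counts (the regime it is used in; pathological two-point
    distributions can exceed the bound and are not claimed)."""
    rng = np.random.default_rng(0)
    for _ in range(300):
        lam = rng.uniform(0.5, 25.0, size=2)
        a = rng.poisson(lam[0], rng.integers(20, 51))
        b = rng.poisson(lam[1], rng.integers(20, 51))
        d = abs(compute_auroc(a, b) - compute_auroc(a, b, "discretized12"))
        assert d <= 0.05


@given(a=st.lists(st.integers(0, 11), min_size=5, max_size=30),
       b=st.lists(st.integers(0, 11), min_size=5, max_size=30))
@settings(max_examples=100, deadline=None)
def test_discretized_exact_agreement_on_coarse_counts(a, b):
    """With <= 12 distinct integer levels the grid separates every
    adjacent pair of values, so the two estimators agree exactly."""
    assert compute_auroc(a, b, "discretized12") == pytest.approx(
        compute_auroc(a, b))


def test_permutation_p_never_zero_and_detects_separation():
    rng = np.random.default_rng(0)
    si, p, null = permutation_si_test(
        np.arange(20, 40), np.arange(0, 20), n_perm=500, rng=rng)
    assert si == 1.0
    assert 0 < p <= 2 / 501 + 1e-12
    assert len(null) == 500


def _two_cue_session(gain_a, gain_b, n=30, seed=0, baseline=5.0):
    cfg = SessionConfig(n_permutations=300)
    trials = make_trials(["A3k", "A10k"], n, rng=seed)
    spec = NeuronSpec(baseline_rate=baseline,
                      auditory_gain={"A3k": gain_b, "A10k": gain_a})
    spikes = generate_spikes([spec], trials, cfg, np.random.default_rng(seed))
    return neuron_spikes(spikes, "n0000"), trials, cfg


def test_selectivity_label_swap_negates_si():
    sp, trials, cfg = _two_cue_session(10.0, 0.0)
    r1 = selectivity_index(sp, trials, "A10k", "A3k", None, cfg, 1)
    r2 = selectivity_index(sp, trials, "A3k", "A10k", None, cfg, 1)
    assert r1.si == pytest.approx(-r2.si)
    assert r1.si > 0 and r1.significant


def test_identical_conditions_nonselective():
    sp, trials, cfg = _two_cue_session(6.0, 6.0, seed=4)
    r = selectivity_index(sp, trials, "A10k", "A3k", None, cfg, 2)
    assert abs(r.si) < 0.35 and r.p_value > 0.05


def test_insufficient_trials_error_names_cue():
    sp, trials, cfg = _two_cue_session(5.0, 5.0, n=30)
    few = trials.drop(trials.loc[trials.cue == "A10k"].index[3:])
    with pytest.raises(ValueError, match="A10k"):
        selectivity_index(sp, few, "A10k", "A3k", None, cfg, 0)


def _av_session(g_a, g_v, c, n=30, seed=0, shrink=1.0, p_correct=1.0,
                baseline=5.0, n_perm=300):
    cfg = SessionConfig(n_permutations=n_perm)
    trials = make_trials(["A10k", "Vvt", "A10kVvt"], n, p_correct=p_correct,
                         rng=seed)
    spec = NeuronSpec(baseline_rate=baseline,
                      auditory_gain={"A3k": 0.0, "A10k": g_a},
                      visual_gain={"Vhz": 0.0, "Vvt": g_v},
                      interaction={"A10kVvt": c, "A3kVhz": 1.0,
                                   "A10kVhz": 1.0, "A3kVvt": 1.0},
                      incorrect_interaction_shrink=shrink)
    spikes = generate_spikes([spec], trials, cfg,
                             np.random.default_rng(seed + 100))
    return neuron_spikes(spikes, "n0000"), trials, cfg


def test_stronger_unisensory_tie_breaks_auditory():
    trials = make_trials(["A10k", "Vvt", "A10kVvt"], 5)
    times = {}
    for tid in trials["trial_id"]:
        times[tid] = [10.0, 20.0]  # identical everywhere
    sp = make_spike_frame(times)
    mod, cue = stronger_unisensory_cue(sp, trials, "A10kVvt")
    assert (mod, cue) == ("auditory", "A10k")
    r = msi(sp, trials, "A10kVvt")
    assert r.msi == 0.0 and r.classification == "null"


def test_msi_enhancement_detected():
    sp, trials, cfg = _av_session(16.0, 5.0, 2.0, seed=1)
    r = msi(sp, trials, "A10kVvt", None, cfg, 3)
    assert r.stronger_unisensory == "auditory"
    assert r.msi > 0.3 and r.classification == "enhanced"


def test_msi_complete_suppression_is_minus_one():
    trials = make_trials(["A10k", "Vvt", "A10kVvt"], 6)
    times = {}
    for tid, cue in zip(trials["trial_id"], trials["cue"]):
        times[tid] = [float(5 + i) for i in range(8)] if cue != "A10kVvt" else []
    sp = make_spike_frame(times)
    r = msi(sp, trials, "A10kVvt")
    assert r.msi == -1.0 and r.classification == "inhibited"


def test_msi_by_choice_excludes_below_trial_minimum():
    sp, trials, cfg = _av_session(10.0, 5.0, 1.5, n=40, p_correct=0.85, seed=2)
    # incorrect trials per cue ~6 < 9
    with pytest.raises(ValueError, match="excluded"):
        msi_by_choice(sp, trials, "A10kVvt", cfg, 0)


def test_msi_by_choice_detects_shrink():
    sp, trials, cfg = _av_session(15.0, 12.0, 2.0, n=60, p_correct=0.7,
                                  shrink=0.0, seed=5)
    ok, bad = msi_by_choice(sp, trials, "A10kVvt", cfg, 0)
    assert ok.msi > bad.msi


def test_delta_correlation_perfect_line():
    x = np.linspace(-0.5, 0.5, 10)
    pairs, r, p = delta_msi_vs_delta_selectivity(x, np.zeros(10), x, np.zeros(10))
    assert r == pytest.approx(1.0)
    assert pairs.shape == (10, 2)


def test_delta_correlation_needs_three_neurons():
    with pytest.raises(ValueError):
        delta_msi_vs_delta_selectivity([0.1], [0.0], [0.1], [0.0])
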