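import numpy as np
import pytest

from avcortex.io_model import SessionConfig
from avcortex.psth import (
    classify_responsiveness,
    count_in_window,
    gaussian_smooth,
    make_psth,
    mean_rate,
    neuron_spikes,
    window_rate,
)
from avcortex.synthdata import NeuronSpec, generate_spikes

from conftest import make_spike_frame, make_trials


def test_count_and_rate_arithmetic():
    trials = make_trials(["A3k"], 1)
    spikes = make_spike_frame({1: [5.0]})
    c = count_in_window(spikes, [1], (0.0, 150.0))
    assert c.loc[1] == 1
    assert window_rate(c.loc[1], (0.0, 150.0)) == pytest.approx(1000 / 150)


def test_half_open_window_excludes_right_edge():
    spikes = make_spike_frame({1: [150.0]})
    assert count_in_window(spikes, [1], (0.0, 150.0)).loc[1] == 0
    assert count_in_window(spikes, [1], (150.0, 300.0)).loc[1] == 1


def test_empty_selection_rejected():
    spikes = make_spike_frame({1: [5.0]})
    with pytest.raises(ValueError, match="empty"):
        count_in_window(spikes, [], (0.0, 150.0))


def test_poisson_window_count_oracle():
    """Homogeneous 20 spikes/s: mean count in [0,150) is 3."""
    cfg = SessionConfig()
    trials = make_trials(["A3k"], 1000)
    spikes = generate_spikes([NeuronSpec(baseline_rate=20.0)], trials, cfg,
                             np.random.default_rng(0))
    counts = count_in_window(neuron_spikes(spikes, "n0000"),
                             trials["trial_id"], (0.0, 150.0)).to_numpy()
    se = np.sqrt(3.0 / 1000)
    assert abs(counts.mean() - 3.0) < 3 * se


def test_bins_partition_epoch():
    """Summed bin counts equal the number of in-epoch spikes."""
    cfg = SessionConfig()
    trials = make_trials(["A3k"], 20)
    spikes = generate_spikes([NeuronSpec(baseline_rate=15.0)], trials, cfg,
                             np.random.default_rng(1))
    p = make_psth(neuron_spikes(spikes, "n0000"), trials, "A3k", cfg)
    total = p.rate.sum() * cfg.bin_ms * p.n_trials / 1000.0
    assert total == pytest.approx(len(spikes))


def test_single_spike_psth_bin_rate():
    trials = make_trials(["A3k"], 1)
    spikes = make_spike_frame({1: [5.0]})
    p = make_psth(spikes, trials, "A3k")
    centers = p.bin_centers_ms
    hot = (centers > 0) & (centers < 10)
    assert p.rate[hot] == pytest.approx([100.0])
    assert p.rate[~hot].sum() == 0.0


def test_smoothing_preserves_integral():
    rng = np.random.default_rng(2)
    v = rng.uniform(0, 50, 220)
    s = gaussian_smooth(v, 5.0)
    interior = slice(20, -20)
    assert s[interior].sum() == pytest.approx(v[interior].sum(), rel=0.01)
    # and exactly overall thanks to edge renormalization of a flat signal
    flat = gaussian_smooth(np.ones(100), 5.0)
    np.testing.assert_allclose(flat, 1.0)


def test_z_rate_null_near_zero():
    """Constant-rate Poisson: post-cue z-scores fluctuate around 0."""
    cfg = SessionConfig()
    trials = make_trials(["A3k"], 60)
    zs = []
    rng = np.random.default_rng(3)
    for _ in range(20):
        spikes = generate_spikes([NeuronSpec(baseline_rate=12.0)], trials,
                                 cfg, rng)
        p = make_psth(neuron_spikes(spikes, "n0000"), trials, "A3k", cfg)
        post = p.bin_centers_ms > 0
        zs.append(p.z_rate[post].mean())
    zs = np.asarray(zs)
    assert abs(zs.mean()) < 3 * zs.std(ddof=1) / np.sqrt(len(zs))


def test_zero_baseline_sd_flagged_degenerate():
    trials = make_trials(["A3k"], 1)
    spikes = make_spike_frame({1: [400.0]})  # silent baseline
    p = make_psth(spikes, trials, "A3k")
    assert p.degenerate and p.z_rate is None


def test_zero_spikes_unresponsive():
    trials = make_trials(["A3k", "A10k", "Vhz", "Vvt", "A3kVhz", "A10kVvt"], 10)
    spikes = make_spike_frame({})
    call = classify_responsiveness(spikes, trials)
    assert call.category == "unresponsive"
    assert all(call.degenerate.values())


def test_rate_gate_blocks_small_evoked_response():
    """A reliable but sub-threshold (<2 spikes/s) response is not
    counted as responsive even though the signed-rank p is tiny."""
    trials = make_trials(["A3k", "A10k", "Vhz", "Vvt", "A3kVhz", "A10kVvt"], 30)
    # one spike in the 300 ms window on 14 of 30 A3k trials -> 1.56 Hz evoked
    hot = trials.loc[trials.cue == "A3k", "trial_id"].iloc[:14]
    spikes = make_spike_frame({tid: [50.0] for tid in hot})
    call = classify_responsiveness(spikes, trials)
    assert call.evoked_rate["A3k"] == pytest.approx(14 / 30 * 1000 / 300, rel=1e-6)
    assert call.p_value["A3k"] < 0.05
    assert not call.responsive["A3k"]


def test_strong_response_detected_and_categorized():
    cfg = SessionConfig()
    trials = make_trials(["A3k", "A10k", "Vhz", "Vvt", "A3kVhz", "A10kVvt"], 30)
    spec = NeuronSpec(baseline_rate=1.0,
                      auditory_gain={"A3k": 0.0, "A10k": 20.0},
                      visual_gain={"Vhz": 0.0, "Vvt": 0.0})
    spikes = generate_spikes([spec], trials, cfg, np.random.default_rng(4))
    call = classify_responsiveness(neuron_spikes(spikes, "n0000"), trials, cfg)
    assert call.responsive["A10k"]
    assert call.category == "A-only"


def test_mean_rate_filter_value():
    cfg = SessionConfig()
    trials = make_trials(["A3k"], 10)
    # 22 spikes over 10 trials x 2.2 s epoch = 1 Hz
    times = {tid: [float(i) for i in range(22)] for tid in [1]}
    spikes = make_spike_frame(times)
    assert mean_rate(spikes, trials, cfg) == pytest.approx(1.0)
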