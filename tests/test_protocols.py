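import numpy as np
import pandas as pd
import pytest
from scipy.special import i0

from attnet import (
    AttentionSpec,
    ModelParams,
    StimulusSpec,
    attention_drive,
    run_attention_task,
    run_sensory_task,
    select_control_neurons,
    sensory_stimulus_set,
    stimulus_drive,
)
from attnet.protocols import RateData


class TestStimulusDrive:
    def test_zero_strength_gives_zero_drive(self, mini_params):
        d = stimulus_drive(StimulusSpec(0, 90.0, 0.0), mini_params)
        assert not d.any()

    def test_peak_density_and_truncation(self, mini_params):
        p = mini_params
        d = stimulus_drive(StimulusSpec(0, 90.0, 10.0), p)
        ring = d[: p.n_first_per_sub]
        theta = np.deg2rad(360.0 * np.arange(p.n_first_per_sub) / p.n_first_per_sub)
        # peak at the neuron nearest mu, value S*e^k/(2 pi I0(k))
        assert ring.argmax() == round(90 / 360 * p.n_first_per_sub)
        assert ring.max() == pytest.approx(10 * np.exp(14) / (2 * np.pi * i0(14)))
        # zero beyond three standard deviations (sigma = 1/sqrt(kappa))
        delta = np.abs((theta - np.pi / 2 + np.pi) % (2 * np.pi) - np.pi)
        assert not ring[delta > 3 / np.sqrt(14)].any()
        assert ring[delta <= 2.9 / np.sqrt(14)].all()
        # other sub-networks silent
        assert not d[p.n_first_per_sub :].any()

    def test_symmetry_about_mu(self, mini_params):
        p = mini_params
        d = stimulus_drive(StimulusSpec(0, 180.0, 5.0), p)[: p.n_first_per_sub]
        center = p.n_first_per_sub // 2
        left = d[center - 10 : center]
        right = d[center + 1 : center + 11][::-1]
        assert np.allclose(left, right)

    def test_rejects_bad_specs(self, mini_params):
        with pytest.raises(ValueError):
            StimulusSpec(0, 0.0, 1.0)  # angle outside (0, 360]
        with pytest.raises(ValueError):
            stimulus_drive(StimulusSpec(9, 90.0, 1.0), mini_params)


class TestAttentionSpec:
    def test_mode_validation(self):
        with pytest.raises(ValueError):
            AttentionSpec(strength=-1.0)
        with pytest.raises(ValueError):
            AttentionSpec(strength=0.5, mode="multiplicative")
        with pytest.raises(ValueError):
            AttentionSpec(proportion=0.0)
        with pytest.raises(ValueError):
            AttentionSpec(mode="divisive")

    def test_drive_vectors(self, mini_params):
        spec = AttentionSpec(target_deg=90.0, strength=6.0, target_ids=(1, 5))
        add, mult = attention_drive(spec, mini_params)
        assert mult is None
        assert add[1] == add[5] == 6.0 and add.sum() == 12.0
        spec = AttentionSpec(target_deg=90.0, strength=3.0,
                             mode="multiplicative", target_ids=(2,))
        add, mult = attention_drive(spec, mini_params)
        assert not add.any()
        assert mult[2] == 3.0 and np.all(np.delete(mult, 2) == 1.0)


def test_sensory_stimulus_set_tiles_circle():
    s = sensory_stimulus_set()
    assert len(s) == 16
    assert s[0] == 22.5 and s[-1] == 360.0
    assert np.allclose(np.diff(s), 22.5)


class TestSelection:
    def _fake_sensory(self, n_second, n_trials=10, n_first=32, seed=0):
        rng = np.random.default_rng(seed)
        stims = np.repeat([90.0, 270.0], n_trials)
        rates = rng.random((stims.size, n_first + n_second))
        return RateData(rates, pd.DataFrame({"stimulus_deg": stims})), rates

    def test_top_fraction_count_uses_floor(self):
        data, _ = self._fake_sensory(n_second=1024)
        assert select_control_neurons(data, 90.0, 0.2, n_second=1024).size == 204
        assert select_control_neurons(data, 90.0, 1.0, n_second=1024).size == 1024

    def test_selects_highest_mean_responders(self):
        data, rates = self._fake_sensory(n_second=64)
        ids = select_control_neurons(data, 90.0, 0.25, n_second=64)
        mask = data.meta["stimulus_deg"].to_numpy() == 90.0
        means = rates[mask, 32:].mean(axis=0)
        expected = np.sort(np.argsort(-means, kind="stable")[:16])
        assert np.array_equal(ids, expected)

    def test_unknown_target_angle_rejected(self):
        data, _ = self._fake_sensory(n_second=64)
        with pytest.raises(ValueError):
            select_control_neurons(data, 45.0, 0.2, n_second=64)

    def test_selection_is_stimulus_specific(self, experiment):
        """Targets for opposite stimuli overlap less than chance."""
        p = experiment.params
        for init in experiment.inits:
            t90, t270 = init.targets[90.0], init.targets[270.0]
            chance = t90.size * t270.size / p.n_second  # hypergeometric mean
            assert t90.size == int(0.2 * p.n_second) == 204
            assert len(set(t90) & set(t270)) < chance


class TestAttentionTask:
    def test_grid_and_pairing(self, mini_conn, mini_params):
        p = mini_params
        ids = {90.0: np.arange(10), 270.0: np.arange(10, 20)}
        data = run_attention_task(
            mini_conn, ids, p, seed=1,
            stim_strengths=range(20), att_strengths=range(0, 19, 2),
            n_trials=1, duration_ms=10.0, baseline_ms=0.0, window_ms=10.0,
        )
        meta = data.meta
        cells = meta.groupby(["stim_strength", "att_strength", "attended_deg"])
        assert len(cells) == 20 * 10 * 2
        assert data.rates.shape == (400, p.n_total)
        # the two stimuli are always 180 degrees apart
        assert (
            np.abs(meta["attended_deg"] - meta["unattended_deg"]) == 180.0
        ).all()

    def test_missing_targets_rejected(self, mini_conn, mini_params):
        with pytest.raises(ValueError):
            run_attention_task(mini_conn, {90.0: np.arange(5)}, mini_params,
                               attended_degs=(90.0, 270.0), n_trials=1,
                               duration_ms=10.0, baseline_ms=0.0, window_ms=10.0)

    def test_zero_additive_equals_unity_multiplicative(self, mini_conn, mini_params):
        """No-modulation baselines coincide bit-for-bit across modes."""
        ids = {90.0: np.arange(20)}
        kw = dict(stim_strengths=[6.0], attended_degs=(90.0,), n_trials=3,
                  duration_ms=60.0, baseline_ms=20.0, window_ms=50.0, seed=5)
        add = run_attention_task(mini_conn, ids, mini_params,
                                 att_strengths=[0.0], mode="additive", **kw)
        mult = run_attention_task(mini_conn, ids, mini_params,
                                  att_strengths=[1.0], mode="multiplicative", **kw)
        assert np.array_equal(add.rates, mult.rates)


def test_targeting_proportion_sweep_keeps_gain_sign(experiment):
    """Modulating 10%, 20%, 40% or 100% of control neurons changes the
    strength of the attentional rate increase, never its direction."""
    from attnet import compute_crf, run_attention_task, select_control_neurons

    init = experiment.inits[0]
    p = experiment.params
    for proportion in (0.1, 0.2, 0.4, 1.0):
        targets = {
            90.0: select_control_neurons(init.sensory, 90.0, proportion, params=p)
        }
        att = run_attention_task(
            init.conn, targets, p, seed=31,
            stim_strengths=[6.0], att_strengths=[0.0, 4.0],
            attended_degs=(90.0,), n_trials=8, proportion=proportion,
            duration_ms=400.0, baseline_ms=0.0, window_ms=250.0,
        )
        crf = compute_crf(att, p).set_index("att_strength")
        assert crf.loc[4.0, "attended_rate"] > crf.loc[0.0, "attended_rate"]


def test_run_experiment_structure(mini_params):
    from attnet import run_experiment

    res = run_experiment(
        mini_params, n_inits=2, master_seed=4,
        sensory_kwargs=dict(stimuli_deg=[90.0, 270.0], n_trials=3,
                            duration_ms=60.0, baseline_ms=20.0, window_ms=50.0),
        attention_kwargs=dict(stim_strengths=[6.0], att_strengths=[0.0, 4.0],
                              n_trials=2, duration_ms=60.0, baseline_ms=20.0,
                              window_ms=50.0),
    )
    assert len(res.per_seed) == 2
    a, b = res.per_seed
    assert a.seed != b.seed
    # different wiring -> different rates; identical protocol metadata
    assert not np.array_equal(a.attention.rates, b.attention.rates)
    assert a.attention.meta.equals(b.attention.meta)
    assert set(a.target_ids) == {90.0, 270.0}
    summary = res.crf_summary()
    assert {"attended_rate_mean", "attended_rate_sem"} <= set(summary.columns)
    assert len(summary) == 2  # one stimulus strength x two attention levels
    with pytest.raises(ValueError):
        run_experiment(mini_params, n_inits=0)
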