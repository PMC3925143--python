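"""Simulator tests: pairwise-oracle agreement, determinism, bounds."""

from dataclasses import replace

import numpy as np
import pytest

import dstdp
from dstdp import brute_force_weight_oracle, depression_amplitude
from dstdp.exceptions import InstanceTooLargeError, ParameterError
from dstdp.inputs import poisson_raster


def run_cfg(mode="additive", d=0.5, **kw):
    seed = kw.pop("seed", 0)
    return dstdp.default_config(mode, d, **kw).with_seed(seed)


class TestOracleEquivalence:
    @pytest.mark.parametrize("mode,bounded,plateau", [
        ("additive", True, False), ("additive", False, False),
        ("mixed", True, False), ("mixed", False, False),
        ("additive", True, True), ("mixed", True, True),
    ])
    @pytest.mark.parametrize("seed", [11, 12, 13])
    def test_trace_weights_match_chronological_pair_sum(self, mode, bounded,
                                                        plateau, seed):
        """On 1-s instances (~1e4 presynaptic and tens of postsynaptic
        spikes) the online traces must reproduce the brute-force pair sum to
        float accuracy, in both update modes, with and without the bound."""
        cfg = run_cfg(mode, duration_s=1.0, w_init=0.12, bounded=bounded,
                      plateau_pairing=plateau, seed=seed)
        res = dstdp.run(cfg)
        assert res.n_post_spikes > 10
        raster = poisson_raster(cfg.inputs, 1000.0)
        w_oracle = brute_force_weight_oracle(raster, res.post_spike_times_ms,
                                             cfg)
        rel = np.abs(res.final_weights - w_oracle) / np.maximum(
            np.abs(w_oracle), 1e-12)
        tol = 1e-8 if mode == "mixed" else 1e-10
        assert rel.max() < tol

    def test_empty_raster_returns_initial_weights(self, tiny_raster):
        cfg = run_cfg(duration_s=1.0, w_init=0.06)
        w = brute_force_weight_oracle(tiny_raster([]), np.array([]), cfg)
        assert np.allclose(w, 0.06)

    def test_instance_size_guard(self, tiny_raster):
        cfg = run_cfg(duration_s=1.0)
        raster = tiny_raster([(b, 0) for b in range(100)])
        with pytest.raises(InstanceTooLargeError):
            brute_force_weight_oracle(raster, np.arange(100.0), cfg,
                                      max_pairs=10)


class TestSinglePairSemantics:
    """Hand-evaluated single pre/post pairs through the pairing oracle."""

    def test_causal_pair_gets_exponential_potentiation(self, tiny_raster):
        # pre 10 ms before the AP onset: +A+ e^(-10/20) g_max
        cfg = run_cfg("additive", d=2.0, w_init=0.06)
        w = brute_force_weight_oracle(tiny_raster([(0, 0)]), np.array([10.0]),
                                      cfg)
        g = cfg.run.g_max
        assert w[0] == pytest.approx(0.06 + 0.005 * np.exp(-0.5) * g, rel=1e-12)
        assert np.allclose(w[1:], 0.06)

    def test_pre_during_ap_plateau_vs_refractory_gating(self, tiny_raster):
        # pre 1 ms after AP onset with d = 2 ms: +A+ g_max when the plateau
        # is credited, no change under the default refractory gating
        raster = tiny_raster([(10, 3)])
        for plateau, dw in ((True, 0.005), (False, 0.0)):
            cfg = run_cfg("additive", d=2.0, w_init=0.06,
                          plateau_pairing=plateau)
            w = brute_force_weight_oracle(raster, np.array([0.0]), cfg)
            assert w[3] == pytest.approx(0.06 + dw * cfg.run.g_max, rel=1e-12)

    def test_pre_after_ap_end_gets_anchored_depression(self, tiny_raster):
        # pre at t0 + d + 20 ms: -B(d) e^-1 (x g_max additive, x w mixed)
        for mode in ("additive", "mixed"):
            cfg = run_cfg(mode, d=2.0, w_init=0.06)
            b = depression_amplitude(cfg.window)
            w = brute_force_weight_oracle(tiny_raster([(220, 0)]),
                                          np.array([0.0]), cfg)
            scale = cfg.run.g_max if mode == "additive" else 0.06
            assert w[0] == pytest.approx(0.06 - b * np.exp(-1.0) * scale,
                                         rel=1e-9)

    def test_first_pre_spike_with_no_posts_changes_nothing(self, tiny_raster):
        cfg = run_cfg("additive", d=2.0, w_init=0.06)
        w = brute_force_weight_oracle(tiny_raster([(50, 2)]), np.array([]), cfg)
        assert np.allclose(w, 0.06)


class TestRunContract:
    def test_identical_seed_gives_bit_identical_results(self):
        cfg = run_cfg(duration_s=10.0, seed=77)
        a, b = dstdp.run(cfg), dstdp.run(cfg)
        assert np.array_equal(a.final_weights, b.final_weights)
        assert np.array_equal(a.rate_trace, b.rate_trace)
        assert np.array_equal(a.post_spike_times_ms, b.post_spike_times_ms)
        assert np.array_equal(a.weight_snapshots, b.weight_snapshots)

    def test_zero_weights_and_no_inputs_stay_silent(self):
        cfg = run_cfg(duration_s=2.0, w_init=0.0, plasticity_on=False)
        cfg = replace(cfg, inputs=replace(cfg.inputs, rate_exc=0.0,
                                          rate_inh=0.0))
        res = dstdp.run(cfg)
        assert res.n_post_spikes == 0
        assert np.all(res.final_weights == 0.0)

    def test_bounded_weights_stay_in_range_throughout(self):
        cfg = run_cfg("additive", d=0.1, duration_s=100.0, seed=5)
        res = dstdp.run(cfg)
        assert res.weight_snapshots.min() >= 0.0
        assert res.weight_snapshots.max() <= cfg.run.g_max + 1e-12
        assert res.n_post_spikes > 50

    def test_config_consistency_is_enforced(self):
        with pytest.raises(ParameterError):
            dstdp.SimConfig(window=dstdp.WindowParams(ap_duration=1.0),
                            neuron=dstdp.NeuronParams(ap_duration=2.0))
        with pytest.raises(ParameterError):
            dstdp.default_config("additive", 0.1, dt=0.2)

    def test_mixed_equilibrium_forgets_igniting_initial_condition(self):
        """Mixed-mode runs started from different (firing) initial weights
        converge to the same weight-dependent equilibrium."""
        means = []
        for frac in (0.5, 0.75, 1.0):
            cfg = run_cfg("mixed", d=0.1, duration_s=300.0,
                          w_init=frac * 0.15, seed=3)
            means.append(dstdp.run(cfg).final_weights.mean())
        assert max(means) / min(means) < 1.2
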