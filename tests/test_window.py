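"""Unit and property tests of the dSTDP pairing window."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from dstdp import (ADDITIVE, MIXED, WindowParams, apply_update,
                   depression_amplitude, kernel_table, window_integral_ratio,
                   window_value)
from dstdp.exceptions import ParameterError, StateCorruptionError


def wp(mode=ADDITIVE, d=2.0, **kw):
    return WindowParams(mode=mode, ap_duration=d, **kw)


class TestDepressionAmplitude:
    @pytest.mark.parametrize("d, expected", [
        # frozen from the quadrature oracle: B = r * A+ * (tau+ + d) / tau-
        (0.0, 0.00525),
        (2.0, 0.005775),
    ])
    def test_closed_form_matches_quadrature_normalization(self, d, expected):
        p = wp(d=d)
        b = depression_amplitude(p)
        assert b == pytest.approx(expected, rel=1e-12)
        # independent check: with this peak, the lobe ratio equals r
        assert window_integral_ratio(p) == pytest.approx(p.ratio, rel=1e-9)

    def test_affine_strictly_increasing_in_duration(self):
        ds = np.linspace(0, 5, 11)
        bs = np.array([depression_amplitude(wp(d=d)) for d in ds])
        assert np.all(np.diff(bs) > 0)
        slopes = np.diff(bs) / np.diff(ds)
        assert np.allclose(slopes, slopes[0], rtol=1e-12)

    def test_vanishes_as_learning_ratio_vanishes(self):
        # depression disappears when the required depression area -> 0
        assert depression_amplitude(wp(ratio=1e-9)) < 1e-10


class TestWindowValue:
    def test_examples(self):
        p = wp(d=2.0)
        assert window_value(20.0, p) == pytest.approx(0.005 * np.exp(-1.0), rel=1e-12)
        assert window_value(-1.0, p) == pytest.approx(0.005)  # inside plateau
        assert window_value(0.0, p) == pytest.approx(0.005)   # tie-break: plateau
        assert window_value(-2.0, p) == pytest.approx(0.005)  # AP end inclusive
        assert window_value(-22.0, p) == pytest.approx(
            -depression_amplitude(p) * np.exp(-1.0), rel=1e-12)
        assert abs(window_value(400.0, p)) < 1e-10
        assert abs(window_value(-400.0, p)) < 1e-10

    def test_zero_duration_recovers_canonical_two_exponential_kernel(self):
        p = wp(d=0.0)
        ts = np.linspace(0.1, 100, 57)
        assert np.allclose(window_value(ts, p), 0.005 * np.exp(-ts / 20.0))
        assert np.allclose(window_value(-ts, p),
                           -1.05 * 0.005 * np.exp(-ts / 20.0))

    def test_continuity_and_single_jump_at_ap_end(self):
        p = wp(d=2.0)
        eps = 1e-9
        # continuous at the LTP/plateau junction
        assert window_value(eps, p) == pytest.approx(window_value(-eps, p),
                                                     abs=1e-11)
        # sign jump at the plateau/LTD junction of size A+ + B(d)
        jump = window_value(-2.0 + eps, p) - window_value(-2.0 - eps, p)
        assert jump == pytest.approx(0.005 + depression_amplitude(p), rel=1e-6)

    def test_rejects_non_finite_interval(self):
        with pytest.raises(ParameterError):
            window_value(np.nan, wp())


class TestIntegralRatio:
    @given(d=st.floats(0.0, 5.0), ratio=st.floats(1.01, 3.0),
           tau=st.floats(5.0, 50.0))
    def test_area_ratio_equals_learning_ratio_for_every_duration(self, d, ratio, tau):
        p = WindowParams(ap_duration=d, ratio=ratio, tau_plus=tau, tau_minus=tau)
        assert window_integral_ratio(p) == pytest.approx(ratio, rel=1e-9)

    def test_mode_defaults(self):
        assert window_integral_ratio(wp(ADDITIVE)) == pytest.approx(1.05, rel=1e-9)
        assert window_integral_ratio(wp(MIXED)) == pytest.approx(2.0, rel=1e-9)


class TestApplyUpdate:
    def test_additive_update_is_weight_independent(self):
        p = wp(ADDITIVE)
        assert apply_update(0.5, 0.005, 1.0, p) == pytest.approx(0.505)
        assert apply_update(0.5, -0.005, 1.0, p) == pytest.approx(0.495)

    def test_additive_clips_at_bound(self):
        p = wp(ADDITIVE)
        assert apply_update(1.0, 0.005, 1.0, p, bounded=True) == 1.0
        assert apply_update(1.0, 0.005, 1.0, p, bounded=False) == pytest.approx(1.005)
        assert apply_update(0.001, -0.005, 1.0, p) == 0.0

    def test_mixed_depression_scales_with_weight_and_fixes_zero(self):
        p = wp(MIXED)
        assert apply_update(0.5, -0.01, 1.0, p) == pytest.approx(0.495)
        assert apply_update(0.0, -0.01, 1.0, p) == 0.0  # multiplicative LTD fixed point
        # potentiation stays additive in g_max
        assert apply_update(0.5, 0.005, 1.0, p) == pytest.approx(0.505)

    def test_negative_weight_is_state_corruption(self):
        with pytest.raises(StateCorruptionError):
            apply_update(-0.1, 0.005, 1.0, wp())


class TestValidation:
    @pytest.mark.parametrize("kw", [
        dict(a_plus=0.0), dict(tau_plus=0.0), dict(tau_minus=-1.0),
        dict(ap_duration=-0.1), dict(ratio=0.0), dict(mode="triplet"),
    ])
    def test_invalid_parameters_rejected(self, kw):
        with pytest.raises(ParameterError):
            WindowParams(**kw)


def test_kernel_table_matches_window_function():
    p = wp(d=1.0)
    tab = kernel_table(p, -50, 50, 0.5)
    assert tab.shape == (201, 2)
    assert np.allclose(tab[:, 1], window_value(tab[:, 0], p))
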