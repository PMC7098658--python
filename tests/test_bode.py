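import math

import numpy as np
import pytest

from essclock.bode import (
    BodeCurve,
    SweepConfig,
    SweepError,
    corner_frequency,
    estimate_order,
    first_order_lowpass,
    linear_tf_bode,
    magnitude_slope,
    phase_at,
    shuttling_system,
    sine_sweep,
)

OMEGA = np.logspace(math.log10(0.01), math.log10(2.0), 25)


@pytest.fixture(scope="module")
def first_order_sweep():
    return sine_sweep(first_order_lowpass(0.05), SweepConfig(omega=OMEGA))


class TestOracle:
    def test_single_pole_reference_point(self):
        curve = linear_tf_bode([-1.0], [], 1.0, omega=np.array([1.0]))
        assert curve.magnitude_db[0] == pytest.approx(-10 * math.log10(2.0), abs=1e-9)
        assert curve.phase_deg[0] == pytest.approx(-45.0, abs=1e-9)

    def test_dc_gain_limit(self):
        curve = linear_tf_bode([-0.5, -2.0], [], 3.0, omega=np.array([1e-6]))
        # |G(0)| = gain / |prod poles|
        assert curve.magnitude_db[0] == pytest.approx(20 * math.log10(3.0 / 1.0), abs=1e-3)

    def test_unstable_pole_rejected(self):
        with pytest.raises(ValueError):
            linear_tf_bode([0.1], [], 1.0)

    def test_second_order_coincident_pole_corner(self):
        # (1 + x^2)^2 = 2 at x = sqrt(sqrt(2) - 1) => corner = 0.1 * 0.6436
        curve = linear_tf_bode([-0.1, -0.1], [], 0.01, omega=np.logspace(-3, 0, 200))
        assert corner_frequency(curve) == pytest.approx(0.1 * math.sqrt(math.sqrt(2.0) - 1.0), rel=0.02)


class TestSweep:
    def test_low_frequency_plateau_is_unit_gain(self, first_order_sweep):
        # at the lowest swept frequency (0.01 rad/h, a fifth of the corner)
        # the true first-order gain is -10*log10(1.04) = -0.17 dB
        assert first_order_sweep.magnitude_db[0] == pytest.approx(0.0, abs=0.25)

    def test_corner_detected_near_true_pole(self, first_order_sweep):
        assert first_order_sweep.corner_frequency == pytest.approx(0.05, rel=0.10)

    def test_phase_at_corner_is_minus_45(self, first_order_sweep):
        ph = phase_at(first_order_sweep, first_order_sweep.corner_frequency)
        assert ph == pytest.approx(-45.0, abs=2.0)

    def test_linear_system_flagged_linear_dominant(self, first_order_sweep):
        assert first_order_sweep.linear_dominant

    def test_matches_closed_form_everywhere(self, first_order_sweep):
        oracle = linear_tf_bode([-0.05], [], 0.05, omega=OMEGA)
        assert np.max(np.abs(first_order_sweep.magnitude_db - oracle.magnitude_db)) < 0.5
        assert np.max(np.abs(first_order_sweep.phase_deg - oracle.phase_deg)) < 3.0

    def test_amplitude_invariance_in_linear_regime(self):
        base = sine_sweep(first_order_lowpass(0.05), SweepConfig(omega=OMEGA[::4], amplitude=0.1))
        half = sine_sweep(first_order_lowpass(0.05), SweepConfig(omega=OMEGA[::4], amplitude=0.05))
        assert np.max(np.abs(base.magnitude_db - half.magnitude_db)) < 0.2

    def test_magnitude_monotone_beyond_plateau(self, first_order_sweep):
        mags = first_order_sweep.magnitude_db
        assert np.all(np.diff(mags) < 1e-3)


class TestOrderEstimation:
    # second order realised as a Butterworth pair so the -3 dB point carries
    # the textbook -90 degree phase
    _BUTTER2 = [0.05 * np.exp(1j * 3 * np.pi / 4), 0.05 * np.exp(-1j * 3 * np.pi / 4)]

    @pytest.mark.parametrize(
        "poles, expected_order",
        [([-0.05], 1), (_BUTTER2, 2)],
    )
    def test_pure_low_pass_orders(self, poles, expected_order):
        gain = np.prod(np.abs(poles))  # unit DC gain
        curve = linear_tf_bode(poles, [], gain, omega=np.logspace(-3, 1, 300))
        est = estimate_order(curve)
        assert est.order == expected_order
        assert not est.ambiguous
        assert est.phase_at_corner_deg == pytest.approx(-45.0 * expected_order, abs=3.0)

    def test_separated_poles_read_first_order(self):
        # two-compartment shuttling with pole ratio ~33 collapses to one
        # effective pole, justifying the aggregated-protein reduction
        system = shuttling_system(a=1.0, r_C=1.0, b_C=5.0, r_N=0.1, b_N=0.1)
        rate_matrix = np.array([[-6.0, 0.1], [1.0, -0.2]])
        poles = np.linalg.eigvals(rate_matrix)
        assert max(abs(poles)) / min(abs(poles)) > 25
        curve = sine_sweep(system, SweepConfig(omega=OMEGA))
        est = estimate_order(curve)
        assert est.order == 1

    def test_sweep_matches_linearisation_oracle(self):
        system = shuttling_system(a=1.0, r_C=1.0, b_C=5.0, r_N=0.1, b_N=0.1)
        poles = np.linalg.eigvals(np.array([[-6.0, 0.1], [1.0, -0.2]]))
        swept = sine_sweep(system, SweepConfig(omega=OMEGA))
        oracle = linear_tf_bode(poles, [], 1.0, omega=OMEGA)
        dmag = (swept.magnitude_db - swept.magnitude_db[0]) - (
            oracle.magnitude_db - oracle.magnitude_db[0]
        )
        assert np.max(np.abs(dmag)) < 0.5
        assert np.max(np.abs(swept.phase_deg - oracle.phase_deg)) < 3.0


def test_flat_curve_has_no_corner():
    flat = BodeCurve(omega=OMEGA, magnitude_db=np.zeros_like(OMEGA), phase_deg=np.zeros_like(OMEGA))
    with pytest.raises(SweepError, match="corner"):
        corner_frequency(flat)
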