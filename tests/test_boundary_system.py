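"""Oriented contrast and gated-dipole habituation dynamics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra import numpy as hnp

from contourfill import (DipoleParams, Frame, dipole_output,
                         oriented_contrast, simulate_dipole_trace,
                         step_gates, to_opponent)
from contourfill.boundary_system import (GateState, OrientedDrive,
                                         gate_equilibrium)

P = DipoleParams()


def _drive_from(lum):
    return oriented_contrast(to_opponent(Frame(np.asarray(lum, float), 1.0),
                                         0.5), P)


class TestOrientedContrast:
    def test_uniform_field_gives_no_drive(self):
        d = _drive_from(np.full((6, 6), 0.7))
        assert np.all(d.vertical == 0) and np.all(d.horizontal == 0)

    def test_vertical_step_edge_drives_vertical_channel_only(self):
        # left half 0.6, right half 0.5: a vertical luminance edge
        lum = np.full((8, 8), 0.5)
        lum[:, :4] = 0.6
        d = _drive_from(lum)
        # central difference S(c+1) - S(c-1) with S step of 0.1 at col 3|4
        expected = P.drive_gain * 0.1
        assert np.allclose(d.vertical[:, 3], expected)
        assert np.allclose(d.vertical[:, 4], expected)
        assert np.all(d.vertical[:, :3] == 0) and np.all(d.vertical[:, 5:] == 0)
        # no horizontal-edge drive away from the frame borders
        assert np.all(d.horizontal[1:-1, :] == 0)

    def test_symmetric_corner_drives_both_orientations_equally(self):
        lum = np.full((9, 9), 0.5)
        lum[:4, :4] = 0.6
        d = _drive_from(lum)
        assert d.vertical[3, 3] == pytest.approx(d.horizontal[3, 3])
        assert d.vertical[3, 3] > 0


class TestGates:
    def test_recovered_gate_is_a_fixed_point_without_input(self):
        params = DipoleParams(tonic=0.0)
        gates = GateState.fresh((3, 3))
        drive = OrientedDrive(np.zeros((3, 3)), np.zeros((3, 3)))
        for _ in range(200):
            gates = step_gates(gates, drive, params, 0.01)
        assert np.allclose(gates.z_vertical, 1.0)
        assert np.allclose(gates.z_horizontal, 1.0)

    def test_balanced_rates_equilibrate_at_one_half(self):
        # beta * S = alpha -> z* = 1/2
        params = DipoleParams(alpha=0.5, beta=0.5, tonic=0.0)
        gates = GateState.fresh((1, 1))
        drive = OrientedDrive(np.full((1, 1), 1.0), np.zeros((1, 1)))
        for _ in range(5000):
            gates = step_gates(gates, drive, params, 0.005)
        assert gates.z_vertical[0, 0] == pytest.approx(0.5, rel=1e-3)

    @pytest.mark.parametrize("signal", [0.5, 2.0, 8.0])
    def test_long_run_matches_closed_form_equilibrium(self, signal):
        drive = signal - P.tonic
        rate = P.alpha + P.beta * signal
        tr = simulate_dipole_trace([(10.0 / rate, drive, 0.0)], P, 0.005)
        assert tr["z_vertical"][-1] == pytest.approx(
            gate_equilibrium(signal, P), rel=0.01)

    def test_stability_guard_rejects_large_steps(self):
        gates = GateState.fresh((2, 2))
        drive = OrientedDrive(np.full((2, 2), 500.0), np.zeros((2, 2)))
        with pytest.raises(ValueError, match="dt"):
            step_gates(gates, drive, P, 0.05)

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(hnp.arrays(float, (4, 4), elements=st.floats(0.0, 20.0)))
    def test_gate_levels_stay_in_unit_interval(self, drive_v):
        gates = GateState.fresh((4, 4))
        drive = OrientedDrive(drive_v, drive_v[::-1])
        for _ in range(100):
            gates = step_gates(gates, drive, P, 0.01)
            for z in (gates.z_vertical, gates.z_horizontal):
                assert np.all(z > 0) and np.all(z <= 1.0)


class TestDipoleOutput:
    def test_balanced_channels_cancel(self):
        gates = GateState.fresh((2, 2))
        drive = OrientedDrive(np.full((2, 2), 3.0), np.full((2, 2), 3.0))
        out = dipole_output(drive, gates, P)
        assert np.all(out.vertical == 0) and np.all(out.horizontal == 0)

    def test_one_sided_drive_activates_one_orientation(self):
        gates = GateState.fresh((2, 2))
        drive = OrientedDrive(np.full((2, 2), 3.0), np.zeros((2, 2)))
        out = dipole_output(drive, gates, P)
        assert np.all(out.vertical > 0) and np.all(out.horizontal == 0)

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(hnp.arrays(float, (3, 3), elements=st.floats(0, 10)),
           hnp.arrays(float, (3, 3), elements=st.floats(0, 10)))
    def test_at_most_one_orientation_wins_per_pixel(self, dv, dh):
        gates = GateState.fresh((3, 3))
        out = dipole_output(OrientedDrive(dv, dh), gates, P)
        assert np.all((out.vertical == 0) | (out.horizontal == 0))
        assert out.vertical.min() >= 0 and out.horizontal.min() >= 0


class TestDipoleTrace:
    def test_driven_channel_habituates_then_drops_at_decrement(self):
        tr = simulate_dipole_trace([(4.0, 5.0, 0.0), (2.0, 0.5, 0.0)], P,
                                   0.005)
        t, yv = tr["times"], tr["y_vertical"]
        during = (t > 0.2) & (t < 4.0 - 1e-6)
        assert np.all(np.diff(yv[during]) <= 0)
        assert yv[during][-1] < yv[during][0]
        i4 = int(np.argmin(np.abs(t - 4.0)))  # first sample of the weak drive
        # the activity drop at the decrement is abrupt, far exceeding the
        # gradual habituation slope
        assert yv[i4] < 0.25 * yv[i4 - 1]

    def test_rebound_appears_only_after_adaptation(self):
        # full-contrast flicker edge: |S| difference of 1.0 -> drive 10
        decrement = [(2.0, 0.5, 0.0)]
        fresh = simulate_dipole_trace(decrement, P, 0.005)
        assert fresh["out_horizontal"].max() == 0.0
        for adapt_s in (1.0, 2.0, 4.0):
            tr = simulate_dipole_trace([(adapt_s, 10.0, 0.0)] + decrement,
                                       P, 0.005)
            i = int(np.argmin(np.abs(tr["times"] - adapt_s)))
            assert tr["out_horizontal"][i:].max() > 0.0

    def test_rebound_is_transient(self):
        tr = simulate_dipole_trace([(4.0, 5.0, 0.0), (30.0, 0.5, 0.0)], P,
                                   0.005)
        assert tr["out_horizontal"][-1] == 0.0

    def test_zero_input_rest_state_is_constant_and_symmetric(self):
        tr = simulate_dipole_trace([(2.0, 0.0, 0.0)], P, 0.005)
        assert np.allclose(tr["y_vertical"], tr["y_horizontal"])
        assert np.allclose(np.diff(tr["out_vertical"]), 0.0)

    def test_erasure_is_monotone_in_adaptation_duration(self):
        # boundary output to a fixed weak test edge never grows with more
        # prior adaptation
        outputs = []
        for adapt_s in (0.0, 1.0, 2.0, 4.0):
            sched = ([(adapt_s, 5.0, 0.0)] if adapt_s else []) + [(0.1, 0.5, 0.0)]
            tr = simulate_dipole_trace(sched, P, 0.005)
            i = np.searchsorted(tr["times"], adapt_s)
            outputs.append(tr["out_vertical"][i])
        assert all(b <= a + 1e-12 for a, b in zip(outputs, outputs[1:]))
        assert outputs[0] > 0 and outputs[-1] < outputs[0]
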