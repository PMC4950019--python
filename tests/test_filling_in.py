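"""Boundary-gated diffusion, its steady-state oracle, and readout."""

import numpy as np
import pytest

from contourfill import (FillParams, PerceptField, permeability,
                         readout_brightness, steady_state_oracle,
                         step_filling)
from contourfill.boundary_system import BoundaryField
from contourfill.front_end import OpponentField
from contourfill.filling_in import max_stable_dt


def _boundaries(shape, vertical=None, horizontal=None):
    return BoundaryField(
        vertical=vertical if vertical is not None else np.zeros(shape),
        horizontal=horizontal if horizontal is not None else np.zeros(shape))


def _run_to_steady(src, perm, params, T=40.0):
    dt = 0.9 * max_stable_dt(params)
    x = PerceptField.zeros(src.shape)
    for _ in range(int(np.ceil(T / (params.decay * dt)))):
        x = step_filling(x, src, perm, params, dt)
    return x


class TestPermeability:
    def test_no_boundaries_gives_baseline_everywhere(self):
        params = FillParams(couple=10.0)
        perm = permeability(_boundaries((5, 5)), params)
        assert np.allclose(perm.horizontal, 10.0)
        assert np.allclose(perm.vertical, 10.0)

    def test_vertical_boundary_blocks_horizontal_flow_only(self):
        params = FillParams(couple=10.0, block=100.0)
        vert = np.zeros((5, 5))
        vert[:, 2] = 1e9
        perm = permeability(_boundaries((5, 5), vertical=vert), params)
        # flow across the boundary column is extinguished ...
        assert np.all(perm.horizontal[:, 1:3] < 1e-6)
        # ... but flow along it (vertically) is untouched
        assert np.allclose(perm.vertical[:, 2], 10.0)

    def test_symmetry_between_directional_views(self):
        rng = np.random.default_rng(0)
        b = _boundaries((6, 6), vertical=rng.uniform(0, 1, (6, 6)),
                        horizontal=rng.uniform(0, 1, (6, 6)))
        perm = permeability(b, FillParams())
        assert np.allclose(perm.right[:, :-1], perm.left[:, 1:])
        assert np.allclose(perm.down[:-1, :], perm.up[1:, :])


class TestStepFilling:
    def test_zero_source_zero_state_is_fixed(self):
        params = FillParams(decay=1.0, couple=10.0)
        src = OpponentField(np.zeros((4, 4)), np.zeros((4, 4)))
        perm = permeability(_boundaries((4, 4)), params)
        x = PerceptField.zeros((4, 4))
        for _ in range(50):
            x = step_filling(x, src, perm, params, 0.01)
        assert np.all(x.on_fill == 0) and np.all(x.off_fill == 0)

    def test_uniform_source_converges_to_C_over_A(self):
        params = FillParams(decay=2.0, couple=10.0, input_gain=4.0)
        src = OpponentField(np.full((6, 6), 0.3), np.zeros((6, 6)))
        perm = permeability(_boundaries((6, 6)), params)
        x = _run_to_steady(src, perm, params, T=30.0)
        assert np.allclose(x.on_fill, 4.0 * 0.3 / 2.0, rtol=1e-6)

    def test_stability_guard(self):
        params = FillParams(decay=1.0, couple=100.0, input_gain=1.0)
        src = OpponentField(np.zeros((4, 4)), np.zeros((4, 4)))
        perm = permeability(_boundaries((4, 4)), params)
        with pytest.raises(ValueError, match="sub-step"):
            step_filling(PerceptField.zeros((4, 4)), src, perm, params, 0.01)

    def test_homogenization_decreases_variance(self):
        params = FillParams(decay=0.0, couple=10.0, input_gain=1.0)
        rng = np.random.default_rng(3)
        x = PerceptField(rng.uniform(0, 1, (8, 8)), np.zeros((8, 8)))
        src = OpponentField(np.zeros((8, 8)), np.zeros((8, 8)))
        perm = permeability(_boundaries((8, 8)), params)
        variances = [x.on_fill.var()]
        for _ in range(30):
            x = step_filling(x, src, perm, params, 0.9 * max_stable_dt(params))
            variances.append(x.on_fill.var())
        assert all(b < a for a, b in zip(variances, variances[1:]))


class TestOracle:
    def test_zero_source_gives_zero_solution(self):
        params = FillParams(decay=1.0, couple=5.0)
        src = OpponentField(np.zeros((5, 5)), np.zeros((5, 5)))
        perm = permeability(_boundaries((5, 5)), params)
        x = steady_state_oracle(src, perm, params)
        assert np.allclose(x.on_fill, 0) and np.allclose(x.off_fill, 0)

    def test_single_pixel_scalar_case(self):
        params = FillParams(decay=2.0, couple=5.0, input_gain=3.0)
        src = OpponentField(np.full((1, 1), 0.4), np.zeros((1, 1)))
        perm = permeability(_boundaries((1, 1)), params)
        x = steady_state_oracle(src, perm, params)
        assert x.on_fill[0, 0] == pytest.approx(3.0 * 0.4 / 2.0)

    def test_zero_decay_is_singular(self):
        params = FillParams(decay=0.0, couple=5.0)
        src = OpponentField(np.zeros((3, 3)), np.zeros((3, 3)))
        perm = permeability(_boundaries((3, 3)), params)
        with pytest.raises(ValueError, match="singular"):
            steady_state_oracle(src, perm, params)

    def test_large_grids_rejected(self):
        params = FillParams()
        src = OpponentField(np.zeros((65, 65)), np.zeros((65, 65)))
        perm = permeability(_boundaries((65, 65)), params)
        with pytest.raises(ValueError, match="64"):
            steady_state_oracle(src, perm, params)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_integrated_steady_state(self, seed):
        rng = np.random.default_rng(seed)
        params = FillParams(decay=float(rng.uniform(0.5, 2.0)),
                            couple=float(rng.uniform(5, 40)),
                            block=float(rng.uniform(0, 10)),
                            input_gain=float(rng.uniform(1, 4)))
        src = OpponentField(rng.uniform(0, 1, (8, 8)),
                            rng.uniform(0, 1, (8, 8)))
        b = _boundaries((8, 8), vertical=rng.uniform(0, 0.5, (8, 8)),
                        horizontal=rng.uniform(0, 0.5, (8, 8)))
        perm = permeability(b, params)
        exact = steady_state_oracle(src, perm, params)
        approx = _run_to_steady(src, perm, params)
        assert np.abs(approx.on_fill - exact.on_fill).max() < 1e-6
        assert np.abs(approx.off_fill - exact.off_fill).max() < 1e-6


class TestTrappingAndLeak:
    @staticmethod
    def _rect_diff(strength, params, open_side=False, T=2.0):
        H = W = 24
        rr, cc = np.indices((H, W))
        top, bot, left, right = 6, 18, 6, 18
        vert = np.zeros((H, W))
        horiz = np.zeros((H, W))
        vert[top:bot + 1, left] = strength
        vert[top:bot + 1, right] = 0.0 if open_side else strength
        horiz[top, left:right + 1] = strength
        horiz[bot, left:right + 1] = strength
        interior = (rr > top) & (rr < bot) & (cc > left) & (cc < right)
        exterior = ~((rr >= top - 1) & (rr <= bot + 1)
                     & (cc >= left - 1) & (cc <= right + 1))
        src = OpponentField(np.where(interior, 0.1, 0.0), np.zeros((H, W)))
        perm = permeability(_boundaries((H, W), vertical=vert,
                                        horizontal=horiz), params)
        dt = 0.9 * max_stable_dt(params)
        x = PerceptField.zeros((H, W))
        for _ in range(int(round(T / dt))):
            x = step_filling(x, src, perm, params, dt)
        b = x.brightness
        return b[interior].mean() - b[exterior].mean()

    def test_trapped_difference_increases_with_boundary_strength(self):
        params = FillParams(decay=0.02, couple=100.0, block=100.0)
        diffs = [self._rect_diff(s, params) for s in (0.1, 0.5, 2.0, 8.0)]
        assert all(b > a for a, b in zip(diffs, diffs[1:]))

    def test_trapped_difference_increases_with_blocking_strength(self):
        diffs = [self._rect_diff(1.0, FillParams(decay=0.02, couple=100.0,
                                                 block=E))
                 for E in (10.0, 100.0, 1000.0)]
        assert all(b > a for a, b in zip(diffs, diffs[1:]))

    def test_one_gap_leak_grows_with_coupling(self):
        # the documented failure mode: one open side lets the region bleed
        # out, the more so the stronger the diffusion
        ratios = []
        for D in (25.0, 100.0, 400.0):
            params = FillParams(decay=0.02, couple=D, block=1000.0)
            closed = self._rect_diff(4.0, params)
            open_ = self._rect_diff(4.0, params, open_side=True)
            ratios.append(open_ / closed)
        assert all(b < a for a, b in zip(ratios, ratios[1:]))
        assert ratios[-1] < 0.5


class TestReadout:
    def test_zero_percept_renders_background(self):
        frame = readout_brightness(PerceptField.zeros((4, 4)), 0.5, 2.0)
        assert np.all(frame.luminance == 0.5)

    def test_balanced_channels_render_background(self):
        x = PerceptField(np.full((4, 4), 0.3), np.full((4, 4), 0.3))
        frame = readout_brightness(x, 0.5, 2.0)
        assert np.all(frame.luminance == 0.5)

    def test_output_is_clipped_to_unit_interval(self):
        x = PerceptField(np.full((2, 2), 100.0), np.zeros((2, 2)))
        frame = readout_brightness(x, 0.5, 2.0)
        assert frame.luminance.max() <= 1.0
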