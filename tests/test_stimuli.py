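"""Stimulus generation: rendering, flicker sequences, demo catalog."""

import numpy as np
import pytest

from contourfill import ShapeSpec, build_demo, render_shape
from contourfill.stimuli import (DEMO_IDS, get_protocol,
                                 make_flicker_sequence, shape_mask)

CANVAS = (96, 96)
CENTER = (48, 48)


class TestRenderShape:
    def test_invisible_shape_gives_uniform_frame(self):
        spec = ShapeSpec("filled_square", CENTER, 40, luminance=0.5)
        frame = render_shape(spec, CANVAS, background=0.5)
        assert np.all(frame.luminance == 0.5)

    def test_sharp_outline_cross_is_binary(self):
        spec = ShapeSpec("outline_cross", CENTER, 40, inner_size=12,
                         luminance=1.0)
        frame = render_shape(spec, CANVAS, background=0.5)
        assert set(np.unique(frame.luminance)) == {0.5, 1.0}

    def test_blur_reduces_max_gradient(self):
        sharp = render_shape(ShapeSpec("outline_cross", CENTER, 40,
                                       inner_size=12), CANVAS, 0.5)
        blurred = render_shape(ShapeSpec("outline_cross", CENTER, 40,
                                         inner_size=12, blur_sigma=3.0),
                               CANVAS, 0.5)

        def max_grad(img):
            gy, gx = np.gradient(img)
            return np.abs(np.hypot(gy, gx)).max()

        assert max_grad(blurred.luminance) < max_grad(sharp.luminance)

    def test_oversized_shape_raises_with_extent(self):
        spec = ShapeSpec("filled_square", CENTER, 120)
        with pytest.raises(ValueError, match="exceeds"):
            render_shape(spec, CANVAS, 0.5)

    @pytest.mark.parametrize("kind,kwargs", [
        ("filled_square", {}),
        ("outline_square", {}),
        ("half_square_outline", {}),
        ("filled_cross", {"inner_size": 12}),
        ("outline_cross", {"inner_size": 12}),
        ("vertical_line", {"line_width": 2}),
        ("annulus", {"inner_size": 20}),
        ("disk", {}),
        ("two_holed_annulus", {"inner_size": 12}),
        ("polar_checkerboard", {"ring_radii": (8.0, 16.0)}),
        ("concentric_square_inducers", {"inner_size": 24}),
        ("pyramid_steps", {"luminance": 0.65}),
        ("bipartite_field", {"luminance": 0.55}),
    ])
    def test_every_kind_renders_deterministically(self, kind, kwargs):
        spec = ShapeSpec(kind, CENTER, 40, **kwargs)
        a = render_shape(spec, CANVAS, 0.5)
        b = render_shape(spec, CANVAS, 0.5)
        assert np.array_equal(a.luminance, b.luminance)
        assert 0.0 <= a.luminance.min() and a.luminance.max() <= 1.0
        assert shape_mask(spec, CANVAS).any()

    def test_spec_validation(self):
        with pytest.raises(ValueError, match="unknown shape kind"):
            ShapeSpec("blob", CENTER, 40)
        with pytest.raises(ValueError, match="inner_size"):
            ShapeSpec("annulus", CENTER, 40, inner_size=40)
        with pytest.raises(ValueError, match="line_width"):
            ShapeSpec("outline_square", CENTER, 40, line_width=0)


class TestFlicker:
    def test_frame_count_and_polarity_alternation(self):
        spec = ShapeSpec("outline_square", CENTER, 40)
        seq = make_flicker_sequence(spec, duration=4.0, half_period=0.5,
                                    background=0.5)
        assert len(seq.frames) == 8
        mask = seq.annotations["adapted_region"]
        values = [f.luminance[mask][0] for f in seq.frames]
        assert values == [1.0, 0.0] * 4

    def test_six_second_adaptation_has_twelve_frames(self):
        spec = ShapeSpec("disk", CENTER, 40)
        seq = make_flicker_sequence(spec, duration=6.0, half_period=0.5,
                                    background=0.5)
        assert len(seq.frames) == 12

    def test_cycle_average_is_background_everywhere(self):
        spec = ShapeSpec("outline_cross", CENTER, 40, inner_size=12)
        seq = make_flicker_sequence(spec, 2.0, 0.25, 0.5)
        avg = np.mean([f.luminance for f in seq.frames], axis=0)
        assert np.allclose(avg, 0.5, atol=1e-12)

    def test_blurred_flicker_also_averages_to_background(self):
        spec = ShapeSpec("filled_square", CENTER, 40, blur_sigma=4.0)
        seq = make_flicker_sequence(spec, 1.0, 0.25, 0.5)
        avg = np.mean([f.luminance for f in seq.frames], axis=0)
        assert np.allclose(avg, 0.5, atol=1e-9)

    def test_nonpositive_half_period_rejected(self):
        spec = ShapeSpec("disk", CENTER, 40)
        with pytest.raises(ValueError, match="half_period"):
            make_flicker_sequence(spec, 2.0, 0.0, 0.5)
        with pytest.raises(ValueError, match="full flicker cycle"):
            make_flicker_sequence(spec, 0.25, 0.25, 0.5)


class TestDemoCatalog:
    def test_unknown_demo_lists_valid_ids(self):
        with pytest.raises(ValueError) as err:
            build_demo("ag_movie99")
        for demo_id in DEMO_IDS:
            assert demo_id in str(err.value)

    @pytest.mark.parametrize("demo_id", DEMO_IDS)
    def test_demo_sequence_invariants(self, demo_id, fast_config):
        seq = build_demo(demo_id, None, fast_config)
        assert seq.total_duration > 0
        for frame in seq.frames:
            assert frame.shape == seq.shape
        for mask in seq.annotations.values():
            assert mask.dtype == bool and mask.shape == seq.shape
        # the test display deviates from background only inside the
        # annotated target region
        test_frame = seq.frames[-1]
        outside = ~seq.annotations["target_region"]
        assert np.allclose(test_frame.luminance[outside], 0.5, atol=1e-12)

    @pytest.mark.parametrize("demo_id", DEMO_IDS)
    def test_demo_rebuild_is_bit_identical(self, demo_id, fast_config):
        a = build_demo(demo_id, None, fast_config)
        b = build_demo(demo_id, None, fast_config)
        for fa, fb in zip(a.frames, b.frames):
            assert np.array_equal(fa.luminance, fb.luminance)

    def test_no_adapt_override_blanks_the_adaptation_phase(self, fast_config):
        adapt = build_demo("ag_movie2_crosses", {"adapt": True}, fast_config)
        ctrl = build_demo("ag_movie2_crosses", {"adapt": False}, fast_config)
        assert len(adapt.frames) == len(ctrl.frames)
        assert adapt.total_duration == ctrl.total_duration
        for frame in ctrl.frames[:-1]:
            assert np.all(frame.luminance == 0.5)

    def test_crosses_demo_has_two_adapted_two_unadapted_targets(self, config):
        proto = get_protocol("ag_movie2_crosses", None, config)
        adapted = proto.masks["adapted_region"]
        overlapping = [
            name for name in ("top", "bottom", "left", "right")
            if (proto.masks[f"target_{name}"] & adapted).any()
        ]
        assert sorted(overlapping) == ["bottom", "top"]

    def test_two_holed_annulus_tests_are_hole_and_half_size(self, config):
        proto = get_protocol("rds_two_holed_annulus",
                             {"px_per_deg": 4.0}, config)
        equal = proto.masks["target_equal"].sum()
        half = proto.masks["target_half"].sum()
        # half the linear size => a quarter of the area
        assert abs(half / equal - 0.25) < 0.05

    def test_illusory_demo_adaptors_differ_only_by_drawn_contour(self, config):
        proto = get_protocol("illusory_vs_real", None, config)
        kinds = [s.kind for s in proto.adaptor_specs]
        assert kinds.count("concentric_square_inducers") == 2
        assert kinds.count("outline_square") == 1
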