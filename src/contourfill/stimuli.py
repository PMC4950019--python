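"""Parametric generation of adaptation/test movies.

Every simulation in this package consumes a :class:`StimulusSequence`: an
ordered list of grayscale frames (luminance in [0, 1], background gray at
0.5) with per-frame durations, plus named boolean pixel masks that mark the
regions whose visibility the psychophysics harness measures.

The demo catalog (:func:`build_demo`) reproduces the contour-erasure
protocols this package models: flickering outline crosses, blurred-edge
surfaces, size-mismatched outlines, half-square outlines, bipartite fields,
brightness pyramids, annuli, two-holed annuli, flickering disks, polar
checkerboards, and illusory-contour inducers.  All rendering is
deterministic: identical specs yield bit-identical frames.

Geometry conventions: row/column indices with the origin at the top-left;
a shape of ``size`` s centered at integer ``c`` covers the half-open pixel
interval [c - s/2, c + s/2), so integer sizes give exact pixel extents.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .config import RunConfig

__all__ = [
    "Frame",
    "ShapeSpec",
    "StimulusSequence",
    "DemoProtocol",
    "SHAPE_KINDS",
    "DEMO_IDS",
    "render_shape",
    "compose_frame",
    "make_flicker_sequence",
    "build_demo",
    "get_protocol",
]

SHAPE_KINDS = (
    "outline_cross",
    "filled_cross",
    "outline_square",
    "filled_square",
    "half_square_outline",
    "vertical_line",
    "annulus",
    "two_holed_annulus",
    "disk",
    "polar_checkerboard",
    "concentric_square_inducers",
    "pyramid_steps",
    "bipartite_field",
)

#: kinds whose rendering is inherently multi-valued (not mask + luminance)
_IMAGE_KINDS = ("polar_checkerboard", "pyramid_steps", "bipartite_field")

_OUTLINE_KINDS = (
    "outline_cross",
    "outline_square",
    "half_square_outline",
    "concentric_square_inducers",
)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Frame:
    """One movie frame: a luminance grid in [0, 1] shown for ``duration`` s."""

    luminance: np.ndarray
    duration: float

    def __post_init__(self):
        lum = np.asarray(self.luminance, dtype=float)
        object.__setattr__(self, "luminance", lum)
        if lum.ndim != 2:
            raise ValueError("frame luminance must be a 2-D grid")
        if lum.min() < -1e-12 or lum.max() > 1 + 1e-12:
            raise ValueError("frame luminance must lie in [0, 1]")
        if not self.duration > 0:
            raise ValueError("frame duration must be positive")

    @property
    def shape(self) -> Tuple[int, int]:
        return self.luminance.shape


@dataclass(frozen=True)
class ShapeSpec:
    """Parametric description of a single stimulus shape.

    ``size`` is the outer extent in pixels; ``inner_size`` parameterizes
    holes, annuli, cross arm widths and the cut-out region of illusory
    inducers (0 where not applicable).  ``luminance`` is the shape's value
    for binary kinds and the contrast carrier for multi-valued kinds
    (e.g. pyramid steps at background + k * (luminance - background)).
    """

    kind: str
    center: Tuple[int, int]
    size: int
    inner_size: int = 0
    line_width: int = 2
    luminance: float = 1.0
    blur_sigma: float = 0.0
    #: polar checkerboards only: ring boundary radii (px) and sector count
    ring_radii: Optional[Tuple[float, ...]] = None
    n_sectors: int = 8

    def __post_init__(self):
        if self.kind not in SHAPE_KINDS:
            raise ValueError(
                f"unknown shape kind {self.kind!r}; valid kinds: {SHAPE_KINDS}")
        if self.inner_size and not self.inner_size < self.size:
            raise ValueError("inner_size must be smaller than size")
        if self.kind in _OUTLINE_KINDS and self.line_width < 1:
            raise ValueError("line_width must be >= 1 for outline kinds")
        if not 0.0 <= self.luminance <= 1.0:
            raise ValueError("luminance must lie in [0, 1]")
        if self.blur_sigma < 0:
            raise ValueError("blur_sigma must be non-negative")


@dataclass
class StimulusSequence:
    """Ordered frames on a common grid plus named annotation masks."""

    frames: List[Frame]
    shape: Tuple[int, int]
    annotations: Dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        for f in self.frames:
            if f.shape != tuple(self.shape):
                raise ValueError("all frames must share the sequence grid shape")
        for name, mask in self.annotations.items():
            mask = np.asarray(mask)
            if mask.dtype != bool or mask.shape != tuple(self.shape):
                raise ValueError(
                    f"annotation {name!r} must be a boolean mask of shape {self.shape}")
            self.annotations[name] = mask

    @property
    def total_duration(self) -> float:
        return float(sum(f.duration for f in self.frames))


# ---------------------------------------------------------------------------
# rasterization
# ---------------------------------------------------------------------------


def _span(coord: np.ndarray, center: float, size: float) -> np.ndarray:
    """Half-open interval [center - size/2, center + size/2) along one axis."""
    return (coord >= center - size / 2.0) & (coord < center + size / 2.0)


def _filled_square(rr, cc, center, size) -> np.ndarray:
    r0, c0 = center
    return _span(rr, r0, size) & _span(cc, c0, size)


def _erode(mask: np.ndarray, width: int) -> np.ndarray:
    if width <= 0:
        return mask
    return ndimage.binary_erosion(mask, iterations=width)


def _outline(mask: np.ndarray, width: int) -> np.ndarray:
    return mask & ~_erode(mask, width)


def _extent_of(spec: ShapeSpec) -> Tuple[float, float]:
    """Half-extents (rows, cols) of the shape around its center."""
    s = spec.size / 2.0
    if spec.kind == "two_holed_annulus":
        return (_body_height(spec) / 2.0, s)
    return (s, s)


def _body_height(spec: ShapeSpec) -> int:
    """Height of the two-holed annulus body (half its width)."""
    return int(round(spec.size * 0.5))


def shape_mask(spec: ShapeSpec, canvas: Tuple[int, int]) -> np.ndarray:
    """Boolean mask of pixels covered by the (un-blurred) shape."""
    H, W = canvas
    rr, cc = np.indices((H, W))
    r0, c0 = spec.center
    k = spec.kind

    if k in ("filled_square", "outline_square", "half_square_outline"):
        filled = _filled_square(rr, cc, spec.center, spec.size)
        if k == "filled_square":
            return filled
        out = _outline(filled, spec.line_width)
        if k == "half_square_outline":
            return out & (cc < c0)
        return out

    if k in ("filled_cross", "outline_cross"):
        arm = spec.inner_size if spec.inner_size else max(2, spec.size // 3)
        horiz = _span(rr, r0, arm) & _span(cc, c0, spec.size)
        vert = _span(cc, c0, arm) & _span(rr, r0, spec.size)
        filled = horiz | vert
        if k == "filled_cross":
            return filled
        return _outline(filled, spec.line_width)

    if k == "vertical_line":
        return _span(cc, c0, spec.line_width) & _span(rr, r0, spec.size)

    if k == "annulus":
        return (_filled_square(rr, cc, spec.center, spec.size)
                & ~_filled_square(rr, cc, spec.center, spec.inner_size))

    if k == "disk":
        return (rr - r0) ** 2 + (cc - c0) ** 2 < (spec.size / 2.0) ** 2

    if k == "two_holed_annulus":
        height = _body_height(spec)
        body = _span(rr, r0, height) & _span(cc, c0, spec.size)
        off = int(round(spec.inner_size * 0.75))
        for dc in (-off, off):
            body &= ~_filled_square(rr, cc, (r0, c0 + dc), spec.inner_size)
        return body

    if k == "concentric_square_inducers":
        # four concentric-square bullseyes centered on the corners of the
        # inner (illusory) square; overall extent = size
        half = spec.inner_size // 2
        bullseye = spec.size - spec.inner_size
        mask = np.zeros((H, W), dtype=bool)
        ring_sizes = [max(4, int(round(bullseye * f))) for f in (1 / 3, 2 / 3, 1.0)]
        for dr in (-half, half):
            for dc in (-half, half):
                for s in ring_sizes:
                    filled = _filled_square(rr, cc, (r0 + dr, c0 + dc), s)
                    mask |= _outline(filled, spec.line_width)
        # cut-out: inducer segments inside the (illusory) test square vanish,
        # leaving sparse line ends along its border
        mask &= ~_filled_square(rr, cc, spec.center, spec.inner_size)
        return mask

    if k == "polar_checkerboard":
        radii = spec.ring_radii or (spec.inner_size / 2.0, spec.size / 2.0)
        return (rr - r0) ** 2 + (cc - c0) ** 2 < max(radii) ** 2

    if k == "pyramid_steps":
        return _filled_square(rr, cc, spec.center, spec.size)

    if k == "bipartite_field":
        return _filled_square(rr, cc, spec.center, spec.size)

    raise AssertionError(f"unhandled kind {k}")  # pragma: no cover


def _shape_image(spec: ShapeSpec, canvas: Tuple[int, int],
                 background: float) -> np.ndarray:
    """Un-blurred luminance image of a single shape on the background."""
    H, W = canvas
    img = np.full((H, W), background, dtype=float)
    k = spec.kind

    if k in _IMAGE_KINDS:
        rr, cc = np.indices((H, W))
        r0, c0 = spec.center
        contrast = spec.luminance - background
        if k == "bipartite_field":
            m = shape_mask(spec, canvas)
            img[m & (cc < c0)] = background - contrast
            img[m & (cc >= c0)] = background + contrast
        elif k == "pyramid_steps":
            sizes = [spec.size, int(round(spec.size * 2 / 3)),
                     int(round(spec.size / 3))]
            for step, s in enumerate(sizes, start=1):
                img[_filled_square(rr, cc, spec.center, s)] = (
                    background + step * contrast)
        else:  # polar_checkerboard
            radii = spec.ring_radii or (spec.inner_size / 2.0, spec.size / 2.0)
            radii = np.sort(np.asarray(radii, dtype=float))
            rad = np.hypot(rr - r0, cc - c0)
            inside = rad < radii[-1]
            ring_idx = np.searchsorted(radii, rad[inside])
            theta = np.arctan2(rr - r0, cc - c0)[inside]
            sector_idx = np.floor((theta + np.pi) / (2 * np.pi)
                                  * spec.n_sectors).astype(int) % spec.n_sectors
            parity = (ring_idx + sector_idx) % 2
            vals = np.where(parity == 0, spec.luminance, 1.0 - spec.luminance)
            img[inside] = vals
    else:
        img[shape_mask(spec, canvas)] = spec.luminance

    if spec.blur_sigma > 0:
        img = ndimage.gaussian_filter(img, spec.blur_sigma, mode="nearest")
    return np.clip(img, 0.0, 1.0)


def _check_fits(spec: ShapeSpec, canvas: Tuple[int, int]) -> None:
    H, W = canvas
    er, ec = _extent_of(spec)
    r0, c0 = spec.center
    if r0 - er < 0 or r0 + er > H or c0 - ec < 0 or c0 + ec > W:
        raise ValueError(
            f"shape {spec.kind!r} at center {spec.center} with extent "
            f"({2 * er:.0f} x {2 * ec:.0f}) px exceeds the {H} x {W} canvas")


def render_shape(spec: ShapeSpec, canvas: Tuple[int, int],
                 background: float, duration: float = 1.0) -> Frame:
    """Render one shape on a uniform background.

    The frame equals ``background`` everywhere except pixels covered by the
    shape; ``blur_sigma > 0`` smooths the shape/background transition with
    an isotropic Gaussian.
    """
    if not 0.0 <= background <= 1.0:
        raise ValueError("background must lie in [0, 1]")
    _check_fits(spec, canvas)
    return Frame(_shape_image(spec, canvas, background), duration)


def compose_frame(specs: Sequence[ShapeSpec], canvas: Tuple[int, int],
                  background: float, duration: float = 1.0) -> Frame:
    """Render several non-overlapping shapes on one canvas.

    Shapes combine additively in their deviation from the background, which
    is exact for disjoint shapes and keeps Gaussian-blurred edges linear.
    """
    deviation = np.zeros(canvas, dtype=float)
    for spec in specs:
        _check_fits(spec, canvas)
        deviation += _shape_image(spec, canvas, background) - background
    return Frame(np.clip(background + deviation, 0.0, 1.0), duration)


def uniform_frame(canvas: Tuple[int, int], background: float,
                  duration: float) -> Frame:
    return Frame(np.full(canvas, background, dtype=float), duration)


# ---------------------------------------------------------------------------
# flicker sequences
# ---------------------------------------------------------------------------


def _flicker_frames(specs: Sequence[ShapeSpec], canvas: Tuple[int, int],
                    background: float, duration: float,
                    half_period: float) -> List[Frame]:
    """Frames alternating all shapes between white (1.0) and black (0.0)."""
    if half_period <= 0:
        raise ValueError("half_period must be positive")
    if duration < 2 * half_period - 1e-9:
        raise ValueError("duration must cover at least one full flicker cycle")
    n = int(round(duration / half_period))
    frames = []
    for i in range(n):
        lum = 1.0 if i % 2 == 0 else 0.0
        polarized = [replace(s, luminance=lum) for s in specs]
        frames.append(compose_frame(polarized, canvas, background, half_period))
    return frames


def make_flicker_sequence(spec: ShapeSpec, duration: float, half_period: float,
                          background: float) -> StimulusSequence:
    """Alternating black/white presentation of one shape.

    Successive frames set the shape luminance to 1.0 and 0.0, each shown for
    ``half_period`` seconds; over any full cycle the sequence integrates to
    the background gray at every pixel.  The shape's pixel mask is attached
    as the ``adapted_region`` annotation.
    """
    canvas = _default_canvas(spec)
    frames = _flicker_frames([spec], canvas, background, duration, half_period)
    mask = _adapted_mask([spec], canvas)
    return StimulusSequence(frames, canvas, {"adapted_region": mask})


def _default_canvas(spec: ShapeSpec) -> Tuple[int, int]:
    er, ec = _extent_of(spec)
    r0, c0 = spec.center
    return (int(np.ceil(r0 + er)) + 4, int(np.ceil(c0 + ec)) + 4)


def _adapted_mask(specs: Sequence[ShapeSpec],
                  canvas: Tuple[int, int]) -> np.ndarray:
    mask = np.zeros(canvas, dtype=bool)
    for s in specs:
        m = shape_mask(s, canvas)
        if s.blur_sigma > 0:
            m = ndimage.binary_dilation(m, iterations=int(np.ceil(3 * s.blur_sigma)))
        mask |= m
    return mask


# ---------------------------------------------------------------------------
# demo protocols
# ---------------------------------------------------------------------------


@dataclass
class DemoProtocol:
    """Adaptation + test recipe behind one demo movie.

    ``test_specs(contrast)`` returns the shapes of the test display at the
    given absolute luminance contrast, so the threshold harness can re-render
    the test phase at arbitrary contrasts without rebuilding the adaptor.
    """

    demo_id: str
    canvas: Tuple[int, int]
    background: float
    adaptor_specs: List[ShapeSpec]
    adapt_duration: float
    half_period: float
    test_duration: float
    test_specs: Callable[[float], List[ShapeSpec]]
    masks: Dict[str, np.ndarray]
    adapt: bool = True
    test_contrast: float = 0.05

    def adapt_frames(self) -> List[Frame]:
        """Flicker frames, or blank frames of equal duration for controls."""
        if self.adapt:
            return _flicker_frames(self.adaptor_specs, self.canvas,
                                   self.background, self.adapt_duration,
                                   self.half_period)
        n = int(round(self.adapt_duration / self.half_period))
        return [uniform_frame(self.canvas, self.background, self.half_period)
                for _ in range(n)]

    def test_frame(self, contrast: Optional[float] = None) -> Frame:
        c = self.test_contrast if contrast is None else contrast
        return compose_frame(self.test_specs(c), self.canvas, self.background,
                             self.test_duration)

    def sequence(self) -> StimulusSequence:
        frames = self.adapt_frames() + [self.test_frame()]
        return StimulusSequence(frames, self.canvas, dict(self.masks))


def _ring(mask: np.ndarray, width: int, gap: int = 1) -> np.ndarray:
    """Annular surround mask: ``width`` px starting ``gap`` px outside."""
    outer = ndimage.binary_dilation(mask, iterations=gap + width)
    inner = ndimage.binary_dilation(mask, iterations=gap)
    return outer & ~inner


def _surround_width(size_px: int) -> int:
    return max(3, int(round(size_px / 5)))


def _px(x: float, scale: float) -> int:
    return max(1, int(round(x * scale)))


def _standard_masks(canvas, targets: Dict[str, np.ndarray],
                    adaptor_specs, extra=None) -> Dict[str, np.ndarray]:
    """Per-target masks + the aggregate masks every sequence carries."""
    masks: Dict[str, np.ndarray] = {}
    union = np.zeros(canvas, dtype=bool)
    for name, tmask in targets.items():
        width = _surround_width(int(np.sqrt(max(1, tmask.sum()))))
        masks[f"target_{name}"] = tmask
        masks[f"surround_{name}"] = _ring(tmask, width)
        union |= tmask
    masks["target_region"] = union
    masks["adapted_region"] = _adapted_mask(adaptor_specs, canvas)
    masks["background_region"] = ~ndimage.binary_dilation(
        union | masks["adapted_region"], iterations=6)
    if extra:
        masks.update(extra)
    return masks


def _ov(overrides, key, default):
    return default if overrides is None else overrides.get(key, default)


# -- individual demo builders ------------------------------------------------


def _proto_ag_movie2(ov, cfg: RunConfig) -> DemoProtocol:
    """Flickering outline crosses at two of four locations (erasure demo)."""
    scale = _ov(ov, "px_per_deg", cfg.px_per_deg) / 10.0
    size, arm, lw = _px(40, scale), _px(12, scale), _px(2, scale)
    canvas = (_px(192, scale), _px(192, scale))
    mid = canvas[0] // 2
    off = _px(44, scale)
    centers = {"top": (mid - off, mid), "bottom": (mid + off, mid),
               "left": (mid, mid - off), "right": (mid, mid + off)}
    adapted_at = ("top", "bottom")
    adaptors = [ShapeSpec("outline_cross", centers[n], size, inner_size=arm,
                          line_width=lw) for n in adapted_at]
    signs = {"top": +1, "bottom": -1, "left": +1, "right": -1}

    def test_specs(c):
        return [ShapeSpec("filled_cross", centers[n], size, inner_size=arm,
                          luminance=0.5 + signs[n] * c) for n in centers]

    targets = {n: shape_mask(ShapeSpec("filled_cross", centers[n], size,
                                       inner_size=arm), canvas)
               for n in centers}
    masks = _standard_masks(canvas, targets, adaptors)
    return DemoProtocol("ag_movie2_crosses", canvas, cfg.background, adaptors,
                        _ov(ov, "adapt_duration", cfg.adapt_duration_outline),
                        _ov(ov, "half_period", cfg.half_period),
                        _ov(ov, "test_duration", cfg.test_duration),
                        test_specs, masks, _ov(ov, "adapt", True),
                        _ov(ov, "test_contrast", cfg.test_contrast))


def _proto_ag_movie3(ov, cfg: RunConfig) -> DemoProtocol:
    """Blurred flickering surface (left) vs sharp outline (right)."""
    scale = _ov(ov, "px_per_deg", cfg.px_per_deg) / 10.0
    size, lw = _px(48, scale), _px(2, scale)
    sigma = _ov(ov, "blur_sigma", 6.0) * scale
    canvas = (_px(128, scale), _px(256, scale))
    mid = canvas[0] // 2
    centers = {"blurred": (mid, canvas[1] // 4),
               "sharp": (mid, 3 * canvas[1] // 4)}
    adaptors = [
        ShapeSpec("filled_square", centers["blurred"], size, blur_sigma=sigma),
        ShapeSpec("outline_square", centers["sharp"], size, line_width=lw),
    ]

    def test_specs(c):
        return [ShapeSpec("filled_square", centers[n], size, luminance=0.5 + c)
                for n in centers]

    targets = {n: shape_mask(ShapeSpec("filled_square", centers[n], size),
                             canvas) for n in centers}
    masks = _standard_masks(canvas, targets, adaptors)
    return DemoProtocol("ag_movie3_blur", canvas, cfg.background, adaptors,
                        _ov(ov, "adapt_duration", cfg.adapt_duration_outline),
                        _ov(ov, "half_period", cfg.half_period),
                        _ov(ov, "test_duration", cfg.test_duration),
                        test_specs, masks, _ov(ov, "adapt", True),
                        _ov(ov, "test_contrast", cfg.test_contrast))


def _proto_ag_movie4(ov, cfg: RunConfig) -> DemoProtocol:
    """One outline size adapts three locations; test sizes match at one."""
    scale = _ov(ov, "px_per_deg", cfg.px_per_deg) / 10.0
    asize, lw = _px(40, scale), _px(2, scale)
    test_sizes = {"matched": asize, "smaller": _px(24, scale),
                  "larger": _px(56, scale)}
    canvas = (_px(96, scale), _px(288, scale))
    mid = canvas[0] // 2
    step = canvas[1] // 3
    centers = {"matched": (mid, step // 2), "smaller": (mid, step // 2 + step),
               "larger": (mid, step // 2 + 2 * step)}
    adaptors = [ShapeSpec("outline_square", centers[n], asize, line_width=lw)
                for n in centers]

    def test_specs(c):
        return [ShapeSpec("filled_square", centers[n], test_sizes[n],
                          luminance=0.5 + c) for n in centers]

    targets = {n: shape_mask(ShapeSpec("filled_square", centers[n],
                                       test_sizes[n]), canvas) for n in centers}
    masks = _standard_masks(canvas, targets, adaptors)
    return DemoProtocol("ag_movie4_size", canvas, cfg.background, adaptors,
                        _ov(ov, "adapt_duration", cfg.adapt_duration_outline),
                        _ov(ov, "half_period", cfg.half_period),
                        _ov(ov, "test_duration", cfg.test_duration),
                        test_specs, masks, _ov(ov, "adapt", True),
                        _ov(ov, "test_contrast", cfg.test_contrast))


def _proto_ag_movie5(ov, cfg: RunConfig) -> DemoProtocol:
    """Half-square outline adaptor; the documented model failure case."""
    scale = _ov(ov, "px_per_deg", cfg.px_per_deg) / 10.0
    size, lw = _px(40, scale), _px(2, scale)
    canvas = (_px(128, scale), _px(128, scale))
    center = (canvas[0] // 2, canvas[1] // 2)
    adaptors = [ShapeSpec("half_square_outline", center, size, line_width=lw)]

    def test_specs(c):
        return [ShapeSpec("filled_square", center, size, luminance=0.5 + c)]

    full = shape_mask(ShapeSpec("filled_square", center, size), canvas)
    cc = np.indices(canvas)[1]
    margin = _px(4, scale)
    targets = {
        "adapted_half": full & (cc < center[1] - margin),
        "unadapted_half": full & (cc >= center[1] + margin),
    }
    masks = _standard_masks(canvas, targets, adaptors)
    masks["target_region"] = full
    return DemoProtocol("ag_movie5_halfsquare", canvas, cfg.background,
                        adaptors,
                        _ov(ov, "adapt_duration", cfg.adapt_duration_outline),
                        _ov(ov, "half_period", cfg.half_period),
                        _ov(ov, "test_duration", cfg.test_duration),
                        test_specs, masks, _ov(ov, "adapt", True),
                        _ov(ov, "test_contrast", cfg.test_contrast))


def _proto_ag_movie6(ov, cfg: RunConfig) -> DemoProtocol:
    """Flickering vertical line, then a bipartite brightness field."""
    scale = _ov(ov, "px_per_deg", cfg.px_per_deg) / 10.0
    size, lw = _px(48, scale), _px(2, scale)
    canvas = (_px(128, scale), _px(128, scale))
    center = (canvas[0] // 2, canvas[1] // 2)
    adaptors = [ShapeSpec("vertical_line", center, size + _px(8, scale),
                          line_width=lw)]

    def test_specs(c):
        return [ShapeSpec("bipartite_field", center, size, luminance=0.5 + c)]

    full = shape_mask(ShapeSpec("bipartite_field", center, size), canvas)
    cc = np.indices(canvas)[1]
    band = _px(4, scale)
    targets = {
        "left_half": full & (cc < center[1] - band),
        "right_half": full & (cc >= center[1] + band),
    }
    masks = _standard_masks(canvas, targets, adaptors)
    masks["target_region"] = full
    return DemoProtocol("ag_movie6_bipartite", canvas, cfg.background,
                        adaptors,
                        _ov(ov, "adapt_duration", cfg.adapt_duration_outline),
                        _ov(ov, "half_period", cfg.half_period),
                        _ov(ov, "test_duration", cfg.test_duration),
                        test_specs, masks, _ov(ov, "adapt", True),
                        _ov(ov, "test_contrast", cfg.test_contrast))


def _proto_ag_movie7(ov, cfg: RunConfig) -> DemoProtocol:
    """Brightness pyramid; outlines flicker at every step edge."""
    scale = _ov(ov, "px_per_deg", cfg.px_per_deg) / 10.0
    size, lw = _px(72, scale), _px(2, scale)
    canvas = (_px(128, scale), _px(128, scale))
    center = (canvas[0] // 2, canvas[1] // 2)
    sizes = [size, int(round(size * 2 / 3)), int(round(size / 3))]
    adaptors = [ShapeSpec("outline_square", center, s, line_width=lw)
                for s in sizes]

    def test_specs(c):
        return [ShapeSpec("pyramid_steps", center, size, luminance=0.5 + c)]

    rr, cc = np.indices(canvas)
    m = _px(4, scale)
    center_sq = _filled_square(rr, cc, center, sizes[2] - m)
    step_ring = (_filled_square(rr, cc, center, sizes[1] - m)
                 & ~_filled_square(rr, cc, center, sizes[2] + m))
    targets = {"center": center_sq}
    masks = _standard_masks(canvas, targets, adaptors,
                            extra={"surround_center": step_ring})
    masks["target_region"] = _filled_square(rr, cc, center, size)
    return DemoProtocol("ag_movie7_pyramids", canvas, cfg.background, adaptors,
                        _ov(ov, "adapt_duration", cfg.adapt_duration_outline),
                        _ov(ov, "half_period", cfg.half_period),
                        _ov(ov, "test_duration", cfg.test_duration),
                        test_specs, masks, _ov(ov, "adapt", True),
                        _ov(ov, "test_contrast", cfg.test_contrast))


def _proto_ag_movie8(ov, cfg: RunConfig) -> DemoProtocol:
    """Outline square at an annulus' inner edge; the hole fills in."""
    scale = _ov(ov, "px_per_deg", cfg.px_per_deg) / 10.0
    outer, inner, lw = _px(64, scale), _px(32, scale), _px(2, scale)
    canvas = (_px(128, scale), _px(128, scale))
    center = (canvas[0] // 2, canvas[1] // 2)
    adaptors = [ShapeSpec("outline_square", center, inner, line_width=lw)]

    def test_specs(c):
        return [ShapeSpec("annulus", center, outer, inner_size=inner,
                          luminance=0.5 + c)]

    rr, cc = np.indices(canvas)
    m = _px(4, scale)
    hole = _filled_square(rr, cc, center, inner - m)
    body = (_filled_square(rr, cc, center, outer - m)
            & ~_filled_square(rr, cc, center, inner + m))
    annulus_full = (_filled_square(rr, cc, center, outer)
                    & ~_filled_square(rr, cc, center, inner))
    targets = {"body": body}
    masks = _standard_masks(canvas, targets, adaptors,
                            extra={"target_hole": hole,
                                   "surround_hole": body})
    # the body's surround is the outside background only: the hole is
    # expected to fill in with body brightness after inner-edge adaptation
    masks["surround_body"] = _ring(_filled_square(rr, cc, center, outer),
                                   _surround_width(outer))
    masks["target_region"] = annulus_full
    return DemoProtocol("ag_movie8_annuli", canvas, cfg.background, adaptors,
                        _ov(ov, "adapt_duration", cfg.adapt_duration_outline),
                        _ov(ov, "half_period", cfg.half_period),
                        _ov(ov, "test_duration", cfg.test_duration),
                        test_specs, masks, _ov(ov, "adapt", True),
                        _ov(ov, "test_contrast", cfg.test_contrast))


def _proto_rds_two_holed(ov, cfg: RunConfig) -> DemoProtocol:
    """Flickering two-holed annulus; equal vs half-size test squares."""
    p = _ov(ov, "px_per_deg", cfg.px_per_deg)
    hole = _px(6 * p, 1.0)
    width = _px(20 * p, 1.0)
    canvas = (_px(16 * p, 1.0), _px(28 * p, 1.0))
    center = (canvas[0] // 2, canvas[1] // 2)
    off = int(round(hole * 0.75))
    adaptors = [ShapeSpec("two_holed_annulus", center, width, inner_size=hole)]
    left = (center[0], center[1] - off)
    right = (center[0], center[1] + off)

    def test_specs(c):
        return [ShapeSpec("filled_square", left, hole, luminance=0.5 + c),
                ShapeSpec("filled_square", right, hole // 2, luminance=0.5 - c)]

    targets = {
        "equal": shape_mask(ShapeSpec("filled_square", left, hole), canvas),
        "half": shape_mask(ShapeSpec("filled_square", right, hole // 2), canvas),
    }
    masks = _standard_masks(canvas, targets, adaptors)
    return DemoProtocol("rds_two_holed_annulus", canvas, cfg.background,
                        adaptors,
                        _ov(ov, "adapt_duration", cfg.adapt_duration_flicker),
                        _ov(ov, "half_period", cfg.half_period),
                        _ov(ov, "test_duration", cfg.test_duration),
                        test_specs, masks, _ov(ov, "adapt", True),
                        _ov(ov, "test_contrast", cfg.test_contrast))


def _disk_canvas(p: float, max_deg: float) -> Tuple[int, int]:
    side = _px(max_deg * p, 1.0) + 2 * _px(1.6 * p, 1.0)
    return (side, side)


def _proto_rds_disks(ov, cfg: RunConfig) -> DemoProtocol:
    """Flickering adaptor disk, then a faint test disk (one condition)."""
    p = _ov(ov, "px_per_deg", cfg.px_per_deg)
    adaptor_deg = _ov(ov, "adaptor_deg", 10.0)
    test_deg = _ov(ov, "test_deg", 10.0)
    canvas = _disk_canvas(p, max(adaptor_deg, test_deg, 15.0))
    center = (canvas[0] // 2, canvas[1] // 2)
    adaptors = [ShapeSpec("disk", center, _px(adaptor_deg * p, 1.0))]
    tsize = _px(test_deg * p, 1.0)

    def test_specs(c):
        return [ShapeSpec("disk", center, tsize, luminance=0.5 + c)]

    targets = {"disk": shape_mask(ShapeSpec("disk", center, tsize), canvas)}
    masks = _standard_masks(canvas, targets, adaptors)
    return DemoProtocol("rds_exp1_disks", canvas, cfg.background, adaptors,
                        _ov(ov, "adapt_duration", cfg.adapt_duration_flicker),
                        _ov(ov, "half_period", cfg.half_period),
                        _ov(ov, "test_duration", cfg.test_duration),
                        test_specs, masks, _ov(ov, "adapt", True),
                        _ov(ov, "test_contrast", cfg.test_contrast))


def _proto_rds_checkerboard(ov, cfg: RunConfig) -> DemoProtocol:
    """Polar checkerboard adaptor with a ring contour at the test edge."""
    p = _ov(ov, "px_per_deg", cfg.px_per_deg)
    inner_check_deg = _ov(ov, "inner_check_deg", 8.0)
    test_deg = _ov(ov, "test_deg", 10.0)
    outer_deg = 16.0
    canvas = _disk_canvas(p, outer_deg)
    center = (canvas[0] // 2, canvas[1] // 2)
    # ring boundaries: innermost check edge, the test-disk edge (always
    # present: every adaptor has a contour at the test location), the rim
    radii_deg = sorted({inner_check_deg / 2.0, test_deg / 2.0, outer_deg / 2.0})
    radii = tuple(r * p for r in radii_deg)
    adaptors = [ShapeSpec("polar_checkerboard", center, _px(outer_deg * p, 1.0),
                          ring_radii=radii, n_sectors=8)]
    tsize = _px(test_deg * p, 1.0)

    def test_specs(c):
        return [ShapeSpec("disk", center, tsize, luminance=0.5 + c)]

    targets = {"disk": shape_mask(ShapeSpec("disk", center, tsize), canvas)}
    masks = _standard_masks(canvas, targets, adaptors)
    return DemoProtocol("rds_exp2_checkerboard", canvas, cfg.background,
                        adaptors,
                        _ov(ov, "adapt_duration", cfg.adapt_duration_flicker),
                        _ov(ov, "half_period", cfg.half_period),
                        _ov(ov, "test_duration", cfg.test_duration),
                        test_specs, masks, _ov(ov, "adapt", True),
                        _ov(ov, "test_contrast", cfg.test_contrast))


def _proto_illusory(ov, cfg: RunConfig) -> DemoProtocol:
    """Illusory-contour inducers (left) vs inducers + drawn contour (right)."""
    scale = _ov(ov, "px_per_deg", cfg.px_per_deg) / 10.0
    tsize, lw = _px(40, scale), _px(2, scale)
    outer = tsize + _px(36, scale)
    canvas = (_px(128, scale), _px(256, scale))
    mid = canvas[0] // 2
    centers = {"illusory": (mid, canvas[1] // 4),
               "real": (mid, 3 * canvas[1] // 4)}
    adaptors = [ShapeSpec("concentric_square_inducers", centers["illusory"],
                          outer, inner_size=tsize, line_width=lw),
                ShapeSpec("concentric_square_inducers", centers["real"],
                          outer, inner_size=tsize, line_width=lw),
                ShapeSpec("outline_square", centers["real"], tsize,
                          line_width=lw)]

    def test_specs(c):
        return [ShapeSpec("filled_square", centers[n], tsize, luminance=0.5 + c)
                for n in centers]

    targets = {n: shape_mask(ShapeSpec("filled_square", centers[n], tsize),
                             canvas) for n in centers}
    masks = _standard_masks(canvas, targets, adaptors)
    return DemoProtocol("illusory_vs_real", canvas, cfg.background, adaptors,
                        _ov(ov, "adapt_duration", cfg.adapt_duration_outline),
                        _ov(ov, "half_period", cfg.half_period),
                        _ov(ov, "test_duration", cfg.test_duration),
                        test_specs, masks, _ov(ov, "adapt", True),
                        _ov(ov, "test_contrast", cfg.test_contrast))


_PROTOCOLS = {
    "ag_movie2_crosses": _proto_ag_movie2,
    "ag_movie3_blur": _proto_ag_movie3,
    "ag_movie4_size": _proto_ag_movie4,
    "ag_movie5_halfsquare": _proto_ag_movie5,
    "ag_movie6_bipartite": _proto_ag_movie6,
    "ag_movie7_pyramids": _proto_ag_movie7,
    "ag_movie8_annuli": _proto_ag_movie8,
    "rds_two_holed_annulus": _proto_rds_two_holed,
    "rds_exp1_disks": _proto_rds_disks,
    "rds_exp2_checkerboard": _proto_rds_checkerboard,
    "illusory_vs_real": _proto_illusory,
}

DEMO_IDS = tuple(sorted(_PROTOCOLS))


def get_protocol(demo_id: str, overrides: Optional[dict] = None,
                 config: Optional[RunConfig] = None) -> DemoProtocol:
    """Resolve a demo id to its adaptation/test protocol."""
    if demo_id not in _PROTOCOLS:
        raise ValueError(
            f"unknown demo id {demo_id!r}; valid ids: {', '.join(DEMO_IDS)}")
    cfg = config or RunConfig()
    return _PROTOCOLS[demo_id](overrides, cfg)


def build_demo(demo_id: str, overrides: Optional[dict] = None,
               config: Optional[RunConfig] = None) -> StimulusSequence:
    """Complete adaptation + test movie for one catalog demo.

    ``overrides`` may replace any protocol parameter; ``{"adapt": False}``
    yields the no-adapt control in which the flicker phase is replaced by a
    uniform background of equal duration.
    """
    return get_protocol(demo_id, overrides, config).sequence()
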