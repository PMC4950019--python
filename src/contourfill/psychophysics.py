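"""Simulated psychophysics on top of the model pipeline.

This module runs complete stimulus movies through the opponent front end,
the gated-dipole boundary system and the filling-in stage, quantifies how
distinct a target region is from its surround at the filling-in stage, and
measures contrast thresholds as the smallest test contrast that still
produces a separate target representation.  The model is fully
deterministic, so thresholds are found by bisection rather than adaptive
staircases.

Visibility criterion.  A target counts as visible when its
target-vs-surround brightness difference exceeds a fixed fraction
(``RunConfig.criterion_fraction``) of the difference the *same* target
produces at the default test contrast with no prior adaptation.  The
criterion is re-derived per geometry, which keeps the visible/invisible
call meaningful under parameter rescaling.  Because adaptation phases leave
residual filled-in activity, the harness subtracts the response to a
zero-contrast test from the same adapted state before applying the
criterion, isolating the test stimulus' own contribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .config import RunConfig
from .front_end import surface_contrast, to_opponent
from .boundary_system import (BoundaryField, GateState, dipole_output,
                              oriented_contrast, step_gates)
from .filling_in import (PerceptField, max_stable_dt, permeability,
                         step_filling)
from .stimuli import DemoProtocol, Frame, StimulusSequence, get_protocol

__all__ = [
    "Simulator",
    "SimulationTrace",
    "ExperimentSpec",
    "ThresholdResult",
    "DemoOutcome",
    "run_simulation",
    "target_visibility",
    "contrast_threshold",
    "ThresholdEngine",
    "run_experiment_battery",
    "check_demo_outcomes",
    "BATTERY_IDS",
]


# ---------------------------------------------------------------------------
# simulator
# ---------------------------------------------------------------------------


class Simulator:
    """Integrates the full model over a stimulus movie.

    Boundary gates advance with the configured ``dt``; the filling-in
    lattice sub-steps within each boundary step to honor its stricter
    explicit-Euler stability bound.  The state (gates + percept) can be
    cloned cheaply, which lets the threshold harness adapt once and replay
    only the test phase at many contrasts.
    """

    def __init__(self, shape: Tuple[int, int], config: RunConfig):
        config.validate()
        self.config = config
        self.shape = tuple(shape)
        self.gates = GateState.fresh(self.shape)
        self.percept = PerceptField.zeros(self.shape)
        self.t = 0.0
        self._nsub = max(1, int(np.ceil(config.dt
                                        / (0.9 * max_stable_dt(config.fill)))))

    def clone(self) -> "Simulator":
        other = Simulator.__new__(Simulator)
        other.config = self.config
        other.shape = self.shape
        other.gates = self.gates.copy()
        other.percept = self.percept.copy()
        other.t = self.t
        other._nsub = self._nsub
        return other

    def run_frame(self, frame: Frame,
                  callback: Optional[Callable] = None) -> None:
        """Advance the model through one frame of the movie.

        ``callback(t, boundary, percept)`` fires after every boundary step.
        """
        if frame.shape != self.shape:
            raise ValueError("frame shape does not match simulator grid")
        cfg = self.config
        opponent = to_opponent(frame, cfg.background)
        drive = oriented_contrast(opponent, cfg.dipole)
        source = surface_contrast(opponent, cfg.source_surround_sigma)
        n = max(1, int(round(frame.duration / cfg.dt)))
        dt_sub = cfg.dt / self._nsub
        for _ in range(n):
            boundary = dipole_output(drive, self.gates, cfg.dipole)
            perm = permeability(boundary, cfg.fill)
            for _ in range(self._nsub):
                self.percept = step_filling(self.percept, source, perm,
                                            cfg.fill, dt_sub)
            self.gates = step_gates(self.gates, drive, cfg.dipole, cfg.dt)
            self.t += cfg.dt
            if callback is not None:
                callback(self.t, boundary, self.percept)

    def run_frames(self, frames: Sequence[Frame],
                   callback: Optional[Callable] = None) -> None:
        for frame in frames:
            self.run_frame(frame, callback)


@dataclass
class SimulationTrace:
    """Sampled boundary and percept snapshots over one movie."""

    times: List[float]
    boundary_snapshots: List[BoundaryField]
    percept_snapshots: List[PerceptField]
    sequence: StimulusSequence

    def __post_init__(self):
        if not (len(self.times) == len(self.boundary_snapshots)
                == len(self.percept_snapshots)):
            raise ValueError("snapshot lists must align with times")
        if any(b <= a for a, b in zip(self.times, self.times[1:])):
            raise ValueError("snapshot times must be strictly increasing")

    @property
    def final_percept(self) -> PerceptField:
        return self.percept_snapshots[-1]

    @property
    def final_boundary(self) -> BoundaryField:
        return self.boundary_snapshots[-1]


def run_simulation(sequence: StimulusSequence,
                   config: Optional[RunConfig] = None,
                   sample_every: Optional[float] = None) -> SimulationTrace:
    """Integrate front end -> boundaries -> filling-in over a full movie.

    Snapshots are recorded every ``sample_every`` seconds and at the end of
    the movie.  The model contains no randomness: reruns are bit-identical.
    """
    cfg = config or RunConfig()
    cadence = sample_every if sample_every is not None else cfg.sample_every
    sim = Simulator(sequence.shape, cfg)
    times: List[float] = []
    bsnaps: List[BoundaryField] = []
    psnaps: List[PerceptField] = []
    next_sample = [cadence]

    def record(t, boundary, percept):
        if t + 1e-9 >= next_sample[0]:
            times.append(t)
            bsnaps.append(BoundaryField(boundary.vertical.copy(),
                                        boundary.horizontal.copy()))
            psnaps.append(percept.copy())
            while next_sample[0] <= t + 1e-9:
                next_sample[0] += cadence

    total = sequence.total_duration
    for frame in sequence.frames:
        sim.run_frame(frame, record)
    if not times or times[-1] < total - 1e-6:
        # guarantee a snapshot at the end of the movie
        frame = sequence.frames[-1]
        src = to_opponent(frame, cfg.background)
        drive = oriented_contrast(src, cfg.dipole)
        times.append(sim.t)
        bsnaps.append(dipole_output(drive, sim.gates, cfg.dipole))
        psnaps.append(sim.percept.copy())
    return SimulationTrace(times, bsnaps, psnaps, sequence)


# ---------------------------------------------------------------------------
# visibility
# ---------------------------------------------------------------------------


def target_visibility(percept: PerceptField, target_mask: np.ndarray,
                      surround_mask: np.ndarray) -> float:
    """Absolute mean-brightness difference between target and surround."""
    if target_mask.sum() == 0 or surround_mask.sum() == 0:
        raise ValueError("visibility masks must be non-empty")
    if np.any(target_mask & surround_mask):
        raise ValueError("target and surround masks must be disjoint")
    b = percept.brightness
    return float(abs(b[target_mask].mean() - b[surround_mask].mean()))


def _signed_separation(percept: PerceptField, target_mask, surround_mask) -> float:
    b = percept.brightness
    return float(b[target_mask].mean() - b[surround_mask].mean())


# ---------------------------------------------------------------------------
# contrast thresholds
# ---------------------------------------------------------------------------


@dataclass
class ExperimentSpec:
    """One threshold measurement: a demo geometry plus search settings."""

    demo_id: str
    overrides: Dict = field(default_factory=dict)
    adapt: bool = True
    #: which annotated target to measure (``target_<name>``); None = the
    #: demo's only target
    target: Optional[str] = None
    search_bounds: Tuple[float, float] = (0.004, 0.5)
    #: absolute visibility criterion; None = derive from the no-adapt
    #: response at the default test contrast
    visibility_criterion: Optional[float] = None
    #: geometry labels (degrees of visual angle) carried into the result
    adaptor_deg: float = float("nan")
    test_deg: float = float("nan")

    def __post_init__(self):
        lo, hi = self.search_bounds
        if not (0.0 < lo < hi <= 0.5):
            raise ValueError("search bounds must lie within (0, 0.5]")


@dataclass
class ThresholdResult:
    """Outcome of one bisection threshold search."""

    demo_id: str
    target: str
    adaptor_deg: float
    test_deg: float
    adapted: bool
    threshold_contrast: Optional[float]
    not_visible_at_max: bool
    criterion: float
    iterations: int

    def __post_init__(self):
        if (self.threshold_contrast is None) == (not self.not_visible_at_max):
            raise ValueError(
                "exactly one of threshold_contrast / not_visible_at_max")


class ThresholdEngine:
    """Threshold measurements with cached adaptation states.

    Adaptation (or blank-control) phases depend only on the adaptor, not on
    the test contrast, so each is simulated once and its end state replayed
    for every probe contrast.
    """

    def __init__(self, config: Optional[RunConfig] = None):
        self.config = config or RunConfig()
        self._state_cache: Dict = {}

    # -- internals ---------------------------------------------------------

    def _adapted_state(self, proto: DemoProtocol) -> Simulator:
        key = (proto.demo_id, proto.canvas, round(proto.adapt_duration, 9),
               round(proto.half_period, 9), proto.adapt,
               tuple(repr(s) for s in proto.adaptor_specs) if proto.adapt
               else None)
        if key not in self._state_cache:
            sim = Simulator(proto.canvas, self.config)
            sim.run_frames(proto.adapt_frames())
            self._state_cache[key] = sim
        return self._state_cache[key].clone()

    def _separation(self, proto: DemoProtocol, state: Simulator,
                    contrast: float, tmask, smask) -> float:
        sim = state.clone()
        sim.run_frame(proto.test_frame(contrast))
        return _signed_separation(sim.percept, tmask, smask)

    def visibility(self, proto: DemoProtocol, contrast: float,
                   target: str) -> float:
        """Baseline-corrected visibility of one target at one contrast."""
        tmask = proto.masks[f"target_{target}"]
        smask = proto.masks[f"surround_{target}"]
        state = self._adapted_state(proto)
        base = self._separation(proto, state, 0.0, tmask, smask)
        sep = self._separation(proto, state, contrast, tmask, smask)
        return abs(sep - base)

    def criterion_for(self, spec: ExperimentSpec, target: str) -> float:
        if spec.visibility_criterion is not None:
            return spec.visibility_criterion
        ctrl = get_protocol(spec.demo_id, {**spec.overrides, "adapt": False},
                            self.config)
        v = self.visibility(ctrl, self.config.test_contrast, target)
        return self.config.criterion_fraction * v

    # -- public API --------------------------------------------------------

    def threshold(self, spec: ExperimentSpec) -> ThresholdResult:
        """Bisection for the smallest visible test contrast.

        Verifies that visibility grows with contrast on the initial bracket
        before bisecting; a non-monotone profile raises with the measured
        values so parameter pathologies surface instead of being silently
        bisected over.
        """
        cfg = self.config
        proto = get_protocol(spec.demo_id,
                             {**spec.overrides, "adapt": spec.adapt}, cfg)
        target = spec.target or _single_target(proto)
        tmask = proto.masks[f"target_{target}"]
        smask = proto.masks[f"surround_{target}"]
        crit = self.criterion_for(spec, target)
        state = self._adapted_state(proto)
        base = self._separation(proto, state, 0.0, tmask, smask)
        iterations = 0

        def vis(c: float) -> float:
            nonlocal iterations
            iterations += 1
            return abs(self._separation(proto, state, c, tmask, smask) - base)

        lo, hi = spec.search_bounds
        mid0 = 0.5 * (lo + hi)
        profile = [(lo, vis(lo)), (mid0, vis(mid0)), (hi, vis(hi))]
        tol = 0.05 * max(v for _, v in profile) + 1e-12
        if not all(a[1] <= b[1] + tol for a, b in zip(profile, profile[1:])):
            raise RuntimeError(
                "visibility is not monotone in contrast on the initial "
                f"bracket: {profile}; inspect model parameters")

        meta = (spec.adaptor_deg, spec.test_deg)
        if profile[-1][1] < crit:
            return ThresholdResult(spec.demo_id, target, *meta, spec.adapt,
                                   None, True, crit, iterations)
        if profile[0][1] >= crit:
            return ThresholdResult(spec.demo_id, target, *meta, spec.adapt,
                                   lo, False, crit, iterations)
        v_mid = profile[1][1]
        if v_mid >= crit:
            hi = mid0
        else:
            lo = mid0
        while hi - lo > 1e-3:
            mid = 0.5 * (lo + hi)
            if vis(mid) >= crit:
                hi = mid
            else:
                lo = mid
        return ThresholdResult(spec.demo_id, target, *meta, spec.adapt,
                               hi, False, crit, iterations)


def _single_target(proto: DemoProtocol) -> str:
    names = [k[len("target_"):] for k in proto.masks
             if k.startswith("target_") and k != "target_region"]
    if len(names) != 1:
        raise ValueError(
            f"demo {proto.demo_id!r} has targets {names}; specify one")
    return names[0]


def contrast_threshold(spec: ExperimentSpec,
                       config: Optional[RunConfig] = None) -> ThresholdResult:
    """Measure one contrast threshold (convenience wrapper)."""
    return ThresholdEngine(config).threshold(spec)


# ---------------------------------------------------------------------------
# experiment batteries
# ---------------------------------------------------------------------------

BATTERY_IDS = ("rds_fig5", "rds_exp1_fig6", "rds_exp2_fig7",
               "ag_size_selectivity")


def _battery_rows(battery_id: str, cfg: RunConfig) -> List[dict]:
    p = cfg.battery_px_per_deg
    if battery_id == "rds_fig5":
        rows = []
        for adapted in (True, False):
            for target, test_deg in (("equal", 6.0), ("half", 3.0)):
                rows.append(dict(demo_id="rds_two_holed_annulus",
                                 overrides={"px_per_deg": p},
                                 adapt=adapted, target=target,
                                 adaptor_deg=6.0, test_deg=test_deg))
        return rows
    if battery_id == "rds_exp1_fig6":
        rows = []
        for test_deg in (2.0, 10.0):
            for adaptor_deg in (2.0, 4.0, 10.0, 12.0, 15.0):
                rows.append(dict(demo_id="rds_exp1_disks",
                                 overrides={"px_per_deg": p,
                                            "adaptor_deg": adaptor_deg,
                                            "test_deg": test_deg},
                                 adapt=True, target="disk",
                                 adaptor_deg=adaptor_deg, test_deg=test_deg))
            rows.append(dict(demo_id="rds_exp1_disks",
                             overrides={"px_per_deg": p,
                                        "adaptor_deg": 10.0,
                                        "test_deg": test_deg},
                             adapt=False, target="disk",
                             adaptor_deg=0.0, test_deg=test_deg))
        return rows
    if battery_id == "rds_exp2_fig7":
        rows = []
        for check_deg in (4.0, 8.0, 10.0):
            rows.append(dict(demo_id="rds_exp2_checkerboard",
                             overrides={"px_per_deg": p,
                                        "inner_check_deg": check_deg,
                                        "test_deg": 10.0},
                             adapt=True, target="disk",
                             adaptor_deg=check_deg, test_deg=10.0))
        rows.append(dict(demo_id="rds_exp2_checkerboard",
                         overrides={"px_per_deg": p, "inner_check_deg": 8.0,
                                    "test_deg": 10.0},
                         adapt=False, target="disk",
                         adaptor_deg=0.0, test_deg=10.0))
        return rows
    if battery_id == "ag_size_selectivity":
        rows = []
        for adapted in (True, False):
            for target, test_deg in (("matched", 4.0), ("smaller", 2.4),
                                     ("larger", 5.6)):
                rows.append(dict(demo_id="ag_movie4_size",
                                 overrides={"px_per_deg": p},
                                 adapt=adapted, target=target,
                                 adaptor_deg=4.0, test_deg=test_deg))
        return rows
    raise ValueError(
        f"unknown battery {battery_id!r}; valid ids: {BATTERY_IDS}")


def run_experiment_battery(battery_id: str,
                           config: Optional[RunConfig] = None,
                           out_dir: Optional[str] = None) -> pd.DataFrame:
    """Full factorial threshold sweep for one experiment analog.

    Returns (and optionally writes) a table with one row per condition:
    ``battery_id, demo_id, adaptor_deg, test_deg, adapted,
    threshold_contrast, criterion, params_hash``.
    """
    cfg = config or RunConfig()
    engine = ThresholdEngine(cfg)
    records = []
    for row in _battery_rows(battery_id, cfg):
        spec = ExperimentSpec(demo_id=row["demo_id"],
                              overrides=row["overrides"],
                              adapt=row["adapt"], target=row["target"],
                              adaptor_deg=row["adaptor_deg"],
                              test_deg=row["test_deg"])
        res = engine.threshold(spec)
        records.append({
            "battery_id": battery_id,
            "demo_id": row["demo_id"],
            "adaptor_deg": row["adaptor_deg"],
            "test_deg": row["test_deg"],
            "adapted": row["adapt"],
            "threshold_contrast": (np.nan if res.threshold_contrast is None
                                   else res.threshold_contrast),
            "criterion": res.criterion,
            "params_hash": cfg.params_hash,
        })
    df = pd.DataFrame.from_records(records)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        df.to_csv(out / f"{battery_id}.csv", index=False,
                  float_format="%.6g")
        _plot_battery(df, battery_id, out / f"{battery_id}.png")
    return df


def _plot_battery(df: pd.DataFrame, battery_id: str, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    labels, values, colors = [], [], []
    for _, row in df.iterrows():
        tag = "adapt" if row["adapted"] else "no-adapt"
        labels.append(f"a={row['adaptor_deg']:g}\nt={row['test_deg']:g}\n{tag}")
        values.append(row["threshold_contrast"])
        colors.append("tab:red" if row["adapted"] else "tab:gray")
    ax.bar(range(len(values)), values, color=colors)
    ax.set_xticks(range(len(values)))
    ax.set_xticklabels(labels, fontsize=7)
    ax.set_ylabel("threshold contrast (model units)")
    ax.set_title(battery_id)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


# ---------------------------------------------------------------------------
# demo outcome checks
# ---------------------------------------------------------------------------


@dataclass
class DemoOutcome:
    """Boolean perceptual claim evaluated for one demo."""

    demo_id: str
    claim: str
    passed: bool
    expected_fail: bool
    values: Dict[str, float]


def _demo_visibilities(engine: ThresholdEngine, demo_id: str,
                       targets: Sequence[str],
                       overrides: Optional[dict] = None,
                       contrast: Optional[float] = None):
    """Adapted visibility, control visibility and criterion per target."""
    cfg = engine.config
    ov = dict(overrides or {})
    c = contrast if contrast is not None else cfg.test_contrast
    proto_a = get_protocol(demo_id, {**ov, "adapt": True}, cfg)
    proto_c = get_protocol(demo_id, {**ov, "adapt": False}, cfg)
    out = {}
    for t in targets:
        va = engine.visibility(proto_a, c, t)
        vc = engine.visibility(proto_c, c, t)
        out[t] = (va, vc, cfg.criterion_fraction * vc)
    return out


def check_demo_outcomes(config: Optional[RunConfig] = None,
                        demo_ids: Optional[Sequence[str]] = None
                        ) -> Dict[str, DemoOutcome]:
    """Evaluate the qualitative perceptual claim behind every demo.

    Each demo runs in its adapt and no-adapt variants; targets count as
    visible when their baseline-corrected visibility exceeds the
    self-calibrated criterion.  The half-square demo is asserted as the
    model's documented *failure*: erasure spreads to the unadapted side.
    """
    cfg = config or RunConfig()
    engine = ThresholdEngine(cfg)
    checks: Dict[str, Callable[[], DemoOutcome]] = {}

    def add(demo_id, claim, fn, expected_fail=False):
        def runner():
            passed, values = fn()
            return DemoOutcome(demo_id, claim, passed, expected_fail, values)
        checks[demo_id] = runner

    def vis_for(demo_id, targets, **kw):
        return _demo_visibilities(engine, demo_id, targets, **kw)

    def _check_movie2():
        v = vis_for("ag_movie2_crosses", ["top", "bottom", "left", "right"])
        passed = (v["top"][0] < v["top"][2] and v["bottom"][0] < v["bottom"][2]
                  and v["left"][0] > v["left"][2]
                  and v["right"][0] > v["right"][2])
        return passed, _flat(v)

    add("ag_movie2_crosses",
        "equal-size test crosses vanish at flickered locations only",
        _check_movie2)

    def _check_movie3():
        v = vis_for("ag_movie3_blur", ["blurred", "sharp"])
        passed = v["blurred"][0] > v["blurred"][2] and v["sharp"][0] < v["sharp"][2]
        return passed, _flat(v)

    add("ag_movie3_blur",
        "blurred-edge flicker does not erase; sharp outline does",
        _check_movie3)

    def _check_movie4():
        v = vis_for("ag_movie4_size", ["matched", "smaller", "larger"])
        passed = (v["matched"][0] < v["matched"][2]
                  and v["smaller"][0] > v["smaller"][2]
                  and v["larger"][0] > v["larger"][2])
        return passed, _flat(v)

    add("ag_movie4_size", "erasure only when adaptor and test sizes match",
        _check_movie4)

    def _check_movie5():
        v = vis_for("ag_movie5_halfsquare", ["adapted_half", "unadapted_half"])
        # the percept keeps the unadapted side nearly normal; the model
        # instead erases the adapted side completely and drains most of the
        # unadapted side through the one-sided boundary gap.  Reproducing
        # that over-erasure is the expected outcome.
        adapted_gone = v["adapted_half"][0] < v["adapted_half"][2]
        unadapted_drained = v["unadapted_half"][0] < 0.6 * v["unadapted_half"][1]
        return adapted_gone and unadapted_drained, _flat(v)

    add("ag_movie5_halfsquare",
        "model over-erases the unadapted side (documented failure)",
        _check_movie5, expected_fail=True)

    def _check_movie6():
        engineer = engine
        cfgl = engineer.config
        proto_a = get_protocol("ag_movie6_bipartite", {"adapt": True}, cfgl)
        proto_c = get_protocol("ag_movie6_bipartite", {"adapt": False}, cfgl)

        def side_diff(proto):
            state = engineer._adapted_state(proto)
            sim = state.clone()
            sim.run_frame(proto.test_frame())
            return abs(_signed_separation(
                sim.percept, proto.masks["target_left_half"],
                proto.masks["target_right_half"]))

        da, dc = side_diff(proto_a), side_diff(proto_c)
        # "same brightness": the side difference collapses to a small
        # fraction of its unadapted value once the divider is erased
        return da < 0.2 * dc, {
            "adapted_side_difference": da, "control_side_difference": dc}

    add("ag_movie6_bipartite",
        "after line adaptation the two half-fields appear equally bright",
        _check_movie6)

    def _check_movie7():
        v = vis_for("ag_movie7_pyramids", ["center"])
        return v["center"][0] < v["center"][2], _flat(v)

    add("ag_movie7_pyramids",
        "pyramid steps merge: the high-contrast center becomes "
        "indistinct from its surrounding step",
        _check_movie7)

    def _check_movie8():
        v = vis_for("ag_movie8_annuli", ["hole", "body"])
        # inner-edge adaptation fills the hole (invisible) while the
        # annulus as a whole remains visible against the background
        passed = v["hole"][0] < v["hole"][2] and v["body"][0] > v["body"][2]
        return passed, _flat(v)

    add("ag_movie8_annuli",
        "inner-edge adaptation yields a filled shape without a hole",
        _check_movie8)

    def _check_rds_annulus():
        v = vis_for("rds_two_holed_annulus", ["equal", "half"],
                    overrides={"px_per_deg": cfg.battery_px_per_deg})
        passed = v["equal"][0] < v["equal"][2] and v["half"][0] > v["half"][2]
        return passed, _flat(v)

    add("rds_two_holed_annulus",
        "hole-sized test erased, half-sized test spared",
        _check_rds_annulus)

    def _check_rds_disks():
        # disks are bounded by curved contours whose diagonal arcs fall in
        # the opponent tie-break of the two-orientation dipole, so even the
        # unadapted disk traps weakly; the effect here is the measured one:
        # a strong reduction in apparent contrast, not full invisibility
        v = vis_for("rds_exp1_disks", ["disk"],
                    overrides={"px_per_deg": cfg.battery_px_per_deg,
                               "adaptor_deg": 10.0, "test_deg": 10.0})
        return v["disk"][0] < 0.5 * v["disk"][1], _flat(v)

    add("rds_exp1_disks",
        "size-matched disk adaptation strongly reduces test-disk contrast",
        _check_rds_disks)

    def _check_rds_checkerboard():
        v = vis_for("rds_exp2_checkerboard", ["disk"],
                    overrides={"px_per_deg": cfg.battery_px_per_deg,
                               "inner_check_deg": 8.0, "test_deg": 10.0})
        return v["disk"][0] < 0.75 * v["disk"][1], _flat(v)

    add("rds_exp2_checkerboard",
        "checkerboard contour at the test edge reduces test-disk contrast",
        _check_rds_checkerboard)

    def _check_illusory():
        v = vis_for("illusory_vs_real", ["illusory", "real"])
        passed = (v["illusory"][0] > v["illusory"][2]
                  and v["real"][0] < v["real"][2])
        return passed, _flat(v)

    add("illusory_vs_real",
        "illusory-contour inducers do not erase; a drawn contour does",
        _check_illusory)

    wanted = list(checks) if demo_ids is None else list(demo_ids)
    return {d: checks[d]() for d in wanted}


def _flat(v: Dict[str, Tuple[float, float, float]]) -> Dict[str, float]:
    out = {}
    for name, (va, vc, crit) in v.items():
        out[f"{name}_adapted"] = va
        out[f"{name}_control"] = vc
        out[f"{name}_criterion"] = crit
    return out
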