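"""End-to-end scientific validation suite.

Each method of :class:`ValidationSuite` re-derives one of the package's
headline results from scratch -- gate dynamics against their closed form,
the filling-in integrator against a direct linear solve, and the full
erasure / size-selectivity / checkerboard / illusory-contour result
patterns via the psychophysics harness.  Expensive batteries are computed
once per suite instance and shared between checks.

The model itself is deterministic; the only randomness is the instance
generator for the filling-in oracle comparison, controlled by ``seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict

import numpy as np
import pandas as pd

from .config import FillParams, RunConfig
from .front_end import OpponentField
from .boundary_system import (BoundaryField, gate_equilibrium,
                              simulate_dipole_trace)
from .filling_in import (PerceptField, max_stable_dt, permeability,
                         step_filling, steady_state_oracle)
from .psychophysics import (ThresholdEngine, _demo_visibilities,
                            run_experiment_battery)
from .stimuli import get_protocol

__all__ = ["ValidationSuite"]


@dataclass
class ValidationSuite:
    """Recomputes the package's validation quantities from scratch."""

    config: RunConfig = field(default_factory=RunConfig)
    seed: int = 0

    def __post_init__(self):
        self._batteries: Dict[str, pd.DataFrame] = {}
        self._engine = ThresholdEngine(self.config)

    # ------------------------------------------------------------------
    # boundary-system dynamics
    # ------------------------------------------------------------------

    def gate_equilibrium_error(self, signal: float = 2.0) -> Dict[str, float]:
        """Integrated gate level vs the closed form alpha/(alpha+beta*S).

        The drive is held constant and the gate integrated for ten time
        constants of the linear relaxation, after which the Euler solution
        should sit on the analytic equilibrium to well under 1%.
        """
        p = self.config.dipole
        drive = signal - p.tonic
        rate = p.alpha + p.beta * signal
        T = 10.0 / rate
        tr = simulate_dipole_trace([(T, drive, 0.0)], p, self.config.dt)
        z_end = tr["z_vertical"][-1]
        z_eq = gate_equilibrium(signal, p)
        return {"relative_error": abs(z_end - z_eq) / z_eq,
                "signal": signal, "z_equilibrium": z_eq}

    def rebound(self, strong: float = 5.0, weak: float = 0.5
                ) -> Dict[str, float]:
        """Opponent rebound after an input decrement, adapted vs fresh.

        Four seconds of strong vertical drive followed by a weak vertical
        drive must produce a transient positive horizontal output; the
        identical decrement applied to fresh gates must not.
        """
        p, dt = self.config.dipole, self.config.dt
        adapted = simulate_dipole_trace([(4.0, strong, 0.0),
                                         (2.0, weak, 0.0)], p, dt)
        i4 = np.searchsorted(adapted["times"], 4.0)
        fresh = simulate_dipole_trace([(2.0, weak, 0.0)], p, dt)
        return {
            "adapted_rebound_peak": float(adapted["out_horizontal"][i4:].max()),
            "fresh_rebound_peak": float(fresh["out_horizontal"].max()),
        }

    # ------------------------------------------------------------------
    # filling-in numerics
    # ------------------------------------------------------------------

    def filling_oracle_error(self, n_instances: int = 20,
                             grid: int = 8) -> Dict[str, float]:
        """Time-stepped steady state vs direct sparse solve on random fields.

        Random sources and boundary fields on small grids; the integrator
        runs to convergence and is compared against the assembled linear
        system in max-norm.
        """
        rng = np.random.default_rng(self.seed)
        worst = 0.0
        for _ in range(n_instances):
            params = FillParams(decay=float(rng.uniform(0.5, 2.0)),
                                couple=float(rng.uniform(5.0, 50.0)),
                                block=float(rng.uniform(0.0, 20.0)),
                                input_gain=float(rng.uniform(1.0, 5.0)))
            src = OpponentField(on=rng.uniform(0, 1, (grid, grid)),
                                off=rng.uniform(0, 1, (grid, grid)))
            bnd = BoundaryField(vertical=rng.uniform(0, 1, (grid, grid))
                                * rng.integers(0, 2, (grid, grid)),
                                horizontal=rng.uniform(0, 1, (grid, grid))
                                * rng.integers(0, 2, (grid, grid)))
            perm = permeability(bnd, params)
            exact = steady_state_oracle(src, perm, params)
            dt = 0.9 * max_stable_dt(params)
            x = PerceptField.zeros((grid, grid))
            for _ in range(int(np.ceil(40.0 / (params.decay * dt)))):
                x = step_filling(x, src, perm, params, dt)
            err = max(np.abs(x.on_fill - exact.on_fill).max(),
                      np.abs(x.off_fill - exact.off_fill).max())
            worst = max(worst, float(err))
        return {"max_abs_error": worst, "n_instances": n_instances}

    def trapping_leak(self, box: int = 20, strength: float = 2.0,
                      duration: float = 3.0) -> Dict[str, float]:
        """Closed vs one-side-open boundary rectangle around a source.

        A closed rectangle of strong boundaries must hold the interior
        far above the exterior; removing a single side must collapse the
        difference -- the model's documented one-gap failure mode.  The
        reference criterion is half of the perfectly trapped accumulation
        ``C * s * T``.
        """
        cfg = self.config
        fp = cfg.fill
        H = W = 48
        s = cfg.test_contrast
        rr, cc = np.indices((H, W))
        half = box // 2
        top, bot = H // 2 - half, H // 2 + half
        left, right = W // 2 - half, W // 2 + half
        vert = np.zeros((H, W))
        horiz = np.zeros((H, W))
        vert[top:bot + 1, left] = strength
        vert[top:bot + 1, right] = strength
        horiz[top, left:right + 1] = strength
        horiz[bot, left:right + 1] = strength
        interior = (rr > top) & (rr < bot) & (cc > left) & (cc < right)
        exterior = ~((rr >= top - 1) & (rr <= bot + 1)
                     & (cc >= left - 1) & (cc <= right + 1))
        src = OpponentField(on=np.where(interior, s, 0.0),
                            off=np.zeros((H, W)))

        def run(vertical):
            perm = permeability(BoundaryField(vertical=vertical,
                                              horizontal=horiz), fp)
            dt = 0.9 * max_stable_dt(fp)
            x = PerceptField.zeros((H, W))
            for _ in range(int(round(duration / dt))):
                x = step_filling(x, src, perm, fp, dt)
            b = x.brightness
            return float(b[interior].mean() - b[exterior].mean())

        closed = run(vert)
        vert_open = vert.copy()
        vert_open[top:bot + 1, right] = 0.0
        open_ = run(vert_open)
        criterion = 0.5 * fp.input_gain * s * duration
        return {"closed_diff": closed, "open_diff": open_,
                "criterion": criterion}

    # ------------------------------------------------------------------
    # erasure demos
    # ------------------------------------------------------------------

    def erasure_crosses(self) -> Dict[str, float]:
        """Outline-cross erasure with orthogonal residual boundaries.

        After flicker adaptation the equal-size test crosses at flickered
        locations must fall below the visibility criterion while the
        unflickered ones stay above it; the residual boundary activity on
        the adapted crosses' edges must be orthogonal to those edges.
        """
        cfg = self.config
        vis = _demo_visibilities(self._engine, "ag_movie2_crosses",
                                 ["top", "left"])
        out = {
            "adapted_visibility": vis["top"][0],
            "unadapted_visibility": vis["left"][0],
            "criterion": vis["top"][2],
        }

        # boundary snapshot shortly after test onset, where the rebound
        # after-responses are strongest
        proto = get_protocol("ag_movie2_crosses", {"adapt": True}, cfg)
        sim = self._engine._adapted_state(proto)
        t0 = sim.t
        snap = {}

        def grab(t, boundary, percept):
            if "b" not in snap and t >= t0 + 0.25 - 1e-9:
                snap["b"] = BoundaryField(boundary.vertical.copy(),
                                          boundary.horizontal.copy())

        sim.run_frame(proto.test_frame(), grab)
        boundary = snap["b"]

        vert_edges, horiz_edges = _edge_masks(proto.masks["target_top"])
        on_vert = (float(boundary.vertical[vert_edges].sum()),
                   float(boundary.horizontal[vert_edges].sum()))
        on_horiz = (float(boundary.vertical[horiz_edges].sum()),
                    float(boundary.horizontal[horiz_edges].sum()))
        residual = on_vert[0] + on_horiz[1]          # parallel to edges
        orthogonal = on_vert[1] + on_horiz[0]        # rebound orientations
        out["orthogonal_residual_fraction"] = (
            orthogonal / max(orthogonal + residual, 1e-12))
        return out

    def blur_non_erasure(self) -> Dict[str, float]:
        """Blurred-surface adaptor spares the test; sharp outline erases."""
        vis = _demo_visibilities(self._engine, "ag_movie3_blur",
                                 ["blurred", "sharp"])
        return {
            "blurred_adaptor_visibility": vis["blurred"][0],
            "sharp_adaptor_visibility": vis["sharp"][0],
            "criterion": vis["blurred"][2],
        }

    def illusory_contour(self) -> Dict[str, float]:
        """Sparse inducers spare the test square; a drawn contour erases."""
        vis = _demo_visibilities(self._engine, "illusory_vs_real",
                                 ["illusory", "real"])
        return {
            "illusory_adaptor_visibility": vis["illusory"][0],
            "real_adaptor_visibility": vis["real"][0],
            "criterion": vis["illusory"][2],
        }

    # ------------------------------------------------------------------
    # threshold batteries
    # ------------------------------------------------------------------

    def battery(self, battery_id: str) -> pd.DataFrame:
        if battery_id not in self._batteries:
            self._batteries[battery_id] = run_experiment_battery(
                battery_id, self.config)
        return self._batteries[battery_id]

    def size_selectivity(self) -> Dict[str, float]:
        """Same-size vs half-size threshold elevation (annulus-hole targets)."""
        df = self.battery("rds_fig5")

        def thr(adapted, test_deg):
            row = df[(df.adapted == adapted) & (df.test_deg == test_deg)]
            return float(row.threshold_contrast.iloc[0])

        return {
            "same_size_elevation_ratio": thr(True, 6.0) / thr(False, 6.0),
            "half_size_relative_change":
                abs(thr(True, 3.0) - thr(False, 3.0)) / thr(False, 3.0),
        }

    def disk_size_diagonal(self) -> Dict[str, float]:
        """Matched-size maximality of threshold elevation across disk sizes."""
        df = self.battery("rds_exp1_fig6")
        out = {}
        for test_deg in (2.0, 10.0):
            sub = df[(df.test_deg == test_deg) & df.adapted]
            matched = float(sub[sub.adaptor_deg == test_deg]
                            .threshold_contrast.iloc[0])
            others = sub[sub.adaptor_deg != test_deg].threshold_contrast
            out[f"matched_minus_max_unmatched_test{int(test_deg)}"] = (
                matched - float(others.max()))
        return out

    def checkerboard_pattern(self) -> Dict[str, float]:
        """All checkerboard adaptors elevate; spread among them is small."""
        df = self.battery("rds_exp2_fig7")
        base = float(df[~df.adapted].threshold_contrast.iloc[0])
        adapted = df[df.adapted].threshold_contrast.astype(float)
        gap = float(adapted.min()) - base
        spread = float(adapted.max() - adapted.min())
        return {"min_elevation": gap, "pairwise_spread": spread,
                "no_adapt_threshold": base}

    def overlap_control(self) -> Dict[str, float]:
        """Non-overlapping contours leave the threshold essentially unchanged.

        The 15-degree disk adaptor's contour lies 2.5 degrees outside the
        10-degree test's contour; its threshold must match no-adapt within
        a few percent.
        """
        df = self.battery("rds_exp1_fig6")
        sub = df[df.test_deg == 10.0]
        t_far = float(sub[(sub.adaptor_deg == 15.0) & sub.adapted]
                      .threshold_contrast.iloc[0])
        t_none = float(sub[~sub.adapted].threshold_contrast.iloc[0])
        return {"relative_change": abs(t_far - t_none) / t_none}

    def determinism(self) -> Dict[str, float]:
        """A full battery rerun must be byte-identical."""
        first = self.battery("rds_fig5")
        again = run_experiment_battery("rds_fig5", self.config)
        identical = first.to_csv(index=False) == again.to_csv(index=False)
        max_diff = float(np.nanmax(np.abs(
            first.threshold_contrast.to_numpy()
            - again.threshold_contrast.to_numpy())))
        return {"rerun_identical": float(identical),
                "max_abs_diff": max_diff}


def _edge_masks(target_mask: np.ndarray):
    """Vertical-edge and horizontal-edge pixel bands of a filled shape."""
    from scipy import ndimage

    dil = ndimage.binary_dilation
    diff_c = np.zeros_like(target_mask)
    diff_c[:, :-1] |= target_mask[:, :-1] != target_mask[:, 1:]
    diff_r = np.zeros_like(target_mask)
    diff_r[:-1, :] |= target_mask[:-1, :] != target_mask[1:, :]
    vert = dil(diff_c, iterations=1)
    horiz = dil(diff_r, iterations=1)
    return vert & ~horiz, horiz & ~vert
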