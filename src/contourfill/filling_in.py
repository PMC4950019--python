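"""Boundary-gated diffusive filling-in of surface brightness.

ON and OFF surface signals each diffuse on a 4-neighbor lattice whose
inter-pixel permeabilities are throttled by boundary activity of the
blocking orientation: vertical boundaries impede horizontal flow and
horizontal boundaries impede vertical flow.  Strong closed boundary chains
trap the injected surface signal inside a region; erased (or open)
boundaries let it spread and dilute into the surround, which is the model's
account of contour erasure -- and, deliberately, of its documented
failure mode for one-sided gaps, where a single missing side lets a whole
region bleed into the background.

Per channel x the lattice obeys

    dx_p/dt = -A x_p + sum_q P(p,q) (x_q - x_p) + C s_p,

with P(p,q) = D / (1 + E * (b_p + b_q)) for the blocking orientation b.
The perceived brightness is the signed difference of the filled ON and OFF
channels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .config import FillParams
from .front_end import OpponentField
from .boundary_system import BoundaryField
from .stimuli import Frame

__all__ = [
    "PerceptField",
    "Permeability",
    "permeability",
    "step_filling",
    "max_stable_dt",
    "steady_state_oracle",
    "readout_brightness",
]


@dataclass(frozen=True)
class PerceptField:
    """Filled-in ON/OFF surface activities; brightness = on - off."""

    on_fill: np.ndarray
    off_fill: np.ndarray

    @classmethod
    def zeros(cls, shape: Tuple[int, int]) -> "PerceptField":
        return cls(np.zeros(shape), np.zeros(shape))

    def copy(self) -> "PerceptField":
        return PerceptField(self.on_fill.copy(), self.off_fill.copy())

    @property
    def brightness(self) -> np.ndarray:
        return self.on_fill - self.off_fill

    @property
    def shape(self):
        return self.on_fill.shape


@dataclass(frozen=True)
class Permeability:
    """Symmetric edge permeabilities of the diffusion lattice.

    ``horizontal[r, c]`` couples pixels (r, c) and (r, c+1) -- flow across
    vertical boundaries; ``vertical[r, c]`` couples (r, c) and (r+1, c).
    Directional per-pixel views (left/right/up/down) are derived, so
    perm(p -> q) = perm(q -> p) by construction.
    """

    horizontal: np.ndarray  # (H, W-1)
    vertical: np.ndarray    # (H-1, W)

    @property
    def right(self) -> np.ndarray:
        H, W = self.vertical.shape[0] + 1, self.horizontal.shape[1] + 1
        out = np.zeros((H, W))
        out[:, :-1] = self.horizontal
        return out

    @property
    def left(self) -> np.ndarray:
        out = np.zeros_like(self.right)
        out[:, 1:] = self.horizontal
        return out

    @property
    def down(self) -> np.ndarray:
        out = np.zeros_like(self.right)
        out[:-1, :] = self.vertical
        return out

    @property
    def up(self) -> np.ndarray:
        out = np.zeros_like(self.right)
        out[1:, :] = self.vertical
        return out


def permeability(boundaries: BoundaryField, params: FillParams) -> Permeability:
    """Edge permeabilities gated by the blocking boundary orientation.

    Horizontal flow between lateral neighbors p, q is blocked by vertical
    boundary activity, ``D / (1 + E * (vert_p + vert_q))``; vertical flow is
    blocked analogously by horizontal boundaries.  With no boundaries every
    permeability equals the baseline D, and flow along a boundary's own
    orientation is unimpeded.
    """
    v, h = boundaries.vertical, boundaries.horizontal
    horiz = params.couple / (1.0 + params.block * (v[:, :-1] + v[:, 1:]))
    vert = params.couple / (1.0 + params.block * (h[:-1, :] + h[1:, :]))
    return Permeability(horizontal=horiz, vertical=vert)


def max_stable_dt(params: FillParams) -> float:
    """Explicit-Euler stability bound for the filling-in step."""
    return 1.0 / (params.decay + 4.0 * params.couple + params.input_gain)


def _step_channel(x: np.ndarray, source: np.ndarray, perm: Permeability,
                  params: FillParams, dt: float) -> np.ndarray:
    flux = np.zeros_like(x)
    fh = perm.horizontal * (x[:, 1:] - x[:, :-1])
    flux[:, :-1] += fh
    flux[:, 1:] -= fh
    fv = perm.vertical * (x[1:, :] - x[:-1, :])
    flux[:-1, :] += fv
    flux[1:, :] -= fv
    return x + dt * (-params.decay * x + flux + params.input_gain * source)


def step_filling(percept: PerceptField, source: OpponentField,
                 perm: Permeability, params: FillParams,
                 dt: float) -> PerceptField:
    """One explicit-Euler step of both filling-in channels.

    Guards the step size with ``dt * (A + 4D + C) < 1``; border pixels
    exchange flux only with their existing neighbors.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if dt >= max_stable_dt(params):
        raise ValueError(
            f"filling-in step unstable: dt = {dt:.4g} s >= "
            f"{max_stable_dt(params):.4g} s = 1 / (A + 4D + C); "
            "sub-step with a smaller dt")
    return PerceptField(
        on_fill=_step_channel(percept.on_fill, source.on, perm, params, dt),
        off_fill=_step_channel(percept.off_fill, source.off, perm, params, dt),
    )


def steady_state_oracle(source: OpponentField, perm: Permeability,
                        params: FillParams) -> PerceptField:
    """Exact steady state by direct sparse linear solve (test oracle).

    Assembles ``(A I + L) x = C s`` with L the permeability-weighted graph
    Laplacian and solves it per channel.  Restricted to small grids; used
    to validate the time-stepped integrator, never inside simulations.
    """
    H, W = source.shape
    if H * W > 64 * 64:
        raise ValueError("steady-state oracle is restricted to grids <= 64 x 64")
    n = H * W

    def idx(r, c):
        return r * W + c

    rows, cols, vals = [], [], []
    diag = np.full(n, params.decay, dtype=float)
    if params.decay == 0.0:
        raise ValueError("singular system: zero decay leaves isolated "
                         "components unconstrained")
    for r in range(H):
        for c in range(W - 1):
            p, q, w = idx(r, c), idx(r, c + 1), perm.horizontal[r, c]
            diag[p] += w
            diag[q] += w
            rows += [p, q]
            cols += [q, p]
            vals += [-w, -w]
    for r in range(H - 1):
        for c in range(W):
            p, q, w = idx(r, c), idx(r + 1, c), perm.vertical[r, c]
            diag[p] += w
            diag[q] += w
            rows += [p, q]
            cols += [q, p]
            vals += [-w, -w]
    rows += list(range(n))
    cols += list(range(n))
    vals += list(diag)
    M = sp.csc_matrix((vals, (rows, cols)), shape=(n, n))
    on = spla.spsolve(M, params.input_gain * source.on.ravel()).reshape(H, W)
    off = spla.spsolve(M, params.input_gain * source.off.ravel()).reshape(H, W)
    return PerceptField(on_fill=on, off_fill=off)


def readout_brightness(percept: PerceptField, background: float,
                       gain: float, duration: float = 1.0) -> Frame:
    """Render the filled-in percept as a displayable luminance frame.

    ``gain`` should be decay/input_gain so that a converged, fully trapped
    percept round-trips approximately to the stimulus it encodes.
    """
    lum = np.clip(background + gain * percept.brightness, 0.0, 1.0)
    return Frame(lum, duration)
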