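"""Oriented boundaries with habituating gated-dipole dynamics.

Two orientation channels (vertical and horizontal) are computed at every
pixel.  Each channel's first-layer signal (oriented luminance contrast plus
a constant tonic input) passes through a habituating transmitter gate
before competing with the orthogonal channel; the thresholded winner is the
boundary output that gates surface filling-in.

The gate z follows mass-action dynamics,

    dz/dt = alpha * (1 - z) - beta * S * z,        S = drive + tonic,

so sustained stimulation depletes the gate toward the equilibrium
``alpha / (alpha + beta * S)`` while recovery pulls it back toward 1.
Because the tonic input feeds both channels, an abrupt drop in the driven
channel's input lets the fresher orthogonal gate win the opponent
competition transiently: the orientation-opponent rebound (after-response)
that marks adapted contours.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np

from .config import DipoleParams
from .front_end import OpponentField

__all__ = [
    "OrientedDrive",
    "GateState",
    "BoundaryField",
    "oriented_contrast",
    "step_gates",
    "dipole_output",
    "simulate_dipole_trace",
]

_Z_FLOOR = 1e-12


@dataclass(frozen=True)
class OrientedDrive:
    """Non-negative drive to vertically / horizontally tuned cells.

    A vertical edge -- luminance changing along the horizontal direction --
    excites the *vertical* channel, and vice versa.
    """

    vertical: np.ndarray
    horizontal: np.ndarray

    def __post_init__(self):
        if self.vertical.shape != self.horizontal.shape:
            raise ValueError("orientation grids must share a shape")

    @property
    def shape(self):
        return self.vertical.shape


@dataclass(frozen=True)
class GateState:
    """Transmitter gate levels in (0, 1] for both orientations."""

    z_vertical: np.ndarray
    z_horizontal: np.ndarray

    @classmethod
    def fresh(cls, shape: Tuple[int, int]) -> "GateState":
        return cls(np.ones(shape), np.ones(shape))

    def copy(self) -> "GateState":
        return GateState(self.z_vertical.copy(), self.z_horizontal.copy())


@dataclass(frozen=True)
class BoundaryField:
    """Thresholded dipole output; at most one orientation wins per pixel."""

    vertical: np.ndarray
    horizontal: np.ndarray

    @property
    def total(self) -> np.ndarray:
        return self.vertical + self.horizontal

    @property
    def shape(self):
        return self.vertical.shape


def _central_diff(S: np.ndarray, axis: int) -> np.ndarray:
    """S(i+1) - S(i-1) along ``axis``; one-sided at the borders."""
    d = np.empty_like(S)
    s_next = np.roll(S, -1, axis=axis)
    s_prev = np.roll(S, 1, axis=axis)
    d[...] = s_next - s_prev
    if axis == 0:
        d[0, :] = S[1, :] - S[0, :]
        d[-1, :] = S[-1, :] - S[-2, :]
    else:
        d[:, 0] = S[:, 1] - S[:, 0]
        d[:, -1] = S[:, -1] - S[:, -2]
    return d


def oriented_contrast(field: OpponentField,
                      params: DipoleParams) -> OrientedDrive:
    """Rectified central-difference contrast per orientation.

    The vertical drive at (r, c) is ``drive_gain * |S(r, c+1) - S(r, c-1)|``
    on the signed surface signal ``S = on - off`` (one-sided differences at
    the borders); the horizontal drive differentiates along rows.
    """
    S = field.signed
    vertical = params.drive_gain * np.abs(_central_diff(S, axis=1))
    horizontal = params.drive_gain * np.abs(_central_diff(S, axis=0))
    return OrientedDrive(vertical=vertical, horizontal=horizontal)


def _check_gate_stability(drive_max: float, params: DipoleParams,
                          dt: float) -> None:
    rate = params.alpha + params.beta * (drive_max + params.tonic)
    if dt * rate >= 1.0:
        raise ValueError(
            f"explicit-Euler gate step unstable: dt * (alpha + beta * S_max) "
            f"= {dt * rate:.3f} >= 1; use dt < {1.0 / rate:.4g} s")


def step_gates(gates: GateState, drive: OrientedDrive, params: DipoleParams,
               dt: float) -> GateState:
    """One explicit-Euler step of the mass-action gate dynamics."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    _check_gate_stability(
        float(max(drive.vertical.max(), drive.horizontal.max())), params, dt)
    out = []
    for z, d in ((gates.z_vertical, drive.vertical),
                 (gates.z_horizontal, drive.horizontal)):
        S = d + params.tonic
        z_new = z + dt * (params.alpha * (1.0 - z) - params.beta * S * z)
        out.append(np.clip(z_new, _Z_FLOOR, 1.0))
    return GateState(out[0], out[1])


def gate_equilibrium(signal: float, params: DipoleParams) -> float:
    """Closed-form steady state ``alpha / (alpha + beta * S)`` of the gate."""
    return params.alpha / (params.alpha + params.beta * signal)


def gated_signals(drive: OrientedDrive, gates: GateState,
                  params: DipoleParams) -> Tuple[np.ndarray, np.ndarray]:
    """Unthresholded second-layer activities ``(drive + tonic) * z``."""
    y_v = (drive.vertical + params.tonic) * gates.z_vertical
    y_h = (drive.horizontal + params.tonic) * gates.z_horizontal
    return y_v, y_h


def dipole_output(drive: OrientedDrive, gates: GateState,
                  params: DipoleParams) -> BoundaryField:
    """Thresholded third-layer output after cross-orientation inhibition.

    ``output_o = max(0, y_o - y_perp - Gamma)``; exact ties yield zero in
    both orientations, so at most one channel is positive per pixel.
    """
    y_v, y_h = gated_signals(drive, gates, params)
    g = params.out_threshold
    return BoundaryField(vertical=np.maximum(0.0, y_v - y_h - g),
                         horizontal=np.maximum(0.0, y_h - y_v - g))


def simulate_dipole_trace(
    drive_schedule: Sequence[Tuple[float, float, float]],
    params: DipoleParams,
    dt: float = 0.005,
) -> dict:
    """Single-pixel dipole time course under a piecewise-constant drive.

    ``drive_schedule`` lists ``(duration, vertical_drive, horizontal_drive)``
    segments; the canonical protocol is a strong vertical drive followed by
    a weak one, which produces gradual habituation, an abrupt activity drop
    at the decrement, and a transient rebound in the horizontal channel.

    Returns a dict with times and the *unthresholded* channel activities
    (plus gate levels and thresholded outputs for inspection).
    """
    times: List[float] = []
    y_v: List[float] = []
    y_h: List[float] = []
    z_v: List[float] = []
    z_h: List[float] = []
    out_v: List[float] = []
    out_h: List[float] = []

    gates = GateState.fresh((1, 1))
    t = 0.0
    for duration, dv, dh in drive_schedule:
        drive = OrientedDrive(np.full((1, 1), float(dv)),
                              np.full((1, 1), float(dh)))
        n = max(1, int(round(duration / dt)))
        for _ in range(n):
            a_v, a_h = gated_signals(drive, gates, params)
            out = dipole_output(drive, gates, params)
            times.append(t)
            y_v.append(float(a_v[0, 0]))
            y_h.append(float(a_h[0, 0]))
            z_v.append(float(gates.z_vertical[0, 0]))
            z_h.append(float(gates.z_horizontal[0, 0]))
            out_v.append(float(out.vertical[0, 0]))
            out_h.append(float(out.horizontal[0, 0]))
            gates = step_gates(gates, drive, params, dt)
            t += dt
    return {
        "times": np.asarray(times),
        "y_vertical": np.asarray(y_v),
        "y_horizontal": np.asarray(y_h),
        "z_vertical": np.asarray(z_v),
        "z_horizontal": np.asarray(z_h),
        "out_vertical": np.asarray(out_v),
        "out_horizontal": np.asarray(out_h),
    }
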