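"""Model parameter blocks and run configuration.

All tunable constants of the model live here so that a single
:class:`RunConfig` object fully determines the behaviour of a simulation.
Configurations serialize to/from YAML and hash stably, which gives every
rendered artifact a reproducible provenance tag.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import yaml

__all__ = ["DipoleParams", "FillParams", "RunConfig"]


@dataclass(frozen=True)
class DipoleParams:
    """Parameters of the habituating gated-dipole boundary circuit.

    Attributes
    ----------
    alpha : float
        Transmitter recovery rate (1/s).  Depleted gates recover toward
        their ceiling of 1 at this rate.
    beta : float
        Transmitter depletion rate per unit of gated signal (1/s).
    tonic : float
        Constant common input J fed to both orientation channels.  It is
        the energy source of opponent rebounds: when a strongly driven
        channel loses its input, the tonic input through the fresher
        opposite gate transiently wins the competition.
    out_threshold : float
        Output threshold Gamma applied after cross-orientation inhibition.
    drive_gain : float
        Scale from opponent-field luminance differences to first-layer
        oriented drive.
    """

    alpha: float = 0.05
    beta: float = 0.3
    tonic: float = 0.2
    out_threshold: float = 0.05
    drive_gain: float = 10.0

    def validate(self) -> None:
        if not (self.alpha > 0 and self.beta > 0 and self.drive_gain > 0):
            raise ValueError("alpha, beta and drive_gain must be positive")
        if self.tonic < 0 or self.out_threshold < 0:
            raise ValueError("tonic and out_threshold must be non-negative")


@dataclass(frozen=True)
class FillParams:
    """Parameters of the boundary-gated diffusive filling-in stage.

    Attributes
    ----------
    decay : float
        Passive decay rate A of filled-in activity (1/s).  Kept far below
        1/test-duration: filling-in is then effectively mass-conserving,
        so closed boundary chains accumulate a region's surface signal
        while open regions share it with the vastly larger background and
        dilute away -- the regime in which a single boundary gap suffices
        to make a region blend into the background.
    couple : float
        Baseline inter-pixel permeability D (1/s).
    block : float
        Boundary blocking strength E.  Permeability across an edge whose
        endpoints carry boundary activity b_p + b_q is
        couple / (1 + block * (b_p + b_q)).
    input_gain : float
        Gain C from opponent surface signals into the filling-in lattice.
    """

    decay: float = 0.02
    couple: float = 800.0
    block: float = 500.0
    input_gain: float = 5.0

    def validate(self) -> None:
        if not (self.couple > 0 and self.input_gain > 0):
            raise ValueError("couple and input_gain must be positive")
        if self.decay < 0 or self.block < 0:
            raise ValueError("decay and block must be non-negative")


@dataclass(frozen=True)
class RunConfig:
    """Complete, hashable description of one simulation setup."""

    dipole: DipoleParams = field(default_factory=DipoleParams)
    fill: FillParams = field(default_factory=FillParams)
    #: mid-gray reference luminance; stimuli are increments/decrements on it
    background: float = 0.5
    #: boundary-system integration step (s); filling-in sub-steps within it
    dt: float = 0.005
    #: cadence at which simulation traces record snapshots (s)
    sample_every: float = 0.25
    #: degrees-of-visual-angle to pixels conversion for demo rendering
    px_per_deg: float = 10.0
    #: scaled-down conversion used by the threshold batteries
    battery_px_per_deg: float = 5.0
    #: flicker half-period of adapting stimuli (s); 0.25 s = 2 Hz full cycle
    half_period: float = 0.25
    #: adaptation durations (s) for the two families of demos
    adapt_duration_outline: float = 4.0
    adapt_duration_flicker: float = 6.0
    #: duration of the low-contrast test presentation (s)
    test_duration: float = 2.0
    #: default test increment/decrement around the background
    test_contrast: float = 0.05
    #: visibility criterion as a fraction of the unadapted visibility of the
    #: same target at the default test contrast
    criterion_fraction: float = 0.1
    #: surround sigma (px) of the center-surround contrast signal feeding
    #: the filling-in stage; <= 0 uses the raw opponent field as source
    source_surround_sigma: float = 3.0

    def validate(self) -> None:
        self.dipole.validate()
        self.fill.validate()
        if not 0.0 <= self.background <= 1.0:
            raise ValueError("background must lie in [0, 1]")
        for name in ("dt", "sample_every", "px_per_deg", "half_period",
                     "test_duration", "test_contrast", "criterion_fraction"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        dipole = DipoleParams(**data.pop("dipole", {}))
        fill = FillParams(**data.pop("fill", {}))
        return cls(dipole=dipole, fill=fill, **data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        cfg = cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})
        cfg.validate()
        return cfg

    def with_overrides(self, **kwargs) -> "RunConfig":
        """Return a copy with top-level fields replaced."""
        return replace(self, **kwargs)

    @property
    def params_hash(self) -> str:
        """Short stable hash of every model parameter (provenance tag)."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
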