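"""Shared domain containers for velocity-encoded cine MRI flow analysis.

The objects here mirror what a phase-contrast (PC-MRI) exam delivers: a
cine series of through-plane velocity maps over one cardiac cycle
(:class:`VelocityCine`), labelled lumen masks (:class:`LumenMask`) and
per-lumen volumetric flow waveforms (:class:`FlowWaveform`).

Units are CGS-based throughout: velocities in cm/s, lengths in cm, areas
in cm^2, flows in ml/min, time in seconds, pressure gradients internally
in dyn/cm^3 and reported in mmHg/cm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np

from .errors import BoundsError, InvalidSpecError

# 1 mmHg = 1333.22 dyn/cm^2, so 1 dyn/cm^3 = 1/1333.22 mmHg/cm
DYN_CM3_PER_MMHG_CM = 1333.22

# Anatomical label taxonomy of the cervical flow exam
ARTERIAL_LABELS = ("RICA", "LICA", "RVA", "LVA")
JUGULAR_LABELS = ("RIJV", "LIJV")
SECONDARY_LABELS = ("DCV", "VV", "EV")
CSF_LABEL = "CSF"
ALL_LABELS = ARTERIAL_LABELS + JUGULAR_LABELS + SECONDARY_LABELS + (CSF_LABEL,)

#: Sign applied to raw integrated flow so that arterial inflow, venous
#: outflow and caudal (cranium-to-spine) CSF flow are all positive.
#: The phantom's velocity axis is positive toward the cranium.
FLOW_SIGN = {**{l: +1.0 for l in ARTERIAL_LABELS},
             **{l: -1.0 for l in JUGULAR_LABELS + SECONDARY_LABELS},
             CSF_LABEL: -1.0}


@dataclass(frozen=True)
class AcquisitionParams:
    """Acquisition parameters of one velocity-encoded cine series.

    Parameters
    ----------
    venc:
        Velocity-encoding limit in cm/s. Velocity maps linearly onto
        image phase, wrapping beyond +/-``venc``.
    n_phases:
        Cardiac phases reconstructed per cycle (retrospective gating).
    pixel_area:
        In-plane pixel area in cm^2.
    cycle_duration:
        Cardiac period in seconds.
    noise_sd:
        Standard deviation of Gaussian noise added in the phase image,
        in radians.
    """

    venc: float
    n_phases: int = 32
    pixel_area: float = 0.003
    cycle_duration: float = 1.0
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.venc) or self.venc <= 0:
            raise InvalidSpecError(f"venc must be > 0, got {self.venc}")
        if self.n_phases < 8:
            raise InvalidSpecError(f"n_phases must be >= 8, got {self.n_phases}")
        if self.pixel_area <= 0:
            raise InvalidSpecError(f"pixel_area must be > 0, got {self.pixel_area}")
        if self.cycle_duration <= 0:
            raise InvalidSpecError(
                f"cycle_duration must be > 0, got {self.cycle_duration}")
        if self.noise_sd < 0:
            raise InvalidSpecError(f"noise_sd must be >= 0, got {self.noise_sd}")

    @property
    def pixel_spacing(self) -> float:
        """Isotropic in-plane pixel spacing in cm."""
        return float(np.sqrt(self.pixel_area))

    @property
    def times(self) -> np.ndarray:
        """Sample times of the cardiac phases in seconds."""
        return np.arange(self.n_phases) * self.cycle_duration / self.n_phases

    def to_sidecar(self) -> dict:
        return {
            "venc_cm_s": self.venc,
            "n_phases": self.n_phases,
            "pixel_area_cm2": self.pixel_area,
            "cycle_duration_s": self.cycle_duration,
            "noise_sd": self.noise_sd,
        }

    @classmethod
    def from_sidecar(cls, d: Mapping) -> "AcquisitionParams":
        return cls(venc=d["venc_cm_s"], n_phases=int(d["n_phases"]),
                   pixel_area=d["pixel_area_cm2"],
                   cycle_duration=d["cycle_duration_s"],
                   noise_sd=d.get("noise_sd", 0.0))


@dataclass(frozen=True)
class FluidProps:
    """Density (g/cm^3) and dynamic viscosity (poise) of the fluid."""

    density: float
    dynamic_viscosity: float

    def __post_init__(self) -> None:
        if self.density <= 0 or self.dynamic_viscosity <= 0:
            raise InvalidSpecError("density and viscosity must be positive")


#: Default fluid properties. CSF is close to water at body temperature;
#: blood is denser and roughly four times as viscous.
CSF_FLUID = FluidProps(density=1.0007, dynamic_viscosity=0.01)
BLOOD_FLUID = FluidProps(density=1.05, dynamic_viscosity=0.04)


def fluid_for_label(label: str) -> FluidProps:
    return CSF_FLUID if label == CSF_LABEL else BLOOD_FLUID


@dataclass
class VelocityCine:
    """One decoded velocity-encoded cine series.

    ``velocity`` holds decoded through-plane velocities (cm/s) of shape
    ``(n_phases, n_rows, n_cols)``; ``magnitude`` is the companion
    magnitude series in arbitrary units. Synthetic series carry a
    ``truth`` dict mapping vessel label to analytic per-phase flow
    (ml/min) and driving pressure gradient (dyn/cm^3) waveforms.
    """

    velocity: np.ndarray
    magnitude: np.ndarray
    params: AcquisitionParams
    name: str = ""
    truth: Optional[dict] = None

    def __post_init__(self) -> None:
        self.velocity = np.asarray(self.velocity, dtype=float)
        self.magnitude = np.asarray(self.magnitude, dtype=float)
        if self.velocity.shape != self.magnitude.shape:
            raise InvalidSpecError("velocity and magnitude shapes differ")
        if self.velocity.ndim != 3 or self.velocity.shape[0] != self.params.n_phases:
            raise InvalidSpecError(
                f"expected ({self.params.n_phases}, ny, nx) velocity array, "
                f"got {self.velocity.shape}")

    @property
    def shape(self) -> tuple:
        return self.velocity.shape[1:]

    @property
    def times(self) -> np.ndarray:
        return self.params.times

    def pixel_series(self, row: int, col: int) -> np.ndarray:
        ny, nx = self.shape
        if not (0 <= row < ny and 0 <= col < nx):
            raise BoundsError(f"pixel ({row}, {col}) outside {self.shape} image")
        return self.velocity[:, row, col]


@dataclass
class LumenMask:
    """Pixel set of one vessel or CSF lumen on a given cine series."""

    label: str
    mask: np.ndarray
    source_cine: str = ""

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise InvalidSpecError("mask must be 2-D")
        if not self.mask.any():
            raise InvalidSpecError(f"empty mask for label {self.label!r}")

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())

    @property
    def coords(self) -> np.ndarray:
        """(N, 2) array of (row, col) pixel coordinates."""
        return np.argwhere(self.mask)


@dataclass
class FlowWaveform:
    """One cardiac cycle of volumetric flow rate for a labelled lumen.

    ``q`` is in ml/min, sampled at ``n_phases`` uniform points over
    ``cycle_duration`` seconds. Sign convention: arterial inflow,
    venous outflow and caudal CSF flow are positive once oriented via
    :data:`FLOW_SIGN`.
    """

    label: str
    q: np.ndarray
    cycle_duration: float

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        if self.q.ndim != 1 or not np.all(np.isfinite(self.q)):
            raise InvalidSpecError("flow waveform must be a finite 1-D array")
        if self.cycle_duration <= 0:
            raise InvalidSpecError("cycle_duration must be positive")

    @property
    def n_phases(self) -> int:
        return self.q.size

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_phases) * self.cycle_duration / self.n_phases

    @property
    def mean(self) -> float:
        """Cycle-mean flow in ml/min (uniform periodic sampling)."""
        return float(self.q.mean())

    def scaled(self, factor: float, label: Optional[str] = None) -> "FlowWaveform":
        return FlowWaveform(label or self.label, self.q * factor,
                            self.cycle_duration)


def cycle_integral(y: np.ndarray, duration: float) -> float:
    """Integral of a periodically sampled waveform over one full cycle.

    Trapezoidal rule with periodic closure; on a uniform grid this
    reduces to ``mean(y) * duration``.
    """
    y = np.asarray(y, dtype=float)
    return float(y.mean() * duration)


def cumulative_cycle_integral(y: np.ndarray, duration: float) -> np.ndarray:
    """Cumulative trapezoidal integral at the n+1 nodes t_0 .. t_n = T.

    The first entry is 0; the last is the full-cycle integral (which
    vanishes for a zero-mean waveform).
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    dt = duration / n
    yc = np.concatenate([y, y[:1]])  # periodic closure
    steps = 0.5 * (yc[:-1] + yc[1:]) * dt
    return np.concatenate([[0.0], np.cumsum(steps)])


def check_aligned(*waveforms: FlowWaveform) -> None:
    """Raise AlignmentError unless all waveforms share one phase grid."""
    from .errors import AlignmentError

    ref = waveforms[0]
    for w in waveforms[1:]:
        if w.n_phases != ref.n_phases or not np.isclose(
                w.cycle_duration, ref.cycle_duration):
            raise AlignmentError(
                f"waveform {w.label!r} ({w.n_phases} phases, "
                f"T={w.cycle_duration}) does not match {ref.label!r} "
                f"({ref.n_phases} phases, T={ref.cycle_duration})")
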