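"""Intracranial volume change, CSF pressure gradient, compliance and MR-ICP.

The craniospinal system is treated as a single compliant compartment.
Over the cardiac cycle the momentary net rate of volume entering the
cranium is

    n(t) = A(t) - V'(t) - CSF(t),

arterial inflow minus (corrected) venous outflow minus caudal CSF flow.
Because PC-MRI misses part of the venous return, the measured venous sum
is rescaled so that the cycle-mean of A - V' vanishes — the steady-state
condition that intracranial volume is constant on average. The
cumulative integral of n(t) is the intracranial volume-change waveform;
its peak-to-trough excursion is the ICVC (ml).

The pressure fluctuation driving craniospinal CSF exchange is estimated
from the CSF velocity field itself through the axial Navier-Stokes
momentum balance: for nearly unidirectional laminar flow,

    G(t) = rho dv/dt - mu laplacian(v)   (= -dp/dz),

evaluated per interior lumen pixel with finite differences and
aggregated robustly across the lumen. The peak-to-peak amplitude of this
waveform (PTP-PG, mmHg/cm) is the pressure surrogate. The compliance
index is ICVC / (PTP-PG * d) with an effective gradient-to-pressure
distance d, and the MR estimate of ICP follows the inverse
compliance-pressure relationship MRICP = a / compliance + b.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Tuple

import numpy as np
from scipy import ndimage

from .core import (DYN_CM3_PER_MMHG_CM, FlowWaveform, FluidProps, LumenMask,
                   VelocityCine, check_aligned, cumulative_cycle_integral)
from .errors import DegenerateInputError, GeometryError, InvalidSpecError

_CROSS = ndimage.generate_binary_structure(2, 1)


@dataclass(frozen=True)
class CalibrationConfig:
    """Compliance/ICP calibration constants.

    pressure_conversion:
        Effective distance d (cm) converting the pressure gradient
        amplitude (mmHg/cm) into a pressure fluctuation (mmHg).
    icp_inverse_coefficient:
        Coefficient a (mmHg x index) of the inverse
        compliance-pressure law.
    icp_offset:
        Additive offset b (mmHg).
    mricp_cap:
        Reporting cap (mmHg) guarding the vanishing-compliance limit.
    """

    pressure_conversion: float = 1.8
    icp_inverse_coefficient: float = 73.0
    icp_offset: float = 0.0
    mricp_cap: float = 100.0

    def __post_init__(self) -> None:
        if self.pressure_conversion <= 0:
            raise InvalidSpecError("pressure_conversion must be > 0")
        if self.icp_inverse_coefficient <= 0:
            raise InvalidSpecError("icp_inverse_coefficient must be > 0")


@dataclass
class ICVCWaveform:
    """Intracranial volume change over the cycle, relative to cycle start.

    ``dv`` holds the n_phases+1 cumulative-integral nodes t_0 .. t_N=T
    (dv[0] = 0; dv[-1] is the cycle closure, ~0 after venous
    correction).
    """

    dv: np.ndarray
    cycle_duration: float

    @property
    def closure(self) -> float:
        return float(self.dv[-1])

    @property
    def icvc(self) -> float:
        return float(self.dv.max() - self.dv.min())


@dataclass
class PressureGradientWaveform:
    """CSF axial pressure-gradient waveform in mmHg/cm."""

    pg: np.ndarray
    cycle_duration: float

    @property
    def ptp_pg(self) -> float:
        return float(self.pg.max() - self.pg.min())


@dataclass
class HydroResult:
    """Headline hydrodynamic quantities for one subject."""

    icvc: float              # ml
    ptp_pg: float            # mmHg/cm
    compliance_index: float  # dimensionless
    mricp: float             # mmHg
    venous_scale: float      # Eq.-(2)-style correction factor


def correct_venous_outflow(arterial: FlowWaveform,
                           venous: FlowWaveform) -> Tuple[FlowWaveform, float]:
    """Rescale the measured venous sum so mean(A - V') = 0 exactly.

    The unmeasured venous pathways are modelled as parallel channels
    proportional to the measured ones, hence a multiplicative scale
    mean(A)/mean(V). Returns the corrected waveform and the scale.
    """
    check_aligned(arterial, venous)
    mean_v = venous.mean
    if mean_v <= 0:
        raise DegenerateInputError(
            f"mean venous outflow must be > 0, got {mean_v:.3g} ml/min")
    scale = arterial.mean / mean_v
    return venous.scaled(scale), float(scale)


def additive_venous_correction(arterial: FlowWaveform,
                               venous: FlowWaveform) -> Tuple[FlowWaveform, float]:
    """Alternative correction: constant offset so mean(A - V') = 0."""
    check_aligned(arterial, venous)
    offset = arterial.mean - venous.mean
    corrected = FlowWaveform(venous.label, venous.q + offset,
                             venous.cycle_duration)
    return corrected, float(offset)


def icvc_waveform(arterial: FlowWaveform, corrected_venous: FlowWaveform,
                  csf: FlowWaveform) -> ICVCWaveform:
    """Cumulative volume balance A - V' - CSF over one cardiac cycle.

    All waveforms must share the phase grid and be orientation-corrected
    (venous outflow positive, caudal CSF flow positive). The CSF term is
    used as its oscillatory (mean-subtracted) component so that any
    residual steady CSF offset — physically bulk flow, practically
    eddy-current bias — does not open the cycle closure that the venous
    correction has enforced.
    """
    check_aligned(arterial, corrected_venous, csf)
    net_ml_s = (arterial.q - corrected_venous.q - (csf.q - csf.q.mean())) / 60.0
    dv = cumulative_cycle_integral(net_ml_s, arterial.cycle_duration)
    return ICVCWaveform(dv=dv, cycle_duration=arterial.cycle_duration)


def _interior_pixels(mask: np.ndarray) -> np.ndarray:
    """Pixels whose full 4-neighbourhood lies inside the mask."""
    return ndimage.binary_erosion(mask, structure=_CROSS, border_value=0)


def csf_pressure_gradient(cine: VelocityCine, csf_mask: LumenMask,
                          fluid: FluidProps,
                          aggregate: str = "median") -> PressureGradientWaveform:
    """Recover the axial pressure gradient from the CSF velocity field.

    Per interior lumen pixel and cardiac phase the driving gradient
    ``rho dv/dt - mu laplacian(v)`` is evaluated with a 5-point spatial
    Laplacian and centred cyclic temporal differences, then aggregated
    across pixels (median by default, robust to rim partial-volume
    pixels). Output is in mmHg/cm.
    """
    if aggregate not in ("median", "mean"):
        raise ValueError(f"unknown aggregate {aggregate!r}")
    if csf_mask.mask.shape != cine.shape:
        raise GeometryError("CSF mask does not match the cine grid")
    interior = _interior_pixels(csf_mask.mask)
    if not interior.any():
        raise GeometryError(
            "CSF lumen has no interior pixel with a full finite-difference "
            "neighbourhood; geometry too thin")

    v = cine.velocity
    h = cine.params.pixel_spacing
    dt = cine.params.cycle_duration / cine.params.n_phases

    lap = (np.roll(v, 1, axis=1) + np.roll(v, -1, axis=1)
           + np.roll(v, 1, axis=2) + np.roll(v, -1, axis=2) - 4.0 * v) / h ** 2
    dvdt = (np.roll(v, -1, axis=0) - np.roll(v, 1, axis=0)) / (2.0 * dt)

    pg_dyn = fluid.density * dvdt[:, interior] - fluid.dynamic_viscosity * lap[:, interior]
    agg = np.median if aggregate == "median" else np.mean
    pg = agg(pg_dyn, axis=1) / DYN_CM3_PER_MMHG_CM
    return PressureGradientWaveform(pg=pg, cycle_duration=cine.params.cycle_duration)


def compliance_and_mricp(icvc: ICVCWaveform, pg: PressureGradientWaveform,
                         cal: CalibrationConfig = CalibrationConfig(),
                         venous_scale: float = 1.0) -> HydroResult:
    """Compliance index ICVC/(PTP-PG * d) and MRICP = a/compliance + b.

    The inverse law compliance * (MRICP - b) = a holds exactly except in
    the vanishing-compliance limit, where MRICP is capped (with a
    warning) at ``cal.mricp_cap``.
    """
    ptp = pg.ptp_pg
    if ptp <= 0:
        raise DegenerateInputError("PTP-PG must be > 0 to define compliance")
    compliance = icvc.icvc / (ptp * cal.pressure_conversion)
    if compliance <= 0:
        raise DegenerateInputError("compliance index must be > 0")
    mricp = cal.icp_inverse_coefficient / compliance + cal.icp_offset
    if mricp > cal.mricp_cap:
        warnings.warn(
            f"MRICP {mricp:.1f} mmHg exceeds cap {cal.mricp_cap}; capped "
            "(vanishing compliance)", RuntimeWarning, stacklevel=2)
        mricp = cal.mricp_cap
    return HydroResult(icvc=icvc.icvc, ptp_pg=ptp,
                       compliance_index=compliance, mricp=mricp,
                       venous_scale=venous_scale)
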