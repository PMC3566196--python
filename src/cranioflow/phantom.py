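"""Synthetic phase-contrast phantoms with analytic ground truth.

Pulsatile laminar flow in a rigid circular tube driven by a band-limited
periodic pressure gradient has an exact solution (Womersley). Writing the
driving gradient (the negative axial pressure gradient, -dp/dz) as a
Fourier series

    G(t) = Re[ sum_n G_n exp(i n w0 t) ],   w0 = 2 pi / T,

the axial velocity is the superposition of the steady Poiseuille parabola
for G_0 and, for each oscillatory harmonic, the Bessel-function profile

    u_n(r, t) = Re[ (G_n / (i rho w_n))
                    (1 - J0(L_n r/R) / J0(L_n)) exp(i w_n t) ],

with L_n = i^{3/2} alpha_n and Womersley number
alpha_n = R sqrt(w_n rho / mu). The corresponding volumetric flow is

    Q_n(t) = Re[ (G_n pi R^2 / (i rho w_n))
                 (1 - 2 J1(L_n) / (L_n J0(L_n))) exp(i w_n t) ].

These closed forms are the ground truth ("truth" field) against which
segmentation, flow integration and Navier-Stokes pressure-gradient
recovery are validated.

Velocity encoding follows the phase-contrast convention: image phase
phi = pi v / VENC, wrapped into (-pi, pi] when |v| > VENC, with optional
Gaussian phase noise; decoding inverts v = VENC phi / pi.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy.special import jv

from .core import (AcquisitionParams, CSF_LABEL, FluidProps, LumenMask,
                   VelocityCine, fluid_for_label)
from .errors import GeometryError, InvalidSpecError

MAX_HARMONICS = 8  # band limit; keeps 32-phase sampling alias-free


@dataclass(frozen=True)
class VesselSpec:
    """Geometry and driving pressure gradient of one circular lumen.

    Parameters
    ----------
    label:
        Anatomical class (RICA, LICA, RVA, LVA, RIJV, LIJV, VV, EV, DCV
        or CSF).
    center:
        (row, col) position of the lumen centre in pixel units (floats
        allowed).
    radius:
        Lumen radius in cm.
    pg_harmonics:
        Complex amplitudes ``G_n`` of the driving pressure gradient in
        dyn/cm^3; index 0 is the steady term.
    direction:
        +1 if flow along the positive velocity axis (toward the
        cranium), -1 otherwise.
    """

    label: str
    center: Tuple[float, float]
    radius: float
    pg_harmonics: Tuple[complex, ...]
    direction: int = +1

    def __post_init__(self) -> None:
        if not np.isfinite(self.radius) or self.radius <= 0:
            raise InvalidSpecError(f"radius must be > 0, got {self.radius}")
        h = np.asarray(self.pg_harmonics, dtype=complex)
        if h.size == 0:
            raise InvalidSpecError("at least one pressure-gradient harmonic required")
        if h.size > MAX_HARMONICS + 1:
            raise InvalidSpecError(
                f"at most {MAX_HARMONICS} oscillatory harmonics supported")
        if not np.all(np.isfinite(h.view(float))):
            raise InvalidSpecError("pg_harmonics must be finite")
        if self.direction not in (+1, -1):
            raise InvalidSpecError(f"direction must be +1 or -1, got {self.direction}")
        object.__setattr__(self, "pg_harmonics", tuple(complex(c) for c in h))


@dataclass(frozen=True)
class PlugSpec:
    """A disc carrying one prescribed temporal waveform (separable field).

    ``velocity`` is the (n_phases,) through-plane velocity in cm/s,
    applied uniformly across the disc, optionally modulated by
    ``radial_profile(r/R)`` (an amplitude factor, 1 at the centre).
    Useful for encoding/segmentation tests where every lumen pixel must
    share exactly one waveform shape.
    """

    label: str
    center: Tuple[float, float]
    radius: float
    velocity: Tuple[float, ...]
    radial_profile: Optional[object] = None  # callable s in [0,1] -> factor

    def __post_init__(self) -> None:
        if not np.isfinite(self.radius) or self.radius <= 0:
            raise InvalidSpecError(f"radius must be > 0, got {self.radius}")
        v = np.asarray(self.velocity, dtype=float)
        if v.ndim != 1 or v.size == 0 or not np.all(np.isfinite(v)):
            raise InvalidSpecError("velocity must be a finite 1-D waveform")
        object.__setattr__(self, "velocity", tuple(float(x) for x in v))

    def sampled_velocity(self, radii: np.ndarray,
                         params: AcquisitionParams) -> np.ndarray:
        v = np.asarray(self.velocity, dtype=float)
        if v.size != params.n_phases:
            raise InvalidSpecError(
                f"plug waveform length {v.size} != n_phases {params.n_phases}")
        factor = np.ones_like(radii) if self.radial_profile is None else \
            np.asarray(self.radial_profile(radii / self.radius), dtype=float)
        return v[:, None] * factor[None, :]

    def flow_waveform(self, params: AcquisitionParams) -> np.ndarray:
        """Analytic flow in ml/min (fine radial quadrature if profiled)."""
        v = np.asarray(self.velocity, dtype=float)
        if self.radial_profile is None:
            area = np.pi * self.radius ** 2
            return v * area * 60.0
        s = np.linspace(0.0, 1.0, 2049)
        f = np.asarray(self.radial_profile(s), dtype=float)
        area_factor = 2.0 * np.pi * self.radius ** 2 * np.trapezoid(f * s, s)
        return v * area_factor * 60.0


def _harmonic_terms(spec: VesselSpec, fluid: FluidProps, cycle_duration: float):
    """Yield (n, omega_n, G_n, Lambda_n) for oscillatory harmonics."""
    w0 = 2.0 * np.pi / cycle_duration
    for n, G in enumerate(spec.pg_harmonics):
        if n == 0 or G == 0:
            continue
        wn = n * w0
        alpha = spec.radius * np.sqrt(wn * fluid.density / fluid.dynamic_viscosity)
        yield n, wn, complex(G), (1j ** 1.5) * alpha


def womersley_velocity_profile(spec: VesselSpec, fluid: FluidProps,
                               params: AcquisitionParams,
                               radii: Optional[np.ndarray] = None) -> np.ndarray:
    """Exact rigid-tube pulsatile velocity field, shape (n_phases, n_radii).

    The steady harmonic contributes the Poiseuille parabola
    ``G_0 (R^2 - r^2) / (4 mu)``; each oscillatory harmonic the
    Womersley profile. No-slip holds exactly at ``r = R``. The vessel's
    ``direction`` sign is applied.
    """
    if radii is None:
        radii = np.linspace(0.0, spec.radius, 65)
    r = np.asarray(radii, dtype=float)
    R = spec.radius
    t = params.times
    u = np.zeros((params.n_phases, r.size))

    G0 = spec.pg_harmonics[0]
    if abs(G0.imag) > 1e-12 * max(1.0, abs(G0)):
        raise InvalidSpecError("steady harmonic must be real")
    u += (G0.real * (R ** 2 - r ** 2) / (4.0 * fluid.dynamic_viscosity))[None, :]

    for _n, wn, G, Lam in _harmonic_terms(spec, fluid, params.cycle_duration):
        prof = (G / (1j * fluid.density * wn)) * (1.0 - jv(0, Lam * r / R) / jv(0, Lam))
        u += np.real(prof[None, :] * np.exp(1j * wn * t)[:, None])

    return spec.direction * u


def womersley_flow_waveform(spec: VesselSpec, fluid: FluidProps,
                            params: AcquisitionParams,
                            times: Optional[np.ndarray] = None) -> np.ndarray:
    """Analytic volumetric flow waveform in ml/min.

    Sampled at the cine phase times by default, or at ``times`` (s) for
    a finer grid (used when building analytic reference quantities).
    """
    R = spec.radius
    t = params.times if times is None else np.asarray(times, dtype=float)
    q = np.full(t.size,
                spec.pg_harmonics[0].real * np.pi * R ** 4
                / (8.0 * fluid.dynamic_viscosity))
    for _n, wn, G, Lam in _harmonic_terms(spec, fluid, params.cycle_duration):
        amp = (G * np.pi * R ** 2 / (1j * fluid.density * wn)) * (
            1.0 - 2.0 * jv(1, Lam) / (Lam * jv(0, Lam)))
        q = q + np.real(amp * np.exp(1j * wn * t))
    return spec.direction * q * 60.0  # cm^3/s -> ml/min


def pressure_gradient_waveform(spec: VesselSpec,
                               params: AcquisitionParams,
                               times: Optional[np.ndarray] = None) -> np.ndarray:
    """Prescribed driving pressure gradient G(t) in dyn/cm^3 (direction-signed)."""
    t = params.times if times is None else np.asarray(times, dtype=float)
    w0 = 2.0 * np.pi / params.cycle_duration
    g = np.full(t.size, spec.pg_harmonics[0].real)
    for n, G in enumerate(spec.pg_harmonics):
        if n == 0 or G == 0:
            continue
        g = g + np.real(complex(G) * np.exp(1j * n * w0 * t))
    return spec.direction * g


def encode_phase(velocity: np.ndarray, venc: float) -> np.ndarray:
    """Map velocity to image phase pi*v/VENC, wrapped into (-pi, pi]."""
    phase = np.pi * np.asarray(velocity, dtype=float) / venc
    # wrap to (-pi, pi]: shift so the boundary value +pi is kept
    return np.pi - np.mod(np.pi - phase, 2.0 * np.pi)


def decode_velocity(phase: np.ndarray, venc: float) -> np.ndarray:
    """Invert the phase-contrast encoding (no unwrapping)."""
    return venc * np.asarray(phase, dtype=float) / np.pi


@dataclass
class SyntheticScan:
    """Paired high-/low-VENC cine series plus ground-truth masks."""

    high: VelocityCine
    low: VelocityCine
    masks: Dict[str, LumenMask]
    vessels: Dict[str, VesselSpec] = field(default_factory=dict)


def _disc_geometry(spec: VesselSpec, shape: Tuple[int, int],
                   spacing: float) -> Tuple[np.ndarray, np.ndarray]:
    """Boolean disc mask (pixel-centre sampling) and radii (cm) of its pixels."""
    ny, nx = shape
    rr, cc = np.mgrid[0:ny, 0:nx]
    dist = spacing * np.hypot(rr - spec.center[0], cc - spec.center[1])
    mask = dist <= spec.radius
    return mask, dist[mask]


def generate_cine(vessels: Sequence[VesselSpec],
                  params_high: AcquisitionParams,
                  params_low: AcquisitionParams,
                  fluid_map: Optional[Mapping[str, FluidProps]] = None,
                  shape: Tuple[int, int] = (96, 96),
                  seed: int = 0) -> SyntheticScan:
    """Synthesize the paired high-/low-VENC cine scans of one exam.

    Each vessel is a circular lumen carrying its exact Womersley velocity
    field sampled at pixel centres; the static background is zero. Both
    series see the same velocities but are encoded with their own VENC
    (so fast arterial flow wraps on the low-VENC series, as on a
    scanner) and their own Gaussian phase-noise realization. The
    ``truth`` field of each cine stores the analytic flow and
    pressure-gradient waveform per vessel.
    """
    if params_high.n_phases != params_low.n_phases or not np.isclose(
            params_high.cycle_duration, params_low.cycle_duration):
        raise InvalidSpecError("high/low series must share the phase grid")
    if not np.isclose(params_high.pixel_area, params_low.pixel_area):
        raise InvalidSpecError("high/low series must share pixel geometry")
    fluid_map = dict(fluid_map or {})
    spacing = params_high.pixel_spacing
    ny, nx = shape

    labels = [v.label for v in vessels]
    if len(set(labels)) != len(labels):
        raise InvalidSpecError(f"duplicate vessel labels in {labels}")

    # geometric feasibility: in-grid and pairwise disjoint
    for v in vessels:
        r_px = v.radius / spacing
        if (v.center[0] - r_px < -0.5 or v.center[0] + r_px > ny - 0.5 or
                v.center[1] - r_px < -0.5 or v.center[1] + r_px > nx - 0.5):
            raise GeometryError(f"vessel {v.label} extends outside the {shape} grid")
    for i, a in enumerate(vessels):
        for b in vessels[i + 1:]:
            d = spacing * np.hypot(a.center[0] - b.center[0],
                                   a.center[1] - b.center[1])
            if d < a.radius + b.radius:
                raise GeometryError(f"vessels {a.label} and {b.label} overlap")

    n_ph = params_high.n_phases
    velocity = np.zeros((n_ph, ny, nx))
    magnitude = np.ones((n_ph, ny, nx))
    masks: Dict[str, LumenMask] = {}
    truth: Dict[str, dict] = {}

    for v in vessels:
        mask, radii = _disc_geometry(v, shape, spacing)
        if not mask.any():
            raise GeometryError(f"vessel {v.label} covers no pixel centre")
        if isinstance(v, PlugSpec):
            velocity[:, mask] = v.sampled_velocity(radii, params_high)
            truth[v.label] = {"flow_ml_per_min": v.flow_waveform(params_high)}
        else:
            fluid = fluid_map.get(v.label, fluid_for_label(v.label))
            velocity[:, mask] = womersley_velocity_profile(
                v, fluid, params_high, radii)
            truth[v.label] = {
                "flow_ml_per_min": womersley_flow_waveform(v, fluid, params_high),
                "pg_dyn_cm3": pressure_gradient_waveform(v, params_high),
                "fluid": fluid,
            }
        magnitude[:, mask] = 2.0  # lumina bright on the magnitude image
        masks[v.label] = LumenMask(v.label, mask)

    rng = np.random.default_rng(seed)
    series = []
    for params, tag in ((params_high, "high_venc"), (params_low, "low_venc")):
        phase = encode_phase(velocity, params.venc)
        if params.noise_sd > 0:
            phase = phase + rng.normal(0.0, params.noise_sd, size=phase.shape)
            phase = np.pi - np.mod(np.pi - phase, 2.0 * np.pi)
        series.append(VelocityCine(decode_velocity(phase, params.venc),
                                   magnitude.copy(), params, name=tag,
                                   truth={k: dict(v) for k, v in truth.items()}))
    high, low = series
    masks = {k: LumenMask(m.label, m.mask, source_cine="geometry")
             for k, m in masks.items()}
    return SyntheticScan(high=high, low=low, masks=masks,
                         vessels={v.label: v for v in vessels})


# ---------------------------------------------------------------------------
# Ready-made exam layout

def _steady_amp(q_ml_min: float, radius: float, fluid: FluidProps) -> float:
    """Steady pressure-gradient amplitude giving a target mean flow."""
    return 8.0 * fluid.dynamic_viscosity * (q_ml_min / 60.0) / (np.pi * radius ** 4)


def default_exam_vessels(tcbf: float = 800.0, jvf_pct: float = 70.0,
                         svf_pct: float = 10.0,
                         csf_pg_amp_mmhg_cm: float = 0.020) -> list:
    """A physiologically scaled ten-lumen layout for a 160x160 grid.

    Mean flows: the internal carotids carry 75% of tCBF and the
    vertebrals 25%; jugular and secondary venous channels carry the
    requested fractions of tCBF (the remainder is the deliberately
    unmeasured venous pathway that the steady-state correction has to
    absorb). The CSF channel is purely oscillatory with a first-harmonic
    driving gradient of amplitude ``csf_pg_amp_mmhg_cm`` (peak-to-peak
    twice that), the scale of cervical CSF pulsation.

    Coordinates are pixel units for 0.03 cm pixel spacing
    (pixel_area 9e-4 cm^2).
    """
    from .core import DYN_CM3_PER_MMHG_CM

    def artery(label, center, radius, q):
        g0 = _steady_amp(q, radius, BLOOD := fluid_for_label(label))
        harm = (g0, 0.5 * g0 * np.exp(-1j * 0.4), 0.18 * g0 * np.exp(-1j * 1.5))
        return VesselSpec(label, center, radius, harm, direction=+1)

    def vein(label, center, radius, q, puls=0.18):
        g0 = _steady_amp(q, radius, fluid_for_label(label))
        harm = (g0, puls * g0 * np.exp(-1j * 1.0))
        return VesselSpec(label, center, radius, harm, direction=-1)

    q_ica = 0.375 * tcbf
    q_va = 0.125 * tcbf
    q_jv = 0.5 * jvf_pct / 100.0 * tcbf
    q_sec = svf_pct / 100.0 * tcbf / 3.0
    g_csf = csf_pg_amp_mmhg_cm * DYN_CM3_PER_MMHG_CM
    vessels = [
        artery("RICA", (35.0, 35.0), 0.30, q_ica),
        artery("LICA", (35.0, 125.0), 0.30, q_ica),
        artery("RVA", (65.0, 22.0), 0.20, q_va),
        artery("LVA", (65.0, 138.0), 0.20, q_va),
        vein("RIJV", (28.0, 65.0), 0.35, q_jv, puls=0.25),
        vein("LIJV", (28.0, 98.0), 0.35, q_jv, puls=0.25),
        vein("DCV", (100.0, 30.0), 0.20, q_sec, puls=0.10),
        vein("VV", (100.0, 130.0), 0.20, q_sec, puls=0.10),
        vein("EV", (118.0, 80.0), 0.20, q_sec, puls=0.10),
        VesselSpec("CSF", (75.0, 80.0), 0.40,
                   (0.0, g_csf * np.exp(-1j * 0.9)), direction=-1),
    ]
    return vessels


def default_exam(seed: int = 0, noise_sd_high: float = 0.0,
                 noise_sd_low: float = 0.0, venc_high: float = 80.0,
                 venc_low: float = 8.0, cycle_duration: float = 1.0,
                 **vessel_kwargs) -> SyntheticScan:
    """Generate the paired scans of the default synthetic subject."""
    vessels = default_exam_vessels(**vessel_kwargs)
    p_high = AcquisitionParams(venc=venc_high, pixel_area=9e-4,
                               cycle_duration=cycle_duration,
                               noise_sd=noise_sd_high)
    p_low = AcquisitionParams(venc=venc_low, pixel_area=9e-4,
                              cycle_duration=cycle_duration,
                              noise_sd=noise_sd_low)
    return generate_cine(vessels, p_high, p_low, shape=(160, 160), seed=seed)


def analytic_subject_truth(vessels: Sequence[VesselSpec],
                           params: AcquisitionParams,
                           n_fine: int = 4096) -> dict:
    """Closed-form reference quantities for a synthetic subject.

    Evaluates every vessel's analytic flow waveform on a fine time grid,
    orients signs (inflow/outflow/caudal positive), applies the exact
    steady-state venous rescaling, and returns drainage fractions, CSF
    stroke volume, the intracranial volume-change extremum (ICVC) and
    the CSF peak-to-peak pressure gradient. Independent of the imaging
    and segmentation pipeline: no pixel sampling is involved.
    """
    from .core import (ARTERIAL_LABELS, DYN_CM3_PER_MMHG_CM, FLOW_SIGN,
                       JUGULAR_LABELS, SECONDARY_LABELS)

    T = params.cycle_duration
    t = np.arange(n_fine) * T / n_fine
    q = {}
    for v in vessels:
        fluid = fluid_for_label(v.label)
        q[v.label] = FLOW_SIGN[v.label] * womersley_flow_waveform(
            v, fluid, params, times=t)

    arterial = sum(q[l] for l in ARTERIAL_LABELS if l in q)
    venous = sum((q[l] for l in JUGULAR_LABELS + SECONDARY_LABELS if l in q),
                 np.zeros(n_fine))
    csf = q.get(CSF_LABEL, np.zeros(n_fine))

    tcbf = float(np.mean(arterial))
    tjvf = float(np.mean(sum((q[l] for l in JUGULAR_LABELS if l in q),
                             np.zeros(n_fine))))
    svf = float(np.mean(sum((q[l] for l in SECONDARY_LABELS if l in q),
                            np.zeros(n_fine))))
    scale = tcbf / float(np.mean(venous))
    net = (arterial - scale * venous - csf) / 60.0  # ml/s
    dt = T / n_fine
    dv = np.concatenate([[0.0], np.cumsum(0.5 * (net[:-1] + net[1:]) * dt)])
    icvc = float(dv.max() - dv.min())

    csf_osc = csf - csf.mean()
    csf_sv = float(np.sum(np.clip(csf_osc, 0.0, None)) * dt / 60.0)

    ptp_pg = 0.0
    for v in vessels:
        if v.label == CSF_LABEL:
            g = pressure_gradient_waveform(v, params, times=t)
            ptp_pg = float((g.max() - g.min()) / DYN_CM3_PER_MMHG_CM)

    return {
        "tcbf": tcbf, "tjvf": tjvf, "jvf_pct": 100.0 * tjvf / tcbf,
        "svf_pct": 100.0 * svf / tcbf, "venous_scale": scale,
        "csf_sv": csf_sv, "icvc": icvc, "ptp_pg": ptp_pg,
    }
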