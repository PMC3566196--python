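"""Volumetric flow waveforms and cerebral drainage summary quantities.

Flow through a lumen is the sum of pixel velocities over the segmented
cross-section times the pixel area, evaluated at each of the cardiac
phases of the cine. Summaries follow the conventions of cervical
flow-quantification studies: total cerebral blood flow (tCBF) is the
summed mean flow of both internal carotid and both vertebral arteries;
total jugular venous flow (tJVF) sums both internal jugular veins;
secondary venous flow (SVF) sums the deep cervical, vertebral and
epidural channels; venous flows are also expressed as percentages of
tCBF. The cervical CSF stroke volume is the volume displaced in one
direction per cycle, i.e. the time integral of the positive lobe of the
oscillatory CSF flow waveform.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np

from .core import (ARTERIAL_LABELS, CSF_LABEL, FLOW_SIGN, FlowWaveform,
                   JUGULAR_LABELS, LumenMask, SECONDARY_LABELS, VelocityCine,
                   cycle_integral)
from .errors import BoundsError, DegenerateInputError


def integrate_flow(cine: VelocityCine, mask: LumenMask,
                   orient: bool = False) -> FlowWaveform:
    """Integrate pixel velocities over a lumen into a flow waveform.

    ``q[t] = sum_pixels v[t, pixel] * pixel_area`` converted to ml/min.
    With ``orient=True`` the anatomical sign convention is applied from
    the mask label (arterial inflow, venous outflow and caudal CSF flow
    positive).
    """
    if mask.mask.shape != cine.shape:
        raise BoundsError(
            f"mask shape {mask.mask.shape} does not match cine {cine.shape}")
    q_ml_min = cine.velocity[:, mask.mask].sum(axis=1) * cine.params.pixel_area * 60.0
    if orient:
        q_ml_min = q_ml_min * FLOW_SIGN.get(mask.label, 1.0)
    return FlowWaveform(label=mask.label, q=q_ml_min,
                        cycle_duration=cine.params.cycle_duration)


def sum_waveforms(waveforms, label: str) -> FlowWaveform:
    """Pointwise sum of waveforms on a common phase grid."""
    from .core import check_aligned

    waveforms = list(waveforms)
    if not waveforms:
        raise DegenerateInputError(f"no waveforms to sum for {label!r}")
    check_aligned(*waveforms)
    q = np.sum([w.q for w in waveforms], axis=0)
    return FlowWaveform(label=label, q=q,
                        cycle_duration=waveforms[0].cycle_duration)


@dataclass
class DrainageProfile:
    """Per-subject drainage summary (one row of the study's flow table)."""

    tcbf: float                      # ml/min
    tjvf: float                      # ml/min
    jvf_pct: float                   # % of tCBF
    dcv_pct: float
    vv_pct: float
    ev_pct: float
    svf_total_pct: float
    csf_stroke_volume: Optional[float] = None  # ml

    def rounded(self) -> dict:
        """Values at the precision used in the study tables."""
        out = {"tcbf": round(self.tcbf), "tjvf": round(self.tjvf)}
        for k in ("jvf_pct", "dcv_pct", "vv_pct", "ev_pct", "svf_total_pct"):
            out[k] = round(getattr(self, k), 1)
        if self.csf_stroke_volume is not None:
            out["csf_stroke_volume"] = round(self.csf_stroke_volume, 2)
        return out


def drainage_profile(waveforms: Mapping[str, FlowWaveform]) -> DrainageProfile:
    """Drainage summary from labelled, orientation-corrected waveforms.

    All four arteries must be present; absent venous channels count as
    zero flow. Percentages are computed from cycle-mean flows.
    """
    missing = [l for l in ARTERIAL_LABELS if l not in waveforms]
    if missing:
        raise DegenerateInputError(f"missing arterial waveforms: {missing}")
    tcbf = sum(waveforms[l].mean for l in ARTERIAL_LABELS)
    if tcbf <= 0:
        raise DegenerateInputError(f"non-positive tCBF ({tcbf:.3g} ml/min)")
    tjvf = sum(waveforms[l].mean for l in JUGULAR_LABELS if l in waveforms)
    pct = {l: 100.0 * waveforms[l].mean / tcbf if l in waveforms else 0.0
           for l in SECONDARY_LABELS}
    return DrainageProfile(
        tcbf=tcbf, tjvf=tjvf, jvf_pct=100.0 * tjvf / tcbf,
        dcv_pct=pct["DCV"], vv_pct=pct["VV"], ev_pct=pct["EV"],
        svf_total_pct=sum(pct.values()))


def csf_stroke_volume(csf: FlowWaveform, mode: str = "oscillatory") -> float:
    """Volume of CSF displaced in one direction per cardiac cycle, in ml.

    ``mode='oscillatory'`` (default) integrates the positive lobe of the
    mean-subtracted waveform — the pure back-and-forth displacement.
    ``mode='raw'`` integrates the positive lobe of the raw waveform.
    Trapezoidal rule with periodic closure on the phase grid.
    """
    if mode not in ("oscillatory", "raw"):
        raise ValueError(f"unknown stroke-volume mode {mode!r}")
    q = csf.q - csf.q.mean() if mode == "oscillatory" else csf.q
    positive = np.clip(q, 0.0, None)
    # ml/min integrated over seconds -> /60 for ml
    yc = np.concatenate([positive, positive[:1]])
    dt = csf.cycle_duration / csf.n_phases
    return float(np.sum(0.5 * (yc[:-1] + yc[1:]) * dt) / 60.0)


def waveforms_to_frame(waveforms: Mapping[str, FlowWaveform],
                       subject_id: str = "") -> "object":
    """Tidy per-phase table (subject, label, phase_index, time_s, q_ml_per_min)."""
    import pandas as pd

    rows = []
    for label, w in waveforms.items():
        for k, (t, q) in enumerate(zip(w.times, w.q)):
            rows.append((subject_id, label, k, t, q))
    return pd.DataFrame(rows, columns=["subject", "label", "phase_index",
                                       "time_s", "q_ml_per_min"])
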