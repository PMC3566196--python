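"""End-to-end orchestration: one subject's exam, and the cohort report.

``run_subject`` chains the stages in acquisition order — segment each
lumen from its cine series (arteries and jugular veins on the high-VENC
series; secondary veins and CSF on the low-VENC series), integrate flow
waveforms, summarize drainage, apply the steady-state venous
correction, accumulate the intracranial volume-change waveform, recover
the CSF pressure gradient, and derive compliance and MRICP.

``reproduce_tables`` recomputes every group summary of the packaged
study tables and runs the statistical battery, emitting a side-by-side
printed-vs-recomputed report.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

from .core import (ARTERIAL_LABELS, CSF_LABEL, FlowWaveform, JUGULAR_LABELS,
                   LumenMask, SECONDARY_LABELS, VelocityCine, fluid_for_label)
from .errors import ConfigurationError, CranioflowError
from .flow import (csf_stroke_volume, drainage_profile, integrate_flow,
                   sum_waveforms, waveforms_to_frame)
from .hydro import (CalibrationConfig, HydroResult, compliance_and_mricp,
                    correct_venous_outflow, csf_pressure_gradient,
                    icvc_waveform)
from .segmentation import PubsConfig, segment_from_seed

#: Which cine series each lumen class is segmented and quantified on.
SERIES_FOR_LABEL = {**{l: "high" for l in ARTERIAL_LABELS + JUGULAR_LABELS},
                    **{l: "low" for l in SECONDARY_LABELS}, CSF_LABEL: "low"}


@dataclass
class RunConfig:
    """Configuration of one subject run.

    ``seeds`` maps lumen label to a (row, col) seed pixel. ``pubs`` may
    be a single PubsConfig or a per-label mapping; unlisted labels use
    the default. By default the CSF lumen is segmented with
    ``polarity=True`` since its flow reverses over the cycle on the
    low-VENC series.
    """

    seeds: Dict[str, Tuple[int, int]]
    pubs: Dict[str, PubsConfig] = field(default_factory=dict)
    calibration: CalibrationConfig = field(default_factory=CalibrationConfig)
    stroke_volume_mode: str = "oscillatory"
    subject_id: str = "subject"
    output_dir: Optional[Path] = None

    def pubs_for(self, label: str) -> PubsConfig:
        if label in self.pubs:
            return self.pubs[label]
        if label == CSF_LABEL:
            return PubsConfig(polarity=True)
        return PubsConfig()

    def content_hash(self) -> str:
        payload = {
            "seeds": {k: list(map(int, v)) for k, v in sorted(self.seeds.items())},
            "pubs": {k: vars(v) for k, v in sorted(self.pubs.items())},
            "calibration": vars(self.calibration),
            "stroke_volume_mode": self.stroke_volume_mode,
        }
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()


@dataclass
class SubjectResult:
    """Everything computed for one subject."""

    record: pd.Series
    masks: Dict[str, LumenMask]
    waveforms: Dict[str, FlowWaveform]
    hydro: HydroResult
    provenance: dict


def _stage(name: str, subject_id: str):
    """Context tagging pipeline errors with the failing stage."""
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and isinstance(exc, CranioflowError):
                exc.args = (f"[{subject_id}:{name}] {exc.args[0]}"
                            if exc.args else f"[{subject_id}:{name}]",)
            return False
    return _Ctx()


def run_subject(high: VelocityCine, low: VelocityCine,
                config: RunConfig) -> SubjectResult:
    """Execute segment -> quantify -> correct -> ICVC -> PG -> compliance."""
    series = {"high": high, "low": low}
    masks: Dict[str, LumenMask] = {}
    waveforms: Dict[str, FlowWaveform] = {}

    for label, seed in config.seeds.items():
        which = SERIES_FOR_LABEL.get(label)
        if which is None:
            raise ConfigurationError(f"unknown lumen label {label!r}")
        cine = series[which]
        with _stage(f"segment:{label}", config.subject_id):
            mask = segment_from_seed(cine, seed, label=label,
                                     config=config.pubs_for(label))
        masks[label] = mask
        with _stage(f"quantify:{label}", config.subject_id):
            waveforms[label] = integrate_flow(cine, mask, orient=True)

    with _stage("drainage", config.subject_id):
        profile = drainage_profile(waveforms)
        if CSF_LABEL in waveforms:
            profile.csf_stroke_volume = csf_stroke_volume(
                waveforms[CSF_LABEL], mode=config.stroke_volume_mode)

    with _stage("venous-correction", config.subject_id):
        arterial = sum_waveforms((waveforms[l] for l in ARTERIAL_LABELS),
                                 label="arterial")
        venous = sum_waveforms(
            (waveforms[l] for l in JUGULAR_LABELS + SECONDARY_LABELS
             if l in waveforms), label="venous")
        venous_corr, scale = correct_venous_outflow(arterial, venous)

    with _stage("icvc", config.subject_id):
        icvc = icvc_waveform(arterial, venous_corr, waveforms[CSF_LABEL])

    with _stage("pressure-gradient", config.subject_id):
        pg = csf_pressure_gradient(low, masks[CSF_LABEL],
                                   fluid_for_label(CSF_LABEL))

    with _stage("compliance", config.subject_id):
        hydro = compliance_and_mricp(icvc, pg, config.calibration,
                                     venous_scale=scale)

    record = pd.Series({
        "subject_id": config.subject_id,
        "tcbf": profile.tcbf, "jvf": profile.tjvf, "jvf_pct": profile.jvf_pct,
        "dcv_pct": profile.dcv_pct, "vv_pct": profile.vv_pct,
        "ev_pct": profile.ev_pct, "svf_total_pct": profile.svf_total_pct,
        "csf_sv": profile.csf_stroke_volume,
        "ptp_pg": hydro.ptp_pg, "icvc": hydro.icvc,
        "compliance_index": hydro.compliance_index, "mricp": hydro.mricp,
        "venous_scale": hydro.venous_scale,
    })
    provenance = {
        "subject_id": config.subject_id,
        "config_hash": config.content_hash(),
        "numpy_version": np.__version__,
        "seeds": {k: list(map(int, v)) for k, v in config.seeds.items()},
        "calibration": vars(config.calibration),
        "series": {k: s.name for k, s in series.items()},
    }
    result = SubjectResult(record=record, masks=masks, waveforms=waveforms,
                           hydro=hydro, provenance=provenance)
    if config.output_dir is not None:
        _write_subject_outputs(result, high, config)
    return result


def _write_subject_outputs(result: SubjectResult, high: VelocityCine,
                           config: RunConfig) -> None:
    from .io import write_masks

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    waveforms_to_frame(result.waveforms, config.subject_id).to_csv(
        out / "waveforms.csv", index=False)
    header = "# calibration: " + json.dumps(vars(config.calibration)) + "\n"
    record_csv = result.record.to_frame().T.to_csv(index=False)
    (out / "hydro_result.csv").write_text(header + record_csv)
    write_masks(result.masks, high.params, out / "masks.nii.gz")
    (out / "provenance.json").write_text(json.dumps(result.provenance, indent=2))


def run_phantom_subject(scan, config: Optional[RunConfig] = None,
                        subject_id: str = "phantom") -> SubjectResult:
    """Run the pipeline on a synthetic exam, seeding at true lumen centres."""
    if config is None:
        seeds = {label: tuple(int(round(c)) for c in spec.center)
                 for label, spec in scan.vessels.items()}
        config = RunConfig(seeds=seeds, subject_id=subject_id)
    return run_subject(scan.high, scan.low, config)


# ---------------------------------------------------------------------------
# Cohort-level reproduction report

#: Continuous variables compared with the rank-transform mixed model,
#: and the ordinal venogram grade compared with Mann-Whitney U.
LMM_VARIABLES = ("tcbf", "jvf", "jvf_pct", "svf_total_pct",
                 "csf_sv", "ptp_pg", "icvc", "mricp")
ORDINAL_VARIABLES = ("mrv_grade",)


def reproduce_tables(output_dir: Optional[Path] = None
                     ) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Recompute the study's group summaries and statistical battery.

    Returns ``(summary, tests)``: ``summary`` compares every printed
    group-summary cell with the value recomputed from the per-subject
    fixtures (difference and a within-rounding flag); ``tests`` holds
    one row per statistical comparison.
    """
    from .datasets import load_printed_summaries, load_subject_table
    from .stats import group_summary, mann_whitney_u, paired_rank_lmm_test

    records = load_subject_table()
    printed = load_printed_summaries()

    rows = []
    for _, cell in printed.iterrows():
        summ = group_summary(records, cell["variable"], cell["statistic"])
        got = summ[cell["group"]]
        recomputed = round(got["value"], int(cell["decimals"]))
        # attainable agreement: one unit in the summary's last printed
        # digit, or the worst-case mean shift from the per-subject
        # values themselves being printed rounded (half a unit of their
        # last digit), whichever is larger
        tol = max(10.0 ** (-int(cell["decimals"])),
                  0.5 * 10.0 ** (-int(cell["input_decimals"])))
        rows.append({
            "table": int(cell["table"]), "variable": cell["variable"],
            "group": cell["group"], "statistic": cell["statistic"],
            "printed": cell["printed"], "recomputed": recomputed,
            "n": got["n"], "difference": recomputed - cell["printed"],
            "within_rounding": abs(recomputed - cell["printed"]) <= tol + 1e-12,
        })
    summary = pd.DataFrame(rows)

    tests = []
    for var in LMM_VARIABLES:
        res = paired_rank_lmm_test(records, var)
        tests.append({"variable": var, "test": res.test,
                      "statistic": res.statistic, "p_value": res.p_value,
                      **{f"n_{k}": v for k, v in res.n.items()},
                      **{f"mean_{k}": v for k, v in res.group_means.items()}})
    for var in ORDINAL_VARIABLES:
        a = records.loc[records["group"] == "mTBI", var]
        b = records.loc[records["group"] == "control", var]
        res = mann_whitney_u(a, b, variable=var)
        tests.append({"variable": var, "test": res.test,
                      "statistic": res.statistic, "p_value": res.p_value,
                      "n_mTBI": res.n["a"], "n_control": res.n["b"],
                      "mean_mTBI": res.group_means["a"],
                      "mean_control": res.group_means["b"]})
    tests = pd.DataFrame(tests)

    if output_dir is not None:
        out = Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)
        summary.to_csv(out / "table_reproduction.csv", index=False)
        tests.to_csv(out / "group_tests.csv", index=False)
    return summary, tests
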