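"""Run the full per-subject pipeline on a synthetic exam.

Chains segmentation, flow integration, drainage summary, the
steady-state venous correction, the intracranial volume-change
waveform, the Navier-Stokes CSF pressure gradient, and the
compliance/MR-ICP estimate, then compares against the phantom's
analytic truth.
"""

import cranioflow as cf

scan = cf.default_exam(seed=1)
result = cf.run_phantom_subject(scan, subject_id="phantom-01")
truth = cf.analytic_subject_truth(list(scan.vessels.values()),
                                  scan.high.params)

r = result.record
print(f"{'quantity':28s} {'pipeline':>10s} {'analytic':>10s}")
rows = [
    ("tCBF (ml/min)", r["tcbf"], truth["tcbf"]),
    ("jugular fraction (%)", r["jvf_pct"], truth["jvf_pct"]),
    ("secondary fraction (%)", r["svf_total_pct"], truth["svf_pct"]),
    ("CSF stroke volume (ml)", r["csf_sv"], truth["csf_sv"]),
    ("ICVC (ml)", r["icvc"], truth["icvc"]),
    ("PTP-PG (mmHg/cm)", r["ptp_pg"], truth["ptp_pg"]),
    ("venous scale", r["venous_scale"], truth["venous_scale"]),
]
for name, got, want in rows:
    print(f"{name:28s} {got:10.3f} {want:10.3f}")
print(f"\ncompliance index {r['compliance_index']:.2f}, "
      f"MR-ICP {r['mricp']:.1f} mmHg (calibration d=1.8 cm, a=73 mmHg)")
print("Pipeline-vs-analytic differences reflect pixel-centre sampling of")
print("the lumen rim; the venous correction absorbs the deliberately")
print("unmeasured fraction of venous outflow (scale > 1).")
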