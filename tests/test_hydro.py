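"""Volume balance, Navier-Stokes pressure gradient, compliance, MR-ICP."""

import numpy as np
import pytest

import cranioflow as cf
from cranioflow.core import DYN_CM3_PER_MMHG_CM, FLOW_SIGN, fluid_for_label
from cranioflow.errors import AlignmentError, DegenerateInputError, GeometryError
from cranioflow.phantom import default_exam_vessels, womersley_flow_waveform


def wf(values, label="arterial", T=1.0):
    return cf.FlowWaveform(label, np.asarray(values, dtype=float), T)


def scaled_subject(target_icvc=0.60):
    """Default exam with oscillatory harmonics rescaled so the analytic
    intracranial volume-change excursion is exactly ``target_icvc`` ml."""
    params = cf.AcquisitionParams(venc=80, pixel_area=9e-4)
    vessels = default_exam_vessels()
    base = cf.analytic_subject_truth(vessels, params)["icvc"]
    c = target_icvc / base
    out = []
    for v in vessels:
        h = (v.pg_harmonics[0],) + tuple(c * g for g in v.pg_harmonics[1:])
        out.append(cf.VesselSpec(v.label, v.center, v.radius, h, v.direction))
    return out, params


class TestVenousCorrection:
    def test_equal_means_leave_waveform_unchanged(self):
        a = wf(600 + 50 * np.sin(2 * np.pi * np.arange(32) / 32))
        v = wf(np.full(32, a.mean), label="venous")
        corrected, scale = cf.correct_venous_outflow(a, v)
        assert scale == pytest.approx(1.0)
        assert np.allclose(corrected.q, v.q)

    def test_scale_is_mean_ratio(self):
        a = wf(np.full(32, 800.0))
        v = wf(np.full(32, 640.0), label="venous")
        _, scale = cf.correct_venous_outflow(a, v)
        assert scale == pytest.approx(1.25)

    def test_enforced_zero_mean_balance(self):
        rng = np.random.default_rng(0)
        a = wf(700 + 80 * rng.standard_normal(32))
        v = wf(np.abs(500 + 60 * rng.standard_normal(32)), label="venous")
        corrected, _ = cf.correct_venous_outflow(a, v)
        assert abs(np.mean(a.q - corrected.q)) < 1e-12 * a.mean

    def test_nonpositive_venous_mean_rejected(self):
        a = wf(np.full(32, 800.0))
        with pytest.raises(DegenerateInputError):
            cf.correct_venous_outflow(a, wf(np.zeros(32), label="venous"))

    def test_additive_mode(self):
        a = wf(np.full(32, 800.0))
        v = wf(np.full(32, 640.0), label="venous")
        corrected, offset = cf.additive_venous_correction(a, v)
        assert offset == pytest.approx(160.0)
        assert np.allclose(corrected.q, 800.0)


class TestICVC:
    def test_zero_net_flow_gives_zero_icvc(self):
        z = wf(np.zeros(32))
        out = cf.icvc_waveform(wf(np.full(32, 500.0)),
                               wf(np.full(32, 500.0), "venous"), z)
        assert out.icvc == pytest.approx(0.0, abs=1e-14)

    def test_sinusoidal_net_flow_closed_form(self):
        # n(t) = B sin(2 pi t), B = 1.5 ml/s -> icvc = B T / pi
        t = np.arange(32) / 32
        B = 1.5 * 60  # ml/min
        a = wf(600 + B * np.sin(2 * np.pi * t))
        v = wf(np.full(32, 600.0), "venous")
        out = cf.icvc_waveform(a, v, wf(np.zeros(32), "CSF"))
        assert out.icvc == pytest.approx(1.5 / np.pi, rel=5e-3)
        assert abs(out.closure) < 1e-9

    def test_mismatched_grids_rejected(self):
        with pytest.raises(AlignmentError):
            cf.icvc_waveform(wf(np.full(32, 1.0)), wf(np.full(16, 1.0)),
                             wf(np.full(32, 0.0)))

    def test_synthetic_subject_with_known_icvc(self):
        # generator built so the analytic excursion is exactly 0.60 ml
        vessels, params = scaled_subject(0.60)
        w = {v.label: wf(FLOW_SIGN[v.label] * womersley_flow_waveform(
            v, fluid_for_label(v.label), params), v.label)
            for v in vessels}
        arterial = cf.sum_waveforms((w[l] for l in cf.ARTERIAL_LABELS), "arterial")
        venous = cf.sum_waveforms(
            (w[l] for l in cf.JUGULAR_LABELS + cf.SECONDARY_LABELS), "venous")
        corrected, _ = cf.correct_venous_outflow(arterial, venous)
        out = cf.icvc_waveform(arterial, corrected, w["CSF"])
        assert out.icvc == pytest.approx(0.60, abs=0.01)
        assert abs(out.closure) < 1e-9


class TestPressureGradient:
    def make_scan(self, alpha, ptp_mmhg_cm=0.040, px_per_radius=12):
        R, rho = 0.4, 1.0
        omega = 2 * np.pi
        mu = omega * rho * R ** 2 / alpha ** 2
        fluid = cf.FluidProps(density=rho, dynamic_viscosity=mu)
        G = 0.5 * ptp_mmhg_cm * DYN_CM3_PER_MMHG_CM
        spec = cf.VesselSpec("CSF", (40.0, 40.0), R,
                             (0.0, G * np.exp(-1j * 0.7)), direction=-1)
        px = R / px_per_radius
        p = cf.AcquisitionParams(venc=10.0, pixel_area=px ** 2)
        scan = cf.generate_cine([spec], p, p, fluid_map={"CSF": fluid},
                                shape=(80, 80), seed=0)
        return scan, fluid

    def test_static_fluid_gives_zero(self):
        v = np.zeros((32, 10, 10))
        mask = np.zeros((10, 10), dtype=bool)
        mask[2:8, 2:8] = True
        cine = cf.VelocityCine(v, np.ones_like(v),
                               cf.AcquisitionParams(venc=8.0))
        pg = cf.csf_pressure_gradient(cine, cf.LumenMask("CSF", mask),
                                      cf.CSF_FLUID)
        assert np.allclose(pg.pg, 0.0)
        assert pg.ptp_pg == 0.0

    def test_steady_poiseuille_inverts_exactly(self):
        # |G| = 1 dyn/cm^3, R = 0.3, mu = 0.01 -> 7.50e-4 mmHg/cm steady
        R = 0.3
        px = R / 12
        spec = cf.VesselSpec("CSF", (30.0, 30.0), R, (1.0,))
        p = cf.AcquisitionParams(venc=10.0, pixel_area=px ** 2)
        scan = cf.generate_cine([spec], p, p, shape=(60, 60), seed=0)
        pg = cf.csf_pressure_gradient(scan.high, scan.masks["CSF"],
                                      cf.CSF_FLUID)
        assert np.allclose(pg.pg * DYN_CM3_PER_MMHG_CM, 1.0, rtol=0.05)
        assert pg.ptp_pg == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("alpha", [2.0, 5.0, 10.0])
    def test_womersley_recovery_across_alpha(self, alpha):
        scan, fluid = self.make_scan(alpha)
        pg = cf.csf_pressure_gradient(scan.high, scan.masks["CSF"], fluid)
        truth = scan.high.truth["CSF"]["pg_dyn_cm3"] / DYN_CM3_PER_MMHG_CM
        rel_rms = np.linalg.norm(pg.pg - truth) / np.linalg.norm(truth)
        assert rel_rms < 0.05
        assert pg.ptp_pg == pytest.approx(truth.max() - truth.min(), rel=0.05)

    def test_too_thin_lumen_rejected(self):
        v = np.zeros((32, 10, 10))
        mask = np.zeros((10, 10), dtype=bool)
        mask[5, 2:8] = True  # one pixel thick: no full neighbourhood
        cine = cf.VelocityCine(v, np.ones_like(v),
                               cf.AcquisitionParams(venc=8.0))
        with pytest.raises(GeometryError):
            cf.csf_pressure_gradient(cine, cf.LumenMask("CSF", mask),
                                     cf.CSF_FLUID)


class TestComplianceAndICP:
    def result(self, icvc_ml, ptp, cal=None):
        dv = np.array([0.0, icvc_ml, 0.0])
        pg = np.array([0.0, ptp])
        return cf.compliance_and_mricp(
            cf.ICVCWaveform(dv, 1.0), cf.PressureGradientWaveform(pg, 1.0),
            cal or cf.CalibrationConfig())

    def test_group_mean_inputs_land_in_reported_range(self):
        # icvc 0.48 ml, ptp 0.043 mmHg/cm, d=1.8, a=73
        res = self.result(0.48, 0.043)
        assert res.compliance_index == pytest.approx(6.20, abs=0.01)
        assert res.mricp == pytest.approx(11.8, abs=0.1)

    def test_scaling_law(self):
        r1 = self.result(0.48, 0.043)
        r2 = self.result(0.48, 0.086)
        assert r2.compliance_index == pytest.approx(r1.compliance_index / 2)
        assert r2.mricp == pytest.approx(2 * r1.mricp)

    def test_inverse_law_exact(self):
        cal = cf.CalibrationConfig(icp_offset=2.0)
        res = self.result(0.37, 0.051, cal)
        assert res.compliance_index * (res.mricp - cal.icp_offset) \
            == pytest.approx(cal.icp_inverse_coefficient, rel=1e-12)

    def test_vanishing_compliance_is_capped_with_warning(self):
        with pytest.warns(RuntimeWarning):
            res = self.result(1e-6, 0.043)
        assert res.mricp == cf.CalibrationConfig().mricp_cap

    def test_zero_ptp_rejected(self):
        with pytest.raises(DegenerateInputError):
            self.result(0.5, 0.0)


class TestCompliancePhysiology:
    def test_csf_tracks_net_blood_flow_more_closely_at_low_compliance(self):
        """A stiff craniospinal system transmits the arterial-venous
        volume load directly into CSF displacement, so corr(CSF, A-V)
        is higher than in a compliant system that buffers and lags it."""
        params = cf.AcquisitionParams(venc=80, pixel_area=9e-4)

        def subject_waveforms(csf_harmonics):
            vessels = [v for v in default_exam_vessels() if v.label != "CSF"]
            csf = cf.VesselSpec("CSF", (75.0, 80.0), 0.40, csf_harmonics,
                                direction=-1)
            w = {v.label: wf(FLOW_SIGN[v.label] * womersley_flow_waveform(
                v, fluid_for_label(v.label), params), v.label)
                for v in vessels + [csf]}
            arterial = cf.sum_waveforms(
                (w[l] for l in cf.ARTERIAL_LABELS), "arterial")
            venous = cf.sum_waveforms(
                (w[l] for l in cf.JUGULAR_LABELS + cf.SECONDARY_LABELS),
                "venous")
            corrected, _ = cf.correct_venous_outflow(arterial, venous)
            return arterial.q - corrected.q, w["CSF"].q

        g = 0.020 * DYN_CM3_PER_MMHG_CM
        # low compliance: CSF driven by first and second harmonics nearly
        # in phase with the net trans-cranial blood load
        av_low, csf_low = subject_waveforms(
            (0.0, g * np.exp(-1j * 0.9), 0.4 * g * np.exp(-1j * 1.2)))
        # high compliance: buffered (single harmonic), strongly lagged
        av_high, csf_high = subject_waveforms((0.0, 0.5 * g * np.exp(-1j * 2.6)))
        corr_low = np.corrcoef(csf_low, av_low)[0, 1]
        corr_high = np.corrcoef(csf_high, av_high)[0, 1]
        assert corr_low > corr_high
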