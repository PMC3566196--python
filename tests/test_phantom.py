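"""Phantom generator: Womersley analytics, VENC encoding, cohorts."""

import numpy as np
import pytest
from scipy.linalg import solve_banded

import cranioflow as cf
from cranioflow.core import DYN_CM3_PER_MMHG_CM
from cranioflow.errors import GeometryError, InvalidSpecError


def oscillatory_ode_oracle(G, omega, rho, mu, R, radii, n_nodes=6000):
    """Brute-force finite-difference solve of the radial momentum ODE.

    i rho w u = G + mu (u'' + u'/r), u'(0) = 0, u(R) = 0, on a staggered
    grid (cell centres), then interpolated onto ``radii``. Independent
    of the Bessel-function closed form.
    """
    d = R / n_nodes
    r = (np.arange(n_nodes) + 0.5) * d
    lower = mu * (1.0 / d ** 2 - 1.0 / (2 * r * d))
    diag = np.full(n_nodes, -2.0 * mu / d ** 2) - 1j * rho * omega
    upper = mu * (1.0 / d ** 2 + 1.0 / (2 * r * d))
    # symmetry ghost at r=-d/2 mirrors node 0; wall ghost is -u_{M-1}
    diag[0] += lower[0]
    diag[-1] -= upper[-1]
    ab = np.zeros((3, n_nodes), dtype=complex)
    ab[0, 1:] = upper[:-1]
    ab[1, :] = diag
    ab[2, :-1] = lower[1:]
    u = solve_banded((1, 1), ab, np.full(n_nodes, -G, dtype=complex))
    u_full = np.interp(radii, np.concatenate([r, [R]]),
                       np.concatenate([u, [0.0]]))
    return u_full


class TestWomersleyProfile:
    def test_poiseuille_centreline(self):
        # steady-only |G| = 1 dyn/cm^3, R = 0.3 cm, mu = 0.01 P
        spec = cf.VesselSpec("CSF", (0, 0), 0.3, (1.0,))
        u = cf.womersley_velocity_profile(
            spec, cf.CSF_FLUID, cf.AcquisitionParams(venc=10),
            radii=np.array([0.0]))
        assert u[:, 0] == pytest.approx(0.3 ** 2 * 1.0 / (4 * 0.01))  # 2.25

    @pytest.mark.parametrize("harmonics", [(1.0,), (0.0, 5.0), (2.0, 3j, 1.0)])
    def test_no_slip_at_wall(self, harmonics):
        spec = cf.VesselSpec("RICA", (0, 0), 0.25, harmonics)
        u = cf.womersley_velocity_profile(
            spec, cf.BLOOD_FLUID, cf.AcquisitionParams(venc=80),
            radii=np.array([0.25]))
        assert np.allclose(u, 0.0, atol=1e-12)

    def test_oscillatory_profile_matches_ode_oracle(self):
        # alpha = 5 via radius and viscosity choice
        R, rho = 0.4, 1.0
        omega = 2 * np.pi
        mu = omega * rho * R ** 2 / 5.0 ** 2
        fluid = cf.FluidProps(density=rho, dynamic_viscosity=mu)
        G = 30.0 * np.exp(-1j * 0.6)
        spec = cf.VesselSpec("CSF", (0, 0), R, (0.0, G))
        params = cf.AcquisitionParams(venc=10)
        radii = np.linspace(0, R, 41)
        u = cf.womersley_velocity_profile(spec, fluid, params, radii=radii)
        u_hat = oscillatory_ode_oracle(G, omega, rho, mu, R, radii)
        t = params.times
        u_oracle = np.real(u_hat[None, :] * np.exp(1j * omega * t)[:, None])
        scale = np.abs(u_oracle).max()
        assert np.max(np.abs(u - u_oracle)) / scale < 1e-3

    def test_cycle_integral_reduces_to_steady_poiseuille(self):
        # oscillatory harmonics integrate to zero over a full cycle
        spec = cf.VesselSpec("LICA", (0, 0), 0.3,
                             (2.0, 10.0 * np.exp(1j), 4j, 1.0 + 1j))
        params = cf.AcquisitionParams(venc=80)
        q = cf.womersley_flow_waveform(spec, cf.BLOOD_FLUID, params)
        steady = cf.womersley_flow_waveform(
            cf.VesselSpec("LICA", (0, 0), 0.3, (2.0,)), cf.BLOOD_FLUID, params)
        assert q.mean() == pytest.approx(steady[0], rel=1e-6)

    def test_linearity_in_pressure_gradient(self):
        params = cf.AcquisitionParams(venc=80)
        base = (1.5, 8.0 * np.exp(-1j * 0.3), 2j)
        c = 3.7
        spec1 = cf.VesselSpec("RVA", (0, 0), 0.2, base)
        spec2 = cf.VesselSpec("RVA", (0, 0), 0.2, tuple(c * g for g in base))
        u1 = cf.womersley_velocity_profile(spec1, cf.BLOOD_FLUID, params)
        u2 = cf.womersley_velocity_profile(spec2, cf.BLOOD_FLUID, params)
        q1 = cf.womersley_flow_waveform(spec1, cf.BLOOD_FLUID, params)
        q2 = cf.womersley_flow_waveform(spec2, cf.BLOOD_FLUID, params)
        assert np.allclose(u2, c * u1, rtol=1e-12)
        assert np.allclose(q2, c * q1, rtol=1e-12)

    @pytest.mark.parametrize("bad", [
        dict(radius=0.0), dict(radius=-1.0),
        dict(pg_harmonics=()), dict(pg_harmonics=(np.nan,)),
        dict(direction=2),
    ])
    def test_invalid_spec_rejected(self, bad):
        kwargs = dict(label="CSF", center=(0, 0), radius=0.3,
                      pg_harmonics=(1.0,), direction=1)
        kwargs.update(bad)
        with pytest.raises(InvalidSpecError):
            cf.VesselSpec(**kwargs)


class TestEncoding:
    def test_uniform_velocity_encodes_to_half_pi(self):
        venc = 8.0
        spec = cf.PlugSpec("VV", (16.0, 16.0), 0.2,
                           tuple(np.full(32, venc / 2)))
        p = cf.AcquisitionParams(venc=venc, pixel_area=9e-4)
        scan = cf.generate_cine([spec], p, p, shape=(32, 32), seed=0)
        phase = cf.encode_phase(scan.high.velocity, venc)
        inside = scan.masks["VV"].mask
        assert np.allclose(phase[:, inside], np.pi / 2)
        assert np.allclose(scan.high.velocity[:, ~inside], 0.0)

    def test_wrap_beyond_venc(self):
        venc = 8.0
        assert cf.decode_velocity(cf.encode_phase(1.5 * venc, venc), venc) \
            == pytest.approx(-0.5 * venc)

    def test_round_trip_within_venc(self):
        rng = np.random.default_rng(0)
        v = rng.uniform(-7.99, 7.99, size=256)
        assert np.allclose(
            cf.decode_velocity(cf.encode_phase(v, 8.0), 8.0), v, atol=1e-12)

    def test_seeded_determinism(self):
        kwargs = dict(noise_sd_high=0.1, noise_sd_low=0.1)
        a = cf.default_exam(seed=42, **kwargs)
        b = cf.default_exam(seed=42, **kwargs)
        c = cf.default_exam(seed=43, **kwargs)
        assert np.array_equal(a.high.velocity, b.high.velocity)
        assert np.array_equal(a.low.velocity, b.low.velocity)
        assert not np.array_equal(a.high.velocity, c.high.velocity)


class TestGeometryValidation:
    def test_overlapping_vessels_rejected(self):
        p = cf.AcquisitionParams(venc=80, pixel_area=9e-4)
        mk = lambda label, col: cf.VesselSpec(label, (16.0, col), 0.3, (1.0,))
        with pytest.raises(GeometryError):
            cf.generate_cine([mk("RICA", 14.0), mk("LICA", 18.0)],
                             p, p, shape=(32, 32), seed=0)

    def test_vessel_outside_grid_rejected(self):
        p = cf.AcquisitionParams(venc=80, pixel_area=9e-4)
        spec = cf.VesselSpec("RICA", (2.0, 2.0), 0.3, (1.0,))
        with pytest.raises(GeometryError):
            cf.generate_cine([spec], p, p, shape=(32, 32), seed=0)


class TestCohortGenerator:
    def test_null_configuration_has_no_group_difference(self):
        spec = cf.CohortEffectSpec(n_per_group=2000, seed=3).with_null_effect()
        df = cf.generate_cohort(spec)
        a = df.loc[df.group == "mTBI", "jvf_pct"]
        b = df.loc[df.group == "control", "jvf_pct"]
        se = np.sqrt(a.var() / len(a) + b.var() / len(b))
        assert abs(a.mean() - b.mean()) < 3 * se

    def test_monte_carlo_convergence_to_configured_mean(self):
        df = cf.generate_cohort(cf.CohortEffectSpec(n_per_group=10000, seed=7))
        jug = df.loc[df.group == "mTBI", "jvf_pct"]
        # truncation to [0, 100] barely moves the configured 60.9 mean
        assert abs(jug.mean() - 60.9) < 0.5

    def test_matched_pair_bookkeeping(self):
        df = cf.generate_cohort(cf.CohortEffectSpec(n_per_group=2, seed=0))
        assert sorted(df.pair_id.unique()) == ["PAIR_01", "PAIR_02"]
        assert df.groupby(["pair_id", "group"]).size().eq(1).all()

    def test_fraction_feasibility_enforced(self):
        df = cf.generate_cohort(cf.CohortEffectSpec(n_per_group=500, seed=1))
        assert ((df.jvf_pct + df.svf_total_pct) <= 100.0 + 1e-9).all()

    def test_infeasible_fractions_rejected(self):
        params = dict(cf.MTBI_LIKE)
        params["jvf_pct"] = (90.0, 1.0)
        params["dcv_pct"] = (15.0, 1.0)
        with pytest.raises(InvalidSpecError):
            cf.CohortEffectSpec(group_a=params)

    def test_inverse_pressure_law_exact_per_subject(self):
        df = cf.generate_cohort(cf.CohortEffectSpec(n_per_group=50, seed=5))
        cal = cf.CalibrationConfig()
        assert np.allclose(df.compliance_index * (df.mricp - cal.icp_offset),
                           cal.icp_inverse_coefficient)
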