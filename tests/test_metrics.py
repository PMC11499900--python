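import numpy as np
import pytest

from aaapiv.hemodynamics import physiological_waveform
from aaapiv.loop import CompliantSegment, WindkesselParams, run_loop
from aaapiv.metrics import (
    M3S_TO_LMIN,
    PhaseEnsemble,
    config_difference,
    flow_balance,
    flow_rate_from_profile,
    phase_average,
    pressure_strain_modulus,
    rms_fluctuations,
    vorticity,
)
from aaapiv.piv import VectorField

SCALE = 24.6


def field_from_velocity(u_ms, v_ms=None, spacing=16.0, **kwargs):
    u_ms = np.asarray(u_ms, float)
    if v_ms is None:
        v_ms = np.zeros_like(u_ms)
    ny, nx = u_ms.shape
    dt = 4e-4
    return VectorField(
        x_px=np.arange(nx) * spacing + spacing,
        y_px=np.arange(ny) * spacing + spacing,
        u_px=np.asarray(u_ms) * SCALE * 1e3 * dt,
        v_px=np.asarray(v_ms) * SCALE * 1e3 * dt,
        snr=np.full((ny, nx), 10.0),
        in_domain=np.ones((ny, nx), bool),
        scale=SCALE,
        dt_s=dt,
        **kwargs,
    )


def ensemble_of(u_list):
    fields = [[field_from_velocity(u) for u in u_list]]
    return PhaseEnsemble(fields=fields, phase_times=np.array([0.0]))


class TestPhaseAverage:
    def test_identical_members_zero_sd(self):
        u = np.full((4, 5), 0.3)
        stats = phase_average(ensemble_of([u, u, u]))
        assert np.allclose(stats["u_mean"][0], 0.3)
        assert np.allclose(stats["u_sd"][0], 0.0)
        assert np.all(stats["count"][0] == 3)

    def test_plus_minus_one_gives_sample_sd_sqrt2(self):
        # two members at u = +1 and u = -1: mean 0, sd (ddof=1) = sqrt(2)
        up = np.ones((3, 3))
        stats = phase_average(ensemble_of([up, -up]))
        assert np.allclose(stats["u_mean"][0], 0.0)
        assert np.allclose(stats["u_sd"][0], np.sqrt(2.0))

    def test_invalid_member_decrements_count(self):
        u = np.full((4, 5), 0.2)
        fields = [field_from_velocity(u) for _ in range(3)]
        fields[1].valid[2, 2] = False
        stats = phase_average(
            PhaseEnsemble(fields=[fields], phase_times=np.array([0.0]))
        )
        assert stats["count"][0][2, 2] == 2
        assert stats["count"][0][0, 0] == 3

    def test_replaced_vectors_do_not_contribute(self):
        u = np.full((4, 5), 0.2)
        fields = [field_from_velocity(u) for _ in range(3)]
        fields[0].u_px[1, 1] = 99.0
        fields[0].replaced[1, 1] = True
        stats = phase_average(
            PhaseEnsemble(fields=[fields], phase_times=np.array([0.0]))
        )
        assert stats["u_mean"][0][1, 1] == pytest.approx(0.2)
        assert stats["count"][0][1, 1] == 2

    def test_single_cycle_rejected(self):
        with pytest.raises(ValueError):
            phase_average(ensemble_of([np.ones((3, 3))]))

    def test_permutation_invariant(self, rng):
        members = [rng.normal(0.2, 0.05, (4, 6)) for _ in range(5)]
        a = phase_average(ensemble_of(members))
        b = phase_average(ensemble_of(members[::-1]))
        assert np.allclose(a["u_mean"][0], b["u_mean"][0])
        assert np.allclose(a["u_sd"][0], b["u_sd"][0])


class TestRmsFluctuations:
    def test_three_four_five(self):
        # sd_x = 3 and sd_y = 4 (two-member ensembles) give u'_rms = 5
        base = np.zeros((3, 3))
        fields = [[
            field_from_velocity(base + 3 / np.sqrt(2), base + 4 / np.sqrt(2)),
            field_from_velocity(base - 3 / np.sqrt(2), base - 4 / np.sqrt(2)),
        ]]
        ens = PhaseEnsemble(fields=fields, phase_times=np.array([0.0]))
        assert np.allclose(rms_fluctuations(ens)[0], 5.0)

    def test_identical_members_zero(self):
        u = np.full((3, 3), 0.4)
        assert np.allclose(rms_fluctuations(ensemble_of([u, u]))[0], 0.0)

    def test_pure_x_fluctuation_equals_sdx(self):
        base = np.zeros((3, 3))
        fields = [[
            field_from_velocity(base + 0.1), field_from_velocity(base - 0.1),
        ]]
        ens = PhaseEnsemble(fields=fields, phase_times=np.array([0.0]))
        sd = 0.2 / np.sqrt(2)  # sample sd of {+0.1, -0.1}
        assert np.allclose(rms_fluctuations(ens)[0], sd)


class TestVorticity:
    def grid_mm(self, field):
        x = field.x_px / SCALE * 1e-3
        y = field.y_px / SCALE * 1e-3
        return np.meshgrid(x, y)

    def test_solid_body_rotation(self):
        omega = 30.0  # rad/s
        f = field_from_velocity(np.zeros((8, 8)))
        xx, yy = self.grid_mm(f)
        f.u_px = (-omega * yy) * SCALE * 1e3 * f.dt_s
        f.v_px = (omega * xx) * SCALE * 1e3 * f.dt_s
        w = vorticity(f)
        assert np.allclose(w, 2 * omega, rtol=1e-9)

    def test_uniform_field_zero(self):
        f = field_from_velocity(np.full((5, 6), 0.3))
        assert np.allclose(vorticity(f), 0.0, atol=1e-12)

    def test_linear_shear(self):
        k = 50.0  # 1/s
        f = field_from_velocity(np.zeros((8, 8)))
        _, yy = self.grid_mm(f)
        f.u_px = (k * yy) * SCALE * 1e3 * f.dt_s
        assert np.allclose(vorticity(f), -k, rtol=1e-9)

    def test_curl_free_field_within_truncation(self):
        # gradient of a smooth potential: analytic curl is zero; central
        # differences leave only discretization residue
        f = field_from_velocity(np.zeros((12, 12)))
        xx, yy = self.grid_mm(f)
        k = 2 * np.pi / 0.02
        # gradient of the potential cos(kx) cosh(ky): curl-free by identity
        u = -k * np.sin(k * xx) * np.cosh(k * yy)
        v = k * np.cos(k * xx) * np.sinh(k * yy)
        f.u_px = u * SCALE * 1e3 * f.dt_s
        f.v_px = v * SCALE * 1e3 * f.dt_s
        w = vorticity(f)
        scale_w = k * np.abs(u).max()
        assert np.abs(w[1:-1, 1:-1]).max() < 0.05 * scale_w  # truncation only

    def test_masked_points_propagate(self):
        f = field_from_velocity(np.full((5, 6), 0.3))
        f.valid[2, 3] = False
        w = vorticity(f)
        assert np.isnan(w[2, 3])

    def test_tiny_grid_rejected(self):
        f = field_from_velocity(np.ones((2, 2)))
        with pytest.raises(ValueError):
            vorticity(f)


class TestFlowRateFromProfile:
    R_MM = 10.0

    def profile_field(self, profile_fn):
        ny = 41
        spacing = 16.0
        y_px = np.arange(ny) * spacing
        axis = y_px.mean()
        r_mm = (y_px - axis) / SCALE
        u = np.tile(profile_fn(r_mm)[:, None], (1, 6))
        f = field_from_velocity(u, spacing=spacing)
        f.y_px = y_px
        f.x_px = np.arange(6) * spacing + 100.0  # band at ~8-12 mm
        return f, axis

    def test_parabolic_profile(self):
        u_c = 0.5
        f, axis = self.profile_field(
            lambda r: u_c * np.clip(1 - (r / self.R_MM) ** 2, 0, None)
        )
        q = flow_rate_from_profile(f, (3.0, 9.0), self.R_MM, axis_row_px=axis)
        expected = u_c * np.pi * (self.R_MM * 1e-3) ** 2 / 2
        assert q == pytest.approx(expected, rel=0.01)

    def test_uniform_profile(self):
        u0 = 0.3
        f, axis = self.profile_field(
            lambda r: np.where(np.abs(r) <= self.R_MM, u0, 0.0)
        )
        q = flow_rate_from_profile(f, (3.0, 9.0), self.R_MM, axis_row_px=axis)
        # top-hat: trapezoid + no-slip closure round the rim; ~R^2 pi u0
        assert q == pytest.approx(u0 * np.pi * (self.R_MM * 1e-3) ** 2, rel=0.05)

    def test_antisymmetric_profile_cancels_under_fold(self):
        # u = k r is antisymmetric across the axis; the symmetric fold
        # (average of the two half-profiles) cancels it exactly — an
        # antisymmetric residue signals a violated axisymmetry assumption
        # and carries no net axisymmetric flow
        k = 0.05  # (m/s) per mm
        f, axis = self.profile_field(lambda r: k * r)
        q = flow_rate_from_profile(f, (3.0, 9.0), self.R_MM, axis_row_px=axis)
        full_scale = 2 * np.pi * (k * 1e3) * (self.R_MM * 1e-3) ** 3 / 3
        assert abs(q) < 1e-3 * full_scale

    def test_band_outside_field_rejected(self):
        f, axis = self.profile_field(lambda r: np.ones_like(r))
        with pytest.raises(ValueError):
            flow_rate_from_profile(f, (50.0, 60.0), self.R_MM, axis_row_px=axis)

    def test_fully_masked_band_rejected(self):
        f, axis = self.profile_field(lambda r: np.ones_like(r))
        f.in_domain[:] = False
        with pytest.raises(ValueError):
            flow_rate_from_profile(f, (3.0, 9.0), self.R_MM, axis_row_px=axis)


class TestConfigDifference:
    def test_identical_fields_zero(self):
        a = field_from_velocity(np.full((4, 5), 0.25))
        b = field_from_velocity(np.full((4, 5), 0.25))
        diff, mx = config_difference(a, b)
        assert mx == 0.0
        assert np.allclose(diff, 0.0)

    def test_uniform_offset_detected(self):
        a = field_from_velocity(np.full((4, 5), 0.27))
        b = field_from_velocity(np.full((4, 5), 0.25))
        _, mx = config_difference(a, b)
        assert mx == pytest.approx(0.02, abs=1e-9)

    def test_invalid_points_propagate(self):
        a = field_from_velocity(np.full((4, 5), 0.5))
        b = field_from_velocity(np.full((4, 5), 0.25))
        a.valid[1, 1] = False
        diff, _ = config_difference(a, b)
        assert np.isnan(diff[1, 1])

    def test_grid_mismatch_rejected(self):
        a = field_from_velocity(np.ones((4, 5)))
        b = field_from_velocity(np.ones((4, 6)))
        with pytest.raises(ValueError):
            config_difference(a, b)


class TestFlowBalance:
    def test_rigid_simulation_balances(self):
        wave = physiological_waveform("FL")
        wk = WindkesselParams.from_case("FL")
        log = run_loop(wave, wk, n_cycles=4, seed=0,
                       seg=CompliantSegment(C_ph=0.0))
        _, mean, _ = flow_balance(log, 0.8, lowpass_hz=None)
        assert np.max(np.abs(mean)) < 1e-12

    def test_compliant_cycle_integral_near_zero(self):
        wave = physiological_waveform("FL")
        wk = WindkesselParams.from_case("FL")
        q_mean = float(np.mean(wave.flows))
        log = run_loop(wave, wk, n_cycles=18, seed=0,
                       seg=CompliantSegment(C_ph=2e-9),
                       pc0=wk.P0 + q_mean * wk.Rd)
        _, mean, _ = flow_balance(log, 0.8, lowpass_hz=None,
                                  last_fraction=0.15)
        net = np.trapezoid(mean, dx=1 / log.fs)
        assert abs(net) < 1e-3 * np.trapezoid(np.abs(wave.flows), wave.times)

    def test_length_mismatch_rejected(self):
        wave = physiological_waveform("FL")
        wk = WindkesselParams.from_case("FL")
        log = run_loop(wave, wk, n_cycles=2, seed=0)
        log.q_in = log.q_in[:-5]
        with pytest.raises(ValueError):
            flow_balance(log, 0.8)


class TestPressureStrainModulus:
    def test_forty_mmhg_two_percent(self):
        # dP = 5333 Pa at 2% strain: Ep = 2.67e5 N/m^2
        ep = pressure_strain_modulus(5333.0, 20.0, 0.4)
        assert ep == pytest.approx(5333.0 / 0.02)
        assert ep == pytest.approx(2.67e5, rel=2e-3)

    def test_round_trips_compliant_segment_strain(self):
        seg_ep = 3.1e5
        dp = 4000.0
        strain = dp / seg_ep
        assert pressure_strain_modulus(dp, 1.0, strain) == pytest.approx(seg_ep)

    def test_linear_in_pressure(self):
        a = pressure_strain_modulus(2000.0, 20.0, 0.2)
        b = pressure_strain_modulus(4000.0, 20.0, 0.2)
        assert b == pytest.approx(2 * a)

    def test_zero_strain_rejected(self):
        with pytest.raises(ValueError):
            pressure_strain_modulus(1000.0, 20.0, 0.0)


class TestUnits:
    def test_lmin_conversion_factor(self):
        assert 1e-3 * M3S_TO_LMIN == pytest.approx(60.0)  # 1 L/s = 60 L/min
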