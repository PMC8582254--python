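"""Quantum weight, 1PT family and the GSTA time-domain equivalence."""

import numpy as np
import pytest
from scipy.integrate import quad

from dostherm.constants import R_GAS, X_OVER_NU_T, beta_h_fs
from dostherm.correlation import Vdos, compute_vacf, compute_vdos
from dostherm.quantum import (
    anharmonic_correction,
    cv_1pt,
    cv_1pt_ac,
    cv_gsta,
    kernel_cv,
    quantum_correction_cv,
    weight_cv,
)

from conftest import exponential_vacf

T = 298.15


def single_mode_vdos(nu0=30.0, dnu=0.05, n=2048, temperature=T, f=1.0):
    freqs = np.arange(n + 1) * dnu
    density = np.zeros(n + 1)
    density[int(round(nu0 / dnu))] = 1.0 / dnu
    return Vdos(freqs, density, "trapezoid", temperature, f)


def einstein_function(nu, temperature=T, hbar_scale=1.0):
    """Scalar high-precision oracle: x^2 e^x / (e^x - 1)^2."""
    x = X_OVER_NU_T * hbar_scale * nu / temperature
    if x == 0:
        return 1.0
    return x * x * np.exp(-x) / np.expm1(-x) ** 2


class TestWeight:
    def test_zero_frequency_is_classical(self):
        assert weight_cv(0.0, T) == 1.0

    def test_oh_stretch_value(self):
        # 9.0 fs period -> 111.1 THz; deep quantum regime
        val = weight_cv(111.1, T)
        assert val == pytest.approx(einstein_function(111.1), rel=1e-12)
        assert val == pytest.approx(5.5e-6, rel=0.02)

    def test_hbar_zero_restores_unity(self):
        nus = np.array([0.0, 1.0, 50.0, 500.0])
        assert np.all(weight_cv(nus, T, hbar_scale=0.0) == 1.0)

    def test_monotone_decreasing_and_bounded(self):
        nus = np.linspace(0, 300, 4001)
        w = weight_cv(nus, T)
        assert np.all(np.diff(w) <= 0)
        assert np.all((w >= 0) & (w <= 1))

    def test_overflow_regime_smooth(self):
        # around the x=700 switch the two branches must agree
        nu_700 = 700.0 * T / X_OVER_NU_T
        lo = weight_cv(nu_700 * 0.999999, T)
        hi = weight_cv(nu_700 * 1.000001, T)
        assert hi == pytest.approx(lo, rel=1e-4)
        assert weight_cv(1e6, T) == 0.0

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            weight_cv(1.0, -5.0)
        with pytest.raises(ValueError):
            weight_cv(-1.0, T)


class TestCv1pt:
    def test_single_mode_is_einstein_heat_capacity(self):
        nu0 = 30.0
        s = single_mode_vdos(nu0)
        assert cv_1pt(s, 1.0, T) == pytest.approx(
            R_GAS * einstein_function(nu0), rel=1e-9
        )

    def test_classical_limit_is_fR(self):
        s = single_mode_vdos(30.0, f=6.0)
        val = cv_1pt(s, 6.0, T, hbar_scale=0.0)
        assert val == pytest.approx(6 * R_GAS, rel=1e-12)
        # 6R = 49.9 J/(mol K) to 3 significant figures
        assert round(val, 1) == 49.9

    def test_bounded_by_fR_on_battery(self, battery):
        for spec, traj, gt in battery:
            v = compute_vacf(traj, t_max=min(3000.0, traj.span / 2))
            s = compute_vdos(v)
            val = cv_1pt(s, gt.f, spec.temperature)
            assert 0 < val <= gt.f * R_GAS * (1 + 1e-9)

    def test_badly_normalized_vdos_renormalized_with_warning(self):
        s = single_mode_vdos(30.0)
        bad = Vdos(s.frequencies, s.density * 1.2, "trapezoid", T, 1.0)
        with pytest.warns(UserWarning, match="renormaliz"):
            val = cv_1pt(bad, 1.0, T)
        assert val == pytest.approx(cv_1pt(s, 1.0, T), rel=1e-9)


class TestQuantumCorrection:
    def test_classical_limit_vanishes(self):
        s = single_mode_vdos(30.0)
        assert quantum_correction_cv(s, 1.0, T, hbar_scale=0.0) == pytest.approx(
            0.0, abs=1e-12
        )

    def test_single_mode_scalar_oracle(self):
        nu0 = 60.0
        s = single_mode_vdos(nu0)
        assert quantum_correction_cv(s, 1.0, T) == pytest.approx(
            R_GAS * (einstein_function(nu0) - 1.0), rel=1e-9
        )

    def test_frozen_high_frequency_mode_gives_minus_R(self):
        nu0 = 150.0  # x ~ 24: mode frozen out, W ~ x^2 e^-x ~ 2e-8
        s = single_mode_vdos(nu0, n=4096)
        val = quantum_correction_cv(s, 1.0, T)
        assert val == pytest.approx(-R_GAS, abs=R_GAS * 1e-7)

    def test_always_nonpositive_and_equals_cv1pt_minus_fR(self, battery):
        for spec, traj, gt in battery:
            v = compute_vacf(traj, t_max=min(3000.0, traj.span / 2))
            s = compute_vdos(v)
            qc = quantum_correction_cv(s, gt.f, spec.temperature)
            assert qc <= 0
            assert qc == pytest.approx(
                cv_1pt(s, gt.f, spec.temperature) - gt.f * R_GAS, abs=1e-8
            )


class TestAnharmonicCorrection:
    def test_rigid_water_arithmetic(self):
        # experimental cv 74.5 J/(K mol) vs 6R: AC = 24.6 J/(K mol)
        assert anharmonic_correction(74.5, 6.0) == pytest.approx(24.6, abs=0.05)

    def test_harmonic_ensemble_has_zero_ac(self, battery):
        spec, traj, gt = battery[0]
        assert gt.cv_classical == pytest.approx(gt.f * R_GAS)
        assert anharmonic_correction(gt.cv_classical, gt.f) == pytest.approx(0.0)


class TestCv1ptAc:
    def test_hbar_zero_recovers_classical_exactly(self, battery):
        for spec, traj, gt in battery:
            v = compute_vacf(traj, t_max=min(3000.0, traj.span / 2))
            s = compute_vdos(v)
            val = cv_1pt_ac(gt.cv_classical, s, gt.f, spec.temperature, hbar_scale=0.0)
            assert val == pytest.approx(gt.cv_classical, abs=1e-9)

    def test_gas_dof_lower_1pt_ac_below_1pt(self, mixture_traj, mixture_spec):
        from dostherm.synthetic import ground_truth

        gt = ground_truth(mixture_spec)
        v = compute_vacf(mixture_traj, t_max=5000.0)
        s = compute_vdos(v)
        c1 = cv_1pt(s, gt.f, T)
        c1ac = cv_1pt_ac(gt.cv_classical, s, gt.f, T)
        # classical cv < fR because OU DOF contribute R/2 each
        assert gt.cv_classical < gt.f * R_GAS
        assert c1ac < c1

    def test_correspondence_monotone_in_hbar(self, mixture_traj, mixture_spec):
        from dostherm.synthetic import ground_truth

        gt = ground_truth(mixture_spec)
        v = compute_vacf(mixture_traj, t_max=5000.0)
        s = compute_vdos(v)
        devs = [
            abs(
                cv_1pt_ac(gt.cv_classical, s, gt.f, T, hbar_scale=h)
                - gt.cv_classical
            )
            for h in (0.1, 0.03, 0.01, 0.0)
        ]
        assert all(a >= b for a, b in zip(devs, devs[1:]))
        assert devs[-1] < 1e-9


class TestGsta:
    def test_kernel_matches_numerical_transform_of_weight(self):
        # mandatory oracle: gamma(t) = 4 int W(beta h nu) cos(2 pi nu t) dnu
        for t_fs in (0.0, 1.0, 5.0, 20.0, 68.0):
            num = 4e-3 * quad(
                lambda nu: weight_cv(nu, T) * np.cos(2 * np.pi * nu * t_fs * 1e-3),
                0,
                2000.0,
                limit=800,
            )[0]  # nu in THz, t in fs -> 1/fs needs the 1e-3
            assert kernel_cv(t_fs, T) == pytest.approx(num, rel=1e-7, abs=1e-12)

    def test_matches_frequency_domain_1pt(self, battery):
        for spec, traj, gt in battery:
            v = compute_vacf(traj, t_max=min(3000.0, traj.span / 2))
            s = compute_vdos(v)
            c_freq = cv_1pt(s, gt.f, spec.temperature)
            c_time = cv_gsta(v, gt.f, spec.temperature)
            assert abs(c_time - c_freq) <= 0.5

    def test_68_fs_truncation_converged(self):
        from dostherm.synthetic import generate, ground_truth, methanol_like

        spec = methanol_like(seed=9, n_frames=16384, dt=0.5)
        traj = generate(spec)
        v = compute_vacf(traj, t_max=4000.0)
        short = cv_gsta(v, spec.f, T, t_max=68.0)
        long = cv_gsta(v, spec.f, T, t_max=4000.0)
        assert short == pytest.approx(long, rel=0.01)

    def test_hbar_zero_kernel_degenerates_to_delta(self):
        v = exponential_vacf()
        assert cv_gsta(v, 3.0, T, hbar_scale=0.0) == pytest.approx(3 * R_GAS)

    def test_too_coarse_lag_spacing_rejected(self):
        v = exponential_vacf(dt_fs=20.0, t_max_fs=2000.0)  # beta h/20 ~ 8 fs at 298 K
        with pytest.raises(ValueError, match="spacing"):
            cv_gsta(v, 3.0, T)

    def test_kernel_scaled_truncation_tracks_temperature(self):
        # kernel decay time is beta h / (4 pi^2); at 2x T half the 298 K window
        bh298 = beta_h_fs(298.15)
        v = exponential_vacf(dt_fs=1.0, t_max_fs=2000.0, temperature=2 * 298.15)
        full = cv_gsta(v, 3.0, 2 * 298.15, t_max=2000.0)
        scaled = cv_gsta(v, 3.0, 2 * 298.15)  # default window = 68 fs * bh/bh298
        assert scaled == pytest.approx(full, rel=1e-3)
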