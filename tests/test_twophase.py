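"""Gas/solid VDOS decomposition, fluidity root, 2PT and 2PT+AC."""

import numpy as np
import pytest

from dostherm.constants import R_GAS
from dostherm.correlation import Vdos, compute_vacf, compute_vdos
from dostherm.quantum import cv_1pt, cv_1pt_ac
from dostherm.thermo import ThermoState
from dostherm.twophase import (
    cv_2pt,
    cv_2pt_ac,
    decompose,
    fluidity_from_diffusivity,
    fluidity_polynomial,
    normalized_diffusivity,
)

T = 298.15


def harmonic_only_vdos(f=6.0):
    """Pure solid: no zero-frequency density."""
    n, dnu = 2048, 0.05
    freqs = np.arange(n + 1) * dnu
    density = np.zeros(n + 1)
    density[int(30.0 / dnu)] = 1.0 / dnu
    return Vdos(freqs, density, "trapezoid", T, f)


@pytest.fixture(scope="module")
def ou_vdos(ou_traj, ou_spec):
    v = compute_vacf(ou_traj, t_max=10000.0)
    return compute_vdos(v)


class TestDecompose:
    def test_zero_s0_gives_pure_solid(self):
        s = harmonic_only_vdos()
        split = decompose(s, fluidity=0.7)
        assert split.gas_fraction == 0.0
        assert np.array_equal(split.solid_density, s.density)

    def test_partition_identity_pointwise(self, ou_vdos):
        split = decompose(ou_vdos, fluidity=0.8)
        resid = split.gas_density + split.solid_density - ou_vdos.density
        assert np.abs(resid).max() < 1e-12

    def test_gas_at_zero_equals_s0_and_solid_zero(self, ou_vdos):
        split = decompose(ou_vdos, fluidity=0.5)
        assert split.gas_density[0] == ou_vdos.density[0]
        assert split.solid_density[0] == 0.0

    def test_riemann_vdos_rejected(self, ou_traj):
        v = compute_vacf(ou_traj, t_max=5000.0)
        s = compute_vdos(v, rule="left_riemann")
        with pytest.raises(ValueError, match="trapezoid"):
            decompose(s, fluidity=0.5)

    def test_auto_without_state_rejected(self, ou_vdos):
        with pytest.raises(ValueError, match="ThermoState"):
            decompose(ou_vdos, fluidity="auto")

    def test_molecule_count_matters_for_polyatomics(self, mixture_traj):
        # using the atom count instead of the molecule count changes the split
        v = compute_vacf(mixture_traj, t_max=5000.0)
        s = compute_vdos(v)
        by_mol = decompose(s, n_molecules=1, fluidity=0.5)
        by_atom = decompose(s, n_molecules=3, fluidity=0.5)  # 3 atoms/molecule
        assert by_mol.gas_fraction != pytest.approx(by_atom.gas_fraction, rel=1e-3)
        assert cv_2pt(by_mol, s.dof_total, T) != pytest.approx(
            cv_2pt(by_atom, s.dof_total, T), rel=1e-4
        )


class TestFluidity:
    def test_root_unique_in_unit_interval(self):
        # sign-change count on a dense grid, several diffusivities
        grid = np.linspace(1e-6, 1.0, 10_000)
        for delta in (0.01, 0.1, 1.0, 10.0, 100.0):
            vals = np.array([fluidity_polynomial(fm, delta) for fm in grid])
            signs = np.sign(vals)
            changes = np.count_nonzero(np.diff(signs[signs != 0]))
            assert changes == 1
            root = fluidity_from_diffusivity(delta)
            assert 0 < root < 1
            assert fluidity_polynomial(root, delta) == pytest.approx(0.0, abs=1e-9)

    def test_bisection_oracle(self):
        # brute-force bisection, independent of brentq
        delta = 0.7
        lo, hi = 1e-12, 1.0
        for _ in range(60):
            mid = (lo + hi) / 2
            if fluidity_polynomial(mid, delta) < 0:
                lo = mid
            else:
                hi = mid
        assert fluidity_from_diffusivity(delta) == pytest.approx(lo, abs=1e-9)

    def test_fluidity_grows_with_diffusivity(self):
        roots = [fluidity_from_diffusivity(d) for d in (0.01, 0.1, 1.0, 10.0, 1e3)]
        assert all(a < b for a, b in zip(roots, roots[1:]))
        assert roots[-1] > 0.99  # gas-like limit

    def test_gas_fraction_approaches_one_for_large_diffusivity(self, ou_vdos):
        split = decompose(ou_vdos, fluidity=fluidity_from_diffusivity(1e4))
        assert split.gas_fraction > 0.95

    def test_auto_route_on_ou_system(self, ou_vdos, ou_spec):
        state = ThermoState(
            temperature=T,
            pressure=1.0,
            density=790.0,
            molar_mass=32.0,
            alpha_p=1.2e-3,
            kappa_T=1.2e-4,
        )
        split = decompose(ou_vdos, fluidity="auto", state=state)
        delta = normalized_diffusivity(
            float(ou_vdos.density[0]), ou_vdos.dof_total, T, 32.0, 790.0
        )
        assert split.fluidity == pytest.approx(fluidity_from_diffusivity(delta))
        assert 0 < split.fluidity < 1


class TestCv2pt:
    def test_no_gas_equals_1pt(self):
        s = harmonic_only_vdos(f=6.0)
        split = decompose(s, fluidity=0.9)
        assert cv_2pt(split, 6.0, T) == pytest.approx(cv_1pt(s, 6.0, T), rel=1e-12)

    def test_full_gas_classical_limit_is_half_fR(self, ou_vdos):
        split = decompose(ou_vdos, fluidity=1.0)
        val = cv_2pt(split, 3.0, T, hbar_scale=0.0)
        lo, hi = 3 * R_GAS / 2, 3 * R_GAS
        assert lo - 1e-9 <= val <= hi
        assert val == pytest.approx(lo, rel=0.02)  # nearly all mass is gas-like

    def test_classical_sandwich_for_every_split(self, battery):
        for spec, traj, gt in battery:
            v = compute_vacf(traj, t_max=min(3000.0, traj.span / 2))
            s = compute_vdos(v)
            for fm in (0.0, 0.3, 1.0):
                split = decompose(s, fluidity=fm)
                val = cv_2pt(split, gt.f, spec.temperature, hbar_scale=0.0)
                assert gt.f * R_GAS / 2 - 1e-9 <= val <= gt.f * R_GAS + 1e-9

    def test_2pt_never_exceeds_1pt(self, battery):
        for spec, traj, gt in battery:
            v = compute_vacf(traj, t_max=min(3000.0, traj.span / 2))
            s = compute_vdos(v)
            c1 = cv_1pt(s, gt.f, spec.temperature)
            for fm in (0.2, 0.6, 1.0):
                split = decompose(s, fluidity=fm)
                assert cv_2pt(split, gt.f, spec.temperature) <= c1 + 1e-9


class TestCv2ptAc:
    def test_hbar_zero_recovers_classical(self, battery):
        for spec, traj, gt in battery:
            v = compute_vacf(traj, t_max=min(3000.0, traj.span / 2))
            s = compute_vdos(v)
            split = decompose(s, fluidity=0.5)
            val = cv_2pt_ac(split, gt.cv_classical, gt.f, spec.temperature,
                            hbar_scale=0.0)
            assert val == pytest.approx(gt.cv_classical, abs=1e-9)

    def test_no_gas_equals_1pt_ac(self):
        s = harmonic_only_vdos(f=6.0)
        split = decompose(s, fluidity=0.9)
        cv_cl = 55.0
        assert cv_2pt_ac(split, cv_cl, 6.0, T) == pytest.approx(
            cv_1pt_ac(cv_cl, s, 6.0, T), rel=1e-9
        )

    def test_close_to_and_above_1pt_ac_on_battery(self, battery):
        for spec, traj, gt in battery:
            v = compute_vacf(traj, t_max=min(3000.0, traj.span / 2))
            s = compute_vdos(v)
            # a solid-like system (no diffusive DOF) gets a near-zero
            # fluidity, as the hard-sphere equation would dictate
            fm = 0.4 if gt.n_gas else 0.02
            split = decompose(s, fluidity=fm)
            a = cv_2pt_ac(split, gt.cv_classical, gt.f, spec.temperature)
            b = cv_1pt_ac(gt.cv_classical, s, gt.f, spec.temperature)
            assert a >= b - 1e-9  # gas weight is h-independent
            assert abs(a - b) < 0.5  # small difference, J/(mol K)
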