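"""Synthetic trajectories with analytically known thermodynamics.

Three generators cover the limiting motions of a liquid:

``harmonic_ensemble``
    Independent classical harmonic modes, exactly integrated sinusoids with
    canonical (exponential) energies, so equipartition holds at T, the VDOS
    is a weighted set of delta lines and the classical heat capacity is
    f R per mole.

``ou_gas``
    Ornstein-Uhlenbeck velocities (exact discrete update), emulating
    gas-like diffusive motion: VACF = exp(-t/tau), Lorentzian VDOS,
    classical heat capacity R/2 per DOF (kinetic only) and diffusivity
    D = kB T tau / m.

``mixture``
    Per molecule, the 3 center-of-mass DOF follow an OU process while the
    3(p-1) internal DOF are harmonic modes built on an orthonormal basis
    of the COM-free subspace; ground truth is additive.

Randomness comes from the counter-based Philox generator, so a fixed seed
gives bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import quad

from .constants import AMU_KG, K_BOLTZMANN, R_GAS, V2_THERMAL
from .quantum import weight_cv
from .trajectory import Topology, VelocityTrajectory

__all__ = ["SyntheticSpec", "GroundTruth", "generate", "ground_truth"]

KINDS = ("harmonic_ensemble", "ou_gas", "mixture")


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for a synthetic velocity trajectory."""

    kind: str
    n_molecules: int = 32
    atoms_per_molecule: int = 1
    frequencies: tuple = ()  # THz, harmonic modes
    weights: tuple = ()  # relative weights, normalized internally
    tau: float = 150.0  # fs, OU correlation time
    temperature: float = 298.15  # K
    dt: float = 1.0  # fs
    n_frames: int = 4096
    seed: int = 0
    mass: float = 10.0  # amu per atom

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ValueError(f"kind must be one of {KINDS}")
        if self.kind != "ou_gas" and len(self.frequencies) == 0:
            raise ValueError("harmonic systems need at least one frequency")
        if any(nu <= 0 for nu in self.frequencies):
            raise ValueError("frequencies must be positive")
        if self.tau <= 0 or self.dt <= 0 or self.temperature <= 0:
            raise ValueError("tau, dt and temperature must be positive")
        if self.kind == "mixture" and self.atoms_per_molecule < 2:
            raise ValueError("mixture needs >= 2 atoms per molecule")
        if self.weights and len(self.weights) != len(self.frequencies):
            raise ValueError("weights must match frequencies")
        # resolution guards
        if self.kind in ("ou_gas", "mixture") and self.dt > self.tau / 5:
            raise ValueError(
                f"dt={self.dt:g} fs too coarse for tau={self.tau:g} fs "
                "(need dt <= tau/5)"
            )
        if self.frequencies:
            period = 1e3 / max(self.frequencies)  # fs
            if self.kind != "ou_gas" and self.dt > period / 10:
                raise ValueError(
                    f"dt={self.dt:g} fs too coarse for the {max(self.frequencies):g} "
                    f"THz mode (need dt <= {period / 10:g} fs)"
                )

    @property
    def norm_weights(self) -> np.ndarray:
        w = np.asarray(self.weights if self.weights else [1.0] * len(self.frequencies))
        return w / w.sum()

    @property
    def f(self) -> float:
        """Degrees of freedom per molecule."""
        return 3.0 * self.atoms_per_molecule

    @property
    def molecular_mass(self) -> float:
        return self.mass * self.atoms_per_molecule


def _largest_remainder_counts(weights: np.ndarray, total: int) -> np.ndarray:
    """Deterministic integer apportionment of ``total`` DOF to the modes."""
    raw = weights * total
    counts = np.floor(raw).astype(int)
    short = total - counts.sum()
    order = np.argsort(-(raw - counts), kind="stable")
    counts[order[:short]] += 1
    return counts


def _mode_assignment(spec: SyntheticSpec, n_dof: int) -> np.ndarray:
    """Per-DOF mode frequencies (THz), apportioned by largest remainder."""
    counts = _largest_remainder_counts(spec.norm_weights, n_dof)
    return np.repeat(np.asarray(spec.frequencies, float), counts)


def _harmonic_series(rng, nus, times_fs, v2_scale):
    """Sinusoidal velocities for independent modes; shape (n_frames, n_dof).

    ``v2_scale`` is kB T / m in (nm/ps)^2; canonical energies are
    exponential, so the ensemble-mean squared velocity equals v2_scale.
    """
    n_dof = len(nus)
    energy = rng.exponential(1.0, size=n_dof)
    phase = rng.uniform(0.0, 2 * np.pi, size=n_dof)
    amp = np.sqrt(2.0 * energy * v2_scale)
    arg = 2 * np.pi * nus[None, :] * times_fs[:, None] * 1e-3 + phase[None, :]
    return amp[None, :] * np.cos(arg), amp, phase


def _harmonic_positions(nus, amp, phase, times_fs):
    """Exact positions of the sinusoidal modes, nm."""
    omega_ps = 2 * np.pi * nus  # rad/ps for nu in THz
    arg = 2 * np.pi * nus[None, :] * times_fs[:, None] * 1e-3 + phase[None, :]
    return (amp / omega_ps)[None, :] * np.sin(arg)


def _ou_series(rng, n_frames, n_dof, tau_fs, dt_fs, v2_scale):
    """Exact stationary OU velocity updates; shape (n_frames, n_dof)."""
    a = np.exp(-dt_fs / tau_fs)
    b = np.sqrt(v2_scale * (1.0 - a * a))
    v = np.empty((n_frames, n_dof))
    v[0] = rng.normal(0.0, np.sqrt(v2_scale), size=n_dof)
    noise = rng.normal(0.0, 1.0, size=(n_frames - 1, n_dof))
    for i in range(1, n_frames):
        v[i] = v[i - 1] * a + b * noise[i - 1]
    return v


def _midpoint_positions(v, dt_fs):
    """Midpoint-rule integration of velocities (nm/ps) to positions (nm)."""
    dt_ps = dt_fs * 1e-3
    x = np.zeros_like(v)
    x[1:] = np.cumsum((v[1:] + v[:-1]) * 0.5 * dt_ps, axis=0)
    return x


def _internal_basis(p: int) -> np.ndarray:
    """Orthonormal basis of the COM-free subspace of p equal-mass atoms,
    shape (p-1, p)."""
    a = np.eye(p) - np.full((p, p), 1.0 / p)
    q, _ = np.linalg.qr(a[:, : p - 1])
    return q.T


def generate(spec: SyntheticSpec) -> VelocityTrajectory:
    """Generate the trajectory described by ``spec`` (bit-reproducible)."""
    rng = np.random.Generator(np.random.Philox(spec.seed))
    times = np.arange(spec.n_frames) * spec.dt
    n_mol, p = spec.n_molecules, spec.atoms_per_molecule
    n_atoms = n_mol * p
    v2 = V2_THERMAL * spec.temperature / spec.mass  # per-atom kB T/m

    if spec.kind == "harmonic_ensemble":
        nus = _mode_assignment(spec, n_atoms * 3)
        vel_flat, amp, phase = _harmonic_series(rng, nus, times, v2)
        pos_flat = _harmonic_positions(nus, amp, phase, times)
    elif spec.kind == "ou_gas":
        vel_flat = _ou_series(rng, spec.n_frames, n_atoms * 3, spec.tau, spec.dt, v2)
        pos_flat = _midpoint_positions(vel_flat, spec.dt)
    else:  # mixture
        v2_com = V2_THERMAL * spec.temperature / spec.molecular_mass
        v_com = _ou_series(rng, spec.n_frames, n_mol * 3, spec.tau, spec.dt, v2_com)
        x_com = _midpoint_positions(v_com, spec.dt)
        n_internal = n_mol * 3 * (p - 1)
        nus = _mode_assignment(spec, n_internal)
        u, amp, phase = _harmonic_series(rng, nus, times, v2)
        xu = _harmonic_positions(nus, amp, phase, times)
        basis = _internal_basis(p)  # (p-1, p)
        # assemble per-atom arrays
        vel = np.zeros((spec.n_frames, n_atoms, 3))
        pos = np.zeros((spec.n_frames, n_atoms, 3))
        v_com = v_com.reshape(spec.n_frames, n_mol, 3)
        x_com = x_com.reshape(spec.n_frames, n_mol, 3)
        u = u.reshape(spec.n_frames, n_mol, 3, p - 1)
        xu = xu.reshape(spec.n_frames, n_mol, 3, p - 1)
        atom_view_v = vel.reshape(spec.n_frames, n_mol, p, 3)
        atom_view_x = pos.reshape(spec.n_frames, n_mol, p, 3)
        atom_view_v += v_com[:, :, None, :]
        atom_view_x += x_com[:, :, None, :]
        # internal mode k adds basis[k, a] * u_k along each axis
        atom_view_v += np.einsum("fmck,ka->fmac", u, basis)
        atom_view_x += np.einsum("fmck,ka->fmac", xu, basis)
        vel_flat = vel.reshape(spec.n_frames, -1)
        pos_flat = pos.reshape(spec.n_frames, -1)

    velocities = vel_flat.reshape(spec.n_frames, n_atoms, 3)
    positions = pos_flat.reshape(spec.n_frames, n_atoms, 3)
    return VelocityTrajectory(
        times=times,
        velocities=velocities,
        masses=np.full(n_atoms, spec.mass),
        molecule_index=np.repeat(np.arange(n_mol), p),
        temperature=spec.temperature,
        positions=positions,
    )


def topology_of(spec: SyntheticSpec) -> Topology:
    n_atoms = spec.n_molecules * spec.atoms_per_molecule
    return Topology(
        masses=np.full(n_atoms, spec.mass),
        molecule_index=np.repeat(np.arange(spec.n_molecules), spec.atoms_per_molecule),
    )


@dataclass(frozen=True)
class GroundTruth:
    """Closed-form references for a synthetic spec (molar, per molecule)."""

    f: float  # DOF per molecule
    n_harmonic: float  # harmonic DOF per molecule
    n_gas: float  # OU DOF per molecule
    mode_frequencies: np.ndarray  # THz
    mode_dof: np.ndarray  # DOF per molecule in each mode
    tau: float  # fs
    temperature: float
    molecular_mass: float  # amu

    @property
    def cv_classical(self) -> float:
        """Equipartition: R per harmonic DOF, R/2 per gas (kinetic-only) DOF."""
        return R_GAS * (self.n_harmonic + 0.5 * self.n_gas)

    def vacf(self, t_fs: np.ndarray) -> np.ndarray:
        """Analytic normalized mass-weighted VACF."""
        t = np.asarray(t_fs, float)
        c = np.zeros_like(t)
        for nu, n in zip(self.mode_frequencies, self.mode_dof):
            c += n * np.cos(2 * np.pi * nu * t * 1e-3)
        c += self.n_gas * np.exp(-t / self.tau)
        return c / self.f

    def vdos_gas(self, nu_thz: np.ndarray) -> np.ndarray:
        """Lorentzian VDOS of the OU part (unit norm per gas DOF), 1/THz."""
        tau_ps = self.tau * 1e-3
        return 4 * tau_ps / (1 + (2 * np.pi * np.asarray(nu_thz) * tau_ps) ** 2)

    def cv_1pt(self, hbar_scale: float = 1.0) -> float:
        """f R sum_i w_i W(nu_i) plus the quadrature over the OU Lorentzian."""
        total = sum(
            n * float(weight_cv(nu, self.temperature, hbar_scale))
            for nu, n in zip(self.mode_frequencies, self.mode_dof)
        )
        if self.n_gas:
            if hbar_scale == 0:
                total += self.n_gas
            else:
                val, _ = quad(
                    lambda nu: self.vdos_gas(nu)
                    * weight_cv(nu, self.temperature, hbar_scale),
                    0,
                    np.inf,
                    limit=400,
                )
                total += self.n_gas * val
        return R_GAS * total

    def quantum_correction(self, hbar_scale: float = 1.0) -> float:
        return self.cv_1pt(hbar_scale) - self.f * R_GAS

    def cv_1pt_ac(self, hbar_scale: float = 1.0) -> float:
        return self.cv_classical + self.quantum_correction(hbar_scale)

    @property
    def diffusivity(self) -> float | None:
        """COM self-diffusion D = kB T tau / M_mol in 1e-9 m^2/s (OU only)."""
        if self.n_gas == 0:
            return None
        d_si = (
            K_BOLTZMANN
            * self.temperature
            * self.tau
            * 1e-15
            / (self.molecular_mass * AMU_KG)
        )
        return d_si / 1e-9


def ground_truth(spec: SyntheticSpec) -> GroundTruth:
    """Analytic references for ``spec``; additive across components."""
    n_mol, p = spec.n_molecules, spec.atoms_per_molecule
    if spec.kind == "harmonic_ensemble":
        counts = _largest_remainder_counts(spec.norm_weights, n_mol * p * 3)
        n_harm, n_gas = 3.0 * p, 0.0
    elif spec.kind == "ou_gas":
        counts = np.zeros(len(spec.frequencies), dtype=float)
        n_harm, n_gas = 0.0, 3.0 * p
    else:
        counts = _largest_remainder_counts(spec.norm_weights, n_mol * 3 * (p - 1))
        n_harm, n_gas = 3.0 * (p - 1), 3.0
    return GroundTruth(
        f=3.0 * p,
        n_harmonic=n_harm,
        n_gas=n_gas,
        mode_frequencies=np.asarray(spec.frequencies, float),
        mode_dof=np.asarray(counts, float) / n_mol,
        tau=spec.tau,
        temperature=spec.temperature,
        molecular_mass=spec.molecular_mass,
    )


def methanol_like(seed: int = 0, n_frames: int = 16384, dt: float = 0.5) -> SyntheticSpec:
    """Six-atom molecules with modes at 3, 10, 30, 90 and 111 THz plus an OU
    translational block (tau = 150 fs): a qualitative stand-in for a
    hydrogen-bonded liquid's spectrum, used for convergence studies."""
    return SyntheticSpec(
        kind="mixture",
        n_molecules=24,
        atoms_per_molecule=6,
        frequencies=(3.0, 10.0, 30.0, 90.0, 111.1),
        weights=(0.3, 0.25, 0.2, 0.15, 0.1),
        tau=150.0,
        temperature=298.15,
        dt=dt,
        n_frames=n_frames,
        seed=seed,
        mass=5.34,  # 32 amu methanol / 6 atoms
    )
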