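"""Self-diffusion by the Green-Kubo (VACF integral) and Einstein (MSD) routes.

Both operate on per-molecule center-of-mass motion.  With the COM VACF
normalized to 1 at lag 0, the Green-Kubo coefficient is

    D = (kB T / M_mol) * int_0^tmax VACF_com(t) dt

(for an Ornstein-Uhlenbeck velocity with correlation time tau this is the
Langevin result kB T tau / M).  The Einstein estimator is the two-point
form D = [MSD(t2) - MSD(t1)] / (6 (t2 - t1)), origin-averaged, with the
8/12 ps defaults customary for liquids; a least-squares fit over a lag
window is available behind a flag.  The left-Riemann option reproduces the
inflated Green-Kubo estimator: at sampling interval dt it exceeds the
trapezoid value by exactly (kB T / M) dt (1 - VACF(tmax)) / 2.

Output unit: 1e-9 m^2/s.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .constants import AMU_KG, K_BOLTZMANN
from .correlation import _batched_acf, integrate
from .trajectory import VelocityTrajectory

__all__ = [
    "DiffusionResult",
    "RegimeWarning",
    "com_velocities",
    "com_positions",
    "com_vacf",
    "diffusion_green_kubo",
    "diffusion_einstein",
]


class RegimeWarning(UserWarning):
    """MSD window appears ballistic rather than diffusive."""


def _com_reduce(per_atom: np.ndarray, traj: VelocityTrajectory):
    """Mass-weighted molecule average of a per-atom frame array."""
    n_mol = traj.n_molecules
    mol_mass = np.bincount(traj.molecule_index, weights=traj.masses, minlength=n_mol)
    out = np.zeros((per_atom.shape[0], n_mol, 3))
    for c in range(3):
        w = per_atom[:, :, c] * traj.masses
        for m in range(n_mol):
            sel = traj.molecule_index == m
            out[:, m, c] = w[:, sel].sum(axis=1) / mol_mass[m]
    return out, mol_mass


def com_velocities(traj: VelocityTrajectory):
    """Per-molecule center-of-mass velocities (n_frames, n_mol, 3), nm/ps."""
    return _com_reduce(traj.velocities, traj)


def com_positions(traj: VelocityTrajectory):
    """Per-molecule center-of-mass positions (n_frames, n_mol, 3), nm."""
    if traj.positions is None:
        raise ValueError("trajectory carries no positions")
    return _com_reduce(traj.positions, traj)


def com_vacf(traj: VelocityTrajectory, t_max: float):
    """Normalized mass-weighted COM VACF up to lag ``t_max`` (fs)."""
    vel, mol_mass = com_velocities(traj)
    dt = traj.dt
    max_allowed = traj.span / 2
    if t_max > max_allowed + 1e-9:
        raise ValueError(
            f"t_max={t_max:g} fs exceeds half the trajectory span "
            f"({max_allowed:g} fs)"
        )
    n_lags = int(round(t_max / dt)) + 1
    flat = vel.reshape(traj.n_frames, -1)
    weights = np.repeat(mol_mass, 3)
    raw = _batched_acf(flat, weights, n_lags)
    if raw[0] == 0:
        raise ValueError("zero center-of-mass kinetic energy; VACF undefined")
    c = raw / raw[0]
    c[0] = 1.0
    return np.arange(n_lags) * dt, c, mol_mass


@dataclass(frozen=True)
class DiffusionResult:
    """Self-diffusion coefficients from both routes, 1e-9 m^2/s."""

    D_green_kubo: float | None
    D_einstein: float | None
    lag_used: float  # ps
    rule: str
    uncertainty: float | None = None

    @property
    def relative_disagreement(self) -> float | None:
        if not self.D_green_kubo or self.D_einstein is None:
            return None
        return abs(self.D_green_kubo - self.D_einstein) / abs(self.D_green_kubo)


def diffusion_green_kubo(
    traj: VelocityTrajectory,
    t_max: float = 10.0,
    rule: str = "trapezoid",
) -> float:
    """Green-Kubo self-diffusion coefficient in 1e-9 m^2/s.

    ``t_max`` is the VACF truncation lag in ps (10 ps default).  The COM
    VACF is normalized at lag 0, so the prefactor is kB T / M_mol with
    M_mol the (mean) molecular mass.
    """
    if not np.any(traj.velocities):
        return 0.0  # static system does not diffuse
    t_max_fs = t_max * 1e3
    lags, c, mol_mass = com_vacf(traj, t_max_fs)
    m_kg = float(mol_mass.mean()) * AMU_KG
    dt_s = traj.dt * 1e-15
    integral_s = integrate(c, dt_s, rule)
    d_si = K_BOLTZMANN * traj.temperature / m_kg * integral_s  # m^2/s
    return d_si / 1e-9


def diffusion_einstein(
    positions: np.ndarray,
    times: np.ndarray,
    t1: float = 8.0,
    t2: float = 12.0,
    box: float | None = None,
    fit: bool = False,
) -> float:
    """Einstein self-diffusion coefficient in 1e-9 m^2/s.

    Parameters
    ----------
    positions
        Unwrapped per-molecule COM track, (n_frames, n_mol, 3) in nm.
    times
        Frame times in fs.
    t1, t2
        MSD evaluation lags in ps; the two-point estimator
        [MSD(t2) - MSD(t1)] / (6 (t2 - t1)) is the default route.
    box
        Optional box edge in nm; single-step displacements beyond box/2
        indicate wrapped coordinates and raise.
    fit
        If True, least-squares fit MSD over [t1, t2] instead of the
        two-point form.
    """
    positions = np.asarray(positions, dtype=float)
    times = np.asarray(times, dtype=float)
    dt = times[1] - times[0]
    if box is not None:
        step = np.abs(np.diff(positions, axis=0))
        if np.any(step > box / 2):
            raise ValueError(
                "single-step displacement exceeds box/2: coordinates look "
                "wrapped; unwrap the trajectory first"
            )
    if t2 <= t1:
        raise ValueError("t2 must exceed t1")
    k1 = int(round(t1 * 1e3 / dt))
    k2 = int(round(t2 * 1e3 / dt))
    if k2 >= len(times):
        raise ValueError(f"t2={t2:g} ps beyond trajectory span")

    def msd(k: int) -> float:
        d = positions[k:] - positions[:-k]
        return float((d**2).sum(axis=2).mean())

    if fit:
        ks = np.unique(np.linspace(k1, k2, 25).astype(int))
        msds = np.array([msd(k) for k in ks])
        slope = np.polyfit(ks * dt, msds, 1)[0]  # nm^2/fs
        d_unit = slope / 6.0 * 1e3  # nm^2/ps
    else:
        m1, m2 = msd(k1), msd(k2)
        ratio = m2 / m1 if m1 > 0 else np.inf
        if ratio > 0.9 * (k2 / k1) ** 2:
            warnings.warn(
                "MSD grows ~quadratically over the window: ballistic regime, "
                "two-point Einstein estimator unreliable",
                RegimeWarning,
                stacklevel=2,
            )
        d_unit = (m2 - m1) / (6.0 * (k2 - k1) * dt) * 1e3  # nm^2/ps
    return d_unit * 1e3  # nm^2/ps = 1e-6 m^2/s = 1e3 * 1e-9 m^2/s


def diffusion_both(
    traj: VelocityTrajectory,
    t_max: float = 10.0,
    t1: float = 8.0,
    t2: float = 12.0,
    rule: str = "trapezoid",
) -> DiffusionResult:
    """Run both routes on one trajectory and record their disagreement."""
    d_gk = diffusion_green_kubo(traj, t_max=t_max, rule=rule)
    d_e = None
    if traj.positions is not None and t2 * 1e3 < traj.span:
        pos, _ = com_positions(traj)
        d_e = diffusion_einstein(pos, traj.times, t1=t1, t2=t2)
    return DiffusionResult(
        D_green_kubo=d_gk, D_einstein=d_e, lag_used=t_max, rule=rule
    )
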