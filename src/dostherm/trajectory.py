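"""Velocity-trajectory and enthalpy-series containers plus file readers/writers.

Supported trajectory formats: GROMACS TRR (through MDAnalysis, velocities
required) and extended XYZ carrying a velocity triple per atom.  Atom masses
and molecule membership come from a sidecar topology table (TSV with columns
``atom_id``, ``mass_amu``, ``molecule_id``) rather than from chemical topology
files, so no force-field parsing is involved.

Internal units: times fs, velocities nm/ps, positions nm, masses amu.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "VelocityTrajectory",
    "EnthalpySeries",
    "Topology",
    "read_topology",
    "write_topology",
    "read_trajectory",
    "write_trajectory",
    "read_enthalpy",
    "write_enthalpy",
]

_TIME_RTOL = 1e-6


@dataclass(frozen=True)
class Topology:
    """Per-atom masses (amu) and molecule membership."""

    masses: np.ndarray
    molecule_index: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "masses", np.asarray(self.masses, dtype=float))
        object.__setattr__(
            self, "molecule_index", np.asarray(self.molecule_index, dtype=int)
        )
        if self.masses.shape != self.molecule_index.shape:
            raise ValueError("masses and molecule_index must have equal length")
        if np.any(self.masses <= 0):
            raise ValueError("every atom must have mass > 0")
        uniq = np.unique(self.molecule_index)
        if not np.array_equal(uniq, np.arange(len(uniq))):
            raise ValueError("molecule_index must form a contiguous 0..n-1 set")

    @property
    def n_molecules(self) -> int:
        return int(self.molecule_index.max()) + 1


@dataclass(frozen=True)
class VelocityTrajectory:
    """Uniformly sampled atomic velocities with masses and molecule map.

    Parameters
    ----------
    times
        Frame times in fs, strictly increasing with constant step.
    velocities
        Array of shape ``(n_frames, n_atoms, 3)`` in nm/ps.
    masses
        Per-atom masses in amu.
    molecule_index
        Per-atom molecule id, contiguous ``0..n_molecules-1``.
    temperature
        Simulation temperature in K.
    dof_per_molecule
        Degrees of freedom per molecule; defaults to ``3 * atoms_per_molecule``
        and is reduced by declared bond constraints.
    positions
        Optional unwrapped positions in nm, same shape as ``velocities``.
    """

    times: np.ndarray
    velocities: np.ndarray
    masses: np.ndarray
    molecule_index: np.ndarray
    temperature: float
    dof_per_molecule: float | None = None
    positions: np.ndarray | None = None

    def __post_init__(self):
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "velocities", np.asarray(self.velocities, dtype=float))
        object.__setattr__(self, "masses", np.asarray(self.masses, dtype=float))
        object.__setattr__(
            self, "molecule_index", np.asarray(self.molecule_index, dtype=int)
        )
        t = self.times
        if t.ndim != 1 or len(t) < 2:
            raise ValueError("need at least 2 frames")
        steps = np.diff(t)
        if np.any(steps <= 0):
            raise ValueError("times must be strictly increasing")
        dt = steps[0]
        bad = np.nonzero(np.abs(steps - dt) > _TIME_RTOL * dt)[0]
        if bad.size:
            raise ValueError(
                f"non-uniform time step at frame {bad[0] + 1}: "
                f"step {steps[bad[0]]:g} fs vs {dt:g} fs"
            )
        if self.velocities.shape != (len(t), len(self.masses), 3):
            raise ValueError("velocities must have shape (n_frames, n_atoms, 3)")
        if np.any(self.masses <= 0):
            raise ValueError("every atom must have mass > 0")
        uniq = np.unique(self.molecule_index)
        if not np.array_equal(uniq, np.arange(len(uniq))):
            raise ValueError("molecule_index must form a contiguous 0..n-1 set")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.dof_per_molecule is None:
            per_mol = len(self.masses) / self.n_molecules
            object.__setattr__(self, "dof_per_molecule", 3.0 * per_mol)
        if self.dof_per_molecule < 3:
            raise ValueError("dof_per_molecule must be >= 3")
        if self.positions is not None:
            pos = np.asarray(self.positions, dtype=float)
            if pos.shape != self.velocities.shape:
                raise ValueError("positions must match velocities in shape")
            object.__setattr__(self, "positions", pos)

    @property
    def dt(self) -> float:
        """Sampling interval in fs."""
        return float(self.times[1] - self.times[0])

    @property
    def n_frames(self) -> int:
        return len(self.times)

    @property
    def n_atoms(self) -> int:
        return len(self.masses)

    @property
    def n_molecules(self) -> int:
        return int(self.molecule_index.max()) + 1

    @property
    def span(self) -> float:
        """Total trajectory length in fs."""
        return float(self.times[-1] - self.times[0])


@dataclass(frozen=True)
class EnthalpySeries:
    """Enthalpy time series for the fluctuation heat capacity.

    ``enthalpy`` holds the total system enthalpy expressed in kJ/mol
    (i.e. H * N_A); ``n_molecules`` is the number of molecules it covers.
    """

    times: np.ndarray
    enthalpy: np.ndarray
    n_molecules: int
    temperature: float

    def __post_init__(self):
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "enthalpy", np.asarray(self.enthalpy, dtype=float))
        if len(self.enthalpy) < 2:
            raise ValueError("enthalpy series needs at least 2 frames")
        bad = np.nonzero(~np.isfinite(self.enthalpy))[0]
        if bad.size:
            raise ValueError(f"non-finite enthalpy at rows {bad[:10].tolist()}")
        if self.temperature <= 0 or self.n_molecules < 1:
            raise ValueError("temperature and n_molecules must be positive")


# ---------------------------------------------------------------------------
# topology sidecar


def read_topology(path: str | Path) -> Topology:
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"atom_id", "mass_amu", "molecule_id"}
    if not required.issubset(df.columns):
        raise ValueError(f"topology table needs columns {sorted(required)}")
    df = df.sort_values("atom_id")
    return Topology(df["mass_amu"].to_numpy(), df["molecule_id"].to_numpy())


def write_topology(top: Topology, path: str | Path) -> None:
    pd.DataFrame(
        {
            "atom_id": np.arange(len(top.masses)),
            "mass_amu": top.masses,
            "molecule_id": top.molecule_index,
        }
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# extended XYZ with velocities
#
# Dialect: comment line carries Properties=species:S:1:pos:R:3:vel:R:3 and
# Time=<fs>; positions in nm, velocities in nm/ps.


def _read_extxyz(path: Path):
    times, frames_v, frames_x = [], [], []
    with open(path) as fh:
        while True:
            line = fh.readline()
            if not line.strip():
                break
            nat = int(line)
            comment = fh.readline()
            if "vel" not in comment:
                raise ValueError(
                    f"{path}: no velocities in extended-XYZ Properties; "
                    "positions alone cannot be analyzed"
                )
            time_fs = 0.0
            for tok in comment.split():
                if tok.startswith("Time="):
                    time_fs = float(tok.split("=")[1])
            vel, pos = [], []
            for _ in range(nat):
                parts = fh.readline().split()
                pos.append([float(p) for p in parts[1:4]])
                vel.append([float(p) for p in parts[4:7]])
            times.append(time_fs)
            frames_v.append(vel)
            frames_x.append(pos)
    if len(times) < 2:
        raise ValueError(f"{path}: fewer than 2 frames")
    return np.array(times), np.array(frames_v), np.array(frames_x)


def _write_extxyz(traj: VelocityTrajectory, path: Path) -> None:
    pos = traj.positions
    if pos is None:
        pos = np.zeros_like(traj.velocities)
    with open(path, "w") as fh:
        for i, t in enumerate(traj.times):
            fh.write(f"{traj.n_atoms}\n")
            fh.write(
                'Properties=species:S:1:pos:R:3:vel:R:3 units="nm nm/ps" '
                f"Time={t:.6f}\n"
            )
            for a in range(traj.n_atoms):
                x, y, z = pos[i, a]
                vx, vy, vz = traj.velocities[i, a]
                fh.write(
                    f"X {x:.12g} {y:.12g} {z:.12g} "
                    f"{vx:.12g} {vy:.12g} {vz:.12g}\n"
                )


# ---------------------------------------------------------------------------
# GROMACS TRR via MDAnalysis (base units A, ps, A/ps)


def _read_trr(path: Path, n_atoms: int):
    import MDAnalysis as mda

    u = mda.Universe.empty(n_atoms, trajectory=True)
    # convert_units=False keeps TRR's native nm / ps / nm/ps — no lossy
    # round trip through Angstroms
    u.load_new(str(path), format="TRR", convert_units=False)
    times, vels, poss = [], [], []
    has_pos = True
    for ts in u.trajectory:
        if not ts.has_velocities:
            raise ValueError(f"{path}: no velocities stored in TRR frame {ts.frame}")
        times.append(ts.time * 1e3)  # ps -> fs
        vels.append(ts.velocities.copy())  # nm/ps
        if ts.has_positions:
            poss.append(ts.positions.copy())  # nm
        else:
            has_pos = False
    if len(times) < 2:
        raise ValueError(f"{path}: fewer than 2 frames")
    pos = np.array(poss) if has_pos and poss else None
    times = np.array(times)
    # TRR stores time as float32; snap to the uniform grid when the jitter
    # is within storage precision, so genuinely non-uniform data still fails
    dt_est = (times[-1] - times[0]) / (len(times) - 1)
    grid = times[0] + np.arange(len(times)) * dt_est
    tol = 4 * np.finfo(np.float32).eps * max(abs(times[-1]), dt_est)
    if np.abs(times - grid).max() <= tol:
        times = grid
    return times, np.array(vels), pos


def _write_trr(traj: VelocityTrajectory, path: Path) -> None:
    # the low-level xdr interface takes native GROMACS units (nm, ps)
    # directly, so the stored float32 values match our arrays exactly
    from MDAnalysis.lib.formats.libmdaxdr import TRRFile

    pos = traj.positions
    if pos is None:
        pos = np.zeros_like(traj.velocities)
    box = np.diag([1e3, 1e3, 1e3]).astype(np.float32)  # unbounded synthetic box
    with TRRFile(str(path), "w") as fh:
        for i in range(traj.n_frames):
            fh.write(
                pos[i].astype(np.float32),
                traj.velocities[i].astype(np.float32),
                None,
                box,
                i,
                float(traj.times[i] / 1e3),  # fs -> ps
                0.0,
                traj.n_atoms,
            )


# ---------------------------------------------------------------------------
# public API


def read_trajectory(
    path: str | Path,
    topology: Topology | str | Path,
    temperature: float,
    constraints_per_molecule: int = 0,
) -> VelocityTrajectory:
    """Read a TRR or extended-XYZ velocity trajectory.

    ``constraints_per_molecule`` lowers ``dof_per_molecule`` below the
    unconstrained ``3 * atoms_per_molecule`` (e.g. 3 for a rigid triatomic's
    bond/angle constraints).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if isinstance(topology, (str, Path)):
        topology = read_topology(topology)
    suffix = path.suffix.lower()
    if suffix == ".trr":
        times, vel, pos = _read_trr(path, len(topology.masses))
    elif suffix in (".xyz", ".extxyz"):
        times, vel, pos = _read_extxyz(path)
    else:
        raise ValueError(f"unsupported trajectory format: {suffix}")
    per_mol = len(topology.masses) / topology.n_molecules
    dof = 3.0 * per_mol - constraints_per_molecule
    return VelocityTrajectory(
        times=times,
        velocities=vel,
        masses=topology.masses,
        molecule_index=topology.molecule_index,
        temperature=temperature,
        dof_per_molecule=dof,
        positions=pos,
    )


def write_trajectory(traj: VelocityTrajectory, path: str | Path) -> None:
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".trr":
        _write_trr(traj, path)
    elif suffix in (".xyz", ".extxyz"):
        _write_extxyz(traj, path)
    else:
        raise ValueError(f"unsupported trajectory format: {suffix}")


def read_enthalpy(
    path: str | Path, n_molecules: int = 1, temperature: float = 298.15
) -> EnthalpySeries:
    """Read a two-column (time/ps, enthalpy/(kJ/mol)) text series."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        data = np.loadtxt(path, comments=("#", "@"), ndmin=2)
    except Exception as exc:
        raise ValueError(f"{path}: cannot parse enthalpy series ({exc})") from exc
    if data.size == 0 or data.shape[0] < 2:
        raise ValueError(f"{path}: enthalpy series needs at least 2 rows")
    if data.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (time, enthalpy)")
    times, h = data[:, 0], data[:, 1]
    bad = np.nonzero(~np.isfinite(h))[0]
    if bad.size:
        raise ValueError(f"{path}: NaN/inf enthalpy at rows {bad[:10].tolist()}")
    return EnthalpySeries(times, h, n_molecules=n_molecules, temperature=temperature)


def write_enthalpy(series: EnthalpySeries, path: str | Path) -> None:
    np.savetxt(
        path,
        np.column_stack([series.times, series.enthalpy]),
        header="time_ps enthalpy_kJ_per_mol",
        fmt="%.12g",
    )
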