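"""Classical heat capacity from enthalpy fluctuations and cp/cv conversion.

In the NpT ensemble the classical isobaric heat capacity follows from the
variance of the enthalpy, Cp = Var(H) / (kB T^2); per mole of molecules and
with H recorded in kJ/mol of the whole system this becomes

    cp_cl = Var(H) / (R T^2 N_mol)       [J/(mol K)]

The isochoric value follows via the thermodynamic identity

    cp - cv = T alpha_p^2 M / (rho kappa_T)

with alpha_p the isobaric thermal expansion coefficient, kappa_T the
isothermal compressibility, M the molar mass and rho the mass density.  For
an ideal gas (alpha_p = 1/T, kappa_T = 1/p, M/rho = RT/p) the identity
returns exactly R.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass

import numpy as np

from .constants import R_GAS
from .correlation import Vacf, Vdos
from .quantum import (
    anharmonic_correction,
    cv_1pt,
    cv_1pt_ac,
    cv_gsta,
    quantum_correction_cv,
)
from .trajectory import EnthalpySeries
from .twophase import TwoPhaseSplit, cv_2pt, cv_2pt_ac

__all__ = [
    "ThermoState",
    "CpEstimate",
    "HeatCapacityReport",
    "cp_classical_fluctuation",
    "cp_minus_cv",
    "assemble_report",
]


@dataclass(frozen=True)
class ThermoState:
    """Thermodynamic state point for the isobaric/isochoric conversion."""

    temperature: float  # K
    pressure: float  # bar
    density: float  # kg/m^3
    molar_mass: float  # g/mol
    alpha_p: float  # 1/K
    kappa_T: float  # 1/bar

    def __post_init__(self):
        for name in ("temperature", "pressure", "density", "molar_mass", "kappa_T"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.alpha_p < 0:
            raise ValueError("alpha_p must be non-negative")

    @classmethod
    def ideal_gas(cls, temperature: float, pressure: float, molar_mass: float):
        """State of an ideal gas: alpha_p = 1/T, kappa_T = 1/p, rho = pM/RT."""
        rho = pressure * 1e5 * molar_mass * 1e-3 / (R_GAS * temperature)
        return cls(
            temperature=temperature,
            pressure=pressure,
            density=rho,
            molar_mass=molar_mass,
            alpha_p=1.0 / temperature,
            kappa_T=1.0 / pressure,
        )


@dataclass(frozen=True)
class CpEstimate:
    """Fluctuation estimate of the classical isobaric heat capacity."""

    value: float  # J/(mol K)
    stderr: float  # block-averaging standard error, J/(mol K)


def cp_classical_fluctuation(series: EnthalpySeries, n_blocks: int = 5) -> CpEstimate:
    """Classical cp from enthalpy fluctuations, Var(H)/(R T^2 N_mol).

    ``series.enthalpy`` must be in kJ/mol for the whole simulated system.
    Uncertainty comes from block averaging over ``n_blocks`` contiguous
    blocks.
    """
    h = series.enthalpy
    if len(h) < 100:
        raise ValueError("need >= 100 frames for a meaningful variance")
    denom = R_GAS * series.temperature**2 * series.n_molecules
    var = h.var(ddof=1) * 1e6  # (kJ/mol)^2 -> (J/mol)^2
    if var == 0.0:
        warnings.warn("enthalpy series has zero variance; cp = 0", stacklevel=2)
        return CpEstimate(0.0, 0.0)
    value = var / denom
    blen = len(h) // n_blocks
    block_vals = np.array(
        [h[i * blen : (i + 1) * blen].var(ddof=1) * 1e6 / denom for i in range(n_blocks)]
    )
    stderr = float(block_vals.std(ddof=1) / np.sqrt(n_blocks))
    return CpEstimate(float(value), stderr)


def cp_minus_cv(state: ThermoState) -> float:
    """cp - cv = T alpha_p^2 M / (rho kappa_T), J/(mol K); strictly positive
    for alpha_p > 0."""
    vm = state.molar_mass * 1e-3 / state.density  # m^3/mol
    kappa_pa = state.kappa_T / 1e5  # 1/bar -> 1/Pa
    return state.temperature * state.alpha_p**2 * vm / kappa_pa


@dataclass(frozen=True)
class HeatCapacityReport:
    """All heat-capacity variants for one system, J/(mol K)."""

    f: float
    temperature: float
    cv_1pt: float
    cv_quantum_correction: float
    cv_classical: float | None = None
    anharmonic_correction: float | None = None
    cv_1pt_ac: float | None = None
    cv_2pt: float | None = None
    cv_2pt_ac: float | None = None
    cv_gsta: float | None = None
    cp_minus_cv: float | None = None
    cp_classical: float | None = None
    cp_1pt: float | None = None
    cp_2pt: float | None = None
    cp_1pt_ac: float | None = None
    cp_2pt_ac: float | None = None

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("quantity\tvalue_J_per_mol_K\n")
            for k, v in asdict(self).items():
                if v is not None:
                    fh.write(f"{k}\t{v:.6g}\n")


def assemble_report(
    vdos: Vdos,
    f: float,
    temperature: float,
    vacf: Vacf | None = None,
    split: TwoPhaseSplit | None = None,
    cv_classical: float | None = None,
    cp_classical: float | None = None,
    state: ThermoState | None = None,
    hbar_scale: float = 1.0,
) -> HeatCapacityReport:
    """Compute every requested heat-capacity variant consistently.

    ``cp_classical`` may be supplied directly (fluctuation route) or is
    derived as ``cv_classical + (cp - cv)`` when a state is given; if both
    are available their consistency is asserted.  Temperatures of the VDOS,
    the state and the request must agree.
    """
    for obj, name in ((vdos, "vdos"), (vacf, "vacf"), (split, "split")):
        if obj is not None and abs(obj.temperature - temperature) > 1e-6:
            raise ValueError(
                f"{name} temperature {obj.temperature} K != requested {temperature} K"
            )
    if state is not None and abs(state.temperature - temperature) > 1e-6:
        raise ValueError("ThermoState temperature inconsistent with request")

    c1 = cv_1pt(vdos, f, temperature, hbar_scale)
    cq = quantum_correction_cv(vdos, f, temperature, hbar_scale)
    ac = c1ac = c2 = c2ac = cgsta = None
    dcp = cpcl = cp1 = cp2 = cp1ac = cp2ac = None

    if cv_classical is not None:
        ac = anharmonic_correction(cv_classical, f)
        c1ac = cv_1pt_ac(cv_classical, vdos, f, temperature, hbar_scale)
    if split is not None:
        c2 = cv_2pt(split, f, temperature, hbar_scale)
        if cv_classical is not None:
            c2ac = cv_2pt_ac(split, cv_classical, f, temperature, hbar_scale)
    if vacf is not None:
        cgsta = cv_gsta(vacf, f, temperature, hbar_scale=hbar_scale)

    if state is not None:
        dcp = cp_minus_cv(state)
        cp1 = c1 + dcp
        if c2 is not None:
            cp2 = c2 + dcp
        derived_cp_cl = None
        if cv_classical is not None:
            derived_cp_cl = cv_classical + dcp
        if cp_classical is None:
            cp_classical = derived_cp_cl
        elif derived_cp_cl is not None and abs(cp_classical - derived_cp_cl) > 1e-6:
            warnings.warn(
                f"supplied cp_classical {cp_classical:.4f} differs from "
                f"cv_classical + (cp-cv) = {derived_cp_cl:.4f}",
                stacklevel=2,
            )
        cpcl = cp_classical
        if cpcl is not None:
            cp1ac = cpcl + cq  # classical isobaric + quantum correction
            if split is not None:
                c2corr = cv_2pt_ac(split, 0.0, f, temperature, hbar_scale)
                cp2ac = cpcl + c2corr

    return HeatCapacityReport(
        f=f,
        temperature=temperature,
        cv_1pt=c1,
        cv_quantum_correction=cq,
        cv_classical=cv_classical,
        anharmonic_correction=ac,
        cv_1pt_ac=c1ac,
        cv_2pt=c2,
        cv_2pt_ac=c2ac,
        cv_gsta=cgsta,
        cp_minus_cv=dcp,
        cp_classical=cpcl,
        cp_1pt=cp1,
        cp_2pt=cp2,
        cp_1pt_ac=cp1ac,
        cp_2pt_ac=cp2ac,
    )
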