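"""Two-phase (2PT) decomposition of the VDOS and 2PT / 2PT+AC heat capacities.

The total VDOS is split into a diffusive "gas" part and a vibrational
"solid" part.  The gas part takes the hard-sphere Lorentzian of the 2PT
literature; in the unit-norm molar convention used here (N_mol = 1, total
norm 1 representing f degrees of freedom per molecule),

    gas(nu) = s0 / (1 + (pi f s0 nu / (6 f_m N_mol))^2),

so that gas(0) = s0 = S(0) exactly and ``int gas dnu = 3 f_m N_mol / f``
(the fluidity fraction of the 3 translational DOF).  The fluidity factor
f_m is either supplied or solved from the hard-sphere universal equation

    2 D^-9/2 fm^15/2 - 6 D^-3 fm^5 - D^-3/2 fm^7/2 + 6 D^-3/2 fm^5/2
      + 2 fm - 2 = 0

with D the dimensionless normalized diffusivity built from S(0), the
temperature, the molecular mass and the number density.  The solid part is
the remainder; where the Lorentzian would exceed the total it is truncated
and the lost integral repartitioned into the remaining headroom so the
pointwise partition identity stays exact.

For the heat capacity, gas-like motion carries the classical weight 1/2
per DOF while solid-like motion carries the quantum harmonic weight, so
2PT lies between f R/2 and f R in the classical limit and is never above
1PT.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .constants import AMU_KG, K_BOLTZMANN, N_AVOGADRO, R_GAS
from .correlation import Vdos
from .quantum import weight_cv

__all__ = [
    "TwoPhaseSplit",
    "normalized_diffusivity",
    "fluidity_from_diffusivity",
    "decompose",
    "cv_2pt",
    "cv_2pt_ac",
]


@dataclass(frozen=True)
class TwoPhaseSplit:
    """Gas/solid partition of a VDOS."""

    frequencies: np.ndarray  # THz
    gas_density: np.ndarray  # 1/THz
    solid_density: np.ndarray  # 1/THz
    s0: float  # VDOS at zero frequency, 1/THz
    fluidity: float  # f_m in [0, 1]
    temperature: float
    dof_total: float
    integration_rule: str

    @property
    def dnu(self) -> float:
        return float(self.frequencies[1] - self.frequencies[0])

    @property
    def gas_fraction(self) -> float:
        """int gas / int total (both trapezoid)."""
        total = np.trapezoid(self.gas_density + self.solid_density, dx=self.dnu)
        if total == 0:
            return 0.0
        return float(np.trapezoid(self.gas_density, dx=self.dnu) / total)


def normalized_diffusivity(
    s0: float,
    f: float,
    temperature: float,
    molar_mass: float,
    density: float,
    n_molecules: int = 1,
) -> float:
    """Dimensionless hard-sphere diffusivity parameter.

    Parameters: ``s0`` in 1/THz from the unit-norm VDOS, ``f`` DOF per
    molecule, ``molar_mass`` in g/mol, mass ``density`` in kg/m^3.
    """
    s0_si = f * s0 * 1e-12  # DOF-normalized S(0) in seconds
    m = molar_mass * 1e-3 / N_AVOGADRO  # kg per molecule
    rho_n = density / (molar_mass * 1e-3) * N_AVOGADRO  # molecules / m^3
    return (
        (2.0 * s0_si / (9.0 * n_molecules))
        * np.sqrt(np.pi * K_BOLTZMANN * temperature / m)
        * rho_n ** (1.0 / 3.0)
        * (6.0 / np.pi) ** (2.0 / 3.0)
    )


def fluidity_polynomial(fm: float, delta: float) -> float:
    """Hard-sphere universal fluidity equation, zero at the physical f_m."""
    return (
        2.0 * delta**-4.5 * fm**7.5
        - 6.0 * delta**-3.0 * fm**5
        - delta**-1.5 * fm**3.5
        + 6.0 * delta**-1.5 * fm**2.5
        + 2.0 * fm
        - 2.0
    )


def fluidity_from_diffusivity(delta: float) -> float:
    """Solve the fluidity equation on [0, 1] by bracketed root-finding."""
    if delta <= 0:
        return 0.0
    return float(brentq(fluidity_polynomial, 1e-14, 1.0, args=(delta,), xtol=1e-13))


def decompose(
    vdos: Vdos,
    n_molecules: int = 1,
    fluidity: float | str = "auto",
    state=None,
) -> TwoPhaseSplit:
    """Split a VDOS into gas and solid components.

    ``n_molecules`` is the number of molecules the VDOS normalization refers
    to — 1 for the molar convention used throughout this package.  Passing an
    atom count here reproduces a historical analysis bug and gives a
    different (wrong) split for polyatomic molecules.

    ``fluidity`` is either a number in [0, 1] or ``"auto"``, which requires a
    :class:`~dostherm.thermo.ThermoState` (for T, molar mass and density) to
    solve the hard-sphere fluidity equation.
    """
    if vdos.integration_rule != "trapezoid":
        raise ValueError("2PT decomposition requires a trapezoid-rule VDOS")
    s0 = float(vdos.density[0])
    if s0 < 0:
        raise ValueError(f"VDOS(0) = {s0:g} is negative")
    f = vdos.dof_total
    nu = vdos.frequencies

    if fluidity == "auto":
        if state is None:
            raise ValueError("fluidity='auto' needs a ThermoState")
        delta = normalized_diffusivity(
            s0, f, vdos.temperature, state.molar_mass, state.density, n_molecules
        )
        fm = fluidity_from_diffusivity(delta)
    else:
        fm = float(fluidity)
        if not 0.0 <= fm <= 1.0:
            raise ValueError("fluidity must lie in [0, 1]")

    if s0 == 0.0 or fm == 0.0:
        gas = np.zeros_like(vdos.density)
        solid = vdos.density.copy()
        return TwoPhaseSplit(
            nu, gas, solid, s0, fm, vdos.temperature, f, vdos.integration_rule
        )

    gas = s0 / (1.0 + (np.pi * f * s0 * nu / (6.0 * fm * n_molecules)) ** 2)
    total = vdos.density
    # gas must stay within the (non-negative part of the) total; negative
    # FFT ripple never belongs to the gas component
    cap = np.maximum(total, 0.0)
    if np.any(gas > cap):
        target = np.trapezoid(gas, dx=vdos.dnu)
        n_excess = int((gas > cap).sum())
        gas = np.minimum(gas, cap)
        # restore the lost integral by rescaling the truncated gas shape,
        # re-capping until converged, so the mass stays at low frequency
        for _ in range(50):
            have = np.trapezoid(gas, dx=vdos.dnu)
            short = target - have
            if short <= 1e-12 * max(target, 1.0) or have == 0.0:
                break
            gas = np.minimum(gas * (1.0 + short / have), cap)
        warnings.warn(
            f"gas component exceeded the total VDOS at {n_excess} "
            "frequencies; truncated and rescaled within the available "
            "headroom",
            stacklevel=2,
        )
    solid = total - gas
    solid[0] = 0.0  # gas(0) = s0 = total(0) exactly
    return TwoPhaseSplit(
        nu, gas, solid, s0, fm, vdos.temperature, f, vdos.integration_rule
    )


def cv_2pt(
    split: TwoPhaseSplit, f: float, temperature: float, hbar_scale: float = 1.0
) -> float:
    """2PT isochoric heat capacity, J/(mol K).

    f R [ int solid(nu) W(nu) dnu + 1/2 int gas(nu) dnu ]; between f R/2 and
    f R in the classical limit and never above the 1PT value.
    """
    w = weight_cv(split.frequencies, temperature, hbar_scale)
    dnu = split.dnu
    solid_part = np.trapezoid(split.solid_density * w, dx=dnu)
    gas_part = 0.5 * np.trapezoid(split.gas_density, dx=dnu)
    return f * R_GAS * float(solid_part + gas_part)


def cv_2pt_ac(
    split: TwoPhaseSplit,
    cv_classical: float,
    f: float,
    temperature: float,
    hbar_scale: float = 1.0,
) -> float:
    """2PT combined with the anharmonic correction.

    The quantum correction is restricted to the solid component (the gas
    weight 1/2 is h-independent, so it drops out of the correction) and
    added to the classical heat capacity:

        cv_2pt_ac = cv_classical + f R int solid (W - 1) dnu.

    The h -> 0 limit is cv_classical exactly (correspondence principle), and
    the difference to 1PT+AC is f R int gas (1 - W) dnu >= 0 — small, since
    the gas component is concentrated at low frequency where W ~ 1.
    """
    w = weight_cv(split.frequencies, temperature, hbar_scale)
    corr = np.trapezoid(split.solid_density * (w - 1.0), dx=split.dnu)
    return cv_classical + f * R_GAS * float(corr)
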