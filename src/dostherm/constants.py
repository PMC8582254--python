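"""Physical constants (CODATA 2018) and unit conversions.

Internal unit system used throughout the package:

========== ==========
quantity   unit
========== ==========
time       fs
velocity   nm/ps
mass       amu
frequency  THz
energy     kJ/mol
heat cap.  J/(mol K)
diffusion  1e-9 m^2/s
========== ==========
"""

H_PLANCK = 6.62607015e-34  # J s
K_BOLTZMANN = 1.380649e-23  # J/K
N_AVOGADRO = 6.02214076e23  # 1/mol
R_GAS = 8.31446261815324  # J/(mol K)
AMU_KG = 1.66053906660e-27  # kg

# x = h*nu/(kB*T) for nu in THz:  x = X_OVER_NU_T * nu / T
X_OVER_NU_T = H_PLANCK * 1e12 / K_BOLTZMANN  # K/THz

# kB*T/m in (nm/ps)^2 for m in amu: V2_THERMAL * T / m
V2_THERMAL = K_BOLTZMANN / AMU_KG * 1e-6  # (nm/ps)^2 amu / K


def beta_h_fs(temperature: float, hbar_scale: float = 1.0) -> float:
    """Thermal time h/(kB*T) in fs, optionally with a scaled Planck constant."""
    return H_PLANCK * hbar_scale / (K_BOLTZMANN * temperature) * 1e15
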