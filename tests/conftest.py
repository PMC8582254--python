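import numpy as np
import pytest

from dostherm.synthetic import SyntheticSpec, generate, ground_truth


@pytest.fixture(scope="session")
def harmonic_spec():
    """Single-mode harmonic ensemble, many periods, for VACF/VDOS oracles."""
    return SyntheticSpec(
        kind="harmonic_ensemble",
        n_molecules=64,
        atoms_per_molecule=1,
        frequencies=(10.0,),
        n_frames=4096,
        dt=1.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def harmonic_traj(harmonic_spec):
    return generate(harmonic_spec)


@pytest.fixture(scope="session")
def ou_spec():
    """Pure OU translational gas with tau = 150 fs."""
    return SyntheticSpec(
        kind="ou_gas",
        n_molecules=64,
        atoms_per_molecule=1,
        tau=150.0,
        n_frames=24000,
        dt=4.0,
        seed=5,
        mass=32.0,
    )


@pytest.fixture(scope="session")
def ou_traj(ou_spec):
    return generate(ou_spec)


@pytest.fixture(scope="session")
def mixture_spec():
    """Triatomic molecules: OU center-of-mass motion + two harmonic modes."""
    return SyntheticSpec(
        kind="mixture",
        n_molecules=32,
        atoms_per_molecule=3,
        frequencies=(10.0, 40.0),
        weights=(0.5, 0.5),
        tau=150.0,
        n_frames=20000,
        dt=1.0,
        seed=7,
        mass=6.0,
    )


@pytest.fixture(scope="session")
def mixture_traj(mixture_spec):
    return generate(mixture_spec)


@pytest.fixture(scope="session")
def battery(harmonic_spec, ou_spec, mixture_spec):
    """The synthetic test battery: (spec, trajectory, ground truth) triples."""
    out = []
    for spec in (harmonic_spec, ou_spec, mixture_spec):
        out.append((spec, generate(spec), ground_truth(spec)))
    return out


def exponential_vacf(tau_fs=200.0, dt_fs=1.0, t_max_fs=6000.0, temperature=298.15):
    """Fixed analytic exponential VACF (no sampling noise)."""
    from dostherm.correlation import Vacf

    lags = np.arange(0.0, t_max_fs + dt_fs / 2, dt_fs)
    return Vacf(
        lags=lags,
        values=np.exp(-lags / tau_fs),
        temperature=temperature,
        dof_total=3.0,
    )
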