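"""Shared fixtures: synthetic trajectories, tables and one thermostated MD run."""

import numpy as np
import pytest

from hydrashell.exafs import ChiParameters
from hydrashell.synthetic import (
    ToyMDConfig,
    gen_scattering_table,
    gen_shell_fixture,
    gen_toy_md,
)
from hydrashell.trajectory_io import SimulationCell, Trajectory, assign_water_topology


@pytest.fixture(scope="session")
def scattering_table():
    return gen_scattering_table()


@pytest.fixture(scope="session")
def single_shell_truth():
    """Ground-truth cumulant parameters used for EXAFS round trips."""
    return ChiParameters(cn=9.2, r=2.87, sigma2=0.0265, c3=7.3e-4, delta_e0=6.3)


@pytest.fixture(scope="session")
def rigid_shell_traj():
    """8 rigid waters at exactly 2.88 Å plus diffuse outer waters."""
    return gen_shell_fixture(
        n_shell=8, r_shell=2.88, n_frames=40, n_outer=24, seed=11
    )


@pytest.fixture(scope="session")
def rigid_shell_topology(rigid_shell_traj):
    return assign_water_topology(rigid_shell_traj)


@pytest.fixture(scope="session")
def thermostated_md():
    """One thermostated toy-MD run shared by the thermodynamics tests.

    40 waters in a 10.7 Å box (≈1.0 g/cm³) around a divalent cation, 330 K,
    4500 steps of 0.5 fs; the last two-thirds are well equilibrated.
    """
    config = ToyMDConfig(
        n_waters=40,
        box=10.7,
        temperature=330.0,
        friction=0.02,
        dt=0.5,
        n_steps=4500,
        stride=10,
        seed=7,
    )
    traj, energy = gen_toy_md(config, return_energy=True)
    return config, traj, energy


@pytest.fixture(scope="session")
def equilibrated_md_tail(thermostated_md):
    """The second half of the thermostated run as its own trajectory."""
    _config, traj, _energy = thermostated_md
    half = traj.n_frames // 2
    return Trajectory(
        traj.cell,
        traj.species,
        traj.coords[half:],
        traj.times[: traj.n_frames - half],
        traj.solute_index,
        traj.solute_species,
    )


def random_gas_trajectory(
    n_targets: int = 100,
    n_frames: int = 400,
    box: float = 14.457,
    seed: int = 5,
    solute_species: str = "Ra",
) -> Trajectory:
    """Ideal-gas fixture: solute fixed at the centre, O atoms uniform in the box."""
    rng = np.random.default_rng(seed)
    cell = SimulationCell.cubic(box)
    species = [solute_species] + ["O"] * n_targets
    coords = np.empty((n_frames, n_targets + 1, 3))
    coords[:, 0] = box / 2.0
    coords[:, 1:] = rng.random((n_frames, n_targets, 3)) * box
    times = np.arange(n_frames, dtype=float) * 10.0
    return Trajectory(cell, species, coords, times, 0, solute_species)
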