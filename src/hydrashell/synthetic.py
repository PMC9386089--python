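"""Synthetic inputs with known ground truth.

Every generator here exists so the analysis pipeline can be exercised against
data whose answer is known in advance:

* :func:`gen_markov_occupancy` — independent two-state Markov chains for
  shell membership, the oracle for the direct residence-time estimator;
* :func:`gen_shell_fixture` — geometrically constructed trajectories of a
  rigid/jittered first shell with controlled radius, tilt-angle law and
  centre-of-mass offset;
* :func:`gen_toy_md` — a small Langevin dynamics simulator (flexible
  SPC-like water + divalent LJ/Coulomb ion) that produces physically shaped,
  deterministic trajectories.  It is an I/O-and-statistics exerciser, NOT a
  physical surrogate for first-principles water;
* :func:`gen_scattering_table` / :func:`gen_exafs_spectrum` — analytic
  backscattering amplitude/phase tables and spectra with known structural
  parameters.

All randomness flows through ``numpy.random.default_rng(seed)`` (PCG64);
identical seeds give identical outputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .exafs import ChiParameters, EXAFSSpectrum, ScatteringTable, chi_model
from .shell_structure import ShellOccupancySeries
from .trajectory_io import SimulationCell, Trajectory

__all__ = [
    "MarkovShellModel",
    "MarkovGroundTruth",
    "ToyMDConfig",
    "SyntheticEXAFSConfig",
    "gen_markov_occupancy",
    "gen_shell_fixture",
    "gen_toy_md",
    "gen_exafs_spectrum",
    "gen_scattering_table",
]

FS_PER_PS = 1000.0
KB = 8.3144621e-3  # kJ/mol/K
COULOMB = 1389.35458  # kJ Å / (mol e²)
ACC = 1.0e-4  # (kJ/mol/Å per u) → Å/fs²

# rigid water geometry used by the constructed fixtures (Å, degrees)
OH_BOND = 0.9572
HOH_ANGLE = 104.52


# ---------------------------------------------------------------------------
# Markov shell-occupancy model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MarkovShellModel:
    """Independent two-state (inside/outside) exchange model.

    ``k_out`` is the exit rate per shell water and ``k_in`` the entry rate
    per outside water (both ps⁻¹).  With both positive the stationary mean
    coordination number is ``n_waters · k_in / (k_in + k_out)``.  Per frame
    of length dt each molecule flips with probability 1 − exp(−k·dt).
    """

    n_waters: int
    k_out: float  # ps^-1
    k_in: float  # ps^-1
    dt: float  # fs
    span: float  # ps
    seed: int
    initial: str = "auto"  # "auto" | "stationary" | "all-in" | "all-out"

    def __post_init__(self) -> None:
        if self.k_out < 0 or self.k_in < 0:
            raise ValueError("rates must be non-negative")
        dt_ps = self.dt / FS_PER_PS
        if dt_ps * max(self.k_out, self.k_in) > 0.1:
            warnings.warn(
                "dt·rate exceeds 0.1; per-frame flip probabilities are coarse",
                stacklevel=2,
            )


@dataclass(frozen=True)
class MarkovGroundTruth:
    """The generator's own record of what it simulated."""

    transitions: tuple[tuple[int, float, str], ...]  # (molecule, time fs, direction)
    stationary_cn: float

    @property
    def n_transitions(self) -> int:
        return len(self.transitions)


def gen_markov_occupancy(
    model: MarkovShellModel,
) -> tuple[ShellOccupancySeries, MarkovGroundTruth]:
    """Simulate the occupancy chains and log every transition."""
    rng = np.random.default_rng(model.seed)
    n_frames = int(round(model.span * FS_PER_PS / model.dt))
    dt_ps = model.dt / FS_PER_PS
    p_exit = 1.0 - np.exp(-model.k_out * dt_ps)
    p_enter = 1.0 - np.exp(-model.k_in * dt_ps)
    total = model.k_in + model.k_out
    p_stat = model.k_in / total if total > 0 else 1.0
    initial = model.initial
    if initial == "auto":
        # a pure-decay model (k_in = 0) starts fully inside so the chains
        # have something to leave; otherwise start at stationarity
        initial = "all-in" if model.k_in == 0 else "stationary"
    if initial == "stationary":
        state = rng.random(model.n_waters) < p_stat
    elif initial == "all-in":
        state = np.ones(model.n_waters, dtype=bool)
    elif initial == "all-out":
        state = np.zeros(model.n_waters, dtype=bool)
    else:
        raise ValueError(f"unknown initial-state rule {model.initial!r}")
    mask = np.empty((n_frames, model.n_waters), dtype=bool)
    mask[0] = state
    transitions: list[tuple[int, float, str]] = []
    for f in range(1, n_frames):
        u = rng.random(model.n_waters)
        flip = np.where(state, u < p_exit, u < p_enter)
        if flip.any():
            t = f * model.dt
            for mol in np.nonzero(flip)[0]:
                transitions.append(
                    (int(mol), float(t), "exit" if state[mol] else "entry")
                )
        state = np.where(flip, ~state, state)
        mask[f] = state
    times = np.arange(n_frames, dtype=float) * model.dt
    series = ShellOccupancySeries(times, mask)
    truth = MarkovGroundTruth(tuple(transitions), model.n_waters * p_stat)
    return series, truth


# ---------------------------------------------------------------------------
# constructed shell fixtures
# ---------------------------------------------------------------------------

def _fibonacci_sphere(n: int) -> np.ndarray:
    """n nearly uniform unit vectors (deterministic)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5.0**0.5) * i
    return np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )


def _octahedron() -> np.ndarray:
    return np.array(
        [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]],
        dtype=float,
    )


def _orthonormal_frame(axis: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two unit vectors orthogonal to ``axis`` and to each other."""
    helper = np.array([1.0, 0.0, 0.0])
    if abs(axis @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(axis, helper)
    e1 /= np.linalg.norm(e1)
    return e1, np.cross(axis, e1)


def _water_atoms(
    o_pos: np.ndarray, dipole_dir: np.ndarray, plane_dir: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """H positions for a rigid water with its dipole along ``dipole_dir``."""
    half = np.radians(HOH_ANGLE / 2.0)
    d_mid = OH_BOND * np.cos(half)  # O → H-midpoint distance
    d_perp = OH_BOND * np.sin(half)
    mid = o_pos + d_mid * dipole_dir
    return mid + d_perp * plane_dir, mid - d_perp * plane_dir


def gen_shell_fixture(
    n_shell: int = 8,
    r_shell: float = 2.88,
    box: float = 14.457,
    n_frames: int = 100,
    dt: float = 50.0,
    jitter: float = 0.0,
    tilt_deg: float | None = None,
    tilt_spread_deg: float = 0.0,
    offset: np.ndarray | None = None,
    n_outer: int = 0,
    outer_min_r: float = 4.5,
    geometry: str = "fibonacci",
    solute_species: str = "Ra",
    seed: int = 0,
) -> Trajectory:
    """Construct a trajectory with a geometrically controlled first shell.

    ``n_shell`` waters sit at radius ``r_shell`` from the ion (cell centre)
    in a near-uniform (``"fibonacci"``) or exactly octahedral arrangement
    (``geometry="octahedral"``, requires n_shell=6).  Optional controls:

    * ``jitter`` — per-frame isotropic Gaussian displacement (Å) of each
      shell O (waters ride rigidly with their O);
    * ``tilt_deg``/``tilt_spread_deg`` — the water dipole makes angle ψ with
      the O→ion direction, drawn per (frame, water) from a normal law
      truncated to [0°, 180°]; default orientation is radially outward
      (ψ = 180°, dipole pointing away from the cation);
    * ``offset`` — a constant Cartesian shift applied to every shell water
      (not the ion), displacing the shell centre of mass by exactly that
      vector;
    * ``n_outer`` — additional waters placed uniformly at random with
      ion distance ≥ ``outer_min_r``, random orientations, giving the RDF a
      populated second region.
    """
    rng = np.random.default_rng(seed)
    cell = SimulationCell.cubic(box)
    center = np.full(3, box / 2.0)
    if geometry == "octahedral":
        if n_shell != 6:
            raise ValueError("octahedral geometry requires n_shell=6")
        dirs = _octahedron()
    elif geometry == "fibonacci":
        dirs = _fibonacci_sphere(n_shell)
    else:
        raise ValueError(f"unknown geometry {geometry!r}")
    off = np.zeros(3) if offset is None else np.asarray(offset, dtype=float)

    # outer oxygens keep ≥2.2 Å from every other O so topology stays unambiguous
    shell_o = center + r_shell * dirs + off
    outer_pos: list[np.ndarray] = []
    min_sep = 2.2
    from .trajectory_io import minimum_image

    for _ in range(n_outer):
        for _attempt in range(5000):
            p = rng.random(3) * box
            if np.linalg.norm(minimum_image(p - center, cell)) < outer_min_r:
                continue
            others = np.vstack([shell_o] + outer_pos)
            seps = np.linalg.norm(minimum_image(others - p, cell), axis=1)
            if np.min(seps) < min_sep:
                continue
            outer_pos.append(p)
            break
        else:
            raise RuntimeError(
                f"could not place {n_outer} outer waters at ≥{min_sep} Å separation"
            )

    n_mol = n_shell + n_outer
    species = [solute_species] + ["O", "H", "H"] * n_mol
    coords = np.empty((n_frames, 1 + 3 * n_mol, 3))
    for f in range(n_frames):
        coords[f, 0] = center
        a = 1
        for m in range(n_shell):
            u = dirs[m]
            o_pos = center + r_shell * u + off
            if jitter > 0:
                o_pos = o_pos + rng.normal(0.0, jitter, 3)
                to_ion = center - o_pos
            else:
                # offset shells keep the unshifted radial orientation so the
                # configuration is an exact rigid translation of the centred one
                to_ion = -u
            to_ion = to_ion / np.linalg.norm(to_ion)
            if tilt_deg is None:
                dip = -to_ion  # radially outward
            else:
                psi = tilt_deg + (
                    rng.normal(0.0, tilt_spread_deg) if tilt_spread_deg > 0 else 0.0
                )
                psi = float(np.clip(psi, 0.0, 180.0))
                e1, _e2 = _orthonormal_frame(to_ion)
                # random azimuth about the O→ion axis
                az = rng.random() * 2 * np.pi if tilt_spread_deg > 0 else 0.0
                e1r = np.cos(az) * e1 + np.sin(az) * np.cross(to_ion, e1)
                dip = np.cos(np.radians(psi)) * to_ion + np.sin(np.radians(psi)) * e1r
            plane = _orthonormal_frame(dip)[0]
            h1, h2 = _water_atoms(o_pos, dip, plane)
            coords[f, a], coords[f, a + 1], coords[f, a + 2] = o_pos, h1, h2
            a += 3
        for p in outer_pos:
            dip = rng.normal(size=3)
            dip /= np.linalg.norm(dip)
            plane = _orthonormal_frame(dip)[0]
            h1, h2 = _water_atoms(p, dip, plane)
            coords[f, a], coords[f, a + 1], coords[f, a + 2] = p, h1, h2
            a += 3
    times = np.arange(n_frames, dtype=float) * dt
    return Trajectory(cell, species, coords, times, 0, solute_species)


# ---------------------------------------------------------------------------
# toy Langevin MD
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ToyMDConfig:
    """Configuration of the classical toy simulator.

    Flexible SPC-like water (point charges, LJ on O, harmonic O–H bonds and
    H–O–H angle) plus one divalent LJ/Coulomb cation.  Nonbonded interactions
    use a shifted-force cutoff (no Ewald).  Parameters are desk-scale
    defaults chosen for stable velocity-Verlet integration at dt ≤ 1 fs.
    """

    n_waters: int = 50
    box: float = 11.5  # Å
    temperature: float = 330.0  # K
    friction: float = 0.02  # fs^-1 Langevin collision rate
    dt: float = 0.5  # fs
    n_steps: int = 4000
    stride: int = 10  # store every stride-th step
    seed: int = 0
    ion_species: str = "Ra"
    ion_charge: float = 2.0  # e
    ion_lj_epsilon: float = 0.6  # kJ/mol
    ion_lj_sigma: float = 3.3  # Å
    q_o: float = -0.82
    q_h: float = 0.41
    o_lj_epsilon: float = 0.65
    o_lj_sigma: float = 3.166
    h_lj_epsilon: float = 0.065  # small H site keeps flexible waters from collapsing
    h_lj_sigma: float = 1.2
    k_bond: float = 1000.0  # kJ/mol/Å²
    r0_bond: float = 1.0  # Å
    k_angle: float = 150.0  # kJ/mol/rad²
    theta0_deg: float = 104.52
    cutoff: float | None = None  # Å; default min(6.0, box/2 − 0.05)
    n_minimize: int = 200  # capped-displacement relaxation steps before dynamics

    def __post_init__(self) -> None:
        if self.dt > 1.0:
            raise ValueError("dt must be ≤ 1.0 fs")
        mass = self.n_waters * (15.999 + 2 * 1.008) / 6.02214076e23
        dens = mass / (self.box**3 * 1e-24)
        if dens > 1.2:
            raise ValueError(f"box too small: water density {dens:.2f} g/cm³ > 1.2")


class ForceBlowupError(RuntimeError):
    """A force exceeded the stability threshold; carries the offending step."""

    def __init__(self, step: int, max_force: float) -> None:
        super().__init__(
            f"force blow-up at step {step}: |F|max = {max_force:.3g} kJ/mol/Å"
        )
        self.step = step


class _ToySystem:
    """Force field state for the toy simulator (internal)."""

    def __init__(self, config: ToyMDConfig, positions: np.ndarray) -> None:
        c = config
        n_atoms = 1 + 3 * c.n_waters
        self.config = c
        self.cell = SimulationCell.cubic(c.box)
        self.species = [c.ion_species] + ["O", "H", "H"] * c.n_waters
        self.masses = np.array(
            [226.0] + [15.999, 1.008, 1.008] * c.n_waters
        )
        self.charges = np.array([c.ion_charge] + [c.q_o, c.q_h, c.q_h] * c.n_waters)
        o_idx = 1 + 3 * np.arange(c.n_waters)
        self.o_idx = o_idx
        # LJ per atom: ion and O only
        eps = np.full(n_atoms, c.h_lj_epsilon)
        sig = np.full(n_atoms, c.h_lj_sigma)
        eps[0], sig[0] = c.ion_lj_epsilon, c.ion_lj_sigma
        eps[o_idx], sig[o_idx] = c.o_lj_epsilon, c.o_lj_sigma
        self.eps, self.sig = eps, sig
        self.rc = c.cutoff if c.cutoff is not None else min(6.0, c.box / 2 - 0.05)
        # nonbonded pair list: all pairs except intramolecular
        pairs = []
        mol_of = np.full(n_atoms, -1)
        for m in range(c.n_waters):
            mol_of[1 + 3 * m : 4 + 3 * m] = m
        for i in range(n_atoms):
            for j in range(i + 1, n_atoms):
                if mol_of[i] >= 0 and mol_of[i] == mol_of[j]:
                    continue
                pairs.append((i, j))
        self.pi = np.array([p[0] for p in pairs])
        self.pj = np.array([p[1] for p in pairs])
        qq = self.charges[self.pi] * self.charges[self.pj] * COULOMB
        self.qq = qq
        e_i, e_j = eps[self.pi], eps[self.pj]
        lj_mask = (e_i > 0) & (e_j > 0)
        self.lj_mask = lj_mask
        self.pair_eps = np.sqrt(e_i * e_j)
        self.pair_sig = 0.5 * (sig[self.pi] + sig[self.pj])
        self.positions = positions
        self.velocities = np.zeros_like(positions)

    # -- potential terms --------------------------------------------------
    def forces_energy(self) -> tuple[np.ndarray, float]:
        from .trajectory_io import minimum_image

        c = self.config
        pos = self.positions
        n_atoms = pos.shape[0]
        forces = np.zeros_like(pos)
        energy = 0.0
        rc = self.rc

        d = minimum_image(pos[self.pj] - pos[self.pi], self.cell)
        r = np.linalg.norm(d, axis=1)
        within = r < rc
        r_w = r[within]
        d_w = d[within]
        inv_r = 1.0 / r_w
        # shifted-force Coulomb: V = qq (1/r − 1/rc + (r − rc)/rc²)
        qq = self.qq[within]
        energy += float(np.sum(qq * (inv_r - 1.0 / rc + (r_w - rc) / rc**2)))
        f_scalar = qq * (inv_r**2 - 1.0 / rc**2)  # −dV/dr
        # shifted-force LJ
        ljm = self.lj_mask[within]
        if ljm.any():
            e_p = self.pair_eps[within][ljm]
            s_p = self.pair_sig[within][ljm]
            r_l = r_w[ljm]
            sr6 = (s_p / r_l) ** 6
            sr6c = (s_p / rc) ** 6
            v = 4 * e_p * (sr6**2 - sr6)
            vc = 4 * e_p * (sr6c**2 - sr6c)
            dvdr = -24 * e_p * (2 * sr6**2 - sr6) / r_l
            dvdrc = -24 * e_p * (2 * sr6c**2 - sr6c) / rc
            energy += float(np.sum(v - vc - (r_l - rc) * dvdrc))
            fl = np.zeros_like(r_w)
            fl[ljm] = -(dvdr - dvdrc)
            f_scalar = f_scalar + fl
        fvec = (f_scalar * inv_r)[:, None] * d_w  # force on atom j
        np.add.at(forces, self.pj[within], fvec)
        np.add.at(forces, self.pi[within], -fvec)

        # intramolecular harmonic bonds and angle
        for m in range(c.n_waters):
            o, h1, h2 = 1 + 3 * m, 2 + 3 * m, 3 + 3 * m
            for h in (h1, h2):
                d_oh = minimum_image(pos[h] - pos[o], self.cell)
                r_oh = np.linalg.norm(d_oh)
                energy += 0.5 * c.k_bond * (r_oh - c.r0_bond) ** 2
                f = -c.k_bond * (r_oh - c.r0_bond) * d_oh / r_oh
                forces[h] += f
                forces[o] -= f
            a = minimum_image(pos[h1] - pos[o], self.cell)
            b = minimum_image(pos[h2] - pos[o], self.cell)
            ra, rb = np.linalg.norm(a), np.linalg.norm(b)
            cos_t = np.clip(a @ b / (ra * rb), -1.0, 1.0)
            theta = np.arccos(cos_t)
            theta0 = np.radians(c.theta0_deg)
            energy += 0.5 * c.k_angle * (theta - theta0) ** 2
            sin_t = max(np.sqrt(1.0 - cos_t**2), 1e-8)
            # force on h1 = −dV/dθ·dθ/da with dθ/da = −(b/(ra·rb) − cosθ·a/ra²)/sinθ
            dV = c.k_angle * (theta - theta0)
            da = dV * (cos_t * a / ra**2 - b / (ra * rb)) / sin_t
            db = dV * (cos_t * b / rb**2 - a / (ra * rb)) / sin_t
            forces[h1] -= da
            forces[h2] -= db
            forces[o] += da + db
        return forces, energy

    def kinetic_energy(self) -> float:
        v2 = np.sum(self.velocities**2, axis=1)
        return float(0.5 * np.sum(self.masses * v2) / ACC)

    def temperature(self) -> float:
        dof = 3 * self.positions.shape[0] - 3
        return 2.0 * self.kinetic_energy() / (dof * KB)


def _initial_positions(config: ToyMDConfig, rng: np.random.Generator) -> np.ndarray:
    """Ion at the centre, waters on a jittered cubic lattice around it."""
    c = config
    n_side = int(np.ceil((c.n_waters + 1) ** (1 / 3)))
    spacing = c.box / n_side
    sites = []
    for ix in range(n_side):
        for iy in range(n_side):
            for iz in range(n_side):
                sites.append((np.array([ix, iy, iz]) + 0.5) * spacing)
    sites = np.array(sites)
    center = np.full(3, c.box / 2)
    order = np.argsort(np.linalg.norm(sites - center, axis=1))
    ion_site = sites[order[0]]
    water_sites = sites[order[1 : c.n_waters + 1]]
    pos = np.empty((1 + 3 * c.n_waters, 3))
    pos[0] = ion_site
    half = np.radians(c.theta0_deg / 2)
    for m, site in enumerate(water_sites):
        o = site + rng.normal(0.0, 0.05, 3)
        dip = rng.normal(size=3)
        dip /= np.linalg.norm(dip)
        e1 = _orthonormal_frame(dip)[0]
        mid = o + c.r0_bond * np.cos(half) * dip
        d_perp = c.r0_bond * np.sin(half)
        pos[1 + 3 * m] = o
        pos[2 + 3 * m] = mid + d_perp * e1
        pos[3 + 3 * m] = mid - d_perp * e1
    return pos


def gen_toy_md(
    config: ToyMDConfig,
    positions: np.ndarray | None = None,
    return_energy: bool = False,
    force_threshold: float = 1.0e5,
):
    """Run the toy Langevin simulation and return the stored trajectory.

    Velocity Verlet with a BAOAB-style Langevin thermostat (friction in
    fs⁻¹); with ``friction=0`` the integrator is plain (microcanonical)
    velocity Verlet and, at ``temperature=0`` starting from rest, fully
    deterministic with no noise at all.  Frames are stored every ``stride``
    steps with positions wrapped into the box.  With ``return_energy=True``
    also returns a dict of per-stored-frame kinetic/potential energies and
    instantaneous temperature.
    """
    c = config
    rng = np.random.default_rng(c.seed)
    if positions is None:
        positions = _initial_positions(c, rng)
    sys = _ToySystem(c, np.array(positions, dtype=float))
    # capped-displacement relaxation removes initial overlaps deterministically
    for _ in range(c.n_minimize):
        f, _e = sys.forces_energy()
        fmax = np.abs(f).max()
        if fmax < 50.0:
            break
        sys.positions += np.clip(f * 1e-4, -0.02, 0.02)
    if c.temperature > 0 and c.friction > 0:
        sigma_v = np.sqrt(KB * c.temperature * ACC / sys.masses)
        sys.velocities = rng.normal(size=sys.positions.shape) * sigma_v[:, None]
        sys.velocities -= np.average(sys.velocities, axis=0, weights=sys.masses)

    a_fric = np.exp(-c.friction * c.dt)
    noise_scale = np.sqrt(KB * c.temperature * ACC / sys.masses * (1 - a_fric**2))
    inv_m = (1.0 / sys.masses)[:, None] * ACC

    forces, pot = sys.forces_energy()
    stored, times = [], []
    energy_log = {
        "time_fs": [],
        "kinetic": [],
        "potential": [],
        "temperature": [],
        "momentum": [],  # |Σ m v|, u·Å/fs
    }

    def store(step: int) -> None:
        frac = sys.cell.fractional(sys.positions)
        stored.append(sys.cell.cartesian(frac - np.floor(frac)))
        times.append(step * c.dt)
        if return_energy:
            energy_log["time_fs"].append(step * c.dt)
            energy_log["kinetic"].append(sys.kinetic_energy())
            energy_log["potential"].append(pot)
            energy_log["temperature"].append(sys.temperature())
            energy_log["momentum"].append(
                float(np.linalg.norm((sys.masses[:, None] * sys.velocities).sum(axis=0)))
            )

    store(0)
    for step in range(1, c.n_steps + 1):
        sys.velocities += 0.5 * c.dt * forces * inv_m
        sys.positions += 0.5 * c.dt * sys.velocities
        if c.friction > 0:
            sys.velocities = (
                a_fric * sys.velocities
                + noise_scale[:, None] * rng.normal(size=sys.velocities.shape)
            )
        sys.positions += 0.5 * c.dt * sys.velocities
        forces, pot = sys.forces_energy()
        fmax = float(np.abs(forces).max())
        if fmax > force_threshold:
            raise ForceBlowupError(step, fmax)
        sys.velocities += 0.5 * c.dt * forces * inv_m
        if step % c.stride == 0:
            store(step)

    coords = np.stack(stored)
    traj = Trajectory(
        sys.cell, sys.species, coords, np.array(times), 0, c.ion_species
    )
    if return_energy:
        return traj, {k: np.array(v) for k, v in energy_log.items()}
    return traj


# ---------------------------------------------------------------------------
# synthetic EXAFS
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticEXAFSConfig:
    """Ground-truth parameters and noise settings for a synthetic χ(k)."""

    truth: ChiParameters
    noise: float = 0.0  # Gaussian noise amplitude relative to RMS of k³χ
    k_min: float = 2.0  # Å⁻¹
    k_max: float = 10.0
    dk: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise < 0:
            raise ValueError("noise must be non-negative")


def gen_exafs_spectrum(
    config: SyntheticEXAFSConfig, table: ScatteringTable
) -> tuple[EXAFSSpectrum, ChiParameters]:
    """χ(k) at the truth parameters plus seeded Gaussian noise.

    Noise is drawn in the k³-weighted domain, scaled to ``noise`` times the
    RMS of k³χ, then divided back — matching how misfit is judged.
    """
    n = int(round((config.k_max - config.k_min) / config.dk)) + 1
    k = config.k_min + config.dk * np.arange(n)
    spec = chi_model(config.truth, table, k)
    chi = spec.chi.copy()
    if config.noise > 0:
        rng = np.random.default_rng(config.seed)
        w = spec.k**3
        rms = np.sqrt(np.mean((w * chi) ** 2))
        chi = chi + rng.normal(0.0, config.noise * rms, chi.size) / w
    return EXAFSSpectrum(spec.k, chi, k_weight=3), config.truth


def gen_scattering_table(
    kind: str = "smooth-default",
    k_max: float = 12.0,
    dk: float = 0.05,
    with_lambda: bool = True,
) -> ScatteringTable:
    """Analytic stand-in for a computed backscattering table (synthetic).

    Fixed, documented closed forms so tables are reproducible anywhere:

    * amplitude  F(k) = 2.8 · (0.2 + k²/4) / (1 + (k/2.4)²)²   [Å]
    * total phase φ(k) = 2.6 − 0.85·k + 0.018·k²               [rad]
    * mean free path λ(k) = 3.5 + 0.9·k                        [Å]

    The amplitude is smooth, positive, peaks near k ≈ 2.5 Å⁻¹ and decays at
    high k; the phase varies slowly, as heavy-scatterer tables do.
    """
    if kind != "smooth-default":
        raise ValueError(f"unknown table kind {kind!r}")
    n = int(round(k_max / dk)) + 1
    k = dk * np.arange(n)
    amp = 2.8 * (0.2 + k**2 / 4.0) / (1.0 + (k / 2.4) ** 2) ** 2
    phase = 2.6 - 0.85 * k + 0.018 * k**2
    lam = 3.5 + 0.9 * k if with_lambda else None
    return ScatteringTable(k, amp, phase, lam)
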