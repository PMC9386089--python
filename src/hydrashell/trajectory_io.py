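"""Reading, validation and normalization of MD trajectories.

Supported on-disk formats are extended XYZ (with a ``Lattice="..."`` cell in
the comment line) and VASP XDATCAR (``Direct`` fractional blocks only).  Both
are plain text; writers are provided so synthetic fixtures can round-trip
through either dialect.

Internal conventions, used consistently across the package:

* units: Å for lengths, fs for times;
* atom and frame indices are 0-based internally (1-based only in user-facing
  error messages);
* the periodic wrap maps fractional components to ``(-0.5, 0.5]`` with the
  boundary assigned to +0.5;
* water covalent topology is assigned once from frame 0 and frozen (molecules
  are treated as intact for the whole trajectory).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "SimulationCell",
    "Frame",
    "Trajectory",
    "WaterTopology",
    "TrajectoryError",
    "TopologyError",
    "read_xyz",
    "write_xyz",
    "read_xdatcar",
    "write_xdatcar",
    "minimum_image",
    "assign_water_topology",
]

# standard atomic weights (u) for center-of-mass work downstream
ATOMIC_MASS = {"O": 15.999, "H": 1.008}


class TrajectoryError(ValueError):
    """Malformed trajectory file or inconsistent trajectory data."""


class TopologyError(ValueError):
    """Water topology cannot be assigned under the stated rules."""


@dataclass(frozen=True)
class SimulationCell:
    """Periodic simulation cell.

    Parameters
    ----------
    lattice : (3, 3) array
        Rows are the lattice vectors **a**, **b**, **c** in Å; a Cartesian
        position is ``frac @ lattice``.
    periodic : tuple of bool
        Periodicity flags per direction (all True for the use cases here).
    """

    lattice: np.ndarray
    periodic: tuple[bool, bool, bool] = (True, True, True)

    def __post_init__(self) -> None:
        lat = np.asarray(self.lattice, dtype=float)
        if lat.shape != (3, 3) or not np.all(np.isfinite(lat)):
            raise TrajectoryError("lattice must be a finite 3x3 matrix (Å)")
        object.__setattr__(self, "lattice", lat)
        if self.volume <= 0.0:
            raise TrajectoryError(
                f"cell volume must be positive (got {self.volume:g} Å³); "
                "lattice vectors must form a right-handed, non-singular set"
            )

    @classmethod
    def cubic(cls, a: float) -> "SimulationCell":
        return cls(np.eye(3) * float(a))

    @property
    def volume(self) -> float:
        """Scalar triple product a · (b × c), Å³."""
        return float(np.linalg.det(self.lattice))

    @property
    def min_width(self) -> float:
        """Smallest perpendicular width of the cell (Å).

        This bounds the radius out to which the minimum-image convention is
        unambiguous (r must stay below half this width).
        """
        lat = self.lattice
        widths = []
        for i in range(3):
            j, k = (i + 1) % 3, (i + 2) % 3
            normal = np.cross(lat[j], lat[k])
            widths.append(abs(np.dot(lat[i], normal)) / np.linalg.norm(normal))
        return float(min(widths))

    def fractional(self, cartesian: np.ndarray) -> np.ndarray:
        return np.asarray(cartesian, dtype=float) @ np.linalg.inv(self.lattice)

    def cartesian(self, fractional: np.ndarray) -> np.ndarray:
        return np.asarray(fractional, dtype=float) @ self.lattice


def minimum_image(displacement: np.ndarray, cell: SimulationCell) -> np.ndarray:
    """Map displacement vector(s) onto their minimum periodic image.

    The displacement is expressed in fractional coordinates, each component is
    wrapped into ``(-0.5, 0.5]`` (ties to +0.5), and mapped back to Cartesian.
    For orthorhombic cells every wrapped component's magnitude is at most half
    the corresponding box length, which makes the result the true nearest
    image for distances below half the box width.

    Parameters
    ----------
    displacement : (..., 3) array, Å
    cell : SimulationCell (must be periodic in all directions)
    """
    if not all(cell.periodic):
        raise TrajectoryError("minimum_image requires a fully periodic cell")
    disp = np.asarray(displacement, dtype=float)
    frac = disp @ np.linalg.inv(cell.lattice)
    # wrap to (-0.5, 0.5] with the boundary tie assigned to +0.5
    frac = frac - np.ceil(frac - 0.5)
    return frac @ cell.lattice


@dataclass(frozen=True)
class Frame:
    """One stored configuration."""

    index: int
    time: float  # fs
    species: tuple[str, ...]
    positions: np.ndarray  # (n_atoms, 3) Å

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        if pos.ndim != 2 or pos.shape[1] != 3:
            raise TrajectoryError("positions must be an (n, 3) array")
        if not np.all(np.isfinite(pos)):
            raise TrajectoryError(f"frame {self.index + 1}: non-finite positions")
        if len(self.species) != pos.shape[0]:
            raise TrajectoryError(
                f"frame {self.index + 1}: {len(self.species)} species for "
                f"{pos.shape[0]} positions"
            )
        object.__setattr__(self, "positions", pos)


class Trajectory:
    """Time-ordered frames in a periodic cell with one designated solute ion.

    Coordinates are stored as a dense ``(n_frames, n_atoms, 3)`` array;
    ``frames`` yields :class:`Frame` views.  Frame times must be uniformly
    spaced (tolerance 1e-6 fs) and the species list constant across frames.
    """

    def __init__(
        self,
        cell: SimulationCell,
        species: Sequence[str],
        coords: np.ndarray,
        times: np.ndarray,
        solute_index: int,
        solute_species: str,
    ) -> None:
        coords = np.asarray(coords, dtype=float)
        times = np.asarray(times, dtype=float)
        if coords.ndim != 3 or coords.shape[2] != 3:
            raise TrajectoryError("coords must have shape (n_frames, n_atoms, 3)")
        if coords.shape[0] != times.shape[0]:
            raise TrajectoryError("one time per frame required")
        if not np.all(np.isfinite(coords)):
            raise TrajectoryError("non-finite coordinates")
        if coords.shape[0] >= 2:
            dts = np.diff(times)
            if np.any(dts <= 0):
                raise TrajectoryError("frame times must be strictly increasing")
            if np.max(np.abs(dts - dts[0])) > 1e-6:
                raise TrajectoryError(
                    "frame times must be uniformly spaced (tolerance 1e-6 fs)"
                )
        n_atoms = coords.shape[1]
        if not 0 <= solute_index < n_atoms:
            raise TrajectoryError(f"solute index {solute_index} out of range")
        if species[solute_index] != solute_species:
            raise TrajectoryError(
                f"atom {solute_index + 1} is {species[solute_index]!r}, "
                f"not the declared solute {solute_species!r}"
            )
        self.cell = cell
        self.species = tuple(species)
        self.coords = coords
        self.times = times
        self.solute_index = int(solute_index)
        self.solute_species = str(solute_species)

    # -- basic geometry ---------------------------------------------------
    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    @property
    def dt(self) -> float:
        """Spacing between stored frames, fs."""
        if self.n_frames < 2:
            raise TrajectoryError("dt undefined for a single-frame trajectory")
        return float(self.times[1] - self.times[0])

    @property
    def span(self) -> float:
        """Total sampled time n_frames * dt, fs."""
        return self.n_frames * self.dt

    @property
    def frames(self) -> Iterator[Frame]:
        for i in range(self.n_frames):
            yield Frame(i, float(self.times[i]), self.species, self.coords[i])

    def species_indices(self, symbol: str, exclude_solute: bool = True) -> np.ndarray:
        idx = np.array([i for i, s in enumerate(self.species) if s == symbol], dtype=int)
        if exclude_solute:
            idx = idx[idx != self.solute_index]
        return idx


def _locate_solute(species: Sequence[str], solute_species: str) -> int:
    matches = [i for i, s in enumerate(species) if s == solute_species]
    if not matches:
        raise TrajectoryError(f"no atom of solute species {solute_species!r} found")
    if len(matches) > 1:
        raise TrajectoryError(
            f"{len(matches)} atoms match solute species {solute_species!r}; "
            "exactly one solute is required"
        )
    return matches[0]


# ---------------------------------------------------------------------------
# extended XYZ
# ---------------------------------------------------------------------------

_LATTICE_RE = re.compile(r'Lattice\s*=\s*"([^"]+)"', re.IGNORECASE)


def _parse_lattice(comment: str) -> np.ndarray | None:
    m = _LATTICE_RE.search(comment)
    if m is None:
        return None
    vals = m.group(1).split()
    if len(vals) != 9:
        raise TrajectoryError(
            f"Lattice entry must hold 9 numbers, found {len(vals)}: {m.group(1)!r}"
        )
    return np.array([float(v) for v in vals]).reshape(3, 3)


def read_xyz(
    path: str | Path,
    dt: float,
    solute_species: str,
    cell: SimulationCell | None = None,
) -> Trajectory:
    """Read an (extended) XYZ trajectory.

    The cell is taken from the first frame's ``Lattice="..."`` comment entry
    unless an explicit ``cell`` override is given.  Frame times are
    ``index * dt`` (fs); the stride at which frames were stored is whatever
    the file contains — no stride is assumed.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    pos_blocks: list[np.ndarray] = []
    species0: list[str] | None = None
    i = 0
    frame_no = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        frame_no += 1
        try:
            n_atoms = int(lines[i].strip())
        except ValueError as exc:
            raise TrajectoryError(
                f"{path.name}: frame {frame_no}: expected an atom count on "
                f"line {i + 1}, found {lines[i]!r}"
            ) from exc
        if i + 1 >= len(lines):
            raise TrajectoryError(f"{path.name}: frame {frame_no}: missing comment line")
        comment = lines[i + 1]
        if cell is None:
            lat = _parse_lattice(comment)
            if lat is not None:
                cell = SimulationCell(lat)
        rows = lines[i + 2 : i + 2 + n_atoms]
        if len(rows) < n_atoms:
            raise TrajectoryError(
                f"{path.name}: frame {frame_no}: expected {n_atoms} atom rows, "
                f"file ends after {len(rows)}"
            )
        spec: list[str] = []
        pos = np.empty((n_atoms, 3))
        for j, row in enumerate(rows):
            parts = row.split()
            if len(parts) < 4:
                raise TrajectoryError(
                    f"{path.name}: frame {frame_no}, atom {j + 1}: malformed row {row!r}"
                )
            spec.append(parts[0])
            pos[j] = [float(parts[1]), float(parts[2]), float(parts[3])]
        if species0 is None:
            species0 = spec
        elif spec != species0:
            raise TrajectoryError(
                f"{path.name}: frame {frame_no}: atom list changed mid-file "
                f"({len(spec)} atoms vs {len(species0)} in frame 1)"
            )
        pos_blocks.append(pos)
        i += 2 + n_atoms
    if not pos_blocks or species0 is None:
        raise TrajectoryError(f"{path.name}: no frames found")
    if cell is None:
        raise TrajectoryError(
            f"{path.name}: no Lattice=\"...\" entry in any comment line and no "
            "explicit cell override given"
        )
    coords = np.stack(pos_blocks)
    times = np.arange(coords.shape[0], dtype=float) * float(dt)
    return Trajectory(
        cell, species0, coords, times, _locate_solute(species0, solute_species), solute_species
    )


def write_xyz(trajectory: Trajectory, path: str | Path) -> None:
    """Write extended XYZ with the cell in every comment line."""
    lat = " ".join(f"{v:.10f}" for v in trajectory.cell.lattice.ravel())
    with open(path, "w") as fh:
        for frame in trajectory.frames:
            fh.write(f"{trajectory.n_atoms}\n")
            fh.write(
                f'Lattice="{lat}" Properties=species:S:1:pos:R:3 '
                f"Time={frame.time:.6f}\n"
            )
            for s, (x, y, z) in zip(frame.species, frame.positions):
                fh.write(f"{s} {x:.10f} {y:.10f} {z:.10f}\n")


# ---------------------------------------------------------------------------
# VASP XDATCAR
# ---------------------------------------------------------------------------

def read_xdatcar(path: str | Path, dt: float, solute_species: str) -> Trajectory:
    """Read a VASP XDATCAR trajectory (``Direct`` fractional blocks only).

    Layout: title, scale factor, three lattice rows, species symbols line,
    per-species counts line, then repeated ``Direct configuration=  N`` blocks
    of fractional coordinates.  ``Cartesian`` blocks are rejected.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if len(lines) < 8:
        raise TrajectoryError(f"{path.name}: truncated header ({len(lines)} lines)")
    try:
        scale = float(lines[1].split()[0])
    except (ValueError, IndexError) as exc:
        raise TrajectoryError(
            f"{path.name}: line 2: expected scale factor, found {lines[1]!r}"
        ) from exc
    lat = np.empty((3, 3))
    for r in range(3):
        parts = lines[2 + r].split()
        try:
            lat[r] = [float(p) for p in parts[:3]]
        except ValueError as exc:
            raise TrajectoryError(
                f"{path.name}: line {3 + r}: non-numeric lattice row {lines[2 + r]!r}"
            ) from exc
    cell = SimulationCell(lat * scale)
    symbols = lines[5].split()
    try:
        counts = [int(c) for c in lines[6].split()]
    except ValueError as exc:
        raise TrajectoryError(
            f"{path.name}: line 7: non-integer species counts {lines[6]!r}"
        ) from exc
    if len(symbols) != len(counts):
        raise TrajectoryError(
            f"{path.name}: line 6 lists {len(symbols)} species but line 7 has "
            f"{len(counts)} counts"
        )
    species: list[str] = []
    for sym, cnt in zip(symbols, counts):
        species.extend([sym] * cnt)
    n_atoms = len(species)
    blocks: list[np.ndarray] = []
    i = 7
    while i < len(lines):
        header = lines[i].strip()
        if not header:
            i += 1
            continue
        low = header.lower()
        if low.startswith("cartesian"):
            raise TrajectoryError(
                f"{path.name}: line {i + 1}: Cartesian configuration blocks are "
                "not supported; only Direct (fractional) XDATCAR output is read"
            )
        if not low.startswith("direct"):
            raise TrajectoryError(
                f"{path.name}: line {i + 1}: expected 'Direct configuration=' "
                f"header, found {header!r}"
            )
        rows = lines[i + 1 : i + 1 + n_atoms]
        if len(rows) < n_atoms:
            raise TrajectoryError(
                f"{path.name}: configuration starting at line {i + 1} truncated: "
                f"expected {n_atoms} coordinate rows, found {len(rows)}"
            )
        frac = np.empty((n_atoms, 3))
        for j, row in enumerate(rows):
            parts = row.split()
            try:
                frac[j] = [float(parts[0]), float(parts[1]), float(parts[2])]
            except (ValueError, IndexError) as exc:
                raise TrajectoryError(
                    f"{path.name}: line {i + 2 + j}: malformed coordinate row {row!r}"
                ) from exc
        blocks.append(cell.cartesian(frac))
        i += 1 + n_atoms
    if not blocks:
        raise TrajectoryError(f"{path.name}: no configuration blocks found")
    coords = np.stack(blocks)
    times = np.arange(coords.shape[0], dtype=float) * float(dt)
    return Trajectory(
        cell, species, coords, times, _locate_solute(species, solute_species), solute_species
    )


def write_xdatcar(trajectory: Trajectory, path: str | Path, wrap: bool = True) -> None:
    """Write an XDATCAR file; atoms are grouped by species as VASP requires.

    With ``wrap=True`` fractional coordinates are wrapped into [0, 1).  Note
    the species grouping permutes atom order when the input interleaves
    species; the written file records the grouped order.
    """
    order: list[int] = []
    uniq: list[str] = []
    for s in trajectory.species:
        if s not in uniq:
            uniq.append(s)
    for s in uniq:
        order.extend(i for i, t in enumerate(trajectory.species) if t == s)
    counts = [sum(1 for t in trajectory.species if t == s) for s in uniq]
    with open(path, "w") as fh:
        fh.write("hydrashell trajectory\n")
        fh.write("1.0\n")
        for row in trajectory.cell.lattice:
            fh.write(f"  {row[0]:.10f}  {row[1]:.10f}  {row[2]:.10f}\n")
        fh.write("  " + "  ".join(uniq) + "\n")
        fh.write("  " + "  ".join(str(c) for c in counts) + "\n")
        for f in range(trajectory.n_frames):
            fh.write(f"Direct configuration= {f + 1:5d}\n")
            frac = trajectory.cell.fractional(trajectory.coords[f][order])
            if wrap:
                frac = frac - np.floor(frac)
            for row in frac:
                fh.write(f"  {row[0]:.10f}  {row[1]:.10f}  {row[2]:.10f}\n")


# ---------------------------------------------------------------------------
# water topology
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WaterTopology:
    """Frozen covalent assignment of hydrogens to water oxygens.

    ``molecules`` holds (O index, H index, H index) triples referring to atom
    indices of the trajectory.  The assignment is made from frame 0 and kept
    for the whole trajectory.
    """

    molecules: tuple[tuple[int, int, int], ...]

    @property
    def n_molecules(self) -> int:
        return len(self.molecules)

    @property
    def o_indices(self) -> np.ndarray:
        return np.array([m[0] for m in self.molecules], dtype=int)

    @property
    def h_indices(self) -> np.ndarray:
        """(n_molecules, 2) hydrogen indices."""
        return np.array([[m[1], m[2]] for m in self.molecules], dtype=int)


def assign_water_topology(
    trajectory: Trajectory, bond_cutoff: float = 1.25
) -> WaterTopology:
    """Assign each H to its nearest O (minimum image) in frame 0.

    Raises :class:`TopologyError` if any H sits farther than ``bond_cutoff``
    (Å) from every O, or if any O does not end up with exactly two hydrogens.
    """
    o_idx = trajectory.species_indices("O")
    h_idx = trajectory.species_indices("H")
    if len(h_idx) != 2 * len(o_idx):
        raise TopologyError(
            f"{len(o_idx)} oxygens but {len(h_idx)} hydrogens; water topology "
            "needs exactly 2 H per O"
        )
    pos = trajectory.coords[0]
    assigned: dict[int, list[int]] = {int(o): [] for o in o_idx}
    for h in h_idx:
        disp = minimum_image(pos[o_idx] - pos[h], trajectory.cell)
        dist = np.linalg.norm(disp, axis=1)
        nearest = int(np.argmin(dist))
        if dist[nearest] > bond_cutoff:
            raise TopologyError(
                f"hydrogen atom {h + 1}: nearest oxygen is {dist[nearest]:.3f} Å "
                f"away, beyond the bond cutoff {bond_cutoff:.3f} Å"
            )
        assigned[int(o_idx[nearest])].append(int(h))
    offenders = {o: hs for o, hs in assigned.items() if len(hs) != 2}
    if offenders:
        msg = "; ".join(
            f"O atom {o + 1} has {len(hs)} hydrogen(s)" for o, hs in offenders.items()
        )
        raise TopologyError(f"invalid water assignment: {msg}")
    molecules = tuple(
        (int(o), assigned[int(o)][0], assigned[int(o)][1]) for o in o_idx
    )
    return WaterTopology(molecules)
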