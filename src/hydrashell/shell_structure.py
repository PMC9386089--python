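"""Static structure of an ion's hydration shell.

Implements the solute-centred radial distribution function g(r) with its
running integration number N(r), detection of the first-shell boundary at the
first minimum of g(r), per-frame shell occupancy, coordination-number
statistics, the distance cumulants (mean r̄, Debye–Waller-type second cumulant
σ², third cumulant C3), the shell eccentricity ε (mean ion → shell
centre-of-mass distance), the water tilt-angle distribution P(cos ψ), and the
effective water radius r̄ − EIR.

Conventions (documented in docs/methods.md):

* g(r) is normalized with exact spherical-shell volumes 4π/3 (r_out³ − r_in³);
  N(r) is accumulated by direct pair counting, so the two agree by
  construction;
* a water is a shell member when its O–ion minimum-image distance is ≤ the
  boundary (boundary equality counts as inside);
* moments use the population (1/N) convention; by default all member distances
  are pooled across frames;
* the tilt angle ψ is between the water dipole direction (O → midpoint of the
  two H) and the O → ion vector; the reported mean is the arithmetic mean of
  ψ in degrees.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .trajectory_io import (
    ATOMIC_MASS,
    SimulationCell,
    Trajectory,
    WaterTopology,
    minimum_image,
)

__all__ = [
    "RDFProfile",
    "ShellDefinition",
    "ShellOccupancySeries",
    "ShellMetrics",
    "ShellDetectionError",
    "compute_rdf",
    "find_first_minimum",
    "shell_occupancy",
    "cn_histogram",
    "distance_cumulants",
    "eccentricity",
    "tilt_angle_distribution",
    "effective_water_radius",
    "compute_shell_metrics",
]

logger = logging.getLogger(__name__)


class ShellDetectionError(ValueError):
    """No usable first shell could be located in the RDF."""


@dataclass(frozen=True)
class RDFProfile:
    """Binned g(r) with its running integration number N(r)."""

    bin_centers: np.ndarray  # Å
    g: np.ndarray
    n_running: np.ndarray
    bin_width: float  # Å
    r_max: float  # Å
    pair_label: str = ""

    def to_tsv(self) -> str:
        lines = [
            f"# pair\t{self.pair_label}",
            f"# bin_width_angstrom\t{self.bin_width:.6g}",
            f"# r_max_angstrom\t{self.r_max:.6g}",
            "r\tg\tN",
        ]
        for r, g, n in zip(self.bin_centers, self.g, self.n_running):
            lines.append(f"{r:.6g}\t{g:.6g}\t{n:.6g}")
        return "\n".join(lines) + "\n"


@dataclass(frozen=True)
class ShellDefinition:
    """First-shell boundary radius and how it was obtained."""

    r_boundary: float  # Å
    method: str = "first-minimum"  # or "fixed"
    smoothing_window: int = 5  # bins (odd)


class ShellOccupancySeries:
    """Per-frame membership of water molecules in the first shell.

    ``member_mask`` is an (n_frames, n_molecules) boolean array; molecule ids
    are indices into the :class:`WaterTopology` molecule list.
    """

    def __init__(self, times: np.ndarray, member_mask: np.ndarray) -> None:
        times = np.asarray(times, dtype=float)
        member_mask = np.asarray(member_mask, dtype=bool)
        if member_mask.ndim != 2 or times.shape[0] != member_mask.shape[0]:
            raise ValueError("member_mask must be (n_frames, n_molecules)")
        self.times = times
        self.member_mask = member_mask

    @property
    def n_frames(self) -> int:
        return self.member_mask.shape[0]

    @property
    def n_molecules(self) -> int:
        return self.member_mask.shape[1]

    @property
    def dt(self) -> float:
        """Frame spacing, fs."""
        if self.n_frames < 2:
            raise ValueError("dt undefined for a single-frame series")
        dts = np.diff(self.times)
        if np.max(np.abs(dts - dts[0])) > 1e-6:
            raise ValueError("series requires uniform frame spacing")
        return float(dts[0])

    @property
    def span(self) -> float:
        """Total sampled time n_frames * dt, fs."""
        return self.n_frames * self.dt

    @property
    def cn_per_frame(self) -> np.ndarray:
        return self.member_mask.sum(axis=1)

    @property
    def members_per_frame(self) -> list[frozenset[int]]:
        return [frozenset(np.nonzero(row)[0].tolist()) for row in self.member_mask]

    @property
    def cn_mean(self) -> float:
        return float(self.cn_per_frame.mean())


@dataclass(frozen=True)
class ShellMetrics:
    """Structural summary of one ion's first hydration shell."""

    r_bar: float  # Å
    cn_mean: float
    sigma2: float  # Å²
    c3: float  # Å³
    eccentricity: float  # Å
    tilt_mean_deg: float
    tilt_bin_centers: np.ndarray  # cos ψ
    tilt_density: np.ndarray  # P(cos ψ), integrates to 1

    def to_json(self) -> str:
        return json.dumps(
            {
                "r_bar_angstrom": self.r_bar,
                "cn_mean": self.cn_mean,
                "sigma2_angstrom2": self.sigma2,
                "c3_angstrom3": self.c3,
                "eccentricity_angstrom": self.eccentricity,
                "tilt_mean_deg": self.tilt_mean_deg,
                "tilt_cos_bin_centers": self.tilt_bin_centers.tolist(),
                "tilt_density": self.tilt_density.tolist(),
            },
            indent=2,
            sort_keys=True,
        )


# ---------------------------------------------------------------------------
# RDF
# ---------------------------------------------------------------------------

def _solute_target_distances(
    trajectory: Trajectory, target_indices: np.ndarray
) -> np.ndarray:
    """(n_frames, n_targets) minimum-image solute–target distances."""
    disp = (
        trajectory.coords[:, target_indices, :]
        - trajectory.coords[:, trajectory.solute_index, None, :]
    )
    flat = minimum_image(disp.reshape(-1, 3), trajectory.cell)
    return np.linalg.norm(flat, axis=1).reshape(disp.shape[0], disp.shape[1])


def compute_rdf(
    trajectory: Trajectory,
    target_species: str = "O",
    bin_width: float = 0.02,
    r_max: float | None = None,
) -> RDFProfile:
    """Solute-centred radial distribution function and running integration.

    g is normalized by the ideal-gas expectation at number density
    ρ = N_target / V using exact shell volumes; N(r) is the direct cumulative
    pair count per frame, so ``N(r_i) = Σ_{j≤i} ρ V_shell(j) g(j)`` holds to
    round-off.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    limit = 0.5 * trajectory.cell.min_width
    if r_max is None:
        r_max = 0.49 * trajectory.cell.min_width
    if r_max > limit + 1e-12:
        raise ValueError(
            f"r_max={r_max:g} Å exceeds the minimum-image limit of half the "
            f"smallest cell width ({limit:g} Å)"
        )
    targets = trajectory.species_indices(target_species)
    if targets.size == 0:
        raise ValueError(f"no atoms of target species {target_species!r}")
    dist = _solute_target_distances(trajectory, targets)
    n_bins = int(np.floor(r_max / bin_width))
    edges = np.arange(n_bins + 1) * bin_width
    counts, _ = np.histogram(dist.ravel(), bins=edges)
    mean_counts = counts / trajectory.n_frames
    rho = targets.size / trajectory.cell.volume
    shell_vol = 4.0 * np.pi / 3.0 * (edges[1:] ** 3 - edges[:-1] ** 3)
    g = mean_counts / (rho * shell_vol)
    n_running = np.cumsum(mean_counts)
    centers = 0.5 * (edges[1:] + edges[:-1])
    label = f"{trajectory.solute_species}–{target_species}"
    return RDFProfile(centers, g, n_running, float(bin_width), float(n_bins * bin_width), label)


def find_first_minimum(rdf: RDFProfile, smoothing_window: int = 5) -> ShellDefinition:
    """Locate the first-shell boundary at the first minimum of g(r).

    A centred moving average of width ``smoothing_window`` (odd number of
    bins) is scanned for the first peak exceeding 1.5; the boundary is the
    first local minimum after that peak, ties broken toward smaller r.
    """
    if smoothing_window < 1 or smoothing_window % 2 == 0:
        raise ValueError("smoothing_window must be a positive odd bin count")
    g = np.asarray(rdf.g, dtype=float)
    if smoothing_window > 1:
        pad = smoothing_window // 2
        padded = np.pad(g, pad, mode="edge")
        kernel = np.ones(smoothing_window) / smoothing_window
        s = np.convolve(padded, kernel, mode="valid")
    else:
        s = g
    # first peak: first index above 1.5 whose smoothed value stops rising
    imax = None
    for i in range(len(s) - 1):
        if s[i] > 1.5 and s[i] >= s[i + 1]:
            imax = i
            break
    if imax is None:
        raise ShellDetectionError(
            "no first maximum with g > 1.5 found; the RDF shows no shell "
            "structure — use a fixed boundary (method='fixed') instead"
        )
    # first subsequent upturn bounds the descending run containing the minimum
    k = None
    for i in range(imax + 1, len(s)):
        if s[i] > s[i - 1]:
            k = i
            break
    if k is None:
        raise ShellDetectionError(
            "g(r) decreases monotonically after its first peak up to r_max; "
            "no first minimum within range — use a fixed boundary instead"
        )
    seg = s[imax + 1 : k]
    j = imax + 1 + int(np.argmin(seg))  # argmin takes the first tie: smaller r
    return ShellDefinition(float(rdf.bin_centers[j]), "first-minimum", smoothing_window)


# ---------------------------------------------------------------------------
# occupancy & statistics
# ---------------------------------------------------------------------------

def shell_occupancy(
    trajectory: Trajectory, topology: WaterTopology, shell_def: ShellDefinition
) -> ShellOccupancySeries:
    """Per-frame first-shell membership of every water molecule.

    A water belongs to the shell in a frame iff its oxygen's minimum-image
    distance to the solute is ≤ ``r_boundary`` (equality counts as inside).
    """
    dist = _solute_target_distances(trajectory, topology.o_indices)
    return ShellOccupancySeries(trajectory.times, dist <= shell_def.r_boundary)


def cn_histogram(series: ShellOccupancySeries) -> dict[int, float]:
    """Probability of each observed coordination number."""
    cns = series.cn_per_frame
    values, counts = np.unique(cns, return_counts=True)
    return {int(v): float(c) / len(cns) for v, c in zip(values, counts)}


def distance_cumulants(
    trajectory: Trajectory,
    topology: WaterTopology,
    series: ShellOccupancySeries,
    per_frame: bool = False,
) -> tuple[float, float, float]:
    """Mean, second and third central moments of shell ion–O distances.

    Default pools every (frame, member) distance before taking moments; with
    ``per_frame=True`` the second/third moments are computed per frame about
    the pooled mean and then time-averaged (alternative reading, provided for
    comparison).  Population (1/N) convention throughout.
    """
    dist = _solute_target_distances(trajectory, topology.o_indices)
    mask = series.member_mask
    if dist.shape != mask.shape:
        raise ValueError("series does not match trajectory/topology size")
    if not mask.any():
        raise ValueError("shell is empty in every frame; no distances to average")
    pooled = dist[mask]
    r_bar = float(pooled.mean())
    if not per_frame:
        dev = pooled - r_bar
        return r_bar, float(np.mean(dev**2)), float(np.mean(dev**3))
    m2, m3, n_used = 0.0, 0.0, 0
    for f in range(dist.shape[0]):
        d = dist[f][mask[f]]
        if d.size == 0:
            continue
        dev = d - r_bar
        m2 += float(np.mean(dev**2))
        m3 += float(np.mean(dev**3))
        n_used += 1
    return r_bar, m2 / n_used, m3 / n_used


def eccentricity(
    trajectory: Trajectory, topology: WaterTopology, series: ShellOccupancySeries
) -> float:
    """Mean ion → first-shell centre-of-mass distance, Å.

    The centre of mass of all member waters (O and both H, standard atomic
    weights) is formed from minimum-image displacements relative to the ion,
    so shells straddling the cell boundary are handled correctly.  Frames
    with an empty shell are skipped.
    """
    m_o, m_h = ATOMIC_MASS["O"], ATOMIC_MASS["H"]
    o_idx, h_idx = topology.o_indices, topology.h_indices
    eps_frames = []
    for f in range(series.n_frames):
        members = np.nonzero(series.member_mask[f])[0]
        if members.size == 0:
            continue
        atoms = np.concatenate([o_idx[members], h_idx[members].ravel()])
        masses = np.concatenate(
            [np.full(members.size, m_o), np.full(2 * members.size, m_h)]
        )
        disp = minimum_image(
            trajectory.coords[f, atoms] - trajectory.coords[f, trajectory.solute_index],
            trajectory.cell,
        )
        cm = (masses[:, None] * disp).sum(axis=0) / masses.sum()
        eps_frames.append(np.linalg.norm(cm))
    if not eps_frames:
        raise ValueError("shell is empty in every frame; eccentricity undefined")
    return float(np.mean(eps_frames))


def tilt_angle_distribution(
    trajectory: Trajectory,
    topology: WaterTopology,
    series: ShellOccupancySeries,
    n_bins: int = 40,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Tilt angle ψ of first-shell waters and its distribution over cos ψ.

    ψ is the angle between the water dipole direction (unit vector from O to
    the midpoint of its two H, minimum image) and the unit vector from O to
    the metal ion.  Returns ``(mean ψ in degrees, bin centres in cos ψ,
    normalized density P(cos ψ))``; the density integrates to 1 over [-1, 1].
    Degenerate geometries (H midpoint within 1e-6 Å of O) are skipped with a
    logged warning.
    """
    cell = trajectory.cell
    o_idx, h_idx = topology.o_indices, topology.h_indices
    cos_vals: list[np.ndarray] = []
    n_degenerate = 0
    for f in range(series.n_frames):
        members = np.nonzero(series.member_mask[f])[0]
        if members.size == 0:
            continue
        pos = trajectory.coords[f]
        o = pos[o_idx[members]]
        h1 = o + minimum_image(pos[h_idx[members, 0]] - o, cell)
        h2 = o + minimum_image(pos[h_idx[members, 1]] - o, cell)
        dipole = 0.5 * (h1 + h2) - o
        to_ion = minimum_image(pos[trajectory.solute_index] - o, cell)
        d_norm = np.linalg.norm(dipole, axis=1)
        ok = d_norm > 1e-6
        n_degenerate += int((~ok).sum())
        u = dipole[ok] / d_norm[ok, None]
        v = to_ion[ok] / np.linalg.norm(to_ion[ok], axis=1)[:, None]
        cos_vals.append(np.clip((u * v).sum(axis=1), -1.0, 1.0))
    if n_degenerate:
        logger.warning(
            "skipped %d degenerate water geometries (H midpoint on O)", n_degenerate
        )
    if not cos_vals:
        raise ValueError("no shell members; tilt distribution undefined")
    cos_all = np.concatenate(cos_vals)
    psi_deg = np.degrees(np.arccos(cos_all))
    edges = np.linspace(-1.0, 1.0, n_bins + 1)
    density, _ = np.histogram(cos_all, bins=edges, density=True)
    centers = 0.5 * (edges[1:] + edges[:-1])
    return float(psi_deg.mean()), centers, density


def effective_water_radius(r_bar: float, effective_ionic_radius: float) -> float:
    """Effective radius of a coordinated water: r̄(ion–O) − EIR, Å."""
    return float(r_bar) - float(effective_ionic_radius)


def compute_shell_metrics(
    trajectory: Trajectory,
    topology: WaterTopology,
    series: ShellOccupancySeries,
    n_tilt_bins: int = 40,
    per_frame_moments: bool = False,
) -> ShellMetrics:
    """Bundle every first-shell structural statistic into one record."""
    r_bar, sigma2, c3 = distance_cumulants(
        trajectory, topology, series, per_frame=per_frame_moments
    )
    eps = eccentricity(trajectory, topology, series)
    tilt_mean, centers, density = tilt_angle_distribution(
        trajectory, topology, series, n_bins=n_tilt_bins
    )
    return ShellMetrics(
        r_bar=r_bar,
        cn_mean=series.cn_mean,
        sigma2=sigma2,
        c3=c3,
        eccentricity=eps,
        tilt_mean_deg=tilt_mean,
        tilt_bin_centers=centers,
        tilt_density=density,
    )
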