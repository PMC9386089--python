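"""RDF, shell boundary, occupancy, cumulants, eccentricity and tilt angles."""

import numpy as np
import pytest
from scipy import stats

from hydrashell.shell_structure import (
    RDFProfile,
    ShellDefinition,
    ShellDetectionError,
    ShellOccupancySeries,
    cn_histogram,
    compute_rdf,
    compute_shell_metrics,
    distance_cumulants,
    eccentricity,
    effective_water_radius,
    find_first_minimum,
    shell_occupancy,
    tilt_angle_distribution,
)
from hydrashell.synthetic import gen_shell_fixture
from hydrashell.trajectory_io import (
    SimulationCell,
    Trajectory,
    assign_water_topology,
)

from conftest import random_gas_trajectory


# ---------------------------------------------------------------------------
# RDF
# ---------------------------------------------------------------------------

class TestRDF:
    def test_uniform_gas_is_flat(self):
        """Ideal-gas g(r) ≈ 1 wherever the expected bin count is large."""
        traj = random_gas_trajectory(n_targets=100, n_frames=2000, seed=9)
        rdf = compute_rdf(traj, "O", bin_width=0.25)
        rho = 100 / traj.cell.volume
        shell_vol = 4 * np.pi / 3 * (
            (rdf.bin_centers + 0.125) ** 3 - (rdf.bin_centers - 0.125) ** 3
        )
        expected_counts = rho * shell_vol * traj.n_frames
        well_sampled = expected_counts >= 500
        assert well_sampled.sum() >= 20
        assert np.all(np.abs(rdf.g[well_sampled] - 1.0) < 0.05)

    def test_uniform_gas_running_integral(self):
        traj = random_gas_trajectory(n_targets=100, n_frames=400, seed=6)
        rdf = compute_rdf(traj, "O", bin_width=0.05)
        rho = 100 / traj.cell.volume
        edges = rdf.bin_centers + rdf.bin_width / 2
        ideal = rho * 4 * np.pi / 3 * edges**3
        sel = edges > 3.0
        assert np.all(np.abs(rdf.n_running[sel] / ideal[sel] - 1.0) < 0.05)

    def test_single_target_single_bin(self):
        """One O at exactly 3.00 Å → all g mass in that bin; N jumps 0 → 1."""
        cell = SimulationCell.cubic(10.0)
        coords = np.array([[[5.0, 5.0, 5.0], [8.0, 5.0, 5.0]]])
        traj = Trajectory(cell, ["Ra", "O"], coords, np.array([0.0]), 0, "Ra")
        rdf = compute_rdf(traj, "O", bin_width=0.02)
        hit = np.digitize(3.0, rdf.bin_centers + rdf.bin_width / 2)
        assert rdf.g[hit] > 0
        assert np.count_nonzero(rdf.g) == 1
        assert rdf.n_running[hit - 1] == 0 and rdf.n_running[hit] == 1
        assert np.all(rdf.n_running[hit:] == 1)

    def test_synthetic_shell_peak_and_plateau(self):
        traj = gen_shell_fixture(
            n_shell=8, r_shell=2.88, jitter=0.05, n_frames=60, n_outer=20, seed=8
        )
        rdf = compute_rdf(traj, "O", bin_width=0.02)
        peak_r = rdf.bin_centers[np.argmax(rdf.g)]
        assert abs(peak_r - 2.88) <= 0.02 + 1e-9
        plateau = (rdf.bin_centers > 3.4) & (rdf.bin_centers < 4.2)
        np.testing.assert_allclose(rdf.n_running[plateau], 8.0, atol=0.05)

    def test_n_running_consistent_with_g(self):
        """Cumulative ρ·V_shell·g reconstructs N(r) (two routes, one count)."""
        traj = gen_shell_fixture(n_shell=8, jitter=0.1, n_frames=20, n_outer=15, seed=2)
        rdf = compute_rdf(traj, "O", bin_width=0.02)
        rho = assign_water_topology(traj).n_molecules / traj.cell.volume
        edges_hi = rdf.bin_centers + rdf.bin_width / 2
        edges_lo = rdf.bin_centers - rdf.bin_width / 2
        shell_vol = 4 * np.pi / 3 * (edges_hi**3 - edges_lo**3)
        np.testing.assert_allclose(
            np.cumsum(rho * shell_vol * rdf.g), rdf.n_running, rtol=1e-6
        )

    def test_r_max_beyond_minimum_image_rejected(self):
        traj = random_gas_trajectory(n_targets=10, n_frames=2)
        with pytest.raises(ValueError, match="half"):
            compute_rdf(traj, "O", r_max=7.5)


# ---------------------------------------------------------------------------
# first minimum
# ---------------------------------------------------------------------------

def analytic_rdf(n_bins=400, r_max=8.0):
    width = r_max / n_bins
    r = (np.arange(n_bins) + 0.5) * width
    g = 1 + np.exp(-((r - 2.9) ** 2) / 0.02) - 0.6 * np.exp(-((r - 3.3) ** 2) / 0.02)
    counts_like = np.maximum(g, 0)
    return RDFProfile(r, counts_like, np.cumsum(counts_like), width, r_max, "test")


class TestFirstMinimum:
    def test_analytic_double_gaussian(self):
        rdf = analytic_rdf()
        # oracle: grid argmin of the closed-form curve between peak and 4 Å
        sel = (rdf.bin_centers > 2.9) & (rdf.bin_centers < 4.0)
        true_min = rdf.bin_centers[sel][np.argmin(rdf.g[sel])]
        sd = find_first_minimum(rdf, smoothing_window=5)
        assert sd.method == "first-minimum"
        assert abs(sd.r_boundary - true_min) <= rdf.bin_width + 1e-12
        assert abs(sd.r_boundary - 3.3) < 0.1

    def test_monotone_g_is_an_error(self):
        r = np.linspace(0.05, 6, 200)
        g = np.exp(-r)
        rdf = RDFProfile(r, g, np.cumsum(g), r[1] - r[0], 6.0, "m")
        with pytest.raises(ShellDetectionError):
            find_first_minimum(rdf)

    def test_ideal_gas_has_no_shell(self):
        traj = random_gas_trajectory(n_targets=100, n_frames=300, seed=12)
        rdf = compute_rdf(traj, "O", bin_width=0.1)
        with pytest.raises(ShellDetectionError, match="fixed"):
            find_first_minimum(rdf)


# ---------------------------------------------------------------------------
# occupancy & CN statistics
# ---------------------------------------------------------------------------

class TestOccupancy:
    def test_boundary_equality_counts_inside(self):
        # box 16 and axis-aligned O at exactly 3.0 Å: all distances exact in fp
        cell = SimulationCell.cubic(16.0)
        center = np.full(3, 8.0)
        pos = [center]
        for u in np.vstack([np.eye(3), -np.eye(3)]):
            o = center + 3.0 * u
            pos += [o, o + [0.59, 0.76, 0.0], o + [0.59, -0.76, 0.0]]
        coords = np.array(pos)[None]
        species = ["Ra"] + ["O", "H", "H"] * 6
        traj = Trajectory(cell, species, coords, np.array([0.0]), 0, "Ra")
        topo = assign_water_topology(traj)
        series = shell_occupancy(traj, topo, ShellDefinition(3.0, "fixed"))
        assert np.all(series.cn_per_frame == 6)
        just_below = shell_occupancy(traj, topo, ShellDefinition(2.999999, "fixed"))
        assert np.all(just_below.cn_per_frame == 0)

    def test_static_shell_constant_cn(self, rigid_shell_traj, rigid_shell_topology):
        series = shell_occupancy(
            rigid_shell_traj, rigid_shell_topology, ShellDefinition(3.4, "fixed")
        )
        assert np.all(series.cn_per_frame == 8)
        assert series.cn_mean == 8.0

    def test_cn_histogram_examples(self):
        times = np.arange(4) * 10.0
        mask = np.zeros((4, 9), dtype=bool)
        for f, cn in enumerate([7, 8, 8, 9]):
            mask[f, :cn] = True
        series = ShellOccupancySeries(times, mask)
        assert cn_histogram(series) == {7: 0.25, 8: 0.5, 9: 0.25}
        const = ShellOccupancySeries(times, np.ones((4, 8), dtype=bool))
        assert cn_histogram(const) == {8: 1.0}

    def test_histogram_expectation_equals_cn_mean(self):
        rng = np.random.default_rng(2)
        mask = rng.random((50, 12)) < 0.6
        series = ShellOccupancySeries(np.arange(50) * 10.0, mask)
        hist = cn_histogram(series)
        assert sum(p for p in hist.values()) == pytest.approx(1.0, abs=1e-12)
        expectation = sum(cn * p for cn, p in hist.items())
        assert expectation == pytest.approx(series.cn_mean, abs=1e-12)


# ---------------------------------------------------------------------------
# cumulants
# ---------------------------------------------------------------------------

def distance_series_trajectory(distances):
    """One water whose O sits at a prescribed distance from the ion per frame."""
    distances = np.asarray(distances, dtype=float)
    cell = SimulationCell.cubic(30.0)
    center = np.full(3, 15.0)
    n = distances.size
    coords = np.empty((n, 4, 3))
    coords[:, 0] = center
    coords[:, 1] = center + np.outer(distances, [1.0, 0, 0])
    coords[:, 2] = coords[:, 1] + [0.59, 0.76, 0]
    coords[:, 3] = coords[:, 1] + [0.59, -0.76, 0]
    traj = Trajectory(
        cell, ["Ra", "O", "H", "H"], coords, np.arange(n) * 10.0, 0, "Ra"
    )
    topo = assign_water_topology(traj)
    series = ShellOccupancySeries(traj.times, np.ones((n, 1), dtype=bool))
    return traj, topo, series


class TestDistanceCumulants:
    def test_constant_distance(self):
        traj, topo, series = distance_series_trajectory([2.88] * 5)
        r_bar, s2, c3 = distance_cumulants(traj, topo, series)
        assert r_bar == pytest.approx(2.88, abs=1e-12)
        assert s2 == pytest.approx(0.0, abs=1e-12)
        assert c3 == pytest.approx(0.0, abs=1e-12)

    def test_two_point_hand_arithmetic(self):
        traj, topo, series = distance_series_trajectory([2.0, 4.0])
        r_bar, s2, c3 = distance_cumulants(traj, topo, series)
        assert (r_bar, s2, c3) == pytest.approx((3.0, 1.0, 0.0), abs=1e-12)

    def test_matches_brute_force_two_pass(self):
        rng = np.random.default_rng(7)
        d = rng.uniform(2.5, 3.5, 200)
        traj, topo, series = distance_series_trajectory(d)
        r_bar, s2, c3 = distance_cumulants(traj, topo, series)
        mean = sum(d) / len(d)
        m2 = sum((x - mean) ** 2 for x in d) / len(d)
        m3 = sum((x - mean) ** 3 for x in d) / len(d)
        assert (r_bar, s2, c3) == pytest.approx((mean, m2, m3), rel=1e-12)

    def test_skew_normal_closed_form(self):
        """Pooled moments recover the law's exact mean/var/3rd central moment."""
        a, loc, scale, n = 4.0, 2.7, 0.2, 40000
        rng = np.random.default_rng(21)
        d = stats.skewnorm.rvs(a, loc=loc, scale=scale, size=n, random_state=rng)
        traj, topo, series = distance_series_trajectory(d)
        r_bar, s2, c3 = distance_cumulants(traj, topo, series)
        mean, var = stats.skewnorm.stats(a, loc=loc, scale=scale, moments="mv")
        skew = stats.skewnorm.stats(a, loc=loc, scale=scale, moments="s")
        m3 = skew * var**1.5
        # plug-in standard errors of the sample moments
        se_mean = np.sqrt(var / n)
        m4 = stats.skewnorm.moment(4, a, loc=loc, scale=scale) - 4 * mean * stats.skewnorm.moment(3, a, loc=loc, scale=scale) + 6 * mean**2 * stats.skewnorm.moment(2, a, loc=loc, scale=scale) - 3 * mean**4
        se_var = np.sqrt(max(m4 - var**2, 0) / n)
        assert abs(r_bar - mean) < 3 * se_mean
        assert abs(s2 - var) < 3 * se_var
        assert abs(c3 - m3) < 5 * se_var * np.sqrt(var)  # conservative bound

    def test_empty_shell_everywhere_is_an_error(self):
        traj, topo, _ = distance_series_trajectory([3.0, 3.0])
        empty = ShellOccupancySeries(traj.times, np.zeros((2, 1), dtype=bool))
        with pytest.raises(ValueError, match="empty"):
            distance_cumulants(traj, topo, empty)

    def test_per_frame_mode_agrees_on_constant_cn(self):
        rng = np.random.default_rng(3)
        d = rng.uniform(2.6, 3.2, 50)
        traj, topo, series = distance_series_trajectory(d)
        pooled = distance_cumulants(traj, topo, series)
        per_frame = distance_cumulants(traj, topo, series, per_frame=True)
        # single member per frame: per-frame averaging equals pooling
        assert per_frame == pytest.approx(pooled, rel=1e-12)


# ---------------------------------------------------------------------------
# eccentricity
# ---------------------------------------------------------------------------

class TestEccentricity:
    def test_octahedral_shell_is_centred(self):
        traj = gen_shell_fixture(n_shell=6, geometry="octahedral", n_frames=3, seed=1)
        topo = assign_water_topology(traj)
        series = shell_occupancy(traj, topo, ShellDefinition(3.4, "fixed"))
        assert eccentricity(traj, topo, series) < 1e-9

    def test_uniform_offset_recovered_exactly(self):
        t = np.array([0.21, -0.13, 0.08])
        traj = gen_shell_fixture(
            n_shell=6, geometry="octahedral", offset=t, n_frames=2, seed=1
        )
        topo = assign_water_topology(traj)
        series = shell_occupancy(traj, topo, ShellDefinition(3.6, "fixed"))
        assert eccentricity(traj, topo, series) == pytest.approx(
            np.linalg.norm(t), abs=1e-9
        )

    def test_single_water_equals_cm_distance(self):
        traj, topo, series = distance_series_trajectory([2.9])
        # CM of the one water, relative to the ion
        m = np.array([15.999, 1.008, 1.008])
        cm = (m[:, None] * (traj.coords[0, 1:4] - traj.coords[0, 0])).sum(0) / m.sum()
        assert eccentricity(traj, topo, series) == pytest.approx(
            np.linalg.norm(cm), abs=1e-12
        )


# ---------------------------------------------------------------------------
# tilt angles
# ---------------------------------------------------------------------------

class TestTiltAngles:
    @pytest.mark.parametrize("tilt,expect", [(180.0, 180.0), (90.0, 90.0)])
    def test_constructed_angles(self, tilt, expect):
        traj = gen_shell_fixture(n_shell=4, tilt_deg=tilt, n_frames=2, seed=3)
        topo = assign_water_topology(traj)
        series = shell_occupancy(traj, topo, ShellDefinition(3.4, "fixed"))
        mean_deg, _, _ = tilt_angle_distribution(traj, topo, series)
        assert mean_deg == pytest.approx(expect, abs=1e-6)

    def test_density_normalization(self, rigid_shell_traj, rigid_shell_topology):
        series = shell_occupancy(
            rigid_shell_traj, rigid_shell_topology, ShellDefinition(3.4, "fixed")
        )
        _, centers, density = tilt_angle_distribution(
            rigid_shell_traj, rigid_shell_topology, series
        )
        width = centers[1] - centers[0]
        assert np.sum(density * width) == pytest.approx(1.0, abs=1e-9)

    def test_isotropic_ensemble_is_flat_in_cos(self):
        """Random dipole orientations → P(cos ψ) uniform (the geometric null)."""
        rng = np.random.default_rng(17)
        psis = np.degrees(np.arccos(rng.uniform(-1, 1, 3200)))
        traj = _fixture_with_psis(psis, n_shell=8, n_frames=400)
        topo = assign_water_topology(traj)
        series = shell_occupancy(traj, topo, ShellDefinition(3.4, "fixed"))
        _, centers, density = tilt_angle_distribution(traj, topo, series, n_bins=10)
        # each of 10 bins holds ~320 samples; 3σ multinomial tolerance
        se = np.sqrt(0.1 * 0.9 / 3200) / 0.2  # density units (bin width 0.2)
        assert np.all(np.abs(density - 0.5) < 3.5 * se)

    def test_law_centred_at_132_recovered(self):
        traj = gen_shell_fixture(
            n_shell=8, tilt_deg=132.0, tilt_spread_deg=15.0, n_frames=200, seed=23
        )
        topo = assign_water_topology(traj)
        series = shell_occupancy(traj, topo, ShellDefinition(3.4, "fixed"))
        mean_deg, _, _ = tilt_angle_distribution(traj, topo, series)
        n = 8 * 200
        se = 15.0 / np.sqrt(n)
        assert abs(mean_deg - 132.0) < 3 * se


def _fixture_with_psis(psis_deg, n_shell, n_frames):
    """Shell fixture whose per-(frame, water) tilt angles are given exactly."""
    from hydrashell.synthetic import gen_shell_fixture as gsf  # geometry helpers
    import hydrashell.synthetic as syn

    cell = SimulationCell.cubic(14.457)
    center = np.full(3, 14.457 / 2)
    dirs = syn._fibonacci_sphere(n_shell)
    rng = np.random.default_rng(99)
    coords = np.empty((n_frames, 1 + 3 * n_shell, 3))
    it = iter(psis_deg)
    for f in range(n_frames):
        coords[f, 0] = center
        for m in range(n_shell):
            u = dirs[m]
            o = center + 2.88 * u
            to_ion = -u
            psi = np.radians(next(it))
            e1, _ = syn._orthonormal_frame(to_ion)
            az = rng.random() * 2 * np.pi
            e1r = np.cos(az) * e1 + np.sin(az) * np.cross(to_ion, e1)
            dip = np.cos(psi) * to_ion + np.sin(psi) * e1r
            plane = syn._orthonormal_frame(dip)[0]
            h1, h2 = syn._water_atoms(o, dip, plane)
            coords[f, 1 + 3 * m] = o
            coords[f, 2 + 3 * m] = h1
            coords[f, 3 + 3 * m] = h2
    species = ["Ra"] + ["O", "H", "H"] * n_shell
    return Trajectory(cell, species, coords, np.arange(n_frames) * 10.0, 0, "Ra")


# ---------------------------------------------------------------------------
# invariances and the effective radius
# ---------------------------------------------------------------------------

class TestInvariances:
    def test_rigid_translation_leaves_metrics_unchanged(self):
        traj = gen_shell_fixture(
            n_shell=6, jitter=0.05, tilt_deg=120.0, tilt_spread_deg=20.0,
            n_frames=10, n_outer=10, seed=5,
        )
        topo = assign_water_topology(traj)
        sd = ShellDefinition(3.4, "fixed")
        base = compute_shell_metrics(traj, topo, shell_occupancy(traj, topo, sd))
        shifted = Trajectory(
            traj.cell,
            traj.species,
            traj.coords + np.array([3.1, -2.2, 0.7]),
            traj.times,
            traj.solute_index,
            traj.solute_species,
        )
        moved = compute_shell_metrics(shifted, topo, shell_occupancy(shifted, topo, sd))
        for attr in ("r_bar", "cn_mean", "sigma2", "c3", "eccentricity", "tilt_mean_deg"):
            assert getattr(moved, attr) == pytest.approx(getattr(base, attr), abs=1e-9)

    def test_water_relabeling_leaves_metrics_unchanged(self):
        traj = gen_shell_fixture(
            n_shell=6, jitter=0.05, tilt_deg=120.0, tilt_spread_deg=20.0,
            n_frames=10, n_outer=10, seed=5,
        )
        topo = assign_water_topology(traj)
        sd = ShellDefinition(3.4, "fixed")
        base = compute_shell_metrics(traj, topo, shell_occupancy(traj, topo, sd))
        from hydrashell.trajectory_io import WaterTopology

        rng = np.random.default_rng(1)
        perm = rng.permutation(topo.n_molecules)
        relabeled = WaterTopology(tuple(topo.molecules[i] for i in perm))
        out = compute_shell_metrics(
            traj, relabeled, shell_occupancy(traj, relabeled, sd)
        )
        for attr in ("r_bar", "cn_mean", "sigma2", "c3", "eccentricity", "tilt_mean_deg"):
            assert getattr(out, attr) == pytest.approx(getattr(base, attr), abs=1e-9)


@pytest.mark.parametrize(
    "r_bar,eir,expected", [(2.87, 1.48, 1.39), (2.79, 1.42, 1.37), (2.5, 2.5, 0.0)]
)
def test_effective_water_radius(r_bar, eir, expected):
    assert effective_water_radius(r_bar, eir) == pytest.approx(expected, abs=1e-12)
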