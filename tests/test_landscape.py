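"""Landscape construction, density interpolation, hotspot detection, rendering."""

import numpy as np
import pandas as pd
import pytest

import rotascape as rs


def wrapped_gaussian_draws(center, sigma, n, seed):
    rng = np.random.default_rng(seed)
    pts = np.asarray(center, float) + rng.standard_normal((n, 3)) * sigma
    pts[:, 0] = rs.wrap_angle(pts[:, 0])
    pts[:, 2] = rs.wrap_angle(pts[:, 2])
    pts[:, 1] = np.clip(pts[:, 1], -90, 90)
    return pts


class TestComputeOrientations:
    def test_equal_poses_give_zero_orientation(self):
        df = pd.DataFrame({
            "particle_id": ["a"], "expansion_index": [0],
            "rot_mod": [33.0], "tilt_mod": [70.0], "psi_mod": [-12.0],
            "rot_cond": [33.0], "tilt_cond": [70.0], "psi_cond": [-12.0],
        })
        orients = rs.compute_orientations(rs.ParticleTable(df))
        assert np.allclose(orients, [[0.0, 0.0, 0.0]], atol=1e-9)

    def test_zero_noise_scene_recovers_truth_exactly(self):
        truth = rs.SceneTruth(
            components=[rs.MixtureComponent(center=(13, 0, 14), sigma=0.0, weight=1.0)],
            n=20, noise_sigma=0.0, seed=2, c2_expand=False)
        mod, cond = rs.scene_tables(truth)
        paired = rs.pair_refinements(mod, cond)
        orients = rs.compute_orientations(paired)
        assert np.allclose(orients, np.tile([13.0, 0.0, 14.0], (20, 1)), atol=1e-9)

    def test_noise_bounded_alpha_error(self):
        truth = rs.SceneTruth(
            components=[rs.MixtureComponent(center=(13, 0, 14), sigma=0.0, weight=1.0)],
            n=1000, noise_sigma=2.0, seed=3, c2_expand=False)
        mod, cond = rs.scene_tables(truth)
        orients = rs.compute_orientations(rs.pair_refinements(mod, cond))
        rms = np.sqrt(np.mean(rs.wrap_angle(orients[:, 0] - 13.0) ** 2))
        # two independent noise rotations of scale sigma -> alpha RMS < ~2*sigma
        assert rms < 2 * truth.noise_sigma

    def test_canonicalized_invariant_to_expansion_copy_swap(self):
        truth = rs.default_scene(n=60, seed=4)
        mod, cond = rs.scene_tables(truth)
        paired = rs.pair_refinements(mod, cond)
        copy0 = paired.df[paired.df["expansion_index"] == 0].reset_index(drop=True)
        copy1 = paired.df[paired.df["expansion_index"] == 1].reset_index(drop=True)
        o0 = rs.compute_orientations(rs.ParticleTable(copy0), canonicalize_flag=True)
        o1 = rs.compute_orientations(rs.ParticleTable(copy1), canonicalize_flag=True)
        assert np.allclose(o0, o1, atol=1e-6)


class TestBuildLandscape:
    def test_single_particle_occupies_one_bin(self):
        grid = rs.build_landscape(np.array([[10.0, 5.0, -20.0]]), bin_width=2.0,
                                  smooth_sigma=0.0)
        assert grid.counts.sum() == 1
        idx = np.argwhere(grid.counts == 1)[0]
        centers = grid.centers
        assert abs(centers[0][idx[0]] - 10.0) <= 1.0
        assert abs(centers[1][idx[1]] - 5.0) <= 1.0
        assert abs(centers[2][idx[2]] + 20.0) <= 1.0

    def test_counts_conserved_and_density_normalized(self):
        pts = wrapped_gaussian_draws((0, 0, 0), 30, 5000, seed=5)
        grid = rs.build_landscape(pts)
        assert grid.counts.sum() == 5000
        assert grid.n_particles == 5000
        assert grid.density.min() >= 0
        assert abs(grid.density.sum() - 1.0) < 1e-9

    def test_boundary_angles_bin_correctly(self):
        # +180 and -180 are the same point on the periodic axes
        grid = rs.build_landscape(np.array([[180.0, 0.0, -180.0]]), smooth_sigma=0.0)
        assert grid.counts.sum() == 1

    def test_mode_recovery_single_component(self):
        pts = wrapped_gaussian_draws((13, 0, 14), 5, 20_000, seed=6)
        grid = rs.build_landscape(pts, bin_width=2.0, smooth_sigma=1.0)
        idx = np.unravel_index(np.argmax(grid.density), grid.density.shape)
        center = [grid.centers[ax][idx[ax]] for ax in range(3)]
        assert abs(center[0] - 13) <= 2.0
        assert abs(center[1] - 0) <= 2.0
        assert abs(center[2] - 14) <= 2.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="zero orientations"):
            rs.build_landscape(np.zeros((0, 3)))

    def test_save_load_round_trip(self, tmp_path):
        pts = wrapped_gaussian_draws((0, 0, 0), 10, 500, seed=7)
        grid = rs.build_landscape(pts)
        grid.save(tmp_path / "grid.npz")
        back = rs.LandscapeGrid.load(tmp_path / "grid.npz")
        assert np.array_equal(back.counts, grid.counts)
        assert np.allclose(back.density, grid.density)
        assert back.n_particles == grid.n_particles


class TestLocalDensity:
    def test_bin_center_returns_bin_value(self):
        pts = wrapped_gaussian_draws((0, 0, 0), 20, 2000, seed=8)
        grid = rs.build_landscape(pts)
        idx = np.unravel_index(np.argmax(grid.density), grid.density.shape)
        coord = [grid.centers[ax][idx[ax]] for ax in range(3)]
        assert rs.local_density(grid, coord) == pytest.approx(grid.density[idx])

    def test_zero_far_from_particles_without_smoothing(self):
        grid = rs.build_landscape(np.array([[0.0, 0.0, 0.0]]), smooth_sigma=0.0)
        assert rs.local_density(grid, (120.0, 45.0, -100.0)) == 0.0

    def test_interpolation_bounded_by_neighbouring_bins(self):
        pts = wrapped_gaussian_draws((0, 0, 0), 15, 3000, seed=9)
        grid = rs.build_landscape(pts)
        ca, cb, cg = grid.centers
        i, j, k = 90, 45, 90  # near the center of the grid
        lo = grid.density[i, j, k]
        hi = grid.density[i + 1, j, k]
        lo, hi = min(lo, hi), max(lo, hi)
        midpoint = ((ca[i] + ca[i + 1]) / 2, cb[j], cg[k])
        value = rs.local_density(grid, midpoint)
        assert lo - 1e-12 <= value <= hi + 1e-12


class TestHotspots:
    def test_uniform_density_has_no_strict_maxima(self):
        grid = rs.build_landscape(np.array([[1.0, 1.0, 1.0]]), smooth_sigma=0.0)
        grid.density = np.full_like(grid.density, 1.0 / grid.density.size)
        assert rs.find_hotspots(grid) == []

    def test_point_mass_gives_single_hotspot(self):
        grid = rs.build_landscape(np.array([[10.0, 5.0, -20.0]]), smooth_sigma=1.0)
        spots = rs.find_hotspots(grid, percentile=50)
        assert len(spots) == 1
        assert rs.orientation_distance(spots[0].center, (10, 5, -20)) < 3.5

    def test_two_separated_modes_found(self):
        pts = np.vstack([
            wrapped_gaussian_draws((-30, 0, 0), 5, 10_000, seed=10),
            wrapped_gaussian_draws((30, 0, 0), 5, 10_000, seed=11),
        ])
        grid = rs.build_landscape(pts)
        spots = rs.find_hotspots(grid, percentile=97.5, min_separation=10.0)
        assert len(spots) == 2
        found = sorted(h.center[0] for h in spots)
        assert abs(found[0] + 30) <= 2.0 and abs(found[1] - 30) <= 2.0
        for h in spots:
            assert abs(h.center[1]) <= 2.0 and abs(h.center[2]) <= 2.0

    def test_min_separation_prunes_to_strongest(self):
        pts = wrapped_gaussian_draws((0, 0, 0), 4, 20_000, seed=12)
        grid = rs.build_landscape(pts)
        spots = rs.find_hotspots(grid, percentile=50, min_separation=30.0)
        assert len(spots) == 1

    def test_sorted_by_descending_density(self):
        pts = np.vstack([
            wrapped_gaussian_draws((-40, 0, 0), 5, 15_000, seed=13),
            wrapped_gaussian_draws((40, 0, 0), 5, 5_000, seed=14),
        ])
        grid = rs.build_landscape(pts)
        spots = rs.find_hotspots(grid, percentile=90)
        densities = [h.density for h in spots]
        assert densities == sorted(densities, reverse=True)
        assert abs(spots[0].center[0] + 40) <= 2.0  # heavier mode first


class TestRender:
    def test_files_written_and_variance_ordering(self, tmp_path):
        narrow = rs.build_landscape(wrapped_gaussian_draws((0, 0, 0), 5, 3000, seed=15))
        broad = rs.build_landscape(wrapped_gaussian_draws((0, 0, 0), 40, 3000, seed=16))
        files = rs.render_landscape(broad, tmp_path / "plot", overlay=narrow)
        assert len(files) == 3
        for f in files:
            assert (tmp_path / f.split("/")[-1]).stat().st_size > 0
        assert narrow.marginal_variance(0) < broad.marginal_variance(0)

    def test_self_overlay_renders(self, tmp_path):
        grid = rs.build_landscape(wrapped_gaussian_draws((0, 0, 0), 20, 1000, seed=17))
        files = rs.render_landscape(grid, tmp_path / "self", overlay=grid)
        assert len(files) == 3
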