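"""Generator correctness: rendering, samplers, interval and plating fixtures."""

import math

import numpy as np
import pytest
import trimesh

from perinuc.envelope import nearest_surface_distance
from perinuc.io_formats import GenomicInterval
from perinuc.proximity import interval_gap
from perinuc.synthetic import (
    GroundTruth,
    SyntheticScene,
    make_colony_fixture,
    make_interval_fixture,
    nearest_distance_to_ellipsoid,
    render_nucleus_stack,
    sample_locus_positions,
)


class TestRenderNucleusStack:
    def test_brightest_locus_voxel_at_planted_center(self, centered_noiseless):
        scene, stack, truth = centered_noiseless
        locus = stack.channel("locus")
        iz, iy, ix = np.unravel_index(np.argmax(locus), locus.shape)
        dx, dy, dz = scene.voxel_size
        assert ((ix + 0.5) * dx, (iy + 0.5) * dy, (iz + 0.5) * dz) == pytest.approx(
            truth.spot_position, abs=1e-12
        )

    def test_seeded_rendering_is_bitwise_deterministic(self):
        a, _ = render_nucleus_stack(SyntheticScene(seed=7))
        b, _ = render_nucleus_stack(SyntheticScene(seed=7))
        np.testing.assert_array_equal(a.data, b.data)

    def test_sphere_ground_truth_volume(self):
        _, truth = render_nucleus_stack(
            SyntheticScene(nucleus_radii=(1.4, 1.4, 1.4), poisson_noise=False, seed=0)
        )
        assert truth.true_volume == pytest.approx(11.494, abs=5e-4)
        assert truth.true_effective_radius == pytest.approx(1.4)

    def test_nucleus_clipped_by_grid_rejected(self):
        with pytest.raises(ValueError, match="clipped"):
            SyntheticScene(nucleus_radii=(3.5, 3.5, 3.5))

    def test_negative_amplitude_rejected(self):
        with pytest.raises(ValueError):
            SyntheticScene(spot_amplitude=-1.0)

    def test_locus_photon_mass_matches_gaussian_integral(self, noiseless_sphere_14):
        # total above-background photons = A (2 pi)^{3/2} sxy^2 sz / voxel volume
        scene, stack, _ = noiseless_sphere_14
        locus = stack.channel("locus")
        dx, dy, dz = scene.voxel_size
        measured = (locus - scene.background).sum()
        expected = (
            scene.spot_amplitude
            * (2 * math.pi) ** 1.5
            * scene.psf_sigma_xy**2
            * scene.psf_sigma_z
            / (dx * dy * dz)
        )
        assert measured == pytest.approx(expected, rel=0.02)

    def test_scaled_depth_matches_fine_mesh_distance(self):
        # analytic nearest-surface depth vs a finely subdivided true-ellipsoid mesh
        scene = SyntheticScene(
            nucleus_radii=(1.5, 1.2, 1.1),
            spot_scaled_depth=0.35,
            spot_direction=(0.3, -1.0, 0.5),
            poisson_noise=False,
            read_noise_sd=0.0,
            seed=1,
        )
        _, truth = render_nucleus_stack(scene)
        mesh = trimesh.creation.icosphere(subdivisions=5, radius=1.0)
        mesh.vertices = mesh.vertices * np.array(scene.nucleus_radii)
        mesh.apply_translation(scene.nucleus_center)
        dist, inside = nearest_surface_distance(truth.spot_position, mesh)
        assert inside
        s_mesh = dist / truth.true_effective_radius
        assert s_mesh == pytest.approx(truth.true_scaled_depth, rel=0.01)


class TestEllipsoidDistance:
    @pytest.mark.parametrize("radii", [(1.0, 1.0, 1.0), (1.6, 1.2, 1.2), (1.5, 1.2, 0.9)])
    def test_matches_dense_surface_sampling(self, radii, rng):
        radii = np.array(radii)
        theta = rng.uniform(0, math.pi, 40000)
        phi = rng.uniform(0, 2 * math.pi, 40000)
        surf = np.stack(
            [
                radii[0] * np.sin(theta) * np.cos(phi),
                radii[1] * np.sin(theta) * np.sin(phi),
                radii[2] * np.cos(theta),
            ],
            axis=1,
        )
        for _ in range(5):
            p = rng.normal(scale=0.5, size=3)
            exact = nearest_distance_to_ellipsoid(p, radii)
            sampled = np.linalg.norm(surf - p, axis=1).min()
            assert exact == pytest.approx(sampled, abs=5e-3)


class TestSampleLocusPositions:
    def test_uniform_ball_mean_radius(self):
        pts = sample_locus_positions(100_000, "uniform_volume", seed=1)
        r = np.linalg.norm(pts, axis=1)
        # E[r] = 3/4 for the uniform unit ball; sd(r) = sqrt(3/80)
        se = math.sqrt(3 / 80) / math.sqrt(len(r))
        assert abs(r.mean() - 0.75) < 3 * se

    @pytest.mark.parametrize("mode,kw", [("uniform_volume", {}), ("periphery_biased", {"depth_scale": 0.05})])
    def test_all_points_inside_unit_ball(self, mode, kw):
        pts = sample_locus_positions(5000, mode, seed=2, **kw)
        r = np.linalg.norm(pts, axis=1)
        assert np.all((r >= 0) & (r <= 1 + 1e-12))

    def test_periphery_bias_concentrates_near_surface(self):
        pts = sample_locus_positions(10_000, "periphery_biased", depth_scale=0.05, seed=3)
        s = 1 - np.linalg.norm(pts, axis=1)
        # truncated exponential: P(s < 0.15) = (1 - e^-3) / (1 - e^-20) = 0.950
        assert (s < 0.15).mean() > 0.80

    def test_nonpositive_depth_scale_rejected(self):
        with pytest.raises(ValueError):
            sample_locus_positions(10, "periphery_biased", depth_scale=0.0, seed=0)


class TestIntervalFixture:
    def test_planted_fraction_one_puts_every_feature_near_a_peak(self):
        features, peaks, truth = make_interval_fixture(
            20, 20, {"chrI": 2_000_000}, planted_fraction=1.0, seed=0
        )
        assert all(truth.values())
        for ft in features:
            assert min(interval_gap(ft, pk) for pk in peaks) <= 600

    def test_half_planted_marks_exactly_twenty_of_forty(self):
        _, _, truth = make_interval_fixture(
            40, 25, {"chrI": 3_000_000, "chrII": 2_000_000}, planted_fraction=0.5, seed=1
        )
        assert sum(truth.values()) == 20

    @pytest.mark.parametrize("seed", range(5))
    def test_brute_force_scan_reproduces_truth_labels(self, seed):
        features, peaks, truth = make_interval_fixture(
            30, 40, {"chrI": 3_000_000, "chrII": 2_500_000},
            planted_fraction=0.4, threshold_bp=600, seed=seed,
        )
        for ft in features:
            near = min(interval_gap(ft, pk) for pk in peaks) <= 600
            assert near == truth[ft.name]

    def test_too_short_chromosome_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            make_interval_fixture(50, 10, {"chrI": 10_000}, planted_fraction=0.5, seed=0)


class TestColonyFixture:
    def test_zero_rate_gives_zero_selective_counts(self):
        df = make_colony_fixture(0.0, n_cultures=30, seed=0)
        assert (df["colonies_selective"] == 0).all()

    def test_mean_selective_count_matches_poisson_mean(self):
        df = make_colony_fixture(1.5e-5, cells_plated_selective=1e6, n_cultures=200, seed=4)
        mean = df["colonies_selective"].mean()
        se = math.sqrt(15 / 200)
        assert abs(mean - 15) < 3 * se

    def test_seeded_fixture_is_reproducible(self):
        a = make_colony_fixture(2e-5, n_cultures=10, seed=9)
        b = make_colony_fixture(2e-5, n_cultures=10, seed=9)
        assert a.equals(b)
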