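"""Envelope reconstruction: initial mesh, energies, descent, mesh geometry."""

import math

import numpy as np
import pytest
import trimesh

from perinuc.envelope import (
    EnergyConfig,
    _point_triangle_distances,
    initial_mesh,
    mesh_volume,
    nearest_surface_distance,
    reconstruct,
    total_energy,
)
from perinuc.io_formats import ImageStack
from perinuc.synthetic import SyntheticScene, render_nucleus_stack


def brute_force_distance(p, triangles):
    """Independent closest-distance oracle: enumerate the candidate closest
    points of every triangle (3 vertices, 3 clamped edge projections, the
    in-plane projection when its barycentric coordinates are admissible)."""
    best = math.inf
    for a, b, c in triangles:
        for q in (a, b, c):
            best = min(best, float(np.linalg.norm(p - q)))
        for u, v in ((a, b), (b, c), (a, c)):
            e = v - u
            t = float(np.clip(np.dot(p - u, e) / np.dot(e, e), 0, 1))
            best = min(best, float(np.linalg.norm(p - (u + t * e))))
        n = np.cross(b - a, c - a)
        nn = float(np.dot(n, n))
        if nn > 0:
            q = p - np.dot(p - a, n) / nn * n
            v0, v1, v2 = b - a, c - a, q - a
            d00, d01, d11 = np.dot(v0, v0), np.dot(v0, v1), np.dot(v1, v1)
            d20, d21 = np.dot(v2, v0), np.dot(v2, v1)
            den = d00 * d11 - d01 * d01
            if den > 0:
                bv = (d11 * d20 - d01 * d21) / den
                bw = (d00 * d21 - d01 * d20) / den
                if bv >= 0 and bw >= 0 and bv + bw <= 1:
                    best = min(best, float(np.linalg.norm(p - q)))
    return best


class TestInitialMesh:
    def test_radius_estimate_within_ten_percent(self, noiseless_sphere_14):
        _, stack, _ = noiseless_sphere_14
        mesh = initial_mesh(stack)
        center = mesh.vertices.mean(axis=0)
        r0 = np.linalg.norm(mesh.vertices - center, axis=1).mean()
        assert r0 == pytest.approx(1.4, rel=0.10)

    def test_blank_membrane_channel_rejected(self):
        stack = ImageStack(np.full((2, 10, 16, 16), 5.0), voxel_size=(0.1, 0.1, 0.26),
                           channel_names=("membrane", "locus"))
        with pytest.raises(ValueError, match="no nucleus"):
            initial_mesh(stack)

    def test_largest_of_two_nuclei_chosen(self):
        # two blurred blobs, one twice the radius: mesh centers on the larger
        from scipy.ndimage import gaussian_filter

        vol = np.zeros((20, 64, 64))
        zz, yy, xx = np.ogrid[:20, :64, :64]
        big = ((zz - 10) ** 2 * 4 + (yy - 16) ** 2 + (xx - 16) ** 2) < 12**2
        small = ((zz - 10) ** 2 * 4 + (yy - 48) ** 2 + (xx - 48) ** 2) < 6**2
        vol[big | small] = 100.0
        vol = gaussian_filter(vol, (1, 2, 2)) + 5.0
        stack = ImageStack(vol[None], voxel_size=(0.1, 0.1, 0.26), channel_names=("membrane",))
        mesh = initial_mesh(stack)
        cx, cy = mesh.vertices.mean(axis=0)[:2]
        assert abs(cx - 16.5 * 0.1) < 0.3 and abs(cy - 16.5 * 0.1) < 0.3


class TestTotalEnergy:
    def test_bending_energy_penalizes_vertex_displacement(self, noiseless_sphere_14):
        _, stack, _ = noiseless_sphere_14
        cfg = EnergyConfig(lambda_bend=1.0, lambda_image=0.0)
        sphere = trimesh.creation.icosphere(subdivisions=3, radius=1.4)
        sphere.apply_translation([3.4, 3.4, 5.2])
        e_sphere = total_energy(sphere, stack, cfg)
        bumped = sphere.copy()
        v = np.array(bumped.vertices)
        v[0] += 0.2 * (v[0] - v.mean(axis=0)) / np.linalg.norm(v[0] - v.mean(axis=0))
        bumped = trimesh.Trimesh(v, bumped.faces, process=False)
        assert e_sphere < total_energy(bumped, stack, cfg)

    def test_image_energy_rewards_sitting_on_the_shell(self, noiseless_sphere_14):
        scene, stack, _ = noiseless_sphere_14
        cfg = EnergyConfig(lambda_bend=0.0, lambda_image=1.0)
        on_shell = trimesh.creation.icosphere(subdivisions=3, radius=1.4)
        on_shell.apply_translation(scene.nucleus_center)
        shrunk = trimesh.creation.icosphere(subdivisions=3, radius=1.4 * 0.7)
        shrunk.apply_translation(scene.nucleus_center)
        assert total_energy(on_shell, stack, cfg) < total_energy(shrunk, stack, cfg)

    def test_zero_image_weight_reduces_to_pure_bending(self, noiseless_sphere_14):
        _, stack, _ = noiseless_sphere_14
        mesh = trimesh.creation.icosphere(subdivisions=2, radius=1.0)
        mesh.apply_translation([3.4, 3.4, 5.2])
        cfg_b = EnergyConfig(lambda_bend=2.5, lambda_image=0.0)
        cfg_unit = EnergyConfig(lambda_bend=1.0, lambda_image=0.0)
        assert total_energy(mesh, stack, cfg_b) == pytest.approx(
            2.5 * total_energy(mesh, stack, cfg_unit)
        )

    def test_both_weights_zero_rejected(self):
        with pytest.raises(ValueError):
            EnergyConfig(lambda_bend=0.0, lambda_image=0.0)


class TestReconstruct:
    def test_noiseless_sphere_recovery(self, noiseless_sphere_14):
        _, stack, truth = noiseless_sphere_14
        nuc = reconstruct(stack)
        assert nuc.converged
        assert nuc.volume == pytest.approx(truth.true_volume, rel=0.08)
        assert nuc.effective_radius == pytest.approx(1.4, rel=0.03)

    def test_prolate_ellipsoid_recovery(self):
        scene = SyntheticScene(nucleus_radii=(1.6, 1.2, 1.2),
                               poisson_noise=False, read_noise_sd=0.0, seed=5)
        stack, truth = render_nucleus_stack(scene)
        nuc = reconstruct(stack)
        assert nuc.volume == pytest.approx(4 / 3 * math.pi * 1.6 * 1.2**2, rel=0.10)

    def test_reconstruction_is_deterministic(self, noisy_default):
        _, stack, _ = noisy_default
        a = reconstruct(stack)
        b = reconstruct(stack)
        np.testing.assert_array_equal(np.asarray(a.mesh.vertices), np.asarray(b.mesh.vertices))

    def test_energy_non_increasing_with_more_iterations(self, noisy_default):
        # the descent trajectory is deterministic, so a longer run extends the
        # shorter one and can only lower the (monotone) energy
        _, stack, _ = noisy_default
        short = reconstruct(stack, EnergyConfig(max_iterations=40, correct_psf_bias=False))
        long = reconstruct(stack, EnergyConfig(max_iterations=120, correct_psf_bias=False))
        assert long.final_energy <= short.final_energy + 1e-12

    def test_effective_radius_consistent_with_volume(self, noisy_default):
        _, stack, _ = noisy_default
        nuc = reconstruct(stack)
        assert nuc.effective_radius**3 * 4 * math.pi / 3 == pytest.approx(nuc.volume, rel=1e-12)


class TestMeshVolume:
    def test_icosphere_volume_close_to_analytic(self):
        m = trimesh.creation.icosphere(subdivisions=3, radius=1.0)
        assert mesh_volume(m) == pytest.approx(4 * math.pi / 3, rel=0.02)

    def test_volume_scales_cubically(self):
        m = trimesh.creation.icosphere(subdivisions=2, radius=1.0)
        doubled = trimesh.Trimesh(np.array(m.vertices) * 2, m.faces, process=False)
        assert mesh_volume(doubled) == pytest.approx(8 * mesh_volume(m), rel=1e-12)

    def test_open_mesh_rejected(self):
        tri = trimesh.Trimesh([[0, 0, 0], [1, 0, 0], [0, 1, 0]], [[0, 1, 2]], process=False)
        with pytest.raises(ValueError, match="closed"):
            mesh_volume(tri)


class TestNearestSurfaceDistance:
    def test_center_of_icosphere(self):
        m = trimesh.creation.icosphere(subdivisions=3, radius=1.2)
        d, inside = nearest_surface_distance([0, 0, 0], m)
        assert inside
        assert d == pytest.approx(1.2, rel=0.02)

    def test_point_on_vertex_has_zero_distance(self):
        m = trimesh.creation.icosphere(subdivisions=2, radius=1.0)
        d, _ = nearest_surface_distance(np.array(m.vertices[5]), m)
        assert d == pytest.approx(0.0, abs=1e-12)

    def test_matches_brute_force_oracle(self, rng):
        m = trimesh.creation.icosphere(subdivisions=2, radius=1.0)
        m.apply_translation([0.3, -0.2, 0.5])
        tri = np.asarray(m.triangles)
        for _ in range(200):
            p = rng.normal(scale=1.2, size=3)
            fast = float(_point_triangle_distances(p, tri).min())
            assert fast == pytest.approx(brute_force_distance(p, tri), abs=1e-9)

    def test_invariant_under_rigid_motion(self, rng):
        from scipy.spatial.transform import Rotation

        m = trimesh.creation.icosphere(subdivisions=2, radius=1.0)
        p = np.array([0.4, 0.1, -0.6])
        d0, in0 = nearest_surface_distance(p, m)
        R = Rotation.from_rotvec([0.3, -1.1, 0.7]).as_matrix()
        t = np.array([2.0, -3.0, 0.5])
        moved = trimesh.Trimesh(np.array(m.vertices) @ R.T + t, m.faces, process=False)
        d1, in1 = nearest_surface_distance(R @ p + t, moved)
        assert d1 == pytest.approx(d0, abs=1e-9)
        assert in0 == in1
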