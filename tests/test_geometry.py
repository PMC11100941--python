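"""Mesh geometry: transforms, normalization, signed distance, ASSD, marching cubes."""

import numpy as np
import pytest

from kneeshape.geometry import (
    EmptySurfaceError,
    NotWatertightError,
    SDFGrid,
    SimilarityTransform,
    TriangleMesh,
    TriangleMeshPair,
    apply_transform,
    assd,
    extract_surface,
    grid_coordinates,
    invert_transform,
    normalize_unit_sphere,
    register_similarity,
    rotation_about_axis,
    signed_distance,
)

from conftest import icosphere_mesh
from oracles import brute_assd, brute_signed_distance


class TestSimilarityTransform:
    def test_identity_leaves_vertices_unchanged(self, sphere):
        out = apply_transform(sphere, SimilarityTransform())
        np.testing.assert_allclose(out.vertices, sphere.vertices)

    def test_round_trip_recovers_vertices(self, sphere):
        rng = np.random.default_rng(0)
        t = SimilarityTransform(
            scale=2.3,
            rotation=rotation_about_axis(rng.normal(size=3), 41.0),
            translation=rng.normal(size=3),
        )
        out = apply_transform(apply_transform(sphere, t), invert_transform(t))
        diam = np.ptp(sphere.vertices, axis=0).max()
        assert np.abs(out.vertices - sphere.vertices).max() < 1e-6 * diam

    def test_compose_matches_sequential_application(self, sphere):
        rng = np.random.default_rng(1)
        t1 = SimilarityTransform(1.4, rotation_about_axis([0, 0, 1], 30), rng.normal(size=3))
        t2 = SimilarityTransform(0.6, rotation_about_axis([1, 0, 0], -15), rng.normal(size=3))
        seq = t2.apply(t1.apply(sphere.vertices))
        comp = t2.compose(t1).apply(sphere.vertices)
        np.testing.assert_allclose(seq, comp, atol=1e-10)

    def test_zero_scale_rejected(self):
        with pytest.raises(ValueError):
            SimilarityTransform(scale=0.0)


class TestNormalization:
    def test_bone_centered_and_max_radius_one(self, shell_pair):
        pair, _ = shell_pair
        shifted = TriangleMeshPair(
            TriangleMesh(pair.bone.vertices + [10, 0, 0], pair.bone.faces),
            TriangleMesh(pair.cartilage.vertices + [10, 0, 0], pair.cartilage.faces),
        )
        normalized, t = normalize_unit_sphere(shifted)
        assert np.linalg.norm(normalized.bone.vertices.mean(axis=0)) < 1e-9
        radii = np.linalg.norm(
            np.vstack([normalized.bone.vertices, normalized.cartilage.vertices]), axis=1
        )
        assert radii.max() == pytest.approx(1.0, abs=1e-12)
        # transform maps original into normalized frame
        np.testing.assert_allclose(t.apply(shifted.bone.vertices), normalized.bone.vertices)

    def test_cartilage_can_set_the_scale(self, shell_pair):
        # the shell extends past the bone, so the cartilage fixes the radius
        pair, _ = shell_pair
        normalized, _ = normalize_unit_sphere(pair)
        bone_r = np.linalg.norm(normalized.bone.vertices, axis=1).max()
        cart_r = np.linalg.norm(normalized.cartilage.vertices, axis=1).max()
        assert cart_r == pytest.approx(1.0, abs=1e-12)
        assert bone_r < 1.0

    def test_already_normalized_pair_gets_identity(self, shell_pair):
        pair, _ = shell_pair
        normalized, _ = normalize_unit_sphere(pair)
        again, t = normalize_unit_sphere(normalized)
        assert t.scale == pytest.approx(1.0, rel=1e-9)
        assert np.linalg.norm(t.translation) < 1e-9


class TestSignedDistance:
    def test_sphere_center_and_vertex(self, sphere):
        s = signed_distance(sphere, np.array([[0.0, 0.0, 0.0], sphere.vertices[0]]))
        assert s[0] == pytest.approx(-1.0, abs=0.01)  # faceting tolerance
        assert abs(s[1]) < 1e-9

    def test_matches_brute_force_oracle(self, ellipsoid):
        rng = np.random.default_rng(4)
        pts = rng.uniform(-1.5, 1.5, (100, 3))
        got = signed_distance(ellipsoid, pts)
        want = brute_signed_distance(ellipsoid.vertices, ellipsoid.faces, pts)
        assert np.abs(got - want).max() < 1e-9

    def test_far_point_outside_ellipsoid(self, ellipsoid):
        s = signed_distance(ellipsoid, np.array([[2.0, 0.0, 0.0]]))
        assert s[0] == pytest.approx(1.0, abs=0.01)

    def test_open_mesh_rejected_with_edge_count(self, sphere):
        open_mesh = TriangleMesh(sphere.vertices, sphere.faces[:-2])
        with pytest.raises(NotWatertightError, match=r"\d+ open edges"):
            signed_distance(open_mesh, np.zeros((1, 3)))


class TestASSD:
    def test_zero_on_identical_meshes(self, sphere):
        assert assd(sphere, sphere) == 0.0

    def test_concentric_spheres_close_to_radius_gap(self):
        a = icosphere_mesh(subdivisions=4, radius=1.0)
        b = icosphere_mesh(subdivisions=4, radius=1.1)
        assert assd(a, b) == pytest.approx(0.1, abs=0.005)

    def test_symmetric_and_matches_brute_force(self):
        a = icosphere_mesh(subdivisions=1, radius=1.0)  # 80 faces
        b = TriangleMesh(a.vertices + [0.05, 0.0, 0.0], a.faces)
        got = assd(a, b)
        assert got == pytest.approx(assd(b, a), abs=1e-12)
        want = brute_assd(a.vertices, a.faces, b.vertices, b.faces)
        assert got == pytest.approx(want, abs=1e-9)


class TestExtractSurface:
    @staticmethod
    def _sphere_grid(radius: float, resolution: int) -> SDFGrid:
        coords = grid_coordinates(resolution)
        vals = np.linalg.norm(coords, axis=1) - radius
        return SDFGrid(vals.reshape((resolution,) * 3))

    def test_analytic_sphere_within_grid_spacing(self):
        grid = self._sphere_grid(0.7, 64)
        mesh = extract_surface(grid)
        r = np.linalg.norm(mesh.vertices, axis=1)
        assert np.abs(r - 0.7).max() <= grid.spacing
        assert mesh.is_watertight()
        assert mesh.to_trimesh().volume > 0  # outward orientation

    def test_single_sign_grid_raises(self):
        grid = SDFGrid(np.ones((8, 8, 8)))
        with pytest.raises(EmptySurfaceError):
            extract_surface(grid)

    def test_sign_flip_gives_same_geometry(self):
        grid = self._sphere_grid(0.6, 48)
        flipped = SDFGrid(-grid.values)
        a = extract_surface(grid)
        b = extract_surface(flipped)
        assert assd(a, b) < grid.spacing * 0.1
        assert b.to_trimesh().volume > 0  # orientation repaired to outward

    @pytest.mark.parametrize("resolution", [48, 64])
    def test_ellipsoid_fidelity_within_spacing(self, resolution):
        coords = grid_coordinates(resolution)
        # analytic-ish ellipsoid SDF surrogate: exact on axes, smooth field
        vals = np.linalg.norm(coords / np.array([0.8, 0.55, 0.4]), axis=1) - 1.0
        grid = SDFGrid(vals.reshape((resolution,) * 3))
        mesh = extract_surface(grid)
        lhs = np.linalg.norm(mesh.vertices / np.array([0.8, 0.55, 0.4]), axis=1)
        # vertices lie on the implicit surface to within ~1 grid spacing
        assert np.abs(lhs - 1.0).max() < 1.5 * grid.spacing / 0.4


class TestRegistration:
    def test_identity_for_same_mesh(self, population):
        bone = population[0].pair.bone
        t = register_similarity(bone, bone)
        assert t.scale == pytest.approx(1.0, abs=1e-6)
        assert np.linalg.norm(t.translation) < 1e-6
        np.testing.assert_allclose(t.rotation, np.eye(3), atol=1e-6)

    def test_recovers_known_similarity(self, population):
        bone = population[0].pair.bone
        true = SimilarityTransform(
            scale=2.0,
            rotation=rotation_about_axis([0, 0, 1], 30.0),
            translation=np.array([5.0, 0.0, 0.0]),
        )
        moved = apply_transform(bone, true)
        rec = register_similarity(moved, bone)
        inv = true.invert()
        assert abs(rec.scale - inv.scale) / inv.scale < 0.01
        cos = (np.trace(rec.rotation @ inv.rotation.T) - 1) / 2
        assert np.degrees(np.arccos(np.clip(cos, -1, 1))) < 1.0
        diam = np.ptp(bone.vertices, axis=0).max()
        assert np.linalg.norm(rec.translation - inv.translation) < 0.01 * diam

    def test_degenerate_mesh_rejected(self):
        flat = TriangleMesh(np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0.0]]), np.array([[0, 1, 2], [1, 3, 2]]))
        with pytest.raises(Exception):
            register_similarity(flat, flat)
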