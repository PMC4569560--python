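import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from adhesim.geometry import (
    FaceSet,
    GeometryError,
    Pose,
    SurfaceMesh,
    cap_for_max_edge,
    face_properties,
    gated_face_pairs,
    icosphere_for_max_edge,
    load_obj,
    make_icosphere,
    make_pmn_cap,
    write_off,
    write_vtk_polydata,
)

UM = 1.0e-6


def triangle_area_oracle(mesh: SurfaceMesh) -> np.ndarray:
    """Independent per-face area computation (explicit loop, cross product)."""
    out = []
    for tri in mesh.faces:
        a, b, c = (mesh.vertices[i] for i in tri)
        out.append(0.5 * np.linalg.norm(np.cross(b - a, c - a)))
    return np.asarray(out)


def random_pose(rng) -> Pose:
    q = Rotation.random(rng=rng).as_quat()
    return Pose(rng.uniform(-10 * UM, 10 * UM, 3), q)


class TestIcosphere:
    @pytest.mark.parametrize("subdiv,expected", [(0, 20), (1, 80), (3, 1280)])
    def test_face_count(self, subdiv, expected):
        assert make_icosphere(4 * UM, subdiv).n_faces == expected

    def test_area_converges_to_sphere(self):
        errors = []
        for s in range(5):
            mesh = make_icosphere(4 * UM, s)
            total = triangle_area_oracle(mesh).sum()
            errors.append(abs(total - 4 * np.pi * (4 * UM) ** 2) / (4 * np.pi * (4 * UM) ** 2))
        assert errors[3] < 0.02  # within 2% at subdivision 3
        assert all(e2 < e1 for e1, e2 in zip(errors, errors[1:]))  # monotone

    def test_max_edge_decreases_with_subdivision(self):
        edges = [make_icosphere(4 * UM, s).max_edge_length() for s in range(4)]
        assert all(e2 < e1 for e1, e2 in zip(edges, edges[1:]))

    def test_invalid_parameters(self):
        with pytest.raises(GeometryError):
            make_icosphere(0.0, 2)
        with pytest.raises(GeometryError):
            make_icosphere(4 * UM, -1)

    def test_max_element_selection_is_smallest_sufficient(self):
        mesh = icosphere_for_max_edge(4 * UM, 1.5 * UM)
        assert mesh.max_edge_length() <= 1.5 * UM
        # one level coarser must violate the bound
        coarser = make_icosphere(4 * UM, int(round(math.log(mesh.n_faces / 20, 4))) - 1)
        assert coarser.max_edge_length() > 1.5 * UM


class TestPMNCap:
    def test_hemisphere_centroid_height(self):
        # solid hemisphere of radius r: volume centroid at 3r/8 above the base
        cap = make_pmn_cap(5 * UM, 5 * UM, 24)
        assert cap.volume_centroid()[1] == pytest.approx(3 * 5 * UM / 8, rel=5e-3)

    def test_closed_and_on_substrate(self):
        cap = make_pmn_cap(5 * UM, 3 * UM, 12)
        assert cap.is_closed()
        assert cap.vertices[:, 1].min() >= 0.0
        assert cap.vertices[:, 1].max() == pytest.approx(3 * UM)

    def test_refinement_monotonicity(self):
        lo = make_pmn_cap(5 * UM, 5 * UM, 8)
        hi = make_pmn_cap(5 * UM, 5 * UM, 16)
        assert hi.n_faces > lo.n_faces
        lo_areas = triangle_area_oracle(lo)
        hi_areas = triangle_area_oracle(hi)
        assert hi_areas.max() < lo_areas.max()

    def test_degenerate_dimensions_rejected(self):
        with pytest.raises(GeometryError):
            make_pmn_cap(0.0, 5 * UM, 8)
        with pytest.raises(GeometryError):
            make_pmn_cap(5 * UM, -1 * UM, 8)

    def test_cap_for_max_edge(self):
        cap = cap_for_max_edge(5 * UM, 5 * UM, 1.0 * UM)
        assert cap.max_edge_length() <= 1.0 * UM
        assert cap.is_closed()


class TestFaceProperties:
    def test_identity_pose_matches_body_frame(self):
        mesh = make_icosphere(4 * UM, 1)
        fs = face_properties(mesh, Pose.identity())
        tri = mesh.vertices[mesh.faces]
        np.testing.assert_allclose(fs.centroids, tri.mean(axis=1))
        np.testing.assert_allclose(fs.areas, triangle_area_oracle(mesh))

    def test_translation_shifts_centroids_only(self):
        mesh = make_icosphere(4 * UM, 1)
        t = np.array([3.0, -2.0, 7.0]) * UM
        a = face_properties(mesh, Pose.identity())
        b = face_properties(mesh, Pose.identity(t))
        np.testing.assert_allclose(b.centroids, a.centroids + t)
        np.testing.assert_allclose(b.areas, a.areas)
        np.testing.assert_allclose(b.normals, a.normals)
        np.testing.assert_allclose(b.lever_arms, a.lever_arms, atol=1e-18)

    def test_rotation_rotates_normals_preserves_area(self):
        mesh = make_icosphere(4 * UM, 1)
        q = Rotation.from_euler("z", 90, degrees=True).as_quat()
        a = face_properties(mesh, Pose.identity())
        b = face_properties(mesh, Pose(np.zeros(3), q))
        R = Rotation.from_quat(q).as_matrix()
        np.testing.assert_allclose(b.normals, a.normals @ R.T, atol=1e-12)
        assert b.total_area() == pytest.approx(a.total_area(), rel=1e-12)

    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_rigid_motion_invariance(self, seed):
        """Areas and within-body centroid distances survive any rigid pose."""
        rng = np.random.default_rng(seed)
        mesh = make_icosphere(4 * UM, 1)
        ref = face_properties(mesh, Pose.identity())
        moved = face_properties(mesh, random_pose(rng))
        np.testing.assert_allclose(moved.areas, ref.areas, rtol=1e-12)
        d_ref = np.linalg.norm(ref.centroids[0] - ref.centroids[1:], axis=1)
        d_mov = np.linalg.norm(moved.centroids[0] - moved.centroids[1:], axis=1)
        np.testing.assert_allclose(d_mov, d_ref, rtol=1e-12)


def single_face_set(position, body_id="b") -> FaceSet:
    p = np.asarray(position, dtype=float)
    return FaceSet(
        body_id=body_id,
        face_ids=np.array([0]),
        centroids=p[None, :],
        areas=np.array([1.0 * UM ** 2]),
        normals=np.array([[0.0, 1.0, 0.0]]),
        lever_arms=np.zeros((1, 3)),
        body_centroid=p.copy(),
    )


def cloud_face_set(rng, n, body_id) -> FaceSet:
    c = rng.uniform(0, 10 * UM, (n, 3))
    return FaceSet(
        body_id=body_id,
        face_ids=np.arange(n),
        centroids=c,
        areas=np.full(n, 1.0 * UM ** 2),
        normals=np.tile([0.0, 1.0, 0.0], (n, 1)),
        lever_arms=c - c.mean(axis=0),
        body_centroid=c.mean(axis=0),
    )


class TestGatedFacePairs:
    def test_three_four_five_triangle(self):
        tc = single_face_set([0.0, 0.0, 0.0], "tc")
        pmn = single_face_set([3 * UM, 4 * UM, 0.0], "pmn")
        pairs = gated_face_pairs(tc, pmn, 6 * UM)
        assert len(pairs) == 1
        assert pairs.distance[0] == pytest.approx(5 * UM)
        np.testing.assert_allclose(pairs.e_hat[0], [0.6, 0.8, 0.0])

    def test_all_pairs_beyond_cutoff_empty(self):
        tc = single_face_set([0.0, 0.0, 0.0], "tc")
        pmn = single_face_set([3 * UM, 4 * UM, 0.0], "pmn")
        assert len(gated_face_pairs(tc, pmn, 1.2 * UM)) == 0

    def test_e_hat_antisymmetric_under_swap(self, rng):
        a = cloud_face_set(rng, 10, "tc")
        b = cloud_face_set(rng, 10, "pmn")
        ab = gated_face_pairs(a, b, 8 * UM)
        ba = gated_face_pairs(b, a, 8 * UM)
        fwd = {(int(t), int(p)): e for t, p, e in zip(ab.tc_ids, ab.pmn_ids, ab.e_hat)}
        for t, p, e in zip(ba.tc_ids, ba.pmn_ids, ba.e_hat):
            np.testing.assert_allclose(e, -fwd[(int(p), int(t))], atol=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        tc = cloud_face_set(rng, 50, "tc")
        pmn = cloud_face_set(rng, 50, "pmn")
        cutoff = rng.uniform(1.0, 6.0) * UM
        pairs = gated_face_pairs(tc, pmn, cutoff)
        got = {(int(t), int(p)): d for t, p, d in zip(pairs.tc_ids, pairs.pmn_ids, pairs.distance)}
        expected = {}
        for i in range(50):
            for j in range(50):
                d = math.dist(tc.centroids[i], pmn.centroids[j])
                if d < cutoff:
                    expected[(i, j)] = d
        assert got.keys() == expected.keys()
        for k in expected:
            assert got[k] == pytest.approx(expected[k], rel=1e-12)


class TestMeshIO:
    def test_off_round_trip(self, tmp_path):
        mesh = make_icosphere(4 * UM, 1)
        path = tmp_path / "tc.off"
        write_off(mesh, path)
        back = load_obj(path)
        np.testing.assert_allclose(back.vertices, mesh.vertices, rtol=1e-8)
        assert back.n_faces == mesh.n_faces

    def test_vtk_header(self, tmp_path):
        mesh = make_icosphere(4 * UM, 0)
        path = tmp_path / "tc.vtk"
        write_vtk_polydata(mesh, path)
        text = path.read_text().splitlines()
        assert text[0].startswith("# vtk DataFile")
        assert "DATASET POLYDATA" in text
        assert f"POINTS {len(mesh.vertices)} double" in text
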