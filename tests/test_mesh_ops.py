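import numpy as np
import pytest
import trimesh as _trimesh

from osseosurf import phantom
from osseosurf.mesh_ops import (
    MeasurementArea,
    TriMesh,
    apply_transform,
    grow_patch,
    map_area,
    nearest_triangle,
    read_mesh,
    unify_areas,
    write_mesh,
)
from osseosurf.registration import RigidTransform

from conftest import make_planar_grid


@pytest.fixture
def cube_mesh():
    return TriMesh.from_trimesh(_trimesh.creation.box(extents=(2.0, 2.0, 2.0)))


class TestIO:
    def test_obj_round_trip_identical(self, tmp_path, cube_mesh):
        p = tmp_path / "cube.obj"
        write_mesh(cube_mesh, p)
        back = read_mesh(p)
        assert np.allclose(back.vertices, cube_mesh.vertices)
        assert np.array_equal(back.faces, cube_mesh.faces)

    def test_stl_cube_rewelds_to_eight_vertices(self, tmp_path, cube_mesh):
        p = tmp_path / "cube.stl"
        write_mesh(cube_mesh, p)
        back = read_mesh(p)
        assert back.n_vertices == 8
        assert back.n_faces == 12

    def test_ply_round_trip(self, tmp_path, cube_mesh):
        p = tmp_path / "cube.ply"
        write_mesh(cube_mesh, p)
        back = read_mesh(p)
        assert back.n_faces == 12

    def test_truncated_stl_rejected(self, tmp_path, cube_mesh):
        p = tmp_path / "cube.stl"
        write_mesh(cube_mesh, p)
        data = p.read_bytes()
        (tmp_path / "bad.stl").write_bytes(data[: len(data) // 2])
        with pytest.raises((IOError, ValueError)):
            read_mesh(tmp_path / "bad.stl")

    def test_unknown_format_rejected(self, tmp_path, cube_mesh):
        with pytest.raises(ValueError):
            write_mesh(cube_mesh, tmp_path / "cube.xyz")

    def test_stl_round_trip_preserves_geometry(self, tmp_path, face_truth_small):
        p = tmp_path / "face.stl"
        write_mesh(face_truth_small, p)
        back = read_mesh(p)
        assert back.n_faces == face_truth_small.n_faces
        assert np.allclose(
            np.sort(back.vertices.ravel()), np.sort(face_truth_small.vertices.ravel()),
            atol=1e-5,
        )


class TestValidation:
    def test_out_of_range_face_index(self):
        with pytest.raises(ValueError):
            TriMesh(np.zeros((3, 3)), [[0, 1, 5]])

    def test_repeated_vertex_in_face(self):
        with pytest.raises(ValueError):
            TriMesh(np.zeros((3, 3)), [[0, 1, 1]])


class TestGrowPatch:
    def test_single_triangle_is_the_seed(self, face_truth_small):
        area = grow_patch(face_truth_small, 7, 1)
        assert area.triangle_ids.tolist() == [7]

    def test_exact_count_and_connectivity(self, face_truth_small):
        area = grow_patch(face_truth_small, 100, 500)
        assert area.n_triangles == 500
        sub = TriMesh(face_truth_small.vertices,
                      face_truth_small.faces[area.triangle_ids])
        from osseosurf.mesh_ops import connected_face_components

        assert len(np.unique(connected_face_components(sub))) == 1

    def test_disc_like_on_planar_grid(self):
        """BFS-ring growth on a flat regular grid yields a disc-like patch:
        no admitted centroid lies beyond 1.5× the equal-area disc radius."""
        mesh = make_planar_grid(60)
        seed = nearest_triangle(mesh, (30.0, 30.0, 0.0))
        area = grow_patch(mesh, seed, 1000)
        assert area.n_triangles == 1000
        centroids = mesh.face_centroids(area.triangle_ids)
        seed_c = mesh.face_centroids(np.asarray([seed]))[0]
        dists = np.linalg.norm(centroids - seed_c, axis=1)
        disc_radius = np.sqrt(1000 * 0.5 / np.pi)  # grid triangle area = 0.5
        assert dists.max() <= 1.5 * disc_radius

    def test_oversized_request_rejected(self, face_truth_small):
        with pytest.raises(ValueError):
            grow_patch(face_truth_small, 0, face_truth_small.n_faces + 1)

    def test_disconnected_reachable_set_reported(self):
        a = make_planar_grid(3)
        b = make_planar_grid(3)
        verts = np.vstack([a.vertices, b.vertices + np.array([100.0, 0, 0])])
        faces = np.vstack([a.faces, b.faces + a.n_vertices])
        mesh = TriMesh(verts, faces)
        with pytest.raises(ValueError, match="reachable"):
            grow_patch(mesh, 0, a.n_faces + 1)


class TestUnifyAreas:
    def _disjoint_patches(self, mesh, n_each, count):
        seeds = np.linspace(0, mesh.n_faces - 1, count).astype(int)
        return [grow_patch(mesh, int(s), n_each, mesh_id="m", name="zygoma") for s in seeds]

    def test_bilateral_union_is_2000(self, face_truth_small):
        """Two disjoint 1000-triangle patches unify into the protocol's
        2000-triangle bilateral reproducibility area."""
        left = grow_patch(face_truth_small, 0, 1000, mesh_id="m", name="zygoma")
        right_seed = int(np.argmax(
            np.linalg.norm(face_truth_small.face_centroids()
                           - face_truth_small.face_centroids(np.asarray([0]))[0], axis=1)
        ))
        right = grow_patch(face_truth_small, right_seed, 1000, mesh_id="m", name="zygoma")
        merged = unify_areas([left, right])
        assert merged.n_triangles == 2000
        assert merged.name == "zygoma"

    def test_four_patches_give_4000(self, face_truth_small):
        patches = [
            grow_patch(face_truth_small, s, 1000, mesh_id="m")
            for s in (0, 5000, 10000, 15000)
        ]
        union = unify_areas(patches)
        # trueness protocol size, provided the patches are disjoint
        if all(
            not np.intersect1d(a.triangle_ids, b.triangle_ids).size
            for i, a in enumerate(patches) for b in patches[i + 1:]
        ):
            assert union.n_triangles == 4000

    def test_idempotent_commutative(self, face_truth_small):
        a = grow_patch(face_truth_small, 0, 200, mesh_id="m")
        b = grow_patch(face_truth_small, 4000, 200, mesh_id="m")
        assert np.array_equal(unify_areas([a, a]).triangle_ids, a.triangle_ids)
        assert np.array_equal(
            unify_areas([a, b]).triangle_ids, unify_areas([b, a]).triangle_ids
        )

    def test_mixed_meshes_rejected(self):
        a = MeasurementArea("m1", "custom", [0, 1])
        b = MeasurementArea("m2", "custom", [2])
        with pytest.raises(ValueError, match="different meshes"):
            unify_areas([a, b])


class TestApplyTransform:
    def test_identity(self, cube_mesh):
        out = apply_transform(cube_mesh, RigidTransform.identity())
        assert np.allclose(out.vertices, cube_mesh.vertices)

    def test_pure_translation(self, cube_mesh):
        t = RigidTransform(np.eye(3), [1.0, 2.0, 3.0])
        out = apply_transform(cube_mesh, t)
        assert np.allclose(out.vertices - cube_mesh.vertices, [1.0, 2.0, 3.0])

    def test_rigidity_preserves_pairwise_distances(self):
        rng = np.random.default_rng(5)
        verts = rng.uniform(-10, 10, size=(10, 3))
        mesh = TriMesh(verts, [[0, 1, 2], [3, 4, 5], [6, 7, 8]])
        t = RigidTransform.from_rotvec_deg([12.0, -7.0, 30.0], [4.0, -2.0, 9.0])
        out = apply_transform(mesh, t)
        d0 = np.linalg.norm(verts[:, None] - verts[None, :], axis=2)
        d1 = np.linalg.norm(out.vertices[:, None] - out.vertices[None, :], axis=2)
        assert np.allclose(d0, d1, atol=1e-9)


class TestMapArea:
    def test_identity_mapping(self, face_truth_small):
        area = grow_patch(face_truth_small, 50, 300, mesh_id="m")
        mapped = map_area(area, face_truth_small, face_truth_small)
        assert np.array_equal(mapped.triangle_ids, area.triangle_ids)

    def test_remeshed_surface_preserves_area(self, sphere_spec10):
        """Transferring a patch to a half-edge re-mesh keeps its total
        surface area within 10%."""
        coarse = phantom.ground_truth_mesh(sphere_spec10, 1.0)
        fine = phantom.ground_truth_mesh(sphere_spec10, 0.5)
        patch = grow_patch(coarse, 10, 300, mesh_id="coarse")
        mapped = map_area(patch, coarse, fine, target_mesh_id="fine")
        a_src = coarse.face_areas()[patch.triangle_ids].sum()
        a_dst = fine.face_areas()[mapped.triangle_ids].sum()
        assert a_dst == pytest.approx(a_src, rel=0.10)

    def test_misaligned_meshes_flagged(self, cube_mesh):
        far = TriMesh(cube_mesh.vertices + np.array([100.0, 0, 0]), cube_mesh.faces)
        area = MeasurementArea("m", "custom", np.arange(12))
        with pytest.warns(UserWarning, match="gate"):
            map_area(area, cube_mesh, far)

    def test_empty_area_rejected(self, cube_mesh):
        area = MeasurementArea("m", "custom", np.zeros(0, dtype=int))
        with pytest.raises(ValueError):
            map_area(area, cube_mesh, cube_mesh)


class TestAreaSerialisation:
    def test_json_round_trip(self, tmp_path, face_truth_small):
        area = grow_patch(face_truth_small, 3, 250, mesh_id="m", name="forehead")
        p = tmp_path / "area.json"
        area.to_json(p)
        back = MeasurementArea.from_json(p)
        assert back.mesh_id == "m"
        assert back.name == "forehead"
        assert np.array_equal(back.triangle_ids, area.triangle_ids)
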