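import numpy as np
import pytest
import trimesh as _trimesh

from osseosurf import phantom
from osseosurf.mesh_ops import TriMesh
from osseosurf.segmentation import extract_isosurface, keep_main_components


@pytest.fixture(scope="session")
def sphere_spec10():
    """Noise-free 10 mm sphere phantom on a 0.5 mm grid (fast)."""
    return phantom.sphere_spec(radius=10.0, spacing=(0.5, 0.5, 0.5),
                               psf_fwhm=0.0, noise_sigma=0.0)


@pytest.fixture(scope="session")
def sphere_volume10(sphere_spec10):
    return phantom.rasterize_phantom(sphere_spec10)


@pytest.fixture(scope="session")
def sphere_mesh10(sphere_spec10, sphere_volume10):
    return keep_main_components(
        extract_isosurface(sphere_volume10, sphere_spec10.midpoint_threshold), 0.01
    )


@pytest.fixture(scope="session")
def face_spec_small():
    """Desk-scale face-like phantom with blur and noise."""
    return phantom.face_like_spec(semi_axes=(16.0, 19.0, 15.0),
                                  spacing=(0.7, 0.7, 0.7),
                                  psf_fwhm=1.2, noise_sigma=40.0, seed=3)


@pytest.fixture(scope="session")
def face_truth_small(face_spec_small):
    return phantom.ground_truth_mesh(face_spec_small, 0.8)


def make_planar_grid(n: int, pitch: float = 1.0) -> TriMesh:
    """Regular (n+1)² vertex grid in the z=0 plane, 2n² triangles."""
    xs = np.arange(n + 1) * pitch
    gx, gy = np.meshgrid(xs, xs, indexing="ij")
    verts = np.column_stack([gx.ravel(), gy.ravel(), np.zeros(gx.size)])
    faces = []
    for i in range(n):
        for j in range(n):
            a = i * (n + 1) + j
            b = a + 1
            c = a + (n + 1)
            d = c + 1
            faces.append([a, b, c])
            faces.append([b, d, c])
    return TriMesh(verts, np.asarray(faces))


def make_random_surface(rng: np.random.Generator, subdivisions: int = 2,
                        bump: float = 0.15) -> TriMesh:
    """Closed random surface: radially perturbed icosphere (≤ 1280 faces)."""
    ico = _trimesh.creation.icosphere(subdivisions=subdivisions, radius=1.0)
    dirs = np.asarray(ico.vertices)
    radii = 1.0 + bump * rng.standard_normal(len(dirs))
    return TriMesh(dirs * radii[:, None], np.asarray(ico.faces))
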