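import numpy as np
import pytest
import trimesh

from splenvas.phantom import PhantomSpec, build_phantom
from splenvas.stain import default_stain_model


@pytest.fixture(scope="session")
def stain_model():
    return default_stain_model()


@pytest.fixture(scope="session")
def default_gt():
    """Default desk-scale phantom ground truth (seed 1)."""
    return build_phantom(PhantomSpec(seed=1))


@pytest.fixture(scope="session")
def quiet_spec():
    """Desk phantom with no jitter and no noise (deterministic rendering)."""
    return PhantomSpec(
        seed=1,
        jitter_translation_px=(0.0, 0.0),
        jitter_rotation_deg=(0.0, 0.0),
        noise_sd=0.0,
    )


def make_tube(radius=8.0, length=300.0, n_theta=36, n_z=100):
    """Open cylinder mesh along +z, rims at z=0 and z=length."""
    theta = np.linspace(0, 2 * np.pi, n_theta, endpoint=False)
    zs = np.linspace(0, length, n_z)
    verts = [
        [radius * np.cos(t), radius * np.sin(t), z] for z in zs for t in theta
    ]
    faces = []
    for iz in range(n_z - 1):
        for it in range(n_theta):
            a = iz * n_theta + it
            b = iz * n_theta + (it + 1) % n_theta
            c = (iz + 1) * n_theta + it
            d = (iz + 1) * n_theta + (it + 1) % n_theta
            faces += [[a, b, c], [b, d, c]]
    return trimesh.Trimesh(vertices=verts, faces=faces, process=False)


def oracle_point_triangle(p, a, b, c):
    """Independent exact point-triangle distance: plane projection when the
    barycentric coordinates are interior, else the minimum over the three
    edge segments (a different decomposition than the library's)."""
    p, a, b, c = (np.asarray(v, dtype=float) for v in (p, a, b, c))
    n = np.cross(b - a, c - a)
    nn = np.dot(n, n)
    best = np.inf
    if nn > 0:
        q = p - np.dot(p - a, n) / nn * n  # projection onto the plane
        # barycentric coordinates of q
        v0, v1, v2 = b - a, c - a, q - a
        d00, d01, d11 = np.dot(v0, v0), np.dot(v0, v1), np.dot(v1, v1)
        d20, d21 = np.dot(v2, v0), np.dot(v2, v1)
        den = d00 * d11 - d01 * d01
        if den > 0:
            v = (d11 * d20 - d01 * d21) / den
            w = (d00 * d21 - d01 * d20) / den
            if v >= 0 and w >= 0 and v + w <= 1:
                best = np.linalg.norm(p - q)

    def seg(u, v):
        uv = v - u
        t = np.clip(np.dot(p - u, uv) / max(np.dot(uv, uv), 1e-300), 0, 1)
        return np.linalg.norm(p - (u + t * uv))

    return min(best, seg(a, b), seg(b, c), seg(c, a))


def oracle_mesh_distances(points, mesh):
    """All-pairs brute-force point-to-mesh distance using the oracle above."""
    tris = mesh.triangles
    return np.array([
        min(oracle_point_triangle(p, *t) for t in tris) for p in points
    ])


@pytest.fixture
def open_cylinder():
    return make_tube(radius=10.0, length=30.0, n_theta=40, n_z=16)


@pytest.fixture
def long_cylinder():
    return make_tube(radius=8.0, length=300.0, n_theta=36, n_z=100)
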