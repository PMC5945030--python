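import numpy as np
import pytest
import trimesh
from hypothesis import settings

from carrypole import SyntheticPoleSpec

settings.register_profile("default", deadline=None, derandomize=True)
settings.load_profile("default")


@pytest.fixture
def pole_spec() -> SyntheticPoleSpec:
    """A typical synthetic pole with fixed seed."""
    return SyntheticPoleSpec(seed=0)


@pytest.fixture
def short_pole_spec() -> SyntheticPoleSpec:
    """A short pole for fast mesh generation."""
    return SyntheticPoleSpec(seed=0, length=0.5)


def make_hollow_cylinder(
    R: float, r: float, length: float, n_ring: int = 128, n_axial: int = 9
) -> trimesh.Trimesh:
    """Watertight hollow cylinder (tube) along x for slice tests."""
    th = np.linspace(0.0, 2.0 * np.pi, n_ring, endpoint=False)
    xs = np.linspace(0.0, length, n_axial)
    verts = []
    for radius in (R, r):
        for x in xs:
            verts.append(
                np.column_stack(
                    [np.full(n_ring, x), radius * np.sin(th), radius * np.cos(th)]
                )
            )
    verts = np.vstack(verts)
    faces = []

    def ring(surface: int, j: int) -> int:
        return (surface * n_axial + j) * n_ring

    for surface, flip in ((0, False), (1, True)):
        for j in range(n_axial - 1):
            b0, b1 = ring(surface, j), ring(surface, j + 1)
            for k in range(n_ring):
                k1 = (k + 1) % n_ring
                tris = [[b0 + k, b0 + k1, b1 + k1], [b0 + k, b1 + k1, b1 + k]]
                if flip:
                    tris = [t[::-1] for t in tris]
                faces.extend(tris)
    for j, flip in ((0, True), (n_axial - 1, False)):
        o, i = ring(0, j), ring(1, j)
        for k in range(n_ring):
            k1 = (k + 1) % n_ring
            tris = [[o + k, o + k1, i + k1], [o + k, i + k1, i + k]]
            if flip:
                tris = [t[::-1] for t in tris]
            faces.extend(tris)
    mesh = trimesh.Trimesh(vertices=verts, faces=np.asarray(faces), process=False)
    trimesh.repair.fix_normals(mesh)
    return mesh
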