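"""Fixed-topology ventricular surface meshes with point correspondence.

The ventricle is represented by a pair of closed triangulated surfaces
(endocardium and epicardium) built on a shared ring parameterization:
``n_rings`` cross-sectional rings of ``n_circ`` vertices each, ordered
base to apex.  Because every mesh in a study shares this topology,
vertex *k* corresponds anatomically across subjects and the flattened
coordinate vector is a valid shape-space embedding.

With the default 24 x 24 grid per surface the endo+epi pair has 1152
vertices, i.e. a 3456-entry shape vector.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import trimesh

N_RINGS = 24
N_CIRC = 24
VERTS_PER_SURFACE = N_RINGS * N_CIRC
SHAPE_VECTOR_LEN = 2 * VERTS_PER_SURFACE * 3  # endo + epi, xyz each


def ring_faces(n_rings: int = N_RINGS, n_circ: int = N_CIRC) -> np.ndarray:
    """Triangulation of a ring-parameterized tube, capped at both ends.

    Caps are triangle fans from the vertex at angular index ``n_circ // 2``
    (the point diametrically opposite the septal dimple), which sees the
    whole cross-section for the star-shaped sections used here.
    """
    faces = []
    v = lambda i, j: i * n_circ + (j % n_circ)
    for i in range(n_rings - 1):
        for j in range(n_circ):
            faces.append([v(i, j), v(i + 1, j), v(i + 1, j + 1)])
            faces.append([v(i, j), v(i + 1, j + 1), v(i, j + 1)])
    jf = n_circ // 2  # fan apex: far free-wall vertex
    for j in range(n_circ):  # base cap (ring 0)
        if j == jf or (j + 1) % n_circ == jf:
            continue
        faces.append([v(0, jf), v(0, j), v(0, j + 1)])
    i = n_rings - 1
    for j in range(n_circ):  # apex cap
        if j == jf or (j + 1) % n_circ == jf:
            continue
        faces.append([v(i, jf), v(i, j + 1), v(i, j)])
    return np.asarray(faces, dtype=np.int64)


_FACES = ring_faces()


def surface_trimesh(vertices: np.ndarray) -> trimesh.Trimesh:
    """Closed trimesh for one ring-parameterized surface (no copy of faces)."""
    m = trimesh.Trimesh(vertices=vertices, faces=_FACES, process=False)
    if m.volume < 0:
        m.invert()
    return m


def enclosed_volume(vertices: np.ndarray) -> float:
    """Signed volume (mm^3) of a closed ring surface via the divergence theorem."""
    return abs(surface_trimesh(vertices).volume)


@dataclass
class CorrespondedMesh:
    """Endo+epi surface pair with fixed topology and point correspondence.

    Attributes
    ----------
    endo, epi : (576, 3) float arrays
        Vertex coordinates in mm, ring-major, base ring first.  ``epi``
        may be ``None`` for cavity-only meshes.
    septal_mask : (576,) bool
        Vertices lying on the septal sector (shared by endo and epi).
    landmark : (3,) float
        LV remnant anchor point, used to fix the circumferential origin
        when aligning subjects.
    fitting_error_mm : float or None
        Mean point-to-surface distance of the personalization fit, when
        the mesh was produced by fitting a segmentation.
    """

    endo: np.ndarray
    epi: np.ndarray | None
    septal_mask: np.ndarray
    landmark: np.ndarray
    n_rings: int = N_RINGS
    n_circ: int = N_CIRC
    fitting_error_mm: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.endo = np.asarray(self.endo, dtype=float)
        if self.epi is not None:
            self.epi = np.asarray(self.epi, dtype=float)
            if self.epi.shape != self.endo.shape:
                raise ValueError("endo and epi must have the same vertex count")
        self.septal_mask = np.asarray(self.septal_mask, dtype=bool)
        self.landmark = np.asarray(self.landmark, dtype=float)

    # -- geometry ----------------------------------------------------------
    def cavity_volume_ml(self) -> float:
        return enclosed_volume(self.endo) / 1000.0

    def wall_volume_ml(self) -> float:
        if self.epi is None:
            raise ValueError("wall volume requires an epicardial surface")
        return (enclosed_volume(self.epi) - enclosed_volume(self.endo)) / 1000.0

    def endo_trimesh(self) -> trimesh.Trimesh:
        return surface_trimesh(self.endo)

    def epi_trimesh(self) -> trimesh.Trimesh:
        if self.epi is None:
            raise ValueError("mesh has no epicardial surface")
        return surface_trimesh(self.epi)

    def rings(self, surface: str = "endo") -> np.ndarray:
        """Vertices regrouped as (n_rings, n_circ, 3)."""
        v = self.endo if surface == "endo" else self.epi
        return v.reshape(self.n_rings, self.n_circ, 3)

    def wall_thickness(self) -> np.ndarray:
        """Per-vertex endo->epi distance (mm) along matched correspondences."""
        if self.epi is None:
            raise ValueError("wall thickness requires an epicardial surface")
        return np.linalg.norm(self.epi - self.endo, axis=1)

    # -- shape vector ------------------------------------------------------
    def shape_vector(self) -> np.ndarray:
        """Flatten to the canonical 3456-entry vector (endo then epi, xyz)."""
        if self.epi is None:
            raise ValueError("shape vector requires both surfaces")
        vec = np.concatenate([self.endo.ravel(), self.epi.ravel()])
        if vec.size != SHAPE_VECTOR_LEN:
            raise ValueError(
                f"unexpected vertex count: vector length {vec.size} != {SHAPE_VECTOR_LEN}"
            )
        return vec

    def with_vertices(self, endo: np.ndarray, epi: np.ndarray | None) -> "CorrespondedMesh":
        return replace(self, endo=np.asarray(endo, float),
                       epi=None if epi is None else np.asarray(epi, float))

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "CorrespondedMesh":
        """Apply a rigid transform x -> R x + t to all vertices and the landmark."""
        R = np.asarray(rotation, float)
        t = np.asarray(translation, float)
        out = self.with_vertices(self.endo @ R.T + t,
                                 None if self.epi is None else self.epi @ R.T + t)
        out.landmark = R @ self.landmark + t
        return out


def save_mesh_ply(mesh: CorrespondedMesh, path) -> None:
    """Write endo+epi as one PLY (endo vertices first) with fixed ordering."""
    if mesh.epi is None:
        raise ValueError("PLY export requires both surfaces")
    verts = np.vstack([mesh.endo, mesh.epi])
    faces = np.vstack([_FACES, _FACES + len(mesh.endo)])
    trimesh.Trimesh(vertices=verts, faces=faces, process=False).export(str(path))


def load_mesh_ply(path, like: CorrespondedMesh) -> CorrespondedMesh:
    """Read a PLY written by :func:`save_mesh_ply`, reusing metadata of `like`."""
    tm = trimesh.load(str(path), process=False)
    v = np.asarray(tm.vertices, dtype=float)
    n = VERTS_PER_SURFACE
    if len(v) != 2 * n:
        raise ValueError(f"expected {2 * n} vertices, found {len(v)}")
    return like.with_vertices(v[:n], v[n:])


def unflatten_shape(vec: np.ndarray, like: CorrespondedMesh) -> CorrespondedMesh:
    """Rebuild a mesh from a 3456-entry shape vector, reusing topology of `like`."""
    vec = np.asarray(vec, dtype=float).ravel()
    if vec.size != SHAPE_VECTOR_LEN:
        raise ValueError(f"shape vector must have length {SHAPE_VECTOR_LEN}, got {vec.size}")
    n = VERTS_PER_SURFACE * 3
    return like.with_vertices(vec[:n].reshape(-1, 3), vec[n:].reshape(-1, 3))
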