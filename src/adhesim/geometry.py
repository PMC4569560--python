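"""Discretized cell-surface geometry.

Cells are represented by closed triangulated surfaces kept in a body-fixed
frame; a rigid pose (translation + unit quaternion) maps them to the world
frame each step, so the mesh itself is never regenerated and face identifiers
are stable for the lifetime of a simulation.

Conventions
-----------
* SI units internally (metres everywhere).
* Right-handed world frame: ``x`` streamwise, ``y`` wall-normal with the
  substrate at ``y = 0``, ``z`` spanwise.
* Quaternions are scalar-last ``[x, y, z, w]`` (scipy convention).
* Body-fixed meshes for rigid bodies are centred on their volume centroid, so
  a pose's translation *is* the body centroid and lever arms are simply
  face centroid minus pose translation.
"""

from __future__ import annotations

import dataclasses
from typing import Iterator, NamedTuple

import numpy as np
import trimesh
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation


class GeometryError(ValueError):
    """Invalid mesh or geometric parameter."""


class Load(NamedTuple):
    """A force/torque pair acting at a body centroid, world frame [N, N*m]."""

    force: np.ndarray
    torque: np.ndarray

    @staticmethod
    def zero() -> "Load":
        return Load(np.zeros(3), np.zeros(3))

    def __add__(self, other):  # type: ignore[override]
        return Load(self.force + other.force, self.torque + other.torque)


@dataclasses.dataclass(frozen=True)
class Pose:
    """Rigid transform from body frame to world frame."""

    position: np.ndarray  # (3,) [m]
    quaternion: np.ndarray  # (4,) scalar-last, unit norm

    def __post_init__(self):
        q = np.asarray(self.quaternion, dtype=float)
        n = np.linalg.norm(q)
        if not np.isfinite(n) or abs(n - 1.0) > 1e-9:
            raise GeometryError("pose quaternion must be unit norm")
        object.__setattr__(self, "position", np.asarray(self.position, dtype=float))
        object.__setattr__(self, "quaternion", q)

    @staticmethod
    def identity(position=(0.0, 0.0, 0.0)) -> "Pose":
        return Pose(np.asarray(position, dtype=float), np.array([0.0, 0.0, 0.0, 1.0]))

    def rotation(self) -> Rotation:
        return Rotation.from_quat(self.quaternion)


@dataclasses.dataclass
class SurfaceMesh:
    """Triangulated cell surface in the body frame.

    ``face_ids`` are stable integers (row indices at construction) used to key
    bonds and the molecule ledger across timesteps.
    """

    vertices: np.ndarray  # (n_v, 3) [m]
    faces: np.ndarray  # (n_f, 3) int vertex indices
    face_ids: np.ndarray  # (n_f,) int

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        self.face_ids = np.asarray(self.face_ids, dtype=np.int64)
        if len(np.unique(self.face_ids)) != len(self.face_ids):
            raise GeometryError("face_ids must be unique")
        areas = _triangle_areas(self.vertices, self.faces)
        if np.any(areas <= 0.0) or not np.all(np.isfinite(areas)):
            raise GeometryError("all face areas must be positive")

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def as_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(vertices=self.vertices, faces=self.faces, process=False)

    def is_closed(self) -> bool:
        return bool(self.as_trimesh().is_watertight)

    def max_edge_length(self) -> float:
        v = self.vertices[self.faces]  # (n_f, 3, 3)
        e = np.linalg.norm(np.roll(v, -1, axis=1) - v, axis=2)
        return float(e.max())

    def volume_centroid(self) -> np.ndarray:
        """Volume centroid (uniform density centre of mass) of the closed body."""
        return np.asarray(self.as_trimesh().center_mass, dtype=float)

    def recentred(self) -> "SurfaceMesh":
        """Copy shifted so the volume centroid sits at the body-frame origin."""
        c = self.volume_centroid()
        return SurfaceMesh(self.vertices - c, self.faces.copy(), self.face_ids.copy())


@dataclasses.dataclass
class FaceSet:
    """World-frame per-face properties of one body at one instant."""

    body_id: str
    face_ids: np.ndarray  # (n_f,)
    centroids: np.ndarray  # (n_f, 3) [m]
    areas: np.ndarray  # (n_f,) [m^2]
    normals: np.ndarray  # (n_f, 3) outward unit normals
    lever_arms: np.ndarray  # (n_f, 3) centroid - body centroid [m]
    body_centroid: np.ndarray  # (3,) [m]

    @property
    def n_faces(self) -> int:
        return len(self.face_ids)

    def total_area(self) -> float:
        return float(self.areas.sum())


class FacePairGeometry(NamedTuple):
    """One gated TC-face / PMN-face pair."""

    tc_face_id: int
    pmn_face_id: int
    distance: float  # centroid separation d [m]
    e_hat: np.ndarray  # unit vector from the TC face centroid to the PMN face


@dataclasses.dataclass
class FacePairs:
    """Vectorised sequence of gated face pairs, sorted by (tc_id, pmn_id).

    ``tc_index``/``pmn_index`` are row indices into the originating FaceSets;
    ``tc_ids``/``pmn_ids`` the corresponding stable face identifiers.
    ``e_hat`` points from the TC face centroid toward the PMN face centroid.
    """

    tc_index: np.ndarray
    pmn_index: np.ndarray
    tc_ids: np.ndarray
    pmn_ids: np.ndarray
    distance: np.ndarray
    e_hat: np.ndarray  # (n, 3)

    def __len__(self) -> int:
        return len(self.distance)

    def __iter__(self) -> Iterator[FacePairGeometry]:
        for k in range(len(self)):
            yield FacePairGeometry(
                int(self.tc_ids[k]),
                int(self.pmn_ids[k]),
                float(self.distance[k]),
                self.e_hat[k],
            )


# ---------------------------------------------------------------------------
# Mesh generation
# ---------------------------------------------------------------------------

def _triangle_areas(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    v = vertices[faces]
    cross = np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0])
    return 0.5 * np.linalg.norm(cross, axis=1)


def make_icosphere(radius: float, subdivisions: int) -> SurfaceMesh:
    """Closed triangulated sphere with ``20 * 4**subdivisions`` faces.

    Parameters
    ----------
    radius : float
        Sphere radius [m], > 0.
    subdivisions : int
        Icosahedron subdivision level, >= 0.
    """
    if not radius > 0.0:
        raise GeometryError("icosphere radius must be positive")
    if subdivisions < 0 or int(subdivisions) != subdivisions:
        raise GeometryError("subdivisions must be a non-negative integer")
    tm = trimesh.creation.icosphere(subdivisions=int(subdivisions), radius=radius)
    return SurfaceMesh(
        vertices=np.asarray(tm.vertices, dtype=float),
        faces=np.asarray(tm.faces, dtype=np.int64),
        face_ids=np.arange(len(tm.faces)),
    )


def icosphere_for_max_edge(radius: float, max_edge: float, max_subdivisions: int = 8) -> SurfaceMesh:
    """Smallest-subdivision icosphere whose longest edge is <= ``max_edge``.

    Mirrors the maximum-element-size convention used for mesh refinement
    studies (e.g. 1.5 um coarse vs 0.5 um fine surfaces).
    """
    if not max_edge > 0.0:
        raise GeometryError("max_edge must be positive")
    for s in range(max_subdivisions + 1):
        mesh = make_icosphere(radius, s)
        if mesh.max_edge_length() <= max_edge:
            return mesh
    raise GeometryError(
        f"max_edge {max_edge:g} m not reachable within {max_subdivisions} subdivisions"
    )


def make_pmn_cap(base_radius: float, height: float, resolution: int) -> SurfaceMesh:
    """Closed half-ellipsoid cap resting on the substrate plane ``y = 0``.

    A parametric stand-in for the flattened, substrate-adherent neutrophil
    shape: the upper half of an ellipsoid with semi-axes
    (base_radius, height, base_radius), closed by a fan-triangulated base
    disk at ``y = 0``, apex at ``y = height``. ``resolution`` is the number of
    latitude rings between apex and base; the azimuthal count scales with it.
    """
    if not (base_radius > 0.0 and height > 0.0):
        raise GeometryError("cap base_radius and height must be positive")
    n_rings = max(2, int(resolution))
    n_seg = max(8, 4 * n_rings)

    verts = [np.array([0.0, height, 0.0])]  # apex
    phi = 2.0 * np.pi * np.arange(n_seg) / n_seg
    for i in range(1, n_rings + 1):
        theta = 0.5 * np.pi * i / n_rings  # polar angle from the +y apex
        rho = base_radius * np.sin(theta)
        y = height * np.cos(theta)
        ring = np.stack([rho * np.cos(phi), np.full(n_seg, y), rho * np.sin(phi)], axis=1)
        verts.append(ring)
    # base disk at y=0, triangulated with concentric rings so its element
    # size tracks the lateral resolution
    for k in range(1, n_rings):
        rho = base_radius * k / n_rings
        ring = np.stack([rho * np.cos(phi), np.zeros(n_seg), rho * np.sin(phi)], axis=1)
        verts.append(ring)
    base_centre_idx = 1 + (2 * n_rings - 1) * n_seg
    vertices = np.vstack([verts[0][None, :]] + verts[1:] + [np.zeros((1, 3))])

    def ring_idx(i: int, j: int) -> int:
        return 1 + (i - 1) * n_seg + (j % n_seg)

    def base_idx(k: int, j: int) -> int:
        # k = 1..n_rings: concentric base ring; k = n_rings is the equator
        if k == n_rings:
            return ring_idx(n_rings, j)
        return 1 + (n_rings + k - 1) * n_seg + (j % n_seg)

    faces = []
    # apex fan
    for j in range(n_seg):
        faces.append([0, ring_idx(1, j), ring_idx(1, j + 1)])
    # lateral quads split into triangles
    for i in range(1, n_rings):
        for j in range(n_seg):
            a, b = ring_idx(i, j), ring_idx(i, j + 1)
            c, d = ring_idx(i + 1, j), ring_idx(i + 1, j + 1)
            faces.append([a, c, d])
            faces.append([a, d, b])
    # base annuli and central fan (wound opposite to the lateral surface so
    # the normal points -y once the whole mesh is oriented outward)
    for k in range(1, n_rings):
        for j in range(n_seg):
            faces.append([base_idx(k, j), base_idx(k + 1, j + 1), base_idx(k + 1, j)])
            faces.append([base_idx(k, j), base_idx(k, j + 1), base_idx(k + 1, j + 1)])
    for j in range(n_seg):
        faces.append([base_centre_idx, base_idx(1, j + 1), base_idx(1, j)])

    faces = np.asarray(faces)
    tm = trimesh.Trimesh(vertices=vertices, faces=faces, process=False)
    if tm.volume < 0.0:  # ensure outward orientation
        faces = faces[:, ::-1]
        tm = trimesh.Trimesh(vertices=vertices, faces=faces, process=False)
    if not tm.is_watertight or tm.volume <= 0.0:
        raise GeometryError("cap construction produced a non-closed or inverted surface")
    return SurfaceMesh(vertices, faces, np.arange(len(faces)))


def cap_for_max_edge(
    base_radius: float, height: float, max_edge: float, max_resolution: int = 200
) -> SurfaceMesh:
    """Smallest-resolution cap whose longest edge is <= ``max_edge``."""
    if not max_edge > 0.0:
        raise GeometryError("max_edge must be positive")
    res = 2
    while res <= max_resolution:
        mesh = make_pmn_cap(base_radius, height, res)
        if mesh.max_edge_length() <= max_edge:
            return mesh
        res = max(res + 1, int(res * 1.4))
    raise GeometryError("requested max_edge too small for cap construction")


# ---------------------------------------------------------------------------
# Per-face properties and pair gating
# ---------------------------------------------------------------------------

def face_properties(mesh: SurfaceMesh, pose: Pose, body_id: str = "body") -> FaceSet:
    """World-frame centroids, areas, outward normals and lever arms.

    Areas are invariant under the rigid transform; the lever arm of a face is
    its world centroid minus the pose translation (the body centroid, since
    body meshes are centroid-centred).
    """
    R = pose.rotation().as_matrix()
    world_v = mesh.vertices @ R.T + pose.position
    tri = world_v[mesh.faces]
    cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    norms = np.linalg.norm(cross, axis=1)
    if np.any(norms <= 0.0):
        raise GeometryError("zero-area face encountered")
    areas = 0.5 * norms
    normals = cross / norms[:, None]
    centroids = tri.mean(axis=1)
    return FaceSet(
        body_id=body_id,
        face_ids=mesh.face_ids.copy(),
        centroids=centroids,
        areas=areas,
        normals=normals,
        lever_arms=centroids - pose.position,
        body_centroid=pose.position.copy(),
    )


def gated_face_pairs(tc: FaceSet, pmn: FaceSet, cutoff: float) -> FacePairs:
    """All (TC face, PMN face) pairs with centroid separation strictly below
    ``cutoff``, sorted ascending by (tc_face_id, pmn_face_id).

    The result is contractually identical (as a set) to the brute-force
    all-pairs computation; the vectorised distance matrix is an implementation
    detail, not an approximation.
    """
    if not cutoff > 0.0:
        raise GeometryError("cutoff must be positive")
    d = cdist(tc.centroids, pmn.centroids)
    ti, pi = np.nonzero(d < cutoff)
    order = np.lexsort((pmn.face_ids[pi], tc.face_ids[ti]))
    ti, pi = ti[order], pi[order]
    dist = d[ti, pi]
    sep = pmn.centroids[pi] - tc.centroids[ti]
    with np.errstate(invalid="ignore", divide="ignore"):
        e_hat = np.where(dist[:, None] > 0.0, sep / np.where(dist == 0.0, 1.0, dist)[:, None], 0.0)
    return FacePairs(
        tc_index=ti,
        pmn_index=pi,
        tc_ids=tc.face_ids[ti],
        pmn_ids=pmn.face_ids[pi],
        distance=dist,
        e_hat=e_hat,
    )


# ---------------------------------------------------------------------------
# Mesh import/export
# ---------------------------------------------------------------------------

def load_obj(path) -> SurfaceMesh:
    """Import a user triangle mesh (OBJ) as a SurfaceMesh."""
    tm = trimesh.load(path, force="mesh")
    return SurfaceMesh(
        vertices=np.asarray(tm.vertices, dtype=float),
        faces=np.asarray(tm.faces, dtype=np.int64),
        face_ids=np.arange(len(tm.faces)),
    )


def write_off(mesh: SurfaceMesh, path, pose: Pose | None = None) -> None:
    v = mesh.vertices
    if pose is not None:
        v = v @ pose.rotation().as_matrix().T + pose.position
    with open(path, "w") as fh:
        fh.write("OFF\n")
        fh.write(f"{len(v)} {len(mesh.faces)} 0\n")
        for p in v:
            fh.write(f"{p[0]:.9e} {p[1]:.9e} {p[2]:.9e}\n")
        for f in mesh.faces:
            fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")


def write_vtk_polydata(mesh: SurfaceMesh, path, pose: Pose | None = None) -> None:
    """Legacy ASCII VTK PolyData snapshot (for ParaView-style visualisation)."""
    v = mesh.vertices
    if pose is not None:
        v = v @ pose.rotation().as_matrix().T + pose.position
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nadhesim surface snapshot\nASCII\n")
        fh.write("DATASET POLYDATA\n")
        fh.write(f"POINTS {len(v)} double\n")
        for p in v:
            fh.write(f"{p[0]:.9e} {p[1]:.9e} {p[2]:.9e}\n")
        fh.write(f"POLYGONS {len(mesh.faces)} {4 * len(mesh.faces)}\n")
        for f in mesh.faces:
            fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")
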