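"""Voxel grids, tetrahedral lumen meshes and the geometric plumbing shared by
every downstream quantity.

The pipeline's spatial substrate is a linear (P1) tetrahedral mesh of the
vessel lumen with labelled boundary patches: ``wall`` (the lumen surface),
``inlet`` and ``outlet`` (the two cut planes the axial Laplace problem is
anchored to).  A mesh is either supplied directly or built from a binary
segmentation mask on the acquisition voxel grid by tessellating every masked
voxel into six tetrahedra (a Kuhn/Freudenthal split, which is conforming
across neighbouring voxels).
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "VoxelGrid",
    "TetMesh",
    "Plane",
    "GeometryError",
    "MeshQualityError",
    "mask_to_mesh",
    "label_boundary_faces",
    "lumped_node_volumes",
]

WALL, INLET, OUTLET = "wall", "inlet", "outlet"


class GeometryError(ValueError):
    """Inconsistent geometry between inputs (shapes, affines, empty patches)."""


class MeshQualityError(ValueError):
    """Degenerate or non-positively-oriented elements."""


@dataclasses.dataclass
class VoxelGrid:
    """Acquisition grid: binary lumen mask plus per-phase 3-component velocity.

    Parameters
    ----------
    shape : tuple of int
        Grid dimensions (nx, ny, nz).
    spacing : array-like of float
        Voxel edge lengths in mm per axis; anisotropy is preserved.
    origin : array-like of float
        World-mm position of the centre of voxel (0, 0, 0).
    mask : ndarray of bool, shape ``shape``
        Lumen segmentation.
    velocity : ndarray, shape ``shape + (n_phases, 3)``
        Velocity in m/s per voxel per cardiac phase.
    phase_times : ndarray, shape (n_phases,)
        Trigger times in ms; phases cover one full cycle (retrospective
        gating) and are treated cyclically.
    """

    shape: tuple
    spacing: np.ndarray
    origin: np.ndarray
    mask: np.ndarray
    velocity: np.ndarray
    phase_times: np.ndarray

    def __post_init__(self):
        self.shape = tuple(int(s) for s in self.shape)
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        self.velocity = np.asarray(self.velocity, dtype=float)
        self.phase_times = np.asarray(self.phase_times, dtype=float)
        if np.any(self.spacing <= 0):
            raise GeometryError("voxel spacing must be positive")
        if self.mask.shape != self.shape:
            raise GeometryError(
                f"mask shape {self.mask.shape} != grid shape {self.shape}"
            )
        if self.velocity.shape[:3] != self.shape or self.velocity.shape[-1] != 3:
            raise GeometryError(
                f"velocity shape {self.velocity.shape} incompatible with grid "
                f"shape {self.shape}"
            )
        if self.n_phases < 3:
            raise GeometryError("at least 3 cardiac phases are required")
        if self.phase_times.shape != (self.n_phases,):
            raise GeometryError("phase_times length must equal phase count")
        if not self.mask.any():
            raise GeometryError("mask is empty")

    @property
    def n_phases(self) -> int:
        return self.velocity.shape[3]

    def voxel_centers_mm(self, ijk: np.ndarray) -> np.ndarray:
        """World-mm coordinates of voxel-index positions (fractional ok)."""
        return self.origin + np.asarray(ijk, dtype=float) * self.spacing

    def mm_to_index(self, xyz: np.ndarray) -> np.ndarray:
        """Inverse of :meth:`voxel_centers_mm` (fractional voxel indices)."""
        return (np.asarray(xyz, dtype=float) - self.origin) / self.spacing


# Outward-oriented faces of a positively oriented tet (a, b, c, d):
# each triple winds counter-clockwise when seen from outside.
_TET_FACES = np.array([[1, 2, 3], [0, 3, 2], [0, 1, 3], [0, 2, 1]])


class TetMesh:
    """Linear tetrahedral mesh with labelled boundary patches.

    ``nodes`` are world-mm coordinates (0-based indexing throughout);
    ``tets`` are positively oriented.  Boundary faces are derived (each is a
    tet face shared by no second tet), wound outward, and labelled
    wall/inlet/outlet.
    """

    def __init__(self, nodes: np.ndarray, tets: np.ndarray,
                 boundary_labels: np.ndarray | None = None):
        self.nodes = np.ascontiguousarray(nodes, dtype=float)
        self.tets = np.ascontiguousarray(tets, dtype=np.int64)
        if self.nodes.ndim != 2 or self.nodes.shape[1] != 3:
            raise GeometryError("nodes must be (n, 3)")
        if self.tets.ndim != 2 or self.tets.shape[1] != 4:
            raise GeometryError("tets must be (m, 4)")
        vol = self.tet_volumes()
        if np.any(vol <= 0):
            bad = int(np.argmin(vol))
            raise MeshQualityError(
                f"tet {bad} has non-positive volume {vol[bad]:.3g} mm^3"
            )
        self.boundary_faces = self._extract_boundary()
        if boundary_labels is None:
            boundary_labels = np.full(len(self.boundary_faces), WALL, dtype=object)
        self.boundary_labels = np.asarray(boundary_labels, dtype=object)
        if len(self.boundary_labels) != len(self.boundary_faces):
            raise GeometryError("one label per boundary face required")

    # -- geometry ---------------------------------------------------------

    def tet_volumes(self) -> np.ndarray:
        """Signed volumes in mm^3 (positive for valid meshes)."""
        x = self.nodes[self.tets]
        e = x[:, 1:] - x[:, :1]
        return np.einsum("ij,ij->i", np.cross(e[:, 0], e[:, 1]), e[:, 2]) / 6.0

    def _extract_boundary(self) -> np.ndarray:
        faces = self.tets[:, _TET_FACES].reshape(-1, 3)
        key = np.sort(faces, axis=1)
        order = np.lexsort(key.T)
        key_sorted = key[order]
        uniq, first, counts = np.unique(
            key_sorted, axis=0, return_index=True, return_counts=True
        )
        if np.any(counts > 2):
            raise MeshQualityError("a face is shared by more than two tets")
        single = first[counts == 1]
        return faces[order[single]]

    def boundary_face_normals(self) -> tuple[np.ndarray, np.ndarray]:
        """(outward unit normals, areas in mm^2) per boundary face."""
        tri = self.nodes[self.boundary_faces]
        n = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        area2 = np.linalg.norm(n, axis=1)
        if np.any(area2 == 0):
            raise MeshQualityError("degenerate boundary face")
        return n / area2[:, None], area2 / 2.0

    def boundary_face_centroids(self) -> np.ndarray:
        return self.nodes[self.boundary_faces].mean(axis=1)

    # -- patches ----------------------------------------------------------

    def patch_faces(self, label: str) -> np.ndarray:
        return self.boundary_faces[self.boundary_labels == label]

    def patch_nodes(self, label: str) -> np.ndarray:
        return np.unique(self.patch_faces(label))

    @property
    def wall_nodes(self) -> np.ndarray:
        return self.patch_nodes(WALL)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_tets(self) -> int:
        return len(self.tets)

    def validate_patches(self) -> None:
        inlet, outlet = self.patch_nodes(INLET), self.patch_nodes(OUTLET)
        if inlet.size == 0 or outlet.size == 0:
            raise GeometryError("inlet and outlet patches must be non-empty")
        if np.intersect1d(inlet, outlet).size:
            raise GeometryError("inlet and outlet patches overlap")

    def shape_gradients(self) -> np.ndarray:
        """Gradients of the four P1 shape functions per tet, (m, 4, 3), 1/mm."""
        x = self.nodes[self.tets]
        a = x[:, 1:] - x[:, :1]          # rows: edge vectors from node 0
        ginv = np.linalg.inv(a)          # columns: grad of shapes 1..3
        g = np.transpose(ginv, (0, 2, 1))
        g0 = -g.sum(axis=1, keepdims=True)
        return np.concatenate([g0, g], axis=1)


@dataclasses.dataclass
class Plane:
    """Cut plane (point + unit normal, mm) used to label inlet/outlet faces.

    The normal points out of the vessel through the cut.
    """

    point: Sequence[float]
    normal: Sequence[float]

    def __post_init__(self):
        self.point = np.asarray(self.point, dtype=float)
        n = np.asarray(self.normal, dtype=float)
        norm = np.linalg.norm(n)
        if norm == 0:
            raise GeometryError("plane normal must be nonzero")
        self.normal = n / norm


def label_boundary_faces(mesh: TetMesh, inlet: Plane, outlet: Plane,
                         tol: float = 1.5, max_angle_deg: float = 45.0) -> None:
    """Assign inlet/outlet labels to boundary faces near the given cut planes.

    A face is labelled when its centroid lies within ``tol`` mm of the plane
    and its outward normal is within ``max_angle_deg`` of the plane normal;
    everything else is wall.  Modifies ``mesh.boundary_labels`` in place.
    """
    centroids = mesh.boundary_face_centroids()
    normals, _ = mesh.boundary_face_normals()
    labels = np.full(len(centroids), WALL, dtype=object)
    cos_min = np.cos(np.deg2rad(max_angle_deg))
    for plane, tag in ((inlet, INLET), (outlet, OUTLET)):
        dist = np.abs((centroids - plane.point) @ plane.normal)
        align = normals @ plane.normal
        labels[(dist <= tol) & (align >= cos_min)] = tag
    mesh.boundary_labels = labels
    mesh.validate_patches()


# Kuhn split of the unit cube: six tets sharing the main diagonal (0,0,0)-(1,1,1).
# Corner order: bit 0 -> +x, bit 1 -> +y, bit 2 -> +z.
_CUBE_TETS = np.array([
    [0, 1, 3, 7],
    [0, 3, 2, 7],
    [0, 2, 6, 7],
    [0, 6, 4, 7],
    [0, 4, 5, 7],
    [0, 5, 1, 7],
])
_CUBE_CORNERS = np.array(
    [[(c >> 0) & 1, (c >> 1) & 1, (c >> 2) & 1] for c in range(8)]
)


def mask_to_mesh(grid: VoxelGrid, inlet: Plane | None = None,
                 outlet: Plane | None = None, tol: float | None = None) -> TetMesh:
    """Tessellate every masked voxel into six tets sharing corner nodes.

    Voxel corners become mesh nodes (a voxel spans +/- half a spacing around
    its centre).  With ``inlet``/``outlet`` planes given, boundary faces are
    labelled; otherwise every boundary face is wall.  ``tol`` defaults to
    0.75x the max spacing (half a voxel plus slack for staircasing).
    """
    if not grid.mask.any():
        raise GeometryError("cannot mesh an empty mask")
    vox = np.argwhere(grid.mask)
    # Corner lattice indices: voxel (i,j,k) owns corners (i..i+1, ...).
    corners = (vox[:, None, :] + _CUBE_CORNERS[None, :, :]).reshape(-1, 3)
    uniq, inverse = np.unique(corners, axis=0, return_inverse=True)
    nodes = grid.voxel_centers_mm(uniq - 0.5)
    corner_ids = inverse.reshape(len(vox), 8)
    tets = corner_ids[:, _CUBE_TETS].reshape(-1, 4)
    # Enforce positive orientation once (same sign for every Kuhn tet).
    x = nodes[tets[0]]
    e = x[1:] - x[0]
    if np.dot(np.cross(e[0], e[1]), e[2]) < 0:
        tets = tets[:, [0, 2, 1, 3]]
    mesh = TetMesh(nodes, tets)
    if inlet is not None and outlet is not None:
        if tol is None:
            tol = 0.75 * float(grid.spacing.max())
        label_boundary_faces(mesh, inlet, outlet, tol=tol)
    return mesh


def lumped_node_volumes(mesh: TetMesh, units: str = "m3") -> np.ndarray:
    """Lumped nodal volumes: each tet contributes a quarter of its volume to
    each of its nodes.  Conserves total volume exactly.
    """
    vol = mesh.tet_volumes()
    if np.any(vol <= 0):
        raise MeshQualityError("degenerate tet")
    out = np.zeros(mesh.n_nodes)
    np.add.at(out, mesh.tets.ravel(), np.repeat(vol / 4.0, 4))
    if units == "m3":
        out *= 1e-9
    elif units != "mm3":
        raise ValueError("units must be 'm3' or 'mm3'")
    return out


def nearest_mask_voxel(grid: VoxelGrid) -> cKDTree:
    """KD-tree over in-mask voxel centres (mm), for nearest-neighbour fallback."""
    centers = grid.voxel_centers_mm(np.argwhere(grid.mask))
    return cKDTree(centers)
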