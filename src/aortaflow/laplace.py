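"""Laplace-equation parameterization of the vessel.

Solving the Laplace problem grad^2 phi = 0 with phi = 0 on the inlet, phi = 1
on the outlet and a natural (zero-flux) condition on the wall yields a smooth
normalized axial coordinate phi in [0, 1] along the lumen.  Its level sets are
cross-sections of the vessel, its normalized gradient is the local axial
direction, and intervals of phi delimited by anatomical landmarks split the
vessel into the 16 regions used for regional reporting.  The approach handles
a single unbranched vessel of interest.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .mesh import INLET, OUTLET, GeometryError, TetMesh

__all__ = [
    "LaplaceMap",
    "CrossSection",
    "RegionPartition",
    "TopologyError",
    "solve_laplace",
    "extract_cross_section",
    "equivalent_diameter",
    "partition_regions",
]


class TopologyError(ValueError):
    pass


@dataclasses.dataclass
class LaplaceMap:
    """Normalized axial coordinate and unit axial direction per node."""

    phi: np.ndarray          # (n_nodes,), in [0, 1]
    axial_dir: np.ndarray    # (n_nodes, 3), unit vectors

    def __post_init__(self):
        self.phi = np.asarray(self.phi, dtype=float)
        self.axial_dir = np.asarray(self.axial_dir, dtype=float)


@dataclasses.dataclass
class CrossSection:
    """Triangulated iso-surface of phi at one level.

    ``edge_nodes``/``edge_weights`` record, for each iso-surface vertex, the
    mesh edge it lies on and the interpolation weight toward the second node,
    so any nodal field can be sampled onto the section.
    """

    level: float
    verts: np.ndarray        # (nv, 3) mm
    tris: np.ndarray         # (nt, 3) vertex indices
    edge_nodes: np.ndarray   # (nv, 2) mesh node ids
    edge_weights: np.ndarray  # (nv,) weight toward edge_nodes[:, 1]
    normal: np.ndarray       # unit vector, aligned with mean axial direction

    @property
    def tri_areas_mm2(self) -> np.ndarray:
        t = self.verts[self.tris]
        return np.linalg.norm(
            np.cross(t[:, 1] - t[:, 0], t[:, 2] - t[:, 0]), axis=1
        ) / 2.0

    @property
    def area_cm2(self) -> float:
        return float(self.tri_areas_mm2.sum()) / 100.0

    @property
    def centroid(self) -> np.ndarray:
        """Area-weighted mean of triangle centroids, mm."""
        a = self.tri_areas_mm2
        c = self.verts[self.tris].mean(axis=1)
        return (a[:, None] * c).sum(axis=0) / a.sum()

    def sample(self, nodal_values: np.ndarray) -> np.ndarray:
        """Linearly interpolate a per-node array onto section vertices."""
        v = np.asarray(nodal_values)
        w = self.edge_weights
        va, vb = v[self.edge_nodes[:, 0]], v[self.edge_nodes[:, 1]]
        shape = (-1,) + (1,) * (v.ndim - 1)
        w = w.reshape(shape)
        return (1.0 - w) * va + w * vb


@dataclasses.dataclass
class RegionPartition:
    """Region label 1..16 per node (0 = proximal to the first landmark).

    Four anatomical landmarks (Valsalva level, brachiocephalic trunk, isthmus,
    diaphragm) given as phi values delimit four super-segments — ascending
    aorta, arch, proximal and distal descending aorta — each subdivided into
    four equal-phi sub-regions.
    """

    landmark_phis: np.ndarray
    region_id: np.ndarray

    def nodes_in_region(self, region: int) -> np.ndarray:
        return np.flatnonzero(self.region_id == region)

    def region_phi_bounds(self, region: int) -> tuple[float, float]:
        lm = self.landmark_phis
        seg, sub = divmod(region - 1, 4)
        lo, hi = lm[seg], lm[seg + 1]
        return (lo + sub * (hi - lo) / 4.0, lo + (sub + 1) * (hi - lo) / 4.0)


def solve_laplace(mesh: TetMesh, rtol: float = 1e-10) -> LaplaceMap:
    """P1 Galerkin solution of the axial Laplace problem.

    Dirichlet phi=0 on inlet nodes and phi=1 on outlet nodes; natural
    condition on the wall.  The axial direction is the normalized
    volume-weighted nodal average of the (element-constant) gradients of phi.
    """
    mesh.validate_patches()
    grads = mesh.shape_gradients()            # (m, 4, 3), 1/mm
    vol = mesh.tet_volumes()                  # mm^3
    ke = np.einsum("e,eid,ejd->eij", vol, grads, grads)
    rows = np.repeat(mesh.tets, 4, axis=1).ravel()
    cols = np.tile(mesh.tets, (1, 4)).ravel()
    K = sp.csr_matrix((ke.ravel(), (rows, cols)),
                      shape=(mesh.n_nodes, mesh.n_nodes))

    phi = np.zeros(mesh.n_nodes)
    phi[mesh.patch_nodes(OUTLET)] = 1.0
    fixed = np.zeros(mesh.n_nodes, dtype=bool)
    fixed[mesh.patch_nodes(INLET)] = True
    fixed[mesh.patch_nodes(OUTLET)] = True
    free = ~fixed
    Kff = K[free][:, free]
    rhs = -K[free][:, fixed] @ phi[fixed]
    try:
        sol = spla.spsolve(Kff.tocsc(), rhs)
    except RuntimeError as exc:   # pragma: no cover - singular factorization
        raise TopologyError(f"Laplace system is singular: {exc}") from exc
    if not np.all(np.isfinite(sol)):
        raise TopologyError("Laplace system is singular (disconnected mesh?)")
    phi[free] = sol
    res = np.linalg.norm(Kff @ sol - rhs)
    if res > rtol * max(1.0, np.linalg.norm(rhs)):
        raise TopologyError(f"Laplace solve did not converge (residual {res:.2e})")

    # Element gradients -> volume-weighted nodal average -> normalize.
    egrad = np.einsum("eid,ei->ed", grads, phi[mesh.tets])
    acc = np.zeros((mesh.n_nodes, 3))
    wsum = np.zeros(mesh.n_nodes)
    np.add.at(acc, mesh.tets.ravel(),
              np.repeat(vol[:, None] * egrad, 4, axis=0).reshape(-1, 3)[::1])
    np.add.at(wsum, mesh.tets.ravel(), np.repeat(vol, 4))
    nodal = acc / wsum[:, None]
    norms = np.linalg.norm(nodal, axis=1)
    ok = norms > 1e-12
    axial = np.zeros_like(nodal)
    axial[ok] = nodal[ok] / norms[ok, None]
    if not ok.all():
        # copy the nearest valid neighbour's direction
        from scipy.spatial import cKDTree

        tree = cKDTree(mesh.nodes[ok])
        _, j = tree.query(mesh.nodes[~ok])
        axial[~ok] = axial[np.flatnonzero(ok)[j]]
    return LaplaceMap(phi=phi, axial_dir=axial)


# marching-tetrahedra connectivity: for each tet, split by nodes below level
def _tet_iso(phi4: np.ndarray, level: float):
    below = phi4 < level
    nb = below.sum()
    if nb == 0 or nb == 4:
        return []
    lo = np.flatnonzero(below)
    hi = np.flatnonzero(~below)
    if nb == 1:
        a = lo[0]
        return [[(a, hi[0]), (a, hi[1]), (a, hi[2])]]
    if nb == 3:
        a = hi[0]
        return [[(lo[0], a), (lo[1], a), (lo[2], a)]]
    # nb == 2: quad through 4 edges, split into two triangles
    a, b = lo
    c, d = hi
    return [[(a, c), (a, d), (b, d)], [(a, c), (b, d), (b, c)]]


def extract_cross_section(mesh: TetMesh, lap: LaplaceMap,
                          level: float) -> CrossSection:
    """Marching-tetrahedra iso-surface of phi at ``level`` (0 < level < 1)."""
    if not (0.0 < level < 1.0):
        raise ValueError(f"level must lie strictly in (0, 1), got {level}")
    phi = lap.phi
    pt = phi[mesh.tets]
    cand = np.flatnonzero((pt.min(axis=1) < level) & (pt.max(axis=1) >= level))
    if cand.size == 0:
        raise ValueError(f"empty iso-surface at level {level}")
    edge_key: dict[tuple[int, int], int] = {}
    edge_nodes: list[tuple[int, int]] = []
    tris: list[list[int]] = []

    def vertex(i: int, j: int) -> int:
        key = (i, j) if i < j else (j, i)
        vid = edge_key.get(key)
        if vid is None:
            vid = len(edge_nodes)
            edge_key[key] = vid
            edge_nodes.append(key)
        return vid

    for e in cand:
        conn = mesh.tets[e]
        for tri in _tet_iso(phi[conn], level):
            tris.append([vertex(conn[i], conn[j]) for i, j in tri])
    en = np.array(edge_nodes, dtype=np.int64)
    pa, pb = phi[en[:, 0]], phi[en[:, 1]]
    w = (level - pa) / (pb - pa)
    verts = (1 - w)[:, None] * mesh.nodes[en[:, 0]] + w[:, None] * mesh.nodes[en[:, 1]]
    tris_arr = np.array(tris, dtype=np.int64)
    sec = CrossSection(level=level, verts=verts, tris=tris_arr,
                       edge_nodes=en, edge_weights=w,
                       normal=np.zeros(3))
    areas = sec.tri_areas_mm2
    keep = areas > 0
    sec.tris = tris_arr[keep]
    if sec.tris.size == 0:
        raise ValueError(f"degenerate iso-surface at level {level}")
    # orient the normal with the mean axial direction on the section
    mean_axial = sec.sample(lap.axial_dir).mean(axis=0)
    t = sec.verts[sec.tris]
    n = np.cross(t[:, 1] - t[:, 0], t[:, 2] - t[:, 0]).sum(axis=0)
    if np.dot(n, mean_axial) < 0:
        n = -n
    sec.normal = n / np.linalg.norm(n)
    return sec


def equivalent_diameter(section: CrossSection, units: str = "cm") -> float:
    """Diameter of the circle with the section's area: D = 2 sqrt(A / pi)."""
    d_cm = 2.0 * np.sqrt(section.area_cm2 / np.pi)
    if units == "cm":
        return d_cm
    if units == "mm":
        return d_cm * 10.0
    raise ValueError("units must be 'cm' or 'mm'")


def partition_regions(lap: LaplaceMap, landmark_phis) -> RegionPartition:
    """Split the vessel into 16 regions: 4 anatomical super-segments between
    consecutive landmarks, each cut into 4 equal-phi sub-regions.

    ``landmark_phis`` holds 5 increasing values (lambda_0..lambda_4) or 4
    values with an implied final bound of 1.  Nodes with phi below lambda_0
    (proximal to the Valsalva level) get region 0 (unlabeled).
    """
    lm = np.asarray(landmark_phis, dtype=float)
    if lm.size == 4:
        lm = np.append(lm, 1.0)
    if lm.size != 5 or np.any(np.diff(lm) <= 0):
        raise ValueError("landmarks must be 4 or 5 strictly increasing phi values")
    if lm[0] <= 0 or lm[-1] > 1:
        raise ValueError("landmarks must lie in (0, 1]")
    edges = np.concatenate(
        [np.linspace(lm[i], lm[i + 1], 5)[:-1] for i in range(4)] + [lm[-1:]]
    )
    region = np.searchsorted(edges, lap.phi, side="right")
    region[lap.phi == lm[-1]] = 16           # include the distal bound itself
    region[lap.phi > lm[-1]] = 0             # distal to the last landmark
    region[lap.phi < lm[0]] = 0
    return RegionPartition(landmark_phis=lm, region_id=region.astype(np.int64))
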