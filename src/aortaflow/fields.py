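"""Per-node fields and voxel-to-node velocity interpolation."""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.ndimage import map_coordinates

from .mesh import GeometryError, TetMesh, VoxelGrid, nearest_mask_voxel

__all__ = ["NodalField", "InterpolationError", "interpolate_velocity"]


class InterpolationError(ValueError):
    pass


@dataclasses.dataclass
class NodalField:
    """A named per-node quantity, per cardiac phase, with units.

    ``values`` has shape (n_support_nodes, n_phases) for scalars,
    (..., 3) for vectors and (..., 3, 3) for tensors.  ``support`` is
    ``"volume"`` (all mesh nodes) or ``"wall"`` (wall nodes only, in the
    order of ``mesh.wall_nodes``).
    """

    name: str
    units: str
    values: np.ndarray
    support: str = "volume"

    RANK_SHAPES = {(): "scalar", (3,): "vector", (3, 3): "tensor"}

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if not self.units:
            raise ValueError("units string must be non-empty")
        if self.support not in ("volume", "wall"):
            raise ValueError("support must be 'volume' or 'wall'")
        if self.rank is None:
            raise ValueError(f"unrecognised value shape {self.values.shape}")

    @property
    def rank(self) -> str | None:
        return self.RANK_SHAPES.get(self.values.shape[2:])

    @property
    def n_phases(self) -> int:
        return self.values.shape[1]

    def check_support(self, mesh: TetMesh) -> None:
        expected = len(mesh.wall_nodes) if self.support == "wall" else mesh.n_nodes
        if self.values.shape[0] != expected:
            raise ValueError(
                f"field '{self.name}' has {self.values.shape[0]} rows; mesh "
                f"{self.support} support needs {expected}"
            )

    def phase(self, k: int) -> np.ndarray:
        return self.values[:, k % self.n_phases]

    def magnitude(self) -> np.ndarray:
        if self.rank != "vector":
            raise ValueError("magnitude defined for vector fields")
        return np.linalg.norm(self.values, axis=-1)


def interpolate_velocity(grid: VoxelGrid, mesh: TetMesh,
                         nan_fallback: bool = True) -> NodalField:
    """Trilinear interpolation of the voxel velocity onto mesh nodes.

    Velocity outside the mask is sampled as-is (no-slip is not enforced);
    if masked-out voxels carry NaN, affected nodes fall back to the value at
    the nearest in-mask voxel centre.  Nodes outside the grid's bounding box
    are an error.
    """
    idx = grid.mm_to_index(mesh.nodes)          # fractional voxel coords
    lo, hi = -0.5, np.asarray(grid.shape) - 0.5
    outside = np.any((idx < lo) | (idx > hi), axis=1)
    if outside.any():
        bad = int(np.argmax(outside))
        raise InterpolationError(
            f"node {bad} at {mesh.nodes[bad]} lies outside the voxel grid"
        )
    n_phases = grid.n_phases
    out = np.empty((mesh.n_nodes, n_phases, 3))
    coords = idx.T
    for p in range(n_phases):
        for c in range(3):
            out[:, p, c] = map_coordinates(
                grid.velocity[..., p, c], coords, order=1, mode="nearest"
            )
    if nan_fallback and np.isnan(out).any():
        tree = nearest_mask_voxel(grid)
        bad_nodes = np.unique(np.argwhere(np.isnan(out))[:, 0])
        _, nearest = tree.query(mesh.nodes[bad_nodes])
        vox = np.argwhere(grid.mask)[nearest]
        out[bad_nodes] = grid.velocity[vox[:, 0], vox[:, 1], vox[:, 2]]
    return NodalField("velocity", "m/s", out, support="volume")
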