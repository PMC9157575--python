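"""Readers and writers: NIfTI voxel data, VTU meshes/fields, CSV tables.

VTU output is the plain ASCII XML UnstructuredGrid flavour, readable by
ParaView and VTK-based tools; only linear tetrahedra (VTK cell type 10) are
emitted.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .mesh import GeometryError, TetMesh, VoxelGrid

__all__ = [
    "read_voxel_grid",
    "write_voxel_grid",
    "write_vtu",
    "write_regional_table",
    "read_cohort_csv",
    "write_cohort_csv",
]


def _grid_geometry(img) -> tuple[np.ndarray, np.ndarray]:
    """(spacing, origin) from a near-axis-aligned NIfTI affine."""
    aff = img.affine
    lin = aff[:3, :3]
    spacing = np.linalg.norm(lin, axis=0)
    if np.any(spacing <= 0):
        raise GeometryError("degenerate NIfTI affine")
    off_axis = np.abs(lin) - np.diag(np.abs(np.diag(lin)))
    if np.max(off_axis) > 1e-3 * spacing.max():
        raise GeometryError(
            "oblique NIfTI affines are not supported; resample to an "
            "axis-aligned grid first")
    return np.abs(np.diag(lin)), aff[:3, 3].copy()


def read_voxel_grid(mask_path, velocity_paths,
                    phase_times_ms: np.ndarray | None = None) -> VoxelGrid:
    """Load a lumen mask plus per-phase 3-component velocity volumes.

    Each velocity file is a 4D NIfTI of shape (nx, ny, nz, 3) in m/s on the
    same grid as the mask.  Fewer than 3 phases, or any shape/affine
    mismatch, is an error.
    """
    mask_img = nib.load(str(mask_path))
    spacing, origin = _grid_geometry(mask_img)
    mask = np.asarray(mask_img.dataobj) > 0
    if len(velocity_paths) < 3:
        raise GeometryError("at least 3 cardiac phases are required")
    vols = []
    for p in velocity_paths:
        img = nib.load(str(p))
        if img.shape[:3] != mask.shape or img.ndim != 4 or img.shape[3] != 3:
            raise GeometryError(
                f"velocity volume {p} has shape {img.shape}; expected "
                f"{mask.shape + (3,)}")
        if not np.allclose(img.affine, mask_img.affine, atol=1e-4):
            raise GeometryError(f"affine of {p} differs from the mask's")
        vols.append(np.asarray(img.dataobj, dtype=float))
    velocity = np.stack(vols, axis=3)                 # (x, y, z, P, 3)
    if phase_times_ms is None:
        phase_times_ms = np.arange(len(vols), dtype=float) * 40.0
    return VoxelGrid(shape=mask.shape, spacing=spacing, origin=origin,
                     mask=mask, velocity=velocity,
                     phase_times=np.asarray(phase_times_ms, dtype=float))


def write_voxel_grid(grid: VoxelGrid, mask_path, velocity_dir) -> list[Path]:
    """Write the mask and one 4D velocity NIfTI per phase; returns the
    velocity paths."""
    aff = np.eye(4)
    aff[:3, :3] = np.diag(grid.spacing)
    aff[:3, 3] = grid.origin
    nib.save(nib.Nifti1Image(grid.mask.astype(np.uint8), aff), str(mask_path))
    velocity_dir = Path(velocity_dir)
    velocity_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for p in range(grid.n_phases):
        path = velocity_dir / f"velocity_phase{p:02d}.nii.gz"
        nib.save(nib.Nifti1Image(grid.velocity[..., p, :], aff), str(path))
        paths.append(path)
    return paths


def _ascii(a: np.ndarray) -> str:
    return " ".join(map(repr, np.asarray(a).ravel().tolist()))


def write_vtu(path, mesh: TetMesh, point_data: dict | None = None) -> Path:
    """Write the mesh and optional per-node arrays as an ASCII VTU file.

    ``point_data`` maps names to arrays of shape (n_nodes,) or (n_nodes, 3);
    multi-phase fields should be sliced to a single phase before export.
    """
    point_data = point_data or {}
    lines = [
        '<?xml version="1.0"?>',
        '<VTKFile type="UnstructuredGrid" version="0.1" '
        'byte_order="LittleEndian">',
        "<UnstructuredGrid>",
        f'<Piece NumberOfPoints="{mesh.n_nodes}" NumberOfCells="{mesh.n_tets}">',
        "<Points>",
        '<DataArray type="Float64" NumberOfComponents="3" format="ascii">',
        _ascii(mesh.nodes),
        "</DataArray>",
        "</Points>",
        "<Cells>",
        '<DataArray type="Int64" Name="connectivity" format="ascii">',
        _ascii(mesh.tets),
        "</DataArray>",
        '<DataArray type="Int64" Name="offsets" format="ascii">',
        _ascii(np.arange(1, mesh.n_tets + 1) * 4),
        "</DataArray>",
        '<DataArray type="UInt8" Name="types" format="ascii">',
        _ascii(np.full(mesh.n_tets, 10, dtype=np.uint8)),
        "</DataArray>",
        "</Cells>",
        "<PointData>",
    ]
    for name, arr in point_data.items():
        arr = np.asarray(arr, dtype=float)
        if arr.shape[0] != mesh.n_nodes:
            raise ValueError(f"point array '{name}' must have one row per node")
        ncomp = 1 if arr.ndim == 1 else arr.shape[1]
        lines += [
            f'<DataArray type="Float64" Name="{name}" '
            f'NumberOfComponents="{ncomp}" format="ascii">',
            _ascii(arr),
            "</DataArray>",
        ]
    lines += ["</PointData>", "</Piece>", "</UnstructuredGrid>", "</VTKFile>"]
    path = Path(path)
    path.write_text("\n".join(lines))
    return path


def read_vtu_points(path) -> np.ndarray:
    """Read back the node coordinates of a VTU written by :func:`write_vtu`."""
    import xml.etree.ElementTree as ET

    root = ET.parse(str(path)).getroot()
    da = root.find(".//Points/DataArray")
    return np.fromstring(da.text, sep=" ").reshape(-1, 3)


def write_regional_table(path, table: pd.DataFrame) -> Path:
    """Regional table CSV: rows = 18 quantities, columns = regions 1-16."""
    path = Path(path)
    table.to_csv(path, index_label="parameter")
    return path


def read_cohort_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"subject", "cohort", "parameter", "region", "value"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"cohort CSV missing columns: {sorted(missing)}")
    return df


def write_cohort_csv(path, cohort: pd.DataFrame) -> Path:
    path = Path(path)
    cohort.to_csv(path, index=False)
    return path


def write_run_metadata(path, **meta) -> Path:
    path = Path(path)
    path.write_text(json.dumps(meta, indent=2, default=str))
    return path
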