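"""Finite-element computation of the 17 hemodynamic parameter fields.

All parameters derive from three ingredients: the nodal velocity field, the
P1 mesh, and the Laplace axial map.  Velocity gradients are recovered at the
nodes by a global Galerkin (consistent-mass) L2 projection of the
element-constant P1 gradients, which is markedly more accurate at the wall
than simple volume-weighted averaging; the lumped average remains available.

Sign conventions
----------------
* The wall normal used for traction points from the wall into the lumen, so
  the wall shear vector is the tangential viscous traction exerted by the
  blood on the wall; forward (downstream) flow gives a positive axial
  component WSSA.
* Helicity density is a signed pseudoscalar; regional tables report the mean
  absolute value while the signed field is retained for export.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .fields import NodalField
from .laplace import (CrossSection, LaplaceMap, RegionPartition,
                      extract_cross_section, equivalent_diameter)
from .mesh import WALL, GeometryError, MeshQualityError, TetMesh, lumped_node_volumes

__all__ = [
    "FluidConstants",
    "WallShearRecord",
    "PARAMETERS",
    "velocity_gradient",
    "wall_normals",
    "wall_shear_stress",
    "vorticity_family",
    "axial_circulation",
    "directional_decomposition",
    "regurgitation_fraction",
    "flow_eccentricity",
    "energetics",
    "peak_systole_frames",
    "cyclic_phase_weights",
    "region_sections",
    "compute_regional_table",
]

#: Canonical regional-table rows: the 17 hemodynamic parameters plus diameter.
PARAMETERS = [
    "diameter_cm",
    "eccentricity_pct",
    "velocity_m_s",
    "forward_velocity_m_s",
    "backward_velocity_m_s",
    "velocity_angle_deg",
    "regurgitation_fraction_pct",
    "wss_Pa",
    "wssa_Pa",
    "wssc_Pa",
    "osi",
    "vorticity_1_s",
    "axial_vorticity_1_s",
    "axial_circulation_cm2_s",
    "helicity_density_m_s2",
    "viscous_dissipation_1e3_s2",
    "energy_loss_uW",
    "kinetic_energy_uJ",
]

#: Parameters computed over the whole cycle rather than the systolic window.
FULL_CYCLE_PARAMETERS = {"regurgitation_fraction_pct", "osi"}


@dataclasses.dataclass
class FluidConstants:
    """Blood constants: dynamic viscosity (Pa s) and density (kg/m^3)."""

    mu: float = 3.5e-3
    rho: float = 1060.0

    def __post_init__(self):
        if self.mu <= 0 or self.rho <= 0:
            raise ValueError("mu and rho must be positive")


@dataclasses.dataclass
class WallShearRecord:
    """Wall shear stress and its decomposition, per wall node per phase."""

    wall_nodes: np.ndarray   # mesh node ids, (nw,)
    tau: np.ndarray          # (nw, P, 3), Pa
    wssa: np.ndarray         # (nw, P) axial component
    wssc: np.ndarray         # (nw, P) circumferential component
    osi: np.ndarray          # (nw,), dimensionless

    @property
    def wss_mag(self) -> np.ndarray:
        return np.linalg.norm(self.tau, axis=-1)


def _assemble_mass(mesh: TetMesh) -> sp.csr_matrix:
    vol = mesh.tet_volumes()
    me = (np.ones((4, 4)) + np.eye(4)) / 20.0
    data = (vol[:, None, None] * me).ravel()
    rows = np.repeat(mesh.tets, 4, axis=1).ravel()
    cols = np.tile(mesh.tets, (1, 4)).ravel()
    return sp.csr_matrix((data, (rows, cols)), shape=(mesh.n_nodes, mesh.n_nodes))


def velocity_gradient(mesh: TetMesh, vel: NodalField,
                      method: str = "l2") -> NodalField:
    """Nodal velocity-gradient tensor G[i, j] = dv_i/dx_j in 1/s.

    ``method="l2"`` solves the consistent-mass Galerkin projection of the
    element gradients (default); ``method="lumped"`` uses the volume-weighted
    average of adjacent element gradients (the lumped-mass approximation).
    """
    vel.check_support(mesh)
    if vel.rank != "vector":
        raise ValueError("velocity must be a vector field")
    vol = mesh.tet_volumes()
    if np.any(vol <= 0):
        raise MeshQualityError("degenerate element")
    grads = mesh.shape_gradients() * 1000.0   # 1/mm -> 1/m
    P = vel.n_phases
    # element gradients: (m, P, 3, 3) is large; accumulate rhs directly.
    # b[node, p, i, j] = sum_e V_e/4 * G_e[p, i, j]
    rhs = np.zeros((mesh.n_nodes, P, 3, 3))
    v_elem = vel.values[mesh.tets]            # (m, 4, P, 3)
    egrad = np.einsum("ekd,ekpi->epid", grads, v_elem)   # (m, P, 3, 3)
    contrib = (vol[:, None, None, None] / 4.0) * egrad
    np.add.at(rhs, mesh.tets.ravel(),
              np.repeat(contrib, 4, axis=0).reshape(-1, P, 3, 3)[: 4 * len(vol)])
    # note: repeat duplicates each element contribution once per vertex
    if method == "lumped":
        vnode = lumped_node_volumes(mesh, units="mm3")
        g = rhs / vnode[:, None, None, None]
    elif method == "l2":
        M = _assemble_mass(mesh)
        lu = spla.splu(M.tocsc())
        flat = rhs.reshape(mesh.n_nodes, -1)
        g = lu.solve(flat).reshape(mesh.n_nodes, P, 3, 3)
    else:
        raise ValueError("method must be 'l2' or 'lumped'")
    return NodalField("velocity_gradient", "1/s", g, support="volume")


def wall_normals(mesh: TetMesh) -> np.ndarray:
    """Inward (wall -> lumen) unit normals per wall node, area-weighted over
    adjacent wall faces."""
    faces = mesh.patch_faces(WALL)
    if faces.size == 0:
        raise GeometryError("mesh has no wall faces")
    n_out, areas = mesh.boundary_face_normals()
    out = n_out[mesh.boundary_labels == WALL]
    acc = np.zeros((mesh.n_nodes, 3))
    np.add.at(acc, faces.ravel(), np.repeat(out * areas[
        mesh.boundary_labels == WALL][:, None], 3, axis=0).reshape(-1, 3))
    wn = mesh.wall_nodes
    vecs = acc[wn]
    norms = np.linalg.norm(vecs, axis=1)
    if np.any(norms == 0):
        raise GeometryError("wall node with undefined normal")
    return -(vecs / norms[:, None])           # flip: outward -> inward


def cyclic_phase_weights(phase_times: np.ndarray | None, n_phases: int) -> np.ndarray:
    """Per-phase time weights dt (ms) for cyclic trapezoid-style sums.

    With retrospective gating the phases tile a full cycle; the weight of
    phase k is half the distance between its cyclic neighbours.  Uniform
    weights are returned when times are not given.
    """
    if phase_times is None:
        return np.full(n_phases, 1.0 / n_phases)
    t = np.asarray(phase_times, dtype=float)
    if t.shape != (n_phases,):
        raise ValueError("phase_times length mismatch")
    if n_phases == 1:
        return np.array([1.0])
    dt = np.diff(t)
    period = t[-1] - t[0] + np.median(dt)
    nxt = np.roll(t, -1).copy()
    nxt[-1] = t[0] + period
    prv = np.roll(t, 1).copy()
    prv[0] = t[-1] - period
    return (nxt - prv) / 2.0


def wall_shear_stress(mesh: TetMesh, vel: NodalField, lap: LaplaceMap,
                      constants: FluidConstants,
                      grad: NodalField | None = None,
                      phase_times: np.ndarray | None = None) -> WallShearRecord:
    """WSS vector, axial/circumferential components and OSI at wall nodes.

    tau is the tangential part of the viscous traction 2 mu D n with
    D = (G + G^T)/2 and n the inward wall normal; the axial unit vector is
    the tangential projection of the Laplace axial direction, and the
    circumferential direction completes the local frame (n x e_axial).
    OSI = (1 - |sum tau dt| / sum |tau| dt) / 2 over the full cycle.
    """
    if grad is None:
        grad = velocity_gradient(mesh, vel)
    wn = mesh.wall_nodes
    n = wall_normals(mesh)                    # (nw, 3) inward
    G = grad.values[wn]                       # (nw, P, 3, 3)
    D = 0.5 * (G + np.swapaxes(G, -1, -2))
    t = 2.0 * constants.mu * np.einsum("wpij,wj->wpi", D, n)
    tau = t - np.einsum("wpi,wi->wp", t, n)[..., None] * n[:, None, :]
    ea = lap.axial_dir[wn]
    ea_t = ea - np.einsum("wi,wi->w", ea, n)[:, None] * n
    ea_norm = np.linalg.norm(ea_t, axis=1)
    ea_norm[ea_norm == 0] = 1.0
    ea_t = ea_t / ea_norm[:, None]
    ec = np.cross(n, ea_t)
    wssa = np.einsum("wpi,wi->wp", tau, ea_t)
    wssc = np.einsum("wpi,wi->wp", tau, ec)
    dt = cyclic_phase_weights(phase_times, vel.n_phases)
    mean_vec = np.einsum("wpi,p->wi", tau, dt)
    mean_mag = np.einsum("wp,p->w", np.linalg.norm(tau, axis=-1), dt)
    with np.errstate(invalid="ignore", divide="ignore"):
        osi = 0.5 * (1.0 - np.linalg.norm(mean_vec, axis=1) / mean_mag)
    osi[mean_mag == 0] = 0.0
    return WallShearRecord(wall_nodes=wn, tau=tau, wssa=wssa, wssc=wssc,
                           osi=np.clip(osi, 0.0, 0.5))


def vorticity_family(mesh: TetMesh, vel: NodalField, lap: LaplaceMap,
                     grad: NodalField | None = None) -> dict[str, NodalField]:
    """Vorticity magnitude (1/s), axial vorticity (1/s) and signed helicity
    density v . omega (m/s^2)."""
    if grad is None:
        grad = velocity_gradient(mesh, vel)
    G = grad.values
    omega = np.stack([
        G[..., 2, 1] - G[..., 1, 2],
        G[..., 0, 2] - G[..., 2, 0],
        G[..., 1, 0] - G[..., 0, 1],
    ], axis=-1)                               # (n, P, 3)
    mag = np.linalg.norm(omega, axis=-1)
    axial = np.einsum("npi,ni->np", omega, lap.axial_dir)
    hel = np.einsum("npi,npi->np", vel.values, omega)
    return {
        "vorticity_vector": NodalField("vorticity_vector", "1/s", omega),
        "vorticity_1_s": NodalField("vorticity", "1/s", mag),
        "axial_vorticity_1_s": NodalField("axial_vorticity", "1/s", axial),
        "helicity_density_m_s2": NodalField("helicity_density", "m/s^2", hel),
    }


def axial_circulation(section: CrossSection,
                      axial_vorticity: np.ndarray) -> np.ndarray:
    """Signed circulation Gamma = integral of axial vorticity over the
    section, cm^2/s, per phase (midpoint rule per triangle)."""
    w = section.sample(np.asarray(axial_vorticity))   # (nv, P)
    tri_mean = w[section.tris].mean(axis=1)           # (nt, P)
    areas = section.tri_areas_mm2                     # mm^2
    return (tri_mean * areas[:, None]).sum(axis=0) * 0.01   # mm^2 -> cm^2


def directional_decomposition(vel: NodalField, lap: LaplaceMap,
                              angle_eps: float = 1e-3) -> dict[str, NodalField]:
    """Speed, forward/backward axial components, and the velocity angle (deg)
    between the velocity vector and the local axial direction.

    The angle is set to 0 where speed < ``angle_eps`` m/s (noise floor)."""
    v = vel.values
    speed = np.linalg.norm(v, axis=-1)
    s = np.einsum("npi,ni->np", v, lap.axial_dir)
    forward = np.maximum(s, 0.0)
    backward = np.abs(np.minimum(s, 0.0))
    with np.errstate(invalid="ignore", divide="ignore"):
        cosang = np.clip(s / speed, -1.0, 1.0)
    angle = np.degrees(np.arccos(cosang))
    angle[speed < angle_eps] = 0.0
    return {
        "velocity_m_s": NodalField("velocity", "m/s", speed),
        "forward_velocity_m_s": NodalField("forward_velocity", "m/s", forward),
        "backward_velocity_m_s": NodalField("backward_velocity", "m/s", backward),
        "velocity_angle_deg": NodalField("velocity_angle", "deg", angle),
    }


def section_flow_rate(section: CrossSection, vel: NodalField) -> np.ndarray:
    """Flow rate Q(t) through a cross-section, ml/s, per phase."""
    vsec = section.sample(vel.values)                 # (nv, P, 3)
    vn = np.einsum("vpi,i->vp", vsec, section.normal)
    tri_mean = vn[section.tris].mean(axis=1)
    areas = section.tri_areas_mm2
    # m/s * mm^2 = 1e-6 m^3/s = ml/s... (1 m/s * 1 mm^2 = 1e-6 m^3/s = 1 ml/s)
    return (tri_mean * areas[:, None]).sum(axis=0)


def regurgitation_fraction(sections: list[CrossSection], vel: NodalField,
                           phase_times: np.ndarray | None = None) -> float:
    """Backward-to-forward volume ratio (percent) over the full cycle,
    averaged across the given cross-sections."""
    dt = cyclic_phase_weights(phase_times, vel.n_phases)
    vals = []
    for sec in sections:
        q = section_flow_rate(sec, vel)
        vf = float(np.sum(np.maximum(q, 0.0) * dt))
        vb = float(np.sum(np.abs(np.minimum(q, 0.0)) * dt))
        if vf == 0.0:
            warnings.warn("regurgitation fraction undefined: no forward flow")
            vals.append(np.nan)
        else:
            vals.append(100.0 * vb / vf)
    return float(np.nanmean(vals)) if vals else np.nan


def flow_eccentricity(section: CrossSection, vel: NodalField) -> np.ndarray:
    """Displacement of the forward-velocity-weighted centroid from the lumen
    centroid, percent of the equivalent radius, per phase; clipped to
    [0, 100].  NaN where there is no forward flow."""
    vsec = section.sample(vel.values)
    w = np.maximum(np.einsum("vpi,i->vp", vsec, section.normal), 0.0)
    tri_w = w[section.tris].mean(axis=1)              # (nt, P)
    tri_c = section.verts[section.tris].mean(axis=1)  # (nt, 3)
    areas = section.tri_areas_mm2
    wsum = (tri_w * areas[:, None]).sum(axis=0)       # (P,)
    cw = np.einsum("tp,t,ti->pi", tri_w, areas, tri_c)
    with np.errstate(invalid="ignore", divide="ignore"):
        cw = cw / wsum[:, None]
    r_eq = 10.0 * np.sqrt(section.area_cm2 / np.pi)   # mm
    ecc = 100.0 * np.linalg.norm(cw - section.centroid, axis=1) / r_eq
    ecc[wsum == 0] = np.nan
    return np.clip(ecc, 0.0, 100.0)


def energetics(mesh: TetMesh, vel: NodalField, grad: NodalField,
               constants: FluidConstants,
               node_volumes: np.ndarray | None = None) -> dict[str, NodalField]:
    """Viscous dissipation function, per-node energy loss and kinetic energy.

    phi_d = 2 D:D (s^-2); energy loss per node = mu phi_d V_node (microwatt);
    kinetic energy per node = rho |v|^2 V_node / 2 (microjoule), with V_node
    the lumped nodal volume in m^3.
    """
    if node_volumes is None:
        node_volumes = lumped_node_volumes(mesh, units="m3")
    G = grad.values
    D = 0.5 * (G + np.swapaxes(G, -1, -2))
    phi_d = 2.0 * np.einsum("npij,npij->np", D, D)
    eloss = constants.mu * phi_d * node_volumes[:, None] * 1e6
    ke = 0.5 * constants.rho * np.sum(vel.values**2, axis=-1) \
        * node_volumes[:, None] * 1e6
    return {
        "viscous_dissipation_s2": NodalField("viscous_dissipation", "1/s^2", phi_d),
        "energy_loss_uW": NodalField("energy_loss", "uW", eloss),
        "kinetic_energy_uJ": NodalField("kinetic_energy", "uJ", ke),
    }


def peak_systole_frames(vel: NodalField,
                        node_volumes: np.ndarray | None = None) -> np.ndarray:
    """The four-phase systolic window {k-1, k, k+1, k+2} (cyclic), where k is
    the phase of maximal mean speed (volume-weighted when volumes given;
    ties break to the lowest index)."""
    P = vel.n_phases
    if P < 4:
        raise ValueError("need at least 4 phases for the systolic window")
    speed = vel.magnitude()
    if node_volumes is None:
        series = speed.mean(axis=0)
    else:
        series = (speed * node_volumes[:, None]).sum(axis=0) / node_volumes.sum()
    k = int(np.argmax(series))
    return np.array([k - 1, k, k + 1, k + 2]) % P


def region_sections(mesh: TetMesh, lap: LaplaceMap, part: RegionPartition,
                    region: int, n_sections: int = 5) -> list[CrossSection]:
    """Evenly spaced cross-sections spanning a region's phi interval."""
    lo, hi = part.region_phi_bounds(region)
    levels = np.linspace(lo, hi, n_sections + 2)[1:-1]
    out = []
    for lv in levels:
        try:
            out.append(extract_cross_section(mesh, lap, float(lv)))
        except ValueError:
            continue
    return out


def compute_regional_table(mesh: TetMesh, vel: NodalField, lap: LaplaceMap,
                           part: RegionPartition,
                           constants: FluidConstants | None = None,
                           phase_times: np.ndarray | None = None,
                           n_sections: int = 5,
                           dissipation_scale: float = 1e3,
                           gradient_method: str = "l2") -> pd.DataFrame:
    """Regional means of the 17 parameters plus diameter: 18 rows x 16 regions.

    Phase-resolved parameters are averaged over the peak-systole window;
    regurgitation fraction and OSI use the entire cycle.  Wall quantities
    average over wall nodes per region; WSSC and helicity density are
    reported as mean absolute values (their signs encode local handedness).
    """
    constants = constants or FluidConstants()
    vel.check_support(mesh)
    node_vol = lumped_node_volumes(mesh, units="m3")
    grad = velocity_gradient(mesh, vel, method=gradient_method)
    window = peak_systole_frames(vel, node_vol)

    direc = directional_decomposition(vel, lap)
    vort = vorticity_family(mesh, vel, lap, grad)
    ener = energetics(mesh, vel, grad, constants, node_vol)
    shear = wall_shear_stress(mesh, vel, lap, constants, grad, phase_times)

    nodal = {
        "velocity_m_s": direc["velocity_m_s"].values,
        "forward_velocity_m_s": direc["forward_velocity_m_s"].values,
        "backward_velocity_m_s": direc["backward_velocity_m_s"].values,
        "velocity_angle_deg": direc["velocity_angle_deg"].values,
        "vorticity_1_s": vort["vorticity_1_s"].values,
        "axial_vorticity_1_s": vort["axial_vorticity_1_s"].values,
        "helicity_density_m_s2": np.abs(vort["helicity_density_m_s2"].values),
        "viscous_dissipation_1e3_s2":
            ener["viscous_dissipation_s2"].values / dissipation_scale,
        "energy_loss_uW": ener["energy_loss_uW"].values,
        "kinetic_energy_uJ": ener["kinetic_energy_uJ"].values,
    }
    wall = {
        "wss_Pa": shear.wss_mag,
        "wssa_Pa": shear.wssa,
        "wssc_Pa": np.abs(shear.wssc),
    }
    wall_region = part.region_id[shear.wall_nodes]

    table = pd.DataFrame(index=PARAMETERS, columns=range(1, 17), dtype=float)
    for region in range(1, 17):
        in_region = part.region_id == region
        wall_mask = wall_region == region
        for name, arr in nodal.items():
            if in_region.any():
                table.loc[name, region] = arr[in_region][:, window].mean()
        for name, arr in wall.items():
            if wall_mask.any():
                table.loc[name, region] = arr[wall_mask][:, window].mean()
        if wall_mask.any():
            table.loc["osi", region] = shear.osi[wall_mask].mean()
        secs = region_sections(mesh, lap, part, region, n_sections)
        if secs:
            table.loc["diameter_cm", region] = float(
                np.mean([equivalent_diameter(s) for s in secs]))
            gam = np.array([
                axial_circulation(s, vort["axial_vorticity_1_s"].values)
                for s in secs])                      # (ns, P)
            table.loc["axial_circulation_cm2_s", region] = gam[:, window].mean()
            ecc = np.array([flow_eccentricity(s, vel) for s in secs])
            table.loc["eccentricity_pct", region] = float(
                np.nanmean(ecc[:, window]))
            table.loc["regurgitation_fraction_pct", region] = \
                regurgitation_fraction(secs, vel, phase_times)
    return table
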