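"""Synthetic vessels, analytic flows with closed-form expectations, and a
simulated patient cohort.

The generator stands in for patient 4D-flow data: a straight circular tube
(thoracic-aorta calibre, R ~ 10-15 mm, L ~ 80-120 mm) carrying canonical
flows whose hemodynamic parameters are known in closed form — Poiseuille,
plug, solid-body rotation, helical (plug + rotation), an eccentric Gaussian
jet, and a reversing waveform.  The cohort simulator draws per-subject
regional parameter tables with the group mean shifts observed between
healthy volunteers and bicuspid-aortic-valve patients, so the downstream
statistics have realistic signal to recover.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .fields import NodalField
from .hemodynamics import PARAMETERS, FluidConstants
from .mesh import INLET, OUTLET, WALL, GeometryError, TetMesh, VoxelGrid

__all__ = [
    "FlowSpec",
    "CohortSpec",
    "GROUP_PARAMETER_TABLE",
    "make_cylinder",
    "default_waveform",
    "analytic_flow",
    "simulate_cohort",
]

FLOW_KINDS = ("poiseuille", "plug", "solid_rotation", "helical",
              "eccentric_jet", "reversing")


@dataclasses.dataclass
class FlowSpec:
    """Analytic flow on a straight tube along +z.

    Amplitudes: ``vmax`` (m/s) for axial profiles, ``omega`` (rad/s) for
    rotation, ``jet_offset``/``jet_width`` (mm) for the eccentric jet.
    ``waveform`` scales the field per phase (length = phase count).
    """

    kind: str
    radius_mm: float = 10.0
    length_mm: float = 80.0
    vmax: float = 1.0
    omega: float = 10.0
    jet_offset_mm: float = 5.0
    jet_width_mm: float = 3.0
    waveform: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self):
        if self.kind not in FLOW_KINDS:
            raise ValueError(f"unknown flow kind '{self.kind}'")
        if self.radius_mm <= 0 or self.length_mm <= 0:
            raise ValueError("radius and length must be positive")
        if self.waveform is None:
            self.waveform = np.ones(4)
        self.waveform = np.asarray(self.waveform, dtype=float)

    @property
    def n_phases(self) -> int:
        return len(self.waveform)


def default_waveform(n_phases: int = 20, systole_fraction: float = 0.35,
                     diastole_level: float = 0.05) -> np.ndarray:
    """Half-sine systolic lobe over the first ``systole_fraction`` of the
    cycle, flat low diastole elsewhere."""
    t = (np.arange(n_phases) + 0.5) / n_phases   # midpoint sampling
    w = np.full(n_phases, diastole_level)
    sys = t < systole_fraction
    w[sys] = np.maximum(np.sin(np.pi * t[sys] / systole_fraction),
                        diastole_level)
    return w


# ---------------------------------------------------------------------------
# cylinder meshing: structured disk triangulation extruded into prisms, each
# prism split into tets with the Dompierre minimum-index rule (conforming).

def _disk_points(R: float, n_rings: int):
    pts = [(0.0, 0.0)]
    ring_start = [0, 1]
    for k in range(1, n_rings + 1):
        n = 6 * k
        ang = 2 * np.pi * np.arange(n) / n
        r = R * k / n_rings
        pts.extend(zip(r * np.cos(ang), r * np.sin(ang)))
        ring_start.append(ring_start[-1] + n)
    return np.array(pts), ring_start


def _disk_triangles(points: np.ndarray) -> np.ndarray:
    from scipy.spatial import Delaunay

    return Delaunay(points).simplices.astype(np.int64)


def _orient_ccw(points: np.ndarray, tris: np.ndarray) -> np.ndarray:
    p = points[tris]
    u, v = p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]
    flip = u[:, 0] * v[:, 1] - u[:, 1] * v[:, 0] < 0
    tris = tris.copy()
    tris[flip] = tris[flip][:, [0, 2, 1]]
    return tris


def _split_prism(bot, top):
    """Split prism (bot 3 ids, top 3 ids, top[i] above bot[i]) into 3 tets
    using the minimum-global-index diagonal rule (conforming across prisms)."""
    V = list(bot) + list(top)
    # rotate so the smallest id sits at position 0 (bottom); flip if on top
    if int(np.argmin(V)) >= 3:
        # flip the prism upside down (vertical pairing preserved)
        V = [V[3], V[5], V[4], V[0], V[2], V[1]]
    r = int(np.argmin(V))
    V = [V[r], V[(r + 1) % 3], V[(r + 2) % 3],
         V[3 + r], V[3 + (r + 1) % 3], V[3 + (r + 2) % 3]]
    if min(V[1], V[5]) < min(V[2], V[4]):
        return [(V[0], V[1], V[2], V[5]),
                (V[0], V[1], V[5], V[4]),
                (V[0], V[4], V[5], V[3])]
    return [(V[0], V[1], V[2], V[4]),
            (V[0], V[4], V[2], V[5]),
            (V[0], V[4], V[5], V[3])]


def make_cylinder(radius_mm: float = 10.0, length_mm: float = 80.0,
                  h_mm: float = 2.5, with_grid: bool = True,
                  n_phases: int = 4):
    """Structured tet mesh of a tube along +z (inlet z=0, outlet z=L) with
    target edge length ``h_mm``, plus the equivalent voxel mask grid.

    Returns ``(mesh, grid)``; ``grid`` is None when ``with_grid`` is False.
    """
    if h_mm >= radius_mm:
        raise GeometryError("target edge length must be smaller than the radius")
    n_rings = max(2, int(round(radius_mm / h_mm)))
    n_layers = max(2, int(round(length_mm / h_mm)))
    disk, _ = _disk_points(radius_mm, n_rings)
    tris = _orient_ccw(disk, _disk_triangles(disk))
    n_disk = len(disk)
    zs = np.linspace(0.0, length_mm, n_layers + 1)
    nodes = np.concatenate([
        np.column_stack([np.tile(disk[:, 0], len(zs)),
                         np.tile(disk[:, 1], len(zs)),
                         np.repeat(zs, n_disk)])
    ])
    tets = []
    for iz in range(n_layers):
        lo, hi = iz * n_disk, (iz + 1) * n_disk
        for t in tris:
            tets.extend(_split_prism([lo + i for i in t], [hi + i for i in t]))
    tets = np.asarray(tets, dtype=np.int64)
    # repair orientation per tet (the split preserves topology, not sign)
    x = nodes[tets]
    e = x[:, 1:] - x[:, :1]
    neg = np.einsum("ij,ij->i", np.cross(e[:, 0], e[:, 1]), e[:, 2]) < 0
    tets[neg] = tets[neg][:, [0, 2, 1, 3]]
    mesh = TetMesh(nodes, tets)
    centroids = mesh.boundary_face_centroids()
    labels = np.full(len(centroids), WALL, dtype=object)
    labels[np.abs(centroids[:, 2]) < 1e-9] = INLET
    labels[np.abs(centroids[:, 2] - length_mm) < 1e-9] = OUTLET
    mesh.boundary_labels = labels
    mesh.validate_patches()

    grid = None
    if with_grid:
        pad = 2
        n_xy = int(np.ceil(2 * radius_mm / h_mm)) + 2 * pad
        n_z = int(np.ceil(length_mm / h_mm)) + 2 * pad
        origin = np.array([-(n_xy / 2 - 0.5) * h_mm,
                           -(n_xy / 2 - 0.5) * h_mm,
                           -(pad - 0.5) * h_mm])
        ii = np.arange(n_xy)
        xs = origin[0] + ii * h_mm
        zs_g = origin[2] + np.arange(n_z) * h_mm
        X, Y = np.meshgrid(xs, xs, indexing="ij")
        in_disk = (X**2 + Y**2) <= radius_mm**2
        in_z = (zs_g >= 0) & (zs_g <= length_mm)
        mask = in_disk[:, :, None] & in_z[None, None, :]
        grid = VoxelGrid(
            shape=(n_xy, n_xy, n_z),
            spacing=np.full(3, h_mm),
            origin=origin,
            mask=mask,
            velocity=np.zeros((n_xy, n_xy, n_z, n_phases, 3)),
            phase_times=np.arange(n_phases) * 40.0,
        )
    return mesh, grid


# ---------------------------------------------------------------------------
# analytic flows

def _velocity_at(points: np.ndarray, spec: FlowSpec) -> np.ndarray:
    """Single-phase (unit-waveform) velocity at mm points, m/s."""
    x, y = points[:, 0], points[:, 1]
    r2 = x**2 + y**2
    R = spec.radius_mm
    v = np.zeros((len(points), 3))
    if spec.kind == "poiseuille":
        v[:, 2] = spec.vmax * np.maximum(1.0 - r2 / R**2, 0.0)
    elif spec.kind in ("plug", "reversing"):
        v[:, 2] = spec.vmax
    elif spec.kind == "solid_rotation":
        v[:, 0] = -spec.omega * y * 1e-3      # mm -> m
        v[:, 1] = spec.omega * x * 1e-3
    elif spec.kind == "helical":
        v[:, 0] = -spec.omega * y * 1e-3
        v[:, 1] = spec.omega * x * 1e-3
        v[:, 2] = spec.vmax
    elif spec.kind == "eccentric_jet":
        d2 = (x - spec.jet_offset_mm)**2 + y**2
        v[:, 2] = spec.vmax * np.exp(-d2 / (2.0 * spec.jet_width_mm**2))
    return v


def analytic_flow(mesh: TetMesh, spec: FlowSpec,
                  constants: FluidConstants | None = None):
    """Velocity field for ``spec`` on ``mesh`` plus closed-form expectations.

    Returns ``(field, expectations)``; the expectations dict holds the exact
    values the hemodynamics stage should reproduce within mesh tolerance.
    """
    constants = constants or FluidConstants()
    base = _velocity_at(mesh.nodes, spec)
    values = base[:, None, :] * spec.waveform[None, :, None]
    field = NodalField("velocity", "m/s", values)

    R_m = spec.radius_mm * 1e-3
    exp: dict[str, float] = {"kind": spec.kind}
    if spec.kind == "poiseuille":
        exp.update(wss_Pa=2 * constants.mu * spec.vmax / R_m,
                   wssc_Pa=0.0, velocity_angle_deg=0.0,
                   eccentricity_pct=0.0, axial_circulation_cm2_s=0.0,
                   helicity_density_m_s2=0.0, osi=0.0)
    elif spec.kind == "solid_rotation":
        exp.update(vorticity_1_s=2 * spec.omega,
                   axial_vorticity_1_s=2 * spec.omega,
                   axial_circulation_cm2_s=2 * spec.omega * np.pi
                   * (spec.radius_mm / 10.0)**2,
                   viscous_dissipation_s2=0.0, energy_loss_uW=0.0)
    elif spec.kind == "helical":
        # angle at radius r: atan(omega r / vz); omega r in m/s with r in m
        exp.update(axial_vorticity_1_s=2 * spec.omega,
                   angle_at_radius=lambda r_mm: np.degrees(
                       np.arctan2(spec.omega * r_mm * 1e-3, spec.vmax)))
    elif spec.kind == "eccentric_jet":
        exp.update(eccentricity_limit_pct=100.0 * spec.jet_offset_mm
                   / spec.radius_mm)
    elif spec.kind == "reversing":
        w = spec.waveform
        pos = float(np.sum(np.maximum(w, 0.0)))
        neg = float(np.sum(np.abs(np.minimum(w, 0.0))))
        exp.update(regurgitation_fraction_pct=100.0 * neg / pos
                   if pos else np.nan)
        if pos > 0 and neg > 0 and abs(pos - neg) / max(pos, neg) < 1e-12:
            exp.update(osi=0.5)
    elif spec.kind == "plug":
        exp.update(velocity_angle_deg=0.0, eccentricity_pct=0.0)
    return field, exp


def fill_grid_velocity(grid: VoxelGrid, spec: FlowSpec) -> None:
    """Write the analytic flow onto the voxel grid (all voxels, all phases)."""
    ii = np.indices(grid.shape).reshape(3, -1).T
    pts = grid.voxel_centers_mm(ii)
    base = _velocity_at(pts, spec).reshape(grid.shape + (3,))
    grid.velocity = base[..., None, :] * spec.waveform[None, None, None, :, None]
    grid.phase_times = np.arange(spec.n_phases) * 40.0


# ---------------------------------------------------------------------------
# cohort simulation

#: Per-parameter (mean, SD) for healthy volunteers and the BAV morphotypes in
#: the ascending aorta; BAV subjects are drawn from their morphotype column.
GROUP_PARAMETER_TABLE = pd.DataFrame(
    {
        "HV": {
            "diameter_cm": (2.87, 0.39),
            "eccentricity_pct": (18.76, 8.08),
            "velocity_m_s": (0.41, 0.14),
            "forward_velocity_m_s": (0.39, 0.14),
            "backward_velocity_m_s": (0.00, 0.005),
            "velocity_angle_deg": (17.79, 7.10),
            "regurgitation_fraction_pct": (13.37, 8.46),
            "wss_Pa": (0.64, 0.25),
            "wssa_Pa": (0.60, 0.26),
            "wssc_Pa": (0.14, 0.06),
            "osi": (0.17, 0.05),
            "vorticity_1_s": (62.76, 17.72),
            "axial_vorticity_1_s": (3.30, 9.47),
            "axial_circulation_cm2_s": (27.18, 64.00),
            "helicity_density_m_s2": (8.18, 4.47),
            "viscous_dissipation_1e3_s2": (6.25, 3.36),
            "energy_loss_uW": (0.39, 0.22),
            "kinetic_energy_uJ": (2.01, 1.34),
        },
        "AAoD": {
            "diameter_cm": (4.34, 0.60),
            "eccentricity_pct": (42.65, 13.02),
            "velocity_m_s": (0.36, 0.11),
            "forward_velocity_m_s": (0.22, 0.07),
            "backward_velocity_m_s": (0.03, 0.02),
            "velocity_angle_deg": (56.24, 12.90),
            "regurgitation_fraction_pct": (44.09, 15.34),
            "wss_Pa": (0.50, 0.19),
            "wssa_Pa": (0.35, 0.14),
            "wssc_Pa": (0.28, 0.14),
            "osi": (0.16, 0.04),
            "vorticity_1_s": (68.36, 23.43),
            "axial_vorticity_1_s": (16.48, 11.14),
            "axial_circulation_cm2_s": (259.67, 170.06),
            "helicity_density_m_s2": (9.33, 5.78),
            "viscous_dissipation_1e3_s2": (7.34, 4.38),
            "energy_loss_uW": (0.46, 0.28),
            "kinetic_energy_uJ": (1.68, 0.89),
        },
        "NonAAoD": {
            "diameter_cm": (3.50, 0.53),
            "eccentricity_pct": (37.83, 14.10),
            "velocity_m_s": (0.43, 0.10),
            "forward_velocity_m_s": (0.33, 0.11),
            "backward_velocity_m_s": (0.02, 0.02),
            "velocity_angle_deg": (40.88, 16.38),
            "regurgitation_fraction_pct": (36.43, 30.23),
            "wss_Pa": (0.65, 0.22),
            "wssa_Pa": (0.52, 0.20),
            "wssc_Pa": (0.29, 0.13),
            "osi": (0.18, 0.05),
            "vorticity_1_s": (79.65, 21.05),
            "axial_vorticity_1_s": (19.14, 15.70),
            "axial_circulation_cm2_s": (204.00, 142.72),
            "helicity_density_m_s2": (10.43, 4.48),
            "viscous_dissipation_1e3_s2": (8.28, 3.84),
            "energy_loss_uW": (0.50, 0.26),
            "kinetic_energy_uJ": (2.15, 1.04),
        },
    }
)

#: Parameters that cannot be negative (truncated at zero when sampling).
_POSITIVE_ONLY = {p for p in PARAMETERS if p not in ("axial_circulation_cm2_s",
                                                     "axial_vorticity_1_s",
                                                     "helicity_density_m_s2")}


@dataclasses.dataclass
class CohortSpec:
    """Simulated cohort: healthy volunteers vs bicuspid-valve patients.

    Defaults mirror the study's composition: 48 volunteers and 74 patients
    (49 right-left and 25 right-non-coronary leaflet fusion; 49 with
    ascending-aorta dilation, 18 non-dilated, 7 root-dilated).  Parameter
    means/SDs come from :data:`GROUP_PARAMETER_TABLE`.  ``correlation`` is
    the common inter-parameter correlation of the latent Gaussian draw;
    ``regional_sd_fraction`` scales the extra per-region noise.
    """

    n_hv: int = 48
    n_aaod: int = 49
    n_nond: int = 18
    n_rootd: int = 7
    n_rl: int = 49
    n_rn: int = 25
    correlation: float = 0.3
    regional_sd_fraction: float = 0.15
    seed: int = 0

    def __post_init__(self):
        if min(self.n_hv, self.n_aaod + self.n_nond + self.n_rootd) < 2:
            raise ValueError("each cohort needs at least 2 subjects")
        if self.n_rl + self.n_rn != self.n_aaod + self.n_nond + self.n_rootd:
            raise ValueError("phenotype counts must sum to the BAV count")
        if not (0 <= self.correlation < 1):
            raise ValueError("correlation must be in [0, 1)")


def _draw_group(rng: np.random.Generator, n: int, column: str,
                corr: float) -> np.ndarray:
    stats = GROUP_PARAMETER_TABLE[column]
    means = np.array([stats[p][0] for p in PARAMETERS])
    sds = np.array([max(stats[p][1], 1e-9) for p in PARAMETERS])
    p = len(PARAMETERS)
    cov = np.full((p, p), corr) + (1 - corr) * np.eye(p)
    z = rng.multivariate_normal(np.zeros(p), cov, size=n,
                                method="cholesky")
    vals = means + z * sds
    for i, name in enumerate(PARAMETERS):
        if name in _POSITIVE_ONLY:
            vals[:, i] = np.maximum(vals[:, i], 0.0)
    return vals


def _draw_zscores(rng: np.random.Generator, morphotype: str):
    """z-score pair consistent with the dilation-morphotype rules."""
    if morphotype == "AAoD":
        zaao = 2.0 + abs(rng.normal(1.5, 0.8)) + 1e-3
        zsinus = min(rng.normal(1.0, 0.8), zaao - 1e-3)
        return zsinus, zaao
    if morphotype == "RootD":
        zsinus = 2.0 + abs(rng.normal(1.0, 0.6)) + 1e-3
        zaao = min(rng.normal(1.0, 0.8), zsinus - 1e-3)
        return zsinus, zaao
    zsinus = min(rng.normal(0.5, 0.8), 2.0)
    zaao = min(rng.normal(0.5, 0.8), 2.0)
    return zsinus, zaao


def simulate_cohort(spec: CohortSpec | None = None) -> pd.DataFrame:
    """Tidy per-subject regional parameter table.

    Columns: subject, cohort (HV/BAV), phenotype (RL/RN/none), morphotype
    (NonD/RootD/AAoD/none), zsinus, zAAo, parameter, region (1-16), value.
    The subject-level draw sets the regions 1-4 mean; per-region values add
    independent noise so regional maps have realistic structure.
    """
    spec = spec or CohortSpec()
    rng = np.random.default_rng(spec.seed)
    rows = []
    groups = ([("HV", "none", "HV")] * spec.n_hv
              + [("BAV", "AAoD", "AAoD")] * spec.n_aaod
              + [("BAV", "NonD", "NonAAoD")] * spec.n_nond
              + [("BAV", "RootD", "NonAAoD")] * spec.n_rootd)
    # leaflet-fusion phenotype labels for the patients, fixed counts
    pheno = np.array(["RL"] * spec.n_rl + ["RN"] * spec.n_rn, dtype=object)
    rng.shuffle(pheno)
    ip = 0
    sds_by_col = {
        c: np.array([max(GROUP_PARAMETER_TABLE[c][p][1], 1e-9)
                     for p in PARAMETERS])
        for c in GROUP_PARAMETER_TABLE.columns
    }
    for sid, (cohort, morpho, column) in enumerate(groups):
        vals = _draw_group(rng, 1, column, spec.correlation)[0]
        if cohort == "BAV":
            phenotype = pheno[ip]
            ip += 1
            zsinus, zaao = _draw_zscores(rng, morpho)
        else:
            phenotype, zsinus, zaao = "none", 0.0, 0.0
        sds = sds_by_col[column]
        regional = vals[:, None] + rng.normal(
            0.0, spec.regional_sd_fraction * sds[:, None], size=(len(PARAMETERS), 16))
        for i, name in enumerate(PARAMETERS):
            if name in _POSITIVE_ONLY:
                regional[i] = np.maximum(regional[i], 0.0)
            for region in range(1, 17):
                rows.append((f"S{sid:03d}", cohort, phenotype,
                             morpho if cohort == "BAV" else "none",
                             zsinus, zaao, name, region,
                             regional[i, region - 1]))
    return pd.DataFrame(rows, columns=[
        "subject", "cohort", "phenotype", "morphotype",
        "zsinus", "zAAo", "parameter", "region", "value",
    ])


def aao_means(cohort: pd.DataFrame) -> pd.DataFrame:
    """Subjects x parameters table of ascending-aorta means (regions 1-4),
    with the grouping columns carried along."""
    aao = cohort[cohort.region.isin([1, 2, 3, 4])]
    wide = aao.pivot_table(index="subject", columns="parameter",
                           values="value", aggfunc="mean")
    meta = cohort.drop_duplicates("subject").set_index("subject")[
        ["cohort", "phenotype", "morphotype", "zsinus", "zAAo"]]
    return meta.join(wide)[list(meta.columns) + PARAMETERS]
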