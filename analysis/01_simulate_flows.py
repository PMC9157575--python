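"""Generate the synthetic study inputs: a thoracic-aorta-calibre tube with
the battery of analytic flows, and compare every computed parameter against
its closed form.

Writes results/oracle_comparison.csv and a VTU of the peak-systole velocity
map under scratch/ (binary-ish bulk output stays out of results/).
"""

from pathlib import Path

import numpy as np
import pandas as pd

from aortaflow.hemodynamics import (FluidConstants, axial_circulation,
                                    directional_decomposition,
                                    flow_eccentricity, vorticity_family,
                                    wall_shear_stress)
from aortaflow.io import write_vtu
from aortaflow.laplace import extract_cross_section, solve_laplace
from aortaflow.synthetic import FlowSpec, analytic_flow, make_cylinder

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch"
R, L, H = 10.0, 80.0, 2.5


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    SCRATCH.mkdir(exist_ok=True)
    mesh, _ = make_cylinder(R, L, H, with_grid=False)
    lap = solve_laplace(mesh)
    constants = FluidConstants()
    sec = extract_cross_section(mesh, lap, 0.5)
    steady = np.ones(4)
    rows = []

    vel, exp = analytic_flow(mesh, FlowSpec("poiseuille", R, L, vmax=1.0,
                                            waveform=steady), constants)
    rec = wall_shear_stress(mesh, vel, lap, constants)
    rows.append(("poiseuille", "wss_Pa", exp["wss_Pa"],
                 rec.wss_mag[:, 0].mean()))
    d = directional_decomposition(vel, lap)
    rows.append(("poiseuille", "velocity_angle_deg", 0.0,
                 d["velocity_angle_deg"].values.max()))
    rows.append(("poiseuille", "eccentricity_pct", 0.0,
                 float(flow_eccentricity(sec, vel)[0])))
    vf = vorticity_family(mesh, vel, lap)
    rows.append(("poiseuille", "helicity_density_m_s2", 0.0,
                 np.abs(vf["helicity_density_m_s2"].values).max()))
    rows.append(("poiseuille", "axial_circulation_cm2_s", 0.0,
                 float(axial_circulation(
                     sec, vf["axial_vorticity_1_s"].values)[0])))

    velr, expr = analytic_flow(mesh, FlowSpec("solid_rotation", R, L,
                                              omega=10.0, waveform=steady))
    vfr = vorticity_family(mesh, velr, lap)
    rows.append(("solid_rotation", "axial_vorticity_1_s",
                 expr["axial_vorticity_1_s"],
                 vfr["axial_vorticity_1_s"].values[:, 0].mean()))
    rows.append(("solid_rotation", "axial_circulation_cm2_s",
                 expr["axial_circulation_cm2_s"],
                 float(axial_circulation(
                     sec, vfr["axial_vorticity_1_s"].values)[0])))

    df = pd.DataFrame(rows, columns=["flow", "parameter", "expected",
                                     "computed"])
    df["rel_err_pct"] = 100 * np.abs(df.computed - df.expected) \
        / df.expected.replace(0, np.nan)
    df.to_csv(RESULTS / "oracle_comparison.csv", index=False)
    write_vtu(SCRATCH / "cylinder_poiseuille.vtu", mesh,
              {"velocity": vel.values[:, 0], "phi": lap.phi})
    print(df.to_string(index=False))
    print(f"\nwrote {RESULTS / 'oracle_comparison.csv'}")


if __name__ == "__main__":
    main()
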