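# aortaflow

Finite-element quantification of three-dimensional hemodynamics from
4D-flow cardiac MR, for a single unbranched vessel such as the thoracic
aorta — plus the statistical battery used to rank hemodynamic parameters as
biomarkers in cohort studies (e.g. bicuspid aortic valve patients vs
healthy volunteers).

Given a lumen segmentation (binary NIfTI mask or tetrahedral mesh) and a
time-resolved velocity field, the pipeline produces:

1. a conforming P1 tetrahedral mesh of the lumen with wall/inlet/outlet
   patches;
2. a Laplace axial parameterization: phi in [0, 1] along the vessel with
   `-div(grad phi) = 0`, phi = 0 at the inlet, 1 at the outlet; its level
   sets are cross-sections and its normalized gradient the local axial
   direction e_a;
3. nodal 3D maps of 17 hemodynamic parameters plus equivalent diameter
   D = 2*sqrt(A/pi): speed, forward/backward velocity, velocity angle
   arccos(v·e_a/|v|), regurgitation fraction, flow eccentricity, the wall
   shear stress vector tau = tangential part of 2 mu D n with its axial and
   circumferential components and OSI, vorticity |curl v|, axial vorticity,
   axial circulation (the cross-sectional integral of axial vorticity),
   helicity density v·curl v, viscous dissipation 2 D:D, energy loss and
   kinetic energy;
4. a 16-region table of regional means (four anatomical segments between
   landmark levels, each split into four sub-regions), averaged over the
   peak-systole window (RF and OSI over the whole cycle);
5. cohort statistics: MANOVA with Pillai's trace, region-wise Mann-Whitney
   maps, ROC/AUC with Youden points, MRMR feature ranking, Spearman
   correlation against diameter with good/strong/excellent bins, and the
   z-score morphotype classifier (non-dilated / root-dilated /
   ascending-dilated).

A synthetic-data module generates tubes carrying analytic flows with known
closed-form parameter values and simulated cohorts with realistic group
shifts, so every stage is validated against independent oracles without any
patient data.

## Worked example

```python
import numpy as np
from aortaflow import (FluidConstants, FlowSpec, analytic_flow,
                       compute_regional_table, make_cylinder,
                       partition_regions, solve_laplace)
from aortaflow.hemodynamics import wall_shear_stress

# a 10 mm radius, 80 mm long tube meshed at the 2.5 mm acquisition scale
mesh, grid = make_cylinder(radius_mm=10, length_mm=80, h_mm=2.5)
lap = solve_laplace(mesh)

# steady Poiseuille flow, peak velocity 1 m/s
vel, expected = analytic_flow(
    mesh, FlowSpec("poiseuille", 10, 80, vmax=1.0, waveform=np.ones(4)))
rec = wall_shear_stress(mesh, vel, lap, FluidConstants())
print(expected["wss_Pa"], rec.wss_mag[:, 0].mean())
```

prints

```
0.7 0.6529235520357796
```

— the analytic wall shear stress 2 mu Vmax / R = 0.70 Pa and the
finite-element estimate on the 2.5 mm mesh (6.7% low; the error drops to
3.2% at 1.25 mm). Continuing,

```python
part = partition_regions(lap, [0.05, 0.30, 0.55, 0.80])
table = compute_regional_table(mesh, vel, lap, part)
print(table.loc["diameter_cm", 1], table.loc["wss_Pa", 1])
```

```
1.988583344459436 0.6534631946256133
```

gives the regional table: the equivalent diameter of the 2 cm tube and the
regional WSS mean in region 1 (first quarter of the ascending segment).

The numbered scripts under `analysis/` run the same machinery as full
narratives — `01_simulate_flows.py` (oracle comparison table),
`02_vessel_geometry.py` (Laplace + cross-sections + regions),
`03_hemodynamic_maps.py` (end-to-end 18 x 16 regional table on a pulsatile
helical flow) and `04_cohort_statistics.py` (the statistical battery on a
simulated cohort) — writing their tables under `results/`.

There is also a small CLI that emits a complete synthetic case (NIfTI mask
and velocity phases, VTU mesh, expectations JSON, cohort CSV):

```bash
aortaflow simulate --kind helical --out case/
```

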