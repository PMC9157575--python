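# Methods

## Overview

`aortaflow` quantifies hemodynamics in a single unbranched vessel (the
thoracic aorta is the motivating case) from 4D-flow CMR data. The inputs
are a lumen segmentation — a binary voxel mask or a linear tetrahedral
mesh — and a time-resolved, three-component velocity field on the voxel
grid. The outputs are nodal 3D maps of 17 hemodynamic parameters plus the
equivalent diameter, a 16-region table of regional means, and a battery of
cohort-comparison statistics for ranking parameters as biomarkers.

All spatial operators are built on P1 (linear) finite elements, so every
parameter is defined everywhere in the lumen rather than on isolated
analysis planes.

## Geometry

**Meshing.** A mask is tessellated by splitting every masked voxel into six
tetrahedra sharing the cube's main diagonal (Kuhn split). The split uses the
same corner ordering in every voxel, which makes neighbouring cubes agree on
the shared-face diagonals; the resulting mesh is conforming and watertight.
Synthetic cylinders instead use a structured disk triangulation (rings of
6k nodes, Delaunay-connected) extruded into prisms, each prism split into
three tetrahedra with the minimum-global-index diagonal rule, which is
likewise conforming. Boundary faces are tet faces owned by exactly one
element; inlet and outlet patches are identified from two configured cut
planes (centroid within a tolerance band, outward normal within 45° of the
plane normal), everything else is wall.

**Axial parameterization.** The normalized axial coordinate phi solves the
Laplace problem

    div(grad phi) = 0,   phi = 0 on the inlet,  phi = 1 on the outlet,
    d(phi)/dn = 0 on the wall,

discretized with a P1 Galerkin method and a sparse direct solve. On a
straight tube the exact solution is linear, so the discrete solution is
exact to round-off — this is asserted in the tests. The local axial
direction e_a is the normalized volume-weighted nodal average of the
element-constant gradients of phi. Level sets of phi are cross-sections,
extracted by marching tetrahedra; each iso-vertex remembers the mesh edge
and interpolation weight it came from so any nodal field can be sampled
onto the section. The equivalent diameter is D = 2*sqrt(A/pi) from the
triangulated section area.

**Regions.** Four anatomical landmarks supplied as phi values (Valsalva
level, brachiocephalic trunk, isthmus, diaphragm; the last bound defaults
to 1) delimit four super-segments — ascending aorta, arch, proximal and
distal descending aorta — each subdivided into four sub-regions of equal
phi width, giving regions 1–16. Equal-phi subdivision is an approximation
to equal arc length; phi is the only parameterization the method defines,
and on a near-uniform-calibre vessel the difference is small. Nodes
proximal to the first landmark are left unlabeled (region 0), as are any
distal to an explicit fifth landmark.

## Velocity gradients

Voxel velocities are interpolated trilinearly to mesh nodes (no-slip is not
enforced; a nearest-in-mask fallback handles NaN-masked data). Element
gradients of the P1 interpolant are constant per tetrahedron; nodal
gradients are recovered by the global Galerkin L2 projection

    M g = b,   M = consistent P1 mass matrix,  b_i = sum_e (V_e/4) G_e,

solved once per mesh (sparse LU, reused across phases and components). The
volume-weighted average of adjacent element gradients — the lumped-mass
approximation of the same projection — is available via
`velocity_gradient(..., method="lumped")` but is noticeably less accurate
at the wall: for a Poiseuille profile the lumped estimate of the wall shear
rate is biased low by about h/(2R), versus roughly 0.27*h/R for the
consistent projection (about 6.7% vs 12.7% at h = 2.5 mm, R = 10 mm in the
validation suite). The consistent projection is therefore the default.

## Parameters

With v the velocity, G = grad v the nodal gradient tensor,
D = (G + G^T)/2 the strain rate, omega = curl v, e_a the axial direction
and n the wall normal pointing *into* the lumen:

- **WSS vector** tau = tangential part of 2*mu*D*n (Pa). With the inward
  normal, downstream flow gives a positive axial component. WSSA = tau.e_t
  with e_t the tangential projection of e_a; WSSC = tau.(n x e_t).
  Regional tables report |WSSC| (its sign encodes local handedness);
  WSSA keeps its sign.
- **OSI** = (1 − |sum_t tau dt| / sum_t |tau| dt)/2 over the full cycle,
  in [0, 0.5]; phase weights come from cyclic midpoint spacing of the
  trigger times.
- **Vorticity family**: |omega| (1/s), axial vorticity omega.e_a (1/s),
  helicity density v.omega (m/s^2, signed pseudoscalar; regional tables
  report the mean absolute value, the signed field is exported).
- **Axial circulation** Gamma = integral over a cross-section of
  omega.e_a dA (cm^2/s), by the midpoint rule per section triangle.
- **Directional parameters**: speed |v|; forward/backward velocities
  max(v.e_a, 0) and |min(v.e_a, 0)|; velocity angle
  arccos(v.e_a/|v|) in degrees, set to 0 below a configurable noise floor
  of 1e-3 m/s.
- **Regurgitation fraction**: per section, Q(t) = integral of v.n_sec dA;
  RF = 100 * (backward volume)/(forward volume) over the full cycle,
  averaged over the region's sections.
- **Flow eccentricity**: 100 * |forward-velocity-weighted centroid −
  geometric centroid| / equivalent radius, clipped to [0, 100]. The weight
  is the forward component through the section; a speed-based weighting
  would differ only for strongly reversed flow.
- **Energetics**: dissipation function phi_d = 2*D:D (s^-2); per-node
  energy loss mu*phi_d*V_node (reported in microwatt) and kinetic energy
  rho*|v|^2*V_node/2 (microjoule), with V_node the lumped nodal volume
  (each tet contributes a quarter of its volume to each vertex, conserving
  total volume exactly). Regional values are nodal means, matching the
  microjoule/microwatt magnitudes of per-node reporting; whole-region
  integrals can be formed by summing instead. The dissipation row of the
  regional table is scaled by 1e-3 (i.e. printed in 10^3/s^2), the most
  plausible reading of the conventional table unit.

**Temporal rule.** All phase-resolved parameters are averaged over the
peak-systole window: the phase of maximal volume-weighted mean speed plus
one phase before and two after, cyclically. RF and OSI always use the full
cycle. Regional section-based quantities (diameter, eccentricity,
circulation, RF) use 5 evenly spaced phi levels per region.

**Fluid constants** default to blood values mu = 3.5e-3 Pa s,
rho = 1060 kg/m^3; both configurable.

## Statistics

- **Morphotype** from diameter z-scores: NonD (zsinus <= 2 and zAAo <= 2),
  RootD (zsinus > 2 and zsinus > zAAo), AAoD (zAAo > 2 and zAAo > zsinus).
  The single uncovered corner (equal z-scores above 2) defaults to AAoD and
  is configurable. Non-AAoD pools NonD and RootD.
- **Pillai's trace** V = tr(H(H+E)^-1) from the between/within SSCP
  matrices with the standard F approximation; in the univariate case V
  reduces exactly to the ANOVA eta^2 (asserted to 1e-12). When a group is
  smaller than the response count the response set is reduced to the most
  univariately separating variables, with a warning. The default response
  set is the 18 ascending-aorta-averaged quantities.
- **Mann-Whitney maps** per parameter x region, exact p for combined
  n <= 20 without ties and the tie-corrected normal approximation
  otherwise; the sign marks which group's median is lower. No
  multiple-testing correction is applied by default (raw p < 0.05 maps);
  callers can correct downstream.
- **ROC/AUC** via the rank identity AUC = (R1 − n1(n1+1)/2)/(n1*n0) with
  midranks for ties, plus the Youden-point sensitivity/specificity.
- **MRMR** in the FCQ variant: relevance = one-way ANOVA F statistic,
  redundancy = mean |Pearson r| with already-selected features, greedy
  score = relevance/redundancy. FCQ is the standard choice for continuous
  features with a class label. Note that with a quotient redundancy an
  exact duplicate of a very strong feature can still outrank weak
  features — the redundancy penalty dominates only when relevances are of
  comparable order; the tests exercise that regime.
- **Spearman bins**: |S| in (0.5, 0.7] good, (0.7, 0.9] strong,
  (0.9, 1] excellent, else none; signs retained.

## Synthetic data

The generator emulates a thoracic-aorta-like tube (default R = 10 mm,
L = 80 mm, h = 2.5 mm to match the acquisition voxel size; refinement
halves h) carrying flows with closed-form parameter values: Poiseuille
(wall shear 2*mu*Vmax/R, zero angle/eccentricity/helicity/circulation),
plug, solid-body rotation (|omega| = 2*Omega, Gamma = 2*Omega*pi*R^2, zero
dissipation), helical plug+rotation (angle = atan(Omega*r/V)), an eccentric
Gaussian jet (eccentricity -> 100*offset/R in the narrow-jet limit), and
reversing waveforms (RF from lobe areas, OSI = 0.5 at perfect reversal).
Default waveforms are a half-sine systole over the first 35% of the cycle
with a low flat diastole, 20 phases.

The cohort simulator draws 48 volunteers and 74 patients (49 RL / 25 RN
fusion; 49 ascending-dilated, 18 non-dilated, 7 root-dilated) from
group-specific means and SDs of all 18 quantities in the ascending aorta,
with a common latent correlation (default 0.3), truncation at zero for
positive-only quantities, per-region noise (15% of the group SD), and
z-scores drawn consistently with each subject's morphotype. It reproduces
the *statistical structure* the analysis assumes — group shifts, spread and
rough inter-parameter correlation — not the physics of patient flow fields:
passing recovery tests shows the statistics can detect shifts of the
documented size, not that the imaging pipeline would measure them in vivo.

## Numerical choices and problem sizes

- Sparse direct solves (LU) for the Laplace system and the gradient mass
  matrix; residuals checked against a 1e-10 relative tolerance.
- Axial directions at nodes with |grad phi| < 1e-12 copy the nearest valid
  neighbour.
- Iso-surfacing treats nodes with phi exactly at the level as "below",
  avoiding degenerate cases; zero-area triangles are dropped.
- Validation meshes: 2 013 nodes / 9 216 tets at h = 2.5 mm and
  14 105 nodes / 55 296 tets at h = 1.25 mm; the full suite runs in well
  under a minute on one core, and the 100-repetition cohort recovery in a
  few seconds.

## Limitations

- One unbranched vessel of interest; the Laplace parameterization does not
  handle side branches (a limitation shared with centerline methods).
- The wall is static over the cycle; no wall motion or FSI.
- Voxel meshing is a staircase approximation of the lumen surface; the
  structured cylinder generator is used when analytic wall accuracy
  matters. Iso-surface-smoothed meshing would reduce the staircase bias
  for patient masks.
- No velocity anti-aliasing, eddy-current or phase-offset correction —
  inputs are assumed preprocessed.
- Turbulent kinetic energy and pressure drop are out of scope.
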