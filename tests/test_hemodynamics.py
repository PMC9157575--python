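"""Hemodynamic parameter fields against closed-form flows."""

import numpy as np
import pytest

from aortaflow.fields import NodalField
from aortaflow.hemodynamics import (FluidConstants, axial_circulation,
                                    compute_regional_table,
                                    cyclic_phase_weights,
                                    directional_decomposition, energetics,
                                    flow_eccentricity, peak_systole_frames,
                                    regurgitation_fraction,
                                    velocity_gradient, vorticity_family,
                                    wall_normals, wall_shear_stress)
from aortaflow.laplace import extract_cross_section, partition_regions
from aortaflow.synthetic import FlowSpec, analytic_flow

RADIUS, LENGTH = 10.0, 80.0
STEADY = np.ones(4)


def flow(mesh, kind, **kw):
    kw.setdefault("waveform", STEADY)
    return analytic_flow(mesh, FlowSpec(kind, RADIUS, LENGTH, **kw))


class TestVelocityGradient:
    def test_rigid_rotation_gradient_exact(self, cylinder_mesh):
        vel, _ = flow(cylinder_mesh, "solid_rotation", omega=10.0)
        g = velocity_gradient(cylinder_mesh, vel).values[:, 0]
        expected = np.array([[0, -10, 0], [10, 0, 0], [0, 0, 0.0]])
        assert np.abs(g - expected).max() < 1e-8

    def test_constant_field_zero_gradient(self, cylinder_mesh):
        vel, _ = flow(cylinder_mesh, "plug", vmax=0.4)
        g = velocity_gradient(cylinder_mesh, vel).values
        assert np.abs(g).max() < 1e-12

    def test_poiseuille_wall_slope_improves_with_refinement(
            self, cylinder_mesh, fine_cylinder_mesh, cylinder_lap,
            fine_cylinder_lap, constants):
        errs = []
        for mesh, lap in ((cylinder_mesh, cylinder_lap),
                          (fine_cylinder_mesh, fine_cylinder_lap)):
            vel, exp = flow(mesh, "poiseuille", vmax=1.0)
            rec = wall_shear_stress(mesh, vel, lap, constants)
            errs.append(abs(rec.wss_mag[:, 0].mean() - exp["wss_Pa"])
                        / exp["wss_Pa"])
        assert errs[1] < errs[0]


class TestWallShear:
    def test_poiseuille_wss_magnitude(self, cylinder_mesh, cylinder_lap,
                                      constants):
        vel, exp = flow(cylinder_mesh, "poiseuille", vmax=1.0)
        rec = wall_shear_stress(cylinder_mesh, vel, cylinder_lap, constants)
        assert exp["wss_Pa"] == pytest.approx(0.70)   # 2 mu Vmax / R
        assert rec.wss_mag[:, 0].mean() == pytest.approx(exp["wss_Pa"],
                                                         rel=0.10)
        assert np.abs(rec.wssc).max() < 1e-10

    def test_forward_flow_gives_positive_axial_component(
            self, cylinder_mesh, cylinder_lap, constants):
        vel, _ = flow(cylinder_mesh, "poiseuille", vmax=1.0)
        rec = wall_shear_stress(cylinder_mesh, vel, cylinder_lap, constants)
        assert rec.wssa[:, 0].mean() > 0

    def test_tau_tangency(self, cylinder_mesh, cylinder_lap, constants):
        vel, _ = flow(cylinder_mesh, "helical", vmax=0.5, omega=10.0)
        rec = wall_shear_stress(cylinder_mesh, vel, cylinder_lap, constants)
        n = wall_normals(cylinder_mesh)
        normal_part = np.abs(np.einsum("wpi,wi->wp", rec.tau, n))
        ratio = normal_part / np.maximum(rec.wss_mag, 1e-300)
        assert ratio.max() < 1e-6

    def test_osi_zero_for_steady_and_half_for_reversal(
            self, cylinder_mesh, cylinder_lap, constants):
        steady, _ = flow(cylinder_mesh, "poiseuille", vmax=1.0)
        rec = wall_shear_stress(cylinder_mesh, steady, cylinder_lap, constants)
        assert np.abs(rec.osi).max() < 1e-12
        rev, _ = flow(cylinder_mesh, "poiseuille", vmax=1.0,
                      waveform=np.array([1.0, -1.0, 1.0, -1.0]))
        rec = wall_shear_stress(cylinder_mesh, rev, cylinder_lap, constants)
        assert np.allclose(rec.osi, 0.5, atol=1e-12)

    def test_magnitude_bounds_components(self, cylinder_mesh, cylinder_lap,
                                         constants):
        vel, _ = flow(cylinder_mesh, "helical", vmax=0.5, omega=10.0)
        rec = wall_shear_stress(cylinder_mesh, vel, cylinder_lap, constants)
        assert np.all(rec.wss_mag >= np.abs(rec.wssa) - 1e-12)
        assert np.all(rec.wss_mag >= np.abs(rec.wssc) - 1e-12)


class TestVorticity:
    def test_solid_rotation_vorticity_twice_omega(self, cylinder_mesh,
                                                  cylinder_lap):
        vel, exp = flow(cylinder_mesh, "solid_rotation", omega=10.0)
        vf = vorticity_family(cylinder_mesh, vel, cylinder_lap)
        assert np.abs(vf["vorticity_1_s"].values - 20.0).max() < 1e-8
        assert np.abs(vf["axial_vorticity_1_s"].values - 20.0).max() < 1e-8

    def test_poiseuille_helicity_zero(self, cylinder_mesh, cylinder_lap):
        vel, _ = flow(cylinder_mesh, "poiseuille", vmax=1.0)
        vf = vorticity_family(cylinder_mesh, vel, cylinder_lap)
        # v is axial, omega azimuthal: pointwise orthogonal
        assert np.abs(vf["helicity_density_m_s2"].values).max() < 1e-10

    def test_mirror_reflection_flips_helicity_sign(self, cylinder_mesh,
                                                   cylinder_lap):
        # the x-z mirror image of a helix with +omega is the helix with
        # -omega; helicity density is a pseudoscalar and must flip sign
        vel, _ = flow(cylinder_mesh, "helical", vmax=0.5, omega=10.0)
        mirrored, _ = flow(cylinder_mesh, "helical", vmax=0.5, omega=-10.0)
        h1 = vorticity_family(cylinder_mesh, vel,
                              cylinder_lap)["helicity_density_m_s2"].values
        h2 = vorticity_family(cylinder_mesh, mirrored,
                              cylinder_lap)["helicity_density_m_s2"].values
        assert np.abs(h1 + h2).max() < 1e-9 * np.abs(h1).max()


class TestCirculation:
    def test_solid_rotation_circulation(self, cylinder_mesh, cylinder_lap):
        vel, exp = flow(cylinder_mesh, "solid_rotation", omega=10.0)
        vf = vorticity_family(cylinder_mesh, vel, cylinder_lap)
        sec = extract_cross_section(cylinder_mesh, cylinder_lap, 0.5)
        gamma = axial_circulation(sec, vf["axial_vorticity_1_s"].values)[0]
        assert exp["axial_circulation_cm2_s"] == pytest.approx(62.83, abs=0.01)
        assert gamma == pytest.approx(exp["axial_circulation_cm2_s"], rel=0.05)

    def test_reversed_rotation_flips_sign(self, cylinder_mesh, cylinder_lap):
        sec = extract_cross_section(cylinder_mesh, cylinder_lap, 0.5)
        out = []
        for om in (10.0, -10.0):
            vel, _ = flow(cylinder_mesh, "solid_rotation", omega=om)
            vf = vorticity_family(cylinder_mesh, vel, cylinder_lap)
            out.append(axial_circulation(
                sec, vf["axial_vorticity_1_s"].values)[0])
        assert out[0] == pytest.approx(-out[1])

    def test_poiseuille_circulation_zero(self, cylinder_mesh, cylinder_lap):
        vel, _ = flow(cylinder_mesh, "poiseuille", vmax=1.0)
        vf = vorticity_family(cylinder_mesh, vel, cylinder_lap)
        sec = extract_cross_section(cylinder_mesh, cylinder_lap, 0.5)
        assert abs(axial_circulation(
            sec, vf["axial_vorticity_1_s"].values)[0]) < 1e-8


class TestDirectional:
    def test_parallel_orthogonal_oblique(self, cylinder_lap, cylinder_mesh):
        n = cylinder_mesh.n_nodes
        e = cylinder_lap.axial_dir            # (0,0,1) everywhere
        cases = {
            (0.0, 0.0, 0.5): (0.0, 0.5, 0.0),
            (0.5, 0.0, 0.0): (90.0, 0.0, 0.0),
            (1 / np.sqrt(2), 0.0, 1 / np.sqrt(2)): (45.0, 1 / np.sqrt(2), 0.0),
        }
        for v, (angle, fwd, bwd) in cases.items():
            vel = NodalField("velocity", "m/s",
                             np.tile(np.array(v), (n, 1, 1)))
            d = directional_decomposition(vel, cylinder_lap)
            assert np.allclose(d["velocity_angle_deg"].values, angle, atol=1e-9)
            assert np.allclose(d["forward_velocity_m_s"].values, fwd)
            assert np.allclose(d["backward_velocity_m_s"].values, bwd)

    def test_angle_zero_below_noise_floor(self, cylinder_mesh, cylinder_lap):
        v = np.full((cylinder_mesh.n_nodes, 1, 3), [5e-4, 0, 0])
        d = directional_decomposition(
            NodalField("velocity", "m/s", v), cylinder_lap)
        assert np.all(d["velocity_angle_deg"].values == 0.0)


class TestRegurgitation:
    def test_forward_only_flow_zero(self, cylinder_mesh, cylinder_lap):
        vel, _ = flow(cylinder_mesh, "plug", vmax=0.5)
        sec = extract_cross_section(cylinder_mesh, cylinder_lap, 0.5)
        assert regurgitation_fraction([sec], vel) == pytest.approx(0.0)

    def test_biphasic_ratio(self, cylinder_mesh, cylinder_lap):
        # positive lobe area 100, negative lobe area 10 -> RF = 10%
        wf = np.array([50.0, 50.0, -5.0, -5.0])
        vel, exp = flow(cylinder_mesh, "reversing", vmax=0.01, waveform=wf)
        sec = extract_cross_section(cylinder_mesh, cylinder_lap, 0.5)
        assert exp["regurgitation_fraction_pct"] == pytest.approx(10.0)
        assert regurgitation_fraction([sec], vel) == pytest.approx(10.0)

    @pytest.mark.parametrize("scale", [0.5, 2.0])
    def test_scale_invariance(self, cylinder_mesh, cylinder_lap, scale):
        wf = np.array([1.0, 0.6, -0.2, 0.1])
        vel, _ = flow(cylinder_mesh, "reversing", vmax=0.4, waveform=wf)
        sec = extract_cross_section(cylinder_mesh, cylinder_lap, 0.5)
        base = regurgitation_fraction([sec], vel)
        scaled = NodalField("velocity", "m/s", vel.values * scale)
        assert regurgitation_fraction([sec], scaled) == pytest.approx(base)


class TestEccentricity:
    def test_axisymmetric_poiseuille_near_zero(self, cylinder_mesh,
                                               cylinder_lap):
        vel, _ = flow(cylinder_mesh, "poiseuille", vmax=1.0)
        sec = extract_cross_section(cylinder_mesh, cylinder_lap, 0.5)
        assert flow_eccentricity(sec, vel)[0] < 2.0

    def test_plug_flow_near_zero(self, cylinder_mesh, cylinder_lap):
        vel, _ = flow(cylinder_mesh, "plug", vmax=0.5)
        sec = extract_cross_section(cylinder_mesh, cylinder_lap, 0.5)
        assert flow_eccentricity(sec, vel)[0] < 2.0

    def test_narrow_offset_jet_approaches_offset_fraction(
            self, cylinder_mesh, cylinder_lap):
        vel, exp = flow(cylinder_mesh, "eccentric_jet", vmax=1.0,
                        jet_offset_mm=5.0, jet_width_mm=2.0)
        sec = extract_cross_section(cylinder_mesh, cylinder_lap, 0.5)
        ecc = flow_eccentricity(sec, vel)[0]
        assert ecc == pytest.approx(exp["eccentricity_limit_pct"], abs=12.0)
        assert 0.0 <= ecc <= 100.0


class TestEnergetics:
    def test_rigid_rotation_no_dissipation(self, cylinder_mesh, cylinder_lap,
                                           constants):
        vel, _ = flow(cylinder_mesh, "solid_rotation", omega=10.0)
        g = velocity_gradient(cylinder_mesh, vel)
        en = energetics(cylinder_mesh, vel, g, constants)
        assert np.abs(en["viscous_dissipation_s2"].values).max() < 1e-12
        assert np.abs(en["energy_loss_uW"].values).max() < 1e-12

    def test_kinetic_energy_closed_form(self, constants):
        # uniform 0.4 m/s, node volume of a 2.5 mm voxel
        ke = 0.5 * constants.rho * 0.4**2 * (2.5e-3)**3 * 1e6
        assert ke == pytest.approx(1.325, abs=0.001)

    def test_simple_shear_dissipation_equals_gamma_squared(self):
        # v_x = gamma * y  ->  phi_d = 2 D:D = gamma^2
        from aortaflow.mesh import TetMesh
        nodes = np.array([[0, 0, 0], [10, 0, 0], [0, 10, 0], [0, 0, 10.0],
                          [10, 10, 10]])
        mesh = TetMesh(nodes, np.array([[0, 1, 2, 3], [1, 2, 3, 4]]))
        gamma = 7.0
        v = np.zeros((5, 1, 3))
        v[:, 0, 0] = gamma * nodes[:, 1] * 1e-3       # mm -> m
        vel = NodalField("velocity", "m/s", v)
        g = velocity_gradient(mesh, vel)
        en = energetics(mesh, vel, g, FluidConstants())
        assert np.allclose(en["viscous_dissipation_s2"].values, gamma**2)


class TestTemporalRules:
    def test_window_around_peak(self, cylinder_mesh):
        w = np.zeros(20)
        w[7] = 1.0
        vel, _ = flow(cylinder_mesh, "plug", vmax=0.5, waveform=w + 0.1)
        assert peak_systole_frames(vel).tolist() == [6, 7, 8, 9]

    def test_cyclic_wrap_at_phase_zero(self, cylinder_mesh):
        w = np.full(20, 0.1)
        w[0] = 1.0
        vel, _ = flow(cylinder_mesh, "plug", vmax=0.5, waveform=w)
        assert peak_systole_frames(vel).tolist() == [19, 0, 1, 2]

    def test_tie_breaks_to_lowest_index(self, cylinder_mesh):
        vel, _ = flow(cylinder_mesh, "plug", vmax=0.5, waveform=np.ones(6))
        assert peak_systole_frames(vel).tolist() == [5, 0, 1, 2]

    def test_too_few_phases_rejected(self, cylinder_mesh):
        vel, _ = flow(cylinder_mesh, "plug", vmax=0.5, waveform=np.ones(3))
        with pytest.raises(ValueError):
            peak_systole_frames(vel)

    def test_cyclic_weights_sum_to_period(self):
        t = np.arange(20) * 40.0
        dt = cyclic_phase_weights(t, 20)
        assert dt.sum() == pytest.approx(800.0)
        assert np.allclose(dt, 40.0)


class TestScalingLaws:
    """Velocity scaling by c: linear, quadratic and invariant parameters."""

    @pytest.mark.parametrize("c", [0.5, 2.0])
    def test_equivariance_table(self, cylinder_mesh, cylinder_lap, constants,
                                c):
        vel, _ = flow(cylinder_mesh, "helical", vmax=0.5, omega=8.0)
        scaled = NodalField("velocity", "m/s", vel.values * c)
        g1 = velocity_gradient(cylinder_mesh, vel)
        g2 = velocity_gradient(cylinder_mesh, scaled)
        d1 = directional_decomposition(vel, cylinder_lap)
        d2 = directional_decomposition(scaled, cylinder_lap)
        assert np.allclose(d2["velocity_m_s"].values,
                           c * d1["velocity_m_s"].values)
        assert np.allclose(d2["forward_velocity_m_s"].values,
                           c * d1["forward_velocity_m_s"].values)
        assert np.allclose(d2["velocity_angle_deg"].values,
                           d1["velocity_angle_deg"].values, atol=1e-9)
        r1 = wall_shear_stress(cylinder_mesh, vel, cylinder_lap, constants, g1)
        r2 = wall_shear_stress(cylinder_mesh, scaled, cylinder_lap, constants,
                               g2)
        assert np.allclose(r2.tau, c * r1.tau)
        assert np.allclose(r2.osi, r1.osi, atol=1e-12)
        v1 = vorticity_family(cylinder_mesh, vel, cylinder_lap, g1)
        v2 = vorticity_family(cylinder_mesh, scaled, cylinder_lap, g2)
        assert np.allclose(v2["vorticity_1_s"].values,
                           c * v1["vorticity_1_s"].values)
        e1 = energetics(cylinder_mesh, vel, g1, constants)
        e2 = energetics(cylinder_mesh, scaled, g2, constants)
        assert np.allclose(e2["kinetic_energy_uJ"].values,
                           c**2 * e1["kinetic_energy_uJ"].values)
        assert np.allclose(e2["viscous_dissipation_s2"].values,
                           c**2 * e1["viscous_dissipation_s2"].values)


class TestRegionalTable:
    def test_full_pipeline_shapes_and_ranges(self, cylinder_mesh,
                                             cylinder_lap, constants):
        from aortaflow.synthetic import default_waveform
        vel, _ = flow(cylinder_mesh, "helical", vmax=0.5, omega=8.0,
                      waveform=default_waveform(12))
        part = partition_regions(cylinder_lap, [0.05, 0.30, 0.55, 0.80])
        tab = compute_regional_table(cylinder_mesh, vel, cylinder_lap, part,
                                     constants, n_sections=3)
        assert tab.shape == (18, 16)
        assert tab.notna().all().all()
        assert ((tab.loc["osi"] >= 0) & (tab.loc["osi"] <= 0.5)).all()
        assert ((tab.loc["eccentricity_pct"] >= 0)
                & (tab.loc["eccentricity_pct"] <= 100)).all()
        assert (tab.loc["regurgitation_fraction_pct"] >= 0).all()
        assert (tab.loc["diameter_cm"] - 2.0).abs().max() < 0.1
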