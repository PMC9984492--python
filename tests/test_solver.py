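"""Axisymmetric finite-strain solver: verification oracles and virtual experiments."""

import numpy as np
import pytest

from morphodisc.growth import make_growth_tensor
from morphodisc.materials import NeoHookeanMaterial
from morphodisc.solver import (
    DiscGeometry,
    Layer,
    build_disc_mesh,
    measure_state,
    simulate_development,
    solve_grown_shape,
    virtual_collagenase,
    virtual_decellularization,
)


def timoshenko_curvature(eps: float, h: float, m: float, n: float) -> float:
    """Bimetal-strip curvature closed form (equal-thickness plate variant).

    m = thickness ratio of the two layers, n = modulus ratio, eps = mismatch
    strain, h = total thickness.  For equal-biaxial growth mismatch of an
    incompressible plate the biaxial moduli cancel in the ratio, so the
    shear-modulus ratio can be used directly.
    """
    return 6.0 * eps * m * (1 + m) ** 2 / (
        h * (3 * (1 + m) ** 2 + (1 + m * n) * (m**2 + 1.0 / (m * n)))
    )


class TestMesh:
    def test_structured_element_count(self):
        geom = DiscGeometry.bilayer()
        mesh = build_disc_mesh(geom, resolution=2, n_radial=10)
        # thinnest layer (ECM, h=0.1) gets 2 rows; DP (10x thicker) sqrt-scaled
        nz_dp = max(2, round(2 * np.sqrt(10)))
        assert mesh.n_elems == 10 * (2 + nz_dp)
        assert mesh.n_nodes == 11 * (2 + nz_dp + 1)

    def test_radial_refinement_quadruples_elements(self):
        geom = DiscGeometry.bilayer()
        m1 = build_disc_mesh(geom, resolution=2, n_radial=10)
        m2 = build_disc_mesh(geom, resolution=4, n_radial=20)
        assert m2.nr == 2 * m1.nr
        # axial rows double up to integer rounding of the sqrt scaling
        assert m2.n_elems == pytest.approx(4 * m1.n_elems, rel=0.1)

    def test_jacobians_positive(self):
        from morphodisc._fem import GrownDiscProblem

        geom = DiscGeometry.bilayer()
        mesh = build_disc_mesh(geom, resolution=2)
        pr = GrownDiscProblem(mesh, {"ECM_DP": 25.0, "DP": 1.0})
        assert np.all(pr._geo["dev"]["w"] > 0)

    def test_degenerate_geometry_rejected(self):
        with pytest.raises(ValueError):
            DiscGeometry(outer_radius=0.0, layers=(Layer("DP", 1.0),))
        with pytest.raises(ValueError):
            Layer("DP", -1.0)
        with pytest.raises(ValueError):
            build_disc_mesh(DiscGeometry.bilayer(), resolution=1)


class TestEquilibriumBasics:
    def test_no_growth_zero_displacement(self):
        geom = DiscGeometry.bilayer()
        st = solve_grown_shape(
            geom,
            {"ECM_DP": make_growth_tensor(1.0, 0.0), "DP": make_growth_tensor(1.0, 0.0)},
            n_increments=1,
        )
        assert np.abs(st.u).max() < 1e-12

    def test_equal_planar_growth_is_stress_free_and_flat(self):
        """Compatible growth: flat disc, residual stress below 1e-6 mu_DP."""
        geom = DiscGeometry.bilayer()
        g = make_growth_tensor(2.0, 0.0)
        st = solve_grown_shape(geom, {"ECM_DP": g, "DP": g}, n_increments=5)
        m = measure_state(st)
        assert abs(m.dome_height) < 1e-6
        assert st.stress_state().max_abs < 1e-6
        # thickness unchanged by purely planar compatible growth
        assert m.thickness["DP"] == pytest.approx(1.0, abs=1e-8)

    def test_homogeneous_slab_thickness_matches_analytic(self):
        """Single grown layer: mesh-measured thickness equals the analytic value."""
        geom = DiscGeometry(2.0, (Layer("DP", 1.0, NeoHookeanMaterial(1.0, 1000.0)),))
        g = make_growth_tensor(1.5, 0.4)  # free layer: relaxed, H = H0 * gamma_z
        st = solve_grown_shape(geom, {"DP": g}, n_increments=4)
        assert measure_state(st).thickness["DP"] == pytest.approx(1.5**0.4, abs=1e-8)

    def test_traction_free_boundary_residual_small(self, grown_best_fit_state):
        st = grown_best_fit_state
        mu_dp = 1.0
        R0 = st.geom.outer_radius
        assert st.residual_norm < 1e-6 * mu_dp * R0**2


class TestTimoshenkoOracle:
    @pytest.mark.parametrize("n", [1.0, 5.0])
    def test_thin_bilayer_curvature(self, n):
        """Small-mismatch bilayer curvature matches the bimetal closed form to 5%."""
        h1 = h2 = 0.1
        R0 = 2.0
        eps = 0.002  # deflection << thickness: linear bimetal regime
        geom = DiscGeometry(
            R0,
            (
                Layer("bottom", h1, NeoHookeanMaterial(1.0, 1000.0)),
                Layer("top", h2, NeoHookeanMaterial(n, 1000.0)),
            ),
        )
        mesh = build_disc_mesh(geom, resolution=3, n_radial=60)
        st = solve_grown_shape(
            geom,
            {
                "bottom": make_growth_tensor(1.0, 0.0),
                "top": make_growth_tensor(1.0 + eps, 0.0),
            },
            mesh=mesh,
            n_increments=2,
        )
        kappa = abs(measure_state(st).basal_curvature)
        expected = timoshenko_curvature(eps, h1 + h2, 1.0, n)
        assert kappa == pytest.approx(expected, rel=0.05)


class TestPathIndependenceAndConvergence:
    def test_final_state_path_independent(self):
        """Hyperelastic equilibrium is independent of the increment count."""
        geom = DiscGeometry.bilayer()
        growth = {
            "DP": make_growth_tensor(2.5, 0.0),
            "ECM_DP": make_growth_tensor(2.1, 0.45),
        }
        mesh = build_disc_mesh(geom, resolution=2)
        m10 = measure_state(solve_grown_shape(geom, growth, mesh=mesh, n_increments=10))
        m40 = measure_state(solve_grown_shape(geom, growth, mesh=mesh, n_increments=40))
        assert m40.thickness["DP"] == pytest.approx(m10.thickness["DP"], rel=1e-4)
        assert m40.thickness["ECM_DP"] == pytest.approx(m10.thickness["ECM_DP"], rel=1e-4)
        assert m40.dome_height == pytest.approx(m10.dome_height, rel=1e-4)

    def test_near_incompressibility_at_equilibrium(self):
        """|det A - 1| < 0.01 everywhere for a converged state at kappa/mu = 1000."""
        geom = DiscGeometry.bilayer(mu_ratio=25.0)
        st = solve_grown_shape(
            geom,
            {
                "DP": make_growth_tensor(1.05, 0.0),
                "ECM_DP": make_growth_tensor(1.03, 0.45),
            },
            n_increments=3,
        )
        J = st.elastic_field("dev")["J"]
        assert np.abs(J - 1.0).max() < 0.01

    def test_incompressibility_at_penalty_points_production_state(self, grown_best_fit_state):
        """At full growth the volumetric constraint holds at the penalty points."""
        J = grown_best_fit_state.elastic_field("vol")["J"]
        assert np.abs(J - 1.0).max() < 0.01


class TestBestFitState:
    def test_stress_sign_structure(self, grown_best_fit_state):
        """ECM carries in-plane tension, the DP is compressed in-plane."""
        ss = grown_best_fit_state.stress_state()
        assert ss.mean_inplane["ECM_DP"] > 0
        assert ss.mean_inplane["DP"] < 0

    def test_dome_points_towards_peripodial_side(self, grown_best_fit_state):
        assert measure_state(grown_best_fit_state).dome_height > 0

    def test_dome_monotone_in_growth_mismatch(self):
        """More in-plane mismatch (at fixed rho, mu) domes the disc more."""
        geom = DiscGeometry.bilayer()
        mesh = build_disc_mesh(geom, resolution=2)
        domes = []
        prev = None
        prev_growth = None
        for gdp in [1.6, 1.9, 2.2]:
            growth = {
                "DP": make_growth_tensor(gdp, 0.0),
                "ECM_DP": make_growth_tensor(1.5, 0.45),
            }
            st = solve_grown_shape(
                geom,
                growth,
                mesh=mesh,
                n_increments=6,
                u0=prev.u if prev else None,
                growth_start=prev_growth,
            )
            domes.append(measure_state(st).dome_height)
            prev, prev_growth = st, growth
        assert domes[0] < domes[1] < domes[2]


class TestSimulateDevelopment:
    def test_thickness_monotone_and_flat_control(self):
        from morphodisc.growth import fit_ecm_growth, fit_planar_growth

        t = np.array([72.0, 96.0, 118.0])
        v_dp = 6.0 ** ((t - 72) / 46.0)
        v_ecm = 5.0 ** ((t - 72) / 46.0)
        geom = DiscGeometry.bilayer()
        schedules = {
            "DP": fit_planar_growth(t, v_dp, layer_id="DP"),
            "ECM_DP": fit_ecm_growth(t, v_ecm, rho=0.45, layer_id="ECM_DP"),
        }
        states = simulate_development(geom, schedules, t, n_increments=6)
        h = [measure_state(s).thickness["DP"] for s in states]
        assert h[0] < h[1] < h[2]

        # same growth in both layers, rho = 0: flat at all times
        schedules_flat = {
            "DP": fit_planar_growth(t, v_dp, layer_id="DP"),
            "ECM_DP": fit_ecm_growth(t, v_dp, rho=0.0, layer_id="ECM_DP"),
        }
        states_flat = simulate_development(geom, schedules_flat, t, n_increments=6)
        for s in states_flat:
            assert abs(measure_state(s).dome_height) < 1e-6


class TestVirtualCollagenase:
    def test_relaxes_to_initial_thickness_and_flat(self, grown_best_fit_state):
        relaxed = virtual_collagenase(grown_best_fit_state)
        m = measure_state(relaxed)
        R0 = grown_best_fit_state.geom.outer_radius
        assert m.thickness["DP"] == pytest.approx(1.0, rel=0.02)
        assert abs(m.basal_curvature) < 1e-6 / R0
        assert abs(m.dome_height) < 1e-6

    def test_initial_time_state_unchanged(self):
        geom = DiscGeometry.bilayer()
        st = solve_grown_shape(
            geom,
            {"ECM_DP": make_growth_tensor(1.0, 0.0), "DP": make_growth_tensor(1.0, 0.0)},
            n_increments=1,
        )
        relaxed = virtual_collagenase(st)
        m = measure_state(relaxed)
        assert m.thickness["DP"] == pytest.approx(1.0, abs=1e-10)
        assert abs(m.dome_height) < 1e-10

    def test_requires_ecm_layer(self):
        geom = DiscGeometry(2.0, (Layer("DP", 1.0),))
        st = solve_grown_shape(geom, {"DP": make_growth_tensor(1.2, 0.0)}, n_increments=2)
        with pytest.raises(ValueError):
            virtual_collagenase(st)


class TestVirtualDecellularization:
    def test_unstressed_planar_ecm_unchanged(self):
        """rho = 0 with compatible growth: relaxed = initial thickness, area ratio 1."""
        geom = DiscGeometry.bilayer()
        g = make_growth_tensor(1.8, 0.0)
        st = solve_grown_shape(geom, {"ECM_DP": g, "DP": g}, n_increments=4)
        d = virtual_decellularization(st)
        assert d.relaxed_thickness == pytest.approx(0.1, rel=1e-10)
        assert d.area_ratio == pytest.approx(1.0, abs=1e-6)
        assert d.thickness_increase == pytest.approx(0.0, abs=1e-6)

    def test_volume_conservation_under_elastic_relaxation(self, grown_best_fit_state):
        """(area ratio) x (thickness ratio) = 1 within 1% (incompressibility)."""
        d = virtual_decellularization(grown_best_fit_state)
        assert d.volume_conservation == pytest.approx(1.0, abs=0.01)

    def test_relaxed_thickness_is_grown_thickness(self, grown_best_fit_state):
        gz = 16.2 ** (0.45 / 2.45)
        d = virtual_decellularization(grown_best_fit_state)
        assert d.relaxed_thickness == pytest.approx(0.1 * gz, rel=1e-10)


class TestTwoTissueScenario:
    """DP + PPE stack (no ECM): growth differences between the tissue layers."""

    @staticmethod
    def _geom():
        return DiscGeometry(
            2.5,
            (
                Layer("DP", 1.0, NeoHookeanMaterial(1.0, 1000.0)),
                Layer("PPE", 1.0 / 3.0, NeoHookeanMaterial(1.0, 1000.0)),
            ),
        )

    def test_equal_growth_no_stress_no_dome(self):
        g = make_growth_tensor(2.0, 0.0)
        st = solve_grown_shape(self._geom(), {"DP": g, "PPE": g}, n_increments=5)
        assert st.stress_state().max_abs < 1e-6
        assert abs(measure_state(st).dome_height) < 1e-6

    def test_faster_ppe_growth_bends_with_ppe_compressed(self):
        """~70% extra PPE volume growth bends the disc the observed way."""
        gdp = 2.0
        gppe = gdp * np.sqrt(1.7)  # 70% more volume under planar growth
        st = solve_grown_shape(
            self._geom(),
            {"DP": make_growth_tensor(gdp, 0.0), "PPE": make_growth_tensor(gppe, 0.0)},
            n_increments=8,
        )
        m = measure_state(st)
        ss = st.stress_state()
        assert m.dome_height > 0  # domes towards the PPE side
        assert ss.mean_inplane["PPE"] < 0  # faster-growing layer in compression

    def test_curvature_monotone_in_tissue_mismatch(self):
        domes = []
        for excess in [1.2, 1.4, 1.7]:
            st = solve_grown_shape(
                self._geom(),
                {
                    "DP": make_growth_tensor(2.0, 0.0),
                    "PPE": make_growth_tensor(2.0 * np.sqrt(excess), 0.0),
                },
                n_increments=8,
            )
            domes.append(measure_state(st).dome_height)
        assert domes[0] < domes[1] < domes[2]
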