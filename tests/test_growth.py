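"""Growth-tensor kinematics, the F = A G decomposition and growth fitting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from morphodisc.growth import (
    DeformationState,
    GrowthSchedule,
    elastic_from_total,
    fit_ecm_growth,
    fit_planar_growth,
    growth_volume_fold,
    make_growth_tensor,
)


def _bisect_gamma(fold: float, rho: float) -> float:
    """Independent oracle: solve gamma**(2 + rho) = fold by bisection."""
    lo, hi = 1e-6, fold
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if mid ** (2.0 + rho) < fold:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


class TestMakeGrowthTensor:
    @pytest.mark.parametrize(
        "gamma, rho, expected_diag",
        [
            (2.0, 0.0, (2.0, 2.0, 1.0)),  # planar growth
            (1.0, 0.7, (1.0, 1.0, 1.0)),  # no growth, any rho
            (2.0, 1.0, (2.0, 2.0, 2.0)),  # isotropic growth
        ],
    )
    def test_diagonal(self, gamma, rho, expected_diag):
        G = make_growth_tensor(gamma, rho)
        assert np.allclose(np.diag(G.as_matrix()), expected_diag)

    def test_nonpositive_gamma_rejected(self):
        with pytest.raises(ValueError):
            make_growth_tensor(0.0, 0.5)
        with pytest.raises(ValueError):
            make_growth_tensor(-1.0, 0.5)
        with pytest.raises(ValueError):
            make_growth_tensor(2.0, -0.1)


class TestGrowthVolumeFold:
    @pytest.mark.parametrize(
        "gamma, rho, expected",
        [(2.0, 0.0, 4.0), (2.0, 1.0, 8.0)],
    )
    def test_simple(self, gamma, rho, expected):
        assert growth_volume_fold(make_growth_tensor(gamma, rho)) == pytest.approx(expected)

    def test_anisotropic_fold_matches_bisection_oracle(self):
        # the gamma solving gamma**2.45 = 16.2 must reproduce the 16.2 fold
        g = _bisect_gamma(16.2, 0.45)
        assert g == pytest.approx(3.117, abs=5e-4)
        G = make_growth_tensor(g, 0.45)
        assert growth_volume_fold(G) == pytest.approx(16.2, rel=1e-6)


class TestElasticFromTotal:
    def test_reference_state_identity(self):
        G = make_growth_tensor(1.7, 0.3)
        assert np.allclose(elastic_from_total(G.as_matrix(), G), np.eye(3))

    def test_identity_total(self):
        A = elastic_from_total(np.eye(3), make_growth_tensor(2.0, 0.0))
        assert np.allclose(A, np.diag([0.5, 0.5, 1.0]))

    @settings(deadline=None, max_examples=30)
    @given(
        st.lists(st.floats(-0.4, 0.4), min_size=9, max_size=9),
        st.floats(0.5, 3.0),
        st.floats(0.0, 1.5),
    )
    def test_round_trip(self, a_entries, gamma, rho):
        """Reassembling A @ G reproduces F to near machine precision."""
        A = np.eye(3) + np.asarray(a_entries).reshape(3, 3)
        G = make_growth_tensor(gamma, rho)
        F = A @ G.as_matrix()
        assert np.allclose(elastic_from_total(F, G), A, atol=1e-12)


class TestDeformationState:
    def test_initial_configuration_all_identity(self):
        s = DeformationState(np.eye(3), make_growth_tensor(1.0, 0.0), np.eye(3), "initial")
        assert np.allclose(s.F, np.eye(3))

    def test_inconsistent_triple_rejected(self):
        with pytest.raises(ValueError):
            DeformationState(np.eye(3), make_growth_tensor(2.0, 0.0), np.eye(3))

    def test_reference_requires_identity_elastic(self):
        G = make_growth_tensor(2.0, 0.0)
        DeformationState.from_total(G.as_matrix(), G, "reference")
        with pytest.raises(ValueError):
            DeformationState.from_total(1.1 * G.as_matrix(), G, "reference")


class TestFitPlanarGrowth:
    def test_two_point_fold_exact_sqrt(self):
        s = fit_planar_growth([65.0, 118.0], [1.0, 66.0])
        assert s.gamma_plane[-1] == pytest.approx(np.sqrt(66.0), rel=1e-12)
        assert s.gamma_plane[0] == 1.0
        assert s.rho == 0.0

    def test_constant_volume_gives_unit_gamma(self):
        s = fit_planar_growth([0.0, 5.0, 10.0], [2.0, 2.0, 2.0])
        assert np.allclose(s.gamma_plane, 1.0)

    def test_exact_exponential_recovered(self):
        t = np.linspace(0, 20, 9)
        k = 0.07
        s = fit_planar_growth(t, 3.0 * np.exp(2 * k * t))
        assert np.allclose(s.gamma_plane, np.exp(k * t), rtol=1e-10)

    def test_nonpositive_volume_rejected(self):
        with pytest.raises(ValueError):
            fit_planar_growth([0.0, 1.0], [1.0, -2.0])


class TestFitEcmGrowth:
    def test_fold_and_rho_against_bisection_oracle(self):
        s = fit_ecm_growth([72.0, 118.0], [1.0, 16.2], rho=0.45)
        assert s.gamma_plane[-1] == pytest.approx(_bisect_gamma(16.2, 0.45), rel=1e-6)

    def test_isotropic_case(self):
        s = fit_ecm_growth([0.0, 1.0], [1.0, 8.0], rho=1.0)
        assert s.gamma_plane[-1] == pytest.approx(2.0, rel=1e-12)

    def test_rho_zero_matches_planar_fit(self):
        t = [72.0, 80.0, 96.0, 118.0]
        v = np.exp(0.0649 * (np.asarray(t) - 72.0))
        a = fit_ecm_growth(t, v, rho=0.0)
        b = fit_planar_growth(t, v)
        assert np.allclose(a.gamma_plane, b.gamma_plane, atol=1e-10)

    @pytest.mark.parametrize("rho", [0.0, 0.3, 0.45, 1.0, 2.0])
    def test_volume_preserving_reparameterisation(self, rho):
        """det G at every time is identical for every rho (tolerance 1e-10)."""
        t = [72.0, 80.0, 96.0, 118.0]
        v = [1.0, 1.7, 4.8, 16.2]
        ref = fit_ecm_growth(t, v, rho=0.0)
        s = fit_ecm_growth(t, v, rho=rho)
        det_ref = ref.gamma_plane ** (2.0 + ref.rho)
        det_s = s.gamma_plane ** (2.0 + s.rho)
        assert np.allclose(det_ref, det_s, atol=1e-10)


class TestGrowthSchedule:
    def test_interpolation_is_exponential_between_anchors(self):
        s = GrowthSchedule("DP", np.array([0.0, 10.0]), np.array([1.0, np.exp(1.0)]))
        assert s.gamma_at(5.0) == pytest.approx(np.exp(0.5), rel=1e-12)

    def test_monotonicity_enforced(self):
        with pytest.raises(ValueError):
            GrowthSchedule("DP", np.array([0.0, 1.0, 2.0]), np.array([1.0, 2.0, 1.5]))

    def test_linear_fit_mode_final_fold_close(self):
        t = np.array([72.0, 80.0, 96.0, 118.0])
        v = np.exp(0.065 * (t - 72.0))
        s = fit_planar_growth(t, v, mode="linear")
        # a straight-line gamma cannot match an exponential exactly, but the
        # final fold must be in the right range
        assert s.gamma_plane[-1] ** 2 == pytest.approx(v[-1], rel=0.15)
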