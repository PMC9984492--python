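import numpy as np
import pytest

from morphodisc.growth import make_growth_tensor
from morphodisc.solver import DiscGeometry, build_disc_mesh, solve_grown_shape


@pytest.fixture(scope="session")
def bilayer_geom():
    """Default DP + bottom-ECM bilayer at the production stiffness ratio."""
    return DiscGeometry.bilayer(mu_ratio=25.0)


@pytest.fixture(scope="session")
def grown_best_fit_state(bilayer_geom):
    """Final-time equilibrium at the calibrated growth folds, rho = 0.45.

    Session-scoped: several tests measure different aspects of the same
    converged state.
    """
    gdp = np.sqrt(19.9)
    gecm = 16.2 ** (1.0 / 2.45)
    growth = {
        "DP": make_growth_tensor(gdp, 0.0),
        "ECM_DP": make_growth_tensor(gecm, 0.45),
    }
    mesh = build_disc_mesh(bilayer_geom, resolution=2)
    return solve_grown_shape(bilayer_geom, growth, mesh=mesh, n_increments=8)
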