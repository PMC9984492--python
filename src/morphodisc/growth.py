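"""Growth-tensor kinematics and growth-parameter fitting.

Volumetric growth is described by a diagonal growth tensor
``G = diag(gamma_plane, gamma_plane, gamma_z)`` in the polar cylindrical
basis ``{E_R, E_theta, E_Z}``.  Radial and orthoradial components are equal
(polar isotropy); the axial component is tied to the in-plane one through a
growth-anisotropy exponent ``rho``: ``gamma_z = gamma_plane ** rho``.
``rho = 0`` is planar growth (epithelium-like, all new volume in the plane),
``rho = 1`` isotropic growth, and intermediate values deposit part of the
new volume in thickness.

Total shape change of a growing elastic body factorises multiplicatively
into growth and elastic accommodation, ``F = A @ G``: growth alone takes
the initial state to a relaxed (stress-free but generally incompatible)
reference state, and the elastic tensor ``A`` carries the residual stress
needed to keep the layers coherent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

__all__ = [
    "GrowthTensor",
    "GrowthSchedule",
    "DeformationState",
    "make_growth_tensor",
    "growth_volume_fold",
    "elastic_from_total",
    "fit_planar_growth",
    "fit_ecm_growth",
]

FitMode = Literal["log-linear", "linear"]


@dataclass(frozen=True)
class GrowthTensor:
    """Diagonal growth tensor in the polar cylindrical basis {E_R, E_theta, E_Z}."""

    gamma_plane: float
    gamma_z: float

    def __post_init__(self) -> None:
        if not (self.gamma_plane > 0.0):
            raise ValueError(f"gamma_plane must be positive, got {self.gamma_plane}")
        if not (self.gamma_z > 0.0):
            raise ValueError(f"gamma_z must be positive, got {self.gamma_z}")

    def as_matrix(self) -> np.ndarray:
        return np.diag([self.gamma_plane, self.gamma_plane, self.gamma_z])

    @property
    def det(self) -> float:
        """Relative volume added by growth, gamma_plane**2 * gamma_z."""
        return self.gamma_plane**2 * self.gamma_z

    def inv_matrix(self) -> np.ndarray:
        return np.diag([1.0 / self.gamma_plane, 1.0 / self.gamma_plane, 1.0 / self.gamma_z])


def make_growth_tensor(gamma_plane: float, rho: float) -> GrowthTensor:
    """Growth tensor diag(g, g, g**rho) for in-plane factor g and anisotropy rho.

    rho = 0 gives planar growth diag(g, g, 1); rho = 1 isotropic growth.
    """
    if not (gamma_plane > 0.0):
        raise ValueError(f"gamma_plane must be positive, got {gamma_plane}")
    if rho < 0.0:
        raise ValueError(f"rho must be non-negative, got {rho}")
    return GrowthTensor(float(gamma_plane), float(gamma_plane) ** float(rho))


def growth_volume_fold(G: GrowthTensor) -> float:
    """det G: the volume fold added by growth."""
    return G.det


def elastic_from_total(F: np.ndarray, G: GrowthTensor | np.ndarray) -> np.ndarray:
    """Elastic tensor A = F @ inv(G) of the decomposition F = A G."""
    F = np.asarray(F, dtype=float)
    if isinstance(G, GrowthTensor):
        Ginv = G.inv_matrix()
    else:
        G = np.asarray(G, dtype=float)
        if abs(np.linalg.det(G)) < 1e-300:
            raise ValueError("growth tensor is singular")
        Ginv = np.linalg.inv(G)
    return F @ Ginv


@dataclass(frozen=True)
class DeformationState:
    """Consistent triple (F, G, A) with F = A @ G, tagged by configuration.

    Configurations: ``initial`` (ungrown, unstressed: all identity),
    ``reference`` (grown, relaxed: A = I) and ``observed`` (grown and
    elastically deformed).
    """

    F: np.ndarray
    G: GrowthTensor
    A: np.ndarray
    configuration: Literal["initial", "reference", "observed"] = "observed"

    def __post_init__(self) -> None:
        F = np.asarray(self.F, dtype=float)
        A = np.asarray(self.A, dtype=float)
        if not np.allclose(F, A @ self.G.as_matrix(), rtol=1e-12, atol=1e-12):
            raise ValueError("F = A @ G violated beyond machine precision")
        if self.configuration == "initial" and not (
            np.allclose(F, np.eye(3)) and np.allclose(A, np.eye(3))
        ):
            raise ValueError("initial configuration requires F = G = A = identity")
        if self.configuration == "reference" and not np.allclose(A, np.eye(3)):
            raise ValueError("reference configuration requires A = identity")

    @classmethod
    def from_total(
        cls, F: np.ndarray, G: GrowthTensor, configuration: str = "observed"
    ) -> "DeformationState":
        return cls(np.asarray(F, float), G, elastic_from_total(F, G), configuration)  # type: ignore[arg-type]


@dataclass(frozen=True)
class GrowthSchedule:
    """In-plane growth factor versus developmental time for one layer.

    ``gamma_plane`` is anchored to 1 at the first time point; the axial
    factor is ``gamma_plane ** rho`` throughout.  Interpolation between the
    stored time points is linear in log(gamma) (exponential growth).
    """

    layer_id: str
    times: np.ndarray
    gamma_plane: np.ndarray
    rho: float = 0.0
    fit_mode: str = "log-linear"
    residual: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        g = np.asarray(self.gamma_plane, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "gamma_plane", g)
        if t.ndim != 1 or t.size < 2 or g.shape != t.shape:
            raise ValueError("times and gamma_plane must be matching 1-D arrays, >= 2 points")
        if not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        if not np.isclose(g[0], 1.0, rtol=0, atol=1e-12):
            raise ValueError("gamma_plane must be 1 at the initial time")
        if np.any(g <= 0) or np.any(np.diff(g) < -1e-12):
            raise ValueError("gamma_plane must be positive and non-decreasing")
        if self.rho < 0:
            raise ValueError("rho must be non-negative")

    @property
    def gamma_z(self) -> np.ndarray:
        return self.gamma_plane**self.rho

    def gamma_at(self, t: float | np.ndarray) -> np.ndarray | float:
        """In-plane growth factor at time t (log-linear interpolation)."""
        return np.exp(np.interp(t, self.times, np.log(self.gamma_plane)))

    def tensor_at(self, t: float) -> GrowthTensor:
        return make_growth_tensor(float(self.gamma_at(t)), self.rho)

    def volume_fold_at(self, t: float) -> float:
        return float(self.gamma_at(t)) ** (2.0 + self.rho)


def _validate_series(times: np.ndarray, volumes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(times, dtype=float).ravel()
    v = np.asarray(volumes, dtype=float).ravel()
    if t.size < 2 or v.size != t.size:
        raise ValueError("need >= 2 (time, volume) pairs of equal length")
    order = np.argsort(t)
    t, v = t[order], v[order]
    if np.any(v <= 0):
        raise ValueError("volumes must be positive")
    return t, v


def _fit_gamma(
    times: np.ndarray,
    volumes: np.ndarray,
    exponent: float,
    mode: FitMode,
) -> tuple[np.ndarray, float]:
    """Fit gamma(t) with gamma(t)**exponent ~= V(t)/V(t0), gamma(t0) = 1.

    ``log-linear`` (default): exponential growth model V = V0 exp(alpha t);
    ordinary least squares on log-volume with the intercept pinned to the
    first observation, so an exactly exponential series is recovered
    exactly.  ``linear``: gamma(t) = 1 + c (t - t0), with c chosen by
    least squares of gamma**exponent against V/V0 (straight-line growth
    factor, matching linear-in-time factor profiles).
    """
    t0 = times[0]
    tau = times - t0
    fold = volumes / volumes[0]
    if mode == "log-linear":
        y = np.log(fold)
        denom = float(tau @ tau)
        alpha = float(tau @ y) / denom if denom > 0 else 0.0
        gamma = np.exp(alpha * tau / exponent)
        resid = float(np.sum((alpha * tau - y) ** 2))
    elif mode == "linear":
        from scipy.optimize import least_squares

        def r(c: np.ndarray) -> np.ndarray:
            return (1.0 + c[0] * tau) ** exponent - fold

        alpha0 = float(tau @ np.log(fold)) / float(tau @ tau) if tau @ tau > 0 else 0.0
        c0 = (np.exp(alpha0 * tau[-1] / exponent) - 1.0) / tau[-1] if tau[-1] > 0 else 0.0
        sol = least_squares(r, x0=[max(c0, 0.0)], bounds=([0.0], [np.inf]))
        gamma = 1.0 + sol.x[0] * tau
        resid = float(np.sum(sol.fun**2))
    else:
        raise ValueError(f"unknown fit mode {mode!r}")
    gamma = np.maximum.accumulate(np.maximum(gamma, 1e-12))
    gamma[0] = 1.0
    return gamma, resid


def fit_planar_growth(
    times: np.ndarray,
    volumes: np.ndarray,
    layer_id: str = "DP",
    mode: FitMode = "log-linear",
) -> GrowthSchedule:
    """Fit a planar (rho = 0) growth schedule: gamma(t)**2 ~ V(t)/V(t0).

    Under planar growth all added volume goes into the plane, so the
    in-plane factor is the square root of the fitted volume fold.
    """
    t, v = _validate_series(times, volumes)
    gamma, resid = _fit_gamma(t, v, exponent=2.0, mode=mode)
    return GrowthSchedule(layer_id, t, gamma, rho=0.0, fit_mode=mode, residual=resid)


def fit_ecm_growth(
    times: np.ndarray,
    volumes: np.ndarray,
    rho: float,
    layer_id: str = "ECM_DP",
    mode: FitMode = "log-linear",
) -> GrowthSchedule:
    """Fit an anisotropic growth schedule: gamma(t)**(2 + rho) ~ V(t)/V(t0).

    rho splits the deposited volume between plane and thickness without
    changing the total grown volume: det G(t) = fitted fold for every rho.
    """
    if rho < 0:
        raise ValueError("rho must be non-negative")
    t, v = _validate_series(times, volumes)
    gamma, resid = _fit_gamma(t, v, exponent=2.0 + rho, mode=mode)
    return GrowthSchedule(layer_id, t, gamma, rho=float(rho), fit_mode=mode, residual=resid)
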