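"""Nearly incompressible neo-Hookean elasticity.

Energy density as a function of the elastic tensor A (stress-free at
A = I), with an isochoric/volumetric split:

    W(A) = mu/2 * (J**(-2/3) * tr(A.T A) - 3) + kappa/2 * (J - 1)**2,
    J = det A.

Near-incompressibility is enforced by a stiff quadratic volumetric penalty
(kappa/mu >= 100, default 1000), which keeps |J - 1| at the percent level
or below in equilibrium solutions.  Only the ratio of layer shear moduli
matters for shape, so stresses are naturally reported in units of the
softer layer's modulus.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "NeoHookeanMaterial",
    "StressState",
    "strain_energy_density",
    "first_piola",
    "cauchy_stress",
]


@dataclass(frozen=True)
class NeoHookeanMaterial:
    """Nearly incompressible neo-Hookean solid.

    Parameters
    ----------
    shear_modulus:
        Shear modulus mu (> 0); units are arbitrary, only ratios matter.
    bulk_to_shear:
        Penalty ratio kappa/mu (>= 100) controlling near-incompressibility.
    """

    shear_modulus: float = 1.0
    bulk_to_shear: float = 1000.0

    def __post_init__(self) -> None:
        if not (self.shear_modulus > 0):
            raise ValueError("shear_modulus must be positive")
        if self.bulk_to_shear < 100:
            raise ValueError("bulk_to_shear must be >= 100 (near-incompressible regime)")

    @property
    def bulk_modulus(self) -> float:
        return self.shear_modulus * self.bulk_to_shear


@dataclass(frozen=True)
class StressState:
    """Cauchy stress field with scalar residual-stress summaries.

    ``stress`` has shape (..., 3, 3) (one symmetric tensor per evaluation
    point); summaries are per-layer scalars keyed by layer name.  Sign
    convention: tension > 0, compression < 0.
    """

    stress: np.ndarray
    max_inplane_principal: dict[str, float]
    min_inplane_principal: dict[str, float]
    mean_inplane: dict[str, float]

    @property
    def max_abs(self) -> float:
        return float(np.max(np.abs(self.stress))) if self.stress.size else 0.0


def _check_A(A: np.ndarray) -> np.ndarray:
    A = np.asarray(A, dtype=float)
    if A.shape[-2:] != (3, 3):
        raise ValueError("A must have shape (..., 3, 3)")
    J = np.linalg.det(A)
    if np.any(J <= 0):
        raise ValueError("det A <= 0: inverted elastic state")
    return A


def strain_energy_density(A: np.ndarray, mat: NeoHookeanMaterial) -> float | np.ndarray:
    """W(A) per unit relaxed volume; zero at A = identity."""
    A = _check_A(A)
    J = np.linalg.det(A)
    I1 = np.einsum("...ij,...ij->...", A, A)
    W = 0.5 * mat.shear_modulus * (J ** (-2.0 / 3.0) * I1 - 3.0) + 0.5 * mat.bulk_modulus * (
        J - 1.0
    ) ** 2
    return float(W) if W.ndim == 0 else W


def first_piola(A: np.ndarray, mat: NeoHookeanMaterial) -> np.ndarray:
    """P = dW/dA (first Piola-Kirchhoff stress wrt the relaxed configuration)."""
    A = _check_A(A)
    J = np.linalg.det(A)[..., None, None]
    I1 = np.einsum("...ij,...ij->...", A, A)[..., None, None]
    AinvT = np.swapaxes(np.linalg.inv(A), -1, -2)
    mu, kappa = mat.shear_modulus, mat.bulk_modulus
    return mu * J ** (-2.0 / 3.0) * (A - (I1 / 3.0) * AinvT) + kappa * (J - 1.0) * J * AinvT


def cauchy_stress(A: np.ndarray, mat: NeoHookeanMaterial) -> np.ndarray:
    """Cauchy stress sigma = J**-1 P A^T; symmetric, zero at A = identity."""
    A = _check_A(A)
    J = np.linalg.det(A)[..., None, None]
    P = first_piola(A, mat)
    sig = P @ np.swapaxes(A, -1, -2) / J
    return 0.5 * (sig + np.swapaxes(sig, -1, -2))
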