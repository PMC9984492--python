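"""Axisymmetric finite-strain finite-element core.

Displacement-based Q1 (bilinear quadrilateral) discretisation of a growing
layered disc in cylindrical coordinates (R, Z), assuming axisymmetry.  The
deformation map is x = (r(R, Z), z(R, Z)); the deformation gradient in the
basis {E_R, E_theta, E_Z} is

    F = [[dr/dR, 0,     dr/dZ],
         [0,     r/R,   0    ],
         [dz/dR, 0,     dz/dZ]]

and the elastic tensor A = F G^{-1} with a per-layer diagonal growth
tensor (radial, hoop, axial components).  The total energy (over the initial
configuration, with the grown-volume factor det G) is

    E = int 2 pi R [ det G * W(A) ] dR dZ.

Volumetric locking under the stiff incompressibility penalty is avoided by
selective reduced integration: the isochoric part of W uses 2x2 Gauss
quadrature, the volumetric penalty a single centre point.

Newton's method with analytic residual and finite-difference element
tangents; growth is applied incrementally (geometric path) with adaptive
step halving on non-convergence.  Everything is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

__all__ = [
    "AxisymMesh",
    "GrownDiscProblem",
    "NonConvergenceError",
    "InvertedElementError",
]

_GP = 1.0 / np.sqrt(3.0)
# 2x2 Gauss points (xi, eta) and weights on [-1, 1]^2
_QPTS = np.array([(-_GP, -_GP), (_GP, -_GP), (_GP, _GP), (-_GP, _GP)])
_QWTS = np.ones(4)
_CPT = np.array([(0.0, 0.0)])
_CWT = np.array([4.0])


def _shape(pts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Q1 shape functions and parent-space gradients at points (Q, 2)."""
    xi, eta = pts[:, 0], pts[:, 1]
    N = 0.25 * np.stack(
        [(1 - xi) * (1 - eta), (1 + xi) * (1 - eta), (1 + xi) * (1 + eta), (1 - xi) * (1 + eta)],
        axis=1,
    )
    dN = np.empty((pts.shape[0], 4, 2))
    dN[:, 0, 0] = -0.25 * (1 - eta)
    dN[:, 1, 0] = 0.25 * (1 - eta)
    dN[:, 2, 0] = 0.25 * (1 + eta)
    dN[:, 3, 0] = -0.25 * (1 + eta)
    dN[:, 0, 1] = -0.25 * (1 - xi)
    dN[:, 1, 1] = -0.25 * (1 + xi)
    dN[:, 2, 1] = 0.25 * (1 + xi)
    dN[:, 3, 1] = 0.25 * (1 - xi)
    return N, dN


class InvertedElementError(RuntimeError):
    """An element reached a non-positive elastic Jacobian."""


class NonConvergenceError(RuntimeError):
    """Newton iteration failed to converge; carries the last converged step."""

    def __init__(self, message: str, last_u: np.ndarray | None = None, last_s: float = 0.0):
        super().__init__(message)
        self.last_u = last_u
        self.last_s = last_s


@dataclass
class AxisymMesh:
    """Structured quad mesh of a layered axisymmetric rectangle.

    Nodes are on a tensor grid: radial index i in [0, nr], axial index j in
    [0, nz_total]; node id = j * (nr + 1) + i.  Element rows are tagged with
    the layer they belong to (bottom to top).
    """

    nodes: np.ndarray  # (N, 2) columns (R, Z)
    elems: np.ndarray  # (E, 4) counter-clockwise
    elem_layer: np.ndarray  # (E,) int index into layer_names
    layer_names: list[str]
    nr: int
    layer_nz: list[int]
    layer_z: list[tuple[float, float]]  # (z_bottom, z_top) per layer

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_elems(self) -> int:
        return self.elems.shape[0]

    @property
    def nz_total(self) -> int:
        return int(sum(self.layer_nz))

    def node_id(self, i: int, j: int) -> int:
        return j * (self.nr + 1) + i

    def axis_nodes(self) -> np.ndarray:
        """Node ids on the symmetry axis R = 0."""
        return np.arange(self.nz_total + 1) * (self.nr + 1)

    def layer_interface_j(self) -> list[int]:
        """Axial node-row indices of the layer boundaries, bottom to top."""
        js = [0]
        for nz in self.layer_nz:
            js.append(js[-1] + nz)
        return js

    @classmethod
    def build(
        cls,
        outer_radius: float,
        layer_names: list[str],
        layer_thicknesses: list[float],
        layer_nz: list[int],
        n_radial: int,
    ) -> "AxisymMesh":
        if outer_radius <= 0 or any(h <= 0 for h in layer_thicknesses):
            raise ValueError("degenerate geometry: radius and thicknesses must be positive")
        if any(nz < 1 for nz in layer_nz) or n_radial < 1:
            raise ValueError("element counts must be >= 1")
        r = np.linspace(0.0, outer_radius, n_radial + 1)
        z_rows = [0.0]
        layer_z = []
        z0 = 0.0
        for h, nz in zip(layer_thicknesses, layer_nz):
            z_rows.extend(np.linspace(z0, z0 + h, nz + 1)[1:].tolist())
            layer_z.append((z0, z0 + h))
            z0 += h
        z = np.asarray(z_rows)
        R, Z = np.meshgrid(r, z)  # (nzt+1, nr+1)
        nodes = np.column_stack([R.ravel(), Z.ravel()])
        nzt = len(z) - 1
        elems = []
        elem_layer = []
        jlims = np.cumsum([0] + list(layer_nz))
        for j in range(nzt):
            lay = int(np.searchsorted(jlims, j, side="right") - 1)
            for i in range(n_radial):
                n0 = j * (n_radial + 1) + i
                elems.append([n0, n0 + 1, n0 + n_radial + 2, n0 + n_radial + 1])
                elem_layer.append(lay)
        return cls(
            nodes=nodes,
            elems=np.asarray(elems, dtype=np.int64),
            elem_layer=np.asarray(elem_layer, dtype=np.int64),
            layer_names=list(layer_names),
            nr=n_radial,
            layer_nz=list(layer_nz),
            layer_z=layer_z,
        )


class GrownDiscProblem:
    """Equilibrium problem for a growing layered axisymmetric disc."""

    def __init__(
        self,
        mesh: AxisymMesh,
        shear_moduli: dict[str, float],
        bulk_to_shear: dict[str, float] | float = 1000.0,
    ):
        self.mesh = mesh
        self.mu_layer = {k: float(v) for k, v in shear_moduli.items()}
        if np.isscalar(bulk_to_shear):
            bulk_to_shear = {name: float(bulk_to_shear) for name in mesh.layer_names}
        self.kappa_layer = {
            name: self.mu_layer[name] * bulk_to_shear[name] for name in mesh.layer_names
        }
        lay = mesh.elem_layer
        self.wrap_mask = getattr(mesh, "wrap_mask", None)
        self.mu_e = np.array([self.mu_layer[mesh.layer_names[l]] for l in lay])
        self.kappa_e = np.array([self.kappa_layer[mesh.layer_names[l]] for l in lay])
        # growth per element (identity until set_growth); general diagonal
        # diag(g1, g2, g3) in {E_R, E_theta, E_Z}; stacked layers use
        # g1 = g2 = gamma_plane, an edge-wrap ring swaps the roles
        self.g1_e = np.ones(mesh.n_elems)
        self.g2_e = np.ones(mesh.n_elems)
        self.g3_e = np.ones(mesh.n_elems)
        self._precompute_geometry()
        # Dirichlet data: u_r = 0 on the axis, u_z pinned at the bottom axis corner
        fixed = np.zeros(2 * mesh.n_nodes, dtype=bool)
        fixed[2 * mesh.axis_nodes()] = True
        fixed[2 * mesh.node_id(0, 0) + 1] = True
        self.fixed = fixed
        self.free = ~fixed

    # -- geometry precomputation ------------------------------------------
    def _precompute_geometry(self) -> None:
        mesh = self.mesh
        X = mesh.nodes[mesh.elems]  # (E, 4, 2)
        self._geo = {}
        for tag, (pts, wts) in {"dev": (_QPTS, _QWTS), "vol": (_CPT, _CWT)}.items():
            N, dN = _shape(pts)  # (Q,4), (Q,4,2)
            # Jacobian dX/dxi: (E, Q, 2, 2)
            J = np.einsum("qak,eaj->eqjk", dN, X)
            detJ = J[..., 0, 0] * J[..., 1, 1] - J[..., 0, 1] * J[..., 1, 0]
            if np.any(detJ <= 0):
                raise ValueError("mesh has non-positive Jacobians")
            Jinv = np.empty_like(J)
            Jinv[..., 0, 0] = J[..., 1, 1]
            Jinv[..., 0, 1] = -J[..., 0, 1]
            Jinv[..., 1, 0] = -J[..., 1, 0]
            Jinv[..., 1, 1] = J[..., 0, 0]
            Jinv /= detJ[..., None, None]
            # physical gradients dN/dR, dN/dZ: (E, Q, 4)
            dNdX = np.einsum("qak,eqkj->eqaj", dN, Jinv)
            Rq = np.einsum("qa,ea->eq", N, X[..., 0])
            Zq = np.einsum("qa,ea->eq", N, X[..., 1])
            self._geo[tag] = {
                "N": N,
                "dNdR": dNdX[..., 0],
                "dNdZ": dNdX[..., 1],
                "R": Rq,
                "Z": Zq,
                "w": wts[None, :] * detJ * 2.0 * np.pi * Rq,
            }

    def set_growth(self, growth: dict[str, tuple[float, float]]) -> None:
        """Assign per-layer growth (gamma_plane, gamma_z).

        Stacked-layer elements grow diag(gp, gp, gz).  Elements flagged as
        edge-wrap (``wrap_mask``) belong to the ECM ring around the disc
        rim: their sheet plane is (theta, Z), so they grow
        diag(gz, gp, gp) instead.
        """
        names = self.mesh.layer_names
        gp = np.array([growth[names[l]][0] for l in self.mesh.elem_layer])
        gz = np.array([growth[names[l]][1] for l in self.mesh.elem_layer])
        if np.any(gp <= 0) or np.any(gz <= 0):
            raise ValueError("growth factors must be positive")
        g1, g2, g3 = gp.copy(), gp.copy(), gz.copy()
        w = self.wrap_mask
        if w is not None and w.any():
            g1[w], g2[w], g3[w] = gz[w], gp[w], gp[w]
        self.g1_e, self.g2_e, self.g3_e = g1, g2, g3

    # -- kinematics and stress --------------------------------------------
    def _elastic_comps(self, ue: np.ndarray, tag: str):
        """Five nonzero components of A = F G^{-1} at the quadrature points."""
        g = self._geo[tag]
        ur, uz = ue[..., 0], ue[..., 1]
        FrR = 1.0 + np.einsum("eqa,ea->eq", g["dNdR"], ur)
        FrZ = np.einsum("eqa,ea->eq", g["dNdZ"], ur)
        FzR = np.einsum("eqa,ea->eq", g["dNdR"], uz)
        FzZ = 1.0 + np.einsum("eqa,ea->eq", g["dNdZ"], uz)
        Fth = 1.0 + np.einsum("qa,ea->eq", g["N"], ur) / g["R"]
        g1 = self.g1_e[:, None]
        g2 = self.g2_e[:, None]
        g3 = self.g3_e[:, None]
        return FrR / g1, FrZ / g3, FzR / g1, FzZ / g3, Fth / g2

    def element_residual(self, ue: np.ndarray) -> np.ndarray:
        """Internal-force contributions (E, 4, 2); raises on inverted states."""
        res = np.zeros((self.mesh.n_elems, 4, 2))
        detG = (self.g1_e * self.g2_e * self.g3_e)[:, None]
        g1 = self.g1_e[:, None]
        g2 = self.g2_e[:, None]
        g3 = self.g3_e[:, None]
        for tag in ("dev", "vol"):
            g = self._geo[tag]
            ArR, ArZ, AzR, AzZ, Ath = self._elastic_comps(ue, tag)
            d2 = ArR * AzZ - ArZ * AzR
            JA = Ath * d2
            if np.any(JA <= 0.0) or np.any(d2 <= 0.0):
                raise InvertedElementError("det A <= 0 during assembly")
            iT_rR = AzZ / d2
            iT_rZ = -AzR / d2
            iT_zR = -ArZ / d2
            iT_zZ = ArR / d2
            iT_th = 1.0 / Ath
            if tag == "dev":
                I1 = ArR**2 + ArZ**2 + AzR**2 + AzZ**2 + Ath**2
                c = self.mu_e[:, None] * JA ** (-2.0 / 3.0)
                PrR = c * (ArR - I1 / 3.0 * iT_rR)
                PrZ = c * (ArZ - I1 / 3.0 * iT_rZ)
                PzR = c * (AzR - I1 / 3.0 * iT_zR)
                PzZ = c * (AzZ - I1 / 3.0 * iT_zZ)
                Pth = c * (Ath - I1 / 3.0 * iT_th)
            else:
                pv = self.kappa_e[:, None] * (JA - 1.0) * JA
                PrR = pv * iT_rR
                PrZ = pv * iT_rZ
                PzR = pv * iT_zR
                PzZ = pv * iT_zZ
                Pth = pv * iT_th
            # pull back to the initial configuration: P_F = det G * P_A G^{-T}
            PFrR = detG * PrR / g1
            PFrZ = detG * PrZ / g3
            PFzR = detG * PzR / g1
            PFzZ = detG * PzZ / g3
            PFth = detG * Pth / g2
            w = g["w"]
            res[..., 0] += np.einsum(
                "eq,eqa->ea", w * PFrR, g["dNdR"]
            ) + np.einsum("eq,eqa->ea", w * PFrZ, g["dNdZ"]) + np.einsum(
                "eq,qa->ea", w * PFth / g["R"], g["N"]
            )
            res[..., 1] += np.einsum("eq,eqa->ea", w * PFzR, g["dNdR"]) + np.einsum(
                "eq,eqa->ea", w * PFzZ, g["dNdZ"]
            )
        return res

    def _gather(self, u: np.ndarray) -> np.ndarray:
        return u.reshape(-1, 2)[self.mesh.elems]

    def residual(self, u: np.ndarray) -> np.ndarray:
        r = np.zeros(2 * self.mesh.n_nodes)
        re = self.element_residual(self._gather(u))
        np.add.at(r, 2 * self.mesh.elems, re[..., 0])
        np.add.at(r, 2 * self.mesh.elems + 1, re[..., 1])
        return r

    def energy(self, u: np.ndarray) -> float:
        """Total strain energy at displacement u."""
        ue = self._gather(u)
        E = 0.0
        detG = self.g1_e * self.g2_e * self.g3_e
        for tag in ("dev", "vol"):
            g = self._geo[tag]
            ArR, ArZ, AzR, AzZ, Ath = self._elastic_comps(ue, tag)
            JA = Ath * (ArR * AzZ - ArZ * AzR)
            if np.any(JA <= 0.0):
                raise InvertedElementError("det A <= 0 in energy evaluation")
            if tag == "dev":
                I1 = ArR**2 + ArZ**2 + AzR**2 + AzZ**2 + Ath**2
                W = 0.5 * self.mu_e[:, None] * (JA ** (-2.0 / 3.0) * I1 - 3.0)
            else:
                W = 0.5 * self.kappa_e[:, None] * (JA - 1.0) ** 2
            E += float(np.sum(g["w"] * detG[:, None] * W))
        return E

    def tangent(self, u: np.ndarray, h: float = 1e-7) -> sp.csr_matrix:
        """Consistent tangent by forward differences of the element residual."""
        ue = self._gather(u)
        r0 = self.element_residual(ue)
        E = self.mesh.n_elems
        Ke = np.empty((E, 8, 8))
        for a in range(4):
            for c in range(2):
                up = ue.copy()
                up[:, a, c] += h
                Ke[:, :, 2 * a + c] = ((self.element_residual(up) - r0) / h).reshape(E, 8)
        dofs = np.empty((E, 8), dtype=np.int64)
        dofs[:, 0::2] = 2 * self.mesh.elems
        dofs[:, 1::2] = 2 * self.mesh.elems + 1
        rows = np.repeat(dofs, 8, axis=1).ravel()
        cols = np.tile(dofs, (1, 8)).ravel()
        n = 2 * self.mesh.n_nodes
        K = sp.coo_matrix((Ke.ravel(), (rows, cols)), shape=(n, n)).tocsr()
        return K

    # -- Newton solve ------------------------------------------------------
    def newton_solve(
        self,
        u0: np.ndarray,
        tol: float | None = None,
        max_iter: int = 100,
    ) -> tuple[np.ndarray, float, int]:
        """Solve equilibrium from initial guess u0 by damped Newton descent.

        Equilibria are minima of the total energy, so globalisation uses an
        Armijo backtracking line search on the energy along the Newton
        direction; when the tangent is indefinite (no descent direction),
        Levenberg damping is raised until one is obtained.  Returns
        (u, final residual infinity-norm on free dofs, iterations).
        """
        if tol is None:
            tol = self.default_tol()
        u = u0.copy()
        free = self.free
        try:
            R = self.residual(u)
            E = self.energy(u)
        except InvertedElementError as exc:
            raise NonConvergenceError(f"initial guess inverted: {exc}") from exc
        rnorm = float(np.max(np.abs(R[free]))) if free.any() else 0.0
        lam = 0.0  # Levenberg damping, raised when Newton fails to descend
        for it in range(max_iter):
            if rnorm < tol:
                return u, rnorm, it
            K = self.tangent(u)
            Kff = K[free][:, free].tocsc()
            dscale = np.abs(Kff.diagonal())
            dscale = np.maximum(dscale, dscale.max() * 1e-8)
            D = sp.diags(dscale, format="csc")
            accepted = False
            while not accepted:
                Ktry = Kff + lam * D if lam > 0 else Kff
                du = np.zeros_like(u)
                try:
                    du[free] = spla.spsolve(Ktry, -R[free])
                except RuntimeError:
                    du[free] = np.nan
                slope = float(R[free] @ du[free]) if np.all(np.isfinite(du)) else np.inf
                if np.isfinite(slope):
                    # fast path: a full step that cuts the residual is taken
                    # outright (quadratic regime; also immune to the
                    # energy-resolution floor of the Armijo test)
                    try:
                        R_try = self.residual(u + du)
                        r_try = float(np.max(np.abs(R_try[free])))
                        if r_try < 0.9 * rnorm:
                            u = u + du
                            R, rnorm = R_try, r_try
                            E = self.energy(u)
                            accepted = True
                    except InvertedElementError:
                        pass
                if not accepted and np.isfinite(slope) and slope < 0.0:
                    alpha = 1.0
                    while alpha >= 1.0 / 256.0:  # fail fast into damping
                        try:
                            E_try = self.energy(u + alpha * du)
                        except InvertedElementError:
                            alpha *= 0.5
                            continue
                        if E_try <= E + 1e-4 * alpha * slope:
                            u = u + alpha * du
                            R = self.residual(u)
                            E = E_try
                            rnorm = float(np.max(np.abs(R[free])))
                            accepted = True
                            break
                        alpha *= 0.5
                if accepted:
                    # relax damping gradually; keep memory across iterations
                    lam = 0.0 if lam < 1e-7 else lam / 3.0
                else:
                    lam = 1e-5 if lam == 0.0 else lam * 10.0
                    if lam > 1e8:
                        raise NonConvergenceError(
                            f"damped Newton stalled at residual {rnorm:.3e}", last_u=u
                        )
        if rnorm < tol:
            return u, rnorm, max_iter
        raise NonConvergenceError(
            f"Newton did not converge in {max_iter} iterations (residual {rnorm:.3e})",
            last_u=u,
        )

    def default_tol(self) -> float:
        """Absolute residual tolerance ~ 1e-10 * mu_max * R0^2 (force scale)."""
        R0 = float(self.mesh.nodes[:, 0].max())
        return 1e-10 * max(self.mu_layer.values()) * R0**2

    def minimize_energy(self, u0: np.ndarray, maxiter: int = 800) -> np.ndarray:
        """Descend the energy with L-BFGS (analytic gradient).

        Used when Newton stalls: equilibria are energy minima, and descent
        is robust through the weakly non-convex doming transition where the
        tangent becomes indefinite.  The result is then polished by Newton.
        """
        from scipy.optimize import minimize

        free = self.free
        u_full = u0.copy()
        big = 1e30

        def fg(x: np.ndarray):
            u_full[free] = x
            try:
                E = self.energy(u_full)
                R = self.residual(u_full)
            except InvertedElementError:
                return big, np.zeros(free.sum())
            if not np.isfinite(E):
                return big, np.zeros(free.sum())
            return E, R[free]

        res = minimize(
            fg,
            u0[free],
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": maxiter, "ftol": 1e-16, "gtol": 1e-12, "maxcor": 30},
        )
        u = u0.copy()
        u[free] = res.x
        return u

    def solve_incremental(
        self,
        growth_target: dict[str, tuple[float, float]],
        u0: np.ndarray | None = None,
        growth_start: dict[str, tuple[float, float]] | None = None,
        n_increments: int = 10,
        tol: float | None = None,
        max_halvings: int = 8,
    ) -> np.ndarray:
        """Ramp growth from growth_start (default: identity) to growth_target.

        The ramp is geometric in each growth factor; on Newton failure the
        current step is halved (recursively, up to max_halvings).
        Intermediate increments are solved to a relaxed tolerance (they only
        serve as a continuation path); the final state is converged tightly.
        """
        names = self.mesh.layer_names
        tol_final = tol if tol is not None else self.default_tol()
        tol_mid = tol_final * 1e4
        if growth_start is None:
            growth_start = {n: (1.0, 1.0) for n in names}
        u = np.zeros(2 * self.mesh.n_nodes) if u0 is None else u0.copy()
        lg0 = {n: np.log(np.asarray(growth_start[n])) for n in names}
        lg1 = {n: np.log(np.asarray(growth_target[n])) for n in names}

        def growth_at(s: float) -> dict[str, tuple[float, float]]:
            return {n: tuple(np.exp((1 - s) * lg0[n] + s * lg1[n])) for n in names}

        s = 0.0
        ds = 1.0 / max(1, n_increments)
        halvings = 0
        u_last = u
        u_prev = None
        ds_prev = None
        while s < 1.0 - 1e-12:
            s_try = min(1.0, s + ds)
            step_tol = tol_final if s_try >= 1.0 - 1e-12 else tol_mid
            self.set_growth(growth_at(s_try))
            # secant predictor from the two previous converged states
            u_start = u_last
            if u_prev is not None and ds_prev and ds_prev > 0:
                u_start = u_last + (u_last - u_prev) * ((s_try - s) / ds_prev)
            try:
                u, _, _ = self.newton_solve(u_start, tol=step_tol)
            except NonConvergenceError:
                try:
                    u_desc = self.minimize_energy(u_last)
                    u, _, _ = self.newton_solve(u_desc, tol=step_tol)
                except NonConvergenceError as exc:
                    halvings += 1
                    if halvings > max_halvings:
                        raise NonConvergenceError(
                            f"growth continuation failed at s={s_try:.4f}: {exc}",
                            last_u=u_last,
                            last_s=s,
                        ) from exc
                    ds *= 0.5
                    u_prev = None
                    continue
            u_prev, ds_prev = u_last, s_try - s
            s = s_try
            u_last = u
        self.set_growth(growth_at(1.0))
        return u_last
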