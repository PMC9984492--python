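"""Equilibrium shapes of the growing layered wing disc and virtual experiments.

The disc is an axisymmetric stack of layers (bottom to top; by convention
the bottom extracellular-matrix layer first, the disc-proper epithelium
above it), each a nearly incompressible neo-Hookean solid with its own
diagonal growth tensor.  Equilibrium minimises the total strain energy
with layers coherently attached, traction-free outer boundaries, and
symmetry at the axis; z increases from the basal (ECM) side towards the
peripodial side, so the observed dome has positive height.

Virtual experiments mirror the wet-lab perturbations:

* collagenase — the ECM layer is removed and the remaining tissue re-solved
  alone; with planar tissue growth the relaxed tissue is flat with its
  initial thickness (also covers Myosin II inhibition, since no active
  contractility is modelled);
* decellularization — the cell layer's load is removed, revealing the ECM's
  relaxed (reference) configuration: relaxed thickness H0_ECM * gamma_ECM**rho
  and the in-plane relaxation of a material patch (the bleached-circle
  read-out).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._fem import AxisymMesh, GrownDiscProblem
from .growth import GrowthSchedule, GrowthTensor
from .materials import NeoHookeanMaterial, StressState

__all__ = [
    "Layer",
    "DiscGeometry",
    "ObservedState",
    "ShapeDescriptors",
    "DecellularizationResult",
    "build_disc_mesh",
    "solve_grown_shape",
    "simulate_development",
    "virtual_collagenase",
    "virtual_decellularization",
    "measure_state",
]


@dataclass(frozen=True)
class Layer:
    name: str
    thickness: float
    material: NeoHookeanMaterial = field(default_factory=NeoHookeanMaterial)

    def __post_init__(self) -> None:
        if not (self.thickness > 0):
            raise ValueError(f"layer {self.name!r}: thickness must be positive")


@dataclass(frozen=True)
class DiscGeometry:
    """Axisymmetric layered disc: layers ordered bottom to top."""

    outer_radius: float
    layers: tuple[Layer, ...]

    def __post_init__(self) -> None:
        if not (self.outer_radius > 0):
            raise ValueError("outer_radius must be positive")
        if len(self.layers) < 1:
            raise ValueError("need at least one layer")
        names = [l.name for l in self.layers]
        if len(set(names)) != len(names):
            raise ValueError("layer names must be unique")

    @property
    def layer_names(self) -> list[str]:
        return [l.name for l in self.layers]

    def layer(self, name: str) -> Layer:
        for l in self.layers:
            if l.name == name:
                return l
        raise KeyError(name)

    @classmethod
    def bilayer(
        cls,
        mu_ratio: float = 25.0,
        outer_radius: float = 2.5,
        h_dp: float = 1.0,
        h_ecm: float = 0.1,
        bulk_to_shear: float = 1000.0,
    ) -> "DiscGeometry":
        """Default DP + bottom-ECM bilayer.

        Lengths are in units of the initial DP thickness: the tissue layer
        is ten times thicker than its basement membrane, and the initial
        pouch radius is 2.5 tissue thicknesses, matching the late-disc
        proportions (final radius ~ 4x final thickness) and producing the
        observed dome rather than a curled rim.  mu_ratio = mu_ECM /
        mu_DP; the DP modulus is the stress unit (mu_DP = 1).
        """
        return cls(
            outer_radius=outer_radius,
            layers=(
                Layer("ECM_DP", h_ecm, NeoHookeanMaterial(mu_ratio, bulk_to_shear)),
                Layer("DP", h_dp, NeoHookeanMaterial(1.0, bulk_to_shear)),
            ),
        )


def build_disc_mesh(
    geom: DiscGeometry,
    resolution: int = 2,
    n_radial: int | None = None,
) -> AxisymMesh:
    """Structured conforming mesh with layer tags.

    ``resolution`` is the number of elements across the thinnest layer;
    thicker layers get proportionally more rows (square-root scaling, so a
    10x thicker layer gets ~3x the rows).  The default radial spacing
    matches the coarsest axial spacing, capped at 120 columns.
    """
    if resolution < 2:
        raise ValueError("resolution must be >= 2 elements across the thinnest layer")
    hs = [l.thickness for l in geom.layers]
    hmin = min(hs)
    layer_nz = [max(resolution, int(round(resolution * np.sqrt(h / hmin)))) for h in hs]
    if n_radial is None:
        dz_max = max(h / nz for h, nz in zip(hs, layer_nz))
        n_radial = int(np.clip(np.ceil(geom.outer_radius / dz_max), 8, 120))
    return AxisymMesh.build(geom.outer_radius, geom.layer_names, hs, layer_nz, n_radial)


@dataclass(frozen=True)
class ShapeDescriptors:
    """Measured shape of an equilibrium state.

    Thicknesses are evaluated on the symmetry axis (the in-vivo measurement
    point is the A/P-D/V boundary intersection at the disc centre).  Dome
    height is apex minus edge of the deformed basal surface; positive when
    the disc bulges towards the peripodial (+z) side.
    """

    thickness: dict[str, float]
    dome_height: float
    basal_curvature: float
    basal_outline: np.ndarray  # (n, 2) deformed (r, z) of the bottom surface


@dataclass
class ObservedState:
    """Converged equilibrium of a grown disc."""

    geom: DiscGeometry
    mesh: AxisymMesh
    u: np.ndarray
    growth: dict[str, GrowthTensor]
    problem: GrownDiscProblem
    residual_norm: float = 0.0

    @property
    def deformed_nodes(self) -> np.ndarray:
        return self.mesh.nodes + self.u.reshape(-1, 2)

    def elastic_field(self, tag: str = "dev"):
        """Per-quadrature-point elastic components and locations.

        Returns dict with 'A' components (ArR, ArZ, AzR, AzZ, Ath), 'J'
        (det A), reference coordinates 'R', 'Z' and the element layer index.
        """
        ue = self.problem._gather(self.u)
        ArR, ArZ, AzR, AzZ, Ath = self.problem._elastic_comps(ue, tag)
        g = self.problem._geo[tag]
        J = Ath * (ArR * AzZ - ArZ * AzR)
        lay = np.broadcast_to(self.mesh.elem_layer[:, None], J.shape)
        return {
            "ArR": ArR, "ArZ": ArZ, "AzR": AzR, "AzZ": AzZ, "Ath": Ath,
            "J": J, "R": g["R"], "Z": g["Z"], "layer": lay,
        }

    def elastic_tensors(self) -> np.ndarray:
        """Full 3x3 elastic tensors at the deviatoric quadrature points, (E, Q, 3, 3)."""
        f = self.elastic_field()
        A = np.zeros(f["J"].shape + (3, 3))
        A[..., 0, 0] = f["ArR"]
        A[..., 0, 2] = f["ArZ"]
        A[..., 1, 1] = f["Ath"]
        A[..., 2, 0] = f["AzR"]
        A[..., 2, 2] = f["AzZ"]
        return A

    def stress_state(self) -> StressState:
        """Cauchy stress per quadrature point with per-layer summaries."""
        from .materials import cauchy_stress

        A = self.elastic_tensors()
        lay = self.mesh.elem_layer
        sig = np.zeros_like(A)
        for li, name in enumerate(self.mesh.layer_names):
            mat = self.geom.layer(name).material
            m = lay == li
            if m.any():
                sig[m] = cauchy_stress(A[m], mat)
        # in-plane principal stresses: eigenvalues of the (r, z) block plus hoop
        smax: dict[str, float] = {}
        smin: dict[str, float] = {}
        smean: dict[str, float] = {}
        for li, name in enumerate(self.mesh.layer_names):
            m = lay == li
            s = sig[m]
            srr, szz, srz, sth = s[..., 0, 0], s[..., 2, 2], s[..., 0, 2], s[..., 1, 1]
            half = 0.5 * (srr + szz)
            rad = np.sqrt((0.5 * (srr - szz)) ** 2 + srz**2)
            p1 = np.maximum(half + rad, sth)
            p2 = np.minimum(half - rad, sth)
            smax[name] = float(p1.max())
            smin[name] = float(p2.min())
            smean[name] = float((0.5 * (srr + sth)).mean())
        return StressState(sig, smax, smin, smean)

    def measure(self) -> ShapeDescriptors:
        return measure_state(self)


def measure_state(state: ObservedState) -> ShapeDescriptors:
    """Shape descriptors of a converged state (thicknesses at the axis, dome)."""
    mesh = state.mesh
    xy = state.deformed_nodes
    js = mesh.layer_interface_j()
    axis = mesh.axis_nodes()
    z_axis = xy[axis, 1]
    thickness = {
        name: float(z_axis[js[k + 1]] - z_axis[js[k]])
        for k, name in enumerate(mesh.layer_names)
    }
    bottom = np.arange(mesh.nr + 1)  # node row j = 0
    outline = xy[bottom]
    dome = float(outline[0, 1] - outline[-1, 1])
    # apex curvature z''(0) from a quadratic fit over the inner third
    r, z = outline[:, 0], outline[:, 1]
    sel = r <= max(0.35 * r[-1], r[2] if len(r) > 2 else r[-1])
    coef = np.polynomial.polynomial.polyfit(r[sel] ** 2, z[sel], 1)
    curvature = float(2.0 * coef[1])
    return ShapeDescriptors(thickness, dome, curvature, outline)


def solve_grown_shape(
    geom: DiscGeometry,
    growth: dict[str, GrowthTensor],
    resolution: int = 2,
    n_radial: int | None = None,
    mesh: AxisymMesh | None = None,
    n_increments: int = 10,
    u0: np.ndarray | None = None,
    growth_start: dict[str, GrowthTensor] | None = None,
    tol: float | None = None,
) -> ObservedState:
    """Equilibrium of the grown disc under per-layer growth tensors.

    Growth is ramped geometrically from identity (or ``growth_start``) in
    ``n_increments`` quasi-static increments with adaptive halving; the
    returned state carries the converged Newton residual norm.
    """
    if set(growth) != set(geom.layer_names):
        raise ValueError("growth must provide one tensor per layer")
    if mesh is None:
        mesh = build_disc_mesh(geom, resolution=resolution, n_radial=n_radial)
    problem = GrownDiscProblem(
        mesh,
        {l.name: l.material.shear_modulus for l in geom.layers},
        {l.name: l.material.bulk_to_shear for l in geom.layers},
    )
    target = {k: (g.gamma_plane, g.gamma_z) for k, g in growth.items()}
    start = (
        {k: (g.gamma_plane, g.gamma_z) for k, g in growth_start.items()}
        if growth_start
        else None
    )
    u = problem.solve_incremental(
        target, u0=u0, growth_start=start, n_increments=n_increments, tol=tol
    )
    rnorm = float(np.max(np.abs(problem.residual(u)[problem.free])))
    return ObservedState(geom, mesh, u, dict(growth), problem, rnorm)


def simulate_development(
    geom: DiscGeometry,
    schedules: dict[str, GrowthSchedule],
    times: np.ndarray,
    resolution: int = 2,
    n_radial: int | None = None,
    n_increments: int = 10,
    tol: float | None = None,
) -> list[ObservedState]:
    """Quasi-static equilibria along the developmental growth schedules.

    Each requested time is reached by incremental growth continuation from
    the previous one (warm start), so the sequence shares one mesh.
    """
    if set(schedules) != set(geom.layer_names):
        raise ValueError("schedules must cover every layer")
    times = np.atleast_1d(np.asarray(times, dtype=float))
    for name, sched in schedules.items():
        if times.min() < sched.times.min() - 1e-9 or times.max() > sched.times.max() + 1e-9:
            raise ValueError(f"schedule for {name!r} does not cover the requested times")
    mesh = build_disc_mesh(geom, resolution=resolution, n_radial=n_radial)
    states: list[ObservedState] = []
    prev_growth: dict[str, GrowthTensor] | None = None
    u = None
    for t in times:
        growth = {name: sched.tensor_at(float(t)) for name, sched in schedules.items()}
        state = solve_grown_shape(
            geom,
            growth,
            mesh=mesh,
            n_increments=n_increments,
            u0=u,
            growth_start=prev_growth,
            tol=tol,
        )
        states.append(state)
        prev_growth = growth
        u = state.u
    return states


def virtual_collagenase(
    state: ObservedState,
    resolution: int = 2,
    n_radial: int | None = None,
    n_increments: int = 10,
) -> ObservedState:
    """Digest the ECM layer(s) and re-solve the tissue alone.

    With purely planar tissue growth the remaining layer relaxes to a flat
    disc of its initial thickness (the early-development value), whatever
    the stage: growth of a free layer is compatible.  Apical contractility
    is not modelled, so this also covers simultaneous Myosin II inhibition.
    """
    keep = [l for l in state.geom.layers if not l.name.upper().startswith("ECM")]
    if len(keep) == len(state.geom.layers):
        raise ValueError("state has no ECM layer to digest")
    if not keep:
        raise ValueError("removing the ECM would leave no layers")
    geom2 = DiscGeometry(state.geom.outer_radius, tuple(keep))
    growth2 = {l.name: state.growth[l.name] for l in keep}
    return solve_grown_shape(
        geom2, growth2, resolution=resolution, n_radial=n_radial, n_increments=n_increments
    )


@dataclass(frozen=True)
class DecellularizationResult:
    """Relaxed-configuration descriptors of the bottom ECM layer.

    The relaxed thickness is the reference-state value H0_ECM * gamma_z
    (growth is the only thickness change once the elastic load is removed).
    ``thickness_increase`` compares it with the loaded thickness measured on
    the axis; ``area_ratio`` is the relaxed/loaded in-plane area of a
    mid-radius material patch (the bleached-circle observable) and
    ``patch_thickness_ratio`` the relaxed/loaded thickness at that patch, so
    ``area_ratio * patch_thickness_ratio`` = 1/det A ~ 1 expresses elastic
    incompressibility.
    """

    layer: str
    relaxed_thickness: float
    loaded_thickness: float
    thickness_increase: float
    area_ratio: float
    patch_thickness_ratio: float
    volume_conservation: float


def virtual_decellularization(
    state: ObservedState,
    layer: str = "ECM_DP",
    patch_radius_band: tuple[float, float] = (0.4, 0.6),
) -> DecellularizationResult:
    """Remove the cell layers' load and report the relaxed ECM configuration.

    No solve is needed: the relaxed configuration of a uniformly grown free
    layer is its grown flat state (A = I), so relaxed descriptors follow
    from the growth tensor, while loaded ones are read off the converged
    state.  The patch relaxation uses the elastic tensor averaged over
    quadrature points in a radial band around mid-radius.
    """
    if layer not in state.mesh.layer_names:
        raise KeyError(f"layer {layer!r} not in state")
    li = state.mesh.layer_names.index(layer)
    G = state.growth[layer]
    H0 = state.geom.layer(layer).thickness
    relaxed = H0 * G.gamma_z
    loaded = measure_state(state).thickness[layer]
    f = state.elastic_field()
    R0 = state.geom.outer_radius
    m = (
        (f["layer"] == li)
        & (f["R"] >= patch_radius_band[0] * R0)
        & (f["R"] <= patch_radius_band[1] * R0)
    )
    if not m.any():
        raise ValueError("no quadrature points in the requested patch band")
    # ||A^{-T} E_Z||: relaxed/loaded thickness of a thin sheet whose
    # reference normal is E_Z; in-plane area then follows from det A.
    d2 = f["ArR"][m] * f["AzZ"][m] - f["ArZ"][m] * f["AzR"][m]
    anorm = np.sqrt(f["AzR"][m] ** 2 + f["ArR"][m] ** 2) / d2
    JA = f["J"][m]
    patch_thickness_ratio = float(np.mean(anorm))
    area_ratio = float(np.mean(1.0 / (JA * anorm)))
    return DecellularizationResult(
        layer=layer,
        relaxed_thickness=float(relaxed),
        loaded_thickness=float(loaded),
        thickness_increase=float(relaxed / loaded - 1.0),
        area_ratio=area_ratio,
        patch_thickness_ratio=patch_thickness_ratio,
        volume_conservation=float(area_ratio * patch_thickness_ratio),
    )
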