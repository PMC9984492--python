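"""(rho, mu) phase-diagram scan and best-fit selection.

The two free model parameters — the ECM growth-anisotropy exponent rho and
the stiffness ratio mu = mu_ECM / mu_DP — are fitted by a tolerance-band
grid scan: for every cell the ECM growth factor is refitted (the total
deposited ECM volume is rho-independent), the disc is grown to the final
developmental time, virtually decellularized, and three measurables are
compared with the experimental targets:

* DP thickness fold-change (final / initial, on the axis),
* loaded bottom-ECM thickness fold-change (on the axis),
* relative bottom-ECM thickness increase upon decellularization
  (material-patch measure, the bleached-circle observable).

A cell is admissible when all three are within the relative tolerance
(default 22.4%); the best fit minimises the summed squared relative error
over the admissible region.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._fem import InvertedElementError, NonConvergenceError
from .growth import GrowthSchedule, fit_ecm_growth, fit_planar_growth
from .solver import (
    DiscGeometry,
    build_disc_mesh,
    measure_state,
    solve_grown_shape,
    virtual_decellularization,
)

__all__ = [
    "FitTargets",
    "NoAdmissibleFitError",
    "CandidateResult",
    "PhaseDiagram",
    "evaluate_candidate",
    "scan_phase_diagram",
    "select_best_fit",
]

_MEASURABLES = ("dp_thickness_fold", "ecm_thickness_fold", "decell_thickness_increase")


@dataclass(frozen=True)
class FitTargets:
    """Experimental ratio targets with a relative tolerance half-width."""

    dp_thickness_fold: float = 2.0
    ecm_thickness_fold: float = 1.36
    decell_thickness_increase: float = 0.25
    tolerance: float = 0.224

    def __post_init__(self) -> None:
        if min(self.dp_thickness_fold, self.ecm_thickness_fold, self.decell_thickness_increase) <= 0:
            raise ValueError("targets must be positive")
        if not (0.0 < self.tolerance < 1.0):
            raise ValueError("tolerance must be in (0, 1)")

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in _MEASURABLES}


@dataclass(frozen=True)
class CandidateResult:
    rho: float
    mu: float
    measurables: dict[str, float]
    admissible: dict[str, bool]
    error: float  # summed squared relative error
    ok: bool  # solver converged
    diagnostic: str = ""

    @property
    def all_admissible(self) -> bool:
        return self.ok and all(self.admissible.values())


@dataclass
class PhaseDiagram:
    rho_grid: np.ndarray
    mu_grid: np.ndarray
    results: list[list[CandidateResult]]  # [i_rho][i_mu]
    targets: FitTargets

    def mask(self, name: str) -> np.ndarray:
        """Boolean admissibility mask for one constraint (rho x mu)."""
        return np.array(
            [[r.ok and r.admissible[name] for r in row] for row in self.results], dtype=bool
        )

    @property
    def intersection(self) -> np.ndarray:
        m = self.mask(_MEASURABLES[0])
        for name in _MEASURABLES[1:]:
            m &= self.mask(name)
        return m

    def measurable_grid(self, name: str) -> np.ndarray:
        return np.array(
            [[r.measurables.get(name, np.nan) for r in row] for row in self.results]
        )

    def nearest_miss(self) -> CandidateResult:
        """Cell minimising the error, ignoring admissibility (diagnostics)."""
        ok = [r for row in self.results for r in row if r.ok]
        if not ok:
            raise NoAdmissibleFitError("no cell converged")
        return min(ok, key=lambda r: r.error)


class NoAdmissibleFitError(RuntimeError):
    """No grid cell satisfies all constraints; carries the nearest miss."""

    def __init__(self, message: str, nearest: CandidateResult | None = None):
        super().__init__(message)
        self.nearest = nearest


def _default_schedules(rho: float, fit_mode: str = "log-linear"):
    """Growth schedules refitted from the packaged volume series for one rho."""
    from .synth import generate_volume_timeseries

    dp = generate_volume_timeseries("DP", noise=0.0)
    ecm = generate_volume_timeseries("ECM_DP", noise=0.0)
    t0 = ecm.times.min()  # common window: the ECM series starts at 72 hAEL
    keep = dp.times >= t0 - 1e-9
    sched_dp = fit_planar_growth(dp.times[keep], dp.volumes[keep], layer_id="DP", mode=fit_mode)
    sched_ecm = fit_ecm_growth(ecm.times, ecm.volumes, rho=rho, layer_id="ECM_DP", mode=fit_mode)
    return {"DP": sched_dp, "ECM_DP": sched_ecm}


def evaluate_candidate(
    rho: float,
    mu: float,
    targets: FitTargets,
    geom: DiscGeometry | None = None,
    schedules: dict[str, GrowthSchedule] | None = None,
    final_time: float | None = None,
    resolution: int = 2,
    n_increments: int = 8,
    fit_mode: str = "log-linear",
) -> CandidateResult:
    """Simulate one (rho, mu) cell and compare with the targets.

    gamma_ECM is refitted for this rho (volume-preserving reparameterisation)
    unless explicit schedules are supplied; the DP + bottom-ECM disc is grown
    to the final scheduled time and virtually decellularized.  Solver
    failures are reported as inadmissible cells, not exceptions.
    """
    if schedules is None:
        schedules = _default_schedules(rho, fit_mode)
    else:
        schedules = dict(schedules)
        schedules["ECM_DP"] = GrowthSchedule(
            "ECM_DP",
            schedules["ECM_DP"].times,
            schedules["ECM_DP"].gamma_plane ** ((2.0 + schedules["ECM_DP"].rho) / (2.0 + rho)),
            rho=rho,
            fit_mode=schedules["ECM_DP"].fit_mode,
        )
    if geom is None:
        geom = DiscGeometry.bilayer(mu_ratio=mu)
    else:
        from dataclasses import replace as _replace

        from .materials import NeoHookeanMaterial

        layers = tuple(
            _replace(
                l,
                material=NeoHookeanMaterial(
                    mu if l.name.upper().startswith("ECM") else 1.0,
                    l.material.bulk_to_shear,
                ),
            )
            for l in geom.layers
        )
        geom = DiscGeometry(geom.outer_radius, layers)
    t_end = final_time if final_time is not None else float(
        min(s.times.max() for s in schedules.values())
    )
    growth = {name: s.tensor_at(t_end) for name, s in schedules.items()}
    h_ecm = geom.layer("ECM_DP").thickness
    h_dp = geom.layer("DP").thickness
    try:
        mesh = build_disc_mesh(geom, resolution=resolution)
        state = solve_grown_shape(geom, growth, mesh=mesh, n_increments=n_increments)
        m = measure_state(state)
        d = virtual_decellularization(state)
    except (NonConvergenceError, InvertedElementError, ValueError) as exc:
        return CandidateResult(
            rho, mu, {}, {k: False for k in _MEASURABLES}, np.inf, False, str(exc)
        )
    meas = {
        "dp_thickness_fold": m.thickness["DP"] / h_dp,
        "ecm_thickness_fold": m.thickness["ECM_DP"] / h_ecm,
        "decell_thickness_increase": d.patch_thickness_ratio - 1.0,
        "decell_area_ratio": d.area_ratio,
        "dome_height": m.dome_height,
    }
    tg = targets.as_dict()
    rel = {k: (meas[k] - tg[k]) / tg[k] for k in _MEASURABLES}
    admissible = {k: bool(abs(rel[k]) <= targets.tolerance) for k in _MEASURABLES}
    error = float(sum(r**2 for r in rel.values()))
    return CandidateResult(float(rho), float(mu), meas, admissible, error, True)


def scan_phase_diagram(
    rho_grid: np.ndarray,
    mu_grid: np.ndarray,
    targets: FitTargets,
    geom: DiscGeometry | None = None,
    schedules: dict[str, GrowthSchedule] | None = None,
    resolution: int = 2,
    n_increments: int = 8,
    fit_mode: str = "log-linear",
    progress: bool = False,
) -> PhaseDiagram:
    """Evaluate every (rho, mu) cell; cells are independent and deterministic."""
    rho_grid = np.atleast_1d(np.asarray(rho_grid, dtype=float))
    mu_grid = np.atleast_1d(np.asarray(mu_grid, dtype=float))
    if rho_grid.size == 0 or mu_grid.size == 0:
        raise ValueError("grids must be non-empty")
    results: list[list[CandidateResult]] = []
    for rho in rho_grid:
        row = []
        cell_schedules = schedules if schedules is not None else _default_schedules(rho, fit_mode)
        for mu in mu_grid:
            r = evaluate_candidate(
                rho,
                mu,
                targets,
                geom=geom,
                schedules=cell_schedules,
                resolution=resolution,
                n_increments=n_increments,
                fit_mode=fit_mode,
            )
            if progress:
                print(
                    f"  rho={rho:.3f} mu={mu:.3g}: "
                    + (
                        ", ".join(f"{k}={v:.3f}" for k, v in r.measurables.items())
                        if r.ok
                        else f"solver failure ({r.diagnostic})"
                    )
                )
            row.append(r)
        results.append(row)
    return PhaseDiagram(rho_grid, mu_grid, results, targets)


def select_best_fit(pd: PhaseDiagram) -> CandidateResult:
    """Admissible cell with the least summed squared relative error.

    Raises NoAdmissibleFitError (with a nearest-miss report) if the
    triple-intersection region is empty.
    """
    admissible = [r for row in pd.results for r in row if r.all_admissible]
    if not admissible:
        nearest = pd.nearest_miss()
        raise NoAdmissibleFitError(
            "no admissible fit: empty intersection region "
            f"(nearest miss rho={nearest.rho}, mu={nearest.mu}, error={nearest.error:.4f})",
            nearest=nearest,
        )
    return min(admissible, key=lambda r: (r.error, r.rho, r.mu))
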