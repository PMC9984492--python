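"""Configuration-driven orchestration of the full analysis.

Stages: generate (or load) volume data -> fit growth schedules -> simulate
development -> virtual collagenase and decellularization -> (rho, mu)
phase-diagram scan -> report.  Every run writes a resolved copy of its
configuration, a machine-readable JSON summary tagged with the config hash
and seed, and diagram/trajectory plots.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from ._fem import NonConvergenceError
from .config import RunConfig
from .growth import fit_ecm_growth, fit_planar_growth
from .io import write_outline_csv, write_thickness_csv, write_vtk
from .phase import FitTargets, NoAdmissibleFitError, scan_phase_diagram, select_best_fit
from .solver import (
    DiscGeometry,
    Layer,
    measure_state,
    simulate_development,
    virtual_collagenase,
    virtual_decellularization,
)
from .materials import NeoHookeanMaterial

log = logging.getLogger("morphodisc")

__all__ = ["run_pipeline", "PipelineError", "build_geometry", "load_or_generate_series"]


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name for resumability."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


def build_geometry(cfg: RunConfig) -> DiscGeometry:
    g, m = cfg.geometry, cfg.material
    return DiscGeometry(
        outer_radius=g.outer_radius,
        layers=(
            Layer("ECM_DP", g.h_ecm, NeoHookeanMaterial(m.mu_ratio, m.bulk_to_shear)),
            Layer("DP", g.h_dp, NeoHookeanMaterial(1.0, m.bulk_to_shear)),
        ),
    )


def load_or_generate_series(cfg: RunConfig):
    """Volume series from configured CSV paths, else the packaged fixtures."""
    from .synth import generate_volume_timeseries

    def load(path: str | None, layer: str):
        if path is not None:
            df = pd.read_csv(path)
            return df["time_hAEL"].to_numpy(float), df["volume"].to_numpy(float)
        fx = generate_volume_timeseries(layer, seed=cfg.seed, noise=0.0)
        return fx.times, fx.volumes

    return load(cfg.growth_fit.dp_series, "DP"), load(cfg.growth_fit.ecm_series, "ECM_DP")


def fit_growth_schedules(cfg: RunConfig):
    (t_dp, v_dp), (t_ecm, v_ecm) = load_or_generate_series(cfg)
    t0 = t_ecm.min()  # common simulation window starts where both series exist
    keep = t_dp >= t0 - 1e-9
    dp = fit_planar_growth(t_dp[keep], v_dp[keep], layer_id="DP", mode=cfg.growth_fit.mode)
    ecm = fit_ecm_growth(
        t_ecm, v_ecm, rho=cfg.growth_fit.rho, layer_id="ECM_DP", mode=cfg.growth_fit.mode
    )
    return {"DP": dp, "ECM_DP": ecm}


def run_pipeline(cfg: RunConfig, outdir: str | Path) -> dict:
    """Execute all stages; returns (and writes) the summary dict."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg.write_yaml(outdir / "config.resolved.yaml")
    summary: dict = {"config_hash": cfg.config_hash(), "seed": cfg.seed}

    # -- growth fitting ----------------------------------------------------
    try:
        schedules = fit_growth_schedules(cfg)
    except Exception as exc:
        raise PipelineError("fit-growth", str(exc)) from exc
    for name, s in schedules.items():
        pd.DataFrame(
            {"time_hAEL": s.times, "gamma_plane": s.gamma_plane, "gamma_z": s.gamma_z}
        ).to_csv(outdir / f"schedule_{name}.csv", index=False)
    summary["gamma_final"] = {
        name: float(s.gamma_plane[-1]) for name, s in schedules.items()
    }
    summary["volume_fold_final"] = {
        name: float(s.volume_fold_at(s.times[-1])) for name, s in schedules.items()
    }
    log.info("fitted growth schedules: %s", summary["gamma_final"])

    # -- development simulation -------------------------------------------
    geom = build_geometry(cfg)
    times = np.asarray(cfg.simulation.times, dtype=float)
    try:
        states = simulate_development(
            geom,
            schedules,
            times,
            resolution=cfg.simulation.resolution,
            n_increments=cfg.simulation.n_increments,
        )
    except NonConvergenceError as exc:
        raise PipelineError("simulate", str(exc)) from exc
    rows = []
    for t, st in zip(times, states):
        m = measure_state(st)
        rows.append(
            {
                "time_hAEL": float(t),
                "H_DP": m.thickness["DP"],
                "H_ECM": m.thickness["ECM_DP"],
                "dome_height": m.dome_height,
                "basal_curvature": m.basal_curvature,
            }
        )
        log.info("t=%.0f hAEL: H_DP=%.3f H_ECM=%.3f dome=%.3f", t, rows[-1]["H_DP"],
                 rows[-1]["H_ECM"], rows[-1]["dome_height"])
    write_thickness_csv(outdir / "trajectory.csv", rows)
    final = states[-1]
    write_outline_csv(outdir / "basal_outline_final.csv", measure_state(final).basal_outline)
    write_vtk(outdir / "final_state.vtk", final.mesh, final.u)
    summary["trajectory"] = rows

    # -- virtual experiments ----------------------------------------------
    try:
        relaxed = virtual_collagenase(final, resolution=cfg.simulation.resolution)
        mr = measure_state(relaxed)
        summary["collagenase"] = {
            "H_DP_relaxed": mr.thickness["DP"],
            "dome_height": mr.dome_height,
            "basal_curvature": mr.basal_curvature,
        }
    except Exception as exc:
        raise PipelineError("collagenase", str(exc)) from exc
    d = virtual_decellularization(final)
    summary["decellularization"] = {
        "relaxed_thickness": d.relaxed_thickness,
        "loaded_thickness": d.loaded_thickness,
        "thickness_increase_axis": d.thickness_increase,
        "patch_thickness_ratio": d.patch_thickness_ratio,
        "area_ratio": d.area_ratio,
        "volume_conservation": d.volume_conservation,
    }

    # -- phase diagram -----------------------------------------------------
    from .synth import packaged_fit_targets

    targets = packaged_fit_targets()
    targets = FitTargets(
        targets.dp_thickness_fold,
        targets.ecm_thickness_fold,
        targets.decell_thickness_increase,
        cfg.phase_diagram.tolerance,
    )
    pdiag = scan_phase_diagram(
        np.asarray(cfg.phase_diagram.rho_grid),
        np.asarray(cfg.phase_diagram.mu_grid),
        targets,
        geom=geom,
        resolution=cfg.simulation.resolution,
        n_increments=cfg.simulation.n_increments,
        fit_mode=cfg.growth_fit.mode,
    )
    masks = {name: pdiag.mask(name).tolist() for name in targets.as_dict()}
    pd.DataFrame(
        [
            {
                "rho": r.rho,
                "mu": r.mu,
                "ok": r.ok,
                "admissible": r.all_admissible,
                "error": r.error,
                **{k: r.measurables.get(k, np.nan) for k in targets.as_dict()},
            }
            for row in pdiag.results
            for r in row
        ]
    ).to_csv(outdir / "phase_diagram.csv", index=False)
    summary["phase_diagram"] = {
        "rho_grid": pdiag.rho_grid.tolist(),
        "mu_grid": pdiag.mu_grid.tolist(),
        "masks": masks,
        "intersection": pdiag.intersection.tolist(),
        "n_admissible": int(pdiag.intersection.sum()),
    }
    try:
        best = select_best_fit(pdiag)
        summary["best_fit"] = {
            "rho": best.rho,
            "mu": best.mu,
            "error": best.error,
            "measurables": best.measurables,
        }
        log.info("best fit: rho=%.3f mu=%.3g", best.rho, best.mu)
    except NoAdmissibleFitError as exc:
        summary["best_fit"] = None
        summary["no_admissible_fit"] = str(exc)
        log.warning("%s", exc)

    _plot_report(outdir, summary, pdiag, rows)
    (outdir / "summary.json").write_text(json.dumps(summary, indent=1, default=float))
    return summary


def _plot_report(outdir: Path, summary: dict, pdiag, rows: list[dict]) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(11, 4.2))
    inter = pdiag.intersection
    extent = None
    im = axes[0].pcolormesh(
        pdiag.mu_grid,
        pdiag.rho_grid,
        sum(pdiag.mask(n).astype(int) for n in pdiag.targets.as_dict()),
        shading="nearest",
        cmap="Blues",
        vmin=0,
        vmax=3,
    )
    axes[0].set_xscale("log")
    fig.colorbar(im, ax=axes[0], label="constraints satisfied")
    if summary.get("best_fit"):
        axes[0].plot(summary["best_fit"]["mu"], summary["best_fit"]["rho"], "r*", ms=14)
    axes[0].set_xlabel(r"$\mu = \mu_{ECM}/\mu_{DP}$")
    axes[0].set_ylabel(r"growth anisotropy $\rho$")
    axes[0].set_title("phase diagram")
    t = [r["time_hAEL"] for r in rows]
    axes[1].plot(t, [r["H_DP"] for r in rows], "o-", label="H_DP")
    axes[1].plot(t, [r["H_ECM"] * 10 for r in rows], "s-", label="H_ECM x 10")
    axes[1].plot(t, [r["dome_height"] for r in rows], "^-", label="dome height")
    axes[1].set_xlabel("time (hAEL)")
    axes[1].set_ylabel("length (units of initial DP thickness)")
    axes[1].legend()
    axes[1].set_title("simulated trajectories")
    fig.tight_layout()
    fig.savefig(outdir / "report.png", dpi=130)
    plt.close(fig)
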