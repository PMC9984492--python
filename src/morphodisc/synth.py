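"""Synthetic measurement data calibrated to the quantified wing-disc growth.

Everything the pipeline consumes can be generated here, so every stage is
testable without microscopy data:

* layer volume time series (wing-pouch DP, bottom ECM, PPE) whose noiseless
  means reproduce the measured fold-changes exactly — DP grows ~66-fold
  from 65 to 118 hAEL (~19.9-fold from 72), the bottom ECM ~16.2-fold and
  the PPE ~8.2-fold from 72 to 118;
* clone-volume tracks from ex vivo movies (10-min frames, up to 10 h) with
  a uniform exponential volume growth rate, default 0.085 / h;
* bleached-circle fixtures for the decellularization read-out;
* the measurement computations used on such data: spherical-cap-corrected
  pouch volume, log2(n) division counts, and the hourly clonal growth-rate
  estimator with 3-frame averaging.

Noise is multiplicative log-normal throughout (volumes are positive and
errors scale with size); every generator is seed-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .phase import FitTargets

__all__ = [
    "VolumeSeriesFixture",
    "CloneTrackFixture",
    "BleachCircleFixture",
    "generate_volume_timeseries",
    "generate_clone_movie",
    "generate_bleach_circles",
    "estimate_clonal_growth_rate",
    "pouch_volume_capcorrected",
    "clone_divisions_from_count",
    "packaged_fit_targets",
]

# calibrated mean-curve anchors: (time hAEL, volume fold relative to first time)
_ANCHORS: dict[str, list[tuple[float, float]]] = {
    # DP pouch: 66x over 65->118 and 19.9x over 72->118
    "DP": [(65.0, 1.0), (72.0, 66.0 / 19.9), (118.0, 66.0)],
    # bottom ECM: estimated volume fold 16.2x over 72->118
    "ECM_DP": [(72.0, 1.0), (118.0, 16.2)],
    # PPE covering the pouch: 8.2x over 72->118
    "PPE": [(72.0, 1.0), (118.0, 8.2)],
}
_SAMPLE_TIMES: dict[str, list[float]] = {
    "DP": [65.0, 72.0, 80.0, 96.0, 118.0],
    "ECM_DP": [72.0, 80.0, 96.0, 118.0],
    "PPE": [72.0, 80.0, 96.0, 118.0],
}


@dataclass(frozen=True)
class VolumeSeriesFixture:
    """Mean layer-volume time series with replicate scatter."""

    layer_id: str
    times: np.ndarray
    volumes: np.ndarray  # mean over replicates, normalised to 1 at times[0]
    sd: np.ndarray
    replicates: np.ndarray  # (n_replicates, n_times)
    n_replicates: int
    noise: float
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_hAEL": self.times, "volume": self.volumes, "sd": self.sd,
             "layer_id": self.layer_id}
        )

    def write(self, path: str | Path) -> None:
        """CSV plus a JSON sidecar with the generation parameters."""
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        meta = {
            "layer_id": self.layer_id,
            "n_replicates": self.n_replicates,
            "noise": self.noise,
            "seed": self.seed,
        }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def _mean_curve(layer: str, times: np.ndarray) -> np.ndarray:
    anchors = _ANCHORS[layer]
    at = np.array([a[0] for a in anchors])
    av = np.array([a[1] for a in anchors])
    return np.exp(np.interp(times, at, np.log(av)))


def generate_volume_timeseries(
    layer: str,
    seed: int = 0,
    noise: float = 0.15,
    n_replicates: int = 14,
    times: np.ndarray | None = None,
) -> VolumeSeriesFixture:
    """Log-normal replicate scatter around the calibrated mean growth curve.

    With ``noise = 0`` the series is exactly the calibrated curve, so the
    printed fold-changes are reproduced exactly.
    """
    if layer not in _ANCHORS:
        raise ValueError(f"unknown layer {layer!r}; expected one of {sorted(_ANCHORS)}")
    t = np.asarray(times, dtype=float) if times is not None else np.asarray(_SAMPLE_TIMES[layer])
    mean = _mean_curve(layer, t)
    rng = np.random.default_rng(seed)
    if noise > 0:
        reps = mean[None, :] * rng.lognormal(0.0, noise, size=(n_replicates, t.size))
    else:
        reps = np.tile(mean, (n_replicates, 1))
    vols = reps.mean(axis=0)
    sd = reps.std(axis=0, ddof=1) if n_replicates > 1 else np.zeros_like(vols)
    if noise == 0:
        vols = mean  # exact calibration
    return VolumeSeriesFixture(layer, t, vols, sd, reps, n_replicates, float(noise), int(seed))


@dataclass(frozen=True)
class CloneTrackFixture:
    """Per-clone volume tracks from a synthetic ex vivo movie."""

    times_h: np.ndarray  # hours from movie start, 10-min spacing
    volumes: np.ndarray  # (n_clones, n_frames)
    rate: float  # generating rate k (1/h)
    noise: float
    seed: int

    @property
    def n_clones(self) -> int:
        return self.volumes.shape[0]

    def to_frame(self) -> pd.DataFrame:
        n, T = self.volumes.shape
        return pd.DataFrame(
            {
                "clone": np.repeat(np.arange(n), T),
                "time_h": np.tile(self.times_h, n),
                "volume": self.volumes.ravel(),
            }
        )


def generate_clone_movie(
    n_clones: int = 14,
    rate: float = 0.085,
    noise: float = 0.10,
    seed: int = 0,
    duration_h: float = 10.0,
    frame_min: float = 10.0,
) -> CloneTrackFixture:
    """Exponential clone growth with multiplicative log-normal frame noise.

    V_c(t) = V_c(0) * exp(k t) * eps(t); initial clone volumes are
    log-normally dispersed.  With ``noise = 0`` tracks are exact
    exponentials.
    """
    if n_clones < 1:
        raise ValueError("need at least one clone")
    if noise < 0:
        raise ValueError("noise must be non-negative")
    t = np.arange(0.0, duration_h + 1e-9, frame_min / 60.0)
    rng = np.random.default_rng(seed)
    v0 = rng.lognormal(0.0, 0.3, size=n_clones)
    tracks = v0[:, None] * np.exp(rate * t)[None, :]
    if noise > 0:
        tracks = tracks * rng.lognormal(0.0, noise, size=tracks.shape)
    return CloneTrackFixture(t, tracks, float(rate), float(noise), int(seed))


def estimate_clonal_growth_rate(
    tracks: CloneTrackFixture | np.ndarray,
    times_h: np.ndarray | None = None,
) -> tuple[np.ndarray, float]:
    """Hourly clonal growth rates with 3-frame averaging.

    Clone volume at each full hour is the mean of the three consecutive
    frames centred on that hour; the per-clone rate is the mean over hours
    of ln(V_{h+1} / V_h) across the full movie span.  Only hours whose
    centred window lies inside the movie are used, so noiseless exponential
    tracks are recovered exactly.  Returns (per-clone rates, mean rate).
    """
    if isinstance(tracks, CloneTrackFixture):
        t, V = tracks.times_h, tracks.volumes
    else:
        if times_h is None:
            raise ValueError("times_h required when passing a bare array")
        t, V = np.asarray(times_h, float), np.atleast_2d(np.asarray(tracks, float))
    if V.shape[1] < 3:
        raise ValueError("need at least 3 frames per clone")
    if np.any(V <= 0):
        raise ValueError("volumes must be positive")
    dt = t[1] - t[0]
    per_hour = max(1, int(round(1.0 / dt)))
    anchors = [
        i
        for i in range(0, V.shape[1], per_hour)
        if i - 1 >= 0 and i + 1 < V.shape[1]
    ]
    if len(anchors) < 2:
        raise ValueError("movie too short for hourly rate estimation")
    hourly = np.stack([(V[:, i - 1] + V[:, i] + V[:, i + 1]) / 3.0 for i in anchors], axis=1)
    hours = t[anchors]
    rates = np.diff(np.log(hourly), axis=1) / np.diff(hours)[None, :]
    per_clone = rates.mean(axis=1)
    return per_clone, float(per_clone.mean())


@dataclass(frozen=True)
class BleachCircleFixture:
    """Bleached-circle areas and local ECM thickness before/after decellularization."""

    layer_id: str  # ECM_DP or ECM_PPE
    area_t0: np.ndarray
    area_t60: np.ndarray
    thickness_t0: np.ndarray
    thickness_t60: np.ndarray
    seed: int

    @property
    def area_ratio(self) -> np.ndarray:
        return self.area_t60 / self.area_t0

    @property
    def thickness_ratio(self) -> np.ndarray:
        return self.thickness_t60 / self.thickness_t0


def generate_bleach_circles(
    layer: str = "ECM_DP",
    n_circles: int = 26,
    seed: int = 0,
    noise: float = 0.03,
    area_relaxation: float = 0.79,
) -> BleachCircleFixture:
    """Synthetic bleached-circle relaxation data.

    The top ECM (ECM_PPE) is unloaded: neither area nor thickness changes.
    The bottom ECM relaxes to ~79% area with the thickness increase set by
    volume conservation (area x thickness conserved by construction, up to
    the stated measurement noise).
    """
    rng = np.random.default_rng(seed)
    a0 = rng.lognormal(0.0, 0.2, n_circles)
    h0 = np.full(n_circles, 1.0) * rng.lognormal(0.0, noise, n_circles)
    if layer == "ECM_PPE":
        ratio = rng.lognormal(0.0, noise, n_circles)
    elif layer == "ECM_DP":
        ratio = area_relaxation * rng.lognormal(0.0, noise, n_circles)
    else:
        raise ValueError("layer must be ECM_DP or ECM_PPE")
    a60 = a0 * ratio
    h60 = h0 / ratio * rng.lognormal(0.0, noise, n_circles)
    return BleachCircleFixture(layer, a0, a60, h0, h60, int(seed))


def pouch_volume_capcorrected(thickness: float, ring_area: float, cap_height: float) -> float:
    """Pouch volume as (spherical-cap-corrected ring area) x thickness.

    The projected area of the pouch-delimiting ring (radius a) undercounts
    the domed surface; the ring is treated as the rim of a spherical cap of
    height h, whose surface area is pi (a^2 + h^2).
    """
    if thickness < 0 or ring_area < 0 or cap_height < 0:
        raise ValueError("inputs must be non-negative")
    a2 = ring_area / np.pi
    return float(np.pi * (a2 + cap_height**2) * thickness)


def clone_divisions_from_count(n_cells: int) -> float:
    """Number of division rounds implied by n cells in a clone: log2(n)."""
    if n_cells < 1 or int(n_cells) != n_cells:
        raise ValueError("cell count must be a positive integer")
    return float(np.log2(n_cells))


def packaged_fit_targets() -> FitTargets:
    """The printed experimental ratio targets for the phase-diagram fit.

    DP thickness doubles over development; loaded bottom-ECM thickness
    increases ~36%; bottom-ECM thickness increases ~25% upon
    decellularization; tolerance band 22.4%.
    """
    return FitTargets(
        dp_thickness_fold=2.0,
        ecm_thickness_fold=1.36,
        decell_thickness_increase=0.25,
        tolerance=0.224,
    )
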