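"""Regional loading metrics for one stance: PP, TPP, PTI and COP velocity.

For each anatomical region the per-frame regional pressure curve is the
maximum pressure over the region's sensors in that frame (the convention
insole software uses for its "peak pressure temporal series").  From it:

* **PP** (peak pressure, kPa) — the curve's maximum over stance;
* **TPP** (time to peak pressure, % of stance) — the first frame at which
  the maximum occurs, as a percentage of stance duration, with the last
  stance frame mapping to exactly 100 %;
* **PTI** (pressure–time integral, kPa·s) — trapezoidal integral of the
  curve over stance time.

The centre of pressure (COP) is the pressure·area-weighted centroid of
sensor positions per frame; its mean velocity (path length over elapsed
time) summarises how fast load progresses over the foot.  The total COP
uses every sensor over the whole stance; regional COPs use the region's
sensors over the frames in which that region carries load.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import trapezoid

from .geometry import REGIONS, RegionMaskSet, StancePhase
from .pressure_io import PressureRecording

__all__ = [
    "RegionSeries",
    "CopPath",
    "RolloverMetrics",
    "SubjectAggregate",
    "UndefinedVelocityError",
    "regional_series",
    "peak_pressure",
    "time_to_peak",
    "pressure_time_integral",
    "cop_trajectory",
    "cop_mean_velocity",
    "compute_rollover_metrics",
    "aggregate_steps",
    "metrics_to_tidy",
]


class UndefinedVelocityError(ValueError):
    """COP path too short to define a mean velocity."""


@dataclass(frozen=True)
class RegionSeries:
    """Per-frame maximum pressure (kPa) over one region's sensors."""

    region: str
    values: np.ndarray  # (n_frames,) kPa
    active: bool        # False when the region has no sensors / no load

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, float))


@dataclass(frozen=True)
class CopPath:
    """COP positions (m) and the frame indices (within stance) they belong to."""

    points: np.ndarray   # (k, 2)
    frames: np.ndarray   # (k,) indices into the stance window
    sampling_rate: float

    @property
    def length(self) -> float:
        """Total path length in m (sum of segment lengths)."""
        if self.points.shape[0] < 2:
            return 0.0
        return float(np.linalg.norm(np.diff(self.points, axis=0), axis=1).sum())


@dataclass(frozen=True)
class RolloverMetrics:
    """All loading metrics for one stance of one foot."""

    stance_duration: float                  # s
    pp: dict[str, float]                    # kPa per region
    tpp: dict[str, float]                   # % of stance per region
    pti: dict[str, float]                   # kPa·s per region
    cop_velocity: dict[str, float]          # m/s per region (NaN if inactive)
    total_cop_velocity: float               # m/s


@dataclass(frozen=True)
class SubjectAggregate:
    """Mean and sample SD of every metric over a subject's analysis steps."""

    n_steps: int
    mean: RolloverMetrics
    sd: RolloverMetrics


def regional_series(rec: PressureRecording, phase: StancePhase,
                    masks: RegionMaskSet) -> list[RegionSeries]:
    """Per-frame max-pressure curve for each of the six regions.

    A region without sensors (possible on sparse footprints) yields an
    all-zero series flagged inactive.
    """
    window = rec.frames[phase.start_frame:phase.end_frame]
    out = []
    for region in REGIONS:
        idx = masks.sensors(region)
        if idx.size == 0:
            out.append(RegionSeries(region, np.zeros(window.shape[0]), False))
        else:
            vals = window[:, idx].max(axis=1)
            out.append(RegionSeries(region, vals, bool(vals.any())))
    return out


def peak_pressure(series: RegionSeries) -> float:
    """Maximum of the regional pressure curve, kPa."""
    if series.values.size == 0:
        raise ValueError("empty series")
    return float(series.values.max())


def time_to_peak(series: RegionSeries, phase: StancePhase) -> float:
    """Instant of the (first) regional maximum as % of stance duration.

    Uses ``100 · argmax / (N − 1)`` so a peak in the final stance frame is
    exactly 100 %.  Ties resolve to the first occurrence.
    """
    n = series.values.size
    if n == 0:
        raise ValueError("empty series")
    if n == 1:
        return 0.0
    return 100.0 * float(np.argmax(series.values)) / (n - 1)


def pressure_time_integral(series: RegionSeries, sampling_rate: float) -> float:
    """Trapezoidal integral of the regional curve over stance time, kPa·s."""
    if sampling_rate <= 0:
        raise ValueError("sampling_rate must be > 0")
    if series.values.size < 2:
        return 0.0
    return float(trapezoid(series.values, dx=1.0 / sampling_rate))


def _weighted_cop(window: np.ndarray, positions: np.ndarray,
                  areas: np.ndarray) -> CopPath:
    load = window * areas  # kPa·m² per sensor
    total = load.sum(axis=1)
    keep = np.flatnonzero(total > 0)
    if keep.size == 0:
        return CopPath(np.empty((0, 2)), keep, 0.0)
    pts = (load[keep] @ positions) / total[keep, None]
    return CopPath(pts, keep, 0.0)


def cop_trajectory(rec: PressureRecording, phase: StancePhase,
                   masks: RegionMaskSet) -> tuple[CopPath, dict[str, CopPath]]:
    """Total and per-region COP paths over the stance.

    Frames with zero load (total, or zero regional load for a regional
    path) are excluded; the regional path therefore covers only that
    region's active window.
    """
    window = rec.frames[phase.start_frame:phase.end_frame]
    if window.size == 0 or not (window > 0).any():
        raise ValueError("stance phase carries no load")
    positions = rec.grid.positions
    areas = rec.grid.area

    total = _weighted_cop(window, positions, areas)
    total = CopPath(total.points, total.frames, rec.sampling_rate)

    regional: dict[str, CopPath] = {}
    for region in REGIONS:
        idx = masks.sensors(region)
        if idx.size == 0:
            regional[region] = CopPath(np.empty((0, 2)), np.empty(0, int),
                                       rec.sampling_rate)
            continue
        p = _weighted_cop(window[:, idx], positions[idx], areas[idx])
        regional[region] = CopPath(p.points, p.frames, rec.sampling_rate)
    return total, regional


def cop_mean_velocity(path: CopPath) -> float:
    """Mean COP velocity: path length / elapsed time over the path window, m/s."""
    if path.points.shape[0] < 2:
        raise UndefinedVelocityError("COP path needs at least 2 points")
    elapsed = (path.frames[-1] - path.frames[0]) / path.sampling_rate
    if elapsed <= 0:
        raise UndefinedVelocityError("COP path spans no time")
    return path.length / elapsed


def compute_rollover_metrics(rec: PressureRecording, phase: StancePhase,
                             masks: RegionMaskSet) -> RolloverMetrics:
    """All regional metrics plus total COP velocity for one stance."""
    series = regional_series(rec, phase, masks)
    total_path, regional_paths = cop_trajectory(rec, phase, masks)
    pp, tpp, pti, vel = {}, {}, {}, {}
    for s in series:
        pp[s.region] = peak_pressure(s)
        tpp[s.region] = time_to_peak(s, phase)
        pti[s.region] = pressure_time_integral(s, rec.sampling_rate)
        p = regional_paths[s.region]
        vel[s.region] = cop_mean_velocity(p) if p.points.shape[0] >= 2 else float("nan")
    return RolloverMetrics(
        stance_duration=phase.duration,
        pp=pp, tpp=tpp, pti=pti, cop_velocity=vel,
        total_cop_velocity=cop_mean_velocity(total_path),
    )


def _fields(m: RolloverMetrics) -> np.ndarray:
    vals = [m.stance_duration, m.total_cop_velocity]
    for region in REGIONS:
        vals += [m.pp[region], m.tpp[region], m.pti[region], m.cop_velocity[region]]
    return np.array(vals)


def _unfields(vals: np.ndarray) -> RolloverMetrics:
    pp, tpp, pti, vel = {}, {}, {}, {}
    for i, region in enumerate(REGIONS):
        pp[region], tpp[region], pti[region], vel[region] = vals[2 + 4 * i: 6 + 4 * i]
    return RolloverMetrics(stance_duration=float(vals[0]), pp=pp, tpp=tpp,
                           pti=pti, cop_velocity=vel,
                           total_cop_velocity=float(vals[1]))


def aggregate_steps(metrics: list[RolloverMetrics]) -> SubjectAggregate:
    """Arithmetic mean and sample SD (ddof=1) per field across steps.

    A single step yields SD 0 by convention.  Regional COP velocities that
    are NaN in some steps (inactive regions) are averaged over the steps
    where they are defined.
    """
    if not metrics:
        raise ValueError("need at least one step")
    arr = np.vstack([_fields(m) for m in metrics])
    mean = np.nanmean(arr, axis=0)
    if arr.shape[0] > 1:
        sd = np.nanstd(arr, axis=0, ddof=1)
    else:
        sd = np.zeros(arr.shape[1])
    return SubjectAggregate(n_steps=len(metrics), mean=_unfields(mean),
                            sd=_unfields(sd))


def metrics_to_tidy(metrics: list[RolloverMetrics], subject: str = "",
                    side: str = "") -> pd.DataFrame:
    """Tidy export: one row per subject × side × step × region × variable."""
    rows = []
    for step, m in enumerate(metrics):
        for region in REGIONS:
            for var, val in (("pp", m.pp[region]), ("tpp", m.tpp[region]),
                             ("pti", m.pti[region]),
                             ("cop_velocity", m.cop_velocity[region])):
                rows.append((subject, side, step, region, var, val))
        rows.append((subject, side, step, "total", "cop_velocity",
                     m.total_cop_velocity))
        rows.append((subject, side, step, "total", "stance_duration",
                     m.stance_duration))
    return pd.DataFrame(rows, columns=["subject", "side", "step", "region",
                                       "variable", "value"])
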