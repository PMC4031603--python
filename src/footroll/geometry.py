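"""Stance-phase detection, step selection, and anatomical region masks.

The six regions used throughout plantar-pressure work — heel, midfoot,
medial forefoot, lateral forefoot, hallux, toes — are defined on the
footprint by percentage bands of foot length and width:

* rearfoot (heel): first 27 % of foot length,
* midfoot: next 28 % (27–55 %),
* forefoot proper: 55–80 % of length, split across width into a medial
  55 % and a lateral 45 % share,
* toe band: final 20 % of length, split into hallux (medial 33 % of
  width) and toes (lateral 67 %).

Foot length runs along the principal axis of the loaded-sensor cloud,
oriented heel→toe from the loading order, so masks do not depend on how
the grid happens to be aligned with its coordinate axes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .pressure_io import PressureRecording

__all__ = [
    "REGIONS",
    "StancePhase",
    "RegionMaskSet",
    "InsufficientStepsError",
    "EmptyFootprintError",
    "detect_stance_phases",
    "select_analysis_steps",
    "build_region_masks",
]

#: Canonical region order used in outputs.
REGIONS = ("heel", "midfoot", "medial_forefoot", "lateral_forefoot",
           "hallux", "toes")

#: Length-band boundaries as fractions of foot length (heel at 0).
LENGTH_BANDS = (0.27, 0.55, 0.80)

#: Medial share of forefoot width; medial (hallux) share of toe-band width.
FOREFOOT_MEDIAL_FRACTION = 0.55
TOEBAND_MEDIAL_FRACTION = 0.33


class InsufficientStepsError(ValueError):
    """Fewer valid steps available than the analysis requires."""


class EmptyFootprintError(ValueError):
    """No sensor carries load during the stance phase."""


@dataclass(frozen=True)
class StancePhase:
    """Half-open frame window [start_frame, end_frame) of one ground contact."""

    start_frame: int
    end_frame: int
    sampling_rate: float

    def __post_init__(self):
        if self.end_frame <= self.start_frame:
            raise ValueError("end_frame must exceed start_frame")

    @property
    def n_frames(self) -> int:
        return self.end_frame - self.start_frame

    @property
    def duration(self) -> float:
        """Stance duration in s."""
        return self.n_frames / self.sampling_rate


@dataclass(frozen=True)
class RegionMaskSet:
    """Assignment of footprint sensors to the six anatomical regions.

    ``labels`` holds one region name per grid sensor, or ``""`` for
    sensors outside the footprint.  ``axis`` is the posterior→anterior
    unit vector of the foot's long axis in grid coordinates.
    """

    labels: np.ndarray  # (n_sensors,) unicode
    foot_length: float  # m
    foot_width: float   # m
    axis: np.ndarray    # (2,) unit vector, heel -> toe
    side: str

    def sensors(self, region: str) -> np.ndarray:
        """Indices (into the grid's sensor order) of *region*'s sensors."""
        return np.flatnonzero(self.labels == region)

    @property
    def footprint(self) -> np.ndarray:
        return np.flatnonzero(self.labels != "")

    def to_frame(self, grid):
        """Mask as a pandas DataFrame (sensor_id, region) for CSV export."""
        import pandas as pd

        return pd.DataFrame({"sensor_id": grid.sensor_ids, "region": self.labels})


def detect_stance_phases(rec: PressureRecording,
                         threshold_fraction: float = 0.05,
                         min_duration: float = 0.2) -> list[StancePhase]:
    """Find ground-contact windows from the total force curve.

    A stance phase is a maximal run of frames whose summed pressure·area
    force exceeds ``threshold_fraction`` of the trial's maximum force and
    which lasts at least ``min_duration`` s (default 0.2 s, rejecting
    spurious blips).  Phases are returned in temporal order and are
    disjoint by construction.
    """
    if not 0 < threshold_fraction < 1:
        raise ValueError("threshold_fraction must lie in (0, 1)")
    force = rec.force()
    if force.size == 0 or force.max() <= 0:
        return []
    above = force > threshold_fraction * force.max()
    # run-length encode the boolean mask
    padded = np.diff(np.concatenate([[0], above.astype(int), [0]]))
    starts = np.flatnonzero(padded == 1)
    ends = np.flatnonzero(padded == -1)
    min_frames = int(np.ceil(min_duration * rec.sampling_rate))
    return [
        StancePhase(int(s), int(e), rec.sampling_rate)
        for s, e in zip(starts, ends)
        if e - s >= min_frames
    ]


def select_analysis_steps(phases_per_trial: list[list[StancePhase]],
                          n_required: int = 25) -> list[StancePhase]:
    """Pick the *n_required* most central steps across trials.

    The first and last step of every trial are discarded (acceleration and
    deceleration strides are not representative of steady gait); remaining
    steps are ranked by how close they sit to their trial's middle and the
    most central ``n_required`` are returned in temporal order.

    Raises :class:`InsufficientStepsError` — listing per-trial step counts
    — if the trials cannot supply enough middle steps.
    """
    if n_required < 1:
        raise ValueError("n_required must be >= 1")
    candidates = []  # (centrality, trial_idx, step_idx, phase)
    for t, phases in enumerate(phases_per_trial):
        n = len(phases)
        if n < 3:
            continue  # no middle steps to take
        centre = (n - 1) / 2
        for i in range(1, n - 1):
            candidates.append((abs(i - centre), t, i, phases[i]))
    if len(candidates) < n_required:
        counts = [len(p) for p in phases_per_trial]
        raise InsufficientStepsError(
            f"need {n_required} middle steps but only {len(candidates)} "
            f"available (steps per trial: {counts})"
        )
    candidates.sort(key=lambda c: (c[0], c[1], c[2]))
    chosen = sorted(candidates[:n_required], key=lambda c: (c[1], c[2]))
    return [c[3] for c in chosen]


def _footprint_axis(positions, weights, first_load, fallback=(0.0, 1.0)):
    """Heel→toe unit axis of the loaded point cloud.

    Principal axis of the (weight-weighted) sensor positions, oriented so
    the axis coordinate increases with first-load time (the heel loads
    before the toes).  If loading order carries no signal (e.g. every
    sensor loads in the same frame) the orientation falls back to the
    grid's declared posterior→anterior +y direction.
    """
    w = weights / weights.sum()
    centre = w @ positions
    centred = positions - centre
    cov = (centred * w[:, None]).T @ centred
    eigvals, eigvecs = np.linalg.eigh(cov)
    u = eigvecs[:, np.argmax(eigvals)]
    s = centred @ u
    t = first_load - first_load.mean()
    orient = float(s @ t)
    if orient != 0.0:
        u = u if orient > 0 else -u
    else:
        fb = np.asarray(fallback, float)
        if float(u @ fb) < 0:
            u = -u
    return u


def build_region_masks(rec: PressureRecording, phase: StancePhase) -> RegionMaskSet:
    """Partition the stance footprint into the six anatomical regions.

    The footprint is the set of sensors with nonzero peak pressure during
    *phase*.  Length bands follow the 27/28/25/20 % scheme; the forefoot
    band is split 55/45 (medial/lateral) and the toe band 33/67
    (hallux/toes) across the width of the respective band's own loaded
    sensors.  A sensor belongs to the band containing its centre; length
    intervals are half-open with the distal-most closed, and width splits
    are closed on the medial side.  Hallux and medial forefoot sit on the
    anatomically medial side, which depends on ``rec.side``.
    """
    window = rec.frames[phase.start_frame:phase.end_frame]
    if window.size == 0:
        raise EmptyFootprintError("stance phase covers no frames")
    peak = window.max(axis=0)
    foot = peak > 0
    if not foot.any():
        raise EmptyFootprintError("no sensor loaded during stance phase")

    positions = rec.grid.positions[foot]
    weights = rec.grid.area[foot]
    loaded = window[:, foot] > 0
    first_load = np.argmax(loaded, axis=0).astype(float)

    u = _footprint_axis(positions, weights, first_load)
    # medial direction: rotate u by 90° CCW gives the left-hand side of the
    # direction of travel, which is medial for a right foot
    v = np.array([-u[1], u[0]])
    medial = v if rec.side == "right" else -v

    s = positions @ u
    s_rel = (s - s.min()) / max(s.max() - s.min(), np.finfo(float).tiny)
    foot_length = float(s.max() - s.min())
    m = positions @ medial
    foot_width = float(m.max() - m.min())

    band = np.searchsorted(np.asarray(LENGTH_BANDS), s_rel, side="right")
    labels_fp = np.empty(positions.shape[0], dtype=object)
    labels_fp[band == 0] = "heel"
    labels_fp[band == 1] = "midfoot"
    for band_idx, med_frac, med_name, lat_name in (
        (2, FOREFOOT_MEDIAL_FRACTION, "medial_forefoot", "lateral_forefoot"),
        (3, TOEBAND_MEDIAL_FRACTION, "hallux", "toes"),
    ):
        in_band = band == band_idx
        if not in_band.any():
            continue
        mb = m[in_band]
        split = mb.max() - med_frac * (mb.max() - mb.min())
        sub = np.where(mb >= split, med_name, lat_name)
        labels_fp[in_band] = sub

    labels = np.full(rec.grid.n_sensors, "", dtype=object)
    labels[np.flatnonzero(foot)] = labels_fp
    return RegionMaskSet(
        labels=labels.astype(str),
        foot_length=foot_length,
        foot_width=foot_width,
        axis=u,
        side=rec.side,
    )
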