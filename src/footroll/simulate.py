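"""Synthetic gait data with closed-form ground truth.

Three generators produce every input the analysis pipeline consumes:

* barefoot stance-phase **rollover recordings** on a sensor grid — each
  anatomical region carries a trapezoidal pressure pulse (raised-cosine
  ramps, flat plateau) riding on a small constant contact pressure, so
  peak pressure, time-to-peak and the pressure–time integral all have
  exact closed forms;
* **gait mechanics** — smooth parametric marker trajectories and ground
  reaction forces for which the net sagittal ankle moment is available in
  closed form (analytic derivatives instead of finite differences);
* two-arm repeated-measures **trial tables** with a shared-intercept
  correlation structure, prescribed group×time effects in SD units, and
  MCAR missingness.

Every generator is a pure function of (scenario, seed).  Default
scenarios emulate barefoot walking at self-selected cadence within
96–116 steps/min, heel-to-toe loading progression, and a 29/26 two-arm
trial; pulse timing and amplitude defaults are placed at the magnitudes
typical for adults with diabetic polyneuropathy (heel peak pressure
≈ 300 kPa peaking near 18 % of stance, forefoot peaks near 80 %, …).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .dynamics import (DEMPSTER, GRAVITY, AnkleSummary, AnthropometricModel,
                       GaitMechanics, extract_ankle_outcomes)
from .geometry import (FOREFOOT_MEDIAL_FRACTION, LENGTH_BANDS, REGIONS,
                       TOEBAND_MEDIAL_FRACTION, StancePhase)
from .pressure_io import PressureRecording, SensorGrid
from .stats import TrialTable

__all__ = [
    "RegionPulse",
    "RolloverScenario",
    "GroundTruthRollover",
    "classify_grid_regions",
    "generate_rollover_recording",
    "GaitProfile",
    "GroundTruthGait",
    "generate_gait_mechanics",
    "VariableSpec",
    "TrialScenario",
    "GroundTruthTrial",
    "generate_trial_dataset",
]


# ---------------------------------------------------------------------------
# rollover pressure recordings

@dataclass(frozen=True)
class RegionPulse:
    """Trapezoidal pressure pulse for one region, in % of stance.

    Rises with a raised-cosine ramp from ``onset`` over ``rise`` %, holds
    the plateau ``amplitude`` (kPa) until ``end − fall``, and decays over
    the final ``fall`` %.  Closed forms: PP = amplitude (+ contact
    pressure), TPP = onset + rise, PTI = amplitude · (end − onset −
    (rise + fall)/2) / 100 · stance duration.
    """

    amplitude: float  # kPa above the contact pedestal
    onset: float      # % stance
    rise: float       # % stance
    end: float        # % stance
    fall: float       # % stance

    def __post_init__(self):
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if not (0 <= self.onset and self.end <= 100):
            raise ValueError("pulse must lie within [0, 100] % of stance")
        if self.rise <= 0 or self.fall <= 0:
            raise ValueError("rise and fall must be > 0")
        if self.onset + self.rise > self.end - self.fall - 2:
            raise ValueError("pulse needs a plateau of at least 2 % stance")

    @property
    def peak_time(self) -> float:
        """% of stance at which the plateau (the maximum) is first reached."""
        return self.onset + self.rise

    def evaluate(self, tau: np.ndarray) -> np.ndarray:
        """Pulse value at ``tau`` (% of stance)."""
        tau = np.asarray(tau, float)
        out = np.zeros_like(tau)
        up = (tau >= self.onset) & (tau < self.onset + self.rise)
        out[up] = np.sin(np.pi * (tau[up] - self.onset) / (2 * self.rise)) ** 2
        flat = (tau >= self.onset + self.rise) & (tau <= self.end - self.fall)
        out[flat] = 1.0
        down = (tau > self.end - self.fall) & (tau <= self.end)
        out[down] = np.sin(np.pi * (self.end - tau[down]) / (2 * self.fall)) ** 2
        return self.amplitude * out

    def integral_pct(self) -> float:
        """Exact integral over stance in kPa · (% stance)."""
        return self.amplitude * (self.end - self.onset - (self.rise + self.fall) / 2)


#: Default pulses: heel-to-toe progression with peak pressures and peak
#: times at magnitudes typical for a neuropathic cohort walking barefoot.
DEFAULT_PULSES: dict[str, RegionPulse] = {
    "heel": RegionPulse(300.0, 0.0, 18.0, 55.0, 20.0),
    "midfoot": RegionPulse(110.0, 8.0, 44.0, 88.0, 18.0),
    "medial_forefoot": RegionPulse(345.0, 25.0, 57.0, 100.0, 14.0),
    "lateral_forefoot": RegionPulse(305.0, 22.0, 59.0, 99.0, 14.0),
    "hallux": RegionPulse(200.0, 50.0, 35.0, 100.0, 8.0),
    "toes": RegionPulse(180.0, 48.0, 35.0, 99.0, 10.0),
}


@dataclass(frozen=True)
class RolloverScenario:
    """Parameters of one synthetic barefoot stance.

    ``contact_pressure`` is a small constant pressure every footprint
    sensor carries throughout stance (sock/insole contact); it makes the
    contact force visible to threshold-based stance detection from the
    first frame and simply adds ``contact_pressure × stance_duration`` to
    every regional PTI and ``contact_pressure`` to every PP.
    """

    pulses: dict[str, RegionPulse] = field(
        default_factory=lambda: dict(DEFAULT_PULSES))
    stance_duration: float = 0.65   # s
    cadence: float = 105.0          # steps/min
    contact_pressure: float = 15.0  # kPa
    noise_sd: float = 0.0           # kPa additive sensor noise
    sampling_rate: float = 100.0    # Hz
    side: str = "left"
    pad_frames: int = 10            # zero frames before/after stance

    def __post_init__(self):
        missing = set(REGIONS) - set(self.pulses)
        if missing:
            raise ValueError(f"pulses missing for regions {sorted(missing)}")
        if self.stance_duration <= 0 or self.sampling_rate <= 0:
            raise ValueError("durations and rates must be > 0")
        if self.contact_pressure < 0 or self.noise_sd < 0:
            raise ValueError("pressures and noise must be >= 0")

    @classmethod
    def random(cls, seed: int, **overrides) -> "RolloverScenario":
        """Jitter the default pulses (±15 % amplitude, ±3 % stance timing)."""
        rng = np.random.default_rng(seed)
        pulses = {}
        for region, p in DEFAULT_PULSES.items():
            amp = p.amplitude * rng.uniform(0.85, 1.15)
            onset = max(0.0, p.onset + rng.uniform(-3, 3))
            rise = max(5.0, p.rise + rng.uniform(-3, 3))
            end = min(100.0, p.end + rng.uniform(-3, 0))
            fall = max(4.0, min(p.fall + rng.uniform(-2, 2),
                                end - onset - rise - 3))
            pulses[region] = RegionPulse(amp, onset, rise, end, fall)
        duration = rng.uniform(0.60, 0.75)
        return cls(pulses=pulses, stance_duration=duration,
                   cadence=rng.uniform(96, 116), **overrides)


@dataclass(frozen=True)
class GroundTruthRollover:
    """Analytic per-region metrics implied by a scenario's pulse formulas."""

    pp: dict[str, float]    # kPa
    tpp: dict[str, float]   # % stance
    pti: dict[str, float]   # kPa·s
    stance_duration: float  # s
    stance: StancePhase     # frame window within the padded recording
    region_of_sensor: np.ndarray  # label per grid sensor


def classify_grid_regions(grid: SensorGrid, side: str) -> np.ndarray:
    """Assign every grid sensor to a region by the percentage scheme.

    Direct per-sensor classification on an axis-aligned grid (y posterior
    →anterior, heel at low y): length bands 27/28/25/20 %, forefoot width
    split 55/45 medial/lateral, toe-band width 33/67 hallux/toes, medial
    side chosen from ``side``.  Used by the generator to place pulses —
    and usable as an independent check of mask construction.
    """
    y = grid.y
    s_rel = (y - y.min()) / (y.max() - y.min())
    band = np.searchsorted(np.asarray(LENGTH_BANDS), s_rel, side="right")
    # medial coordinate: +x is medial for a left foot, -x for a right foot
    m = grid.x if side == "left" else -grid.x
    labels = np.empty(grid.n_sensors, dtype=object)
    labels[band == 0] = "heel"
    labels[band == 1] = "midfoot"
    for bi, frac, med, lat in ((2, FOREFOOT_MEDIAL_FRACTION,
                                "medial_forefoot", "lateral_forefoot"),
                               (3, TOEBAND_MEDIAL_FRACTION, "hallux", "toes")):
        sel = band == bi
        if sel.any():
            mb = m[sel]
            split = mb.max() - frac * (mb.max() - mb.min())
            labels[sel] = np.where(mb >= split, med, lat)
    return labels.astype(str)


def generate_rollover_recording(scenario: RolloverScenario,
                                grid: SensorGrid | None = None,
                                seed: int = 0
                                ) -> tuple[PressureRecording, GroundTruthRollover]:
    """One synthetic stance on *grid* plus its analytic ground truth.

    Every sensor of a region follows the region's pulse scaled by a
    spatial taper in (0.6, 1]; the sensor nearest the region centroid
    carries the unscaled pulse, so the per-frame regional maximum equals
    the pulse exactly and PP/TPP/PTI have the stated closed forms (up to
    frame quantisation of TPP).  Additive Gaussian noise (``noise_sd``)
    is clipped at zero pressure.
    """
    if grid is None:
        grid = SensorGrid.rectangular()
    rng = np.random.default_rng(seed)
    labels = classify_grid_regions(grid, scenario.side)
    for region in REGIONS:
        if not (labels == region).any():
            raise ValueError(f"grid has no sensors in region {region!r}")

    n_stance = int(round(scenario.stance_duration * scenario.sampling_rate)) + 1
    tau = 100.0 * np.arange(n_stance) / (n_stance - 1)
    stance_frames = np.zeros((n_stance, grid.n_sensors))
    positions = grid.positions
    for region in REGIONS:
        idx = np.flatnonzero(labels == region)
        centroid = positions[idx].mean(axis=0)
        dist = np.linalg.norm(positions[idx] - centroid, axis=1)
        taper = np.where(dist.max() > 0, 1.0 - 0.4 * dist / max(dist.max(), 1e-12),
                         1.0)
        taper[np.argmin(dist)] = 1.0
        pulse = scenario.pulses[region].evaluate(tau)
        stance_frames[:, idx] = pulse[:, None] * taper[None, :]
    stance_frames += scenario.contact_pressure
    if scenario.noise_sd > 0:
        stance_frames = np.clip(
            stance_frames + rng.normal(0, scenario.noise_sd, stance_frames.shape),
            0, None)

    pad = np.zeros((scenario.pad_frames, grid.n_sensors))
    frames = np.vstack([pad, stance_frames, pad])
    rec = PressureRecording(grid=grid, sampling_rate=scenario.sampling_rate,
                            frames=frames, side=scenario.side,
                            cadence=scenario.cadence)

    T = scenario.stance_duration
    base = scenario.contact_pressure
    truth = GroundTruthRollover(
        pp={r: scenario.pulses[r].amplitude + base for r in REGIONS},
        tpp={r: scenario.pulses[r].peak_time for r in REGIONS},
        pti={r: scenario.pulses[r].integral_pct() / 100.0 * T + base * T
             for r in REGIONS},
        stance_duration=T,
        stance=StancePhase(scenario.pad_frames, scenario.pad_frames + n_stance,
                           scenario.sampling_rate),
        region_of_sensor=labels,
    )
    return rec, truth


# ---------------------------------------------------------------------------
# gait mechanics with closed-form ankle moment

def _lobe(tau, c, w, d=0):
    """Raised-cosine lobe cos²(π(τ−c)/w) on |τ−c| < w/2, or its τ-derivatives."""
    tau = np.asarray(tau, float)
    x = (tau - c) / w
    inside = np.abs(x) < 0.5
    out = np.zeros_like(tau)
    if d == 0:
        out[inside] = np.cos(np.pi * x[inside]) ** 2
    elif d == 1:
        out[inside] = -(np.pi / w) * np.sin(2 * np.pi * x[inside])
    elif d == 2:
        out[inside] = -2 * (np.pi / w) ** 2 * np.cos(2 * np.pi * x[inside])
    else:
        raise ValueError("d must be 0, 1 or 2")
    return out


def _smoothstep(u, d=0):
    u = np.clip(np.asarray(u, float), 0.0, 1.0)
    if d == 0:
        return u * u * (3 - 2 * u)
    if d == 1:
        return 6 * u * (1 - u)
    return 6 - 12 * u


@dataclass(frozen=True)
class GaitProfile:
    """Parametric stance-phase gait: GRF, COP progression, segment motion.

    The vertical force is a sum of three raised-cosine lobes (loading and
    push-off humps plus a midstance fill), the anteroposterior force a
    braking and a propulsive lobe, the plate COP a smooth monotone
    heel→toe progression, the foot flat until ``heel_rise_at`` and then
    rotating about the planted toe, and the ankle angle a prescribed sum
    of lobes (heel-strike plantarflexion, midstance dorsiflexion peak,
    push-off plantarflexion).  Everything is analytically differentiable,
    which is what makes the closed-form moment possible.  Amplitudes are
    in body-weight multiples; angles in degrees; times in stance
    fractions.
    """

    stance_duration: float = 0.65
    sampling_rate: float = 100.0
    pad_duration: float = 0.15        # zero-GRF lead-in/out, s
    foot_length: float = 0.26         # m, heel→toe
    ankle_fraction: float = 0.22      # ankle along heel→toe axis
    ankle_height: float = 0.08        # m above the foot axis
    shank_length: float = 0.43
    thigh_length: float = 0.44
    fz_lobes: tuple = ((1.05, 0.28, 0.56), (0.55, 0.50, 0.50),
                       (1.05, 0.74, 0.52))  # (amp·BW, centre, width)
    fy_lobes: tuple = ((-0.12, 0.18, 0.36), (0.16, 0.82, 0.36))
    cop_start: float = 0.14           # fraction of foot length
    cop_end: float = 0.87
    heel_rise_at: float = 0.60        # stance fraction
    heel_rise_angle: float = 32.0     # degrees of foot rotation at toe-off
    ankle_angle_lobes: tuple = ((-9.0, 0.0, 1.0), (13.0, 0.62, 0.8),
                                (-9.0, 1.0, 1.0))  # (deg, centre, width)
    marker_noise_sd: float = 0.0      # m
    grf_noise_sd: float = 0.0         # N

    @classmethod
    def quasi_static(cls, fz: float = 700.0, cop_offset: float = 0.12,
                     **overrides) -> "GaitProfile":
        """Motionless flat foot under constant vertical load.

        The COP sits ``cop_offset`` m anterior to the ankle — the static
        lever-arm configuration whose moment is ``cop_offset · fz`` plus
        the foot-weight term.
        """
        kw = dict(
            fz_lobes=((fz, None, None),),  # sentinel: constant force
            fy_lobes=(),
            heel_rise_angle=0.0,
            ankle_angle_lobes=(),
            cop_start=None, cop_end=None,
        )
        kw.update(overrides)
        prof = cls(**kw)
        object.__setattr__(prof, "_static_fz", fz)
        object.__setattr__(prof, "_static_cop_offset", cop_offset)
        return prof

    @classmethod
    def at_rest(cls, **overrides) -> "GaitProfile":
        """Zero GRF, zero motion: the moment is the foot's gravity term only."""
        kw = dict(fz_lobes=(), fy_lobes=(), heel_rise_angle=0.0,
                  ankle_angle_lobes=())
        kw.update(overrides)
        return cls(**kw)

    @property
    def is_static(self) -> bool:
        return hasattr(self, "_static_fz")


@dataclass(frozen=True)
class GroundTruthGait:
    """Analytic ankle series and summary for a generated trial."""

    summary: AnkleSummary
    moment: np.ndarray        # %BW·h per frame (NaN outside stance)
    angle: np.ndarray         # degrees per frame
    stance: StancePhase


def _foot_theta(tau, profile, d=0):
    """Foot-axis angle (rad) and derivatives w.r.t. stance fraction τ."""
    tr = profile.heel_rise_at
    u = (np.asarray(tau, float) - tr) / (1 - tr)
    amp = -math.radians(profile.heel_rise_angle)
    s = _smoothstep(u, d)
    if d > 0:
        s = np.where((u > 0) & (u < 1), s, 0.0) / (1 - tr) ** d
    return amp * s


def generate_gait_mechanics(profile: GaitProfile | None = None,
                            body_mass: float = 75.0, height: float = 1.68,
                            seed: int = 0,
                            model: AnthropometricModel = DEMPSTER
                            ) -> tuple[GaitMechanics, GroundTruthGait]:
    """Marker + GRF streams and the analytic ankle ground truth.

    The net ankle moment is evaluated from the same Newton–Euler balance
    the pipeline uses but with *analytic* velocities and accelerations of
    the prescribed motion, giving a closed-form reference series that a
    finite-difference pipeline must reproduce.  The returned summary
    (ROM, end-propulsion angle, windowed moment peaks) is extracted from
    the analytic series over the true stance window.
    """
    if profile is None:
        profile = GaitProfile()
    rng = np.random.default_rng(seed)
    fs = profile.sampling_rate
    T = profile.stance_duration
    n_st = int(round(T * fs)) + 1
    n_pad = int(round(profile.pad_duration * fs))
    tau = np.arange(n_st) / (n_st - 1)
    bw = body_mass * GRAVITY
    L = profile.foot_length

    # --- forces ------------------------------------------------------------
    if profile.is_static:
        fz = np.full(n_st, profile._static_fz)
        fy = np.zeros(n_st)
    else:
        fz = bw * sum(a * _lobe(tau, c, w) for a, c, w in profile.fz_lobes) \
            if profile.fz_lobes else np.zeros(n_st)
        fy = bw * sum(a * _lobe(tau, c, w) for a, c, w in profile.fy_lobes) \
            if profile.fy_lobes else np.zeros(n_st)

    # --- foot motion (toe planted at y = L, heel at origin when flat) ------
    theta = _foot_theta(tau, profile, 0)
    theta_d1 = _foot_theta(tau, profile, 1) / T          # rad/s
    theta_d2 = _foot_theta(tau, profile, 2) / T ** 2     # rad/s²
    e = np.column_stack([np.cos(theta), np.sin(theta)])
    nvec = np.column_stack([-np.sin(theta), np.cos(theta)])
    toe = np.tile([L, 0.0], (n_st, 1))
    heel = toe - L * e
    ankle = heel + profile.ankle_fraction * L * e + profile.ankle_height * nvec
    com = heel + model.foot.com_fraction * L * e
    # a_com = -(1-fc)·L · d²e/dt², with d²e/dt² = θ''·n − θ'²·e
    de2 = theta_d2[:, None] * nvec - (theta_d1 ** 2)[:, None] * e
    a_com = -(1 - model.foot.com_fraction) * L * de2

    # --- COP ----------------------------------------------------------------
    if profile.is_static:
        cop_y = ankle[:, 0] + profile._static_cop_offset
    elif profile.cop_start is None:
        cop_y = ankle[:, 0].copy()
    else:
        frac = profile.cop_start + (profile.cop_end - profile.cop_start) \
            * _smoothstep(tau)
        cop_y = heel[0, 0] + frac * L

    # --- shank / thigh from the prescribed ankle angle ----------------------
    angle_deg = sum(a * _lobe(tau, c, w) for a, c, w in profile.ankle_angle_lobes) \
        if profile.ankle_angle_lobes else np.zeros(n_st)
    theta_shank = np.radians(90.0 + np.degrees(theta) - angle_deg)
    knee = ankle + profile.shank_length * np.column_stack(
        [np.cos(theta_shank), np.sin(theta_shank)])
    theta_thigh = np.radians(90.0 - 8.0 * (tau - 0.5))
    hip = knee + profile.thigh_length * np.column_stack(
        [np.cos(theta_thigh), np.sin(theta_thigh)])

    # --- closed-form ankle moment -------------------------------------------
    m_foot = model.foot.mass_fraction * body_mass
    inertia = m_foot * (model.foot.gyration_fraction * L) ** 2

    def cross(r, f):
        return r[:, 0] * f[:, 1] - r[:, 1] * f[:, 0]

    grf = np.column_stack([fy, fz])
    cop = np.column_stack([cop_y, np.zeros(n_st)])
    f_net = m_foot * a_com - m_foot * np.array([0.0, -GRAVITY]) - grf
    tau_ankle = inertia * theta_d2 - cross(ankle - com, f_net) \
        - cross(cop - com, grf)
    moment_true = -tau_ankle * 100.0 / (body_mass * GRAVITY * height)

    # --- assemble padded streams --------------------------------------------
    def pad(arr):
        first = np.repeat(arr[:1], n_pad, axis=0)
        last = np.repeat(arr[-1:], n_pad, axis=0)
        return np.concatenate([first, arr, last], axis=0)

    markers = {"heel": pad(heel), "toe": pad(toe), "ankle": pad(ankle),
               "knee": pad(knee), "hip": pad(hip)}
    if profile.marker_noise_sd > 0:
        markers = {k: v + rng.normal(0, profile.marker_noise_sd, v.shape)
                   for k, v in markers.items()}
    grf_full = np.vstack([np.zeros((n_pad, 2)), grf, np.zeros((n_pad, 2))])
    if profile.grf_noise_sd > 0:
        grf_full = grf_full + rng.normal(0, profile.grf_noise_sd, grf_full.shape)
    cop_full = pad(cop_y[:, None])[:, 0]

    mech = GaitMechanics(sampling_rate=fs, markers=markers, grf=grf_full,
                         cop_y=cop_full, body_mass=body_mass, height=height)

    # true stance window: frames whose analytic Fz clears the 5 % threshold
    if fz.max() > 0:
        in_stance = np.flatnonzero(fz >= 0.05 * fz.max())
        start, end = n_pad + in_stance[0], n_pad + in_stance[-1] + 1
    else:
        start, end = n_pad, n_pad + n_st
    stance = StancePhase(int(start), int(end), fs)

    nan_pad = np.full(n_pad, np.nan)
    moment_full = np.concatenate([nan_pad, moment_true, nan_pad])
    angle_full = np.concatenate([np.full(n_pad, angle_deg[0]), angle_deg,
                                 np.full(n_pad, angle_deg[-1])])
    summary = extract_ankle_outcomes(angle_full, moment_full, stance)
    truth = GroundTruthGait(summary=summary, moment=moment_full,
                            angle=angle_full, stance=stance)
    return mech, truth


# ---------------------------------------------------------------------------
# two-arm repeated-measures trial tables

@dataclass(frozen=True)
class VariableSpec:
    """One outcome variable's generating parameters.

    ``effect_sd`` is the group×time effect: the intervention arm's
    week-12 mean shifts by this many baseline SDs; if ``reverts`` the
    week-24 mean returns to baseline (the follow-up pattern this kind of
    intervention shows).
    """

    name: str
    baseline_mean: float
    baseline_sd: float
    effect_sd: float = 0.0
    kind: str = "parametric"       # or "nonparametric"
    reverts: bool = True


@dataclass(frozen=True)
class TrialScenario:
    """Two-arm repeated-measures design with prescribed effects.

    Defaults mirror the trial this pipeline targets: 29 control / 26
    intervention subjects, within-subject correlation 0.6 via a shared
    subject intercept, and 15.6 % MCAR missingness applied to
    post-baseline cells (the observed loss-to-follow-up fraction).
    """

    variables: tuple[VariableSpec, ...] = (
        VariableSpec("pp_lateral_forefoot", 316.8, 79.5, 0.8),
    )
    n_control: int = 29
    n_intervention: int = 26
    correlation: float = 0.6
    missing_rate: float = 0.156

    def __post_init__(self):
        if not -1 < self.correlation < 1:
            raise ValueError("correlation must lie in (-1, 1)")
        if not 0 <= self.missing_rate <= 0.2:
            raise ValueError("missing_rate must lie in [0, 0.2]")
        if self.n_control < 2 or self.n_intervention < 2:
            raise ValueError("need at least 2 subjects per arm")


@dataclass(frozen=True)
class GroundTruthTrial:
    """The effects actually injected, per variable."""

    effect_sd: dict[str, float]
    effect_raw: dict[str, float]
    n_missing: int


def generate_trial_dataset(scenario: TrialScenario, seed: int = 0
                           ) -> tuple[TrialTable, GroundTruthTrial]:
    """Draw a trial table from the scenario.

    Each subject gets a shared random intercept with variance ρσ² and
    residuals with variance (1−ρ)σ², so any two timepoints of the same
    subject correlate at ρ.  MCAR missingness is applied to post-baseline
    outcome cells only (baseline was measured before any loss occurred).
    Week-24 rows exist only for the intervention arm.
    """
    rng = np.random.default_rng(seed)
    rows = []
    subj = 0
    for group, n in (("control", scenario.n_control),
                     ("intervention", scenario.n_intervention)):
        tps = TIMEPOINTS_FOR[group]
        for _ in range(n):
            sid = f"S{subj:03d}"
            subj += 1
            intercepts = {v.name: rng.normal(0, math.sqrt(scenario.correlation)
                                             * v.baseline_sd)
                          for v in scenario.variables}
            for tp in tps:
                row = {"subject": sid, "group": group, "timepoint": tp}
                for v in scenario.variables:
                    mu = v.baseline_mean
                    if group == "intervention" and tp == "week12":
                        mu += v.effect_sd * v.baseline_sd
                    elif group == "intervention" and tp == "week24" \
                            and not v.reverts:
                        mu += v.effect_sd * v.baseline_sd
                    eps = rng.normal(0, math.sqrt(1 - scenario.correlation)
                                     * v.baseline_sd)
                    row[v.name] = mu + intercepts[v.name] + eps
                rows.append(row)
    df = pd.DataFrame(rows)

    n_missing = 0
    if scenario.missing_rate > 0:
        post = df["timepoint"] != "baseline"
        for v in scenario.variables:
            mask = post & (rng.random(len(df)) < scenario.missing_rate)
            df.loc[mask, v.name] = np.nan
            n_missing += int(mask.sum())

    table = TrialTable(df, {v.name: v.kind for v in scenario.variables})
    truth = GroundTruthTrial(
        effect_sd={v.name: v.effect_sd for v in scenario.variables},
        effect_raw={v.name: v.effect_sd * v.baseline_sd
                    for v in scenario.variables},
        n_missing=n_missing,
    )
    return table, truth


TIMEPOINTS_FOR = {"control": ("baseline", "week12"),
                  "intervention": ("baseline", "week12", "week24")}
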