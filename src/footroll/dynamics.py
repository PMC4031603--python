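"""Sagittal ankle kinematics and bottom-up inverse dynamics.

The lower limb is modelled as three linked rigid segments (foot, shank,
thigh) in the sagittal plane (y anterior, z vertical).  Marker positions
and force-plate signals sampled at a common rate are low-pass filtered
(zero-phase Butterworth, conventionally 6 Hz for kinematics and 20 Hz for
force), the ankle angle is taken between the shank and foot long axes
(zero at neutral standing, dorsiflexion positive), and the net ankle
moment follows from a Newton–Euler balance on the foot segment: ground
reaction force applied at the plate's centre of pressure, plus the foot's
weight and inertial terms from standard anthropometric tables.  Moments
are reported normalised to body weight × height (%BW·h), plantarflexor
positive, so values are comparable across subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import butter, filtfilt

from .geometry import StancePhase

__all__ = [
    "GRAVITY",
    "SegmentParameters",
    "AnthropometricModel",
    "DEMPSTER",
    "GaitMechanics",
    "AnkleSummary",
    "GeometryError",
    "butterworth_lowpass",
    "filter_mechanics",
    "sagittal_ankle_angle",
    "inverse_dynamics_ankle_moment",
    "extract_ankle_outcomes",
    "write_gait_mechanics",
    "read_gait_mechanics",
]

GRAVITY = 9.81  # m/s²

LANDMARKS = ("heel", "toe", "ankle", "knee", "hip")


class GeometryError(ValueError):
    """Degenerate marker geometry (zero-length segment)."""


@dataclass(frozen=True)
class SegmentParameters:
    """Anthropometric fractions for one segment.

    ``mass_fraction`` of body mass; ``com_fraction`` of segment length
    from the proximal end; ``gyration_fraction`` of segment length (radius
    of gyration about the segment COM).
    """

    mass_fraction: float
    com_fraction: float
    gyration_fraction: float

    def __post_init__(self):
        for v in (self.mass_fraction, self.com_fraction, self.gyration_fraction):
            if not 0 < v < 1:
                raise ValueError("anthropometric fractions must lie in (0, 1)")


@dataclass(frozen=True)
class AnthropometricModel:
    """Mass/COM/inertia fractions for exactly the foot, shank and thigh."""

    foot: SegmentParameters
    shank: SegmentParameters
    thigh: SegmentParameters


#: Classical cadaver-study segment parameters (Dempster's tables) for the
#: three-segment lower-limb model.  The foot COM fraction is measured from
#: the heel along the heel→toe axis.
DEMPSTER = AnthropometricModel(
    foot=SegmentParameters(0.0145, 0.50, 0.475),
    shank=SegmentParameters(0.0465, 0.433, 0.302),
    thigh=SegmentParameters(0.100, 0.433, 0.323),
)


@dataclass(frozen=True)
class GaitMechanics:
    """Synchronised sagittal-plane markers, GRF and subject anthropometry.

    ``markers`` maps landmark names (heel, toe, ankle, knee, hip) to
    (n_frames, 2) arrays of (y, z) positions in m.  ``grf`` is (n_frames,
    2) of (Fy, Fz) in N; ``cop_y`` the plate centre of pressure (m) along
    the walking direction, on the plate surface z = 0.
    """

    sampling_rate: float
    markers: dict[str, np.ndarray]
    grf: np.ndarray
    cop_y: np.ndarray
    body_mass: float
    height: float

    def __post_init__(self):
        if self.body_mass <= 0 or self.height <= 0:
            raise ValueError("body_mass and height must be > 0")
        n = self.grf.shape[0]
        if self.cop_y.shape[0] != n:
            raise ValueError("cop_y and grf must have equal length")
        for name, arr in self.markers.items():
            if arr.shape != (n, 2):
                raise ValueError(f"marker {name!r} not synchronised: "
                                 f"{arr.shape} vs {n} frames")

    @property
    def n_frames(self) -> int:
        return int(self.grf.shape[0])


@dataclass(frozen=True)
class AnkleSummary:
    """The four sagittal ankle outcomes for one stance."""

    rom: float                    # degrees, max-min over stance
    end_propulsion_angle: float   # degrees, at the last stance frame
    extensor_peak: float          # %BW·h, minimum in early stance (<= 0 typically)
    flexor_peak: float            # %BW·h, maximum in late stance


def butterworth_lowpass(signal: np.ndarray, sampling_rate: float,
                        cutoff: float, order: int = 4) -> np.ndarray:
    """Zero-phase low-pass Butterworth filter.

    The requested *order* is the net order: a filter of half that order is
    applied forward and backward (``filtfilt``), doubling the order while
    cancelling phase lag — the dominant convention in gait analysis.
    Works along the first axis for multi-column signals.
    """
    if not 0 < cutoff < sampling_rate / 2:
        raise ValueError(
            f"cutoff {cutoff} Hz must lie in (0, Nyquist={sampling_rate / 2} Hz)"
        )
    if order < 2 or order % 2:
        raise ValueError("order must be an even integer >= 2")
    b, a = butter(order // 2, cutoff, fs=sampling_rate)
    return filtfilt(b, a, np.asarray(signal, float), axis=0)


def filter_mechanics(mech: GaitMechanics, cutoff_force: float = 20.0,
                     cutoff_kinematics: float = 6.0,
                     order: int = 4) -> GaitMechanics:
    """Return a copy with force at 20 Hz and kinematics at 6 Hz (defaults)."""
    markers = {k: butterworth_lowpass(v, mech.sampling_rate, cutoff_kinematics,
                                      order)
               for k, v in mech.markers.items()}
    grf = butterworth_lowpass(mech.grf, mech.sampling_rate, cutoff_force, order)
    cop = butterworth_lowpass(mech.cop_y, mech.sampling_rate, cutoff_force, order)
    return replace(mech, markers=markers, grf=grf, cop_y=cop)


def _axis_angle(a: np.ndarray, b: np.ndarray, what: str) -> np.ndarray:
    """Angle (deg) of the b−a axis in the sagittal plane (0° = +y, CCW +)."""
    d = b - a
    if np.any(np.linalg.norm(d, axis=1) == 0):
        raise GeometryError(f"zero-length {what} segment")
    return np.degrees(np.arctan2(d[:, 1], d[:, 0]))


def sagittal_ankle_angle(mech: GaitMechanics) -> np.ndarray:
    """Per-frame sagittal ankle angle, degrees.

    Angle between the shank (ankle→knee) and foot (heel→toe) long axes,
    re-zeroed to the neutral standing pose (shank vertical over a flat
    foot, axes perpendicular).  Dorsiflexion positive, plantarflexion
    negative.
    """
    theta_foot = _axis_angle(mech.markers["heel"], mech.markers["toe"], "foot")
    theta_shank = _axis_angle(mech.markers["ankle"], mech.markers["knee"], "shank")
    return 90.0 - theta_shank + theta_foot


def inverse_dynamics_ankle_moment(mech: GaitMechanics,
                                  model: AnthropometricModel = DEMPSTER,
                                  stance_threshold: float = 0.05
                                  ) -> np.ndarray:
    """Net sagittal ankle moment by Newton–Euler balance on the foot.

    Per frame the moment about the ankle balances the ground reaction
    force at the plate COP and the foot segment's weight and inertial
    terms (mass, COM and radius of gyration from *model*, segment length
    from the heel/toe markers).  Inputs are expected already filtered.

    Returns the moment in %BW·h (``100·M / (body_mass·g·height)``),
    plantarflexor positive.  Frames whose vertical force falls below
    ``stance_threshold`` × the peak vertical force are not in ground
    contact and are set to NaN.
    """
    heel = mech.markers["heel"]
    toe = mech.markers["toe"]
    ankle = mech.markers["ankle"]
    seg = toe - heel
    lengths = np.linalg.norm(seg, axis=1)
    if np.any(lengths == 0):
        raise GeometryError("zero-length foot segment")
    foot_length = float(lengths.mean())

    m_foot = model.foot.mass_fraction * mech.body_mass
    inertia = m_foot * (model.foot.gyration_fraction * foot_length) ** 2
    com = heel + model.foot.com_fraction * seg

    dt = 1.0 / mech.sampling_rate
    a_com = np.gradient(np.gradient(com, dt, axis=0), dt, axis=0)
    theta = np.unwrap(np.arctan2(seg[:, 1], seg[:, 0]))
    alpha = np.gradient(np.gradient(theta, dt), dt)

    fy, fz = mech.grf[:, 0], mech.grf[:, 1]
    cop = np.column_stack([mech.cop_y, np.zeros_like(mech.cop_y)])

    # CCW-positive torque of the ankle on the foot; 2D cross r_y·F_z − r_z·F_y
    def cross(r, f):
        return r[:, 0] * f[:, 1] - r[:, 1] * f[:, 0]

    grf = np.column_stack([fy, fz])
    f_net = m_foot * a_com - np.array([0.0, -GRAVITY]) * m_foot - grf
    tau_ankle = inertia * alpha - cross(ankle - com, f_net) - cross(cop - com, grf)

    # CCW positive is dorsiflexor for progression along +y; report
    # plantarflexor positive
    moment = -tau_ankle
    norm = 100.0 / (mech.body_mass * GRAVITY * mech.height)
    out = moment * norm
    # no-load frames are not ground contact; with zero GRF throughout
    # (foot held in the air) the series is just the gravity term, valid
    # everywhere, so there is nothing to exclude
    peak_fz = fz.max() if fz.size else 0.0
    if peak_fz > 0:
        out = np.where(fz >= stance_threshold * peak_fz, out, np.nan)
    return out


def extract_ankle_outcomes(angles: np.ndarray, moments: np.ndarray,
                           stance: StancePhase,
                           extensor_window: tuple[float, float] = (5.0, 40.0),
                           flexor_window: tuple[float, float] = (60.0, 95.0)
                           ) -> AnkleSummary:
    """The four ankle outcomes over one stance window.

    ROM = max − min of the angle series over stance; the end-propulsion
    angle is the angle at the final stance frame.  The extensor (dorsi-
    flexor, negative) peak is the moment minimum within 5–40 % of stance
    and the flexor (plantarflexor, positive) peak the maximum within
    60–95 % — windowed versions of the conventional "≈20 %" and "≈80 %"
    events, robust to noise away from those events.
    """
    if stance.n_frames < 10:
        raise ValueError("stance shorter than 10 frames")
    a = np.asarray(angles, float)[stance.start_frame:stance.end_frame]
    m = np.asarray(moments, float)[stance.start_frame:stance.end_frame]
    if a.size < stance.n_frames or m.size < stance.n_frames:
        raise ValueError("series do not cover the stance window")
    n = stance.n_frames
    pct = 100.0 * np.arange(n) / (n - 1)

    ext = m[(pct >= extensor_window[0]) & (pct <= extensor_window[1])]
    flex = m[(pct >= flexor_window[0]) & (pct <= flexor_window[1])]
    return AnkleSummary(
        rom=float(np.nanmax(a) - np.nanmin(a)),
        end_propulsion_angle=float(a[-1]),
        extensor_peak=float(np.nanmin(ext)),
        flexor_peak=float(np.nanmax(flex)),
    )


# ---------------------------------------------------------------------------
# text dialect: one CSV row per frame, subject metadata in '#' header lines

def write_gait_mechanics(mech: GaitMechanics, path) -> str:
    """Write mechanics to CSV (``# key: value`` header, one row per frame)."""
    cols = []
    names = []
    for lm in LANDMARKS:
        arr = mech.markers[lm]
        cols += [arr[:, 0], arr[:, 1]]
        names += [f"{lm}_y", f"{lm}_z"]
    cols += [mech.grf[:, 0], mech.grf[:, 1], mech.cop_y]
    names += ["fy", "fz", "cop_y"]
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"# sampling_rate: {mech.sampling_rate!r}\n")
        fh.write(f"# body_mass: {mech.body_mass!r}\n")
        fh.write(f"# height: {mech.height!r}\n")
        fh.write(",".join(["frame"] + names) + "\n")
        for i in range(mech.n_frames):
            fh.write(",".join([str(i)] + [repr(float(c[i])) for c in cols]) + "\n")
    return str(path)


def read_gait_mechanics(path) -> GaitMechanics:
    """Read mechanics written by :func:`write_gait_mechanics`."""
    meta = {}
    rows = []
    with open(path, "r", encoding="utf-8") as fh:
        header = None
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, val = line[1:].partition(":")
                meta[key.strip()] = float(val)
            elif header is None:
                header = line.split(",")
            else:
                rows.append([float(v) for v in line.split(",")])
    data = np.asarray(rows)
    idx = {name: j for j, name in enumerate(header)}
    markers = {
        lm: np.column_stack([data[:, idx[f"{lm}_y"]], data[:, idx[f"{lm}_z"]]])
        for lm in LANDMARKS
    }
    return GaitMechanics(
        sampling_rate=meta["sampling_rate"],
        markers=markers,
        grf=np.column_stack([data[:, idx["fy"]], data[:, idx["fz"]]]),
        cop_y=data[:, idx["cop_y"]],
        body_mass=meta["body_mass"],
        height=meta["height"],
    )
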