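"""Reading, writing and validating insole pressure-grid recordings.

An in-shoe pressure system samples a grid of capacitive sensors at a fixed
rate (typically 100 Hz for gait work) and reports one pressure value per
sensor per frame, in kPa.  Vendors store these recordings in proprietary
binary formats; this module defines an equivalent self-describing text
format so that recordings round-trip losslessly through plain CSV:

* a ``key: value`` header block (``sampling_rate`` in Hz, ``side``,
  optional ``cadence`` in steps/min),
* a sensor table with one row per sensor (``sensor_id,x,y,area`` — x
  medio-lateral and y posterior→anterior, both in m; area in m²),
* a ``frames:`` marker followed by one CSV row of per-sensor pressures
  (kPa) per frame, in sensor-table order.

Units are fixed (kPa, m, Hz); there is no unit autodetection.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "SensorGrid",
    "PressureRecording",
    "PressureFormatError",
    "read_pressure_recording",
    "write_pressure_recording",
    "validate_recording",
    "CADENCE_RANGE",
    "STANDARD_SAMPLING_RATE",
]

#: Self-selected walking cadence band treated as normal gait (steps/min).
CADENCE_RANGE = (96.0, 116.0)

#: Sampling rate (Hz) insole systems conventionally use for gait.
STANDARD_SAMPLING_RATE = 100.0


class PressureFormatError(ValueError):
    """Raised when a recording file or object violates the format contract."""


@dataclass(frozen=True)
class SensorGrid:
    """Geometry of an insole sensor grid.

    Parameters
    ----------
    sensor_ids : (n,) int array
        Unique sensor identifiers.
    x, y : (n,) float arrays
        Sensor-centre coordinates in m; x medio-lateral, y
        posterior→anterior.
    area : (n,) float array
        Effective sensing area per sensor in m².
    """

    sensor_ids: np.ndarray
    x: np.ndarray
    y: np.ndarray
    area: np.ndarray

    def __post_init__(self):
        ids = np.asarray(self.sensor_ids, dtype=int)
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        area = np.asarray(self.area, dtype=float)
        if not (ids.shape == x.shape == y.shape == area.shape):
            raise PressureFormatError("sensor table columns have unequal lengths")
        if ids.size < 4:
            raise PressureFormatError("a sensor grid needs at least 4 sensors")
        if np.unique(ids).size != ids.size:
            raise PressureFormatError("sensor_ids must be unique")
        if not np.all(area > 0):
            raise PressureFormatError("sensor areas must be > 0")
        object.__setattr__(self, "sensor_ids", ids)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "area", area)

    @property
    def n_sensors(self) -> int:
        return int(self.sensor_ids.size)

    @property
    def positions(self) -> np.ndarray:
        """(n, 2) array of sensor centres, columns (x, y)."""
        return np.column_stack([self.x, self.y])

    @classmethod
    def rectangular(cls, n_cols: int = 10, n_rows: int = 30,
                    pitch: float = 0.01) -> "SensorGrid":
        """Uniform ``n_cols × n_rows`` grid with square sensors of side *pitch* m.

        Columns run medio-laterally (x), rows posterior→anterior (y).
        Convenient for synthetic work; real insoles have irregular layouts,
        which the explicit sensor table accommodates equally well.
        """
        xs, ys = np.meshgrid(np.arange(n_cols) * pitch, np.arange(n_rows) * pitch)
        n = n_cols * n_rows
        return cls(
            sensor_ids=np.arange(n),
            x=xs.ravel(),
            y=ys.ravel(),
            area=np.full(n, pitch * pitch),
        )


@dataclass(frozen=True)
class PressureRecording:
    """One walking trial's insole recording.

    ``frames`` is a (n_frames, n_sensors) array of pressures in kPa,
    columns ordered as ``grid.sensor_ids``.  ``cadence`` (steps/min) is
    optional trial metadata carried through for validation.
    """

    grid: SensorGrid
    sampling_rate: float
    frames: np.ndarray
    side: str
    cadence: float | None = None

    def __post_init__(self):
        frames = np.atleast_2d(np.asarray(self.frames, dtype=float))
        if frames.size == 0:
            frames = frames.reshape(0, self.grid.n_sensors)
        if frames.shape[1] != self.grid.n_sensors:
            raise PressureFormatError(
                f"frames have {frames.shape[1]} columns, grid has "
                f"{self.grid.n_sensors} sensors"
            )
        if np.any(frames < 0):
            raise PressureFormatError("pressures must be >= 0 kPa")
        if not self.sampling_rate > 0:
            raise PressureFormatError("sampling_rate must be > 0")
        if self.side not in ("left", "right"):
            raise PressureFormatError("side must be 'left' or 'right'")
        object.__setattr__(self, "frames", frames)
        object.__setattr__(self, "sampling_rate", float(self.sampling_rate))

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    @property
    def duration(self) -> float:
        """Trial duration in s."""
        return self.n_frames / self.sampling_rate

    def force(self) -> np.ndarray:
        """Total vertical force proxy per frame: Σ pressure·area, in kN."""
        return self.frames @ self.grid.area


def _fmt(v: float) -> str:
    return repr(float(v))


def write_pressure_recording(rec: PressureRecording, path) -> str:
    """Write *rec* to *path* in the documented text dialect.

    Numeric fields are written with ``repr`` (full double precision) so a
    write→read→write cycle is byte-stable.  Returns the path written.
    """
    buf = io.StringIO()
    buf.write("format: footroll-pressure v1\n")
    buf.write(f"sampling_rate: {_fmt(rec.sampling_rate)}\n")
    buf.write(f"side: {rec.side}\n")
    if rec.cadence is not None:
        buf.write(f"cadence: {_fmt(rec.cadence)}\n")
    buf.write("sensors:\n")
    buf.write("sensor_id,x,y,area\n")
    g = rec.grid
    for i in range(g.n_sensors):
        buf.write(f"{g.sensor_ids[i]},{_fmt(g.x[i])},{_fmt(g.y[i])},{_fmt(g.area[i])}\n")
    buf.write("frames:\n")
    for row in rec.frames:
        buf.write(",".join(_fmt(v) for v in row) + "\n")
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(buf.getvalue())
    return str(path)


def read_pressure_recording(path) -> PressureRecording:
    """Read a recording written by :func:`write_pressure_recording`.

    Raises :class:`PressureFormatError` naming the offending line on
    malformed headers, ragged rows or negative pressures.
    """
    with open(path, "r", encoding="utf-8") as fh:
        lines = fh.read().splitlines()

    meta: dict[str, str] = {}
    i = 0
    while i < len(lines) and lines[i].strip() != "sensors:":
        line = lines[i].strip()
        if line:
            if ":" not in line:
                raise PressureFormatError(f"line {i + 1}: expected 'key: value', got {line!r}")
            key, _, val = line.partition(":")
            meta[key.strip()] = val.strip()
        i += 1
    if i == len(lines):
        raise PressureFormatError("missing 'sensors:' section")
    if "sampling_rate" not in meta or "side" not in meta:
        raise PressureFormatError("header must declare sampling_rate and side")
    i += 1  # past 'sensors:'
    if i >= len(lines) or lines[i].strip() != "sensor_id,x,y,area":
        raise PressureFormatError(f"line {i + 1}: expected sensor table header")
    i += 1
    ids, xs, ys, areas = [], [], [], []
    while i < len(lines) and lines[i].strip() != "frames:":
        parts = lines[i].strip().split(",")
        if len(parts) != 4:
            raise PressureFormatError(f"line {i + 1}: sensor row needs 4 fields")
        try:
            ids.append(int(parts[0]))
            xs.append(float(parts[1]))
            ys.append(float(parts[2]))
            areas.append(float(parts[3]))
        except ValueError as exc:
            raise PressureFormatError(f"line {i + 1}: {exc}") from exc
        i += 1
    if i == len(lines):
        raise PressureFormatError("missing 'frames:' section")
    grid = SensorGrid(np.array(ids), np.array(xs), np.array(ys), np.array(areas))
    i += 1
    rows = []
    for j in range(i, len(lines)):
        line = lines[j].strip()
        if not line:
            continue
        parts = line.split(",")
        if len(parts) != grid.n_sensors:
            raise PressureFormatError(
                f"line {j + 1}: frame row has {len(parts)} values, "
                f"expected {grid.n_sensors}"
            )
        try:
            row = [float(v) for v in parts]
        except ValueError as exc:
            raise PressureFormatError(f"line {j + 1}: {exc}") from exc
        if any(v < 0 for v in row):
            raise PressureFormatError(f"line {j + 1}: negative pressure")
        rows.append(row)
    frames = np.array(rows, dtype=float).reshape(len(rows), grid.n_sensors)
    cadence = float(meta["cadence"]) if "cadence" in meta else None
    try:
        rate = float(meta["sampling_rate"])
    except ValueError as exc:
        raise PressureFormatError(f"bad sampling_rate: {meta['sampling_rate']!r}") from exc
    return PressureRecording(grid=grid, sampling_rate=rate, frames=frames,
                             side=meta["side"], cadence=cadence)


def validate_recording(rec: PressureRecording) -> list[str]:
    """Return advisory warnings for a recording; never mutates it.

    Checks the trial metadata against normal-gait acquisition conventions:
    cadence within 96–116 steps/min (when cadence metadata is present) and
    the 100 Hz sampling rate.
    """
    warnings: list[str] = []
    if rec.cadence is not None:
        lo, hi = CADENCE_RANGE
        if not (lo <= rec.cadence <= hi):
            warnings.append(
                f"cadence {rec.cadence:g} steps/min outside normal range "
                f"[{lo:g}, {hi:g}]"
            )
    if rec.sampling_rate != STANDARD_SAMPLING_RATE:
        warnings.append(
            f"sampling rate {rec.sampling_rate:g} Hz differs from the "
            f"conventional {STANDARD_SAMPLING_RATE:g} Hz"
        )
    return warnings
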