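import numpy as np
import pytest

from footroll.pressure_io import PressureRecording, SensorGrid


@pytest.fixture
def grid():
    """Default 10×30 rectangular grid with 1 cm square sensors."""
    return SensorGrid.rectangular(10, 30, 0.01)


@pytest.fixture
def staggered_recording(grid):
    """Fully loaded footprint whose rows load heel-first (low y first).

    The loading order pins the heel end of the long axis, so region masks
    are well defined even after rigid rotations of the grid.
    """
    n_rows, n_cols = 30, 10
    frames = np.zeros((n_rows + 5, grid.n_sensors))
    y_order = np.argsort(grid.y, kind="stable")
    for k in range(n_rows):
        row_sensors = y_order[: (k + 1) * n_cols]
        frames[k:, row_sensors] = 100.0
    return PressureRecording(grid=grid, sampling_rate=100.0, frames=frames,
                             side="left", cadence=105.0)


def pulse_recording(grid, n_on=60, n_pad=20, level=100.0, side="left"):
    """Recording with one rectangular force pulse of ``n_on`` frames."""
    frames = np.zeros((n_pad + n_on + n_pad, grid.n_sensors))
    frames[n_pad:n_pad + n_on, :] = level
    return PressureRecording(grid=grid, sampling_rate=100.0, frames=frames,
                             side=side)
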