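"""Uniform resampling of irregular streams and channel-matrix assembly.

Smartwatch sensors deliver samples at roughly, but not exactly, 100 Hz.  All
downstream processing operates on a uniform grid, so streams are linearly
interpolated per axis onto that grid.  Selected streams are then stacked into
a single samples x (3*S) matrix in a fixed canonical channel order so that the
three axes of one sensor are always contiguous.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from .types import (
    AXES,
    DEVICES,
    SENSORS,
    ChannelMatrix,
    SensorStream,
    Session,
    ValidationError,
)

#: Canonical (device, sensor) order: wrist before ankle; accelerometer,
#: gyroscope, orientation within a device.  Axes are always x, y, z.
CANONICAL_PAIRS: tuple[tuple[str, str], ...] = tuple(
    (d, s) for d in DEVICES for s in SENSORS
)

ALL_SENSORS = CANONICAL_PAIRS
WRIST_SENSORS = tuple(p for p in CANONICAL_PAIRS if p[0] == "wrist")
ANKLE_SENSORS = tuple(p for p in CANONICAL_PAIRS if p[0] == "ankle")

#: Named sensor subsets for experiments on sensor importance.
SENSOR_SUBSETS: dict[str, tuple[tuple[str, str], ...]] = {
    "all": ALL_SENSORS,
    "wrist": WRIST_SENSORS,
    "ankle": ANKLE_SENSORS,
    "wrist_accel": (("wrist", "accelerometer"),),
    "wrist_gyro": (("wrist", "gyroscope"),),
    "wrist_orientation": (("wrist", "orientation"),),
    "wrist_accel_gyro": (("wrist", "accelerometer"), ("wrist", "gyroscope")),
}


def canonical_selection(
    selection: Sequence[tuple[str, str]],
) -> tuple[tuple[str, str], ...]:
    """Sort a (device, sensor) selection into the canonical order."""
    sel = set(map(tuple, selection))
    for pair in sel:
        if pair not in CANONICAL_PAIRS:
            raise ValidationError(f"unknown (device, sensor) pair {pair}")
    return tuple(p for p in CANONICAL_PAIRS if p in sel)


def resample_stream(
    stream: SensorStream,
    rate: float = 100.0,
    grid: Optional[tuple[float, float]] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Resample one stream onto a uniform grid by per-axis linear interpolation.

    Parameters
    ----------
    stream
        The irregular source stream; needs at least two raw samples.
    rate
        Target sampling rate in Hz.
    grid
        ``(t_start, t_end)`` in seconds.  Must lie within the stream's raw
        coverage — no extrapolation is performed.  Defaults to the stream's
        own [first, last] timestamp range.

    Returns
    -------
    times, values
        ``times`` is the uniform grid (``t_start + k/rate`` up to ``t_end``);
        ``values`` has shape ``(len(times), 3)``.
    """
    t = stream.timestamps
    if t.size < 2:
        raise ValidationError(
            f"stream {stream.key}: need at least 2 samples to resample"
        )
    if grid is None:
        grid = (float(t[0]), float(t[-1]))
    t_start, t_end = grid
    if t_start < t[0] - 1e-9 or t_end > t[-1] + 1e-9:
        raise ValidationError(
            f"stream {stream.key}: grid [{t_start}, {t_end}] outside raw "
            f"coverage [{t[0]}, {t[-1]}]"
        )
    n = int(np.floor((t_end - t_start) * rate + 1e-9)) + 1
    times = t_start + np.arange(n) / rate
    values = np.empty((n, 3))
    for axis in range(3):
        values[:, axis] = np.interp(times, t, stream.values[:, axis])
    return times, values


def common_grid(
    session: Session, selection: Sequence[tuple[str, str]]
) -> tuple[float, float]:
    """Largest grid covered by every selected stream (no extrapolation)."""
    sel = canonical_selection(selection)
    starts, ends = [], []
    for device, sensor in sel:
        try:
            s = session.stream(device, sensor)
        except KeyError:
            raise ValidationError(
                f"session {session.participant_id}: missing stream "
                f"({device}, {sensor})"
            ) from None
        starts.append(s.timestamps[0])
        ends.append(s.timestamps[-1])
    return float(max(starts)), float(min(ends))


def assemble_channels(
    session: Session,
    sensor_selection: Sequence[tuple[str, str]],
    grid: Optional[tuple[float, float]] = None,
    rate: float = 100.0,
) -> ChannelMatrix:
    """Resample and stack the selected streams into one channel matrix.

    Channels follow the canonical order (wrist before ankle; accelerometer,
    gyroscope, orientation; axes x, y, z), restricted to the selection, so the
    result does not depend on the order streams appear in the session.  The
    channel count is 3*S for S selected (device, sensor) pairs — 18 when all
    six sensors of both watches are used.
    """
    sel = canonical_selection(sensor_selection)
    if not sel:
        raise ValidationError("empty sensor selection")
    if grid is None:
        grid = common_grid(session, sel)
    columns = []
    order: list[tuple[str, str, str]] = []
    for device, sensor in sel:
        try:
            stream = session.stream(device, sensor)
        except KeyError:
            raise ValidationError(
                f"session {session.participant_id}: missing stream "
                f"({device}, {sensor})"
            ) from None
        _, values = resample_stream(stream, rate=rate, grid=grid)
        columns.append(values)
        order.extend((device, sensor, ax) for ax in AXES)
    data = np.hstack(columns)
    return ChannelMatrix(rate=rate, data=data, channel_order=tuple(order), t0=grid[0])
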