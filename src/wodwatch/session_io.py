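"""On-disk session format: a JSON manifest plus one CSV per (device, sensor).

Layout of a session directory::

    session.json                   # participant, experience, sets
    wrist_accelerometer.csv        # header t,x,y,z ; t in seconds
    wrist_gyroscope.csv
    ...

``read_session`` / ``write_session`` round-trip a :class:`Session` up to
floating-point representation.  A plug-in reader registry lets externally
collected datasets with other layouts be adapted without touching this module.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Callable

import pandas as pd

from .types import (
    DEVICES,
    SENSORS,
    ExerciseSet,
    FormatError,
    SensorStream,
    Session,
)

log = logging.getLogger(__name__)

MANIFEST_NAME = "session.json"

_READERS: dict[str, Callable[[Path], Session]] = {}


def register_session_reader(name: str):
    """Decorator registering an adapter that reads a foreign session layout."""

    def deco(fn: Callable[[Path], Session]):
        _READERS[name] = fn
        return fn

    return deco


def _set_to_dict(s: ExerciseSet) -> dict:
    d = {
        "label": s.label,
        "start_time": s.start_time,
        "end_time": s.end_time,
        "vibration_times": list(s.vibration_times),
    }
    if s.declared_reps is not None:
        d["declared_reps"] = s.declared_reps
    if s.reference_starts is not None:
        d["reference_starts"] = list(s.reference_starts)
    return d


def write_session(session: Session, path: str | Path) -> None:
    """Write a session directory (manifest + one CSV per stream)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    manifest = {
        "participant_id": session.participant_id,
        "experience": session.experience,
        "sets": [_set_to_dict(s) for s in session.sets],
        "streams": [list(s.key) for s in session.streams],
    }
    with open(path / MANIFEST_NAME, "w") as fh:
        json.dump(manifest, fh, indent=1)
    for stream in session.streams:
        df = pd.DataFrame(
            {
                "t": stream.timestamps,
                "x": stream.values[:, 0],
                "y": stream.values[:, 1],
                "z": stream.values[:, 2],
            }
        )
        df.to_csv(path / f"{stream.device}_{stream.sensor}.csv", index=False)


def read_session(path: str | Path, format: str = "native") -> Session:
    """Read a session directory written by :func:`write_session`.

    ``format`` selects a registered adapter for foreign layouts; the default
    reads the native manifest + CSV format.
    """
    path = Path(path)
    if format != "native":
        try:
            return _READERS[format](path)
        except KeyError:
            raise FormatError(f"no session reader registered for {format!r}") from None
    manifest_path = path / MANIFEST_NAME
    if not manifest_path.is_file():
        raise FormatError(f"missing manifest {manifest_path}")
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    sets = [
        ExerciseSet(
            label=d["label"],
            start_time=float(d["start_time"]),
            end_time=float(d["end_time"]),
            vibration_times=d.get("vibration_times", ()),
            declared_reps=d.get("declared_reps"),
            reference_starts=d.get("reference_starts"),
        )
        for d in manifest.get("sets", [])
    ]
    streams = []
    for csv_path in sorted(path.glob("*.csv")):
        parts = csv_path.stem.split("_", 1)
        if len(parts) != 2 or parts[0] not in DEVICES or parts[1] not in SENSORS:
            log.warning("ignoring unrecognized stream file %s", csv_path.name)
            continue
        device, sensor = parts
        df = pd.read_csv(csv_path)
        if list(df.columns) != ["t", "x", "y", "z"]:
            raise FormatError(
                f"{csv_path.name}: expected header t,x,y,z, got {list(df.columns)}"
            )
        streams.append(
            SensorStream(
                device=device,
                sensor=sensor,
                timestamps=df["t"].to_numpy(dtype=float),
                values=df[["x", "y", "z"]].to_numpy(dtype=float),
            )
        )
    return Session(
        participant_id=str(manifest["participant_id"]),
        experience=manifest.get("experience", "unknown"),
        sets=sets,
        streams=streams,
    )


def write_dataset(sessions, root: str | Path) -> list[Path]:
    """Write many sessions, one directory per participant, under ``root``."""
    root = Path(root)
    paths = []
    for i, session in enumerate(sessions):
        p = root / f"{i:03d}_{session.participant_id}"
        write_session(session, p)
        paths.append(p)
    return paths


def read_dataset(root: str | Path) -> list[Session]:
    """Read every session directory under ``root`` (sorted by name)."""
    root = Path(root)
    sessions = []
    for p in sorted(root.iterdir()):
        if p.is_dir() and (p / MANIFEST_NAME).is_file():
            sessions.append(read_session(p))
    if not sessions:
        raise FormatError(f"no session directories under {root}")
    return sessions
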