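"""Reading and writing of trajectory, hop-record and report formats.

All quantities are carried in a fixed unit system: angstrom (positions,
distances), picosecond (times), degree (angles), kcal/mol (energies).
File headers declare these units.

The trajectory format is a multi-frame extended XYZ dialect: the comment
line of each frame carries ``key=value`` metadata (``t=<ps>``,
``state=<S0|S1|S2>`` and optional scalar channels such as ``d1=<deg>``),
and the atom-name column carries a *role label* (``D_ring_N``,
``His278_NE2``, ``WAT0_O``, ...) rather than an element symbol.  Hop
records are plain CSV with an empty ``hop_time_ps`` field denoting a
right-censored trajectory.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "UNITS",
    "ElectronicState",
    "AtomRecord",
    "Frame",
    "Trajectory",
    "HopRecord",
    "TrajectoryFormatError",
    "ValidationError",
    "read_xyz_trajectory",
    "write_xyz_trajectory",
    "read_pdb_frame",
    "read_hop_records",
    "write_hop_records",
    "write_report",
]

#: Unit system used throughout the package.
UNITS = {"length": "angstrom", "time": "ps", "angle": "deg", "energy": "kcal/mol"}


class TrajectoryFormatError(ValueError):
    """Malformed trajectory file (bad counts, times, or labels)."""


class ValidationError(ValueError):
    """Domain-object invariant violated."""


class ElectronicState(str, Enum):
    S0 = "S0"
    S1 = "S1"
    S2 = "S2"


@dataclass(frozen=True)
class AtomRecord:
    """A labeled atom: role name plus Cartesian position in angstrom."""

    label: str
    position: np.ndarray

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,):
            raise ValidationError(f"position of {self.label!r} must be a 3-vector")
        if not np.all(np.isfinite(pos)):
            raise ValidationError(f"non-finite position for atom {self.label!r}")
        object.__setattr__(self, "position", pos)


class Frame:
    """One time point: electronic state plus labeled atomic positions.

    Positions are stored as an ``(n, 3)`` array with a parallel label
    tuple; ``atoms`` materializes :class:`AtomRecord` views on demand.
    ``scalars`` carries auxiliary per-frame channels (e.g. the D1-D3
    dihedrals of the bilin model, which are not resolved atomically).
    """

    __slots__ = ("time", "electronic_state", "labels", "coords", "scalars", "_index")

    def __init__(
        self,
        time: float,
        electronic_state: ElectronicState | str,
        labels: Sequence[str],
        coords: np.ndarray,
        scalars: Mapping[str, float] | None = None,
    ) -> None:
        if time < 0:
            raise ValidationError(f"frame time must be >= 0 ps, got {time}")
        self.time = float(time)
        self.electronic_state = ElectronicState(electronic_state)
        self.labels = tuple(labels)
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.labels), 3):
            raise ValidationError(
                f"coords shape {coords.shape} does not match {len(self.labels)} labels"
            )
        if not np.all(np.isfinite(coords)):
            raise ValidationError("non-finite coordinates in frame")
        if len(set(self.labels)) != len(self.labels):
            raise ValidationError("duplicate atom labels within a frame")
        self.coords = coords
        self.scalars = dict(scalars or {})
        self._index = {lab: i for i, lab in enumerate(self.labels)}

    @property
    def atoms(self) -> list[AtomRecord]:
        return [AtomRecord(lab, self.coords[i]) for i, lab in enumerate(self.labels)]

    def position(self, label: str) -> np.ndarray:
        try:
            return self.coords[self._index[label]]
        except KeyError:
            raise KeyError(f"no atom labeled {label!r} in frame") from None

    def has(self, label: str) -> bool:
        return label in self._index

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (
            f"Frame(t={self.time} ps, state={self.electronic_state.value}, "
            f"n_atoms={len(self.labels)})"
        )


@dataclass
class Trajectory:
    """Time-ordered frames with uniform spacing ``dt`` (ps)."""

    id: str
    frames: list[Frame]
    dt: float

    def __post_init__(self) -> None:
        if len(self.frames) < 2:
            raise ValidationError(f"trajectory {self.id!r} needs >= 2 frames")
        labels0 = self.frames[0].labels
        times = [f.time for f in self.frames]
        for i, f in enumerate(self.frames):
            if f.labels != labels0:
                raise ValidationError(
                    f"trajectory {self.id!r}: frame {i} label set differs from frame 0"
                )
            if i > 0 and times[i] <= times[i - 1]:
                raise ValidationError(
                    f"trajectory {self.id!r}: times not strictly increasing at frame {i}"
                )
        # S2 is only populated before the first surface hop to S0.
        seen_s0 = False
        for i, f in enumerate(self.frames):
            if f.electronic_state is ElectronicState.S0:
                seen_s0 = True
            elif f.electronic_state is ElectronicState.S2 and seen_s0:
                raise ValidationError(
                    f"trajectory {self.id!r}: S2 after the first hop (frame {i})"
                )

    @property
    def times(self) -> np.ndarray:
        return np.array([f.time for f in self.frames])

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def __len__(self) -> int:
        return len(self.frames)


#: Sentinel for censored hop times (encoded as an empty CSV field).
CENSORED = None


@dataclass(frozen=True)
class HopRecord:
    """Per-trajectory S1->S0 hop time with right censoring.

    ``hop_time`` is ``None`` for trajectories still excited at
    ``censor_time``; censored records are by construction non-reactive.
    """

    trajectory_id: str
    hop_time: float | None
    censor_time: float
    reactive: bool

    def __post_init__(self) -> None:
        if self.censored:
            if self.reactive:
                raise ValidationError(
                    f"record {self.trajectory_id!r}: censored records cannot be reactive"
                )
        else:
            if self.hop_time is None or not math.isfinite(self.hop_time):
                raise ValidationError(f"record {self.trajectory_id!r}: bad hop time")
            if self.hop_time > self.censor_time:
                raise ValidationError(
                    f"record {self.trajectory_id!r}: hop_time {self.hop_time} "
                    f"exceeds censor_time {self.censor_time}"
                )

    @property
    def censored(self) -> bool:
        return self.hop_time is None


# ---------------------------------------------------------------------------
# extended XYZ


def _format_frame(frame: Frame) -> str:
    meta = [f"t={frame.time:.6f}", f"state={frame.electronic_state.value}"]
    for key in sorted(frame.scalars):
        meta.append(f"{key}={frame.scalars[key]:.6f}")
    lines = [str(len(frame.labels)), " ".join(meta)]
    for lab, (x, y, z) in zip(frame.labels, frame.coords):
        lines.append(f"{lab} {x:.6f} {y:.6f} {z:.6f}")
    return "\n".join(lines)


def write_xyz_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write a trajectory as multi-frame extended XYZ (deterministic bytes)."""
    text = "\n".join(_format_frame(f) for f in traj.frames) + "\n"
    Path(path).write_text(text)


def read_xyz_trajectory(path: str | Path, traj_id: str | None = None) -> Trajectory:
    """Parse a multi-frame extended XYZ file written by this package.

    ``dt`` is inferred from the first two frame times.  Raises
    :class:`TrajectoryFormatError` naming the offending frame on malformed
    atom counts, non-increasing times, or inconsistent label sets.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    frames: list[Frame] = []
    i = 0
    frame_idx = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n_atoms = int(lines[i].strip())
        except ValueError:
            raise TrajectoryFormatError(
                f"frame {frame_idx}: expected atom count, got {lines[i]!r}"
            ) from None
        if i + 1 + n_atoms >= len(lines) + 1 and i + 1 + n_atoms > len(lines):
            raise TrajectoryFormatError(
                f"frame {frame_idx}: file truncated ({n_atoms} atoms declared)"
            )
        meta: dict[str, str] = {}
        for tok in lines[i + 1].split():
            if "=" not in tok:
                raise TrajectoryFormatError(
                    f"frame {frame_idx}: bad comment token {tok!r}"
                )
            k, v = tok.split("=", 1)
            meta[k] = v
        if "t" not in meta or "state" not in meta:
            raise TrajectoryFormatError(
                f"frame {frame_idx}: comment line must carry t= and state="
            )
        labels: list[str] = []
        coords: list[list[float]] = []
        for j in range(n_atoms):
            row = lines[i + 2 + j].split()
            if len(row) != 4:
                raise TrajectoryFormatError(
                    f"frame {frame_idx}: atom line {j} malformed (atom count mismatch?)"
                )
            labels.append(row[0])
            try:
                coords.append([float(c) for c in row[1:]])
            except ValueError:
                raise TrajectoryFormatError(
                    f"frame {frame_idx}: non-numeric coordinate on atom line {j}"
                ) from None
        scalars = {
            k: float(v) for k, v in meta.items() if k not in ("t", "state")
        }
        try:
            frame = Frame(float(meta["t"]), meta["state"], labels, np.array(coords), scalars)
        except (ValidationError, ValueError) as exc:
            raise TrajectoryFormatError(f"frame {frame_idx}: {exc}") from None
        frames.append(frame)
        i += 2 + n_atoms
        frame_idx += 1
    if len(frames) < 2:
        raise TrajectoryFormatError("trajectory file holds fewer than 2 frames")
    dt = frames[1].time - frames[0].time
    try:
        return Trajectory(traj_id or path.stem, frames, dt)
    except ValidationError as exc:
        raise TrajectoryFormatError(str(exc)) from None


def read_pdb_frame(path: str | Path) -> Frame:
    """Read a single-model minimal PDB (ATOM/HETATM) as a ``t=0, S0`` frame.

    Role labels are reconstructed from the atom fields: CA atoms become
    ``CA<resid>``, water oxygens ``WAT<resid>_O``, and everything else
    ``<Resname><resid>_<atomname>`` (e.g. ``His278_NE2``).
    """
    from biotite.structure.io.pdb import PDBFile

    structure = PDBFile.read(str(path)).get_structure(model=1)
    labels = []
    for name, res, rid in zip(
        structure.atom_name, structure.res_name, structure.res_id
    ):
        if name == "CA":
            labels.append(f"CA{rid}")
        elif res in ("HOH", "WAT", "SOL"):
            labels.append(f"WAT{rid}_{name}")
        else:
            labels.append(f"{res.capitalize()}{rid}_{name}")
    return Frame(0.0, ElectronicState.S0, labels, np.asarray(structure.coord, float))


# ---------------------------------------------------------------------------
# hop records

_HOP_FIELDS = ["trajectory_id", "hop_time_ps", "censor_time_ps", "reactive"]


def write_hop_records(records: Iterable[HopRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_HOP_FIELDS)
        for r in records:
            hop = "" if r.censored else f"{r.hop_time:.6f}"
            writer.writerow(
                [r.trajectory_id, hop, f"{r.censor_time:.6f}", str(r.reactive).lower()]
            )


def read_hop_records(path: str | Path) -> list[HopRecord]:
    """Parse hop-record CSV; empty ``hop_time_ps`` means censored."""
    records: list[HopRecord] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        missing = set(_HOP_FIELDS) - set(reader.fieldnames or [])
        if missing:
            raise TrajectoryFormatError(f"hop CSV missing columns: {sorted(missing)}")
        for i, row in enumerate(reader):
            raw = (row["hop_time_ps"] or "").strip()
            hop = None if raw == "" else float(raw)
            reactive = row["reactive"].strip().lower() in ("true", "1", "yes")
            if hop is None and reactive:
                raise ValidationError(
                    f"hop CSV row {i}: censored record marked reactive"
                )
            records.append(
                HopRecord(
                    trajectory_id=row["trajectory_id"],
                    hop_time=hop,
                    censor_time=float(row["censor_time_ps"]),
                    reactive=reactive,
                )
            )
    return records


# ---------------------------------------------------------------------------
# reports


def _check_finite(obj, path: str, bad: list[str]) -> None:
    if isinstance(obj, Mapping):
        for k, v in obj.items():
            _check_finite(v, f"{path}.{k}" if path else str(k), bad)
    elif isinstance(obj, (list, tuple)):
        for i, v in enumerate(obj):
            _check_finite(v, f"{path}[{i}]", bad)
    elif isinstance(obj, (float, int, np.floating, np.integer)) and not isinstance(
        obj, bool
    ):
        if not math.isfinite(float(obj)):
            bad.append(path)


def _jsonable(obj):
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, pd.DataFrame):
        return {
            "columns": list(map(str, obj.columns)),
            "data": [[_jsonable(v) for v in row] for row in obj.itertuples(index=False)],
        }
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, Enum):
        return obj.value
    return obj


def write_report(results: Mapping[str, object], path: str | Path) -> None:
    """Serialize analysis outputs as deterministic JSON.

    Field order is sorted, so identical inputs yield byte-identical files.
    Non-finite numbers are rejected with an error naming the offending keys.
    """
    payload = _jsonable(results)
    bad: list[str] = []
    _check_finite(payload, "", bad)
    if bad:
        raise ValidationError(f"non-finite values in report: {bad}")
    doc = {"_units": dict(UNITS), "results": payload}
    Path(path).write_text(json.dumps(doc, sort_keys=True, indent=2) + "\n")
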