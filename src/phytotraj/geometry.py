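"""Signed dihedrals, angle unwrapping, bilin stereochemistry, and
hula-twist isomerization detection.

Conventions
-----------
Dihedrals follow the IUPAC sign convention: looking from atom 2 toward
atom 3, a positive angle means the far bond is rotated clockwise relative
to the near bond; values lie in ``(-180, 180]`` degrees.  A rotation
*sense* of a time series is called ``ccw`` when the net unwrapped change
is negative (viewed from the C-ring side of the C-D methine bridge) and
``cw`` when positive.  This viewing convention is the package's own fixed
choice; only its internal consistency is meaningful.

Bilin stereochemistry codes render the three methine-bridge double bonds
(Z/E) followed by the three single bonds (syn/anti): the resting Pfr state
of a bathy phytochrome is ``ZZEssa`` and the Pr photoproduct ``ZZZssa``.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np

__all__ = [
    "DihedralName",
    "DihedralSeries",
    "StereoCode",
    "RotationSense",
    "IsomerizationEvent",
    "DegenerateGeometryError",
    "dihedral",
    "wrap_angle",
    "unwrap_angles",
    "unwrap_series",
    "stereo_code",
    "rotation_sense",
    "detect_isomerization",
    "dihedral_series",
    "DEFAULT_DOUBLE_BONDS",
    "BRIDGE_CHAIN_LABELS",
]


class DegenerateGeometryError(ValueError):
    """Three consecutive dihedral atoms are (numerically) collinear."""


class DihedralName(str, Enum):
    D1 = "D1"
    D2 = "D2"
    D3 = "D3"
    D4 = "D4"
    D5 = "D5"
    D6 = "D6"


#: Default assignment of bridge dihedrals to bond classes (configurable;
#: the graphical definition leaves the mapping open).
DEFAULT_DOUBLE_BONDS: frozenset[str] = frozenset({"D2", "D4", "D6"})

#: Atom chain of the C-D methine-bridge model: consecutive quadruples
#: define D4, D5 and D6.
BRIDGE_CHAIN_LABELS: tuple[str, ...] = (
    "C_ring_Cb",
    "C_ring_Ca",
    "CD_bridge_C",
    "D_ring_Ca",
    "D_ring_Cb",
    "D_ring_Cc",
)


class RotationSense(str, Enum):
    CCW = "ccw"
    CW = "cw"
    NONE = "none"


@dataclass
class DihedralSeries:
    """Unwrapped dihedral time series (degrees, continuous in time)."""

    name: str
    times: np.ndarray
    values: np.ndarray
    bond_class: str = "single"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, float)
        self.values = np.asarray(self.values, float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have equal length")
        if np.any(np.abs(np.diff(self.values)) >= 180.0):
            raise ValueError(
                f"series {self.name}: successive steps >= 180 deg break unwrap validity"
            )

    def wrapped(self) -> np.ndarray:
        return wrap_angle(self.values)


@dataclass(frozen=True)
class StereoCode:
    """Z/E letters for the double bonds, s/a for the singles."""

    doubles: str
    singles: str

    @property
    def rendered(self) -> str:
        return self.doubles + self.singles

    def __str__(self) -> str:
        return self.rendered


@dataclass(frozen=True)
class IsomerizationEvent:
    dihedral: str
    crossing_time: float
    sense: RotationSense
    partner_sense: RotationSense
    hula_twist: bool


# ---------------------------------------------------------------------------
# primitives


def dihedral(p1, p2, p3, p4) -> float:
    """Signed torsion angle of four points, degrees in ``(-180, 180]``.

    Invariant under rigid rotation/translation; flips sign under mirror
    reflection.  Raises :class:`DegenerateGeometryError` when either bond
    triple is collinear.
    """
    p1, p2, p3, p4 = (np.asarray(p, float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2n = np.linalg.norm(b2)
    if np.linalg.norm(n1) < 1e-10 * max(np.linalg.norm(b1) * b2n, 1e-300) or (
        np.linalg.norm(n2) < 1e-10 * max(np.linalg.norm(b3) * b2n, 1e-300)
    ):
        raise DegenerateGeometryError("collinear atoms leave the torsion undefined")
    # atan2 form: numerically stable for all quadrants
    y = np.dot(np.cross(n1, n2), b2) / b2n
    x = np.dot(n1, n2)
    ang = np.degrees(np.arctan2(y, x))
    return 180.0 if ang == -180.0 else float(ang)


def wrap_angle(a):
    """Wrap degrees into ``(-180, 180]``."""
    a = np.asarray(a, float)
    w = (a + 180.0) % 360.0 - 180.0
    w = np.where(w == -180.0, 180.0, w)
    return float(w) if w.ndim == 0 else w


def unwrap_angles(raw: Sequence[float]) -> np.ndarray:
    """Add +-360k multiples so successive differences are minimal.

    The first value is preserved.  Assumes the true per-step change is
    below 180 degrees (a precondition on frame spacing).
    """
    return np.unwrap(np.asarray(raw, float), period=360.0)


def unwrap_series(
    times: Sequence[float],
    raw: Sequence[float],
    name: str = "D6",
    bond_class: str | None = None,
) -> DihedralSeries:
    if bond_class is None:
        bond_class = "double" if name in DEFAULT_DOUBLE_BONDS else "single"
    return DihedralSeries(name, np.asarray(times, float), unwrap_angles(raw), bond_class)


def stereo_code(
    d: Sequence[float],
    double_bonds: frozenset[str] | set[str] = DEFAULT_DOUBLE_BONDS,
) -> StereoCode:
    """Assign the six-letter stereochemistry code from D1..D6 (degrees).

    Double bonds map to ``Z`` when the wrapped magnitude is below 90 deg,
    else ``E``; single bonds map to ``s``/``a`` likewise.  A value at
    exactly +-90 ties to the anti/E side.  Depends only on wrapped values.
    """
    d = np.asarray(d, float)
    if d.shape != (6,):
        raise ValueError("stereo_code expects six dihedral values D1..D6")
    mag = np.abs(wrap_angle(d))
    letters = {}
    for i, name in enumerate(("D1", "D2", "D3", "D4", "D5", "D6")):
        if name in double_bonds:
            letters[name] = "Z" if mag[i] < 90.0 else "E"
        else:
            letters[name] = "s" if mag[i] < 90.0 else "a"
    doubles = "".join(letters[n] for n in ("D1", "D2", "D3", "D4", "D5", "D6") if n in double_bonds)
    singles = "".join(letters[n] for n in ("D1", "D2", "D3", "D4", "D5", "D6") if n not in double_bonds)
    return StereoCode(doubles=doubles, singles=singles)


def rotation_sense(
    series: DihedralSeries,
    window: tuple[float, float] | None = None,
    threshold: float = 90.0,
) -> RotationSense:
    """Net rotation sense over a time window of an unwrapped series.

    ``ccw`` when the net change is <= -threshold, ``cw`` when >= +threshold,
    ``none`` otherwise.  Endpoint values are linearly interpolated.
    """
    t, v = series.times, series.values
    if window is None:
        lo, hi = t[0], t[-1]
    else:
        lo, hi = max(window[0], t[0]), min(window[1], t[-1])
    if hi <= lo:
        return RotationSense.NONE
    net = np.interp(hi, t, v) - np.interp(lo, t, v)
    if net <= -threshold:
        return RotationSense.CCW
    if net >= threshold:
        return RotationSense.CW
    return RotationSense.NONE


def _net_sense(net: float) -> RotationSense:
    return RotationSense.CCW if net < 0 else RotationSense.CW


def detect_isomerization(
    d5: DihedralSeries,
    d6: DihedralSeries,
    crossing_threshold: float = 90.0,
    partner_threshold: float = 30.0,
    neighborhood: float = 1.0,
) -> list[IsomerizationEvent]:
    """Detect D6 isomerization events and their hula-twist pairing.

    An event is recorded at each crossing of the unwrapped D6 series
    through the ``+-90 + 180k`` family.  The rotation sense is the sign of
    the D6 change over ``+-neighborhood`` ps around the crossing; the event
    is a hula twist when the paired D5 series rotates with opposite sense
    by at least ``partner_threshold`` degrees over the same window.
    """
    if d5.times.shape != d6.times.shape or not np.allclose(d5.times, d6.times):
        raise ValueError("D5 and D6 series must share the same time base")
    t, v = d6.times, d6.values
    # sector index: which (90 + 180k, 90 + 180(k+1)) band each value is in
    sector = np.floor((v - crossing_threshold) / 180.0)
    events: list[IsomerizationEvent] = []
    for i in np.nonzero(np.diff(sector) != 0)[0]:
        # boundary crossed between frames i and i+1; locate by interpolation
        step = sector[i + 1] - sector[i]
        boundary = crossing_threshold + 180.0 * (
            sector[i] + (1.0 if step > 0 else 0.0)
        )
        frac = (boundary - v[i]) / (v[i + 1] - v[i])
        tc = float(t[i] + frac * (t[i + 1] - t[i]))
        lo, hi = tc - neighborhood, tc + neighborhood
        net6 = np.interp(min(hi, t[-1]), t, v) - np.interp(max(lo, t[0]), t, v)
        net5 = np.interp(min(hi, t[-1]), d5.times, d5.values) - np.interp(
            max(lo, t[0]), d5.times, d5.values
        )
        sense = _net_sense(net6)
        partner = _net_sense(net5) if abs(net5) > 0 else RotationSense.NONE
        hula = (partner != sense) and (abs(net5) >= partner_threshold)
        events.append(
            IsomerizationEvent(
                dihedral=d6.name,
                crossing_time=tc,
                sense=sense,
                partner_sense=partner,
                hula_twist=bool(hula),
            )
        )
    return events


# ---------------------------------------------------------------------------
# trajectory-level extraction


def dihedral_series(traj, chain: Sequence[str] = BRIDGE_CHAIN_LABELS) -> dict[str, DihedralSeries]:
    """Extract D1..D6 series from a trajectory of the bilin bridge model.

    D4, D5, D6 are computed from consecutive quadruples of the six-atom
    bridge chain; D1-D3 are read from the per-frame scalar channels when
    present (the minimal scaffold does not resolve the A-B and B-C bridges
    atomically).
    """
    times = traj.times
    raw = {name: [] for name in ("D4", "D5", "D6")}
    scal = {name: [] for name in ("d1", "d2", "d3")}
    for frame in traj.frames:
        pts = [frame.position(lab) for lab in chain]
        raw["D4"].append(dihedral(*pts[0:4]))
        raw["D5"].append(dihedral(*pts[1:5]))
        raw["D6"].append(dihedral(*pts[2:6]))
        for k in scal:
            if k in frame.scalars:
                scal[k].append(frame.scalars[k])
    out = {
        name: unwrap_series(times, vals, name=name) for name, vals in raw.items()
    }
    for k, vals in scal.items():
        if len(vals) == len(traj.frames):
            out[k.upper()] = unwrap_series(times, vals, name=k.upper())
    return out
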