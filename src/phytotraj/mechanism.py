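"""Hydrogen-bond detection, photoproduct/intermediate classification, and
spine-tilt geometry.

States
------
The relaxation taxonomy distinguishes, after the D6 photoisomerization:

* ``BV_PR`` - D5 and D6 both inside their Pr windows and the D-ring
  carbonyl hydrogen-bonded to His278 or Tyr165;
* ``BV_PR_DPRIME`` - all bridge dihedrals near-planar;
* ``BV_PR_PRIME`` - D6 in the Pr (Z) window but D5 stalled between the
  Pfr and Pr windows;
* ``PFR`` - anything else (including the unreacted resting state).

A Meta-F-like pocket signature is reported as an overlay on top of the
dihedral label: carbonyl-His278 H-bond, Gln190 displaced from its
D-ring-proximal reference, and the Trp440 gate open (far from Gln190).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial import cKDTree

from . import _refs
from .geometry import wrap_angle
from .io import Frame

__all__ = [
    "HBond",
    "HBondCriteria",
    "StateValue",
    "StateLabel",
    "StateWindows",
    "MetaFThresholds",
    "detect_hbonds",
    "water_bridges",
    "classify_photoproduct",
    "metaF_signature",
    "spine_tilt",
]


@dataclass(frozen=True)
class HBond:
    donor_label: str
    acceptor_label: str
    distance: float                 # angstrom
    hydrogen_label: str | None = None
    angle: float | None = None      # D-H...A degrees, when hydrogen modeled
    water_mediated: bool = False
    bridging_water: str | None = None

    def involves(self, *labels: str) -> bool:
        mine = {self.donor_label, self.acceptor_label}
        return all(any(lab.startswith(q) for lab in mine) for q in labels)


@dataclass(frozen=True)
class HBondCriteria:
    """Geometric H-bond definition (standard MD-analysis values)."""

    distance_cutoff: float = 3.5    # donor-acceptor, angstrom
    angle_min: float = 120.0        # D-H...A, applied only when H modeled


#: Label suffixes treated as polar (possible H-bond partners) when no
#: explicit donor/acceptor lists are given.
_POLAR_SUFFIXES = ("_N", "_O", "_OH", "_NE2", "_OD1", "_OD2", "_OG", "_NH")


def _polar_labels(frame: Frame) -> list[str]:
    return [lab for lab in frame.labels if lab.endswith(_POLAR_SUFFIXES)]


def detect_hbonds(
    frame: Frame,
    donors: Sequence[str] | None = None,
    acceptors: Sequence[str] | None = None,
    criteria: HBondCriteria = HBondCriteria(),
    hydrogens: Mapping[str, str] | None = None,
) -> list[HBond]:
    """Geometric hydrogen bonds in one frame, sorted by distance.

    ``donors``/``acceptors`` default to every polar-labeled atom in the
    frame (self-pairs excluded).  ``hydrogens`` optionally maps a donor
    label to its hydrogen label, enabling the D-H...A angle criterion.
    """
    donors = list(donors) if donors is not None else _polar_labels(frame)
    acceptors = list(acceptors) if acceptors is not None else _polar_labels(frame)
    if not donors or not acceptors:
        return []
    acc_pos = np.array([frame.position(a) for a in acceptors])
    tree = cKDTree(acc_pos)
    out: list[HBond] = []
    for d in donors:
        dpos = frame.position(d)
        for j in tree.query_ball_point(dpos, criteria.distance_cutoff):
            a = acceptors[j]
            if a == d:
                continue
            dist = float(np.linalg.norm(acc_pos[j] - dpos))
            h_label = hydrogens.get(d) if hydrogens else None
            angle = None
            if h_label is not None and frame.has(h_label):
                h = frame.position(h_label)
                v1 = dpos - h
                v2 = acc_pos[j] - h
                cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
                angle = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
                if angle < criteria.angle_min:
                    continue
            out.append(
                HBond(
                    donor_label=d,
                    acceptor_label=a,
                    distance=dist,
                    hydrogen_label=h_label,
                    angle=angle,
                )
            )
    out.sort(key=lambda hb: (hb.distance, hb.donor_label, hb.acceptor_label))
    return out


def water_bridges(
    frame: Frame, partner_a: str, partner_b: str, cutoff: float = 3.5
) -> list[HBond]:
    """Water oxygens bridging two partners (within ``cutoff`` of both)."""
    pa = frame.position(partner_a)
    pb = frame.position(partner_b)
    out = []
    for lab in frame.labels:
        if not (lab.startswith("WAT") and lab.endswith("_O")):
            continue
        w = frame.position(lab)
        da = float(np.linalg.norm(w - pa))
        db = float(np.linalg.norm(w - pb))
        if da <= cutoff and db <= cutoff:
            out.append(
                HBond(
                    donor_label=partner_a,
                    acceptor_label=partner_b,
                    distance=max(da, db),
                    water_mediated=True,
                    bridging_water=lab,
                )
            )
    out.sort(key=lambda hb: hb.distance)
    return out


# ---------------------------------------------------------------------------
# state classification


class StateValue(str, Enum):
    PFR = "PFR"
    BV_PR = "BV_PR"
    BV_PR_PRIME = "BV_PR_PRIME"
    BV_PR_DPRIME = "BV_PR_DPRIME"
    META_F_LIKE = "META_F_LIKE"


@dataclass(frozen=True)
class StateLabel:
    value: StateValue
    evidence: tuple[str, ...] = ()


@dataclass(frozen=True)
class StateWindows:
    """Dihedral windows making the relaxation taxonomy operational.

    Angles in wrapped degrees; the D5 Pr window is centered on the
    synthetic Pr reference.  Windows are half-open with the stated
    boundaries; the taxonomy itself is qualitative.
    """

    d6_pr_halfwidth: float = _refs.D6_PR_HALFWIDTH     # |D6| < 90 (Z region)
    d5_pr_center: float = wrap_angle(_refs.PR_D5_CENTER)
    d5_pr_halfwidth: float = _refs.PR_D5_HALFWIDTH
    d5_intermediate: tuple[float, float] = (
        wrap_angle(_refs.D5_INTERMEDIATE[0]),
        wrap_angle(_refs.D5_INTERMEDIATE[1]),
    )
    planarity_tol: float = _refs.PLANARITY_TOL

    def d6_in_pr(self, d6: float) -> bool:
        return abs(wrap_angle(d6)) < self.d6_pr_halfwidth

    def d5_in_pr(self, d5: float) -> bool:
        return abs(wrap_angle(d5 - self.d5_pr_center)) <= self.d5_pr_halfwidth

    def d5_in_intermediate(self, d5: float) -> bool:
        lo, hi = self.d5_intermediate
        w = wrap_angle(d5)
        if lo <= hi:
            return lo < w < hi
        return w > lo or w < hi  # window straddles the wrap point

    def is_planar(self, theta: float) -> bool:
        w = abs(wrap_angle(theta))
        return w <= self.planarity_tol or w >= 180.0 - self.planarity_tol


def _as_dihedral_map(final_dihedrals) -> dict[str, float]:
    if isinstance(final_dihedrals, Mapping):
        d = {k.upper(): float(v) for k, v in final_dihedrals.items()}
    else:
        vals = list(final_dihedrals)
        d = {f"D{i + 1}": float(v) for i, v in enumerate(vals)}
    missing = [k for k in ("D4", "D5", "D6") if k not in d]
    if missing:
        raise ValueError(f"missing required dihedrals: {missing}")
    return d


def classify_photoproduct(
    final_dihedrals,
    hbonds: Sequence[HBond],
    windows: StateWindows = StateWindows(),
) -> StateLabel:
    """Assign the relaxation-population label from final-frame evidence.

    ``final_dihedrals`` is a mapping ``{"D1": .., ..}`` (D4-D6 required)
    or a 6-sequence; angles are interpreted modulo 360.
    """
    d = _as_dihedral_map(final_dihedrals)
    evidence: list[str] = []
    d5, d6 = d["D5"], d["D6"]
    carbonyl_partner = None
    for hb in hbonds:
        for partner in ("His278", "Tyr165"):
            if hb.involves("D_ring_O", partner):
                carbonyl_partner = partner
                break
        if carbonyl_partner:
            break

    if windows.d6_in_pr(d6):
        evidence.append("D6 in Pr (Z) window")
    if windows.d5_in_pr(d5):
        evidence.append("D5 in Pr window")
    bridge = [d[k] for k in ("D4", "D5", "D6")]
    planar = all(windows.is_planar(t) for t in bridge)
    if planar:
        evidence.append("bridge dihedrals near-planar")
    if carbonyl_partner:
        evidence.append(f"D-ring carbonyl H-bonds {carbonyl_partner}")

    if windows.d6_in_pr(d6) and windows.d5_in_pr(d5) and carbonyl_partner:
        value = StateValue.BV_PR
    elif windows.d6_in_pr(d6) and planar:
        # planarity alone would also match the (planar, E-configured) Pfr
        # resting state; the photoproduct taxonomy applies only after the
        # D6 isomerization, hence the Z-window requirement
        value = StateValue.BV_PR_DPRIME
    elif windows.d6_in_pr(d6) and windows.d5_in_intermediate(d5):
        evidence.append("D5 between Pfr and Pr windows")
        value = StateValue.BV_PR_PRIME
    else:
        value = StateValue.PFR
    return StateLabel(value=value, evidence=tuple(evidence))


# ---------------------------------------------------------------------------
# Meta-F pocket signature


@dataclass(frozen=True)
class MetaFThresholds:
    gln_displacement: float = 4.0   # angstrom from the Pfr-proximal reference
    trp_gate: float = 6.0           # Trp440-Gln190 distance opening the gate


@dataclass(frozen=True)
class MetaFSignature:
    is_metaf_like: bool
    score: float                    # satisfied criteria / 3
    criteria: tuple[str, ...]


def metaF_signature(
    frame: Frame,
    gln190_reference: np.ndarray | Frame,
    thresholds: MetaFThresholds = MetaFThresholds(),
    hbond_criteria: HBondCriteria = HBondCriteria(),
) -> MetaFSignature:
    """Meta-F-like pocket signature of one frame.

    True iff (i) the D-ring carbonyl H-bonds His278, (ii) Gln190 has
    moved more than the displacement threshold from its reference
    (typically its position in the Pfr starting frame of the same
    trajectory), and (iii) the Trp440 gate is open (Trp440 far from
    Gln190).  The score is the satisfied-criteria fraction.
    """
    if isinstance(gln190_reference, Frame):
        gln190_reference = gln190_reference.position("Gln190_NE2")
    gln190_reference = np.asarray(gln190_reference, float)
    satisfied: list[str] = []

    hbs = detect_hbonds(
        frame, donors=["His278_NE2"], acceptors=["D_ring_O"], criteria=hbond_criteria
    ) + detect_hbonds(
        frame, donors=["D_ring_O"], acceptors=["His278_NE2"], criteria=hbond_criteria
    )
    if hbs:
        satisfied.append("carbonyl-His278 H-bond")
    gln = frame.position("Gln190_NE2")
    if float(np.linalg.norm(gln - gln190_reference)) > thresholds.gln_displacement:
        satisfied.append("Gln190 displaced")
    if float(np.linalg.norm(frame.position("Trp440_CZ2") - gln)) > thresholds.trp_gate:
        satisfied.append("Trp440 gate open")
    score = len(satisfied) / 3.0
    return MetaFSignature(
        is_metaf_like=len(satisfied) == 3, score=score, criteria=tuple(satisfied)
    )


# ---------------------------------------------------------------------------
# spine tilt


def spine_tilt(helix_a: np.ndarray, helix_b: np.ndarray) -> float:
    """Angle (degrees, folded to [0, 90]) between the principal axes of
    two CA point clouds.  Invariant to rigid motion of the complex and
    symmetric in its arguments."""
    angles = []
    axes = []
    for pts in (helix_a, helix_b):
        pts = np.asarray(pts, float)
        if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 4:
            raise ValueError("each helix needs at least 4 CA positions")
        centered = pts - pts.mean(axis=0)
        _, _, vt = np.linalg.svd(centered, full_matrices=False)
        axes.append(vt[0])
    cosang = abs(float(np.dot(axes[0], axes[1])))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
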