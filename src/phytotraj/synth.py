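"""Synthetic ensemble generators.

These generators replace the excited-state QM/MM surface-hopping and
ground-state MD engines with minimal constructions that carry the
statistical structure the downstream analyses assume:

* a surface-hopping ensemble whose S1->S0 hop times follow a
  biexponential mixture with a censored long-lived subpopulation, a fixed
  per-trajectory reaction probability, and ccw D6 / cw D5 hula-twist
  kinematics on the reactive members;
* a ground-state relaxation ensemble partitioned into BV-Pr / BV-Pr' /
  BV-Pr'' sub-populations, the BV-Pr members hydrogen-bonding the D-ring
  carbonyl to His278 or Tyr165;
* Gaussian pocket-geometry clusters in distance-feature space;
* ideal alpha-helix pairs at controlled tilt.

Every generator is a pure function of its config (which includes the
seed), and each returns bookkeeping sufficient to serve as an oracle for
the analysis stage it feeds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np
import pandas as pd

from . import _refs
from .geometry import BRIDGE_CHAIN_LABELS
from .io import ElectronicState, Frame, HopRecord, Trajectory

__all__ = [
    "ConfigError",
    "SHEnsembleConfig",
    "RelaxationEnsembleConfig",
    "PocketEnsembleConfig",
    "SHEnsemble",
    "RelaxationEnsemble",
    "generate_sh_ensemble",
    "generate_relaxation_ensemble",
    "generate_pocket_frames",
    "generate_helix_pair",
    "HelixPair",
    "build_bridge_frame",
    "DEFAULT_POCKET_PAIRS",
    "DEFAULT_POCKET_CENTERS",
    "PRESETS",
    "get_preset",
]


class ConfigError(ValueError):
    """Generator configuration violates an invariant."""


# ---------------------------------------------------------------------------
# configs

#: Surviving-trajectory statistics of the reference surface-hopping
#: ensemble: 61 of 3028 trajectories still excited at the 20 ps cutoff.
_SH_N = 3028
_SH_SURVIVORS = 61


@dataclass(frozen=True)
class SHEnsembleConfig:
    """Surface-hopping ensemble parameters.

    ``amp_fast`` plus the implied slow amplitude plus
    ``long_lived_fraction`` sum to one; hop times of the decaying part are
    drawn from the (renormalized) biexponential mixture truncated below
    ``censor_time``, and exactly ``round(long_lived_fraction * n_traj)``
    trajectories are censored at ``censor_time``.
    """

    n_traj: int = _SH_N
    reaction_probability: float = 0.28 * _SH_N / (_SH_N - _SH_SURVIVORS)
    tau_fast: float = 0.71          # ps
    tau_slow: float = 4.25          # ps
    amp_fast: float = 0.6 * (1.0 - _SH_SURVIVORS / _SH_N)
    long_lived_fraction: float = _SH_SURVIVORS / _SH_N
    censor_time: float = 20.0       # ps
    dt: float = 0.25                # ps
    seed: int = 1
    noise_deg: float = 2.0
    tail: float = 2.0               # ps of ground-state frames kept after the hop

    def __post_init__(self) -> None:
        if self.n_traj < 1:
            raise ConfigError("n_traj must be positive")
        if not 0.0 <= self.reaction_probability <= 1.0:
            raise ConfigError("reaction_probability must lie in [0, 1]")
        if not self.tau_fast < self.tau_slow:
            raise ConfigError("tau_fast must be smaller than tau_slow")
        if not 0.0 <= self.long_lived_fraction < 1.0:
            raise ConfigError("long_lived_fraction must lie in [0, 1)")
        if not 0.0 <= self.amp_fast <= 1.0 - self.long_lived_fraction:
            raise ConfigError(
                "amp_fast must lie in [0, 1 - long_lived_fraction] so that the "
                "mixture amplitudes sum to one"
            )
        if self.censor_time <= 0 or self.dt <= 0:
            raise ConfigError("censor_time and dt must be positive")

    @property
    def amp_slow(self) -> float:
        return 1.0 - self.amp_fast - self.long_lived_fraction


@dataclass(frozen=True)
class RelaxationEnsembleConfig:
    """Ground-state relaxation ensemble (Lumi-F heterogeneity)."""

    n_traj: int = 63
    n_pr: int = 20
    n_pr_prime: int = 41
    n_pr_dprime: int = 2
    hbond_partner_split: float = 0.5   # fraction of BV-Pr members bonding His278
    dt: float = 30.0                   # ps between stored frames
    n_frames: int = 50
    seed: int = 42
    noise_deg: float = 2.0

    def __post_init__(self) -> None:
        if self.n_pr + self.n_pr_prime + self.n_pr_dprime != self.n_traj:
            raise ConfigError("population counts must sum to n_traj")
        if min(self.n_pr, self.n_pr_prime, self.n_pr_dprime) < 0:
            raise ConfigError("population counts must be non-negative")
        if not 0.0 <= self.hbond_partner_split <= 1.0:
            raise ConfigError("hbond_partner_split must lie in [0, 1]")
        if self.n_frames < 2:
            raise ConfigError("n_frames must be >= 2")


#: Distance pairs spanning the D-ring environment (angstrom features).
DEFAULT_POCKET_PAIRS: tuple[tuple[str, str], ...] = (
    ("D_ring_N", "Asp196_OD1"),
    ("D_ring_O", "WAT0_O"),
    ("D_ring_O", "Gln190_NE2"),
    ("D_ring_O", "His278_NE2"),
    ("D_ring_O", "Tyr165_OH"),
    ("D_ring_N", "Gln190_NE2"),
    ("D_ring_O", "Trp440_CZ2"),
    ("D_ring_N", "His278_NE2"),
)

#: Three pocket arrangements: Gln190-coordinated carbonyl, Asp196+water
#: coordination, and a looser His/Tyr-proximal pocket.
DEFAULT_POCKET_CENTERS: np.ndarray = np.array(
    [
        [4.5, 5.5, 2.9, 5.5, 5.0, 3.4, 6.5, 6.0],
        [2.7, 2.8, 5.2, 5.0, 5.5, 5.8, 6.5, 5.5],
        [4.0, 4.2, 4.4, 3.2, 3.0, 4.8, 8.0, 4.0],
    ]
)


@dataclass(frozen=True)
class PocketEnsembleConfig:
    n_frames: int = 300
    n_clusters: int = 3
    cluster_centers: np.ndarray = field(default_factory=lambda: DEFAULT_POCKET_CENTERS.copy())
    cluster_spread: float = 0.25    # angstrom
    seed: int = 0

    def __post_init__(self) -> None:
        centers = np.atleast_2d(np.asarray(self.cluster_centers, float))
        object.__setattr__(self, "cluster_centers", centers)
        if centers.shape[0] != self.n_clusters:
            raise ConfigError("cluster_centers must provide one row per cluster")
        if self.cluster_spread < 0:
            raise ConfigError("cluster_spread must be non-negative")
        if self.n_clusters > 1 and self.cluster_spread > 0:
            d = np.linalg.norm(centers[:, None] - centers[None, :], axis=-1)
            np.fill_diagonal(d, np.inf)
            if d.min() <= 3.0 * self.cluster_spread:
                raise ConfigError(
                    "cluster centers must be separated by more than 3x spread"
                )


# ---------------------------------------------------------------------------
# geometry construction

_BOND = 1.45
_ANGLE = 120.0


def _place(a: np.ndarray, b: np.ndarray, c: np.ndarray, bond: float,
           angle_deg: float, dih_deg: float) -> np.ndarray:
    """Natural-extension placement: position d with given internal coords."""
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    ang = math.radians(angle_deg)
    dih = math.radians(dih_deg)
    d2 = np.array(
        [
            -bond * math.cos(ang),
            bond * math.sin(ang) * math.cos(dih),
            bond * math.sin(ang) * math.sin(dih),
        ]
    )
    return c + d2[0] * bc + d2[1] * m + d2[2] * n


# azimuth/elevation (deg) of each probe direction in the local frame
# anchored at the D-ring carbonyl oxygen or ring nitrogen
_PROBE_GEOMETRY = {
    "His278_NE2": ("D_ring_O", 0.0, 20.0),
    "Tyr165_OH": ("D_ring_O", 120.0, 20.0),
    "Gln190_NE2": ("D_ring_O", 240.0, 35.0),
    "Trp440_CZ2": ("D_ring_O", 300.0, -30.0),
    "Asp196_OD1": ("D_ring_N", 0.0, 25.0),
    "WAT0_O": ("D_ring_O", 60.0, -25.0),
    "WAT1_O": ("D_ring_N", 180.0, -25.0),
}


def build_bridge_frame(
    time: float,
    state: ElectronicState | str,
    d4: float,
    d5: float,
    d6: float,
    scalars: dict[str, float] | None = None,
    probe_distances: dict[str, float] | None = None,
) -> Frame:
    """Construct a frame of the minimal bilin bridge scaffold.

    The six-atom C-D bridge chain realizes D4/D5/D6 exactly; the D-ring
    nitrogen and carbonyl oxygen ride with the ring, and each probe atom
    named in ``probe_distances`` is placed at the requested distance from
    its anchor (D_ring_O or D_ring_N) along a fixed label-specific
    direction.
    """
    p0 = np.zeros(3)
    p1 = np.array([_BOND, 0.0, 0.0])
    ang = math.radians(180.0 - _ANGLE)
    p2 = p1 + _BOND * np.array([math.cos(ang), math.sin(ang), 0.0])
    p3 = _place(p0, p1, p2, _BOND, _ANGLE, d4)
    p4 = _place(p1, p2, p3, _BOND, _ANGLE, d5)
    p5 = _place(p2, p3, p4, _BOND, _ANGLE, d6)
    ring_n = _place(p3, p4, p5, 1.40, _ANGLE, 180.0)
    ring_o = _place(p3, p4, p5, 1.25, _ANGLE, 0.0)

    labels = list(BRIDGE_CHAIN_LABELS) + ["D_ring_N", "D_ring_O"]
    coords = [p0, p1, p2, p3, p4, p5, ring_n, ring_o]

    if probe_distances:
        anchors = {"D_ring_N": ring_n, "D_ring_O": ring_o}
        # local orthonormal frame at each anchor
        frames = {}
        for name, pos in anchors.items():
            e1 = pos - p5
            e1 /= np.linalg.norm(e1)
            r = p4 - p5
            e2 = r - np.dot(r, e1) * e1
            e2 /= np.linalg.norm(e2)
            e3 = np.cross(e1, e2)
            frames[name] = (pos, e1, e2, e3)
        for label in sorted(probe_distances):
            dist = probe_distances[label]
            try:
                anchor, az, el = _PROBE_GEOMETRY[label]
            except KeyError:
                raise ConfigError(f"no placement geometry for probe {label!r}") from None
            pos, e1, e2, e3 = frames[anchor]
            az_r, el_r = math.radians(az), math.radians(el)
            u = (
                math.sin(el_r) * e1
                + math.cos(el_r) * (math.cos(az_r) * e2 + math.sin(az_r) * e3)
            )
            labels.append(label)
            coords.append(pos + dist * u)
    return Frame(time, state, labels, np.array(coords), scalars)


# ---------------------------------------------------------------------------
# surface-hopping ensemble

_FAR = 5.6     # non-bonded probe distance, angstrom
_NEAR = 2.8    # hydrogen-bonded probe distance, angstrom


@dataclass
class SHEnsemble:
    """Generated surface-hopping ensemble plus bookkeeping.

    Iterating yields ``(trajectories, hop_records)`` so the object
    unpacks like the documented pair; ``manifest`` carries the
    per-trajectory ground truth (component, hop/crossing times, pocket
    interaction pattern).
    """

    trajectories: list[Trajectory]
    hop_records: list[HopRecord]
    manifest: pd.DataFrame

    def __iter__(self) -> Iterator:
        return iter((self.trajectories, self.hop_records))


def _sh_pocket(pattern: str) -> dict[str, float]:
    base = {
        "His278_NE2": _FAR,
        "Tyr165_OH": _FAR,
        "Trp440_CZ2": 4.0,
        "Asp196_OD1": _FAR,
        "Gln190_NE2": _FAR,
        "WAT0_O": _FAR,
    }
    if pattern == "asp_water":
        base["Asp196_OD1"] = 2.7
        base["WAT0_O"] = _NEAR
    else:  # Gln190 coordinates the carbonyl, no water
        base["Gln190_NE2"] = 2.9
    return base


def _sh_trajectory(
    tid: str,
    hop_time: float | None,
    reactive: bool,
    cfg: SHEnsembleConfig,
    pattern: str,
    rng: np.random.Generator,
) -> Trajectory:
    ref = _refs.PFR_ANGLES
    if hop_time is None:
        t_end = cfg.censor_time
    else:
        t_end = min(hop_time + cfg.tail, cfg.censor_time)
        t_end = max(t_end, cfg.dt)  # keep >= 2 frames
    times = np.arange(0.0, t_end + 0.5 * cfg.dt, cfg.dt)
    th = math.inf if hop_time is None else hop_time
    ramp = 0.5  # ps half-duration of the isomerization ramp

    # the ramp cannot start before the trajectory does: for hops earlier
    # than the ramp half-width the pre-hop leg steepens so the 90 deg
    # crossing still falls exactly at the hop
    t_a = max(th - ramp, 0.0) if hop_time is not None else 0.0
    if hop_time is not None and reactive:
        mid6 = 0.5 * (ref["D6"] + _refs.LUMI_START_D6)
        mid5 = 0.5 * (ref["D5"] + _refs.LUMI_START_D5)
        d6 = np.interp(times, [t_a, th, th + ramp], [ref["D6"], mid6, _refs.LUMI_START_D6])
        d5 = np.interp(times, [t_a, th, th + ramp], [ref["D5"], mid5, _refs.LUMI_START_D5])
    elif hop_time is not None:
        # abortive excursion: D6 dips toward 90 but returns to the E region
        d6 = ref["D6"] + np.interp(times, [t_a, th, th + ramp], [0.0, -50.0, 0.0])
        d5 = ref["D5"] + np.interp(times, [t_a, th, th + ramp], [0.0, 15.0, 0.0])
    else:
        d6 = np.full_like(times, ref["D6"])
        d5 = np.full_like(times, ref["D5"])

    noise = cfg.noise_deg
    probes = _sh_pocket(pattern)
    frames = []
    for i, t in enumerate(times):
        state = ElectronicState.S1 if t < th else ElectronicState.S0
        scal = {
            "d1": ref["D1"] + rng.normal(0.0, noise),
            "d2": ref["D2"] + rng.normal(0.0, noise),
            "d3": ref["D3"] + rng.normal(0.0, noise),
        }
        frames.append(
            build_bridge_frame(
                float(t),
                state,
                ref["D4"] + rng.normal(0.0, noise),
                float(d5[i] + rng.normal(0.0, noise)),
                float(d6[i] + rng.normal(0.0, noise)),
                scalars=scal,
                probe_distances={
                    k: v + rng.normal(0.0, 0.05) for k, v in probes.items()
                },
            )
        )
    return Trajectory(tid, frames, cfg.dt)


def generate_sh_ensemble(
    config: SHEnsembleConfig, trajectories: bool = True
) -> SHEnsemble:
    """Sample a surface-hopping ensemble (pure function of the config).

    Hop times are drawn from the fast/slow exponential mixture truncated
    below ``censor_time``; exactly ``round(long_lived_fraction * n_traj)``
    trajectories are censored at ``censor_time``.  Each hopped trajectory
    is reactive with probability ``reaction_probability``; reactive
    members perform the ccw D6 / cw D5 hula twist centered at the hop.
    Set ``trajectories=False`` to generate hop records and bookkeeping
    only (the kinetics analyses need no geometry).
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_traj
    n_long = int(round(cfg.long_lived_fraction * n))
    long_idx = set(rng.permutation(n)[:n_long].tolist())

    p_fast = cfg.amp_fast / (cfg.amp_fast + cfg.amp_slow) if cfg.amp_fast + cfg.amp_slow > 0 else 0.0
    # slow/censored members carry the Asp196+water pocket, fast ones the
    # Gln190-coordinated pocket (lifetime-pattern coupling)
    rows = []
    trajs: list[Trajectory] = []
    records: list[HopRecord] = []
    for i in range(n):
        tid = f"sh{i:05d}"
        if i in long_idx:
            component, hop, reactive, pattern = "long", None, False, "asp_water"
        else:
            component = "fast" if rng.random() < p_fast else "slow"
            tau = cfg.tau_fast if component == "fast" else cfg.tau_slow
            hop = float(rng.exponential(tau))
            while hop >= cfg.censor_time:
                hop = float(rng.exponential(tau))
            reactive = bool(rng.random() < cfg.reaction_probability)
            pattern = "gln" if component == "fast" else "asp_water"
        records.append(HopRecord(tid, hop, cfg.censor_time, reactive))
        rows.append(
            {
                "trajectory_id": tid,
                "component": component,
                "hop_time": np.nan if hop is None else hop,
                "censored": hop is None,
                "reactive": reactive,
                "crossing_time": hop if (reactive and hop is not None) else np.nan,
                "pattern": pattern,
            }
        )
        if trajectories:
            trajs.append(_sh_trajectory(tid, hop, reactive, cfg, pattern, rng))
    manifest = pd.DataFrame(rows)
    return SHEnsemble(trajs, records, manifest)


# ---------------------------------------------------------------------------
# relaxation ensemble


@dataclass
class RelaxationEnsemble:
    """List-like container of relaxation trajectories with bookkeeping."""

    trajectories: list[Trajectory]
    manifest: pd.DataFrame

    def __iter__(self) -> Iterator[Trajectory]:
        return iter(self.trajectories)

    def __len__(self) -> int:
        return len(self.trajectories)

    def __getitem__(self, i):
        return self.trajectories[i]


def _relaxation_trajectory(
    tid: str,
    population: str,
    partner: str | None,
    cfg: RelaxationEnsembleConfig,
    rng: np.random.Generator,
) -> Trajectory:
    ref = _refs.PFR_ANGLES
    times = np.arange(cfg.n_frames) * cfg.dt
    frac = times / times[-1]
    if population == "BV_PR":
        d5_final = _refs.PR_D5_CENTER + rng.uniform(-12.0, 12.0)
        d4_final = ref["D4"]
    elif population == "BV_PR_PRIME":
        d5_final = rng.uniform(205.0, 228.0)
        d4_final = ref["D4"]
    else:  # BV_PR_DPRIME: near-planar bridge
        d5_final = 180.0 + rng.uniform(-8.0, 8.0)
        d4_final = 0.0
    d5 = _refs.LUMI_START_D5 + (d5_final - _refs.LUMI_START_D5) * frac
    d6 = np.full_like(times, _refs.LUMI_START_D6)
    d4 = ref["D4"] + (d4_final - ref["D4"]) * frac

    partner_far = {"His278_NE2": _FAR, "Tyr165_OH": _FAR}
    frames = []
    noise = cfg.noise_deg
    for i, t in enumerate(times):
        probes = dict(partner_far)
        probes.update({"Gln190_NE2": 3.0, "Trp440_CZ2": 3.6, "Asp196_OD1": 4.5})
        if partner is not None:
            # the stabilizing partner approaches over the run
            probes[partner] = _FAR + (_NEAR - _FAR) * frac[i]
        scal = {
            "d1": ref["D1"] + rng.normal(0.0, noise),
            "d2": ref["D2"] + rng.normal(0.0, noise),
            "d3": ref["D3"] + rng.normal(0.0, noise),
        }
        # final frame realizes the population's defining window exactly
        jitter = 0.0 if i == cfg.n_frames - 1 else rng.normal(0.0, noise)
        frames.append(
            build_bridge_frame(
                float(t),
                ElectronicState.S0,
                float(d4[i] + (0.0 if i == cfg.n_frames - 1 else rng.normal(0.0, noise))),
                float(d5[i] + jitter),
                float(d6[i] + (0.0 if i == cfg.n_frames - 1 else rng.normal(0.0, noise))),
                scalars=scal,
                probe_distances={
                    k: v + (0.0 if i == cfg.n_frames - 1 else rng.normal(0.0, 0.05))
                    for k, v in probes.items()
                },
            )
        )
    return Trajectory(tid, frames, cfg.dt)


def generate_relaxation_ensemble(config: RelaxationEnsembleConfig) -> RelaxationEnsemble:
    """Generate the ground-state relaxation ensemble.

    Exactly ``n_pr`` members end with D5 in the Pr window and an H-bond
    from the D-ring carbonyl to His278 or Tyr165 (split by
    ``hbond_partner_split``), ``n_pr_prime`` end between the Pr and Pfr
    windows, and ``n_pr_dprime`` end near-planar.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    populations = (
        ["BV_PR"] * cfg.n_pr
        + ["BV_PR_PRIME"] * cfg.n_pr_prime
        + ["BV_PR_DPRIME"] * cfg.n_pr_dprime
    )
    n_his = int(round(cfg.hbond_partner_split * cfg.n_pr))
    partners: list[str | None] = ["His278_NE2"] * n_his + ["Tyr165_OH"] * (
        cfg.n_pr - n_his
    ) + [None] * (cfg.n_pr_prime + cfg.n_pr_dprime)
    order = rng.permutation(cfg.n_traj)
    trajs, rows = [], []
    for rank, j in enumerate(order):
        tid = f"relax{rank:03d}"
        traj = _relaxation_trajectory(tid, populations[j], partners[j], cfg, rng)
        trajs.append(traj)
        rows.append(
            {
                "trajectory_id": tid,
                "population": populations[j],
                "hbond_partner": partners[j],
            }
        )
    return RelaxationEnsemble(trajs, pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# pocket feature blobs


def generate_pocket_frames(
    config: PocketEnsembleConfig,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Gaussian blobs around the configured pocket-distance centers.

    Returns the feature matrix (one row per frame, one labeled distance
    column per pair) together with the generative cluster labels.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    k = cfg.n_clusters
    counts = [cfg.n_frames // k + (1 if i < cfg.n_frames % k else 0) for i in range(k)]
    feats, labels = [], []
    for c, n_c in enumerate(counts):
        feats.append(
            cfg.cluster_centers[c] + cfg.cluster_spread * rng.standard_normal((n_c, cfg.cluster_centers.shape[1]))
        )
        labels.extend([c] * n_c)
    X = np.vstack(feats)
    y = np.array(labels)
    order = rng.permutation(len(y))
    n_feat = cfg.cluster_centers.shape[1]
    if n_feat == len(DEFAULT_POCKET_PAIRS):
        columns = [f"{a}-{b}" for a, b in DEFAULT_POCKET_PAIRS]
    else:
        columns = [f"dist_{i}" for i in range(n_feat)]
    return pd.DataFrame(X[order], columns=columns), y[order]


# ---------------------------------------------------------------------------
# helix pair


@dataclass
class HelixPair:
    """Two ideal alpha-helical CA traces at a controlled axis tilt.

    A single frame suffices for the tilt estimator, so the pair is
    returned as one :class:`Frame` plus the per-helix coordinate arrays.
    """

    frame: Frame
    ca_a: np.ndarray
    ca_b: np.ndarray
    tilt_deg: float


def generate_helix_pair(
    tilt_deg: float,
    n_res: int = 18,
    seed: int = 0,
    separation: float = 10.0,
    jitter: float = 0.05,
) -> HelixPair:
    """Build two ideal helices (rise 1.5 A, 100 deg/residue, radius 2.3 A)
    whose fitted axes subtend ``tilt_deg``."""
    if n_res < 4:
        raise ConfigError("n_res must be >= 4")
    rng = np.random.default_rng(seed)
    i = np.arange(n_res)
    theta = np.radians(100.0 * i)
    helix = np.column_stack([2.3 * np.cos(theta), 2.3 * np.sin(theta), 1.5 * i])
    helix = helix - helix.mean(axis=0)
    a = helix + rng.normal(0.0, jitter, helix.shape)
    t = math.radians(tilt_deg)
    rot_x = np.array(
        [[1, 0, 0], [0, math.cos(t), -math.sin(t)], [0, math.sin(t), math.cos(t)]]
    )
    b = helix @ rot_x.T + np.array([separation, 0.0, 0.0])
    b = b + rng.normal(0.0, jitter, b.shape)
    labels = [f"CA{j + 1}" for j in range(2 * n_res)]
    frame = Frame(0.0, ElectronicState.S0, labels, np.vstack([a, b]))
    return HelixPair(frame=frame, ca_a=a, ca_b=b, tilt_deg=float(tilt_deg))


# ---------------------------------------------------------------------------
# presets


def _preset_agp2_sh(seed: int | None = None) -> SHEnsembleConfig:
    cfg = SHEnsembleConfig()
    return cfg if seed is None else replace(cfg, seed=seed)


def _preset_lumi_f_63(seed: int | None = None) -> RelaxationEnsembleConfig:
    cfg = RelaxationEnsembleConfig()
    return cfg if seed is None else replace(cfg, seed=seed)


def _preset_pocket_3(seed: int | None = None) -> PocketEnsembleConfig:
    cfg = PocketEnsembleConfig()
    return cfg if seed is None else replace(cfg, seed=seed)


PRESETS = {
    "agp2-sh": _preset_agp2_sh,
    "lumi-f-63": _preset_lumi_f_63,
    "pocket-3": _preset_pocket_3,
}


def get_preset(name: str, seed: int | None = None):
    """Return the named preset config, optionally overriding its seed."""
    try:
        factory = PRESETS[name]
    except KeyError:
        raise ConfigError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}"
        ) from None
    return factory(seed)
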