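"""One-dimensional keto<->enol proton-transfer model with adaptive-bias
enhanced sampling.

The collective variable is the proton-distance difference
``x = d(N-H) - d(O-H)`` (angstrom) between the D-ring nitrogen and
carbonyl oxygen.  The model surface is a tilted quartic double well
calibrated so that the enol-keto energy difference and the forward
barrier match their requested values exactly; the keto minimum defines
the energy zero.  Dynamics are overdamped Langevin (Euler-Maruyama), and
the free-energy difference is estimated from a well-tempered adaptive
bias built from deposited Gaussian kernels, cross-checked by reweighted
sampling and by direct quadrature of the basin partition functions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
import numpy as np
from scipy.integrate import quad
from scipy.optimize import brentq

__all__ = [
    "GAS_CONSTANT_KCAL",
    "PTSurface",
    "HarmonicWell",
    "AdaptiveBias",
    "SimResult",
    "potential",
    "simulate",
    "update_bias",
    "FreeEnergyEstimate",
    "free_energy_difference",
    "quadrature_free_energy_difference",
]

#: kcal mol^-1 K^-1
GAS_CONSTANT_KCAL = 1.987204258640832e-3


def _kt(temperature: float) -> float:
    return GAS_CONSTANT_KCAL * temperature


# ---------------------------------------------------------------------------
# surfaces


def _quartic_stationary(h: float, c: float) -> tuple[float, float, float]:
    """Stationary points (keto min, barrier top, enol min) in reduced x."""
    roots = np.roots([4.0 * h, 0.0, -4.0 * h, 0.5 * c])
    real = np.sort(roots[np.abs(roots.imag) < 1e-9].real)
    if len(real) != 3 or real[0] == real[1] or real[1] == real[2]:
        raise ValueError("surface parameters do not yield two minima")
    return float(real[0]), float(real[1]), float(real[2])


def _quartic_u(h: float, c: float, xr) -> np.ndarray:
    xr = np.asarray(xr, float)
    return h * (xr * xr - 1.0) ** 2 + 0.5 * c * (xr + 1.0)


@dataclass(frozen=True)
class PTSurface:
    """Tilted-quartic double well along the proton-transfer coordinate.

    ``delta_e`` (kcal/mol) is the exact enol-minus-keto minimum energy
    difference and ``barrier`` the exact forward barrier from the keto
    minimum; ``half_width`` sets the spatial scale (minima near
    ``center +- half_width``).  Per-well stiffness is derived, not free.
    """

    delta_e: float = 27.0
    barrier: float = 36.0
    half_width: float = 1.5
    center: float = 0.0

    def __post_init__(self) -> None:
        if self.barrier <= max(self.delta_e, 0.0):
            raise ValueError("forward barrier must exceed delta_e (and be > 0)")
        if self.delta_e < 0:
            raise ValueError("delta_e must be >= 0 (keto is the reference minimum)")

        target_du, target_bar = self.delta_e, self.barrier

        def du_bar(h: float, c: float) -> tuple[float, float]:
            xk, xb, xe = _quartic_stationary(h, c)
            uk = _quartic_u(h, c, xk)
            return (
                float(_quartic_u(h, c, xe) - uk),
                float(_quartic_u(h, c, xb) - uk),
            )

        def c_for_du(h: float) -> float | None:
            """Tilt realizing the requested energy split at this h, if any."""
            if target_du == 0.0:
                return 0.0
            c_max = 8.0 * h / (3.0 * math.sqrt(3.0)) * (1.0 - 1e-7)
            if du_bar(h, c_max)[0] < target_du:
                return None
            return brentq(
                lambda cc: du_bar(h, cc)[0] - target_du, 0.0, c_max, xtol=1e-14
            )

        if target_du == 0.0:
            h, c = target_bar, 0.0  # symmetric well: barrier is simply h
        else:
            # smallest h whose spinodal split still reaches delta_e
            h_hi = max(target_du, 1.0)
            while c_for_du(h_hi) is None:
                h_hi *= 2.0
            h_lo = h_hi / 2.0 if c_for_du(h_hi / 2.0) is None else 1e-6
            while c_for_du(h_lo) is not None and h_lo > 1e-6:
                h_lo /= 2.0
            for _ in range(80):
                mid = 0.5 * (h_lo + h_hi)
                if c_for_du(mid) is None:
                    h_lo = mid
                else:
                    h_hi = mid
            h_star = h_hi * (1.0 + 1e-6)

            def g(h: float) -> float:
                return du_bar(h, c_for_du(h))[1] - target_bar

            if g(h_star) > 0.0:
                raise ValueError(
                    f"barrier {target_bar} is unreachable for delta_e {target_du}: "
                    f"minimum realizable forward barrier is "
                    f"{du_bar(h_star, c_for_du(h_star))[1]:.2f} kcal/mol"
                )
            h_hi = h_star * 2.0
            while g(h_hi) < 0.0:
                h_hi *= 2.0
            h = brentq(g, h_star, h_hi, xtol=1e-13)
            c = c_for_du(h)

        xk, xb, xe = _quartic_stationary(h, c)
        du = float(_quartic_u(h, c, xe) - _quartic_u(h, c, xk))
        bar = float(_quartic_u(h, c, xb) - _quartic_u(h, c, xk))
        if abs(du - target_du) > 1e-9 or abs(bar - target_bar) > 1e-9:
            raise ValueError("surface calibration did not converge")
        object.__setattr__(self, "_h", h)
        object.__setattr__(self, "_c", c)
        object.__setattr__(self, "_offset", float(_quartic_u(h, c, xk)))
        a, x0 = self.half_width, self.center
        object.__setattr__(self, "keto_position", x0 + a * xk)
        object.__setattr__(self, "enol_position", x0 + a * xe)
        object.__setattr__(self, "barrier_position", x0 + a * xb)

    # -- evaluation ---------------------------------------------------------

    def _reduced(self, x):
        return (np.asarray(x, float) - self.center) / self.half_width

    def energy(self, x):
        """Potential energy (kcal/mol), zero at the keto minimum."""
        u = _quartic_u(self._h, self._c, self._reduced(x)) - self._offset
        return float(u) if u.ndim == 0 else u

    def gradient(self, x):
        xr = self._reduced(x)
        g = (4.0 * self._h * xr * (xr * xr - 1.0) + 0.5 * self._c) / self.half_width
        return float(g) if np.ndim(g) == 0 else g

    @property
    def domain(self) -> tuple[float, float]:
        return (self.center - 2.2 * self.half_width, self.center + 2.2 * self.half_width)

    def stiffness(self) -> tuple[float, float]:
        """Second derivative of U at the keto and enol minima (kcal/mol/A^2)."""
        out = []
        for x in (self.keto_position, self.enol_position):
            xr = float(self._reduced(x))
            out.append(self._h * (12.0 * xr * xr - 4.0) / self.half_width**2)
        return tuple(out)


@dataclass(frozen=True)
class HarmonicWell:
    """Single harmonic well, mainly for integrator validation."""

    stiffness: float = 10.0   # kcal/mol/A^2
    center: float = 0.0
    halfwidth: float = 6.0

    def energy(self, x):
        return 0.5 * self.stiffness * (np.asarray(x, float) - self.center) ** 2

    def gradient(self, x):
        return self.stiffness * (np.asarray(x, float) - self.center)

    @property
    def domain(self) -> tuple[float, float]:
        return (self.center - self.halfwidth, self.center + self.halfwidth)


def potential(surface, x):
    """Potential energy of ``surface`` at ``x`` (kcal/mol)."""
    return surface.energy(x)


# ---------------------------------------------------------------------------
# adaptive bias


class AdaptiveBias:
    """Well-tempered adaptive bias from deposited Gaussian kernels.

    Kernel heights attenuate as ``exp(-V(x) / ((gamma - 1) kT))`` so the
    bias converges toward ``(1 - 1/gamma)`` of the free-energy well depth
    (``gamma = inf`` recovers the non-tempered limit).  The bias and its
    force are kept on a fixed grid for O(1) evaluation.
    """

    def __init__(
        self,
        domain: tuple[float, float],
        gamma: float = 15.0,
        bandwidth: float = 0.05,
        height: float = 1.0,
        temperature: float = 300.0,
        n_grid: int = 1101,
    ) -> None:
        if gamma <= 1.0 and not math.isinf(gamma):
            raise ValueError("bias factor gamma must exceed 1")
        self.gamma = gamma
        self.bandwidth = bandwidth
        self.height = height
        self.kt = _kt(temperature)
        self.grid = np.linspace(domain[0], domain[1], n_grid)
        self.values = np.zeros(n_grid)
        self.force = np.zeros(n_grid)
        self.centers: list[float] = []
        self.heights: list[float] = []
        #: optional probe positions whose bias values are logged at every
        #: deposition (enables time-averaged free-energy estimates)
        self.probes: tuple[float, float] | None = None
        self.probe_history: list[tuple[float, float]] = []

    @property
    def n_kernels(self) -> int:
        return len(self.centers)

    def value(self, x):
        return np.interp(x, self.grid, self.values)

    def update(self, x: float) -> None:
        """Deposit one kernel at ``x`` with well-tempered attenuation."""
        if math.isinf(self.gamma):
            h = self.height
        else:
            h = self.height * math.exp(
                -float(self.value(x)) / ((self.gamma - 1.0) * self.kt)
            )
        self.values += h * np.exp(-0.5 * ((self.grid - x) / self.bandwidth) ** 2)
        self.force = -np.gradient(self.values, self.grid)
        self.centers.append(float(x))
        self.heights.append(h)
        if self.probes is not None:
            self.probe_history.append(
                (float(self.value(self.probes[0])), float(self.value(self.probes[1])))
            )


def update_bias(bias: AdaptiveBias, x_sample: float) -> AdaptiveBias:
    bias.update(x_sample)
    return bias


# ---------------------------------------------------------------------------
# dynamics


@dataclass
class SimResult:
    positions: np.ndarray     # recorded CV samples
    dt: float
    record_every: int
    bias: AdaptiveBias | None = None

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.positions)) * self.dt * self.record_every


def simulate(
    surface,
    bias: AdaptiveBias | None = None,
    n_steps: int = 1_000_000,
    temperature: float = 300.0,
    friction: float = 5.0,
    dt: float = 0.001,
    seed: int = 0,
    x0: float | None = None,
    record_every: int = 1,
    deposit_stride: int = 500,
) -> SimResult:
    """Overdamped Langevin (Euler-Maruyama) on ``U + V_bias``.

    ``friction`` is the overdamped drag coefficient zeta in
    kcal mol^-1 ps A^-2: the update is
    ``x += -(dt/zeta) dU/dx + sqrt(2 kT dt / zeta) xi``.  When ``bias``
    is given, a kernel is deposited every ``deposit_stride`` steps
    (on-the-fly).  Deterministic given ``seed``.  A step larger than a
    tenth of the domain raises a divergence error with a suggested dt.
    """
    kt = _kt(temperature)
    lo, hi = surface.domain
    grid = np.linspace(lo, hi, 2201)
    force_grid = -np.asarray(surface.gradient(grid), float)
    inv_dx = (len(grid) - 1) / (hi - lo)
    mob_dt = dt / friction
    sigma = math.sqrt(2.0 * kt * dt / friction)
    max_step = 0.1 * (hi - lo)

    if x0 is None:
        x0 = getattr(surface, "keto_position", getattr(surface, "center", 0.5 * (lo + hi)))
    x = float(x0)
    if (
        bias is not None
        and bias.probes is None
        and hasattr(surface, "keto_position")
    ):
        bias.probes = (surface.keto_position, surface.enol_position)
    rng = np.random.default_rng(seed)
    n_rec = n_steps // record_every
    out = np.empty(n_rec)
    bias_force = bias.force if bias is not None else None
    bias_grid = bias.grid if bias is not None else None

    chunk = 16384
    i = 0
    rec = 0
    fg = force_grid
    while i < n_steps:
        m = min(chunk, n_steps - i)
        noise = rng.standard_normal(m) * sigma
        for j in range(m):
            u = (x - lo) * inv_dx
            if u < 0.0 or u >= len(grid) - 1:
                raise ValueError(
                    f"trajectory left the domain at step {i + j} (x={x:.3f}); "
                    f"dt={dt} is too large, try dt={dt / 5:g}"
                )
            ui = int(u)
            frac = u - ui
            f = fg[ui] * (1.0 - frac) + fg[ui + 1] * frac
            if bias_force is not None:
                ub = (x - bias_grid[0]) * (len(bias_grid) - 1) / (
                    bias_grid[-1] - bias_grid[0]
                )
                if 0.0 <= ub < len(bias_grid) - 1:
                    bi = int(ub)
                    bfrac = ub - bi
                    f += bias_force[bi] * (1.0 - bfrac) + bias_force[bi + 1] * bfrac
            step = mob_dt * f + noise[j]
            if not math.isfinite(step) or abs(step) > max_step:
                raise ValueError(
                    f"divergent step at {i + j} (|dx|={abs(step):.3g} A); "
                    f"dt={dt} is too large, try dt={dt / 5:g}"
                )
            x += step
            idx = i + j
            if bias is not None and (idx + 1) % deposit_stride == 0:
                bias.update(x)
                bias_force = bias.force
            if (idx + 1) % record_every == 0 and rec < n_rec:
                out[rec] = x
                rec += 1
        i += m
    return SimResult(positions=out[:rec], dt=dt, record_every=record_every, bias=bias)


# ---------------------------------------------------------------------------
# free-energy estimators


@dataclass(frozen=True)
class FreeEnergyEstimate:
    delta_f: float                   # kcal/mol, enol - keto (bias-based)
    delta_f_reweighted: float | None
    discrepancy: float | None

    def best(self) -> float:
        return self.delta_f


def free_energy_difference(
    bias: AdaptiveBias,
    surface: PTSurface,
    temperature: float = 300.0,
    samples: np.ndarray | None = None,
) -> FreeEnergyEstimate:
    """Enol-minus-keto free-energy difference from the converged bias.

    Uses the well-tempered relation ``F(x) = -gamma/(gamma-1) V(x) + c``
    evaluated at the two basin minima, cross-checked (when samples are
    given) by reweighting samples with ``exp(V(x)/kT)`` and integrating
    each basin.  Raises when the bias never reached one of the basins.
    """
    kt = _kt(temperature)
    v_keto = float(bias.value(surface.keto_position))
    v_enol = float(bias.value(surface.enol_position))
    if min(v_keto, v_enol) < 0.5 * bias.height:
        raise RuntimeError(
            "not converged: the bias never reached both basins "
            f"(V_keto={v_keto:.3g}, V_enol={v_enol:.3g} kcal/mol)"
        )
    if math.isinf(bias.gamma):
        scale = 1.0
    else:
        scale = bias.gamma / (bias.gamma - 1.0)
    # the instantaneous bias oscillates around the converged profile;
    # average Delta V over the tail of the deposition history when the
    # bias logged its basin probes during the run
    if bias.probe_history and bias.probes is not None:
        hist = np.asarray(bias.probe_history)
        tail = hist[len(hist) // 2:]
        mask = tail.min(axis=1) > 0.5 * bias.height
        if mask.any():
            dv = tail[mask, 1] - tail[mask, 0]
            delta_f = float(-scale * dv.mean())
        else:
            delta_f = -scale * (v_enol - v_keto)
    else:
        delta_f = -scale * (v_enol - v_keto)

    delta_rw = None
    disc = None
    if samples is not None and len(samples):
        w = np.exp((np.asarray(bias.value(samples), float) - max(v_keto, v_enol)) / kt)
        keto_side = samples < surface.barrier_position
        z_k = w[keto_side].sum()
        z_e = w[~keto_side].sum()
        if z_k > 0 and z_e > 0:
            delta_rw = float(-kt * math.log(z_e / z_k))
            disc = abs(delta_rw - delta_f)
    return FreeEnergyEstimate(
        delta_f=float(delta_f), delta_f_reweighted=delta_rw, discrepancy=disc
    )


def quadrature_free_energy_difference(
    surface, temperature: float = 300.0, split: float | None = None
) -> float:
    """Direct quadrature oracle: ``-kT ln(Z_enol / Z_keto)`` with basins
    split at the barrier top."""
    kt = _kt(temperature)
    lo, hi = surface.domain
    if split is None:
        split = surface.barrier_position
    z_k, _ = quad(lambda x: math.exp(-surface.energy(x) / kt), lo, split, limit=200)
    z_e, _ = quad(lambda x: math.exp(-surface.energy(x) / kt), split, hi, limit=200)
    return float(-kt * math.log(z_e / z_k))
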