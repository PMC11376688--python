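"""Excited-state decay kinetics and photoisomerization quantum yield.

The S1 population decay of a surface-hopping ensemble is summarized by a
Kaplan-Meier survival curve and by maximum-likelihood fits of
right-censored exponential mixtures,

.. math::

    \\log L = \\sum_{\\mathrm{unc}} \\log \\sum_j \\frac{a_j}{\\tau_j}
              e^{-t/\\tau_j}
            + \\sum_{\\mathrm{cens}} \\log \\sum_j a_j e^{-c/\\tau_j},

with an optional *long-lived* plateau component
``S(t) = p + (1 - p) * sum_j a_j exp(-t / tau_j)`` for ensembles that
carry a distinct subpopulation still excited at the censoring cutoff.
The quantum yield is the fraction of reactive trajectories over the full
ensemble (censored trajectories count as non-reactive), with a Wilson
score interval.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp
from sklearn.base import BaseEstimator

from .io import HopRecord

__all__ = [
    "DecayFit",
    "YieldEstimate",
    "SurvivalCurve",
    "CensoredExponentialMixture",
    "ModelComparison",
    "survival_curve",
    "fit_exponential_mixture",
    "quantum_yield",
    "compare_models",
]


def _split_records(records: Sequence[HopRecord]) -> tuple[np.ndarray, np.ndarray]:
    """(durations, event_observed) arrays from hop records."""
    durations = np.array(
        [r.censor_time if r.censored else r.hop_time for r in records], float
    )
    observed = np.array([not r.censored for r in records], bool)
    return durations, observed


# ---------------------------------------------------------------------------
# survival curve


class SurvivalCurve:
    """Kaplan-Meier product-limit estimate of S(t), right-continuous."""

    def __init__(self, durations: np.ndarray, observed: np.ndarray) -> None:
        from lifelines import KaplanMeierFitter

        if len(durations) == 0:
            raise ValueError("survival curve needs at least one record")
        kmf = KaplanMeierFitter()
        kmf.fit(durations, event_observed=observed)
        sf = kmf.survival_function_
        self.times = sf.index.to_numpy(float)
        self.probabilities = sf.iloc[:, 0].to_numpy(float)
        self._kmf = kmf

    def __call__(self, t) -> np.ndarray | float:
        t = np.asarray(t, float)
        idx = np.searchsorted(self.times, t, side="right") - 1
        vals = self.probabilities[np.clip(idx, 0, len(self.times) - 1)]
        vals = np.where(idx < 0, 1.0, vals)
        return float(vals) if vals.ndim == 0 else vals


def survival_curve(records: Sequence[HopRecord]) -> SurvivalCurve:
    """Kaplan-Meier survival of the excited state over the ensemble."""
    if not records:
        raise ValueError("no hop records given")
    durations, observed = _split_records(records)
    return SurvivalCurve(durations, observed)


# ---------------------------------------------------------------------------
# censored exponential mixture


@dataclass(frozen=True)
class DecayFit:
    """Fitted right-censored exponential-mixture decay."""

    k: int
    lifetimes: tuple[float, ...]        # ps, ascending
    amplitudes: tuple[float, ...]       # sum to 1 over the decaying part
    log_likelihood: float               # nats
    aic: float
    n_used: int
    n_censored: int
    long_lived_fraction: float = 0.0    # plateau weight (0 without plateau)

    def __post_init__(self) -> None:
        if list(self.lifetimes) != sorted(self.lifetimes):
            raise ValueError("lifetimes must be sorted ascending")
        if abs(sum(self.amplitudes) - 1.0) > 1e-9 or min(self.amplitudes) < -1e-12:
            raise ValueError("amplitudes must be non-negative and sum to 1")


class CensoredExponentialMixture(BaseEstimator):
    """MLE of a right-censored exponential mixture (sklearn-style).

    Parameters
    ----------
    k : number of exponential components (1, 2 or 3).
    long_lived : add a plateau component with infinite lifetime, for
        ensembles with a distinct subpopulation that never decays on the
        observation window.
    n_starts : multi-start count; initial lifetimes are quantile-spaced
        over the uncensored times and jittered.
    random_state : seed of the start jitter (fit is deterministic given it).

    Fitted attributes
    -----------------
    ``lifetimes_`` (ascending, ps), ``amplitudes_`` (sum to one over the
    decaying components), ``long_lived_fraction_``, ``log_likelihood_``,
    ``aic_``, ``n_used_``, ``n_censored_``.
    """

    def __init__(
        self,
        k: int = 2,
        long_lived: bool = False,
        n_starts: int = 8,
        random_state: int = 0,
    ) -> None:
        self.k = k
        self.long_lived = long_lived
        self.n_starts = n_starts
        self.random_state = random_state

    # -- likelihood ---------------------------------------------------------

    @staticmethod
    def _nll_grad(theta, t_unc, t_cens, k, long_lived):
        """Negative log-likelihood and its analytic gradient.

        Parameters are ``[log tau_1..k, logits]`` with the last mixture
        weight (the plateau when ``long_lived``) carrying a fixed zero
        logit.
        """
        log_tau = theta[:k]
        tau = np.exp(log_tau)
        n_w = k + (1 if long_lived else 0)
        if n_w > 1:
            w_logits = np.concatenate([theta[k:], [0.0]])
            log_w = w_logits - logsumexp(w_logits)
        else:
            log_w = np.zeros(1)
        w = np.exp(log_w)
        ll = 0.0
        g_lt = np.zeros(k)
        g_w = np.zeros(n_w)  # d ll / d log-weight (pre chain rule to logits)
        if len(t_unc):
            terms = log_w[None, :k] - log_tau[None, :] - t_unc[:, None] / tau[None, :]
            li = logsumexp(terms, axis=1)
            ll += li.sum()
            p = np.exp(terms - li[:, None])          # responsibilities
            g_lt += (p * (t_unc[:, None] / tau[None, :] - 1.0)).sum(axis=0)
            g_w[:k] += p.sum(axis=0)
        if len(t_cens):
            terms = log_w[None, :k] - t_cens[:, None] / tau[None, :]
            if long_lived:
                terms = np.concatenate(
                    [terms, np.broadcast_to(log_w[k], (len(t_cens), 1))], axis=1
                )
            li = logsumexp(terms, axis=1)
            ll += li.sum()
            q = np.exp(terms - li[:, None])
            g_lt += (q[:, :k] * (t_cens[:, None] / tau[None, :])).sum(axis=0)
            g_w += q.sum(axis=0)
        n_obs = len(t_unc) + len(t_cens)
        # d ll / d theta_m = sum_i (p_im - w_m) for the free logits m < n_w-1
        grad = np.concatenate([g_lt, g_w[: n_w - 1] - n_obs * w[: n_w - 1]])
        return -ll, -grad

    @classmethod
    def _nll(cls, theta, t_unc, t_cens, k, long_lived):
        return cls._nll_grad(theta, t_unc, t_cens, k, long_lived)[0]

    def fit(self, durations, event_observed):
        durations = np.asarray(durations, float)
        observed = np.asarray(event_observed, bool)
        if self.k not in (1, 2, 3):
            raise ValueError("k must be 1, 2 or 3")
        t_unc = durations[observed]
        t_cens = durations[~observed]
        if len(t_unc) < 10:
            raise ValueError("need at least 10 uncensored records")

        k = self.k
        if k == 1 and not self.long_lived:
            # closed-form MLE: tau = total observed time / number of events
            tau = float((t_unc.sum() + t_cens.sum()) / len(t_unc))
            ll = -self._nll(np.array([math.log(tau)]), t_unc, t_cens, 1, False)
            self._set_fit((tau,), (1.0,), 0.0, float(ll), len(durations), len(t_cens))
            return self

    # multi-start numerical optimization
        rng = np.random.default_rng(self.random_state)
        q = np.quantile(t_unc, (np.arange(k) + 1.0) / (k + 1.0))
        q = np.maximum(q, 1e-6)
        best = None
        for s in range(self.n_starts):
            jitter = rng.normal(0.0, 0.4, k) if s else np.zeros(k)
            x0 = list(np.log(q) + jitter)
            if self.long_lived:
                # plateau weight carries the fixed zero logit; start the k
                # free exponential logits at the observed censored fraction
                frac = min(max(len(t_cens) / len(durations), 1e-4), 1.0 - 1e-4)
                x0 += [math.log((1.0 - frac) / (k * frac))] * k
            else:
                x0 += [0.0] * (k - 1)
            res = minimize(
                self._nll_grad,
                np.asarray(x0, float),
                args=(t_unc, t_cens, k, self.long_lived),
                method="L-BFGS-B",
                jac=True,
                options={"maxiter": 500, "ftol": 1e-13, "gtol": 1e-10},
            )
            if best is None or res.fun < best.fun:
                best = res
        if best is None or not np.all(np.isfinite(best.x)):
            raise RuntimeError("mixture fit failed to converge from any start")

        theta = best.x
        tau = np.exp(theta[:k])
        n_w = k + (1 if self.long_lived else 0)
        if n_w > 1:
            logits = np.concatenate([theta[k:], [0.0]])
            w = np.exp(logits - logsumexp(logits))
        else:
            w = np.ones(1)
        plateau = float(w[k]) if self.long_lived else 0.0
        amps = w[:k] / w[:k].sum()
        order = np.argsort(tau)
        self._set_fit(
            tuple(float(t) for t in tau[order]),
            tuple(float(a) for a in amps[order]),
            plateau,
            float(-best.fun),
            len(durations),
            len(t_cens),
        )
        return self

    def _set_fit(self, lifetimes, amplitudes, plateau, ll, n_used, n_censored):
        self.lifetimes_ = lifetimes
        self.amplitudes_ = amplitudes
        self.long_lived_fraction_ = plateau
        self.log_likelihood_ = ll
        n_params = 2 * self.k - 1 + (1 if self.long_lived else 0)
        self.aic_ = 2.0 * n_params - 2.0 * ll
        self.n_used_ = n_used
        self.n_censored_ = n_censored

    def decay_fit(self) -> DecayFit:
        return DecayFit(
            k=self.k,
            lifetimes=self.lifetimes_,
            amplitudes=self.amplitudes_,
            log_likelihood=self.log_likelihood_,
            aic=self.aic_,
            n_used=self.n_used_,
            n_censored=self.n_censored_,
            long_lived_fraction=self.long_lived_fraction_,
        )

    def survival(self, t) -> np.ndarray:
        """Model survival S(t) at the fitted parameters."""
        t = np.asarray(t, float)
        amps = np.asarray(self.amplitudes_) * (1.0 - self.long_lived_fraction_)
        s = self.long_lived_fraction_ + np.sum(
            amps[None, :] * np.exp(-t[..., None] / np.asarray(self.lifetimes_)), axis=-1
        )
        return s


def fit_exponential_mixture(
    records: Sequence[HopRecord],
    k: int = 2,
    long_lived: bool = False,
    random_state: int = 0,
) -> DecayFit:
    """Fit a right-censored exponential mixture to hop records."""
    durations, observed = _split_records(records)
    est = CensoredExponentialMixture(
        k=k, long_lived=long_lived, random_state=random_state
    ).fit(durations, observed)
    return est.decay_fit()


# ---------------------------------------------------------------------------
# quantum yield


@dataclass(frozen=True)
class YieldEstimate:
    n_reactive: int
    n_total: int
    point: float
    ci_low: float
    ci_high: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.ci_low <= self.point + 1e-12:
            raise ValueError("interval must bracket the point estimate")
        if not self.point - 1e-12 <= self.ci_high <= 1.0:
            raise ValueError("interval must bracket the point estimate")


def quantum_yield(records: Sequence[HopRecord]) -> YieldEstimate:
    """Photoisomerization quantum yield with a 95% Wilson interval.

    Censored (never-hopped) trajectories count as non-reactive in the
    denominator, matching the convention of counting reactive
    trajectories against the full ensemble.
    """
    from statsmodels.stats.proportion import proportion_confint

    n_total = len(records)
    if n_total == 0:
        raise ValueError("no hop records given")
    n_reactive = sum(1 for r in records if r.reactive)
    lo, hi = proportion_confint(n_reactive, n_total, alpha=0.05, method="wilson")
    return YieldEstimate(
        n_reactive=n_reactive,
        n_total=n_total,
        point=n_reactive / n_total,
        ci_low=max(0.0, float(lo)),
        ci_high=min(1.0, float(hi)),
    )


# ---------------------------------------------------------------------------
# model comparison


@dataclass(frozen=True)
class ModelComparison:
    selected_k: int
    fits: tuple[DecayFit, ...]

    @property
    def delta_aic(self) -> dict[int, float]:
        best = min(f.aic for f in self.fits)
        return {f.k: f.aic - best for f in self.fits}


def compare_models(
    records: Sequence[HopRecord],
    k_max: int = 3,
    long_lived: bool = False,
    random_state: int = 0,
) -> ModelComparison:
    """Fit k = 1..k_max mixtures and select the minimal-AIC model."""
    fits = tuple(
        fit_exponential_mixture(records, k=k, long_lived=long_lived, random_state=random_state)
        for k in range(1, k_max + 1)
    )
    selected = min(fits, key=lambda f: f.aic).k
    return ModelComparison(selected_k=selected, fits=fits)
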