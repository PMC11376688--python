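"""Survival curves, censored mixture MLE, quantum yield."""

import numpy as np
import pytest
from scipy.stats import binom

from phytotraj import kinetics as kin
from phytotraj import synth
from phytotraj.io import HopRecord


def _records(times, censored_flags, censor_time=20.0, reactive=None):
    out = []
    for i, (t, c) in enumerate(zip(times, censored_flags)):
        r = bool(reactive[i]) if reactive is not None else False
        out.append(
            HopRecord(
                f"t{i:03d}",
                None if c else float(t),
                float(t) if c else censor_time,  # censored rows end at t
                r and not c,
            )
        )
    return out


class TestSurvivalCurve:
    def test_all_censored_stays_at_one(self):
        recs = _records([20.0] * 5, [True] * 5)
        s = kin.survival_curve(recs)
        assert s(10.0) == pytest.approx(1.0)

    def test_empirical_survival_no_censoring(self):
        recs = _records([1, 2, 3, 4], [False] * 4)
        s = kin.survival_curve(recs)
        assert s(2.5) == pytest.approx(0.5)

    def test_product_limit_hand_table(self):
        """Mixed censoring against a hand-computed Kaplan-Meier table."""
        times = [1, 2, 3, 4, 5, 6, 7, 8, 9, 10]
        cens = [False, True, False, False, True, False, False, True, False, False]
        s = kin.survival_curve(_records(times, cens))
        # at-risk/product-limit arithmetic done by hand:
        assert s(1.0) == pytest.approx(0.9)
        assert s(4.5) == pytest.approx(0.9 * (7 / 8) * (6 / 7))
        assert s(7.5) == pytest.approx(0.675 * (4 / 5) * (3 / 4))
        assert s(9.5) == pytest.approx(0.405 * 0.5)
        assert s(10.0) == pytest.approx(0.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            kin.survival_curve([])


class TestMixtureFit:
    def test_k1_closed_form_is_sample_mean(self):
        rng = np.random.default_rng(3)
        t = rng.exponential(2.0, 50)
        fit = kin.fit_exponential_mixture(_records(t, [False] * 50), k=1)
        assert fit.lifetimes[0] == pytest.approx(t.mean(), abs=1e-12)

    def test_k1_censored_closed_form(self):
        """With censoring: tau = total time at risk / number of events."""
        t = [1.0, 2.0, 3.0, 4.0] * 5
        cens = ([False] * 15) + ([True] * 5)
        recs = _records(t, cens)
        fit = kin.fit_exponential_mixture(recs, k=1)
        total = sum(t)  # durations: hop times plus censoring times
        assert fit.lifetimes[0] == pytest.approx(total / 15, abs=1e-12)

    def test_too_few_uncensored_rejected(self):
        recs = _records([1.0] * 5, [False] * 5)
        with pytest.raises(ValueError, match="10 uncensored"):
            kin.fit_exponential_mixture(recs, k=2)

    def test_grid_search_oracle(self):
        """The optimizer's censored-mixture log-likelihood dominates an
        exhaustive grid at 0.01 resolution around the generating values."""
        rng = np.random.default_rng(7)
        n = 200
        comp = rng.random(n) < 0.6
        t = np.where(comp, rng.exponential(0.7, n), rng.exponential(4.0, n))
        cens = t >= 20.0
        t = np.where(cens, 20.0, t)
        recs = _records(t, cens)
        fit = kin.fit_exponential_mixture(recs, k=2)

        tu, tc = t[~cens], t[cens]
        tau1 = np.arange(0.40, 1.20, 0.01)
        tau2 = np.arange(2.50, 6.50, 0.01)
        assert tau1[0] < fit.lifetimes[0] < tau1[-1]
        assert tau2[0] < fit.lifetimes[1] < tau2[-1]
        d1 = np.exp(-tu[:, None] / tau1) / tau1          # (n_unc, n1)
        d2 = np.exp(-tu[:, None] / tau2) / tau2          # (n_unc, n2)
        s1 = np.exp(-tc[:, None] / tau1)
        s2 = np.exp(-tc[:, None] / tau2)
        best = -np.inf
        for a1 in np.arange(0.01, 1.0, 0.01):
            ll = np.log(
                a1 * d1[:, :, None] + (1 - a1) * d2[:, None, :]
            ).sum(axis=0)
            if len(tc):
                ll = ll + np.log(
                    a1 * s1[:, :, None] + (1 - a1) * s2[:, None, :]
                ).sum(axis=0)
            best = max(best, float(ll.max()))
        assert fit.log_likelihood >= best - 1e-6
        assert fit.log_likelihood - best < 0.05

    def test_mle_dominates_truth(self):
        """Fitted likelihood >= likelihood at the generating parameters."""
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            n = 400
            comp = rng.random(n) < 0.5
            t = np.where(comp, rng.exponential(1.0, n), rng.exponential(5.0, n))
            cens = t >= 15.0
            t = np.where(cens, 15.0, t)
            recs = _records(t, cens, censor_time=15.0)
            fit = kin.fit_exponential_mixture(recs, k=2)
            tu, tc = t[~cens], t[cens]
            ll_true = (
                np.log(0.5 * np.exp(-tu / 1.0) / 1.0 + 0.5 * np.exp(-tu / 5.0) / 5.0).sum()
                + np.log(0.5 * np.exp(-tc / 1.0) + 0.5 * np.exp(-tc / 5.0)).sum()
            )
            assert fit.log_likelihood >= ll_true - 1e-9

    def test_preset_scale_recovery_over_seeds(self):
        """Median relative lifetime error < 10% over 20 preset-scale fits;
        the fast/slow ordering never swaps after sorting."""
        errs_fast, errs_slow = [], []
        for seed in range(200, 220):
            cfg = synth.get_preset("agp2-sh", seed=seed)
            ens = synth.generate_sh_ensemble(cfg, trajectories=False)
            fit = kin.fit_exponential_mixture(ens.hop_records, k=2, long_lived=True)
            assert fit.lifetimes[0] < fit.lifetimes[1]
            errs_fast.append(abs(fit.lifetimes[0] - cfg.tau_fast) / cfg.tau_fast)
            errs_slow.append(abs(fit.lifetimes[1] - cfg.tau_slow) / cfg.tau_slow)
        assert np.median(errs_fast) < 0.10
        assert np.median(errs_slow) < 0.10


class TestQuantumYield:
    def test_zero_reactive(self):
        recs = _records([1.0] * 10, [False] * 10, reactive=[False] * 10)
        y = kin.quantum_yield(recs)
        assert y.point == 0.0 and y.ci_low == 0.0

    def test_one_of_four(self):
        recs = _records([1, 2, 3, 4], [False] * 4, reactive=[True, False, False, False])
        assert kin.quantum_yield(recs).point == pytest.approx(0.25)

    def test_order_invariance(self, sh_records_preset):
        _, ens = sh_records_preset
        recs = list(ens.hop_records)
        y1 = kin.quantum_yield(recs)
        y2 = kin.quantum_yield(list(reversed(recs)))
        assert (y1.point, y1.ci_low, y1.ci_high) == (y2.point, y2.ci_low, y2.ci_high)

    def test_wilson_coverage_by_binomial_enumeration(self):
        """At n = 40, enumerated binomial coverage of the 95% Wilson
        interval stays near nominal for a range of true yields."""
        n = 40
        intervals = []
        for k in range(n + 1):
            recs = _records(
                np.ones(n), [False] * n, reactive=[i < k for i in range(n)]
            )
            y = kin.quantum_yield(recs)
            assert 0.0 <= y.ci_low <= y.point <= y.ci_high <= 1.0
            intervals.append((y.ci_low, y.ci_high))
        for p in (0.1, 0.28, 0.5, 0.75):
            cover = sum(
                binom.pmf(k, n, p)
                for k, (lo, hi) in enumerate(intervals)
                if lo <= p <= hi
            )
            assert cover >= 0.92

    def test_ci_width_shrinks_as_root_n(self):
        def width(n):
            k = round(0.28 * n)
            recs = _records(
                np.ones(n), [False] * n, reactive=[i < k for i in range(n)]
            )
            y = kin.quantum_yield(recs)
            return y.ci_high - y.ci_low

        ratio = width(500) / width(50_000)
        assert 10.0 * 0.8 <= ratio <= 10.0 * 1.2

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            kin.quantum_yield([])


class TestModelComparison:
    def test_monoexponential_selects_k1(self):
        rng = np.random.default_rng(21)
        t = rng.exponential(2.0, 5000)
        recs = _records(t, [False] * 5000, censor_time=1e9)
        comp = kin.compare_models(recs, k_max=3)
        assert comp.selected_k == 1

    def test_below_precondition_errors(self):
        recs = _records([1.0] * 6, [False] * 6)
        with pytest.raises(ValueError):
            kin.compare_models(recs)
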