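import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar

from petasp.phantoms import CohortSimSpec, simulate_cohort
from petasp.survival_stats import (
    cox_fit,
    km_estimate,
    logrank,
    multivariate_select,
    optimal_cutoff,
    spearman,
    survival_at,
)


def efron_loglik_naive(beta: float, x, time, event) -> float:
    """Independent single-covariate Efron log partial likelihood,
    written with explicit loops (no shared code with the package)."""
    x = np.asarray(x, float)
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    ll = 0.0
    for tau in np.unique(time[event == 1]):
        D = np.where((time == tau) & (event == 1))[0]
        R = np.where(time >= tau)[0]
        m = len(D)
        s_r = sum(np.exp(beta * x[i]) for i in R)
        s_d = sum(np.exp(beta * x[i]) for i in D)
        for i in D:
            ll += beta * x[i]
        for l in range(m):
            ll -= np.log(s_r - (l / m) * s_d)
    return ll


class TestSpearman:
    def test_monotone_is_one(self):
        x = np.array([1.0, 2.0, 5.0, 9.0])
        assert spearman(x, np.exp(x))[0] == pytest.approx(1.0)

    def test_hand_example(self):
        rho, _ = spearman(np.array([1, 2, 3]), np.array([3, 1, 2]))
        assert rho == pytest.approx(-0.5)

    def test_constant_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            spearman(np.array([1.0, 2.0, 3.0]), np.ones(3))


class TestCoxFit:
    def test_exchangeable_groups_null(self):
        base = pd.DataFrame({"time_months": [1, 2, 3, 5, 8], "event": [1, 1, 0, 1, 1]})
        df = pd.concat(
            [base.assign(x=0.0), base.assign(x=1.0)], ignore_index=True
        )
        fit = cox_fit(df, "x")
        assert fit.beta[0] == pytest.approx(0.0, abs=1e-8)
        assert fit.hr[0] == pytest.approx(1.0, abs=1e-8)

    def test_four_subject_closed_form(self):
        """Score equation u^2 - u - 4 = 0 -> HR = (1 + sqrt(17)) / 2."""
        df = pd.DataFrame({"time_months": [1, 2, 3, 4], "event": [1, 1, 1, 1],
                           "x": [1.0, 0.0, 1.0, 0.0]})
        fit = cox_fit(df, "x")
        assert fit.hr[0] == pytest.approx((1 + np.sqrt(17)) / 2, abs=1e-8)

    def test_matches_independent_maximizer(self):
        """Newton solution equals a derivative-free maximization of an
        independently coded Efron partial likelihood."""
        for i in range(5):
            d = simulate_cohort(CohortSimSpec(n=60, seed=300 + i))
            fit = cox_fit(d, "asp_pct")
            res = minimize_scalar(
                lambda b: -efron_loglik_naive(
                    b, d.asp_pct, d.time_months, d.event
                ),
                bounds=(-2, 2),
                method="bounded",
                options={"xatol": 1e-12},
            )
            assert abs(fit.beta[0] - res.x) < 1e-6

    def test_matches_lifelines(self):
        from lifelines import CoxPHFitter

        d = simulate_cohort(CohortSimSpec(n=80, seed=17))
        fit = cox_fit(d, ["asp_pct", "mtv_ml"])
        cph = CoxPHFitter().fit(
            d[["asp_pct", "mtv_ml", "time_months", "event"]], "time_months", "event"
        )
        assert np.allclose(fit.beta, cph.params_.to_numpy(), atol=1e-5)
        assert np.allclose(fit.se, cph.standard_errors_.to_numpy(), atol=1e-5)

    def test_monotone_time_transform_invariance(self):
        """With a binary covariate and no ties, only the time order matters."""
        rng = np.random.default_rng(8)
        t = rng.exponential(10, size=30)
        event = rng.integers(0, 2, 30)
        event[:2] = 1
        df = pd.DataFrame({"time_months": t, "event": event,
                           "x": rng.integers(0, 2, 30).astype(float)})
        f1 = cox_fit(df, "x")
        df2 = df.assign(time_months=np.log1p(df.time_months) ** 2)
        f2 = cox_fit(df2, "x")
        assert f1.beta[0] == pytest.approx(f2.beta[0], abs=1e-10)

    def test_separation_flagged(self):
        df = pd.DataFrame({"time_months": [1, 2, 3, 10, 11, 12],
                           "event": [1, 1, 1, 1, 1, 1],
                           "x": [1.0, 1.0, 1.0, 0.0, 0.0, 0.0]})
        with pytest.warns(RuntimeWarning, match="monotone"):
            fit = cox_fit(df, "x")
        assert fit.monotone

    def test_constant_covariate_rejected(self):
        df = pd.DataFrame({"time_months": [1, 2, 3], "event": [1, 1, 1], "x": [1.0] * 3})
        with pytest.raises(ValueError, match="constant"):
            cox_fit(df, "x")


class TestOptimalCutoff:
    def test_matches_exhaustive_enumeration(self):
        """The scan equals an independent exhaustive scan that picks the
        smallest Wald p over all IQR-interior distinct values."""
        from lifelines import CoxPHFitter

        d = simulate_cohort(CohortSimSpec(n=60, seed=42))
        res = optimal_cutoff(d, "asp_pct")
        x = d.asp_pct.to_numpy()
        q1, q3 = np.quantile(x, [0.25, 0.75])
        best = None
        for v in np.unique(x[(x >= q1) & (x <= q3)]):
            ind = (x > v).astype(float)
            if ind.sum() in (0, len(x)):
                continue
            dd = pd.DataFrame({"i": ind, "t": d.time_months, "e": d.event})
            cph = CoxPHFitter().fit(dd, "t", "e")
            z = abs(float(cph.summary["z"].iloc[0]))
            if best is None or z > best[1] + 1e-9:
                best = (v, z)
        assert res.cutoff == pytest.approx(best[0])
        assert q1 <= res.cutoff <= q3

    def test_direction_normalized_hr_ge_one(self):
        d = simulate_cohort(CohortSimSpec(n=80, seed=21))
        for cov in ("asp_pct", "solidity"):
            res = optimal_cutoff(d, cov)
            assert res.fit.hr[0] >= 1.0
            assert res.direction in (">", "<")
        # solidity is protective by construction: high group is below cutoff
        assert optimal_cutoff(d, "solidity").direction == "<"

    def test_clear_structure_recovered(self):
        """All events concentrated above x = 7 -> cutoff found there."""
        df = pd.DataFrame(
            {
                "x": np.arange(1.0, 13.0),
                "time_months": [20.0] * 7 + [2.0, 3.0, 2.5, 4.0, 3.5],
                "event": [0] * 7 + [1] * 5,
            }
        )
        res = optimal_cutoff(df, "x")
        assert 6.0 <= res.cutoff <= 8.0
        assert res.direction == ">"

    def test_constant_covariate_rejected(self):
        df = pd.DataFrame({"x": np.ones(20), "time_months": np.arange(1, 21),
                           "event": [1] * 20})
        with pytest.raises(ValueError):
            optimal_cutoff(df, "x")

    def test_scan_table_complete(self):
        d = simulate_cohort(CohortSimSpec(n=40, seed=1))
        res = optimal_cutoff(d, "mtv_ml")
        x = d.mtv_ml.to_numpy()
        q1, q3 = np.quantile(x, [0.25, 0.75])
        assert len(res.scan) == ((np.unique(x) >= q1) & (np.unique(x) <= q3)).sum()


class TestMultivariateSelect:
    def test_single_admitted_equals_univariate(self):
        d = simulate_cohort(CohortSimSpec(n=100, seed=33))
        sel = multivariate_select(d, ["asp_pct"])
        uni = cox_fit(d, "asp_pct")
        assert sel.final.beta[0] == pytest.approx(uni.beta[0])

    def test_collinear_pair_admits_one(self):
        """TLG and MTV (rho ~ 0.96): exactly one enters the joint model."""
        d = simulate_cohort(CohortSimSpec(n=200, seed=5, covariate="mtv_ml"))
        sel = multivariate_select(d, ["mtv_ml", "tlg_ml"])
        assert len(sel.collinear_dropped) == 1
        assert len(sel.final.covariates) == 1

    def test_true_effect_retained(self):
        """One real effect + one noise covariate: the real one survives
        backward elimination in most replicates."""
        rng = np.random.default_rng(0)
        kept = 0
        n_rep = 60
        for i in range(n_rep):
            d = simulate_cohort(CohortSimSpec(n=200, seed=40_000 + i))
            spec = CohortSimSpec(n=200, seed=40_000 + i)
            d["asp_high"] = (d.asp_pct > spec.true_cutoff()).astype(float)
            d["noise"] = rng.normal(size=len(d))
            try:
                sel = multivariate_select(d, ["asp_high", "noise"])
            except ValueError:
                continue
            kept += "asp_high" in sel.final.covariates
        assert kept / n_rep > 0.8

    def test_nothing_admitted_rejected(self):
        rng = np.random.default_rng(3)
        d = simulate_cohort(CohortSimSpec(n=50, hazard_ratio=1.0, seed=9))
        d["pure_noise"] = rng.normal(size=len(d))
        fit = cox_fit(d, "pure_noise")
        if fit.p[0] > 0.10:
            with pytest.raises(ValueError, match="admitted"):
                multivariate_select(d, ["pure_noise"])


class TestKaplanMeier:
    def test_no_events_flat(self):
        c = km_estimate([3, 5, 8], [0, 0, 0])
        assert np.all(c.survival == 1.0)

    def test_hand_product_limit(self):
        c = km_estimate([2, 4, 5, 7, 9], [1, 1, 0, 1, 0])
        assert survival_at(c, 2) == pytest.approx(0.8)
        assert survival_at(c, 4) == pytest.approx(0.6)
        assert survival_at(c, 7) == pytest.approx(0.3)
        assert survival_at(c, 0.5) == 1.0

    def test_reduces_to_empirical_without_censoring(self):
        times = [1.0, 2.0, 3.0, 4.0, 5.0]
        c = km_estimate(times, [1] * 5)
        for t in times:
            assert survival_at(c, t) == pytest.approx(np.mean(np.array(times) > t))

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            km_estimate([], [])


class TestLogrank:
    def test_identical_groups_null(self):
        t = [1, 2, 3, 4, 5]
        e = [1, 1, 0, 1, 1]
        stat, p = logrank(t + t, e + e, [0] * 5 + [1] * 5)
        assert stat == pytest.approx(0.0, abs=1e-10)
        assert p == pytest.approx(1.0)

    def test_matches_occurrence_expectation_oracle(self):
        """Observed-minus-expected summation on small cohorts."""
        rng = np.random.default_rng(12)
        for _ in range(10):
            n = int(rng.integers(8, 20))
            time = np.round(rng.exponential(10, n), 1) + 0.1
            event = rng.integers(0, 2, n)
            group = rng.integers(0, 2, n)
            if len(np.unique(group)) < 2 or event.sum() == 0:
                continue
            o_minus_e = 0.0
            var = 0.0
            for tau in np.unique(time[event == 1]):
                at_risk = time >= tau
                n_tot = at_risk.sum()
                n_1 = (at_risk & (group == 1)).sum()
                d_tot = ((time == tau) & (event == 1)).sum()
                d_1 = ((time == tau) & (event == 1) & (group == 1)).sum()
                o_minus_e += d_1 - d_tot * n_1 / n_tot
                if n_tot > 1:
                    var += (
                        d_tot * (n_1 / n_tot) * (1 - n_1 / n_tot) * (n_tot - d_tot) / (n_tot - 1)
                    )
            if var == 0:
                continue
            expected = o_minus_e**2 / var
            stat, _ = logrank(time, event, group)
            assert stat == pytest.approx(expected, rel=1e-6)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError, match="two groups"):
            logrank([1, 2], [1, 1], [0, 0])
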