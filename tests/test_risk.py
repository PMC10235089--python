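"""Elastic-net Cox risk model: OSRS, stratification, roles, evaluation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phenotil import (
    cluster_roles,
    compute_osrs,
    evaluate_survival,
    fit_risk_model,
    gen_cluster_counts,
    gen_survival,
    stratify,
)
from phenotil.risk import (
    DegenerateStratificationError,
    NoEventsError,
    PenaltyConfig,
    RiskModel,
)
from phenotil.synthetic import STRONG_BETA_STAR

from _oracles import breslow_cox_fit, manual_logrank

BETA_AD = np.array([4.0, -3.2, -10.2, 15.4, 0.2, 0.5, 0.2, -12.7])
BETA_SCC = np.array([-2.5, 9.9, 0.2, 5.2, 1.8, 8.9, -2.6, 2.1])


class TestOsrs:
    def test_published_ad_vector_unit_count(self):
        """A patient with a single C4 TIL scores exactly beta_4 = 15.4."""
        e4 = np.zeros((1, 8))
        e4[0, 3] = 1.0
        assert compute_osrs(e4, BETA_AD)[0] == pytest.approx(15.4)

    def test_zero_counts_zero_score(self):
        assert compute_osrs(np.zeros((3, 8)), BETA_AD).tolist() == [0.0] * 3

    def test_matches_brute_force_summation(self):
        rng = np.random.default_rng(0)
        N = rng.integers(0, 40, (20, 8)).astype(float)
        beta = rng.normal(0, 3, 8)
        expected = [sum(N[i, j] * beta[j] for j in range(8)) for i in range(20)]
        np.testing.assert_allclose(compute_osrs(N, beta), expected)

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 2**31 - 1), st.floats(-5, 5), st.floats(-5, 5))
    def test_linearity(self, seed, a, b):
        rng = np.random.default_rng(seed)
        N1, N2 = rng.normal(size=(2, 6, 8))
        beta = rng.normal(size=8)
        np.testing.assert_allclose(
            compute_osrs(a * N1 + b * N2, beta),
            a * compute_osrs(N1, beta) + b * compute_osrs(N2, beta),
            atol=1e-8,
        )


class TestStratify:
    def test_median_cutoff_example(self):
        groups = stratify(np.array([1.0, 2.0, 3.0, 4.0]), 2.5)
        assert groups.tolist() == ["low", "low", "high", "high"]

    def test_ties_go_low(self):
        assert (stratify(np.full(5, 3.0), 3.0) == "low").all()

    def test_partition(self):
        rng = np.random.default_rng(1)
        s = rng.normal(size=101)
        g = stratify(s, np.median(s))
        assert (g == "low").sum() + (g == "high").sum() == 101
        # unique scores: sizes ceil/floor of n/2
        assert (g == "high").sum() == 50


class TestClusterRoles:
    def test_ad_constructive_set(self):
        roles = cluster_roles(BETA_AD)
        cons = {f"C{i+1}" for i, r in enumerate(roles) if r == "constructive"}
        assert cons == {"C1", "C4", "C5", "C6", "C7"}
        obs = {f"C{i+1}" for i, r in enumerate(roles) if r == "obstructive"}
        assert obs == {"C2", "C3", "C8"}

    def test_scc_sign_rule(self):
        roles = cluster_roles(BETA_SCC)
        cons = {f"C{i+1}" for i, r in enumerate(roles) if r == "constructive"}
        assert cons == {"C2", "C3", "C4", "C5", "C6", "C8"}
        assert {f"C{i+1}" for i, r in enumerate(roles) if r == "obstructive"} == {"C1", "C7"}

    def test_zero_beta_all_neutral(self):
        assert cluster_roles(np.zeros(8)) == ["neutral"] * 8


def _cohort(n=300, beta=STRONG_BETA_STAR, seed=0, censor=0.3):
    N = gen_cluster_counts(n, 30.0, seed=seed)
    surv = gen_survival(N, beta, censor_rate=censor, seed=seed + 1000)
    return N, surv


class TestFitRiskModel:
    def test_planted_sign_recovery(self):
        N, surv = _cohort(seed=0)
        rm = fit_risk_model(N, surv, seed=0)
        assert (np.sign(rm.beta) == np.sign(STRONG_BETA_STAR)).sum() >= 7

    def test_deterministic(self):
        N, surv = _cohort(n=100, seed=1)
        a = fit_risk_model(N, surv, seed=3)
        b = fit_risk_model(N, surv, seed=3)
        np.testing.assert_array_equal(a.beta, b.beta)
        assert a.alpha == b.alpha and a.cutoff == b.cutoff

    def test_all_censored_raises(self):
        N = gen_cluster_counts(50, 20.0, seed=2)
        surv = gen_survival(N, STRONG_BETA_STAR, censor_rate=0.0, seed=2)
        surv["event"] = 0
        with pytest.raises(NoEventsError):
            fit_risk_model(N, surv)

    def test_too_small_cohort_raises(self):
        N, surv = _cohort(n=20, seed=3)
        with pytest.raises(ValueError, match="n >= 30"):
            fit_risk_model(N, surv)

    def test_zero_variance_column_forced_zero(self):
        N, surv = _cohort(n=100, seed=4)
        N[:, 5] = 7.0
        with pytest.warns(UserWarning, match="zero-variance"):
            rm = fit_risk_model(N, surv, seed=0)
        assert rm.beta[5] == 0.0

    def test_duplication_invariance_of_partial_likelihood(self):
        """Breslow partial-likelihood maximizer is invariant to duplicating
        every patient; the fitted model tracks that oracle."""
        rng = np.random.default_rng(5)
        X = rng.normal(size=(60, 3))
        t = rng.exponential(np.exp(-X @ [1.0, -0.5, 0.2]))
        e = np.ones(60, int)
        b1 = breslow_cox_fit(X, t, e)
        b2 = breslow_cox_fit(np.vstack([X, X]), np.concatenate([t, t]),
                             np.concatenate([e, e]))
        np.testing.assert_allclose(b1, b2, atol=1e-6)

    def test_coefficients_track_independent_coxnet(self):
        """Cross-check against an independently implemented elastic-net Cox."""
        sksurv = pytest.importorskip("sksurv.linear_model")
        N, surv = _cohort(seed=6)
        rm = fit_risk_model(N, surv, penalty=PenaltyConfig(alphas=(0.01,)), seed=0)
        y = np.array(list(zip(surv.event.astype(bool), surv.time)),
                     dtype=[("e", bool), ("t", float)])
        cox = sksurv.CoxnetSurvivalAnalysis(l1_ratio=0.5, alphas=[0.01])
        cox.fit(np.asarray(N), y)
        other = cox.coef_[:, 0]
        cos = (rm.beta @ other) / (np.linalg.norm(rm.beta) * np.linalg.norm(other))
        assert cos > 0.95

    def test_json_round_trip(self, tmp_path):
        N, surv = _cohort(n=100, seed=7)
        rm = fit_risk_model(N, surv, seed=0)
        rm.to_json(tmp_path / "rm.json")
        loaded = RiskModel.from_json(tmp_path / "rm.json")
        np.testing.assert_array_equal(rm.beta, loaded.beta)
        np.testing.assert_array_equal(rm.scores(N), loaded.scores(N))


class TestEvaluate:
    def test_identical_groups_null(self):
        rng = np.random.default_rng(8)
        t = rng.exponential(30, 40)
        surv = pd.DataFrame({
            "patient_id": [f"p{i}" for i in range(80)],
            "time": np.concatenate([t, t]),
            "event": 1,
        })
        groups = np.array(["low"] * 40 + ["high"] * 40)
        rep = evaluate_survival(surv, groups=groups)
        assert rep.hr == pytest.approx(1.0, abs=1e-6)
        assert rep.logrank_p > 0.99

    def test_perfect_ordering_gives_c_one(self):
        n = 30
        t = np.arange(1, n + 1, dtype=float)
        surv = pd.DataFrame({"patient_id": [f"p{i}" for i in range(n)],
                             "time": t, "event": 1})
        scores = -t  # higher score = earlier death
        rep = evaluate_survival(surv, scores=scores)
        assert rep.c_index == 1.0

    def test_logrank_matches_manual_oracle(self):
        t = np.array([2.0, 4.0, 5.0, 7.0, 3.0, 6.0, 8.0, 9.0])
        e = np.array([1, 1, 0, 1, 1, 1, 1, 0])
        g = np.array(["low"] * 4 + ["high"] * 4)
        surv = pd.DataFrame({"patient_id": [f"p{i}" for i in range(8)],
                             "time": t, "event": e})
        rep = evaluate_survival(surv, groups=g)
        from scipy.stats import chi2
        stat = manual_logrank(t[:4], e[:4], t[4:], e[4:])
        assert rep.logrank_p == pytest.approx(chi2.sf(stat, 1), rel=1e-6)

    def test_empty_group_raises(self):
        surv = pd.DataFrame({"patient_id": ["a", "b"], "time": [1.0, 2.0],
                             "event": [1, 1]})
        with pytest.raises(DegenerateStratificationError):
            evaluate_survival(surv, groups=np.array(["low", "low"]))

    def test_km_curves_monotone_from_one(self):
        N, surv = _cohort(n=120, seed=9)
        scores = compute_osrs(N, STRONG_BETA_STAR)
        rep = evaluate_survival(surv, scores=scores)
        for df in rep.km.values():
            s = df["survival"].to_numpy()
            assert s[0] == 1.0
            assert (np.diff(s) <= 1e-12).all()

    def test_planted_effect_separates_groups(self):
        N, surv = _cohort(n=300, seed=10)
        scores = compute_osrs(N, STRONG_BETA_STAR)
        rep = evaluate_survival(surv, scores=scores)
        assert rep.hr > 1
        assert rep.logrank_p < 0.01
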