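import math

import numpy as np
import pandas as pd
import pytest
from lifelines.statistics import logrank_test

from vfprog.survival import breslow_test, cox_robust, km_estimate
from vfprog.synth import simulate_survival_table


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def weighted_logrank_oracle(df, weight="gehan"):
    """Direct summation of U = sum_j w_j (O_j - E_j) and its variance."""
    times = np.sort(df.loc[df.status == 1, "time"].unique())
    U = V = 0.0
    for s in times:
        at = df.time >= s
        n = int(at.sum())
        n1 = int((at & (df.group == 1)).sum())
        d = int(((df.time == s) & (df.status == 1)).sum())
        d1 = int(((df.time == s) & (df.status == 1) & (df.group == 1)).sum())
        w = n if weight == "gehan" else 1.0
        U += w * (d1 - d * n1 / n)
        if n > 1:
            V += w ** 2 * d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return U ** 2 / V


def cox_sandwich_oracle(df, covs, cluster):
    """Score-residual sandwich at the fitted beta (Breslow form; the
    fixture has no tied event times, where Breslow and Efron coincide)."""
    fit = cox_robust(df, covariates=covs, cluster_col=cluster,
                     scales={c: 1.0 for c in covs})
    beta = fit.summary["coef"].to_numpy()
    X = df[list(covs)].to_numpy(float)
    t = df["time"].to_numpy(float)
    e = df["status"].to_numpy(int)
    r = np.exp(X @ beta)
    n, p = X.shape

    def risk(s):
        return t >= s

    def xbar(s):
        a = risk(s)
        return (r[a, None] * X[a]).sum(0) / r[a].sum()

    U = np.zeros((n, p))
    info = np.zeros((p, p))
    for i in range(n):
        U[i] = e[i] * (X[i] - xbar(t[i]))
        for j in range(n):
            if e[j] and t[j] <= t[i]:
                U[i] -= r[i] * (X[i] - xbar(t[j])) / r[risk(t[j])].sum()
    for j in range(n):
        if e[j]:
            a = risk(t[j])
            xb = xbar(t[j])
            dev = X[a] - xb
            info += (r[a, None, None] * dev[:, :, None] * dev[:, None, :]
                     ).sum(0) / r[a].sum()
    groups = df[cluster].to_numpy()
    B = np.zeros((p, p))
    for g in np.unique(groups):
        u = U[groups == g].sum(0)
        B += np.outer(u, u)
    iinv = np.linalg.inv(info)
    return fit, np.sqrt(np.diag(iinv @ B @ iinv))


@pytest.fixture
def ten_record_fixture():
    return pd.DataFrame({
        "time": [2.0, 3.0, 4.0, 5.0, 6.0, 2.5, 3.5, 4.5, 6.5, 7.0],
        "status": [1, 1, 0, 1, 0, 1, 1, 1, 0, 1],
        "group": [0, 0, 0, 0, 0, 1, 1, 1, 1, 1],
        "test_type": ["SAP"] * 5 + ["FDT"] * 5,
    })


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------

class TestKaplanMeier:
    def test_no_events_gives_flat_curve(self):
        df = pd.DataFrame({"time": [1.0, 2.0, 3.0], "status": [0, 0, 0]})
        km = km_estimate(df)
        assert np.allclose(km.survival, 1.0)

    def test_hand_product_limit_two_records(self):
        df = pd.DataFrame({"time": [1.0, 2.0], "status": [1, 0]})
        km = km_estimate(df).set_index("time")
        assert km.loc[1.0, "survival"] == pytest.approx(0.5)
        assert km.loc[2.0, "survival"] == pytest.approx(0.5)
        assert km.loc[2.0, "n_censored"] == 1

    def test_hand_product_limit_ten_records(self, ten_record_fixture):
        df = ten_record_fixture
        km = km_estimate(df).set_index("time")
        # hand computation over pooled records
        surv = 1.0
        expected = {}
        for s in sorted(df.time.unique()):
            at = (df.time >= s).sum()
            d = ((df.time == s) & (df.status == 1)).sum()
            surv *= 1 - d / at
            expected[s] = surv
        for s, v in expected.items():
            assert km.loc[s, "survival"] == pytest.approx(v)

    def test_duplication_invariance(self, ten_record_fixture):
        df = ten_record_fixture
        doubled = pd.concat([df, df], ignore_index=True)
        a = km_estimate(df)
        b = km_estimate(doubled)
        assert np.allclose(a.survival, b.survival)

    def test_nonpositive_times_rejected(self):
        with pytest.raises(ValueError):
            km_estimate(pd.DataFrame({"time": [0.0, 1.0], "status": [1, 1]}))


# ---------------------------------------------------------------------------
# Gehan-Breslow test
# ---------------------------------------------------------------------------

class TestBreslow:
    def test_identical_groups_give_null_statistic(self):
        df = pd.DataFrame({
            "time": [1.0, 2.0, 3.0] * 2,
            "status": [1, 0, 1] * 2,
            "test_type": ["SAP"] * 3 + ["FDT"] * 3,
        })
        res = breslow_test(df)
        assert res["statistic"] == pytest.approx(0.0, abs=1e-12)
        assert res["p_value"] == pytest.approx(1.0)

    def test_matches_direct_summation_oracle(self, ten_record_fixture):
        df = ten_record_fixture
        res = breslow_test(df)
        assert res["statistic"] == pytest.approx(
            weighted_logrank_oracle(df, "gehan"), rel=1e-9)

    def test_equal_weights_reduce_to_logrank(self, ten_record_fixture):
        df = ten_record_fixture
        lr = logrank_test(df[df.group == 0].time, df[df.group == 1].time,
                          df[df.group == 0].status, df[df.group == 1].status)
        assert lr.test_statistic == pytest.approx(
            weighted_logrank_oracle(df, "logrank"), rel=1e-9)

    def test_requires_two_groups_and_events(self):
        df = pd.DataFrame({"time": [1.0, 2.0], "status": [1, 1],
                           "test_type": ["SAP", "SAP"]})
        with pytest.raises(ValueError):
            breslow_test(df)
        df2 = pd.DataFrame({"time": [1.0, 2.0], "status": [0, 0],
                            "test_type": ["SAP", "FDT"]})
        with pytest.raises(ValueError):
            breslow_test(df2)


# ---------------------------------------------------------------------------
# Cox with cluster-robust sandwich
# ---------------------------------------------------------------------------

class TestCoxRobust:
    def _fixture(self, seed=42, n=20, n_clusters=10):
        rng = np.random.default_rng(seed)
        return pd.DataFrame({
            "time": rng.exponential(1, n).round(6),
            "status": (rng.random(n) < 0.7).astype(int),
            "x": rng.normal(0, 1, n),
            "z": rng.normal(0, 1, n),
            "subject_id": np.repeat(np.arange(n_clusters), n // n_clusters),
        })

    def test_sandwich_matches_score_residual_oracle(self):
        df = self._fixture()
        fit, oracle_se = cox_sandwich_oracle(df, ("x", "z"), "subject_id")
        assert np.allclose(fit.summary["robust_se"].to_numpy(), oracle_se,
                           rtol=1e-5)

    def test_singleton_clusters_equal_rowwise_sandwich(self):
        df = self._fixture()
        df["subject_id"] = np.arange(len(df))  # one eye per subject
        fit, oracle_se = cox_sandwich_oracle(df, ("x", "z"), "subject_id")
        assert np.allclose(fit.summary["robust_se"].to_numpy(), oracle_se,
                           rtol=1e-5)

    def test_point_estimates_invariant_to_within_cluster_order(self):
        df = self._fixture()
        shuffled = df.sample(frac=1.0, random_state=1).reset_index(drop=True)
        a = cox_robust(df, covariates=("x", "z"),
                       scales={"x": 1.0, "z": 1.0})
        b = cox_robust(shuffled, covariates=("x", "z"),
                       scales={"x": 1.0, "z": 1.0})
        assert np.allclose(a.summary["coef"], b.summary["coef"], atol=1e-8)

    def test_covariate_scaling_transforms_hazard_ratio(self):
        df = self._fixture(seed=3)
        fit1 = cox_robust(df, covariates=("x",), scales={"x": 1.0})
        fit2 = cox_robust(df, covariates=("x",), scales={"x": 2.0})
        # dividing x by 2 doubles the per-unit log hazard ratio
        assert fit2.summary.loc["x", "coef"] == pytest.approx(
            2 * fit1.summary.loc["x", "coef"], rel=1e-6)

    def test_requires_events(self):
        df = self._fixture()
        df["status"] = 0
        with pytest.raises(ValueError):
            cox_robust(df, covariates=("x",), scales={"x": 1.0})

    def test_null_covariate_type_I_error(self):
        """Robust Wald test keeps ~5% size under the null."""
        rng = np.random.default_rng(11)
        n, reps, rej = 120, 400, 0
        for _ in range(reps):
            df = pd.DataFrame({
                "time": rng.exponential(1, n),
                "status": (rng.random(n) < 0.8).astype(int),
                "x": rng.normal(0, 1, n),
                "subject_id": np.arange(n),
            })
            fit = cox_robust(df, covariates=("x",), scales={"x": 1.0})
            if fit.summary.loc["x", "p_value"] < 0.05:
                rej += 1
        rate = rej / reps
        assert abs(rate - 0.05) < 3 * math.sqrt(0.05 * 0.95 / reps)

    def test_parameter_recovery_on_simulated_cohort(self):
        """Age log-HR recovered within 3 robust SEs at n = 400 subjects."""
        df = simulate_survival_table(n_subjects=400, seed=5)
        fit = cox_robust(df)
        beta = math.log(fit.hazard_ratio("age"))
        se = float(fit.summary.loc["age", "robust_se"])
        assert abs(beta - math.log(1.13)) < 3 * se
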