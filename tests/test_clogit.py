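import datetime as dt

import numpy as np
import pytest

from flarecc import FlareDefinition, ModelSpec, RiskSet, Window, fit, or_table
from flarecc.clogit import stratum_loglik, stratum_loglik_enumerate

from oracles import enumeration_loglik, numeric_score_info

D = dt.date(2021, 3, 1)


def make_risk_set(pid, hazard_x, control_x, exposure="anxiety"):
    """1-exposure risk set; x values enter through the 3-day mean slot."""

    def win(label, x):
        return Window(
            pid,
            FlareDefinition.AT,
            label,
            D,
            None,
            {exposure: float(x)},
            {exposure: 0.0},
        )

    return RiskSet(
        pid,
        FlareDefinition.AT,
        [win("hazard", x) for x in np.atleast_1d(hazard_x)],
        [win("control", x) for x in np.atleast_1d(control_x)],
    )


class TestStratumLoglik:
    def test_symmetric_null_pair(self):
        ll, score, info = stratum_loglik([[1.0], [0.0]], [1, 0], [0.0])
        assert ll == pytest.approx(np.log(0.5))

    def test_no_contrast_gives_zero_score(self, rng):
        for beta in rng.normal(size=5):
            x = np.full((4, 1), 2.7)
            ll, score, info = stratum_loglik(x, [1, 1, 0, 0], [beta])
            assert np.allclose(score, 0)

    def test_concordant_stratum_contributes_nothing(self):
        ll, score, info = stratum_loglik([[1.0], [2.0]], [1, 1], [0.3])
        assert ll == 0 and np.all(score == 0) and np.all(info == 0)

    @pytest.mark.parametrize("p", [1, 2])
    def test_matches_enumeration_and_finite_differences(self, p, rng):
        # every stratum size m <= 8, every case count 1 <= k < m, random beta
        for m in range(2, 9):
            for k in range(1, m):
                x = rng.normal(size=(m, p))
                y = np.zeros(m, int)
                y[rng.choice(m, k, replace=False)] = 1
                for _ in range(3):
                    beta = rng.normal(scale=1.0, size=p)
                    ll, score, info = stratum_loglik(x, y, beta)
                    ll_ref = enumeration_loglik(x, y, beta)
                    assert ll == pytest.approx(ll_ref, rel=1e-10, abs=1e-10)
                    s_ref, i_ref = numeric_score_info(x, y, beta)
                    assert np.allclose(score, s_ref, rtol=1e-6, atol=1e-5)
                    assert np.allclose(info, i_ref, rtol=1e-4, atol=1e-4)

    def test_package_enumeration_helper_agrees(self, rng):
        x = rng.normal(size=(6, 2))
        y = np.array([1, 0, 1, 0, 0, 0])
        beta = np.array([0.4, -0.2])
        ll, _, _ = stratum_loglik(x, y, beta)
        assert ll == pytest.approx(stratum_loglik_enumerate(x, y, beta), rel=1e-12)

    def test_invariant_to_within_stratum_shift(self, rng):
        x = rng.normal(size=(5, 1))
        y = np.array([1, 0, 0, 1, 0])
        beta = np.array([0.8])
        ll1, s1, i1 = stratum_loglik(x, y, beta)
        ll2, s2, i2 = stratum_loglik(x + 11.3, y, beta)
        assert ll1 == pytest.approx(ll2, rel=1e-9)
        assert np.allclose(s1, s2) and np.allclose(i1, i2)

    def test_single_case_reduces_to_softmax(self, rng):
        x = rng.normal(size=(6, 1))
        y = np.zeros(6, int)
        y[2] = 1
        beta = np.array([0.5])
        ll, _, _ = stratum_loglik(x, y, beta)
        eta = (x @ beta).ravel()
        direct = eta[2] - np.log(np.exp(eta).sum())
        assert ll == pytest.approx(direct, rel=1e-12)


class TestFit:
    def test_matched_pairs_closed_form(self, rng):
        # 1:1 strata with binary exposure: beta-hat = log(n10 / n01)
        for _ in range(20):
            n10 = int(rng.integers(5, 40))
            n01 = int(rng.integers(5, 40))
            n_conc = int(rng.integers(0, 10))
            rs = []
            i = 0
            for _ in range(n10):
                rs.append(make_risk_set(f"P{i}", 1.0, 0.0)); i += 1
            for _ in range(n01):
                rs.append(make_risk_set(f"P{i}", 0.0, 1.0)); i += 1
            for _ in range(n_conc):
                rs.append(make_risk_set(f"P{i}", 1.0, 1.0)); i += 1
            res = fit(rs, ModelSpec("at", "anxiety", ("mean",)))
            assert res.converged
            assert res.beta[0] == pytest.approx(np.log(n10 / n01), abs=1e-6)

    def test_no_informative_strata_is_failure(self):
        rs = [make_risk_set("P1", 2.0, 2.0), make_risk_set("P2", 3.0, 3.0)]
        with pytest.raises(ValueError, match="no informative strata"):
            fit(rs, ModelSpec("at", "anxiety", ("mean",)))

    def test_separation_detected(self):
        # exposure perfectly predicts case status across many strata
        rs = [make_risk_set(f"P{i}", 1.0, 0.0) for i in range(30)]
        res = fit(rs, ModelSpec("at", "anxiety", ("mean",)))
        assert not res.converged
        assert "separation" in res.message

    def test_cross_check_against_statsmodels(self, rng):
        from statsmodels.discrete.conditional_models import ConditionalLogit

        rs = []
        rows_y, rows_x, rows_g = [], [], []
        for i in range(60):
            m = int(rng.integers(3, 8))
            k = int(rng.integers(1, min(3, m - 1) + 1))
            x = rng.normal(size=m)
            y = np.zeros(m, int)
            y[rng.choice(m, k, replace=False)] = 1
            x[y == 1] += 0.5  # induce signal
            rs.append(make_risk_set(f"P{i}", x[y == 1], x[y == 0]))
            rows_y.extend(y)
            rows_x.extend(x)
            rows_g.extend([i] * m)
        res = fit(rs, ModelSpec("at", "anxiety", ("mean",)))
        sm = ConditionalLogit(
            np.array(rows_y), np.array(rows_x)[:, None], groups=np.array(rows_g)
        ).fit(disp=0)
        assert res.converged
        assert res.beta[0] == pytest.approx(sm.params[0], abs=1e-5)
        assert res.se_model[0] == pytest.approx(sm.bse[0], rel=1e-3)

    def test_robust_matches_model_se_under_correct_model(self, rng):
        # one informative stratum per cluster, correctly specified model:
        # sandwich and model-based SEs agree asymptotically
        rs = []
        beta_true = 0.6
        for i in range(4000):
            x = rng.normal(size=2)
            p = 1 / (1 + np.exp(-(beta_true * (x[0] - x[1]))))
            if rng.uniform() < p:
                rs.append(make_risk_set(f"P{i}", x[0], x[1]))
            else:
                rs.append(make_risk_set(f"P{i}", x[1], x[0]))
        res = fit(rs, ModelSpec("at", "anxiety", ("mean",)))
        assert res.converged
        assert res.beta[0] == pytest.approx(beta_true, abs=0.1)
        assert res.se_robust[0] / res.se_model[0] == pytest.approx(1.0, abs=0.08)

    def test_hazard_stratum_mode_matches_participant_mode_for_single_hazard(self, rng):
        rs = []
        for i in range(40):
            x = rng.normal(size=4)
            rs.append(make_risk_set(f"P{i}", x[0] + 0.4, x[1:]))
        res_p = fit(rs, ModelSpec("at", "anxiety", ("mean",)), stratum_mode="participant")
        res_h = fit(rs, ModelSpec("at", "anxiety", ("mean",)), stratum_mode="hazard")
        assert res_p.beta[0] == pytest.approx(res_h.beta[0], abs=1e-8)


class TestOrTable:
    def test_or_and_ci_formulas(self):
        rs = [make_risk_set(f"P{i}", 1.0, 0.0) for i in range(12)]
        rs += [make_risk_set(f"Q{i}", 0.0, 1.0) for i in range(6)]
        res = fit(rs, ModelSpec("at", "anxiety", ("mean",)))
        tab = or_table([res])
        row = tab.iloc[0]
        assert row["or"] == pytest.approx(np.exp(res.beta[0]))
        assert row["ci_low"] == pytest.approx(np.exp(res.beta[0] - 1.96 * res.se_robust[0]))
        assert row["ci_high"] == pytest.approx(np.exp(res.beta[0] + 1.96 * res.se_robust[0]))
        assert row["significant"] == (row["ci_low"] > 1 or row["ci_high"] < 1)

    def test_known_numbers(self):
        # coefficient 0.7 with robust SE 0.3: OR ~2.014, CI ~[1.119, 3.626]
        beta, se = 0.7, 0.3
        assert np.exp(beta) == pytest.approx(2.0138, abs=1e-4)
        lo, hi = np.exp(beta - 1.96 * se), np.exp(beta + 1.96 * se)
        assert lo == pytest.approx(1.1185, abs=1e-4)
        assert hi == pytest.approx(3.6255, abs=1e-4)

    def test_nonconverged_fit_flagged(self):
        rs = [make_risk_set(f"P{i}", 1.0, 0.0) for i in range(30)]
        res = fit(rs, ModelSpec("at", "anxiety", ("mean",)))
        tab = or_table([res])
        assert not tab.iloc[0]["converged"]
        assert np.isnan(tab.iloc[0]["or"])
        assert tab.iloc[0]["message"] != ""
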