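"""Prediction, variance partition, LRT and stepwise selection."""

import numpy as np
import pandas as pd
import pytest

import gwreg
from gwreg import (
    DataValidationError,
    PartitionUndefinedError,
    build_design,
    fit_gw,
    lrt,
    partvar,
    predict_mean,
    scan_terms,
    step_select,
)
from gwreg.ugwd import UGWDParams, ugwd_moments

from conftest import fit_at


@pytest.fixture(scope="module")
def printed_fit():
    """A fit pinned at externally reported estimates for a binary covariate."""
    df = pd.DataFrame({"numvisit": [1, 5], "badh": [0, 1]})
    d = build_design(df, "numvisit", ["badh"])
    return fit_at(d, [6.581e-01, 1.162e00], 1.567578, 6.852336)


class TestPredict:
    def test_reproduces_reported_predictions(self, printed_fit):
        nd = pd.DataFrame({"badh": [0, 1]})
        mu = predict_mean(printed_fit, nd)
        assert mu[0] == pytest.approx(1.931035, rel=5e-4)
        assert mu[1] == pytest.approx(6.173427, rel=5e-4)
        eta = predict_mean(printed_fit, nd, type="link")
        assert np.allclose(np.exp(eta), mu)

    def test_zero_coefficients_predict_one(self, badh_design):
        fit = fit_at(badh_design, [0.0, 0.0], 1.5, 6.0)
        assert np.allclose(predict_mean(fit), 1.0)

    def test_offset_is_multiplicative(self, goals_fit, goals_data):
        nd = goals_data.head(10).copy()
        mu1 = predict_mean(goals_fit, nd)
        nd2 = nd.copy()
        nd2["Matches"] = nd2["Matches"] * 2
        assert np.allclose(predict_mean(goals_fit, nd2), 2 * mu1)


class TestPartvar:
    def test_reproduces_reported_proportions(self, printed_fit):
        pv = partvar(printed_fit, pd.DataFrame({"badh": [0, 1]}))
        p = pv.proportion.to_numpy()
        want0 = (0.2930119, 0.1550451, 0.551943)
        want1 = (0.1324292, 0.07007398, 0.7974968)
        assert np.allclose(p[0], want0, rtol=5e-4)
        assert np.allclose(p[1], want1, rtol=5e-4)

    def test_proportions_sum_to_one_and_match_moments(self, badh_fit):
        pv = partvar(badh_fit)
        assert np.allclose(pv.proportion.sum(axis=1), 1.0, atol=1e-10)
        assert np.all(pv.absolute.to_numpy() >= 0)
        # total equals the distribution variance at (mu(rho-1)/k, k, rho)
        i = 3
        mu = pv.mu[i]
        m = ugwd_moments(UGWDParams(mu * (badh_fit.rho - 1) / badh_fit.k, badh_fit.k, badh_fit.rho))
        assert pv.total_variance[i] == pytest.approx(m.variance, rel=1e-10)

    def test_undefined_below_two_raises(self, badh_design):
        fit = fit_at(badh_design, [0.5, 0.5], 1.0, 1.8)
        with pytest.raises(PartitionUndefinedError):
            partvar(fit)

    def test_near_boundary_warns(self, badh_design):
        fit = fit_at(badh_design, [0.5, 0.5], 1.0, 2.0005)
        with pytest.warns(UserWarning, match="boundary"):
            partvar(fit)

    def test_share_monotonicity_in_mu(self, printed_fit):
        # as mu grows (k, rho fixed) randomness share falls, proneness share rises
        mus = np.array([0.5, 1.0, 2.0, 4.0, 8.0])
        k, rho = printed_fit.k, printed_fit.rho
        shares = []
        for mu in mus:
            m = ugwd_moments(UGWDParams(mu * (rho - 1) / k, k, rho))
            shares.append(m.proportions)
        shares = np.array(shares)
        assert np.all(np.diff(shares[:, 0]) < 0)
        assert np.all(np.diff(shares[:, 2]) > 0)


class TestLRT:
    def test_fit_vs_itself(self, badh_fit):
        t = lrt(badh_fit, badh_fit)
        assert t.statistic == pytest.approx(0.0, abs=1e-8)
        assert t.p_value == 1.0

    def test_informative_covariate_detected(self, badh_null_fit, badh_fit):
        t = lrt(badh_null_fit, badh_fit)
        assert t.df == 1
        assert t.statistic > 10
        assert t.p_value < 1e-3

    def test_non_nested_rejected(self, badh_fit, goals_fit):
        with pytest.raises(DataValidationError):
            lrt(badh_fit, goals_fit)

    def test_invariant_to_affine_recoding(self, badh_data):
        df = badh_data.copy()
        df["badh2"] = 2.0 * df["badh"] + 1.0
        d0 = build_design(df, "numvisit", [])
        f0 = fit_gw(d0, hessian=False)
        fa = fit_gw(build_design(df, "numvisit", ["badh"]), hessian=False)
        fb = fit_gw(build_design(df, "numvisit", ["badh2"]), hessian=False)
        ta, tb = lrt(f0, fa), lrt(f0, fb)
        assert ta.statistic == pytest.approx(tb.statistic, abs=1e-4)

    def test_type_one_error_rate_near_nominal(self):
        # truly null covariate: rejection rate at alpha=.05 within binomial noise
        import warnings

        nsim, n, alpha = 120, 400, 0.05
        rej = 0
        for s in range(nsim):
            df, _ = gwreg.generate_dataset(
                n, beta=(0.6,), k=1.5, rho=5.0,
                covariate_profile=[], seed=10_000 + s,
            )
            df["x"] = np.random.default_rng(20_000 + s).normal(size=n)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                f0 = fit_gw(build_design(df, "y", []), hessian=False)
                f1 = fit_gw(build_design(df, "y", ["x"]), hessian=False)
            if lrt(f0, f1).p_value < alpha:
                rej += 1
        # 99% binomial band around 0.05 for 120 draws: [0, ~0.11]
        assert rej / nsim < 0.12
        assert rej / nsim >= 0.0


class TestSelection:
    def test_add1_prefers_informative_term(self, badh_null_fit):
        tab = scan_terms(badh_null_fit, ["badh", "age"], mode="add1", criterion="AIC")
        best = tab.iloc[0]
        assert best["term"] == "badh"
        assert best["AIC"] < tab.loc[tab["term"] == "<none>", "AIC"].iloc[0]

    def test_drop1_matches_direct_refit(self, badh_fit, badh_null_fit):
        tab = scan_terms(badh_fit, ["badh"], mode="drop1", criterion="AIC")
        dropped = tab.loc[tab["term"] == "badh"].iloc[0]
        assert dropped["AIC"] == pytest.approx(badh_null_fit.aic, abs=5e-2)

    def test_lrt_mode_carries_test_columns(self, badh_null_fit):
        tab = scan_terms(badh_null_fit, ["badh"], mode="add1", criterion="LRT")
        row = tab.loc[tab["term"] == "badh"].iloc[0]
        assert row["df"] == 1 and row["Pr(Chi)"] < 1e-3

    def test_step_selects_informative_and_drops_noise(self, badh_null_fit):
        # fixture truth: badh matters, age has a zero coefficient
        selected, trace = step_select(badh_null_fit, ["badh", "age"], direction="both")
        assert selected.design.terms == ["badh"]
        assert len(trace) >= 2
        assert all("candidates" in rnd for rnd in trace)

    def test_step_empty_scope_returns_start(self, badh_null_fit):
        selected, trace = step_select(badh_null_fit, [], direction="forward")
        assert selected is badh_null_fit

    def test_bic_never_selects_superset_of_aic(self, badh_null_fit):
        sel_aic, _ = step_select(badh_null_fit, ["badh", "age"], criterion="AIC")
        sel_bic, _ = step_select(badh_null_fit, ["badh", "age"], criterion="BIC")
        assert set(sel_bic.design.terms) <= set(sel_aic.design.terms)
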