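import numpy as np
import pandas as pd
import pytest

from irpair import (
    ClinicalTable,
    RiskModel,
    compute_risk_score,
    repeated_lasso_select,
    stepwise_cox_fit,
    univariate_cox_screen,
)
from irpair.pairs import PairMatrix
from conftest import exponential_cohort
from oracles import brute_force_cox_beta, naive_efron_loglik


def _pm(rows, names=None, samples=None):
    rows = np.asarray(rows)
    names = names or [f"g{i}|h{i}" for i in range(rows.shape[0])]
    samples = samples or [f"p{i}" for i in range(rows.shape[1])]
    return PairMatrix(pd.DataFrame(rows, index=names, columns=samples))


def _surv(times, events, samples=None):
    samples = samples or [f"p{i}" for i in range(len(times))]
    return ClinicalTable(
        pd.DataFrame({"sample_id": samples, "os_time": times, "os_event": events})
    )


def test_constant_pair_skipped():
    pm = _pm([[1, 1, 1, 1, 1, 1], [1, 0, 1, 0, 1, 0]])
    surv = _surv([10, 20, 30, 40, 50, 60], [1, 1, 1, 1, 1, 1])
    retained, table = univariate_cox_screen(pm, surv)
    assert table.loc["g0|h0", "status"] == "constant"
    assert "g0|h0" not in retained


def test_toy_beta_matches_brute_force_oracle():
    """Six patients, all events, mixed indicator: the fitted coefficient
    maximizes the written-out Efron partial likelihood.  (An indicator
    that exactly tracks the earliest deaths has a monotone likelihood and
    no finite maximizer, so the toy interleaves groups.)"""
    z = [1, 1, 0, 1, 0, 0]
    times = [1, 2, 3, 4, 5, 6]
    pm = _pm([z])
    surv = _surv(times, [1] * 6)
    _, table = univariate_cox_screen(pm, surv, p_max=1.0)
    beta_hat = table.iloc[0]["beta"]
    beta_oracle, ll_oracle = brute_force_cox_beta(z, times, [1] * 6)
    assert beta_hat == pytest.approx(beta_oracle, abs=1e-6)


def test_separated_indicator_reported_non_convergent():
    """An indicator that is 1 for exactly the earliest deaths has a
    monotone partial likelihood; the screen flags it instead of returning
    an arbitrary coefficient."""
    pm = _pm([[1, 1, 1, 0, 0, 0]])
    surv = _surv([1, 2, 3, 4, 5, 6], [1] * 6)
    retained, table = univariate_cox_screen(pm, surv, p_max=1.0)
    assert table.iloc[0]["status"] == "non-convergent"
    assert retained == []


def test_beta_with_ties_matches_oracle():
    z = [1, 0, 1, 0, 1, 0, 1, 0]
    times = [5, 5, 10, 10, 10, 20, 30, 30]
    events = [1, 1, 1, 0, 1, 1, 1, 1]
    pm = _pm([z])
    surv = _surv(times, events)
    _, table = univariate_cox_screen(pm, surv, p_max=1.0)
    beta_oracle, _ = brute_force_cox_beta(z, times, events)
    assert table.iloc[0]["beta"] == pytest.approx(beta_oracle, abs=1e-6)


def test_null_screen_calibration():
    """With no true signal the p < 0.01 screen retains ~1% of pairs."""
    rates = []
    for seed in range(10):
        rng = np.random.default_rng(seed)
        n, k = 300, 200
        Z = rng.integers(0, 2, (k, n))
        surv = exponential_cohort(n, np.zeros(n), censor_frac=0.2, seed=seed + 1000)
        surv.data["os_time"] = np.maximum(np.rint(surv.data["os_time"]), 1)
        pm = _pm(Z, names=[f"a{i}|b{i}" for i in range(k)],
                 samples=surv.sample_ids)
        retained, _ = univariate_cox_screen(pm, surv)
        rates.append(len(retained) / k)
    assert 0.002 <= np.mean(rates) <= 0.03


def _signal_cohort(n, betas, prevalence=0.5, seed=0, n_noise=0):
    rng = np.random.default_rng(seed)
    k = len(betas)
    Z = (rng.random((k + n_noise, n)) < prevalence).astype(int)
    lp = np.asarray(betas) @ Z[:k]
    surv = exponential_cohort(n, lp, censor_frac=0.15, seed=seed + 5000)
    pm = _pm(Z, names=[f"s{i:03d}|t{i:03d}" for i in range(k + n_noise)],
             samples=surv.sample_ids)
    return pm, surv


def test_lasso_single_repeat_selects_dominant_pair():
    pm, surv = _signal_cohort(400, [2.0], n_noise=4, seed=3)
    selected, counts = repeated_lasso_select(
        pm, surv, n_repeats=1, count_min=0, seed=9
    )
    assert "s000|t000" in selected


def test_lasso_determinism():
    pm, surv = _signal_cohort(150, [1.5], n_noise=6, seed=4)
    _, c1 = repeated_lasso_select(pm, surv, n_repeats=5, seed=42)
    _, c2 = repeated_lasso_select(pm, surv, n_repeats=5, seed=42)
    pd.testing.assert_series_equal(c1, c2)


def test_lasso_recovers_true_pairs_among_noise():
    """5 true pairs (beta 1) among 45 null candidates are recovered."""
    recalls = []
    for seed in range(3):
        pm, surv = _signal_cohort(300, [1.0] * 5, n_noise=45, seed=seed)
        selected, counts = repeated_lasso_select(pm, surv, n_repeats=20, seed=seed)
        true_ids = [f"s{i:03d}|t{i:03d}" for i in range(5)]
        recalls.append(np.mean([t in selected for t in true_ids]))
    assert np.mean(recalls) >= 0.8


def test_stepwise_drops_noise_keeps_signal():
    pm, surv = _signal_cohort(400, [1.5], n_noise=1, seed=6)
    model = stepwise_cox_fit(pm, surv)
    assert "s000|t000" in model.pairs
    # AIC of the final model never exceeds the full starting model
    full = stepwise_cox_fit(pm, surv, selected=list(pm.pair_ids))
    assert model.fit_stats["aic"] <= full.fit_stats["aic"] + 1e-9


def test_stepwise_single_pair_is_plain_fit():
    pm, surv = _signal_cohort(200, [1.0], seed=7)
    model = stepwise_cox_fit(pm, surv)
    assert model.pairs == ["s000|t000"]
    z = pm.indicator.iloc[0].to_numpy(dtype=float)
    beta_oracle, _ = brute_force_cox_beta(
        z, surv.data["os_time"], surv.data["os_event"]
    )
    assert model.betas[0] == pytest.approx(beta_oracle, abs=1e-4)


def test_final_aic_matches_partial_likelihood_oracle():
    pm, surv = _signal_cohort(150, [1.2], seed=8)
    model = stepwise_cox_fit(pm, surv)
    z = pm.indicator.loc[model.pairs[0]].to_numpy(dtype=float)
    ll = naive_efron_loglik(
        model.betas[0], z, surv.data["os_time"], surv.data["os_event"]
    )
    assert model.fit_stats["aic"] == pytest.approx(2.0 - 2.0 * ll, abs=1e-8)


def test_orientation_flip_negates_beta():
    pm, surv = _signal_cohort(250, [1.0], seed=9)
    flipped = PairMatrix((1 - pm.indicator).astype(int))
    m1 = stepwise_cox_fit(pm, surv)
    m2 = stepwise_cox_fit(flipped, surv)
    assert m2.betas[0] == pytest.approx(-m1.betas[0], abs=1e-6)
    assert m2.fit_stats["log_partial_likelihood"] == pytest.approx(
        m1.fit_stats["log_partial_likelihood"], abs=1e-8
    )


def test_risk_score_arithmetic():
    pm = _pm([[1, 0, 1], [1, 0, 0]], names=["A|B", "C|D"])
    model = RiskModel(pairs=["A|B", "C|D"], betas=np.array([1.5, -0.5]))
    scores = compute_risk_score(model, pm)
    assert scores.tolist() == [1.0, 0.0, 1.5]


def test_risk_score_missing_pair_errors():
    pm = _pm([[1, 0]], names=["A|B"])
    model = RiskModel(pairs=["X|Y"], betas=np.array([1.0]))
    with pytest.raises(KeyError):
        compute_risk_score(model, pm)


def test_risk_score_value_count_bounded():
    rng = np.random.default_rng(2)
    pm = _pm(rng.integers(0, 2, (3, 50)), names=["A|B", "C|D", "E|F"])
    model = RiskModel(pairs=["A|B", "C|D", "E|F"], betas=np.array([0.7, -1.1, 0.3]))
    scores = compute_risk_score(model, pm)
    assert scores.nunique() <= 2**3


def test_beta_recovery_at_scale():
    """Fitting the true pairs alone on a large cohort recovers beta."""
    errs = []
    for seed in range(4):
        pm, surv = _signal_cohort(2000, [1.0, -1.0], seed=seed + 20)
        model = stepwise_cox_fit(pm, surv, selected=list(pm.pair_ids))
        fitted = dict(zip(model.pairs, model.betas))
        errs.append(abs(fitted["s000|t000"] - 1.0))
        errs.append(abs(fitted["s001|t001"] + 1.0))
    assert max(errs) < 0.15


def test_out_of_sample_concordance():
    """A model fitted on one cohort keeps concordance >= 0.7 on new data."""
    from sksurv.metrics import concordance_index_censored

    pm, surv = _signal_cohort(400, [1.5, -1.5], seed=30)
    model = stepwise_cox_fit(pm, surv, selected=list(pm.pair_ids))
    pm_test, surv_test = _signal_cohort(400, [1.5, -1.5], seed=31)
    scores = compute_risk_score(model, pm_test)
    ci = concordance_index_censored(
        surv_test.data["os_event"].astype(bool),
        surv_test.data["os_time"],
        scores.loc[surv_test.sample_ids],
    )[0]
    assert ci >= 0.7


def test_model_json_round_trip(tmp_path):
    model = RiskModel(
        pairs=["A|B", "C|D"],
        betas=np.array([0.5, -0.25]),
        selection_counts=pd.Series({"A|B": 90, "C|D": 55}),
        fit_stats={"aic": 123.4},
    )
    path = tmp_path / "model.json"
    path.write_text(model.to_json())
    back = RiskModel.from_json(path)
    assert back.pairs == model.pairs
    np.testing.assert_allclose(back.betas, model.betas)
    assert back.fit_stats["aic"] == 123.4
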