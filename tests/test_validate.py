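import numpy as np
import pandas as pd
import pytest

from irpair import (
    ClinicalTable,
    SimConfig,
    build_pair_matrix,
    chi_square_association,
    cohort_summary,
    compute_risk_score,
    km_logrank,
    multivariable_cox,
    predict_survival_probability,
    rank_sum_by_category,
    significance_stars,
    simulate_cohort,
    stepwise_cox_fit,
)
from irpair.pairs import PairMatrix
from conftest import exponential_cohort
from oracles import (
    brute_force_cox_beta,
    chi2_oracle,
    km_empirical,
    logrank_oracle,
    wilcoxon_exact_oracle,
)


def _surv(times, events, samples=None):
    samples = samples or [f"p{i}" for i in range(len(times))]
    return ClinicalTable(
        pd.DataFrame({"sample_id": samples, "os_time": times, "os_event": events})
    )


# ---------------------------------------------------------------- log-rank

def test_logrank_identical_groups():
    times = [50, 120, 300, 50, 120, 300]
    events = [1, 1, 0, 1, 1, 0]
    groups = pd.Series(
        ["a", "a", "a", "b", "b", "b"], index=[f"p{i}" for i in range(6)]
    )
    res = km_logrank(groups, _surv(times, events))
    assert res.chi2 == pytest.approx(0.0, abs=1e-12)
    assert res.p == pytest.approx(1.0)


def test_logrank_matches_hand_tabulation():
    times = [31, 60, 90, 150, 210, 400]
    events = [1, 1, 1, 1, 1, 1]
    labels = ["a", "b", "a", "b", "a", "b"]
    groups = pd.Series(labels, index=[f"p{i}" for i in range(6)])
    res = km_logrank(groups, _surv(times, events))
    assert res.chi2 == pytest.approx(
        logrank_oracle(times, events, np.array(labels)), abs=1e-10
    )


def test_logrank_fully_separated_groups():
    times = list(range(10, 110, 10)) + list(range(500, 1500, 100))
    events = [1] * 20
    labels = ["early"] * 10 + ["late"] * 10
    groups = pd.Series(labels, index=[f"p{i}" for i in range(20)])
    res = km_logrank(groups, _surv(times, events))
    assert res.p < 0.01


def test_km_without_censoring_is_empirical():
    times = [100, 200, 200, 300, 500]
    groups = pd.Series(
        ["g", "g", "g", "g", "g", "h"], index=[f"p{i}" for i in range(6)]
    )
    surv = _surv(times + [900], [1] * 6)
    res = km_logrank(groups, surv)
    s = km_empirical(times)
    curve = res.curves["g"]
    for t in [100, 200, 300, 500]:
        assert curve.loc[t].iloc[0] == pytest.approx(s(t), abs=1e-12)


# -------------------------------------------------------------- chi-square

def test_chi_square_diagonal_table():
    groups = pd.Series(["high"] * 10 + ["low"] * 10)
    cov = pd.Series(["x"] * 10 + ["y"] * 10)
    chi2, dof, p, stars = chi_square_association(groups, cov)
    assert chi2 == pytest.approx(20.0)
    assert chi2 == pytest.approx(chi2_oracle([[10, 0], [0, 10]]))
    assert dof == 1 and p < 0.001 and stars == "***"


def test_chi_square_proportional_table():
    groups = pd.Series(["high"] * 30 + ["low"] * 30)
    cov = pd.Series((["x"] * 10 + ["y"] * 20) * 2)
    chi2, _, p, stars = chi_square_association(groups, cov)
    assert chi2 == pytest.approx(0.0, abs=1e-12)
    assert stars == ""


def test_chi_square_degenerate_margin_errors():
    groups = pd.Series(["high"] * 4)
    cov = pd.Series(["x", "x", "y", "y"])
    with pytest.raises(ValueError):
        chi_square_association(groups, cov)


def test_star_coding():
    assert significance_stars(0.0005) == "***"
    assert significance_stars(0.005) == "**"
    assert significance_stars(0.03) == "*"
    assert significance_stars(0.2) == ""


# ---------------------------------------------------------------- rank-sum

def test_rank_sum_exact_small_sample():
    scores = pd.Series([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
    cov = pd.Series(["a", "a", "a", "b", "b", "b"])
    res = rank_sum_by_category(scores, cov)
    assert res.iloc[0]["p"] == pytest.approx(0.1)
    assert res.iloc[0]["p"] == pytest.approx(
        wilcoxon_exact_oracle([1, 2, 3], [4, 5, 6])
    )


def test_rank_sum_identical_groups():
    scores = pd.Series([1.0, 2.0, 3.0] * 20)
    cov = pd.Series(["a"] * 30 + ["b"] * 30)
    res = rank_sum_by_category(scores, cov)
    assert res.iloc[0]["p"] == pytest.approx(1.0)


def test_rank_sum_exact_vs_normal_agree():
    rng = np.random.default_rng(0)
    diffs = []
    for _ in range(20):
        x = rng.normal(0, 1, 10)
        y = rng.normal(0.5, 1, 10)
        p_exact = wilcoxon_exact_oracle(x, y)
        from scipy import stats

        p_norm = stats.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=False
        ).pvalue
        diffs.append(abs(p_exact - p_norm))
    assert np.mean(diffs) < 0.02


def test_rank_sum_empty_category_errors():
    scores = pd.Series([1.0, 2.0])
    cov = pd.Series(["a", "a"])
    with pytest.raises(ValueError):
        rank_sum_by_category(scores, cov)


# --------------------------------------------------------------------- cox

def test_single_binary_covariate_matches_oracle():
    rng = np.random.default_rng(1)
    n = 60
    z = rng.integers(0, 2, n)
    surv = exponential_cohort(n, 1.2 * z, seed=2)
    surv.data["t_stage"] = np.where(z == 1, "T2", "T1")
    uni, multi = multivariable_cox(surv, ["t_stage"])
    beta_oracle, _ = brute_force_cox_beta(
        z, surv.data["os_time"], surv.data["os_event"]
    )
    assert np.log(multi.loc["t_stage", "hr"]) == pytest.approx(beta_oracle, abs=1e-6)


def test_wald_ci_coverage_null_covariate():
    """The 95% CI of an uninformative covariate covers HR = 1 about 95%
    of the time."""
    covered = 0
    n_seeds = 40
    for seed in range(n_seeds):
        rng = np.random.default_rng(seed)
        n = 300
        z = rng.integers(0, 2, n)
        surv = exponential_cohort(n, np.zeros(n), censor_frac=0.2, seed=seed + 100)
        surv.data["er"] = np.where(z == 1, "positive", "negative")
        _, multi = multivariable_cox(surv, ["er"])
        covered += multi.loc["er", "ci_low"] <= 1.0 <= multi.loc["er", "ci_high"]
    assert covered >= 0.85 * n_seeds


def test_risk_score_independent_prognostic_factor():
    """A riskScore built from true signal stays significant alongside
    noise clinical covariates in the multivariable model."""
    hits = 0
    n_seeds = 8
    for seed in range(n_seeds):
        cfg = SimConfig(
            n_tumor=250, n_normal=20, n_lnc=40, n_irgene=30, n_other_coding=10,
            n_de_lnc=12, n_true_pairs=3, true_beta=(1.0, 1.0, 1.0),
            stage_link=0.0,  # clinical covariates independent of survival
            seed=seed,
        )
        expr, clin, truth = simulate_cohort(cfg)
        tumor = expr.subset_samples(expr.tumor_samples())
        pm = build_pair_matrix(tumor, {g for p in truth.true_pairs for g in p})
        model = stepwise_cox_fit(
            pm, clin, selected=[f"{x}|{y}" for x, y in truth.true_pairs]
        )
        scores = compute_risk_score(model, pm)
        _, multi = multivariable_cox(
            clin, ["age", "t_stage", "n_stage", "stage"], scores=scores
        )
        hits += multi.loc["risk_score", "p"] < 0.05
    assert hits >= 0.9 * n_seeds


# ----------------------------------------------------- survival prediction

def test_predicted_survival_matches_closed_form():
    """Exponential-hazard truth: predicted S(t|x) tracks exp(-lambda t)."""
    rng = np.random.default_rng(3)
    n = 2000
    z = rng.integers(0, 2, n).astype(float)
    true_beta = 0.8
    h0 = 4e-4
    surv = exponential_cohort(n, true_beta * z, h0=h0, seed=4)
    surv.data["er"] = np.where(z == 1, "positive", "negative")
    _, multi = multivariable_cox(surv, ["er"])
    fitted = multi.attrs["model"]
    X = pd.DataFrame({"er": [0.0, 1.0]})
    pred = predict_survival_probability(fitted, X, years=(3.0, 5.0))
    from irpair.roc import YEAR_DAYS

    for i, lp in enumerate([0.0, true_beta]):
        for j, y in enumerate((3.0, 5.0)):
            truth = np.exp(-h0 * np.exp(lp) * y * YEAR_DAYS)
            assert pred.iloc[i, j] == pytest.approx(truth, abs=0.05)


def test_predicted_survival_monotone_and_baseline():
    rng = np.random.default_rng(5)
    n = 300
    z = rng.integers(0, 2, n).astype(float)
    surv = exponential_cohort(n, z, seed=6)
    surv.data["er"] = np.where(z == 1, "positive", "negative")
    _, multi = multivariable_cox(surv, ["er"])
    fitted = multi.attrs["model"]
    X = pd.DataFrame({"er": [0.0, 1.0]})
    pred = predict_survival_probability(fitted, X, years=(3.0, 5.0, 7.0))
    assert (pred.to_numpy()[:, :-1] >= pred.to_numpy()[:, 1:] - 1e-12).all()
    # a subject at the covariate mean follows the stored baseline survival
    # (queried at an observed event time to avoid interpolation ambiguity)
    base = fitted.baseline_survival_
    t_query = float(base.index[base.index <= 3.0 * 365.25].max())
    expected = float(base.loc[t_query].iloc[0])
    pred_mean = predict_survival_probability(
        fitted, pd.DataFrame({"er": [z.mean()]}), years=(t_query / 365.25,)
    )
    assert pred_mean.iloc[0, 0] == pytest.approx(expected, abs=1e-9)


def test_horizon_beyond_followup_warns():
    surv = _surv([100, 200, 300, 400], [1, 1, 1, 0])
    surv.data["er"] = ["positive", "negative", "positive", "negative"]
    _, multi = multivariable_cox(surv, ["er"])
    with pytest.warns(UserWarning, match="last observed"):
        predict_survival_probability(
            multi.attrs["model"], pd.DataFrame({"er": [0.0]}), years=(7.0,)
        )


# ---------------------------------------------------------- cohort summary

def _expand_counts(var, counts):
    rows = []
    for level, n in counts.items():
        rows.extend([level] * n)
    return pd.Series(rows, name=var)


def test_cohort_summary_percentages():
    """Percentages reproduce large-cohort tabulations to one decimal:
    902/922 M0 -> 97.8, 514/1064 N0 -> 48.3, 277/1080 T1 -> 25.6."""
    m = _expand_counts("m_stage", {"M0": 902, "M1": 20})
    n = _expand_counts("n_stage", {"N0": 514, "N1": 358, "N2": 116, "N3": 76})
    t = _expand_counts("t_stage", {"T1": 277, "T2": 629, "T3": 139, "T4": 35})
    size = max(len(m), len(n), len(t))
    df = pd.DataFrame(
        {
            "sample_id": [f"p{i}" for i in range(size)],
            "os_time": 100.0,
            "os_event": 0,
            "m_stage": m.reindex(range(size)),
            "n_stage": n.reindex(range(size)),
            "t_stage": t.reindex(range(size)),
        }
    )
    summary = cohort_summary(ClinicalTable(df))
    lookup = summary.set_index(["variable", "level"])["percent"]
    assert lookup[("m_stage", "M0")] == 97.8
    assert lookup[("n_stage", "N0")] == 48.3
    assert lookup[("t_stage", "T1")] == 25.6


def test_cohort_summary_single_category_and_sum():
    df = pd.DataFrame(
        {
            "sample_id": ["a", "b", "c"],
            "os_time": [100, 200, 300],
            "os_event": [1, 0, 1],
            "er": ["positive", "positive", "positive"],
            "pam50": ["LumA", "Basal", "Her2"],
            "age": [50, 60, 70],
        }
    )
    summary = cohort_summary(ClinicalTable(df))
    lookup = summary.set_index(["variable", "level"])
    assert lookup.loc[("er", "positive"), "percent"] == 100.0
    for var in ("er", "pam50"):
        total = summary[summary["variable"] == var]["percent"].sum()
        assert abs(total - 100.0) <= 0.2
    assert "median (IQR) 60 (55, 65)" in summary["level"].values
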