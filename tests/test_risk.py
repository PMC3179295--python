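import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import optimize, stats

from hipshape.risk import (
    DEFAULT_STRATA,
    SeparationError,
    assign_stratum,
    auroc,
    auroc_ci,
    fit_logistic,
    mcfadden_r2,
    model_comparison_table,
    odds_ratio_table,
    stratified_auroc,
    _delong_variance,
)


def test_intercept_only_balanced_outcome():
    y = np.repeat([0, 1], 50)
    fit = fit_logistic(np.empty((100, 0)), y)
    assert fit.params[0] == pytest.approx(0.0, abs=1e-8)


def test_two_by_two_matches_closed_form_log_odds_ratio():
    """Binary-exposure logistic slope equals the contingency-table log OR."""
    a, b, c, d = 30, 20, 10, 40  # exposed case/ctrl, unexposed case/ctrl
    x = np.concatenate([np.ones(a + b), np.zeros(c + d)])[:, None]
    y = np.concatenate([np.ones(a), np.zeros(b), np.ones(c), np.zeros(d)])
    fit = fit_logistic(x, y, names=["exposed"])
    assert fit.params[1] == pytest.approx(np.log(a * d / (b * c)), abs=1e-8)


def test_mle_matches_independent_optimizer(rng):
    """IRLS estimates agree with a generic optimizer minimizing the same
    negative log-likelihood to 1e-6."""
    n = 120
    x = rng.normal(size=(n, 3))
    eta = 0.3 + x @ [0.8, -0.5, 0.2]
    y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
    fit = fit_logistic(x, y)

    xd = np.column_stack([np.ones(n), x])

    def negll(beta):
        z = xd @ beta
        return np.sum(np.log1p(np.exp(z)) - y * z)

    res = optimize.minimize(negll, np.zeros(4), method="BFGS", tol=1e-12)
    np.testing.assert_allclose(fit.params, res.x, atol=1e-6)


def test_separation_raises_with_ridge_advice():
    x = np.concatenate([-np.arange(1, 11.0), np.arange(1, 11.0)])[:, None]
    y = np.concatenate([np.zeros(10), np.ones(10)])
    with pytest.raises(SeparationError, match="ridge"):
        fit_logistic(x, y)
    fit = fit_logistic(x, y, ridge=1e-4)
    assert fit.converged and np.isfinite(fit.params).all()


def test_singular_design_names_collinear_columns(rng):
    x = rng.normal(size=(50, 2))
    x = np.column_stack([x, x[:, 0] + x[:, 1]])
    y = (rng.random(50) < 0.5).astype(int)
    with pytest.raises(ValueError, match="collinear"):
        fit_logistic(x, y, names=["a", "b", "a_plus_b"])


def test_odds_ratio_table_wald_formulas(rng):
    n = 500
    x = rng.normal(size=(n, 1))
    y = (rng.random(n) < 0.5).astype(int)
    fit = fit_logistic(x, y, names=["z"])
    tab = odds_ratio_table(fit)
    beta, se = fit.params[1], fit.bse[1]
    row = tab.iloc[0]
    assert row.odds_ratio == pytest.approx(np.exp(beta))
    assert row.ci_low == pytest.approx(np.exp(beta - 1.96 * se))
    assert row.ci_high == pytest.approx(np.exp(beta + 1.96 * se))
    assert row.p_value == pytest.approx(2 * stats.norm.sf(abs(beta / se)))
    assert row.ci_low <= row.odds_ratio <= row.ci_high


def test_auroc_perfect_and_exhaustive_pairs(rng):
    assert auroc([0.1, 0.2, 0.9, 0.8], [0, 0, 1, 1]) == 1.0
    for _ in range(5):
        n = int(rng.integers(8, 30))
        y = np.zeros(n, int)
        y[rng.choice(n, size=int(rng.integers(2, n - 1)), replace=False)] = 1
        s = np.round(rng.normal(size=n), 1)  # coarse values force ties
        cases, ctrls = s[y == 1], s[y == 0]
        wins = sum(
            1.0 if c > k else 0.5 if c == k else 0.0 for c in cases for k in ctrls
        )
        oracle = wins / (len(cases) * len(ctrls))
        assert auroc(s, y) == pytest.approx(oracle, abs=1e-12)


@settings(deadline=None, max_examples=25, derandomize=True)
@given(a=st.floats(0.01, 5.0), b=st.floats(-3.0, 3.0))
def test_auroc_invariant_under_monotone_transform(a, b):
    rng = np.random.default_rng(11)
    s = rng.normal(size=60)
    y = (rng.random(60) < 0.4).astype(int)
    if y.min() == y.max():
        return
    assert auroc(a * s + b, y) == pytest.approx(auroc(s, y))
    assert auroc(np.exp(a * s), y) == pytest.approx(auroc(s, y))


def test_null_scores_auroc_near_half(rng):
    aucs = [
        auroc(rng.normal(size=400), np.repeat([0, 1], 200)) for _ in range(50)
    ]
    se = np.sqrt((200 + 200 + 1) / (12 * 200 * 200))
    assert abs(np.mean(aucs) - 0.5) < 3 * se / np.sqrt(50)


def test_nested_model_auroc_never_lower(paper_data):
    """In-sample AUROC of a containing model is at least that of the nested
    model on the same training data."""
    y = paper_data["fracture"].to_numpy(int)
    small = fit_logistic(paper_data[["age", "bmi"]], y)
    big = fit_logistic(paper_data[["age", "bmi", "bmd_fn", "mode4"]], y)
    assert auroc(big.fitted_probs, y) >= auroc(small.fitted_probs, y) - 1e-12


def test_delong_matches_jackknife_oracle(rng):
    """DeLong variance agrees with a leave-one-out jackknife within 10%."""
    n = 60
    s = rng.normal(size=n) + np.repeat([0.0, 1.0], n // 2)
    y = np.repeat([0, 1], n // 2)
    _, v_delong = _delong_variance(s, y)
    theta = auroc(s, y)
    jack = np.array([auroc(np.delete(s, i), np.delete(y, i)) for i in range(n)])
    m = (y == 1).sum()
    nn = n - m
    # grouped jackknife: per-class pseudo-value variances
    v_cases = jack[y == 1].var(ddof=1) * (m - 1) ** 2 / m
    v_ctrls = jack[y == 0].var(ddof=1) * (nn - 1) ** 2 / nn
    v_jack = v_cases + v_ctrls
    assert v_delong == pytest.approx(v_jack, rel=0.10)


def test_delong_ci_coverage():
    """Normal-approximation DeLong CI covers a known binormal AUROC of 0.8
    in 95% +/- 2% of replicates."""
    delta = np.sqrt(2) * stats.norm.ppf(0.8)
    rng = np.random.default_rng(2026)
    hits = 0
    reps = 1000
    for _ in range(reps):
        s = np.concatenate([rng.normal(0, 1, 200), rng.normal(delta, 1, 200)])
        y = np.repeat([0, 1], 200)
        lo, hi = auroc_ci(s, y)
        hits += lo <= 0.8 <= hi
    assert hits / reps == pytest.approx(0.95, abs=0.02)


def test_auroc_ci_degenerate_bootstrap():
    s = np.concatenate([np.zeros(20), np.ones(20)])
    y = np.repeat([0, 1], 20)
    lo, hi = auroc_ci(s, y)
    assert hi == 1.0
    assert lo > 0.5


def test_mcfadden_null_zero_and_manual_oracle():
    rng = np.random.default_rng(4)
    y = np.repeat([0, 1], 30)
    x = rng.normal(size=(60, 1))
    null_like = fit_logistic(np.empty((60, 0)), y)
    assert mcfadden_r2(null_like) == pytest.approx(0.0, abs=1e-9)

    # manual 4-observation oracle
    x4 = np.array([[0.0], [0.0], [1.0], [1.0]])
    y4 = np.array([0, 1, 0, 1])
    fit = fit_logistic(x4, y4, ridge=1e-4)
    probs = fit.fitted_probs
    ll = np.sum(y4 * np.log(probs) + (1 - y4) * np.log1p(-probs))
    llnull = 4 * np.log(0.5)
    assert mcfadden_r2(fit) == pytest.approx(1 - ll / llnull, rel=1e-9)


def test_mcfadden_perfect_predictor_approaches_one():
    x = np.concatenate([-np.arange(1, 21.0), np.arange(1, 21.0)])[:, None]
    y = np.concatenate([np.zeros(20), np.ones(20)])
    fit = fit_logistic(x, y, ridge=1e-6)
    assert mcfadden_r2(fit) > 0.95


# ---------------------------------------------------------------------------
# comparison grids


def _paper_count_cohort(rng):
    """Covariate table with the real analysis counts: 86 femoral-neck,
    75 intertrochanteric and 7 other-site fractures vs 231 controls."""
    n = 399
    y = np.zeros(n, bool)
    y[:168] = True
    sites = np.array(
        ["femoral_neck"] * 86 + ["intertrochanteric"] * 75 + ["other"] * 7 + ["none"] * 231
    )
    risk = rng.normal(size=n) + 0.8 * y
    return pd.DataFrame(
        dict(
            subject_id=[str(i) for i in range(n)],
            fracture=y,
            fracture_site=sites,
            age=rng.normal(71, 4.5, n),
            bmi=rng.normal(26, 4.2, n),
            score=risk,
        )
    )


def test_site_specific_subset_counts(rng):
    df = _paper_count_cohort(rng)
    tab = model_comparison_table(df, {"score": ["score"]})
    by = tab.set_index("outcome")
    assert by.loc["all", "n_cases"] == 168 and by.loc["all", "n_controls"] == 231
    assert by.loc["femoral_neck", "n_cases"] == 86
    assert by.loc["intertrochanteric", "n_cases"] == 75
    assert by.loc["femoral_neck", "n_controls"] == 231
    # 86 + 75 + 7 excluded + 231 = 399
    assert 86 + 75 + 7 + 231 == len(df)


def test_constant_predictor_named_in_error(rng):
    df = _paper_count_cohort(rng)
    df["flat"] = 1.0
    with pytest.raises(ValueError, match="flat"):
        model_comparison_table(df, {"flat": ["flat"]})


def test_combined_model_auroc_at_least_single(paper_data):
    tab = model_comparison_table(
        paper_data,
        {"modes": [f"mode{j}" for j in range(1, 11)],
         "modes_plus_bmd": [f"mode{j}" for j in range(1, 11)] + ["bmd_fn"]},
        outcome_sets=("all",),
    )
    modes = tab[tab.model == "modes"].auroc.iloc[0]
    combined = tab[tab.model == "modes_plus_bmd"].auroc.iloc[0]
    assert combined >= modes - 1e-12


@pytest.mark.parametrize(
    "t,expected",
    [(-0.99, "normal"), (-1.0, "osteopenic"), (-2.5, "osteopenic"),
     (-2.51, "osteoporotic"), (0.7, "normal"), (-1.7, "osteopenic")],
)
def test_tscore_stratum_boundaries(t, expected):
    """Both boundaries belong to the osteopenic stratum; the three rules
    partition the line."""
    assert assign_stratum(t) == expected
    assert sum(spec.contains(t) for spec in DEFAULT_STRATA) == 1


def test_stratified_reports_case_percentages(paper_data):
    tab = stratified_auroc(paper_data, {"fn_bmd": ["bmd_fn"]})
    for _, row in tab.iterrows():
        if row.n:
            assert row.case_percent == pytest.approx(
                round(100.0 * row.n_cases / row.n), abs=0.5
            )


def test_stratified_handles_empty_strata(rng):
    df = _paper_count_cohort(rng)
    df["fn_tscore"] = rng.uniform(-0.9, 1.0, len(df))  # everyone normal BMD
    df["bmd_fn"] = rng.normal(0.8, 0.05, len(df))
    tab = stratified_auroc(df, {"score": ["score"]})
    empty = tab[tab.stratum != "normal"]
    assert (empty.note.str.startswith("not_estimable")).all()
    assert np.isfinite(tab[tab.stratum == "normal"].auroc).all()
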