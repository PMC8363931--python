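"""Cox machinery, PH diagnostics, corrections, nonparametric tests."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

from mesozone.cohort import CohortSpec, generate_cohort
from mesozone.survival import (ConvergenceError, bonferroni, cox_fit,
                               logrank, mann_whitney, ph_test, run_screen,
                               spearman)


def _sim(n, beta=0.5, seed=0, censor_upper=30.0, binary=False):
    rng = np.random.default_rng(seed)
    x = rng.binomial(1, 0.5, n).astype(float) if binary \
        else rng.normal(size=n)
    t = rng.exponential(1.0 / (0.05 * np.exp(beta * x)))
    c = rng.uniform(0, censor_upper, n)
    return pd.DataFrame({"x": x, "months": np.minimum(t, c),
                         "event": (t <= c).astype(int)})


# --- Cox fitting ------------------------------------------------------


def tiny_datasets():
    """Small tie-free datasets for the exhaustive-likelihood oracle."""
    return [
        ([2.0, 5.0, 1.0, 7.0, 3.5], [1, 1, 0, 1, 1],
         [0.5, -1.2, 0.3, 2.0, -0.7]),
        ([1.0, 2.0, 3.0, 4.0, 5.0, 6.0], [1, 0, 1, 1, 0, 1],
         [1.0, 0.0, -1.0, 0.5, 1.5, -0.5]),
        ([4.0, 9.0, 2.5, 6.0, 8.0, 1.5, 3.0, 7.0], [1, 1, 1, 0, 1, 1, 0, 1],
         [0.2, -0.4, 1.1, 0.9, -1.3, 0.6, 0.0, -0.8]),
    ]


def _hand_partial_loglik(beta, times, events, x):
    """Direct textbook partial likelihood (no ties), independent of the
    package implementation."""
    ll = 0.0
    for i in range(len(times)):
        if events[i] != 1:
            continue
        risk = [j for j in range(len(times)) if times[j] >= times[i]]
        ll += beta * x[i] - np.log(sum(np.exp(beta * x[j]) for j in risk))
    return ll


@pytest.mark.parametrize("data", tiny_datasets())
def test_beta_matches_bruteforce_likelihood_maximum(data):
    """Newton beta equals direct scalar maximization of the hand-coded
    partial likelihood to 1e-6 on tiny datasets."""
    times, events, x = data
    fit = cox_fit(pd.DataFrame({"x": x}), times, events)
    res = optimize.minimize_scalar(
        lambda b: -_hand_partial_loglik(b, times, events, x),
        bounds=(-10, 10), method="bounded",
        options={"xatol": 1e-10})
    assert fit.beta[0] == pytest.approx(res.x, abs=1e-6)


def test_identical_groups_give_null_fit():
    """A group indicator with identical survival in both groups fits
    HR ~ 1, p ~ 1."""
    t = [3.0, 6.0, 9.0, 12.0]
    df = pd.DataFrame({
        "g": [0, 0, 0, 0, 1, 1, 1, 1],
        "months": t + t,
        "event": [1] * 8,
    })
    fit = cox_fit(df[["g"]], df["months"], df["event"])
    res = fit.results()[0]
    assert res.hr == pytest.approx(1.0, abs=1e-6)
    assert res.p == pytest.approx(1.0, abs=1e-6)


def test_matches_lifelines_with_and_without_ties():
    from lifelines import CoxPHFitter
    for ties in (False, True):
        df = _sim(250, beta=0.4, seed=4)
        if ties:
            df["months"] = np.ceil(df["months"])
        fit = cox_fit(df[["x"]], df["months"], df["event"])
        cph = CoxPHFitter().fit(df, "months", "event")
        assert fit.beta[0] == pytest.approx(cph.params_["x"], abs=1e-5)
        assert fit.se[0] == pytest.approx(cph.standard_errors_["x"],
                                          abs=1e-5)


def test_wald_ci_brackets_hr():
    df = _sim(200, seed=1)
    res = cox_fit(df[["x"]], df["months"], df["event"]).results()[0]
    assert res.ci_low <= res.hr <= res.ci_high
    assert res.hr > 0


def test_cox_invariances():
    """Adding a constant leaves beta unchanged; scaling by c divides beta by
    c (exactly the x1000 convention)."""
    df = _sim(300, seed=2)
    base = cox_fit(df[["x"]], df["months"], df["event"]).beta[0]
    shifted = cox_fit(pd.DataFrame({"x": df["x"] + 100.0}),
                      df["months"], df["event"]).beta[0]
    scaled = cox_fit(pd.DataFrame({"x": df["x"] * 250.0}),
                     df["months"], df["event"]).beta[0]
    assert shifted == pytest.approx(base, rel=1e-8, abs=1e-10)
    assert scaled == pytest.approx(base / 250.0, rel=1e-8)


def test_perfect_separation_raises():
    n = 12
    t = np.arange(1.0, n + 1)
    x = -t  # larger x -> strictly earlier death
    with pytest.raises(ConvergenceError):
        cox_fit(pd.DataFrame({"x": x}), t, np.ones(n, int))


def test_degenerate_inputs_rejected():
    with pytest.raises(ValueError, match="events"):
        cox_fit(pd.DataFrame({"x": [1.0, 2.0, 3.0]}), [1, 2, 3], [1, 0, 0])
    with pytest.raises(ValueError, match="constant"):
        cox_fit(pd.DataFrame({"x": [1.0, 1.0, 1.0, 1.0]}),
                [1, 2, 3, 4], [1, 1, 1, 1])


def test_ci_coverage_is_nominal():
    """95% Wald CIs cover the simulated binary-covariate HR = 1.5 at close
    to nominal rate."""
    hits = 0
    reps = 120
    for seed in range(reps):
        df = _sim(400, beta=np.log(1.5), seed=seed, binary=True)
        res = cox_fit(df[["x"]], df["months"], df["event"]).results()[0]
        hits += res.ci_low <= 1.5 <= res.ci_high
    assert 0.90 <= hits / reps <= 0.99


# --- PH diagnostics ---------------------------------------------------


def test_ph_test_matches_lifelines():
    from lifelines import CoxPHFitter
    from lifelines.statistics import proportional_hazard_test
    df = _sim(200, beta=0.4, seed=6)
    df["z"] = np.random.default_rng(0).normal(size=len(df))
    fit = cox_fit(df[["x", "z"]], df["months"], df["event"])
    mine = ph_test(fit).set_index("variable")
    cph = CoxPHFitter().fit(df, "months", "event")
    ref = proportional_hazard_test(cph, df, time_transform="identity")
    for var in ("x", "z"):
        assert mine.loc[var, "chi2"] == pytest.approx(
            ref.summary.loc[var, "test_statistic"], abs=1e-4)


def test_ph_type_one_error_calibrated():
    """Under proportional hazards, rejection at 0.05 stays near nominal."""
    rejections = 0
    reps = 500
    for seed in range(reps):
        df = _sim(60, beta=0.4, seed=10_000 + seed)
        try:
            fit = cox_fit(df[["x"]], df["months"], df["event"])
        except (ValueError, ConvergenceError):
            continue
        p = ph_test(fit).iloc[0]["ph_p"]
        rejections += p < 0.05
    assert 0.02 <= rejections / reps <= 0.09


def test_ph_detects_time_varying_effect():
    """A covariate whose effect flips sign at the median event time is
    flagged in most replicates."""
    hits = 0
    reps = 40
    for seed in range(reps):
        rng = np.random.default_rng(seed)
        n = 300
        x = rng.normal(size=n)
        # piecewise hazard: effect +1 before t0, -1 after
        t0 = 10.0
        t1 = rng.exponential(1.0 / (0.08 * np.exp(1.0 * x)))
        t = np.where(t1 < t0, t1,
                     t0 + rng.exponential(1.0 / (0.08 * np.exp(-1.0 * x))))
        fit = cox_fit(pd.DataFrame({"x": x}), t, np.ones(n, int))
        hits += ph_test(fit).iloc[0]["ph_p"] < 0.05
    assert hits / reps > 0.5


def test_ph_needs_three_events():
    df = pd.DataFrame({"x": [0.1, 0.9, 0.4, 0.2],
                       "months": [1.0, 2.0, 3.0, 4.0],
                       "event": [1, 1, 0, 0]})
    fit = cox_fit(df[["x"]], df["months"], df["event"])
    with pytest.raises(ValueError, match="3 events"):
        ph_test(fit)


# --- corrections ------------------------------------------------------


def test_bonferroni_worked_examples():
    """m = 70: p = 0.03 caps at 1.00; p = 0.0006 corrects to 0.04 at two
    decimals."""
    assert bonferroni([0.03], m=70)[0] == 1.0
    assert round(float(bonferroni([0.0006], m=70)[0]), 2) == 0.04
    assert bonferroni([0.5], m=1)[0] == 0.5


def test_bonferroni_properties():
    rng = np.random.default_rng(0)
    p = np.sort(rng.random(20))
    corr = bonferroni(p, m=40)
    assert np.all(corr >= p)           # never decreases
    assert np.all(np.diff(corr) >= 0)  # order-preserving
    with pytest.raises(ValueError):
        bonferroni([0.1], m=0)
    with pytest.raises(ValueError):
        bonferroni([0.1, 0.2], m=1)
    with pytest.raises(ValueError):
        bonferroni([1.5], m=2)


# --- log-rank ---------------------------------------------------------


def test_logrank_identical_groups():
    t = [2.0, 4.0, 6.0, 8.0]
    stat, p = logrank({"a": (t, [1, 1, 1, 1]), "b": (t, [1, 1, 1, 1])})
    assert stat == pytest.approx(0.0, abs=1e-12)
    assert p == pytest.approx(1.0)


def test_logrank_matches_manual_risk_set_tabulation():
    """Two-group statistic equals the hand-tabulated (O-E)^2/V form."""
    ta, ea = [1.0, 3.0, 5.0, 7.0], [1, 1, 0, 1]
    tb, eb = [2.0, 4.0, 6.0, 8.0], [1, 0, 1, 1]
    stat, p = logrank({"a": (ta, ea), "b": (tb, eb)})

    # manual tabulation over pooled event times
    times = sorted({t for t, e in zip(ta + tb, ea + eb) if e == 1})
    O = E = V = 0.0
    for t in times:
        na = sum(1 for s in ta if s >= t)
        nb = sum(1 for s in tb if s >= t)
        d = sum(1 for s, e in zip(ta + tb, ea + eb) if s == t and e == 1)
        da = sum(1 for s, e in zip(ta, ea) if s == t and e == 1)
        n = na + nb
        O += da
        E += d * na / n
        if n > 1:
            V += d * (na / n) * (nb / n) * (n - d) / (n - 1)
    manual = (O - E) ** 2 / V
    assert stat == pytest.approx(manual, rel=1e-9)
    assert p == pytest.approx(stats.chi2.sf(manual, 1), rel=1e-9)


def test_logrank_errors():
    with pytest.raises(ValueError, match="2 groups"):
        logrank({"a": ([1.0], [1])})
    with pytest.raises(ValueError, match="empty"):
        logrank({"a": ([1.0], [1]), "b": ([], [])})


def test_logrank_agrees_with_cox_asymptotically():
    df = _sim(1000, beta=np.log(1.4), seed=8, binary=True)
    stat, p_lr = logrank({
        "lo": (df.loc[df.x == 0, "months"], df.loc[df.x == 0, "event"]),
        "hi": (df.loc[df.x == 1, "months"], df.loc[df.x == 1, "event"])})
    p_cox = cox_fit(df[["x"]], df["months"], df["event"]).results()[0].p
    assert p_lr == pytest.approx(p_cox, abs=0.02)


# --- rank tests -------------------------------------------------------


def test_mann_whitney_identical_samples():
    x = [1.0, 2.0, 3.0, 4.0]
    _, p = mann_whitney(x, x)
    assert p > 0.8


def test_mann_whitney_fully_separated_exact():
    """n = 3 vs 3, complete separation: U in {0, 9}, exact two-sided
    p = 2/20 = 0.1."""
    u, p = mann_whitney([1.0, 2.0, 3.0], [10.0, 11.0, 12.0])
    assert u in (0.0, 9.0)
    assert p == pytest.approx(0.1)


def test_mann_whitney_monotone_invariance():
    rng = np.random.default_rng(3)
    x, y = rng.random(12), rng.random(15) + 0.2
    _, p1 = mann_whitney(x, y)
    _, p2 = mann_whitney(np.exp(x), np.exp(y))
    assert p1 == pytest.approx(p2)


def test_spearman_perfect_monotone():
    assert spearman([1, 2, 3, 4], [10, 20, 30, 40])[0] == pytest.approx(1.0)
    assert spearman([1, 2, 3, 4], [8, 6, 4, 2])[0] == pytest.approx(-1.0)


def test_spearman_exact_permutation_p_for_small_n():
    """n = 5: p equals exhaustive enumeration over all 120 orderings."""
    x = [1.0, 2.0, 3.0, 4.0, 5.0]
    y = [2.0, 1.0, 4.0, 3.0, 5.0]
    rho, p = spearman(x, y)
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    obs = np.corrcoef(rx, ry)[0, 1]
    count = sum(abs(np.corrcoef(rx, perm)[0, 1]) >= abs(obs) - 1e-12
                for perm in itertools.permutations(ry))
    assert rho == pytest.approx(obs)
    assert p == pytest.approx(count / 120)


def test_spearman_zero_rank_variance_warns():
    with pytest.warns(UserWarning, match="zero variance"):
        rho, p = spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
    assert np.isnan(rho) and np.isnan(p)


# --- the screen -------------------------------------------------------


def _screen_inputs(n=200, beta=0.0, n_vars=5, seed=0):
    cohort = generate_cohort(CohortSpec(n_patients=n, beta=beta, seed=seed))
    rng = np.random.default_rng(seed + 1)
    data = {f"V{i}_stroma": rng.beta(2, 50, n) * 1000.0
            for i in range(n_vars)}
    data["V0_meso"] = cohort["marker_raw"].to_numpy() * 1000.0
    table = pd.DataFrame(data, index=cohort["patient_id"])
    table.attrs["intensity_scale"] = 1000.0
    return table, cohort.drop(columns=["marker_raw"])


def test_screen_single_variable_m1_corrected_equals_raw():
    table, cohort = _screen_inputs(n_vars=0)
    report = run_screen(table, cohort, compute_ph=False)
    assert len(report) == 1
    assert report.loc[0, "p_corrected"] == pytest.approx(report.loc[0, "p"])


def test_screen_requires_scaled_table():
    table, cohort = _screen_inputs()
    table.attrs["intensity_scale"] = 1.0
    with pytest.raises(ValueError, match="unscaled"):
        run_screen(table, cohort)


def test_screen_too_few_cases_rejected():
    table, cohort = _screen_inputs(n=200)
    with pytest.raises(ValueError, match="complete cases"):
        run_screen(table.iloc[:5], cohort.iloc[:5])


def test_screen_recovers_single_effect_variable():
    """With one truly prognostic variable among 70, it attains the smallest
    corrected p in nearly every replicate."""
    hits = 0
    reps = 20
    for seed in range(reps):
        cohort = generate_cohort(CohortSpec(n_patients=500,
                                            beta=np.log(1.02), seed=seed))
        rng = np.random.default_rng(seed + 1000)
        data = {f"N{i}": rng.beta(2, 50, 500) * 1000.0 for i in range(69)}
        data["PDGFRB_meso"] = cohort["marker_raw"].to_numpy() * 1000.0
        table = pd.DataFrame(data, index=cohort["patient_id"])
        table.attrs["intensity_scale"] = 1000.0
        report = run_screen(table, cohort.drop(columns=["marker_raw"]),
                            compute_ph=False)
        hits += report.iloc[0]["variable"] == "PDGFRB_meso"
    assert hits / reps >= 0.9


def test_screen_multivariable_model_adjusts_for_clinical():
    table, cohort = _screen_inputs(n=300, beta=np.log(1.02))
    report = run_screen(table, cohort, compute_ph=True,
                        covariate_sets={"m1": ["V0_meso"]})
    multi = report[report.model_id == "m1"]
    assert {"age", "sex_female", "side_left", "stage_high"} \
        <= set(multi["variable"])
    effect = multi[multi.variable == "V0_meso"].iloc[0]
    assert effect.hr > 1.0
    assert np.isfinite(effect.ph_p)
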