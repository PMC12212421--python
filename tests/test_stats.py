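"""AUROC machinery, resampling inference, survival statistics, correlations."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst
from scipy.optimize import minimize_scalar

from hnmil import stats as st


def _auroc_by_enumeration(scores, labels):
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def test_auroc_equals_pairwise_concordance_enumeration():
    rng = np.random.default_rng(0)
    for n in range(2, 13):
        for rep in range(30):
            labels = rng.integers(0, 2, n)
            if labels.sum() in (0, n):
                continue
            scores = rng.choice([0.1, 0.25, 0.5, 0.5, 0.9], size=n)  # with ties
            assert st.auroc(scores, labels) == pytest.approx(
                _auroc_by_enumeration(scores, labels), abs=1e-12
            )


def test_auroc_worked_example_and_edges():
    assert st.auroc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == 0.75
    assert st.auroc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0
    assert st.auroc([0.5] * 6, [0, 1] * 3) == 0.5
    with pytest.raises(ValueError):
        st.auroc([0.1, 0.2], [1, 1])


@settings(max_examples=50, derandomize=True)
@given(hst.lists(hst.floats(0, 1, allow_nan=False), min_size=4, max_size=20))
def test_auroc_score_negation_complement(raw):
    scores = np.array(raw)
    if np.unique(scores).size < len(scores):
        scores = scores + np.linspace(0, 1e-9, len(scores))  # enforce tie-free
    labels = np.array([0, 1] * (len(scores) // 2) + [0] * (len(scores) % 2))
    a = st.auroc(scores, labels)
    b = st.auroc(-scores, labels)
    assert a + b == pytest.approx(1.0, abs=1e-12)


def test_bootstrap_ci_determinism_and_perfect_separation():
    scores = [0.1, 0.2, 0.8, 0.9]
    labels = [0, 0, 1, 1]
    r1 = st.bootstrap_auroc_ci(scores, labels, n_boot=200, seed=7)
    r2 = st.bootstrap_auroc_ci(scores, labels, n_boot=200, seed=7)
    assert (r1.ci_low, r1.ci_high) == (r2.ci_low, r2.ci_high)
    assert r1.ci_low == 1.0 and r1.ci_high == 1.0
    assert r1.ci_low <= r1.auroc <= r1.ci_high


def test_bootstrap_ci_coverage():
    """Percentile CI covers the analytic AUROC of the binormal model 90-99%."""
    from scipy.stats import norm

    mu = 1.0
    true_auroc = norm.cdf(mu / np.sqrt(2))
    covered = 0
    reps = 200
    for rep in range(reps):
        rng = np.random.default_rng(rep)
        y = np.r_[np.zeros(50, int), np.ones(50, int)]
        s = rng.standard_normal(100) + mu * y
        res = st.bootstrap_auroc_ci(s, y, n_boot=500, rng=rng)
        covered += res.ci_low <= true_auroc <= res.ci_high
    assert 0.90 * reps <= covered <= 0.99 * reps


def test_permutation_test_identical_models_gives_p_one():
    s = [0.1, 0.4, 0.35, 0.8]
    assert st.permutation_auroc_test(s, s, [0, 0, 1, 1], n=200, seed=0) == 1.0
    with pytest.raises(ValueError):
        st.permutation_auroc_test([0.1], [0.1, 0.2], [0, 1], n=10)


def test_permutation_test_type_one_error_calibration():
    rejections = 0
    reps = 200
    for rep in range(reps):
        rng = np.random.default_rng(1000 + rep)
        n = 80
        y = np.r_[np.zeros(40, int), np.ones(40, int)]
        x = y + rng.normal(0, 1, n)
        sa = x + rng.normal(0, 0.8, n)
        sb = x + rng.normal(0, 0.8, n)
        p = st.permutation_auroc_test(sa, sb, y, n=200, rng=rng)
        rejections += p < 0.05
    assert 0.02 <= rejections / reps <= 0.09


def test_permutation_test_power_for_a_truly_better_model():
    wins = 0
    for rep in range(10):
        rng = np.random.default_rng(2000 + rep)
        n = 500
        y = rng.integers(0, 2, n)
        good = y + rng.normal(0, 0.8, n)
        bad = y + rng.normal(0, 3.0, n)
        p = st.permutation_auroc_test(good, bad, y, n=300,
                                      alternative="greater", rng=rng)
        wins += p < 0.05
    assert wins >= 6  # majority of replicates


def test_km_no_events_and_worked_example():
    km = st.km_curve([3, 5, 8], [0, 0, 0])
    assert km.evaluate(100.0) == 1.0
    km2 = st.km_curve([5, 10], [1, 0])
    assert km2.evaluate(2) == 1.0
    assert km2.evaluate(5) == 0.5
    assert km2.evaluate(12) == 0.5


def test_km_matches_product_limit_oracle():
    rng = np.random.default_rng(3)
    times = rng.exponential(10, 40).round(1)
    events = rng.integers(0, 2, 40)
    km = st.km_curve(times, events)
    for t in np.unique(times):
        s = 1.0
        for u in np.unique(times[(events == 1)]):
            if u <= t:
                d = ((times == u) & (events == 1)).sum()
                at_risk = (times >= u).sum()
                s *= 1 - d / at_risk
        assert km.evaluate(t) == pytest.approx(s, abs=1e-12)
    # nonincreasing, starts at 1
    assert km.evaluate(0) <= 1.0 + 1e-12
    vals = [km.evaluate(t) for t in np.sort(times)]
    assert all(a >= b - 1e-12 for a, b in zip(vals, vals[1:]))


def test_logrank_identical_groups_and_errors():
    t = [5, 6, 7, 8] * 2
    e = [1, 0, 1, 0] * 2
    g = [0] * 4 + [1] * 4
    stat, p = st.logrank_test(t, e, g)
    assert stat == pytest.approx(0.0, abs=1e-12)
    assert p == pytest.approx(1.0)
    with pytest.raises(ValueError):
        st.logrank_test([1, 2], [1, 1], [0, 0])


def test_logrank_type_one_error_calibration():
    rejections = 0
    reps = 500
    for rep in range(reps):
        rng = np.random.default_rng(3000 + rep)
        t = rng.exponential(1.0, 120)
        e = (rng.random(120) > 0.2).astype(int)
        g = np.r_[np.zeros(60, int), np.ones(60, int)]
        _, p = st.logrank_test(t, e, g)
        rejections += p < 0.05
    assert 0.03 <= rejections / reps <= 0.08


def test_logrank_power_under_strong_hazard_ratio():
    small_p = 0
    for rep in range(10):
        rng = np.random.default_rng(4000 + rep)
        g = np.r_[np.zeros(100, int), np.ones(100, int)]
        t = np.where(g == 1, rng.exponential(1 / 3, 200), rng.exponential(1.0, 200))
        _, p = st.logrank_test(t, np.ones(200, int), g)
        small_p += p < 0.001
    assert small_p >= 8


def test_cox_matches_brute_force_partial_likelihood():
    rng = np.random.default_rng(5)
    g = np.arange(20) % 2
    t = np.where(g == 1, rng.exponential(0.5, 20), rng.exponential(1.0, 20))
    e = np.ones(20, int)
    res = st.cox_hr_binary(t, e, g)

    def neg_pl(beta):
        ll = 0.0
        for i in np.argsort(t):
            if e[i]:
                risk = t >= t[i]
                ll += beta * g[i] - np.log(np.exp(beta * g[risk]).sum())
        return -ll

    beta_hat = minimize_scalar(neg_pl, bounds=(-5, 5), method="bounded").x
    assert res.hr == pytest.approx(np.exp(beta_hat), abs=1e-3)


def test_cox_recovery_of_true_hazard_ratio():
    covered = 0
    for rep in range(100):
        rng = np.random.default_rng(5000 + rep)
        g = np.r_[np.zeros(200, int), np.ones(200, int)]
        rate = np.where(g == 1, 0.2, 0.1)  # true HR = 2
        t_event = rng.exponential(1 / rate)
        t_cens = rng.exponential(20.0, 400)
        t = np.minimum(t_event, t_cens)
        e = (t_event <= t_cens).astype(int)
        res = st.cox_hr_binary(t, e, g)
        covered += res.ci_low <= 2.0 <= res.ci_high
    assert covered >= 90


def test_cox_null_and_degenerate():
    t = [1, 2, 3, 4, 1, 2, 3, 4]
    e = [1, 1, 0, 1] * 2
    g = [0] * 4 + [1] * 4
    res = st.cox_hr_binary(t, e, g)
    assert res.hr == pytest.approx(1.0, abs=0.05)
    res0 = st.cox_hr_binary([1, 2], [0, 0], [0, 1])
    assert res0.degenerate and res0.hr is None


def test_stratify_cutoff_and_degenerate_contract():
    res = st.stratify_by_median([0.1, 0.2, 0.3, 0.4], [0.3, 0.3], [5, 9], [1, 1])
    assert res.cutoff == pytest.approx(0.25)
    all_high = st.stratify_by_median([0.1, 0.2], [0.9, 0.8, 0.7], [1, 2, 3], [1, 1, 0])
    assert all_high.degenerate_flag and all_high.hr is None
    with pytest.raises(ValueError):
        st.stratify_by_median([], [0.5], [1], [1])


def test_stratification_separates_risk_ordered_survival():
    rng = np.random.default_rng(6)
    n = 300
    risk = rng.standard_normal(n)
    scores = 1 / (1 + np.exp(-2 * risk))
    t_event = rng.exponential(1 / (0.05 * np.exp(1.2 * risk)))
    t_cens = rng.exponential(60, n)
    t = np.minimum(t_event, t_cens)
    e = (t_event <= t_cens).astype(int)
    res = st.stratify_by_median(scores, scores, t, e)
    assert not res.degenerate_flag
    assert res.hr > 1.0
    assert res.logrank_p < 0.05
    # direction agreement between HR and observed event counts
    high = res.high_risk
    assert e[high].mean() > e[~high].mean()


def test_correlations_kinds_and_examples():
    scores = np.array([0.1, 0.2, 0.3, 0.4])
    clin = pd.DataFrame({
        "age": [50, 55, 60, 65],
        "t_stage": [1, 2, 3, 4],
        "n_stage": [0, 0, 0, 0],
        "sex": [0, 0, 1, 1],
        "chemo": [0, 1, 0, 1],
        "hpv_positive": [1, 0, 1, 0],
    })
    out = st.correlate_scores_clinical(scores, clin).set_index("variable")
    assert out.loc["t_stage", "coefficient"] == pytest.approx(1.0)
    assert out.loc["t_stage", "kind"] == "spearman"
    assert out.loc["sex", "kind"] == "pointbiserial"
    assert out.loc["sex", "coefficient"] == pytest.approx(0.894, abs=1e-3)
    assert bool(out.loc["n_stage", "flagged_constant"])
    assert np.isnan(out.loc["n_stage", "coefficient"])


def test_correlations_null_behaves():
    rhos, ps = [], []
    for rep in range(50):
        rng = np.random.default_rng(6000 + rep)
        scores = rng.random(80)
        clinical = pd.DataFrame({"age": rng.normal(60, 8, 80)})
        row = st.correlate_scores_clinical(scores, clinical).iloc[0]
        rhos.append(row["coefficient"])
        ps.append(row["p"])
    assert abs(np.mean(rhos)) < 0.1
    assert 0.3 <= np.mean(ps) <= 0.7


def test_bh_adjustment_examples_and_properties():
    np.testing.assert_allclose(st.bh_adjust([0.01, 0.02, 0.03, 0.04]),
                               [0.04, 0.04, 0.04, 0.04])
    np.testing.assert_allclose(st.bh_adjust([0.2]), [0.2])
    rng = np.random.default_rng(7)
    p = rng.random(30)
    adj = st.bh_adjust(p)
    assert (adj >= p - 1e-12).all()
    assert (adj <= 1.0).all()
    order = np.argsort(p)
    assert (np.diff(adj[order]) >= -1e-12).all()  # monotone in raw ranks
    with pytest.raises(ValueError):
        st.bh_adjust([0.5, 1.5])
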