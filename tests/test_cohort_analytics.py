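"""Statistics layer vs independent brute-force oracles; clustering; survival."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import special, stats

from aluedit import (
    Site,
    bh_fdr,
    cluster_samples,
    correlate,
    cox_multivariate,
    group_ttest,
    km_logrank,
    variance_ftest,
)
from aluedit.cohort_analytics import cohort_summary, km_median, silhouette_scores
from aluedit.recurrence_catalog import EditingMatrix


def _matrix(freq: pd.DataFrame) -> EditingMatrix:
    sites = [Site("c", i, "+", str(k)) for i, k in enumerate(freq.index)]
    freq = freq.copy()
    freq.index = [s.key for s in sites]
    d = freq.notna().astype(int) * 100
    e = (freq.fillna(0) * 100).round().astype(int)
    return EditingMatrix(sites=sites, samples=list(freq.columns), freq=freq,
                         depth=d, edited=e, min_cov=10)


# ---------------------------------------------------------------------------
# brute-force oracles


def brute_pearson(x, y):
    x, y = np.asarray(x, float), np.asarray(y, float)
    n = len(x)
    xm, ym = x - x.mean(), y - y.mean()
    r = (xm * ym).sum() / np.sqrt((xm**2).sum() * (ym**2).sum())
    t = r * np.sqrt((n - 2) / (1 - r**2))
    p = 2 * (1 - special.stdtr(n - 2, abs(t)))
    return r, p


def brute_welch_t(a, b):
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    se2 = va / na + vb / nb
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2 * (1 - special.stdtr(df, abs(t)))
    return t, p


def brute_bh(p):
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        rank = m - rank_from_top
        running = min(running, p[idx] * m / rank)
        adj[idx] = running
    return adj


def brute_km_curve(times, events):
    """Product-limit estimate as a list of (time, survival) steps."""
    df = pd.DataFrame({"t": times, "e": events}).sort_values("t")
    s = 1.0
    curve = []
    for t in sorted(df["t"].unique()):
        at_risk = int((df["t"] >= t).sum())
        d = int(df.loc[(df["t"] == t) & (df["e"] == 1)].shape[0])
        if d:
            s *= 1 - d / at_risk
        curve.append((t, s))
    return curve


def brute_km_median(times, events):
    for t, s in brute_km_curve(times, events):
        if s <= 0.5:
            return t
    return np.inf


def brute_logrank(times, events, groups):
    """O-E log-rank chi-square by direct enumeration over event times."""
    times, events, groups = map(np.asarray, (times, events, groups))
    obs = exp = var = 0.0
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & (groups == np.unique(groups)[1])).sum()
        d = ((times == t) & (events == 1)).sum()
        d1 = ((times == t) & (events == 1) & (groups == np.unique(groups)[1])).sum()
        obs += d1
        exp += d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    chi2 = (obs - exp) ** 2 / var
    return chi2, stats.chi2.sf(chi2, 1)


# ---------------------------------------------------------------------------


class TestCorrelate:
    def test_perfect_linear_relation(self):
        x = np.arange(10.0)
        r, p = correlate(x, 2 * x + 1)
        assert r == pytest.approx(1.0)

    def test_matches_brute_force_formula(self):
        x = [1.0, 2.0, 4.0, 4.5, 7.0]
        y = [2.2, 1.9, 3.1, 4.0, 3.7]
        r, p = correlate(x, y)
        rb, pb = brute_pearson(x, y)
        assert r == pytest.approx(rb, abs=1e-12)
        assert p == pytest.approx(pb, abs=1e-10)

    def test_zero_variance_is_error(self):
        with pytest.raises(ValueError, match="variance"):
            correlate([1, 1, 1, 1], [1, 2, 3, 4])

    def test_too_few_pairs_is_error(self):
        with pytest.raises(ValueError, match="at least 3"):
            correlate([1, 2], [3, 4])


class TestGroupTtest:
    def test_identical_groups_give_zero_t(self):
        v = np.r_[np.arange(5.0), np.arange(5.0)]
        g = np.r_[np.zeros(5), np.ones(5)]
        t, p = group_ttest(v, g)
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_matches_brute_force_welch(self):
        a = [3.1, 2.7, 4.5, 3.3, 2.9, 3.8]
        b = [5.0, 4.8, 6.1, 5.5]
        t, p = group_ttest(a + b, ["x"] * 6 + ["y"] * 4)
        tb, pb = brute_welch_t(a, b)
        assert t == pytest.approx(tb, abs=1e-12)
        assert p == pytest.approx(pb, abs=1e-10)

    def test_small_group_is_error(self):
        with pytest.raises(ValueError, match="n >= 2"):
            group_ttest([1.0, 2.0, 3.0], ["a", "b", "b"])

    def test_power_matches_analytic_approximation(self):
        """At effect size d = 1 with n = 30/arm, empirical power over
        simulations is close to the analytic normal-approximation power."""
        rng = np.random.default_rng(42)
        n, d, alpha, reps = 30, 1.0, 0.05, 400
        hits = 0
        for _ in range(reps):
            a = rng.normal(0, 1, n)
            b = rng.normal(d, 1, n)
            _, p = group_ttest(np.r_[a, b], np.r_[np.zeros(n), np.ones(n)])
            hits += p < alpha
        se = np.sqrt(2 / n)
        power = stats.norm.sf(stats.norm.isf(alpha / 2) - d / se) + stats.norm.cdf(
            -stats.norm.isf(alpha / 2) - d / se
        )
        assert abs(hits / reps - power) < 3 * np.sqrt(power * (1 - power) / reps) + 0.02


class TestVarianceFtest:
    def test_equal_variances_near_one(self):
        rng = np.random.default_rng(1)
        res = variance_ftest(rng.normal(0, 1, 2000), rng.normal(5, 1, 2000))
        assert 0.85 < res.f_statistic < 1.2

    def test_known_variance_ratio(self):
        rng = np.random.default_rng(2)
        res = variance_ftest(rng.normal(0, 2, 5000), rng.normal(0, 1, 5000))
        assert 3.6 < res.f_statistic < 4.4
        assert res.p_value < 1e-10

    def test_matches_direct_arithmetic(self):
        a = [1.0, 2.0, 4.0, 7.0, 11.0]
        b = [1.0, 1.5, 2.0, 2.5, 3.0]
        res = variance_ftest(a, b)
        f = np.var(a, ddof=1) / np.var(b, ddof=1)
        assert res.f_statistic == pytest.approx(f, abs=1e-12)
        assert res.df == (4, 4)
        assert res.p_value == pytest.approx(2 * stats.f.sf(f, 4, 4), abs=1e-12)

    def test_zero_variance_is_error(self):
        with pytest.raises(ValueError, match="zero variance"):
            variance_ftest([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestBhFdr:
    def test_all_tied(self):
        assert np.allclose(bh_fdr([0.05] * 10), 0.05)

    def test_single_value_unchanged(self):
        assert bh_fdr([0.33])[0] == pytest.approx(0.33)

    def test_worked_example(self):
        assert np.allclose(bh_fdr([0.01, 0.02, 0.03, 0.5]), brute_bh([0.01, 0.02, 0.03, 0.5]))

    def test_out_of_range_is_error(self):
        with pytest.raises(ValueError):
            bh_fdr([0.1, 0.0])
        with pytest.raises(ValueError):
            bh_fdr([0.1, 1.2])

    @given(st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=6))
    def test_matches_brute_force_definition(self, p):
        """BH output equals the step-up definition on all small instances."""
        assert np.allclose(bh_fdr(p), brute_bh(p), atol=1e-12)


class TestClusterSamples:
    def test_disjoint_blocks_split_perfectly(self):
        rng = np.random.default_rng(0)
        left = 0.6 + 0.02 * rng.standard_normal((6, 8))
        right = 0.05 + 0.02 * rng.standard_normal((6, 8))
        freq = pd.DataFrame(
            np.hstack([left, right]).clip(0, 1),
            index=[f"s{i}" for i in range(6)],
            columns=[f"A{i}" for i in range(8)] + [f"B{i}" for i in range(8)],
        )
        m = _matrix(freq)
        labels = cluster_samples(m, k=2).labels
        a = {labels[f"A{i}"] for i in range(8)}
        b = {labels[f"B{i}"] for i in range(8)}
        assert len(a) == 1 and len(b) == 1 and a != b

    def test_partition_invariant_to_sample_order(self):
        rng = np.random.default_rng(3)
        freq = pd.DataFrame(
            rng.random((5, 12)), index=[f"s{i}" for i in range(5)],
            columns=[f"S{i:02d}" for i in range(12)],
        )
        m = _matrix(freq)
        perm = list(rng.permutation(m.samples))
        labels1 = cluster_samples(m, k=3).labels
        labels2 = cluster_samples(m.subset_samples(perm), k=3).labels
        assert (labels1.sort_index() == labels2.sort_index()).all()

    def test_k_larger_than_n_is_error(self):
        freq = pd.DataFrame(np.zeros((3, 2)), index=list("abc"), columns=["S1", "S2"])
        with pytest.raises(ValueError, match="exceeds"):
            cluster_samples(_matrix(freq), k=5)

    def test_silhouette_prefers_true_k(self):
        rng = np.random.default_rng(9)
        blocks = []
        for mu in (0.1, 0.45, 0.8):
            blocks.append(mu + 0.02 * rng.standard_normal((6, 10)))
        freq = pd.DataFrame(
            np.hstack(blocks).clip(0, 1),
            index=[f"s{i}" for i in range(6)],
            columns=[f"S{i:02d}" for i in range(30)],
        )
        scores = silhouette_scores(_matrix(freq), k_range=range(2, 7))
        assert scores.idxmax() == 3


class TestSurvival:
    def test_identical_groups_hr_one_p_one(self):
        times = [5.0, 8.0, 12.0, 20.0, 25.0, 30.0]
        events = [1, 0, 1, 1, 0, 1]
        res = km_logrank(times * 2, events * 2, [0] * 6 + [1] * 6)
        assert res.hazard_ratio == pytest.approx(1.0, abs=1e-6)
        assert res.p_value == pytest.approx(1.0)
        assert res.median_a == res.median_b

    def test_no_events_is_error(self):
        with pytest.raises(ValueError, match="undefined"):
            km_logrank([1, 2, 3, 4], [0, 0, 0, 0], [0, 0, 1, 1])

    def test_empty_group_is_error(self):
        with pytest.raises(ValueError, match="2 groups"):
            km_logrank([1, 2, 3], [1, 1, 1], [0, 0, 0])

    def test_six_subject_toy_matches_enumeration(self):
        times = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        events = [1, 0, 1, 1, 0, 1]
        groups = [0, 0, 0, 1, 1, 1]
        res = km_logrank(times, events, groups)
        chi2, p = brute_logrank(times, events, groups)
        assert res.logrank_stat == pytest.approx(chi2, abs=1e-10)
        assert res.p_value == pytest.approx(p, abs=1e-10)
        assert res.median_a == brute_km_median(times[:3], events[:3])
        assert res.median_b == brute_km_median(times[3:], events[3:])

    def test_km_median_unreached_is_inf(self):
        assert km_median([5, 6, 7, 8], [1, 0, 0, 0]) == np.inf


class TestCoxMultivariate:
    def test_single_binary_covariate_matches_km_logrank(self):
        rng = np.random.default_rng(8)
        n = 120
        groups = np.r_[np.zeros(n // 2), np.ones(n // 2)]
        times = rng.exponential(1.0 / (0.01 * 2.0**groups))
        events = np.ones(n, dtype=int)
        res = km_logrank(times, events, groups)
        table = cox_multivariate(times, events, pd.DataFrame({"g": groups}))
        assert table.loc["g", "HR"] == pytest.approx(res.hazard_ratio, rel=1e-8)

    def test_duplicated_covariate_is_singular(self):
        rng = np.random.default_rng(8)
        x = rng.random(50)
        with pytest.raises(ValueError, match="collinear"):
            cox_multivariate(
                rng.exponential(10, 50), np.ones(50, dtype=int),
                pd.DataFrame({"a": x, "b": x}),
            )

    def test_constant_covariate_is_error(self):
        rng = np.random.default_rng(8)
        with pytest.raises(ValueError, match="constant"):
            cox_multivariate(
                rng.exponential(10, 20), np.ones(20, dtype=int),
                pd.DataFrame({"a": np.ones(20)}),
            )

    def test_recovers_known_hazard_ratios(self):
        """With two independent binary covariates at true HR 2, mean estimates
        over replicates sit near 2."""
        rng = np.random.default_rng(12)
        hrs = []
        for _ in range(25):
            n = 300
            x1 = rng.integers(0, 2, n)
            x2 = rng.integers(0, 2, n)
            hazard = 0.01 * 2.0**x1 * 2.0**x2
            times = rng.exponential(1.0 / hazard)
            table = cox_multivariate(times, np.ones(n, int), pd.DataFrame({"x1": x1, "x2": x2}))
            hrs.append(table["HR"].to_numpy())
        mean = np.mean(hrs, axis=0)
        assert np.all((1.8 < mean) & (mean < 2.2))


def test_cohort_summary_table_percentages(tiny_cohort):
    table = cohort_summary(tiny_cohort.cohort[tiny_cohort.cohort["sample_type"] == "CLL"])
    row = table[(table["parameter"] == "ighv_status") & (table["level"] == "unmutated")]
    assert int(row["count"].iloc[0]) == 5
    assert float(row["percent"].iloc[0]) == round(100 * 5 / 12)
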