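"""Statistical layer: correlations, group tests, FDR, clustering, survival.

Thin, contract-enforcing wrappers over scipy / statsmodels / scikit-learn /
lifelines, plus the hierarchical clustering of editing profiles and the
Kaplan-Meier / log-rank / Cox machinery used to relate editing clusters to
time-to-first-treatment endpoints.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.metrics import silhouette_score
from statsmodels.stats.multitest import multipletests

from .recurrence_catalog import EditingMatrix


@dataclass(frozen=True)
class ClusterAssignment:
    labels: pd.Series  # sample -> 1-based cluster label
    linkage_method: str
    metric: str
    k: int

    def __post_init__(self) -> None:
        if self.labels.index.duplicated().any():
            raise ValueError("duplicate sample in cluster assignment")


@dataclass(frozen=True)
class SurvivalResult:
    median_a: float  # months; inf when unreached
    median_b: float
    hazard_ratio: float
    ci_low: float
    ci_high: float
    logrank_stat: float
    p_value: float
    n_a: int
    n_b: int

    def __post_init__(self) -> None:
        if not np.isnan(self.hazard_ratio) and not (
            self.ci_low <= self.hazard_ratio <= self.ci_high
        ):
            raise ValueError("CI must bracket the hazard ratio")
        if not 0 < self.p_value <= 1:
            raise ValueError("p-value must lie in (0, 1]")


@dataclass(frozen=True)
class VarianceTestResult:
    f_statistic: float
    df: tuple[int, int]
    p_value: float

    def __post_init__(self) -> None:
        if self.f_statistic <= 0:
            raise ValueError("F must be positive")


def correlate(x, y, method: str = "pearson") -> tuple[float, float]:
    """Pearson or Spearman correlation with two-sided p; NaN pairs dropped."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ValueError("need at least 3 paired non-missing values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in input vector")
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
    elif method == "spearman":
        r, p = stats.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(r), float(p)


def group_ttest(values, groups, equal_var: bool = False) -> tuple[float, float]:
    """Two-sided unpaired t-test between the two groups (Welch by default)."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    levels = pd.unique(groups[~pd.isna(groups)])
    if len(levels) != 2:
        raise ValueError(f"expected exactly 2 groups, got {len(levels)}")
    a = values[groups == levels[0]]
    b = values[groups == levels[1]]
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p)


def variance_ftest(values_a, values_b) -> VarianceTestResult:
    """Two-sided F-test of equal variances, larger variance in the numerator."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if min(va, vb) == 0:
        raise ValueError("zero variance denominator")
    if va >= vb:
        f, dfn, dfd = va / vb, len(a) - 1, len(b) - 1
    else:
        f, dfn, dfd = vb / va, len(b) - 1, len(a) - 1
    p = min(1.0, 2.0 * stats.f.sf(f, dfn, dfd))
    return VarianceTestResult(f_statistic=float(f), df=(dfn, dfd), p_value=float(p))


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def cohort_summary(cohort: pd.DataFrame) -> pd.DataFrame:
    """Counts and percentages of categorical cohort covariates.

    Percentages are of the full table, rounded to the nearest integer the
    way clinical characteristics tables print them, with one decimal also
    reported.
    """
    n = len(cohort)
    rows = []
    for status in ("mutated", "unmutated", "unknown"):
        c = int((cohort["ighv_status"] == status).sum())
        rows.append(("ighv_status", status, c, round(100.0 * c / n), round(100.0 * c / n, 1)))
    for flag in ("del11q", "del13q", "del17p", "trisomy12"):
        if flag in cohort.columns:
            c = int(cohort[flag].fillna(0).astype(bool).sum())
            rows.append((flag, "present", c, round(100.0 * c / n), round(100.0 * c / n, 1)))
    return pd.DataFrame(rows, columns=["parameter", "level", "count", "percent", "percent_1dp"])


# ---------------------------------------------------------------------------
# Clustering


def impute_site_means(freq: pd.DataFrame) -> pd.DataFrame:
    """Replace missing cells with the site's cross-sample mean frequency."""
    means = freq.mean(axis=1)
    if means.isna().any():
        raise ValueError("site with no observed cells cannot be imputed")
    return freq.apply(lambda row: row.fillna(means[row.name]), axis=1)


def cluster_samples(matrix: EditingMatrix, k: int) -> ClusterAssignment:
    """Agglomerative (Ward, Euclidean) clustering of samples on site profiles.

    Missing cells are imputed with the site's cross-sample mean; the
    dendrogram is cut into exactly ``k`` groups.  Labels are renumbered
    1..k by decreasing cluster size (ties by smallest sample id) so the
    partition is deterministic and invariant to sample order.
    """
    n = len(matrix.samples)
    if k > n:
        raise ValueError(f"k={k} exceeds number of samples ({n})")
    filled = impute_site_means(matrix.freq)
    # cluster in a fixed sample order so the linkage is order-invariant
    order = sorted(matrix.samples)
    X = filled[order].to_numpy().T
    Z = linkage(X, method="ward", metric="euclidean")
    raw = fcluster(Z, t=k, criterion="maxclust")
    labels = pd.Series(raw, index=order)
    # deterministic relabelling
    groups = sorted(
        ((lab, grp.index.min(), len(grp)) for lab, grp in labels.groupby(labels)),
        key=lambda t: (-t[2], t[1]),
    )
    remap = {old: i + 1 for i, (old, _first, _size) in enumerate(groups)}
    labels = labels.map(remap).reindex(matrix.samples)
    return ClusterAssignment(labels=labels, linkage_method="ward", metric="euclidean", k=k)


def silhouette_scores(matrix: EditingMatrix, k_range=range(2, 9)) -> pd.Series:
    """Mean silhouette score of the Ward cut for each candidate k."""
    filled = impute_site_means(matrix.freq)
    X = filled[sorted(matrix.samples)].to_numpy().T
    Z = linkage(X, method="ward", metric="euclidean")
    out = {}
    for k in k_range:
        if k >= len(matrix.samples):
            continue
        lab = fcluster(Z, t=k, criterion="maxclust")
        if len(np.unique(lab)) < 2:
            continue
        out[k] = float(silhouette_score(X, lab, metric="euclidean"))
    return pd.Series(out, name="silhouette")


# ---------------------------------------------------------------------------
# Survival


def km_median(times, events) -> float:
    """Kaplan-Meier median survival time; inf when never reached."""
    kmf = KaplanMeierFitter()
    kmf.fit(np.asarray(times, dtype=float), np.asarray(events, dtype=int))
    return float(kmf.median_survival_time_)


def km_logrank(times, events, groups, compute_hr: bool = True) -> SurvivalResult:
    """Two-group Kaplan-Meier comparison: medians, log-rank test, Cox HR.

    Group ordering: the two group levels are sorted; the hazard ratio is
    for the second level relative to the first.  Raises on empty groups or
    when no event occurred anywhere (the test is undefined).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups)
    if np.isnan(times).any():
        raise ValueError("missing survival times")
    levels = sorted(pd.unique(groups).tolist())
    if len(levels) != 2:
        raise ValueError(f"expected exactly 2 groups, got {len(levels)}")
    mask_b = groups == levels[1]
    n_a, n_b = int((~mask_b).sum()), int(mask_b.sum())
    if n_a == 0 or n_b == 0:
        raise ValueError("each group needs at least one subject")
    if events.sum() == 0:
        raise ValueError("no events in either group: log-rank test undefined")

    med_a = km_median(times[~mask_b], events[~mask_b])
    med_b = km_median(times[mask_b], events[mask_b])
    lr = logrank_test(times[~mask_b], times[mask_b], events[~mask_b], events[mask_b])
    p = float(min(1.0, lr.p_value)) if lr.p_value > 0 else np.nextafter(0, 1)

    if compute_hr:
        hr, lo, hi = _cox_univariate_hr(times, events, mask_b.astype(float))
    else:
        hr = lo = hi = float("nan")
    return SurvivalResult(
        median_a=med_a,
        median_b=med_b,
        hazard_ratio=hr,
        ci_low=lo,
        ci_high=hi,
        logrank_stat=float(lr.test_statistic),
        p_value=p,
        n_a=n_a,
        n_b=n_b,
    )


def _cox_univariate_hr(times, events, covariate) -> tuple[float, float, float]:
    df = pd.DataFrame({"T": times, "E": events, "x": covariate})
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            cph.fit(df, duration_col="T", event_col="E")
        except ConvergenceError as exc:
            raise ValueError(f"Cox fit failed: {exc}") from exc
    hr = float(np.exp(cph.params_.iloc[0]))
    ci = cph.confidence_intervals_.to_numpy()[0]
    with np.errstate(over="ignore"):  # tiny samples can have unbounded CIs
        return hr, float(np.exp(ci[0])), float(np.exp(ci[1]))


def cox_multivariate(times, events, covariates: pd.DataFrame) -> pd.DataFrame:
    """Multivariate Cox proportional-hazards fit; per-covariate HR, CI, p.

    Partial-likelihood maximisation via lifelines with Wald confidence
    intervals.  Constant or duplicated covariates raise before fitting;
    non-convergence and separation surface as errors with diagnostics.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    X = covariates.astype(float)
    if len(X) != len(times):
        raise ValueError("covariate table length mismatch")
    for col in X.columns:
        if X[col].nunique() < 2:
            raise ValueError(f"covariate {col!r} is constant")
    corr = X.corr().abs().to_numpy()
    np.fill_diagonal(corr, 0.0)
    if np.any(corr > 1 - 1e-12):
        i, j = np.unravel_index(np.argmax(corr), corr.shape)
        raise ValueError(
            f"singular design: covariates {X.columns[i]!r} and {X.columns[j]!r} are collinear"
        )
    if events.sum() < X.shape[1]:
        raise ValueError("fewer events than covariates")
    df = X.copy()
    df["T"] = times
    df["E"] = events
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            cph.fit(df, duration_col="T", event_col="E")
        except ConvergenceError as exc:
            raise ValueError(f"Cox fit did not converge: {exc}") from exc
    if np.any(np.abs(cph.params_.to_numpy()) > 20):
        bad = cph.params_.index[np.argmax(np.abs(cph.params_.to_numpy()))]
        raise ValueError(f"separation detected: coefficient for {bad!r} diverges")
    ci = np.exp(cph.confidence_intervals_.to_numpy())
    return pd.DataFrame(
        {
            "HR": np.exp(cph.params_.to_numpy()),
            "ci_low": ci[:, 0],
            "ci_high": ci[:, 1],
            "p": cph.summary["p"].to_numpy(),
        },
        index=list(X.columns),
    )
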