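"""Classical inference: mixed repeated-measures ANOVA, slope ANCOVA, Tukey HSD,
Pearson correlation and simple regression.

Everything is computed from textbook sums-of-squares and closed-form
expressions; scipy supplies only the reference distributions (F, t and the
studentized range).  This keeps every statistic auditable against brute-force
cell-means computations, which is exactly how the test suite checks them.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ConfigurationError, UnbalancedDesignError


@dataclass(frozen=True)
class AnovaRow:
    effect: str
    ss: float
    df: float
    ms: float
    f: float
    p: float


@dataclass(frozen=True)
class AnovaTable:
    rows: tuple[AnovaRow, ...]
    gg_epsilon: float | None = None   # Greenhouse-Geisser sphericity correction

    def __getitem__(self, effect: str) -> AnovaRow:
        for row in self.rows:
            if row.effect == effect:
                return row
        raise KeyError(effect)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([row.__dict__ for row in self.rows])


@dataclass(frozen=True)
class SlopeComparison:
    """Homogeneity-of-slopes ANCOVA plus the per-subject-slope sensitivity test."""

    group_slopes: Mapping[str, tuple[float, float]]   # group -> (slope, SE)
    f_interaction: float
    df: tuple[float, float]
    p: float
    t_subject: float | None = None    # two-sample t on per-subject slopes (2 groups)
    p_subject: float | None = None


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    n: int
    t: float
    p: float


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r: float
    p: float
    stderr: float


def _f_p(ss_num: float, df_num: float, ss_den: float, df_den: float) -> tuple[float, float]:
    """F and p with a defined answer for the all-constant degenerate case."""
    ms_num = ss_num / df_num
    ms_den = ss_den / df_den
    if ms_den == 0.0:
        if ms_num == 0.0:
            return 0.0, 1.0
        return float("inf"), 0.0
    f = ms_num / ms_den
    return f, float(sps.f.sf(f, df_num, df_den))


# ---------------------------------------------------------------------------
# Mixed-design repeated-measures ANOVA


def _check_balanced(data: pd.DataFrame) -> tuple[list, list, np.ndarray, np.ndarray]:
    subjects = sorted(data["subject"].unique())
    times = sorted(data["time"].unique())
    cell = data.pivot_table(index="subject", columns="time", values="value", aggfunc="count")
    if cell.reindex(index=subjects, columns=times).isna().any().any() or (cell != 1).any().any():
        raise UnbalancedDesignError("every subject must have exactly one value at every time")
    groups = data.drop_duplicates("subject").set_index("subject")["group"]
    if groups.reindex(subjects).isna().any():
        raise UnbalancedDesignError("every subject needs a group label")
    sizes = groups.value_counts()
    if sizes.nunique() != 1:
        raise UnbalancedDesignError("group sizes must be equal for the classical decomposition")
    wide = data.pivot(index="subject", columns="time", values="value").loc[subjects, times]
    return subjects, times, wide.to_numpy(), groups.loc[subjects].to_numpy()


def _gg_epsilon(wide: np.ndarray, group: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from the pooled within-group covariance."""
    t = wide.shape[1]
    pooled = np.zeros((t, t))
    dof = 0
    for g in np.unique(group):
        block = wide[group == g]
        if len(block) > 1:
            pooled += np.cov(block, rowvar=False) * (len(block) - 1)
            dof += len(block) - 1
    if dof == 0:
        return 1.0
    s = pooled / dof
    h = np.eye(t) - np.ones((t, t)) / t
    sc = h @ s @ h
    tr = np.trace(sc)
    denom = (t - 1) * np.trace(sc @ sc)
    if denom <= 0:
        return 1.0
    eps = tr**2 / denom
    return float(np.clip(eps, 1.0 / (t - 1), 1.0))


def rm_anova(data: pd.DataFrame, gg_correction: bool = True) -> AnovaTable:
    """Mixed (between = group, within = time) repeated-measures ANOVA.

    Requires a complete balanced design (columns subject, group, time, value);
    missing cells raise :class:`UnbalancedDesignError` — no imputation.  With
    ``gg_correction`` the within-subject p-values use Greenhouse-Geisser
    adjusted degrees of freedom (the F statistics are unchanged).
    """
    for col in ("subject", "group", "time", "value"):
        if col not in data.columns:
            raise ConfigurationError(f"rm_anova input missing column {col!r}")
    subjects, times, wide, group = _check_balanced(data)
    a = len(np.unique(group))
    t = len(times)
    n = len(subjects) // a

    grand = wide.mean()
    subj_means = wide.mean(axis=1)
    time_means = wide.mean(axis=0)
    group_labels = np.unique(group)
    group_means = np.array([wide[group == g].mean() for g in group_labels])
    cell_means = np.array([wide[group == g].mean(axis=0) for g in group_labels])  # (a, t)

    ss_total = float(np.sum((wide - grand) ** 2))
    ss_subjects = float(t * np.sum((subj_means - grand) ** 2))
    ss_group = float(n * t * np.sum((group_means - grand) ** 2))
    ss_subj_err = ss_subjects - ss_group
    ss_time = float(a * n * np.sum((time_means - grand) ** 2))
    ss_inter = float(n * np.sum(
        (cell_means - group_means[:, None] - time_means[None, :] + grand) ** 2
    ))
    ss_err = ss_total - ss_subjects - ss_time - ss_inter

    df_group, df_subj_err = a - 1, a * (n - 1)
    df_time, df_inter = t - 1, (a - 1) * (t - 1)
    df_err = a * (n - 1) * (t - 1)

    eps = _gg_epsilon(wide, group) if gg_correction else 1.0

    f_g, p_g = _f_p(ss_group, df_group, ss_subj_err, df_subj_err)
    f_t, _ = _f_p(ss_time, df_time, ss_err, df_err)
    f_i, _ = _f_p(ss_inter, df_inter, ss_err, df_err)
    # GG: same F, adjusted df
    if np.isinf(f_t):
        p_t = 0.0
    else:
        p_t = 1.0 if f_t == 0 and ss_err == 0 else float(sps.f.sf(f_t, eps * df_time, eps * df_err))
    if np.isinf(f_i):
        p_i = 0.0
    else:
        p_i = 1.0 if f_i == 0 and ss_err == 0 else float(sps.f.sf(f_i, eps * df_inter, eps * df_err))
    if ss_err == 0 and ss_time == 0:
        p_t = 1.0
    if ss_err == 0 and ss_inter == 0:
        p_i = 1.0

    rows = (
        AnovaRow("group", ss_group, df_group, ss_group / df_group, f_g, p_g),
        AnovaRow("subject(group)", ss_subj_err, df_subj_err, ss_subj_err / df_subj_err,
                 float("nan"), float("nan")),
        AnovaRow("time", ss_time, df_time, ss_time / df_time, f_t, p_t),
        AnovaRow("group:time", ss_inter, df_inter, ss_inter / df_inter, f_i, p_i),
        AnovaRow("error", ss_err, df_err, ss_err / df_err, float("nan"), float("nan")),
    )
    return AnovaTable(rows=rows, gg_epsilon=eps if gg_correction else None)


def pairwise_contrasts_by_time(data: pd.DataFrame) -> pd.DataFrame:
    """Bonferroni-adjusted pairwise group contrasts at each time point.

    Pooled-variance two-sample t-tests between groups at each time; each
    per-time family of p-values is multiplied by its number of pairwise
    comparisons (capped at 1).  Bonferroni never decreases a p-value.
    """
    rows = []
    for time, sub in data.groupby("time", sort=True):
        by_group = {g: s["value"].to_numpy() for g, s in sub.groupby("group")}
        pairs = list(combinations(sorted(by_group), 2))
        m = len(pairs)
        for g1, g2 in pairs:
            x, y = by_group[g1], by_group[g2]
            n1, n2 = len(x), len(y)
            df = n1 + n2 - 2
            sp2 = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / df
            se = np.sqrt(sp2 * (1 / n1 + 1 / n2))
            diff = x.mean() - y.mean()
            if se == 0:
                tstat, p = (0.0, 1.0) if diff == 0 else (np.inf * np.sign(diff), 0.0)
            else:
                tstat = diff / se
                p = float(2 * sps.t.sf(abs(tstat), df))
            rows.append({"time": time, "group1": g1, "group2": g2, "mean_diff": diff,
                         "t": tstat, "df": df, "p_unadjusted": p,
                         "p_bonferroni": min(1.0, p * m)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Homogeneity-of-slopes ANCOVA


def ancova_slopes(data: pd.DataFrame) -> SlopeComparison:
    """Test for a difference in regression slopes between groups.

    Pooled linear model ``value ~ gd + group + gd:group``; the reported F is
    the homogeneity-of-slopes interaction test.  For two groups the per-subject
    slope two-sample t-test is reported alongside as a sensitivity analysis
    (it is robust to between-subject intercept variance, which inflates the
    pooled residual and makes the interaction F conservative).
    """
    for col in ("subject", "group", "gd", "value"):
        if col not in data.columns:
            raise ConfigurationError(f"ancova_slopes input missing column {col!r}")
    groups = sorted(data["group"].unique())
    k = len(groups)
    if k < 2:
        raise ConfigurationError("need at least two groups")
    for g in groups:
        if data.loc[data["group"] == g, "gd"].nunique() < 2:
            raise ConfigurationError(f"group {g!r} has fewer than 2 gestational days")

    y = data["value"].to_numpy(dtype=float)
    x = data["gd"].to_numpy(dtype=float)
    n_obs = len(y)
    dummies = np.column_stack([(data["group"] == g).to_numpy(float) for g in groups[1:]]) \
        if k > 1 else np.empty((n_obs, 0))
    x_full = np.column_stack([np.ones(n_obs), dummies, x, dummies * x[:, None]])
    x_red = np.column_stack([np.ones(n_obs), dummies, x])

    beta_f, sse_f = _ols(x_full, y)
    _, sse_r = _ols(x_red, y)
    df_num = k - 1
    df_den = n_obs - x_full.shape[1]
    f, p = _f_p(sse_r - sse_f, df_num, sse_f, df_den)

    mse = sse_f / df_den if df_den > 0 else 0.0
    xtx_inv = np.linalg.pinv(x_full.T @ x_full)
    slope_idx = {groups[0]: [k]}          # column k is the common gd column
    for j, g in enumerate(groups[1:]):
        slope_idx[g] = [k, k + 1 + j]
    group_slopes = {}
    for g, idx in slope_idx.items():
        c = np.zeros(x_full.shape[1])
        c[idx] = 1.0
        slope = float(c @ beta_f)
        se = float(np.sqrt(max(c @ xtx_inv @ c, 0.0) * mse))
        group_slopes[g] = (slope, se)

    t_subj = p_subj = None
    if k == 2:
        slopes = {g: [] for g in groups}
        for (subj, g), sub in data.groupby(["subject", "group"]):
            gx = sub["gd"].to_numpy(float)
            gy = sub["value"].to_numpy(float)
            xc = gx - gx.mean()
            denom = np.dot(xc, xc)
            if denom > 0:
                slopes[g].append(np.dot(xc, gy) / denom)
        s1, s2 = (np.asarray(slopes[g]) for g in groups)
        if len(s1) > 1 and len(s2) > 1:
            df_t = len(s1) + len(s2) - 2
            sp2 = ((len(s1) - 1) * s1.var(ddof=1) + (len(s2) - 1) * s2.var(ddof=1)) / df_t
            se = np.sqrt(sp2 * (1 / len(s1) + 1 / len(s2)))
            if se > 0:
                t_subj = float((s1.mean() - s2.mean()) / se)
                p_subj = float(2 * sps.t.sf(abs(t_subj), df_t))

    return SlopeComparison(group_slopes=group_slopes, f_interaction=f,
                           df=(df_num, df_den), p=p, t_subject=t_subj, p_subject=p_subj)


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    return beta, float(resid @ resid)


# ---------------------------------------------------------------------------
# One-way ANOVA with Tukey HSD


def oneway_anova_tukey(groups: Mapping[str, Sequence[float]]) -> tuple[AnovaTable, pd.DataFrame]:
    """Classical one-way ANOVA with Tukey HSD pairwise comparisons.

    Tukey p-values come from the studentized-range distribution with the
    Tukey-Kramer standard error for (possibly) unequal group sizes.
    """
    names = sorted(groups)
    arrays = [np.asarray(groups[g], dtype=float) for g in names]
    if len(arrays) < 2:
        raise ConfigurationError("need at least two groups")
    if any(len(a) < 2 for a in arrays):
        raise ConfigurationError("every group needs at least two values")
    k = len(arrays)
    n_total = sum(len(a) for a in arrays)
    grand = np.concatenate(arrays).mean()
    ss_between = sum(len(a) * (a.mean() - grand) ** 2 for a in arrays)
    ss_within = sum(np.sum((a - a.mean()) ** 2) for a in arrays)
    df_b, df_w = k - 1, n_total - k
    f, p = _f_p(ss_between, df_b, ss_within, df_w)
    table = AnovaTable(rows=(
        AnovaRow("between", float(ss_between), df_b, ss_between / df_b, f, p),
        AnovaRow("within", float(ss_within), df_w, ss_within / df_w, float("nan"), float("nan")),
    ))

    mse = ss_within / df_w
    rows = []
    for (i, g1), (j, g2) in combinations(enumerate(names), 2):
        a1, a2 = arrays[i], arrays[j]
        diff = a1.mean() - a2.mean()
        se = np.sqrt(mse / 2 * (1 / len(a1) + 1 / len(a2)))
        if se == 0:
            q, p_t = (0.0, 1.0) if diff == 0 else (np.inf, 0.0)
        else:
            q = abs(diff) / se
            p_t = float(sps.studentized_range.sf(q, k, df_w))
        rows.append({"group1": g1, "group2": g2, "mean_diff": diff, "q": q, "p_tukey": p_t})
    return table, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Correlation and simple regression


def pearson(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Product-moment correlation with the exact t-based two-tailed p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 3 or len(y) != n:
        raise ConfigurationError("pearson needs two equal-length samples with n >= 3")
    xc, yc = x - x.mean(), y - y.mean()
    sxx, syy = np.dot(xc, xc), np.dot(yc, yc)
    if sxx == 0 or syy == 0:
        raise ConfigurationError("correlation undefined: zero variance")
    r = float(np.dot(xc, yc) / np.sqrt(sxx * syy))
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) == 1.0:
        return CorrelationResult(r=r, n=n, t=float("inf") * np.sign(r), p=0.0)
    t = r * np.sqrt((n - 2) / (1 - r**2))
    return CorrelationResult(r=r, n=n, t=float(t), p=float(2 * sps.t.sf(abs(t), n - 2)))


def linear_regression(x: Sequence[float], y: Sequence[float]) -> RegressionResult:
    """Simple OLS regression of y on x; p is the two-tailed slope test."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 3 or len(y) != n:
        raise ConfigurationError("linear_regression needs n >= 3")
    xc = x - x.mean()
    sxx = np.dot(xc, xc)
    if sxx == 0:
        raise ConfigurationError("regression undefined: constant predictor")
    slope = float(np.dot(xc, y) / sxx)
    intercept = float(y.mean() - slope * x.mean())
    resid = y - (intercept + slope * x)
    sse = float(resid @ resid)
    syy = float(np.sum((y - y.mean()) ** 2))
    r = 0.0 if syy == 0 else float(np.sign(slope) * np.sqrt(max(1 - sse / syy, 0.0)))
    if sse <= 1e-300 * max(syy, 1.0):
        return RegressionResult(slope=slope, intercept=intercept, r=r, p=0.0, stderr=0.0)
    stderr = float(np.sqrt(sse / (n - 2) / sxx))
    t = slope / stderr
    return RegressionResult(slope=slope, intercept=intercept, r=r,
                            p=float(2 * sps.t.sf(abs(t), n - 2)), stderr=stderr)
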