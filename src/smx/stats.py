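"""Cohort-level statistics: 2x2 mixed factorial ANOVA (Type III), Levene
gating with White-Huber (sandwich) corrected tests, Tukey-adjusted marginal
mean contrasts, Cohen's d with noncentral-t confidence intervals, per-group
Pearson correlations, and the full analysis report.

The mixed ANOVA (between factor: group; within factor: condition, both
2-level, complete within-subject data) uses the classical univariate
decomposition, which for this design coincides with Type III sums of
squares: the between-subjects test is a one-way ANOVA on subject means, and
the within-subject tests are contrasts on the per-subject condition
difference scores with the group-cell-means error term (df = N - 2).  With
unequal group sizes, main-effect estimates are unweighted means of group
cell means, as Type III requires.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.optimize import brentq

from .exceptions import DegenerateInputError, ValidationError
from .io_model import GROUP_BVI, GROUP_SIGHTED, CohortTable

logger = logging.getLogger(__name__)

__all__ = [
    "EffectResult",
    "AnovaResult",
    "CorrelationResult",
    "mixed_anova_2x2",
    "mixed_anova_arrays",
    "between_anova",
    "levene_test",
    "hc_correct",
    "emm_contrasts",
    "pairwise_tukey",
    "cohens_d_ci",
    "pearson_ci",
    "reproduce_analysis",
    "collect_pvalues",
]


# ---------------------------------------------------------------------------
# result containers
# ---------------------------------------------------------------------------

@dataclass
class EffectResult:
    F: float
    df_num: int
    df_den: int
    p: float
    mean_difference: float | None = None
    cohens_d: float | None = None
    d_ci_95: tuple[float, float] | None = None


@dataclass
class AnovaResult:
    between: EffectResult
    within: EffectResult | None = None
    interaction: EffectResult | None = None
    heteroscedasticity_corrected: bool = False

    def effects(self) -> dict[str, EffectResult]:
        out = {"between": self.between}
        if self.within is not None:
            out["within"] = self.within
        if self.interaction is not None:
            out["interaction"] = self.interaction
        return out


@dataclass
class CorrelationResult:
    r: float
    df: int
    ci_95: tuple[float, float]
    p: float
    n: int


# ---------------------------------------------------------------------------
# effect sizes and correlations
# ---------------------------------------------------------------------------

def _pooled_sd(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = len(a), len(b)
    return float(np.sqrt(
        ((na - 1) * np.var(a, ddof=1) + (nb - 1) * np.var(b, ddof=1))
        / (na + nb - 2)
    ))


def cohens_d_ci(a, b, confidence: float = 0.95) -> tuple[float, tuple[float, float]]:
    """Cohen's d = (mean_a - mean_b) / pooled sd, CI by noncentral-t inversion."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = len(a), len(b)
    if na < 2 or nb < 2:
        raise ValidationError("need at least 2 observations per sample")
    sp = _pooled_sd(a, b)
    if sp == 0:
        raise DegenerateInputError("zero pooled standard deviation")
    d = float((a.mean() - b.mean()) / sp)
    scale = np.sqrt(1.0 / na + 1.0 / nb)
    df = na + nb - 2
    lo, hi = _nct_interval(d / scale, df, confidence)
    return d, (lo * scale, hi * scale)


def _nct_interval(t_obs: float, df: int, confidence: float) -> tuple[float, float]:
    """Noncentrality-parameter interval for an observed t statistic."""
    alpha = (1.0 - confidence) / 2.0

    def cdf(nc):
        v = sps.nct.cdf(t_obs, df, nc)
        if np.isnan(v):  # far tails can underflow inside scipy
            return 0.0 if nc > t_obs else 1.0
        return float(v)

    span = abs(t_obs) + 10.0 + 4.0 * np.sqrt(df)
    lo = brentq(lambda nc: cdf(nc) - (1.0 - alpha),
                t_obs - span, t_obs + span, xtol=1e-10)
    hi = brentq(lambda nc: cdf(nc) - alpha,
                t_obs - span, t_obs + span, xtol=1e-10)
    return float(lo), float(hi)


def _paired_d_ci(diff: np.ndarray, sd_ref: float, confidence: float = 0.95):
    """Standardised within-subject effect: mean difference over a reference
    sd (pooled across the two condition cells), CI scaled from the t CI of
    the mean difference."""
    n = len(diff)
    m = float(np.mean(diff))
    se = float(np.std(diff, ddof=1) / np.sqrt(n))
    if sd_ref == 0 or se == 0:
        raise DegenerateInputError("zero variance in paired effect")
    tcrit = sps.t.ppf(1 - (1 - confidence) / 2, n - 1)
    d = m / sd_ref
    return d, ((m - tcrit * se) / sd_ref, (m + tcrit * se) / sd_ref)


def pearson_ci(x, y, confidence: float = 0.95) -> CorrelationResult:
    """Pearson r with two-sided t-test p (df = n - 2) and Fisher-z CI."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValidationError("x and y must have equal length")
    n = len(x)
    if n < 3:
        raise ValidationError("need at least 3 paired observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise DegenerateInputError("zero variance in x or y")
    r, p = sps.pearsonr(x, y)
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) == 1.0:
        ci = (r, r)
    elif n <= 3:
        ci = (-1.0, 1.0)  # Fisher z has no precision at n = 3
    else:
        z = np.arctanh(r)
        zse = 1.0 / np.sqrt(n - 3)
        zcrit = sps.norm.ppf(1 - (1 - confidence) / 2)
        ci = (float(np.tanh(z - zcrit * zse)), float(np.tanh(z + zcrit * zse)))
    return CorrelationResult(r=r, df=n - 2, ci_95=ci, p=float(p), n=n)


# ---------------------------------------------------------------------------
# Levene's test
# ---------------------------------------------------------------------------

def levene_test(groups: Sequence[np.ndarray], center: str = "mean"):
    """Levene's homogeneity-of-variance test (classic mean-centred form).

    Returns (W, (df_num, df_den), p).  Globally constant data give W = 0,
    p = 1 (no evidence of heterogeneity).
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValidationError("need >= 2 groups with >= 2 observations each")
    k = len(groups)
    n_total = sum(len(g) for g in groups)
    df = (k - 1, n_total - k)
    devs = [np.abs(g - (np.mean(g) if center == "mean" else np.median(g)))
            for g in groups]
    if all(np.ptp(d) == 0 for d in devs) and np.ptp(np.concatenate(devs)) == 0:
        return 0.0, df, 1.0
    W, p = sps.levene(*groups, center=center)
    return float(W), df, float(p)


# ---------------------------------------------------------------------------
# mixed 2x2 ANOVA
# ---------------------------------------------------------------------------

def _pivot_2x2(table: CohortTable, dv: str, conditions: Sequence[str] | None):
    df = table.subset(dv, conditions)
    if df.empty:
        raise ValidationError(f"no rows for dv {dv!r}")
    conds = sorted(df["condition"].unique()) if conditions is None else list(conditions)
    if len(conds) != 2:
        raise ValidationError(f"dv {dv!r} needs exactly 2 within levels, got {conds}")
    wide = df.pivot_table(index=["participant_id", "group"], columns="condition",
                          values="value", aggfunc="first")
    incomplete = wide[wide[conds].isna().any(axis=1)]
    if len(incomplete):
        ids = [i for i, _ in incomplete.index]
        raise ValidationError(f"participants missing a within level: {ids}")
    wide = wide.reset_index()
    groups = wide["group"].to_numpy()
    return groups, wide[conds[0]].to_numpy(), wide[conds[1]].to_numpy(), conds


def mixed_anova_arrays(
    groups: np.ndarray,
    y1: np.ndarray,
    y2: np.ndarray,
    group_order: tuple[str, str] = (GROUP_BVI, GROUP_SIGHTED),
) -> AnovaResult:
    """Core 2x2 mixed ANOVA on wide-format arrays (condition 1 and 2 values
    per participant).  ``group_order`` fixes the sign of group contrasts
    (first minus second)."""
    groups = np.asarray(groups)
    y1 = np.asarray(y1, dtype=float)
    y2 = np.asarray(y2, dtype=float)
    labels = [g for g in group_order if g in groups]
    if len(labels) != 2:
        labels = sorted(set(groups))
    if len(labels) != 2:
        raise ValidationError("need exactly 2 groups")
    m1 = groups == labels[0]
    m2 = groups == labels[1]
    n1, n2 = int(m1.sum()), int(m2.sum())
    if n1 < 2 or n2 < 2:
        raise ValidationError("need >= 2 participants per group")
    N = n1 + n2

    subj_mean = (y1 + y2) / 2.0
    diff = y2 - y1

    # between-subjects effect: one-way ANOVA on subject means
    a, b = subj_mean[m1], subj_mean[m2]
    ss_between = n1 * (a.mean() - subj_mean.mean()) ** 2 + \
        n2 * (b.mean() - subj_mean.mean()) ** 2
    ss_subj = float(np.sum((a - a.mean()) ** 2) + np.sum((b - b.mean()) ** 2))
    ms_err_b = ss_subj / (N - 2)
    # the within-level multiplicity cancels between numerator and error term,
    # so this equals the one-way ANOVA F on subject means
    F_b = float(ss_between / ms_err_b)
    p_b = float(sps.f.sf(F_b, 1, N - 2))
    d_b, dci_b = cohens_d_ci(a, b)
    between = EffectResult(
        F=F_b, df_num=1, df_den=N - 2, p=p_b,
        mean_difference=float(a.mean() - b.mean()),
        cohens_d=d_b, d_ci_95=dci_b,
    )

    # within-subject effects: contrasts on difference scores, error df = N-2
    d1, d2 = diff[m1], diff[m2]
    mse_d = (np.sum((d1 - d1.mean()) ** 2) + np.sum((d2 - d2.mean()) ** 2)) / (N - 2)

    def _wald(est, var):
        if var == 0:
            return 0.0 if est == 0 else float("inf")
        return float(est * est / var)

    est_c = 0.5 * (d1.mean() + d2.mean())  # unweighted (Type III) condition effect
    var_c = mse_d * (1.0 / n1 + 1.0 / n2) / 4.0
    F_c = _wald(est_c, var_c)
    pooled_cell_sd = _pooled_sd(y1, y2)
    d_c = float(est_c / pooled_cell_sd) if pooled_cell_sd > 0 else np.nan
    tcrit = sps.t.ppf(0.975, N - 2)
    half = tcrit * np.sqrt(var_c)
    within = EffectResult(
        F=F_c, df_num=1, df_den=N - 2, p=float(sps.f.sf(F_c, 1, N - 2)),
        mean_difference=float(est_c), cohens_d=d_c,
        d_ci_95=(float((est_c - half) / pooled_cell_sd),
                 float((est_c + half) / pooled_cell_sd))
        if pooled_cell_sd > 0 else None,
    )

    est_i = d1.mean() - d2.mean()
    var_i = mse_d * (1.0 / n1 + 1.0 / n2)
    F_i = _wald(est_i, var_i)
    sd_d = np.sqrt(mse_d) if mse_d > 0 else np.nan
    half_i = tcrit * np.sqrt(var_i)
    interaction = EffectResult(
        F=F_i, df_num=1, df_den=N - 2, p=float(sps.f.sf(F_i, 1, N - 2)),
        mean_difference=float(est_i), cohens_d=float(est_i / sd_d),
        d_ci_95=(float((est_i - half_i) / sd_d), float((est_i + half_i) / sd_d)),
    )
    return AnovaResult(between=between, within=within, interaction=interaction)


def mixed_anova_2x2(
    table: CohortTable,
    dv: str,
    conditions: Sequence[str] | None = None,
    group_order: tuple[str, str] = (GROUP_BVI, GROUP_SIGHTED),
) -> AnovaResult:
    """Type III 2x2 mixed ANOVA (between: group, within: condition) of one
    dependent variable in a long-format cohort table."""
    groups, y1, y2, _ = _pivot_2x2(table, dv, conditions)
    return mixed_anova_arrays(groups, y1, y2, group_order)


def between_anova(
    a: np.ndarray, b: np.ndarray
) -> EffectResult:
    """One-way between-groups comparison (2 groups): F(1, N-2), Cohen's d."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("need >= 2 observations per group")
    F, p = sps.f_oneway(a, b)
    d, dci = cohens_d_ci(a, b)
    return EffectResult(
        F=float(F), df_num=1, df_den=len(a) + len(b) - 2, p=float(p),
        mean_difference=float(a.mean() - b.mean()), cohens_d=d, d_ci_95=dci,
    )


# ---------------------------------------------------------------------------
# White-Huber (sandwich) corrected tests
# ---------------------------------------------------------------------------

def _hc_wald_1df(y: np.ndarray, masks: list[np.ndarray], contrast: np.ndarray,
                 cov_type: str = "HC3") -> tuple[float, float, int]:
    """Wald F test of one contrast on a cell-means OLS fit with a
    heteroscedasticity-robust covariance."""
    import statsmodels.api as sm

    X = np.column_stack([m.astype(float) for m in masks])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValidationError("singular cell-means design")
    fit = sm.OLS(y, X).fit(cov_type=cov_type)
    est = float(contrast @ fit.params)
    var = float(contrast @ fit.cov_params() @ contrast)
    if not np.isfinite(var) or var <= 0:
        raise DegenerateInputError("robust covariance is not positive")
    df_den = int(fit.df_resid)
    F = est * est / var
    p = float(sps.f.sf(F, 1, df_den))
    return F, p, df_den


def hc_correct(
    groups: np.ndarray,
    y1: np.ndarray,
    y2: np.ndarray,
    group_order: tuple[str, str] = (GROUP_BVI, GROUP_SIGHTED),
    cov_type: str = "HC3",
) -> AnovaResult:
    """2x2 mixed ANOVA with White-Huber (sandwich, default HC3) covariance.

    The between test is a robust Wald test of the group contrast on subject
    means; the within and interaction tests are robust Wald tests of the
    condition and group-difference contrasts on the per-subject difference
    scores.  Effect sizes carry over from the uncorrected decomposition.
    """
    base = mixed_anova_arrays(groups, y1, y2, group_order)
    groups = np.asarray(groups)
    labels = [g for g in group_order if g in groups] or sorted(set(groups))
    m1, m2 = groups == labels[0], groups == labels[1]
    subj_mean = (np.asarray(y1, float) + np.asarray(y2, float)) / 2.0
    diff = np.asarray(y2, float) - np.asarray(y1, float)

    F_b, p_b, df_b = _hc_wald_1df(subj_mean, [m1, m2], np.array([1.0, -1.0]), cov_type)
    F_c, p_c, df_c = _hc_wald_1df(diff, [m1, m2], np.array([0.5, 0.5]), cov_type)
    F_i, p_i, df_i = _hc_wald_1df(diff, [m1, m2], np.array([1.0, -1.0]), cov_type)

    base.between.F, base.between.p, base.between.df_den = F_b, p_b, df_b
    base.within.F, base.within.p, base.within.df_den = F_c, p_c, df_c
    base.interaction.F, base.interaction.p, base.interaction.df_den = F_i, p_i, df_i
    base.heteroscedasticity_corrected = True
    return base


# ---------------------------------------------------------------------------
# estimated marginal means with Tukey adjustment
# ---------------------------------------------------------------------------

def pairwise_tukey(values: np.ndarray, labels: np.ndarray) -> pd.DataFrame:
    """All pairwise level contrasts of a one-way layout with Tukey
    (studentized-range) adjusted p-values.

    Returns a DataFrame with columns level_a, level_b, estimate, se, t,
    p_raw, p_tukey.  For k = 2 levels the adjustment is an identity.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    levels = list(pd.unique(labels))
    k = len(levels)
    if k < 2:
        raise ValidationError("need at least 2 levels")
    cells = {lv: values[labels == lv] for lv in levels}
    if any(len(c) < 2 for c in cells.values()):
        raise ValidationError("need >= 2 observations per level")
    n_total = len(values)
    df_err = n_total - k
    mse = sum(np.sum((c - c.mean()) ** 2) for c in cells.values()) / df_err
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            a, b = levels[i], levels[j]
            est = cells[a].mean() - cells[b].mean()
            se = np.sqrt(mse * (1.0 / len(cells[a]) + 1.0 / len(cells[b])))
            t = est / se
            p_raw = 2.0 * sps.t.sf(abs(t), df_err)
            p_tukey = float(sps.studentized_range.sf(abs(t) * np.sqrt(2.0), k, df_err))
            rows.append({"level_a": a, "level_b": b, "estimate": float(est),
                         "se": float(se), "t": float(t), "p_raw": float(p_raw),
                         "p_tukey": min(1.0, p_tukey)})
    return pd.DataFrame(rows)


def emm_contrasts(
    table: CohortTable,
    dv: str,
    conditions: Sequence[str] | None = None,
) -> dict[str, pd.DataFrame]:
    """Tukey-adjusted pairwise marginal-mean contrasts of both factors of a
    2x2 mixed design: group contrasts on subject means, condition contrasts
    on stacked difference information (equivalent to the within test)."""
    groups, y1, y2, conds = _pivot_2x2(table, dv, conditions)
    subj_mean = (y1 + y2) / 2.0
    out = {"group": pairwise_tukey(subj_mean, groups)}

    # condition marginal contrast: paired structure, Type III unweighted
    diff = y2 - y1
    labels = list(pd.unique(groups))
    m = [groups == g for g in labels]
    n = [int(x.sum()) for x in m]
    N = sum(n)
    mse_d = sum(np.sum((diff[mm] - diff[mm].mean()) ** 2) for mm in m) / (N - 2)
    est = float(np.mean([diff[mm].mean() for mm in m]))
    se = float(np.sqrt(mse_d * sum(1.0 / x for x in n) / 4.0))
    t = est / se if se > 0 else np.inf
    p_raw = 2.0 * sps.t.sf(abs(t), N - 2)
    out["condition"] = pd.DataFrame([
        {"level_a": conds[1], "level_b": conds[0], "estimate": est, "se": se,
         "t": float(t), "p_raw": float(p_raw), "p_tukey": float(p_raw)}
    ])
    return out


# ---------------------------------------------------------------------------
# full analysis report
# ---------------------------------------------------------------------------

#: dv -> (within conditions for the group comparison), None = single condition
_GROUP_ANALYSES: dict[str, tuple[str, ...] | None] = {
    "pea": ("bipedal_ec", "semitandem_ec"),
    "activity": ("basic", "exercise"),
    "sls_time": None,
    "stride_time_sd": None,
    "lle": None,
    "angle_error": None,
    "distance_error": None,
}

#: dv -> (ec condition, eo condition) pairs for the sighted-only vision effect
_VISION_ANALYSES: dict[str, list[tuple[str, str]]] = {
    "pea": [("bipedal_ec", "bipedal_eo"), ("semitandem_ec", "semitandem_eo")],
    "stride_time_sd": [("ec", "eo")],
    "lle": [("ec", "eo")],
}

#: correlation targets: dv -> condition whose (eyes-closed) value enters
_CORR_DVS: dict[str, str | tuple[str, ...]] = {
    "pea": ("bipedal_ec", "semitandem_ec"),  # averaged
    "sls_time": "ec",
    "stride_time_sd": "ec",
    "lle": "ec",
    "angle_error": "ec",
    "distance_error": "ec",
}


def _participant_value(df: pd.DataFrame, conditions) -> pd.Series:
    if isinstance(conditions, str):
        conditions = (conditions,)
    sub = df[df["condition"].isin(conditions)]
    return sub.groupby("participant_id")["value"].mean()


def reproduce_analysis(cohort: CohortTable, alpha_levene: float = 0.05) -> dict:
    """Run the full analysis chain on a cohort table.

    Per dependent variable: the blind/visually-impaired (BVI) vs. sighted
    comparison on eyes-closed data (mixed 2x2 where a within factor exists,
    one-way otherwise), with Levene's test gating a White-Huber corrected
    re-test; the eyes-open vs. eyes-closed comparison within the sighted
    group; and per-group Pearson correlations of exercise and basic-activity
    minutes with every outcome.  Missing variables are listed as warnings,
    never fatal.
    """
    report: dict = {
        "group_comparisons": {},
        "vision_comparisons": {},
        "correlations": {},
        "levene": {},
        "warnings": [],
    }
    data = cohort.data
    if data.empty:
        report["warnings"].append("empty cohort")
        return report
    present = set(cohort.dvs())

    for dv, conds in _GROUP_ANALYSES.items():
        if dv not in present:
            report["warnings"].append(f"dv {dv!r} missing from cohort")
            continue
        df = cohort.subset(dv)
        try:
            if conds is not None:
                groups, y1, y2, _ = _pivot_2x2(cohort, dv, conds)
                lev_vals = [(y1 + y2)[groups == g] / 2.0 for g in np.unique(groups)]
                W, ldf, lp = levene_test(lev_vals)
                if lp < alpha_levene:
                    res = hc_correct(groups, y1, y2)
                else:
                    res = mixed_anova_arrays(groups, y1, y2)
            else:
                per = df[df["condition"] == "ec"]
                a = per[per["group"] == GROUP_BVI]["value"].to_numpy()
                b = per[per["group"] == GROUP_SIGHTED]["value"].to_numpy()
                W, ldf, lp = levene_test([a, b])
                res = AnovaResult(between=between_anova(a, b))
                if lp < alpha_levene:
                    # robust one-way via sandwich Wald on group cell means
                    y = np.concatenate([a, b])
                    g = np.array([GROUP_BVI] * len(a) + [GROUP_SIGHTED] * len(b))
                    F, p, dfden = _hc_wald_1df(
                        y, [g == GROUP_BVI, g == GROUP_SIGHTED],
                        np.array([1.0, -1.0]))
                    res.between.F, res.between.p, res.between.df_den = F, p, dfden
                    res.heteroscedasticity_corrected = True
            report["levene"][dv] = {"W": W, "df": ldf, "p": lp}
            report["group_comparisons"][dv] = res
        except (ValidationError, DegenerateInputError) as exc:
            report["warnings"].append(f"group comparison for {dv!r} failed: {exc}")

    # vision effect, sighted only: paired ec vs eo per dv (averaging over
    # stance where both stances exist)
    sighted = data[data["group"] == GROUP_SIGHTED]
    for dv, pairs in _VISION_ANALYSES.items():
        if dv not in present:
            continue
        df = sighted[sighted["dv_name"] == dv]
        ec_conds = [p[0] for p in pairs]
        eo_conds = [p[1] for p in pairs]
        if not set(eo_conds) & set(df["condition"].unique()):
            report["warnings"].append(f"no eyes-open data for {dv!r}")
            continue
        ec = _participant_value(df, tuple(ec_conds))
        eo = _participant_value(df, tuple(eo_conds))
        ids = ec.index.intersection(eo.index)
        if len(ids) < 2:
            report["warnings"].append(f"too few paired vision observations for {dv!r}")
            continue
        diff = (ec.loc[ids] - eo.loc[ids]).to_numpy()  # ec minus eo
        n = len(diff)
        se = np.std(diff, ddof=1) / np.sqrt(n)
        if se == 0:
            report["warnings"].append(f"zero variance in vision contrast for {dv!r}")
            continue
        t = float(np.mean(diff) / se)
        sd_ref = _pooled_sd(ec.loc[ids].to_numpy(), eo.loc[ids].to_numpy())
        if sd_ref > 0:
            d, dci = _paired_d_ci(diff, sd_ref)
        else:
            d, dci = np.nan, None
        report["vision_comparisons"][dv] = EffectResult(
            F=t * t, df_num=1, df_den=n - 1, p=float(2 * sps.t.sf(abs(t), n - 1)),
            mean_difference=float(np.mean(diff)), cohens_d=d, d_ci_95=dci,
        )

    # per-group correlations of activity with every outcome (eyes closed)
    if "activity" in present:
        act = data[data["dv_name"] == "activity"]
        for group in (GROUP_BVI, GROUP_SIGHTED):
            ga = act[act["group"] == group]
            gdata = data[data["group"] == group]
            gout: dict[str, dict[str, CorrelationResult]] = {}
            for act_cond in ("exercise", "basic"):
                xs = ga[ga["condition"] == act_cond].set_index("participant_id")["value"]
                sub: dict[str, CorrelationResult] = {}
                for dv, conds in _CORR_DVS.items():
                    if dv not in present:
                        continue
                    ys = _participant_value(gdata[gdata["dv_name"] == dv], conds)
                    ids = xs.index.intersection(ys.index)
                    if len(ids) < 3:
                        continue
                    try:
                        sub[dv] = pearson_ci(xs.loc[ids].to_numpy(),
                                             ys.loc[ids].to_numpy())
                    except (ValidationError, DegenerateInputError) as exc:
                        report["warnings"].append(
                            f"correlation {group}/{act_cond}/{dv} failed: {exc}")
                gout[act_cond] = sub
            report["correlations"][group] = gout
    else:
        report["warnings"].append("no activity scores; correlations skipped")
    return report


def collect_pvalues(report: dict) -> list[float]:
    """Flatten every p-value a report contains (for calibration checks)."""
    ps: list[float] = []
    for res in report["group_comparisons"].values():
        for eff in res.effects().values():
            ps.append(eff.p)
    for eff in report["vision_comparisons"].values():
        ps.append(eff.p)
    for gout in report["correlations"].values():
        for sub in gout.values():
            ps.extend(c.p for c in sub.values())
    return ps


def report_to_jsonable(report: dict) -> dict:
    """Convert a report (dataclass-laden dict) into plain JSON types."""
    from dataclasses import asdict, is_dataclass

    def conv(obj):
        if is_dataclass(obj):
            return conv(asdict(obj))
        if isinstance(obj, dict):
            return {str(k): conv(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [conv(v) for v in obj]
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        return obj

    return conv(report)
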