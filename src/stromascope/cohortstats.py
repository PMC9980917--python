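"""Cohort-level statistics: group tests, correlations, cross-tabulations,
biomarker dichotomization, univariable Cox screening with Bonferroni control,
Kaplan-Meier / log-rank, Cox proportional-hazards fits, Schoenfeld PH
diagnostics and DeLong comparison of correlated AUCs.

Test selection follows the classical recipe: a Kolmogorov-Smirnov normality
check (Lilliefors critical values, since mean and SD are estimated) decides
between Student's t and Mann-Whitney U for two-group contrasts; Fisher's
exact test is used for 2x2 tables with small expected counts, chi-square
otherwise; Cox models use the Efron tie correction with Wald inference;
family-wise error across the univariable screen is controlled by Bonferroni.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test, proportional_hazard_test
from scipy import stats
from statsmodels.stats.diagnostic import lilliefors

from stromascope.errors import (
    DegenerateInputError,
    InsufficientDataError,
    ParameterError,
)

#: default Bonferroni family: the full univariable screen of clinical plus
#: image-analysis variables run together.
DEFAULT_FAMILY_SIZE = 53

ALPHA = 0.05


@dataclass
class StatResult:
    statistic_name: str
    statistic: float
    effect: float | None
    p_raw: float
    p_corrected: float | None = None
    n_used: int = 0
    two_sided: bool = True
    extra: dict = field(default_factory=dict)


@dataclass
class CrossTab:
    counts: np.ndarray
    row_percent: np.ndarray
    row_labels: list
    col_labels: list
    test_used: str
    p: float


@dataclass
class SurvivalFit:
    model: str  # "km" | "cox_uni" | "cox_multi"
    coefs: pd.DataFrame | None = None  # per covariate: beta, HR, CI, p
    logrank_chi2: float | None = None
    logrank_p: float | None = None
    ph_p: dict | None = None
    converged: bool = True
    extra: dict = field(default_factory=dict)


def bonferroni(p_raw: float, family_size: int) -> float:
    """min(1, p * m) — monotone in p and capped at 1."""
    if not 0.0 <= p_raw <= 1.0:
        raise ParameterError("p-value outside [0,1]")
    return min(1.0, p_raw * family_size)


# ---------------------------------------------------------------------------
# group comparison & correlation
# ---------------------------------------------------------------------------


def _is_normal(x: np.ndarray, alpha: float = ALPHA) -> bool:
    """KS normality with Lilliefors critical values.

    Samples too small for the test to have any power (< 10) count as
    non-normal so the rank test is the safe default.
    """
    if len(x) < 10 or np.unique(x).size < 3:
        return False
    return lilliefors(x, dist="norm")[1] > alpha


def compare_groups(x, y, paired: bool = False) -> StatResult:
    """Two-group contrast with a normality-driven choice of test.

    Both groups normal (KS/Lilliefors at alpha=0.05) -> Student t (paired
    when ``paired``); otherwise Mann-Whitney U (Wilcoxon signed-rank when
    paired), tie-corrected, two-sided.  The chosen test is recorded in
    ``statistic_name``.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    x, y = x[np.isfinite(x)], y[np.isfinite(y)]
    if len(x) < 3 or len(y) < 3:
        raise InsufficientDataError("need >= 3 values per group")
    if paired and len(x) != len(y):
        raise ParameterError("paired comparison needs equal-length groups")
    normal = _is_normal(x) and _is_normal(y)
    if normal:
        if paired:
            t, p = stats.ttest_rel(x, y)
            name = "paired_t"
        else:
            t, p = stats.ttest_ind(x, y)
            name = "t"
        stat = float(t)
    else:
        if paired:
            d = x - y
            if np.all(d == 0):
                stat, p = 0.0, 1.0
            else:
                stat, p = stats.wilcoxon(x, y)
            name = "wilcoxon"
        else:
            method = "exact" if (len(x) <= 8 and len(y) <= 8
                                 and np.unique(np.r_[x, y]).size == len(x) + len(y)
                                 ) else "asymptotic"
            u, p = stats.mannwhitneyu(x, y, alternative="two-sided",
                                      method=method)
            stat, name = float(u), "mannwhitney_u"
    return StatResult(
        statistic_name=name, statistic=float(stat),
        effect=float(np.median(x) - np.median(y)),
        p_raw=float(min(1.0, p)), n_used=len(x) + len(y),
    )


def correlate(x, y, method: str = "pearson") -> StatResult:
    """Pearson r or Spearman rho with a two-sided p, pairwise-complete."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise ParameterError("x and y must be paired")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise InsufficientDataError("need >= 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant vector, correlation undefined")
        return StatResult(method, math.nan, None, math.nan, n_used=len(x))
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
    elif method == "spearman":
        r, p = stats.spearmanr(x, y)
    else:
        raise ParameterError(f"unknown correlation method {method!r}")
    return StatResult(method, float(r), float(r), float(p), n_used=len(x))


# ---------------------------------------------------------------------------
# dichotomization & cross-tabulation
# ---------------------------------------------------------------------------


def dichotomize(values, rule: str = "median", cutoff: float | None = None
                ) -> tuple[np.ndarray, float]:
    """Binary high/low labels from a continuous biomarker.

    Rules: ``median`` (high <=> value > median of the analysis set),
    ``fixed`` (high <=> value > ``cutoff``), ``top_decile`` /
    ``bottom_decile`` (exactly ~10% of patients marked, ties broken by
    stable input order).  Returns ``(labels, cutoff_used)``; NaNs get label
    -1.  The cut is strict (">").
    """
    v = np.asarray(values, float)
    finite = np.isfinite(v)
    vv = v[finite]
    if vv.size < 2:
        raise InsufficientDataError("need >= 2 non-missing values")
    if np.unique(vv).size == 1 and rule != "fixed":
        raise DegenerateInputError("all values equal, cannot dichotomize")
    labels = np.full(v.shape, -1, dtype=int)
    if rule == "median":
        c = float(np.median(vv))
        labels[finite] = (vv > c).astype(int)
    elif rule == "fixed":
        if cutoff is None:
            raise ParameterError("fixed rule needs a cutoff")
        c = float(cutoff)
        labels[finite] = (vv > c).astype(int)
    elif rule in ("top_decile", "bottom_decile"):
        k = max(1, int(round(0.1 * vv.size)))
        signed = -vv if rule == "top_decile" else vv
        order = np.argsort(signed, kind="stable")
        chosen = order[:k]
        lab = np.zeros(vv.size, dtype=int)
        lab[chosen] = 1
        labels[finite] = lab
        c = float(vv[chosen[-1]])
    else:
        raise ParameterError(f"unknown dichotomization rule {rule!r}")
    return labels, c


def crosstab(row, col, min_expected: float = 5.0,
             force_fisher: bool = False) -> CrossTab:
    """Categorical association table with Fisher-exact / chi-square test.

    Fisher's exact test is used for 2x2 tables when any expected cell is
    below ``min_expected`` (or when forced); chi-square (without continuity
    correction, as r x c) otherwise.  Row percentages are reported alongside
    counts.
    """
    r = pd.Series(row)
    c = pd.Series(col)
    ok = r.notna() & c.notna()
    r, c = r[ok], c[ok]
    if r.empty or r.nunique() < 2 or c.nunique() < 2:
        raise InsufficientDataError("crosstab needs >= 2 levels per variable")
    tab = pd.crosstab(r, c)
    counts = tab.to_numpy()
    expected = np.outer(counts.sum(1), counts.sum(0)) / counts.sum()
    if counts.shape == (2, 2) and (force_fisher or (expected < min_expected).any()):
        _, p = stats.fisher_exact(counts)
        test = "fisher_exact"
    else:
        _, p, _, _ = stats.chi2_contingency(counts, correction=False)
        test = "chi2"
    row_pct = 100.0 * counts / counts.sum(axis=1, keepdims=True)
    return CrossTab(
        counts=counts, row_percent=row_pct,
        row_labels=list(tab.index), col_labels=list(tab.columns),
        test_used=test, p=float(p),
    )


def crosstab_from_counts(counts, min_expected: float = 5.0,
                         force_fisher: bool = False) -> CrossTab:
    """:func:`crosstab` on an already-tabulated counts matrix."""
    counts = np.asarray(counts, dtype=int)
    if counts.ndim != 2 or (counts < 0).any():
        raise ParameterError("counts must be a nonnegative 2-D matrix")
    expected = np.outer(counts.sum(1), counts.sum(0)) / counts.sum()
    if counts.shape == (2, 2) and (force_fisher or (expected < min_expected).any()):
        _, p = stats.fisher_exact(counts)
        test = "fisher_exact"
    else:
        _, p, _, _ = stats.chi2_contingency(counts, correction=False)
        test = "chi2"
    row_pct = 100.0 * counts / counts.sum(axis=1, keepdims=True)
    return CrossTab(
        counts=counts, row_percent=row_pct,
        row_labels=list(range(counts.shape[0])),
        col_labels=list(range(counts.shape[1])),
        test_used=test, p=float(p),
    )


# ---------------------------------------------------------------------------
# survival: fast univariable Cox (screen), lifelines-backed full fits
# ---------------------------------------------------------------------------


def _cox_single_newton(time, event, x, max_iter: int = 25, tol: float = 1e-9):
    """Newton-Raphson on the single-covariate Cox partial likelihood.

    Breslow handling of ties (the screen operates on continuous times where
    ties are absent and Breslow equals Efron).  Returns (beta, se,
    converged).
    """
    order = np.argsort(-time, kind="stable")  # decreasing time
    t, d, z = time[order], event[order], x[order]
    # risk set of subject i (sorted decreasing) = subjects 0..j with t>=t_i;
    # with decreasing order, cumulative sums give risk-set aggregates
    beta = 0.0
    for _ in range(max_iter):
        w = np.exp(beta * z)
        s0 = np.cumsum(w)
        s1 = np.cumsum(w * z)
        s2 = np.cumsum(w * z * z)
        # handle tied times: risk set includes all with equal time
        s0 = _tie_expand(t, s0)
        s1 = _tie_expand(t, s1)
        s2 = _tie_expand(t, s2)
        ev = d == 1
        mu = s1[ev] / s0[ev]
        grad = float(np.sum(z[ev] - mu))
        hess = float(np.sum(s2[ev] / s0[ev] - mu * mu))
        if hess <= 0:
            return beta, math.inf, False
        step = grad / hess
        beta += step
        if abs(step) < tol:
            se = 1.0 / math.sqrt(hess)
            return beta, se, True
        if abs(beta) > 50:  # monotone likelihood / separation
            return beta, math.inf, False
    return beta, 1.0 / math.sqrt(hess), False


def _tie_expand(t: np.ndarray, cs: np.ndarray) -> np.ndarray:
    """Propagate cumulative sums so tied times share the full risk set."""
    if t.size < 2 or not np.any(t[1:] == t[:-1]):
        return cs
    # last index of each tie block (times sorted decreasing)
    out = cs.copy()
    i = t.size - 1
    while i > 0:
        j = i
        while j > 0 and t[j - 1] == t[i]:
            j -= 1
        if j < i:
            out[j:i] = cs[i]
        i = j - 1
    return out


def univariable_cox(time, event, x) -> StatResult:
    """Single-covariate Cox fit (fast path): beta, HR, Wald p."""
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    x = np.asarray(x, float)
    ok = np.isfinite(time) & np.isfinite(x)
    time, event, x = time[ok], event[ok], x[ok]
    if event.sum() < 2:
        raise InsufficientDataError("need >= 2 events")
    if x.std() == 0:
        raise DegenerateInputError("zero-variance covariate")
    # standardize for Newton stability; rescale estimates afterwards
    mu, sd = x.mean(), x.std()
    beta_s, se_s, conv = _cox_single_newton(time, event, (x - mu) / sd)
    beta, se = beta_s / sd, se_s / sd
    z = beta / se if se > 0 and math.isfinite(se) else 0.0
    p = 2.0 * stats.norm.sf(abs(z)) if math.isfinite(z) else 1.0
    return StatResult(
        statistic_name="cox_wald_z", statistic=float(z),
        effect=float(math.exp(beta)) if abs(beta) < 500 else math.inf,
        p_raw=float(p), n_used=len(x),
        extra={"beta": float(beta), "se": float(se), "converged": conv},
    )


def univariable_screen(
    table: pd.DataFrame,
    variables: list[str],
    family_size: int | None = None,
    time_col: str = "time_months",
    event_col: str = "event",
) -> list[StatResult]:
    """Univariable Cox per variable with Bonferroni-corrected p-values.

    Continuous variables enter as-is (image-analysis fractions are screened
    on the continuous scale).  ``family_size`` defaults to the number of
    screened variables, or the package default of 53 when the table is part
    of the standard clinical + image-analysis screen.  Non-converging fits
    are flagged and excluded from the corrected ranking (p_corrected None).
    """
    m = family_size if family_size is not None else max(
        len(variables), DEFAULT_FAMILY_SIZE if len(variables) > 20 else len(variables)
    )
    out = []
    for var in variables:
        sub = table[[time_col, event_col, var]].dropna()
        try:
            res = univariable_cox(sub[time_col], sub[event_col], sub[var])
        except (InsufficientDataError, DegenerateInputError) as exc:
            res = StatResult("cox_wald_z", math.nan, None, math.nan,
                             extra={"skipped": str(exc), "converged": False})
        res.statistic_name = f"cox[{var}]"
        if res.extra.get("converged", False):
            res.p_corrected = bonferroni(res.p_raw, m)
        else:
            res.p_corrected = None
        out.append(res)
    return out


def km_logrank(time, event, group) -> tuple[SurvivalFit, pd.DataFrame]:
    """Kaplan-Meier curves per group with a two-group log-rank test.

    Returns the fit (log-rank chi2/p, plus the univariable Cox HR of group
    membership when exactly two groups) and a tidy curve table
    (group, time, survival) of right-continuous step functions starting at 1.
    """
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    group = np.asarray(group)
    if event.sum() < 1:
        raise InsufficientDataError("need >= 1 event")
    levels = [g for g in pd.unique(group)]
    if any((group == g).sum() == 0 for g in levels) or len(levels) < 1:
        raise ParameterError("every group needs >= 1 subject")
    curves = []
    for g in levels:
        sel = group == g
        km = KaplanMeierFitter()
        km.fit(time[sel], event[sel], label=str(g))
        sf = km.survival_function_
        curves.append(pd.DataFrame({
            "group": str(g),
            "time": sf.index.to_numpy(dtype=float),
            "survival": sf.iloc[:, 0].to_numpy(dtype=float),
        }))
    curve_df = pd.concat(curves, ignore_index=True)
    fit = SurvivalFit(model="km")
    if len(levels) == 2:
        a, b = (group == levels[0]), (group == levels[1])
        lr = logrank_test(time[a], time[b], event[a], event[b])
        fit.logrank_chi2 = float(lr.test_statistic)
        fit.logrank_p = float(lr.p_value)
        try:
            hr = univariable_cox(time, event, (group == levels[1]).astype(float))
            fit.extra["hr"] = hr.effect
            fit.extra["hr_p"] = hr.p_raw
        except (InsufficientDataError, DegenerateInputError):
            pass
    return fit, curve_df


def cox_fit(time, event, covariates: pd.DataFrame) -> SurvivalFit:
    """Multivariable Cox PH fit (Efron ties) with Wald CIs per covariate.

    ``coefs`` has one row per covariate: beta, HR, ci_low, ci_high, p.
    Separation / monotone likelihood is reported via ``converged=False``.
    """
    cov = pd.DataFrame(covariates).reset_index(drop=True)
    df = cov.copy()
    df["_time"] = np.asarray(time, float)
    df["_event"] = np.asarray(event, int)
    df = df.dropna()
    n_events = int(df["_event"].sum())
    if n_events < len(cov.columns) + 1:
        raise InsufficientDataError("need more events than covariates")
    cph = CoxPHFitter()
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            cph.fit(df, duration_col="_time", event_col="_event")
        except Exception:
            converged = False
    if not converged:
        return SurvivalFit(model="cox", coefs=None, converged=False)
    s = cph.summary
    coefs = pd.DataFrame({
        "beta": s["coef"],
        "HR": s["exp(coef)"],
        "ci_low": s["exp(coef) lower 95%"],
        "ci_high": s["exp(coef) upper 95%"],
        "p": s["p"],
    })
    model = "cox_uni" if len(cov.columns) == 1 else "cox_multi"
    fit = SurvivalFit(model=model, coefs=coefs, converged=True)
    fit.extra["fitter"] = cph
    fit.extra["df"] = df
    return fit


def ph_check(fit: SurvivalFit) -> dict[str, float]:
    """Schoenfeld-residual proportional-hazards test per covariate.

    Tests correlation of the scaled Schoenfeld residuals with (rank-
    transformed) time; returns covariate -> p.  Zero-variance covariates are
    reported as NaN.
    """
    if not fit.converged or "fitter" not in fit.extra:
        raise ParameterError("needs a converged cox_fit result")
    cph = fit.extra["fitter"]
    df = fit.extra["df"]
    if int(df["_event"].sum()) < 3:
        raise InsufficientDataError("need >= 3 events for the PH check")
    out = {}
    res = proportional_hazard_test(cph, df, time_transform="rank")
    pvals = res.summary["p"]
    for name in fit.coefs.index:
        if df[name].std() == 0:
            out[name] = math.nan
        else:
            out[name] = float(pvals.loc[name])
    return out


# ---------------------------------------------------------------------------
# DeLong comparison of correlated AUCs
# ---------------------------------------------------------------------------


def _auc_placements(pos: np.ndarray, neg: np.ndarray):
    """AUC and DeLong placement values via midranks."""
    m, n = len(pos), len(neg)
    allv = np.r_[pos, neg]
    ranks = stats.rankdata(allv)  # midranks
    rpos = stats.rankdata(pos)
    rneg = stats.rankdata(neg)
    v10 = (ranks[:m] - rpos) / n  # per positive
    v01 = 1.0 - (ranks[m:] - rneg) / m  # per negative
    auc = v10.mean()
    return auc, v10, v01


def delong_compare(outcome, score_a, score_b) -> StatResult:
    """DeLong test for two correlated ROC curves on the same subjects.

    Returns delta AUC (a minus b) with its DeLong variance and two-sided p;
    ``extra`` carries both AUCs.  Identical scores give delta 0, p = 1.
    """
    y = np.asarray(outcome, int)
    a = np.asarray(score_a, float)
    b = np.asarray(score_b, float)
    ok = np.isfinite(a) & np.isfinite(b)
    y, a, b = y[ok], a[ok], b[ok]
    if len(np.unique(y)) < 2:
        raise InsufficientDataError("need both outcome classes")
    pos, neg = y == 1, y == 0
    auc_a, v10a, v01a = _auc_placements(a[pos], a[neg])
    auc_b, v10b, v01b = _auc_placements(b[pos], b[neg])
    m, n = int(pos.sum()), int(neg.sum())
    s10 = np.cov(np.vstack([v10a, v10b]))
    s01 = np.cov(np.vstack([v01a, v01b]))
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m \
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    delta = auc_a - auc_b
    if var <= 1e-16:
        z, p = 0.0, 1.0
    else:
        z = delta / math.sqrt(var)
        p = 2.0 * stats.norm.sf(abs(z))
    return StatResult(
        statistic_name="delong_z", statistic=float(z), effect=float(delta),
        p_raw=float(p), n_used=m + n,
        extra={"auc_a": float(auc_a), "auc_b": float(auc_b)},
    )
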