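"""Group-level statistical models linking BAGs to behavior and diagnosis.

Covariate-adjusted GLMs for BAG-behavior associations, omnibus partial-F
tests with Tukey-Kramer post-hocs for diagnosis-count and transition
groups, spline GAM incremental-variance (adjusted delta R^2) effect
sizes for follow-up cognition, random-intercept linear mixed models for
puberty/hormone analyses, PDS pubertal staging, Spearman comparison of
tract-wise effect patterns, and Benjamini-Hochberg FDR control.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GlmResult",
    "GamResult",
    "LmmResult",
    "glm_bag_behavior",
    "glm_group_effect",
    "gam_delta_r2",
    "lmm_developmental",
    "pds_categorize",
    "diagnosis_grouping",
    "effect_pattern_similarity",
    "bh_fdr",
]

PDS_STAGES = ("prepubertal", "early", "mid", "late", "postpubertal")


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, >= raw p)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p.ravel(), method="fdr_bh")[1].reshape(p.shape)


@dataclass
class GlmResult:
    outcome: str
    predictor: str
    coef: float
    stat: float  # t for continuous predictors, F for factors
    df: tuple
    p: float
    p_fdr: float | None = None
    posthoc: pd.DataFrame | None = None


@dataclass
class GamResult:
    outcome: str
    predictor: str
    f_stat: float
    delta_r2_pct: float
    p: float
    p_fdr: float | None = None


@dataclass
class LmmResult:
    predictor: str
    fixed_effects: pd.DataFrame
    coef: float
    stat: float
    df: float
    p: float
    re_variance: float
    singular: bool = False
    p_fdr: float | None = None


def _design(age, sex, extra=None):
    cols = {"age": np.asarray(age, float), "sex": np.asarray(sex, float)}
    if extra is not None:
        cols = {**extra, **cols}
    D = pd.DataFrame(cols)
    return sm.add_constant(D)


def glm_bag_behavior(bag, behavior, age, sex, outcome_id="bag",
                     predictor_id="behavior") -> GlmResult:
    """GLM of BAG on one behavioral score, controlling age and sex.

    BAG = b0 + b1 * Behavior + b2 * Age + b3 * Sex; reports the t test of
    b1. FDR correction over the tested family is applied by the caller.
    """
    y = np.asarray(bag, float)
    if len(y) <= 10:
        raise ValueError("need more than 10 complete cases")
    X = _design(age, sex, {"behavior": np.asarray(behavior, float)})
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient design")
    res = sm.OLS(y, X).fit()
    return GlmResult(
        outcome=outcome_id,
        predictor=predictor_id,
        coef=float(res.params["behavior"]),
        stat=float(res.tvalues["behavior"]),
        df=(int(res.df_resid),),
        p=float(res.pvalues["behavior"]),
    )


def glm_group_effect(bag, group, age=None, sex=None, adjusted: bool = True,
                     outcome_id="bag", predictor_id="group") -> GlmResult:
    """Omnibus partial-F test of a group factor with Tukey post-hoc contrasts.

    The factor (e.g. diagnosis-count class 0/1/>=2 or transition class
    HH/PH/HP/PP) enters a covariate-adjusted linear model as dummy
    columns; the omnibus F compares the models with and without those
    columns. Pairwise contrasts use the Tukey-Kramer studentized-range
    procedure on covariate-adjusted group means (or raw means with
    ``adjusted=False`` / no covariates).
    """
    y = np.asarray(bag, float)
    group = np.asarray(group)
    levels, idx = np.unique(group, return_inverse=True)
    counts = np.bincount(idx)
    if np.any(counts < 2):
        raise ValueError("every group needs at least 2 members")
    G = len(levels)
    dummies = np.zeros((len(y), G - 1))
    for g in range(1, G):
        dummies[idx == g, g - 1] = 1.0

    use_cov = adjusted and age is not None
    if use_cov:
        Xr = _design(age, sex)
    else:
        Xr = pd.DataFrame({"const": np.ones(len(y))})
    Xf = Xr.copy()
    for g in range(1, G):
        Xf[f"g_{levels[g]}"] = dummies[:, g - 1]

    fit_f = sm.OLS(y, Xf).fit()
    fit_r = sm.OLS(y, Xr).fit()
    df_num = G - 1
    df_den = int(fit_f.df_resid)
    ss_diff = fit_r.ssr - fit_f.ssr
    sst = float(((y - y.mean()) ** 2).sum())
    eps = 1e-12 * max(sst, 1.0)
    if fit_f.ssr > eps:
        F = (ss_diff / df_num) / (fit_f.ssr / df_den)
    else:  # saturated or degenerate fit: decide from the explained SS alone
        F = 0.0 if ss_diff <= eps else np.inf
    p = float(stats.f.sf(F, df_num, df_den)) if np.isfinite(F) else 0.0

    # Tukey-Kramer on (adjusted) means: q = |diff| / (SE_diff / sqrt(2))
    params = fit_f.params
    cov = fit_f.cov_params()
    eff = np.zeros(G)
    for g in range(1, G):
        eff[g] = params[f"g_{levels[g]}"]
    base = params["const"]
    if use_cov:
        base = base + params["age"] * np.mean(age) + params["sex"] * np.mean(sex)
    adj_means = base + eff
    rows = []
    for i in range(G):
        for j in range(i + 1, G):
            c = pd.Series(0.0, index=params.index)
            if i > 0:
                c[f"g_{levels[i]}"] = 1.0
            if j > 0:
                c[f"g_{levels[j]}"] -= 1.0
            se = float(np.sqrt(c @ cov @ c))
            diff = adj_means[i] - adj_means[j]
            q = np.abs(diff) / (se / np.sqrt(2.0)) if se > 0 else np.inf
            p_t = float(stats.studentized_range.sf(q, G, df_den))
            rows.append(
                {
                    "group_a": levels[i],
                    "group_b": levels[j],
                    "diff": diff,
                    "se": se,
                    "q": q,
                    "p_tukey": p_t,
                }
            )
    posthoc = pd.DataFrame(rows)
    res = GlmResult(
        outcome=outcome_id,
        predictor=predictor_id,
        coef=float(np.ptp(adj_means)),
        stat=float(F),
        df=(df_num, df_den),
        p=p,
        posthoc=posthoc,
    )
    res.adjusted_means = pd.Series(adj_means, index=levels)
    return res


def _spline_basis(age, df: int = 10):
    from statsmodels.gam.smooth_basis import BSplines

    age = np.asarray(age, float)
    return BSplines(age[:, None], df=[df], degree=[3], include_intercept=False)


def gam_delta_r2(outcome, bag, age, sex, spline_df: int = 10,
                 outcome_id="outcome", predictor_id="bag") -> GamResult:
    """Incremental adjusted R^2 (percent) of a BAG term over a covariate GAM.

    A generalized additive model with a cubic B-spline smooth of age
    (basis dimension ``spline_df``) and a linear sex term is fit with and
    without the BAG predictor; the effect size is
    100 * (adjR2_full - adjR2_null) and the F statistic tests the added
    term.
    """
    y = np.asarray(outcome, float)
    n = len(y)
    if n <= 50:
        raise ValueError("need more than 50 observations")
    basis = _spline_basis(age, df=spline_df).basis
    Xn = np.column_stack([np.ones(n), np.asarray(sex, float), basis])
    Xf = np.column_stack([Xn, np.asarray(bag, float)])

    fit_n = sm.OLS(y, Xn).fit()
    fit_f = sm.OLS(y, Xf).fit()
    df_den = int(fit_f.df_resid)
    F = ((fit_n.ssr - fit_f.ssr) / 1.0) / (fit_f.ssr / df_den) if fit_f.ssr > 0 else np.inf
    p = float(stats.f.sf(F, 1, df_den)) if np.isfinite(F) else 0.0
    delta = 100.0 * (fit_f.rsquared_adj - fit_n.rsquared_adj)
    return GamResult(
        outcome=outcome_id,
        predictor=predictor_id,
        f_stat=float(F),
        delta_r2_pct=float(delta),
        p=p,
    )


def lmm_developmental(bag, predictor, age, sex, timepoint, subject,
                      extra_covariates: dict | None = None,
                      predictor_id="predictor") -> LmmResult:
    """Random-intercept LMM of BAG on a developmental predictor.

    BAG = b0 + b1 * Predictor + b2 * Age + b3 * Sex + b4 * Timepoint
    [+ collection covariates] + (1 | Subject), fit by REML. The t test of
    b1 uses a residual-type degrees-of-freedom approximation
    (n_obs - n_fixed - n_subjects + 1). A singular (zero) random-effect
    fit is reported via the ``singular`` flag, never dropped.
    """
    import warnings

    y = np.asarray(bag, float)
    cols = {
        "predictor": np.asarray(predictor, float),
        "age": np.asarray(age, float),
        "sex": np.asarray(sex, float),
        "timepoint": np.asarray(timepoint, float),
    }
    if extra_covariates:
        for k, v in extra_covariates.items():
            cols[k] = np.asarray(v, float)
    X = sm.add_constant(pd.DataFrame(cols))
    groups = np.asarray(subject)
    n_groups = len(np.unique(groups))
    if np.max(np.bincount(pd.factorize(groups)[0])) < 2:
        raise ValueError("need repeated visits for at least one subject")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.MixedLM(y, X, groups=groups).fit(reml=True)
    re_var = float(np.asarray(res.cov_re)[0, 0])
    singular = re_var < 1e-8 or not res.converged
    df = max(len(y) - X.shape[1] - n_groups + 1, 1)
    coef = float(res.params["predictor"])
    t = float(res.params["predictor"] / res.bse["predictor"])
    p = float(2 * stats.t.sf(np.abs(t), df))
    fe = pd.DataFrame(
        {"coef": res.params[X.columns], "se": res.bse[X.columns]}
    )
    return LmmResult(
        predictor=predictor_id,
        fixed_effects=fe,
        coef=coef,
        stat=t,
        df=float(df),
        p=p,
        re_variance=re_var,
        singular=singular,
    )


def pds_categorize(sex, item_sum, menarche=False) -> str:
    """Five-level pubertal stage from sex-specific PDS item sums.

    Males (3 items, sum 3-12): 3 prepubertal; 4-5 early; 6-8 mid; 9-11
    late; 12 postpubertal. Females (2 items, sum 2-8): 2 prepubertal;
    3 without menarche early; >3 without menarche mid; <=7 with menarche
    late; 8 with menarche postpubertal.
    """
    s = int(item_sum)
    if int(sex) == 1:  # male
        if not 3 <= s <= 12:
            raise ValueError(f"male PDS sum out of range [3, 12]: {s}")
        if s == 3:
            return "prepubertal"
        if s in (4, 5):
            return "early"
        if 6 <= s <= 8:
            return "mid"
        if 9 <= s <= 11:
            return "late"
        return "postpubertal"
    if not 2 <= s <= 8:
        raise ValueError(f"female PDS sum out of range [2, 8]: {s}")
    if bool(menarche):
        return "late" if s <= 7 else "postpubertal"
    if s == 2:
        return "prepubertal"
    if s == 3:
        return "early"
    return "mid"


def diagnosis_grouping(count_baseline, count_followup) -> pd.DataFrame:
    """Count classes {0, 1, >=2} per visit and HH/PH/HP/PP transition classes."""
    b = np.minimum(np.asarray(count_baseline, int), 2)
    f = np.minimum(np.asarray(count_followup, int), 2)
    if np.any(b < 0) or np.any(f < 0):
        raise ValueError("diagnosis counts must be non-negative")
    trans = np.where(
        b == 0, np.where(f == 0, "HH", "HP"), np.where(f == 0, "PH", "PP")
    )
    return pd.DataFrame(
        {"class_baseline": b, "class_followup": f, "transition": trans}
    )


def effect_pattern_similarity(effects_a, effects_b,
                              exact_max_n: int = 10) -> tuple[float, float]:
    """Spearman correlation of two tract-wise effect patterns.

    Average ranks for ties; the two-sided p-value is computed by exact
    enumeration over all permutations when length <= ``exact_max_n``,
    otherwise by the t approximation.
    """
    a = np.asarray(effects_a, float)
    b = np.asarray(effects_b, float)
    if len(a) != len(b):
        raise ValueError("effect vectors must have equal length")
    if len(a) < 5:
        raise ValueError("need at least 5 tracts")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("constant effect vector")
    rho, p_t = stats.spearmanr(a, b)
    if len(a) <= exact_max_n:
        ra = stats.rankdata(a)
        rb = stats.rankdata(b)
        obs = np.abs(rho)
        count = 0
        total = 0
        for perm in permutations(range(len(a))):
            r = np.corrcoef(ra[list(perm)], rb)[0, 1]
            count += np.abs(r) >= obs - 1e-12
            total += 1
        return float(rho), count / total
    return float(rho), float(p_t)
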