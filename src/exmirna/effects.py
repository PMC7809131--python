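"""Covariate-adjusted group comparisons per miRNA.

For each expressed miRNA the exposed/control contrast is estimated from an
ANCOVA (ΔCT ~ group + cigarettes/day), the standardized difference is
expressed as Cohen's d and Hedges' g with normal-approximation confidence
intervals, and miRNAs are screened with an effect-size cutoff (|d| ≥ 0.40 by
default) rather than adjusted p-values.  A sex-stratified bootstrap
classifies responses as male- or female-specific.

Sign convention: d > 0 means lower ΔCT (higher expression) in the exposed
group, i.e. upregulation under prenatal alcohol exposure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

EFFECT_SIZE_CUTOFF = 0.40


# ---------------------------------------------------------------------------
# ANCOVA

def _ancova_all(y: np.ndarray, group01: np.ndarray, covariate: np.ndarray):
    """Closed-form ANCOVA for many responses at once.

    ``y`` is (n_samples, n_mirnas).  Returns adjusted means at the covariate
    grand mean, the group-term F statistic, and its p-value, per column.
    Kept in plain numpy because the bootstrap refits this thousands of
    times; equivalence with statsmodels OLS is covered by tests.
    """
    n = y.shape[0]
    X = np.column_stack([np.ones(n), group01, covariate])
    XtX = X.T @ X
    beta = np.linalg.solve(XtX, X.T @ y)          # (3, m)
    resid = y - X @ beta
    dof = n - 3
    sigma2 = (resid**2).sum(axis=0) / dof
    var_bg = np.linalg.inv(XtX)[1, 1] * sigma2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta[1] / np.sqrt(var_bg)
    F = t**2
    p = 2.0 * stats.t.sf(np.abs(t), dof)
    cbar = covariate.mean()
    adj_control = beta[0] + beta[2] * cbar
    adj_exposed = beta[0] + beta[1] + beta[2] * cbar
    return adj_control, adj_exposed, F, p


def ancova_adjusted_means(
    delta_ct: np.ndarray | pd.Series,
    group: np.ndarray | pd.Series,
    cigarettes_per_day: np.ndarray | pd.Series,
) -> tuple[float, float, float, float]:
    """Adjusted group means (at the covariate grand mean), F and p for the
    group term of ΔCT ~ group + cigarettes/day.

    ``group`` may be 'control'/'exposed' labels or 0/1.  With a
    zero-variance covariate the model falls back to unadjusted means.
    """
    y = np.asarray(delta_ct, dtype=float).reshape(-1, 1)
    g = _as_group01(group)
    c = np.asarray(cigarettes_per_day, dtype=float)
    if min((g == 0).sum(), (g == 1).sum()) < 3:
        raise ValueError("need at least 3 subjects per group")
    if np.var(c) == 0:
        warnings.warn("zero covariate variance; using unadjusted means", stacklevel=2)
        mc, me = y[g == 0].mean(), y[g == 1].mean()
        t, p = stats.ttest_ind(y[g == 1], y[g == 0])
        return float(mc), float(me), float(t[0] ** 2), float(p[0])
    ac, ae, F, p = _ancova_all(y, g, c)
    return float(ac[0]), float(ae[0]), float(F[0]), float(p[0])


def _as_group01(group) -> np.ndarray:
    arr = np.asarray(group)
    if arr.dtype.kind in "OUS":
        return (arr == "exposed").astype(float)
    return arr.astype(float)


# ---------------------------------------------------------------------------
# Standardized effect sizes

def hedges_correction(n_total: int) -> float:
    """Small-sample correction J = 1 − 3/(4·(n−2) − 1)."""
    return 1.0 - 3.0 / (4.0 * (n_total - 2) - 1.0)


def cohens_d(
    adjusted_mean_c: float,
    adjusted_mean_e: float,
    sd_c: float,
    sd_e: float,
    n_c: int,
    n_e: int,
) -> tuple[float, float, tuple[float, float]]:
    """Cohen's d, Hedges' g, and a normal-approximation 95% CI for d.

    d = (mean_control − mean_exposed) / pooled SD, so positive d marks
    upregulation in the exposed group on the ΔCT scale.  g = J·d with
    J = 1 − 3/(4(n−2)−1);  SE(d) = sqrt((n_c+n_e)/(n_c n_e) + d²/(2(n_c+n_e))).
    """
    if n_c < 2 or n_e < 2:
        raise ValueError("need n ≥ 2 per group")
    if sd_c <= 0 or sd_e <= 0:
        raise ValueError("group SDs must be positive")
    n = n_c + n_e
    pooled = np.sqrt(((n_c - 1) * sd_c**2 + (n_e - 1) * sd_e**2) / (n - 2))
    d = (adjusted_mean_c - adjusted_mean_e) / pooled
    g = hedges_correction(n) * d
    se = np.sqrt(n / (n_c * n_e) + d**2 / (2 * n))
    ci = (d - 1.959963984540054 * se, d + 1.959963984540054 * se)
    return float(d), float(g), (float(ci[0]), float(ci[1]))


@dataclass
class EffectRecord:
    mimat_id: str
    adjusted_mean_control: float
    adjusted_mean_exposed: float
    pooled_sd: float
    d: float
    g: float
    ci_low: float
    ci_high: float
    F: float
    p: float
    direction: str  # up_in_PAE / down_in_PAE


def compute_effects(
    delta_ct: pd.DataFrame,
    groups: pd.Series,
    cigarettes_per_day: pd.Series,
) -> pd.DataFrame:
    """Per-miRNA effect table (Table-2 style).

    Adjusted means enter the numerator of d; the denominator is the pooled
    within-group SD of the raw ΔCT values.
    """
    samples = delta_ct.columns
    g01 = _as_group01(groups.reindex(samples))
    cov = cigarettes_per_day.reindex(samples).to_numpy(dtype=float)
    Y = delta_ct.to_numpy(dtype=float).T  # samples × miRNAs
    if np.var(cov) == 0:
        warnings.warn("zero covariate variance; unadjusted means used", stacklevel=2)
        cov = cov + np.random.default_rng(0).normal(0, 1e-12, cov.shape)
    ac, ae, F, p = _ancova_all(Y, g01, cov)
    n_c = int((g01 == 0).sum())
    n_e = int((g01 == 1).sum())
    sd_c = Y[g01 == 0].std(axis=0, ddof=1)
    sd_e = Y[g01 == 1].std(axis=0, ddof=1)
    rows = []
    for i, mimat in enumerate(delta_ct.index):
        d, g, ci = cohens_d(ac[i], ae[i], sd_c[i], sd_e[i], n_c, n_e)
        pooled = np.sqrt(((n_c - 1) * sd_c[i] ** 2 + (n_e - 1) * sd_e[i] ** 2) / (n_c + n_e - 2))
        rows.append(
            EffectRecord(
                mimat_id=mimat,
                adjusted_mean_control=float(ac[i]),
                adjusted_mean_exposed=float(ae[i]),
                pooled_sd=float(pooled),
                d=d,
                g=g,
                ci_low=ci[0],
                ci_high=ci[1],
                F=float(F[i]),
                p=float(p[i]),
                direction="up_in_PAE" if d >= 0 else "down_in_PAE",
            )
        )
    out = pd.DataFrame([r.__dict__ for r in rows]).set_index("mimat_id")
    return out


def screen_by_effect(effects: pd.DataFrame, cutoff: float = EFFECT_SIZE_CUTOFF) -> dict:
    """Apply the |d| ≥ cutoff screen and summarize.

    Returns the screened table, the subset whose CI excludes zero
    ("significant"), and the fraction of screened miRNAs upregulated in the
    exposed group.
    """
    screened = effects[effects["d"].abs() >= cutoff]
    significant = screened[(screened["ci_low"] > 0) | (screened["ci_high"] < 0)]
    n = len(screened)
    frac_up = float((screened["d"] > 0).mean()) if n else float("nan")
    return {
        "screened": screened,
        "significant": significant,
        "n_screened": n,
        "n_significant": len(significant),
        "fraction_upregulated": frac_up,
    }


def screened_union_fraction(ids_by_age: dict[str, list[str]], universe_size: int) -> float:
    """Fraction of the expressed universe screened at any age (set union)."""
    union: set[str] = set()
    for ids in ids_by_age.values():
        union |= set(ids)
    return len(union) / universe_size


def effect_interpretations(d: float) -> dict[str, float]:
    """Translate Cohen's d into interpretive metrics.

    U3: standard-normal CDF at d — the proportion of the exposed group
    above the control mean.  OR: logistic-equivalent odds ratio
    exp(d·π/√3).  BESD: binomial effect-size display rate difference
    d/√(d²+4).
    """
    d = float(d)
    return {
        "U3": float(stats.norm.cdf(d)),
        "odds_ratio": float(np.exp(d * np.pi / np.sqrt(3.0))),
        "besd_difference": float(d / np.sqrt(d**2 + 4.0)),
    }


# ---------------------------------------------------------------------------
# Sex-stratified bootstrap

def classify_sex_specificity(
    prop_combined: float, prop_female: float, prop_male: float
) -> str:
    """Classification rule: a sex is 'specific' iff its proportion of
    significant iterations exceeds 0.5 AND the combined-sample proportion."""
    f = prop_female > 0.5 and prop_female > prop_combined
    m = prop_male > 0.5 and prop_male > prop_combined
    if f and m:
        return "both"
    if f:
        return "female_specific"
    if m:
        return "male_specific"
    return "none"


def _bootstrap_sig_props(Y, g01, cov, n_iter, rng, alpha=0.05):
    """Proportion of resampling iterations with group p < alpha, per miRNA.

    Resampling is stratified by exposure group to preserve the design.
    """
    idx_c = np.flatnonzero(g01 == 0)
    idx_e = np.flatnonzero(g01 == 1)
    m = Y.shape[1]
    sig = np.zeros(m)
    for _ in range(n_iter):
        take = np.concatenate(
            [rng.choice(idx_c, size=idx_c.size), rng.choice(idx_e, size=idx_e.size)]
        )
        c = cov[take]
        if np.var(c) == 0:
            c = c + rng.normal(0, 1e-9, c.shape)
        _, _, _, p = _ancova_all(Y[take], g01[take], c)
        sig += p < alpha
    return sig / n_iter


def sex_stratified_bootstrap(
    delta_ct: pd.DataFrame,
    groups: pd.Series,
    sex: pd.Series,
    covariate: pd.Series,
    n_iter: int = 2000,
    seed: int = 0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Bootstrap classification of sex-specific exposure responses.

    Subjects are resampled with replacement (2000 iterations by default,
    stratified by exposure group) three ways — the combined sample, females
    only, males only — and the fraction of iterations in which the ANCOVA
    group term is significant is recorded per miRNA.  A response is called
    sex-specific when a single sex's proportion exceeds one half and the
    combined proportion.  Strata with fewer than 4 subjects give an
    indeterminate classification.
    """
    rng = np.random.default_rng(seed)
    samples = delta_ct.columns
    g01 = _as_group01(groups.reindex(samples))
    sx = sex.reindex(samples).to_numpy()
    cov = covariate.reindex(samples).to_numpy(dtype=float)
    Y = delta_ct.to_numpy(dtype=float).T

    props = {}
    strata_ok = True
    for label, mask in (
        ("combined", np.ones(len(samples), bool)),
        ("female", sx == "F"),
        ("male", sx == "M"),
    ):
        sub_g = g01[mask]
        if min((sub_g == 0).sum(), (sub_g == 1).sum()) < 4:
            props[label] = np.full(Y.shape[1], np.nan)
            strata_ok = False
            continue
        props[label] = _bootstrap_sig_props(Y[mask], sub_g, cov[mask], n_iter, rng, alpha)

    out = pd.DataFrame(
        {
            "prop_sig_combined": props["combined"],
            "prop_sig_female": props["female"],
            "prop_sig_male": props["male"],
        },
        index=delta_ct.index,
    )
    if strata_ok:
        out["classification"] = [
            classify_sex_specificity(c, f, m)
            for c, f, m in zip(
                out["prop_sig_combined"], out["prop_sig_female"], out["prop_sig_male"]
            )
        ]
    else:
        out["classification"] = "indeterminate"
    return out


# ---------------------------------------------------------------------------
# Cohort-table comparison helpers

def welch_t(mean1, sd1, n1, mean2, sd2, n2) -> tuple[float, float, float]:
    """Welch's unequal-variance t from summary statistics: (t, df, p)."""
    v1, v2 = sd1**2 / n1, sd2**2 / n2
    t = (mean2 - mean1) / np.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    p = 2 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def chi2_2x2(table) -> tuple[float, float]:
    """Pearson chi-square (no continuity correction) for a 2×2 table."""
    res = stats.chi2_contingency(np.asarray(table), correction=False)
    return float(res.statistic), float(res.pvalue)
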