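"""Linear mediation of exposure effects on growth and cognition.

A saturated single-mediator path model on standardized variables:

    mediator = a·exposure + ε₁
    outcome  = c'·exposure + b·mediator + ε₂

The specific indirect effect is the product a·b, tested by the Sobel
z-test (delta-method SE) and by a bias-corrected (BC) percentile bootstrap
of case resamples.  The total effect equals c' + a·b exactly for least
squares fitted on the same sample.  Maternal smoking is handled as an
exogenous variable correlated with exposure by default; a sensitivity
switch includes it as a covariate in both regressions instead.

On the ΔCT scale a factor score is *inversely* related to expression, so
the signs of a and b are interpreted accordingly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

OUTCOMES = ("length_z", "weight_z", "hc_z", "ftii_novelty")


@dataclass
class MediationDesign:
    exposure: str = "aa_per_day"
    mediator: str = "factor_score"
    outcome: str = "weight_z"
    covariate: str | None = "cigarettes_per_day"
    smoking_as_covariate: bool = False   # sensitivity switch
    standardize: bool = True


@dataclass
class MediationResult:
    a: float
    b: float
    c_prime: float
    indirect: float
    total: float
    se_a: float
    se_b: float
    se_c_prime: float
    se_indirect: float
    z: float
    p: float
    p_a: float
    p_b: float
    p_c_prime: float
    n: int
    boot_ci: tuple[float, float] | None = None
    n_boot: int = 0
    classification: str = "no_mediation"
    extra: dict = field(default_factory=dict)


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance in a model variable")
    return (x - x.mean()) / sd


def _ols(y: np.ndarray, X: np.ndarray):
    """Least squares with classical SEs; X excludes the intercept."""
    n = y.size
    Xd = np.column_stack([np.ones(n), X])
    XtX = Xd.T @ Xd
    beta = np.linalg.solve(XtX, Xd.T @ y)
    resid = y - Xd @ beta
    dof = n - Xd.shape[1]
    sigma2 = resid @ resid / dof
    se = np.sqrt(np.diag(np.linalg.inv(XtX)) * sigma2)
    t = beta / se
    p = 2.0 * stats.t.sf(np.abs(t), dof)
    return beta[1:], se[1:], p[1:]


def _paths(x, m, y, cov=None):
    """(a, b, c') and classical SEs/p-values from the two regressions."""
    Xm = x[:, None] if cov is None else np.column_stack([x, cov])
    beta_m, se_m, p_m = _ols(m, Xm)
    Xy = np.column_stack([x, m]) if cov is None else np.column_stack([x, m, cov])
    beta_y, se_y, p_y = _ols(y, Xy)
    return (
        (beta_m[0], beta_y[1], beta_y[0]),
        (se_m[0], se_y[1], se_y[0]),
        (p_m[0], p_y[1], p_y[0]),
    )


def fit_mediation(design: MediationDesign, data: pd.DataFrame,
                  alpha: float = 0.05) -> MediationResult:
    """Fit the path model on complete cases.

    Coefficients are standardized when ``design.standardize`` (the
    default), making them comparable across outcomes.  The Sobel SE is
    sqrt(a²·SE_b² + b²·SE_a²); with a = b = 0 exactly the z-test is
    undefined and p is reported as 1.
    """
    cols = [design.exposure, design.mediator, design.outcome]
    if design.covariate and design.smoking_as_covariate:
        cols.append(design.covariate)
    frame = data[cols].dropna()
    n = len(frame)
    if n < 10:
        raise ValueError("need ≥ 10 complete cases")
    arrs = {c: frame[c].to_numpy(dtype=float) for c in cols}
    if design.standardize:
        arrs = {c: _zscore(v) for c, v in arrs.items()}
    else:
        for v in arrs.values():
            if v.std(ddof=1) == 0:
                raise ValueError("zero variance in a model variable")
    x, m, y = arrs[design.exposure], arrs[design.mediator], arrs[design.outcome]
    cov = arrs.get(design.covariate) if design.smoking_as_covariate else None

    (a, b, c_prime), (se_a, se_b, se_c), (p_a, p_b, p_c) = _paths(x, m, y, cov)
    indirect = a * b
    se_ind = float(np.sqrt(a**2 * se_b**2 + b**2 * se_a**2))
    if se_ind == 0:
        z, p = float("nan"), 1.0
    else:
        z = indirect / se_ind
        p = 2.0 * stats.norm.sf(abs(z))

    Xt = x[:, None] if cov is None else np.column_stack([x, cov])
    total_beta, _, _ = _ols(y, Xt)
    total = float(total_beta[0])

    classification = _classify(p, p_c, alpha)
    return MediationResult(
        a=float(a), b=float(b), c_prime=float(c_prime),
        indirect=float(indirect), total=total,
        se_a=float(se_a), se_b=float(se_b), se_c_prime=float(se_c),
        se_indirect=se_ind, z=float(z), p=float(p),
        p_a=float(p_a), p_b=float(p_b), p_c_prime=float(p_c), n=n,
    )


def _classify(p_indirect: float, p_direct: float, alpha: float) -> str:
    if p_indirect >= alpha:
        return "no_mediation"
    return "partial" if p_direct < alpha else "full"


def bootstrap_indirect_ci(
    design: MediationDesign,
    data: pd.DataFrame,
    n_boot: int = 10_000,
    seed: int = 0,
    level: float = 0.95,
) -> tuple[float, float]:
    """Bias-corrected percentile bootstrap CI for the indirect effect.

    Cases are resampled with replacement and the full model refitted; the
    BC interval shifts the percentile endpoints by the median-bias
    correction z₀ = Φ⁻¹(fraction of bootstrap estimates below the point
    estimate).  Degenerate resamples (constant columns) are skipped.
    """
    if n_boot < 1000:
        raise ValueError("n_boot must be ≥ 1000")
    cols = [design.exposure, design.mediator, design.outcome]
    if design.covariate and design.smoking_as_covariate:
        cols.append(design.covariate)
    frame = data[cols].dropna()
    n = len(frame)
    mat = frame.to_numpy(dtype=float)
    point = fit_mediation(design, frame).indirect

    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    kept = 0
    skipped = 0
    while kept < n_boot:
        take = rng.integers(0, n, size=n)
        sub = mat[take]
        if (sub.std(axis=0, ddof=1) == 0).any():
            skipped += 1
            if skipped > 100 * n_boot:
                raise RuntimeError("too many degenerate bootstrap resamples")
            continue
        arr = (sub - sub.mean(axis=0)) / sub.std(axis=0, ddof=1) \
            if design.standardize else sub
        x, m, y = arr[:, 0], arr[:, 1], arr[:, 2]
        cov = arr[:, 3] if arr.shape[1] > 3 else None
        (a, b, _), _, _ = _paths(x, m, y, cov)
        boots[kept] = a * b
        kept += 1
    if skipped:
        warnings.warn(f"{skipped} degenerate resamples skipped", stacklevel=2)

    prop = np.clip((boots < point).mean(), 1.0 / (n_boot + 1), 1 - 1.0 / (n_boot + 1))
    lo_q, hi_q = _bc_quantiles(prop, level)
    return (float(np.quantile(boots, lo_q)), float(np.quantile(boots, hi_q)))


def _bc_quantiles(prop_below: float, level: float = 0.95) -> tuple[float, float]:
    """Bias-corrected percentile positions.

    With the bootstrap median at the point estimate (``prop_below`` = 0.5)
    the correction vanishes and the plain percentile positions return.
    """
    z0 = stats.norm.ppf(prop_below)
    zc = stats.norm.ppf(1.0 - (1.0 - level) / 2.0)
    return float(stats.norm.cdf(2 * z0 - zc)), float(stats.norm.cdf(2 * z0 + zc))


class MediationModel(BaseEstimator):
    """Single-mediator path model as an sklearn-style estimator.

    ``fit(data)`` consumes a DataFrame with the design's columns and
    exposes the fitted paths as ``result_`` plus convenience attributes
    ``a_``, ``b_``, ``c_prime_``, ``indirect_``, ``total_``, ``boot_ci_``.
    """

    def __init__(self, design: MediationDesign | None = None,
                 n_boot: int = 0, seed: int = 0):
        self.design = design
        self.n_boot = n_boot
        self.seed = seed

    def fit(self, data: pd.DataFrame, y=None):
        design = self.design or MediationDesign()
        res = fit_mediation(design, data)
        if self.n_boot:
            res.boot_ci = bootstrap_indirect_ci(design, data, self.n_boot, self.seed)
            res.n_boot = self.n_boot
        self.result_ = res
        self.a_, self.b_, self.c_prime_ = res.a, res.b, res.c_prime
        self.indirect_, self.total_ = res.indirect, res.total
        self.boot_ci_ = res.boot_ci
        return self


def run_mediation_battery(
    factor_scores: pd.DataFrame,
    data: pd.DataFrame,
    outcomes: tuple[str, ...] = OUTCOMES,
    exposure: str = "aa_per_day",
    covariate: str | None = "cigarettes_per_day",
    n_boot: int = 0,
    seed: int = 0,
) -> pd.DataFrame:
    """Single-factor models for every factor × outcome, plus a joint model
    with all factors as simultaneous mediators per outcome.

    In the joint model the outcome equation includes every factor score
    (their residual association is left free, the regression analogue of
    residually correlated mediators); each specific indirect is aᵢ·bᵢ.
    Signs follow the ΔCT convention: a higher factor score means lower
    expression.
    """
    merged = data.join(factor_scores, how="inner")
    rows = []
    for outcome in outcomes:
        for factor in factor_scores.columns:
            design = MediationDesign(exposure=exposure, mediator=factor,
                                     outcome=outcome, covariate=covariate)
            try:
                res = fit_mediation(design, merged)
            except ValueError:
                continue
            if n_boot:
                res.boot_ci = bootstrap_indirect_ci(design, merged, n_boot, seed)
                res.n_boot = n_boot
            rows.append({
                "model": "single", "outcome": outcome, "factor": factor,
                "a": res.a, "b": res.b, "c_prime": res.c_prime,
                "indirect": res.indirect, "total": res.total,
                "z": res.z, "p": res.p, "boot_low": res.boot_ci[0] if res.boot_ci else np.nan,
                "boot_high": res.boot_ci[1] if res.boot_ci else np.nan,
                "classification": _classify(res.p, res.p_c_prime, 0.05),
                "n": res.n,
            })
        joint = _joint_model(merged, exposure, list(factor_scores.columns), outcome)
        rows.extend(joint)
    return pd.DataFrame(rows)


def _joint_model(data: pd.DataFrame, exposure: str, factors: list[str],
                 outcome: str) -> list[dict]:
    cols = [exposure, *factors, outcome]
    frame = data[cols].dropna()
    if len(frame) < 10:
        return []
    arr = {c: _zscore(frame[c].to_numpy(dtype=float)) for c in cols}
    x = arr[exposure]
    M = np.column_stack([arr[f] for f in factors])
    y = arr[outcome]
    beta_y, se_y, p_y = _ols(y, np.column_stack([x, M]))
    out = []
    for i, f in enumerate(factors):
        a, se_a, p_a = _ols(arr[f], x[:, None])
        b, se_b = beta_y[1 + i], se_y[1 + i]
        ind = a[0] * b
        se_ind = np.sqrt(a[0] ** 2 * se_b**2 + b**2 * se_a[0] ** 2)
        z = ind / se_ind if se_ind else np.nan
        p = 2 * stats.norm.sf(abs(z)) if np.isfinite(z) else 1.0
        out.append({
            "model": "joint", "outcome": outcome, "factor": f,
            "a": float(a[0]), "b": float(b), "c_prime": float(beta_y[0]),
            "indirect": float(ind), "total": np.nan, "z": float(z),
            "p": float(p), "boot_low": np.nan, "boot_high": np.nan,
            "classification": _classify(p, p_y[0], 0.05), "n": len(frame),
        })
    return out
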