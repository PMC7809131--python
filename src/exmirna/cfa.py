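"""Confirmatory factor analysis by maximum likelihood.

Fits unidimensional, correlated-k-factor, and bifactor measurement models
to a sample covariance matrix by minimizing the normal-theory ML
discrepancy

    F(θ) = log|Σ(θ)| + tr(S Σ(θ)⁻¹) − log|S| − p,

with Σ(θ) = Λ Φ Λᵀ + Ψ.  Identification fixes factor variances to 1 (all
loadings free); in the bifactor model the general factor is orthogonal to
the mutually orthogonal specific factors.  The omnibus statistic is
χ² = (n−1)·F_min; descriptive fit (CFI, TLI, RMSEA with noncentral-χ² CI,
SRMR), information criteria, nested Δχ² tests, Bartlett's multiplicative
small-sample correction, and the omega / maximal-reliability-H internal
consistency coefficients are all computed from the fitted solution.

Estimation is quasi-Newton (L-BFGS) with the analytic gradient

    ∂F/∂Σ = Σ⁻¹(Σ − S)Σ⁻¹,

chained to loadings, factor covariances and residual (co)variances.
Standard errors come from the inverse observed information, approximated
by central finite differences of the analytic gradient.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy import optimize, stats
from sklearn.base import BaseEstimator

_HEYWOOD_TOL = -1e-6


@dataclass
class CfaSpec:
    """Measurement-model specification.

    ``factors`` maps factor name → item list; every item belongs to exactly
    one specific factor.  ``bifactor=True`` adds a general factor loading
    on all items, orthogonal to the (then mutually orthogonal) specific
    factors.  ``residual_covariances`` lists item pairs whose residuals are
    allowed to covary.
    """

    factors: dict[str, list[str]]
    residual_covariances: list[tuple[str, str]] = field(default_factory=list)
    bifactor: bool = False
    general_name: str = "G"

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for f, items in self.factors.items():
            for it in items:
                if it in seen:
                    raise ValueError(f"item {it} assigned to more than one factor")
                seen.add(it)
        for a, b in self.residual_covariances:
            if a == b:
                raise ValueError("residual covariance pairs must be distinct items")
            if a not in seen or b not in seen:
                raise ValueError(f"residual pair ({a},{b}) not among items")

    @property
    def items(self) -> list[str]:
        out: list[str] = []
        for its in self.factors.values():
            out.extend(its)
        return out

    @property
    def factor_names(self) -> list[str]:
        names = list(self.factors)
        if self.bifactor:
            names.append(self.general_name)
        return names

    @property
    def k(self) -> int:
        return len(self.factor_names)

    @property
    def k_specific(self) -> int:
        return len(self.factors)

    def n_free_parameters(self) -> int:
        p = len(self.items)
        loads = p * (2 if self.bifactor else 1)
        phis = 0 if self.bifactor else self.k * (self.k - 1) // 2
        return loads + phis + p + len(self.residual_covariances)

    def degrees_of_freedom(self) -> int:
        p = len(self.items)
        return p * (p + 1) // 2 - self.n_free_parameters()

    @classmethod
    def unidimensional(cls, items: list[str], name: str = "F1",
                       residual_covariances=()) -> "CfaSpec":
        return cls({name: list(items)}, list(residual_covariances))

    def to_yaml(self, path) -> None:
        payload = {
            "factors": {f: list(v) for f, v in self.factors.items()},
            "residual_covariances": [list(p) for p in self.residual_covariances],
            "bifactor": self.bifactor,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "CfaSpec":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        return cls(
            factors=payload["factors"],
            residual_covariances=[tuple(p) for p in payload.get("residual_covariances", [])],
            bifactor=bool(payload.get("bifactor", False)),
        )


# ---------------------------------------------------------------------------
# Parameterization

class _Parameterization:
    """Index bookkeeping between θ and (Λ, Φ, Ψ)."""

    def __init__(self, spec: CfaSpec):
        self.spec = spec
        self.items = spec.items
        self.p = len(self.items)
        self.k = spec.k
        item_pos = {it: i for i, it in enumerate(self.items)}
        self.load_entries: list[tuple[int, int]] = []
        names = list(spec.factors)
        for q, f in enumerate(names):
            for it in spec.factors[f]:
                self.load_entries.append((item_pos[it], q))
        if spec.bifactor:
            g = len(names)
            for it in self.items:
                self.load_entries.append((item_pos[it], g))
        self.phi_entries: list[tuple[int, int]] = []
        if not spec.bifactor:
            for q in range(self.k):
                for r in range(q + 1, self.k):
                    self.phi_entries.append((q, r))
        self.rescov_entries = [
            (item_pos[a], item_pos[b]) for a, b in spec.residual_covariances
        ]
        self.n_load = len(self.load_entries)
        self.n_phi = len(self.phi_entries)
        self.n_params = self.n_load + self.n_phi + self.p + len(self.rescov_entries)

    def unpack(self, theta: np.ndarray):
        L = np.zeros((self.p, self.k))
        for v, (i, q) in zip(theta[: self.n_load], self.load_entries):
            L[i, q] = v
        Phi = np.eye(self.k)
        off = theta[self.n_load : self.n_load + self.n_phi]
        for v, (q, r) in zip(off, self.phi_entries):
            Phi[q, r] = Phi[r, q] = v
        psi = theta[self.n_load + self.n_phi : self.n_load + self.n_phi + self.p]
        Psi = np.diag(psi.copy())
        for v, (i, j) in zip(theta[self.n_load + self.n_phi + self.p :],
                             self.rescov_entries):
            Psi[i, j] = Psi[j, i] = v
        return L, Phi, Psi

    def names(self) -> list[str]:
        fnames = self.spec.factor_names
        out = [f"lambda[{self.items[i]}~{fnames[q]}]" for i, q in self.load_entries]
        out += [f"phi[{fnames[q]}~{fnames[r]}]" for q, r in self.phi_entries]
        out += [f"psi[{self.items[i]}]" for i in range(self.p)]
        out += [f"theta[{self.items[i]}~{self.items[j]}]" for i, j in self.rescov_entries]
        return out


def ml_discrepancy(S: np.ndarray, Sigma: np.ndarray) -> float:
    """Normal-theory ML discrepancy between a sample covariance S and a
    model-implied covariance Σ."""
    p = S.shape[0]
    sign, logdet_sigma = np.linalg.slogdet(Sigma)
    if sign <= 0:
        return np.inf
    _, logdet_s = np.linalg.slogdet(S)
    return float(logdet_sigma + np.trace(S @ np.linalg.inv(Sigma)) - logdet_s - p)


def _objective(theta, par: _Parameterization, S: np.ndarray, logdet_s: float):
    L, Phi, Psi = par.unpack(theta)
    Sigma = L @ Phi @ L.T + Psi
    try:
        c = np.linalg.cholesky(Sigma)
    except np.linalg.LinAlgError:
        # outside the PD region: finite barrier growing with infeasibility so
        # the line search can back off (an inf return stalls it)
        eigmin = float(np.linalg.eigvalsh(Sigma)[0])
        return 1e8 * (1.0 - eigmin), np.zeros_like(theta)
    logdet = 2.0 * np.log(np.diag(c)).sum()
    Sinv = np.linalg.inv(Sigma)
    F = logdet + np.trace(S @ Sinv) - logdet_s - par.p
    G = Sinv @ (Sigma - S) @ Sinv
    grad = np.empty_like(theta)
    GLP = G @ L @ Phi
    for idx, (i, q) in enumerate(par.load_entries):
        grad[idx] = 2.0 * GLP[i, q]
    LGL = L.T @ G @ L
    for idx, (q, r) in enumerate(par.phi_entries):
        grad[par.n_load + idx] = 2.0 * LGL[q, r]
    base = par.n_load + par.n_phi
    for i in range(par.p):
        grad[base + i] = G[i, i]
    for idx, (i, j) in enumerate(par.rescov_entries):
        grad[base + par.p + idx] = 2.0 * G[i, j]
    return F, grad


def _start_values(par: _Parameterization, S: np.ndarray) -> np.ndarray:
    """Principal-axis-flavoured starting values.

    Each specific factor starts at the scaled first eigenvector of its
    item-block covariance; residual variances start at half the observed
    variances (bifactor: general from the full-matrix first component).
    """
    theta = np.zeros(par.n_params)
    diag = np.diag(S)
    fnames = list(par.spec.factors)
    item_pos = {it: i for i, it in enumerate(par.items)}
    start_load = {}
    for f in fnames:
        idx = [item_pos[it] for it in par.spec.factors[f]]
        block = S[np.ix_(idx, idx)]
        w, v = np.linalg.eigh(block)
        lead = v[:, -1] * np.sqrt(max(w[-1], 1e-6))
        if lead.sum() < 0:
            lead = -lead
        for i, val in zip(idx, lead):
            start_load[(i, fnames.index(f))] = 0.8 * val
    if par.spec.bifactor:
        w, v = np.linalg.eigh(S)
        lead = v[:, -1] * np.sqrt(max(w[-1], 1e-6))
        if lead.sum() < 0:
            lead = -lead
        g = len(fnames)
        for i in range(par.p):
            start_load[(i, g)] = 0.6 * lead[i]
            for q in range(g):
                if (i, q) in start_load:
                    start_load[(i, q)] *= 0.6
    for idx, entry in enumerate(par.load_entries):
        theta[idx] = start_load.get(entry, 0.3)
    theta[par.n_load : par.n_load + par.n_phi] = 0.3
    base = par.n_load + par.n_phi
    theta[base : base + par.p] = 0.5 * diag
    return theta


def _hessian(fun, theta: np.ndarray, rel_step: float = 1e-5) -> np.ndarray:
    """Central finite differences of the analytic gradient."""
    q = theta.size
    H = np.empty((q, q))
    for j in range(q):
        h = rel_step * max(1.0, abs(theta[j]))
        tp, tm = theta.copy(), theta.copy()
        tp[j] += h
        tm[j] -= h
        _, gp = fun(tp)
        _, gm = fun(tm)
        H[:, j] = (gp - gm) / (2.0 * h)
    return (H + H.T) / 2.0


# ---------------------------------------------------------------------------
# Fit statistics

def baseline_chi2(S: np.ndarray, n_obs: int) -> tuple[float, int]:
    """Independence-model (diagonal Σ) chi-square and df."""
    p = S.shape[0]
    _, logdet_s = np.linalg.slogdet(S)
    F = float(np.log(np.diag(S)).sum() - logdet_s)
    return (n_obs - 1) * F, p * (p - 1) // 2


def fit_indices(
    chi2: float,
    df: int,
    chi2_baseline: float,
    df_baseline: int,
    n_obs: int,
    ci_level: float = 0.90,
) -> dict:
    """CFI, TLI, RMSEA (with noncentral-χ² CI) from chi-square statistics.

    df = 0 models are perfect by convention (CFI = 1, RMSEA = 0).
    """
    if df == 0:
        return {"cfi": 1.0, "tli": 1.0, "rmsea": 0.0, "rmsea_ci": (0.0, 0.0)}
    num = max(chi2 - df, 0.0)
    denom = max(chi2_baseline - df_baseline, chi2 - df, 0.0)
    cfi = 1.0 - (num / denom if denom > 0 else 0.0)
    rb = chi2_baseline / df_baseline
    rm = chi2 / df
    tli = (rb - rm) / (rb - 1.0) if rb != 1.0 else 1.0
    rmsea = float(np.sqrt(num / (df * (n_obs - 1))))
    ci = _rmsea_ci(chi2, df, n_obs, ci_level)
    return {"cfi": float(min(cfi, 1.0)), "tli": float(min(tli, 1.0)),
            "rmsea": rmsea, "rmsea_ci": ci}


def _rmsea_ci(chi2: float, df: int, n_obs: int, level: float) -> tuple[float, float]:
    """Invert the noncentral χ² to a (lower, upper) RMSEA interval."""
    tail = (1.0 - level) / 2.0

    def solve(target_cdf):
        if stats.chi2.cdf(chi2, df) < target_cdf:
            return 0.0
        lo, hi = 0.0, max(chi2 * 2.0, 10.0)
        while stats.ncx2.cdf(chi2, df, hi) > target_cdf and hi < 1e7:
            hi *= 2.0
        return optimize.brentq(
            lambda nc: stats.ncx2.cdf(chi2, df, nc) - target_cdf, lo, hi, xtol=1e-8
        )

    nc_lo = solve(1.0 - tail)
    nc_hi = solve(tail)
    scale = df * (n_obs - 1)
    return (float(np.sqrt(max(nc_lo, 0.0) / scale)), float(np.sqrt(max(nc_hi, 0.0) / scale)))


def srmr(S: np.ndarray, Sigma: np.ndarray) -> float:
    """Standardized root-mean-square residual over the lower triangle."""
    d = np.sqrt(np.diag(S))
    std_resid = (S - Sigma) / np.outer(d, d)
    il = np.tril_indices(S.shape[0])
    return float(np.sqrt((std_resid[il] ** 2).mean()))


def information_criteria(minus2ll: float, n_params: int, n_obs: int) -> dict:
    """AIC, BIC and the sample-size-adjusted BIC (penalty ln((n+2)/24))."""
    return {
        "aic": minus2ll + 2.0 * n_params,
        "bic": minus2ll + n_params * np.log(n_obs),
        "sabic": minus2ll + n_params * np.log((n_obs + 2.0) / 24.0),
    }


def chi2_difference(chi2_nested: float, df_nested: int,
                    chi2_general: float, df_general: int) -> dict:
    """Likelihood-ratio test between nested models.

    The nested (more constrained) model must have more df; a negative
    difference is reported with p = 1 and a warning.
    """
    if df_nested <= df_general:
        raise ValueError("nested model must have more degrees of freedom")
    delta = chi2_nested - chi2_general
    ddf = df_nested - df_general
    if delta < 0:
        warnings.warn("negative chi-square difference; p set to 1", stacklevel=2)
        return {"delta_chi2": float(delta), "delta_df": ddf, "p": 1.0}
    return {"delta_chi2": float(delta), "delta_df": ddf,
            "p": float(stats.chi2.sf(delta, ddf))}


def bartlett_factor(k: int, p: int, n: int) -> float:
    """Bartlett's corrective factor 1 − (4k + 2p + 5)/(6n).

    ``k`` latent variables, ``p`` observed variables, ``n`` the sample size
    plus one (the convention used with this correction).
    """
    factor = 1.0 - (4.0 * k + 2.0 * p + 5.0) / (6.0 * n)
    if factor <= 0:
        raise ValueError("sample too small for the Bartlett correction")
    return factor


def bartlett_correction(chi2: float, k: int, p: int, n: int) -> float:
    """Multiplicatively corrected chi-square (see :func:`bartlett_factor`)."""
    return chi2 * bartlett_factor(k, p, n)


# ---------------------------------------------------------------------------
# Reliability

def omega_total(loadings, residual_variances, residual_covariances=()) -> float:
    """Composite reliability ω = (Σλ)² / ((Σλ)² + ΣVar(ε) + 2·Σ cov(ε)).

    The residual-covariance term adjusts for collinearity in the residuals;
    positive residual covariance strictly lowers ω.
    """
    lam = np.asarray(loadings, dtype=float)
    psi = np.asarray(residual_variances, dtype=float)
    rc = 2.0 * float(np.sum(residual_covariances))
    num = lam.sum() ** 2
    denom = num + psi.sum() + rc
    if denom <= 0:
        raise ValueError("non-positive total variance in omega")
    return float(num / denom)


def maximal_reliability_h(std_loadings) -> float:
    """Maximal reliability H = Σ(l²/(1−l²)) / (1 + Σ(l²/(1−l²))).

    Invariant to loading signs (negative loadings contribute through l²)
    and never below the reliability l² of the best single item.
    """
    l = np.asarray(std_loadings, dtype=float)
    if np.any(np.abs(l) >= 1):
        raise ValueError("standardized loadings must satisfy |l| < 1")
    s = float(np.sum(l**2 / (1.0 - l**2)))
    return s / (1.0 + s)


def factor_mean_scores(delta_ct: pd.DataFrame, spec: CfaSpec) -> pd.DataFrame:
    """Per-sample factor scores as the unweighted mean ΔCT of each
    factor's items (lower score = higher expression)."""
    missing = [it for it in spec.items if it not in delta_ct.index]
    if missing:
        raise ValueError(f"items missing from expression matrix: {missing}")
    scores = {
        f: delta_ct.loc[items].mean(axis=0) for f, items in spec.factors.items()
    }
    return pd.DataFrame(scores)


# ---------------------------------------------------------------------------
# Estimator

@dataclass
class CfaFit:
    """Flat record of a fitted model (JSON-friendly view of a CFAModel)."""

    loadings: pd.DataFrame
    std_loadings: pd.DataFrame
    residual_variances: pd.Series
    residual_covariances: dict
    factor_cov: pd.DataFrame
    chi2: float
    df: int
    p_value: float
    chi2_baseline: float
    df_baseline: int
    cfi: float
    tli: float
    rmsea: float
    rmsea_ci: tuple
    srmr: float
    minus2ll: float
    aic: float
    bic: float
    sabic: float
    converged: bool
    heywood: bool
    n_obs: int
    se: dict
    estimates: dict


class CFAModel(BaseEstimator):
    """Confirmatory factor analysis estimator.

    Parameters
    ----------
    spec : CfaSpec
        Item → factor assignment, residual covariance pairs, bifactor flag.
    max_ridge_restarts : int
        Restarts with inflated residual starting values when the search
        leaves the positive-definite region.
    tol : float
        Convergence tolerance on the discrepancy-function change.
    compute_se : bool
        Whether to invert the observed information for standard errors.

    After ``fit(X)`` (X: samples × items, complete data) the fitted
    attributes carry the solution: ``loadings_``, ``std_loadings_``,
    ``factor_cov_``, ``residual_variances_``, ``chi2_``, ``df_``,
    ``cfi_``, ``tli_``, ``rmsea_``, ``srmr_``, ``aic_``, ``bic_``,
    ``sabic_``, ``converged_``, ``se_``.
    """

    def __init__(self, spec: CfaSpec, max_ridge_restarts: int = 5,
                 tol: float = 1e-8, compute_se: bool = True):
        self.spec = spec
        self.max_ridge_restarts = max_ridge_restarts
        self.tol = tol
        self.compute_se = compute_se

    # -- fitting -----------------------------------------------------------
    def fit(self, X, y=None):
        items = self.spec.items
        if isinstance(X, pd.DataFrame):
            missing = [it for it in items if it not in X.columns]
            if missing:
                raise ValueError(f"data lacks items: {missing}")
            X = X[items].to_numpy(dtype=float)
        else:
            X = np.asarray(X, dtype=float)
            if X.shape[1] != len(items):
                raise ValueError("column count does not match spec items")
        if np.isnan(X).any():
            raise ValueError("complete data required")
        n = X.shape[0]
        S = np.cov(X, rowvar=False, ddof=1)
        self.fit_from_cov(S, n_obs=n)
        return self

    def fit_from_cov(self, S: np.ndarray, n_obs: int):
        """Fit directly from a sample covariance matrix."""
        par = _Parameterization(self.spec)
        if S.shape != (par.p, par.p):
            raise ValueError("covariance dimension does not match spec")
        _, logdet_s = np.linalg.slogdet(S)
        fun = lambda t: _objective(t, par, S, logdet_s)

        theta0 = _start_values(par, S)
        # with unit factor variances the factor covariances are correlations
        bounds = [(None, None)] * par.n_load
        bounds += [(-0.999, 0.999)] * par.n_phi
        bounds += [(None, None)] * (par.p + len(par.rescov_entries))
        best = None
        for attempt in range(self.max_ridge_restarts + 1):
            res = optimize.minimize(
                fun, theta0, jac=True, method="L-BFGS-B", bounds=bounds,
                options={"maxiter": 1000, "ftol": self.tol, "gtol": 1e-7},
            )
            if np.isfinite(res.fun) and (best is None or res.fun < best.fun):
                best = res
            if np.isfinite(res.fun) and res.fun < 1e8 and (
                res.success or np.max(np.abs(res.jac)) < 1e-4
            ):
                break
            # ridge restart: inflate residuals, shrink loadings
            theta0 = _start_values(par, S)
            base = par.n_load + par.n_phi
            theta0[:par.n_load] *= 0.5 ** (attempt + 1)
            theta0[base : base + par.p] = np.diag(S) * (0.7 + 0.1 * attempt)
        res = best
        theta = res.x
        L, Phi, Psi = par.unpack(theta)
        Sigma = L @ Phi @ L.T + Psi
        F_min = max(float(res.fun), 0.0)

        psi_diag = np.diag(Psi)
        heywood = bool((psi_diag < _HEYWOOD_TOL).any())
        converged = bool(
            np.isfinite(res.fun)
            and (res.success or np.max(np.abs(res.jac)) < 1e-4)
            and not heywood
        )

        p = par.p
        chi2 = (n_obs - 1) * F_min
        df = self.spec.degrees_of_freedom()
        if df < 0:
            raise ValueError("negative degrees of freedom: model not identified")
        chi2_b, df_b = baseline_chi2(S, n_obs)
        idx = fit_indices(chi2, df, chi2_b, df_b, n_obs)
        # Gaussian covariance log-likelihood (n−1 convention, matching χ²)
        _, logdet_s = np.linalg.slogdet(S)
        minus2ll = (n_obs - 1) * (F_min + logdet_s + p + p * np.log(2 * np.pi))
        ic = information_criteria(minus2ll, par.n_params, n_obs)

        se = np.full(par.n_params, np.nan)
        if self.compute_se and converged:
            H = _hessian(fun, theta)
            try:
                cov = 2.0 / (n_obs - 1) * np.linalg.inv(H)
                d = np.diag(cov)
                se = np.sqrt(np.where(d > 0, d, np.nan))
            except np.linalg.LinAlgError:
                warnings.warn("singular information matrix; SEs unavailable",
                              stacklevel=2)

        fnames = self.spec.factor_names
        implied_sd = np.sqrt(np.diag(Sigma))
        self.loadings_ = pd.DataFrame(L, index=par.items, columns=fnames)
        self.std_loadings_ = self.loadings_.div(implied_sd, axis=0)
        self.residual_variances_ = pd.Series(psi_diag, index=par.items)
        self.residual_covariances_ = {
            (par.items[i], par.items[j]): float(Psi[i, j])
            for i, j in par.rescov_entries
        }
        self.factor_cov_ = pd.DataFrame(Phi, index=fnames, columns=fnames)
        self.implied_cov_ = pd.DataFrame(Sigma, index=par.items, columns=par.items)
        self.sample_cov_ = pd.DataFrame(S, index=par.items, columns=par.items)
        self.discrepancy_ = F_min
        self.chi2_ = float(chi2)
        self.df_ = int(df)
        self.p_value_ = float(stats.chi2.sf(chi2, df)) if df > 0 else 1.0
        self.chi2_baseline_ = float(chi2_b)
        self.df_baseline_ = int(df_b)
        self.cfi_ = idx["cfi"]
        self.tli_ = idx["tli"]
        self.rmsea_ = idx["rmsea"]
        self.rmsea_ci_ = idx["rmsea_ci"]
        self.srmr_ = srmr(S, Sigma)
        self.minus2ll_ = float(minus2ll)
        self.aic_ = float(ic["aic"])
        self.bic_ = float(ic["bic"])
        self.sabic_ = float(ic["sabic"])
        self.converged_ = converged
        self.heywood_ = heywood
        self.n_obs_ = int(n_obs)
        self.n_params_ = par.n_params
        self.se_ = dict(zip(par.names(), se))
        self.estimates_ = dict(zip(par.names(), theta))
        return self

    # -- small-sample correction ------------------------------------------
    def bartlett_corrected(self, extra_n: int = 1) -> dict:
        """Corrected omnibus test and recomputed descriptive indices.

        Uses n = fitted sample size + ``extra_n`` in the corrective factor
        (the +1 convention by default).
        """
        factor = bartlett_factor(self.spec.k, len(self.spec.items),
                                 self.n_obs_ + extra_n)
        chi2_c = self.chi2_ * factor
        idx = fit_indices(chi2_c, self.df_, self.chi2_baseline_ * factor,
                          self.df_baseline_, self.n_obs_)
        return {
            "factor": factor,
            "chi2": chi2_c,
            "p_value": float(stats.chi2.sf(chi2_c, self.df_)) if self.df_ else 1.0,
            **idx,
        }

    # -- reliability and scores -------------------------------------------
    def omega(self, factor: str) -> float:
        items = self.spec.factors[factor]
        lam = self.loadings_.loc[items, factor].to_numpy()
        psi = self.residual_variances_.loc[items].to_numpy()
        rc = [v for (a, b), v in self.residual_covariances_.items()
              if a in items and b in items]
        return omega_total(lam, psi, rc)

    def reliability_h(self, factor: str) -> float:
        items = self.spec.factors[factor]
        l = self.std_loadings_.loc[items, factor].to_numpy()
        return maximal_reliability_h(np.clip(l, -0.999999, 0.999999))

    def factor_scores(self, delta_ct: pd.DataFrame) -> pd.DataFrame:
        return factor_mean_scores(delta_ct, self.spec)

    def to_fit(self) -> CfaFit:
        return CfaFit(
            loadings=self.loadings_, std_loadings=self.std_loadings_,
            residual_variances=self.residual_variances_,
            residual_covariances=self.residual_covariances_,
            factor_cov=self.factor_cov_, chi2=self.chi2_, df=self.df_,
            p_value=self.p_value_, chi2_baseline=self.chi2_baseline_,
            df_baseline=self.df_baseline_, cfi=self.cfi_, tli=self.tli_,
            rmsea=self.rmsea_, rmsea_ci=self.rmsea_ci_, srmr=self.srmr_,
            minus2ll=self.minus2ll_, aic=self.aic_, bic=self.bic_,
            sabic=self.sabic_, converged=self.converged_, heywood=self.heywood_,
            n_obs=self.n_obs_, se=self.se_, estimates=self.estimates_,
        )


def fit_ml(spec: CfaSpec, data, n_obs: int | None = None) -> CfaFit:
    """Functional wrapper: fit ``spec`` to raw data (samples × items) or,
    when ``n_obs`` is given, to a covariance matrix."""
    model = CFAModel(spec)
    if n_obs is not None:
        model.fit_from_cov(np.asarray(data, dtype=float), n_obs=n_obs)
    else:
        model.fit(data)
    return model.to_fit()


def model_comparison_table(fits: dict[str, CfaFit],
                           order: list[str] | None = None) -> pd.DataFrame:
    """Model-comparison table (χ², df, p, Δχ² against the previous row,
    AIC/BIC/SABIC), in the style used for competing measurement models."""
    names = order or list(fits)
    rows = []
    prev = None
    for name in names:
        f = fits[name]
        delta = ddf = pd_ = np.nan
        if prev is not None and f.df < prev.df:
            d = chi2_difference(prev.chi2, prev.df, f.chi2, f.df)
            delta, ddf, pd_ = d["delta_chi2"], d["delta_df"], d["p"]
        rows.append({
            "model": name, "chi2": f.chi2, "df": f.df, "p": f.p_value,
            "delta_chi2": delta, "delta_df": ddf, "delta_p": pd_,
            "aic": f.aic, "bic": f.bic, "sabic": f.sabic,
        })
        prev = f
    return pd.DataFrame(rows).set_index("model")
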