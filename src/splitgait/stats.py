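"""Mixed-effects group comparison of adaptation outcomes.

For each response (steps to plateau, plateau magnitude, aftereffect
magnitude) the model is

    response ~ group * gait_parameter + (1 | subject)

with age group and gait parameter as fixed effects and a per-subject
random intercept, fitted by REML (statsmodels ``MixedLM``).  Fixed
effects are tested with type-III F statistics using Satterthwaite
denominator degrees of freedom; posthoc inference computes least-squares
means per group x parameter with 95% confidence intervals, and group
differences are judged by CI non-overlap.

Satterthwaite details: for a contrast ``l`` the variance
``g(theta) = l' C(theta) l`` (``C`` the fixed-effects covariance,
``theta`` the residual and subject variance components) is differentiated
numerically; ``df = 2 g^2 / (grad' A grad)`` with ``A`` the inverse
observed information of the REML likelihood.  Multi-row contrasts use
the eigen-decomposition combination of the per-direction dfs
(the Fai-Cornelius construction used by lmerTest).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.optimize import minimize
from statsmodels.regression.mixed_linear_model import MixedLM

__all__ = [
    "LmmResult",
    "fit_lmm",
    "anova_fixed_effects",
    "posthoc_lsmeans",
    "ci_nonoverlap",
]

_DF_MAX = 1e6


class _RandomInterceptREML:
    """Closed-form REML quantities for the one-random-intercept model."""

    def __init__(self, X, y, subjects):
        self.X = np.asarray(X, dtype=float)
        self.y = np.asarray(y, dtype=float)
        codes, _ = pd.factorize(np.asarray(subjects))
        self.n_i = np.bincount(codes)
        k = len(self.n_i)
        p = self.X.shape[1]
        self.S = np.zeros((k, p))  # per-subject column sums of X
        np.add.at(self.S, codes, self.X)
        self.sy = np.bincount(codes, weights=self.y)
        self.XtX = self.X.T @ self.X
        self.Xty = self.X.T @ self.y
        self.yty = float(self.y @ self.y)

    def _weights(self, theta):
        s2e, s2b = theta
        return s2b / (s2e + self.n_i * s2b)

    def cov_beta(self, theta):
        s2e, _ = theta
        w = self._weights(theta)
        xtvx = (self.XtX - (self.S.T * w) @ self.S) / s2e
        return np.linalg.inv(xtvx)

    def beta_hat(self, theta):
        s2e, _ = theta
        w = self._weights(theta)
        xtvy = (self.Xty - self.S.T @ (w * self.sy)) / s2e
        return self.cov_beta(theta) @ xtvy

    def reml_loglik(self, theta):
        s2e, s2b = theta
        if s2e <= 0 or s2b < 0:
            return -np.inf
        w = self._weights(theta)
        xtvx = (self.XtX - (self.S.T * w) @ self.S) / s2e
        sign, logdet_xtvx = np.linalg.slogdet(xtvx)
        if sign <= 0:
            return -np.inf
        beta = np.linalg.solve(xtvx, (self.Xty - self.S.T @ (w * self.sy)) / s2e)
        r = self.y - self.X @ beta
        sr = self.sy - self.S @ beta
        quad = (float(r @ r) - float((w * sr) @ sr)) / s2e
        logdet_v = float(np.sum((self.n_i - 1) * np.log(s2e) + np.log(s2e + self.n_i * s2b)))
        return -0.5 * (logdet_v + logdet_xtvx + quad)


def _sum_code(levels, values):
    """Sum-to-zero coding: one column per non-reference level."""
    levels = list(levels)
    cols = np.zeros((len(values), len(levels) - 1))
    for j, lev in enumerate(levels[:-1]):
        cols[:, j] = np.where(values == lev, 1.0, np.where(values == levels[-1], -1.0, 0.0))
    return cols


@dataclass
class LmmResult:
    """Fitted mixed model with the pieces needed for downstream inference."""

    beta: np.ndarray
    cov_beta: np.ndarray
    theta: tuple  # (residual variance, subject-intercept variance)
    colnames: list
    group_levels: list
    param_levels: list
    reml: _RandomInterceptREML
    theta_cov: np.ndarray  # asymptotic covariance of theta
    converged: bool
    n_obs: int
    n_subjects: int
    degenerate: bool = False  # residual variance collapsed; OLS fallback

    @property
    def variance_components(self) -> dict:
        return {"residual": self.theta[0], "subject_intercept": self.theta[1]}


def fit_lmm(table: pd.DataFrame, response: str = "value") -> LmmResult:
    """Fit ``response ~ group * parameter + (1 | subject)`` by REML.

    ``table`` needs columns subject, group, parameter and the response.
    Requires two group levels with at least 2 subjects each and at least
    two parameter levels; raises ``ValueError`` otherwise (including the
    singular-design case).
    """
    for col in ("subject", "group", "parameter", response):
        if col not in table:
            raise ValueError(f"missing column {col!r}")
    tab = table.dropna(subset=[response]).copy()
    group_levels = sorted(tab["group"].unique())
    param_levels = sorted(tab["parameter"].unique())
    if len(group_levels) != 2:
        raise ValueError(f"need exactly 2 group levels, got {group_levels}")
    for g in group_levels:
        if tab.loc[tab["group"] == g, "subject"].nunique() < 2:
            raise ValueError(f"need >= 2 subjects in group {g!r}")
    if len(param_levels) < 2:
        raise ValueError("need >= 2 gait-parameter levels")

    g = np.where(tab["group"].to_numpy() == group_levels[0], 1.0, -1.0)
    P = _sum_code(param_levels, tab["parameter"].to_numpy())
    X = np.column_stack([np.ones(len(tab)), g, P, P * g[:, None]])
    colnames = (["intercept", "group"]
                + [f"param[{p}]" for p in param_levels[:-1]]
                + [f"group:param[{p}]" for p in param_levels[:-1]])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("singular design: some group x parameter cells are empty")

    y = tab[response].to_numpy(dtype=float)
    subjects = tab["subject"].to_numpy()
    reml = _RandomInterceptREML(X, y, subjects)
    model = MixedLM(y, X, groups=subjects)
    var_y = max(float(np.var(y)), 1e-12)
    start = (var_y / 2, var_y / 2)
    with np.errstate(all="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = model.fit(reml=True)
            if fit.converged:
                start = (float(fit.scale), max(float(np.asarray(fit.cov_re)[0, 0]), 0.0))
        except (np.linalg.LinAlgError, ValueError):
            pass
    # polish on the closed-form REML profile (log scale keeps s2e > 0 and
    # lets s2b approach its boundary); also rescues optimizer failures
    floor = 1e-10 * var_y

    def neg_ll(logtheta):
        return -reml.reml_loglik(np.exp(logtheta))

    opt = minimize(neg_ll, np.log(np.maximum(start, floor)),
                   method="Nelder-Mead",
                   options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 2000})
    theta = tuple(np.exp(opt.x))
    if theta[1] <= 2 * floor:
        theta = (theta[0], 0.0)

    degenerate = theta[0] < 1e-10 * var_y
    if degenerate:
        # (near) zero residual variance: GLS is numerically meaningless but
        # OLS is exact (estimates are the cell means, intervals collapse)
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        resid = y - X @ beta
        s2e = float(resid @ resid) / max(len(y) - X.shape[1], 1)
        theta = (s2e, theta[1])
        cov = np.linalg.inv(X.T @ X) * s2e
        theta_cov = np.zeros((2, 2))
    else:
        beta = reml.beta_hat(theta)
        cov = reml.cov_beta(theta)
        theta_cov = _observed_info_inv(reml, theta)
    return LmmResult(
        beta=beta,
        cov_beta=cov,
        theta=theta,
        colnames=colnames,
        group_levels=group_levels,
        param_levels=param_levels,
        reml=reml,
        theta_cov=theta_cov,
        converged=bool(opt.success),
        n_obs=len(y),
        n_subjects=tab["subject"].nunique(),
        degenerate=degenerate,
    )


def _observed_info_inv(reml, theta):
    """Inverse negative Hessian of the REML log-likelihood (2x2)."""
    theta = np.asarray(theta, dtype=float)
    h = np.maximum(np.abs(theta), 1e-8 * max(theta[0], 1e-12)) * 1e-4
    if theta[1] > 0:
        h[1] = min(h[1], theta[1] / 2)  # keep s2b - h inside the domain
    hess = np.empty((2, 2))
    # boundary evaluations may return -inf; NaN entries are caught below
    with np.errstate(invalid="ignore"):
        f0 = reml.reml_loglik(theta)
        for i in range(2):
            for j in range(i + 1):
                ei = np.eye(2)[i] * h[i]
                ej = np.eye(2)[j] * h[j]
                if i == j:
                    fp = reml.reml_loglik(theta + ei)
                    fm = reml.reml_loglik(theta - ei)
                    hess[i, i] = (fp - 2 * f0 + fm) / h[i] ** 2
                else:
                    fpp = reml.reml_loglik(theta + ei + ej)
                    fpm = reml.reml_loglik(theta + ei - ej)
                    fmp = reml.reml_loglik(theta - ei + ej)
                    fmm = reml.reml_loglik(theta - ei - ej)
                    hess[i, j] = hess[j, i] = (fpp - fpm - fmp + fmm) / (4 * h[i] * h[j])
    if not np.all(np.isfinite(hess)):
        return np.full((2, 2), np.nan)
    try:
        return np.linalg.inv(-hess)
    except np.linalg.LinAlgError:
        return np.linalg.pinv(-hess)


def _satterthwaite_df(result: LmmResult, ell: np.ndarray) -> float:
    """Satterthwaite df for a single contrast of the fixed effects."""
    if result.degenerate or result.theta[1] <= 0:
        # boundary/degenerate fit: inference reduces to OLS residual df
        return float(result.n_obs - len(result.beta))
    theta = np.asarray(result.theta, dtype=float)
    h = np.maximum(np.abs(theta), 1e-8) * 1e-4
    grad = np.empty(2)
    for i in range(2):
        ei = np.eye(2)[i] * h[i]
        gp = float(ell @ result.reml.cov_beta(theta + ei) @ ell)
        tm = theta - ei
        tm[1] = max(tm[1], 0.0)
        gm = float(ell @ result.reml.cov_beta(tm) @ ell)
        grad[i] = (gp - gm) / (h[i] + (theta[i] - tm[i]))
    g_val = float(ell @ result.cov_beta @ ell)
    denom = float(grad @ result.theta_cov @ grad)
    if not np.isfinite(denom) or denom <= 0:
        return _DF_MAX
    df = 2.0 * g_val**2 / denom
    return float(np.clip(df, 1.0, _DF_MAX))


def _ftest_satterthwaite(result: LmmResult, L: np.ndarray):
    """Type-III F test with multi-dimensional Satterthwaite df."""
    L = np.atleast_2d(L)
    q = L.shape[0]
    M = L @ result.cov_beta @ L.T
    vals, vecs = np.linalg.eigh(M)
    keep = vals > max(vals.max(), 0) * 1e-12
    vals, vecs = vals[keep], vecs[:, keep]
    Ltil = (vecs / np.sqrt(vals)).T @ L  # rows have unit variance at theta-hat
    t2 = (Ltil @ result.beta) ** 2
    F = float(t2.sum() / q)
    nus = np.array([_satterthwaite_df(result, row) for row in Ltil])
    ok = nus > 2
    if not np.any(ok):
        den_df = _DF_MAX
    else:
        E = float(np.sum(nus[ok] / (nus[ok] - 2)))
        den_df = 2 * E / (E - q) if E > q else _DF_MAX
    den_df = float(np.clip(den_df, 1.0, _DF_MAX))
    p = float(sps.f.sf(F, q, den_df))
    return F, q, den_df, p


def anova_fixed_effects(result: LmmResult) -> pd.DataFrame:
    """Type-III ANOVA table (F, dfs, p) for group, parameter, interaction."""
    if not result.converged:
        raise RuntimeError("mixed model did not converge; ANOVA unavailable")
    p = len(result.param_levels)
    k = 2 + 2 * (p - 1)
    idx = {"group": [1],
           "parameter": list(range(2, 1 + p)),
           "group:parameter": list(range(1 + p, k))}
    rows = []
    for name, cols in idx.items():
        L = np.zeros((len(cols), k))
        for r, c in enumerate(cols):
            L[r, c] = 1.0
        F, num_df, den_df, pval = _ftest_satterthwaite(result, L)
        rows.append({"effect": name, "F": F, "num_df": num_df,
                     "den_df": den_df, "p": pval})
    return pd.DataFrame(rows)


def posthoc_lsmeans(result: LmmResult, conf: float = 0.95) -> pd.DataFrame:
    """Least-squares means per group x parameter with confidence intervals.

    The LS mean of a cell is the model prediction at that group and
    parameter level (balanced over nothing else in this two-factor
    design); its SE comes from the fixed-effects covariance and its df
    from the Satterthwaite approximation for that prediction contrast.
    """
    p = len(result.param_levels)
    rows = []
    for gi, group in enumerate(result.group_levels):
        gcode = 1.0 if gi == 0 else -1.0
        for param in result.param_levels:
            x = np.zeros(2 + 2 * (p - 1))
            x[0], x[1] = 1.0, gcode
            for j, lev in enumerate(result.param_levels[:-1]):
                if param == lev:
                    x[2 + j] = 1.0
                elif param == result.param_levels[-1]:
                    x[2 + j] = -1.0
            x[1 + p:] = gcode * x[2:1 + p]
            est = float(x @ result.beta)
            se = float(np.sqrt(max(x @ result.cov_beta @ x, 0.0)))
            df = _satterthwaite_df(result, x)
            tcrit = sps.t.ppf(0.5 + conf / 2, df)
            rows.append({"group": group, "parameter": param, "lsmean": est,
                         "se": se, "df": df,
                         "lower": est - tcrit * se, "upper": est + tcrit * se})
    return pd.DataFrame(rows)


def ci_nonoverlap(posthoc: pd.DataFrame) -> pd.DataFrame:
    """Group-difference flags per parameter: CIs that do not overlap."""
    rows = []
    for param, grp in posthoc.groupby("parameter", sort=False):
        if len(grp) != 2 or grp[["lower", "upper"]].isna().any().any():
            rows.append({"parameter": param, "significant": False, "separation": np.nan})
            continue
        a, b = grp.iloc[0], grp.iloc[1]
        sep = max(a["lower"] - b["upper"], b["lower"] - a["upper"])
        rows.append({"parameter": param, "significant": bool(sep > 0),
                     "separation": float(sep)})
    return pd.DataFrame(rows)
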