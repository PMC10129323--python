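"""Linear mixed model with a single random intercept per group.

The association analyses need three things from their mixed models that no
single installed routine supplies together at simulation speed: profiled
ML/REML fits of the random-intercept model, Satterthwaite-approximate
denominator degrees of freedom for t-tests of fixed effects, and type-3
Wald chi-square tests with partial eta-squared effect sizes.  This module
implements them directly, exploiting the closed form of the marginal
covariance for a grouped random intercept.

Model:  y = X beta + Z b + e,  b_i ~ N(0, sigma_b^2) per group i,
e ~ N(0, sigma_e^2 I).  With lambda = sigma_b^2 / sigma_e^2 the group
covariance is V_i = sigma_e^2 (I + lambda 11'), whose inverse and
determinant are available in closed form, so both ML and REML deviances
profile down to a one-dimensional search over lambda.

Satterthwaite df for a contrast c follow the standard recipe: with
f(theta) = Var(c' beta_hat) as a function of theta = (sigma_e^2,
sigma_b^2), df = 2 f^2 / (g' W g), where g is the gradient of f and W the
asymptotic covariance of theta_hat from the curvature of the restricted
log-likelihood.  Derivatives are taken numerically (central differences).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = ["LMMFit", "fit_lmm", "lr_test", "wald_type3", "partial_eta2"]

_LOG2PI = np.log(2.0 * np.pi)


def _group_stats(y: np.ndarray, X: np.ndarray, groups: np.ndarray):
    """Sufficient statistics per group for the profiled deviance."""
    uniq, inv = np.unique(groups, return_inverse=True)
    G = len(uniq)
    n, p = X.shape
    n_i = np.bincount(inv, minlength=G).astype(float)
    # S[g] = X_g' 1 ; gy[g] = 1' y_g
    S = np.zeros((G, p))
    for j in range(p):
        S[:, j] = np.bincount(inv, weights=X[:, j], minlength=G)
    gy = np.bincount(inv, weights=y, minlength=G)
    return uniq, inv, n_i, S, gy, X.T @ X, X.T @ y, float(y @ y)


class _Profile:
    """Profiled deviance machinery over lambda = sigma_b^2/sigma_e^2."""

    def __init__(self, y, X, groups):
        self.y, self.X = y, X
        (self.group_labels, self.inv, self.n_i, self.S, self.gy,
         self.XtX, self.Xty, self.yty) = _group_stats(y, X, groups)
        self.n, self.p = X.shape

    def pieces(self, lam: float):
        c = lam / (1.0 + lam * self.n_i)          # shrinkage weight per group
        A = self.XtX - (self.S * c[:, None]).T @ self.S
        u = self.Xty - self.S.T @ (c * self.gy)
        q = self.yty - float(c @ (self.gy**2))
        return A, u, q, c

    def solve(self, lam: float):
        A, u, q, c = self.pieces(lam)
        beta = np.linalg.solve(A, u)
        rss = max(q - float(u @ beta), 1e-300)    # y' V*^-1 y at beta_hat
        return A, beta, rss, c

    def deviance(self, lam: float, reml: bool) -> float:
        A, beta, rss, _ = self.solve(lam)
        logdet_v = float(np.sum(np.log1p(lam * self.n_i)))
        if reml:
            dof = self.n - self.p
            sig2 = rss / dof
            sign, logdet_a = np.linalg.slogdet(A)
            if sign <= 0:
                return np.inf
            return dof * (np.log(sig2) + _LOG2PI + 1.0) + logdet_v + logdet_a
        sig2 = rss / self.n
        return self.n * (np.log(sig2) + _LOG2PI + 1.0) + logdet_v

    # --- unprofiled restricted log-likelihood, for Satterthwaite ---
    def reml_m2ll(self, theta: np.ndarray) -> float:
        sig_e2, sig_b2 = float(theta[0]), float(theta[1])
        if sig_e2 <= 0 or sig_b2 < 0:
            return np.inf
        lam = sig_b2 / sig_e2
        A, beta, rss, _ = self.solve(lam)
        logdet_v = self.n * np.log(sig_e2) + float(np.sum(np.log1p(lam * self.n_i)))
        sign, logdet_a = np.linalg.slogdet(A / sig_e2)
        if sign <= 0:
            return np.inf
        return logdet_v + logdet_a + rss / sig_e2 + (self.n - self.p) * _LOG2PI

    def covbeta(self, theta: np.ndarray) -> np.ndarray:
        sig_e2, sig_b2 = float(theta[0]), float(theta[1])
        lam = max(sig_b2, 0.0) / sig_e2
        A, _, _, _ = self.pieces(lam)
        return sig_e2 * np.linalg.inv(A)


@dataclass
class LMMFit:
    """Fitted random-intercept linear mixed model."""

    exog_names: list[str]
    params: np.ndarray
    cov_params: np.ndarray
    sigma2_e: float
    sigma2_b: float
    loglik: float
    reml: bool
    n_obs: int
    n_groups: int
    group_labels: np.ndarray
    ranef: np.ndarray  # BLUPs, one per group
    _profile: _Profile = field(repr=False)

    @property
    def df_resid_naive(self) -> int:
        return self.n_obs - len(self.params)

    def bse(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_params))

    def satterthwaite_df(self, contrast: np.ndarray) -> float:
        """Approximate denominator df for t = c'beta / se(c'beta)."""
        c = np.asarray(contrast, dtype=float)
        theta = np.array([self.sigma2_e, max(self.sigma2_b, 0.0)])
        prof = self._profile

        def f(th):
            return float(c @ prof.covbeta(th) @ c)

        h = np.maximum(np.abs(theta), self.sigma2_e) * 1e-4
        grad = np.zeros(2)
        for j in range(2):
            e = np.zeros(2)
            e[j] = h[j]
            lo = np.maximum(theta - e, [1e-12, 0.0])  # keep variances admissible
            grad[j] = (f(theta + e) - f(lo)) / (theta[j] + h[j] - lo[j])
        # Hessian of -2 log L_R / 2  ->  observed information for theta
        H = np.zeros((2, 2))
        for j in range(2):
            for k in range(j, 2):
                ej, ek = np.zeros(2), np.zeros(2)
                ej[j], ek[k] = h[j], h[k]
                fpp = prof.reml_m2ll(np.maximum(theta + ej + ek, [1e-12, 0.0]))
                fpm = prof.reml_m2ll(np.maximum(theta + ej - ek, [1e-12, 0.0]))
                fmp = prof.reml_m2ll(np.maximum(theta - ej + ek, [1e-12, 0.0]))
                fmm = prof.reml_m2ll(np.maximum(theta - ej - ek, [1e-12, 0.0]))
                H[j, k] = H[k, j] = (fpp - fpm - fmp + fmm) / (4 * h[j] * h[k]) / 2.0
        fallback = float(self.df_resid_naive)
        try:
            W = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            return fallback
        denom = float(grad @ W @ grad)
        fval = f(theta)
        if not np.isfinite(denom) or denom <= 0 or fval <= 0:
            return fallback
        df = 2.0 * fval**2 / denom
        return float(min(max(df, 1.0), fallback))

    def coef_table(self) -> pd.DataFrame:
        """lmerTest-style summary: Estimate, SE, Satterthwaite df, t, p."""
        se = self.bse()
        rows = []
        for j, name in enumerate(self.exog_names):
            cvec = np.zeros(len(self.params))
            cvec[j] = 1.0
            df = self.satterthwaite_df(cvec)
            t = self.params[j] / se[j] if se[j] > 0 else np.nan
            p = 2 * stats.t.sf(abs(t), df) if np.isfinite(t) else np.nan
            rows.append((name, self.params[j], se[j], df, t, p))
        return pd.DataFrame(
            rows, columns=["term", "Estimate", "Std. Error", "DF", "t value", "Pr(>|t|)"]
        ).set_index("term")


def fit_lmm(
    y,
    X: pd.DataFrame | np.ndarray,
    groups,
    reml: bool = True,
) -> LMMFit:
    """Fit a linear mixed model with one random intercept per group.

    Parameters
    ----------
    y : response vector.
    X : fixed-effects design matrix (a DataFrame keeps column names).
    groups : group label per observation.
    reml : restricted ML (reporting) vs plain ML (model comparison).
    """
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        Xa = X.to_numpy(dtype=float)
    else:
        Xa = np.asarray(X, dtype=float)
        names = [f"x{j}" for j in range(Xa.shape[1])]
    ya = np.asarray(y, dtype=float)
    ga = np.asarray(groups)
    if ya.ndim != 1 or Xa.shape[0] != ya.size or ga.size != ya.size:
        raise ValueError("y, X, groups must align on observations")
    if Xa.shape[0] <= Xa.shape[1]:
        raise ValueError("more parameters than observations")
    prof = _Profile(ya, Xa, ga)

    def obj(loglam):
        return prof.deviance(float(np.exp(loglam)), reml)

    res = optimize.minimize_scalar(obj, bounds=(-12.0, 12.0), method="bounded",
                                   options={"xatol": 1e-8})
    lam = float(np.exp(res.x))
    if prof.deviance(0.0, reml) <= res.fun:  # boundary: no group variance
        lam = 0.0
    A, beta, rss, c = prof.solve(lam)
    dof = prof.n - prof.p if reml else prof.n
    sig_e2 = rss / dof
    sig_b2 = lam * sig_e2
    cov = sig_e2 * np.linalg.inv(A)
    m2ll = prof.deviance(lam, reml)
    ranef = c * (prof.gy - prof.S @ beta) * 1.0  # BLUP per group
    return LMMFit(
        exog_names=names,
        params=beta,
        cov_params=cov,
        sigma2_e=float(sig_e2),
        sigma2_b=float(sig_b2),
        loglik=float(-0.5 * m2ll),
        reml=reml,
        n_obs=prof.n,
        n_groups=len(prof.group_labels),
        group_labels=prof.group_labels,
        ranef=ranef,
        _profile=prof,
    )


def lr_test(fit_null: LMMFit, fit_alt: LMMFit) -> tuple[float, int, float]:
    """Likelihood-ratio test between two nested ML fits.

    Returns (chi2, df, p).  Both fits must be plain-ML; the statistic is
    clipped at zero against numerical noise.
    """
    if fit_null.reml or fit_alt.reml:
        raise ValueError("likelihood-ratio comparisons require ML fits")
    chi2 = max(2.0 * (fit_alt.loglik - fit_null.loglik), 0.0)
    df = len(fit_alt.params) - len(fit_null.params)
    if df <= 0:
        raise ValueError("models are not nested in the right direction")
    return chi2, df, float(stats.chi2.sf(chi2, df))


def wald_type3(params: np.ndarray, cov: np.ndarray,
               term_columns: dict[str, list[int]]) -> pd.DataFrame:
    """Type-3 Wald chi-square per model term.

    For each term the statistic is the quadratic form of its coefficients
    against their covariance block — the marginal test of the term given
    every other term, valid under the package's sum-to-zero/centered
    codings.  Singular blocks are flagged (chi2 = NaN), never skipped.
    """
    rows = []
    for term, idx in term_columns.items():
        b = params[idx]
        C = cov[np.ix_(idx, idx)]
        df = len(idx)
        if np.allclose(b, 0.0):
            rows.append((term, 0.0, df, 1.0, False))
            continue
        try:
            chi2 = float(b @ np.linalg.solve(C, b))
            if chi2 < 0:
                raise np.linalg.LinAlgError
            rows.append((term, chi2, df, float(stats.chi2.sf(chi2, df)), False))
        except np.linalg.LinAlgError:
            rows.append((term, np.nan, df, np.nan, True))
    return pd.DataFrame(
        rows, columns=["term", "chi2", "df", "p", "singular"]
    ).set_index("term")


def partial_eta2(chi2: float, df_den: float) -> float:
    """Partial eta-squared from a Wald chi-square and its denominator df.

    Equivalent to F-based partial eta^2 with F = chi2/df_num:
    eta_p^2 = chi2 / (chi2 + df_den).
    """
    if not np.isfinite(chi2) or chi2 < 0:
        return np.nan
    return float(chi2 / (chi2 + df_den))
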