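"""Gaussian linear mixed model with independent random intercepts.

Implements the model

    y = X b + sum_k Z_k u_k + e,   u_k ~ N(0, s_k^2 I),   e ~ N(0, s^2 I)

where each Z_k is the indicator matrix of a categorical grouping factor
(e.g. monkey, neuron-within-monkey).  The profiled REML (or ML) criterion is
minimized over the log variance ratios g_k = s_k^2 / s^2; the residual
variance and fixed effects are then recovered in closed form by GLS.

Fixed-effect P-values use Satterthwaite's denominator degrees of freedom,
obtained by the delta method: the asymptotic covariance of the variance
parameters comes from a finite-difference Hessian of the REML criterion, and
the gradient of Var(c'b) with respect to the variance parameters from central
differences.  A parametric-bootstrap likelihood-ratio test between nested
fixed-effect structures (fit by ML) is provided for whole-model inference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats
from scipy.linalg import solve_triangular

__all__ = ["MixedLM", "MixedLMResult", "parametric_bootstrap"]

_LOG_GAMMA_MIN = -12.0
_LOG_GAMMA_MAX = 12.0


def _encode_groups(groups) -> list[np.ndarray]:
    coded = []
    for g in groups:
        _, codes = np.unique(np.asarray(g), return_inverse=True)
        coded.append(codes.astype(np.int64))
    return coded


@dataclass
class MixedLMResult:
    """Fitted mixed model; enough state to simulate and refit."""

    model: "MixedLM"
    beta: np.ndarray
    cov_beta: np.ndarray
    sigma2: float
    var_components: np.ndarray   # one per grouping factor
    loglik: float                # value of the fitted criterion (REML or ML)
    reml: bool
    converged: bool
    singular: bool               # any variance ratio at the boundary

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_beta))

    def loglik_ml(self) -> float:
        """ML log-likelihood at the fitted variance ratios (for LR tests)."""
        if not self.reml:
            return self.loglik
        gammas = self.var_components / self.sigma2
        return -0.5 * self.model._neg2ll(np.log(np.maximum(gammas, 1e-12)), reml=False)

    def satterthwaite(self, contrast=None):
        """t-tests with Satterthwaite df for each coefficient (or a contrast).

        Returns an array of records ``(estimate, se, df, t, p)``; for a single
        contrast vector, a single record.
        """
        p = len(self.beta)
        if contrast is None:
            cs = np.eye(p)
        else:
            cs = np.atleast_2d(np.asarray(contrast, dtype=float))
        theta = np.concatenate([[self.sigma2], self.var_components])
        A = self.model._theta_cov(theta)
        out = []
        for c in cs:
            est = float(c @ self.beta)
            v = float(c @ self.cov_beta @ c)
            se = np.sqrt(v)
            df = self.model._satterthwaite_df(theta, c, v, A)
            t = est / se if se > 0 else np.nan
            pval = 2.0 * stats.t.sf(abs(t), df) if np.isfinite(t) else np.nan
            out.append((est, se, df, t, pval))
        arr = np.array(
            out, dtype=[("estimate", float), ("se", float), ("df", float),
                        ("t", float), ("p", float)]
        )
        return arr[0] if contrast is not None and np.ndim(contrast) == 1 else arr

    def simulate(self, rng: np.random.Generator) -> np.ndarray:
        """Draw a response vector from the fitted model."""
        m = self.model
        y = m.X @ self.beta + rng.normal(0.0, np.sqrt(self.sigma2), m.n)
        for codes, s2 in zip(m.groups, self.var_components):
            n_levels = codes.max() + 1
            u = rng.normal(0.0, np.sqrt(max(s2, 0.0)), n_levels)
            y += u[codes]
        return y


class MixedLM:
    """Random-intercepts LMM on a fixed design.

    Parameters
    ----------
    X : (n, p) fixed-effect design matrix (include the intercept column).
    y : (n,) response.
    groups : sequence of length-n label arrays, one per random intercept
        factor.  Nested factors are passed as their own fully crossed codes
        (e.g. the neuron factor coded uniquely within monkey).
    """

    def __init__(self, X, y, groups):
        self.X = np.asarray(X, dtype=float)
        self.y = np.asarray(y, dtype=float)
        if self.X.ndim != 2 or len(self.X) != len(self.y):
            raise ValueError("X must be (n, p) matching y")
        self.n, self.p = self.X.shape
        if self.n <= self.p:
            raise ValueError("more parameters than observations")
        self.groups = _encode_groups(groups)
        self.k = len(self.groups)
        # Stack the indicator matrix Z = [Z_1 | ... | Z_k] once; every GLS
        # solve then goes through the Woodbury identity on the m x m level
        # space (m = total random-effect levels), independent of n.
        cols = []
        col_factor = []
        for f, codes in enumerate(self.groups):
            m_f = int(codes.max()) + 1
            Zf = np.zeros((self.n, m_f))
            Zf[np.arange(self.n), codes] = 1.0
            cols.append(Zf)
            col_factor.extend([f] * m_f)
        self._Z = np.concatenate(cols, axis=1)
        self._col_factor = np.asarray(col_factor)
        self.m = self._Z.shape[1]
        self._A = self._Z.T @ self._Z
        self._ZX = self._Z.T @ self.X
        self._Zy = self._Z.T @ self.y
        self._XX = self.X.T @ self.X
        self._Xy = self.X.T @ self.y
        self._yy = float(self.y @ self.y)

    # -- likelihood machinery -------------------------------------------------

    def _gls(self, gammas: np.ndarray):
        """GLS at variance ratios ``gammas``: W = I + Z diag(d) Z'.

        Returns (beta, X'W^-1 X, r'W^-1 r, log|W|, log|X'W^-1 X|).
        """
        d = np.asarray(gammas, dtype=float)[self._col_factor]
        s = np.sqrt(d)
        M = np.eye(self.m) + (s[:, None] * self._A) * s[None, :]
        L = np.linalg.cholesky(M)

        def m_solve(B):
            return solve_triangular(
                L.T, solve_triangular(L, B, lower=True), lower=False
            )

        SZX = s[:, None] * self._ZX
        SZy = s * self._Zy
        XtWX = self._XX - SZX.T @ m_solve(SZX)
        XtWy = self._Xy - SZX.T @ m_solve(SZy)
        beta = np.linalg.solve(XtWX, XtWy)
        yWy = self._yy - float(SZy @ m_solve(SZy))
        rss = yWy - 2.0 * float(beta @ XtWy) + float(beta @ XtWX @ beta)
        rss = max(rss, 1e-300)
        logdet_W = 2.0 * float(np.log(np.diag(L)).sum())
        _, logdet_XtX = np.linalg.slogdet(XtWX)
        return beta, XtWX, rss, logdet_W, logdet_XtX

    def _neg2ll(self, log_gammas: np.ndarray, reml: bool = True) -> float:
        gammas = np.exp(np.clip(log_gammas, _LOG_GAMMA_MIN, _LOG_GAMMA_MAX))
        try:
            beta, XtX, rss, logdet_W, logdet_XtX = self._gls(gammas)
        except np.linalg.LinAlgError:
            return np.inf
        if rss <= 0:
            return np.inf
        if reml:
            df = self.n - self.p
            s2 = rss / df
            return (
                df * np.log(2.0 * np.pi * s2)
                + df
                + logdet_W
                + logdet_XtX
            )
        s2 = rss / self.n
        return self.n * np.log(2.0 * np.pi * s2) + self.n + logdet_W

    def fit(self, reml: bool = True, start_log_gamma: float = 0.0) -> MixedLMResult:
        x0 = np.full(self.k, float(start_log_gamma))
        if self.k == 1:
            res = optimize.minimize_scalar(
                lambda s: self._neg2ll(np.array([s]), reml),
                bounds=(_LOG_GAMMA_MIN, _LOG_GAMMA_MAX),
                method="bounded",
                options={"xatol": 1e-6},
            )
            log_g = np.array([res.x])
            converged = bool(res.success)
        else:
            res = optimize.minimize(
                lambda s: self._neg2ll(s, reml),
                x0,
                method="Nelder-Mead",
                options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 2000},
            )
            log_g = np.clip(res.x, _LOG_GAMMA_MIN, _LOG_GAMMA_MAX)
            converged = bool(res.success)
        gammas = np.exp(log_g)
        beta, XtX, rss, _, _ = self._gls(gammas)
        dof = self.n - self.p if reml else self.n
        sigma2 = rss / dof
        cov_beta = sigma2 * np.linalg.inv(XtX)
        singular = bool((log_g <= _LOG_GAMMA_MIN + 1e-6).any())
        return MixedLMResult(
            model=self,
            beta=beta,
            cov_beta=cov_beta,
            sigma2=float(sigma2),
            var_components=gammas * sigma2,
            loglik=-0.5 * self._neg2ll(log_g, reml),
            reml=reml,
            converged=converged,
            singular=singular,
        )

    # -- Satterthwaite helpers ------------------------------------------------

    def _neg2ll_theta(self, theta: np.ndarray) -> float:
        """REML criterion as a function of raw variances (s^2, s_1^2, ...)."""
        s2 = theta[0]
        if s2 <= 0 or (theta[1:] < 0).any():
            return np.inf
        gammas = theta[1:] / s2
        try:
            _, _, rss, logdet_W, logdet_XtX = self._gls(gammas)
        except np.linalg.LinAlgError:
            return np.inf
        # -2 log L_R with V = s2 * W:  log|V| - p log s2 collapses with the
        # Gaussian constant into (n - p) log s2.
        df = self.n - self.p
        return df * np.log(2.0 * np.pi * s2) + rss / s2 + logdet_W + logdet_XtX

    def _vc(self, theta: np.ndarray, c: np.ndarray) -> float:
        s2 = theta[0]
        gammas = np.maximum(theta[1:], 0.0) / s2
        _, XtX, _, _, _ = self._gls(gammas)
        cov = s2 * np.linalg.inv(XtX)
        return float(c @ cov @ c)

    def _steps(self, theta: np.ndarray) -> np.ndarray:
        return 1e-4 * np.maximum(np.abs(theta), 1e-3 * max(theta[0], 1e-8))

    def _theta_cov(self, theta: np.ndarray) -> np.ndarray:
        """Asymptotic covariance of the variance parameters (inverse Hessian)."""
        d = len(theta)
        h = self._steps(theta)
        H = np.zeros((d, d))

        def f(t):
            return 0.5 * self._neg2ll_theta(np.maximum(t, 1e-12))

        f0 = f(theta)
        for i in range(d):
            ei = np.zeros(d); ei[i] = h[i]
            for j in range(i, d):
                ej = np.zeros(d); ej[j] = h[j]
                if i == j:
                    H[i, i] = (f(theta + ei) - 2 * f0 + f(theta - ei)) / h[i] ** 2
                else:
                    H[i, j] = H[j, i] = (
                        f(theta + ei + ej)
                        - f(theta + ei - ej)
                        - f(theta - ei + ej)
                        + f(theta - ei - ej)
                    ) / (4 * h[i] * h[j])
        try:
            return np.linalg.inv(H)
        except np.linalg.LinAlgError:
            return np.full((d, d), np.nan)

    def _satterthwaite_df(
        self, theta: np.ndarray, c: np.ndarray, v: float, A: np.ndarray
    ) -> float:
        d = len(theta)
        h = self._steps(theta)
        g = np.zeros(d)
        for i in range(d):
            ei = np.zeros(d); ei[i] = h[i]
            g[i] = (
                self._vc(np.maximum(theta + ei, 1e-12), c)
                - self._vc(np.maximum(theta - ei, 1e-12), c)
            ) / (2 * h[i])
        denom = float(g @ A @ g)
        if not np.isfinite(denom) or denom <= 0:
            return float(self.n - self.p)  # fall back to residual df
        df = 2.0 * v**2 / denom
        if not np.isfinite(df) or df <= 0:
            return float(self.n - self.p)
        return min(df, float(self.n - self.p))


def parametric_bootstrap(
    full: MixedLMResult,
    null: MixedLMResult,
    n_boot: int = 10_000,
    seed: int = 0,
):
    """Parametric-bootstrap LR test of nested fixed-effect structures.

    Both models must share the response and grouping structure; the null's
    fixed effects must nest in the full's.  Models are refit by ML on each
    response simulated from the fitted null; the p-value is
    ``(1 + #{LR* >= LR_obs}) / (n_ok + 1)`` over successful refits.

    Returns ``(p, lr_obs, null_lrs, n_failures)``.
    """
    if full.model.n != null.model.n:
        raise ValueError("full and null models must share the data")
    full_ml = full if not full.reml else full.model.fit(reml=False)
    null_ml = null if not null.reml else null.model.fit(reml=False)
    lr_obs = max(2.0 * (full_ml.loglik - null_ml.loglik), 0.0)

    rng = np.random.default_rng(seed)
    lrs = []
    failures = 0
    for _ in range(n_boot):
        y_star = null_ml.simulate(rng)
        try:
            m_full = MixedLM(full.model.X, y_star, full.model.groups)
            m_null = MixedLM(null.model.X, y_star, null.model.groups)
            lr = 2.0 * (m_full.fit(reml=False).loglik - m_null.fit(reml=False).loglik)
            lrs.append(max(lr, 0.0))
        except (np.linalg.LinAlgError, ValueError):
            failures += 1
    lrs = np.asarray(lrs)
    p = (1.0 + float((lrs >= lr_obs).sum())) / (len(lrs) + 1.0)
    return p, lr_obs, lrs, failures
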