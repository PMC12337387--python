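"""Single-component REML machinery shared by the association and
prediction modules.

The model is y = Q alpha + g + e with Var(g) = sigma_g^2 G and
Var(e) = sigma_e^2 I. G is eigendecomposed once; the REML log-likelihood
is profiled over delta = sigma_e^2 / sigma_g^2 on the rotated data
(EMMA-style), then optimized on log(delta) by grid search plus bounded
refinement. Downstream scans whiten with the fitted V^{-1/2} and fall
back to per-test OLS on the whitened data, which reduces exactly to
ordinary least squares when G is the identity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar


@dataclass
class NullModel:
    sigma_g2: float
    sigma_e2: float
    delta: float  # sigma_e2 / sigma_g2
    U: np.ndarray  # eigenvectors of G
    S: np.ndarray  # eigenvalues of G
    alpha: np.ndarray  # GLS covariate effects
    Q: np.ndarray
    y: np.ndarray
    loglik: float

    @property
    def weights(self) -> np.ndarray:
        """1 / (S_i + delta); V^{-1} = U diag(w) U' / sigma_g2."""
        return 1.0 / (self.S + self.delta)

    def whiten(self, X: np.ndarray) -> np.ndarray:
        """Apply V^{-1/2} up to the sigma_g scalar: diag(sqrt(w)) U' X."""
        Xr = self.U.T @ X
        return Xr * np.sqrt(self.weights)[:, None] if X.ndim == 2 \
            else Xr * np.sqrt(self.weights)

    def conditional_residuals(self) -> np.ndarray:
        """e-hat = y - Q alpha - BLUP(g); the HGWAS second-step phenotype."""
        r = self.y - self.Q @ self.alpha
        rt = self.U.T @ r
        et = self.delta * self.weights * rt  # sigma_e2 * w / sigma_g2 = delta * w
        return self.U @ et

    def blup_g(self) -> np.ndarray:
        r = self.y - self.Q @ self.alpha
        rt = self.U.T @ r
        return self.U @ (self.S * self.weights * rt)


def fit_null_lmm(y, Q, G, eig=None) -> NullModel:
    """REML fit of y = Q alpha + g + e with Var(g) = sigma_g^2 G.

    `eig` may carry a precomputed ``(S, U)`` eigendecomposition of G.
    """
    y = np.asarray(y, dtype=float)
    Q = np.atleast_2d(np.asarray(Q, dtype=float))
    if Q.shape[0] != len(y):
        Q = Q.T
    n, q = Q.shape
    if np.ptp(y) == 0:
        raise ValueError("degenerate trait: y is constant")
    if eig is None:
        S, U = np.linalg.eigh(np.asarray(G, dtype=float))
    else:
        S, U = eig
    S = np.maximum(S, 0.0)
    yt = U.T @ y
    Qt = U.T @ Q

    def neg_loglik(log_delta):
        delta = float(np.exp(log_delta))
        w = 1.0 / (S + delta)
        Qw = Qt * w[:, None]
        A = Qt.T @ Qw
        try:
            alpha = np.linalg.solve(A, Qw.T @ yt)
        except np.linalg.LinAlgError:
            return 1e300
        r = yt - Qt @ alpha
        rss = float(r @ (w * r))
        if rss <= 0:
            return 1e300
        sigma_g2 = rss / (n - q)
        _, logdet_A = np.linalg.slogdet(A)
        ll = -0.5 * ((n - q) * np.log(sigma_g2) - np.sum(np.log(w)) + logdet_A
                     + (n - q))
        return -ll

    grid = np.linspace(-12.0, 12.0, 49)
    vals = [neg_loglik(g_) for g_ in grid]
    i = int(np.argmin(vals))
    lo, hi = grid[max(i - 1, 0)], grid[min(i + 1, len(grid) - 1)]
    res = minimize_scalar(neg_loglik, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-8})
    log_delta = float(res.x) if res.fun <= vals[i] else float(grid[i])
    delta = float(np.exp(log_delta))

    w = 1.0 / (S + delta)
    Qw = Qt * w[:, None]
    alpha = np.linalg.solve(Qt.T @ Qw, Qw.T @ yt)
    r = yt - Qt @ alpha
    sigma_g2 = float(r @ (w * r)) / (n - q)
    return NullModel(sigma_g2=sigma_g2, sigma_e2=delta * sigma_g2, delta=delta,
                     U=U, S=S, alpha=alpha, Q=Q, y=y,
                     loglik=-neg_loglik(log_delta))


def gls_scan(null: NullModel, X: np.ndarray):
    """Per-column association test with the null variance structure fixed.

    Whitens y, covariates and every test column with the fitted V^{-1/2},
    residualizes on the covariates, and performs per-column OLS t-tests
    with the residual scale re-estimated per column (so with G = I the
    p-values are exactly the OLS ones).

    Returns (beta, se, p) arrays over columns of X.
    """
    from scipy import stats

    yw = null.whiten(null.y)
    Qw = null.whiten(null.Q)
    Xw = null.whiten(np.asarray(X, dtype=float))
    n, q = Qw.shape
    QtQ_inv = np.linalg.pinv(Qw.T @ Qw)
    yr = yw - Qw @ (QtQ_inv @ (Qw.T @ yw))
    Xr = Xw - Qw @ (QtQ_inv @ (Qw.T @ Xw))
    xtx = np.einsum("ij,ij->j", Xr, Xr)
    xty = Xr.T @ yr
    yty = float(yr @ yr)
    df = n - q - 1
    ok = xtx > 1e-12 * max(float(xtx.max(initial=0.0)), 1.0)
    beta = np.zeros(X.shape[1])
    se = np.full(X.shape[1], np.nan)
    p = np.ones(X.shape[1])
    beta[ok] = xty[ok] / xtx[ok]
    rss = np.maximum(yty - beta[ok] * xty[ok], 0.0)
    sigma2 = rss / df
    se[ok] = np.sqrt(sigma2 / xtx[ok])
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = beta[ok] / se[ok]
    p[ok] = 2.0 * stats.t.sf(np.abs(tstat), df)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    return beta, se, p
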