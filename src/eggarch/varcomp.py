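"""Two-GRM random-effect model for the proportion of variance explained.

The model is y = Q alpha + u1 + u2 + e with Var(u_i) = sigma_i^2 K_i,
where K_1 is built from significant loci and K_2 from the remaining
(insignificant) loci. Components are estimated by EM-REML, whose
iterates keep the restricted likelihood non-decreasing, and

    PVE_sig        = sigma_1^2 / (sigma_1^2 + sigma_2^2 + sigma_e^2)
    PVE_genomewide = (sigma_1^2 + sigma_2^2) / (sigma_1^2 + sigma_2^2 + sigma_e^2)
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class ConvergenceError(RuntimeError):
    pass


@dataclass
class VarianceComponents:
    sigma_sig: float
    sigma_insig: float
    sigma_e: float
    n_iter: int
    converged: bool
    loglik_trace: list = field(default_factory=list)

    @property
    def pve_sig(self) -> float:
        tot = self.sigma_sig + self.sigma_insig + self.sigma_e
        return self.sigma_sig / tot if tot > 0 else 0.0

    @property
    def pve_genomewide(self) -> float:
        tot = self.sigma_sig + self.sigma_insig + self.sigma_e
        return (self.sigma_sig + self.sigma_insig) / tot if tot > 0 else 0.0


def _projection(y, Q, V):
    """(P, Py, restricted loglik) with one Cholesky factorization of V."""
    from scipy.linalg import cho_factor, cho_solve

    n = len(y)
    c, low = cho_factor(V, lower=True, check_finite=False)
    logdet_V = 2.0 * float(np.sum(np.log(np.diag(c))))
    Vi = cho_solve((c, low), np.eye(n), check_finite=False)
    ViQ = Vi @ Q
    A = Q.T @ ViQ
    signA, logdet_A = np.linalg.slogdet(A)
    if signA <= 0:
        raise np.linalg.LinAlgError("singular covariate cross-product")
    P = Vi - ViQ @ np.linalg.solve(A, ViQ.T)
    Py = P @ y
    ll = float(-0.5 * (logdet_V + logdet_A + y @ Py))
    return P, Py, ll


def emreml_two_grm(y, K1, K2, covariates=None, max_iter: int = 500,
                   tol: float = 1e-6, floor_frac: float = 1e-8,
                   jitter_restart: bool = True) -> VarianceComponents:
    """EM-REML for y = Q alpha + u1 + u2 + e, Var(u_i) = sigma_i^2 K_i.

    Components are floored at `floor_frac * var(y)`; if a component pins
    to the floor early, one jittered restart is attempted. With K1 =
    None (no significant loci) the model collapses to a single genomic
    component and PVE_sig = 0.
    """
    y = np.asarray(y, float)
    keep = np.isfinite(y)
    y = y[keep]
    n = len(y)
    if np.ptp(y) == 0:
        raise ValueError("degenerate trait")
    vy = float(np.var(y))
    if covariates is None:
        Q = np.ones((n, 1))
    else:
        C = np.asarray(covariates, float)[keep]
        Q = np.hstack([np.ones((n, 1)), C.reshape(n, -1)])

    if K1 is None:
        sub = emreml_two_grm(y, np.asarray(K2, float)[np.ix_(keep, keep)]
                             if K2.shape[0] != n else K2,
                             np.zeros((n, n)), covariates=None if covariates is None
                             else np.asarray(covariates, float)[keep],
                             max_iter=max_iter, tol=tol)
        return VarianceComponents(0.0, sub.sigma_sig, sub.sigma_e,
                                  sub.n_iter, sub.converged, sub.loglik_trace)

    K1 = np.asarray(K1, float)
    K2 = np.asarray(K2, float)
    if K1.shape[0] != n:
        K1 = K1[np.ix_(keep, keep)]
    if K2.shape[0] != n:
        K2 = K2[np.ix_(keep, keep)]
    use2 = float(np.abs(K2).max()) > 0
    Ks = [K1, K2, np.eye(n)]
    active = [True, use2, True]
    floor = floor_frac * vy

    def run(start):
        sig = list(start)
        trace = []
        for it in range(1, max_iter + 1):
            V = sum(s * K for s, K, a in zip(sig, Ks, active) if a)
            try:
                P, Py, ll = _projection(y, Q, V)
            except np.linalg.LinAlgError:
                V = V + floor * np.eye(n)
                P, Py, ll = _projection(y, Q, V)
            trace.append(ll)
            new = []
            for s, K, a in zip(sig, Ks, active):
                if not a:
                    new.append(0.0)
                    continue
                # tr(P K) via the elementwise product (both symmetric)
                upd = (s**2 * (Py @ (K @ Py)) + s * n - s**2 * float(np.sum(P * K))) / n
                new.append(max(float(upd), floor))
            rel = max(abs(ns - s) / max(s, floor) for ns, s in zip(new, sig))
            sig = new
            if rel < tol:
                return sig, it, True, trace
            # EM crawls once a component pins near zero; a restricted
            # likelihood flat on the scale of the requested tolerance is
            # as converged as the data allow
            if len(trace) >= 3 and abs(trace[-1] - trace[-3]) < \
                    1e-3 * tol * max(1.0, abs(trace[-1])):
                return sig, it, True, trace
        return sig, max_iter, False, trace

    start = [vy / 3] * 3 if use2 else [vy / 2, 0.0, vy / 2]
    sig, it, ok, trace = run(start)
    if jitter_restart and any(s <= floor * 1.01 for s, a in zip(sig, active) if a):
        rng = np.random.default_rng(0)
        start2 = [s * float(rng.uniform(0.5, 1.5)) + vy * 0.05 for s in start]
        sig2, it2, ok2, trace2 = run(start2)
        if trace2 and (not trace or trace2[-1] > trace[-1] + 1e-9):
            sig, it, ok, trace = sig2, it2, ok2, trace2
    if not ok and (len(trace) < 2 or abs(trace[-1] - trace[-2]) > 1e-3):
        raise ConvergenceError(f"EM-REML did not converge in {max_iter} iterations")
    s1, s2, se = sig
    return VarianceComponents(s1, s2 if use2 else 0.0, se, it, ok, trace)


def estimate_h2(y, K, covariates=None) -> float:
    """Narrow-sense heritability from a single GRM by exact REML.

    Profiles the restricted likelihood on the eigen-rotated model (no EM
    iteration needed for one component); returns
    sigma_g^2 / (sigma_g^2 + sigma_e^2).
    """
    from .lmm import fit_null_lmm

    y = np.asarray(y, float)
    keep = np.isfinite(y)
    y_ = y[keep]
    K_ = np.asarray(K, float)
    if K_.shape[0] != len(y_):
        K_ = K_[np.ix_(keep, keep)]
    if covariates is None:
        Q = np.ones((len(y_), 1))
    else:
        C = np.asarray(covariates, float)[keep]
        Q = np.hstack([np.ones((len(y_), 1)), C.reshape(len(y_), -1)])
    null = fit_null_lmm(y_, Q, K_)
    return null.sigma_g2 / (null.sigma_g2 + null.sigma_e2)
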