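"""Single-SNP mixed-linear-model association scan.

The scan follows the standard two-stage desk approximation: variance
components are estimated once by REML under the null model
y = Q alpha + g + e (no SNP term), then every SNP is tested by
generalized least squares with those components fixed. Covariates
default to an intercept, a batch indicator if provided, and the top
principal components of the genomic relationship matrix. Multiple
testing is controlled by Benjamini-Hochberg FDR.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .genio import PhasedGenotypes
from .lmm import NullModel, fit_null_lmm, gls_scan


class EmptyGRMError(ValueError):
    """Every site monomorphic: no information for a relationship matrix."""


def compute_grm(g, dosages: np.ndarray | None = None) -> np.ndarray:
    """VanRaden genomic relationship matrix from 0/1/2 dosages.

    Z is the column-centered dosage matrix restricted to polymorphic
    sites; GRM = Z Z' / sum_j 2 p_j (1 - p_j).
    """
    D = g.dosages() if isinstance(g, PhasedGenotypes) else np.asarray(g, float)
    D = D.astype(float)
    p = D.mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    if not poly.any():
        raise EmptyGRMError("all sites monomorphic")
    Z = D[:, poly] - 2.0 * p[poly]
    denom = float(np.sum(2.0 * p[poly] * (1.0 - p[poly])))
    return (Z @ Z.T) / denom


def compute_pcs(grm: np.ndarray, k: int = 10) -> np.ndarray:
    """Top-k eigenvectors of the GRM with a deterministic sign convention
    (the largest-magnitude loading of each PC is made positive)."""
    grm = np.asarray(grm, float)
    n = grm.shape[0]
    if k >= n:
        raise ValueError(f"k={k} must be < N={n}")
    if k == 0:
        return np.empty((n, 0))
    vals, vecs = np.linalg.eigh(grm)
    order = np.argsort(vals)[::-1][:k]
    pcs = vecs[:, order]
    for j in range(k):
        i = int(np.argmax(np.abs(pcs[:, j])))
        if pcs[i, j] < 0:
            pcs[:, j] = -pcs[:, j]
    return pcs


def _design(n, covariates, pcs):
    parts = [np.ones((n, 1))]
    if covariates is not None:
        C = np.asarray(covariates, float)
        parts.append(C.reshape(n, -1))
    if pcs is not None and np.size(pcs):
        parts.append(np.asarray(pcs, float).reshape(n, -1))
    return np.hstack(parts)


def snp_scan(y, g, grm: np.ndarray, covariates=None, pcs=None,
             null: NullModel | None = None) -> pd.DataFrame:
    """MLM association scan of trait y against every SNP.

    Missing trait values are dropped (with the matching GRM rows/columns
    and genotypes). Returns a DataFrame with chrom, pos, beta, se, p, q.
    """
    y = np.asarray(y, dtype=float)
    if isinstance(g, PhasedGenotypes):
        D = g.dosages().astype(float)
        variants = g.variants
    else:
        D = np.asarray(g, float)
        variants = pd.DataFrame({"chrom": "chr0", "pos": np.arange(1, D.shape[1] + 1)})
    keep = np.isfinite(y)
    y_, D_ = y[keep], D[keep]
    grm_ = np.asarray(grm, float)[np.ix_(keep, keep)]
    cov_ = None if covariates is None else np.asarray(covariates, float)[keep]
    pcs_ = None if pcs is None else np.asarray(pcs, float)[keep]
    if np.ptp(y_) == 0:
        raise ValueError("degenerate trait: constant after missing removal")
    Q = _design(len(y_), cov_, pcs_)
    if null is None:
        null = fit_null_lmm(y_, Q, grm_)
    beta, se, p = gls_scan(null, D_)
    q = bh_fdr(p)
    return pd.DataFrame({
        "chrom": variants["chrom"].to_numpy(),
        "pos": variants["pos"].to_numpy(),
        "beta": beta, "se": se, "p": p, "q": q,
    })


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values with monotonicity enforcement."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.array([])
    return multipletests(p, method="fdr_bh")[1]
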