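"""Canonical-correlation multi-trait association and the
genotype-by-stage interaction model.

With a single genotype dosage on one side and q traits on the other,
the first (and only) canonical correlation satisfies rho^2 = R^2 of
regressing the dosage on the traits. Significance uses Bartlett's
chi-square approximation
chi2 = -(n - 1 - (1 + q + 1)/2) ln(1 - rho^2) on q degrees of freedom.
Trait-side canonical coefficients are reported on standardized traits,
scaled so the canonical variate has unit variance, with the sign fixed
so the first (nonzero) trait coefficient is non-negative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .assoc_snp import bh_fdr
from .genio import PhasedGenotypes


@dataclass
class CCAResult:
    table: pd.DataFrame  # per SNP: chrom, pos, rho, chi2, p, q
    coefficients: np.ndarray  # M x q trait-side coefficients
    trait_names: list[str]
    n_used: int  # post listwise-deletion sample size


def _fix_sign(b: np.ndarray) -> np.ndarray:
    nz = np.flatnonzero(np.abs(b) > 1e-12)
    if nz.size and b[nz[0]] < 0:
        return -b
    return b


def cca_scan(g, trait_matrix: pd.DataFrame) -> CCAResult:
    """Per-SNP canonical correlation between dosage and a stage's traits.

    Rows of `trait_matrix` with any missing value are dropped (listwise
    deletion); the post-deletion n enters Bartlett's statistic.
    """
    if isinstance(g, PhasedGenotypes):
        D = g.dosages().astype(float)
        variants = g.variants
    else:
        D = np.asarray(g, float)
        variants = pd.DataFrame({"chrom": "chr0", "pos": np.arange(1, D.shape[1] + 1)})
    Y = trait_matrix.to_numpy(dtype=float) if isinstance(trait_matrix, pd.DataFrame) \
        else np.asarray(trait_matrix, float)
    trait_names = list(trait_matrix.columns) if isinstance(trait_matrix, pd.DataFrame) \
        else [f"trait{j}" for j in range(Y.shape[1])]
    if Y.ndim != 2 or Y.shape[1] == 0:
        raise ValueError("need at least one trait")
    keep = np.all(np.isfinite(Y), axis=1)
    Y, D = Y[keep], D[keep]
    n, q = Y.shape
    if n <= q + 2:
        raise ValueError("too few complete rows for CCA")

    sd = Y.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    Yz = (Y - Y.mean(axis=0)) / sd
    Syy = (Yz.T @ Yz) / (n - 1)
    Syy_pinv = np.linalg.pinv(Syy)

    Xc = D - D.mean(axis=0)
    cross = (Yz.T @ Xc) / (n - 1)  # q x M
    B = Syy_pinv @ cross  # unnormalized coefficient vectors per SNP
    proj = Yz @ B  # canonical variates (unscaled)
    num = np.einsum("ij,ij->j", proj, Xc)
    den_x = np.einsum("ij,ij->j", Xc, Xc)
    den_y = np.einsum("ij,ij->j", proj, proj)
    with np.errstate(divide="ignore", invalid="ignore"):
        rho2 = np.where((den_x > 1e-12) & (den_y > 1e-12),
                        num**2 / (den_x * den_y), 0.0)
    rho2 = np.clip(rho2, 0.0, 1.0 - 1e-15)
    factor = n - 1 - (1 + q + 1) / 2.0
    chi2 = -factor * np.log1p(-rho2)
    p = stats.chi2.sf(chi2, df=q)
    p = np.where(den_x > 1e-12, p, 1.0)  # constant genotype sentinel
    p = np.clip(p, np.finfo(float).tiny, 1.0)

    # standardized, unit-variance, sign-fixed coefficients
    var_b = np.einsum("qj,qk,kj->j", B, Syy, B)
    scale = np.where(var_b > 1e-24, 1.0 / np.sqrt(np.maximum(var_b, 1e-300)), 0.0)
    coefs = (B * scale).T  # M x q
    coefs = np.array([_fix_sign(b) for b in coefs])

    table = pd.DataFrame({
        "chrom": variants["chrom"].to_numpy(),
        "pos": variants["pos"].to_numpy(),
        "rho": np.sqrt(rho2), "chi2": chi2, "p": p, "q": bh_fdr(p),
    })
    return CCAResult(table=table, coefficients=coefs,
                     trait_names=trait_names, n_used=n)


def canonical_coefficients(result: CCAResult, only_significant: bool = True,
                           fdr: float = 0.05) -> pd.DataFrame:
    """Signed standardized trait-side coefficients per (significant) SNP."""
    mask = result.table["q"] <= fdr if only_significant \
        else np.ones(len(result.table), dtype=bool)
    out = result.table.loc[mask, ["chrom", "pos"]].reset_index(drop=True)
    coef = pd.DataFrame(result.coefficients[np.asarray(mask)],
                        columns=result.trait_names)
    return pd.concat([out, coef], axis=1)


@dataclass
class InteractionResult:
    interaction_p: float
    f_stat: float
    df: tuple[int, int]
    posthoc: pd.DataFrame | None  # stage, genotype, emm, contrast, se, p_adj


def stage_interaction_test(long: pd.DataFrame, value_col: str = "value",
                           stage_col: str = "stage", geno_col: str = "genotype",
                           alpha: float = 0.05) -> InteractionResult:
    """Two-way fixed-effect model value ~ stage * genotype with an F-test
    for the interaction; when significant, per-genotype-within-stage
    contrasts against that stage's mean of genotype means, Bonferroni
    adjusted.

    Genotype levels with an empty cell in either stage are dropped with a
    warning (the interaction is not estimable for them).
    """
    df = long[[stage_col, geno_col, value_col]].dropna().copy()
    stages = sorted(df[stage_col].unique())
    if len(stages) != 2:
        raise ValueError("exactly two stages required")
    counts = df.groupby([geno_col, stage_col], observed=True).size().unstack(fill_value=0)
    good = counts.index[(counts > 0).all(axis=1)]
    dropped = set(counts.index) - set(good)
    if dropped:
        warnings.warn(f"dropping genotype levels with empty cells: {sorted(dropped)}")
        df = df[df[geno_col].isin(good)]
    genos = sorted(df[geno_col].unique())
    if len(genos) < 2:
        raise ValueError("need >= 2 genotype levels with both stages present")

    y = df[value_col].to_numpy(float)
    s_idx = df[stage_col].map({s: i for i, s in enumerate(stages)}).to_numpy()
    g_idx = df[geno_col].map({g: i for i, g in enumerate(genos)}).to_numpy()
    G, S = len(genos), 2

    def rss_of(design):
        coef, res, rank, _ = np.linalg.lstsq(design, y, rcond=None)
        fitted = design @ coef
        return float(np.sum((y - fitted) ** 2)), rank

    def dummies(idx, k):
        Z = np.zeros((len(idx), k))
        Z[np.arange(len(idx)), idx] = 1.0
        return Z[:, 1:]  # drop first level

    inter = np.einsum("ij,ik->ijk",
                      dummies(g_idx, G), dummies(s_idx, S)).reshape(len(y), -1)
    X_add = np.hstack([np.ones((len(y), 1)), dummies(g_idx, G), dummies(s_idx, S)])
    X_full = np.hstack([X_add, inter])
    rss_f, rank_f = rss_of(X_full)
    rss_a, rank_a = rss_of(X_add)
    df1 = rank_f - rank_a
    df2 = len(y) - rank_f
    tss = float(np.sum((y - y.mean()) ** 2))
    if df1 <= 0 or df2 <= 0 or rss_f <= 1e-12 * max(tss, 1e-300):
        return InteractionResult(1.0, 0.0, (max(df1, 0), max(df2, 0)), None)
    F = max(((rss_a - rss_f) / df1) / (rss_f / df2), 0.0)
    p_int = float(stats.f.sf(F, df1, df2))

    posthoc = None
    if p_int < alpha:
        cells = df.groupby([stage_col, geno_col], observed=True)[value_col] \
                  .agg(["mean", "count"])
        sigma2 = rss_f / df2
        rows = []
        for s in stages:
            emms = np.array([cells.loc[(s, g), "mean"] for g in genos])
            ns = np.array([cells.loc[(s, g), "count"] for g in genos])
            grand = emms.mean()
            for i, g_lab in enumerate(genos):
                contrast = emms[i] - grand
                coef = np.full(G, -1.0 / G)
                coef[i] += 1.0
                var = sigma2 * np.sum(coef**2 / ns)
                se = np.sqrt(var)
                t = contrast / se if se > 0 else 0.0
                p_raw = 2 * stats.t.sf(abs(t), df2)
                rows.append((s, g_lab, emms[i], contrast, se,
                             min(1.0, p_raw * G * S)))
        posthoc = pd.DataFrame(rows, columns=["stage", "genotype", "emm",
                                              "contrast", "se", "p_adj"])
    return InteractionResult(p_int, float(F), (df1, df2), posthoc)
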