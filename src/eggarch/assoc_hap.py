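"""Haplotype-block association: block construction, haplotype GRM,
two-step residual scan, and per-allele effect estimation.

The genome is cut into non-overlapping blocks of five successive SNPs.
Distinct 5-mer sequences within a block are the block's haplotype
alleles; each diploid individual carries an unordered pair of allele
codes. The haplotype relationship matrix assigns 1 to equal allele
pairs and 0 otherwise per block, averages over blocks (Gamma), and is
collapsed to the individual level as H = K Gamma K'/2 with
K = I_m (x) [1 1].

The scan is two-step: a null mixed model with H as the polygenic
covariance is fitted once; its conditional residuals are then regressed
on each block's haplotype-combination factor with an overall F-test.
Allele effects within significant blocks are estimated as fixed effects
on dosage codes (0/1/2 copies per allele), and alleles with nominal
p < 0.05 are classified as beneficial (BHA) or unbeneficial (UHA)
according to the trait's desirable direction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .assoc_snp import bh_fdr, _design
from .genio import PhasedGenotypes
from .lmm import fit_null_lmm

RARE_CARRIER_MIN = 5  # combination levels with fewer carriers merge into "rare"


@dataclass
class HaplotypeBlock:
    id: int
    chrom: str
    snp_cols: np.ndarray  # global variant columns (block_size of them)
    start: int  # 1-based bp of first SNP
    end: int  # 1-based bp of last SNP
    alleles: np.ndarray  # A x block_size allele sequences, frequency-sorted
    freqs: np.ndarray  # allele population frequencies (sum to 1)
    codes: np.ndarray  # per-haplotype allele code, length 2N
    meta: dict = field(default_factory=dict)

    @property
    def n_alleles(self) -> int:
        return len(self.freqs)

    def allele_seq(self, code: int) -> str:
        return "".join(map(str, self.alleles[code]))

    def pairs(self) -> np.ndarray:
        """N x 2 unordered (sorted) allele-code pairs per individual."""
        a, b = self.codes[0::2], self.codes[1::2]
        return np.sort(np.stack([a, b], axis=1), axis=1)

    def subset(self, individuals: np.ndarray) -> "HaplotypeBlock":
        rows = np.empty(2 * len(individuals), dtype=int)
        rows[0::2] = 2 * np.asarray(individuals)
        rows[1::2] = 2 * np.asarray(individuals) + 1
        return HaplotypeBlock(
            id=self.id, chrom=self.chrom, snp_cols=self.snp_cols,
            start=self.start, end=self.end, alleles=self.alleles,
            freqs=self.freqs, codes=self.codes[rows], meta=dict(self.meta))


def build_blocks(g: PhasedGenotypes, block_size: int = 5) -> list[HaplotypeBlock]:
    """Non-overlapping consecutive windows of `block_size` SNPs per
    chromosome; the trailing remainder shorter than a block is dropped."""
    blocks: list[HaplotypeBlock] = []
    bid = 0
    for chrom, sub in g.variants.groupby("chrom", sort=False):
        idx = sub.index.to_numpy()
        if len(idx) < block_size:
            warnings.warn(f"{chrom}: fewer than {block_size} SNPs, no blocks")
            continue
        for s in range(0, len(idx) - block_size + 1, block_size):
            cols = idx[s: s + block_size]
            seqs = g.hap[:, cols]
            uniq, inv, counts = np.unique(seqs, axis=0, return_inverse=True,
                                          return_counts=True)
            freq = counts / seqs.shape[0]
            order = np.argsort(-freq, kind="stable")  # code 0 = most frequent
            rank = np.empty_like(order)
            rank[order] = np.arange(len(order))
            blocks.append(HaplotypeBlock(
                id=bid, chrom=str(chrom), snp_cols=cols,
                start=int(g.variants["pos"].iloc[cols[0]]),
                end=int(g.variants["pos"].iloc[cols[-1]]),
                alleles=uniq[order], freqs=freq[order],
                codes=rank[inv].astype(np.int32)))
            bid += 1
    return blocks


def hap_grm(blocks: list[HaplotypeBlock], return_gamma: bool = False):
    """Individual-level haplotype relationship matrix H = K Gamma K'/2.

    Gamma_i has entry 1 where two haplotypes carry equal block-i alleles;
    Gamma averages Gamma_i over blocks; K = I_m (x) [1 1] collapses the
    2m haplotypes to m individuals.
    """
    if not blocks:
        raise ValueError("need at least one block")
    n2 = len(blocks[0].codes)
    gamma = np.zeros((n2, n2))
    for b in blocks:
        Z = np.zeros((n2, b.n_alleles))
        Z[np.arange(n2), b.codes] = 1.0
        gamma += Z @ Z.T
    gamma /= len(blocks)
    H = (gamma[0::2, 0::2] + gamma[0::2, 1::2]
         + gamma[1::2, 0::2] + gamma[1::2, 1::2]) / 2.0
    return (H, gamma) if return_gamma else H


def _combination_levels(block: HaplotypeBlock, min_carriers: int = RARE_CARRIER_MIN):
    """Integer level per individual for the unordered allele-code pair;
    levels carried by < min_carriers individuals merge into one 'rare'."""
    pairs = block.pairs()
    uniq, inv, counts = np.unique(pairs, axis=0, return_inverse=True,
                                  return_counts=True)
    levels = inv.copy()
    rare = counts < min_carriers
    if rare.any():
        rare_code = len(uniq)
        levels[np.isin(inv, np.flatnonzero(rare))] = rare_code
    _, levels = np.unique(levels, return_inverse=True)
    return levels


def hgwas_scan(y, blocks: list[HaplotypeBlock], H: np.ndarray,
               covariates=None, min_carriers: int = RARE_CARRIER_MIN) -> pd.DataFrame:
    """Two-step haplotype-block scan; returns per-block F-test p and BH q."""
    y = np.asarray(y, float)
    keep = np.isfinite(y)
    y_ = y[keep]
    if np.ptp(y_) == 0:
        raise ValueError("degenerate trait: constant after missing removal")
    ind = np.flatnonzero(keep)
    H_ = np.asarray(H, float)[np.ix_(ind, ind)]
    cov_ = None if covariates is None else np.asarray(covariates, float)[ind]
    Q = _design(len(y_), cov_, None)
    null = fit_null_lmm(y_, Q, H_)
    resid = null.conditional_residuals()

    n = len(resid)
    tss = float(np.sum((resid - resid.mean()) ** 2))
    rows = []
    for b in blocks:
        bb = b.subset(ind) if len(ind) != len(b.codes) // 2 else b
        levels = _combination_levels(bb, min_carriers)
        k = levels.max() + 1
        if k < 2 or tss <= 0:
            rows.append((b.id, b.chrom, b.start, b.end, k, 1.0))
            continue
        means = np.bincount(levels, weights=resid) / np.bincount(levels)
        fitted = means[levels]
        ssb = float(np.sum((fitted - resid.mean()) ** 2))
        ssw = max(tss - ssb, 0.0)
        df1, df2 = k - 1, n - k
        if df2 <= 0 or ssw <= 0:
            rows.append((b.id, b.chrom, b.start, b.end, k, 1.0))
            continue
        F = (ssb / df1) / (ssw / df2)
        p = float(stats.f.sf(F, df1, df2))
        rows.append((b.id, b.chrom, b.start, b.end, k, max(p, np.finfo(float).tiny)))
    out = pd.DataFrame(rows, columns=["block", "chrom", "start", "end",
                                      "n_levels", "p"])
    out["q"] = bh_fdr(out["p"].to_numpy())
    return out


def dosage_code(block: HaplotypeBlock) -> np.ndarray:
    """N x n_alleles matrix counting copies (0/1/2) of each allele; row sums 2."""
    n2 = len(block.codes)
    Z = np.zeros((n2, block.n_alleles))
    Z[np.arange(n2), block.codes] = 1.0
    return Z[0::2] + Z[1::2]


def _drop_collinear(X: np.ndarray, tol: float = 1e-8):
    from scipy.linalg import qr

    if X.shape[1] == 0:
        return np.array([], dtype=int)
    _, R, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    rank = int(np.sum(diag > tol * max(diag[0], 1.0)))
    return np.sort(piv[:rank])


def estimate_allele_effects(y, blocks: list[HaplotypeBlock], covariates=None,
                            direction: int = +1, alpha: float = 0.05,
                            joint: bool = True) -> pd.DataFrame:
    """Fixed-effect estimates for haplotype alleles in significant blocks.

    One reference allele per block (the most frequent, code 0) is dropped
    for identifiability; effects are per-copy deviations from it. With
    ``joint=True`` all blocks enter one OLS; otherwise one model per
    block. ``direction`` is the trait's desirable direction (+1 higher is
    better): significant alleles pushing the trait the desirable way are
    BHA, the others UHA.
    """
    y = np.asarray(y, float)
    keep = np.isfinite(y)
    ind = np.flatnonzero(keep)
    y_ = y[keep]
    cov_ = None if covariates is None else np.asarray(covariates, float)[ind]
    if not blocks:
        return pd.DataFrame(columns=["block", "code", "allele", "freq",
                                     "effect", "se", "p", "cls"])

    def fit_group(group: list[HaplotypeBlock]) -> pd.DataFrame:
        cols, labels = [], []
        for b in group:
            bb = b.subset(ind) if len(ind) != len(b.codes) // 2 else b
            D = dosage_code(bb)
            for code in range(1, b.n_alleles):  # drop code 0 = reference
                cols.append(D[:, code])
                labels.append((b.id, code, b.allele_seq(code), float(b.freqs[code])))
        if not cols:
            return pd.DataFrame(columns=["block", "code", "allele", "freq",
                                         "effect", "se", "p", "cls"])
        X = np.column_stack(cols)
        Q = _design(len(y_), cov_, None)
        full = np.hstack([Q, X])
        keep_cols = _drop_collinear(full)
        kept_x = [j - Q.shape[1] for j in keep_cols if j >= Q.shape[1]]
        dropped = X.shape[1] - len(kept_x)
        if dropped:
            warnings.warn(f"dropped {dropped} collinear dosage columns")
        import statsmodels.api as sm

        design = np.hstack([Q, X[:, kept_x]])
        fit = sm.OLS(y_, design).fit()
        recs = []
        for pos_in_x, j in enumerate(kept_x):
            bid, code, seq, freq = labels[j]
            est = fit.params[Q.shape[1] + pos_in_x]
            se = fit.bse[Q.shape[1] + pos_in_x]
            pv = fit.pvalues[Q.shape[1] + pos_in_x]
            if pv < alpha:
                cls = "BHA" if est * direction > 0 else "UHA"
            else:
                cls = "neutral"
            recs.append((bid, code, seq, freq, est, se, pv, cls))
        return pd.DataFrame(recs, columns=["block", "code", "allele", "freq",
                                           "effect", "se", "p", "cls"])

    if joint:
        return fit_group(blocks)
    return pd.concat([fit_group([b]) for b in blocks], ignore_index=True)
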