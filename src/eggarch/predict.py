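"""Haplotype-based phenotype prediction (HPPS, HBLUP) and GBLUP baselines
with a fixed-validation-set cross-validation protocol.

HPPS sums estimated fixed allele effects times dosages over significant
blocks (variants: all blocks, blocks containing beneficial alleles only,
or blocks containing unbeneficial alleles only). HBLUP treats allele
effects as i.i.d. random effects (a ridge-type mixed model); GBLUP
predicts via a genomic relationship matrix without per-marker effects.

The protocol draws a fixed validation set per repeat, excludes it from
all training, and inside each repeat runs k-fold training on the
remainder; block discovery and effect estimation are re-done within each
training split so no phenotype information leaks into prediction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .assoc_hap import HaplotypeBlock, dosage_code, estimate_allele_effects, hgwas_scan
from .assoc_snp import _design
from .lmm import fit_null_lmm

METHODS = ("hpps-all", "hpps-bene", "hpps-unbe", "hblup", "gblup-snp", "gblup-hap")


class LeakageError(RuntimeError):
    """A validation individual appeared in a training design."""


def hpps(effects: pd.DataFrame, blocks_by_id: dict[int, HaplotypeBlock],
         subset: str = "all") -> np.ndarray:
    """Per-individual polygenic score = sum(effect x dosage) over the
    chosen subset of significant blocks ('all' | 'bene' | 'unbe')."""
    if subset not in ("all", "bene", "unbe"):
        raise ValueError(subset)
    if subset == "all":
        use_blocks = set(effects["block"])
    else:
        cls = "BHA" if subset == "bene" else "UHA"
        use_blocks = set(effects.loc[effects["cls"] == cls, "block"])
    any_block = next(iter(blocks_by_id.values()))
    n = len(any_block.codes) // 2
    score = np.zeros(n)
    if not use_blocks:
        warnings.warn(f"subset {subset!r} empty: zero scores")
        return score
    for bid, sub in effects.groupby("block"):
        if bid not in use_blocks:
            continue
        D = dosage_code(blocks_by_id[bid])
        for _, row in sub.iterrows():
            score += row["effect"] * D[:, int(row["code"])]
    return score


@dataclass
class BlupFit:
    alpha: np.ndarray
    sigma_g2: float
    sigma_e2: float
    train_idx: np.ndarray
    _vinv_r: np.ndarray  # V^{-1} (y_tr - Q_tr alpha), for covariance prediction

    def predict_from_cov(self, Q_new: np.ndarray, C_new_tr: np.ndarray) -> np.ndarray:
        """Q_new alpha + sigma_g2 * C_new,tr V_tr^{-1} (y_tr - Q_tr alpha)."""
        return Q_new @ self.alpha + self.sigma_g2 * (C_new_tr @ self._vinv_r)


def _fit_blup(y_tr, Q_tr, K_tr) -> BlupFit:
    null = fit_null_lmm(y_tr, Q_tr, K_tr)
    r = y_tr - Q_tr @ null.alpha
    # V^{-1} r = U diag(w) U' r / sigma_g2
    vinv_r = null.U @ (null.weights * (null.U.T @ r)) / null.sigma_g2
    return BlupFit(alpha=null.alpha, sigma_g2=null.sigma_g2,
                   sigma_e2=null.sigma_e2, train_idx=np.array([]), _vinv_r=vinv_r)


def gblup_fit(y, K: np.ndarray, train_idx, val_idx, covariates=None) -> np.ndarray:
    """Train a GRM-based BLUP on `train_idx`, predict `val_idx`.

    Out-of-sample genetic values come through the genomic covariance
    between validation and training individuals.
    """
    train_idx = np.asarray(train_idx)
    val_idx = np.asarray(val_idx)
    y = np.asarray(y, float)
    K = np.asarray(K, float)
    cov = None if covariates is None else np.asarray(covariates, float)
    Q_tr = _design(len(train_idx), None if cov is None else cov[train_idx], None)
    Q_val = _design(len(val_idx), None if cov is None else cov[val_idx], None)
    fit = _fit_blup(y[train_idx], Q_tr, K[np.ix_(train_idx, train_idx)])
    return fit.predict_from_cov(Q_val, K[np.ix_(val_idx, train_idx)])


def hblup_fit(y, Z: np.ndarray, train_idx, val_idx, covariates=None) -> np.ndarray:
    """Ridge-type mixed model with i.i.d. random allele effects.

    Z is the N x A dosage matrix of significant-block alleles. Equivalent
    to GBLUP on K = Z Z' (per-allele variance absorbed into sigma_g2), so
    prediction uses the Z_val Z_tr' covariance.
    """
    train_idx = np.asarray(train_idx)
    val_idx = np.asarray(val_idx)
    y = np.asarray(y, float)
    Z = np.asarray(Z, float)
    cov = None if covariates is None else np.asarray(covariates, float)
    Q_tr = _design(len(train_idx), None if cov is None else cov[train_idx], None)
    Q_val = _design(len(val_idx), None if cov is None else cov[val_idx], None)
    Z_tr, Z_val = Z[train_idx], Z[val_idx]
    fit = _fit_blup(y[train_idx], Q_tr, Z_tr @ Z_tr.T)
    return fit.predict_from_cov(Q_val, Z_val @ Z_tr.T)


def _significant_blocks(scan: pd.DataFrame, fdr: float = 0.05) -> list[int]:
    """FDR hits; falls back to nominal p < 0.05, then the 5 smallest p."""
    hit = scan.loc[scan["q"] <= fdr, "block"]
    if len(hit):
        return hit.tolist()
    hit = scan.loc[scan["p"] < 0.05, "block"]
    if len(hit):
        return hit.tolist()
    return scan.nsmallest(5, "p")["block"].tolist()


def _safe_corr(a, b) -> float:
    if np.std(a) == 0 or np.std(b) == 0 or not (np.all(np.isfinite(a))
                                                and np.all(np.isfinite(b))):
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


@dataclass
class CVReport:
    method: str
    per_repeat: np.ndarray

    @property
    def mean_correlation(self) -> float:
        return float(np.mean(self.per_repeat))


def cross_validate(method: str, y, blocks: list[HaplotypeBlock] | None = None,
                   H: np.ndarray | None = None, grm: np.ndarray | None = None,
                   covariates=None, direction: int = +1,
                   n_validation: int = 100, folds: int = 10, repeats: int = 50,
                   seed: int = 0, fdr: float = 0.05,
                   reuse_discovery: pd.DataFrame | None = None) -> CVReport:
    """Fixed-validation-set cross-validation of one prediction method.

    Per repeat: draw `n_validation` individuals as the fixed validation
    set, split the remainder into `folds` folds, train on each
    (folds-1)/folds portion, predict the validation set, and record the
    mean Pearson correlation over folds. Haplotype methods re-run block
    discovery (hgwas_scan) and effect estimation inside every training
    split unless `reuse_discovery` passes a whole-data scan (the leaky
    variant, for comparison only).
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}")
    y = np.asarray(y, float)
    cov = None if covariates is None else np.asarray(covariates, float)
    finite = np.isfinite(y)
    if not finite.all():  # complete cases only: missing traits drop out
        idx = np.flatnonzero(finite)
        y = y[idx]
        cov = None if cov is None else cov[idx]
        H = None if H is None else np.asarray(H, float)[np.ix_(idx, idx)]
        grm = None if grm is None else np.asarray(grm, float)[np.ix_(idx, idx)]
        blocks = None if blocks is None else [b.subset(idx) for b in blocks]
    n = len(y)
    if n <= n_validation + folds:
        raise ValueError("too few individuals for the requested protocol")
    blocks_by_id = {b.id: b for b in (blocks or [])}
    rng = np.random.default_rng(seed)

    per_repeat = []
    for _ in range(repeats):
        val_idx = rng.choice(n, size=n_validation, replace=False)
        rest = np.setdiff1d(np.arange(n), val_idx)
        rest = rng.permutation(rest)
        fold_sets = np.array_split(rest, folds)
        fold_corrs = []
        for f in range(folds):
            train_idx = np.concatenate([fold_sets[j] for j in range(folds) if j != f])
            if np.intersect1d(train_idx, val_idx).size:
                raise LeakageError("validation individual in training design")
            if method.startswith("hpps") or method == "hblup":
                if reuse_discovery is not None:
                    scan = reuse_discovery
                else:
                    y_tr = np.full(n, np.nan)
                    y_tr[train_idx] = y[train_idx]
                    scan = hgwas_scan(y_tr, blocks, H,
                                      covariates=None if cov is None else cov)
                sig_ids = _significant_blocks(scan, fdr)
                sig_blocks = [blocks_by_id[b] for b in sig_ids]
                y_tr_only = np.full(n, np.nan)
                y_tr_only[train_idx] = y[train_idx]
                eff = estimate_allele_effects(y_tr_only, sig_blocks,
                                              covariates=cov,
                                              direction=direction)
                if method == "hblup":
                    cols = [dosage_code(blocks_by_id[b.id])[:, 1:] for b in sig_blocks]
                    Z = np.hstack(cols) if cols else np.zeros((n, 1))
                    pred = hblup_fit(y, Z, train_idx, val_idx, covariates=cov)
                else:
                    subset = method.split("-")[1]
                    score = hpps(eff, blocks_by_id, subset=subset)
                    pred = score[val_idx]
            elif method == "gblup-snp":
                pred = gblup_fit(y, grm, train_idx, val_idx, covariates=cov)
            elif method == "gblup-hap":
                pred = gblup_fit(y, H, train_idx, val_idx, covariates=cov)
            fold_corrs.append(_safe_corr(pred, y[val_idx]))
        per_repeat.append(float(np.mean(fold_corrs)))
    return CVReport(method=method, per_repeat=np.asarray(per_repeat))
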