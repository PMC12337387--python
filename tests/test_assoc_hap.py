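"""Haplotype blocks, the haplotype GRM, the two-step scan, and allele
effects."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_block
from eggarch import assoc_hap, genio
from eggarch.assoc_hap import (build_blocks, dosage_code,
                               estimate_allele_effects, hap_grm, hgwas_scan)


def _toy_genotypes(hap, positions=None, chrom="chr1"):
    hap = np.asarray(hap, dtype=np.int8)
    m = hap.shape[1]
    pos = positions if positions is not None else np.arange(1, m + 1) * 10
    variants = pd.DataFrame({"chrom": chrom, "pos": pos,
                             "id": [f"v{i}" for i in range(m)],
                             "ref": "A", "alt": "G"})
    samples = [f"i{k}" for k in range(hap.shape[0] // 2)]
    return genio.PhasedGenotypes(samples=samples, variants=variants, hap=hap)


def test_block_partition_drops_remainder():
    rng = np.random.default_rng(0)
    g = _toy_genotypes(rng.integers(0, 2, size=(8, 12)))
    blocks = build_blocks(g, block_size=5)
    assert len(blocks) == 2  # 12 SNPs -> 2 blocks, 2 SNPs dropped
    assert blocks[0].snp_cols.tolist() == [0, 1, 2, 3, 4]
    assert blocks[1].snp_cols.tolist() == [5, 6, 7, 8, 9]


def test_block_short_chromosome_warns():
    g = _toy_genotypes(np.zeros((4, 3), dtype=np.int8))
    with pytest.warns(UserWarning):
        blocks = build_blocks(g, block_size=5)
    assert blocks == []


def test_identical_haplotypes_single_allele():
    g = _toy_genotypes(np.tile([1, 0, 1, 0, 1], (6, 1)))
    (block,) = build_blocks(g)
    assert block.n_alleles == 1
    assert block.freqs[0] == 1.0


def test_allele_catalogue_frequencies():
    hap = np.array([[0, 0, 0, 0, 0],
                    [0, 0, 0, 0, 1],
                    [1, 1, 1, 1, 1],
                    [1, 1, 1, 1, 1]], dtype=np.int8)
    (block,) = build_blocks(_toy_genotypes(hap))
    assert block.n_alleles == 3
    np.testing.assert_allclose(sorted(block.freqs), [0.25, 0.25, 0.5])
    assert block.freqs[0] == 0.5  # code 0 is the most frequent allele


def brute_force_H(blocks, n_ind):
    """Loop over haplotype pairs: the independent oracle for H."""
    H = np.zeros((n_ind, n_ind))
    for j in range(n_ind):
        for k in range(n_ind):
            acc = 0.0
            for b in blocks:
                for hj in (2 * j, 2 * j + 1):
                    for hk in (2 * k, 2 * k + 1):
                        acc += float(b.codes[hj] == b.codes[hk])
            H[j, k] = acc / len(blocks) / 2.0
    return H


def test_hap_grm_worked_example():
    """Individuals carrying (h1,h2) and (h1,h1) give H = [[1,1],[1,2]]."""
    block = make_block([0, 1, 0, 0])
    H = hap_grm([block])
    np.testing.assert_allclose(H, [[1.0, 1.0], [1.0, 2.0]], atol=1e-12)


def test_hap_grm_bounds():
    # homozygous everywhere -> diagonal 2
    b_hom = make_block([0, 0, 1, 1, 2, 2])
    H = hap_grm([b_hom])
    np.testing.assert_allclose(np.diag(H), [2.0, 2.0, 2.0])
    # no shared alleles, all heterozygous -> identity
    b_dist = make_block([0, 1, 2, 3, 4, 5])
    np.testing.assert_allclose(hap_grm([b_dist]), np.eye(3), atol=1e-12)


def test_hap_grm_brute_force_random_instances():
    rng = np.random.default_rng(1)
    for _ in range(20):
        n_ind = int(rng.integers(2, 7))
        blocks = [make_block(rng.integers(0, rng.integers(2, 5),
                                          size=2 * n_ind), n_alleles=5,
                             block_id=i)
                  for i in range(int(rng.integers(1, 5)))]
        H, gamma = hap_grm(blocks, return_gamma=True)
        np.testing.assert_allclose(H, brute_force_H(blocks, n_ind), atol=1e-12)
        np.testing.assert_allclose(gamma, gamma.T)
        np.testing.assert_allclose(np.diag(gamma), 1.0)
        assert np.diag(H).min() >= 1.0 - 1e-12
        assert np.diag(H).max() <= 2.0 + 1e-12


def test_dosage_code_pairs():
    block = make_block([0, 0, 0, 1, 1, 2])  # (A1,A1), (A1,A2), (A2,A3)
    D = dosage_code(block)
    np.testing.assert_allclose(D, [[2, 0, 0], [1, 1, 0], [0, 1, 1]])
    np.testing.assert_allclose(D.sum(axis=1), 2.0)


def test_dosage_rows_sum_two(small_blocks):
    for b in small_blocks:
        np.testing.assert_allclose(dosage_code(b).sum(axis=1), 2.0)


def test_hgwas_constant_trait_raises(small_blocks):
    H = hap_grm(small_blocks)
    with pytest.raises(ValueError):
        hgwas_scan(np.zeros(len(small_blocks[0].codes) // 2), small_blocks, H)


def test_hgwas_single_level_block_p_one():
    rng = np.random.default_rng(2)
    mono = make_block(np.zeros(40, dtype=int), block_id=0)
    poly = make_block(rng.integers(0, 2, size=40), block_id=1)
    H = hap_grm([mono, poly])
    res = hgwas_scan(rng.normal(size=20), [mono, poly], H)
    assert res.loc[res["block"] == 0, "p"].iloc[0] == 1.0


def test_rare_combination_merging():
    codes = np.array([0] * 36 + [1, 2, 3, 4])  # 2 rare heterozygotes
    block = make_block(codes)
    levels = assoc_hap._combination_levels(block)
    assert levels.max() + 1 == 2  # common homozygote + merged rare


def test_allele_effect_noiseless_recovery():
    rng = np.random.default_rng(3)
    codes = rng.integers(0, 3, size=120)
    block = make_block(codes)
    D = dosage_code(block)
    # +1 per copy of allele 1 vs reference; vanishing noise keeps the
    # residual variance (hence the t-test) defined
    y = 1.0 * D[:, 1] + 0.25 + rng.normal(0, 1e-7, len(D))
    eff = estimate_allele_effects(y, [block], direction=+1)
    row = eff[(eff["block"] == 0) & (eff["code"] == 1)].iloc[0]
    assert row["effect"] == pytest.approx(1.0, abs=1e-5)
    assert row["cls"] == "BHA"
    row2 = eff[(eff["code"] == 2)].iloc[0]
    assert row2["effect"] == pytest.approx(0.0, abs=1e-5)


def test_allele_effect_no_blocks_empty():
    eff = estimate_allele_effects(np.random.default_rng(0).normal(size=10), [])
    assert eff.empty


def test_allele_effect_direction_registry():
    """With a lower-is-better trait, a trait-decreasing allele is BHA."""
    rng = np.random.default_rng(4)
    codes = rng.integers(0, 2, size=100)
    block = make_block(codes)
    D = dosage_code(block)
    y = -2.0 * D[:, 1] + rng.normal(0, 0.1, 50)
    eff = estimate_allele_effects(y, [block], direction=-1)
    assert eff[(eff["code"] == 1)].iloc[0]["cls"] == "BHA"


def test_two_step_matches_exact_gls_ranking(small_backbone):
    """Two-step residual p-values track exact one-step GLS F-tests."""
    from scipy import stats as sps

    from eggarch.lmm import fit_null_lmm

    rng = np.random.default_rng(5)
    blocks = build_blocks(small_backbone)
    H = hap_grm(blocks)
    n = small_backbone.n_individuals
    L = np.linalg.cholesky(H + 1e-6 * np.eye(n))
    y = L @ rng.normal(size=n) * 0.6 + rng.normal(size=n)
    two_step = hgwas_scan(y, blocks, H)

    null = fit_null_lmm(y, np.ones((n, 1)), H)
    yw = null.whiten(y)
    qw = null.whiten(np.ones((n, 1)))
    exact_p = []
    for b in blocks:
        levels = assoc_hap._combination_levels(b)
        k = levels.max() + 1
        if k < 2:
            exact_p.append(1.0)
            continue
        Z = np.zeros((n, k))
        Z[np.arange(n), levels] = 1.0
        Xw = null.whiten(Z[:, 1:])
        X0 = qw
        X1 = np.hstack([qw, Xw])
        rss0 = float(yw @ yw - yw @ X0 @ np.linalg.lstsq(X0, yw, rcond=None)[0])
        beta1 = np.linalg.lstsq(X1, yw, rcond=None)[0]
        rss1 = float(np.sum((yw - X1 @ beta1) ** 2))
        df1, df2 = k - 1, n - 1 - k + 1 - 1
        F = ((rss0 - rss1) / df1) / (rss1 / max(df2, 1))
        exact_p.append(float(sps.f.sf(F, df1, max(df2, 1))))
    rho = sps.spearmanr(two_step["p"], exact_p).statistic
    assert rho >= 0.9
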