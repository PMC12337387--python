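"""Singleton-density scores, windowed statistics, and diversity oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from eggarch import genio, selection, simdata
from eggarch.selection import (find_singletons, msds_windows, raw_sds,
                               standardize_sds, tajima_pi_windows,
                               tsds_polarize, tsds_trend)


def _genotypes(hap, positions, chrom="chr1"):
    hap = np.asarray(hap, dtype=np.int8)
    variants = pd.DataFrame({"chrom": chrom, "pos": positions,
                             "id": [f"v{i}" for i in range(hap.shape[1])],
                             "ref": "A", "alt": "G"})
    return genio.PhasedGenotypes(
        samples=[f"i{k}" for k in range(hap.shape[0] // 2)],
        variants=variants, hap=hap)


def test_singletons_recovered_exactly(small_cohort):
    g, _ = small_cohort
    found = find_singletons(g)
    truth = g.meta["singletons"]
    for h, expected in truth.items():
        got = sorted((c, int(p)) for c, arr in found[h].items() for p in arr)
        assert got == expected


def test_doubleton_not_a_singleton():
    hap = np.array([[1, 1], [0, 1], [0, 0], [0, 0]], dtype=np.int8)
    g = _genotypes(hap, [100, 200])
    found = find_singletons(g)
    all_pos = [int(p) for h in found.values() for arr in h.values() for p in arr]
    assert all_pos == [100]  # AC=1 site only; AC=2 site excluded


def test_raw_sds_hand_computed_gap_ratio():
    """Ref haplotypes with 10 kb gaps on each side, alt haplotypes with
    40 kb gaps: rSDS = ln(80000) - ln(20000) = ln 4."""
    P = 100_000  # test SNP position
    pos = [P - 40_000, P - 10_000, P - 10_000 + 1, P - 40_000 + 1, P,
           P + 10_000, P + 40_000, P + 10_000 + 1, P + 40_000 + 1]
    # columns: 4 upstream singletons, test SNP, 4 downstream singletons
    hap = np.zeros((4, 9), dtype=np.int8)
    hap[:, 4] = [0, 0, 1, 1]  # 2 ref, 2 alt carriers at the test SNP
    hap[0, 1], hap[0, 5] = 1, 1  # ref hap 0: +/-10 kb
    hap[1, 2], hap[1, 7] = 1, 1  # ref hap 1: +/-10 kb (offset by 1 bp)
    hap[2, 0], hap[2, 6] = 1, 1  # alt hap 2: +/-40 kb
    hap[3, 3], hap[3, 8] = 1, 1  # alt hap 3: +/-40 kb (offset by 1 bp)
    order = np.argsort(pos)
    g = _genotypes(hap[:, order], np.array(pos)[order])
    test_col = int(np.flatnonzero(g.variants["pos"] == P)[0])
    res = raw_sds(g, [test_col])
    # per-haplotype gap sums: ref 20,000 each; alt 80,000 each (the 1-bp
    # offsets cancel within each haplotype)
    assert res["rsds"].iloc[0] == pytest.approx(np.log(4.0), abs=1e-9)


def test_raw_sds_symmetry_and_antisymmetry(small_cohort):
    g, _ = small_cohort
    cols = np.flatnonzero(~g.meta["is_singleton_site"])[::6]
    res = raw_sds(g, cols)
    flipped = genio.PhasedGenotypes(samples=list(g.samples),
                                    variants=g.variants.copy(),
                                    hap=g.hap.copy(), meta=dict(g.meta))
    flipped.hap[:, cols] = 1 - flipped.hap[:, cols]
    res_f = raw_sds(flipped, cols)
    both = np.isfinite(res["rsds"].to_numpy()) & np.isfinite(res_f["rsds"].to_numpy())
    np.testing.assert_allclose(res["rsds"].to_numpy()[both],
                               -res_f["rsds"].to_numpy()[both], atol=1e-10)


def test_raw_sds_missing_when_too_few_carriers():
    hap = np.zeros((4, 3), dtype=np.int8)
    hap[0, 1] = 1  # test SNP carried by one haplotype only
    hap[0, 0], hap[1, 2] = 1, 1  # some singletons
    g = _genotypes(hap, [10, 50, 90])
    res = raw_sds(g, [1])
    assert np.isnan(res["rsds"].iloc[0])


def _score_frame(rng, n=400):
    return pd.DataFrame({
        "chrom": "chr1", "pos": np.arange(1, n + 1) * 997,
        "af": rng.uniform(0.05, 0.95, n), "rsds": rng.normal(size=n)})


def test_standardize_bins_centered_unit_sd():
    rng = np.random.default_rng(0)
    df = _score_frame(rng, 2000)
    out = standardize_sds(df)
    for _, sub in out.groupby("bin"):
        assert abs(sub["sds"].mean()) < 1e-8
        assert sub["sds"].std(ddof=0) == pytest.approx(1.0, abs=1e-8)


def test_standardize_range_rule_and_rank_preservation():
    rng = np.random.default_rng(1)
    df = _score_frame(rng, 600)
    df.loc[0, "af"] = 0.96
    out = standardize_sds(df)
    assert df.loc[0, "pos"] not in set(out["pos"])
    sub = out[out["bin"] == out["bin"].iloc[0]]
    raw_rank = sub["rsds"].rank()
    std_rank = sub["sds"].rank()
    assert (raw_rank == std_rank).all()


def test_standardize_idempotent():
    rng = np.random.default_rng(2)
    out = standardize_sds(_score_frame(rng, 1500))
    again = standardize_sds(out.rename(columns={"sds": "tmp"}),
                            score_col="tmp")
    np.testing.assert_allclose(out["sds"].to_numpy(), again["sds"].to_numpy(),
                               atol=1e-8)


def test_msds_window_convention():
    df = pd.DataFrame({"chrom": ["chr1", "chr1", "chr1"],
                       "pos": [10_000, 49_999, 50_000],
                       "sds": [1.0, -1.0, 2.5]})
    out = msds_windows(df, window=50_000)
    assert len(out) == 2
    first = out[out["start"] == 0].iloc[0]
    assert first["msds"] == pytest.approx(0.0)  # +1 and -1 average to 0
    second = out[out["start"] == 50_000].iloc[0]
    assert second["msds"] == 2.5  # pos 50,000 falls in the second window


def test_tsds_polarization():
    rng = np.random.default_rng(3)
    sds = pd.DataFrame({"chrom": "chr1", "pos": np.arange(1, 51) * 10,
                        "sds": rng.normal(size=50)})
    assoc = pd.DataFrame({"chrom": "chr1", "pos": np.arange(1, 51) * 10,
                          "beta": np.abs(rng.normal(size=50)) + 0.01,
                          "p": rng.uniform(size=50)})
    t1 = tsds_polarize(sds, assoc)
    np.testing.assert_allclose(t1["tsds"], t1["sds"])  # all beta > 0
    assoc2 = assoc.assign(beta=-assoc["beta"])
    t2 = tsds_polarize(sds, assoc2)
    np.testing.assert_allclose(t2["tsds"], -t1["tsds"])
    assoc3 = assoc.assign(beta=0.0)
    assert tsds_polarize(sds, assoc3)["tsds"].isna().all()


def test_tsds_trend_monotone_and_insufficient():
    n = 300
    df = pd.DataFrame({"tsds": np.linspace(-1, 1, n),
                       "p": np.linspace(1, 1e-8, n)})
    rho, p, means = tsds_trend(df, bin_size=30)
    assert rho == pytest.approx(1.0)
    assert len(means) == 10
    with pytest.raises(ValueError):
        tsds_trend(df, bin_size=500)


def test_tsds_trend_null_centered():
    rng = np.random.default_rng(4)
    coefs = []
    for _ in range(100):
        df = pd.DataFrame({"tsds": rng.normal(size=300),
                           "p": rng.uniform(size=300)})
        coefs.append(tsds_trend(df, bin_size=30)[0])
    se = np.std(coefs) / np.sqrt(len(coefs))
    assert abs(np.mean(coefs)) < 2 * se + 1e-12


def test_pi_zero_for_identical_haplotypes():
    # every haplotype identical -> no site segregates
    g = _genotypes(np.zeros((6, 4), dtype=np.int8), [10, 20, 30, 40])
    win = tajima_pi_windows(g)
    assert (win["pi"] == 0).all()
    assert win["tajima_d"].isna().all()


def test_tajima_hand_computed_oracle():
    """4 haplotypes, 3 segregating sites: D and pi match a from-scratch
    computation via average pairwise differences."""
    hap = np.array([
        [1, 0, 0],
        [1, 1, 0],
        [0, 0, 1],
        [0, 0, 0]], dtype=np.int8)
    g = _genotypes(hap, [1000, 2000, 3000])
    win = tajima_pi_windows(g, window=100_000).iloc[0]

    n = 4
    k_pairs = [np.sum(hap[i] != hap[j])
               for i, j in itertools.combinations(range(n), 2)]
    pi_sum = float(np.mean(k_pairs))
    S = 3
    a1 = sum(1 / i for i in range(1, n))
    a2 = sum(1 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1, e2 = c1 / a1, c2 / (a1**2 + a2)
    D = (pi_sum - S / a1) / np.sqrt(e1 * S + e2 * S * (S - 1))
    assert win["tajima_d"] == pytest.approx(D, abs=1e-10)
    assert win["pi"] == pytest.approx(pi_sum / 100_000, abs=1e-15)
    assert win["n_seg"] == 3


def test_neutral_coalescent_tajima_d_near_zero():
    """On msprime neutral constant-size simulations the windowed D
    averages near 0 and pi matches tskit's site diversity."""
    import msprime

    means = []
    for seed in range(1, 11):
        ts = msprime.sim_ancestry(samples=20, population_size=10_000,
                                  sequence_length=1_000_000,
                                  recombination_rate=1e-8, random_seed=seed)
        ts = msprime.sim_mutations(ts, rate=1.5e-8, random_seed=seed)
        gm = ts.genotype_matrix()
        bi = np.array([len(v.alleles) == 2 for v in ts.variants()])
        pos = ts.tables.sites.position.astype(int)[bi] + 1
        _, uniq = np.unique(pos, return_index=True)
        hap = gm[bi][uniq].T.astype(np.int8)
        g = _genotypes(hap, pos[uniq])
        win = tajima_pi_windows(g, window=100_000)
        means.append(win["tajima_d"].mean())
        if seed == 1:
            total_pi = float((win["pi"] * 100_000).sum()) / ts.sequence_length
            assert total_pi == pytest.approx(
                float(ts.diversity(span_normalise=True)), rel=0.02)
    assert abs(float(np.mean(means))) < 0.3


def test_sparser_singletons_on_swept_haplotypes_give_positive_rsds():
    """Thinning singletons on alternative-allele haplotypes (a sweep
    surrogate) drives the mean rSDS at the swept SNP positive."""
    scores = []
    for seed in range(20):
        rng = np.random.default_rng(seed)
        cfg = simdata.SimConfig(n_individuals=40, n_snps_per_chrom=60,
                                n_chroms=1, chrom_length_bp=2_000_000,
                                mutation_density=0.0, seed=seed)
        g = simdata.simulate_haplotypes(cfg)
        col = 30
        alt = g.hap[:, col] == 1
        if alt.sum() < 2 or (~alt).sum() < 2:
            continue
        rates = np.where(alt, 2.0, 8.0)  # alt haplotypes 4x sparser
        g2 = simdata.inject_singletons(g, rates, seed=seed + 1000)
        col2 = int(np.flatnonzero(~g2.meta["is_singleton_site"])[col])
        res = raw_sds(g2, [col2])
        scores.append(res["rsds"].iloc[0])
    assert np.nanmean(scores) > 0
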