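import numpy as np
import pytest

from eggarch import assoc_hap, curves, simdata, traits


@pytest.fixture(scope="session")
def small_cohort():
    """60 individuals, 2 chromosomes x 120 SNPs, with singletons."""
    cfg = simdata.SimConfig(n_individuals=60, n_snps_per_chrom=120, n_chroms=2,
                            chrom_length_bp=2_000_000, mutation_density=5.0,
                            recombination_prob=0.02, seed=11)
    return simdata.simulate_haplotypes(cfg), cfg


@pytest.fixture(scope="session")
def small_backbone(small_cohort):
    g, _ = small_cohort
    return simdata.backbone_only(g)


@pytest.fixture(scope="session")
def small_blocks(small_backbone):
    return assoc_hap.build_blocks(small_backbone)


@pytest.fixture(scope="session")
def laying_cohort():
    """150 individuals with one planted SNP QTL driving the laying rate."""
    cfg = simdata.SimConfig(n_individuals=150, n_snps_per_chrom=150, n_chroms=1,
                            chrom_length_bp=3_000_000, mutation_density=0.0,
                            qtl_list=[simdata.QTLSpec(("chr1", 75), 1.0, "snp")],
                            h2_target=0.4, seed=21)
    g = simdata.simulate_haplotypes(cfg)
    rec = simdata.simulate_laying_records(g, cfg)
    return g, rec, cfg


@pytest.fixture(scope="session")
def default_stages():
    return curves.StageDefinition(up=(21, 26), sustained=(27, 43))


@pytest.fixture(scope="session")
def trait_table(laying_cohort, default_stages):
    _, rec, _ = laying_cohort
    return traits.derive_traits(rec, default_stages)


def make_block(codes, n_alleles=None, block_id=0):
    """HaplotypeBlock from an explicit per-haplotype allele-code vector."""
    codes = np.asarray(codes, dtype=np.int32)
    k = int(n_alleles if n_alleles is not None else codes.max() + 1)
    freqs = np.bincount(codes, minlength=k) / len(codes)
    alleles = np.zeros((k, 5), dtype=np.int8)
    alleles[:, -1] = np.arange(k) % 2
    alleles[:, 0] = np.arange(k)  # distinct rows (sequences unused in math)
    return assoc_hap.HaplotypeBlock(
        id=block_id, chrom="chr1", snp_cols=np.arange(5), start=1, end=5,
        alleles=alleles, freqs=freqs, codes=codes)
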