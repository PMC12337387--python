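"""Synthetic cohorts with the statistical structure the pipeline assumes.

Phased haplotypes are generated by copying from a small founder pool with
per-SNP template switching, which creates block-level linkage
disequilibrium without a coalescent simulator and is exactly reproducible
from a seed. Singleton mutations are injected as separate private sites
(each used once), so selection statistics built on singleton density have
unambiguous ground truth. Daily laying records are Bernoulli draws around
a Yang-Ning-shaped weekly rate with additive genetic values from planted
QTLs and individual environmental noise, scaled to a target heritability
on the latent rate scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import curves
from .genio import VARIANT_COLUMNS, PhasedGenotypes

N_DAYS = 7 * curves.N_WEEKS  # 161 days covering weeks 21..43


class InvalidConfigError(ValueError):
    pass


class UnknownLocusError(KeyError):
    pass


@dataclass
class QTLSpec:
    """A planted causal locus: SNP index or 5-SNP block index on a chromosome."""

    locus: tuple  # (chrom, index); SNP index or block index within chrom
    effect: float  # trait units per allele copy
    kind: str = "snp"  # 'snp' | 'haplotype-allele'


@dataclass
class SimConfig:
    n_individuals: int = 600
    n_snps_per_chrom: int = 1000
    n_chroms: int = 5
    chrom_length_bp: int = 10_000_000
    mutation_density: float = 2.0  # singletons per haplotype per Mb
    recombination_prob: float = 0.01  # per-SNP template-switch probability
    n_founders: int = 8
    qtl_list: list = field(default_factory=list)
    curve_params: tuple = (0.837, 0.015, 1.182, 2.621)  # (a, b, c, d)
    h2_target: float = 0.3
    individual_sd: float = 0.15  # latent between-individual SD on the rate scale
    seed: int = 0

    def validate(self) -> None:
        if self.n_individuals < 1 or self.n_snps_per_chrom < 1 or self.n_chroms < 1:
            raise InvalidConfigError("counts must be positive")
        if self.chrom_length_bp <= 0:
            raise InvalidConfigError("chrom_length_bp must be positive")
        if not (0.0 <= self.recombination_prob <= 1.0):
            raise InvalidConfigError("recombination_prob must be in [0, 1]")
        if not (0.0 <= self.h2_target <= 1.0):
            raise InvalidConfigError("h2_target must be in [0, 1]")
        if self.mutation_density < 0 or self.individual_sd < 0:
            raise InvalidConfigError("densities and SDs must be non-negative")
        a = self.curve_params[0]
        if not (0.0 <= a <= 1.0):
            raise InvalidConfigError("curve max rate a must be in [0, 1]")


@dataclass
class LayingRecords:
    """Daily 0/1 laying indicators, N individuals x 161 days (weeks 21-43)."""

    samples: list[str]
    matrix: np.ndarray  # N x 161, int8 in {0, 1}
    truth: dict = field(default_factory=dict)

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=np.int8)
        if self.matrix.shape != (len(self.samples), N_DAYS):
            raise ValueError(f"matrix must be N x {N_DAYS}")
        if self.matrix.size and not np.isin(self.matrix, (0, 1)).all():
            raise ValueError("laying entries must be 0/1")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.matrix,
            index=pd.Index(self.samples, name="sample"),
            columns=[f"day_{d}" for d in range(1, N_DAYS + 1)],
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "LayingRecords":
        return cls(samples=list(df.index.astype(str)), matrix=df.to_numpy())


def week_day_slice(week: int) -> slice:
    """Day columns of week-of-age `week`: days 7(w-21)+1 .. 7(w-21)+7."""
    k = week - 21
    return slice(7 * k, 7 * k + 7)


def _distinct_positions(rng, n, length, taken=()):
    taken = set(taken)
    out = []
    while len(out) < n:
        for p in rng.integers(1, length + 1, size=max(2 * (n - len(out)), 16)):
            p = int(p)
            if p not in taken:
                taken.add(p)
                out.append(p)
                if len(out) == n:
                    break
    return sorted(out)


def simulate_haplotypes(config: SimConfig) -> PhasedGenotypes:
    """Generate 2N phased haplotypes over the backbone SNP set plus singletons.

    Returns a :class:`PhasedGenotypes` whose ``meta`` carries
    ``singletons`` (haplotype row -> list of (chrom, pos)) and
    ``is_singleton_site`` (bool per variant column).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_hap = 2 * config.n_individuals
    chrom_names = [f"chr{i + 1}" for i in range(config.n_chroms)]

    per_chrom = []
    for chrom in chrom_names:
        m = config.n_snps_per_chrom
        pos = _distinct_positions(rng, m, config.chrom_length_bp)
        # founder pool: per-site frequency then Bernoulli founder alleles
        p = rng.uniform(0.05, 0.95, size=m)
        founders = (rng.random((config.n_founders, m)) < p).astype(np.int8)
        # ensure polymorphism among founders at each site
        mono = founders.min(0) == founders.max(0)
        if mono.any():
            flip_rows = rng.integers(0, config.n_founders, size=int(mono.sum()))
            founders[flip_rows, np.flatnonzero(mono)] ^= 1
        # copy with template switching
        switch = rng.random((n_hap, m)) < config.recombination_prob
        switch[:, 0] = True
        draws = rng.integers(0, config.n_founders, size=(n_hap, m))
        cols = np.arange(m)
        last_sw = np.maximum.accumulate(np.where(switch, cols, -1), axis=1)
        founder_id = np.take_along_axis(draws, last_sw, axis=1)
        hap = founders[founder_id, cols]
        per_chrom.append((chrom, np.asarray(pos), hap))

    g = _assemble(config, chrom_names, per_chrom)
    return inject_singletons(
        g,
        np.full(n_hap, config.mutation_density),
        seed=int(rng.integers(0, 2**31 - 1)),
    )


def _assemble(config, chrom_names, per_chrom) -> PhasedGenotypes:
    frames, mats = [], []
    for chrom, pos, hap in per_chrom:
        frames.append(pd.DataFrame({
            "chrom": chrom, "pos": pos,
            "id": [f"{chrom}_{p}" for p in pos],
            "ref": "A", "alt": "G",
        }))
        mats.append(hap)
    variants = pd.concat(frames, ignore_index=True)[VARIANT_COLUMNS]
    samples = [f"ind{i + 1}" for i in range(config.n_individuals)]
    g = PhasedGenotypes(samples=samples, variants=variants, hap=np.hstack(mats))
    g.meta["chrom_length_bp"] = config.chrom_length_bp
    g.meta["is_singleton_site"] = np.zeros(g.n_variants, dtype=bool)
    g.meta["singletons"] = {}
    return g


def inject_singletons(g: PhasedGenotypes, density_per_mb, seed: int) -> PhasedGenotypes:
    """Sprinkle private singleton sites onto existing backbone genotypes.

    ``density_per_mb`` is one expected-singletons-per-Mb rate per haplotype
    row; counts are Poisson per haplotype per chromosome. Each singleton is
    a brand-new variant column carried by exactly one haplotype. Existing
    singleton sites (if any) are dropped first so the operation is a
    re-assignment, not an accumulation.
    """
    rng = np.random.default_rng(seed)
    density = np.broadcast_to(np.asarray(density_per_mb, float), (g.hap.shape[0],))
    backbone = g.subset_variants(~g.meta.get(
        "is_singleton_site", np.zeros(g.n_variants, dtype=bool)))
    length = g.meta.get("chrom_length_bp", int(backbone.variants["pos"].max()) + 1)
    mb = length / 1e6
    n_hap = backbone.hap.shape[0]

    per_chrom, singleton_truth = [], {h: [] for h in range(n_hap)}
    for chrom, sub in backbone.variants.groupby("chrom", sort=False):
        idx = sub.index.to_numpy()
        counts = rng.poisson(density * mb)
        total = int(counts.sum())
        new_pos = _distinct_positions(rng, total, length, taken=sub["pos"].tolist())
        new_pos = rng.permutation(new_pos)
        owners = np.repeat(np.arange(n_hap), counts)
        cols = np.zeros((n_hap, total), dtype=np.int8)
        cols[owners, np.arange(total)] = 1
        for h, p in zip(owners, new_pos):
            singleton_truth[int(h)].append((chrom, int(p)))
        pos_all = np.concatenate([sub["pos"].to_numpy(), new_pos])
        order = np.argsort(pos_all, kind="stable")
        hap_all = np.hstack([backbone.hap[:, idx], cols])
        per_chrom.append((chrom, pos_all[order], hap_all[:, order],
                          np.concatenate([np.zeros(len(idx), bool),
                                          np.ones(total, bool)])[order]))

    frames, mats, sing_mask = [], [], []
    for chrom, pos, hap, mask in per_chrom:
        frames.append(pd.DataFrame({
            "chrom": chrom, "pos": pos,
            "id": [f"{chrom}_{p}" for p in pos],
            "ref": "A", "alt": "G",
        }))
        mats.append(hap)
        sing_mask.append(mask)
    variants = pd.concat(frames, ignore_index=True)[VARIANT_COLUMNS]
    out = PhasedGenotypes(samples=list(g.samples), variants=variants,
                          hap=np.hstack(mats), meta=dict(g.meta))
    out.meta["is_singleton_site"] = np.concatenate(sing_mask)
    out.meta["singletons"] = {h: sorted(v) for h, v in singleton_truth.items()}
    out.meta["chrom_length_bp"] = length
    return out


def backbone_only(g: PhasedGenotypes) -> PhasedGenotypes:
    """Drop singleton sites, keeping the LD backbone used by association scans."""
    mask = g.meta.get("is_singleton_site")
    if mask is None:
        return g
    out = g.subset_variants(~np.asarray(mask))
    out.meta["singletons"] = {}  # truth refers to the dropped private sites
    return out


def _chrom_backbone_index(g: PhasedGenotypes, chrom: str, index: int) -> int:
    """Global variant column of the index-th backbone SNP on `chrom`."""
    mask = (~np.asarray(g.meta.get("is_singleton_site",
                                   np.zeros(g.n_variants, bool)))) \
        & (g.variants["chrom"] == chrom).to_numpy()
    idx = np.flatnonzero(mask)
    if index < 0 or index >= len(idx):
        raise UnknownLocusError(f"no backbone SNP {index} on {chrom}")
    return int(idx[index])


def qtl_dosages(g: PhasedGenotypes, qtl: QTLSpec, block_size: int = 5):
    """Dosage vector (0/1/2 per individual) for a planted QTL.

    For 'snp' QTLs this is the alternative-allele dosage. For
    'haplotype-allele' QTLs the locus index names a non-overlapping
    `block_size`-SNP block; the tagged allele is the most frequent 5-mer
    with frequency <= 0.85 (falling back to the most frequent).
    """
    chrom, index = qtl.locus
    if qtl.kind == "snp":
        j = _chrom_backbone_index(g, chrom, int(index))
        d = g.hap[0::2, j].astype(np.int16) + g.hap[1::2, j]
        return d, {"column": j, "pos": int(g.variants["pos"].iloc[j])}
    if qtl.kind != "haplotype-allele":
        raise InvalidConfigError(f"unknown QTL kind {qtl.kind!r}")
    start = int(index) * block_size
    cols = [_chrom_backbone_index(g, chrom, start + k) for k in range(block_size)]
    seqs = g.hap[:, cols]
    uniq, inv, counts = np.unique(seqs, axis=0, return_inverse=True, return_counts=True)
    freq = counts / seqs.shape[0]
    order = np.argsort(-freq, kind="stable")
    pick = next((i for i in order if freq[i] <= 0.85), order[0])
    carrier = (inv == pick).astype(np.int16)
    d = carrier[0::2] + carrier[1::2]
    allele = "".join(map(str, uniq[pick]))
    return d, {"columns": cols, "allele": allele, "allele_freq": float(freq[pick])}


def simulate_laying_records(g: PhasedGenotypes, config: SimConfig) -> LayingRecords:
    """Daily Bernoulli laying records driven by the Yang-Ning weekly rate.

    Weekly probability for individual i in week w is
    ``clamp(yangning(w - 20; a,b,c,d) + g_i + e_i, 0, 1)`` where the
    genetic value g is the planted-QTL dosage score scaled so that
    var(g) / (var(g) + var(e)) = h2_target on the latent scale and
    var(g) + var(e) = individual_sd**2.
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 104729)
    n = g.n_individuals
    a, b, c, d = config.curve_params
    base = curves.yangning(curves.WEEKS - curves.WEEK_OFFSET, a, b, c, d)

    qtl_truth = []
    g_raw = np.zeros(n)
    for q in config.qtl_list:
        dose, info = qtl_dosages(g, q)
        g_raw = g_raw + q.effect * dose
        qtl_truth.append({"locus": list(q.locus), "kind": q.kind,
                          "effect": q.effect, **info})

    var_tot = config.individual_sd**2
    v = float(np.var(g_raw))
    if config.h2_target > 0 and v > 0:
        g_val = (g_raw - g_raw.mean()) * np.sqrt(config.h2_target * var_tot / v)
        e_sd = np.sqrt((1.0 - config.h2_target) * var_tot)
    else:
        g_val = np.zeros(n)
        e_sd = config.individual_sd
    e_val = rng.normal(0.0, e_sd, size=n) if e_sd > 0 else np.zeros(n)

    p_week = np.clip(base[None, :] + g_val[:, None] + e_val[:, None], 0.0, 1.0)
    p_day = np.repeat(p_week, 7, axis=1)  # week w covers days 7(w-21)+1..+7
    mat = (rng.random((n, N_DAYS)) < p_day).astype(np.int8)
    truth = {
        "genetic_value": g_val,
        "genetic_value_raw": g_raw,
        "env_value": e_val,
        "p_week": p_week,
        "qtls": qtl_truth,
        "h2_target": config.h2_target,
        "seed": config.seed,
    }
    return LayingRecords(samples=list(g.samples), matrix=mat, truth=truth)


def simulate_population_panel(base: PhasedGenotypes, n_pops: int, drift: float,
                              seed: int, n_individuals: int = 100):
    """Derive population panels whose allele frequencies drift from `base`.

    Each panel's per-site target frequency is ``clip(p + drift*U, 0, 1)``
    with U ~ Uniform(-1, 1) drawn independently per site and population
    (so E|shift| = drift/2 away from the boundaries); panel haplotypes are
    then sampled site-independently at the target frequencies.
    """
    if n_pops < 1:
        raise InvalidConfigError("n_pops must be >= 1")
    if not (0.0 <= drift <= 1.0):
        raise InvalidConfigError("drift must be in [0, 1]")
    rng = np.random.default_rng(seed)
    p = base.af
    panels = []
    for k in range(n_pops):
        shift = drift * rng.uniform(-1.0, 1.0, size=len(p))
        p2 = np.clip(p + shift, 0.0, 1.0)
        hap = (rng.random((2 * n_individuals, len(p))) < p2).astype(np.int8)
        pg = PhasedGenotypes(
            samples=[f"pop{k + 1}_ind{i + 1}" for i in range(n_individuals)],
            variants=base.variants.copy().reset_index(drop=True),
            hap=hap,
        )
        pg.meta["target_af"] = p2
        pg.meta["population"] = f"pop{k + 1}"
        panels.append(pg)
    return panels
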