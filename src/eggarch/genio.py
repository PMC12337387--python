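"""Readers/writers for the formats the pipeline touches.

Internal coordinates are 1-based (VCF dialect) throughout; only BED-style
window output is 0-based half-open. Phased haplotypes live in a dense
``2N x M`` binary matrix with two consecutive rows per individual.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

VARIANT_COLUMNS = ["chrom", "pos", "id", "ref", "alt"]


class EmptyInputError(ValueError):
    """No usable (phased, biallelic) records in the input."""


@dataclass
class PhasedGenotypes:
    """Phased biallelic genotypes for N individuals at M sites.

    ``hap`` holds one row per haplotype (rows 2i and 2i+1 belong to
    individual i), one column per variant, entries in {0, 1} where 1 is
    the alternative allele. ``variants`` is a DataFrame with columns
    chrom, pos (1-based), id, ref, alt, sorted in genome order.
    """

    samples: list[str]
    variants: pd.DataFrame
    hap: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.hap = np.asarray(self.hap, dtype=np.int8)
        if self.hap.ndim != 2 or self.hap.shape[0] != 2 * len(self.samples):
            raise ValueError("hap must be 2N x M")
        if self.hap.shape[1] != len(self.variants):
            raise ValueError("hap columns must match variant count")
        if self.hap.size and not np.isin(self.hap, (0, 1)).all():
            raise ValueError("hap entries must be 0/1")
        for _, sub in self.variants.groupby("chrom", sort=False):
            pos = sub["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError("positions must be strictly increasing per chromosome")

    @property
    def n_individuals(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return int(self.hap.shape[1])

    @property
    def af(self) -> np.ndarray:
        """Alternative-allele frequency per variant (column mean of hap)."""
        return self.hap.mean(axis=0) if self.hap.size else np.zeros(self.n_variants)

    def dosages(self) -> np.ndarray:
        """N x M matrix of alternative-allele dosages (0/1/2)."""
        return (self.hap[0::2].astype(np.int16) + self.hap[1::2]).astype(np.int8)

    def subset_variants(self, mask: np.ndarray) -> "PhasedGenotypes":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        meta = dict(self.meta)
        if "is_singleton_site" in meta and \
                len(meta["is_singleton_site"]) == self.n_variants:
            meta["is_singleton_site"] = np.asarray(meta["is_singleton_site"])[idx]
        return PhasedGenotypes(
            samples=list(self.samples),
            variants=self.variants.iloc[idx].reset_index(drop=True),
            hap=self.hap[:, idx],
            meta=meta,
        )

    def subset_individuals(self, idx: np.ndarray) -> "PhasedGenotypes":
        idx = np.asarray(idx)
        rows = np.empty(2 * len(idx), dtype=int)
        rows[0::2] = 2 * idx
        rows[1::2] = 2 * idx + 1
        return PhasedGenotypes(
            samples=[self.samples[i] for i in idx],
            variants=self.variants.copy().reset_index(drop=True),
            hap=self.hap[rows],
            meta=dict(self.meta),
        )


def read_phased_vcf(path) -> PhasedGenotypes:
    """Read phased biallelic records from a VCF.

    Multi-allelic and unphased records are skipped (counts logged and
    recorded in ``meta['n_skipped']``). Raises :class:`EmptyInputError`
    if nothing usable remains.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, haps = [], []
    n_skipped = 0
    for rec in vcf:
        if len(rec.ALT) != 1:
            n_skipped += 1
            continue
        gts = rec.genotypes  # [allele0, allele1, phased] per sample
        if not all(g[-1] for g in gts):
            n_skipped += 1
            continue
        col = np.empty(2 * len(samples), dtype=np.int8)
        col[0::2] = [g[0] for g in gts]
        col[1::2] = [g[1] for g in gts]
        if col.min() < 0 or col.max() > 1:
            n_skipped += 1
            continue
        rows.append((rec.CHROM, rec.POS, rec.ID or ".", rec.REF, rec.ALT[0]))
        haps.append(col)
    if not rows:
        raise EmptyInputError(f"no phased biallelic records in {path}")
    if n_skipped:
        log.info("skipped %d multi-allelic/unphased records in %s", n_skipped, path)
    variants = pd.DataFrame(rows, columns=VARIANT_COLUMNS)
    g = PhasedGenotypes(samples=samples, variants=variants, hap=np.column_stack(haps))
    g.meta["n_skipped"] = n_skipped
    return g


def write_phased_vcf(g: PhasedGenotypes, path) -> None:
    """Write VCF 4.2 with '|'-separated GT fields and contig header lines."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=eggarch\n")
        for chrom in pd.unique(g.variants["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT")
        if g.samples:
            fh.write("\t" + "\t".join(g.samples))
        fh.write("\n")
        hap = g.hap
        for j, row in enumerate(g.variants.itertuples(index=False)):
            gts = "\t".join(
                f"{hap[2 * i, j]}|{hap[2 * i + 1, j]}" for i in range(g.n_individuals)
            )
            fields = [str(row.chrom), str(row.pos), str(row.id), row.ref, row.alt,
                      ".", "PASS", ".", "GT"]
            if gts:
                fields.append(gts)
            fh.write("\t".join(fields) + "\n")


def read_laying_tsv(path) -> pd.DataFrame:
    """Laying records: rows = individuals (index), columns day_1..day_161."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.isna().any().any():
        raise ValueError(f"ragged/missing entries in laying table {path}")
    return df


def write_laying_tsv(records, path) -> None:
    records.to_frame().to_csv(path, sep="\t")


def write_trait_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=True, na_rep="NA")


def read_trait_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0, na_values="NA")


def write_assoc_table(res: pd.DataFrame, path) -> None:
    """Association results with chrom, pos, effect, SE, p, q columns."""
    res.to_csv(path, sep="\t", index=False, na_rep="NA")


def write_window_bed(windows: pd.DataFrame, path, stat_cols=None) -> None:
    """Window statistics, BED-style: chrom, 0-based half-open start, end, stats."""
    cols = ["chrom", "start", "end"] + list(
        stat_cols if stat_cols is not None
        else [c for c in windows.columns if c not in ("chrom", "start", "end")]
    )
    windows[cols].to_csv(path, sep="\t", index=False, header=False, na_rep="NA")


def write_truth_json(truth: dict, path) -> None:
    def _default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        raise TypeError(type(o))

    with open(path, "w") as fh:
        json.dump(truth, fh, indent=1, default=_default)
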