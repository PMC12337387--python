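"""Enriched scores of trait-associated haplotype alleles across
population panels.

For a trait's beneficial (BHA) or unbeneficial (UHA) haplotype alleles
discovered in the mapping cohort, the enriched score of population k is
E_k = sum over those alleles of their haplotype frequency in that
population. Panel haplotypes are sliced at the block's SNP coordinates;
positions genotyped in the discovery cohort but absent from a panel are
filled with the discovery REF allele so alleles remain directly
comparable across SNP sets. Sequences not in the discovery catalogue
count as "other" and never contribute to E.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .assoc_hap import HaplotypeBlock
from .genio import PhasedGenotypes


@dataclass
class EnrichedScore:
    population: str
    allele_class: str  # 'BHA' | 'UHA'
    E: float
    n_alleles: int


def allele_frequency_in_panel(block: HaplotypeBlock,
                              discovery: PhasedGenotypes,
                              panel: PhasedGenotypes) -> dict:
    """Frequency of each catalogued block allele in a panel.

    Returns {'<allele seq>': freq, ..., 'other': freq}. Positions missing
    from the panel are reference-filled (allele 0).
    """
    want = [(discovery.variants["chrom"].iloc[c], discovery.variants["pos"].iloc[c])
            for c in block.snp_cols]
    key = {(c, p): j for j, (c, p) in enumerate(
        zip(panel.variants["chrom"], panel.variants["pos"]))}
    n_hap = panel.hap.shape[0]
    seqs = np.zeros((n_hap, len(want)), dtype=np.int8)
    n_missing = 0
    for k, cp in enumerate(want):
        j = key.get(cp)
        if j is None:
            n_missing += 1  # reference fill: column stays 0
        else:
            seqs[:, k] = panel.hap[:, j]
    if n_missing == len(want):
        warnings.warn(f"block {block.id}: no overlapping positions, all-reference fill")
    catalogue = {block.allele_seq(code): code for code in range(block.n_alleles)}
    labels = ["".join(map(str, row)) for row in seqs]
    freqs = dict.fromkeys(catalogue, 0.0)
    freqs["other"] = 0.0
    for lab in labels:
        freqs[lab if lab in catalogue else "other"] += 1.0 / n_hap
    return freqs


def enriched_score(effects: pd.DataFrame, allele_class: str,
                   blocks_by_id: dict[int, HaplotypeBlock],
                   discovery: PhasedGenotypes, panel: PhasedGenotypes,
                   population: str | None = None) -> EnrichedScore:
    """E = sum of panel frequencies of the trait's BHA (or UHA) alleles."""
    if allele_class not in ("BHA", "UHA"):
        raise ValueError(allele_class)
    rows = effects[effects["cls"] == allele_class]
    name = population or panel.meta.get("population", "panel")
    if not len(rows):
        return EnrichedScore(name, allele_class, np.nan, 0)
    E = 0.0
    for bid, sub in rows.groupby("block"):
        freqs = allele_frequency_in_panel(blocks_by_id[bid], discovery, panel)
        for _, r in sub.iterrows():
            E += freqs.get(r["allele"], 0.0)
    return EnrichedScore(name, allele_class, float(E), int(len(rows)))


def enriched_score_table(effects: pd.DataFrame,
                         blocks_by_id: dict[int, HaplotypeBlock],
                         discovery: PhasedGenotypes,
                         panels: list[PhasedGenotypes]) -> pd.DataFrame:
    """E per population x allele class, one row per combination."""
    recs = []
    for panel in panels:
        for cls in ("BHA", "UHA"):
            s = enriched_score(effects, cls, blocks_by_id, discovery, panel)
            recs.append((s.population, cls, s.E, s.n_alleles))
    return pd.DataFrame(recs, columns=["population", "class", "E", "n_alleles"])
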