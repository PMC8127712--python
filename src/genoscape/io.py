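"""Standard-format input: VCF to population allele frequencies, CSV tables."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .gea import AlleleFreqTable

__all__ = ["read_pop_map", "read_vcf_to_freq_table", "read_freq_csv", "write_freq_csv"]

logger = logging.getLogger(__name__)


def read_pop_map(path) -> pd.DataFrame:
    """Sample→population map CSV with columns sample, population, lon, lat."""
    df = pd.read_csv(path)
    required = {"sample", "population", "lon", "lat"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"pop map lacks column(s): {', '.join(sorted(missing))}")
    return df


def read_vcf_to_freq_table(vcf_path, pop_map: pd.DataFrame) -> AlleleFreqTable:
    """Population allele frequencies from a VCF.

    For each population and biallelic SNP, frequency = alt-allele count /
    called-allele count.  Multi-allelic sites and sites with all
    genotypes missing are skipped with a logged tally.  Every sample in
    the VCF must appear in ``pop_map`` (columns sample, population, lon,
    lat; one coordinate per population).
    """
    from cyvcf2 import VCF  # deferred: only needed on the VCF path

    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    known = set(pop_map["sample"])
    absent = [s for s in samples if s not in known]
    if absent:
        raise ValueError(f"samples in VCF absent from pop map: {', '.join(absent)}")
    sample_pop = dict(zip(pop_map["sample"], pop_map["population"]))
    pops = list(dict.fromkeys(pop_map["population"]))  # stable order
    pop_idx = {p: i for i, p in enumerate(pops)}
    col_pop = np.array([pop_idx[sample_pop[s]] for s in samples])
    coords = (
        pop_map.groupby("population", sort=False)[["lon", "lat"]].first().loc[pops].to_numpy()
    )

    snp_ids: list[str] = []
    rows: list[np.ndarray] = []
    n_multi = n_missing = 0
    for v in vcf:
        if len(v.ALT) != 1:
            n_multi += 1
            continue
        gt = np.asarray(v.genotype.array())[:, :2]  # ploidy-2 allele columns
        called = gt >= 0
        if not called.any():
            n_missing += 1
            continue
        alt = ((gt == 1) & called).sum(axis=1).astype(float)
        tot = called.sum(axis=1).astype(float)
        freq = np.full(len(pops), np.nan)
        for p in range(len(pops)):
            sel = col_pop == p
            t = tot[sel].sum()
            if t > 0:
                freq[p] = alt[sel].sum() / t
        snp_id = v.ID if v.ID and v.ID != "." else f"{v.CHROM}:{v.POS}"
        snp_ids.append(snp_id)
        rows.append(freq)
    if n_multi or n_missing:
        logger.info("skipped %d multi-allelic and %d all-missing sites", n_multi, n_missing)
    if not rows:
        raise ValueError("no usable biallelic SNPs in VCF")
    return AlleleFreqTable(
        site_ids=[str(p) for p in pops],
        coordinates=coords,
        snp_ids=snp_ids,
        frequencies=np.vstack(rows).T,
    )


def read_freq_csv(path) -> AlleleFreqTable:
    """Frequency matrix CSV (rows = sites with lon/lat, columns = SNPs)."""
    return AlleleFreqTable.from_frame(
        pd.read_csv(path, index_col=0, float_precision="round_trip")
    )


def write_freq_csv(table: AlleleFreqTable, path) -> None:
    table.to_frame().to_csv(path, float_format="%.17g")
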