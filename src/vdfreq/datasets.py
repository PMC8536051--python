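"""Packaged reference data.

One table ships with the package: the published shortlist of vitamin-D
SNPs whose signed log10 Fisher statistic in the Korean cohort exceeds 100
in magnitude (29 SNPs), with effect-allele frequencies and signed
statistics for the five continental groups and the Korean cohort, GRCh37
coordinates, and REF/ALT alleles.  The effect allele is the ALT allele
throughout this table.

Helpers turn the printed frequencies back into approximate allele counts
(using the published cohort sizes) so the enrichment statistics can be
recomputed and compared against the printed ones.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .catalog import SnpCatalog, SnpRecord
from .frequencies import (
    GLOBAL,
    GLOBAL_SIZE,
    KOREAN_COHORT_SIZE,
    SUPERPOPULATION_SIZES,
    FrequencyTable,
    counts_from_frequency,
)

__all__ = [
    "POPULATION_ORDER",
    "load_extreme_korean_snps",
    "extreme_snps_catalog",
    "extreme_snps_frequency_table",
    "extreme_snps_printed_matrix",
]

#: column order used for matrices built from the packaged table
POPULATION_ORDER = ("AMR", "AFR", "EAS", "SAS", "EUR", "KOR")


def load_extreme_korean_snps() -> pd.DataFrame:
    """The packaged 29-SNP table, one row per SNP.

    Columns: ``rsid, chrom, position, gene, function, ref_allele,
    alt_allele, GLOBAL_eaf`` and per population ``{POP}_eaf,
    {POP}_log10p`` (signed, positive = enriched vs the global panel).
    """
    with resources.files("vdfreq").joinpath("data/extreme_korean_snps.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def extreme_snps_catalog() -> SnpCatalog:
    """The packaged table as a curated catalog (effect allele = ALT)."""
    df = load_extreme_korean_snps()
    records = [
        SnpRecord(
            rsid=r.rsid,
            chrom=str(r.chrom),
            position=int(r.position),
            mapped_gene=str(r.gene),
            functional_class=str(r.function),
            effect_allele=str(r.alt_allele),
            other_allele=str(r.ref_allele),
            effect_allele_resolved_by="catalog",
        )
        for r in df.itertuples()
    ]
    return SnpCatalog(records, provenance="packaged extreme-Korean-SNP table")


def extreme_snps_frequency_table(
    cohort_sizes: dict[str, int] | None = None,
) -> FrequencyTable:
    """Reconstruct allele counts from the packaged table's frequencies.

    ``cohort_sizes`` maps population label to diploid sample count and
    defaults to the published sizes (1000 Genomes phase 3 continental
    groups, 2504 pooled, 1722 Koreans).  Counts are rounded half-up from
    the printed frequencies, so recomputed statistics carry the table's
    two-to-three-digit rounding.
    """
    sizes = dict(SUPERPOPULATION_SIZES)
    sizes[GLOBAL] = GLOBAL_SIZE
    sizes["KOR"] = KOREAN_COHORT_SIZE
    if cohort_sizes:
        sizes.update(cohort_sizes)
    df = load_extreme_korean_snps()
    rows = []
    for r in df.itertuples():
        for pop in (GLOBAL, *POPULATION_ORDER):
            eaf = float(getattr(r, f"{pop}_eaf"))
            k, n = counts_from_frequency(eaf, sizes[pop])
            rows.append((r.rsid, pop, eaf, k, n, "frequency_file"))
    return FrequencyTable.from_records(rows)


def extreme_snps_printed_matrix() -> pd.DataFrame:
    """The published signed log10 p matrix (SNPs × populations).

    Values above ~312.6 in magnitude are saturated in the source table,
    consistent with a probability-space computation bottoming out at the
    double-precision underflow threshold.
    """
    df = load_extreme_korean_snps().set_index("rsid")
    return df[[f"{pop}_log10p" for pop in POPULATION_ORDER]].rename(
        columns={f"{pop}_log10p": pop for pop in POPULATION_ORDER}
    )
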