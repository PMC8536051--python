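"""Composite genetic risk scores from effect-allele dosages.

The composite (unweighted) GRS of an individual over a panel of I SNPs is

    GRS = sum_i X_i / (2 I),    X_i in {0, 1, 2},

the fraction of effect alleles carried: 1 for a double carrier at every
SNP, 0 for a complete non-carrier, and expectation 0.5 under uniformly
random dosages.  An unweighted score is used deliberately — per-allele
effect sizes for 25(OH)D3 are unstable across ancestries, so a weighted
polygenic score would import noise the composite score avoids.

Cohort-level scores average individual scores; with complete genotypes the
cohort mean equals the mean of per-SNP effect-allele frequencies, which is
also the frequency-only closed form used when genotypes are unavailable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .catalog import SnpCatalog
from .frequencies import FrequencyTable, GenotypeMatrix, PopulationPanel

logger = logging.getLogger(__name__)

__all__ = [
    "GrsResult",
    "individual_grs",
    "cohort_grs",
    "expected_grs_from_eaf",
    "phase_concordance_filter",
]


@dataclass(frozen=True)
class GrsResult:
    sample_id: str
    score: float
    n_snps: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.score <= 1.0:
            raise ValueError(f"score {self.score} outside [0,1]")


def individual_grs(
    dosages: np.ndarray,
    sample_id: str = "",
    population_eaf: np.ndarray | None = None,
    missing_policy: str = "impute_eaf",
) -> GrsResult:
    """Composite GRS of one individual.

    Parameters
    ----------
    dosages:
        Effect-allele dosages aligned to the catalog; NaN marks missing.
    population_eaf:
        Per-SNP effect-allele frequencies of the individual's population,
        required by the ``impute_eaf`` policy.
    missing_policy:
        ``"impute_eaf"`` replaces a missing dosage with its expectation
        ``2·eaf`` so the denominator stays 2I; ``"strict"`` raises on any
        missing dosage.
    """
    x = np.asarray(dosages, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise ValueError("dosages must be a non-empty 1-D vector")
    missing = np.isnan(x)
    if missing.all():
        raise ValueError(f"{sample_id or 'sample'}: all dosages missing")
    if missing.any():
        if missing_policy == "strict":
            raise ValueError(
                f"{sample_id or 'sample'}: {missing.sum()} missing dosage(s) "
                "under strict policy"
            )
        if missing_policy != "impute_eaf":
            raise ValueError(f"unknown missing policy {missing_policy!r}")
        if population_eaf is None:
            raise ValueError("impute_eaf policy needs population_eaf")
        x = np.where(missing, 2.0 * np.asarray(population_eaf, dtype=float), x)
    n_snps = x.size
    return GrsResult(sample_id, float(x.sum() / (2 * n_snps)), n_snps)


def cohort_grs(
    genotypes: GenotypeMatrix,
    panel: PopulationPanel,
    grouping: str = "population",
    missing_policy: str = "impute_eaf",
) -> pd.DataFrame:
    """Mean and SD of individual composite scores per population.

    Returns a DataFrame with columns ``population, mean_score, sd_score,
    n_samples``.  Under ``impute_eaf``, missing dosages are replaced by
    twice the group's empirical effect-allele frequency at that SNP.  With
    no missing data the group mean equals the mean of the group's per-SNP
    frequencies exactly.
    """
    labels = np.array([panel.group_of(s, grouping) for s in genotypes.sample_ids])
    rows = []
    for pop in dict.fromkeys(labels):
        sub = genotypes.dosages[labels == pop, :]
        if sub.shape[0] == 0:
            logger.warning("population %s has no samples, skipped", pop)
            continue
        eaf = None
        if np.isnan(sub).any() and missing_policy == "impute_eaf":
            with np.errstate(invalid="ignore"):
                eaf = np.nanmean(sub, axis=0) / 2.0
            eaf = np.nan_to_num(eaf, nan=0.5)  # SNPs with no calls in group
        scores = [
            individual_grs(sub[i], population_eaf=eaf, missing_policy=missing_policy).score
            for i in range(sub.shape[0])
        ]
        rows.append(
            {
                "population": pop,
                "mean_score": float(np.mean(scores)),
                "sd_score": float(np.std(scores, ddof=1)) if len(scores) > 1 else 0.0,
                "n_samples": len(scores),
            }
        )
    return pd.DataFrame(rows)


def expected_grs_from_eaf(
    freq_table: FrequencyTable, population: str, catalog: SnpCatalog | None = None
) -> float:
    """Frequency-only cohort GRS: the mean effect-allele frequency.

    Under Hardy–Weinberg dosages, E[sum X_i / 2I] = mean_i(eaf_i); this is
    the code path for cohorts published as frequencies only.  Raises when
    any catalog SNP lacks a frequency for the population.
    """
    rsids = catalog.rsids if catalog is not None else freq_table.rsids
    sub = freq_table.data[freq_table.data["population"] == population]
    eaf_of = dict(zip(sub["rsid"], sub["eaf"]))
    missing = [r for r in rsids if r not in eaf_of]
    if missing:
        raise ValueError(
            f"no {population} frequency for SNP(s): {', '.join(missing[:10])}"
            + ("..." if len(missing) > 10 else "")
        )
    return float(np.mean([eaf_of[r] for r in rsids]))


def phase_concordance_filter(
    catalog: SnpCatalog,
    freq_total: np.ndarray,
    freq_phase2: np.ndarray,
    threshold: float = 0.10,
) -> tuple[pd.DataFrame, SnpCatalog]:
    """Drop SNPs whose total-cohort and second-phase frequencies disagree.

    A SNP is excluded iff ``|freq_total − freq_phase2| > threshold``
    (strict: a difference of exactly the threshold is retained).  The
    threshold is an absolute frequency difference, default 0.10.  Returns
    the per-SNP report and the filtered catalog in original order.
    """
    ft = np.asarray(freq_total, dtype=float)
    fp = np.asarray(freq_phase2, dtype=float)
    if ft.shape != (len(catalog),) or fp.shape != (len(catalog),):
        raise ValueError(
            f"frequency vectors must align to the catalog "
            f"({len(catalog)} SNPs), got {ft.shape} and {fp.shape}"
        )
    diff = np.abs(ft - fp)
    excluded = diff > threshold
    report = pd.DataFrame(
        {
            "rsid": catalog.rsids,
            "freq_total": ft,
            "freq_phase2": fp,
            "abs_difference": diff,
            "excluded": excluded,
        }
    )
    kept = [r for r, ex in zip(catalog.rsids, excluded) if not ex]
    if excluded.any():
        logger.info(
            "phase-concordance filter excluded %d of %d SNPs (threshold %.2f)",
            int(excluded.sum()), len(catalog), threshold,
        )
    return report, catalog.subset(kept)
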