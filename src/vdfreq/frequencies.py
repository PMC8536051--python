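"""Per-population effect-allele frequencies from genotype panels.

Two sources feed the frequency stage: a multi-sample VCF of biallelic SNVs
with a sample→population map (1000 Genomes phase 3 style, GRCh37), and a
KRGDB-style published frequency table (variant, alleles, ALT frequency,
sample count) for cohorts whose genotypes are not distributed.

All frequencies are expressed on the catalog's *effect* allele, whichever
of REF/ALT it is, so downstream enrichment and GRS arithmetic never see
allele orientation again.  Missing genotypes shrink the denominator; no
imputation happens at this stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import pysam

from .catalog import SnpCatalog

logger = logging.getLogger(__name__)

__all__ = [
    "PopulationPanel",
    "GenotypeMatrix",
    "FrequencyTable",
    "GLOBAL",
    "read_vcf_genotypes",
    "read_frequency_table",
    "compute_eaf",
    "counts_from_frequency",
    "panel_variants_from_vcf",
]

#: label of the pooled base-panel background group
GLOBAL = "GLOBAL"

#: published 1000 Genomes phase 3 sample counts per continental group;
#: overridable wherever counts are reconstructed from printed frequencies
SUPERPOPULATION_SIZES = {"AFR": 661, "AMR": 347, "EAS": 504, "EUR": 503, "SAS": 489}
GLOBAL_SIZE = 2504
KOREAN_COHORT_SIZE = 1722
KOREAN_PHASE2_SIZE = 1099


@dataclass
class PopulationPanel:
    """Sample→population and population→superpopulation assignments."""

    population_of: dict[str, str]
    superpopulation_of: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for s, p in self.population_of.items():
            if not s or not p:
                raise ValueError("sample and population labels must be non-empty")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.population_of)

    @property
    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.population_of.values():
            seen.setdefault(p)
        return list(seen)

    def group_of(self, sample: str, level: str = "population") -> str:
        pop = self.population_of[sample]
        if level == "population":
            return pop
        if level == "superpopulation":
            return self.superpopulation_of.get(pop, pop)
        raise ValueError(f"unknown grouping level {level!r}")

    def to_tsv(self, path: str | Path) -> None:
        rows = [
            (s, p, self.superpopulation_of.get(p, p))
            for s, p in self.population_of.items()
        ]
        pd.DataFrame(rows, columns=["sample_id", "population", "superpopulation"]).to_csv(
            path, sep="\t", index=False
        )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PopulationPanel":
        df = pd.read_csv(path, sep="\t", dtype=str)
        population_of = dict(zip(df["sample_id"], df["population"]))
        superpopulation_of = (
            dict(zip(df["population"], df["superpopulation"]))
            if "superpopulation" in df.columns
            else {}
        )
        return cls(population_of, superpopulation_of)


@dataclass
class GenotypeMatrix:
    """Effect-allele dosages, samples × SNPs; NaN marks a missing call."""

    dosages: np.ndarray  # float array, values in {0,1,2} or NaN
    sample_ids: list[str]
    rsids: list[str]

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.sample_ids), len(self.rsids)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.rsids)} SNPs"
            )
        valid = np.isnan(self.dosages) | np.isin(self.dosages, (0.0, 1.0, 2.0))
        if not valid.all():
            raise ValueError("dosages must be 0, 1, 2 or NaN")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_snps(self) -> int:
        return len(self.rsids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.dosages, index=self.sample_ids, columns=self.rsids)


class FrequencyTable:
    """Effect-allele frequency rows keyed by (rsid, population).

    Wraps a DataFrame with columns ``rsid, population, eaf, k_effect,
    n_alleles, source``.  ``source`` records whether a row was counted from
    genotypes or taken from a published frequency file; counted rows satisfy
    ``eaf == k_effect / n_alleles`` exactly.
    """

    COLUMNS = ("rsid", "population", "eaf", "k_effect", "n_alleles", "source")

    def __init__(self, data: pd.DataFrame):
        missing = [c for c in self.COLUMNS if c not in data.columns]
        if missing:
            raise ValueError(f"FrequencyTable missing column(s) {missing}")
        df = data.loc[:, list(self.COLUMNS)].reset_index(drop=True)
        bad = df[(df["eaf"] < 0) | (df["eaf"] > 1)]
        if len(bad):
            raise ValueError(f"eaf outside [0,1] for {bad['rsid'].tolist()}")
        if ((df["k_effect"] < 0) | (df["k_effect"] > df["n_alleles"])).any():
            raise ValueError("k_effect must lie in [0, n_alleles]")
        self.data = df

    def __len__(self) -> int:
        return len(self.data)

    @property
    def populations(self) -> list[str]:
        return list(dict.fromkeys(self.data["population"]))

    @property
    def rsids(self) -> list[str]:
        return list(dict.fromkeys(self.data["rsid"]))

    def row(self, rsid: str, population: str) -> pd.Series | None:
        sel = self.data[
            (self.data["rsid"] == rsid) & (self.data["population"] == population)
        ]
        if sel.empty:
            return None
        return sel.iloc[0]

    def counts(self, rsid: str, population: str) -> tuple[int, int]:
        r = self.row(rsid, population)
        if r is None:
            raise KeyError((rsid, population))
        return int(r["k_effect"]), int(r["n_alleles"])

    def eaf(self, rsid: str, population: str) -> float:
        r = self.row(rsid, population)
        if r is None:
            raise KeyError((rsid, population))
        return float(r["eaf"])

    def concat(self, other: "FrequencyTable") -> "FrequencyTable":
        return FrequencyTable(pd.concat([self.data, other.data], ignore_index=True))

    def to_tsv(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "FrequencyTable":
        return cls(pd.read_csv(path, sep="\t"))

    @classmethod
    def from_records(cls, records: Iterable[tuple]) -> "FrequencyTable":
        return cls(pd.DataFrame(records, columns=list(cls.COLUMNS)))


def counts_from_frequency(eaf: float, n_individuals: int) -> tuple[int, int]:
    """Reconstruct allele counts from a published frequency.

    ``n_alleles = 2 * n_individuals``; the effect-allele count is rounded
    half-up, because banker's rounding would bias reconstructed Fisher
    tables at the extreme frequencies this analysis cares about.
    """
    if not 0.0 <= eaf <= 1.0:
        raise ValueError(f"eaf must lie in [0,1], got {eaf}")
    if n_individuals <= 0:
        raise ValueError("n_individuals must be positive")
    n_alleles = 2 * n_individuals
    k_effect = int(np.floor(eaf * n_alleles + 0.5))
    return min(k_effect, n_alleles), n_alleles


def read_vcf_genotypes(
    vcf_path: str | Path, panel: PopulationPanel, catalog: SnpCatalog
) -> GenotypeMatrix:
    """Load effect-allele dosages for the catalog SNPs from a VCF.

    The dosage counts copies of the catalog's effect allele: when the
    effect allele is ALT it is the number of ``1`` alleles in GT, when it
    is REF it is two minus that number.  Missing GT → NaN.  Multi-allelic
    records at catalog sites are skipped with a warning; VCF samples not in
    the panel raise.
    """
    effect = catalog.effect_alleles()
    with pysam.VariantFile(str(vcf_path)) as vcf:
        samples = list(vcf.header.samples)
        unknown = [s for s in samples if s not in panel.population_of]
        if unknown:
            raise ValueError(
                f"VCF sample(s) absent from population panel: {', '.join(unknown)}"
            )
        dosages = np.full((len(samples), len(catalog)), np.nan)
        col = {rsid: j for j, rsid in enumerate(catalog.rsids)}
        seen: set[str] = set()
        for rec in vcf:
            rsid = rec.id
            if rsid not in col:
                continue
            if rec.alts is None or len(rec.alts) != 1 or len(rec.ref) != 1 or len(rec.alts[0]) != 1:
                logger.warning("%s: not a biallelic SNV, skipped", rsid)
                continue
            j = col[rsid]
            eff = effect[rsid]
            if eff not in (rec.ref, rec.alts[0]):
                logger.warning(
                    "%s: catalog effect allele %s not among VCF alleles %s/%s, skipped",
                    rsid, eff, rec.ref, rec.alts[0],
                )
                continue
            effect_is_alt = eff == rec.alts[0]
            seen.add(rsid)
            for i, sample in enumerate(samples):
                gt = rec.samples[sample]["GT"]
                if gt is None or any(a is None for a in gt):
                    continue
                alt_count = sum(1 for a in gt if a == 1)
                dosages[i, j] = alt_count if effect_is_alt else len(gt) - alt_count
        absent = set(catalog.rsids) - seen
        if absent:
            logger.warning("%d catalog SNP(s) not found in VCF", len(absent))
    return GenotypeMatrix(dosages, samples, catalog.rsids)


def read_frequency_table(
    path: str | Path, catalog: SnpCatalog, population: str
) -> FrequencyTable:
    """Read a KRGDB-style published frequency TSV for one population.

    Expected columns: ``ID, REF, ALT, ALT_FREQ, N_SAMPLES``.  The file's
    ALT frequency is mapped onto the catalog's effect allele (complemented
    to ``1 - f`` when the effect allele is the file's REF) and allele
    counts are reconstructed with :func:`counts_from_frequency`.
    """
    df = pd.read_csv(path, sep="\t", dtype={"ID": str, "REF": str, "ALT": str})
    required = ("ID", "REF", "ALT", "ALT_FREQ", "N_SAMPLES")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {', '.join(missing)}")
    effect = catalog.effect_alleles()
    rows = []
    for idx, r in enumerate(df.itertuples(), start=2):  # 1-based incl. header
        rsid = r.ID
        if rsid not in effect:
            continue
        try:
            freq = float(r.ALT_FREQ)
        except (TypeError, ValueError):
            raise ValueError(f"{path}:{idx}: non-numeric frequency {r.ALT_FREQ!r}")
        if not 0.0 <= freq <= 1.0:
            raise ValueError(f"{path}:{idx}: frequency {freq} outside [0,1]")
        eff = effect[rsid]
        if eff == str(r.ALT).upper():
            eaf = freq
        elif eff == str(r.REF).upper():
            eaf = 1.0 - freq
        else:
            logger.warning(
                "%s: effect allele %s not among file alleles %s/%s, skipped",
                rsid, eff, r.REF, r.ALT,
            )
            continue
        k, n = counts_from_frequency(eaf, int(r.N_SAMPLES))
        rows.append((rsid, population, eaf, k, n, "frequency_file"))
    return FrequencyTable.from_records(rows)


def compute_eaf(
    genotypes: GenotypeMatrix,
    panel: PopulationPanel,
    grouping: str = "population",
) -> FrequencyTable:
    """Count effect-allele frequencies per group from a genotype matrix.

    ``grouping`` is ``"population"``, ``"superpopulation"`` or ``"GLOBAL"``
    (pool every sample of the panel).  Missing calls reduce the
    denominator; a group with no calls at a SNP gets no row (the cell is
    undefined and propagates as missing downstream).
    """
    if grouping == GLOBAL:
        groups = {GLOBAL: np.arange(genotypes.n_samples)}
    elif grouping in ("population", "superpopulation"):
        labels = [panel.group_of(s, grouping) for s in genotypes.sample_ids]
        groups = {}
        for i, lab in enumerate(labels):
            groups.setdefault(lab, []).append(i)
        groups = {lab: np.asarray(ix) for lab, ix in groups.items()}
    else:
        raise ValueError(f"unknown grouping {grouping!r}")

    rows = []
    for lab, ix in groups.items():
        sub = genotypes.dosages[ix, :]
        called = ~np.isnan(sub)
        k = np.nansum(sub, axis=0)
        n = 2 * called.sum(axis=0)
        for j, rsid in enumerate(genotypes.rsids):
            if n[j] == 0:
                logger.warning("%s/%s: no called genotypes, cell undefined", rsid, lab)
                continue
            rows.append(
                (rsid, lab, k[j] / n[j], int(k[j]), int(n[j]), "genotypes")
            )
    return FrequencyTable.from_records(rows)


def panel_variants_from_vcf(vcf_path: str | Path) -> pd.DataFrame:
    """Collect ``rsid, ref, alt, alt_freq`` for biallelic SNVs in a VCF.

    Used to harmonize a GWAS catalog against the panel; ``alt_freq`` is
    counted from GT over all samples and feeds the minor-allele fallback.
    """
    rows = []
    with pysam.VariantFile(str(vcf_path)) as vcf:
        for rec in vcf:
            if rec.id is None or rec.alts is None or len(rec.alts) != 1:
                continue
            if len(rec.ref) != 1 or len(rec.alts[0]) != 1:
                continue
            alt = n = 0
            for sample in rec.samples.values():
                gt = sample["GT"]
                if gt is None or any(a is None for a in gt):
                    continue
                alt += sum(1 for a in gt if a == 1)
                n += len(gt)
            rows.append(
                (rec.id, rec.ref, rec.alts[0], alt / n if n else np.nan)
            )
    return pd.DataFrame(rows, columns=["rsid", "ref", "alt", "alt_freq"])
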