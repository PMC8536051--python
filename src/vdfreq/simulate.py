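"""Synthetic multi-population data with the structure the pipeline assumes.

Population allele frequencies follow the Balding–Nichols model: around an
ancestral frequency p0, a population with differentiation F draws its
frequency from Beta(p0(1−F)/F, (1−p0)(1−F)/F), which has mean p0 and
variance F·p0(1−p0) — F plays the role of F_ST, a single differentiation
knob per population with closed-form moments for testing.  An optional
two-level clade tree draws an intermediate frequency per clade first, so
populations inside a clade are correlated and clades separate cleanly in
the enrichment matrix.

Genotypes are Hardy–Weinberg draws (dosage ~ Binomial(2, p)); phenotypes
follow the association stage's linear model (concentration = β0 +
β_grs·GRS + β_lat·latitude + ε); a two-phase subsampler emulates the
total-vs-second-phase cohort comparison behind the concordance filter.

The default configuration mirrors the study conditions: six cohorts
labelled like the continental groups plus the Korean cohort, with the
published cohort sizes, 320 SNPs, and the two clades the enrichment
clustering is expected to recover.

All randomness flows from one root seed through named substreams, so each
stage can be regenerated independently and whole-pipeline runs are
byte-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .catalog import SnpCatalog, SnpRecord
from .frequencies import (
    GenotypeMatrix,
    PopulationPanel,
    KOREAN_COHORT_SIZE,
    SUPERPOPULATION_SIZES,
)

__all__ = [
    "PopulationSpec",
    "SimulationConfig",
    "SimulatedTruth",
    "substream",
    "simulate_allele_frequencies",
    "simulate_genotypes",
    "simulate_phenotypes",
    "simulate_two_phase",
    "emit_fixtures",
]

# named substream indices hanging off the root seed
_STREAMS = {"frequencies": 0, "genotypes": 1, "phenotypes": 2, "subsampling": 3,
            "fixtures": 4}


def substream(seed: int, name: str) -> np.random.Generator:
    """Independent generator for one named stage of the simulation."""
    return np.random.default_rng(np.random.SeedSequence((seed, _STREAMS[name])))


@dataclass(frozen=True)
class PopulationSpec:
    label: str
    n_individuals: int
    fst: float
    latitude: float
    clade: str | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.fst < 1.0:
            raise ValueError(f"{self.label}: F_st must lie in (0,1)")
        if self.n_individuals < 1:
            raise ValueError(f"{self.label}: need at least one individual")


def _default_populations() -> tuple[PopulationSpec, ...]:
    # continental groups + Korean cohort at published sizes; clades follow
    # the bipartition the enrichment clustering resolves
    west, east = "WEST", "EAST"
    sizes = SUPERPOPULATION_SIZES
    return (
        PopulationSpec("EUR", sizes["EUR"], 0.02, 50.0, west),
        PopulationSpec("AMR", sizes["AMR"], 0.02, 10.0, west),
        PopulationSpec("SAS", sizes["SAS"], 0.02, 25.0, west),
        PopulationSpec("AFR", sizes["AFR"], 0.02, 0.0, east),
        PopulationSpec("EAS", sizes["EAS"], 0.02, 35.0, east),
        PopulationSpec("KOR", KOREAN_COHORT_SIZE, 0.02, 37.0, east),
    )


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the generator; defaults are the package's study conditions."""

    populations: tuple[PopulationSpec, ...] = field(default_factory=_default_populations)
    n_snps: int = 320
    clade_fst: float = 0.2
    ancestral_freq_range: tuple[float, float] = (0.05, 0.95)
    beta0: float = -75.0        # ng/mL; centres concentration near 25 at GRS 0.5
    beta_grs: float = 200.0     # ng/mL per unit composite score
    beta_lat: float = -0.05     # ng/mL per degree
    sigma: float = 0.3          # ng/mL residual SD
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_snps < 1:
            raise ValueError("need at least one SNP")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        lo, hi = self.ancestral_freq_range
        if not 0.0 < lo <= hi < 1.0:
            raise ValueError("ancestral_freq_range must lie inside (0,1)")
        if not 0.0 < self.clade_fst < 1.0:
            raise ValueError("clade_fst must lie in (0,1)")

    @property
    def labels(self) -> list[str]:
        return [p.label for p in self.populations]


@dataclass
class SimulatedTruth:
    """Ground truth retained for parameter-recovery tests."""

    ancestral_freq: np.ndarray            # (n_snps,)
    clade_freq: dict[str, np.ndarray]     # clade label -> (n_snps,)
    population_freq: pd.DataFrame         # populations × SNPs
    clade_of: dict[str, str | None]
    beta: tuple[float, float, float]      # (beta0, beta_grs, beta_lat)


def _balding_nichols(rng: np.random.Generator, p0: np.ndarray, fst: float) -> np.ndarray:
    a = p0 * (1.0 - fst) / fst
    b = (1.0 - p0) * (1.0 - fst) / fst
    return rng.beta(a, b)


def simulate_allele_frequencies(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, SimulatedTruth]:
    """Draw per-population effect-allele frequencies under Balding–Nichols.

    Returns a populations × SNPs DataFrame (rows ordered as configured,
    columns ``snp0001``…) plus the generating truth.  With clades, each
    clade first draws an intermediate frequency at ``clade_fst`` around
    the ancestral one; populations then differentiate from their clade's
    frequency at their own F.
    """
    rng = substream(config.seed, "frequencies")
    lo, hi = config.ancestral_freq_range
    p0 = rng.uniform(lo, hi, config.n_snps)
    clades = [p.clade for p in config.populations]
    clade_freq: dict[str, np.ndarray] = {}
    for clade in dict.fromkeys(c for c in clades if c is not None):
        clade_freq[clade] = _balding_nichols(rng, p0, config.clade_fst)
    rows = {}
    for spec in config.populations:
        base = clade_freq[spec.clade] if spec.clade is not None else p0
        rows[spec.label] = _balding_nichols(rng, base, spec.fst)
    snp_ids = [f"rs9{i:06d}" for i in range(1, config.n_snps + 1)]
    freq = pd.DataFrame(rows, index=snp_ids).T
    truth = SimulatedTruth(
        ancestral_freq=p0,
        clade_freq=clade_freq,
        population_freq=freq.copy(),
        clade_of={p.label: p.clade for p in config.populations},
        beta=(config.beta0, config.beta_grs, config.beta_lat),
    )
    return freq, truth


def simulate_genotypes(
    frequencies: pd.DataFrame, config: SimulationConfig
) -> tuple[GenotypeMatrix, PopulationPanel]:
    """Hardy–Weinberg dosages per sample per SNP from population frequencies."""
    rng = substream(config.seed, "genotypes")
    spec_of = {p.label: p for p in config.populations}
    sample_ids: list[str] = []
    population_of: dict[str, str] = {}
    blocks = []
    for label in frequencies.index:
        spec = spec_of[label]
        p = frequencies.loc[label].to_numpy(dtype=float)
        blocks.append(rng.binomial(2, p, size=(spec.n_individuals, p.size)))
        for i in range(spec.n_individuals):
            sid = f"{label}{i + 1:05d}"
            sample_ids.append(sid)
            population_of[sid] = label
    dosages = np.vstack(blocks).astype(float)
    panel = PopulationPanel(population_of)
    return GenotypeMatrix(dosages, sample_ids, list(frequencies.columns)), panel


def simulate_phenotypes(
    grs: dict[str, float] | pd.Series,
    latitudes: dict[str, float] | pd.Series,
    config: SimulationConfig,
) -> pd.DataFrame:
    """Population phenotype table under the linear concentration model.

    concentration = β0 + β_grs·GRS + β_lat·latitude + ε,  ε ~ N(0, σ²)
    independently per population.  Returns columns ``population,
    concentration_ng_per_ml, latitude_deg, grs``.
    """
    rng = substream(config.seed, "phenotypes")
    grs = dict(grs)
    latitudes = dict(latitudes)
    if set(grs) != set(latitudes):
        raise ValueError("GRS and latitude tables must cover the same populations")
    labels = list(grs)
    eps = rng.normal(0.0, config.sigma, len(labels)) if config.sigma > 0 else np.zeros(len(labels))
    rows = [
        {
            "population": lab,
            "concentration_ng_per_ml": config.beta0
            + config.beta_grs * grs[lab]
            + config.beta_lat * latitudes[lab]
            + eps[i],
            "latitude_deg": latitudes[lab],
            "grs": grs[lab],
        }
        for i, lab in enumerate(labels)
    ]
    return pd.DataFrame(rows)


def simulate_two_phase(
    population_freq: np.ndarray,
    n_total: int,
    n_phase2: int,
    n_discordant: int = 0,
    config: SimulationConfig | None = None,
    shift: float = 0.15,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Total-cohort vs second-phase empirical frequencies.

    Alleles for the total cohort are drawn binomially at the true
    frequency; the second phase is a hypergeometric subsample of those
    alleles (a random subset of the cohort).  ``n_discordant`` SNPs then
    receive an injected frequency shift of ``shift`` (> 0.10, alternating
    sign, clipped to [0,1]) in the phase-2 vector so the concordance
    filter has known positives.  Returns (freq_total, freq_phase2,
    indices of injected SNPs).
    """
    if n_phase2 > n_total:
        raise ValueError("n_phase2 cannot exceed n_total")
    p = np.asarray(population_freq, dtype=float)
    if n_discordant > p.size:
        raise ValueError("more discordant SNPs requested than SNPs available")
    rng = substream(config.seed if config is not None else 0, "subsampling")
    k_total = rng.binomial(2 * n_total, p)
    freq_total = k_total / (2 * n_total)
    if n_phase2 == n_total:
        freq_phase2 = freq_total.copy()
    else:
        k_phase2 = rng.hypergeometric(k_total, 2 * n_total - k_total, 2 * n_phase2)
        freq_phase2 = k_phase2 / (2 * n_phase2)
    injected = rng.choice(p.size, size=n_discordant, replace=False)
    for rank, j in enumerate(sorted(injected)):
        direction = 1.0 if rank % 2 == 0 else -1.0
        if freq_phase2[j] + direction * shift > 1.0 or freq_phase2[j] + direction * shift < 0.0:
            direction = -direction
        freq_phase2[j] = float(np.clip(freq_phase2[j] + direction * shift, 0.0, 1.0))
    return freq_total, freq_phase2, np.sort(injected)


# --------------------------------------------------------------------------
# fixture emission: the same file formats the real pipeline consumes

_VCF_HEADER = """##fileformat=VCFv4.2
##source=vdfreq-simulator
##contig=<ID={chrom}>
##INFO=<ID=AC,Number=A,Type=Integer,Description="Alternate allele count">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
"""

_ALLELE_PAIRS = (("A", "G"), ("C", "T"), ("G", "A"), ("T", "C"), ("A", "C"), ("G", "T"))


def _simulated_catalog(rsids: list[str]) -> SnpCatalog:
    """Assign ref/alt pairs and effect alleles to the simulated SNPs.

    The simulated frequency is always the *effect*-allele frequency; the
    effect allele is ALT for most SNPs and REF for a deterministic minority
    so orientation handling is exercised.
    """
    records = []
    for i, rsid in enumerate(rsids):
        other, effect = _ALLELE_PAIRS[i % len(_ALLELE_PAIRS)]
        records.append(
            SnpRecord(
                rsid=rsid,
                chrom="1",
                position=1000 + 10 * i,
                mapped_gene=f"GENE{i % 7}",
                functional_class="intron_variant",
                effect_allele=effect,
                other_allele=other,
                effect_allele_resolved_by="catalog",
            )
        )
    return SnpCatalog(records, provenance="simulated")


def _vcf_orientation(rec: SnpRecord) -> tuple[str, str]:
    """(REF, ALT) written to fixture files for a simulated SNP.

    The effect allele is ALT for most SNPs; a deterministic minority (rsid
    ending in 4 or 9) stores it as REF so orientation handling is
    exercised by round-trip tests.
    """
    if rec.rsid.endswith(("4", "9")):
        return rec.effect_allele, rec.other_allele
    return rec.other_allele, rec.effect_allele


def _write_vcf(path: Path, catalog: SnpCatalog, genotypes: GenotypeMatrix) -> None:
    lines = [_VCF_HEADER.format(chrom="1")]
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(genotypes.sample_ids)
        + "\n"
    )
    for j, rec in enumerate(catalog):
        ref, alt = _vcf_orientation(rec)
        effect_is_alt = alt == rec.effect_allele
        gts = []
        ac = 0
        for i in range(genotypes.n_samples):
            d = genotypes.dosages[i, j]
            if np.isnan(d):
                gts.append("./.")
                continue
            alt_dose = int(d) if effect_is_alt else 2 - int(d)
            ac += alt_dose
            gts.append({0: "0/0", 1: "0/1", 2: "1/1"}[alt_dose])
        lines.append(
            f"{rec.chrom}\t{rec.position}\t{rec.rsid}\t{ref}\t{alt}\t.\tPASS\t"
            f"AC={ac}\tGT\t" + "\t".join(gts) + "\n"
        )
    path.write_text("".join(lines))


def _write_gwas_catalog_tsv(path: Path, catalog: SnpCatalog) -> None:
    """Catalog-dialect TSV with injected duplicates and '?' alleles."""
    header = "SNPS\tSTRONGEST SNP-RISK ALLELE\tCHR_ID\tCHR_POS\tMAPPED_GENE\tCONTEXT\tSTUDY ACCESSION\tDISEASE/TRAIT\n"
    rows = []
    for i, rec in enumerate(catalog):
        token = (
            f"{rec.rsid}-?" if i % 11 == 10 else f"{rec.rsid}-{rec.effect_allele}"
        )
        rows.append(
            f"{rec.rsid}\t{token}\t{rec.chrom}\t{rec.position}\t{rec.mapped_gene}\t"
            f"{rec.functional_class}\tGCST{900000 + i}\tVitamin D measurement\n"
        )
        if i % 13 == 12:  # duplicate association from a second study
            rows.append(
                f"{rec.rsid}\t{rec.rsid}-{rec.effect_allele}\t{rec.chrom}\t"
                f"{rec.position}\t{rec.mapped_gene}\t{rec.functional_class}\t"
                f"GCST{910000 + i}\tVitamin D measurement\n"
            )
    path.write_text(header + "".join(rows))


def emit_fixtures(out_dir: str | Path, config: SimulationConfig | None = None) -> dict[str, Path]:
    """Write a complete synthetic input set in the real pipeline's formats.

    Emits: VCF + sample map for every configured population except the
    frequency-only cohort (``KOR`` when present, mirroring a cohort
    published as frequencies), a KRGDB-dialect frequency TSV for that
    cohort, a GWAS-catalog-dialect association TSV (with injected
    duplicate rows and unknown-allele tokens for curation tests), and a
    phenotype TSV.  Returns the path of each artifact.
    """
    config = config or SimulationConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    freq, truth = simulate_allele_frequencies(config)
    catalog = _simulated_catalog(list(freq.columns))

    freq_only_label = "KOR" if "KOR" in freq.index else None
    vcf_labels = [l for l in freq.index if l != freq_only_label]
    vcf_config = replace(
        config,
        populations=tuple(p for p in config.populations if p.label in vcf_labels),
    )
    genotypes, panel = simulate_genotypes(freq.loc[vcf_labels], vcf_config)

    paths = {
        "vcf": out / "panel.vcf",
        "sample_map": out / "samples.tsv",
        "gwas_catalog": out / "gwas_catalog.tsv",
        "phenotypes": out / "phenotypes.tsv",
    }
    _write_vcf(paths["vcf"], catalog, genotypes)
    panel.to_tsv(paths["sample_map"])
    _write_gwas_catalog_tsv(paths["gwas_catalog"], catalog)

    if freq_only_label is not None:
        spec = next(p for p in config.populations if p.label == freq_only_label)
        paths["krgdb"] = out / "krgdb.tsv"
        rows = []
        for j, rec in enumerate(catalog):
            ref, alt = _vcf_orientation(rec)
            p_eff = float(freq.loc[freq_only_label].iloc[j])
            alt_freq = p_eff if alt == rec.effect_allele else 1.0 - p_eff
            rows.append((rec.rsid, ref, alt, round(alt_freq, 6), spec.n_individuals))
        pd.DataFrame(
            rows, columns=["ID", "REF", "ALT", "ALT_FREQ", "N_SAMPLES"]
        ).to_csv(paths["krgdb"], sep="\t", index=False)

    grs_by_pop = {lab: float(freq.loc[lab].mean()) for lab in freq.index}
    lat_by_pop = {p.label: p.latitude for p in config.populations}
    simulate_phenotypes(grs_by_pop, lat_by_pop, config).to_csv(
        paths["phenotypes"], sep="\t", index=False
    )
    return paths
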