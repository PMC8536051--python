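"""GWAS-catalog parsing and curation of a vitamin-D SNP panel.

The association export of the NHGRI-EBI GWAS catalog is a wide TSV whose
rows are study-level associations.  Curation proceeds in three steps:

1. :func:`parse_gwas_catalog` — read the export into light records, one per
   reported SNP (multi-SNP haplotype/interaction entries are split on the
   catalog's delimiters and logged);
2. :func:`deduplicate` — keep the first association per rsID, in file order;
3. :func:`harmonize_with_panel` — intersect with a reference panel
   (e.g. 1000 Genomes phase 3) and resolve the effect allele against the
   panel's REF/ALT pair, falling back to the panel minor allele when the
   catalog reports no risk allele ("rsXXXX-?").

Strand handling: an exact allele match is preferred; failing that, the
reverse complement is tried.  Strand-ambiguous A/T and C/G variants are
accepted on exact match only, and flagged in the log, because a complement
match is uninformative for them.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "RawAssociation",
    "SnpRecord",
    "SnpCatalog",
    "CatalogFormatError",
    "parse_gwas_catalog",
    "deduplicate",
    "harmonize_with_panel",
    "risk_allele_from_token",
]

BASES = frozenset("ACGT")
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: required columns of the GWAS-catalog association dialect
REQUIRED_COLUMNS = ("SNPS", "STRONGEST SNP-RISK ALLELE", "CHR_ID", "CHR_POS")

_RSID_RE = re.compile(r"^rs\d+$")
# catalog rows may list several SNPs: "rs1; rs2" (haplotypes) or
# "rs1 x rs2" (interactions)
_MULTI_SNP_SPLIT = re.compile(r";|\sx\s")


class CatalogFormatError(ValueError):
    """A catalog file does not conform to the expected dialect."""


def reverse_complement(allele: str) -> str:
    return allele.translate(_COMPLEMENT)[::-1]


def risk_allele_from_token(token: str) -> str | None:
    """Extract the allele from a ``rsID-X`` risk-allele token.

    Returns ``None`` when the catalog marks the allele unknown (``?``) or
    the token carries no single-base allele.
    """
    if "-" not in token:
        return None
    allele = token.rsplit("-", 1)[1].strip().upper()
    return allele if allele in BASES else None


@dataclass(frozen=True)
class RawAssociation:
    """One catalog association row, restricted to the fields curation uses."""

    rsid: str
    risk_allele_token: str
    chrom: str
    position: int | None
    mapped_gene: str = ""
    study_id: str = ""
    functional_class: str = ""

    def __post_init__(self) -> None:
        if not self.rsid:
            raise ValueError("rsid must be non-empty")
        if self.position is not None and self.position <= 0:
            raise ValueError(f"position must be positive, got {self.position}")

    @property
    def risk_allele(self) -> str | None:
        return risk_allele_from_token(self.risk_allele_token)


@dataclass(frozen=True)
class SnpRecord:
    """A curated SNP with a resolved effect/other allele pair."""

    rsid: str
    chrom: str
    position: int | None
    mapped_gene: str
    functional_class: str
    effect_allele: str
    other_allele: str
    effect_allele_resolved_by: str  # "catalog" | "minor_allele_fallback"

    def __post_init__(self) -> None:
        if self.effect_allele not in BASES or self.other_allele not in BASES:
            raise ValueError(
                f"{self.rsid}: alleles must be single bases, got "
                f"{self.effect_allele!r}/{self.other_allele!r}"
            )
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.rsid}: effect and other allele are equal")


@dataclass
class SnpCatalog:
    """Ordered, deduplicated list of curated SNPs."""

    records: list[SnpRecord]
    provenance: str = ""

    def __post_init__(self) -> None:
        seen = [r.rsid for r in self.records]
        if len(seen) != len(set(seen)):
            raise ValueError("SnpCatalog rsids must be unique")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SnpRecord]:
        return iter(self.records)

    def __getitem__(self, rsid: str) -> SnpRecord:
        for rec in self.records:
            if rec.rsid == rsid:
                return rec
        raise KeyError(rsid)

    @property
    def rsids(self) -> list[str]:
        return [r.rsid for r in self.records]

    def effect_alleles(self) -> dict[str, str]:
        return {r.rsid: r.effect_allele for r in self.records}

    def subset(self, rsids: Sequence[str]) -> "SnpCatalog":
        """Restrict to ``rsids``, preserving catalog order."""
        keep = set(rsids)
        return SnpCatalog(
            [r for r in self.records if r.rsid in keep], self.provenance
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rsid": [r.rsid for r in self.records],
                "chrom": [r.chrom for r in self.records],
                "pos": [r.position for r in self.records],
                "gene": [r.mapped_gene for r in self.records],
                "function": [r.functional_class for r in self.records],
                "effect_allele": [r.effect_allele for r in self.records],
                "other_allele": [r.other_allele for r in self.records],
                "resolved_by": [r.effect_allele_resolved_by for r in self.records],
            }
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, provenance: str = "") -> "SnpCatalog":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        records = [
            SnpRecord(
                rsid=row.rsid,
                chrom=str(row.chrom),
                position=None if pd.isna(row.pos) else int(row.pos),
                mapped_gene="" if pd.isna(row.gene) else str(row.gene),
                functional_class="" if pd.isna(row.function) else str(row.function),
                effect_allele=row.effect_allele,
                other_allele=row.other_allele,
                effect_allele_resolved_by=row.resolved_by,
            )
            for row in df.itertuples()
        ]
        return cls(records, provenance=provenance or str(path))


def parse_gwas_catalog(
    path: str | Path, trait: str | None = None
) -> list[RawAssociation]:
    """Read a GWAS-catalog association TSV into :class:`RawAssociation` rows.

    Parameters
    ----------
    path:
        Tab-separated association export (``SNPS``, ``STRONGEST SNP-RISK
        ALLELE``, ``CHR_ID``, ``CHR_POS`` required; ``MAPPED_GENE``,
        ``CONTEXT``, ``STUDY ACCESSION``, ``DISEASE/TRAIT`` used when present).
    trait:
        Optional case-insensitive substring filter on ``DISEASE/TRAIT``;
        trait restriction is normally done upstream by the catalog export.

    Rows whose SNP field yields no parseable rsID are skipped with a logged
    warning; multi-SNP entries are split into one association per rsID.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise CatalogFormatError(
            f"{path}: missing required column(s) {', '.join(missing)}"
        )
    if trait is not None and "DISEASE/TRAIT" in df.columns:
        df = df[df["DISEASE/TRAIT"].str.contains(trait, case=False, regex=False)]

    associations: list[RawAssociation] = []
    n_skipped = 0
    n_multi = 0
    for rowd in df.to_dict("records"):
        snp_field = rowd["SNPS"].strip()
        rsids = [t.strip() for t in _MULTI_SNP_SPLIT.split(snp_field) if t.strip()]
        rsids = [t for t in rsids if _RSID_RE.match(t)]
        if not rsids:
            n_skipped += 1
            logger.warning("skipping row with unparseable SNP field %r", snp_field)
            continue
        if len(rsids) > 1:
            n_multi += 1
            logger.warning(
                "multi-SNP entry %r split into %d associations", snp_field, len(rsids)
            )
        tokens = [
            t.strip()
            for t in _MULTI_SNP_SPLIT.split(rowd["STRONGEST SNP-RISK ALLELE"])
            if t.strip()
        ]
        try:
            position = int(rowd["CHR_POS"]) if rowd["CHR_POS"].strip() else None
        except ValueError:
            position = None
        for i, rsid in enumerate(rsids):
            token = tokens[i] if i < len(tokens) else f"{rsid}-?"
            associations.append(
                RawAssociation(
                    rsid=rsid,
                    risk_allele_token=token,
                    chrom=rowd["CHR_ID"].strip(),
                    position=position if len(rsids) == 1 else None,
                    mapped_gene=rowd.get("MAPPED_GENE", "").strip(),
                    study_id=rowd.get("STUDY ACCESSION", "").strip(),
                    functional_class=rowd.get("CONTEXT", "").strip(),
                )
            )
    if n_skipped:
        logger.warning("%d row(s) skipped for unparseable rsid", n_skipped)
    return associations


def deduplicate(associations: Iterable[RawAssociation]) -> list[RawAssociation]:
    """Keep the first association per rsID, preserving input order.

    The choice of occurrence is arbitrary for the frequency analysis (only
    the rsID and allele are used downstream); first-in-file is deterministic
    and auditable.  Idempotent.
    """
    seen: set[str] = set()
    out: list[RawAssociation] = []
    for assoc in associations:
        if assoc.rsid not in seen:
            seen.add(assoc.rsid)
            out.append(assoc)
    return out


def _is_strand_ambiguous(ref: str, alt: str) -> bool:
    # A/T and C/G pairs read the same on both strands
    return reverse_complement(ref) == alt


def harmonize_with_panel(
    associations: Iterable[RawAssociation],
    panel_alleles: Mapping[str, tuple[str, str]] | pd.DataFrame,
    panel_alt_freq: Mapping[str, float] | None = None,
    provenance: str = "",
) -> SnpCatalog:
    """Intersect associations with a reference panel and resolve effect alleles.

    Parameters
    ----------
    associations:
        Deduplicated catalog associations.
    panel_alleles:
        ``rsid -> (ref, alt)`` mapping, or a DataFrame with columns
        ``rsid, ref, alt`` and optionally ``alt_freq``.
    panel_alt_freq:
        ``rsid -> ALT allele frequency`` used for the minor-allele fallback
        when the catalog reports no risk allele.  May be embedded in the
        DataFrame form instead.

    Resolution order per SNP: exact match of the catalog allele against the
    panel pair; reverse-complement match (non-ambiguous SNPs only); panel
    minor allele when the catalog allele is unknown.  A stated catalog
    allele matching neither panel allele nor its complement drops the record
    with a warning.
    """
    if isinstance(panel_alleles, pd.DataFrame):
        df = panel_alleles
        if panel_alt_freq is None and "alt_freq" in df.columns:
            panel_alt_freq = dict(zip(df["rsid"], df["alt_freq"]))
        panel_alleles = {
            r.rsid: (str(r.ref).upper(), str(r.alt).upper()) for r in df.itertuples()
        }
    panel_alt_freq = panel_alt_freq or {}

    records: list[SnpRecord] = []
    n_absent = n_dropped = 0
    for assoc in associations:
        pair = panel_alleles.get(assoc.rsid)
        if pair is None:
            n_absent += 1
            continue
        ref, alt = pair
        if ref not in BASES or alt not in BASES or ref == alt:
            logger.warning("%s: panel alleles %s/%s not a SNV, dropped",
                           assoc.rsid, ref, alt)
            n_dropped += 1
            continue
        allele = assoc.risk_allele
        resolved_by = "catalog"
        if allele is None:
            # catalog reports "?": fall back to the panel minor allele
            freq = panel_alt_freq.get(assoc.rsid)
            if freq is None:
                logger.warning(
                    "%s: unknown risk allele and no panel frequency, dropped",
                    assoc.rsid,
                )
                n_dropped += 1
                continue
            allele = alt if freq <= 0.5 else ref
            resolved_by = "minor_allele_fallback"
        elif allele not in (ref, alt):
            flipped = reverse_complement(allele)
            if flipped in (ref, alt) and not _is_strand_ambiguous(ref, alt):
                logger.info("%s: strand flip %s->%s", assoc.rsid, allele, flipped)
                allele = flipped
            else:
                logger.warning(
                    "%s: catalog allele %s matches neither panel allele %s/%s "
                    "(or SNP is strand-ambiguous), dropped",
                    assoc.rsid, allele, ref, alt,
                )
                n_dropped += 1
                continue
        if _is_strand_ambiguous(ref, alt):
            logger.info("%s: strand-ambiguous %s/%s accepted on exact match",
                        assoc.rsid, ref, alt)
        other = alt if allele == ref else ref
        records.append(
            SnpRecord(
                rsid=assoc.rsid,
                chrom=assoc.chrom,
                position=assoc.position,
                mapped_gene=assoc.mapped_gene,
                functional_class=assoc.functional_class,
                effect_allele=allele,
                other_allele=other,
                effect_allele_resolved_by=resolved_by,
            )
        )
    if n_absent or n_dropped:
        logger.warning(
            "harmonization dropped %d record(s) absent from panel, "
            "%d with irreconcilable alleles", n_absent, n_dropped,
        )
    return SnpCatalog(records, provenance=provenance)
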