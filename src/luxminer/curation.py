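"""Curation of LuxI- and LuxR-family reference protein sets.

Reference collections (e.g. a UniProt export) arrive as a protein FASTA plus a
metadata table.  A :class:`CurationRule` expresses the mechanical part of the
curation applied to each family: bacterial taxonomy, a 100–500 aa length
window, required InterPro/Pfam domain annotations, and description-keyword
exclusions (e.g. dropping LuxR entries annotated as two-component systems,
which can belong to non-AHL signalling circuits).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWYX")

#: InterPro accession of the LuxI-family autoinducer synthase domain.
LUXI_DOMAINS = frozenset({"IPR001690"})
#: LuxR-family domains: C-terminal HTH (IPR000792) and N-terminal
#: autoinducer-binding domain (IPR005143 / IPR036693, integrating PF03472).
LUXR_DOMAINS = frozenset({"IPR000792", "IPR005143", "IPR036693"})


class CurationConfigError(ValueError):
    """Raised for an internally inconsistent curation rule."""


@dataclass(frozen=True)
class ProteinRecord:
    """A reference protein with the metadata fields used during curation."""

    accession: str
    sequence: str
    taxonomy: tuple[str, ...] = ()
    description: str = ""
    domain_annotations: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.accession:
            raise ValueError("accession must be non-empty")
        bad = set(self.sequence.upper()) - AMINO_ACIDS
        if bad:
            raise ValueError(
                f"{self.accession}: non-amino-acid symbols {sorted(bad)!r}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class CurationRule:
    """Declarative filter defining a family's positive reference set."""

    family: str  # "LuxI" or "LuxR"
    required_taxon: str = "Bacteria"
    length_min: int = 100
    length_max: int = 500
    required_domains: frozenset[str] = frozenset()
    exclude_description_keywords: tuple[str, ...] = ()
    include_description_keywords: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.length_min > self.length_max:
            raise CurationConfigError(
                f"length_min {self.length_min} > length_max {self.length_max}"
            )
        if not self.required_domains:
            raise CurationConfigError("required_domains must be non-empty")


def luxi_rule() -> CurationRule:
    """Default LuxI curation rule (bacteria, 100–500 aa, IPR001690)."""
    return CurationRule(family="LuxI", required_domains=LUXI_DOMAINS)


def luxr_rule() -> CurationRule:
    """Default LuxR curation rule; drops "two-component" descriptions."""
    return CurationRule(
        family="LuxR",
        required_domains=LUXR_DOMAINS,
        exclude_description_keywords=("two-component",),
    )


# reason codes for the exclusion report
REASON_TAXONOMY = "taxonomy"
REASON_LENGTH = "length"
REASON_DOMAIN = "missing_required_domain"
REASON_EXCLUDED_KEYWORD = "excluded_keyword"
REASON_MISSING_INCLUDE = "missing_include_keyword"


def exclusion_reason(record: ProteinRecord, rule: CurationRule) -> str | None:
    """Return the reason code excluding ``record``, or None if it passes.

    The first failing check (taxonomy, length, domains, keywords) wins; a
    record failing several rules therefore carries a single reason code.
    """
    if rule.required_taxon not in record.taxonomy:
        return REASON_TAXONOMY
    if not (rule.length_min <= record.length <= rule.length_max):
        return REASON_LENGTH
    if not (record.domain_annotations & rule.required_domains):
        return REASON_DOMAIN
    desc = record.description.lower()
    for kw in rule.exclude_description_keywords:
        if kw.lower() in desc:
            return REASON_EXCLUDED_KEYWORD
    if rule.include_description_keywords is not None:
        if not any(kw.lower() in desc for kw in rule.include_description_keywords):
            return REASON_MISSING_INCLUDE
    return None


def filter_reference_set(
    records: list[ProteinRecord],
    rule: CurationRule,
    *,
    return_exclusions: bool = False,
):
    """Apply ``rule`` to ``records``, preserving input order.

    Length bounds are inclusive at both ends; taxonomy membership is tested
    anywhere in the lineage; keyword matching is case-insensitive substring
    matching on the description.  With ``return_exclusions=True`` also return
    a list of (accession, reason-code) pairs for every dropped record.
    """
    kept: list[ProteinRecord] = []
    excluded: list[tuple[str, str]] = []
    for rec in records:
        reason = exclusion_reason(rec, rule)
        if reason is None:
            kept.append(rec)
        else:
            excluded.append((rec.accession, reason))
    if return_exclusions:
        return kept, excluded
    return kept


def deduplicate(records: list[ProteinRecord]) -> list[ProteinRecord]:
    """Drop records repeating an accession or an identical sequence.

    First occurrence wins; idempotent by construction.
    """
    seen_acc: set[str] = set()
    seen_seq: set[str] = set()
    out: list[ProteinRecord] = []
    for rec in records:
        if rec.accession in seen_acc or rec.sequence in seen_seq:
            continue
        seen_acc.add(rec.accession)
        seen_seq.add(rec.sequence)
        out.append(rec)
    return out


def assign_family(
    record: ProteinRecord,
    luxi_domains: frozenset[str] = LUXI_DOMAINS,
    luxr_domains: frozenset[str] = LUXR_DOMAINS,
) -> str:
    """Assign "LuxI", "LuxR", "ambiguous" or "none" from domain annotations.

    Records lacking domain metadata are "none" — sequence-based assignment is
    the job of a profile scan, not of curation.
    """
    has_i = bool(record.domain_annotations & luxi_domains)
    has_r = bool(record.domain_annotations & luxr_domains)
    if has_i and has_r:
        logger.warning("%s carries both LuxI and LuxR domains", record.accession)
        return "ambiguous"
    if has_i:
        return "LuxI"
    if has_r:
        return "LuxR"
    return "none"


# ---------------------------------------------------------------------------
# IO: protein FASTA + TSV metadata (accession, taxonomy, description, length,
# domains semicolon-separated)

def read_reference_collection(fasta: Path | str, metadata_tsv: Path | str) -> list[ProteinRecord]:
    """Read a FASTA + metadata TSV pair into :class:`ProteinRecord` objects."""
    meta = pd.read_csv(metadata_tsv, sep="\t", dtype=str).fillna("")
    meta = meta.set_index("accession")
    records = []
    for seq_rec in SeqIO.parse(str(fasta), "fasta"):
        acc = seq_rec.id
        row = meta.loc[acc]
        taxonomy = tuple(t for t in row["taxonomy"].split(";") if t)
        domains = frozenset(d for d in row["domains"].split(";") if d)
        rec = ProteinRecord(
            accession=acc,
            sequence=str(seq_rec.seq).upper(),
            taxonomy=taxonomy,
            description=row["description"],
            domain_annotations=domains,
        )
        if "length" in row.index and row["length"]:
            if int(row["length"]) != rec.length:
                raise ValueError(
                    f"{acc}: metadata length {row['length']} != sequence length {rec.length}"
                )
        records.append(rec)
    return records


def write_reference_collection(
    records: list[ProteinRecord], fasta: Path | str, metadata_tsv: Path | str
) -> None:
    """Write records as FASTA + metadata TSV (inverse of the reader)."""
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.accession, description="") for r in records
    ]
    SeqIO.write(seq_records, str(fasta), "fasta")
    pd.DataFrame(
        {
            "accession": [r.accession for r in records],
            "taxonomy": [";".join(r.taxonomy) for r in records],
            "description": [r.description for r in records],
            "length": [r.length for r in records],
            "domains": [";".join(sorted(r.domain_annotations)) for r in records],
        }
    ).to_csv(metadata_tsv, sep="\t", index=False)


def write_exclusion_report(
    excluded: list[tuple[str, str]], path: Path | str
) -> None:
    pd.DataFrame(excluded, columns=["accession", "reason"]).to_csv(
        path, sep="\t", index=False
    )
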