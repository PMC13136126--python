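"""Proteome extraction from annotated genomes and profile scanning.

Input is a nucleotide FASTA plus its annotation (GFF3 CDS features or a
GenBank flat file); no ab initio gene calling is performed.  Coordinates are
1-based inclusive throughout, the GFF3/GenBank convention, and all distance
arithmetic downstream relies on that.
"""

from __future__ import annotations

import logging
import urllib.parse
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

from .profiles import ProfileModel

logger = logging.getLogger(__name__)

# typical (not filtering) protein-length windows per family, aa, inclusive
TYPICAL_LENGTH = {"LuxI": (157, 257), "LuxR": (210, 272)}


@dataclass(frozen=True)
class GeneFeature:
    """An annotated CDS with 1-based inclusive coordinates."""

    seq_id: str
    start: int
    end: int
    strand: str
    locus_tag: str
    product: str = ""
    translation: str | None = None

    def __post_init__(self) -> None:
        if self.start < 1 or self.start > self.end:
            raise ValueError(
                f"{self.locus_tag}: invalid coordinates {self.start}..{self.end}"
            )
        if self.strand not in {"+", "-"}:
            raise ValueError(f"{self.locus_tag}: strand must be '+' or '-'")

    @property
    def span(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class HomologHit:
    """A scored family assignment on an annotated feature."""

    feature: GeneFeature
    family: str
    evalue: float
    bitscore: float
    protein_length: int
    length_class: str = "typical"
    architecture: str | None = None  # filled by the architecture module


# ---------------------------------------------------------------------------
# Annotation IO

def read_genome_fasta(path: Path | str) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def read_gff3(path: Path | str, feature_types: tuple[str, ...] = ("CDS",)) -> list[GeneFeature]:
    """Read CDS features from a GFF3 file into GeneFeature objects."""
    features: list[GeneFeature] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 9 or cols[2] not in feature_types:
                continue
            attrs = {}
            for item in cols[8].split(";"):
                if "=" in item:
                    k, v = item.split("=", 1)
                    attrs[k.strip()] = urllib.parse.unquote(v.strip())
            features.append(
                GeneFeature(
                    seq_id=cols[0],
                    start=int(cols[3]),
                    end=int(cols[4]),
                    strand=cols[6],
                    locus_tag=attrs.get("locus_tag", attrs.get("ID", "")),
                    product=attrs.get("product", ""),
                    translation=attrs.get("translation"),
                )
            )
    return features


def read_genbank(path: Path | str) -> tuple[dict[str, str], list[GeneFeature]]:
    """Read sequences and CDS features from a GenBank flat file."""
    genome: dict[str, str] = {}
    features: list[GeneFeature] = []
    for rec in SeqIO.parse(str(path), "genbank"):
        genome[rec.id] = str(rec.seq).upper()
        for f in rec.features:
            if f.type != "CDS":
                continue
            features.append(
                GeneFeature(
                    seq_id=rec.id,
                    start=int(f.location.start) + 1,
                    end=int(f.location.end),
                    strand="+" if f.location.strand != -1 else "-",
                    locus_tag=f.qualifiers.get("locus_tag", [""])[0],
                    product=f.qualifiers.get("product", [""])[0],
                    translation=f.qualifiers.get("translation", [None])[0],
                )
            )
    return genome, features


# ---------------------------------------------------------------------------
# Proteome extraction

def extract_proteome(
    genome: dict[str, str], features: list[GeneFeature]
) -> list[tuple[GeneFeature, str]]:
    """Translate annotated CDS features (table 11) into a proteome.

    Minus-strand CDS are reverse-complemented before translation; a trailing
    stop is removed.  Features that are out of contig bounds, not a multiple
    of three, or contain internal stops are excluded with a logged reason.
    When the annotation supplies a translation it is trusted (a mismatch
    with the computed translation logs a warning).
    """
    proteome: list[tuple[GeneFeature, str]] = []
    for feat in features:
        contig = genome.get(feat.seq_id)
        if contig is None or feat.end > len(contig):
            logger.warning("%s: outside contig bounds, skipped", feat.locus_tag)
            continue
        nt = contig[feat.start - 1 : feat.end]
        if feat.strand == "-":
            nt = str(Seq(nt).reverse_complement())
        if len(nt) % 3 != 0:
            logger.warning("%s: length not divisible by 3, flagged partial", feat.locus_tag)
            continue
        aa = str(Seq(nt).translate(table=11))
        if aa.endswith("*"):
            aa = aa[:-1]
        if "*" in aa:
            logger.warning("%s: internal stop, flagged pseudogene", feat.locus_tag)
            continue
        if feat.translation is not None:
            if feat.translation != aa:
                logger.warning(
                    "%s: supplied translation differs from computed one", feat.locus_tag
                )
            aa = feat.translation
        proteome.append((feat, aa))
    return proteome


# ---------------------------------------------------------------------------
# Scanning

def flag_length_class(family: str, protein_length: int) -> str:
    """'typical' iff the length falls in the family's canonical window."""
    lo, hi = TYPICAL_LENGTH.get(family, (0, 10 ** 9))
    return "typical" if lo <= protein_length <= hi else "atypical"


def scan_proteome(
    proteome: list[tuple[GeneFeature, str]],
    model: ProfileModel,
    *,
    cutoff: float | None = None,
) -> list[HomologHit]:
    """Scan a proteome with a family profile; hits sorted by e-value.

    E-values are scaled by the proteome size (whole-proteome scan); only
    hits at or below the model's inclusion cutoff (or an explicit override)
    are returned, at most one per feature.
    """
    if not proteome:
        return []
    cutoff = model.inclusion_cutoff if cutoff is None else cutoff
    by_tag = {feat.locus_tag: (feat, aa) for feat, aa in proteome}
    table = model.search([(feat.locus_tag, aa) for feat, aa in proteome])
    hits: list[HomologHit] = []
    for row in table.itertuples(index=False):
        if row.evalue > cutoff:
            continue
        feat, aa = by_tag[row.id]
        hits.append(
            HomologHit(
                feature=feat,
                family=model.family,
                evalue=float(row.evalue),
                bitscore=float(row.bitscore),
                protein_length=len(aa),
                length_class=flag_length_class(model.family, len(aa)),
            )
        )
    return hits


def hits_to_frame(hits: list[HomologHit]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "seq_id": h.feature.seq_id,
                "start": h.feature.start,
                "end": h.feature.end,
                "strand": h.feature.strand,
                "locus_tag": h.feature.locus_tag,
                "family": h.family,
                "evalue": h.evalue,
                "bitscore": h.bitscore,
                "length": h.protein_length,
                "length_class": h.length_class,
                "architecture": h.architecture or "",
            }
            for h in hits
        ],
        columns=[
            "seq_id", "start", "end", "strand", "locus_tag", "family",
            "evalue", "bitscore", "length", "length_class", "architecture",
        ],
    )


def write_hits(hits: list[HomologHit], tsv: Path | str, gff3: Path | str | None = None) -> None:
    """Write the hit table as TSV and optionally a GFF3 subset of features."""
    hits_to_frame(hits).to_csv(tsv, sep="\t", index=False, float_format="%.6g")
    if gff3 is not None:
        with open(gff3, "w") as fh:
            fh.write("##gff-version 3\n")
            for h in hits:
                f = h.feature
                attrs = f"ID={f.locus_tag};locus_tag={f.locus_tag};family={h.family}"
                fh.write(
                    f"{f.seq_id}\tluxminer\tCDS\t{f.start}\t{f.end}\t"
                    f"{h.evalue:.3g}\t{f.strand}\t0\t{attrs}\n"
                )


def with_architecture(hit: HomologHit, architecture: str) -> HomologHit:
    """Return a copy of the hit with its architecture slot filled."""
    return HomologHit(
        feature=hit.feature,
        family=hit.family,
        evalue=hit.evalue,
        bitscore=hit.bitscore,
        protein_length=hit.protein_length,
        length_class=hit.length_class,
        architecture=architecture,
    )
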