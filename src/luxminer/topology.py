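"""Genomic-context classification of luxI/luxR hits.

Signed intergenic distances (negative = overlap, 0 = abutting), relative
transcriptional orientation, cognate luxI/R pairing within a local window
(~3 kb), solo calls with exact nearest-partner distances, and flank gene
inventories with functional category tags.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .genome_scan import GeneFeature, HomologHit

DEFAULT_WINDOW_BP = 3000
FLANK_SCALES_BP = (3000, 10000)


# ---------------------------------------------------------------------------
# Distance and orientation arithmetic

def intergenic_distance(a: GeneFeature, b: GeneFeature) -> int | None:
    """Signed intergenic distance in bp; None across contigs.

    Disjoint features: number of bases strictly between them (abutting = 0).
    Overlapping features: minus the overlap length.  Symmetric.
    """
    if a.seq_id != b.seq_id:
        return None
    u, d = (a, b) if a.end <= b.end else (b, a)
    gap = d.start - u.end - 1
    if gap >= 0:
        return gap
    return -min(u.end - d.start + 1, u.span, d.span)


def classify_orientation(a: GeneFeature, b: GeneFeature) -> str:
    """Relative transcriptional orientation of two same-contig features.

    With u the upstream feature (smaller coordinate): co_directional when
    strands are equal, convergent when u is '+' and the downstream is '-'
    (3' ends facing), divergent in the opposite case (5' ends facing).
    """
    if a.seq_id != b.seq_id:
        raise ValueError("orientation is undefined across contigs")
    u, d = (a, b) if (a.start, a.end) <= (b.start, b.end) else (b, a)
    if u.strand == d.strand:
        return "co_directional"
    return "convergent" if u.strand == "+" else "divergent"


# ---------------------------------------------------------------------------
# Pair and solo calls

@dataclass(frozen=True)
class PairCall:
    """A cognate luxI/luxR pair within the local window."""

    luxI_hit: HomologHit
    luxR_hit: HomologHit
    distance_bp: int
    orientation: str
    window_bp: int = DEFAULT_WINDOW_BP
    luxR_architecture: str | None = None


@dataclass(frozen=True)
class SoloCall:
    """A hit with no family partner within the window."""

    hit: HomologHit
    partner_family: str
    nearest_partner_distance_bp: int | None  # None: no same-contig partner


_ARCH_RANK = {"CANONICAL": 0, "ABD_ONLY": 1, "HTH_ONLY": 2, "NONE": 3, None: 4, "": 4}


def _sorted_hits(hits: list[HomologHit]) -> list[HomologHit]:
    return sorted(hits, key=lambda h: (h.feature.seq_id, h.feature.start,
                                       h.feature.end, h.feature.locus_tag))


def find_cognate_pairs(
    hits: list[HomologHit], window_bp: int = DEFAULT_WINDOW_BP
) -> tuple[list[PairCall], list[SoloCall]]:
    """Pair luxI with luxR hits within ``window_bp``; rest become solos.

    Each luxI pairs with at most one luxR and vice versa.  Candidate pairs
    (|distance| <= window, same contig) are ranked preferring CANONICAL
    luxR architecture, then smallest |distance|, then smallest e-value;
    the globally best candidate is accepted repeatedly until none remain,
    which makes the result independent of input hit order.  Unpaired hits
    become SoloCalls carrying the exact distance to the nearest same-contig
    partner, however large.
    """
    luxi = _sorted_hits([h for h in hits if h.family == "LuxI"])
    luxr = _sorted_hits([h for h in hits if h.family == "LuxR"])

    candidates = []
    for i, hi in enumerate(luxi):
        for j, hr in enumerate(luxr):
            d = intergenic_distance(hi.feature, hr.feature)
            if d is None or abs(d) > window_bp:
                continue
            key = (_ARCH_RANK.get(hr.architecture, 4), abs(d), hr.evalue,
                   hi.feature.locus_tag, hr.feature.locus_tag)
            candidates.append((key, i, j, d))
    candidates.sort(key=lambda c: c[0])

    paired_i: set[int] = set()
    paired_r: set[int] = set()
    pairs: list[PairCall] = []
    for key, i, j, d in candidates:
        if i in paired_i or j in paired_r:
            continue
        paired_i.add(i)
        paired_r.add(j)
        hi, hr = luxi[i], luxr[j]
        pairs.append(
            PairCall(
                luxI_hit=hi,
                luxR_hit=hr,
                distance_bp=d,
                orientation=classify_orientation(hi.feature, hr.feature),
                window_bp=window_bp,
                luxR_architecture=hr.architecture,
            )
        )
    pairs.sort(key=lambda p: (p.luxI_hit.feature.seq_id, p.luxI_hit.feature.start))

    solos: list[SoloCall] = []
    for pool, partners, taken, partner_family in (
        (luxi, luxr, paired_i, "LuxR"),
        (luxr, luxi, paired_r, "LuxI"),
    ):
        for idx, h in enumerate(pool):
            if idx in taken:
                continue
            dists = [
                intergenic_distance(h.feature, p.feature)
                for p in partners
                if p.feature.seq_id == h.feature.seq_id
            ]
            dists = [d for d in dists if d is not None]
            nearest = min(dists, key=abs) if dists else None
            solos.append(SoloCall(hit=h, partner_family=partner_family,
                                  nearest_partner_distance_bp=nearest))
    return pairs, solos


# ---------------------------------------------------------------------------
# Neighborhood inventories

#: default keyword -> functional category map (first match wins, top to
#: bottom); keys are lower-case substrings of the annotated product text.
DEFAULT_CATEGORY_KEYWORDS: tuple[tuple[str, str], ...] = (
    ("electron transfer flavoprotein", "redox_electron_transfer"),
    ("etfa", "redox_electron_transfer"),
    ("etfb", "redox_electron_transfer"),
    ("fixb", "redox_electron_transfer"),
    ("oxidoreductase", "redox_electron_transfer"),
    ("methionine-sulfoxide reductase", "redox_electron_transfer"),
    ("cysteine desulfurase", "sulfur_trna"),
    ("2-thiouridylase", "sulfur_trna"),
    ("trna", "sulfur_trna"),
    ("monooxygenase", "secondary_metabolism"),
    ("dehydrogenase", "secondary_metabolism"),
    ("methyltransferase", "secondary_metabolism"),
    ("synthase", "secondary_metabolism"),
    ("histidine kinase", "stress_sensing"),
    ("stress", "stress_sensing"),
    ("transcriptional regulator", "regulator"),
    ("regulator", "regulator"),
    ("abc transporter", "transport"),
    ("permease", "transport"),
    ("transporter", "transport"),
    ("hypothetical", "hypothetical"),
)


def categorize_product(
    product_text: str,
    keyword_map: tuple[tuple[str, str], ...] = DEFAULT_CATEGORY_KEYWORDS,
) -> str:
    """First-match keyword categorization of an annotated product string."""
    text = product_text.lower()
    for keyword, category in keyword_map:
        if keyword in text:
            return category
    return "other"


@dataclass(frozen=True)
class NeighborhoodInventory:
    """Genes within +-flank_bp of a focal hit, in positional order."""

    focal_hit: HomologHit
    flank_bp: int
    #: (feature, signed offset bp, orientation relative to focal, category)
    genes: tuple[tuple[GeneFeature, int, str, str], ...]


def neighborhood_inventory(
    focal_hit: HomologHit,
    features: list[GeneFeature],
    flank_bp: int = DEFAULT_WINDOW_BP,
) -> NeighborhoodInventory:
    """List annotated genes intersecting the focal flank interval.

    Offsets are signed genome-coordinate distances from the focal feature
    (negative = upstream in genome coordinates); the focal feature itself
    is not listed.
    """
    focal = focal_hit.feature
    lo, hi = focal.start - flank_bp, focal.end + flank_bp
    rows = []
    for feat in features:
        if feat.seq_id != focal.seq_id or feat.locus_tag == focal.locus_tag:
            continue
        if feat.end < lo or feat.start > hi:
            continue
        d = intergenic_distance(focal, feat)
        if d is None:
            continue
        # overlap with the focal feature keeps its negative sign; otherwise
        # the gap is signed by genomic direction (negative = upstream)
        offset = d if d < 0 or feat.start >= focal.start else -d
        orientation = (
            "same_strand" if feat.strand == focal.strand else "opposite_strand"
        )
        rows.append((feat, offset, orientation, categorize_product(feat.product)))
    rows.sort(key=lambda r: (r[0].start, r[0].end, r[0].locus_tag))
    return NeighborhoodInventory(focal_hit=focal_hit, flank_bp=flank_bp,
                                 genes=tuple(rows))


# ---------------------------------------------------------------------------
# Exports

def pairs_to_frame(pairs: list[PairCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "seq_id": p.luxI_hit.feature.seq_id,
                "luxI_locus": p.luxI_hit.feature.locus_tag,
                "luxR_locus": p.luxR_hit.feature.locus_tag,
                "distance_bp": p.distance_bp,
                "orientation": p.orientation,
                "luxR_architecture": p.luxR_architecture or "",
                "window_bp": p.window_bp,
            }
            for p in pairs
        ],
        columns=["seq_id", "luxI_locus", "luxR_locus", "distance_bp",
                 "orientation", "luxR_architecture", "window_bp"],
    )


def solos_to_frame(solos: list[SoloCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "seq_id": s.hit.feature.seq_id,
                "locus_tag": s.hit.feature.locus_tag,
                "family": s.hit.family,
                "partner_family": s.partner_family,
                "nearest_partner_distance_bp": (
                    "" if s.nearest_partner_distance_bp is None
                    else s.nearest_partner_distance_bp
                ),
            }
            for s in solos
        ],
        columns=["seq_id", "locus_tag", "family", "partner_family",
                 "nearest_partner_distance_bp"],
    )


def inventory_to_frame(inv: NeighborhoodInventory) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "focal_locus": inv.focal_hit.feature.locus_tag,
                "flank_bp": inv.flank_bp,
                "locus_tag": feat.locus_tag,
                "start": feat.start,
                "end": feat.end,
                "strand": feat.strand,
                "offset_bp": offset,
                "orientation": orient,
                "category": cat,
                "product": feat.product,
            }
            for feat, offset, orient, cat in inv.genes
        ],
        columns=["focal_locus", "flank_bp", "locus_tag", "start", "end",
                 "strand", "offset_bp", "orientation", "category", "product"],
    )


def inventory_to_json(inv: NeighborhoodInventory, path: Path | str) -> None:
    """Per-locus JSON suitable for redrawing neighborhood diagrams."""
    focal = inv.focal_hit.feature
    payload = {
        "focal": {
            "locus_tag": focal.locus_tag, "seq_id": focal.seq_id,
            "start": focal.start, "end": focal.end, "strand": focal.strand,
            "family": inv.focal_hit.family,
        },
        "flank_bp": inv.flank_bp,
        "genes": [
            {
                "locus_tag": feat.locus_tag, "start": feat.start, "end": feat.end,
                "strand": feat.strand, "offset_bp": offset,
                "orientation": orient, "category": cat, "product": feat.product,
            }
            for feat, offset, orient, cat in inv.genes
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=1))
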