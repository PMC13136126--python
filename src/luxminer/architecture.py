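"""Domain-architecture classification of LuxR-family proteins.

Canonical LuxR regulators carry an N-terminal autoinducer-binding domain
(ABD) and a C-terminal helix-turn-helix (HTH) DNA-binding domain; a large
fraction of LuxR homologs retain only the HTH ("HTH-only").  Classification
is by domain presence/absence in the 2x2 table {ABD} x {HTH}; the expected
N-terminal-ABD / C-terminal-HTH order is checked only as an advisory
anomaly flag.

Domain evidence can come from a consumed InterProScan-style TSV or from
built-in mini-profiles for the ABD and HTH regions scanned with the
package's own engine; the evidence source is recorded per call.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd

from .profiles import ProfileModel, encode

#: domains whose presence marks an autoinducer-binding domain
ABD_DOMAINS = frozenset({"IPR005143", "IPR036693", "PF03472"})
#: domains whose presence marks the LuxR-family HTH DNA-binding domain
HTH_DOMAINS = frozenset({"IPR000792"})

DEFAULT_DOMAIN_EVALUE = 1e-5


class Architecture(str, Enum):
    CANONICAL = "CANONICAL"  # ABD + HTH
    HTH_ONLY = "HTH_ONLY"
    ABD_ONLY = "ABD_ONLY"
    NONE = "NONE"


@dataclass(frozen=True)
class DomainHit:
    """One domain-scan match on a protein (1-based inclusive aa positions)."""

    protein_id: str
    domain_accession: str
    start: int
    end: int
    evalue: float
    source: str = "tsv"

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise ValueError(
                f"{self.protein_id}/{self.domain_accession}: bad span "
                f"{self.start}..{self.end}"
            )


def classify_architecture(
    protein_length: int,
    domain_hits: list[DomainHit],
    *,
    evalue_threshold: float = DEFAULT_DOMAIN_EVALUE,
) -> tuple[Architecture, list[str]]:
    """Classify by ABD/HTH presence; returns (class, anomaly flags).

    A domain is "present" when any hit at or below the e-value threshold
    carries one of its accessions.  The order anomaly flag fires when the
    ABD midpoint lies C-terminal of the HTH midpoint.
    """
    for h in domain_hits:
        if h.end > protein_length:
            raise ValueError(
                f"{h.protein_id}: domain hit {h.domain_accession} ends at {h.end} "
                f"beyond protein length {protein_length}"
            )
    usable = [h for h in domain_hits if h.evalue <= evalue_threshold]
    abd = [h for h in usable if h.domain_accession in ABD_DOMAINS]
    hth = [h for h in usable if h.domain_accession in HTH_DOMAINS]
    if abd and hth:
        cls = Architecture.CANONICAL
    elif hth:
        cls = Architecture.HTH_ONLY
    elif abd:
        cls = Architecture.ABD_ONLY
    else:
        cls = Architecture.NONE
    flags: list[str] = []
    if abd and hth:
        abd_mid = min((h.start + h.end) / 2 for h in abd)
        hth_mid = max((h.start + h.end) / 2 for h in hth)
        if abd_mid > hth_mid:
            flags.append("abd_c_terminal_of_hth")
    return cls, flags


def summarize_counts(
    hits_with_architecture,
    genome_id: str,
) -> dict:
    """Per-genome homolog counts: luxI, luxR, and LuxR architecture classes.

    ``hits_with_architecture`` is an iterable of HomologHit with the
    architecture slot filled for LuxR hits.
    """
    n_luxi = n_luxr = n_canonical = n_hth_only = n_other = 0
    for h in hits_with_architecture:
        if h.family == "LuxI":
            n_luxi += 1
        elif h.family == "LuxR":
            n_luxr += 1
            if h.architecture == Architecture.CANONICAL.value:
                n_canonical += 1
            elif h.architecture == Architecture.HTH_ONLY.value:
                n_hth_only += 1
            else:
                n_other += 1
    return {
        "genome_id": genome_id,
        "n_luxI": n_luxi,
        "n_luxR": n_luxr,
        "n_canonical": n_canonical,
        "n_hth_only": n_hth_only,
        "n_other": n_other,
    }


# ---------------------------------------------------------------------------
# Evidence source (a): InterProScan TSV

#: InterProScan TSV columns (no header in the format)
IPRSCAN_COLUMNS = [
    "protein_accession", "md5", "length", "analysis", "signature_accession",
    "signature_description", "start", "stop", "score", "status", "date",
    "interpro_accession", "interpro_description",
]


def read_interproscan_tsv(path: Path | str) -> list[DomainHit]:
    """Parse the InterProScan TSV dialect into DomainHit objects.

    Both the member-database signature accession (e.g. PF03472) and the
    integrated InterPro accession (e.g. IPR005143) yield a hit so that
    either vocabulary can drive classification.
    """
    df = pd.read_csv(
        path, sep="\t", header=None, names=IPRSCAN_COLUMNS,
        usecols=range(len(IPRSCAN_COLUMNS)), dtype=str,
    )
    hits: list[DomainHit] = []
    for row in df.itertuples(index=False):
        try:
            ev = float(row.score)
        except (TypeError, ValueError):
            ev = 0.0  # some analyses report '-' instead of an e-value
        for acc in {row.signature_accession, row.interpro_accession}:
            if not acc or pd.isna(acc) or acc == "-":
                continue
            hits.append(
                DomainHit(
                    protein_id=row.protein_accession,
                    domain_accession=acc,
                    start=int(row.start),
                    end=int(row.stop),
                    evalue=ev,
                    source="interproscan_tsv",
                )
            )
    return hits


# ---------------------------------------------------------------------------
# Evidence source (b): built-in mini-profiles

def _best_segment_with_location(query: str, pssm: np.ndarray) -> tuple[float, int, int]:
    """Best gap-free local score and its 1-based query interval."""
    codes = encode(query)
    q, L = len(codes), pssm.shape[0]
    M = pssm[:, codes].T
    B = np.zeros((q, L + q - 1), dtype=np.float64)
    cols = np.arange(L)[None, :] - np.arange(q)[:, None] + (q - 1)
    np.put_along_axis(B, cols, M, axis=1)
    prefix = np.vstack([np.zeros(B.shape[1]), np.cumsum(B, axis=0)])
    running_min = prefix[0].copy()
    best, best_i, best_k, best_c = -np.inf, 0, 0, 0
    min_idx = np.zeros(B.shape[1], dtype=np.int64)
    for i in range(q):
        gains = prefix[i + 1] - running_min
        c = int(np.argmax(gains))
        if gains[c] > best:
            best, best_i, best_k, best_c = float(gains[c]), i, int(min_idx[c]), c
        better = prefix[i + 1] < running_min
        running_min = np.where(better, prefix[i + 1], running_min)
        min_idx = np.where(better, i + 1, min_idx)
    return max(best, 0.0), best_k + 1, best_i + 1


def domain_scan_with_profiles(
    proteins: list[tuple[str, str]],
    domain_models: dict[str, ProfileModel],
    *,
    evalue_threshold: float = DEFAULT_DOMAIN_EVALUE,
) -> list[DomainHit]:
    """Scan proteins with mini-profiles keyed by domain accession.

    Each model is a profile built (by the profile module) from curated
    sub-domain sequences; a hit is emitted at the best-scoring segment when
    its e-value passes the threshold.
    """
    hits: list[DomainHit] = []
    for name, seq in proteins:
        for accession, model in domain_models.items():
            score, start, end = _best_segment_with_location(seq, model.pssm)
            ev = 10.0 ** model.log10_evalue(score, len(seq), z=max(len(proteins), 1))
            if ev <= evalue_threshold:
                hits.append(
                    DomainHit(
                        protein_id=name,
                        domain_accession=accession,
                        start=start,
                        end=end,
                        evalue=ev,
                        source="builtin_miniprofile",
                    )
                )
    return hits


# ---------------------------------------------------------------------------
# Exports

def architecture_frame(assignments: dict[str, tuple[Architecture, list[str]]]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"protein_id": pid, "architecture": cls.value, "flags": ";".join(flags)}
            for pid, (cls, flags) in assignments.items()
        ],
        columns=["protein_id", "architecture", "flags"],
    )


def write_itol_binary_dataset(
    assignments: dict[str, Architecture], path: Path | str,
    dataset_label: str = "LuxR architecture",
) -> None:
    """iTOL-compatible binary dataset marking canonical vs HTH-only leaves."""
    lines = [
        "DATASET_BINARY",
        "SEPARATOR TAB",
        f"DATASET_LABEL\t{dataset_label}",
        "COLOR\t#2166ac",
        "FIELD_SHAPES\t2\t3",
        "FIELD_LABELS\tABD+HTH\tHTH-only",
        "DATA",
    ]
    for leaf, arch in assignments.items():
        canon = 1 if arch == Architecture.CANONICAL else -1
        hth = 1 if arch == Architecture.HTH_ONLY else -1
        lines.append(f"{leaf}\t{canon}\t{hth}")
    Path(path).write_text("\n".join(lines) + "\n")
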