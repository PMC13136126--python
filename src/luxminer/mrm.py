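"""AHL mass arithmetic and LC-MRM-MS transition matching.

An N-acyl homoserine lactone (AHL) is a homoserine lactone ring amide-linked
to an acyl chain of n carbons, optionally carrying a 3-oxo substitution.
On a unit-resolution triple-quadrupole instrument every AHL shares one
diagnostic product ion: the protonated homoserine lactone ring at nominal
m/z 102 (neutral-loss signature).  Screening therefore matches observed
(precursor, product, retention-time) transitions against a standards table;
peaks that fragment to m/z 102 but fit no standard precursor are reported
as putative unknown AHLs with their retention time, never silently dropped.

Molecular formulas follow from the scaffold: the unsubstituted Cn-HSL is
C(n+4) H(2(n+4)-3) N O3 and the 3-oxo variant replaces two hydrogens with
one oxygen, C(n+4) H(2(n+4)-5) N O4.  Nominal (integer) masses mirror the
instrument's unit resolution; monoisotopic masses are carried alongside to
four decimals for completeness.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

NOMINAL_MASS = {"C": 12, "H": 1, "N": 14, "O": 16}
MONOISOTOPIC_MASS = {"C": 12.0, "H": 1.00783, "N": 14.00307, "O": 15.99491}

#: molecular formula of the neutral homoserine lactone ring fragment; its
#: protonated ion is the diagnostic MRM product for every AHL
HSL_RING_FORMULA = {"C": 4, "H": 7, "N": 1, "O": 2}

DEFAULT_MZ_TOL = 0.5  # Da, unit-resolution quadrupole practice
DEFAULT_RT_TOL = 0.2  # minutes


def nominal_mass(formula: dict[str, int]) -> int:
    return sum(NOMINAL_MASS[el] * n for el, n in formula.items())


def monoisotopic_mass(formula: dict[str, int]) -> float:
    return round(sum(MONOISOTOPIC_MASS[el] * n for el, n in formula.items()), 4)


def hsl_fragment_mz() -> int:
    """Nominal m/z of the protonated homoserine lactone ring product ion."""
    return nominal_mass(HSL_RING_FORMULA) + NOMINAL_MASS["H"]


def ahl_formula(n: int, is_3oxo: bool) -> dict[str, int]:
    """Molecular formula of an AHL with an n-carbon acyl chain."""
    if n < 4:
        raise ValueError("acyl chains shorter than 4 carbons are not AHLs")
    carbons = n + 4
    if is_3oxo:
        return {"C": carbons, "H": 2 * carbons - 5, "N": 1, "O": 4}
    return {"C": carbons, "H": 2 * carbons - 3, "N": 1, "O": 3}


@dataclass(frozen=True)
class AhlSpecies:
    """An AHL analyte and its MRM transition."""

    chain_length: int
    is_3oxo: bool
    reference_rt: float | None = None  # minutes, from the standards table

    def __post_init__(self) -> None:
        if self.chain_length < 4:
            raise ValueError("chain_length must be >= 4")

    @property
    def name(self) -> str:
        return f"{'3-oxo-' if self.is_3oxo else ''}C{self.chain_length}"

    @property
    def molecular_formula(self) -> dict[str, int]:
        return ahl_formula(self.chain_length, self.is_3oxo)

    @property
    def nominal_mass(self) -> int:
        return nominal_mass(self.molecular_formula)

    @property
    def monoisotopic_mass(self) -> float:
        return monoisotopic_mass(self.molecular_formula)

    @property
    def precursor_mz(self) -> int:
        """Nominal [M+H]+ m/z."""
        return self.nominal_mass + NOMINAL_MASS["H"]

    @property
    def product_mz(self) -> int:
        return hsl_fragment_mz()


def precursor_mz(species: AhlSpecies) -> int:
    return species.precursor_mz


#: the ten AHL standards screened by the study, with their observed
#: retention times (minutes)
STANDARD_RT = {
    ("3-oxo-C6", 6, True): 3.0,
    ("C6", 6, False): 3.8,
    ("C7", 7, False): 4.3,
    ("C8", 8, False): 4.6,
    ("3-oxo-C10", 10, True): 4.9,
    ("C10", 10, False): 5.4,
    ("3-oxo-C12", 12, True): 5.6,
    ("C12", 12, False): 6.1,
    ("3-oxo-C14", 14, True): 6.3,
    ("C14", 14, False): 6.8,
}


def default_standards() -> list[AhlSpecies]:
    """The ten-standard panel with reference retention times."""
    return [
        AhlSpecies(chain_length=n, is_3oxo=oxo, reference_rt=rt)
        for (_, n, oxo), rt in STANDARD_RT.items()
    ]


def standards_table(standards: list[AhlSpecies] | None = None) -> pd.DataFrame:
    """Standards as a DataFrame (name, n, is_3oxo, mz, monoisotopic, rt)."""
    standards = default_standards() if standards is None else standards
    return pd.DataFrame(
        [
            {
                "name": s.name,
                "n": s.chain_length,
                "is_3oxo": s.is_3oxo,
                "mz": s.precursor_mz,
                "monoisotopic_mz": round(s.monoisotopic_mass + MONOISOTOPIC_MASS["H"], 4),
                "rt": s.reference_rt,
            }
            for s in standards
        ]
    )


def read_standards_csv(path: Path | str) -> list[AhlSpecies]:
    df = pd.read_csv(path)
    return [
        AhlSpecies(
            chain_length=int(r["n"]),
            is_3oxo=bool(r["is_3oxo"]),
            reference_rt=None if pd.isna(r.get("rt")) else float(r["rt"]),
        )
        for _, r in df.iterrows()
    ]


# ---------------------------------------------------------------------------
# Transition matching

@dataclass(frozen=True)
class Transition:
    """An observed MRM peak."""

    sample_id: str
    precursor_mz_obs: float
    product_mz_obs: float
    rt_obs: float
    peak_area: float

    def __post_init__(self) -> None:
        if self.peak_area < 0:
            raise ValueError("peak_area must be >= 0")
        if self.precursor_mz_obs <= 0 or self.product_mz_obs <= 0:
            raise ValueError("m/z values must be positive")


def read_peaklist_csv(path: Path | str) -> list[Transition]:
    df = pd.read_csv(path)
    return [
        Transition(
            sample_id=str(r["sample"]),
            precursor_mz_obs=float(r["precursor_mz"]),
            product_mz_obs=float(r["product_mz"]),
            rt_obs=float(r["rt"]),
            peak_area=float(r["peak_area"]),
        )
        for _, r in df.iterrows()
    ]


def match_transitions(
    peaks: list[Transition],
    standards: list[AhlSpecies] | None = None,
    mz_tol: float = DEFAULT_MZ_TOL,
    rt_tol: float = DEFAULT_RT_TOL,
) -> pd.DataFrame:
    """Assign each peak exactly one verdict: matched / unknown / ignored.

    A peak matches a standard iff its product ion is within ``mz_tol`` of
    the homoserine-lactone fragment (m/z 102), its precursor is within
    ``mz_tol`` of the standard's [M+H]+, and — when the standard carries a
    reference retention time — the observed retention time is within
    ``rt_tol``.  Ties between standards sharing a nominal precursor (the
    C7 / 3-oxo-C6 pair at m/z 214) resolve by retention time; when no
    retention time discriminates, the peak is matched to the closest
    precursor and flagged ambiguous.  Peaks fragmenting to ~102 with no
    matching precursor are putative unknown AHLs, reported with their
    retention time; peaks with product ions far from 102 are ignored.
    """
    if mz_tol < 0 or rt_tol < 0:
        raise ValueError("tolerances must be non-negative")
    standards = default_standards() if standards is None else standards
    fragment = hsl_fragment_mz()
    rows = []
    for peak in peaks:
        if abs(peak.product_mz_obs - fragment) > mz_tol:
            rows.append(_verdict_row(peak, "ignored", None, ""))
            continue
        candidates = [
            s for s in standards
            if abs(peak.precursor_mz_obs - s.precursor_mz) <= mz_tol
        ]
        with_rt = [
            s for s in candidates
            if s.reference_rt is not None and abs(peak.rt_obs - s.reference_rt) <= rt_tol
        ]
        no_rt = [s for s in candidates if s.reference_rt is None]
        viable = with_rt + no_rt
        if viable:
            best = min(
                viable,
                key=lambda s: (
                    abs(peak.rt_obs - s.reference_rt) if s.reference_rt is not None else rt_tol,
                    abs(peak.precursor_mz_obs - s.precursor_mz),
                ),
            )
            note = "ambiguous_precursor" if len(viable) > 1 else ""
            rows.append(_verdict_row(peak, "matched", best, note))
        else:
            note = "rt_mismatch" if candidates else ""
            rows.append(_verdict_row(peak, "unknown", None, note))
    return pd.DataFrame(
        rows,
        columns=["sample", "precursor_mz", "product_mz", "rt", "peak_area",
                 "verdict", "analyte", "note"],
    )


def _verdict_row(peak: Transition, verdict: str, species: AhlSpecies | None, note: str):
    if verdict == "unknown":
        analyte = f"putative unknown AHL ({peak.rt_obs:g})"
    else:
        analyte = species.name if species is not None else ""
    return {
        "sample": peak.sample_id,
        "precursor_mz": peak.precursor_mz_obs,
        "product_mz": peak.product_mz_obs,
        "rt": peak.rt_obs,
        "peak_area": peak.peak_area,
        "verdict": verdict,
        "analyte": analyte,
        "note": note,
    }


def presence_matrix(
    matches: pd.DataFrame,
    standards: list[AhlSpecies] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Detected/– table (analyte x sample) plus a relative peak-area table.

    Peak areas are for relative comparison only; absolute quantification is
    out of scope of an MRM screen like this one.
    """
    standards = default_standards() if standards is None else standards
    analytes = [s.name for s in standards]
    samples = sorted(matches["sample"].unique()) if len(matches) else []
    matched = matches[matches["verdict"] == "matched"]
    unknown = matches[matches["verdict"] == "unknown"]
    unknown_analytes = sorted(unknown["analyte"].unique())
    index = analytes + unknown_analytes
    detect = pd.DataFrame("–", index=index, columns=samples)
    areas = pd.DataFrame(0.0, index=index, columns=samples)
    for sub in (matched, unknown):
        for row in sub.itertuples(index=False):
            detect.loc[row.analyte, row.sample] = "Detected"
            areas.loc[row.analyte, row.sample] += row.peak_area
    detect.index.name = "analyte"
    areas.index.name = "analyte"
    return detect, areas
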