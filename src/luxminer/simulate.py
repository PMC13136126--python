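"""Ground-truthed synthetic inputs for every pipeline stage.

Generates (a) protein families as mutated copies of a random ancestor plus
unrelated decoys with labels, (b) annotated genomes with planted luxI/luxR
loci at specified intergenic distances (including overlaps), strands and
domain architectures among neutral neighborhood genes, together with a
truth table, and (c) MRM peak lists with planted AHL transitions and noise.

Every generator is a pure function of (specification, seed).  The planted
genome layouts use the vocabulary of real luxI neighborhoods — cognate
pairs tens of bp apart, solos flanked by sulfur/tRNA and electron-transfer
genes, scattered HTH-only luxR regulators — so the downstream scan,
architecture, topology and MRM stages are exercised under realistic
geometry without downloading anything.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import unambiguous_dna_by_id

from .genome_scan import GeneFeature
from .mrm import AhlSpecies, default_standards, hsl_fragment_mz
from .profiles import AA20

# default family geometry: ancestor lengths (aa) and per-site substitution
# probability applied independently to every member
LUXI_LENGTH = 200
ABD_LENGTH = 160
HTH_LENGTH = 60
HTH_ONLY_NTERM_LENGTH = 150
DEFAULT_MUTATION_RATE = 0.1

_TABLE11 = unambiguous_dna_by_id[11]
_CODONS_FOR: dict[str, list[str]] = {}
for codon, aa in sorted(_TABLE11.forward_table.items()):
    _CODONS_FOR.setdefault(aa, []).append(codon)


# ---------------------------------------------------------------------------
# Protein families and decoys

@dataclass(frozen=True)
class FamilySpec:
    """Specification of a synthetic protein family."""

    name: str
    length: int
    mutation_rate: float = DEFAULT_MUTATION_RATE


def random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AA20), size=length))


def mutate(sequence: str, rate: float, rng: np.random.Generator) -> str:
    """Independent per-site substitution to one of the 19 other residues."""
    out = list(sequence)
    hit = rng.random(len(out)) < rate
    for i in np.flatnonzero(hit):
        alternatives = [a for a in AA20 if a != out[i]]
        out[i] = alternatives[rng.integers(len(alternatives))]
    return "".join(out)


def generate_family(
    spec: FamilySpec, n_members: int, seed: int
) -> tuple[str, list[tuple[str, str]]]:
    """Mutated copies of a seeded random ancestor; all members positives.

    Returns (ancestor, [(member id, sequence), ...]); reproducible per seed.
    """
    if not 0 <= spec.mutation_rate < 0.5:
        raise ValueError("mutation_rate must be in [0, 0.5)")
    rng = np.random.default_rng(seed)
    ancestor = random_protein(rng, spec.length)
    members = [
        (f"{spec.name}_m{i}", mutate(ancestor, spec.mutation_rate, rng))
        for i in range(n_members)
    ]
    return ancestor, members


def expected_pairwise_identity(rate: float) -> float:
    """Closed-form mean identity of two independently mutated copies."""
    return (1.0 - rate) ** 2 + (rate ** 2) / 19.0


def generate_decoys(
    n: int, length_range: tuple[int, int], seed: int, prefix: str = "decoy"
) -> list[tuple[str, str]]:
    """Unrelated random proteins (uniform residue background), labelled."""
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        out.append((f"{prefix}_{i}", random_protein(rng, length)))
    return out


def write_fasta(records: list[tuple[str, str]], path: Path | str) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n{seq}\n")


# ---------------------------------------------------------------------------
# A coherent set of QS protein families for genome planting

@dataclass
class FamilyKit:
    """Seeded ancestors for LuxI, the LuxR ABD and the LuxR HTH domain.

    Canonical LuxR proteins are an ABD segment followed by an HTH segment
    (N-terminal ABD, C-terminal HTH); HTH-only proteins replace the ABD
    with unrelated sequence.  Segment lengths put LuxI members at 200 aa
    and LuxR members at 210–220 aa, inside each family's typical window.
    """

    seed: int
    mutation_rate: float = DEFAULT_MUTATION_RATE

    def __post_init__(self) -> None:
        rng = np.random.default_rng(self.seed)
        self.luxi_ancestor = random_protein(rng, LUXI_LENGTH)
        self.abd_ancestor = random_protein(rng, ABD_LENGTH)
        self.hth_ancestor = random_protein(rng, HTH_LENGTH)

    def luxi_member(self, rng: np.random.Generator) -> str:
        return mutate(self.luxi_ancestor, self.mutation_rate, rng)

    def luxr_member(self, rng: np.random.Generator, architecture: str) -> str:
        hth = mutate(self.hth_ancestor, self.mutation_rate, rng)
        if architecture == "CANONICAL":
            return mutate(self.abd_ancestor, self.mutation_rate, rng) + hth
        if architecture == "HTH_ONLY":
            return random_protein(rng, HTH_ONLY_NTERM_LENGTH) + hth
        raise ValueError(f"unsupported planted architecture {architecture!r}")

    def training_sets(self, n_members: int, seed: int):
        """(luxI members, canonical luxR members, ABD segments, HTH segments)."""
        rng = np.random.default_rng(seed)
        luxi = [(f"luxI_t{i}", self.luxi_member(rng)) for i in range(n_members)]
        luxr, abd, hth = [], [], []
        for i in range(n_members):
            a = mutate(self.abd_ancestor, self.mutation_rate, rng)
            h = mutate(self.hth_ancestor, self.mutation_rate, rng)
            luxr.append((f"luxR_t{i}", a + h))
            abd.append((f"abd_t{i}", a))
            hth.append((f"hth_t{i}", h))
        return luxi, luxr, abd, hth


# ---------------------------------------------------------------------------
# Genome plans

@dataclass(frozen=True)
class LocusSpec:
    """One planted gene.

    ``gap`` is the signed intergenic distance to the previous locus on the
    contig (negative = overlap); ``start`` may instead pin the locus to an
    absolute 1-based coordinate.  ``pair_with`` declares the expected
    cognate partner (by locus tag) for truth-table purposes.
    """

    locus_tag: str
    kind: str  # "luxI" | "luxR" | "neighbor"
    strand: str = "+"
    gap: int | None = None
    start: int | None = None
    architecture: str | None = None  # for luxR loci
    product: str = ""
    length_aa: int | None = None  # neighbors only; families fix their own
    pair_with: str | None = None


@dataclass(frozen=True)
class ContigPlan:
    seq_id: str
    length: int
    loci: tuple[LocusSpec, ...]


@dataclass(frozen=True)
class GenomePlan:
    contigs: tuple[ContigPlan, ...]
    seed: int
    mutation_rate: float = DEFAULT_MUTATION_RATE


def back_translate(protein: str, rng: np.random.Generator) -> str:
    """Uniform synonymous codon choice per residue (table 11) plus a stop."""
    codons = [
        _CODONS_FOR[aa][rng.integers(len(_CODONS_FOR[aa]))] for aa in protein
    ]
    return "".join(codons) + "TAA"


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def generate_genome(
    plan: GenomePlan, kit: FamilyKit | None = None
) -> tuple[dict[str, str], list[GeneFeature], pd.DataFrame, list[dict]]:
    """Emit (contig sequences, CDS features, truth table, domain hits).

    Planted CDS are back-translated family members (no internal stops by
    construction); the rest of each contig is random background DNA.  The
    returned domain-hit dicts describe the planted ABD/HTH/synthase domains
    in InterProScan vocabulary, consistent with each locus's architecture.
    """
    kit = kit if kit is not None else FamilyKit(plan.seed, plan.mutation_rate)
    rng = np.random.default_rng(plan.seed + 1)
    genome: dict[str, str] = {}
    features: list[GeneFeature] = []
    truth_rows = []
    domain_rows = []
    for contig in plan.contigs:
        seq = list("".join(rng.choice(list("ACGT"), size=contig.length)))
        prev_end = 0
        for locus in contig.loci:
            if locus.kind == "luxI":
                protein = kit.luxi_member(rng)
                family = "LuxI"
            elif locus.kind == "luxR":
                arch = locus.architecture or "CANONICAL"
                protein = kit.luxr_member(rng, arch)
                family = "LuxR"
            else:
                protein = random_protein(rng, locus.length_aa or 120)
                family = "none"
            cds = back_translate(protein, rng)
            if locus.start is not None:
                start = locus.start
            elif locus.gap is not None:
                start = prev_end + locus.gap + 1
            else:
                start = prev_end + int(rng.integers(100, 400)) + 1
            end = start + len(cds) - 1
            if start < 1 or end > contig.length:
                raise ValueError(
                    f"{locus.locus_tag}: planted CDS {start}..{end} outside "
                    f"contig {contig.seq_id} (length {contig.length})"
                )
            insert = cds if locus.strand == "+" else _revcomp(cds)
            seq[start - 1 : end] = list(insert)
            prev_end = max(prev_end, end)
            features.append(
                GeneFeature(
                    seq_id=contig.seq_id, start=start, end=end,
                    strand=locus.strand, locus_tag=locus.locus_tag,
                    product=locus.product,
                )
            )
            truth_rows.append(
                {
                    "locus_tag": locus.locus_tag,
                    "seq_id": contig.seq_id,
                    "start": start,
                    "end": end,
                    "strand": locus.strand,
                    "family": family,
                    "architecture": locus.architecture or "",
                    "pair_with": locus.pair_with or "",
                    "product": locus.product,
                }
            )
            if family == "LuxI":
                domain_rows.append(
                    {"protein_id": locus.locus_tag, "domain_accession": "IPR001690",
                     "start": 1, "end": len(protein), "evalue": 1e-30}
                )
            elif family == "LuxR":
                arch = locus.architecture or "CANONICAL"
                hth_start = len(protein) - HTH_LENGTH + 1
                if arch == "CANONICAL":
                    domain_rows.append(
                        {"protein_id": locus.locus_tag, "domain_accession": "IPR005143",
                         "start": 1, "end": ABD_LENGTH, "evalue": 1e-25}
                    )
                domain_rows.append(
                    {"protein_id": locus.locus_tag, "domain_accession": "IPR000792",
                     "start": hth_start, "end": len(protein), "evalue": 1e-20}
                )
        genome[contig.seq_id] = "".join(seq)
    truth = pd.DataFrame(truth_rows)
    return genome, features, truth, domain_rows


def write_genome(
    genome: dict[str, str], features: list[GeneFeature],
    fasta_path: Path | str, gff3_path: Path | str,
) -> None:
    with open(fasta_path, "w") as fh:
        for seq_id, seq in genome.items():
            fh.write(f">{seq_id}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
    with open(gff3_path, "w") as fh:
        fh.write("##gff-version 3\n")
        for seq_id, seq in genome.items():
            fh.write(f"##sequence-region {seq_id} 1 {len(seq)}\n")
        for f in features:
            attrs = f"ID={f.locus_tag};locus_tag={f.locus_tag};product={f.product}"
            fh.write(
                f"{f.seq_id}\tluxminer_sim\tCDS\t{f.start}\t{f.end}\t.\t"
                f"{f.strand}\t0\t{attrs}\n"
            )


# neighbor product vocabulary drawn from real luxI neighborhoods
NEIGHBOR_PRODUCTS = (
    "cysteine desulfurase",
    "tRNA-specific 2-thiouridylase",
    "electron transfer flavoprotein subunit A",
    "electron transfer flavoprotein subunit B",
    "monooxygenase",
    "sensor histidine kinase",
    "ABC transporter ATP-binding protein",
    "hypothetical protein",
)


def default_plan(seed: int = 13, n_scattered_hth_only: int = 20) -> GenomePlan:
    """A three-contig plan covering the canonical layout repertoire.

    contig_A: one cognate pair on opposite strands with a 77 bp intergenic
    region (convergent), among neutral neighbors.
    contig_B: two co-directional pairs whose regulators sit 82 bp and 92 bp
    upstream of their synthases.
    contig_C: a solo luxI in a redox/sulfur neighborhood — upstream
    cysteine desulfurase, an electron-transfer flavoprotein gene 124 bp
    downstream, its partner overlapping it by 46 bp — with the nearest
    luxR far beyond the 3 kb window.
    Scattered HTH-only luxR solos are spread across a fourth contig.
    """
    contig_a = ContigPlan(
        seq_id="contig_A", length=30_000,
        loci=(
            LocusSpec("A_hyp1", "neighbor", "+", start=2_001,
                      product="hypothetical protein"),
            LocusSpec("A_rcsC", "neighbor", "+", gap=250,
                      product="sensor histidine kinase RcsC"),
            LocusSpec("A_luxI", "luxI", "+", gap=300, pair_with="A_luxR"),
            LocusSpec("A_luxR", "luxR", "-", gap=77, architecture="CANONICAL",
                      pair_with="A_luxI"),
            LocusSpec("A_yedZ", "neighbor", "+", gap=400,
                      product="methionine-sulfoxide reductase subunit YedZ"),
        ),
    )
    contig_b = ContigPlan(
        seq_id="contig_B", length=40_000,
        loci=(
            LocusSpec("B_kdgT", "neighbor", "+", start=3_001,
                      product="KdgT permease"),
            LocusSpec("B_rpaR", "luxR", "+", gap=200, architecture="CANONICAL",
                      pair_with="B_rpaI"),
            LocusSpec("B_rpaI", "luxI", "+", gap=82, pair_with="B_rpaR"),
            LocusSpec("B_dmlR", "neighbor", "+", gap=5_000,
                      product="transcriptional regulator DmlR"),
            LocusSpec("B_lasR", "luxR", "+", gap=298, architecture="CANONICAL",
                      pair_with="B_lasI"),
            LocusSpec("B_lasI", "luxI", "+", gap=92, pair_with="B_lasR"),
        ),
    )
    contig_c = ContigPlan(
        seq_id="contig_C", length=40_000,
        loci=(
            LocusSpec("C_iscS", "neighbor", "-", start=5_001,
                      product="cysteine desulfurase"),
            LocusSpec("C_mnmA", "neighbor", "-", gap=150,
                      product="tRNA-specific 2-thiouridylase"),
            LocusSpec("C_luxI", "luxI", "-", gap=200),
            LocusSpec("C_etfA", "neighbor", "-", gap=124,
                      product="electron transfer flavoprotein subunit A",
                      length_aa=250),
            LocusSpec("C_etfB", "neighbor", "-", gap=-46,
                      product="electron transfer flavoprotein subunit B",
                      length_aa=250),
            LocusSpec("C_fixB", "neighbor", "-", gap=80,
                      product="electron transfer flavoprotein FixB"),
            LocusSpec("C_luxR_far", "luxR", "+", start=25_001,
                      architecture="HTH_ONLY"),
        ),
    )
    rng = np.random.default_rng(seed)
    scattered = []
    pos = 2_001
    for i in range(n_scattered_hth_only):
        pos += int(rng.integers(800, 1_800))
        scattered.append(
            LocusSpec(f"D_luxR_{i:02d}", "luxR",
                      "+" if rng.random() < 0.5 else "-",
                      start=pos, architecture="HTH_ONLY")
        )
        pos += 3 * (HTH_ONLY_NTERM_LENGTH + HTH_LENGTH + 1) + 2_500
    contig_d = ContigPlan(
        seq_id="contig_D", length=pos + 5_000, loci=tuple(scattered)
    )
    return GenomePlan(
        contigs=(contig_a, contig_b, contig_c, contig_d), seed=seed
    )


# ---------------------------------------------------------------------------
# MRM peak lists

def generate_peaklist(
    true_analytes: list[tuple[str, AhlSpecies]],
    n_noise: int,
    seed: int,
    *,
    mz_jitter: float = 0.1,
    rt_jitter: float = 0.05,
    n_unknown: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Planted MRM peaks plus noise; returns (peak list, truth labels).

    ``true_analytes`` pairs a sample id with a standard to plant; noise
    peaks carry product ions far from the homoserine-lactone fragment and
    precursors away from every standard window.  ``n_unknown`` additionally
    plants peaks that fragment to the diagnostic product but sit off the
    precursor grid — ground truth for the putative-unknown verdict.
    """
    rng = np.random.default_rng(seed)
    fragment = hsl_fragment_mz()
    standard_mzs = np.array([s.precursor_mz for s in default_standards()])
    peaks, labels = [], []

    def emit(sample, prec, prod, rt, area, label):
        peaks.append(
            {"sample": sample, "precursor_mz": round(prec, 3),
             "product_mz": round(prod, 3), "rt": round(rt, 3),
             "peak_area": round(area, 1)}
        )
        labels.append({"sample": sample, "label": label})

    for sample, species in true_analytes:
        rt_ref = species.reference_rt if species.reference_rt is not None else 5.0
        emit(
            sample,
            species.precursor_mz + rng.uniform(-mz_jitter, mz_jitter),
            fragment + rng.uniform(-mz_jitter, mz_jitter),
            rt_ref + rng.uniform(-rt_jitter, rt_jitter),
            rng.uniform(1e4, 1e6),
            species.name,
        )
    for i in range(n_unknown):
        while True:
            prec = rng.uniform(150.0, 400.0)
            if np.abs(standard_mzs - prec).min() > 2.0:
                break
        emit(
            "unknown_sample", prec,
            fragment + rng.uniform(-mz_jitter, mz_jitter),
            rng.uniform(2.0, 8.0), rng.uniform(1e3, 1e5), "unknown_ahl",
        )
    for i in range(n_noise):
        prod = rng.uniform(110.0, 250.0)
        if abs(prod - fragment) < 2.0:
            prod += 5.0
        emit(
            f"noise_{i % 3}", rng.uniform(150.0, 400.0), prod,
            rng.uniform(1.0, 9.0), rng.uniform(1e2, 1e4), "noise",
        )
    return pd.DataFrame(peaks), pd.DataFrame(labels)


# ---------------------------------------------------------------------------
# Fixture bundle

def make_fixtures(out_dir: Path | str, seed: int = 13) -> dict[str, Path]:
    """Regenerate every fixture family/genome/peaklist under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    kit = FamilyKit(seed)
    luxi, luxr, abd, hth = kit.training_sets(30, seed + 100)
    for name, records in (("luxi_family", luxi), ("luxr_family", luxr),
                          ("abd_segments", abd), ("hth_segments", hth)):
        p = out / f"{name}.fasta"
        write_fasta(records, p)
        paths[name] = p
    decoys = generate_decoys(1000, (100, 400), seed + 200)
    paths["decoys"] = out / "decoys.fasta"
    write_fasta(decoys, paths["decoys"])

    plan = default_plan(seed)
    genome, features, truth, domains = generate_genome(plan, kit)
    paths["genome_fasta"] = out / "genome.fasta"
    paths["genome_gff3"] = out / "genome.gff3"
    write_genome(genome, features, paths["genome_fasta"], paths["genome_gff3"])
    paths["truth"] = out / "truth.tsv"
    truth.to_csv(paths["truth"], sep="\t", index=False)
    paths["domains"] = out / "planted_domains.tsv"
    pd.DataFrame(domains).to_csv(paths["domains"], sep="\t", index=False)

    analytes = [("wt", s) for s in default_standards()[:4]]
    peaklist, labels = generate_peaklist(analytes, n_noise=20, seed=seed + 300,
                                         n_unknown=2)
    paths["peaklist"] = out / "peaklist.csv"
    peaklist.to_csv(paths["peaklist"], index=False)
    paths["peaklist_truth"] = out / "peaklist_truth.csv"
    labels.to_csv(paths["peaklist_truth"], index=False)

    manifest = {k: str(v) for k, v in paths.items()}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return paths
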