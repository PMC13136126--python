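"""Position-specific scoring profiles with empirical e-value calibration.

The search step of the pipeline needs a family model that (a) scores any
protein and reports a bit score and an e-value, (b) is deterministic, and
(c) can be calibrated against a negative set to estimate a false-positive
rate and an inclusion cutoff.  Two engines satisfy that contract:

``builtin_pssm``
    A position-specific log-odds matrix derived from alignment column
    frequencies with add-0.5 pseudocounts.  A query is scored by the best
    ungapped local segment over all query/profile diagonals (a gap-free
    Smith–Waterman).  The score null is empirical: 200 seeded
    composition-preserving shuffles of the training residues are scored at
    model-build time and a Gumbel law is moment-fit to them; per-query
    e-values apply the standard search-space (length) correction and are
    scaled by the number of target sequences in a scan, so they compose like
    HMMER e-values.  This engine is not a profile HMM — it is a calibrated
    PSSM with the same scoring contract, which keeps the pipeline free of
    external binaries and exactly reproducible.

``external_hmm``
    A thin wrapper over pyhmmer (HMMER3) for users who want full Plan-7
    scoring; it emits the same hit-table schema.
"""

from __future__ import annotations

import json
import math
import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .curation import ProteinRecord

AA20 = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AA20)}
AA_INDEX["X"] = 20  # unknown residue: scores 0 in every column

DEFAULT_INCLUSION_CUTOFF = 1e-10
DEFAULT_REPORTING_THRESHOLD = 10.0
DEFAULT_NULL_SHUFFLES = 200
_EULER_GAMMA = 0.5772156649015329
_LOG10_MIN_EVALUE = -300.0


def encode(seq: str) -> np.ndarray:
    """Encode an amino-acid string to integer codes (X and gaps -> 20)."""
    return np.fromiter(
        (AA_INDEX.get(c, 20) for c in seq.upper()), dtype=np.int64, count=len(seq)
    )


def best_ungapped_segment_score(query_codes: np.ndarray, pssm: np.ndarray) -> float:
    """Best gap-free local alignment score of a query against a PSSM.

    Equivalent to a Smith–Waterman without gaps: the maximum contiguous sum
    along any diagonal of the (query x profile-column) score matrix.
    """
    q = len(query_codes)
    L = pssm.shape[0]
    if q == 0 or L == 0:
        return 0.0
    # M[i, j] = score of query residue i at profile column j
    M = pssm[:, query_codes].T  # (q, L)
    # Skew rows so that each column of B is one diagonal of M; diagonals are
    # contiguous within a column, and zero padding cannot raise a maximum.
    B = np.zeros((q, L + q - 1), dtype=np.float64)
    cols = np.arange(L)[None, :] - np.arange(q)[:, None] + (q - 1)
    np.put_along_axis(B, cols, M, axis=1)
    prefix = np.vstack([np.zeros(B.shape[1]), np.cumsum(B, axis=0)])
    running_min = np.minimum.accumulate(prefix[:-1], axis=0)
    best = float(np.max(prefix[1:] - running_min))
    return max(best, 0.0)


@dataclass
class ProfileModel:
    """A calibrated position-specific scoring profile for one family."""

    family: str
    pssm: np.ndarray  # (model_length, 21) log2-odds; column 20 (X) is 0
    alignment_id: str = ""
    engine: str = "builtin_pssm"
    inclusion_cutoff: float = DEFAULT_INCLUSION_CUTOFF
    # Gumbel null fitted to shuffled-sequence scores at build time
    null_mu: float = 0.0
    null_beta: float = 1.0
    null_ref_cells: float = 1.0  # search-space size the null was fit at
    null_shuffles: int = DEFAULT_NULL_SHUFFLES
    null_seed: int = 0

    def __post_init__(self) -> None:
        if self.model_length < 1:
            raise ValueError("model must have at least one column")
        if self.inclusion_cutoff <= 0:
            raise ValueError("inclusion_cutoff must be positive")

    @property
    def model_length(self) -> int:
        return int(self.pssm.shape[0])

    # -- scoring ------------------------------------------------------------

    def bitscore(self, sequence: str) -> float:
        return best_ungapped_segment_score(encode(sequence), self.pssm)

    def log10_evalue(self, bitscore: float, query_length: int, z: int = 1) -> float:
        """Length-corrected log10 e-value for one query in a z-sequence scan."""
        cells = max(query_length, 1) * self.model_length
        mu_q = self.null_mu + self.null_beta * math.log(cells / self.null_ref_cells)
        x = (bitscore - mu_q) / self.null_beta
        if x > 30.0:  # deep tail: P ~ exp(-x)
            log10_p = -x * math.log10(math.e)
        else:
            p = -math.expm1(-math.exp(-x))
            log10_p = math.log10(max(p, 1e-320))
        return max(log10_p + math.log10(z), _LOG10_MIN_EVALUE)

    def evalue(self, sequence: str, z: int = 1) -> float:
        s = self.bitscore(sequence)
        return 10.0 ** self.log10_evalue(s, len(sequence), z)

    def search(self, sequences: list[tuple[str, str]], z: int | None = None) -> pd.DataFrame:
        """Score named sequences; e-values scaled by the scan size ``z``.

        Returns a DataFrame (id, length, bitscore, evalue) sorted by
        ascending e-value, ties broken by id for determinism.
        """
        if z is None:
            z = len(sequences)
        rows = []
        for name, seq in sequences:
            s = self.bitscore(seq)
            e = 10.0 ** self.log10_evalue(s, len(seq), max(z, 1))
            rows.append((name, len(seq), s, e))
        df = pd.DataFrame(rows, columns=["id", "length", "bitscore", "evalue"])
        return df.sort_values(["evalue", "id"], kind="mergesort").reset_index(drop=True)

    # -- serialization ------------------------------------------------------

    def to_json(self, path: Path | str) -> None:
        payload = {
            "format": "luxminer-profile",
            "version": 1,
            "family": self.family,
            "alignment_id": self.alignment_id,
            "engine": self.engine,
            "inclusion_cutoff": self.inclusion_cutoff,
            "null": {
                "mu": self.null_mu,
                "beta": self.null_beta,
                "ref_cells": self.null_ref_cells,
                "shuffles": self.null_shuffles,
                "seed": self.null_seed,
            },
            "alphabet": AA20 + "X",
            "pssm": self.pssm.tolist(),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: Path | str) -> "ProfileModel":
        d = json.loads(Path(path).read_text())
        if d.get("format") != "luxminer-profile":
            raise ValueError(f"{path} is not a profile container")
        return cls(
            family=d["family"],
            pssm=np.asarray(d["pssm"], dtype=np.float64),
            alignment_id=d["alignment_id"],
            engine=d["engine"],
            inclusion_cutoff=d["inclusion_cutoff"],
            null_mu=d["null"]["mu"],
            null_beta=d["null"]["beta"],
            null_ref_cells=d["null"]["ref_cells"],
            null_shuffles=d["null"]["shuffles"],
            null_seed=d["null"]["seed"],
        )


# ---------------------------------------------------------------------------
# Model building

class AlignmentError(RuntimeError):
    """Raised when the pluggable aligner fails."""


def _align_with_mafft(sequences: list[str]) -> list[str]:
    """Align unequal-length training sequences with MAFFT (pluggable step)."""
    if shutil.which("mafft") is None:
        raise AlignmentError(
            "training sequences have unequal lengths and no aligner is available "
            "(mafft not on PATH); provide pre-aligned sequences"
        )
    with tempfile.TemporaryDirectory() as tmp:
        fin = Path(tmp) / "in.fasta"
        fin.write_text("".join(f">s{i}\n{s}\n" for i, s in enumerate(sequences)))
        try:
            proc = subprocess.run(
                ["mafft", "--auto", "--quiet", str(fin)],
                capture_output=True, text=True, check=True,
            )
        except subprocess.CalledProcessError as exc:  # pragma: no cover
            raise AlignmentError(f"mafft failed: {exc.stderr}") from exc
    aligned: dict[str, str] = {}
    name = None
    for line in proc.stdout.splitlines():
        if line.startswith(">"):
            name = line[1:].strip()
            aligned[name] = ""
        elif name is not None:
            aligned[name] += line.strip()
    return [aligned[f"s{i}"].upper() for i in range(len(sequences))]


def _as_sequences(records) -> list[str]:
    out = []
    for r in records:
        out.append(r.sequence if isinstance(r, ProteinRecord) else str(r))
    return out


def build_profile(
    curated_records,
    family: str = "",
    *,
    inclusion_cutoff: float = DEFAULT_INCLUSION_CUTOFF,
    pseudocount: float = 0.5,
    max_column_gap_fraction: float = 0.5,
    null_shuffles: int = DEFAULT_NULL_SHUFFLES,
    null_seed: int = 0,
    alignment_id: str = "",
    aligner=_align_with_mafft,
) -> ProfileModel:
    """Build a calibrated PSSM from curated training sequences.

    Sequences of unequal length are first aligned with the pluggable
    ``aligner`` (MAFFT by default); alignment columns with a gap fraction
    above ``max_column_gap_fraction`` are dropped (treated as inserts).
    Column residue frequencies receive ``pseudocount`` per residue, and the
    PSSM holds log2 odds against a uniform background.  The score null is
    fitted at build time from seeded shuffles of the pooled training
    residues, making every downstream e-value a pure function of the model.
    """
    sequences = _as_sequences(curated_records)
    if len(sequences) < 2:
        raise ValueError("building a profile requires at least 2 sequences")
    lengths = {len(s) for s in sequences}
    if len(lengths) > 1:
        sequences = aligner(sequences)

    codes = np.stack([encode(s) for s in sequences])  # gaps/X -> 20
    gap_frac = (codes == 20).mean(axis=0)
    keep = gap_frac <= max_column_gap_fraction
    if not keep.any():
        raise ValueError("no usable alignment columns after gap filtering")
    codes = codes[:, keep]
    L = codes.shape[1]

    counts = np.zeros((L, 20), dtype=np.float64)
    for a in range(20):
        counts[:, a] = (codes == a).sum(axis=0)
    probs = (counts + pseudocount) / (counts.sum(axis=1, keepdims=True) + 20 * pseudocount)
    pssm = np.zeros((L, 21), dtype=np.float64)
    pssm[:, :20] = np.log2(probs / 0.05)

    # Empirical null: shuffle the pooled training residues, score fragments
    # of the median training length, moment-fit a Gumbel law.
    pool = codes[codes < 20]
    ref_len = int(np.median([len(s.replace("-", "")) for s in sequences]))
    ref_len = max(ref_len, 10)
    rng = np.random.default_rng(null_seed)
    null_scores = np.empty(null_shuffles)
    for k in range(null_shuffles):
        frag = rng.choice(pool, size=ref_len, replace=True)
        null_scores[k] = best_ungapped_segment_score(frag, pssm)
    beta = float(null_scores.std(ddof=1) * math.sqrt(6.0) / math.pi)
    beta = max(beta, 1e-6)
    mu = float(null_scores.mean() - _EULER_GAMMA * beta)

    return ProfileModel(
        family=family,
        pssm=pssm,
        alignment_id=alignment_id,
        engine="builtin_pssm",
        inclusion_cutoff=inclusion_cutoff,
        null_mu=mu,
        null_beta=beta,
        null_ref_cells=float(ref_len * L),
        null_shuffles=null_shuffles,
        null_seed=null_seed,
    )


# ---------------------------------------------------------------------------
# Negative-set sampling and calibration

def sample_negative_set(
    records: list[ProteinRecord],
    fraction: float,
    seed: int,
    *,
    group_rank: int = -1,
) -> list[ProteinRecord]:
    """Stratified sample of ~``fraction`` of records per taxonomy group.

    Groups are the lineage element at ``group_rank`` (genus by convention,
    the last element).  Every non-empty group contributes at least one
    record, maximizing phylogenetic breadth; the sample is reproducible for
    a fixed seed and returned in input order.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    if fraction == 1.0:
        return list(records)
    groups: dict[str, list[int]] = {}
    for i, rec in enumerate(records):
        key = rec.taxonomy[group_rank] if rec.taxonomy else ""
        groups.setdefault(key, []).append(i)
    rng = np.random.default_rng(seed)
    chosen: set[int] = set()
    for key in sorted(groups):
        idx = groups[key]
        n = max(1, round(fraction * len(idx)))
        chosen.update(rng.choice(idx, size=n, replace=False).tolist())
    return [records[i] for i in sorted(chosen)]


@dataclass
class CalibrationReport:
    """Empirical false-positive summary for one profile model."""

    family: str
    n_negatives: int
    n_false_hits: int
    fpr: float
    false_hit_evalues: list[float]
    mean_log10_evalue: float | None
    suggested_cutoff: float
    reporting_threshold: float

    def to_json(self, path: Path | str) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=1))

    def to_frame(self) -> pd.DataFrame:
        d = dict(self.__dict__)
        d["false_hit_evalues"] = ";".join(f"{e:.3g}" for e in d["false_hit_evalues"])
        return pd.DataFrame([d])


def calibrate(
    model: ProfileModel,
    negative_records,
    reporting_threshold: float = DEFAULT_REPORTING_THRESHOLD,
    *,
    default_cutoff: float = DEFAULT_INCLUSION_CUTOFF,
) -> CalibrationReport:
    """Run ``model`` against a negative set and summarize false positives.

    A negative counts as a false hit when its e-value (scaled by the size of
    the negative set, i.e. a whole-database scan) is at or below
    ``reporting_threshold``.  The suggested inclusion cutoff is the
    geometric mean of the false-hit e-values — 10 to the arithmetic mean of
    their log10 values — falling back to ``default_cutoff`` when the scan
    produced no false hit at all.
    """
    sequences = [
        (r.accession if isinstance(r, ProteinRecord) else f"neg{i}",
         r.sequence if isinstance(r, ProteinRecord) else str(r))
        for i, r in enumerate(negative_records)
    ]
    if not sequences:
        raise ValueError("negative set must be non-empty")
    hits = model.search(sequences, z=len(sequences))
    false = hits[hits["evalue"] <= reporting_threshold]
    n_false = int(len(false))
    evalues = [float(e) for e in false["evalue"]]
    if n_false:
        mean_log10 = float(np.mean(np.log10(evalues)))
        suggested = 10.0 ** mean_log10
    else:
        mean_log10 = None
        suggested = default_cutoff
    return CalibrationReport(
        family=model.family,
        n_negatives=len(sequences),
        n_false_hits=n_false,
        fpr=n_false / len(sequences),
        false_hit_evalues=evalues,
        mean_log10_evalue=mean_log10,
        suggested_cutoff=suggested,
        reporting_threshold=reporting_threshold,
    )


# ---------------------------------------------------------------------------
# External engine: pyhmmer (HMMER3) behind the same hit-table schema

def build_hmmer_profile(curated_records, family: str = ""):
    """Build a Plan-7 HMM from pre-aligned training sequences via pyhmmer."""
    import pyhmmer

    sequences = _as_sequences(curated_records)
    if len({len(s) for s in sequences}) > 1:
        sequences = _align_with_mafft(sequences)
    alphabet = pyhmmer.easel.Alphabet.amino()
    msa = pyhmmer.easel.TextMSA(
        name=(family or "profile").encode(),
        sequences=[
            pyhmmer.easel.TextSequence(name=f"s{i}".encode(), sequence=s)
            for i, s in enumerate(sequences)
        ],
    )
    builder = pyhmmer.plan7.Builder(alphabet)
    background = pyhmmer.plan7.Background(alphabet)
    hmm, _, _ = builder.build_msa(msa.digitize(alphabet), background)
    return hmm


def hmmer_search(hmm, sequences: list[tuple[str, str]], z: int | None = None) -> pd.DataFrame:
    """hmmsearch of named sequences; same columns as ProfileModel.search."""
    import pyhmmer

    alphabet = pyhmmer.easel.Alphabet.amino()
    block = pyhmmer.easel.TextSequenceBlock(
        [pyhmmer.easel.TextSequence(name=n.encode(), sequence=s) for n, s in sequences]
    ).digitize(alphabet)
    lengths = {n: len(s) for n, s in sequences}
    z_eff = z if z is not None else len(sequences)
    hits = next(iter(pyhmmer.hmmsearch([hmm], block, Z=float(max(z_eff, 1)))))
    def _name(h):
        return h.name.decode() if isinstance(h.name, bytes) else h.name

    rows = [
        (_name(h), lengths[_name(h)], float(h.score), float(h.evalue))
        for h in hits
    ]
    df = pd.DataFrame(rows, columns=["id", "length", "bitscore", "evalue"])
    return df.sort_values(["evalue", "id"], kind="mergesort").reset_index(drop=True)
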