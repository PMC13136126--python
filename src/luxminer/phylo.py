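"""Alignment trimming, distance trees, monophyly tests, annotated export.

The pipeline's phylogenetic stage mirrors the standard protein workflow:
gap-threshold trimming of a multiple sequence alignment, tree building, a
monophyly test for a leaf set, and export of a Newick tree with companion
leaf annotations (family, architecture, taxon class).  Tree inference here
is neighbor joining on p- or Poisson-corrected distances, which keeps the
stage self-contained; maximum-likelihood inference can be swapped in via an
external-engine hook that consumes the trimmed alignment and returns
Newick.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

logger = logging.getLogger(__name__)

DEFAULT_GAP_THRESHOLD = 0.5
GAP = "-"


@dataclass(frozen=True)
class Alignment:
    """A fixed-width protein alignment ('-' for gaps)."""

    ids: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows must have equal length")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate sequence ids in alignment")
        widths = {len(r) for r in self.rows}
        if len(widths) > 1:
            raise ValueError("alignment rows have unequal lengths")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def to_fasta(self, path: Path | str) -> None:
        with open(path, "w") as fh:
            for name, row in zip(self.ids, self.rows):
                fh.write(f">{name}\n{row}\n")

    @classmethod
    def from_fasta(cls, path: Path | str) -> "Alignment":
        ids, rows, current = [], [], []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if line.startswith(">"):
                    if current:
                        rows.append("".join(current))
                        current = []
                    ids.append(line[1:].split()[0])
                elif line:
                    current.append(line.upper())
        if current:
            rows.append("".join(current))
        return cls(ids=tuple(ids), rows=tuple(rows))


def trim_alignment(
    alignment: Alignment, gap_threshold: float = DEFAULT_GAP_THRESHOLD
) -> tuple[Alignment, np.ndarray]:
    """Drop low-coverage columns; returns (trimmed alignment, kept mask).

    A column is kept iff the fraction of rows without a gap is at least
    ``gap_threshold`` (inclusive boundary: coverage exactly at the
    threshold is kept).  Row order is preserved; the mask has one boolean
    per original column, so trimming is idempotent on the retained columns.
    """
    if alignment.n_rows == 0:
        raise ValueError("empty alignment")
    mat = np.array([list(r) for r in alignment.rows])
    coverage = (mat != GAP).mean(axis=0)
    keep = coverage >= gap_threshold
    if not keep.any():
        logger.warning("gap-threshold trimming removed every column")
    trimmed_rows = tuple("".join(row) for row in mat[:, keep])
    return Alignment(ids=alignment.ids, rows=trimmed_rows), keep


# ---------------------------------------------------------------------------
# Distances and neighbor joining

def pairwise_distances(alignment: Alignment, distance: str = "p_distance") -> DistanceMatrix:
    """Pairwise distances ignoring columns gapped (or 'X') in either member.

    ``p_distance`` is the fraction of differing comparable sites;
    ``poisson_corrected`` is -ln(1 - p), the standard multiple-hit
    correction for proteins.
    """
    if distance not in {"p_distance", "poisson_corrected"}:
        raise ValueError(f"unknown distance {distance!r}")
    mat = np.array([list(r) for r in alignment.rows])
    comparable_site = (mat != GAP) & (mat != "X")
    n = alignment.n_rows
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = comparable_site[i] & comparable_site[j]
            m = int(ok.sum())
            if m == 0:
                raise ValueError(
                    f"sequences {alignment.ids[i]!r} and {alignment.ids[j]!r} "
                    "share no comparable columns"
                )
            p = float((mat[i, ok] != mat[j, ok]).mean())
            if distance == "poisson_corrected":
                p = -np.log(max(1.0 - p, 1e-12))
            dm[i, j] = dm[j, i] = p
    return DistanceMatrix(dm, ids=list(alignment.ids))


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Neighbor joining with lexicographic-id processing order.

    Taxa are fed to the agglomeration in sorted-id order so ties in the NJ
    Q-criterion break identically across runs; negative branch lengths from
    the NJ arithmetic are clamped to zero.
    """
    if len(dm.ids) < 3:
        raise ValueError("neighbor joining requires at least 3 taxa")
    ordered = sorted(dm.ids)
    tree = nj(dm.filter(ordered))
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
    return tree


def build_distance_tree(
    alignment: Alignment, distance: str = "p_distance"
) -> TreeNode:
    """Neighbor-joining tree from pairwise alignment distances."""
    if alignment.n_rows < 3:
        raise ValueError("distance tree requires at least 3 sequences")
    return neighbor_joining(pairwise_distances(alignment, distance))


# ---------------------------------------------------------------------------
# Monophyly

def check_monophyly(tree: TreeNode, leaf_subset) -> tuple[bool, frozenset | None]:
    """Does ``leaf_subset`` form a clade of the unrooted tree?

    True iff the bipartition (subset | complement) is induced by some edge.
    Singletons and the full leaf set are monophyletic by convention.
    Returns (verdict, supporting bipartition side or None).
    """
    leaves = frozenset(t.name for t in tree.tips())
    subset = frozenset(leaf_subset)
    unknown = subset - leaves
    if unknown:
        raise ValueError(f"unknown leaf labels: {sorted(unknown)}")
    if len(subset) <= 1 or subset == leaves:
        return True, subset
    complement = leaves - subset
    if len(complement) <= 1:  # a tip edge induces (rest | single leaf)
        return True, subset
    for node in tree.traverse(include_self=False):
        if node.is_tip():
            continue
        clade = frozenset(t.name for t in node.tips())
        if clade == subset or clade == complement:
            return True, clade
    return False, None


# ---------------------------------------------------------------------------
# Annotated export

def export_annotated_tree(
    tree: TreeNode,
    annotations: dict[str, dict],
    newick_path: Path | str,
    annotation_path: Path | str,
) -> None:
    """Write Newick plus a leaf-annotation TSV (family/architecture/class).

    Annotation keys must be existing leaf labels; duplicate leaf labels in
    the tree are rejected because annotation joins would be ambiguous.
    """
    names = [t.name for t in tree.tips()]
    if len(names) != len(set(names)):
        raise ValueError("duplicate leaf labels in tree")
    unknown = set(annotations) - set(names)
    if unknown:
        raise ValueError(f"annotations for unknown leaves: {sorted(unknown)}")
    buf = io.StringIO()
    tree.write(buf, format="newick")
    Path(newick_path).write_text(buf.getvalue())
    fields = sorted({k for v in annotations.values() for k in v})
    rows = [
        {"leaf": leaf, **{f: annotations.get(leaf, {}).get(f, "") for f in fields}}
        for leaf in names
    ]
    pd.DataFrame(rows, columns=["leaf", *fields]).to_csv(
        annotation_path, sep="\t", index=False
    )


def read_newick(path: Path | str) -> TreeNode:
    return TreeNode.read(str(path), format="newick")


def external_ml_hook(command_template: str):
    """Build a tree-inference hook that shells out to an external ML engine.

    The returned callable takes (trimmed alignment FASTA path, output Newick
    path) and runs ``command_template.format(alignment=..., tree=...)``.
    The pipeline treats the result exactly like the built-in NJ tree.
    """
    import shlex
    import subprocess

    def run(alignment_fasta: Path | str, newick_out: Path | str) -> TreeNode:
        cmd = command_template.format(alignment=alignment_fasta, tree=newick_out)
        subprocess.run(shlex.split(cmd), check=True)
        return read_newick(newick_out)

    return run
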