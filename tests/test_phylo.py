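"""Alignment trimming, NJ tree oracles, monophyly, annotated export."""

import itertools
import random

import numpy as np
import pytest
from skbio import DistanceMatrix, TreeNode

from luxminer import phylo
from luxminer.phylo import (
    Alignment,
    build_distance_tree,
    check_monophyly,
    export_annotated_tree,
    neighbor_joining,
    pairwise_distances,
    trim_alignment,
)

# ---------------------------------------------------------------------------
# Independent oracle helpers: random additive trees built from scratch


def random_binary_tree(labels, rng):
    """Random unrooted binary tree as nested ((child, branch-length), ...)."""
    nodes = [(lab, None) for lab in labels]
    while len(nodes) > 3:
        i, j = sorted(rng.sample(range(len(nodes)), 2), reverse=True)
        a, b = nodes.pop(i), nodes.pop(j)
        nodes.append(
            (((a[0], rng.uniform(0.05, 1.0)), (b[0], rng.uniform(0.05, 1.0))), None)
        )
    return tuple((child, rng.uniform(0.05, 1.0)) for child, _ in nodes)


def _leaf_depths(node, depth, out):
    child = node[0] if isinstance(node, tuple) and len(node) == 2 else node
    if isinstance(child, str):
        out[child] = depth
        return
    for sub, bl in child:
        _leaf_depths((sub, None), depth + bl, out)


def tree_distances(root):
    """All leaf pairwise path lengths of the nested-tuple tree."""
    # distance(a, b) = depth(a) + depth(b) - 2 * depth(lca); compute by
    # walking: collect per-subtree leaf depth maps bottom-up
    def walk(children):
        maps = []
        for child, bl in children:
            if isinstance(child, str):
                maps.append({child: bl})
            else:
                sub = walk(child)
                maps.append({k: v + bl for k, v in sub.items()})
        dists = {}
        for m1, m2 in itertools.combinations(maps, 2):
            for a, da in m1.items():
                for b, db in m2.items():
                    dists[frozenset((a, b))] = da + db
        merged = {}
        for m in maps:
            merged.update(m)
        walk.pair_dists.update(dists)
        return merged

    walk.pair_dists = {}
    walk(root)
    return walk.pair_dists


def tree_bipartitions(root, all_labels):
    """Every edge-induced leaf bipartition of the nested-tuple tree."""
    sides = []

    def leaves_under(child):
        if isinstance(child, str):
            return frozenset((child,))
        out = frozenset()
        for sub, _ in child:
            out |= leaves_under(sub)
        return out

    def walk(children):
        for child, _ in children:
            side = leaves_under(child)
            sides.append(side)
            if not isinstance(child, str):
                walk(child)

    walk(root)
    total = frozenset(all_labels)
    return {frozenset((s, total - s)) for s in sides}


def skbio_bipartitions(tree):
    leaves = frozenset(t.name for t in tree.tips())
    out = set()
    for node in tree.traverse(include_self=False):
        side = frozenset(t.name for t in node.tips())
        out.add(frozenset((side, leaves - side)))
    return out


# ---------------------------------------------------------------------------
# Trimming


class TestTrimAlignment:
    def test_all_gap_column_is_removed(self):
        aln = Alignment(ids=("a", "b"), rows=("A-C", "A-C"))
        trimmed, mask = trim_alignment(aln)
        assert trimmed.rows == ("AC", "AC")
        assert mask.tolist() == [True, False, True]

    def test_half_coverage_column_kept_at_boundary(self):
        aln = Alignment(ids=tuple("abcd"), rows=("AC", "A-", "AC", "A-"))
        trimmed, _ = trim_alignment(aln, gap_threshold=0.5)
        assert trimmed.n_columns == 2  # coverage 0.5 column is kept

    def test_kept_columns_monotone_in_threshold(self):
        rng = np.random.default_rng(31)
        rows = tuple(
            "".join(rng.choice(list("ACDEF-"), size=60)) for _ in range(10)
        )
        aln = Alignment(ids=tuple(f"s{i}" for i in range(10)), rows=rows)
        kept = [trim_alignment(aln, t)[1].sum() for t in (0.1, 0.5, 0.9)]
        assert kept[0] >= kept[1] >= kept[2]

    def test_trimming_is_idempotent_with_full_length_mask(self):
        rng = np.random.default_rng(32)
        rows = tuple("".join(rng.choice(list("AC-"), size=40)) for _ in range(6))
        aln = Alignment(ids=tuple(f"s{i}" for i in range(6)), rows=rows)
        once, mask = trim_alignment(aln)
        twice, mask2 = trim_alignment(once)
        assert twice == once
        assert len(mask) == 40 and mask2.all()

    def test_agrees_with_brute_force_column_coverage(self):
        rng = np.random.default_rng(33)
        rows = tuple("".join(rng.choice(list("ACDE--"), size=30)) for _ in range(7))
        aln = Alignment(ids=tuple(f"s{i}" for i in range(7)), rows=rows)
        for threshold in (0.1, 0.5, 0.9):
            _, mask = trim_alignment(aln, threshold)
            expected = [
                sum(r[c] != "-" for r in rows) / len(rows) >= threshold
                for c in range(30)
            ]
            assert mask.tolist() == expected


# ---------------------------------------------------------------------------
# Distances + NJ


class TestDistanceTree:
    def test_pairwise_distance_skips_columns_gapped_in_either(self):
        aln = Alignment(ids=("a", "b"), rows=("ACD-EF", "AC-XEW"))
        dm = pairwise_distances(aln)
        # comparable columns: 1,2,5 (0-based 0,1,4 and 5); 'X' and gaps skip
        assert dm["a", "b"] == pytest.approx(1 / 4)

    def test_zero_comparable_columns_names_the_pair(self):
        aln = Alignment(ids=("a", "b", "c"), rows=("A--", "-C-", "AC-"))
        with pytest.raises(ValueError, match="'a' and 'b'"):
            pairwise_distances(aln)

    def test_identical_sequences_form_zero_length_cherry(self):
        aln = Alignment(
            ids=("a", "b", "c", "d"),
            rows=("ACDEFGHIKL", "ACDEFGHIKL", "KLMNPQRSTV", "KLMNPQRSTW"),
        )
        tree = build_distance_tree(aln)
        tips = {t.name: t for t in tree.tips()}
        assert tips["a"].distance(tips["b"]) == pytest.approx(0.0)

    @pytest.mark.parametrize("n_leaves", [4, 5, 6, 7, 8])
    def test_nj_recovers_generating_topology_from_additive_matrix(self, n_leaves):
        rng = random.Random(3 + n_leaves)
        labels = [f"t{i}" for i in range(n_leaves)]
        true_tree = random_binary_tree(labels, rng)
        dists = tree_distances(true_tree)
        mat = np.zeros((n_leaves, n_leaves))
        for i, a in enumerate(labels):
            for j, b in enumerate(labels):
                if i != j:
                    mat[i, j] = dists[frozenset((a, b))]
        nj_tree = neighbor_joining(DistanceMatrix(mat, ids=labels))
        assert skbio_bipartitions(nj_tree) >= {
            bp for bp in tree_bipartitions(true_tree, labels)
            if min(len(s) for s in bp) >= 2
        }

    def test_nj_reproduces_additive_metric(self):
        rng = random.Random(3)
        labels = [f"t{i}" for i in range(6)]
        true_tree = random_binary_tree(labels, rng)
        dists = tree_distances(true_tree)
        mat = np.zeros((6, 6))
        for i, a in enumerate(labels):
            for j, b in enumerate(labels):
                if i != j:
                    mat[i, j] = dists[frozenset((a, b))]
        tree = neighbor_joining(DistanceMatrix(mat, ids=labels))
        tips = {t.name: t for t in tree.tips()}
        for a, b in itertools.combinations(labels, 2):
            assert tips[a].distance(tips[b]) == pytest.approx(
                dists[frozenset((a, b))], abs=1e-9
            )


# ---------------------------------------------------------------------------
# Monophyly


class TestMonophyly:
    def test_full_set_and_singletons_are_monophyletic(self):
        tree = TreeNode.read(["((a:1,b:1):1,(c:1,d:1):1);"])
        assert check_monophyly(tree, {"a", "b", "c", "d"})[0]
        assert check_monophyly(tree, {"c"})[0]

    def test_unknown_leaf_is_an_error(self):
        tree = TreeNode.read(["((a:1,b:1):1,(c:1,d:1):1);"])
        with pytest.raises(ValueError, match="unknown leaf"):
            check_monophyly(tree, {"a", "zzz"})

    def test_all_subsets_match_exhaustive_bipartition_enumeration(self):
        """Every non-trivial subset of a random 6-leaf tree, versus a
        brute-force oracle over the generating tree's edges."""
        rng = random.Random(41)
        labels = [f"t{i}" for i in range(6)]
        true_tree = random_binary_tree(labels, rng)
        bps = tree_bipartitions(true_tree, labels)
        sides = {side for bp in bps for side in bp}
        newick = _to_newick(true_tree) + ";"
        tree = TreeNode.read([newick])
        total = frozenset(labels)
        for r in range(1, 6):
            for combo in itertools.combinations(labels, r):
                subset = frozenset(combo)
                expected = (
                    len(subset) <= 1
                    or len(total - subset) <= 1
                    or subset in sides
                    or (total - subset) in sides
                )
                verdict, support = check_monophyly(tree, subset)
                assert verdict == expected, subset
                if verdict:
                    assert support is not None


def _to_newick(children) -> str:
    parts = []
    for child, bl in children:
        if isinstance(child, str):
            parts.append(f"{child}:{bl}")
        else:
            parts.append(f"{_to_newick(child)}:{bl}")
    return "(" + ",".join(parts) + ")"


# ---------------------------------------------------------------------------
# Export


class TestExport:
    def test_newick_round_trip_and_annotation_file(self, tmp_path):
        tree = TreeNode.read(["((a:1,b:2):0.5,(c:1,d:1):0.5);"])
        annotations = {
            "a": {"family": "LuxR", "architecture": "HTH_ONLY", "class": "Actinomycetes"},
            "b": {"family": "LuxR", "architecture": "CANONICAL", "class": "Gamma"},
        }
        nwk, tsv = tmp_path / "t.nwk", tmp_path / "ann.tsv"
        export_annotated_tree(tree, annotations, nwk, tsv)
        reread = phylo.read_newick(nwk)
        assert skbio_bipartitions(reread) == skbio_bipartitions(tree)
        import pandas as pd

        table = pd.read_csv(tsv, sep="\t").set_index("leaf")
        assert table.loc["a", "architecture"] == "HTH_ONLY"

    def test_unknown_annotated_leaf_is_rejected(self, tmp_path):
        tree = TreeNode.read(["((a:1,b:2):0.5,c:1);"])
        with pytest.raises(ValueError, match="unknown leaves"):
            export_annotated_tree(tree, {"nope": {}}, tmp_path / "t.nwk",
                                  tmp_path / "a.tsv")

    def test_simulated_single_clade_family_is_monophyletic(self, kit):
        """Sequences simulated from one family ancestor group together
        against unrelated outgroups."""
        from luxminer import simulate

        rng = np.random.default_rng(51)
        ingroup = {f"in{i}": kit.luxi_member(rng) for i in range(4)}
        outgroup = {f"out{i}": simulate.random_protein(rng, 200) for i in range(3)}
        ids = tuple(list(ingroup) + list(outgroup))
        rows = tuple(list(ingroup.values()) + list(outgroup.values()))
        tree = build_distance_tree(Alignment(ids=ids, rows=rows))
        verdict, _ = check_monophyly(tree, set(ingroup))
        assert verdict
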