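"""Intergenic distances, orientation, cognate pairing, neighborhoods."""

import random

import numpy as np
import pytest

from luxminer import topology
from luxminer.genome_scan import GeneFeature, HomologHit
from luxminer.topology import (
    categorize_product,
    classify_orientation,
    find_cognate_pairs,
    intergenic_distance,
    neighborhood_inventory,
)


def _feat(start, end, strand="+", seq_id="c1", tag=None, product=""):
    return GeneFeature(seq_id=seq_id, start=start, end=end, strand=strand,
                       locus_tag=tag or f"g{start}", product=product)


def _hit(start, end, family, strand="+", seq_id="c1", arch=None, evalue=1e-30, tag=None):
    return HomologHit(
        feature=_feat(start, end, strand, seq_id, tag), family=family,
        evalue=evalue, bitscore=50.0, protein_length=(end - start + 1) // 3 - 1,
        architecture=arch,
    )


class TestIntergenicDistance:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ((1, 100), (101, 200), 0),     # abutting
            ((1, 100), (150, 200), 49),    # 150-100-1
            ((1, 100), (80, 180), -21),    # overlap 100-80+1
            ((1, 100), (102, 200), 1),
            ((50, 60), (1, 100), -11),     # containment: full span overlap
        ],
    )
    def test_signed_distance(self, a, b, expected):
        assert intergenic_distance(_feat(*a), _feat(*b)) == expected

    def test_symmetry_on_random_layouts(self):
        rng = random.Random(3)
        for _ in range(50):
            s1, s2 = rng.randrange(1, 500), rng.randrange(1, 500)
            f1 = _feat(s1, s1 + rng.randrange(10, 200))
            f2 = _feat(s2, s2 + rng.randrange(10, 200))
            assert intergenic_distance(f1, f2) == intergenic_distance(f2, f1)

    def test_cross_contig_is_undefined(self):
        assert intergenic_distance(_feat(1, 10), _feat(1, 10, seq_id="c2")) is None

    def test_ordered_triple_additivity(self):
        """For disjoint ordered a < b < c: gap(a,c) = gap(a,b) + span(b) + gap(b,c)."""
        rng = random.Random(9)
        for _ in range(30):
            a_end = rng.randrange(50, 100)
            b_start = a_end + 1 + rng.randrange(0, 50)
            b_end = b_start + rng.randrange(10, 80)
            c_start = b_end + 1 + rng.randrange(0, 50)
            a, b, c = _feat(1, a_end), _feat(b_start, b_end), _feat(c_start, c_start + 10)
            assert intergenic_distance(a, c) == (
                intergenic_distance(a, b) + b.span + intergenic_distance(b, c)
            )


class TestOrientation:
    @pytest.mark.parametrize(
        "up_strand, down_strand, expected",
        [
            ("+", "+", "co_directional"),
            ("-", "-", "co_directional"),
            ("+", "-", "convergent"),
            ("-", "+", "divergent"),
        ],
    )
    def test_strand_combinations(self, up_strand, down_strand, expected):
        up, down = _feat(1, 100, up_strand), _feat(200, 300, down_strand)
        assert classify_orientation(up, down) == expected
        assert classify_orientation(down, up) == expected  # argument order free


class TestCognatePairs:
    def test_close_opposite_strand_pair(self):
        """One luxI and one canonical luxR 77 bp apart on opposite strands
        form a single cognate pair."""
        hi = _hit(1000, 1899, "LuxI", "+")
        hr = _hit(1977, 2639, "LuxR", "-", arch="CANONICAL")
        pairs, solos = find_cognate_pairs([hi, hr])
        assert len(pairs) == 1 and solos == []
        assert pairs[0].distance_bp == 77
        assert pairs[0].orientation == "convergent"

    def test_distant_partner_becomes_solo_with_exact_distance(self):
        hi = _hit(1000, 1899, "LuxI")
        hr = _hit(314_900, 315_500, "LuxR", arch="HTH_ONLY")
        pairs, solos = find_cognate_pairs([hi, hr])
        assert pairs == []
        by_family = {s.hit.family: s for s in solos}
        assert by_family["LuxI"].nearest_partner_distance_bp == 314_900 - 1899 - 1
        assert by_family["LuxR"].partner_family == "LuxI"

    def test_canonical_architecture_preferred_over_distance(self):
        """Candidates at 50 bp (HTH-only) and 90 bp (canonical): the
        canonical regulator wins the pairing."""
        hi = _hit(1000, 1899, "LuxI")
        near_hth = _hit(1950, 2500, "LuxR", arch="HTH_ONLY", tag="near")
        far_canon = _hit(1990, 2600, "LuxR", arch="CANONICAL", tag="far")
        # place them so distances are 50 and 90
        near_hth = _hit(1950, 2500, "LuxR", arch="HTH_ONLY", tag="near")
        far_canon = _hit(1990 + 0, 2600, "LuxR", arch="CANONICAL", tag="far")
        d_near = topology.intergenic_distance(hi.feature, near_hth.feature)
        assert d_near == 50
        pairs, solos = find_cognate_pairs([hi, near_hth, far_canon])
        assert pairs[0].luxR_hit.feature.locus_tag == "far"
        assert {s.hit.feature.locus_tag for s in solos} == {"near"}

    def test_never_pairs_across_contigs(self):
        hi = _hit(1000, 1899, "LuxI", seq_id="c1")
        hr = _hit(2000, 2600, "LuxR", seq_id="c2", arch="CANONICAL")
        pairs, solos = find_cognate_pairs([hi, hr])
        assert pairs == []
        assert all(s.nearest_partner_distance_bp is None for s in solos)

    def test_pairing_stable_under_hit_permutation(self):
        rng = np.random.default_rng(17)
        hits = []
        pos = 1000
        for i in range(6):
            fam = "LuxI" if i % 2 == 0 else "LuxR"
            arch = None if fam == "LuxI" else ("CANONICAL" if i % 4 == 1 else "HTH_ONLY")
            hits.append(_hit(pos, pos + 600, fam, arch=arch, tag=f"h{i}"))
            pos += 700 + int(rng.integers(0, 2000))
        baseline = find_cognate_pairs(hits)
        base_keys = [
            (p.luxI_hit.feature.locus_tag, p.luxR_hit.feature.locus_tag)
            for p in baseline[0]
        ]
        for seed in range(5):
            shuffled = hits[:]
            random.Random(seed).shuffle(shuffled)
            pairs, _ = find_cognate_pairs(shuffled)
            assert [
                (p.luxI_hit.feature.locus_tag, p.luxR_hit.feature.locus_tag)
                for p in pairs
            ] == base_keys


class TestNeighborhood:
    def test_downstream_neighbor_offset(self):
        """A neighbor gene 124 bp downstream appears at offset +124."""
        focal = _hit(5000, 5899, "LuxI", tag="focal")
        etfa = _feat(6024, 6800, product="electron transfer flavoprotein subunit A",
                     tag="etfA")
        inv = neighborhood_inventory(focal, [focal.feature, etfa], flank_bp=3000)
        (feat, offset, orient, cat), = inv.genes
        assert feat.locus_tag == "etfA"
        assert offset == 124
        assert cat == "redox_electron_transfer"

    def test_zero_flank_lists_only_overlapping_features(self):
        focal = _hit(5000, 5899, "LuxI", tag="focal")
        inside = _feat(5800, 6100, tag="inside")
        outside = _feat(5901, 6200, tag="outside")
        inv = neighborhood_inventory(focal, [inside, outside], flank_bp=0)
        assert [f.locus_tag for f, *_ in inv.genes] == ["inside"]

    def test_matches_brute_force_interval_scan(self):
        """25-gene contig, 10 kb flank: inventory equals exhaustive
        interval intersection."""
        rng = random.Random(23)
        feats, pos = [], 1
        for i in range(25):
            pos += rng.randrange(50, 1500)
            end = pos + rng.randrange(100, 1200)
            feats.append(_feat(pos, end, rng.choice("+-"), tag=f"n{i}"))
            pos = end
        focal = _hit(feats[12].start, feats[12].end, "LuxI", tag=feats[12].locus_tag)
        inv = neighborhood_inventory(focal, feats, flank_bp=10_000)
        lo, hi = focal.feature.start - 10_000, focal.feature.end + 10_000
        expected = [
            f.locus_tag for f in sorted(feats, key=lambda f: (f.start, f.end))
            if f.locus_tag != focal.feature.locus_tag
            and not (f.end < lo or f.start > hi)
        ]
        assert [f.locus_tag for f, *_ in inv.genes] == expected


class TestCategorizeProduct:
    @pytest.mark.parametrize(
        "product, category",
        [
            ("electron transfer flavoprotein subunit A", "redox_electron_transfer"),
            ("cysteine desulfurase IscS", "sulfur_trna"),
            ("tRNA-specific 2-thiouridylase MnmA", "sulfur_trna"),
            ("2,5-diketocamphane 1,2-monooxygenase", "secondary_metabolism"),
            ("sensor histidine kinase RcsC", "stress_sensing"),
            ("ABC transporter ATP-binding protein", "transport"),
            ("hypothetical protein", "hypothetical"),
            ("transcriptional regulator DmlR", "regulator"),
            ("", "other"),
            ("ribosomal protein L1", "other"),
        ],
    )
    def test_keyword_map(self, product, category):
        assert categorize_product(product) == category
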