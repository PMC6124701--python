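"""Synteny blocks, conserved fractions, ribbons, ORFs, gene matrix."""

from __future__ import annotations

import numpy as np
import pytest

from egt.core import Feature, FeatureKind, Genome, Interval, Role, Topology, revcomp
from egt.synteny import (
    conserved_fraction,
    find_orfs,
    find_synteny_blocks,
    gene_presence_matrix,
    ribbon_map,
    stringent_params,
)

from .conftest import rand_seq
from .oracles import orf_oracle


def gene(gid: str, start: int, end: int, name: str) -> Feature:
    return Feature(Interval(gid, start, end), FeatureKind.gene, name)


class TestSyntenyBlocks:
    def test_identical_genomes_one_block(self, rng):
        s = rand_seq(rng, 10_000)
        ga = Genome(id="a", seq=s, role=Role.mitogenome)
        gb = Genome(id="b", seq=s, role=Role.mitogenome)
        blocks = find_synteny_blocks(ga, gb, [gene("a", 100, 700, "nad1")])
        assert len(blocks) == 1
        b = blocks[0]
        assert b.orientation == "same" and b.length >= 9_900 and "nad1" in b.genes

    def test_internal_inversion_three_blocks(self, rng):
        s = rand_seq(rng, 12_000)
        inverted = s[:4_000] + revcomp(s[4_000:7_000]) + s[7_000:]
        ga = Genome(id="a", seq=s, role=Role.mitogenome)
        gb = Genome(id="b", seq=inverted, role=Role.mitogenome)
        annot = [gene("a", 1_000, 1_600, "g1"), gene("a", 5_000, 5_600, "g2"), gene("a", 9_000, 9_600, "g3")]
        blocks = find_synteny_blocks(ga, gb, annot)
        assert len(blocks) == 3
        assert [b.orientation for b in blocks] == ["same", "inverted", "same"]
        mid = blocks[1]
        assert abs(mid.a.start - 4_000) <= 5 and abs(mid.a.end - 7_000) <= 5
        # non-overlap on gA
        for x, y in zip(blocks, blocks[1:]):
            assert x.a.end <= y.a.start

    def test_random_genomes_no_blocks(self, rng):
        ga = Genome(id="a", seq=rand_seq(rng, 8_000), role=Role.mitogenome)
        gb = Genome(id="b", seq=rand_seq(rng, 8_000), role=Role.mitogenome)
        assert find_synteny_blocks(ga, gb, [gene("a", 0, 300, "x")]) == []

    def test_gene_filter_drops_geneless_blocks(self, rng):
        s = rand_seq(rng, 6_000)
        ga = Genome(id="a", seq=s, role=Role.mitogenome)
        gb = Genome(id="b", seq=s, role=Role.mitogenome)
        assert find_synteny_blocks(ga, gb, []) == []
        assert len(find_synteny_blocks(ga, gb, None, require_gene=False)) == 1

    def test_missing_annotation_error(self, rng):
        s = rand_seq(rng, 3_000)
        ga = Genome(id="a", seq=s, role=Role.mitogenome)
        with pytest.raises(ValueError):
            find_synteny_blocks(ga, ga, None, require_gene=True)


class TestConservedFraction:
    def _g(self, gid, seq):
        return Genome(id=gid, seq=seq, role=Role.mitogenome)

    def test_three_identical_all_core(self, rng):
        s = rand_seq(rng, 6_000)
        out = conserved_fraction([self._g("a", s), self._g("b", s), self._g("c", s)])
        for gid in "abc":
            assert out[gid]["shared_with_both"] == 6_000
            assert sum(out[gid].values()) == 6_000

    def test_pair_plus_random(self, rng):
        s = rand_seq(rng, 6_000)
        out = conserved_fraction(
            [self._g("a", s), self._g("b", s), self._g("c", rand_seq(rng, 6_000))]
        )
        assert out["a"]["shared_with_b_only"] == 6_000
        assert out["a"]["shared_with_both"] == 0
        assert out["c"]["unique"] == 6_000

    def test_simulated_trio_core_and_extras(self, rng):
        core = rand_seq(rng, 12_000)
        ab = rand_seq(rng, 3_000)  # shared by a and b only
        a = core + ab + rand_seq(rng, 2_000)
        b = ab + rand_seq(rng, 1_500) + core
        c = rand_seq(rng, 1_000) + core + rand_seq(rng, 2_500)
        out = conserved_fraction([self._g("a", a), self._g("b", b), self._g("c", c)])
        assert out["a"]["shared_with_both"] == pytest.approx(12_000, abs=200)
        assert out["a"]["shared_with_b_only"] == pytest.approx(3_000, abs=200)
        assert out["a"]["unique"] == pytest.approx(2_000, abs=200)
        for gid in "abc":
            assert sum(out[gid].values()) == len({"a": a, "b": b, "c": c}[gid])

    def test_requires_three(self, rng):
        g = self._g("a", rand_seq(rng, 500))
        with pytest.raises(ValueError):
            conserved_fraction([g, g])


class TestRibbonMap:
    def test_single_hsp_top_bin(self, rng):
        s = rand_seq(rng, 2_000)
        rb = ribbon_map(Genome(id="a", seq=s, role=Role.mitogenome), Genome(id="b", seq=s, role=Role.mitogenome))
        assert len(rb) == 1 and rb[0].ratio == 1.0 and rb[0].bin == ">0.75"

    def test_constructed_bins_consistent(self, rng):
        shared_big = rand_seq(rng, 2_000)
        shared_small = rand_seq(rng, 300)
        a = shared_big + rand_seq(rng, 800) + shared_small
        b = rand_seq(rng, 500) + shared_big + rand_seq(rng, 700) + shared_small
        rb = ribbon_map(
            Genome(id="a", seq=a, role=Role.mitogenome), Genome(id="b", seq=b, role=Role.mitogenome)
        )
        assert max(r.ratio for r in rb) == 1.0
        for r in rb:
            expect = (
                "<=0.25" if r.ratio <= 0.25 else "<=0.50" if r.ratio <= 0.50 else "<=0.75" if r.ratio <= 0.75 else ">0.75"
            )
            assert r.bin == expect
        # sorted by gA coordinate
        starts = [r.hsp.query.start for r in rb]
        assert starts == sorted(starts)

    def test_empty(self, rng):
        a = Genome(id="a", seq=rand_seq(rng, 1_000), role=Role.mitogenome)
        b = Genome(id="b", seq=rand_seq(rng, 1_000), role=Role.mitogenome)
        assert ribbon_map(a, b) == []


class TestFindOrfs:
    def test_306bp_orf_found(self, rng):
        orf = "ATG" + "GCT" * 100 + "TAA"
        g = Genome(id="g", seq=rand_seq(rng, 400) + orf + rand_seq(rng, 400))
        feats = [f for f in find_orfs(g) if len(f.interval) == 306]
        assert any(f.interval.start == 400 and f.interval.strand == "+" for f in feats)

    def test_300bp_below_threshold(self):
        orf = "ATG" + "GCT" * 98 + "TAA"  # 300 bp
        g = Genome(id="g", seq="C" * 100 + orf + "C" * 100)
        assert all(len(f.interval) != 300 for f in find_orfs(g))

    def test_reverse_strand_coordinates(self, rng):
        orf = "ATG" + "GGT" * 110 + "TAG"
        fwd = rand_seq(rng, 300) + orf + rand_seq(rng, 300)
        g = Genome(id="g", seq=revcomp(fwd))
        feats = [f for f in find_orfs(g) if len(f.interval) == len(orf)]
        assert any(f.interval.strand == "-" for f in feats)

    def test_matches_bruteforce_oracle_on_random_sequence(self):
        rng = np.random.default_rng(77)
        seq = rand_seq(rng, 20_000)
        g = Genome(id="g", seq=seq)
        got = {(f.interval.start, len(f.interval), f.interval.strand) for f in find_orfs(g, min_len=150)}
        assert got == orf_oracle(seq, 150)

    def test_circular_orf_found_across_copies(self, rng):
        orf = "ATG" + "CAT" * 105 + "TGA"
        # place the ORF across the origin of a circular genome
        seq = orf[100:] + rand_seq(rng, 2_000) + orf[:100]
        g = Genome(id="g", seq=seq, topology=Topology.circular)
        feats = find_orfs(g)
        assert any(len(f.interval) >= 200 for f in feats)


class TestGenePresence:
    def test_duplicated_single_absent(self):
        ann = {
            "g1": [
                Feature(Interval("g1", 0, 10), FeatureKind.rRNA, "rrn5"),
                Feature(Interval("g1", 50, 60), FeatureKind.rRNA, "rrn5"),
                Feature(Interval("g1", 100, 110), FeatureKind.gene, "nad1"),
            ],
            "g2": [Feature(Interval("g2", 0, 10), FeatureKind.rRNA, "rrn5")],
        }
        counts, classes, dups = gene_presence_matrix(ann)
        assert classes.loc["rrn5", "g1"] == "duplicated"
        assert classes.loc["rrn5", "g2"] == "single"
        assert classes.loc["nad1", "g2"] == "absent"

    def test_orf_and_trna_excluded_from_dup_count(self):
        ann = {
            "g1": [
                Feature(Interval("g1", 0, 9), FeatureKind.ORF, "orf1"),
                Feature(Interval("g1", 20, 29), FeatureKind.ORF, "orf1"),
                Feature(Interval("g1", 40, 50), FeatureKind.tRNA, "trnF"),
                Feature(Interval("g1", 60, 70), FeatureKind.tRNA, "trnF"),
                Feature(Interval("g1", 80, 90), FeatureKind.gene, "rps3"),
                Feature(Interval("g1", 95, 105), FeatureKind.gene, "rps3"),
            ]
        }
        _, _, dups = gene_presence_matrix(ann)
        assert dups["g1"] == 1  # only rps3 counts

    def test_hand_tally_on_trio(self):
        ann = {
            "A": [gene("A", i * 20, i * 20 + 10, n) for i, n in enumerate(["x", "y", "y", "z"])],
            "B": [gene("B", i * 20, i * 20 + 10, n) for i, n in enumerate(["x", "z"])],
            "C": [gene("C", i * 20, i * 20 + 10, n) for i, n in enumerate(["y"])],
        }
        counts, classes, dups = gene_presence_matrix(ann)
        assert counts.loc["y", "A"] == 2 and counts.loc["y", "B"] == 0 and counts.loc["y", "C"] == 1
        assert dups == {"A": 1, "B": 0, "C": 0}
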