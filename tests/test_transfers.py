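"""Transfer calling, repeat dedup, compartment attribution, summaries, clusters."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from egt.core import Genome, Interval, PlastomeStructure, Role, revcomp
from egt.homolog import HomologyParams
from egt.repeats import find_exact_repeats
from egt.simulate import ImplantSpec, MtptSpec, SimConfig, simulate_mitogenome, simulate_nuclear, simulate_plastome
from egt.transfers import (
    TransferCall,
    attribute_compartment,
    call_transfers,
    cluster_large_fragments,
    dedup_repeat_hits,
    dotmatrix_report,
    summarize_by_chromosome,
)

from .conftest import rand_seq


def mk_call(chrom: str, start: int, end: int, src=(0, 100), score=None, klass="NUMT") -> TransferCall:
    return TransferCall(
        klass=klass,
        target=Interval(chrom, start, end),
        source=Interval("mitogenome", *src),
        identity=1.0,
        evalue=1e-20,
        length=end - start,
        score=score if score is not None else end - start,
    )


class TestCallTransfers:
    def test_role_combinations(self, rng):
        mito = Genome(id="m", seq=rand_seq(rng, 2000), role=Role.mitogenome)
        nuc = Genome(id="c", seq=rand_seq(rng, 2000), role=Role.nuclear_chromosome)
        with pytest.raises(ValueError, match="no transfer class"):
            call_transfers(nuc, [mito])

    def test_null_specificity_zero_calls(self):
        """Independent random organelle vs host yields no calls at E<=1e-5."""
        for trial in range(5):
            rng = np.random.default_rng(300 + trial)
            org = Genome(id="m", seq=rand_seq(rng, 10_000), role=Role.mitogenome)
            host = Genome(id="c", seq=rand_seq(rng, 50_000), role=Role.nuclear_chromosome)
            assert call_transfers(org, [host]) == []

    def test_implants_recovered_with_class(self):
        cfg = SimConfig(
            seed=21, mito_len=20_000, repeat_spec=(), mtpt_spec=(),
            n_chromosomes=2, chrom_len=30_000,
            numt_spec=(ImplantSpec(400, count=5, divergence=0.0),),
            nupt_spec=(),
        )
        mito, _ = simulate_mitogenome(cfg)
        chroms, truth = simulate_nuclear(cfg, mito)
        calls = call_transfers(mito, chroms)
        assert len(calls) == 5 and all(c.klass == "NUMT" for c in calls)
        truth_loci = {(e.target.seq_id, e.target.start, e.target.end) for e in truth.events}
        got = {(c.target.seq_id, c.target.start, c.target.end) for c in calls}
        assert got == truth_loci


class TestDedupRepeatHits:
    def _repeat_scenario(self, rng, copies: int):
        """Organelle with a repeat family; one nuclear insertion of the repeat."""
        unit = rand_seq(rng, 600)
        parts = []
        for _ in range(copies):
            parts.append(unit)
            parts.append(rand_seq(rng, 900))
        org = Genome(id="mitogenome", seq=rand_seq(rng, 400) + "".join(parts), role=Role.mitogenome)
        host = Genome(
            id="chr01", seq=rand_seq(rng, 2_000) + unit + rand_seq(rng, 2_000),
            role=Role.nuclear_chromosome,
        )
        calls = call_transfers(org, [host])
        reps = find_exact_repeats(org)
        return calls, reps

    def test_two_copy_repeat_collapses_to_one(self, rng):
        calls, reps = self._repeat_scenario(rng, 2)
        assert len(calls) == 2
        deduped = dedup_repeat_hits(calls, reps)
        assert len(deduped) == 1 and deduped[0].deduped

    def test_three_copy_repeat_single_survivor(self, rng):
        calls, reps = self._repeat_scenario(rng, 3)
        assert len(calls) == 3
        assert len(dedup_repeat_hits(calls, reps)) == 1

    def test_no_repeats_passthrough(self, rng):
        calls = [mk_call("c", 0, 100), mk_call("c", 500, 700)]
        assert dedup_repeat_hits(calls, []) == calls

    def test_idempotent(self, rng):
        calls, reps = self._repeat_scenario(rng, 3)
        once = dedup_repeat_hits(calls, reps)
        assert dedup_repeat_hits(once, reps) == once


class TestAttributeCompartment:
    def _structure(self):
        return PlastomeStructure(
            lsc=Interval("plastome", 0, 1000),
            ira=Interval("plastome", 1000, 1400),
            ssc=Interval("plastome", 1400, 1600),
            irb=Interval("plastome", 1600, 2000),
        )

    def test_ssc_hit_counts_fully(self):
        calls = [mk_call("m", 0, 32, src=(1450, 1482), klass="MTPT")]
        labelled, totals = attribute_compartment(calls, self._structure())
        assert labelled[0].compartment == "SSC"
        assert totals["SSC"] == 32

    def test_identical_ir_hits_counted_once(self):
        # the same segment hitting IRa and (reflected) IRb
        calls = [
            mk_call("m", 0, 100, src=(1100, 1200), klass="MTPT"),
            mk_call("m", 0, 100, src=(1800, 1900), klass="MTPT"),
        ]
        _, totals = attribute_compartment(calls, self._structure())
        assert totals["IR"] == 100

    def test_missing_structure_all_na(self):
        calls = [mk_call("m", 0, 100, src=(0, 100), klass="MTPT")]
        with pytest.warns(UserWarning):
            labelled, totals = attribute_compartment(calls, None)
        assert labelled[0].compartment == "NA" and totals["total"] == 0

    def test_table2_geometry_exact(self):
        """MTPT implants with the published LSC/SSC/IR footprint are recovered
        with exact per-compartment totals (2,558 + 32 + 7,008 = 9,598 bp)."""
        cfg = SimConfig(
            seed=2, plastome_len=30_000, ir_len=8_000, ssc_len=2_000,
            mito_len=45_000, repeat_spec=(),
            mtpt_spec=(MtptSpec(2_558, "LSC"), MtptSpec(32, "SSC"), MtptSpec(7_008, "IR")),
            n_chromosomes=1, chrom_len=10_000, numt_spec=(), nupt_spec=(),
        )
        pl, st = simulate_plastome(cfg)
        mito, _ = simulate_mitogenome(cfg, pl, st)
        calls, totals = attribute_compartment(call_transfers(pl, [mito]), st)
        assert (totals["LSC"], totals["SSC"], totals["IR"]) == (2_558, 32, 7_008)
        assert totals["total"] == 9_598


class TestSummaries:
    def test_arithmetic_example(self):
        host = [Genome(id="c", seq="A" * 10_000, role=Role.nuclear_chromosome)]
        calls = [mk_call("c", 0, 36), mk_call("c", 1000, 1100), mk_call("c", 5000, 5300)]
        summaries, rollup = summarize_by_chromosome(calls, host)
        s = summaries[0]
        assert (s.n, s.n_ge_threshold) == (3, 1)
        assert s.median_len == 100 and s.cumulative_bp == 436
        assert s.pct_of_chromosome == pytest.approx(4.36)
        assert rollup["cumulative_bp"] == 436

    def test_empty_calls(self):
        host = [Genome(id="c", seq="A" * 1_000, role=Role.nuclear_chromosome)]
        summaries, rollup = summarize_by_chromosome([], host)
        s = summaries[0]
        assert s.n == 0 and s.cumulative_bp == 0 and s.pct_of_chromosome == 0.0

    def test_thousand_random_calls_vs_direct_recomputation(self, rng):
        host = [
            Genome(id=f"c{i}", seq="A" * 50_000, role=Role.nuclear_chromosome) for i in range(3)
        ]
        calls = []
        for _ in range(1000):
            chrom = f"c{int(rng.integers(3))}"
            start = int(rng.integers(0, 49_000))
            length = int(rng.integers(36, 1000))
            calls.append(mk_call(chrom, start, min(50_000, start + length)))
        summaries, rollup = summarize_by_chromosome(calls, host, sub_threshold=250)
        df = pd.DataFrame(
            {
                "chrom": [c.target.seq_id for c in calls],
                "len": [c.length for c in calls],
                "start": [c.target.start for c in calls],
                "end": [c.target.end for c in calls],
            }
        )
        for s in summaries:
            sub = df[df.chrom == s.chrom_id]
            assert s.n == len(sub)
            assert s.mean_len == pytest.approx(sub.len.mean())
            assert s.median_len == pytest.approx(sub.len.median())
            assert s.n_ge_threshold == int((sub.len >= 250).sum())
            mask = np.zeros(50_000, dtype=bool)
            for _, row in sub.iterrows():
                mask[row.start : row.end] = True
            assert s.cumulative_bp == int(mask.sum())
        assert rollup["n"] == 1000


class TestClusters:
    def test_two_calls_within_gap_cluster(self):
        calls = [mk_call("c", 0, 2_000), mk_call("c", 12_000, 14_000)]
        cl = cluster_large_fragments(calls, min_large_len=1_000, max_gap=100_000)
        assert len(cl) == 1 and len(cl[0].members) == 2

    def test_gap_too_large_suppresses_singletons(self):
        calls = [mk_call("c", 0, 2_000), mk_call("c", 12_000, 14_000)]
        assert cluster_large_fragments(calls, min_large_len=1_000, max_gap=5_000) == []

    def test_small_calls_ignored(self):
        calls = [mk_call("c", 0, 500), mk_call("c", 600, 1_100)]
        assert cluster_large_fragments(calls, min_large_len=1_000) == []

    def test_simulated_clusters_match_truth(self):
        cfg = SimConfig(
            seed=31, mito_len=25_000, repeat_spec=(), mtpt_spec=(),
            n_chromosomes=2, chrom_len=60_000,
            numt_spec=(
                ImplantSpec(2_000, count=4, divergence=0.0, clustered=True, chromosome=0),
                ImplantSpec(1_500, count=3, divergence=0.0, clustered=True, chromosome=1),
            ),
            nupt_spec=(),
        )
        mito, _ = simulate_mitogenome(cfg)
        chroms, truth = simulate_nuclear(cfg, mito)
        calls = call_transfers(mito, chroms)
        clusters = cluster_large_fragments(calls, min_large_len=1_000, max_gap=100_000)
        per_chrom = {c.chrom_id: len(c.members) for c in clusters}
        assert per_chrom == {"chr01": 4, "chr02": 3}


class TestDotMatrix:
    def test_verbatim_region_single_fragment(self, rng):
        org = Genome(id="m", seq=rand_seq(rng, 20_000), role=Role.mitogenome)
        region = Genome(id="r", seq=org.seq[5_000: 8_000], role=Role.nuclear_chromosome)
        frags, mosaic = dotmatrix_report(region, org)
        assert len(frags) == 1
        assert frags[0].identity_pct == 100.0 and not mosaic

    def test_stitched_distant_segments_flag_mosaic(self, rng):
        org = Genome(id="m", seq=rand_seq(rng, 40_000), role=Role.mitogenome)
        region = Genome(
            id="r", seq=org.seq[1_000:3_000] + org.seq[30_000:32_000],
            role=Role.nuclear_chromosome,
        )
        frags, mosaic = dotmatrix_report(region, org)
        assert len(frags) == 2 and mosaic

    def test_inverted_middle_third_gives_three_fragments(self, rng):
        org = Genome(id="m", seq=rand_seq(rng, 30_000), role=Role.mitogenome)
        seg = org.seq[4_000:10_000]
        third = len(seg) // 3
        region_seq = seg[:third] + revcomp(seg[third : 2 * third]) + seg[2 * third :]
        region = Genome(id="r", seq=region_seq, role=Role.nuclear_chromosome)
        frags, mosaic = dotmatrix_report(region, org)
        assert [f.orientation for f in frags] == ["+", "-", "+"]
        assert mosaic  # mixed orientations
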