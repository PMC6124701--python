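"""Generator contracts: geometry, determinism, truth logging, read statistics."""

from __future__ import annotations

import numpy as np
import pytest

from egt.core import revcomp, Topology
from egt.repeats import find_exact_repeats
from egt.simulate import (
    ConfigError,
    ImplantSpec,
    MtptSpec,
    RepeatSpec,
    SimConfig,
    simulate_mitogenome,
    simulate_nuclear,
    simulate_plastome,
    simulate_reads,
)


def small_cfg(**kw) -> SimConfig:
    base = dict(
        seed=11,
        plastome_len=15_000,
        ir_len=2_000,
        ssc_len=1_500,
        mito_len=20_000,
        repeat_spec=(),
        mtpt_spec=(),
        n_chromosomes=2,
        chrom_len=30_000,
        numt_spec=(),
        nupt_spec=(),
        depth=50.0,
        error_rate=0.0,
    )
    base.update(kw)
    return SimConfig(**base)


class TestPlastome:
    def test_lsc_length_from_geometry(self):
        g, st = simulate_plastome(small_cfg())
        assert len(st.lsc) == 15_000 - 2 * 2_000 - 1_500 == 9_500
        assert len(g) == 15_000 and g.topology is Topology.circular

    def test_deterministic(self):
        g1, _ = simulate_plastome(small_cfg())
        g2, _ = simulate_plastome(small_cfg())
        assert g1.seq == g2.seq

    def test_irb_is_revcomp_of_ira(self):
        g, st = simulate_plastome(small_cfg())
        ira = g.seq[st.ira.start : st.ira.end]
        irb = g.seq[st.irb.start : st.irb.end]
        assert irb == revcomp(ira)

    def test_bad_geometry_rejected(self):
        with pytest.raises(ConfigError):
            small_cfg(plastome_len=5_000, ir_len=2_000, ssc_len=1_500)


class TestMitogenome:
    def test_planted_direct_repeat_recovered(self):
        cfg = small_cfg(repeat_spec=(RepeatSpec(2_000, "direct"),))
        mito, truth = simulate_mitogenome(cfg)
        pairs = [p for p in find_exact_repeats(mito) if p.orientation == "direct"]
        assert len(pairs) == 1 and pairs[0].length >= 2_000
        ev = truth.of_class("repeat")[0]
        got = {(pairs[0].a.start, pairs[0].a.end), (pairs[0].b.start, pairs[0].b.end)}
        assert got == {(ev.source.start, ev.source.end), (ev.target.start, ev.target.end)}

    def test_inverted_repeat_recovered(self):
        cfg = small_cfg(repeat_spec=(RepeatSpec(800, "inverted"),))
        mito, _ = simulate_mitogenome(cfg)
        inv = [p for p in find_exact_repeats(mito) if p.orientation == "inverted"]
        assert len(inv) == 1 and inv[0].length >= 800

    def test_empty_specs_mean_no_repeats(self):
        mito, truth = simulate_mitogenome(small_cfg())
        assert truth.events == []
        assert find_exact_repeats(mito) == []

    def test_overfull_config_rejected(self):
        cfg = small_cfg(repeat_spec=(RepeatSpec(11_000, "direct", copies=2),))
        with pytest.raises(ConfigError):
            simulate_mitogenome(cfg)

    def test_mtpt_requires_plastome(self):
        with pytest.raises(ConfigError):
            simulate_mitogenome(small_cfg(mtpt_spec=(MtptSpec(500, "LSC"),)), plastome=None)

    def test_mtpt_copied_verbatim_and_logged(self):
        cfg = small_cfg(mtpt_spec=(MtptSpec(1_000, "IR"),))
        pl, st = simulate_plastome(cfg)
        mito, truth = simulate_mitogenome(cfg, pl, st)
        ev = truth.of_class("MTPT")[0]
        assert mito.seq[ev.target.start : ev.target.end] == pl.seq[ev.source.start : ev.source.end]
        assert st.ira.start <= ev.source.start < ev.source.end <= st.ira.end


class TestNuclear:
    def test_undiverged_implant_verbatim(self):
        cfg = small_cfg(numt_spec=(ImplantSpec(3_000, count=1, divergence=0.0),))
        mito, _ = simulate_mitogenome(cfg)
        chroms, truth = simulate_nuclear(cfg, mito)
        ev = truth.of_class("NUMT")[0]
        chrom = next(c for c in chroms if c.id == ev.target.seq_id)
        got = chrom.seq[ev.target.start : ev.target.end]
        src = mito.seq[ev.source.start : ev.source.end]
        assert got == (src if ev.orientation == "+" else revcomp(src))
        assert len(got) == 3_000

    def test_length_conservation(self):
        cfg = small_cfg(
            numt_spec=(ImplantSpec(500, count=4, divergence=0.0),),
            nupt_spec=(ImplantSpec(300, count=2, divergence=0.0),),
        )
        pl, _ = simulate_plastome(cfg)
        mito, _ = simulate_mitogenome(cfg)
        chroms, truth = simulate_nuclear(cfg, mito, pl)
        implanted = sum(len(e.target) for e in truth.events)
        assert sum(len(c) for c in chroms) == 2 * cfg.chrom_len + implanted

    def test_divergence_measured_within_binomial_band(self):
        cfg = small_cfg(numt_spec=(ImplantSpec(3_000, count=2, divergence=0.05),))
        mito, _ = simulate_mitogenome(cfg)
        chroms, truth = simulate_nuclear(cfg, mito)
        from egt.transfers import call_transfers

        calls = call_transfers(mito, chroms)
        assert calls
        for c in calls:
            assert 0.93 <= c.identity <= 0.97

    def test_clustered_implants_share_one_window(self):
        cfg = small_cfg(
            nupt_spec=(ImplantSpec(1_200, count=10, divergence=0.0, clustered=True, chromosome=0),)
        )
        pl, _ = simulate_plastome(cfg)
        chroms, truth = simulate_nuclear(cfg, plastome=pl)
        evs = truth.of_class("NUPT")
        assert len(evs) == 10
        assert {e.target.seq_id for e in evs} == {"chr01"}
        span = max(e.target.end for e in evs) - min(e.target.start for e in evs)
        assert span <= 5 * sum(len(e.target) for e in evs)

    def test_implant_longer_than_chromosome_rejected(self):
        cfg = small_cfg(numt_spec=(ImplantSpec(3_000, count=1),), chrom_len=2_000, mito_len=20_000)
        mito, _ = simulate_mitogenome(cfg)
        with pytest.raises(ConfigError):
            simulate_nuclear(cfg, mito)


class TestReads:
    def test_total_bases_match_depth(self):
        cfg = small_cfg(depth=200.0, mito_len=40_000)
        mito, _ = simulate_mitogenome(cfg)
        rs = simulate_reads([mito], cfg)
        total = sum(len(s) for s in rs.r1) + sum(len(s) for s in rs.r2)
        assert total == pytest.approx(200 * 40_000, rel=0.02)

    def test_error_free_reads_are_exact_substrings(self):
        cfg = small_cfg()
        mito, _ = simulate_mitogenome(cfg)
        rs = simulate_reads([mito], cfg)
        doubled = mito.seq + mito.seq
        for s in rs.r1[:200] + rs.r2[:200]:
            assert s in doubled or revcomp(s) in doubled

    def test_byte_identical_fastq_for_same_config(self, tmp_path):
        cfg = small_cfg()
        mito, _ = simulate_mitogenome(cfg)
        for tag in ("a", "b"):
            rs = simulate_reads([mito], cfg)
            rs.write_fastq(tmp_path / f"{tag}_1.fq", tmp_path / f"{tag}_2.fq")
        assert (tmp_path / "a_1.fq").read_bytes() == (tmp_path / "b_1.fq").read_bytes()
        assert (tmp_path / "a_2.fq").read_bytes() == (tmp_path / "b_2.fq").read_bytes()

    def test_plastome_weight_boosts_mtpt_depth(self):
        cfg = small_cfg(mtpt_spec=(MtptSpec(2_000, "LSC"),), depth=40.0, mito_len=25_000)
        pl, st = simulate_plastome(cfg)
        mito, truth = simulate_mitogenome(cfg, pl, st)
        rs = simulate_reads([mito, pl], cfg, weights={"plastome": 10.0})
        from egt.assemble import AssemblyParams, coverage_profile

        depth, _, _ = coverage_profile(mito, rs, AssemblyParams(min_depth_qc=1))
        ev = truth.of_class("MTPT")[0]
        inside = depth[ev.target.start + 100 : ev.target.end - 100].mean()
        outside = np.concatenate([depth[: ev.target.start - 100], depth[ev.target.end + 100 :]]).mean()
        assert inside >= 5 * outside

    def test_read_longer_than_genome_rejected(self):
        cfg = small_cfg()
        from egt.core import Genome

        tiny = Genome(id="t", seq="ACGT" * 10)
        with pytest.raises(ConfigError):
            simulate_reads([tiny], cfg)

    def test_error_rate_produces_mismatches(self):
        cfg = small_cfg(error_rate=0.01)
        mito, _ = simulate_mitogenome(cfg)
        rs = simulate_reads([mito], cfg)
        doubled = mito.seq + mito.seq
        mismatched = sum(1 for s in rs.r1[:300] if s not in doubled and revcomp(s) not in doubled)
        assert mismatched > 100  # ~63% of 100bp reads carry >= 1 error at 1%
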