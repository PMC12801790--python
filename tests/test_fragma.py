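import numpy as np
import pandas as pd
import pytest

from fragclass.fragma import (
    ALU_FEATURE_NAMES,
    CGCG_FEATURE_NAMES,
    FRAGMA_FEATURE_NAMES,
    EndEvents,
    collect_end_events,
    fragma_alu_ratios,
    fragma_cgcg_ratios,
    fragma_features,
)
from fragclass.fragments import ReferenceGenome, encode_seq
from fragclass.manifests import RegionSet

from .conftest import make_fragments
from .oracle_fragma import enumerate_fragma


def _regions(rows):
    return RegionSet(pd.DataFrame(rows, columns=["chrom", "start", "end"]))


def _events_from_motifs(motifs):
    """EndEvents with given motif strings at dummy positions."""
    return EndEvents(
        chrom_codes=np.zeros(len(motifs), dtype=np.int16),
        chrom_names=("c",),
        pos=np.arange(len(motifs), dtype=np.int64),
        minus=np.zeros(len(motifs), dtype=bool),
        motif=np.stack([encode_seq(m) for m in motifs]),
    )


class TestCollectEndEvents:
    def test_both_ends_inside_region(self):
        ref = {"c": "ACGT" * 100}
        frags, _ = make_fragments(ref, [("c", 100, 267)])
        ev = collect_end_events(frags, _regions([("c", 0, 500)]))
        assert len(ev) == 2
        assert sorted(ev.pos.tolist()) == [100, 266]
        assert sorted(ev.minus.tolist()) == [False, True]

    def test_fragment_outside_region(self):
        ref = {"c": "ACGT" * 200}
        frags, _ = make_fragments(ref, [("c", 600, 767)])
        ev = collect_end_events(frags, _regions([("c", 0, 500)]))
        assert len(ev) == 0

    def test_per_end_membership(self):
        ref = {"c": "ACGT" * 200}
        frags, _ = make_fragments(ref, [("c", 400, 600)])  # left in, right out
        ev = collect_end_events(frags, _regions([("c", 0, 500)]))
        assert len(ev) == 1 and not ev.minus[0]

    def test_empty_region_set_raises(self):
        ref = {"c": "ACGT" * 10}
        frags, _ = make_fragments(ref, [("c", 0, 10)])
        with pytest.raises(ValueError, match="no regions"):
            collect_end_events(frags, RegionSet(pd.DataFrame(columns=["chrom", "start", "end"])))

    def test_left_only_mode(self):
        ref = {"c": "ACGT" * 100}
        frags, _ = make_fragments(ref, [("c", 100, 267)])
        ev = collect_end_events(frags, _regions([("c", 0, 500)]), ends="left_only")
        assert len(ev) == 1 and not ev.minus[0]


class TestAluRatios:
    def test_hand_counted_mixture(self):
        ev = _events_from_motifs(["CGA", "CGA", "ACG"] + ["TTT"] * 7)
        r = fragma_alu_ratios(ev)
        assert r["r_CGA"] == pytest.approx(0.2)
        assert r["r_ACG"] == pytest.approx(0.1)
        assert r["r_CGN_over_NCG"] == pytest.approx(2.0)

    def test_single_motif_saturates(self):
        r = fragma_alu_ratios(_events_from_motifs(["CGT"] * 5))
        assert r["r_CGT"] == 1.0
        for name in ("r_CGA", "r_CGC", "r_CGG", "r_ACG", "r_CCG", "r_GCG", "r_TCG"):
            assert r[name] == 0.0

    def test_zero_ncg_pseudo_count_with_warning(self):
        ev = _events_from_motifs(["CGA", "CGT"])
        with pytest.warns(UserWarning, match="pseudo-count"):
            r = fragma_alu_ratios(ev)
        assert r["r_CGN_over_NCG"] == 2.0  # 2 CGN / pseudo-denominator 1

    def test_eight_ratios_partition_bound(self):
        rng = np.random.default_rng(0)
        bases = "ACGT"
        motifs = ["".join(rng.choice(list(bases), 3)) for _ in range(500)]
        r = fragma_alu_ratios(_events_from_motifs(motifs))
        s = sum(r[n] for n in ALU_FEATURE_NAMES[:8])
        assert 0.0 <= s <= 1.0


class TestCgcgRatios:
    def test_event_at_cgc_register(self):
        # single CGCG at position 2 of AACGCGTT; an event at pos 2 reads CGC
        ref = {"c": "AACGCGTT"}
        frags, rg = make_fragments(ref, [("c", 2, 7)])
        ev = collect_end_events(frags, _regions([("c", 0, 8)]), ends="left_only")
        r = fragma_cgcg_ratios(ev, _regions([("c", 0, 8)]), rg)
        assert r["c_CGC"] == 1.0
        assert sum(r[n] for n in CGCG_FEATURE_NAMES[:10]) == 1.0
        assert r["c_CGN_over_CGC"] == 0.0

    def test_event_at_upstream_ncg_register(self):
        ref = {"c": "AACGCGTT"}
        frags, rg = make_fragments(ref, [("c", 1, 6)])  # pos 1, motif ACG
        ev = collect_end_events(frags, _regions([("c", 0, 8)]), ends="left_only")
        r = fragma_cgcg_ratios(ev, _regions([("c", 0, 8)]), rg)
        assert r["c_NCG_A"] == 1.0

    def test_no_cgcg_occurrences_all_zero_with_warning(self):
        ref = {"c": "ATATATATAT"}
        frags, rg = make_fragments(ref, [("c", 0, 6)])
        regions = _regions([("c", 0, 10)])
        ev = collect_end_events(frags, regions, ends="left_only")
        with pytest.warns(UserWarning, match="no CGCG"):
            r = fragma_cgcg_ratios(ev, regions, rg)
        assert all(r[n] == 0.0 for n in CGCG_FEATURE_NAMES)

    def test_reverse_strand_register(self):
        # right end at pos p+3 of a CGCG reads CGC on the minus strand
        ref = {"c": "AACGCGTT"}
        frags, rg = make_fragments(ref, [("c", 0, 6)])  # right end pos 5 = p+3
        regions = _regions([("c", 0, 8)])
        ev = collect_end_events(frags, regions)
        minus = ev.minus
        assert minus.any()
        r = fragma_cgcg_ratios(ev, regions, rg)
        assert r["c_CGC"] > 0.0


class TestFragmaFeatures:
    def test_exactly_21_named_features(self):
        ref = {"c": "AACGCGTTAACGCGTT" * 4}
        frags, rg = make_fragments(ref, [("c", 1, 40), ("c", 2, 41), ("c", 9, 50)])
        f = fragma_features(frags, _regions([("c", 0, 64)]), rg)
        assert len(f.values) == 21
        assert f.names == FRAGMA_FEATURE_NAMES

    def test_duplication_invariance(self):
        # fixture has CGN, NCG and CGCG-register events, so every ratio
        # denominator is nonzero and exact duplication must be a no-op
        ref = {"c": "AACGCGTTAACGCGTT" * 8}
        triples = [("c", 1, 40), ("c", 2, 41), ("c", 9, 50), ("c", 18, 100), ("c", 64, 120)]
        regions = _regions([("c", 0, 128)])
        frags1, rg = make_fragments(ref, triples)
        frags2, _ = make_fragments(ref, triples * 2)
        f1 = fragma_features(frags1, regions, rg)
        f2 = fragma_features(frags2, regions, rg)
        np.testing.assert_allclose(f1.values, f2.values, atol=1e-12)

    def test_n_motifs_only_handled_without_nan(self):
        ref = {"c": "NNNNNNNNNNNNNNNN"}
        frags, rg = make_fragments(ref, [("c", 0, 8)])
        with pytest.warns(UserWarning):
            f = fragma_features(frags, _regions([("c", 0, 16)]), rg)
        assert np.isfinite(f.values).all()

    def test_motif_bias_direction_in_simulated_cohort(self, toy_genome, toy_cfg):
        """Tumor samples with elevated CpG cleavage show a higher mean
        CGN/NCG end-motif ratio than healthy samples."""
        import fragclass as fc

        tumor, healthy = [], []
        for i in range(12):
            fh = fc.simulate_sample(toy_genome, toy_cfg, "healthy", 0.0, f"h{i}", 5000 + i)
            healthy.append(fragma_features(fh, toy_genome.alu, toy_genome.reference)["r_CGN_over_NCG"])
            ft = fc.simulate_sample(toy_genome, toy_cfg, "cancer", 0.3, f"c{i}", 6000 + i)
            tumor.append(fragma_features(ft, toy_genome.alu, toy_genome.reference)["r_CGN_over_NCG"])
        assert np.mean(tumor) > np.mean(healthy)


class TestBruteForceOracle:
    """Exhaustive enumeration on a hand-built reference reproduces every
    feature exactly."""

    REF = {
        "t": (
            "TTACGCGTTACGTAGCGCGATCCGTTTACGCGTAACGTTGCGCGTTACCGTAGGCA"
            "TGACGCGATTTCGCGTAATCGTACGGCATCGCGTACGTTAGGCGCGATTACGTAGC"
            "ATCGCGTTAACGCGTATCCGTAGGCATTACGCGTTAGGCATCGTACGGCATTAGCA"
        )
    }
    REGIONS = [("t", 0, 60), ("t", 70, 168)]
    FRAGMENTS = [
        ("t", 1, 40), ("t", 2, 45), ("t", 9, 60), ("t", 15, 77), ("t", 18, 90),
        ("t", 27, 95), ("t", 30, 101), ("t", 58, 120), ("t", 60, 131), ("t", 71, 140),
        ("t", 75, 150), ("t", 80, 155), ("t", 96, 160), ("t", 100, 165), ("t", 110, 167),
        ("t", 3, 33), ("t", 40, 112), ("t", 62, 129),
    ]

    def test_all_21_features_match_enumeration(self):
        frags, rg = make_fragments(self.REF, self.FRAGMENTS)
        regions = _regions(self.REGIONS)
        got = fragma_features(frags, regions, rg).as_dict()
        expected = enumerate_fragma(self.REF, self.FRAGMENTS, self.REGIONS)
        assert set(got) == set(expected)
        for name in FRAGMA_FEATURE_NAMES:
            assert got[name] == pytest.approx(expected[name], abs=1e-12), name

    def test_cgcg_context_ratios_partition_to_one(self):
        frags, rg = make_fragments(self.REF, self.FRAGMENTS)
        got = fragma_features(frags, _regions(self.REGIONS), rg).as_dict()
        assert sum(got[n] for n in CGCG_FEATURE_NAMES[:10]) == pytest.approx(1.0, abs=1e-12)
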