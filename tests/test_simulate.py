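import hashlib
import json
from dataclasses import replace

import numpy as np
import pytest
from scipy.stats import ks_2samp

import fragclass as fc
from fragclass.simulate import (
    GenomeConfig,
    SimulationConfig,
    TumorModel,
    build_toy_genome,
    simulate_cohort,
    simulate_sample,
)


def _small_cfg(seed=21, **genome_kw):
    g = dict(n_chroms=2, chrom_length=2_000_000)
    g.update(genome_kw)
    return SimulationConfig(genome=GenomeConfig(**g), seed=seed, depth=0.5)


class TestToyGenome:
    def test_arm_and_bin_arithmetic(self, toy_genome):
        assert len(toy_genome.arms) == 8  # 4 chroms x 2 arms
        assert len(toy_genome.bins) == 12  # 4 x 3 bins of 1 Mb

    def test_same_seed_identical_sequence(self):
        cfg = _small_cfg()
        g1 = build_toy_genome(cfg)
        g2 = build_toy_genome(cfg)
        assert g1.sequences == g2.sequences

    def test_short_chromosomes_rejected(self):
        with pytest.raises(ValueError, match="2 Mb"):
            build_toy_genome(_small_cfg(chrom_length=1_000_000))

    def test_cgcg_enriched_in_alu(self, toy_genome):
        total_cgcg = 0
        alu_cgcg = 0
        alu_span = 0
        genome_span = 0
        by_chrom = toy_genome.alu.per_chrom()
        for name in toy_genome.chroms.names:
            seq = toy_genome.sequences[name]
            genome_span += len(seq)
            positions = []
            start = seq.find("CGCG")
            while start != -1:
                positions.append(start)
                start = seq.find("CGCG", start + 1)
            total_cgcg += len(positions)
            ivals = by_chrom[name]
            alu_span += int((ivals[:, 1] - ivals[:, 0]).sum())
            for p in positions:
                if ((ivals[:, 0] <= p) & (p + 4 <= ivals[:, 1])).any():
                    alu_cgcg += 1
        background_rate = (total_cgcg - alu_cgcg) / (genome_span - alu_span)
        alu_rate = alu_cgcg / alu_span
        assert alu_rate >= 3 * background_rate

    def test_written_genome_reloads_identically(self, tmp_path):
        cfg = _small_cfg()
        g = build_toy_genome(cfg)
        g.write(tmp_path)
        chroms = fc.load_chrom_table(tmp_path / "chroms.tsv")
        assert chroms.names == g.chroms.names
        from fragclass.fragments import ReferenceGenome

        ref = ReferenceGenome(tmp_path / "genome.fa")
        for name in g.chroms.names:
            assert ref.seq(name, 0, 100) == g.sequences[name][:100]


class TestSimulateSample:
    def test_healthy_mean_length_matches_mixture(self, toy_genome, toy_cfg):
        frags = fc.simulate_sample(toy_genome, toy_cfg, "healthy", 0.0, "h", 1)
        expected = toy_cfg.healthy.mean_length
        assert abs(frags.length.mean() - expected) < 2.0

    def test_healthy_with_positive_tf_rejected(self, toy_genome, toy_cfg):
        with pytest.raises(ValueError, match="healthy"):
            simulate_sample(toy_genome, toy_cfg, "healthy", 0.1, "h", 1)

    def test_invalid_copy_number_rejected(self):
        with pytest.raises(ValueError, match="copy_number"):
            SimulationConfig(tumor=TumorModel(cnv_segments=(("toy1", 0, 1000, 2),)))

    def test_cn3_density_matches_dosage_closed_form(self, toy_genome, toy_cfg):
        tf = 0.3
        frags = fc.simulate_sample(toy_genome, toy_cfg, "cancer", tf, "c", 13)
        chrom_of = np.asarray(frags.chrom_names)[frags.chrom_codes]
        mid = (frags.start + frags.end) // 2
        # CN=3 segment toy1:0.5-2.5 Mb vs the untouched chromosome toy3
        seg = (chrom_of == "toy1") & (mid >= 500_000) & (mid < 2_500_000)
        bg = chrom_of == "toy3"
        dens_seg = seg.sum() / 2_000_000
        dens_bg = bg.sum() / 3_000_000
        assert dens_seg / dens_bg == pytest.approx(1 + tf / 2, abs=0.03)

    def test_tf_zero_cancer_equals_healthy_distribution(self, toy_genome):
        cfg = replace(fc.SimulationConfig(seed=7), depth=1.0)
        h = simulate_sample(toy_genome, cfg, "healthy", 0.0, "h", 31)
        c = simulate_sample(toy_genome, cfg, "cancer", 0.0, "c", 32)
        n = 50_000
        assert ks_2samp(h.length[:n], c.length[:n]).pvalue > 0.01
        assert ks_2samp(h.start[:n], c.start[:n]).pvalue > 0.01

    def test_same_seed_identical_fragments(self, toy_genome, toy_cfg):
        a = simulate_sample(toy_genome, toy_cfg, "cancer", 0.2, "c", 55)
        b = simulate_sample(toy_genome, toy_cfg, "cancer", 0.2, "c", 55)
        np.testing.assert_array_equal(a.start, b.start)
        np.testing.assert_array_equal(a.end, b.end)


class TestSimulateCohort:
    def test_default_study_shape(self):
        cfg = _small_cfg()
        co = simulate_cohort(cfg)
        sheet = co.sheet
        train = sheet[sheet["split"] == "train"]
        val = sheet[sheet["split"] == "validation"]
        assert len(train) == 231 and (train["label"] == "cancer").sum() == 119
        assert len(val) == 164 and (val["label"] == "cancer").sum() == 85

    def test_stage_proxy_monotone_in_tf(self):
        co = simulate_cohort(_small_cfg(), tf_range=(0.05, 0.3))
        sheet = co.sheet
        cancer = sheet[sheet["label"] == "cancer"]
        means = cancer.groupby("stage")["tf"].mean()
        assert means["I"] < means["II"] < means["III"]

    def test_too_small_cohort_rejected(self):
        with pytest.raises(ValueError, match=">= 2"):
            simulate_cohort(_small_cfg(), n_train=(1, 5))

    def test_reproducible_from_seed(self, tmp_path):
        cfg = _small_cfg(seed=33)
        genome = build_toy_genome(cfg)
        digests = []
        for rep in range(2):
            co = simulate_cohort(cfg, n_train=(2, 2), n_validation=(2, 2))
            out = tmp_path / f"rep{rep}"
            co.write(genome, out)
            h = hashlib.sha256()
            for p in sorted(out.rglob("*.bed")):
                h.update(p.read_bytes())
            h.update((out / "cohort_sheet.tsv").read_bytes())
            digests.append(h.hexdigest())
        assert digests[0] == digests[1]

    def test_truth_record_regenerates_sample(self, toy_genome, toy_cfg):
        co = simulate_cohort(toy_cfg, n_train=(2, 2), n_validation=(2, 2))
        truth = co.truth()
        rec = truth["samples"][0]
        a = co.samples[0].simulate(toy_genome, toy_cfg)
        b = simulate_sample(
            toy_genome, toy_cfg, rec["label"], rec["tf"], rec["sample_id"],
            np.random.SeedSequence(rec["seed_entropy"]),
        )
        np.testing.assert_array_equal(a.start, b.start)

    def test_single_axis_signal_lands_in_matching_block(self, toy_genome):
        """With only one signal axis active, that axis's feature block has
        the best out-of-fold AUC."""
        from fragclass.ensemble import auc_score, stack, train_base_models, default_specs
        from fragclass.pipeline import build_feature_matrix, summarize_cohort

        h = fc.HealthyModel()
        axes = {
            "fsd": fc.TumorModel(size_mode=145.0, cnv_segments=(), motif_effect=1.0),
            "cnv": fc.TumorModel(size_mode=h.size_mode, size_sd=h.size_sd, motif_effect=1.0),
            "fragma": fc.TumorModel(size_mode=h.size_mode, size_sd=h.size_sd,
                                    cnv_segments=(), motif_effect=4.0),
        }
        for expected_block, tumor in axes.items():
            cfg = fc.SimulationConfig(tumor=tumor, seed=7, depth=1.0)
            co = simulate_cohort(cfg, n_train=(30, 30), n_validation=(2, 2),
                                 tf_range=(0.3, 0.3), seed=70 + len(expected_block))
            summaries = summarize_cohort(co, toy_genome)
            fm, _, _ = build_feature_matrix(summaries, toy_genome.bins)
            tr = fm.training()
            _, oof = train_base_models(tr, default_specs(sorted(tr.blocks), seed=1), seed=1)
            block_auc = {
                b: auc_score(stack(oof[[c for c in oof.columns if c[0] == b]]), tr.labels)
                for b in tr.blocks
            }
            top = max(block_auc, key=block_auc.get)
            assert top == expected_block, block_auc
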