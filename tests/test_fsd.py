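import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import ranksums

import fragclass as fc
from fragclass.fsd import (
    SizeBinScheme,
    fit_fsd_normalizer,
    fsd_features,
    fsd_gc_correct,
    fsd_raw,
)

from .conftest import make_fragments


class TestSizeBinScheme:
    @pytest.mark.parametrize(
        "length,expected", [(110, 0), (114, 0), (115, 1), (229, 23), (230, -1), (90, -1), (109, -1)]
    )
    def test_half_open_boundaries(self, length, expected):
        assert SizeBinScheme().bin_of(np.array([length]))[0] == expected

    def test_default_covers_110_to_230(self):
        s = SizeBinScheme()
        assert (s.lower, s.upper, s.n_bins) == (110, 230, 24)

    @settings(max_examples=100, deadline=None)
    @given(st.integers(1, 600))
    def test_bin_index_consistent_with_interval(self, length):
        s = SizeBinScheme()
        k = int(s.bin_of(np.array([length]))[0])
        if k == -1:
            assert length < s.lower or length >= s.upper
        else:
            assert s.lower + k * s.width <= length < s.lower + (k + 1) * s.width

    def test_hg19_label_count_is_936(self):
        arms = fc.load_hg19_arm_table()
        labels = SizeBinScheme().labels(arms.included["arm_id"])
        assert len(labels) == 936
        assert labels[0] == "1p_110"


class TestFsdRaw:
    def test_conservation_per_arm(self, toy_genome, toy_cfg):
        frags = fc.simulate_sample(toy_genome, toy_cfg, "healthy", 0.0, "h", 5)
        raw = fsd_raw(frags, toy_genome.arms)
        scheme = raw.scheme
        in_support = (frags.length >= scheme.lower) & (frags.length < scheme.upper)
        mid = (frags.start + frags.end) // 2
        chrom_of = np.asarray(frags.chrom_names)[frags.chrom_codes]
        for ai, arm in enumerate(toy_genome.arms.included.itertuples(index=False)):
            on_arm = in_support & (chrom_of == arm.chrom) & (mid >= arm.start) & (mid < arm.end)
            assert raw.counts[ai].sum() == on_arm.sum()

    def test_out_of_support_ignored(self):
        ref = {"c": "A" * 10_000}
        frags, _ = make_fragments(ref, [("c", 0, 90), ("c", 0, 167)])
        arms = fc.ArmTable(
            __import__("pandas").DataFrame(
                [("cp", "c", 0, 5_000, False), ("cq", "c", 5_000, 10_000, False)],
                columns=["arm_id", "chrom", "start", "end", "excluded"],
            )
        )
        raw = fsd_raw(frags, arms)
        assert raw.counts.sum() == 1

    def test_toy_matrix_shape(self, toy_genome, toy_cfg):
        frags = fc.simulate_sample(toy_genome, toy_cfg, "healthy", 0.0, "h", 6)
        raw = fsd_raw(frags, toy_genome.arms)
        assert raw.counts.shape == (8, 24)  # 4 chroms x 2 arms, 24 size bins


class TestFsdGcCorrect:
    def _counts(self, n_arms=12, seed=0):
        rng = np.random.default_rng(seed)
        return rng.poisson(5_000, size=(n_arms, 24)).astype(float), rng.uniform(0.35, 0.6, n_arms)

    def test_flat_counts_nearly_unchanged(self):
        counts, gc = self._counts()
        out = fsd_gc_correct(counts, gc)
        rel = np.abs(out - counts) / counts
        assert rel.max() < 0.05

    def test_gc_proportional_trend_removed(self):
        _, gc = self._counts()
        counts = np.outer(gc, np.full(24, 10_000.0))
        out = fsd_gc_correct(counts, gc)
        for k in range(24):
            b0 = np.polyfit(gc, counts[:, k], 1)[0]
            b1 = np.polyfit(gc, out[:, k], 1)[0]
            assert abs(b1) < 0.05 * abs(b0)

    def test_identical_gc_identity_with_warning(self):
        counts, _ = self._counts()
        with pytest.warns(UserWarning, match="skipped"):
            out = fsd_gc_correct(counts, np.full(12, 0.5))
        np.testing.assert_array_equal(out, counts)

    def test_too_few_arms_identity_with_warning(self):
        counts, gc = self._counts(n_arms=8)
        with pytest.warns(UserWarning, match="fewer than 10 arms"):
            out = fsd_gc_correct(counts, gc)
        np.testing.assert_array_equal(out, counts)


class TestNormalizer:
    def test_hand_computed_mean_and_sample_sd(self):
        training = [np.full((1, 1), v) for v in (10.0, 20.0, 30.0)]
        norm = fit_fsd_normalizer(training)
        assert norm.mean[0] == 20.0
        assert norm.std[0] == 10.0  # sample sd, ddof=1
        assert norm.transform(np.array([[30.0]]))[0] == pytest.approx(1.0)

    def test_degenerate_features_forced_to_zero(self):
        training = [np.full((2, 3), 5.0) for _ in range(4)]
        with pytest.warns(UserWarning, match="degenerate"):
            norm = fit_fsd_normalizer(training)
        z = norm.transform(np.full((2, 3), 99.0))
        np.testing.assert_array_equal(z, np.zeros(6))

    def test_training_mean_sample_maps_to_zero(self):
        rng = np.random.default_rng(0)
        training = [rng.normal(100, 10, size=(3, 4)) for _ in range(5)]
        norm = fit_fsd_normalizer(training)
        z = norm.transform(np.mean(np.stack([t.ravel() for t in training]), axis=0))
        np.testing.assert_allclose(z, 0.0, atol=1e-9)

    def test_round_trip(self):
        rng = np.random.default_rng(1)
        training = [rng.normal(50, 5, size=(2, 24)) for _ in range(4)]
        norm = fit_fsd_normalizer(training)
        x = rng.normal(50, 5, size=48)
        np.testing.assert_allclose(norm.inverse(norm.transform(x)), x, atol=1e-9)

    def test_training_cohort_standardized(self):
        rng = np.random.default_rng(2)
        training = [rng.normal(100, 20, size=(2, 24)) for _ in range(10)]
        norm = fit_fsd_normalizer(training)
        zs = np.stack([fsd_features(t, norm) for t in training])
        np.testing.assert_allclose(zs.mean(axis=0), 0.0, atol=1e-9)
        np.testing.assert_allclose(zs.std(axis=0, ddof=1), 1.0, atol=1e-9)

    def test_shape_mismatch_rejected(self):
        norm = fit_fsd_normalizer([np.ones((2, 24)) + i for i in range(3)])
        with pytest.raises(ValueError, match="length"):
            norm.transform(np.ones(24))


class TestSizeShiftSignal:
    def test_short_bin_zscores_elevated_in_cancer(self, toy_genome, toy_cfg):
        """Cancer samples (size mode shifted 167 -> 145 at tf = 0.2) show
        higher z in the sub-150 bp bins than matched healthy samples."""
        n = 30
        corrected = []
        labels = []
        for i in range(n):
            f = fc.simulate_sample(toy_genome, toy_cfg, "healthy", 0.0, f"h{i}", 3000 + i)
            corrected.append(fsd_raw(f, toy_genome.arms).counts.astype(float))
            labels.append(0)
        for i in range(n):
            f = fc.simulate_sample(toy_genome, toy_cfg, "cancer", 0.2, f"c{i}", 4000 + i)
            corrected.append(fsd_raw(f, toy_genome.arms).counts.astype(float))
            labels.append(1)
        norm = fit_fsd_normalizer(corrected)
        scheme = SizeBinScheme()
        short = np.array([scheme.lower + k * scheme.width < 150 for k in range(scheme.n_bins)])
        short_mask = np.tile(short, len(corrected[0]))
        mean_short_z = np.array(
            [fsd_features(c, norm)[short_mask].mean() for c in corrected]
        )
        labels = np.array(labels, dtype=bool)
        assert mean_short_z[labels].mean() > mean_short_z[~labels].mean()
        assert ranksums(mean_short_z[labels], mean_short_z[~labels]).pvalue < 0.01
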