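import itertools
import math

import numpy as np
import pytest
from scipy import stats

from rnashapespace import (
    SamplerConfig,
    build_spectrum,
    default_level,
    discovery_curve,
    fold_maxpair,
    neutral_set_size,
    rank_spectrum,
    sample_sequences,
)
from rnashapespace.gsampling import ShapeSpectrum


class TestSamplerConfig:
    def test_gc_override(self):
        config = SamplerConfig(10, 5, 0, gc=0.7)
        assert config.probs == pytest.approx((0.15, 0.35, 0.35, 0.15))

    def test_bad_probs_rejected(self):
        with pytest.raises(ValueError):
            SamplerConfig(10, 5, 0, base_probs=(0.5, 0.5, 0.5, 0.5))

    def test_negative_n_rejected(self):
        with pytest.raises(ValueError):
            SamplerConfig(10, -1, 0)


class TestSampleSequences:
    def test_empty_stream(self):
        assert list(sample_sequences(SamplerConfig(10, 0, 0))) == []

    def test_gc_one_is_all_cg(self):
        seqs = list(sample_sequences(SamplerConfig(20, 50, 1, gc=1.0)))
        assert all(set(s) <= {"C", "G"} for s in seqs)

    def test_seed_reproducibility_is_bit_exact(self):
        a = list(sample_sequences(SamplerConfig(30, 200, 7)))
        b = list(sample_sequences(SamplerConfig(30, 200, 7)))
        assert a == b

    def test_uniform_base_frequencies(self):
        # each base's empirical frequency within the 99.9% binomial interval
        n, L = 10_000, 30
        seqs = list(sample_sequences(SamplerConfig(L, n, 13)))
        text = "".join(seqs)
        total = n * L
        lo, hi = stats.binom.interval(0.999, total, 0.25)
        for base in "ACGU":
            assert lo <= text.count(base) <= hi


class TestShapeSpectrum:
    def test_counts_must_sum_to_n(self):
        with pytest.raises(ValueError):
            ShapeSpectrum(10, 5, 5, {"[]": 3})

    def test_frequencies_sum_to_one(self):
        spec = ShapeSpectrum(10, 5, 10, {"[]": 7, "_": 3})
        assert math.isclose(sum(spec.frequencies.values()), 1.0)

    def test_wilson_ci_brackets_frequency(self):
        spec = ShapeSpectrum(10, 5, 100, {"[]": 80, "_": 20})
        for shape in spec.counts:
            lo, hi = spec.wilson_ci(shape)
            assert lo <= spec.frequency(shape) <= hi

    def test_merge_sums_counts(self):
        a = ShapeSpectrum(10, 5, 4, {"[]": 3, "_": 1})
        b = ShapeSpectrum(10, 5, 2, {"[]": 1, "[][]": 1})
        merged = a.merge(b)
        assert merged.counts == {"[]": 4, "_": 1, "[][]": 1}
        assert merged.n_samples == 6

    def test_merge_rejects_mismatched_config(self):
        a = ShapeSpectrum(10, 5, 1, {"[]": 1})
        b = ShapeSpectrum(12, 5, 1, {"[]": 1})
        with pytest.raises(ValueError):
            a.merge(b)


class TestBuildSpectrum:
    def test_degenerate_folder(self, builtin_folder):
        spec = build_spectrum(iter(["AAAA"] * 5), lambda s: "." * len(s), 5)
        assert spec.counts == {"_": 5}
        assert spec.frequency("_") == 1.0

    def test_determinism(self, builtin_folder):
        config = SamplerConfig(25, 500, 3)
        a = build_spectrum(sample_sequences(config), builtin_folder, 5, L=25)
        b = build_spectrum(sample_sequences(config), builtin_folder, 5, L=25)
        assert a.counts == b.counts

    def test_exhaustive_L8_enumeration_vs_sampling(self, builtin_folder):
        """The all-4^8-sequences spectrum is the infinite-sample limit; a
        seeded 10^5 sample's Wilson CIs must cover the exact frequencies
        for >= 90% of its shapes."""
        level = 1  # finest level: resolves the most shapes at this tiny L
        exact = build_spectrum(
            ("".join(p) for p in itertools.product("ACGU", repeat=8)),
            builtin_folder, level, L=8)
        assert exact.n_samples == 4 ** 8

        sampled = build_spectrum(
            sample_sequences(SamplerConfig(8, 100_000, 17)),
            builtin_folder, level, L=8)
        # sampling can only find shapes that exist
        assert set(sampled.counts) <= set(exact.counts)
        covered = 0
        for shape in sampled.counts:
            lo, hi = sampled.wilson_ci(shape)
            if lo <= exact.frequency(shape) <= hi:
                covered += 1
        assert covered / sampled.n_shapes >= 0.9


class TestRankSpectrum:
    def test_descending_with_byte_order_ties(self):
        spec = ShapeSpectrum(10, 5, 7, {"[]": 2, "[[]]": 2, "_": 3})
        ranked = rank_spectrum(spec)
        assert [r[1] for r in ranked] == ["_", "[[]]", "[]"]
        assert [r[0] for r in ranked] == [1, 2, 3]

    def test_rank_frequency_spans_orders_of_magnitude(self, gsample_spectrum_L30):
        ranked = rank_spectrum(gsample_spectrum_L30)
        span = math.log10(ranked[0][2] / ranked[-1][2])
        assert span >= 2.0


class TestDiscoveryCurve:
    def test_zero_checkpoint(self, builtin_folder):
        assert discovery_curve(SamplerConfig(20, 0, 0), builtin_folder, 5,
                               [0]) == [(0, 0)]

    def test_monotone_nondecreasing(self, builtin_folder):
        curve = discovery_curve(SamplerConfig(25, 0, 5), builtin_folder, 5,
                                [50, 100, 200, 400, 800])
        counts = [c for _, c in curve]
        assert counts == sorted(counts)

    def test_rejects_unsorted_checkpoints(self, builtin_folder):
        with pytest.raises(ValueError):
            discovery_curve(SamplerConfig(25, 0, 5), builtin_folder, 5,
                            [100, 50])


class TestNeutralSetSize:
    @pytest.mark.parametrize("f, L, expected", [
        (1.0, 1, 4.0),
        (0.0, 10, 0.0),
        (0.25, 10, 262144.0),
    ])
    def test_arithmetic(self, f, L, expected):
        assert neutral_set_size(f, L) == expected

    def test_bounded_by_sequence_space(self):
        assert neutral_set_size(0.37, 20) <= 4 ** 20


def test_default_level_rule():
    assert [default_level(L) for L in (40, 55, 70, 126)] == [3, 3, 5, 5]
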