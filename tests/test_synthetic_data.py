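import pytest

from rnashapespace import (
    SamplerConfig,
    SyntheticSpec,
    build_spectrum,
    compare_spectra,
    natural_spectrum,
    overrepresentation_test,
    rank_spectrum,
    sample_sequences,
)
from rnashapespace.synthetic_data import (
    generate_database,
    generate_deposition_bias,
    generate_gc_biased,
    generate_null_database,
    generate_selected_database,
)

LEVEL = 5


class TestSpec:
    def test_rejects_unknown_mode(self):
        with pytest.raises(ValueError):
            SyntheticSpec(mode="bogus")

    def test_rejects_nonpositive_weights(self):
        with pytest.raises(ValueError):
            SyntheticSpec(mode="selected", weights={"[]": 0.0})


class TestNullGenerator:
    def test_empty(self):
        assert len(generate_null_database(SyntheticSpec(n=0))) == 0

    def test_seed_reproducible(self):
        a = generate_null_database(SyntheticSpec(L=20, n=100, seed=4))
        b = generate_null_database(SyntheticSpec(L=20, n=100, seed=4))
        assert a.sequences == b.sequences

    def test_deduplicated_fixed_length(self):
        ds = generate_null_database(SyntheticSpec(L=12, n=500, seed=1))
        assert len(set(ds.sequences)) == 500
        assert all(len(s) == 12 for s in ds.sequences)


class TestSelectedGenerator:
    def test_equal_weights_match_null_distribution(self, builtin_folder):
        # equal weights accept everything: the draw stream is the null one
        spec = SyntheticSpec(L=15, n=200, seed=3, mode="selected",
                             weights={"[]": 1.0})
        sel = generate_selected_database(spec, builtin_folder, LEVEL)
        null = generate_null_database(
            SyntheticSpec(L=15, n=200, seed=3), builtin_folder, LEVEL)
        assert len(sel) == len(null) == 200

    def test_downweighted_top_shape_is_suppressed(self, builtin_folder,
                                                  gsample_spectrum_L30):
        top_shape = rank_spectrum(gsample_spectrum_L30)[0][1]
        spec = SyntheticSpec(L=30, n=1500, seed=21, mode="selected",
                             weights={top_shape: 0.01})
        sel = generate_selected_database(spec, builtin_folder, LEVEL)
        sel_spec = natural_spectrum(sel, builtin_folder, LEVEL)
        f_sel = sel_spec.frequency(top_shape)
        f_g = gsample_spectrum_L30.frequency(top_shape)
        # ~100-fold suppression; allow broad sampling slack
        assert f_sel < f_g / 20

    def test_selection_degrades_correlation(self, builtin_folder,
                                            gsample_spectrum_L30):
        """Inverting the rank order via extreme weights must lower r
        relative to the paired-seed null run."""
        ranked = rank_spectrum(gsample_spectrum_L30)
        # favor rare shapes with a 100x weight ratio: enough to invert the
        # ranks of the common shapes while keeping acceptance practical
        weights = {shape: 1.0 / max(f, 1e-2)
                   for _, shape, f, _ in ranked}
        sel = generate_selected_database(
            SyntheticSpec(L=30, n=800, seed=33, mode="selected",
                          weights=weights),
            builtin_folder, LEVEL)
        null = generate_null_database(
            SyntheticSpec(L=30, n=800, seed=33), builtin_folder, LEVEL)
        r_sel = compare_spectra(natural_spectrum(sel, builtin_folder, LEVEL),
                                gsample_spectrum_L30,
                                min_natural_count=5).pearson_r
        r_null = compare_spectra(natural_spectrum(null, builtin_folder, LEVEL),
                                 gsample_spectrum_L30,
                                 min_natural_count=5).pearson_r
        assert r_sel < r_null - 0.1


class TestDepositionBias:
    def test_multiplier_one_is_identity(self, builtin_folder):
        base = generate_null_database(
            SyntheticSpec(L=20, n=100, seed=2), builtin_folder, LEVEL)
        assert generate_deposition_bias(base, "[]", 1.0, builtin_folder,
                                        LEVEL, seed=0) is base

    def test_spike_inflates_only_target_shape(self, builtin_folder):
        base = generate_null_database(
            SyntheticSpec(L=25, n=400, seed=6), builtin_folder, LEVEL)
        base_spec = natural_spectrum(base, builtin_folder, LEVEL)
        target = rank_spectrum(base_spec)[1][1]
        spiked = generate_deposition_bias(base, target, 5.0, builtin_folder,
                                          LEVEL, seed=8)
        spiked_spec = natural_spectrum(spiked, builtin_folder, LEVEL)
        assert spiked_spec.counts[target] == 5 * base_spec.counts[target]
        for shape, count in base_spec.counts.items():
            if shape != target:
                assert spiked_spec.counts[shape] == count

    def test_absent_shape_rejected(self, builtin_folder):
        base = generate_null_database(
            SyntheticSpec(L=20, n=50, seed=2), builtin_folder, LEVEL)
        with pytest.raises(ValueError):
            generate_deposition_bias(base, "[[[[[]]]]]", 2.0,
                                     builtin_folder, LEVEL, seed=0)


class TestGcBiased:
    def test_gc_one_is_all_cg_and_heavily_paired(self, builtin_folder):
        ds = generate_gc_biased(
            SyntheticSpec(L=25, n=300, seed=5, mode="gc_biased", gc=1.0),
            builtin_folder, LEVEL)
        assert all(set(s) <= {"C", "G"} for s in ds.sequences)
        spec = natural_spectrum(ds, builtin_folder, LEVEL)
        # all-GC strands pair heavily: unfolded chains should be rare
        assert spec.frequency("_") < 0.05

    def test_matched_gc_comparison_stays_strong(self, builtin_folder):
        """GC-shifted database vs a GC-matched G-sample should correlate
        about as well as the null does (robustness to composition bias)."""
        gc = 0.7
        ds = generate_gc_biased(
            SyntheticSpec(L=30, n=1500, seed=14, mode="gc_biased", gc=gc),
            builtin_folder, LEVEL)
        nat = natural_spectrum(ds, builtin_folder, LEVEL)
        gs = build_spectrum(
            sample_sequences(SamplerConfig(30, 15_000, 15, gc=gc)),
            builtin_folder, LEVEL, L=30)
        res = compare_spectra(nat, gs, min_natural_count=5)
        assert res.coverage > 0.9
        assert res.pearson_r > 0.85


class TestDispatch:
    def test_generate_database_modes(self, builtin_folder):
        null = generate_database(SyntheticSpec(L=15, n=50, seed=1),
                                 builtin_folder, LEVEL)
        assert len(null) == 50
        with pytest.raises(ValueError):
            generate_database(SyntheticSpec(L=15, n=10, seed=1,
                                            mode="deposition_bias"),
                              builtin_folder, LEVEL)
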