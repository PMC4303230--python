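import numpy as np
import pytest

from ctdx.genome import CNAEvent, arm_interval
from ctdx.io import write_histogram
from ctdx.simulate import (
    CohortConfig,
    expected_bin_weights,
    make_germline_dbsnp_fixture,
    make_index_patient_fixture,
    make_variant_cascade_fixture,
    simulate_bin_counts,
    simulate_cohort,
    simulate_deep_seq_counts,
    simulate_size_histogram,
    tumor_fraction_to_af,
    uniform_baseline,
    INDEX_GENES,
    TRUNCAL_GENES,
)


class TestSimulateBinCounts:
    def test_f0_expected_uniform(self, toy):
        events = [CNAEvent("chr1", 0, 50_000_000, 1)]
        p = expected_bin_weights(toy, events, 0.0)
        assert np.allclose(p, 1.0 / toy.n_bins)

    def test_f1_gain_expected_1_5x(self, hg19_small):
        chrom, start, end = arm_interval(hg19_small, "1q")
        p = expected_bin_weights(hg19_small, [CNAEvent(chrom, start, end, 1)], 1.0)
        arms = hg19_small.arm_labels()
        in_arm, outside = p[arms == "1q"], p[arms != "1q"]
        # (2+1)/2 = 1.5x the diploid baseline
        assert np.allclose(in_arm / outside[0], 1.5)

    def test_conservation(self, toy, rng):
        counts = simulate_bin_counts(toy, [], 0.1, 12_345, rng)
        assert counts.sum() == 12_345

    def test_same_seed_identical(self, toy):
        ev = [CNAEvent("chr2", 0, 50_000_000, -1)]
        a = simulate_bin_counts(toy, ev, 0.3, 10_000, seed=7)
        b = simulate_bin_counts(toy, ev, 0.3, 10_000, seed=7)
        assert np.array_equal(a, b)

    def test_bad_tumor_fraction(self, toy):
        with pytest.raises(ValueError):
            simulate_bin_counts(toy, [], 1.5, 100, seed=0)

    def test_bad_total_reads(self, toy):
        with pytest.raises(ValueError):
            simulate_bin_counts(toy, [], 0.5, 0, seed=0)


class TestSimulateSizeHistogram:
    def test_mass_integrates_to_one(self):
        hist = simulate_size_histogram(0.8, 0.2, 0.0, seed=0)
        assert hist.total_mass() == pytest.approx(1.0, abs=1e-6)

    def test_single_component_single_peak(self):
        hist = simulate_size_histogram(1.0, 0.0, 0.0, seed=1)
        peak = hist.sizes[np.argmax(hist.density)]
        assert 152 <= peak <= 172
        # no mass beyond the mononucleosomal tail in the long band
        long_mass = hist.density[(hist.sizes >= 250) & (hist.sizes < 450)].sum()
        assert long_mass / hist.density.sum() < 0.002

    def test_two_components_two_peaks(self):
        from ctdx.sizing import detect_peaks

        hist = simulate_size_histogram(0.8, 0.2, 0.0, seed=2)
        peaks = detect_peaks(hist)
        assert any(152 <= p <= 172 for p in peaks)
        assert any(300 <= p <= 340 for p in peaks)

    def test_all_zero_weights_rejected(self):
        with pytest.raises(ValueError):
            simulate_size_histogram(0.0, 0.0, 0.0, seed=0)

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError):
            simulate_size_histogram(-0.1, 1.0, 0.0, seed=0)

    def test_analytic_mode_deterministic(self):
        a = simulate_size_histogram(0.7, 0.3, 0.0, n_fragments=None)
        b = simulate_size_histogram(0.7, 0.3, 0.0, n_fragments=None)
        assert np.array_equal(a.density, b.density)

    def test_same_seed_byte_identical_file(self, tmp_path):
        for name in ("a.tsv", "b.tsv"):
            write_histogram(tmp_path / name, simulate_size_histogram(0.8, 0.2, seed=42))
        assert (tmp_path / "a.tsv").read_bytes() == (tmp_path / "b.tsv").read_bytes()


class TestSimulateDeepSeq:
    def test_af_zero(self):
        assert simulate_deep_seq_counts(0.0, 1000, seed=0) == (0, 1000)

    def test_af_one(self):
        assert simulate_deep_seq_counts(1.0, 1000, seed=0) == (1000, 1000)

    def test_binomial_mean_recovery(self):
        # printed tumor-A DDR2 AF as ground truth
        rng = np.random.default_rng(0)
        fracs = [
            simulate_deep_seq_counts(0.364, 10_000, rng)[0] / 10_000
            for _ in range(1_000)
        ]
        assert np.mean(fracs) == pytest.approx(0.364, abs=0.005)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            simulate_deep_seq_counts(1.2, 100, seed=0)
        with pytest.raises(ValueError):
            simulate_deep_seq_counts(0.5, 0, seed=0)


def test_tumor_fraction_to_af():
    assert tumor_fraction_to_af(0.3) == pytest.approx(0.15)
    assert tumor_fraction_to_af(0.3, heterozygous=False) == pytest.approx(0.3)


class TestIndexFixture:
    def test_lesion_a_carries_mll3_lacks_pik3ca(self, index_fixture):
        a = index_fixture.lesions["A"]
        assert "MLL3" in a.snv_set
        assert "PIK3CA" not in a.snv_set

    def test_truncal_five_in_every_lesion(self, index_fixture):
        for spec in index_fixture.lesions.values():
            assert set(TRUNCAL_GENES) <= spec.snv_set

    def test_ddr2_af_elevated_in_a(self, index_fixture):
        lesions = index_fixture.lesions
        assert lesions["A"].snv_afs["DDR2"] == pytest.approx(0.364)
        assert lesions["C"].snv_afs["DDR2"] == pytest.approx(0.153)
        assert lesions["D"].snv_afs["DDR2"] == pytest.approx(0.166)

    def test_pik3ca_in_lymph_nodes_and_ctcs_only(self, index_fixture):
        for lid in ("LN15", "LN17", "LNA"):
            assert "PIK3CA" in index_fixture.lesions[lid].snv_set
        for spec in index_fixture.ctcs.values():
            assert "PIK3CA" in spec.snv_set
        for lid in ("A", "C", "D"):
            assert "PIK3CA" not in index_fixture.lesions[lid].snv_set

    def test_plasma_true_af_in_printed_range(self, index_fixture):
        for spec in index_fixture.plasma.values():
            for af in spec.snv_afs.values():
                assert 0.02 <= af <= 0.03

    def test_ctcs_add_1p_loss(self, index_fixture):
        g = index_fixture.genome
        cen = g.centromeres["chr1"]
        for spec in index_fixture.ctcs.values():
            assert any(
                e.chrom == "chr1" and e.delta < 0 and e.end <= cen for e in spec.events
            )

    def test_phylogeny_consistency(self, index_fixture):
        samples = index_fixture.all_samples()
        for spec in samples.values():
            if spec.parent is not None:
                assert samples[spec.parent].snv_set <= spec.snv_set


class TestCohortConfig:
    def test_negative_composition_rejected(self):
        with pytest.raises(ValueError):
            CohortConfig(n_biphasic_detected=-1)

    def test_n_samples(self):
        assert CohortConfig().n_samples == 71

    def test_roundtrip_dict(self):
        c = CohortConfig(n_patients=10)
        assert CohortConfig.from_dict(c.to_dict()) == c


@pytest.fixture(scope="module")
def small_bundle():
    config = CohortConfig(
        n_biphasic_detected=3,
        n_biphasic_undetected=2,
        n_monophasic_detected=1,
        n_monophasic_undetected=4,
        n_patients=8,
        genome_bins=500,
        total_reads=50_000,
        hist_fragments=10_000,
    )
    return simulate_cohort(config, seed=3)


class TestSimulateCohort:
    def test_sample_count_and_metadata(self, small_bundle):
        assert len(small_bundle.samples) == 10
        meta = small_bundle.metadata()
        assert list(meta.columns[:2]) == ["sample", "patient"]
        assert meta["true_detectable"].sum() == 4

    def test_counts_conserved(self, small_bundle):
        for s in small_bundle.samples:
            assert s.counts.sum() == small_bundle.config.total_reads

    def test_all_monophasic_low_tf_all_balanced_expected(self):
        config = CohortConfig(
            n_biphasic_detected=0,
            n_biphasic_undetected=0,
            n_monophasic_detected=0,
            n_monophasic_undetected=5,
            n_patients=5,
            genome_bins=400,
            total_reads=50_000,
            hist_fragments=5_000,
        )
        bundle = simulate_cohort(config, seed=1)
        assert all(not s.detectable and s.events == () for s in bundle.samples)

    def test_same_seed_byte_identical_metadata(self, tmp_path):
        config = CohortConfig(
            n_biphasic_detected=1, n_biphasic_undetected=1,
            n_monophasic_detected=1, n_monophasic_undetected=1,
            n_patients=4, genome_bins=400, total_reads=10_000, hist_fragments=2_000,
        )
        for name in ("m1.tsv", "m2.tsv"):
            simulate_cohort(config, seed=9).metadata().to_csv(tmp_path / name, sep="\t", index=False)
        assert (tmp_path / "m1.tsv").read_bytes() == (tmp_path / "m2.tsv").read_bytes()


class TestVariantFixtures:
    def test_germline_partition_sizes(self):
        calls, known = make_germline_dbsnp_fixture(seed=1, n_total=500, n_known=420)
        assert len(calls) == 500
        assert sum(c.key in known for c in calls) == 420

    def test_invalid_partition_rejected(self):
        with pytest.raises(ValueError):
            make_germline_dbsnp_fixture(n_total=10, n_known=11)

    def test_cascade_fixture_somatic_counts_in_printed_range(self, cascade_fixture):
        germline_keys = {c.key for c in cascade_fixture.germline_calls}
        for sample, calls in cascade_fixture.tumor_calls.items():
            somatic = [c for c in calls if c.key not in germline_keys]
            assert 716 <= len(somatic) <= 1589

    def test_cascade_fixture_planted_genes_are_drivers(self, cascade_fixture):
        assert set(INDEX_GENES) <= set(cascade_fixture.resources.driver_genes)
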