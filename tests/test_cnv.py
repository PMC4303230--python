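import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ctdx.cnv import (
    CopyNumberProfile,
    Dendrogram,
    _segment_chromosome,
    call_status,
    counts_to_log2,
    hcluster_complete,
    is_balanced,
    manhattan_distance_matrix,
    recurrence_summary,
    segment_profile,
)
from ctdx.genome import CNAEvent, arm_interval, index_tumor_events, make_genome_model, toy_genome
from ctdx.simulate import expected_bin_weights, simulate_bin_counts, uniform_baseline


def noise_free_profile(genome, events, f):
    """Expected (noise-free) counts -> log2 profile."""
    weights = expected_bin_weights(genome, events, f)
    return counts_to_log2(weights * 1e6, uniform_baseline(genome), genome)


def status_profile(genome, status, sample_id="."):
    return CopyNumberProfile(
        genome=genome, log2=np.zeros(genome.n_bins), status=np.asarray(status, dtype=np.int8),
        sample_id=sample_id,
    )


class TestCountsToLog2:
    def test_identity(self, toy):
        baseline = uniform_baseline(toy)
        prof = counts_to_log2(baseline * 1e6, baseline, toy)
        assert np.allclose(prof.log2, 0.0)

    def test_full_tumor_gain_is_log2_1_5(self, toy):
        chrom, start, end = arm_interval(toy, "1q")
        prof = noise_free_profile(toy, [CNAEvent(chrom, start, end, 1)], 1.0)
        arms = toy.arm_labels()
        assert np.allclose(prof.log2[arms == "1q"], np.log2(1.5), atol=1e-12)
        assert np.allclose(prof.log2[arms != "1q"], 0.0, atol=1e-12)

    def test_diluted_gain_is_log2_1_1(self, toy):
        chrom, start, end = arm_interval(toy, "1q")
        prof = noise_free_profile(toy, [CNAEvent(chrom, start, end, 1)], 0.2)
        arms = toy.arm_labels()
        assert np.allclose(prof.log2[arms == "1q"], np.log2(1.1), atol=1e-12)

    def test_grid_mismatch_rejected(self, toy):
        with pytest.raises(ValueError):
            counts_to_log2(np.ones(10), np.ones(10), toy)

    def test_zero_baseline_rejected(self, toy):
        baseline = uniform_baseline(toy).copy()
        baseline[0] = 0.0
        with pytest.raises(ValueError):
            counts_to_log2(np.ones(toy.n_bins), baseline, toy)


def brute_force_segment(y, penalty):
    """Exhaustive minimum of SSE + penalty * n_segments over all segmentations."""
    n = len(y)
    best_cost, best_bounds = np.inf, None
    for k in range(n):
        for cuts in itertools.combinations(range(1, n), k):
            bounds = list(zip((0,) + cuts, cuts + (n,)))
            cost = sum(
                np.sum((y[s:e] - np.mean(y[s:e])) ** 2) for s, e in bounds
            ) + penalty * len(bounds)
            if cost < best_cost - 1e-12:
                best_cost, best_bounds = cost, bounds
    return best_cost, best_bounds


class TestSegmentation:
    def test_noise_free_step_exact_breakpoints(self):
        genome = make_genome_model({"chr1": 1_000_000}, n_bins=40)
        log2 = np.where(np.arange(40) < 25, 0.0, 0.585)
        prof = CopyNumberProfile(genome=genome, log2=log2)
        seg = segment_profile(prof)
        assert [(s.start_bin, s.end_bin) for s in seg.segments] == [(0, 25), (25, 40)]
        assert seg.segments[1].mean_log2 == pytest.approx(0.585)

    def test_constant_profile_single_segment_per_chromosome(self, toy):
        prof = CopyNumberProfile(genome=toy, log2=np.zeros(toy.n_bins))
        seg = segment_profile(prof)
        assert len(seg.segments) == len(toy.chromosomes)

    def test_non_finite_rejected(self, toy):
        log2 = np.zeros(toy.n_bins)
        log2[5] = np.inf
        with pytest.raises(ValueError):
            segment_profile(CopyNumberProfile(genome=toy, log2=log2))

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_on_small_chromosomes(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 13))
        y = np.round(rng.normal(0, 0.5, n), 3)
        penalty = float(rng.uniform(0.05, 1.0))
        oracle_cost, _ = brute_force_segment(y, penalty)
        bounds = _segment_chromosome(y, penalty)
        cost = sum(
            np.sum((y[s:e] - np.mean(y[s:e])) ** 2) for s, e in bounds
        ) + penalty * len(bounds)
        assert cost == pytest.approx(oracle_cost, abs=1e-9)


class TestCallStatus:
    def test_gain_neutral_loss(self, toy):
        chrom, start, end = arm_interval(toy, "1q")
        seg = segment_profile(noise_free_profile(toy, [CNAEvent(chrom, start, end, 1)], 1.0))
        called = call_status(seg, gain_cut=0.2, loss_cut=-0.2)
        arms = toy.arm_labels()
        assert np.all(called.status[arms == "1q"] == 1)
        assert np.all(called.status[arms != "1q"] == 0)

    def test_deep_loss(self, toy):
        prof = CopyNumberProfile(genome=toy, log2=np.full(toy.n_bins, -0.9))
        called = call_status(segment_profile(prof))
        assert np.all(called.status == -1)

    def test_inverted_cuts_rejected(self, toy):
        seg = segment_profile(CopyNumberProfile(genome=toy, log2=np.zeros(toy.n_bins)))
        with pytest.raises(ValueError):
            call_status(seg, gain_cut=-0.1, loss_cut=0.1)


class TestIsBalanced:
    def test_all_neutral_balanced(self, toy):
        assert is_balanced(status_profile(toy, np.zeros(toy.n_bins)))

    def test_low_tumor_fraction_plasma_balanced(self, hg19_small):
        events = index_tumor_events(hg19_small)
        counts = simulate_bin_counts(hg19_small, events, 0.025, 200_000, seed=11)
        prof = counts_to_log2(counts, uniform_baseline(hg19_small), hg19_small)
        assert is_balanced(call_status(segment_profile(prof)))

    def test_tumor_fraction_0_35_unbalanced(self, hg19_small):
        events = index_tumor_events(hg19_small)
        counts = simulate_bin_counts(hg19_small, events, 0.35, 200_000, seed=11)
        prof = counts_to_log2(counts, uniform_baseline(hg19_small), hg19_small)
        assert not is_balanced(call_status(segment_profile(prof)))


class TestRecurrence:
    def test_single_unbalanced_fractions_binary(self, toy):
        status = np.zeros(toy.n_bins)
        status[:100] = 1
        rec = recurrence_summary([status_profile(toy, status)])
        assert set(np.unique(rec.gain_fraction)) <= {0.0, 1.0}
        assert rec.n_profiles == 1

    def test_balanced_only_rejected(self, toy):
        with pytest.raises(ValueError):
            recurrence_summary([status_profile(toy, np.zeros(toy.n_bins))])

    def test_balanced_profiles_excluded(self, toy):
        status = np.zeros(toy.n_bins)
        status[:100] = -1
        balanced = status_profile(toy, np.zeros(toy.n_bins))
        rec = recurrence_summary([status_profile(toy, status), balanced])
        assert rec.n_profiles == 1
        assert rec.loss_fraction[0] == 1.0


class TestManhattanDistance:
    def test_identical_zero(self, toy):
        p = status_profile(toy, np.zeros(toy.n_bins))
        assert manhattan_distance_matrix([p, p])[0, 1] == 0.0

    def test_one_bin_gain_vs_neutral(self, toy):
        a = np.zeros(toy.n_bins)
        b = a.copy()
        b[7] = 1
        d = manhattan_distance_matrix([status_profile(toy, a), status_profile(toy, b)])
        assert d[0, 1] == 1.0

    def test_gain_vs_loss_counts_double(self, toy):
        k = 13
        a, b = np.zeros(toy.n_bins), np.zeros(toy.n_bins)
        a[:k], b[:k] = 1, -1
        d = manhattan_distance_matrix([status_profile(toy, a), status_profile(toy, b)])
        assert d[0, 1] == 2 * k

    @given(st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_metric_axioms(self, seed):
        genome = toy_genome(n_chrom=2, n_bins=30)
        rng = np.random.default_rng(seed)
        profiles = [
            status_profile(genome, rng.integers(-1, 2, genome.n_bins)) for _ in range(4)
        ]
        d = manhattan_distance_matrix(profiles)
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0)
        for i, j, k in itertools.permutations(range(4), 3):
            assert d[i, k] <= d[i, j] + d[j, k] + 1e-9


def brute_force_complete_linkage(dist, labels):
    """Independent complete-linkage: recompute all inter-cluster distances
    from the raw matrix at every step; merge the min (lexicographic ties)."""
    idx = {l: (i,) for i, l in enumerate(labels)}
    clusters = sorted(idx)
    merges = []
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(sorted(clusters), 2):
            d = max(dist[i][j] for i in idx[a] for j in idx[b])
            key = (d, min(a.split("|")), min(b.split("|")))
            if best is None or key < best[0]:
                best = (key, a, b)
        (d, _, _), a, b = best
        merges.append((d, frozenset(a.split("|")) | frozenset(b.split("|"))))
        new = "|".join(sorted(a.split("|") + b.split("|")))
        idx[new] = idx.pop(a) + idx.pop(b)
        clusters = [c for c in clusters if c not in (a, b)] + [new]
    return merges


class TestHcluster:
    def test_three_point_example(self):
        dist = np.array([[0, 1, 10], [1, 0, 10], [10, 10, 0]], float)
        dendro = hcluster_complete(dist, ["A", "B", "C"])
        assert dendro.merges[0] == (("A",), ("B",), 1.0)
        assert dendro.merges[1][2] == 10.0

    def test_single_leaf(self):
        dendro = hcluster_complete(np.zeros((1, 1)), ["X"])
        assert dendro.newick == "X;"
        assert dendro.merges == ()

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValueError):
            hcluster_complete(np.array([[0, 1], [2, 0]], float), ["A", "B"])

    def test_merge_heights_non_decreasing(self, rng):
        for _ in range(10):
            pts = rng.normal(size=(6, 3))
            dist = np.abs(pts[:, None] - pts[None, :]).sum(axis=2)
            np.fill_diagonal(dist, 0.0)
            dendro = hcluster_complete(dist, list("ABCDEF"))
            heights = dendro.heights
            assert all(h2 >= h1 - 1e-12 for h1, h2 in zip(heights, heights[1:]))

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_brute_force_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 7))
        labels = [f"s{i}" for i in range(n)]
        pts = rng.normal(size=(n, 2))
        dist = np.abs(pts[:, None] - pts[None, :]).sum(axis=2)
        np.fill_diagonal(dist, 0.0)
        dendro = hcluster_complete(dist, labels)
        oracle = brute_force_complete_linkage(dist, labels)
        assert len(dendro.merges) == len(oracle)
        for (a, b, h), (oh, omembers) in zip(dendro.merges, oracle):
            assert h == pytest.approx(oh)
            assert frozenset(a) | frozenset(b) == omembers

    def test_index_fixture_groups_co_cluster(self, index_fixture):
        genome = index_fixture.genome
        baseline = uniform_baseline(genome, 200_000.0)
        specs = {**index_fixture.lesions, **index_fixture.ctcs}
        profiles = []
        for i, (sid, spec) in enumerate(sorted(specs.items())):
            counts = simulate_bin_counts(genome, list(spec.events), spec.tumor_fraction,
                                         200_000, seed=100 + i)
            prof = counts_to_log2(counts, baseline, genome, sample_id=sid)
            profiles.append(call_status(segment_profile(prof)))
        dist = manhattan_distance_matrix(profiles)
        dendro = hcluster_complete(dist, [p.sample_id for p in profiles])
        merged_groups = [frozenset(a) | frozenset(b) for a, b, _ in dendro.merges]
        assert frozenset({"C", "D"}) in merged_groups
        assert any(g == {"LN15", "LN17", "LNA"} for g in merged_groups)
        assert any(g == {"CTC1", "CTC2", "CTC3"} for g in merged_groups)
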