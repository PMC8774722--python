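"""Removal-order sampling, cluster labeling, spanning, and break-step
detection, each checked against an independent oracle."""

import numpy as np
import pytest
from scipy import ndimage, stats

from shellperc import (
    LatticeSpec,
    RemovalOrder,
    assign_shells,
    find_critical_density,
    find_critical_density_forward,
    label_clusters,
    largest_cluster,
    removal_probabilities,
    sample_removal_order,
    snapshot_at_density,
    snapshot_at_threshold,
    spans,
)

FOUR_CONN = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])


def canonical_partition(labels):
    """Map a label image to first-occurrence canonical form so two labelings
    can be compared as partitions."""
    flat = labels.ravel()
    out = np.full(flat.shape, -1, dtype=np.int64)
    seen = {}
    for idx, lab in enumerate(flat):
        if lab <= 0:
            continue
        out[idx] = seen.setdefault(lab, len(seen))
    return out


class TestSampleRemovalOrder:
    @pytest.mark.parametrize("method", ["race", "rejection"])
    @pytest.mark.parametrize("r", [0.0, 0.3])
    def test_sequence_is_a_permutation(self, method, r):
        spec = LatticeSpec(8, 2)
        order = sample_removal_order(
            assign_shells(spec), removal_probabilities(r, 2), seed=42, method=method
        )
        assert np.array_equal(np.sort(order.sequence), np.arange(64))

    @pytest.mark.parametrize("method", ["race", "rejection"])
    def test_uniform_first_removal_without_gradient(self, method):
        # r = 0 reduces to a uniform shuffle: the first removed site is
        # uniform over all L^2 sites (chi-square, alpha = 0.01)
        spec = LatticeSpec(4, 2)
        sm, sched = assign_shells(spec), removal_probabilities(0.0, 2)
        firsts = [
            sample_removal_order(sm, sched, seed=s, method=method).sequence[0]
            for s in range(4000)
        ]
        counts = np.bincount(firsts, minlength=16)
        assert stats.chisquare(counts).pvalue > 0.01

    @pytest.mark.parametrize("method", ["race", "rejection"])
    def test_first_removal_matches_rejection_acceptance_law(self, method):
        # 4x4 lattice, 2 shells, r = 0.5: outer ring has 12 sites at weight 1,
        # inner 2x2 block 4 sites at weight 0.5.  Exact first-removal law of
        # the rejection process: P(outer) = 12*1 / (12*1 + 4*0.5) = 6/7.
        spec = LatticeSpec(4, 2)
        sm, sched = assign_shells(spec), removal_probabilities(0.5, 2)
        outer = sm.shell_index.ravel() == 0
        assert outer.sum() == 12
        n = 6000
        hits = sum(
            outer[sample_removal_order(sm, sched, seed=s, method=method).sequence[0]]
            for s in range(n)
        )
        p_exact = (12 * 1.0) / (12 * 1.0 + 4 * 0.5)
        # three-sigma binomial band around the exact law
        sigma = np.sqrt(p_exact * (1 - p_exact) / n)
        assert abs(hits / n - p_exact) < 3.5 * sigma

    def test_samplers_agree_in_distribution(self):
        # same first-removal shell frequencies from both implementations
        spec = LatticeSpec(4, 2)
        sm, sched = assign_shells(spec), removal_probabilities(0.5, 2)
        outer = sm.shell_index.ravel() == 0
        counts = {}
        for method in ("race", "rejection"):
            firsts = [
                sample_removal_order(sm, sched, seed=s, method=method).sequence[0]
                for s in range(3000)
            ]
            counts[method] = np.array(
                [np.sum(outer[firsts]), np.sum(~outer[firsts])]
            )
        table = np.vstack([counts["race"], counts["rejection"]])
        assert stats.chi2_contingency(table).pvalue > 0.01

    def test_mismatched_shell_counts_rejected(self):
        spec = LatticeSpec(6, 3)
        with pytest.raises(ValueError):
            sample_removal_order(
                assign_shells(spec), removal_probabilities(0.1, 2), seed=0
            )

    def test_reproducible_given_seed(self):
        spec = LatticeSpec(10, 3)
        sm, sched = assign_shells(spec), removal_probabilities(0.2, 3)
        a = sample_removal_order(sm, sched, seed=7)
        b = sample_removal_order(sm, sched, seed=7)
        assert np.array_equal(a.sequence, b.sequence)

    def test_invalid_sequence_rejected(self):
        spec = LatticeSpec(2, 1)
        with pytest.raises(ValueError, match="permutation"):
            RemovalOrder(sequence=np.array([0, 1, 2, 2]), seed=0, spec=spec)


class TestLabelClusters:
    def test_empty_and_full_grids(self):
        assert label_clusters(np.zeros((5, 5), dtype=bool)).n_clusters == 0
        state = label_clusters(np.ones((5, 5), dtype=bool))
        assert state.n_clusters == 1
        assert state.sizes[1] == 25
        assert spans(state)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_independent_flood_fill(self, seed):
        rng = np.random.default_rng(seed)
        grid = rng.random((20, 20)) < 0.5
        state = label_clusters(grid)
        ref, n_ref = ndimage.label(grid, structure=FOUR_CONN)
        assert state.n_clusters == n_ref
        assert np.array_equal(
            canonical_partition(state.labels), canonical_partition(ref)
        )
        assert sorted(state.sizes[1:]) == sorted(
            np.bincount(ref.ravel())[1:]
        )


class TestSpans:
    def test_single_column_spans_up_down(self):
        grid = np.zeros((6, 6), dtype=bool)
        grid[:, 2] = True
        assert spans(label_clusters(grid))

    def test_single_row_spans_left_right(self):
        grid = np.zeros((6, 6), dtype=bool)
        grid[3, :] = True
        assert spans(label_clusters(grid))

    def test_two_disjoint_half_columns_do_not_span(self):
        grid = np.zeros((6, 6), dtype=bool)
        grid[:3, 1] = True
        grid[4:, 1] = True
        assert not spans(label_clusters(grid))


class TestLargestCluster:
    def test_single_cluster_mask_equals_occupancy(self):
        grid = np.zeros((4, 4), dtype=bool)
        grid[1:3, 1:3] = True
        snap = largest_cluster(label_clusters(grid))
        assert np.array_equal(snap.largest_cluster, grid)

    def test_picks_the_bigger_of_two_components(self):
        grid = np.zeros((5, 5), dtype=bool)
        grid[0, :3] = True  # 3-site cluster
        grid[2:4, 2:4] = True
        grid[4, 3] = True  # joined: 5-site cluster
        state = label_clusters(grid)
        assert sorted(state.sizes[1:]) == [3, 5]
        mask = largest_cluster(state).largest_cluster
        ref, _ = ndimage.label(grid, structure=FOUR_CONN)
        big = np.argmax(np.bincount(ref.ravel())[1:]) + 1
        assert np.array_equal(mask, ref == big)
        assert mask.sum() == 5

    def test_empty_grid_raises(self):
        with pytest.raises(ValueError, match="empty"):
            largest_cluster(label_clusters(np.zeros((3, 3), dtype=bool)))


class TestCriticalDensity:
    def test_forward_and_reverse_agree_on_tiny_lattice(self):
        spec = LatticeSpec(2, 1)
        # keep the left column until the end: spanning persists until one of
        # its sites goes, which disconnects top from bottom
        order = RemovalOrder(np.array([1, 3, 0, 2]), seed=0, spec=spec)
        fwd = find_critical_density_forward(order)
        rev = find_critical_density(order)
        # {(0,0),(1,0)} still spans up/down; removing (0,0) breaks it,
        # leaving the single site (1,0)
        assert fwd.n_remaining == rev.n_remaining == 1
        assert rev.p_c == 0.25

    @pytest.mark.parametrize("r", [0.0, 0.3])
    def test_forward_and_reverse_agree_on_random_orders(self, r):
        spec = LatticeSpec(8, 2)
        sm, sched = assign_shells(spec), removal_probabilities(r, 2)
        for s in range(10):
            order = sample_removal_order(sm, sched, seed=s)
            assert (
                find_critical_density(order).n_remaining
                == find_critical_density_forward(order).n_remaining
            )

    def test_threshold_sample_bounds(self):
        spec = LatticeSpec(16, 4)
        sm, sched = assign_shells(spec), removal_probabilities(0.2, 4)
        ts = find_critical_density(sample_removal_order(sm, sched, seed=3))
        assert 0.0 < ts.p_c < 1.0
        assert ts.n_remaining == round(ts.p_c * 256)


class TestSnapshots:
    def test_density_endpoints(self):
        spec = LatticeSpec(6, 3)
        sm, sched = assign_shells(spec), removal_probabilities(0.2, 3)
        order = sample_removal_order(sm, sched, seed=5)
        assert snapshot_at_density(order, p=1.0).occupancy.all()
        assert not snapshot_at_density(order, p=0.0).occupancy.any()
        snap = snapshot_at_density(order, p=0.5)
        assert snap.occupancy.sum() == 18

    def test_density_out_of_range_rejected(self):
        spec = LatticeSpec(4, 2)
        order = sample_removal_order(
            assign_shells(spec), removal_probabilities(0.0, 2), seed=1
        )
        with pytest.raises(ValueError):
            snapshot_at_density(order, p=1.2)

    def test_threshold_snapshot_spans_and_breaks_next_step(self):
        spec = LatticeSpec(32, 4)
        sm, sched = assign_shells(spec), removal_probabilities(0.3, 4)
        order = sample_removal_order(sm, sched, seed=11)
        ts = find_critical_density(order)
        snap = snapshot_at_threshold(order)
        # last spanning configuration has n_remaining + 1 occupied sites
        assert snap.occupancy.sum() == ts.n_remaining + 1
        state = label_clusters(snap.occupancy)
        assert spans(state)
        # its largest-cluster mask touches opposite boundaries on some axis
        mask = snap.largest_cluster
        assert mask is not None and mask.sum() <= snap.occupancy.sum()
        assert spans(label_clusters(mask))
        # one more removal destroys spanning
        after = snapshot_at_density(order, p=ts.n_remaining / spec.n_sites)
        assert not spans(label_clusters(after.occupancy))

    def test_gradient_concentrates_occupancy_at_center(self):
        from shellperc import per_shell_occupancy

        spec = LatticeSpec(100, 5)
        sm, sched = assign_shells(spec), removal_probabilities(0.4, 5)
        order = sample_removal_order(sm, sched, seed=2)
        frac = per_shell_occupancy(sm, snapshot_at_density(order, p=0.59).occupancy)
        assert frac[-1] > frac[0]  # innermost denser than periphery
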