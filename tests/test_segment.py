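"""Circular binary segmentation: arc statistic, permutation test, recursion.

The oracles here are deliberately naive: an O(n^2) Python scan over every
arc, and exact enumeration of all orderings for the permutation null.
"""

import itertools
import math

import numpy as np
import pytest

from cnvscreen import (
    SegmentationParams,
    arc_statistic,
    max_arc_statistic,
    normalize_counts,
    permutation_pvalue,
    segment_genome,
    segment_values,
)


def oracle_max_arc(x):
    """Exhaustive scan over every admissible arc (independent oracle).

    An arc and its complement share |T| exactly, so ties are structural:
    the winner is the first arc in (i, j) order within a small relative
    tolerance of the maximum.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    sigma2 = x.var(ddof=1)
    arcs = [
        (i, j, abs(arc_statistic(x, i, j, sigma2)) if sigma2 > 0 else 0.0)
        for i in range(n)
        for j in range(i + 1, min(i + n, n + 1))
    ]
    m = max(t for _, _, t in arcs)
    return next((i, j, t) for i, j, t in arcs if t >= m - 1e-9 * max(1.0, m))


class TestArcStatistic:
    def test_constant_input_is_zero(self):
        x = np.full(8, 3.5)
        assert arc_statistic(x, 2, 5, x.var(ddof=1)) == 0.0

    def test_hand_computed_example(self):
        # x = [0,0,1,1,0,0], arc (2,4): means 1 vs 0, sigma2 = 4/15,
        # T = 1 / sqrt(4/15 * (1/2 + 1/4)) = sqrt(5)
        x = np.array([0, 0, 1, 1, 0, 0], dtype=float)
        t = arc_statistic(x, 2, 4, x.var(ddof=1))
        assert t == pytest.approx(math.sqrt(5))

    def test_sign_flip(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=12)
        s2 = x.var(ddof=1)
        assert arc_statistic(-x, 3, 7, s2) == pytest.approx(-arc_statistic(x, 3, 7, s2))

    @pytest.mark.parametrize("i,j", [(3, 3), (0, 6), (5, 2)])
    def test_degenerate_arcs_raise(self, i, j):
        with pytest.raises(ValueError):
            arc_statistic(np.arange(6.0), i, j, 1.0)


class TestMaxArcStatistic:
    def test_constant_gives_zero(self):
        i, j, t = max_arc_statistic(np.full(6, 2.0))
        assert t == 0.0

    def test_step_block_found(self):
        i, j, t = max_arc_statistic([0, 0, 1, 1, 0, 0])
        assert (i, j) == (2, 4)
        assert t == pytest.approx(math.sqrt(5))

    def test_matches_exhaustive_oracle_on_random_vectors(self):
        rng = np.random.default_rng(42)
        for _ in range(60):
            n = int(rng.integers(2, 51))
            x = rng.normal(size=n)
            oi, oj, ot = oracle_max_arc(x)
            i, j, t = max_arc_statistic(x)
            assert t == pytest.approx(ot, rel=1e-9, abs=1e-9)
            assert (i, j) == (oi, oj)

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            max_arc_statistic([1.0])


def exact_pvalue(x, t_obs):
    """p over all orderings of x (exhaustive enumeration oracle)."""
    n = len(x)
    hits = total = 0
    for perm in itertools.permutations(x):
        total += 1
        _, _, t = max_arc_statistic(np.array(perm))
        if t >= t_obs - 1e-9:
            hits += 1
    return hits / total


class TestPermutationPvalue:
    def test_constant_input_p_is_one(self):
        x = np.full(6, 1.0)
        assert permutation_pvalue(x, 0.0, 500, seed=1) == 1.0

    def test_within_three_binomial_se_of_exact_enumeration(self):
        x = np.array([0.1, -0.2, 1.4, 1.1, 0.2, -0.3, 0.05])
        _, _, t_obs = max_arc_statistic(x)
        p_exact = exact_pvalue(x, t_obs)  # all 5040 orderings
        n_perm = 4000
        p_hat = permutation_pvalue(x, t_obs, n_perm, seed=5)
        se = math.sqrt(p_exact * (1 - p_exact) / n_perm)
        assert abs(p_hat - p_exact) <= 3 * se + 2 / n_perm

    def test_deterministic_for_fixed_seed(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=20)
        _, _, t = max_arc_statistic(x)
        assert permutation_pvalue(x, t, 500, seed=7) == permutation_pvalue(x, t, 500, seed=7)

    def test_never_zero(self):
        x = np.concatenate([np.zeros(10), np.ones(10)]) + np.random.default_rng(1).normal(0, 0.01, 20)
        _, _, t = max_arc_statistic(x)
        assert permutation_pvalue(x, t, 200, seed=3) >= 1 / 201


def params(seed, **kw):
    kw.setdefault("n_perm", 1000)
    return SegmentationParams(seed=seed, **kw)


class TestSegmentValues:
    def test_constant_vector_single_segment(self):
        segs = segment_values(np.full(30, 0.2), params(seed=1))
        assert len(segs) == 1
        assert segs[0][:2] == (0, 30)

    def test_partition_property(self):
        rng = np.random.default_rng(4)
        x = np.concatenate([rng.normal(0, 0.1, 20), rng.normal(-1, 0.1, 15), rng.normal(0, 0.1, 25)])
        segs = segment_values(x, params(seed=2))
        assert segs[0][0] == 0 and segs[-1][1] == len(x)
        for (a, b, *_), (c, d, *_) in zip(segs, segs[1:]):
            assert b == c
        for a, b, mean, _ in segs:
            assert mean == pytest.approx(x[a:b].mean())

    def test_step_function_boundary_recovered(self):
        """The 0 -> -1 step at bin 50 is found within one bin in every seed;
        without post-hoc merge pruning an occasional extra split inside a
        noisy half is tolerated (at most one seed in ten)."""
        exact = 0
        for seed in range(10):
            rng = np.random.default_rng(1000 + seed)
            x = np.concatenate([rng.normal(0, 0.1, 50), rng.normal(-1, 0.1, 50)])
            segs = segment_values(x, params(seed=seed))
            assert any(abs(b - 50) <= 1 for _, b, *_ in segs[:-1])
            if len(segs) == 2:
                exact += 1
        assert exact >= 9

    def test_interior_deletion_geometry(self):
        """A 30-bin block at -1 inside 92 bins at 0 yields three segments
        with the middle mean near -1 (the focal-deletion geometry)."""
        for seed in range(5):
            rng = np.random.default_rng(2000 + seed)
            x = rng.normal(0, 0.1, 92)
            x[31:61] += -1.0
            segs = segment_values(x, params(seed=seed))
            assert len(segs) == 3
            assert abs(segs[1][0] - 31) <= 1 and abs(segs[1][1] - 61) <= 1
            assert segs[1][2] == pytest.approx(-1.0, abs=0.1)

    def test_alpha_monotonicity(self):
        rng = np.random.default_rng(8)
        x = np.concatenate([rng.normal(0, 0.3, 40), rng.normal(-0.6, 0.3, 20), rng.normal(0, 0.3, 40)])
        n_segs = [
            len(segment_values(x, params(seed=3, alpha=a))) for a in (0.2, 0.05, 0.01, 0.001)
        ]
        assert n_segs == sorted(n_segs, reverse=True)

    def test_min_bins_blocks_tiny_pieces(self):
        x = np.zeros(20)
        x[9] = 5.0  # single-bin spike cannot split with min_bins=3
        segs = segment_values(x, params(seed=1, min_bins=3))
        assert len(segs) == 1

    def test_changepoint_recovery_at_depth_75(self):
        """Planted 1.0-log2 steps at Poisson depth 75 are recovered within
        one bin in at least 95% of seeded runs."""
        hits = 0
        n_runs = 20
        for seed in range(n_runs):
            rng = np.random.default_rng(3000 + seed)
            counts = np.concatenate([rng.poisson(75, 60), rng.poisson(37.5, 40)])
            x = np.log2(counts / np.median(counts[:60]))
            segs = segment_values(x, params(seed=seed))
            boundaries = [b for _, b, *_ in segs[:-1]]
            if any(abs(b - 60) <= 1 for b in boundaries):
                hits += 1
        assert hits >= 0.95 * n_runs


class TestSegmentGenome:
    def test_all_zero_track_one_segment_per_chromosome(self, rhino_grid):
        from cnvscreen import CopyRatioTrack

        values = np.zeros(rhino_grid.n_bins)
        values[rhino_grid.default_mask()] = np.nan
        track = CopyRatioTrack(rhino_grid, values)
        result = segment_genome(track, params(seed=1))
        per_chrom = {s.chrom for s in result.segments}
        assert len(result.segments) == len(per_chrom) == 41

    def test_partition_and_mask_exclusion(self, rhino_index, rhino_grid, sim):
        track = normalize_counts(sim(rhino_index, rhino_grid, seed=5))
        result = segment_genome(track, params(seed=6))
        covered = np.zeros(rhino_grid.n_bins, dtype=int)
        for s in result.segments:
            covered[s.first_bin : s.last_bin + 1] += 1
        assert (covered[track.unmasked] == 1).all()
        assert (covered[track.masked] == 0).all()

    def test_whole_chromosome_gain_is_one_elevated_segment(self, rhino_index, rhino_grid, sim):
        from cnvscreen import CnvSpec

        cnvs = [
            CnvSpec("chr2", 0, rhino_index["chr2"].length, 1.5),
            CnvSpec("chr17", 0, rhino_index["chr17"].length, 1.5),
        ]
        track = normalize_counts(sim(rhino_index, rhino_grid, seed=12, cnvs=cnvs))
        result = segment_genome(track, params(seed=13))
        for chrom in ("chr2", "chr17"):
            segs = result.for_chrom(chrom)
            assert len(segs) == 1
            assert segs[0].mean_value == pytest.approx(np.log2(1.5), abs=0.1)

    def test_segment_fields_consistent(self, rhino_index, rhino_grid, sim):
        track = normalize_counts(sim(rhino_index, rhino_grid, seed=20))
        result = segment_genome(track, params(seed=21))
        for s in result.segments:
            assert s.n_bins == s.last_bin - s.first_bin + 1
            assert s.start == rhino_grid.starts[s.first_bin]
            assert s.end == rhino_grid.ends[s.last_bin]


def test_params_validation():
    with pytest.raises(ValueError):
        SegmentationParams(seed=1, alpha=0)
    with pytest.raises(ValueError):
        SegmentationParams(seed=1, n_perm=10)
    with pytest.raises(ValueError):
        SegmentationParams(seed=1, min_bins=0)
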