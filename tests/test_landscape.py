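"""Quench dynamics, basin decomposition, configurational entropy, clustering."""

import numpy as np
import pytest

import repeatscape as rs
from repeatscape.entropy import enumerate_states
from repeatscape.landscape import clustering_leaf_order, exhaustive_local_minima

from conftest import random_small_model


def two_basin_toy():
    """2L=4, q=2 block-ferromagnet with two planted ground states.

    Strong positive J on every pair for aligned symbols makes all-0 and all-1
    the two ground states; zero fields keep them degenerate.
    """
    n, q = 4, 2
    J = np.zeros((n, n, q, q))
    mask = rs.make_mask_full(n)
    for i in range(n):
        for j in range(i + 1, n):
            blk = np.array([[1.0, -1.0], [-1.0, 1.0]])
            J[i, j] = blk
            J[j, i] = blk.T
    return rs.PottsModel(np.zeros((n, q)), J, np.zeros(3), mask)


class TestQuench:
    def test_independent_model_reaches_consensus_from_any_start(self, planted_alignment):
        obs = rs.compute_observables(planted_alignment)
        m = rs.independent_model(obs, pseudocount=1e-6)
        consensus = rs.consensus_sequence(obs)
        rng = np.random.default_rng(21)
        for k in range(10):
            start = rng.integers(0, 3, m.n_sites).astype(np.int8)
            out = rs.quench(m, start, seed=k)
            np.testing.assert_array_equal(out.minimum, consensus)

    def test_start_at_minimum_returns_unchanged(self, planted_alignment):
        obs = rs.compute_observables(planted_alignment)
        m = rs.independent_model(obs, pseudocount=1e-6)
        consensus = rs.consensus_sequence(obs)
        out = rs.quench(m, consensus, seed=0)
        assert out.n_steps == 0
        np.testing.assert_array_equal(out.minimum, consensus)

    def test_frustrated_toy_reaches_planted_ground_states(self):
        m = two_basin_toy()
        states = enumerate_states(4, 2)
        hits = set()
        for s, start in enumerate(states):
            out = rs.quench(m, start, seed=s)
            key = tuple(out.minimum.tolist())
            assert key in {(0, 0, 0, 0), (1, 1, 1, 1)}
            hits.add(key)
        assert hits == {(0, 0, 0, 0), (1, 1, 1, 1)}

    def test_quench_ignores_lambda(self):
        """Overlap multipliers are excluded from quench energetics."""
        m = two_basin_toy()
        biased = rs.PottsModel(m.h, m.J.copy(), np.array([0.0, 5.0, -5.0]), m.mask)
        for s, start in enumerate(enumerate_states(4, 2)):
            a = rs.quench(m, start, seed=s).minimum
            b = rs.quench(biased, start, seed=s).minimum
            np.testing.assert_array_equal(a, b)

    def test_endpoints_are_true_local_minima(self):
        """Quench endpoints all pass the exhaustive neighbor check (oracle)."""
        rng = np.random.default_rng(22)
        for _ in range(3):
            m = random_small_model(rng, L=3, q=3, density=0.5, coupling_scale=1.2,
                                   with_lambda=False)
            true_minima = {tuple(s.tolist()) for s in exhaustive_local_minima(m)}
            starts = rng.integers(0, 3, size=(30, 6)).astype(np.int8)
            for k, start in enumerate(starts):
                out = rs.quench(m, start, seed=k)
                assert tuple(out.minimum.tolist()) in true_minima

    def test_energy_decreases_strictly(self):
        rng = np.random.default_rng(23)
        m = random_small_model(rng, L=3, q=3, density=0.6, with_lambda=False)
        m0 = m.with_lambda_zero()
        start = rng.integers(0, 3, 6).astype(np.int8)
        out = rs.quench(m, start, seed=1)
        assert m0.energy(out.minimum) <= m0.energy(start)

    def test_without_doubles_pair_minima_factorize(self):
        """On a model with independent repeats, pair minima are products of
        single-repeat minima."""
        rng = np.random.default_rng(24)
        L, q = 2, 3
        n = 2 * L
        h_half = rng.normal(0, 0.5, (L, q))
        J = np.zeros((n, n, q, q))
        mask = rs.make_mask_intra_repeat(n)
        blk = rng.normal(0, 1.0, (q, q))
        for (i, j) in [(0, 1), (L, L + 1)]:
            J[i, j] = blk
            J[j, i] = blk.T
        m = rs.PottsModel(np.vstack([h_half, h_half]), J, np.zeros(L + 1), mask)
        minima = exhaustive_local_minima(m, allow_paired_double=False)
        halves = {tuple(s[:L].tolist()) for s in minima} | {tuple(s[L:].tolist()) for s in minima}
        combos = {tuple(list(a) + list(b)) for a in halves for b in halves}
        assert {tuple(s.tolist()) for s in minima} == combos


class TestBasins:
    def test_single_basin_zero_conf_entropy(self, planted_alignment):
        obs = rs.compute_observables(planted_alignment)
        m = rs.independent_model(obs, pseudocount=1e-6)
        part = rs.basin_decomposition(m, planted_alignment.sequences[:100], seed=0)
        assert len(part.minima) == 1
        assert part.S_conf_bits == pytest.approx(0.0)

    def test_two_equal_basins_one_bit(self):
        """Equal-weight starts in the two ground states give S_conf = 1 bit."""
        m = two_basin_toy()
        starts = np.array([[0, 0, 0, 0], [1, 1, 1, 1]], dtype=np.int8)
        part = rs.basin_decomposition(m, starts, seed=0)
        assert len(part.minima) == 2
        assert part.S_conf_bits == pytest.approx(1.0, abs=1e-12)
        # from all 16 states: still exactly the two planted basins
        full = rs.basin_decomposition(m, enumerate_states(4, 2), seed=0)
        assert len(full.minima) == 2

    def test_four_equal_basins_two_bits(self):
        """Two independent two-basin repeat blocks give 4 product minima;
        equal occupation yields S_conf = 2 bits."""
        n, q = 4, 2
        J = np.zeros((n, n, q, q))
        mask = rs.make_mask_intra_repeat(n)
        blk = np.array([[1.0, -1.0], [-1.0, 1.0]])
        for (i, j) in [(0, 1), (2, 3)]:
            J[i, j] = blk
            J[j, i] = blk.T
        m = rs.PottsModel(np.zeros((n, q)), J, np.zeros(3), mask)
        starts = np.array([[0, 0, 0, 0], [0, 0, 1, 1], [1, 1, 0, 0], [1, 1, 1, 1]],
                          dtype=np.int8)
        part = rs.basin_decomposition(m, starts, seed=0, allow_paired_double=False)
        assert len(part.minima) == 4
        assert part.S_conf_bits == pytest.approx(2.0, abs=1e-12)

    def test_weighted_sizes_and_ordering(self):
        m = two_basin_toy()
        starts = np.array([[0, 0, 0, 0], [1, 1, 1, 1], [1, 1, 1, 1]], dtype=np.int8)
        w = np.array([1.0, 0.25, 0.25])
        part = rs.basin_decomposition(m, starts, start_weights=w, seed=0)
        assert part.sizes.tolist() == [1.0, 0.5]  # largest basin first
        np.testing.assert_allclose(part.P_b, [2 / 3, 1 / 3])
        assert part.assignment.tolist() == [0, 1, 1]


class TestMinimaClustering:
    def _partition(self):
        minima = np.array([[0, 0, 0, 0], [1, 1, 1, 1], [0, 0, 1, 1]], dtype=np.int8)
        sizes = np.array([0.45, 0.45, 0.10])
        return rs.BasinPartition(
            minima=minima, energies=np.array([-3.0, -2.9, -1.0]),
            assignment=np.array([0, 1, 2]), sizes=sizes, P_b=sizes / sizes.sum(),
            S_conf_bits=1.37,
        )

    def test_coverage_selects_largest_basins(self):
        D, Z, sel = rs.minima_clustering(self._partition(), coverage=0.9)
        assert sel.tolist() == [0, 1]
        assert D.shape == (2, 2) and D[0, 1] == 4  # Hamming distance in sites

    def test_average_linkage_definition(self):
        """Cluster distance = mean pairwise Hamming distance between members."""
        part = self._partition()
        D, Z, sel = rs.minima_clustering(part, coverage=1.0)
        assert len(sel) == 3
        # distances: d(0,1)=4, d(0,2)=2, d(1,2)=2; closest pair merges at 2,
        # the singleton then joins at the average (4+2)/2 = 3
        assert D[0, 1] == 4 and D[0, 2] == 2 and D[1, 2] == 2
        assert Z[0, 2] == 2
        assert Z[1, 2] == pytest.approx(3.0)
        order = clustering_leaf_order(Z)
        assert sorted(order.tolist()) == [0, 1, 2]

    def test_single_minimum_trivial_output(self):
        part = self._partition()
        part.P_b = np.array([1.0, 0.0, 0.0])
        D, Z, sel = rs.minima_clustering(part, coverage=0.9)
        assert len(sel) == 1 and Z is None


class TestConsensus:
    def test_consensus_of_onehot_observables(self):
        mat = np.tile(np.array([2, 0, 2, 0], dtype=np.int8), (5, 1))
        obs = rs.compute_observables(rs.Alignment(mat, list("abcde"), 2, q=3))
        np.testing.assert_array_equal(rs.consensus_sequence(obs), [2, 0, 2, 0])

    def test_independent_model_consensus_is_global_minimum(self, planted_alignment):
        obs = rs.compute_observables(planted_alignment)
        m = rs.independent_model(obs, pseudocount=1e-6)
        states = enumerate_states(m.n_sites, m.q)
        assert rs.consensus_energy(m, obs) == pytest.approx(m.energies(states).min())

    def test_frustrated_consensus_above_global_minimum(self):
        """With frustration the consensus can sit above the true minimum."""
        rng = np.random.default_rng(25)
        found = False
        for _ in range(5):
            m = random_small_model(rng, L=3, q=3, density=0.6, coupling_scale=1.5,
                                   with_lambda=False)
            aln = rs.make_planted_alignment(m, 2000, seed=int(rng.integers(2**31)))
            obs = rs.compute_observables(aln)
            states = enumerate_states(m.n_sites, m.q)
            gmin = m.with_lambda_zero().energies(states).min()
            ce = rs.consensus_energy(m, obs)
            assert ce >= gmin - 1e-9
            if ce > gmin + 1e-9:
                found = True
        assert found
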