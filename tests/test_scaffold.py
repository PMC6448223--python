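"""QT clustering semantics, scaffold selection, and reports."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from scaffoldkit import (
    AtomSelection,
    ClusterAssignment,
    DistanceMatrix,
    Trajectory,
    cluster_report,
    cutoff_sweep,
    make_toy_protein,
    pairwise_rmsd_matrix,
    qt_cluster,
    select_scaffolds,
)
from scaffoldkit.synth import SynthTrajectorySpec, make_synthetic_trajectory

from oracles import brute_force_qt


def _random_distance_matrix(rng: np.random.Generator, n: int) -> np.ndarray:
    d = rng.uniform(0, 2, size=(n, n))
    d = (d + d.T) / 2
    np.fill_diagonal(d, 0.0)
    return d


class TestPairwiseRmsdMatrix:
    def test_identical_frames_zero_matrix(self, toy):
        t = Trajectory(topology=toy, frames=[toy.coords] * 3)
        m = pairwise_rmsd_matrix(t, AtomSelection())
        np.testing.assert_allclose(m.d, 0.0, atol=1e-10)

    def test_uniform_translation_closed_form(self, toy):
        t = Trajectory(topology=toy, frames=[toy.coords, toy.coords + [2.0, 0, 0]])
        m = pairwise_rmsd_matrix(t, AtomSelection())
        assert m.d[0, 1] == pytest.approx(2.0, abs=1e-9)

    def test_matches_double_loop_oracle(self, toy, rng):
        frames = [toy.coords + rng.normal(scale=0.5, size=(toy.n_atoms, 3))
                  for _ in range(6)]
        t = Trajectory(topology=toy, frames=frames)
        sel = AtomSelection(resids=frozenset({2, 5, 9}))
        m = pairwise_rmsd_matrix(t, sel)
        from scaffoldkit.structio import resolve_selection
        from scaffoldkit.geometry import rmsd_between

        idx = resolve_selection(sel, toy)
        for i in range(6):
            for j in range(6):
                expected = rmsd_between(frames[i][idx], frames[j][idx])
                assert m.d[i, j] == pytest.approx(expected, abs=1e-9)


class TestQtCluster:
    def test_all_within_cutoff_single_cluster(self):
        d = _random_distance_matrix(np.random.default_rng(0), 4) * 0.1
        a = qt_cluster(DistanceMatrix(d), cutoff=0.7)
        assert a.populations == [4]
        assert a.n_unclustered == 0
        assert set(a.labels) == {1}

    def test_two_planted_blobs_at_paper_cutoff(self, rng):
        # Two tight blobs: intra ~0.1 A, inter ~5 A; 0.7 A threshold splits them.
        n1, n2 = 7, 5
        d = np.zeros((n1 + n2, n1 + n2))
        d[:n1, :n1] = 0.1
        d[n1:, n1:] = 0.1
        d[:n1, n1:] = 5.0
        d[n1:, :n1] = 5.0
        np.fill_diagonal(d, 0.0)
        a = qt_cluster(DistanceMatrix(d), cutoff=0.7)
        assert a.populations == [7, 5]
        assert list(a.labels[:n1]) == [1] * n1
        assert list(a.labels[n1:]) == [2] * n2

    def test_hand_built_tie_matrix_matches_exhaustive_simulation(self):
        # Frames 0-2 and 3-5 form two triangles of equal size; frame 6 is
        # isolated.  Neighbor counts tie (3 vs 3): founder must be frame 0.
        inf = 9.0
        d = np.full((7, 7), inf)
        for grp in ((0, 1, 2), (3, 4, 5)):
            for i in grp:
                for j in grp:
                    d[i, j] = 0.2 if i != j else 0.0
        np.fill_diagonal(d, 0.0)
        a = qt_cluster(DistanceMatrix(d), cutoff=0.5, max_clusters=5)
        exp_labels, exp_pops, exp_founders = brute_force_qt(d, 0.5, 5)
        assert a.founders[0] == 0  # lowest-index tie-break
        assert list(a.labels) == list(exp_labels)
        assert a.populations == exp_pops
        assert a.founders == exp_founders

    @given(seed=st.integers(0, 2**31 - 1), n=st.integers(2, 8))
    @settings(max_examples=60, deadline=None)
    def test_equivalent_to_brute_force_for_small_n(self, seed, n):
        rng = np.random.default_rng(seed)
        d = _random_distance_matrix(rng, n)
        cutoff = float(rng.uniform(0.1, 1.5))
        a = qt_cluster(DistanceMatrix(d), cutoff=cutoff, max_clusters=5)
        exp_labels, exp_pops, exp_founders = brute_force_qt(d, cutoff, 5)
        assert list(a.labels) == list(exp_labels)
        assert a.populations == exp_pops
        assert a.founders == exp_founders

    @given(seed=st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_cluster1_population_monotone_in_cutoff(self, seed):
        rng = np.random.default_rng(seed)
        d = _random_distance_matrix(rng, 12)
        pops = [
            qt_cluster(DistanceMatrix(d), cutoff=c).populations[0]
            for c in (0.2, 0.5, 0.8, 1.2, 1.8)
        ]
        assert all(a <= b for a, b in zip(pops, pops[1:]))

    def test_populations_nonincreasing_and_medoid_optimal(self, rng):
        d = _random_distance_matrix(rng, 20)
        a = qt_cluster(DistanceMatrix(d), cutoff=0.8, max_clusters=5)
        assert all(
            p1 >= p2 for p1, p2 in zip(a.populations, a.populations[1:])
        )
        for rank in range(1, a.n_clusters + 1):
            members = a.members(rank)
            medoid = a.medoids[rank - 1]
            assert medoid in members
            sums = d[np.ix_(members, members)].sum(axis=1)
            assert d[medoid, members].sum() <= sums.min() + 1e-12

    def test_members_within_cutoff_of_founder(self, rng):
        d = _random_distance_matrix(rng, 15)
        a = qt_cluster(DistanceMatrix(d), cutoff=0.6)
        for rank in range(1, a.n_clusters + 1):
            founder = a.founders[rank - 1]
            assert np.all(d[founder, a.members(rank)] <= 0.6)

    def test_invalid_matrices_rejected(self):
        bad = np.array([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            qt_cluster(bad, cutoff=0.5)
        neg = np.array([[0.0, -1.0], [-1.0, 0.0]])
        with pytest.raises(ValueError):
            qt_cluster(neg, cutoff=0.5)
        with pytest.raises(ValueError):
            qt_cluster(np.zeros((3, 3)), cutoff=-0.1)


def _assignment(populations, n, cutoff=0.7):
    labels = np.zeros(n, dtype=int)
    start = 0
    medoids = []
    for rank, p in enumerate(populations, start=1):
        labels[start:start + p] = rank
        medoids.append(start)
        start += p
    return ClusterAssignment(
        labels=labels, populations=list(populations), medoids=medoids,
        founders=medoids, cutoff=cutoff, max_clusters=5,
    )


class TestSelectScaffolds:
    def _trajectory(self, n, toy):
        rng = np.random.default_rng(5)
        frames = [toy.coords + rng.normal(scale=0.1, size=(toy.n_atoms, 3))
                  for _ in range(n)]
        return Trajectory(topology=toy, frames=frames)

    def test_ten_percent_threshold_arithmetic(self, toy):
        a = _assignment([60, 30, 8, 2], n=100)
        t = self._trajectory(100, toy)
        out = select_scaffolds(a, t, min_occupancy=0.10, variant_label="95R")
        assert len(out) == 2
        assert [s.rank for s in out.scaffolds] == [1, 2]
        assert out.labels() == ["95R-1", "95R-2"]
        assert out.scaffolds[0].occupancy == pytest.approx(0.60)

    def test_single_full_cluster(self, toy):
        a = _assignment([100], n=100)
        out = select_scaffolds(a, self._trajectory(100, toy), variant_label="WT")
        assert len(out) == 1
        assert out.scaffolds[0].occupancy == pytest.approx(1.0)

    def test_zero_qualifying_warns_and_returns_empty(self, toy):
        a = _assignment([5, 4, 3], n=100)  # 88 unclustered
        with pytest.warns(UserWarning, match="no scaffolds"):
            out = select_scaffolds(a, self._trajectory(100, toy))
        assert len(out) == 0

    def test_count_monotone_in_threshold(self, toy, rng):
        t = self._trajectory(50, toy)
        for _ in range(10):
            pops = sorted(rng.integers(1, 20, size=4), reverse=True)
            total = sum(pops) + int(rng.integers(0, 10))
            if total > 50:
                continue
            a = _assignment(pops, n=50)
            import warnings as _warnings

            with _warnings.catch_warnings():
                _warnings.simplefilter("ignore", UserWarning)
                counts = [
                    len(select_scaffolds(a, t, min_occupancy=f))
                    for f in (0.05, 0.10, 0.20, 0.40)
                ]
            assert all(c1 >= c2 for c1, c2 in zip(counts, counts[1:]))

    def test_scaffold_is_medoid_frame(self, toy):
        base = toy
        spec = SynthTrajectorySpec(
            base=base, k=3, weights=(0.5, 0.3, 0.2),
            displacement_resids=frozenset(range(4, 9)),
            center_separation=2.0, sigma=0.1, n_frames=120, seed=11,
        )
        traj, truth = make_synthetic_trajectory(spec)
        sel = AtomSelection(resids=frozenset(range(4, 9)))
        m = pairwise_rmsd_matrix(traj, sel)
        a = qt_cluster(m, cutoff=0.7)
        out = select_scaffolds(a, traj, variant_label="SYN")
        assert len(out) == 3
        # Each scaffold sits within noise of its planted center.
        from scaffoldkit.geometry import rmsd_between

        idx = truth.displaced_atom_indices
        for s in out.scaffolds:
            true_c = truth.centers[truth.labels[s.frame_index]]
            r = rmsd_between(s.structure.coords[idx], true_c[idx])
            assert r <= 4 * spec.sigma


class TestClusterReport:
    def test_unclustered_row_zero(self):
        df = cluster_report(_assignment([60, 30, 8, 2], n=100), "WT")
        uncl = df[df.cluster == "Unclustered"]
        assert int(uncl.population.iloc[0]) == 0

    def test_unclustered_row_counts_leftovers(self):
        df = cluster_report(_assignment([60, 30], n=100), "WT")
        uncl = df[df.cluster == "Unclustered"]
        assert int(uncl.population.iloc[0]) == 10

    @given(seed=st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_fractions_conserve(self, seed):
        rng = np.random.default_rng(seed)
        d = _random_distance_matrix(rng, 25)
        a = qt_cluster(DistanceMatrix(d), cutoff=float(rng.uniform(0.2, 1.0)))
        df = cluster_report(a, "X")
        assert df.fraction.sum() == pytest.approx(1.0, abs=1e-9)
        assert df.population.sum() == 25


class TestCutoffSweep:
    def test_grid_shape_and_monotone_top_population(self, toy):
        spec = SynthTrajectorySpec(
            base=toy, k=2, weights=(0.6, 0.4),
            displacement_resids=frozenset(range(4, 9)),
            center_separation=2.0, sigma=0.1, n_frames=60, seed=3,
        )
        traj, _ = make_synthetic_trajectory(spec)
        m = pairwise_rmsd_matrix(traj, AtomSelection(resids=frozenset(range(4, 9))))
        grid = [0.3, 0.7, 1.5, 3.0]
        table = cutoff_sweep(m, grid)
        assert list(table.cutoff) == grid
        assert table.top_population.is_monotonic_increasing
        # At a cutoff above the separation everything merges.
        assert table.n_clusters.iloc[-1] == 1
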