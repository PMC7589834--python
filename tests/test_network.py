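"""Residue interaction networks: BC, shortest paths, delta profiles."""

import itertools

import numpy as np
import pandas as pd
import pytest

from vardyn.errors import ComparisonError
from vardyn.network import (
    DeltaProfile, betweenness_profile, build_rin, delta_profile,
    residue_usage, shortest_path_profile,
)
from vardyn.structure import select_atoms
from vardyn.synthetic import build_ca_chain, build_ideal_helix

from conftest import make_trajectory


def _point_trajectory(points, residue_indices=None):
    points = np.asarray(points, dtype=float)
    n = len(points)
    return make_trajectory(
        points, names=["CA"] * n,
        elements=["C"] * n,
        residue_indices=residue_indices or list(range(1, n + 1)),
    )


# ---------------------------------------------------------------------------
# independent oracles (pure python, no networkx)
# ---------------------------------------------------------------------------

def _all_shortest_paths(adj, s, t):
    """All shortest s-t paths by breadth-first layer expansion."""
    n = len(adj)
    if s == t:
        return 0, [[s]]
    dist = {s: 0}
    frontier = [s]
    parents = {i: [] for i in range(n)}
    while frontier and t not in dist:
        nxt = []
        for u in frontier:
            for v in range(n):
                if adj[u][v]:
                    if v not in dist:
                        dist[v] = dist[u] + 1
                        nxt.append(v)
                    if dist.get(v) == dist[u] + 1:
                        parents[v].append(u)
        frontier = nxt
    if t not in dist:
        return None, []
    paths = []

    def back(v, acc):
        if v == s:
            paths.append([s] + list(reversed(acc)))
            return
        for p in parents[v]:
            back(p, acc + [v])

    back(t, [])
    return dist[t], paths


def oracle_betweenness(adj):
    """Normalised BC by exhaustive shortest-path enumeration."""
    n = len(adj)
    bc = [0.0] * n
    for s, t in itertools.combinations(range(n), 2):
        d, paths = _all_shortest_paths(adj, s, t)
        if not paths:
            continue
        for v in range(n):
            if v in (s, t):
                continue
            through = sum(1 for p in paths if v in p)
            bc[v] += through / len(paths)
    norm = (n - 1) * (n - 2) / 2 if n > 2 else 1.0
    return [b / norm for b in bc]


def oracle_avg_path(adj):
    """L_i over reachable partners via hand-rolled Floyd-Warshall."""
    n = len(adj)
    inf = float("inf")
    d = [[0 if i == j else (1 if adj[i][j] else inf) for j in range(n)]
         for i in range(n)]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i][k] + d[k][j] < d[i][j]:
                    d[i][j] = d[i][k] + d[k][j]
    out = []
    for i in range(n):
        reach = [d[i][j] for j in range(n) if j != i and d[i][j] < inf]
        out.append(sum(reach) / len(reach) if reach else np.nan)
    return out


def _adjacency(graph, nodes):
    idx = {node: k for k, node in enumerate(nodes)}
    adj = [[0] * len(nodes) for _ in nodes]
    for u, v in graph.edges:
        adj[idx[u]][idx[v]] = adj[idx[v]][idx[u]] = 1
    return adj


class TestBuildRin:
    def test_collinear_chain_is_path_graph(self):
        traj = _point_trajectory([[0.0, 0, 0], [5.0, 0, 0], [10.0, 0, 0]])
        rin = build_rin(traj, cutoff=6.7, selection="CA")
        assert sorted(rin.edges) == [(1, 2), (2, 3)]

    def test_no_edges_beyond_cutoff(self):
        traj = _point_trajectory([[0.0, 0, 0], [7.0, 0, 0], [14.0, 0, 0]])
        rin = build_rin(traj, cutoff=6.7, selection="CA")
        assert rin.edges == []

    def test_cutoff_boundary_is_inclusive(self):
        traj = _point_trajectory([[0.0, 0, 0], [6.7, 0, 0]])
        rin = build_rin(traj, cutoff=6.7, selection="CA")
        assert rin.edges == [(1, 2)]

    def test_helix_connects_first_three_neighbours(self):
        helix = build_ideal_helix(12)
        ca = select_atoms(helix, "CA")
        rin = build_rin(ca, cutoff=6.7, selection="CA")
        labels = ca.topology.residue_index_labels
        for i in labels:
            for off in (1, 2, 3):
                if i + off <= labels[-1]:
                    assert rin.graph.has_edge(int(i), int(i + off))

    def test_increasing_cutoff_never_removes_edges(self):
        rng = np.random.default_rng(9)
        traj = _point_trajectory(6.0 * rng.standard_normal((8, 3)))
        degrees = []
        for cutoff in (3.0, 5.0, 6.7, 9.0, 12.0):
            rin = build_rin(traj, cutoff=cutoff, selection="CA")
            degrees.append(
                np.array([rin.graph.degree(n) for n in sorted(rin.nodes)])
            )
        for a, b in zip(degrees, degrees[1:]):
            assert np.all(b >= a)


class TestCentrality:
    def test_path_graph_closed_form(self):
        traj = _point_trajectory([[0.0, 0, 0], [5.0, 0, 0], [10.0, 0, 0]])
        bc = betweenness_profile(traj, selection="CA").values
        assert bc.tolist() == [0.0, 1.0, 0.0]

    def test_complete_graph_has_zero_betweenness(self):
        traj = _point_trajectory(2.0 * np.random.default_rng(0).random((5, 3)))
        bc = betweenness_profile(traj, selection="CA").values
        assert np.allclose(bc, 0.0)

    def test_star_graph_center_is_one(self):
        pts = [[0.0, 0, 0], [5.0, 0, 0], [-5.0, 0, 0], [0.0, 5, 0],
               [0.0, -5, 0]]
        traj = _point_trajectory(pts)
        bc = betweenness_profile(traj, selection="CA").values
        assert bc.loc[1] == pytest.approx(1.0)
        assert np.allclose(bc.loc[2:], 0.0)

    def test_path_graph_average_path_lengths(self):
        traj = _point_trajectory([[0.0, 0, 0], [5.0, 0, 0], [10.0, 0, 0]])
        pl = shortest_path_profile(traj, selection="CA")
        assert pl.values.tolist() == [1.5, 1.0, 1.5]
        assert not pl.had_unreachable.any()

    def test_disconnected_dimers_flagged(self):
        traj = _point_trajectory(
            [[0.0, 0, 0], [3.0, 0, 0], [50.0, 0, 0], [53.0, 0, 0]]
        )
        pl = shortest_path_profile(traj, selection="CA")
        assert np.allclose(pl.values, 1.0)
        assert pl.had_unreachable.all()

    def test_matches_enumeration_oracles_on_random_graphs(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            n = int(rng.integers(3, 9))
            pts = 7.0 * rng.random((n, 3))
            traj = _point_trajectory(pts)
            rin = build_rin(traj, cutoff=6.7, selection="CA")
            nodes = sorted(rin.nodes)
            adj = _adjacency(rin, nodes)
            bc = betweenness_profile(traj, selection="CA").values
            assert np.allclose(bc.to_numpy(), oracle_betweenness(adj),
                               atol=1e-12)
            pl = shortest_path_profile(traj, selection="CA").values
            expected = oracle_avg_path(adj)
            assert np.allclose(pl.to_numpy(), expected, atol=1e-12,
                               equal_nan=True)

    def test_betweenness_invariant_under_relabeling(self):
        pts = 7.0 * np.random.default_rng(10).random((7, 3))
        t1 = _point_trajectory(pts)
        t2 = _point_trajectory(pts, residue_indices=list(range(101, 108)))
        bc1 = betweenness_profile(t1, selection="CA").values
        bc2 = betweenness_profile(t2, selection="CA").values
        assert np.allclose(bc1.to_numpy(), bc2.to_numpy())


class TestDeltaProfiles:
    def test_profile_minus_itself_is_zero(self):
        s = pd.Series([0.1, 0.4, 0.2], index=[1, 2, 3])
        d = delta_profile(s, s)
        assert np.allclose(d.values, 0.0)

    def test_disjoint_seeds_of_same_generator_agree(self):
        from vardyn.synthetic import HarmonicEnsembleSpec, sample_harmonic_ensemble

        ref = build_ca_chain(10, spacing=5.0)
        cov = 0.05 * np.eye(10)
        bcs = []
        for seed in (1, 2):
            traj = sample_harmonic_ensemble(
                HarmonicEnsembleSpec(ref, cov, 400, seed=seed)
            )
            bcs.append(betweenness_profile(traj, selection="CA").values)
        d = delta_profile(bcs[0], bcs[1])
        assert np.abs(d.values).max() < 0.1

    def test_contact_loss_localises_delta(self):
        # path graph 1-2-3-4 vs the same with the 2-3 contact broken
        a = _point_trajectory([[0.0, 0, 0], [5.0, 0, 0], [10.0, 0, 0],
                               [15.0, 0, 0]])
        b = _point_trajectory([[0.0, 0, 0], [5.0, 0, 0], [12.5, 0, 0],
                               [17.5, 0, 0]])
        bc_a = betweenness_profile(a, selection="CA").values
        bc_b = betweenness_profile(b, selection="CA").values
        d = delta_profile(bc_a, bc_b).values
        assert d.loc[2] > 0 and d.loc[3] > 0
        assert d.loc[1] == 0 and d.loc[4] == 0

    def test_usage_antisymmetric(self):
        w = DeltaProfile(pd.Series([0.2, 0.1], index=[1, 2]), "vs_first_frame")
        v = DeltaProfile(pd.Series([0.05, 0.3], index=[1, 2]), "vs_first_frame")
        fwd = residue_usage(w, v).values
        rev = residue_usage(v, w).values
        assert np.allclose(fwd, -rev)

    def test_empty_intersection_rejected(self):
        with pytest.raises(ComparisonError):
            delta_profile(pd.Series([1.0], index=[1]),
                          pd.Series([1.0], index=[2]))
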