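"""Shared fixtures and independent oracles for the test suite.

The oracles here (brute-force clique percolation, Monte-Carlo random walks,
exhaustive decoy enumeration) are deliberately written from first principles,
independent of the library code paths they check.
"""

from __future__ import annotations

from itertools import combinations

import networkx as nx
import numpy as np
import pytest

from allosteer import enm
from allosteer.structure_io import CoarseStructure, Residue


# ---------------------------------------------------------------------------
# Small structure builders
# ---------------------------------------------------------------------------

def structure_from_coords(coords, types=None, chain="A") -> CoarseStructure:
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    types = types or ["GLY"] * n
    residues = [Residue(chain_id=chain, author_number=i + 1, serial_index=i,
                        residue_type=types[i], ca_coord=coords[i])
                for i in range(n)]
    return CoarseStructure(residues=residues, label="test")


def network_from_graph(graph: nx.Graph) -> enm.ElasticNetwork:
    """Elastic network directly from a graph (bypasses geometry)."""
    nodes = sorted(graph.nodes)
    index = {u: k for k, u in enumerate(nodes)}
    n = len(nodes)
    kirchhoff = np.zeros((n, n))
    for u, v in graph.edges:
        i, j = index[u], index[v]
        kirchhoff[i, j] = kirchhoff[j, i] = -1.0
    np.fill_diagonal(kirchhoff, -kirchhoff.sum(axis=1))
    return enm.ElasticNetwork(kirchhoff=kirchhoff, cutoff_rc=np.nan)


def random_connected_graph(rng: np.random.Generator, n_nodes: int,
                           p_edge: float = 0.3) -> nx.Graph:
    """Erdős–Rényi graph resampled until connected."""
    while True:
        graph = nx.Graph()
        graph.add_nodes_from(range(n_nodes))
        for i, j in combinations(range(n_nodes), 2):
            if rng.random() < p_edge:
                graph.add_edge(i, j)
        if nx.is_connected(graph):
            return graph


def random_graph(rng: np.random.Generator, n_nodes: int,
                 p_edge: float) -> nx.Graph:
    graph = nx.Graph()
    graph.add_nodes_from(range(n_nodes))
    for i, j in combinations(range(n_nodes), 2):
        if rng.random() < p_edge:
            graph.add_edge(i, j)
    return graph


# ---------------------------------------------------------------------------
# Clique-percolation oracle: exhaustive enumeration + transitive closure
# ---------------------------------------------------------------------------

def brute_force_communities(graph: nx.Graph, k: int, overlap_rule: str):
    """All k-cliques by subset enumeration; communities by closure.

    Returns (set of frozenset cliques, set of frozenset communities).
    """
    cliques = []
    for nodes in combinations(sorted(graph.nodes), k):
        if all(graph.has_edge(a, b) for a, b in combinations(nodes, 2)):
            cliques.append(frozenset(nodes))
    threshold = k - 1 if overlap_rule == "k-1" else k - 2
    parent = list(range(len(cliques)))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in combinations(range(len(cliques)), 2):
        if len(cliques[a] & cliques[b]) >= threshold:
            parent[find(a)] = find(b)
    groups: dict[int, set] = {}
    for idx, clique in enumerate(cliques):
        groups.setdefault(find(idx), set()).update(clique)
    return set(cliques), {frozenset(g) for g in groups.values()}


# ---------------------------------------------------------------------------
# Monte-Carlo commute-time oracle
# ---------------------------------------------------------------------------

def mc_commute_time(graph: nx.Graph, source: int, target: int,
                    n_walks: int, rng: np.random.Generator,
                    max_steps: int = 100_000):
    """Empirical round-trip step count of a uniform random walk.

    Returns (mean, standard error) over ``n_walks`` independent walks
    source → target → source.
    """
    nodes = sorted(graph.nodes)
    index = {u: k for k, u in enumerate(nodes)}
    neighbors = [np.array([index[v] for v in graph.neighbors(u)])
                 for u in nodes]
    position = np.full(n_walks, index[source])
    phase = np.zeros(n_walks, dtype=int)  # 0: to target, 1: back to source
    steps = np.zeros(n_walks, dtype=np.int64)
    active = np.ones(n_walks, dtype=bool)
    src, tgt = index[source], index[target]
    for _ in range(max_steps):
        if not active.any():
            break
        new_position = position.copy()
        for node in np.unique(position[active]):
            mask = active & (position == node)
            count = int(mask.sum())
            new_position[mask] = neighbors[node][
                rng.integers(0, len(neighbors[node]), size=count)]
        position = new_position
        steps[active] += 1
        arrived_target = active & (phase == 0) & (position == tgt)
        phase[arrived_target] = 1
        arrived_home = active & (phase == 1) & (position == src)
        active[arrived_home] = False
    assert not active.any(), "random walks did not all finish"
    return float(steps.mean()), float(steps.std(ddof=1) / np.sqrt(n_walks))


# ---------------------------------------------------------------------------
# Exhaustive decoy-statistics oracle
# ---------------------------------------------------------------------------

def enumerate_decoy_stats(potential, types, type_probs, bin_edges, bin_probs):
    """Exact decoy mean/sd for a piecewise-constant (step-well) potential.

    Enumerates every (type_a, type_b, distance bin) outcome; the energy is
    evaluated at the bin midpoint, which is exact when no bin straddles the
    potential's well boundary.
    """
    mean = 0.0
    second = 0.0
    for a, pa in zip(types, type_probs):
        for b, pb in zip(types, type_probs):
            for bin_idx, pbin in enumerate(bin_probs):
                mid = (bin_edges[bin_idx] + bin_edges[bin_idx + 1]) / 2.0
                energy = potential.pair_energy(a, b, mid)
                weight = pa * pb * pbin
                mean += weight * energy
                second += weight * energy ** 2
    variance = second - mean ** 2
    return mean, float(np.sqrt(max(variance, 0.0)))


# ---------------------------------------------------------------------------
# Common fixtures
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def path3():
    from allosteer import synthetic_data as syn
    return syn.make_chain(3, 3.8, "path")


@pytest.fixture(scope="session")
def dumbbell():
    from allosteer import synthetic_data as syn
    return syn.make_dumbbell(12, 4)


@pytest.fixture(scope="session")
def three_residue_pdb() -> str:
    return (
        "ATOM      1  N   ALA A   1      10.000  10.000  10.000  1.00  0.00           N\n"
        "ATOM      2  CA  ALA A   1      11.000  10.000  10.000  1.00  0.00           C\n"
        "ATOM      3  CB  ALA A   1      11.500  11.200  10.500  1.00  0.00           C\n"
        "ATOM      4  CA  GLY A   2      14.500  10.000  10.000  1.00  0.00           C\n"
        "ATOM      5  CA  SER A   3      18.000  10.000  10.000  1.00  0.00           C\n"
        "ATOM      6  OG  SER A   3      18.500  11.000  10.800  1.00  0.00           O\n"
        "END\n"
    )
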