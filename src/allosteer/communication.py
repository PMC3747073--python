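"""Commute-time allosteric communication analysis.

The commute time C(i, j) is the expected round-trip time of a random walk on
the residue contact network between nodes i and j. In terms of the
pseudo-inverse of the Kirchhoff matrix,

    C(i, j) ∝ Γ⁺_ii + Γ⁺_jj − 2 Γ⁺_ij,

the bracket being the resistance distance between i and j — equivalently the
mean-square inter-residue distance fluctuation ⟨ΔR_ij²⟩ up to the 3 k_B T / γ
prefactor. Residue pairs whose distance fluctuates with low intensity
communicate efficiently; pairs that are spatially distant (Cα separation ≥
20 Å) yet have short commute times are flagged as effective communicators.
Residues with high local interaction density (coordination number, the Γ
diagonal) tend to be effective communicators.

Two normalizations are exposed and produce identical pair rankings:

* ``graph-walk``: scale 2·|E|, so values are expected random-walk round-trip
  step counts;
* ``fluctuation``: scale 3 k_B T / γ, so values equal ⟨ΔR_ij²⟩.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from . import enm
from .structure_io import CoarseStructure

DEFAULT_MIN_SEPARATION_A = 20.0
DEFAULT_CP_QUANTILE = 0.05


class DisconnectedNetworkError(ValueError):
    """Raised when commute times are requested on a disconnected network."""


@dataclass
class CommuteMatrix:
    """Symmetric commute-time matrix with its normalization and density."""

    commute: np.ndarray
    normalization: str
    local_density: np.ndarray

    @property
    def n_nodes(self) -> int:
        return self.commute.shape[0]


@dataclass
class CommunicatorReport:
    """Effectively communicating residue pairs and their clusters.

    ``pairs`` rows are (i, j, commute time, Cα distance Å) with i < j serial
    indices; every pair satisfies distance ≥ ``min_separation_A`` and commute
    time ≤ ``threshold_used``. ``clusters`` are residue groups obtained by
    single-linkage over shared residues among the qualifying pairs.
    """

    pairs: list[tuple[int, int, float, float]]
    clusters: list[set[int]]
    threshold_used: float
    min_separation_A: float


def commute_times(
    network: enm.ElasticNetwork,
    normalization: str = "graph-walk",
) -> CommuteMatrix:
    """Commute-time matrix of the elastic network.

    Raises
    ------
    DisconnectedNetworkError
        If the contact graph has more than one connected component; the
        message names the components.
    """
    spectrum = enm.decompose(network)
    if spectrum.n_zero_modes != 1:
        components = _components(network.kirchhoff)
        raise DisconnectedNetworkError(
            f"network has {len(components)} connected components: "
            f"{[sorted(c)[:6] for c in components]}"
        )
    pinv = enm.pseudo_inverse(spectrum)
    diag = np.diag(pinv)
    resistance = diag[:, None] + diag[None, :] - 2.0 * pinv
    np.fill_diagonal(resistance, 0.0)
    if normalization == "graph-walk":
        scale = 2.0 * network.n_springs
    elif normalization == "fluctuation":
        scale = 3.0 * network.kBT / network.spring_gamma
    else:
        raise ValueError(f"unknown normalization {normalization!r}")
    commute = scale * resistance
    commute = (commute + commute.T) / 2.0
    return CommuteMatrix(commute=commute, normalization=normalization,
                         local_density=network.degrees())


def _components(kirchhoff: np.ndarray) -> list[set[int]]:
    import networkx as nx

    adjacency = (kirchhoff < 0)
    graph = nx.from_numpy_array(adjacency.astype(int))
    return [set(c) for c in nx.connected_components(graph)]


def density_profile(network: enm.ElasticNetwork) -> np.ndarray:
    """Local interaction density d_i (coordination number, diagonal of Γ)."""
    return network.degrees()


def effective_pairs(
    commute: CommuteMatrix,
    structure: CoarseStructure,
    threshold: float | None = None,
    quantile: float = DEFAULT_CP_QUANTILE,
    min_separation_A: float = DEFAULT_MIN_SEPARATION_A,
) -> CommunicatorReport:
    """Residue pairs that communicate fast despite long spatial separation.

    Qualifying pairs have Cα distance ≥ ``min_separation_A`` and commute time
    ≤ the threshold. If ``threshold`` is None it is set to the ``quantile``
    (default 5th percentile) of commute times over all long-range pairs.
    An empty report (no qualifying pair) is valid, not an error.
    """
    coords = structure.ca_coords()
    if coords.shape[0] != commute.n_nodes:
        raise ValueError("structure size does not match commute matrix")
    dist = squareform(pdist(coords))
    iu, ju = np.triu_indices(commute.n_nodes, k=1)
    far = dist[iu, ju] >= min_separation_A
    commute_far = commute.commute[iu, ju][far]
    if threshold is None:
        if commute_far.size == 0:
            threshold = 0.0
        else:
            if not 0.0 < quantile <= 1.0:
                raise ValueError("quantile must be in (0, 1]")
            threshold = float(np.quantile(commute_far, quantile))
    elif threshold <= 0:
        raise ValueError("threshold must be positive")

    qual = far & (commute.commute[iu, ju] <= threshold)
    pairs = [(int(i), int(j), float(commute.commute[i, j]),
              float(dist[i, j]))
             for i, j in zip(iu[qual], ju[qual])]
    return CommunicatorReport(pairs=pairs, clusters=_link_clusters(pairs),
                              threshold_used=float(threshold),
                              min_separation_A=min_separation_A)


def _link_clusters(pairs) -> list[set[int]]:
    """Single-linkage residue clusters: pairs sharing a residue merge."""
    import networkx as nx

    graph = nx.Graph()
    for i, j, *_ in pairs:
        graph.add_edge(i, j)
    return sorted((set(c) for c in nx.connected_components(graph)),
                  key=lambda c: (min(c), len(c)))
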