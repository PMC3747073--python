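"""Synthetic structures with known ground truth.

Every analysis stage in this package is testable without downloading real
structures: the generators here build bead chains and rings with closed-form
elastic-network spectra, two-domain "dumbbells" with a flexible linker hinge,
conformational ensembles with designed per-edge contact persistence
probabilities (the stand-in for MD snapshot trajectories), and sequences with
planted energetically optimal / frustrated contacts under a stated potential.

All generators are deterministic given their parameters (and seed, where
stochastic), and every emitted structure round-trips through the PDB reader
and writer in :mod:`allosteer.structure_io`.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .frustration import ContactPotential
from .structure_io import CoarseStructure, Residue, StructureEnsemble

CA_SPACING_A = 3.8  # canonical Cα–Cα virtual bond length


def make_structure(coords: np.ndarray,
                    residue_types: list[str] | None = None,
                    sidechains: dict[int, list[tuple[str, np.ndarray]]] | None = None,
                    chain_id: str = "A",
                    label: str = "synthetic",
                    author_start: int = 1) -> CoarseStructure:
    n = coords.shape[0]
    if residue_types is None:
        residue_types = ["GLY"] * n
    sidechains = sidechains or {}
    residues = [
        Residue(chain_id=chain_id, author_number=author_start + i,
                serial_index=i, residue_type=residue_types[i],
                ca_coord=np.asarray(coords[i], dtype=float),
                sidechain_atoms=sidechains.get(i, []))
        for i in range(n)
    ]
    return CoarseStructure(residues=residues, label=label)


def make_chain(n: int, spacing_A: float = CA_SPACING_A,
               topology: str = "path") -> CoarseStructure:
    """Bead chain: ``path`` along x, or ``ring`` with the given chord spacing.

    For a ring, adjacent beads sit ``spacing_A`` apart on a circle; choosing
    the spacing relative to the elastic-network cutoff controls whether only
    nearest neighbors connect (giving the circulant closed-form spectrum
    λ_k = 4 sin²(πk/n)).
    """
    if n < 3:
        raise ValueError("n must be >= 3")
    if topology == "path":
        coords = np.zeros((n, 3))
        coords[:, 0] = np.arange(n) * spacing_A
    elif topology == "ring":
        radius = spacing_A / (2.0 * np.sin(np.pi / n))
        angles = 2.0 * np.pi * np.arange(n) / n
        coords = np.column_stack([radius * np.cos(angles),
                                  radius * np.sin(angles),
                                  np.zeros(n)])
    else:
        raise ValueError(f"unknown topology {topology!r}")
    return make_structure(coords, label=f"{topology}{n}")


@dataclass
class DumbbellTruth:
    """Ground truth for a dumbbell fixture."""

    domain1: list[int]
    linker: list[int]
    domain2: list[int]


def _blob(n: int, center: np.ndarray, spacing: float) -> np.ndarray:
    """n beads on a compact cubic grid (spacing Å) around a center."""
    side = int(np.ceil(n ** (1.0 / 3.0)))
    pts = []
    for x in range(side):
        for y in range(side):
            for z in range(side):
                pts.append((x, y, z))
    pts = np.array(pts, dtype=float)
    pts -= pts.mean(axis=0)
    order = np.argsort(np.linalg.norm(pts, axis=1), kind="stable")
    return pts[order[:n]] * spacing + center


def make_dumbbell(n_per_domain: int = 12, linker_len: int = 4,
                  compactness: float = 4.5,
                  ) -> tuple[CoarseStructure, DumbbellTruth]:
    """Two compact domains joined by an extended single-strand linker.

    The slowest nonzero elastic-network mode separates the domains with
    opposite eigenvector signs (anti-correlated inter-domain motion) and the
    mobility profile has its minima inside the linker — the hinge.

    Parameters
    ----------
    n_per_domain : int
        Beads per domain (≥ 8 so domains are genuinely compact blobs).
    linker_len : int
        Number of linker beads between the domains.
    compactness : float
        Grid spacing of the domain blobs in Å (smaller = stiffer domain).
    """
    if n_per_domain < 8:
        raise ValueError("n_per_domain must be >= 8")
    spacing = CA_SPACING_A
    blob1 = _blob(n_per_domain, np.zeros(3), compactness)
    # Order beads by x so the linker attachment bead (max x, nearest the
    # linker axis) is the last residue of domain 1.
    key = np.lexsort((-(blob1[:, 1] ** 2 + blob1[:, 2] ** 2).round(6),
                      blob1[:, 0].round(6)))
    blob1 = blob1[key]
    attach1 = blob1[-1]
    gap = (linker_len + 1) * spacing
    # Domain 2 is the exact mirror image of domain 1 through the plane
    # bisecting the linker, with mirrored residue ordering, so the whole
    # structure (and hence its mobility profile) is symmetric under serial
    # reversal.
    mirror_x = attach1[0] + gap / 2.0
    blob2 = blob1[::-1].copy()
    blob2[:, 0] = 2.0 * mirror_x - blob2[:, 0]
    attach2 = blob2[0]
    linker = np.linspace(attach1, attach2, linker_len + 2)[1:-1]
    coords = np.vstack([blob1, linker, blob2])
    truth = DumbbellTruth(
        domain1=list(range(n_per_domain)),
        linker=list(range(n_per_domain, n_per_domain + linker_len)),
        domain2=list(range(n_per_domain + linker_len,
                           2 * n_per_domain + linker_len)),
    )
    return make_structure(coords, label="dumbbell"), truth


def make_bound_dumbbell(n_per_domain: int = 12, linker_len: int = 4,
                        compactness: float = 4.5, n_extra: int = 10,
                        ) -> tuple[CoarseStructure, DumbbellTruth]:
    """Dumbbell plus an extra chain of beads rigidifying the second domain.

    The extra beads (chain B) pack against domain 2, adding contacts that
    lower its fluctuations — the synthetic analogue of a bound partner
    increasing structural stability of its docking domain.
    """
    base, truth = make_dumbbell(n_per_domain, linker_len, compactness)
    coords = base.ca_coords()
    d2 = coords[truth.domain2]
    center = d2.mean(axis=0) + np.array([0.0, 0.0,
                                         d2[:, 2].max() - d2[:, 2].min() + 4.0])
    extra = _blob(n_extra, center, compactness)
    residues = list(base.residues)
    for i in range(n_extra):
        residues.append(Residue(
            chain_id="B", author_number=i + 1, serial_index=len(residues),
            residue_type="GLY", ca_coord=extra[i], sidechain_atoms=[]))
    return CoarseStructure(residues=residues,
                           label="dumbbell+partner"), truth


# ---------------------------------------------------------------------------
# Persistence ensembles
# ---------------------------------------------------------------------------

#: Side-chain pseudo-atom layout: each designed contact (i, j) is realized by
#: two pseudo-atoms per residue placed near the i–j midpoint. "On" puts the
#: atom pairs ~3 Å apart (4 atom pairs within the 4.5 Å contact distance, so
#: raw interaction strength 4% > the 3.0% default cutoff); "off" separates
#: them to ~7 Å (0 pairs).
_ON_GAP_A = 3.0
_OFF_GAP_A = 7.0
_TWIN_OFFSET_A = 0.4
_GRID_SPACING_A = 12.0


@dataclass
class PersistenceTruth:
    """Ground truth for a persistence-ensemble fixture."""

    stable_edges: list[tuple[int, int]]
    background_edges: list[tuple[int, int]]
    p_stable: float
    p_background: float


def make_contact_base(n: int, designed_edges: list[tuple[int, int]],
                      label: str = "contact-fixture") -> CoarseStructure:
    """Residues on a sparse grid whose PSN edges are exactly the designed ones.

    Residue Cα's sit on a 12 Å grid (no incidental side-chain contacts); each
    designed edge gets a dedicated pair of two-atom side-chain clusters
    straddling the edge midpoint, in contact ("on") by default.
    """
    for i, j in designed_edges:
        if abs(i - j) < 2:
            raise ValueError(
                f"designed edge ({i}, {j}) joins sequence neighbors, which "
                "the structure-network's covalent-neighbor exclusion removes; "
                "use residues at least 2 apart in serial index")
    side = int(np.ceil(np.sqrt(n)))
    coords = np.array([[ (i % side) * _GRID_SPACING_A,
                         (i // side) * _GRID_SPACING_A, 0.0]
                       for i in range(n)])
    sidechains: dict[int, list[tuple[str, np.ndarray]]] = {i: [] for i in range(n)}
    for e_idx, (i, j) in enumerate(designed_edges):
        _add_edge_atoms(sidechains, coords, e_idx, i, j, on=True)
    types = ["ALA"] * n
    return make_structure(coords, residue_types=types,
                           sidechains=sidechains, label=label)


def _edge_geometry(coords: np.ndarray, i: int, j: int, gap: float):
    mid = (coords[i] + coords[j]) / 2.0
    direction = coords[j] - coords[i]
    direction = direction / np.linalg.norm(direction)
    # Perpendicular used to offset the twin atoms.
    perp = np.cross(direction, [0.0, 0.0, 1.0])
    if np.linalg.norm(perp) < 1e-9:
        perp = np.cross(direction, [0.0, 1.0, 0.0])
    perp = perp / np.linalg.norm(perp)
    a_side = mid - direction * gap / 2.0
    b_side = mid + direction * gap / 2.0
    return a_side, b_side, perp


#: Each designed edge's pseudo-atoms live in their own z-layer, spaced wider
#: than the contact distance, so atoms of different edges can never touch
#: (e.g. edges whose in-plane midpoints coincide).
_LAYER_SPACING_A = 5.0


def _add_edge_atoms(sidechains, coords, e_idx: int, i: int, j: int,
                    on: bool) -> None:
    gap = _ON_GAP_A if on else _OFF_GAP_A
    a_side, b_side, perp = _edge_geometry(coords, i, j, gap)
    layer = np.array([0.0, 0.0, _LAYER_SPACING_A * (e_idx + 1)])
    tag = chr(ord("A") + e_idx % 26) + str(e_idx // 26)
    for owner, base in ((i, a_side), (j, b_side)):
        for t, sign in enumerate((+1.0, -1.0)):
            name = f"S{tag}{t}"
            coord = base + layer + perp * sign * _TWIN_OFFSET_A / 2.0
            sidechains[owner].append((name, coord))


def make_scheduled_ensemble(
    base: CoarseStructure,
    edges: list[tuple[int, int]],
    schedule: np.ndarray,
) -> StructureEnsemble:
    """Ensemble whose designed contacts follow an explicit on/off schedule.

    ``schedule`` is a boolean (n_frames, n_edges) array: in frame f, edge e's
    side-chain pseudo-atoms sit in contact iff ``schedule[f, e]``. This gives
    exact control over per-clique intact counts (e.g. a clique intact in 8 of
    10 frames). ``base`` must come from :func:`make_contact_base` built with
    the same ``edges``.
    """
    schedule = np.asarray(schedule, dtype=bool)
    if schedule.ndim != 2 or schedule.shape[1] != len(edges):
        raise ValueError("schedule must be (n_frames, n_edges) boolean")
    coords = base.ca_coords()
    types = [r.residue_type for r in base.residues]
    frames = []
    for frame_row in schedule:
        sidechains: dict[int, list[tuple[str, np.ndarray]]] = {
            i: [] for i in range(base.n_residues)}
        for e_idx, (i, j) in enumerate(edges):
            _add_edge_atoms(sidechains, coords, e_idx, i, j,
                            on=bool(frame_row[e_idx]))
        frames.append(make_structure(coords, residue_types=types,
                                     sidechains=sidechains, label=base.label))
    return StructureEnsemble(frames=frames, label=base.label)


def make_persistence_ensemble(
    base: CoarseStructure,
    stable_edges: list[tuple[int, int]],
    background_edges: list[tuple[int, int]] | None = None,
    p_stable: float = 0.95,
    p_background: float = 0.3,
    n_frames: int = 100,
    rng_seed: int = 0,
) -> tuple[StructureEnsemble, PersistenceTruth]:
    """Ensemble whose designed contacts survive per frame with set probability.

    Per frame and per designed edge an independent Bernoulli draw decides
    whether the edge's side-chain pseudo-atoms sit in contact (within the
    4.5 Å boundary) or are jittered across it. Edges inside the stable region
    use ``p_stable``; background edges use ``p_background``.

    ``base`` must come from :func:`make_contact_base` built with
    ``stable_edges + background_edges``.
    """
    if not 0.0 <= p_background < p_stable <= 1.0:
        raise ValueError("require 0 <= p_background < p_stable <= 1")
    background_edges = background_edges or []
    all_edges = list(stable_edges) + list(background_edges)
    probs = np.array([p_stable] * len(stable_edges)
                     + [p_background] * len(background_edges))
    rng = np.random.default_rng(rng_seed)
    schedule = rng.random((n_frames, len(all_edges))) < probs[None, :]
    ensemble = make_scheduled_ensemble(base, all_edges, schedule)
    truth = PersistenceTruth(stable_edges=list(stable_edges),
                             background_edges=list(background_edges),
                             p_stable=p_stable, p_background=p_background)
    return ensemble, truth


def clique_edges(nodes: list[int]) -> list[tuple[int, int]]:
    """All edges of the complete graph on ``nodes``."""
    return [(a, b) for a, b in combinations(sorted(nodes), 2)]


# ---------------------------------------------------------------------------
# Frustration designs
# ---------------------------------------------------------------------------

@dataclass
class FrustrationTruth:
    """Ground truth for a frustration-design fixture."""

    optimal_pairs: list[tuple[int, int]]
    frustrated_pairs: list[tuple[int, int]]
    background_pairs: list[tuple[int, int]]


#: Background residue alphabet for frustration designs: mostly mid-hydropathy
#: types (a concentrated decoy-energy bulk) with sparse extreme types
#: supplying the distribution's tails.
_BACKGROUND_TYPES = ["ALA", "GLY", "SER", "THR", "ALA", "GLY", "SER", "THR",
                     "ALA", "GLY", "ILE", "ARG"]


def make_frustration_design(
    n: int = 24,
    planted_optimal_pairs: list[tuple[int, int]] | None = None,
    planted_frustrated_pairs: list[tuple[int, int]] | None = None,
    potential: ContactPotential | None = None,
    rng_seed: int = 0,
) -> tuple[CoarseStructure, ContactPotential, FrustrationTruth]:
    """Two-strand hairpin with planted optimal and frustrated contacts.

    Residues 0..n/2−1 form one strand, n/2..n−1 the antiparallel strand 5.5 Å
    away, so cross-strand pairs (i, n−1−i) are native contacts inside the
    potential's full-depth well. Planted optimal pairs receive the potential's
    minimum-energy type pair, planted frustrated pairs its maximum-energy
    pair (lexicographic tie-break); all other residues draw from a background
    alphabet dominated by mid-energy types.
    """
    if n < 12 or n % 2:
        raise ValueError("n must be even and >= 12")
    if potential is None:
        potential = ContactPotential.from_hydropathy()
    half = n // 2
    cross = [(i, n - 1 - i) for i in range(half)]
    default_opt = [cross[2]]
    default_bad = [cross[half - 3]]
    planted_optimal_pairs = (default_opt if planted_optimal_pairs is None
                             else planted_optimal_pairs)
    planted_frustrated_pairs = (default_bad if planted_frustrated_pairs is None
                                else planted_frustrated_pairs)
    planted = set()
    for pair in planted_optimal_pairs + planted_frustrated_pairs:
        if pair in planted:
            raise ValueError(f"planted pairs must be disjoint; {pair} repeats")
        planted.add(pair)
        planted.update(pair)

    coords = np.zeros((n, 3))
    coords[:half, 0] = np.arange(half) * CA_SPACING_A
    coords[half:, 0] = np.arange(half - 1, -1, -1) * CA_SPACING_A
    coords[half:, 1] = 5.5

    rng = np.random.default_rng(rng_seed)
    types = [str(rng.choice(_BACKGROUND_TYPES)) for _ in range(n)]
    (best_a, best_b), (worst_a, worst_b) = potential.extreme_pairs()
    for i, j in planted_optimal_pairs:
        types[i], types[j] = best_a, best_b
    for i, j in planted_frustrated_pairs:
        types[i], types[j] = worst_a, worst_b

    structure = make_structure(coords, residue_types=types,
                                label="frustration-design")
    background = [p for p in cross
                  if p not in set(planted_optimal_pairs)
                  and p not in set(planted_frustrated_pairs)
                  and types[p[0]] not in (best_a, best_b, worst_a, worst_b)
                  and types[p[1]] not in (best_a, best_b, worst_a, worst_b)]
    truth = FrustrationTruth(optimal_pairs=list(planted_optimal_pairs),
                             frustrated_pairs=list(planted_frustrated_pairs),
                             background_pairs=background)
    return structure, potential, truth


def make_compact_globule(n: int = 60, rng_seed: int = 0) -> CoarseStructure:
    """Collapsed self-avoiding chain: a generic compact test structure.

    A random-walk chain with Cα spacing 3.8 Å biased toward the origin, giving
    protein-like contact density for frustration and network analyses.
    """
    rng = np.random.default_rng(rng_seed)
    coords = np.zeros((n, 3))
    for i in range(1, n):
        for _ in range(200):
            step = rng.normal(size=3)
            step /= np.linalg.norm(step)
            # Bias toward the centroid keeps the chain compact.
            pull = -coords[i - 1]
            norm = np.linalg.norm(pull)
            if norm > 1e-9:
                step = 0.6 * step + 0.4 * pull / norm
                step /= np.linalg.norm(step)
            candidate = coords[i - 1] + step * CA_SPACING_A
            clash = np.linalg.norm(coords[:i] - candidate, axis=1).min() < 3.5
            if not clash:
                coords[i] = candidate
                break
        else:
            coords[i] = coords[i - 1] + np.array([CA_SPACING_A, 0.0, 0.0])
    types = [str(t) for t in
             np.random.default_rng(rng_seed + 1).choice(
                 list(sorted({"ALA", "GLY", "SER", "THR", "LEU", "VAL",
                              "ILE", "PHE", "LYS", "ARG", "GLU", "ASP"})),
                 size=n)]
    return make_structure(coords, residue_types=types, label="globule")
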