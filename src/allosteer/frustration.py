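"""Local frustration profiling of native contacts.

The configurational frustration index measures how energetically optimized a
native residue–residue contact is relative to the set of contacts that *could*
occupy the same place. For each native contact (i, j) a pool of decoys is
generated by randomizing both the residue identities (drawn from the
structure's own composition) and the contact distance (drawn from the
empirical native-contact distance distribution). The index is a Z-score,

    F_ij = (⟨E_decoy⟩ − E_native) / sd(E_decoy),

so a native contact more stabilizing than typical decoys has positive F.
Contacts are classified as

* minimally frustrated:  F ≥ 0.78  (boundary inclusive),
* highly frustrated:     F < −1    (strict),
* neutral:               −1 ≤ F < 0.78.

The pairwise energy model is pluggable; the shipped default is a
hydropathy-derived contact potential (more hydrophobic pairs are more
stabilizing) with a distance well: full depth inside 6.5 Å, linear taper to
zero at the native-contact cutoff (8.0 Å). Frustration density profiles count,
for each residue, the contacts of each category whose midpoint lies within
5 Å of its Cα.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .structure_io import CoarseStructure

MINIMAL_THRESHOLD = 0.78   # F >= threshold -> minimally frustrated
HIGH_THRESHOLD = -1.0      # F <  threshold -> highly frustrated
DEFAULT_N_DECOYS = 1000
DEFAULT_CONTACT_CUTOFF_A = 8.0
DEFAULT_MIN_SEQ_SEPARATION = 3
DEFAULT_DENSITY_RADIUS_A = 5.0
DEFAULT_WELL_A = 6.5
N_DISTANCE_BINS = 20

CATEGORIES = ("minimal", "neutral", "high")

# Kyte–Doolittle hydropathy scale (unitless).
HYDROPATHY = {
    "ILE": 4.5, "VAL": 4.2, "LEU": 3.8, "PHE": 2.8, "CYS": 2.5,
    "MET": 1.9, "ALA": 1.8, "GLY": -0.4, "THR": -0.7, "SER": -0.8,
    "TRP": -0.9, "TYR": -1.3, "PRO": -1.6, "HIS": -3.2, "GLU": -3.5,
    "GLN": -3.5, "ASP": -3.5, "ASN": -3.5, "LYS": -3.9, "ARG": -4.5,
}


class DegenerateDecoysError(ValueError):
    """Raised when the decoy energy distribution has zero spread."""


@dataclass
class ContactPotential:
    """Pairwise contact energy: type-pair well depth × distance modulation.

    ``pair_energy(type_a, type_b, distance)`` returns the energy in arbitrary
    units; it is symmetric in the residue types. ``well_table`` maps unordered
    type pairs to well depths; ``well_A``/``cutoff_A`` define the distance
    modulation w(d) = 1 for d ≤ well_A, linearly tapering to 0 at cutoff_A.
    Set ``taper=False`` for a hard step well (w = 1 inside well_A, else 0),
    which is convenient for exhaustively enumerable fixtures.
    """

    well_table: dict[frozenset, float]
    name: str = "custom"
    well_A: float = DEFAULT_WELL_A
    cutoff_A: float = DEFAULT_CONTACT_CUTOFF_A
    taper: bool = True

    def __post_init__(self) -> None:
        for pair, energy in self.well_table.items():
            if not np.isfinite(energy):
                raise ValueError(f"non-finite energy for pair {set(pair)}")

    def distance_weight(self, distance: float) -> float:
        if distance <= self.well_A:
            return 1.0
        if not self.taper or distance >= self.cutoff_A:
            return 0.0
        return (self.cutoff_A - distance) / (self.cutoff_A - self.well_A)

    def well_depth(self, type_a: str, type_b: str) -> float:
        key = frozenset((type_a, type_b))
        try:
            return self.well_table[key]
        except KeyError:
            raise KeyError(f"no energy for type pair ({type_a}, {type_b}) in "
                           f"potential {self.name!r}") from None

    def pair_energy(self, type_a: str, type_b: str, distance: float) -> float:
        return self.well_depth(type_a, type_b) * self.distance_weight(distance)

    def extreme_pairs(self) -> tuple[tuple[str, str], tuple[str, str]]:
        """(min-energy pair, max-energy pair); ties broken lexicographically."""
        items = []
        for pair, energy in self.well_table.items():
            members = sorted(pair)
            items.append(((members[0], members[-1]), energy))
        min_e = min(e for _, e in items)
        max_e = max(e for _, e in items)
        best = min(p for p, e in items if e == min_e)
        worst = min(p for p, e in items if e == max_e)
        return best, worst

    @classmethod
    def from_hydropathy(cls, scale: dict[str, float] | None = None,
                        depth_scale: float = 0.25,
                        **kwargs) -> "ContactPotential":
        """Default potential: e(a, b) = −depth_scale·(h_a + h_b).

        Hydrophobic pairs (large h) get negative, stabilizing energies;
        charged/polar pairs are destabilizing in a contact well, mimicking the
        burial-driven ordering of statistical contact potentials.
        """
        scale = HYDROPATHY if scale is None else scale
        table = {
            frozenset((a, b)): -depth_scale * (scale[a] + scale[b])
            for a in scale for b in scale
        }
        kwargs.setdefault("name", "hydropathy")
        return cls(well_table=table, **kwargs)


@dataclass
class Contact:
    """One scored native contact."""

    i: int
    j: int
    distance: float
    native_energy: float = np.nan
    decoy_mean: float = np.nan
    decoy_sd: float = np.nan
    index: float = np.nan
    category: str = ""


@dataclass
class FrustrationProfile:
    """Per-contact frustration indices and categories for one structure."""

    contacts: list[Contact]
    n_decoys: int
    rng_seed: int
    thresholds: tuple[float, float] = (MINIMAL_THRESHOLD, HIGH_THRESHOLD)

    def category_fractions(self) -> dict[str, float]:
        total = len(self.contacts)
        if total == 0:
            return {c: 0.0 for c in CATEGORIES}
        return {c: sum(1 for x in self.contacts if x.category == c) / total
                for c in CATEGORIES}


@dataclass
class FrustrationDensity:
    """Per-residue counts of nearby contacts in each frustration category."""

    counts: dict[str, np.ndarray]
    radius_A: float = DEFAULT_DENSITY_RADIUS_A

    def total(self) -> np.ndarray:
        return sum(self.counts.values())


def native_contacts(
    structure: CoarseStructure,
    contact_cutoff_A: float = DEFAULT_CONTACT_CUTOFF_A,
    min_seq_separation: int = DEFAULT_MIN_SEQ_SEPARATION,
) -> list[Contact]:
    """Native contact list: |i−j| ≥ 3 (same chain) and Cα distance ≤ cutoff.

    Residues on different chains are only subject to the distance criterion.
    """
    coords = structure.ca_coords()
    dist = squareform(pdist(coords))
    residues = structure.residues
    contacts = []
    n = len(residues)
    for i in range(n):
        for j in range(i + 1, n):
            same_chain = residues[i].chain_id == residues[j].chain_id
            if same_chain and j - i < min_seq_separation:
                continue
            if dist[i, j] <= contact_cutoff_A:
                contacts.append(Contact(i=i, j=j, distance=float(dist[i, j])))
    return contacts


def _composition(structure: CoarseStructure) -> tuple[list[str], np.ndarray]:
    types, counts = np.unique(
        [r.residue_type for r in structure.residues], return_counts=True)
    return list(types), counts / counts.sum()


def _distance_histogram(distances: np.ndarray,
                        n_bins: int = N_DISTANCE_BINS):
    """Empirical native-contact distance histogram (bin edges, probabilities)."""
    lo, hi = float(distances.min()), float(distances.max())
    if hi <= lo:
        edges = np.array([lo, lo])  # degenerate: single distance
        return edges, np.array([1.0])
    edges = np.linspace(lo, hi, n_bins + 1)
    counts, _ = np.histogram(distances, bins=edges)
    return edges, counts / counts.sum()


def decoy_set(
    contact: Contact,
    structure: CoarseStructure,
    potential: ContactPotential,
    n_decoys: int = DEFAULT_N_DECOYS,
    rng_seed: int = 0,
    _cache: dict | None = None,
) -> np.ndarray:
    """Decoy energies for one contact: randomized identities and distances.

    Each decoy draws two residue types independently from the structure's
    composition and a distance from the empirical native-contact distance
    histogram (bin by frequency, uniform within the bin), then evaluates the
    potential. Bit-reproducible for a fixed ``rng_seed``.
    """
    if n_decoys < 2:
        raise ValueError("n_decoys must be >= 2")
    if _cache is not None and "setup" in _cache:
        types, probs, edges, bin_probs = _cache["setup"]
    else:
        types, probs = _composition(structure)
        distances = np.array(
            [c.distance for c in native_contacts(
                structure, contact_cutoff_A=potential.cutoff_A)])
        if distances.size == 0:
            distances = np.array([contact.distance])
        edges, bin_probs = _distance_histogram(distances)
        if _cache is not None:
            _cache["setup"] = (types, probs, edges, bin_probs)

    rng = np.random.default_rng(rng_seed)
    type_a = rng.choice(len(types), size=n_decoys, p=probs)
    type_b = rng.choice(len(types), size=n_decoys, p=probs)
    bins = rng.choice(len(bin_probs), size=n_decoys, p=bin_probs)
    lo, hi = edges[bins], edges[bins + 1]
    dists = lo + rng.random(n_decoys) * (hi - lo)
    energies = np.array([
        potential.pair_energy(types[a], types[b], d)
        for a, b, d in zip(type_a, type_b, dists)
    ])
    if len(types) == 1 and np.allclose(edges[0], edges[-1]):
        # Single residue type and single distance: decoys are degenerate.
        raise DegenerateDecoysError(
            "structure has a single residue type and a single contact "
            "distance; decoy distribution is degenerate")
    return energies


def frustration_index(native_energy: float,
                      decoy_energies: np.ndarray) -> float:
    """Z-score of the native energy against the decoy distribution.

    Uses the population standard deviation (ddof=0). A native contact more
    stabilizing (lower energy) than the decoy mean gets a positive index.
    """
    decoys = np.asarray(decoy_energies, dtype=float)
    sd = float(np.std(decoys))
    if sd == 0.0:
        raise DegenerateDecoysError("decoy standard deviation is zero; "
                                    "frustration index undefined")
    return (float(np.mean(decoys)) - float(native_energy)) / sd


def classify(index: float,
             minimal_threshold: float = MINIMAL_THRESHOLD,
             high_threshold: float = HIGH_THRESHOLD) -> str:
    """Category from the frustration index.

    F ≥ 0.78 → minimal (boundary inclusive); F < −1 → high (strict);
    otherwise neutral.
    """
    if index >= minimal_threshold:
        return "minimal"
    if index < high_threshold:
        return "high"
    return "neutral"


def frustration_profile(
    structure: CoarseStructure,
    potential: ContactPotential | None = None,
    n_decoys: int = DEFAULT_N_DECOYS,
    rng_seed: int = 0,
    contact_cutoff_A: float = DEFAULT_CONTACT_CUTOFF_A,
) -> FrustrationProfile:
    """Score and classify every native contact of a structure.

    Per-contact decoy seeds are derived deterministically from ``rng_seed``,
    so the full profile is reproducible bit-for-bit.
    """
    if potential is None:
        potential = ContactPotential.from_hydropathy(
            cutoff_A=contact_cutoff_A)
    contacts = native_contacts(structure, contact_cutoff_A=contact_cutoff_A)
    seed_seq = np.random.SeedSequence(rng_seed)
    child_seeds = seed_seq.spawn(len(contacts))
    cache: dict = {}
    residues = structure.residues
    for contact, child in zip(contacts, child_seeds):
        decoys = decoy_set(contact, structure, potential,
                           n_decoys=n_decoys,
                           rng_seed=child, _cache=cache)
        contact.native_energy = potential.pair_energy(
            residues[contact.i].residue_type,
            residues[contact.j].residue_type,
            contact.distance)
        contact.decoy_mean = float(np.mean(decoys))
        contact.decoy_sd = float(np.std(decoys))
        contact.index = frustration_index(contact.native_energy, decoys)
        contact.category = classify(contact.index)
    return FrustrationProfile(contacts=contacts, n_decoys=n_decoys,
                              rng_seed=rng_seed)


def frustration_density(
    profile: FrustrationProfile,
    structure: CoarseStructure,
    radius_A: float = DEFAULT_DENSITY_RADIUS_A,
) -> FrustrationDensity:
    """Count contacts per category within ``radius_A`` of each residue's Cα.

    A contact is located at the midpoint of its two Cα positions and may be
    counted for several residues (all those whose Cα lies within the radius).
    """
    coords = structure.ca_coords()
    counts = {c: np.zeros(structure.n_residues, dtype=int)
              for c in CATEGORIES}
    for contact in profile.contacts:
        midpoint = (coords[contact.i] + coords[contact.j]) / 2.0
        near = np.linalg.norm(coords - midpoint, axis=1) <= radius_A
        counts[contact.category][near] += 1
    return FrustrationDensity(counts=counts, radius_A=radius_A)


def profile_table(profile: FrustrationProfile, structure: CoarseStructure):
    """Contact profile as a DataFrame in author numbering."""
    import pandas as pd

    rows = []
    for c in profile.contacts:
        ri, rj = structure.residues[c.i], structure.residues[c.j]
        rows.append({
            "chain_i": ri.chain_id, "res_i": ri.author_number,
            "chain_j": rj.chain_id, "res_j": rj.author_number,
            "distance_A": c.distance, "native_energy": c.native_energy,
            "decoy_mean": c.decoy_mean, "decoy_sd": c.decoy_sd,
            "F": c.index, "category": c.category,
        })
    return pd.DataFrame(rows, columns=[
        "chain_i", "res_i", "chain_j", "res_j", "distance_A",
        "native_energy", "decoy_mean", "decoy_sd", "F", "category"])


def density_table(density: FrustrationDensity, structure: CoarseStructure):
    """Per-residue frustration density as a DataFrame."""
    import pandas as pd

    return pd.DataFrame({
        "chain": [r.chain_id for r in structure.residues],
        "author_number": [r.author_number for r in structure.residues],
        "n_minimal": density.counts["minimal"],
        "n_neutral": density.counts["neutral"],
        "n_high": density.counts["high"],
    })
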