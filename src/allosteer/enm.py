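"""Gaussian network model (GNM) elastic-network analysis.

Residues are nodes of an elastic network; pairs of Cα atoms within a cutoff
distance r_c (default 7.0 Å) are joined by springs of uniform force constant γ.
The network topology is encoded in the Kirchhoff (graph Laplacian) matrix Γ:
off-diagonal Γ_ij = −1 for contacts, diagonal Γ_ii = coordination number.
Equilibrium dynamics follow from the eigendecomposition of Γ: the N−1 nonzero
modes give residue mean-square fluctuations

    ⟨ΔR_i²⟩ = (3 k_B T / γ) Σ_k λ_k⁻¹ [u_k]_i²

and cross-correlations ⟨ΔR_i·ΔR_j⟩ by the analogous mode sum, which over the
full nonzero spectrum equals (3 k_B T / γ)·Γ⁺, the Moore–Penrose pseudo-inverse.
Low-frequency (small λ) modes describe the large-scale collective motions;
minima of mode-averaged mobility profiles mark hinge candidates, maxima mark
flexible sites.

k_B T and γ default to 1 (arbitrary units): every analysis here uses relative
fluctuations only.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .structure_io import CoarseStructure

logger = logging.getLogger(__name__)

DEFAULT_CUTOFF_A = 7.0
#: Mode-count presets used for mobility maps: 3 and 10 low-frequency modes for
#: mode-averaged profiles, 20 computed low modes as the general default.
MODE_PRESETS = {"slow3": 3, "slow10": 10, "default": 20}
#: Eigenvalues below ZERO_MODE_RTOL × λ_max count as zero (rigid-body) modes.
ZERO_MODE_RTOL = 1e-8


@dataclass
class ElasticNetwork:
    """Kirchhoff matrix of a Cα contact network plus its parameters."""

    kirchhoff: np.ndarray
    cutoff_rc: float
    spring_gamma: float = 1.0
    kBT: float = 1.0
    structure_ref: CoarseStructure | None = None

    @property
    def n_nodes(self) -> int:
        return self.kirchhoff.shape[0]

    @property
    def n_springs(self) -> int:
        """Number of springs |E| (edges of the contact graph)."""
        return int(np.round(np.trace(self.kirchhoff) / 2))

    def degrees(self) -> np.ndarray:
        """Coordination number of every residue (diagonal of Γ)."""
        return np.diag(self.kirchhoff).copy()


@dataclass
class ModeSpectrum:
    """Eigendecomposition of the Kirchhoff matrix.

    ``eigenvalues`` ascend; ``eigenvectors[:, k]`` is the orthonormal mode u_k
    with its largest-magnitude component fixed positive (deterministic sign).
    ``n_zero_modes`` counts the near-zero eigenvalues, which equals the number
    of connected components of the contact graph.
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    n_zero_modes: int
    spring_gamma: float = 1.0
    kBT: float = 1.0

    @property
    def n_nodes(self) -> int:
        return self.eigenvalues.shape[0]

    def nonzero_modes(self) -> np.ndarray:
        """Indices of all nonzero (internal) modes, slowest first."""
        return np.arange(self.n_zero_modes, self.n_nodes)

    def slowest_modes(self, n_modes: int) -> np.ndarray:
        """Indices of the ``n_modes`` lowest-frequency nonzero modes."""
        return self.nonzero_modes()[:n_modes]


@dataclass
class MobilityProfile:
    """Per-residue mean-square fluctuation profile over selected modes."""

    msf: np.ndarray
    nmsf: np.ndarray
    modes_used: np.ndarray
    normalization: str = "unit-max"
    hinge_candidates: np.ndarray = field(default_factory=lambda: np.array([], int))
    flexible_sites: np.ndarray = field(default_factory=lambda: np.array([], int))


@dataclass
class CorrelationMap:
    """Cross-correlations of residue fluctuations over selected modes.

    ``raw`` holds ⟨ΔR_i·ΔR_j⟩; ``normalized`` has unit diagonal and entries in
    [−1, +1] (+1 fully correlated, −1 fully anti-correlated). ``defined`` masks
    entries whose normalization was well-posed (raw variance > 0); undefined
    entries are reported as 0.
    """

    raw: np.ndarray
    normalized: np.ndarray
    modes_used: np.ndarray
    defined: np.ndarray


def build_network(
    structure: CoarseStructure,
    cutoff_rc: float = DEFAULT_CUTOFF_A,
    spring_gamma: float = 1.0,
    kBT: float = 1.0,
) -> ElasticNetwork:
    """Build the Kirchhoff matrix from Cα coordinates.

    Residue pairs with Cα distance ≤ ``cutoff_rc`` (inclusive) are connected.
    Coincident Cα pairs trigger a warning but stay connected.
    """
    if cutoff_rc <= 0:
        raise ValueError("cutoff_rc must be positive")
    coords = structure.ca_coords()
    n = coords.shape[0]
    dist = squareform(pdist(coords))
    contact = dist <= cutoff_rc
    np.fill_diagonal(contact, False)
    n_coincident = int(np.sum((dist == 0) & contact) // 2)
    if n_coincident:
        warnings.warn(
            f"{n_coincident} coincident Cα pair(s) (zero distance); "
            "kept connected", stacklevel=2)
    gamma_matrix = -contact.astype(float)
    np.fill_diagonal(gamma_matrix, contact.sum(axis=1))
    return ElasticNetwork(kirchhoff=gamma_matrix, cutoff_rc=cutoff_rc,
                          spring_gamma=spring_gamma, kBT=kBT,
                          structure_ref=structure)


def decompose(network: ElasticNetwork) -> ModeSpectrum:
    """Full eigendecomposition of Γ with deterministic eigenvector signs."""
    eigenvalues, eigenvectors = np.linalg.eigh(network.kirchhoff)
    # Sign convention: largest-magnitude component of each mode is positive.
    for k in range(eigenvectors.shape[1]):
        pivot = np.argmax(np.abs(eigenvectors[:, k]))
        if eigenvectors[pivot, k] < 0:
            eigenvectors[:, k] *= -1
    lam_max = float(eigenvalues[-1]) if eigenvalues.size else 0.0
    tol = ZERO_MODE_RTOL * max(lam_max, 1.0)
    n_zero = int(np.sum(eigenvalues < tol))
    return ModeSpectrum(eigenvalues=eigenvalues, eigenvectors=eigenvectors,
                        n_zero_modes=n_zero,
                        spring_gamma=network.spring_gamma, kBT=network.kBT)


def _resolve_modes(spectrum: ModeSpectrum, modes) -> np.ndarray:
    modes = np.asarray(modes, dtype=int)
    zero = modes[modes < spectrum.n_zero_modes]
    if zero.size:
        raise ValueError(
            f"mode selection includes zero (rigid-body) mode(s) {zero.tolist()}"
        )
    if np.any(modes >= spectrum.n_nodes):
        raise ValueError("mode index out of range")
    return modes


def _mode_sum(spectrum: ModeSpectrum, modes: np.ndarray) -> np.ndarray:
    """(3 kBT/γ) Σ_{k∈modes} λ_k⁻¹ u_k u_kᵀ."""
    lam = spectrum.eigenvalues[modes]
    u = spectrum.eigenvectors[:, modes]
    prefactor = 3.0 * spectrum.kBT / spectrum.spring_gamma
    return prefactor * (u / lam) @ u.T


def mean_square_fluctuations(
    spectrum: ModeSpectrum,
    modes=None,
) -> MobilityProfile:
    """Per-residue MSF over the selected modes (default: all nonzero modes).

    With the full nonzero-mode set this equals (3 kBT/γ)·diag(Γ⁺).
    """
    if modes is None:
        modes = spectrum.nonzero_modes()
    modes = _resolve_modes(spectrum, modes)
    lam = spectrum.eigenvalues[modes]
    u = spectrum.eigenvectors[:, modes]
    prefactor = 3.0 * spectrum.kBT / spectrum.spring_gamma
    msf = prefactor * np.sum(u ** 2 / lam, axis=1)
    nmsf = _normalize(msf, "unit-max")
    return MobilityProfile(msf=msf, nmsf=nmsf, modes_used=modes)


def _normalize(msf: np.ndarray, how: str) -> np.ndarray:
    if how == "unit-max":
        peak = msf.max()
        return msf / peak if peak > 0 else msf.copy()
    if how == "unit-sum":
        total = msf.sum()
        return msf / total if total > 0 else msf.copy()
    raise ValueError(f"unknown normalization {how!r}")


#: Minimum prominence (on a unit-max profile) for a stationary point to count
#: as a hinge candidate or flexible site; suppresses intra-domain wiggles.
STATIONARY_PROMINENCE = 0.1


def _stationary_points(profile: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Interior local minima (hinge candidates) and maxima (flexible sites).

    Only stationary points with prominence ≥ ``STATIONARY_PROMINENCE`` on the
    unit-max-scaled profile are reported: a hinge is a pronounced mobility
    dip, not a small fluctuation inside a rigid block.
    """
    from scipy.signal import find_peaks

    scale = profile.max()
    scaled = profile / scale if scale > 0 else profile
    prominence = STATIONARY_PROMINENCE
    maxima, _ = find_peaks(scaled, prominence=prominence)
    minima, _ = find_peaks(-scaled, prominence=prominence)
    return minima.astype(int), maxima.astype(int)


def nmsf_profile(
    spectrum: ModeSpectrum,
    n_modes: int = MODE_PRESETS["default"],
    normalization: str = "unit-max",
) -> MobilityProfile:
    """Normalized MSF averaged over the ``n_modes`` lowest nonzero modes.

    Also reports stationary points of the profile: local minima are hinge
    candidates, local maxima flexible sites. ``n_modes`` exceeding the N−1
    internal modes is clamped with a warning.
    """
    if n_modes < 1:
        raise ValueError("n_modes must be >= 1")
    available = spectrum.n_nodes - spectrum.n_zero_modes
    if n_modes > available:
        warnings.warn(
            f"n_modes={n_modes} exceeds the {available} available nonzero "
            "modes; clamped", stacklevel=2)
        n_modes = available
    modes = spectrum.slowest_modes(n_modes)
    lam = spectrum.eigenvalues[modes]
    u = spectrum.eigenvectors[:, modes]
    prefactor = 3.0 * spectrum.kBT / spectrum.spring_gamma
    msf = prefactor * np.sum(u ** 2 / lam, axis=1)
    nmsf = _normalize(msf, normalization)
    minima, maxima = _stationary_points(nmsf)
    return MobilityProfile(msf=msf, nmsf=nmsf, modes_used=modes,
                           normalization=normalization,
                           hinge_candidates=minima, flexible_sites=maxima)


def cross_correlations(
    spectrum: ModeSpectrum,
    modes=None,
) -> CorrelationMap:
    """Cross-correlation map ⟨ΔR_i·ΔR_j⟩ over selected modes.

    ``normalized[i, j] = raw[i, j] / sqrt(raw[i, i]·raw[j, j])``. With a
    truncated mode set some residues may have zero variance; those rows and
    columns are masked in ``defined`` and reported as 0.
    """
    if modes is None:
        modes = spectrum.nonzero_modes()
    modes = _resolve_modes(spectrum, modes)
    raw = _mode_sum(spectrum, modes)
    raw = (raw + raw.T) / 2.0  # enforce exact symmetry
    variance = np.diag(raw).copy()
    ok = variance > np.finfo(float).eps * max(variance.max(), 1.0)
    defined = np.outer(ok, ok)
    denom = np.sqrt(np.outer(np.where(ok, variance, 1.0),
                             np.where(ok, variance, 1.0)))
    normalized = np.where(defined, raw / denom, 0.0)
    normalized = np.clip(normalized, -1.0, 1.0)
    if np.all(ok):
        np.fill_diagonal(normalized, 1.0)
    if not np.all(ok):
        logger.warning("%d residue(s) have zero variance under the selected "
                       "modes; their correlations are masked",
                       int(np.sum(~ok)))
    return CorrelationMap(raw=raw, normalized=normalized, modes_used=modes,
                          defined=defined)


def pseudo_inverse(spectrum: ModeSpectrum) -> np.ndarray:
    """Moore–Penrose pseudo-inverse of Γ from its nonzero modes."""
    modes = spectrum.nonzero_modes()
    lam = spectrum.eigenvalues[modes]
    u = spectrum.eigenvectors[:, modes]
    return (u / lam) @ u.T
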