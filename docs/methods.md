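# Methods

This note records the models implemented in `allosteer`, the defaults and
why they were chosen, what the synthetic fixtures do and do not emulate, and
the numerical conventions a user re-deriving results will need.

## Coarse-grained structure model

A structure is one node per residue: the Cα coordinate, residue type, chain
and author (crystal) numbering, and the heavy side-chain atoms. Parsing
keeps altloc ' '/'A' conformers only and ignores HETATM records entirely —
waters, nucleotides and ligands are not part of the residue network, which
is a deliberate simplification: a bound nucleotide rigidifies its pocket in
reality, and its absence here means nucleotide-mediated stiffening is only
captured indirectly through the protein conformation itself.

Author numbering (with insertion codes) is preserved in every report;
internally residues get a consecutive 0-based serial index. Chain gaps are
compressed — no loop modeling is attempted — and a gap report is logged so
the user can see where the serial index jumps author numbering. Multi-MODEL
files become frame-aligned ensembles; frames must agree exactly on residue
identity.

## Elastic network (GNM)

* **Cutoff r_c = 7.0 Å, inclusive (≤).** 7.0 Å is the standard Cα-network
  radius capturing first-shell contacts; inclusivity at the boundary is
  fixed so that results are reproducible bit-for-bit across platforms.
* **Uniform spring constant γ = 1, k_B T = 1.** All analyses in this
  package use relative fluctuations; absolute units would only rescale
  every profile by a constant.
* **Mode counts.** The general default computes 20 low-frequency modes;
  mobility-map presets of 3 and 10 modes are exposed because domain-level
  hinge structure is typically visible in the slowest handful of modes
  while 10–20 modes recover finer features. With all N−1 nonzero modes the
  mode sum equals the Moore–Penrose pseudo-inverse of Γ, which the tests
  verify directly.
* **Zero modes.** Eigenvalues below 1e-8·λ_max count as rigid-body modes;
  their number equals the number of connected components, a robust
  identity that doubles as a connectivity check.
* **Eigenvector signs** are fixed by making the largest-magnitude component
  of each mode positive, so serialized outputs are deterministic.
* **NMSF normalization** divides by the profile maximum (profiles in
  [0, 1]); unit-sum normalization is available as an option since both
  conventions appear in practice.
* **Stationary points.** Hinge candidates are local minima (and flexible
  sites local maxima) of the mode-averaged profile with prominence ≥ 0.1 on
  the unit-max scale. The prominence floor exists because the interior of a
  rigid domain shows small mobility wiggles that are not hinges; 0.1 keeps
  only dips comparable to genuine inter-domain minima.

## Commute-time communication

C(i,j) = scale·(Γ⁺_ii + Γ⁺_jj − 2Γ⁺_ij). Two scales are exposed:
`graph-walk` (2·|E|, values are expected random-walk round-trip step counts,
checked against direct walk simulation) and `fluctuation` (3 k_B T/γ, values
are mean-square inter-residue distance fluctuations). The two differ by a
constant factor and rank pairs identically.

Effective communicators are pairs at Cα separation ≥ 20 Å with commute time
at or below a threshold. The printed literature value for this threshold is
not recoverable, so the default is the 5th percentile of commute times over
all long-range pairs — preserving the "fast communicators among distant
pairs" semantics without inventing a constant — and both an absolute
threshold and a quantile are accepted. Qualifying pairs aggregate into
clusters by single-linkage over shared residues: the simplest deterministic
rule, chosen because no aggregation method is prescribed in the source
analyses.

## Protein structure network

I_ij = 100·n_ij/√(N_i·N_j) with n_ij the count of heavy side-chain atom
pairs within 4.5 Å. Conventions:

* **Strict inequalities** at both the I_min = 3.0% edge cutoff and the 0.75
  persistence threshold, following the "greater than" wording of the
  method's definition.
* **Normalization table.** The per-residue-type constants N_i shipped here
  are this package's own calibration, proportional to each side chain's
  heavy-atom contact capacity (Gly smallest, Trp largest). The published
  constants of the originating web tool are not printed in the sources this
  package follows, so the table is explicitly configurable per call, and a
  raw mode (N_i = 100, I_ij = n_ij) exists for designed fixtures where
  exact edge arithmetic matters.
* **Glycine** contributes its Cα as its only "side-chain" atom — otherwise
  it would be invisible to the network.
* **Sequence neighbors** (|i−j| < 2 on a chain) are excluded so covalently
  forced contacts do not dominate.
* **k-clique communities.** Both adjacency rules are implemented: cliques
  sharing ≥ k−1 nodes (the classical percolation rule) or ≥ k−2 nodes.
  The default is k = 3 with the k−2 rule (any shared node percolates),
  the more inclusive of the two documented conventions; community detection
  is verified against exhaustive subset enumeration on random graphs, and
  against networkx's percolation routine for the k−1 rule.
* **Persistence.** A clique is intact in a frame iff all its edges exist in
  that frame's PSN; candidates are the k-cliques of the union graph over
  frames. Retained cliques (intact fraction > 0.75) percolate into the
  persistent communities; community persistence is the mean over its
  cliques.

## Local frustration

The frustration *procedure* — decoys, Z-score, three-way classification —
is implemented in full; the energy model is deliberately pluggable. The
default potential is hydropathy-derived: pair well depth
e(a,b) = −0.25·(h_a + h_b) on the Kyte–Doolittle scale, so hydrophobic
pairs are stabilizing in a contact well, times a distance modulation (full
depth within 6.5 Å, linear taper to zero at the 8.0 Å contact cutoff). This
reproduces the burial-driven ordering of statistical contact potentials
with fully transparent provenance; any 20×20 table can be supplied instead.

* **Native contacts**: Cα distance ≤ 8.0 Å and sequence separation ≥ 3
  (different chains: distance only) — common frustratometer practice, both
  configurable.
* **Decoys** (default 1000 per contact) draw two residue types from the
  structure's own composition and a distance from the empirical
  native-contact distance histogram (20 bins, uniform within a bin). This
  implements "appropriately distributed" decoys deterministically from the
  input itself.
* **Z-score** uses the population standard deviation (ddof = 0); the sign
  convention makes a native contact that is more stabilizing than typical
  decoys positive.
* **Classification**: F ≥ 0.78 minimal (boundary inclusive), F < −1 high
  (strict), else neutral. A reading of the minimal threshold as |F| ≥ 0.78
  exists; this package follows the frustratometer convention of a signed
  threshold, and the thresholds are parameters of `classify` for users who
  want the other reading.
* **Density profiles** locate a contact at the midpoint of its two Cα
  positions and count contacts per category within 5 Å of each residue's
  Cα; a contact may be counted for several residues.
* **Reproducibility**: per-contact decoy seeds are spawned deterministically
  from the profile seed, so a profile is bit-for-bit reproducible.

## Synthetic fixtures and what they show

The generators provide every input the test suite needs, with ground truth
known by construction:

* **Chains and rings** have closed-form network spectra (ring:
  λ_k = 4 sin²(πk/N)) and path-graph pseudo-inverses, pinning the elastic
  machinery to exact values. At the canonical 3.8 Å spacing a straight
  chain's next-nearest neighbors sit at 7.6 Å — outside the 7.0 Å cutoff —
  so straight chains are exact path graphs.
* **Dumbbells** (two mirror-image compact domains, default 12 beads at
  4.5 Å grid spacing, joined by an extended linker) realize the hinge
  phenomenology: anti-correlated domains in the slowest mode, mobility
  minima inside the linker, and — with an extra bead cluster packed against
  one domain — a negative mobility delta confined to the bound domain.
* **Persistence ensembles** realize designed contacts with per-edge, per-
  frame Bernoulli survival (or an explicit schedule for exact arithmetic).
  Each designed edge's pseudo-atom pair lives in its own z-layer spaced
  wider than the contact distance, so edges are geometrically independent
  by construction.
* **Frustration designs** plant the potential's extreme type pairs on
  hairpin cross-strand contacts; the background alphabet concentrates
  mid-hydropathy types with sparse extremes so background natives land in
  the bulk of the decoy distribution (mostly neutral).

What these fixtures do **not** emulate: real side-chain packing and rotamer
correlations, sequence-dependent backbone geometry, solvent and nucleotide
effects, or MD-quality conformational sampling. Passing tests demonstrate
that the implemented operators are mathematically correct and recover
planted structure; they do not validate the biological accuracy of any
particular potential or parameter choice on real proteins.

## Comparative pipeline

Differences are always (complex − unbound), computed once from the two
mapped arrays so self-comparison yields exact zeros. Residues are matched
on (chain, author number, insertion code, residue type); mismatches are
listed, and per-residue deltas live on the common mapping. PSN counts and
frustration category fractions are reported side by side per structure
because they are not per-residue quantities. Config-file runs (YAML) log
every parameter and seed and reject unknown keys; a rerun with the same
config is byte-identical.

## Known limitations

* The Cα-isotropic network has no directional information; anisotropic
  (3N×3N) models are out of scope.
* The default frustration potential is a one-parameter hydropathy model —
  adequate for the procedure's statistics, not a validated force field.
* The PSN normalization table is a package calibration, not the constants
  of the original web tool; absolute I_ij values depend on it (edge *sets*
  near the 2–4% range are fairly robust, but cutoff-boundary edges can
  differ).
* HETATM omission means nucleotide-bound and nucleotide-free forms of the
  same conformation produce identical networks.
* k-clique enumeration on very dense contact graphs can grow
  combinatorially; typical protein PSNs at I_min = 3% are sparse.
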