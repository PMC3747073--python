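# allosteer

Coarse-grained allostery analysis for protein structures and structural
ensembles: elastic-network functional dynamics, commute-time communication
propensities, side-chain protein structure networks with clique-percolation
communities and ensemble persistence, and decoy-based local frustration
profiling — plus differential (unbound vs. complex) comparison reports.

The toolkit targets questions like the ones raised by chaperone–cochaperone
systems such as Hsp90 with p23 and Aha1: where are the inter-domain hinges
that pivot collective motions, which distant residue pairs communicate
efficiently, which residue communities stay structurally intact across a
conformational ensemble, and how does partner binding redistribute local
energetic frustration.

## The models

**Gaussian network model (GNM).** Each residue is a node at its Cα; pairs
within r_c = 7.0 Å are joined by springs of uniform force constant γ. The
Kirchhoff (graph Laplacian) matrix Γ has Γ_ij = −1 for contacts and
Γ_ii = the coordination number. Its N−1 nonzero eigenmodes (λ_k, u_k) give
residue mean-square fluctuations and cross-correlations

    ⟨ΔR_i·ΔR_j⟩ = (3 k_B T / γ) Σ_k λ_k⁻¹ [u_k]_i [u_k]_j ,

which over all nonzero modes equals (3 k_B T / γ)·Γ⁺. Low-frequency modes
describe collective domain motions; minima of mode-averaged mobility
profiles mark hinge candidates.

**Commute-time communication.** The commute time
C(i,j) ∝ Γ⁺_ii + Γ⁺_jj − 2Γ⁺_ij is the expected round-trip time of a random
walk on the contact network, equivalently the mean-square fluctuation of the
inter-residue distance. Residue pairs at ≥ 20 Å spatial separation whose
commute times fall below a threshold (default: the 5th percentile over all
long-range pairs) are *effective communicators* — distant yet dynamically
coupled.

**Protein structure network (PSN).** Residues i, j are linked when the
interaction strength I_ij = 100·n_ij / √(N_i N_j) exceeds I_min = 3.0%,
where n_ij counts side-chain heavy-atom pairs within 4.5 Å and N_i is a
per-residue-type normalization. Hubs have more than three connections;
k-cliques (default k = 3) percolate into communities when adjacent cliques
share k−1 or k−2 nodes. Over a multi-model ensemble, cliques intact in more
than 75% of frames form the dynamically stable network.

**Local frustration.** Each native contact is scored by a Z-score against
~1000 decoys with randomized residue identities and contact distances:
F = (⟨E_decoy⟩ − E_native)/sd(E_decoy). Contacts with F ≥ 0.78 are minimally
frustrated, F < −1 highly frustrated, otherwise neutral; per-residue density
profiles count nearby contacts (within 5 Å) in each category.

## Worked example

```python
import numpy as np
from allosteer import enm, communication, pipeline, synthetic_data as syn

# A two-domain dumbbell with a 4-residue flexible linker
unbound, truth = syn.make_dumbbell(n_per_domain=12, linker_len=4)

network = enm.build_network(unbound, cutoff_rc=7.0)
spectrum = enm.decompose(network)
profile = enm.nmsf_profile(spectrum, n_modes=3)
print("hinge candidates:", profile.hinge_candidates)

corr = enm.cross_correlations(spectrum, modes=spectrum.slowest_modes(1))
block = corr.normalized[np.ix_(truth.domain1, truth.domain2)]
print("inter-domain correlation:", round(block.mean(), 3))

# Bind a partner against domain 2 and compare
bound, _ = syn.make_bound_dumbbell(n_per_domain=12, linker_len=4)
report = pipeline.compare(unbound, bound, analyses=("gnm",))
print("domain 2 mobility delta:",
      round(report.mobility_delta[truth.domain2].mean(), 3))
```

Output:

```
hinge candidates: [14]
inter-domain correlation: -1.0
domain 2 mobility delta: -1.769
```

Residue 14 sits mid-linker — the hinge. The two domains move fully
anti-correlated in the slowest mode, and binding a partner to domain 2
lowers that domain's fluctuations (negative mobility delta, the complex −
unbound convention) while leaving the free domain mobile.

The same analyses are available from the shell:

```
allosteer synth --kind dumbbell --n 12 --out dumbbell.pdb
allosteer gnm --pdb dumbbell.pdb --n-modes 3 --out-prefix dumbbell
allosteer cp --pdb dumbbell.pdb --min-sep 20 --cp-quantile 0.05
allosteer psn --pdb ensemble.pdb --imin 3.0 --k 3 --persistence 0.75
allosteer frustration --pdb structure.pdb --n-decoys 1000 --seed 17
allosteer run --config run.yaml
```

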