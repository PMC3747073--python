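"""Local frustration: native contacts, decoy statistics, Z-scores,
classification, density profiles.

The decoy oracle is exhaustive enumeration over a two-letter alphabet and a
step-well potential whose energy is constant within every distance bin.
"""

import numpy as np
import pytest

from allosteer import frustration as fr
from allosteer import synthetic_data as syn
from conftest import enumerate_decoy_stats, structure_from_coords


def two_letter_fixture():
    """8 residues, 4 isolated contact pairs at distances {5.0, 7.5} Å.

    Types are half ILE / half ARG; the step-well potential is constant inside
    6.5 Å and zero beyond, so every (type pair, distance bin) decoy outcome
    has an exactly enumerable energy.
    """
    coords = [
        [0, 0, 0], [100, 0, 0], [200, 0, 0], [300, 0, 0],
        [5.0, 0, 0], [105.0, 0, 0], [207.5, 0, 0], [307.5, 0, 0],
    ]
    types = ["ILE", "ILE", "ILE", "ARG", "ARG", "ILE", "ARG", "ARG"]
    structure = structure_from_coords(coords, types)
    potential = fr.ContactPotential(
        well_table={
            frozenset({"ILE"}): -2.0,
            frozenset({"ILE", "ARG"}): 0.5,
            frozenset({"ARG"}): 2.0,
        },
        name="two-letter-step", well_A=6.5, cutoff_A=8.0, taper=False)
    return structure, potential


class TestNativeContacts:
    def test_two_residue_structure_has_no_contacts(self):
        s = structure_from_coords([[0, 0, 0], [5, 0, 0]])
        assert fr.native_contacts(s) == []

    def test_extended_chain_has_no_contacts(self):
        # spacing 3.8 Å: the closest |i-j| >= 3 pair is 11.4 Å > 8 Å
        s = syn.make_chain(10, 3.8, "path")
        assert fr.native_contacts(s) == []

    def test_designed_pair_found(self):
        coords = [[3.8 * i, 0, 0] for i in range(8)]
        coords[5] = [coords[1][0] + 3.0, 5.2, 0]  # fold residue 5 onto 1
        s = structure_from_coords(coords)
        pairs = {(c.i, c.j) for c in fr.native_contacts(s)}
        assert (1, 5) in pairs

    def test_interchain_pairs_only_distance_filtered(self):
        coords = [[0, 0, 0], [3.8, 0, 0], [0, 5, 0], [3.8, 5, 0]]
        residues = structure_from_coords(coords).residues
        for r in residues[2:]:
            r.chain_id = "B"
        s = type(structure_from_coords(coords))(residues=residues,
                                                label="dimer")
        pairs = {(c.i, c.j) for c in fr.native_contacts(s)}
        assert (0, 2) in pairs and (1, 3) in pairs
        assert (0, 1) not in pairs  # same-chain neighbors stay excluded


class TestDecoySet:
    def test_fixed_seed_is_bit_identical(self):
        structure, potential = two_letter_fixture()
        contact = fr.native_contacts(structure)[0]
        a = fr.decoy_set(contact, structure, potential, 500, rng_seed=123)
        b = fr.decoy_set(contact, structure, potential, 500, rng_seed=123)
        assert np.array_equal(a, b)

    def test_different_seeds_differ(self):
        structure, potential = two_letter_fixture()
        contact = fr.native_contacts(structure)[0]
        a = fr.decoy_set(contact, structure, potential, 500, rng_seed=1)
        b = fr.decoy_set(contact, structure, potential, 500, rng_seed=2)
        assert not np.array_equal(a, b)

    def test_too_few_decoys_rejected(self):
        structure, potential = two_letter_fixture()
        contact = fr.native_contacts(structure)[0]
        with pytest.raises(ValueError, match="n_decoys"):
            fr.decoy_set(contact, structure, potential, 1)

    def test_monte_carlo_matches_exhaustive_enumeration(self):
        structure, potential = two_letter_fixture()
        contacts = fr.native_contacts(structure)
        distances = np.array([c.distance for c in contacts])
        edges = np.linspace(distances.min(), distances.max(), 21)
        counts, _ = np.histogram(distances, bins=edges)
        exact_mean, exact_sd = enumerate_decoy_stats(
            potential, ["ILE", "ARG"], [0.5, 0.5], edges,
            counts / counts.sum())
        n = 4000
        decoys = fr.decoy_set(contacts[0], structure, potential, n,
                              rng_seed=99)
        se_mean = exact_sd / np.sqrt(n)
        assert abs(decoys.mean() - exact_mean) < 3 * se_mean
        # sd of the sample sd ~ sd/sqrt(2n) for well-behaved distributions
        assert abs(decoys.std() - exact_sd) < 4 * exact_sd / np.sqrt(2 * n)


class TestFrustrationIndex:
    def test_native_at_decoy_mean_is_zero(self):
        assert fr.frustration_index(1.0, np.array([0.0, 2.0])) == 0.0

    def test_stabilizing_native_is_positive(self):
        # decoys {0, 2}: mean 1, sd 1; native -1 -> F = 2
        assert fr.frustration_index(-1.0, np.array([0.0, 2.0])) == 2.0

    def test_destabilizing_native_is_negative(self):
        assert fr.frustration_index(3.0, np.array([0.0, 2.0])) == -2.0

    def test_zero_spread_raises(self):
        with pytest.raises(fr.DegenerateDecoysError):
            fr.frustration_index(0.0, np.array([1.0, 1.0, 1.0]))


class TestClassify:
    @pytest.mark.parametrize("index, category", [
        (0.78, "minimal"),    # boundary inclusive
        (2.0, "minimal"),
        (0.7799, "neutral"),
        (0.0, "neutral"),
        (-1.0, "neutral"),    # boundary: "lower than -1" is strict
        (-1.01, "high"),
        (-5.0, "high"),
    ])
    def test_threshold_boundaries(self, index, category):
        assert fr.classify(index) == category


class TestProfile:
    def test_full_profile_reproducible_bit_for_bit(self):
        structure, potential, _ = syn.make_frustration_design(16, rng_seed=3)
        a = fr.frustration_profile(structure, potential, n_decoys=200,
                                   rng_seed=5)
        b = fr.frustration_profile(structure, potential, n_decoys=200,
                                   rng_seed=5)
        assert [(c.i, c.j, c.index, c.category) for c in a.contacts] == \
            [(c.i, c.j, c.index, c.category) for c in b.contacts]

    def test_planted_pairs_classify_as_designed(self):
        structure, potential, truth = syn.make_frustration_design(
            24, rng_seed=17)
        profile = fr.frustration_profile(structure, potential,
                                         n_decoys=1000, rng_seed=17)
        by_pair = {(c.i, c.j): c for c in profile.contacts}
        for pair in truth.optimal_pairs:
            assert by_pair[pair].category == "minimal"
            assert by_pair[pair].index >= 0.78
        for pair in truth.frustrated_pairs:
            assert by_pair[pair].category == "high"

    def test_background_pairs_mostly_neutral_across_seeds(self):
        neutral = total = 0
        for seed in range(20):
            structure, potential, truth = syn.make_frustration_design(
                24, rng_seed=seed)
            profile = fr.frustration_profile(structure, potential,
                                             n_decoys=300, rng_seed=seed)
            by_pair = {(c.i, c.j): c for c in profile.contacts}
            for pair in truth.background_pairs:
                if pair in by_pair:
                    total += 1
                    neutral += by_pair[pair].category == "neutral"
        assert total >= 40
        assert neutral / total > 0.5

    def test_category_fractions_sum_to_one(self):
        structure, potential, _ = syn.make_frustration_design(16, rng_seed=1)
        profile = fr.frustration_profile(structure, potential,
                                         n_decoys=200, rng_seed=2)
        fractions = profile.category_fractions()
        assert sum(fractions.values()) == pytest.approx(1.0)


class TestDensity:
    def test_contact_free_structure_all_zero(self):
        s = syn.make_chain(8, 3.8, "path")
        profile = fr.FrustrationProfile(contacts=[], n_decoys=0, rng_seed=0)
        density = fr.frustration_density(profile, s)
        assert np.all(density.total() == 0)

    def test_midpoint_counted_for_both_partners(self):
        # contact midpoint 3 Å from each partner's Cα, far from everyone else
        coords = [[0, 0, 0], [50, 0, 0], [100, 0, 0], [6.0, 0, 0]]
        s = structure_from_coords(coords)
        contact = fr.Contact(i=0, j=3, distance=6.0, category="minimal")
        profile = fr.FrustrationProfile(contacts=[contact], n_decoys=0,
                                        rng_seed=0)
        density = fr.frustration_density(profile, s, radius_A=5.0)
        assert density.counts["minimal"][0] == 1
        assert density.counts["minimal"][3] == 1
        assert density.counts["minimal"][1] == 0

    def test_category_totals_conserved(self):
        structure, potential, _ = syn.make_frustration_design(20, rng_seed=9)
        profile = fr.frustration_profile(structure, potential,
                                         n_decoys=200, rng_seed=4)
        density = fr.frustration_density(profile, structure)
        total = density.total()
        by_cat = sum(density.counts[c] for c in fr.CATEGORIES)
        assert np.array_equal(total, by_cat)


def test_constant_potential_gives_degenerate_decoys():
    structure, _ = two_letter_fixture()
    flat = fr.ContactPotential(
        well_table={frozenset({"ILE"}): 1.0, frozenset({"ILE", "ARG"}): 1.0,
                    frozenset({"ARG"}): 1.0},
        name="flat", taper=False, well_A=500.0, cutoff_A=501.0)
    contact = fr.native_contacts(structure)[0]
    decoys = fr.decoy_set(contact, structure, flat, 100, rng_seed=0)
    assert np.all(decoys == decoys[0])
    with pytest.raises(fr.DegenerateDecoysError):
        fr.frustration_index(1.0, decoys)
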