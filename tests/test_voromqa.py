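"""Statistical potential, pseudo-energies, light score and the dark predictor."""

import math

import numpy as np
import pytest

from camqa.contacts import ContactMap, aggregate_residues, compute_contact_map
from camqa.errors import InsufficientDataError, UndefinedScoreError
from camqa.structures import Atom, Structure, make_dimer
from camqa.voromqa import (
    SOLVENT,
    DarkModel,
    Potential,
    atom_type,
    dark_features,
    dark_score,
    dark_train,
    derive_potential,
    interface_energy,
    light_global,
    pseudo_energy,
    FEATURE_NAMES,
)


def atom(chain, resi, name, element="C", pos=(0, 0, 0), r=1.7, resname="ALA"):
    return Atom(chain, resi, resname, name, element, np.array(pos, float), r)


class TestAtomTyping:
    @pytest.mark.parametrize(
        "name,element,expected",
        [
            ("CA", "C", "CA"),
            ("CB", "C", "CB"),
            ("N", "N", "bb-N"),
            ("C", "C", "bb-C"),
            ("O", "O", "bb-O"),
            ("OXT", "O", "bb-O"),
            ("SG", "S", "S"),
            ("CG", "C", "sc-C"),
            ("OG", "O", "sc-O"),
            ("ND1", "N", "sc-N"),
        ],
    )
    def test_vocabulary(self, name, element, expected):
        assert atom_type(atom("A", 1, name, element)) == expected

    def test_unknown_carbon_falls_back_to_sidechain(self):
        assert atom_type(atom("A", 1, "X1", "C", resname="XXX")) == "sc-C"


class TestDerivePotential:
    def test_symmetry(self, potential):
        for (a, b), e in potential.entries.items():
            assert potential.get(a, b) == potential.get(b, a) == e
            assert math.isfinite(e)

    def test_empty_refs_rejected(self):
        with pytest.raises(InsufficientDataError):
            derive_potential([])

    def test_independently_mixed_reference_gives_zero_energies(self):
        """An observed table that follows the independence null exactly
        produces energies within the pseudocount tolerance of zero."""
        from camqa.voromqa import potential_from_observed_areas

        weights = {"CA": 3.0, "CB": 2.0, "bb-O": 1.0, SOLVENT: 4.0}
        scale = 400.0
        observed = {}
        for a in weights:
            for b in weights:
                if a > b or (a == SOLVENT and b == SOLVENT):
                    continue
                mult = 1.0 if a == b else 2.0
                observed[(a, b)] = scale * weights[a] * weights[b] * mult
        pot = potential_from_observed_areas(observed, pseudocount=1.0)
        for e in pot.entries.values():
            assert abs(e) < 0.05

    def test_unseen_pair_has_positive_energy(self, potential):
        # S never occurs in the helical fixtures but is in the vocabulary of
        # observed solvent/backbone shares only if present; absent entries
        # default to 0 via get(); derive a potential with an S atom present
        # but never in contact to exercise the pseudocount path
        rng = np.random.default_rng(1)
        atoms = [
            atom("A", i + 1, "CA", pos=tuple(rng.uniform(0, 8, 3))) for i in range(10)
        ]
        atoms.append(atom("A", 99, "SG", element="S", pos=(50, 50, 50), r=1.8))
        pot = derive_potential([Structure(atoms)], n_samples=128, seed=0)
        assert pot.get("S", "CA") > 0.0

    def test_self_consistency_mean_energy_near_zero(self, potential):
        refs = [make_dimer(16, seed=i) for i in range(6)]
        total_e = 0.0
        total_atoms = 0
        for s in refs:
            cm = compute_contact_map(s, n_samples=128, seed=0)
            _, tot = pseudo_energy(cm, s, potential)
            total_e += tot
            total_atoms += s.n_atoms
        assert abs(total_e / total_atoms) < 0.1

    def test_round_trip_serialization(self, potential, tmp_path):
        path = tmp_path / "pot.tsv"
        potential.save(path)
        loaded = Potential.load(path)
        for key, e in potential.entries.items():
            assert loaded.entries[key] == pytest.approx(e, abs=1e-6)


class TestPseudoEnergy:
    def hand_system(self):
        s = Structure(
            [
                atom("A", 1, "CA", pos=(0, 0, 0)),
                atom("A", 1, "CB", pos=(2, 0, 0)),
                atom("B", 1, "CA", pos=(0, 2.5, 0)),
            ]
        )
        cm = ContactMap(
            atom_contacts={(0, 1): 4.0, (0, 2): 6.0},
            solvent_areas=np.array([10.0, 0.0, 5.0]),
            probe=0.0,
            n_samples=64,
            seed=0,
        )
        p = Potential(
            entries={
                ("CA", "CA"): -1.0,
                ("CA", "CB"): 0.5,
                ("CA", SOLVENT): 0.2,
                ("CB", SOLVENT): 0.1,
            }
        )
        return s, cm, p

    def test_hand_sum(self):
        s, cm, p = self.hand_system()
        per_atom, total = pseudo_energy(cm, s, p)
        # contacts: 4*0.5 (CA-CB) + 6*(-1) (CA-CA) = -4; solvent: 10*0.2 + 5*0.2 = 3
        assert total == pytest.approx(-1.0, abs=1e-12)
        assert per_atom[0] == pytest.approx(0.5 * 4 * 0.5 + 0.5 * 6 * -1.0 + 10 * 0.2)

    def test_zero_potential_gives_zero(self):
        s, cm, _ = self.hand_system()
        _, total = pseudo_energy(cm, s, Potential(entries={}))
        assert total == 0.0

    def test_linearity_in_area(self):
        s, cm, p = self.hand_system()
        _, t1 = pseudo_energy(cm, s, p)
        cm2 = ContactMap(
            atom_contacts={(0, 1): 8.0, (0, 2): 6.0},
            solvent_areas=cm.solvent_areas,
            probe=0.0,
            n_samples=64,
            seed=0,
        )
        _, t2 = pseudo_energy(cm2, s, p)
        assert t2 - t1 == pytest.approx(4.0 * 0.5, abs=1e-12)

    def test_interface_plus_intra_plus_solvent_is_total(self, dimer, dimer_maps, potential):
        cm, _ = dimer_maps
        per_atom, total = pseudo_energy(cm, dimer, potential)
        iface = interface_energy(cm, dimer, potential)
        types = [atom_type(a) for a in dimer.atoms]
        chains = [a.chain_id for a in dimer.atoms]
        intra = sum(
            area * potential.get(types[i], types[j])
            for i, j, area in cm.iter_contacts()
            if chains[i] == chains[j]
        )
        solvent = sum(
            float(a) * potential.get(types[i], SOLVENT)
            for i, a in enumerate(cm.solvent_areas)
        )
        assert iface + intra + solvent == pytest.approx(total, abs=1e-9)

    def test_monomer_interface_energy_is_zero(self, potential):
        s = Structure([atom("A", 1, "CA")])
        cm = ContactMap({}, np.array([10.0]), 1.4, 64, 0)
        assert interface_energy(cm, s, potential) == 0.0

    def test_interface_energy_matches_explicit_loop(self, dimer, dimer_maps, potential):
        cm, _ = dimer_maps
        types = [atom_type(a) for a in dimer.atoms]
        chains = [a.chain_id for a in dimer.atoms]
        expected = sum(
            area * potential.get(types[i], types[j])
            for i, j, area in cm.iter_contacts()
            if chains[i] != chains[j]
        )
        assert interface_energy(cm, dimer, potential) == pytest.approx(expected)
        assert expected < 0  # the native hydrophobic interface is favorable


class TestLightGlobal:
    def test_zero_energy_gives_half(self):
        cm = ContactMap({(0, 1): 5.0}, np.array([1.0, 1.0]), 0.0, 64, 0)
        assert light_global(np.zeros(2), cm) == pytest.approx(0.5)

    def test_negative_energies_score_above_half(self):
        cm = ContactMap({(0, 1): 5.0}, np.array([1.0, 1.0]), 0.0, 64, 0)
        assert light_global(np.array([-1.0, -2.0]), cm) > 0.5

    def test_strict_ordering_under_one_worsened_contact(self):
        cm = ContactMap({(0, 1): 5.0}, np.array([1.0, 1.0]), 0.0, 64, 0)
        good = light_global(np.array([-1.0, -1.0]), cm)
        worse = light_global(np.array([-1.0, -0.5]), cm)
        assert good > worse

    def test_zero_area_undefined(self):
        cm = ContactMap({}, np.zeros(1), 0.0, 64, 0)
        with pytest.raises(UndefinedScoreError):
            light_global(np.zeros(1), cm)


class TestDarkFeatures:
    def test_feature_vector_contract(self, dimer, dimer_maps, potential):
        cm, rcm = dimer_maps
        feats = dark_features(dimer, rcm, cm, potential)
        assert set(feats) == set(dimer.residue_keys())
        for vec in feats.values():
            assert vec.shape == (len(FEATURE_NAMES),)
            assert np.all(np.isfinite(vec))

    def test_cross_chain_feature_zero_without_interface(self, potential):
        from camqa.structures import make_helix

        h = make_helix(10, seed=0)
        cm = compute_contact_map(h, n_samples=128, seed=0)
        rcm = aggregate_residues(cm, h)
        feats = dark_features(h, rcm, cm, potential)
        cross_idx = FEATURE_NAMES.index("cross_chain_area")
        assert all(vec[cross_idx] == 0.0 for vec in feats.values())

    def test_buried_residue_has_zero_solvent_and_full_burial(self, potential):
        # a residue completely caged by neighbors
        center = atom("A", 5, "CA", pos=(0, 0, 0))
        cage = [
            atom("A", i + 10, "CA", pos=tuple(3.0 * np.array(d)))
            for i, d in enumerate(
                [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1),
                 (0.7, 0.7, 0), (-0.7, 0.7, 0), (0.7, -0.7, 0), (-0.7, -0.7, 0),
                 (0.7, 0, 0.7), (-0.7, 0, 0.7), (0.7, 0, -0.7), (-0.7, 0, -0.7),
                 (0, 0.7, 0.7), (0, -0.7, 0.7), (0, 0.7, -0.7), (0, -0.7, -0.7)]
            )
        ]
        s = Structure([center] + cage)
        cm = compute_contact_map(s, probe=1.4, n_samples=512, seed=0)
        rcm = aggregate_residues(cm, s)
        feats = dark_features(s, rcm, cm, Potential(entries={}))
        solv_idx = FEATURE_NAMES.index("solvent_area")
        burial_idx = FEATURE_NAMES.index("burial_fraction")
        assert feats[("A", 5)][solv_idx] == pytest.approx(0.0, abs=1.0)
        assert feats[("A", 5)][burial_idx] > 0.95


class TestDarkModel:
    def test_overfit_small_sample(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(30, 6))
        y = 1.0 / (1.0 + np.exp(-X[:, 0] + 0.5 * X[:, 1]))
        model = dark_train(list(zip(X, y)), hidden=20, iterations=2000, seed=1)
        assert model.final_loss < 0.01

    def test_constant_targets_learned(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(40, 4))
        model = dark_train([(x, 0.5) for x in X], hidden=8, iterations=800, seed=2)
        preds = model.predict(X)
        assert np.all(np.abs(preds - 0.5) < 0.05)

    def test_training_is_deterministic(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(20, 5))
        y = rng.uniform(0, 1, 20)
        m1 = dark_train(list(zip(X, y)), seed=9, iterations=300)
        m2 = dark_train(list(zip(X, y)), seed=9, iterations=300)
        np.testing.assert_array_equal(m1.w1, m2.w1)
        np.testing.assert_array_equal(m1.w2, m2.w2)

    def test_empty_examples_rejected(self):
        with pytest.raises(InsufficientDataError):
            dark_train([])

    def test_outputs_in_unit_interval(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(15, 3))
        y = rng.uniform(0, 1, 15)
        model = dark_train(list(zip(X, y)), iterations=200, seed=0)
        preds = model.predict(rng.normal(size=(50, 3)) * 10)
        assert np.all((preds > 0) & (preds < 1))

    def test_round_trip_serialization(self, tmp_path):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(10, 4))
        y = rng.uniform(0, 1, 10)
        model = dark_train(list(zip(X, y)), iterations=100, seed=4)
        path = tmp_path / "dark.json"
        model.save(path)
        loaded = DarkModel.load(path)
        np.testing.assert_allclose(loaded.predict(X), model.predict(X), atol=1e-12)


class TestDarkScore:
    def test_global_is_exact_mean_of_locals(self, dimer, dimer_maps, potential, dark_model):
        cm, rcm = dimer_maps
        local, global_dark = dark_score(dark_model, dimer, rcm, cm, potential)
        assert global_dark == pytest.approx(np.mean(list(local.values())), abs=1e-15)
        assert all(0 < v < 1 for v in local.values())

    def test_single_residue_global_equals_local(self, potential, dark_model):
        s = Structure([atom("A", 1, "CA"), atom("A", 1, "CB", pos=(1.5, 0, 0))])
        cm = compute_contact_map(s, n_samples=128, seed=0)
        rcm = aggregate_residues(cm, s)
        local, global_dark = dark_score(dark_model, s, rcm, cm, potential)
        assert len(local) == 1
        assert global_dark == next(iter(local.values()))
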