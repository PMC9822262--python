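"""Contact geometry on handcrafted coordinates, redundancy weighting, and
weighted ensemble contact frequencies."""

import numpy as np
import pytest

from kinothread.contacts import (
    ACTIVE,
    INACTIVE,
    StructureContacts,
    StructureRecord,
    contact_map,
    delta_contacts,
    ensemble_frequencies,
    load_structure_record,
    read_delta_table,
    redundancy_weights,
    write_contact_table,
)
from tests.conftest import ala


def record_from_coords(coords: dict[int, np.ndarray], L=30, state=ACTIVE) -> StructureRecord:
    return StructureRecord(
        structure_id="toy", chain="A", uniprot_id="U1", state=state,
        class_label="TK", L=L, coords=coords,
    )


def sc(sid, uid, state, contacts, resolved=None, L=30, cls="TK") -> StructureContacts:
    if resolved is None:
        resolved = frozenset(range(1, L + 1))
    return StructureContacts(
        structure_id=sid, chain="A", uniprot_id=uid, state=state, class_label=cls,
        L=L, contacts=frozenset(contacts), resolved=frozenset(resolved),
    )


class TestContactGeometry:
    def test_strictly_inside_cutoff_is_contact(self):
        coords = {1: np.array([[0.0, 0.0, 0.0]]), 11: np.array([[5.99, 0.0, 0.0]])}
        assert (1, 11) in contact_map(record_from_coords(coords)).contacts

    def test_exactly_at_cutoff_is_not(self):
        coords = {1: np.array([[0.0, 0.0, 0.0]]), 11: np.array([[6.0, 0.0, 0.0]])}
        assert contact_map(record_from_coords(coords)).contacts == frozenset()

    def test_sequence_separation_rule(self):
        # 3 A apart but only 4 columns apart: excluded; 5 apart: included
        coords = {1: np.array([[0.0, 0.0, 0.0]]),
                  5: np.array([[3.0, 0.0, 0.0]]),
                  6: np.array([[0.0, 3.0, 0.0]])}
        cm = contact_map(record_from_coords(coords))
        assert (1, 5) not in cm.contacts
        assert (1, 6) in cm.contacts

    def test_nearest_atom_governs_and_geometry_is_rigid_motion_invariant(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 1, (4, 3))
        b = rng.normal(0, 1, (3, 3)) + np.array([5.0, 0, 0])
        base = contact_map(record_from_coords({2: a, 9: b})).contacts
        # random rotation + translation preserves all pairwise distances
        theta = 0.7
        R = np.array([[np.cos(theta), -np.sin(theta), 0],
                      [np.sin(theta), np.cos(theta), 0], [0, 0, 1]])
        t = np.array([10.0, -3.0, 2.0])
        moved = contact_map(
            record_from_coords({2: a @ R.T + t, 9: b[::-1] @ R.T + t})
        ).contacts
        assert moved == base

    def test_pdb_parsing_sidechain_only(self, pdb_writer):
        # CB atoms 5 A apart; backbone atoms are closer but must be ignored
        path = pdb_writer("pair.pdb", [ala(1, (0, 0, 0)), ala(11, (5.0, 0, 0))])
        rec = load_structure_record(
            path, "A", {1: 1, 11: 11}, "UP1", ACTIVE, "TK", L=30
        )
        assert set(rec.coords) == {1, 11}
        assert all(len(v) == 1 for v in rec.coords.values())  # CB only
        assert (1, 11) in contact_map(rec).contacts

    def test_glycine_ca_proxy(self, pdb_writer):
        gly = {"resseq": 11, "resname": "GLY",
               "atoms": [("N", "N", 4.0, 0, 2.0), ("CA", "C", 5.0, 0, 0),
                         ("C", "C", 6.0, 0, 2.0), ("O", "O", 7.0, 0, 2.5)]}
        path = pdb_writer("gly.pdb", [ala(1, (0, 0, 0)), gly])
        rec = load_structure_record(path, "A", {1: 1, 11: 11}, "UP1", ACTIVE, "TK", L=30)
        assert (1, 11) in contact_map(rec).contacts
        rec_off = load_structure_record(
            path, "A", {1: 1, 11: 11}, "UP1", ACTIVE, "TK", L=30, gly_ca_proxy=False
        )
        # glycine has no side-chain heavy atoms: contributes nothing, no crash
        assert contact_map(rec_off).contacts == frozenset()


class TestRedundancyWeights:
    def test_three_in_active_one_in_inactive(self):
        recs = [sc(f"a{i}", "UPX", ACTIVE, []) for i in range(3)]
        recs.append(sc("b0", "UPX", INACTIVE, []))
        assert np.allclose(redundancy_weights(recs), 0.25)

    def test_unique_ids_unit_weight(self):
        recs = [sc(f"a{i}", f"UP{i}", ACTIVE, []) for i in range(4)]
        assert np.allclose(redundancy_weights(recs), 1.0)

    def test_same_cluster_pair(self):
        recs = [sc("a0", "UPX", ACTIVE, []), sc("a1", "UPX", ACTIVE, [])]
        assert np.allclose(redundancy_weights(recs), 0.5)

    def test_missing_uniprot_treated_unique(self):
        recs = [sc("a0", None, ACTIVE, []), sc("a1", None, ACTIVE, [])]
        assert np.allclose(redundancy_weights(recs), 1.0)
        with pytest.raises(ValueError):
            redundancy_weights(recs, missing_policy="error")


class TestEnsembleFrequencies:
    def test_single_structure(self):
        ens = ensemble_frequencies([sc("a", "U1", ACTIVE, [(10, 20)])], np.ones(1), ACTIVE)
        assert ens.frequency(10, 20) == 1.0
        assert ens.frequency(10, 25) == 0.0

    def test_two_equal_weights_half(self):
        recs = [sc("a", "U1", ACTIVE, [(10, 20)]), sc("b", "U2", ACTIVE, [])]
        ens = ensemble_frequencies(recs, np.ones(2), ACTIVE)
        assert ens.frequency(10, 20) == 0.5

    def test_weighted_hand_evaluation(self):
        # weights (1/2, 1/2, 1); contact only in the weight-1 structure:
        # c = 1*1 / (1/2 + 1/2 + 1) = 0.5
        recs = [sc("a", "U1", ACTIVE, []), sc("b", "U1", ACTIVE, []),
                sc("c", "U2", ACTIVE, [(3, 12)])]
        ens = ensemble_frequencies(recs, np.array([0.5, 0.5, 1.0]), ACTIVE)
        assert ens.frequency(3, 12) == pytest.approx(0.5)

    def test_per_pair_normalization_excludes_unresolved(self):
        # second structure does not resolve column 12: pair (3, 12) is
        # normalized over the first structure only
        recs = [
            sc("a", "U1", ACTIVE, [(3, 12)]),
            sc("b", "U2", ACTIVE, [], resolved=set(range(1, 31)) - {12}),
        ]
        ens = ensemble_frequencies(recs, np.ones(2), ACTIVE)
        assert ens.frequency(3, 12) == 1.0
        assert ens.n_support[2, 11] == 1

    def test_global_denominator_mode(self):
        recs = [
            sc("a", "U1", ACTIVE, [(3, 12)]),
            sc("b", "U2", ACTIVE, [], resolved=set(range(1, 31)) - {12}),
        ]
        ens = ensemble_frequencies(recs, np.ones(2), ACTIVE, denominator="global")
        assert ens.frequency(3, 12) == 0.5

    def test_fully_unresolved_pair_flagged_undefined(self):
        recs = [sc("a", "U1", ACTIVE, [], resolved=set(range(1, 31)) - {12})]
        ens = ensemble_frequencies(recs, np.ones(1), ACTIVE)
        assert not ens.defined[2, 11]
        assert ens.frequency(3, 12) == 0.0

    def test_duplication_with_recomputed_weights_invariant(self):
        base = [sc("a", "U1", ACTIVE, [(3, 12)]), sc("b", "U2", ACTIVE, [(5, 15)])]
        w_base = redundancy_weights(base)
        ens1 = ensemble_frequencies(base, w_base, ACTIVE)
        dup = base + [sc("a2", "U1", ACTIVE, [(3, 12)]), sc("b2", "U2", ACTIVE, [(5, 15)])]
        ens2 = ensemble_frequencies(dup, redundancy_weights(dup), ACTIVE)
        assert np.allclose(ens1.c, ens2.c)

    def test_empty_list_and_state_mismatch(self):
        with pytest.raises(ValueError, match="empty"):
            ensemble_frequencies([], np.array([]), ACTIVE)
        with pytest.raises(ValueError, match="state"):
            ensemble_frequencies([sc("a", "U1", INACTIVE, [])], np.ones(1), ACTIVE)


class TestDeltaContacts:
    def make_pair(self, c_active, c_inactive):
        a = ensemble_frequencies([sc("a", "U1", ACTIVE, c_active)], np.ones(1), ACTIVE)
        b = ensemble_frequencies([sc("b", "U1", INACTIVE, c_inactive)], np.ones(1), INACTIVE)
        return a, b

    def test_identical_ensembles_zero(self):
        a, b = self.make_pair([(3, 12)], [(3, 12)])
        assert np.all(delta_contacts(a, b).delta == 0)

    def test_lost_contact_positive_delta(self):
        a, b = self.make_pair([(3, 12)], [])
        dmap = delta_contacts(a, b)
        assert dmap.value(3, 12) == 1.0

    def test_swap_negates(self):
        a, b = self.make_pair([(3, 12)], [(5, 15)])
        d1 = delta_contacts(a, b).delta
        d2 = delta_contacts(b, a).delta
        assert np.allclose(d1, -d2)

    def test_class_mismatch_hard_error(self):
        a = ensemble_frequencies([sc("a", "U1", ACTIVE, [], cls="TK")], np.ones(1), ACTIVE)
        b = ensemble_frequencies([sc("b", "U1", INACTIVE, [], cls="STK")], np.ones(1), INACTIVE)
        with pytest.raises(ValueError, match="class"):
            delta_contacts(a, b)

    def test_contact_table_round_trip(self, tmp_path):
        a, b = self.make_pair([(3, 12), (5, 20)], [(5, 20), (7, 22)])
        path = tmp_path / "contacts.tsv"
        write_contact_table(a, b, path)
        dmap = read_delta_table(path, L=30)
        ref = delta_contacts(a, b)
        assert np.allclose(dmap.delta, ref.delta)
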