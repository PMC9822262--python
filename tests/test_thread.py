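"""Threaded penalties ΔE, weighted bivariate marginals, and the exact
residue-pair decomposition of the class divergence ΔΔE."""

import numpy as np
import pytest

from kinothread.contacts import DeltaContactMap
from kinothread.potts import PottsModel, pair_index, zero_gauge
from kinothread.sequences import AlignedSequenceSet
from kinothread.threadcalc import (
    divergence,
    thread_energies,
    thread_energy,
    weighted_bimarg,
)
from tests.conftest import random_model


def dmap_from_entries(L, entries, cls="TK"):
    delta = np.zeros((L, L))
    for (i, j, v) in entries:
        delta[i - 1, j - 1] = v
        delta[j - 1, i - 1] = v
    return DeltaContactMap(class_label=cls, L=L, delta=delta,
                           defined=np.ones((L, L), bool))


def thread_oracle(model, seq, dmap):
    """Independent quadruple-loop evaluation of the threading sum."""
    total = 0.0
    L = model.L
    for i in range(L):
        for j in range(i + 1, L):
            if j - i <= dmap.min_separation:
                continue
            Jij = model.coupling(i + 1, j + 1)
            for a in range(model.q):
                for b in range(model.q):
                    if seq[i] == a and seq[j] == b:
                        total -= Jij[a, b] * dmap.delta[i, j]
    return total


def two_class_set(seq_x, seq_y, alphabet, wx=1.0, wy=1.0):
    return AlignedSequenceSet(
        ids=["x0", "y0"],
        seqs=np.stack([seq_x, seq_y]),
        alphabet=alphabet,
        classes=np.array(["STK", "TK"], dtype=object),
        weights=np.array([wx, wy]),
    )


class TestThreadEnergy:
    def test_zero_delta_map_zero_penalty(self):
        m = zero_gauge(random_model(10, 4, seed=0))
        dmap = dmap_from_entries(10, [])
        S = np.random.default_rng(0).integers(0, 4, (5, 10))
        assert np.all(thread_energies(m, S, dmap) == 0.0)

    def test_single_pair_hand_value(self):
        # breaking a favorable active-state contact (J = -2, delta = +1)
        # costs +2 statistical-energy units
        L, q = 12, 3
        J = np.zeros((L * (L - 1) // 2, q, q))
        p = pair_index(1, 8, L)
        J[p, 0, 2] = -2.0
        J = J - J.mean(axis=1, keepdims=True) - J.mean(axis=2, keepdims=True) \
            + J.mean(axis=(1, 2), keepdims=True)
        m = PottsModel(h=np.zeros((L, q)), J=J, alphabet="ARW")
        seq = np.zeros(L, dtype=np.uint8)
        seq[8] = 2
        dmap = dmap_from_entries(L, [(2, 9, 1.0)])
        expected = -m.coupling(2, 9)[0, 2] * 1.0
        assert thread_energy(m, seq, dmap) == pytest.approx(expected)
        assert expected > 0  # the gauge leaves the (0,2) cell negative

    def test_linearity_in_delta(self):
        m = zero_gauge(random_model(12, 4, seed=1))
        d1 = dmap_from_entries(12, [(1, 7, 0.5), (3, 11, -0.25)])
        d2 = dmap_from_entries(12, [(1, 7, 1.0), (3, 11, -0.5)])
        S = np.random.default_rng(1).integers(0, 4, (8, 12))
        assert np.allclose(2 * thread_energies(m, S, d1), thread_energies(m, S, d2))

    def test_matches_quadruple_loop_oracle(self):
        rng = np.random.default_rng(2)
        for seed in range(4):
            L = int(rng.integers(7, 11))
            q = int(rng.integers(2, 5))
            m = zero_gauge(random_model(L, q, seed=seed))
            entries = [(1, 6, float(rng.normal())), (2, L, float(rng.normal()))]
            dmap = dmap_from_entries(L, entries)
            seq = rng.integers(0, q, L).astype(np.uint8)
            assert thread_energy(m, seq, dmap) == pytest.approx(
                thread_oracle(m, seq, dmap), abs=1e-10
            )

    def test_width_mismatch_hard_error(self):
        m = zero_gauge(random_model(10, 4, seed=3))
        with pytest.raises(ValueError, match="width"):
            thread_energies(m, np.zeros((2, 9), dtype=int), dmap_from_entries(10, []))

    def test_non_zero_gauge_warns_and_corrects(self):
        m = random_model(10, 4, seed=4)
        dmap = dmap_from_entries(10, [(1, 7, 1.0)])
        seq = np.zeros(10, dtype=np.uint8)
        with pytest.warns(UserWarning, match="zero gauge"):
            val = thread_energy(m, seq, dmap)
        assert val == pytest.approx(thread_energy(zero_gauge(m), seq, dmap))

    def test_gap_zero_mode_silences_gap_pairs(self):
        base = random_model(10, 4, seed=5)
        m = zero_gauge(PottsModel(h=base.h, J=base.J, alphabet="ACD-"))
        dmap = dmap_from_entries(10, [(1, 7, 1.0)])
        seq = np.zeros(10, dtype=np.uint8)
        seq[0] = 3  # gap at one side of the pair
        assert thread_energy(m, seq, dmap, gap_mode="zero") == 0.0
        assert thread_energy(m, seq, dmap, gap_mode="model") != 0.0


class TestWeightedBimarg:
    def make_set(self, rows, weights, classes=None):
        n = len(rows)
        return AlignedSequenceSet(
            ids=[f"s{i}" for i in range(n)],
            seqs=np.array(rows, dtype=np.uint8),
            alphabet="ARW",
            classes=np.array(classes or ["TK"] * n, dtype=object),
            weights=np.array(weights, dtype=float),
        )

    def test_single_sequence_delta_function(self):
        aset = self.make_set([[0, 2, 1]], [1.0])
        f = weighted_bimarg(aset, "TK", 1, 3)
        assert f[0, 1] == 1.0 and f.sum() == 1.0

    def test_two_equal_weights(self):
        aset = self.make_set([[0, 0, 1], [2, 0, 1]], [1.0, 1.0])
        f = weighted_bimarg(aset, "TK", 1, 2)
        assert f[0, 0] == 0.5 and f[2, 0] == 0.5

    def test_weighted_direct_count(self):
        # weights (1/2, 1/2, 1) with three distinct pairs -> (0.25, 0.25, 0.5)
        aset = self.make_set([[0, 0, 0], [1, 1, 0], [2, 2, 0]], [0.5, 0.5, 1.0])
        f = weighted_bimarg(aset, "TK", 1, 2)
        assert f[0, 0] == pytest.approx(0.25)
        assert f[1, 1] == pytest.approx(0.25)
        assert f[2, 2] == pytest.approx(0.5)

    def test_empty_class_hard_error(self):
        aset = self.make_set([[0, 1, 2]], [1.0])
        with pytest.raises(ValueError, match="no members"):
            weighted_bimarg(aset, "STK", 1, 2)


class TestDivergence:
    def test_single_sequence_classes_hand_value(self):
        L, q = 12, 3
        m = zero_gauge(random_model(L, q, seed=6))
        dmap = dmap_from_entries(L, [(2, 9, 1.0)])
        rng = np.random.default_rng(3)
        sx = rng.integers(0, q, L).astype(np.uint8)
        sy = rng.integers(0, q, L).astype(np.uint8)
        aset = two_class_set(sx, sy, m.alphabet)
        res = divergence(m, aset, dmap, dmap)
        expected = thread_energy(m, sx, dmap) - thread_energy(m, sy, dmap)
        assert res.ddE == pytest.approx(expected)
        assert res.decomposition_sum == pytest.approx(expected)

    def test_decomposition_identity_on_scenario(self, small_scenario):
        sc = small_scenario
        res = divergence(sc.model, sc.aset, sc.dmap_x, sc.dmap_y)
        assert abs(res.decomposition_sum - res.ddE) < 1e-8
        assert abs(res.mean_x - res.mean_x_from_marginals) < 1e-8
        assert abs(res.mean_y - res.mean_y_from_marginals) < 1e-8

    def test_planted_pairs_rank_first(self, small_scenario):
        sc = small_scenario
        res = divergence(sc.model, sc.aset, sc.dmap_x, sc.dmap_y)
        top = res.report(top=len(sc.planted_pairs))
        assert set(zip(top["i"], top["j"])) == sc.expected_top_pairs
        assert res.ddE * sc.expected_sign > 0

    def test_report_cumulative_fraction_reaches_one(self, small_scenario):
        sc = small_scenario
        res = divergence(sc.model, sc.aset, sc.dmap_x, sc.dmap_y)
        rep = res.report()
        assert rep["cumulative_fraction"].iloc[-1] == pytest.approx(1.0)

    def test_permutation_invariance(self, small_scenario):
        sc = small_scenario
        res = divergence(sc.model, sc.aset, sc.dmap_x, sc.dmap_y)
        rng = np.random.default_rng(4)
        perm = rng.permutation(len(sc.aset))
        res_p = divergence(sc.model, sc.aset.subset(perm), sc.dmap_x, sc.dmap_y)
        assert res_p.ddE == pytest.approx(res.ddE, abs=1e-10)
        assert np.allclose(res_p.pair_matrix, res.pair_matrix, atol=1e-10)

    def test_identical_classes_rejected(self, small_scenario):
        sc = small_scenario
        with pytest.raises(ValueError, match="distinct"):
            divergence(sc.model, sc.aset, sc.dmap_x, sc.dmap_y, "TK", "TK")
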