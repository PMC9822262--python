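"""Potts Hamiltonian: statistical energies, zero-gauge transform, sampling.

The model is the standard pairwise Hamiltonian over aligned sequences,

    H(S) = sum_{i<j} J_ij(s_i, s_j) + sum_i h_i(s_i) + offset,

with lower H meaning more probable, P(S) ∝ exp(-H(S)).  With that sign
convention a positive threaded penalty ΔE disfavors the second conformation.
Couplings are stored for the L(L-1)/2 unordered pairs in lexicographic i<j
order as a P x q x q array; ``offset`` is a scalar absorbed by gauge
transformations so that H is preserved exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
from numba import njit

from kinothread.sequences import ALPHABET, AlignedSequenceSet, encode


def pair_index(i: int, j: int, L: int) -> int:
    """Index of unordered pair (i, j), 0-based i < j, in lexicographic order."""
    if not 0 <= i < j < L:
        raise ValueError(f"need 0 <= i < j < L, got ({i}, {j}) with L={L}")
    return i * (2 * L - i - 1) // 2 + (j - i - 1)


def pair_list(L: int) -> np.ndarray:
    """(P, 2) array of 0-based column pairs in lexicographic order."""
    iu = np.triu_indices(L, k=1)
    return np.column_stack(iu)


@dataclass
class PottsModel:
    """Fields ``h`` (L x q) and couplings ``J`` (P x q x q) over an alignment
    of width L with q states."""

    h: np.ndarray
    J: np.ndarray
    alphabet: str = ALPHABET
    offset: float = 0.0

    def __post_init__(self) -> None:
        self.h = np.asarray(self.h, dtype=float)
        self.J = np.asarray(self.J, dtype=float)
        L, q = self.h.shape
        P = L * (L - 1) // 2
        if self.J.shape != (P, q, q):
            raise ValueError(
                f"couplings shape {self.J.shape} inconsistent with h {self.h.shape}"
            )
        if len(self.alphabet) != q:
            raise ValueError("alphabet length must equal q")

    @property
    def L(self) -> int:
        return self.h.shape[0]

    @property
    def q(self) -> int:
        return self.h.shape[1]

    def pairs(self) -> np.ndarray:
        return pair_list(self.L)

    def coupling(self, i: int, j: int) -> np.ndarray:
        """q x q coupling block for 1-based columns i < j (symmetrized access:
        coupling(j, i) is the transpose)."""
        a, b = i - 1, j - 1
        if a > b:
            return self.J[pair_index(b, a, self.L)].T
        return self.J[pair_index(a, b, self.L)]

    def dense_couplings(self) -> np.ndarray:
        """L x L x q x q tensor with J[i, j] = J[j, i].T and zero diagonal."""
        L, q = self.L, self.q
        Jd = np.zeros((L, L, q, q))
        pairs = self.pairs()
        Jd[pairs[:, 0], pairs[:, 1]] = self.J
        Jd[pairs[:, 1], pairs[:, 0]] = np.transpose(self.J, (0, 2, 1))
        return Jd

    # -- energies ---------------------------------------------------------

    def energy(self, seq: str | np.ndarray) -> float:
        return float(self.energies(np.atleast_2d(self._codes(seq)))[0])

    def energies(self, seqs: np.ndarray | AlignedSequenceSet) -> np.ndarray:
        """Vectorized H(S) for an N x L code grid (or sequence set)."""
        if isinstance(seqs, AlignedSequenceSet):
            seqs = seqs.seqs
        S = np.asarray(seqs)
        if S.ndim == 1:
            S = S[None, :]
        if S.shape[1] != self.L:
            raise ValueError(f"sequence width {S.shape[1]} != model L {self.L}")
        if S.max(initial=0) >= self.q:
            bad = np.argwhere(S >= self.q)[0]
            raise ValueError(
                f"state {int(S[tuple(bad)])} at column {int(bad[-1]) + 1} "
                f"outside the q={self.q} alphabet"
            )
        pairs = self.pairs()
        e = self.h[np.arange(self.L), S].sum(axis=1)
        e = e + self.J[np.arange(len(pairs)), S[:, pairs[:, 0]], S[:, pairs[:, 1]]].sum(
            axis=1
        )
        return e + self.offset

    def _codes(self, seq: str | np.ndarray) -> np.ndarray:
        if isinstance(seq, str):
            return encode(seq, self.alphabet)
        return np.asarray(seq, dtype=np.uint8)

    # -- gauge ------------------------------------------------------------

    def is_zero_gauge(self, tol: float = 1e-10) -> bool:
        row = np.abs(self.J.sum(axis=1)).max(initial=0.0)
        col = np.abs(self.J.sum(axis=2)).max(initial=0.0)
        return max(row, col) < tol * self.q

    def save(self, path: str | Path) -> None:
        """Write the array container: datasets ``h`` and ``J`` plus attributes
        L, q, alphabet, offset."""
        with h5py.File(path, "w") as f:
            f.create_dataset("h", data=self.h)
            f.create_dataset("J", data=self.J)
            f.attrs["L"] = self.L
            f.attrs["q"] = self.q
            f.attrs["alphabet"] = self.alphabet
            f.attrs["offset"] = self.offset

    @classmethod
    def load(cls, path: str | Path) -> "PottsModel":
        with h5py.File(path, "r") as f:
            return cls(
                h=f["h"][...],
                J=f["J"][...],
                alphabet=str(f.attrs["alphabet"]),
                offset=float(f.attrs.get("offset", 0.0)),
            )

    def save_tsv(self, path: str | Path) -> None:
        """Plain-text export for small models: one row per parameter."""
        pairs = self.pairs()
        with open(path, "w") as fh:
            fh.write(f"# L={self.L} q={self.q} alphabet={self.alphabet} "
                     f"offset={self.offset:.17g}\n")
            fh.write("kind\ti\tj\talpha\tbeta\tvalue\n")
            for i in range(self.L):
                for a in range(self.q):
                    fh.write(f"h\t{i + 1}\t.\t{self.alphabet[a]}\t.\t{self.h[i, a]:.17g}\n")
            for p, (i, j) in enumerate(pairs):
                for a in range(self.q):
                    for b in range(self.q):
                        fh.write(
                            f"J\t{i + 1}\t{j + 1}\t{self.alphabet[a]}\t"
                            f"{self.alphabet[b]}\t{self.J[p, a, b]:.17g}\n"
                        )

    @classmethod
    def load_tsv(cls, path: str | Path) -> "PottsModel":
        with open(path) as fh:
            header = fh.readline().strip().lstrip("# ").split()
            meta = dict(kv.split("=", 1) for kv in header)
            L, q = int(meta["L"]), int(meta["q"])
            alphabet = meta["alphabet"]
            offset = float(meta["offset"])
            sym = {a: k for k, a in enumerate(alphabet)}
            h = np.zeros((L, q))
            J = np.zeros((L * (L - 1) // 2, q, q))
            fh.readline()  # column header
            for line in fh:
                kind, i, j, a, b, value = line.rstrip("\n").split("\t")
                if kind == "h":
                    h[int(i) - 1, sym[a]] = float(value)
                else:
                    p = pair_index(int(i) - 1, int(j) - 1, L)
                    J[p, sym[a], sym[b]] = float(value)
        return cls(h=h, J=J, alphabet=alphabet, offset=offset)


def zero_gauge(model: PottsModel) -> PottsModel:
    """Transform to the zero-sum gauge.

    Every coupling block gets zero row and column sums; the removed
    single-site parts move into the fields, fields are centered, and the
    constant goes into ``offset`` so H(S) is unchanged for every sequence.
    Idempotent up to floating-point tolerance.
    """
    L, q = model.L, model.q
    pairs = model.pairs()
    row = model.J.mean(axis=2)          # (P, q): mean over beta, func of alpha
    col = model.J.mean(axis=1)          # (P, q): mean over alpha, func of beta
    tot = model.J.mean(axis=(1, 2))     # (P,)
    J = model.J - row[:, :, None] - col[:, None, :] + tot[:, None, None]
    h = model.h.copy()
    np.add.at(h, pairs[:, 0], row - tot[:, None])
    np.add.at(h, pairs[:, 1], col - tot[:, None])
    offset = model.offset + tot.sum()
    hbar = h.mean(axis=1)
    h -= hbar[:, None]
    offset += hbar.sum()
    return PottsModel(h=h, J=J, alphabet=model.alphabet, offset=float(offset))


# -- Gibbs sampling -------------------------------------------------------


@njit(cache=False)
def _gibbs_kernel(h, Jd, state, uniforms, burn_in, thin, out):  # pragma: no cover
    L, q = h.shape
    n = out.shape[0]
    total = uniforms.shape[0]
    k = 0
    for sweep in range(total):
        for i in range(L):
            # conditional energies for site i given the rest
            emin = 1e300
            e = np.empty(q)
            for a in range(q):
                s = h[i, a]
                for j in range(L):
                    if j != i:
                        s += Jd[i, j, a, state[j]]
                e[a] = s
                if s < emin:
                    emin = s
            z = 0.0
            for a in range(q):
                e[a] = np.exp(-(e[a] - emin))
                z += e[a]
            u = uniforms[sweep, i] * z
            acc = 0.0
            pick = q - 1
            for a in range(q):
                acc += e[a]
                if u < acc:
                    pick = a
                    break
            state[i] = pick
        if sweep >= burn_in and (sweep - burn_in) % thin == 0 and k < n:
            for i in range(L):
                out[k, i] = state[i]
            k += 1


def gibbs_sample(
    model: PottsModel,
    n: int,
    burn_in: int = 100,
    thin: int = 5,
    seed: int = 0,
) -> AlignedSequenceSet:
    """Draw n sequences from P(S) ∝ exp(-H(S)) by sequential-scan heat-bath
    updates on a single chain.

    The chain starts from a uniform random state, runs ``burn_in`` sweeps,
    then records one sequence every ``thin`` sweeps.  All randomness derives
    from ``seed``; identical (seed, parameters) give identical output.
    """
    if n < 1:
        raise ValueError("need n >= 1")
    rng = np.random.default_rng(seed)
    L, q = model.L, model.q
    total = burn_in + (n - 1) * thin + 1
    state = rng.integers(0, q, size=L).astype(np.int64)
    uniforms = rng.random((total, L))
    out = np.zeros((n, L), dtype=np.int64)
    Jd = model.dense_couplings()
    _gibbs_kernel(model.h, Jd, state, uniforms, int(burn_in), int(thin), out)
    ids = [f"sample_{k:05d}" for k in range(n)]
    return AlignedSequenceSet(ids=ids, seqs=out.astype(np.uint8), alphabet=model.alphabet)


def enumerate_distribution(model: PottsModel) -> tuple[np.ndarray, np.ndarray]:
    """Exhaustive Boltzmann distribution over all q**L sequences (tiny L only).

    Returns (states, probabilities); the independent oracle for sampler tests.
    """
    L, q = model.L, model.q
    if q**L > 2_000_000:
        raise ValueError("state space too large to enumerate")
    grids = np.meshgrid(*[np.arange(q)] * L, indexing="ij")
    states = np.stack([g.ravel() for g in grids], axis=1).astype(np.uint8)
    e = model.energies(states)
    w = np.exp(-(e - e.min()))
    return states, w / w.sum()
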