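"""Threaded conformational penalties and class divergence.

The penalty for a sequence S in class X to move from the active ensemble to
the inactive one is

    ΔE(S) = − Σ_{i<j, |i−j|>4} J_ij(s_i, s_j) · Δc_ij(X),

evaluated with zero-gauge couplings.  Positive ΔE means the transition is
disfavored: the sequence loses more favorable couplings than it gains.  The
class divergence ΔΔE = ⟨ΔE⟩_X − ⟨ΔE⟩_Y decomposes exactly into residue-pair
terms via the weighted bivariate marginals of each class,

    ΔΔE_ij = − Σ_{α,β} J_ij(α,β) [ f^ij_αβ(X) Δc_ij(X) − f^ij_αβ(Y) Δc_ij(Y) ].
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from kinothread.contacts import DeltaContactMap
from kinothread.potts import PottsModel, pair_index, zero_gauge
from kinothread.sequences import GAP, AlignedSequenceSet, encode

logger = logging.getLogger(__name__)


def _effective_couplings(model: PottsModel, gap_mode: str) -> np.ndarray:
    """Coupling tensor actually used for threading.

    ``gap_mode="model"`` keeps the model's own gap-state couplings;
    ``"zero"`` zeroes the gap row/column so gap-containing pairs contribute
    nothing.
    """
    if gap_mode == "model":
        return model.J
    if gap_mode == "zero":
        if GAP not in model.alphabet:
            return model.J
        g = model.alphabet.index(GAP)
        J = model.J.copy()
        J[:, g, :] = 0.0
        J[:, :, g] = 0.0
        return J
    raise ValueError(f"unknown gap_mode {gap_mode!r}")


def _delta_pairs(dmap: DeltaContactMap) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Upper-triangle pairs with nonzero Δc: (i0, j0, delta) with 0-based i<j."""
    iu = np.triu_indices(dmap.L, k=dmap.min_separation + 1)
    d = dmap.delta[iu]
    keep = d != 0
    return iu[0][keep], iu[1][keep], d[keep]


def _ensure_zero_gauge(model: PottsModel) -> PottsModel:
    if not model.is_zero_gauge():
        warnings.warn(
            "model is not in the zero gauge; applying zero_gauge() before threading",
            stacklevel=3,
        )
        return zero_gauge(model)
    return model


def thread_energies(
    model: PottsModel,
    seqs: np.ndarray | AlignedSequenceSet,
    dmap: DeltaContactMap,
    gap_mode: str = "model",
) -> np.ndarray:
    """Vectorized ΔE for an N x L grid of sequence codes."""
    if isinstance(seqs, AlignedSequenceSet):
        seqs = seqs.seqs
    S = np.atleast_2d(np.asarray(seqs))
    if S.shape[1] != model.L or dmap.L != model.L:
        raise ValueError(
            f"width mismatch: model L={model.L}, sequences L={S.shape[1]}, "
            f"contact map L={dmap.L}"
        )
    model = _ensure_zero_gauge(model)
    J = _effective_couplings(model, gap_mode)
    pi, pj, d = _delta_pairs(dmap)
    if pi.size == 0:
        return np.zeros(S.shape[0])
    pidx = np.array([pair_index(a, b, model.L) for a, b in zip(pi, pj)])
    terms = J[pidx[None, :], S[:, pi], S[:, pj]] * d[None, :]
    return -terms.sum(axis=1)


def thread_energy(
    model: PottsModel,
    seq: str | np.ndarray,
    dmap: DeltaContactMap,
    gap_mode: str = "model",
) -> float:
    """ΔE of a single aligned sequence (string or code vector)."""
    if isinstance(seq, str):
        seq = encode(seq, model.alphabet)
    return float(thread_energies(model, seq, dmap, gap_mode)[0])


def weighted_bimarg(
    aset: AlignedSequenceSet, class_label: str, i: int, j: int
) -> np.ndarray:
    """Weighted bivariate marginal f^ij_αβ for one class (1-based columns);
    entries sum to 1."""
    members = aset.class_members(class_label)
    if members.size == 0:
        raise ValueError(f"class {class_label!r} has no members")
    w = aset.effective_weights()[members]
    q = aset.q
    si = aset.seqs[members, i - 1].astype(np.int64)
    sj = aset.seqs[members, j - 1].astype(np.int64)
    f = np.bincount(si * q + sj, weights=w, minlength=q * q).reshape(q, q)
    return f / w.sum()


@dataclass
class DivergenceResult:
    """Class-divergence summary: weighted means, ΔΔE, and its exact
    residue-pair decomposition."""

    class_x: str
    class_y: str
    mean_x: float
    mean_y: float
    ddE: float
    pair_matrix: np.ndarray       # symmetric L x L of ΔΔE_ij (upper triangle source)
    energies_x: np.ndarray
    energies_y: np.ndarray
    weights_x: np.ndarray
    weights_y: np.ndarray
    mean_x_from_marginals: float
    mean_y_from_marginals: float

    @property
    def decomposition_sum(self) -> float:
        return float(np.triu(self.pair_matrix).sum())

    def report(self, top: int | None = None) -> pd.DataFrame:
        """Ranked pair report: descending ΔΔE_ij, ties by ascending (i, j);
        cumulative fraction of the total ΔΔE."""
        iu = np.triu_indices(self.pair_matrix.shape[0], k=1)
        vals = self.pair_matrix[iu]
        keep = vals != 0
        df = pd.DataFrame(
            {"i": iu[0][keep] + 1, "j": iu[1][keep] + 1, "ddE_ij": vals[keep]}
        )
        df = df.sort_values(
            by=["ddE_ij", "i", "j"], ascending=[False, True, True], kind="mergesort"
        ).reset_index(drop=True)
        total = self.ddE if self.ddE != 0 else np.nan
        df["cumulative_fraction"] = df["ddE_ij"].cumsum() / total
        return df.head(top) if top is not None else df


def divergence(
    model: PottsModel,
    aset: AlignedSequenceSet,
    dmap_x: DeltaContactMap,
    dmap_y: DeltaContactMap,
    class_x: str = "STK",
    class_y: str = "TK",
    gap_mode: str = "model",
) -> DivergenceResult:
    """ΔΔE = ⟨ΔE⟩_X − ⟨ΔE⟩_Y with class-specific Δc maps, plus the exact
    per-pair decomposition.

    Sequences of class X are threaded on ``dmap_x`` and class Y on
    ``dmap_y``; means use the set's phylogenetic weights.  The decomposition
    identity Σ_ij ΔΔE_ij = ΔΔE holds because both routes share the same
    weights and couplings.
    """
    if class_x == class_y:
        raise ValueError("the two classes must be distinct")
    idx_x = aset.class_members(class_x)
    idx_y = aset.class_members(class_y)
    if idx_x.size == 0 or idx_y.size == 0:
        raise ValueError("both classes must be nonempty")
    dup = {aset.ids[i] for i in idx_x} & {aset.ids[i] for i in idx_y}
    if dup:
        raise ValueError(f"sequences present in both classes: {sorted(dup)[:5]}")
    model = _ensure_zero_gauge(model)
    w = aset.effective_weights()
    wx, wy = w[idx_x], w[idx_y]
    ex = thread_energies(model, aset.seqs[idx_x], dmap_x, gap_mode)
    ey = thread_energies(model, aset.seqs[idx_y], dmap_y, gap_mode)
    mean_x = float(np.average(ex, weights=wx))
    mean_y = float(np.average(ey, weights=wy))

    J = _effective_couplings(model, gap_mode)
    L, q = model.L, model.q
    pair_matrix = np.zeros((L, L))
    pairs: set[tuple[int, int]] = set()
    for dmap in (dmap_x, dmap_y):
        pi, pj, _ = _delta_pairs(dmap)
        pairs.update(zip(pi.tolist(), pj.tolist()))
    sub_x = aset.subset(idx_x)
    sub_y = aset.subset(idx_y)
    sum_x = 0.0
    sum_y = 0.0
    for (a, b) in sorted(pairs):
        p = pair_index(a, b, L)
        fx = weighted_bimarg(sub_x, class_x, a + 1, b + 1)
        fy = weighted_bimarg(sub_y, class_y, a + 1, b + 1)
        tx = -(J[p] * fx).sum() * dmap_x.delta[a, b]
        ty = -(J[p] * fy).sum() * dmap_y.delta[a, b]
        sum_x += tx
        sum_y += ty
        val = tx - ty
        pair_matrix[a, b] = val
        pair_matrix[b, a] = val
    return DivergenceResult(
        class_x=class_x,
        class_y=class_y,
        mean_x=mean_x,
        mean_y=mean_y,
        ddE=mean_x - mean_y,
        pair_matrix=pair_matrix,
        energies_x=ex,
        energies_y=ey,
        weights_x=wx,
        weights_y=wy,
        mean_x_from_marginals=float(sum_x),
        mean_y_from_marginals=float(sum_y),
    )
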