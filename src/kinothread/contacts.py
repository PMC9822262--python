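"""Residue–residue contacts from structural ensembles.

A contact between MSA columns i and j in one structure exists when the
nearest side-chain heavy atoms of the mapped residues lie strictly within
the cutoff (default 6 Å) and the columns are more than 4 apart.  Ensemble
contact frequencies are weighted averages over structures, down-weighted for
UniProt redundancy across the paired conformational clusters, with
unresolved residues excluded from both numerator and denominator pair by
pair.  The active-minus-inactive difference Δc feeds the threading penalty.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ACTIVE = "active_DFG_in"
INACTIVE = "classical_DFG_out"
STATES = (ACTIVE, INACTIVE)

CONTACT_CUTOFF = 6.0
MIN_SEPARATION = 4  # only |i - j| > 4 pairs count

BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT"}


@dataclass
class StructureRecord:
    """One chain with side-chain heavy-atom coordinates mapped to MSA columns.

    ``coords`` maps each resolved 1-based MSA column to a (k, 3) array of
    side-chain heavy atoms (Cβ and beyond; glycine contributes its Cα as a
    proxy side chain when enabled at load time).
    """

    structure_id: str
    chain: str
    uniprot_id: str | None
    state: str
    class_label: str
    L: int
    coords: dict[int, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for col in self.coords:
            if not 1 <= col <= self.L:
                raise ValueError(f"column_map maps residue to column {col} outside 1..{self.L}")


@dataclass(frozen=True)
class StructureContacts:
    """Binary contact map of one chain: the Eq-level input to ensemble
    frequencies.  ``contacts`` holds 1-based (i, j) with i < j; ``resolved``
    the columns with mapped, resolved residues."""

    structure_id: str
    chain: str
    uniprot_id: str | None
    state: str
    class_label: str
    L: int
    contacts: frozenset
    resolved: frozenset

    @property
    def key(self) -> str:
        return f"{self.structure_id}_{self.chain}"


def load_structure_record(
    path: str | Path,
    chain: str,
    column_map: dict[int, int],
    uniprot_id: str | None,
    state: str,
    class_label: str,
    L: int,
    gly_ca_proxy: bool = True,
) -> StructureRecord:
    """Read a PDB/mmCIF file (model 1, highest-occupancy altloc) and map
    side-chain heavy atoms onto MSA columns via ``column_map``
    (author residue number -> 1-based column)."""
    import gemmi

    st = gemmi.read_structure(str(path))
    st.setup_entities()
    model = st[0]  # first model only
    target = None
    for ch in model:
        if ch.name == chain:
            target = ch
            break
    if target is None:
        raise ValueError(f"chain {chain!r} not found in {path}")
    coords: dict[int, np.ndarray] = {}
    for residue in target:
        resnum = residue.seqid.num
        if resnum not in column_map:
            continue
        col = column_map[resnum]
        best: dict[str, tuple[float, np.ndarray]] = {}
        for atom in residue:
            if atom.element.is_hydrogen:
                continue
            name = atom.name
            if name in BACKBONE_ATOMS:
                if not (gly_ca_proxy and residue.name == "GLY" and name == "CA"):
                    continue
            occ = atom.occ
            pos = np.array([atom.pos.x, atom.pos.y, atom.pos.z])
            if name not in best or occ > best[name][0]:
                best[name] = (occ, pos)
        if best:
            coords[col] = np.stack([pos for _, pos in best.values()])
    return StructureRecord(
        structure_id=st.name or Path(path).stem,
        chain=chain,
        uniprot_id=uniprot_id,
        state=state,
        class_label=class_label,
        L=L,
        coords=coords,
    )


def contact_map(
    record: StructureRecord,
    cutoff: float = CONTACT_CUTOFF,
    min_separation: int = MIN_SEPARATION,
) -> StructureContacts:
    """Binary contacts: min side-chain heavy-atom distance strictly below
    ``cutoff`` and column separation strictly above ``min_separation``.
    Residues with no side-chain heavy atoms contribute no contacts."""
    cols = sorted(record.coords)
    contacts = set()
    for a_idx, i in enumerate(cols):
        xi = record.coords[i]
        if xi.size == 0:
            continue
        for j in cols[a_idx + 1:]:
            if j - i <= min_separation:
                continue
            xj = record.coords[j]
            if xj.size == 0:
                continue
            d2 = ((xi[:, None, :] - xj[None, :, :]) ** 2).sum(axis=2)
            if d2.min() < cutoff * cutoff:
                contacts.add((i, j))
    return StructureContacts(
        structure_id=record.structure_id,
        chain=record.chain,
        uniprot_id=record.uniprot_id,
        state=record.state,
        class_label=record.class_label,
        L=record.L,
        contacts=frozenset(contacts),
        resolved=frozenset(record.coords),
    )


def redundancy_weights(
    records: list[StructureContacts],
    missing_policy: str = "unique",
) -> np.ndarray:
    """w_n = 1 / u_n, where u_n counts chains sharing structure n's UniProt ID
    across the combined active+inactive cluster passed in ``records``.

    Chains without a UniProt ID are treated as unique (with a warning) under
    the default policy, or rejected under ``missing_policy="error"``.
    """
    counts: dict[str, int] = {}
    for rec in records:
        if rec.uniprot_id:
            counts[rec.uniprot_id] = counts.get(rec.uniprot_id, 0) + 1
        elif missing_policy == "error":
            raise ValueError(f"structure {rec.key} has no UniProt ID")
        else:
            logger.warning("structure %s has no UniProt ID; treated as unique", rec.key)
    w = np.empty(len(records))
    for n, rec in enumerate(records):
        w[n] = 1.0 / counts[rec.uniprot_id] if rec.uniprot_id else 1.0
    return w


@dataclass
class ConformationEnsemble:
    """Weighted contact frequencies c_ij of one conformational cluster.

    ``c`` and ``support_weight`` are dense L x L symmetric arrays; a pair is
    *defined* when at least one contributing structure resolves both columns
    (``support_weight > 0``).  Undefined pairs carry c = 0 and are flagged.
    """

    class_label: str
    state: str
    L: int
    c: np.ndarray
    support_weight: np.ndarray
    n_support: np.ndarray
    n_structures: int
    min_separation: int = MIN_SEPARATION

    @property
    def defined(self) -> np.ndarray:
        return self.support_weight > 0

    def frequency(self, i: int, j: int) -> float:
        return float(self.c[i - 1, j - 1])


@dataclass
class DeltaContactMap:
    """Contact-frequency difference Δc = c_active − c_inactive for one
    sequence class; antisymmetric under swapping the two ensembles."""

    class_label: str
    L: int
    delta: np.ndarray
    defined: np.ndarray
    min_separation: int = MIN_SEPARATION
    orientation: str = f"{ACTIVE} minus {INACTIVE}"

    def value(self, i: int, j: int) -> float:
        return float(self.delta[i - 1, j - 1])


def _separation_mask(L: int, min_separation: int) -> np.ndarray:
    idx = np.arange(L)
    return np.abs(idx[:, None] - idx[None, :]) > min_separation


def ensemble_frequencies(
    records: list[StructureContacts],
    weights: np.ndarray,
    state: str,
    denominator: str = "per_pair",
) -> ConformationEnsemble:
    """Weighted contact frequencies for one cluster.

    c_ij = Σ_n w_n δ_ij(n) / Σ_n' w_n', where (default ``per_pair``) both
    sums run only over structures resolving both columns — missing residues
    are missing data, not non-contacts.  ``denominator="global"`` instead
    divides the same numerator by the total cluster weight.
    """
    if not records:
        raise ValueError("empty structure list")
    bad = [r.key for r in records if r.state != state]
    if bad:
        raise ValueError(f"structures not in state {state!r}: {bad}")
    L = records[0].L
    if any(r.L != L for r in records):
        raise ValueError("inconsistent alignment widths among structures")
    weights = np.asarray(weights, dtype=float)
    if weights.shape != (len(records),):
        raise ValueError("one weight per structure required")
    num = np.zeros((L, L))
    den = np.zeros((L, L))
    n_support = np.zeros((L, L), dtype=int)
    for rec, w in zip(records, weights):
        r = np.zeros(L, dtype=bool)
        r[[c - 1 for c in rec.resolved]] = True
        pair_resolved = np.outer(r, r)
        den += w * pair_resolved
        n_support += pair_resolved
        for (i, j) in rec.contacts:
            num[i - 1, j - 1] += w
            num[j - 1, i - 1] += w
    sep = _separation_mask(L, MIN_SEPARATION)
    den *= sep
    num *= sep
    n_support *= sep
    if denominator == "global":
        total = weights.sum()
        c = num / total
        support = np.where(den > 0, total, 0.0)
    elif denominator == "per_pair":
        with np.errstate(invalid="ignore", divide="ignore"):
            c = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
        support = den
    else:
        raise ValueError(f"unknown denominator mode {denominator!r}")
    undefined = int((~(support > 0) & sep & np.triu(np.ones((L, L), bool), 1)).sum())
    if undefined:
        logger.warning(
            "%s/%s ensemble: %d pairs have no resolved support (treated as c=0)",
            records[0].class_label, state, undefined,
        )
    return ConformationEnsemble(
        class_label=records[0].class_label,
        state=state,
        L=L,
        c=c,
        support_weight=support,
        n_support=n_support,
        n_structures=len(records),
    )


def delta_contacts(
    active: ConformationEnsemble, inactive: ConformationEnsemble
) -> DeltaContactMap:
    """Δc = c_active − c_inactive for matching class ensembles."""
    if active.class_label != inactive.class_label:
        raise ValueError(
            f"class mismatch: {active.class_label!r} vs {inactive.class_label!r}"
        )
    if active.L != inactive.L:
        raise ValueError("alignment width mismatch between ensembles")
    return DeltaContactMap(
        class_label=active.class_label,
        L=active.L,
        delta=active.c - inactive.c,
        defined=active.defined & inactive.defined,
        orientation=f"{active.state} minus {inactive.state}",
    )


def write_contact_table(
    active: ConformationEnsemble,
    inactive: ConformationEnsemble,
    path: str | Path,
) -> None:
    """Round-trippable TSV of per-pair frequencies: i, j, c_active,
    c_inactive, delta, n_support (min of the two clusters' counts)."""
    dmap = delta_contacts(active, inactive)
    rows = []
    for i in range(active.L):
        for j in range(i + 1, active.L):
            if j - i <= active.min_separation:
                continue
            if active.n_support[i, j] == 0 and inactive.n_support[i, j] == 0:
                continue
            rows.append(
                (i + 1, j + 1, active.c[i, j], inactive.c[i, j],
                 dmap.delta[i, j],
                 int(min(active.n_support[i, j], inactive.n_support[i, j])))
            )
    df = pd.DataFrame(rows, columns=["i", "j", "c_active", "c_inactive", "delta", "n_support"])
    df.insert(0, "class", active.class_label)
    df.to_csv(path, sep="\t", index=False)


def read_delta_table(path: str | Path, L: int) -> DeltaContactMap:
    """Rebuild a DeltaContactMap from a contact-table TSV."""
    df = pd.read_csv(path, sep="\t")
    delta = np.zeros((L, L))
    defined = np.zeros((L, L), dtype=bool)
    i = df["i"].to_numpy() - 1
    j = df["j"].to_numpy() - 1
    d = df["delta"].to_numpy()
    sup = df["n_support"].to_numpy() > 0
    delta[i, j] = d
    delta[j, i] = d
    defined[i, j] = sup
    defined[j, i] = sup
    label = str(df["class"].iloc[0]) if "class" in df.columns and len(df) else "?"
    return DeltaContactMap(class_label=label, L=L, delta=delta, defined=defined)


def load_label_table(path: str | Path) -> pd.DataFrame:
    """Label table TSV: structure_id, chain, uniprot_id, state, class."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"structure_id", "chain", "uniprot_id", "state", "class"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"label table missing columns: {sorted(missing)}")
    bad = set(df["state"]) - set(STATES)
    if bad:
        raise ValueError(f"unknown conformational states: {sorted(bad)}")
    return df


def load_column_maps(path: str | Path) -> dict[tuple[str, str], dict[int, int]]:
    """Column-map TSV: structure_id, chain, author_residue_number, msa_column.

    Returns {(structure_id, chain): {author_resnum: msa_column}}; each map
    must be injective into the alignment columns.
    """
    df = pd.read_csv(path, sep="\t")
    maps: dict[tuple[str, str], dict[int, int]] = {}
    for (sid, ch), grp in df.groupby(["structure_id", "chain"]):
        m = dict(zip(grp["author_residue_number"].astype(int), grp["msa_column"].astype(int)))
        if len(set(m.values())) != len(m):
            raise ValueError(f"column map for {sid}/{ch} is not injective")
        maps[(str(sid), str(ch))] = m
    return maps
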