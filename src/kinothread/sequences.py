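"""Fixed-width kinase alignments: parsing, classification, gap filtering,
phylogenetic weights.

All MSA columns in public interfaces are 1-based.  The working alphabet has
21 symbols: the 20 standard amino acids plus the gap ``-``, so that sequences
index directly into a q=21 Potts coupling table.  Nonstandard residue codes
(X, B, Z, U, O) are mapped to gap by default; ``.`` is treated as a gap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import AlignIO, SeqIO

logger = logging.getLogger(__name__)

ALPHABET = "ACDEFGHIKLMNPQRSTVWY-"
GAP = "-"
GAP_CODE = ALPHABET.index(GAP)
#: codes with no standard one-letter state in the Potts alphabet
AMBIGUOUS_CODES = set("XBZUOJ")

# Side-chain van der Waals volumes in cubic angstroms.  The small/large split
# at 110 A^3 controls gatekeeper classification: residues below the threshold
# leave the back pocket accessible to type-II inhibitors.  Asp sits in neither
# canonical set; it is assigned 111 (large), adjacent to Asn.
SIDECHAIN_VOLUMES = {
    "G": 48.0, "A": 67.0, "S": 73.0, "C": 86.0, "P": 90.0, "T": 93.0,
    "V": 105.0, "D": 111.0, "N": 114.0, "H": 118.0, "I": 124.0, "L": 124.0,
    "M": 124.0, "K": 135.0, "F": 135.0, "E": 138.0, "Y": 141.0, "Q": 143.0,
    "R": 148.0, "W": 163.0,
}
GATEKEEPER_VOLUME_THRESHOLD = 110.0


def encode(seq: str, alphabet: str = ALPHABET, unknown_policy: str = "gap") -> np.ndarray:
    """Encode a sequence string into integer state codes.

    Parameters
    ----------
    unknown_policy:
        ``"gap"`` maps nonstandard codes (X, B, Z, U, O, J) to the gap state;
        ``"error"`` raises on them.
    """
    lut = np.full(128, -1, dtype=np.int16)
    for k, a in enumerate(alphabet):
        lut[ord(a)] = k
    gap_code = alphabet.index(GAP) if GAP in alphabet else -1
    if gap_code >= 0:
        lut[ord(".")] = gap_code
        if unknown_policy == "gap":
            for c in AMBIGUOUS_CODES:
                lut[ord(c)] = gap_code
    raw = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    codes = lut[raw]
    if (codes < 0).any():
        bad = int(np.argmax(codes < 0))
        raise ValueError(
            f"symbol {seq[bad]!r} at column {bad + 1} is not in the alphabet"
        )
    return codes.astype(np.uint8)


def decode(codes: np.ndarray, alphabet: str = ALPHABET) -> str:
    return "".join(alphabet[c] for c in codes)


@dataclass
class AlignedSequenceSet:
    """A fixed-width alignment with per-sequence class labels and weights.

    ``seqs`` is an N x L integer grid over ``alphabet``; ``weights`` lie in
    (0, 1] so the effective sample size ``n_eff = weights.sum()`` satisfies
    1 <= n_eff <= N.
    """

    ids: list[str]
    seqs: np.ndarray
    alphabet: str = ALPHABET
    classes: np.ndarray | None = None
    weights: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.seqs = np.asarray(self.seqs, dtype=np.uint8)
        if self.seqs.ndim != 2:
            raise ValueError("seqs must be a 2-D N x L grid")
        if len(self.ids) != self.seqs.shape[0]:
            raise ValueError("number of ids does not match number of sequences")
        if self.seqs.size and self.seqs.max() >= len(self.alphabet):
            raise ValueError("sequence codes exceed alphabet size")
        if self.weights is not None:
            self.weights = np.asarray(self.weights, dtype=float)
        if self.classes is not None:
            self.classes = np.asarray(self.classes, dtype=object)

    def __len__(self) -> int:
        return self.seqs.shape[0]

    @property
    def L(self) -> int:
        return self.seqs.shape[1]

    @property
    def q(self) -> int:
        return len(self.alphabet)

    @property
    def n_eff(self) -> float:
        w = self.effective_weights()
        return float(w.sum())

    def effective_weights(self) -> np.ndarray:
        if self.weights is None:
            return np.ones(len(self), dtype=float)
        return self.weights

    def gap_counts(self) -> np.ndarray:
        gap_code = self.alphabet.index(GAP)
        return (self.seqs == gap_code).sum(axis=1)

    def sequence(self, i: int) -> str:
        return decode(self.seqs[i], self.alphabet)

    def column(self, col: int) -> np.ndarray:
        """Residue codes at a 1-based MSA column."""
        if not 1 <= col <= self.L:
            raise IndexError(f"column {col} outside 1..{self.L}")
        return self.seqs[:, col - 1]

    def subset(self, index: Sequence[int] | np.ndarray) -> "AlignedSequenceSet":
        index = np.asarray(index)
        return AlignedSequenceSet(
            ids=[self.ids[i] for i in index],
            seqs=self.seqs[index],
            alphabet=self.alphabet,
            classes=None if self.classes is None else self.classes[index],
            weights=None if self.weights is None else self.weights[index],
            metadata=dict(self.metadata),
        )

    def class_members(self, label: str) -> np.ndarray:
        if self.classes is None:
            raise ValueError("class labels have not been assigned")
        return np.flatnonzero(self.classes == label)

    def write_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for i, sid in enumerate(self.ids):
                fh.write(f">{sid}\n{self.sequence(i)}\n")


def read_alignment(
    path: str | Path,
    format: str = "fasta",
    alphabet: str = ALPHABET,
    unknown_policy: str = "gap",
) -> AlignedSequenceSet:
    """Read a fixed-width alignment from FASTA or Stockholm.

    Symbols are uppercased; ``.`` and nonstandard codes map to gap (by
    default).  A ragged alignment is a hard error naming the offending
    record; an empty file is a hard error.
    """
    path = Path(path)
    fmt = format.lower()
    if fmt == "fasta":
        records = list(SeqIO.parse(str(path), "fasta"))
    elif fmt == "stockholm":
        try:
            records = list(AlignIO.read(str(path), "stockholm"))
        except ValueError as exc:
            raise ValueError(f"could not parse Stockholm alignment {path}: {exc}")
    else:
        raise ValueError(f"unsupported alignment format {format!r}")
    if not records:
        raise ValueError(f"alignment file {path} contains no sequences")
    widths = {len(r.seq) for r in records}
    if len(widths) > 1:
        mode = max(widths, key=lambda w: sum(len(r.seq) == w for r in records))
        bad = next(r for r in records if len(r.seq) != mode)
        raise ValueError(
            f"ragged alignment: record {bad.id!r} has width {len(bad.seq)}, "
            f"expected {mode}"
        )
    ids = [r.id for r in records]
    seqs = np.stack([encode(str(r.seq), alphabet, unknown_policy) for r in records])
    return AlignedSequenceSet(ids=ids, seqs=seqs, alphabet=alphabet)


def recode(aset: AlignedSequenceSet, alphabet: str) -> AlignedSequenceSet:
    """Re-encode a sequence set onto another alphabet (e.g. a reduced-state
    Potts alphabet).  Symbols absent from the target alphabet are a hard
    error naming the first offender."""
    if aset.alphabet == alphabet:
        return aset
    lut = np.full(len(aset.alphabet), -1, dtype=np.int16)
    for k, sym in enumerate(aset.alphabet):
        if sym in alphabet:
            lut[k] = alphabet.index(sym)
    codes = lut[aset.seqs.astype(np.int64)]
    if (codes < 0).any():
        row, col = np.argwhere(codes < 0)[0]
        raise ValueError(
            f"symbol {aset.alphabet[aset.seqs[row, col]]!r} in sequence "
            f"{aset.ids[row]!r} column {col + 1} is not in the target alphabet"
        )
    return replace(aset, seqs=codes.astype(np.uint8), alphabet=alphabet)


@dataclass(frozen=True)
class ClassificationRule:
    """TK/STK classification by diagnostic MSA columns.

    The canonical rule inspects the HRD+2, HRD+4 and APE-2 positions
    (columns 126, 128 and 165 of the 259-column kinase alignment): a kinase
    is a TK iff HRD+2 is Ala or Arg, HRD+4 is Arg and APE-2 is Trp; it is an
    STK iff HRD+2 is Lys and HRD+4 is not Arg.  Anything else — including a
    gap at any diagnostic column — is "other".  The column triple is
    configurable so that scaled-down synthetic alignments can carry the same
    predicate structure.
    """

    columns: tuple[int, int, int] = (126, 128, 165)
    tk_col1: frozenset[str] = frozenset({"A", "R"})
    tk_col2: str = "R"
    tk_col3: str = "W"
    stk_col1: str = "K"

    def classify(self, c1: str, c2: str, c3: str) -> str:
        if GAP in (c1, c2, c3):
            return "other"
        if c1 in self.tk_col1 and c2 == self.tk_col2 and c3 == self.tk_col3:
            return "TK"
        if c1 == self.stk_col1 and c2 != self.tk_col2:
            return "STK"
        return "other"


DEFAULT_RULE = ClassificationRule()


def classify_kinase(
    seq: str | np.ndarray,
    rule: ClassificationRule = DEFAULT_RULE,
    alphabet: str = ALPHABET,
) -> str:
    """Classify one aligned sequence as TK, STK or other."""
    if isinstance(seq, str):
        symbols = seq.upper()
    else:
        symbols = decode(np.asarray(seq, dtype=np.uint8), alphabet)
    need = max(rule.columns)
    if len(symbols) < need:
        raise ValueError(
            f"sequence length {len(symbols)} is shorter than diagnostic column {need}"
        )
    c1, c2, c3 = (symbols[c - 1] for c in rule.columns)
    return rule.classify(c1, c2, c3)


def classify_all(
    aset: AlignedSequenceSet, rule: ClassificationRule = DEFAULT_RULE
) -> AlignedSequenceSet:
    """Return a copy of the set with class labels assigned from the rule."""
    labels = np.array(
        [classify_kinase(aset.seqs[i], rule, aset.alphabet) for i in range(len(aset))],
        dtype=object,
    )
    return replace(aset, classes=labels)


def gatekeeper_class(
    residue: str,
    volumes: dict[str, float] = SIDECHAIN_VOLUMES,
    threshold: float = GATEKEEPER_VOLUME_THRESHOLD,
) -> str:
    """Classify a gatekeeper residue as ``small`` or ``large`` by side-chain
    volume; gaps and unknown symbols give ``unclassifiable``."""
    r = residue.upper()
    if r not in volumes:
        return "unclassifiable"
    return "small" if volumes[r] < threshold else "large"


def filter_gapped(aset: AlignedSequenceSet, max_gaps: int = 31) -> AlignedSequenceSet:
    """Drop sequences with more than ``max_gaps`` gap columns (order kept).

    The default retains sequences with at most 31 gaps, i.e. removes those
    with 32 or more.
    """
    keep = np.flatnonzero(aset.gap_counts() <= max_gaps)
    dropped = len(aset) - keep.size
    if dropped:
        logger.info("filter_gapped: removed %d of %d sequences", dropped, len(aset))
    return aset.subset(keep)


def pairwise_identity(seqs: np.ndarray, block: int = 256) -> np.ndarray:
    """Exact all-pairs fractional identity over all columns, gap counted as an
    ordinary 21st symbol.  O(N^2 L); intended for desk-scale N."""
    n, L = seqs.shape
    out = np.empty((n, n), dtype=float)
    for start in range(0, n, block):
        stop = min(start + block, n)
        eq = (seqs[start:stop, None, :] == seqs[None, :, :]).sum(axis=2)
        out[start:stop] = eq / L
    return out


def phylo_weights(
    aset: AlignedSequenceSet,
    divergence_threshold: float = 0.40,
    class_restricted: bool = True,
) -> np.ndarray:
    """Phylogenetic down-weights: w(s) = 1 / n(s), where n(s) counts the
    sequences in s's neighborhood (itself included).

    A neighbor is a sequence whose pairwise identity is at least
    ``1 - divergence_threshold`` (default: divergence <= 40%, identity >=
    60%).  With ``class_restricted`` the count runs only over sequences
    sharing s's class label.  The per-class effective sample size is the sum
    of the weights.
    """
    ident = pairwise_identity(aset.seqs)
    neighbor = ident >= (1.0 - divergence_threshold)
    if class_restricted:
        if aset.classes is None:
            raise ValueError("class_restricted weighting requires class labels")
        same = aset.classes[:, None] == aset.classes[None, :]
        neighbor = neighbor & same
    counts = neighbor.sum(axis=1)
    return 1.0 / counts


def with_weights(
    aset: AlignedSequenceSet,
    divergence_threshold: float = 0.40,
    class_restricted: bool = True,
) -> AlignedSequenceSet:
    w = phylo_weights(aset, divergence_threshold, class_restricted)
    return replace(aset, weights=w)


def write_sequence_report(
    aset: AlignedSequenceSet,
    path: str | Path,
    gatekeeper_column: int | None = None,
) -> None:
    """TSV report: id, class, n_gaps, gatekeeper residue/class, weight.

    Undefined cells are written as ``.``.
    """
    gaps = aset.gap_counts()
    weights = aset.effective_weights()
    with open(path, "w") as fh:
        fh.write("id\tclass\tn_gaps\tgatekeeper_residue\tgatekeeper_class\tweight\n")
        for i, sid in enumerate(aset.ids):
            cls = aset.classes[i] if aset.classes is not None else "."
            if gatekeeper_column is not None:
                res = aset.alphabet[aset.column(gatekeeper_column)[i]]
                gk = gatekeeper_class(res)
            else:
                res, gk = ".", "."
            fh.write(f"{sid}\t{cls}\t{gaps[i]}\t{res}\t{gk}\t{weights[i]:.8g}\n")
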