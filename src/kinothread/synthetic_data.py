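"""Planted-ground-truth generators for end-to-end pipeline tests.

The generator emulates the statistical structure the analysis assumes, at
desk scale and with no downloads: a Potts model with planted
conformation-sensitive couplings, two sequence classes whose bivariate
marginals differ at the planted pairs, and two structural ensembles per
class (as contact maps, not coordinates) whose contact difference Δc is
nonzero exactly at the planted pairs.  Structure redundancy (repeated
pseudo-UniProt IDs) and missing residues exercise the weighting and
per-pair normalization rules.  Fidelity is statistical, not biological: no
real kinase phylogeny or contact topology is imitated.

All randomness flows from one master seed through named substreams, so
regeneration is byte-identical and components can be regenerated
independently.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from kinothread.contacts import (
    ACTIVE,
    INACTIVE,
    ConformationEnsemble,
    DeltaContactMap,
    StructureContacts,
    delta_contacts,
    ensemble_frequencies,
    redundancy_weights,
    write_contact_table,
)
from kinothread.potts import PottsModel, gibbs_sample, pair_index, zero_gauge
from kinothread.sequences import (
    ALPHABET,
    AlignedSequenceSet,
    ClassificationRule,
    classify_kinase,
    phylo_weights,
)

#: state index favored by the low-penalty class at planted pairs
TK_STATE = 0
#: state index favored by the high-penalty class at planted pairs
STK_STATE = 1

_SUBSTREAMS = ("model", "sequences", "structures", "masks")


def default_alphabet(q: int) -> str:
    """An alphabet whose first states include the diagnostic letters
    (A, R, W, K, G) so scaled-down classes can carry real signatures."""
    if q == 21:
        return ALPHABET
    letters = "ARWKGCDEFHILMNPQSTVY"
    if q - 1 > len(letters):
        raise ValueError(f"q={q} too large for the synthetic alphabet")
    return letters[: q - 1] + "-"


def _substream_seeds(seed: int) -> dict[str, int]:
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(_SUBSTREAMS))
    return {
        name: int(child.generate_state(1)[0] % (2**31))
        for name, child in zip(_SUBSTREAMS, children)
    }


def scaled_rule(L: int) -> ClassificationRule:
    """Diagnostic columns for an alignment of width L: the canonical triple
    when it fits, otherwise a scaled-down triple with the same predicates."""
    if L >= 165:
        return ClassificationRule()
    if L < 25:
        raise ValueError("alignments shorter than 25 columns cannot host the rule")
    return ClassificationRule(columns=(10, 12, 20))


def make_potts(
    L: int,
    q: int = 6,
    n_planted: int = 6,
    contrast: float = 3.0,
    seed: int = 0,
    background: float = 0.05,
    exclude_columns: tuple[int, ...] = (),
) -> tuple[PottsModel, list[tuple[int, int]]]:
    """Ground-truth Potts model with planted conformation-sensitive pairs.

    Background couplings are small Gaussian noise; each planted pair gets a
    structured block of magnitude ``contrast``: the (STK_STATE, STK_STATE)
    cell is lowered (a favorable active-state anchor whose loss is
    penalized) and the (TK_STATE, TK_STATE) cell is raised.  The model is
    returned in the zero gauge.  Planted pairs respect |i−j| > 4 and avoid
    ``exclude_columns`` (1-based).
    """
    if L < 10:
        raise ValueError("need L >= 10")
    rng = np.random.default_rng(seed)
    excluded = set(exclude_columns)
    candidates = [
        (i, j)
        for i in range(1, L + 1)
        for j in range(i + 5, L + 1)
        if i not in excluded and j not in excluded
    ]
    if n_planted > len(candidates):
        raise ValueError(
            f"cannot plant {n_planted} pairs: only {len(candidates)} admissible"
        )
    pick = rng.choice(len(candidates), size=n_planted, replace=False)
    planted = sorted(candidates[k] for k in pick)
    P = L * (L - 1) // 2
    h = rng.normal(0.0, 0.1, size=(L, q))
    J = rng.normal(0.0, background, size=(P, q, q))
    for (i, j) in planted:
        p = pair_index(i - 1, j - 1, L)
        J[p, STK_STATE, STK_STATE] -= contrast
        J[p, TK_STATE, TK_STATE] += contrast
    model = zero_gauge(PottsModel(h=h, J=J, alphabet=default_alphabet(q)))
    return model, planted


def make_structures(
    class_label: str,
    state: str,
    n: int,
    L: int,
    planted_contacts: list[tuple[int, int]],
    flip_set: list[tuple[int, int]],
    redundancy: int = 1,
    missing_fraction: float = 0.0,
    seed: int = 0,
) -> tuple[list[StructureContacts], pd.DataFrame]:
    """Synthetic contact maps for one class/state cluster.

    Active-state maps carry ``planted_contacts``; in the inactive state the
    pairs in ``flip_set`` are toggled.  Pseudo-UniProt IDs repeat every
    ``redundancy`` chains (shared across states for the same class, so the
    combined-cluster weighting rule is exercised), and ``missing_fraction``
    masks random columns to exercise per-pair normalization.
    """
    rng = np.random.default_rng(seed)
    base = set(planted_contacts)
    if state == INACTIVE:
        base ^= set(flip_set)
    records = []
    rows = []
    for k in range(n):
        masked = set()
        if missing_fraction > 0:
            mask = rng.random(L) < missing_fraction
            masked = {int(c) + 1 for c in np.flatnonzero(mask)}
        resolved = frozenset(c for c in range(1, L + 1) if c not in masked)
        contacts = frozenset(
            (i, j) for (i, j) in base if i in resolved and j in resolved
        )
        sid = f"SYN{class_label}{'A' if state == ACTIVE else 'B'}{k:03d}"
        uid = f"UP_{class_label}_{k // redundancy:03d}"
        records.append(
            StructureContacts(
                structure_id=sid, chain="A", uniprot_id=uid, state=state,
                class_label=class_label, L=L, contacts=contacts, resolved=resolved,
            )
        )
        rows.append((sid, "A", uid, state, class_label))
    table = pd.DataFrame(
        rows, columns=["structure_id", "chain", "uniprot_id", "state", "class"]
    )
    return records, table


def make_two_class_msa(
    model: PottsModel,
    n_per_class: int,
    planted_pairs: list[tuple[int, int]],
    marginal_shift: float = 0.8,
    seed: int = 0,
    rule: ClassificationRule | None = None,
    burn_in: int = 60,
    thin: int = 2,
    class_x: str = "STK",
    class_y: str = "TK",
) -> AlignedSequenceSet:
    """Two sequence classes with controllably different bivariate marginals.

    Both classes are Gibbs samples from the model; diagnostic columns are
    overwritten with the TK/STK signatures, and with probability
    ``marginal_shift`` each planted pair is set to the class's favored state
    pair (STK_STATE for class X, TK_STATE for class Y).  Every sequence is
    recoverable by the classification rule.
    """
    rule = rule or scaled_rule(model.L)
    tk_sig = ("A", "R", "W")
    stk_sig = ("K", "K", "A")
    if rule.classify(*tk_sig) != "TK" or rule.classify(*stk_sig) != "STK":
        raise ValueError("class signatures inconsistent with the classification rule")
    for sym in tk_sig + stk_sig:
        if sym not in model.alphabet:
            raise ValueError(f"signature symbol {sym!r} missing from model alphabet")
    ss = np.random.SeedSequence(seed)
    seeds = [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(3)]
    sets = {}
    for label, sig, state, sub_seed in (
        (class_x, stk_sig, STK_STATE, seeds[0]),
        (class_y, tk_sig, TK_STATE, seeds[1]),
    ):
        sample = gibbs_sample(model, n_per_class, burn_in=burn_in, thin=thin, seed=sub_seed)
        S = sample.seqs.copy()
        for col, sym in zip(rule.columns, sig):
            S[:, col - 1] = model.alphabet.index(sym)
        sets[label] = S
    shift_rng = np.random.default_rng(seeds[2])
    for label, state in ((class_x, STK_STATE), (class_y, TK_STATE)):
        S = sets[label]
        for (i, j) in planted_pairs:
            hit = shift_rng.random(n_per_class) < marginal_shift
            S[hit, i - 1] = state
            S[hit, j - 1] = state
    seqs = np.concatenate([sets[class_x], sets[class_y]])
    ids = [f"{class_x}_{k:05d}" for k in range(n_per_class)] + [
        f"{class_y}_{k:05d}" for k in range(n_per_class)
    ]
    labels = np.array(
        [classify_kinase(s, rule, model.alphabet) for s in seqs], dtype=object
    )
    return AlignedSequenceSet(
        ids=ids, seqs=seqs, alphabet=model.alphabet, classes=labels
    )


@dataclass
class PlantedScenario:
    """A complete synthetic study: ground-truth model, planted pairs, the
    two-class alignment with weights, per-class Δc maps, and the expected
    outcome (sign of ΔΔE for class_x − class_y; top-pair set)."""

    seed: int
    model: PottsModel
    planted_pairs: list[tuple[int, int]]
    aset: AlignedSequenceSet
    dmap_x: DeltaContactMap
    dmap_y: DeltaContactMap
    ensembles: dict[tuple[str, str], ConformationEnsemble]
    label_table: pd.DataFrame
    class_x: str = "STK"
    class_y: str = "TK"
    expected_sign: int = 1
    rule: ClassificationRule | None = None

    @property
    def expected_top_pairs(self) -> set[tuple[int, int]]:
        return set(self.planted_pairs)


def make_scenario(
    seed: int = 0,
    L: int = 60,
    q: int = 6,
    n_per_class: int = 500,
    n_planted: int = 6,
    contrast: float = 3.0,
    marginal_shift: float = 0.8,
    n_structures: int = 8,
    redundancy: int = 2,
    missing_fraction: float = 0.05,
    compute_weights: bool = True,
) -> PlantedScenario:
    """Generate a full planted scenario from one master seed.

    Defaults are the desk-scale study conditions: L=60 columns, q=6 states,
    500 sequences per class, 6 planted pairs with strong contrast, 8
    structures per ensemble with 2-fold pseudo-UniProt redundancy and 5%
    missing residues.
    """
    seeds = _substream_seeds(seed)
    rule = scaled_rule(L)
    model, planted = make_potts(
        L, q, n_planted, contrast, seed=seeds["model"],
        exclude_columns=rule.columns,
    )
    aset = make_two_class_msa(
        model, n_per_class, planted, marginal_shift,
        seed=seeds["sequences"], rule=rule,
    )
    if compute_weights:
        aset.weights = phylo_weights(aset, class_restricted=True)
    ensembles: dict[tuple[str, str], ConformationEnsemble] = {}
    tables = []
    struct_rng = np.random.default_rng(seeds["structures"])
    dmaps = {}
    for class_label in ("STK", "TK"):
        cluster: list[StructureContacts] = []
        by_state: dict[str, list[StructureContacts]] = {}
        for state in (ACTIVE, INACTIVE):
            recs, table = make_structures(
                class_label, state, n_structures, L,
                planted_contacts=planted, flip_set=planted,
                redundancy=redundancy, missing_fraction=missing_fraction,
                seed=int(struct_rng.integers(2**31)),
            )
            by_state[state] = recs
            cluster.extend(recs)
            tables.append(table)
        weights = redundancy_weights(cluster)
        w_by_key = {r.key: w for r, w in zip(cluster, weights)}
        for state in (ACTIVE, INACTIVE):
            recs = by_state[state]
            w = np.array([w_by_key[r.key] for r in recs])
            ensembles[(class_label, state)] = ensemble_frequencies(recs, w, state)
        dmaps[class_label] = delta_contacts(
            ensembles[(class_label, ACTIVE)], ensembles[(class_label, INACTIVE)]
        )
    return PlantedScenario(
        seed=seed,
        model=model,
        planted_pairs=planted,
        aset=aset,
        dmap_x=dmaps["STK"],
        dmap_y=dmaps["TK"],
        ensembles=ensembles,
        label_table=pd.concat(tables, ignore_index=True),
        rule=rule,
    )


def write_scenario(scenario: PlantedScenario, outdir: str | Path) -> dict[str, Path]:
    """Write the scenario in the same formats the real pipeline reads:
    FASTA alignment, Potts container, per-class contact tables, label table."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "msa": outdir / "alignment.fasta",
        "model": outdir / "potts_model.h5",
        "labels": outdir / "structure_labels.tsv",
        "contacts_STK": outdir / "contacts_STK.tsv",
        "contacts_TK": outdir / "contacts_TK.tsv",
        "planted": outdir / "planted_pairs.tsv",
    }
    scenario.aset.write_fasta(paths["msa"])
    scenario.model.save(paths["model"])
    scenario.label_table.to_csv(paths["labels"], sep="\t", index=False)
    for cls in ("STK", "TK"):
        write_contact_table(
            scenario.ensembles[(cls, ACTIVE)],
            scenario.ensembles[(cls, INACTIVE)],
            paths[f"contacts_{cls}"],
        )
    pd.DataFrame(scenario.planted_pairs, columns=["i", "j"]).to_csv(
        paths["planted"], sep="\t", index=False
    )
    import yaml

    config = {
        "outdir": str(outdir / "run"),
        "msa": str(paths["msa"]),
        "potts_model": str(paths["model"]),
        "contact_table_x": str(paths["contacts_STK"]),
        "contact_table_y": str(paths["contacts_TK"]),
        "seed": scenario.seed,
    }
    paths["config"] = outdir / "config.yaml"
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(config, fh)
    return paths
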