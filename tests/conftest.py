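"""Shared fixtures: random Potts models, a desk-scale planted scenario, and
handcrafted coordinate fixtures (synthetic structures built atom by atom)."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pytest

from kinothread.potts import PottsModel
from kinothread.synthetic_data import make_scenario


def random_model(L: int, q: int, seed: int, scale: float = 1.0) -> PottsModel:
    rng = np.random.default_rng(seed)
    P = L * (L - 1) // 2
    alphabet = "ACDEFGHIKLMNPQRSTVWY-"[:q]
    return PottsModel(
        h=rng.normal(0, scale, (L, q)),
        J=rng.normal(0, scale, (P, q, q)),
        alphabet=alphabet,
    )


@pytest.fixture(scope="session")
def small_scenario():
    """Planted scenario at reduced scale for fast cross-module tests."""
    return make_scenario(seed=7, L=40, q=6, n_per_class=80, n_planted=4,
                         n_structures=6, redundancy=2, missing_fraction=0.05)


PDB_ATOM = (
    "ATOM  {serial:>5} {name:<4} {res:>3} {chain}{resseq:>4}    "
    "{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}          {el:>2}\n"
)


def write_pdb(path: Path, residues: list[dict]) -> None:
    """Write a minimal synthetic PDB from residue dicts:
    {"resseq": int, "resname": str, "atoms": [(name, element, x, y, z), ...]}."""
    serial = 1
    with open(path, "w") as fh:
        for res in residues:
            for (name, el, x, y, z) in res["atoms"]:
                fh.write(PDB_ATOM.format(
                    serial=serial, name=name, res=res["resname"], chain="A",
                    resseq=res["resseq"], x=x, y=y, z=z, occ=1.0, b=0.0, el=el,
                ))
                serial += 1
        fh.write("END\n")


def ala(resseq: int, cb: tuple[float, float, float]) -> dict:
    """Alanine with backbone near the CB site; only CB is a side-chain atom."""
    x, y, z = cb
    return {
        "resseq": resseq,
        "resname": "ALA",
        "atoms": [
            ("N", "N", x - 1.0, y, z + 2.0),
            ("CA", "C", x, y, z + 1.5),
            ("C", "C", x + 1.0, y, z + 2.0),
            ("O", "O", x + 2.0, y, z + 2.5),
            ("CB", "C", x, y, z),
        ],
    }


@pytest.fixture()
def pdb_writer(tmp_path):
    def _write(name: str, residues: list[dict]) -> Path:
        path = tmp_path / name
        write_pdb(path, residues)
        return path

    return _write
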