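"""Stage orchestration: classify → weights → contacts → thread → divergence
→ stats, with a run manifest.

Every stage reads its inputs from files and writes TSV outputs with header
rows into the run directory; no stage mutates another stage's outputs.  A
manifest (config values, input checksums, package version) makes a run
reproducible: identical inputs and seed give identical tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
import shutil
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from kinothread import __version__
from kinothread.contacts import (
    ACTIVE,
    INACTIVE,
    contact_map,
    delta_contacts,
    ensemble_frequencies,
    load_column_maps,
    load_label_table,
    load_structure_record,
    read_delta_table,
    redundancy_weights,
    write_contact_table,
)
from kinothread.potts import PottsModel
from kinothread.sequences import (
    classify_all,
    recode,
    filter_gapped,
    phylo_weights,
    read_alignment,
    write_sequence_report,
)
from kinothread.stats import welch_weighted
from kinothread.synthetic_data import scaled_rule
from kinothread.threadcalc import divergence

logger = logging.getLogger(__name__)

STAGES = ("classify", "weights", "contacts", "thread", "divergence", "stats")


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    """Paths, thresholds and the seed of one analysis run.

    Thresholds default to the canonical analysis constants: 6 Å contact
    cutoff, sequence separation > 4, 40% divergence neighborhood, 10 μM hit
    threshold, 110 Å³ gatekeeper volume, gap filter at 32 gaps.
    """

    outdir: str
    msa: str | None = None
    potts_model: str | None = None
    structure_labels: str | None = None
    structures_dir: str | None = None
    column_maps: str | None = None
    contact_table_x: str | None = None   # precomputed per-class contact tables
    contact_table_y: str | None = None
    affinity_table: str | None = None
    class_x: str = "STK"
    class_y: str = "TK"
    contact_cutoff: float = 6.0
    min_separation: int = 4
    divergence_threshold: float = 0.40
    hit_threshold_molar: float = 1e-5
    gatekeeper_volume: float = 110.0
    max_gaps: int = 31
    gatekeeper_column: int | None = None
    temperature: float = 298.15
    gap_mode: str = "model"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_dict(self) -> dict:
        return asdict(self)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _require(path: Path, stage: str, upstream: str) -> Path:
    if not path.exists():
        raise PipelineError(
            f"stage {stage!r} requires output of stage {upstream!r} "
            f"(missing file: {path})"
        )
    return path


def run_pipeline(config: RunConfig, stages: list[str] | None = None) -> dict:
    """Execute the requested stages in dependency order; returns the manifest."""
    stages = list(STAGES) if stages is None else [s for s in STAGES if s in set(stages)]
    unknown = set(stages or []) - set(STAGES)
    if unknown:
        raise PipelineError(f"unknown stages: {sorted(unknown)}")
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    inputs = {
        k: v for k, v in config.to_dict().items()
        if k.endswith(("msa", "model", "labels", "maps", "table", "table_x", "table_y"))
        and isinstance(v, str) and Path(v).is_file()
    }

    if "classify" in stages:
        _stage_classify(config, out)
    if "weights" in stages:
        _stage_weights(config, out)
    if "contacts" in stages:
        _stage_contacts(config, out)
    if "thread" in stages or "divergence" in stages:
        _stage_thread_divergence(config, out, run_thread="thread" in stages,
                                 run_divergence="divergence" in stages)
    if "stats" in stages:
        _stage_stats(config, out)

    manifest = {
        "version": __version__,
        "stages": stages,
        "config": config.to_dict(),
        "input_checksums": {k: _sha256(Path(v)) for k, v in inputs.items()},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _load_msa(config: RunConfig):
    if not config.msa:
        raise PipelineError("config.msa is required for this stage")
    fmt = "stockholm" if str(config.msa).endswith((".sto", ".stk")) else "fasta"
    return read_alignment(config.msa, format=fmt)


def _stage_classify(config: RunConfig, out: Path) -> None:
    aset = _load_msa(config)
    aset = filter_gapped(aset, config.max_gaps)
    aset = classify_all(aset, scaled_rule(aset.L))
    write_sequence_report(aset, out / "classified.tsv", config.gatekeeper_column)
    counts = pd.Series(aset.classes).value_counts().to_dict()
    logger.info("classified %d sequences: %s", len(aset), counts)


def _stage_weights(config: RunConfig, out: Path) -> None:
    _require(out / "classified.tsv", "weights", "classify")
    aset = _load_msa(config)
    aset = filter_gapped(aset, config.max_gaps)
    aset = classify_all(aset, scaled_rule(aset.L))
    aset.weights = phylo_weights(
        aset, divergence_threshold=config.divergence_threshold, class_restricted=True
    )
    write_sequence_report(aset, out / "weights.tsv", config.gatekeeper_column)


def _stage_contacts(config: RunConfig, out: Path) -> None:
    if config.contact_table_x and config.contact_table_y:
        shutil.copy(config.contact_table_x, out / f"contacts_{config.class_x}.tsv")
        shutil.copy(config.contact_table_y, out / f"contacts_{config.class_y}.tsv")
        return
    if not (config.structure_labels and config.structures_dir and config.column_maps):
        raise PipelineError(
            "stage 'contacts' requires either precomputed contact tables or "
            "structure_labels + structures_dir + column_maps"
        )
    labels = load_label_table(config.structure_labels)
    maps = load_column_maps(config.column_maps)
    model = PottsModel.load(_require(Path(config.potts_model), "contacts", "input"))
    sdir = Path(config.structures_dir)
    for cls in (config.class_x, config.class_y):
        sub = labels[labels["class"] == cls]
        records = []
        for _, row in sub.iterrows():
            sid, ch = str(row["structure_id"]), str(row["chain"])
            path = next(
                (p for ext in (".pdb", ".cif", ".ent") for p in [sdir / f"{sid}{ext}"] if p.exists()),
                None,
            )
            if path is None:
                logger.warning("no coordinate file for %s; skipped", sid)
                continue
            rec = load_structure_record(
                path, ch, maps[(sid, ch)], row["uniprot_id"], row["state"], cls, model.L
            )
            records.append(contact_map(rec, config.contact_cutoff, config.min_separation))
        weights = redundancy_weights(records)
        by_state = {
            s: ([r for r in records if r.state == s],
                np.array([w for r, w in zip(records, weights) if r.state == s]))
            for s in (ACTIVE, INACTIVE)
        }
        ens = {s: ensemble_frequencies(rs, ws, s) for s, (rs, ws) in by_state.items()}
        write_contact_table(ens[ACTIVE], ens[INACTIVE], out / f"contacts_{cls}.tsv")


def _stage_thread_divergence(
    config: RunConfig, out: Path, run_thread: bool, run_divergence: bool
) -> None:
    stage = "thread" if run_thread else "divergence"
    _require(out / "weights.tsv", stage, "weights")
    cx = _require(out / f"contacts_{config.class_x}.tsv", stage, "contacts")
    cy = _require(out / f"contacts_{config.class_y}.tsv", stage, "contacts")
    if not config.potts_model:
        raise PipelineError(f"stage {stage!r} requires config.potts_model")
    model = PottsModel.load(config.potts_model)
    aset = recode(_load_msa(config), model.alphabet)
    meta = pd.read_csv(out / "weights.tsv", sep="\t", index_col="id")
    keep = [i for i, sid in enumerate(aset.ids) if sid in meta.index]
    aset = aset.subset(keep)
    aset.classes = meta.loc[aset.ids, "class"].to_numpy(dtype=object)
    aset.weights = meta.loc[aset.ids, "weight"].to_numpy(dtype=float)
    dmap_x = read_delta_table(cx, model.L)
    dmap_y = read_delta_table(cy, model.L)
    res = divergence(
        model, aset, dmap_x, dmap_y, config.class_x, config.class_y, config.gap_mode
    )
    if run_thread:
        ids_x = [aset.ids[i] for i in aset.class_members(config.class_x)]
        ids_y = [aset.ids[i] for i in aset.class_members(config.class_y)]
        df = pd.DataFrame(
            {"id": ids_x + ids_y,
             "class": [config.class_x] * len(ids_x) + [config.class_y] * len(ids_y),
             "dE": np.concatenate([res.energies_x, res.energies_y]),
             "weight": np.concatenate([res.weights_x, res.weights_y])}
        )
        df.to_csv(out / "thread_energies.tsv", sep="\t", index=False, float_format="%.10g")
    if run_divergence:
        res.report().to_csv(
            out / "divergence_pairs.tsv", sep="\t", index=False, float_format="%.10g"
        )
        summary = pd.DataFrame(
            [{
                "class_x": config.class_x, "class_y": config.class_y,
                "mean_x": res.mean_x, "mean_y": res.mean_y, "ddE": res.ddE,
                "decomposition_sum": res.decomposition_sum,
                "n_x": len(res.energies_x), "n_y": len(res.energies_y),
                "n_eff_x": res.weights_x.sum(), "n_eff_y": res.weights_y.sum(),
            }]
        )
        summary.to_csv(out / "divergence_summary.tsv", sep="\t", index=False,
                       float_format="%.10g")


def _stage_stats(config: RunConfig, out: Path) -> None:
    path = _require(out / "thread_energies.tsv", "stats", "thread")
    df = pd.read_csv(path, sep="\t")
    gx = df[df["class"] == config.class_x]
    gy = df[df["class"] == config.class_y]
    res = welch_weighted(
        gx["dE"].to_numpy(), gy["dE"].to_numpy(),
        gx["weight"].to_numpy(), gy["weight"].to_numpy(),
    )
    pd.DataFrame(
        [{
            "t": res.t, "df": res.df, "p_one_tailed": res.p_one_tailed,
            "p_label": res.p_label,
            "mean_x": res.mean_x, "mean_y": res.mean_y,
            "se_x": res.se_x, "se_y": res.se_y,
            "n_eff_x": res.n_eff_x, "n_eff_y": res.n_eff_y,
        }]
    ).to_csv(out / "welch.tsv", sep="\t", index=False, float_format="%.10g")
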