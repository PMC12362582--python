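"""End-to-end orchestration: descriptors -> ensembles -> relations.

Each stage is independently skippable; a stage whose inputs are missing
raises a dependency error before any file is written. Every run emits a
JSON manifest (package version, configuration hash, per-output row
counts, seed) so results are traceable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import pandas as pd

from . import __version__
from . import config as cfg
from . import io as pio
from .chromatography import compute_descriptors
from .ensembles import (
    SamplingMethod,
    SolventClass,
    summarize_ensemble,
)
from .errors import DependencyError
from .pharmacokinetics import Route, oral_bioavailability
from .relations import linear_relation

log = logging.getLogger("protacprofiler")

#: default relation suite: the key inverse ER/lipophilicity line plus the
#: polarity cross-check
DEFAULT_RELATIONS = (
    ("logk80_plrps", "er"),
    ("delta_logkw_iam", "epsa"),
    ("er", "f_percent"),
)


@dataclass
class PipelineInputs:
    retention_csv: Optional[Path] = None
    compounds_csv: Optional[Path] = None
    pk_csv: Optional[Path] = None
    conformer_descriptors_csv: Optional[Path] = None


def _config_hash(config: cfg.PipelineConfig) -> str:
    payload = json.dumps(dataclasses.asdict(config), sort_keys=True, default=list)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(
    inputs: PipelineInputs,
    out_dir: str | Path,
    *,
    config: cfg.PipelineConfig = cfg.DEFAULT_CONFIG,
    stages: tuple[str, ...] = ("descriptors", "pk", "ensemble", "relations"),
) -> dict:
    """Run the requested stages and write their outputs under ``out_dir``.

    Returns the manifest dictionary (also written as ``manifest.json``).
    Dependencies are validated up front so a failing run leaves no
    partial outputs.
    """
    out_dir = Path(out_dir)
    requested = tuple(stages)

    # validate dependencies before any work
    if "descriptors" in requested and inputs.retention_csv is None:
        raise DependencyError("descriptors stage needs a retention table")
    if "pk" in requested and inputs.pk_csv is None:
        raise DependencyError("pk stage needs a concentration-time table")
    if "ensemble" in requested and inputs.conformer_descriptors_csv is None:
        raise DependencyError("ensemble stage needs per-frame descriptors")
    if "relations" in requested and inputs.compounds_csv is None:
        raise DependencyError("relations stage needs a compound table")
    if "relations" in requested and inputs.compounds_csv is not None:
        if not Path(inputs.compounds_csv).exists():
            raise DependencyError(f"missing input {inputs.compounds_csv}")
        if pd.read_csv(inputs.compounds_csv).empty:
            raise DependencyError("compound table is empty")

    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "outputs": {},
    }

    if "descriptors" in requested:
        measurements = pio.read_retention_csv(inputs.retention_csv)
        meta = {}
        if inputs.compounds_csv is not None and Path(inputs.compounds_csv).exists():
            meta_df = pd.read_csv(inputs.compounds_csv)
            if "epsa" in meta_df.columns or "tpsa" in meta_df.columns:
                meta = {
                    str(r["compound_id"]): {
                        "epsa": r.get("epsa"),
                        "tpsa": r.get("tpsa"),
                    }
                    for _, r in meta_df.iterrows()
                }
        records = compute_descriptors(measurements, meta, config=config)
        path = out_dir / "descriptors.csv"
        pio.write_descriptors_csv(records, path)
        manifest["outputs"]["descriptors.csv"] = len(records)
        log.info("descriptors: %d compounds", len(records))

    if "pk" in requested:
        profiles = pio.read_pk_csv(inputs.pk_csv)
        by_compound: dict[str, dict[Route, object]] = {}
        for p in profiles:
            by_compound.setdefault(p.compound_id, {})[p.route] = p
        rows = []
        for cid, arms in sorted(by_compound.items()):
            if Route.ORAL not in arms or Route.IV not in arms:
                warnings.warn(f"{cid}: missing a dosing arm; skipped")
                continue
            res = oral_bioavailability(arms[Route.ORAL], arms[Route.IV],
                                       config=config)
            rows.append(
                {
                    "compound_id": cid,
                    "auc_oral": res.auc_oral,
                    "auc_iv": res.auc_iv,
                    "auc_dn_oral": res.auc_dn_oral,
                    "auc_dn_iv": res.auc_dn_iv,
                    "f_percent": res.f_percent,
                    "f_class": res.f_class.value,
                }
            )
        path = out_dir / "bioavailability.csv"
        pd.DataFrame(rows).to_csv(path, index=False)
        manifest["outputs"]["bioavailability.csv"] = len(rows)
        log.info("pk: %d compounds", len(rows))

    if "ensemble" in requested:
        grouped = pio.read_conformer_descriptors_csv(
            inputs.conformer_descriptors_csv
        )
        summaries = []
        for (cid, solvent, method), frames in sorted(grouped.items()):
            solvent_class = (
                SolventClass.POLAR
                if solvent.lower() in ("polar", "water")
                else SolventClass.NONPOLAR
            )
            summaries.append(
                summarize_ensemble(
                    frames,
                    cid,
                    solvent_class,
                    solvent_label=solvent,
                    method=SamplingMethod(method),
                    x_bin_width=config.rgyr_bin_width,
                    y_bin_width=config.psa_bin_width,
                    rgyr_threshold=config.rgyr_folded_threshold,
                    psa_threshold=config.psa_lowpolar_threshold,
                )
            )
        path = out_dir / "ensemble_summary.csv"
        pio.write_ensemble_summary_csv(summaries, path)
        manifest["outputs"]["ensemble_summary.csv"] = len(summaries)
        log.info("ensemble: %d summaries", len(summaries))

    if "relations" in requested:
        records = pio.read_compounds_csv(inputs.compounds_csv)
        results = []
        for x_field, y_field in DEFAULT_RELATIONS:
            try:
                results.append(linear_relation(records, x_field, y_field))
            except Exception as exc:  # insufficient data for this relation
                log.warning("relation %s ~ %s skipped: %s", y_field, x_field, exc)
        path = out_dir / "relations.csv"
        pio.write_relations_csv(results, path)
        manifest["outputs"]["relations.csv"] = len(results)
        log.info("relations: %d fits", len(results))

    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
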