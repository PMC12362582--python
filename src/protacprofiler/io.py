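"""Readers and writers for the pipeline's file formats.

CSV schemas (comma-separated, UTF-8, mandatory headers, empty field =
missing):

* ``retention.csv``   compound_id,system,organic_fraction,ph,t_r,t_0
* ``pk.csv``          compound_id,route,dose,time_h,conc_ng_ml
* ``compounds.csv``   Table-shaped per-compound metadata/ADME fields
* ``descriptors.csv`` one row per compound, full descriptor suite
* ``conformer_descriptors.csv`` / ``ensemble_summary.csv`` / ``relations.csv``

Structure files: multi-model PDB (MODEL/ENDMDL delimited, CONECT records
used for bonds when present, element taken from the element column or
the atom name) and multi-frame XYZ (repeated ``n / comment / element x y
z`` blocks, no bonds).
"""

from __future__ import annotations

import math
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .chromatography import (
    ChromatographicSystem,
    DescriptorRecord,
    RetentionMeasurement,
)
from .conformers import Conformer, ConformerDescriptors
from .ensembles import EnsembleSummary
from .errors import FormatParseError
from .pharmacokinetics import PkProfile, Route
from .relations import CompoundRecord, RelationResult


class StructureFormat(str, Enum):
    PDB_MULTIMODEL = "PDB_MULTIMODEL"
    XYZ_MULTIFRAME = "XYZ_MULTIFRAME"


# ------------------------------------------------------------------- CSV in

def read_retention_csv(path: str | Path) -> list[RetentionMeasurement]:
    df = pd.read_csv(path)
    required = {"compound_id", "system", "organic_fraction", "ph", "t_r", "t_0"}
    missing = required - set(df.columns)
    if missing:
        raise FormatParseError(f"{path}: missing columns {sorted(missing)}")
    return [
        RetentionMeasurement(
            compound_id=str(row.compound_id),
            system=ChromatographicSystem(row.system),
            organic_fraction=float(row.organic_fraction),
            ph=float(row.ph),
            t_r=float(row.t_r),
            t_0=float(row.t_0),
        )
        for row in df.itertuples(index=False)
    ]


def read_pk_csv(path: str | Path) -> list[PkProfile]:
    df = pd.read_csv(path)
    required = {"compound_id", "route", "dose", "time_h", "conc_ng_ml"}
    missing = required - set(df.columns)
    if missing:
        raise FormatParseError(f"{path}: missing columns {sorted(missing)}")
    profiles = []
    for (cid, route), grp in df.groupby(["compound_id", "route"], sort=False):
        grp = grp.sort_values("time_h")
        profiles.append(
            PkProfile(
                compound_id=str(cid),
                route=Route(route),
                dose=float(grp["dose"].iloc[0]),
                timepoints=tuple(
                    zip(grp["time_h"].astype(float), grp["conc_ng_ml"].astype(float))
                ),
            )
        )
    return profiles


_COMPOUND_FIELDS = (
    "series", "n_linker_methyls", "f_percent", "er", "papp", "solubility",
    "clearance", "epsa", "tpsa", "brlogd", "logk80_plrps", "logkw_iam",
    "delta_logkw_iam", "chamelogk", "etr",
)


def read_compounds_csv(path: str | Path) -> list[CompoundRecord]:
    df = pd.read_csv(path)
    if "compound_id" not in df.columns:
        raise FormatParseError(f"{path}: missing compound_id column")
    records = []
    for _, row in df.iterrows():
        kwargs = {}
        for name in _COMPOUND_FIELDS:
            if name in df.columns:
                v = row[name]
                if isinstance(v, float) and math.isnan(v):
                    continue
                if name == "n_linker_methyls":
                    kwargs[name] = int(v)
                elif name == "series":
                    kwargs[name] = str(v)
                else:
                    kwargs[name] = float(v)
        records.append(CompoundRecord(compound_id=str(row["compound_id"]), **kwargs))
    return records


# ------------------------------------------------------------------ CSV out

def write_descriptors_csv(records: Sequence[DescriptorRecord],
                          path: str | Path) -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "compound_id": r.compound_id,
                "logk60_rp18": r.logk60_rp18,
                "brlogd": r.brlogd,
                "logk80_plrps": r.logk80_plrps,
                "logkw_iam": r.logkw_iam,
                "clogkw_iam": r.clogkw_iam,
                "delta_logkw_iam": r.delta_logkw_iam,
                "chamelogk": r.chamelogk,
                "epsa": r.epsa,
                "tpsa": r.tpsa,
                "etr": r.etr,
                "ionization_class": r.ionization_class.value,
                "flags": ";".join(r.flags),
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def write_conformer_descriptors_csv(
    rows: Iterable[tuple[str, str, str, ConformerDescriptors]],
    path: str | Path,
) -> None:
    """Rows are (compound_id, solvent, method, descriptors)."""
    pd.DataFrame(
        [
            {
                "compound_id": cid,
                "solvent": solvent,
                "method": method,
                "frame_id": d.frame_id,
                "r_gyr": d.r_gyr,
                "psa_0": d.psa_0,
                "psa_14": d.psa_14,
                "sasa_total": d.sasa_total,
                "n_imhb": d.n_imhb,
            }
            for cid, solvent, method, d in rows
        ]
    ).to_csv(path, index=False)


def read_conformer_descriptors_csv(
    path: str | Path,
) -> dict[tuple[str, str, str], list[ConformerDescriptors]]:
    df = pd.read_csv(path)
    out: dict[tuple[str, str, str], list[ConformerDescriptors]] = {}
    for row in df.itertuples(index=False):
        key = (str(row.compound_id), str(row.solvent), str(row.method))
        out.setdefault(key, []).append(
            ConformerDescriptors(
                frame_id=int(row.frame_id),
                r_gyr=float(row.r_gyr),
                psa_0=float(row.psa_0),
                psa_14=float(row.psa_14),
                sasa_total=float(row.sasa_total),
                n_imhb=int(row.n_imhb),
            )
        )
    return out


def write_ensemble_summary_csv(summaries: Sequence[EnsembleSummary],
                               path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "compound_id": s.compound_id,
                "solvent": s.solvent.value,
                "solvent_label": s.solvent_label,
                "method": s.method.value,
                "n_frames": s.n_frames,
                "median_rgyr": s.median_rgyr,
                "median_psa14": s.median_psa14,
                "iqr_rgyr": s.iqr_rgyr,
                "iqr_psa14": s.iqr_psa14,
                "density_max_frame": s.density_max_frame,
                "fraction_folded_lowpolar": s.fraction_folded_lowpolar,
            }
            for s in summaries
        ]
    ).to_csv(path, index=False)


def write_relations_csv(results: Sequence[RelationResult],
                        path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "x": r.x_name,
                "y": r.y_name,
                "slope": r.slope,
                "intercept": r.intercept,
                "r2": r.r2,
                "n_used": r.n_used,
                "excluded": ";".join(r.excluded_ids),
            }
            for r in results
        ]
    ).to_csv(path, index=False)


# ------------------------------------------------------------ structure I/O

def read_conformers(
    path: str | Path, fmt: StructureFormat | str | None = None
) -> list[Conformer]:
    """Read a conformer ensemble; format inferred from the suffix when
    not given."""
    path = Path(path)
    if fmt is None:
        fmt = (
            StructureFormat.XYZ_MULTIFRAME
            if path.suffix.lower() == ".xyz"
            else StructureFormat.PDB_MULTIMODEL
        )
    fmt = StructureFormat(fmt)
    if fmt is StructureFormat.PDB_MULTIMODEL:
        return _read_pdb_multimodel(path)
    return _read_xyz_multiframe(path)


def _pdb_element(line: str, lineno: int) -> str:
    elem = line[76:78].strip() if len(line) >= 78 else ""
    if not elem:
        # PDB convention: columns 13-16 hold the atom name, element first
        name = line[12:16].strip()
        elem = "".join(c for c in name if c.isalpha())[:2]
        if len(elem) == 2 and elem[1].islower():
            pass
        elif elem[:1]:
            elem = elem[0]
    if not elem:
        raise FormatParseError(f"line {lineno}: cannot resolve element")
    return elem.capitalize() if len(elem) == 2 else elem.upper()


def _read_pdb_multimodel(path: Path) -> list[Conformer]:
    frames: list[Conformer] = []
    elements: list[str] = []
    coords: list[list[float]] = []
    bonds: set[tuple[int, int]] = set()
    serial_to_index: dict[int, int] = {}
    in_model = False
    saw_model_records = False

    def flush(frame_id: int) -> None:
        if not elements:
            raise FormatParseError(f"{path}: empty model {frame_id}")
        frames.append(
            Conformer(
                elements=list(elements),
                coords=np.array(coords),
                bonds=sorted(bonds) if bonds else None,
                frame_id=frame_id,
            )
        )

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec == "MODEL":
                if in_model:
                    raise FormatParseError(
                        f"line {lineno}: MODEL without closing ENDMDL"
                    )
                in_model = True
                saw_model_records = True
                elements, coords, bonds = [], [], set()
                serial_to_index = {}
            elif rec == "ENDMDL":
                if not in_model:
                    raise FormatParseError(f"line {lineno}: stray ENDMDL")
                flush(len(frames))
                in_model = False
            elif rec in ("ATOM", "HETATM"):
                try:
                    serial = int(line[6:11])
                    x = float(line[30:38])
                    y = float(line[38:46])
                    z = float(line[46:54])
                except ValueError as exc:
                    raise FormatParseError(f"line {lineno}: {exc}") from exc
                serial_to_index[serial] = len(elements)
                elements.append(_pdb_element(line, lineno))
                coords.append([x, y, z])
            elif rec == "CONECT":
                try:
                    serials = [int(s) for s in line[6:].split()]
                except ValueError as exc:
                    raise FormatParseError(f"line {lineno}: {exc}") from exc
                if serials:
                    a = serial_to_index.get(serials[0])
                    for s in serials[1:]:
                        b = serial_to_index.get(s)
                        if a is not None and b is not None and a != b:
                            bonds.add((min(a, b), max(a, b)))
    if in_model:
        raise FormatParseError(f"{path}: truncated final MODEL block")
    if not saw_model_records and elements:
        flush(0)  # single-model file without MODEL/ENDMDL wrapping
    if not frames:
        raise FormatParseError(f"{path}: no frames found")
    return frames


def _read_xyz_multiframe(path: Path) -> list[Conformer]:
    frames: list[Conformer] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    lineno = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError as exc:
            raise FormatParseError(f"line {i + 1}: expected atom count") from exc
        elements, coords = [], []
        for j in range(n):
            lineno = i + 2 + j
            if lineno >= len(lines):
                raise FormatParseError(f"line {lineno + 1}: truncated frame")
            parts = lines[lineno].split()
            if len(parts) < 4:
                raise FormatParseError(f"line {lineno + 1}: malformed atom line")
            elements.append(parts[0])
            try:
                coords.append([float(parts[1]), float(parts[2]), float(parts[3])])
            except ValueError as exc:
                raise FormatParseError(f"line {lineno + 1}: {exc}") from exc
        frames.append(
            Conformer(elements=elements, coords=np.array(coords),
                      bonds=None, frame_id=len(frames))
        )
        i += 2 + n
    if not frames:
        raise FormatParseError(f"{path}: no frames found")
    return frames


def write_pdb_multimodel(frames: Sequence[Conformer], path: str | Path) -> None:
    """Multi-model PDB with HETATM records and CONECT bonds (frame 0's)."""
    with open(path, "w") as fh:
        for m, frame in enumerate(frames, start=1):
            fh.write(f"MODEL     {m:4d}\n")
            for i, (elem, xyz) in enumerate(zip(frame.elements, frame.coords),
                                            start=1):
                name = f"{elem}{i}"[:4]
                fh.write(
                    f"HETATM{i:5d} {name:<4s} LIG A   1    "
                    f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
                    f"  1.00  0.00          {elem:>2s}\n"
                )
            if frame.bonds:
                for a, b in frame.bonds:
                    fh.write(f"CONECT{a + 1:5d}{b + 1:5d}\n")
            fh.write("ENDMDL\n")
        fh.write("END\n")


def write_xyz_multiframe(frames: Sequence[Conformer], path: str | Path) -> None:
    with open(path, "w") as fh:
        for frame in frames:
            fh.write(f"{frame.n_atoms}\nframe {frame.frame_id}\n")
            for elem, xyz in zip(frame.elements, frame.coords):
                fh.write(f"{elem} {xyz[0]:.6f} {xyz[1]:.6f} {xyz[2]:.6f}\n")
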