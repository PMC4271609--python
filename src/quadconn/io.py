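"""File formats: NIfTI volumes, electrode/event/score TSV tables, YAML config.

Voxel indices in every TSV are 0-based; world coordinates are mm under the
NIfTI affine.  FOD fields are stored as 4D NIfTI with one volume per
direction, ordered as :data:`quadconn.structural.OFFSETS` (lexicographic over
``{-1,0,1}^3`` minus the origin); the offset table is written alongside as a
TSV so the ordering is self-describing on disk.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .errors import FormatError
from .grid import VolumeGrid
from .phantom import Contact, ElectrodeTable
from .rsfmri import BOLDSeries
from .structural import OFFSETS, FODField


# -- NIfTI ---------------------------------------------------------------------

def write_nifti(data: np.ndarray, grid: VolumeGrid, path, tr_s: float | None = None) -> None:
    """Write a 3D/4D volume as float32 NIfTI with the grid's affine."""
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), np.asarray(grid.affine))
    if tr_s is not None and data.ndim == 4:
        zooms = list(grid.voxel_size) + [float(tr_s)]
        img.header.set_zooms(zooms)
        img.header.set_xyzt_units("mm", "sec")
    nib.save(img, str(path))


def read_nifti(path) -> tuple[np.ndarray, VolumeGrid, float | None]:
    """Read a NIfTI volume; returns (data, grid, tr_s-or-None)."""
    try:
        img = nib.load(str(path))
        data = np.asarray(img.get_fdata())
    except Exception as err:  # nibabel raises several exception types
        raise FormatError(f"{path}: not a readable NIfTI file ({err})") from err
    affine = img.affine
    zooms = img.header.get_zooms()
    voxel_size = tuple(float(z) for z in zooms[:3])
    grid = VolumeGrid(tuple(int(s) for s in data.shape[:3]), voxel_size, affine)
    tr = float(zooms[3]) if data.ndim == 4 and len(zooms) > 3 and zooms[3] > 0 else None
    return data, grid, tr


def read_bold(path) -> BOLDSeries:
    data, grid, tr = read_nifti(path)
    if data.ndim != 4:
        raise FormatError(f"{path}: expected 4D BOLD, got shape {data.shape}")
    return BOLDSeries(grid, data, tr if tr else 1.0)


def write_fod(fod: FODField, path) -> None:
    write_nifti(fod.amplitudes, fod.grid, path)
    p = Path(str(path))
    stem = p.name.split(".")[0]
    table = pd.DataFrame(OFFSETS, columns=["di", "dj", "dk"])
    table.index.name = "volume"
    table.to_csv(p.parent / f"{stem}_directions.tsv", sep="\t")


def read_fod(path) -> FODField:
    data, grid, _ = read_nifti(path)
    if data.ndim != 4 or data.shape[3] != 26:
        raise FormatError(f"{path}: FOD must be 4D with 26 direction volumes")
    return FODField.normalized(grid, data)


# -- electrode / event tables --------------------------------------------------

ELECTRODE_COLUMNS = ["id", "x_mm", "y_mm", "z_mm", "role"]


def write_electrodes(table: ElectrodeTable, path) -> None:
    rows = [
        {"id": c.contact_id, "x_mm": c.world_mm[0], "y_mm": c.world_mm[1],
         "z_mm": c.world_mm[2], "role": c.role}
        for c in table.contacts
    ]
    pd.DataFrame(rows, columns=ELECTRODE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_electrodes(path, grid: VolumeGrid) -> ElectrodeTable:
    """Parse an electrode TSV; errors carry the offending line number."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in ELECTRODE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    if len(df) == 0:
        raise FormatError(f"{path}: electrode table has no rows")
    seen: dict[str, int] = {}
    contacts: list[Contact] = []
    for i, row in df.iterrows():
        line = i + 2  # 1-based, after the header
        cid = row["id"]
        if cid in seen:
            raise FormatError(f"{path}:{line}: duplicate contact id {cid!r} "
                              f"(first at line {seen[cid]})")
        seen[cid] = line
        try:
            world = tuple(float(row[c]) for c in ("x_mm", "y_mm", "z_mm"))
        except (TypeError, ValueError) as err:
            raise FormatError(f"{path}:{line}: non-numeric coordinate") from err
        vox = tuple(int(v) for v in grid.world_to_index(world))
        contacts.append(Contact(cid, world, vox, str(row["role"]), vox))
    return ElectrodeTable(contacts)


def write_events(onsets_s: np.ndarray, polarity: np.ndarray, path) -> None:
    pd.DataFrame({"onset_s": onsets_s, "polarity": polarity}).to_csv(
        path, sep="\t", index=False
    )


def read_events(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    for col in ("onset_s", "polarity"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    return df


def write_scores(scores: dict[str, float], path, window_tag: str, n_used: dict | None = None) -> None:
    rows = [
        {"contact": k, "window": window_tag, "score_uv": v,
         "n_used": (n_used or {}).get(k, "")}
        for k, v in scores.items()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_value_table(path) -> dict[str, float]:
    """Generic per-target value TSV: columns (target, value)."""
    df = pd.read_csv(path, sep="\t")
    if "target" not in df.columns or "value" not in df.columns:
        raise FormatError(f"{path}: need columns 'target' and 'value'")
    return dict(zip(df["target"].astype(str), df["value"].astype(float)))


def write_value_table(values: dict, path) -> None:
    pd.DataFrame(
        {"target": list(values.keys()), "value": list(values.values())}
    ).to_csv(path, sep="\t", index=False)


# -- config / provenance -------------------------------------------------------

def write_config(obj: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=True)


def read_config(path) -> dict:
    with open(path) as fh:
        obj = yaml.safe_load(fh)
    if not isinstance(obj, dict):
        raise FormatError(f"{path}: config must be a mapping")
    return obj


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class ProvenanceRecord:
    """What produced an artifact: stage, parameters and input hashes."""

    stage: str
    parameters: dict
    input_hashes: dict = field(default_factory=dict)
    software_version: str = ""

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"stage": self.stage, "parameters": self.parameters,
                 "input_hashes": self.input_hashes,
                 "software_version": self.software_version},
                fh, indent=1, sort_keys=True, default=str,
            )
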