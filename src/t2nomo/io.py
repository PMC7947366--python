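"""NIfTI and table I/O with JSON sidecars.

Per-subject images are NIfTI-1 with an identity affine (the analysis lives
entirely in voxel space): the echo stack is 4D with the 4th axis indexing
echoes, the mask a 3D integer volume. Acquisition metadata (echo times)
and the label table travel in JSON sidecars next to the images. Tabular
interchange is CSV with explicit column schemas; models are JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import LabelTableError, MetadataError, SchemaError
from .phantom import MultiEchoVolume, VOIMask
from .relaxometry import T2Map

__all__ = [
    "write_echo_stack", "read_echo_stack",
    "write_mask", "read_mask",
    "write_t2map", "read_t2map",
    "read_table", "write_table",
]

_AFFINE = np.eye(4)

FEATURE_TABLE_KEY = ["patient_id", "side"]


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".json")
    return path.with_suffix(".json")


def write_echo_stack(path: str | Path, volume: MultiEchoVolume) -> Path:
    """4D NIfTI (x, y, z, echo) plus a sidecar with ``echo_times_ms``."""
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(volume.data, dtype=np.float32), _AFFINE)
    nib.save(img, str(path))
    _sidecar_path(path).write_text(json.dumps(
        {"echo_times_ms": [float(t) for t in volume.echo_times_ms]},
        indent=2))
    return path


def read_echo_stack(path: str | Path) -> MultiEchoVolume:
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise MetadataError(f"missing sidecar {sidecar.name}")
    meta = json.loads(sidecar.read_text())
    if "echo_times_ms" not in meta:
        raise MetadataError(f"sidecar {sidecar.name} lacks echo_times_ms")
    data = np.asanyarray(nib.load(str(path)).dataobj).astype(float)
    if data.ndim != 4:
        raise ValueError(f"{path.name}: expected a 4D echo stack")
    te = np.asarray(meta["echo_times_ms"], dtype=float)
    if data.shape[3] != len(te):
        raise ValueError(
            f"{path.name}: {data.shape[3]} volumes but {len(te)} echo times listed")
    return MultiEchoVolume(data, te)


def write_mask(path: str | Path, mask: VOIMask) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(mask.labels, dtype=np.int16), _AFFINE)
    nib.save(img, str(path))
    table = {str(lab): {"muscle": m, "side": s}
             for lab, (m, s) in sorted(mask.label_table.items())}
    _sidecar_path(path).write_text(json.dumps({"label_table": table}, indent=2))
    return path


def read_mask(path: str | Path) -> VOIMask:
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise MetadataError(f"missing sidecar {sidecar.name}")
    meta = json.loads(sidecar.read_text())
    if "label_table" not in meta:
        raise MetadataError(f"sidecar {sidecar.name} lacks label_table")
    labels = np.asanyarray(nib.load(str(path)).dataobj).astype(np.int16)
    table = {int(k): (v["muscle"], v["side"])
             for k, v in meta["label_table"].items()}
    present = set(np.unique(labels)) - {0}
    unlisted = sorted(present - set(table))
    if unlisted:
        raise LabelTableError(
            f"{path.name}: labels {unlisted} present in the volume but "
            f"absent from the label table")
    return VOIMask(labels, table)


def write_t2map(path_stem: str | Path, t2map: T2Map) -> dict[str, Path]:
    """Write t2/r2/valid volumes as ``<stem>_t2.nii.gz`` etc."""
    stem = Path(path_stem)
    out = {}
    for key, arr, dtype in (("t2", t2map.t2_ms, np.float32),
                            ("r2", t2map.r_squared, np.float32),
                            ("valid", t2map.valid, np.uint8)):
        p = stem.parent / f"{stem.name}_{key}.nii.gz"
        nib.save(nib.Nifti1Image(np.asarray(arr, dtype=dtype), _AFFINE), str(p))
        out[key] = p
    return out


def read_t2map(path_stem: str | Path) -> T2Map:
    stem = Path(path_stem)
    vols = {}
    for key in ("t2", "r2", "valid"):
        p = stem.parent / f"{stem.name}_{key}.nii.gz"
        if not p.exists():
            raise MetadataError(f"missing T2-map component {p.name}")
        vols[key] = np.asanyarray(nib.load(str(p)).dataobj)
    valid = vols["valid"].astype(bool)
    t2 = vols["t2"].astype(float)
    s0 = np.full_like(t2, np.nan)  # S0 is not persisted; not used downstream
    return T2Map(t2_ms=t2, s0=s0, r_squared=vols["r2"].astype(float),
                 valid=valid)


def write_table(path: str | Path, df: pd.DataFrame) -> Path:
    path = Path(path)
    df.to_csv(path, index=False)
    return path


def read_table(path: str | Path, required: list[str] | None = None
               ) -> pd.DataFrame:
    df = pd.read_csv(path)
    if required:
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise SchemaError(f"{Path(path).name}: missing column(s) {missing}")
    return df
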