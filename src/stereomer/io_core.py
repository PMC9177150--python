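"""Reading and writing every external format the tool touches.

All other modules consume only in-memory domain types; this module is the
single boundary to disk.  World coordinates are millimetres, RAS; NIfTI
volumes are reoriented to RAS on read; no operation silently rescales.

Formats
-------
* Plans: a documented JSON schema (see :func:`write_plan` for the layout).
* MER segments: WAV (PCM16/float32) or single-column CSV, each with a JSON
  sidecar (``channel``, ``dtt_mm``, ``fs_hz``) or one manifest for the set.
* Regions: NIfTI label volumes or closed STL/PLY meshes.
* Streamlines: TRK or JSON polylines, vertices in world mm.
* Tables: CSV (pandas).
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import trimesh
from scipy.io import wavfile

from .exceptions import SchemaError
from .models import AnatomyModel, Fiducial, PlanRecord, SegmentRecord

__all__ = [
    "read_plan", "write_plan",
    "read_segments", "write_segment",
    "read_region", "write_volume", "make_mesh",
    "read_streamlines", "write_streamlines",
    "read_table", "write_table",
]


# -- plans ---------------------------------------------------------------

_REQUIRED_PLAN_FIELDS = ("patient_id", "side", "target_frame", "ring_deg",
                         "arc_deg", "mounting", "fiducials", "bengun")


def read_plan(path: str | Path) -> PlanRecord:
    """Read a stereotactic plan from its JSON schema.

    Raises :class:`SchemaError` naming the missing/invalid field.
    """
    with open(path) as fh:
        doc = json.load(fh)
    for key in _REQUIRED_PLAN_FIELDS:
        if key not in doc:
            raise SchemaError(f"plan file missing required field {key!r}")
    fids = []
    for f in doc["fiducials"]:
        for key in ("name", "point_image", "point_frame"):
            if key not in f:
                raise SchemaError(f"fiducial entry missing field {key!r}")
        fids.append(Fiducial(f["name"], f["point_image"], f["point_frame"]))
    bengun = doc["bengun"]
    if "configuration" not in bengun or "channels" not in bengun:
        raise SchemaError("bengun must carry 'configuration' and 'channels'")
    return PlanRecord(
        patient_id=doc["patient_id"], side=doc["side"],
        target_frame=doc["target_frame"], ring_deg=float(doc["ring_deg"]),
        arc_deg=float(doc["arc_deg"]), mounting=doc["mounting"], fiducials=fids,
        bengun_config=bengun["configuration"], channels=tuple(bengun["channels"]))


def write_plan(plan: PlanRecord, path: str | Path) -> None:
    doc = {
        "patient_id": plan.patient_id,
        "side": plan.side,
        "target_frame": list(plan.target_frame),
        "ring_deg": plan.ring_deg,
        "arc_deg": plan.arc_deg,
        "mounting": plan.mounting,
        "fiducials": [
            {"name": f.name, "point_image": list(f.point_image),
             "point_frame": list(f.point_frame)} for f in plan.fiducials
        ],
        "bengun": {"configuration": plan.bengun_config, "channels": list(plan.channels)},
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


# -- MER segments --------------------------------------------------------

def _read_signal(path: Path, fs_sidecar: float) -> tuple[float, np.ndarray]:
    if path.suffix.lower() == ".wav":
        fs, data = wavfile.read(path)
        if abs(fs - fs_sidecar) > 1e-6:
            raise SchemaError(f"{path.name}: WAV header fs {fs} Hz does not match "
                              f"sidecar fs {fs_sidecar} Hz")
        if data.dtype == np.int16:
            data = data.astype(float)  # µV per LSB is the writer's convention
        return float(fs), np.asarray(data, float)
    if path.suffix.lower() == ".csv":
        vals = pd.read_csv(path, header=None).to_numpy(float).ravel()
        return fs_sidecar, vals
    raise SchemaError(f"unsupported segment format {path.suffix!r}")


def _sidecar_meta(entry: dict, source: str) -> tuple[str, float, float]:
    for key in ("channel", "dtt_mm", "fs_hz"):
        if key not in entry:
            raise SchemaError(f"{source}: sidecar missing field {key!r}")
    return entry["channel"], float(entry["dtt_mm"]), float(entry["fs_hz"])


def read_segments(dir_or_manifest: str | Path) -> list[SegmentRecord]:
    """Read all MER segments below a directory or from a manifest JSON.

    A directory is scanned for ``*.wav``/``*.csv`` with a matching
    ``<stem>.json`` sidecar; a manifest JSON has a ``segments`` list of
    ``{file, channel, dtt_mm, fs_hz}``.  The result is sorted by channel and
    descending dtt (drive order).
    """
    root = Path(dir_or_manifest)
    entries: list[tuple[Path, dict]] = []
    if root.is_dir():
        for p in sorted(root.iterdir()):
            if p.suffix.lower() not in (".wav", ".csv"):
                continue
            sidecar = p.with_suffix(".json")
            if not sidecar.exists():
                raise SchemaError(f"segment {p.name} has no sidecar {sidecar.name}")
            with open(sidecar) as fh:
                entries.append((p, json.load(fh)))
    else:
        with open(root) as fh:
            manifest = json.load(fh)
        if "segments" not in manifest:
            raise SchemaError("manifest missing 'segments' list")
        for e in manifest["segments"]:
            if "file" not in e:
                raise SchemaError("manifest entry missing 'file'")
            entries.append((root.parent / e["file"], e))
    records = []
    for path, meta in entries:
        channel, dtt, fs = _sidecar_meta(meta, path.name)
        fs_actual, samples = _read_signal(path, fs)
        records.append(SegmentRecord(channel, dtt, fs_actual, samples))
    records.sort(key=lambda r: (r.channel, -r.dtt_mm))
    return records


def write_segment(record: SegmentRecord, path: str | Path, fmt: str = "wav") -> None:
    """Write one segment plus its JSON sidecar (float32 WAV or CSV)."""
    path = Path(path)
    if fmt == "wav":
        wavfile.write(path.with_suffix(".wav"),
                      int(round(record.fs_hz)), record.samples.astype(np.float32))
        out = path.with_suffix(".wav")
    elif fmt == "csv":
        np.savetxt(path.with_suffix(".csv"), record.samples, fmt="%.6f")
        out = path.with_suffix(".csv")
    else:
        raise ValueError(f"unknown format {fmt!r}")
    with open(out.with_suffix(".json"), "w") as fh:
        json.dump({"channel": record.channel, "dtt_mm": record.dtt_mm,
                   "fs_hz": record.fs_hz}, fh)


# -- regions and volumes -------------------------------------------------

def read_region(path: str | Path, name: str = "region", label: int | None = None,
                space: str = "patient") -> AnatomyModel:
    """Read an anatomical region from a NIfTI label volume or an STL/PLY mesh.

    NIfTI volumes are reoriented to RAS; a multi-label volume requires
    ``label`` to pick the region of interest.
    """
    path = Path(path)
    if path.suffix.lower() in (".stl", ".ply"):
        mesh = trimesh.load(path, force="mesh")
        if len(mesh.faces) and mesh.faces.max() >= len(mesh.vertices):
            raise SchemaError(f"mesh {path.name}: face indices exceed vertex count")
        return AnatomyModel(name, mesh=mesh, space=space)
    img = nib.as_closest_canonical(nib.load(path))
    data = np.asarray(img.dataobj)
    uniq = np.unique(data)
    if label is not None:
        data = data == label
    elif not np.all(np.isin(uniq, (0, 1))):
        raise SchemaError(f"volume {path.name} is not binary and no label id was given "
                          f"(labels present: {uniq[:10]})")
    return AnatomyModel(name, volume=data.astype(bool), affine=img.affine, space=space)


def write_volume(data: np.ndarray, affine: np.ndarray, path: str | Path) -> None:
    """Write a volume (density, counts, label) as NIfTI with the given RAS affine."""
    nib.save(nib.Nifti1Image(np.asarray(data, np.float32), np.asarray(affine, float)),
             str(path))


def make_mesh(vertices: np.ndarray, faces: np.ndarray) -> trimesh.Trimesh:
    """Construct a validated triangle mesh (consistent indices, watertight)."""
    vertices = np.asarray(vertices, float)
    faces = np.asarray(faces, int)
    if len(faces) and (faces.min() < 0 or faces.max() >= len(vertices)):
        raise SchemaError("face indices inconsistent with vertex count")
    mesh = trimesh.Trimesh(vertices=vertices, faces=faces, process=False)
    if not mesh.is_watertight:
        raise SchemaError("mesh is not closed")
    return mesh


# -- streamlines ---------------------------------------------------------

def read_streamlines(path: str | Path) -> list[np.ndarray]:
    """Read a streamline bundle (TRK or JSON polylines) as world-mm polylines."""
    path = Path(path)
    if path.suffix.lower() == ".trk":
        tractogram = nib.streamlines.load(str(path))
        return [np.asarray(s, float) for s in tractogram.streamlines]
    with open(path) as fh:
        doc = json.load(fh)
    if "streamlines" not in doc:
        raise SchemaError("streamline JSON missing 'streamlines' list")
    return [np.asarray(line, float) for line in doc["streamlines"]]


def write_streamlines(polylines: list[np.ndarray], path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".trk":
        t = nib.streamlines.Tractogram([np.asarray(p, np.float32) for p in polylines],
                                       affine_to_rasmm=np.eye(4))
        nib.streamlines.save(t, str(path))
    else:
        with open(path, "w") as fh:
            json.dump({"streamlines": [np.asarray(p, float).tolist() for p in polylines]}, fh)


# -- tables --------------------------------------------------------------

def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False)
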