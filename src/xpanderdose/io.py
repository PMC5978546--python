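"""File formats: volumes (NRRD/MetaImage), structures, measurements, plans.

NRRD is the canonical volume format (text header, arbitrary key-value
metadata); MetaImage is supported as an alternative.  Every volume written
carries its unit tag, the package version and, when given, the seed and a
config hash, so any artifact can be traced back to the run that made it.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import SimpleITK as sitk
import yaml

from . import __version__
from .engine import BeamSpec, Fluence, PlanSpec, WedgeSpec, arc_to_beams
from .measurements import DepthDoseRecord, MeasurementSet, PointMeasurement
from .structures import StructureSet
from .volume import VoxelVolume

_VOLUME_EXTENSIONS = (".nrrd", ".mha", ".mhd")
_META_PREFIX = "xpanderdose_"


def write_volume(volume: VoxelVolume, path, metadata: dict | None = None) -> None:
    """Write a volume as NRRD or MetaImage with provenance metadata."""
    path = Path(path)
    if path.suffix.lower() not in _VOLUME_EXTENSIONS:
        raise ValueError(f"unsupported volume extension {path.suffix!r}; use {_VOLUME_EXTENSIONS}")
    img = sitk.GetImageFromArray(np.ascontiguousarray(volume.values.T))
    img.SetSpacing(tuple(volume.spacing))
    img.SetOrigin(tuple(volume.origin))
    img.SetMetaData(_META_PREFIX + "unit", volume.unit)
    img.SetMetaData(_META_PREFIX + "frame", volume.frame)
    img.SetMetaData(_META_PREFIX + "version", __version__)
    for key, value in (metadata or {}).items():
        img.SetMetaData(_META_PREFIX + str(key), str(value))
    sitk.WriteImage(img, str(path), useCompression=False)


def read_volume(path) -> VoxelVolume:
    """Read an NRRD or MetaImage volume; the unit tag is restored."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"volume file not found: {path}")
    if path.suffix.lower() not in _VOLUME_EXTENSIONS:
        raise ValueError(f"unsupported volume extension {path.suffix!r}; use {_VOLUME_EXTENSIONS}")
    try:
        img = sitk.ReadImage(str(path))
    except RuntimeError as exc:
        raise ValueError(f"cannot read volume {path}: {exc}") from exc
    values = sitk.GetArrayFromImage(img).T
    unit = img.GetMetaData(_META_PREFIX + "unit") if img.HasMetaDataKey(_META_PREFIX + "unit") else "density"
    frame = img.GetMetaData(_META_PREFIX + "frame") if img.HasMetaDataKey(_META_PREFIX + "frame") else "LPS"
    return VoxelVolume(
        origin=np.array(img.GetOrigin()),
        spacing=np.array(img.GetSpacing()),
        values=np.asarray(values, dtype=float),
        unit=unit,
        frame=frame,
    )


def volume_metadata(path) -> dict:
    """Provenance key-value pairs stored with a volume."""
    img = sitk.ReadImage(str(path))
    return {
        k[len(_META_PREFIX):]: img.GetMetaData(k)
        for k in img.GetMetaDataKeys()
        if k.startswith(_META_PREFIX)
    }


def config_hash(obj) -> str:
    """Short stable hash of a JSON-serializable configuration."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


# ---------------------------------------------------------------------------
# Structures


def write_structures(structures: StructureSet, path, fmt: str = "json") -> None:
    if fmt == "json":
        structures.save_json(path)
    elif fmt == "dicom-rtstruct":
        write_rtstruct(structures, path)
    else:
        raise ValueError(f"unsupported structure format {fmt!r}")


def read_structures(path) -> StructureSet:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"structure file not found: {path}")
    return StructureSet.load_json(path)


def write_rtstruct(structures: StructureSet, path) -> None:
    """Minimal DICOM RT-STRUCT export: one ROI per structure, one
    CLOSED_PLANAR contour per slice polygon."""
    import pydicom
    from pydicom.dataset import Dataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, generate_uid

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = pydicom.uid.UID("1.2.840.10008.5.1.4.1.1.481.3")
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = Dataset()
    ds.file_meta = meta
    ds.SOPClassUID = meta.MediaStorageSOPClassUID
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "RTSTRUCT"
    ds.StructureSetLabel = "xpanderdose"
    ds.PatientName = "phantom"
    ds.PatientID = "phantom"
    ds.StructureSetROISequence = []
    ds.ROIContourSequence = []
    for number, roi in enumerate(structures.rois, start=1):
        ssr = Dataset()
        ssr.ROINumber = number
        ssr.ROIName = roi.name
        ssr.ROIGenerationAlgorithm = "AUTOMATIC"
        ds.StructureSetROISequence.append(ssr)
        rc = Dataset()
        rc.ReferencedROINumber = number
        rc.ContourSequence = []
        for z, verts in roi.slices:
            contour = Dataset()
            contour.ContourGeometricType = "CLOSED_PLANAR"
            contour.NumberOfContourPoints = len(verts)
            data = []
            for x, y in verts:
                data += [float(x), float(y), float(z)]
            contour.ContourData = data
            rc.ContourSequence.append(contour)
        ds.ROIContourSequence.append(rc)
    ds.save_as(str(path), enforce_file_format=True)


# ---------------------------------------------------------------------------
# Measurement CSVs


def write_point_measurements(ms: MeasurementSet, path) -> None:
    rows = [
        {
            "label": p.label,
            "x_mm": p.position_mm[0],
            "y_mm": p.position_mm[1],
            "z_mm": p.position_mm[2],
            "dose": p.dose,
            "sd": p.sd,
        }
        for p in ms.points
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_point_measurements(path) -> MeasurementSet:
    frame = pd.read_csv(path)
    points = [
        PointMeasurement(
            label=str(r["label"]),
            position_mm=(r["x_mm"], r["y_mm"], r["z_mm"]),
            dose=None if pd.isna(r.get("dose")) else float(r["dose"]),
            sd=None if pd.isna(r.get("sd")) else float(r["sd"]),
        )
        for _, r in frame.iterrows()
    ]
    return MeasurementSet(points=points)


def write_depth_dose(ms: MeasurementSet, path) -> None:
    rows = []
    for rec in ms.depth_dose:
        for d, v in zip(rec.depths_mm, rec.doses):
            rows.append({"setup": rec.setup, "energy_mv": rec.energy_mv, "depth_mm": d, "dose": v})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_depth_dose(path) -> MeasurementSet:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"measurement file not found: {path}")
    frame = pd.read_csv(path)
    records = []
    for (setup, energy), grp in frame.groupby(["setup", "energy_mv"], sort=True):
        grp = grp.sort_values("depth_mm")
        records.append(
            DepthDoseRecord(
                setup=str(setup),
                energy_mv=int(energy),
                depths_mm=grp["depth_mm"].to_numpy(),
                doses=grp["dose"].to_numpy(),
            )
        )
    return MeasurementSet(depth_dose=records)


# ---------------------------------------------------------------------------
# Plan files


def read_plan(path) -> PlanSpec:
    """Load a plan description (YAML).

    Schema::

        prescription_gy: 1.0
        fractions: 1
        norm_point: [0, 0, 0]        # optional
        beams:
          - energy_mv: 6
            gantry_deg: 90
            ssd_mm: 907              # or sad_mm
            isocenter: [0, 0, 0]     # optional
            field_size: [100, 100]
            wedge: {angle_deg: 20, orientation: 1}   # optional
            weight: 1.0
            fluence: {file: flu.csv, spacing_mm: 5}  # optional
          - arc: {start_deg: 90, stop_deg: 270, step_deg: 10}
            energy_mv: 6
            sad_mm: 1000
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"plan file not found: {path}")
    payload = yaml.safe_load(path.read_text())
    beams: list[BeamSpec] = []
    for entry in payload["beams"]:
        entry = dict(entry)
        arc = entry.pop("arc", None)
        wedge = entry.pop("wedge", None)
        fluence = entry.pop("fluence", None)
        kwargs = dict(
            energy_mv=int(entry.get("energy_mv", 6)),
            gantry_deg=float(entry.get("gantry_deg", 0.0)),
            field_size=tuple(entry.get("field_size", (100.0, 100.0))),
            weight=float(entry.get("weight", 1.0)),
        )
        if "ssd_mm" in entry:
            kwargs["ssd_mm"] = float(entry["ssd_mm"])
            kwargs["sad_mm"] = None
        elif "sad_mm" in entry:
            kwargs["sad_mm"] = float(entry["sad_mm"])
        if entry.get("isocenter") is not None:
            kwargs["isocenter"] = tuple(float(c) for c in entry["isocenter"])
        if wedge:
            kwargs["wedge"] = WedgeSpec(
                angle_deg=float(wedge["angle_deg"]), orientation=int(wedge.get("orientation", 1))
            )
        if fluence:
            values = pd.read_csv(path.parent / fluence["file"], header=None).to_numpy(dtype=float)
            kwargs["fluence"] = Fluence(values=values, spacing_mm=float(fluence.get("spacing_mm", 5.0)))
        template = BeamSpec(**kwargs)
        if arc:
            beams.extend(
                arc_to_beams(
                    float(arc["start_deg"]), float(arc["stop_deg"]), float(arc.get("step_deg", 10.0)), template
                )
            )
        else:
            beams.append(template)
    return PlanSpec(
        beams=tuple(beams),
        prescription_gy=float(payload.get("prescription_gy", 1.0)),
        fractions=int(payload.get("fractions", 1)),
        norm_point=tuple(payload["norm_point"]) if payload.get("norm_point") else None,
    )
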