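"""Named regions of interest as per-slice closed polygons.

A :class:`StructureSet` is a list of ROIs; each ROI carries an optional
density override (g/cm^3) and an override priority (higher wins where ROIs
overlap), plus one closed planar polygon per axial slice, stored open
(first vertex not repeated) and closed only on serialization.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np


@dataclasses.dataclass
class ROI:
    name: str
    override_density: float | None = None
    priority: int = 0
    slices: list[tuple[float, np.ndarray]] = dataclasses.field(default_factory=list)

    def __post_init__(self) -> None:
        cleaned = []
        for z, verts in self.slices:
            verts = np.asarray(verts, dtype=float)
            if verts.ndim != 2 or verts.shape[1] != 2:
                raise ValueError(f"ROI {self.name!r}: vertices must be an Nx2 array")
            cleaned.append((float(z), verts))
        self.slices = cleaned

    @property
    def n_vertices(self) -> int:
        return sum(len(v) for _, v in self.slices)


@dataclasses.dataclass
class StructureSet:
    rois: list[ROI] = dataclasses.field(default_factory=list)

    def __post_init__(self) -> None:
        names = [r.name for r in self.rois]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate ROI names: {names}")

    def __iter__(self):
        return iter(self.rois)

    def __len__(self) -> int:
        return len(self.rois)

    def names(self) -> list[str]:
        return [r.name for r in self.rois]

    def __getitem__(self, name: str) -> ROI:
        for roi in self.rois:
            if roi.name == name:
                return roi
        raise KeyError(name)

    def __contains__(self, name: str) -> bool:
        return any(r.name == name for r in self.rois)

    def add(self, roi: ROI) -> None:
        if roi.name in self:
            raise ValueError(f"ROI {roi.name!r} already present")
        self.rois.append(roi)

    # -- JSON serialization ----------------------------------------------

    def to_json_dict(self) -> dict:
        rois = []
        for roi in self.rois:
            slices = []
            for z, verts in roi.slices:
                closed = np.vstack([verts, verts[:1]])  # close on write only
                slices.append({"z": z, "vertices": closed.tolist()})
            rois.append(
                {
                    "name": roi.name,
                    "override_density": roi.override_density,
                    "priority": roi.priority,
                    "slices": slices,
                }
            )
        return {"rois": rois}

    @classmethod
    def from_json_dict(cls, payload: dict) -> "StructureSet":
        rois = []
        for entry in payload.get("rois", []):
            slices = []
            for sl in entry["slices"]:
                verts = np.asarray(sl["vertices"], dtype=float)
                if len(verts) > 1 and np.allclose(verts[0], verts[-1]):
                    verts = verts[:-1]
                slices.append((float(sl["z"]), verts))
            rois.append(
                ROI(
                    name=entry["name"],
                    override_density=entry.get("override_density"),
                    priority=int(entry.get("priority", 0)),
                    slices=slices,
                )
            )
        return cls(rois=rois)

    def save_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_json_dict(), indent=1))

    @classmethod
    def load_json(cls, path) -> "StructureSet":
        return cls.from_json_dict(json.loads(Path(path).read_text()))


def structure_from_mask(name: str, mask: np.ndarray, grid, override_density=None, priority: int = 0) -> ROI:
    """Trace per-slice contours of a boolean mask into an ROI.

    Intended for phantom construction; contouring is at grid resolution
    (marching squares on the voxel lattice), not sub-voxel.
    """
    from skimage import measure

    slices: list[tuple[float, np.ndarray]] = []
    xs, ys, zs = (grid.axis_coords(i) for i in range(3))
    for iz, z in enumerate(zs):
        plane = mask[:, :, iz].astype(float)
        if not plane.any():
            continue
        for contour in measure.find_contours(plane, 0.5):
            verts = np.column_stack(
                [
                    xs[0] + contour[:, 0] * grid.spacing[0],
                    ys[0] + contour[:, 1] * grid.spacing[1],
                ]
            )
            if np.linalg.norm(verts[0] - verts[-1]) < 1e-9:
                verts = verts[:-1]
            if len(verts) >= 3:
                slices.append((float(z), verts))
    return ROI(name=name, override_density=override_density, priority=priority, slices=slices)
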