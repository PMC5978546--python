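"""Regular voxel grids: the substrate for phantoms, CT volumes and dose.

World coordinates are right-handed, LPS-like, in millimetres: +x left,
+y posterior, +z superior.  Axial slices are perpendicular to z.  A volume
stores one scalar per voxel, indexed ``values[ix, iy, iz]``, with the value
located at the voxel *center*; the volume extent is half-open.  The ``unit``
tag distinguishes CT numbers (``"HU"``), mass density (``"density"``,
g/cm^3) and dose (``"Gy"``).
"""

from __future__ import annotations

import dataclasses

import numpy as np

VALID_UNITS = ("HU", "density", "Gy")


@dataclasses.dataclass
class VoxelVolume:
    """A regular 3D grid of scalar values.

    Parameters
    ----------
    origin : (3,) array_like
        World position (mm) of the center of voxel (0, 0, 0).
    spacing : (3,) array_like
        Voxel spacing (mm) along x, y, z; strictly positive.
    values : ndarray, shape (nx, ny, nz)
        One scalar per voxel; must be finite.
    unit : {"HU", "density", "Gy"}
    frame : str
        Free-form frame label carried through I/O.
    """

    origin: np.ndarray
    spacing: np.ndarray
    values: np.ndarray
    unit: str = "density"
    frame: str = "LPS"

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("values must be a 3D array")
        if not np.all(self.spacing > 0):
            raise ValueError("spacing must be strictly positive")
        if self.unit not in VALID_UNITS:
            raise ValueError(f"unit must be one of {VALID_UNITS}, got {self.unit!r}")
        if not np.all(np.isfinite(self.origin)) or not np.all(np.isfinite(self.spacing)):
            raise ValueError("origin and spacing must be finite")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("voxel values must be finite")

    # -- geometry ---------------------------------------------------------

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def axis_coords(self, axis: int) -> np.ndarray:
        """Voxel-center world coordinates along one axis."""
        n = self.values.shape[axis]
        return self.origin[axis] + self.spacing[axis] * np.arange(n)

    def voxel_centers(self) -> np.ndarray:
        """All voxel centers as an (nx, ny, nz, 3) array (mm)."""
        xs, ys, zs = (self.axis_coords(i) for i in range(3))
        gx, gy, gz = np.meshgrid(xs, ys, zs, indexing="ij")
        return np.stack([gx, gy, gz], axis=-1)

    def world_to_index(self, points: np.ndarray) -> np.ndarray:
        """Continuous (fractional) voxel indices of world points (mm)."""
        points = np.asarray(points, dtype=float)
        return (points - self.origin) / self.spacing

    def contains_point(self, point: np.ndarray) -> bool:
        idx = self.world_to_index(point)
        return bool(np.all(idx >= 0) and np.all(idx <= np.array(self.dims) - 1))

    def same_geometry(self, other: "VoxelVolume", tol: float = 1e-9) -> bool:
        return (
            self.dims == other.dims
            and np.allclose(self.origin, other.origin, atol=tol)
            and np.allclose(self.spacing, other.spacing, atol=tol)
        )

    # -- derived volumes --------------------------------------------------

    def copy_with(self, values: np.ndarray | None = None, unit: str | None = None) -> "VoxelVolume":
        return VoxelVolume(
            origin=self.origin.copy(),
            spacing=self.spacing.copy(),
            values=self.values.copy() if values is None else np.asarray(values, dtype=float),
            unit=self.unit if unit is None else unit,
            frame=self.frame,
        )

    @property
    def voxel_volume_cm3(self) -> float:
        return float(np.prod(self.spacing)) / 1000.0


def empty_grid(
    origin, spacing, dims, fill: float = 0.0, unit: str = "density", frame: str = "LPS"
) -> VoxelVolume:
    """Convenience constructor for a constant-filled grid."""
    dims = tuple(int(d) for d in dims)
    if any(d < 1 for d in dims):
        raise ValueError("dims must be >= 1")
    return VoxelVolume(
        origin=np.asarray(origin, dtype=float),
        spacing=np.asarray(spacing, dtype=float),
        values=np.full(dims, float(fill)),
        unit=unit,
        frame=frame,
    )


def centered_grid(extent_mm, spacing, fill: float = 0.0, unit: str = "density") -> VoxelVolume:
    """Grid symmetric about the world origin with the given physical extent."""
    extent = np.asarray(extent_mm, dtype=float)
    spacing = np.asarray(spacing, dtype=float)
    dims = np.maximum(1, np.round(extent / spacing).astype(int))
    origin = -(dims - 1) / 2.0 * spacing
    return empty_grid(origin, spacing, dims, fill=fill, unit=unit)
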