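"""Parametric tilted-disk metallic-port geometry.

The injection port of a saline tissue expander is modeled as a single
homogeneous finite cylinder ("disk"): diameter, thickness, bulk mass
density, a world-space center and two tilt angles.  The disk axis starts
anterior-posterior, (0, 1, 0); the sagittal tilt (rotation about the
left-right x-axis) is applied first, then the transverse tilt (rotation
about the superior-inferior z-axis), both in degrees with the right-hand
rule.

The radiologically calibrated defaults are 17.5 mm diameter, 5 mm
thickness and 7.5 g/cm^3 density.  Nominal physical dimensions of the two
components (neodymium magnet, titanium shell) are kept as named constants;
the thin Ti shell contributes < 0.2 g/cm^2 of areal density and is excluded
from the default model, but can be attached through ``ShellSpec``.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
from skimage import measure

from .structures import ROI, StructureSet
from .volume import VoxelVolume

# Radiologically determined model defaults.
PORT_DIAMETER_MM = 17.5
PORT_THICKNESS_MM = 5.0
PORT_DENSITY_G_CM3 = 7.5

# Nominal physical component specifications.
MAGNET_DIAMETER_MM = 21.0
MAGNET_THICKNESS_MM = 3.5
MAGNET_DENSITY_G_CM3 = 7.4
TI_SHELL_DIAMETER_MM = 35.0
TI_SHELL_THICKNESS_MM = 0.4
TI_SHELL_DENSITY_G_CM3 = 4.2

_DEFAULT_AXIS = np.array([0.0, 1.0, 0.0])


@dataclasses.dataclass(frozen=True)
class ShellSpec:
    """Optional thin casing around the disk (thickness mm, density g/cm^3)."""

    shell_thickness: float = TI_SHELL_THICKNESS_MM
    shell_density: float = TI_SHELL_DENSITY_G_CM3


@dataclasses.dataclass(frozen=True)
class PortModel:
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    tilt_transverse: float = 0.0  # deg, rotation about superior-inferior z
    tilt_sagittal: float = 0.0  # deg, rotation about left-right x
    diameter: float = PORT_DIAMETER_MM
    thickness: float = PORT_THICKNESS_MM
    density: float = PORT_DENSITY_G_CM3
    shell: ShellSpec | None = None

    def __post_init__(self) -> None:
        for name in ("diameter", "thickness", "density"):
            value = getattr(self, name)
            if not np.isfinite(value):
                raise ValueError(f"{name} must be finite, got {value}")
            if value <= 0:
                raise ValueError(f"{name} must be > 0, got {value}")
        center = np.asarray(self.center, dtype=float).reshape(3)
        if not np.all(np.isfinite(center)):
            raise ValueError("center must be finite")
        object.__setattr__(self, "center", tuple(float(c) for c in center))
        for name in ("tilt_transverse", "tilt_sagittal"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")

    @property
    def radius(self) -> float:
        return self.diameter / 2.0

    @property
    def rotation(self) -> np.ndarray:
        """World-from-local rotation matrix, Rz(transverse) @ Rx(sagittal)."""
        ts = math.radians(self.tilt_sagittal)
        tt = math.radians(self.tilt_transverse)
        rx = np.array(
            [
                [1, 0, 0],
                [0, math.cos(ts), -math.sin(ts)],
                [0, math.sin(ts), math.cos(ts)],
            ]
        )
        rz = np.array(
            [
                [math.cos(tt), -math.sin(tt), 0],
                [math.sin(tt), math.cos(tt), 0],
                [0, 0, 1],
            ]
        )
        return rz @ rx

    @property
    def axis(self) -> np.ndarray:
        """Unit vector along the disk axis (thickness direction)."""
        return self.rotation @ _DEFAULT_AXIS

    def local_coords(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Axial and radial coordinates (mm) of world points.

        ``axial`` is the signed distance along the disk axis from the disk
        center; ``radial`` the distance from the axis.
        """
        points = np.asarray(points, dtype=float)
        rel = points - np.asarray(self.center)
        axial = rel @ self.axis
        radial = np.linalg.norm(rel - np.multiply.outer(axial, self.axis), axis=-1)
        return axial, radial

    def contains(self, points: np.ndarray) -> np.ndarray:
        axial, radial = self.local_coords(points)
        return (np.abs(axial) <= self.thickness / 2.0) & (radial <= self.radius)

    def signed_boundary(self, points: np.ndarray) -> np.ndarray:
        """Level-set function: negative inside, zero on the boundary."""
        axial, radial = self.local_coords(points)
        return np.maximum(np.abs(axial) - self.thickness / 2.0, radial - self.radius)

    @property
    def analytic_volume_cm3(self) -> float:
        return math.pi * (self.radius / 10.0) ** 2 * (self.thickness / 10.0)

    def bounding_radius(self) -> float:
        """Radius of the bounding sphere about the center."""
        return math.hypot(self.radius, self.thickness / 2.0)


def make_port(
    center=(0.0, 0.0, 0.0),
    tilt_transverse: float = 0.0,
    tilt_sagittal: float = 0.0,
    diameter: float = PORT_DIAMETER_MM,
    thickness: float = PORT_THICKNESS_MM,
    density: float = PORT_DENSITY_G_CM3,
    shell: ShellSpec | None = None,
) -> PortModel:
    """Construct and validate a :class:`PortModel` (see class docs for units)."""
    return PortModel(
        center=tuple(np.asarray(center, dtype=float)),
        tilt_transverse=float(tilt_transverse),
        tilt_sagittal=float(tilt_sagittal),
        diameter=float(diameter),
        thickness=float(thickness),
        density=float(density),
        shell=shell,
    )


def areal_density(thickness_cm: float, density_g_cm3: float) -> float:
    """Areal (mass) density in g/cm^2 of a slab: thickness x density."""
    if thickness_cm < 0 or density_g_cm3 < 0:
        raise ValueError("thickness and density must be >= 0")
    return float(thickness_cm) * float(density_g_cm3)


# ---------------------------------------------------------------------------
# Ray-chord queries


def _interval_1d(o: float, d: float, half: float) -> tuple[float, float]:
    """Parameter interval where |o + t d| <= half (slab test)."""
    if abs(d) < 1e-300:
        return (-math.inf, math.inf) if abs(o) <= half else (math.inf, -math.inf)
    t1 = (-half - o) / d
    t2 = (half - o) / d
    return (t1, t2) if t1 <= t2 else (t2, t1)


def chord_length(port: PortModel, ray_origin, ray_direction) -> float:
    """Length (mm) of the ray segment inside the finite cylinder.

    Exact analytic solution intersecting the lateral quadric and the two
    cap planes; the ray starts at ``ray_origin`` (t >= 0 only).  Returns
    0.0 on a miss.
    """
    origin = np.asarray(ray_origin, dtype=float).reshape(3)
    direction = np.asarray(ray_direction, dtype=float).reshape(3)
    norm = np.linalg.norm(direction)
    if norm < 1e-12:
        raise ValueError("ray_direction must have non-zero norm")
    if abs(norm - 1.0) > 1e-6:
        raise ValueError("ray_direction must be unit-norm")
    rot = port.rotation
    o = rot.T @ (origin - np.asarray(port.center))
    d = rot.T @ direction
    # local frame: axis along y, radial in the x-z plane
    lo_a, hi_a = _interval_1d(o[1], d[1], port.thickness / 2.0)
    a = d[0] ** 2 + d[2] ** 2
    if a < 1e-24:
        inside = o[0] ** 2 + o[2] ** 2 <= port.radius**2
        lo_r, hi_r = (-math.inf, math.inf) if inside else (math.inf, -math.inf)
    else:
        b = 2.0 * (o[0] * d[0] + o[2] * d[2])
        c = o[0] ** 2 + o[2] ** 2 - port.radius**2
        disc = b * b - 4.0 * a * c
        if disc < 0:
            return 0.0
        root = math.sqrt(disc)
        lo_r = (-b - root) / (2.0 * a)
        hi_r = (-b + root) / (2.0 * a)
    lo = max(lo_a, lo_r, 0.0)
    hi = min(hi_a, hi_r)
    return max(0.0, hi - lo)


def chord_lengths(port: PortModel, ray_origins, ray_direction) -> np.ndarray:
    """Vectorized :func:`chord_length` for a parallel bundle of rays."""
    origins = np.atleast_2d(np.asarray(ray_origins, dtype=float))
    direction = np.asarray(ray_direction, dtype=float).reshape(3)
    norm = np.linalg.norm(direction)
    if norm < 1e-12:
        raise ValueError("ray_direction must have non-zero norm")
    direction = direction / norm
    rot = port.rotation
    o = (origins - np.asarray(port.center)) @ rot
    d = rot.T @ direction
    half = port.thickness / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        if abs(d[1]) < 1e-300:
            inside_a = np.abs(o[:, 1]) <= half
            lo_a = np.where(inside_a, -np.inf, np.inf)
            hi_a = np.where(inside_a, np.inf, -np.inf)
        else:
            t1 = (-half - o[:, 1]) / d[1]
            t2 = (half - o[:, 1]) / d[1]
            lo_a, hi_a = np.minimum(t1, t2), np.maximum(t1, t2)
        a = d[0] ** 2 + d[2] ** 2
        if a < 1e-24:
            inside_r = o[:, 0] ** 2 + o[:, 2] ** 2 <= port.radius**2
            lo_r = np.where(inside_r, -np.inf, np.inf)
            hi_r = np.where(inside_r, np.inf, -np.inf)
        else:
            b = 2.0 * (o[:, 0] * d[0] + o[:, 2] * d[2])
            c = o[:, 0] ** 2 + o[:, 2] ** 2 - port.radius**2
            disc = b * b - 4.0 * a * c
            ok = disc >= 0
            root = np.sqrt(np.where(ok, disc, 0.0))
            lo_r = np.where(ok, (-b - root) / (2.0 * a), np.inf)
            hi_r = np.where(ok, (-b + root) / (2.0 * a), -np.inf)
    lo = np.maximum(np.maximum(lo_a, lo_r), 0.0)
    hi = np.minimum(hi_a, hi_r)
    return np.maximum(0.0, hi - lo)


# ---------------------------------------------------------------------------
# Contouring and rasterization

CONTOUR_VERTEX_SPACING_MM = 0.5
_CONTOUR_GRID_MM = 0.25


def _resample_polygon(vertices: np.ndarray, max_spacing: float) -> np.ndarray:
    """Resample a closed polygon so consecutive vertices are <= max_spacing apart."""
    closed = np.vstack([vertices, vertices[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    arclen = np.concatenate([[0.0], np.cumsum(seg)])
    total = arclen[-1]
    n = max(8, int(np.ceil(total / max_spacing)))
    t = np.linspace(0.0, total, n, endpoint=False)
    x = np.interp(t, arclen, closed[:, 0])
    y = np.interp(t, arclen, closed[:, 1])
    return np.column_stack([x, y])


def _signed_area(vertices: np.ndarray) -> float:
    x, y = vertices[:, 0], vertices[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def slice_contours(port: PortModel, grid: VoxelVolume, name: str = "port") -> StructureSet:
    """Per-axial-slice closed polygons of the tilted disk cross-section.

    For every axial slice plane (voxel-center z) of ``grid`` that
    intersects the solid, the zero level of the disk's boundary function is
    extracted on a fine in-plane lattice with sub-pixel interpolation and
    resampled to a vertex spacing <= 0.5 mm.  Polygons are oriented
    counter-clockwise in the x-y plane.  Slices with no intersection carry
    no contour; a grid entirely outside the port yields an empty ROI.
    """
    center = np.asarray(port.center)
    reach = port.bounding_radius()
    margin = 2.0
    xs = np.arange(center[0] - reach - margin, center[0] + reach + margin, _CONTOUR_GRID_MM)
    ys = np.arange(center[1] - reach - margin, center[1] + reach + margin, _CONTOUR_GRID_MM)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    slices: list[tuple[float, np.ndarray]] = []
    for z in grid.axis_coords(2):
        if abs(z - center[2]) > reach:
            continue
        pts = np.stack([gx, gy, np.full_like(gx, z)], axis=-1)
        level = port.signed_boundary(pts)
        if level.min() >= 0:
            continue
        for contour in measure.find_contours(level, 0.0):
            verts = np.column_stack(
                [xs[0] + contour[:, 0] * _CONTOUR_GRID_MM, ys[0] + contour[:, 1] * _CONTOUR_GRID_MM]
            )
            if np.linalg.norm(verts[0] - verts[-1]) < 1e-9:
                verts = verts[:-1]
            if len(verts) < 3:
                continue
            verts = _resample_polygon(verts, CONTOUR_VERTEX_SPACING_MM)
            if _signed_area(verts) < 0:
                verts = verts[::-1]
            slices.append((float(z), verts))
    roi = ROI(name=name, override_density=port.density, priority=100, slices=slices)
    return StructureSet(rois=[roi] if slices else [roi])


def rasterize(obj: PortModel | StructureSet | ROI, grid: VoxelVolume) -> np.ndarray:
    """Boolean voxel occupancy of a port or structure set on ``grid``.

    Uses a voxel-center inclusion test: analytic for :class:`PortModel`,
    point-in-polygon (per-slice) for structures.  The mask volume times the
    voxel volume approximates the analytic solid volume.
    """
    if isinstance(obj, PortModel):
        return rasterize_port(obj, grid)
    if isinstance(obj, ROI):
        return _rasterize_roi(obj, grid)
    if isinstance(obj, StructureSet):
        mask = np.zeros(grid.dims, dtype=bool)
        for roi in obj.rois:
            mask |= _rasterize_roi(roi, grid)
        return mask
    raise TypeError(f"cannot rasterize {type(obj).__name__}")


def rasterize_port(port: PortModel, grid: VoxelVolume) -> np.ndarray:
    xs, ys, zs = (grid.axis_coords(i) for i in range(3))
    center = np.asarray(port.center)
    rel = (
        np.multiply.outer(xs - center[0], np.array([1.0, 0.0, 0.0]))[:, None, None, :]
        + np.multiply.outer(ys - center[1], np.array([0.0, 1.0, 0.0]))[None, :, None, :]
        + np.multiply.outer(zs - center[2], np.array([0.0, 0.0, 1.0]))[None, None, :, :]
    )
    axis = port.axis
    axial = rel @ axis
    radial_sq = np.einsum("...i,...i->...", rel, rel) - axial**2
    return (np.abs(axial) <= port.thickness / 2.0) & (radial_sq <= port.radius**2)


def _rasterize_roi(roi: ROI, grid: VoxelVolume) -> np.ndarray:
    from matplotlib.path import Path

    mask = np.zeros(grid.dims, dtype=bool)
    if not roi.slices:
        return mask
    xs, ys = grid.axis_coords(0), grid.axis_coords(1)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    zs = grid.axis_coords(2)
    for z, verts in roi.slices:
        iz = int(np.argmin(np.abs(zs - z)))
        if abs(zs[iz] - z) > grid.spacing[2] / 2.0 + 1e-9:
            continue
        inside = Path(verts).contains_points(pts).reshape(gx.shape)
        mask[:, :, iz] |= inside
    return mask
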