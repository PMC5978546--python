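"""Seeded synthetic phantoms for every measured geometry.

Three families are produced, all as density (or HU) voxel volumes plus
structure sets and setup metadata:

* the ion-chamber water tank (port on a slab 5 cm below the surface,
  SSD 85 cm, isocenter at 15 cm depth, sample depths 7-15 cm), in parallel
  and perpendicular port orientation;
* simplified anthropomorphic chest phantoms for an inflated (6.3 cm
  water-equivalent block) or deflated (2 cm block) expander over a 1 cm
  bolus "chest wall" and a low-density lung slab, with four TLD points;
* a patient-like half-cylindrical chest with an embedded water expander,
  the port at its anterior face, a PTV and four evaluation points.

A seeded streak simulator adds CT metal artifacts to HU volumes, and
policy helpers generate the ROI sets the density-override policies need.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from . import geometry
from .ct import EXTENDED_TABLE, CTConversionTable, hu_from_density
from .geometry import PortModel, make_port, rasterize_port, slice_contours
from .measurements import MeasurementSet, PointMeasurement
from .structures import ROI, StructureSet, structure_from_mask
from .volume import VoxelVolume, empty_grid

AIR_DENSITY = 0.001
LUNG_DENSITY = 0.30  # wooden lung-substitute slab
ORIENTATIONS = ("parallel", "perpendicular")
ANTHRO_STATES = ("inflated", "deflated")

# Ion-chamber tank setup
IC_SSD_MM = 850.0
IC_ISO_DEPTH_MM = 150.0
IC_PORT_TOP_DEPTH_MM = 50.0
IC_FIELD_MM = (100.0, 100.0)
IC_SAMPLE_DEPTHS_MM = tuple(float(d) for d in range(70, 151, 10))

# Anthropomorphic phantom setup
ANTHRO_SSD_MM = {"inflated": 907.0, "deflated": 950.0}
ANTHRO_BLOCK_MM = {"inflated": 63.0, "deflated": 20.0}
ANTHRO_BOLUS_MM = 10.0
ANTHRO_LUNG_MM = 80.0
ANTHRO_PORT_DEPTH_MM = 20.0  # surface to port center
TLD_LATERAL_OFFSET_MM = 25.0


@dataclasses.dataclass
class PhantomBuild:
    """A generated phantom: volume, structures, placed port and metadata."""

    volume: VoxelVolume
    structures: StructureSet
    port: PortModel | None
    metadata: dict


def _to_unit(values_density: np.ndarray, unit: str, table: CTConversionTable) -> np.ndarray:
    if unit == "density":
        return values_density
    if unit == "HU":
        return np.asarray(hu_from_density(table, values_density))
    raise ValueError(f"phantoms can be built in 'density' or 'HU', not {unit!r}")


def place_ic_port(port: PortModel, orientation: str) -> PortModel:
    """Position a port in the tank with its top face 5 cm below the surface."""
    if orientation not in ORIENTATIONS:
        raise ValueError(f"orientation must be one of {ORIENTATIONS}")
    if orientation == "perpendicular":
        # disk axis along the beam (+y): axial extent = thickness
        center_y = IC_PORT_TOP_DEPTH_MM + port.thickness / 2.0
        return dataclasses.replace(port, center=(0.0, center_y, 0.0), tilt_transverse=0.0, tilt_sagittal=0.0)
    center_y = IC_PORT_TOP_DEPTH_MM + port.diameter / 2.0
    return dataclasses.replace(port, center=(0.0, center_y, 0.0), tilt_transverse=90.0, tilt_sagittal=0.0)


def build_ic_phantom(
    port: PortModel | None = None,
    orientation: str = "perpendicular",
    spacing=(2.0, 2.0, 2.0),
    depth_mm: float = 220.0,
    lateral_mm: float = 160.0,
    unit: str = "density",
    table: CTConversionTable = EXTENDED_TABLE,
) -> PhantomBuild:
    """Water tank with the port per the ion-chamber depth-dose setup.

    The beam irradiates from anterior (+y is depth below the water surface
    at y = 0).  The grid must cover at least 20 cm of water depth.
    """
    if depth_mm < 200.0:
        raise ValueError("IC tank grid must cover >= 200 mm of water depth")
    port = place_ic_port(port if port is not None else make_port(), orientation)
    spacing = np.asarray(spacing, dtype=float)
    nxz = int(round(lateral_mm / spacing[0]))
    ny = int(round(depth_mm / spacing[1]))
    origin = (-(nxz - 1) / 2.0 * spacing[0], spacing[1] / 2.0, -(nxz - 1) / 2.0 * spacing[2])
    vol = empty_grid(origin, spacing, (nxz, ny, nxz), fill=1.0, unit="density")
    mask = rasterize_port(port, vol)
    vol.values[mask] = port.density
    vol.values[:] = _to_unit(vol.values, unit, table)
    vol.unit = unit
    structures = slice_contours(port, vol)
    meta = {
        "setup": "ic_tank",
        "orientation": orientation,
        "ssd_mm": IC_SSD_MM,
        "isocenter": (0.0, IC_ISO_DEPTH_MM, 0.0),
        "isocenter_depth_mm": IC_ISO_DEPTH_MM,
        "field_mm": IC_FIELD_MM,
        "sample_depths_mm": IC_SAMPLE_DEPTHS_MM,
        "port_top_depth_mm": IC_PORT_TOP_DEPTH_MM,
    }
    return PhantomBuild(volume=vol, structures=structures, port=port, metadata=meta)


def anthro_port_center(state: str) -> tuple[float, float, float]:
    block = ANTHRO_BLOCK_MM[state]
    surface_x = ANTHRO_BOLUS_MM + block
    return (surface_x - ANTHRO_PORT_DEPTH_MM, 0.0, 0.0)


def build_anthro_phantom(
    state: str,
    port: PortModel | None = None,
    spacing=(2.0, 2.0, 2.5),
    lateral_mm: float = 160.0,
    unit: str = "density",
    lung_density: float = LUNG_DENSITY,
    table: CTConversionTable = EXTENDED_TABLE,
) -> PhantomBuild:
    """Slab phantom emulating an inflated or deflated expander on a chest.

    Layers along x (the lateral beam direction): lung slab in
    ``[-80, 0)``, 1 cm bolus (chest wall) in ``[0, 10)``, water-equivalent
    block of state-dependent thickness above, air beyond.  The port center
    sits 2 cm below the block surface with its face toward the surface; the
    isocenter is at the lung/chest-wall interface aligned with the port.
    """
    if state not in ANTHRO_STATES:
        raise ValueError(f"state must be one of {ANTHRO_STATES}, got {state!r}")
    block = ANTHRO_BLOCK_MM[state]
    surface_x = ANTHRO_BOLUS_MM + block
    base = port if port is not None else make_port()
    port = dataclasses.replace(
        base, center=anthro_port_center(state), tilt_transverse=90.0, tilt_sagittal=0.0
    )
    spacing = np.asarray(spacing, dtype=float)
    x_lo, x_hi = -ANTHRO_LUNG_MM, surface_x + 20.0
    nx = int(round((x_hi - x_lo) / spacing[0]))
    nyz = int(round(lateral_mm / spacing[1]))
    nz = int(round(lateral_mm / spacing[2]))
    origin = (x_lo + spacing[0] / 2.0, -(nyz - 1) / 2.0 * spacing[1], -(nz - 1) / 2.0 * spacing[2])
    vol = empty_grid(origin, spacing, (nx, nyz, nz), fill=AIR_DENSITY, unit="density")
    xs = vol.axis_coords(0)
    lung = xs < 0
    bolus = (xs >= 0) & (xs < ANTHRO_BOLUS_MM)
    blk = (xs >= ANTHRO_BOLUS_MM) & (xs < surface_x)
    vol.values[lung, :, :] = lung_density
    vol.values[bolus, :, :] = 1.0
    vol.values[blk, :, :] = 1.0
    mask = rasterize_port(port, vol)
    vol.values[mask] = port.density
    vol.values[:] = _to_unit(vol.values, unit, table)
    vol.unit = unit
    structures = slice_contours(port, vol)
    meta = {
        "setup": f"anthro_{state}",
        "state": state,
        "ssd_mm": ANTHRO_SSD_MM[state],
        "isocenter": (0.0, 0.0, 0.0),
        "surface_x_mm": surface_x,
        "block_mm": block,
        "bolus_mm": ANTHRO_BOLUS_MM,
        "port_depth_mm": ANTHRO_PORT_DEPTH_MM,
        "prescription_gy": 1.0,
        "field_mm": (100.0, 100.0),
    }
    return PhantomBuild(volume=vol, structures=structures, port=port, metadata=meta)


def place_measurement_points(state: str) -> MeasurementSet:
    """TLD point layout: 1, 2, 4 at 2.5 cm from the port center, 3 under it."""
    if state not in ANTHRO_STATES:
        raise ValueError(f"state must be one of {ANTHRO_STATES}, got {state!r}")
    c = np.asarray(anthro_port_center(state))
    off = TLD_LATERAL_OFFSET_MM
    points = [
        PointMeasurement("point1", tuple(c + [0.0, off, 0.0])),
        PointMeasurement("point2", tuple(c + [0.0, 0.0, off])),
        PointMeasurement("point3", tuple(c + [-off, 0.0, 0.0])),
        PointMeasurement("point4", tuple(c + [0.0, 0.0, -off])),
    ]
    return MeasurementSet(points=points)


def tld_packet_inventory() -> pd.DataFrame:
    """Enumerate the TLD packets of the phantom validation design.

    4 measurement points x 3 plans x 2 expander states, plus one
    background packet and three calibration packets.
    """
    rows = []
    for state in ANTHRO_STATES:
        for plan in ("open", "vmat", "4fld-imrt"):
            for point in (1, 2, 3, 4):
                rows.append({"role": "measurement", "state": state, "plan": plan, "point": point})
    rows.append({"role": "background", "state": None, "plan": None, "point": None})
    for i in range(3):
        rows.append({"role": "calibration", "state": None, "plan": None, "point": i + 1})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Metal-artifact simulation

ARTIFACT_RANGE_MM = 80.0


def add_metal_artifacts(
    volume: VoxelVolume,
    port_mask: np.ndarray,
    magnitude_hu: float = 300.0,
    n_streaks: int = 8,
    seed: int = 0,
) -> VoxelVolume:
    """Add alternating bright/dark radial streaks around the port.

    Streaks emanate from the port-mask centroid in every slice containing
    the port, with amplitude bounded by ``magnitude_hu``, decaying linearly
    to zero at 8 cm; voxels further than 8 cm are untouched.  Deterministic
    per seed (one random streak phase shared by all slices).
    """
    if volume.unit != "HU":
        raise ValueError("artifacts are defined on HU volumes")
    if port_mask.shape != volume.values.shape:
        raise ValueError("port mask must match the volume shape")
    rng = np.random.default_rng(seed)
    phase = rng.uniform(0.0, 2.0 * np.pi)
    out = volume.copy_with()
    if magnitude_hu == 0 or not port_mask.any():
        return out
    xs, ys = volume.axis_coords(0), volume.axis_coords(1)
    ang_width = 2.0 * np.pi / n_streaks / 6.0
    for iz in range(volume.dims[2]):
        plane_mask = port_mask[:, :, iz]
        if not plane_mask.any():
            continue
        ii, jj = np.nonzero(plane_mask)
        cx, cy = xs[ii].mean(), ys[jj].mean()
        gx, gy = np.meshgrid(xs - cx, ys - cy, indexing="ij")
        r = np.hypot(gx, gy)
        phi = np.arctan2(gy, gx)
        delta = np.zeros_like(r)
        for k in range(n_streaks):
            phi_k = phase + 2.0 * np.pi * k / n_streaks
            dphi = np.angle(np.exp(1j * (phi - phi_k)))
            sign = 1.0 if k % 2 == 0 else -1.0
            delta += sign * np.exp(-0.5 * (dphi / ang_width) ** 2)
        radial = np.clip(1.0 - r / ARTIFACT_RANGE_MM, 0.0, 1.0)
        out.values[:, :, iz] += magnitude_hu * radial * np.clip(delta, -1.0, 1.0)
    return out


# ---------------------------------------------------------------------------
# Policy ROI construction

ARTIFACT_ROI_MARGIN_MM = 30.0
CLINICAL2_DILATION_MM = 3.0


def build_policy_structures(port: PortModel, grid: VoxelVolume, policy: str) -> StructureSet:
    """ROI set feeding :func:`~xpanderdose.ct.apply_override_policy`.

    ``clinical1`` contours magnet and shell at their physical dimensions
    with nominal density overrides; ``clinical2`` contours the port from
    the (artifact-contaminated) image, emulated by dilating the true port
    by 3 mm, with no override (CT-derived density); ``new`` contours the
    calibrated disk model.  All policies carry a surrounding-artifact ROI
    overridden as water.
    """
    artifact_disk = dataclasses.replace(
        port,
        diameter=port.diameter + 2 * ARTIFACT_ROI_MARGIN_MM,
        thickness=port.thickness + 20.0,
        density=1.0,
    )
    artifact = slice_contours(artifact_disk, grid, name="artifact")["artifact"]
    artifact.override_density = 1.0
    artifact.priority = 10
    rois = [artifact]
    if policy == "clinical1":
        magnet = dataclasses.replace(
            port,
            diameter=geometry.MAGNET_DIAMETER_MM,
            thickness=geometry.MAGNET_THICKNESS_MM,
            density=geometry.MAGNET_DENSITY_G_CM3,
        )
        shell = dataclasses.replace(
            port,
            diameter=geometry.TI_SHELL_DIAMETER_MM,
            thickness=geometry.MAGNET_THICKNESS_MM + 2 * geometry.TI_SHELL_THICKNESS_MM,
            density=geometry.TI_SHELL_DENSITY_G_CM3,
        )
        shell_roi = slice_contours(shell, grid, name="shell")["shell"]
        shell_roi.override_density = geometry.TI_SHELL_DENSITY_G_CM3
        shell_roi.priority = 50
        port_roi = slice_contours(magnet, grid, name="port")["port"]
        port_roi.priority = 100
        rois += [shell_roi, port_roi]
    elif policy == "clinical2":
        contaminated = dataclasses.replace(
            port,
            diameter=port.diameter + 2 * CLINICAL2_DILATION_MM,
            thickness=port.thickness + 2 * CLINICAL2_DILATION_MM,
        )
        port_roi = slice_contours(contaminated, grid, name="port")["port"]
        port_roi.override_density = None  # CT-derived through the saturating table
        port_roi.priority = 100
        rois.append(port_roi)
    elif policy in ("new", "nodisk"):
        port_roi = slice_contours(port, grid, name="port")["port"]
        port_roi.priority = 100
        rois.append(port_roi)
    else:
        raise ValueError(f"unknown policy {policy!r}")
    return StructureSet(rois=rois)


# ---------------------------------------------------------------------------
# Patient-like chest phantom


def build_patient_like(seed: int = 0, spacing=(2.0, 2.0, 2.5)) -> PhantomBuild:
    """Half-cylindrical chest with an embedded expander and port.

    The body is a half-cylinder (axis superior-inferior) with its flat,
    posterior face against a chest-wall plane; a water-filled expander
    bulges into the anterior half with the metallic port at its anterior
    face.  The PTV covers the chest-wall shell plus the expander region on
    the port-bearing slices.  Four labeled evaluation points are placed:
    skin1/skin2 just over 1 cm deep near the anterior surface, CW1/CW2 on
    the chest wall.  Fully deterministic per seed.
    """
    rng = np.random.default_rng(seed)
    body_radius = 90.0 + rng.uniform(-3.0, 3.0)
    exp_a = 34.0 + rng.uniform(-2.0, 2.0)  # lateral semi-axis
    exp_b = 32.0 + rng.uniform(-2.0, 2.0)  # anterior semi-axis
    exp_c = 30.0 + rng.uniform(-2.0, 2.0)  # superior semi-axis
    spacing = np.asarray(spacing, dtype=float)
    extent = np.array([2 * body_radius + 20.0, body_radius + 30.0, 140.0])
    dims = np.round(extent / spacing).astype(int)
    wall_y = 20.0  # posterior flat face of the half-cylinder
    origin = (-(dims[0] - 1) / 2.0 * spacing[0], wall_y - (dims[1] - 1) * spacing[1], -(dims[2] - 1) / 2.0 * spacing[2])
    vol = empty_grid(origin, spacing, dims, fill=AIR_DENSITY, unit="density")
    xs, ys, zs = (vol.axis_coords(i) for i in range(3))
    gx = xs[:, None, None]
    gy = ys[None, :, None]
    gz = zs[None, None, :]
    body = (gx**2 + (gy - wall_y) ** 2 <= body_radius**2) & (gy <= wall_y) & (np.abs(gz) <= 60.0)
    vol.values[body] = 1.0

    exp_center = np.array([0.0, wall_y - exp_b, 0.0])
    expander = (
        ((gx - exp_center[0]) / exp_a) ** 2
        + ((gy - exp_center[1]) / exp_b) ** 2
        + ((gz - exp_center[2]) / exp_c) ** 2
    ) <= 1.0
    expander &= body
    port = make_port(
        center=(0.0, exp_center[1] - exp_b + 6.0, 0.0),
        tilt_transverse=float(rng.uniform(-15.0, 15.0)),
        tilt_sagittal=float(rng.uniform(-10.0, 10.0)),
    )
    port_mask = rasterize_port(port, vol) & body
    vol.values[port_mask] = port.density

    # anterior shell of the body = chest wall + skin region
    r_body = np.sqrt(gx**2 + (gy - wall_y) ** 2)
    shell = body & (body_radius - r_body <= 15.0)
    port_slices = port_mask.any(axis=(0, 1))
    ptv = (shell | expander | port_mask) & body & port_slices[None, None, :]

    masks = {"body": body, "expander": expander, "port": port_mask, "ptv": ptv}
    structures = StructureSet(
        rois=[
            structure_from_mask("ptv", ptv, vol, priority=0),
            structure_from_mask("expander", expander, vol, override_density=1.0, priority=20),
            slice_contours(port, vol)["port"],
        ]
    )
    structures["port"].priority = 100

    depth = 12.0
    r_pt = body_radius - depth
    points = []
    for label, theta in (("skin1", -0.45), ("skin2", 0.45)):
        pos = (r_pt * np.sin(theta), wall_y - r_pt * np.cos(theta), 10.0)
        points.append(PointMeasurement(label, pos))
    for label, x in (("CW1", -35.0), ("CW2", 35.0)):
        points.append(PointMeasurement(label, (x, wall_y - 4.0, 0.0)))
    meta = {
        "setup": "patient_like",
        "seed": seed,
        "body_radius_mm": body_radius,
        "chest_wall_y_mm": wall_y,
        "skin_point_depth_mm": depth,
        "masks": masks,
        "points": MeasurementSet(points=points),
        "prescription_gy": 50.0,
        "fractions": 25,
        "isocenter": tuple(exp_center),
    }
    return PhantomBuild(volume=vol, structures=structures, port=port, metadata=meta)
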