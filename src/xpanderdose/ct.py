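"""HU <-> mass-density conversion tables and ROI density-override policies.

Treatment planning systems convert CT numbers to mass density through a
piecewise-linear calibration table.  Standard clinical tables saturate at a
few g/cm^3; an *extended* table continues well beyond so that a metallic
implant (here up to 10 g/cm^3) can be represented by density override.

Three port-modeling policies are implemented:

``clinical1``
    Magnet and shell contoured from physical dimensions; both overridden by
    their nominal densities (7.4 and 4.2 g/cm^3), surrounding artifacts
    overridden as water.
``clinical2``
    Port contoured from the CT image alone (so part of the bright artifact
    is inside the contour); the port keeps CT-derived densities through a
    *non-extended* table (saturating, hence underestimating), artifacts
    outside it overridden as water.
``new``
    The calibrated tilted-disk model: disk ROI overridden to 7.5 g/cm^3,
    artifacts overridden as water.
``nodisk``
    Baseline: port, shell and expander all overridden as water, emulating a
    homogeneous breast without an expander.

Overlap is resolved by priority: port > shell > artifact > background.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import geometry
from .geometry import rasterize
from .structures import StructureSet
from .volume import VoxelVolume


@dataclasses.dataclass(frozen=True)
class CTConversionTable:
    """Piecewise-linear (HU, density) calibration curve.

    HU breakpoints must be strictly increasing, densities non-negative and
    non-decreasing.  Lookups clamp at the table ends; a non-extended table
    additionally saturates at ``max_density``.
    """

    breakpoints: tuple[tuple[float, float], ...]
    extended: bool = True
    max_density: float = 3.0

    def __post_init__(self) -> None:
        hu = np.array([b[0] for b in self.breakpoints], dtype=float)
        rho = np.array([b[1] for b in self.breakpoints], dtype=float)
        if hu.size == 0:
            raise ValueError("conversion table must have at least one breakpoint")
        if hu.size > 1 and not np.all(np.diff(hu) > 0):
            raise ValueError("HU breakpoints must be strictly increasing")
        if np.any(rho < 0) or (rho.size > 1 and np.any(np.diff(rho) < 0)):
            raise ValueError("densities must be non-negative and non-decreasing")
        if self.extended and rho.max() < 7.5:
            raise ValueError("extended table must reach >= 7.5 g/cm^3")

    @property
    def hu_values(self) -> np.ndarray:
        return np.array([b[0] for b in self.breakpoints], dtype=float)

    @property
    def density_values(self) -> np.ndarray:
        return np.array([b[1] for b in self.breakpoints], dtype=float)

    def non_extended(self, max_density: float | None = None) -> "CTConversionTable":
        """Saturating clinical version of this table."""
        cap = self.max_density if max_density is None else max_density
        pts = tuple((hu, min(rho, cap)) for hu, rho in self.breakpoints)
        return CTConversionTable(breakpoints=pts, extended=False, max_density=cap)


#: Extended calibration reaching 10 g/cm^3; water anchored at HU = 0.
EXTENDED_TABLE = CTConversionTable(
    breakpoints=((-1000.0, 0.001), (0.0, 1.0), (1000.0, 1.6), (3000.0, 3.0), (10000.0, 10.0)),
    extended=True,
)

#: Typical clinical table saturating at 3.0 g/cm^3.
STANDARD_TABLE = EXTENDED_TABLE.non_extended(3.0)


def density_from_hu(table: CTConversionTable, hu) -> np.ndarray | float:
    """Piecewise-linear HU -> density (g/cm^3), clamped at the table ends."""
    rho = np.interp(np.asarray(hu, dtype=float), table.hu_values, table.density_values)
    if not table.extended:
        rho = np.minimum(rho, table.max_density)
    return rho if np.ndim(hu) else float(rho)


def hu_from_density(table: CTConversionTable, density) -> np.ndarray | float:
    """Inverse lookup on the monotone (strictly increasing) table segments."""
    rho_pts = table.density_values
    hu_pts = table.hu_values
    keep = np.concatenate([[True], np.diff(rho_pts) > 0])
    hu = np.interp(np.asarray(density, dtype=float), rho_pts[keep], hu_pts[keep])
    return hu if np.ndim(density) else float(hu)


POLICIES = ("clinical1", "clinical2", "new", "nodisk")

_REQUIRED_ROIS = {
    "clinical1": ("port", "shell", "artifact"),
    "clinical2": ("port", "artifact"),
    "new": ("port", "artifact"),
    "nodisk": ("port",),
}


def apply_override_policy(
    volume: VoxelVolume,
    structures: StructureSet,
    policy: str,
    table: CTConversionTable = EXTENDED_TABLE,
) -> VoxelVolume:
    """Convert a volume to mass density under one of the port-model policies.

    The input may be in HU (converted through ``table``) or already in
    density units; ``clinical2`` requires HU because its port ROI keeps
    CT-derived (saturated-table) densities.  Voxels outside every ROI are
    untouched apart from the HU->density conversion, and re-applying a
    policy to its own output is a no-op for the density-only policies.
    """
    if policy not in POLICIES:
        raise ValueError(f"unknown policy {policy!r}; expected one of {POLICIES}")
    for required in _REQUIRED_ROIS[policy]:
        if required not in structures:
            raise ValueError(f"policy {policy!r} requires ROI {required!r}")
    if volume.unit == "HU":
        base = np.asarray(density_from_hu(table, volume.values))
    elif volume.unit == "density":
        if policy == "clinical2":
            raise ValueError("clinical2 requires an HU volume (CT-derived port densities)")
        base = volume.values.copy()
    else:
        raise ValueError(f"cannot apply overrides to a volume in {volume.unit!r}")

    def mask_of(name: str) -> np.ndarray:
        return rasterize(structures[name], volume)

    # lowest priority first so later assignments win
    if policy == "nodisk":
        for name in ("artifact", "expander", "shell", "port"):
            if name in structures:
                base[mask_of(name)] = 1.0
    else:
        base[mask_of("artifact")] = 1.0
        if policy == "clinical1":
            if "shell" in structures:
                roi = structures["shell"]
                base[mask_of("shell")] = (
                    roi.override_density
                    if roi.override_density is not None
                    else geometry.TI_SHELL_DENSITY_G_CM3
                )
            roi = structures["port"]
            base[mask_of("port")] = (
                roi.override_density
                if roi.override_density is not None
                else geometry.MAGNET_DENSITY_G_CM3
            )
        elif policy == "clinical2":
            capped = table.non_extended()
            port_mask = mask_of("port")
            base[port_mask] = np.asarray(density_from_hu(capped, volume.values))[port_mask]
        elif policy == "new":
            roi = structures["port"]
            base[mask_of("port")] = (
                roi.override_density
                if roi.override_density is not None
                else geometry.PORT_DENSITY_G_CM3
            )
    return volume.copy_with(values=base, unit="density")
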