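"""Dosimetric evaluation tooling.

Percent-difference comparison tables (calculated vs reference point
doses), cumulative dose-volume histograms, the reduced planning target
volume, full-width-at-half-maximum dimensioning of the port from
projection images, and the linear TLD calibration fit.

Rounding follows the half-away-from-zero convention of printed clinical
tables (-8.544 % prints as -8.5).
"""

from __future__ import annotations

import dataclasses
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources

import numpy as np
import pandas as pd

from .engine import DEFAULT_BEAM_DATA, BeamDataTable
from .geometry import PortModel, chord_lengths
from .volume import VoxelVolume

MODELS_TABLE1 = ("clinical1", "clinical2", "new")


def _round_half_away(x: float, decimals: int) -> float:
    q = Decimal(10) ** -decimals
    d = Decimal(repr(float(x)))
    return float(d.copy_abs().quantize(q, rounding=ROUND_HALF_UP) * (1 if x >= 0 else -1))


def percent_difference(calculated: float, reference: float, decimals: int = 1) -> float:
    """(calculated - reference) / reference x 100, rounded half-away-from-zero."""
    if reference <= 0:
        raise ValueError("reference dose must be > 0")
    return _round_half_away((calculated - reference) / reference * 100.0, decimals)


def comparison_table(
    reference: dict[str, float],
    model_doses: dict[str, dict[str, float]],
    decimals: int = 1,
) -> pd.DataFrame:
    """Reference vs per-model doses with percent differences.

    ``reference`` maps point labels to the reference dose; ``model_doses``
    maps model names to per-label calculated doses (labels must match).
    The returned frame has one row per point plus a ``max |diff|`` summary
    row per model.
    """
    labels = list(reference)
    for model, doses in model_doses.items():
        missing = sorted(set(labels) ^ set(doses))
        if missing:
            raise ValueError(f"model {model!r}: label mismatch for {missing}")
    rows = []
    for label in labels:
        row: dict = {"label": label, "reference": reference[label]}
        for model, doses in model_doses.items():
            row[f"{model}_dose"] = doses[label]
            row[f"{model}_diff_pct"] = percent_difference(doses[label], reference[label], decimals)
        rows.append(row)
    frame = pd.DataFrame(rows).set_index("label")
    summary = {"reference": np.nan}
    for model in model_doses:
        summary[f"{model}_dose"] = np.nan
        summary[f"{model}_diff_pct"] = frame[f"{model}_diff_pct"].abs().max()
    frame.loc["max |diff|"] = pd.Series(summary)
    return frame


# ---------------------------------------------------------------------------
# Shipped dose columns of the phantom and patient comparison tables


def load_table_fixture(which: int) -> pd.DataFrame:
    """Fixture CSV with the printed reference/model dose columns (cGy)."""
    if which not in (1, 2):
        raise ValueError("table fixture must be 1 or 2")
    name = f"table{which}_doses.csv"
    with resources.files("xpanderdose.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def reproduce_table(which: int) -> pd.DataFrame:
    """Recompute every percent difference of a fixture table.

    Adds ``<model>_recomputed`` columns (rounded like the printed ones:
    1 decimal for the phantom table, 2 for the patient table) and
    ``<model>_consistent`` flags.  The printed dose columns are themselves
    rounded, which propagates to at most one unit in the last printed
    digit of the difference; the consistency flag allows exactly that.
    """
    frame = load_table_fixture(which).copy()
    decimals = 1 if which == 1 else 2
    ulp = 10.0**-decimals
    for model in MODELS_TABLE1:
        recomputed = [
            percent_difference(c, r, decimals)
            for c, r in zip(frame[f"{model}_dose"], frame["reference_dose"])
        ]
        frame[f"{model}_recomputed"] = recomputed
        frame[f"{model}_consistent"] = (
            (frame[f"{model}_recomputed"] - frame[f"{model}_diff"]).abs() <= ulp + 1e-9
        )
    return frame


def reproduce_tables() -> tuple[pd.DataFrame, pd.DataFrame, bool]:
    """Both tables plus an overall all-consistent flag."""
    t1 = reproduce_table(1)
    t2 = reproduce_table(2)
    ok = bool(
        all(t1[f"{m}_consistent"].all() for m in MODELS_TABLE1)
        and all(t2[f"{m}_consistent"].all() for m in MODELS_TABLE1)
    )
    return t1, t2, ok


# ---------------------------------------------------------------------------
# DVH and reduced PTV


def dvh(dose: VoxelVolume, mask: np.ndarray, bin_width_gy: float = 0.01):
    """Cumulative dose-volume histogram of the masked region.

    Returns ``(levels_gy, pct_volume)`` where ``pct_volume[i]`` is the
    percentage of the masked volume receiving at least ``levels_gy[i]``;
    100 % at zero dose, non-increasing, 0 % beyond the maximum dose.
    """
    if bin_width_gy <= 0:
        raise ValueError("bin width must be > 0")
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != dose.values.shape:
        raise ValueError("mask geometry does not match the dose grid")
    doses = dose.values[mask]
    if doses.size == 0:
        raise ValueError("empty mask")
    top = float(doses.max()) + bin_width_gy
    levels = np.arange(0.0, top + bin_width_gy, bin_width_gy)
    pct = np.array([(doses >= lv).mean() * 100.0 for lv in levels])
    return levels, pct


def reduced_ptv(ptv: np.ndarray, expander: np.ndarray, port: np.ndarray, grid: VoxelVolume) -> np.ndarray:
    """PTV narrowed to port-bearing slices, minus expander and port.

    The axial (z) slices retained are exactly those where the port mask is
    non-empty; within them the expander and port voxels are excluded.
    """
    for name, mask in (("ptv", ptv), ("expander", expander), ("port", port)):
        if np.asarray(mask).shape != grid.dims:
            raise ValueError(f"{name} mask does not match the grid geometry")
    port_slices = port.any(axis=(0, 1))
    return ptv & port_slices[None, None, :] & ~(expander | port)


# ---------------------------------------------------------------------------
# Projection images and FWHM dimensioning


@dataclasses.dataclass
class ProjectionImage:
    """2D transmission image (e.g. a scanned film), pixel spacing in mm."""

    values: np.ndarray
    spacing_mm: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("projection image must be 2D")
        if self.spacing_mm <= 0:
            raise ValueError("pixel spacing must be > 0")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("image values must be finite")


def fwhm(profile, spacing_mm: float) -> float:
    """Full width at half maximum (mm) of a single-trough/peak profile.

    The baseline is the median of the outer 20 % of samples; the half
    level sits midway between baseline and extremum, and the crossings are
    located by linear interpolation on either side of the extremum.
    """
    y = np.asarray(profile, dtype=float)
    if y.ndim != 1 or y.size < 5:
        raise ValueError("profile must be a 1D array with >= 5 samples")
    k = max(1, int(0.1 * y.size))
    baseline = float(np.median(np.concatenate([y[:k], y[-k:]])))
    trough = float(y.min())
    peak = float(y.max())
    depth_down = baseline - trough
    depth_up = peak - baseline
    span = peak - trough
    if span <= 0 or max(depth_down, depth_up) < 1e-12 * max(1.0, abs(baseline)):
        raise ValueError("profile is flat; no dominant feature")
    if depth_down >= depth_up:
        idx = int(np.argmin(y))
        half = (baseline + trough) / 2.0
        below = y <= half
    else:
        idx = int(np.argmax(y))
        half = (baseline + peak) / 2.0
        below = y >= half
    if not below[idx]:
        raise ValueError("no samples beyond the half level")
    left = idx
    while left > 0 and below[left - 1]:
        left -= 1
    right = idx
    while right < y.size - 1 and below[right + 1]:
        right += 1
    # sub-sample crossings
    if left > 0:
        x_left = left - (half - y[left]) / (y[left - 1] - y[left])
    else:
        x_left = 0.0
    if right < y.size - 1:
        x_right = right + (half - y[right]) / (y[right + 1] - y[right])
    else:
        x_right = float(y.size - 1)
    return float((x_right - x_left) * spacing_mm)


def project_port(
    port: PortModel,
    setup: str,
    pixel_mm: float = 0.2,
    extent_mm: float = 60.0,
    table: BeamDataTable = DEFAULT_BEAM_DATA,
    energy_mv: int = 6,
) -> ProjectionImage:
    """Synthetic transmission image of the port (parallel-ray projection).

    The beam travels along +y; ``perpendicular`` orients the disk axis
    along the beam (the image shows the full circle), ``parallel`` puts
    the disk edge-on (the image shows the diameter x thickness rectangle,
    thickness along the image rows).
    """
    from .phantoms import place_ic_port

    placed = place_ic_port(port, setup)
    n = int(round(extent_mm / pixel_mm))
    coords = (np.arange(n) - (n - 1) / 2.0) * pixel_mm
    cx, cz = placed.center[0], placed.center[2]
    # image rows follow x (the thickness direction in the parallel setup),
    # columns follow z
    rows = np.repeat(coords + cx, n)
    cols = np.tile(coords + cz, n)
    origins = np.column_stack([rows, np.full(n * n, -100.0), cols])
    chords = chord_lengths(placed, origins, (0.0, 1.0, 0.0)).reshape(n, n)
    mu = table[energy_mv].mu_rho
    transmission = np.exp(-mu * (port.density - 1.0) * chords / 10.0)
    return ProjectionImage(values=transmission, spacing_mm=pixel_mm)


def port_dims_from_projection(image: ProjectionImage, setup: str) -> float:
    """Port extent (mm) from the FWHM of the central transmission profile.

    Perpendicular setup: the central row crosses the disk circle, so the
    FWHM estimates the diameter.  Parallel setup: the central column of
    the edge-on rectangle estimates the thickness.
    """
    if setup == "perpendicular":
        profile = image.values[image.values.shape[0] // 2, :]
    elif setup == "parallel":
        profile = image.values[:, image.values.shape[1] // 2]
    else:
        raise ValueError("setup must be 'parallel' or 'perpendicular'")
    return fwhm(profile, image.spacing_mm)


# ---------------------------------------------------------------------------
# TLD calibration


@dataclasses.dataclass
class TldCalibrationFit:
    """Least-squares line mapping delivered dose to TLD reading."""

    slope: float  # reading per Gy
    intercept: float
    residuals: np.ndarray
    stderr_slope: float
    stderr_intercept: float

    def summary(self) -> str:
        return (
            "TLD calibration: reading = slope x dose + intercept\n"
            f"  slope     = {self.slope:.6g} +/- {self.stderr_slope:.3g}\n"
            f"  intercept = {self.intercept:.6g} +/- {self.stderr_intercept:.3g}\n"
            f"  RMS residual = {np.sqrt(np.mean(self.residuals**2)):.3g}"
        )


def tld_calibration_fit(readings, delivered_doses_gy) -> TldCalibrationFit:
    """Ordinary least squares of reading on delivered dose (>= 2 dose levels)."""
    r = np.asarray(readings, dtype=float)
    d = np.asarray(delivered_doses_gy, dtype=float)
    if r.shape != d.shape or r.ndim != 1:
        raise ValueError("readings and doses must be matching 1D arrays")
    if np.unique(d).size < 2:
        raise ValueError("need at least 2 distinct dose levels")
    design = np.column_stack([d, np.ones_like(d)])
    coef, *_ = np.linalg.lstsq(design, r, rcond=None)
    slope, intercept = float(coef[0]), float(coef[1])
    resid = r - design @ coef
    dof = max(1, r.size - 2)
    s2 = float(resid @ resid) / dof
    xtx_inv = np.linalg.inv(design.T @ design)
    return TldCalibrationFit(
        slope=slope,
        intercept=intercept,
        residuals=resid,
        stderr_slope=float(np.sqrt(s2 * xtx_inv[0, 0])),
        stderr_intercept=float(np.sqrt(s2 * xtx_inv[1, 1])),
    )


def tld_dose(reading: float, fit: TldCalibrationFit) -> float:
    """Invert the calibration line: dose (Gy) for one reading."""
    if fit.slope == 0:
        raise ValueError("degenerate calibration: zero slope")
    return (float(reading) - fit.intercept) / fit.slope
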