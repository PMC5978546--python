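"""Port-model determination from depth-dose measurements.

The port density (and optionally diameter and thickness) is adjusted until
engine-calculated depth doses under the port match ion-chamber style
measurements taken in both the parallel and the perpendicular tank setup
across beam energies.  The forward model is the dose engine's primary term
restricted to the central axis: inverse-square x depth dose x
``exp(-mu/rho * (rho - 1) * chord)``, with the chord through the tilted
disk computed analytically for the candidate geometry.

The objective is the root-mean-square of relative differences
``(calc - meas) / meas`` over all depths, setups and energies, with equal
weights.  It is minimized by a coarse-to-fine grid search (two successive
x10 refinements of the step), which is robust to the non-smoothness a
voxelized forward model would introduce; exact ties break toward the
smaller density (conservative attenuation), then smaller diameter and
thickness.

Identifiability: on-axis depth doses determine the two excess areal
densities ``(rho - 1) x thickness`` (perpendicular) and ``(rho - 1) x
diameter`` (parallel) but not all three parameters separately, so the
joint search is exact only when the true parameters lie on the search
grid; see the methods note.  Measurements from a *single* setup leave even
more freedom — fitting the parallel setup alone does not reproduce
perpendicular measurements, which the joint-fit diagnostics quantify.
"""

from __future__ import annotations

import dataclasses
import itertools

import numpy as np

from .engine import DEFAULT_BEAM_DATA, BeamDataTable, pdd
from .geometry import PortModel, chord_length, make_port
from .measurements import SETUPS, DepthDoseRecord, MeasurementSet
from .phantoms import IC_FIELD_MM, IC_SSD_MM, place_ic_port

_SOURCE = (0.0, -IC_SSD_MM, 0.0)
_BEAM_DIR = (0.0, 1.0, 0.0)

PARAM_ORDER = ("density", "diameter", "thickness")
DEFAULT_SEARCH = {"density": (4.0, 10.0, 0.5)}
REFINEMENTS = 2  # each refinement shrinks the step x10


def predict_depth_doses(
    port: PortModel,
    setup: str,
    energy_mv: int,
    depths_mm: np.ndarray,
    table: BeamDataTable = DEFAULT_BEAM_DATA,
) -> np.ndarray:
    """Central-axis doses at depths below the water surface (relative units)."""
    placed = place_ic_port(port, setup)
    chord = chord_length(placed, _SOURCE, _BEAM_DIR)
    excess = (port.density - 1.0) * chord / 10.0  # g/cm^2
    depths = np.asarray(depths_mm, dtype=float)
    isq = (1000.0 / (IC_SSD_MM + depths)) ** 2
    mu = table[energy_mv].mu_rho
    return isq * pdd(energy_mv, depths, IC_FIELD_MM, table) * np.exp(-mu * excess)


def make_synthetic_measurements(
    port: PortModel,
    setups=SETUPS,
    energies=(6, 10, 15),
    depths_mm=tuple(float(d) for d in range(70, 151, 10)),
    noise_sigma: float = 0.0,
    rng: np.random.Generator | None = None,
    table: BeamDataTable = DEFAULT_BEAM_DATA,
) -> MeasurementSet:
    """Engine-generated depth-dose records, optionally with multiplicative
    Gaussian noise of relative width ``noise_sigma``."""
    if noise_sigma > 0 and rng is None:
        raise ValueError("noisy measurements require an explicit rng")
    records = []
    for setup in setups:
        for energy in energies:
            doses = predict_depth_doses(port, setup, energy, np.asarray(depths_mm), table)
            if noise_sigma > 0:
                doses = doses * (1.0 + noise_sigma * rng.standard_normal(doses.shape))
            records.append(DepthDoseRecord(setup, energy, np.asarray(depths_mm), doses))
    return MeasurementSet(depth_dose=records)


@dataclasses.dataclass
class CalibrationProblem:
    """Measurements plus the search-space definition.

    ``search`` maps parameter names (subset of density/diameter/thickness)
    to ``(low, high, step)``; unlisted geometry parameters are fixed at the
    values in ``fixed_port``.
    """

    measurements: MeasurementSet
    search: dict[str, tuple[float, float, float]] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_SEARCH)
    )
    fixed_port: PortModel = dataclasses.field(default_factory=make_port)

    def __post_init__(self) -> None:
        if not self.measurements.depth_dose:
            raise ValueError("calibration requires at least one depth-dose record")
        for rec in self.measurements.depth_dose:
            if len(rec) < 2:
                raise ValueError(
                    f"record ({rec.setup}, {rec.energy_mv} MV) has fewer than 2 depths"
                )
            if np.any(rec.doses <= 0):
                raise ValueError("measured doses must be > 0 for a relative objective")
        if not self.search:
            raise ValueError("empty search space")
        for name, (lo, hi, step) in self.search.items():
            if name not in PARAM_ORDER:
                raise ValueError(f"unknown search parameter {name!r}")
            if step <= 0 or hi < lo:
                raise ValueError(f"invalid search range for {name}: ({lo}, {hi}, {step})")

    def candidate(self, **params) -> PortModel:
        return dataclasses.replace(self.fixed_port, **params)


def discrepancy(
    problem: CalibrationProblem,
    candidate: PortModel,
    table: BeamDataTable = DEFAULT_BEAM_DATA,
    records: list[DepthDoseRecord] | None = None,
) -> float:
    """RMS relative difference between calculated and measured depth doses."""
    records = problem.measurements.depth_dose if records is None else records
    sq_sum = 0.0
    n = 0
    for rec in records:
        calc = predict_depth_doses(candidate, rec.setup, rec.energy_mv, rec.depths_mm, table)
        rel = (calc - rec.doses) / rec.doses
        sq_sum += float(np.sum(rel**2))
        n += len(rec)
    return float(np.sqrt(sq_sum / n))


def _axis(lo: float, hi: float, step: float) -> np.ndarray:
    n = int(np.floor((hi - lo) / step + 1e-9))
    return lo + step * np.arange(n + 1)


def _grid_search(problem, names, ranges, table, records=None):
    """Coarse-to-fine search; returns (best params, diagnostics)."""
    steps = {n: ranges[n][2] for n in names}
    los = {n: ranges[n][0] for n in names}
    his = {n: ranges[n][1] for n in names}
    diagnostics: dict = {"levels": []}
    best = None
    for level in range(REFINEMENTS + 1):
        axes = [_axis(los[n], his[n], steps[n]) for n in names]
        if any(len(a) < 2 for a in axes) and level == 0 and len(names) > 1:
            raise ValueError("search space too coarse: need >= 2 points per dimension")
        values = []
        combos = list(itertools.product(*axes))
        best_obj = np.inf
        best_combo = None
        for combo in combos:  # lexicographic order => ties keep the smallest
            cand = problem.candidate(**dict(zip(names, combo)))
            obj = discrepancy(problem, cand, table, records=records)
            values.append(obj)
            if obj < best_obj:
                best_obj = obj
                best_combo = combo
        diagnostics["levels"].append(
            {
                "step": dict(steps),
                "grid": {n: axes[i] for i, n in enumerate(names)},
                "candidates": np.array(combos),
                "objective": np.array(values),
            }
        )
        best = dict(zip(names, best_combo))
        diagnostics["objective"] = best_obj
        if level < REFINEMENTS:
            for n in names:
                new_step = steps[n] / 10.0
                los[n] = max(ranges[n][0], best[n] - steps[n])
                his[n] = min(ranges[n][1], best[n] + steps[n])
                steps[n] = new_step
    diagnostics["final_step"] = dict(steps)
    return best, diagnostics


def fit_density(
    problem: CalibrationProblem,
    table: BeamDataTable = DEFAULT_BEAM_DATA,
) -> tuple[float, dict]:
    """Density-only coarse-to-fine fit; diameter/thickness stay fixed.

    Returns the fitted density and diagnostics containing the full
    objective curve of the coarse scan and each refinement level.
    """
    if set(problem.search) != {"density"}:
        raise ValueError("fit_density expects a density-only search space")
    best, diagnostics = _grid_search(problem, ("density",), problem.search, table)
    diagnostics["density_grid"] = diagnostics["levels"][0]["grid"]["density"]
    diagnostics["objective_curve"] = diagnostics["levels"][0]["objective"]
    return best["density"], diagnostics


def fit_port_parameters(
    problem: CalibrationProblem,
    table: BeamDataTable = DEFAULT_BEAM_DATA,
    cross_check: bool = True,
) -> tuple[PortModel, dict]:
    """Joint grid search over (density, diameter, thickness).

    Diagnostics additionally report the cross-setup check: the same search
    restricted to parallel-setup records, evaluated on the perpendicular
    records — the mismatch that motivates fitting both setups jointly.
    """
    names = tuple(n for n in PARAM_ORDER if n in problem.search)
    if len(names) < 2:
        raise ValueError("fit_port_parameters expects a 2-3 dimensional search space")
    best, diagnostics = _grid_search(problem, names, problem.search, table)
    fitted = problem.candidate(**best)
    perp = [r for r in problem.measurements.depth_dose if r.setup == "perpendicular"]
    par = [r for r in problem.measurements.depth_dose if r.setup == "parallel"]
    if cross_check and perp and par:
        par_best, _ = _grid_search(problem, names, problem.search, table, records=par)
        par_fit = problem.candidate(**par_best)
        diagnostics["parallel_only_params"] = par_best
        diagnostics["parallel_only_perpendicular_rms"] = discrepancy(
            problem, par_fit, table, records=perp
        )
        diagnostics["joint_perpendicular_rms"] = discrepancy(problem, fitted, table, records=perp)
    return fitted, diagnostics


def sample_identifiable_ports(
    n: int,
    search: dict[str, tuple[float, float, float]],
    rng: np.random.Generator,
) -> list[PortModel]:
    """Random ground-truth ports on the coarse search grid, restricted to
    identifiable combinations.

    On-axis depth doses determine only the products ``(rho - 1) x
    thickness`` and ``(rho - 1) x diameter``; a combination is excluded if
    a *smaller-density* lattice point — on the coarse grid or on either
    refinement lattice around the truth — reproduces both products exactly
    (an alias the smaller-density tie-break would rightly prefer).  The
    remaining combinations have a unique exact zero of the objective on
    every lattice the search visits, so parameter recovery is well-posed.
    """
    axes = {name: _axis(*search[name]) for name in ("density", "diameter", "thickness")}

    def on_grid(value: float, name: str) -> bool:
        lo, hi, step = search[name]
        if value < lo - 1e-9 or value > hi + 1e-9:
            return False
        return abs((value - lo) / step - round((value - lo) / step)) < 1e-9

    def on_lattice(delta: float, step: float) -> bool:
        return abs(delta) <= 10 * step + 1e-9 and abs(delta / step - round(delta / step)) < 1e-9

    def has_alias(rho: float, dia: float, thk: float) -> bool:
        for rho2 in axes["density"]:
            if rho2 >= rho - 1e-12:
                break
            f = (rho - 1.0) / (rho2 - 1.0)
            if on_grid(thk * f, "thickness") and on_grid(dia * f, "diameter"):
                return True
        # refinement lattices: step/10^L within +/- 10 steps of the truth
        for level in (1, 2):
            s_rho = search["density"][2] / 10**level
            s_dia = search["diameter"][2] / 10**level
            s_thk = search["thickness"][2] / 10**level
            for k in range(1, 11):
                rho2 = rho - k * s_rho
                if rho2 <= 1.0:
                    break
                f = (rho - 1.0) / (rho2 - 1.0)
                if on_lattice(thk * (f - 1.0), s_thk) and on_lattice(dia * (f - 1.0), s_dia):
                    return True
        return False

    ports: list[PortModel] = []
    while len(ports) < n:
        rho = float(rng.choice(axes["density"]))
        dia = float(rng.choice(axes["diameter"]))
        thk = float(rng.choice(axes["thickness"]))
        if not has_alias(rho, dia, thk):
            ports.append(make_port(density=rho, diameter=dia, thickness=thk))
    return ports


# ---------------------------------------------------------------------------
# Model / results interface


class PortCalibration:
    """Calibration model: measurements in, fitted port parameters out.

    Mirrors the usual model/results split: construct with a
    :class:`MeasurementSet` (and optionally a search space and fixed
    geometry), call :meth:`fit`, inspect the returned
    :class:`PortCalibrationResult`.
    """

    def __init__(
        self,
        measurements: MeasurementSet,
        search: dict | None = None,
        fixed_port: PortModel | None = None,
        table: BeamDataTable = DEFAULT_BEAM_DATA,
    ) -> None:
        self.problem = CalibrationProblem(
            measurements=measurements,
            search=dict(search) if search else dict(DEFAULT_SEARCH),
            fixed_port=fixed_port if fixed_port is not None else make_port(),
        )
        self.table = table

    def fit(self) -> "PortCalibrationResult":
        if set(self.problem.search) == {"density"}:
            density, diagnostics = fit_density(self.problem, self.table)
            port = self.problem.candidate(density=density)
            params = {"density": density}
        else:
            port, diagnostics = fit_port_parameters(self.problem, self.table)
            params = {n: getattr(port, n) for n in PARAM_ORDER if n in self.problem.search}
        rms = discrepancy(self.problem, port, self.table)
        return PortCalibrationResult(self, port, params, rms, diagnostics)


@dataclasses.dataclass
class PortCalibrationResult:
    model: PortCalibration
    port: PortModel
    params: dict[str, float]
    rms: float
    diagnostics: dict

    @property
    def final_step(self) -> dict[str, float]:
        return self.diagnostics["final_step"]

    def summary(self) -> str:
        n_pts = sum(len(r) for r in self.model.problem.measurements.depth_dose)
        lines = [
            "Port calibration (coarse-to-fine grid search)",
            "=" * 52,
            f"{'parameter':<12}{'estimate':>12}{'final step':>14}",
            "-" * 52,
        ]
        units = {"density": "g/cm^3", "diameter": "mm", "thickness": "mm"}
        for name, value in self.params.items():
            step = self.final_step[name]
            lines.append(f"{name:<12}{value:>12.4g}{step:>14.4g}  {units[name]}")
        lines += [
            "-" * 52,
            f"RMS relative difference: {self.rms:.3e}",
            f"records: {len(self.model.problem.measurements.depth_dose)}"
            f"  depth points: {n_pts}",
        ]
        if "parallel_only_perpendicular_rms" in self.diagnostics:
            lines.append(
                "perpendicular RMS, parallel-only fit: "
                f"{self.diagnostics['parallel_only_perpendicular_rms']:.3e}"
                f" (joint: {self.diagnostics['joint_perpendicular_rms']:.3e})"
            )
        return "\n".join(lines)
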