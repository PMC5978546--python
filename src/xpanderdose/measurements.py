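"""Measured or reference doses: labeled points and depth-dose records."""

from __future__ import annotations

import dataclasses

import numpy as np

SETUPS = ("parallel", "perpendicular")


@dataclasses.dataclass
class PointMeasurement:
    label: str
    position_mm: tuple[float, float, float]
    dose: float | None = None
    sd: float | None = None

    def __post_init__(self) -> None:
        self.position_mm = tuple(float(c) for c in np.asarray(self.position_mm).reshape(3))
        if self.dose is not None and self.dose < 0:
            raise ValueError(f"point {self.label!r}: dose must be >= 0")


@dataclasses.dataclass
class DepthDoseRecord:
    """Doses along the beam axis under the port for one setup and energy."""

    setup: str
    energy_mv: int
    depths_mm: np.ndarray
    doses: np.ndarray

    def __post_init__(self) -> None:
        if self.setup not in SETUPS:
            raise ValueError(f"setup must be one of {SETUPS}, got {self.setup!r}")
        self.depths_mm = np.asarray(self.depths_mm, dtype=float)
        self.doses = np.asarray(self.doses, dtype=float)
        if self.depths_mm.shape != self.doses.shape or self.depths_mm.ndim != 1:
            raise ValueError("depths and doses must be matching 1D arrays")
        if np.any(np.diff(self.depths_mm) <= 0):
            raise ValueError("depths must be strictly increasing")
        if np.any(self.doses < 0):
            raise ValueError("doses must be >= 0")

    def __len__(self) -> int:
        return len(self.depths_mm)


@dataclasses.dataclass
class MeasurementSet:
    points: list[PointMeasurement] = dataclasses.field(default_factory=list)
    depth_dose: list[DepthDoseRecord] = dataclasses.field(default_factory=list)

    def __post_init__(self) -> None:
        labels = [p.label for p in self.points]
        if len(set(labels)) != len(labels):
            raise ValueError(f"duplicate point labels: {labels}")

    def point(self, label: str) -> PointMeasurement:
        for p in self.points:
            if p.label == label:
                return p
        raise KeyError(label)

    def labels(self) -> list[str]:
        return [p.label for p in self.points]
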