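"""Phantom-based densitometric calibration of CT volumes.

A calibration phantom with inserts of known equivalent calcium-hydroxyapatite
density is scanned together with the subject.  An ordinary-least-squares line
through the (mean insert HU, insert density) points maps Hounsfield units to
apparent density; ash density then follows from the affine conversion

    rho_ash = 1.22 * rho_apparent + 0.0526   [g/cm^3]

The insert densities are treated directly as apparent densities (an optional
affine adaptor is available for scanner-specific CaHA-to-apparent
conversions, default identity).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import stats

from .volume import CTVolume, PhantomSpec

#: Coefficients of the apparent-to-ash affine conversion.
ASH_SLOPE = 1.22
ASH_INTERCEPT = 0.0526


@dataclass
class CalibrationLine:
    """HU -> density affine map fitted on the phantom inserts.

    ``rho = slope * HU + intercept`` with ``slope`` in g/cm^3 per HU.
    """

    slope: float
    intercept: float
    r_squared: float
    n_points: int

    def __post_init__(self) -> None:
        if self.n_points < 2:
            raise ValueError("calibration needs at least 2 inserts")
        if not (-1e-9 <= self.r_squared <= 1 + 1e-9):
            raise ValueError("r_squared must lie in [0, 1]")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "slope": self.slope, "intercept": self.intercept,
            "r_squared": self.r_squared, "n_points": self.n_points,
        }, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "CalibrationLine":
        d = json.loads(Path(path).read_text())
        return cls(d["slope"], d["intercept"], d["r_squared"], d["n_points"])


@dataclass
class DensityVolume:
    """Per-voxel apparent and ash density, g/cm^3."""

    rho_apparent: np.ndarray
    spacing: tuple[float, float, float]
    rho_ash: np.ndarray | None = None
    n_clamped: int = 0

    def __post_init__(self) -> None:
        self.rho_apparent = np.asarray(self.rho_apparent, dtype=float)
        if np.any(self.rho_apparent < 0):
            raise ValueError("rho_apparent must be clamped to >= 0")


def fit_calibration(volume: CTVolume, phantom: PhantomSpec) -> CalibrationLine:
    """OLS line mapping mean insert HU to known insert density.

    Raises if fewer than two inserts are available or the insert ROI means
    are indistinguishable (singular fit).
    """
    if len(phantom.insert_densities) < 2:
        raise ValueError("calibration needs at least 2 inserts")
    hu = phantom.roi_means(volume)
    rho = np.asarray(phantom.insert_densities)
    if np.ptp(hu) == 0:
        raise ValueError("identical ROI means for distinct densities: singular fit")
    res = stats.linregress(hu, rho)
    return CalibrationLine(slope=float(res.slope), intercept=float(res.intercept),
                           r_squared=float(res.rvalue ** 2), n_points=len(rho))


def hu_to_apparent(volume: CTVolume, line: CalibrationLine) -> DensityVolume:
    """Apply the calibration line voxelwise; negative densities clamp to zero.

    Voxels with negative calibrated density (air, soft tissue, marrow fat
    below the line's zero crossing) are set to 0 g/cm^3 and counted in
    ``n_clamped``.
    """
    rho = line.slope * volume.intensities + line.intercept
    n_clamped = int(np.count_nonzero(rho < 0))
    return DensityVolume(rho_apparent=np.maximum(rho, 0.0),
                         spacing=volume.spacing, n_clamped=n_clamped)


def apparent_to_ash(dv: DensityVolume) -> DensityVolume:
    """Fill ``rho_ash = 1.22 * rho_apparent + 0.0526`` elementwise."""
    dv.rho_ash = ASH_SLOPE * dv.rho_apparent + ASH_INTERCEPT
    return dv


def ash_to_apparent(rho_ash: np.ndarray | float) -> np.ndarray | float:
    """Analytic inverse of :func:`apparent_to_ash`."""
    return (rho_ash - ASH_INTERCEPT) / ASH_SLOPE


def calibrate_volume(volume: CTVolume, phantom: PhantomSpec,
                     line: CalibrationLine | None = None) -> tuple[DensityVolume, CalibrationLine]:
    """Fit (or reuse) a calibration line and produce the full density volume."""
    if line is None:
        line = fit_calibration(volume, phantom)
    dv = apparent_to_ash(hu_to_apparent(volume, line))
    return dv, line
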