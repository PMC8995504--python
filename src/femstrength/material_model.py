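"""Density-to-material laws and discretisation into material bins.

Bone elastic modulus and yield strength are empirical piecewise power/linear
laws of ash density (g/cm^3):

    E(rho) [MPa]  = 0.001                    rho = 0
                  = 33900 * rho**2.2         0   < rho <= 0.27
                  =  5307 * rho + 469        0.27 < rho <= 0.6
                  = 10200 * rho**2.01        rho > 0.6

    sigma_y(rho) [MPa] = 137 * rho**1.88     rho < 0.317
                       = 114 * rho**1.72     rho >= 0.317

Poisson's ratio is 0.4 everywhere.  Both laws are continuous at their
breakpoints to well under 1% and non-decreasing, so binning densities before
evaluation loses little accuracy.  Finite-element models group bone elements
into a fixed number of material bins (default 120) spanning the observed ash
density range, with each bin's properties evaluated at the bin midpoint.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .calibration import DensityVolume

#: Poisson's ratio of bone.
POISSON_BONE = 0.4

#: Modulus floor (MPa), the tabulated value at zero ash density; keeps the
#: global stiffness matrix non-singular for fully demineralised voxels.
E_FLOOR = 0.001

DEFAULT_N_BINS = 120


def elastic_modulus(rho_ash):
    """Elastic modulus (MPa) from ash density (g/cm^3).

    Accepts scalars or arrays; negative densities are rejected.  Breakpoints
    belong to the lower branch (0.27 and 0.6 evaluate on the left law).
    """
    rho = np.asarray(rho_ash, dtype=float)
    if np.any(rho < 0):
        raise ValueError("ash density must be non-negative")
    e = np.empty_like(rho)
    low = rho <= 0.27
    mid = (rho > 0.27) & (rho <= 0.6)
    high = rho > 0.6
    e[low] = 33900.0 * rho[low] ** 2.2
    e[mid] = 5307.0 * rho[mid] + 469.0
    e[high] = 10200.0 * rho[high] ** 2.01
    # The tabulated value at zero density acts as a floor: the power branch
    # dips below it for rho < ~0.053 g/cm^3, and flooring keeps the map
    # non-decreasing while preserving the stated zero-density modulus.
    np.maximum(e, E_FLOOR, out=e)
    return e if e.ndim else float(e)


def yield_strength(rho_ash):
    """Yield strength (MPa) from ash density (g/cm^3).

    Lower power law below 0.317 g/cm^3, upper at and above it.
    """
    rho = np.asarray(rho_ash, dtype=float)
    if np.any(rho < 0):
        raise ValueError("ash density must be non-negative")
    s = np.where(rho < 0.317, 137.0 * rho ** 1.88, 114.0 * rho ** 1.72)
    return s if s.ndim else float(s)


@dataclass
class MaterialTable:
    """Binned material properties plus the per-element bin assignment.

    ``bin_edges`` has ``n_bins + 1`` entries over the observed ash-density
    range; ``E``/``sigma_y`` are evaluated at each bin's midpoint density.
    """

    n_bins: int
    bin_edges: np.ndarray
    rho_mid: np.ndarray
    E: np.ndarray
    sigma_y: np.ndarray
    poisson: float
    element_to_bin: np.ndarray

    @property
    def n_occupied(self) -> int:
        """Number of distinct materials actually used by elements."""
        return int(np.unique(self.element_to_bin).size)

    def element_modulus(self) -> np.ndarray:
        return self.E[self.element_to_bin]

    def element_yield(self) -> np.ndarray:
        return self.sigma_y[self.element_to_bin]


def bin_materials(rho_ash_elements: np.ndarray,
                  n_bins: int = DEFAULT_N_BINS) -> MaterialTable:
    """Split element ash densities into equal-width bins and tabulate E, sigma.

    ``rho_ash_elements`` is the per-element ash density (one value per bone
    element, already resampled to the mesh).  The observed density range is
    divided into ``n_bins`` equal-width bins; each element maps to the bin
    containing its density, and each bin's modulus and yield strength are the
    laws evaluated at the bin midpoint.  A uniform field degenerates to a
    single occupied bin.
    """
    rho = np.asarray(rho_ash_elements, dtype=float).ravel()
    if rho.size == 0:
        raise ValueError("no elements to bin (empty mask)")
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    lo, hi = float(rho.min()), float(rho.max())
    if hi == lo:
        hi = lo + max(1e-9, abs(lo) * 1e-9)
    edges = np.linspace(lo, hi, n_bins + 1)
    idx = np.clip(np.searchsorted(edges, rho, side="right") - 1, 0, n_bins - 1)
    mid = 0.5 * (edges[:-1] + edges[1:])
    return MaterialTable(
        n_bins=n_bins, bin_edges=edges, rho_mid=mid,
        E=np.asarray(elastic_modulus(mid)),
        sigma_y=np.asarray(yield_strength(mid)),
        poisson=POISSON_BONE, element_to_bin=idx,
    )


def bin_materials_from_volume(dv: DensityVolume, bone_mask: np.ndarray,
                              n_bins: int = DEFAULT_N_BINS) -> MaterialTable:
    """Bin the masked voxels of a density volume (no resampling)."""
    mask = np.asarray(bone_mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty bone mask")
    if dv.rho_ash is None:
        raise ValueError("density volume has no ash density; run apparent_to_ash first")
    return bin_materials(dv.rho_ash[mask], n_bins=n_bins)


def exact_materials(rho_ash_elements: np.ndarray) -> MaterialTable:
    """Unbinned table: one material per element, laws evaluated pointwise.

    Used to quantify the discretisation error of the 120-bin assignment.
    """
    rho = np.asarray(rho_ash_elements, dtype=float).ravel()
    if rho.size == 0:
        raise ValueError("no elements")
    edges = np.concatenate([rho, [rho.max()]])
    return MaterialTable(
        n_bins=rho.size, bin_edges=edges, rho_mid=rho,
        E=np.asarray(elastic_modulus(rho)),
        sigma_y=np.asarray(yield_strength(rho)),
        poisson=POISSON_BONE,
        element_to_bin=np.arange(rho.size),
    )
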