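"""Synthetic CT volumes and cohorts with known ground truth.

Every downstream stage of the pipeline — phantom calibration, material
assignment, meshing, the finite-element solve and the cohort statistics — is
exercised against data produced here, because the study-style inputs (QCT
scans of proximal femurs with an in-scan calcium-hydroxyapatite phantom, and
an 18-subject clinical covariate table) are not publicly deposited.

Three generators are provided:

* :func:`generate_phantom_volume` — a volume containing only the calibration
  inserts, intensities synthesised from a known affine HU(rho) map.
* :func:`generate_femur_volume` — a parametric femur-like solid (vertical
  shaft cylinder + neck frustum + head sphere) with a dense cortical shell
  grading into a smooth low-density trabecular interior, plus the phantom
  inserts below the bone.  A degenerate "column" preset gives the uniform
  rectangular prism used by the analytic finite-element oracles.
* :func:`generate_cohort` — per-subject covariate tables for a diabetic and a
  control arm, with femoral strength generated from a known linear model so
  regression recovery can be tested exactly.

All randomness flows through one explicit integer seed per call; identical
seeds give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .volume import CTVolume, PhantomSpec, SyntheticTruth

#: Equivalent CaHA densities of the three calibration inserts, g/cm^3.
DEFAULT_INSERT_DENSITIES = (0.05, 0.1, 0.2)

#: Default affine HU model used when synthesising intensities: HU = 1000*rho.
DEFAULT_HU_SLOPE = 1000.0
DEFAULT_HU_INTERCEPT = 0.0


def default_phantom(shape: tuple[int, int, int] = (48, 48, 96),
                    insert_densities: tuple[float, ...] = DEFAULT_INSERT_DENSITIES,
                    roi_size: int = 8) -> PhantomSpec:
    """Three-insert phantom laid out along x near the low-y edge of the grid.

    The inserts sit below the bone (low y), mirroring a phantom placed under
    the hip during scanning.
    """
    nx, ny, nz = shape
    n = len(insert_densities)
    roi_size = min(roi_size, (nx - n) // n, ny - 2, nz - 2)
    if roi_size < 1:
        raise ValueError(f"grid {shape} too small for a {n}-insert phantom")
    gap = max(1, (nx - n * roi_size) // (n + 1))
    k0 = nz // 2 - roi_size // 2
    rois = []
    for i in range(n):
        i0 = gap + i * (roi_size + gap)
        rois.append(((i0, i0 + roi_size), (1, 1 + roi_size), (k0, k0 + roi_size)))
    spec = PhantomSpec(tuple(insert_densities), tuple(rois))
    spec.check_inside(shape)
    return spec


def _synthesize_hu(rho: np.ndarray, hu_slope: float, hu_intercept: float,
                   noise_sd: float, rng: np.random.Generator) -> np.ndarray:
    hu = hu_slope * rho + hu_intercept
    if noise_sd > 0:
        hu = hu + rng.normal(0.0, noise_sd, size=rho.shape)
    return hu


def generate_phantom_volume(phantom: PhantomSpec,
                            shape: tuple[int, int, int] = (48, 48, 96),
                            spacing: tuple[float, float, float] = (1.5, 1.5, 1.5),
                            hu_slope: float = DEFAULT_HU_SLOPE,
                            hu_intercept: float = DEFAULT_HU_INTERCEPT,
                            noise_sd: float = 0.0,
                            seed: int = 0) -> tuple[CTVolume, SyntheticTruth]:
    """Volume containing only the calibration inserts.

    Each insert ROI is filled with its equivalent density; intensities are
    ``hu_slope * rho + hu_intercept`` plus i.i.d. Gaussian noise of standard
    deviation ``noise_sd`` (HU).  The returned truth records the generating
    affine map, so calibration recovery can be checked against it.
    """
    phantom.check_inside(shape)
    rng = np.random.default_rng(seed)
    rho = np.zeros(shape)
    for i in range(len(phantom.insert_densities)):
        rho[phantom.roi_slices(i)] = phantom.insert_densities[i]
    hu = _synthesize_hu(rho, hu_slope, hu_intercept, noise_sd, rng)
    vol = CTVolume(hu, spacing)
    truth = SyntheticTruth(rho, np.zeros(shape, dtype=bool),
                           hu_slope, hu_intercept, noise_sd, seed)
    return vol, truth


@dataclass
class FemurShape:
    """Parametric femur-like solid, dimensions in mm.

    The shaft is a vertical cylinder, the head a sphere whose apex is the
    superior-most point of the bone, and the neck a frustum joining the shaft
    top to the head centre.  ``shell_thickness`` is the cortical shell depth
    measured inward from the bone surface.
    """

    shaft_radius: float = 11.0
    shaft_height: float = 60.0
    neck_radius: float = 8.0
    head_radius: float = 16.0
    head_offset_x: float = 14.0
    shell_thickness: float = 4.0

    def __post_init__(self) -> None:
        if self.shell_thickness <= 0:
            raise ValueError("cortical shell thickness must be positive")
        if min(self.shaft_radius, self.neck_radius, self.head_radius,
               self.shaft_height) <= 0:
            raise ValueError("all femur dimensions must be positive")


@dataclass
class DensityParams:
    """Apparent-density ranges of the synthetic bone, g/cm^3.

    The trabecular interior is a smooth random field in
    ``[trabecular_min, trabecular_max]``; across the cortical shell the
    density ramps linearly from the trabecular ceiling at the shell's inner
    boundary up to ``cortical_max`` at the bone surface, so the full range
    ``[trabecular_min, cortical_max]`` is covered without gaps.
    """

    trabecular_min: float = 0.1
    trabecular_max: float = 0.6
    cortical_max: float = 1.8
    smoothness_mm: float = 6.0

    def __post_init__(self) -> None:
        if not (0 <= self.trabecular_min < self.trabecular_max < self.cortical_max):
            raise ValueError("density ranges must satisfy 0 <= trab_min < trab_max < cort_max")


def _femur_depth(shape, spacing, geom: FemurShape) -> np.ndarray:
    """Analytic inside-depth (mm) of the femur solid at each voxel centre.

    Positive inside the bone, negative outside; the union of shaft cylinder,
    neck frustum and head sphere takes the maximum of the per-primitive
    depths, which is continuous across voxels (unlike a voxelised distance
    transform) so the cortical ramp produces a gap-free density spectrum.
    """
    nx, ny, nz = shape
    dx, dy, dz = spacing
    x = (np.arange(nx) + 0.5) * dx
    y = (np.arange(ny) + 0.5) * dy
    z = (np.arange(nz) + 0.5) * dz
    X, Y, Z = np.meshgrid(x, y, z, indexing="ij")

    # Shaft axis placed away from the phantom (which sits at low y).
    cx = 0.32 * nx * dx
    cy = 0.60 * ny * dy
    z0 = 2.0 * dz
    z1 = z0 + geom.shaft_height
    r_xy = np.sqrt((X - cx) ** 2 + (Y - cy) ** 2)
    d_shaft = np.minimum(geom.shaft_radius - r_xy, np.minimum(Z - z0, z1 - Z))

    # Head: sphere whose apex is the superior-most bone point.
    hx = cx + geom.head_offset_x
    head_cz = min(z1 + 1.6 * geom.head_radius, nz * dz - geom.head_radius - 2 * dz)
    d_head = geom.head_radius - np.sqrt(
        (X - hx) ** 2 + (Y - cy) ** 2 + (Z - head_cz) ** 2)

    # Neck: frustum from the shaft-top centre to the head centre.
    p0 = np.array([cx, cy, z1 - 2.0])
    p1 = np.array([hx, cy, head_cz])
    axis = p1 - p0
    L = float(np.linalg.norm(axis))
    u = axis / L
    rel = np.stack([X - p0[0], Y - p0[1], Z - p0[2]], axis=-1)
    t = rel @ u
    radial = np.sqrt(np.maximum(np.einsum("...i,...i", rel, rel) - t ** 2, 0.0))
    r_t = geom.shaft_radius + (geom.neck_radius - geom.shaft_radius) * np.clip(t / L, 0, 1)
    d_neck = np.minimum(r_t - radial, np.minimum(t, L - t))

    return np.maximum(d_shaft, np.maximum(d_head, d_neck))


def generate_femur_volume(shape: tuple[int, int, int] = (48, 48, 96),
                          spacing: tuple[float, float, float] = (1.5, 1.5, 1.5),
                          geometry: FemurShape | None = None,
                          density: DensityParams | None = None,
                          phantom: PhantomSpec | None = None,
                          hu_slope: float = DEFAULT_HU_SLOPE,
                          hu_intercept: float = DEFAULT_HU_INTERCEPT,
                          noise_sd: float = 0.0,
                          seed: int = 0) -> tuple[CTVolume, SyntheticTruth, PhantomSpec]:
    """Femur-like volume with phantom inserts and exact ground truth.

    Returns the HU volume, the generating truth (density field, bone mask,
    affine HU map) and the phantom spec used.
    """
    geometry = geometry or FemurShape()
    density = density or DensityParams()
    if phantom is None:
        phantom = default_phantom(shape)
    phantom.check_inside(shape)
    rng = np.random.default_rng(seed)

    depth = _femur_depth(shape, spacing, geometry)
    mask = depth > 0
    if not mask.any():
        raise ValueError("femur geometry does not intersect the grid")

    # Smooth trabecular field: Gaussian-filtered white noise rescaled to the
    # requested range.
    raw = rng.standard_normal(shape)
    sigma_vox = [density.smoothness_mm / s for s in spacing]
    smooth = ndimage.gaussian_filter(raw, sigma=sigma_vox)
    lo, hi = smooth.min(), smooth.max()
    trab = density.trabecular_min + (density.trabecular_max - density.trabecular_min) \
        * (smooth - lo) / (hi - lo)

    # Cortical ramp: density rises linearly from the trabecular value at the
    # shell's inner boundary to cortical_max at the surface.
    t_shell = np.clip(1.0 - depth / geometry.shell_thickness, 0.0, 1.0)
    rho = np.where(mask, trab + t_shell * (density.cortical_max - trab), 0.0)
    # Voxelisation quantises the surface depth, so the ramp never quite
    # attains the endpoints; rescale the masked field to span the requested
    # range exactly.
    vals = rho[mask]
    lo_v, hi_v = vals.min(), vals.max()
    rho[mask] = density.trabecular_min + (vals - lo_v) \
        * (density.cortical_max - density.trabecular_min) / (hi_v - lo_v)

    for i in range(len(phantom.insert_densities)):
        sl = phantom.roi_slices(i)
        if mask[sl].any():
            raise ValueError("phantom ROI intersects the bone")
        rho[sl] = phantom.insert_densities[i]

    hu = _synthesize_hu(rho, hu_slope, hu_intercept, noise_sd, rng)
    vol = CTVolume(hu, spacing)
    truth = SyntheticTruth(rho, mask, hu_slope, hu_intercept, noise_sd, seed)
    return vol, truth, phantom


def generate_column_volume(column_shape: tuple[int, int, int] = (8, 8, 24),
                           grid_shape: tuple[int, int, int] | None = None,
                           spacing: tuple[float, float, float] = (1.5, 1.5, 1.5),
                           rho_apparent: float = 0.8,
                           phantom: PhantomSpec | None = None,
                           hu_slope: float = DEFAULT_HU_SLOPE,
                           hu_intercept: float = DEFAULT_HU_INTERCEPT,
                           noise_sd: float = 0.0,
                           seed: int = 0) -> tuple[CTVolume, SyntheticTruth, PhantomSpec]:
    """Uniform-density rectangular prism — the analytic oracle geometry.

    The column is centred in x/y and rests two voxel layers above the grid
    bottom; its uniform apparent density makes closed-form column mechanics
    (reaction = E*eps*A elastic, sigma*A plastic) exact references for the
    solver.
    """
    a, b, c = column_shape
    if min(a, b, c) <= 0:
        raise ValueError("column dimensions must be positive")
    if grid_shape is None:
        grid_shape = (a + 8, b + 8, c + 8)
    nx, ny, nz = grid_shape
    if a > nx or b > ny or c + 4 > nz:
        raise ValueError("column does not fit inside the grid")
    if phantom is None:
        # Inserts sit at low y; keep them clear of the centred column.
        roi_size = min(4, (ny - b) // 2 - 2)
        phantom = default_phantom(grid_shape, roi_size=max(1, roi_size))
    rng = np.random.default_rng(seed)

    mask = np.zeros(grid_shape, dtype=bool)
    i0, j0, k0 = (nx - a) // 2, (ny - b) // 2, 2
    mask[i0:i0 + a, j0:j0 + b, k0:k0 + c] = True
    rho = np.where(mask, float(rho_apparent), 0.0)
    for i in range(len(phantom.insert_densities)):
        sl = phantom.roi_slices(i)
        if mask[sl].any():
            raise ValueError("phantom ROI intersects the column")
        rho[sl] = phantom.insert_densities[i]

    hu = _synthesize_hu(rho, hu_slope, hu_intercept, noise_sd, rng)
    vol = CTVolume(hu, spacing)
    truth = SyntheticTruth(rho, mask, hu_slope, hu_intercept, noise_sd, seed)
    return vol, truth, phantom


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

@dataclass
class GroupSpec:
    """Generating model for one study arm.

    Covariates are drawn from a multivariate normal with the given means,
    SDs and correlation matrix; femoral strength is
    ``intercept + slopes . covariates + N(0, noise_sd)``.
    """

    name: str
    n: int
    covariates: tuple[str, ...]
    means: np.ndarray
    sds: np.ndarray
    correlation: np.ndarray
    intercept: float
    slopes: dict[str, float]
    noise_sd: float

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=float)
        self.sds = np.asarray(self.sds, dtype=float)
        self.correlation = np.asarray(self.correlation, dtype=float)
        p = len(self.covariates)
        if self.n < 3:
            raise ValueError("each group needs n >= 3 subjects")
        if self.means.shape != (p,) or self.sds.shape != (p,):
            raise ValueError("means/sds must match the covariate list")
        if self.correlation.shape != (p, p):
            raise ValueError("correlation matrix shape mismatch")
        if not np.allclose(self.correlation, self.correlation.T):
            raise ValueError("correlation matrix must be symmetric")
        eig = np.linalg.eigvalsh(self.correlation)
        if eig.min() < -1e-10:
            raise ValueError("correlation matrix must be positive semi-definite")
        unknown = set(self.slopes) - set(self.covariates)
        if unknown:
            raise ValueError(f"slopes refer to unknown covariates: {sorted(unknown)}")


@dataclass
class CohortSpec:
    """Two-arm cohort specification with per-arm generating models."""

    groups: tuple[GroupSpec, ...]
    seed: int = 0


_COHORT_COVARIATES = ("age", "bmi", "femoral_bmd", "fn_t_score",
                      "hba1c", "p1np", "pentosidine", "c_peptide")


def _corr(pairs: dict[tuple[str, str], float]) -> np.ndarray:
    p = len(_COHORT_COVARIATES)
    idx = {c: i for i, c in enumerate(_COHORT_COVARIATES)}
    m = np.eye(p)
    for (a, b), r in pairs.items():
        m[idx[a], idx[b]] = m[idx[b], idx[a]] = r
    return m


def default_cohort_spec(n_t2dm: int = 10, n_control: int = 8,
                        noise_sd: float = 400.0, seed: int = 0) -> CohortSpec:
    """Cohort emulating the study arms: elderly diabetic men vs controls.

    Covariate locations follow the published group medians (age ~68 vs ~62 y,
    HbA1c ~8 vs ~5.6 %, P1NP lower in the diabetic arm, femoral BMD tightly
    coupled to the neck T score).  Strength is generated from the published
    best-model coefficients of each arm, so the diabetic arm's strength is
    positively tied to the T score and negatively to pentosidine, age and
    HbA1c, while the control arm's is driven by the T score, BMI and P1NP.
    """
    shared_corr = {
        ("femoral_bmd", "fn_t_score"): 0.9,
        ("pentosidine", "age"): 0.3,
        ("pentosidine", "c_peptide"): 0.35,
        ("p1np", "c_peptide"): 0.2,
    }
    t2dm = GroupSpec(
        name="t2dm", n=n_t2dm, covariates=_COHORT_COVARIATES,
        means=np.array([68.0, 25.7, 1016.0, 0.0, 8.0, 33.3, 575.0, 1.17]),
        sds=np.array([7.0, 1.8, 120.0, 1.3, 1.0, 8.0, 150.0, 0.4]),
        correlation=_corr(shared_corr),
        intercept=29240.848,
        slopes={"fn_t_score": 315.404, "pentosidine": -14.118, "age": -153.863,
                "hba1c": -879.085, "p1np": 161.406},
        noise_sd=noise_sd,
    )
    control = GroupSpec(
        name="control", n=n_control, covariates=_COHORT_COVARIATES,
        means=np.array([62.0, 23.7, 935.0, -1.8, 5.6, 54.3, 617.0, 1.64]),
        sds=np.array([5.0, 2.2, 90.0, 1.0, 0.3, 20.0, 200.0, 0.45]),
        correlation=_corr(shared_corr),
        intercept=9584.833,
        slopes={"fn_t_score": 745.051, "bmi": -40.206, "p1np": -13.840},
        noise_sd=noise_sd,
    )
    return CohortSpec(groups=(t2dm, control), seed=seed)


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw a cohort table from a :class:`CohortSpec`.

    Returns one row per subject with a ``group`` column, all covariates, the
    observed ``femoral_strength`` and the noiseless generating
    ``strength_true`` (kept so coefficient-recovery tests have an exact
    reference).
    """
    rng = np.random.default_rng(spec.seed)
    frames = []
    sid = 0
    for g in spec.groups:
        chol = np.linalg.cholesky(
            g.correlation + 1e-12 * np.eye(len(g.covariates)))
        z = rng.standard_normal((g.n, len(g.covariates)))
        x = g.means + (z @ chol.T) * g.sds
        beta = np.array([g.slopes.get(c, 0.0) for c in g.covariates])
        strength_true = g.intercept + x @ beta
        strength = strength_true + rng.normal(0.0, g.noise_sd, size=g.n)
        df = pd.DataFrame(x, columns=list(g.covariates))
        df.insert(0, "subject_id", [f"{g.name}_{sid + i:03d}" for i in range(g.n)])
        df.insert(1, "group", g.name)
        df["femoral_strength"] = strength
        df["strength_true"] = strength_true
        sid += g.n
        frames.append(df)
    return pd.concat(frames, ignore_index=True)
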