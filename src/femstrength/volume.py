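"""Voxel-volume containers and image IO.

The central container is :class:`CTVolume`, a 3D grid of Hounsfield-unit
intensities with isotropic-or-not voxel spacing in millimetres.  The volume
axis convention throughout the package is ``(x, y, z)`` with ``z`` the
superior–inferior loading axis: ``intensities[i, j, k]`` is the voxel at
``origin + (i*dx, j*dy, k*dz)``.

Volumes round-trip through NIfTI (via nibabel) and MetaImage (via SimpleITK);
ground-truth annotations for synthetic volumes travel in a JSON sidecar.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np


@dataclass
class CTVolume:
    """A CT-like voxel volume in Hounsfield units.

    Parameters
    ----------
    intensities : ndarray, shape (nx, ny, nz)
        HU value per voxel.
    spacing : tuple of float
        Voxel edge lengths ``(dx, dy, dz)`` in mm; strictly positive.
    origin : tuple of float
        Physical offset of voxel ``(0, 0, 0)`` in mm.
    """

    intensities: np.ndarray
    spacing: tuple[float, float, float] = (1.5, 1.5, 1.5)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 3 or self.intensities.size == 0:
            raise ValueError("intensities must be a non-empty 3D array")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be three strictly positive lengths")
        self.origin = tuple(float(o) for o in self.origin)
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape

    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.spacing))


@dataclass
class PhantomSpec:
    """Calibration-phantom description: insert densities and their voxel ROIs.

    ``insert_densities`` are equivalent calcium-hydroxyapatite densities in
    g/cm^3, strictly increasing.  ``insert_rois`` are half-open voxel index
    boxes ``((i0, i1), (j0, j1), (k0, k1))``, one per insert, pairwise
    disjoint.
    """

    insert_densities: tuple[float, ...]
    insert_rois: tuple[tuple[tuple[int, int], tuple[int, int], tuple[int, int]], ...]

    def __post_init__(self) -> None:
        self.insert_densities = tuple(float(d) for d in self.insert_densities)
        if len(self.insert_densities) != len(self.insert_rois):
            raise ValueError("one ROI per insert density required")
        if any(b <= a for a, b in zip(self.insert_densities, self.insert_densities[1:])):
            raise ValueError("insert densities must be strictly increasing")
        rois = []
        for roi in self.insert_rois:
            roi = tuple((int(lo), int(hi)) for lo, hi in roi)
            if any(hi <= lo for lo, hi in roi):
                raise ValueError(f"degenerate ROI {roi}")
            rois.append(roi)
        self.insert_rois = tuple(rois)
        for a in range(len(rois)):
            for b in range(a + 1, len(rois)):
                if _boxes_overlap(rois[a], rois[b]):
                    raise ValueError(f"insert ROIs {a} and {b} overlap")

    def check_inside(self, shape: tuple[int, int, int]) -> None:
        for roi in self.insert_rois:
            for (lo, hi), n in zip(roi, shape):
                if lo < 0 or hi > n:
                    raise ValueError(f"ROI {roi} outside grid of shape {shape}")

    def roi_slices(self, index: int) -> tuple[slice, slice, slice]:
        return tuple(slice(lo, hi) for lo, hi in self.insert_rois[index])

    def roi_means(self, volume: CTVolume) -> np.ndarray:
        """Mean HU inside each insert ROI."""
        self.check_inside(volume.shape)
        return np.array(
            [float(volume.intensities[self.roi_slices(i)].mean())
             for i in range(len(self.insert_densities))]
        )


def _boxes_overlap(a, b) -> bool:
    return all(lo_a < hi_b and lo_b < hi_a
               for (lo_a, hi_a), (lo_b, hi_b) in zip(a, b))


@dataclass
class SyntheticTruth:
    """Ground truth attached to a synthetic volume.

    Records the per-voxel apparent-density field the intensities were
    synthesised from, the bone mask, and the affine HU model
    ``HU = hu_slope * rho_apparent + hu_intercept`` plus the noise level,
    so downstream stages can be checked against exact expectations.
    """

    rho_apparent_field: np.ndarray
    bone_mask: np.ndarray
    hu_slope: float
    hu_intercept: float
    noise_sd: float
    seed: int | None = None

    def __post_init__(self) -> None:
        self.rho_apparent_field = np.asarray(self.rho_apparent_field, dtype=float)
        self.bone_mask = np.asarray(self.bone_mask, dtype=bool)
        if self.rho_apparent_field.shape != self.bone_mask.shape:
            raise ValueError("truth field and mask shapes differ")
        if np.any(self.rho_apparent_field < 0):
            raise ValueError("rho_apparent_field must be non-negative")


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

def save_volume(volume: CTVolume, path: str | Path) -> None:
    """Write a volume as NIfTI (``.nii``/``.nii.gz``) or MetaImage (``.mha``/``.mhd``)."""
    path = Path(path)
    suffixes = "".join(path.suffixes)
    if suffixes.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        affine = np.diag(list(volume.spacing) + [1.0])
        affine[:3, 3] = volume.origin
        nib.save(nib.Nifti1Image(volume.intensities, affine), str(path))
    elif path.suffix in (".mha", ".mhd"):
        import SimpleITK as sitk

        # SimpleITK indexes (z, y, x); transpose so spacing semantics survive.
        img = sitk.GetImageFromArray(np.ascontiguousarray(volume.intensities.T))
        img.SetSpacing(volume.spacing)
        img.SetOrigin(volume.origin)
        sitk.WriteImage(img, str(path))
    else:
        raise ValueError(f"unsupported volume format: {path.name}")


def load_volume(path: str | Path) -> CTVolume:
    """Read a NIfTI or MetaImage volume into a :class:`CTVolume`."""
    path = Path(path)
    suffixes = "".join(path.suffixes)
    if suffixes.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        img = nib.load(str(path))
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        origin = tuple(float(v) for v in img.affine[:3, 3])
        return CTVolume(np.asarray(img.dataobj, dtype=float), spacing, origin)
    if path.suffix in (".mha", ".mhd"):
        import SimpleITK as sitk

        img = sitk.ReadImage(str(path))
        data = sitk.GetArrayFromImage(img).T
        return CTVolume(np.asarray(data, dtype=float),
                        tuple(img.GetSpacing()), tuple(img.GetOrigin()))
    raise ValueError(f"unsupported volume format: {path.name}")


def save_truth(truth: SyntheticTruth, path: str | Path) -> None:
    """Write ground-truth annotations as a JSON sidecar (fields inline as lists)."""
    payload = {
        "hu_slope": truth.hu_slope,
        "hu_intercept": truth.hu_intercept,
        "noise_sd": truth.noise_sd,
        "seed": truth.seed,
        "shape": list(truth.bone_mask.shape),
        "rho_apparent_field": truth.rho_apparent_field.ravel().tolist(),
        "bone_mask": truth.bone_mask.ravel().astype(int).tolist(),
    }
    Path(path).write_text(json.dumps(payload))


def load_truth(path: str | Path) -> SyntheticTruth:
    payload = json.loads(Path(path).read_text())
    shape = tuple(payload["shape"])
    return SyntheticTruth(
        rho_apparent_field=np.array(payload["rho_apparent_field"]).reshape(shape),
        bone_mask=np.array(payload["bone_mask"], dtype=bool).reshape(shape),
        hu_slope=payload["hu_slope"],
        hu_intercept=payload["hu_intercept"],
        noise_sd=payload["noise_sd"],
        seed=payload.get("seed"),
    )
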