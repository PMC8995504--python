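"""Voxel hexahedral meshing of the bone mask, with PMMA load pads.

Each retained bone voxel (after optional resampling to the element size)
becomes one 8-node hexahedral element on a regular lattice; neighbouring
elements share nodes, so the mesh is conforming by construction.  PMMA pads
are added as extra element layers above the femoral head and below the
distal cut; the tie constraint between pad and bone is realised by node
sharing on the common lattice, which for conforming voxel grids is
kinematically identical to a tied interface.

The loading axis is the volume z axis; the femoral height used to convert
the prescribed deformation fraction into a displacement is the bone-only
extent along z (pads excluded).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .calibration import DensityVolume

logger = logging.getLogger(__name__)

#: PMMA pad elastic constants.
PAD_E = 2500.0
PAD_POISSON = 0.3

#: Hex8 corner offsets in VTK ordering.
_CORNERS = np.array([
    [0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0],
    [0, 0, 1], [1, 0, 1], [1, 1, 1], [0, 1, 1],
], dtype=np.int64)


@dataclass
class HexModel:
    """Voxel hexahedral mesh with node sets and per-element density.

    ``element_rho_ash`` is NaN for pad elements; ``bone_element_index`` gives
    the positions of bone elements in element order, which is also the order
    expected by a :class:`~femstrength.material_model.MaterialTable` built
    for this mesh.
    """

    nodes: np.ndarray                    # (n_nodes, 3) mm
    elements: np.ndarray                 # (n_elements, 8) node ids
    element_ijk: np.ndarray              # (n_elements, 3) lattice indices
    element_rho_ash: np.ndarray          # (n_elements,) g/cm^3, NaN for pads
    is_pad: np.ndarray                   # (n_elements,) bool
    element_size: float                  # mm
    top_surface_nodes: np.ndarray        # driven node set
    bottom_surface_nodes: np.ndarray     # fully fixed node set
    femoral_height: float                # mm, bone-only extent along z
    n_dropped_voxels: int = 0

    def __post_init__(self) -> None:
        if self.femoral_height <= 0:
            raise ValueError("femoral height must be positive")
        if self.top_surface_nodes.size == 0 or self.bottom_surface_nodes.size == 0:
            raise ValueError("empty boundary node set")

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_elements(self) -> int:
        return self.elements.shape[0]

    @property
    def bone_element_index(self) -> np.ndarray:
        return np.flatnonzero(~self.is_pad)

    @property
    def bone_rho_ash(self) -> np.ndarray:
        """Ash density of bone elements, in bone-element order."""
        return self.element_rho_ash[~self.is_pad]

    def total_volume(self) -> float:
        return self.n_elements * self.element_size ** 3


def _resample(mask: np.ndarray, rho_ash: np.ndarray,
              spacing: tuple[float, float, float],
              element_size: float) -> tuple[np.ndarray, np.ndarray]:
    """Box-average the density field onto an element-size lattice.

    The element size must be an integer multiple of each voxel spacing; a
    coarse voxel becomes bone when at least half of its fine voxels are bone,
    and its density is the mean over the contributing bone voxels.
    """
    factors = []
    for s in spacing:
        f = element_size / s
        if abs(f - round(f)) > 1e-8 or round(f) < 1:
            raise ValueError(
                f"element size {element_size} mm is not an integer multiple "
                f"of voxel spacing {s} mm")
        factors.append(int(round(f)))
    if factors == [1, 1, 1]:
        return mask.copy(), np.where(mask, rho_ash, 0.0)

    fx, fy, fz = factors
    nx, ny, nz = mask.shape
    px, py, pz = (-nx) % fx, (-ny) % fy, (-nz) % fz
    mask_p = np.pad(mask, ((0, px), (0, py), (0, pz)))
    rho_p = np.pad(np.where(mask, rho_ash, 0.0), ((0, px), (0, py), (0, pz)))
    shape6 = (mask_p.shape[0] // fx, fx, mask_p.shape[1] // fy, fy,
              mask_p.shape[2] // fz, fz)
    mblk = mask_p.reshape(shape6)
    rblk = rho_p.reshape(shape6)
    n_bone = mblk.sum(axis=(1, 3, 5))
    coarse_mask = n_bone * 2 >= fx * fy * fz
    with np.errstate(invalid="ignore"):
        coarse_rho = np.where(coarse_mask,
                              rblk.sum(axis=(1, 3, 5)) / np.maximum(n_bone, 1), 0.0)
    return coarse_mask, coarse_rho


def _largest_component(mask: np.ndarray) -> tuple[np.ndarray, int]:
    """Keep the largest 6-connected component; return it and the dropped count."""
    structure = ndimage.generate_binary_structure(3, 1)
    labels, n = ndimage.label(mask, structure=structure)
    if n == 0:
        raise ValueError("bone mask is empty")
    counts = np.bincount(labels.ravel())[1:]
    keep = int(np.argmax(counts)) + 1
    dropped = int(mask.sum() - counts[keep - 1])
    if dropped:
        logger.info("dropped %d voxels in %d disconnected islands", dropped, n - 1)
    return labels == keep, dropped


def _mesh_from_occupancy(occ: np.ndarray, rho: np.ndarray, is_pad: np.ndarray,
                         h: float, dropped: int) -> HexModel:
    ijk = np.argwhere(occ)
    if ijk.size == 0:
        raise ValueError("no elements to mesh")
    # Corner lattice keys -> node ids.
    corners = ijk[:, None, :] + _CORNERS[None, :, :]          # (M, 8, 3)
    nx, ny, nz = occ.shape
    key = (corners[..., 0] * (ny + 1) + corners[..., 1]) * (nz + 1) + corners[..., 2]
    uniq, inv = np.unique(key, return_inverse=True)
    elements = inv.reshape(-1, 8).astype(np.int64)
    kx = uniq // ((ny + 1) * (nz + 1))
    rem = uniq % ((ny + 1) * (nz + 1))
    ky, kz = rem // (nz + 1), rem % (nz + 1)
    nodes = np.stack([kx, ky, kz], axis=1).astype(float) * h

    pad_flags = is_pad[tuple(ijk.T)]
    rho_elem = np.where(pad_flags, np.nan, rho[tuple(ijk.T)])

    bone_k = ijk[~pad_flags, 2]
    femoral_height = float((bone_k.max() - bone_k.min() + 1) * h)

    kz_all = nodes[:, 2] / h
    top = np.flatnonzero(np.isclose(kz_all, kz_all.max()))
    bottom = np.flatnonzero(np.isclose(kz_all, kz_all.min()))
    # Restrict to nodes that belong to elements touching those planes.
    return HexModel(
        nodes=nodes, elements=elements, element_ijk=ijk,
        element_rho_ash=rho_elem, is_pad=pad_flags, element_size=h,
        top_surface_nodes=top, bottom_surface_nodes=bottom,
        femoral_height=femoral_height, n_dropped_voxels=dropped,
    )


def build_mesh(dv: DensityVolume, bone_mask: np.ndarray,
               element_size: float | None = None) -> HexModel:
    """Mesh the bone mask with cubic hexahedra of the given edge length.

    Requires isotropic voxel spacing (or an element size that is an integer
    multiple of each spacing component).  Voxel islands disconnected from the
    largest 6-connected component are dropped and logged.
    """
    mask = np.asarray(bone_mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty bone mask")
    if dv.rho_ash is None:
        raise ValueError("density volume has no ash density; run apparent_to_ash first")
    if element_size is None:
        if len(set(dv.spacing)) != 1:
            raise ValueError("anisotropic spacing needs an explicit element size")
        element_size = dv.spacing[0]
    coarse_mask, coarse_rho = _resample(mask, dv.rho_ash, dv.spacing, element_size)
    if not coarse_mask.any():
        raise ValueError("bone mask empty after resampling")
    coarse_mask, dropped = _largest_component(coarse_mask)
    is_pad = np.zeros_like(coarse_mask)
    return _mesh_from_occupancy(coarse_mask, coarse_rho, is_pad,
                                float(element_size), dropped)


def attach_pads(model: HexModel, pad_layers: int = 2,
                embed_depth_mm: float = 6.0) -> HexModel:
    """Add PMMA pad layers above the head and below the distal cut.

    The pads are flat slabs of ``pad_layers`` elements covering the projected
    bone footprint, placed directly above the superior-most and below the
    inferior-most bone surfaces.  Because the superior head surface is
    curved, pad material additionally fills the space between the slab and
    the bone for columns whose top lies within ``embed_depth_mm`` of the
    apex — emulating the moulded seating of a PMMA cap on the femoral head.
    At the distal end the cut is flat, so the fill is a no-op there.

    Tie constraints are realised by node sharing on the common lattice.
    """
    if pad_layers < 1:
        raise ValueError("pad thickness must be at least one element layer")
    if model.is_pad.any():
        raise ValueError("model already has pads")
    h = model.element_size
    ijk = model.element_ijk
    kmin, kmax = int(ijk[:, 2].min()), int(ijk[:, 2].max())
    embed = int(round(embed_depth_mm / h))

    nx = int(ijk[:, 0].max()) + 1
    ny = int(ijk[:, 1].max()) + 1
    # Re-grid with room for the pads in z.
    shift = pad_layers
    occ = np.zeros((nx, ny, kmax - kmin + 1 + 2 * pad_layers), dtype=bool)
    rho = np.zeros_like(occ, dtype=float)
    bi = ijk[:, 0]
    bj = ijk[:, 1]
    bk = ijk[:, 2] - kmin + shift
    occ[bi, bj, bk] = True
    rho[bi, bj, bk] = model.element_rho_ash
    is_pad = np.zeros_like(occ)

    footprint = occ.any(axis=2)
    cols = np.argwhere(footprint)
    ktop = np.where(footprint, occ.shape[2] - 1 - occ[:, :, ::-1].argmax(axis=2), -1)
    kbot = np.where(footprint, occ.argmax(axis=2), -1)
    k_apex = int(ktop.max())
    k_base = int(kbot[footprint].min())

    for i, j in cols:
        # Top slab above the apex plane; moulded fill down to nearby columns.
        top_fill_from = k_apex + 1
        if ktop[i, j] >= k_apex - embed:
            top_fill_from = ktop[i, j] + 1
        for k in range(top_fill_from, k_apex + 1 + pad_layers):
            occ[i, j, k] = True
            is_pad[i, j, k] = True
        # Bottom slab below the base plane (flat distal cut: fill is trivial).
        bot_fill_to = k_base - 1
        if kbot[i, j] <= k_base + embed:
            bot_fill_to = kbot[i, j] - 1
        for k in range(k_base - pad_layers, bot_fill_to + 1):
            occ[i, j, k] = True
            is_pad[i, j, k] = True

    return _mesh_from_occupancy(occ, rho, is_pad, h, model.n_dropped_voxels)


def write_vtk(model: HexModel, path: str | Path,
              cell_data: dict[str, np.ndarray] | None = None) -> None:
    """Write the mesh as a legacy-ASCII VTK unstructured grid of hexahedra."""
    path = Path(path)
    lines = ["# vtk DataFile Version 3.0", "femstrength hexahedral mesh",
             "ASCII", "DATASET UNSTRUCTURED_GRID",
             f"POINTS {model.n_nodes} double"]
    lines += [" ".join(f"{c:.6g}" for c in p) for p in model.nodes]
    m = model.n_elements
    lines.append(f"CELLS {m} {m * 9}")
    lines += ["8 " + " ".join(str(n) for n in e) for e in model.elements]
    lines.append(f"CELL_TYPES {m}")
    lines += ["12"] * m
    data = {"is_pad": model.is_pad.astype(float),
            "rho_ash": np.nan_to_num(model.element_rho_ash)}
    if cell_data:
        data.update(cell_data)
    lines.append(f"CELL_DATA {m}")
    for name, values in data.items():
        lines.append(f"SCALARS {name} double 1")
        lines.append("LOOKUP_TABLE default")
        lines += [f"{v:.6g}" for v in np.asarray(values, dtype=float)]
    path.write_text("\n".join(lines) + "\n")
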