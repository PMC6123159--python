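"""Voxel phantom construction: analytic slab stacks and HU-array conversion.

HU conversion follows the stoichiometric (Schneider-style) approach: the HU
axis is segmented into bins, each carrying a tissue material and a base
density, and a per-bin density correction factor is solved so that the
resulting relative stopping power (RSP) reproduces a target HU-vs-RSP
calibration curve at a reference energy (default 160 MeV).

Voxel convention: 0-based indices, half-open voxels; world position of a
voxel center is origin + (index + 0.5) * voxel_size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dfield

import numpy as np

from . import materials as M
from .transport import Geometry, Region, VoxelGrid

__all__ = [
    "HuBin",
    "HuConversionTable",
    "default_hu_table",
    "default_hu_rsp_curve",
    "solve_density_correction",
    "hu_to_voxels",
    "override_hu",
    "make_slab_phantom",
]

# ICRU-flavoured tissue compositions (mass fractions)
LUNG_TISSUE = M.Material.from_composition(
    "lung_tissue",
    {"H": 0.103, "C": 0.105, "N": 0.031, "O": 0.749, "P": 0.002, "S": 0.003,
     "Cl": 0.003, "K": 0.002, "Na": 0.002},
    0.26,
)
SOFT_TISSUE = M.Material.from_composition(
    "soft_tissue",
    {"H": 0.102, "C": 0.143, "N": 0.034, "O": 0.708, "Na": 0.002, "P": 0.003,
     "S": 0.003, "Cl": 0.002, "K": 0.003},
    1.03,
)
ADIPOSE = M.Material.from_composition(
    "adipose",
    {"H": 0.114, "C": 0.598, "N": 0.007, "O": 0.278, "Na": 0.001, "S": 0.001,
     "Cl": 0.001},
    0.95,
)
BONE = M.Material.from_composition(
    "bone",
    {"H": 0.034, "C": 0.155, "N": 0.042, "O": 0.435, "Na": 0.001, "Mg": 0.002,
     "P": 0.103, "S": 0.003, "Ca": 0.225},
    1.92,
)


@dataclass
class HuBin:
    hu_lo: float
    hu_hi: float
    material: M.Material
    base_density: float
    correction: float = 1.0

    @property
    def center(self) -> float:
        return 0.5 * (self.hu_lo + self.hu_hi)


@dataclass
class HuConversionTable:
    """Piecewise HU -> (material, density) lookup covering [-1000, 3000]."""

    bins: list[HuBin]

    def __post_init__(self) -> None:
        self.bins = sorted(self.bins, key=lambda b: b.hu_lo)
        if self.bins[0].hu_lo > -1000 or self.bins[-1].hu_hi < 3000:
            raise ValueError("table must cover [-1000, 3000] HU")
        for b in self.bins:
            if b.base_density < 0:
                raise ValueError("densities must be non-negative")

    @property
    def materials(self) -> list[M.Material]:
        mats: list[M.Material] = []
        for b in self.bins:
            if b.material not in mats:
                mats.append(b.material)
        return mats

    def bin_index(self, hu) -> np.ndarray:
        edges = np.array([b.hu_lo for b in self.bins[1:]])
        return np.digitize(np.asarray(hu, dtype=float), edges)

    def rsp(self, hu, energy: float = 160.0) -> np.ndarray:
        """Relative stopping power of the converted voxels at ``energy``."""
        hu = np.asarray(hu, dtype=float)
        idx = self.bin_index(hu)
        dens = _density_from_hu(hu)
        out = np.empty(idx.shape)
        s_w = M.mass_stopping_power(M.WATER, energy)
        for i, b in enumerate(self.bins):
            sel = idx == i
            if np.any(sel):
                rho = dens[sel] * b.correction
                out[sel] = M.mass_stopping_power(b.material, energy) * rho / s_w
        return out


def _density_from_hu(hu):
    """Continuous CT density calibration (g/cm^3).

    Bins assign the tissue composition; the density follows this continuous
    HU calibration scaled by the per-bin correction factor.
    """
    h = np.asarray(hu, dtype=float)
    below = 0.00121 + (1.0 - 0.00121) * (h + 1000.0) / 1000.0
    soft = 1.0 + h * 0.001
    bone = 1.1 + (h - 100.0) * 0.0005
    out = np.where(h < 0, below, np.where(h < 100.0, soft, bone))
    out = np.where(h < -950.0, 0.00121, out)  # air plateau
    return np.maximum(out, 0.00121)


def default_hu_table() -> HuConversionTable:
    """Schneider-style segmentation with air, lung, adipose, soft tissue, bone."""
    bins: list[HuBin] = [HuBin(-1000.0, -950.0, M.AIR, 0.00121)]
    for lo in np.arange(-950.0, -120.0, 83.0):
        hi = min(lo + 83.0, -120.0)
        bins.append(HuBin(lo, hi, LUNG_TISSUE,
                          float(_density_from_hu(0.5 * (lo + hi)))))
    for lo in np.arange(-120.0, -20.0, 25.0):
        hi = lo + 25.0
        bins.append(HuBin(lo, hi, ADIPOSE,
                          float(_density_from_hu(0.5 * (lo + hi)))))
    for lo in np.arange(-20.0, 100.0, 20.0):
        hi = lo + 20.0
        bins.append(HuBin(lo, hi, SOFT_TISSUE,
                          float(_density_from_hu(0.5 * (lo + hi)))))
    for lo in np.arange(100.0, 3000.0, 181.25):
        hi = min(lo + 181.25, 3000.0)
        bins.append(HuBin(lo, hi, BONE,
                          float(_density_from_hu(0.5 * (lo + hi)))))
    return HuConversionTable(bins)


def default_hu_rsp_curve(hu) -> np.ndarray:
    """Target HU-vs-RSP calibration curve (planning-system style).

    Air plateau below -950 HU, then piecewise linear through (0, 1.0), with a
    flatter slope above water (bone RSP grows more slowly than HU).
    """
    h = np.asarray(hu, dtype=float)
    below = 0.001 + (1.0 - 0.001) * (h + 1000.0) / 1000.0
    above = 1.0 + h * 0.000485
    out = np.where(h <= 0, below, above)
    return np.where(h < -950.0, 0.00121, out)


def solve_density_correction(
    table: HuConversionTable,
    target_rsp=default_hu_rsp_curve,
    reference_energy: float = 160.0,
) -> HuConversionTable:
    """Set per-bin density correction factors to match the target RSP curve.

    Because RSP is linear in density, factor = target RSP / model RSP at each
    bin center.  Returns the table (modified in place) for chaining.
    """
    s_w = M.mass_stopping_power(M.WATER, reference_energy)
    for b in table.bins:
        model = (
            M.mass_stopping_power(b.material, reference_energy)
            * float(_density_from_hu(b.center)) / s_w
        )
        tgt = float(np.asarray(target_rsp(b.center)))
        b.correction = tgt / model if model > 0 else 1.0
    return table


def hu_to_voxels(
    hu_array: np.ndarray,
    table: HuConversionTable,
    voxel_size=(1.0, 1.0, 1.0),
    origin=(0.0, 0.0, 0.0),
) -> VoxelGrid:
    """Convert a 3D HU array to a (material id, density) voxel grid.

    HU values outside the table span are clamped with a warning.
    """
    hu = np.asarray(hu_array, dtype=float)
    lo, hi = table.bins[0].hu_lo, table.bins[-1].hu_hi
    if hu.min() < lo or hu.max() > hi:
        warnings.warn("HU values outside table span were clamped", stacklevel=2)
        hu = np.clip(hu, lo, hi)
    idx = table.bin_index(hu)
    mats = table.materials
    mat_of_bin = np.array([mats.index(b.material) for b in table.bins])
    corr_of_bin = np.array([b.correction for b in table.bins])
    return VoxelGrid(
        material_ids=mat_of_bin[idx].astype(np.int64),
        density=_density_from_hu(hu) * corr_of_bin[idx],
        materials=mats,
        origin=tuple(float(v) for v in origin),
        voxel_size=tuple(float(v) for v in voxel_size),
    )


def override_hu(hu_array: np.ndarray, mask: np.ndarray,
                value: float) -> np.ndarray:
    """Return a copy with ``mask`` voxels set to ``value`` (HU).

    Used before conversion to remove couches, add boluses, or flatten
    artifacts, mirroring clinical structure-override practice.
    """
    out = np.array(hu_array, dtype=float, copy=True)
    out[np.asarray(mask, dtype=bool)] = value
    return out


def make_slab_phantom(
    slabs: list[tuple[M.Material, float]],
    lateral_mm: float = 300.0,
    voxel_mm: float = 1.0,
    surface_z: float = 0.0,
) -> Geometry:
    """Voxelized slab stack: first slab at the (upstream) surface.

    ``slabs`` is a list of (material, thickness mm) encountered in beam order.
    """
    total = sum(t for _, t in slabs)
    nxy = max(int(round(lateral_mm / voxel_mm)), 1)
    nz = max(int(round(total / voxel_mm)), 1)
    mats: list[M.Material] = []
    for m, _ in slabs:
        if m not in mats:
            mats.append(m)
    ids = np.zeros((nxy, nxy, nz), dtype=np.int64)
    dens = np.ones((nxy, nxy, nz))
    # z index 0 is the bottom (most downstream); fill from the top
    depth = 0.0
    for m, t in slabs:
        i_hi = nz - int(round(depth / voxel_mm))
        i_lo = nz - int(round((depth + t) / voxel_mm))
        ids[:, :, i_lo:i_hi] = mats.index(m)
        dens[:, :, i_lo:i_hi] = m.density
        depth += t
    grid = VoxelGrid(
        material_ids=ids,
        density=dens,
        materials=mats,
        origin=(-lateral_mm / 2.0, -lateral_mm / 2.0, surface_z - total),
        voxel_size=(voxel_mm, voxel_mm, voxel_mm),
    )
    region = Region(z_top=surface_z, z_bottom=surface_z - total, voxels=grid)
    return Geometry([region])
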