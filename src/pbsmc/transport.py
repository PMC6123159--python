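"""Condensed-history Monte Carlo proton transport and dose scoring.

Particles are carried as structure-of-arrays batches and stepped in lockstep
through an ordered stack of material regions (uniform slabs or voxel grids)
along -z; the space between regions is vacuum, so inter-region transport is an
analytic drift.  Per step the engine applies mean Bethe energy loss plus
Gaussian (Bohr) straggling, a Highland multiple-Coulomb-scattering deflection,
and nonelastic/removal sampling from the embedded water cross-section table
scaled by water-equivalent path.  A removal event terminates the primary and
emits one weighted effective secondary proton; energy not given to the
secondary is split between local deposition and an escaping-neutrals sink.

Step length is min(max_step, 2% of the residual CSDA range) with a 0.1 mm
floor; protons dropping below the 2 MeV cutoff deposit their residual energy
locally.  Transport is strictly forward-peaked: particles whose z-direction
turns non-negative are booked as escaped.

All simulations are reproducible given a seed: one numpy Generator stream
per transport call drives the vectorized path directly and seeds the
compiled kernel's internal stream per region pass.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import materials as mat
from .constants import CUTOFF_MEV, MEV_TO_J

__all__ = [
    "ParticleBatch",
    "VoxelGrid",
    "Region",
    "Geometry",
    "TransportConfig",
    "TransportResult",
    "DoseGrid",
    "IDDScorer",
    "PlaneScorer",
    "transport",
    "score_idd",
    "simulate_spot",
    "simulate_field",
    "water_box",
]

PRIMARY = 0
SECONDARY = 1

_LOG_E_GRID = np.log(np.geomspace(0.5, 300.0, 1024))
_E_GRID = np.exp(_LOG_E_GRID)


def _deposit_add(flat: np.ndarray, idx: np.ndarray, val: np.ndarray) -> None:
    np.add.at(flat, idx, val)


try:  # optional numba acceleration for scatter-add scoring
    from numba import njit

    @njit(cache=True)
    def _deposit_numba(flat, idx, val):  # pragma: no cover - jitted
        for i in range(idx.size):
            flat[idx[i]] += val[i]

    _deposit = _deposit_numba
except Exception:  # pragma: no cover
    _deposit = _deposit_add


# ---------------------------------------------------------------------------
# particle batch
# ---------------------------------------------------------------------------

@dataclass
class ParticleBatch:
    """Structure-of-arrays proton batch (positions mm, unit directions, MeV)."""

    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    dx: np.ndarray
    dy: np.ndarray
    dz: np.ndarray
    energy: np.ndarray
    weight: np.ndarray
    species: np.ndarray

    def __post_init__(self) -> None:
        n = self.x.size
        for name in ("y", "z", "dx", "dy", "dz", "energy", "weight", "species"):
            if getattr(self, name).size != n:
                raise ValueError("batch arrays must share a common length")

    @property
    def n(self) -> int:
        return self.x.size

    def validate(self) -> None:
        norm = np.sqrt(self.dx**2 + self.dy**2 + self.dz**2)
        if not np.allclose(norm, 1.0, atol=1e-9):
            raise ValueError("directions must be unit vectors")
        if np.any(self.weight <= 0):
            raise ValueError("weights must be positive")

    def select(self, mask: np.ndarray) -> "ParticleBatch":
        return ParticleBatch(
            *(getattr(self, f)[mask]
              for f in ("x", "y", "z", "dx", "dy", "dz", "energy", "weight",
                        "species"))
        )

    @staticmethod
    def concatenate(batches: list["ParticleBatch"]) -> "ParticleBatch":
        fields = ("x", "y", "z", "dx", "dy", "dz", "energy", "weight", "species")
        return ParticleBatch(
            *(np.concatenate([getattr(b, f) for b in batches]) for f in fields)
        )

    @classmethod
    def pencil(cls, n: int, energy: float, z: float = 460.0,
               species: int = PRIMARY) -> "ParticleBatch":
        """Monoenergetic zero-emittance pencil along -z (testing aid)."""
        zeros = np.zeros(n)
        return cls(
            x=zeros.copy(), y=zeros.copy(), z=np.full(n, float(z)),
            dx=zeros.copy(), dy=zeros.copy(), dz=np.full(n, -1.0),
            energy=np.full(n, float(energy)), weight=np.ones(n),
            species=np.full(n, species, dtype=np.uint8),
        )


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

@dataclass
class VoxelGrid:
    """Voxelized material-id + density arrays.

    0-based indices, half-open voxels; world position of voxel centers is
    origin + (index + 0.5) * voxel_size.  ``origin`` is the minimum corner.
    """

    material_ids: np.ndarray  # (nx, ny, nz) integer
    density: np.ndarray  # (nx, ny, nz) g/cm^3
    materials: list[mat.Material]
    origin: tuple[float, float, float]
    voxel_size: tuple[float, float, float]

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel size must be positive")
        if self.material_ids.shape != self.density.shape:
            raise ValueError("material id and density shapes differ")

    def lookup(self, x, y, z) -> tuple[np.ndarray, np.ndarray]:
        """Material ids and densities at world positions (indices clamped)."""
        ids = []
        for arr, o, v, npts in (
            (x, self.origin[0], self.voxel_size[0], self.material_ids.shape[0]),
            (y, self.origin[1], self.voxel_size[1], self.material_ids.shape[1]),
            (z, self.origin[2], self.voxel_size[2], self.material_ids.shape[2]),
        ):
            i = np.floor((np.asarray(arr) - o) / v).astype(np.int64)
            ids.append(np.clip(i, 0, npts - 1))
        return self.material_ids[ids[0], ids[1], ids[2]], self.density[ids[0], ids[1], ids[2]]


@dataclass
class Region:
    """A z-slab of the beamline: uniform material or voxel grid."""

    z_top: float
    z_bottom: float
    material: mat.Material | None = None
    voxels: VoxelGrid | None = None

    def __post_init__(self) -> None:
        if self.z_top <= self.z_bottom:
            raise ValueError("z_top must exceed z_bottom")
        if (self.material is None) == (self.voxels is None):
            raise ValueError("specify exactly one of material or voxels")

    @property
    def materials(self) -> list[mat.Material]:
        return [self.material] if self.material is not None else self.voxels.materials


@dataclass
class Geometry:
    """Ordered, non-overlapping material regions along -z; vacuum elsewhere."""

    regions: list[Region]
    lateral_halfsize: float = 400.0

    def __post_init__(self) -> None:
        self.regions = sorted(self.regions, key=lambda r: -r.z_top)
        for a, b in zip(self.regions, self.regions[1:]):
            if b.z_top > a.z_bottom + 1e-9:
                raise ValueError("regions overlap")

    @classmethod
    def beamline(
        cls,
        phantom: Region | "Geometry",
        machine=None,
        use_range_shifter: bool = False,
        lateral_halfsize: float = 400.0,
    ) -> "Geometry":
        """Assemble the simulated beamline for a plan field.

        With ``use_range_shifter`` the machine's range-shifter slab is placed
        with its upstream face at the machine source plane.
        """
        regions = list(phantom.regions) if isinstance(phantom, Geometry) else [phantom]
        if use_range_shifter:
            if machine is None or machine.range_shifter is None:
                raise ValueError("machine with a range-shifter spec required")
            rs = machine.range_shifter
            z_top = machine.geometry.source_plane_z
            regions.insert(
                0,
                Region(
                    z_top=z_top,
                    z_bottom=z_top - rs.thickness_mm,
                    material=mat.BUILTIN_MATERIALS[rs.material],
                ),
            )
        return cls(regions, lateral_halfsize=lateral_halfsize)


def water_box(surface_z: float = 0.0, depth_mm: float = 400.0,
              material: mat.Material = mat.WATER) -> Region:
    """Uniform water (or other material) phantom slab with its surface at z."""
    return Region(z_top=surface_z, z_bottom=surface_z - depth_mm, material=material)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class TransportConfig:
    max_step_mm: float = 1.0
    range_fraction: float = 0.02
    min_step_mm: float = 0.1
    cutoff_mev: float = CUTOFF_MEV
    nuclear: mat.NuclearCrossSectionTable = field(
        default_factory=lambda: mat.WATER_REMOVAL_TABLE
    )
    nuclear_enabled: bool = True
    secondaries_enabled: bool = True
    max_generations: int = 3
    #: use the compiled stepping kernel when available (None = auto)
    use_numba: bool | None = None


# ---------------------------------------------------------------------------
# scorers
# ---------------------------------------------------------------------------

class DoseGrid:
    """3D energy/dose scorer on a regular grid.

    Grid indices are 0-based with half-open voxels; world position of voxel
    centers is origin + (index + 0.5) * spacing.  ``energy`` holds deposited
    energy in MeV per voxel; :meth:`dose` converts to Gy using the voxel mass.
    Per-voxel statistical uncertainty is estimated from the sum of squared
    deposits when ``track_uncertainty`` is enabled.
    """

    def __init__(
        self,
        origin: tuple[float, float, float],
        shape: tuple[int, int, int],
        spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
        density: float | np.ndarray = 1.0,
        track_uncertainty: bool = False,
    ) -> None:
        self.origin = tuple(float(v) for v in origin)
        self.shape = tuple(int(v) for v in shape)
        self.spacing = tuple(float(v) for v in spacing)
        self.energy = np.zeros(self.shape)
        self.sumsq = np.zeros(self.shape) if track_uncertainty else None
        self.density = density
        self.n_source_particles = 0

    @classmethod
    def centered(cls, lateral_mm: float, z_top: float, z_depth: float,
                 spacing: float = 1.0, **kw) -> "DoseGrid":
        nx = int(round(lateral_mm / spacing))
        nz = int(round(z_depth / spacing))
        return cls(
            origin=(-lateral_mm / 2.0, -lateral_mm / 2.0, z_top - z_depth),
            shape=(nx, nx, nz),
            spacing=(spacing, spacing, spacing),
            **kw,
        )

    @property
    def voxel_volume_cm3(self) -> float:
        return self.spacing[0] * self.spacing[1] * self.spacing[2] * 1e-3

    def centers(self, axis: int) -> np.ndarray:
        return self.origin[axis] + (np.arange(self.shape[axis]) + 0.5) * self.spacing[axis]

    def deposit(self, px, py, pz, edep) -> None:
        ix = np.floor((px - self.origin[0]) / self.spacing[0]).astype(np.int64)
        iy = np.floor((py - self.origin[1]) / self.spacing[1]).astype(np.int64)
        iz = np.floor((pz - self.origin[2]) / self.spacing[2]).astype(np.int64)
        ok = (
            (ix >= 0) & (ix < self.shape[0])
            & (iy >= 0) & (iy < self.shape[1])
            & (iz >= 0) & (iz < self.shape[2])
            & (edep > 0)
        )
        if not np.any(ok):
            return
        flat = (ix[ok] * self.shape[1] + iy[ok]) * self.shape[2] + iz[ok]
        _deposit(self.energy.reshape(-1), flat, edep[ok])
        if self.sumsq is not None:
            _deposit(self.sumsq.reshape(-1), flat, edep[ok] ** 2)

    def segment(self, p0, p1, energy, weight) -> None:  # dose grids score deposits
        pass

    def dose(self) -> np.ndarray:
        """Absolute dose in Gy for the accumulated energy."""
        mass_kg = self.voxel_volume_cm3 * np.asarray(self.density) * 1e-3
        return self.energy * MEV_TO_J / mass_kg

    def dose_per_primary(self) -> np.ndarray:
        if self.n_source_particles == 0:
            raise ValueError("no source particles recorded")
        return self.dose() / self.n_source_particles

    def relative_uncertainty(self) -> np.ndarray:
        if self.sumsq is None:
            raise ValueError("uncertainty tracking was not enabled")
        with np.errstate(divide="ignore", invalid="ignore"):
            rel = np.sqrt(self.sumsq) / self.energy
        return np.where(self.energy > 0, rel, 0.0)

    def save_h5(self, path) -> None:
        """Write dose (Gy), deposited energy and geometry attrs to HDF5."""
        import h5py

        with h5py.File(path, "w") as fh:
            fh.create_dataset("dose", data=self.dose(), compression="gzip")
            fh.create_dataset("energy", data=self.energy, compression="gzip")
            if self.sumsq is not None:
                fh.create_dataset(
                    "relative_uncertainty", data=self.relative_uncertainty(),
                    compression="gzip",
                )
            fh.attrs["origin"] = self.origin
            fh.attrs["spacing"] = self.spacing
            fh.attrs["density"] = np.asarray(self.density)
            fh.attrs["n_source_particles"] = self.n_source_particles

    @classmethod
    def load_h5(cls, path) -> "DoseGrid":
        import h5py

        with h5py.File(path, "r") as fh:
            energy = fh["energy"][...]
            grid = cls(
                origin=tuple(fh.attrs["origin"]),
                shape=energy.shape,
                spacing=tuple(fh.attrs["spacing"]),
                density=np.asarray(fh.attrs["density"])[()],
            )
            grid.energy = energy
            grid.n_source_particles = int(fh.attrs["n_source_particles"])
        return grid


class IDDScorer:
    """Integral depth-dose scorer: energy per depth bin inside a cylinder.

    Mirrors a large-radius Bragg-peak chamber: default radius 40.8 mm and
    0.5 mm depth resolution, depth measured from ``z_surface`` downward.
    """

    def __init__(self, z_surface: float, depth_mm: float = 400.0,
                 bin_mm: float = 0.5, radius_mm: float = 40.8) -> None:
        self.z_surface = float(z_surface)
        self.bin_mm = float(bin_mm)
        self.radius_mm = float(radius_mm)
        self.nbins = int(np.ceil(depth_mm / bin_mm))
        self.energy = np.zeros(self.nbins)

    def deposit(self, px, py, pz, edep) -> None:
        depth = self.z_surface - pz
        ib = np.floor(depth / self.bin_mm).astype(np.int64)
        ok = (
            (ib >= 0) & (ib < self.nbins)
            & (px**2 + py**2 <= self.radius_mm**2)
            & (edep > 0)
        )
        if np.any(ok):
            _deposit(self.energy, ib[ok], edep[ok])

    def segment(self, p0, p1, energy, weight) -> None:
        pass

    def curve(self) -> tuple[np.ndarray, np.ndarray]:
        """(depth centers mm, dose normalized to unit integral)."""
        depths = (np.arange(self.nbins) + 0.5) * self.bin_mm
        total = self.energy.sum()
        if total <= 0:
            return depths, self.energy.copy()
        return depths, self.energy / (total * self.bin_mm)


class PlaneScorer:
    """Planar crossing scorer: weight and energy-weighted 2D maps per z-plane.

    Used for in-air/in-water spot profiles and halo integrals; bins are square
    with the given resolution over a centered window.
    """

    def __init__(self, planes_z, halfsize_mm: float = 200.0,
                 bin_mm: float = 0.5) -> None:
        self.planes_z = [float(z) for z in planes_z]
        self.bin_mm = float(bin_mm)
        self.halfsize = float(halfsize_mm)
        self.nbins = int(round(2 * halfsize_mm / bin_mm))
        self.fluence = np.zeros((len(self.planes_z), self.nbins, self.nbins))
        self.energy_fluence = np.zeros_like(self.fluence)

    def deposit(self, px, py, pz, edep) -> None:
        pass

    def segment(self, p0, p1, energy, weight) -> None:
        x0, y0, z0 = p0
        x1, y1, z1 = p1
        for k, zp in enumerate(self.planes_z):
            crossing = (z0 >= zp) & (z1 < zp)
            if not np.any(crossing):
                continue
            t = (z0[crossing] - zp) / (z0[crossing] - z1[crossing])
            xc = x0[crossing] + t * (x1[crossing] - x0[crossing])
            yc = y0[crossing] + t * (y1[crossing] - y0[crossing])
            ix = np.floor((xc + self.halfsize) / self.bin_mm).astype(np.int64)
            iy = np.floor((yc + self.halfsize) / self.bin_mm).astype(np.int64)
            ok = (ix >= 0) & (ix < self.nbins) & (iy >= 0) & (iy < self.nbins)
            flat = ix[ok] * self.nbins + iy[ok]
            _deposit(self.fluence[k].reshape(-1), flat, weight[crossing][ok])
            _deposit(
                self.energy_fluence[k].reshape(-1),
                flat,
                (weight[crossing] * energy[crossing])[ok],
            )


    def axes(self) -> np.ndarray:
        return -self.halfsize + (np.arange(self.nbins) + 0.5) * self.bin_mm

    def spot_sigma(self, plane_index: int, axis: str = "x",
                   clip_sigma: float = 3.0, n_iter: int = 4) -> float:
        """Gaussian-core sigma of the planar profile via iterated +-3 sigma moments."""
        img = self.fluence[plane_index]
        marg = img.sum(axis=1 if axis == "x" else 0)
        pos = self.axes()
        w = marg.copy()
        lo, hi = pos[0], pos[-1]
        for _ in range(n_iter):
            sel = (pos >= lo) & (pos <= hi)
            ww = w[sel]
            if ww.sum() <= 0:
                return float("nan")
            mu = np.average(pos[sel], weights=ww)
            var = np.average((pos[sel] - mu) ** 2, weights=ww)
            sig = np.sqrt(var)
            lo, hi = mu - clip_sigma * sig, mu + clip_sigma * sig
        return float(sig)


# ---------------------------------------------------------------------------
# material property tables (per geometry, vectorized lookup)
# ---------------------------------------------------------------------------

class _MatTables:
    """Stacked per-material lookup tables on a common log-energy grid."""

    def __init__(self, materials: list[mat.Material]) -> None:
        self.materials = materials
        n = len(materials)
        self.s_mass = np.empty((n, _E_GRID.size))
        self.r_mass = np.empty((n, _E_GRID.size))
        self.rsp_mass = np.empty((n, _E_GRID.size))
        self.x0_mass = np.empty(n)
        self.z_over_a = np.empty(n)
        self.base_density = np.empty(n)
        s_w = mat._mass_stopping_raw(mat.WATER, _E_GRID)
        for i, m in enumerate(materials):
            self.s_mass[i] = mat._mass_stopping_raw(m, _E_GRID)
            tab = mat.range_table(m)
            self.r_mass[i] = tab.csda_range(_E_GRID)
            self.rsp_mass[i] = self.s_mass[i] / s_w
            self.x0_mass[i] = m.radiation_length
            self.z_over_a[i] = m.z_over_a
            self.base_density[i] = m.density

    def lookup(self, table: np.ndarray, mat_ids: np.ndarray,
               energy: np.ndarray) -> np.ndarray:
        loge = np.log(np.clip(energy, _E_GRID[0], _E_GRID[-1]))
        out = np.empty(energy.size)
        if table.shape[0] == 1:
            return np.interp(loge, _LOG_E_GRID, table[0])
        for i in np.unique(mat_ids):
            m = mat_ids == i
            out[m] = np.interp(loge[m], _LOG_E_GRID, table[i])
        return out


# ---------------------------------------------------------------------------
# transport
# ---------------------------------------------------------------------------

@dataclass
class TransportResult:
    exit_batch: ParticleBatch
    accounting: dict

    def energy_balance_error(self) -> float:
        """|initial - (deposited + escaped + exit + weight residual)| / initial."""
        a = self.accounting
        total = (
            a["deposited"]
            + a["escaped_lateral"]
            + a["escaped_neutral"]
            + a["exit_kinetic"]
            + a["secondary_weight_residual"]
        )
        return abs(a["initial_kinetic"] - total) / a["initial_kinetic"]

    def surviving_primary_fraction(self) -> float:
        return self.accounting["exit_primary_weight"] / self.accounting["initial_weight"]


def _transverse_basis(dx, dy, dz):
    """Orthonormal transverse basis for nearly -z directions (vectorized)."""
    # e1 = normalize(d x xhat) ; robust because |dz| ~ 1 in this geometry
    e1x = np.zeros_like(dx)
    e1y = dz.copy()
    e1z = -dy
    norm = np.sqrt(e1y**2 + e1z**2)
    norm = np.where(norm < 1e-12, 1.0, norm)
    e1y /= norm
    e1z /= norm
    # e2 = d x e1
    e2x = dy * e1z - dz * e1y
    e2y = dz * e1x - dx * e1z
    e2z = dx * e1y - dy * e1x
    return (e1x, e1y, e1z), (e2x, e2y, e2z)


def _rotate(dx, dy, dz, tx, ty):
    """Deflect unit directions by transverse angle components (tx, ty) rad."""
    theta = np.sqrt(tx**2 + ty**2)
    small = theta < 1e-12
    theta_safe = np.where(small, 1.0, theta)
    ct, st = np.cos(theta), np.sin(theta)
    (e1x, e1y, e1z), (e2x, e2y, e2z) = _transverse_basis(dx, dy, dz)
    ux = (tx * e1x + ty * e2x) / theta_safe
    uy = (tx * e1y + ty * e2y) / theta_safe
    uz = (tx * e1z + ty * e2z) / theta_safe
    ndx = np.where(small, dx, dx * ct + ux * st)
    ndy = np.where(small, dy, dy * ct + uy * st)
    ndz = np.where(small, dz, dz * ct + uz * st)
    norm = np.sqrt(ndx**2 + ndy**2 + ndz**2)
    return ndx / norm, ndy / norm, ndz / norm


def _drift_to(batch_arrays, z_target, scorers, acct, lateral_halfsize):
    """Vacuum drift of live particles to plane z_target; returns updated arrays."""
    x, y, z, dx, dy, dz, e, w, sp = batch_arrays
    forward = dz < -1e-6
    above = z > z_target + 1e-9
    move = forward & above
    bad = above & ~forward
    if np.any(bad):
        acct["escaped_lateral"] += float(np.sum(e[bad] * w[bad]))
        acct["exit_primary_weight"] -= 0.0
    keep = ~bad
    s = np.zeros_like(z)
    s[move] = (z[move] - z_target) / (-dz[move])
    x1 = x + dx * s
    y1 = y + dy * s
    z1 = np.where(move, z_target, z)
    for sc in scorers:
        sc.segment((x, y, z), (x1, y1, z1), e, w)
    out = (x1[keep], y1[keep], z1[keep], dx[keep], dy[keep], dz[keep],
           e[keep], w[keep], sp[keep])
    esc = (
        (np.abs(x1) > lateral_halfsize) | (np.abs(y1) > lateral_halfsize)
    )[keep]
    if np.any(esc):
        acct["escaped_lateral"] += float(np.sum(out[6][esc] * out[7][esc]))
        out = tuple(a[~esc] for a in out)
    return out


def _step_region(arrays, region, tables, mat_index_map, scorers, rng, cfg, acct,
                 lateral_halfsize, generation):
    """Transport particles through one material region.

    Returns (exit arrays at region bottom, list of secondary arrays created).
    """
    x, y, z, dx, dy, dz, e, w, sp = (a.copy() for a in arrays)
    alive = np.ones(x.size, dtype=bool)
    exited = np.zeros(x.size, dtype=bool)
    secondaries: list[tuple] = []
    z_bot = region.z_bottom
    nuc = cfg.nuclear
    emin_f, emax_f = nuc.energy_fraction_range
    ang100 = np.deg2rad(nuc.angular_sigma_deg_100)

    uniform = region.material is not None
    if uniform:
        mid_const = mat_index_map[region.material.name]

    while np.any(alive):
        idx = np.nonzero(alive)[0]
        xe, ye, ze = x[idx], y[idx], z[idx]
        dxe, dye, dze = dx[idx], dy[idx], dz[idx]
        ee, we = e[idx], w[idx]

        # material at current position
        if uniform:
            mids = np.full(idx.size, mid_const)
            rho = np.full(idx.size, region.material.density)
        else:
            vids, rho = region.voxels.lookup(xe, ye, ze)
            mids = vids
        rho = np.maximum(rho, 1e-6)

        # step control: min(max_step, 2% residual range), floored
        r_res_cm = tables.lookup(tables.r_mass, mids, ee) / rho
        step_mm = np.clip(
            cfg.range_fraction * r_res_cm * 10.0, cfg.min_step_mm, cfg.max_step_mm
        )
        if not uniform:
            step_mm = np.minimum(step_mm, min(region.voxels.voxel_size))
        s_geo = (ze - z_bot) / np.maximum(-dze, 1e-9)
        at_boundary = s_geo <= step_mm
        s_mm = np.where(at_boundary, np.maximum(s_geo, 0.0), step_mm)
        s_cm = s_mm / 10.0

        # energy loss with Bohr straggling, evaluated at mid-step energy
        s1 = tables.lookup(tables.s_mass, mids, ee) * rho
        e_half = np.maximum(ee - 0.5 * s1 * s_cm, 0.6)
        de_mean = tables.lookup(tables.s_mass, mids, e_half) * rho * s_cm
        var = 0.1569 * tables.z_over_a[mids] * rho * s_cm
        de = de_mean + np.sqrt(var) * rng.standard_normal(idx.size)
        de = np.clip(de, 0.0, ee)
        e_new = ee - de

        # mid-step position (deposition point)
        xm = xe + dxe * (s_mm / 2.0)
        ym = ye + dye * (s_mm / 2.0)
        zm = ze + dze * (s_mm / 2.0)

        stopped = e_new < cfg.cutoff_mev
        edep = np.where(stopped, ee, de) * we
        for sc in scorers:
            sc.deposit(xm, ym, zm, edep)
        acct["deposited"] += float(edep.sum())

        # nonelastic / removal sampling on surviving steps
        ev = np.zeros(idx.size, dtype=bool)
        if cfg.nuclear_enabled and generation < cfg.max_generations:
            s_wet_cm = s_cm * tables.lookup(tables.rsp_mass, mids, e_half) * rho
            p_nuc = nuc.sigma(e_half) * s_wet_cm
            ev = (~stopped) & (rng.random(idx.size) < p_nuc)
            if np.any(ev):
                e_avail = e_new[ev]
                wv = we[ev]
                frac = rng.uniform(emin_f, emax_f, ev.sum())
                e_sec = frac * e_avail
                # local/neutral split of the non-secondary energy
                local = nuc.local_deposit_fraction * (e_avail - e_sec) * wv
                for sc in scorers:
                    sc.deposit(xm[ev], ym[ev], zm[ev], local)
                acct["deposited"] += float(local.sum())
                acct["escaped_neutral"] += float(
                    ((1.0 - nuc.local_deposit_fraction) * (e_avail - e_sec) * wv).sum()
                )
                acct["secondary_weight_residual"] += float(
                    (e_sec * wv * (1.0 - nuc.secondary_weight)).sum()
                )
                if cfg.secondaries_enabled:
                    ok = e_sec >= cfg.cutoff_mev
                    if np.any(ok):
                        sig = np.minimum(
                            ang100 * (100.0 / np.maximum(e_avail[ok], 1.0))
                            ** nuc.angular_energy_exponent,
                            np.deg2rad(nuc.angular_sigma_max_deg),
                        )
                        tx = rng.normal(0.0, sig)
                        ty = rng.normal(0.0, sig)
                        sdx, sdy, sdz = _rotate(
                            dxe[ev][ok], dye[ev][ok], dze[ev][ok], tx, ty
                        )
                        secondaries.append(
                            (
                                xm[ev][ok], ym[ev][ok], zm[ev][ok],
                                sdx, sdy, sdz,
                                e_sec[ok], wv[ok] * nuc.secondary_weight,
                                np.full(int(ok.sum()), SECONDARY, dtype=np.uint8),
                            )
                        )
                    if np.any(~ok):
                        # secondary below cutoff: deposit it locally
                        sub = e_sec[~ok] * wv[~ok] * nuc.secondary_weight
                        for sc in scorers:
                            sc.deposit(xm[ev][~ok], ym[ev][~ok], zm[ev][~ok], sub)
                        acct["deposited"] += float(sub.sum())
                        acct["secondary_weight_residual"] -= 0.0
                else:
                    acct["secondary_weight_residual"] += float(
                        (e_sec * wv * nuc.secondary_weight).sum()
                    )

        # MCS deflection (post-step direction)
        x_rad = rho * s_cm / tables.x0_mass[mids]
        pv = e_half * (e_half + 2.0 * 938.27208816) / (e_half + 938.27208816)
        with np.errstate(divide="ignore", invalid="ignore"):
            theta0 = (
                14.1 / pv * np.sqrt(x_rad)
                * (1.0 + np.log10(np.maximum(x_rad, 1e-30)) / 9.0)
            )
        theta0 = np.maximum(theta0, 0.0)
        tx = rng.normal(0.0, 1.0, idx.size) * theta0
        ty = rng.normal(0.0, 1.0, idx.size) * theta0
        ndx, ndy, ndz = _rotate(dxe, dye, dze, tx, ty)

        # advance
        x1 = xe + dxe * s_mm
        y1 = ye + dye * s_mm
        z1 = np.where(at_boundary, z_bot, ze + dze * s_mm)
        for sc in scorers:
            sc.segment((xe, ye, ze), (x1, y1, z1), e_new, we)

        dead = stopped | ev
        lateral = (np.abs(x1) > lateral_halfsize) | (np.abs(y1) > lateral_halfsize)
        backward = ndz >= -1e-3
        escape = (~dead) & (lateral | backward)
        if np.any(escape):
            acct["escaped_lateral"] += float((e_new[escape] * we[escape]).sum())

        out = at_boundary & ~dead & ~escape
        # write back
        x[idx] = x1
        y[idx] = y1
        z[idx] = z1
        dx[idx] = ndx
        dy[idx] = ndy
        dz[idx] = ndz
        e[idx] = np.where(dead | escape, 0.0, e_new)
        alive_local = ~(dead | escape | out)
        alive[idx] = alive_local
        exited[idx[out]] = True

    ex = exited
    return (x[ex], y[ex], z[ex], dx[ex], dy[ex], dz[ex], e[ex], w[ex], sp[ex]), secondaries


try:
    from . import _kernels as _K

    _HAVE_NUMBA = True
    _NORM_TABLE = _K.make_norm_table()
except Exception:  # pragma: no cover
    _K = None
    _HAVE_NUMBA = False
    _NORM_TABLE = None

_DUMMY3 = np.zeros((1, 1, 1))
_DUMMY3I = np.zeros((1, 1, 1), dtype=np.int64)
_DUMMY1 = np.zeros(1)


def _step_region_fast(arrays, region, tables, scorers, rng, cfg, acct,
                      lateral_halfsize, generation):
    """Dispatch one region pass to the compiled kernel."""
    x, y, z, dx, dy, dz, e, w, sp = (a.copy() for a in arrays)
    n = x.size
    dg = next((s for s in scorers if isinstance(s, DoseGrid)), None)
    idd = next((s for s in scorers if isinstance(s, IDDScorer)), None)
    pl = next((s for s in scorers if isinstance(s, PlaneScorer)), None)

    if region.material is not None:
        is_voxel = False
        uni_mid = tables.materials.index(region.material)
        uni_rho = region.material.density
        vox_ids, vox_rho = _DUMMY3I, _DUMMY3
        vox_o = (0.0, 0.0, 0.0)
        vox_s = (1.0, 1.0, 1.0)
        vox_n = (1, 1, 1)
        vox_min = 1.0
    else:
        vg = region.voxels
        is_voxel = True
        uni_mid, uni_rho = 0, 1.0
        vox_ids = np.ascontiguousarray(vg.material_ids.astype(np.int64))
        vox_rho = np.ascontiguousarray(vg.density.astype(float))
        vox_o = vg.origin
        vox_s = vg.voxel_size
        vox_n = vg.material_ids.shape
        vox_min = float(min(vg.voxel_size))

    nuc = cfg.nuclear
    allow = bool(cfg.nuclear_enabled and generation < cfg.max_generations)
    nuc_sig_grid = nuc.sigma(_E_GRID) if allow else _DUMMY1
    if allow and nuc_sig_grid.size != _E_GRID.size:
        nuc_sig_grid = np.asarray(nuc_sig_grid, dtype=float)

    bufs = [np.empty(n) for _ in range(8)]
    seed = int(rng.integers(1 << 31))

    ret = _K.step_region_kernel(
        x, y, z, dx, dy, dz, e, w, sp,
        float(region.z_bottom),
        is_voxel, vox_ids, vox_rho,
        float(vox_o[0]), float(vox_o[1]), float(vox_o[2]),
        float(vox_s[0]), float(vox_s[1]), float(vox_s[2]),
        int(vox_n[0]), int(vox_n[1]), int(vox_n[2]), vox_min,
        uni_mid, float(uni_rho),
        float(_LOG_E_GRID[0]), float(_LOG_E_GRID[1] - _LOG_E_GRID[0]),
        _E_GRID.size, tables.s_mass, tables.r_mass, tables.rsp_mass,
        tables.x0_mass, tables.z_over_a,
        allow, nuc_sig_grid, bool(cfg.secondaries_enabled),
        float(nuc.secondary_weight), float(nuc.energy_fraction_range[0]),
        float(nuc.energy_fraction_range[1]),
        float(np.deg2rad(nuc.angular_sigma_deg_100)),
        float(nuc.angular_energy_exponent),
        float(np.deg2rad(nuc.angular_sigma_max_deg)),
        float(nuc.local_deposit_fraction),
        float(cfg.max_step_mm), float(cfg.min_step_mm),
        float(cfg.range_fraction), float(cfg.cutoff_mev),
        float(lateral_halfsize),
        dg is not None,
        dg.energy if dg is not None else _DUMMY3,
        dg.sumsq if (dg is not None and dg.sumsq is not None) else _DUMMY3,
        bool(dg is not None and dg.sumsq is not None),
        *(
            (dg.origin[0], dg.origin[1], dg.origin[2],
             dg.spacing[0], dg.spacing[1], dg.spacing[2],
             dg.shape[0], dg.shape[1], dg.shape[2])
            if dg is not None
            else (0.0, 0.0, 0.0, 1.0, 1.0, 1.0, 1, 1, 1)
        ),
        idd is not None,
        idd.energy if idd is not None else _DUMMY1,
        idd.z_surface if idd is not None else 0.0,
        idd.bin_mm if idd is not None else 1.0,
        idd.radius_mm**2 if idd is not None else 0.0,
        idd.nbins if idd is not None else 1,
        pl is not None,
        np.asarray(pl.planes_z) if pl is not None else _DUMMY1,
        pl.fluence if pl is not None else _DUMMY3,
        pl.energy_fluence if pl is not None else _DUMMY3,
        pl.halfsize if pl is not None else 1.0,
        pl.bin_mm if pl is not None else 1.0,
        pl.nbins if pl is not None else 1,
        *bufs,
        _NORM_TABLE, seed,
    )
    n_exit, n_sec, dep, esc, neut, resid = ret
    acct["deposited"] += dep
    acct["escaped_lateral"] += esc
    acct["escaped_neutral"] += neut
    acct["secondary_weight_residual"] += resid
    exit_arr = (
        x[:n_exit].copy(), y[:n_exit].copy(), z[:n_exit].copy(),
        dx[:n_exit].copy(), dy[:n_exit].copy(), dz[:n_exit].copy(),
        e[:n_exit].copy(), w[:n_exit].copy(), sp[:n_exit].copy(),
    )
    secs = []
    if n_sec:
        secs.append(
            tuple(b[:n_sec].copy() for b in bufs[:7])
            + (bufs[7][:n_sec].copy(),
               np.full(n_sec, SECONDARY, dtype=np.uint8))
        )
    return exit_arr, secs


def _fast_path_ok(scorers) -> bool:
    counts = {"dose": 0, "idd": 0, "plane": 0}
    for s in scorers:
        if isinstance(s, DoseGrid):
            counts["dose"] += 1
        elif isinstance(s, IDDScorer):
            counts["idd"] += 1
        elif isinstance(s, PlaneScorer):
            counts["plane"] += 1
        else:
            return False
    return all(v <= 1 for v in counts.values())


def transport(
    batch: ParticleBatch,
    geometry: Geometry,
    scorers: tuple = (),
    seed: int | np.random.Generator = 0,
    config: TransportConfig | None = None,
) -> TransportResult:
    """Transport a particle batch through the geometry, updating scorers.

    Returns the exit phase space (particles leaving the most-downstream region
    alive) and an energy-accounting dictionary whose terms close to the initial
    kinetic energy (see :meth:`TransportResult.energy_balance_error`).
    Bit-identical results for identical seeds.
    """
    cfg = config or TransportConfig()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if np.any(batch.energy > 300.0) or np.any(~np.isfinite(batch.energy)):
        raise ValueError("batch energies outside supported band")

    all_mats: list[mat.Material] = []
    for reg in geometry.regions:
        for m in reg.materials:
            if m not in all_mats:
                all_mats.append(m)
    tables = _MatTables(all_mats)
    name_map = {m.name: i for i, m in enumerate(all_mats)}

    acct = {
        "initial_kinetic": float((batch.energy * batch.weight).sum()),
        "initial_weight": float(batch.weight[batch.species == PRIMARY].sum()),
        "deposited": 0.0,
        "escaped_lateral": 0.0,
        "escaped_neutral": 0.0,
        "secondary_weight_residual": 0.0,
        "exit_kinetic": 0.0,
        "exit_primary_weight": 0.0,
        "n_secondaries": 0,
    }

    arrays = tuple(
        getattr(batch, f).astype(float).copy() if f != "species" else batch.species.copy()
        for f in ("x", "y", "z", "dx", "dy", "dz", "energy", "weight", "species")
    )

    use_fast = cfg.use_numba
    if use_fast is None:
        use_fast = _HAVE_NUMBA and _fast_path_ok(scorers)
    elif use_fast and not (_HAVE_NUMBA and _fast_path_ok(scorers)):
        raise ValueError("compiled kernel unavailable for this scorer set")

    pending = [(arrays, 0, 0)]  # (arrays, region_index, generation)
    exits: list[tuple] = []
    while pending:
        arr, reg_idx, gen = pending.pop()
        if arr[0].size == 0:
            continue
        if reg_idx >= len(geometry.regions):
            exits.append(arr)
            continue
        region = geometry.regions[reg_idx]
        # vacuum drift to the region top (only for particles above it)
        arr = _drift_to(arr, region.z_top, scorers, acct, geometry.lateral_halfsize)
        if arr[0].size == 0:
            continue
        if region.voxels is not None:
            # remap voxel material ids onto the global table indexing
            remap = np.array([name_map[m.name] for m in region.voxels.materials])
            voxels = VoxelGrid(
                remap[region.voxels.material_ids],
                region.voxels.density,
                all_mats,
                region.voxels.origin,
                region.voxels.voxel_size,
            )
            region = Region(region.z_top, region.z_bottom, voxels=voxels)
        if use_fast:
            exit_arr, secs = _step_region_fast(
                arr, region, tables, scorers, rng, cfg, acct,
                geometry.lateral_halfsize, gen,
            )
        else:
            exit_arr, secs = _step_region(
                arr, region, tables, name_map, scorers, rng, cfg, acct,
                geometry.lateral_halfsize, gen,
            )
        if secs:
            merged = tuple(np.concatenate(parts) for parts in zip(*secs))
            acct["n_secondaries"] += merged[0].size
            pending.append((merged, reg_idx, gen + 1))
        pending.append((exit_arr, reg_idx + 1, gen))

    if exits:
        fields = list(zip(*exits))
        out = ParticleBatch(*(np.concatenate(f) for f in fields))
    else:
        out = ParticleBatch(*(np.empty(0) for _ in range(8)),
                            np.empty(0, dtype=np.uint8))
    # score plane crossings downstream of the last material region (in-air
    # profiles after a range shifter): straight-line drift of the exit batch
    plane_scorers = [s for s in scorers if isinstance(s, PlaneScorer)]
    if out.n and plane_scorers:
        lowest = min(min(s.planes_z) for s in plane_scorers) - 1.0
        if np.any(out.z > lowest):
            move = out.dz < -1e-6
            s_len = np.where(move, (out.z - lowest) / np.where(move, -out.dz, 1.0), 0.0)
            p1 = (out.x + out.dx * s_len, out.y + out.dy * s_len,
                  np.where(move, lowest, out.z))
            for sc in plane_scorers:
                sc.segment((out.x, out.y, out.z), p1, out.energy, out.weight)

    acct["exit_kinetic"] = float((out.energy * out.weight).sum())
    acct["exit_primary_weight"] = float(out.weight[out.species == PRIMARY].sum())
    return TransportResult(out, acct)


# ---------------------------------------------------------------------------
# high-level simulation helpers
# ---------------------------------------------------------------------------

def score_idd(
    machine,
    energy: float,
    n: int = 200_000,
    seed: int | np.random.Generator = 0,
    mean_energy: float | None = None,
    energy_spread_pct: float | None = None,
    phantom_depth: float = 400.0,
    bin_mm: float = 0.5,
    config: TransportConfig | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Integral depth-dose of a single spot in water (surface at isocenter).

    ``mean_energy``/``energy_spread_pct`` override the machine's stored energy
    model (used by the commissioning tuning loops).  Returns (depth mm, dose
    normalized to unit integral) with Bragg-peak-chamber scoring (81.6 mm
    diameter, 0.5 mm bins).
    """
    from .source import EnergyModelParams, interpolate_machine, sample_spot_phase_space

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    batch = sample_spot_phase_space(machine, energy, (0.0, 0.0), n, rng)
    if mean_energy is not None or energy_spread_pct is not None:
        _, emod, _ = interpolate_machine(machine, energy)
        me = mean_energy if mean_energy is not None else emod.mean_energy
        sp = energy_spread_pct if energy_spread_pct is not None else emod.energy_spread_pct
        emod2 = EnergyModelParams(energy, me, sp)
        batch.energy = (
            rng.normal(me, emod2.sigma_mev, n) if emod2.sigma_mev > 0
            else np.full(n, me)
        )
        batch.energy = np.clip(batch.energy, 2.5, 299.5)
    geom = Geometry([water_box(0.0, phantom_depth)])
    cfg = config or TransportConfig(max_step_mm=0.5)
    scorer = IDDScorer(0.0, depth_mm=phantom_depth, bin_mm=bin_mm)
    transport(batch, geom, (scorer,), rng, cfg)
    return scorer.curve()


def simulate_spot(
    machine,
    energy: float,
    n: int = 100_000,
    seed: int | np.random.Generator = 0,
    spot_iso_position: tuple[float, float] = (0.0, 0.0),
    geometry: Geometry | None = None,
    scorers: tuple = (),
    config: TransportConfig | None = None,
) -> TransportResult:
    """Sample one spot's phase space and transport it through the geometry."""
    from .source import sample_spot_phase_space

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    batch = sample_spot_phase_space(machine, energy, spot_iso_position, n, rng)
    geom = geometry or Geometry([water_box(0.0)])
    res = transport(batch, geom, scorers, rng, config)
    for sc in scorers:
        if isinstance(sc, DoseGrid):
            sc.n_source_particles += n
    return res


def shift_add(target: np.ndarray, kernel: np.ndarray, sx: int, sy: int,
              weight: float) -> None:
    """Add ``weight * kernel`` shifted by integer voxels (sx, sy) into target."""
    nx, ny = kernel.shape[:2]
    x0t, x1t = max(0, sx), min(nx, nx + sx)
    y0t, y1t = max(0, sy), min(ny, ny + sy)
    if x0t >= x1t or y0t >= y1t:
        return
    target[x0t:x1t, y0t:y1t] += weight * kernel[
        x0t - sx : x1t - sx, y0t - sy : y1t - sy
    ]


def simulate_field(
    machine,
    field,
    n_per_kernel: int = 200_000,
    seed: int | np.random.Generator = 0,
    geometry: Geometry | None = None,
    grid: DoseGrid | None = None,
    kernel_reuse: bool = True,
    absolute: bool = True,
    config: TransportConfig | None = None,
) -> DoseGrid:
    """Simulate a scanned field onto a dose grid.

    With ``kernel_reuse`` (default) one central-axis kernel per distinct energy
    is simulated with ``n_per_kernel`` protons and superposed at the spot
    positions (valid for spot grids commensurate with the dose grid spacing).
    With ``absolute`` the grid is scaled to Gy using MU x protons-per-MU per
    spot; otherwise dose is per simulated proton.
    """
    from .source import interpolate_machine

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    geom = geometry or Geometry.beamline(
        water_box(0.0), machine, use_range_shifter=field.use_range_shifter
    )
    out = grid or DoseGrid.centered(400.0, 0.0, 400.0)
    if not kernel_reuse:
        for spot in field.spots:
            k = DoseGrid(out.origin, out.shape, out.spacing, out.density)
            simulate_spot(
                machine, spot.energy, n_per_kernel, rng,
                spot_iso_position=(spot.x, spot.y), geometry=geom, scorers=(k,),
                config=config,
            )
            _, _, ppmu = interpolate_machine(machine, spot.energy)
            scale = (spot.mu * ppmu / n_per_kernel) if absolute else (1.0 / n_per_kernel)
            out.energy += k.energy * scale
        out.n_source_particles += n_per_kernel * len(field.spots)
        return out

    energies = sorted({spot.energy for spot in field.spots})
    for e in energies:
        kgrid = DoseGrid(out.origin, out.shape, out.spacing, out.density)
        simulate_spot(machine, e, n_per_kernel, rng, geometry=geom,
                      scorers=(kgrid,), config=config)
        _, _, ppmu = interpolate_machine(machine, e)
        for spot in field.spots:
            if spot.energy != e:
                continue
            sx = int(round(spot.x / out.spacing[0]))
            sy = int(round(spot.y / out.spacing[1]))
            scale = (spot.mu * ppmu / n_per_kernel) if absolute else (1.0 / n_per_kernel)
            shift_add(out.energy, kgrid.energy, sx, sy, scale)
    out.n_source_particles += n_per_kernel * len(energies)
    return out
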