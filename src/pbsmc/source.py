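"""Parameterized phase-space source model for a scanned proton pencil beam.

The transverse phase space of each spot is described per axis by Courant-Snyder
parameters referenced at isocenter: spot sigma ``sigma0`` (mm), angular sigma
``sigma_theta`` (rad), and position-angle correlation ``rho0``.  Under a pure
drift the covariance propagates linearly, giving the spot-size parabola

    sigma^2(Z) = sigma0^2 - 2 rho0 sigma0 sigma_theta Z + sigma_theta^2 Z^2

with Z the plane coordinate (positive upstream, IEC61217 gantry system, origin
at isocenter; the beam travels toward decreasing Z).  ``rho(Z) > 0`` means the
beam is defocusing at that plane, ``< 0`` focusing.

Scanning deflections are modeled by two effective focal points at distances
``fx``/``fy`` upstream of isocenter: a spot aimed at iso position x follows
x(Z) = x * (f - Z)/f.

x and y are commissioned independently (elliptical spots); there is no x-y
correlation.  The region between the source plane and the first material is
vacuum, so the angular sigma is exactly preserved in the drift.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "OpticsParams",
    "ScanGeometry",
    "EnergyModelParams",
    "RangeShifterSpec",
    "MachineModel",
    "sigma_at",
    "rho_at",
    "covariance_at",
    "fit_optics",
    "fit_effective_sad",
    "interpolate_machine",
    "sample_spot_phase_space",
]


@dataclass(frozen=True)
class OpticsParams:
    """Per-axis Courant-Snyder parameters at isocenter.

    sigma0 in mm, sigma_theta in radians, rho0 dimensionless in [-1, 1].
    """

    sigma0_x: float
    sigma_theta_x: float
    rho0_x: float
    sigma0_y: float
    sigma_theta_y: float
    rho0_y: float

    def __post_init__(self) -> None:
        for ax in ("x", "y"):
            if getattr(self, f"sigma0_{ax}") <= 0:
                raise ValueError(f"sigma0_{ax} must be positive")
            if getattr(self, f"sigma_theta_{ax}") <= 0:
                raise ValueError(f"sigma_theta_{ax} must be positive")
            if abs(getattr(self, f"rho0_{ax}")) > 1:
                raise ValueError(f"|rho0_{ax}| must be <= 1")

    def axis(self, ax: str) -> tuple[float, float, float]:
        return (
            getattr(self, f"sigma0_{ax}"),
            getattr(self, f"sigma_theta_{ax}"),
            getattr(self, f"rho0_{ax}"),
        )


@dataclass(frozen=True)
class ScanGeometry:
    """Effective source-axis distances and the source-plane location (mm)."""

    fx: float
    fy: float
    source_plane_z: float

    def __post_init__(self) -> None:
        if self.fx <= 0 or self.fy <= 0:
            raise ValueError("focal distances must be positive")
        if self.source_plane_z <= 0:
            raise ValueError("source plane must be upstream of isocenter (z > 0)")


@dataclass(frozen=True)
class EnergyModelParams:
    """Gaussian energy spectrum: mean (MeV) and spread as % of the mean."""

    nominal_energy: float
    mean_energy: float
    energy_spread_pct: float

    def __post_init__(self) -> None:
        if self.energy_spread_pct < 0:
            raise ValueError("energy spread must be non-negative")
        if abs(self.mean_energy - self.nominal_energy) > 0.05 * self.nominal_energy:
            raise ValueError("mean energy deviates more than 5% from nominal")

    @property
    def sigma_mev(self) -> float:
        return self.mean_energy * self.energy_spread_pct / 100.0


@dataclass(frozen=True)
class RangeShifterSpec:
    """Range shifter: material name and physical thickness in mm."""

    material: str
    thickness_mm: float


@dataclass
class MachineModel:
    """Per-energy lookup table of optics, energy model and protons/MU.

    ``energies`` are the commissioned nominal energies (sorted ascending);
    interpolation between them is linear in each parameter separately and only
    valid inside the commissioned band.
    """

    energies: list[float]
    optics: dict[float, OpticsParams]
    energy_model: dict[float, EnergyModelParams]
    protons_per_mu: dict[float, float]
    geometry: ScanGeometry
    range_shifter: RangeShifterSpec | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.energies = sorted(float(e) for e in self.energies)
        if len(self.energies) < 2:
            raise ValueError("machine model needs at least two commissioned energies")

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "format": "pbsmc-machine-1",
            "energies": self.energies,
            "geometry": {
                "fx": self.geometry.fx,
                "fy": self.geometry.fy,
                "source_plane_z": self.geometry.source_plane_z,
            },
            "range_shifter": (
                None
                if self.range_shifter is None
                else {
                    "material": self.range_shifter.material,
                    "thickness_mm": self.range_shifter.thickness_mm,
                }
            ),
            "table": {
                str(e): {
                    "optics": vars(self.optics[e]).copy(),
                    "energy_model": vars(self.energy_model[e]).copy(),
                    "protons_per_mu": self.protons_per_mu[e],
                }
                for e in self.energies
            },
            "meta": self.meta,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MachineModel":
        geo = ScanGeometry(**d["geometry"])
        rs = d.get("range_shifter")
        energies = [float(e) for e in d["energies"]]
        optics, emod, ppmu = {}, {}, {}
        for key, row in d["table"].items():
            e = float(key)
            optics[e] = OpticsParams(**row["optics"])
            emod[e] = EnergyModelParams(**row["energy_model"])
            ppmu[e] = float(row["protons_per_mu"])
        return cls(
            energies=energies,
            optics=optics,
            energy_model=emod,
            protons_per_mu=ppmu,
            geometry=geo,
            range_shifter=None if rs is None else RangeShifterSpec(**rs),
            meta=d.get("meta", {}),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "MachineModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# drift optics
# ---------------------------------------------------------------------------

def sigma_at(sigma0: float, sigma_theta: float, rho0: float, z) -> np.ndarray | float:
    """Spot sigma (mm) at plane Z from the isocenter parameters (one axis)."""
    z = np.asarray(z, dtype=float)
    var = sigma0**2 - 2.0 * rho0 * sigma0 * sigma_theta * z + (sigma_theta * z) ** 2
    out = np.sqrt(var)
    return float(out) if out.ndim == 0 else out


def rho_at(sigma0: float, sigma_theta: float, rho0: float, z) -> np.ndarray | float:
    """Position-angle correlation at plane Z (one axis); in [-1, 1]."""
    s = sigma_at(sigma0, sigma_theta, rho0, z)
    out = (rho0 * sigma0 - sigma_theta * np.asarray(z, dtype=float)) / s
    out = np.clip(out, -1.0, 1.0)
    return float(out) if np.ndim(out) == 0 else out


def covariance_at(sigma0: float, sigma_theta: float, rho0: float, z: float) -> np.ndarray:
    """2x2 (position, angle) covariance at plane Z via the drift transfer matrix."""
    c0 = np.array(
        [
            [sigma0**2, rho0 * sigma0 * sigma_theta],
            [rho0 * sigma0 * sigma_theta, sigma_theta**2],
        ]
    )
    m = np.array([[1.0, -z], [0.0, 1.0]])
    return m @ c0 @ m.T


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

@dataclass
class OpticsFitResult:
    sigma0: float
    sigma_theta: float
    rho0: float
    rms_residual_mm: float
    physical: bool


def fit_optics(measurements: list[tuple[float, float]]) -> OpticsFitResult:
    """Least-squares fit of measured spot sigmas to the drift parabola (one axis).

    ``measurements`` is a list of (plane Z in mm, sigma in mm) with at least
    three distinct planes.  Returns isocenter parameters plus the RMS sigma
    residual; a fit with |rho0| > 1 is flagged non-physical.
    """
    if len(measurements) < 3:
        raise ValueError("need at least three planes to fit optics")
    z = np.array([m[0] for m in measurements], dtype=float)
    s = np.array([m[1] for m in measurements], dtype=float)
    if len(np.unique(z)) < 3:
        raise ValueError("need at least three distinct plane locations")
    # sigma^2(Z) = c0 + c1 Z + c2 Z^2
    coeff = np.polyfit(z, s**2, 2)  # [c2, c1, c0]
    c2, c1, c0 = coeff
    if c0 <= 0 or c2 <= 0:
        raise ValueError("fit yields non-positive sigma0^2 or sigma_theta^2")
    sigma0 = float(np.sqrt(c0))
    sigma_theta = float(np.sqrt(c2))
    rho0 = float(-c1 / (2.0 * sigma0 * sigma_theta))
    fitted = sigma_at(sigma0, sigma_theta, np.clip(rho0, -1, 1), z)
    rms = float(np.sqrt(np.mean((fitted - s) ** 2)))
    return OpticsFitResult(sigma0, sigma_theta, rho0, rms, physical=abs(rho0) <= 1.0)


def fit_effective_sad(deflections: list[list[tuple[float, float]]]) -> float:
    """Effective source-axis distance from beam positions at >= 2 planes.

    ``deflections`` holds, per requested scan offset, a list of (plane Z mm,
    lateral position mm).  For each deflection the positions follow
    x(Z) = x_iso (f - Z)/f, a straight line whose intercept/slope ratio gives
    f; the result is averaged over deflections.  A parallel beam (zero slope)
    yields ``inf``.
    """
    fs = []
    for planes in deflections:
        if len(planes) < 2:
            raise ValueError("need at least two planes per deflection")
        z = np.array([p[0] for p in planes], dtype=float)
        x = np.array([p[1] for p in planes], dtype=float)
        slope, intercept = np.polyfit(z, x, 1)
        if intercept == 0:
            raise ValueError("deflection passes through the axis; cannot infer SAD")
        if abs(slope) * (np.abs(z).max() + 1.0) < 1e-9 * abs(intercept):
            fs.append(np.inf)  # parallel beam: no finite focal point
        else:
            fs.append(-intercept / slope)
    return float(np.mean(fs))


# ---------------------------------------------------------------------------
# machine interpolation and sampling
# ---------------------------------------------------------------------------

def interpolate_machine(
    machine: MachineModel, energy: float
) -> tuple[OpticsParams, EnergyModelParams, float]:
    """Componentwise linear interpolation of the lookup table at ``energy``.

    Exact at commissioned nodes; raises outside the commissioned band.
    """
    e = float(energy)
    elo, ehi = machine.energies[0], machine.energies[-1]
    if not elo <= e <= ehi:
        raise ValueError(f"energy {e} outside commissioned band [{elo}, {ehi}]")
    if e in machine.optics:
        return machine.optics[e], machine.energy_model[e], machine.protons_per_mu[e]
    idx = np.searchsorted(machine.energies, e)
    e0, e1 = machine.energies[idx - 1], machine.energies[idx]
    t = (e - e0) / (e1 - e0)

    def lerp(a: float, b: float) -> float:
        return (1.0 - t) * a + t * b

    o0, o1 = machine.optics[e0], machine.optics[e1]
    optics = OpticsParams(
        *(lerp(getattr(o0, f), getattr(o1, f)) for f in (
            "sigma0_x", "sigma_theta_x", "rho0_x",
            "sigma0_y", "sigma_theta_y", "rho0_y",
        ))
    )
    m0, m1 = machine.energy_model[e0], machine.energy_model[e1]
    emod = EnergyModelParams(
        nominal_energy=e,
        mean_energy=lerp(m0.mean_energy, m1.mean_energy),
        energy_spread_pct=lerp(m0.energy_spread_pct, m1.energy_spread_pct),
    )
    ppmu = lerp(machine.protons_per_mu[e0], machine.protons_per_mu[e1])
    return optics, emod, ppmu


def sample_spot_phase_space(
    machine: MachineModel,
    energy: float,
    spot_iso_position: tuple[float, float],
    n: int,
    rng: np.random.Generator | int,
):
    """Sample a particle batch for one spot at the source plane.

    The per-axis (position, angle) pairs are drawn from the isocenter
    covariance propagated back to the source plane through the vacuum drift;
    the mean direction is aimed from the effective focal point through the
    spot's isocenter position.  Angles are slopes dx/ds with s the path length
    along the beam (toward decreasing z).  Energies are Gaussian per the
    energy model.  Returns a :class:`pbsmc.transport.ParticleBatch`.
    """
    from .transport import ParticleBatch

    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    optics, emod, _ = interpolate_machine(machine, energy)
    zs = machine.geometry.source_plane_z
    xs_iso, ys_iso = spot_iso_position

    pos = {}
    ang = {}
    for ax, f in (("x", machine.geometry.fx), ("y", machine.geometry.fy)):
        s0, st, r0 = optics.axis(ax)
        cov = covariance_at(s0, st, r0, 0.0)
        # method="eigh" guards tiny negative eigenvalues in degenerate cases
        sample = rng.multivariate_normal([0.0, 0.0], cov, size=n, method="eigh")
        x_iso_dev, theta = sample[:, 0], sample[:, 1]
        # theta is the slope dx/ds along the beam (s increases toward -z), so
        # a particle reaching x_iso at isocenter sits at x_iso - theta * Z at
        # the source plane; the variance at plane Z then follows the
        # sigma_at parabola.
        offset = xs_iso if ax == "x" else ys_iso
        theta_scan = offset / f
        pos[ax] = x_iso_dev - theta * zs + offset * (f - zs) / f
        ang[ax] = theta + theta_scan

    e = rng.normal(emod.mean_energy, emod.sigma_mev, size=n) if emod.sigma_mev > 0 \
        else np.full(n, emod.mean_energy)
    e = np.clip(e, 2.5, 299.5)

    dz = -1.0 / np.sqrt(1.0 + ang["x"] ** 2 + ang["y"] ** 2)
    batch = ParticleBatch(
        x=pos["x"],
        y=pos["y"],
        z=np.full(n, zs),
        dx=-dz * ang["x"],
        dy=-dz * ang["y"],
        dz=dz,
        energy=e,
        weight=np.ones(n),
        species=np.zeros(n, dtype=np.uint8),
    )
    return batch
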