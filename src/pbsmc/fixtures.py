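"""Virtual machine and pseudo-measurement generation.

The virtual machine emulates a dedicated scanned-proton nozzle: six
commissioned energies between 100 and 225 MeV, elliptical spots that shrink
with energy (divergence falling from ~6 mrad at 100 MeV to ~3 mrad at
210 MeV, with a slight re-increase at 225 MeV), Gaussian energy spreads
falling from 0.67% of the mean at 100 MeV to 0.28% at 225 MeV, protons per MU
rising from ~9e7 to ~1.5e8 in exact proportion to the inverse electronic
stopping power of air (emulating an air-filled monitor chamber at 3 nC per
MU), effective source-axis distances fx = 1859.1 mm / fy = 2234.8 mm, and a
65 mm Lexan range shifter whose upstream face defines the source plane.

Optics values at energies the trends do not pin down are smooth interpolants;
they are fixture inventions, not measured quantities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import materials as M
from .commissioning import EnergyMeasurement, MeasurementSet, reference_field_dose
from .source import (
    EnergyModelParams,
    MachineModel,
    OpticsParams,
    RangeShifterSpec,
    ScanGeometry,
    sigma_at,
)
from .transport import score_idd

__all__ = [
    "FIXTURE_ENERGIES",
    "MEASUREMENT_PLANES",
    "NoiseConfig",
    "make_virtual_machine",
    "generate_measurement_set",
    "make_toy_lung_phantom",
]

FIXTURE_ENERGIES = (100.0, 115.0, 150.0, 180.0, 210.0, 225.0)
#: in-air spot-profile plane locations (mm, isocenter at 0)
MEASUREMENT_PLANES = (455.0, 330.0, 200.0, 100.0, 0.0, -100.0)
SOURCE_PLANE_Z = 460.0

# per-energy ground-truth optics (sigma0 mm, sigma_theta mrad, rho0)
_OPTICS = {
    100.0: (6.0, 6.0, 0.18, 6.8, 5.5, 0.52),
    115.0: (5.6, 5.5, 0.17, 6.3, 5.1, 0.50),
    150.0: (4.8, 4.6, 0.16, 5.4, 4.3, 0.47),
    180.0: (4.2, 3.9, 0.15, 4.7, 3.7, 0.45),
    210.0: (3.6, 3.0, 0.14, 4.0, 3.1, 0.43),
    225.0: (3.8, 3.3, 0.14, 4.2, 3.2, 0.43),
}


def _spread_pct(e: float) -> float:
    """Energy spread, % of mean: 0.67 at 100 MeV to 0.28 at 225 MeV (linear)."""
    return 0.67 + (0.28 - 0.67) * (e - 100.0) / 125.0


def make_virtual_machine(seed: int = 0) -> MachineModel:
    """Ground-truth machine model for the virtual nozzle (deterministic)."""
    c_mu = 9.0e7 * M.mass_stopping_power(M.AIR, 100.0)
    optics = {}
    emod = {}
    ppmu = {}
    for e in FIXTURE_ENERGIES:
        sx, stx, rx, sy, sty, ry = _OPTICS[e]
        optics[e] = OpticsParams(sx, stx * 1e-3, rx, sy, sty * 1e-3, ry)
        emod[e] = EnergyModelParams(e, e, _spread_pct(e))
        ppmu[e] = c_mu / M.mass_stopping_power(M.AIR, e)
    return MachineModel(
        energies=list(FIXTURE_ENERGIES),
        optics=optics,
        energy_model=emod,
        protons_per_mu=ppmu,
        geometry=ScanGeometry(fx=1859.1, fy=2234.8, source_plane_z=SOURCE_PLANE_Z),
        range_shifter=RangeShifterSpec("lexan", 65.0),
        meta={"fixture": "virtual dedicated nozzle", "seed": seed},
    )


@dataclass
class NoiseConfig:
    """Gaussian measurement-noise magnitudes (relative unless noted)."""

    spot_sigma_rel: float = 0.01
    reference_dose_rel: float = 0.005
    deflection_mm: float = 0.05


def generate_measurement_set(
    machine: MachineModel,
    noise: NoiseConfig | None = None,
    seed: int = 0,
    n_idd: int = 200_000,
    n_ref: int = 200_000,
    energies=None,
    include_idd: bool = True,
    include_reference_dose: bool = True,
) -> MeasurementSet:
    """Pseudo-measurements from the ground-truth machine.

    Spot sigmas follow the drift parabola plus relative noise; IDDs are
    simulated with the transport engine (their noise is the Monte Carlo
    noise); absolute reference doses come from the ground-truth protons/MU
    with relative noise.  Different seeds give different sets.
    """
    noise = noise or NoiseConfig()
    rng = np.random.default_rng(seed)
    energies = list(energies or machine.energies)

    measurements = {}
    for e in energies:
        opt = machine.optics[e]
        sig_x = []
        sig_y = []
        for zp in MEASUREMENT_PLANES:
            for ax, out in (("x", sig_x), ("y", sig_y)):
                s0, st, r0 = opt.axis(ax)
                s = sigma_at(s0, st, r0, zp)
                s *= 1.0 + noise.spot_sigma_rel * rng.standard_normal()
                out.append((float(zp), float(s)))
        idd_depth = idd_dose = None
        if include_idd:
            idd_depth, idd_dose = score_idd(
                machine, e, n=n_idd, seed=rng,
                phantom_depth=min(
                    M.csda_range(M.WATER, e) * 10.0 * 1.25 + 30.0, 400.0
                ),
            )
        ref_dose = None
        if include_reference_dose:
            d_per_spot_proton = reference_field_dose(
                machine, e, n=n_ref, seed=rng
            )
            ref_dose = machine.protons_per_mu[e] * d_per_spot_proton
            ref_dose *= 1.0 + noise.reference_dose_rel * rng.standard_normal()
        measurements[e] = EnergyMeasurement(
            nominal_energy=e,
            spot_sigmas_x=sig_x,
            spot_sigmas_y=sig_y,
            idd_depth=None if idd_depth is None else np.asarray(idd_depth),
            idd_dose=None if idd_dose is None else np.asarray(idd_dose),
            reference_dose_gy=ref_dose,
        )

    # SAD deflection data: positions of deflected beams at two planes
    # spanning the full measured region (lever arm matters for the fit)
    defl_x, defl_y = [], []
    for offset in (60.0, 100.0):
        for f, out in ((machine.geometry.fx, defl_x), (machine.geometry.fy, defl_y)):
            planes = []
            for zp in (0.0, 455.0):
                xpos = offset * (f - zp) / f
                planes.append(
                    (zp, float(xpos + noise.deflection_mm * rng.standard_normal()))
                )
            out.append(planes)

    return MeasurementSet(
        measurements=measurements,
        deflections_x=defl_x,
        deflections_y=defl_y,
        source_plane_z=machine.geometry.source_plane_z,
        range_shifter=machine.range_shifter,
        meta={"seed": seed, "n_idd": n_idd},
    )


def make_toy_lung_phantom(
    voxel_mm: float = 2.0,
    size_mm: tuple[float, float, float] = (120.0, 120.0, 120.0),
    surface_z: float = 0.0,
):
    """Toy thorax analog: soft-tissue box, lung insert (RSP ~0.31), target.

    Returns (hu_array, target_mask, origin, voxel_size).  The lung insert HU
    is chosen so the default calibration maps it to RSP 0.31; the embedded
    target is soft-tissue-equivalent and lies fully inside the lung insert.
    """
    nx, ny, nz = (max(int(round(s / voxel_mm)), 1) for s in size_mm)
    hu = np.zeros((nx, ny, nz))
    # lung insert occupying the central half in x/y and depth 25-75%
    lung_hu = -690.0  # default curve: RSP(-690) ~ 0.31
    sl = (
        slice(nx // 4, 3 * nx // 4),
        slice(ny // 4, 3 * ny // 4),
        slice(nz // 4, 3 * nz // 4),
    )
    hu[sl] = lung_hu
    # soft-tissue target centered in the insert
    target = np.zeros_like(hu, dtype=bool)
    tx = slice(int(nx * 0.42), int(nx * 0.58))
    ty = slice(int(ny * 0.42), int(ny * 0.58))
    tz = slice(int(nz * 0.42), int(nz * 0.58))
    target[tx, ty, tz] = True
    hu[target] = 0.0
    origin = (-size_mm[0] / 2.0, -size_mm[1] / 2.0, surface_z - size_mm[2])
    return hu, target, origin, (voxel_mm, voxel_mm, voxel_mm)
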