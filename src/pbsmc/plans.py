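"""Delivery data model: spots, fields, plans, field generators and JSON I/O.

A *spot* is one scanned pencil beam (energy, isocenter position, monitor
units); a *field* is a list of spots delivered at fixed gantry/couch angles,
optionally through the range shifter.  The JSON dialect is versioned
("pbsmc-plan-1") and validated on read.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dfield
from pathlib import Path

import numpy as np

__all__ = [
    "Spot",
    "Field",
    "Plan",
    "make_square_field",
    "make_sobp",
    "read_plan",
    "write_plan",
    "PlanValidationError",
]


class PlanValidationError(ValueError):
    pass


@dataclass(frozen=True)
class Spot:
    energy: float  # MeV
    x: float  # mm at isocenter
    y: float
    mu: float

    def __post_init__(self) -> None:
        if self.mu <= 0:
            raise PlanValidationError("spot MU must be positive")


@dataclass
class Field:
    spots: list[Spot]
    use_range_shifter: bool = False
    gantry_angle: float = 0.0
    couch_angle: float = 0.0
    air_gap_mm: float | None = None
    name: str = "field"

    @property
    def energies(self) -> list[float]:
        return sorted({s.energy for s in self.spots})

    @property
    def total_mu(self) -> float:
        return sum(s.mu for s in self.spots)


@dataclass
class Plan:
    fields: list[Field]
    name: str = "plan"
    meta: dict = dfield(default_factory=dict)


def make_square_field(
    energy: float,
    side_mm: float,
    spacing_mm: float = 4.0,
    mu_per_spot: float = 1.0,
    inclusive_edges: bool = True,
    **field_kwargs,
) -> Field:
    """Square scanned field centered on the axis.

    With ``inclusive_edges`` spots run from -side/2 to +side/2 inclusive,
    giving (side/spacing + 1)^2 spots; exclusive mode drops one edge row and
    column, matching the 625-spot (25 x 25) reference variant for a 100 mm
    field at 4 mm spacing.
    """
    half = side_mm / 2.0
    n = int(np.floor(side_mm / spacing_mm + 1e-9)) + 1
    if not inclusive_edges:
        n -= 1
    if n < 1:
        n = 1
    pos = (np.arange(n) - (n - 1) / 2.0) * spacing_mm
    pos = pos[np.abs(pos) <= half + 1e-9]
    spots = [
        Spot(energy=energy, x=float(px), y=float(py), mu=mu_per_spot)
        for px in pos
        for py in pos
    ]
    return Field(spots=spots, **field_kwargs)


def make_sobp(
    range_mm: float,
    modulation_mm: float,
    machine,
    side_mm: float = 96.0,
    spacing_mm: float = 4.0,
    n_per_layer: int = 20_000,
    seed: int = 0,
    layer_spacing_fraction: float = 0.4,
    use_range_shifter: bool = False,
) -> Field:
    """Build a spread-out Bragg peak field (energy layers + solved weights).

    Layers are chosen so that successive pristine-peak R80s differ by about
    ``layer_spacing_fraction`` of the distal layer's peak FWHM (the default
    0.4 keeps the inter-layer ripple of these sharply peaked curves within a
    few percent); layer weights
    are solved by non-negative least squares for a flat central-axis dose over
    [range - modulation, range].  Raises if the requested range is infeasible
    for the commissioned band.
    """
    from scipy.optimize import nnls

    from . import materials as M
    from .commissioning import r80 as _r80
    from .transport import score_idd

    wtab = M.range_table(M.WATER)
    shift = 0.0
    if use_range_shifter:
        rs = machine.range_shifter
        shift = M.wet(M.BUILTIN_MATERIALS[rs.material], rs.thickness_mm, 160.0)

    def energy_for_range(r_mm: float) -> float:
        return float(wtab.energy_from_range((r_mm + shift) / 10.0))

    e_lo, e_hi = machine.energies[0], machine.energies[-1]
    e_distal = energy_for_range(range_mm)
    if not e_lo <= e_distal <= e_hi:
        raise ValueError(
            f"range {range_mm} mm needs {e_distal:.1f} MeV, outside "
            f"[{e_lo}, {e_hi}] MeV"
        )

    rng = np.random.default_rng(seed)
    # distal layer IDD -> peak FWHM -> layer spacing
    energies = [e_distal]
    curves = []
    d, c = score_idd(machine, e_distal, n=n_per_layer, seed=rng)
    curves.append((d, c))
    half = c >= 0.5 * c.max()
    fwhm = d[half][-1] - d[half][0]
    spacing = max(layer_spacing_fraction * fwhm, 1.0)

    if modulation_mm > 0:
        r = range_mm - spacing
        while r > range_mm - modulation_mm - spacing / 2.0:
            e = energy_for_range(max(r, 1.0))
            if e < e_lo:
                break
            energies.append(e)
            d, c = score_idd(machine, e, n=n_per_layer, seed=rng)
            curves.append((d, c))
            r -= spacing

    # weight solve: flat unit dose over the modulation region
    depths = curves[0][0]
    sel = (depths >= range_mm - modulation_mm - 1.0) & (depths <= range_mm - 1.0)
    if modulation_mm == 0:
        weights = np.array([1.0])
    else:
        a = np.stack([np.interp(depths[sel], dd, cc) for dd, cc in curves], axis=1)
        weights, _ = nnls(a, np.ones(sel.sum()))
        if weights[0] <= 0:
            weights[0] = max(weights.max(), 1.0)
    weights = weights / weights.max()

    spots: list[Spot] = []
    for e, wgt in zip(energies, weights):
        if wgt <= 1e-6:
            continue
        layer = make_square_field(e, side_mm, spacing_mm, mu_per_spot=float(wgt))
        spots.extend(layer.spots)
    return Field(
        spots=spots,
        use_range_shifter=use_range_shifter,
        name=f"R{range_mm:.0f}M{modulation_mm:.0f}",
    )


# ---------------------------------------------------------------------------
# JSON dialect
# ---------------------------------------------------------------------------

def write_plan(plan: Plan, path: str | Path) -> None:
    doc = {
        "format": "pbsmc-plan-1",
        "name": plan.name,
        "meta": plan.meta,
        "fields": [
            {
                "name": f.name,
                "use_range_shifter": f.use_range_shifter,
                "gantry_angle": f.gantry_angle,
                "couch_angle": f.couch_angle,
                "air_gap_mm": f.air_gap_mm,
                "spots": [
                    {"energy": s.energy, "x": s.x, "y": s.y, "mu": s.mu}
                    for s in f.spots
                ],
            }
            for f in plan.fields
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def read_plan(path: str | Path) -> Plan:
    doc = json.loads(Path(path).read_text())
    if doc.get("format") != "pbsmc-plan-1":
        raise PlanValidationError(f"unsupported plan format: {doc.get('format')!r}")
    fields = []
    for fi, fd in enumerate(doc.get("fields", [])):
        spots = []
        for si, sd in enumerate(fd.get("spots", [])):
            for key in ("energy", "x", "y", "mu"):
                if key not in sd:
                    raise PlanValidationError(
                        f"field {fi}, spot {si}: missing {key!r}"
                    )
            spots.append(Spot(sd["energy"], sd["x"], sd["y"], sd["mu"]))
        fields.append(
            Field(
                spots=spots,
                use_range_shifter=bool(fd.get("use_range_shifter", False)),
                gantry_angle=float(fd.get("gantry_angle", 0.0)),
                couch_angle=float(fd.get("couch_angle", 0.0)),
                air_gap_mm=fd.get("air_gap_mm"),
                name=fd.get("name", f"field{fi}"),
            )
        )
    return Plan(fields=fields, name=doc.get("name", "plan"), meta=doc.get("meta", {}))
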