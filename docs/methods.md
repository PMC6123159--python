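# Methods

`pbsmc` is a desk-scale Monte Carlo dose platform for proton pencil-beam
scanning (PBS): a parameterized beam source commissioned from measurements, a
condensed-history transport engine, and the dosimetric QA analyses used to
validate such engines. This note records the model, its assumptions, the
parameters that matter, and the limits of what the synthetic test bench can
show.

## Coordinate system and geometry

IEC61217 gantry coordinates with the origin at isocenter; the beam travels
toward decreasing z, the source plane sits at the upstream face of the range
shifter (z = +460 mm in the virtual machine). Material regions are ordered
slabs along z — uniform (a water tank, the Lexan range shifter) or voxelized
(material id + density arrays, 0-based half-open voxels, world position =
origin + (index + 0.5) · voxel size). Everything between regions is vacuum:
the in-air divergence is fitted from in-air spot measurements, so air
scattering is already folded into the source model and the gap is not
re-simulated.

## Single-proton physics

**Stopping power.** Bethe formula with the material's mean excitation energy,
no shell or density-effect corrections. That choice is adequate above
~10 MeV (agreement with published PSTAR water values is ≤0.1% at
100–250 MeV and ~0.6% at 10 MeV, verified in the test suite); the transport
cutoff at 2 MeV keeps the model inside its validity band, with residual
energy deposited locally. Supported band: 2–300 MeV.

**Ranges and WET.** CSDA range–energy tables are built once per material by
trapezoidal integration of 1/S on a 4096-point log grid (0.5–300 MeV) and
cached; lookups interpolate linearly in log–log space. Water-equivalent
thickness is solved by range differencing: find the slab exit energy from the
material table, then the water thickness producing the same energy loss. WET
is quoted at 160 MeV (mid-band); for Lexan it varies by <0.5% over
100–225 MeV.

**Energy straggling.** Gaussian (Bohr) straggling with variance
0.1569 · (Z/A) · ρ·s MeV² per step — additive in path length, valid for
steps short compared with the residual range.

**Multiple Coulomb scattering.** Highland parameterization
θ₀ = 14.1 MeV/(pv) · √(x/X₀) · (1 + log₁₀(x/X₀)/9), applied per
condensed-history step as independent Gaussian deflections in the two
transverse planes; radiation lengths come from the Tsai elemental
approximation combined by mass fraction. Because the logarithmic term makes
Highland non-additive, the step-control policy below keeps the step-size
dependence of the accumulated angle under ~1%, and the Fermi–Eyges
consistency test (MC vs deterministic quadrature of the same per-step angles)
agrees to <3% at depth.

**Nuclear interactions.** A single macroscopic *removal* cross section per cm
of water-equivalent path stands in for nonelastic reactions plus the
large-angle elastic tail. The embedded water table is zero below 8 MeV, peaks
near 20–25 MeV (~0.016 cm⁻¹) and declines slowly above 50 MeV
(~0.011–0.012 cm⁻¹); its overall normalization is fixed so that a 115 MeV
proton crossing the 74.1 mm-WET range shifter loses ≈9% of primaries,
matching published full-MC attenuation for that geometry. Other materials
scale by water-equivalent path, which is accurate at the percent level for
low-Z media.

**Secondary protons.** Each removal event terminates the primary and emits
one *effective* secondary proton carrying a uniform fraction U(0.10, 0.78) of
the post-step primary energy, deflected by a Gaussian angle with
σ = 45° · (100 MeV/E)^1.8 capped at 55°, and weighted by a multiplicity
factor of 3.0. Energy not given to the secondary splits 40% locally
deposited / 60% escaping neutrals. These four numbers are the engine's halo
model; they were calibrated once against the field-size-factor targets
(≈3% FSF difference between 40 and 200 mm fields at low energy, ≈11% at
225 MeV mid-range) and then frozen. The statistical weight >1 means secondary
energy is deliberately over-represented to emulate the multi-particle halo a
full nuclear model would produce; the energy ledger accounts for the excess
explicitly so conservation can still be asserted. Secondaries are transported
with full proton physics for up to three generations.

## Transport engine

Step length is min(1 mm, 2% of the residual CSDA range) with a 0.1 mm floor
(0.5 mm cap for depth-dose scoring to match the 0.5 mm bins). Per step: mean
Bethe loss evaluated at the mid-step energy, Bohr straggling, removal
sampling, Highland deflection, deposition at the step midpoint. Particles are
strictly forward-peaked; a direction turning non-negative in z books the
particle as escaped (relevant only for the widest-angle secondaries).
Scorers: 3D dose grids (energy per voxel, Gy via voxel mass, optional
per-voxel statistical uncertainty from summed squared deposits), integral
depth-dose cylinders (Bragg-peak-chamber geometry: 81.6 mm diameter, 0.5 mm
bins, normalized to unit integral), and plane-crossing fluence maps for spot
profiles and halo integrals.

The inner stepping loop has two interchangeable implementations: a vectorized
numpy path and a numba-compiled per-particle kernel (the default where numba
is importable; ~20× faster). The compiled kernel draws randomness from an
internal xorshift64* stream with a 2¹⁶-entry stratified inverse-CDF table for
Gaussian deviates (tails truncated at 4σ — negligible for dose scoring, where
the explicit secondary model, not the Gaussian tail, carries the halo). Both
paths are deterministic given the transport seed; they are statistically
equivalent but not bit-identical to each other.

**Energy accounting.** Every transport run returns a ledger — deposited,
laterally escaped, escaping neutrals, exiting kinetic energy, and the
secondary-weight residual (the negative bookkeeping entry for the ×3
multiplicity) — that closes against the initial kinetic energy to machine
precision; the test suite asserts closure to 0.1%.

## Source model

Per axis, spot size σ₀, divergence σ_θ and correlation ρ₀ are referenced at
isocenter; a pure drift gives σ²(Z) = σ₀² − 2ρ₀σ₀σ_θZ + σ_θ²Z² (ρ > 0
defocusing). Sampling draws (x_iso, θ) from the isocenter covariance and
back-propagates to the source plane; scanning deflections aim the mean
direction from effective focal points at fx = 1859.1 mm / fy = 2234.8 mm. x
and y are independent (elliptical spots). The Gaussian energy spectrum has a
sigma quoted as % of the mean energy. Between commissioned energies every
parameter interpolates linearly; extrapolation outside the band is an error.

## Commissioning

- **Optics:** least-squares quadratic fit of σ²(Z) at the six standard planes
  (455, 330, 200, 100, 0, −100 mm); |ρ₀| > 1 is flagged non-physical.
- **Effective SAD:** straight-line fit x(Z) = x_iso(f − Z)/f per deflection,
  averaged; a parallel beam yields f = ∞.
- **Mean energy:** initial estimate by inverting the water range table at the
  measured R80, then a refinement loop that simulates the IDD and corrects by
  the local dE/dR slope (bisection fallback on oscillation) until
  |ΔR80| ≤ 0.1 mm; error after 20 simulations.
- **Energy spread:** grid search at 0.05 MeV resolution (default span
  0.1–1.0% of the mean) minimizing equal-weighted |Δ(peak-to-plateau ratio)|
  plus mean point-to-point |Δdose| on integral-normalized curves. The plateau
  is defined as 20–40% of the R80 depth, the peak as the maximum bin — both
  conventions are exposed in the code. Flat objectives and boundary optima
  produce warnings.
- **Protons per MU:** N_MU = D_meas/(D_MC/N_MC) with the standard reference
  field (625 spots, 100 × 100 mm², 4 mm spacing, 1 MU per spot; dose averaged
  over the central 16 × 16 mm² at 42 mm depth). The central dose of the
  superposed field is evaluated directly from the single-spot kernel's
  integral image, which is algebraically identical to full-field superposition
  for identical spots and far cheaper. 1 MU corresponds to 3 nC of monitor
  charge; that constant is carried as metadata only.

Tuning simulations default to 2×10⁵ protons (sub-0.5% statistical noise on
the quantities being matched). Per-energy failures are collected in the
commissioning report rather than aborting the run.

## Field synthesis and QA

Square fields support inclusive (side/spacing + 1)² and exclusive grids (the
625-spot reference variant). Fields are simulated by kernel reuse — one
central-axis kernel per distinct energy, superposed at spot offsets (exact
for spot grids commensurate with the dose grid) — with a direct per-spot path
available for validation. SOBP fields pick energy layers so successive
pristine R80s differ by 40% of the distal peak's FWHM (the common 80%
heuristic leaves ~18% ripple here because the fixture's Bragg peaks have
narrow cores relative to their shoulder-inclusive FWHM) and solve layer
weights by non-negative least squares for a flat modulation region; the
R120M40 build achieves ≤3% central-axis ripple and distal R80 within 1 mm.

QA metrics: field-size factors (central dose = mean over the central
10 × 10 mm²); lateral-profile penumbra (20–80%, averaged over both edges) and
95%/5% half-widths with linear interpolation; global gamma index (dose
normalized to the reference maximum, default 10% low-dose threshold, exact
local search over 2×DTA with DTA/5 subvoxel interpolation, plus a brute-force
upsampled oracle kept for tests — gamma is asymmetric under ref/eval swap and
a test documents it); cumulative DVH with D_q as the (100−q)th percentile;
and radial halo integrals normalized at 200 mm radius with the halo metric
1 − fraction(40 mm).

## The virtual machine (what the fixtures emulate)

Six commissioned energies (100, 115, 150, 180, 210, 225 MeV) with: spot
sigmas shrinking from ~6 to ~3.6 mm (and a slight re-increase at 225 MeV),
divergences from ~6 to ~3 mrad, mildly positive ρ₀ in x (focus-then-defocus)
and larger ρ₀ in y (continuously defocusing); energy spreads falling linearly
from 0.67% at 100 MeV to 0.28% at 225 MeV; protons/MU rising from 9×10⁷ to
~1.5×10⁸ in exact proportion to the inverse electronic stopping power of air
(an ideal air-filled monitor chamber); and a 65 mm Lexan range shifter
(C 75.575 / O 18.876 / H 5.549% by mass, ρ = 1.20 g/cm³, I = 73.1 eV) whose
upstream face defines the source plane. Optics at energies the published
trends do not pin down are smooth interpolants — fixture inventions, not
measurements.

Pseudo-measurements add Gaussian noise: 1% relative on spot sigmas, 0.5% on
reference doses, 0.05 mm on deflection centroids; IDD "measurements" are
engine simulations at 2×10⁵ protons, so their noise is Monte Carlo noise.

What passing the recovery suite does **not** show: the generator and the
commissioning chain share the same transport engine, so systematic engine
errors cancel in closed-loop tests. The physics itself is anchored
independently (PSTAR stopping powers and ranges, closed-form Highland/Bohr
oracles, published WET / exit-energy / attenuation values for the range
shifter); but agreement with a real machine's measured halo, detector
response, beamline-specific optics, or patient CT data is outside what this
bench can demonstrate.

## Numerical choices and degenerate inputs

- Transport cutoff 2 MeV (residual deposited locally); supported band to
  300 MeV.
- Lookup tables on a shared 1024-point log-energy grid; linear interpolation.
- Dose conversion: 1 MeV = 1.602×10⁻¹³ J; voxel mass from the local density.
- R80 and profile crossings: linear interpolation between samples; R80
  requires an interior maximum and scans distally from the peak.
- Degenerate optics fits (fewer than three distinct planes, non-positive
  fitted variances) raise; near-singular sampling covariances use an
  eigenvalue-clipped decomposition so zero-variance test configurations work.
- NNLS weight solves normalize to the maximum layer weight; layers below
  10⁻⁶ relative weight are dropped.

## Problem sizes

Defaults are chosen so the statistical noise sits well below each assertion's
tolerance at desk scale: 2×10⁵ protons for IDD/commissioning work (<0.5%
noise), 10⁶ for the FSF halo kernels and the range-shifter attenuation, and
the 0.5 mm IDD / 1 mm dose-grid resolutions of standard QA practice.

## Known limitations

- No neutron/photon/electron transport: their energy is an explicit sink
  (escaping-neutrals ledger entry), so secondary-species inventories are out
  of scope.
- One effective secondary proton per removal event with calibrated weight:
  halo *dose* is reproduced at FSF level, but the in-air halo far from the
  axis after a range shifter is under-represented (the wide-angle part of the
  real spectrum is truncated), so air-gap halo fractions reproduce trends,
  not magnitudes.
- Highland with per-step application, not Molière theory: no single-scatter
  tail beyond what the removal model absorbs.
- No magnetic-field or divergence-dependent nozzle modeling beyond the
  effective focal points; gantry/couch angles are carried in the plan model
  but fields are simulated in the gantry frame.
- HU conversion uses a compact five-tissue segmentation with a continuous
  density calibration; it reproduces a target HU–RSP curve by construction,
  not the full Schneider stoichiometric tissue set.
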