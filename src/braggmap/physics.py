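"""1D proton transport through layered attenuators and 2D scanned-field dose.

The transport model is deliberately simple: a Bragg–Kleeman range–energy power
law ``R = a E^p`` in water, water-equivalent scaling for every other material,
and a Gaussian residual-range distribution (beam energy spread mapped through
``dR/dE`` combined in quadrature with intrinsic range straggling).  Depth dose
is the fluence-averaged stopping power of the surviving spectrum; dose-averaged
LET is the dose-weighted mean stopping power.  Nuclear interactions, lateral
scattering and secondary particles are out of scope: the model exists to place
the columns of a 96-well plate along a pristine Bragg curve, and the free
parameters (effective energy, energy spread) are calibrated to the measured
beam range and peak-to-entrance dose ratio rather than predicted.

Units: energies in MeV, macroscopic lengths in cm, LET and stopping power in
keV/µm (1 MeV/cm = 0.1 keV/µm), doses in cGy at the machine-calibration
boundary and Gy elsewhere.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import InvalidInputError, UnreachableTargetError

MEV_PER_CM_TO_KEV_PER_UM = 0.1

# Bragg-Kleeman constants for water in the therapeutic range.
WATER_RANGE_COEFF_A = 0.0022  # cm / MeV^p
WATER_RANGE_EXP_P = 1.77

#: Measured beam range of the reference 79.7 MeV spot-scanning beam.
REFERENCE_RANGE_WATER_CM = 4.8
REFERENCE_RANGE_LUCITE_CM = 4.1


# ---------------------------------------------------------------------------
# Materials and geometry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Material:
    """A homogeneous attenuator described by water-equivalent scaling.

    ``water_equivalent_ratio`` is cm of water per cm of material; the
    range–energy law in the material is the water law divided by this ratio.
    """

    name: str
    density: float  # g/cm^3
    water_equivalent_ratio: float
    range_coeff_a: float = field(default=0.0)  # cm * MeV^-p, derived if 0
    range_exp_p: float = WATER_RANGE_EXP_P

    def __post_init__(self):
        if self.density <= 0:
            raise InvalidInputError(f"density must be positive, got {self.density}")
        if self.water_equivalent_ratio <= 0:
            raise InvalidInputError("water_equivalent_ratio must be positive")
        if not 1.0 < self.range_exp_p < 2.0:
            raise InvalidInputError("range exponent p must lie in (1, 2)")
        if self.range_coeff_a == 0.0:
            object.__setattr__(
                self, "range_coeff_a",
                WATER_RANGE_COEFF_A / self.water_equivalent_ratio,
            )
        if self.range_coeff_a <= 0:
            raise InvalidInputError("range coefficient a must be positive")


WATER = Material("water", density=1.0, water_equivalent_ratio=1.0)

#: Lucite (PMMA): the jig material.  The water-equivalent ratio is fixed by the
#: measured beam ranges, 4.8 cm water vs 4.1 cm Lucite.
LUCITE = Material(
    "lucite",
    density=1.19,
    water_equivalent_ratio=REFERENCE_RANGE_WATER_CM / REFERENCE_RANGE_LUCITE_CM,
)

#: 96-well plate bottom (polystyrene).  Assumed to share Lucite's mass
#: stopping-power ratio; only the WET matters for column placement.
POLYSTYRENE = Material(
    "polystyrene",
    density=1.09,
    water_equivalent_ratio=1.09 * (LUCITE.water_equivalent_ratio / LUCITE.density),
)

#: Radiochromic film treated as a Lucite-equivalent slab of printed thickness.
FILM_MATERIAL = Material(
    "film (lucite-equivalent)",
    density=1.19,
    water_equivalent_ratio=LUCITE.water_equivalent_ratio,
)

FILM_THICKNESS_CM = 268e-4  # 268 um per film
DEFAULT_CELL_LAYER_UM = 5.0
DEFAULT_PLATE_BOTTOM_CM = 0.1  # not printed; 1 mm config default


@dataclass(frozen=True)
class Slab:
    material: Material
    thickness: float  # cm

    def __post_init__(self):
        if self.thickness < 0:
            raise InvalidInputError("slab thickness must be non-negative")

    @property
    def wet(self) -> float:
        return self.thickness * self.material.water_equivalent_ratio


@dataclass(frozen=True)
class BeamSpec:
    """Scanned monoenergetic proton beam with its machine calibration.

    ``effective_energy`` is calibrated so that the modelled range equals the
    measured beam range (the nominal energy includes upstream material the
    model does not track); ``energy_spread_sigma`` is calibrated so the
    peak-to-entrance column dose ratio matches measurement.
    """

    nominal_energy: float = 79.7  # MeV
    effective_energy: float | None = None  # MeV, range-calibrated if None
    energy_spread_sigma: float = 0.677  # MeV, calibrated (see docs/methods.md)
    spot_fwhm: float = 3.3  # cm
    spot_spacing: float = 1.0  # cm
    dose_per_painting_col1: float = 2.6  # cGy
    mu_per_painting: float = 17.64
    straggling_fraction: float = 0.0085  # sigma_R(intrinsic) = f * R0^0.935

    def __post_init__(self):
        if self.effective_energy is None:
            e_eff = energy_from_residual_range(REFERENCE_RANGE_WATER_CM, WATER)
            object.__setattr__(self, "effective_energy", min(e_eff, self.nominal_energy))
        for name in ("nominal_energy", "effective_energy", "spot_fwhm",
                     "spot_spacing", "dose_per_painting_col1", "mu_per_painting"):
            if getattr(self, name) <= 0:
                raise InvalidInputError(f"{name} must be positive")
        if self.energy_spread_sigma < 0 or self.straggling_fraction < 0:
            raise InvalidInputError("spread parameters must be non-negative")
        if self.effective_energy > self.nominal_energy + 1e-9:
            raise InvalidInputError("effective_energy cannot exceed nominal_energy")

    @property
    def range_water(self) -> float:
        """Modelled range in water of the calibrated beam, cm."""
        return range_from_energy(self.effective_energy, WATER)

    @property
    def range_sigma(self) -> float:
        """Total 1-sigma spread of the range distribution in water, cm."""
        e = self.effective_energy
        drde = (WATER_RANGE_COEFF_A * WATER_RANGE_EXP_P
                * e ** (WATER_RANGE_EXP_P - 1.0))
        sigma_beam = drde * self.energy_spread_sigma
        sigma_strag = self.straggling_fraction * self.range_water ** 0.935
        return math.hypot(sigma_beam, sigma_strag)


@dataclass(frozen=True)
class JigGeometry:
    """Ordered attenuator stacks for the 12 columns of a 96-well plate.

    Each column's stack is the Lucite step, the inserted films, and the plate
    bottom; the scored cell layer sits immediately downstream.
    """

    step_thicknesses: tuple[float, ...]  # cm of Lucite, one per column
    n_films: int = 3
    film_thickness: float = FILM_THICKNESS_CM
    plate_bottom_thickness: float = DEFAULT_PLATE_BOTTOM_CM
    cell_layer_um: float = DEFAULT_CELL_LAYER_UM
    step_material: Material = LUCITE
    film_material: Material = FILM_MATERIAL
    plate_material: Material = POLYSTYRENE

    def __post_init__(self):
        if len(self.step_thicknesses) != 12:
            raise InvalidInputError("a jig has exactly 12 columns")
        steps = self.step_thicknesses
        if any(t < 0 for t in steps):
            raise InvalidInputError("step thicknesses must be non-negative")
        if any(b < a - 1e-12 for a, b in zip(steps, steps[1:])):
            raise InvalidInputError("step thickness must be non-decreasing with column")
        if self.cell_layer_um <= 0:
            raise InvalidInputError("cell layer thickness must be positive")

    def column_stack(self, column: int) -> list[Slab]:
        """Attenuator stack for a 1-based column index."""
        if not 1 <= column <= 12:
            raise InvalidInputError("column index must be 1..12")
        stack = [Slab(self.step_material, self.step_thicknesses[column - 1])]
        stack += [Slab(self.film_material, self.film_thickness)] * self.n_films
        stack.append(Slab(self.plate_material, self.plate_bottom_thickness))
        return stack

    def cell_depth_water(self, column: int) -> float:
        """Water-equivalent depth of the middle of the cell layer, cm."""
        base = water_equivalent_thickness(self.column_stack(column))
        return base + 0.5 * self.cell_layer_um * 1e-4  # cells ~ water


@dataclass(frozen=True)
class DepthProfile:
    depths: np.ndarray  # cm
    dose: np.ndarray  # relative
    let_d: np.ndarray  # keV/um

    @property
    def peak_depth(self) -> float:
        return float(self.depths[int(np.argmax(self.dose))])

    @property
    def peak_to_entrance(self) -> float:
        return float(np.max(self.dose) / self.dose[0])


@dataclass(frozen=True)
class ColumnCondition:
    column: int  # 1-based
    step_thickness: float  # cm
    dose_relative: float  # column 1 == 1
    dose_per_painting: float  # cGy
    let_d: float  # keV/um
    beyond_range: bool = False
    dose_uncertainty: float = 0.0  # same units as dose_per_painting
    let_uncertainty: float = 0.0  # keV/um


# ---------------------------------------------------------------------------
# Range-energy relations
# ---------------------------------------------------------------------------

def range_from_energy(energy: float, material: Material = WATER) -> float:
    """CSDA-style range ``R = a E^p`` in the material, cm."""
    if energy < 0:
        raise InvalidInputError(f"energy must be non-negative, got {energy}")
    return material.range_coeff_a * energy ** material.range_exp_p


def energy_from_residual_range(residual: float, material: Material = WATER) -> float:
    """Inverse of :func:`range_from_energy`: ``E = (R/a)^(1/p)``, MeV."""
    if residual < 0:
        raise InvalidInputError(f"residual range must be non-negative, got {residual}")
    return (residual / material.range_coeff_a) ** (1.0 / material.range_exp_p)


def stopping_power(energy: float, material: Material = WATER) -> float:
    """Unrestricted stopping power dE/dx in keV/µm.

    Differentiating R = a E^p gives S = E^(1-p) / (a p); this equals the
    track-averaged LET of a monoenergetic beam.
    """
    if energy <= 0:
        raise InvalidInputError("energy must be positive for stopping power")
    s_mev_cm = energy ** (1.0 - material.range_exp_p) / (
        material.range_coeff_a * material.range_exp_p)
    return s_mev_cm * MEV_PER_CM_TO_KEV_PER_UM


def water_equivalent_thickness(stack: list[Slab]) -> float:
    """Additive water-equivalent thickness of a slab stack, cm of water."""
    return float(sum(s.wet for s in stack))


# ---------------------------------------------------------------------------
# Bragg curve
# ---------------------------------------------------------------------------

_N_SINGULAR = 1500  # nodes resolving the S ~ r^((1-p)/p) track-end singularity
_N_BULK = 800  # nodes resolving the Gaussian range distribution


def _stopping_power_of_residual(r: np.ndarray) -> np.ndarray:
    """S(E(r)) in keV/µm for residual water range r > 0 (vectorised)."""
    energy = (r / WATER_RANGE_COEFF_A) ** (1.0 / WATER_RANGE_EXP_P)
    s = energy ** (1.0 - WATER_RANGE_EXP_P) / (WATER_RANGE_COEFF_A * WATER_RANGE_EXP_P)
    return s * MEV_PER_CM_TO_KEV_PER_UM


def _dose_let_at_depth(z, r0: float, sigma: float):
    """Dose (relative) and dose-averaged LET at water depth z.

    The total range R of an incident proton is Normal(r0, sigma); protons with
    R > z survive to depth z with residual range r = R - z and local stopping
    power S(E(r)).  Dose is the fluence-weighted mean of S (stopped protons
    contribute zero), LET_d the dose-weighted mean.  The quadrature is a
    composite trapezoid over the union of a power-stretched grid (r = rmax·t^5,
    resolving the integrable S ~ r^-0.435 singularity at track ends) and a
    uniform grid across ±8 sigma of the Gaussian bulk.
    """
    z = np.atleast_1d(np.asarray(z, dtype=float))
    sigma = max(sigma, 1e-6)
    t5 = np.linspace(0.0, 1.0, _N_SINGULAR) ** 5
    bulk = np.linspace(-8.0, 8.0, _N_BULK)
    dose = np.zeros_like(z)
    second = np.zeros_like(z)
    for i, zi in enumerate(z):
        rmax = r0 + 8.0 * sigma - zi
        if rmax <= 0:
            continue
        r = rmax * t5
        r_bulk = (r0 - zi) + sigma * bulk
        r = np.union1d(r, r_bulk[(r_bulk > 0) & (r_bulk < rmax)])
        s = np.zeros_like(r)
        s[r > 0] = _stopping_power_of_residual(r[r > 0])
        w = np.exp(-0.5 * ((r + zi - r0) / sigma) ** 2) / (sigma * math.sqrt(2 * math.pi))
        dose[i] = np.trapezoid(w * s, r)
        second[i] = np.trapezoid(w * s * s, r)
    with np.errstate(invalid="ignore", divide="ignore"):
        let_d = np.where(dose > 0, second / np.where(dose > 0, dose, 1.0), 0.0)
    return dose, let_d


def bragg_depth_dose(beam: BeamSpec, material: Material = WATER,
                     depth_grid: np.ndarray | None = None) -> DepthProfile:
    """Pristine Bragg curve (relative dose and LET_d) on a depth grid.

    Depths are in the given material; internally they are converted to water
    equivalent.  The default grid uses 100 µm steps, refined to 10 µm within
    ±5 mm of the peak.
    """
    r0 = beam.range_water
    sigma = beam.range_sigma
    wer = material.water_equivalent_ratio
    if depth_grid is None:
        r0_mat = r0 / wer
        coarse = np.arange(0.0, r0_mat + 0.8, 0.01)
        fine = np.arange(max(r0_mat - 0.5, 0.0), min(r0_mat + 0.5, coarse[-1]), 0.001)
        depth_grid = np.unique(np.concatenate([coarse, fine]))
    else:
        depth_grid = np.asarray(depth_grid, dtype=float)
        if depth_grid.ndim != 1 or np.any(np.diff(depth_grid) <= 0):
            raise InvalidInputError("depth grid must be 1D strictly increasing")
    dose, let_d = _dose_let_at_depth(depth_grid * wer, r0, sigma)
    return DepthProfile(depths=depth_grid, dose=dose, let_d=let_d)


def column_conditions(beam: BeamSpec, jig: JigGeometry) -> list[ColumnCondition]:
    """Predicted dose and LET_d in the cell layer of each plate column.

    Doses are normalised to column 1 and anchored in cGy per painting by the
    machine calibration; columns whose stack exceeds the beam range by more
    than 5 sigma are flagged beyond range with zero dose.
    """
    r0, sigma = beam.range_water, beam.range_sigma
    depths = np.array([jig.cell_depth_water(c) for c in range(1, 13)])
    dose, let_d = _dose_let_at_depth(depths, r0, sigma)
    if dose[0] <= 0:
        raise InvalidInputError("column 1 receives no dose; beam range too short")
    rel = dose / dose[0]
    out = []
    for i in range(12):
        beyond = depths[i] > r0 + 5.0 * sigma or dose[i] <= 0
        out.append(ColumnCondition(
            column=i + 1,
            step_thickness=jig.step_thicknesses[i],
            dose_relative=0.0 if beyond else float(rel[i]),
            dose_per_painting=0.0 if beyond else float(rel[i] * beam.dose_per_painting_col1),
            let_d=0.0 if beyond else float(let_d[i]),
            beyond_range=beyond,
        ))
    return out


# ---------------------------------------------------------------------------
# Jig design
# ---------------------------------------------------------------------------

#: Dose-averaged LET values of the 12 plate columns (keV/µm), entrance to
#: distal falloff, used as design targets for the default geometry.  The
#: physical step thicknesses were never published; the shipped default jig is
#: reverse-engineered so its columns reproduce these LET values.
DEFAULT_COLUMN_LETS = (0.9, 1.2, 1.6, 1.8, 1.9, 2.3, 3.0, 5.1,
                       10.8, 15.2, 17.7, 19.0)


def dose_peak_depth(beam: BeamSpec) -> float:
    """Water depth of the Bragg peak (maximum of the depth-dose curve), cm."""
    from scipy.optimize import minimize_scalar
    r0, sigma = beam.range_water, beam.range_sigma
    res = minimize_scalar(
        lambda zz: -_dose_let_at_depth(zz, r0, sigma)[0][0],
        bounds=(max(r0 - 6 * sigma, 0.0), r0 + 2 * sigma), method="bounded",
        options={"xatol": 1e-5})
    return float(res.x)


def _depth_for_let(target_let: float, beam: BeamSpec, z_max: float) -> float:
    """Invert the monotone LET_d(z) curve by bisection."""
    lo, hi = 0.0, z_max
    let_lo = _dose_let_at_depth(lo, beam.range_water, beam.range_sigma)[1][0]
    let_hi = _dose_let_at_depth(hi, beam.range_water, beam.range_sigma)[1][0]
    if target_let <= let_lo:
        return 0.0
    if target_let > let_hi:
        raise UnreachableTargetError(
            f"LET_d {target_let} keV/um not reachable (max {let_hi:.1f} at {z_max} cm)")
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if _dose_let_at_depth(mid, beam.range_water, beam.range_sigma)[1][0] < target_let:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def design_jig_steps(beam: BeamSpec, targets: list[float], kind: str = "let",
                     template: JigGeometry | None = None) -> JigGeometry:
    """Choose step thicknesses placing each column's cell layer at its target.

    ``targets`` are either water-equivalent depths (cm, ``kind='depth'``) or
    dose-averaged LET values (keV/µm, ``kind='let'``), sorted increasing, at
    most 12; with fewer than 12 the remaining steps repeat the last thickness.
    Targets shallower than the film+plate baseline clamp the step to zero.
    """
    if len(targets) == 0 or len(targets) > 12:
        raise InvalidInputError("need 1..12 design targets")
    if any(b < a for a, b in zip(targets, targets[1:])):
        raise InvalidInputError("targets must be sorted increasing")
    tmpl = template or JigGeometry(step_thicknesses=(0.0,) * 12)
    base_wet = (tmpl.n_films * tmpl.film_thickness * tmpl.film_material.water_equivalent_ratio
                + tmpl.plate_bottom_thickness * tmpl.plate_material.water_equivalent_ratio
                + 0.5 * tmpl.cell_layer_um * 1e-4)
    z_max = beam.range_water + 4.0 * beam.range_sigma
    if kind == "depth":
        depths = [float(t) for t in targets]
        if depths[-1] > z_max:
            raise UnreachableTargetError(
                f"target depth {depths[-1]} cm beyond beam range {z_max:.2f} cm")
    elif kind == "let":
        depths = [_depth_for_let(t, beam, z_max) for t in targets]
    else:
        raise InvalidInputError("kind must be 'let' or 'depth'")
    wer = tmpl.step_material.water_equivalent_ratio
    steps = [max(0.0, (z - base_wet) / wer) for z in depths]
    steps = steps + [steps[-1]] * (12 - len(steps))
    # enforce monotone non-decreasing against numerical jitter
    for i in range(1, 12):
        steps[i] = max(steps[i], steps[i - 1])
    return replace(tmpl, step_thicknesses=tuple(steps))


def default_jig(beam: BeamSpec | None = None) -> JigGeometry:
    """The packaged 12-step geometry, reverse-engineered from the published
    per-column LET values (see :data:`DEFAULT_COLUMN_LETS`).

    The exact fabricated step thicknesses were never published, so the default
    follows the documented design procedure: columns 1-8 sample the entrance
    plateau and proximal rise at the published LET values, column 9 sits
    exactly at the Bragg peak (the role of the three inserted films), and
    columns 10-12 sample the high-gradient distal falloff at the published
    LET values.
    """
    beam = beam or BeamSpec()
    z_max = beam.range_water + 4.0 * beam.range_sigma
    z_peak = dose_peak_depth(beam)
    depths = [_depth_for_let(t, beam, z_max) for t in DEFAULT_COLUMN_LETS[:8]]
    depths.append(z_peak)
    for t in DEFAULT_COLUMN_LETS[9:]:
        depths.append(max(_depth_for_let(t, beam, z_max), depths[-1] + 1e-4))
    return design_jig_steps(beam, depths, kind="depth")


# ---------------------------------------------------------------------------
# Scan field and dose delivery
# ---------------------------------------------------------------------------

def scan_field_dose(x, y, beam: BeamSpec, grid_half_count: int = 10):
    """Relative dose at (x, y) from a square scanned-spot grid.

    Spots are Gaussians of the beam's FWHM on a (2n+1)^2 grid at the spot
    spacing, centred on the origin; n=10 gives the 441-spot 20x20 cm field.
    """
    if grid_half_count < 0:
        raise InvalidInputError("grid_half_count must be >= 0")
    x = np.atleast_1d(np.asarray(x, dtype=float))
    y = np.atleast_1d(np.asarray(y, dtype=float))
    sigma = beam.spot_fwhm / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    centres = beam.spot_spacing * np.arange(-grid_half_count, grid_half_count + 1)
    gx = np.exp(-0.5 * ((x[..., None] - centres) / sigma) ** 2).sum(axis=-1)
    gy = np.exp(-0.5 * ((y[..., None] - centres) / sigma) ** 2).sum(axis=-1)
    out = gx * gy
    return out if out.size > 1 else float(out[0])


def paintings_for_dose(target_dose_gy: float, beam: BeamSpec) -> tuple[int, float]:
    """Nearest-integer repainting count for a column-1 dose and the exact
    dose it delivers (Gy).  Relative column doses are unaffected."""
    if target_dose_gy < 0:
        raise InvalidInputError("target dose must be non-negative")
    per_painting_gy = beam.dose_per_painting_col1 / 100.0
    n = int(round(target_dose_gy / per_painting_gy))
    return n, n * per_painting_gy
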