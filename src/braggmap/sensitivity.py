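"""Setup-uncertainty sensitivity analysis.

The attenuating components upstream of the cell layer (jig step, films, plate
bottom) carry thickness and density tolerances.  Following the deterministic
three-setup scheme, tolerances are stacked coherently toward a shorter
(``low``) or longer (``high``) water-equivalent path, transport is evaluated
for each setup, and the per-column uncertainty is the average absolute
deviation of the low and high results from the nominal — these are the error
bars on the per-column dose and LET.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import InvalidInputError
from .physics import BeamSpec, ColumnCondition, JigGeometry, Material, column_conditions


@dataclass(frozen=True)
class SetupTolerances:
    """Component tolerances; defaults reconstruct plausible fabrication specs
    (jig milled to ±3 µm; vendor film tolerance ~1%; moulded plate bottom
    ±50 µm; densities ±0.5%) and are explicit config, not published values."""

    step_thickness_cm: float = 3e-4  # +-3 um milling accuracy
    film_thickness_rel: float = 0.01
    plate_bottom_cm: float = 5e-3  # +-50 um
    density_rel: float = 0.005
    classification: str = "systematic"

    def __post_init__(self):
        for name in ("step_thickness_cm", "film_thickness_rel",
                     "plate_bottom_cm", "density_rel"):
            if getattr(self, name) < 0:
                raise InvalidInputError(f"{name} must be non-negative")


def _scaled_material(mat: Material, factor: float) -> Material:
    """Material with density (and hence WET per cm) scaled by ``factor``."""
    return Material(mat.name, density=mat.density * factor,
                    water_equivalent_ratio=mat.water_equivalent_ratio * factor,
                    range_exp_p=mat.range_exp_p)


def perturb_setup(beam: BeamSpec, jig: JigGeometry, tol: SetupTolerances
                  ) -> dict[str, tuple[BeamSpec, JigGeometry]]:
    """Nominal, low and high setups with tolerances stacked coherently.

    ``low`` applies every tolerance toward a shorter water-equivalent stack
    (thinner, less dense components), ``high`` toward a longer one.
    """
    setups = {"nominal": (beam, jig)}
    for key, sign in (("low", -1.0), ("high", +1.0)):
        dens = 1.0 + sign * tol.density_rel
        steps = tuple(max(0.0, t + sign * tol.step_thickness_cm)
                      for t in jig.step_thicknesses)
        # clamping at zero can break monotonicity only at identical steps
        steps = tuple(np.maximum.accumulate(steps))
        perturbed = replace(
            jig,
            step_thicknesses=steps,
            film_thickness=jig.film_thickness * (1.0 + sign * tol.film_thickness_rel),
            plate_bottom_thickness=max(
                0.0, jig.plate_bottom_thickness + sign * tol.plate_bottom_cm),
            step_material=_scaled_material(jig.step_material, dens),
            film_material=_scaled_material(jig.film_material, dens),
            plate_material=_scaled_material(jig.plate_material, dens),
        )
        setups[key] = (beam, perturbed)
    return setups


def propagate_uncertainty(setups: dict[str, tuple[BeamSpec, JigGeometry]]
                          ) -> list[ColumnCondition]:
    """Evaluate transport for the three setups and attach per-column error
    bars: uncertainty = mean(|low − nominal|, |high − nominal|)."""
    for key in ("nominal", "low", "high"):
        if key not in setups:
            raise InvalidInputError(f"missing setup '{key}'")
    results = {key: column_conditions(*setups[key]) for key in ("nominal", "low", "high")}
    out = []
    for nom, low, high in zip(results["nominal"], results["low"], results["high"]):
        dose_unc = 0.5 * (abs(low.dose_per_painting - nom.dose_per_painting)
                          + abs(high.dose_per_painting - nom.dose_per_painting))
        let_unc = 0.5 * (abs(low.let_d - nom.let_d) + abs(high.let_d - nom.let_d))
        out.append(replace(nom, dose_uncertainty=dose_unc, let_uncertainty=let_unc))
    return out


def column_conditions_with_uncertainty(beam: BeamSpec, jig: JigGeometry,
                                       tol: SetupTolerances | None = None
                                       ) -> list[ColumnCondition]:
    """Convenience wrapper: perturb, transport, and attach error bars."""
    return propagate_uncertainty(perturb_setup(beam, jig, tol or SetupTolerances()))
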