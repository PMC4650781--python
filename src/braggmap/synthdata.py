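"""Synthetic data generators for every input the pipeline consumes.

Three generators mirror the three experimental data streams:

* 96-well plates of colony counts under linear-quadratic survival with
  Poisson counting noise (the wet-lab clonogenic assay),
* event streams of (ε, l) track steps with a configurable ε/l spectrum
  (the Monte Carlo scoring stream), and
* per-nucleus γH2AX focus counts (Poisson, dose × LET-dependent yield).

Defaults reproduce the published study conditions: 100 cells seeded per well,
two plates per dose level (16 replicate wells per dose–LET condition), and
the published α/β radiosensitivity parameters of the H460 and H1437 NSCLC
lines as ground truth.  All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .clonogenics import PlateCounts
from .errors import InvalidInputError
from .letscore import TrackStep
from .physics import ColumnCondition

#: Published LQ radiosensitivity parameters (α Gy⁻¹, β Gy⁻²) per column LET
#: (keV/µm) for the two NSCLC lines, used as generator ground truth.
H460_LQ_PARAMS: dict[float, tuple[float, float]] = {
    0.9: (0.268, 0.097), 1.2: (0.226, 0.112), 1.6: (0.151, 0.134),
    1.8: (0.150, 0.134), 1.9: (0.166, 0.134), 2.3: (0.137, 0.146),
    3.0: (0.206, 0.125), 5.1: (0.117, 0.159), 10.8: (0.318, 0.154),
    15.2: (0.446, 0.341), 17.7: (0.596, 0.662), 19.0: (0.883, 0.956),
}
H1437_LQ_PARAMS: dict[float, tuple[float, float]] = {
    0.9: (0.077, 0.028), 1.2: (0.136, 0.020), 1.6: (0.067, 0.027),
    1.8: (0.059, 0.038), 1.9: (0.094, 0.031), 2.3: (0.096, 0.032),
    3.0: (0.111, 0.033), 5.1: (0.034, 0.052), 10.8: (0.119, 0.054),
    15.2: (0.180, 0.095), 17.7: (0.328, 0.149), 19.0: (0.360, 0.272),
}
H460_PHOTON_PARAMS: tuple[float, float] = (0.290, 0.083)
H1437_PHOTON_PARAMS: tuple[float, float] = (0.050, 0.041)

#: γH2AX foci-per-nucleus calibration anchors: (LET keV/µm, dose Gy, mean
#: foci); yields per Gy are interpolated between these.
FOCI_ANCHORS = ((4.6, 2.9, 3.57), (17.3, 1.7, 7.02))


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# Clonogenic plates
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExperimentDesign:
    """Ground truth and layout of a simulated clonogenic experiment."""

    cell_line_params: dict[float, tuple[float, float]] = field(
        default_factory=lambda: dict(H460_LQ_PARAMS))
    photon_params: tuple[float, float] = H460_PHOTON_PARAMS
    seeded_per_well: int = 100
    plating_efficiency: float = 0.8
    # column-1 doses, Gy; the low levels keep >=3 dose levels above the
    # detection limit in the distal columns, which receive ~5x the entrance dose
    dose_levels: tuple[float, ...] = (0.0, 0.1, 0.2, 0.5, 1.0, 2.0, 4.0, 6.0)
    plates_per_dose: int = 2
    seeding_noise_cv: float = 0.0  # optional log-normal plate seeding error
    random_seed: int = 0

    def __post_init__(self):
        if self.plates_per_dose < 1:
            raise InvalidInputError("plates_per_dose must be >= 1")
        if not 0.0 < self.plating_efficiency <= 1.0:
            raise InvalidInputError("plating efficiency must lie in (0, 1]")
        if self.seeded_per_well <= 0:
            raise InvalidInputError("seeded_per_well must be positive")

    def params_for_let(self, let_d: float) -> tuple[float, float]:
        """Ground-truth (α, β) for a column LET via nearest-key lookup."""
        key = min(self.cell_line_params, key=lambda k: abs(k - let_d))
        return self.cell_line_params[key]


def simulate_plate(design: ExperimentDesign, conditions: list[ColumnCondition],
                   paintings: int, rng=None, plate_id: str = "sim",
                   replicate_id: int = 1) -> PlateCounts:
    """One 96-well plate of Poisson colony counts.

    Column c receives dose D_c = paintings × (cGy per painting)/100; each well
    count is Poisson(seeded · PE · exp(−α_c D_c − β_c D_c²)).  An optional
    log-normal multiplier on the plate's effective seeding density models the
    counting error of the stock cell solution (off by default).
    """
    if len(conditions) != 12:
        raise InvalidInputError("need 12 column conditions")
    rng = _rng(rng if rng is not None else design.random_seed)
    seeded_eff = design.seeded_per_well
    if design.seeding_noise_cv > 0:
        sigma = math.sqrt(math.log(1.0 + design.seeding_noise_cv ** 2))
        seeded_eff = seeded_eff * rng.lognormal(-0.5 * sigma ** 2, sigma)
    counts = np.zeros((8, 12), dtype=int)
    cond_map = {}
    for j, cond in enumerate(conditions):
        dose = paintings * cond.dose_per_painting / 100.0  # Gy
        alpha, beta = design.params_for_let(cond.let_d)
        sf = math.exp(-alpha * dose - beta * dose * dose)
        mean = seeded_eff * design.plating_efficiency * sf
        counts[:, j] = rng.poisson(mean, size=8)
        cond_map[j + 1] = (dose, cond.let_d)
    return PlateCounts(counts=counts, conditions=cond_map,
                       seeded_per_well=design.seeded_per_well,
                       plate_id=plate_id, replicate_id=replicate_id)


def simulate_experiment(design: ExperimentDesign,
                        conditions: list[ColumnCondition],
                        rng=None) -> list[PlateCounts]:
    """Plates for every dose level: ``plates_per_dose`` replicates each, with
    painting counts rounded from the column-1 dose levels."""
    rng = _rng(rng if rng is not None else design.random_seed)
    per_painting = conditions[0].dose_per_painting  # cGy at column 1
    plates = []
    for dose in design.dose_levels:
        n_paint = int(round(dose / (per_painting / 100.0)))
        for rep in range(design.plates_per_dose):
            plates.append(simulate_plate(
                design, conditions, n_paint, rng=rng,
                plate_id=f"dose{dose:g}Gy", replicate_id=rep + 1))
    return plates


def parameter_recovery(design: ExperimentDesign,
                       conditions: list[ColumnCondition],
                       n_experiments: int = 200, rng=None):
    """Repeated generate→analyse experiments for fit validation.

    Each experiment simulates the full plate set, recomputes the plating
    efficiency from its control plates, LOD-filters, and fits every LET
    condition; returns a DataFrame with one row per (experiment, condition)
    carrying the ground truth, the estimates and their standard errors, and
    whether each parameter lies within 2 SE of truth.
    """
    import pandas as pd
    from .clonogenics import (fit_lq, lod_filter, per_well_survival,
                              plating_efficiency)
    from .errors import FitFailureError, InsufficientDataError
    rng = _rng(rng if rng is not None else design.random_seed)
    rows = []
    for exp in range(n_experiments):
        plates = simulate_experiment(design, conditions, rng)
        controls = np.concatenate(
            [p.counts.ravel() for p in plates
             if max(d for d, _ in p.conditions.values()) == 0.0])
        pe, _ = plating_efficiency(controls, design.seeded_per_well)
        wells = per_well_survival(plates, pe)
        for let in sorted({p.let_d for p in wells}):
            alpha, beta = design.params_for_let(let)
            pts = lod_filter([p for p in wells if p.let_d == let],
                             design.seeded_per_well, pe)
            try:
                fit = fit_lq(pts)
            except (FitFailureError, InsufficientDataError):
                rows.append({"experiment": exp, "let": let, "alpha_true": alpha,
                             "beta_true": beta, "fitted": False,
                             "alpha_hat": np.nan, "beta_hat": np.nan,
                             "se_alpha": np.nan, "se_beta": np.nan,
                             "alpha_covered": False, "beta_covered": False})
                continue
            rows.append({
                "experiment": exp, "let": let,
                "alpha_true": alpha, "beta_true": beta, "fitted": True,
                "alpha_hat": fit.alpha, "beta_hat": fit.beta,
                "se_alpha": fit.se_alpha, "se_beta": fit.se_beta,
                "alpha_covered": abs(fit.alpha - alpha) <= 2 * fit.se_alpha,
                "beta_covered": abs(fit.beta - beta) <= 2 * fit.se_beta,
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Track-step event streams
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrackSpectrum:
    """Dose-weighted ε/l spectrum of a scoring layer.

    ``kind`` is one of ``delta`` (params: value), ``uniform`` (low, high),
    ``lognormal`` (median, sigma_log, optional low/high truncation) or
    ``mixture`` (components: list of (weight, TrackSpectrum)).  The spectrum
    describes the distribution of ε/l weighted by energy deposition — the
    quantity whose mean is LET_d.
    """

    kind: str
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        kinds = {"delta", "uniform", "lognormal", "mixture"}
        if self.kind not in kinds:
            raise InvalidInputError(f"kind must be one of {sorted(kinds)}")
        p = self.params
        if self.kind == "delta" and p.get("value", 0) <= 0:
            raise InvalidInputError("delta spectrum needs a positive 'value'")
        if self.kind == "uniform":
            if not 0 < p.get("low", 0) < p.get("high", 0):
                raise InvalidInputError("uniform spectrum needs 0 < low < high")
        if self.kind == "lognormal":
            if p.get("median", 0) <= 0 or p.get("sigma_log", 0) <= 0:
                raise InvalidInputError("lognormal needs positive median, sigma_log")
        if self.kind == "mixture":
            comps = p.get("components", [])
            if not comps or any(w < 0 for w, _ in comps):
                raise InvalidInputError("mixture needs non-negative weights")

    def sample(self, n: int, rng) -> np.ndarray:
        rng = _rng(rng)
        if self.kind == "delta":
            return np.full(n, float(self.params["value"]))
        if self.kind == "uniform":
            return rng.uniform(self.params["low"], self.params["high"], n)
        if self.kind == "lognormal":
            mu = math.log(self.params["median"])
            vals = rng.lognormal(mu, self.params["sigma_log"], n)
            lo = self.params.get("low", 0.0)
            hi = self.params.get("high", np.inf)
            bad = (vals < lo) | (vals > hi)
            while bad.any():  # resample the truncated tail
                vals[bad] = rng.lognormal(mu, self.params["sigma_log"], bad.sum())
                bad = (vals < lo) | (vals > hi)
            return vals
        comps = self.params["components"]
        weights = np.array([w for w, _ in comps], dtype=float)
        weights = weights / weights.sum()
        choice = rng.choice(len(comps), size=n, p=weights)
        out = np.empty(n)
        for i, (_, spec) in enumerate(comps):
            mask = choice == i
            out[mask] = spec.sample(int(mask.sum()), rng)
        return out

    def mean(self, n_quad: int = 200001) -> float:
        """Dose-weighted mean ε/l (the LET_d the spectrum encodes)."""
        if self.kind == "delta":
            return float(self.params["value"])
        if self.kind == "uniform":
            return 0.5 * (self.params["low"] + self.params["high"])
        if self.kind == "lognormal":
            mu, s = math.log(self.params["median"]), self.params["sigma_log"]
            lo = self.params.get("low", 0.0)
            hi = self.params.get("high", None)
            if lo <= 0 and hi is None:
                return math.exp(mu + 0.5 * s * s)
            hi = hi if hi is not None else math.exp(mu + 12 * s)
            x = np.linspace(max(lo, 1e-9), hi, n_quad)
            pdf = np.exp(-0.5 * ((np.log(x) - mu) / s) ** 2) / x
            return float(np.trapezoid(x * pdf, x) / np.trapezoid(pdf, x))
        comps = self.params["components"]
        weights = np.array([w for w, _ in comps], dtype=float)
        weights = weights / weights.sum()
        return float(sum(w * spec.mean() for w, spec in zip(weights, (s for _, s in comps))))


def distal_mixture(target_let_d: float = 19.0, low: float = 3.0,
                   high: float = 80.0) -> TrackSpectrum:
    """Two-component ε/l mixture emulating the distal-column spectrum.

    A slowed-primary component and a track-end component, truncated to the
    given support, with the component weight solved so the dose-weighted mean
    equals ``target_let_d``.
    """
    comp_low = TrackSpectrum("lognormal", {"median": 8.0, "sigma_log": 0.45,
                                           "low": low, "high": high})
    comp_high = TrackSpectrum("lognormal", {"median": 45.0, "sigma_log": 0.35,
                                            "low": low, "high": high})
    m1, m2 = comp_low.mean(), comp_high.mean()
    if not m1 < target_let_d < m2:
        raise InvalidInputError("target LET_d outside component means")
    w_low = (m2 - target_let_d) / (m2 - m1)
    return TrackSpectrum("mixture", {"components": [(w_low, comp_low),
                                                    (1.0 - w_low, comp_high)]})


def simulate_tracks(spectrum: TrackSpectrum, n_events: int = 10000,
                    rng=None, energy_per_step: float = 1.0) -> list[TrackStep]:
    """Event stream whose dose-weighted ε/l distribution follows ``spectrum``.

    Each step deposits the same energy (``energy_per_step`` keV) so that the
    sampled ε/l values are dose weights by construction; step lengths are
    ε divided by the sampled ε/l.
    """
    if n_events < 1:
        raise InvalidInputError("need at least one event")
    if energy_per_step <= 0:
        raise InvalidInputError("energy per step must be positive")
    rng = _rng(rng)
    ratios = spectrum.sample(n_events, rng)
    return [TrackStep(energy_deposit=energy_per_step,
                      step_length=energy_per_step / r) for r in ratios]


# ---------------------------------------------------------------------------
# γH2AX foci
# ---------------------------------------------------------------------------

def foci_yield_per_gy(let_d: float) -> float:
    """Foci per nucleus per Gy, linearly interpolated in LET between the
    calibration anchors and clamped outside them."""
    (l1, d1, m1), (l2, d2, m2) = FOCI_ANCHORS
    y1, y2 = m1 / d1, m2 / d2
    if let_d <= l1:
        return y1
    if let_d >= l2:
        return y2
    return y1 + (y2 - y1) * (let_d - l1) / (l2 - l1)


def simulate_foci(dose_gy: float, let_d: float, n_nuclei: int = 200,
                  rng=None, yield_per_gy=None) -> np.ndarray:
    """Per-nucleus focus counts ~ Poisson(dose × yield(LET))."""
    if n_nuclei < 1:
        raise InvalidInputError("need at least one nucleus")
    if dose_gy < 0:
        raise InvalidInputError("dose must be non-negative")
    rng = _rng(rng)
    rate = yield_per_gy(let_d) if callable(yield_per_gy) else (
        yield_per_gy if yield_per_gy is not None else foci_yield_per_gy(let_d))
    return rng.poisson(dose_gy * rate, size=n_nuclei)
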