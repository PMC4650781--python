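"""Clonogenic survival analysis: colony counts → survival fractions →
linear-quadratic fits → SF2 / D10 / RBE with propagated uncertainty.

The linear-quadratic (LQ) model is SF(D) = exp(−αD − βD²) with α (Gy⁻¹) and
β (Gy⁻²) fitted by weighted nonlinear least squares on the linear SF scale
with 1/Y weights (w = 1/SF, floored to avoid infinite weights at zero-count
wells).  For Poisson colony counts the variance of an observed SF is
proportional to its expectation, so 1/Y weighting is inverse-variance
weighting up to a constant that the residual scale estimate absorbs.

RBE at a survival level s is the ratio of isoeffect doses, the positive roots
of βD² + αD + ln s = 0 for the reference (photon) and test (proton) fits; its
standard deviation is obtained by the delta method from each fit's (α, β)
covariance, treating the two fits as independent.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import FitFailureError, InsufficientDataError, InvalidInputError

PLATE_ROWS = "ABCDEFGH"


@dataclass(frozen=True)
class PlateCounts:
    """Colony counts (colonies of >= 50 cells) for one 96-well plate.

    ``counts`` is an 8x12 grid (rows A-H, columns 1-12); ``conditions`` maps
    the 1-based column index to its delivered (dose Gy, LET_d keV/µm).
    """

    counts: np.ndarray
    conditions: dict[int, tuple[float, float]]
    seeded_per_well: int = 100
    plate_id: str = "plate"
    replicate_id: int = 1

    def __post_init__(self):
        counts = np.asarray(self.counts, dtype=int)
        if counts.shape != (8, 12):
            raise InvalidInputError(f"plate grid must be 8x12, got {counts.shape}")
        if (counts < 0).any():
            raise InvalidInputError("colony counts must be non-negative")
        if self.seeded_per_well <= 0:
            raise InvalidInputError("seeded_per_well must be positive")
        object.__setattr__(self, "counts", counts)

    def column_counts(self, column: int) -> np.ndarray:
        if not 1 <= column <= 12:
            raise InvalidInputError("column index must be 1..12")
        return self.counts[:, column - 1]


@dataclass(frozen=True)
class SurvivalPoint:
    dose: float  # Gy
    sf: float
    sem: float = 0.0
    n_wells: int = 1
    let_d: float = float("nan")  # keV/um

    def __post_init__(self):
        if self.dose < 0 or self.sf < 0 or self.sem < 0 or self.n_wells < 1:
            raise InvalidInputError("invalid survival point")


@dataclass(frozen=True)
class LQFit:
    alpha: float  # 1/Gy
    beta: float  # 1/Gy^2
    se_alpha: float = 0.0
    se_beta: float = 0.0
    cov_alpha_beta: float = 0.0
    residual_ss: float = 0.0
    dof: int = 0
    label: str = ""

    @classmethod
    def from_params(cls, alpha: float, beta: float, label: str = "") -> "LQFit":
        """A fit object carrying parameters only (e.g. published values)."""
        return cls(alpha=alpha, beta=beta, label=label)

    @property
    def cov(self) -> np.ndarray:
        return np.array([[self.se_alpha ** 2, self.cov_alpha_beta],
                         [self.cov_alpha_beta, self.se_beta ** 2]])


@dataclass(frozen=True)
class RBEResult:
    rbe: float
    sd: float
    survival_level: float
    reference_label: str = "photons"


# ---------------------------------------------------------------------------
# Survival fractions
# ---------------------------------------------------------------------------

def plating_efficiency(control_counts, seeded_per_well: int) -> tuple[float, float]:
    """Plating efficiency of unirradiated control wells, with its s.e.m."""
    counts = np.asarray(list(control_counts), dtype=float)
    if counts.size == 0:
        raise InvalidInputError("need at least one control well")
    if seeded_per_well <= 0:
        raise InvalidInputError("seeded_per_well must be positive")
    pe = counts.mean() / seeded_per_well
    sem = (counts.std(ddof=1) / math.sqrt(counts.size) / seeded_per_well
           if counts.size > 1 else 0.0)
    return float(pe), float(sem)


def survival_fractions(plates, pe: float) -> list[SurvivalPoint]:
    """Pooled survival fraction per (dose, LET) condition.

    Wells sharing a condition are pooled across plates (two plates of 8 wells
    per column give the 16 replicates per dose–LET combination); SF is the
    mean count over seeded·PE and the s.e.m. is taken across wells.
    """
    if pe <= 0:
        raise InvalidInputError("plating efficiency must be positive")
    pooled: dict[tuple[float, float], list[np.ndarray]] = {}
    seeded = None
    for plate in plates:
        seeded = plate.seeded_per_well
        for col, cond in plate.conditions.items():
            pooled.setdefault(tuple(cond), []).append(plate.column_counts(col))
    points = []
    for (dose, let), chunks in sorted(pooled.items()):
        wells = np.concatenate(chunks).astype(float)
        if wells.size == 0:
            warnings.warn(f"condition dose={dose} has no wells; skipped")
            continue
        sf_wells = wells / (seeded * pe)
        sem = (sf_wells.std(ddof=1) / math.sqrt(wells.size)
               if wells.size > 1 else 0.0)
        points.append(SurvivalPoint(dose=dose, sf=float(sf_wells.mean()),
                                    sem=float(sem), n_wells=int(wells.size),
                                    let_d=let))
    return points


def per_well_survival(plates, pe: float) -> list[SurvivalPoint]:
    """One survival point per well (n_wells=1), for regression on raw wells."""
    if pe <= 0:
        raise InvalidInputError("plating efficiency must be positive")
    points = []
    for plate in plates:
        for col, (dose, let) in plate.conditions.items():
            for c in plate.column_counts(col):
                points.append(SurvivalPoint(
                    dose=dose, sf=float(c) / (plate.seeded_per_well * pe),
                    n_wells=1, let_d=let))
    return points


def lod_threshold(seeded_per_well: int, pe: float) -> float:
    """Limit of detection: the SF of one colony per well, 1/(seeded·PE)."""
    if pe <= 0 or seeded_per_well <= 0:
        raise InvalidInputError("seeded_per_well and pe must be positive")
    return 1.0 / (seeded_per_well * pe)


def lod_filter(points, seeded_per_well: int, pe: float) -> list[SurvivalPoint]:
    """Drop dose levels whose aggregate SF falls below the limit of detection.

    The aggregate SF at each dose is compared against 1/(seeded·PE); dose
    levels strictly below the limit are omitted (points exactly at the limit
    are retained).  Filtering acts on whole dose levels so that per-well
    points at a detectable dose are kept even if an individual well is empty.
    """
    threshold = lod_threshold(seeded_per_well, pe)
    by_dose: dict[float, list[SurvivalPoint]] = {}
    for p in points:
        by_dose.setdefault(p.dose, []).append(p)
    keep = set()
    for dose, pts in by_dose.items():
        n = sum(p.n_wells for p in pts)
        aggregate = sum(p.sf * p.n_wells for p in pts) / n
        if aggregate >= threshold:
            keep.add(dose)
    return [p for p in points if p.dose in keep]


# ---------------------------------------------------------------------------
# Linear-quadratic fitting
# ---------------------------------------------------------------------------

def lq_survival(dose, alpha: float, beta: float):
    dose = np.asarray(dose, dtype=float)
    return np.exp(-alpha * dose - beta * dose * dose)


def fit_lq(points, weight_floor: float | None = None,
           non_negative: bool = False, label: str = "",
           reweight_iterations: int = 3) -> LQFit:
    """Weighted (1/Y) nonlinear LQ regression.

    Minimises Σ wᵢ (SFᵢ − exp(−αDᵢ − βDᵢ²))² with wᵢ = nᵢ / max(Ŷᵢ, floor),
    where Ŷ is the fitted curve: weights are refreshed from the current fit
    (iteratively reweighted least squares), which keeps them unbiased by the
    counting noise of individual wells and is how "1/Y" weighting is defined
    in the common curve-fitting packages.  The floor (default: the smallest
    positive observed SF) bounds the weights.  Standard errors and the α–β
    covariance come from the weighted information matrix scaled by the
    residual variance.
    """
    points = list(points)
    if len(points) < 3:
        raise InsufficientDataError("need at least 3 survival points")
    dose = np.array([p.dose for p in points])
    sf = np.array([p.sf for p in points])
    n = np.array([p.n_wells for p in points], dtype=float)
    if len(np.unique(dose)) < 3:
        raise InsufficientDataError("need at least 3 distinct dose levels")
    if weight_floor is None:
        positive = sf[sf > 0]
        if positive.size == 0:
            raise InsufficientDataError("all survival fractions are zero")
        weight_floor = float(positive.min())

    # starting values from a log-linear fit on the positive points
    mask = sf > 0
    design = np.column_stack([dose[mask], dose[mask] ** 2])
    coef, *_ = np.linalg.lstsq(design, -np.log(sf[mask]), rcond=None)
    p0 = np.clip(coef, 0.0, None) if non_negative else coef
    p0 = np.nan_to_num(p0, nan=0.1)

    bounds = ((0.0, 0.0), (np.inf, np.inf)) if non_negative else (-np.inf, np.inf)
    popt = p0
    w = n / np.maximum(sf, weight_floor)  # first pass: observed-SF weights
    try:
        with warnings.catch_warnings():
            # exact fits legitimately yield an inestimable covariance
            warnings.simplefilter("ignore", optimize.OptimizeWarning)
            for _ in range(max(reweight_iterations, 0) + 1):
                w_used = w
                popt, pcov = optimize.curve_fit(
                    lq_survival, dose, sf, p0=popt,
                    sigma=1.0 / np.sqrt(w_used),
                    absolute_sigma=False, bounds=bounds, maxfev=10000)
                w = n / np.maximum(lq_survival(dose, *popt), weight_floor)
        w = w_used
    except (RuntimeError, optimize.OptimizeWarning) as exc:
        raise FitFailureError(
            "LQ fit failed to converge",
            diagnostics={"p0": p0.tolist(), "n_points": len(points)}) from exc
    resid = sf - lq_survival(dose, *popt)
    rss = float(np.sum(w * resid ** 2))
    if not np.all(np.isfinite(pcov)):
        if rss <= 1e-18 * float(np.sum(w * sf ** 2)):
            pcov = np.zeros((2, 2))  # exact fit: no residual information
        else:
            raise FitFailureError("singular covariance in LQ fit",
                                  diagnostics={"popt": popt.tolist()})
    return LQFit(alpha=float(popt[0]), beta=float(popt[1]),
                 se_alpha=float(np.sqrt(pcov[0, 0])),
                 se_beta=float(np.sqrt(pcov[1, 1])),
                 cov_alpha_beta=float(pcov[0, 1]),
                 residual_ss=rss, dof=len(points) - 2, label=label)


def sf_at_dose(fit: LQFit, dose: float) -> float:
    """SF(D) = exp(−αD − βD²); SF2 is this at D = 2 Gy."""
    if dose < 0:
        raise InvalidInputError("dose must be non-negative")
    return float(lq_survival(dose, fit.alpha, fit.beta))


def _isoeffect_dose(alpha: float, beta: float, level: float) -> float:
    log_kill = -math.log(level)  # > 0
    if abs(beta) < 1e-12:
        if alpha <= 0:
            raise InvalidInputError("no positive isoeffect dose for alpha<=0, beta=0")
        return log_kill / alpha
    disc = alpha * alpha + 4.0 * beta * log_kill
    if disc < 0:
        raise InvalidInputError("no real isoeffect dose for these parameters")
    dose = (-alpha + math.sqrt(disc)) / (2.0 * beta)
    if dose <= 0:
        raise InvalidInputError("no positive isoeffect dose for these parameters")
    return dose


def dose_at_sf(fit: LQFit, sf: float) -> float:
    """Isoeffect dose: the positive root of βD² + αD + ln(sf) = 0, Gy."""
    if not 0.0 < sf < 1.0:
        raise InvalidInputError("survival level must lie strictly in (0, 1)")
    return _isoeffect_dose(fit.alpha, fit.beta, sf)


def _isoeffect_gradient(alpha: float, beta: float, level: float) -> np.ndarray:
    """d(dose)/d(alpha, beta) at the positive root, for delta-method errors."""
    log_kill = -math.log(level)
    if abs(beta) < 1e-9:
        # series limit of the quadratic-root derivatives as beta -> 0
        return np.array([-log_kill / alpha ** 2, -log_kill ** 2 / alpha ** 3])
    root = math.sqrt(alpha * alpha + 4.0 * beta * log_kill)
    dose = (-alpha + root) / (2.0 * beta)
    d_alpha = (alpha / root - 1.0) / (2.0 * beta)
    d_beta = log_kill / (beta * root) - dose / beta
    return np.array([d_alpha, d_beta])


def rbe(reference: LQFit, test: LQFit, survival_level: float = 0.10) -> RBEResult:
    """RBE at a survival level with delta-method standard deviation.

    RBE = D_ref / D_test at the common survival level; the variance combines
    each fit's (α, β) covariance through the isoeffect-dose gradients, with
    the two fits treated as independent.
    """
    if not 0.0 < survival_level < 1.0:
        raise InvalidInputError("survival level must lie strictly in (0, 1)")
    d_ref = dose_at_sf(reference, survival_level)
    d_test = dose_at_sf(test, survival_level)
    value = d_ref / d_test
    rel_var = 0.0
    for fit, d in ((reference, d_ref), (test, d_test)):
        g = _isoeffect_gradient(fit.alpha, fit.beta, survival_level)
        rel_var += float(g @ fit.cov @ g) / d ** 2
    return RBEResult(rbe=value, sd=value * math.sqrt(max(rel_var, 0.0)),
                     survival_level=survival_level,
                     reference_label=reference.label or "photons")


# ---------------------------------------------------------------------------
# Curve comparison and report table
# ---------------------------------------------------------------------------

def compare_fits_f_test(points_a, points_b, weight_floor: float | None = None
                        ) -> tuple[float, float]:
    """Extra sum-of-squares F test for a common vs separate LQ curves.

    The null model fits one (α, β) to the pooled data; the alternative fits
    each dataset separately.  F = ((SS_pooled − SS_sep)/Δdf) / (SS_sep/df_sep)
    with Δdf = 2.  Weights use a common floor so the pooled and separate sums
    of squares are comparable.
    """
    points_a, points_b = list(points_a), list(points_b)
    if weight_floor is None:
        positive = [p.sf for p in points_a + points_b if p.sf > 0]
        if not positive:
            raise InsufficientDataError("all survival fractions are zero")
        weight_floor = min(positive)
    fit_a = fit_lq(points_a, weight_floor=weight_floor)
    fit_b = fit_lq(points_b, weight_floor=weight_floor)
    fit_pooled = fit_lq(points_a + points_b, weight_floor=weight_floor)
    ss_sep = fit_a.residual_ss + fit_b.residual_ss
    df_sep = fit_a.dof + fit_b.dof
    ss_pool = fit_pooled.residual_ss
    delta_df = 2
    if df_sep <= 0:
        raise InsufficientDataError("no residual degrees of freedom")
    f_stat = max((ss_pool - ss_sep) / delta_df, 0.0) / (ss_sep / df_sep)
    p_value = float(stats.f.sf(f_stat, delta_df, df_sep))
    return float(f_stat), p_value


def rbe_let_table(fits: dict[float, LQFit], reference: LQFit,
                  survival_level: float = 0.10) -> pd.DataFrame:
    """One row per LET: α, β (with SEs), SF2, D10 and RBE ± sd.

    Entries whose isoeffect dose is undefined are left as NaN with the row
    retained.
    """
    if len(fits) == 0:
        raise InvalidInputError("need at least one fit")
    rows = []
    for let in sorted(fits):
        fit = fits[let]
        row = {
            "let_keV_um": let,
            "alpha_Gy-1": fit.alpha, "se_alpha": fit.se_alpha,
            "beta_Gy-2": fit.beta, "se_beta": fit.se_beta,
            "sf2": sf_at_dose(fit, 2.0),
            "d10_Gy": np.nan, "rbe": np.nan, "rbe_sd": np.nan,
        }
        try:
            row["d10_Gy"] = dose_at_sf(fit, survival_level)
            result = rbe(reference, fit, survival_level)
            row["rbe"], row["rbe_sd"] = result.rbe, result.sd
        except InvalidInputError:
            pass
        rows.append(row)
    return pd.DataFrame(rows)
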