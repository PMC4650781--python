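# Methods

## Transport model

The beam model is a one-dimensional analytic surrogate for condensed-history
Monte Carlo transport.  Its purpose is narrow: place the cell layer of each
96-well-plate column at a known water-equivalent depth on a pristine Bragg
curve and predict relative dose and dose-averaged LET there.  It makes three
assumptions:

1. **Bragg–Kleeman range–energy law.**  R = aEᵖ in water with
   a = 0.0022 cm·MeV⁻ᵖ and p = 1.77, standard values for therapeutic proton
   energies.  Stopping power follows by differentiation,
   S(E) = E^(1−p)/(ap).  Other materials are handled through a
   water-equivalent ratio (WER, cm water per cm material): Lucite's
   1.1707 is fixed by the measured beam ranges (4.8 cm water / 4.1 cm
   Lucite); the polystyrene plate bottom is assumed to share Lucite's mass
   stopping-power ratio (WER = 1.0723 at ρ = 1.09 g/cm³); radiochromic films
   are treated as Lucite-equivalent slabs of their printed 268-µm thickness.
   Only the WET of these thin components matters for column placement.
2. **Gaussian residual-range distribution.**  A proton's total range is
   Normal(R₀, σ_R), where σ_R combines the beam's energy spread mapped
   through dR/dE with intrinsic range straggling (0.0085·R₀^0.935, fixed a
   priori) in quadrature.  Dose at depth z is the fluence-weighted mean
   stopping power of protons still in flight (stopped protons contribute
   nothing); dose-averaged LET is the dose-weighted mean,
   LET_d(z) = E[S²]/E[S].
3. **No nuclear interactions, secondaries or lateral transport.**  Dose is
   relative; the absolute scale enters only through the machine calibration
   (2.6 cGy per repainting at column 1, 17.64 MU).

### Numerical treatment

S ~ r^((1−p)/p) ≈ r^−0.435 diverges (integrably) at track ends, and near the
peak the quadrature must resolve both this singularity and the Gaussian
bulk.  The expectation over residual range uses a composite trapezoid rule on
the union of a power-stretched grid (r = r_max·t⁵, 1500 nodes) and a uniform
grid over ±8σ of the Gaussian (800 nodes).  Off-the-shelf Gauss–Hermite
quadrature underestimates E[S²] near the peak by 2–3× and was rejected.
Depth profiles default to 100-µm steps, refined to 10 µm within ±5 mm of the
peak.  The σ→0 limit is exact to one grid step (a 1-µm floor on σ guards the
degenerate case).

### Calibrated parameters

Two beam parameters are calibrated, not predicted, and are so documented in
the default config:

* **Effective energy, 76.97 MeV.**  The nominal 79.7-MeV beam traverses
  upstream material the model does not track; the effective energy is chosen
  so the modelled water range equals the measured 4.8 cm.
* **Energy spread, σ_E = 0.677 MeV.**  The momentum spread of the machine is
  not published; σ_E is set so the peak-to-entrance column dose ratio of the
  default geometry equals the measured 5.5.  The acceptance check on this
  ratio is therefore a configuration reproduction, not a prediction.

### Default jig geometry

The fabricated step thicknesses were never published; the packaged default
follows the documented design procedure instead.  Columns 1–8 are placed at
the depths where the model's LET_d equals the published proximal column
values (0.9–5.1 keV/µm); column 9 is placed exactly at the dose peak (the
role of the three inserted films in the physical setup); columns 10–12 are
placed at the published distal LET values (15.2, 17.7, 19.0 keV/µm).  Step
increments are coarse near the entrance and sub-millimetre near the range
end, reproducing the published design logic.  A pure LET-target design
(`design_jig_steps(..., kind="let")`) is also provided and round-trips its
targets through the transport to within 10%; it is not the default because
the simplified model crosses LET_d = 10.8 keV/µm distal to the dose peak,
which would strand the nominal peak column in the falloff.

With this model the LET_d at the peak column is ≈ 14 keV/µm versus the
published 10.8 — the model lacks the nuclear-interaction and
secondary-particle effects that shape the Monte Carlo value — and the distal
dose falloff is shallower than measured.  Column placement, dose ratios up to
the peak, and LET ordering (the quantities the analysis consumes) are
faithful.

## LET scoring

Within a thin scoring layer, each step contributes an energy deposition ε
over a length l; ε/l is a random-variable form of LET.  The scorer reports
LET_t = Σε/Σl and LET_d = Σε(ε/l)/Σε (ε as dose weight), a dose-weighted
histogram of ε/l on 100 log-spaced bins spanning the observed range, and a
batch-means relative uncertainty (default 10 consecutive batches; the
estimator scales as 1/√N on i.i.d. streams).  Zero-ε steps lengthen the
track denominator but carry no dose weight.  LET_d ≥ LET_t always
(Cauchy–Schwarz on (ε/√l, √l)), with equality iff ε/l is constant.

## Survival analysis

Counts are colonies of ≥ 50 cells.  Plating efficiency (PE) is the mean
control-well count over cells seeded; survival fractions are counts over
seeded·PE, pooled per dose–LET condition (two plates of 8 wells give the 16
replicates).  Dose levels whose aggregate SF falls strictly below the limit
of detection 1/(seeded·PE) are dropped whole; a level exactly at the limit
is retained.

The LQ model SF(D) = exp(−αD − βD²) is fitted on the linear SF scale by
weighted least squares with 1/Y weights.  Y is the **fitted** curve value,
refreshed over three reweighting passes (IRLS), floored at the smallest
positive observed SF.  Two reasons: (i) for Poisson counts Var(SF) ∝ E[SF],
so 1/Ŷ weighting is inverse-variance weighting; (ii) weights built from
*observed* per-well SFs correlate with the residuals and bias β upward by
about one standard error under the default study conditions (measured: 78%
2-SE coverage for β, versus ~95% with fitted weights).  Fits are
unconstrained by default (`non_negative=True` available).  Standard errors
and the α–β covariance come from the weighted information matrix scaled by
the residual variance; exact (zero-residual) fits report zero uncertainty.

Isoeffect doses are the positive roots of βD² + αD + ln s = 0 (linear case
handled in closed form).  RBE(s) = D_ref(s)/D_test(s); its standard
deviation propagates each fit's full (α, β) covariance through the
analytic root gradients (delta method), treating the two fits as
independent.  Curve pairs are compared with the extra sum-of-squares F test
(pooled single-(α, β) fit versus separate fits, common weight floor).
Multiplicity correction is not applied; the report rounds α/β to 3 decimals
and RBE to 2, matching the published table format.

## Synthetic data

The generators emulate the statistical structure the analysis assumes — and
only that:

* **Plates**: per-well counts ~ Poisson(seeded · PE · SF(D_c)) with D_c from
  the repainting count and the column's dose per painting.  Defaults: 100
  cells/well, 2 plates per dose (16 replicates per condition), published
  α/β per column LET as ground truth, PE 0.8 (H460-like) or 0.5
  (H1437-like; neither PE was published).  Column-1 dose ladder
  {0, 0.1, 0.2, 0.5, 1, 2, 4, 6} Gy: the exact experimental levels were not
  published, and the low levels are required because distal columns receive
  ~5× the entrance dose — without them the high-LET conditions would retain
  fewer than three dose levels above the detection limit and be unfittable.
  An optional log-normal multiplier on plate seeding density models the
  15–30% counting error of stock cell solutions (off by default; the
  analysis itself assumes Poisson wells).
* **Tracks**: the spectrum object parameterises the *dose-weighted* ε/l
  distribution (delta, uniform, truncated log-normal, or mixture); events
  carry equal ε so the sampled values are dose weights by construction.
  The distal-column factory mixes a slowed-primary and a track-end
  log-normal component on support 3–80 keV/µm with the component weight
  solved so the dose-weighted mean is exactly the target (default
  19 keV/µm).
* **Foci**: per-nucleus counts ~ Poisson(dose · yield(LET)), with yields
  interpolated between the two published calibration anchors
  (3.57 foci at 4.6 keV/µm & 2.9 Gy; 7.02 at 17.3 keV/µm & 1.7 Gy).  These
  anchors calibrate the generator; reproducing them is not a prediction.

All generators are deterministic under a fixed seed.  What passing tests
show: the analysis chain is unbiased and its reported uncertainties are
calibrated *for data matching these assumptions*.  What they do not show:
robustness to over-dispersion, plate-edge effects, colony-merging at high
survival, mis-segmentation, or any systematic biology the Poisson-LQ model
omits.

## Sensitivity analysis

Thickness and density tolerances of the jig step, films and plate bottom
(defaults ±3 µm, ±1%, ±50 µm, ±0.5% — reconstructed fabrication-spec values,
flagged as such in the config) are stacked coherently toward shorter (low)
or longer (high) water-equivalent paths; the per-column uncertainty is the
mean absolute deviation of the low and high transport results from nominal.
Uncertainties are largest in the distal falloff where the dose gradient is
steepest.  A random-sampling tolerance mode is deliberately out of scope.

## Validation problem sizes

The statistical calibration study runs 200 simulated experiments per
parameter set (each: 8 dose levels × 16 wells × 12 conditions) for both cell
lines plus the photon references, and 1000 replicate null comparisons for
the F-test size — sizes chosen so that a true 90% pass criterion is resolved
with ~2% binomial noise.  Event-stream checks use 2×10⁴ steps, at which the
batch-means LET_d uncertainty is below 1%.

## Known limitations

* LET_d near and beyond the Bragg peak is only ordinal-accurate (no nuclear
  interactions or secondary particles); distal falloff is shallower than
  measured.
* The default jig is reverse-engineered from published per-column LET
  values, not the fabricated drawings.
* Fit standard errors assume independent wells; a shared plating-efficiency
  error becomes non-negligible when hundreds of wells share one control set.
* The spot-FWHM default is 3.3 cm; 3.5 cm (also reported) is available via
  config.
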