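# Methods

This note records the models, the numerical choices and the reasoning
behind the places where the design was genuinely open. Everything stated
here is computed by the test suite or by `scripts/acceptance.py`; nothing
is quoted from elsewhere.

## Biomass allometry

A cane is modelled as stalk plus leaves. The stalk is an ideal cylinder of
diameter `D` and height `H` (both in metres, measured at ground level and
to the crown respectively) filled with stalk matter of density `ρ_S(t)`
(kg/m³), corrected by a dimensionless taper factor `F`:

    BM_S = (π D²/4) · H · ρ_S(t) · F,    BM_C = BM_S + BM_L(t).

The cross-section is `π D²/4` — the circle area. This is the only form
consistent with the stalk-density computation it must invert
(`ρ_S = mass / (π D²/4 · H)`, no taper correction at that stage, since `F`
is calibrated against exactly these uncorrected estimates). `F` defaults to
0.977 and is treated as time-invariant. Calibration uses the **mean of
per-sample ratios** of weighed to estimated stalk mass; a pooled ratio
(sum/sum) is available (`method="pooled"`) — the two differ only at second
order in the scatter.

Yield: `TCH = BM_C · C · 10 / S` with `C` in canes **per row-metre** and
`S` the mean row spacing in metres (default 1.2 = mean of the 0.9 m and
1.5 m spacings of double-row planting). `C/S` is then canes/m², the only
dimensionally consistent reading given counts are taken along crop rows.
Internally everything is SI (m, kg, kg/m³); unit conversion happens once,
at file reading.

No wet/dry correction is applied to the leaf term of the biomass relation;
wet-content computation (`1 − dry/wet`) is provided separately.

LAI: the optical instrument reports *effective* LAI; a constant clumping
offset — the mean difference between instrument readings and destructively
observed leaf-area fractions — is subtracted. Corrected values slightly
below zero are retained and flagged; `clamped()` floors them at zero for
export/plotting.

## Growth interpolators

Cane biomass and cane spatial density follow the three-parameter logistic
`f(t) = Δy/(1+e^{−k(t−t0)})` in days since start of growth; density uses
`k < 0` (declining, as weaker tillers die off) and `Δy > 0`. Fitting is
trust-region nonlinear least squares (`scipy.optimize.least_squares`,
`xtol = ftol = 1e-10`, max 10 000 evaluations). Initial values: asymptote
1.05·max(y); rate from a straight-line slope via the identity
max-slope = Δy·k/4; midpoint at the observation nearest half the asymptote
guess.

* **Origin forcing.** A logistic cannot pass exactly through the origin
  (`f(0) = Δy/(1+e^{k·t0}) > 0`), so "forced through zero" is implemented
  as an appended pseudo-observation (t=0, y=0) with a weight equal to one
  ordinary observation (configurable, 0 disables). Biomass fits use it by
  default; density fits never do (the stand starts the season densely
  tillered). Consistency tests that require *exact* recovery of a logistic
  truth run with the weight at 0, because the pseudo-observation
  intentionally biases `f(0)` toward zero.
* **Confidence intervals.** Linearized (Jacobian) covariance with
  t-quantiles at `n − 3` degrees of freedom.
* **Constrained re-fit.** Per-field/per-ESU re-fits start at the general
  coefficients and are box-constrained to the general 95% CIs widened by
  10% of each interval's half-width per side (symmetric). The alternative
  (±10% of each bound's magnitude) is selectable; the half-width reading
  treats the widening as extra slack proportional to the estimated
  uncertainty rather than to the coefficient size. Degenerate (zero-width)
  CIs from exact fits are opened by a relative 1e-8 margin. Returned
  coefficients always lie inside the widened box (property-tested).
* **Degeneracy guard.** Near-linear data push a logistic toward
  `Δy → ∞, k → 0`; the default asymptote bound is capped at 10× the
  largest observation unless the caller supplies bounds.

Auxiliary trends by OLS in the monomial basis: stalk density linear in
time; leaf biomass per cane a second-order polynomial through the origin
(through-origin is a config flag; the zero-leaf seedling state motivates
the default). Each trend's RMSE (n denominator, over all residuals) is the
*function-fitting precision* of that quantity.

Growth stages: early `t < 150` d, mid `150 ≤ t ≤ 300` d, late `t > 300` d;
per-stage summaries evaluate at midpoints 75/225/350 d (the averaging
basis is otherwise arbitrary; fields harvested before day 350 use their
last day if still in the late stage).

## Precision framework

Three tiers, per parameter and growth stage:

* **instrument operation** — sample s.d. (n−1) of replicate blocks
  re-measuring the same plant;
* **idealization** — the same for neighbouring plants within ~5 m (GPS
  accuracy): local plant variability, which *contains* the instrument
  tier, so the two are never treated as independent;
* **function fitting** — the trend RMSE of the modelled quantities (ρ_S,
  BM_L), constant over stages.

No c4 small-sample correction is applied to replicate s.d.s; with five
replicates the estimator is ~6% low on average (documented by test).
Stalk density is never measured directly; its instrument/idealization
sigmas come from inverse propagation,
`σ_ρ = ρ·√((σ_BMC/BMC)² + (2σ_D/D)² + (σ_H/H)²)`, using the cane-mass
dispersion at the destructive units as the mass term. Leaf-biomass
idealization scales the per-visit cane-mass s.d. by the leaf fraction
BM_L/BM_C at the stage midpoint.

The **total precision at location** mixes tiers: idealization for the
directly measured D and H (and C for yield), fitting RMSE for ρ_S and BM_L
— their idealization spread is already inside the fit residuals and would
be double-counted. The **within-ESU** tier replaces the idealization
sigmas with the corner-point dispersion of ordinary visits. Missing
tier/stage combinations stay absent (NaN), never zero. Instrument-above-
idealization entries trigger a warning, not an error.

## Delta-method propagation

With relative sigmas `c_X = σ_X/X`, the stalk term has

    θ = √((2c_D)² + c_H² + c_ρ²)
    χ = √(c_D⁴ + (2c_D c_H)² + (2c_D c_ρ)² + (c_H c_ρ)²)

and analogously for the areal stalk (TSH, with the density CV added) and
leaf (TLH) components. Two compositions of θ and χ are implemented,
selected by `second_order`:

* `"quadrature"` (default): `√(θ² + χ²)`. This is the second-order delta
  method for a product of independent Gaussians — exact for the two-factor
  leaf×density product and within 0.5% of a 10⁶-draw Monte-Carlo up to 10%
  CVs (verified by the acceptance suite). It also keeps the second-order
  contribution under 2 percentage points of TCH at campaign-scale CVs.
* `"additive"`: `θ + χ`, the form propagation equations are often typeset
  in. It overstates the sigma by up to ~12% at 10% CVs (the θ·χ cross term
  does not belong in a variance) and is retained for comparison; the
  worked hand examples for this mode are asserted in the tests.
* `"none"`: first order only.

The total TCH variance adds the stalk and leaf components in quadrature
**plus** their covariance `2·TSH·TLH·(σ_C/C)²`, because both components
contain the same measured density. The term is algebraically exact for
independent inputs; without it the Monte-Carlo comparison fails by up to
6% exactly where the stalk CVs are small. `density_covariance=False`
restores the pure two-group form.

All propagation assumes uncorrelated, normally distributed input errors;
correlated-error propagation is out of scope.

## Perturbation bands

Per-visit unit means of cane biomass (per field) and cane density (per
ESU) are perturbed with independent `N(0, σ)` noise at the per-stage
total-at-location sigmas, and the constrained logistic is re-fitted —
100 replicates each by default. TCH bands come from the pointwise sample
s.d. over all 100×100 products of perturbed biomass × density curves
(materialized explicitly; ~30 MB per ESU at a daily grid). The mean
profile is the product of the *unperturbed* re-fitted curves. Perturbation
at aggregated means is the default; per-corner perturbation would be a
straightforward variation. Replicate fits that fail to converge are
dropped and logged; more than 20% failures aborts the ensemble with
diagnostics. Quantile bands are available alongside the s.d. band.

Biomass and density ensembles are treated as independent (no covariance
between the two perturbation chains).

## Synthetic campaign generator

The generator is first-class, tested code; its defaults define the study
conditions the rest of the suite measures under.

* **Truth shapes.** Per-field biomass logistics with asymptotes 2.3–2.7
  kg/cane, rates ~0.02/day, midpoints ~150 d; per-ESU density logistics
  declining gently from ~14 to ~10 canes/row-m (the stage-mean densities
  implied jointly by the shipped absolute density sigmas 6.3/4.0/2.1 and
  the relative density precisions they correspond to); ρ_S(t) = 850+0.7t
  kg/m³; BM_L(t) = 1.5e-3·t − 2.2e-6·t² kg; a through-origin LAI
  polynomial plus a 0.3 clumping offset.
* **Self-consistency.** H and D are *derived* from the biomass truth by
  inverting the allometric relation at a configured D/H ratio (0.010), so
  a zero-noise campaign reproduces the configured curves exactly
  end-to-end (verified to ~1e-12).
* **Noise.** Additive Gaussian per tier with the published per-stage
  sigmas as defaults; idealization noise for ordinary corner records
  (instrument noise is a nested component of it, so recovered tables obey
  instrument ≤ idealization). Plant-to-plant cane-mass spread at ESUBs:
  20/15/12% by stage. Negative draws are redrawn at the physical floor and
  the redraw count logged — truncation slightly biases small-mean
  quantities such as early-season density under large sigmas.
* **Design.** 4 fields (ratoon cycles 1–9, harvests 340–420 d), 3–5 ESUs
  of which 1–2 ESUBs each, 4 corner replicates, 12 visits per field evenly
  spaced from day 30 to 5 days before that field's harvest (campaigns
  follow each field to its own harvest; a schedule cut off at a common day
  would leave short-season fields with a single late-stage visit and make
  the late-stage band degenerate). Intensive replicate blocks (5 re-reads,
  instrument and idealization) once per stage, repeated cane weighings for
  the mass instrument tier, and a 24-point line transect at day 66 with
  5/10/20 m spacing segments.
* **Seeding.** One master seed; per-unit substreams via stable CRC32
  hashes of unit names, so adding a unit never perturbs another unit's
  draws.

What the generator does **not** emulate: spatial autocorrelation (transect
noise is i.i.d., so the synthetic variogram is flat by construction),
weather, measurement drift, operator bias, or departures from the logistic
shape (no rise-then-fall density). Passing tests therefore demonstrate
correctness of the estimators under the stated error model, not robustness
to structure the model excludes.

## Spatial statistics

The empirical variogram assigns each unordered pair's squared difference
to the half-open lag bin `[lo, hi)` containing its separation;
`2γ(h)` is the per-bin mean. Empty bins are reported with zero pairs (no
value), out-of-range pairs are counted and dropped. No variogram model
fitting or kriging. The precipitation agreement rate is the fraction of
station-pair-days with equal daily detection status (pairwise mean);
an all-station unanimity rate is available by flag. Missing records are
excluded pairwise.

## Problem sizes

Defaults throughout are the sizes the package ships with: 10⁶-draw
Monte-Carlo oracles on a 27-point CV grid, 100 synthetic campaigns for
recovery statistics, 100×100 perturbation ensembles on daily grids, 200
random transects against the brute-force variogram oracle. The full test
suite runs in about a minute on one core; the acceptance script in a
similar time.

## Known limitations

* The paper-style campaign this emulates measured the *highest* canes; the
  generator draws around the stand truth instead, so selection bias is not
  represented.
* The constrained re-fit inherits the general fit's identifiability: for
  gently declining density curves the k–t0 box is wide and the late-season
  band is governed by the box geometry as much as by the data.
* Relative precision tables depend on the stage-midpoint convention; a
  different averaging basis shifts the percentages by a few points.
* The additive second-order composition is retained only for comparison;
  its hand-example values are not MC-consistent (see above).
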