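# canemetrics

Sugarcane ground-campaign analytics: turn non-destructive field biometrics
into cane-biomass and yield estimates with a fully quantified uncertainty
budget.

Ground campaigns that support remote-sensing or agronomic studies measure
stalk height `H`, stalk diameter `D`, cane counts per row-metre `C` and LAI
at many sampling locations (ESUs), but weigh actual biomass only at a few
destructive locations (ESUBs) — cutting plants biases the very signals the
campaign exists to calibrate. `canemetrics` implements the full inference
chain that bridges this imbalance, plus a synthetic campaign generator with
known ground truth so every stage is testable without field data.

## The model

**Allometry.** Stalk biomass per cane is a taper-corrected cylinder filled
with stalk matter, leaves add their own mass:

```
BM_S = (π D² / 4) · H · ρ_S(t) · F          BM_C = BM_S + BM_L(t)
```

with `ρ_S(t)` the stalk mass density (kg/m³, rising linearly as sucrose
accumulates), `BM_L(t)` the leaf biomass per cane (second-order polynomial
through the origin) and `F = 0.977` a time-constant taper factor calibrated
by dividing destructively weighed stalk mass by the uncorrected cylinder
estimate. Yield in tons cane per hectare is

```
TCH = BM_C · C · 10 / S
```

where `C` is canes per row-metre, `S = 1.2` m the mean row spacing (average
of the 0.9/1.5 m double-row pattern), and 10 converts kg/m² to t/ha.

**Growth interpolators.** Cane biomass and cane density follow a logistic
`f(t) = Δy / (1 + e^{−k(t−t0)})` in days since start of growth. A pooled
*general* fit anchors the shape; per-field (biomass) and per-ESU (density)
curves are *re-fitted* inside the general fit's 95% confidence intervals
widened by 10% — sparse local data cannot escape what the whole campaign
supports.

**Uncertainty, three ways.** (1) Replicate-based precisions at three tiers:
instrument operation (re-measuring the same plant), idealization
(neighbouring plants within GPS accuracy) and function fitting (trend
RMSE). (2) Delta-method propagation through the equations above, with
first-order terms `θ` and second-order terms `χ` (e.g.
`θ_BMS = √((2σ_D/D)² + (σ_H/H)² + (σ_ρ/ρ)²)`). (3) Monte-Carlo
perturbation: perturb the observations at their total-at-location sigmas,
re-fit the constrained interpolators 100×, and band TCH from the 100×100
pairwise curve products. The bands are far tighter than direct propagation
— the central payoff of the interpolator approach. An empirical variogram
of transect TCH estimates and a station-pair precipitation agreement rate
round out the spatial checks.

## Worked example

```python
import canemetrics as cm

config = cm.default_truth_config(seed=7)   # 4 fields, 16 ESUs, known truth
campaign = cm.simulate_campaign(config)    # noisy records at 3 precision tiers
fits = cm.fit_campaign(campaign)           # trends + logistic hierarchy

g = fits.general_biomass
print(f"general: dy={g.delta_y:.2f} kg, k={g.k:.4f}/d, t0={g.t0:.0f} d")
p = fits.field_biomass["F1"]
print(f"F1 refit: dy={p.delta_y:.2f} (truth 2.40)")
```

prints

```
general: dy=2.57 kg, k=0.0187/d, t0=158 d
F1 refit: dy=2.50 (truth 2.40)
```

— the pooled asymptote of ~2.6 kg/cane and the per-field re-fit pulled
toward field F1's true 2.4 kg within the widened bounds. The narrative
scripts under `examples/` walk through each capability (simulation,
allometry, fitting, propagation, perturbation bands, variogram) and print
what every number means; e.g. `examples/05_perturbation_bands.py` shows the
TCH band at ~17% of the mean early in the season against ~42% for direct
propagation of the same sigmas.

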