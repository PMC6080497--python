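"""Perturbation-based TCH uncertainty bands versus direct propagation.

Observations are perturbed at their total-at-location sigmas, the
constrained logistic interpolators are re-fitted 100 times each, and every
perturbed biomass curve is multiplied with every perturbed density curve
(10,000 products).  Because each re-fit pools a season of data, the band is
much tighter than pushing the same sigmas directly through the yield
equation — the main benefit of the interpolator approach.
"""
import numpy as np

import canemetrics as cm
from canemetrics.uncertainty import build_precision_table

config = cm.default_truth_config(seed=7)
campaign = cm.simulate_campaign(config)
fits = cm.fit_campaign(campaign)
precision = build_precision_table(campaign, fits)

profiles = cm.tch_profiles(campaign, fits, precision, n_biomass=100,
                           n_density=100, seed=7)

p = profiles["F1-E1"]
print("ESU F1-E1 TCH profile (mean +/- one s.d.):")
for day in (75, 150, 225, 300, 335):
    i = int(np.argmin(np.abs(p.t_grid - day)))
    print(f"  day {day:3d}: {p.mean[i]:6.1f} +/- {p.sd[i]:5.1f} t/ha")

rel = {}
for prof in profiles.values():
    for stage, v in prof.stage_relative_sd().items():
        rel.setdefault(stage, []).append(100 * v)
print("\nrelative band width, averaged over all ESUs:")
for stage in ("early", "mid", "late"):
    direct = precision.relative_value("TCH", "total_at_location", stage)
    print(f"  {stage:5s}: band {np.mean(rel[stage]):5.1f}%   "
          f"direct propagation {direct:5.1f}%")
print("\nfitting shrinks the uncertainty well below the direct propagation;")
print("the relative band is widest early, when yields are still small.")
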