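"""The allometric cane-biomass relation and its satellite computations.

Stalk biomass is a taper-corrected cylinder volume times the stalk mass
density; cane biomass adds the leaf mass; yield in tons cane per hectare
(TCH) spreads the per-cane biomass over the counted cane density.
"""
from canemetrics import allometry

# a mature cane: 3 cm diameter, 3 m tall, stalk density 1100 kg/m^3
est = allometry.cane_biomass(D=0.030, H=3.00, rho_S=1100.0, F=0.977,
                             BM_L=0.100)
print(f"stalk biomass per cane: {est.BM_S:.4f} kg")
print(f"cane  biomass per cane: {est.BM_C:.4f} kg")

# 8 canes per row-metre at the default 1.2 m mean row spacing
yield_tch = allometry.tch(est.BM_C, C_row=8.0, S=1.2)
print(f"yield: {yield_tch:.1f} t cane/ha   (row spacing {allometry.DEFAULT_ROW_SPACING} m)")

# taper factor calibration from destructive stalk weighings: the ratio of
# weighed stalk mass to the uncorrected cylinder estimate
F = allometry.calibrate_taper_factor([2.00, 1.95], [2.05, 2.00])
print(f"calibrated taper factor from 2 samples: {F:.4f} "
      f"(shipped default {allometry.DEFAULT_TAPER_FACTOR})")

# stalk density from a weighed sample, and wet content from oven drying
rho = allometry.stalk_density_from_sample(mass=2.33264, D=0.03, H=3.0)
print(f"stalk density from sample: {rho:.1f} kg/m^3")
print(f"wet content (30 g dry of 100 g wet): {allometry.wet_content(0.030, 0.100):.2f}")

# effective -> actual LAI via the destructive clumping calibration
res = allometry.correct_lai([2.5, 0.2], [(2.0, 1.8), (3.0, 2.6)])
print(f"LAI offset {res.offset:.2f}; corrected {res.actual.tolist()} "
      f"(clamped export {res.clamped().tolist()})")
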