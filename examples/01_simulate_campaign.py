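"""Generate a synthetic ground campaign and write it as delimited text.

The default configuration mimics a season-long sugarcane campaign: four
fields with logistic per-cane biomass growth, 3-5 sampling units (ESUs) per
field with declining cane density, destructive biomass units (ESUBs),
intensive replicate blocks for the precision tiers and a single-date line
transect.
"""
import tempfile
from pathlib import Path

import canemetrics as cm

config = cm.default_truth_config(seed=7)
campaign = cm.simulate_campaign(config)

report = cm.validate_campaign(campaign)
print(f"fields:             {len(campaign.fields)}")
print(f"biometric records:  {len(campaign.biometrics)}")
print(f"biomass records:    {len(campaign.biomass)}")
print(f"validation issues:  {len(report.violations)}")

out = Path(tempfile.mkdtemp()) / "campaign"
cm.write_campaign(campaign, out)
print(f"written to {out} (fields.csv, biometrics.csv, biomass.csv)")

back = cm.read_campaign(out)
assert back.biometrics == campaign.biometrics
print("read back: identical record for record")

# The biometric table carries stalk height/diameter (m), cane counts per
# row-metre and effective LAI per corner replicate; the biomass table the
# destructive masses.  Truth curves for test oracles:
curves = cm.true_curves(config, [60, 180, 330])
print("\nnoise-free truth, field F1 (BM_C in kg/cane):")
print(curves["biomass"].query("field_id == 'F1'")[["t", "BM_C", "BM_L", "rho_S"]]
      .to_string(index=False))
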