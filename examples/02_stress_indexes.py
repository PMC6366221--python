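"""Preprocess spectra and compute window-wise stress indexes.

The preprocessing chain (SNR quality test, rubberband baseline, vector
normalization) mirrors a standard FTIR workflow; the stress index per
biochemical window is the Euclidean distance between stressed and control
fingerprints, normalized by the total-to-window point-count ratio.  The
whole-spectrum index is the global stress index (GSI).
"""

from ftirstress import SyntheticConfig, generate_experiment, preprocess_set
from ftirstress.stress import compute_si_table

cfg = SyntheticConfig(seed=1)
spectra, _, _ = generate_experiment(cfg)
processed = preprocess_set(spectra)          # QC + baseline + normalization
si = compute_si_table(processed, control_condition="RC_0")

print("Global stress index (GSI) by strain and dose:")
gsi = si[si.window == "WS"].pivot(index="strain", columns="condition", values="si")
print(gsi[["RC_L", "RC_M", "RC_H"]].round(3).to_string())

print("\nPer-window SI for the intermediate strain at the top dose:")
row = si[(si.strain == "I1") & (si.condition == "RC_H")]
print(row[["window", "si", "si_sd"]].round(4).to_string(index=False))
print("\nSI rises monotonically with dose; si_sd is the between-replicate "
      "spread, calibrated to sit near the 2.5e-2 replicate variability of "
      "real cell spectra.")
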