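"""Fit the inverse-calibration dose models and score their predictions.

Primary models are per-window quadratics RC = a SI^2 + b SI + c; the
general model per strain combines them with non-negative weights chosen
by exhaustive grid search on the weight simplex.  The full pipeline runs
in one call and writes every table to disk.
"""

from pathlib import Path

from ftirstress import RunConfig, run_pipeline

outdir = Path("scratch_example_run")
cfg = RunConfig(outdir=str(outdir), seed=1, weight_strategy="grid")
artifacts = run_pipeline(cfg)

print("Primary quadratic models (one per strain x window):")
primaries = artifacts["primaries"]
for strain, per_window in primaries.items():
    best = max(per_window.values(), key=lambda m: m.r2)
    print(f"  {strain}: best window {best.window} "
          f"(a={best.a:.1f}, b={best.b:.1f}, c={best.c:.2f}, R2={best.r2:.3f})")

print("\nGeneral-model weights chosen by the grid search:")
for strain, g in artifacts["generals"].items():
    print(f"  {strain}: {g.weights}")

print("\nPrediction report (dose predicted from spectra alone):")
report = artifacts["report"]
cols = ["strain", "level", "predicted_rc", "expected_rc",
        "crc_predicted", "crc_expected", "pearson", "t_test_p"]
print(report[cols].round(2).to_string(index=False))
print("\ncrc_* are quartile classes (floor(RC/25 + 1/2)): the expected doses "
      "25/50/100 map to classes 1/2/4.  A Pearson r near 1 and a t-test p "
      "near 1 mean predicted and expected doses are statistically "
      "indistinguishable.")
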