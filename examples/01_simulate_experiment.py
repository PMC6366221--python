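"""Simulate a complete FTIR bioassay experiment and look at the raw data.

Generates the full factorial design — three biosensor strains (resistant,
intermediate, sensitive) x four inhibitor dose levels (relative
concentration 0 / 25 / 50 / 100) x three replicates — as yeast-like
fingerprint spectra plus viable plate counts.
"""

from ftirstress import SyntheticConfig, generate_experiment
from ftirstress.viability import mortality_frame, mortality_table

cfg = SyntheticConfig(seed=1)
spectra, counts, truth = generate_experiment(cfg)

print(f"{len(spectra)} spectra on a {spectra.n_points}-point grid "
      f"({spectra.grid[0]:.0f} -> {spectra.grid[-1]:.0f} cm-1)")
print("\nViable counts (first rows):")
print(counts.head(6).to_string(index=False))

mort = mortality_frame(mortality_table(counts, "RC_0"))
print("\nMortality per strain and dose (percent of control viability lost):")
print(mort[["strain", "condition", "mortality_pct"]]
      .pivot(index="strain", columns="condition", values="mortality_pct")
      .round(1).to_string())
print("\nThe sensitive strain (S1) saturates near 100% mortality at the top "
      "dose; the resistant strain (R1) barely responds — the two ends of the "
      "biosensor panel.")
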