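"""Spectral-count differential abundance on a synthetic proteome.

Generates a 1,000-protein, 2x2 shotgun-proteomics experiment with planted
4-fold effects, runs the G-test pipeline and prints the discovery summary
and the recovery of the planted effects.
"""

from omstress import SimulationConfig, gen_spectral_counts, run_proteomics_diff

cfg = SimulationConfig(seed=42)
counts, design, truth = gen_spectral_counts(cfg)
result = run_proteomics_diff(counts, design, q=0.05, bh_mode="literal")

print("discovery summary:", result.summary)

rec = result.records.join(truth)
planted = rec[rec["true_status"] != "null"]
recovered = (planted["status"] == planted["true_status"]).sum()
print(f"planted effects: {len(planted)}, recovered with correct sign: {recovered}")
print(rec[rec["status"] == "UP"].nlargest(3, "log2_ratio")[["log2_ratio", "p_value", "status"]])

# The summary counts are proteins called UP or DOWN (chi2 p < 0.05, FDR rule
# passed, replicates strictly separated); n_fold_* restrict the calls to at
# least 1.5-fold / 2-fold changes. Recovery close to the number planted shows
# the test finds genuine abundance shifts at this sequencing depth.
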