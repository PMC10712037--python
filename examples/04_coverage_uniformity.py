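"""Coverage uniformity: sequence-agnostic vs. restriction digestion.

Computes the interquartile range of RPKM-normalized 500-bp window coverage
for matched-depth simulations of S1 (cuts wherever chromatin is
accessible) and of a GATC restriction enzyme (cuts only at its sites).
A larger IQR means less uniform genome coverage.
"""

from nucleocut import workflows

iqr = workflows.coverage_uniformity_iqr(seed=1)
print("per-window RPKM-sum IQR at matched depth")
print(f"  S1 (sequence-agnostic): {iqr['S1']:8.1f}")
print(f"  GATC restriction model: {iqr['RE']:8.1f}")
print(f"\nratio RE/S1 = {iqr['RE'] / iqr['S1']:.2f} — site-anchored "
      "cutting concentrates coverage and widens the window distribution.")
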