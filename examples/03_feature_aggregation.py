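"""Cut-site signal around open chromatin, with a shuffle-permutation null.

Aggregates the high-units S1 cut-site track over open-chromatin regions
and compares it with a null band built from 100 random, blacklist-avoiding
re-placements of the same features.  Over-digestion depletes the region
centers below the band; the positioned flanking nucleosomes push signal
above it.
"""

import numpy as np

from nucleocut import workflows

prof = workflows.open_chromatin_profile(seed=1)
center = np.abs(prof.offsets) <= 100
flank = (np.abs(prof.offsets) >= 200) & (np.abs(prof.offsets) <= 1500)

print(f"features aggregated: {prof.n_features}")
print(f"observed signal at center (+-100 bp): "
      f"{prof.mean_signal[center].mean():.4f}")
print(f"null band at center: [{prof.band_low[center].mean():.4f}, "
      f"{prof.band_high[center].mean():.4f}]")
print(f"center offsets below the band: "
      f"{100 * np.mean(prof.mean_signal[center] < prof.band_low[center]):.0f}%")
print(f"flank offsets above the band: "
      f"{100 * np.mean(prof.mean_signal[flank] > prof.band_high[flank]):.0f}%")
print("\nThe central dip below the +-3 SD band is the open-chromatin "
      "depletion signature of a high-concentration digest.")
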