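"""Genome-wide numeric signal tracks.

A :class:`SignalTrack` holds one numeric value per fixed-width bin for every
chromosome.  Per-base tracks (``bin_size=1``) are used for nuclease cut-site
coverage; coarser bins for read-depth and eigenvector tracks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SignalTrack"]


@dataclass
class SignalTrack:
    """Per-bin numeric signal over a genome.

    Parameters
    ----------
    bin_size
        Width of each bin in bp.
    data
        Mapping from chromosome name to a 1-D float array of per-bin values.
        The last bin may cover a partial window at the chromosome end.
    chrom_sizes
        Chromosome lengths in bp.
    """

    bin_size: int
    data: dict[str, np.ndarray]
    chrom_sizes: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.bin_size < 1:
            raise ValueError("bin_size must be >= 1")
        if not self.chrom_sizes:
            self.chrom_sizes = {
                c: len(a) * self.bin_size for c, a in self.data.items()
            }

    @classmethod
    def zeros(cls, chrom_sizes: dict[str, int], bin_size: int = 1) -> "SignalTrack":
        data = {
            c: np.zeros(-(-size // bin_size), dtype=float)
            for c, size in chrom_sizes.items()
        }
        return cls(bin_size=bin_size, data=data, chrom_sizes=dict(chrom_sizes))

    def total(self) -> float:
        """Total track mass (sum over all bins of all chromosomes)."""
        return float(sum(a.sum() for a in self.data.values()))

    def scaled(self, factor: float) -> "SignalTrack":
        return SignalTrack(
            bin_size=self.bin_size,
            data={c: a * factor for c, a in self.data.items()},
            chrom_sizes=dict(self.chrom_sizes),
        )

    def to_bedgraph(self, path: str, skip_zero: bool = True) -> None:
        """Write the track as bedGraph (0-based half-open intervals)."""
        with open(path, "w") as fh:
            for chrom, arr in self.data.items():
                size = self.chrom_sizes[chrom]
                for i, v in enumerate(arr):
                    if skip_zero and v == 0:
                        continue
                    start = i * self.bin_size
                    end = min(start + self.bin_size, size)
                    fh.write(f"{chrom}\t{start}\t{end}\t{v:g}\n")

    @classmethod
    def from_bedgraph(
        cls, path: str, chrom_sizes: dict[str, int], bin_size: int = 1
    ) -> "SignalTrack":
        """Read a bedGraph file into a track with the given binning.

        Values are distributed per-base and summed into bins, so intervals
        not aligned to the binning are apportioned by overlap length.
        """
        track = cls.zeros(chrom_sizes, bin_size)
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith(("track", "#")):
                    continue
                chrom, s, e, v = line.split()[:4]
                if chrom not in track.data:
                    continue
                s, e, v = int(s), int(e), float(v)
                arr = track.data[chrom]
                b0, b1 = s // bin_size, (e - 1) // bin_size
                if b0 == b1:
                    arr[b0] += v * (e - s) / bin_size if bin_size > 1 else v * (e - s)
                else:
                    for b in range(b0, b1 + 1):
                        lo = max(s, b * bin_size)
                        hi = min(e, (b + 1) * bin_size)
                        arr[b] += v * (hi - lo) / (bin_size if bin_size > 1 else 1)
        return track
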