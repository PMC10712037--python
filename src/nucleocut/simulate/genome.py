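"""Synthetic genome and chromatin annotation model.

The genome model carries everything the digestion and ligation simulators
need as ground truth: the DNA sequence, positioned nucleosomes (dyads with a
147-bp protected footprint), open-chromatin regions with accessibility
boosts, TSS with expression tiers, oriented CTCF sites, contiguous A/B
compartment blocks with a continuous score, and a blacklist.

Chromatin accessibility has three layers that multiply into the digestion
hazard: (i) nucleosome-protected DNA (within ``protection_halfwidth`` of a
dyad) is strongly shielded (``footprint_protection``); (ii) a fraction of
internucleosomal linkers is occluded by fiber-level compaction
(``occluded_linker_fraction`` at ``occluded_accessibility``), which is what
produces the di-/tri-nucleosome ladder of partially digested chromatin; and
(iii) open regions carry a triangular accessibility bump peaking at the
region center.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["GenomeModel", "make_genome"]

_BASES = np.frombuffer(b"ACGT", dtype="S1")

#: expression-tier labels, from most to least expressed
TIERS = ("high", "intermediate", "other", "non_expressed")


@dataclass
class GenomeModel:
    """Ground-truth genome + chromatin annotation for the simulator."""

    chrom_names: list[str]
    chrom_lengths: dict[str, int]
    sequence: dict[str, str]
    nucleosome_dyads: dict[str, np.ndarray]
    open_regions: pd.DataFrame  # chrom, start, end, multiplier
    tss: pd.DataFrame  # chrom, pos, strand, tpm, tier
    ctcf_sites: pd.DataFrame  # chrom, pos, strand
    compartment_track: pd.DataFrame  # chrom, start, end, label, score
    blacklist: pd.DataFrame  # chrom, start, end
    occluded_linkers: dict[str, np.ndarray]  # (n, 2) start/end per chrom
    protection_halfwidth: int = 73
    footprint_protection: float = 0.02
    occluded_accessibility: float = 0.01
    _base_arrays: dict = field(default_factory=dict, repr=False)

    def seq_array(self, chrom: str) -> np.ndarray:
        """Sequence as a uint8 array of ASCII codes (cached)."""
        if chrom not in self._base_arrays:
            self._base_arrays[chrom] = np.frombuffer(
                self.sequence[chrom].encode(), dtype=np.uint8
            )
        return self._base_arrays[chrom]

    def base_frequencies(self) -> dict[str, float]:
        """Genome-wide mononucleotide frequencies on the forward strand."""
        counts = {b: 0 for b in "ACGT"}
        for chrom in self.chrom_names:
            arr = self.seq_array(chrom)
            for b in "ACGT":
                counts[b] += int((arr == ord(b)).sum())
        total = sum(counts.values())
        return {b: c / total for b, c in counts.items()}

    def footprints(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        """(starts, ends) of nucleosome-protected intervals, half-open."""
        d = self.nucleosome_dyads[chrom]
        return d - self.protection_halfwidth, d + self.protection_halfwidth + 1

    def validate(self) -> None:
        """Check the structural invariants; raise ``ValueError`` on breach."""
        for chrom in self.chrom_names:
            L = self.chrom_lengths[chrom]
            d = self.nucleosome_dyads[chrom]
            if len(d) and (np.diff(d) <= 0).any():
                raise ValueError(f"{chrom}: dyads not strictly increasing")
            if len(d) > 1 and (np.diff(d) < 2 * self.protection_halfwidth + 1).any():
                raise ValueError(f"{chrom}: adjacent dyads closer than a footprint")
            for df, name in (
                (self.open_regions, "open region"),
                (self.blacklist, "blacklist"),
            ):
                sub = df[df["chrom"] == chrom]
                if len(sub) and (
                    (sub["start"] < 0).any() or (sub["end"] > L).any()
                ):
                    raise ValueError(f"{chrom}: {name} outside chromosome bounds")
            # open regions must not touch the blacklist
            op = self.open_regions[self.open_regions["chrom"] == chrom]
            bl = self.blacklist[self.blacklist["chrom"] == chrom]
            for _, o in op.iterrows():
                hit = (bl["start"] < o["end"]) & (bl["end"] > o["start"])
                if hit.any():
                    raise ValueError(f"{chrom}: open region overlaps blacklist")
            comp = self.compartment_track[self.compartment_track["chrom"] == chrom]
            if len(comp):
                starts = comp["start"].to_numpy()
                ends = comp["end"].to_numpy()
                if starts[0] != 0 or (starts[1:] != ends[:-1]).any():
                    raise ValueError(f"{chrom}: compartment blocks do not tile")


def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(_BASES, size=length, p=p).tobytes().decode()


def make_genome(
    n_chroms: int = 1,
    length_bp: int = 2_000_000,
    gc: float = 0.41,
    seed: int = 0,
    *,
    nucleosome_repeat: int = 200,
    repeat_jitter: int = 20,
    occluded_linker_fraction: float = 0.65,
    footprint_protection: float = 0.02,
    occluded_accessibility: float = 0.01,
    open_region_spacing: int = 40_000,
    open_multiplier: float = 5.0,
    nfr_halfwidth: int = 150,
    block_size: int = 250_000,
    compartment_bin: int = 25_000,
    ctcf_spacing: int = 40_000,
    blacklist_per_mb: int = 2,
) -> GenomeModel:
    """Generate a synthetic genome with chromatin annotations.

    Nucleosome dyads are laid down at ``nucleosome_repeat`` bp (uniform
    jitter ``±repeat_jitter``) and re-anchored at open-region edges so the
    nucleosomes flanking a nucleosome-free region are well positioned.
    Compartments tile each chromosome in contiguous blocks of
    ``block_size`` bp with alternating A/B labels and a continuous score.

    All coordinates are 0-based half-open.  Deterministic under ``seed``.
    """
    if length_bp < 100_000:
        raise ValueError("chromosomes must be at least 100 kb")
    if not 0 < gc < 1:
        raise ValueError("gc must be in (0, 1)")
    rng = np.random.default_rng(seed)
    halfw = 73

    chrom_names = [f"chr{i + 1}" for i in range(n_chroms)]
    chrom_lengths = {c: int(length_bp) for c in chrom_names}
    sequence, dyads_d, occl_d = {}, {}, {}
    open_rows, tss_rows, ctcf_rows, comp_rows, bl_rows = [], [], [], [], []

    for chrom in chrom_names:
        L = chrom_lengths[chrom]
        sequence[chrom] = _random_sequence(rng, L, gc)

        # --- open regions (promoters / peaks), evenly spread with jitter
        centers = np.arange(open_region_spacing // 2, L, open_region_spacing)
        centers = centers + rng.integers(-5000, 5001, size=len(centers))
        centers = centers[(centers > 3500) & (centers < L - 3500)]
        half_open = 300
        for c in centers:
            open_rows.append((chrom, int(c - half_open), int(c + half_open),
                              float(open_multiplier)))

        # --- TSS: most open regions are promoters; assign TPM by tier later
        nfr_cores = [(int(c - nfr_halfwidth), int(c + nfr_halfwidth)) for c in centers]
        strands = rng.choice(["+", "-"], size=len(centers))
        tpms = rng.lognormal(mean=1.0, sigma=2.0, size=len(centers))
        tpms[rng.random(len(centers)) < 0.25] = 0.0  # silent genes
        for c, st, tpm in zip(centers, strands, tpms):
            tss_rows.append((chrom, int(c), st, float(tpm)))

        # --- nucleosome dyads, re-anchored at NFR edges
        core_starts = np.array([s for s, _ in nfr_cores])
        core_ends = np.array([e for _, e in nfr_cores])
        dyads = []
        pos = 100 + halfw
        while pos < L - halfw - 1:
            i = np.searchsorted(core_ends, pos - halfw, side="right")
            if i < len(core_starts) and pos + halfw >= core_starts[i]:
                pos = int(core_ends[i]) + halfw + 7  # phase reset past the NFR
                continue
            dyads.append(pos)
            pos += nucleosome_repeat + int(rng.integers(-repeat_jitter,
                                                        repeat_jitter + 1))
        dyads = np.asarray(dyads, dtype=np.int64)
        dyads_d[chrom] = dyads

        # --- occluded linkers (fiber compaction); NFR gaps stay accessible
        fp_end = dyads[:-1] + halfw + 1
        fp_start_next = dyads[1:] - halfw
        gap = fp_start_next - fp_end
        occludable = gap <= nucleosome_repeat  # exclude NFR-spanning gaps
        occ = occludable & (rng.random(len(gap)) < occluded_linker_fraction)
        occl_d[chrom] = np.column_stack([fp_end[occ], fp_start_next[occ]])

        # --- compartment blocks
        label0 = rng.integers(0, 2)
        n_blocks = max(1, L // block_size)
        for b in range(n_blocks):
            s = b * block_size
            e = (b + 1) * block_size if b < n_blocks - 1 else L
            label = "A" if (b + label0) % 2 == 0 else "B"
            mag = rng.uniform(0.4, 1.0)
            score = mag if label == "A" else -mag
            for bs in range(s, e, compartment_bin):
                be = min(bs + compartment_bin, e)
                comp_rows.append((chrom, bs, be, label, score))

        # --- CTCF sites with orientation
        sites = np.arange(ctcf_spacing, L - ctcf_spacing, ctcf_spacing)
        sites = sites + rng.integers(-8000, 8001, size=len(sites))
        orient = rng.choice(["+", "-"], size=len(sites))
        for p, o in zip(sites, orient):
            ctcf_rows.append((chrom, int(p), o))

        # --- blacklist, avoiding open regions
        n_bl = max(1, blacklist_per_mb * L // 1_000_000)
        placed = 0
        while placed < n_bl:
            w = int(rng.integers(2000, 8000))
            s = int(rng.integers(0, L - w))
            if np.any((core_starts - 3000 < s + w) & (core_ends + 3000 > s)):
                continue
            bl_rows.append((chrom, s, s + w))
            placed += 1

    tss = pd.DataFrame(tss_rows, columns=["chrom", "pos", "strand", "tpm"])
    # expression tiers over the whole transcript set (top 5%, 5-20%, bottom 20%)
    order = tss.sort_values(["tpm", "pos"], ascending=[False, True]).index
    n = len(tss)
    tier = pd.Series("other", index=tss.index)
    tier.loc[order[: max(1, int(0.05 * n))]] = "high"
    tier.loc[order[max(1, int(0.05 * n)): int(0.20 * n)]] = "intermediate"
    tier.loc[order[n - int(0.20 * n):]] = "non_expressed"
    tss["tier"] = tier

    genome = GenomeModel(
        chrom_names=chrom_names,
        chrom_lengths=chrom_lengths,
        sequence=sequence,
        nucleosome_dyads=dyads_d,
        open_regions=pd.DataFrame(
            open_rows, columns=["chrom", "start", "end", "multiplier"]
        ),
        tss=tss,
        ctcf_sites=pd.DataFrame(ctcf_rows, columns=["chrom", "pos", "strand"]),
        compartment_track=pd.DataFrame(
            comp_rows, columns=["chrom", "start", "end", "label", "score"]
        ),
        blacklist=pd.DataFrame(bl_rows, columns=["chrom", "start", "end"]),
        occluded_linkers=occl_d,
        protection_halfwidth=halfw,
        footprint_protection=footprint_protection,
        occluded_accessibility=occluded_accessibility,
    )
    genome.validate()
    return genome
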