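"""Proximity-ligation (Hi-C) pair simulator.

Ligation pairs are sampled cis with P(separation = s) proportional to
``s ** decay_exponent``, re-weighted by ``homotypic_boost`` when both ends
fall in the same compartment label and by ``loop_boost`` when the two ends
sit within ``anchor_window`` of the two anchors of a convergent CTCF site
pair.  A configurable fraction of output pairs are dangling ends (both
reads from one unligated fragment, inward-facing, separation equal to the
fragment length) or exact duplicates of earlier pairs.  Every emitted pair
carries its ground-truth class.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..hic import convergent_ctcf_pairs
from .digest import Fragment
from .genome import GenomeModel

__all__ = ["SimulatedPair", "simulate_hic"]


@dataclass(slots=True)
class SimulatedPair:
    """One simulated di-tag with ground truth."""

    read_id: str
    chrom1: str
    pos1: int
    strand1: str
    chrom2: str
    pos2: int
    strand2: str
    truth_class: str  # "ligation" | "dangling_end" | "duplicate_of:<id>"


class _ChromState:
    """Per-chromosome lookup tables for the sampler."""

    def __init__(self, genome: GenomeModel, chrom: str, anchor_window: int):
        self.length = genome.chrom_lengths[chrom]
        comp = genome.compartment_track
        comp = comp[comp["chrom"] == chrom]
        self.comp_starts = comp["start"].to_numpy()
        self.comp_labels = (comp["label"] == "A").to_numpy().astype(np.int8)
        sites = genome.ctcf_sites[genome.ctcf_sites["chrom"] == chrom]
        self.plus = np.sort(sites.loc[sites["strand"] == "+", "pos"].to_numpy())
        self.minus = np.sort(sites.loc[sites["strand"] == "-", "pos"].to_numpy())
        conv = convergent_ctcf_pairs(sites)
        self.conv_pairs = set(zip(conv["pos1"], conv["pos2"]))
        self.window = anchor_window

    def labels(self, pos: np.ndarray) -> np.ndarray:
        idx = np.searchsorted(self.comp_starts, pos, side="right") - 1
        return self.comp_labels[np.clip(idx, 0, len(self.comp_labels) - 1)]

    def _near(self, sites: np.ndarray, pos: int) -> list[int]:
        if not len(sites):
            return []
        i = np.searchsorted(sites, pos)
        out = []
        for j in (i - 1, i):
            if 0 <= j < len(sites) and abs(int(sites[j]) - pos) <= self.window:
                out.append(int(sites[j]))
        return out

    def is_loop(self, p1: int, p2: int) -> bool:
        for a in self._near(self.plus, p1):
            for b in self._near(self.minus, p2):
                if (a, b) in self.conv_pairs:
                    return True
        return False


def _sample_separation(rng, n, alpha, s_min, s_max):
    u = rng.random(n)
    if alpha == -1.0:
        return (s_min * (s_max / s_min) ** u).astype(np.int64)
    a1 = alpha + 1.0
    lo, hi = s_min ** a1, s_max ** a1
    return ((lo + u * (hi - lo)) ** (1.0 / a1)).astype(np.int64)


def simulate_hic(
    genome: GenomeModel,
    fragments: list[Fragment],
    n_pairs: int = 100_000,
    decay_exponent: float = -1.0,
    homotypic_boost: float = 3.0,
    loop_boost: float = 3.0,
    de_fraction: float = 0.05,
    dup_fraction: float = 0.05,
    min_sep: int = 10_000,
    anchor_window: int = 10_000,
    seed: int = 0,
) -> list[SimulatedPair]:
    """Sample ``n_pairs`` di-tags with known truth classes.

    ``fragments`` supplies the dangling-end molecules (pass the
    size-selected digestion output).  Mates are emitted in canonical order
    ((chrom1, pos1) <= (chrom2, pos2)).  Deterministic under ``seed``.
    """
    if decay_exponent >= 0:
        raise ValueError("decay_exponent must be < 0")
    for name, frac in (("de_fraction", de_fraction), ("dup_fraction", dup_fraction)):
        if not 0 <= frac < 1:
            raise ValueError(f"{name} must be in [0, 1)")
    if homotypic_boost < 1:
        raise ValueError("homotypic_boost must be >= 1")
    if loop_boost < 1:
        raise ValueError("loop_boost must be >= 1")
    if de_fraction > 0 and not fragments:
        raise ValueError("de_fraction > 0 requires fragments")

    rng = np.random.default_rng(seed)
    states = {c: _ChromState(genome, c, anchor_window) for c in genome.chrom_names}
    chrom_names = list(genome.chrom_names)
    lengths = np.array([genome.chrom_lengths[c] for c in chrom_names], dtype=float)
    chrom_p = lengths / lengths.sum()
    max_boost = homotypic_boost * loop_boost

    def sample_ligations(n_needed: int) -> list[tuple]:
        out: list[tuple] = []
        while len(out) < n_needed:
            m = max(1024, 2 * (n_needed - len(out)))
            ci = rng.choice(len(chrom_names), size=m, p=chrom_p)
            for k in np.unique(ci):
                chrom = chrom_names[k]
                st = states[chrom]
                idx = np.flatnonzero(ci == k)
                s = _sample_separation(rng, len(idx), decay_exponent,
                                       min_sep, st.length // 2)
                p1 = (rng.random(len(idx)) * (st.length - s)).astype(np.int64)
                p2 = p1 + s
                w = np.ones(len(idx))
                same = st.labels(p1) == st.labels(p2)
                w[same] *= homotypic_boost
                if loop_boost != 1.0 and st.conv_pairs:
                    looped = np.fromiter(
                        (st.is_loop(int(a), int(b)) for a, b in zip(p1, p2)),
                        dtype=bool, count=len(idx),
                    )
                    w[looped] *= loop_boost
                acc = rng.random(len(idx)) < w / max_boost
                str1 = rng.choice(["+", "-"], size=len(idx))
                str2 = rng.choice(["+", "-"], size=len(idx))
                for a, b, s1, s2, ok in zip(p1, p2, str1, str2, acc):
                    if ok:
                        out.append((chrom, int(a), s1, chrom, int(b), s2))
        return out[:n_needed]

    class_draw = rng.random(n_pairs)
    n_lig = int(np.sum(class_draw >= dup_fraction + de_fraction)) + 1
    ligations = iter(sample_ligations(n_lig))

    # dangling-end molecules are distinct library fragments: sample their
    # source fragments without replacement where possible, so accidental
    # exact repeats do not masquerade as PCR duplicates
    n_de = int(np.sum((class_draw >= dup_fraction)
                      & (class_draw < dup_fraction + de_fraction))) + 1
    if de_fraction > 0:
        if n_de <= len(fragments):
            de_idx = iter(rng.choice(len(fragments), size=n_de, replace=False))
        else:
            de_idx = iter(rng.integers(0, len(fragments), size=n_de))

    pairs: list[SimulatedPair] = []
    for i in range(n_pairs):
        rid = f"P{i:08d}"
        r = class_draw[i]
        if r < dup_fraction and pairs:
            src = pairs[int(rng.integers(0, len(pairs)))]
            pairs.append(SimulatedPair(
                rid, src.chrom1, src.pos1, src.strand1,
                src.chrom2, src.pos2, src.strand2,
                f"duplicate_of:{src.read_id}",
            ))
        elif r < dup_fraction + de_fraction:
            f = fragments[int(next(de_idx))]
            pairs.append(SimulatedPair(
                rid, f.chrom, f.start, "+", f.chrom, f.end, "-",
                "dangling_end",
            ))
        else:
            c1, a, s1, c2, b, s2 = next(ligations)
            pairs.append(SimulatedPair(rid, c1, a, s1, c2, b, s2, "ligation"))
    return pairs
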