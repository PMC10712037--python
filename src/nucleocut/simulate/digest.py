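"""Chromatin digestion simulator.

Cuts are drawn per simulated cell as independent per-base Bernoulli events
with hazard

    base_rate x accessibility(x) x linker_preference^(is_linker)
              x g_multiplier^(next base is G)

where ``base_rate = units * cut_rate / 1000`` per bp, accessibility encodes
nucleosome footprint protection, occluded linkers and open-chromatin bumps
(see :mod:`nucleocut.simulate.genome`), and the G multiplier is derived from
the enzyme's observable-scale ``g_bias``.  Consecutive cuts on a chromosome
delimit fragments; enzyme-specific end chemistry (nicks, 3'-overhang
blunting, exonucleolytic trimming) is applied afterwards.

Cut positions are bond indices: a cut at bond ``p`` severs the backbone
between bases ``p-1`` and ``p``, so base ``p`` is the first base of the
downstream fragment.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np

from .enzymes import EnzymeModel
from .genome import GenomeModel

__all__ = ["Fragment", "digest", "size_select", "cut_hazard"]

_MAX_HAZARD = 0.5


@dataclass(slots=True)
class Fragment:
    """One digestion product (0-based half-open coordinates)."""

    chrom: str
    start: int
    end: int
    left_end_is_nick: bool = False
    right_end_is_nick: bool = False
    cell: int = 0

    @property
    def length(self) -> int:
        return self.end - self.start


def _g_multiplier(g_bias: float, g_freq: float) -> float:
    """Per-site hazard multiplier that realizes a frequency fold-enrichment
    of ``g_bias`` for G at the cut +1 position, given genomic G frequency.

    With multiplier m the expected frequency of G among cut sites is
    m*f / (1 + (m-1)*f), so m = g*(1-f) / (1 - g*f).
    """
    if g_bias == 1.0:
        return 1.0
    if g_bias * g_freq >= 1.0:
        raise ValueError(
            f"g_bias {g_bias} unattainable at G frequency {g_freq:.3f}"
        )
    return g_bias * (1.0 - g_freq) / (1.0 - g_bias * g_freq)


def accessibility_profile(genome: GenomeModel, chrom: str) -> np.ndarray:
    """Per-base accessibility multiplier for one chromosome."""
    L = genome.chrom_lengths[chrom]
    acc = np.ones(L)
    fp_s, fp_e = genome.footprints(chrom)
    for s, e in zip(fp_s, fp_e):
        acc[max(s, 0):e] = genome.footprint_protection
    for s, e in genome.occluded_linkers[chrom]:
        acc[s:e] = genome.occluded_accessibility
    op = genome.open_regions[genome.open_regions["chrom"] == chrom]
    for _, row in op.iterrows():
        s, e, mult = int(row["start"]), int(row["end"]), float(row["multiplier"])
        x = np.arange(s, e)
        center, halfw = (s + e) / 2, (e - s) / 2
        bump = 1.0 + (mult - 1.0) * (1.0 - np.abs(x - center) / halfw)
        acc[s:e] = np.maximum(acc[s:e], 1.0) * bump
    return acc


def cut_hazard(genome: GenomeModel, enzyme: EnzymeModel, chrom: str) -> np.ndarray:
    """Per-bond cutting probability for one chromosome.

    Index ``p`` is the bond 5' of base ``p``; ``hazard[0]`` is zero (a cut
    at the chromosome start is not observable as a fragment boundary).
    """
    L = genome.chrom_lengths[chrom]
    base_rate = enzyme.units * enzyme.cut_rate / 1000.0
    acc = accessibility_profile(genome, chrom)

    if enzyme.recognition_site is not None:
        # restriction digestion runs to near-completion in Hi-C protocols;
        # model it as site-anchored cutting independent of accessibility
        h = np.zeros(L)
        p_site = min(0.95, enzyme.units * enzyme.cut_rate)
        for m in re.finditer(enzyme.recognition_site, genome.sequence[chrom]):
            h[m.start()] = p_site
        h[0] = 0.0
        return h

    fp_s, fp_e = genome.footprints(chrom)
    in_fp = np.zeros(L, dtype=bool)
    for s, e in zip(fp_s, fp_e):
        in_fp[max(s, 0):e] = True
    h = base_rate * acc
    h[~in_fp] *= enzyme.linker_preference
    if enzyme.g_bias != 1.0:
        f_g = genome.base_frequencies()["G"]
        m = _g_multiplier(enzyme.g_bias, f_g)
        h[genome.seq_array(chrom) == ord("G")] *= m
    h[0] = 0.0
    return np.clip(h, 0.0, _MAX_HAZARD)


def _trim_left(starts, trims, fp_s, fp_e):
    """Trim fragment starts rightward, stopping at footprint boundaries."""
    idx = np.searchsorted(fp_s, starts, side="right")
    inside = np.zeros(len(starts), dtype=bool)
    has_prev = idx > 0
    inside[has_prev] = fp_e[idx[has_prev] - 1] > starts[has_prev]
    cap = np.where(idx < len(fp_s), fp_s[np.minimum(idx, len(fp_s) - 1)],
                   np.iinfo(np.int64).max)
    cap[inside] = starts[inside]  # already protected: no trimming
    return np.minimum(starts + trims, cap)


def _trim_right(ends, trims, fp_s, fp_e):
    """Trim fragment ends leftward, stopping at footprint boundaries."""
    idx = np.searchsorted(fp_s, ends, side="right")
    inside = np.zeros(len(ends), dtype=bool)
    has_prev = idx > 0
    inside[has_prev] = fp_e[idx[has_prev] - 1] > ends[has_prev]
    j = np.searchsorted(fp_e, ends, side="right") - 1
    cap = np.where(j >= 0, fp_e[np.maximum(j, 0)], 0)
    cap[inside] = ends[inside]
    return np.maximum(ends - trims, cap)


def digest(
    genome: GenomeModel,
    enzyme: EnzymeModel,
    n_cells: int = 1,
    seed: int = 0,
) -> list[Fragment]:
    """Digest the genome in ``n_cells`` simulated cells.

    Returns fragments ordered by (cell, chromosome, start); within one cell
    and chromosome, fragments are non-overlapping and tile the cut region.
    A zero ``cut_rate`` yields an empty list.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    fragments: list[Fragment] = []
    for ci, chrom in enumerate(genome.chrom_names):
        h = cut_hazard(genome, enzyme, chrom)
        if h.max() <= 0:
            continue
        fp_s, fp_e = genome.footprints(chrom)
        for cell in range(n_cells):
            # independent streams so cut draws are matched across enzyme
            # settings with the same seed (hazard coupling)
            rng_cut = np.random.default_rng([seed, ci, cell, 0])
            rng_post = np.random.default_rng([seed, ci, cell, 1])
            cuts = np.flatnonzero(rng_cut.random(len(h)) < h)
            nick_pos = np.empty(0, dtype=np.int64)
            if enzyme.nick_fraction > 0 and cuts.size:
                is_nick = rng_post.random(cuts.size) < enzyme.nick_fraction
                nick_pos = cuts[is_nick]
                cuts = cuts[~is_nick]
            if cuts.size < 2:
                continue
            starts = cuts[:-1].copy()
            ends = cuts[1:].copy()
            if enzyme.overhang_3p > 0:
                # asymmetric cleavage: blunting recesses the right end
                ends = ends - enzyme.overhang_3p
            if enzyme.exo_trim > 0 and len(fp_s):
                t_l = np.rint(rng_post.exponential(enzyme.exo_trim,
                                                   starts.size)).astype(np.int64)
                t_r = np.rint(rng_post.exponential(enzyme.exo_trim,
                                                   ends.size)).astype(np.int64)
                starts = _trim_left(starts, t_l, fp_s, fp_e)
                ends = _trim_right(ends, t_r, fp_s, fp_e)
            keep = ends > starts
            starts, ends = starts[keep], ends[keep]
            left_nick = np.zeros(starts.size, dtype=bool)
            right_nick = np.zeros(starts.size, dtype=bool)
            if nick_pos.size and starts.size:
                fi = np.searchsorted(starts, nick_pos, side="right") - 1
                ok = (fi >= 0) & (nick_pos < ends[np.maximum(fi, 0)])
                fi, npos = fi[ok], nick_pos[ok]
                left_side = (npos - starts[fi]) <= (ends[fi] - npos)
                left_nick[fi[left_side]] = True
                right_nick[fi[~left_side]] = True
            fragments.extend(
                Fragment(chrom, int(s), int(e), bool(ln), bool(rn), cell)
                for s, e, ln, rn in zip(starts, ends, left_nick, right_nick)
            )
    return fragments


def size_select(fragments: list[Fragment], max_len: int) -> list[Fragment]:
    """Keep fragments with length <= ``max_len`` (inclusive), preserving
    order — the in-silico analogue of bead-based size selection."""
    if max_len <= 0:
        raise ValueError("max_len must be > 0")
    return [f for f in fragments if f.length <= max_len]
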