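"""Nuclease cut-site extraction and characterization.

The exact cut position is recovered from the cut-proximal end of each
aligned read: for a forward read the cut bond lies immediately 5' of the
first aligned base; for a reverse read immediately 3' of the last aligned
base.  Reads with clips/indels (CIGAR other than a single match run) or a
mismatch at the cut-proximal base are discarded, because there the aligned
end cannot be trusted to mark the cut.

Conventions: cut positions are 0-based bond indices — a cut at ``pos``
lies between reference bases ``pos - 1`` and ``pos``.  For forward reads
this equals the 0-based leftmost aligned position; for reverse reads it is
one past the rightmost aligned base (derived from the CIGAR span, or from
``fixed_span`` for compatibility with fixed-length pipelines).
"""

from __future__ import annotations

import os
import re
import tempfile
from dataclasses import dataclass, field

import numpy as np
import pysam
from scipy.signal import find_peaks

from .tracks import SignalTrack

__all__ = [
    "CutEvent",
    "SizeHistogram",
    "ContextMatrix",
    "extract_cuts",
    "cut_track",
    "fragment_sizes",
    "context_enrichment",
]

_MD_FWD_MISMATCH = re.compile(r"^0[ACGTN]")
_MD_REV_MISMATCH = re.compile(r"[ACGTN]0$")


@dataclass(slots=True)
class CutEvent:
    """A strand-resolved single-base cut position (0-based bond index)."""

    chrom: str
    pos: int
    strand: str  # '+': event from a forward read (fragment 5' end)


@dataclass
class SizeHistogram:
    """Pair-level fragment-size distribution with detected modes."""

    bin_edges: np.ndarray
    counts: np.ndarray
    modal_length: float
    modes: list[tuple[float, float]]  # (bin center, count) incl. the primary
    n_pairs: int
    n_skipped: int


@dataclass
class ContextMatrix:
    """Base composition around cut sites, on the reference strand of the
    sequenced fragment (reverse-strand events reverse-complemented so that
    offset +1 is always the first base inside the fragment)."""

    offsets: np.ndarray  # -k..-1, +1..+k (the bond itself has no base)
    frequencies: dict[str, np.ndarray]  # base -> per-offset frequency
    background: dict[str, float]
    enrichment: dict[str, np.ndarray]  # freq / background; NaN if undefined
    n_events: int
    undefined: dict[str, bool] = field(default_factory=dict)


def _open_alignments(source):
    """Accept a path, an open AlignmentFile, or raw SAM text."""
    if isinstance(source, pysam.AlignmentFile):
        return source, None
    if isinstance(source, str) and "\n" in source:
        tmp = tempfile.NamedTemporaryFile(
            "w", suffix=".sam", delete=False)
        tmp.write(source)
        tmp.close()
        return pysam.AlignmentFile(tmp.name, "r", check_sq=False), tmp.name
    return pysam.AlignmentFile(source, "r", check_sq=False), None


def _blacklist_index(blacklist):
    """Per-chrom sorted (starts, ends) arrays from a BED-like frame."""
    idx = {}
    if blacklist is None or not len(blacklist):
        return idx
    for chrom, sub in blacklist.groupby("chrom"):
        sub = sub.sort_values("start")
        idx[chrom] = (sub["start"].to_numpy(), sub["end"].to_numpy())
    return idx


def _in_blacklist(idx, chrom, pos) -> bool:
    if chrom not in idx:
        return False
    starts, ends = idx[chrom]
    i = np.searchsorted(starts, pos, side="right") - 1
    return i >= 0 and pos < ends[i]


def extract_cuts(
    source,
    blacklist=None,
    fixed_span: int | None = None,
) -> tuple[list[CutEvent], dict[str, int]]:
    """Extract one cut event per passing read.

    Forward reads must have a single match-run CIGAR and no mismatch at the
    first aligned base (MD not starting ``0<base>``); the event is the
    leftmost aligned position.  Reverse reads analogously at the 3' end
    (MD not ending ``<base>0``); the event is one past the rightmost
    aligned base.  ``fixed_span`` replaces the CIGAR-derived span for
    reverse reads, reproducing fixed-read-length pipelines (e.g. span 100
    recovers the classic ``POS + 99`` arithmetic on 1-based input).

    Returns the events and a dictionary of per-filter drop counts.
    """
    counts = {
        "total": 0, "unmapped": 0, "secondary": 0, "no_md": 0,
        "cigar": 0, "terminal_mismatch": 0, "blacklist": 0, "pass": 0,
    }
    bl_idx = _blacklist_index(blacklist)
    events: list[CutEvent] = []
    af, tmp_path = _open_alignments(source)
    try:
        for read in af:
            counts["total"] += 1
            if read.is_unmapped:
                counts["unmapped"] += 1
                continue
            if read.is_secondary or read.is_supplementary:
                counts["secondary"] += 1
                continue
            ct = read.cigartuples
            if ct is None or len(ct) != 1 or ct[0][0] != 0:
                counts["cigar"] += 1
                continue
            try:
                md = read.get_tag("MD")
            except KeyError:
                counts["no_md"] += 1
                continue
            if not read.is_reverse:
                if _MD_FWD_MISMATCH.match(md):
                    counts["terminal_mismatch"] += 1
                    continue
                pos, strand = read.reference_start, "+"
            else:
                if _MD_REV_MISMATCH.search(md):
                    counts["terminal_mismatch"] += 1
                    continue
                span = fixed_span if fixed_span is not None else ct[0][1]
                pos, strand = read.reference_start + span, "-"
            if _in_blacklist(bl_idx, read.reference_name, pos):
                counts["blacklist"] += 1
                continue
            counts["pass"] += 1
            events.append(CutEvent(read.reference_name, pos, strand))
    finally:
        af.close()
        if tmp_path:
            os.unlink(tmp_path)
    return events, counts


def cut_track(
    events: list[CutEvent],
    chrom_sizes: dict[str, int],
    bin_size: int = 1,
) -> SignalTrack:
    """Count cut events per bin; total track mass equals the event count.

    An event at ``pos == chrom_length`` (a cut bond at the chromosome end)
    is counted in the last bin; positions beyond that raise.
    """
    track = SignalTrack.zeros(chrom_sizes, bin_size)
    for ev in events:
        if ev.chrom not in chrom_sizes:
            raise ValueError(f"event on unknown chromosome: {ev}")
        size = chrom_sizes[ev.chrom]
        if ev.pos > size or ev.pos < 0:
            raise ValueError(f"event beyond chromosome end: {ev}")
        b = min(ev.pos, size - 1) // bin_size
        track.data[ev.chrom][b] += 1
    return track


def fragment_sizes(
    source,
    bin_width: int = 1,
    max_size: int = 2000,
    mode_bin: int = 20,
    prominence: float = 0.25,
) -> SizeHistogram:
    """Histogram of absolute outer distances (|TLEN|) per read pair.

    Each pair is counted once (via its leftmost mate); pairs with TLEN 0
    are skipped and counted.  ``modal_length`` is the center of the
    fullest ``bin_width`` bin.  Secondary modes are local maxima of the
    distribution re-binned at ``mode_bin`` bp whose height exceeds
    ``prominence`` times the global maximum.
    """
    sizes = []
    n_skipped = 0
    af, tmp_path = _open_alignments(source)
    try:
        for read in af:
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            if not read.is_read1:
                continue
            if read.template_length == 0:
                n_skipped += 1
                continue
            sizes.append(abs(read.template_length))
    finally:
        af.close()
        if tmp_path:
            os.unlink(tmp_path)
    if not sizes:
        raise ValueError("no pairs with nonzero TLEN")
    sizes = np.array(sizes)
    sizes = sizes[sizes <= max_size]
    edges = np.arange(0, max_size + bin_width, bin_width)
    counts, _ = np.histogram(sizes, bins=edges)
    # at 1-bp resolution the bin IS the size; otherwise report bin centers
    centers = (edges[:-1] if bin_width == 1
               else edges[:-1] + bin_width / 2)
    modal_length = float(centers[int(np.argmax(counts))])

    medges = np.arange(0, max_size + mode_bin, mode_bin)
    mcounts, _ = np.histogram(sizes, bins=medges)
    mcenters = medges[:-1] + mode_bin / 2
    peaks, _ = find_peaks(np.concatenate([[0.0], mcounts, [0.0]]))
    peaks -= 1
    gmax = mcounts.max()
    modes = [
        (float(mcenters[p]), float(mcounts[p]))
        for p in peaks
        if mcounts[p] >= prominence * gmax
    ]
    modes.sort(key=lambda m: -m[1])
    return SizeHistogram(
        bin_edges=edges, counts=counts, modal_length=modal_length,
        modes=modes, n_pairs=int(len(sizes)), n_skipped=n_skipped,
    )


_COMP = bytes.maketrans(b"ACGT", b"TGCA")


class _SeqDict:
    """Adapter giving a dict of sequence strings the genome-model API."""

    def __init__(self, sequences: dict[str, str]):
        self._arrays = {
            c: np.frombuffer(s.encode(), dtype=np.uint8)
            for c, s in sequences.items()
        }

    def seq_array(self, chrom: str) -> np.ndarray:
        return self._arrays[chrom]

    def base_frequencies(self) -> dict[str, float]:
        counts = {b: 0 for b in "ACGT"}
        for arr in self._arrays.values():
            for b in "ACGT":
                counts[b] += int((arr == ord(b)).sum())
        total = sum(counts.values())
        return {b: c / total for b, c in counts.items()}


def context_enrichment(events, genome, k: int = 5) -> ContextMatrix:
    """Base frequencies and enrichment at offsets -k..+k around cut bonds.

    Offsets are counted along the sequenced fragment: +1 is the first base
    inside the fragment, -1 the first base outside.  Reverse-strand events
    are reverse-complemented onto this frame.  Enrichment is frequency
    divided by genome-wide mononucleotide frequency; events within ``k`` of
    a chromosome end are excluded.
    """
    if not events:
        raise ValueError("no cut events: context is undefined")
    if isinstance(genome, dict):
        genome = _SeqDict(genome)
    offsets = np.array([o for o in range(-k, k + 1) if o != 0])
    base_counts = {b: np.zeros(len(offsets), dtype=np.int64) for b in "ACGT"}
    n_used = 0

    by_chrom: dict[tuple[str, str], list[int]] = {}
    for ev in events:
        by_chrom.setdefault((ev.chrom, ev.strand), []).append(ev.pos)

    for (chrom, strand), poss in by_chrom.items():
        arr = genome.seq_array(chrom)
        L = len(arr)
        pos = np.asarray(poss)
        pos = pos[(pos >= k + 1) & (pos <= L - k - 1)]
        if not len(pos):
            continue
        n_used += len(pos)
        for oi, o in enumerate(offsets):
            if strand == "+":
                # bond at p: base at offset o>0 is seq[p+o-1], o<0 is seq[p+o]
                gidx = pos + (o - 1 if o > 0 else o)
                bases = arr[gidx]
            else:
                # mirrored: offset o>0 is comp(seq[p-o]), o<0 comp(seq[p-o-1])
                gidx = pos - (o if o > 0 else o + 1)
                bases = np.frombuffer(
                    arr[gidx].tobytes().translate(_COMP), dtype=np.uint8
                )
            for b in "ACGT":
                base_counts[b][oi] += int((bases == ord(b)).sum())

    if n_used == 0:
        raise ValueError("all events within k of a chromosome end")
    background = genome.base_frequencies()
    frequencies = {b: base_counts[b] / n_used for b in "ACGT"}
    enrichment, undefined = {}, {}
    for b in "ACGT":
        if background[b] == 0:
            enrichment[b] = np.full(len(offsets), np.nan)
            undefined[b] = True
        else:
            enrichment[b] = frequencies[b] / background[b]
            undefined[b] = False
    return ContextMatrix(
        offsets=offsets, frequencies=frequencies, background=background,
        enrichment=enrichment, n_events=n_used, undefined=undefined,
    )
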