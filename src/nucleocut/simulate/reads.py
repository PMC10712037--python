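"""Render digestion fragments as aligned paired-end reads (SAM text).

Each fragment yields one proper pair: a forward read starting at the
fragment start and a reverse read ending at the fragment end, both with a
single match-run CIGAR of ``min(read_len, fragment_length)`` and a perfect
MD tag.  An optional terminal mismatch (at the cut-proximal base) can be
injected at a configurable rate to exercise downstream cut-site filters.
Internal coordinates are 0-based half-open; the SAM writer converts to
1-based POS.
"""

from __future__ import annotations

import logging

import numpy as np

from .digest import Fragment
from .genome import GenomeModel

__all__ = ["fragments_to_sam"]

logger = logging.getLogger(__name__)

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def _mismatch_base(rng: np.random.Generator, ref: str) -> str:
    choices = [b for b in "ACGT" if b != ref]
    return choices[rng.integers(0, 3)]


def fragments_to_sam(
    fragments: list[Fragment],
    genome: GenomeModel,
    read_len: int = 150,
    seed: int = 0,
    mismatch_rate: float = 0.0,
    min_frag_len: int = 30,
) -> str:
    """Return SAM text for one proper pair per fragment.

    Fragments shorter than ``min_frag_len`` are skipped (and the skip count
    logged) — the in-silico analogue of library molecules too short to
    sequence.  Deterministic under ``seed``.
    """
    if read_len < 30:
        raise ValueError("read_len must be >= 30")
    rng = np.random.default_rng(seed)
    lines = ["@HD\tVN:1.6\tSO:coordinate"]
    for chrom in genome.chrom_names:
        lines.append(f"@SQ\tSN:{chrom}\tLN:{genome.chrom_lengths[chrom]}")

    n_skipped = 0
    records: list[tuple[str, int, str]] = []  # (chrom, pos, line) for sorting
    for i, frag in enumerate(fragments):
        flen = frag.length
        if flen < min_frag_len:
            n_skipped += 1
            continue
        span = min(read_len, flen)
        qname = f"rd{i:08d}"
        seq = genome.sequence[frag.chrom]

        fwd_start = frag.start
        rev_start = frag.end - span
        fwd_seq = seq[fwd_start:fwd_start + span]
        rev_seq = seq[rev_start:rev_start + span]
        fwd_md, rev_md = str(span), str(span)
        fwd_nm, rev_nm = 0, 0
        if mismatch_rate > 0:
            if rng.random() < mismatch_rate:  # forward: first aligned base
                ref = fwd_seq[0]
                fwd_seq = _mismatch_base(rng, ref) + fwd_seq[1:]
                fwd_md, fwd_nm = f"0{ref}{span - 1}", 1
            if rng.random() < mismatch_rate:  # reverse: last aligned base
                ref = rev_seq[-1]
                rev_seq = rev_seq[:-1] + _mismatch_base(rng, ref)
                rev_md, rev_nm = f"{span - 1}{ref}0", 1

        qual = "I" * span
        cigar = f"{span}M"
        fwd = (
            f"{qname}\t99\t{frag.chrom}\t{fwd_start + 1}\t60\t{cigar}\t=\t"
            f"{rev_start + 1}\t{flen}\t{fwd_seq}\t{qual}\t"
            f"NM:i:{fwd_nm}\tMD:Z:{fwd_md}"
        )
        rev = (
            f"{qname}\t147\t{frag.chrom}\t{rev_start + 1}\t60\t{cigar}\t=\t"
            f"{fwd_start + 1}\t{-flen}\t{rev_seq}\t{qual}\t"
            f"NM:i:{rev_nm}\tMD:Z:{rev_md}"
        )
        records.append((frag.chrom, fwd_start, fwd))
        records.append((frag.chrom, rev_start, rev))

    if n_skipped:
        logger.info("fragments_to_sam: skipped %d fragments shorter than %d bp",
                    n_skipped, min_frag_len)
    chrom_rank = {c: i for i, c in enumerate(genome.chrom_names)}
    records.sort(key=lambda r: (chrom_rank[r[0]], r[1]))
    lines.extend(r[2] for r in records)
    return "\n".join(lines) + "\n"
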