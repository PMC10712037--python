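"""Text-format writers for simulator output.

All formats are the plain-text genomics standards: FASTA for the genome,
SAM for fragment reads, 7-column pairs text plus a truth TSV for Hi-C
di-tags, BED for intervals (CTCF with a strand column), and bedGraph for
the compartment score track.
"""

from __future__ import annotations

import pandas as pd

from .genome import GenomeModel

__all__ = [
    "write_fasta",
    "write_sam",
    "write_pairs",
    "write_truth",
    "write_bed",
    "write_ctcf_bed",
    "write_compartment_bedgraph",
]


def write_fasta(genome: GenomeModel, path: str, width: int = 60) -> None:
    with open(path, "w") as fh:
        for chrom in genome.chrom_names:
            fh.write(f">{chrom}\n")
            seq = genome.sequence[chrom]
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def write_sam(sam_text: str, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(sam_text)


def write_pairs(pairs, path: str) -> None:
    """readID chrom1 pos1 strand1 chrom2 pos2 strand2, one pair per line."""
    with open(path, "w") as fh:
        for p in pairs:
            fh.write(f"{p.read_id}\t{p.chrom1}\t{p.pos1}\t{p.strand1}\t"
                     f"{p.chrom2}\t{p.pos2}\t{p.strand2}\n")


def write_truth(pairs, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\ttruth_class\n")
        for p in pairs:
            fh.write(f"{p.read_id}\t{p.truth_class}\n")


def write_bed(df: pd.DataFrame, path: str) -> None:
    df[["chrom", "start", "end"]].to_csv(
        path, sep="\t", header=False, index=False)


def write_ctcf_bed(sites: pd.DataFrame, path: str) -> None:
    """BED6 with the orientation in the strand column."""
    out = pd.DataFrame({
        "chrom": sites["chrom"],
        "start": sites["pos"],
        "end": sites["pos"] + 1,
        "name": "CTCF",
        "score": 0,
        "strand": sites["strand"],
    })
    out.to_csv(path, sep="\t", header=False, index=False)


def write_compartment_bedgraph(genome: GenomeModel, path: str) -> None:
    genome.compartment_track[["chrom", "start", "end", "score"]].to_csv(
        path, sep="\t", header=False, index=False)
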