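"""Cut-site extraction: filters, coordinates, and the classic text-pipeline
oracle on fixed-length alignments."""

import re

import numpy as np
import pandas as pd
import pytest

from nucleocut import cutsites, simulate

HEADER = "@HD\tVN:1.6\tSO:coordinate\n@SQ\tSN:chr1\tLN:200000\n"


def sam_line(qname, flag, pos, cigar, md, tlen=100):
    # SEQ/QUAL omitted ('*') so CIGARs of any span parse cleanly
    return (f"{qname}\t{flag}\tchr1\t{pos}\t60\t{cigar}\t=\t{pos}\t{tlen}\t"
            f"*\t*\tMD:Z:{md}")


class TestExtractCuts:
    def test_forward_event_is_leftmost_position(self):
        sam = HEADER + sam_line("r1", 0, 1001, "150M", "150") + "\n"
        events, counts = cutsites.extract_cuts(sam)
        assert len(events) == 1
        assert (events[0].chrom, events[0].pos, events[0].strand) == \
            ("chr1", 1000, "+")
        assert counts["pass"] == 1

    def test_forward_terminal_mismatch_filtered(self):
        sam = HEADER + sam_line("r1", 0, 1001, "150M", "0A149") + "\n"
        events, counts = cutsites.extract_cuts(sam)
        assert events == []
        assert counts["terminal_mismatch"] == 1

    def test_reverse_event_is_one_past_end(self):
        sam = HEADER + sam_line("r1", 16, 1001, "100M", "100") + "\n"
        events, _ = cutsites.extract_cuts(sam)
        assert (events[0].pos, events[0].strand) == (1100, "-")

    def test_reverse_terminal_mismatch_filtered(self):
        sam = HEADER + sam_line("r1", 16, 1001, "100M", "99A0") + "\n"
        events, counts = cutsites.extract_cuts(sam)
        assert events == []
        assert counts["terminal_mismatch"] == 1

    def test_fixed_span_overrides_cigar(self):
        sam = HEADER + sam_line("r1", 16, 1001, "150M", "150") + "\n"
        events, _ = cutsites.extract_cuts(sam, fixed_span=100)
        assert events[0].pos == 1100  # not 1150

    def test_non_single_match_cigar_filtered(self):
        sam = HEADER + "\n".join([
            sam_line("r1", 0, 1001, "50M1I49M", "99"),
            sam_line("r2", 0, 2001, "10S90M", "90"),
        ]) + "\n"
        events, counts = cutsites.extract_cuts(sam)
        assert events == [] and counts["cigar"] == 2

    def test_missing_md_and_unmapped_counted(self):
        no_md = "r1\t0\tchr1\t100\t60\t50M\t=\t100\t50\t*\t*"
        unmapped = sam_line("r2", 4, 0, "*", "0")
        sam = HEADER + no_md + "\n" + unmapped + "\n"
        events, counts = cutsites.extract_cuts(sam)
        assert events == []
        assert counts["no_md"] == 1 and counts["unmapped"] == 1

    def test_blacklisted_events_dropped(self):
        bl = pd.DataFrame({"chrom": ["chr1"], "start": [900], "end": [1100]})
        sam = HEADER + "\n".join([
            sam_line("r1", 0, 1001, "150M", "150"),   # pos 1000, inside
            sam_line("r2", 0, 5001, "150M", "150"),   # pos 5000, outside
        ]) + "\n"
        events, counts = cutsites.extract_cuts(sam, blacklist=bl)
        assert [e.pos for e in events] == [5000]
        assert counts["blacklist"] == 1


def awk_oracle(sam_text):
    """Literal transcription of the classic samtools/awk filters for
    100-bp alignments: forward keeps ``^[0-9]+M`` CIGARs without
    ``MD:Z:0[ACTG]`` anywhere in the line and prints POS (1-based);
    reverse keeps single-M-run CIGARs without ``[ACTG]0`` before a field
    separator or line end, printing POS + 99."""
    fwd, rev = [], []
    for line in sam_text.splitlines():
        if line.startswith("@"):
            continue
        f = line.split("\t")
        flag, pos, cigar = int(f[1]), int(f[3]), f[5]
        if flag & 16 == 0:
            if (re.search(r"^[0-9]+M", cigar)
                    and not re.search(r"MD:Z:0[ACTG]", line)):
                fwd.append((f[2], pos))
        else:
            if (re.search(r"M$", cigar) and re.search(r"^[0-9]+M", cigar)
                    and not re.search(r"[ACTG]0[\t ]", line)
                    and not re.search(r"[ACTG]0$", line)):
                rev.append((f[2], pos + 99))
    return fwd, rev


@pytest.fixture(scope="module")
def fixed_length_sam(genome_small):
    # fragments >= 100 bp so every read is exactly 100M
    frags = simulate.digest(genome_small, simulate.s1(300), n_cells=1, seed=13)
    frags = [f for f in frags if f.length >= 100][:2000]
    return simulate.fragments_to_sam(frags, genome_small, read_len=100,
                                     mismatch_rate=0.3, seed=14)


def test_awk_oracle_equivalence_on_fixed_length_reads(fixed_length_sam):
    """On 100M-only alignments the generalized extractor must reproduce
    the classic awk pipeline position-for-position."""
    events, _ = cutsites.extract_cuts(fixed_length_sam)
    ours_fwd = [(e.chrom, e.pos + 1) for e in events if e.strand == "+"]
    ours_rev = [(e.chrom, e.pos) for e in events if e.strand == "-"]
    awk_fwd, awk_rev = awk_oracle(fixed_length_sam)
    assert ours_fwd == awk_fwd
    assert ours_rev == awk_rev


class TestCutTrack:
    def test_counts_accumulate(self):
        events = [cutsites.CutEvent("chr1", 10, "+")] * 3
        track = cutsites.cut_track(events, {"chr1": 100})
        assert track.data["chr1"][10] == 3
        assert track.total() == 3

    def test_empty_events_zero_track(self):
        track = cutsites.cut_track([], {"chr1": 50})
        assert track.total() == 0

    def test_mass_equals_per_chrom_counts(self):
        rng = np.random.default_rng(3)
        sizes = {"chr1": 1000, "chr2": 500}
        events = [
            cutsites.CutEvent(c, int(rng.integers(0, sizes[c])), "+")
            for c in rng.choice(["chr1", "chr2"], 500)
        ]
        track = cutsites.cut_track(events, sizes)
        for c in sizes:
            n = sum(1 for e in events if e.chrom == c)
            assert track.data[c].sum() == n

    def test_event_beyond_end_raises(self):
        with pytest.raises(ValueError, match="beyond"):
            cutsites.cut_track([cutsites.CutEvent("chr1", 200, "+")],
                               {"chr1": 100})


def test_mass_conservation_through_pipeline(genome_small):
    """events in = track mass + blacklist-dropped + filter-dropped."""
    frags = simulate.digest(genome_small, simulate.s1(500), n_cells=1, seed=19)
    frags = [f for f in frags if f.length >= 40][:3000]
    sam = simulate.fragments_to_sam(frags, genome_small, mismatch_rate=0.2,
                                    seed=20)
    events, counts = cutsites.extract_cuts(sam,
                                           blacklist=genome_small.blacklist)
    track = cutsites.cut_track(events, genome_small.chrom_lengths)
    assert track.total() == counts["pass"] == len(events)
    assert counts["total"] == (counts["pass"] + counts["terminal_mismatch"]
                               + counts["blacklist"] + counts["cigar"]
                               + counts["no_md"] + counts["unmapped"]
                               + counts["secondary"])
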