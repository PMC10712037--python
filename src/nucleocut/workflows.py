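"""End-to-end simulation studies at their canonical conditions.

Each function runs one complete in-silico experiment — generate chromatin,
digest, sequence, analyze — at the study conditions the package is
calibrated for (2-4 Mb genomes, a handful of simulated cells, ~10^5 Hi-C
pairs), and returns the measured quantities.  They are the single source
of truth for the worked examples, the test suite, and the reproduction
script.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import aggregate, coverage, cutsites, hic, simulate
from .tracks import SignalTrack

__all__ = [
    "mnase_limit_modal_length",
    "s1_fragment_size_modes",
    "s1_cut_context",
    "qc_class_recovery",
    "coverage_uniformity_iqr",
    "saddle_auc_vs_homotypic_boost",
    "open_chromatin_profile",
]


def _reads_sam(genome, fragments, seed, read_len=150):
    return simulate.fragments_to_sam(
        fragments, genome, read_len=read_len, seed=seed)


def mnase_limit_modal_length(
    seed: int = 0, length_bp: int = 2_000_000, n_cells: int = 4
) -> cutsites.SizeHistogram:
    """High-concentration MNase digestion of a nucleosome array.

    At high units the exonucleolytic trimming removes the linker DNA
    entirely, so the fragment-size distribution collapses onto the 147-bp
    protected footprint; the histogram (1-bp bins) is returned.
    """
    genome = simulate.make_genome(1, length_bp, 0.41, seed=seed)
    enzyme = simulate.mnase(units=1000)
    frags = simulate.digest(genome, enzyme, n_cells=n_cells, seed=seed + 1)
    frags = simulate.size_select(frags, 1000)
    sam = _reads_sam(genome, frags, seed + 2)
    return cutsites.fragment_sizes(sam, bin_width=1)


def s1_fragment_size_modes(
    seed: int = 0, length_bp: int = 2_000_000, n_cells: int = 4
) -> tuple[cutsites.SizeHistogram, float | None]:
    """High-units S1 digestion on 200-bp-repeat chromatin.

    Returns the fragment-size histogram and the center of the secondary
    (dinucleosome) mode — the qualifying local maximum in the 250-520 bp
    range — or None if no such mode reaches the prominence threshold.
    """
    genome = simulate.make_genome(1, length_bp, 0.41, seed=seed)
    enzyme = simulate.s1(units=1000)
    frags = simulate.digest(genome, enzyme, n_cells=n_cells, seed=seed + 1)
    frags = simulate.size_select(frags, 1000)
    sam = _reads_sam(genome, frags, seed + 2)
    hist = cutsites.fragment_sizes(sam, bin_width=1)
    secondary = [c for c, _ in hist.modes if 250 <= c <= 520]
    return hist, (secondary[0] if secondary else None)


def s1_cut_context(
    seed: int = 0, length_bp: int = 2_000_000, n_cells: int = 16, k: int = 5
) -> cutsites.ContextMatrix:
    """Full cut-site pipeline for S1: digest, render reads, extract cuts,
    and compute context enrichment at the fragment 5' ends (forward-read
    events), where the enzyme's G preference is observable.

    Moderate units are used: sequence context is a per-cut property, and a
    gentler digest keeps most products sequenceable so the measured
    context is not distorted by loss of sub-30-bp molecules.
    """
    genome = simulate.make_genome(1, length_bp, 0.41, seed=seed)
    enzyme = simulate.s1(units=200)
    frags = simulate.digest(genome, enzyme, n_cells=n_cells, seed=seed + 1)
    frags = simulate.size_select(frags, 1000)
    sam = _reads_sam(genome, frags, seed + 2)
    events, _ = cutsites.extract_cuts(sam, blacklist=genome.blacklist)
    fwd = [e for e in events if e.strand == "+"]
    return cutsites.context_enrichment(fwd, genome, k=k)


@dataclass
class QCRecovery:
    """Configured vs. classified pair-class fractions."""

    configured: dict[str, float]
    truth_fractions: dict[str, float]
    classified_fractions: dict[str, float]
    n_pairs: int


def qc_class_recovery(
    seed: int = 0,
    n_pairs: int = 100_000,
    de_fraction: float = 0.2,
    dup_fraction: float = 0.05,
) -> QCRecovery:
    """Simulate a Hi-C library with known dangling-end and duplicate
    fractions and recover them with the geometric pair classifier."""
    genome = simulate.make_genome(1, 2_000_000, 0.41, seed=seed)
    frags = simulate.size_select(
        simulate.digest(genome, simulate.s1(1000), n_cells=1, seed=seed + 1),
        1000,
    )
    pairs = simulate.simulate_hic(
        genome, frags, n_pairs=n_pairs, de_fraction=de_fraction,
        dup_fraction=dup_fraction, seed=seed + 2,
    )
    df = hic.pairs_frame(pairs)
    truth = df["truth_class"].str.replace(r"duplicate_of:.*", "duplicate",
                                          regex=True)
    truth_frac = truth.value_counts(normalize=True).to_dict()
    _, report = hic.classify_pairs(df)
    classified = dict(report.fractions)
    classified["ligation"] = classified.pop("valid")
    return QCRecovery(
        configured={"dangling_end": de_fraction, "duplicate": dup_fraction,
                    "ligation": 1 - de_fraction - dup_fraction},
        truth_fractions={k: float(v) for k, v in truth_frac.items()},
        classified_fractions=classified,
        n_pairs=n_pairs,
    )


def _read_start_track(genome, fragments, read_len=150, bin_size=500):
    """Count both read 5' positions per bin (sequencing-coverage proxy)."""
    track = SignalTrack.zeros(genome.chrom_lengths, bin_size)
    for f in fragments:
        arr = track.data[f.chrom]
        arr[f.start // bin_size] += 1
        arr[max(f.start, f.end - read_len) // bin_size] += 1
    return track


def coverage_uniformity_iqr(
    seed: int = 0, length_bp: int = 2_000_000
) -> dict[str, float]:
    """Window-coverage IQR for a restriction-site digestion model vs. the
    sequence-agnostic S1 model at matched depth.

    Site-anchored cutting piles coverage around fixed genomic positions,
    widening the per-window RPKM-sum distribution; the returned IQRs
    quantify that contrast.
    """
    genome = simulate.make_genome(1, length_bp, 0.41, seed=seed)
    frag_sets = {}
    for name, enzyme in (
        ("S1", simulate.s1(1000)),
        ("RE", simulate.restriction("GATC", 1000)),
    ):
        frags = simulate.size_select(
            simulate.digest(genome, enzyme, n_cells=4, seed=seed + 1), 1000)
        frags = [f for f in frags if f.length >= 30]
        frag_sets[name] = frags
    depth = min(len(v) for v in frag_sets.values())
    rng = np.random.default_rng(seed + 9)
    out = {}
    for name, frags in frag_sets.items():
        idx = rng.choice(len(frags), size=depth, replace=False)
        sub = [frags[i] for i in sorted(idx)]
        counts = _read_start_track(genome, sub)
        rpkm = coverage.rpkm_track(counts)
        wc = coverage.window_coverage(rpkm, 500)
        out[name] = coverage.coverage_iqr(wc)
    return out


def saddle_auc_vs_homotypic_boost(
    seed: int = 0,
    boosts: tuple[float, ...] = (1.5, 3.0),
    n_pairs: int = 150_000,
    length_bp: int = 4_000_000,
    bin_size: int = 100_000,
) -> dict[float, float]:
    """Saddle AUC as a function of the simulator's homotypic boost.

    Stronger preference for same-compartment contacts must yield a larger
    compartmentalization score; the truth compartment score provides E1.
    """
    genome = simulate.make_genome(1, length_bp, 0.41, seed=seed)
    frags = simulate.size_select(
        simulate.digest(genome, simulate.s1(1000), n_cells=1, seed=seed + 1),
        1000,
    )
    comp = genome.compartment_track
    out = {}
    for boost in boosts:
        pairs = simulate.simulate_hic(
            genome, frags, n_pairs=n_pairs, homotypic_boost=boost,
            loop_boost=1.0, de_fraction=0.0, dup_fraction=0.0,
            seed=seed + 3,
        )
        df = hic.pairs_frame(pairs)
        cmap = hic.bin_pairs(df, genome.chrom_lengths, bin_size)
        cmap = hic.balance(cmap, min_nnz=3, mad_frac=0.0)
        # truth E1: compartment score at each bin midpoint
        e1 = np.empty(cmap.n_bins)
        for bi, row in cmap.bins.iterrows():
            mid = (row["start"] + row["end"]) // 2
            sub = comp[(comp["chrom"] == row["chrom"])
                       & (comp["start"] <= mid) & (comp["end"] > mid)]
            e1[bi] = sub["score"].iloc[0] if len(sub) else np.nan
        res = hic.saddle(cmap, e1, n_qbins=10)
        out[boost] = res.auc_score
    return out


def open_chromatin_profile(
    seed: int = 0, length_bp: int = 2_000_000, n_cells: int = 4,
    n_shuffles: int = 100,
) -> aggregate.AggregateProfile:
    """Cut-site signal around open-chromatin regions for high-units S1,
    with the shuffle-null band.

    Over-digestion of accessible DNA removes the shortest library
    molecules, so the observed cut signal dips below the null band at the
    region centers and rises on the positioned flanking nucleosomes.
    """
    genome = simulate.make_genome(1, length_bp, 0.41, seed=seed)
    frags = simulate.size_select(
        simulate.digest(genome, simulate.s1(1000), n_cells=n_cells,
                        seed=seed + 1),
        1000,
    )
    sam = _reads_sam(genome, frags, seed + 2)
    events, _ = cutsites.extract_cuts(sam, blacklist=genome.blacklist)
    track = cutsites.cut_track(events, genome.chrom_lengths)
    # desk-scale depth: a light moving average stabilizes the per-offset
    # null band without changing the mean profile shape
    win = 25
    kernel = np.ones(win) / win
    track = SignalTrack(
        bin_size=1,
        data={c: np.convolve(a, kernel, mode="same")
              for c, a in track.data.items()},
        chrom_sizes=dict(track.chrom_sizes),
    )
    return aggregate.profile_with_null(
        track, genome.open_regions, genome.blacklist, genome.chrom_lengths,
        n_shuffles=n_shuffles, seed=seed + 3,
    )
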