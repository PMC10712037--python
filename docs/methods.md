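# Methods

`nucleocut` models how different nucleases fragment fixed chromatin, how
those fragments appear after sequencing, and how the resulting Hi-C and
cut-site libraries are scored. This note documents the models, the
conventions, and the choices made where the design was open.

## Chromatin model

A synthetic genome (`simulate.make_genome`) is an i.i.d. base sequence at a
target GC fraction carrying:

- **Nucleosomes** as dyad positions laid down at a repeat length of 200 bp
  with uniform ±20 bp jitter. Each dyad protects a 147-bp footprint
  (half-width 73 bp). Dyads are re-anchored at the edges of
  nucleosome-free regions so the first flanking nucleosomes are well
  positioned and phasing decays with distance, as around real regulatory
  elements.
- **Open regions** (promoter/peak surrogates, one per ~40 kb, 600 bp wide)
  with a triangular accessibility bump (×5 at the center) and a
  nucleosome-free core.
- **Occluded linkers**: a fraction (default 0.65) of internucleosomal
  linkers is nearly inaccessible (accessibility ×0.01), standing in for
  fiber-level compaction and crosslinking. This is what generates the
  di-/tri-nucleosome ladder of partial digests: a homogeneous
  linker-cutting model provably cannot place the dinucleosome mode at
  ~350 bp (= 147 + linker + 147) — with uniform cuts in 53-bp linkers the
  mode sits near two repeat lengths (~400 bp), and making the residual
  linker stubs short enough to move it down also makes dinucleosomes
  vanishingly rare. With occluded linkers, accessible linkers are cut to
  their footprint edges while intact occluded linkers span two
  nucleosomes, giving modes at ≈150 and ≈350 bp with the observed
  prominence. The 0.65 default was set so the dinucleosome peak clears
  the 25% mode-prominence threshold with margin at the canonical study
  scale.
- **Footprint protection** is a chromatin property (default ×0.02 hazard
  inside footprints), entering the digestion hazard through the
  accessibility term; enzyme `linker_preference` is the enzyme's
  *additional* preference on top of that steric protection. Keeping
  protection in the chromatin model lets a weakly linker-preferring
  enzyme (S1, preference 3) still produce a nucleosomal ladder, which a
  3:1 per-base hazard ratio alone cannot (3 × 53/147 ≈ 1.08 cuts per
  linker per cut per footprint).
- **Compartments** tiling each chromosome in contiguous 250-kb A/B blocks
  with a continuous per-25-kb score; **CTCF sites** every ~40 kb with
  random orientation; a **blacklist** of 2-8 kb intervals kept clear of
  open regions.

Coordinates are 0-based half-open throughout; the SAM writer converts to
1-based at the boundary.

## Digestion model

Cuts are independent per-base Bernoulli events per simulated cell, with
per-bond hazard

    base_rate × accessibility(x) × linker_preference^(is_linker) × g(x)

where `base_rate = units × cut_rate / 1000` per bp (concentration maps
linearly to rate), clipped at 0.5/bp. Consecutive cuts delimit fragments;
cut positions are bond indices (a cut at bond *p* makes base *p* the first
base of the downstream fragment).

**G preference on the observable scale.** The S1 model's `g_bias` is the
*realized* fold-enrichment of G at the first fragment base relative to the
genomic background, because that is the quantity a sequencing readout
measures. A raw hazard multiplier *m* yields frequency enrichment
`m / (1 + (m-1) f_G)`, which is ≈1.66 for *m* = 2 at `f_G` ≈ 0.2; the
multiplier actually applied is therefore
`m = g (1 - f_G) / (1 - g f_G)`, which makes the measured enrichment equal
`g` exactly in expectation.

**End chemistry.**

- *S1* cleaves asymmetrically, leaving 3'-sticky ends; after end repair
  the blunted fragment end is recessed by `overhang_3p` (default 2) bp.
  Consequently the G preference is visible at fragment 5' ends but is not
  mirrored as a C immediately outside the 3' ends — the package's
  end-asymmetry check compares exactly these two enrichments.
- *MNase* trims free fragment ends exonucleolytically toward the nearest
  protected footprint boundary; trim lengths are exponential with mean
  `exo_trim` (concentration-scaled, 0.15 × units), capped at the
  footprint edge. In the high-concentration limit fragment sizes collapse
  onto 147 bp.
- *DNase I* converts a fraction of cut events (default 0.4) into
  single-strand nicks: nicks do not delimit fragments; each nick flags
  the nearer end of its containing fragment, the substrate for
  biotin-filled unligated molecules.
- *Restriction enzymes* cut only at motif positions with per-site
  probability `units × cut_rate`, independent of chromatin accessibility
  (restriction digests in Hi-C protocols run to near-completion; the
  property under study is the site-anchored coverage geometry).

Enzyme presets (`s1`, `mnase`, `dnase_i`, `restriction`) fix `cut_rate`
per unit so that 1000 units of S1 gives ~7-10 expected cuts per accessible
linker — the regime that reproduces the mono/dinucleosome pattern — and
1000 units of MNase fully trims linkers.

**Determinism and coupling.** Each (chromosome, cell) has two independent
seeded streams: one for the cut draws, one for post-processing. Because
the cut stream is shared across enzyme settings at the same seed, raising
`units` can only add cuts, making mean fragment length monotonically
non-increasing in concentration by construction.

## Reads and ligation pairs

`fragments_to_sam` renders one proper pair per fragment ≥30 bp (shorter
molecules are unsequenceable and dropped, with a logged count): forward
read at the fragment start, reverse read ending at the fragment end,
single-match-run CIGARs, perfect MD tags, and an optional injected
terminal mismatch used to exercise the cut-site filters.

`simulate_hic` samples cis ligation pairs with separation density
∝ `s^decay_exponent` (default −1) on [10 kb, L/2], re-weighted by
`homotypic_boost` for same-compartment ends and `loop_boost` when the two
ends fall within 10 kb of the two anchors of a convergent CTCF pair
(accept/reject against the maximal weight). Dangling ends are unligated
fragments read from both ends (inward-facing, separation = fragment
length), drawn without replacement so they do not masquerade as
duplicates; duplicates are exact copies of earlier pairs. Every pair
carries its truth class.

## Analysis conventions

- **Cut extraction**: forward reads must have a single M-run CIGAR and no
  mismatch at the first aligned base (MD starting `0<base>`); the event is
  the 0-based leftmost position. Reverse reads are filtered at the 3' end
  and the event is one past the rightmost aligned base, derived from the
  CIGAR span. A `fixed_span` option reproduces fixed-length pipelines
  that hard-code the span (span 100 equals the classic 1-based `POS+99`
  arithmetic); the CIGAR-derived span is the default because read lengths
  vary.
- **Context matrix**: offsets −k..+k exclude 0 (the cut bond itself has no
  base); +1 is the first base inside the sequenced fragment, with
  reverse-strand events reverse-complemented onto that frame. Enrichment
  divides by genome-wide mononucleotide frequencies; a base absent from
  the genome is flagged undefined rather than infinite.
- **Size histograms** count |TLEN| once per pair. The modal length is the
  fullest raw bin (at 1-bp binning, the size itself). Secondary modes are
  local maxima of the distribution re-binned at 20 bp that reach 25% of
  the global maximum — 20 bp matches gel-level size resolution and keeps
  the dinucleosome cluster, which is spread by linker-length jitter, in
  one bin.
- **Aggregation**: profiles sample feature-midpoint-centered windows
  (±3000 bp, step 2); the null band is the per-offset mean ± 3 SD over 100
  length-preserving uniform re-placements per chromosome, rejecting
  blacklist overlaps (≤1000 tries per feature). Shuffled features may
  overlap each other.
- **Coverage**: RPKM `= count × 10^9 / (total × bin_bp)`; 500-bp windows
  tile each chromosome with the last partial window excluded; IQR uses
  linear-interpolation (type 7) quantiles; windows are attributed to
  strata by midpoint. Compartment assignment takes the top/bottom 15% of
  finite E1 values with ties included on the A/B side respectively.
- **Contact maps** store upper-triangle counts; balancing is iterative
  correction to equal row sums (square-root damped updates, masked bins:
  <10 nonzero entries or the lowest 2% of marginals; tolerance 1e-5 on
  the max relative row-sum deviation, 500 sweeps max with a warning).
  Balanced rows are normalized to sum ≈1; all downstream statistics are
  scale-free.
- **Saddle**: bins are ranked into E1 quantile groups (50 by default,
  reduced with a warning when fewer scored bins exist); the saddle entry
  is the count-weighted mean cis obs/exp between groups.
  `strength(q) = (mean AA + mean BB) / (mean AB + mean BA)` over the
  top/bottom `q` fraction of groups, and the AUC score is the trapezoidal
  mean of strength over `q ∈ (0, 0.5]`. The hand-checkable identity
  (2-block matrix with within 2 / between 1 → strength exactly 2) holds
  on an explicit obs/exp matrix, which `saddle` accepts directly; for a
  ContactMap the per-diagonal expected model makes it approximate.
- **Pileups** average obs/exp windows (flank 200 kb at 5-kb bins).
  Loop strength = central 3×3 mean over the mean of the four 3×3 corner
  boxes. Insulation score = mean of the two cross-boundary quadrants over
  the two within-side quadrants (lower = stronger insulation). Both are
  deterministic, order- and scale-invariant.
- **Reproducibility**: per-row Spearman between balanced replicate
  matrices over positions finite in both rows; rows with <10 shared
  positions or zero variance are skipped and counted; the summary is the
  median coefficient.

## Study scale and desk-scale adaptations

The canonical conditions are 2-4 Mb single-chromosome genomes, 4-16
simulated cells (~2-6 × 10^4 sequenced fragments per digest) and ~10^5
Hi-C pairs; every workflow finishes in seconds. Two adaptations
compensate for the ~1000× depth gap to real libraries:

- the cut-context study uses moderate S1 units (200) so the measured
  context is not distorted by the loss of sub-30-bp over-digestion
  products (the context itself is a per-cut property, not a
  concentration effect);
- the open-chromatin aggregation profiles a 25-bp moving-average-smoothed
  cut track, which leaves the mean profile unchanged but keeps the
  per-offset shuffle band away from zero so that central depletion is
  resolvable.

## What the simulator does and does not emulate

It emulates nucleosome-protected digestion with enzyme-specific end
chemistry and concentration dependence, accessibility structure around
open regions, and Hi-C pairs with distance decay, compartment blocks,
CTCF loops, dangling ends and duplicates. It does **not** model
sequencing errors beyond the optional terminal mismatch, base qualities,
mappability, GC bias, trans-chromosomal 3D structure, or replication/copy
number — so green tests certify the statistical machinery and its
calibration on a faithful null, not robustness to every artifact of real
libraries.

## Known limitations

- The occluded-linker fraction is a coarse stand-in for fiber structure;
  real partial digests show continuous protection gradients.
- The dangling-end model treats DEs as biotin-filled unligated fragments;
  re-ligation and self-circle species are not modeled.
- Balancing on dense per-chromosome matrices is adequate for megabase
  toys but would need a sparse path for genome-scale matrices.
- The E1 helper (leading eigenvector of the obs/exp correlation) is a
  convenience for simulated maps; real-data compartment calling needs
  GC-based phasing, which is out of scope.
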