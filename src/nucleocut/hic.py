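"""Hi-C pair QC, contact matrices, and pattern metrics.

Covers the contact-level quality and structure statistics used to compare
digestion enzymes: pair classification (valid / dangling-end / duplicate),
binned contact-map construction with iterative-correction balancing,
distance-decay expected models, compartment saddle strength with an AUC
summary, convergent-CTCF loop pileups, insulation pileups, and replicate
reproducibility as per-row Spearman correlation.

Dangling ends are recognized by geometry: same-chromosome, inward-facing
(+/-) pairs closer than ``de_max_sep`` — an unligated fragment sequenced
from both ends.  Duplicates are exact repeats of the six-tuple
(chrom1, pos1, strand1, chrom2, pos2, strand2) after canonical mate
ordering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import spearmanr

__all__ = [
    "QCReport",
    "ContactMap",
    "SaddleResult",
    "PileupResult",
    "read_pairs",
    "pairs_frame",
    "classify_pairs",
    "bin_pairs",
    "balance",
    "expected_by_distance",
    "oe_matrix",
    "saddle",
    "convergent_ctcf_pairs",
    "pileup_windows",
    "loop_strength",
    "insulation_score",
    "loop_pileup",
    "insulation_pileup",
    "replicate_spearman",
    "compute_e1",
]

PAIR_COLUMNS = ["read_id", "chrom1", "pos1", "strand1",
                "chrom2", "pos2", "strand2"]


@dataclass
class QCReport:
    """Pair-class counts and fractions of the total library."""

    counts: dict[str, int]
    fractions: dict[str, float]
    total: int
    note: str = ("dangling ends called geometrically: inward-facing "
                 "cis pairs with separation < de_max_sep")


@dataclass
class SaddleResult:
    """Quantile-binned obs/exp saddle and its strength/AUC summary."""

    saddle: np.ndarray  # n_qbins x n_qbins mean obs/exp
    counts: np.ndarray
    q_grid: np.ndarray
    strength: np.ndarray  # strength(q) over q_grid
    auc_score: float
    n_qbins: int


@dataclass
class PileupResult:
    """Averaged obs/exp submatrix around anchors and its scalar score."""

    matrix: np.ndarray  # odd-sized average obs/exp window
    score: float
    n_used: int
    n_dropped: int
    flank_bins: int


# ---------------------------------------------------------------------------
# pairs


def read_pairs(path: str) -> pd.DataFrame:
    """Read 7-column pair text (readID chrom1 pos1 strand1 chrom2 pos2
    strand2); malformed lines raise with their line number."""
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 7:
                raise ValueError(f"{path}:{ln}: expected 7 fields, "
                                 f"got {len(parts)}")
            try:
                rows.append((parts[0], parts[1], int(parts[2]), parts[3],
                             parts[4], int(parts[5]), parts[6]))
            except ValueError as exc:
                raise ValueError(f"{path}:{ln}: {exc}") from None
    return pd.DataFrame(rows, columns=PAIR_COLUMNS)


def pairs_frame(pairs) -> pd.DataFrame:
    """DataFrame from a list of simulated pairs (keeps truth_class)."""
    return pd.DataFrame(
        {
            "read_id": [p.read_id for p in pairs],
            "chrom1": [p.chrom1 for p in pairs],
            "pos1": [p.pos1 for p in pairs],
            "strand1": [p.strand1 for p in pairs],
            "chrom2": [p.chrom2 for p in pairs],
            "pos2": [p.pos2 for p in pairs],
            "strand2": [p.strand2 for p in pairs],
            "truth_class": [p.truth_class for p in pairs],
        }
    )


def _canonicalize(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    swap = (df["chrom1"] > df["chrom2"]) | (
        (df["chrom1"] == df["chrom2"]) & (df["pos1"] > df["pos2"])
    )
    for a, b in (("chrom1", "chrom2"), ("pos1", "pos2"), ("strand1", "strand2")):
        df.loc[swap, [a, b]] = df.loc[swap, [b, a]].to_numpy()
    return df


def classify_pairs(
    df: pd.DataFrame, de_max_sep: int = 1000
) -> tuple[pd.DataFrame, QCReport]:
    """Assign each pair a QC class: duplicate, dangling_end, or valid.

    Duplicates are exact repeats of the canonical six-tuple (all but the
    first occurrence).  Dangling ends are same-chromosome inward-facing
    (+/-) pairs with separation below ``de_max_sep``.  Everything else is
    valid.
    """
    df = _canonicalize(df)
    key = ["chrom1", "pos1", "strand1", "chrom2", "pos2", "strand2"]
    dup = df.duplicated(subset=key, keep="first")
    de = (
        ~dup
        & (df["chrom1"] == df["chrom2"])
        & (df["strand1"] == "+")
        & (df["strand2"] == "-")
        & (df["pos2"] - df["pos1"] < de_max_sep)
    )
    qc = np.full(len(df), "valid", dtype=object)
    qc[de.to_numpy()] = "dangling_end"
    qc[dup.to_numpy()] = "duplicate"
    df["qc_class"] = qc
    counts = {c: int((qc == c).sum())
              for c in ("valid", "dangling_end", "duplicate")}
    total = len(df)
    fractions = {c: n / total for c, n in counts.items()} if total else {}
    return df, QCReport(counts=counts, fractions=fractions, total=total)


# ---------------------------------------------------------------------------
# contact maps


@dataclass
class ContactMap:
    """Binned symmetric contact matrix stored as upper-triangle counts."""

    bin_size: int
    bins: pd.DataFrame  # chrom, start, end
    counts: sp.csr_matrix  # upper triangle (incl. diagonal)
    chrom_bin_ranges: dict[str, tuple[int, int]]
    weights: np.ndarray | None = None  # NaN where masked
    balanced: bool = False
    _expected: dict = field(default_factory=dict, repr=False)

    @property
    def n_bins(self) -> int:
        return len(self.bins)

    def full(self) -> np.ndarray:
        """Dense symmetric count matrix."""
        m = self.counts.toarray().astype(float)
        return m + np.triu(m, 1).T

    def balanced_full(self) -> np.ndarray:
        """Dense symmetric balanced matrix (NaN on masked bins)."""
        if self.weights is None:
            raise ValueError("map is not balanced")
        m = self.full()
        w = self.weights
        out = m * w[:, None] * w[None, :]
        return out

    def chrom_matrix(self, chrom: str, balanced: bool = True) -> np.ndarray:
        lo, hi = self.chrom_bin_ranges[chrom]
        m = self.balanced_full() if balanced else self.full()
        return m[lo:hi, lo:hi]


def _bin_table(chrom_sizes: dict[str, int], bin_size: int):
    rows, ranges = [], {}
    offset = 0
    for chrom, size in chrom_sizes.items():
        n = -(-size // bin_size)
        for i in range(n):
            rows.append((chrom, i * bin_size, min((i + 1) * bin_size, size)))
        ranges[chrom] = (offset, offset + n)
        offset += n
    return pd.DataFrame(rows, columns=["chrom", "start", "end"]), ranges


def bin_pairs(
    df: pd.DataFrame, chrom_sizes: dict[str, int], bin_size: int
) -> ContactMap:
    """Accumulate pairs into an upper-triangle binned count matrix.

    Both mate orderings map to the same upper-triangle element; the
    diagonal is included.  Positions beyond the chromosome end raise.
    """
    if bin_size < 1000:
        raise ValueError("bin_size must be >= 1000")
    bins, ranges = _bin_table(chrom_sizes, bin_size)
    n = len(bins)

    def bin_ids(chroms, poss):
        ids = np.empty(len(chroms), dtype=np.int64)
        for chrom, (lo, hi) in ranges.items():
            sel = (chroms == chrom).to_numpy()
            if not sel.any():
                continue
            p = poss.to_numpy()[sel]
            size = chrom_sizes[chrom]
            if (p > size).any() or (p < 0).any():
                bad = p[(p > size) | (p < 0)][0]
                raise ValueError(f"position {bad} beyond {chrom} end {size}")
            b = np.minimum(p, size - 1) // bin_size
            ids[sel] = lo + b
        unknown = ~chroms.isin(list(ranges)).to_numpy()
        if unknown.any():
            raise ValueError(
                f"unknown chromosome: {chroms[unknown].iloc[0]}")
        return ids

    b1 = bin_ids(df["chrom1"], df["pos1"])
    b2 = bin_ids(df["chrom2"], df["pos2"])
    i = np.minimum(b1, b2)
    j = np.maximum(b1, b2)
    m = sp.coo_matrix(
        (np.ones(len(df)), (i, j)), shape=(n, n)
    ).tocsr()
    return ContactMap(bin_size=bin_size, bins=bins, counts=m,
                      chrom_bin_ranges=ranges)


def balance(
    cmap: ContactMap,
    min_nnz: int = 10,
    mad_frac: float = 0.02,
    tol: float = 1e-5,
    max_iter: int = 500,
) -> ContactMap:
    """Iterative correction to equal row sums.

    Bins with fewer than ``min_nnz`` nonzero entries, or with marginals in
    the lowest ``mad_frac`` fraction of nonzero marginals, are masked
    (weight NaN) and excluded from all downstream means.  Convergence:
    maximum relative row-sum deviation below ``tol`` (or ``max_iter``
    sweeps, with a warning).
    """
    m = cmap.full()
    n = m.shape[0]
    nnz = (m > 0).sum(axis=1)
    marg = m.sum(axis=1)
    mask = nnz < min_nnz
    alive = marg[~mask & (marg > 0)]
    if mad_frac > 0 and len(alive):
        thresh = np.quantile(alive, mad_frac)
        mask |= marg < thresh
    if mask.all():
        raise ValueError("all bins masked: cannot balance")

    w = np.ones(n)
    w[mask] = 0.0
    sub = m[np.ix_(~mask, ~mask)]
    ws = np.ones(sub.shape[0])
    for _ in range(max_iter):
        s = (sub * ws[None, :]).sum(axis=1) * ws
        mean_s = s.mean()
        if mean_s == 0:
            raise ValueError("empty matrix after masking")
        dev = np.abs(s / mean_s - 1).max()
        if dev < tol:
            break
        ws /= np.sqrt(s / mean_s)
    else:
        warnings.warn(f"balancing did not converge to {tol} "
                      f"in {max_iter} iterations (dev={dev:.2e})")
    ws /= np.sqrt(mean_s)  # convention: balanced rows sum to ~1
    weights = np.full(n, np.nan)
    weights[~mask] = ws
    return ContactMap(
        bin_size=cmap.bin_size, bins=cmap.bins, counts=cmap.counts,
        chrom_bin_ranges=cmap.chrom_bin_ranges, weights=weights,
        balanced=True,
    )


def expected_by_distance(cmap: ContactMap) -> dict[str, np.ndarray]:
    """Mean balanced signal per separation diagonal, per chromosome.

    Masked bins are excluded from the diagonal means; diagonals with no
    unmasked pairs are NaN.
    """
    if not cmap.balanced:
        raise ValueError("balance the map first")
    if cmap._expected:
        return cmap._expected
    out = {}
    full = cmap.balanced_full()
    for chrom, (lo, hi) in cmap.chrom_bin_ranges.items():
        sub = full[lo:hi, lo:hi]
        n = sub.shape[0]
        exp = np.full(n, np.nan)
        for d in range(n):
            diag = np.diagonal(sub, offset=d)
            good = np.isfinite(diag)
            if good.any():
                exp[d] = diag[good].mean()
        out[chrom] = exp
    cmap._expected.update(out)
    return out


def oe_matrix(cmap: ContactMap, chrom: str) -> np.ndarray:
    """Cis observed/expected matrix for one chromosome (NaN on masked bins
    and on diagonals with undefined expected)."""
    expected = expected_by_distance(cmap)[chrom]
    sub = cmap.chrom_matrix(chrom, balanced=True)
    n = sub.shape[0]
    d = np.abs(np.arange(n)[:, None] - np.arange(n)[None, :])
    exp = expected[d]
    with np.errstate(invalid="ignore", divide="ignore"):
        oe = sub / exp
    oe[~np.isfinite(oe)] = np.nan
    return oe


# ---------------------------------------------------------------------------
# saddle


def saddle(
    source,
    e1: np.ndarray,
    n_qbins: int = 50,
    q_grid: np.ndarray | None = None,
) -> SaddleResult:
    """Compartment saddle and strength-vs-top-fraction AUC score.

    ``source`` is either a balanced :class:`ContactMap` (cis obs/exp is
    computed per chromosome) or an explicit obs/exp matrix (then ``e1``
    aligns with its rows).  Bins are sorted into ``n_qbins`` E1 quantile
    groups; ``saddle[i, j]`` is the mean obs/exp between groups i
    (lowest E1) and j.  ``strength(q)`` pools the top and bottom ``q``
    fraction of groups: (mean AA + mean BB) / (mean AB + mean BA); the
    AUC score is the trapezoidal mean of strength over the q grid.
    """
    e1 = np.asarray(e1, dtype=float)
    if isinstance(source, ContactMap):
        blocks = []
        for chrom, (lo, hi) in source.chrom_bin_ranges.items():
            oe = oe_matrix(source, chrom)
            blocks.append((oe, e1[lo:hi]))
    else:
        oe = np.asarray(source, dtype=float)
        if oe.shape[0] != len(e1):
            raise ValueError("e1 length must match matrix size")
        blocks = [(oe, e1)]

    scored = sum(int(np.isfinite(b_e1).sum()) for _, b_e1 in blocks)
    if scored < n_qbins:
        warnings.warn(
            f"only {scored} scored bins; reducing n_qbins from {n_qbins}")
        n_qbins = max(2, scored)

    # global quantile grouping across all blocks
    all_e1 = np.concatenate([b_e1 for _, b_e1 in blocks])
    finite = np.isfinite(all_e1)
    order = np.argsort(all_e1[finite], kind="stable")
    group_of = np.full(len(all_e1), -1)
    gidx = np.floor(np.arange(finite.sum()) * n_qbins / finite.sum()).astype(int)
    tmp = np.full(finite.sum(), -1)
    tmp[order] = gidx
    group_of[finite] = tmp

    sums = np.zeros((n_qbins, n_qbins))
    cnts = np.zeros((n_qbins, n_qbins))
    offset = 0
    for oe, b_e1 in blocks:
        n = oe.shape[0]
        g = group_of[offset:offset + n]
        offset += n
        ok = g >= 0
        oe_ok = oe[np.ix_(ok, ok)]
        gg = g[ok]
        val = np.nan_to_num(oe_ok, nan=0.0)
        cnt = np.isfinite(oe_ok).astype(float)
        for gi in range(n_qbins):
            rows = gg == gi
            if not rows.any():
                continue
            sums[gi] += np.bincount(gg, weights=val[rows].sum(axis=0),
                                    minlength=n_qbins)
            cnts[gi] += np.bincount(gg, weights=cnt[rows].sum(axis=0),
                                    minlength=n_qbins)
    with np.errstate(invalid="ignore"):
        S = sums / cnts

    if q_grid is None:
        ks = np.arange(1, n_qbins // 2 + 1)
        q_grid = ks / n_qbins
    q_grid = np.asarray(q_grid, dtype=float)

    strength = np.empty(len(q_grid))
    for qi, q in enumerate(q_grid):
        k = max(1, int(round(q * n_qbins)))
        bot = slice(0, k)
        top = slice(n_qbins - k, n_qbins)
        m_aa = np.nansum(sums[top, top]) / max(np.nansum(cnts[top, top]), 1e-12)
        m_bb = np.nansum(sums[bot, bot]) / max(np.nansum(cnts[bot, bot]), 1e-12)
        cross = (np.nansum(sums[top, bot]) + np.nansum(sums[bot, top])) / max(
            np.nansum(cnts[top, bot]) + np.nansum(cnts[bot, top]), 1e-12)
        strength[qi] = (m_aa + m_bb) / (2 * cross) if cross > 0 else np.nan
    good = np.isfinite(strength)
    if good.sum() > 1:
        auc = float(np.trapezoid(strength[good], q_grid[good])
                    / (q_grid[good][-1] - q_grid[good][0]))
    else:
        auc = float(strength[good][0]) if good.any() else float("nan")
    return SaddleResult(saddle=S, counts=cnts, q_grid=q_grid,
                        strength=strength, auc_score=auc, n_qbins=n_qbins)


# ---------------------------------------------------------------------------
# CTCF anchors and pileups


def convergent_ctcf_pairs(
    sites: pd.DataFrame,
    min_sep: int = 50_000,
    max_sep: int = 1_000_000,
) -> pd.DataFrame:
    """All same-chromosome convergent site pairs (upstream '+', downstream
    '-') with separation in ``[min_sep, max_sep]``."""
    rows = []
    for chrom, sub in sites.groupby("chrom"):
        plus = np.sort(sub.loc[sub["strand"] == "+", "pos"].to_numpy())
        minus = np.sort(sub.loc[sub["strand"] == "-", "pos"].to_numpy())
        for p in plus:
            lo = np.searchsorted(minus, p + min_sep, side="left")
            hi = np.searchsorted(minus, p + max_sep, side="right")
            for m in minus[lo:hi]:
                rows.append((chrom, int(p), int(m)))
    return pd.DataFrame(rows, columns=["chrom", "pos1", "pos2"])


def pileup_windows(
    oe: np.ndarray, centers: list[tuple[int, int]], flank_bins: int
) -> tuple[np.ndarray, int, int]:
    """NaN-aware average of ``(2*flank_bins+1)``-sized obs/exp submatrices
    centered at (row, col) bin pairs; out-of-range centers are dropped.

    Returns ``(average_window, n_used, n_dropped)``.
    """
    acc, cnt, n_used, n_dropped = _pileup_sums(oe, centers, flank_bins)
    with np.errstate(invalid="ignore"):
        avg = acc / cnt
    return avg, n_used, n_dropped


def _pileup_sums(oe, centers, f):
    """Accumulated (sum, count) window matrices for exact averaging."""
    size = 2 * f + 1
    acc = np.zeros((size, size))
    cnt = np.zeros((size, size))
    n_used = n_dropped = 0
    n = oe.shape[0]
    for b1, b2 in centers:
        if b1 - f < 0 or b2 - f < 0 or b1 + f >= n or b2 + f >= n:
            n_dropped += 1
            continue
        win = oe[b1 - f:b1 + f + 1, b2 - f:b2 + f + 1]
        good = np.isfinite(win)
        acc[good] += win[good]
        cnt += good
        n_used += 1
    return acc, cnt, n_used, n_dropped


def loop_strength(avg: np.ndarray) -> float:
    """Mean of the central 3x3 box over the mean of the four 3x3 corner
    boxes of an averaged obs/exp window."""
    c = avg.shape[0] // 2
    center = np.nanmean(avg[c - 1:c + 2, c - 1:c + 2])
    corners = [avg[:3, :3], avg[:3, -3:], avg[-3:, :3], avg[-3:, -3:]]
    corner = np.nanmean(np.stack(corners))
    return float(center / corner) if corner > 0 else float("nan")


def insulation_score(avg: np.ndarray) -> float:
    """Mean of the two cross-boundary quadrants over the mean of the two
    within-side quadrants of an averaged on-diagonal window; lower means
    stronger insulation."""
    f = avg.shape[0] // 2
    a = np.nanmean(avg[:f, :f])  # within left
    d = np.nanmean(avg[f + 1:, f + 1:])  # within right
    cross = (np.nanmean(avg[:f, f + 1:]) + np.nanmean(avg[f + 1:, :f])) / 2
    within = (a + d) / 2
    return float(cross / within) if within > 0 else float("nan")


def _pileup(cmap, centers, flank):
    """Average obs/exp submatrices at per-chromosome (row, col) centers."""
    f = flank // cmap.bin_size
    size = 2 * f + 1
    acc = np.zeros((size, size))
    cnt = np.zeros((size, size))
    n_used = n_dropped = 0
    oe_cache = {}
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, b1, b2 in centers:
        by_chrom.setdefault(chrom, []).append((b1, b2))
    for chrom, cs in by_chrom.items():
        if chrom not in oe_cache:
            oe_cache[chrom] = oe_matrix(cmap, chrom)
        acc_c, cnt_c, used, dropped = _pileup_sums(oe_cache[chrom], cs, f)
        acc += acc_c
        cnt += cnt_c
        n_used += used
        n_dropped += dropped
    if n_used == 0:
        raise ValueError("no usable anchors within matrix bounds")
    with np.errstate(invalid="ignore"):
        avg = acc / cnt
    return avg, n_used, n_dropped, f


def loop_pileup(
    cmap: ContactMap, anchors: pd.DataFrame, flank: int = 200_000
) -> PileupResult:
    """Average obs/exp around convergent-CTCF anchor pairs.

    Loop strength = mean of the central 3x3 box over the mean of the four
    3x3 corner boxes of the averaged window.
    """
    centers = []
    for _, row in anchors.iterrows():
        b1 = int(row["pos1"]) // cmap.bin_size
        b2 = int(row["pos2"]) // cmap.bin_size
        centers.append((row["chrom"], b1, b2))
    avg, n_used, n_dropped, f = _pileup(cmap, centers, flank)
    return PileupResult(matrix=avg, score=loop_strength(avg), n_used=n_used,
                        n_dropped=n_dropped, flank_bins=f)


def insulation_pileup(
    cmap: ContactMap, sites: pd.DataFrame, flank: int = 200_000
) -> PileupResult:
    """Average obs/exp around single boundary sites.

    Insulation score = mean of the two cross-boundary quadrants divided by
    the mean of the two within-side quadrants; lower means stronger
    insulation.
    """
    centers = []
    for _, row in sites.iterrows():
        b = int(row["pos"]) // cmap.bin_size
        centers.append((row["chrom"], b, b))
    avg, n_used, n_dropped, f = _pileup(cmap, centers, flank)
    return PileupResult(matrix=avg, score=insulation_score(avg),
                        n_used=n_used, n_dropped=n_dropped, flank_bins=f)


# ---------------------------------------------------------------------------
# reproducibility and eigenvector


def replicate_spearman(
    map_a: ContactMap, map_b: ContactMap, min_finite: int = 10
) -> tuple[np.ndarray, float, int]:
    """Per-row Spearman correlation between two balanced replicate maps.

    Rows are compared over positions finite in both maps; rows with fewer
    than ``min_finite`` shared positions (or zero variance) are skipped
    and counted.  Returns (coefficients, median, n_skipped).
    """
    if not (map_a.balanced and map_b.balanced):
        raise ValueError("balance both maps first")
    if len(map_a.bins) != len(map_b.bins):
        raise ValueError("bin tables differ")
    A = map_a.balanced_full()
    B = map_b.balanced_full()
    coeffs = []
    n_skipped = 0
    for i in range(A.shape[0]):
        good = np.isfinite(A[i]) & np.isfinite(B[i])
        if good.sum() < min_finite:
            n_skipped += 1
            continue
        a, b = A[i, good], B[i, good]
        if a.std() == 0 or b.std() == 0:
            n_skipped += 1
            continue
        rho = spearmanr(a, b).statistic
        coeffs.append(rho)
    if not coeffs:
        raise ValueError("no usable rows")
    coeffs = np.array(coeffs)
    return coeffs, float(np.median(coeffs)), n_skipped


def compute_e1(
    cmap: ContactMap, phasing: np.ndarray | None = None
) -> np.ndarray:
    """Leading eigenvector of the per-chromosome obs/exp Pearson
    correlation matrix, optionally sign-oriented by correlation with a
    ``phasing`` track (e.g. a reference compartment score)."""
    e1 = np.full(cmap.n_bins, np.nan)
    for chrom, (lo, hi) in cmap.chrom_bin_ranges.items():
        oe = oe_matrix(cmap, chrom)
        good = np.isfinite(oe).sum(axis=1) > 0
        if good.sum() < 3:
            continue
        sub = oe[np.ix_(good, good)]
        sub = np.nan_to_num(sub - np.nanmean(sub), nan=0.0)
        corr = np.corrcoef(sub)
        corr = np.nan_to_num(corr, nan=0.0)
        vals, vecs = np.linalg.eigh(corr)
        vec = vecs[:, -1] * np.sqrt(max(vals[-1], 0.0))
        out = np.full(hi - lo, np.nan)
        out[good] = vec
        if phasing is not None:
            ph = phasing[lo:hi]
            both = np.isfinite(out) & np.isfinite(ph)
            if both.sum() > 2 and np.corrcoef(out[both], ph[both])[0, 1] < 0:
                out = -out
        e1[lo:hi] = out
    return e1
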