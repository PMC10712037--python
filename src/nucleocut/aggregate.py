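"""Feature-centered signal aggregation with a shuffle-permutation null.

The average signal around a set of genomic features (peak midpoints, TSS)
is compared to a null band obtained by redrawing each feature uniformly on
its own chromosome (length-preserving, blacklist-avoiding) ``n_shuffles``
times; the band is the per-offset shuffle mean ± 3 shuffle SD.  TSS can be
stratified into expression tiers (top 5% of transcripts by TPM, the 5-20
percentile band, and the bottom 20%) for tiered profiling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tracks import SignalTrack

__all__ = [
    "AggregateProfile",
    "ExpressionTiers",
    "feature_profile",
    "shuffle_null",
    "profile_with_null",
    "tss_tiers",
]


@dataclass
class AggregateProfile:
    """Observed feature-centered profile plus its shuffle-null band."""

    offsets: np.ndarray
    mean_signal: np.ndarray
    n_features: int
    null_mean: np.ndarray
    null_sd: np.ndarray

    @property
    def band_low(self) -> np.ndarray:
        return self.null_mean - 3 * self.null_sd

    @property
    def band_high(self) -> np.ndarray:
        return self.null_mean + 3 * self.null_sd


@dataclass
class ExpressionTiers:
    """Transcript identifiers per expression tier."""

    high: list[str]
    intermediate: list[str]
    non_expressed: list[str]


def _offsets(window: int, step: int) -> np.ndarray:
    return np.arange(-window, window + 1, step)


def feature_profile(
    track: SignalTrack,
    features: pd.DataFrame,
    window: int = 3000,
    step: int = 2,
    orient_by_strand: bool = False,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Mean signal at offsets ``-window..+window`` (every ``step`` bp) from
    feature midpoints.

    Features whose window would cross a chromosome boundary are dropped
    (their count is reported via the returned ``n_features``).  With
    ``orient_by_strand`` (off by default), features on the '-' strand
    contribute their signal vector reversed, so positive offsets point
    downstream of e.g. a TSS.  Requires a per-base track.  Returns
    ``(offsets, mean_signal, n_features_used)``.
    """
    if track.bin_size != 1:
        raise ValueError("feature_profile requires a per-base track")
    if not len(features):
        raise ValueError("no features given")
    if orient_by_strand and "strand" not in features.columns:
        raise ValueError("orient_by_strand requires a strand column")
    offs = _offsets(window, step)
    total = np.zeros(len(offs))
    n_used = 0
    for chrom, sub in features.groupby("chrom"):
        if chrom not in track.data:
            continue
        arr = track.data[chrom]
        centers = ((sub["start"].to_numpy() + sub["end"].to_numpy()) // 2)
        keep = (centers - window >= 0) & (centers + window < len(arr))
        centers = centers[keep]
        if not len(centers):
            continue
        mat = arr[centers[:, None] + offs[None, :]]
        if orient_by_strand:
            minus = (sub["strand"].to_numpy() == "-")[keep]
            mat[minus] = mat[minus, ::-1]
        total += mat.sum(axis=0)
        n_used += len(centers)
    if n_used == 0:
        raise ValueError("all features dropped (chromosome bounds / unknown)")
    return offs, total / n_used, n_used


def _merged_intervals(df: pd.DataFrame, chrom: str):
    sub = df[df["chrom"] == chrom].sort_values("start")
    if not len(sub):
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    starts = sub["start"].to_numpy()
    ends = sub["end"].to_numpy()
    m_starts, m_ends = [starts[0]], [ends[0]]
    for s, e in zip(starts[1:], ends[1:]):
        if s <= m_ends[-1]:
            m_ends[-1] = max(m_ends[-1], e)
        else:
            m_starts.append(s)
            m_ends.append(e)
    return np.asarray(m_starts), np.asarray(m_ends)


def shuffle_null(
    track: SignalTrack,
    features: pd.DataFrame,
    blacklist: pd.DataFrame | None,
    chrom_sizes: dict[str, int],
    n_shuffles: int = 100,
    seed: int = 0,
    window: int = 3000,
    step: int = 2,
    max_tries: int = 1000,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-offset mean and SD of feature-centered profiles over
    ``n_shuffles`` random re-placements of the features.

    Each shuffle redraws each feature uniformly on its own chromosome,
    preserving its length and rejecting placements that overlap the
    blacklist (up to ``max_tries`` attempts per feature, then an error
    naming the chromosome).  Overlaps among shuffled features are allowed.
    Deterministic under ``seed``.
    """
    rng = np.random.default_rng(seed)
    bl = {}
    if blacklist is not None:
        for chrom in features["chrom"].unique():
            bl[chrom] = _merged_intervals(blacklist, chrom)

    feats = features[["chrom", "start", "end"]].reset_index(drop=True)
    lengths = (feats["end"] - feats["start"]).to_numpy()
    chroms = feats["chrom"].to_numpy()
    profiles = np.empty((n_shuffles, len(_offsets(window, step))))
    for s_i in range(n_shuffles):
        new_starts = np.empty(len(feats), dtype=np.int64)
        for f_i, (chrom, flen) in enumerate(zip(chroms, lengths)):
            L = chrom_sizes[chrom]
            bls, ble = bl.get(chrom, (None, None))
            for _ in range(max_tries):
                s = int(rng.integers(0, L - flen + 1))
                if bls is None or not len(bls):
                    break
                j = np.searchsorted(bls, s + flen)
                if j == 0 or ble[j - 1] <= s:
                    break
            else:
                raise RuntimeError(
                    f"could not place a shuffled feature on {chrom} "
                    f"after {max_tries} tries"
                )
            new_starts[f_i] = s
        shuffled = pd.DataFrame(
            {"chrom": chroms, "start": new_starts, "end": new_starts + lengths}
        )
        _, profiles[s_i], _ = feature_profile(track, shuffled, window, step)
    return profiles.mean(axis=0), profiles.std(axis=0, ddof=1)


def profile_with_null(
    track: SignalTrack,
    features: pd.DataFrame,
    blacklist: pd.DataFrame | None,
    chrom_sizes: dict[str, int],
    window: int = 3000,
    step: int = 2,
    n_shuffles: int = 100,
    seed: int = 0,
) -> AggregateProfile:
    """Observed profile together with its shuffle-null band."""
    offs, mean_signal, n_used = feature_profile(track, features, window, step)
    null_mean, null_sd = shuffle_null(
        track, features, blacklist, chrom_sizes,
        n_shuffles=n_shuffles, seed=seed, window=window, step=step,
    )
    return AggregateProfile(offs, mean_signal, n_used, null_mean, null_sd)


def tss_tiers(expression: pd.DataFrame | dict) -> ExpressionTiers:
    """Partition transcripts into expression tiers by TPM.

    ``high`` is the top 5% of transcripts, ``intermediate`` the 5-20
    percentile band, ``non_expressed`` the bottom 20%.  Ties are broken by
    transcript identifier (lexicographic), so the tiers are deterministic
    and disjoint.
    """
    if isinstance(expression, dict):
        expression = pd.DataFrame(
            {"transcript": list(expression), "tpm": list(expression.values())}
        )
    if not len(expression):
        raise ValueError("empty expression table")
    if len(expression) < 20:
        raise ValueError("need at least 20 transcripts to form tiers")
    if (expression["tpm"] < 0).any():
        raise ValueError("TPM must be >= 0")
    ranked = expression.sort_values(
        ["tpm", "transcript"], ascending=[False, True]
    )["transcript"].tolist()
    n = len(ranked)
    n_high = int(round(0.05 * n))
    n_top20 = int(round(0.20 * n))
    n_low = int(round(0.20 * n))
    return ExpressionTiers(
        high=ranked[:n_high],
        intermediate=ranked[n_high:n_top20],
        non_expressed=ranked[n - n_low:],
    )
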