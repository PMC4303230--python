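"""Shallow-WGS copy-number profiling.

Per-bin read counts are converted to median-centered log2 ratios,
segmented per chromosome by penalized least squares (optimal
partitioning), thresholded into gain/neutral/loss statuses, and either
flagged balanced/unbalanced or summarized across a cohort.  Profiles
are compared by Manhattan distance on the -1/0/+1 status encoding and
clustered with deterministic complete linkage.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genome import GenomeModel

__all__ = [
    "CopyNumberProfile",
    "Segment",
    "SegmentedProfile",
    "RecurrenceSummary",
    "Dendrogram",
    "counts_to_log2",
    "segment_profile",
    "call_status",
    "is_balanced",
    "recurrence_summary",
    "manhattan_distance_matrix",
    "hcluster_complete",
]

DEFAULT_GAIN_CUT = 0.2
DEFAULT_LOSS_CUT = -0.2
DEFAULT_MIN_ABERRANT_FRACTION = 0.05

_STATUS_NAMES = {-1: "loss", 0: "neutral", 1: "gain"}


@dataclass(frozen=True)
class CopyNumberProfile:
    """Per-bin log2 ratios, optionally with -1/0/+1 statuses."""

    genome: GenomeModel
    log2: np.ndarray = field(repr=False)
    status: np.ndarray | None = field(default=None, repr=False)
    sample_id: str = "."

    def __post_init__(self):
        log2 = np.asarray(self.log2, dtype=float)
        object.__setattr__(self, "log2", log2)
        if log2.size != self.genome.n_bins:
            raise ValueError("log2 length does not match the genome bin grid")
        if self.status is not None:
            status = np.asarray(self.status, dtype=np.int8)
            if status.size != self.genome.n_bins:
                raise ValueError("status length does not match the genome bin grid")
            if not np.all(np.isin(status, (-1, 0, 1))):
                raise ValueError("statuses must be -1, 0 or +1")
            object.__setattr__(self, "status", status)

    def aberrant_fraction(self) -> float:
        if self.status is None:
            raise ValueError("statuses not assigned")
        return float(np.mean(self.status != 0))

    def to_dataframe(self) -> pd.DataFrame:
        df = self.genome.bins_dataframe()[["chrom", "start", "end"]].copy()
        df["log2"] = self.log2
        df["status"] = (
            [_STATUS_NAMES[int(s)] for s in self.status]
            if self.status is not None
            else "."
        )
        return df


@dataclass(frozen=True)
class Segment:
    chrom: str
    start_bin: int   # bin index, half-open [start_bin, end_bin)
    end_bin: int
    mean_log2: float
    status: int | None = None


@dataclass(frozen=True)
class SegmentedProfile:
    genome: GenomeModel
    segments: tuple
    sample_id: str = "."

    def __post_init__(self):
        covered = 0
        for seg in self.segments:
            if seg.end_bin <= seg.start_bin:
                raise ValueError("zero-length segment")
            covered += seg.end_bin - seg.start_bin
        if covered != self.genome.n_bins:
            raise ValueError("segments do not tile the bin grid")


def counts_to_log2(
    counts: np.ndarray,
    baseline: np.ndarray,
    genome: GenomeModel,
    sample_id: str = ".",
) -> CopyNumberProfile:
    """Median-centered log2 of depth-normalized counts over the baseline.

    Zero-count bins are floored at 0.5 reads before the ratio; the
    baseline must be strictly positive on every bin.
    """
    counts = np.asarray(counts, dtype=float)
    baseline = np.asarray(baseline, dtype=float)
    if counts.size != genome.n_bins or baseline.size != genome.n_bins:
        raise ValueError("counts/baseline length does not match the genome bin grid")
    if np.any(baseline <= 0):
        raise ValueError("baseline has non-positive bins")
    safe = np.where(counts > 0, counts, 0.5)
    ratio = (safe / counts.sum()) / (baseline / baseline.sum())
    log2 = np.log2(ratio)
    log2 -= np.median(log2)
    return CopyNumberProfile(genome=genome, log2=log2, sample_id=sample_id)


def _segment_chromosome(y: np.ndarray, penalty: float) -> list:
    """Optimal partitioning minimizing SSE + penalty * (#segments).

    Returns breakpoints as a list of segment (start, end) index pairs.
    O(n^2) dynamic program with vectorized inner loop.
    """
    n = y.size
    s1 = np.concatenate(([0.0], np.cumsum(y)))
    s2 = np.concatenate(([0.0], np.cumsum(y * y)))
    best = np.empty(n + 1)
    best[0] = 0.0
    prev = np.zeros(n + 1, dtype=np.int64)
    for t in range(1, n + 1):
        starts = np.arange(t)
        lens = t - starts
        seg_cost = (s2[t] - s2[starts]) - (s1[t] - s1[starts]) ** 2 / lens
        total = best[:t] + seg_cost + penalty
        i = int(np.argmin(total))
        best[t] = total[i]
        prev[t] = i
    bounds = []
    t = n
    while t > 0:
        bounds.append((int(prev[t]), t))
        t = int(prev[t])
    return bounds[::-1]


def estimate_noise_sd(log2: np.ndarray) -> float:
    """Robust per-bin noise scale from median absolute first differences."""
    diffs = np.abs(np.diff(log2))
    return float(np.median(diffs) / (np.sqrt(2.0) * 0.6744897501960817))


def segment_profile(profile: CopyNumberProfile, penalty: float | None = None) -> SegmentedProfile:
    """Per-chromosome piecewise-constant least-squares fit.

    ``penalty`` is the cost per segment; by default a BIC-like
    ``2 * sigma^2 * log(n_bins)`` with sigma estimated robustly from
    first differences (floored so noise-free profiles are not
    over-segmented).
    """
    if not np.all(np.isfinite(profile.log2)):
        raise ValueError("profile contains non-finite log2 values")
    if penalty is None:
        sigma = estimate_noise_sd(profile.log2)
        penalty = max(2.0 * sigma**2 * np.log(profile.genome.n_bins), 1e-8)
    if penalty <= 0:
        raise ValueError("penalty must be positive")

    segments = []
    for chrom, sl in profile.genome.chrom_slices().items():
        y = profile.log2[sl]
        for s, e in _segment_chromosome(y, penalty):
            segments.append(
                Segment(
                    chrom=chrom,
                    start_bin=sl.start + s,
                    end_bin=sl.start + e,
                    mean_log2=float(y[s:e].mean()),
                )
            )
    return SegmentedProfile(
        genome=profile.genome, segments=tuple(segments), sample_id=profile.sample_id
    )


def call_status(
    segmented: SegmentedProfile,
    gain_cut: float = DEFAULT_GAIN_CUT,
    loss_cut: float = DEFAULT_LOSS_CUT,
) -> CopyNumberProfile:
    """Threshold segment means into statuses and broadcast to bins."""
    if not loss_cut < 0 < gain_cut:
        raise ValueError(f"cuts must satisfy loss_cut < 0 < gain_cut, got {loss_cut}, {gain_cut}")
    log2 = np.empty(segmented.genome.n_bins)
    status = np.zeros(segmented.genome.n_bins, dtype=np.int8)
    for seg in segmented.segments:
        s = 0
        if seg.mean_log2 >= gain_cut:
            s = 1
        elif seg.mean_log2 <= loss_cut:
            s = -1
        log2[seg.start_bin:seg.end_bin] = seg.mean_log2
        status[seg.start_bin:seg.end_bin] = s
    return CopyNumberProfile(
        genome=segmented.genome, log2=log2, status=status, sample_id=segmented.sample_id
    )


def is_balanced(
    profile: CopyNumberProfile,
    min_aberrant_fraction: float = DEFAULT_MIN_ABERRANT_FRACTION,
) -> bool:
    """Balanced iff fewer than ``min_aberrant_fraction`` of bins are non-neutral."""
    return profile.aberrant_fraction() < min_aberrant_fraction


@dataclass(frozen=True)
class RecurrenceSummary:
    """Per-bin gain/loss frequencies over the unbalanced cohort profiles."""

    genome: GenomeModel
    gain_fraction: np.ndarray = field(repr=False)
    loss_fraction: np.ndarray = field(repr=False)
    n_profiles: int = 0

    def arm_table(self) -> pd.DataFrame:
        """Mean gain/loss fraction per chromosome arm, most recurrent first."""
        df = pd.DataFrame(
            {
                "arm": self.genome.arm_labels(),
                "gain": self.gain_fraction,
                "loss": self.loss_fraction,
            }
        )
        return df.groupby("arm", sort=False).mean().reset_index()

    def to_dataframe(self) -> pd.DataFrame:
        df = self.genome.bins_dataframe()[["chrom", "start", "end"]].copy()
        df["gain_fraction"] = self.gain_fraction
        df["loss_fraction"] = self.loss_fraction
        return df


def recurrence_summary(
    profiles: list,
    min_aberrant_fraction: float = DEFAULT_MIN_ABERRANT_FRACTION,
) -> RecurrenceSummary:
    """Per-bin aberration frequencies over unbalanced profiles only.

    Balanced profiles are excluded; raises if none remain.
    """
    if not profiles:
        raise ValueError("no profiles supplied")
    genome = profiles[0].genome
    unbalanced = []
    for p in profiles:
        if not genome.same_grid(p.genome):
            raise ValueError("profiles are on different bin grids")
        if not is_balanced(p, min_aberrant_fraction):
            unbalanced.append(p)
    if not unbalanced:
        raise ValueError("no unbalanced profiles: recurrence summary undefined")
    statuses = np.stack([p.status for p in unbalanced])
    return RecurrenceSummary(
        genome=genome,
        gain_fraction=np.mean(statuses == 1, axis=0),
        loss_fraction=np.mean(statuses == -1, axis=0),
        n_profiles=len(unbalanced),
    )


def manhattan_distance_matrix(profiles: list) -> np.ndarray:
    """Pairwise Manhattan distance on the -1/0/+1 status encoding."""
    if not profiles:
        raise ValueError("no profiles supplied")
    genome = profiles[0].genome
    for p in profiles:
        if not genome.same_grid(p.genome):
            raise ValueError("profiles are on different bin grids")
        if p.status is None:
            raise ValueError(f"profile {p.sample_id!r} has no statuses")
    S = np.stack([p.status.astype(np.int64) for p in profiles])
    return np.abs(S[:, None, :] - S[None, :, :]).sum(axis=2).astype(float)


@dataclass(frozen=True)
class Dendrogram:
    """Agglomerative clustering result: merge table and Newick string.

    ``merges`` is a tuple of (left_members, right_members, height)
    with members given as sorted label tuples.
    """

    labels: tuple
    merges: tuple
    newick: str

    @property
    def heights(self) -> tuple:
        return tuple(m[2] for m in self.merges)


def _complete_distance(dist, a_idx, b_idx) -> float:
    return max(dist[i, j] for i in a_idx for j in b_idx)


def hcluster_complete(dist: np.ndarray, labels: list) -> Dendrogram:
    """Complete-linkage agglomerative clustering with deterministic ties.

    Ties on the merge height are broken by merging the pair whose
    (lexicographically smallest member of each side) sorts first.
    """
    dist = np.asarray(dist, dtype=float)
    n = len(labels)
    if dist.shape != (n, n):
        raise ValueError("distance matrix shape does not match labels")
    if not np.allclose(dist, dist.T) or not np.allclose(np.diag(dist), 0):
        raise ValueError("distance matrix must be symmetric with zero diagonal")
    if len(set(labels)) != n:
        raise ValueError("labels must be unique")

    # cluster: (sorted member labels, member indices, newick, height)
    clusters = [((labels[i],), (i,), str(labels[i]), 0.0) for i in range(n)]
    clusters.sort(key=lambda c: c[0])
    merges = []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = _complete_distance(dist, clusters[i][1], clusters[j][1])
                key = (d, clusters[i][0][0], clusters[j][0][0])
                if best is None or key < best[0]:
                    best = (key, i, j)
        (h, _, _), i, j = best
        a, b = clusters[i], clusters[j]
        nwk = f"({a[2]}:{(h - a[3]) / 2:g},{b[2]}:{(h - b[3]) / 2:g})"
        merged = (
            tuple(sorted(a[0] + b[0])),
            a[1] + b[1],
            nwk,
            h,
        )
        merges.append((a[0], b[0], float(h)))
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
        clusters.append(merged)
        clusters.sort(key=lambda c: c[0])
    return Dendrogram(
        labels=tuple(labels), merges=tuple(merges), newick=clusters[0][2] + ";"
    )
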