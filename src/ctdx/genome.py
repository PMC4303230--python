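"""Genome bin-grid models and copy-number event definitions.

A :class:`GenomeModel` tiles every chromosome with a fixed number of
equal-width bins; the genome-wide bin budget is split across chromosomes
in proportion to their lengths (largest-remainder apportionment).  Each
bin belongs to exactly one chromosome arm, determined by its midpoint
relative to the centromere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenomeModel",
    "CNAEvent",
    "make_genome_model",
    "toy_genome",
    "hg19_genome",
    "arm_interval",
    "events_from_arm_spec",
    "index_tumor_events",
    "ctc_extra_events",
    "breast_archetype_events",
    "HG19_CHROM_LENGTHS",
    "HG19_CENTROMERES",
]

# hg19 chromosome lengths (bp) and approximate centromere positions.
HG19_CHROM_LENGTHS = {
    "chr1": 249_250_621, "chr2": 243_199_373, "chr3": 198_022_430,
    "chr4": 191_154_276, "chr5": 180_915_260, "chr6": 171_115_067,
    "chr7": 159_138_663, "chr8": 146_364_022, "chr9": 141_213_431,
    "chr10": 135_534_747, "chr11": 135_006_516, "chr12": 133_851_895,
    "chr13": 115_169_878, "chr14": 107_349_540, "chr15": 102_531_392,
    "chr16": 90_354_753, "chr17": 81_195_210, "chr18": 78_077_248,
    "chr19": 59_128_983, "chr20": 63_025_520, "chr21": 48_129_895,
    "chr22": 51_304_566, "chrX": 155_270_560,
}

HG19_CENTROMERES = {
    "chr1": 125_000_000, "chr2": 93_300_000, "chr3": 91_000_000,
    "chr4": 50_400_000, "chr5": 48_400_000, "chr6": 61_000_000,
    "chr7": 59_900_000, "chr8": 45_600_000, "chr9": 49_000_000,
    "chr10": 40_200_000, "chr11": 53_700_000, "chr12": 35_800_000,
    "chr13": 17_900_000, "chr14": 17_600_000, "chr15": 19_000_000,
    "chr16": 36_600_000, "chr17": 24_000_000, "chr18": 17_200_000,
    "chr19": 26_500_000, "chr20": 27_500_000, "chr21": 13_200_000,
    "chr22": 14_700_000, "chrX": 60_600_000,
}


@dataclass(frozen=True)
class GenomeModel:
    """Bin grid over a set of chromosomes.

    Attributes
    ----------
    chromosomes : tuple of str
        Chromosome names in genome order.
    lengths : dict
        Chromosome length in bp.
    centromeres : dict
        Centromere position in bp per chromosome (p/q boundary).
    bin_chrom, bin_start, bin_end, bin_arm : ndarray
        One entry per bin; coordinates 0-based half-open.
    """

    chromosomes: tuple
    lengths: dict
    centromeres: dict
    bin_chrom: np.ndarray = field(repr=False)
    bin_start: np.ndarray = field(repr=False)
    bin_end: np.ndarray = field(repr=False)
    bin_arm: np.ndarray = field(repr=False)

    @property
    def n_bins(self) -> int:
        return self.bin_start.size

    def chrom_mask(self, chrom: str) -> np.ndarray:
        return self.bin_chrom == chrom

    def chrom_slices(self) -> dict:
        """Mapping chromosome -> slice of its (contiguous) bins."""
        out = {}
        for chrom in self.chromosomes:
            idx = np.flatnonzero(self.bin_chrom == chrom)
            out[chrom] = slice(int(idx[0]), int(idx[-1]) + 1)
        return out

    def arm_labels(self) -> np.ndarray:
        """Per-bin labels like ``'1q'`` (chromosome name sans 'chr' + arm)."""
        names = np.array([c.removeprefix("chr") for c in self.bin_chrom])
        return np.char.add(names, self.bin_arm.astype(str))

    def bins_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": self.bin_chrom,
                "start": self.bin_start,
                "end": self.bin_end,
                "arm": self.bin_arm,
            }
        )

    def same_grid(self, other: "GenomeModel") -> bool:
        return (
            self.n_bins == other.n_bins
            and np.array_equal(self.bin_chrom, other.bin_chrom)
            and np.array_equal(self.bin_start, other.bin_start)
            and np.array_equal(self.bin_end, other.bin_end)
        )


@dataclass(frozen=True)
class CNAEvent:
    """A copy-number aberration over a genomic interval.

    ``delta`` is the integer copy-number change relative to the diploid
    state (+1 = single-copy gain, -1 = single-copy loss).  Coordinates
    are 0-based half-open.
    """

    chrom: str
    start: int
    end: int
    delta: int

    def __post_init__(self):
        if self.delta == 0:
            raise ValueError("CNAEvent delta must be non-zero")
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")

    @property
    def direction(self) -> str:
        return "gain" if self.delta > 0 else "loss"

    def validate(self, genome: GenomeModel) -> None:
        if self.chrom not in genome.lengths:
            raise ValueError(f"unknown chromosome {self.chrom!r}")
        if self.end > genome.lengths[self.chrom]:
            raise ValueError(
                f"event end {self.end} beyond {self.chrom} "
                f"length {genome.lengths[self.chrom]}"
            )


def _apportion(lengths: list, n_bins: int) -> list:
    """Largest-remainder apportionment with at least one bin each."""
    total = float(sum(lengths))
    quotas = [n_bins * (l / total) for l in lengths]
    counts = [int(q) for q in quotas]
    remainders = [q - c for q, c in zip(quotas, counts)]
    short = n_bins - sum(counts)
    for i in sorted(range(len(lengths)), key=lambda i: -remainders[i])[:short]:
        counts[i] += 1
    # guarantee >= 1 bin per chromosome
    while min(counts) == 0:
        counts[counts.index(max(counts))] -= 1
        counts[counts.index(0)] += 1
    return counts


def make_genome_model(
    lengths: dict,
    centromeres: dict | None = None,
    n_bins: int = 50_000,
) -> GenomeModel:
    """Build a bin grid with ``n_bins`` bins apportioned by length.

    Parameters
    ----------
    lengths : dict
        Ordered mapping chromosome -> length in bp (all positive).
    centromeres : dict, optional
        Chromosome -> centromere position; defaults to the midpoint.
    n_bins : int
        Genome-wide bin count; must be >= the number of chromosomes.
    """
    chroms = tuple(lengths)
    if not chroms:
        raise ValueError("need at least one chromosome")
    if any(l <= 0 for l in lengths.values()):
        raise ValueError("chromosome lengths must be positive")
    if n_bins < len(chroms):
        raise ValueError(
            f"n_bins={n_bins} is smaller than the chromosome count {len(chroms)}"
        )
    if centromeres is None:
        centromeres = {c: lengths[c] // 2 for c in chroms}

    per_chrom = _apportion([lengths[c] for c in chroms], n_bins)
    bin_chrom, bin_start, bin_end, bin_arm = [], [], [], []
    for chrom, k in zip(chroms, per_chrom):
        edges = np.linspace(0, lengths[chrom], k + 1).astype(np.int64)
        starts, ends = edges[:-1], edges[1:]
        mids = (starts + ends) // 2
        arms = np.where(mids < centromeres[chrom], "p", "q")
        bin_chrom.append(np.full(k, chrom, dtype=object))
        bin_start.append(starts)
        bin_end.append(ends)
        bin_arm.append(arms)

    return GenomeModel(
        chromosomes=chroms,
        lengths=dict(lengths),
        centromeres=dict(centromeres),
        bin_chrom=np.concatenate(bin_chrom),
        bin_start=np.concatenate(bin_start),
        bin_end=np.concatenate(bin_end),
        bin_arm=np.concatenate(bin_arm).astype("<U1"),
    )


def toy_genome(n_chrom: int = 4, length: int = 100_000_000, n_bins: int = 400) -> GenomeModel:
    """Small equal-chromosome genome for fast tests."""
    lengths = {f"chr{i + 1}": length for i in range(n_chrom)}
    return make_genome_model(lengths, n_bins=n_bins)


def hg19_genome(n_bins: int = 50_000) -> GenomeModel:
    """hg19-proportioned model (chr1-22, X)."""
    return make_genome_model(HG19_CHROM_LENGTHS, HG19_CENTROMERES, n_bins=n_bins)


def arm_interval(genome: GenomeModel, arm: str, distal: bool = False) -> tuple:
    """Resolve an arm name like ``'8p'`` or ``'11q'`` to (chrom, start, end).

    With ``distal=True`` only the telomeric half of the arm is returned.
    """
    name, side = arm[:-1], arm[-1]
    chrom = name if name in genome.lengths else f"chr{name}"
    if chrom not in genome.lengths or side not in "pq":
        raise ValueError(f"cannot resolve arm {arm!r}")
    cen = genome.centromeres[chrom]
    if side == "p":
        start, end = 0, cen
        if distal:
            end = cen // 2
    else:
        start, end = cen, genome.lengths[chrom]
        if distal:
            start = cen + (end - cen) // 2
    return chrom, start, end


def events_from_arm_spec(
    genome: GenomeModel,
    gains: list | None = None,
    losses: list | None = None,
    distal_losses: list | None = None,
    delta: int = 1,
) -> list:
    """Build single-copy :class:`CNAEvent` lists from arm names."""
    events = []
    for arm in gains or []:
        c, s, e = arm_interval(genome, arm)
        events.append(CNAEvent(c, s, e, +delta))
    for arm in losses or []:
        c, s, e = arm_interval(genome, arm)
        events.append(CNAEvent(c, s, e, -delta))
    for arm in distal_losses or []:
        c, s, e = arm_interval(genome, arm, distal=True)
        events.append(CNAEvent(c, s, e, -delta))
    return events


def index_tumor_events(genome: GenomeModel) -> list:
    """Aberrations shared by the index patient's tumor lesions:
    gains of 1q and 8q; losses of 6q, 8p, distal 11q, and 17p."""
    return events_from_arm_spec(
        genome,
        gains=["1q", "8q"],
        losses=["6q", "8p", "17p"],
        distal_losses=["11q"],
    )


def ctc_extra_events(genome: GenomeModel) -> list:
    """Additional change seen in CTCs: loss of 1p."""
    return events_from_arm_spec(genome, losses=["1p"])


def breast_archetype_events(genome: GenomeModel) -> list:
    """Recurrent breast-cancer aberrations:
    losses of 1p, 8p, 13q, 16q; gains of 1q, 8q, 16p, 17q."""
    return events_from_arm_spec(
        genome,
        gains=["1q", "8q", "16p", "17q"],
        losses=["1p", "8p", "13q", "16q"],
    )


def event_delta_per_bin(genome: GenomeModel, events: list) -> np.ndarray:
    """Sum of event deltas applying to each bin (by bin midpoint)."""
    delta = np.zeros(genome.n_bins, dtype=np.int64)
    mids = (genome.bin_start + genome.bin_end) // 2
    for ev in events:
        ev.validate(genome)
        mask = (genome.bin_chrom == ev.chrom) & (mids >= ev.start) & (mids < ev.end)
        delta[mask] += ev.delta
    return delta
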