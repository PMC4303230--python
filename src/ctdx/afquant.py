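"""Allele-fraction estimation and circulating mutant-fragment totals.

AF is the binomial maximum-likelihood estimate mutant/total with a 1%
detection cutoff.  Per-ml mutant-fragment concentrations are scaled to a
whole-body total via a volume of distribution of 60 ml/kg body weight.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "DeepSeqCount",
    "AFEstimate",
    "MutantFragmentEstimate",
    "compute_af",
    "summarize_afs",
    "total_mutant_fragments",
    "round_sigfigs",
    "DEFAULT_AF_CUTOFF",
    "DEFAULT_VOLUME_OF_DISTRIBUTION",
    "CTDNA_HALF_LIFE_MIN",
    "INDEX_PER_ML_AVERAGES",
]

DEFAULT_AF_CUTOFF = 0.01
# 60-70 ml/kg is the plausible range; 60 reproduces all worked totals
DEFAULT_VOLUME_OF_DISTRIBUTION = 60.0
# documented metadata only: drives no computation
CTDNA_HALF_LIFE_MIN = 16.0
# measured average mutant fragments per ml plasma for the index patient's
# three serial blood collections
INDEX_PER_ML_AVERAGES = (6320.0, 8524.0, 4419.0)
INDEX_BODY_WEIGHT_KG = 60.0


@dataclass(frozen=True)
class DeepSeqCount:
    variant: str
    sample: str
    mut_reads: int
    total_reads: int

    def __post_init__(self):
        if self.total_reads <= 0:
            raise ValueError("total_reads must be positive")
        if not 0 <= self.mut_reads <= self.total_reads:
            raise ValueError("need 0 <= mut_reads <= total_reads")


@dataclass(frozen=True)
class AFEstimate:
    variant: str
    sample: str
    af: float
    detected: bool
    cutoff: float

    def __post_init__(self):
        if (self.af >= self.cutoff) != self.detected:
            raise ValueError("detected flag inconsistent with AF and cutoff")


@dataclass(frozen=True)
class MutantFragmentEstimate:
    """Whole-body mutant fragment count from a per-ml concentration.

    ``total`` equals per_ml * v_ml_per_kg * weight_kg exactly.  Since
    ctDNA turns over fast (half-life ~16 min), the total approximately
    equals the number of tumor cells releasing ctDNA at draw time,
    exposed as ``tumor_cell_equivalent``.
    """

    per_ml: float
    weight_kg: float
    v_ml_per_kg: float
    total: float
    total_2sf: float

    @property
    def tumor_cell_equivalent(self) -> float:
        return self.total


def round_sigfigs(x: float, sigfigs: int = 2) -> float:
    """Round to ``sigfigs`` significant figures, ties to even."""
    if x == 0:
        return 0.0
    exponent = math.floor(math.log10(abs(x))) - (sigfigs - 1)
    scaled = x / 10**exponent
    # round-half-even on the scaled value
    nearest = math.floor(scaled)
    frac = scaled - nearest
    if abs(frac - 0.5) < 1e-9:
        rounded = nearest if nearest % 2 == 0 else nearest + 1
    else:
        rounded = round(scaled)
    return float(rounded * 10**exponent)


def compute_af(count: DeepSeqCount, cutoff: float = DEFAULT_AF_CUTOFF) -> AFEstimate:
    """Binomial MLE allele fraction with detection flag (AF >= cutoff)."""
    af = count.mut_reads / count.total_reads
    return AFEstimate(
        variant=count.variant,
        sample=count.sample,
        af=af,
        detected=af >= cutoff,
        cutoff=cutoff,
    )


def summarize_afs(estimates: list) -> tuple:
    """(mean AF, sample standard deviation, number detected)."""
    if not estimates:
        raise ValueError("no AF estimates supplied")
    afs = np.array([e.af for e in estimates], dtype=float)
    sd = float(np.std(afs, ddof=1)) if afs.size > 1 else 0.0
    return float(afs.mean()), sd, int(sum(e.detected for e in estimates))


def total_mutant_fragments(
    per_ml: float,
    weight_kg: float = INDEX_BODY_WEIGHT_KG,
    v_ml_per_kg: float = DEFAULT_VOLUME_OF_DISTRIBUTION,
) -> MutantFragmentEstimate:
    """Scale a per-ml plasma concentration to a whole-body fragment count."""
    if per_ml <= 0 or weight_kg <= 0 or v_ml_per_kg <= 0:
        raise ValueError("all arguments must be positive")
    total = per_ml * v_ml_per_kg * weight_kg
    return MutantFragmentEstimate(
        per_ml=per_ml,
        weight_kg=weight_kg,
        v_ml_per_kg=v_ml_per_kg,
        total=total,
        total_2sf=round_sigfigs(total, 2),
    )
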