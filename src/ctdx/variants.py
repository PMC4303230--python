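"""Somatic SNV filter cascade with a per-step audit trail.

The cascade, applied in fixed order per sample:

1. subtract germline calls (exact chrom/pos/ref/alt match),
2. restrict to exons padded by 2 bp on each side,
3. keep calls in known driver genes,
4. keep SNVs shared by at least ``min_samples`` samples.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

__all__ = [
    "VariantCall",
    "AnnotationResources",
    "CascadeAudit",
    "subtract_germline",
    "restrict_exonic",
    "annotate_dbsnp",
    "filter_cosmic",
    "filter_shared",
    "run_cascade",
]

EXON_PAD = 2  # bp added to each side of every exon

_VALID_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class VariantCall:
    """A single-nucleotide variant call in one sample (1-based position)."""

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str = "."
    sample: str = "."

    def __post_init__(self):
        if self.ref not in _VALID_BASES or self.alt not in _VALID_BASES:
            raise ValueError(f"alleles must be single nucleotides, got {self.ref}>{self.alt}")
        if self.ref == self.alt:
            raise ValueError("ref and alt alleles are identical")
        if self.pos < 1:
            raise ValueError("position must be 1-based and positive")

    @property
    def key(self) -> tuple:
        """Identity of the variant irrespective of sample: (chrom, pos, ref, alt)."""
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class AnnotationResources:
    """Known-variant set, driver-gene list and exon intervals.

    ``exons`` maps chromosome -> sorted tuple of (start, end) 0-based
    half-open intervals (assumed non-overlapping after merging).
    """

    known_variants: frozenset
    driver_genes: frozenset
    exons: dict

    def merged_exons(self) -> dict:
        out = {}
        for chrom, ivs in self.exons.items():
            merged = []
            for s, e in sorted(ivs):
                if merged and s <= merged[-1][1]:
                    merged[-1] = (merged[-1][0], max(merged[-1][1], e))
                else:
                    merged.append((s, e))
            out[chrom] = merged
        return out


@dataclass
class CascadeAudit:
    """Ordered (step, sample, n_in, n_out) records of the filter cascade."""

    records: list = field(default_factory=list)

    def add(self, step: str, sample: str, n_in: int, n_out: int) -> None:
        if n_out > n_in:
            raise ValueError(f"audit violation at {step}/{sample}: {n_out} > {n_in}")
        self.records.append({"step": step, "sample": sample, "n_in": n_in, "n_out": n_out})

    def to_json(self, indent: int = 2) -> str:
        return json.dumps({"cascade": self.records}, indent=indent)


def subtract_germline(tumor_calls: list, germline_calls: list) -> list:
    """Tumor calls whose (chrom, pos, ref, alt) is absent from the germline set."""
    germline_keys = {c.key for c in germline_calls}
    return [c for c in tumor_calls if c.key not in germline_keys]


def restrict_exonic(calls: list, exons: dict, pad: int = EXON_PAD) -> list:
    """Keep calls within an exon interval expanded by ``pad`` bp each side."""
    merged = {}
    for chrom, ivs in exons.items():
        merged[chrom] = sorted(ivs)

    def _in_exon(call) -> bool:
        p0 = call.pos - 1  # to 0-based
        for s, e in merged.get(call.chrom, ()):
            if s - pad <= p0 < e + pad:
                return True
        return False

    return [c for c in calls if _in_exon(c)]


def annotate_dbsnp(calls: list, known_set) -> tuple:
    """Partition calls into (known, novel) by membership of the resource.

    Returns ``(known_calls, novel_calls, counts)`` with
    ``counts = {'total', 'known', 'novel'}``; known + novel = total.
    """
    known_set = set(known_set)
    known = [c for c in calls if c.key in known_set]
    novel = [c for c in calls if c.key not in known_set]
    counts = {"total": len(calls), "known": len(known), "novel": len(novel)}
    return known, novel, counts


def filter_cosmic(calls: list, driver_genes) -> list:
    """Keep calls whose gene symbol is in the driver-gene list."""
    driver_genes = set(driver_genes)
    return [c for c in calls if c.gene in driver_genes]


def filter_shared(calls_by_sample: dict, min_samples: int = 3) -> list:
    """SNV keys observed in at least ``min_samples`` distinct samples.

    Returns the shared variant keys sorted by genomic coordinate.
    """
    if min_samples < 2:
        raise ValueError("min_samples must be >= 2")
    carriers: dict = {}
    for sample, calls in calls_by_sample.items():
        for c in calls:
            carriers.setdefault(c.key, set()).add(sample)
    shared = [k for k, s in carriers.items() if len(s) >= min_samples]
    return sorted(shared)


def run_cascade(
    tumor_calls: dict,
    germline_calls: list,
    resources: AnnotationResources,
    min_samples: int = 3,
) -> tuple:
    """Run the full cascade; returns ``(candidates, audit)``.

    ``candidates`` is a list of dicts (chrom, pos, ref, alt, gene,
    samples) for each SNV surviving all four filters.
    """
    audit = CascadeAudit()
    filtered: dict = {}
    for sample in sorted(tumor_calls):
        calls = tumor_calls[sample]
        somatic = subtract_germline(calls, germline_calls)
        audit.add("subtract_germline", sample, len(calls), len(somatic))
        exonic = restrict_exonic(somatic, resources.exons)
        audit.add("restrict_exonic", sample, len(somatic), len(exonic))
        drivers = filter_cosmic(exonic, resources.driver_genes)
        audit.add("filter_cosmic", sample, len(exonic), len(drivers))
        filtered[sample] = drivers

    shared_keys = filter_shared(filtered, min_samples=min_samples)
    for sample in sorted(filtered):
        kept = [c for c in filtered[sample] if c.key in set(shared_keys)]
        audit.add("filter_shared", sample, len(filtered[sample]), len(kept))

    gene_of = {}
    samples_of: dict = {}
    for sample, calls in filtered.items():
        for c in calls:
            if c.key in set(shared_keys):
                gene_of[c.key] = c.gene
                samples_of.setdefault(c.key, set()).add(sample)

    candidates = [
        {
            "chrom": k[0],
            "pos": k[1],
            "ref": k[2],
            "alt": k[3],
            "gene": gene_of[k],
            "samples": sorted(samples_of[k]),
        }
        for k in shared_keys
    ]
    return candidates, audit
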