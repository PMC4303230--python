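"""Synthetic-data generators for every pipeline input.

Produces nucleosomal fragment-size mixtures, shallow-WGS bin counts with
planted copy-number aberrations attenuated by tumor fraction, binomial
deep-sequencing counts at planted SNVs, a seven-lesion index-patient
fixture (four primary tumor foci are sampled as A/C/D plus three lymph
node metastases), and a full plasma cohort with a configurable
biphasic/monophasic x detected/undetected composition.

All randomness flows through one explicitly passed seeded generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from scipy.special import expit
from scipy.stats import norm

from .genome import (
    CNAEvent,
    GenomeModel,
    breast_archetype_events,
    ctc_extra_events,
    event_delta_per_bin,
    events_from_arm_spec,
    hg19_genome,
    index_tumor_events,
)
from .sizing import SizeHistogram
from .variants import AnnotationResources, VariantCall

__all__ = [
    "simulate_bin_counts",
    "simulate_size_histogram",
    "simulate_deep_seq_counts",
    "tumor_fraction_to_af",
    "uniform_baseline",
    "LesionSpec",
    "IndexPatientFixture",
    "make_index_patient_fixture",
    "simulate_index_af_matrix",
    "CohortConfig",
    "CohortSample",
    "CohortBundle",
    "simulate_cohort",
    "make_germline_dbsnp_fixture",
    "make_variant_cascade_fixture",
    "INDEX_GENES",
    "TRUNCAL_GENES",
]

NUCLEOSOME_CENTERS = (162.0, 324.0, 486.0)  # 142 bp core + 20 bp linker multiples
DEFAULT_COMPONENT_SD = 15.0

# the eight informative genes of the index patient; first five are truncal
INDEX_GENES = ("PCDH20", "OR4X1", "ALK", "DNPEP", "SH3TC2", "DDR2", "MLL3", "PIK3CA")
TRUNCAL_GENES = INDEX_GENES[:5]

# (chrom, position) anchor per index gene, hg19-like coordinates
_GENE_LOCI = {
    "PCDH20": ("chr13", 61_322_431),
    "OR4X1": ("chr11", 48_286_190),
    "ALK": ("chr2", 29_443_695),
    "DNPEP": ("chr2", 220_219_432),
    "SH3TC2": ("chr5", 148_406_480),
    "DDR2": ("chr1", 162_601_163),
    "MLL3": ("chr7", 151_845_520),
    "PIK3CA": ("chr3", 178_936_091),
}

_BASES = ("A", "C", "G", "T")


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# elementary generators
# ---------------------------------------------------------------------------

def simulate_bin_counts(
    genome: GenomeModel,
    events: list,
    tumor_fraction: float,
    total_reads: int,
    seed=None,
) -> np.ndarray:
    """Multinomial per-bin read counts for a tumor-fraction-diluted sample.

    The expected count of bin *i* is proportional to
    ``(1 - f) * 2 + f * (2 + delta_i)`` where ``delta_i`` sums the copy
    deltas of the events overlapping the bin.  Counts sum to
    ``total_reads`` exactly.
    """
    if not 0.0 <= tumor_fraction <= 1.0:
        raise ValueError(f"tumor_fraction {tumor_fraction} outside [0, 1]")
    if total_reads <= 0:
        raise ValueError("total_reads must be positive")
    delta = event_delta_per_bin(genome, events)
    weights = 2.0 + tumor_fraction * delta
    if np.any(weights <= 0):
        raise ValueError("events drive expected copy number below zero")
    p = weights / weights.sum()
    return _rng(seed).multinomial(total_reads, p)


def expected_bin_weights(genome: GenomeModel, events: list, tumor_fraction: float) -> np.ndarray:
    """Normalized expected bin proportions (the multinomial ``p`` vector)."""
    delta = event_delta_per_bin(genome, events)
    weights = 2.0 + tumor_fraction * delta
    return weights / weights.sum()


def uniform_baseline(genome: GenomeModel, total: float = 1.0) -> np.ndarray:
    """Expected counts of an aberration-free sample (equal-count-target bins)."""
    return np.full(genome.n_bins, total / genome.n_bins)


def simulate_size_histogram(
    mono_fraction: float,
    di_fraction: float,
    tri_fraction: float = 0.0,
    noise_sd: float = 2.0,
    seed=None,
    n_fragments: int | None = 50_000,
    component_sd: float = DEFAULT_COMPONENT_SD,
    grid: np.ndarray | None = None,
) -> SizeHistogram:
    """Nucleosomal fragment-size mixture with peaks near 162/324/486 bp.

    ``noise_sd`` is per-fragment measurement jitter in bp, added in
    quadrature to the component spread.  With ``n_fragments`` set, the
    density is an (smoothed) empirical histogram of that many sampled
    fragments; with ``n_fragments=None`` the exact mixture density is
    returned (deterministic, seed unused).  The density integrates to 1.
    """
    w = np.array([mono_fraction, di_fraction, tri_fraction], dtype=float)
    if np.any(w < 0):
        raise ValueError("mixture weights must be non-negative")
    if w.sum() <= 0:
        raise ValueError("at least one mixture weight must be positive")
    w = w / w.sum()
    if grid is None:
        grid = np.arange(50.0, 601.0)
    centers = np.asarray(NUCLEOSOME_CENTERS)
    sd_eff = float(np.hypot(component_sd, noise_sd))

    if n_fragments is None:
        density = np.zeros_like(grid, dtype=float)
        for wk, ck in zip(w, centers):
            if wk > 0:
                density += wk * norm.pdf(grid, loc=ck, scale=sd_eff)
    else:
        rng = _rng(seed)
        comp = rng.choice(3, size=n_fragments, p=w)
        sizes = centers[comp] + rng.normal(0.0, sd_eff, size=n_fragments)
        edges = np.concatenate([grid - 0.5, [grid[-1] + 0.5]])
        counts, _ = np.histogram(sizes, bins=edges)
        density = gaussian_filter1d(counts.astype(float), sigma=3.0)

    total = np.trapezoid(density, grid)
    if total <= 0:
        raise ValueError("degenerate histogram (no mass on grid)")
    return SizeHistogram(grid, density / total)


def simulate_deep_seq_counts(true_af: float, depth: int, seed=None) -> tuple:
    """Binomial mutant-read count at a planted SNV: (mutant, total)."""
    if not 0.0 <= true_af <= 1.0:
        raise ValueError(f"true_af {true_af} outside [0, 1]")
    if depth <= 0:
        raise ValueError("depth must be positive")
    mutant = int(_rng(seed).binomial(depth, true_af))
    return mutant, int(depth)


def tumor_fraction_to_af(tumor_fraction: float, heterozygous: bool = True) -> float:
    """Expected plasma AF of a clonal SNV at a given tumor fraction.

    A heterozygous clonal SNV contributes half the tumor-derived
    fragments (local copy-number adjustment ignored).
    """
    return tumor_fraction / 2.0 if heterozygous else tumor_fraction


# ---------------------------------------------------------------------------
# index-patient fixture
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LesionSpec:
    """Planted truth for one lesion/sample: SNV allele fractions,
    copy-number events, tumor fraction and the parent lesion."""

    lesion_id: str
    snv_afs: dict
    events: tuple
    tumor_fraction: float
    parent: str | None = None

    def __post_init__(self):
        for gene, af in self.snv_afs.items():
            if not 0.0 <= af <= 1.0:
                raise ValueError(f"AF {af} for {gene} outside [0, 1]")

    @property
    def snv_set(self) -> frozenset:
        return frozenset(g for g, af in self.snv_afs.items() if af > 0)


@dataclass(frozen=True)
class IndexPatientFixture:
    """Planted seven-lesion phylogeny plus CTC pools and plasma draws."""

    genome: GenomeModel
    lesions: dict       # A, C, D, LN15, LN17, LNA
    ctcs: dict          # CTC pools (descend from the LN clones, +1p loss)
    plasma: dict        # serial plasma samples, true AF 2-3%
    genes: tuple = INDEX_GENES
    truncal_genes: tuple = TRUNCAL_GENES

    def all_samples(self) -> dict:
        return {**self.lesions, **self.ctcs, **self.plasma}


def _lesion_afs() -> dict:
    truncal = {"PCDH20": 0.31, "OR4X1": 0.29, "ALK": 0.30, "DNPEP": 0.32, "SH3TC2": 0.28}
    afs = {
        "A": {**truncal, "DDR2": 0.364, "MLL3": 0.141, "PIK3CA": 0.0},
        "C": {**truncal, "DDR2": 0.153, "MLL3": 0.0, "PIK3CA": 0.0},
        "D": {**truncal, "DDR2": 0.166, "MLL3": 0.0, "PIK3CA": 0.0},
        "LN15": {**truncal, "DDR2": 0.35, "MLL3": 0.242, "PIK3CA": 0.25},
        "LN17": {**truncal, "DDR2": 0.34, "MLL3": 0.210, "PIK3CA": 0.24},
        "LNA": {**truncal, "DDR2": 0.33, "MLL3": 0.189, "PIK3CA": 0.26},
    }
    return afs


def make_index_patient_fixture(seed: int = 0, genome: GenomeModel | None = None) -> IndexPatientFixture:
    """Build the planted index-patient bundle.

    Lesion truth: five truncal SNVs in every lesion; DDR2 in all lesions
    with an elevated AF in tumor A (36.4%) versus C (15.3%) / D (16.6%);
    MLL3 in A (14.1%) and the lymph nodes (18.9-24.2%); PIK3CA in the
    lymph nodes only.  CTC pools carry all eight SNVs and add a 1p loss.
    Plasma samples carry all eight SNVs at a true AF drawn uniformly in
    [0.02, 0.03].
    """
    rng = _rng(seed)
    if genome is None:
        genome = hg19_genome(n_bins=2_000)

    base = tuple(index_tumor_events(genome))
    # small lineage-private events so copy-number clustering can separate
    # the groups (the paper's dendrogram separates them empirically)
    a_extra = tuple(events_from_arm_spec(genome, gains=["20q"]))
    ln_extra = tuple(events_from_arm_spec(genome, gains=["17q"]))
    ctc_extra = tuple(ctc_extra_events(genome))

    afs = _lesion_afs()
    lesions = {
        "C": LesionSpec("C", afs["C"], base, 0.75, parent=None),
        "D": LesionSpec("D", afs["D"], base, 0.75, parent=None),
        "A": LesionSpec("A", afs["A"], base + a_extra, 0.75, parent="C"),
        "LN15": LesionSpec("LN15", afs["LN15"], base + a_extra + ln_extra, 0.75, parent="A"),
        "LN17": LesionSpec("LN17", afs["LN17"], base + a_extra + ln_extra, 0.75, parent="A"),
        "LNA": LesionSpec("LNA", afs["LNA"], base + a_extra + ln_extra, 0.75, parent="A"),
    }

    ctc_events = base + a_extra + ln_extra + ctc_extra
    ctcs = {}
    for i in range(1, 4):
        ctc_afs = {g: float(np.clip(rng.normal(0.42, 0.03), 0.2, 0.7)) for g in INDEX_GENES}
        ctcs[f"CTC{i}"] = LesionSpec(f"CTC{i}", ctc_afs, ctc_events, 0.95, parent="LN15")

    plasma = {}
    for i in range(1, 4):
        f = float(rng.uniform(0.02, 0.03))
        plasma_afs = {g: f for g in INDEX_GENES}
        plasma[f"P{i}"] = LesionSpec(f"P{i}", plasma_afs, base + a_extra + ln_extra, f, parent="LN15")

    return IndexPatientFixture(genome=genome, lesions=lesions, ctcs=ctcs, plasma=plasma)


def simulate_index_af_matrix(
    fixture: IndexPatientFixture,
    depth: int = 10_000,
    seed=None,
    samples: dict | None = None,
) -> tuple:
    """Deep-sequence every (lesion, gene) pair of the fixture.

    Returns ``(counts, af_matrix)``: a tidy DataFrame of read counts and
    a lesions x genes allele-fraction matrix.
    """
    rng = _rng(seed)
    if samples is None:
        samples = fixture.lesions
    rows = []
    for sid, spec in samples.items():
        for gene in fixture.genes:
            mut, tot = simulate_deep_seq_counts(spec.snv_afs.get(gene, 0.0), depth, rng)
            rows.append({"variant": gene, "sample": sid, "mut_reads": mut, "total_reads": tot})
    counts = pd.DataFrame(rows)
    af = counts.assign(af=counts.mut_reads / counts.total_reads).pivot(
        index="sample", columns="variant", values="af"
    )
    af = af.loc[list(samples), list(fixture.genes)]
    return counts, af


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortConfig:
    """Composition and sequencing parameters for the plasma cohort.

    The four composition counts are the target 2x2 tally
    (size class x copy-number detectability); their sum is the number
    of plasma samples.  The shipped default reproduces a 32/39
    biphasic/monophasic split with 25 and 3 detected respectively.
    """

    n_biphasic_detected: int = 25
    n_biphasic_undetected: int = 7
    n_monophasic_detected: int = 3
    n_monophasic_undetected: int = 36
    n_patients: int = 57
    detected_tf_range: tuple = (0.35, 0.55)
    undetected_tf_range: tuple = (0.01, 0.035)
    biphasic_di_range: tuple = (0.15, 0.30)
    event_rate: float = 0.9          # per-sample inclusion prob. of each archetype event
    total_reads: int = 200_000
    hist_fragments: int = 20_000
    noise_sd: float = 2.0
    liver_log_odds: float = 2.0
    genome_bins: int = 2_000

    def __post_init__(self):
        counts = (
            self.n_biphasic_detected,
            self.n_biphasic_undetected,
            self.n_monophasic_detected,
            self.n_monophasic_undetected,
        )
        if any(c < 0 for c in counts):
            raise ValueError("composition counts must be non-negative")
        if sum(counts) == 0:
            raise ValueError("cohort composition is empty")
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")

    @property
    def n_samples(self) -> int:
        return (
            self.n_biphasic_detected
            + self.n_biphasic_undetected
            + self.n_monophasic_detected
            + self.n_monophasic_undetected
        )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        d = dict(d)
        for key in ("detected_tf_range", "undetected_tf_range", "biphasic_di_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass(frozen=True)
class CohortSample:
    sample_id: str
    patient_id: str
    size_class: str          # planted truth
    detectable: bool         # planted truth
    tumor_fraction: float
    liver_metastasis: bool
    events: tuple
    hist: SizeHistogram = field(repr=False)
    counts: np.ndarray = field(repr=False)


@dataclass(frozen=True)
class CohortBundle:
    genome: GenomeModel
    config: CohortConfig
    samples: tuple
    baseline: np.ndarray = field(repr=False)

    def metadata(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample": [s.sample_id for s in self.samples],
                "patient": [s.patient_id for s in self.samples],
                "true_size_class": [s.size_class for s in self.samples],
                "true_detectable": [int(s.detectable) for s in self.samples],
                "tumor_fraction": [round(s.tumor_fraction, 6) for s in self.samples],
                "liver_metastasis": [int(s.liver_metastasis) for s in self.samples],
            }
        )


def simulate_cohort(config: CohortConfig, seed: int = 0, genome: GenomeModel | None = None) -> CohortBundle:
    """Generate the plasma cohort: size histograms, bin counts, metadata.

    Each sample's tumor fraction and dinucleosomal weight are drawn so
    that the default classifiers reproduce the configured 2x2 tally.
    Unbalanced samples carry a random subset of the recurrent
    breast-cancer aberrations (losses 1p/8p/13q/16q, gains 1q/8q/16p/17q).
    """
    rng = _rng(seed)
    if genome is None:
        genome = hg19_genome(n_bins=config.genome_bins)
    archetype = breast_archetype_events(genome)

    cells = (
        [("biphasic", True)] * config.n_biphasic_detected
        + [("biphasic", False)] * config.n_biphasic_undetected
        + [("monophasic", True)] * config.n_monophasic_detected
        + [("monophasic", False)] * config.n_monophasic_undetected
    )
    order = rng.permutation(len(cells))

    samples = []
    for i, idx in enumerate(order):
        size_class, detectable = cells[idx]
        lo, hi = config.detected_tf_range if detectable else config.undetected_tf_range
        tf = float(rng.uniform(lo, hi))

        if detectable:
            keep = rng.random(len(archetype)) < config.event_rate
            if keep.sum() < 4:  # guarantee enough aberrant genome to call
                keep[rng.choice(len(archetype), 4, replace=False)] = True
            events = tuple(ev for ev, k in zip(archetype, keep) if k)
        else:
            events = ()

        if size_class == "biphasic":
            di = float(rng.uniform(*config.biphasic_di_range))
            tri = 0.25 * di
        else:
            di = tri = 0.0
        hist = simulate_size_histogram(
            1.0 - di - tri, di, tri,
            noise_sd=config.noise_sd, seed=rng, n_fragments=config.hist_fragments,
        )
        counts = simulate_bin_counts(genome, list(events), tf, config.total_reads, rng)

        p_liver = float(expit(-1.5 + config.liver_log_odds * (tf - 0.2) / 0.2))
        liver = bool(rng.random() < p_liver)

        samples.append(
            CohortSample(
                sample_id=f"B{i + 1:02d}",
                patient_id=f"PT{(i % config.n_patients) + 1:02d}",
                size_class=size_class,
                detectable=detectable,
                tumor_fraction=tf,
                liver_metastasis=liver,
                events=events,
                hist=hist,
                counts=counts,
            )
        )

    baseline = uniform_baseline(genome, total=float(config.total_reads))
    return CohortBundle(genome=genome, config=config, samples=tuple(samples), baseline=baseline)


# ---------------------------------------------------------------------------
# variant-call fixtures
# ---------------------------------------------------------------------------

def _random_call(rng, chrom: str, lo: int, hi: int, gene: str, sample: str, used: set) -> VariantCall:
    while True:
        pos = int(rng.integers(lo, hi))
        ref, alt = rng.choice(4, size=2, replace=False)
        key = (chrom, pos, _BASES[ref], _BASES[alt])
        if key not in used:
            used.add(key)
            return VariantCall(chrom, pos, _BASES[ref], _BASES[alt], gene, sample)


def make_germline_dbsnp_fixture(seed: int = 0, n_total: int = 21_741, n_known: int = 20_749) -> tuple:
    """Germline call set of ``n_total`` SNVs of which ``n_known`` are in
    the known-variant resource.  Returns ``(calls, known_set)``."""
    if not 0 <= n_known <= n_total:
        raise ValueError("need 0 <= n_known <= n_total")
    rng = _rng(seed)
    used: set = set()
    calls = [
        _random_call(rng, "chr1", 1_000_000, 240_000_000, f"G{i:05d}", "germline", used)
        for i in range(n_total)
    ]
    known_idx = rng.choice(n_total, size=n_known, replace=False)
    known = {calls[i].key for i in known_idx}
    # pad the resource with known variants not present in this sample
    for i in range(2_000):
        extra = _random_call(rng, "chr2", 1_000_000, 240_000_000, f"X{i:05d}", "resource", used)
        known.add(extra.key)
    return calls, known


@dataclass(frozen=True)
class VariantCascadeFixture:
    tumor_calls: dict            # sample -> list of VariantCall
    germline_calls: list
    resources: AnnotationResources
    planted_genes: tuple = INDEX_GENES


# which index genes each sample carries
_PRESENCE = {
    "A": INDEX_GENES[:7],
    "C": INDEX_GENES[:6],
    "D": INDEX_GENES[:6],
    "LN15": INDEX_GENES,
    "LN17": INDEX_GENES,
    "LNA": INDEX_GENES,
}

# somatic call counts per sample after germline subtraction (range 716-1589)
_SOMATIC_N = {"C": 716, "LN15": 1589, "A": 1104, "D": 967, "LN17": 1312, "LNA": 1248}


def make_variant_cascade_fixture(seed: int = 0, n_germline: int = 3_000) -> VariantCascadeFixture:
    """Tumor/germline call tables plus annotation resources for which the
    filter cascade returns exactly the eight planted index-gene SNVs.

    Per sample the somatic set holds the planted SNVs, a handful of
    private driver-gene passengers (so the driver filter leaves < 20
    calls), many non-driver exonic passengers and ~8% non-exonic calls.
    """
    rng = _rng(seed)
    used: set = set()

    # gene models: index genes + driver pool + passenger pool, one exon each
    gene_loci = dict(_GENE_LOCI)
    for i in range(30):
        gene_loci[f"DRV{i:02d}"] = ("chr9", 1_000_000 + i * 200_000)
    for i in range(400):
        gene_loci[f"PSG{i:03d}"] = ("chr4", 1_000_000 + i * 300_000)
    driver_genes = set(INDEX_GENES) | {f"DRV{i:02d}" for i in range(30)}

    exons = {}
    for gene, (chrom, pos) in gene_loci.items():
        exons.setdefault(chrom, []).append((pos - 500, pos + 500))

    # fixed planted SNV per index gene, shared across carrying samples
    planted = {}
    for gene in INDEX_GENES:
        chrom, pos = gene_loci[gene]
        ref, alt = "C", "T"
        used.add((chrom, pos, ref, alt))
        planted[gene] = (chrom, pos, ref, alt)

    germline = []
    psg_names = [f"PSG{i:03d}" for i in range(400)]
    for i in range(n_germline):
        gene = psg_names[int(rng.integers(0, 400))]
        chrom, pos = gene_loci[gene]
        germline.append(_random_call(rng, chrom, pos - 480, pos + 480, gene, "germline", used))
    known = {c.key for c in germline}

    tumor_calls = {}
    for sample, n_somatic in _SOMATIC_N.items():
        calls = [VariantCall(*planted[g], g, sample) for g in _PRESENCE[sample]]
        n_driver_psg = int(rng.integers(4, 9))
        for _ in range(n_driver_psg):
            gene = f"DRV{int(rng.integers(0, 30)):02d}"
            chrom, pos = gene_loci[gene]
            calls.append(_random_call(rng, chrom, pos - 480, pos + 480, gene, sample, used))
        n_rest = n_somatic - len(calls)
        n_nonexonic = int(round(0.08 * n_rest))
        for _ in range(n_nonexonic):
            calls.append(_random_call(rng, "chr6", 70_000_000, 100_000_000, ".", sample, used))
        for _ in range(n_rest - n_nonexonic):
            gene = psg_names[int(rng.integers(0, 400))]
            chrom, pos = gene_loci[gene]
            calls.append(_random_call(rng, chrom, pos - 480, pos + 480, gene, sample, used))
        assert len(calls) == n_somatic
        # germline variants appear in the tumor too and must be subtracted
        tumor_calls[sample] = calls + [
            VariantCall(c.chrom, c.pos, c.ref, c.alt, c.gene, sample) for c in germline
        ]

    resources = AnnotationResources(
        known_variants=frozenset(known),
        driver_genes=frozenset(driver_genes),
        exons={c: tuple(sorted(iv)) for c, iv in exons.items()},
    )
    return VariantCascadeFixture(
        tumor_calls=tumor_calls, germline_calls=germline, resources=resources
    )
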