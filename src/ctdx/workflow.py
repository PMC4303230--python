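"""End-to-end pipelines with reproducible run manifests.

Two orchestrations:

* cohort:  simulate -> size-classify -> copy-number profile -> 2x2 tally
  -> chi-squared -> recurrence summary
* index patient: variant cascade -> deep-seq AF matrix -> clonal ordering
  -> copy-number clustering -> mutant-fragment totals
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

from . import __version__
from . import io as ctdx_io
from .afquant import (
    INDEX_PER_ML_AVERAGES,
    compute_af,
    DeepSeqCount,
    total_mutant_fragments,
)
from .clonal import AFMatrix, assign_sample, order_lesions, truncal_set
from .cnv import (
    call_status,
    counts_to_log2,
    hcluster_complete,
    is_balanced,
    manhattan_distance_matrix,
    recurrence_summary,
    segment_profile,
)
from .simulate import (
    CohortConfig,
    make_index_patient_fixture,
    make_variant_cascade_fixture,
    simulate_bin_counts,
    simulate_cohort,
    simulate_index_af_matrix,
    uniform_baseline,
)
from .sizing import classify_profile
from .stats import chi_square_2x2, row_percentages, tally_cohort
from .variants import run_cascade

__all__ = ["RunManifest", "run_cohort_pipeline", "run_index_pipeline"]

log = logging.getLogger("ctdx")


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    version: str
    files: dict = field(default_factory=dict)
    created: str = ""

    def record(self, path: Path) -> None:
        digest = hashlib.sha256(Path(path).read_bytes()).hexdigest()
        self.files[Path(path).name] = digest

    def write(self, path: Path) -> None:
        payload = {
            "config_hash": self.config_hash,
            "seed": self.seed,
            "version": self.version,
            "files": dict(sorted(self.files.items())),
            "created": self.created,
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def _setup_logging() -> None:
    if not log.handlers:
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(logging.Formatter("[%(name)s:%(levelname)s] %(message)s"))
        log.addHandler(handler)
        log.setLevel(logging.INFO)


def _hash_config(payload: dict) -> str:
    return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()


@dataclass
class CohortResult:
    table: object
    percentages: tuple
    chi2: tuple
    recurrence: object
    size_calls: list
    balanced: list
    manifest: RunManifest


def run_cohort_pipeline(
    config: CohortConfig | None,
    seed: int,
    out_dir,
    genome=None,
    write_per_sample: bool = False,
) -> CohortResult:
    """Simulate the cohort and run all cohort-level analyses."""
    _setup_logging()
    if config is None:
        config = CohortConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config_hash=_hash_config(config.to_dict()),
        seed=seed,
        version=__version__,
        created=datetime.now(timezone.utc).isoformat(timespec="seconds"),
    )

    log.info("stage=simulate n_samples=%d", config.n_samples)
    bundle = simulate_cohort(config, seed=seed, genome=genome)
    meta_path = out / "metadata.tsv"
    bundle.metadata().to_csv(meta_path, sep="\t", index=False)
    manifest.record(meta_path)

    log.info("stage=size-classify")
    size_calls = [classify_profile(s.hist) for s in bundle.samples]

    log.info("stage=cn-profile")
    profiles, balanced = [], []
    for s in bundle.samples:
        prof = counts_to_log2(s.counts, bundle.baseline, bundle.genome, sample_id=s.sample_id)
        called = call_status(segment_profile(prof))
        profiles.append(called)
        balanced.append(is_balanced(called))
        if write_per_sample:
            ctdx_io.write_histogram(out / f"hist_{s.sample_id}.tsv", s.hist)
            ctdx_io.write_bin_counts(out / f"counts_{s.sample_id}.tsv", bundle.genome, s.counts)

    log.info("stage=tally")
    table = tally_cohort(size_calls, balanced)
    pct = row_percentages(table)
    chi2 = chi_square_2x2(table)

    log.info("stage=recurrence")
    rec = recurrence_summary(profiles)
    rec_path = out / "recurrence.tsv"
    rec.to_dataframe().to_csv(rec_path, sep="\t", index=False, float_format="%.6f")
    manifest.record(rec_path)

    results_path = out / "cohort_results.json"
    ctdx_io.write_json(
        results_path,
        {
            "table": {"a": table.a, "b": table.b, "c": table.c, "d": table.d},
            "biphasic_detected_pct": pct[0],
            "monophasic_detected_pct": pct[1],
            "chi2_statistic": round(chi2[0], 6),
            "chi2_df": chi2[1],
            "chi2_p": chi2[2],
            "n_unbalanced": rec.n_profiles,
        },
    )
    manifest.record(results_path)
    manifest.write(out / "manifest.json")
    log.info("stage=done table=(%d,%d,%d,%d) p=%.3g", table.a, table.b, table.c, table.d, chi2[2])
    return CohortResult(table, pct, chi2, rec, size_calls, balanced, manifest)


@dataclass
class IndexResult:
    candidates: list
    audit: object
    af_matrix: object
    tree: object
    ctc_assignments: dict
    dendrogram: object
    fragment_totals: list
    manifest: RunManifest


def run_index_pipeline(seed: int, out_dir, depth: int = 10_000, reads_per_sample: int = 200_000) -> IndexResult:
    """Full index-patient analysis from the planted fixture."""
    _setup_logging()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config_hash=_hash_config({"seed": seed, "depth": depth, "reads": reads_per_sample}),
        seed=seed,
        version=__version__,
        created=datetime.now(timezone.utc).isoformat(timespec="seconds"),
    )

    log.info("stage=variant-cascade")
    vfix = make_variant_cascade_fixture(seed=seed)
    candidates, audit = run_cascade(
        vfix.tumor_calls, vfix.germline_calls, vfix.resources, min_samples=3
    )
    (out / "audit.json").write_text(audit.to_json() + "\n")
    manifest.record(out / "audit.json")
    ctdx_io.write_json(out / "candidates.json", candidates)
    manifest.record(out / "candidates.json")

    log.info("stage=deep-seq n_candidates=%d", len(candidates))
    fixture = make_index_patient_fixture(seed=seed)
    counts_df, af = simulate_index_af_matrix(fixture, depth=depth, seed=seed + 1)
    af_path = out / "af_matrix.tsv"
    af.T.to_csv(af_path, sep="\t", float_format="%.6f")  # variant rows, lesion columns
    manifest.record(af_path)

    log.info("stage=clonal-ordering")
    matrix = AFMatrix(af)
    tree = order_lesions(matrix)
    (out / "clone_tree.json").write_text(tree.to_json() + "\n")
    manifest.record(out / "clone_tree.json")

    _, ctc_af = simulate_index_af_matrix(fixture, depth=depth, seed=seed + 2, samples=fixture.ctcs)
    ctc_assignments = {
        sid: assign_sample(ctc_af.loc[sid].to_dict(), tree) for sid in ctc_af.index
    }

    log.info("stage=clustering")
    genome = fixture.genome
    baseline = uniform_baseline(genome, total=float(reads_per_sample))
    specs = {**fixture.lesions, **fixture.ctcs}
    profiles = []
    for i, (sid, spec) in enumerate(sorted(specs.items())):
        counts = simulate_bin_counts(
            genome, list(spec.events), spec.tumor_fraction, reads_per_sample, seed + 10 + i
        )
        prof = counts_to_log2(counts, baseline, genome, sample_id=sid)
        profiles.append(call_status(segment_profile(prof)))
    dist = manhattan_distance_matrix(profiles)
    dendro = hcluster_complete(dist, [p.sample_id for p in profiles])
    (out / "dendrogram.nwk").write_text(dendro.newick + "\n")
    manifest.record(out / "dendrogram.nwk")

    log.info("stage=fragment-totals")
    totals = [total_mutant_fragments(per_ml) for per_ml in INDEX_PER_ML_AVERAGES]
    ctdx_io.write_json(
        out / "fragment_totals.json",
        [
            {
                "per_ml": t.per_ml,
                "weight_kg": t.weight_kg,
                "v_ml_per_kg": t.v_ml_per_kg,
                "total": t.total,
                "total_2sf": t.total_2sf,
            }
            for t in totals
        ],
    )
    manifest.record(out / "fragment_totals.json")

    af_estimates = [
        compute_af(DeepSeqCount(r.variant, r.sample, r.mut_reads, r.total_reads))
        for r in counts_df.itertuples(index=False)
    ]
    ctdx_io.write_json(
        out / "af_estimates.json",
        [
            {"variant": e.variant, "sample": e.sample, "af": round(e.af, 6), "detected": e.detected}
            for e in af_estimates
        ],
    )
    manifest.record(out / "af_estimates.json")
    ctdx_io.write_json(out / "ctc_assignments.json", ctc_assignments)
    manifest.record(out / "ctc_assignments.json")

    manifest.write(out / "manifest.json")
    log.info("stage=done candidates=%d roots=%s", len(candidates), tree.roots)
    return IndexResult(
        candidates=candidates,
        audit=audit,
        af_matrix=matrix,
        tree=tree,
        ctc_assignments=ctc_assignments,
        dendrogram=dendro,
        fragment_totals=totals,
        manifest=manifest,
    )
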