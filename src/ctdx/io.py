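"""Plain-text readers/writers for the pipeline's file contracts.

All tables are tab-separated with a header line; coordinates in bin and
BED tables are 0-based half-open, variant positions are 1-based.  Output
formatting is fixed so identical inputs yield byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import GenomeModel, make_genome_model
from .sizing import SizeHistogram
from .variants import VariantCall

__all__ = [
    "write_bin_counts",
    "read_bin_counts",
    "write_histogram",
    "read_histogram",
    "write_profile",
    "read_profile",
    "write_variants_tsv",
    "read_variants_tsv",
    "write_vcf",
    "read_vcf",
    "read_bed",
    "write_json",
]

_STATUS_CODE = {"loss": -1, "neutral": 0, "gain": 1, ".": 0}


def write_bin_counts(path, genome: GenomeModel, counts: np.ndarray) -> None:
    df = pd.DataFrame(
        {
            "chrom": genome.bin_chrom,
            "start": genome.bin_start,
            "end": genome.bin_end,
            "count": np.asarray(counts),
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_bin_counts(path) -> tuple:
    """Returns ``(genome, counts)``; the genome is rebuilt from the grid."""
    df = pd.read_csv(path, sep="\t")
    genome = _genome_from_bins(df)
    return genome, df["count"].to_numpy()


def _genome_from_bins(df: pd.DataFrame) -> GenomeModel:
    lengths = df.groupby("chrom", sort=False)["end"].max().to_dict()
    n_bins = len(df)
    genome = make_genome_model(lengths, n_bins=n_bins)
    # trust the file's own grid rather than the reconstruction
    return GenomeModel(
        chromosomes=genome.chromosomes,
        lengths=genome.lengths,
        centromeres=genome.centromeres,
        bin_chrom=df["chrom"].to_numpy(dtype=object),
        bin_start=df["start"].to_numpy(dtype=np.int64),
        bin_end=df["end"].to_numpy(dtype=np.int64),
        bin_arm=genome.bin_arm,
    )


def write_histogram(path, hist: SizeHistogram) -> None:
    df = pd.DataFrame({"size_bp": hist.sizes, "density": hist.density})
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_histogram(path) -> SizeHistogram:
    df = pd.read_csv(path, sep="\t")
    return SizeHistogram(df["size_bp"].to_numpy(), df["density"].to_numpy())


def write_profile(path, profile) -> None:
    profile.to_dataframe().to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_profile(path):
    from .cnv import CopyNumberProfile

    df = pd.read_csv(path, sep="\t")
    genome = _genome_from_bins(df.rename(columns={"log2": "count"}))
    status = None
    if "status" in df and not (df["status"] == ".").all():
        status = df["status"].map(_STATUS_CODE).to_numpy(dtype=np.int8)
    return CopyNumberProfile(genome=genome, log2=df["log2"].to_numpy(), status=status)


def write_variants_tsv(path, calls: list) -> None:
    df = pd.DataFrame(
        [
            {"chrom": c.chrom, "pos": c.pos, "ref": c.ref, "alt": c.alt,
             "gene": c.gene, "sample": c.sample}
            for c in calls
        ],
        columns=["chrom", "pos", "ref", "alt", "gene", "sample"],
    )
    df.to_csv(path, sep="\t", index=False)


def read_variants_tsv(path) -> list:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "gene": str, "sample": str})
    return [
        VariantCall(r.chrom, int(r.pos), r.ref, r.alt, r.gene, r.sample)
        for r in df.itertuples(index=False)
    ]


def write_vcf(path, calls: list, sample: str = "SAMPLE") -> None:
    """Minimal VCF 4.2 writer (sites only, GENE in INFO)."""
    lines = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
    ]
    for c in calls:
        info = f"GENE={c.gene}" if c.gene != "." else "."
        lines.append(f"{c.chrom}\t{c.pos}\t.\t{c.ref}\t{c.alt}\t.\tPASS\t{info}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_vcf(path, sample: str = ".") -> list:
    """Minimal VCF reader for single-nucleotide records."""
    calls = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        chrom, pos, _, ref, alt = fields[:5]
        if len(ref) != 1 or len(alt) != 1:
            continue  # SNVs only
        gene = "."
        if len(fields) > 7:
            for kv in fields[7].split(";"):
                if kv.startswith("GENE="):
                    gene = kv[5:]
        calls.append(VariantCall(chrom, int(pos), ref, alt, gene, sample))
    return calls


def read_bed(path) -> dict:
    """BED (0-based half-open) -> {chrom: [(start, end), ...]} sorted."""
    exons: dict = {}
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith(("#", "track", "browser")):
            continue
        chrom, start, end = line.split("\t")[:3]
        exons.setdefault(chrom, []).append((int(start), int(end)))
    return {c: sorted(iv) for c, iv in exons.items()}


def write_json(path, payload) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
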