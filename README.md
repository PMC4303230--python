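# ctdx

Analysis toolkit for plasma circulating tumor DNA (ctDNA) in metastatic
breast cancer, with a synthetic-data generator covering every input the
pipeline consumes:

- **`ctdx.simulate`** — synthetic cohort generator: nucleosomal
  fragment-size mixtures (peaks near 162/324/486 bp), shallow-WGS bin
  counts with planted copy-number aberrations attenuated by tumor
  fraction, binomial deep-sequencing counts at planted SNVs, a planted
  seven-lesion index-patient phylogeny, and a 71-sample plasma cohort
  with configurable biphasic/monophasic × detected/undetected
  composition.
- **`ctdx.sizing`** — fragment-size histograms: band masses (85–250 and
  250–450 bp), peak detection, monophasic/biphasic classification.
- **`ctdx.cnv`** — per-bin log2 copy-number profiles, penalized
  least-squares segmentation, gain/loss calling, balanced/unbalanced
  flagging, cohort recurrence summaries, Manhattan-distance matrices on
  copy-number statuses and deterministic complete-linkage clustering.
- **`ctdx.variants`** — somatic SNV filter cascade (germline
  subtraction → exon ± 2 bp restriction → driver-gene filter →
  shared-across-samples filter) with a per-step audit trail.
- **`ctdx.afquant`** — allele fractions from deep-sequencing read counts
  (1% detection cutoff), AF summaries, and whole-body mutant-fragment
  totals from per-ml plasma concentrations (volume of distribution
  60 ml/kg).
- **`ctdx.clonal`** — clonal ordering of lesions from an AF matrix:
  presence binarization, truncal set, containment (Hasse) tree with
  "newly gained" and "AF increased" edge annotations, sample-to-node
  assignment.
- **`ctdx.stats`** — 2×2 contingency tally of size-profile class versus
  copy-number detectability, row percentages, Pearson chi-squared test.
- **`ctdx.workflow`** — end-to-end cohort and index-patient pipelines
  with seeded determinism and checksum manifests.

## CLI

The `ctdx` umbrella command exposes each stage:

```sh
ctdx simulate-cohort --seed 1 --out sim/        # histograms, bin counts, metadata
ctdx size-classify --hist sim/hist_B01.tsv      # one-line JSON size call
ctdx cnprofile --counts sim/counts_B01.tsv --baseline sim/baseline.tsv --out prof.tsv
ctdx cluster --profiles profiles/ --out tree.nwk
ctdx recurrence --profiles profiles/ --out recurrence.tsv
ctdx prioritize --tumor tumor/ --germline germ.tsv --dbsnp dbsnp.tsv \
    --cosmic drivers.txt --exons exons.bed --min-samples 3 --out prio/
ctdx af --counts deepseq.tsv --cutoff 0.01
ctdx fragments-total --per-ml 6320 --weight-kg 60 --vd 60
ctdx clonal --af-matrix af_matrix.tsv --increase-ratio 1.5
ctdx cohort-stats --table 25,7,3,36
ctdx run-cohort --seed 1 --out out/cohort      # full cohort pipeline
ctdx run-index --seed 1 --out out/index        # full index-patient pipeline
```

All tables are plain TSV; bin and BED coordinates are 0-based
half-open, variant positions 1-based. Trees are written as Newick
(dendrograms) or JSON/DOT (clone trees).

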