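# combichip

Combinatorial transcription-factor promoter occupancy analysis for
probe-level ChIP enrichment tracks.

The package turns per-probe log2 IP/input enrichment over TSS-anchored
promoter regions (−1000…+500 bp) into:

- a filtered promoter universe (sex-chromosome, unsequenced-run and
  duplicated-window exclusion rules),
- per-promoter mean enrichments, threshold-based **binding calls** and
  **induced / repressed / unchanged** differential calls (RNA polymerase II,
  H3K9 acetylation, mRNA, MeDIP methylation),
- a 2³ **occupancy-pattern classification** over a three-factor set
  (CREB / C/EBPβ / c-Jun by default; C/EBPα variant available),
- per-pattern **enrichment statistics** against the chance expectation
  (fraction, expected fraction, enrichment ratio, χ² goodness-of-fit,
  pooled/Welch t-test, 15/50/85 percentile summaries),
- **methylation stratification** of the enrichment analyses,
- degenerate **consensus-motif scanning** (IUPAC + `(C/G)` alternation) in
  the −500…0 window with motif-combination enrichment and colocalization
  ratios per occupancy group, and
- a fully **seeded synthetic-data generator** that emits a complete
  truth-tagged bundle (BED, FASTA, bedGraph tracks, expression TSV, truth
  table) so every stage is testable offline.

## CLI

```sh
# generate a synthetic dataset bundle
combichip simulate --seed 1 --n 2000 --outdir sim/

# run the whole pipeline end-to-end
combichip run-all \
    --promoters sim/promoters.bed \
    --sequences sim/sequences.fa \
    --tracks-dir sim/tracks \
    --expression sim/expression.tsv \
    --outdir out/
```

Stages can also be run one at a time (`filter`, `call`, `classify`,
`enrich`, `motifs`, `report`), sharing one output directory; see
`combichip --help`. All outputs are plain TSV/JSON. Thresholds are
configurable through a YAML file (`--thresholds`); defaults are the
published log2 cut-offs (binding: CREB 0.4, C/EBPβ 0.4, C/EBPα 0.36,
c-Jun 0.36, RNAP 0.4; RNAP induction: diff > 0.4 and diff − undiff > 0.3;
H3K9ac delta 0.36; mRNA |log2FC| > 0.5).

### Input formats

- **Promoters**: BED6; the `start` field is the TSS, the `name` field is
  `promoter_id|gene_id1|gene_id2…`.
- **Sequences**: FASTA keyed by promoter id, 1500 bp promoter-strand
  sequence covering −1000…+500.
- **Tracks**: one bedGraph per factor×condition×replicate named
  `FACTOR_condition_repN.bedGraph` (probe position = interval midpoint).
- **Expression**: TSV with `row_id`, identifier columns (`genbank`,
  `symbol`, `unigene_cluster`, `unigene_id`) and `expr_*` value columns.

## Library use

```python
from combichip import SyntheticConfig, generate_dataset
from combichip.pipeline import analyze_bundle

bundle, truth = generate_dataset(SyntheticConfig(seed=1, n_promoters=20_000))
result = analyze_bundle(bundle, truth)
result["enrichment_rnap"]       # per-pattern induction/repression enrichment
result["motif_combo_enrichment"]
result["summary"]
```
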