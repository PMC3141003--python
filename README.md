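# symbiokern

Analysis toolkit for comparing symbiotic and aposymbiotic sea-anemone
transcriptomes on two-color oligoarrays, plus the companion qPCR
quantification workflows. The pipeline covers:

- **synthetic_data** — generators for GPR-like array scans (dye-swap pairs
  against a common aposymbiotic reference), epidermis/gastroderm tissue
  designs, probe annotation, and qPCR plates, all with planted ground truth
  for recovery testing.
- **array_preprocess** — GPR-like TSV ingestion, replicate-spot averaging,
  background correction with a positive offset (default 50), MA computation
  with dye-swap orientation, print-tip loess within-array normalization and
  quantile between-array normalization.
- **diffexpr** — per-gene contrast fits on a per-specimen linear model,
  empirical-Bayes variance moderation (d0, s0² by scaled-F moment matching),
  moderated t and the B log-odds statistic, and the strict |M| > 0.59 &
  B > 0 call rule.
- **state_profiling** — the batch contrast plus the 11 individual-vs-pooled
  contrasts, the per-gene support histogram, the consensus ("Kern")
  selection rule (cnidarian origin, supported in ≥ 8 of 11 individuals),
  and hierarchical specimen clustering with Newick export.
- **tissue_profiling** — gastroderm/epidermis assignment requiring agreement
  of the direct hybridization and the transitive (via-reference) contrast,
  and the disjoint Venn cross-classification against the state calls.
- **qpcr** — standard curves and amplification efficiencies, symbiont:host
  nuclei copy ratios with calibrator normalization, locus-ratio diagnostics,
  reference-gene stability ranking (average pairwise-variation statistic)
  with iterative exclusion, geometric-mean normalization factors,
  calibrator-relative expression, and heat-stress time-course folds.
- **enrichment** — Fisher's exact GO-term enrichment of one gene set against
  another, with optional Benjamini-Hochberg adjustment.
- **pipeline_cli** — end-to-end orchestration, packaged result-table
  fixtures with validators, and the `symbiokern` command.

## Command line

```bash
symbiokern run-all --out demo_run --seed 1         # simulate + all stages
symbiokern validate-fixture                        # check the packaged table
symbiokern simulate --out sim --n-probes 600 --seed 1
symbiokern preprocess --scans sim/scans --design sim/design.tsv --out ma.tsv
symbiokern de --ma ma.tsv --design sim/design.tsv \
    --contrast "batch=Sy1+Sy2+Sy3+Sy4+Sy5/vs/AS1+AS2+AS3+AS4+AS5+AS6" --out de.tsv
symbiokern kern --ma ma.tsv --design sim/design.tsv \
    --annotation sim/annotation.tsv --min-support 8 --out kern_out
symbiokern enrich --test sy.txt --ref apo.txt --annotation sim/annotation.tsv \
    --out enrichment.tsv
```

`run-all` accepts a flat YAML config (`--config run.yaml`) whose keys match
the fields of `pipeline_cli.RunConfig`; all analysis constants (0.59, 0, 8,
11, 50, 0.05) live in `pipeline_cli.DEFAULTS`.

Exit codes: 0 ok, 1 validation failure, 2 runtime error.

## Data formats

All inputs and outputs are plain TSV: GPR-like scans (Block, Row, Column,
ID, F635_Median, B635_Median, F532_Median, B532_Median), a design table
(array_id, cy3_sample, cy5_sample, dye_swap_of), a probe annotation table
(probe_id, origin, go_terms), and long-format qPCR tables (sample, assay,
role, log10_copies, replicate, cq). Real scanner exports can be used after
conversion to these columns.
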