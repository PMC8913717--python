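# allotrace

Longitudinal TCR-beta repertoire analysis for transplant cohorts:

- **Ingestion** of clonotype tables (MiXCR-export or canonical TSV dialects,
  gzip accepted), cohort manifests and VDJdb-style specificity tables.
- **Preprocessing**: CD4/CD8 phenotype-ambiguity correction (a shared
  clonotype goes to the fraction with at least twice the reads, otherwise it
  is removed from both) and sequencing-depth normalization by repeated
  downsampling without replacement (multivariate hypergeometric; metrics are
  reported as means over replicates, 1000 by default).
- **Donor-reactive clonotypes**: called once from the pre-transplant
  unstimulated/MLR-stimulated pair at a fold-change threshold (default ≥ 5 on
  depth-normalized reads), then tracked through post-transplant bulk
  repertoires (% of clonotypes, cumulative frequency) with pre→post delta
  tables.
- **Diversity & overlap**: clonality (1 − Pielou evenness), R20, Jensen–
  Shannon divergence of top-clone and V/J-usage distributions, V×J usage
  matrices (circos-style plot input).
- **Specificity annotation**: exact (optionally fuzzy) CDR3 amino-acid
  matching against a specificity table, per-species cumulative-frequency
  summaries.
- **Cohort statistics**: paired/unpaired t-tests and split-plot mixed ANOVA
  (between: treatment group; within: timepoint) with Mauchly sphericity test
  and Greenhouse–Geisser correction; a headline battery mirrors the study
  design (pre-vs-post paired contrasts, group×time ANOVAs, virus-specificity
  stability, donor-reactive CMV enrichment).
- **Synthetic cohorts**: a generator with programmed ground truth (planted
  donor-reactive sets with MLR expansion, persistence/turnover, ATLG
  lymphodepletion, CD4/CD8 cross-contamination, planted virus-specific
  CDR3s) for end-to-end validation — real cohort data of this kind are
  controlled-access.

## CLI

Generate a synthetic cohort and analyze it:

```sh
allotrace synth cohort --out cohort/ --seed 1

cat > run.yaml <<EOF
manifest: cohort/manifest.tsv
specificity: cohort/specificity.tsv
out_dir: results/
n_replicates: 1000
seed: 1
EOF

allotrace run --config run.yaml
```

`results/` then contains long-format TSV tables (clonotype counts,
clonality, R20, JSD turnover, donor-reactive tracking and deltas,
specificity summaries, per-sample V×J matrices, donor-reactive key lists), a
human-readable `stats_report.txt` and `provenance.json` (config hash, seed,
per-stage row counts). Identical config + seed ⇒ byte-identical output.

Stage subcommands for debugging: `allotrace ingest|ambiguity|reactive|
metrics|annotate|stats` and `allotrace synth fixtures` (hand-checkable toy
tables). See `allotrace --help`.

## Library

```python
from allotrace import (CohortSpec, generate_cohort, call_donor_reactive,
                       clonality, r20, jsd, mixed_anova)

cohort = generate_cohort(CohortSpec(seed=1))
unstim = cohort.repertoires[("P01", "preTx", "CD4", "bulk")]
stim = cohort.repertoires[("P01", "preTx", "CD4", "stimulated")]
reactive = call_donor_reactive(unstim, stim, threshold=5.0)
```

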