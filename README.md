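# drivermosaic

Driver-gene alteration analysis for multi-region tumour cohorts: somatic
variant ingestion and filtering, IHC protein-status classification,
mutation + IHC integration into a patient × gene alteration matrix,
Jaccard-index heterogeneity quantification, and Fisher-exact meta-synthesis
against reference cohort counts — plus a synthetic cohort generator with
known ground truth so every stage is testable without external data.

## Pipeline stages

| Stage          | What it does                                                             |
|----------------|--------------------------------------------------------------------------|
| `simulate`     | generate a synthetic cohort (inputs + truth files)                        |
| `ingest`       | read VCF/TSV calls, normalize, annotate consequences, AF-filter (≥ 0.2 by default), subtract matched normals |
| `score`        | classify IHC measurements (p16 / p53 / SMAD4 / Ki67) per sample and patient |
| `summarize`    | patient × gene alteration calls, matrix TSV, cohort summary JSON          |
| `heterogeneity`| pairwise Jaccard indices and per-patient / per-gene medians               |
| `meta`         | two-sided Fisher exact comparisons against reference cohort counts        |

Run one stage at a time, or everything from a config file:

```bash
drivermosaic simulate --seed 7 --out cohort/
drivermosaic run --config run.cfg
```

`run.cfg` is a flat `key = value` file (CLI flags on subcommands override the
same settings):

```
variants      = cohort/variants.tsv
sample_sheet  = cohort/samples.tsv
ihc_table     = cohort/ihc.tsv
ddpcr_table   = cohort/ddpcr.tsv
outdir        = results
af_threshold  = 0.2
key_mode      = genomic        # or: protein (collapse same protein effect)
```

Outputs: `annotated_variants.tsv`, `ihc_status.tsv`, `alteration_matrix.tsv`,
`cohort_summary.json`, `heterogeneity.tsv`, `heterogeneity_summary.tsv`,
`meta_synthesis.tsv`, `run.log`.

## Input dialects

* **Variants** — VCF 4.x (per-sample genotypes; AF format field or AD depths)
  or TSV with header `sample_id  chrom  pos  ref  alt  af[  qual]`.
* **Sample sheet** — TSV `sample_id  patient_id  tissue_class[  age]`;
  tissue classes `normal, primary_tumour, lymph_node_met, liver_met,
  peritoneal_met, omental_met, abdominal_wall_met` (abbreviations
  N/PT/LNM/LM/PM/OM/AWM accepted).
* **ddPCR table** — TSV `patient_id  sample_id  mutation_label  result`
  (result `positive`/`negative`; labels G12A/C/D/R/S/V, G13D).
* **IHC table** — TSV `sample_id  marker  percent_positive
  nuclear_stain_present  cytoplasmic_stain_present  positive_cells
  cells_counted` (`.` for not-applicable fields).
* **Reference counts** — TSV `cohort  age_class  gene  altered  n`
  (a versioned ICGC table is packaged; literature counts use the same schema).
* **Transcript models** — documented key/value text file
  (`src/drivermosaic/data/transcript_models.txt`) with per-gene coding
  segments, strand, codon offset and amplicon targets.

## Library use

```python
from drivermosaic import (
    CohortConfig, generate_cohort, fisher_exact_two_sided, jaccard,
)

generate_cohort(CohortConfig(n_patients=33, seed=7), "cohort/")
print(fisher_exact_two_sided(155, 504, 17, 16).p_two_sided)  # 0.00072
```
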