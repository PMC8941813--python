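# surfscore

Multi-omic surfaceome target prioritization as a tested, reusable
pipeline. Tumor-vs-normal expression datasets are normalized and tested
for differential expression; upregulated genes are restricted to a
surface-protein catalog; per-cell-line proteomic identification lists
contribute presence channels; and every protein in the combined universe
gets an additive evidence score (default design: 3 genomic datasets +
3 cell lines x 2 proteomic methods = 9 channels, maximum score 9). A
candidate must appear in at least one genomic and one proteomic channel
(prerequisite) and, by default, reach score >= 5.

A seeded synthetic-data generator produces every input format with known
ground truth (planted surface targets, non-surface decoys,
abundance-driven proteomic detection), so the whole pipeline runs and is
tested without any downloads.

## Modules

| module | contents |
| --- | --- |
| `surfscore.synthetic` | `SimulationConfig`, catalog/expression/proteomics generators, TSV/JSON writers |
| `surfscore.preprocess` | quantile normalization, Tukey median-polish summarization, duplicate-gene collapsing, TSV / GEO series-matrix readers |
| `surfscore.diffexp` | log2 fold change, pooled-variance t, empirical-Bayes moderated t, BH adjustment, upregulation filter (p < 0.05, log2FC > 1.5) |
| `surfscore.surfaceome` | catalog parsing, identifier canonicalization, surface filtering |
| `surfscore.evidence` | evidence-matrix assembly, prerequisite + scoring + ranking, Venn region counts, channel reports |
| `surfscore.validation_stats` | Pearson r with t-based p, tumor volume `V = L*W^2/2`, percent-of-control normalization |
| `surfscore.pipeline` / `surfscore.cli` | YAML-configured end-to-end orchestration and the `surfscore` CLI |

## CLI

```bash
# generate synthetic inputs (expression TSVs, proteomics TSV, catalog)
surfscore simulate --seed 1 --out synthetic_inputs

# full pipeline from a YAML config
surfscore run --config examples/config.yaml --seed 1 --out results_dir

# individual stages
surfscore diffexp --expr expression_DS1.tsv --meta metadata_DS1.tsv \
    --stat moderated --p-max 0.05 --lfc-min 1.5 --out de.tsv
surfscore score --proteomics proteomics.tsv --genomic DS1 up_genes.tsv \
    --catalog catalog.tsv --min-score 5 --out candidates.tsv
```

A minimal `run` config:

```yaml
simulation:
  n_genes: 800
  surface_fraction: 0.25
  n_planted: 40
  effect_delta: 3.0
  n_tumor: 10
  n_normal: 10
  seed: 123
min_score: 5
outdir: results_dir
```

Real inputs replace the `simulation` block with `expression` (list of
`{expr, meta, dataset_id}`), `proteomics`, and `catalog` paths. Outputs:
`candidates.tsv`, `de_<dataset>.tsv`, `venn.json`, `report.json`.

Exit codes: 0 success, 2 validation error, 3 stage failure.

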