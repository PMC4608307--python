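# blocknet

Gene-prioritization pipeline for blocked factorial expression studies:
per-gene randomized-complete-block ANOVA with pairwise cell-mean contrasts
and a triple significance filter (contrast p-value, median per-subject fold
change, median absolute intensity difference), Venn partitioning of the
up/down gene sets across the three vs-medium comparisons, hypergeometric
functional-category enrichment with seed-set augmentation, and directed
functional-network ranking by betweenness centrality and HITS hub/authority
scores. A truth-known synthetic-data generator emulates the 8-donor x
4-condition (medium / IgG / IL12 / IgG_IL12) duplicate-array design with
planted effect classes, enriched categories and bridge/hub/authority network
motifs.

## Package layout

| module                  | contents                                                         |
|-------------------------|------------------------------------------------------------------|
| `blocknet.io`           | `ExpressionStudy`, `AnnotationCatalog`, edge tables; TSV/GMT/Pajek read/write, replicate collapse and concordance |
| `blocknet.simulate`     | `SimulationConfig` and the generators for expression, annotations and motif networks |
| `blocknet.de`           | block-treatment ANOVA, cell-mean contrasts, Bonferroni cutoff, triple filter |
| `blocknet.set_analysis` | 7-region Venn partition, variable-gene selection, hierarchical clustering |
| `blocknet.enrichment`   | hypergeometric overrepresentation, BH adjustment, gene-set augmentation |
| `blocknet.network`      | network assembly, Brandes betweenness, HITS power iteration, rank tables |
| `blocknet.pipeline`     | end-to-end orchestration, report directory with checksum manifest |

## CLI

Every stage is a subcommand of `blocknet` and runs standalone on persisted
TSV intermediates:

```bash
blocknet simulate --out fixtures --seed 1 --n-genes 2000
blocknet de --matrix fixtures/matrix.tsv --samples fixtures/samples.tsv --out de_out
blocknet venn --contrasts de_out/contrasts.tsv --out venn.tsv
blocknet cluster --matrix fixtures/matrix.tsv --samples fixtures/samples.tsv \
    --contrasts de_out/contrasts.tsv --out cluster_out
blocknet enrich --genes genes.txt --gmt fixtures/annotations.gmt --out enrichment.tsv
blocknet network --genes genes.txt --edges fixtures/edges.tsv --neighbors --out net_out
blocknet rank --centrality net_out/centrality.tsv
```

The full workflow runs from one YAML config:

```bash
blocknet all --config config.yaml
blocknet summarize --dir <outdir>   # checksum + count verification
```

Minimal config:

```yaml
outdir: run1
seed: 7
simulation:
  n_genes: 2000
  seed: 7
  effect_classes:
    - {name: combo_up, n_genes: 100, log2_effects: [0.0, 0.0, 0.0, 1.585]}
thresholds:
  alpha_per_contrast: 0.008
  fc_threshold: 2
  diff_threshold: 150
```

Exit codes: 0 success, 2 validation/config error, 3 stage failure.

## Tests

```bash
python -m pytest -q
```

`tests/test_acceptance.py` holds the acceptance criteria (oracle
equivalences against brute-force/eigendecomposition/big-integer references,
null calibration, planted-truth recovery, end-to-end determinism).

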