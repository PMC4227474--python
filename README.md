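# tricall

Analysis toolkit for **trinary gene response-call tables** (up / unchanged /
down calls per gene and treatment contrast). It implements the inferential
chain that links inhibitor and hormone transcriptome responses:

- **calls** — the call-table data model, TSV IO, and derivation of trinary
  calls from continuous expression changes plus significance flags;
- **contingency** — multi-factor response-mode cross-tabulation (3^k x 3
  cells), independence-expected counts, observed/expected enrichment
  ratios, and a plain chi-squared statistic;
- **clustering** — step-wise rule-based assignment of hormone-responsive
  genes to clusters A/B/C/D (with near-miss variant labels), reconciliation
  of two inhibitor analyses into stringent (intersection) and loose (union)
  clusters, and modifier-contrast over-representation profiles;
- **enrichment** — functional-category frequency enrichment normalized to a
  genome background, with bootstrap mean/SD (gene resampling with
  replacement);
- **motifs** — promoter extraction (up-to-1000 bp upstream windows with
  neighbor truncation) and exhaustive 4–10 bp motif over-representation
  scanning (per-promoter presence, both strands canonicalized, 2x2
  chi-squared, p < 1e-5), plus IUPAC cis-element catalog matching;
- **similarity** — expression signatures (top-n up + top-n down genes) and
  Euclidean-distance similarity ranking of experiment panels, with a
  relative score normalized so 1 marks panel-average similarity;
- **synthetic** — seeded generators for every input format with planted,
  parameterized structure and truth sidecars;
- **pipeline / cli** — a YAML-configured end-to-end runner with a
  reproducibility manifest.

## CLI

All functionality is exposed through the `tricall` command
(exit codes: 0 ok, 1 configuration error, 2 runtime error):

```sh
# generate synthetic inputs with planted structure
tricall simulate calls --n-genes 20000 --seed 1 --out calls.tsv
tricall simulate clusters --sizes A=105,B=39,C=97,D=23 --seed 1 --out planted.tsv
tricall simulate promoters --motif TTGACC --p-fg 0.5 --p-bg 0.01 --seed 1 --out-prefix prom
tricall simulate annotations --seed 1 --out-prefix ann
tricall simulate panel --seed 1 --out-prefix panel

# analyses
tricall crosstab --table planted.tsv --rows EDE,U73 --col SA --out-prefix crosstab
tricall cluster --table planted.tsv --inhibitor EDE --inhibitor U73 --out-prefix clusters
tricall enrich --set-file ann_set.txt --annotations ann_annotations.tsv --seed 1 --out enrich.tsv
tricall scan --fg prom_fg.fasta --bg prom_bg.fasta --out hits.tsv
tricall rank --changes panel_changes.tsv --panel panel_panel.tsv --out rank.tsv

# everything from one YAML config, with a manifest
tricall run-all --config config.yaml
```

A minimal `config.yaml`:

```yaml
seed: 7
outdir: runs/demo
crosstab: {rows: [EDE, U73], col: SA}
cluster: {inhibitors: [EDE, U73]}
enrichment: {simulate: {n_universe: 1000, set_size: 100}, set: simulated, n_boot: 100}
motifs: {simulate: {n_fg: 50, n_bg: 50, length: 300}}
similarity: {simulate: {n_genes: 1000, n_experiments: 8}, n_top: 200}
```

Canonical contrast names: `SA`, `EDE`, `U73`, `W30B`, `W30SA`, `NBUT`,
`NBUTSA`, `R59` (map your own column names via `contrast_map` in the
config).

## Notable conventions

- Level order everywhere is up, nc, down; contingency rows enumerate the
  Cartesian product of levels over the row factors in that order.
- Grand totals are always the sum of observed cells, never a quoted figure.
- Reported ratios are rounded half-up (1 decimal, integer at >= 10) for
  display only; full precision is kept internally.
- The cluster-D rule excludes inhibitor-induced genes by default
  (`--no-d-excludes-inhibitor-up` to disable); cluster C places no
  constraint on the hormone+W30 contrast unless `--c-excludes-w30sa-up`
  is set.
- Motif scanning counts per-promoter presence (not occurrences), merges
  reverse-complement pairs under the lexicographically smaller spelling,
  and applies no multiple-testing correction beyond the fixed threshold.
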