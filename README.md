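# metdep

Explaining cancer cell-line-specific essentiality of **metabolic genes** from
loss-of-function screen data (RNAi/CRISPR dependency scores), by combining:

- **metabolic-network-derived functional relatedness** — neighboring enzymes
  (sharing a non-currency metabolite, capped at 50 per gene and ranked by the
  connecting metabolite's network degree) and isozymes (OR-alternatives in
  gene–reaction rules);
- **culture-media confounder analysis** — per-gene rank-sum tests of dependency
  between media (e.g. DMEM vs RPMI), partial Spearman correlations controlling
  culture type, and robustness checks against cancer-lineage indicators;
- **expression-association analysis** — Spearman correlations of dependency with
  the gene's own / isozyme / neighbor expression, with shuffled-gene-set
  permutation nulls and sign (binomial) tests;
- **permutation-calibrated predictive models** — per-gene bagged regression
  forests (100 trees, min leaf 5) over molecular, media and lineage features,
  scored by out-of-bag Pearson correlation, calibrated against a
  permute-the-dependency-vector null, with OOB permutation feature importance,
  positive-importance refits and top-feature categorization;
- a **synthetic-data generator** producing toy metabolic models and screens with
  plantable ground-truth effects (media shifts, neighbor/isozyme expression
  couplings, mutation-conditional couplings, lineage shifts, and a deliberate
  media×culture-type confounding structure), so every stage is testable without
  external downloads.

## Usage

Metabolic models are read from SBML (Level 2 notes or Level 3 fbc gene
associations) or a two-file tabular dialect; screen inputs are five delimited
text files (dependency / expression / copy-number / mutation matrices,
gene × cell line, plus a cell-line annotation table with medium, culture type
and lineage).

```bash
# generate a synthetic fixture with ground truth
metdep simulate --seed 1 --out fixture/

# run everything (config file documents every knob; flags override)
metdep run --config config.yaml --seed 1 --out results/
metdep summarize --out results/

# individual stages
metdep neighbors --config config.yaml     # relatedness TSV + GMT only
metdep media     --config config.yaml     # media association stage
metdep correlate --config config.yaml --reps 1000
metdep model     --config config.yaml --reps 25000
```

Minimal `config.yaml`:

```yaml
model_reactions: fixture/reactions.tsv
model_gpr: fixture/gpr.tsv
dependency: fixture/dependency.tsv
expression: fixture/expression.tsv
cnv: fixture/cnv.tsv
mutations: fixture/mutations.tsv
annotations: fixture/annotations.tsv
out_dir: results
seed: 1
```

Stage-specific variability thresholds default to 6 SD (media analysis), 4 SD
(pairwise correlations) and 2 SD (modeling); the currency-metabolite fraction
defaults to 0.01 (strict `>`), the neighbor cap to 50, the signaling-gene
exclusion list to `[EGFR, PIK]`, the permutation-null repetitions to 25000 and
the shuffled-related-set control to 100 — all overridable per run. Outputs are
TSV tables plus a JSON manifest (config echo, seed, stage timings); reruns with
the same config and seed are byte-identical at any `--threads` value.

## Layout

- `src/metdep/model_io.py` — SBML/tabular model reading, GPR rule parsing
- `src/metdep/neighbors.py` — currency metabolites, neighbor/isozyme maps
- `src/metdep/screen_data.py` — screen loading, alignment, variability filter
- `src/metdep/association.py` — rank-sum, BH-FDR, (partial) Spearman, nulls
- `src/metdep/models.py` — bagged forests, OOB importance, empirical calibration
- `src/metdep/synthetic.py` — toy model/screen generator with ground truth
- `src/metdep/pipeline.py`, `src/metdep/cli.py` — orchestration, config, CLI
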