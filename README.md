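# coexcons

Cross-species co-expression conservation analysis.

`coexcons` builds vote-counting co-expression maps from per-dataset
expression matrices, extracts per-gene top-percent co-expression lists and
directed percentage-threshold networks, and scores the conservation of
co-expression connectivity between two species:

- **CCG** (commonly co-expressed genes): for each homolog pair, how many
  species-A genes in the pair's top-5% co-expression list have a homolog in
  the species-B top-5% list.
- **DiffK**: a pseudocount-stabilized, folded connectivity ratio between
  the two species' top-1% networks (0 = equal connectivity; the sign marks
  the more-connected species).
- **Gene-set evaluation**: tissue / pathway / disease style GMT collections
  scored with four conservation parameters (CCG conservation, differential
  connectivity, duplication ratio, non-homolog ratio) using Mann-Whitney
  and Fisher exact tests with Benjamini-Hochberg correction.
- **Candidate associations**: genes recurrently present in the CCG
  overlaps of a gene set's homolog pairs, with permutation p-values.
- A **synthetic data generator** that emulates two gene universes linked by
  one2one / one2many / many2many homology, dN/dS rates coupled to a latent
  divergence variable, module-structured expression with tunable
  cross-species preservation, and planted conserved / diverged / null gene
  sets — so the whole pipeline is testable offline.

## CLI

```bash
# generate a synthetic world
coexcons simulate --seed 1 --out world/              # defaults
coexcons simulate --config my_generator.yaml --seed 1 --out world/

# run the full pipeline on it
coexcons run --world world/ --out results/run1 --seed 1

# or stage by stage
coexcons build-maps --world world/ --out maps/
coexcons ccg --map-a maps/map_a.tsv --map-b maps/map_b.tsv \
    --homology world/homology.tsv --out ccg.tsv --overlaps overlaps.tsv
coexcons network --map-a maps/map_a.tsv --map-b maps/map_b.tsv \
    --homology world/homology.tsv --out nets/
coexcons evaluate --ccg ccg.tsv --diffk nets/diffk.tsv \
    --homology world/homology.tsv --sets world/genesets.gmt --out report.tsv
coexcons associate --ccg ccg.tsv --overlaps overlaps.tsv \
    --sets world/genesets.gmt --out assoc.tsv
```

Real-mode inputs use the same plain formats: homology as TSV
(`gene_a  gene_b  dn  ds  [relationship]`), co-expression maps as long-form
TSV (`gene_a  gene_b  score`), expression as gene x condition TSV, gene
sets as GMT.  Exit codes: 0 success, 2 configuration error, 3 data error.

Key thresholds (CLI flags mirror these): top percent for CCG lists (5),
network threshold (1), ranked-extreme export percent (5), minimum gene-set
size (10), FDR alpha (0.05), permutation iterations (10,000 for the
Spearman association, 1,000 for candidate-gene permutation).

## Layout

| module | contents |
| --- | --- |
| `coexcons.homology` | homology table, relationship classification, dN/dS class comparison, quartile binning |
| `coexcons.coexpr` | expression datasets, vote-counting map builder, top-percent lists |
| `coexcons.network` | directed networks, connectivity, DiffK, degree-distribution diagnostics |
| `coexcons.conservation` | CCG counting, permutation Spearman, ranked extremes, distribution diagnostics |
| `coexcons.genesets` | GMT I/O, size filter, four-parameter conservation report |
| `coexcons.associations` | candidate-gene frequencies and permutation significance |
| `coexcons.synthetic_data` | world generator and direct-map shortcuts |
| `coexcons.cli` | `coexcons` command-line entry point |
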