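# gxp

A headless analysis engine + CLI for factor-aware omics quantification
tables (bulk or single-cell expression, metabolite quantifications):

- **tables_io** — reads TSV/CSV quantification tables whose column names
  encode the experimental design (`<group...>.<x-level>.<replicate>`, e.g.
  `S_lycopersicum.ctrl1.1`, separator configurable), typed annotation
  tables (free text / categorical incl. multi-valued cells / numeric),
  entity search, and round-trippable session bundles (zip archives with a
  `GXP_settings.json` marker).
- **profiles** — replicate aggregation into per-condition profiles with
  error bars (sd or sem) and bar / line / stacked-line SVG plots.
- **similarity** — row-wise z-transformation, correlation likeness
  (d = 1 − |c|, so anticorrelation counts as maximal likeness) and
  Euclidean distances, agglomerative hierarchical clustering (single /
  complete / average / ward, deterministic tie-breaking) with heatmap +
  dendrogram SVG and Newick export, and PCA with a variance-explained
  scatter.
- **ora** — overrepresentation analysis: criterion- or id-based entity
  selection, per-term 2×2 contingency tables against the whole annotation
  table as background, one-sided Fisher's exact p-values from a
  from-scratch log-gamma hypergeometric pmf, Bonferroni / Benjamini-
  Hochberg correction.
- **mapman** — pathway-sketch rendering: genes mapped to diagram areas by
  component-wise bin-prefix matching (`1.1.1.1.1` → area `1.1`, but
  `1.10` ↛ `1.1`), colored boxes under divergent (blue-white-red) or
  sequential (white-red, quartile-bounded) scales, legend and five-number
  summary strip. Layouts are a small versioned JSON schema; two built-in
  mini layouts ship with the package.
- **fixtures** — deterministic synthetic-data generator (planted group
  structure, differential expression, term enrichment, searchable
  descriptions) with a machine-readable truth record; everything the test
  suite needs is generated, no downloads.

## CLI

```sh
gxp fixtures --seed 42 --out data/           # synthetic dataset + truth.json
gxp load    --counts data/quantification.tsv --info data/info.tsv
gxp search  "chalcone synthase" --counts ... --info ...
gxp plot    --ids gene0001,gene0002 --mode bars --out plot.svg --counts ...
gxp cluster --metric correlation --linkage average --out heatmap.svg \
            --newick tree.nwk --counts ...
gxp pca     --out pca.svg --counts ...
gxp ora     --select "log2FC_cold>1" --terms-column mapman_bin \
            --method bh --alpha 0.05 --out ora.tsv --counts ... --info ...
gxp mapman  --layout metabolism_overview_mini --value-column log2FC_cold \
            --scale divergent --limit 2 --out mm.svg --counts ... --info ...
gxp export  db.zip --counts ... --info ...
gxp import  db.zip
```

Exit codes: 0 success, 1 runtime error, 2 usage error.

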