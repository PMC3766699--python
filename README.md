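# mircircuitnet

Integrative analysis of matched miRNA and gene expression profiles across
tumor progression — normal mucosa (N), primary tumor (T) and metastasis (M)
— for researchers studying post-transcriptional regulation in cancer
cohorts. The package identifies differentially expressed miRNAs (DEMs) with
a from-scratch Significance Analysis of Microarrays (SAM), finds predicted
miRNA→target relations *supported* by anti-correlated expression, induces
the resulting regulatory networks, enumerates mixed miRNA–transcription-
factor feed-forward circuits, tests gene-set perturbation, and screens
miRNAs against patient survival — all runnable end to end on a synthetic
matched cohort with planted ground truth, so every stage's error control
and power can be verified without any external data.

## The statistics at the core

- **SAM**: per-feature relative difference `d = (x̄_A − x̄_B)/(s + s0)` with
  pooled standard error `s` and fudge factor `s0` (percentile of the `s`
  distribution minimizing the CV of the d spread across s-quantile
  windows); permutation order statistics give expected `d̄`, a delta
  threshold tuned to FDR < 0.01 via `FDR = π0·median(false calls)/calls`,
  and q-values per feature. Unpaired and paired (within-patient sign-flip)
  designs.
- **Target support**: Pearson r between a miRNA and each predicted target
  over matched samples, `t = r√(n−2)/√(1−r²)`, Benjamini–Hochberg q ≤ 0.01
  with r < 0 required.
- **Mixed circuits**: TF-driven (TF→miRNA, TF→gene, miRNA⊣gene) and
  miRNA-driven (miRNA⊣TF, miRNA⊣gene, TF→gene) triangles enumerated
  exhaustively on correlation-scored edge sets; edge p-values combined by
  Fisher's method.
- **Pathways**: set-level z = (mean_S − mean_all)·√|S|/sd_all over per-gene
  t statistics, both one- and two-directional.
- **Survival**: univariate Cox (Breslow ties, Newton from 0, monotone-
  likelihood detection), Bonferroni control over the screened list, and
  median-dichotomized Kaplan–Meier curves.

See `docs/methods.md` for the full model descriptions and design choices.

## Worked example

Run the full pipeline on the default synthetic cohort (78 miRNA-assay and
80 gene-assay samples sharing 77, from 42 patients; 300 miRNAs, 2,000 genes,
100 planted repressions, 5,000 decoy predictions, 6 planted circuits):

```bash
mircircuitnet run --seed 1 --outdir run
# or: python -c "from mircircuitnet.pipeline import run_full; run_full(outdir='run', seed=1)"
```

The run directory contains every intermediate table plus `report.json`.
With seed 1 the funnel reads:

```
mirnas_profiled        300   -> 293 after detection -> 203 over signal floor
genes_profiled        2016   -> 1411 after variability filter
predictions           5103   -> 3453 tested -> 95 supported relations
dems_TvN                20   (of 24 called at FDR<0.01; FC>3 + background rule)
network_components      18
circuits                 6   (all 6 planted circuits recovered, 0 spurious)
```

Reading the numbers: 95 of 5,103 predicted pairs are supported by
significant anti-correlation (weakest supported r = −0.495 at n = 77); the
20 selected DEMs and their supported targets form 18 network components;
circuit enumeration recovers exactly the 6 planted TF/miRNA/gene triangles,
e.g. the top row of `circuits.tsv`:

```
circuit_type  tf     mirna    gene      combined_p
miRNA_driven  TF005  miR-005  GENE0065  2.8e-79
```

The survival screen over 20 DEMs reports its top hazard ratio with the
Bonferroni-adjusted p (at the default cohort size of 46 patients the
planted β = 0.4 effect is not reliably the top hit — small-cohort screens
are noisy by nature, which the recovery metrics in `report.json` make
explicit). Rerunning with the same seed reproduces every output file
byte for byte.

Each stage is also a library function (`sam_de.sam_fdr`,
`target_support.support_targets`, `networks.enumerate_circuits`,
`survival.screen_mirnas`, …) and a CLI subcommand (`simulate`,
`preprocess`, `diffexp`, `support`, `network`, `circuits`, `pathways`,
`survival`, `run`) operating on plain TSV/GMT/GraphML files.

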