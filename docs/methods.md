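# Methods

`mircircuitnet` implements an integrative analysis of matched miRNA and gene
expression profiles across three tissue classes — normal colon mucosa (N),
primary tumor (T) and liver metastasis (M) — aimed at identifying
differentially expressed miRNAs (DEMs), the target genes they plausibly
repress, the regulatory networks and mixed miRNA–transcription-factor
circuits they form, the pathways they perturb, and their association with
patient survival. This note documents the models, the statistical choices
made where the design was genuinely open, and what the synthetic cohorts do
and do not establish about real data.

## Input model and preprocessing

All expression values are log2 intensities on a [0, 15] scale, assumed
normalized upstream (no RMA or quantile normalization is performed here).
Three filters precede any inference:

- **Detection filter (miRNAs).** A miRNA is kept when detected (value above
  a detection floor, default 1.0, or an explicit boolean call matrix) in at
  least `min_detected` samples (default 20). A miRNA failing the count is
  still kept when *all* of its undetected samples fall in a single tissue
  class: class-wide absence is treated as biology (e.g. a liver-specific
  miRNA absent from colon mucosa), not probe failure. The alternative
  reading — counting detection per class — was considered; the class-
  exemption rule was chosen because it is monotone (never removes a miRNA
  the plain count would keep) and easier to audit.
- **Variability filter (genes).** Features are ranked by variance of log2
  values across all samples and the top `floor((1 − f)·n)` kept (default
  f = 0.30). Variance on the log2 scale was chosen over CV or IQR as the
  conventional microarray reading of "expression profile variability"; the
  floor rule makes the retained count exactly reproducible (22,517 genes →
  15,761 at f = 0.30). Ties keep the earlier input row.
- **Mean-signal floor (miRNAs).** Features whose mean log2 signal does not
  exceed 5.0 (strictly) are removed; the floor corresponds to the average
  miRNA expression on this scale. Scope is the mean over all samples by
  default; a per-class variant keeps a feature when any class mean passes.

Descriptive statistics: transition pattern counts classify each feature as
up, down, or unchanged per contrast at |log2FC| > 1 (log2FC = difference of
class means); unsupervised clustering uses 1 − Pearson correlation distance
with average linkage (neither is canonical for this analysis — both are
config-overridable); the per-patient pairing score is the fraction of
patients with both T and M samples whose two samples are mutual nearest
neighbors in cophenetic distance, this package's own operationalization of
"per-patient sample pairing" in a dendrogram. The biogenesis-balance check
pools DEM expression values per class and compares class pairs with Welch
t-tests; profile stability for reference-feature selection is measured as
Shannon entropy over 10 equal-width bins of the profile's range (constant
profile ⇒ 0 bits; maximum log2 10).

## SAM differential expression

The two-class statistic is the relative difference
`d = (x̄_A − x̄_B) / (s + s0)` with `s` the pooled standard error and `s0` a
fudge factor stabilizing low-variance features. `s0` is selected from the
percentiles {0, 5, …, 100} of the per-feature `s` distribution as the value
minimizing the coefficient of variation, across ten s-quantile windows, of
the window-wise median absolute deviation of `d`; ties take the smallest
percentile. Significance is assessed against expected order statistics
`d̄_(i)` averaged over label permutations (all distinct assignments when
fewer than `n_permutations`, otherwise sampled without replacement, seeded).
For a threshold delta, asymmetric cutoffs are the smallest positive sorted
`d` with `d_(i) − d̄_(i) ≥ delta` and the largest negative one with
difference ≤ −delta; the FDR estimate at delta is
`π0 · median permuted call count / observed call count`, with π0 the
fraction of observed `d` inside the central 50% of the permuted
distribution (capped at 1). The reported delta is the smallest on a
100-point grid whose (monotonized) FDR meets the target, default 0.01. Each
feature's q-value is the lowest FDR at which it is called — the FDR at the
tightest delta still calling it; call sets are nested in delta, so called
features always satisfy q ≤ target.

The paired design forms within-patient differences (patients lacking either
tissue are dropped) and runs the one-sample analogue with sign-flip
permutations.

DEM selection applies two composable screens after the q threshold:
|log2FC| > 3 (read on the log2 scale, i.e. 8-fold linear, consistent with
the log2 usage elsewhere; a config switch reads the threshold as a linear
ratio instead) and mean expression above the background value 5 in at least
one contrasted group.

## Expression-supported targets

Predicted miRNA→gene pairs (an external table; scores are carried but not
thresholded on) are tested for expression support: Pearson correlation over
the samples profiled on both assays, two-sided p from
`t = r·√(n−2)/√(1−r²)` on n−2 df, Benjamini–Hochberg correction over all
performed tests (duplicate site-level predictions collapse to one test
first), support requiring q ≤ 0.01 and r < 0. Correlations span all matched
samples regardless of class — the analysis builds one network over N+T+M.
BH is the default because it is deterministic and conservative; a
Storey-style q-value with π0 estimated at λ = 0.5 is available behind a
flag. The realized r cut (the weakest supported anti-correlation) is
reported for transparency but is a consequence of the q threshold, not a
parameter.

The correction spans the tests actually performed (predictions whose miRNA
and gene survive upstream filters), and the count is reported alongside the
results.

## Networks and mixed circuits

The DEM-centered post-transcriptional network takes the selected DEMs plus
their supported targets; gene nodes are flagged when they are themselves
differentially expressed, and components induced by up- versus
down-modulated DEMs are reported separately. The mixed network adds
TF→gene and TF→miRNA candidate edges from validated interaction tables,
scored by Pearson correlation of the two members' profiles over matched
samples: miRNA edges must be negative, TF edges accept either sign
(activation or repression), and each edge class is BH-corrected separately
with edges kept at q ≤ 0.05 and ranked by |r|. "Most differential genes"
enter the mixed network by ranking on the maximum |log2FC| across the
analysis contrasts and keeping the top 75% — one interpretation among
several possible; it is exposed as a parameter. TFs without an expression
profile contribute no edges and are counted in the run report.

Two triangular feed-forward circuit types are enumerated exhaustively:
TF-driven (TF→miRNA, TF→gene, miRNA⊣gene) and miRNA-driven (miRNA⊣TF,
miRNA⊣gene, TF→gene). Each circuit's three edge p-values are combined with
Fisher's method; circuits are deduplicated on (type, TF, miRNA, gene) and
sorted by combined p. No combination rule is canonical for circuit-level
significance, so a per-edge-significance-only reading is available by
ignoring the combined p. Mutual miRNA⊣TF / TF→miRNA pairs (feedback loops)
remain in the network but only the two triangle types are enumerated as
circuits.

## Pathway perturbation

Per-gene contrast statistics are two-sample t values. A gene set S in a
universe of tested genes is scored as
`z = (mean_S − mean_universe)·√|S| / sd_universe` with normal tails for
coordinated up- or down-shifts and a two-sided variant for perturbation in
either direction. This is the parametric core of the two-directional
gene-set approach; the full method's one-on-one sample pairing with
meta-combination is deliberately not reproduced — a sample-label permutation
null is provided instead for small cohorts. Two strategies define the
universe: (A) all supported targets of the selected DEMs; (B) only targets
that are themselves differentially expressed. Sets with fewer than two
members in the universe are flagged untestable; significance defaults to
raw p < 0.05 with an optional BH flag (whether the original threshold was
multiplicity-adjusted is not determinable, so both are offered).

## Survival screening

One univariate Cox proportional-hazards model per miRNA, linear in the
covariate, maximized by Newton iteration from β = 0 on the Breslow partial
likelihood (Efron tie handling behind a flag; Breslow is the simpler
default and the two coincide without ties). Convergence requires the score
to fall below 1e−8 within 50 iterations; steps are clipped at 5 and a
coefficient escaping |β| > 10 marks monotone likelihood (e.g. perfect
separation), returned as an unconverged fit rather than a spurious
estimate. Hazard ratios carry 95% Wald intervals. The family-wise error
across a screened list of m miRNAs is controlled by Bonferroni: per-test
level α/m (0.05/26 ≈ 0.002 for the reference 26-miRNA screen) and adjusted
p = min(1, m·p); both the raw and adjusted values are reported since either
convention may be quoted. Kaplan–Meier curves (lifelines' product-limit
estimator) are drawn after dichotomizing the covariate at its median, ties
assigned to "low"; median survival is the first time S(t) ≤ 0.5 and is
undefined when never reached. Only univariate fits are offered — multi-
covariate models are out of scope at these cohort sizes.

## Synthetic cohorts

The generator emulates the matched-study structure end to end: 78
miRNA-assay samples (23 N / 31 T / 24 M) and 80 gene-assay samples
(23 N / 30 T / 27 M) sharing 77, drawn from 42 patients of whom 8
contribute full N-T-M triplets. A sample value is
`baseline + class effect + patient effect + noise`: baselines are
N(6, 1.5²) on the log2 scale (planted DEMs N(8.5, 0.5²), reflecting that
selected DEMs are well-expressed), within-sample noise is N(0, 1), and a
per-(feature, patient) random effect (sd 0.8) is shared by the T and M
samples of a patient, reproducing per-patient T/M clustering. T-vs-N
effects (default ±3.5 log2 units, 24 features) persist in M — the
generator's encoding of the observation that most expression change happens
at the normal→tumor transition — and a smaller M-vs-T set (6 features,
applied to M only) models the second transition. A planted repression
(m, g, b) sets `g = g0 − b·(m − mean(m)) + η` with b = 1 and
η ~ N(0, 1), so the population anti-correlation is analytically
`−b·sd_m/√(b²·sd_m² + σ²)` (≈ −0.71 for a null-background miRNA); linearity
in log2 space was chosen because the analysis only assumes monotone
anti-correlation and a linear model makes the planted r known in closed
form. Ten percent of miRNAs are near-background rows exercising the
detection filter. Values are clipped to [0, 15] and clip events counted.

Prediction tables carry all planted pairs plus decoys drawn uniformly over
non-interacting pairs; planted pairs get more negative miRSVR-style scores
and an 87% conserved-site fraction versus 25% for decoys — the scores are
deliberately decorative because the pipeline thresholds on correlation
support, not prediction score. TF layers realize each planted circuit by
coupling a TF expression row to the circuit's miRNA (positively for
TF-driven, negatively — i.e. as a repressed target — for miRNA-driven) and
add independent decoy TFs with random edges. Survival records follow an
exponential proportional-hazards model: hazard `λ0·exp(β·x)` with λ0 = 0.05
per month, standard-normal covariates, independent exponential censoring
calibrated to a 30% rate.

What the synthetic cohorts do **not** emulate: probe-level noise, batch
effects, heavy-tailed intensity distributions, correlated gene modules
beyond the planted structure, tissue admixture (e.g. residual liver signal
in metastases), and non-linear or translational-level repression.
Recovery results on these cohorts therefore demonstrate correctness of the
statistical machinery under its own assumptions, not expected performance
on microarray data.

## Problem sizes and numerical choices

Default cohorts use 300 miRNAs and 2,000 genes with 100 planted
repressions and 5,000 decoy predictions; SAM runs use 200 permutations in
the pipeline default and calibration studies (1,000 in the single-contrast
CLI default) with a 100-point delta grid. These sizes keep a full pipeline
run under a minute while leaving every stage's statistics in their
asymptotic regime; all are config knobs. Degenerate inputs are errors, not
silent results: empty classes, constant covariates or correlation vectors,
all-censored survival data, shape-mismatched detection matrices, and
predictions referencing absent features (the last are skipped and counted).
Determinism is end-to-end: every stochastic stage consumes a seed derived
from the single config seed, and a rerun with the same config produces
byte-identical outputs including the run report (which contains no
timestamps for this reason).

## Known limitations

- The SAM q-value definition follows the canonical implementation (lowest
  FDR at which a feature is called); other conventions exist.
- The GAGE-style z test is conservative for sets that are a large fraction
  of the universe (finite-population effect); at the default set/universe
  ratios the effect is negligible.
- The mixed-network edge ranking reports all edges passing the q threshold;
  no attempt is made to pick a "strongest k" cutoff, which would require an
  arbitrary k.
- Cox fits are univariate by design; confounding between correlated miRNA
  covariates is not modeled.
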