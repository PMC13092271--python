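# Methods

scivccc infers treatment-induced cell–cell communication (CCC) channels from
paired pre/post-treatment single-cell RNA-seq. This note describes the
statistical model behind each stage, the tunable parameters and their
defaults, what the synthetic-data generator does and does not emulate, the
numerical conventions, and the design choices made where the design was
genuinely open.

## The inference problem

A perturbation (the motivating case is anti-PD-1 immunotherapy, which binds
PD-1 and therefore acts directly only on *PDCD1*-expressing T cells) is
applied between two biopsies of the same patients. Genes in non-targeted
cell types nevertheless change expression. The question is which of those
changes are *communicated* — sender-cell pathway activation → ligand
secretion → receptor engagement on a receiver cell → downstream module
response — and which merely reflect shared confounding (patient effects,
composition shifts, batch).

Correlation-based CCC tools cannot separate these. scivccc uses two causal
devices:

1. **Treatment as an instrumental variable (IV).** Let Z ∈ {0, 1} be
   pre/post treatment, X a differentially expressed gene (DEG) in the
   targeted sender cell type, Y a DEG in a non-targeted receiver type, all
   measured on per-sample pseudo-bulk. Because the treatment targets only
   the sender type, Z is (a) correlated with X, (b) connected to Y only
   through the sender compartment, (c) independent of patient-level
   confounders U (U is shared by both timepoints of a patient; Z is a
   within-patient contrast). Two-stage least squares (2SLS) then estimates
   the causal effect of X on Y free of confounding by U.

2. **Conditional independence over ligand–receptor (LR) pairs.** For each
   candidate mediating LR pair, the interaction intensity is summarized as
   M = (sender pseudo-bulk ligand level) × (receiver pseudo-bulk receptor
   level), per sample. If the LR pair carries the X→Y signal, then X ⊥ Y | M:
   the Fisher-z conditional independence test (CIT) should *fail to reject*.
   Mediation additionally requires the ligand to be co-expressed with X in
   sender cells and the receptor with Y in receiver cells (single-cell
   Pearson r ≥ 0.3), and the marginal X–Y association to be significant —
   otherwise "independence given M" is vacuous.

DEG pairs passing the IV screen, mediated by a common LR pair, are grouped
into gene expression modules (GEM X in the sender, GEM Y in the receiver);
each (GEM X, LR, GEM Y) group is one channel of the CCC network.

## Stage-by-stage model

### QC and pseudo-bulk

Cells are retained when: detected genes in [`min_genes`, `max_genes`] =
[500, 5000] (inclusive — "fewer than 500" and "more than 5000" are read as
exclusive removals), total UMIs in [400, 25000], and mitochondrial UMI
fraction ≤ 0.20 (removal is strictly greater). Pseudo-bulk sums raw counts
over the cells of each (sample, cell type), scales to counts-per-million,
and applies log2(x + 1). CPM is used in place of length-corrected TPM
because UMI counts carry no gene-length bias; a gene-length file can be
supplied for true TPM if working from full-length protocols. Summing counts
before normalizing (rather than averaging normalized cells) preserves the
count statistics of the aggregate.

### Paired differential expression

Per gene and cell type, a paired t-test on per-patient (post − pre)
pseudo-bulk values; only patients with both timepoints enter. log2
fold-change is the mean paired difference (values are already log2-scale).
A gene is significant when p < `alpha_deg` (0.05) and |log2FC| >
`fc_min` (0.5), on raw p-values; Benjamini–Hochberg is available behind
`bh_correction`. Genes with zero counts in every sample are excluded;
zero-variance nonzero differences are flagged degenerate and assigned the
smallest representable p-value rather than dropped, so noiseless planted
fixtures behave predictably.

### IV screen

For every (significant sender DEG X, significant receiver DEG Y):

- First stage: OLS of X on [1, Z], fitted values X̂ (δ̂ is the first-stage
  slope). A first-stage covariance numerically indistinguishable from zero
  raises a weak-instrument error rather than returning garbage.
- Second stage: OLS of Y on [1, X̂] giving β₀, β₁. Standard errors use the
  2SLS convention — residuals Y − β₀ − β₁·X with the *original* X — and the
  β₁ p-value is two-sided t with n − 2 df. For a single binary instrument
  with intercepts, β₁ equals the Wald estimator
  (ΔȲ between treatment groups) / (ΔX̄ between treatment groups); this
  identity is the oracle the implementation is tested against, and the
  statsmodels IV2SLS implementation serves as an independent cross-check in
  the test suite.
- Exclusion-restriction check: OLS-regress Y on [1, X], correlate the
  residuals with Z (two-sided t, n − 2 df). A *large* p supports the
  exclusion restriction. Pairs are retained when p_β₁ ≤ `alpha_iv` (0.05)
  and p_exclusion > `alpha_excl` (0.05). Zero-variance residuals (perfect
  mediation) give p_exclusion = 1 with a degeneracy flag.

A property of the residual-correlation form of the exclusion check worth
knowing: because Z is itself correlated with X, regressing Y on X partially
removes Z from the residuals, so the check is *conservative* (rejects less
than nominally) when the first stage is strong; at first-stage correlation
≈ 0.45 the null rejection rate is ≈ 0.028 instead of 0.05. The calibration
study in the acceptance suite therefore uses a pure Z→X→Y chain with a
modest first stage (corr(Z, X) ≈ 0.15), where the nominal level is attained.
The conservative direction is the safe one for this pipeline — it retains
genuine mediation chains — while strong direct Z→Y paths are still rejected
with essentially full power at these sample sizes.

Only the sender→receiver direction is fitted; the reverse direction would
violate the instrument's exclusion restriction by construction (the
treatment targets the sender type).

### Fisher-z conditional independence test

For partial correlation r of X and Y given conditioning set S:

    w = ½ ln((1 + r)/(1 − r)),   σ = 1/√(n − |S| − 3),   z = (w − 0)/σ,
    p = 2(1 − Φ(|z|)).

σ uses n − |S| − 3, the standard Fisher-z CIT convention (what the
causal-learn package implements); a `strict_paper_sigma` flag restores the
plain 1/√(n − 3), which differs negligibly at |S| = 1. r is computed as the
Pearson correlation of the residuals of X and Y after OLS on [1, S] — the
test suite verifies this agrees with the recursive partial-correlation
formula to 1e-10 and with an independent implementation (pingouin).
|r| = 1 saturates the transform; the result is flagged and p = 0.

Conditioning variables: M = ligand × receptor pseudo-bulk levels
(elementwise per sample). Multi-subunit receptor complexes score as the
MIN over subunit pseudo-bulk levels (limiting-subunit logic, as in
CellPhoneDB-style scoring), configurable to the geometric mean. A pair
(X, Y) is *mediated* by an LR pair when simultaneously: conditional p >
`alpha_cit` (0.05, strict), marginal X–Y p < `alpha_cit`, and both
single-cell co-expression constraints hold at `rho_min` = 0.3 (per-cell
log2(CPM + 1) over pooled cells of the type; complexes use the per-cell
subunit minimum). The marginal-dependence prerequisite is implied by the
upstream IV filter but enforced explicitly, because an LR pair cannot
meaningfully "explain" an association that is absent.

### GEM filter and network assembly

Mediating triples pass an anti-direct-co-expression filter before grouping.
The published description lists five Pearson comparisons to be held below
0.3 — X–Y, X–ligand, X–M, receptor–Y, M–Y — without stating the level
(raw pseudo-bulk vs post-conditioning residual). The raw reading is
internally impossible in this pipeline:

- Mediation requires the X–Y association to flow through M, i.e.
  r(X,Y) ≈ r(X,M)·r(Y,M). Holding both raw |r(X,M)| and |r(M,Y)| below 0.3
  caps r(X,Y) at ≈ 0.09, below the marginal-significance bound (≈ 0.25 at
  n = 62) that the CIT stage itself requires.
- Raw pseudo-bulk |r(X, ligand)| < 0.3 contradicts the required single-cell
  ligand–X co-expression ≥ 0.3 whenever cross-sample covariation dominates,
  since pooled single-cell correlation is an attenuated version of the
  pseudo-bulk correlation in that regime.

The default mode therefore evaluates all five comparisons on residuals
given M (for X–M and M–Y this is identically zero by OLS orthogonality and
acts as a no-op; the binding checks are residual X–Y — the mediation
completeness — and residual X–ligand / receptor–Y, which catch
self-referential triples such as an "X" that duplicates the ligand: its
residual correlation with the ligand's residual is exactly 1). A
`literal` mode applies the thresholds to raw pseudo-bulk correlations as
printed; under genuine mediation it returns empty results, for the reasons
above, and exists for comparison only.

Surviving triples are partitioned by (sender type, receiver type, LR pair);
X genes form the sender GEM, Y genes the receiver GEM, with deterministic
ids (groups sorted by cell types and LR pair). Channels carry the number of
distinct (X, Y) pairs and the median conditional p-value. Identical inputs
and configuration yield byte-identical output files; the run manifest
records a config hash and per-stage counts, and contains no timestamps.

## The synthetic-data generator

The generator plants the full causal chain at study scale so the pipeline
can be validated against a known ground truth. Defaults mirror the
motivating study design: 31 patients, paired pre/post samples, one
treatment-targeted sender type ("T") and one receiver type ("myeloid"),
200 cells per sample per type, 200 genes, 5 planted channels (3 genes per
GEM), 50 decoy LR pairs, 20 confounded decoy gene pairs, 20 background
genes. A "smoke" preset (8 patients, 50 cells, 1 channel, 40 genes) runs in
well under a second for desk tests.

Latent structure, per patient i and timepoint z (natural-log scale):

- patient confounder u_i ~ N(0, σ_u²), shared by both timepoints and both
  cell types (σ_u = 0.25);
- sender pathway activity per channel: A = a1·z + u_i + ε_A
  (a1 = 1.0, σ_pathway = 0.2);
- ligand latent ℓ = θ_lig·A + ε_lig (θ_lig = 0.8, σ_lig = 0.1); receptor
  activity ρ = ρ0 + ε_R (ρ0 = 1, σ_receptor = 0.015);
- transmitted signal S = ℓ·ρ, using the *population* (sample-level) ligand
  latent — not single-cell pairing — because the inference operates on
  pseudo-bulk;
- receiver pathway B = b1·S + c_u·u_i + ε_B (b1 = 1, c_u = 0.1: a small
  direct confounder path that the LR product cannot explain; kept small
  because any X–Y dependence not carried by M is, correctly, evidence
  against mediation);
- confounded decoy pair (X′, Y′): X′ = 0.7·z + 1.2·u + ε (σ = 0.6, a poor
  proxy of the treatment signal), Y′ = 0.9·z + 1.2·u + ε (σ = 0.15). Both
  are strong DEGs and strongly correlated, but Y′ has a direct treatment
  path not mediated by X′ — exactly the violation the exclusion check
  detects;
- decoy LR pairs: expressed with independent sample-level variation
  (σ_decoy = 0.4), causally inert;
- background genes: i.i.d. per-gene per-sample noise (σ = 0.2).

Expression: gene log-rates are linear in the latent activities; GEM genes
load λ_x = θ_y = 0.8 and carry per-gene per-sample noise σ_gene = 0.2.
Within a sample, every cell adds per-cell pathway noise η_c ~ N(0,
σ_cell² = 0.81) shared by a channel's module genes and its ligand (loading
as the sample loading) and, on the receiver side, by the receptor
(γ_rec_cell = 0.55) and GEM Y genes — this within-sample covariation is
what produces single-cell ligand–module and receptor–module co-expression
while leaving cross-sample correlations controlled. Counts are Poisson with
per-cell log-normal library factors (σ_lib = 0.3); gamma–Poisson
(negative-binomial) overdispersion is available via `nb_dispersion`,
default off. The `expected` debug flag (and `SimConfig.noiseless()`)
returns expected counts with all noise zeroed, in which pseudo-bulk module
levels are exact functions of z and planted X–Y correlations equal 1.

Three regime choices were fixed by a calibration study and matter for
anyone re-tuning:

1. **The LR genes must be well measured.** M is a product of two measured
   pseudo-bulk levels; its measurement noise (dominated by the receptor,
   whose biological sample-level variance is small) directly limits how
   much of the X–Y dependence conditioning can remove, and leaks into every
   residual the GEM filter inspects. Ligand/receptor genes are therefore
   highly expressed (`lr_base_boost` = 2.0 ≈ 18 counts/cell; decoy LR genes
   are boosted identically so expression level cannot reveal decoy status).
2. **CPM denominators must be stable.** With 35 of 200 genes responding to
   treatment, library totals would shift ~20% and every gene would inherit
   a treatment-correlated compositional component. Background genes are
   boosted (`bg_base_boost` = 3.0) to act as the housekeeping mass that
   dominates real libraries.
3. **Per-cell pathway heterogeneity** (σ_cell = 0.9) is the mechanism for
   single-cell co-expression; its pseudo-bulk footprint (the sampling noise
   of a lognormal mean over 200 cells) is the price, which the receptor's
   reduced loading keeps acceptable.

Seeding: one master seed; per-patient generator streams are derived by
fixed offsets, so increasing the patient count extends the cohort without
reshuffling earlier patients. The same seed yields byte-identical datasets.

What the generator does *not* emulate: doublets, ambient RNA, batch
effects, cell-type misannotation, overdispersion (by default), gene–gene
regulatory networks beyond the planted modules, multi-subunit receptor
complexes in the planted channels (complex handling is exercised by unit
fixtures), spatial structure, and dropout beyond Poisson sampling. Passing
tests on this generator show the pipeline recovers its assumed causal
structure under realistic noise — not that real tissues satisfy those
assumptions; in particular the IV premises (the perturbation touches only
the sender type; confounders are patient-level) are modeled as true here
and must be argued biologically for any real dataset.

Because the synthetic transcriptome has ~200 genes and a few hundred UMIs
per cell, end-to-end synthetic runs configure permissive QC bounds; the
defaults above remain the package defaults for real data and are exercised
by dedicated unit fixtures.

## Problem sizes used in validation

The statistical acceptance checks run at: 100 random instances for the
Wald-oracle identity; 1000 replicates (31 paired samples) for
bias-recovery; 2000 replicates at n = 62 for the Fisher-z and exclusion
calibrations (500 for exclusion power); 50 simulated null datasets of 200
genes (50 cells/sample) for DEG calibration and 10 datasets
(100 cells/sample) for module recall; and 20 full-scale simulated studies
(31 patients, 200 cells/sample/type, 200 genes) for planted-channel
recovery. The reduced cell counts in the DEG checks keep the suite quick;
pseudo-bulk statistics at 50 cells/sample are already normal enough for the
paired t-test to hold its level, which is what the check verifies.

## Numerical conventions and degenerate inputs

- Weak-instrument guard: |first-stage covariance| below 1e-8 (scaled by the
  data) raises an error.
- Fisher-z requires n ≥ |S| + 4 and non-degenerate inputs; zero-variance
  vectors are errors at the test level, while zero-variance single-cell
  expression in a co-expression query returns r = 0 (failing the ≥ 0.3
  constraint) with a logged warning.
- Paired t-tests with zero-variance differences: p = 1 when the mean
  difference is 0; the floor p-value with a degeneracy flag otherwise.
- Tables are tab-separated with `%.17g` floats, which round-trip IEEE
  doubles exactly; the network export is sorted-key JSON.
- Gene identity is the case-sensitive symbol string; duplicated symbols are
  suffix-disambiguated with a logged warning; receptor complexes use "_"
  between subunits ("/" is accepted on input and normalized).

## Known limitations

- The exclusion-restriction check's conservativeness under strong first
  stages (above) means its nominal level is an upper bound in exactly the
  regime where the instrument is most informative.
- M is a surrogate for interaction intensity; a linear conditioning on a
  product of measured levels cannot remove dependence carried by unmeasured
  co-factors or by the interaction's curvature, and noisy LR measurement
  biases the CIT toward *retaining* residual dependence (i.e. missing true
  channels, not inventing false ones).
- With one binary instrument, only one endogenous regressor is identified;
  covariates, multiple instruments, and sensitivity analysis for the IV
  assumptions are out of scope.
- Clustering, annotation, and embedding are upstream of this package:
  cell-type labels are trusted inputs.
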