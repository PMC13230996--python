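# Methods

## Scope and data model

`csitme` consumes per-cell-type deconvolved expression matrices (TPM-like
genes × samples; the deconvolution itself, e.g. CODEFACS on CIBERSORTx
fractions, happens upstream), a clinical table keyed by sample id, a
ligand–receptor pair table, a binary nonsynonymous-mutation matrix, and
Visium-like spatial slides (spot coordinates plus spot × gene expression).
All cross-table operations work on the intersection of sample ids. Genes
whose deconvolution confidence is not strictly above 0.95 can be filtered at
load time.

## Latent states (module `states`)

Preprocessing is `log2(x+1)` followed by a per-gene z-score across samples
(sample SD, n−1). Zero-variance genes are removed and logged. The model is
`X = A S` with `A` the genes × k mixing/loading matrix and `S` the
k × samples source matrix (unit-variance rows).

**Algorithm.** FastICA (scikit-learn), symmetric extraction first with a
deflation fallback when the symmetric fixed point does not converge; the
variant used is recorded in the model metadata. The decomposition is
deterministic given the seed. Components are ordered by decreasing
loading-column norm, and each component's sign is flipped so the skewness of
its loading column is negative: ICA's sign is arbitrary, and this convention
makes the heavy loading tail the negative signature, reproducibly. A
consequence worth knowing: the recovered sign of a component need not match
any external notion of "activity", so a genuinely co-High state pair can
surface in the screen as the merged one-Low-one-High class. The three bin
classes jointly cover all such relabelings.

**Rank selection.** The Frobenius reconstruction error for k = 1..k_max is
computed from the singular spectrum: a rank-k ICA reconstruction spans the
top-k principal subspace, so its Frobenius error equals the PCA truncation
error exactly; computing it spectrally is faster and exactly monotone in k.
A two-segment piecewise-linear fit over all candidate breakpoints (least
total squared residual) picks the elbow; a left/right slope ratio below 3
flags a low-confidence (near-linear) curve, as arises on structureless data.
Rank selection recovers a planted rank within ±1 at noise SD 0.2 in the
suite's conditions.

**Signatures.** Per loading column, genes beyond ±2.5 SD of the column mean
(per-column mean and SD; a zero-SD column yields empty sets). Empty
signature sets are legal.

**Projection.** A new cohort is preprocessed with the same recipe (its own
per-gene center/scale), aligned to the model's genes by identifier (≥ 80%
overlap required by default), and scored as `pinv(A) @ X` — the
least-squares source estimate, which reproduces the fitted `S` exactly on
the training data (residuals are orthogonal to the span of `A`). A literal
`Aᵀ X` mode exists for comparison but lacks that self-consistency.

**Single-cell validation.** Module scores use the control-gene-bin scheme
(24 expression bins, 100 controls per signature gene, pooled unique control
set); the clustering test compares intra-group vs inter-group Euclidean
distances in a supplied PC embedding with a one-sided rank-sum test,
declaring a component "clustered" at BH FDR < 0.20 and a mean-distance gap
above 10%.

## The prognostic screen (module `screen`)

Per component, samples are cut into tertiles by stable rank (ties broken by
input sample order; bin sizes differ by at most one). For each unordered
pair of cell types, each component pair, and each joint class —
bin1 = (Low, Low), bin9 = (High, High), bin3or7 = (Low, High) ∪ (High, Low)
— the indicator enters

    hazard ~ IC1 + IC2 + I + age + sex

with the component scores continuous and sex categorical. Samples in a Med
bin keep indicator 0 by default (`exclude_medium=True` drops them instead).
Tests are skipped (and logged) when the cohort has fewer than 10 events or
the indicator marks fewer than 5 samples; rows with missing age/sex are
dropped, not imputed. BH correction is applied across all converged tests as
one family by default (`fdr_family="per_pair"` is available). Candidates at
FDR < 0.20 are refit on 10 bootstrap resamples of the cohort (bins
recomputed per resample); retention requires p < 0.05 with the full-data
coefficient sign in at least ⌈0.7 · 10⌉ = 7 resamples. Negative controls
rebuild the network after permuting whole clinical rows against sample ids,
which preserves every clinical marginal.

The same machinery runs at gene level: tertiles of a gene's deconvolved
expression in its own cell type replace component bins, z-scored log
expression replaces the continuous scores, and for bin 1 a positive
coefficient reads as "simultaneous downregulation associates with worse
survival".

Null calibration of the interaction term sits at the nominal level (Wald
p < 0.05 fraction ≈ 0.05 across fully null cohorts) and BH keeps the
family-level false-discovery proportion controlled in the suite's 20-cohort
check. A known property of the design, inherited from proportional hazards:
when several true interactions share one cohort, each per-pair fit omits the
others, and this unmodeled heterogeneity attenuates coefficients
(non-collapsibility). The power check plants five interactions at
|log-HR| = 0.8 and recovers them conditional on that attenuation.

## Network metrics (module `metrics`)

Activity of an interaction in a cohort is the joint indicator recomputed on
that cohort's own tertiles (cohort-relative, also after projection).
Penetrance is the activity row mean, load the column mean, computed
separately for pro-tumor (β > 0) and anti-tumor subsets where relevant; the
mean over samples of load equals the mean over interactions of penetrance by
construction. Samples are labeled pro-dominant / anti-dominant / unassigned
by comparing the two loads (ties unassigned). Differential activity between
two sample groups uses two-sided Fisher tests with BH across interactions;
group-level penetrance comparisons use rank-sum tests (a paired variant for
patient-matched designs such as primary/recurrent biopsies, since the
stated analysis does not say whether pairing was used — both modes exist).
Kaplan–Meier curves and log-rank tests come from lifelines; the
covariate-adjusted check (e.g., subtype ~ anti-tumor load + age) is an OLS
fit that rejects rank-deficient designs.

## Ligand–receptor support and spatial co-localization (module `crosstalk`)

For two signature gene sets of sizes m and n, the observed count c of
database pairs with the ligand in one set and the receptor in the other is
normalized by the expectation under the database's global density
F = P/(L·R): `O/E = c/(m·n·F)`. With the full ligand and receptor universes
and c = P the ratio is exactly 1. Interaction-level mapping enumerates all
four signature-side combinations, counts unique database pairs once, and
assigns each pair an activation state: a positive-side gene is "up" when its
component is High, a negative-side gene when Low; the pair is activated iff
both partners are up in the bin's active configuration (for bin 3/7, either
symmetric configuration). Cell-type-level concordance correlates the
network degree of each cell-type pair with its mean O/E across component
pairs and side combinations (Spearman; per-side aggregates also reported).

Slides are hexagonal lattices; each spot links to up to six nearest
neighbors within 1.3× the lattice pitch, symmetrized, so interior spots have
exactly six and boundary spots fewer. Spot activity thresholds at the 90th
percentile of pooled reference-state scores (states expected absent from the
tissue), per slide. The co-localization statistic is

    O(X, Y) = |∪ nbhds where X and Y are both active| /
              |∪ nbhds where X or Y is active|

where a neighborhood (a spot plus its neighbors) counts as state-active if
its center spot is active (a member-based rule is available). Significance
comes from shuffling each state's spot scores independently 100 times,
fitting a normal to the null overlaps, and taking the upper-tail one-sided
p; BH runs within a slide across state pairs. The statistic's power depends
on the background activity rate: with ~10% scattered false-positive spots
the shuffle null is broad, while sparse backgrounds give sharp detection of
planted patches; null p-values are uniform in both regimes. Enrichment of
ligand-receptor-supported interactions among spatially proximal pairs uses
one-sided Fisher tests per slide combined across slides by Fisher's method.

## Mutations (module `genetics`)

Recurrently mutated genes are those mutated in strictly more than 1% of
samples. Gene-component associations model quantile-binned activity (0/1/2)
as successes out of two trials in a binomial GLM on mutation status — the
reading that yields a single coefficient per pair — with a
proportional-odds alternative behind `method="ordinal"`. Gene-interaction
associations are Fisher tests of activity × mutation 2×2 tables (infinite
odds ratios capped, exact p kept). Grade-stratified analysis counts
interaction-active samples in the four (early/late) × (mutant/wild-type)
cells, early being WHO grade II, and reports (c1/c2)/(c3/c4); the
alternative formulation regresses late grade on the mutation–interaction
co-occurrence indicator MIC = m ∧ i controlling for m and i in a logistic
model, rejecting separated or collinear fits.

## Marker annotation (module `markers`)

One-sided Fisher overlap of signature sides against published marker sets
within an explicit gene universe (default: the genes of the relevant
deconvolved matrix, the space in which signatures are defined); marker sets
are intersected with the universe before testing; BH per batch.

## Synthetic data (module `synthdata`)

The cohort generator draws, per cell type, k unit-variance Laplace source
rows (heavy tails make the ICA identifiable; a Gaussian mode exists as a
negative control for exactly that reason), mixes them through sparse
standard-normal loadings (20% density) onto a log₂ scale with per-gene
baselines Uniform(1, 8) and Gaussian noise (SD 0.2), and exponentiates to
TPM-like values. Survival is exponential with hazard
`1e-3 · exp(Σ βI + 0.01·(age−mean) + 0.1·[male])` per day and independent
exponential censoring targeting a 30% censoring fraction; age and sex
effects are deliberately non-zero so the covariate adjustment is exercised.
Planted interactions couple their two source rows through a Gaussian copula
whose correlation is chosen analytically so the planted joint-tertile class
holds ~25% of samples (|ρ| = 0.84 for bin1/bin9; 0.104 for the merged and
already-likelier bin3or7 class); planting fails loudly if the class holds
fewer than 5 samples. Slides are hex lattices with unit pitch, iid Gaussian
background expression, and circular patches of elevated signature genes;
mutation matrices are Bernoulli per gene at Uniform(0.02, 0.1) base
frequencies with logit-linear modulation by a chosen component level or
interaction activity. Every generator is a pure function of (config, seed).

What the generator does **not** emulate: deconvolution error and its
confidence structure, count noise and library-size variation, correlated
gene modules beyond the planted low-rank structure, spatial autocorrelation
of background expression, co-mutation structure, or informative censoring.
Passing tests therefore demonstrate correctness and calibration of the
statistical machinery under the stated generative assumptions, not
robustness to the failure modes of real deconvolved data.

## Numerical choices and problem sizes

Tie-breaks in tertiles use stable sample order; all seeds are explicit and
all CLI outputs are byte-identical under rerun. The test suite and the
acceptance script run at desk scale — e.g., 1000 × 300 matrices for
recovery, 20 null cohorts of n = 400 for calibration, one n = 500 cohort
with five planted interactions for power, 30 × 30 slides with 100 shuffles
for spatial checks — sizes chosen to make the statistical properties
measurable while keeping a full run in minutes on one CPU.

## Known limitations

- The bin 3/7 class merges two configurations; combined with ICA sign
  indeterminacy, a planted directional interaction may be detected in a
  different (but logically consistent) bin class than planted, with some
  dilution of the effect.
- Hazard-ratio non-collapsibility attenuates per-pair estimates when
  multiple true interactions coexist; the screen detects, it does not
  unbiasedly estimate, in that regime.
- The spatial permutation null ignores spatial autocorrelation of the
  background; on real slides with smooth score fields the null is
  anti-conservative, which is why the slide-level BH and the
  reference-state thresholding matter.
- The rank-selection elbow is a heuristic; stability-based criteria can
  disagree with it, and the component count is exposed as a parameter
  (default 10) rather than auto-selected.
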