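# Methods

`pufgba` implements a guilt-by-association (GBA) workflow for proposing
putative functions for bacterial proteins of unknown function (PUFs)
from label-free proteomics and comparative genomics, together with a
synthetic-data generator that plants known structure so every stage can
be validated without raw mass spectrometry data.  This note records the
models, the tunable parameters, the numerical choices, and what the
synthetic data do and do not establish.

## Quantification (`proteoquant`)

Peptide MS1 intensities are summed to proteins per sample.  A
protein/sample cell is *valid* only with at least `min_peptides = 2`
distinct peptides and `min_psms = 2` peptide-spectrum matches in that
sample, and a protein must be valid in at least `min_replicates = 2` of
the 4 replicates of a (strain, timepoint) group or the whole group is
treated as missing.  The two rules are applied per sample and per
group, respectively — the stricter of the plausible readings, and the
one that makes planted violations exactly recoverable.

Valid intensities are divided by protein length (per-residue
abundance), each MS run is rescaled so its total matches the grand mean
of run totals (totals rather than medians; configurable), values are
log2 transformed, and samples are quantile normalized over their
present values: the reference quantile function is the average of the
per-sample empirical quantile functions on mid-rank fractions, so
samples with equal numbers of present values map exactly onto the
rank-wise mean of sorted values.  Median-centering is available as an
alternative but changes the absolute scale on which the downstream
low-abundance cutoff (23, see below) is defined.

Remaining missing values are assumed left-censored at the detection
limit and imputed from a down-shifted, narrowed Gaussian per sample:
`Normal(mu_s − 1.8·sd_s, (0.3·sd_s)²)` with `mu_s`, `sd_s` the sample's
observed mean and SD.  The 1.8/0.3 constants are the conventional
defaults for left-censored proteomics imputation and are exposed in
`QuantConfig`.  The pre-imputation missingness mask is retained because
the co-expression stage filters on it.

## Differential expression (`diffexpr`)

Proteins with grand-mean normalized abundance below 23 (closed boundary:
23.0 is kept) are removed; the constant is interpreted on the final
log2-quantile-normalized scale and is configurable.  A group-means
linear model over (strain, timepoint) groups yields per-protein group
means and a pooled residual variance `s_g²` on `d_g = N − G` degrees of
freedom.  Contrasts compare strains at matched growth phases — early,
mid and late log — with the slower strain's *second* of four timepoints
taken as mid-log and its fourth as late-log (the phase assignment the
sample PCA supports).  One joint fit with per-phase contrasts is used
rather than separate per-phase fits; the two differ only in variance
pooling.

Moderation follows the standard empirical-Bayes variance model with an
abundance trend: `log s_g²` is lowess-smoothed against average
abundance (span 0.3); under the model the de-trended `log s_g²` is a
scaled log-F whose spread in excess of `trigamma(d_g/2)` identifies the
prior degrees of freedom via `trigamma(d_0/2) = var(z − trend) −
trigamma(d_g/2)` (non-positive excess ⇒ `d_0 = ∞`), and digamma
identities bias-correct the trend to the prior-variance scale.  Robust
mode winsorizes the de-trended residuals at the 5%/95% quantiles before
the moment equations, which bounds the influence of variance outliers.
The moderated statistic uses `s_post² = (d_0 s_0² + d_g s_g²)/(d_0 +
d_g)` with a t reference on `d_0 + d_g` df (normal when `d_0 = ∞`);
`d_0 = 0` reduces exactly to the ordinary pooled-variance t.  Two-sided
p-values are BH-adjusted within contrast at α = 0.05.

## Co-expression and differential co-expression (`coexpression`)

Per strain, proteins missing (pre-imputation) in more than 50% of that
strain's measurements are dropped; replicate means per timepoint are
formed; profiles spanning less than `variation_min = 0.5` log2 units
are dropped as flat; survivors are z-scored.  Clustering is a
tight-clustering stand-in with the defining contract of the original
tool (tight clusters, genes may stay unassigned): k-means with 20
seeded restarts over `k ∈ [2, 8]`, k chosen by maximum mean silhouette,
members with Pearson r to their centroid below τ = 0.7 moved to the
unassigned pool, clusters below 5 members dissolved.  Profiles are
sorted by protein id before clustering so membership is invariant to
input row order.

Differential co-expression uses the dCp statistic: with link sets `L_i
= {j : |r_A(i,j)| ≥ 0.8 or |r_B(i,j)| ≥ 0.8}` (proteins with fewer than
5 links are not tested), `dCp_i = sqrt(Σ_{j∈L_i}(r_A(i,j) −
r_B(i,j))²/|L_i|)`.  The null permutes the condition labels of samples
(1000 permutations) with link sets held fixed, `p = (1 + #{perm ≥
obs})/(n_perm + 1)` (never exactly zero), BH across tested proteins.
The link threshold and permutation count are package defaults, exposed
in `DcpConfig`.

A caveat established during validation: with only ~12 samples per
condition, sample correlations have SD ≈ 0.3, so thresholded links are
selected extremes and the observed dCp is not exchangeable with its
permutation null (p-values deviate from uniform even under a shared
correlation structure).  The null-calibration check therefore uses 20
samples per condition, where selection effects are negligible; at
study-like sample counts the test is conservative/distorted in the
tails and its q-values should be read as rankings more than
frequencies.

## Coevolution screen (`coevolution`)

Orthogroups are binary species traits (1 = at least one member gene in
the species).  On the rooted species tree, each (PUF orthogroup, other
orthogroup) pair is fit under two continuous-time Markov chains: an
independent model (two 2-state chains; 4 free rates; its pair
likelihood factorizes and the two prunings' log-likelihoods add) and a
dependent model over {00, 01, 10, 11} in which each trait's gain/loss
rates depend on the partner's state (8 free rates; simultaneous dual
changes have rate 0).  Likelihoods use Felsenstein pruning with
per-branch `exp(Qt)`; the 2-state exponential is closed-form, the
4-state one uses an eigendecomposition of Q validated by row-sum and
imaginary-part checks with a `scipy.linalg.expm` fallback.  The root
state prior is flat by default (this keeps the all-patterns likelihood
sum exactly 1), with the stationary distribution available.

Rates are maximized on the log scale with L-BFGS-B in bounds
[1e-8, 1e3], 5 seeded random restarts, tolerance 1e-8; the dependent
fit adds one start at the independent solution embedded in the 8-rate
space, which guarantees the nested-model inequality `logL_dep ≥
logL_indep` up to optimizer tolerance.  Gradients are central finite
differences evaluated as one batched pruning pass over the stencil.
Models are compared by AICc with n = number of species (one trait
observation per species) and k = 4 vs 8; a pair is *coevolving* when
`AICc_indep − AICc_dep ≥ 2`.  Invariant trait columns are
non-identifiable and reported as skipped; unconverged fits are reported,
never silently dropped.

Operating characteristics measured under the synthetic trait model
(27-tip Yule tree of height 1, base rates uniform on (0.5, 3), tenfold
dependence multiplier): independent pairs are flagged in ≈0–2% of
cases; strongly dependent pairs in ≈45–50%.  The decision rule is
conservative by construction — with n = 27 and k = 8 vs 4, the AICc
penalty difference is 14.2, so the dependent model must improve the
log-likelihood by ≥ 7.1 units to be flagged.

## Enrichment (`enrichment`)

Annotations are propagated up `is_a`/`part_of` edges before testing.
Classic enrichment is the one-sided hypergeometric tail against the
detected-protein background; the DAG-decorrelating algorithm is *elim*:
terms are processed deepest-first and when a term's p falls below
`elim_cutoff = 0.01` its annotated study genes are removed from all
ancestors before those are tested.  elim is fully specified in the
literature, which is why it (rather than an undocumented hybrid
weighting scheme) is the decorrelation method here; the algorithm tag is
carried in every result row.  GO p-values are reported uncorrected —
the DAG-aware tests violate the independence assumptions of FDR
procedures — while flat KEGG-style pathway over-representation carries
BH q-values.  A score-based one-sided two-sample KS variant (lower
score = more significant) covers DE- and dCp-driven enrichment.  Terms
with fewer than 3 annotated background genes are skipped.

## Synthetic data (`simulate`)

Trees are Yule (pure birth), with tip branches extended by the waiting
time to the next birth (the simulator otherwise returns the newest two
tips with zero-length branches) and height scaled to 1.  Traits evolve
by exponential waiting times along branches; dependent pairs multiply a
trait's gain rate by `dependence_strength` when the partner is present
and its loss rate when the partner is absent, so strength 1 is exactly
the independent product chain.

The study generator emulates the two-strain design: 3 and 4 timepoints,
4 replicates, ~400 proteins by default with 10% planted DE of ±2 log2
units in the second strain.  Protein log2 abundance is Normal(25, 2.5);
cluster temporal shapes are evaluated on a phase-anchored pseudotime
(early = 0, mid = 0.5, extra point 0.75, late = 1) so matched phases
agree across strains and the only strain differences are the planted
effects.  Replicate noise is Gaussian with a mean-variance trend
(`log σ² = 1.92 − 0.15·abundance`, i.e. SD ≈ 0.4 at abundance 25,
rising at low abundance) plus protein-specific log-variance scatter of
SD 0.4 — without that scatter the empirical-Bayes problem degenerates
to `d_0 = ∞`.  Peptide counts are uniform on [2, 8] with Dirichlet
intensity splits; designated "invalid" proteins get a single peptide
with a single PSM.  Censoring replaces each sample's lowest
`lod_quantile` (default 5%) of peptide intensities with missing values,
reproducing left-censored missingness.

What the generator does *not* emulate: peptide-level interference and
shared peptides, retention-time effects, batch structure, non-Gaussian
heavy tails, correlated noise between proteins outside the planted
clusters, and annotation noise.  Passing tests therefore establish
internal correctness and calibration under a clean generative model,
not performance on real spectra.

## Problem sizes used in validation

The acceptance checks run at sizes chosen to finish in minutes on one
CPU while keeping estimates stable: 50 trees of ≤ 6 tips for the
pruning oracle, 100 pairs for the nesting inequality, 200 + 200 pairs
for screen operating characteristics, 40 replicates each at 32 and 256
tips for rate-recovery scaling, 2000 proteins for null calibration, 400
proteins for the planted-study recovery, 500 proteins / 1000
permutations for the dCp null, and the default 400-protein pipeline run
twice for byte-level reproducibility.

## Known limitations

- The 4-state eigendecomposition falls back to `expm` on defective rate
  matrices; both paths are exercised by the oracle tests.
- AICc with n = 27 species treats species as independent observations;
  the tree corrects for shared ancestry in the likelihood, not in the
  effective sample size.
- The tight-clustering stand-in reproduces the behavioural contract of
  consensus tight clustering (unassigned genes, tight clusters), not
  its exact membership.
- Quantile normalization under strong asymmetric differential
  expression slightly distorts null proteins; empirical FDR in planted
  studies runs up to ~0.11 at q < 0.05 rather than the nominal 0.05.
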