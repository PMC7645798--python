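# Methods

`mechstrat` implements a mechanism-level genetic stratification of AD and PD
patients: instead of clustering raw SNP profiles (which are sparse and nearly
equidistant under 0/1/2 coding), each patient is summarized by a short vector
of *mechanism burden scores* — one per literature-derived molecular mechanism
shared between the two diseases — and patients are clustered in that space.
This note records the models, the defaults and why, what the synthetic data
do and do not emulate, and the numerical choices.

## Mechanism catalogue and SNP grouping

A mechanism is a named gene set (15 sets over 27 distinct genes in the
packaged default). SNPs attach to genes by proximity — a gene's closed
interval extended by a symmetric 10 kb window on 1-based coordinates — and
optionally by precomputed eQTL pairs, which are unioned in with a source tag.
A SNP whose genes sit in several mechanisms appears in every one of their
groups: burden scores are per-mechanism aggregates, so sharing is the
semantically correct treatment. Mechanisms with no mapped SNPs are dropped
with a warning.

The packaged catalogue carries 16 real AD/PD gene symbols (APOE, MAPT, SNCA,
TOMM40, CDK5, GSK3B, PICALM, CD33, NLRP3, IL1B, IL6, TP53, CYCS, AKT1,
MAPK9, MTHFR) padded with clearly labelled placeholder genes to 27, and 148
synthetic SNP ids. Coordinates are synthetic but internally consistent: the
proximity mapper applied to the shipped positions reproduces the shipped
SNP→gene map exactly, which is tested.

## Burden scores: sparse autoencoders

One tiny autoencoder per mechanism: inputs are the mechanism's SNP dosages,
standardized per SNP (constant SNPs become zeros; missing dosages are
imputed by the per-SNP mode), encoded through a sigmoid bottleneck (default
width 1) and decoded linearly. The bottleneck activation is the burden
score. The sigmoid bounds scores in [0, 1], which simultaneously guarantees
the non-negativity the downstream factorization requires.

The training objective is mean squared reconstruction error plus an L1
penalty on encoder weights (`sparsity_weight`, default 1e-3) plus a small L2
ridge on all weights (default 1e-3). The ridge is there for identifiability:
with duplicated or perfectly collinear SNP columns only the *sum* of their
encoder weights is determined by MSE+L1, and the ridge makes the symmetric
split the unique optimum, so interchangeable SNPs receive equal contribution
weights. Training is full-batch Adam (step 0.05), epoch cap 800, relative
loss tolerance 1e-6, with one fresh-seed retry if the fit fails to beat the
all-mean reconstruction. SNP columns are sorted lexicographically inside
each group before training, making scores invariant to genotype column
order.

Two post-fit conventions matter downstream:

* **Orientation.** A sigmoid unit can be flipped (z → 1 − z) without
  changing the reconstruction loss, so the score's direction is otherwise
  arbitrary. Each unit is oriented to correlate positively with the mean
  imputed dosage of its mechanism's SNPs — a burden score increases with
  risk-allele load. Besides interpretability this matters for the
  factorization: consistently oriented scores present cluster structure as
  additive high-burden blocks, which a non-negative factorization can
  represent; mixed orientations destabilize it.
* **Contributions.** The relative contribution of SNP i is
  |w_i| / Σ_j |w_j| over first-layer encoder weights — non-negative and
  summing to 1 per mechanism. Degenerate mechanisms (all-constant input)
  score 0.5 for everyone and report uniform contributions with a warning.

Validation cohorts are scored with the discovery-trained encoders (the
scaler and imputation modes travel with the weights), never refit — except
inside cross-validation, where encoders are refit per training fold to keep
held-out patients out of encoder training.

## Consensus sparse NMF and cluster-number selection

The patients × mechanisms burden matrix X is factorized as X ≈ A·S with
A ≥ 0 (patients × k, soft cluster assignment) and S ≥ 0 (k × mechanisms,
sparse mechanism loading), minimizing ‖X − A·S‖² + λ·Σ|S|. The L1 penalty
acts on S only — sparsity is wanted in the mechanism-to-cluster mapping, not
in patient assignments. Updates are multiplicative (Lee–Seung form, with λ
in the S-update denominator), which keeps the objective monotonically
non-increasing; λ defaults to 0.01, small relative to the squared-error term
at these matrix sizes. Convergence: relative objective change below 1e-6 or
500 iterations. Hard per-run labels are the row-wise argmax of A, ties to
the lowest cluster index.

Because the factorization depends on initialization, it is repeated 50 times
(seeds `seed + run`), and the runs are summarized by the consensus matrix
C (co-clustering frequency; symmetric, unit diagonal). Final labels cut the
average-linkage dendrogram of 1 − C at k groups — labels come from the
consensus, never from a single run. Three stability criteria are computed:

* PAC: fraction of off-diagonal consensus entries strictly inside
  (0.1, 0.9) — the conventional ambiguity band;
* silhouette index on the distance 1 − C with the final labels;
* cophenetic correlation between 1 − C and the dendrogram's cophenetic
  distances.

The null model shuffles every column of X independently (patient structure
destroyed, per-mechanism marginals preserved; default 20 permutations) and
repeats the whole consensus procedure. A candidate k is *significant* when
its silhouette and cophenetic correlation both exceed the 95th percentile of
their nulls; among significant candidates the minimum PAC wins, PAC ties
going to the smallest k; if nothing is significant, no clustering is
declared. Only initialization is perturbed across restarts, not the patient
rows: the instability being averaged over is the algorithm's dependence on
its random starting factors.

## Transfer and In-Group Proportion

Cluster transfer uses L1-penalized multinomial logistic regression on the
burden features by default (a raw-SNP mode is available — the nearest
defensible alternatives differ on whether the classifier should see encoded
or raw features, so both are exposed). The penalty grid is 30 log-spaced
values spanning [1e-4, 1e2] of the max-gradient scale of the standardized
data, chosen by 5-fold cross-validated deviance, warm-starting along the
path. A fully shrunk model falls back to the analytic intercept-only
optimum, i.e. class priors. Out-of-sample discriminability is the Hand–Till
multi-class AUC (average of all pairwise one-vs-one AUCs; the ordinary AUC
when k = 2) over 10×10 repeated stratified cross-validation, pooled per
repeat and averaged.

The In-Group Proportion of a transferred clustering is the fraction of
validation patients whose Euclidean nearest neighbour in the discovery
cohort (burden space; ties to the lowest patient index) carries the same
label, reported per cluster and pooled. Significance comes from uniformly
permuting the discovery labels 1000 times and recomputing; the add-one
estimator p = (1 + #{perm ≥ obs}) / (n_perm + 1) avoids p = 0.

## Association statistics

Baseline: multinomial logistic regression with the cluster indicator as
response (robust to skewed outcome distributions). Confounders are chosen
once per study by bidirectional stepwise search under AIC starting from the
null model (the search direction is a declared default; quasi-separated
candidates are skipped with a warning, detected by a coefficient-magnitude
guard at |β| > 25). Each outcome is then tested by a likelihood-ratio test
of confounders + outcome against confounders alone (k − 1 df); on nominal
significance, Wald tests compare the outcome coefficient between every
cluster pair. All LRT and Wald p-values of one study battery are jointly
Benjamini–Hochberg adjusted. Imaging-type outcomes reuse the same engine
with the confounder set fixed to {age, sex}; volume normalization by
intracranial volume is expected upstream.

Longitudinal: outcomes become progression scores, (value − the patient's
baseline value) / SD of baseline values across patients. For each cluster
pair a linear mixed model with fixed cluster, time and cluster × time
effects and a per-patient random intercept is fit by maximum likelihood
(REML is unnecessary at these sample sizes), with time coded numerically or
categorically, whichever has the lower AIC. The cluster effect (main +
interaction jointly) is tested by LRT. Baseline rows are identically zero
by construction and are excluded from the fit — keeping them pushes the
random-intercept variance onto the boundary. If every optimizer fails, the
model falls back to fixed-effects OLS with a warning.

## Synthetic study design

The generator emulates the statistical shape of the emulated cohorts: 486 +
358 discovery patients (two study labels), 561 validation patients drawn
from the identical generative law on an independent random stream, 148 SNPs
in 15 mechanism groups of uneven width (4–20 SNPs; the exact split
(20, 4, 14, 6, 12, 8, 10, 10, 8, 12, 6, 14, 4, 10, 10) is a documented
constant). Four planted clusters with uniform proportions follow a cyclic
signature — cluster c burdens mechanisms c, c+4, c+8, … — so every cluster
is a mixture of mechanisms and every mechanism is burdened by exactly one
cluster. Baseline minor-allele frequencies are uniform on (0.05, 0.35);
SNPs in a burdened mechanism have their frequency shifted up by
`effect_delta` (default 0.2, kept as the reference effect size throughout
the examples) for patients of that cluster. Dosages are Hardy–Weinberg
binomial draws: no LD, no population stratification, no imputation error.
Age, sex and study are drawn independently of cluster — confounders are
non-informative by default. Outcomes are linear in cluster means,
standardized confounders and noise; longitudinal outcomes add a
cluster-specific slope per visit, a per-patient normal random intercept and
fresh visit noise.

What passing tests therefore show: the pipeline recovers cluster structure
of this planted, LD-free, mechanism-aligned form at realistic effect sizes,
selects the right cluster number against a marginal-preserving null, and
its statistics are calibrated. What they do not show: performance under LD
between SNPs, ancestry structure, mechanism misspecification (SNPs assigned
to the wrong gene set), or batch effects between genotyping platforms —
none of which the generator emulates.

## Problem sizes used in checks

The cluster-number recovery check runs the full default design (844 × 148,
k ∈ 2..7, 50 restarts, 20 permutations). Recovery-vs-effect-size uses 10
generator seeds per effect size at full cohort size. Calibration checks use
1000 simulated null batteries for the LRT, 50 seeds for IGP null coverage
and mixed-model power, and scaled cohorts (a few hundred patients) where a
property is size-independent. These sizes are the package's own choice of
desk-scale defaults; all are reproducible from fixed seeds.

## Known limitations

* The autoencoder is a single bounded unit per mechanism by default; wider
  bottlenecks are supported but the burden score then averages the units,
  which blurs interpretation of per-SNP contributions.
* Multiplicative NMF updates stall on exact zeros; the epsilon guard
  (1e-12) keeps iterates positive but very sparse solutions are approached,
  not hit exactly.
* The permutation null for cluster-number selection shares one null per k
  across metrics; silhouette and cophenetic correlation are correlated, so
  the joint 95th-percentile gate is conservative rather than exact.
* MNLogit-based stepwise selection refits from scratch at every step;
  with many candidate confounders (≫ 10) this is slow, though exact.
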