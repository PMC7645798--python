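# mechstrat

Mechanism-level genetic stratification of Alzheimer's (AD) and Parkinson's
(PD) patients: instead of clustering raw SNP profiles — which are sparse and
nearly equidistant under additive 0/1/2 coding — each patient is summarized
by a short vector of **mechanism burden scores**, one per molecular
mechanism shared between the two diseases, and patients are clustered
jointly in that space. The package is aimed at researchers stratifying
genotyped neurodegeneration cohorts and at anyone who wants a tested,
reusable implementation of this class of pipeline.

The pipeline has four stages, each usable on its own:

1. **Burden encoding.** For each mechanism *m* (a gene set; SNPs attach to
   genes by a 10 kb proximity window and optional eQTL pairs), a sparse
   autoencoder maps the mechanism's SNP dosages to a score
   *b<sub>m</sub>(x) = σ(wᵀx̃ + c) ∈ [0, 1]*, trained to minimize
   ‖x̃ − x̂‖² + λ₁‖w‖₁ (+ a small ridge). Per-SNP contributions are
   |wᵢ| / Σⱼ|wⱼ|.
2. **Consensus sparse NMF.** The patients × mechanisms matrix X is
   factorized X ≈ A·S (A, S ≥ 0, L1 penalty on the mechanism loadings S),
   repeated over 50 random restarts into a consensus matrix C; final labels
   cut the average-linkage tree of 1 − C. The cluster number k is the
   smallest k with minimal PAC (proportion of ambiguously clustered pairs)
   among candidates whose silhouette and cophenetic correlation beat the
   95th percentile of a column-permutation null.
3. **Transfer + IGP.** An L1-penalized (LASSO) multinomial classifier
   assigns validation patients to discovery clusters (Hand–Till multi-class
   AUC via repeated stratified CV, encoders refit inside folds); coherence
   is the In-Group Proportion — the fraction of validation patients whose
   nearest discovery neighbour shares their label — with a 1000-fold
   label-permutation test.
4. **Association statistics.** Cluster–outcome tests by multinomial
   logistic LRT with AIC-stepwise confounder selection and pairwise Wald
   post-hocs, joint Benjamini–Hochberg correction, and random-intercept
   mixed models on baseline-normalized progression scores for longitudinal
   outcomes.

A synthetic cohort generator with planted mechanism-structured clusters
(148 SNPs, 15 mechanisms, 486 + 358 discovery and 561 validation patients
by default) makes the whole pipeline runnable and testable without access
to any controlled cohort data. See `docs/methods.md` for models, defaults
and limitations.

## Worked example

```python
import mechstrat as ms

cfg  = ms.SyntheticConfig(seed=1)              # default study design
coh  = ms.generate_cohort(cfg)                 # 844 patients x 148 SNPs
cat  = ms.default_catalog()                    # 15 mechanisms, 27 genes
grp  = ms.group_snps_by_mechanism(cat, coh.genotypes.snp_ids)
prof = ms.compute_burden_scores(coh.genotypes, grp, ms.EncoderSpec(seed=1))
print(prof.scores.shape)                       # (844, 15)

res = ms.consensus_cluster(prof.values(), k=4, n_runs=50, seed=1)
print(res.metrics)
tops = ms.top_mechanisms(res.best_run.S, mechanism_names=prof.mechanism_names)
```

Output (seed 1):

```
PAC=0.014 silhouette=0.986 cophenetic=0.998
cluster sizes: {1: 188, 2: 207, 3: 224, 4: 225}
cluster 1: ['synuclein_aggregation', 'kinase_cascade', 'proteostasis', ...]
cluster 2: ['mitochondrial_stress', 'gsk3_signaling', 'inflammasome_activation']
cluster 3: ['apoe_lipid_clearance', 'cytokine_signaling', 'endocytic_trafficking', ...]
cluster 4: ['microglial_activation', 'oxidative_stress', 'apoptosis_signaling', ...]
ARI vs planted clusters: 0.977
```

PAC near 0 with silhouette and cophenetic correlation near 1 means the 50
restarts almost always co-cluster the same patients — a stable 4-cluster
solution — and each cluster's top-loading mechanisms recover one planted
mechanism signature.

The same flow is available from the shell:

```bash
mechstrat all --seed 1 --out runs/demo          # simulate -> cluster -> validate
mechstrat cluster --genotypes geno.tsv --out runs/real   # your own TSV/VCF
```

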