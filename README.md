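# wgpred

Whole-genome prediction and SNP heritability analysis for asthma-related
phenotypes: weighted genomic-relatedness matrices (GRMs) with functional
SNP-prioritization weighting, GREML variance components, GRM-kriging /
G-BLUP prediction with covariate integration, permutation-tested AUC
evaluation, and derivation of longitudinal lung-function phenotypes —
exercised end-to-end on a synthetic cohort generator with known ground
truth.

The package is aimed at statistical geneticists and respiratory-disease
researchers who want to estimate how much of a trait's variance genome-wide
SNPs explain, and how well those SNPs predict the trait in held-out
subjects, on cohorts of the scale of a pediatric asthma trial (hundreds of
subjects, 10^5–10^6 SNPs after quality control).

## The model

Genotype dosages x_ij ∈ {0,1,2} (minor-allele counts, QC'd to autosomes,
MAF ≥ 0.05, Hardy–Weinberg p ≥ 0.001) define a weighted genomic relatedness
matrix

    A_jk = Σ_i w_i (x_ij − 2p_i)(x_ik − 2p_i) / (2 p_i (1 − p_i)) / Σ_i w_i ,

where p_i is the sample allele frequency; the 1/(2p(1−p)) factor is the
standard inverse-variance weight (rarer alleles weigh more), and w_i admits
functional-prioritization schemes: **W1** (total priority score), **W2**
(regulatory-evidence component only), and **NZW** (drop zero-score SNPs,
standard weights on the rest).

Heritability comes from the GRM mixed model y ~ N(Xβ, σ²_g A + σ²_e I),
fitted by AI-REML with EM fallback and a profile-likelihood polish;
h² = σ²_g/(σ²_g + σ²_e) with a delta-method standard error and a boundary
likelihood-ratio test (½χ²₀ + ½χ²₁).

Prediction is G-BLUP / GRM-kriging: a test subject's score is a weighted
sum of the training subjects' (case/control) values with weights from the
genomic similarity, score = K_xt (K_tt + λI)⁻¹ (y − β̂) + β̂, with
λ = σ̂²_e/σ̂²_g from REML. Covariates enter through a convex combination of
the genetic GRM and a covariate-similarity kernel. Evaluation follows the
repeated 75/25-split (25 repeats) and leave-one-out protocols, scoring AUC,
convex-hull AUC, and one-sided label-permutation p-values.

## Worked example

```python
import wgpred as w

cfg = w.SimConfig(n_subjects=400, n_snps=2000, h2_true=0.5, seed=7)
cohort = w.simulate_cohort(cfg)

g, report = w.qc_pipeline(cohort.genotypes)          # autosome -> MAF -> HWE
g = w.mean_impute_genotypes(g)
kin = w.compute_grm(g)                                # standard weights

y = cohort.phenotypes["trait"].to_numpy()
vc = w.greml_fit(y, None, kin)
stat, p = w.lrt_h2(vc, y, None)
print(f"h2 = {vc.h2:.3f} (SE {vc.se_h2:.3f}), LRT p = {p:.2e}")

labels = cohort.phenotypes["label"].to_numpy()
scores = w.loo_predict(kin, labels.astype(float), "gblup",
                       ridge=vc.sigma2_e / vc.sigma2_g)
res = w.loo_eval(lambda: scores.scores, labels, n_permutations=999, seed=1)
print(f"LOO AUC = {res.auc:.3f}, convex-hull AUC = {res.ch_auc:.3f}, "
      f"permutation p = {res.p_empirical:.4f}")
```

Output:

```
h2 = 0.605 (SE 0.151), LRT p = 1.12e-04
LOO AUC = 0.562, convex-hull AUC = 0.588, permutation p = 0.0090
```

The heritability estimate recovers the simulated h² = 0.5 within one
standard error; the leave-one-out AUC of 0.56 says a random case outranks a
random control 56% of the time, and the permutation p-value (add-one form,
999 label shuffles) rejects chance-level prediction.

There is also a CLI mirroring the pipeline stages:

```bash
wgpred simulate --n-subjects 400 --n-snps 2000 --seed 7 --out demo/
wgpred qc demo/genotypes.bed --out demo/clean
wgpred grm demo/clean.bed --out demo/grm.tsv
wgpred reml demo/grm.tsv demo/phenotypes.tsv --out demo/h2.json
wgpred run-all --n-subjects 400 --n-snps 2000 --seed 7 --out demo/run
```

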