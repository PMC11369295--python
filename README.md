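# adipocop

Joint copula-based transcriptome association, GO-term enrichment, Mendelian
randomization and TWAS-style replication for **body fat mass** and **body fat
distribution**.

## The scientific problem

Subcutaneous adipose tissue (SAT) mass measures absolute body fat; the ratio
of SAT to total adipose tissue (SAT/TAT) measures how fat is distributed
between the subcutaneous and visceral compartments. The two traits are
correlated (Kendall's τ ≈ 0.36) but biologically distinct, and a central
question in obesity genomics is which genes' adipose-tissue expression drives
each one. `adipocop` implements the full analysis chain for cohorts that
combine adipose RNA-seq with whole-body MRI phenotypes:

1. **Screen** — for each gene *j*, a joint model of both outcomes given
   expression *g<sub>j</sub>* and covariates *x₁…x₅* (sex, age, smoking,
   physical activity, education):

   *F*(SAT, SAT/TAT | **x**) = *C*<sub>ψ</sub>(*F*₁(SAT | **x**), *F*₂(SAT/TAT | **x**)),

   with linear-Gaussian marginal models

   log SAT = γ₀ + γᵀx + β<sub>j</sub> g<sub>j</sub> + ε,  SAT/TAT = γ′₀ + γ′ᵀx + β′<sub>j</sub> g<sub>j</sub> + ε′,

   coupled by the two-parameter (BB1) Archimedean copula
   *C*(u₁,u₂) = {[(u₁<sup>−φ</sup>−1)<sup>θ</sup> + (u₂<sup>−φ</sup>−1)<sup>θ</sup>]<sup>1/θ</sup> + 1}<sup>−1/φ</sup>,
   φ > 0, θ ≥ 1. All parameters are estimated by one-stage maximum
   likelihood; H₀: β<sub>j</sub> = 0 and H₀: β′<sub>j</sub> = 0 are tested with
   large-sample Wald statistics and Bonferroni correction across genes.
   Modelling the outcome dependence (implied Kendall's
   τ = 1 − 2/(θ(φ+2))) increases power over per-outcome linear regression.
2. **Enrichment** — two-sided Fisher's exact tests of the associated genes
   against the analyzed background per GO term, correction over analyzed
   terms, and summarization by highest-level parent terms.
3. **Mendelian randomization** — per gene, cis-eQTL instruments are filtered
   (eQTL membership; no confounder association; no outcome association
   conditional on expression; Spearman-correlation pruning at |ρ| > 0.9) and
   the causal effect of expression is estimated by inverse-variance-weighted
   GLS that accommodates correlated instruments, with delta weights carrying
   the exposure-uncertainty and exposure–outcome-correlation terms.
4. **Replication** — per-gene SNV weights from a multiple regression of
   expression on the surviving instruments impute genetically-determined
   expression in an independent exome-sequenced cohort, tested against
   abdominal SAT and aSAT/(aSAT+VAT) with covariate adjustment.

Real cohorts of this design are access-restricted, so the package ships a
first-class synthetic-data generator (`adipocop.simulate`) reproducing the
statistical structure of a discovery cohort of n = 160 (τ = 0.36 outcome
dependence via the BB1 copula, ~10% expression variance from cis SNVs,
sex-stratified covariate and phenotype scales) and of a larger replication
cohort with an exome-capture availability mask.

## Worked example

```python
from adipocop import (SimConfig, simulate_cohort, transcriptome_screen,
                      select_instruments, ivw_correlated)

cfg = SimConfig(n_samples=160, n_genes=12, n_causal=2,
                beta_sat=0.5, beta_ratio=0.08, eqtl_r2=0.25, seed=7)
cohort, eqtl, _ = simulate_cohort(cfg)

results, summary = transcriptome_screen(cohort, alpha=0.05)
print(results[["beta", "se", "p", "significant_sat"]].head(4))
print({k: summary[k] for k in ("sat_only", "ratio_only", "both", "total", "cutoff")})

inst = select_instruments("GENE0000", "sat", eqtl, cohort)
mr = ivw_correlated(inst)
print(f"MR GENE0000: theta={mr.theta:.3f} se={mr.se:.3f} p={mr.p:.3g} "
      f"n_var={mr.n_var} R2={mr.r2:.2f}")
```

prints

```
              beta        se             p  significant_sat
gene_id
GENE0000  1.058769  0.096664  6.419245e-28             True
GENE0001  2.715151  0.242841  5.064569e-29             True
GENE0002  0.078890  0.087383  3.666284e-01            False
GENE0003 -0.141185  0.156049  3.655979e-01            False
{'sat_only': 0, 'ratio_only': 0, 'both': 2, 'total': 2, 'cutoff': 0.004166666666666667}
MR GENE0000: theta=0.886 se=0.250 p=0.000393 n_var=5 R2=0.21
```

The two genes engineered with expression effects (`GENE0000`, `GENE0001`) are
the two flagged at the Bonferroni cutoff 0.05/12; `beta` is the change in
log SAT per unit of Yeo-Johnson-transformed expression with its Wald standard
error. The MR line reports the causal effect of `GENE0000` expression on
log SAT estimated from its 5 surviving cis instruments, which jointly explain
21% of its expression variance.

The same stages are available from the shell:

```bash
adipocop simulate --out sim/ --seed 1
adipocop screen --cohort sim/ --out out/
adipocop pipeline --out run/ --seed 1     # full chain incl. MR + replication
```

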