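# mrdietcvd

A summary-statistics pipeline for testing whether dietary habits (binary
"never eat eggs / dairy / wheat / sugar" exposures and a balanced-diet
indicator) causally influence cardiovascular diseases.  It is written for
genetic epidemiologists who have GWAS summary statistics in hand (one row
per SNP: effect allele, beta, SE, p, allele frequency, sample sizes) and
want a reproducible, offline implementation of the full analysis chain:

1. **Two-sample Mendelian randomization** — instrument selection
   (p < 5×10⁻⁶, LD clumping at r² < 0.001 within 10,000 kb, confounder
   exclusion list), exposure/outcome harmonization, and five estimators:
   IVW (fixed / multiplicative random / heterogeneity-switched), MR-Egger,
   weighted median, and simple/weighted mode.  Each SNP contributes a Wald
   ratio β̂ᵧ/β̂ₓ; IVW pools them inverse-variance, β̂ = Σwⱼρⱼ/Σwⱼ with
   wⱼ = 1/SE(ρⱼ)².
2. **Sensitivity battery** — Cochran's Q and I², the MR-Egger intercept
   (directional pleiotropy), the Steiger directionality test
   (r² = z²/(z²+n) per trait side), leave-one-out influence analysis, and
   grouped Benjamini–Hochberg FDR.
3. **Meta-analysis** — per-disease pooling of the per-dataset IVW odds
   ratios on the log scale: fixed-effect inverse variance and
   DerSimonian–Laird random effects (τ² = max(0, (Q−(k−1))/C)).
4. **Colocalization** — Wakefield approximate Bayes factors per SNP,
   lABF = ½(log(1−r) + r·z²) with shrinkage r = W/(V+W), combined into
   posterior probabilities PP.H0–PP.H4 over the five causal configurations
   of a ±500 kb region, plus per-SNP SNP.PP.H4.
5. **ROC evaluation** — per-gene AUC (Mann–Whitney, ties half) with DeLong
   or bootstrap 95% CIs and an AUC > 0.6 accuracy flag.

A seed-deterministic synthetic-GWAS module generates exposure/outcome
pairs, LD-coherent two-trait regions (H0–H4 scenarios), and a 111-case /
46-control expression matrix, so every stage runs and is tested without any
external downloads.

## Worked example

```python
from mrdietcvd import (MrSimConfig, simulate_mr_pair, harmonize, run_all,
                       sensitivity_report, compute_labf)

exp, out, truth = simulate_mr_pair(MrSimConfig(n_snps=30, theta=0.5, seed=7))
h = harmonize(exp, out)
print(f"instruments kept: {h.nsnp}")
for est in run_all(h, seed=17):
    print(f"{est.method:>14}  OR {est.or_:.3f} "
          f"({est.or_lci95:.3f}-{est.or_uci95:.3f})  p {est.pval:.3g}")
rep = sensitivity_report(h)
print(f"Q = {rep.q_stat:.2f} (p {rep.q_pval:.3f}), "
      f"Egger intercept {rep.egger_intercept:.4f} (p {rep.egger_intercept_p:.3f}), "
      f"Steiger {rep.steiger_direction}")
```

prints

```
instruments kept: 30
     IVW_fixed  OR 1.638 (1.580-1.697)  p 8.33e-161
         Egger  OR 1.563 (1.327-1.840)  p 1.06e-05
WeightedMedian  OR 1.617 (1.539-1.698)  p 1.87e-82
    SimpleMode  OR 1.604 (1.459-1.765)  p 2.29e-22
  WeightedMode  OR 1.604 (1.459-1.765)  p 2.29e-22
Q = 19.40 (p 0.911), Egger intercept 0.0017 (p 0.571), Steiger True
```

The true causal effect is θ = 0.5 (OR e^0.5 ≈ 1.65): all five estimators
agree with it and with each other, the heterogeneity and pleiotropy tests
are quiet, and Steiger confirms the exposure→outcome direction.  The
colocalization primitive works the same way from printed inputs:

```python
labf, r = compute_labf(z=-11.74203928, V=0.04 * (1 - 0.997908885) / 0.997908885, W=0.04)
print(f"lABF = {labf:.8f}  (r = {r:.9f})")
# lABF = 65.70855755  (r = 0.997908885)
```

— the log Bayes factor of the shared-locus SNP rs12740374 for its outcome
trait, a decisive single-variant association.

## Command line

```sh
mr-dietcvd simulate mr    --out sim/ --seed 3         # synthetic GWAS pair
mr-dietcvd mr run  --exposure sim/exposure.tsv --outcome sim/outcome.tsv \
                   --out table1.tsv --seed 17
mr-dietcvd meta run  --table1 table1.tsv --groups groups.yaml --out table2.tsv
mr-dietcvd coloc run --trait1 a.tsv --trait2 b.tsv --center 1:1000000 \
                     --out table3.tsv
mr-dietcvd roc run   --matrix expr.tsv --labels labels.tsv \
                     --genes PSRC1,CELSR2,MYBPHL --out roc.tsv
mr-dietcvd run --config pipeline.yaml                 # all three steps
```

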