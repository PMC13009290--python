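# growvar

Quantitative genetics of **growth resilience** from longitudinal fish
weights. Fish that grow steadily are presumed to cope better with
environmental perturbations (e.g. the daily hypoxia of a non-aerated
earthen pond) than fish whose growth fluctuates. `growvar` turns repeated
weight records into a heritable resilience indicator and estimates its
genetic architecture with a genomic animal model — the full chain used in
tilapia breeding research, reimplemented as a tested, reusable Python
package with a synthetic-data generator so every stage runs at desk scale.

## The model

Growth follows an allometric curve `W_it = a + b_i t^f`. The package
estimates the weight exponent *f* from the data (a power-transform profile
likelihood; ≈1.77 for pond-reared tilapia), linearizes weights as
`W^(1/f)`, and fits a straight line per fish:

```
W_exp,it^(1/f) = a_i + DGC_i · t
```

The slope `DGC_i` is the daily growth coefficient. Deviations
`dev_it = W_obs,it^(1/f) − W_exp,it^(1/f)` are homoscedastic across ages on
this scale, and the resilience indicator is

```
LnVar_ind,i = ln Var(dev_i1 … dev_iT)        (sample variance, T = 5 ages)
```

with a cohort variant `LnVar_coh` that standardizes deviations from the
hapa × sex × pond mean weight per age. Genetic parameters come from the
animal model

```
y_ijk = μ + CAGE_i + SEX_j + (b·SW_k) + a_k + e_ijk
a ~ N(0, σ²_A G),   e ~ N(0, σ²_e I)
```

with **G** a VanRaden method-2 genomic relationship matrix from SNP
dosages. Bivariate fits use `N(0, G ⊗ C)` / `N(0, I ⊗ R)` covariances;
for traits recorded in different ponds on different fish the residual
covariance is fixed at zero and the cross-environment genetic correlation
`r_g` quantifies genotype-by-environment interaction. Heritability is
`h² = σ²_A / σ²_P`. Variance components are estimated by
average-information REML written in-repo (dense LAPACK algebra, monotone
likelihood, delta-method standard errors, BLUP breeding values).

See `docs/methods.md` for the full model description, numerical choices
and generator calibration.

## Worked example

```python
import pandas as pd
from growvar import (SimConfig, simulate_genotypes, simulate_weights,
                     compute_grm, estimate_weight_exponent,
                     fit_individual_lines, resilience_table,
                     descriptive_stats, build_design, reml_univariate)
from growvar.records import WeightRecordSet

cfg = SimConfig(n_fish_per_pond=(300, 300), n_snps=3000, seed=42)
ped, dosages = simulate_genotypes(cfg, seed=42)
per_pond, truth = simulate_weights(cfg, pedigree=ped, seed=43)
records = WeightRecordSet(pd.concat([per_pond[p].data for p in per_pond],
                                    ignore_index=True))

fit = estimate_weight_exponent(records)
print(f"estimated weight exponent f = {fit.f:.3f}")

fits = fit_individual_lines(records, fit.f)
table = resilience_table(records, fits)
print(descriptive_stats(table).round(3)[["aerated_mean", "aerated_sd",
                                         "non_aerated_mean", "non_aerated_sd",
                                         "welch_p"]])

grm = compute_grm(dosages, ped["fish_id"])
sub = table[table["pond"] == "non_aerated"]
y, X, ids, _ = build_design(sub, "lnvar_ind", grm)
res = reml_univariate(y, X, grm, ids, trait="lnvar_ind")
print(f"h2(LnVar_ind, non-aerated) = {res.h2['lnvar_ind']:.2f} "
      f"+/- {res.h2_se['lnvar_ind']:.2f}")
```

Output:

```
estimated weight exponent f = 1.792
           aerated_mean  aerated_sd  non_aerated_mean  non_aerated_sd  welch_p
trait
w5              772.784     205.263           586.598         137.952    0.000
dgc               0.150       0.029             0.122           0.022    0.000
lnvar_ind         1.225       1.089             0.980           1.181    0.009
lnvar_coh        -0.726       0.937            -0.735           0.980    0.907
h2(LnVar_ind, non-aerated) = 0.28 +/- 0.14
```

Reading it: the exponent lands near its generating value (1.77); harvest
weight, growth rate and LnVar_ind are all higher in the aerated pond
(Welch p < 0.01) while the cohort indicator does not differ; and at this
reduced n = 600 the REML heritability of LnVar_ind in the harsher pond is
0.28 with a correspondingly wide standard error. The pond contrasts and
the heritability mirror the generating configuration.

The same chain is available from the shell:

```
growvar simulate --seed 1 --out run/
growvar fit-growth --records run/weights.csv --out run/fit/
growvar indicators --records run/weights.csv \
        --exponent-json run/fit/exponent.json --out run/resilience.csv
growvar grm --dosages run/dosages.tsv --out run/grm.txt
growvar reml --table run/resilience.csv --grm run/grm.txt \
        --trait lnvar_ind --cross-env --out run/rg.json
growvar report --seed 1 --out report/     # full pipeline + tables + figures
```

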