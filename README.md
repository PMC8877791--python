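# mlmetab

Multilevel random-forest analysis of paired arterial and venous umbilical
cord plasma metabolomes.

Umbilical cord blood carries two distinct plasmas: venous blood flowing
from the placenta to the fetus (maternal oxygen and nutrients) and
arterial blood flowing back (fetal waste). Metabolomic studies often pool
the two in unknown proportions, which blurs any signal that differs
between them. `mlmetab` is for researchers who sample the two vessels
separately and want to (a) quantify how distinguishable the two
metabolomes are, (b) find which metabolites drive the difference, and (c)
test whether maternal or infant traits (parity, sex, gestational length,
birth weight, maternal age, BMI) are associated with either vessel's
metabolome — all with cross-validated, permutation-guarded machinery that
is hard to overfit at cohort sizes of a few dozen subjects.

## The model

For subject *i* and metabolite *j* with arterial intensity *A\_ij* and
venous intensity *V\_ij*, the within-subject contrast is isolated in the
**effect matrix**

```
E_ij = log2(A_ij / V_ij)
```

which cancels the (dominant) between-subject variation. `E` stacked with
`−E` is modeled against targets −1/+1 by a random forest inside a
**repeated double cross-validation** (rdCV) with recursive variable
elimination: an inner CV eliminates variables by forest importance and
picks minimal/intermediate/maximal near-optimal model sizes, an outer CV
supplies unbiased out-of-fold predictions, and the whole procedure is
repeated over fresh fold partitions. The **classification rate** (CR) is
the fraction of observations whose repetition-averaged out-of-fold
prediction falls on the correct side of zero; continuous responses are
scored by **Q2 = 1 − PRESS/TSS**. Models clearing an a-priori gate
(CR > 66% or Q2 > 0.2) are tested by design-respecting permutations
(within-subject sign flips for the paired design, label permutations for
trait models) with the add-one estimator
`p = (1 + #{null ≥ observed}) / (1 + n_perm)`. Selected metabolites get
geometric-mean fold changes, Mann-Whitney U and paired t-tests, and
Benjamini-Hochberg FDR adjustment.

Because paired cord-plasma cohorts are rarely public, the package includes
a first-class synthetic-data generator that emulates the study design
(paired samples, dominant between-subject variance, planted fold changes
of realistic magnitude, acquisition batches, sparse missingness, cord pH
with occasional sampling errors) so the entire workflow is testable
against known ground truth.

## Worked example

```python
from mlmetab import (SynthConfig, generate, build_effect_matrix,
                     build_design, RandomForestRdCV, permutation_test,
                     performance_gate)

# a 48-subject study with 11 planted arteriovenous fold changes (0.71-1.72)
cfg = SynthConfig(n_features=100, trait_log2fc=(), n_batches=1,
                  missing_rate=0.0, frac_delayed=0.0, delayed_noise_sd=0.0,
                  seed=0)
table, pairs, truth = generate(cfg)

E = build_effect_matrix(table, pairs)          # 48 x 100 log2(A/V)
design = build_design(E)                       # 96 x 100, targets -1/+1

model = RandomForestRdCV(n_rep=2, n_outer=5, n_inner=4, var_ratio=0.6,
                         min_features=5, n_trees=31, random_state=0)
model.fit(design.X, design.y, groups=design.groups)
print(f"classification rate: {model.fitness_:.3f}")
print(f"gate passed: {performance_gate('classification_rate', model.fitness_)}")
hit = set(truth.vessel_effects) & set(model.selected_mid_)
print(f"planted features in mid-size selection: {len(hit)}/11")
```

prints

```
classification rate: 0.875
gate passed: True
planted features in mid-size selection: 10/11
```

— 84 of the 96 stacked observations end on the correct side of the zero
boundary (the planted arteriovenous effects are clearly detectable at this
noise level), the model clears the 66% gate, and 10 of the 11 planted
metabolites are among the variables the elimination keeps in the
intermediate-size model. A follow-up
`permutation_test(..., scheme="signflip", n_perm=99)` on this fit returns
`p_value = 0.01` — the observed fitness exceeds all 99 within-subject
sign-flip nulls.

The same engine runs from the shell:

```sh
mlmetab simulate --out-dir study/          # features.csv, metadata.csv, truth.json
mlmetab preprocess --features study/features.csv --metadata study/metadata.csv --out-dir clean/
mlmetab fit --features study/features.csv --metadata study/metadata.csv \
            --design multilevel --seed 1 --out vessel.json
mlmetab run --out-dir full_run/            # the whole workflow end to end
```

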