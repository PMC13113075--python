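# vocpartition

Hierarchical variance partitioning and subject-wise validated distress
classification for pig vocalization acoustics.

## The problem

Acoustic features of pig calls (intensity, duration, pitch, formants F1–F4,
amplitude and energy descriptors) carry information about welfare-relevant
distress states — pain, hunger, thirst, cold stress, heat stress — but they
are also shaped by two confounders that can make naive classifiers look far
better than they are:

* **development**: growth phase (farrowing → nursery → growing → finishing)
  shifts the baseline acoustic phenotype;
* **individuality**: each pig has a stable "voice identity", so a model
  evaluated with samples of the same animals in train and test partly
  memorizes individuals instead of learning distress.

`vocpartition` implements the full analysis chain for this setting, for
researchers in bioacoustic welfare phenotyping and precision livestock
farming:

1. **Variance partitioning** (`variance_partition`). For each trait *y* a
   linear mixed model
   *y = β₀ + β₁·Sex + β₂·Phase + β₃·Distress + u_animal + v_recording + ε*,
   with *u* ~ N(0, σ²_Animal), *v* ~ N(0, σ²_Recording) nested in animal
   (the three 20 s samples cut from one 60 s recording), ε ~ N(0, σ²).
   Reported per trait: ICC_Animal = σ²_Animal/(σ²_Animal + σ²_Recording + σ²),
   Nakagawa marginal/conditional R², drop-one ΔR² per fixed block
   (sex / phase / distress), distress×phase interaction selection
   (ML likelihood-ratio test + AIC), Benjamini–Hochberg FDR across the
   trait×block family.
2. **Subject-wise classification** (`subject_cv`). Animal-grouped,
   stratified k-fold cross-validation — no animal ever in both train and
   test — with leakage-free within-fold preprocessing (train-fold median /
   mode imputation, train-fold z-scaling), multinomial logistic regression,
   random forest and gradient boosting; balanced accuracy, macro-F1,
   per-class precision/recall/F1. Sensitivity variants: acoustics-only,
   pitch-excluded, complete-case vs imputed.
3. **Confusability / uncertainty** (`confusability`). Row-normalized
   confusion C(a→b), symmetric confusability S(a,b) = ½[C(a→b) + C(b→a)],
   per-sample prediction entropy and top-two margin, phase-stratified
   overlap maps, and hierarchical clustering of classes on 1 − S with
   fold-stability (adjusted Rand index).
4. **Permutation importance** (`importance`). Δmacro-F1 when one predictor
   is shuffled in the held-out animals, aggregated across grouped folds
   with empirical percentile intervals; categorical predictors are permuted
   as a unit.
5. **Synthetic data** (`synthetic_data`). A generator that reproduces the
   study design — 40 animals × 4 phases × up to 6 conditions (heat stress
   only from growing on, thirst absent in farrowing), one 60 s recording
   per cell split into three 20 s samples — with per-trait fixed effects,
   animal and recording random intercepts, log-normal options for skewed
   traits, and MNAR pitch missingness driven logistically by phase and
   condition.

`datasets` additionally embeds the study's released cell-level summaries
(design counts with pitch missingness; per-condition trait moments) and can
build an exact-moment synthetic stand-in table from them.

## Worked example

```python
from vocpartition import default_config, generate_dataset
from vocpartition import subject_cv as scv, variance_partition as vp

table = generate_dataset(default_config(seed=3))     # 2280 samples, 40 pigs
res = vp.partition_traits(table, ["intensity", "f2"],
                          random=("animal", "recording"))
for r in res:
    print(f"{r.trait}: ICC={r.icc:.3f}  R2m={r.r2_marginal:.3f} "
          f"R2c={r.r2_conditional:.3f}  dR2(distress)={r.delta_r2['distress']:.3f}")

plan = scv.make_grouped_folds(table, k=5, seed=3)
cv = scv.run_cv(table, plan, models=("rf",), seed=3)["rf"]
print(f"rf: balanced accuracy {cv.balanced_accuracy:.3f}, "
      f"macro-F1 {cv.macro_f1:.3f}")
print(cv.per_class.round(3))
```

prints (seed 3):

```
intensity: ICC=0.102  R2m=0.327 R2c=0.484  dR2(distress)=0.314
f2: ICC=0.047  R2m=0.363 R2c=0.445  dR2(distress)=0.289
rf: balanced accuracy 0.525, macro-F1 0.518
        precision  recall     f1  support
normal      0.383   0.373  0.378      480
pain        0.810   0.921  0.862      480
hunger      0.378   0.385  0.381      480
thirst      0.389   0.303  0.341      360
cold        0.561   0.592  0.576      240
heat        0.566   0.575  0.570      240
```

Reading this: distress exposure dominates the explained variance of
intensity and F2 (ΔR² ≈ 0.3), animal identity adds a consistent increment
(R²c − R²m ≈ 0.05–0.15), and under strict unseen-animal evaluation pain is
by far the most separable state while the non-pain conditions overlap —
the qualitative pattern the generator is calibrated to.

The same pipeline runs from the shell:

```bash
vocpartition simulate --out table.csv --seed 17
vocpartition validate table.csv
vocpartition partition table.csv --traits intensity,f2
vocpartition cv table.csv --k 5 --models logit,rf --seed 17
```

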