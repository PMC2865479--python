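# sexconstraint

Simulation-based comparative testing of **sexual constraint** on the
evolution of dimorphic ornaments.

Males and females of a clade often carry the same ornament to a similar
or lesser degree in females. A cross-species correlation between male
and female ornament scores says that *something* binds their evolution,
but not what: selection on males dragging females along (constraint on
females), the reverse (constraint on males), or both sexes pulling on
each other (mutual constraint). This package implements a Monte-Carlo
comparative method that discriminates these explanations for a clade
with no reversed dimorphism (female score ≤ male score in every
species), as in cardueline finch coloration.

## The method

On a rooted **speciational** phylogeny (every branch = one unit of
change), each branch updates the lineage's (M, F) score pair in three
steps:

1. **Brownian motion** — independent increments `M += R_m`, `F += R_f`,
   with `R ~ N(0, 1)`;
2. **block reversed dimorphism** — if `F > M`, reset the constrained
   sex (females: `F = M`; males: `M = F`; mutual: both to their mean);
3. **constraint pull** — the constrained sex moves toward the other by
   a fixed proportion `C` of the difference, e.g. `F += C·(M − F)`
   (under mutual constraint both move simultaneously, so `C ≤ 0.5`).

`C` is calibrated by bisection (common random numbers) so that the mean
Pearson correlation between extant male and female scores matches the
observed one — the three models are equally parameterised.

Each calibrated model is run 1000 times; from each run's extant scores,
after standardizing their joint distribution, three statistics are
computed:

- **DSD** = SD(male) − SD(female) — the constrained sex diversifies
  less;
- **SK** = Zg₁ (D'Agostino–Pearson normalized skewness) of the pooled
  male + female values — the pooled distribution skews toward the
  independent sex;
- **DRS** = slope(F on M) − slope(M on F) = r·(SD_F/SD_M − SD_M/SD_F).

A model is **rejected** when an observed statistic falls outside the
two-tailed 95% CI of its 1000 simulated values; the best-supported
model survives all three statistics while its alternatives are
rejected. Pairwise discriminability is quantified as the probability
that one model's statistic falls inside another model's CI (the type II
error; 1 − it is the power to tell the pair apart).

Composite ornament scores can be built from raw colour measurements via
correlation-matrix PCA with broken-stick (or Kaiser) component
retention, each retained component weighted by its eigenvalue
(`sexconstraint score`).

## Worked example

Entirely synthetic: generate a 23-species speciational tree and a
pseudo-observed score table evolved under constraint on females, then
test all three models against it.

```sh
printf 'synthetic:\n  n_species: 23\n  target_r: 0.893\n  seed: 3\nn_runs: 1000\nseed: 42\nout_dir: report\n' > run.yaml
sexconstraint analyze --config run.yaml
```

prints

```
run seed 42; report written to report
constraint_on_females: indeterminate
constraint_on_males: rejected
mutual_constraint: indeterminate
```

and `report/table2.tsv` holds the percentile of the observed statistic
in each model's null distribution with its two-tailed P:

```
model                  statistic  observed   percentile  p_two_tailed  rejected
constraint_on_females  DSD        0.179729   0.533       0.934         False
constraint_on_females  SK         0.371256   0.475       0.95          False
constraint_on_females  DRS        -0.264499  0.49        0.98          False
constraint_on_males    DSD        0.179729   0.982       0.036         True
constraint_on_males    SK         0.371256   0.765       0.47          False
constraint_on_males    DRS        -0.264499  0.02        0.04          True
mutual_constraint      DSD        0.179729   0.867       0.266         False
mutual_constraint      SK         0.371256   0.611       0.778         False
mutual_constraint      DRS        -0.264499  0.126       0.252         False
```

Read it as: the observed DSD (0.18) sits at the 98.2nd percentile of
the male-constraint null — too far in the tail (P = 0.036), so
constraint on males is rejected by DSD (and by DRS); the female and
mutual models survive every statistic, so with this single pseudo-
observed draw the data cannot separate them and both are reported
indeterminate rather than forcing a winner. `report/power.tsv` holds
the pairwise type-II-error matrix and `report/run.json` the calibrated
pull constants (here C ≈ 0.13/0.13/0.10) and every seed, making the run
exactly reproducible.

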