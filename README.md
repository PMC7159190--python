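# elemdyn

Attractor-state and recurrence analysis of longitudinal biomarker time
series.

Some biomarkers can be measured hundreds of times along a developmental
axis — the motivating case is elemental concentrations in tooth dentine,
which record roughly weekly values from birth through adolescence. Such
profiles are dynamical objects: a series may occupy one homeostatic regime
or switch between several, and it may cycle regularly or erratically.
`elemdyn` quantifies both aspects per subject and element and carries them
into epidemiological group comparisons and disease classification. It is
aimed at biostatisticians and exposure-biology researchers who have (or
want to simulate) cohorts of such profiles.

Per series it computes:

- **Quasi-stable state count** from the potential landscape: the stationary
  density P_d (Gaussian KDE, Scott bandwidth) defines a potential through
  the Fokker–Planck steady state, U = −(σ²/2) log P_d with the series
  standardised to σ = 1. Local minima of U are attractor states, local
  maxima the tipping points between them.
- **Recurrence features** from the Takens delay embedding (delay τ from the
  first AMI minimum, dimension m from false-nearest-neighbour
  minimisation) and a recurrence plot thresholded adaptively at a 10%
  recurrence rate: determinism DET = Σ_{l≥lmin} l·P(l) / Σ_{l≥1} l·P(l),
  mean diagonal length MDL = Σ_{l≥lmin} l·P(l) / Σ_{l≥lmin} P(l), and
  diagonal entropy ENT = −Σ p(l) ln p(l), with lmin = 3.

Cohort-level, it fits Poisson regressions on state counts and linear models
on RQA features (sex- and age-adjusted, Benjamini–Hochberg FDR across
elements), and trains LASSO and gradient-boosted-tree classifiers on the
dynamical features with bootstrap ROC confidence bands and a rank-based
test of AUC against chance. Because real dentine datasets are not publicly
deposited, a first-class synthetic module generates cohorts with the same
structure (bistable/mono-stable Langevin wells, regime-switching
oscillations, planted case/control effects) for development, calibration
and power studies.

## Worked example

```python
import elemdyn as ed

subjects = ed.simulate_cohort(ed.planted_cohort_spec(seed=1))  # 36 cases / 31 controls
table = ed.build_feature_table(subjects)                       # 67 x (5 elements x 4 features)

series = subjects[36].series["Cu"]   # first control subject, copper
print(f"{series.subject_id}: {series.n} samples, "
      f"{ed.count_states(series)} quasi-stable states")
res = ed.rqa_features(series)
print(f"tau={res.params.delay} m={res.params.dimension} "
      f"DET={res.determinism:.3f} MDL={res.mean_diagonal_length:.2f} "
      f"ENT={res.entropy:.3f}")

tests = ed.compare_groups(table)
print(tests[tests.element == "Cu"][["feature", "estimate", "p_raw", "p_fdr"]]
      .to_string(index=False))

out = ed.evaluate_classifiers(table, seed=1)
roc = out["lasso"]["roc"]
print(f"LASSO test AUC {roc.auc:.2f} (95% CI {roc.auc_ci[0]:.2f}-{roc.auc_ci[1]:.2f}), "
      f"threshold {roc.optimal_threshold:.3f}, accuracy {roc.accuracy_at_threshold:.1%}, "
      f"p vs chance {roc.p_vs_chance:.1e}")
```

prints

```
ctrl_037: 454 samples, 2 quasi-stable states
tau=7 m=6 DET=0.606 MDL=4.35 ENT=1.445
 feature  estimate        p_raw        p_fdr
n_states -0.547785 6.716903e-03 1.679226e-02
     det -0.450334 7.125383e-39 3.562691e-38
     mdl -2.016258 3.904990e-10 9.762474e-10
     ent -0.856449 9.968900e-13 4.984450e-12
LASSO test AUC 1.00 (95% CI 1.00-1.00), threshold -3.325, accuracy 100.0%, p vs chance 5.0e-08
```

Reading this: the control subject's copper profile is bistable (2 states)
with moderate periodicity (DET 0.61); across the cohort, cases have about
exp(−0.55) ≈ 0.58 times the controls' state-formation rate for copper and
markedly lower determinism, both surviving FDR; and on the held-out 40%
test split the LASSO separates the planted case/control difference
perfectly. (The planted synthetic effects are stronger than anything one
should expect from real cohorts.)

The same pipeline is available from the shell:

```
elemdyn simulate -o cohort/                 # packaged demo cohort (67 subjects)
elemdyn features -m cohort/manifest.csv -o cohort/features.csv
elemdyn compare  -f cohort/features.csv -o cohort/group_tests.csv
elemdyn predict  -f cohort/features.csv -o cohort/ --plot
# or: elemdyn run-all -c config.yaml -o out/
```

Exit codes: 0 success, 2 config error, 3 data error. Each run writes
`run_log.json` with the config hash, seeds, resolved parameters and stage
timings.

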