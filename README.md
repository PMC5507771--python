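# metabopredict

Pre-intervention urinary ¹H-NMR metabotypes as predictors of later
metabolic-disease outcomes, as a tested, reusable Python pipeline.

## The problem

Isogenic C57BL/6J mice put on a high-fat diet (HFD) diverge within weeks
into markedly different phenotypes: obese glucose-intolerant (*Ob-IGT*),
lean glucose-intolerant (*L-IGT*), lean normoglycemic non-responders
(*LNG*), and a large midgroup. Urinary metabolic profiles collected
**before** the diet switch — dominated by microbial-host co-metabolites
such as trimethylamine-N-oxide (TMAO), the other methylamines, hippurate
and phenylacetylglycine (PAG) — carry enough information to predict which
group an animal will end up in. This package implements the complete
statistical workflow needed to make and validate that claim, together with
a fully specified synthetic cohort generator so every stage is testable
without access to the original (undeposited) instrument data.

## The method

Given spectral matrices X (samples × ppm) and a phenotype table:

1. **Preprocessing** — recursive segment-wise peak alignment (RSPA) to a
   reference spectrum by exhaustive integer-shift correlation search with
   recursive bisection; removal of the water/urea windows; probabilistic
   quotient normalization (PQN): each sample is divided by the median of
   its intensity quotients against the median spectrum, correcting urinary
   dilution.
2. **Feature extraction** — statistical recoupling of variables (SRV):
   consecutive spectral variables whose correlation landscape
   r_j = corr(x_j, x_{j+1}) stays ≥ 0.9 are merged into clusters; cluster
   mean intensities are log-transformed (variance stabilization) and
   annotated against a metabolite library.
3. **Modelling** — orthogonal projections to latent structures
   (O-PLS / O-PLS-DA). For a single response, the predictive weight vector
   is w ∝ Xᵀy; response-orthogonal components w_o ∝ p − (wᵀp)w are
   stripped from X before the final predictive component. Goodness of
   prediction is Q² = 1 − PRESS/TSS from 7-fold cross-validation.
4. **Validation** — empirical p-values for Q² from permutations of the
   response (CV re-run inside every iteration; add-one correction
   p = (1 + #{Q²_perm ≥ Q²_obs})/(n_iter + 1)); ROC/AUC on the
   cross-validated predictive scores (midrank Mann-Whitney).
5. **Association mapping** — feature × phenotype Spearman correlations
   with per-cell permutation p-values and significance masking at
   p < 0.05, plus an O-PLS regression screen of every quantitative
   phenotype.
6. **Stratification** — the 2-SD rule: animals above mean + 2·SD of
   cumulative glycemia (and body weight) become L-IGT (Ob-IGT); a
   configurable lower rule defines LNG.

## Worked example

```python
import metabopredict as mp

cohort = mp.simulate_cohort(mp.CohortConfig(seed=7))         # 50 animals, 4 urine timepoints
ds = mp.rspa_align(cohort.spectra[0]).aligned                # day-0 spectra
ds = mp.exclude_regions(ds, [(4.5, 5.0), (5.4, 6.2)])
features = mp.extract_features(ds, cohort.library)           # PQN + SRV + log

groups = mp.stratify(cohort.phenotypes)                      # 2-SD rule
ids, y, _ = mp.groups_to_targets(groups, "extreme")
report = mp.validate_model(features.subset_samples(ids).values,
                           y.to_numpy(float), mode="da",
                           k=7, n_orth=1, n_iter=999, seed=0)
print(groups.counts())
print(report.cv.summary())
print(report.permutation.summary())
print(report.roc.summary())
```

Output:

```
{'LNG': 4, 'L-IGT': 2, 'Ob-IGT': 2, 'midgroup': 42}
7-fold CV (n=50, n_orth=1): Q2 = 0.6506, PRESS = 2.348, TSS = 6.72
observed = 0.6720, permutation p = 0.001 (999 iterations)
AUC = 1.0000 (51 curve points)
```

The 2-SD rule finds 8 extreme responders among the 50 animals; their
day-0 urinary metabotype separates them from the midgroup with a
cross-validated Q² of ~0.65 and an AUC of 1.0, and the model beats all
999 permuted-response models (p = 0.001) — the prodromal-prediction claim
on a cohort where the planted ground truth is known.

The same run as one command:

```bash
metabo run --seed 7 --out run_out
```

writes all intermediates (spectra, feature tables, labelled phenotypes,
association matrices) as delimited text plus a `report.json`.

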