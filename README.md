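# paleoxeno

Censoring-aware analysis of tea- and tobacco-related xenobiotics measured
in hair from historical individuals.

## The problem

Hair preserves xenobiotics for centuries.  In frozen burials from eastern
Siberia (17th–19th century), concentrations of three tea methylxanthines
(theobromine, caffeine, theophylline) and two tobacco markers (nicotine
and its metabolite cotinine) record how two addictive substances spread
through a population that had never been exposed to them.  The data are
awkward in three classic ways: measurements are left-censored at the
quantification limit (non-detects, "ND"), the cohort is small (n = 47) and
stratified by era, sex, age and social status, and the geography that
drives the story — distance to the trading routes through which tea and
tobacco arrived — is only partially published.

`paleoxeno` is a reusable pipeline for exactly this kind of dataset,
aimed at biomolecular-archaeology and hair-toxicology practitioners:

* a data model in which ND is a state, never a number, with the analytical
  limits (LOD/LLOQ) attached, plus the embedded 47-individual cohort;
* LC-MS/MS calibration mathematics (1/x-weighted quadratic regression,
  accuracy/precision acceptance at 25%/20%);
* a deterministic rule engine mapping detection patterns to beverage type
  (herbal/green/black tea, coffee, ...) and the nicotine+cotinine mean to a
  tobacco-consumption tier;
* era-stratified summaries, Fisher exact contrasts of methylxanthine
  combinations, and logistic regressions of use on time and status;
* comparison of nicotine/cotinine correlations across age classes by the
  independent-groups Fisher r-to-z test with Zou confidence intervals;
* geography: great-circle distance correlations, permutation ANOVA over
  excavation regions, and a 10%-perturbation robustness test;
* PCA-based tea/tobacco use indices interpolated into a spatial surface;
* a synthetic-cohort generator (log-normal censored concentrations,
  Gaussian-copula nicotine/cotinine, NE–SW caffeine gradient, pipe model)
  so every stage is testable and power-checkable without any download.

## Core statistics

For two independent correlations the comparison statistic is

    z = (atanh r1 − atanh r2) / sqrt(1/(n1−3) + 1/(n2−3))

with Zou's interval for r1 − r2 built from the back-transformed
single-group intervals.  Permutation p-values use the +1 Monte-Carlo
correction, p = (1 + #{T* ≥ T}) / (1 + B).  The robustness probability is
P(|rs| > 0.5) over replicates in which a random 10% of values are permuted
among themselves.  Product-use indices are axis-1 scores of
correlation-matrix PCA on log1p concentrations (ND → 0).

## Worked example

```python
import paleoxeno as px

cohort = px.load_cohort()            # the embedded 47-individual table
summary = px.detection_summary(cohort)
print(summary.detection_counts)
print(summary.medians["before_1800"]["caffeine"][1],
      summary.medians["after_1800"]["caffeine"][1])

calls = px.classify_cohort(cohort).set_index("sample_id")
print(calls.loc[29, ["drink", "tobacco_index", "tobacco_tier"]].to_dict())

fit = px.fit_logistic(cohort)        # era ~ theophylline + theobromine + caffeine
print(round(fit.params["caffeine"], 6))

pca, tea_index = px.product_use_index(cohort, "tea")
print(pca.eigenvalues.round(3))
```

prints

```
{'theobromine': 31, 'caffeine': 29, 'theophylline': 19, 'nicotine': 43, 'cotinine': 47}
28.0 55.0
{'drink': 'nothing', 'tobacco_index': 6124.5, 'tobacco_tier': 'very_high'}
0.006822
[2.159 0.593 0.248]
```

Reading: theobromine is the most-detected methylxanthine (31/47), the
detected-only caffeine median doubles after 1800 (28 → 55 pg/mg),
individual #29 shows no tea compounds but a tobacco index of 6124.5 pg/mg
— a very high consumer; the era logistic model puts a positive coefficient
on caffeine (0.0068 per pg/mg, the shift toward caffeinated tea after
1800), and the tea-use PCA concentrates 2.16 of 3 units of variance on its
first axis.

A `paleoxeno` command-line tool wraps the same functions
(`validate`, `classify`, `stats`, `correlations`, `geo`, `surface`,
`simulate`); see `paleoxeno --help`.

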