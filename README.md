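# relw — relative-weight diagnostic scoring

`relw` implements an interpretable additive scoring model for binary
diagnostic variables — patient symptoms or medical-image findings such as
ground-glass opacity (GGO) on chest CT. It is aimed at clinicians and
clinical-informatics developers who want a prediction they can audit line by
line: every score is a sum of per-variable weights that can be traced back
to patient counts in a cohort.

## The model

Given a *counting dataset* — for each variable *v*, the number of patients
`count(v)` exhibiting it — the **relative weight** of a variable is

```
w(v) = count(v) / Σ_u count(u)
```

so the weights sum to 1 and rank variables by how often they occur. A
patient's presence/absence profile is scored as

```
+LR = Σ w(v)  over present variables v        (sum-of-present mode)
−LR = 1 − (+LR)
```

The output labels follow the clinical "positive/negative likelihood ratio"
usage of the source tables, but these are additive scores in [0, 1], not
sensitivity/specificity-based likelihood ratios. A second *complement* mode
computes `+LR = 1 − Σ w(absent)`; the two coincide exactly whenever the
weight table sums to 1, and differ by the excess on published tables that
sum to more than 100%. For *k* variables the full **explanation table** of
all 2^k profiles can be streamed, looked up row by row, or reduced to its
top-scoring rows.

All weight arithmetic is exact rational arithmetic (`fractions.Fraction`),
so `+LR + (−LR) = 1` holds exactly and percent rendering is a faithful
half-up rounding of the true value.

## Worked example

The package bundles a published COVID-19 cohort (112 patients, 15 symptom
variables whose counts sum to 279; see `relw.data`). Scoring a patient with
dry cough, low-grade fever, headache and myalgia:

```sh
python -c "from relw.data import covid_symptom_counts; \
           from relw.dataset_io import write_dataset; \
           write_dataset(covid_symptom_counts(), 'symptoms.csv')"
relw score symptoms.csv -p "Dry Cough" -p "Low-grade fever (37.3–38.0)" \
     -p "Headache" -p "Myalgia"
```

prints

```
variable                                 status     weight   cum +LR
Dry Cough                                present     17.2%     17.2%
Low-grade fever (37.3–38.0)              present     16.5%     33.7%
Myalgia                                  present      6.5%     40.1%
Headache                                 present      2.9%     43.0%
Moderate-grade fever (38.1–39.0)         absent      11.1%         -
...
+LR = 43.0%   -LR = 57.0%   (mode: sum_present)
```

Read: dry cough is the strongest contributor (48 of the 279 symptom counts,
weight 48/279 ≈ 17.2%); the four present symptoms together account for
43.0% of the total weight, so the additive score for this presentation is
+LR 43.0%, −LR 57.0%. `relw weights symptoms.csv` prints the full weight
table (it sums to 100.0%), `relw enumerate symptoms.csv -o table.tsv`
streams all 2^15 = 32,768 profiles with their scores, and
`relw synth --n 15 --seed 7 -o synth.csv` generates a seeded synthetic
counting dataset. The same operations are available as library functions
(`relw.relative_weights`, `relw.score`, `relw.enumerate_profiles`, …).

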