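# dentage

Dental maturity scoring and age estimation toolkit.

Seven left mandibular permanent teeth (third molar excluded) are each rated
on the ordinal scale `0 < A < ... < H`. A sex-specific stage-weight table
turns the seven ratings into a maturity score on a 0–100 scale, and
interchangeable *population standards* — monotone (score, age) lookup tables,
linear models, or cubic polynomials — convert the score to a dental age.
The package also ships:

- the Saudi calibration prediction tables and the least-squares cubic
  models refit from them (`saudi_{male,female}_{table,cubic}`), plus
  schema-valid demo placeholders for other population standards;
- a statistical comparison pipeline: per-subject DA−CA under multiple
  standards, per-age-group summaries with paired t-tests, one-way ANOVA,
  Scheffé pairwise contrasts and SPSS-convention homogeneous subsets
  (harmonic-mean n for unequal groups);
- a synthetic-cohort generator (uniform ages within 1-year bins, monotone
  latent score plus Gaussian rating noise, greedy stage decomposition) with
  ground truth for end-to-end and parameter-recovery testing;
- two-session Cronbach's alpha for rater reliability.

The Demirjian sex-specific stage weights are not redistributed here; a
synthetic demo weight table with the same structural invariants ships
instead, and real weights can be supplied as JSON
(`{sex, provenance, weights: {tooth: {stage: number}}}`).

## CLI

```sh
dentage simulate --seed 1 --sigma 2.0 --out run/          # cohort.csv + truth.json
dentage score run/cohort.csv --out run/scores.csv         # adds maturity_score
dentage estimate run/scores.csv --standard saudi_male_table \
    --standard saudi_female_table --out run/estimates.csv
dentage fit --builtin saudi_male_table --sex male --degree 3 --out cubic.json
dentage table --model saudi_male_cubic --scores 30:98:1 --out table.json
dentage compare run/cohort.csv --standard saudi_male_table \
    --standard saudi_female_table --standard demo_kuwaiti_male \
    --standard demo_kuwaiti_female --out run/report/
```

Standards are referenced by builtin key (see `dentage.available_builtins()`)
or by path to a standard JSON document. Logs go to stderr; data to stdout or
files. Ages print to 5 decimals, summary statistics to 2.

Cohort CSV dialect:
`subject_id,sex,birth_date,exam_date,ca_years,I1,I2,C,PM1,PM2,M1,M2` with
ISO dates (`ca_years` may be left empty when both dates are present) and
single-character stage codes (`0`, `A`–`H`).

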