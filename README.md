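# chronopanel

Circadian epidemiology for household panel surveys: MCTQ chronotype
scoring, social jetlag, age/sex chronotype normalization, fasting-biomarker
preprocessing, and household-clustered mixed models — plus a seeded
synthetic cohort generator with planted effects so every stage of the
analysis can be validated by parameter recovery.

## Who this is for

Epidemiologists and chronobiologists analyzing sleep-timing questionnaires
(MCTQ-style) collected in household surveys, where participants are
clustered in households, biomarkers are assayed across multiple labs, and
the questions of interest are of the form *"is social jetlag associated
with cholesterol after adjusting for age, sex, BMI and disease burden?"*

## The quantities and models at the core

From each participant's workday/free-day bed and wake times the package
derives sleep durations (`SD_w`, `SD_f`, and the workday-weighted
`SD_week`), mid-sleep phases (`MSW`, `MSF`), the MCTQ chronotype

    MSF_sc = MSF − (SD_f − SD_week)/2        (when SD_f > SD_w)

and social jetlag `SJL = |MSF − MSW|` (circular difference). Chronotype is
age- and sex-normalized by sex-specific cubic fits anchored at age 30
(`MSF_sasc`), and the extreme-chronotype score is the absolute deviation
from the population median, `MAD_MSF_sasc`.

Biomarker outcomes are modeled with household random intercepts:

    y_ij = x_ij' β + u_j + ε_ij,   u_j ~ N(0, σ²_u),  ε_ij ~ N(0, σ²_ε)

with REML coefficients and Wald z tests, and likelihood-ratio chi-square
tests (ML refits) against null models without the main exposure. Rank
statistics (Mann–Whitney, Kruskal–Wallis + Dunn, partial Spearman,
paired Wilcoxon) and a cross-validated Fisher discriminant cover the
univariate and classification analyses. See `docs/methods.md` for the
full model descriptions and assumptions.

## Worked example

Simulate a default cohort (1600 participants in ~1000 households, with a
paired follow-up wave) and run the whole pipeline:

```python
from chronopanel.pipeline import run_pipeline

res = run_pipeline(simulate=True, seed=1)
exposures = res.suite_table.query("role == 'exposure'")
print(exposures[["outcome", "term", "coef", "se", "z", "p"]].round(4))
print("SJL median split at", round(res.sjl_split.threshold, 3), "h")
print(res.longitudinal.query("group == 'home_office'")[
    ["variable", "mean_diff_min", "p_value"]].round(3))
```

prints

```
outcome         term    coef     se       z      p
    CHL          SJL  0.1317 0.0313  4.2136 0.0000
    CHL       MSF_sc -0.0297 0.0294 -1.0082 0.3133
    LDL          SJL  0.0934 0.0297  3.1440 0.0017
    LDL       MSF_sc -0.0046 0.0279 -0.1655 0.8685
    HDL          SJL  0.0086 0.0084  1.0253 0.3052
    HDL MAD_MSF_sasc -0.0244 0.0131 -1.8699 0.0615
    TAG          SJL  0.0103 0.0227  0.4520 0.6513
    TAG MAD_MSF_sasc  0.0712 0.0351  2.0280 0.0426
    AIP          SJL -0.0117 0.0092 -1.2740 0.2027
    AIP MAD_MSF_sasc  0.0725 0.0142  5.1077 0.0000
SJL median split at 0.654 h
 variable  mean_diff_min  p_value
   MSF_sc         10.845      0.0
      SJL        -19.002      0.0
  SD_week         12.858      0.0
```

Reading this: each row is one fixed effect from one biomarker's
random-intercept model on this simulated cohort. The social-jetlag
coefficient on total cholesterol (0.13 mmol/L per hour of jetlag) and the
extreme-chronotype coefficients on HDL/TAG/AIP recover the effects the
generator planted, at the standard errors the cohort size supports; the
median split lands at ≈ 0.65 h; and the simulated home-office group shows
its planted two-wave shifts (chronotype +11 min, social jetlag −18.6 min,
sleep +12.6 min) within Monte-Carlo error. A single cohort fluctuates by
about one standard error; averaging over many seeds (see below) pins the
recovered coefficients to within a few percent of the planted values.

The same stages are available from the shell:

```sh
chronopanel simulate --seed 1 --out sim/
chronopanel score --input sim/cohort.csv --out scored.csv
chronopanel run-all --simulate --seed 1 --out results/
```

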