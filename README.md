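# pdcthresh

Adherence-threshold discovery for claims-based time-to-event cohorts.

The conventional cutoff for "good" medication adherence — a proportion of
days covered (PDC) of 0.80 — is a historical default, not an estimate. For a
new-user cohort with dispensation claims and time-to-event outcomes, this
package estimates the *outcome-specific* optimal PDC threshold and
adjudicates candidate thresholds by model fit. It is written for
pharmacoepidemiologists who have four flat claims tables (dispensations,
hospital stays, outcome/vital events, baseline covariates) and want an
auditable pipeline from raw rows to a threshold-comparison table, plus a
fully synthetic claims generator with known ground truth so every stage can
be validated without access to administrative data.

## What it computes

**PDC.** For patient *i* with observation window *W* (event-anchored for
event cases, patient-specific for losses, a fixed 1825-day window for
completers),

    PDC_i = |covered days in W outside hospital| / (|W| − |hospital days in W|),

where a day is covered if at least one fill's supply interval
`[dispense_day, dispense_day + days_supply)` spans it (`union` mode), or
with early-refill surplus pushed forward (`carryover` mode). Hospital days
drop out of numerator and denominator because in-hospital drug use is
invisible to pharmacy claims.

**Maximally selected log-rank (Contal–O'Quigley).** For each candidate
threshold *c* (grouping rule: poor adherence ⇔ PDC < *c*), the log-rank
numerator over ordered distinct event times *t₁ < … < t_D*:

    U(c) = Σ_i [ d_i^low − d_i · n_i^low / n_i ],

with the scan statistic `q = max_c |U(c)| / (s·√(D−1))` where
`s² = (1/(D−1)) Σ_{i=1}^{D} (1 − Σ_{j≤i} 1/(D−j+1))²`, an approximate
p-value `2·exp(−2q²)` (meaningful for q > 1), and the threshold estimate
`argmax_c |U(c)|`.

**ROC indices.** With Sn(c) = fraction of event subjects with PDC < c and
Sp(c) = fraction of non-event subjects with PDC ≥ c: Youden
`J = Sn + Sp − 1` (maximized) and the minimum distance to the perfect
corner `d = √[(1−Sn)² + (1−Sp)²]` (minimized).

**Threshold adjudication.** Adjusted Cox models with the exposure
1(PDC < c) at each method threshold plus bracketing alternates; models
compared by `AIC = −2·log PL + 2k` re-baselined against the minimum;
thresholds with ΔAIC < 4 are retained to define the threshold range, and
every row carries a Burnham–Anderson support category (ΔAIC ≤ 2
substantial, 4–7 considerably less, > 10 none).

## Worked example

```bash
python analysis/01_simulate.py      # synthetic cohort, n = 10,000, tau* = 0.50
python analysis/02_build_cohort.py  # new-user funnel
python analysis/03_compute_pdc.py
python analysis/04_estimate_cutpoints.py
python analysis/05_compare_thresholds.py
```

On the reference synthetic cohort (seed 1; true threshold 0.50, true hazard
ratio 2.0, ACS/stroke analysis with 352 events among 8,769 included
patients) the last two steps print:

```
ACS_STROKE CONTAL_OQUIGLEY  0.62   (q = 3.03)
ACS_STROKE YOUDEN           0.62   (J = 0.15)
ACS_STROKE MIN_DISTANCE     0.70   (d = 0.61)

threshold     hr   aic        delta_aic  support            provenance
     0.52  1.796   6295.769      6.451   considerably-less  alternate
     0.62  1.883   6289.317      0.000   substantial        contal_oquigley
     0.70  1.792   6294.023      4.706   considerably-less  min_distance
     0.80  1.544   6307.388     18.071   none               alternate
retained range (0.60, 0.67)
```

Read this as: the scan and Youden agree on a threshold, the comparison
table shows the hazard ratio attenuating as the dichotomization point moves
away from the AIC-best threshold (1.88 → 1.54 at 0.80), and the strict
ΔAIC < 4 rule brackets the estimate. Note the estimate sits above the true
0.50: with ~370 events the estimator is noisy, and PDC measured from claims
is a biased proxy for latent adherence — `analysis/07_replicate_experiments.py`
quantifies both effects across 20 replicate cohorts (median estimate 0.54,
mean HR 1.88 at the true threshold vs 1.59 when dichotomizing 0.3 too high,
null calibration P(p > 0.05) = 0.93). See `docs/methods.md`.

The same pipeline runs from a shell on any four CSV tables:

```bash
pdcthresh simulate --n 10000 --seed 1 --out data/
pdcthresh run --dispensations data/dispensations.csv --stays data/hospital_stays.csv \
    --outcomes data/outcomes.csv --patients data/patients.csv --out report/
```

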