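# Methods

## Scoring model

Both charts are declarative band tables: per parameter, a list of
(predicate → points) entries with points in {1, 2, 3}. Predicates are
closed numeric intervals (`a–b` means `[a, b]`), strict open bounds
(`<x`, `>x`), one closed bound (`≥7` for pain), a boolean flag (oxygen
supplementation) and AVPU-level membership. Three reading rules fix the
semantics everywhere:

1. **Maximum over matching bands.** The printed tables overlap at some
   boundaries (MEOWS systolic 150 and 160; heart rate 50/60, 120/130;
   pain 7). A value matching several bands takes the highest points —
   the safety-first reading of an escalation chart.
2. **Unlisted values score 0.** The tables print no 0-point column; any
   value matching no band scores 0. This is applied literally even
   inside discontinuities of the printed ladder (a heart rate of exactly
   40 or 130 under the general EWS, a temperature in [35.0, 35.1), a
   respiratory rate of exactly 30, a systolic pressure in [70, 71)).
   `validate_observation` surfaces such values as `band_gap` warnings —
   a gap is a bounded uncovered interval between covered regions other
   than the single widest one, which is taken to be the chart's implicit
   normal zone. The gaps are reported, never silently patched.
3. **Missing values score 0** and are counted in `n_missing`; there is
   no imputation (none is defined for bedside charts). An observation
   missing *every* parameter a system scores is rejected.

Values are compared at full floating precision; no rounding happens
before band lookup. Two open table-reading questions are resolved
literally: MEOWS heart-rate `50–60 → 2` includes 60, and the EWS
temperature row has no 3-point band (its column is printed empty), so
the EWS temperature score is bounded by 2.

The tables are data: they serialise to YAML and the packaged files
round-trip bit-exactly to the built-in constructors, so a site variant
chart can be dropped in without touching code. A vectorised scorer
(`score_table`) is used on whole cohort tables; the test suite pins it
to the per-observation scorer and both to an independently transcribed
brute-force oracle on a dense 0.1 grid.

## Triage and stay aggregation

MEOWS: red at total ≥ 7, yellow at total 5–6 *or* any single 3-point
value, green at total 1–4. Since the printed ladder starts at 1, a
score-0 observation belongs to a fourth stratum (`NONE`) below green;
folding it into green would be arithmetically incompatible with the
published green-row specificity. EWS: inform at total ≥ 2, emergency at
total ≥ 4 ("exceeds 3 points").

A woman's stay maps to her *worst* observation under each system. The
source study evaluates women (not observations) without stating the
aggregation; worst-over-stay matches screening semantics — one trigger
anywhere during monitoring is a positive — and is monotone: raising any
single observation's score can never lower the stay's stratum. The
acute-deterioration clinical override (not computable from vitals) is
exposed only as a manual `red_override` flag on the stay.

## Diagnostic accuracy

Each trigger definition against the morbidity label yields a 2×2 table.
The interval methods are a deliberate design choice (the source study
names none): Clopper–Pearson (exact beta-quantile) for sensitivity and
specificity; the standard-logit (Mercaldo prevalence-form) interval for
predictive values at the *sample* prevalence; the log method for
likelihood ratios; z = 1.96 throughout. This triplet reproduces the
published intervals within presentation rounding for every row whose
counts the printed values determine uniquely. No continuity corrections
are applied: zero-cell degeneracies (PPV = 1, FP = 0, FN = 0) return
flagged estimates with logical bounds instead of corrected ones, since
the emulated study has no zero cells in its trigger rows.

The canonical 2×2 counts were recovered by integer enumeration: with 24
morbid and 699 non-morbid women fixed, every (TP, FP) pair is scored and
compared, after presentation rounding, against the published strings.
The red row (14, 6, 10, 693) and the EWS ≥ 4 row (2, 6, 22, 693) are
uniquely determined including their intervals; the remaining rows are
fixed to the consistent solution in which the four MEOWS strata
partition the 699 non-morbid women as 6 + 259 + 294 + 140. The
enumeration is re-run in the test suite. One known residual: with the
green-row counts fixed by that partition, the log-method PLR upper bound
formats to 0.7 where the study prints 0.8 (neighbouring partitions
reproduce it, but are inconsistent with the other published cells); all
36 point estimates reproduce exactly.

Formatting follows the published convention: proportions as integer
percent, except estimates below 1% shown to one decimal; likelihood
ratios to one decimal, except values below 0.05 shown to two decimals;
half-up rounding; prevalence with one decimal. Rounding is
presentation-only — every computation and comparison runs unrounded.

## Synthetic cohorts

The generator emulates the *structure* of the validation cohort, not its
physiology:

* 723 women, observed every 4 h for 48 h (13 observations each). The
  morbid count is fixed at `round(n × prevalence)` = 24 and assigned to
  shuffled positions — the emulated cohort has a fixed composition, so
  the default prevalence is exactly 24/723 every run.
* Each woman draws a target worst-MEOWS stratum from her group's
  frequency table ((14, 8, 2, 0)/24 morbid; (6, 259, 294, 140)/699
  non-morbid) and a cause subtype (hypertensive 13/24, hemorrhage 8/24,
  pulmonary 2/24, anesthesia 1/24; non-morbid women use a generic
  profile).
* Baseline observations are clipped normals inside the MEOWS zero-score
  region. One uniformly chosen peak observation is *composed from the
  band table itself*: a set of (parameter → points) parts summing into
  the stratum's score window is drawn with subtype-weighted propensities
  (hypertensive → pressures, hemorrhage → tachycardia/hypotension/SpO₂,
  pulmonary → respiratory rate/SpO₂/oxygen, anesthesia → AVPU/pain), a
  concrete value is sampled from the exact-score region of each chosen
  band (regions are derived from the rule, so the sampler cannot drift
  out of sync with the table), values are rounded to chart precision,
  and the observation is verified by re-scoring with the real engine —
  a failed verification is rejected and redrawn. The realised stratum is
  therefore *exact*, making the generator unbiased for the configured
  MEOWS margins.
* The EWS stratum of a generated woman is whatever the EWS table yields.
  Only the MEOWS margins are calibrated; the published margins do not
  identify the joint MEOWS/EWS distribution. Profile weights are free
  calibration constants chosen once (benign deviations lean on pressures
  and pain, which the adult EWS largely ignores) so the generated EWS
  rates land near the published margins, but they are not enforced and
  the accuracy evaluation of EWS rows runs on the canonical counts.
* Covariates are split half-normal quantile draws matching the published
  per-group medians and quartiles (exact at the median and quartiles,
  clipped to plausible ranges), categorical mixtures at the published
  proportions, and discrete HDU-length distributions with the published
  medians (2 vs 3 days) and ranges.

What passing tests therefore show: the scoring, triage, aggregation and
accuracy code recovers configured operating characteristics from raw
vital-sign tables at study scale. What they cannot show: anything about
real vital-sign dynamics — the generator has no autocorrelated
deterioration trajectories, no treatment effects, no measurement error
model, and one deteriorated observation per stay. It is a structural
test harness, not a physiological simulator.

## Numerical and interface choices

* Determinism: one `numpy` Generator drives everything; a config plus a
  seed reproduces a cohort byte-for-byte in CSV form.
* Rejection budgets: 1000 attempts per peak observation (compositions
  are constructive, so rejections are rare); exhaustion raises instead
  of degrading.
* Scale choices in tests: the simulator round-trip runs 200 cohorts of
  723 women (seeds 1–200) and checks the mean red-or-yellow sensitivity
  and specificity within 3 Monte-Carlo standard errors of 22/24 and
  434/699; covariate calibration uses 10,000 draws per group within 5%
  of the published medians.
* CSV schema: one row per observation, fixed headers, AVPU as letters,
  booleans as 0/1, missing as empty cells, covariates constant within a
  woman; malformed rows are reported with 1-based file line numbers.
  CLI exit codes: 0 success, 2 schema/validation error, 3 degenerate
  estimates.

## Known limitations

* The NONE stratum and the worst-over-stay aggregation are reconstructions
  of unstated study choices; both are forced (arithmetically and
  semantically) but not documented in the source.
* Green-row PLR upper bound: see above.
* The generator's per-observation independence understates within-woman
  correlation; stay-level quantities are calibrated directly, so this
  mainly limits any per-observation reuse of the simulator.
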