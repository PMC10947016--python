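# Methods

## The model

`fibrescen` models a *composition-change* (reformulation) intervention on
dietary fibre intake. The intervention raises the fibre density of foods
made from white flour by 50% and of wholemeal foods by 20%, while leaving
what people eat completely unchanged. Because daily fibre intake is linear
in the fibre densities of the foods consumed, the effect on each person is
exact and closed-form:

    intake(d)   = (1/D) * sum_e amount_e * fibre(food_e) / 100
    delta       = sum_c (factor_c - 1) * contribution_c

where `D` is the number of diary days, the sum runs over a participant's
diary entries, `factor_c` is the scaling factor of food category `c`
(white_flour, wholemeal, other) and `contribution_c` is the baseline g/day
of fibre obtained from that category. `compute_intakes` reports baseline,
scenario intake, delta and the per-category decomposition, and the test
suite checks the identity to 1e-9.

Daily intake divides by the participant's *stated* diary days, not by
days with recorded consumption: a day with nothing recorded is a
zero-intake day, which matches the averaging convention of multi-day
dietary recalls.

Scaling is item-wholesale: a food categorised `white_flour` has its entire
fibre density scaled even if only part of the food is flour. A
`custom_factor` column in the category map overrides the category factor
per food when finer control is needed (e.g. composite dishes).

## Population summaries

The summary table follows the conventional dietary-survey presentation:
rows for Male and Female, then five age bands — Pre-school (1.5–3 y),
Junior School (4–10 y), Adolescents (11–18 y), Adults (19–65 y), Older
Adults (>65 y). Band labels use integer years; the implementation makes
them exhaustive and disjoint with half-open intervals [1.5, 4), [4, 11),
[11, 19), [19, 66), [66, ∞). Ages below 1.5 y are out of scope.

Per group and diet (current / scenario) we report the weighted mean intake
with a design-based standard error

    se = sqrt( sum w_i^2 (x_i - x_bar_w)^2 ) / sum w_i

(which reduces to the population-SD/√n for unit weights), and the weighted
percentage of members whose intake is at or above their age's recommended
intake, with the binomial-style error

    se_pct = 100 * sqrt( p (1 - p) * sum w_i^2 ) / sum w_i.

Neither estimator corrects for the clustering or stratification of a
complex survey design; with genuine survey data these SEs understate
design effects. Weighting is off by default (`--weighted` turns it on)
because published survey tables do not always state whether weights were
applied.

Ties count as reaching the recommendation (`x >= threshold`). The default
recommendation schedule is 30 g/day from age 16 (the UK adult dietary
reference value) with SACN-style child bands: 15 g (1.5–5 y, the 2–5 y
recommendation extended down to cover the youngest surveyed ages), 20 g
(5–11 y), 25 g (11–16 y). All thresholds are overridable via a YAML
schedule, since published child thresholds vary between analyses.

The fibre column is treated as AOAC total dietary fibre — the basis of
the 30 g/day recommendation. Nothing in the arithmetic depends on the
assay; users of Englyst/NSP values should supply a matching schedule.

## Synthetic survey generator

UK dietary-survey microdata (multi-day individual recalls matched to a
national food composition table) are access-controlled, so the package
generates synthetic populations with the structure the pipeline assumes.
Per sex × age-band stratum, each participant draws

* a total daily fibre intake `T ~ Gamma(mean, sd)` — strictly positive
  and right-skewed like real intake distributions (log-normal would also
  be defensible; Gamma was chosen for its simple mean/SD
  parameterisation and is swappable);
* category shares `s ~ Dirichlet(alpha)`, so the white/wholemeal/other
  split varies between people around `alpha / sum(alpha)`;
* a survey weight from a Gamma with CV 0.2 around the stratum's weight
  mean (positive, mildly dispersed).

Diary entries then *exactly realise* the drawn intake: the fibre from
each category is split evenly over that category's foods and all diary
days, with gram amounts chosen to invert the intake computation. This
makes the closed-form stratum-level expected scenario effect

    E[delta] = intake_mean * sum_c E[share_c] * (factor_c - 1)

available (`expected_delta`) for parameter-recovery tests, which check
recovery at n = 10 000 within 3 Monte-Carlo standard errors.

Default problem sizes: the bundled default population has 3558
participants in 10 strata with 4-day diaries and 2 foods per category
(~85 000 diary entries); the parameter-recovery check uses a single
10 000-participant stratum. Both run in seconds.

Defaults emulate a UK-survey-like population:

* stratum sizes and intake means follow published sex margins
  (n = 1636 males at 19.7 g/day, 1922 females at 17.2 g/day) and
  age-band margins (10.4–19.7 g/day);
* stratum SDs are back-calculated from published band standard errors
  (SE·√n);
* expected category shares put ~10% of fibre intake on white-flour foods
  (white bread alone supplies about 8–10% in UK adults) and less on
  wholemeal, with Dirichlet concentration 30 (share SDs of a few
  percentage points). These share distributions are **illustrative**, not
  estimated from microdata;
* fibre densities are uniform per category: white 1.0–4.0 g/100 g
  (anchored on the ~4% dry-weight fibre content of white flour),
  wholemeal 5.0–9.0, other 0.5–8.0.

One reconciliation choice deserves note: the published sex margins and
age-band margins imply *different* overall means (18.4 vs 17.0 g/day), so
no equal-weight population can match both, presumably because the source
estimates were survey-weighted. The default configuration reproduces the
age-band margins and applies a multiplicative sex adjustment that
preserves the published male:female ratio; sex-level means therefore come
out ~1.5 g/day below the published sex margins. Parameter-recovery tests
compare against the *configured* values, never against published ones.

What passing tests show: that the pipeline arithmetic, estimators and
generator are mutually consistent and deterministic. What they do not
show: agreement with results computed on real microdata, which depend on
the actual food-item list, real share distributions, survey weighting and
design-corrected errors. The adapter recipe for real data is in
`ndns_adapter.md`.

## Flour composition model

White-flour fibre is modelled as five components — arabinoxylan (AX),
β-glucan, fructans, cellulose, arabinogalactan peptide (AGP) — each with
a content (% dry weight) and a water-soluble fraction. Literature values
are often ranges, so every quantity is an `Interval` (lo, hi, optional
reported central value) evaluated at a selectable point (`lo | mid | hi`,
default `mid`; `mid` returns the reported central value when one exists).
Defaults: AX 1.9 (1.35–2.75) with solubility 25–50%, β-glucan 0.2 (30%
soluble), fructans 1.5–1.7 (fully soluble), cellulose <0.1 (insoluble,
stored as 0–0.1), AGP 0.3 (fully soluble). Resistant starch (~1% DM in
white bread) is excluded from the component totals.

`total_fibre` sums the components (≈4% dw at defaults); `soluble_fraction`
computes the soluble share of total fibre. Evaluated at the AX-solubility
bounds, the default profile brackets 60–72% soluble. The corresponding
published range is 56–69%; the exact arithmetic behind that printed range
is not derivable from the printed component values under obvious
assumptions, so the package reports its own computed bracket and records
the discrepancy rather than forcing agreement.

`apply_ax_scenario` substitutes the AX content (e.g. 2% → 4% dw, lifting
the total from 4% to 6%); the total changes by exactly the substitution.
`water_absorption` applies the linear coefficients 10 g water/g insoluble
AX and 11 g/g soluble AX.

## Numerical and design choices

* All randomness flows through one `numpy.random.default_rng(seed)`
  stream; identical configs give byte-identical CSV outputs (floats are
  written with shortest round-trip repr).
* Decomposition/conservation identities are asserted at 1e-9 absolute
  tolerance; Monte-Carlo checks use 3 standard errors.
* Degenerate inputs: empty datasets are valid (empty summaries); a group
  with no members yields an n = 0 row with missing statistics and a
  warning; `diary_days = 0` and non-positive weights are rejected.
* Validation reports violations as data (record, rule, message) rather
  than raising, so callers can triage; the loader raises on any
  violation.

## Known limitations

* No behaviour-change scenarios (e.g. swapping white for wholemeal
  bread): composition changes only.
* No recipe disaggregation: foods are scaled wholesale by category.
* SEs are not design-corrected for clustered, stratified samples.
* The generator does not mimic real food coding, under-reporting
  adjustments, or day-of-week structure.
* Only fibre is modelled; no other nutrient travels through the pipeline.
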