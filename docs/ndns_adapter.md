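# Running the pipeline on real survey microdata

The population results that motivate this package were computed on UK
National Diet and Nutrition Survey (NDNS) rolling-programme microdata
(rounds 9–11, n = 3558), which are access-controlled (UK Data Service,
study SN 6533) and cannot be redistributed here. This note describes how
to export those data — or any comparable multi-day diary survey — into
the package's four-CSV schema.

## 1. Obtain the data

Register with the UK Data Service and download study SN 6533 (NDNS RP).
You need the individual-level files covering: person characteristics
(sex, age, survey weight), the food-level diary (person, day, food code,
amount consumed), and the nutrient databank giving fibre per 100 g for
each food code.

## 2. Export to the input schema

Create four UTF-8, comma-separated files with header rows:

| file | columns |
|---|---|
| `participants.csv` | `participant_id,sex,age_years,survey_weight,diary_days` |
| `entries.csv` | `participant_id,day_index,food_code,amount_g` |
| `foods.csv` | `food_code,description,fibre_g_per_100g` |
| `category_map.csv` | `food_code,category[,custom_factor]` |

Notes:

* `sex` is `male`/`female`; `day_index` runs 1..`diary_days`.
* `fibre_g_per_100g` should be AOAC total dietary fibre (the basis of
  the 30 g/day recommendation). NDNS also reports Englyst NSP — do not
  mix the two, and adjust the recommendation schedule if you use NSP.
* `category` is one of `white_flour`, `wholemeal`, `other`. This file is
  the analysis's item list: every food whose composition the scenario
  should scale must be categorised (uncategorised foods default to
  `other`, i.e. unscaled). Building this list is the substantive
  curation step; the published analysis used a dedicated list of
  manipulated food items, which accompanies the source article as
  supplementary material.
* Use `custom_factor` for foods that should scale by an item-specific
  factor instead of the category factor.

## 3. Run

```sh
cat > run.yaml <<EOF
participants: participants.csv
entries: entries.csv
foods: foods.csv
category_map: category_map.csv
EOF
fibrescen run --config run.yaml --weighted --out results/
```

`--weighted` applies the survey weights to means and percentages. The
reported SEs are *not* design-corrected; for publication-grade errors,
re-estimate them with a survey package (e.g. R `survey`) from the
per-person intakes in `results/intakes.csv`, which carry everything
needed (baseline, scenario, delta, category contributions).

## 4. What to expect

With the real item list and microdata, the current/higher-fibre summary
in `results/summary.txt` is directly comparable to published NDNS-based
scenario tables. Synthetic data bundled with this package reproduce the
*structure* of that analysis, not its numbers.
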