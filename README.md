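# hhdiet

Analysis pipeline for household nutrition surveys: convert 24-h household
food records to per-adult-female-equivalent (AFE) intakes, derive dietary
patterns by principal component analysis of 18 food-group intakes, score
nutrient adequacy (probability of adequacy / MPA) and women's minimum
dietary diversity (MDD-W), attach greenhouse-gas and blue-water footprints,
and report every outcome by pattern-adherence quintile.

Because the survey data this kind of analysis targets is typically
proprietary, the package ships a synthetic-survey generator with planted
latent dietary patterns (`hhdiet.simulate`), so every stage is testable
against known ground truth.

## Pipeline stages

| stage | module | CLI |
|-------|--------|-----|
| table I/O and validation | `hhdiet.io` | (used by all commands) |
| synthetic survey | `hhdiet.simulate` | `hhdiet simulate` |
| AFE conversion | `hhdiet.afe` | `hhdiet convert` |
| dietary patterns (PCA) | `hhdiet.patterns` | `hhdiet patterns` |
| diet quality (PA/MPA, MDD-W) | `hhdiet.quality` | `hhdiet quality` |
| GHGE / blue-water footprints | `hhdiet.footprint` | `hhdiet footprint` |
| quintile tables and trend tests | `hhdiet.reporting` | `hhdiet report` |
| orchestration + manifest | `hhdiet.pipeline` | `hhdiet run-all` |

## Quick start

End-to-end on simulated data (deterministic under `--seed`):

```bash
hhdiet run-all --simulate --n 2000 --seed 1 --out out/
```

This writes the synthetic inputs under `out/inputs/`, then `per_afe.csv`,
`loadings.csv`, `scores.csv`, `quintiles.csv`, `scree.csv`, `quality.csv`,
`footprint_results.csv`, contribution tables, the three report tables, and a
`manifest.json` with config and file digests. Rerunning with the same seed
reproduces every file bit-identically (`run.log`, which holds wall-clock
timings, is the one exception).

Stage by stage:

```bash
hhdiet simulate --out data/ --seed 1 --n 2000
hhdiet convert  --in data/ --out work/
hhdiet patterns --in work/per_afe.csv --k 3 --out work/patterns/
hhdiet quality  --in work/per_afe.csv --items work/per_afe_items.csv \
                --groupmap data/groupmap.csv --out work/quality.csv
hhdiet footprint --in work/per_afe.csv --items work/per_afe_items.csv \
                 --factors data/footprint.csv --groupmap data/groupmap.csv \
                 --out work/footprint.csv
hhdiet report   --quality work/quality.csv --footprint work/footprint.csv \
                --quintiles work/patterns/quintiles.csv --out work/report/
```

## Input formats

All tables are UTF-8 CSV with a single header row (schemas in
`hhdiet/io.py`):

- `roster.csv` — one row per household member: `household_id, member_id,
  age, sex, activity_level, region, wealth_quintile`
- `consumption.csv` — long 24-h log: `household_id, item_code, grams_raw`
  (raw, uncooked grams per day for the whole household)
- `fct.csv` — food composition per 100 g, including per-nutrient retention
  factors (`ret_<nutrient>`, multiplicative, in [0,1])
- `groupmap.csv` — item → one of 18 pattern groups and optionally one of
  the 10 MDD-W groups
- `footprint.csv` — per-kg GHGE and blue-water factors. When building a
  factor table from a source that reports ranges, use the highest value of
  the range. The blue-water field must be *empty* (not 0) for items in the
  condiments, sweet-foods and alcohol groups: these groups are excluded
  from water-use accounting.

Requirement parameters (EAR/CV per nutrient, the iron absorbed-requirement
distribution at 5% bioavailability, the 1,000 mg calcium adequate intake)
and the energy-requirement table (reference: female 19–30 y, moderate
activity, 2,200 kcal = 1 AFE) are configurable via YAML; documented defaults
live in `hhdiet/config.py`.

## Method notes

- Intakes are standardized to 2,000 kcal (nutrient-density scaling) before
  computing each probability of adequacy; MPA is the unweighted mean of the
  per-nutrient PAs, flagged low below 0.5.
- PCA runs on the correlation matrix; loadings are variable–component
  correlations, scores are standardized, and component signs are fixed
  deterministically. Retention defaults to the eigenvalue > 1 rule but is a
  user decision informed by `scree_report`.
- Footprint standardization per 2,000 kcal is applied per household before
  any averaging (mean of ratios, never ratio of means).
- The quintile trend test is OLS on the quintile index; the homogeneity test
  is the unstratified Cochran–Mantel–Haenszel general-association statistic.

A fully hand-computed 3-household worked example is documented in
`docs/worked_example.md` and asserted by the unit tests.

## Acceptance

Acceptance is property-based (PA oracle equivalence, boundary exactness,
AFE conservation, planted-pattern recovery, quintile balance, footprint
conservation/exclusion, null calibration of the tests, end-to-end
determinism); see `tests/test_acceptance.py`. The acceptance report script
runs the pipeline end-to-end and writes the (empty) numeric target map:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```
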