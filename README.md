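# headconc

Lexicon-based headline concreteness scoring and a moderated meta-analysis
pipeline for headline A/B-test archives.

The package has three layers:

1. **Scoring** (`lexicon`, `ner`, `morphology`, `scorer`) — maps each
   headline to a continuous concreteness value on the 0–5 scale: person /
   place / organization entities are pinned at 5, stopwords are removed
   (keeping forward references like *this*/*these* and personal pronouns),
   punctuation and cardinal numbers are ignored, and remaining tokens are
   resolved against a word-concreteness lexicon with rule-based
   singular / present-tense / base-adjective / hyphen-split fallbacks.
   Headlines containing an unresolvable word of three or more letters are
   excluded rather than scored.
2. **Analysis** (`abtest_prep`, `glmm`, `moderation`, `rater_validation`) —
   splits archive tests by image into validly comparable headline sets,
   standardizes concreteness (group-mean centering, two-SD scaling), fits a
   binomial random-intercepts/random-slopes multilevel model with a
   cross-level interaction via a Laplace-approximated marginal likelihood
   (pure NumPy/SciPy; agrees with `lme4::glmer` to ~4 decimals), and runs
   simple-slopes tests, Holm correction, and the Johnson–Neyman
   significance region.  Rater-validation utilities provide rater QC,
   one-way random-effects ICCs for incomplete designs, and stratified
   sampling.
3. **Simulation** (`synth`) — generates synthetic archives with known
   ground truth (headlines are synthetic token strings whose scorer output
   equals the assigned concreteness), plus parameter-recovery and power
   harnesses.

The default entity tagger is a deterministic rule/gazetteer backend with no
model download, so results are reproducible offline; alternative backends
can be registered via `headconc.ner.register_backend`.

## CLI

```bash
headconc simulate --out sim/ --seed 1 --n-tests 500      # synthetic archive
headconc score --lexicon sim/lexicon.csv --in sim/archive.csv --out scored.csv
headconc prep  --archive sim/archive.csv --lexicon sim/lexicon.csv --out analysis.csv
headconc fit   --data analysis.csv --out fit.json
headconc slopes --fit fit.json --at 2.06,3.08,4.41
headconc jn     --fit fit.json --data analysis.csv --crit 1.96
headconc power  --grid 500,1000,2000,3500 --replicates 50
headconc run    --config config.yaml --out report.json   # full pipeline
headconc validate-raters --ratings ratings.csv --scores scores.csv --out v.json
```

`run` expects a YAML config with at least `lexicon:` and `archive:` paths;
every report embeds the seed and a config hash.

## Data formats

- **Lexicon**: delimited text with `Word` and `Conc.M` columns (names
  configurable); ratings must lie in [0, 5].
- **Archive**: CSV with `clickability_test_id, headline, eyecatcher_id,
  impressions, clicks` (names configurable via `abtest_prep.ColumnMap`).
- **Ratings**: long CSV with `rater_id, headline_id, item_class
  (calibration|attention_check|main), rating`, optional `dont_understand`.
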