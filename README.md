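# pupilmem

Pupillometry analysis pipeline for auditory event-boundary paradigms:
preprocessing of continuous pupil recordings, tone-evoked dilation contrasts,
temporal PCA of condition-averaged pupil waveforms with Kaiser-normalized
Varimax rotation, scoring of temporal-order / temporal-distance / source
memory tests, and participant-level pupil–memory linkage via subtraction-score
Spearman correlations — plus a synthetic-data generator with known ground
truth for parameter-recovery testing.

## Layout

| module | role |
| --- | --- |
| `pupilmem.config` | `AnalysisConfig` / `SimulationConfig` (validated dataclasses, YAML-loadable) |
| `pupilmem.dataio` | canonical TSV schemas, readers/writers, `PupilRecording`, condition labelling |
| `pupilmem.synth` | task-design, pupil-trace and memory-outcome generators with `GroundTruth`; numeric-integration oracles for planted effects |
| `pupilmem.preprocess` | artifact detection, linear interpolation, block exclusion, epoching, baseline correction |
| `pupilmem.evoked` | evoked-window dilation, paired and one-sample contrasts |
| `pupilmem.decompose` | covariance-metric temporal PCA, retention rules, Varimax rotation, regression scores, condition-split / short-window variants |
| `pupilmem.behavior` | memory-test scoring, rm-ANOVA (+ multivariate variant), Bonferroni pairwise comparisons |
| `pupilmem.linkage` | Spearman machinery, subtraction scores, trial-level mixed models (logistic GH-ML / linear REML), pitch-change and pupil-stability analyses |
| `pupilmem.pipeline` | orchestration and on-disk result bundle |
| `pupilmem.cli` | `pupilmem` command-line interface |

## CLI

```sh
# generate a synthetic dataset (TSVs + ground_truth.json)
pupilmem simulate --seed 1 --out-dir data/
# individual stages
pupilmem preprocess   --samples data/samples.tsv --events data/events.tsv --out-dir out/
pupilmem decompose    --samples data/samples.tsv --events data/events.tsv --out-dir out/
pupilmem score-memory --pairs data/pairs.tsv --items data/items.tsv --out-dir out/
pupilmem link         --scores out/scores.tsv --pairs data/pairs.tsv --items data/items.tsv --out-dir out/
# everything at once
pupilmem run-all --samples data/samples.tsv --events data/events.tsv \
    --pairs data/pairs.tsv --items data/items.tsv --out-dir out/
```

`--config` accepts a YAML key/value file mirroring the relevant config
dataclass; `--seed` overrides the config seed. Logs go to stderr.

### Canonical formats (tab-separated, with headers)

* samples: `participant block time_ms pupil valid`
* events: `participant block onset_ms event_type list_index event_index
  position_in_event tone_condition frequency_hz ear item_id`
* behavior pairs: `participant block item_a item_b pair_condition lag
  order_correct distance_rating`; items: `participant block item_id item_type
  source_correct`

Vendor eye-tracker formats are out of scope; convert upstream. Input files
are expected to contain only analyzed lists (no practice list).

## Notes

* Epoch windows are half-open `[a, b)` in integer ms, so a 3000 ms window at
  250 Hz is exactly 750 samples.
* The 130-row waveform matrix is built by trial-averaging within participant
  × condition (65 participants × 2 conditions) — the only reading of the
  source description consistent with "130 variables".
* Component retention defaults to the covariance-metric Kaiser analogue
  (eigenvalue ≥ trace/n_timepoints); the correlation-metric `>1` rule is
  available as `retention_rule="unit_eigenvalue"`.
* Mixed-model structure in the linkage analyses (random intercepts; logistic
  link for binary outcomes) is a documented reconstruction and is labelled as
  such in the output summaries.
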