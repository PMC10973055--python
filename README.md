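# splitaudit

Audit train/validation/test splits of frame-wise surgical workflow
annotations.

Machine-learning datasets for surgical phase and instrument recognition are
heavily imbalanced: phases differ in length by orders of magnitude, some
phases are optional or re-occur, and instrument usage is correlated with the
phase. When whole surgeries are assigned to train/val/test sets, rare
attributes — a particular phase transition, an instrument, or an exact
combination of simultaneously visible instruments — can end up entirely
missing from one set, silently distorting model evaluation.

`splitaudit` derives these attributes from frame-wise annotations,
aggregates them per split set, flags every attribute that is unrepresented
in a non-empty set, supports re-assigning surgeries between sets (with a
before/after diff), greedily repairs splits, and renders static phase /
instrument / supplementary views.

## Features

- **Annotation IO** (`splitaudit.io_annotations`): phase TSVs (one label per
  frame, optional header) and binary instrument TSVs (header-mapped 0/1
  columns), stride-based downsampling to align the two streams (e.g. 25 fps
  phases against 1 fps tools), idle-phase exclusion that merges the
  surrounding runs, and length-mismatch truncation with logging.
- **Phase statistics** (`splitaudit.workflow_stats`): per-set phase frame
  counts, run-length-encoded phase transitions with START/END sentinels and
  forward/backward classification, per-phase instrument counts, durations.
- **Instrument statistics** (`splitaudit.instrument_stats`): individual
  occurrence, idle frames, and exact-set instrument combinations (a frame
  showing {A,B,C} counts toward {A,B,C} only; a `subset` semantics switch is
  available for superset-style counting).
- **Split auditing** (`splitaudit.split_audit`): unrepresented-attribute
  flags, a per-kind x per-set summary matrix (sentinel transitions in their
  own sub-row), per-set totals, pure re-assignment with diff, and a
  deterministic greedy hill-climber over surgery swaps.
- **Synthetic data** (`splitaudit.synthetic`): a seeded workflow generator
  (geometric run lengths, phase-conditioned or pool-based instrument draws,
  skip/repeat quirks) that reports its exact ground-truth attribute
  inventory, plus `plant_unrepresented` for closed-loop audit testing and a
  fixture writer that round-trips through the readers.
- **Rendering** (`splitaudit.report_viz`): static arc-diagram phase view,
  radial instrument/co-occurrence view with seeded force-directed node
  layout, supplementary totals/duration view, and JSON/Markdown/CSV report
  writers. Renderers are split into testable layout-model builders and thin
  matplotlib drawing code.

## CLI

Every command reads a dataset config (YAML/JSON) that declares the phase
vocabulary in conceptual order, the instrument vocabulary, frame rates, the
split, and where the annotation files live:

```yaml
name: mydataset
phases: [Preparation, Dissection, Retraction]
instruments: [Grasper, Hook]
phase_fps: 25
instrument_fps: 1
idle_phase_label: null
split:
  train: [video01, video02]
  val: []
  test: [video03]
annotations:
  dir: .                    # relative to this file
  phase_suffix: "-phase.txt"
  instrument_suffix: "-tool.txt"
```

```sh
# generate a synthetic fixture dataset (writes annotations + config.yaml)
splitaudit simulate --out data/ --seed 1

# audit the configured split
splitaudit audit --config data/config.yaml --out report.json
splitaudit audit --config data/config.yaml --out report.md --format markdown

# what-if: move surgeries between sets and diff the audits
splitaudit diff --config data/config.yaml --moves moves.yaml

# greedy repair (size-preserving swaps)
splitaudit improve --config data/config.yaml --keep-sizes --max-iter 20

# static views
splitaudit plot --config data/config.yaml --view phase --out phase.svg
splitaudit plot --config data/config.yaml --view instruments --normalize-bars --out tools.svg
splitaudit plot --config data/config.yaml --view summary --out summary.svg
```

`moves.yaml` is a list of `{surgery: id, to: train|val|test}` entries. The
`plot` command accepts `--filter-phase`, `--filter-transition src,tgt`,
`--filter-instrument` and `--filter-combination A+B` to recompute the
aggregates on a filtered frame subset before rendering — the batch
equivalent of linked-view filtering.

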