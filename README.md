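# hedlite

Hierarchical event-descriptor (HED-style) annotation machinery for BIDS
event files, built around a self-contained mini vocabulary schema and the
Wakeman–Henson (W-H) face-perception design as a worked example.

The package provides:

* **schema** — a rooted forest of uniquely named vocabulary terms with
  case-insensitive lookup, short↔long form expansion
  (`Circle` ↔ `Item/Object/Geometric-object/2D-shape/Ellipse/Circle`) and
  subsumption queries. A plain-text mini-schema with 7 root nodes is
  packaged as a fixture.
* **strings** — parser/serializer for annotation strings (comma-separated
  tags with nested parenthesized groups), order-insensitive structural
  equality, and generalization search.
* **definitions** — named annotation concepts: `(Definition/Name, ...)`
  collection and linting, `Def/Name` references, `(Def-expand/Name, ...)`
  expansion with `#` parameter substitution.
* **bids** — `...events.tsv` / `...events.json` reading and writing,
  sidecar inheritance merging, categorical vs. value column
  classification, per-row HED string assembly, and whole-dataset
  validation producing lint-style issues.
* **temporal** — resolution of `(Def/X, Onset)` / `(Def/X, Offset)`
  groups into event processes with durations, and `Event-context`
  insertion for events inside ongoing processes.
* **design** — extraction of condition variables (factors and levels)
  from definitions carrying `Condition-variable`, per-event design-matrix
  assignment for both column- and row-encoded conditions, and summaries.
* **restructure** — unfolding by-trial event tables (one row per trial
  with embedded durations/delays) into one-marker-per-line tables, driven
  by an explicit user-supplied mapping spec.
* **simulate** — a synthetic W-H-style session/dataset generator: 6 runs,
  140–150 face presentations per run, every face shown exactly twice,
  immediate (lag 1) vs. delayed (lag 5–15) repeats, exactly balanced
  face-sex inventory, counterbalanced key assignment across participants.

## CLI

```sh
hedlite schema-info                       # root/node counts, uniqueness
hedlite expand --form long "Circle"       # short <-> long form
hedlite search --query 2D-shape "Circle, Image"
hedlite defs sidecar_events.json --validate
hedlite simulate --out ds --participants 19 --seed 1
hedlite validate ds                       # exit non-zero on issues
hedlite assemble ds --expand-defs
hedlite temporal ds --durations           # resolved event processes (TSV)
hedlite design ds                         # factor summary + design matrix
hedlite explode by_trial_events.tsv --spec trial_spec.yaml
```

## Packaged fixtures (`src/hedlite/data/`)

* `mini_schema.txt` — the mini vocabulary (7 roots, 85 terms).
* `task-FacePerception_events.json` — reconstructed dataset-level sidecar
  with column annotations and the definition pool.
* `wh_excerpt_events.tsv` — the 8-row worked-example events excerpt.
* `wh_fmri_by_trial_events.tsv` + `wh_fmri_trial_spec.yaml` — a by-trial
  fMRI excerpt and the mapping that unfolds it.
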