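# fishsurvey

Programmatic surveys of digitized natural-history fish collections from
aggregated Darwin Core occurrence data.

Natural-history aggregators publish collections data as *recordsets* that
rarely map onto institutional collections: one grant-funded recordset may mix
fishes with amphibians, one collection may be split across adult / juvenile /
larval / egg recordsets, and institution codes are reported inconsistently.
`fishsurvey` is for collection managers, biodiversity informaticians and
curators who want reproducible digitization metrics out of that mess: which
collections are fish collections, how many lots and individual specimens they
hold, their type material, georeferencing and preparation coverage, and how
holdings have grown since a historical survey.

## The method in brief

* **Discovery** uses two complementary flags and takes their union:
  case-insensitive metadata keywords ("fish", "ichthy") over recordset
  title/description/publisher, and an indicator taxon — records with
  `family = Centrarchidae`, a family assumed present in every U.S. fish
  collection — aggregated by (collectionCode, institutionCode, recordset).
  Flagged recordsets are reconciled against a registry of standardized
  symbolic codes (exact code, then aliases), with declarative merge rules for
  split collections. A fish collection is non-fossilized, preserved material
  with locality data and/or tissues; decoys are dropped with logged reasons.
* **Validation** builds a dictionary of `dwc:family` values from collections
  at or above the 80th percentile on record count, family cardinality and
  type holdings jointly, then drops records whose family is blocklisted
  (non-fish vertebrates) or beyond Damerau-Levenshtein distance 2 from every
  dictionary entry — keeping misspelled fish records while removing true
  contaminants. Verbatim taxonomy is never "corrected".
* **Normalization** lumps free-text `dwc:preparations` into canonical
  categories via an editable synonym grammar and extracts embedded counts
  (`"EtOH -15, Skeleton—1"` → ethanol 15 + skeleton 1 = 16 individuals).
  Lot counts resolve by strict precedence: usable `dwc:individualCount`
  (placeholders such as 9999 treated as absent) → preparations total →
  default of one individual.
* **Summaries** report per-collection lots, specimens, types, verbatim name
  cardinalities, geopoint and country percentages and preparation/media
  tallies; **comparison** joins a historical baseline on registry code and
  reports deltas and percent growth (negative deltas flagged, unmatched
  collections listed, never dropped).

A deterministic synthetic-recordset generator plants all of these
pathologies with a ground-truth manifest, so the full pipeline is testable
offline. See `docs/methods.md` for the model, parameters and limitations.

## Worked example

Generate a small synthetic world (4 collections, 500 fish lots each, with
contaminated and decoy recordsets), run the pipeline, and print the report:

```sh
fishsurvey simulate --seed 42 --out-dir sim --collections 4 \
    --records-per-collection 500 --recordsets 9
fishsurvey run --occurrences sim/occurrences.csv --catalog sim/catalog.csv \
    --registry sim/registry.csv --merge-rules sim/merge_rules.json \
    --baseline sim/baseline.csv --out-dir run
fishsurvey report --run-dir run
```

```
4 collections; 1977 records, 23877 specimens (mean 12.1/record) -> run
collections: 4
n_mediarecords: 125
n_primary_types: 10
n_records: 1977
n_records_cleared_stained: 73
n_records_media_in_preps: 16
n_records_skeletal: 116
n_records_tissue: 185
n_secondary_types: 44
n_specimens: 23877
n_unique_families: 621
n_unique_species: 1723
mean_specimens_per_record: 12.1
pct_geopoint: 57.7
top countries: US 65.3%, AU 13.8%, CA 11.3%, MX 3.6%, PH 2.7%
```

Reading this: the five decoy/contaminant recordsets were rejected or
filtered (only the 4 planted collections survive); 1,977 of the 2,000
planted lots remain after per-record fossil exclusion; 23,877 individual
specimens were synthesized from counts and preparation strings (mean 12.1
per lot); 621 unique verbatim family entries include planted misspellings,
which are counted as published, not corrected. Every number equals the
generator's ground-truth manifest — that equality is asserted by the test
suite.

The run directory also holds `checklist.csv` (reconciled identities),
`validated.csv`, `normalized.csv`, `collection_summaries.csv`,
`aggregate_summary.json`, `registry_coverage.csv`, `comparison.json`, and
one JSON log per stage.

## Acceptance script

`scripts/acceptance.py` re-runs the package's main computation from scratch
— it generates a seeded synthetic bundle, executes the full pipeline over
it, and evaluates the preparation-parser worked example — then writes the
measured values as JSON:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

## Library use

```python
from fishsurvey import parse_preparations

parse = parse_preparations("EtOH -15, Skeleton—1")
parse.category_counts   # {'ethanol': 15, 'skeleton': 1}
parse.total_individuals # 16
```

Every pipeline stage is an importable function (`flag_by_metadata`,
`reconcile`, `build_dictionary`, `filter_records`, `resolve_count`,
`summarize_collection`, `compare_surveys`, ...); the CLI is a thin wrapper
over these.
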