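# Methods

## Problem and approach

Biodiversity aggregators publish occurrence data in *recordsets* — units of
publication that rarely map one-to-one onto institutional collections. A
recordset may hold part of a collection, several collections, or a taxonomic
mixture digitized under one grant. `fishsurvey` re-creates, as a reusable
offline pipeline, the programmatic survey workflow for one discipline (U.S.
fish collections): find the fish collections inside that heterogeneity,
clean the records without altering verbatim taxonomy, and report the
digitization metrics a collection manager or funder would ask for.

The pipeline runs five stages:

1. **discover** — two complementary flags, then reconciliation;
2. **validate** — a family dictionary built from high-quality collections
   filters erroneous records;
3. **normalize** — preparation strings are lumped into canonical categories
   and per-lot individual counts are synthesized;
4. **summarize** — per-collection and aggregate metric vectors;
5. **compare** — deltas and growth against a historical baseline table.

## Discovery

Two flags are deliberately crude and complementary:

* **Metadata keywords** ("fish", "ichthy") matched as case-insensitive
  substrings over title, description and publisher. False positives
  ("Catfish Survey") are tolerated; the later fish-collection definition and
  family filter remove them. Institution codes are never used for discovery:
  they are not specific to fish collections.
* **Indicator taxon**: records of a family assumed present in every fish
  collection (default Centrarchidae, the North American sunfishes),
  aggregated by (collection code, institution code, recordset id).

Neither alone suffices — a sub-recordset of eggs may contain no sunfish but a
keyworded title, and a tersely-titled recordset may be found only through its
specimens — so the union is taken.

Flagged recordsets are folded into collection identities: declarative merge
rules first (for the one-collection-many-recordsets case, e.g. adult /
juvenile / larval / egg sub-collections), then by each recordset's *modal*
(institution, collection) code pair — providers report codes inconsistently,
so the most frequent case-folded pair is used — then one identity per
code-less recordset. Registry reconciliation tries an exact symbolic-code
match (collection code before institution code), then known aliases; an
alias matching two registry entries is a hard error, never a silent
tie-break. Unmatched identities are retained with no registry code.

A *fish collection* is a collection of non-fossilized, preserved specimens
with locality data and/or tissues: identities whose records are all fossil,
all living stock, or contain no fish-family record are dropped (reasons
logged); mixed identities are kept and the exclusion is applied per record
downstream.

## Validation

Verbatim taxonomy is never corrected, so contaminant records (reptiles,
birds, mammals in mixed recordsets) must be removed by reference, not by
cleaning. Reference collections are those at or above a percentile (default
80th) on three quality criteria *simultaneously*: record count, family
cardinality, and type-record count.

Percentile semantics: the threshold is the value at 0-based index
`floor(p/100·n)` of the ascending sort, ties included. With five distinct
values and p = 80 exactly the maximum qualifies; with all values tied,
everyone does. If the triple intersection is empty the selection falls back,
with a logged warning, to 2-of-3 criteria, and — a case that arises on small
surveys when each metric has a different leader — finally to 1-of-3 (the
per-metric leaders). Every fallback is visible in the validation report.

The dictionary is the set of case-folded, trimmed `dwc:family` values from
the reference collections, minus exact matches to a packaged blocklist of
non-fish vertebrate families. A record is dropped iff its family exactly
matches the blocklist, or is present, outside the dictionary, and beyond a
bounded Damerau-Levenshtein distance (optimal string alignment; default 2)
from every entry. Misspelled fish names therefore survive; records with no
family are kept and counted (dropping them would discard validly digitized
lots that merely lack higher taxonomy). Filtering is idempotent and
monotone in the distance bound.

## Normalization

`dwc:preparations` free text is split on commas/semicolons; each token is
matched against an editable synonym grammar (`data/prep_grammar.tsv`) into
the categories ethanol, skeleton, cleared_and_stained, tissue, formalin,
dried, media, other. A trailing integer separated by hyphen, en/em dash,
colon or space is the token's count — hyphens adjacent to digits are
separators, never minus signs — so `"EtOH -15, Skeleton—1"` parses to
ethanol 15 + skeleton 1 = 16 individuals. Unmatched tokens (e.g. "churn",
"microdissection") stay in `other`/unrecognized; no guess is made. The
parser is total and deterministic.

Per-lot counts resolve with strict precedence: (1) `dwc:individualCount`
when it parses as a positive integer and is not a placeholder (0, 9999,
99999 — values providers use for uncounted lots); (2) the preparations
total; (3) one individual, when the record shows lot evidence (any
preparation or family), as the minimal-bias default — switchable off, in
which case such lots are excluded from specimen totals. Null preparations
are *not* assumed to be ethanol for category tallies: that is a plausible
community assumption, not an observation, and asserting it would fabricate
data.

Type status is classified by substring against a configurable vocabulary,
longest term first (so "paralectotype" never matches its embedded
"lectotype"): holotype/lectotype/neotype/syntype are primary (name-bearing);
paratype/paralectotype/allotype/topotype/cotype secondary. Name
cardinalities are distinct verbatim values after surrounding-whitespace trim
only, case-sensitive — the survey reports what providers published.

## Summaries and comparison

Per collection: lots, specimens (Σ resolved counts), primary/secondary type
records, unique family and scientific-name entries, % records with a
geopoint (both coordinates present and in range; (0,0) counts — no
null-island heuristic), % holdings per ISO country code (computed over
records bearing a code; the code-less share is reported separately), records
with ≥1 cleared-and-stained / skeletal / tissue preparation, and two media
measures: records whose preparations mention media vs. separately published
media records. Percentages are rounded half-up to one decimal. Aggregates
sum per-collection integers; mean specimens/record is the ratio of totals at
one decimal; top-k tables (default k = 5) break ties by identity id.

Comparison joins strictly on registry code (historical tables use the same
standardized codes). Deltas are current − baseline per metric where both
sides report it; absent baseline metrics yield absent deltas, not zeros.
Negative deltas are legal and flagged — historical holdings were staff
estimates and were sometimes overestimated. Aggregate percent growth is
computed from summed matched totals, not a mean of per-collection rates.
Zero baselines make per-collection growth undefined (absent, with warning).

## Synthetic worlds

The generator emits a full input bundle (occurrences, catalog, registry,
merge rules, baseline) plus a ground-truth manifest holding exactly the
totals a perfect pipeline run should recover. Defaults state the emulated
world once:

| parameter | default | rationale |
|---|---|---|
| specimens per lot | geometric, mean 14 | surveys of this corpus report ≈14 specimens per lot |
| missing `individualCount` | 0.30 | counts frequently omitted by providers |
| count recoverable from preparations | 0.70 | of the missing ones |
| placeholder counts (9999 etc.) | 0.01 | documented provider habit |
| misspelled family names | 0.05 | below the filter's distance-2 tolerance |
| geopoint present | 0.60 | roughly the observed georeferencing split |
| primary / secondary type rates | 0.005 / 0.014 | of order the corpus-wide type fractions |
| country mix | US-dominated (0.66), then MX/PH/BR/VE | the reported ranking |
| keyword in fish recordset title | 0.80 | leaves a slice discoverable only via the indicator |
| mixed (contaminated) recordsets | 0.30 at 85% fish | institutionally mixed publication |

Pathologies planted: tetrapod contaminants from the packaged blocklist,
inconsistent code casing and alias institution codes, sub-recordset splits
with emitted merge rules, and four decoy recordset types (keyword-titled
with no fish; plain tetrapod; all-fossil; living stock).

Construction guarantees, required by the generator's stated recovery
invariants: every collection carries one clean "anchor" record per lexicon
family (correct spelling, family present, non-fossil). This makes every
canonical family reachable from any reference collection, so planted
misspellings (distance ≤ 2) are always kept and contaminants always dropped
— recovery is exact by construction, not by luck of the seed. Misspellings
and fossils are planted only on non-anchor draws.

What a green recovery test does **not** establish: the generator does not
model collection-size power laws, geographic clustering, multi-institution
recordsets (each recordset belongs to one identity), free-text country
names, or nomenclatural drift beyond edit-distance-2 misspellings. Results
on real aggregator exports depend on provider behaviour the synthetic world
cannot certify.

## Numerical and degenerate-input choices

* Rounding: half-up at one decimal for all reported percentages and means.
* Edit distance: optimal-string-alignment Damerau-Levenshtein; bounded scan
  with length pre-filter; per-name memoization in the filter.
* Empty inputs: empty record list writes a header-only file; an identity
  with no records summarizes to zeros with a warning; an empty reference
  set is a hard error (no dictionary, no filtering).
* Determinism: a single seeded RNG drives generation; pipeline outputs are
  sorted and byte-stable across reruns; stage logs carry timings and are
  excluded from byte-comparisons.

## Known limitations

* Coordinate columns are assumed decimal degrees; no datum or verbatim
  DMS handling.
* Country handling is pass-through upper-cased ISO 3166-1 alpha-2; free-text
  country names are not resolved.
* The Darwin Core Archive reader covers the common occurrence-core layout
  (meta.xml with indexed fields); extensions other than a media-link table
  are ignored.
* Genuinely ambiguous preparation terms remain unclassified by design.
* The static HTML chart report is not emitted; the data tables (CSV/JSON)
  behind the would-be charts are.
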