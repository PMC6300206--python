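"""Deterministic generator of aggregator-like recordsets with planted ground
truth.

The generator emulates the pathologies real aggregated occurrence data show:
institutionally mixed recordsets carrying tetrapod contaminants alongside
fish lots, misspelled family names, counts missing from
``dwc:individualCount`` but recoverable from free-text preparation strings
("EtOH -15", "Skeleton—1" and similar separator dialects), placeholder
counts (9999), partial georeferencing, inconsistent institution/collection
code casing and alias codes, sub-recordsets that must be merged into one
collection, and decoy recordsets (keyword-titled with no fish, all-fossil,
living stock) that the fish-collection definition must reject.

Every fish collection is planted with Centrarchidae — the indicator family
assumed present in every fish collection — and recordset titles carry the
"fish"/"ichthy" keywords at a configurable rate, with sub-recordsets
arranged so that neither discovery approach alone finds everything.

The :class:`GroundTruthManifest` records, per collection, exactly the totals
a perfect pipeline run should recover; identical config + seed reproduces
byte-identical output files.
"""

from __future__ import annotations

import csv
import json
import math
import random
import string
from dataclasses import asdict, dataclass, field
from pathlib import Path

from pydantic import BaseModel, Field, field_validator

from .dwc import Recordset, SpecimenRecord, write_occurrences, write_recordset_catalog
from .lexicons import fish_families, nonfish_families

__all__ = ["GeneratorConfig", "GroundTruthManifest", "generate", "write_bundle", "perturb_family"]

INDICATOR_FAMILY = "Centrarchidae"

_PRIMARY_TYPES = ("Holotype", "holotype", "Lectotype", "Neotype", "Syntype", "syntype")
_SECONDARY_TYPES = ("Paratype", "paratype", "Paralectotype", "Allotype", "allotype", "Topotype")
_JUNK_TYPES = ("possible t. material", "see notes", "unknown status")

_CATEGORY_SYNONYMS = {
    "ethanol": ("EtOH", "etoh", "Ethanol", "alcohol", "ETOH"),
    "skeleton": ("Skeleton", "skel", "Skeletal", "dry skeleton"),
    "cleared_and_stained": ("C&S", "c&s", "Cleared and Stained", "cs"),
    "tissue": ("Tissue", "tissue", "DNA", "frozen tissue"),
    "formalin": ("Formalin", "formalin"),
    "dried": ("Dried", "dry"),
}
_MEDIA_SYNONYMS = ("photo", "Photograph", "image", "x-ray", "slide")
_JUNK_PREPS = ("churn", "microdissection", "misc")
#: Count-separator dialects seen in the wild: hyphen, em dash, en dash,
#: colon, bare space.
_COUNT_SEPARATORS = (" -", "—", "–", ": ", " ", " - ")

_CATEGORY_WEIGHTS = (
    ("ethanol", 0.78),
    ("tissue", 0.08),
    ("skeleton", 0.06),
    ("cleared_and_stained", 0.04),
    ("formalin", 0.03),
    ("dried", 0.01),
)

_EPITHETS = (
    "americanus", "pallidus", "niger", "fasciatus", "maculatus", "punctatus",
    "gracilis", "borealis", "australis", "vulgaris", "minor", "elegans",
)

_PLACES = (
    "Alachua", "Boulder", "Cumberland", "Deerfield", "Elkhart", "Greenville",
    "Huron", "Juneau", "Kalamazoo", "Laramie", "Monroe", "Norwood", "Ozark",
    "Piedmont", "Quincy", "Roanoke", "Sandusky", "Tuscaloosa", "Umatilla",
    "Vernon", "Waverly", "Yellowstone",
)

_STATUS_WEIGHTS = (
    ("none", 0.78),
    ("gbif_only", 0.10),
    ("fishnet_or_vertnet_only", 0.05),
    ("grbio_metadata_only", 0.04),
    ("multiple_other", 0.03),
)


class GeneratorConfig(BaseModel):
    """Stated world of the generator; defaults echo the surveyed corpus
    (mean ~14 specimens per lot, U.S.-dominated country mix, most records in
    ethanol) — see docs/methods.md for each choice."""

    seed: int = 0
    n_recordsets: int = 14
    n_collections: int = 10
    n_records_per_collection: int = 2000
    fish_fraction_per_recordset: float = 0.85
    misspelling_rate: float = 0.05
    missing_count_rate: float = 0.30
    prep_embedded_count_rate: float = 0.70
    geopoint_rate: float = 0.60
    type_rates: tuple[float, float] = (0.005, 0.014)
    country_weights: dict[str, float] = Field(
        default={"US": 0.662, "MX": 0.036, "PH": 0.025, "BR": 0.020, "VE": 0.017,
                 "CA": 0.12, "AU": 0.12}
    )
    mixed_recordset_rate: float = 0.30
    keyword_title_rate: float = 0.80
    sub_recordset_rate: float = 0.20
    mean_specimens_per_lot: float = 14.0
    placeholder_rate: float = 0.01
    country_missing_rate: float = 0.10
    family_missing_rate: float = 0.02
    prep_missing_rate: float = 0.10
    fossil_rate: float = 0.01
    junk_type_rate: float = 0.005
    junk_prep_rate: float = 0.02
    media_prep_rate: float = 0.01
    media_record_rate: float = 0.02
    decoy_records: int = 120
    alias_rate: float = 0.20
    code_case_jitter: float = 0.20
    n_registry_unmobilized: int = 20

    @field_validator(
        "fish_fraction_per_recordset", "misspelling_rate", "missing_count_rate",
        "prep_embedded_count_rate", "geopoint_rate", "mixed_recordset_rate",
        "keyword_title_rate", "sub_recordset_rate", "placeholder_rate",
        "country_missing_rate", "family_missing_rate", "prep_missing_rate",
        "fossil_rate", "junk_type_rate", "junk_prep_rate", "media_prep_rate",
        "media_record_rate", "alias_rate", "code_case_jitter",
    )
    @classmethod
    def _rate(cls, v: float) -> float:
        if not 0.0 <= v <= 1.0:
            raise ValueError("rates must lie in [0, 1]")
        return v

    @field_validator("type_rates")
    @classmethod
    def _type_rates(cls, v):
        if not all(0.0 <= r <= 1.0 for r in v) or sum(v) > 1.0:
            raise ValueError("type rates must lie in [0, 1] and sum to <= 1")
        return v

    @field_validator("country_weights")
    @classmethod
    def _weights(cls, v):
        if any(w < 0 for w in v.values()) or not any(w > 0 for w in v.values()):
            raise ValueError("country weights must be non-negative, not all zero")
        return v

    @field_validator("mean_specimens_per_lot")
    @classmethod
    def _mean(cls, v: float) -> float:
        if v < 1.0:
            raise ValueError("mean specimens per lot must be >= 1")
        return v


@dataclass
class GroundTruthManifest:
    """Planted truth: what a perfect pipeline run recovers."""

    collections: dict[str, dict] = field(default_factory=dict)
    recordset_composition: dict[str, dict] = field(default_factory=dict)
    misspellings: list[dict] = field(default_factory=list)
    contaminant_record_ids: list[str] = field(default_factory=list)
    excluded_record_ids: list[str] = field(default_factory=list)
    decoy_recordsets: list[dict] = field(default_factory=list)
    registry_rows: list[dict] = field(default_factory=list)
    merge_rules: dict = field(default_factory=lambda: {"merges": [], "exclude_recordsets": []})
    baseline_rows: list[dict] = field(default_factory=list)
    config: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruthManifest":
        return cls(**json.loads(text))


# ---------------------------------------------------------------------------
# Family-name perturbation


def _perturb(name: str, rng: random.Random, avoid: set[str]) -> str:
    letters = string.ascii_lowercase
    for _ in range(200):
        chars = list(name)
        n_edits = 1 if rng.random() < 0.8 else 2
        for _ in range(n_edits):
            op = rng.choice(("sub", "ins", "del", "swap"))
            # Keep the capitalized initial intact so names stay name-like.
            i = rng.randrange(1, len(chars)) if len(chars) > 1 else 0
            if op == "sub":
                chars[i] = rng.choice(letters)
            elif op == "ins":
                chars.insert(i, rng.choice(letters))
            elif op == "del" and len(chars) > 3:
                del chars[i]
            elif op == "swap" and i < len(chars) - 1:
                chars[i], chars[i + 1] = chars[i + 1], chars[i]
        cand = "".join(chars)
        if cand != name and cand.casefold() not in avoid:
            return cand
    return name + "x"  # unreachable in practice


_AVOID: set[str] | None = None


def _default_avoid() -> set[str]:
    global _AVOID
    if _AVOID is None:
        _AVOID = {f.casefold() for f in fish_families()} | {
            f.casefold() for f in nonfish_families()
        }
    return _AVOID


def perturb_family(name: str, seed: int) -> str:
    """A misspelling of ``name`` at Damerau-Levenshtein distance 1-2 that
    equals no entry of either packaged lexicon."""
    if not name:
        raise ValueError("name must be non-empty")
    return _perturb(name, random.Random(seed), _default_avoid())


# ---------------------------------------------------------------------------
# Small sampling helpers


def _weighted(rng: random.Random, pairs) -> str:
    total = sum(w for _, w in pairs)
    x = rng.random() * total
    acc = 0.0
    for key, w in pairs:
        acc += w
        if x <= acc:
            return key
    return pairs[-1][0]


def _geometric(rng: random.Random, mean: float) -> int:
    if mean <= 1.0:
        return 1
    p = 1.0 / mean
    u = rng.random()
    return 1 + int(math.log(1.0 - u) / math.log(1.0 - p))


def _species_for(family: str, rng: random.Random) -> str:
    genus = family[:-4] + "us" if family.endswith("idae") else family
    return f"{genus} {rng.choice(_EPITHETS)}"


def _new_code(rng: random.Random, used: set[str]) -> str:
    while True:
        code = "".join(rng.choice(string.ascii_uppercase) for _ in range(rng.choice((3, 4))))
        if code not in used:
            used.add(code)
            return code


def _jitter_code(code: str, rng: random.Random, rate: float) -> str:
    if rng.random() < rate:
        return code.lower() if rng.random() < 0.5 else code.title()
    return code


_SUB_LABELS = ("adult", "juvenile", "larval", "egg")


# ---------------------------------------------------------------------------
# Generation


def generate(config: GeneratorConfig):
    """Generate ``(recordsets, records, manifest)`` for the stated world."""
    rng = random.Random(config.seed)
    fish = fish_families()
    nonfish = nonfish_families()
    avoid = {f.casefold() for f in fish} | {f.casefold() for f in nonfish}

    recordsets: list[Recordset] = []
    records: list[SpecimenRecord] = []
    manifest = GroundTruthManifest(config=json.loads(config.model_dump_json()))

    if config.n_recordsets == 0 or config.n_collections == 0:
        return recordsets, records, manifest

    # Reserve casefold-collisions with generic collection-code labels so a
    # random symbolic code never exact-matches a "Fish" collection code.
    used_codes: set[str] = {"FISH", "LIVE"}
    country_pairs = sorted(config.country_weights.items())
    rs_seq = 0

    # truth rows: (record, collection_code | None, kind, resolved, planted_cats,
    #              planted_type)  kind in {fish, contaminant, decoy}
    truth: list[tuple] = []

    def next_rsid() -> str:
        nonlocal rs_seq
        rs_seq += 1
        return f"rs-{rs_seq:03d}-{rng.getrandbits(32):08x}"

    def make_fish_record(
        rid: str, rsid: str, inst_pub: str, coll_pub: str, symbolic: str,
        family: str, guaranteed: bool,
    ) -> None:
        rec = SpecimenRecord(record_id=rid, recordset_id=rsid)
        rec.institution_code = _jitter_code(inst_pub, rng, config.code_case_jitter)
        rec.collection_code = _jitter_code(coll_pub, rng, config.code_case_jitter)
        # Anchor records (one per lexicon family per collection) are kept
        # clean — correctly spelled, family present, never fossil — so every
        # canonical family name is reachable from any reference collection
        # and planted misspellings stay recoverable by construction.
        canonical = family
        fam_verbatim: str | None = canonical
        if not guaranteed:
            if rng.random() < config.family_missing_rate:
                fam_verbatim = None
            elif rng.random() < config.misspelling_rate:
                fam_verbatim = _perturb(canonical, rng, avoid)
                manifest.misspellings.append(
                    {"record_id": rid, "verbatim": fam_verbatim, "canonical": canonical}
                )
        rec.family_verbatim = fam_verbatim
        rec.scientific_name_verbatim = _species_for(canonical, rng)

        true_count = _geometric(rng, config.mean_specimens_per_lot)
        count_emitted = rng.random() >= config.missing_count_rate
        placeholder = count_emitted and rng.random() < config.placeholder_rate
        if count_emitted:
            rec.individual_count_verbatim = (
                rng.choice(("9999", "0", "99999")) if placeholder else str(true_count)
            )
        count_usable = count_emitted and not placeholder

        cats: list[str] = []
        prep_tokens: list[str] = []
        planted_cats: set[str] = set()
        media_in_preps = False
        if rng.random() >= config.prep_missing_rate:
            cats.append(_weighted(rng, _CATEGORY_WEIGHTS))
            if rng.random() < 0.15:
                second = _weighted(rng, _CATEGORY_WEIGHTS)
                if second != cats[0]:
                    cats.append(second)
            embed = (
                (not count_usable and rng.random() < config.prep_embedded_count_rate)
                or (count_usable and rng.random() < 0.2)
            )
            counts_for_tokens: list[int | None] = [None] * len(cats)
            if embed:
                k = true_count
                n_tok = min(len(cats), k)
                shares = [1] * n_tok
                shares[0] += k - n_tok
                # Tokens beyond n_tok carry no count; the parsed total then
                # still equals the true lot count.
                counts_for_tokens = list(shares) + [None] * (len(cats) - n_tok)
            for cat, cnt in zip(cats, counts_for_tokens):
                syn = rng.choice(_CATEGORY_SYNONYMS[cat])
                if cnt is None:
                    prep_tokens.append(syn)
                else:
                    prep_tokens.append(f"{syn}{rng.choice(_COUNT_SEPARATORS)}{cnt}")
                planted_cats.add(cat)
            if rng.random() < config.media_prep_rate:
                prep_tokens.append(rng.choice(_MEDIA_SYNONYMS))
                planted_cats.add("media")
                media_in_preps = True
            if rng.random() < config.junk_prep_rate:
                prep_tokens.append(rng.choice(_JUNK_PREPS))
                planted_cats.add("other")
            rec.preparations_verbatim = ", ".join(prep_tokens)
            embedded_total = sum(c for c in counts_for_tokens if c is not None) or None
        else:
            embedded_total = None

        # Expected resolved count under the default policy (strict precedence).
        if count_usable:
            resolved: int | None = true_count
        elif embedded_total is not None:
            resolved = embedded_total
        elif rec.preparations_verbatim or rec.family_verbatim:
            resolved = 1
        else:
            resolved = None

        u = rng.random()
        p_primary, p_secondary = config.type_rates
        planted_type = "none"
        if u < p_primary:
            rec.type_status_verbatim = rng.choice(_PRIMARY_TYPES)
            planted_type = "primary"
        elif u < p_primary + p_secondary:
            rec.type_status_verbatim = rng.choice(_SECONDARY_TYPES)
            planted_type = "secondary"
        elif u < p_primary + p_secondary + config.junk_type_rate:
            rec.type_status_verbatim = rng.choice(_JUNK_TYPES)

        if rng.random() >= config.country_missing_rate:
            rec.country_code_indexed = _weighted(rng, country_pairs)
        if rng.random() < config.geopoint_rate:
            rec.latitude = round(rng.uniform(-60.0, 70.0), 4)
            rec.longitude = round(rng.uniform(-180.0, 180.0), 4)
            rec.has_geopoint_indexed = True
        if rng.random() < config.media_record_rate:
            rec.media_record_count = rng.randint(1, 5)
        if not guaranteed and rng.random() < config.fossil_rate:
            rec.is_fossil = True
            manifest.excluded_record_ids.append(rid)

        records.append(rec)
        truth.append((rec, symbolic, "fish", resolved, planted_cats, planted_type))

    def make_contaminant(rid: str, rsid: str, inst_pub: str, coll_pub: str) -> None:
        family = rng.choice(nonfish)
        rec = SpecimenRecord(
            record_id=rid,
            recordset_id=rsid,
            institution_code=_jitter_code(inst_pub, rng, config.code_case_jitter),
            collection_code=_jitter_code(coll_pub, rng, config.code_case_jitter),
            family_verbatim=family,
            scientific_name_verbatim=_species_for(family, rng),
            individual_count_verbatim=str(rng.randint(1, 4)),
        )
        if rng.random() >= config.country_missing_rate:
            rec.country_code_indexed = _weighted(rng, country_pairs)
        records.append(rec)
        manifest.contaminant_record_ids.append(rid)
        truth.append((rec, None, "contaminant", None, set(), "none"))

    # ---- fish collections -------------------------------------------------
    keyword_titles = (
        "{name} Fish Collection", "{name} Ichthyology Collection",
        "Fishes of the {place} Basin", "{name} ichthyological survey",
    )
    plain_titles = (
        "{name} Aquatic Vertebrate Survey", "{name} Natural History Holdings",
        "{place} Basin Biodiversity Inventory", "{name} Museum Recordset",
    )

    for ci in range(config.n_collections):
        symbolic = _new_code(rng, used_codes)
        place = _PLACES[ci % len(_PLACES)]
        inst_name = f"University of {place}"
        aliases: list[str] = []
        inst_pub = symbolic
        if rng.random() < config.alias_rate:
            inst_pub = _new_code(rng, used_codes)
            aliases.append(inst_pub)
        coll_base = rng.choice(("Fish", "Fishes", "Ichthyology"))
        multi = rng.random() < config.sub_recordset_rate
        n_subs = 4 if multi else 1

        sub_ids: list[str] = []
        sub_colls: list[str] = []
        for si in range(n_subs):
            rsid = next_rsid()
            sub_ids.append(rsid)
            label = _SUB_LABELS[si] if multi else None
            coll_pub = f"{coll_base} {label}" if multi else coll_base
            sub_colls.append(coll_pub)
            if multi and si > 0:
                keyword = True  # sub-recordsets lack the indicator: need metadata
            else:
                keyword = rng.random() < config.keyword_title_rate
            tmpl = rng.choice(keyword_titles if keyword else plain_titles)
            title = tmpl.format(name=inst_name, place=place)
            if not keyword:
                assert "fish" not in title.lower() and "ichthy" not in title.lower()
            recordsets.append(
                Recordset(
                    recordset_id=rsid,
                    title=title if not multi else f"{title} ({label})",
                    description=f"Specimen records published by {inst_name}.",
                    publisher=inst_name,
                )
            )
            manifest.recordset_composition[rsid] = {
                "collection": symbolic, "fish": 0, "contaminant": 0, "decoy_type": None,
            }

        # Guarantee every lexicon family (the indicator included) in the
        # first sub-recordset, then free draws.
        n = config.n_records_per_collection
        fam_seq = list(fish[: min(len(fish), n)])
        fam_seq += [rng.choice(fish) for _ in range(n - len(fam_seq))]
        for i, family in enumerate(fam_seq):
            guaranteed = i < min(len(fish), n)
            si = 0 if guaranteed else rng.randrange(n_subs)
            rsid = sub_ids[si]
            rid = f"{rsid}:{i:05d}"
            make_fish_record(rid, rsid, inst_pub, sub_colls[si], symbolic, family, guaranteed)
            manifest.recordset_composition[rsid]["fish"] += 1

        # Contaminants in institutionally mixed recordsets.
        for si, rsid in enumerate(sub_ids):
            if rng.random() < config.mixed_recordset_rate:
                n_fish_rs = manifest.recordset_composition[rsid]["fish"]
                frac = config.fish_fraction_per_recordset
                n_cont = int(round(n_fish_rs * (1.0 - frac) / frac)) if frac > 0 else 0
                for j in range(n_cont):
                    rid = f"{rsid}:c{j:05d}"
                    make_contaminant(rid, rsid, inst_pub, sub_colls[si])
                    manifest.recordset_composition[rsid]["contaminant"] += 1

        if multi:
            manifest.merge_rules["merges"].append(
                {
                    "identity_id": symbolic,
                    "recordset_ids": sub_ids,
                    "labels": [f"{symbolic} {lbl}" for lbl in _SUB_LABELS],
                }
            )
        manifest.registry_rows.append(
            {
                "symbolic_code": symbolic,
                "institution_name": inst_name,
                "aliases": "|".join(aliases),
                "country": "US",
                "mobilization_status": "idigbio",
            }
        )
        manifest.collections[symbolic] = {"recordset_ids": sub_ids, "institution_code": inst_pub}

    # ---- decoy recordsets -------------------------------------------------
    n_fish_rs = rs_seq
    n_decoys = max(0, config.n_recordsets - n_fish_rs)
    decoy_cycle = ("keyword_no_fish", "plain_tetrapod", "all_fossil", "living_stock")
    for di in range(n_decoys):
        kind = decoy_cycle[di % len(decoy_cycle)]
        rsid = next_rsid()
        code = _new_code(rng, used_codes)
        place = _PLACES[(config.n_collections + di) % len(_PLACES)]
        if kind == "keyword_no_fish":
            title = f"{place} State Fish and Wildlife Teaching Collection"
            coll = "Herps"
        elif kind == "plain_tetrapod":
            title = f"{place} Herpetology Collection"
            coll = "Herps"
        elif kind == "all_fossil":
            title = f"Fossil fishes of the {place} Formation"
            coll = "Paleo Fish"
        else:
            title = f"{place} Hatchery Fish Living Stock Register"
            coll = "Live Fish"
        recordsets.append(
            Recordset(
                recordset_id=rsid, title=title,
                description=f"{place} teaching and survey material.",
                publisher=f"{place} State College",
            )
        )
        manifest.recordset_composition[rsid] = {
            "collection": None, "fish": 0, "contaminant": 0, "decoy_type": kind,
        }
        manifest.decoy_recordsets.append({"recordset_id": rsid, "decoy_type": kind})
        for j in range(config.decoy_records):
            rid = f"{rsid}:d{j:05d}"
            if kind in ("keyword_no_fish", "plain_tetrapod"):
                family = rng.choice(nonfish)
            else:
                family = rng.choice(fish)
            rec = SpecimenRecord(
                record_id=rid, recordset_id=rsid,
                institution_code=code, collection_code=coll,
                family_verbatim=family,
                scientific_name_verbatim=_species_for(family, rng),
                individual_count_verbatim=str(rng.randint(1, 20)),
                is_fossil=(kind == "all_fossil"),
                is_living_stock=(kind == "living_stock"),
            )
            records.append(rec)
            truth.append((rec, None, "decoy", None, set(), "none"))

    # ---- registry padding (collections not mobilized anywhere) ------------
    for _ in range(config.n_registry_unmobilized):
        code = _new_code(rng, used_codes)
        place = rng.choice(_PLACES)
        manifest.registry_rows.append(
            {
                "symbolic_code": code,
                "institution_name": f"{place} College",
                "aliases": "",
                "country": "US",
                "mobilization_status": _weighted(rng, _STATUS_WEIGHTS),
            }
        )

    # ---- recount: per-collection ground truth -----------------------------
    for symbolic, entry in manifest.collections.items():
        kept = [
            t for t in truth
            if t[1] == symbolic and t[2] == "fish" and not t[0].is_fossil
        ]
        recs = [t[0] for t in kept]
        entry.update(
            n_records=len(recs),
            n_specimens=sum(t[3] for t in kept if t[3] is not None),
            n_primary_types=sum(1 for t in kept if t[5] == "primary"),
            n_secondary_types=sum(1 for t in kept if t[5] == "secondary"),
            n_unique_families=len(
                {r.family_verbatim.strip() for r in recs if r.family_verbatim}
            ),
            n_unique_species=len(
                {r.scientific_name_verbatim.strip() for r in recs if r.scientific_name_verbatim}
            ),
            n_geopoint=sum(1 for r in recs if r.has_geopoint_indexed),
            n_records_cleared_stained=sum(1 for t in kept if "cleared_and_stained" in t[4]),
            n_records_skeletal=sum(1 for t in kept if "skeleton" in t[4]),
            n_records_tissue=sum(1 for t in kept if "tissue" in t[4]),
            n_records_media_in_preps=sum(1 for t in kept if "media" in t[4]),
            n_mediarecords=sum(r.media_record_count for r in recs),
        )

    # ---- baseline table (historical survey, scaled-down holdings) ---------
    for symbolic in sorted(manifest.collections):
        entry = manifest.collections[symbolic]
        f = rng.uniform(0.4, 0.9)
        manifest.baseline_rows.append(
            {
                "registry_code": symbolic,
                "year": 1995,
                "lots": max(1, int(entry["n_records"] * f)),
                "specimens": max(1, int(entry["n_specimens"] * rng.uniform(0.4, 0.9))),
                "species": max(1, int(entry["n_unique_species"] * rng.uniform(0.5, 1.0))),
                "primary_types": (
                    max(0, int(entry["n_primary_types"] * rng.uniform(0.5, 1.2)))
                    if rng.random() >= 0.2 else None
                ),
                "secondary_types": (
                    max(0, int(entry["n_secondary_types"] * rng.uniform(0.5, 1.2)))
                    if rng.random() >= 0.2 else None
                ),
            }
        )
    # Two baseline-only codes: collections surveyed historically but not
    # digitized (exercise the unmatched section).
    for _ in range(2):
        code = _new_code(rng, used_codes)
        manifest.baseline_rows.append(
            {
                "registry_code": code, "year": 1995,
                "lots": rng.randint(1000, 50000),
                "specimens": rng.randint(10000, 500000),
                "species": rng.randint(100, 3000),
                "primary_types": rng.randint(0, 50),
                "secondary_types": rng.randint(0, 500),
            }
        )

    for rs in recordsets:
        rs.record_count = sum(1 for r in records if r.recordset_id == rs.recordset_id)
    return recordsets, records, manifest


# ---------------------------------------------------------------------------
# File emission


def write_bundle(config: GeneratorConfig, out_dir: str | Path) -> dict[str, Path]:
    """Generate and write occurrences, catalog, registry, merge rules,
    baseline and manifest; returns the path of each artifact."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    recordsets, records, manifest = generate(config)
    paths = {
        "occurrences": out / "occurrences.csv",
        "catalog": out / "catalog.csv",
        "registry": out / "registry.csv",
        "merge_rules": out / "merge_rules.json",
        "baseline": out / "baseline.csv",
        "manifest": out / "manifest.json",
    }
    write_occurrences(records, paths["occurrences"])
    write_recordset_catalog(recordsets, paths["catalog"])
    with open(paths["registry"], "w", newline="", encoding="utf-8") as handle:
        w = csv.DictWriter(
            handle,
            fieldnames=["symbolic_code", "institution_name", "aliases", "country",
                        "mobilization_status"],
            lineterminator="\n",
        )
        w.writeheader()
        w.writerows(manifest.registry_rows)
    paths["merge_rules"].write_text(
        json.dumps(manifest.merge_rules, indent=1, sort_keys=True), encoding="utf-8"
    )
    with open(paths["baseline"], "w", newline="", encoding="utf-8") as handle:
        w = csv.DictWriter(
            handle,
            fieldnames=["registry_code", "year", "lots", "specimens", "species",
                        "primary_types", "secondary_types"],
            lineterminator="\n",
        )
        w.writeheader()
        for row in manifest.baseline_rows:
            w.writerow({k: ("" if v is None else v) for k, v in row.items()})
    paths["manifest"].write_text(manifest.to_json(), encoding="utf-8")
    return paths
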