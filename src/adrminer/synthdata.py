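"""Synthetic test universe: dictionary, ontologies, labels, planted truth.

Real ADR vocabularies (MedDRA) are license-restricted and the drug-label
corpus with gold annotations is access-restricted, so every input the
pipeline consumes is synthesized here with planted ground truth:

* an ADR vocabulary built from a closed word list (no licensed strings),
  including lab-test terms with abbreviations and one deliberately ambiguous
  acronym ("ALL") to exercise the acronym guard;
* an adverse-event is-a hierarchy grouping ADR terms under body systems, and
  a chemical is-a hierarchy grouping drugs into classes;
* XML drug labels whose sections embed planted ADR surface forms — a
  configured fraction rendered through the dictionary's own expansion rules
  (plurals, lab-variant orderings) so every planted mention is recoverable —
  plus table-header lines carrying mentions a correct tagger must exclude,
  and distractor sentences with acronym traps;
* drug classes with planted shared-ADR sets (class effects), e.g. a 3-drug
  class sharing exactly 43 ADRs.

A single integer seed drives one pseudo-random stream; with the seed fixed,
two runs produce byte-identical files.
"""

from __future__ import annotations

import json
import random
from dataclasses import asdict, dataclass, field
from pathlib import Path

from .errors import ConfigError
from . import termdict
from .labelio import GoldMention, LabelDocument, Section, write_label_xml
from .termdict import ExpansionConfig, Ontology, TermEntry

_QUALIFIERS = [
    "acral", "axial", "brachial", "caudal", "cortical", "dermal", "distal",
    "dorsal", "femoral", "focal", "frontal", "gingival", "hepatic", "iliac",
    "jugular", "lingual", "lumbar", "malar", "nasal", "neural", "ocular",
    "palmar", "pelvic", "plantar", "renal", "sacral", "spinal", "sternal",
    "tibial", "ulnar", "volar", "zonal",
]
_NOUNS = [
    "blister", "cramp", "eruption", "fissure", "flutter", "lesion", "murmur",
    "nodule", "papule", "plaque", "pustule", "spasm", "swelling", "tremor",
    "twitch", "ulcer", "weal", "neuropathy", "myoclonus", "dystrophy",
]
_ANALYTES = [
    ("serum alanase", "SAL"), ("plasma bilinase", "PBL"),
    ("blood citranase", "BCN"), ("serum dextranase", "SDX"),
    ("plasma ferritase", "PFT"), ("blood gluconase", "BGN"),
    ("serum histaminase", "SHM"), ("plasma keratase", "PKT"),
]
_DRUG_BASES = [
    "zalto", "mirva", "tovra", "barlo", "upra", "fedra", "lumra", "nivra",
    "pemra", "rosva", "dapra", "canva", "empra", "sivta", "vilra", "linva",
    "alvo", "saxva", "telva", "orva",
]
_DRUG_SUFFIXES = ["prazole", "micin", "fenib", "setron"]
_SYSTEMS = [
    "behavioral and neurological system AE", "digestive system AE",
    "skin and subcutaneous tissue AE", "immune system AE",
    "hematopoietic system AE", "muscular system AE", "homeostasis AE",
]
_TEMPLATES = [
    "Patients commonly experienced {} in clinical trials.",
    "Cases of {} were reported during therapy.",
    "Treatment was discontinued when {} occurred.",
    "Postmarketing reports describe {} in some patients.",
]
_DISTRACTORS = [
    "In all patients the dose was well tolerated.",
    "Monitoring is advised for all subjects receiving therapy.",
    "ALL enrolled subjects completed the study visits.",
]


@dataclass(frozen=True)
class ClassSpec:
    """One planted drug class: size, shared-ADR count, per-drug extras."""

    n_drugs: int
    n_shared_adrs: int
    n_extra_adrs: int


@dataclass(frozen=True)
class SynthConfig:
    n_drugs: int = 20
    n_adr_terms: int = 60
    n_labels_per_drug: int = 2
    mentions_per_label: int = 8
    fraction_variant_forms: float = 0.3
    planted_class_specs: tuple[ClassSpec, ...] = (ClassSpec(3, 43, 5),)
    distractor_rate: float = 0.1
    #: Highly prevalent "core" ADRs (the headache/nausea tier of real labels):
    #: each non-planted drug carries each core ADR with ``common_adr_prob``,
    #: so the thresholded co-occurrence network has a dense hub.
    n_common_adrs: int = 8
    common_adr_prob: float = 0.75
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_drugs, self.n_adr_terms, self.n_labels_per_drug,
               self.mentions_per_label) < 1:
            raise ConfigError("all counts must be positive")
        if not 0 <= self.n_common_adrs <= self.n_adr_terms:
            raise ConfigError("n_common_adrs must be in [0, n_adr_terms]")
        if not 0 <= self.common_adr_prob <= 1:
            raise ConfigError("common_adr_prob must be in [0, 1]")
        if not 0 <= self.fraction_variant_forms <= 1:
            raise ConfigError("fraction_variant_forms must be in [0, 1]")
        if self.distractor_rate < 0:
            raise ConfigError("distractor_rate must be >= 0")
        planted = sum(s.n_drugs for s in self.planted_class_specs)
        if planted > self.n_drugs:
            raise ConfigError("planted classes need more drugs than configured")
        for s in self.planted_class_specs:
            if s.n_drugs < 1 or s.n_shared_adrs < 0 or s.n_extra_adrs < 0:
                raise ConfigError("class spec counts must be non-negative")
            if s.n_shared_adrs + s.n_drugs * s.n_extra_adrs > self.n_adr_terms:
                raise ConfigError(
                    f"class spec {s} needs more ADR terms than n_adr_terms="
                    f"{self.n_adr_terms}"
                )


@dataclass
class PlantedMention:
    label_id: str
    section_id: str
    start: int
    length: int
    surface: str
    term_id: str
    in_header: bool


@dataclass
class Universe:
    """In-memory view of one generated universe plus its ground truth."""

    config: SynthConfig
    entries: list[TermEntry]
    adr_ontology: Ontology
    drug_ontology: Ontology
    drug_terms: dict[str, str]  # drug name -> chemical term id
    documents: list[LabelDocument]
    mentions: list[PlantedMention]
    profiles: dict[str, frozenset[str]]
    class_members: dict[str, tuple[str, ...]]  # classes with >= 2 members
    shared_by_class: dict[str, frozenset[str]]
    planted_classes: tuple[str, ...]
    expected_edges: dict[tuple[str, str], int] = field(default_factory=dict)

    def ground_truth(self) -> dict:
        labels: dict[str, dict] = {}
        for doc in self.documents:
            labels[doc.label_id] = {"drug": doc.drug_name, "mentions": []}
        for m in self.mentions:
            labels[m.label_id]["mentions"].append(
                {
                    "section": m.section_id,
                    "start": m.start,
                    "len": m.length,
                    "surface": m.surface,
                    "term_id": m.term_id,
                    "in_header": m.in_header,
                }
            )
        return {
            "profiles": {d: sorted(p) for d, p in sorted(self.profiles.items())},
            "labels": labels,
            "network": {
                "fraction": 0.5,
                "edges": [[a, b, w] for (a, b), w in sorted(self.expected_edges.items())],
            },
            "classes": {
                c: {
                    "members": list(self.class_members[c]),
                    "shared_adrs": sorted(self.shared_by_class[c]),
                }
                for c in sorted(self.class_members)
            },
            "planted_classes": list(self.planted_classes),
        }


def _make_vocabulary(config: SynthConfig, rng: random.Random) -> list[TermEntry]:
    n_lab = min(len(_ANALYTES), max(2, config.n_adr_terms // 10))
    n_plain = config.n_adr_terms - n_lab - 1  # one slot for the acronym trap
    if n_plain < 0:
        raise ConfigError("n_adr_terms too small (need >= 4)")
    combos = [f"{q} {n}" for q in _QUALIFIERS for n in _NOUNS]
    if n_plain > len(combos):
        raise ConfigError(f"n_adr_terms exceeds vocabulary capacity {len(combos)}")
    names = rng.sample(combos, n_plain)
    entries: list[TermEntry] = []
    next_id = 1

    def new_id() -> str:
        nonlocal next_id
        tid = f"AE:{next_id:07d}"
        next_id += 1
        return tid

    for i, name in enumerate(names):
        synonyms = frozenset([f"{name} disorder"]) if i % 5 == 0 else frozenset()
        entries.append(TermEntry(new_id(), name, synonyms=synonyms))
    for i in range(n_lab):
        analyte, short = _ANALYTES[i]
        direction = "increased" if i % 2 == 0 else "decreased"
        entries.append(
            TermEntry(
                new_id(),
                f"{analyte} {direction}",
                abbreviations=frozenset([(analyte, short)]),
            )
        )
    # Ambiguous-acronym trap: its short form collides with the everyday word
    # "all"; the tagger's stoplist must keep bare "all"/"ALL" untagged.
    entries.append(
        TermEntry(
            new_id(),
            "acute lymphoid leukopathy",
            abbreviations=frozenset([("acute lymphoid leukopathy", "ALL")]),
        )
    )
    return entries


def _make_adr_ontology(entries: list[TermEntry]) -> Ontology:
    terms = {"AEO:0000000": "adverse event"}
    edges: list[tuple[str, str]] = []
    system_ids = []
    for i, name in enumerate(_SYSTEMS, start=1):
        sid = f"AEO:{i:07d}"
        terms[sid] = name
        edges.append((sid, "AEO:0000000"))
        system_ids.append(sid)
    for i, entry in enumerate(sorted(entries, key=lambda e: e.term_id)):
        terms[entry.term_id] = entry.preferred_name
        edges.append((entry.term_id, system_ids[i % len(system_ids)]))
    return Ontology(terms, edges)


def _make_drug_names(config: SynthConfig, rng: random.Random) -> list[str]:
    pool = [b + s for s in _DRUG_SUFFIXES for b in _DRUG_BASES]
    if config.n_drugs > len(pool):
        raise ConfigError(f"n_drugs exceeds name capacity {len(pool)}")
    return rng.sample(pool, config.n_drugs)


def _surface_candidates(entry: TermEntry, expansion: ExpansionConfig) -> list[str]:
    """Plantable surfaces for one term, produced by the expansion rules."""
    base = set(entry.names)
    for name in entry.names:
        base |= termdict._lab_variants(name, entry.abbreviations, expansion)
    surfaces: set[str] = set()
    for s in base:
        surfaces |= termdict.expand_number(s)
    return sorted(s for s in surfaces if len(s) >= expansion.min_acronym_len)


def generate_universe(
    config: SynthConfig,
    out_dir: str | Path | None = None,
    expansion: ExpansionConfig | None = None,
) -> Universe:
    """Generate the full universe; optionally write it under ``out_dir``."""
    config.validate()
    expansion = expansion or ExpansionConfig()
    rng = random.Random(config.seed)

    entries = _make_vocabulary(config, rng)
    adr_ids = sorted(e.term_id for e in entries)
    by_id = {e.term_id: e for e in entries}
    adr_ontology = _make_adr_ontology(entries)
    drugs = _make_drug_names(config, rng)

    # --- chemical ontology with planted classes -------------------------------
    chem_terms = {"CHEM:0000000": "chemical entity"}
    chem_edges: list[tuple[str, str]] = []
    drug_terms: dict[str, str] = {}
    planted_classes: list[str] = []
    group_of: dict[str, str] = {}
    cursor = 0
    for j, spec in enumerate(config.planted_class_specs, start=1):
        gid = f"CHEM:1{j:06d}"
        chem_terms[gid] = f"planted chemoclass {j}"
        chem_edges.append((gid, "CHEM:0000000"))
        planted_classes.append(gid)
        for drug in drugs[cursor : cursor + spec.n_drugs]:
            group_of[drug] = gid
        cursor += spec.n_drugs
    filler = drugs[cursor:]
    n_filler_groups = max(1, min(3, len(filler) // 4)) if filler else 0
    for k in range(n_filler_groups):
        gid = f"CHEM:2{k:06d}"
        chem_terms[gid] = f"filler chemoclass {k + 1}"
        chem_edges.append((gid, "CHEM:0000000"))
        for drug in filler[k::n_filler_groups]:
            group_of[drug] = gid
    for i, drug in enumerate(drugs, start=1):
        tid = f"CHEM:3{i:06d}"
        chem_terms[tid] = drug
        chem_edges.append((tid, group_of[drug]))
        drug_terms[drug] = tid
    drug_ontology = Ontology(chem_terms, chem_edges)

    # --- profiles with planted class effects ----------------------------------
    # A prevalent "core" of ADRs seeds the co-occurrence network's hub; the
    # planted shared sets contain the core, mirroring how real class-effect
    # ADR sets overlap the most common label ADRs.
    common_core = rng.sample(adr_ids, config.n_common_adrs)
    profiles: dict[str, set[str]] = {}
    cursor = 0
    for j, spec in enumerate(config.planted_class_specs):
        members = drugs[cursor : cursor + spec.n_drugs]
        cursor += spec.n_drugs
        shared = list(common_core[: spec.n_shared_adrs])
        remaining = [t for t in adr_ids if t not in shared]
        shared += rng.sample(remaining, spec.n_shared_adrs - len(shared))
        extra_pool = [t for t in adr_ids if t not in shared]
        for drug in members:
            extras = rng.sample(extra_pool, min(spec.n_extra_adrs, len(extra_pool)))
            extra_pool = [t for t in extra_pool if t not in extras]
            profiles[drug] = set(shared) | set(extras)
    rare_pool = [t for t in adr_ids if t not in common_core]
    for drug in filler:
        core = {t for t in common_core if rng.random() < config.common_adr_prob}
        k = rng.randint(4, max(4, min(12, config.n_adr_terms // 2)))
        profiles[drug] = core | set(rng.sample(rare_pool, min(k, len(rare_pool))))

    # Remove unplanned class effects: any class (filler group or root) with
    # >= 2 members must not share an ADR unless the class was planted.
    member_map: dict[str, list[str]] = {}
    for drug in drugs:
        for cid in sorted(drug_ontology.ancestors(drug_terms[drug])):
            member_map.setdefault(cid, []).append(drug)
    planted_shared: dict[str, frozenset[str]] = {
        d: frozenset() for d in drugs
    }
    cursor2 = 0
    for spec, cid in zip(config.planted_class_specs, planted_classes):
        members = drugs[cursor2 : cursor2 + spec.n_drugs]
        cursor2 += spec.n_drugs
        common = set.intersection(*(profiles[d] for d in members)) if members else set()
        for d in members:
            planted_shared[d] = frozenset(common)
    for cid, members in sorted(member_map.items()):
        if cid in planted_classes or len(members) < 2:
            continue
        common = set.intersection(*(profiles[d] for d in members))
        for adr in sorted(common):
            # Strip from the drug with the biggest profile, never touching a
            # planted shared ADR of a planted-class member.
            candidates = sorted(
                (d for d in members if adr not in planted_shared[d] and len(profiles[d]) > 1),
                key=lambda d: (-len(profiles[d]), d),
            )
            if candidates:
                profiles[candidates[0]].discard(adr)

    frozen_profiles = {d: frozenset(p) for d, p in profiles.items()}

    # --- labels with planted mentions -----------------------------------------
    documents: list[LabelDocument] = []
    mentions: list[PlantedMention] = []
    for drug in drugs:
        terms = sorted(frozen_profiles[drug])
        per_label: list[list[str]] = [[] for _ in range(config.n_labels_per_drug)]
        for i, t in enumerate(terms):
            per_label[i % config.n_labels_per_drug].append(t)
        for k, label_terms in enumerate(per_label, start=1):
            pool = label_terms or terms[:1]
            while pool and len(label_terms) < config.mentions_per_label:
                label_terms.append(pool[len(label_terms) % len(pool)])
            label_id = f"{drug}_{k}"
            doc, planted = _render_label(
                drug, label_id, label_terms, by_id, expansion, config, rng
            )
            documents.append(doc)
            mentions.extend(planted)

    # --- expected network (brute-force pair counting) -------------------------
    threshold = -(-len(drugs) // 2)  # ceil(n/2) at fraction 0.5
    pair_counts: dict[tuple[str, str], int] = {}
    for p in frozen_profiles.values():
        ordered = sorted(p)
        for i, a in enumerate(ordered):
            for b in ordered[i + 1 :]:
                pair_counts[(a, b)] = pair_counts.get((a, b), 0) + 1
    expected_edges = {k: v for k, v in pair_counts.items() if v >= threshold}

    class_members = {
        cid: tuple(sorted(members))
        for cid, members in member_map.items()
        if len(members) >= 2
    }
    shared_by_class = {
        cid: frozenset(set.intersection(*(set(frozen_profiles[d]) for d in members)))
        for cid, members in class_members.items()
    }

    universe = Universe(
        config=config,
        entries=entries,
        adr_ontology=adr_ontology,
        drug_ontology=drug_ontology,
        drug_terms=drug_terms,
        documents=documents,
        mentions=mentions,
        profiles=frozen_profiles,
        class_members=class_members,
        shared_by_class=shared_by_class,
        planted_classes=tuple(planted_classes),
        expected_edges=expected_edges,
    )
    if out_dir is not None:
        write_universe(universe, Path(out_dir))
    return universe


def _render_label(
    drug: str,
    label_id: str,
    label_terms: list[str],
    by_id: dict[str, TermEntry],
    expansion: ExpansionConfig,
    config: SynthConfig,
    rng: random.Random,
) -> tuple[LabelDocument, list[PlantedMention]]:
    lines: list[str] = ["ADVERSE REACTIONS"]
    planted: list[PlantedMention] = []
    pending: list[tuple[int, int, str, str, bool]] = []  # line_no, col, surface, tid, hdr

    for t in label_terms:
        entry = by_id[t]
        if rng.random() < config.fraction_variant_forms:
            surface = rng.choice(_surface_candidates(entry, expansion))
        else:
            surface = entry.preferred_name
        template = rng.choice(_TEMPLATES)
        prefix = template.split("{}")[0]
        pending.append((len(lines), len(prefix), surface, t, False))
        lines.append(template.format(surface))
        if config.distractor_rate and rng.random() < config.distractor_rate:
            lines.append(rng.choice(_DISTRACTORS))

    # One table-header line carrying a mention the tagger must exclude.
    if label_terms and rng.random() < 0.5:
        t = rng.choice(sorted(set(label_terms)))
        surface = by_id[t].preferred_name.upper()
        header = f"TABLE 1 {surface} INCIDENCE"
        pending.append((len(lines), len("TABLE 1 "), surface, t, True))
        lines.append(header)
        lines.append("Rates in the table are per 100 patient-years.")

    text = "\n".join(lines)
    line_starts = []
    pos = 0
    for line in lines:
        line_starts.append(pos)
        pos += len(line) + 1
    gold: list[GoldMention] = []
    gold_terms: set[str] = set()
    for line_no, col, surface, term_id, in_header in pending:
        start = line_starts[line_no] + col
        assert text[start : start + len(surface)] == surface
        planted.append(
            PlantedMention(label_id, "S1", start, len(surface), surface, term_id, in_header)
        )
        if not in_header:
            gold.append(GoldMention("S1", start, len(surface), "AdverseReaction", surface))
            gold_terms.add(term_id)
    doc = LabelDocument(
        drug_name=drug,
        label_id=label_id,
        sections=[Section("S1", "ADVERSE REACTIONS", text)],
        gold_mentions=sorted(gold, key=lambda m: (m.section_id, m.start)),
        gold_reactions=frozenset(gold_terms),
    )
    return doc, planted


def write_dictionary_tsv(entries: list[TermEntry], path: Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("term_id\tpreferred_name\tsynonyms\tabbreviations\n")
        for e in sorted(entries, key=lambda e: e.term_id):
            syns = "|".join(sorted(e.synonyms))
            abbr = "|".join(f"{a}={b}" for a, b in sorted(e.abbreviations))
            fh.write(f"{e.term_id}\t{e.preferred_name}\t{syns}\t{abbr}\n")


def write_universe(universe: Universe, out_dir: Path) -> dict[str, Path]:
    """Write every artifact of the universe; byte-identical for a fixed seed."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "dictionary": out_dir / "dictionary.tsv",
        "adr_ontology": out_dir / "adr_ontology.obo",
        "drug_ontology": out_dir / "drug_classes.obo",
        "drug_terms": out_dir / "drug_terms.tsv",
        "labels": out_dir / "labels",
        "ground_truth": out_dir / "ground_truth.json",
    }
    write_dictionary_tsv(universe.entries, paths["dictionary"])
    paths["adr_ontology"].write_text(
        universe.adr_ontology.to_obo_str("synthetic adverse-event hierarchy"),
        encoding="utf-8",
    )
    paths["drug_ontology"].write_text(
        universe.drug_ontology.to_obo_str("synthetic chemical classification"),
        encoding="utf-8",
    )
    with open(paths["drug_terms"], "w", encoding="utf-8") as fh:
        fh.write("drug_name\tterm_id\n")
        for drug, tid in sorted(universe.drug_terms.items()):
            fh.write(f"{drug}\t{tid}\n")
    paths["labels"].mkdir(exist_ok=True)
    for doc in universe.documents:
        write_label_xml(doc, paths["labels"] / f"{doc.label_id}.xml")
    with open(paths["ground_truth"], "w", encoding="utf-8") as fh:
        json.dump(
            {"config": asdict(universe.config), **universe.ground_truth()},
            fh,
            indent=1,
            sort_keys=True,
        )
        fh.write("\n")
    return paths
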