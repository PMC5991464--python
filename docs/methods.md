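# Methods

This document specifies the algorithms, parameters and numerical choices in
adrminer, and what the synthetic-data generator does and does not emulate.

## 1. Term dictionary and expansion rules

A `TermEntry` holds a PT identifier, a preferred name, optional synonyms, and
optional abbreviation pairs `(long form, short form)`. Compilation
(`termdict.compile_dictionary`) produces, per entry, the closure of:

1. **Base surfaces** — preferred name and synonyms, Unicode-NFC-normalized,
   tokenized on `[^\W_]+` boundaries.
2. **Number inflection** (`expand_number`) — the last token (head noun) is
   pluralized/singularized with a hand-written English inflector. The
   inflector refuses tokens that are shorter than 3 characters, non-alphabetic,
   all-uppercase (acronyms) or end in "-ed" (participles such as "increased"),
   and leaves plural-looking words unchanged. This guarantees the
   *expansion-closure invariant*: applying `expand_number` to any indexed
   surface yields only indexed surfaces.
3. **Laboratory-test variants** (`generate_lab_variants`) — if an entry's name
   has the form `<analyte> <direction>` where `<direction>` belongs to a
   configured direction-synonym group, the grammar
   `{analyte long form, abbreviation short form} × {group members} ×
   {prefix, postfix}` is generated. Default groups:
   `{increased, elevated, high, raised}` and
   `{decreased, reduced, low, lowered}`. So "aspartate aminotransferase
   increased" + AST indexes "increased AST", "AST elevated", "high AST",
   "raised aspartate aminotransferase", etc. Variants are themselves
   number-expanded.
4. **Bare abbreviations** — short forms are indexed case-sensitively.

**Case policy** (`ExpansionConfig.case_policy = "fold_long_only"`): surfaces
with ≥ `min_acronym_len = 5` characters are matched case-insensitively;
shorter surfaces match case-sensitively. Rationale: short lowercase strings
collide with function words, so "ALL" matches only in uppercase, while a bare
lowercase "all" never fires. A stoplist (default `{"all", "aids"}`) suppresses
the folded forms outright. Legitimate short terms ("rash") remain matchable
because the guard applies to uppercase acronym forms, not to ordinary words.

## 2. Label I/O and header exclusion

Labels are XML (`Label/Text/Section`, optional gold `Mentions` and
`Reactions`), parsed with lxml; unknown attributes round-trip. Offsets are
0-based half-open character offsets into the section text and are validated on
load. A line is a header if it equals the section title or matches
`^(?=.*[A-Z])[^a-z]{4,}$` (≥ 4 characters, at least one uppercase letter, no
lowercase) — this captures all-caps headings and table captions such as
"TABLE 1 VOMITING INCIDENCE". `tagger.filter_headers` removes any mention
whose span overlaps a header line.

## 3. Tagging

Per section, the tagger scans token positions left to right; at each position
it tries window lengths from `min(max_tokens, remaining)` down to 1 and takes
the longest window found in either the case-sensitive or the case-folded
index (leftmost-longest, non-overlapping). `normalize_to_profile` collapses a
drug's mentions (over all its labels) into a PT multiset; the profile is the
PT set.

## 4. Evaluation

`EvaluationResult.from_counts(tp, gold, pred)` with
recall = tp/gold, precision = tp/pred, F = harmonic mean (0 when undefined).
`aggregate(results, mode)`: *micro* sums counts then recomputes; *macro*
averages per-drug metrics. Reference example: pooled TP = 4198 over 5158 gold
and 5360 predicted PTs gives micro recall 0.81. Aggregating an empty list
raises `EmptyInputError` rather than returning 0, since silent zeros mask
pipeline wiring errors.

## 5. Co-occurrence network

- Edge rule: weight w(a, b) = number of drugs whose profiles contain both;
  keep iff w ≥ `min_edge_count(n_drugs, fraction)` = ⌈fraction · n⌉
  (53 drugs, fraction 0.5 → 27). Isolated nodes are not added.
- Degree centrality: raw degree in the thresholded graph.
- Eigenvector centrality: computed on the **largest connected component**
  (ties broken by smallest sorted node list); other components score 0 and a
  warning is logged. For ≤ 500 nodes the principal eigenvector comes from
  `numpy.linalg.eigh` on the dense unweighted adjacency matrix; above that, a
  power iteration with tolerance 1e-10 is used. The vector's sign is fixed to
  non-negative, negatives from rounding are clipped to 0, and it is scaled to
  unit Euclidean norm. By Perron–Frobenius the principal eigenvector of a
  connected graph is strictly positive, so the sign fix is well defined.
- Ranking: sort by (−eigenvector, −degree, node id); deterministic.
  `rankings_consistent` checks that degree and eigenvector orderings agree up
  to ties; `rank_and_compare` contrasts two networks' rankings.

## 6. Class effects and sub-ontology extraction

Ontologies are child→parent `is_a` DAGs (OBO via obonet; cycles raise
`CycleError`). A drug is assigned to every ancestor of its chemical term.
PCR(C, a) = |{d ∈ C : a ∈ profile(d)}| / |C|; class effect iff PCR = 1;
`shared_adrs` computes the equivalent profile intersection directly.
`pcr_table` enumerates classes with ≥ `min_class_size = 2` members.

`extract_subtree(ontology, selected, mode="computed_intermediate")` keeps:

- the selected terms;
- **convergence points**: terms that are ancestor-or-self of ≥ 2 selected
  terms;
- terms on a **directed path between** selected terms (ancestor of one,
  descendant of another);
- for each selected term not yet connected upward, the **cheapest root path**
  by Dijkstra where a step costs 1 plus a large penalty (|ontology| + 1) if it
  leaves the already-included set — so paths reuse included nodes whenever
  possible; ties break on (cost, root id) for determinism.

Edges are restricted to kept nodes and transitively reduced, so the extracted
sub-ontology has no shortcut `is_a` edges. `mode="ancestors_all"` instead
keeps every ancestor of every selected term.

## 7. Synthetic-data generator

All real terminologies and annotated corpora in this domain are
access-restricted, so `synthdata.generate_universe(SynthConfig)` synthesizes
a self-contained universe with machine-readable ground truth. A single
`random.Random(seed)` drives all randomness; iteration orders are sorted;
outputs are byte-identical across runs.

It emulates:

- a closed ADR vocabulary (qualifier × noun phrases plus laboratory analytes
  with abbreviations, including an acronym trap whose short form is "ALL");
- an ADR ontology (root plus organ-system groupings) and a chemical ontology
  (root → group → drug term) with planted drug classes;
- per-drug ADR profiles with a common core (`n_common_adrs = 8`,
  `common_adr_prob = 0.75`) that makes a hub neighborhood dense enough to
  survive the fraction-0.5 edge threshold, mirroring the empirical structure
  where a network emerges from frequently co-reported ADRs;
- one planted class (`ClassSpec(n_drugs=3, n_shared_adrs=43, n_extra_adrs=5)`
  by default) whose members share *exactly* 43 ADRs; the shared set contains
  the common core, member-specific extras are pairwise disjoint, and any
  *unplanned* class effect elsewhere is stripped by removing the offending ADR
  from the largest non-protected member profile (never shrinking a profile
  below 2 ADRs, never touching planted shared ADRs);
- XML labels whose first line is an "ADVERSE REACTIONS" heading, sentence
  templates embedding planted surfaces (a `fraction_variant_forms = 0.3` share
  rendered as rule-generated variants rather than preferred names), optional
  distractor sentences (`distractor_rate`, including bare "all" traps), and
  uppercase table-caption lines deliberately containing ADR surfaces that must
  be header-excluded;
- ground truth: gold mention spans, gold PT reaction sets, per-drug profiles,
  the brute-force thresholded edge set, and the shared-ADR map per class.

It does **not** emulate: hierarchical PT/LLT terminology depth, negated or
hypothetical mentions, discontinuous spans, frequency/severity qualifiers, or
realistic label prose; tagging clean synthetic labels is therefore expected
to reach recall = precision = 1.0, which is the point — deviations localize
implementation faults rather than modelling error.

Feasibility is validated up front (`ConfigError` if a planted class needs more
ADRs or drugs than exist).

## 8. Determinism and limitations

Every artifact except the run `manifest.json` (which carries a timestamp and
config hash) is byte-identical for a fixed seed and config. JSON is written
with sorted keys.

Limitations: the matcher is token-exact (no fuzzy matching, no morphological
variants beyond the two rules); header detection is line-based and misses
mixed-case headings; eigenvector centrality on multi-component graphs reports
only the largest component; PCR treats class membership as crisp and ignores
profile uncertainty; the generator's closed vocabulary cannot probe
out-of-dictionary recall.
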