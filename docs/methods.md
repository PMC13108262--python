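# Methods

## The pipeline

`metacure` models metadata standardization as five composable stages:

1. **Read** — records from BioSample attribute XML, GEO SOFT, or the
   package's JSONL interchange dialect. A record is an ordered list of
   (field name, field value) pairs plus an optional free-text block;
   duplicate field names are legal and order is preserved. Malformed
   BioSample entries are skipped and counted rather than aborting the
   read, matching how real corpora are assembled.
2. **Label** — an approximate gold standard from an ordered keyword
   cascade over the tissue field (lung; else liver/HCC; else
   ovary/ovarian; else PBMC/blood; else plasma; else lymph; else
   unknown).
3. **Correct** — a pluggable backend rewrites field values under DD
   (data dictionary) or CEDAR-style (structured template) guidance.
4. **Search** — exact `field:value` retrieval.
5. **Evaluate** — record-wise confusion counts per query, P/R/F1,
   across-run statistics, ANOVA and Cohen's d, side-by-side diffs.

## Normalization: one rule everywhere

Stored values, query values and permissible terms are compared after
Unicode NFC, surrounding-whitespace trim, and case-fold. Nothing else —
no stemming, no partial matching, no synonym expansion. Compliance
checking targets the same canonical form that retrieval uses, so "a
value the template accepts" and "a value the search can find" coincide.
`search(..., raw_exact=True)` disables normalization for strict byte
equality; real repository search engines plausibly sit between the two
readings, which is why both are exposed.

## Templates and data dictionaries

The template dialect is a small JSON format capturing the three
restriction kinds that matter for correction: datatype (string /
integer / date, with dates restricted to ISO-8601 calendar dates — one
unambiguous dialect avoids locale drift), enumerated permissible-value
sets, and per-term vocabulary tags (e.g. an UBERON branch for tissue)
with optional usage frequencies in [0, 1]. Ontological restrictions are
pre-materialized as static term lists; there is no live ontology
service, which keeps the semantics reproducible offline. A data
dictionary deliberately has *no* permissible-value enumeration — names,
descriptions and formats only — because that absence is exactly what
separates the two guidance modes experimentally.

## The gold-standard labeler

"Contains the word" is implemented as case-insensitive substring
matching, not word-boundary matching: acronyms like HCC and PBMC occur
inside compound tokens (PBMCs, HCC-derived) in real metadata, and a
boundary rule would silently miss them. The
`case_sensitive_acronyms` switch restores exact-case matching for the
acronym keywords for anyone who wants the stricter reading. Labels
depend only on tissue-field values: information recorded solely in the
description block is deliberately missed, which makes the labeler
conservative (it marks such records unknown) — a known limitation of
rule-based gold standards that the TRUE labels returned by the
synthetic generator let you quantify.

## Correction backends

The backend contract is minimal: (prompt, record, sub-seed) → response
text containing one JSON object of field name → corrected value.
Response parsing is tolerant (first decodable JSON object anywhere in
the text, fenced blocks and prose included) because real LLM output is
messy; a response with no object, or with non-text values, is a
declared parse failure and the record falls back to its original form.
Fallback-to-original rather than record-dropping is a hard rule:
retrieval evaluation is defined over the whole corpus, so every record
must survive every stage.

The deterministic template backend applies, per restricted field:
(1) value-set membership → canonical term; (2) whole-value synonym-table
lookup → canonical term; (3) if exactly one permissible term occurs as a
case-insensitive token of the value, that term; (4) otherwise unchanged.
It is pure and idempotent. The deterministic dictionary backend performs
only step (2), because a dictionary gives it no value set to target —
this is the package's operationalization of dictionary-guided
correction, and it reproduces the expected ordering (baseline ≤ DD ≤
template-guided) on synthetic corpora. The synonym table is a versioned
TSV data file (blood preparations, disease-name variants), not embedded
heuristics.

In CEDAR mode a post-hoc compliance guard re-validates every restricted
field of the backend's candidate: compliant values are canonicalized,
non-compliant ones are restored to the original value and the verdict
logged. The resulting invariant — every restricted field holds either a
canonical permissible term or its untouched original value — is asserted
per record in the tests.

Per-record sub-seeds are derived as a SHA-256 hash of (master seed, run
index, record id), kept below 2^31, so stochastic-backend results are
reproducible independently of corpus order.

## Synthetic corpora

The generator emulates the failure modes of real sample metadata rather
than any particular corpus: tissue values confounded by disease names
("lung cancer" in a tissue field), blood behind preparation terms
(PBMC, whole blood, blood sample), GEO-style verbose descriptions
mentioning unrelated organs, empty values, and a blood prevalence of
50% among labeled records (the one prevalence reliably observed in
practice; the remaining label weights — lung/liver/ovary 0.15 each,
plasma 0.03, lymph 0.02, plus a 0.10 unknown fraction — are package
choices, fully configurable).

Tissue-value corruption is a single categorical draw per record over
{value_drop, disease_name_swap, synonym_variant, none} whose
probabilities are the configured rates (they must sum to ≤ 1). This
makes the rates directly interpretable — with swap 0.6 and synonym 0.3,
exactly the remaining 10% of labeled records keep a canonical,
baseline-retrievable value — whereas independent per-operator coin
flips would leave P(clean) = 0.4·0.7 = 0.28 and blur what each rate
means. The free-text confounder is an independent flip because it only
touches the description, never the tissue value. Defaults (drop 0,
swap 0.6, synonym 0.3, free-text 0.2) are the package's standard study
conditions.

Every generated variant is chosen so its rule-based gold label equals
the TRUE label (e.g. plasma variants avoid the word "blood", which
would be captured by the earlier blood rule). Consequently, on an
uncorrupted or value-preserving corpus the labeler recovers the TRUE
label exactly, and the deterministic backend with the full synonym
table reaches the recall = 1 limit — both properties are asserted, and
they are what "the symbolic knowledge source is complete for this
corpus" means operationally. Real corpora are messier: synonym tables
are never complete, gold rules mislabel, and free text confuses LLMs.
Passing tests therefore demonstrate the machinery and its limits under
controlled conditions, not field performance.

The mock backend models an imperfect LLM: per record, with a
configurable probability it emits non-JSON prose (exercising the
fallback path), otherwise it behaves like the deterministic backend but
with probability `error_rate` replaces the corrected tissue value with
a wrong canonical term, biased blood → lung by default (the
characteristic confusion when long records mention other organs),
otherwise a seeded draw among the remaining tissues.

## Statistics

- SE = SD/√n with sample SD (n − 1); n = 6 runs by default.
- Error limits [max(0, mean − SE), mean + SE]: metrics are non-negative,
  so bars must not extend below zero. For non-negative run values
  mean − SE ≥ 0 holds mathematically (equality at the one-nonzero-run
  extreme); the clamp guards the boundary and floating-point error.
- One-way ANOVA via the standard between/within mean-square ratio
  (scipy); a degenerate input (all values identical in every group)
  yields an undefined flag, not an exception.
- Cohen's d with pooled SD (n − 1 weights); |d| bands at 0.2 / 0.5 /
  0.8, boundary inclusive (0.8 is "large"); zero pooled SD → undefined.
- Undefined (0/0) metrics propagate as flags; run-level averages skip
  them and report how many were skipped. Query-averaged summaries are
  reported both unweighted and weighted by each query's relevant-record
  count, since the two can differ noticeably when prevalences are
  skewed.
- Pairwise ANOVAs are reported raw (no multiple-testing correction) to
  match common practice at this scale; a Bonferroni adjustment is a
  one-line transformation of the reported p values if needed.

## Problem sizes

The shipped experiment sizes — 2,400-record corpora, six runs, four
queries, 10,000-record/10,000-string oracle checks in the test suite —
were chosen as the package's standard desk-scale conditions: large
enough that observed rates sit within a couple of percent of their
expectations, small enough to iterate on quickly.

## Known limitations

- The labeler reads only the tissue field; description-only evidence is
  missed by design.
- The reference backends operate per-field on whole values; they do not
  read the description block, so free-text confounders only matter for
  LLM-class backends.
- The GEO SOFT reader maps `!Sample_*` keys generically; repository
  dialect quirks beyond characteristics/description lines are passed
  through as-is, with the key-suffix mapping exposed rather than
  hard-coded semantics.
- No ranking, indexing, fuzzy or ontology-expanded search: retrieval is
  deliberately the exact-match rule under evaluation.
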