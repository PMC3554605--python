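# Methods

This note documents the models and procedures implemented in
`nomenmatch`, the parameters that matter, the numerical and design
choices made where the design was open, what the synthetic-data
generator does and does not emulate, and the known limitations.

## Reference store

The reference taxonomy is an in-memory store loaded from one or more
Darwin-Core-style TSV exchange files (columns `taxonID, scientificName,
scientificNameAuthorship, taxonRank, parentNameUsageID,
acceptedNameUsageID, taxonomicStatus, family`).  Ranks: family, genus,
species, subspecies, variety, forma (a quadrinomial is carried on an
infraspecific record with a second indicator/epithet pair).  Statuses:
accepted, synonym, illegitimate, invalid, no_opinion.

Loading validates everything that downstream code assumes: known rank
and status tokens, per-source `taxonID` uniqueness, no dangling parent
or accepted-name links, acyclic parent chains, and that every
non-accepted record ultimately reaches an accepted one.  Multi-hop
synonym chains (synonym → synonym → accepted) are collapsed at load
time so that synonym resolution is a single hop at query time; a
synonym cycle is a validation error.  Family membership is taken
directly from the exchange file's `family` column; multiple
simultaneous family classifications are not supported.

Three indexes are rebuilt on every load:

* a nested-set (preorder interval) labeling of the classification
  tree, giving descendant queries by interval containment;
* exact-lookup maps on the canonical name and on canonical + author;
* per-record phonetic keys and epithet stems, precomputed with the
  same functions the matcher applies to queries (an invariant that is
  tested directly).

Several sources can be loaded side by side; each keeps its own
records, synonymy and integer priority (load order by default).
Conflicting synonymies between sources are never merged.

## Pre-processing

Pipeline order: trim and convert underscores to spaces → split off a
leading family (token ending in `-aceae`/`-idae`, or one of the
conserved names Gramineae, Compositae, Leguminosae, Cruciferae,
Umbelliferae, Labiatae, Palmae, Guttiferae; the list is extensible) →
remove annotations → fix case (only for entirely upper-case strings:
first letter up, rest down) → exact whole-string lookup.

The annotation vocabulary covers `cf.`, `aff.`, `indet.`, `sp.`,
`spp.`, `sp. nov.`, `sp. nova`, `ined.`, `?`, `s.l.`, `s.s.` (matched
case-insensitively, final period optional), a morphospecies code
following `sp.`/`spp.` (digits, a single letter, or an alphanumeric
code), and trailing accession-style codes (two or more characters
containing a digit) as produced by phylogeny tip labels like
`Poa_annua_AB123`.  Everything removed is recorded, not discarded.

A string that is empty after cleaning is degenerate: it resolves at
family rank if a family prefix was found, otherwise it is a no-match.
An exact whole-string hit (canonical, or canonical plus author) is
assigned an overall score of 1.0 and skips fuzzy matching; exact hits
are still ranked, so homonymous exact matches are detected and flagged
rather than silently picking one.

## Parsing

A rule-ordered tokenizer assigns components greedily left to right:
the leading capitalized token is the genus (or the family, when it has
a family ending); subsequent lower-case tokens are epithets; the
recognized rank-indicator spellings are standardized (`ssp`, `ssp.`,
`subsp` → `subsp.`; `f.`, `fo` → `fo.`; `var`, `v.` → `var.`);
parenthesized text starts the basionym author and the remaining tokens
the combining author; bare trailing capitalized material is the
author.  Years are folded into the author string.  Parsing is case
sensitive — a lower-case leading token is a failed parse, by design,
since case is what identifies components.

Parse quality records how much tolerance was needed: `strict` (clean),
`relaxed` (diacritics, bracketed years, double parentheses),
`salvage` (some tokens could not be placed and sit in
`unmatched_text`; this includes the discarded right-hand side of a
hybrid formula), `failed`.  Hybrid markers set a flag and only the
leading parent name is parsed; hybrid formulas are not atomized into
both parents.  "Nees ex Steud." is kept as one basionym-author token;
ex-author relationships are not modeled.  No token is ever dropped:
every input character lands in exactly one output field.

## Distances and phonetic equivalence

**MDLD.**  Single-character insertions, deletions and substitutions
cost 1; a transposition of two adjacent blocks of k1 and k2 characters
costs max(k1, k2), the adjacent-character transposition being the
1, 1 case.  Block length is capped at 4: that covers documented
syllable swaps while excluding pathological long-range rearrangements.
Comparison is case-insensitive.  The classic Damerau–Levenshtein
distance (single-character transpositions only) is kept as a separate
routine; it upper-bounds MDLD and is itself checked against an
exhaustive recursive oracle in the tests.

**Stemming.**  The endings -a, -is, -us, -ys, -es, -um, -as, -os are
interchangeable at the end of a species or infraspecific epithet; all
are rewritten to -a.  One ending is replaced, a stem of at least two
characters must remain, and the operation is idempotent.

**Phonetic key.**  Lower-case, fold diacritics, keep letters only,
stem (epithets), then apply the substitution table — anchored rules
once (`mc-` → `mac-`, initial `x` → `z`, initial `ps`/`pt`/`ts`
simplified), unanchored rules to a fixed point (`ae`, `oe` → `e`;
`ph` → `f`; `th` → `t`; `sz` → `s`; `y` → `i`; `k` → `c`; non-initial
`ch` → `c`) — and collapse doubled letters.  Running the unanchored
rules to a fixed point makes the key idempotent, so key equality is a
true equivalence relation.  The table ships as a plain-text data file
and can be overridden; the default reproduces all the documented
equivalences (e.g. *Zygophyllum* ≡ *Zigofillum*, and the stemmed
epithet variants above).

**Author similarity.**  Tokens are split on whitespace, known
abbreviations are expanded from a plain-text dictionary (about fifty
common botanical authors; extensible), punctuation is stripped and
case folded, and Dice similarity is computed over token-internal
n-grams without padding (a token shorter than n contributes itself as
a single gram, so initials still compare).  The score blends 2/3
bigram with 1/3 trigram similarity and is computed twice — on the raw
strings and on diacritic-folded strings — and averaged, scoring
accent-only variants as similar but not identical.  When either side
has no author, no author comparison is made (the name-only score
formula is used instead); an absent author is deliberately not
penalized, since most reference records and many queries omit
authorship.

## Scoring

With k the number of name components (family if submitted, genus,
epithets — rank indicators and authors are not components):

* `PMS = 1 − 2·ED/MaxED` per component, where MaxED is the longer of
  the two strings; 0.3 is subtracted when a submitted infraspecific
  rank indicator differs from the reference's; PMS is clamped at −1.
* `SNMS = Σ PMS`, in [−k, k].
* `SNMS_tr = atan((s·SNMS/k)^(2t+1)) / (2·atan(s^(2t+1))) + 0.5`,
  with the odd power applied sign-preservingly for non-integer t.
  This form was chosen because it satisfies every constraint the
  transform must meet simultaneously: fixed endpoints (−k → 0,
  0 → 0.5, k → 1) for all s > 0, t ≥ 0; strict monotonicity; a linear
  limit as s → 0 with t = 0; a double-logistic shape at the default
  s = 2, t = 1 (flat regions of certainty at both extremes, a flat
  central region of uncertainty, steep regions of discrimination
  between); and it reproduces the documented worked scores (0.96 for
  a one-edit genus with exact epithet; 0.50 for a perfect genus with
  unmatched epithet) with the default parameters, with no per-example
  fitting.
* `OMS = 0.8·SNMS_tr + 0.2·AMS − p` when an author was submitted and
  compared, `OMS = SNMS_tr − p` otherwise; p = 0.1 if the query
  carried text that matched nothing.  OMS is clamped to [0, 1]; a
  pre-parse exact whole-string hit is pinned at exactly 1.0.

A query component with no counterpart in a shallower reference (the
epithet of a species query matched only at genus rank) contributes
PMS = −1.  This is the unique choice under which a perfect genus
partial match scores exactly 0.5 — the transform's midpoint,
i.e. "no evidence either way about the species".

Defaults (all exposed in the `scoring:` config section): s = 2, t = 1,
name/author weights 0.8/0.2, wrong-rank penalty 0.3, unmatched-text
penalty 0.1, per-part ED budget 2, threshold ratios 0.5 (MSL < 6) and
0.3334 (MSL ≥ 6), block cap 4, minimum reported OMS 0 ("match
accuracy" slider).  No parameter is fitted to data.

## Candidate tests

A candidate must pass the **maximum-ED test** — total ED across
compared components ≤ 2 × (number of name parts), rank indicators not
counted, so 4 for a binomial and 6 for a trinomial — and at least one
of:

* the **phonetic test**: every compared component phonetically equal;
* the **threshold test**, per component: ED ≤ 1 passes outright;
  2 ≤ ED ≤ 4 requires ED/MSL within the length-dependent ratio and a
  matching first character (first three characters when ED = 4);
  ED > 4 fails.

Two readings of the printed rules required a decision.  The threshold
conjunction as stated is unsatisfiable for ED ∈ {0, 1}, so small EDs
pass unconditionally — anything else would reject near-exact matches.
The maximum-ED budget is read as a bound on the whole-name total (one
number per name), not per component.

## Search

Candidates are found genus-first: a reference genus survives when it
is phonetically equal to the query genus or within ED 2 (the one-part
budget); species are compared only inside surviving genera, and
infraspecific names only under species whose epithet survived a
looser screen (phonetic equality or ED ≤ 4, the largest distance the
threshold test can ever accept).  All qualifying genera are searched,
not only the single best — the candidate set is defined to be
identical to a whole-database scan through the same per-component
screens, and the tests enforce that equivalence on randomized stores.
Genus-level records themselves enter the candidate list as partial
matches, so a species query can surface a genus when nothing survives
at species rank (and a family when no genus survives, if a family was
submitted).  A submitted family restricts candidate genera to that
family and is itself a scored component.

## Ranking, warnings, synonym resolution

Two rankings are always computed.  **Unconstrained:** descending SNMS,
then OMS, then taxonomic status (accepted < synonym ≡ illegitimate ≡
invalid < no_opinion), then canonical name alphabetically, then record
id — a total order, so output is independent of candidate order.
**Constrained by higher taxonomy:** candidates are compared on the
vector of per-component scores in taxonomic order (family if
submitted, genus, species, infraspecifics), then OMS, status, and the
same final tie-breaks; a perfect genus with an unmatched epithet
therefore outranks a one-edit species match.  Constrain-by-source, when
enabled, stably partitions either ranking by source priority, so a
low-scoring hit in the top source outranks a better hit elsewhere.

Warnings: `partial_match` (best match shallower than the submitted
rank); `ambiguous_match` (the top two candidates tie on every score
and status key; the alphabetical head is returned); and the paired
cross-ranking warnings — `better_higher_taxonomic_match_available` on
the unconstrained best when the constrained ranking prefers a
different record, and `better_spelling_match_in_different_higher_taxon`
on the constrained best when the unconstrained best has a higher OMS
in a different genus or family.  These are computed between the two
ranking heads, which is where the disagreement is defined.

The best match's status is reported and, for non-accepted matches, the
stored accepted name is attached (one hop, since chains were collapsed
at load).  The "parse names only" processing mode bypasses matching
and returns the parsed components.

## Synthetic data

The generator builds deterministic (per-seed) reference taxonomies of
pronounceable pseudo-Latin names — CV-syllable words, never real
genera, so no match can leak in from outside knowledge — arranged as
families > genera > species (> varieties), with a configurable synonym
fraction (synonyms point to accepted congeners), infraspecific
fraction, and cross-family homonym pairs that duplicate a genus and
species name verbatim in another family.  Epithets carry the
stemmable endings so ending-swap corruption is meaningful.

Names within one namespace (all family/genus names; the epithets of
one genus) are generated at pairwise MDLD ≥ 5 and with distinct
phonetic keys.  This separation is what makes recovery exact rather
than probabilistic: a corruption within the candidate-test budget (two
edits per component) stays strictly closer to its source than to any
other name, so the ground truth is the unique admissible answer.
Query corruption samples from an operation profile — substitution,
insertion, deletion, transposition, block transposition (never
touching the first character), ending swaps (phonetically silent,
nonzero ED), wrong rank indicators (the −0.3 case), all-caps,
pre-pended families, annotations, morphospecies codes — and records,
per query, the realized per-component EDs as measured by the engine's
own metric.

What the generator does **not** emulate, and therefore what passing
tests do not show about real data: realistic name-frequency and
length distributions; naturally occurring near-collisions between
real names (real floras contain congeners one edit apart, where a
misspelling is genuinely ambiguous); OCR frame shifts and vernacular
names; real homonymy structure beyond exact duplicates; authorship
variation beyond a small abbreviation dictionary.  Recovery rates on
fixtures are upper bounds for dirty real-world lists.

## Problem sizes and numerical choices

The test suite exercises: the full cross-product of string pairs up to
length 6 over a three-letter alphabet against the recursive
edit-distance oracle; fifty randomized stores of up to ~500 records
for search-equivalence; one hundred budget-bounded corrupted queries
for exact recovery; twenty randomized taxonomies (≤ 200 records) for
nested-set correctness.  These sizes give exhaustive or
high-multiplicity coverage of every code path at interactive runtimes.
Scores are compared to nine decimal places when testing ties (to
absorb float summation noise), rankings break final ties on canonical
name then record id, and degenerate inputs (empty components,
zero-length strings, absent authors) are defined explicitly rather
than left to fall through.

## Known limitations

* Hybrid formulas are flagged and truncated to the leading parent, not
  atomized.
* The author-abbreviation dictionary is a small built-in sample; the
  full standard abbreviation index is not shipped.
* One family classification at a time; conflicting synonymies across
  sources are kept separate, never reconciled.
* Exact lookup is authority-sensitive only when the query carries an
  author; there is no fuzzy author-based disambiguation of homonyms.
* The store is rebuilt in memory per run; there is no persistent
  database, by design — desk-scale batch jobs are the target.
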