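# nomenmatch

Batch standardization of scientific (plant) names against a reference
taxonomy, with no external database dependency.

Ecological plots, herbarium labels, trait tables and phylogeny tip
labels are full of misspelled genera, swapped epithet endings,
identification annotations ("cf.", "aff.", "Indet. sp. 21"), all-caps
strings and outdated synonyms.  Joining such data across studies
requires mapping every string to a single canonical, accepted name.
`nomenmatch` does that mapping: it cleans and parses each submitted
string, finds near matches in a reference taxonomy by modified edit
distance and phonetic equivalence, scores and ranks the candidates,
flags ambiguities, and converts synonyms to accepted names.

## The method

For each submitted name:

1. **Pre-processing** — a pre-pended family name is split off (by the
   standard `-aceae`/`-idae` endings or the conserved-family list),
   annotations and morphospecies/accession codes are removed, all-caps
   strings are case-corrected, and the cleaned string is matched
   exactly against the store (an exact hit scores 1.0 and skips fuzzy
   matching).
2. **Parsing** — the string is atomized into genus, specific and
   infraspecific epithets, rank indicators ("var.", "subsp.", "fo.")
   and authorship (basionym and combining authors).
3. **Fuzzy matching** — candidate reference names are found genus-first:
   genera passing a phonetic-equality or edit-distance screen are kept,
   and only their species (and those species' infraspecific taxa) are
   compared further.  Orthographic similarity uses a modified
   Damerau–Levenshtein distance (MDLD) in which a transposition of k
   adjacent characters costs k, so `vecusilosus` → `vesiculosus` is 2
   edits, not 4.  Phonetic equality uses a normalization tuned to
   latinized nomenclature, including stemming of the interchangeable
   epithet endings (-a, -is, -us, -ys, -es, -um, -as, -os).  Authorship
   is compared by a 2/3-bigram + 1/3-trigram n-gram similarity,
   averaged over a diacritic-sensitive and a diacritic-folded pass,
   with known author abbreviations expanded first.
4. **Scoring** — each name component gets a partial match score
   `PMS = 1 − 2·ED/MaxED` (minus 0.3 for a wrong rank indicator); the
   scientific-name score `SNMS = Σ PMS` is rescaled to [0, 1] by

   `SNMS_tr = atan((s·SNMS/k)^(2t+1)) / (2·atan(s^(2t+1))) + 0.5`

   (k = number of components; defaults s = 2, t = 1 give a
   double-logistic curve), and the overall match score blends in the
   author similarity: `OMS = 0.8·SNMS_tr + 0.2·AMS − p`, with p = 0.1
   when unmatched text remains.
5. **Candidate tests** — a candidate must pass the maximum-ED budget
   (total ED ≤ 2 × number of name parts) and either the phonetic test
   or the per-component threshold test (ED/MSL ≤ 0.5 for short
   components, ≤ 0.3334 otherwise, with leading-prefix requirements).
6. **Ranking & warnings** — survivors are ranked two ways (by whole-name
   score, and component-by-component starting at the highest taxon),
   optionally partitioned by source priority; ties, partial matches and
   conflicts between the two rankings produce explicit warnings; the
   matched name's accepted synonym-resolution target is attached.

## A worked example

`examples/resolve_messy_names.py` builds a ten-record reference store
and resolves five messy strings; it prints:

```
=== default (unconstrained) ranking ===
[1] 'Ficus insipida Willd.' -> Ficus insipida  (OMS 1.00, accepted)
[2] 'Fucus insipida' -> Ficus insipida  (OMS 0.96, accepted)
      warning: better_higher_taxonomic_match_available
[3] 'Chondrophora nudata fo. virgata' -> Chondrophora nudata var. virgata  (OMS 0.98, accepted)
[4] 'ASTERACEAE CF. CHONDROPHORA NUDATA' -> Chondrophora nudata  (OMS 1.00, accepted)
[5] 'Chondrophora virens' -> Chondrophora virens  (OMS 1.00, synonym)
      accepted name: Chondrophora nudata

=== constrained by higher taxonomy ===
[2] 'Fucus insipida' -> Fucus (OMS 0.50, partial=True)
      warning: better_spelling_match_in_different_higher_taxon
      warning: partial_match
```

Reading the numbers: `Fucus insipida` is one edit from the fig species
*Ficus insipida* (OMS 0.96) but exactly matches the brown-algal genus
*Fucus* at genus rank (OMS 0.50 — perfect genus, unmatched epithet).
The default ranking surfaces the best-spelled full name; constraining
by higher taxonomy surfaces the exactly-matching genus instead, and
the warnings record the disagreement.  The wrong rank indicator in
query 3 costs a 0.3 component penalty; the annotations, case and
family prefix in query 4 are removed before matching, leaving a
perfect hit.

The other examples show the matching primitives
(`examples/fuzzy_primitives.py`) and an exact, ground-truthed recovery
benchmark on a generated taxonomy (`examples/synthetic_benchmark.py`).

## Command line

```bash
nomenmatch makefixtures -d fx --species 60 --queries 100 --seed 7
nomenmatch resolve -i fx/queries.txt -r fx/reference.tsv -o results.csv
nomenmatch parse -i fx/queries.txt -o parsed.csv
nomenmatch validate -r fx/reference.tsv
nomenmatch loaddb -r fx/reference.tsv -o normalized.tsv
```

Reference taxonomies are UTF-8 TSV files with Simple-Darwin-Core-style
columns (`taxonID, scientificName, scientificNameAuthorship, taxonRank,
parentNameUsageID, acceptedNameUsageID, taxonomicStatus, family`);
name lists are one name per line, optionally `id<TAB>name`.  Output is
CSV with the run settings embedded as `#` header comments.  Scoring
constants and run settings can also be supplied as a YAML config
(`--config`), with command-line flags taking precedence.

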