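"""End-to-end name resolution against a tiny reference store.

Builds a ten-record reference taxonomy in memory, then resolves a
handful of messy submissions: an exact hit, a misspelled genus, a wrong
rank indicator, an annotated all-caps string, and a synonym.  For each
name it prints the best match, its overall match score (OMS, 0 = no
confidence, 1 = certain), the taxonomic status, the accepted name, and
any warnings.
"""

from nomenmatch import RunSettings, TaxonStore, resolve_names

ROWS = [
    dict(taxonID="f1", scientificName="Moraceae", scientificNameAuthorship="",
         taxonRank="family", parentNameUsageID="", acceptedNameUsageID="",
         taxonomicStatus="accepted", family="Moraceae"),
    dict(taxonID="f2", scientificName="Fucaceae", scientificNameAuthorship="",
         taxonRank="family", parentNameUsageID="", acceptedNameUsageID="",
         taxonomicStatus="accepted", family="Fucaceae"),
    dict(taxonID="f3", scientificName="Asteraceae", scientificNameAuthorship="",
         taxonRank="family", parentNameUsageID="", acceptedNameUsageID="",
         taxonomicStatus="accepted", family="Asteraceae"),
    dict(taxonID="g1", scientificName="Ficus", scientificNameAuthorship="L.",
         taxonRank="genus", parentNameUsageID="f1", acceptedNameUsageID="",
         taxonomicStatus="accepted", family="Moraceae"),
    dict(taxonID="g2", scientificName="Fucus", scientificNameAuthorship="L.",
         taxonRank="genus", parentNameUsageID="f2", acceptedNameUsageID="",
         taxonomicStatus="accepted", family="Fucaceae"),
    dict(taxonID="g3", scientificName="Chondrophora", scientificNameAuthorship="",
         taxonRank="genus", parentNameUsageID="f3", acceptedNameUsageID="",
         taxonomicStatus="accepted", family="Asteraceae"),
    dict(taxonID="s1", scientificName="Ficus insipida", scientificNameAuthorship="Willd.",
         taxonRank="species", parentNameUsageID="g1", acceptedNameUsageID="",
         taxonomicStatus="accepted", family="Moraceae"),
    dict(taxonID="s2", scientificName="Chondrophora nudata", scientificNameAuthorship="",
         taxonRank="species", parentNameUsageID="g3", acceptedNameUsageID="",
         taxonomicStatus="accepted", family="Asteraceae"),
    dict(taxonID="s3", scientificName="Chondrophora virens", scientificNameAuthorship="",
         taxonRank="species", parentNameUsageID="g3", acceptedNameUsageID="s2",
         taxonomicStatus="synonym", family="Asteraceae"),
    dict(taxonID="i1", scientificName="Chondrophora nudata var. virgata",
         scientificNameAuthorship="", taxonRank="variety", parentNameUsageID="s2",
         acceptedNameUsageID="", taxonomicStatus="accepted", family="Asteraceae"),
]

store = TaxonStore()
store.load_rows(ROWS, source_id="demo", priority=1)

queries = [
    (1, "Ficus insipida Willd."),        # exact, including the author
    (2, "Fucus insipida"),               # misspelled genus (or wrong genus?)
    (3, "Chondrophora nudata fo. virgata"),  # wrong rank indicator
    (4, "ASTERACEAE CF. CHONDROPHORA NUDATA"),  # all caps + annotation + family
    (5, "Chondrophora virens"),          # a synonym
]

print("=== default (unconstrained) ranking ===")
for result in resolve_names(queries, store):
    best = result.best
    line = f"[{result.submitted_id}] {result.submitted!r} -> "
    if best is None:
        print(line + "no match")
        continue
    print(line + f"{best.reference.canonical}  (OMS {best.oms:.2f}, "
          f"{result.status_of_match})")
    if result.status_of_match == "synonym":
        print(f"      accepted name: {result.accepted.canonical}")
    for warning in sorted(result.warnings):
        print(f"      warning: {warning}")

print()
print("=== constrained by higher taxonomy ===")
settings = RunSettings(constrain_by_higher_taxonomy=True)
for result in resolve_names([(2, "Fucus insipida")], store, settings=settings):
    best = result.best
    print(f"[2] {result.submitted!r} -> {best.reference.canonical} "
          f"(OMS {best.oms:.2f}, partial={best.is_partial})")
    for warning in sorted(result.warnings):
        print(f"      warning: {warning}")
print()
print("Unconstrained ranking favours the best-spelled full name;")
print("constraining by higher taxonomy favours the exactly-matching")
print("genus and reports the species part as unmatched (partial match).")
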