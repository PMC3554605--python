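"""Shared test fixtures data and independent oracles.

The oracles here deliberately avoid the implementation paths they check:
the edit-distance oracle is a memoized recursion on suffix pairs, the
ancestry oracle walks parent pointers, and the search oracle scans every
record in the store instead of descending the hierarchy.
"""

from __future__ import annotations

from nomenmatch.fuzzymatch import (
    _component,
    component_prefilter,
    genus_prefilter,
)
from nomenmatch.scoring import ScoringParams
from nomenmatch.taxondb import TaxonStore

# A tiny hand-written reference store: two families, the Ficus/Fucus
# near-homonym pair, one species, and a varietal with a synonym.
DEMO_ROWS = [
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


def make_demo_store() -> TaxonStore:
    store = TaxonStore()
    store.load_rows(DEMO_ROWS, source_id="demo", priority=1)
    return store


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------

_dl_memo: dict[tuple[str, str], int] = {}


def oracle_dl(a: str, b: str) -> int:
    """Exhaustive recursive Damerau-Levenshtein distance (memoized)."""
    key = (a, b)
    hit = _dl_memo.get(key)
    if hit is not None:
        return hit
    if not a:
        res = len(b)
    elif not b:
        res = len(a)
    else:
        res = min(
            oracle_dl(a[1:], b) + 1,
            oracle_dl(a, b[1:]) + 1,
            oracle_dl(a[1:], b[1:]) + (a[0] != b[0]),
        )
        if len(a) >= 2 and len(b) >= 2 and a[0] == b[1] and a[1] == b[0]:
            res = min(res, oracle_dl(a[2:], b[2:]) + 1)
    _dl_memo[key] = res
    return res


def ancestors_by_parent_pointer(store: TaxonStore, name_id: str) -> set[str]:
    """Ancestor set by walking parent pointers."""
    out = set()
    cur = store.get(name_id).parent_id
    while cur is not None:
        out.add(cur)
        cur = store.get(cur).parent_id
    return out


def descendants_by_parent_pointer(store: TaxonStore, name_id: str) -> set[str]:
    """Transitive closure over parent pointers, computed by brute force."""
    return {
        nid for nid in (r.name_id for r in store.records())
        if name_id in ancestors_by_parent_pointer(store, nid)
    }


def brute_force_search(parsed, store: TaxonStore, params: ScoringParams | None = None) -> set[str]:
    """Whole-database scan through the same per-component tests the
    hierarchical search applies; returns the candidate name_id set."""
    if params is None:
        params = ScoringParams()
    out: set[str] = set()

    def fam_ok(rec) -> bool:
        if not parsed.family:
            return True
        comp = _component("family", parsed.family, rec.family or "", epithet=False,
                          max_block=params.max_block)
        return genus_prefilter(comp, params)

    depth = sum(
        1 for v in (parsed.genus, parsed.specific_epithet,
                    parsed.infraspecific_epithet, parsed.infraspecific_epithet2)
        if v
    )
    for rec in store.records():
        if not fam_ok(rec):
            continue
        if rec.rank == "family":
            if depth == 0 and parsed.family:
                comp = _component("family", parsed.family, rec.family, epithet=False,
                                  max_block=params.max_block)
                if genus_prefilter(comp, params):
                    out.add(rec.name_id)
            continue
        if depth == 0:
            continue
        gcomp = _component("genus", parsed.genus, rec.genus, epithet=False,
                           max_block=params.max_block)
        if not genus_prefilter(gcomp, params):
            continue
        if rec.rank == "genus":
            out.add(rec.name_id)
            continue
        if depth < 2:
            continue
        scomp = _component("specific_epithet", parsed.specific_epithet,
                           rec.specific_epithet, epithet=True, max_block=params.max_block)
        if not component_prefilter(scomp, params):
            continue
        if rec.rank == "species":
            out.add(rec.name_id)
            continue
        if depth < 3:
            continue
        icomp = _component("infraspecific_epithet", parsed.infraspecific_epithet,
                           rec.infraspecific_epithet, epithet=True,
                           max_block=params.max_block)
        if component_prefilter(icomp, params):
            out.add(rec.name_id)
    return out
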