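"""Reference store: loading, validation, indexes, lookups."""

import random

import pytest

from helpers import DEMO_ROWS, descendants_by_parent_pointer

from nomenmatch.fixtures import FixtureSpec, generate_taxonomy
from nomenmatch.fuzzymatch import phonetic_key, stem_epithet
from nomenmatch.taxondb import ExchangeValidationError, TaxonStore

MINI_ROWS = [
    dict(taxonID="1", scientificName="Poaceae", scientificNameAuthorship="",
         taxonRank="family", parentNameUsageID="", acceptedNameUsageID="",
         taxonomicStatus="accepted", family="Poaceae"),
    dict(taxonID="2", scientificName="Poa", scientificNameAuthorship="L.",
         taxonRank="genus", parentNameUsageID="1", acceptedNameUsageID="",
         taxonomicStatus="accepted", family="Poaceae"),
    dict(taxonID="3", scientificName="Poa annua", scientificNameAuthorship="L.",
         taxonRank="species", parentNameUsageID="2", acceptedNameUsageID="",
         taxonomicStatus="accepted", family="Poaceae"),
    dict(taxonID="4", scientificName="Poa infirma", scientificNameAuthorship="Kunth",
         taxonRank="species", parentNameUsageID="2", acceptedNameUsageID="3",
         taxonomicStatus="synonym", family="Poaceae"),
    dict(taxonID="5", scientificName="Poa supina", scientificNameAuthorship="Schrad.",
         taxonRank="species", parentNameUsageID="2", acceptedNameUsageID="",
         taxonomicStatus="no_opinion", family="Poaceae"),
]


def _load(rows, source="src", priority=1):
    store = TaxonStore()
    store.load_rows(rows, source, priority)
    return store


class TestLoading:
    def test_mini_file_loads_and_resolves_synonym(self):
        store = _load(MINI_ROWS)
        assert len(store) == 5
        assert store.resolve_accepted("src:4").canonical == "Poa annua"

    def test_dangling_accepted_link_is_an_error(self):
        rows = [dict(MINI_ROWS[0]), dict(MINI_ROWS[1]),
                dict(MINI_ROWS[3], parentNameUsageID="2")]
        with pytest.raises(ExchangeValidationError, match="dangling acceptedNameUsageID"):
            _load(rows)

    def test_dangling_parent_is_an_error(self):
        rows = [dict(MINI_ROWS[2], parentNameUsageID="99")]
        with pytest.raises(ExchangeValidationError, match="dangling parentNameUsageID"):
            _load(rows)

    def test_duplicate_taxon_id_is_an_error(self):
        with pytest.raises(ExchangeValidationError, match="duplicate"):
            _load(MINI_ROWS + [dict(MINI_ROWS[2])])

    def test_unknown_rank_is_an_error(self):
        with pytest.raises(ExchangeValidationError, match="unknown taxonRank"):
            _load([dict(MINI_ROWS[0], taxonRank="kingdom")])

    def test_synonym_without_link_is_an_error(self):
        rows = [dict(MINI_ROWS[0]), dict(MINI_ROWS[1]),
                dict(MINI_ROWS[3], acceptedNameUsageID="")]
        with pytest.raises(ExchangeValidationError, match="requires acceptedNameUsageID"):
            _load(rows)

    def test_parent_cycle_is_an_error(self):
        rows = [
            dict(MINI_ROWS[0], parentNameUsageID="2"),
            dict(MINI_ROWS[1], parentNameUsageID="1"),
        ]
        with pytest.raises(ExchangeValidationError, match="cycle in parent chain"):
            _load(rows)

    def test_synonym_chain_collapses_to_final_accepted(self):
        rows = MINI_ROWS + [
            dict(taxonID="6", scientificName="Poa vetus", scientificNameAuthorship="",
                 taxonRank="species", parentNameUsageID="2", acceptedNameUsageID="4",
                 taxonomicStatus="synonym", family="Poaceae"),
        ]
        store = _load(rows)
        assert store.get("src:6").accepted_name_id == "src:3"
        assert store.resolve_accepted("src:6").canonical == "Poa annua"

    def test_fixture_taxonomy_loads_with_expected_count(self, fixture_store):
        assert len(fixture_store) == 63


class TestNestedSet:
    def test_intervals_well_formed(self, fixture_store):
        seen = set()
        for rec in fixture_store.records():
            left, right = fixture_store.bounds(rec.name_id)
            assert left < right
            seen.update([left, right])
        assert len(seen) == 2 * len(fixture_store)

    def test_leaf_has_no_descendants(self, fixture_store):
        leaves = [r for r in fixture_store.records() if r.rank == "species"]
        assert fixture_store.descendants(leaves[0].name_id) == set()

    def test_root_family_descends_to_everything_below(self, fixture_store):
        fam = fixture_store.families()[0]
        got = fixture_store.descendants(fam.name_id)
        assert got == descendants_by_parent_pointer(fixture_store, fam.name_id)

    @pytest.mark.parametrize("seed", range(100))
    def test_containment_equals_parent_reachability_on_random_trees(self, seed):
        rng = random.Random(seed)
        spec = FixtureSpec(
            n_families=rng.randint(1, 5),
            n_genera=rng.randint(1, 20),
            n_species=rng.randint(1, 120),
            synonym_fraction=rng.random() * 0.4,
            infraspecific_fraction=rng.random() * 0.4,
            seed=seed,
        )
        store = _load(generate_taxonomy(spec), "t")
        assert len(store) <= 200
        for rec in rng.sample(store.records(), min(6, len(store))):
            assert store.descendants(rec.name_id) == descendants_by_parent_pointer(
                store, rec.name_id
            )


class TestResolveAccepted:
    def test_accepted_is_itself(self):
        store = _load(MINI_ROWS)
        assert store.resolve_accepted("src:3").name_id == "src:3"

    def test_no_opinion_is_itself(self):
        store = _load(MINI_ROWS)
        rec = store.resolve_accepted("src:5")
        assert rec.name_id == "src:5"
        assert rec.status == "no_opinion"

    def test_unknown_id_raises(self):
        store = _load(MINI_ROWS)
        with pytest.raises(KeyError):
            store.resolve_accepted("src:99")


class TestExactLookup:
    def test_hit_and_near_miss(self):
        store = _load(MINI_ROWS)
        assert len(store.exact_lookup("Poa annua")) == 1
        assert store.exact_lookup("Poa annuaa") == []

    def test_author_filter(self):
        store = _load(MINI_ROWS)
        assert store.exact_lookup("Poa annua", author="L.")
        assert store.exact_lookup("Poa annua", author="Kunth") == []

    def test_homonym_across_sources_ordered_by_priority(self):
        store = TaxonStore()
        store.load_rows(MINI_ROWS, "secondary", 2)
        store.load_rows(MINI_ROWS, "primary", 1)
        hits = store.exact_lookup("Poa annua")
        assert [h.source_id for h in hits] == ["primary", "secondary"]


class TestIndexesAndRoundTrip:
    def test_phonetic_keys_match_recomputation(self, fixture_store):
        for rec in fixture_store.records():
            keys = fixture_store.phonetic_keys(rec.name_id)
            if rec.genus:
                assert keys["genus"] == phonetic_key(rec.genus)
            if rec.specific_epithet:
                assert keys["specific_epithet"] == phonetic_key(
                    rec.specific_epithet, epithet=True
                )
                assert fixture_store.stemmed_epithets(rec.name_id)[
                    "specific_epithet"
                ] == stem_epithet(rec.specific_epithet)

    def test_export_reload_roundtrip(self, tmp_path):
        store = _load(DEMO_ROWS, "demo")
        out = tmp_path / "export.tsv"
        store.export_exchange_file(out, "demo")
        reloaded = TaxonStore()
        reloaded.load_exchange_file(out, "demo", 1)
        originals = {r.name_id: r for r in store.records()}
        copies = {r.name_id: r for r in reloaded.records()}
        assert originals == copies
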