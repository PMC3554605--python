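import pytest

from helpers import make_demo_store

from nomenmatch.fixtures import FixtureSpec, generate_taxonomy
from nomenmatch.taxondb import TaxonStore


@pytest.fixture(scope="session")
def demo_store():
    """Hand-written 10-record store with the Ficus/Fucus pair."""
    return make_demo_store()


@pytest.fixture(scope="session")
def fixture_store():
    """Synthetic 3-family / 10-genus / 50-species taxonomy (63 records)."""
    spec = FixtureSpec(n_families=3, n_genera=10, n_species=50,
                       synonym_fraction=0.2, seed=42)
    store = TaxonStore()
    store.load_rows(generate_taxonomy(spec), source_id="fixture", priority=1)
    return store
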