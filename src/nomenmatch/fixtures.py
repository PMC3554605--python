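"""Synthetic reference taxonomies and ground-truthed corrupted queries.

Everything the engine consumes can be generated here deterministically
from a seed: a hierarchical reference taxonomy (families > genera >
species > infraspecific taxa) of pronounceable pseudo-Latin names with a
configurable fraction of synonyms and optional cross-family homonym
pairs, plus query strings derived from known records by controlled
corruption — misspellings of a known edit distance, swapped epithet
endings, wrong rank indicators, all-caps, pre-pended family names,
identification annotations and morphospecies codes.  Each query carries
the identity of the record it was derived from, so end-to-end recovery
can be measured exactly.

Generated names are random syllable strings, deliberately not real
genera, so matches can never leak in from outside knowledge.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence, Union

from .fuzzymatch import mdld
from .taxondb import EXCHANGE_COLUMNS, ReferenceName, TaxonStore

__all__ = [
    "FixtureSpec",
    "GroundTruthQuery",
    "generate_taxonomy",
    "write_exchange",
    "corrupt",
    "generate_queries",
    "write_fixture_set",
    "CORRUPTION_OPS",
]

CORRUPTION_OPS = (
    "substitute", "insert", "delete", "transpose", "block_transpose",
    "ending_swap", "rank_indicator_swap", "all_caps", "prepend_family",
    "append_annotation", "append_morphospecies",
)

_CONSONANTS = "bcdfglmnprstv"
_VOWELS = "aeiou"
_EPITHET_ENDINGS = ("a", "us", "um", "is")
_STEM_SWAP = ("a", "is", "us", "es", "um", "os")


@dataclass
class FixtureSpec:
    """Parameters of one synthetic taxonomy + query set."""

    n_families: int = 3
    n_genera: int = 10
    n_species: int = 50
    synonym_fraction: float = 0.2
    infraspecific_fraction: float = 0.0
    homonym_pairs: int = 0
    corruption_profile: list[tuple[str, float]] = field(
        default_factory=lambda: [("substitute", 0.5), ("transpose", 0.3)]
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_families, self.n_genera, self.n_species) < 1:
            raise ValueError("all counts must be >= 1")
        if not 0.0 <= self.synonym_fraction <= 1.0:
            raise ValueError("synonym_fraction must be in [0, 1]")
        if not 0.0 <= self.infraspecific_fraction <= 1.0:
            raise ValueError("infraspecific_fraction must be in [0, 1]")
        if self.homonym_pairs > self.n_species // 2:
            raise ValueError("homonym_pairs may not exceed n_species / 2")
        for op, p in self.corruption_profile:
            if op not in CORRUPTION_OPS:
                raise ValueError(f"unknown corruption op {op!r}")
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")


@dataclass
class GroundTruthQuery:
    """A corrupted query string with its provenance."""

    raw: str
    true_taxon_id: str
    applied_operations: list[str]
    intended_ed: int
    component_eds: dict[str, int] = field(default_factory=dict)


def _syllable(rng: random.Random) -> str:
    s = rng.choice(_CONSONANTS) + rng.choice(_VOWELS)
    if rng.random() < 0.2:
        s += rng.choice("nrst")
    return s


def _word(rng: random.Random, n_syllables: int) -> str:
    return "".join(_syllable(rng) for _ in range(n_syllables))


# Generated names within one namespace (all genera; the epithets of one
# genus) are kept at least this far apart, so a corruption within the
# candidate-test budget can never land closer to a neighbour than to the
# name it came from.
_MIN_SEPARATION = 5


def _too_close(a: str, b: str) -> bool:
    # cheap lower bounds before the full distance
    if abs(len(a) - len(b)) >= _MIN_SEPARATION:
        return False
    bag = 0
    for ch in set(a) | set(b):
        bag += abs(a.count(ch) - b.count(ch))
    if max(abs(len(a) - len(b)), bag // 2) >= _MIN_SEPARATION:
        return False
    return mdld(a, b) < _MIN_SEPARATION


def _unique(make, taken: set[str], rng: random.Random) -> str:
    from .fuzzymatch import phonetic_key

    keys = {phonetic_key(w) for w in taken}
    for _ in range(5000):
        w = make()
        if w in taken or phonetic_key(w) in keys:
            continue
        if any(_too_close(w.lower(), other.lower()) for other in taken):
            continue
        taken.add(w)
        return w
    raise RuntimeError("could not generate a unique, well-separated name")


def generate_taxonomy(spec: FixtureSpec) -> list[dict[str, str]]:
    """Generate exchange-format rows for a synthetic taxonomy.

    Deterministic per seed.  Record counts: ``n_families + n_genera +
    n_species`` plus one variety per selected species and two extra
    records (genus + species) per homonym pair.
    """
    rng = random.Random(spec.seed)
    taken: set[str] = set()
    rows: list[dict[str, str]] = []

    def row(tid, name, author, rank, parent, accepted, status, family):
        rows.append({
            "taxonID": tid, "scientificName": name,
            "scientificNameAuthorship": author, "taxonRank": rank,
            "parentNameUsageID": parent, "acceptedNameUsageID": accepted,
            "taxonomicStatus": status, "family": family,
        })

    families = []
    for i in range(spec.n_families):
        name = _unique(lambda: _word(rng, 3).capitalize() + "aceae", taken, rng)
        families.append((f"f{i + 1}", name))
        row(f"f{i + 1}", name, "", "family", "", "", "accepted", name)

    genera = []
    for i in range(spec.n_genera):
        fam_id, fam_name = families[i % spec.n_families]
        name = _unique(lambda: _word(rng, 3).capitalize(), taken, rng)
        genera.append((f"g{i + 1}", name, fam_name))
        row(f"g{i + 1}", name, "", "genus", fam_id, "", "accepted", fam_name)

    n_synonyms = int(spec.synonym_fraction * spec.n_species)
    species = []
    epithets_by_genus: dict[str, set[str]] = {}
    for i in range(spec.n_species):
        gen_id, gen_name, fam_name = genera[i % spec.n_genera]
        pool = epithets_by_genus.setdefault(gen_id, set())
        epithet = _unique(
            lambda: _word(rng, 3) + rng.choice(_EPITHET_ENDINGS),
            pool, rng,
        )
        author = rng.choice(["L.", "Benth.", "Kunth", "DC.", "Mart.", ""])
        species.append((f"s{i + 1}", gen_id, gen_name, fam_name, epithet, author))
    accepted_species = species[n_synonyms:]
    if not accepted_species:
        accepted_species = species
        n_synonyms = 0
    for idx, (sid, gen_id, gen_name, fam_name, epithet, author) in enumerate(species):
        if idx < n_synonyms:
            congeners = [s for s in accepted_species if s[1] == gen_id]
            target = rng.choice(congeners or accepted_species)
            row(sid, f"{gen_name} {epithet}", author, "species",
                gen_id, target[0], "synonym", fam_name)
        else:
            row(sid, f"{gen_name} {epithet}", author, "species",
                gen_id, "", "accepted", fam_name)

    n_infra = int(spec.infraspecific_fraction * len(accepted_species))
    for j in range(n_infra):
        sid, gen_id, gen_name, fam_name, epithet, author = accepted_species[j]
        pool = epithets_by_genus[gen_id]
        infra = _unique(
            lambda: _word(rng, 3) + rng.choice(_EPITHET_ENDINGS), pool, rng
        )
        row(f"i{j + 1}", f"{gen_name} {epithet} var. {infra}", author,
            "variety", sid, "", "accepted", fam_name)

    for h in range(spec.homonym_pairs):
        sid, gen_id, gen_name, fam_name, epithet, author = accepted_species[
            h % len(accepted_species)
        ]
        other = rng.choice([f for f in families if f[1] != fam_name] or families)
        row(f"h{h + 1}g", gen_name, "", "genus", other[0], "", "accepted", other[1])
        row(f"h{h + 1}s", f"{gen_name} {epithet}", "Raf.", "species",
            f"h{h + 1}g", "", "accepted", other[1])

    return rows


def write_exchange(rows: Sequence[dict[str, str]], path: Union[str, Path]) -> None:
    """Write exchange rows as the UTF-8 TSV the loader consumes."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write("\t".join(EXCHANGE_COLUMNS) + "\n")
        for r in rows:
            fh.write("\t".join(r[c] for c in EXCHANGE_COLUMNS) + "\n")


# ---------------------------------------------------------------------------
# Corruption
# ---------------------------------------------------------------------------

def _edit_component(word: str, op: str, rng: random.Random) -> str:
    """Apply one character-level edit, never touching the first character."""
    if op == "substitute":
        if len(word) < 2:
            return word
        pos = rng.randrange(1, len(word))
        alt = rng.choice([c for c in _CONSONANTS + _VOWELS if c != word[pos]])
        return word[:pos] + alt + word[pos + 1:]
    if op == "insert":
        pos = rng.randrange(1, len(word) + 1)
        return word[:pos] + rng.choice(_CONSONANTS + _VOWELS) + word[pos:]
    if op == "delete":
        if len(word) < 4:
            return word
        pos = rng.randrange(1, len(word))
        return word[:pos] + word[pos + 1:]
    if op == "transpose":
        pairs = [i for i in range(1, len(word) - 1) if word[i] != word[i + 1]]
        if not pairs:
            return word
        i = rng.choice(pairs)
        return word[:i] + word[i + 1] + word[i] + word[i + 2:]
    if op == "block_transpose":
        if len(word) < 6:
            return word
        i = rng.randrange(1, len(word) - 3)
        a, b = word[i:i + 2], word[i + 2:i + 4]
        if a == b:
            return word
        return word[:i] + b + a + word[i + 4:]
    raise ValueError(f"not a character-level op: {op}")


def corrupt(
    name: ReferenceName,
    profile: Sequence[tuple[str, float]],
    seed: Union[int, random.Random],
) -> GroundTruthQuery:
    """Corrupt one reference name according to a sampled operation profile.

    Character-level edits are applied to a randomly chosen component,
    ``ending_swap`` exchanges one stemmable epithet ending for another
    (a phonetically equal, nonzero-ED variant), ``rank_indicator_swap``
    replaces the infraspecific rank indicator, and the remaining
    operations decorate the assembled string.  ``intended_ed`` is the
    realized edit distance, re-measured per component with the engine's
    own metric.
    """
    rng = seed if isinstance(seed, random.Random) else random.Random(seed)
    parts = {
        "genus": name.genus,
        "specific_epithet": name.specific_epithet,
        "infraspecific_epithet": name.infraspecific_epithet,
    }
    originals = dict(parts)
    indicator = name.infra_rank_indicator
    applied: list[str] = []
    decorations: list[str] = []
    for op, p in profile:
        if rng.random() >= p:
            continue
        if op in ("substitute", "insert", "delete", "transpose", "block_transpose"):
            editable = [k for k, v in parts.items() if v]
            comp = rng.choice(editable)
            edited = _edit_component(parts[comp], op, rng)
            if edited != parts[comp]:
                parts[comp] = edited
                applied.append(f"{op}:{comp}")
        elif op == "ending_swap":
            for comp in ("infraspecific_epithet", "specific_epithet"):
                word = parts[comp]
                for end in _STEM_SWAP:
                    if word and word.endswith(end) and len(word) - len(end) >= 2:
                        new_end = rng.choice([e for e in _STEM_SWAP if e != end])
                        parts[comp] = word[: -len(end)] + new_end
                        applied.append(f"ending_swap:{comp}")
                        break
                else:
                    continue
                break
        elif op == "rank_indicator_swap" and indicator:
            indicator = rng.choice([i for i in ("var.", "subsp.", "fo.") if i != indicator])
            applied.append("rank_indicator_swap")
        elif op in ("all_caps", "prepend_family", "append_annotation", "append_morphospecies"):
            decorations.append(op)

    tokens = [parts["genus"]]
    if "append_annotation" in decorations:
        tokens.append("cf.")
        applied.append("append_annotation")
    if parts["specific_epithet"]:
        tokens.append(parts["specific_epithet"])
    if parts["infraspecific_epithet"]:
        tokens.extend([indicator, parts["infraspecific_epithet"]])
    if "append_morphospecies" in decorations and not parts["specific_epithet"]:
        tokens.extend(["sp.", str(rng.randint(1, 99))])
        applied.append("append_morphospecies")
    raw = " ".join(t for t in tokens if t)
    if "prepend_family" in decorations and name.family:
        raw = f"{name.family} {raw}"
        applied.append("prepend_family")
    if "all_caps" in decorations:
        raw = raw.upper()
        applied.append("all_caps")

    component_eds = {
        k: mdld(parts[k], originals[k])
        for k in parts
        if originals[k] or parts[k]
    }
    return GroundTruthQuery(
        raw=raw,
        true_taxon_id=name.taxon_id,
        applied_operations=applied,
        intended_ed=sum(component_eds.values()),
        component_eds=component_eds,
    )


def generate_queries(
    records: Sequence[ReferenceName],
    profile: Sequence[tuple[str, float]],
    n: int,
    seed: int,
) -> list[GroundTruthQuery]:
    """Draw n corrupted queries from the species-or-deeper records."""
    rng = random.Random(seed)
    pool = [r for r in records if r.rank not in ("family", "genus")]
    if not pool:
        pool = list(records)
    return [corrupt(rng.choice(pool), profile, rng) for _ in range(n)]


def write_fixture_set(
    outdir: Union[str, Path],
    spec: FixtureSpec,
    n_queries: int = 100,
) -> dict[str, Path]:
    """Write a complete fixture set: reference TSV, query list, ground truth.

    Returns the paths of the three files (``reference.tsv``,
    ``queries.txt`` with ``id<TAB>name`` lines, ``truth.tsv``).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = generate_taxonomy(spec)
    ref_path = outdir / "reference.tsv"
    write_exchange(rows, ref_path)
    store = TaxonStore()
    store.load_rows(rows, source_id="fixture", priority=1)
    queries = generate_queries(store.records(), spec.corruption_profile,
                               n_queries, spec.seed + 1)
    q_path = outdir / "queries.txt"
    t_path = outdir / "truth.tsv"
    with open(q_path, "w", encoding="utf-8") as fh:
        for i, q in enumerate(queries, start=1):
            fh.write(f"{i}\t{q.raw}\n")
    with open(t_path, "w", encoding="utf-8") as fh:
        fh.write("query_id\ttrue_taxonID\toperations\tintended_ed\n")
        for i, q in enumerate(queries, start=1):
            fh.write(f"{i}\t{q.true_taxon_id}\t{';'.join(q.applied_operations)}\t{q.intended_ed}\n")
    return {"reference": ref_path, "queries": q_path, "truth": t_path}
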