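"""Fuzzy-matching core for scientific names.

This module implements the orthographic and phonetic near-match machinery
used to compare a submitted name component (genus, epithet, ...) against a
reference taxonomy:

* a modified Damerau-Levenshtein edit distance (:func:`mdld`) that, in
  addition to the classic single-character operations and adjacent
  transpositions, permits transpositions of *blocks* of adjacent characters
  at a cost equal to the length of the longer block — so a syllable swap
  like ``vecusilosus`` / ``vesiculosus`` costs 2 rather than 4;
* epithet stemming (:func:`stem_epithet`) that folds the interchangeable
  Latin gender/case endings (-us, -um, -is, ...) to a single form;
* a phonetic key (:func:`phonetic_key`) under which names that sound alike
  under the lexical conventions of latinized nomenclature compare equal;
* an n-gram author-string similarity (:func:`author_similarity`) blending
  bigram and trigram overlap, computed on both the original and the
  diacritic-folded strings;
* the genus-first hierarchical candidate search
  (:func:`hierarchical_search`) that narrows the reference store to
  plausible genera before comparing epithets.
"""

from __future__ import annotations

import unicodedata
from dataclasses import dataclass
from importlib import resources
from typing import Optional, Sequence

from .nameparse import ParsedName
from .scoring import MatchScores, ScoringParams
from .taxondb import ReferenceName, TaxonStore

__all__ = [
    "mdld",
    "classic_dl",
    "stem_epithet",
    "phonetic_key",
    "fold_diacritics",
    "author_similarity",
    "hierarchical_search",
    "AuthorScore",
    "ComponentComparison",
    "CandidateMatch",
    "load_phonetic_table",
    "load_abbreviations",
]


# ---------------------------------------------------------------------------
# Edit distances
# ---------------------------------------------------------------------------

def mdld(a: str, b: str, max_block: int = 4) -> int:
    """Modified Damerau-Levenshtein distance with block transpositions.

    Single-character insertions, deletions and substitutions cost 1.  A
    transposition of two adjacent blocks of ``k1`` and ``k2`` characters
    costs ``max(k1, k2)`` (so the classic adjacent-character transposition
    is the ``k1 = k2 = 1`` case).  Block length is capped at ``max_block``.
    Comparison is case-insensitive and symmetric.
    """
    a = a.lower()
    b = b.lower()
    n, m = len(a), len(b)
    if n == 0:
        return m
    if m == 0:
        return n
    # d[i][j] = distance between a[:i] and b[:j]
    d = [[0] * (m + 1) for _ in range(n + 1)]
    for i in range(n + 1):
        d[i][0] = i
    for j in range(m + 1):
        d[0][j] = j
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            best = min(
                d[i - 1][j] + 1,
                d[i][j - 1] + 1,
                d[i - 1][j - 1] + (a[i - 1] != b[j - 1]),
            )
            # block transposition: a[:i] ends in X Y while b[:j] ends in Y X
            for k1 in range(1, max_block + 1):
                if best <= 1:
                    break
                for k2 in range(1, max_block + 1):
                    if i < k1 + k2 or j < k1 + k2:
                        break
                    cost = max(k1, k2)
                    if d[i - k1 - k2][j - k1 - k2] + cost >= best:
                        continue
                    if (
                        a[i - k1 - k2 : i - k2] == b[j - k1 : j]
                        and a[i - k2 : i] == b[j - k1 - k2 : j - k1]
                    ):
                        best = d[i - k1 - k2][j - k1 - k2] + cost
            d[i][j] = best
    return d[n][m]


def classic_dl(a: str, b: str) -> int:
    """Damerau-Levenshtein distance with single-character transpositions.

    The textbook dynamic program (optimal string alignment): insertions,
    deletions, substitutions and adjacent-pair transpositions, all cost 1.
    Case-insensitive.  Serves as an upper bound for :func:`mdld`.
    """
    a = a.lower()
    b = b.lower()
    n, m = len(a), len(b)
    if n == 0:
        return m
    if m == 0:
        return n
    d = [[0] * (m + 1) for _ in range(n + 1)]
    for i in range(n + 1):
        d[i][0] = i
    for j in range(m + 1):
        d[0][j] = j
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            best = min(
                d[i - 1][j] + 1,
                d[i][j - 1] + 1,
                d[i - 1][j - 1] + (a[i - 1] != b[j - 1]),
            )
            if (
                i > 1
                and j > 1
                and a[i - 1] == b[j - 2]
                and a[i - 2] == b[j - 1]
            ):
                best = min(best, d[i - 2][j - 2] + 1)
            d[i][j] = best
    return d[n][m]


# ---------------------------------------------------------------------------
# Phonetic normalization and stemming
# ---------------------------------------------------------------------------

_STEM_ENDINGS = ("is", "us", "ys", "es", "um", "as", "os")


def stem_epithet(epithet: str) -> str:
    """Fold interchangeable Latin epithet endings to ``-a``.

    The endings -a, -is, -us, -ys, -es, -um, -as and -os are treated as
    equivalent; all are rewritten to -a, so "nitidus", "nitidum" and
    "nitida" share one stem.  Only one trailing ending is replaced and a
    minimum stem of two characters is required, making the operation
    idempotent.
    """
    if not epithet:
        return epithet
    for end in _STEM_ENDINGS:
        if epithet.endswith(end) and len(epithet) - len(end) >= 2:
            return epithet[: -len(end)] + "a"
    return epithet


def fold_diacritics(text: str) -> str:
    """Strip diacritical marks (é -> e) via Unicode canonical decomposition."""
    decomposed = unicodedata.normalize("NFKD", text)
    return "".join(c for c in decomposed if not unicodedata.combining(c))


def _read_rules(name: str) -> list[tuple[str, str]]:
    rules = []
    text = resources.files("nomenmatch.data").joinpath(name).read_text("utf-8")
    for line in text.splitlines():
        line = line.rstrip()
        if not line or line.startswith("#"):
            continue
        pattern, _, replacement = line.partition("\t")
        rules.append((pattern, replacement))
    return rules


def load_phonetic_table(path: Optional[str] = None) -> list[tuple[str, str]]:
    """Load phonetic substitution rules (built-in table by default).

    Each rule is ``(pattern, replacement)``; a leading ``^`` anchors the
    pattern to the start of the string.
    """
    if path is None:
        return _read_rules("phonetic_table.txt")
    rules = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip()
            if not line or line.startswith("#"):
                continue
            pattern, _, replacement = line.partition("\t")
            rules.append((pattern, replacement))
    return rules


_DEFAULT_TABLE = load_phonetic_table()


def phonetic_key(
    component: str,
    *,
    epithet: bool = False,
    table: Optional[list[tuple[str, str]]] = None,
) -> str:
    """Reduce a name component to its phonetic key.

    Two components are considered phonetically equal iff their keys are
    identical.  The key is built by lower-casing, folding diacritics,
    stemming (epithets only), applying the substitution table (anchored
    rules once, the rest to a fixed point), replacing non-initial "ch"
    with "c", and collapsing runs of repeated letters.
    """
    if table is None:
        table = _DEFAULT_TABLE
    s = fold_diacritics(component).lower()
    s = "".join(c for c in s if c.isalpha())
    if not s:
        return s
    if epithet:
        s = stem_epithet(s)
    for pattern, replacement in table:
        if pattern.startswith("^"):
            head = pattern[1:]
            if s.startswith(head):
                s = replacement + s[len(head) :]
    unanchored = [(p, r) for p, r in table if not p.startswith("^")]
    while True:
        prev = s
        for pattern, replacement in unanchored:
            s = s.replace(pattern, replacement)
        # "ch" simplifies to "c" only when not word-initial
        s = s[0] + s[1:].replace("ch", "c")
        if s == prev:
            break
    collapsed = []
    for c in s:
        if not collapsed or collapsed[-1] != c:
            collapsed.append(c)
    return "".join(collapsed)


# ---------------------------------------------------------------------------
# Author similarity
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AuthorScore:
    """Blended n-gram similarity between two authority strings."""

    ams: float
    utf8_similarity: float
    ascii_similarity: float


def load_abbreviations(path: Optional[str] = None) -> dict[str, str]:
    """Load the author-abbreviation dictionary (built-in sample by default)."""
    rules = _read_rules("author_abbreviations.txt") if path is None else load_phonetic_table(path)
    return dict(rules)


_DEFAULT_ABBREVIATIONS = load_abbreviations()


def _author_tokens(text: str, abbreviations: dict[str, str]) -> list[str]:
    tokens: list[str] = []
    for raw in text.split():
        expanded = abbreviations.get(raw, raw)
        for part in expanded.split():
            cleaned = "".join(c for c in part if c.isalpha())
            if cleaned:
                tokens.append(cleaned.lower())
    return tokens


def _ngrams(tokens: Sequence[str], n: int) -> list[str]:
    # no padding; a token shorter than n contributes itself as one gram
    grams: list[str] = []
    for tok in tokens:
        if len(tok) < n:
            grams.append(tok)
        else:
            grams.extend(tok[i : i + n] for i in range(len(tok) - n + 1))
    return grams


def _dice(grams_a: list[str], grams_b: list[str]) -> float:
    if not grams_a and not grams_b:
        return 1.0
    if not grams_a or not grams_b:
        return 0.0
    counts: dict[str, int] = {}
    for g in grams_a:
        counts[g] = counts.get(g, 0) + 1
    shared = 0
    for g in grams_b:
        if counts.get(g, 0) > 0:
            counts[g] -= 1
            shared += 1
    return 2.0 * shared / (len(grams_a) + len(grams_b))


def ngram_similarity(a: str, b: str, abbreviations: Optional[dict[str, str]] = None) -> float:
    """Blended 2/3-bigram + 1/3-trigram Dice similarity of two author strings."""
    if abbreviations is None:
        abbreviations = _DEFAULT_ABBREVIATIONS
    ta = _author_tokens(a, abbreviations)
    tb = _author_tokens(b, abbreviations)
    bi = _dice(_ngrams(ta, 2), _ngrams(tb, 2))
    tri = _dice(_ngrams(ta, 3), _ngrams(tb, 3))
    return (2.0 * bi + tri) / 3.0


def author_similarity(
    a: str,
    b: str,
    abbreviations: Optional[dict[str, str]] = None,
) -> Optional[AuthorScore]:
    """Author match score between two authority strings.

    The blended n-gram similarity is computed twice — on the original
    strings and on their diacritic-folded versions — and averaged, so
    that spellings differing only in accents score high but not perfect.
    Known author abbreviations are expanded before comparison.  Returns
    ``None`` when either string is empty (no author comparison possible).
    """
    if not a.strip() or not b.strip():
        return None
    if abbreviations is None:
        abbreviations = _DEFAULT_ABBREVIATIONS
    utf8 = ngram_similarity(a, b, abbreviations)
    folded = ngram_similarity(fold_diacritics(a), fold_diacritics(b), abbreviations)
    return AuthorScore(ams=(utf8 + folded) / 2.0, utf8_similarity=utf8, ascii_similarity=folded)


# ---------------------------------------------------------------------------
# Candidate search
# ---------------------------------------------------------------------------

@dataclass
class ComponentComparison:
    """Outcome of comparing one name component of query vs. reference."""

    component: str  # "family" | "genus" | "specific_epithet" | "infraspecific_epithet" | "infra2_epithet"
    query: str
    reference: str
    ed: Optional[int]  # None when the query component has no counterpart
    max_ed: int
    msl: int
    phonetic_equal: bool
    wrong_rank_indicator: bool = False

    @property
    def unmatched(self) -> bool:
        return self.ed is None


@dataclass
class CandidateMatch:
    """One reference name considered as a match for a submitted name."""

    reference: ReferenceName
    per_component: list[ComponentComparison]
    source_id: str
    is_partial: bool = False
    ams: Optional[float] = None
    query_has_unmatched_text: bool = False
    scores: Optional[MatchScores] = None
    passed_phonetic: bool = False
    passed_max_ed: bool = False
    passed_threshold: bool = False
    forced_exact: bool = False  # pre-parse whole-string exact hit

    @property
    def total_ed(self) -> int:
        return sum(c.ed for c in self.per_component if c.ed is not None)

    @property
    def oms(self) -> float:
        return self.scores.oms if self.scores is not None else 0.0


def _component(
    name: str, query: str, reference: str, *, epithet: bool, wrong_rank: bool = False,
    max_block: int = 4,
) -> ComponentComparison:
    ed = mdld(query, reference, max_block=max_block)
    return ComponentComparison(
        component=name,
        query=query,
        reference=reference,
        ed=ed,
        max_ed=max(len(query), len(reference)),
        msl=min(len(query), len(reference)),
        phonetic_equal=phonetic_key(query, epithet=epithet)
        == phonetic_key(reference, epithet=epithet),
        wrong_rank_indicator=wrong_rank,
    )


def _unmatched(name: str, query: str) -> ComponentComparison:
    return ComponentComparison(
        component=name, query=query, reference="", ed=None,
        max_ed=max(len(query), 1), msl=max(len(query), 1), phonetic_equal=False,
    )


def component_prefilter(comp: ComponentComparison, params: ScoringParams) -> bool:
    """Search-stage retention test for one compared component.

    A component survives if it is phonetically equal or its edit distance
    does not exceed twice the per-part budget (the largest distance the
    downstream match-threshold test can ever accept).
    """
    if comp.phonetic_equal:
        return True
    assert comp.ed is not None
    return comp.ed <= 2 * params.max_ed_per_part


def genus_prefilter(comp: ComponentComparison, params: ScoringParams) -> bool:
    """Genus-stage retention: phonetically equal or within the one-part budget."""
    if comp.phonetic_equal:
        return True
    assert comp.ed is not None
    return comp.ed <= params.max_ed_per_part


def _query_parts(parsed: ParsedName) -> list[tuple[str, str, bool]]:
    """Ordered (component name, query text, is_epithet) parts of the query."""
    parts: list[tuple[str, str, bool]] = []
    if parsed.genus:
        parts.append(("genus", parsed.genus, False))
    if parsed.specific_epithet:
        parts.append(("specific_epithet", parsed.specific_epithet, True))
    if parsed.infraspecific_epithet:
        parts.append(("infraspecific_epithet", parsed.infraspecific_epithet, True))
    if parsed.infraspecific_epithet2:
        parts.append(("infra2_epithet", parsed.infraspecific_epithet2, True))
    return parts


def _candidate_for(
    parsed: ParsedName,
    ref: ReferenceName,
    comparisons: list[ComponentComparison],
    depth: int,
    query_depth: int,
    params: ScoringParams,
) -> CandidateMatch:
    comps = list(comparisons)
    # query components deeper than the reference remain unmatched
    parts = _query_parts(parsed)
    for name, text, _ in parts[depth:]:
        comps.append(_unmatched(name, text))
    ams = None
    if parsed.author and ref.author:
        score = author_similarity(parsed.author, ref.author)
        if score is not None:
            ams = score.ams
    return CandidateMatch(
        reference=ref,
        per_component=comps,
        source_id=ref.source_id,
        is_partial=depth < query_depth,
        ams=ams,
        query_has_unmatched_text=bool(parsed.unmatched_text),
    )


def hierarchical_search(
    parsed: ParsedName,
    db: TaxonStore,
    params: Optional[ScoringParams] = None,
) -> list[CandidateMatch]:
    """Genus-first hierarchical candidate search.

    Reference genera are screened first (phonetic equality or a small
    edit-distance budget); species are then compared only within the
    surviving genera, and infraspecific names only under surviving
    species.  Matches at every depth up to the submitted rank are
    returned, so a species-rank query can yield both full species
    matches and genus-level partial matches.  A submitted family
    restricts candidate genera to that family.
    """
    if params is None:
        params = ScoringParams()
    candidates: list[CandidateMatch] = []
    parts = _query_parts(parsed)
    query_depth = len(parts)

    family_comp: Optional[ComponentComparison] = None
    allowed_families: Optional[set[str]] = None
    if parsed.family:
        allowed_families = set()
        for fam in db.families():
            comp = _component("family", parsed.family, fam.family or fam.canonical,
                              epithet=False, max_block=params.max_block)
            if genus_prefilter(comp, params):
                allowed_families.add((fam.family or fam.canonical).lower())
                if query_depth == 0:
                    candidates.append(
                        _candidate_for(parsed, fam, [comp], 0, 0, params)
                    )
    if query_depth == 0:
        return candidates

    # stage 1: genera
    surviving: list[tuple[ReferenceName, list[ComponentComparison]]] = []
    genus_name, genus_text, _ = parts[0]
    for gen in db.genera():
        if allowed_families is not None and (gen.family or "").lower() not in allowed_families:
            continue
        comp = _component(genus_name, genus_text, gen.genus or gen.canonical,
                          epithet=False, max_block=params.max_block)
        if not genus_prefilter(comp, params):
            continue
        comps = [comp]
        if parsed.family and family_comp is None:
            fam_cmp = _component("family", parsed.family, gen.family or "",
                                 epithet=False, max_block=params.max_block)
            comps = [fam_cmp, comp]
        if gen.rank == "genus":
            surviving.append((gen, comps))
            candidates.append(
                _candidate_for(parsed, gen, comps, 1, query_depth, params)
            )

    if query_depth == 1:
        return candidates

    # stage 2 and 3: species within surviving genera, infraspecifics below
    for gen, gcomps in surviving:
        for sp in db.species_of(gen.name_id):
            comp = _component(parts[1][0], parts[1][1], sp.specific_epithet,
                              epithet=True, max_block=params.max_block)
            if not component_prefilter(comp, params):
                continue
            scomps = gcomps + [comp]
            candidates.append(
                _candidate_for(parsed, sp, scomps, 2, query_depth, params)
            )
            if query_depth < 3:
                continue
            for infra in db.infraspecifics_of(sp.name_id):
                icmp = _component(
                    parts[2][0], parts[2][1], infra.infraspecific_epithet,
                    epithet=True,
                    wrong_rank=bool(parsed.rank_indicator)
                    and parsed.rank_indicator != infra.infra_rank_indicator,
                    max_block=params.max_block,
                )
                if not component_prefilter(icmp, params):
                    continue
                icomps = scomps[:-1] + [
                    _component(parts[1][0], parts[1][1], infra.specific_epithet,
                               epithet=True, max_block=params.max_block),
                    icmp,
                ]
                if query_depth >= 4 and infra.infra2_epithet:
                    i2 = _component(
                        parts[3][0], parts[3][1], infra.infra2_epithet,
                        epithet=True,
                        wrong_rank=bool(parsed.rank_indicator2)
                        and parsed.rank_indicator2 != infra.infra2_rank_indicator,
                        max_block=params.max_block,
                    )
                    if component_prefilter(i2, params):
                        candidates.append(
                            _candidate_for(parsed, infra, icomps + [i2], 4,
                                           query_depth, params)
                        )
                    continue
                candidates.append(
                    _candidate_for(parsed, infra, icomps, 3, query_depth, params)
                )
    return candidates
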