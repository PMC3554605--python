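"""Candidate selection, ranking, warnings and synonym resolution.

Turns the raw candidate list produced by the fuzzy-matching search into
final per-name results: applies the three candidate tests (maximum edit
distance, phonetic, match threshold), ranks the survivors under the
unconstrained and the taxonomically-constrained algorithms, optionally
partitions by source priority, attaches the four warnings, and converts
synonymous matches to their accepted names.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from . import nameparse
from .preprocess import PreprocessResult, preprocess as _preprocess
from .fuzzymatch import CandidateMatch, hierarchical_search, _component
from .nameparse import ParsedName
from .scoring import ScoringParams, score_candidate
from .taxondb import ReferenceName, TaxonStore

__all__ = [
    "RunSettings",
    "ResolutionResult",
    "max_ed_test",
    "threshold_test",
    "apply_candidate_tests",
    "rank_unconstrained",
    "rank_constrained",
    "rank_by_source",
    "resolve_name",
    "resolve_names",
]

WARNING_PARTIAL = "partial_match"
WARNING_AMBIGUOUS = "ambiguous_match"
WARNING_BETTER_SPELLING = "better_spelling_match_in_different_higher_taxon"
WARNING_BETTER_HIGHER = "better_higher_taxonomic_match_available"

_STATUS_RANK = {
    "accepted": 0,
    "synonym": 1,
    "illegitimate": 1,
    "invalid": 1,
    "no_opinion": 2,
}


@dataclass
class RunSettings:
    """User-facing run configuration (processing + best-match settings)."""

    mode: str = "resolve"                 # "resolve" | "parse_only"
    min_oms: float = 0.0                  # match-accuracy floor
    allow_partial: bool = True
    constrain_by_higher_taxonomy: bool = False
    constrain_by_source: bool = False
    source_order: Optional[list[str]] = None
    max_alternatives: int = 20


@dataclass
class ResolutionResult:
    """Final outcome for one submitted name."""

    submitted: str
    submitted_id: Optional[int] = None
    parsed: Optional[ParsedName] = None
    preprocessed: Optional[PreprocessResult] = None
    best_unconstrained: Optional[CandidateMatch] = None
    best_constrained: Optional[CandidateMatch] = None
    alternatives: list[CandidateMatch] = field(default_factory=list)
    warnings: set[str] = field(default_factory=set)
    accepted: Optional[ReferenceName] = None
    status_of_match: str = "none"

    @property
    def best(self) -> Optional[CandidateMatch]:
        """Best match under the active ranking mode (set by resolve_name)."""
        return self.alternatives[0] if self.alternatives else None


# ---------------------------------------------------------------------------
# Candidate tests
# ---------------------------------------------------------------------------

def max_ed_test(total_ed: int, n_parts: int, params: Optional[ScoringParams] = None) -> bool:
    """Whole-name edit-distance budget: total ED <= budget-per-part * parts.

    Rank indicators are not counted as name parts, so a binomial has two
    parts (budget 4 by default) and a variety three (budget 6).
    """
    if params is None:
        params = ScoringParams()
    if n_parts < 1:
        raise ValueError("n_parts must be at least 1")
    return total_ed <= params.max_ed_per_part * n_parts


def threshold_test(
    ed: int,
    msl: int,
    query: str,
    reference: str,
    params: Optional[ScoringParams] = None,
) -> bool:
    """Per-component match-threshold test.

    An ED of 0 or 1 always passes.  Larger EDs must stay within the
    length-dependent ratio (ED/MSL <= 0.5 for short strings, 0.3334 for
    MSL >= 6) and share a leading prefix: the first character for
    2 <= ED < 4, the first three characters for ED = 4.  ED > 4 fails
    (only phonetic equality can rescue such a candidate).
    """
    if params is None:
        params = ScoringParams()
    if ed <= 1:
        return True
    if ed > 4:
        return False
    maxedr = params.maxedr_short if msl < params.msl_short_cutoff else params.maxedr_long
    if msl <= 0 or ed / msl > maxedr:
        return False
    q = query.lower()
    r = reference.lower()
    if ed < 4:
        return bool(q and r) and q[0] == r[0]
    return q[:3] == r[:3] and len(q) >= 3


def apply_candidate_tests(
    candidate: CandidateMatch, params: Optional[ScoringParams] = None
) -> bool:
    """Run the three candidate tests; record outcomes; return retention.

    A candidate is retained iff it passes the maximum-ED test and also
    passes either the phonetic test (every compared component
    phonetically equal) or the match-threshold test (every compared
    component within threshold).  Unmatched query components of a
    partial match are not compared.
    """
    if params is None:
        params = ScoringParams()
    compared = [c for c in candidate.per_component if c.ed is not None]
    if not compared:
        return False
    total_ed = sum(c.ed for c in compared)
    candidate.passed_max_ed = max_ed_test(total_ed, len(compared), params)
    candidate.passed_phonetic = all(c.phonetic_equal for c in compared)
    candidate.passed_threshold = all(
        threshold_test(c.ed, c.msl, c.query, c.reference, params) for c in compared
    )
    return candidate.passed_max_ed and (
        candidate.passed_phonetic or candidate.passed_threshold
    )


# ---------------------------------------------------------------------------
# Ranking
# ---------------------------------------------------------------------------

def _status_rank(candidate: CandidateMatch) -> int:
    return _STATUS_RANK.get(candidate.reference.status, 3)


def _unconstrained_sort_key(c: CandidateMatch):
    s = c.scores
    return (-s.snms, -s.oms, _status_rank(c), c.reference.canonical, c.reference.name_id)


def _unconstrained_tie_key(c: CandidateMatch):
    s = c.scores
    return (round(s.snms, 9), round(s.oms, 9), _status_rank(c))


_COMPONENT_ORDER = [
    "family", "genus", "specific_epithet", "infraspecific_epithet", "infra2_epithet",
]


def _component_vector(c: CandidateMatch, components: Sequence[str]) -> tuple[float, ...]:
    pms_of = {}
    for comp, pms in zip(c.per_component, c.scores.pms):
        pms_of[comp.component] = pms
    return tuple(pms_of.get(name, -1.0) for name in components)


def _constrained_sort_key(c: CandidateMatch, components: Sequence[str]):
    vec = _component_vector(c, components)
    s = c.scores
    return (
        tuple(-v for v in vec),
        -s.oms,
        _status_rank(c),
        c.reference.canonical,
        c.reference.name_id,
    )


def _constrained_tie_key(c: CandidateMatch, components: Sequence[str]):
    vec = _component_vector(c, components)
    s = c.scores
    return (tuple(round(v, 9) for v in vec), round(s.oms, 9), _status_rank(c))


def rank_unconstrained(candidates: Sequence[CandidateMatch]) -> list[CandidateMatch]:
    """Rank by descending SNMS, then OMS, then taxonomic status
    (accepted > synonym > no opinion), alphabetical canonical as tie-break."""
    return sorted(candidates, key=_unconstrained_sort_key)


def rank_constrained(
    candidates: Sequence[CandidateMatch],
    submitted_components: Sequence[str],
) -> list[CandidateMatch]:
    """Rank component-by-component, highest taxon first.

    Candidates are compared on the partial match score of the family (if
    submitted), then genus, then specific epithet, then infraspecific
    epithets; a perfect genus with an unmatched epithet therefore
    outranks a fuzzy full-species match.
    """
    comps = tuple(submitted_components)
    return sorted(candidates, key=lambda c: _constrained_sort_key(c, comps))


def rank_by_source(
    ranked: Sequence[CandidateMatch], source_priority: Sequence[str]
) -> list[CandidateMatch]:
    """Stable partition: all candidates from higher-priority sources first."""
    order = {sid: i for i, sid in enumerate(source_priority)}
    return sorted(ranked, key=lambda c: order.get(c.source_id, len(order)))


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

def _exact_candidates(
    parsed: ParsedName, hits: Iterable[ReferenceName], params: ScoringParams
) -> list[CandidateMatch]:
    out = []
    for ref in hits:
        comps = []
        if parsed.family:
            comps.append(_component("family", parsed.family, ref.family or "",
                                    epithet=False, max_block=params.max_block))
        if ref.rank == "family" and not parsed.genus:
            comps.append(_component("family", parsed.family or ref.family, ref.family,
                                    epithet=False, max_block=params.max_block))
        if parsed.genus:
            comps.append(_component("genus", parsed.genus, ref.genus,
                                    epithet=False, max_block=params.max_block))
        if parsed.specific_epithet:
            comps.append(_component("specific_epithet", parsed.specific_epithet,
                                    ref.specific_epithet, epithet=True,
                                    max_block=params.max_block))
        if parsed.infraspecific_epithet:
            comps.append(_component("infraspecific_epithet", parsed.infraspecific_epithet,
                                    ref.infraspecific_epithet, epithet=True,
                                    max_block=params.max_block))
        if parsed.infraspecific_epithet2:
            comps.append(_component("infra2_epithet", parsed.infraspecific_epithet2,
                                    ref.infra2_epithet, epithet=True,
                                    max_block=params.max_block))
        cand = CandidateMatch(
            reference=ref,
            per_component=[c for c in comps if c.reference or c.query],
            source_id=ref.source_id,
            forced_exact=True,
        )
        out.append(cand)
    return out


def _submitted_components(parsed: ParsedName) -> list[str]:
    comps = []
    if parsed.family:
        comps.append("family")
    if parsed.genus:
        comps.append("genus")
    if parsed.specific_epithet:
        comps.append("specific_epithet")
    if parsed.infraspecific_epithet:
        comps.append("infraspecific_epithet")
    if parsed.infraspecific_epithet2:
        comps.append("infra2_epithet")
    return comps


def _higher_taxon(ref: ReferenceName) -> str:
    return (ref.genus or ref.family or "").lower()


def resolve_name(
    raw: str,
    db: TaxonStore,
    params: Optional[ScoringParams] = None,
    settings: Optional[RunSettings] = None,
    submitted_id: Optional[int] = None,
) -> ResolutionResult:
    """Resolve one submitted name string against the store."""
    if params is None:
        params = ScoringParams()
    if settings is None:
        settings = RunSettings()

    result = ResolutionResult(submitted=raw, submitted_id=submitted_id)
    pre = _preprocess(raw, db, settings.source_order)
    result.preprocessed = pre

    if pre.degenerate:
        if not pre.family_prefix:
            return result
        parsed = ParsedName(family=pre.family_prefix)
    else:
        parsed = nameparse.parse(pre.cleaned)
        if pre.family_prefix and not parsed.family:
            parsed.family = pre.family_prefix
        if parsed.parse_quality == "failed":
            return result
    result.parsed = parsed

    if pre.exact_hits:
        candidates = _exact_candidates(parsed, pre.exact_hits, params)
    else:
        candidates = hierarchical_search(parsed, db, params)
        for cand in candidates:
            score_candidate(cand, params)
        candidates = [c for c in candidates if apply_candidate_tests(c, params)]
        if not settings.allow_partial:
            candidates = [c for c in candidates if not c.is_partial]
        # fallback to family when nothing at or below genus survived
        if not candidates and settings.allow_partial and parsed.family and parsed.genus:
            fam_query = ParsedName(family=parsed.family)
            fallback = hierarchical_search(fam_query, db, params)
            for cand in fallback:
                cand.is_partial = True
                # account for the unmatched genus/epithets of the original query
                from .fuzzymatch import _unmatched
                for name, text in (
                    ("genus", parsed.genus),
                    ("specific_epithet", parsed.specific_epithet),
                    ("infraspecific_epithet", parsed.infraspecific_epithet),
                    ("infra2_epithet", parsed.infraspecific_epithet2),
                ):
                    if text:
                        cand.per_component.append(_unmatched(name, text))
            candidates = [c for c in fallback if apply_candidate_tests(c, params)]

    for cand in candidates:
        if cand.scores is None:
            score_candidate(cand, params)
    if settings.min_oms > 0:
        candidates = [c for c in candidates if c.oms >= settings.min_oms]
    if not candidates:
        return result

    components = _submitted_components(parsed)
    unconstrained = rank_unconstrained(candidates)
    constrained = rank_constrained(candidates, components)
    if settings.constrain_by_source and settings.source_order:
        unconstrained = rank_by_source(unconstrained, settings.source_order)
        constrained = rank_by_source(constrained, settings.source_order)

    result.best_unconstrained = unconstrained[0]
    result.best_constrained = constrained[0]
    active = constrained if settings.constrain_by_higher_taxonomy else unconstrained
    result.alternatives = list(active[: settings.max_alternatives])
    best = active[0]

    # warnings
    if best.is_partial:
        result.warnings.add(WARNING_PARTIAL)
    if settings.constrain_by_higher_taxonomy:
        tie_key = lambda c: _constrained_tie_key(c, tuple(components))
    else:
        tie_key = _unconstrained_tie_key
    if len(active) > 1 and tie_key(active[0]) == tie_key(active[1]):
        result.warnings.add(WARNING_AMBIGUOUS)
    bu, bc = result.best_unconstrained, result.best_constrained
    if bu.reference.name_id != bc.reference.name_id:
        if settings.constrain_by_higher_taxonomy:
            if bu.oms > bc.oms and _higher_taxon(bu.reference) != _higher_taxon(bc.reference):
                result.warnings.add(WARNING_BETTER_SPELLING)
        else:
            result.warnings.add(WARNING_BETTER_HIGHER)

    result.status_of_match = best.reference.status
    result.accepted = db.resolve_accepted(best.reference.name_id)
    return result


def resolve_names(
    queries: Iterable[tuple[Optional[int], str]],
    db: TaxonStore,
    params: Optional[ScoringParams] = None,
    settings: Optional[RunSettings] = None,
) -> list[ResolutionResult]:
    """Resolve a batch of (id, name) queries; each name is independent."""
    return [
        resolve_name(raw, db, params, settings, submitted_id=qid)
        for qid, raw in queries
    ]
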