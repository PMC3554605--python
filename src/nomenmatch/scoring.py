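"""Match-score calculation.

A candidate match is scored in four steps:

1. each name component (family if submitted, genus, epithets — but not
   rank indicators or the author) receives a *partial match score*

       PMS = 1 - 2 * ED / MaxED

   where MaxED is the length of the longer of the two strings, so PMS
   ranges from -1 (nothing in common) to 1 (identical).  A fixed penalty
   (default 0.3) is subtracted when an infraspecific rank indicator is
   present but wrong ("fo." submitted where the reference has "var.");
2. the scientific-name match score SNMS is the plain sum of the PMSs;
3. SNMS is rescaled to [0, 1] by a sign-preserving arctangent transform

       SNMS_tr = atan((s * SNMS / k)^(2t+1)) / (2 * atan(s^(2t+1))) + 0.5

   with k the number of name components.  With the default s = 2, t = 1
   the curve is double-logistic: flat near the endpoints (certainty) and
   near the center (uncertainty), steep in between (discrimination);
4. the overall match score blends in the author similarity when an
   authority was submitted and compared (OMS = 0.8 * SNMS_tr + 0.2 * AMS),
   otherwise OMS = SNMS_tr; a penalty of 0.1 is subtracted if the query
   carried text that matched nothing.  OMS is clamped to [0, 1], and a
   whole-string exact hit is pinned at 1.0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

__all__ = [
    "ScoringParams",
    "MatchScores",
    "partial_match_score",
    "transform_snms",
    "overall_score",
    "score_candidate",
]


@dataclass
class ScoringParams:
    """Tunable constants of the scoring scheme and candidate tests."""

    s: float = 2.0                    # transform steepness, > 0
    t: float = 1.0                    # transform center flatness, >= 0
    name_weight: float = 0.8          # weight of SNMS_tr in OMS
    author_weight: float = 0.2        # weight of AMS in OMS
    wrong_rank_penalty: float = 0.3   # PMS penalty for a wrong rank indicator
    unmatched_text_penalty: float = 0.1
    maxedr_short: float = 0.5         # max ED/MSL ratio when MSL < cutoff
    maxedr_long: float = 0.3334       # max ED/MSL ratio when MSL >= cutoff
    msl_short_cutoff: int = 6
    max_ed_per_part: int = 2          # total ED budget = this * name parts
    min_oms: float = 0.0              # "match accuracy" floor on reported OMS
    max_block: int = 4                # block-transposition cap in MDLD

    def __post_init__(self) -> None:
        if self.s <= 0:
            raise ValueError("s must be positive")
        if self.t < 0:
            raise ValueError("t must be non-negative")
        if abs(self.name_weight + self.author_weight - 1.0) > 1e-9:
            raise ValueError("name_weight + author_weight must equal 1")


@dataclass
class MatchScores:
    """All scores attached to one candidate match."""

    pms: list[float]
    snms: float
    snms_tr: float
    oms: float
    k: int
    ams: Optional[float] = None


def partial_match_score(
    ed: int,
    max_ed: int,
    wrong_rank_indicator: bool = False,
    params: Optional[ScoringParams] = None,
) -> float:
    """Per-component partial match score, in [-1, 1]."""
    if params is None:
        params = ScoringParams()
    if max_ed <= 0:
        raise ValueError("MaxED must be positive")
    pms = 1.0 - 2.0 * ed / max_ed
    if wrong_rank_indicator:
        pms -= params.wrong_rank_penalty
    return max(pms, -1.0)


def transform_snms(snms: float, k: int, params: Optional[ScoringParams] = None) -> float:
    """Arctangent rescaling of SNMS to [0, 1].

    Strictly increasing in SNMS with fixed endpoints: -k maps to 0,
    0 to 0.5 and k (a perfect match on every component) to 1.
    """
    if params is None:
        params = ScoringParams()
    if k < 1:
        raise ValueError("k must be at least 1")
    if snms < -k - 1e-9 or snms > k + 1e-9:
        raise ValueError(f"SNMS {snms} outside [-{k}, {k}]")
    exponent = 2.0 * params.t + 1.0
    x = params.s * snms / k
    powered = math.copysign(abs(x) ** exponent, x)
    value = math.atan(powered) / (2.0 * math.atan(params.s ** exponent)) + 0.5
    return min(max(value, 0.0), 1.0)


def overall_score(
    snms_tr: float,
    ams: Optional[float] = None,
    has_unmatched_text: bool = False,
    params: Optional[ScoringParams] = None,
) -> float:
    """Overall match score: blend of name and author scores, minus penalties."""
    if params is None:
        params = ScoringParams()
    if ams is not None:
        oms = params.name_weight * snms_tr + params.author_weight * ams
    else:
        oms = snms_tr
    if has_unmatched_text:
        oms -= params.unmatched_text_penalty
    return min(max(oms, 0.0), 1.0)


def score_candidate(candidate, params: Optional[ScoringParams] = None) -> MatchScores:
    """Score one candidate match end to end (PMS -> SNMS -> SNMS_tr -> OMS).

    Query components with no counterpart in the reference (a species
    query matched only at genus rank, say) contribute PMS = -1.  The
    result is stored on ``candidate.scores`` and returned.
    """
    if params is None:
        params = ScoringParams()
    pms_list: list[float] = []
    for comp in candidate.per_component:
        if comp.ed is None:
            pms_list.append(-1.0)
        else:
            pms_list.append(
                partial_match_score(
                    comp.ed, comp.max_ed, comp.wrong_rank_indicator, params
                )
            )
    k = len(pms_list)
    snms = sum(pms_list)
    snms_tr = transform_snms(snms, k, params)
    if candidate.forced_exact:
        oms = 1.0
    else:
        oms = overall_score(
            snms_tr, candidate.ams, candidate.query_has_unmatched_text, params
        )
    scores = MatchScores(
        pms=pms_list, snms=snms, snms_tr=snms_tr, oms=oms, k=k, ams=candidate.ams
    )
    candidate.scores = scores
    return scores
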