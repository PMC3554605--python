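"""Query-string cleanup before parsing and matching.

Each submitted string is trimmed, pre-pended family names are split off
(recognized by the standard endings -aceae/-idae or membership in the
conserved-family list), identification annotations ("cf.", "aff.",
"indet.", morphospecies codes, embedded accession codes) are removed and
recorded, all-caps strings are case-corrected, and finally the cleaned
string is matched exactly against the reference store — a whole-string
hit short-circuits fuzzy matching with an overall score of 1.0.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional

from .taxondb import ReferenceName, TaxonStore

__all__ = [
    "PreprocessResult",
    "strip_family",
    "remove_annotations",
    "normalize_case",
    "preprocess",
    "CONSERVED_FAMILIES",
    "ANNOTATION_VOCABULARY",
]

# conserved plant family names without the standard -aceae ending
CONSERVED_FAMILIES = {
    "Gramineae", "Compositae", "Leguminosae", "Cruciferae",
    "Umbelliferae", "Labiatae", "Palmae", "Guttiferae",
}

# single-token annotations, matched case-insensitively, optional final period
ANNOTATION_VOCABULARY = {
    "cf", "aff", "indet", "sp", "spp", "ined", "?", "s.l", "s.s",
}

# two-token annotations ("sp. nov.", "sp. nova")
ANNOTATION_PAIRS = {("sp", "nov"), ("sp", "nova"), ("spp", "nov")}

_CODE_RE = re.compile(r"^[A-Za-z0-9\-]*\d[A-Za-z0-9\-]*$")
_MORPHO_RE = re.compile(r"^(\d+|[A-Za-z]|[A-Za-z0-9\-]*\d[A-Za-z0-9\-]*)$")


@dataclass
class PreprocessResult:
    """Outcome of cleaning one submitted string."""

    family_prefix: str = ""
    cleaned: str = ""
    removed_annotations: list[str] = field(default_factory=list)
    was_all_caps: bool = False
    exact_hits: list[ReferenceName] = field(default_factory=list)
    degenerate: bool = False

    @property
    def exact_hit(self) -> Optional[ReferenceName]:
        return self.exact_hits[0] if self.exact_hits else None


def _norm_token(token: str) -> str:
    return token.lower().rstrip(".")


def strip_family(raw: str) -> tuple[str, str]:
    """Split a pre-pended family name off the start of the string."""
    tokens = raw.split()
    if len(tokens) < 2:
        return "", raw.strip()
    first = tokens[0]
    lower = first.lower().rstrip(".")
    is_family = lower.endswith(("aceae", "idae")) or first.capitalize() in CONSERVED_FAMILIES
    if is_family:
        return first, " ".join(tokens[1:])
    return "", raw.strip()


def remove_annotations(raw: str) -> tuple[str, list[str]]:
    """Remove identification annotations and morphospecies/accession codes."""
    tokens = raw.split()
    kept: list[str] = []
    removed: list[str] = []
    i = 0
    while i < len(tokens):
        tok = tokens[i]
        norm = _norm_token(tok)
        nxt = _norm_token(tokens[i + 1]) if i + 1 < len(tokens) else None
        if (norm, nxt) in ANNOTATION_PAIRS:
            removed.extend(tokens[i : i + 2])
            i += 2
            continue
        if norm in ANNOTATION_VOCABULARY or tok == "?":
            removed.append(tok)
            # a morphospecies code may follow "sp." / "spp."
            if norm in ("sp", "spp") and i + 1 < len(tokens) and _MORPHO_RE.match(tokens[i + 1]):
                removed.append(tokens[i + 1])
                i += 1
            i += 1
            continue
        kept.append(tok)
        i += 1
    # trailing accession-style codes (>= 2 chars containing a digit)
    while kept and len(kept[-1]) >= 2 and _CODE_RE.match(kept[-1]):
        removed.append(kept.pop())
    return " ".join(kept), removed


def normalize_case(raw: str) -> str:
    """Capitalize the first letter and lower the rest — only for all-caps input."""
    letters = [c for c in raw if c.isalpha()]
    if letters and all(c.isupper() for c in letters):
        return raw[:1].upper() + raw[1:].lower()
    return raw


def preprocess(
    raw: str,
    db: Optional[TaxonStore] = None,
    source_ids: Optional[list[str]] = None,
) -> PreprocessResult:
    """Full cleanup pipeline: family strip, annotation removal, case fix,
    then an exact whole-string lookup against the store (when given)."""
    result = PreprocessResult()
    text = raw.strip().replace("_", " ")
    family, remainder = strip_family(text)
    if family:
        result.family_prefix = normalize_case(family)
    cleaned, removed = remove_annotations(remainder)
    result.removed_annotations = removed
    before = cleaned
    cleaned = normalize_case(cleaned)
    result.was_all_caps = bool(cleaned) and cleaned != before or (
        bool(family) and result.family_prefix != family
    )
    result.cleaned = cleaned
    if not cleaned:
        result.degenerate = True
        return result
    if db is not None:
        result.exact_hits = db.exact_lookup_string(cleaned, source_ids)
    return result
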