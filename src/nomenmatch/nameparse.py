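"""Scientific-name parsing.

Atomizes a name string into genus, specific and infraspecific epithets,
rank indicators and authorship, following the positional and case
conventions of botanical nomenclature: the genus is the leading
capitalized token, epithets are lower-case, rank indicators ("var.",
"subsp.", "fo.", ...) introduce infraspecific epithets, and authorship is
the trailing capitalized material, optionally with a parenthesized
basionym author.  Parsing is case sensitive and never raises: anything
that cannot be placed lands in ``unmatched_text`` and the parse quality
is downgraded (strict -> relaxed -> salvage -> failed).
"""

from __future__ import annotations

import re
import unicodedata
from dataclasses import dataclass, field

__all__ = [
    "ParsedName",
    "parse",
    "canonical",
    "rank_of",
    "standardize_rank_indicator",
    "RANK_INDICATORS",
]

# accepted spellings -> standardized form
RANK_INDICATORS: dict[str, str] = {
    "var.": "var.", "var": "var.", "v.": "var.",
    "subsp.": "subsp.", "subsp": "subsp.", "ssp.": "subsp.", "ssp": "subsp.",
    "fo.": "fo.", "fo": "fo.", "f.": "fo.", "forma": "fo.",
    "subvar.": "subvar.", "subvar": "subvar.",
    "subf.": "subf.", "subfo.": "subf.",
}

_FAMILY_ENDINGS = ("aceae", "idae")
_HYBRID_CHARS = ("\N{MULTIPLICATION SIGN}",)


def standardize_rank_indicator(token: str) -> str:
    """Map a rank-indicator spelling to its standardized form ("ssp" -> "subsp.")."""
    return RANK_INDICATORS.get(token.lower(), token)


@dataclass
class ParsedName:
    """Atomized scientific name."""

    family: str = ""
    genus: str = ""
    specific_epithet: str = ""
    rank_indicator: str = ""
    infraspecific_epithet: str = ""
    rank_indicator2: str = ""
    infraspecific_epithet2: str = ""
    author: str = ""
    basionym_author: str = ""
    combining_author: str = ""
    annotations: list[str] = field(default_factory=list)
    unmatched_text: str = ""
    is_hybrid: bool = False
    parse_quality: str = "strict"  # strict | relaxed | salvage | failed


def _is_alpha_word(token: str, *, allow_hyphen: bool = True) -> bool:
    body = token.replace("-", "") if allow_hyphen else token
    return bool(body) and all(unicodedata.category(c).startswith("L") for c in body)


def _has_diacritics(token: str) -> bool:
    return any(unicodedata.combining(c) for c in unicodedata.normalize("NFD", token))


def _is_lower_epithet(token: str) -> bool:
    return _is_alpha_word(token) and token == token.lower() and len(token) >= 2


def _is_genus_like(token: str) -> bool:
    return (
        _is_alpha_word(token)
        and token[0].isupper()
        and token[1:] == token[1:].lower()
        and len(token) >= 2
    )


_YEAR_RE = re.compile(r"^\[?\(?1[5-9]\d\d\??\)?\]?,?$|^\[?\(?20\d\d\??\)?\]?,?$")
_AUTHOR_CONNECTIVES = {"ex", "et", "&", "in", "ex.", "al.", "f.", "fil.", "von", "de", "la", "den"}


def _is_author_token(token: str) -> bool:
    if token in _AUTHOR_CONNECTIVES or _YEAR_RE.match(token):
        return True
    stripped = token.strip("(),")
    if not stripped:
        return False
    return any(c.isupper() for c in stripped)


def parse(raw: str) -> ParsedName:
    """Parse a scientific-name string into its components.

    Components are assigned greedily left to right; the worst case is
    ``parse_quality='failed'`` with the whole input in ``unmatched_text``.
    Hybrid markers set ``is_hybrid``; for a hybrid formula (two names
    joined by a multiplication sign or a free-standing "x") only the
    leading name is parsed and the rest is salvaged into
    ``unmatched_text``.
    """
    result = ParsedName()
    text = raw.strip()
    if not text:
        result.parse_quality = "failed"
        return result

    relaxed = False
    # hybrid marker glued to the genus: "×Poa" / "xPoa"
    for marker in _HYBRID_CHARS:
        if text.startswith(marker):
            result.is_hybrid = True
            result.annotations.append(marker)
            text = text[len(marker):].strip()

    tokens = text.split()

    # hybrid formula: keep the left-hand name only
    for i, tok in enumerate(tokens):
        if tok in _HYBRID_CHARS or (tok in ("x", "X") and 0 < i < len(tokens) - 1):
            result.is_hybrid = True
            result.annotations.append(tok)
            result.unmatched_text = " ".join(tokens[i + 1:])
            tokens = tokens[:i]
            break

    unmatched: list[str] = []
    author_tokens: list[str] = []
    i = 0
    n = len(tokens)
    if n == 0:
        result.parse_quality = "failed"
        return result

    first = tokens[0]
    if _is_genus_like(first):
        if _has_diacritics(first):
            relaxed = True
        if first.lower().endswith(_FAMILY_ENDINGS):
            result.family = first
        else:
            result.genus = first
        i = 1
    else:
        result.unmatched_text = " ".join(
            t for t in (" ".join(tokens), result.unmatched_text) if t
        )
        result.parse_quality = "failed"
        return result

    # epithets and rank indicators
    epithet_slots = ["specific_epithet", "infraspecific_epithet", "infraspecific_epithet2"]
    slot = 0
    while i < n and not author_tokens:
        tok = tokens[i]
        if tok.lower() in RANK_INDICATORS and i + 1 < n and _is_lower_epithet(tokens[i + 1]):
            indicator = standardize_rank_indicator(tok)
            if not result.infraspecific_epithet:
                result.rank_indicator = indicator
                result.infraspecific_epithet = tokens[i + 1]
                slot = 2
            elif not result.infraspecific_epithet2:
                result.rank_indicator2 = indicator
                result.infraspecific_epithet2 = tokens[i + 1]
                slot = 3
            else:
                unmatched.extend(tokens[i:i + 2])
            if _has_diacritics(tokens[i + 1]):
                relaxed = True
            i += 2
            continue
        if _is_lower_epithet(tok) and slot < len(epithet_slots) and not result.family:
            # bare epithet (no indicator); allowed through the infra2 slot
            if slot == 0 and not result.specific_epithet:
                result.specific_epithet = tok
            elif slot <= 1 and not result.infraspecific_epithet:
                result.infraspecific_epithet = tok
            else:
                unmatched.append(tok)
                i += 1
                continue
            if _has_diacritics(tok):
                relaxed = True
            slot += 1
            i += 1
            continue
        if _is_author_token(tok):
            author_tokens = tokens[i:]
            i = n
            break
        unmatched.append(tok)
        i += 1

    if author_tokens:
        _assign_authors(result, author_tokens)
        if "((" in " ".join(author_tokens) or any(
            _YEAR_RE.match(t) and ("[" in t or "?" in t) for t in author_tokens
        ):
            relaxed = True

    result.unmatched_text = " ".join(
        t for t in (" ".join(unmatched), result.unmatched_text) if t
    )
    if result.unmatched_text:
        result.parse_quality = "salvage"
    elif relaxed:
        result.parse_quality = "relaxed"
    else:
        result.parse_quality = "strict"
    return result


def _assign_authors(result: ParsedName, tokens: list[str]) -> None:
    text = " ".join(tokens)
    if text.startswith("("):
        depth = 0
        split_at = len(text)
        for idx, ch in enumerate(text):
            if ch == "(":
                depth += 1
            elif ch == ")":
                depth -= 1
                if depth == 0:
                    split_at = idx + 1
                    break
        basionym = text[:split_at].strip("() ")
        combining = text[split_at:].strip()
        result.basionym_author = basionym
        result.combining_author = combining
        if combining:
            result.author = f"({basionym}) {combining}"
        else:
            result.author = f"({basionym})"
    else:
        result.author = text


def canonical(parsed: ParsedName) -> str:
    """Canonical form: name components and standardized rank indicators, no author."""
    if parsed.parse_quality == "failed":
        raise ValueError("cannot build a canonical form from a failed parse")
    if parsed.family and not parsed.genus:
        return parsed.family
    parts = [parsed.genus]
    if parsed.specific_epithet:
        parts.append(parsed.specific_epithet)
    if parsed.infraspecific_epithet:
        if parsed.rank_indicator:
            parts.append(parsed.rank_indicator)
        parts.append(parsed.infraspecific_epithet)
    if parsed.infraspecific_epithet2:
        if parsed.rank_indicator2:
            parts.append(parsed.rank_indicator2)
        parts.append(parsed.infraspecific_epithet2)
    return " ".join(p for p in parts if p)


def rank_of(parsed: ParsedName) -> str:
    """Rank of the submitted name: the deepest component present."""
    if parsed.infraspecific_epithet2:
        return "infraspecies2"
    if parsed.infraspecific_epithet:
        return "infraspecies"
    if parsed.specific_epithet:
        return "species"
    if parsed.genus:
        return "genus"
    if parsed.family:
        return "family"
    return "none"
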