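"""Reference-taxonomy store.

Loads one or more Darwin-Core-style tab-separated exchange files into an
in-memory store, validates the parent and synonym links, and builds the
indexes the matching engine needs: a nested-set (preorder interval)
labeling of the classification tree for constant-form descendant
queries, exact-lookup indexes on canonical names, and precomputed
phonetic keys and epithet stems for every record.

Exchange format: UTF-8 TSV with header columns ``taxonID,
scientificName, scientificNameAuthorship, taxonRank, parentNameUsageID,
acceptedNameUsageID, taxonomicStatus, family`` (Simple Darwin Core
terms).  An empty string means null.  Recognized ranks: family, genus,
species, subspecies, variety, forma.  Recognized statuses: accepted,
synonym, illegitimate, invalid, no_opinion.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from typing import Iterable, Optional

__all__ = [
    "ReferenceName",
    "TaxonStore",
    "ExchangeValidationError",
    "LookupError_",
    "EXCHANGE_COLUMNS",
    "RANKS",
    "STATUSES",
]

EXCHANGE_COLUMNS = [
    "taxonID",
    "scientificName",
    "scientificNameAuthorship",
    "taxonRank",
    "parentNameUsageID",
    "acceptedNameUsageID",
    "taxonomicStatus",
    "family",
]

RANKS = {"family", "genus", "species", "subspecies", "variety", "forma"}
STATUSES = {"accepted", "synonym", "illegitimate", "invalid", "no_opinion"}

_INFRA_INDICATOR = {"subspecies": "subsp.", "variety": "var.", "forma": "fo."}


class ExchangeValidationError(ValueError):
    """Raised when an exchange file violates the schema or link integrity."""


class LookupError_(KeyError):
    """Raised when a name_id is not present in the store."""


@dataclass(frozen=True)
class ReferenceName:
    """One name record of the reference taxonomy."""

    name_id: str
    source_id: str
    taxon_id: str           # identifier within the source file
    rank: str
    family: str = ""
    genus: str = ""
    specific_epithet: str = ""
    infra_rank_indicator: str = ""
    infraspecific_epithet: str = ""
    infra2_rank_indicator: str = ""
    infra2_epithet: str = ""
    author: str = ""
    status: str = "accepted"
    accepted_name_id: Optional[str] = None
    parent_id: Optional[str] = None

    @property
    def canonical(self) -> str:
        if self.rank == "family":
            return self.family
        parts = [self.genus]
        if self.specific_epithet:
            parts.append(self.specific_epithet)
        if self.infraspecific_epithet:
            if self.infra_rank_indicator:
                parts.append(self.infra_rank_indicator)
            parts.append(self.infraspecific_epithet)
        if self.infra2_epithet:
            if self.infra2_rank_indicator:
                parts.append(self.infra2_rank_indicator)
            parts.append(self.infra2_epithet)
        return " ".join(p for p in parts if p)

    @property
    def full_name(self) -> str:
        return f"{self.canonical} {self.author}".strip()


def _split_canonical(name: str, rank: str, row_no: int) -> dict[str, str]:
    """Atomize the scientificName column according to the declared rank."""
    from .nameparse import RANK_INDICATORS, standardize_rank_indicator

    tokens = name.split()
    out = {
        "genus": "", "specific_epithet": "",
        "infra_rank_indicator": "", "infraspecific_epithet": "",
        "infra2_rank_indicator": "", "infra2_epithet": "",
    }
    if rank == "family":
        return out
    if not tokens:
        raise ExchangeValidationError(f"row {row_no}: empty scientificName")
    out["genus"] = tokens[0]
    rest = tokens[1:]
    if rank == "genus":
        if rest:
            raise ExchangeValidationError(
                f"row {row_no}: genus record {name!r} has extra tokens"
            )
        return out
    if not rest:
        raise ExchangeValidationError(
            f"row {row_no}: rank {rank} requires a specific epithet in {name!r}"
        )
    out["specific_epithet"] = rest[0]
    rest = rest[1:]
    infra_slots = [("infra_rank_indicator", "infraspecific_epithet"),
                   ("infra2_rank_indicator", "infra2_epithet")]
    slot = 0
    while rest:
        if slot >= len(infra_slots):
            raise ExchangeValidationError(
                f"row {row_no}: too many components in {name!r}"
            )
        ind_field, epi_field = infra_slots[slot]
        if rest[0].lower() in RANK_INDICATORS and len(rest) >= 2:
            out[ind_field] = standardize_rank_indicator(rest[0])
            out[epi_field] = rest[1]
            rest = rest[2:]
        else:
            out[ind_field] = _INFRA_INDICATOR.get(rank, "")
            out[epi_field] = rest[0]
            rest = rest[1:]
        slot += 1
    if rank == "species" and out["infraspecific_epithet"]:
        raise ExchangeValidationError(
            f"row {row_no}: species record {name!r} has infraspecific components"
        )
    if rank in ("subspecies", "variety", "forma") and not out["infraspecific_epithet"]:
        raise ExchangeValidationError(
            f"row {row_no}: rank {rank} requires an infraspecific epithet in {name!r}"
        )
    return out


class TaxonStore:
    """In-memory reference taxonomy with classification and match indexes."""

    def __init__(self) -> None:
        self._records: dict[str, ReferenceName] = {}
        self._priority: dict[str, int] = {}       # source_id -> priority
        self._children: dict[Optional[str], list[str]] = {}
        self._bounds: dict[str, tuple[int, int]] = {}   # nested-set intervals
        self._canonical_index: dict[str, list[str]] = {}
        self._full_index: dict[str, list[str]] = {}
        self._phonetic: dict[str, dict[str, str]] = {}  # name_id -> component keys
        self._stems: dict[str, dict[str, str]] = {}

    # -- loading ----------------------------------------------------------

    def load_exchange_file(self, path: str, source_id: str, priority: int) -> int:
        """Load one exchange TSV as a taxonomic source; returns records loaded.

        Validates ranks, statuses, parent and accepted-name links (a
        dangling or cyclic link is an :class:`ExchangeValidationError`
        naming the offending row), collapses multi-hop synonym chains,
        and rebuilds all indexes.
        """
        with open(path, encoding="utf-8", newline="") as fh:
            reader = csv.DictReader(fh, delimiter="\t")
            if reader.fieldnames != EXCHANGE_COLUMNS:
                raise ExchangeValidationError(
                    f"{path}: header must be {EXCHANGE_COLUMNS}, got {reader.fieldnames}"
                )
            rows = list(reader)
        return self.load_rows(rows, source_id, priority)

    def load_rows(self, rows: Iterable[dict[str, str]], source_id: str, priority: int) -> int:
        new: dict[str, ReferenceName] = {}
        row_of: dict[str, int] = {}
        for row_no, row in enumerate(rows, start=2):  # 1-based, after header
            taxon_id = (row.get("taxonID") or "").strip()
            if not taxon_id:
                raise ExchangeValidationError(f"row {row_no}: missing taxonID")
            name_id = f"{source_id}:{taxon_id}"
            if name_id in new or name_id in self._records:
                raise ExchangeValidationError(
                    f"row {row_no}: duplicate taxonID {taxon_id!r} in source {source_id!r}"
                )
            rank = (row.get("taxonRank") or "").strip().lower()
            if rank not in RANKS:
                raise ExchangeValidationError(
                    f"row {row_no}: unknown taxonRank {row.get('taxonRank')!r}"
                )
            status = (row.get("taxonomicStatus") or "").strip().lower().replace(" ", "_")
            if status not in STATUSES:
                raise ExchangeValidationError(
                    f"row {row_no}: unknown taxonomicStatus {row.get('taxonomicStatus')!r}"
                )
            name = (row.get("scientificName") or "").strip()
            family = (row.get("family") or "").strip()
            if rank == "family" and not family:
                family = name
            parts = _split_canonical(name, rank, row_no)
            parent = (row.get("parentNameUsageID") or "").strip()
            accepted = (row.get("acceptedNameUsageID") or "").strip()
            rec = ReferenceName(
                name_id=name_id,
                source_id=source_id,
                taxon_id=taxon_id,
                rank=rank,
                family=family,
                author=(row.get("scientificNameAuthorship") or "").strip(),
                status=status,
                accepted_name_id=f"{source_id}:{accepted}" if accepted else None,
                parent_id=f"{source_id}:{parent}" if parent else None,
                **parts,
            )
            new[name_id] = rec
            row_of[name_id] = row_no

        self._validate_links(new, row_of)
        self._records.update(new)
        self._priority[source_id] = priority
        self._rebuild_indexes()
        return len(new)

    def _validate_links(self, new: dict[str, ReferenceName], row_of: dict[str, int]) -> None:
        known = lambda nid: nid in new or nid in self._records
        for nid, rec in new.items():
            row_no = row_of[nid]
            if rec.parent_id is not None and not known(rec.parent_id):
                raise ExchangeValidationError(
                    f"row {row_no}: dangling parentNameUsageID {rec.parent_id!r}"
                )
            if rec.accepted_name_id is not None and not known(rec.accepted_name_id):
                raise ExchangeValidationError(
                    f"row {row_no}: dangling acceptedNameUsageID {rec.accepted_name_id!r}"
                )
            if rec.status in ("synonym", "illegitimate", "invalid") and rec.accepted_name_id is None:
                raise ExchangeValidationError(
                    f"row {row_no}: status {rec.status!r} requires acceptedNameUsageID"
                )
            if rec.status == "accepted" and rec.accepted_name_id not in (None, nid):
                raise ExchangeValidationError(
                    f"row {row_no}: accepted record points at a different accepted name"
                )
        # parent chains must be acyclic
        get = lambda nid: new.get(nid) or self._records.get(nid)
        for nid in new:
            seen = set()
            cur: Optional[str] = nid
            while cur is not None:
                if cur in seen:
                    raise ExchangeValidationError(
                        f"row {row_of[nid]}: cycle in parent chain at {cur!r}"
                    )
                seen.add(cur)
                cur = get(cur).parent_id
        # collapse synonym chains; a synonym cycle is an error
        for nid, rec in list(new.items()):
            if rec.accepted_name_id is None or rec.status == "accepted":
                continue
            seen = {nid}
            target = rec.accepted_name_id
            while True:
                tgt = get(target)
                if tgt.status in ("accepted", "no_opinion") or tgt.accepted_name_id is None:
                    break
                if target in seen:
                    raise ExchangeValidationError(
                        f"row {row_of[nid]}: synonym cycle involving {target!r}"
                    )
                seen.add(target)
                target = tgt.accepted_name_id
            if get(target).status not in ("accepted", "no_opinion"):
                raise ExchangeValidationError(
                    f"row {row_of[nid]}: synonym chain from {nid!r} does not reach an accepted name"
                )
            if target != rec.accepted_name_id:
                new[nid] = replace(rec, accepted_name_id=target)

    # -- indexes ----------------------------------------------------------

    def _rebuild_indexes(self) -> None:
        from .fuzzymatch import phonetic_key, stem_epithet

        self._children = {}
        for nid, rec in self._records.items():
            self._children.setdefault(rec.parent_id, []).append(nid)
        for kids in self._children.values():
            kids.sort(key=lambda nid: (self._records[nid].canonical, nid))

        # nested-set labeling via iterative preorder walk
        self._bounds = {}
        counter = 1
        roots = sorted(
            (nid for nid, r in self._records.items() if r.parent_id is None),
            key=lambda nid: (self._records[nid].canonical, nid),
        )
        stack: list[tuple[str, bool]] = [(nid, False) for nid in reversed(roots)]
        lefts: dict[str, int] = {}
        while stack:
            nid, done = stack.pop()
            if done:
                self._bounds[nid] = (lefts[nid], counter)
                counter += 1
                continue
            lefts[nid] = counter
            counter += 1
            stack.append((nid, True))
            for child in reversed(self._children.get(nid, [])):
                stack.append((child, False))

        self._canonical_index = {}
        self._full_index = {}
        self._phonetic = {}
        self._stems = {}
        for nid, rec in self._records.items():
            self._canonical_index.setdefault(rec.canonical, []).append(nid)
            self._full_index.setdefault(rec.full_name, []).append(nid)
            keys: dict[str, str] = {}
            stems: dict[str, str] = {}
            if rec.rank == "family":
                keys["family"] = phonetic_key(rec.family)
            if rec.genus:
                keys["genus"] = phonetic_key(rec.genus)
            if rec.specific_epithet:
                keys["specific_epithet"] = phonetic_key(rec.specific_epithet, epithet=True)
                stems["specific_epithet"] = stem_epithet(rec.specific_epithet)
            if rec.infraspecific_epithet:
                keys["infraspecific_epithet"] = phonetic_key(
                    rec.infraspecific_epithet, epithet=True
                )
                stems["infraspecific_epithet"] = stem_epithet(rec.infraspecific_epithet)
            if rec.infra2_epithet:
                keys["infra2_epithet"] = phonetic_key(rec.infra2_epithet, epithet=True)
                stems["infra2_epithet"] = stem_epithet(rec.infra2_epithet)
            self._phonetic[nid] = keys
            self._stems[nid] = stems

    # -- queries ----------------------------------------------------------

    def __len__(self) -> int:
        return len(self._records)

    def __contains__(self, name_id: str) -> bool:
        return name_id in self._records

    def get(self, name_id: str) -> ReferenceName:
        try:
            return self._records[name_id]
        except KeyError:
            raise LookupError_(f"unknown name_id {name_id!r}") from None

    def records(self) -> list[ReferenceName]:
        return list(self._records.values())

    def source_priority(self, source_id: str) -> int:
        return self._priority.get(source_id, 10**9)

    def sources(self) -> list[str]:
        return sorted(self._priority, key=self._priority.get)

    def bounds(self, name_id: str) -> tuple[int, int]:
        self.get(name_id)
        return self._bounds[name_id]

    def phonetic_keys(self, name_id: str) -> dict[str, str]:
        return self._phonetic[name_id]

    def stemmed_epithets(self, name_id: str) -> dict[str, str]:
        return self._stems[name_id]

    def descendants(self, name_id: str) -> set[str]:
        """All records inside the query's nested-set interval, excluding itself."""
        left, right = self.bounds(name_id)
        return {
            nid
            for nid, (l, r) in self._bounds.items()
            if left < l and r < right
        }

    def children(self, name_id: Optional[str]) -> list[ReferenceName]:
        return [self._records[nid] for nid in self._children.get(name_id, [])]

    def families(self) -> list[ReferenceName]:
        return [r for r in self._records.values() if r.rank == "family"]

    def genera(self) -> list[ReferenceName]:
        return [r for r in self._records.values() if r.rank == "genus"]

    def species_of(self, genus_id: str) -> list[ReferenceName]:
        return [r for r in self.children(genus_id) if r.rank == "species"]

    def infraspecifics_of(self, species_id: str) -> list[ReferenceName]:
        return [
            r for r in self.children(species_id)
            if r.rank in ("subspecies", "variety", "forma")
        ]

    def resolve_accepted(self, name_id: str) -> ReferenceName:
        """The accepted name for a record (itself when accepted or no_opinion)."""
        rec = self.get(name_id)
        if rec.status in ("accepted", "no_opinion"):
            return rec
        if rec.accepted_name_id is None:
            raise ExchangeValidationError(
                f"{name_id!r} has status {rec.status!r} but no accepted name link"
            )
        return self.get(rec.accepted_name_id)

    def exact_lookup(
        self,
        canonical: str,
        author: str = "",
        source_ids: Optional[list[str]] = None,
    ) -> list[ReferenceName]:
        """Case-sensitive exact match on the canonical name.

        The author is compared only when supplied.  Results are ordered
        by source priority (then name_id for determinism).
        """
        if not canonical:
            raise ValueError("canonical must be non-empty")
        hits = [self._records[nid] for nid in self._canonical_index.get(canonical, [])]
        if author:
            hits = [r for r in hits if r.author == author]
        return self._order_hits(hits, source_ids)

    def exact_lookup_string(
        self, text: str, source_ids: Optional[list[str]] = None
    ) -> list[ReferenceName]:
        """Exact match of a whole string against canonical or canonical+author."""
        hits = {nid for nid in self._canonical_index.get(text, [])}
        hits |= {nid for nid in self._full_index.get(text, [])}
        return self._order_hits([self._records[nid] for nid in hits], source_ids)

    def _order_hits(
        self, hits: list[ReferenceName], source_ids: Optional[list[str]]
    ) -> list[ReferenceName]:
        if source_ids is not None:
            order = {sid: i for i, sid in enumerate(source_ids)}
            hits = [r for r in hits if r.source_id in order]
            return sorted(hits, key=lambda r: (order[r.source_id], r.name_id))
        return sorted(
            hits, key=lambda r: (self.source_priority(r.source_id), r.name_id)
        )

    # -- export -----------------------------------------------------------

    def export_exchange_file(self, path: str, source_id: str) -> int:
        """Write one source back out in the exchange format; returns rows written."""
        recs = [r for r in self._records.values() if r.source_id == source_id]
        recs.sort(key=lambda r: r.taxon_id)
        with open(path, "w", encoding="utf-8", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(EXCHANGE_COLUMNS)
            for r in recs:
                strip = lambda nid: nid.split(":", 1)[1] if nid else ""
                writer.writerow([
                    r.taxon_id,
                    r.canonical,
                    r.author,
                    r.rank,
                    strip(r.parent_id),
                    strip(r.accepted_name_id),
                    r.status,
                    "" if r.rank == "family" else r.family,
                ])
        return len(recs)
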