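"""Searchable term index over merged concepts, with snapshot persistence.

Every descriptor of every merged concept is indexed under a folded form of
the term; a posting records which concept the term points to and at what
match strength. Member ids index at CONCEPT_ID strength so a group is
reachable through any constituent record's identifier. Persistence is a
single-file JSON snapshot with an embedded schema version — hermetic,
diffable, and sufficient for local deployments.
"""
from __future__ import annotations

import json
import unicodedata
from dataclasses import dataclass, field
from enum import IntEnum
from typing import Iterable

from .errors import SchemaVersionError
from .graph import MergedConcept

SCHEMA_VERSION = 1


class MatchType(IntEnum):
    """Match strength, strongest first; NO_MATCH is strictly least."""

    CONCEPT_ID = 50
    LABEL = 40
    TRADE_NAME = 30
    ALIAS = 20
    XREF = 10
    NO_MATCH = 0


def fold_term(raw: str) -> str:
    """Canonical folded form used for all term lookups.

    Whitespace is trimmed and internal runs collapsed to single spaces; the
    result is Unicode case-folded and NFC-normalized. The same folding is
    applied to indexed descriptors and to queries, and to the
    pre-harmonization string comparison, so pre/post overlap numbers are
    computed on the same key space.
    """
    collapsed = " ".join(raw.split())
    return unicodedata.normalize("NFC", collapsed.casefold())


@dataclass
class TermIndex:
    """Folded term -> postings, plus the concept store.

    ``entries`` maps each folded term to ``{concept_id: MatchType}``; per
    (term, concept) pair only the strongest match type is kept. ``concepts``
    maps rendered concept ids to their merged records.
    """

    entries: dict[str, dict[str, MatchType]] = field(default_factory=dict)
    concepts: dict[str, MergedConcept] = field(default_factory=dict)

    def _post(self, term: str, concept_id: str, match_type: MatchType) -> None:
        folded = fold_term(term)
        if not folded:
            return
        postings = self.entries.setdefault(folded, {})
        if match_type > postings.get(concept_id, MatchType.NO_MATCH):
            postings[concept_id] = match_type

    def lookup(self, folded: str) -> dict[str, MatchType]:
        return dict(self.entries.get(folded, {}))

    def __len__(self) -> int:
        return len(self.entries)


def build_term_index(concepts: Iterable[MergedConcept]) -> TermIndex:
    """Index every concept's identifiers and descriptors.

    Postings: concept id and all member ids at CONCEPT_ID strength, the
    label at LABEL, trade names at TRADE_NAME, aliases at ALIAS, and
    external xrefs at XREF.
    """
    index = TermIndex()
    for concept in concepts:
        cid = str(concept.concept_id)
        index.concepts[cid] = concept
        index._post(cid, cid, MatchType.CONCEPT_ID)
        for member in concept.members:
            index._post(str(member), cid, MatchType.CONCEPT_ID)
        if concept.label:
            index._post(concept.label, cid, MatchType.LABEL)
        for name in concept.trade_names:
            index._post(name, cid, MatchType.TRADE_NAME)
        for alias in concept.aliases:
            index._post(alias, cid, MatchType.ALIAS)
        for xref in concept.xrefs:
            index._post(str(xref), cid, MatchType.XREF)
    return index


def save_index(index: TermIndex, path) -> None:
    """Write a snapshot; ``load_index`` restores it structurally equal."""
    payload = {
        "schema_version": SCHEMA_VERSION,
        "concepts": [
            index.concepts[cid].to_dict() for cid in sorted(index.concepts)
        ],
        "entries": {
            term: {cid: int(mt) for cid, mt in sorted(postings.items())}
            for term, postings in sorted(index.entries.items())
        },
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, ensure_ascii=False)


def load_index(path) -> TermIndex:
    """Load a snapshot written by :func:`save_index`.

    Raises :class:`SchemaVersionError` on a version mismatch and the usual
    I/O errors on unreadable paths.
    """
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    version = payload.get("schema_version")
    if version != SCHEMA_VERSION:
        raise SchemaVersionError(
            f"snapshot schema version {version!r} is not supported "
            f"(expected {SCHEMA_VERSION})"
        )
    index = TermIndex()
    for concept_payload in payload["concepts"]:
        concept = MergedConcept.from_dict(concept_payload)
        index.concepts[str(concept.concept_id)] = concept
    for term, postings in payload["entries"].items():
        index.entries[term] = {
            cid: MatchType(mt) for cid, mt in postings.items()
        }
    return index
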