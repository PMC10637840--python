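"""Record schema and interchange readers.

Therapeutic records arrive one per line in a JSON Lines interchange format.
Each record belongs to exactly one source vocabulary, carries a compact
identifier (CURIE, ``namespace:code``), descriptors (label, aliases, trade
names), outgoing cross-references to records in other sources, and optional
approval annotations.
"""
from __future__ import annotations

import io
import json
import unicodedata
from dataclasses import dataclass
from typing import Iterable, Iterator, Optional

from pydantic import BaseModel, field_validator

from .errors import (
    DuplicateRecordError,
    ParseError,
    RecordValidationError,
    SourceMismatchError,
)
from .registry import SourceMeta, SourceRegistry, default_registry


@dataclass(frozen=True, order=True)
class Curie:
    """Compact identifier ``namespace:code`` (e.g. ``rxcui:282388``).

    The namespace is a lowercase registered token; the code is a nonempty
    string that may not itself contain a colon, so rendering introduces
    exactly one separator.
    """

    namespace: str
    code: str

    def __post_init__(self):
        if not self.namespace or self.namespace != self.namespace.lower():
            raise ValueError(f"namespace must be a lowercase token: {self.namespace!r}")
        if not self.code:
            raise ValueError("code must be nonempty")
        if ":" in self.code:
            raise ValueError(f"code may not contain ':': {self.code!r}")

    def __str__(self) -> str:
        return f"{self.namespace}:{self.code}"

    @classmethod
    def parse(cls, text: str, registry: SourceRegistry | None = None) -> "Curie":
        """Parse a rendered CURIE, optionally canonicalizing the namespace."""
        ns, sep, code = text.partition(":")
        if not sep:
            raise ValueError(f"not a CURIE (missing ':'): {text!r}")
        if registry is not None:
            return canonicalize_curie(ns, code, registry)
        return cls(ns.strip().lower(), code.strip())


def canonicalize_curie(
    namespace_raw: str, code_raw: str, registry: SourceRegistry | None = None
) -> Curie:
    """Build a canonical :class:`Curie` from raw namespace and code parts.

    The namespace is lowercased and mapped through the registry's synonym
    table (``RxNorm`` -> ``rxcui``); the code is whitespace-trimmed with case
    preserved. Unknown namespaces raise :class:`UnknownNamespaceError`.
    """
    registry = registry if registry is not None else default_registry()
    ns = registry.resolve_namespace(namespace_raw)
    code = code_raw.strip()
    if not code:
        raise ValueError("code must be nonempty after trimming")
    return Curie(ns, code)


def _nfc(value: str) -> str:
    return unicodedata.normalize("NFC", value)


class Approval(BaseModel):
    """Regulatory approval annotation: a status plus application codes."""

    model_config = {"frozen": True}

    status: str
    applications: tuple[str, ...] = ()

    @field_validator("status")
    @classmethod
    def _norm_status(cls, v: str) -> str:
        return _nfc(v)


@dataclass(frozen=True)
class SourceRecord:
    """One therapeutic entry from one source vocabulary.

    Descriptor strings are stored as given, NFC-normalized, so multi-language
    labels survive round-trips. Invariants (namespace agreement, nonempty
    descriptors, no self-xref) are checked by :func:`validate_record`, which
    reports violations as data rather than raising.
    """

    id: Curie
    label: str = ""
    aliases: frozenset[str] = frozenset()
    trade_names: frozenset[str] = frozenset()
    xrefs: frozenset[Curie] = frozenset()
    associations: frozenset[str] = frozenset()
    approval: Optional[Approval] = None

    def __post_init__(self):
        object.__setattr__(self, "label", _nfc(self.label))
        object.__setattr__(self, "aliases", frozenset(_nfc(a) for a in self.aliases))
        object.__setattr__(
            self, "trade_names", frozenset(_nfc(t) for t in self.trade_names)
        )
        object.__setattr__(self, "xrefs", frozenset(self.xrefs))
        object.__setattr__(
            self, "associations", frozenset(_nfc(a) for a in self.associations)
        )

    def descriptors(self) -> set[str]:
        """All searchable surface strings: label, aliases, trade names."""
        out = set(self.aliases) | set(self.trade_names)
        if self.label:
            out.add(self.label)
        return out


@dataclass(frozen=True)
class Violation:
    """One schema-invariant violation: the offending field and the rule."""

    field: str
    rule: str
    detail: str = ""

    def __str__(self) -> str:
        msg = f"{self.field}: {self.rule}"
        return f"{msg} ({self.detail})" if self.detail else msg


def validate_record(record: SourceRecord) -> list[Violation]:
    """Check all :class:`SourceRecord` invariants; empty list means valid."""
    violations: list[Violation] = []
    for name, values in (("aliases", record.aliases), ("trade_names", record.trade_names)):
        for v in values:
            if not v.strip():
                violations.append(
                    Violation(name, "empty-descriptor", f"whitespace-only entry {v!r}")
                )
    if record.id in record.xrefs:
        violations.append(
            Violation("xrefs", "self-xref", f"record references its own id {record.id}")
        )
    return violations


def record_to_dict(record: SourceRecord) -> dict:
    """Serialize one record to a plain dict with deterministic array order."""
    out: dict = {"id": str(record.id)}
    if record.label:
        out["label"] = record.label
    if record.aliases:
        out["aliases"] = sorted(record.aliases)
    if record.trade_names:
        out["trade_names"] = sorted(record.trade_names)
    if record.xrefs:
        out["xrefs"] = sorted(str(x) for x in record.xrefs)
    if record.associations:
        out["associations"] = sorted(record.associations)
    if record.approval is not None:
        out["approval"] = {
            "status": record.approval.status,
            "applications": sorted(record.approval.applications),
        }
    return out


def record_from_dict(payload: dict, registry: SourceRegistry | None = None) -> SourceRecord:
    """Deserialize one record; CURIEs are canonicalized through the registry."""
    registry = registry if registry is not None else default_registry()
    approval = payload.get("approval")
    return SourceRecord(
        id=Curie.parse(payload["id"], registry),
        label=payload.get("label", ""),
        aliases=frozenset(payload.get("aliases", ())),
        trade_names=frozenset(payload.get("trade_names", ())),
        xrefs=frozenset(Curie.parse(x, registry) for x in payload.get("xrefs", ())),
        associations=frozenset(payload.get("associations", ())),
        approval=Approval(**approval) if approval else None,
    )


def parse_source_records(
    stream: Iterable[str] | io.TextIOBase,
    meta: SourceMeta | None = None,
    registry: SourceRegistry | None = None,
    strict: bool = True,
) -> list[SourceRecord]:
    """Read records from a JSON Lines stream, in input order.

    Parameters
    ----------
    stream:
        Iterable of lines (or an open text file), one JSON record per line.
        Blank lines are ignored.
    meta:
        Declaring source; when given, every record id must live in that
        source's namespace.
    strict:
        When true (default), invariant violations raise
        :class:`RecordValidationError`.

    Raises
    ------
    ParseError
        Malformed JSON, with the 1-based line number.
    DuplicateRecordError
        Two records with the same id in one stream.
    SourceMismatchError
        A record namespace differing from ``meta.name``.
    """
    registry = registry if registry is not None else default_registry()
    records: list[SourceRecord] = []
    seen: set[Curie] = set()
    violations: list[Violation] = []
    for lineno, line in enumerate(stream, start=1):
        if not line.strip():
            continue
        try:
            payload = json.loads(line)
        except json.JSONDecodeError as exc:
            raise ParseError(f"malformed record: {exc.msg}", lineno) from exc
        if not isinstance(payload, dict) or "id" not in payload:
            raise ParseError("record must be a JSON object with an 'id' field", lineno)
        try:
            record = record_from_dict(payload, registry)
        except (ValueError, TypeError) as exc:
            raise ParseError(str(exc), lineno) from exc
        if meta is not None and record.id.namespace != meta.name:
            raise SourceMismatchError(
                f"line {lineno}: record {record.id} does not belong to source {meta.name!r}"
            )
        if record.id in seen:
            raise DuplicateRecordError(f"line {lineno}: duplicate record id {record.id}")
        seen.add(record.id)
        violations.extend(validate_record(record))
        records.append(record)
    if strict and violations:
        raise RecordValidationError(violations)
    return records


def serialize_records(records: Iterable[SourceRecord]) -> Iterator[str]:
    """Yield one JSON line per record, field order deterministic."""
    for record in records:
        yield json.dumps(record_to_dict(record), ensure_ascii=False, sort_keys=False)


def write_records(records: Iterable[SourceRecord], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for line in serialize_records(records):
            fh.write(line + "\n")


def read_records(
    path,
    meta: SourceMeta | None = None,
    registry: SourceRegistry | None = None,
    strict: bool = True,
) -> list[SourceRecord]:
    with open(path, encoding="utf-8") as fh:
        return parse_source_records(fh, meta=meta, registry=registry, strict=strict)
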