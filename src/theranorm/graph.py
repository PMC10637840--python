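"""Cross-reference graph construction and concept merging.

Records act as nodes and curated cross-references act as directed
"has reference to" edges. Grouping ignores edge direction: curated xrefs are
frequently unreciprocated, and a one-directional pointer is still evidence
that the two records describe the same therapeutic. Each weakly connected
component becomes one merged concept, identified by its anchor node — the
member from the most trusted source.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from typing import Iterable, Iterator, Optional, Sequence

import networkx as nx

from .errors import TheranormError
from .records import Approval, Curie, SourceRecord
from .registry import SourceRegistry, default_registry

logger = logging.getLogger(__name__)

#: Components larger than this trigger a possible-overmerge warning.
DEFAULT_SIZE_WARNING = 50


@dataclass
class ReferenceGraph:
    """Directed graph over record identifiers, plus the dangling xrefs.

    ``dangling`` lists (source id, target id) pairs whose target is not a
    loaded record; such targets never become nodes — a stub node would
    fabricate a record the sources never declared.
    """

    digraph: nx.DiGraph
    dangling: list[tuple[Curie, Curie]]

    @property
    def nodes(self) -> set[Curie]:
        return set(self.digraph.nodes)

    @property
    def edges(self) -> set[tuple[Curie, Curie]]:
        return set(self.digraph.edges)


@dataclass(frozen=True)
class MergedConcept:
    """Unified record for one connected group of source records.

    The concept id is the anchor node's id; descriptors are the deduplicated
    union over members; xrefs are the members' external pointers (member ids
    removed, dangling externals retained).
    """

    concept_id: Curie
    anchor_source: str
    members: frozenset[Curie]
    label: str = ""
    label_fallback: bool = False
    aliases: frozenset[str] = frozenset()
    trade_names: frozenset[str] = frozenset()
    xrefs: frozenset[Curie] = frozenset()
    associations: frozenset[str] = frozenset()
    approval: Optional[Approval] = None

    def to_dict(self) -> dict:
        out: dict = {
            "concept_id": str(self.concept_id),
            "anchor_source": self.anchor_source,
            "members": sorted(str(m) for m in self.members),
            "label": self.label,
        }
        if self.label_fallback:
            out["label_fallback"] = True
        out["aliases"] = sorted(self.aliases)
        out["trade_names"] = sorted(self.trade_names)
        out["xrefs"] = sorted(str(x) for x in self.xrefs)
        out["associations"] = sorted(self.associations)
        if self.approval is not None:
            out["approval"] = {
                "status": self.approval.status,
                "applications": sorted(self.approval.applications),
            }
        return out

    @classmethod
    def from_dict(cls, payload: dict) -> "MergedConcept":
        approval = payload.get("approval")
        return cls(
            concept_id=Curie.parse(payload["concept_id"]),
            anchor_source=payload["anchor_source"],
            members=frozenset(Curie.parse(m) for m in payload["members"]),
            label=payload.get("label", ""),
            label_fallback=payload.get("label_fallback", False),
            aliases=frozenset(payload.get("aliases", ())),
            trade_names=frozenset(payload.get("trade_names", ())),
            xrefs=frozenset(Curie.parse(x) for x in payload.get("xrefs", ())),
            associations=frozenset(payload.get("associations", ())),
            approval=Approval(**approval) if approval else None,
        )


def build_reference_graph(records: Sequence[SourceRecord]) -> ReferenceGraph:
    """Build the directed xref graph over the loaded records.

    Nodes are the record ids; an edge runs from a record to each xref target
    that is itself a loaded record. Xrefs to unloaded targets are reported in
    the dangling list instead of becoming edges.
    """
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise TheranormError("record ids must be unique to build a reference graph")
    loaded = set(ids)
    g: nx.DiGraph = nx.DiGraph()
    g.add_nodes_from(ids)
    dangling: list[tuple[Curie, Curie]] = []
    for record in records:
        for target in sorted(record.xrefs):
            if target == record.id:
                continue
            if target in loaded:
                g.add_edge(record.id, target)
            else:
                dangling.append((record.id, target))
    return ReferenceGraph(digraph=g, dangling=dangling)


def find_concept_components(graph: ReferenceGraph) -> list[set[Curie]]:
    """Partition the graph into weakly connected components.

    Direction is ignored for grouping; it is retained on the graph for
    provenance only. Components are returned sorted by their smallest member
    id (rendered form), and are disjoint and covering by construction.
    """
    components = [set(c) for c in nx.weakly_connected_components(graph.digraph)]
    return sorted(components, key=lambda c: min(str(m) for m in c))


def select_anchor(members: Iterable[Curie], registry: SourceRegistry | None = None) -> Curie:
    """Pick the anchor node: minimal source rank, then smallest code.

    The anchor's id names the merged concept. Ties within one source are
    broken by lexicographically smallest code for determinism.
    """
    registry = registry if registry is not None else default_registry()
    members = list(members)
    if not members:
        raise TheranormError("cannot select an anchor from an empty member set")
    return min(members, key=lambda m: (registry.rank(m.namespace), m.code))


def _canonical_member_order(
    records: Sequence[SourceRecord], registry: SourceRegistry
) -> list[SourceRecord]:
    return sorted(records, key=lambda r: (registry.rank(r.id.namespace), r.id.code))


def _dedupe_casefold(values: Iterable[str]) -> frozenset[str]:
    """Deduplicate under case-folding, keeping the first-seen surface form."""
    seen: dict[str, str] = {}
    for v in values:
        key = v.casefold()
        if key not in seen:
            seen[key] = v
    return frozenset(seen.values())


def merge_component(
    members: Sequence[SourceRecord],
    anchor: Curie,
    registry: SourceRegistry | None = None,
) -> MergedConcept:
    """Merge one component's records under the anchor's identifier.

    The label is the anchor record's label, falling back down the source
    priority order when empty (the fallback is flagged on the output).
    Member labels other than the chosen one are folded into the alias union
    so every descriptor remains searchable. Aliases, trade names and
    associations are deduplicated unions; per case-folded key the surface
    form from the highest-priority member wins.
    """
    registry = registry if registry is not None else default_registry()
    by_id = {r.id: r for r in members}
    if anchor not in by_id:
        raise TheranormError(f"anchor {anchor} is not among the component members")
    ordered = _canonical_member_order(members, registry)

    label = by_id[anchor].label
    fallback = False
    if not label:
        for record in ordered:
            if record.label:
                label = record.label
                fallback = True
                break

    member_ids = frozenset(by_id)

    def _alias_pool():
        for r in ordered:
            if r.label and r.label.casefold() != label.casefold():
                yield r.label
            yield from sorted(r.aliases)

    aliases = _dedupe_casefold(_alias_pool())
    trade_names = _dedupe_casefold(t for r in ordered for t in sorted(r.trade_names))
    associations = _dedupe_casefold(a for r in ordered for a in sorted(r.associations))
    xrefs = frozenset(
        x for r in ordered for x in r.xrefs if x not in member_ids
    )
    approval = next((r.approval for r in ordered if r.approval is not None), None)

    return MergedConcept(
        concept_id=anchor,
        anchor_source=anchor.namespace,
        members=member_ids,
        label=label,
        label_fallback=fallback,
        aliases=aliases,
        trade_names=trade_names,
        xrefs=xrefs,
        associations=associations,
        approval=approval,
    )


def normalize_corpus(
    records: Sequence[SourceRecord],
    registry: SourceRegistry | None = None,
    size_warning: int = DEFAULT_SIZE_WARNING,
) -> list[MergedConcept]:
    """Run the full grouping routine: graph, components, anchors, merges.

    The output is sorted by concept id and is independent of input record
    order. Over-merged "mega-components" are kept intact (no splitting); a
    warning is logged above ``size_warning`` members.
    """
    registry = registry if registry is not None else default_registry()
    graph = build_reference_graph(records)
    by_id = {r.id: r for r in records}
    concepts: list[MergedConcept] = []
    for component in find_concept_components(graph):
        if len(component) > size_warning:
            logger.warning(
                "component of %d records (> %d) — possible over-merge, kept intact",
                len(component),
                size_warning,
            )
        anchor = select_anchor(component, registry)
        concepts.append(
            merge_component([by_id[m] for m in component], anchor, registry)
        )
    return sorted(concepts, key=lambda c: str(c.concept_id))


def serialize_concepts(concepts: Iterable[MergedConcept]) -> Iterator[str]:
    """One JSON line per concept, deterministic field and array order."""
    for concept in concepts:
        yield json.dumps(concept.to_dict(), ensure_ascii=False)


def write_concepts(concepts: Iterable[MergedConcept], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for line in serialize_concepts(concepts):
            fh.write(line + "\n")
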