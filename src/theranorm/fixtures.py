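"""Hermetic multi-source fixtures with known ground truth.

Three fixture families:

* a synthetic corpus generator that plants concepts across sources, wires
  cross-references per a chosen topology, optionally thins them, and records
  ground truth for recovery tests;
* the packaged imatinib worked example — nine records, one per source,
  forming a single connected group anchored at ``rxcui:282388``, carrying
  the generic name, development code, salt forms and thirteen trade names;
* the packaged failure-term vocabularies: surface terms (general drug
  categories, treatment regimens, cell-therapy descriptions, misspellings,
  unknown identifiers) that a descriptor-exact normalizer cannot resolve.

Synthetic codes use clearly artificial placeholders (``SYN``/``RND``
counters) so fixtures never impersonate real vocabulary codes; the only
real identifiers are the two printed imatinib CURIEs.
"""
from __future__ import annotations

import json
import random
from importlib import resources
from pathlib import Path
from typing import Literal

from pydantic import BaseModel, Field, model_validator

from .errors import ConfigError
from .index import fold_term
from .records import Approval, Curie, SourceRecord, write_records
from .registry import default_registry

_CONSONANTS = "bdfgklmnprstvz"
_VOWELS = "aeiou"

Topology = Literal["star-to-anchor", "chain", "random-spanning"]


class FixtureSpec(BaseModel):
    """Parameters of one synthetic corpus.

    ``sources_per_concept``, ``alias_count`` and ``trade_name_count`` are
    weighted distributions (value -> weight). Defaults emulate realistic
    study conditions: most concepts appear in 2–5 sources, carry a couple of
    aliases and at most a couple of trade names, and every non-anchor record
    points at its anchor (star topology) with no dropout.
    """

    n_concepts: int = Field(ge=1, default=50)
    sources_per_concept: dict[int, float] = {
        1: 0.10, 2: 0.40, 3: 0.25, 4: 0.12, 5: 0.08, 6: 0.05,
    }
    xref_topology: Topology = "star-to-anchor"
    xref_dropout_p: float = Field(ge=0.0, le=1.0, default=0.0)
    alias_count: dict[int, float] = {0: 0.2, 1: 0.4, 2: 0.3, 3: 0.1}
    trade_name_count: dict[int, float] = {0: 0.5, 1: 0.3, 2: 0.2}
    shared_term_rate: float = Field(ge=0.0, le=1.0, default=0.0)
    seed: int = 7

    @model_validator(mode="after")
    def _check_distributions(self):
        for name, dist in (
            ("sources_per_concept", self.sources_per_concept),
            ("alias_count", self.alias_count),
            ("trade_name_count", self.trade_name_count),
        ):
            if not dist or any(w < 0 for w in dist.values()) or sum(dist.values()) <= 0:
                raise ConfigError(f"{name} must be a nonempty nonnegative distribution")
        if any(not 1 <= k <= 9 for k in self.sources_per_concept):
            raise ConfigError("sources_per_concept support must lie in 1..9")
        return self


class GroundTruth(BaseModel):
    """True record-to-concept assignment of a generated corpus."""

    assignment: dict[str, int]
    descriptors: dict[int, list[str]]

    def partition(self) -> list[set[str]]:
        """True member sets, sorted by smallest member id."""
        groups: dict[int, set[str]] = {}
        for record_id, concept in self.assignment.items():
            groups.setdefault(concept, set()).add(record_id)
        return sorted(groups.values(), key=min)


def _sample(rng: random.Random, dist: dict[int, float]) -> int:
    values = sorted(dist)
    return rng.choices(values, weights=[dist[v] for v in values], k=1)[0]


def _token(rng: random.Random, syllables: int) -> str:
    """Pronounceable lowercase token of alternating consonant-vowel pairs."""
    return "".join(
        rng.choice(_CONSONANTS) + rng.choice(_VOWELS) for _ in range(syllables)
    )


def _code_alias(rng: random.Random) -> str:
    prefix = "".join(rng.choice(_CONSONANTS) for _ in range(3)).upper()
    return f"{prefix}-{rng.randrange(100, 1000)}"


def generate_sources(
    spec: FixtureSpec,
) -> tuple[dict[str, list[SourceRecord]], GroundTruth]:
    """Generate per-source record lists plus ground truth.

    Deterministic for a fixed seed (explicit Mersenne Twister stream, no
    environment-dependent state). Each concept is materialized as one record
    per sampled source; cross-references are wired per the topology, then
    each edge is dropped independently with probability ``xref_dropout_p``.
    """
    registry = default_registry()
    rng = random.Random(spec.seed)
    ranked_sources = registry.source_names()
    per_source: dict[str, list[SourceRecord]] = {s: [] for s in ranked_sources}
    assignment: dict[str, int] = {}
    inventory: dict[int, list[str]] = {}
    alias_pool: list[tuple[int, str]] = []

    for concept_idx in range(spec.n_concepts):
        base = _token(rng, rng.randint(3, 4))
        n_sources = min(_sample(rng, spec.sources_per_concept), len(ranked_sources))
        sources = sorted(
            rng.sample(ranked_sources, n_sources), key=registry.rank
        )
        ids = [Curie(src, f"RND{concept_idx:05d}") for src in sources]
        anchor_pos = 0  # sources sorted by rank: first is the anchor

        aliases: list[str] = []
        for _ in range(_sample(rng, spec.alias_count)):
            if alias_pool and rng.random() < spec.shared_term_rate:
                aliases.append(rng.choice(alias_pool)[1])
            else:
                alias = _code_alias(rng) if rng.random() < 0.5 else _token(rng, rng.randint(2, 3))
                aliases.append(alias)
                alias_pool.append((concept_idx, alias))
        trade_names = [
            _token(rng, rng.randint(2, 3)).capitalize()
            for _ in range(_sample(rng, spec.trade_name_count))
        ]

        # xref wiring (directed pairs of member positions)
        edges: list[tuple[int, int]] = []
        if len(ids) > 1:
            if spec.xref_topology == "star-to-anchor":
                edges = [(j, anchor_pos) for j in range(len(ids)) if j != anchor_pos]
            elif spec.xref_topology == "chain":
                edges = [(j, j - 1) for j in range(1, len(ids))]
            else:  # random spanning tree, random direction per edge
                order = list(range(len(ids)))
                rng.shuffle(order)
                for pos in range(1, len(order)):
                    a, b = order[pos], rng.choice(order[:pos])
                    edges.append((a, b) if rng.random() < 0.5 else (b, a))
            edges = [e for e in edges if rng.random() >= spec.xref_dropout_p]

        xrefs_by_pos: dict[int, set[Curie]] = {}
        for src_pos, dst_pos in edges:
            xrefs_by_pos.setdefault(src_pos, set()).add(ids[dst_pos])

        descriptors = {base} | set(aliases) | set(trade_names)
        inventory[concept_idx] = sorted(fold_term(d) for d in descriptors)
        for pos, (src, rid) in enumerate(zip(sources, ids)):
            assignment[str(rid)] = concept_idx
            record = SourceRecord(
                id=rid,
                label=base if pos == 0 else rng.choice([base, base.capitalize()]),
                aliases=frozenset(rng.sample(aliases, rng.randint(0, len(aliases)))
                                  if pos else aliases),
                trade_names=frozenset(trade_names if pos == 0
                                      else rng.sample(trade_names, rng.randint(0, len(trade_names)))),
                xrefs=frozenset(xrefs_by_pos.get(pos, set())),
            )
            per_source[src].append(record)

    truth = GroundTruth(assignment=assignment, descriptors=inventory)
    return per_source, truth


def all_records(per_source: dict[str, list[SourceRecord]]) -> list[SourceRecord]:
    """Flatten a per-source mapping into one record list, source-rank order."""
    registry = default_registry()
    out: list[SourceRecord] = []
    for src in registry.source_names():
        out.extend(per_source.get(src, []))
    return out


def write_fixture(
    per_source: dict[str, list[SourceRecord]],
    out_dir,
    truth: GroundTruth | None = None,
) -> list[Path]:
    """Write one JSON Lines file per source (plus optional ground truth)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for src in sorted(per_source):
        if not per_source[src]:
            continue
        path = out_dir / f"{src}.jsonl"
        write_records(per_source[src], path)
        written.append(path)
    if truth is not None:
        path = out_dir / "ground_truth.json"
        path.write_text(truth.model_dump_json(indent=2), encoding="utf-8")
        written.append(path)
    return written


#: The thirteen printed trade names of the worked example.
IMATINIB_TRADE_NAMES = (
    "Gleevec", "Glivec", "Celonib", "Enliven", "Gleevac", "Imalek", "Imatib",
    "Mesylonib", "Mitinab", "Plivatinib", "Shantinib", "Temsan", "Veenat",
)

#: Sixteen surface forms that must all resolve to the single merged concept.
IMATINIB_SURFACE_FORMS = (
    "imatinib", "imatinib mesylate", "STI-571", *IMATINIB_TRADE_NAMES,
)


def imatinib_records() -> dict[str, list[SourceRecord]]:
    """The packaged imatinib worked example: nine records, one per source.

    The two printed identifiers (``rxcui:282388``, ``drugbank:DB00619``) are
    real, including the printed xref direction; every other code is a
    synthetic ``SYN`` placeholder. The nine records form a single weakly
    connected component whose anchor, under the default priority order, is
    the RxNorm record.
    """
    r = lambda ns, code: Curie(ns, code)  # noqa: E731 - local shorthand
    records = {
        "rxcui": [SourceRecord(
            id=r("rxcui", "282388"),
            label="imatinib mesylate",
            aliases=frozenset({"imatinib methanesulfonate"}),
            trade_names=frozenset({"Gleevec"}),
            xrefs=frozenset({r("drugbank", "DB00619")}),
        )],
        "ncit": [SourceRecord(
            id=r("ncit", "SYN0001"),
            label="Imatinib",
            trade_names=frozenset({"Gleevec", "Glivec"}),
            xrefs=frozenset({r("rxcui", "282388")}),
        )],
        "hemonc": [SourceRecord(
            id=r("hemonc", "SYN0002"),
            label="imatinib",
            associations=frozenset({"indication:chronic myelogenous leukemia"}),
            xrefs=frozenset({r("rxcui", "282388")}),
        )],
        "drugbank": [SourceRecord(
            id=r("drugbank", "DB00619"),
            label="Imatinib",
            aliases=frozenset({"STI-571"}),
        )],
        "drugsatfda": [SourceRecord(
            id=r("drugsatfda", "SYN0003"),
            label="IMATINIB MESYLATE",
            approval=Approval(status="approved", applications=("NDA-SYN021588",)),
            xrefs=frozenset({r("rxcui", "282388")}),
        )],
        "guidetopharmacology": [SourceRecord(
            id=r("guidetopharmacology", "SYN0004"),
            label="imatinib",
            xrefs=frozenset({r("drugbank", "DB00619")}),
        )],
        "chembl": [SourceRecord(
            id=r("chembl", "SYN0005"),
            label="IMATINIB",
            aliases=frozenset({"STI-571"}),
            xrefs=frozenset({r("drugbank", "DB00619")}),
        )],
        "chemidplus": [SourceRecord(
            id=r("chemidplus", "SYN0006"),
            label="Imatinib mesylate",
            xrefs=frozenset({r("rxcui", "282388")}),
        )],
        "wikidata": [SourceRecord(
            id=r("wikidata", "SYN0007"),
            label="imatinib",
            trade_names=frozenset(IMATINIB_TRADE_NAMES),
            xrefs=frozenset({r("chembl", "SYN0005")}),
        )],
    }
    return records


def imatinib_fixture(out_dir) -> list[Path]:
    """Write the imatinib worked example as per-source record files."""
    return write_fixture(imatinib_records(), out_dir)


def _packaged_terms(filename: str) -> list[str]:
    text = resources.files("theranorm.data").joinpath(filename).read_text("utf-8")
    return [
        line.strip()
        for line in text.splitlines()
        if line.strip() and not line.strip().startswith("#")
    ]


def table1_terms() -> list[str]:
    """The 25 most frequent failure terms (verbatim)."""
    return _packaged_terms("table1_terms.txt")


def table2_terms() -> list[str]:
    """Additional annotated failure-term examples (verbatim)."""
    return _packaged_terms("table2_terms.txt")


def failure_terms_fixture(out_dir) -> list[Path]:
    """Write the packaged failure vocabularies as plain-text term lists."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, terms in (
        ("failure_terms_frequent.txt", table1_terms()),
        ("failure_terms_examples.txt", table2_terms()),
    ):
        path = out_dir / name
        path.write_text("\n".join(terms) + "\n", encoding="utf-8")
        written.append(path)
    return written
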