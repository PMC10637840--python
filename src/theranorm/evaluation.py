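"""Vocabulary overlap and normalization-rate evaluation.

Reproduces the evaluation design at fixture scale: exact-string vocabulary
intersections before harmonization, concept-id intersections after, the
fraction of items shared by two or more vocabularies, anchor-source
distributions for normalized terms, and merged-group size histograms.

Both comparison modes use the same term folding as the lookup index: a
stricter pre-harmonization string match would make the pre/post comparison
incoherent.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd

from .errors import ConfigError
from .graph import MergedConcept
from .index import TermIndex, fold_term
from .query import QueryResult, normalize_term

#: Key under which normalization failures are counted in anchor distributions.
UNNORMALIZED = "unnormalized"


@dataclass
class VocabularySet:
    """A named vocabulary: unique folded terms with surface forms retained.

    Aggregate vocabularies (those compiled from other resources) can be
    flagged so an analysis may exclude them from pre-harmonization
    comparisons.
    """

    name: str
    surface_forms: dict[str, str] = field(default_factory=dict)
    aggregate: bool = False

    @property
    def terms(self) -> set[str]:
        """The folded, deduplicated term set."""
        return set(self.surface_forms)

    @classmethod
    def from_terms(
        cls, name: str, terms: Iterable[str], aggregate: bool = False
    ) -> "VocabularySet":
        surface: dict[str, str] = {}
        for raw in terms:
            folded = fold_term(raw)
            if folded and folded not in surface:
                surface[folded] = raw.strip()
        return cls(name=name, surface_forms=surface, aggregate=aggregate)

    @classmethod
    def from_file(cls, path, name: str | None = None, aggregate: bool = False) -> "VocabularySet":
        """Read a plain-text vocabulary: one term per line, ``#`` comments."""
        terms = read_term_list(path)
        if name is None:
            name = str(path)
        return cls.from_terms(name, terms, aggregate=aggregate)


def read_term_list(path) -> list[str]:
    """Read one term per line; blank lines and ``#`` comments are ignored."""
    terms: list[str] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            stripped = line.strip()
            if stripped and not stripped.startswith("#"):
                terms.append(stripped)
    return terms


@dataclass
class IntersectionReport:
    """Item counts per exact subset of vocabularies (UpSet-style).

    ``subset_counts`` maps a sorted tuple of vocabulary names to the number
    of items present in exactly that subset; counts sum to the number of
    distinct items. ``mode`` records whether items are folded strings or
    concept ids; ``failures`` lists, per vocabulary, terms excluded because
    they did not normalize (concept mode only).
    """

    mode: str
    subset_counts: dict[tuple[str, ...], int]
    vocab_names: tuple[str, ...]
    failures: dict[str, list[str]] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    @property
    def total_items(self) -> int:
        return sum(self.subset_counts.values())

    def items_in_subsets_of_size(self, k_min: int, k_max: int | None = None) -> int:
        return sum(
            n
            for subset, n in self.subset_counts.items()
            if len(subset) >= k_min and (k_max is None or len(subset) <= k_max)
        )

    def to_frame(self) -> pd.DataFrame:
        """Tabular view: one row per nonempty subset, sorted for diffability."""
        rows = [
            {"subset": "&".join(subset), "degree": len(subset), "count": n}
            for subset, n in sorted(self.subset_counts.items())
        ]
        return pd.DataFrame(rows, columns=["subset", "degree", "count"])

    def membership_matrix(self) -> pd.DataFrame:
        """Boolean membership matrix (subset x vocabulary) with counts."""
        rows = []
        for subset, n in sorted(self.subset_counts.items()):
            row = {name: name in subset for name in self.vocab_names}
            row["count"] = n
            rows.append(row)
        return pd.DataFrame(rows, columns=[*self.vocab_names, "count"])

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def write_json(self, path) -> None:
        payload = {
            "mode": self.mode,
            "vocabularies": list(self.vocab_names),
            "subsets": [
                {"subset": list(subset), "count": n}
                for subset, n in sorted(self.subset_counts.items())
            ],
            "failures": self.failures,
            "metadata": self.metadata,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, ensure_ascii=False, indent=2)


def _check_vocabs(vocabs: Sequence[VocabularySet]) -> None:
    if len(vocabs) < 2:
        raise ConfigError("overlap analysis needs at least 2 vocabularies")
    names = [v.name for v in vocabs]
    if len(set(names)) != len(names):
        raise ConfigError("duplicate vocabulary names")


def string_overlap(vocabs: Sequence[VocabularySet]) -> IntersectionReport:
    """Pre-harmonization intersections: items are exact folded strings."""
    _check_vocabs(vocabs)
    counts: dict[tuple[str, ...], int] = {}
    all_terms = set().union(*(v.terms for v in vocabs))
    for term in all_terms:
        subset = tuple(sorted(v.name for v in vocabs if term in v.terms))
        counts[subset] = counts.get(subset, 0) + 1
    return IntersectionReport(
        mode="STRING",
        subset_counts=counts,
        vocab_names=tuple(v.name for v in vocabs),
        metadata={"canonicalization": "fold_term", "aggregate_flagged": [
            v.name for v in vocabs if v.aggregate
        ]},
    )


def concept_overlap(
    vocabs: Sequence[VocabularySet], index: TermIndex
) -> IntersectionReport:
    """Post-harmonization intersections: items are merged concept ids.

    Each folded term is normalized; terms without a merged concept are
    excluded from intersection counting but reported per vocabulary.
    """
    _check_vocabs(vocabs)
    failures: dict[str, list[str]] = {}
    concept_sets: dict[str, set[str]] = {}
    for vocab in vocabs:
        concepts: set[str] = set()
        failed: list[str] = []
        for folded in sorted(vocab.terms):
            result = normalize_term(folded, index)
            if result.is_success:
                concepts.add(str(result.concept.concept_id))
            else:
                failed.append(vocab.surface_forms[folded])
        concept_sets[vocab.name] = concepts
        if failed:
            failures[vocab.name] = failed
    counts: dict[tuple[str, ...], int] = {}
    all_concepts = set().union(*concept_sets.values())
    for cid in all_concepts:
        subset = tuple(sorted(n for n, s in concept_sets.items() if cid in s))
        counts[subset] = counts.get(subset, 0) + 1
    return IntersectionReport(
        mode="CONCEPT",
        subset_counts=counts,
        vocab_names=tuple(v.name for v in vocabs),
        failures=failures,
        metadata={"canonicalization": "fold_term"},
    )


def overlap_fraction(report: IntersectionReport) -> Optional[float]:
    """Fraction of items present in two or more vocabularies (null if empty)."""
    total = report.total_items
    if total == 0:
        return None
    return report.items_in_subsets_of_size(2) / total


def anchor_distribution(results: Iterable[QueryResult]) -> dict[str, int]:
    """Count anchor sources among results; failures under ``unnormalized``.

    Successful results are tallied by the namespace of their concept id (the
    anchor node's source); results without a concept — failures and
    ambiguous hits alike — are tallied under the reserved key.
    """
    counts: dict[str, int] = {}
    for result in results:
        key = (
            result.concept.concept_id.namespace
            if result.concept is not None
            else UNNORMALIZED
        )
        counts[key] = counts.get(key, 0) + 1
    return counts


def group_size_histogram(
    concepts: Sequence[MergedConcept],
) -> tuple[dict[int, int], Optional[float]]:
    """Histogram of merged-group sizes and the share of sizes in [2, 5]."""
    hist: dict[int, int] = {}
    for concept in concepts:
        size = len(concept.members)
        hist[size] = hist.get(size, 0) + 1
    total = sum(hist.values())
    if total == 0:
        return hist, None
    in_band = sum(n for size, n in hist.items() if 2 <= size <= 5)
    return hist, in_band / total
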