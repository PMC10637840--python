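"""Scikit-learn style estimator wrapping the full normalization pipeline.

``TherapyNormalizer`` is fitted on source records (building the
cross-reference graph, merged concepts and term index) and then maps raw
surface terms to merged concept identifiers via ``transform`` / ``predict``.
It follows the scikit-learn estimator contract (``get_params`` /
``set_params``, fitted attributes with trailing underscores, ``clone``
compatibility), so it composes with sklearn pipelines operating on string
features.
"""
from __future__ import annotations

from typing import Iterable, Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.exceptions import NotFittedError

from .graph import DEFAULT_SIZE_WARNING, MergedConcept, normalize_corpus
from .index import TermIndex, build_term_index
from .query import BatchSummary, QueryResult, batch_normalize, normalize_term
from .records import SourceRecord
from .registry import SourceRegistry


class TherapyNormalizer(TransformerMixin, BaseEstimator):
    """Normalize raw therapeutic terms to merged concept identifiers.

    Parameters
    ----------
    registry:
        Source registry to use; ``None`` selects the packaged nine-source
        registry with the default priority order.
    size_warning:
        Log a possible-overmerge warning for groups larger than this.
    missing_value:
        Output token for terms that do not resolve to a unique concept
        (failures and ambiguous ties).

    Attributes
    ----------
    concepts_ : list of MergedConcept
        The merged concepts, sorted by concept id.
    index_ : TermIndex
        The searchable term index over the merged concepts.
    n_records_ : int
        Number of source records consumed during ``fit``.
    """

    def __init__(
        self,
        registry: Optional[SourceRegistry] = None,
        size_warning: int = DEFAULT_SIZE_WARNING,
        missing_value: str = "",
    ):
        self.registry = registry
        self.size_warning = size_warning
        self.missing_value = missing_value

    def fit(self, X: Sequence[SourceRecord], y=None) -> "TherapyNormalizer":
        """Build merged concepts and the term index from source records."""
        records = list(X)
        for record in records:
            if not isinstance(record, SourceRecord):
                raise TypeError(
                    f"fit expects SourceRecord instances, got {type(record).__name__}"
                )
        self.concepts_ = normalize_corpus(
            records, registry=self.registry, size_warning=self.size_warning
        )
        self.index_ = build_term_index(self.concepts_)
        self.n_records_ = len(records)
        return self

    def _check_fitted(self) -> TermIndex:
        if not hasattr(self, "index_"):
            raise NotFittedError(
                "This TherapyNormalizer instance is not fitted yet; "
                "call 'fit' with source records first."
            )
        return self.index_

    def query(self, term: str) -> QueryResult:
        """Full normalization outcome for one raw term."""
        return normalize_term(term, self._check_fitted())

    def query_batch(
        self, terms: Sequence[str]
    ) -> tuple[list[QueryResult], BatchSummary]:
        """Per-term results plus a summary over unique folded terms."""
        return batch_normalize(terms, self._check_fitted())

    def transform(self, X: Iterable[str]) -> np.ndarray:
        """Map raw terms to concept ids (``missing_value`` where unresolved)."""
        index = self._check_fitted()
        out = [
            str(r.concept.concept_id) if r.concept is not None else self.missing_value
            for r in (normalize_term(t, index) for t in X)
        ]
        return np.asarray(out, dtype=object)

    def predict(self, X: Iterable[str]) -> np.ndarray:
        """Alias of :meth:`transform` for classifier-style call sites."""
        return self.transform(X)

    def get_concept(self, concept_id: str) -> Optional[MergedConcept]:
        return self._check_fitted().concepts.get(concept_id)

    def __sklearn_tags__(self):
        tags = super().__sklearn_tags__()
        tags.input_tags.two_d_array = False
        tags.input_tags.string = True
        tags.no_validation = True
        tags.requires_fit = True
        return tags
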