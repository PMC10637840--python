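"""Term normalization: resolve raw surface terms to merged concepts.

Success means a merged concept is retrieved for the term; a term with no
postings fails outright. When two or more concepts tie at the best match
strength the result is ambiguous: candidates are reported and no concept is
returned, rather than silently picking a winner — arbitrary tie-breaking
would corrupt evaluation counts. There is no fuzzy or approximate matching:
a misspelling fails.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .graph import MergedConcept
from .index import MatchType, TermIndex, fold_term


@dataclass(frozen=True)
class QueryResult:
    """Outcome of normalizing one raw term."""

    query_raw: str
    query_folded: str
    match_type: MatchType
    concept: Optional[MergedConcept] = None
    candidates: tuple[tuple[str, MatchType], ...] = ()

    @property
    def is_success(self) -> bool:
        return self.concept is not None

    @property
    def is_ambiguous(self) -> bool:
        return bool(self.candidates)

    def to_dict(self) -> dict:
        out: dict = {
            "query_raw": self.query_raw,
            "query_folded": self.query_folded,
            "match_type": self.match_type.name,
        }
        if self.concept is not None:
            out["concept"] = self.concept.to_dict()
        if self.candidates:
            out["candidates"] = [
                {"concept_id": cid, "match_type": mt.name}
                for cid, mt in self.candidates
            ]
        return out


@dataclass
class BatchSummary:
    """Counts over the unique folded terms of one batch.

    Ambiguous hits are neither successes nor failures; all three counts are
    reported so either stricter convention can be recomputed. The success
    rate is null for an empty batch.
    """

    n_terms: int = 0
    n_success: int = 0
    n_ambiguous: int = 0
    n_failure: int = 0

    @property
    def success_rate(self) -> Optional[float]:
        return self.n_success / self.n_terms if self.n_terms else None

    def to_dict(self) -> dict:
        return {
            "n_terms": self.n_terms,
            "n_success": self.n_success,
            "n_ambiguous": self.n_ambiguous,
            "n_failure": self.n_failure,
            "success_rate": self.success_rate,
        }


def normalize_term(raw: str, index: TermIndex) -> QueryResult:
    """Normalize one raw term against the index.

    The folded term's postings are ranked by match strength. A unique best
    posting yields that concept; a tie yields an ambiguous result listing
    all tied candidates; no postings yields NO_MATCH.
    """
    folded = fold_term(raw)
    postings = index.lookup(folded)
    if not postings:
        return QueryResult(raw, folded, MatchType.NO_MATCH)
    best = max(postings.values())
    winners = sorted(cid for cid, mt in postings.items() if mt == best)
    if len(winners) == 1:
        return QueryResult(raw, folded, best, concept=index.concepts[winners[0]])
    return QueryResult(
        raw, folded, best, candidates=tuple((cid, best) for cid in winners)
    )


def batch_normalize(
    terms: Sequence[str], index: TermIndex
) -> tuple[list[QueryResult], BatchSummary]:
    """Normalize a batch of terms; summarize over unique folded terms.

    Results are returned per input term in input order; the summary counts
    each distinct folded term once, so repeated surface forms do not inflate
    the rate.
    """
    results = [normalize_term(t, index) for t in terms]
    summary = BatchSummary()
    seen: set[str] = set()
    for result in results:
        if result.query_folded in seen:
            continue
        seen.add(result.query_folded)
        summary.n_terms += 1
        if result.is_success:
            summary.n_success += 1
        elif result.is_ambiguous:
            summary.n_ambiguous += 1
        else:
            summary.n_failure += 1
    return results, summary
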