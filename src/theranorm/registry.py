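"""Source registry: the ranked vocabulary sources and namespace synonyms.

Nine source vocabularies participate in concept merging. Each carries a
priority rank (1 = most trusted) used to pick the anchor record of a merged
group: sources curated for clinical decision-making outrank generalized
thesauri. External namespaces (e.g. ``atc``) may appear as cross-reference
targets but never contribute records of their own.
"""
from __future__ import annotations

import json
from importlib import resources

from pydantic import BaseModel, Field

from .errors import ConfigError, UnknownNamespaceError


class SourceMeta(BaseModel):
    """Metadata for one source vocabulary."""

    model_config = {"frozen": True}

    name: str
    priority_rank: int = Field(ge=1)
    version_label: str = ""
    display: str = ""


class SourceRegistry:
    """Registry of ranked sources, namespace synonyms and external namespaces.

    Parameters
    ----------
    sources:
        Source metadata entries; priority ranks must be pairwise distinct.
    synonyms:
        Mapping from alternative namespace spellings (lowercased) to the
        canonical namespace token, e.g. ``rxnorm -> rxcui``.
    external_namespaces:
        Namespaces allowed as dangling cross-reference targets.
    """

    def __init__(
        self,
        sources: list[SourceMeta],
        synonyms: dict[str, str] | None = None,
        external_namespaces: set[str] | None = None,
    ):
        ranks = [s.priority_rank for s in sources]
        if len(set(ranks)) != len(ranks):
            raise ConfigError("source priority ranks must be pairwise distinct")
        names = [s.name for s in sources]
        if len(set(names)) != len(names):
            raise ConfigError("source names must be unique")
        self._sources: dict[str, SourceMeta] = {s.name: s for s in sources}
        self._synonyms: dict[str, str] = dict(synonyms or {})
        self._externals: set[str] = set(external_namespaces or ())

    @property
    def sources(self) -> dict[str, SourceMeta]:
        return dict(self._sources)

    def source_names(self) -> list[str]:
        """Source tokens in ascending rank order (most trusted first)."""
        return sorted(self._sources, key=lambda n: self._sources[n].priority_rank)

    def resolve_namespace(self, raw: str) -> str:
        """Map a raw namespace spelling to its canonical token.

        Raises :class:`UnknownNamespaceError` if the token is neither a
        registered source nor a registered external namespace.
        """
        token = raw.strip().lower()
        token = self._synonyms.get(token, token)
        if token in self._sources or token in self._externals:
            return token
        raise UnknownNamespaceError(
            f"namespace {raw!r} is not a registered source or external namespace"
        )

    def is_source(self, namespace: str) -> bool:
        return namespace in self._sources

    def is_external(self, namespace: str) -> bool:
        return namespace in self._externals

    def register_external(self, namespace: str) -> None:
        self._externals.add(namespace.strip().lower())

    def rank(self, namespace: str) -> int:
        """Priority rank of a source namespace (1 = most trusted)."""
        try:
            return self._sources[namespace].priority_rank
        except KeyError:
            raise UnknownNamespaceError(
                f"{namespace!r} is not a registered source"
            ) from None

    def meta(self, namespace: str) -> SourceMeta:
        try:
            return self._sources[namespace]
        except KeyError:
            raise UnknownNamespaceError(
                f"{namespace!r} is not a registered source"
            ) from None

    @classmethod
    def from_dict(cls, payload: dict) -> "SourceRegistry":
        return cls(
            sources=[SourceMeta(**s) for s in payload.get("sources", [])],
            synonyms=payload.get("synonyms", {}),
            external_namespaces=set(payload.get("external_namespaces", [])),
        )

    @classmethod
    def from_json(cls, path) -> "SourceRegistry":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


def default_registry() -> SourceRegistry:
    """The packaged nine-source registry with default ranks and synonyms."""
    payload = json.loads(
        resources.files("theranorm.data").joinpath("sources.json").read_text("utf-8")
    )
    return SourceRegistry.from_dict(payload)
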