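# Methods

## Model

`theranorm` treats therapeutic-vocabulary harmonization as entity
resolution over a curated cross-reference graph. Source records are nodes;
each explicit xref is a directed edge. Two modelling commitments follow:

* **Weak connectivity defines a concept.** Curated xrefs are frequently
  one-directional (a newer source points at an older one that never points
  back), yet an unreciprocated pointer is still evidence of identity.
  Grouping therefore ignores edge direction; direction is retained on the
  graph purely as provenance. The resulting partition is the transitive
  closure of the symmetrized relation, which tests verify against an
  independent union-find oracle.
* **The anchor names the concept.** Within a component, the member from the
  source with the smallest priority rank becomes the anchor and its CURIE
  becomes the concept id. The default ranking (RxNorm 1 → Wikidata 9)
  prefers sources curated for clinical decision-making over generalized
  thesauri. Rank ties cannot occur across sources (ranks are pairwise
  distinct by construction); within one source the lexicographically
  smallest code wins, purely for determinism.

Merging is a union: aliases, trade names, associations and approval
annotations of all members are pooled under the concept id. The concept
label is the anchor's label, falling back down the priority order when the
anchor's is empty (flagged in the output). Member labels that are not the
chosen concept label are folded into the alias union — without this, the
generic name would vanish whenever the anchor carries the salt-form label,
and a descriptor present in the inputs would become unsearchable.
Descriptor unions deduplicate under Unicode case-folding, keeping the
surface form contributed by the highest-priority member. Merged xrefs are
the members' pointers minus the member ids themselves; dangling external
pointers are retained. Components are never split: an over-merged group is
kept intact and a warning is logged above a size threshold (default 50
members), since splitting would require evidence the sources do not
provide.

Dangling xrefs to records that were never loaded do not create nodes — a
stub node would fabricate a record no source declared. They are reported in
a side list for audit.

## Normalization semantics

All lookups run on a folded key: whitespace trimmed and collapsed, Unicode
case-folded, NFC-normalized. Match strength is an explicit total order —
`CONCEPT_ID > LABEL > TRADE_NAME > ALIAS > XREF > NO_MATCH` — a declared
convention (sources do not define descriptor precedence) surfaced in every
result. Member ids index at `CONCEPT_ID` strength so a group is reachable
through any constituent identifier. A term whose best match strength is
shared by two or more concepts returns an *ambiguous* result listing the
tied candidates instead of an arbitrary winner; batch summaries report
success / ambiguous / failure separately so either stricter convention is
recomputable. Batch rates are computed over unique folded terms, so
repeated surface forms do not inflate them; an empty batch reports a null
rate. Failure means exactly: no merged concept retrieved. There is no
fuzzy matching, spelling correction or multi-language expansion, so
misspellings and uncaptured translations fail by design.

The pre-harmonization "exact string" comparison in the evaluation module
uses the same folding as the index. Anything stricter would make the
pre/post overlap comparison incoherent, since the post side necessarily
folds before lookup.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| source priority ranks | RxNorm 1 … Wikidata 9 | anchor selection order |
| `size_warning` | 50 members | over-merge warning threshold (groups are never split) |
| `MatchType` order | see above | tie-free descriptor precedence |
| index `SCHEMA_VERSION` | 1 | snapshot compatibility guard |

Persistence is a single-file JSON snapshot with an embedded schema version:
hermetic, diffable, and sufficient for local deployments; a networked store
can sit behind the same save/load interface.

## Synthetic corpus generator

The generator emulates multi-source vocabulary extraction at desk scale.
Defaults are chosen once as realistic study conditions: most concepts
appear in 2–5 sources (the `sources_per_concept` weights put ~85% of
groups in that band, matching how real merged groups concentrate), concepts
carry 0–3 aliases (pronounceable tokens or `XXX-###` development-style
codes) and 0–2 brand-like trade names, xrefs are wired star-to-anchor with
zero dropout, and ambiguity injection (`shared_term_rate`) is off. The
PRNG is an explicit seeded Mersenne Twister stream, so output is
byte-identical across platforms for a fixed seed.

What the generator does *not* emulate — and hence what passing tests do not
show about real data: real drug-name morphology and collisions, source
record volumes (real sources hold 10³–10⁶ records), incomplete or wrong
curated xrefs beyond independent random dropout, and multi-label records.
Generated tokens are built from a restricted consonant/vowel alphabet with
no consonant clusters, which guarantees by construction that they can never
collide with the packaged failure terms or the worked-example descriptors.
Synthetic codes are namespaced counters (`RND#####` for generated corpora,
`SYN####` for the packaged worked example) so fixtures are self-evidently
artificial and the two families cannot collide; the only real identifiers
packaged are the two printed ones, `rxcui:282388` and `drugbank:DB00619`.

## Numerical and degenerate-input choices

* Output determinism: concepts sort by concept id, members and descriptor
  arrays serialize sorted, so merged output is byte-identical under input
  permutation (tested over 10 shuffles).
* Component enumeration sorts by smallest member id.
* Empty inputs: empty record stream → empty corpus; empty concept list →
  empty index; empty batch → null success rate; empty intersection report →
  null overlap fraction; empty group list → null 2–5 share.
* Codes containing `:` are rejected outright; an escaping dialect would buy
  ambiguity for no modelled source that needs it.
* Record invariant violations (self-xref, whitespace-only descriptors) are
  reported as data by the validator; the strict parser raises on them,
  `strict=False` admits them for inspection.

## Scale of the shipped checks

The test suite and acceptance script run at fixture scale by choice:
random digraphs up to n=500 for the grouping oracle, ≥200 generated corpora
of ~12 concepts for the invariant sweep, 20 replicates per dropout level
for the recovery curve, and a 50-concept synthetic corpus plus the 9-record
worked example for the end-to-end failure-vocabulary count. Corpus-scale
statistics from full source dumps (total group counts, per-source anchor
shares, real normalization rates) require the real vocabularies and are out
of scope here.

## Known limitations

* Over-merged components are detected only by size, never repaired.
* One label per record; multi-label sources must pick one and demote the
  rest to aliases before interchange.
* Ambiguity resolution is deliberately absent; downstream consumers must
  handle candidate lists.
* The estimator's `transform` collapses failures and ambiguous ties to the
  same missing token; use `query_batch` when the distinction matters.
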