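# theranorm

Harmonize drug and therapeutic vocabularies into unified, searchable
**merged concepts**.

The same therapeutic routinely carries many names: a generic (USAN) name
(*imatinib*), salt formulations (*imatinib mesylate*), a development code
(*STI-571*), and a dozen brand names (*Gleevec*, *Glivec*, *Veenat*, …).
Each drug knowledgebase records some subset of these under its own
identifier, which makes cross-resource analyses — drug–gene interaction
aggregation, clinical decision support, pharmacovigilance — painful.
`theranorm` resolves this with an entity-resolution approach over curated
cross-references:

1. **Ingest.** Records from ranked source vocabularies (RxNorm, NCIt,
   HemOnc, DrugBank, Drugs@FDA, Guide to Pharmacology, ChEMBL, ChemIDplus,
   Wikidata) are read from a JSON Lines interchange format. Each record has
   a CURIE identifier (`rxcui:282388`), descriptors, and outgoing xrefs.
2. **Graph.** Records are nodes; each curated xref is a directed
   "has reference to" edge (e.g. `rxcui:282388 → drugbank:DB00619`).
3. **Group.** Each *weakly* connected component — direction ignored, since
   curated xrefs are often unreciprocated — becomes one concept. Formally,
   the concept partition is the transitive closure of the symmetrized xref
   relation.
4. **Anchor & merge.** Within a component, the member from the
   highest-trust source (rank 1 = RxNorm … rank 9 = Wikidata; ties broken
   by smallest code) is the **anchor**, and its CURIE names the merged
   concept. Labels, aliases, trade names, associations and approval
   annotations of all members merge under that identifier.
5. **Normalize.** Any raw surface term folds (trim, collapse whitespace,
   Unicode casefold, NFC) and resolves through a term index with an explicit
   match-strength order: `CONCEPT_ID > LABEL > TRADE_NAME > ALIAS > XREF`.
   A term with no posting fails; a tie across concepts is reported as
   ambiguous rather than silently broken. There is **no fuzzy matching** —
   a misspelling is a failure by design.

The package also reproduces, at fixture scale, the evaluation design used
to study harmonization: exact-string vocabulary intersections before
normalization versus concept-id intersections after, the fraction of items
shared by ≥2 vocabularies, anchor-source distributions, and merged-group
size histograms.

## Worked example

```python
from theranorm import TherapyNormalizer, anchor_distribution
from theranorm.fixtures import all_records, imatinib_records

est = TherapyNormalizer().fit(all_records(imatinib_records()))
print(len(est.concepts_), est.concepts_[0].concept_id)
print(est.transform(["Gleevec", "STI-571", "chemotherapy"]))
print(est.query("Glivec").match_type.name)
```

prints

```
1 rxcui:282388
['rxcui:282388' 'rxcui:282388' '']
TRADE_NAME
```

Nine records (one per source) collapse into a single merged concept named
by the RxNorm anchor `rxcui:282388`; brand names and the development code
resolve to it, while a category term like *chemotherapy* has no merged
concept and fails (empty string in `transform` output).

The same workflow from the shell:

```bash
theranorm fixtures --preset imatinib --out fx/
theranorm build fx/*.jsonl --db index.json
theranorm normalize Gleevec --db index.json
# Gleevec	TRADE_NAME	rxcui:282388	imatinib mesylate
theranorm batch --input terms.txt --db index.json --out results.tsv
theranorm overlap vocabA.txt vocabB.txt --db index.json
```

A synthetic-corpus generator (`theranorm.fixtures.generate_sources`) plants
concepts across sources with configurable topology, xref dropout and
ambiguity injection, and records ground truth so grouping recovery is
testable end to end.

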