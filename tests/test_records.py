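"""Record schema, CURIE canonicalization and interchange round-trips."""
import json

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from theranorm import (
    Curie,
    DuplicateRecordError,
    ParseError,
    RecordValidationError,
    SourceMismatchError,
    SourceRecord,
    UnknownNamespaceError,
    canonicalize_curie,
    default_registry,
    parse_source_records,
    serialize_records,
    validate_record,
)

REGISTRY = default_registry()


class TestCurie:
    def test_renders_with_single_colon(self):
        assert str(Curie("rxcui", "282388")) == "rxcui:282388"

    @pytest.mark.parametrize(
        "ns,code", [("", "x"), ("RX", "1"), ("rxcui", ""), ("rxcui", "a:b")]
    )
    def test_rejects_invalid_parts(self, ns, code):
        with pytest.raises(ValueError):
            Curie(ns, code)

    def test_parse_roundtrip(self):
        c = Curie.parse("drugbank:DB00619")
        assert c == Curie("drugbank", "DB00619")


class TestCanonicalize:
    @pytest.mark.parametrize(
        "ns,code,expected",
        [
            ("RxNorm", " 282388 ", "rxcui:282388"),
            ("drugbank", "DB00619", "drugbank:DB00619"),
            ("IUPHAR", "77", "guidetopharmacology:77"),
            ("Drugs@FDA", "A1", "drugsatfda:A1"),
        ],
    )
    def test_synonyms_and_trimming(self, ns, code, expected):
        assert str(canonicalize_curie(ns, code, REGISTRY)) == expected

    def test_unregistered_namespace_errors(self):
        with pytest.raises(UnknownNamespaceError):
            canonicalize_curie("pubchem", "123", REGISTRY)

    def test_registered_external_is_allowed(self):
        reg = default_registry()
        reg.register_external("pubchem")
        assert str(canonicalize_curie("pubchem", "123", reg)) == "pubchem:123"

    @given(
        ns=st.sampled_from([s for s in REGISTRY.source_names()]),
        code=st.text(
            st.characters(blacklist_characters=":", blacklist_categories=("Cs", "Zs", "Cc")),
            min_size=1,
            max_size=12,
        ),
    )
    @settings(max_examples=100, deadline=None)
    def test_idempotent(self, ns, code):
        once = canonicalize_curie(ns, code, REGISTRY)
        twice = canonicalize_curie(once.namespace, once.code, REGISTRY)
        assert once == twice


class TestValidate:
    def test_self_xref_violation(self):
        rec = SourceRecord(id=Curie("ncit", "C1"), xrefs=frozenset({Curie("ncit", "C1")}))
        rules = [v.rule for v in validate_record(rec)]
        assert rules == ["self-xref"]

    def test_whitespace_alias_violation(self):
        rec = SourceRecord(id=Curie("ncit", "C1"), aliases=frozenset({"  "}))
        violations = validate_record(rec)
        assert [v.field for v in violations] == ["aliases"]
        assert violations[0].rule == "empty-descriptor"

    def test_packaged_worked_example_is_valid(self, imatinib_corpus):
        assert all(validate_record(r) == [] for r in imatinib_corpus)


class TestParse:
    def test_printed_xref_example(self):
        line = json.dumps(
            {"id": "rxcui:282388", "label": "imatinib mesylate", "xrefs": ["drugbank:DB00619"]}
        )
        (rec,) = parse_source_records([line], REGISTRY.meta("rxcui"))
        assert rec.id == Curie("rxcui", "282388")
        assert rec.xrefs == frozenset({Curie("drugbank", "DB00619")})

    def test_empty_stream(self):
        assert parse_source_records([]) == []

    def test_duplicate_id_errors(self):
        line = json.dumps({"id": "ncit:C1"})
        with pytest.raises(DuplicateRecordError):
            parse_source_records([line, line])

    def test_malformed_line_reports_line_number(self):
        with pytest.raises(ParseError) as err:
            parse_source_records([json.dumps({"id": "ncit:C1"}), "{nope"])
        assert err.value.line_number == 2

    def test_source_mismatch(self):
        line = json.dumps({"id": "ncit:C1"})
        with pytest.raises(SourceMismatchError):
            parse_source_records([line], REGISTRY.meta("rxcui"))

    def test_strict_mode_raises_on_violations(self):
        line = json.dumps({"id": "ncit:C1", "xrefs": ["ncit:C1"]})
        with pytest.raises(RecordValidationError):
            parse_source_records([line])
        (rec,) = parse_source_records([line], strict=False)
        assert rec.id in rec.xrefs


_descriptor = st.text(
    st.characters(blacklist_categories=("Cs", "Cc")), min_size=1, max_size=20
).filter(lambda s: s.strip())
_code = st.text(
    st.characters(whitelist_categories=("Lu", "Ll", "Nd")), min_size=1, max_size=8
)


@st.composite
def record_lists(draw):
    names = REGISTRY.source_names()
    n = draw(st.integers(1, 6))
    codes = draw(st.lists(_code, min_size=n, max_size=n, unique=True))
    records = []
    for code in codes:
        ns = draw(st.sampled_from(names))
        records.append(
            SourceRecord(
                id=Curie(ns, code),
                label=draw(st.one_of(st.just(""), _descriptor)),
                aliases=frozenset(draw(st.lists(_descriptor, max_size=3))),
                trade_names=frozenset(draw(st.lists(_descriptor, max_size=2))),
                xrefs=frozenset(
                    Curie(draw(st.sampled_from(names)), c)
                    for c in draw(st.lists(_code, max_size=2))
                ) - {Curie(ns, code)},
            )
        )
    return records


class TestRoundTrip:
    @given(records=record_lists())
    @settings(max_examples=75, deadline=None)
    def test_parse_serialize_identity(self, records):
        lines = list(serialize_records(records))
        back = parse_source_records(lines)
        assert back == records

    def test_multilanguage_label_survives(self):
        rec = SourceRecord(id=Curie("wikidata", "SYNX1"), label="Cysplatynaé")
        (back,) = parse_source_records(serialize_records([rec]))
        assert back.label == rec.label
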