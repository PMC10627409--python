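"""Label grammar, map I/O, validation, lookup, summaries, crosswalk."""

import math

import pytest
from hypothesis import given, strategies as st

import phenomap as pm
from phenomap.map_model import (
    DIALECT_V12,
    Finding,
    IcdMapping,
    PhecodeEntry,
    PhecodeLabel,
    parse_v12_code,
    v12_ancestors,
)


# ---------------------------------------------------------------------------
# Label grammar
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "text, prefix, root, suffix, depth",
    [
        ("CV_416.22", "CV", "416", "22", 2),
        ("EM_202.1", "EM", "202", "1", 1),
        ("CV_416", "CV", "416", "", 0),
        ("GI_008", "GI", "008", "", 0),
        ("NS_100.123", "NS", "100", "123", 3),
    ],
)
def test_parse_label(text, prefix, root, suffix, depth):
    lab = pm.parse_label(text)
    assert (lab.category_prefix, lab.root, lab.suffix, lab.depth) == (prefix, root, suffix, depth)
    assert str(lab) == text


@pytest.mark.parametrize(
    "text, component",
    [
        ("427.2", "prefix"),       # bare v1.2-style code: no category prefix
        ("cv_416", "prefix"),      # lowercase prefix
        ("CVX_416", "prefix"),     # three-letter prefix
        ("CV_41", "root"),         # root not three digits
        ("CV_4166", "root"),
        ("CV_416.2222", "suffix"), # more than three decimals
        ("CV_416.", "suffix"),
        ("", "label"),
    ],
)
def test_parse_label_rejects_and_names_component(text, component):
    with pytest.raises(pm.MalformedLabelError) as exc:
        pm.parse_label(text)
    assert exc.value.component == component


label_strategy = st.builds(
    PhecodeLabel,
    category_prefix=st.text(alphabet="ABCDEFGHIJKLMNOPQRSTUVWXYZ", min_size=2, max_size=2),
    root=st.integers(0, 999).map(lambda n: f"{n:03d}"),
    suffix=st.text(alphabet="0123456789", min_size=0, max_size=3),
)


@given(label_strategy)
def test_grammar_round_trip(label):
    assert pm.parse_label(str(label)) == label


@given(label_strategy)
def test_ancestor_chain_matches_depth_and_truncation(label):
    chain = pm.ancestors(label)
    assert len(chain) == label.depth
    child = label
    for anc in chain:
        assert str(anc) == str(child)[:-1].rstrip(".")
        child = anc
    assert all(a.depth == label.depth - i - 1 for i, a in enumerate(chain))


def test_ancestors_worked_examples():
    assert [str(a) for a in pm.ancestors(pm.parse_label("CV_416.221"))] == [
        "CV_416.22", "CV_416.2", "CV_416"]
    assert pm.ancestors(pm.parse_label("CV_416")) == []
    assert [str(a) for a in pm.ancestors(pm.parse_label("GI_520.11"))] == [
        "GI_520.1", "GI_520"]


def test_v12_codes_tolerate_legacy_quirks():
    assert parse_v12_code("008") == "008"          # leading zeros preserved
    assert parse_v12_code("427.2") == "427.2"
    with pytest.raises(pm.MalformedLabelError):
        parse_v12_code("CV_416")
    with pytest.raises(pm.MalformedLabelError):
        parse_v12_code("427.123")                  # >2 decimals
    assert v12_ancestors("411.21") == ["411.2", "411"]


# ---------------------------------------------------------------------------
# Reading and writing maps
# ---------------------------------------------------------------------------

SIX_ROW_CSV = """\
icd_code,vocabulary,phecode,phecode_string,category,icd10_only
A010,ICD10CM,ID_100,Phenotype A,Infectious diseases,false
A011,ICD10CM,ID_100,Phenotype A,Infectious diseases,false
B020,ICD10CM,ID_101,Phenotype B,Infectious diseases,false
B020,ICD10CM,RE_300,Phenotype C,Respiratory,false
C030,ICD10CM,RE_301,Phenotype D,Respiratory,false
D040,ICD10CM,CV_200,Phenotype E,Cardiovascular,false
"""


def test_read_map_counts_mappings_and_entries(tmp_path):
    # 6 rows, one multi-mapped ICD (B020): 6 mappings over 5 distinct phecodes.
    path = tmp_path / "map.csv"
    path.write_text(SIX_ROW_CSV)
    pmap = pm.read_map(path)
    assert len(pmap.mappings) == 6
    assert len(pmap.entries) == 5


def test_read_map_is_deterministic(tmp_path):
    path = tmp_path / "map.csv"
    path.write_text(SIX_ROW_CSV)
    assert pm.read_map(path) == pm.read_map(path)


def test_read_map_rejects_unknown_vocabulary_with_row_number(tmp_path):
    bad = SIX_ROW_CSV.replace("C030,ICD10CM", "C030,ICD11")
    path = tmp_path / "map.csv"
    path.write_text(bad)
    with pytest.raises(pm.MapReadError, match="row 6.*ICD11"):
        pm.read_map(path)


def test_read_map_rejects_empty_file(tmp_path):
    path = tmp_path / "empty.csv"
    path.write_text("")
    with pytest.raises(pm.MapReadError, match="empty"):
        pm.read_map(path)
    path.write_text("icd_code,vocabulary,phecode\n")
    with pytest.raises(pm.MapReadError, match="no rows"):
        pm.read_map(path)


def test_read_map_accepts_tabs_and_column_overrides(tmp_path):
    tsv = SIX_ROW_CSV.replace(",", "\t").replace("icd_code", "ICD")
    path = tmp_path / "map.tsv"
    path.write_text(tsv)
    pmap = pm.read_map(path, column_config={"icd_code": "ICD"})
    assert len(pmap.mappings) == 6


def test_read_map_normalizes_icd_codes(paper_map):
    assert any(m.icd_code == "K401" for m in paper_map.mappings)
    assert not any("." in m.icd_code for m in paper_map.mappings)


def test_map_io_round_trip(tmp_path, paper_map):
    out = tmp_path / "rt.csv"
    pm.write_map(paper_map, out)
    assert pm.read_map(out) == paper_map


def test_v12_map_io_round_trip(tmp_path, v12_map):
    out = tmp_path / "rt12.csv"
    pm.write_map(v12_map, out)
    assert pm.read_map(out, dialect=DIALECT_V12) == v12_map


def test_v12_reader_populates_exclude_ranges(v12_map):
    assert v12_map.exclude_ranges["411"] == ("410-414.99",)
    assert "427.2" not in v12_map.exclude_ranges


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def _tiny_map(entries, mappings, **kw):
    return pm.PhecodeMap(entries={e.label: e for e in entries},
                         mappings=tuple(mappings), **kw)


def test_validator_flags_orphan_child():
    lab = pm.parse_label("CV_416.22")  # parent CV_416.2 missing
    pmap = _tiny_map(
        [PhecodeEntry(lab, "Atrial flutter", "Cardiovascular"),
         PhecodeEntry(pm.parse_label("CV_416"), "Arrhythmia", "Cardiovascular")],
        [IcdMapping("I483", "ICD10CM", lab)])
    report = pm.validate_map(pmap)
    assert [f.rule for f in report.findings] == ["orphan_child"]


def test_validator_flags_prefix_category_mismatch():
    lab = pm.parse_label("CV_416")
    pmap = _tiny_map([PhecodeEntry(lab, "x", "Gastrointestinal")],
                     [IcdMapping("I48", "ICD10CM", lab)])
    report = pm.validate_map(pmap)
    assert [f.rule for f in report.findings] == ["prefix_mismatch"]


def test_validator_flags_duplicates_and_icd10_only_violations():
    lab = pm.parse_label("CV_416")
    pmap = _tiny_map(
        [PhecodeEntry(lab, "no star", "Cardiovascular", icd10_only=True)],
        [IcdMapping("I48", "ICD10CM", lab), IcdMapping("I48", "ICD10CM", lab),
         IcdMapping("4270", "ICD9CM", lab)])
    rules = {f.rule for f in pm.validate_map(pmap).findings}
    assert rules == {"duplicate_mapping", "icd10_only_description", "icd10_only_icd9_mapping"}


def test_validator_flags_exclude_ranges_in_phecodex():
    lab = pm.parse_label("CV_416")
    pmap = _tiny_map([PhecodeEntry(lab, "x", "Cardiovascular")],
                     [IcdMapping("I48", "ICD10CM", lab)],
                     exclude_ranges={lab: ("410-414.99",)})
    assert pm.validate_map(pmap).by_rule("exclude_ranges_in_phecodex")


def test_clean_fixture_and_synthetic_maps_validate_empty(paper_map):
    assert pm.validate_map(paper_map).ok
    pmap, _ = pm.simulate_map(pm.MapSimConfig(seed=11))
    assert pm.validate_map(pmap).ok


def test_report_json_structure():
    report = pm.ValidationReport([Finding("orphan_child", "error", "msg", "CV_1")])
    assert '"rule": "orphan_child"' in report.to_json()
    assert not report.ok


# ---------------------------------------------------------------------------
# Lookup
# ---------------------------------------------------------------------------

def test_lookup_multi_mapped_worked_examples(paper_map):
    assert {str(p) for p in pm.lookup(paper_map, "K40.1", "ICD10CM")} == {"GI_520.11", "ID_091"}
    assert {str(p) for p in pm.lookup(paper_map, "550.0", "ICD9CM")} == {"GI_520.11", "ID_091"}
    # Pre-coordinated staphylococcal pneumonia: the code carries both the
    # organism and the pneumonia phenotype (asserted as an unordered set).
    assert {str(p) for p in pm.lookup(paper_map, "J15.2", "ICD10CM")} == {"ID_009", "RE_468.2"}


def test_lookup_normalizes_query(paper_map):
    assert pm.lookup(paper_map, "k401", "ICD10CM") == pm.lookup(paper_map, "K40.1", "ICD10CM")


def test_lookup_unmapped_returns_empty_set(paper_map):
    assert pm.lookup(paper_map, "Z99.99", "ICD10CM") == set()


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

def test_summary_multi_map_fraction_constructed(tmp_path):
    # 10 ICD-10 codes, 3 of them multi-mapped -> fraction 0.3.
    rows = ["icd_code,vocabulary,phecode,phecode_string,category,icd10_only"]
    for i in range(10):
        rows.append(f"A{i:03d},ICD10CM,ID_{100 + i},P{i},Infectious diseases,false")
    for i in range(3):
        rows.append(f"A{i:03d},ICD10CM,RE_{300 + i},Q{i},Respiratory,false")
    path = tmp_path / "m.csv"
    path.write_text("\n".join(rows) + "\n")
    summary = pm.summarize_map(pm.read_map(path))
    assert summary.vocabularies["ICD10CM"].n_icd_codes == 10
    assert summary.vocabularies["ICD10CM"].multi_map_fraction == pytest.approx(0.3)


def test_summary_matches_brute_force_recount_and_partitions():
    pmap, _ = pm.simulate_map(pm.MapSimConfig(n_categories=4, roots_per_category=8,
                                              multi_map_rate=0.15, seed=5))
    summary = pm.summarize_map(pmap)
    # Brute-force recount: group mappings by (icd, vocab), count groups >1.
    groups: dict = {}
    for m in pmap.mappings:
        groups.setdefault((m.vocabulary, m.icd_code), set()).add(m.phecode)
    for vocab in summary.vocabularies:
        expected = sum(1 for (v, _), t in groups.items() if v == vocab and len(t) > 1)
        total = sum(1 for (v, _) in groups if v == vocab)
        assert summary.vocabularies[vocab].n_multi_mapped == expected
        assert summary.vocabularies[vocab].n_icd_codes == total
    # Category counts partition the entries.
    assert sum(summary.category_counts.values()) == summary.n_entries == len(pmap.entries)
    assert summary.n_icd10_only == sum(e.icd10_only for e in pmap.entries.values())


def test_summary_leaf_exclusion_list(paper_map):
    base = pm.summarize_map(paper_map)
    fewer = pm.summarize_map(paper_map, exclude_from_leaf_stats=["ID_091"])
    assert fewer.n_leaves == base.n_leaves - 1


def test_percent_and_ratio_helpers():
    assert pm.percent(1, 3) == 33.3
    assert pm.expansion_ratio(3, 2) == 1.5
    with pytest.raises(ZeroDivisionError):
        pm.percent(1, 0)


# ---------------------------------------------------------------------------
# Crosswalk
# ---------------------------------------------------------------------------

XWALK_CSV = """\
phecode_v12,phecode_x
427.2,CV_416.2
550.1,GI_520.11
008,ID_100
008,ID_101
"""


@pytest.fixture
def crosswalk(tmp_path):
    path = tmp_path / "xw.csv"
    path.write_text(XWALK_CSV)
    return pm.read_crosswalk(path)


def test_translate_both_directions(crosswalk):
    assert [str(t) for t in pm.translate(crosswalk, "427.2", "v12_to_X")] == ["CV_416.2"]
    assert pm.translate(crosswalk, "CV_416.2", "X_to_v12") == ("427.2",)


def test_translate_no_counterpart_is_explicit(crosswalk):
    assert pm.translate(crosswalk, "803", "v12_to_X") == ()  # injury code absent by design
    assert pm.translate(crosswalk, "CV_999", "X_to_v12") == ()


def test_translate_one_to_many_sorted_and_round_trip(crosswalk):
    assert [str(t) for t in pm.translate(crosswalk, "008", "v12_to_X")] == ["ID_100", "ID_101"]
    # 1:1 pair round-trips.
    (x,) = pm.translate(crosswalk, "550.1", "v12_to_X")
    assert pm.translate(crosswalk, x, "X_to_v12") == ("550.1",)
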