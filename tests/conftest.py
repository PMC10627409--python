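"""Shared fixtures: a hand-written worked-example map and oracle helpers."""

import pandas as pd
import pytest
from hypothesis import settings

import phenomap as pm

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


# A hand-built phecodeX-dialect map around the canonical multi-mapping worked
# examples: Inguinal hernia with gangrene (K40.1 / 550.0 -> GI_520.11 and
# ID_091) and staphylococcal pneumonia (J15.2 / 482.4 -> {ID_009, RE_468.2}),
# plus the atrial fibrillation/flutter hierarchy CV_416 ... CV_416.221 and the
# multi-mapped type-1 diabetes code EM_202.1.
PAPER_MAP_CSV = """\
icd_code,vocabulary,phecode,phecode_string,category,icd10_only
K409,ICD10CM,GI_520,Hernia,Gastrointestinal,false
K408,ICD10CM,GI_520.1,Abdominal hernia,Gastrointestinal,false
K40.1,ICD10CM,GI_520.11,Inguinal hernia,Gastrointestinal,false
550.0,ICD9CM,GI_520.11,Inguinal hernia,Gastrointestinal,false
K40.1,ICD10CM,ID_091,Gangrene,Infectious diseases,false
550.0,ICD9CM,ID_091,Gangrene,Infectious diseases,false
R02,ICD10CM,ID_091,Gangrene,Infectious diseases,false
J15.2,ICD10CM,ID_009,Staphylococcus infections,Infectious diseases,false
482.4,ICD9CM,ID_009,Staphylococcus infections,Infectious diseases,false
J18,ICD10CM,RE_468,Pneumonia,Respiratory,false
J15.2,ICD10CM,RE_468.2,Bacterial pneumonia,Respiratory,false
482.4,ICD9CM,RE_468.2,Bacterial pneumonia,Respiratory,false
I48,ICD10CM,CV_416,Cardiac arrhythmias,Cardiovascular,false
I48.9,ICD10CM,CV_416.2,Atrial fibrillation and flutter,Cardiovascular,false
I48.0,ICD10CM,CV_416.21,Atrial fibrillation,Cardiovascular,false
I48.3,ICD10CM,CV_416.22,Atrial flutter,Cardiovascular,false
I48.31,ICD10CM,CV_416.221,Typical atrial flutter,Cardiovascular,true
I48.32,ICD10CM,CV_416.222,Atypical atrial flutter,Cardiovascular,true
E08,ICD10CM,EM_202,Diabetes mellitus,Endocrine/Metabolic,false
E10,ICD10CM,EM_202.1,Type 1 diabetes,Endocrine/Metabolic,false
O24.01,ICD10CM,EM_202.1,Type 1 diabetes,Endocrine/Metabolic,false
250.01,ICD9CM,EM_202.1,Type 1 diabetes,Endocrine/Metabolic,false
"""

# Fix the icd10_only rows: descriptions must end with '*'.
PAPER_MAP_CSV = PAPER_MAP_CSV.replace(
    "Typical atrial flutter,Cardiovascular,true", "Typical atrial flutter*,Cardiovascular,true"
).replace(
    "Atypical atrial flutter,Cardiovascular,true", "Atypical atrial flutter*,Cardiovascular,true"
)


@pytest.fixture
def paper_map_file(tmp_path):
    path = tmp_path / "paper_map.csv"
    path.write_text(PAPER_MAP_CSV)
    return path


@pytest.fixture
def paper_map(paper_map_file):
    return pm.read_map(paper_map_file)


# A v1.2-dialect map with an exclude range on ischemic heart disease (411):
# controls coded for anything in 410-414.99 are removed from 411's control arm.
V12_MAP_CSV = """\
icd_code,vocabulary,phecode,phecode_string,category,icd10_only,exclude_range
4100,ICD9CM,410,Myocardial infarction,Cardiovascular,false,410-414.99
4110,ICD9CM,411,Ischemic heart disease,Cardiovascular,false,410-414.99
4140,ICD9CM,414,Other chronic ischemic heart disease,Cardiovascular,false,410-414.99
4270,ICD9CM,427.2,Atrial fibrillation and flutter,Cardiovascular,false,
0081,ICD9CM,008,Intestinal infection,Infectious diseases,false,
"""


@pytest.fixture
def v12_map(tmp_path):
    path = tmp_path / "v12_map.csv"
    path.write_text(V12_MAP_CSV)
    return pm.read_map(path, dialect="v1.2")


def string_ancestors(phecode: str) -> list[str]:
    """Truncation ancestors computed by pure string manipulation (oracle helper).

    Works for both label dialects: drop one trailing decimal digit at a time;
    drop the dangling dot when the decimals run out.
    """
    out = []
    cur = phecode
    while "." in cur:
        cur = cur[:-1]
        if cur.endswith("."):
            cur = cur[:-1]
        out.append(cur)
    return out


def brute_force_counts(events: pd.DataFrame, pmap, rollup: bool = True) -> dict:
    """Independent recount: expand every event to its mapped phecodes (and all
    string-truncation ancestors under rollup), dedup by (person, phecode, date),
    and count.  Returns {(person_id, phecode): count}."""
    direct = {}
    for m in pmap.mappings:
        direct.setdefault((m.icd_code, m.vocabulary), set()).add(str(m.phecode))
    triples = set()
    for _, row in events.iterrows():
        icd = pm.normalize_icd(str(row["icd_code"]))
        for p in direct.get((icd, row["vocabulary"]), ()):
            codes = [p] + string_ancestors(p) if rollup else [p]
            for c in codes:
                triples.add((str(row["person_id"]), c, str(row["date"])))
    counts: dict = {}
    for person, phecode, _ in triples:
        counts[(person, phecode)] = counts.get((person, phecode), 0) + 1
    return counts


def counts_to_dict(counts: "pm.PhenomeCounts") -> dict:
    return {(r.person_id, r.phecode): int(r.count)
            for r in counts.counts.itertuples(index=False)}
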