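"""Phenome construction: ICD event streams -> person x phecode matrices.

A person's phenome is built in two steps.  First, each dated ICD event is
translated through the phecode map: the event contributes to every phecode its
ICD code maps to directly and, with hierarchical rollup enabled, to every
ancestor obtained by truncating the decimal suffix.  Contributions are
deduplicated to one per (person, phecode, date), so same-day duplicate billing
never manufactures evidence; the count for a (person, phecode) cell is the
number of distinct dates on which it was coded.  Second, counts are thresholded
into case / control / neither status: ``count >= min_code_count`` makes a case,
``count == 0`` a control, and anything in between is "neither" (excluded from
both arms).  Legacy v1.2 maps additionally support exclude ranges, which demote
controls carrying related conditions to "neither".
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .map_model import (
    DIALECT_PHECODEX,
    DIALECT_V12,
    Crosswalk,
    PhecodeMap,
    V12_TO_X,
    X_TO_V12,
    normalize_icd,
    normalize_vocabulary,
    translate,
)

__all__ = [
    "EVENT_COLUMNS",
    "CONTROL",
    "NEITHER",
    "CASE",
    "STATUS_LABELS",
    "PhenomeCounts",
    "CaseControlMatrix",
    "read_events",
    "read_roster",
    "map_events",
    "assign_case_control",
    "apply_exclude_ranges",
    "crosswalk_phenome",
]

EVENT_COLUMNS = ("person_id", "icd_code", "vocabulary", "date")

# Status encoding in the case/control matrix.
CONTROL, NEITHER, CASE = 0, 1, 2
STATUS_LABELS = {CONTROL: "control", NEITHER: "neither", CASE: "case"}


def read_events(path) -> pd.DataFrame:
    """Read a person-level ICD event table (person_id, icd_code, vocabulary, date).

    Dates must be ISO 8601; vocabularies must be among the supported set.
    """
    sep = "\t" if "\t" in open(path).readline() else ","
    df = pd.read_csv(path, dtype=str, sep=sep, keep_default_na=False)
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: event table missing columns {missing}")
    return validate_events(df)


def validate_events(events: pd.DataFrame) -> pd.DataFrame:
    """Validate and canonicalize an in-memory event table."""
    df = events.copy()
    df["vocabulary"] = [normalize_vocabulary(v) for v in df["vocabulary"].astype(str)]
    # ISO 8601 check; raises on malformed dates.
    parsed = pd.to_datetime(df["date"], format="ISO8601")
    df["date"] = parsed.dt.strftime("%Y-%m-%d")
    df["person_id"] = df["person_id"].astype(str)
    df["icd_code"] = df["icd_code"].astype(str)
    return df


def read_roster(path) -> list[str]:
    """Read a cohort roster: one person id per line (blank lines ignored)."""
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


@dataclass
class PhenomeCounts:
    """Sparse person x phecode distinct-date counts plus bookkeeping reports.

    ``counts`` is long-format (person_id, phecode, count) with phecodes as
    strings; ``persons`` is the full cohort universe (event persons plus any
    roster), so zero-count controls are representable; ``phecode_universe`` is
    the full set of phecodes in the map used.  ``unmapped`` tallies events
    whose ICD had no mapping — they are reported, never silently dropped.
    """

    counts: pd.DataFrame
    persons: tuple
    phecode_universe: tuple
    unmapped: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["icd_code", "vocabulary", "n_events"]))
    dropped_codes: tuple = ()  # populated by crosswalk_phenome

    def to_wide(self) -> pd.DataFrame:
        """Dense person x phecode integer matrix over the full universes."""
        wide = self.counts.pivot_table(index="person_id", columns="phecode",
                                       values="count", aggfunc="sum", fill_value=0)
        wide = wide.reindex(index=list(self.persons), columns=list(self.phecode_universe),
                            fill_value=0)
        return wide.astype(np.int64)

    def unmapped_report(self) -> str:
        recs = self.unmapped.to_dict(orient="records")
        return json.dumps({"n_unmapped_events": int(self.unmapped["n_events"].sum())
                           if len(self.unmapped) else 0,
                           "codes": recs}, indent=2)


def _ancestor_expansion(pmap: PhecodeMap) -> pd.DataFrame:
    """Long table (phecode -> rolled phecode) mapping each phecode to itself
    and every truncation ancestor."""
    rows = []
    seen = set()
    for m in pmap.mappings:
        p = m.phecode
        if p in seen:
            continue
        seen.add(p)
        chain = [p] + pmap.ancestors_of(p)
        rows.extend((str(p), str(a)) for a in chain)
    return pd.DataFrame(rows, columns=["phecode", "rolled"])


def map_events(events: pd.DataFrame, pmap: PhecodeMap, rollup: bool = True,
               roster: Iterable[str] | None = None) -> PhenomeCounts:
    """Translate dated ICD events into distinct-date phecode counts.

    Each event contributes to every directly mapped phecode (multi-mapping
    fans one event out to several phenotypes) and, when ``rollup`` is true, to
    every truncation ancestor.  Contributions are deduplicated to one per
    (person, phecode, date) before counting.  Events with unmapped ICD codes
    are tallied in the unmapped report.
    """
    ev = validate_events(events)
    ev = ev.assign(icd_code=[normalize_icd(c) for c in ev["icd_code"]])

    mapping = pmap.mapping_frame().drop_duplicates()
    hit = ev.merge(mapping, on=["icd_code", "vocabulary"], how="left", sort=False)
    unmapped_rows = hit[hit["phecode"].isna()]
    unmapped = (unmapped_rows.groupby(["icd_code", "vocabulary"], sort=True)
                .size().rename("n_events").reset_index()
                if len(unmapped_rows) else
                pd.DataFrame(columns=["icd_code", "vocabulary", "n_events"]))
    hit = hit.dropna(subset=["phecode"])

    if rollup:
        expansion = _ancestor_expansion(pmap)
        hit = hit.merge(expansion, on="phecode", how="left", sort=False)
        hit = hit.drop(columns=["phecode"]).rename(columns={"rolled": "phecode"})

    dedup = hit.drop_duplicates(subset=["person_id", "phecode", "date"])
    counts = (dedup.groupby(["person_id", "phecode"], sort=True)
              .size().rename("count").reset_index())

    persons = set(ev["person_id"])
    if roster is not None:
        persons |= {str(p) for p in roster}
    universe = tuple(sorted(str(p) for p in pmap.entries))
    return PhenomeCounts(counts=counts, persons=tuple(sorted(persons)),
                         phecode_universe=universe, unmapped=unmapped)


@dataclass
class CaseControlMatrix:
    """Person x phecode status in {case, control, neither} with provenance.

    ``status`` is a dense int8 frame using the CONTROL/NEITHER/CASE encoding.
    """

    status: pd.DataFrame
    min_code_count: int
    exclude_policy: str = "none"

    def to_long(self) -> pd.DataFrame:
        long = self.status.stack().rename("status").reset_index()
        long.columns = ["person_id", "phecode", "status"]
        long["status"] = long["status"].map(STATUS_LABELS)
        return long

    def n_cases(self) -> pd.Series:
        return (self.status == CASE).sum(axis=0)

    def n_controls(self) -> pd.Series:
        return (self.status == CONTROL).sum(axis=0)


def assign_case_control(counts: PhenomeCounts, min_code_count: int = 2) -> CaseControlMatrix:
    """Threshold distinct-date counts into case/control/neither status.

    A person is a case for a phecode when their count reaches
    ``min_code_count`` (default 2), a control at zero, and "neither" in
    between — sub-threshold persons are excluded from both arms.  Persons in
    the universe but absent from the event table have zero counts everywhere
    and are controls for all phecodes.
    """
    if min_code_count < 1:
        raise ValueError("min_code_count must be >= 1")
    wide = counts.to_wide()
    status = np.where(wide.values >= min_code_count, CASE,
                      np.where(wide.values == 0, CONTROL, NEITHER)).astype(np.int8)
    return CaseControlMatrix(
        status=pd.DataFrame(status, index=wide.index, columns=wide.columns),
        min_code_count=min_code_count,
    )


def _range_members(phecodes: Sequence[str], range_spec: str) -> list[str]:
    """v1.2 phecodes falling in a numeric interval like '410-414.99' (inclusive)."""
    lo_s, _, hi_s = range_spec.partition("-")
    lo = float(lo_s)
    hi = float(hi_s) if hi_s else lo
    out = []
    for p in phecodes:
        try:
            v = float(p)
        except ValueError:
            continue
        if lo <= v <= hi:
            out.append(p)
    return out


def apply_exclude_ranges(matrix: CaseControlMatrix, counts: PhenomeCounts,
                         pmap: PhecodeMap, min_count: int = 1) -> CaseControlMatrix:
    """Demote controls carrying conditions in a phecode's exclude range.

    For each v1.2 phecode with an exclude range, any control with a count of
    at least ``min_count`` (default: any nonzero count) on any phecode inside
    the range becomes "neither".  Cases are never touched.  With a phecodeX
    map this is the identity transform — that dialect defines no exclude
    ranges, and passing one with ranges is an error.
    """
    if pmap.dialect == DIALECT_PHECODEX:
        if pmap.exclude_ranges:
            raise ValueError("phecodeX maps must not carry exclude ranges")
        return replace(matrix, exclude_policy="phecodeX:none")
    if min_count < 1:
        raise ValueError("min_count must be >= 1")

    wide = counts.to_wide().reindex(index=matrix.status.index,
                                    columns=matrix.status.columns, fill_value=0)
    status = matrix.status.copy()
    all_phecodes = list(status.columns)
    for phecode, ranges in sorted(pmap.exclude_ranges.items(), key=lambda kv: str(kv[0])):
        col = str(phecode)
        if col not in status.columns:
            continue
        members: list[str] = []
        for spec in ranges:
            members.extend(_range_members(all_phecodes, spec))
        if not members:
            continue
        flagged = (wide[sorted(set(members))] >= min_count).any(axis=1)
        demote = flagged & (status[col] == CONTROL)
        status.loc[demote, col] = NEITHER
    return CaseControlMatrix(status=status, min_code_count=matrix.min_code_count,
                             exclude_policy=f"v1.2:min_count={min_count}")


def crosswalk_phenome(counts: PhenomeCounts, crosswalk: Crosswalk,
                      direction: str = V12_TO_X) -> PhenomeCounts:
    """Re-key a phenome count table across phecode releases.

    Counts move to each counterpart of their phecode.  Where several source
    phecodes land on one target, the target takes the *maximum* of the source
    counts, not the sum — the sources typically describe the same underlying
    events, and summing would double-count them.  Phecodes without a
    counterpart go to the ``dropped_codes`` report.
    """
    dropped = []
    rows = []
    for phecode in counts.phecode_universe:
        targets = translate(crosswalk, phecode, direction)
        if not targets:
            dropped.append(phecode)
        else:
            rows.extend((phecode, str(t)) for t in targets)
    xmap = pd.DataFrame(rows, columns=["phecode", "target"])

    merged = counts.counts.merge(xmap, on="phecode", how="inner", sort=False)
    if len(merged):
        out = (merged.groupby(["person_id", "target"], sort=True)["count"]
               .max().rename("count").reset_index()
               .rename(columns={"target": "phecode"}))
    else:
        out = pd.DataFrame(columns=["person_id", "phecode", "count"])
    universe = tuple(sorted(set(xmap["target"])))
    return PhenomeCounts(counts=out, persons=counts.persons, phecode_universe=universe,
                         unmapped=counts.unmapped, dropped_codes=tuple(dropped))
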