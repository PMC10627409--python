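"""Phecode map model.

Phecodes are manually curated groups of ICD diagnosis codes, each representing
one clinically meaningful phenotype and organized in a shallow hierarchy.  This
module houses the label grammar, readers for the two mapping-file dialects
(the current prefixed dialect, here called *phecodeX*, and the legacy numeric
*v1.2* dialect), structural validation, hierarchy derivation, the
v1.2-to-phecodeX crosswalk, and map summary statistics.

Labels in the phecodeX dialect look like ``CV_416.22``: a two-letter category
prefix, an underscore, a three-digit root, and up to three decimal digits of
child specificity.  Legacy v1.2 codes are bare numeric strings (``427.2``)
with at most two decimals; they are stored opaquely, preserving leading
zeros.  One ICD code may map to several phecodes (multi-mapping), which is how
pre-coordinated codes — a single ICD encoding both a diagnosis and, say, an
infectious agent — are represented faithfully.
"""

from __future__ import annotations

import csv
import io
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "VOCABULARIES",
    "MalformedLabelError",
    "MapReadError",
    "PhecodeLabel",
    "PhecodeEntry",
    "IcdMapping",
    "PhecodeMap",
    "CategoryRegistry",
    "DEFAULT_REGISTRY",
    "Crosswalk",
    "MapSummary",
    "VocabularySummary",
    "Finding",
    "ValidationReport",
    "parse_label",
    "ancestors",
    "normalize_icd",
    "normalize_vocabulary",
    "parse_v12_code",
    "v12_ancestors",
    "read_map",
    "write_map",
    "validate_map",
    "lookup",
    "summarize_map",
    "read_crosswalk",
    "translate",
    "percent",
    "expansion_ratio",
]

# Supported source vocabularies: the two US clinical modifications plus the
# WHO base ICD-10 system.
VOCABULARIES = ("ICD9CM", "ICD10CM", "ICD10WHO")

DIALECT_PHECODEX = "phecodeX"
DIALECT_V12 = "v1.2"
DIALECTS = (DIALECT_PHECODEX, DIALECT_V12)


class MalformedLabelError(ValueError):
    """A phecode label violates the grammar; ``component`` names the offender."""

    def __init__(self, text: str, component: str, detail: str):
        self.text = text
        self.component = component
        super().__init__(f"malformed phecode label {text!r}: {detail} (component: {component})")


class MapReadError(ValueError):
    """A mapping file could not be ingested; message carries row-numbered diagnostics."""


# --------------------------------------------------------------------------
# Label grammar
# --------------------------------------------------------------------------

_LABEL_RE = re.compile(r"^([A-Z]{2})_(\d{3})(?:\.(\d{1,3}))?$")
_V12_RE = re.compile(r"^\d+(?:\.\d{1,2})?$")


@dataclass(frozen=True, order=True)
class PhecodeLabel:
    """A parsed phecodeX label: category prefix, 3-digit root, decimal suffix.

    ``depth`` equals the number of suffix digits (0 for a root code).  Labels
    are immutable, hashable and totally ordered, so they can key dictionaries
    and sort deterministically.
    """

    category_prefix: str
    root: str
    suffix: str = ""

    @property
    def depth(self) -> int:
        return len(self.suffix)

    def __str__(self) -> str:
        if self.suffix:
            return f"{self.category_prefix}_{self.root}.{self.suffix}"
        return f"{self.category_prefix}_{self.root}"

    def parent(self) -> "PhecodeLabel | None":
        """Immediate parent obtained by dropping one suffix digit; None at the root."""
        if not self.suffix:
            return None
        return PhecodeLabel(self.category_prefix, self.root, self.suffix[:-1])


def parse_label(text: str) -> PhecodeLabel:
    """Parse a phecodeX label string, naming the offending component on failure.

    >>> parse_label("CV_416.22")
    PhecodeLabel(category_prefix='CV', root='416', suffix='22')
    """
    if not text:
        raise MalformedLabelError(text, "label", "empty label")
    m = _LABEL_RE.match(text)
    if m:
        return PhecodeLabel(m.group(1), m.group(2), m.group(3) or "")
    # Diagnose which component broke the grammar.
    if "_" not in text:
        raise MalformedLabelError(text, "prefix", "missing two-letter category prefix and underscore")
    prefix, _, rest = text.partition("_")
    if not re.fullmatch(r"[A-Z]{2}", prefix):
        raise MalformedLabelError(text, "prefix", f"prefix {prefix!r} is not two uppercase letters")
    root, dot, suffix = rest.partition(".")
    if not re.fullmatch(r"\d{3}", root):
        raise MalformedLabelError(text, "root", f"root {root!r} is not exactly three digits")
    if dot and not re.fullmatch(r"\d{1,3}", suffix):
        raise MalformedLabelError(text, "suffix", f"suffix {suffix!r} is not 1-3 digits")
    raise MalformedLabelError(text, "label", "does not match the label grammar")


def ancestors(label: PhecodeLabel) -> list[PhecodeLabel]:
    """Chain from immediate parent up to the root; length equals ``label.depth``."""
    out = []
    cur = label.parent()
    while cur is not None:
        out.append(cur)
        cur = cur.parent()
    return out


def parse_v12_code(text: str) -> str:
    """Validate a legacy v1.2 phecode: digits with at most two decimals.

    Codes are kept as opaque strings (leading zeros are meaningful: phecode
    ``008`` must not collapse to ``8``).
    """
    if not text or not _V12_RE.match(text):
        raise MalformedLabelError(text, "label", "not a numeric v1.2 code (digits, <=2 decimals)")
    return text


def v12_ancestors(code: str) -> list[str]:
    """Truncation ancestors of a v1.2 numeric code: ``411.21`` -> [``411.2``, ``411``]."""
    out = []
    root, dot, dec = code.partition(".")
    while dec:
        dec = dec[:-1]
        out.append(f"{root}.{dec}" if dec else root)
    return out


def normalize_icd(code: str) -> str:
    """Canonical ICD form: uppercase, dots and whitespace stripped.

    EHR extracts store ICD-10-CM both dotted (``K40.1``) and undotted
    (``K401``); matching happens after normalization only.
    """
    return re.sub(r"[.\s]", "", code).upper()


def normalize_vocabulary(token: str) -> str:
    """Map a vocabulary token to its canonical form; raise on unknown tokens."""
    canon = re.sub(r"[-_\s]", "", token).upper()
    aliases = {"ICD9": "ICD9CM", "ICD10": "ICD10CM", "ICD10WHO": "ICD10WHO"}
    canon = aliases.get(canon, canon)
    if canon not in VOCABULARIES:
        raise ValueError(f"unknown vocabulary token {token!r} (expected one of {VOCABULARIES})")
    return canon


# --------------------------------------------------------------------------
# Map containers
# --------------------------------------------------------------------------

#: A phecode key is a PhecodeLabel in the phecodeX dialect and a bare numeric
#: string in the v1.2 dialect.
Phecode = "PhecodeLabel | str"


@dataclass(frozen=True)
class PhecodeEntry:
    """One phecode: label, human-readable description, category, ICD-10-only flag.

    Phecodes supported only by ICD-10-era billing codes carry
    ``icd10_only=True`` and, in the phecodeX dialect, a description ending in
    ``*``.
    """

    label: object  # PhecodeLabel (phecodeX) or str (v1.2)
    description: str
    category: str
    icd10_only: bool = False


@dataclass(frozen=True)
class IcdMapping:
    """One (ICD code, vocabulary) -> phecode arrow; codes stored normalized."""

    icd_code: str
    vocabulary: str
    phecode: object


@dataclass
class PhecodeMap:
    """An indexed phecode map: entries, ICD mappings, dialect and version.

    ``exclude_ranges`` is populated only for v1.2 maps: per phecode, intervals
    of related phecodes (e.g. ``"410-414.99"``) whose carriers are removed
    from that phecode's control group.  The phecodeX dialect defines no
    exclude ranges by design.
    """

    dialect: str = DIALECT_PHECODEX
    version: str = ""
    entries: dict = field(default_factory=dict)  # phecode -> PhecodeEntry
    mappings: tuple = ()  # tuple[IcdMapping, ...]
    exclude_ranges: dict = field(default_factory=dict)  # phecode -> tuple[str, ...]

    def __eq__(self, other) -> bool:
        if not isinstance(other, PhecodeMap):
            return NotImplemented
        return (
            self.dialect == other.dialect
            and self.version == other.version
            and self.entries == other.entries
            and set(self.mappings) == set(other.mappings)
            and {k: tuple(v) for k, v in self.exclude_ranges.items()}
            == {k: tuple(v) for k, v in other.exclude_ranges.items()}
        )

    # -- hierarchy ---------------------------------------------------------

    def parent_of(self, phecode):
        if self.dialect == DIALECT_PHECODEX:
            return phecode.parent()
        anc = v12_ancestors(phecode)
        return anc[0] if anc else None

    def ancestors_of(self, phecode) -> list:
        if self.dialect == DIALECT_PHECODEX:
            return ancestors(phecode)
        return v12_ancestors(phecode)

    def children_index(self) -> dict:
        """phecode -> list of direct child phecodes present in the map."""
        idx: dict = {p: [] for p in self.entries}
        for p in self.entries:
            parent = self.parent_of(p)
            if parent is not None and parent in idx:
                idx[parent].append(p)
        return idx

    def leaves(self) -> list:
        """Phecodes with no child entry present in the map, sorted."""
        idx = self.children_index()
        return sorted((p for p, kids in idx.items() if not kids), key=str)

    # -- lookup ------------------------------------------------------------

    def lookup_index(self) -> dict:
        """(normalized icd, vocabulary) -> frozenset of phecodes."""
        if not hasattr(self, "_lookup_cache") or self._lookup_cache[0] is not self.mappings:
            idx: dict = {}
            for m in self.mappings:
                idx.setdefault((m.icd_code, m.vocabulary), set()).add(m.phecode)
            object.__setattr__(self, "_lookup_cache", (self.mappings, idx))
        return self._lookup_cache[1]

    def phecode_str(self, phecode) -> str:
        return str(phecode)

    def mapping_frame(self) -> pd.DataFrame:
        """Mappings as a DataFrame with string phecodes (for joins downstream)."""
        return pd.DataFrame(
            {
                "icd_code": [m.icd_code for m in self.mappings],
                "vocabulary": [m.vocabulary for m in self.mappings],
                "phecode": [str(m.phecode) for m in self.mappings],
            }
        )


# --------------------------------------------------------------------------
# Category registry
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class CategoryRegistry:
    """Ordered (two-letter prefix, category name) pairs; prefixes and names unique."""

    categories: tuple  # tuple[tuple[str, str], ...]

    def __post_init__(self):
        prefixes = [p for p, _ in self.categories]
        names = [n for _, n in self.categories]
        if len(set(prefixes)) != len(prefixes):
            raise ValueError("duplicate category prefixes in registry")
        if len(set(names)) != len(names):
            raise ValueError("duplicate category names in registry")

    def prefix_for(self, name: str) -> str | None:
        for p, n in self.categories:
            if n == name:
                return p
        return None

    def name_for(self, prefix: str) -> str | None:
        for p, n in self.categories:
            if p == prefix:
                return n
        return None

    def prefixes(self) -> list[str]:
        return [p for p, _ in self.categories]

    def __len__(self) -> int:
        return len(self.categories)

    @classmethod
    def from_file(cls, path) -> "CategoryRegistry":
        """Read a two-column delimited file (prefix, name) with a header row."""
        df = pd.read_csv(path, dtype=str, sep=None, engine="python")
        return cls(tuple((r.iloc[0].strip(), r.iloc[1].strip()) for _, r in df.iterrows()))


#: Default 18-category registry.  CV, ID, RE, GI, EM and GE carry their
#: published category meanings; the remaining names follow common phecode
#: category naming and are configurable from file (``CategoryRegistry.from_file``).
DEFAULT_REGISTRY = CategoryRegistry(
    (
        ("BI", "Blood/Immune"),
        ("CM", "Congenital anomalies"),
        ("CV", "Cardiovascular"),
        ("DE", "Dermatological"),
        ("EM", "Endocrine/Metabolic"),
        ("EY", "Eye/Vision"),
        ("GE", "Genetic"),
        ("GI", "Gastrointestinal"),
        ("GU", "Genitourinary"),
        ("ID", "Infectious diseases"),
        ("MB", "Mental/Behavioral"),
        ("MS", "Musculoskeletal"),
        ("NN", "Neonatal"),
        ("NP", "Neoplasms"),
        ("NS", "Neurological"),
        ("PG", "Pregnancy"),
        ("RE", "Respiratory"),
        ("SS", "Symptoms/Signs"),
    )
)


# --------------------------------------------------------------------------
# Reading and writing mapping files
# --------------------------------------------------------------------------

_PHECODEX_COLUMNS = {
    "icd_code": "icd_code",
    "vocabulary": "vocabulary",
    "phecode": "phecode",
    "phecode_string": "phecode_string",
    "category": "category",
    "icd10_only": "icd10_only",
}
_V12_EXTRA_COLUMNS = {"exclude_range": "exclude_range"}

_TRUE_TOKENS = {"true", "t", "1", "yes"}
_FALSE_TOKENS = {"false", "f", "0", "no", ""}


def _parse_bool(token: str, row: int) -> bool:
    t = token.strip().lower()
    if t in _TRUE_TOKENS:
        return True
    if t in _FALSE_TOKENS:
        return False
    raise MapReadError(f"row {row}: cannot interpret icd10_only value {token!r} as boolean")


def _sniff_delimiter(path) -> str:
    with open(path, "r", newline="") as fh:
        first = fh.readline()
    return "\t" if "\t" in first else ","


def read_map(path, dialect: str = DIALECT_PHECODEX, column_config: Mapping[str, str] | None = None,
             version: str = "") -> PhecodeMap:
    """Read a delimited mapping file into a :class:`PhecodeMap`.

    The file must have a header row.  Comma is the default delimiter; tab is
    detected automatically.  ``column_config`` maps logical column names
    (``icd_code``, ``vocabulary``, ``phecode``, ``phecode_string``,
    ``category``, ``icd10_only``, and for v1.2 ``exclude_range``) to the
    actual header names of the release file.

    ICD codes are normalized (uppercased, dots stripped) before storage.
    Any malformed row aborts the read with a row-numbered diagnostic.
    """
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}")
    cols = dict(_PHECODEX_COLUMNS)
    if dialect == DIALECT_V12:
        cols.update(_V12_EXTRA_COLUMNS)
    if column_config:
        cols.update(column_config)

    sep = _sniff_delimiter(path)
    try:
        df = pd.read_csv(path, dtype=str, sep=sep, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise MapReadError(f"{path}: empty mapping file") from None
    if df.empty:
        raise MapReadError(f"{path}: mapping file has a header but no rows")

    required = ["icd_code", "vocabulary", "phecode"]
    missing = [cols[c] for c in required if cols[c] not in df.columns]
    if missing:
        raise MapReadError(f"{path}: missing required columns {missing}")

    entries: dict = {}
    mappings: list[IcdMapping] = []
    exclude_ranges: dict = {}
    problems: list[str] = []

    for i, row in enumerate(df.itertuples(index=False), start=2):  # row 1 = header
        rec = dict(zip(df.columns, row))
        try:
            vocab = normalize_vocabulary(rec[cols["vocabulary"]])
        except ValueError as exc:
            problems.append(f"row {i}: {exc}")
            continue
        raw_label = rec[cols["phecode"]].strip()
        try:
            if dialect == DIALECT_PHECODEX:
                phecode = parse_label(raw_label)
            else:
                phecode = parse_v12_code(raw_label)
        except MalformedLabelError as exc:
            problems.append(f"row {i}: {exc}")
            continue
        icd = normalize_icd(rec[cols["icd_code"]])
        if not icd:
            problems.append(f"row {i}: empty ICD code")
            continue
        description = rec.get(cols["phecode_string"], "") or ""
        category = rec.get(cols["category"], "") or ""
        flag_raw = rec.get(cols["icd10_only"], "") or ""
        try:
            icd10_only = _parse_bool(flag_raw, i)
        except MapReadError as exc:
            problems.append(str(exc))
            continue
        if phecode not in entries:
            entries[phecode] = PhecodeEntry(phecode, description, category, icd10_only)
        mappings.append(IcdMapping(icd, vocab, phecode))
        if dialect == DIALECT_V12:
            rng = (rec.get(cols["exclude_range"], "") or "").strip()
            if rng and phecode not in exclude_ranges:
                exclude_ranges[phecode] = tuple(s.strip() for s in rng.split(",") if s.strip())

    if problems:
        raise MapReadError(f"{path}: {len(problems)} bad row(s):\n" + "\n".join(problems))

    return PhecodeMap(
        dialect=dialect,
        version=version,
        entries=entries,
        mappings=tuple(mappings),
        exclude_ranges=exclude_ranges,
    )


def write_map(pmap: PhecodeMap, path, delimiter: str = ",") -> None:
    """Write a map back to delimited text; ``read_map`` of the output round-trips."""
    cols = ["icd_code", "vocabulary", "phecode", "phecode_string", "category", "icd10_only"]
    if pmap.dialect == DIALECT_V12:
        cols.append("exclude_range")
    rows = []
    for m in sorted(pmap.mappings, key=lambda m: (str(m.phecode), m.vocabulary, m.icd_code)):
        e = pmap.entries[m.phecode]
        rec = [m.icd_code, m.vocabulary, str(m.phecode), e.description, e.category,
               "true" if e.icd10_only else "false"]
        if pmap.dialect == DIALECT_V12:
            rec.append(",".join(pmap.exclude_ranges.get(m.phecode, ())))
        rows.append(rec)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter=delimiter)
        w.writerow(cols)
        w.writerows(rows)


# --------------------------------------------------------------------------
# Validation
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class Finding:
    """One validator finding: rule id, severity, human message, subject reference."""

    rule: str
    severity: str
    message: str
    subject: str = ""

    def to_dict(self) -> dict:
        return {"rule": self.rule, "severity": self.severity,
                "message": self.message, "subject": self.subject}


@dataclass
class ValidationReport:
    findings: list = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.findings

    def by_rule(self, rule: str) -> list:
        return [f for f in self.findings if f.rule == rule]

    def to_json(self) -> str:
        return json.dumps({"ok": self.ok, "findings": [f.to_dict() for f in self.findings]},
                          indent=2)


def validate_map(pmap: PhecodeMap, registry: CategoryRegistry = DEFAULT_REGISTRY) -> ValidationReport:
    """Structural validation; an empty report means the map is well-formed.

    Rules: hierarchy closure (every child's truncation parent exists), category
    prefix consistency, duplicate mapping triples, icd10_only consistency (the
    flag implies a ``*``-terminated description and no ICD-9 mapping), missing
    entries for mapped phecodes, and absence of exclude ranges in the phecodeX
    dialect.  Findings are report entries, never exceptions.
    """
    findings: list[Finding] = []

    # Hierarchy closure by suffix truncation.
    for p in sorted(pmap.entries, key=str):
        parent = pmap.parent_of(p)
        if parent is not None and parent not in pmap.entries:
            findings.append(Finding("orphan_child", "error",
                                    f"{p} has no parent entry {parent} in the map", str(p)))

    # Category prefix consistency (phecodeX labels carry their category prefix).
    if pmap.dialect == DIALECT_PHECODEX:
        for p, e in sorted(pmap.entries.items(), key=lambda kv: str(kv[0])):
            if not e.category:
                continue
            expected = registry.prefix_for(e.category)
            if expected is None:
                findings.append(Finding("unknown_category", "warning",
                                        f"{p}: category {e.category!r} not in registry", str(p)))
            elif p.category_prefix != expected:
                findings.append(Finding(
                    "prefix_mismatch", "error",
                    f"{p}: prefix {p.category_prefix} != registered prefix {expected} "
                    f"for category {e.category!r}", str(p)))

    # Duplicate (icd, vocabulary, phecode) triples.
    seen: set = set()
    for m in pmap.mappings:
        key = (m.icd_code, m.vocabulary, str(m.phecode))
        if key in seen:
            findings.append(Finding("duplicate_mapping", "error",
                                    f"duplicate mapping {key}", str(m.phecode)))
        seen.add(key)

    # Mapped phecode without an entry.
    for m in pmap.mappings:
        if m.phecode not in pmap.entries:
            findings.append(Finding("missing_entry", "error",
                                    f"mapping {m.icd_code}/{m.vocabulary} points at "
                                    f"unknown phecode {m.phecode}", str(m.phecode)))

    # icd10_only consistency.
    icd9_targets = {m.phecode for m in pmap.mappings if m.vocabulary == "ICD9CM"}
    for p, e in sorted(pmap.entries.items(), key=lambda kv: str(kv[0])):
        if e.icd10_only:
            if pmap.dialect == DIALECT_PHECODEX and not e.description.endswith("*"):
                findings.append(Finding("icd10_only_description", "error",
                                        f"{p}: icd10_only set but description lacks trailing '*'",
                                        str(p)))
            if p in icd9_targets:
                findings.append(Finding("icd10_only_icd9_mapping", "error",
                                        f"{p}: icd10_only set but an ICD-9 mapping exists", str(p)))

    # Exclude ranges are a v1.2-only construct.
    if pmap.dialect == DIALECT_PHECODEX and pmap.exclude_ranges:
        findings.append(Finding("exclude_ranges_in_phecodex", "error",
                                f"phecodeX map defines {len(pmap.exclude_ranges)} exclude range(s)"))

    return ValidationReport(findings)


# --------------------------------------------------------------------------
# Lookup and summaries
# --------------------------------------------------------------------------


def lookup(pmap: PhecodeMap, icd_code: str, vocabulary: str) -> set:
    """Directly mapped phecodes for one ICD code (no ancestor expansion).

    The query code is normalized exactly like stored codes; an unmapped code
    yields the empty set.
    """
    vocab = normalize_vocabulary(vocabulary)
    return set(pmap.lookup_index().get((normalize_icd(icd_code), vocab), set()))


def percent(numerator: float, denominator: float, digits: int = 1) -> float:
    """A percentage rounded for display: percent(543, 2688, 0) -> 20.0."""
    if denominator == 0:
        raise ZeroDivisionError("percentage with zero denominator")
    return round(100.0 * numerator / denominator, digits)


def expansion_ratio(new_count: float, old_count: float, digits: int = 1) -> float:
    """Fold-expansion between two category sizes: expansion_ratio(297, 58) -> 5.1."""
    if old_count == 0:
        raise ZeroDivisionError("expansion ratio with zero baseline")
    return round(new_count / old_count, digits)


@dataclass(frozen=True)
class VocabularySummary:
    n_icd_codes: int
    n_multi_mapped: int

    @property
    def multi_map_fraction(self) -> float:
        return self.n_multi_mapped / self.n_icd_codes if self.n_icd_codes else 0.0


@dataclass
class MapSummary:
    """Descriptive statistics of a phecode map."""

    n_entries: int
    category_counts: dict  # category name -> entry count
    vocabularies: dict  # vocab -> VocabularySummary
    n_leaves: int
    n_leaves_multi_mapped: int
    n_icd10_only: int

    @property
    def leaf_multi_map_fraction(self) -> float:
        return self.n_leaves_multi_mapped / self.n_leaves if self.n_leaves else 0.0

    def to_dict(self) -> dict:
        return {
            "n_entries": self.n_entries,
            "category_counts": dict(sorted(self.category_counts.items())),
            "vocabularies": {
                v: {"n_icd_codes": s.n_icd_codes, "n_multi_mapped": s.n_multi_mapped,
                    "multi_map_fraction": s.multi_map_fraction}
                for v, s in sorted(self.vocabularies.items())
            },
            "n_leaves": self.n_leaves,
            "n_leaves_multi_mapped": self.n_leaves_multi_mapped,
            "leaf_multi_map_fraction": self.leaf_multi_map_fraction,
            "n_icd10_only": self.n_icd10_only,
        }


def summarize_map(pmap: PhecodeMap, exclude_from_leaf_stats: Iterable = ()) -> MapSummary:
    """Compute :class:`MapSummary` counts.

    ``exclude_from_leaf_stats`` removes high-level combination phecodes (which
    multi-map by construction) from the leaf denominator; it defaults to empty,
    which is appropriate for synthetic maps.
    """
    excluded = {str(p) for p in exclude_from_leaf_stats}

    category_counts: dict = {}
    n_icd10_only = 0
    for e in pmap.entries.values():
        category_counts[e.category] = category_counts.get(e.category, 0) + 1
        if e.icd10_only:
            n_icd10_only += 1

    # Per-vocabulary multi-mapping: group mappings by (icd, vocab), count
    # groups whose distinct phecode targets exceed one.
    per_vocab_targets: dict = {}
    for m in pmap.mappings:
        per_vocab_targets.setdefault((m.vocabulary, m.icd_code), set()).add(m.phecode)
    vocabularies: dict = {}
    for vocab in sorted({v for v, _ in per_vocab_targets}):
        groups = [t for (v, _), t in per_vocab_targets.items() if v == vocab]
        vocabularies[vocab] = VocabularySummary(
            n_icd_codes=len(groups),
            n_multi_mapped=sum(1 for t in groups if len(t) > 1),
        )

    multi_mapped_icds = {(v, c) for (v, c), t in per_vocab_targets.items() if len(t) > 1}
    leaves = [p for p in pmap.leaves() if str(p) not in excluded]
    leaf_set = set(leaves)
    leaves_hit: set = set()
    for m in pmap.mappings:
        if m.phecode in leaf_set and (m.vocabulary, m.icd_code) in multi_mapped_icds:
            leaves_hit.add(m.phecode)

    return MapSummary(
        n_entries=len(pmap.entries),
        category_counts=category_counts,
        vocabularies=vocabularies,
        n_leaves=len(leaves),
        n_leaves_multi_mapped=len(leaves_hit),
        n_icd10_only=n_icd10_only,
    )


# --------------------------------------------------------------------------
# Crosswalk between v1.2 and phecodeX
# --------------------------------------------------------------------------

V12_TO_X = "v12_to_X"
X_TO_V12 = "X_to_v12"


@dataclass(frozen=True)
class Crosswalk:
    """Partial translation table between v1.2 numeric codes and phecodeX labels.

    The crosswalk is many-to-many by design; codes on either side without a
    counterpart translate to the empty tuple (an explicit no-counterpart
    marker) rather than failing.
    """

    pairs: tuple  # tuple[tuple[str v12, PhecodeLabel], ...]

    def _index(self, direction: str) -> dict:
        idx: dict = {}
        for v12, x in self.pairs:
            if direction == V12_TO_X:
                idx.setdefault(v12, set()).add(x)
            else:
                idx.setdefault(str(x), set()).add(v12)
        return {k: tuple(sorted(v, key=str)) for k, v in idx.items()}


def read_crosswalk(path, column_config: Mapping[str, str] | None = None) -> Crosswalk:
    """Read a two-column crosswalk file (``phecode_v12``, ``phecode_x``)."""
    cols = {"phecode_v12": "phecode_v12", "phecode_x": "phecode_x"}
    if column_config:
        cols.update(column_config)
    sep = _sniff_delimiter(path)
    df = pd.read_csv(path, dtype=str, sep=sep, keep_default_na=False)
    pairs = []
    for i, row in df.iterrows():
        v12 = parse_v12_code(row[cols["phecode_v12"]].strip())
        x = parse_label(row[cols["phecode_x"]].strip())
        pairs.append((v12, x))
    return Crosswalk(tuple(pairs))


def translate(crosswalk: Crosswalk, code, direction: str = V12_TO_X) -> tuple:
    """Translate one phecode across releases.

    Returns a sorted tuple of counterparts; the empty tuple marks a code with
    no counterpart (never an exception, never a silent drop).
    """
    if direction not in (V12_TO_X, X_TO_V12):
        raise ValueError(f"unknown direction {direction!r}")
    return crosswalk._index(direction).get(str(code), ())
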