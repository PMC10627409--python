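"""Synthetic phecode maps and simulated EHR cohorts.

Real phecode releases and EHR event streams cannot ship with a toolkit, so
this module generates miniatures with the same structure: grammar-valid
hierarchical maps with controllable multi-mapping and ICD-10-only fractions,
and cohorts of dated ICD events driven by a simple genotype-phenotype model.

The cohort generative model: each person carries a genotype dosage
``g ~ Binomial(2, MAF)``.  For every leaf phecode the person is *affected*
with probability ``expit(logit(prevalence) + beta * g)``, where ``beta`` is
the planted log-odds-ratio (zero for null phenotypes).  Affected persons emit
ICD codes drawn uniformly from the leaf's mapped codes on ``D`` distinct
dates, ``D ~ 1 + Poisson(mean_dates - 1)``, so most affected persons clear a
minimum code count of two while a computable fraction (``exp(-(mean_dates-1))``
has D=1) does not.  Background noise events are sprinkled uniformly over the
whole map.  Effects are planted at leaves; ancestors inherit signal only
through hierarchical rollup, which is exactly the mechanism the rest of the
pipeline must get right.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .map_model import (
    CategoryRegistry,
    DEFAULT_REGISTRY,
    DIALECT_PHECODEX,
    IcdMapping,
    PhecodeEntry,
    PhecodeLabel,
    PhecodeMap,
)
from .phenome import assign_case_control, map_events
from .phewas import PhewasConfig, run_phewas

__all__ = [
    "MapSimConfig",
    "CohortSimConfig",
    "CalibrationResult",
    "simulate_map",
    "simulate_cohort",
    "null_calibration",
]


@dataclass
class MapSimConfig:
    """Shape of a synthetic map.

    ``multi_map_rate`` is the target fraction of ICD codes (per vocabulary)
    mapped to more than one phecode; ``icd10_only_fraction`` is the fraction
    of phecodes with no ICD-9 support.  ``child_prob`` / ``grandchild_prob``
    control how often a root grows children and a child grandchildren.
    """

    n_categories: int = 3
    roots_per_category: int = 5
    child_prob: float = 0.5
    grandchild_prob: float = 0.3
    max_children: int = 3
    multi_map_rate: float = 0.1
    icd10_only_fraction: float = 0.1
    mean_icd_per_phecode: float = 2.0
    who_fraction: float = 0.0
    seed: int = 0
    registry: CategoryRegistry = DEFAULT_REGISTRY

    def __post_init__(self):
        for name in ("child_prob", "grandchild_prob", "multi_map_rate",
                     "icd10_only_fraction", "who_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_categories < 1 or self.roots_per_category < 1:
            raise ValueError("n_categories and roots_per_category must be >= 1")
        if self.n_categories > len(self.registry):
            raise ValueError("more categories requested than the registry defines")
        if self.mean_icd_per_phecode < 1.0:
            raise ValueError("mean_icd_per_phecode must be >= 1")


def _unique_codes(rng, existing: set, n: int, make) -> list[str]:
    out = []
    while len(out) < n:
        c = make(rng)
        if c not in existing:
            existing.add(c)
            out.append(c)
    return out


def _make_icd10(rng) -> str:
    # letter + three digits, like the normalized (undotted) form K401
    return chr(ord("A") + int(rng.integers(0, 26))) + f"{int(rng.integers(0, 1000)):03d}"


def _make_icd9(rng) -> str:
    return f"{int(rng.integers(1000, 10000))}"


def simulate_map(config: MapSimConfig) -> tuple[PhecodeMap, dict]:
    """Generate a grammar-valid phecodeX-dialect map plus its ground truth.

    The returned map passes structural validation with an empty report, and
    the realized multi-mapping rate equals round(rate*n)/n codes per
    vocabulary.  ICD codes are synthetic but vocabulary-shaped (letter+digits
    for ICD-10-like, digits for ICD-9-like).
    """
    rng = np.random.default_rng(config.seed)
    categories = config.registry.categories[: config.n_categories]

    n_roots = config.n_categories * config.roots_per_category
    if n_roots > 900:
        raise ValueError("at most 900 distinct three-digit roots exist")
    root_numbers = rng.choice(np.arange(100, 1000), size=n_roots, replace=False)

    labels: list[PhecodeLabel] = []
    for ci, (prefix, _) in enumerate(categories):
        for ri in range(config.roots_per_category):
            root = f"{int(root_numbers[ci * config.roots_per_category + ri]):03d}"
            root_label = PhecodeLabel(prefix, root)
            labels.append(root_label)
            if rng.random() < config.child_prob:
                for c in range(1, int(rng.integers(1, config.max_children + 1)) + 1):
                    child = PhecodeLabel(prefix, root, str(c))
                    labels.append(child)
                    if rng.random() < config.grandchild_prob:
                        for gsuffix in range(1, int(rng.integers(1, config.max_children + 1)) + 1):
                            labels.append(PhecodeLabel(prefix, root, f"{c}{gsuffix}"))

    icd10_only = {lab: bool(rng.random() < config.icd10_only_fraction) for lab in labels}

    cat_name = dict(categories)
    entries: dict = {}
    for lab in labels:
        desc = f"Synthetic phenotype {lab}"
        if icd10_only[lab]:
            desc += "*"
        entries[lab] = PhecodeEntry(lab, desc, cat_name[lab.category_prefix],
                                    icd10_only[lab])

    # Base (one-to-one) ICD assignment per vocabulary.
    used10: set = set()
    used9: set = set()
    mappings: list[IcdMapping] = []
    home10: dict = {}  # icd -> home label
    home9: dict = {}
    for lab in labels:
        k10 = 1 + int(rng.poisson(config.mean_icd_per_phecode - 1.0))
        for code in _unique_codes(rng, used10, k10, _make_icd10):
            mappings.append(IcdMapping(code, "ICD10CM", lab))
            home10[code] = lab
            if config.who_fraction and rng.random() < config.who_fraction:
                mappings.append(IcdMapping(code, "ICD10WHO", lab))
        if not icd10_only[lab]:
            k9 = 1 + int(rng.poisson(config.mean_icd_per_phecode - 1.0))
            for code in _unique_codes(rng, used9, k9, _make_icd9):
                mappings.append(IcdMapping(code, "ICD9CM", lab))
                home9[code] = lab

    # Multi-mapping: promote round(rate * n) codes per vocabulary to a second
    # phecode.  ICD-9 codes may not target icd10_only phecodes.
    multi_truth: dict = {"ICD10CM": {}, "ICD9CM": {}}
    for vocab, home, eligible_targets in (
        ("ICD10CM", home10, labels),
        ("ICD9CM", home9, [l for l in labels if not icd10_only[l]]),
    ):
        codes = sorted(home)
        n_multi = int(round(config.multi_map_rate * len(codes)))
        if n_multi == 0:
            continue
        if len(eligible_targets) < 2:
            raise ValueError(
                f"infeasible config: multi-mapping requested but fewer than two "
                f"eligible phecodes exist for {vocab}")
        chosen = rng.choice(len(codes), size=n_multi, replace=False)
        for ci in sorted(chosen):
            code = codes[ci]
            options = [l for l in eligible_targets if l != home[code]]
            target = options[int(rng.integers(0, len(options)))]
            mappings.append(IcdMapping(code, vocab, target))
            multi_truth[vocab][code] = [str(home[code]), str(target)]

    mappings.sort(key=lambda m: (str(m.phecode), m.vocabulary, m.icd_code))
    pmap = PhecodeMap(dialect=DIALECT_PHECODEX, version="synthetic-1",
                      entries=dict(sorted(entries.items(), key=lambda kv: str(kv[0]))),
                      mappings=tuple(mappings))
    truth = {
        "config": config,
        "labels": [str(l) for l in labels],
        "icd10_only": {str(l): f for l, f in icd10_only.items()},
        "multi_mapped": multi_truth,
    }
    return pmap, truth


@dataclass
class CohortSimConfig:
    """Cohort generative-model parameters.

    ``effects`` maps phecode label strings to planted log-odds-ratios (per
    genotype dosage); ``prevalence`` is the baseline (g=0) affection
    probability, a scalar for all leaves or a per-leaf dict; ``mean_dates`` is
    the mean number of distinct coded dates for an affected phenotype (keep it
    >= the minimum code count plus slack so affected persons usually qualify
    as cases); ``background_rate`` is the mean number of noise events per
    person drawn uniformly from the whole map.
    """

    n_persons: int = 5000
    maf: float = 0.3
    effects: dict = field(default_factory=dict)
    prevalence: object = 0.05
    mean_dates: float = 3.0
    background_rate: float = 1.0
    n_days: int = 2000
    start_date: str = "2015-01-01"
    seed: int = 0

    def __post_init__(self):
        if self.n_persons < 2:
            raise ValueError("n_persons must be >= 2")
        if not (0.0 < self.maf <= 0.5):
            raise ValueError("maf must be in (0, 0.5]")
        prevs = (self.prevalence.values() if isinstance(self.prevalence, dict)
                 else [self.prevalence])
        if not all(0.0 < p < 1.0 for p in prevs):
            raise ValueError("prevalences must be in (0, 1)")
        if self.mean_dates < 1.0:
            raise ValueError("mean_dates must be >= 1")
        if self.background_rate < 0.0:
            raise ValueError("background_rate must be >= 0")


def _distinct_days(rng, pair_ids: np.ndarray, n_days: int) -> np.ndarray:
    """Draw one day per row, distinct within each pair id (vectorized redraw)."""
    days = rng.integers(0, n_days, size=len(pair_ids))
    for _ in range(30):
        order = np.lexsort((days, pair_ids))
        key_p, key_d = pair_ids[order], days[order]
        dup_sorted = np.zeros(len(days), dtype=bool)
        dup_sorted[1:] = (key_p[1:] == key_p[:-1]) & (key_d[1:] == key_d[:-1])
        if not dup_sorted.any():
            break
        dup = np.zeros(len(days), dtype=bool)
        dup[order] = dup_sorted
        days[dup] = rng.integers(0, n_days, size=int(dup.sum()))
    return days


def simulate_cohort(pmap: PhecodeMap, config: CohortSimConfig
                    ) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Simulate an event table, a predictor table and the ground truth.

    Returns ``(events, predictors, truth)``: events with columns
    (person_id, icd_code, vocabulary, date); predictors with
    (person_id, genotype, age, sex) where age and sex carry no planted effect;
    truth records the genotype vector, the person x leaf affection matrix and
    the parameters, enough to recompute every planted quantity.
    """
    rng = np.random.default_rng(config.seed)
    leaves = [str(l) for l in pmap.leaves()]
    icds_by_phecode: dict = {}
    for m in pmap.mappings:
        icds_by_phecode.setdefault(str(m.phecode), []).append((m.icd_code, m.vocabulary))
    for p in icds_by_phecode:
        icds_by_phecode[p].sort()

    for p, beta in config.effects.items():
        if p not in {str(l) for l in pmap.entries}:
            raise ValueError(f"planted phecode {p} is absent from the map")
        if not icds_by_phecode.get(p):
            raise ValueError(f"planted phecode {p} has no mapped ICD codes")

    n = config.n_persons
    person_ids = np.array([f"P{i:06d}" for i in range(n)])
    genotype = rng.binomial(2, config.maf, size=n)

    def prev_of(leaf: str) -> float:
        if isinstance(config.prevalence, dict):
            return float(config.prevalence.get(leaf, 0.0))
        return float(config.prevalence)

    person_parts, day_parts, icd_parts, vocab_parts = [], [], [], []
    affected_cols = {}
    base_day = np.datetime64(config.start_date)
    lam = config.mean_dates - 1.0
    for li, leaf in enumerate(leaves):
        prev = prev_of(leaf)
        if prev <= 0.0:
            affected_cols[leaf] = np.zeros(n, dtype=bool)
            continue
        beta = float(config.effects.get(leaf, 0.0))
        logit = np.log(prev / (1.0 - prev)) + beta * genotype
        p_aff = 1.0 / (1.0 + np.exp(-logit))
        affected = rng.random(n) < p_aff
        affected_cols[leaf] = affected
        idx = np.flatnonzero(affected)
        if len(idx) == 0:
            continue
        d = 1 + rng.poisson(lam, size=len(idx))
        rep = np.repeat(idx, d)
        pair = np.repeat(np.arange(len(idx)), d) + li * (n + 1)
        days = _distinct_days(rng, pair, config.n_days)
        codes = icds_by_phecode[leaf]
        pick = rng.integers(0, len(codes), size=len(rep))
        person_parts.append(rep)
        day_parts.append(days)
        icd_parts.append(np.array([codes[j][0] for j in pick]))
        vocab_parts.append(np.array([codes[j][1] for j in pick]))

    # Background contamination: uniform draws over every mapping in the map.
    if config.background_rate > 0:
        all_codes = sorted({(m.icd_code, m.vocabulary) for m in pmap.mappings})
        b = rng.poisson(config.background_rate, size=n)
        rep = np.repeat(np.arange(n), b)
        if len(rep):
            days = rng.integers(0, config.n_days, size=len(rep))
            pick = rng.integers(0, len(all_codes), size=len(rep))
            person_parts.append(rep)
            day_parts.append(days)
            icd_parts.append(np.array([all_codes[j][0] for j in pick]))
            vocab_parts.append(np.array([all_codes[j][1] for j in pick]))

    if person_parts:
        pidx = np.concatenate(person_parts)
        days = np.concatenate(day_parts)
        events = pd.DataFrame({
            "person_id": person_ids[pidx],
            "icd_code": np.concatenate(icd_parts),
            "vocabulary": np.concatenate(vocab_parts),
            "date": (base_day + days.astype("timedelta64[D]")).astype(str),
        })
    else:
        events = pd.DataFrame(columns=["person_id", "icd_code", "vocabulary", "date"])

    predictors = pd.DataFrame({
        "person_id": person_ids,
        "genotype": genotype,
        "age": rng.integers(18, 90, size=n),
        "sex": rng.integers(0, 2, size=n),
    })
    truth = {
        "config": config,
        "genotype": genotype,
        "affected": pd.DataFrame(affected_cols, index=person_ids),
        "leaves": leaves,
    }
    return events, predictors, truth


@dataclass(frozen=True)
class CalibrationResult:
    rate: float
    se: float
    n_tested: int
    n_significant: int


def null_calibration(pmap: PhecodeMap, config: CohortSimConfig, alpha: float = 0.05,
                     min_code_count: int = 2, min_cases: int = 100) -> CalibrationResult:
    """Empirical type-I error of the full pipeline under the null.

    Simulates a cohort with no planted effects, builds the phenome, runs the
    scan, and returns the fraction of tested phecodes with p < alpha together
    with its binomial standard error.
    """
    if any(b != 0 for b in config.effects.values()):
        raise ValueError("null calibration requires a config without planted effects")
    if not (0.0 < alpha <= 1.0):
        raise ValueError("alpha must be in (0, 1]")
    events, predictors, _ = simulate_cohort(pmap, config)
    counts = map_events(events, pmap, rollup=True,
                        roster=[f"P{i:06d}" for i in range(config.n_persons)])
    matrix = assign_case_control(counts, min_code_count=min_code_count)
    results = run_phewas(matrix, predictors,
                         PhewasConfig(min_cases=min_cases, predictor="genotype"))
    tested = [r for r in results if r.skipped is None]
    if not tested:
        raise ValueError("no phecodes reached the case-count floor; nothing to calibrate")
    n_sig = sum(1 for r in tested if r.p_value < alpha)
    rate = n_sig / len(tested)
    se = float(np.sqrt(max(rate * (1 - rate), 1e-12) / len(tested)))
    return CalibrationResult(rate=rate, se=se, n_tested=len(tested), n_significant=n_sig)
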