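"""Phenome-wide association scan (PheWAS).

For every phecode-defined phenotype with enough cases, case/control status is
regressed on a predictor (typically a genotype dosage 0/1/2 or a binary
exposure) with optional covariates, via maximum-likelihood logistic
regression.  Per-phecode "neither" persons are dropped test-wise.  Phenotypes
below the case-count floor are reported as skipped, never silently omitted.
Multiple testing is handled with the Bonferroni bound alpha/m by default;
Benjamini-Hochberg is available for exploratory use.

The logistic fits use iteratively reweighted least squares (IRLS), the Newton
iteration for the canonical logit link.  Quasi-separated or otherwise
non-convergent fits are flagged — the coefficient step fails to shrink below
tolerance when the likelihood has no interior maximum — and their p-values
should not be trusted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .map_model import CategoryRegistry, DEFAULT_REGISTRY
from .phenome import CASE, CONTROL, CaseControlMatrix

__all__ = [
    "LogisticFit",
    "PhewasConfig",
    "PhewasResult",
    "fit_logistic",
    "run_phewas",
    "bonferroni_threshold",
    "benjamini_hochberg",
    "results_frame",
    "phenome_plot_data",
    "plot_phewas",
]


@dataclass(frozen=True)
class LogisticFit:
    beta: np.ndarray
    se: np.ndarray
    converged: bool
    n_iter: int


def fit_logistic(y: np.ndarray, X: np.ndarray, tol: float = 1e-8,
                 max_iter: int = 25) -> LogisticFit:
    """Maximum-likelihood logistic regression by IRLS.

    ``X`` must include the intercept column and have full column rank, and
    ``y`` (0/1) must contain both classes.  Convergence is declared when the
    largest coefficient change drops below ``tol``; failure to converge within
    ``max_iter`` iterations — which is also how (quasi-)separation manifests,
    as the estimates diverge — is reported through the ``converged`` flag,
    never silently.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("design matrix and outcome shapes disagree")
    n, p = X.shape
    if not (np.any(y == 0) and np.any(y == 1)):
        raise ValueError("outcome must contain both classes")
    if np.linalg.matrix_rank(X) < p:
        raise np.linalg.LinAlgError("design matrix is rank deficient")

    beta = np.zeros(p)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.clip(mu * (1.0 - mu), 1e-12, None)
        XtW = X.T * w
        info = XtW @ X
        score = X.T @ (y - mu)
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            break
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            converged = True
            break

    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = np.clip(mu * (1.0 - mu), 1e-12, None)
    info = (X.T * w) @ X
    try:
        cov = np.linalg.inv(info)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
        converged = False
    return LogisticFit(beta=beta, se=se, converged=converged, n_iter=it)


@dataclass
class PhewasConfig:
    """Scan configuration.

    ``min_cases`` (default 100) filters out rare phenotypes before testing —
    with few cases the logistic Wald test is unstable and such codes are
    conventionally excluded from PheWAS.  ``covariates`` names columns of the
    predictor table entered as adjustment terms.
    """

    min_cases: int = 100
    alpha: float = 0.05
    covariates: tuple = ()
    max_iter: int = 25
    tol: float = 1e-8
    predictor: str = "predictor"

    def __post_init__(self):
        if self.min_cases < 1:
            raise ValueError("min_cases must be >= 1")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")


@dataclass(frozen=True)
class PhewasResult:
    """Association result for one phecode (or the reason it was skipped)."""

    phecode: str
    n_case: int
    n_control: int
    beta: float = np.nan
    se: float = np.nan
    odds_ratio: float = np.nan
    p_value: float = np.nan
    converged: bool = False
    skipped: str | None = None


def run_phewas(matrix: CaseControlMatrix, predictors: pd.DataFrame,
               config: PhewasConfig | None = None) -> list[PhewasResult]:
    """Scan every phecode against the predictor.

    Persons with "neither" status for a phecode are excluded from that
    phecode's test only (test-wise deletion).  Phecodes with fewer than
    ``min_cases`` cases are emitted with ``skipped="low_case_count"``; a
    single-class outcome or a constant predictor among the retained persons
    yields ``skipped="degenerate"``.  Output order is deterministic (sorted by
    phecode label).
    """
    cfg = config or PhewasConfig()
    pred = predictors.copy()
    pred["person_id"] = pred["person_id"].astype(str)
    if pred["person_id"].duplicated().any():
        raise ValueError("predictor table must have one row per person")
    if pred[cfg.predictor].isna().any():
        raise ValueError("missing predictor values are not allowed")
    pred = pred.set_index("person_id")

    shared = matrix.status.index.intersection(pred.index)
    if len(shared) == 0:
        raise ValueError("no persons shared between case/control matrix and predictors")
    status = matrix.status.loc[shared]
    design_cols = [cfg.predictor, *cfg.covariates]
    Z = pred.loc[shared, design_cols].to_numpy(dtype=float)

    results: list[PhewasResult] = []
    for phecode in sorted(status.columns, key=str):
        s = status[phecode].to_numpy()
        keep = (s == CASE) | (s == CONTROL)
        y = (s[keep] == CASE).astype(float)
        n_case = int(y.sum())
        n_control = int(keep.sum() - n_case)
        if n_case < cfg.min_cases:
            results.append(PhewasResult(str(phecode), n_case, n_control,
                                        skipped="low_case_count"))
            continue
        Xk = np.column_stack([np.ones(keep.sum()), Z[keep]])
        if n_control == 0 or np.any(np.ptp(Xk[:, 1:], axis=0) == 0):
            results.append(PhewasResult(str(phecode), n_case, n_control,
                                        skipped="degenerate"))
            continue
        try:
            fit = fit_logistic(y, Xk, tol=cfg.tol, max_iter=cfg.max_iter)
        except (ValueError, np.linalg.LinAlgError):
            results.append(PhewasResult(str(phecode), n_case, n_control,
                                        skipped="degenerate"))
            continue
        beta = float(fit.beta[1])
        se = float(fit.se[1])
        z = beta / se if se > 0 else np.nan
        p = float(np.clip(2.0 * stats.norm.sf(abs(z)), np.nextafter(0, 1), 1.0))
        results.append(PhewasResult(str(phecode), n_case, n_control, beta=beta, se=se,
                                    odds_ratio=float(np.exp(beta)), p_value=p,
                                    converged=fit.converged))
    return results


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Family-wise significance threshold alpha / m.

    With the full current-release map (3612 phecodes) at alpha=0.05 this is
    1.38e-5; with the legacy 1866-code release, 2.68e-5.
    """
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    return alpha / n_tests


def benjamini_hochberg(p_values, alpha: float = 0.05) -> np.ndarray:
    """FDR-significance flags (exploratory alternative to Bonferroni)."""
    reject, _, _, _ = multipletests(np.asarray(p_values, dtype=float),
                                    alpha=alpha, method="fdr_bh")
    return reject


def results_frame(results: list[PhewasResult]) -> pd.DataFrame:
    """Results as a DataFrame, ready for TSV export."""
    return pd.DataFrame(
        {
            "phecode": [r.phecode for r in results],
            "n_case": [r.n_case for r in results],
            "n_control": [r.n_control for r in results],
            "beta": [r.beta for r in results],
            "se": [r.se for r in results],
            "odds_ratio": [r.odds_ratio for r in results],
            "p_value": [r.p_value for r in results],
            "converged": [r.converged for r in results],
            "skipped": [r.skipped or "" for r in results],
        }
    )


def phenome_plot_data(results: list[PhewasResult],
                      registry: CategoryRegistry = DEFAULT_REGISTRY,
                      alpha: float = 0.05) -> pd.DataFrame:
    """Manhattan-style plot table for tested phecodes.

    Rows carry (phecode, category, x, neg_log10_p, direction); x positions
    are contiguous within each category and categories follow registry order,
    with unregistered prefixes collected under "other" (with a warning).  The
    Bonferroni threshold over the tested phecodes is attached as
    ``df.attrs["threshold"]``.
    """
    tested = [r for r in results if r.skipped is None]
    if not tested:
        raise ValueError("no tested results to plot")
    rows = []
    for r in tested:
        prefix = r.phecode[:2]
        category = registry.name_for(prefix)
        if category is None:
            warnings.warn(f"phecode {r.phecode}: prefix {prefix!r} not in category registry; "
                          f"plotted under 'other'")
            category = "other"
        rows.append({"phecode": r.phecode, "category": category,
                     "neg_log10_p": -np.log10(r.p_value),
                     "direction": 1 if r.beta >= 0 else -1})
    df = pd.DataFrame(rows)
    order = {name: i for i, (_, name) in enumerate(registry.categories)}
    order["other"] = len(order)
    df = df.sort_values(["category", "phecode"],
                        key=lambda s: s.map(order) if s.name == "category" else s)
    df = df.reset_index(drop=True)
    df["x"] = np.arange(len(df))
    df.attrs["threshold"] = bonferroni_threshold(alpha, len(tested))
    return df[["phecode", "category", "x", "neg_log10_p", "direction"]]


def plot_phewas(plot_df: pd.DataFrame, ax=None):
    """Render the Manhattan-style phenome plot (optional figure output)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(10, 4))
    for i, (cat, grp) in enumerate(plot_df.groupby("category", sort=False)):
        ax.scatter(grp["x"], grp["neg_log10_p"], s=12, label=cat,
                   color=f"C{i % 10}")
    thr = plot_df.attrs.get("threshold")
    if thr:
        ax.axhline(-np.log10(thr), color="red", linestyle="--", linewidth=1)
    ax.set_xlabel("phecode (grouped by category)")
    ax.set_ylabel(r"$-\log_{10} p$")
    ax.legend(fontsize=6, ncol=3)
    return ax
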