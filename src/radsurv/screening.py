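"""Univariable survival screening and correlation pruning.

Workflow: univariable Cox regression (Wald tests, Efron tie handling) for
every candidate predictor plus log-rank tests for categorical ones; keep
variables with p < 0.100 (strict) as the *full* input; prune significantly
Spearman-correlated pairs (p < 0.05) with deterministic priority rules to
obtain the *uncorrelated* input.  Clinicopathological variables are
systematically privileged over radiomics-based ones.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy.stats import norm, spearmanr

from .coxfit import ConvergenceError, cox_newton_fit

__all__ = [
    "UnivariableResult",
    "InputSet",
    "fit_univariable_cox",
    "fit_univariable_categorical",
    "logrank_test",
    "kaplan_meier",
    "screen_variables",
    "filter_candidates",
    "prune_correlated",
]


@dataclass
class UnivariableResult:
    variable: str
    hr: float
    ci_low: float
    ci_high: float
    p: float
    beta: float
    se: float
    provenance: str = "radiomics"  # or "clinicopathological"
    levels: list[dict] | None = None  # per-level rows for categoricals
    logrank_p: float | None = None

    @property
    def min_p(self) -> float:
        """Smallest per-level Wald p for categoricals, else the Wald p."""
        if self.levels:
            return min(lv["p"] for lv in self.levels)
        return self.p


@dataclass
class InputSet:
    label: str  # clinicopathological | full | uncorrelated
    variables: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps({"label": self.label, "variables": self.variables})
        )


def _check_outcomes(time: np.ndarray, event: np.ndarray) -> None:
    time = np.asarray(time, dtype=float)
    if not np.all(np.isfinite(time)) or np.any(time <= 0):
        raise ValueError("times must be finite and positive")
    if int(np.asarray(event).sum()) < 2:
        raise ValueError("need at least 2 events")


def fit_univariable_cox(
    x: np.ndarray | pd.Series,
    time: np.ndarray,
    event: np.ndarray,
    name: str = "x",
    provenance: str = "radiomics",
) -> UnivariableResult:
    """Univariable Cox fit (partial likelihood, Efron ties, Newton iteration).

    Returns the hazard ratio with its Wald 95% CI and Wald p.  Constant
    covariates and non-convergent (e.g. perfectly separating) fits raise.
    """
    x = np.asarray(x, dtype=float)
    _check_outcomes(time, event)
    if np.ptp(x) == 0:
        raise ValueError(f"covariate {name!r} is constant")
    try:
        fit = cox_newton_fit(x[:, None], np.asarray(time, float), event)
    except (ConvergenceError, ValueError) as exc:
        raise RuntimeError(f"univariable Cox fit failed for {name!r}: {exc}") from exc
    beta = float(fit.beta[0])
    se = float(fit.se[0])
    return UnivariableResult(
        variable=name,
        hr=float(np.exp(beta)),
        ci_low=float(np.exp(beta - 1.96 * se)),
        ci_high=float(np.exp(beta + 1.96 * se)),
        p=float(2.0 * norm.sf(abs(beta / se))) if se > 0 else 1.0,
        beta=beta,
        se=se,
        provenance=provenance,
    )


def fit_univariable_categorical(
    x: pd.Series,
    time: np.ndarray,
    event: np.ndarray,
    name: str = "x",
    reference: str | None = None,
    provenance: str = "clinicopathological",
) -> UnivariableResult:
    """Per-level hazard ratios vs a reference level plus a log-rank p.

    The per-level HRs come from a single Cox fit on the level indicators
    (reference dropped); the headline p is the smallest per-level Wald p.
    """
    _check_outcomes(time, event)
    levels = sorted(pd.unique(x.astype(str)))
    if reference is None:
        reference = levels[0]
    others = [lv for lv in levels if lv != reference]
    if not others:
        raise ValueError(f"covariate {name!r} has a single level")
    design = np.column_stack(
        [(x.astype(str) == lv).astype(float).to_numpy() for lv in others]
    )
    fit = cox_newton_fit(design, np.asarray(time, float), event)
    lv_rows = []
    for j, lv in enumerate(others):
        b, se = float(fit.beta[j]), float(fit.se[j])
        lv_rows.append(
            {
                "level": lv,
                "hr": float(np.exp(b)),
                "ci_low": float(np.exp(b - 1.96 * se)),
                "ci_high": float(np.exp(b + 1.96 * se)),
                "p": float(2.0 * norm.sf(abs(b / se))) if se > 0 else 1.0,
            }
        )
    chi2, lr_p = logrank_test(x.astype(str).to_numpy(), time, event)
    best = min(lv_rows, key=lambda r: r["p"])
    return UnivariableResult(
        variable=name,
        hr=best["hr"],
        ci_low=best["ci_low"],
        ci_high=best["ci_high"],
        p=best["p"],
        beta=float(np.log(best["hr"])),
        se=float("nan"),
        provenance=provenance,
        levels=lv_rows,
        logrank_p=lr_p,
    )


def logrank_test(
    groups: np.ndarray, time: np.ndarray, event: np.ndarray
) -> tuple[float, float]:
    """Standard log-rank test over pooled event times; returns (chi2, p)."""
    groups = np.asarray(groups)
    if len(pd.unique(groups)) < 2:
        raise ValueError("log-rank requires at least 2 groups")
    res = multivariate_logrank_test(np.asarray(time, float), groups, np.asarray(event))
    return float(res.test_statistic), float(res.p_value)


def kaplan_meier(
    time: np.ndarray, event: np.ndarray, at: float | None = None
) -> dict:
    """Product-limit estimate with Greenwood-type log-log CIs.

    Returns the fitted step function (as a DataFrame), the median (None when
    not reached) and, when ``at`` is given, the survival probability at that
    time with its 95% CI.
    """
    kmf = KaplanMeierFitter()
    kmf.fit(np.asarray(time, float), np.asarray(event))
    median = float(kmf.median_survival_time_)
    out = {
        "survival": kmf.survival_function_,
        "median": None if np.isinf(median) else median,
    }
    if at is not None:
        s = float(kmf.predict(at))
        ci = kmf.confidence_interval_
        idx = ci.index[ci.index <= at]
        if len(idx):
            lo = float(ci.iloc[ci.index.get_loc(idx[-1]), 0])
            hi = float(ci.iloc[ci.index.get_loc(idx[-1]), 1])
        else:
            lo, hi = 1.0, 1.0
        out["at"] = {"t": at, "s": s, "ci": (min(lo, hi), max(lo, hi))}
    return out


def screen_variables(
    data: pd.DataFrame,
    time: np.ndarray,
    event: np.ndarray,
    provenance: dict[str, str],
    categorical: list[str] | None = None,
    threshold: float = 0.100,
) -> tuple[list[UnivariableResult], InputSet, InputSet]:
    """Univariable screen over all columns of ``data``.

    ``provenance`` maps each variable to "clinicopathological" or
    "radiomics"; ``categorical`` names the columns screened with per-level
    HRs and log-rank.  Returns (results, full input, clinicopathological
    input).
    """
    categorical = categorical or []
    results: list[UnivariableResult] = []
    for col in data.columns:
        prov = provenance.get(col, "radiomics")
        if col in categorical:
            res = fit_univariable_categorical(
                data[col], time, event, name=col, provenance=prov
            )
        else:
            res = fit_univariable_cox(
                data[col].to_numpy(dtype=float), time, event, name=col, provenance=prov
            )
        results.append(res)
    full, clin = filter_candidates(results, threshold=threshold)
    return results, full, clin


def filter_candidates(
    results: list[UnivariableResult], threshold: float = 0.100
) -> tuple[InputSet, InputSet]:
    """Keep variables with univariable p < threshold (strict).

    Categorical variables pass when their minimum per-level Wald p crosses
    the threshold.  Returns (full input, clinicopathological input); the
    clinicopathological input is the clinicopathological subset of the full
    input.
    """
    kept = [r.variable for r in results if r.min_p < threshold]
    clin = [
        r.variable
        for r in results
        if r.min_p < threshold and r.provenance == "clinicopathological"
    ]
    return InputSet("full", kept), InputSet("clinicopathological", clin)


def prune_correlated(
    full: InputSet,
    data: pd.DataFrame,
    results: list[UnivariableResult],
    alpha: float = 0.05,
) -> InputSet:
    """Spearman-based pruning of the full input.

    Significantly correlated pairs (Spearman p < alpha) are visited in
    descending |rho| (ties broken by variable names, making the procedure
    deterministic).  In each pair still alive: a clinicopathological variable
    is privileged over a radiomics one (the radiomics one is dropped
    regardless of p); between two radiomics variables the one with the higher
    univariable p is dropped; clinicopathological pairs are both kept.
    """
    prov = {r.variable: r.provenance for r in results}
    pmap = {r.variable: r.min_p for r in results}
    alive = set(full.variables)
    numeric = {}
    for v in full.variables:
        col = data[v]
        if col.dtype == object or str(col.dtype) == "category":
            numeric[v] = pd.Categorical(col).codes.astype(float)
        else:
            numeric[v] = col.to_numpy(dtype=float)

    pairs = []
    for a, b in combinations(sorted(full.variables), 2):
        rho, p = spearmanr(numeric[a], numeric[b])
        if np.isfinite(p) and p < alpha:
            pairs.append((abs(rho), a, b))
    pairs.sort(key=lambda t: (-t[0], t[1], t[2]))

    for _, a, b in pairs:
        if a not in alive or b not in alive:
            continue
        pa, pb = prov.get(a, "radiomics"), prov.get(b, "radiomics")
        if pa == "clinicopathological" and pb == "clinicopathological":
            continue  # pruning only runs against radiomics features
        if pa == "clinicopathological":
            alive.discard(b)
        elif pb == "clinicopathological":
            alive.discard(a)
        else:
            # drop the radiomics variable with the higher univariable p
            alive.discard(a if pmap[a] > pmap[b] else b)
    ordered = [v for v in full.variables if v in alive]
    return InputSet("uncorrelated", ordered)


def results_to_frame(results: list[UnivariableResult]) -> pd.DataFrame:
    """Univariable results in a report-table shape (one row per level)."""
    rows = []
    for r in results:
        if r.levels:
            for lv in r.levels:
                rows.append(
                    {
                        "variable": r.variable,
                        "level": lv["level"],
                        "hr": lv["hr"],
                        "ci_low": lv["ci_low"],
                        "ci_high": lv["ci_high"],
                        "wald_p": lv["p"],
                        "logrank_p": r.logrank_p,
                        "provenance": r.provenance,
                    }
                )
        else:
            rows.append(
                {
                    "variable": r.variable,
                    "level": "",
                    "hr": r.hr,
                    "ci_low": r.ci_low,
                    "ci_high": r.ci_high,
                    "wald_p": r.p,
                    "logrank_p": np.nan,
                    "provenance": r.provenance,
                }
            )
    return pd.DataFrame(rows)
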