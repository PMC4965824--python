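"""Facies-level univariate statistics and richness model selection.

Covers the rank-based group comparisons (Kruskal-Wallis with its
post-hoc multi-comparison on mean ranks), ordinary least squares
regressions against elevation, and AICc-based forward selection of a
parsimonious multiple-regression model for OTU richness.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .io import ValidationError


@dataclass(frozen=True)
class KruskalResult:
    """Tie-corrected Kruskal-Wallis omnibus test."""

    h_statistic: float
    df: int
    p_value: float
    mean_ranks: dict[str, float]
    group_sizes: dict[str, int]


def _split_groups(values, group_labels):
    values = np.asarray(values, dtype=float)
    labels = np.asarray(group_labels)
    if values.shape != labels.shape:
        raise ValidationError("values and group labels must align")
    groups = {}
    for g in pd.unique(labels):
        groups[g] = values[labels == g]
    if len(groups) < 2:
        raise ValidationError("need at least 2 groups")
    for g, v in groups.items():
        if len(v) == 0:
            raise ValidationError(f"group {g!r} is empty")
    return values, labels, groups


def kruskal_wallis(values, group_labels) -> KruskalResult:
    """Kruskal-Wallis H test across groups.

    H is tie-corrected; p comes from the chi-square approximation with
    df = groups - 1. All-identical data degenerate to H = 0, p = 1.
    """
    values, labels, groups = _split_groups(values, group_labels)
    ranks = sps.rankdata(values)
    mean_ranks = {g: float(ranks[labels == g].mean()) for g in groups}
    sizes = {g: int((labels == g).sum()) for g in groups}
    if np.all(values == values[0]):
        return KruskalResult(0.0, len(groups) - 1, 1.0, mean_ranks, sizes)
    h, p = sps.kruskal(*groups.values())
    return KruskalResult(float(h), len(groups) - 1, float(p), mean_ranks, sizes)


@dataclass(frozen=True)
class PosthocResult:
    """Pairwise mean-rank comparisons after a Kruskal-Wallis omnibus."""

    comparisons: pd.DataFrame  # group_a, group_b, rank_diff, critical, significant
    alpha: float

    def significant_pairs(self) -> set[frozenset]:
        sig = self.comparisons[self.comparisons["significant"]]
        return {frozenset((a, b)) for a, b in zip(sig["group_a"], sig["group_b"])}


def posthoc_multicomp(values, group_labels, alpha: float = 0.05) -> PosthocResult:
    """Post-hoc multi-comparison on mean ranks (Siegel-Castellan).

    Pair (i, j) is significant when
    |Rbar_i - Rbar_j| > z_{1 - alpha/(g(g-1))} * sqrt(N(N+1)/12 * (1/n_i + 1/n_j)).
    """
    values, labels, groups = _split_groups(values, group_labels)
    ranks = sps.rankdata(values)
    names = list(groups)
    g = len(names)
    n_total = len(values)
    z_crit = sps.norm.ppf(1 - alpha / (g * (g - 1)))
    rows = []
    for i in range(g):
        for j in range(i + 1, g):
            a, b = names[i], names[j]
            na, nb = (labels == a).sum(), (labels == b).sum()
            diff = abs(ranks[labels == a].mean() - ranks[labels == b].mean())
            crit = z_crit * math.sqrt(
                n_total * (n_total + 1) / 12.0 * (1.0 / na + 1.0 / nb)
            )
            rows.append(
                {"group_a": a, "group_b": b, "rank_diff": float(diff),
                 "critical": float(crit), "significant": bool(diff > crit)}
            )
    return PosthocResult(comparisons=pd.DataFrame(rows), alpha=alpha)


@dataclass(frozen=True)
class OlsResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float  # two-sided t-test on the slope
    n: int


def ols_vs_elevation(values, elevations) -> OlsResult:
    """Simple OLS of a variable on elevation."""
    y = np.asarray(values, dtype=float)
    x = np.asarray(elevations, dtype=float)
    if len(y) != len(x):
        raise ValidationError("values and elevations must align")
    if len(y) < 3:
        raise ValidationError("need at least 3 observations")
    if np.ptp(x) == 0:
        raise ValidationError("zero variance in elevations")
    if np.ptp(y) == 0:  # constant response: flat fit, nothing explained
        return OlsResult(slope=0.0, intercept=float(y[0]), r_squared=0.0,
                         p_value=1.0, n=len(y))
    model = sm.OLS(y, sm.add_constant(x)).fit()
    return OlsResult(
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        r_squared=float(model.rsquared),
        p_value=float(model.pvalues[1]),
        n=len(y),
    )


def aicc(rss: float, n: int, p: int) -> float:
    """Small-sample Akaike Information Criterion for a Gaussian model.

    ``p`` counts every estimated parameter: the regression coefficients
    (including the intercept) plus one for the error variance. Additive
    constants are dropped; only AICc differences are meaningful.
    """
    if n - p - 1 <= 0:
        raise ValidationError(f"AICc undefined for n={n}, p={p} (n <= p + 1)")
    if rss <= 0:
        raise ValidationError("rss must be positive")
    return n * math.log(rss / n) + 2 * p + 2 * p * (p + 1) / (n - p - 1)


@dataclass(frozen=True)
class AiccSelectionResult:
    """Forward AICc selection path and the refit final model."""

    selected: tuple[str, ...]
    aicc_path: tuple[float, ...]  # intercept-only value first, then each step
    coefficients: dict[str, float]  # includes "intercept"
    r_squared: float
    p_value: float  # F-test of the final model (NaN for intercept-only)
    n: int
    candidates: tuple[str, ...]
    excluded_samples: tuple[str, ...]


def _fit(y: np.ndarray, X: pd.DataFrame):
    return sm.OLS(y, sm.add_constant(X, has_constant="add")).fit()


def forward_select_aicc(
    response: pd.Series, candidates: pd.DataFrame
) -> AiccSelectionResult:
    """Forward selection of a multiple-regression model by AICc.

    Complete cases only: samples missing the response or any candidate
    are excluded and reported. Starting from the intercept-only model,
    each step adds the candidate that most lowers AICc; selection stops
    when no candidate lowers it. The final model is refit by OLS.
    """
    data = candidates.copy()
    data["__response__"] = response
    complete = data.dropna()
    excluded = tuple(str(s) for s in data.index if s not in complete.index)
    y = complete["__response__"].to_numpy(dtype=float)
    X_all = complete.drop(columns="__response__")
    n = len(y)
    if n < 4:
        raise ValidationError("too few complete cases for model selection")
    rss0 = float(np.sum((y - y.mean()) ** 2))
    current_aicc = aicc(rss0, n, p=2)  # intercept + variance
    path = [current_aicc]
    selected: list[str] = []
    remaining = list(X_all.columns)
    while remaining:
        trial = {}
        scale = float(np.sum((y - y.mean()) ** 2)) or 1.0
        for name in remaining:
            cols = selected + [name]
            p = len(cols) + 2  # coefficients + intercept + variance
            if n - p - 1 <= 0:
                continue
            fit = _fit(y, X_all[cols])
            ssr = float(fit.ssr)
            # a numerically perfect fit dominates any penalty
            trial[name] = -math.inf if ssr <= 1e-12 * scale else aicc(ssr, n, p)
        if not trial:
            break
        best = min(trial, key=trial.get)
        if trial[best] >= current_aicc:
            break
        selected.append(best)
        remaining.remove(best)
        current_aicc = trial[best]
        path.append(current_aicc)
    if selected:
        fit = _fit(y, X_all[selected])
        coefs = {"intercept": float(fit.params.iloc[0])}
        coefs.update({name: float(v) for name, v in zip(selected, fit.params.iloc[1:])})
        r2 = float(fit.rsquared)
        p_val = float(fit.f_pvalue)
    else:
        coefs = {"intercept": float(y.mean())}
        r2 = 0.0
        p_val = float("nan")
    return AiccSelectionResult(
        selected=tuple(selected),
        aicc_path=tuple(path),
        coefficients=coefs,
        r_squared=r2,
        p_value=p_val,
        n=n,
        candidates=tuple(str(c) for c in X_all.columns),
        excluded_samples=excluded,
    )


def partial_regression_data(
    response: pd.Series, predictors: pd.DataFrame, variable: str
) -> tuple[np.ndarray, np.ndarray]:
    """Paired residual vectors for a partial regression (added-variable) plot.

    Residuals of the response on all retained predictors except
    ``variable``, against residuals of ``variable`` on the same set. By
    the Frisch-Waugh theorem the OLS slope between the two residual
    vectors equals the variable's multiple-regression coefficient.
    """
    if variable not in predictors.columns:
        raise ValidationError(f"{variable!r} not among the retained predictors")
    others = [c for c in predictors.columns if c != variable]
    y = response.to_numpy(dtype=float)
    v = predictors[variable].to_numpy(dtype=float)
    if others:
        X = predictors[others]
        y_res = y - _fit(y, X).fittedvalues
        v_res = v - _fit(v, X).fittedvalues
    else:
        y_res = y - y.mean()
        v_res = v - v.mean()
    return np.asarray(v_res, dtype=float), np.asarray(y_res, dtype=float)
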