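"""Group-difference and hierarchical-regression statistics.

Provides Bartlett's homogeneity test, Welch's heteroscedastic one-way
ANOVA with omega-squared, Games-Howell post hoc comparisons, a
pairwise-complete Spearman correlation matrix, and nested ("hierarchical")
robust-SE regression sequences with adjusted-R-squared increments and a
robust Wald test of each added block.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .model import INTERCEPT, FittedModel, fit_robust

__all__ = [
    "AnovaResult",
    "PairwiseResult",
    "HierarchicalStep",
    "HierarchicalResult",
    "bartlett_test",
    "welch_anova",
    "games_howell",
    "spearman_matrix",
    "hierarchical_regression",
]


# ---------------------------------------------------------------------------
# group comparisons

@dataclass
class AnovaResult:
    F: float
    df1: float
    df2: float
    p: float
    omega_sq: float


@dataclass
class PairwiseResult:
    group_a: str
    group_b: str
    mean_diff: float
    p_adj: float


def _split_groups(values, groups, min_size: int = 2):
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if values.shape[0] != groups.shape[0]:
        raise ValueError("values and groups differ in length")
    labels = list(pd.unique(groups))
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    out = {}
    for g in labels:
        x = values[groups == g]
        if x.size < min_size:
            raise ValueError(f"group {g!r} has fewer than {min_size} observations")
        out[g] = x
    return out


def bartlett_test(values, groups) -> tuple[float, int, float]:
    """Bartlett's test of homogeneity of variance.

    Returns ``(chi_sq, df, p)`` with ``df = n_groups - 1``.
    """
    by = _split_groups(values, groups)
    stat, p = sps.bartlett(*by.values())
    return float(stat), len(by) - 1, float(p)


def welch_anova(values, groups) -> AnovaResult:
    """Welch's heteroscedastic one-way ANOVA.

    Statistic and Welch-Satterthwaite df2 follow the standard
    weighted-means formulas; the effect size is
    ``omega_sq = df1*(F-1) / (df1*(F-1) + N)``.
    """
    by = _split_groups(values, groups)
    g = len(by)
    ns = np.array([x.size for x in by.values()], dtype=float)
    means = np.array([x.mean() for x in by.values()])
    vars_ = np.array([x.var(ddof=1) for x in by.values()])
    if np.any(vars_ == 0):
        raise ValueError("a group has zero variance")
    w = ns / vars_
    W = w.sum()
    grand = float((w * means).sum() / W)
    A = float((w * (means - grand) ** 2).sum()) / (g - 1)
    lam = float(((1.0 - w / W) ** 2 / (ns - 1)).sum())
    B = 1.0 + 2.0 * (g - 2) / (g * g - 1.0) * lam
    F = A / B
    df1 = g - 1
    df2 = (g * g - 1.0) / (3.0 * lam)
    p = float(sps.f.sf(F, df1, df2))
    N = float(ns.sum())
    omega = df1 * (F - 1.0) / (df1 * (F - 1.0) + N)
    return AnovaResult(F=float(F), df1=float(df1), df2=float(df2), p=p,
                       omega_sq=float(omega))


def games_howell(values, groups) -> list[PairwiseResult]:
    """Games-Howell post hoc tests for all unordered group pairs.

    Each pair uses a Welch t statistic with Welch-Satterthwaite df and a
    studentized-range p-value with the full number of group means.
    """
    by = _split_groups(values, groups)
    labels = list(by)
    k = len(labels)
    out: list[PairwiseResult] = []
    for a, b in combinations(labels, 2):
        xa, xb = by[a], by[b]
        na, nb = xa.size, xb.size
        va, vb = xa.var(ddof=1), xb.var(ddof=1)
        se2 = va / na + vb / nb
        diff = float(xa.mean() - xb.mean())
        t = diff / np.sqrt(se2)
        df = se2 ** 2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
        q = abs(t) * np.sqrt(2.0)
        p = float(sps.studentized_range.sf(q, k, df))
        out.append(PairwiseResult(group_a=str(a), group_b=str(b),
                                  mean_diff=diff, p_adj=min(max(p, 0.0), 1.0)))
    return out


# ---------------------------------------------------------------------------
# correlations

def spearman_matrix(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise-complete Spearman correlation matrix with p-values.

    Ties get average ranks. Pairs with a constant variable (undefined
    correlation) or fewer than 3 complete rows are flagged as NaN.
    Returns ``(rho, pvals)`` as DataFrames indexed by column name.
    """
    cols = list(table.columns)
    m = len(cols)
    rho = np.full((m, m), np.nan)
    pv = np.full((m, m), np.nan)
    for i in range(m):
        rho[i, i] = 1.0
        pv[i, i] = 0.0
        for j in range(i + 1, m):
            pair = table.iloc[:, [i, j]].dropna()
            if len(pair) < 3:
                continue
            x = pair.iloc[:, 0].to_numpy(float)
            y = pair.iloc[:, 1].to_numpy(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            r, p = sps.spearmanr(x, y)
            rho[i, j] = rho[j, i] = r
            pv[i, j] = pv[j, i] = p
    return (pd.DataFrame(rho, index=cols, columns=cols),
            pd.DataFrame(pv, index=cols, columns=cols))


# ---------------------------------------------------------------------------
# hierarchical regression

@dataclass
class HierarchicalStep:
    label: str
    added_terms: list[str]
    model: FittedModel
    adjusted_r2: float
    delta_r2: Optional[float]
    p_block: Optional[float]

    def table(self):
        return self.model.table()


@dataclass
class HierarchicalResult:
    dv: str
    steps: list[HierarchicalStep] = field(default_factory=list)

    @property
    def final_model(self) -> FittedModel:
        return self.steps[-1].model


def _expand_terms(data: pd.DataFrame, terms: Sequence[str],
                  reference_levels: dict[str, str],
                  centered: dict[str, np.ndarray],
                  *, center: bool) -> list[tuple[str, np.ndarray]]:
    """Resolve term names into design columns.

    Numeric terms are mean-centred (when ``center``); categorical terms
    expand into treatment dummies against the stated reference level;
    ``a:b`` builds the product of the two centred numeric columns.
    """
    cols: list[tuple[str, np.ndarray]] = []

    def centred(name: str) -> np.ndarray:
        if name not in centered:
            if name not in data.columns:
                raise KeyError(f"term {name!r} not found in data")
            v = data[name].to_numpy(dtype=float)
            centered[name] = v - v.mean() if center else v
        return centered[name]

    for term in terms:
        if ":" in term:
            a, b = (s.strip() for s in term.split(":", 1))
            cols.append((f"{a}:{b}", centred(a) * centred(b)))
        elif term in data.columns and not pd.api.types.is_numeric_dtype(data[term]):
            levels = list(pd.unique(data[term].astype(str)))
            ref = reference_levels.get(term)
            if ref is None:
                ref = sorted(levels)[0]
            elif ref not in levels:
                raise ValueError(f"reference level {ref!r} not in {term!r}")
            vals = data[term].astype(str).to_numpy()
            for lev in [l for l in levels if l != ref]:
                cols.append((f"{term}[{lev}]", (vals == lev).astype(float)))
        else:
            cols.append((term, centred(term)))
    return cols


def _robust_wald_block(model: FittedModel, block_terms: Sequence[str]
                       ) -> float:
    """Robust Wald F test that all coefficients in ``block_terms`` are 0."""
    idx = [model.terms.index(t) for t in block_terms]
    b = model.beta[idx]
    V = model.cov[np.ix_(idx, idx)]
    try:
        stat = float(b @ np.linalg.solve(V, b))
    except np.linalg.LinAlgError:
        return float("nan")
    q = len(idx)
    Fstat = stat / q
    return float(sps.f.sf(Fstat, q, model.df_resid))


def hierarchical_regression(data: pd.DataFrame, dv: str,
                            step_terms: Sequence[tuple[str, Sequence[str]]],
                            hc_flavor: str = "HC2",
                            reference_levels: Optional[dict[str, str]] = None,
                            *, center: bool = True) -> HierarchicalResult:
    """Fit a nested sequence of robust-SE regressions.

    ``step_terms`` is an ordered list of ``(label, [terms])``; each step's
    model contains all previous terms plus the new block. Continuous
    predictors are mean-centred before interaction products are built.
    Reports per-step adjusted R-squared, its increment over the previous
    step (which may be negative), and a robust Wald p-value for the added
    block.
    """
    if dv not in data.columns:
        raise KeyError(f"dependent variable {dv!r} not in data")
    if not step_terms:
        raise ValueError("no steps specified")
    reference_levels = reference_levels or {}
    y = data[dv].to_numpy(dtype=float)
    centered: dict[str, np.ndarray] = {}

    result = HierarchicalResult(dv=dv)
    design: list[tuple[str, np.ndarray]] = []
    seen: set[str] = set()
    prev_adj: Optional[float] = None
    for label, terms in step_terms:
        new_cols = _expand_terms(data, terms, reference_levels, centered,
                                 center=center)
        added = []
        for nm, col in new_cols:
            if nm in seen:
                raise ValueError(f"step {label!r} re-adds term {nm!r}; "
                                 "steps must be strictly nested")
            seen.add(nm)
            design.append((nm, col))
            added.append(nm)
        X = np.column_stack([c for _, c in design])
        names = [nm for nm, _ in design]
        model = fit_robust(X, y, names, hc_flavor=hc_flavor)
        delta = None if prev_adj is None else model.adjusted_r2 - prev_adj
        p_block = _robust_wald_block(model, added) if added else None
        result.steps.append(HierarchicalStep(
            label=label, added_terms=added, model=model,
            adjusted_r2=model.adjusted_r2, delta_r2=delta, p_block=p_block))
        prev_adj = model.adjusted_r2
    return result
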