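"""Three-step typicality modelling: predictor screening, best-subset
search, repeated k-fold cross-validated model selection, and a final
linear fit with heteroscedasticity-consistent (sandwich) standard errors.
Per-word form typicality is the z-scored fitted value of the selected
model over the whole lexicon.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
from scipy import linalg as sla
from scipy import stats as sps

from .phonology import PhonemeInventory, WordEntry, encode_lexicon

__all__ = [
    "ScreenReport",
    "CandidateModel",
    "SelectionResult",
    "FittedModel",
    "TypicalityScores",
    "TypicalityConfig",
    "TypicalityRun",
    "screen_predictors",
    "best_subsets",
    "cv_select",
    "fit_robust",
    "typicality_scores",
    "run_typicality",
]

INTERCEPT = "(Intercept)"


# ---------------------------------------------------------------------------
# screening

@dataclass
class ScreenReport:
    kept_columns: list[str]
    dropped_zero_variance: list[str]
    dropped_linear_combo: list[str]

    @property
    def kept_indices(self) -> list[int]:
        return self._kept_indices

    _kept_indices: list[int] = field(default_factory=list, repr=False)


def screen_predictors(X: np.ndarray, names: Optional[Sequence[str]] = None,
                      tol: float = 1e-7, *, include_intercept: bool = True
                      ) -> ScreenReport:
    """Drop zero-variance columns, then columns that are (numerically)
    linear combinations of earlier kept columns.

    Dependency detection is a greedy Gram-Schmidt sweep in column order,
    so earlier columns are preferred for retention. When
    ``include_intercept`` is true the constant vector seeds the basis, so
    indicator sets that sum to a constant lose exactly one member.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D")
    if np.isnan(X).any():
        raise ValueError("X contains missing values")
    n, p = X.shape
    if names is None:
        names = [f"x{j}" for j in range(p)]
    names = list(names)
    if len(names) != p:
        raise ValueError("names length does not match number of columns")

    zero_var = [j for j in range(p) if np.ptp(X[:, j]) == 0.0]
    if len(zero_var) == p:
        raise ValueError("all columns are constant")

    basis: list[np.ndarray] = []
    if include_intercept:
        basis.append(np.full(n, 1.0 / np.sqrt(n)))
    kept_idx: list[int] = []
    combo: list[int] = []
    zv = set(zero_var)
    for j in range(p):
        if j in zv:
            continue
        c = X[:, j].astype(float)
        norm0 = np.linalg.norm(c)
        r = c.copy()
        for q in basis:
            r -= q @ c * q
        # second orthogonalization pass for numerical safety
        for q in basis:
            r -= q @ r * q
        if np.linalg.norm(r) <= tol * max(norm0, 1.0):
            combo.append(j)
        else:
            kept_idx.append(j)
            basis.append(r / np.linalg.norm(r))

    report = ScreenReport(
        kept_columns=[names[j] for j in kept_idx],
        dropped_zero_variance=[names[j] for j in zero_var],
        dropped_linear_combo=[names[j] for j in combo],
    )
    report._kept_indices = kept_idx
    return report


# ---------------------------------------------------------------------------
# best-subset search

@dataclass(frozen=True)
class CandidateModel:
    """Best size-k predictor subset with its residual sum of squares."""

    size: int
    columns: tuple[str, ...]
    rss: float
    exact: bool = True


def _subset_rss(G: np.ndarray, c: np.ndarray, yty: float, idx: Sequence[int]) -> float:
    """RSS of the OLS fit on centred data restricted to columns ``idx``."""
    idx = list(idx)
    try:
        b = sla.solve(G[np.ix_(idx, idx)], c[idx], assume_a="pos")
    except (np.linalg.LinAlgError, sla.LinAlgError):
        b = np.linalg.lstsq(G[np.ix_(idx, idx)], c[idx], rcond=None)[0]
    return max(yty - float(c[idx] @ b), 0.0)


def best_subsets(X: np.ndarray, y: np.ndarray, kmax: int,
                 names: Optional[Sequence[str]] = None,
                 *, exact_limit: int = 15) -> list[CandidateModel]:
    """One best (minimum-RSS) subset per size 1..kmax, intercept implied.

    For ``p <= exact_limit`` every subset is enumerated (exact winners).
    Beyond that a forward/backward stepwise hybrid is used and the
    ``exact`` flag on the returned candidates is False.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if names is None:
        names = [f"x{j}" for j in range(p)]
    names = list(names)
    if kmax < 1:
        raise ValueError("kmax must be >= 1")
    kmax = min(kmax, p)
    if n <= kmax:
        raise ValueError("n must exceed kmax")

    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    G = Xc.T @ Xc
    c = Xc.T @ yc
    yty = float(yc @ yc)

    if p <= exact_limit:
        best: dict[int, tuple[float, tuple[int, ...]]] = {}
        for k in range(1, kmax + 1):
            for idx in combinations(range(p), k):
                rss = _subset_rss(G, c, yty, idx)
                if k not in best or rss < best[k][0] - 0.0:
                    best[k] = (rss, idx)
        return [CandidateModel(k, tuple(names[j] for j in best[k][1]),
                               best[k][0], exact=True)
                for k in range(1, kmax + 1)]

    # forward path
    fwd: dict[int, tuple[float, tuple[int, ...]]] = {}
    current: list[int] = []
    remaining = set(range(p))
    for k in range(1, kmax + 1):
        scored = [(_subset_rss(G, c, yty, current + [j]), j) for j in remaining]
        rss, j = min(scored)
        current.append(j)
        remaining.discard(j)
        fwd[k] = (rss, tuple(current))
    # backward path from the full model
    bwd: dict[int, tuple[float, tuple[int, ...]]] = {}
    cur = list(range(p))
    rss_full = _subset_rss(G, c, yty, cur)
    if p <= kmax:
        bwd[p] = (rss_full, tuple(cur))
    while len(cur) > 1:
        scored = [(_subset_rss(G, c, yty, [i for i in cur if i != j]), j) for j in cur]
        rss, j = min(scored)
        cur.remove(j)
        if len(cur) <= kmax:
            bwd[len(cur)] = (rss, tuple(cur))

    out: list[CandidateModel] = []
    for k in range(1, kmax + 1):
        pick = min((d[k] for d in (fwd, bwd) if k in d), key=lambda t: t[0])
        out.append(CandidateModel(k, tuple(names[j] for j in sorted(pick[1])),
                                  pick[0], exact=False))
    return out


# ---------------------------------------------------------------------------
# cross-validated selection

@dataclass
class SelectionResult:
    chosen: CandidateModel
    cv_rmse_by_size: dict[int, tuple[float, float]]
    folds: int
    repeats: int
    seed: int
    selection_rule: str = "best"


def _forward_sets_by_size(G: np.ndarray, c: np.ndarray, cols: Sequence[int],
                          sizes: Sequence[int]) -> dict[int, list[int]]:
    """Greedy forward-selection path on a Gram system with the intercept
    (index 0) always included; returns selected index lists per size."""
    current = [0]
    remaining = list(cols)
    out: dict[int, list[int]] = {}
    kmax = max(sizes)
    want = set(sizes)
    for k in range(1, kmax + 1):
        best = None
        for j in remaining:
            idx = current + [j]
            try:
                b = sla.solve(G[np.ix_(idx, idx)], c[idx], assume_a="pos")
            except (np.linalg.LinAlgError, sla.LinAlgError):
                continue
            rss = -float(c[idx] @ b)  # yty constant; minimise -explained
            if best is None or rss < best[0]:
                best = (rss, j)
        if best is None:
            break
        current = current + [best[1]]
        remaining.remove(best[1])
        if k in want:
            out[k] = list(current)
    return out


def cv_select(X: np.ndarray, y: np.ndarray, candidates: Sequence[CandidateModel],
              names: Optional[Sequence[str]] = None, folds: int = 10,
              repeats: int = 200, seed: int = 0, *, tie_tol: float = 1e-12,
              reselect_within_folds: bool = True,
              selection_rule: str = "best") -> SelectionResult:
    """Pick the subset size minimising mean held-out RMSE over
    ``folds x repeats`` random partitions; ties go to the smaller model.

    Folds are simple random near-equal partitions, re-randomised on every
    repeat. By default the subset search itself is re-run (greedy forward
    path) inside every training fold, so held-out errors are free of
    full-data selection leakage; the returned ``chosen`` model is the
    full-data candidate of the winning size. With
    ``reselect_within_folds=False`` the fixed candidate column sets are
    refit (OLS with intercept) inside each training fold instead.

    ``selection_rule='best'`` takes the argmin of the mean RMSE;
    ``'one_se'`` takes the smallest model whose mean RMSE is within one
    standard error (of the minimiser's mean) of the minimum — the usual
    parsimony rule for flat CV curves. Deterministic given ``seed``.
    """
    if selection_rule not in ("best", "one_se"):
        raise ValueError("selection_rule must be 'best' or 'one_se'")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if not candidates:
        raise ValueError("no candidate models")
    if n < 2 * folds:
        raise ValueError("need n >= 2*folds")
    if names is None:
        names = [f"x{j}" for j in range(p)]
    pos = {nm: j for j, nm in enumerate(names)}
    idx_sets = []
    for cand in candidates:
        try:
            idx_sets.append([0] + [pos[c] + 1 for c in cand.columns])
        except KeyError as exc:
            raise KeyError(f"candidate column {exc} not found in names") from None

    A = np.column_stack([np.ones(n), X])
    G_full = A.T @ A
    c_full = A.T @ y

    min_fold = n // folds
    for cand, cols in zip(candidates, idx_sets):
        if min_fold < 1 or (n - (n // folds + 1)) <= len(cols):
            raise ValueError(f"folds too small for candidate of size {cand.size}")

    sizes = [cand.size for cand in candidates]
    all_cols = list(range(1, p + 1))
    rng = np.random.default_rng(seed)
    sums = np.zeros(len(candidates))
    sqsums = np.zeros(len(candidates))
    count = 0
    for _ in range(repeats):
        perm = rng.permutation(n)
        bounds = np.linspace(0, n, folds + 1).astype(int)
        for f in range(folds):
            te = perm[bounds[f]:bounds[f + 1]]
            A_te = A[te]
            y_te = y[te]
            G_tr = G_full - A_te.T @ A_te
            c_tr = c_full - A_te.T @ y_te
            if reselect_within_folds:
                per_size = _forward_sets_by_size(G_tr, c_tr, all_cols, sizes)
                fold_sets = [per_size.get(s) for s in sizes]
            else:
                fold_sets = idx_sets
            for ci, cols in enumerate(fold_sets):
                if cols is None:
                    cols = idx_sets[ci]
                try:
                    b = sla.solve(G_tr[np.ix_(cols, cols)], c_tr[cols],
                                  assume_a="pos")
                except (np.linalg.LinAlgError, sla.LinAlgError):
                    b = np.linalg.lstsq(G_tr[np.ix_(cols, cols)], c_tr[cols],
                                        rcond=None)[0]
                resid = y_te - A_te[:, cols] @ b
                rmse = float(np.sqrt(np.mean(resid ** 2)))
                sums[ci] += rmse
                sqsums[ci] += rmse * rmse
            count += 1

    means = sums / count
    sds = np.sqrt(np.maximum(sqsums / count - means ** 2, 0.0))
    # argmin with parsimony tie-break: smaller size wins within tie_tol
    best_ci = 0
    for ci in range(1, len(candidates)):
        if means[ci] < means[best_ci] - tie_tol:
            best_ci = ci
        elif abs(means[ci] - means[best_ci]) <= tie_tol and \
                candidates[ci].size < candidates[best_ci].size:
            best_ci = ci
    if selection_rule == "one_se":
        threshold = means[best_ci] + sds[best_ci] / np.sqrt(count)
        eligible = [ci for ci in range(len(candidates))
                    if means[ci] <= threshold]
        best_ci = min(eligible, key=lambda ci: candidates[ci].size)
    by_size = {cand.size: (float(means[ci]), float(sds[ci]))
               for ci, cand in enumerate(candidates)}
    return SelectionResult(chosen=candidates[best_ci], cv_rmse_by_size=by_size,
                           folds=folds, repeats=repeats, seed=seed,
                           selection_rule=selection_rule)


# ---------------------------------------------------------------------------
# robust fit

@dataclass
class FittedModel:
    """OLS fit with heteroscedasticity-consistent standard errors."""

    terms: list[str]            # includes "(Intercept)" first
    beta: np.ndarray
    robust_se: np.ndarray
    t: np.ndarray
    p: np.ndarray
    adjusted_r2: float
    r2: float
    hc_flavor: str
    n: int
    df_resid: int
    cov: np.ndarray = field(repr=False, default=None)

    def predict(self, X: np.ndarray, names: Sequence[str]) -> np.ndarray:
        """Fitted values for new data holding the model's term columns."""
        X = np.asarray(X, dtype=float)
        pos = {nm: j for j, nm in enumerate(names)}
        cols = [pos[t] for t in self.terms[1:]]
        return self.beta[0] + X[:, cols] @ self.beta[1:]

    def table(self):
        """Coefficient table (term, estimate, std_error, t, p) as records."""
        return [
            {"term": t, "estimate": float(b), "std_error": float(se),
             "t": float(tv), "p": float(pv)}
            for t, b, se, tv, pv in zip(self.terms, self.beta, self.robust_se,
                                        self.t, self.p)
        ]


_HC_FLAVORS = ("HC0", "HC1", "HC2", "HC3")


def fit_robust(X: np.ndarray, y: np.ndarray,
               names: Optional[Sequence[str]] = None,
               hc_flavor: str = "HC2", *, add_intercept: bool = True
               ) -> FittedModel:
    """OLS coefficients with an HC0-HC3 sandwich covariance.

    t statistics use the requested robust SEs with n - p - 1 residual
    degrees of freedom (p excluding the intercept).
    """
    if hc_flavor not in _HC_FLAVORS:
        raise ValueError(f"hc_flavor must be one of {_HC_FLAVORS}")
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if names is None:
        names = [f"x{j}" for j in range(p)]
    names = list(names)
    if add_intercept:
        A = np.column_stack([np.ones(n), X])
        terms = [INTERCEPT] + names
    else:
        A = X
        terms = names
    k = A.shape[1]
    if n <= k:
        raise ValueError(f"n={n} too small for {k} coefficients")
    if np.linalg.matrix_rank(A) < k:
        raise ValueError("design matrix is rank deficient")

    AtA_inv = np.linalg.inv(A.T @ A)
    beta = AtA_inv @ (A.T @ y)
    resid = y - A @ beta
    h = np.einsum("ij,jk,ik->i", A, AtA_inv, A)
    e2 = resid ** 2
    if hc_flavor == "HC0":
        w = e2
    elif hc_flavor == "HC1":
        w = e2 * n / (n - k)
    elif hc_flavor == "HC2":
        w = e2 / np.clip(1.0 - h, 1e-12, None)
    else:  # HC3
        w = e2 / np.clip(1.0 - h, 1e-12, None) ** 2
    meat = (A * w[:, None]).T @ A
    cov = AtA_inv @ meat @ AtA_inv
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))

    df_resid = n - k
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, np.nan)
    pvals = np.where(np.isnan(t), np.nan,
                     2.0 * sps.t.sf(np.abs(np.nan_to_num(t)), df_resid))

    if add_intercept:
        tss = float(np.sum((y - y.mean()) ** 2))
    else:
        tss = float(y @ y)
    rss = float(resid @ resid)
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    adj = 1.0 - (1.0 - r2) * (n - 1) / df_resid

    return FittedModel(terms=terms, beta=beta, robust_se=se, t=t, p=pvals,
                       adjusted_r2=adj, r2=r2, hc_flavor=hc_flavor, n=n,
                       df_resid=df_resid, cov=cov)


# ---------------------------------------------------------------------------
# typicality scores

@dataclass
class TypicalityScores:
    """Per-word fitted values and their z-transform (mean 0, SD 1)."""

    fitted: np.ndarray
    z: np.ndarray


def typicality_scores(model: FittedModel, X: np.ndarray,
                      names: Sequence[str]) -> TypicalityScores:
    """Z-scored fitted values of ``model`` over the full form matrix.

    Standardisation uses the sample SD (n - 1 denominator); raises when
    the fitted values have zero variance.
    """
    fitted = model.predict(X, names)
    sd = float(np.std(fitted, ddof=1))
    scale = max(1.0, float(np.abs(fitted).max(initial=0.0)))
    if not np.isfinite(sd) or sd <= 1e-12 * scale:
        raise ValueError("fitted values have zero variance; cannot z-score")
    z = (fitted - fitted.mean()) / sd
    return TypicalityScores(fitted=fitted, z=z)


# ---------------------------------------------------------------------------
# driver

@dataclass
class TypicalityConfig:
    folds: int = 10
    repeats: int = 200
    seed: int = 0
    kmax: int = 40
    exact_limit: int = 15
    hc_flavor: str = "HC2"
    screen_tol: float = 1e-7
    voicing_includes_vowels: bool = False
    selection_rule: str = "best"

    def to_dict(self) -> dict:
        return dict(self.__dict__)

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class TypicalityRun:
    dv: str
    screen: ScreenReport
    candidates: list[CandidateModel]
    selection: SelectionResult
    model: FittedModel
    scores: TypicalityScores
    manifest: dict


_DVS = ("valence", "emotionality", "arousal")


def _dv_values(entries: Sequence[WordEntry], dv: str) -> np.ndarray:
    if dv == "valence":
        return np.array([e.ratings.valence_mean for e in entries])
    if dv == "arousal":
        return np.array([e.ratings.arousal_mean for e in entries])
    if dv == "emotionality":
        return np.array([e.ratings.emotionality for e in entries])
    raise ValueError(f"unknown dv {dv!r}; expected one of {_DVS}")


def run_typicality(entries: Sequence[WordEntry], inventory: PhonemeInventory,
                   dv: str, config: TypicalityConfig | None = None
                   ) -> TypicalityRun:
    """Full per-DV pipeline on an already-filtered lexicon:
    encode -> screen -> best subsets -> CV selection -> robust fit ->
    typicality scores, with a reproducibility manifest."""
    config = config or TypicalityConfig()
    entries = list(entries)
    y = _dv_values(entries, dv)
    X_all, all_names = encode_lexicon(
        entries, inventory,
        voicing_includes_vowels=config.voicing_includes_vowels)

    screen = screen_predictors(X_all, all_names, tol=config.screen_tol)
    X = X_all[:, screen.kept_indices]
    names = screen.kept_columns

    kmax = min(config.kmax, len(names))
    candidates = best_subsets(X, y, kmax, names,
                              exact_limit=config.exact_limit)
    selection = cv_select(X, y, candidates, names, folds=config.folds,
                          repeats=config.repeats, seed=config.seed,
                          selection_rule=config.selection_rule)
    pos = {nm: j for j, nm in enumerate(names)}
    sel_idx = [pos[c] for c in selection.chosen.columns]
    model = fit_robust(X[:, sel_idx], y, list(selection.chosen.columns),
                       hc_flavor=config.hc_flavor)
    scores = typicality_scores(model, X, names)

    manifest = {
        "dv": dv,
        "seed": config.seed,
        "config_hash": config.hash(),
        "config": config.to_dict(),
        "inventory_id": inventory.inventory_id,
        "n_words": len(entries),
        "n_form_variables": len(all_names),
        "n_kept_predictors": len(names),
        "search_exact": all(c.exact for c in candidates),
        "chosen_size": selection.chosen.size,
        "chosen_columns": list(selection.chosen.columns),
        "adjusted_r2": model.adjusted_r2,
    }
    return TypicalityRun(dv=dv, screen=screen, candidates=candidates,
                         selection=selection, model=model, scores=scores,
                         manifest=manifest)
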