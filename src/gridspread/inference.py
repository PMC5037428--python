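"""Non-spatial inference: univariate screening, collinearity checks,
and multi-predictor OLS with transforms, standardization and
backward-AIC selection.

The regression convention follows the richness analysis this package
supports: the response (a species count per coarse cell) stays on its
raw scale; selected skewed predictors are log(x+1) transformed (for the
LGM precipitation anomaly, on absolute values); a second-order
polynomial can be attached to a term; and every design column —
including polynomial columns — is z-scored so fitted coefficients are
standardized effect sizes. Polynomial columns are built from the
transformed, centred base column before squaring, then standardized;
backward selection respects the hierarchy (the squared column leaves
before its base).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from itertools import chain, combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "TermSpec",
    "ModelSpec",
    "FitResult",
    "spearman",
    "variance_partition",
    "VariancePartition",
    "vif",
    "collinearity_screen",
    "ScreenResult",
    "ols_fit",
    "aic_backward",
    "partial_residuals",
]

TRANSFORMS = ("none", "log1p", "log1p_abs")


@dataclass(frozen=True)
class TermSpec:
    """One model term: a table column, its transform, and its degree."""

    name: str
    transform: str = "none"
    degree: int = 1

    def __post_init__(self) -> None:
        if self.transform not in TRANSFORMS:
            raise ValueError(f"unknown transform {self.transform!r}")
        if self.degree < 1:
            raise ValueError("degree must be >= 1")


@dataclass(frozen=True)
class ModelSpec:
    """Response name, term list, and whether predictors are z-scored."""

    response: str
    terms: tuple[TermSpec, ...]
    standardize: bool = True

    def __post_init__(self) -> None:
        terms = tuple(
            t if isinstance(t, TermSpec) else TermSpec(t) for t in self.terms
        )
        names = [t.name for t in terms]
        if len(set(names)) != len(names):
            raise ValueError("duplicate term names in model spec")
        object.__setattr__(self, "terms", terms)

    def drop(self, name: str) -> "ModelSpec":
        """Spec with one term removed, or its polynomial degree reduced."""
        new_terms = []
        for t in self.terms:
            if t.name != name:
                new_terms.append(t)
            elif t.degree > 1:
                new_terms.append(replace(t, degree=t.degree - 1))
        return replace(self, terms=tuple(new_terms))


@dataclass
class FitResult:
    """Fitted least-squares model with the pieces downstream stages need."""

    spec: ModelSpec
    params: pd.Series          # coefficients on the (standardized) design scale
    pvalues: pd.Series
    bse: pd.Series
    raw_params: pd.Series      # back-scaled to the transformed-predictor scale
    residuals: pd.Series
    fitted: pd.Series
    design: pd.DataFrame       # standardized design columns (no intercept)
    response: pd.Series
    r2: float
    aic: float
    n: int
    scale_info: pd.DataFrame   # per-column mean/sd used for standardization

    @property
    def term_names(self) -> list[str]:
        return list(self.design.columns)


def _apply_transform(x: np.ndarray, transform: str) -> np.ndarray:
    if transform == "none":
        return x
    if transform == "log1p":
        return np.log1p(x)
    if transform == "log1p_abs":
        # sign is not restored: the transform measures anomaly magnitude
        return np.log1p(np.abs(x))
    raise ValueError(f"unknown transform {transform!r}")


def build_design(
    table: pd.DataFrame, spec: ModelSpec
) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame]:
    """Design matrix, response, and the centering/scaling bookkeeping.

    Complete cases only: rows missing the response or any term column
    are excluded. Column order is term order, with each polynomial
    column (named ``term^k``) immediately after its base.
    """
    needed = [spec.response] + [t.name for t in spec.terms]
    missing_cols = [c for c in needed if c not in table.columns]
    if missing_cols:
        raise KeyError(f"columns absent from the table: {missing_cols}")
    data = table[needed].dropna()
    y = data[spec.response].astype(float)
    cols: dict[str, np.ndarray] = {}
    info_rows = []
    for term in spec.terms:
        x = _apply_transform(data[term.name].to_numpy(dtype=float), term.transform)
        centred = x - x.mean()
        for k in range(1, term.degree + 1):
            col = centred**k
            mu, sd = col.mean(), col.std(ddof=0)
            name = term.name if k == 1 else f"{term.name}^{k}"
            if spec.standardize:
                if sd == 0:
                    raise ValueError(f"column {name!r} is constant after transform")
                cols[name] = (col - mu) / sd
            else:
                cols[name] = col - mu
            info_rows.append({"column": name, "base": term.name, "mean": mu, "sd": sd})
    X = pd.DataFrame(cols, index=data.index)
    info = pd.DataFrame(info_rows).set_index("column")
    return X, y, info


def spearman(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman rank correlation (mid-ranks for ties) with the
    large-sample t approximation for the p-value."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError("x and y differ in length")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError("need at least 3 paired finite observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Spearman correlation undefined for a constant vector")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def _ols_r2(y: np.ndarray, X: np.ndarray) -> float:
    """R^2 of an intercept-included least-squares fit (lstsq; handles
    rank deficiency by fitting on the column space)."""
    design = np.column_stack([np.ones(len(y)), X]) if X.size else np.ones((len(y), 1))
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    tss = np.sum((y - y.mean()) ** 2)
    return float(1.0 - np.sum(resid**2) / tss)


@dataclass
class VariancePartition:
    """All-subset R^2 values over predictor groups plus derived fractions."""

    groups: tuple[str, ...]
    subset_r2: dict[frozenset, float]
    unique: dict[str, float]
    full_r2: float

    @property
    def shared(self) -> float:
        """Jointly explained variance not unique to any single group."""
        return self.full_r2 - sum(self.unique.values())


def variance_partition(
    y: np.ndarray,
    groups: Mapping[str, Sequence[str]],
    table: pd.DataFrame,
) -> VariancePartition:
    """Partition explained variance of ``y`` across predictor groups.

    Fits OLS on every union of groups; the unique fraction of group g is
    R^2(all) - R^2(all minus g), and the full set of subset R^2 values is
    returned so any shared component can be derived.
    """
    if not groups:
        raise ValueError("at least one predictor group is required")
    y = np.asarray(y, dtype=float).ravel()
    cols = {g: [table[c].to_numpy(dtype=float) for c in members] for g, members in groups.items()}
    stacked = np.column_stack(
        [np.asarray(y)] + [c for members in cols.values() for c in members]
    )
    ok = np.all(np.isfinite(stacked), axis=1)
    y = y[ok]
    cols = {g: [c[ok] for c in members] for g, members in cols.items()}
    names = tuple(groups)
    subset_r2: dict[frozenset, float] = {}
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            X = np.column_stack(list(chain.from_iterable(cols[g] for g in combo)))
            if np.linalg.matrix_rank(np.column_stack([np.ones(len(y)), X])) < X.shape[1] + 1:
                warnings.warn(
                    f"rank-deficient subset {combo}; R^2 computed on its column space",
                    stacklevel=2,
                )
            subset_r2[frozenset(combo)] = _ols_r2(y, X)
    full = subset_r2[frozenset(names)]
    unique = {
        g: full - (subset_r2[frozenset(set(names) - {g})] if len(names) > 1 else 0.0)
        for g in names
    }
    return VariancePartition(groups=names, subset_r2=subset_r2, unique=unique, full_r2=full)


def vif(table: pd.DataFrame, terms: Sequence[str]) -> pd.Series:
    """Variance inflation factors: VIF_j = 1/(1 - R^2_j) from regressing
    each term on the others (plus intercept); infinite when collinear."""
    terms = list(terms)
    if len(terms) < 2:
        raise ValueError("VIF needs at least two terms")
    data = table[terms].dropna().to_numpy(dtype=float)
    if data.shape[0] <= len(terms):
        raise ValueError("need more observations than terms")
    out = {}
    for j, name in enumerate(terms):
        others = np.delete(data, j, axis=1)
        r2 = _ols_r2(data[:, j], others)
        out[name] = np.inf if r2 >= 1 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out, name="vif")


@dataclass
class ScreenResult:
    retained: list[str]
    dropped: list[dict]  # each: {"term", "reason", "statistic", "partner"?}


def collinearity_screen(
    table: pd.DataFrame,
    terms: Sequence[str],
    r_max: float = 0.70,
    vif_max: float = 5.0,
) -> ScreenResult:
    """Iteratively drop collinear predictors.

    First, while any pair has |Spearman r| > ``r_max``, the member of
    the worst pair with the larger mean absolute correlation to all
    other retained terms is dropped (ties: the later column). Then any
    term whose VIF exceeds ``vif_max`` is dropped, worst first. Every
    drop is recorded with the offending statistic.
    """
    if r_max <= 0 or vif_max <= 0:
        raise ValueError("thresholds must be positive")
    retained = list(terms)
    dropped: list[dict] = []

    def _spearman_matrix(cols: list[str]) -> np.ndarray:
        data = table[cols].dropna().to_numpy(dtype=float)
        if len(cols) == 2:
            rho = np.array([[1.0, stats.spearmanr(data[:, 0], data[:, 1]).statistic]] * 2)
            rho[1, 0] = rho[0, 1]
        else:
            rho = np.asarray(stats.spearmanr(data).statistic)
        rho = rho.copy()
        np.fill_diagonal(rho, 0.0)
        return np.abs(rho)

    while len(retained) > 1:
        r_abs = _spearman_matrix(retained)
        i, j = np.unravel_index(np.argmax(r_abs), r_abs.shape)
        if r_abs[i, j] <= r_max:
            break
        mean_i = r_abs[i].sum() / (len(retained) - 1)
        mean_j = r_abs[j].sum() / (len(retained) - 1)
        # drop the member more entangled with everything else
        if mean_i > mean_j:
            victim, partner = i, j
        elif mean_j > mean_i:
            victim, partner = j, i
        else:
            victim, partner = max(i, j), min(i, j)
        dropped.append(
            {
                "term": retained[victim],
                "reason": "pairwise_r",
                "statistic": float(r_abs[i, j]),
                "partner": retained[partner],
            }
        )
        del retained[victim]

    while len(retained) > 1:
        v = vif(table, retained)
        worst = v.idxmax()
        if not np.isfinite(v[worst]) or v[worst] > vif_max:
            dropped.append(
                {"term": worst, "reason": "vif", "statistic": float(v[worst])}
            )
            retained.remove(worst)
        else:
            break
    if not retained:
        raise ValueError("collinearity screen dropped every term")
    return ScreenResult(retained=retained, dropped=dropped)


def _aic(n: int, rss: float, k: int) -> float:
    """Gaussian AIC without the additive constant: n ln(RSS/n) + 2(k+1),
    k = coefficients excluding the intercept."""
    return n * np.log(rss / n) + 2 * (k + 1)


def ols_fit(table: pd.DataFrame, spec: ModelSpec) -> FitResult:
    """Least-squares fit of a :class:`ModelSpec` on complete cases.

    Predictors (including polynomial columns) are transformed, centred
    and z-scored so coefficients are standardized effect sizes; the
    response stays on its raw scale. Raw-scale slopes (per unit of the
    transformed predictor) are recovered by back-scaling.
    """
    X, y, info = build_design(table, spec)
    k = X.shape[1]
    if len(y) < k + 2:
        raise ValueError("too few complete cases for the requested terms")
    design = sm.add_constant(X, has_constant="add")
    arr = design.to_numpy()
    if np.linalg.matrix_rank(arr) < arr.shape[1]:
        bad, rank = [], 1
        for idx in range(1, arr.shape[1]):  # column 0 is the constant
            r_new = np.linalg.matrix_rank(arr[:, : idx + 1])
            if r_new == rank:
                bad.append(str(design.columns[idx]))
            rank = r_new
        raise ValueError(f"singular design; offending columns: {bad}")
    res = sm.OLS(y, design).fit()
    resid = y - res.fittedvalues
    rss = float(np.sum(resid**2))
    sds = info["sd"].reindex(X.columns)
    raw = res.params.drop("const") / sds.where(sds != 0, np.nan) if spec.standardize else res.params.drop("const")
    return FitResult(
        spec=spec,
        params=res.params,
        pvalues=res.pvalues,
        bse=res.bse,
        raw_params=raw,
        residuals=resid,
        fitted=res.fittedvalues,
        design=X,
        response=y,
        r2=float(res.rsquared),
        aic=_aic(len(y), rss, k),
        n=int(len(y)),
        scale_info=info,
    )


def aic_backward(table: pd.DataFrame, spec: ModelSpec) -> FitResult:
    """Stepwise backward selection minimizing AIC.

    At each step the single drop that lowers AIC most is taken; a
    polynomial term loses its highest-order column first, and a base
    column is never removed while its square remains. Stops when no
    drop lowers AIC. Returns the fit of the selected model (with the
    visited (terms, AIC) path attached as ``selection_path``).
    """
    current = ols_fit(table, spec)
    path = [(tuple(t.name for t in spec.terms), current.aic)]
    while len(current.spec.terms) > 1:
        candidates = []
        for term in current.spec.terms:
            cand_spec = current.spec.drop(term.name)
            if not cand_spec.terms:
                continue
            candidates.append((ols_fit(table, cand_spec), term.name))
        if not candidates:
            break
        best, dropped_name = min(candidates, key=lambda c: c[0].aic)
        if best.aic < current.aic - 1e-10:
            current = best
            path.append((tuple(t.name for t in current.spec.terms), current.aic))
        else:
            break
    current.selection_path = path  # type: ignore[attr-defined]
    return current


def partial_residuals(fit: FitResult, term: str) -> np.ndarray:
    """Partial residuals for one design column: residuals plus the
    fitted coefficient times the (standardized) column. The standard
    diagnostic for non-linearity/heteroscedasticity of a single term."""
    if term not in fit.design.columns:
        raise KeyError(f"term {term!r} not in the fitted design")
    return (fit.residuals + fit.params[term] * fit.design[term]).to_numpy()
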