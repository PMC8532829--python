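"""Regression and group-comparison statistics for carcass fatness data.

Implements the analysis toolkit of the grading comparison: ordinary least
squares with R^2 and a residual-standard-error style RMSE, one-way ANOVA
across fatness-score groups with Tukey HSD (Tukey-Kramer for unequal n) and
a compact letter display, and bidirectional stepwise selection over a
candidate set of transformed variables and their interactions with the
retention rule p < 0.05.

RMSE here is the regression standard error sqrt(SSE / (n - p)) in response
units, with p the number of estimated coefficients including the intercept.
"""

from __future__ import annotations

import itertools
import math
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import studentized_range

__all__ = [
    "RegressionFit",
    "AnovaResult",
    "FeatureSpec",
    "ols_fit",
    "one_way_anova",
    "tukey_hsd",
    "build_feature_set",
    "stepwise_select",
    "predict_cutting_fat",
]

TRANSFORMS = ("identity", "square", "log10", "ln")


@dataclass(frozen=True)
class RegressionFit:
    """A fitted linear model: terms, coefficients, inference and fit quality.

    ``terms`` excludes the intercept; ``coef``/``pvalues``/``conf_int`` are
    aligned with ["const"] + terms.
    """

    terms: tuple[str, ...]
    coef: np.ndarray
    pvalues: np.ndarray
    conf_int: np.ndarray  # (p, 2), 95% by default
    r2: float
    rmse: float
    n: int
    df_resid: int

    @property
    def intercept(self) -> float:
        return float(self.coef[0])

    def summary_row(self, name: str) -> dict:
        return {
            "model": name,
            "terms": " + ".join(self.terms) if self.terms else "(intercept only)",
            "n_terms": len(self.terms),
            "r2": self.r2,
            "rmse": self.rmse,
            "n": self.n,
        }


@dataclass(frozen=True)
class AnovaResult:
    """One-way ANOVA outcome, optionally with Tukey HSD letters."""

    f_stat: float
    p_value: float
    group_means: dict
    alpha: float = 0.05
    letters: dict | None = None  # group -> letter string
    pairwise_p: dict | None = None  # frozenset({g1, g2}) -> p


@dataclass(frozen=True)
class FeatureSpec:
    """Candidate-variable specification for the multiple-regression search."""

    base: tuple[str, ...]
    transforms: tuple[str, ...] = ("identity",)
    interaction_order: int = 1
    alpha_enter: float = 0.05
    alpha_remove: float = 0.05

    def __post_init__(self) -> None:
        if not 1 <= self.interaction_order <= 4:
            raise ValueError("interaction order must lie in [1, 4]")
        for a in (self.alpha_enter, self.alpha_remove):
            if not 0.0 < a < 1.0:
                raise ValueError("alpha must lie in (0, 1)")
        for t in self.transforms:
            if t not in TRANSFORMS:
                raise ValueError(f"unknown transform {t!r}")


def _design_with_const(X: pd.DataFrame, n: int) -> np.ndarray:
    return np.column_stack([np.ones(n)] + [X[c].to_numpy(float) for c in X.columns])


def _collinear_columns(M: np.ndarray, names: list[str]) -> list[str]:
    """Columns made redundant by earlier ones, via greedy rank growth."""
    bad, kept = [], np.empty((M.shape[0], 0))
    for j, name in enumerate(names):
        cand = np.column_stack([kept, M[:, j]])
        if np.linalg.matrix_rank(cand) > kept.shape[1]:
            kept = cand
        else:
            bad.append(name)
    return bad


def ols_fit(response: np.ndarray | pd.Series, design: pd.DataFrame) -> RegressionFit:
    """Least-squares fit of response on design columns plus an intercept.

    R^2 = 1 - SSE/SST; RMSE = sqrt(SSE / (n - p)); two-sided t-test p-value
    per coefficient.  Raises on rank-deficient designs, naming the collinear
    terms, and on n <= #terms + 1.
    """
    y = np.asarray(response, dtype=float)
    terms = tuple(design.columns)
    n = len(y)
    if len(design) != n:
        raise ValueError("response and design have different lengths")
    if n <= len(terms) + 1:
        raise ValueError(f"too few observations (n={n}) for {len(terms)} terms")
    M = _design_with_const(design, n)
    if np.linalg.matrix_rank(M) < M.shape[1]:
        bad = _collinear_columns(M, ["const", *terms])
        raise ValueError(f"rank-deficient design; collinear terms: {bad}")

    res = sm.OLS(y, M).fit()
    sse = float(res.ssr)
    p = M.shape[1]
    rmse = math.sqrt(sse / (n - p))
    return RegressionFit(
        terms=terms,
        coef=np.asarray(res.params),
        pvalues=np.asarray(res.pvalues),
        conf_int=np.asarray(res.conf_int(alpha=0.05)),
        r2=float(res.rsquared),
        rmse=rmse,
        n=n,
        df_resid=int(res.df_resid),
    )


def _group_arrays(values, groups) -> dict:
    s = pd.Series(np.asarray(values, dtype=float))
    g = pd.Series(np.asarray(groups))
    out = {k: v.to_numpy() for k, v in s.groupby(g)}
    if len(out) < 2:
        raise ValueError("need at least 2 groups")
    for k, v in out.items():
        if len(v) < 2:
            raise ValueError(f"group {k!r} has fewer than 2 observations")
    return out


def one_way_anova(values, groups, alpha: float = 0.05) -> AnovaResult:
    """Standard between/within variance decomposition; F = MSB / MSW."""
    arrs = _group_arrays(values, groups)
    all_vals = np.concatenate(list(arrs.values()))
    grand = all_vals.mean()
    ssb = sum(len(v) * (v.mean() - grand) ** 2 for v in arrs.values())
    ssw = sum(((v - v.mean()) ** 2).sum() for v in arrs.values())
    df_b = len(arrs) - 1
    df_w = len(all_vals) - len(arrs)
    if ssw == 0:
        raise ValueError("degenerate MSE (zero within-group variance)")
    f_stat = (ssb / df_b) / (ssw / df_w)
    from scipy.stats import f as f_dist

    p = float(f_dist.sf(f_stat, df_b, df_w))
    return AnovaResult(
        f_stat=float(f_stat),
        p_value=p,
        group_means={k: float(v.mean()) for k, v in arrs.items()},
        alpha=alpha,
    )


def _compact_letters(names: list[str], means: dict, differs) -> dict:
    """Insert-and-absorb compact letter display.

    Starts from one column holding every group; each significant pair splits
    every column containing both; columns that became subsets are absorbed.
    Letters are assigned to columns ordered by their best (highest) mean.
    """
    cols: list[set] = [set(names)]
    order = sorted(names, key=lambda g: means[g])
    for a, b in itertools.combinations(order, 2):
        if not differs(a, b):
            continue
        for col in [c for c in cols if a in c and b in c]:
            cols.remove(col)
            cols.extend([col - {a}, col - {b}])
        cols = [c for c in cols if not any(c < d for d in cols if d is not c)]
        # drop exact duplicates
        uniq = []
        for c in cols:
            if c not in uniq:
                uniq.append(c)
        cols = uniq
    cols.sort(key=lambda c: min(means[g] for g in c))
    letters = {g: "" for g in names}
    for letter, col in zip("abcdefghijklmnopqrstuvwxyz", cols):
        for g in col:
            letters[g] += letter
    return {g: "".join(sorted(letters[g])) for g in names}


def tukey_hsd(values, groups, alpha: float = 0.05) -> AnovaResult:
    """All-pairs Tukey HSD with Tukey-Kramer standard errors and letters.

    The pairwise statistic is q = |m_i - m_j| / sqrt(MSE/2 * (1/n_i + 1/n_j))
    referred to the studentized range with k groups and the pooled residual
    degrees of freedom; groups sharing no letter differ at ``alpha``.
    """
    base = one_way_anova(values, groups, alpha=alpha)
    arrs = _group_arrays(values, groups)
    k = len(arrs)
    df_w = sum(len(v) for v in arrs.values()) - k
    mse = sum(((v - v.mean()) ** 2).sum() for v in arrs.values()) / df_w
    if mse == 0:
        raise ValueError("degenerate MSE (zero within-group variance)")

    pairwise = {}
    for a, b in itertools.combinations(arrs, 2):
        va, vb = arrs[a], arrs[b]
        se = math.sqrt(mse / 2.0 * (1.0 / len(va) + 1.0 / len(vb)))
        q = abs(va.mean() - vb.mean()) / se
        pairwise[frozenset((a, b))] = float(studentized_range.sf(q, k, df_w))

    names = list(arrs)
    letters = _compact_letters(
        names,
        base.group_means,
        lambda a, b: pairwise[frozenset((a, b))] < alpha,
    )
    return AnovaResult(
        f_stat=base.f_stat,
        p_value=base.p_value,
        group_means=base.group_means,
        alpha=alpha,
        letters=letters,
        pairwise_p=pairwise,
    )


def _factor_name(var: str, transform: str) -> str:
    return {
        "identity": var,
        "square": f"{var}^2",
        "log10": f"log10({var})",
        "ln": f"ln({var})",
    }[transform]


def _apply_transform(x: np.ndarray, transform: str, var: str) -> np.ndarray:
    if transform in ("log10", "ln") and (x <= 0).any():
        raise ValueError(f"variable {var!r} has nonpositive values under {transform}")
    return {
        "identity": lambda v: v,
        "square": lambda v: v**2,
        "log10": np.log10,
        "ln": np.log,
    }[transform](x)


def build_feature_set(table: pd.DataFrame, spec: FeatureSpec) -> tuple[pd.DataFrame, list[str]]:
    """Enumerate the candidate design: transformed variables and interactions.

    Candidates are each base variable under each requested transform, plus
    products of 2..interaction_order DISTINCT transformed factors, in the
    deterministic enumeration order (variables in spec order, transforms in
    spec order, then combinations in lexicographic order over that factor
    list).  Duplicate/aliased terms are collapsed by canonical name.
    """
    for v in spec.base:
        if v not in table.columns:
            raise KeyError(f"base variable {v!r} not in table")
    factors: dict[str, np.ndarray] = {}
    for v in spec.base:
        x = table[v].to_numpy(float)
        for t in spec.transforms:
            name = _factor_name(v, t)
            if name not in factors:
                factors[name] = _apply_transform(x, t, v)

    names = list(factors)
    design: dict[str, np.ndarray] = dict(factors)
    for order in range(2, spec.interaction_order + 1):
        for combo in itertools.combinations(names, order):
            term = ":".join(combo)
            if term not in design:
                design[term] = np.prod([factors[c] for c in combo], axis=0)
    return pd.DataFrame(design, index=table.index), list(design)


def _partial_p(y: np.ndarray, M: np.ndarray) -> float | None:
    """Two-sided t-test p-value of the LAST column of M; None if singular.

    Fast path used only inside the forward sweep; the reported final model is
    always refit through ols_fit.
    """
    n, p = M.shape
    if n - p < 1:
        return None
    q, r = np.linalg.qr(M)
    if abs(np.diag(r)).min() < 1e-10 * max(1.0, abs(np.diag(r)).max()):
        return None
    coef = np.linalg.solve(r, q.T @ y)
    resid = y - M @ coef
    sse = float(resid @ resid)
    if sse <= 0:
        return 0.0
    sigma2 = sse / (n - p)
    # (X'X)^-1[p,p] = ||R^-T e_p||^2 = 1/r_pp^2 for triangular R
    var_last = sigma2 / float(r[-1, -1]) ** 2
    t = coef[-1] / math.sqrt(var_last)
    from scipy.stats import t as t_dist

    return float(2.0 * t_dist.sf(abs(t), n - p))


def stepwise_select(
    response,
    candidates: pd.DataFrame,
    alpha_enter: float = 0.05,
    alpha_remove: float = 0.05,
    max_iter: int = 200,
) -> RegressionFit:
    """Bidirectional stepwise selection with the retention rule p < alpha.

    Forward: add the candidate with the smallest partial-F p-value if it is
    below ``alpha_enter``.  Backward: drop any included term whose p-value is
    >= ``alpha_remove`` (worst first).  Alternates until no add or drop
    changes the model; ties break by candidate list order.  Candidates that
    would make the design rank-deficient are skipped.
    """
    if candidates.shape[1] == 0:
        raise ValueError("need at least one candidate term")
    y = np.asarray(response, dtype=float)
    n = len(y)
    cols = list(candidates.columns)
    X = {c: candidates[c].to_numpy(float) for c in cols}
    current: list[str] = []
    seen: set[tuple[str, ...]] = set()

    for _ in range(max_iter):
        changed = False
        # forward
        base_M = np.column_stack([np.ones(n)] + [X[c] for c in current])
        best_p, best_c = None, None
        for c in cols:
            if c in current:
                continue
            p = _partial_p(y, np.column_stack([base_M, X[c]]))
            if p is not None and (best_p is None or p < best_p):
                best_p, best_c = p, c
        if best_p is not None and best_p < alpha_enter:
            current.append(best_c)
            changed = True
        # backward
        while current:
            M = np.column_stack([np.ones(n)] + [X[c] for c in current])
            ps = [
                _partial_p(y, np.column_stack([np.ones(n)]
                                              + [X[c] for c in current if c != drop]
                                              + [X[drop]]))
                for drop in current
            ]
            worst = max(range(len(current)), key=lambda i: (ps[i] is None, ps[i] or 0.0))
            if ps[worst] is None or ps[worst] >= alpha_remove:
                current.pop(worst)
                changed = True
            else:
                break
        state = tuple(sorted(current))
        if not changed or state in seen:
            break
        seen.add(state)

    return ols_fit(y, candidates[current])


_FACTOR_RE = re.compile(r"^(?:(log10|ln)\((?P<v1>[^()]+)\)|(?P<v2>[^()]+?)(?P<sq>\^2)?)$")


def _eval_factor(name: str, table: pd.DataFrame) -> np.ndarray:
    m = _FACTOR_RE.match(name)
    if m is None:
        raise ValueError(f"cannot parse term factor {name!r}")
    if m.group(1):
        var, transform = m.group("v1"), m.group(1)
    else:
        var = m.group("v2")
        transform = "square" if m.group("sq") else "identity"
    if var not in table.columns:
        raise KeyError(f"missing column {var!r} needed by term {name!r}")
    return _apply_transform(table[var].to_numpy(float), transform, var)


def predict_cutting_fat(fit: RegressionFit, table: pd.DataFrame) -> np.ndarray:
    """Evaluate a fitted model's linear predictor on new rows.

    Term names follow the build_feature_set grammar (``v``, ``v^2``,
    ``log10(v)``, ``ln(v)``, products joined by ``:``), so any fit produced
    by ols_fit or stepwise_select on such a design can be applied to a new
    table containing the base columns.
    """
    pred = np.full(len(table), fit.intercept)
    for name, beta in zip(fit.terms, fit.coef[1:]):
        vals = np.prod([_eval_factor(f, table) for f in name.split(":")], axis=0)
        pred = pred + beta * vals
    return pred
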