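"""Tests on trait means: size ANOVA, shape MANCOVA (Pillai's trace),
canonical variate analysis and numeric reaction norms.

The linear models use sequential (Type I) sums of squares in the fixed
order treatment, full-sib family, treatment x family (size as the last
covariate in the shape model).  The design is unbalanced, so the order
matters and is part of the contract; each effect's hypothesis SSCP is the
increment in fitted cross-products when its block of columns is added to
the cumulative design matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, stats

logger = logging.getLogger(__name__)

__all__ = [
    "CvaResult",
    "size_anova",
    "shape_mancova",
    "cva",
    "reaction_norms",
    "sequential_linear_model",
]


def _dummies(values: np.ndarray) -> np.ndarray:
    """Treatment-coded (drop-first) indicator columns, levels sorted."""
    values = np.asarray(values)
    levels = np.unique(values)
    return (values[:, None] == levels[None, 1:]).astype(float)


def _interaction(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    cols = [a[:, i: i + 1] * b[:, j: j + 1] for i in range(a.shape[1]) for j in range(b.shape[1])]
    return np.hstack(cols) if cols else np.empty((len(a), 0))


def sequential_linear_model(
    Y: np.ndarray, blocks: list[tuple[str, np.ndarray]]
) -> tuple[list[tuple[str, int, np.ndarray]], np.ndarray, int]:
    """Sequential (Type I) multivariate decomposition.

    ``blocks`` are (name, design columns) added after an implicit
    intercept, in order.  Returns per-effect ``(name, df, H)`` hypothesis
    SSCP matrices, the residual SSCP ``E`` and its degrees of freedom.
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n = len(Y)
    X = np.ones((n, 1))
    rank_prev = 1
    fitted_prev = np.full_like(Y, Y.mean(axis=0))
    sscp_prev = fitted_prev.T @ Y
    effects: list[tuple[str, int, np.ndarray]] = []
    for name, cols in blocks:
        cols = np.asarray(cols, dtype=float)
        if cols.ndim == 1:
            cols = cols[:, None]
        X = np.hstack([X, cols])
        beta, _, rank, _ = np.linalg.lstsq(X, Y, rcond=None)
        fitted = X @ beta
        sscp = fitted.T @ Y
        H = sscp - sscp_prev
        H = (H + H.T) / 2.0
        effects.append((name, rank - rank_prev, H))
        rank_prev, sscp_prev = rank, sscp
    resid = Y - fitted
    E = resid.T @ resid
    E = (E + E.T) / 2.0
    df_e = n - rank_prev
    return effects, E, df_e


def _check_cells(treatment: np.ndarray, family: np.ndarray) -> None:
    tab = pd.crosstab(pd.Series(treatment, name="treatment"), pd.Series(family, name="family"))
    empty = [(t, f) for t in tab.index for f in tab.columns if tab.loc[t, f] == 0]
    if empty:
        raise ValueError(
            "interaction inestimable: empty treatment x family cells " f"{empty}"
        )


def _anova_from_blocks(y: np.ndarray, blocks: list[tuple[str, np.ndarray]]) -> pd.DataFrame:
    effects, E, df_e = sequential_linear_model(y, blocks)
    ms_res = float(E[0, 0]) / df_e
    rows = []
    for name, df, H in effects:
        ss = float(H[0, 0])
        ms = ss / df if df > 0 else np.nan
        f = ms / ms_res if ms_res > 0 else np.inf
        rows.append(
            {
                "effect": name, "df": df, "SS": ss, "MS": ms, "F": f,
                "p": float(stats.f.sf(f, df, df_e)) if df > 0 else np.nan,
            }
        )
    rows.append(
        {"effect": "Residuals", "df": df_e, "SS": float(E[0, 0]), "MS": ms_res,
         "F": np.nan, "p": np.nan}
    )
    return pd.DataFrame(rows)


def size_anova(
    cs: np.ndarray,
    treatment: np.ndarray,
    family: np.ndarray,
    sex: np.ndarray | None = None,
    by_sex: bool = False,
):
    """ANOVA on specimen-level centroid size.

    Sequential decomposition in the order treatment, family,
    treatment x family; F against the residual mean square.  With
    ``by_sex`` a separate table is returned per sex (dict keyed by sex),
    otherwise sexes are pooled.
    """
    cs = np.asarray(cs, dtype=float)
    treatment = np.asarray(treatment)
    family = np.asarray(family)
    if by_sex:
        if sex is None:
            raise ValueError("by_sex requires a sex vector")
        sex = np.asarray(sex)
        return {
            s: size_anova(cs[sex == s], treatment[sex == s], family[sex == s])
            for s in np.unique(sex)
        }
    if len(np.unique(treatment)) < 2 or len(np.unique(family)) < 2:
        raise ValueError("need >= 2 levels of treatment and family")
    _check_cells(treatment, family)
    dt, dfam = _dummies(treatment), _dummies(family)
    blocks = [
        ("Treatment", dt),
        ("Full-sib family", dfam),
        ("Treatment x full-sib family", _interaction(dt, dfam)),
    ]
    return _anova_from_blocks(cs, blocks)


def _pillai_f(V: float, q: int, p: int, df_e: int) -> tuple[float, float, float, float]:
    """Standard F approximation for Pillai's trace."""
    s = min(p, q)
    m = (abs(p - q) - 1) / 2.0
    nn = (df_e - p - 1) / 2.0
    df1 = s * (2 * m + s + 1)
    df2 = s * (2 * nn + s + 1)
    denom = s - V
    f = (df2 / df1) * (V / denom) if denom > 0 else np.inf
    pval = float(stats.f.sf(f, df1, df2)) if np.isfinite(f) else 0.0
    return f, df1, df2, pval


def shape_mancova(
    scores: np.ndarray,
    treatment: np.ndarray,
    family: np.ndarray,
    cs: np.ndarray,
) -> pd.DataFrame:
    """Sequential MANCOVA on shape variables with Pillai's trace.

    Effects in order: treatment, family, treatment x family, centroid size
    (covariate last).  ``scores`` are the specimen-level shape variables
    (tangent coordinates or PCA scores spanning the full shape space).
    """
    Y = np.asarray(scores, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n, p = Y.shape
    treatment = np.asarray(treatment)
    family = np.asarray(family)
    cs = np.asarray(cs, dtype=float)
    _check_cells(treatment, family)
    dt, dfam = _dummies(treatment), _dummies(family)
    blocks = [
        ("Treatment", dt),
        ("Full-sib family", dfam),
        ("Treatment x full-sib family", _interaction(dt, dfam)),
        ("Size", (cs - cs.mean())[:, None]),
    ]
    model_df = 1 + sum(np.asarray(b).shape[1] for _, b in blocks)
    if n <= p + model_df:
        raise ValueError(f"n = {n} too small for {p} responses and {model_df} model df")
    effects, E, df_e = sequential_linear_model(Y, blocks)
    cond = np.linalg.cond(E)
    if not np.isfinite(cond) or cond > 1e12:
        raise ValueError(
            "residual SSCP matrix is (near-)singular; reduce the shape-space "
            "dimensionality before the MANCOVA"
        )
    rows = []
    for name, q, H in effects:
        V = float(np.trace(np.linalg.solve((H + E).T, H.T).T))
        f, df1, df2, pval = _pillai_f(V, q, p, df_e)
        rows.append(
            {"effect": name, "df": q, "pillai": V, "F": f,
             "df_num": df1, "df_den": df2, "p": pval}
        )
    rows.append(
        {"effect": "Residuals", "df": df_e, "pillai": np.nan, "F": np.nan,
         "df_num": np.nan, "df_den": np.nan, "p": np.nan}
    )
    return pd.DataFrame(rows)


@dataclass
class CvaResult:
    """Canonical variate analysis of group structure in shape space."""

    loadings: np.ndarray      # p x a canonical axes
    eigenvalues: np.ndarray   # a
    scores: np.ndarray        # n x a individual scores (unit within-group variance)
    group_scores: pd.DataFrame  # group means on the canonical axes
    groups: np.ndarray


def cva(scores: np.ndarray, groups: np.ndarray) -> CvaResult:
    """Canonical variates: eigenvectors of W^-1 B (pooled within-group vs
    between-group-means covariance), scores scaled to unit within-group
    variance per axis.  A rank-deficient W triggers an automatic projection
    onto its leading principal components (logged)."""
    X = np.asarray(scores, dtype=float)
    groups = np.asarray(groups)
    uniq, inv = np.unique(groups, return_inverse=True)
    g = len(uniq)
    if g < 2:
        raise ValueError("need >= 2 groups")
    n, p = X.shape
    grand = X.mean(axis=0)
    means = np.stack([X[inv == i].mean(axis=0) for i in range(g)])
    counts = np.bincount(inv)
    W = np.zeros((p, p))
    for i in range(g):
        d = X[inv == i] - means[i]
        W += d.T @ d
    W /= (n - g)
    B = (counts[:, None] * (means - grand)).T @ (means - grand) / (g - 1)

    evals_w = np.linalg.eigvalsh(W)
    proj = np.eye(p)
    if evals_w.min() < 1e-10 * max(evals_w.max(), 1e-300):
        vals, vecs = np.linalg.eigh(W)
        keep = vals > 1e-10 * vals.max()
        proj = vecs[:, keep]
        logger.info("CVA: W rank-deficient, projecting %d -> %d dimensions", p, keep.sum())
        W = proj.T @ (W @ proj)
        B = proj.T @ (B @ proj)

    evals, vecs = linalg.eigh(B, W)      # generalized symmetric-definite problem
    order = np.argsort(evals)[::-1]
    a = min(g - 1, W.shape[0])
    evals = np.clip(evals[order][:a], 0.0, None)
    vecs = vecs[:, order][:, :a]         # normalised so v' W v = 1
    loadings = proj @ vecs
    ind_scores = (X - grand) @ loadings
    grp_scores = (means - grand) @ vecs
    group_df = pd.DataFrame(grp_scores, columns=[f"CV{i + 1}" for i in range(a)])
    group_df.insert(0, "group", uniq)
    return CvaResult(
        loadings=loadings, eigenvalues=evals, scores=ind_scores,
        group_scores=group_df, groups=groups,
    )


def reaction_norms(
    values: np.ndarray,
    family: np.ndarray,
    treatment: np.ndarray,
    variable_names: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-family treatment response (reaction norms) and a parallelism
    summary.

    Returns a long table (family, variable, control mean, treated mean,
    difference) and a per-variable summary with the variance of the
    family differences — zero when all reaction norms are parallel.
    Families missing a treatment are excluded with a warning.
    """
    import warnings

    X = np.asarray(values, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    p = X.shape[1]
    names = variable_names or (["value"] if p == 1 else [f"v{i + 1}" for i in range(p)])
    family = np.asarray(family)
    treatment = np.asarray(treatment).astype(str)
    rows = []
    for f in np.unique(family):
        mask = family == f
        ts = set(treatment[mask])
        if not {"control", "treated"} <= ts:
            warnings.warn(f"family {f} lacks one treatment group; excluded from reaction norms")
            continue
        mc = X[mask & (treatment == "control")].mean(axis=0)
        mt = X[mask & (treatment == "treated")].mean(axis=0)
        for j, nm in enumerate(names):
            rows.append(
                {"family": f, "variable": nm, "control_mean": mc[j],
                 "treated_mean": mt[j], "difference": mt[j] - mc[j]}
            )
    table = pd.DataFrame(rows)
    if table.empty:
        raise ValueError("no family has both treatment groups")
    summary = (
        table.groupby("variable", sort=False)["difference"]
        .agg(mean_difference="mean", parallelism_variance=lambda d: d.var(ddof=1) if len(d) > 1 else 0.0)
        .reset_index()
    )
    return table, summary
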