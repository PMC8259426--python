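"""Variance decomposition of bilateral traits: individual variation,
directional asymmetry, fluctuating asymmetry and measurement error.

For every family x treatment cell a two-factor crossed ANOVA (individual x
side, two digitisation replicates in the residual) is computed for
centroid size ("regular" ANOVA) and for shape (Procrustes ANOVA: sums of
squares pooled over all tangent coordinates, degrees of freedom multiplied
by the shape dimension).  The measurement-error-corrected fluctuating-
asymmetry index is

    FA10 = (MS_individual_x_side - MS_error) / 2

with two replicates; the among-individual mean square estimates individual
(micro-environmental) variation.  Like mean squares are compared between
treatments with two-sided F tests, and among-family mean squares from a
one-way (Procrustes) ANOVA per treatment estimate genetic variation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AsymmetryDecomposition",
    "VarianceComparison",
    "GeneticVariation",
    "sides_anova",
    "compare_variances",
    "genetic_variation",
    "decomposition_table",
]


@dataclass
class AsymmetryDecomposition:
    """Sides-ANOVA table for one family x treatment cell and one trait."""

    family: int | None
    treatment: str | None
    trait: str                  # "size" or "shape"
    anova: pd.DataFrame         # rows: individual, side, individual x side, error
    fa10: float
    individual_ms: float
    n_individuals: int
    shape_dim: int              # 1 for size
    negative_fa10: bool
    n_replicates: int = 2


@dataclass
class VarianceComparison:
    family: int | None
    trait: str
    level: str                  # "individual" | "fa"
    ms_control: float
    ms_treated: float
    F: float
    df_treated: int
    df_control: int
    p: float


@dataclass
class GeneticVariation:
    trait: str
    ms_family: dict             # treatment -> among-family MS
    ms_residual: dict
    df_family: dict
    F: float                    # treated / control family MS
    p: float


def _two_sided_f_p(f: float, df1: int, df2: int) -> float:
    if not np.isfinite(f) or f <= 0:
        return 0.0
    lower = stats.f.cdf(f, df1, df2)
    upper = stats.f.sf(f, df1, df2)
    return float(min(1.0, 2.0 * min(lower, upper)))


def sides_anova(
    values: np.ndarray,
    specimen: np.ndarray,
    side: np.ndarray,
    replicate: np.ndarray,
    family: int | None = None,
    treatment: str | None = None,
    trait: str = "size",
    shape_dim: int | None = None,
) -> AsymmetryDecomposition:
    """Two-way crossed (individual x side) ANOVA with replicates as error.

    ``values`` is (n_obs,) for size or (n_obs, p) for shape coordinates;
    each specimen must contribute both sides with two replicates each
    (incomplete specimens are dropped with a warning).  For shape, sums of
    squares are pooled over the ``p`` columns and degrees of freedom are
    scaled by ``shape_dim`` (default ``p``; pass 2k - 4 for tangent
    coordinates from a Procrustes fit).
    """
    values = np.asarray(values, dtype=float)
    if values.ndim == 1:
        values = values[:, None]
    p = values.shape[1]
    df_mult = 1 if trait == "size" else int(shape_dim if shape_dim is not None else p)
    if trait == "size" and p != 1:
        raise ValueError("size trait expects a single value column")

    tab = pd.DataFrame(
        {
            "specimen": np.asarray(specimen).astype(str),
            "side": np.asarray(side).astype(str),
            "replicate": np.asarray(replicate).astype(int),
            "row": np.arange(len(values)),
        }
    )
    complete: list[np.ndarray] = []
    dropped: list[str] = []
    for spec_id, grp in tab.groupby("specimen", sort=True):
        cells = grp.set_index(["side", "replicate"])["row"]
        wanted = [(s, r) for s in ("L", "R") for r in (1, 2)]
        if sorted(cells.index.tolist()) == sorted(wanted) :
            # order: sides sorted (L, R), replicates (1, 2)
            complete.append(np.array([cells.loc[w] for w in wanted]))
        else:
            dropped.append(spec_id)
    if dropped:
        warnings.warn(
            f"dropped {len(dropped)} specimens lacking the full 2-side x 2-replicate "
            f"structure: {dropped[:5]}{'...' if len(dropped) > 5 else ''}"
        )
    n = len(complete)
    if n < 3:
        raise ValueError(f"need >= 3 complete specimens, have {n}")
    idx = np.stack(complete)                       # n x 4 row indices (L1, L2, R1, R2)
    Y = values[idx].reshape(n, 2, 2, p)            # n x side x replicate x p

    grand = Y.mean(axis=(0, 1, 2))
    m_i = Y.mean(axis=(1, 2))                      # n x p
    m_s = Y.mean(axis=(0, 2))                      # 2 x p
    m_is = Y.mean(axis=2)                          # n x 2 x p

    ss_ind = 4.0 * ((m_i - grand) ** 2).sum()
    ss_side = 2.0 * n * ((m_s - grand) ** 2).sum()
    ss_int = 2.0 * ((m_is - m_i[:, None, :] - m_s[None, :, :] + grand) ** 2).sum()
    ss_err = ((Y - m_is[:, :, None, :]) ** 2).sum()

    df = np.array([n - 1, 1, n - 1, 2 * n]) * df_mult
    ss = np.array([ss_ind, ss_side, ss_int, ss_err])
    ms = ss / df
    # side tested over interaction, interaction over error, individual over
    # interaction (side fixed, individual random)
    F = np.array([ms[0] / ms[2] if ms[2] > 0 else np.inf,
                  ms[1] / ms[2] if ms[2] > 0 else np.inf,
                  ms[2] / ms[3] if ms[3] > 0 else np.inf,
                  np.nan])
    pvals = np.array([
        stats.f.sf(F[0], df[0], df[2]),
        stats.f.sf(F[1], df[1], df[2]),
        stats.f.sf(F[2], df[2], df[3]),
        np.nan,
    ])
    anova = pd.DataFrame(
        {
            "effect": ["individual", "side", "individual x side", "error"],
            "df": df,
            "SS": ss,
            "MS": ms,
            "F": F,
            "p": pvals,
        }
    )
    fa10 = float((ms[2] - ms[3]) / 2.0)
    return AsymmetryDecomposition(
        family=family,
        treatment=treatment,
        trait=trait,
        anova=anova,
        fa10=fa10,
        individual_ms=float(ms[0]),
        n_individuals=n,
        shape_dim=df_mult,
        negative_fa10=fa10 < 0,
    )


_LEVEL_ROW = {"individual": 0, "fa": 2}


def compare_variances(
    control: AsymmetryDecomposition,
    treated: AsymmetryDecomposition,
    level: str,
) -> VarianceComparison:
    """Two-sided F test of like mean squares between treatments.

    ``level`` is ``"individual"`` (among-individual MS) or ``"fa"``
    (individual x side interaction MS).
    """
    if level not in _LEVEL_ROW:
        raise ValueError(f"unknown level {level!r}; use 'individual' or 'fa'")
    row = _LEVEL_ROW[level]
    ms_c = float(control.anova["MS"].iloc[row])
    ms_t = float(treated.anova["MS"].iloc[row])
    df_c = int(control.anova["df"].iloc[row])
    df_t = int(treated.anova["df"].iloc[row])
    if ms_c <= 0:
        return VarianceComparison(
            family=control.family, trait=control.trait, level=level,
            ms_control=ms_c, ms_treated=ms_t, F=np.inf,
            df_treated=df_t, df_control=df_c, p=0.0,
        )
    f = ms_t / ms_c
    return VarianceComparison(
        family=control.family, trait=control.trait, level=level,
        ms_control=ms_c, ms_treated=ms_t, F=float(f),
        df_treated=df_t, df_control=df_c, p=_two_sided_f_p(f, df_t, df_c),
    )


def genetic_variation(
    values: np.ndarray,
    family: np.ndarray,
    treatment: np.ndarray,
    trait: str = "size",
    shape_dim: int | None = None,
) -> GeneticVariation:
    """Among-family (genetic) variation per treatment and its F ratio.

    One-way (Procrustes) ANOVA with full-sib family as the single effect,
    computed within each treatment on specimen-level values; the
    treated/control ratio of among-family mean squares is tested two-sided
    with (families - 1) x shape_dim degrees of freedom per group.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim == 1:
        values = values[:, None]
    p = values.shape[1]
    df_mult = 1 if trait == "size" else int(shape_dim if shape_dim is not None else p)
    family = np.asarray(family)
    treatment = np.asarray(treatment).astype(str)

    ms_family: dict = {}
    ms_residual: dict = {}
    df_family: dict = {}
    for t in np.unique(treatment):
        mask = treatment == t
        fams = family[mask]
        Y = values[mask]
        uniq = np.unique(fams)
        if len(uniq) < 2:
            raise ValueError(f"treatment {t!r} has fewer than 2 families")
        grand = Y.mean(axis=0)
        ss_fam = 0.0
        ss_res = 0.0
        for f in uniq:
            sub = Y[fams == f]
            m = sub.mean(axis=0)
            ss_fam += len(sub) * ((m - grand) ** 2).sum()
            ss_res += ((sub - m) ** 2).sum()
        dff = (len(uniq) - 1) * df_mult
        dfr = (len(Y) - len(uniq)) * df_mult
        ms_family[t] = float(ss_fam / dff)
        ms_residual[t] = float(ss_res / dfr) if dfr > 0 else np.nan
        df_family[t] = dff

    if {"control", "treated"} <= set(ms_family):
        if ms_family["control"] == 0:
            f = np.nan if ms_family["treated"] == 0 else np.inf
            pval = np.nan if ms_family["treated"] == 0 else 0.0
        else:
            f = ms_family["treated"] / ms_family["control"]
            pval = _two_sided_f_p(f, df_family["treated"], df_family["control"])
    else:
        f, pval = np.nan, np.nan
    return GeneticVariation(
        trait=trait, ms_family=ms_family, ms_residual=ms_residual,
        df_family=df_family, F=float(f), p=float(pval),
    )


def decomposition_table(decomps: list[AsymmetryDecomposition]) -> pd.DataFrame:
    """Long-format summary of many decompositions (one row per cell/trait)."""
    rows = []
    for d in decomps:
        rows.append(
            {
                "family": d.family,
                "treatment": d.treatment,
                "trait": d.trait,
                "n_individuals": d.n_individuals,
                "individual_ms": d.individual_ms,
                "side_ms": float(d.anova["MS"].iloc[1]),
                "interaction_ms": float(d.anova["MS"].iloc[2]),
                "error_ms": float(d.anova["MS"].iloc[3]),
                "fa10": d.fa10,
                "negative_fa10": d.negative_fa10,
            }
        )
    return pd.DataFrame(rows)
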