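"""Kendall rank-concordance analyses across full-sib families.

Families are ranked by a per-family variability statistic (among-
individual mean square or FA10) and concordance is measured with the
tie-corrected Kendall tau-b: between treatments (are the most variable /
most asymmetric families under control conditions also the most variable
when treated?) and between individual variation and FA within each
treatment (are canalisation and developmental stability coupled?).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .asymmetry import AsymmetryDecomposition

__all__ = ["TauResult", "kendall_tau", "concordance_report"]


@dataclass
class TauResult:
    tau: float
    n: int
    p: float


def kendall_tau(x: np.ndarray, y: np.ndarray) -> TauResult:
    """Kendall tau-b with a two-sided p-value.

    Exact enumeration when n <= 10 and there are no ties, normal
    approximation otherwise.  All-tied input is undefined and rejected.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("tau undefined for an all-tied vector")
    no_ties = len(np.unique(x)) == n and len(np.unique(y)) == n
    method = "exact" if (n <= 10 and no_ties) else "asymptotic"
    res = stats.kendalltau(x, y, variant="b", method=method, alternative="two-sided")
    return TauResult(tau=float(res.statistic), n=n, p=float(res.pvalue))


def _pivot(decomps: list[AsymmetryDecomposition], trait: str, attr: str) -> pd.DataFrame:
    rows = [
        {"family": d.family, "treatment": d.treatment, "value": getattr(d, attr)}
        for d in decomps
        if d.trait == trait
    ]
    if not rows:
        return pd.DataFrame()
    return (
        pd.DataFrame(rows)
        .pivot(index="family", columns="treatment", values="value")
        .dropna()
    )


def concordance_report(decomps: list[AsymmetryDecomposition]) -> pd.DataFrame:
    """The full set of tau analyses on per-family variance estimates.

    For each trait (size, shape): cross-treatment concordance of
    individual variation and of FA10, plus the individual-variation vs FA
    association within each treatment.  Requires >= 3 families complete in
    both treatments.
    """
    rows = []
    for trait in ("size", "shape"):
        iv = _pivot(decomps, trait, "individual_ms")
        fa = _pivot(decomps, trait, "fa10")
        if iv.empty and fa.empty:
            continue
        for statistic, piv in (("individual", iv), ("fa", fa)):
            if len(piv) < 3:
                raise ValueError(
                    f"fewer than 3 families with both treatments for {statistic}/{trait}"
                )
            res = kendall_tau(piv["control"].to_numpy(), piv["treated"].to_numpy())
            rows.append(
                {"statistic": statistic, "trait": trait,
                 "comparison": "control_vs_treated",
                 "tau": res.tau, "n": res.n, "p": res.p}
            )
        both = iv.join(fa, lsuffix="_iv", rsuffix="_fa").dropna()
        for t in ("control", "treated"):
            if len(both) < 3:
                raise ValueError(f"fewer than 3 complete families for IV-vs-FA in {t}")
            res = kendall_tau(
                both[f"{t}_iv"].to_numpy(), both[f"{t}_fa"].to_numpy()
            )
            rows.append(
                {"statistic": "iv_vs_fa", "trait": trait, "comparison": t,
                 "tau": res.tau, "n": res.n, "p": res.p}
            )
    if not rows:
        raise ValueError("no decompositions supplied")
    return pd.DataFrame(rows)
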