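"""Covariance-matrix comparison machinery.

Builds the labelled shape covariance matrices of the analysis — among
individuals within family x treatment (environmental canalisation), of
signed fluctuating-asymmetry vectors (developmental stability), and among
family means within treatment (genetic canalisation) — compares them by
element-wise matrix correlation including the diagonal, tests the
correlations by permuting landmark labels (coordinate pairs move jointly,
because x and y of one landmark are not independent), and ordinates the
matrices by principal coordinates analysis on the distance 1 - r².
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CovMatrix",
    "CovarianceMatrixSet",
    "PCOEmbedding",
    "reduce_basis",
    "build_matrices",
    "matrix_correlation",
    "landmark_permutation_test",
    "correlation_distance",
    "distance_matrix",
    "pco",
    "pco_from_distances",
]


@dataclass
class CovMatrix:
    matrix: np.ndarray
    mtype: str                       # "individual" | "fa" | "genetic"
    family: int | str | None         # family number or "pooled"
    treatment: str
    n: int                           # observations behind the matrix

    @property
    def label(self) -> str:
        fam = self.family if self.family is not None else "pooled"
        return f"{self.mtype}:{fam}:{self.treatment}"


@dataclass
class CovarianceMatrixSet:
    matrices: list[CovMatrix]
    basis: np.ndarray | None = None  # p x d projection basis (None = raw basis)
    basis_kind: str = "coordinate"   # "coordinate" (landmark blocks) or "reduced"

    def __post_init__(self) -> None:
        for m in self.matrices:
            a = m.matrix
            if a.shape[0] != a.shape[1] or not np.allclose(a, a.T, atol=1e-10):
                raise ValueError(f"matrix {m.label} is not symmetric")
    def __len__(self) -> int:
        return len(self.matrices)

    def labels(self) -> list[str]:
        return [m.label for m in self.matrices]

    def select(self, mtype: str) -> "CovarianceMatrixSet":
        return CovarianceMatrixSet(
            [m for m in self.matrices if m.mtype == mtype],
            basis=self.basis, basis_kind=self.basis_kind,
        )


@dataclass
class PCOEmbedding:
    coordinates: np.ndarray   # m x q over positive-eigenvalue axes
    eigenvalues: np.ndarray   # all m eigenvalues, descending (negatives reported)
    distance_fit: float       # correlation between input and embedded distances
    labels: list[str] = field(default_factory=list)


def reduce_basis(
    scores: np.ndarray, target_dim: int = 14
) -> tuple[np.ndarray, np.ndarray]:
    """Project scores onto the first ``target_dim`` principal components of
    the pooled dataset; all covariance matrices are then computed on this
    common basis (the among-family matrices of a 14-family design have at
    most 14 dimensions, so every matrix is reduced to 14)."""
    X = np.asarray(scores, dtype=float)
    centred = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(centred, full_matrices=False)
    rank = int((s > s[0] * 1e-10).sum()) if len(s) else 0
    if target_dim > rank:
        raise ValueError(f"target_dim {target_dim} exceeds available rank {rank}")
    basis = Vt[:target_dim].T           # p x target_dim
    return centred @ basis, basis


def _specimen_aggregate(scores: np.ndarray, meta: pd.DataFrame) -> pd.DataFrame:
    """Per-specimen mean shape and signed asymmetry vector (R - L)/2 of
    replicate-averaged sides."""
    df = meta.reset_index(drop=True).copy()
    p = scores.shape[1]
    cols = [f"c{i}" for i in range(p)]
    df[cols] = scores
    out = []
    for (spec, fam, treat), grp in df.groupby(
        ["specimen_id", "family", "treatment"], sort=True
    ):
        sides = grp.groupby(grp["side"].astype(str).str.upper())[cols].mean()
        if not {"L", "R"} <= set(sides.index):
            warnings.warn(f"specimen {spec} lacks a side; skipped")
            continue
        mean_shape = grp[cols].mean().to_numpy()
        asym = (sides.loc["R"].to_numpy() - sides.loc["L"].to_numpy()) / 2.0
        out.append(
            {"specimen_id": spec, "family": fam, "treatment": treat,
             "mean": mean_shape, "asym": asym}
        )
    return pd.DataFrame(out)


def build_matrices(
    scores: np.ndarray,
    meta: pd.DataFrame,
    min_individuals: int = 3,
    basis: np.ndarray | None = None,
    basis_kind: str = "coordinate",
) -> CovarianceMatrixSet:
    """Individual, FA and genetic covariance matrices from per-wing scores.

    * individual: covariance of specimen mean shapes within each
      family x treatment cell;
    * fa: covariance of per-specimen signed asymmetry vectors
      ((R - L)/2 of replicate-averaged sides), centred on the cell's mean
      asymmetry so directional asymmetry is removed;
    * genetic: covariance of family mean shapes within each treatment.

    Cells with fewer than ``min_individuals`` specimens are omitted with a
    warning (divisor n - 1 throughout).
    """
    agg = _specimen_aggregate(np.asarray(scores, dtype=float), meta)
    if agg.empty:
        raise ValueError("no complete specimens")
    matrices: list[CovMatrix] = []
    for (fam, treat), grp in agg.groupby(["family", "treatment"], sort=True):
        n = len(grp)
        if n < min_individuals:
            warnings.warn(
                f"family {fam} / {treat}: only {n} specimens (< {min_individuals}); "
                "matrices omitted"
            )
            continue
        means = np.stack(grp["mean"].to_numpy())
        asyms = np.stack(grp["asym"].to_numpy())
        matrices.append(CovMatrix(np.cov(means, rowvar=False, ddof=1), "individual", fam, treat, n))
        matrices.append(CovMatrix(np.cov(asyms, rowvar=False, ddof=1), "fa", fam, treat, n))
    for treat, grp in agg.groupby("treatment", sort=True):
        fam_means = grp.groupby("family")["mean"].apply(lambda s: np.stack(s.to_numpy()).mean(axis=0))
        if len(fam_means) < 3:
            warnings.warn(f"treatment {treat}: fewer than 3 families; genetic matrix omitted")
            continue
        G = np.cov(np.stack(fam_means.to_numpy()), rowvar=False, ddof=1)
        matrices.append(CovMatrix(G, "genetic", "pooled", treat, len(fam_means)))
    return CovarianceMatrixSet(matrices, basis=basis, basis_kind=basis_kind)


def _unique_elements(A: np.ndarray, include_diagonal: bool) -> np.ndarray:
    iu = np.triu_indices(A.shape[0], k=0 if include_diagonal else 1)
    return A[iu]


def matrix_correlation(
    A: np.ndarray, B: np.ndarray, include_diagonal: bool = True
) -> float:
    """Pearson correlation over the unique elements of two symmetric
    matrices (upper triangle, diagonal included by default because the
    variances carry information too)."""
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.shape != B.shape or A.shape[0] != A.shape[1]:
        raise ValueError("matrices must be square and of equal size")
    a = _unique_elements(A, include_diagonal)
    b = _unique_elements(B, include_diagonal)
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("matrix correlation undefined for a constant matrix")
    return float(np.corrcoef(a, b)[0, 1])


def _landmark_permutation_index(perm: np.ndarray) -> np.ndarray:
    """Coordinate indices moving landmark blocks (x, y interleaved) jointly."""
    idx = np.empty(2 * len(perm), dtype=int)
    idx[0::2] = 2 * perm
    idx[1::2] = 2 * perm + 1
    return idx


def landmark_permutation_test(
    A: np.ndarray,
    B: np.ndarray,
    n_perm: int = 999,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    include_diagonal: bool = True,
) -> tuple[float, float]:
    """Matrix-correlation permutation test against the null of complete
    dissimilarity.

    Landmark labels of one matrix are permuted — rows and columns moved in
    coordinate blocks of two, x and y jointly — the correlation is
    recomputed each time, and the one-tailed p-value is
    ``(1 + #{r_perm >= r_obs}) / (1 + n_perm)``.  Requires matrices on a
    landmark-coordinate basis (even dimension, x1 y1 x2 y2 ... ordering);
    on a reduced basis the block structure is destroyed, so run the test
    on the coordinate basis instead.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    p = A.shape[0]
    if p % 2 != 0:
        raise ValueError(
            "landmark permutation test needs an even coordinate dimension "
            "(landmark-block structure); run it on the landmark-coordinate basis"
        )
    if n_perm < 99:
        warnings.warn(f"n_perm = {n_perm} is small; p-value resolution is coarse")
    k = p // 2
    r_obs = matrix_correlation(A, B, include_diagonal)
    if rng is None:
        rng = np.random.default_rng(seed)
    perms = np.stack([rng.permutation(k) for _ in range(n_perm)])
    idx = np.stack([_landmark_permutation_index(pm) for pm in perms])  # n_perm x p
    Bp = B[idx[:, :, None], idx[:, None, :]]                            # n_perm x p x p
    iu = np.triu_indices(p, k=0 if include_diagonal else 1)
    vecs = Bp[:, iu[0], iu[1]]
    a = _unique_elements(A, include_diagonal)
    ac = a - a.mean()
    vc = vecs - vecs.mean(axis=1, keepdims=True)
    denom = np.sqrt((ac**2).sum() * (vc**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r_perm = (vc @ ac) / denom
    r_perm = np.nan_to_num(r_perm, nan=-np.inf)
    pval = (1.0 + int((r_perm >= r_obs - 1e-12).sum())) / (1.0 + n_perm)
    return r_obs, float(pval)


def correlation_distance(A: np.ndarray, B: np.ndarray, include_diagonal: bool = True) -> float:
    """1 - r² distance between two covariance matrices."""
    r = matrix_correlation(A, B, include_diagonal)
    return float(1.0 - r**2)


def distance_matrix(mset: CovarianceMatrixSet, include_diagonal: bool = True) -> np.ndarray:
    m = len(mset)
    D = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            D[i, j] = D[j, i] = correlation_distance(
                mset.matrices[i].matrix, mset.matrices[j].matrix, include_diagonal
            )
    return D


def pco_from_distances(D: np.ndarray, labels: list[str] | None = None) -> PCOEmbedding:
    """Classical (Torgerson-Gower) scaling of a distance matrix.

    Double-centres -0.5 * J D∘D J, eigendecomposes, and scales the
    eigenvectors of positive eigenvalues by their square roots.  Negative
    eigenvalues are reported, never silently dropped.
    """
    D = np.asarray(D, dtype=float)
    m = D.shape[0]
    if m < 3:
        raise ValueError("PCO needs at least 3 items")
    if not np.allclose(D, D.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    J = np.eye(m) - np.ones((m, m)) / m
    Bmat = -0.5 * J @ (D**2) @ J
    evals, evecs = np.linalg.eigh(Bmat)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    tol = 1e-12 * max(abs(evals).max(), 1.0)
    pos = evals > tol
    coords = evecs[:, pos] * np.sqrt(evals[pos])
    if coords.shape[1] == 0:
        fit = 1.0 if np.allclose(D, 0) else 0.0
    else:
        emb = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(axis=2))
        iu = np.triu_indices(m, k=1)
        din, dout = D[iu], emb[iu]
        fit = 1.0 if np.std(din) == 0 else float(np.corrcoef(din, dout)[0, 1])
    return PCOEmbedding(
        coordinates=coords, eigenvalues=evals, distance_fit=fit, labels=labels or []
    )


def pco(mset: CovarianceMatrixSet, include_diagonal: bool = True) -> PCOEmbedding:
    """Principal coordinates ordination of a covariance-matrix set on the
    1 - r² distance."""
    D = distance_matrix(mset, include_diagonal)
    return pco_from_distances(D, labels=mset.labels())
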