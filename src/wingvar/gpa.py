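"""Geometry core: centroid size, reflection, generalised Procrustes
superimposition, tangent projection and shape PCA.

All configurations are k x 2 landmark matrices.  A generalised Procrustes
fit centres every configuration, scales it to unit centroid size, and
iteratively rotates it to the running consensus (rotations only — left
wings are reflected beforehand from metadata, never freely, since a free
reflection would silently absorb directional asymmetry).  The aligned
coordinates are then orthogonally projected to the tangent plane at the
consensus, giving 2k-dimensional tangent vectors of rank 2k - 4.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .tps import read_tps

__all__ = [
    "LandmarkSet",
    "ProcrustesResult",
    "ShapePCA",
    "GPAConvergenceError",
    "centroid_size",
    "reflect",
    "procrustes_distance",
    "gpa_fit",
    "shape_pca",
    "load_dataset",
]

META_COLUMNS = ["specimen_id", "family", "sex", "treatment", "side", "replicate"]


class GPAConvergenceError(RuntimeError):
    """Generalised Procrustes iteration failed to converge."""

    def __init__(self, deltas: list[float]):
        self.deltas = deltas
        super().__init__(
            "GPA did not converge after "
            f"{len(deltas)} iterations; consensus change trace: {deltas}"
        )


@dataclass
class LandmarkSet:
    """One wing's landmark configuration plus its identity."""

    coords: np.ndarray
    specimen_id: str = ""
    side: str = "R"
    replicate: int = 1
    family: int | None = None
    sex: str | None = None
    treatment: str | None = None
    image_coords: np.ndarray | None = None  # as digitised, before scale calibration
    scale: float | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValueError("coords must be a k x 2 matrix")
        if not np.isfinite(self.coords).all():
            raise ValueError("coords contain NaN/inf")


@dataclass
class ProcrustesResult:
    """Output of a generalised Procrustes fit on a whole dataset."""

    aligned: np.ndarray        # n x k x 2, unit centroid size, centred
    tangent: np.ndarray        # n x 2k tangent-space coordinates
    consensus: np.ndarray      # k x 2 mean shape, unit centroid size
    centroid_sizes: np.ndarray  # n original centroid sizes
    shape_dim: int             # 2k - 4
    meta: pd.DataFrame
    n_iterations: int
    procrustes_ss: float

    @property
    def n(self) -> int:
        return self.aligned.shape[0]

    @property
    def k(self) -> int:
        return self.aligned.shape[1]


@dataclass
class ShapePCA:
    scores: np.ndarray        # n x m
    eigenvectors: np.ndarray  # 2k x m, columns are PCs
    eigenvalues: np.ndarray   # m
    mean: np.ndarray          # 2k


def centroid_size(coords: np.ndarray) -> float:
    """Square root of the summed squared distances from each landmark to
    the configuration centroid.  Zero when all landmarks coincide."""
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[0] < 1:
        raise ValueError("coords must be a k x 2 matrix with k >= 1")
    if not np.isfinite(coords).all():
        raise ValueError("coords contain NaN/inf")
    centred = coords - coords.mean(axis=0)
    return float(np.sqrt((centred**2).sum()))


def reflect(coords: np.ndarray) -> np.ndarray:
    """Mirror about the vertical axis (negate x, preserve y)."""
    out = np.array(coords, dtype=float, copy=True)
    out[:, 0] *= -1.0
    return out


def _preshape(coords: np.ndarray) -> np.ndarray:
    centred = np.asarray(coords, dtype=float)
    centred = centred - centred.mean(axis=0)
    cs = np.sqrt((centred**2).sum())
    if cs <= 0:
        raise ValueError("degenerate configuration with zero centroid size")
    return centred / cs


def _rotmat(theta: float) -> np.ndarray:
    c, s = np.cos(theta), np.sin(theta)
    # points are row vectors: p @ _rotmat(theta) rotates p counterclockwise
    return np.array([[c, s], [-s, c]])


def _optimal_rotations(X: np.ndarray, C: np.ndarray) -> np.ndarray:
    """Rotation matrices R_i (det +1) minimising ||X_i R_i - C|| (batched)."""
    M = np.einsum("nki,kj->nij", X, C)
    U, _, Vt = np.linalg.svd(M)
    det = np.linalg.det(U @ Vt)
    U = U.copy()
    U[:, :, 1] *= np.sign(det)[:, None]
    return U @ Vt


def procrustes_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Procrustes distance between two configurations on unit preshapes
    (rotation-only alignment, no reflection)."""
    pa, pb = _preshape(a), _preshape(b)
    R = _optimal_rotations(pa[None], pb)[0]
    return float(np.sqrt(((pa @ R - pb) ** 2).sum()))


def _as_array_and_meta(
    landmark_sets: Sequence[LandmarkSet] | np.ndarray,
) -> tuple[np.ndarray, pd.DataFrame]:
    if isinstance(landmark_sets, np.ndarray):
        X = np.asarray(landmark_sets, dtype=float)
        if X.ndim != 3 or X.shape[2] != 2:
            raise ValueError("array input must have shape (n, k, 2)")
        meta = pd.DataFrame(
            {
                "specimen_id": [str(i) for i in range(len(X))],
                "family": pd.NA,
                "sex": pd.NA,
                "treatment": pd.NA,
                "side": "R",
                "replicate": 1,
            }
        )
        return X.copy(), meta
    sets = list(landmark_sets)
    if not sets:
        raise ValueError("empty dataset")
    ks = {s.coords.shape[0] for s in sets}
    if len(ks) != 1:
        raise ValueError(f"mixed landmark counts {sorted(ks)}")
    X = np.stack([s.coords for s in sets]).astype(float)
    meta = pd.DataFrame(
        {
            "specimen_id": [s.specimen_id for s in sets],
            "family": [s.family for s in sets],
            "sex": [s.sex for s in sets],
            "treatment": [s.treatment for s in sets],
            "side": [s.side for s in sets],
            "replicate": [s.replicate for s in sets],
        }
    )
    return X, meta


def gpa_fit(
    landmark_sets: Sequence[LandmarkSet] | np.ndarray,
    reflect_left: bool = True,
    tol: float = 1e-10,
    max_iter: int = 100,
) -> ProcrustesResult:
    """Generalised full Procrustes fit with tangent projection.

    All configurations (every specimen, side, replicate and treatment)
    enter one joint fit.  With ``reflect_left``, configurations whose
    metadata side is ``L`` are mirrored about the vertical axis first, so
    left and right wings live in the same shape space.

    The consensus orientation is standardised (major principal axis along
    x, first landmark's x >= 0), making the output reproducible across
    runs and input orders.
    """
    X, meta = _as_array_and_meta(landmark_sets)
    n, k = X.shape[0], X.shape[1]
    if n < 2:
        raise ValueError("need at least two configurations")
    if not np.isfinite(X).all():
        raise ValueError("landmarks contain NaN/inf")
    if reflect_left:
        left = meta["side"].astype(str).str.upper().str.startswith("L").to_numpy()
        X[left, :, 0] *= -1.0

    centred = X - X.mean(axis=1, keepdims=True)
    cs = np.sqrt((centred**2).sum(axis=(1, 2)))
    if np.any(cs <= 1e-300):
        bad = np.nonzero(cs <= 1e-300)[0]
        raise ValueError(f"degenerate configurations (zero centroid size) at indices {bad.tolist()}")
    P = centred / cs[:, None, None]

    consensus = P[0].copy()
    deltas: list[float] = []
    aligned = P
    for _ in range(max_iter):
        R = _optimal_rotations(P, consensus)
        aligned = np.einsum("nki,nij->nkj", P, R)
        new = aligned.mean(axis=0)
        new = new - new.mean(axis=0)
        new /= np.sqrt((new**2).sum())
        delta = float(np.sqrt(((new - consensus) ** 2).sum()))
        deltas.append(delta)
        consensus = new
        if delta < tol:
            break
    else:
        raise GPAConvergenceError(deltas)

    # final alignment pass against the converged consensus
    R = _optimal_rotations(P, consensus)
    aligned = np.einsum("nki,nij->nkj", P, R)

    # orientation convention: major principal axis of the consensus -> x,
    # sign fixed so that landmark 1 has non-negative x
    cov2 = consensus.T @ consensus
    evals, evecs = np.linalg.eigh(cov2)
    major = evecs[:, np.argmax(evals)]
    phi = float(np.arctan2(major[1], major[0]))
    Rstd = _rotmat(-phi)
    if (consensus @ Rstd)[0, 0] < 0:
        Rstd = Rstd @ _rotmat(np.pi)
    consensus = consensus @ Rstd
    aligned = aligned @ Rstd

    # tangent projection: remove components along the similarity-transform
    # directions at the consensus (scale = c, rotation = 90-degree-rotated c,
    # x/y translations); all four are mutually orthogonal here
    c = consensus.ravel()
    w = np.empty_like(consensus)
    w[:, 0] = -consensus[:, 1]
    w[:, 1] = consensus[:, 0]
    w = w.ravel()
    tx = np.tile([1.0, 0.0], k) / np.sqrt(k)
    ty = np.tile([0.0, 1.0], k) / np.sqrt(k)
    Q = np.stack([c, w / np.linalg.norm(w), tx, ty])
    Q, _ = np.linalg.qr(Q.T)  # orthonormalise defensively
    V = aligned.reshape(n, 2 * k) - c
    tangent = V - (V @ Q) @ Q.T

    ss = float(((aligned - consensus) ** 2).sum())
    return ProcrustesResult(
        aligned=aligned,
        tangent=tangent,
        consensus=consensus,
        centroid_sizes=cs,
        shape_dim=2 * k - 4,
        meta=meta,
        n_iterations=len(deltas),
        procrustes_ss=ss,
    )


def shape_pca(result: ProcrustesResult, n_components: int | None = None) -> ShapePCA:
    """PCA of the tangent coordinates (covariance-matrix eigendecomposition).

    At most 2k - 4 eigenvalues are nonzero; the eigenvalue sum equals the
    total tangent variance.
    """
    X = result.tangent
    n = X.shape[0]
    if n <= 2:
        raise ValueError("shape PCA requires more than two configurations")
    if n_components is None:
        n_components = result.shape_dim
    mean = X.mean(axis=0)
    cov = np.cov(X, rowvar=False, ddof=1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)[:n_components]
    evecs = evecs[:, order][:, :n_components]
    scores = (X - mean) @ evecs
    return ShapePCA(scores=scores, eigenvectors=evecs, eigenvalues=evals, mean=mean)


_IMAGE_RE = re.compile(r"^(?P<specimen>.+)_(?P<side>[LR])(?P<rep>\d+)\.[A-Za-z0-9]+$")


def load_dataset(tps_path: str | Path, meta_path: str | Path) -> list[LandmarkSet]:
    """Read a TPS file and its metadata CSV into labelled landmark sets.

    TPS records are joined to metadata rows on (specimen_id, side,
    replicate), parsed from each record's IMAGE name
    ``<specimen>_<side><replicate>.<ext>``.
    """
    records = read_tps(tps_path)
    meta = pd.read_csv(meta_path)
    missing = [c for c in META_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"metadata is missing columns {missing}")
    meta = meta.copy()
    meta["replicate"] = meta["replicate"].astype(int)
    key = meta.set_index(
        [meta["specimen_id"].astype(str), meta["side"].astype(str), meta["replicate"]]
    )
    if key.index.has_duplicates:
        raise ValueError("duplicated (specimen_id, side, replicate) rows in metadata")
    sets: list[LandmarkSet] = []
    for rec in records:
        m = _IMAGE_RE.match(rec.image)
        if m is None:
            raise ValueError(
                f"cannot parse specimen/side/replicate from IMAGE={rec.image!r}; "
                "expected '<specimen>_<side><replicate>.<ext>'"
            )
        idx = (m["specimen"], m["side"], int(m["rep"]))
        try:
            row = key.loc[idx]
        except KeyError as exc:
            raise ValueError(f"TPS record {rec.image!r} has no metadata row {idx}") from exc
        sets.append(
            LandmarkSet(
                coords=rec.coords,
                specimen_id=str(row["specimen_id"]),
                side=str(row["side"]),
                replicate=int(row["replicate"]),
                family=int(row["family"]),
                sex=str(row["sex"]),
                treatment=str(row["treatment"]),
                image_coords=rec.raw_coords,
                scale=rec.scale,
            )
        )
    return sets
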