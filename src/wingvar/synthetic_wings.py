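"""Synthetic wing-landmark datasets with a full quantitative-genetic
variance structure.

The generator emulates a split full-sib-family experiment: each of
``n_families`` families contributes insects of both sexes to a control and
a treated group, every insect has a left and a right wing, and every wing
is digitised twice.  The latent shape of insect *i* in family *f* under
treatment *t* is

    template + m_G(t) * g_f + t * (treatment_shape_effect + gxe_f) + e_i
             + side_sign * (da_vector + fa_i)

with independent isotropic Gaussian landmark displacements per layer
(genetic g, genotype-by-treatment gxe, individual e, fluctuating asymmetry
fa) and side_sign = +1 for right, -1 for left wings.  Each digitised
replicate adds measurement-error noise and a random similarity nuisance
transform (translation, rotation, pixel-scale jitter); left wings are
written mirrored about the vertical axis, as a camera sees them.  The
pixel-scale jitter is recorded as the TPS SCALE factor, playing the role
of the reference scale included in each photograph.

Treated-group SD multipliers on the individual, FA and genetic layers
emulate systematically larger variation after insecticide exposure; an
optional structured inflation adds treated-group individual variation
along one fixed shape direction, which is what makes individual-variation
covariance matrices (but not FA matrices) cluster by treatment downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .gpa import LandmarkSet, centroid_size, reflect, _rotmat
from .tps import TPSRecord, write_tps

__all__ = [
    "SimulationConfig",
    "NuisanceConfig",
    "DEFAULT_TEMPLATE",
    "lateral_dilatation_field",
    "generate_dataset",
    "write_dataset",
]

# Ten wing-like landmarks (vein-intersection positions along an elongated
# wing outline); normalised to centroid 0 / unit centroid size at use.
DEFAULT_TEMPLATE = np.array(
    [
        [0.05, 0.12],
        [0.22, 0.20],
        [0.42, 0.24],
        [0.66, 0.21],
        [0.88, 0.13],
        [1.00, 0.00],
        [0.78, -0.12],
        [0.52, -0.16],
        [0.28, -0.13],
        [0.08, -0.05],
    ]
)


def _normalise(template: np.ndarray) -> np.ndarray:
    t = np.asarray(template, dtype=float)
    t = t - t.mean(axis=0)
    cs = np.sqrt((t**2).sum())
    if cs <= 0:
        raise ValueError("template has zero centroid size")
    return t / cs


def lateral_dilatation_field(template: np.ndarray = DEFAULT_TEMPLATE) -> np.ndarray:
    """Unit-norm displacement field widening the wing laterally: each
    landmark moves away from the long axis in proportion to its offset."""
    t = _normalise(template)
    f = np.zeros_like(t)
    f[:, 1] = t[:, 1] - t[:, 1].mean()
    norm = np.sqrt((f**2).sum())
    return f / norm


def _default_shape_effect() -> np.ndarray:
    return 0.012 * lateral_dilatation_field()


def _default_da() -> np.ndarray:
    # fixed right-minus-left displacement concentrated on the distal part
    # of the wing (unit-norm pattern scaled to a small magnitude)
    pattern = np.zeros((10, 2))
    pattern[4] = [0.4, 0.2]
    pattern[5] = [0.6, -0.3]
    pattern[6] = [0.3, 0.4]
    pattern[7] = [-0.2, 0.3]
    pattern /= np.sqrt((pattern**2).sum())
    return 0.003 * pattern


@dataclass
class NuisanceConfig:
    """Per-image random similarity transform (digitisation nuisance)."""

    translation: float = 2.0        # uniform +/- range, same units as coordinates
    rotation: float = np.pi         # uniform +/- range in radians
    scale_jitter: tuple[float, float] = (0.8, 1.25)  # pixel-per-unit factor range

    def __post_init__(self) -> None:
        lo, hi = self.scale_jitter
        if not (0 < lo <= hi):
            raise ValueError("scale_jitter bounds must be positive and ordered")
        if self.translation < 0 or self.rotation < 0:
            raise ValueError("nuisance ranges must be non-negative")


@dataclass
class SimulationConfig:
    """Generating conditions for one synthetic dataset.

    SDs of the shape layers are per-landmark-coordinate displacements in
    unit-centroid-size shape units; the same values act as coefficients of
    variation of centroid size (scaled by ``size_baseline`` and
    ``size_noise_factor``).  ``variance_multipliers`` scales the layer SDs
    per treatment group.
    """

    n_families: int = 14
    n_per_cell: tuple[int, int] = (4, 20)   # insects per family x sex x treatment
    template: np.ndarray = field(default_factory=lambda: DEFAULT_TEMPLATE.copy())
    size_baseline: float = 7.0
    treatment_size_effect: float = 0.7
    treatment_shape_effect: np.ndarray = field(default_factory=_default_shape_effect)
    sigma_G: float = 0.008
    sigma_GxT: float = 0.004
    sigma_I: float = 0.010
    da_vector: np.ndarray = field(default_factory=_default_da)
    sigma_FA: float = 0.004
    sigma_ME: float = 0.002
    variance_multipliers: dict = field(
        default_factory=lambda: {"treated": {"sigma_I": 2.0, "sigma_FA": 2.0, "sigma_G": 2.0}}
    )
    family_scale_sd: float = 0.5       # lognormal sd of per-family FA/IV scale factors
    family_scales_shared: bool = True  # shared across treatments (preserves family ranks)
    iv_inflation_sd: float = 0.03      # treated-only structured individual variation
    iv_inflation_field: np.ndarray | None = None  # default: lateral dilatation direction
    sex_size_effect: float = 0.0
    allometry: float = 0.0             # size -> shape displacement per size unit
    size_noise_factor: float = 1.0     # 0 disables size variability (shape layers only)
    survival: dict | None = None       # optional per-treatment survival fraction (thins cohorts)
    nuisance: NuisanceConfig | None = field(default_factory=NuisanceConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        self.template = np.asarray(self.template, dtype=float)
        self.treatment_shape_effect = np.asarray(self.treatment_shape_effect, dtype=float)
        self.da_vector = np.asarray(self.da_vector, dtype=float)
        if self.template.ndim != 2 or self.template.shape[1] != 2 or self.template.shape[0] < 3:
            raise ValueError("template must be a k x 2 matrix with k >= 3")
        if centroid_size(self.template) <= 0:
            raise ValueError("template has zero centroid size")
        k = self.template.shape[0]
        for name in ("treatment_shape_effect", "da_vector"):
            if getattr(self, name).shape != (k, 2):
                raise ValueError(f"{name} must match the template shape {(k, 2)}")
        for name in ("sigma_G", "sigma_GxT", "sigma_I", "sigma_FA", "sigma_ME",
                     "family_scale_sd", "iv_inflation_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        lo, hi = self.n_per_cell
        if not (1 <= lo <= hi):
            raise ValueError("n_per_cell bounds must satisfy 1 <= lo <= hi")
        if self.n_families < 1:
            raise ValueError("n_families must be positive")
        if isinstance(self.nuisance, dict):
            self.nuisance = NuisanceConfig(**self.nuisance)
        if self.iv_inflation_field is None:
            self.iv_inflation_field = lateral_dilatation_field(self.template)
        else:
            self.iv_inflation_field = np.asarray(self.iv_inflation_field, dtype=float)
            if self.iv_inflation_field.shape != (k, 2):
                raise ValueError("iv_inflation_field must match the template shape")

    @property
    def k(self) -> int:
        return self.template.shape[0]

    def multiplier(self, treatment: str, sigma_name: str) -> float:
        return float(self.variance_multipliers.get(treatment, {}).get(sigma_name, 1.0))

    # --- YAML round trip -------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        for key in ("template", "treatment_shape_effect", "da_vector", "iv_inflation_field"):
            d[key] = np.asarray(d[key]).tolist()
        d["n_per_cell"] = list(d["n_per_cell"])
        if d["nuisance"] is not None:
            d["nuisance"]["scale_jitter"] = list(d["nuisance"]["scale_jitter"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "n_per_cell" in d:
            d["n_per_cell"] = tuple(d["n_per_cell"])
        if d.get("nuisance") is not None and isinstance(d["nuisance"], dict):
            nu = dict(d["nuisance"])
            if "scale_jitter" in nu:
                nu["scale_jitter"] = tuple(nu["scale_jitter"])
            d["nuisance"] = NuisanceConfig(**nu)
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict()))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


TREATMENTS = ("control", "treated")
SEXES = ("F", "M")
SIDES = ("R", "L")


def generate_dataset(
    config: SimulationConfig,
) -> tuple[list[LandmarkSet], pd.DataFrame, pd.DataFrame]:
    """Draw one dataset.

    Returns ``(landmark_sets, metadata, truth)``: one landmark set per
    digitised image (2 sides x 2 replicates per insect), a metadata table
    with one row per image, and a truth table of the realised per-layer
    SDs per treatment plus the per-family scale factors.

    Coordinates in the returned landmark sets are scale-calibrated (the
    pixel jitter has been multiplied out via the recorded SCALE factor,
    exactly as the TPS reader would do); the raw digitised coordinates and
    the scale are kept on each set for lossless TPS export.
    """
    cfg = config
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    k = cfg.k
    tmpl = _normalise(cfg.template)
    F = cfg.n_families

    # family-level draws (unit scale; treatment multipliers applied at use)
    g_shape = rng.normal(size=(F, k, 2))
    g_size = rng.normal(size=F)
    gxe_shape = rng.normal(size=(F, k, 2))
    gxe_size = rng.normal(size=F)
    if cfg.family_scale_sd > 0:
        if cfg.family_scales_shared:
            fa_scale = np.exp(rng.normal(0.0, cfg.family_scale_sd, size=F))
            iv_scale = np.exp(rng.normal(0.0, cfg.family_scale_sd, size=F))
            fa_scale = {t: fa_scale for t in TREATMENTS}
            iv_scale = {t: iv_scale for t in TREATMENTS}
        else:
            fa_scale = {t: np.exp(rng.normal(0.0, cfg.family_scale_sd, size=F)) for t in TREATMENTS}
            iv_scale = {t: np.exp(rng.normal(0.0, cfg.family_scale_sd, size=F)) for t in TREATMENTS}
    else:
        ones = np.ones(F)
        fa_scale = {t: ones for t in TREATMENTS}
        iv_scale = {t: ones for t in TREATMENTS}

    lo, hi = cfg.n_per_cell
    counts = rng.integers(lo, hi + 1, size=(F, len(SEXES), len(TREATMENTS)))
    if cfg.survival:
        for ti, t in enumerate(TREATMENTS):
            p = float(cfg.survival.get(t, 1.0))
            if not (0 < p <= 1):
                raise ValueError("survival fractions must be in (0, 1]")
            counts[:, :, ti] = rng.binomial(counts[:, :, ti], p)
    if (counts < 1).any():
        counts = np.maximum(counts, 1)  # keep every cell represented

    infl_unit = cfg.iv_inflation_field / max(np.sqrt((cfg.iv_inflation_field**2).sum()), 1e-300)

    sets: list[LandmarkSet] = []
    meta_rows: list[dict] = []
    for f in range(F):
        for si, sex in enumerate(SEXES):
            for ti, t in enumerate(TREATMENTS):
                is_treated = 1.0 if t == "treated" else 0.0
                m_G = cfg.multiplier(t, "sigma_G")
                m_I = cfg.multiplier(t, "sigma_I")
                m_FA = cfg.multiplier(t, "sigma_FA")
                sd_I = cfg.sigma_I * m_I * iv_scale[t][f]
                sd_FA = cfg.sigma_FA * m_FA * fa_scale[t][f]
                fam_shape = (
                    m_G * cfg.sigma_G * g_shape[f]
                    + is_treated * (cfg.treatment_shape_effect + cfg.sigma_GxT * gxe_shape[f])
                )
                fam_size_rel = (
                    m_G * cfg.sigma_G * g_size[f] + is_treated * cfg.sigma_GxT * gxe_size[f]
                )
                for i in range(counts[f, si, ti]):
                    specimen = f"fam{f + 1:02d}_{t[0]}_{sex}_{i + 1:02d}"
                    e_shape = rng.normal(size=(k, 2)) * sd_I
                    if is_treated and cfg.iv_inflation_sd > 0:
                        e_shape = e_shape + rng.normal() * cfg.iv_inflation_sd * infl_unit
                    fa_shape = rng.normal(size=(k, 2)) * sd_FA
                    e_size_rel = rng.normal() * sd_I
                    fa_size_rel = rng.normal() * sd_FA
                    latent = tmpl + fam_shape + e_shape
                    base_rel = fam_size_rel + e_size_rel
                    mean_size = (
                        cfg.size_baseline
                        + is_treated * cfg.treatment_size_effect
                        + (cfg.sex_size_effect if sex == "M" else 0.0)
                    )
                    for side in SIDES:
                        sgn = 1.0 if side == "R" else -1.0
                        shape_side = latent + sgn * (cfg.da_vector + fa_shape)
                        size_side = mean_size + cfg.size_baseline * cfg.size_noise_factor * (
                            base_rel + sgn * fa_size_rel
                        )
                        if cfg.allometry:
                            shape_side = shape_side + (
                                cfg.allometry * (size_side - cfg.size_baseline) * infl_unit
                            )
                        for rep in (1, 2):
                            me = rng.normal(size=(k, 2)) * cfg.sigma_ME
                            coords = size_side * (shape_side + me)
                            if side == "L":
                                coords = reflect(coords)
                            if cfg.nuisance is not None:
                                nu = cfg.nuisance
                                theta = rng.uniform(-nu.rotation, nu.rotation)
                                trans = rng.uniform(-nu.translation, nu.translation, size=2)
                                jit = rng.uniform(*nu.scale_jitter)
                                img = jit * (coords @ _rotmat(theta)) + trans
                                scale = 1.0 / jit
                                calibrated = img * scale  # same float op as the TPS reader
                            else:
                                img = coords
                                scale = None
                                calibrated = coords
                            sets.append(
                                LandmarkSet(
                                    coords=calibrated,
                                    specimen_id=specimen,
                                    side=side,
                                    replicate=rep,
                                    family=f + 1,
                                    sex=sex,
                                    treatment=t,
                                    image_coords=img,
                                    scale=scale,
                                )
                            )
                            meta_rows.append(
                                {
                                    "specimen_id": specimen,
                                    "family": f + 1,
                                    "sex": sex,
                                    "treatment": t,
                                    "side": side,
                                    "replicate": rep,
                                }
                            )
    meta = pd.DataFrame(meta_rows)

    truth_rows = []
    for t in TREATMENTS:
        for layer, base, mname in (
            ("G", cfg.sigma_G, "sigma_G"),
            ("GxT", cfg.sigma_GxT if t == "treated" else 0.0, None),
            ("I", cfg.sigma_I, "sigma_I"),
            ("FA", cfg.sigma_FA, "sigma_FA"),
            ("ME", cfg.sigma_ME, None),
        ):
            mult = cfg.multiplier(t, mname) if mname else 1.0
            truth_rows.append(
                {"treatment": t, "layer": layer, "family": pd.NA, "sigma": base * mult}
            )
        for f in range(F):
            truth_rows.append(
                {"treatment": t, "layer": "FA_family_scale", "family": f + 1,
                 "sigma": float(fa_scale[t][f])}
            )
            truth_rows.append(
                {"treatment": t, "layer": "IV_family_scale", "family": f + 1,
                 "sigma": float(iv_scale[t][f])}
            )
    truth = pd.DataFrame(truth_rows)
    return sets, meta, truth


def write_dataset(
    sets: Sequence[LandmarkSet],
    meta: pd.DataFrame,
    tps_path: str | Path,
    meta_path: str | Path,
) -> None:
    """Write a generated dataset as a TPS file plus a metadata CSV.

    Raw digitised coordinates and the SCALE factor are written when
    present, so reading the files back reproduces the calibrated
    coordinates exactly.
    """
    records = []
    for i, s in enumerate(sets):
        image = f"{s.specimen_id}_{s.side}{s.replicate}.jpg"
        records.append(
            TPSRecord(
                coords=s.coords,
                id=str(i + 1),
                image=image,
                scale=s.scale,
                raw_coords=s.image_coords if s.image_coords is not None else s.coords,
            )
        )
    write_tps(records, tps_path)
    meta.to_csv(meta_path, index=False)
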