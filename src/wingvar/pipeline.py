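"""End-to-end orchestration: simulate/read -> GPA -> mean models ->
asymmetry decompositions -> variance comparisons -> tau report ->
covariance matrices -> permutation tests -> PCO.

One root seed drives every stochastic stage through named substreams, so
a rerun with the same configuration is reproducible; deterministic stages
are byte-identical.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .asymmetry import (
    compare_variances,
    decomposition_table,
    genetic_variation,
    sides_anova,
)
from .gpa import ProcrustesResult, gpa_fit, load_dataset, shape_pca
from .matrix_tools import (
    build_matrices,
    distance_matrix,
    landmark_permutation_test,
    matrix_correlation,
    pco,
    reduce_basis,
)
from .mean_models import cva, reaction_norms, shape_mancova, size_anova
from .rank_stats import concordance_report
from .synthetic_wings import SimulationConfig, generate_dataset, write_dataset

__all__ = ["RunConfig", "PipelineStageError", "run_all", "STAGES", "specimen_table"]

STAGES = ["simulate", "read", "gpa", "means", "asym", "tau", "matrices", "perm", "pco"]


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        self.stage = stage
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")


@dataclass
class RunConfig:
    """One analysis run: exactly one of (tps+meta paths) or a simulation."""

    simulate: SimulationConfig | None = None
    tps: str | None = None
    meta: str | None = None
    outdir: str | None = None
    seed: int = 0
    by_sex: bool = True
    n_perm: int = 199          # all-pairs stage; standalone tests default to 999
    target_dim: int = 14
    pairwise_basis: str = "coordinate"   # basis for matrix correlations / permutation tests
    min_individuals: int = 3

    def __post_init__(self) -> None:
        has_paths = self.tps is not None or self.meta is not None
        if has_paths and self.simulate is not None:
            raise ValueError("give either input paths or a simulation config, not both")
        if has_paths and (self.tps is None or self.meta is None):
            raise ValueError("both --tps and --meta are required for file input")
        if not has_paths and self.simulate is None:
            self.simulate = SimulationConfig(seed=self.seed)

    def to_dict(self) -> dict:
        d = {
            "tps": self.tps, "meta": self.meta, "outdir": self.outdir,
            "seed": self.seed, "by_sex": self.by_sex, "n_perm": self.n_perm,
            "target_dim": self.target_dim, "pairwise_basis": self.pairwise_basis,
            "min_individuals": self.min_individuals,
            "simulate": self.simulate.to_dict() if self.simulate else None,
        }
        return d

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        if d.get("simulate") is not None:
            d["simulate"] = SimulationConfig.from_dict(d["simulate"])
        d.update(overrides)
        return cls(**d)


def specimen_table(result: ProcrustesResult) -> pd.DataFrame:
    """Specimen-level aggregation: centroid size and tangent coordinates
    averaged over the 2 sides x 2 replicates (avoids pseudo-replication in
    the mean models)."""
    meta = result.meta.copy()
    meta["cs"] = result.centroid_sizes
    tang_cols = [f"t{i}" for i in range(result.tangent.shape[1])]
    meta[tang_cols] = result.tangent
    agg = meta.groupby(["specimen_id", "family", "sex", "treatment"], sort=True).agg(
        {**{"cs": "mean"}, **{c: "mean" for c in tang_cols}}
    )
    counts = meta.groupby(["specimen_id", "family", "sex", "treatment"], sort=True).size()
    agg["n_wings"] = counts
    return agg.reset_index()


def _derived_seed(root: np.random.SeedSequence, index: int) -> int:
    return int(root.spawn(index + 1)[index].generate_state(1)[0] & 0x7FFFFFFF)


def run_all(config: RunConfig, upto: str = "pco") -> dict:
    """Run the analysis graph, returning a report bundle (dict of tables
    and result objects); writes each stage's CSVs when ``outdir`` is set.

    ``upto`` truncates the graph after the named stage.
    """
    if upto not in STAGES:
        raise ValueError(f"unknown stage {upto!r}; choose from {STAGES}")
    stop = STAGES.index(upto)
    root = np.random.SeedSequence(config.seed)
    bundle: dict = {"stages_run": []}
    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)

    def save(name: str, df: pd.DataFrame) -> None:
        if outdir is not None:
            df.to_csv(outdir / f"{name}.csv", index=False)

    def stage(name):
        bundle["stages_run"].append(name)

    # --- simulate / read -------------------------------------------------
    try:
        if config.simulate is not None:
            sim = config.simulate
            sets, meta, truth = generate_dataset(sim)
            bundle["truth"] = truth
            if outdir:
                write_dataset(sets, meta, outdir / "landmarks.tps", outdir / "metadata.csv")
                truth.to_csv(outdir / "truth.csv", index=False)
            stage("simulate")
        else:
            sets = load_dataset(config.tps, config.meta)
            meta = None
            stage("read")
    except PipelineStageError:
        raise
    except Exception as exc:
        raise PipelineStageError("simulate" if config.simulate else "read", exc) from exc
    bundle["n_configurations"] = len(sets)
    if stop <= 1:
        return bundle

    # --- GPA -------------------------------------------------------------
    try:
        result = gpa_fit(sets, reflect_left=True)
        pca = shape_pca(result)
        spec = specimen_table(result)
    except Exception as exc:
        raise PipelineStageError("gpa", exc) from exc
    bundle["gpa"] = result
    bundle["pca"] = pca
    bundle["specimens"] = spec
    if outdir:
        aligned = result.meta.copy()
        aligned["cs"] = result.centroid_sizes
        for i in range(result.aligned.shape[1]):
            aligned[f"x{i + 1}"] = result.aligned[:, i, 0]
            aligned[f"y{i + 1}"] = result.aligned[:, i, 1]
        save("aligned", aligned)
        save("specimens", spec)
    stage("gpa")
    if stop <= 2:
        _finish(bundle, config, outdir)
        return bundle

    tang_cols = [c for c in spec.columns if c.startswith("t") and c[1:].isdigit()]
    spec_tangent = spec[tang_cols].to_numpy()
    spec_pca = shape_pca_scores(spec_tangent, result.shape_dim)
    treatment = spec["treatment"].to_numpy()
    family = spec["family"].to_numpy()
    sex = spec["sex"].to_numpy()
    cs = spec["cs"].to_numpy()

    # --- mean models -----------------------------------------------------
    try:
        anova_pooled = size_anova(cs, treatment, family)
        bundle["size_anova"] = {"pooled": anova_pooled}
        if config.by_sex:
            bundle["size_anova"].update(size_anova(cs, treatment, family, sex=sex, by_sex=True))
        bundle["mancova"] = shape_mancova(spec_pca, treatment, family, cs)
        groups = np.char.add(
            np.char.add(family.astype(str), ":"), treatment.astype(str)
        )
        bundle["cva"] = cva(spec_pca, groups)
        rn_size, rn_size_sum = reaction_norms(cs, family, treatment, ["cs"])
        cv_scores = bundle["cva"].scores[:, : min(2, bundle["cva"].scores.shape[1])]
        rn_shape, rn_shape_sum = reaction_norms(
            cv_scores, family, treatment, [f"CV{i + 1}" for i in range(cv_scores.shape[1])]
        )
        bundle["reaction_norms"] = {
            "size": rn_size, "size_summary": rn_size_sum,
            "shape": rn_shape, "shape_summary": rn_shape_sum,
        }
    except Exception as exc:
        raise PipelineStageError("means", exc) from exc
    if outdir:
        for key, df in bundle["size_anova"].items():
            save(f"size_anova_{key}", df)
        save("mancova", bundle["mancova"])
        save("cva_groups", bundle["cva"].group_scores)
        save("reaction_norms_size", rn_size)
        save("reaction_norms_shape", rn_shape)
    stage("means")
    if stop <= 3:
        _finish(bundle, config, outdir)
        return bundle

    # --- asymmetry decompositions & variance comparisons -----------------
    try:
        wings = result.meta
        decomps = []
        for (fam, treat), grp in wings.groupby(["family", "treatment"], sort=True):
            idx = grp.index.to_numpy()
            common = dict(
                specimen=wings.loc[idx, "specimen_id"].to_numpy(),
                side=wings.loc[idx, "side"].to_numpy(),
                replicate=wings.loc[idx, "replicate"].to_numpy(),
                family=fam,
                treatment=treat,
            )
            decomps.append(
                sides_anova(result.centroid_sizes[idx], trait="size", **common)
            )
            decomps.append(
                sides_anova(
                    result.tangent[idx], trait="shape", shape_dim=result.shape_dim, **common
                )
            )
        bundle["asymmetry"] = decomps
        bundle["asymmetry_table"] = decomposition_table(decomps)

        comparisons = []
        for trait in ("size", "shape"):
            per_fam: dict = {}
            for d in decomps:
                if d.trait == trait:
                    per_fam.setdefault(d.family, {})[d.treatment] = d
            for fam, pair in sorted(per_fam.items()):
                if {"control", "treated"} <= set(pair):
                    for level in ("individual", "fa"):
                        comparisons.append(
                            compare_variances(pair["control"], pair["treated"], level)
                        )
        bundle["variance_comparisons"] = pd.DataFrame(
            [c.__dict__ for c in comparisons]
        )

        gen = {
            "size": genetic_variation(cs, family, treatment, trait="size"),
            "shape": genetic_variation(
                spec_tangent, family, treatment, trait="shape", shape_dim=result.shape_dim
            ),
        }
        bundle["genetic_variation"] = gen
        bundle["genetic_table"] = pd.DataFrame(
            [
                {
                    "trait": tr,
                    "ms_family_control": g.ms_family.get("control"),
                    "ms_family_treated": g.ms_family.get("treated"),
                    "df": g.df_family.get("control"),
                    "F": g.F,
                    "p": g.p,
                }
                for tr, g in gen.items()
            ]
        )
    except Exception as exc:
        raise PipelineStageError("asym", exc) from exc
    if outdir:
        save("asymmetry", bundle["asymmetry_table"])
        save("variance_comparisons", bundle["variance_comparisons"])
        save("genetic_variation", bundle["genetic_table"])
    stage("asym")
    if stop <= 4:
        _finish(bundle, config, outdir)
        return bundle

    # --- tau concordance -------------------------------------------------
    try:
        bundle["tau"] = concordance_report(decomps)
    except Exception as exc:
        raise PipelineStageError("tau", exc) from exc
    save("tau", bundle["tau"])
    stage("tau")
    if stop <= 5:
        _finish(bundle, config, outdir)
        return bundle

    # --- covariance matrices --------------------------------------------
    try:
        mset_coord = build_matrices(
            result.tangent, wings, min_individuals=config.min_individuals,
            basis=None, basis_kind="coordinate",
        )
        reduced, basis = reduce_basis(result.tangent, target_dim=config.target_dim)
        mset_reduced = build_matrices(
            reduced, wings, min_individuals=config.min_individuals,
            basis=basis, basis_kind="reduced",
        )
    except Exception as exc:
        raise PipelineStageError("matrices", exc) from exc
    bundle["matrices_coordinate"] = mset_coord
    bundle["matrices_reduced"] = mset_reduced
    if outdir:
        mdir = outdir / "matrices"
        mdir.mkdir(exist_ok=True)
        manifest_rows = []
        for m in mset_reduced.matrices:
            fname = m.label.replace(":", "_") + ".csv"
            pd.DataFrame(m.matrix).to_csv(mdir / fname, index=False)
            manifest_rows.append(
                {"label": m.label, "type": m.mtype, "family": m.family,
                 "treatment": m.treatment, "n": m.n, "file": fname}
            )
        pd.DataFrame(manifest_rows).to_csv(mdir / "manifest.csv", index=False)
    stage("matrices")
    if stop <= 6:
        _finish(bundle, config, outdir)
        return bundle

    # --- pairwise correlations + permutation tests -----------------------
    try:
        pair_set = mset_coord if config.pairwise_basis == "coordinate" else mset_reduced
        perm_seed = _derived_seed(root, 1)
        rng = np.random.default_rng(perm_seed)
        rows = []
        mats = pair_set.matrices
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for i in range(len(mats)):
                for j in range(i + 1, len(mats)):
                    if config.pairwise_basis == "coordinate":
                        r, pval = landmark_permutation_test(
                            mats[i].matrix, mats[j].matrix, n_perm=config.n_perm, rng=rng
                        )
                    else:
                        r = matrix_correlation(mats[i].matrix, mats[j].matrix)
                        pval = np.nan
                    rows.append(
                        {"a": mats[i].label, "b": mats[j].label, "r": r,
                         "distance": 1 - r**2, "p": pval}
                    )
        bundle["matrix_correlations"] = pd.DataFrame(rows)
    except Exception as exc:
        raise PipelineStageError("perm", exc) from exc
    save("matrix_correlations", bundle["matrix_correlations"])
    stage("perm")
    if stop <= 7:
        _finish(bundle, config, outdir)
        return bundle

    # --- PCO -------------------------------------------------------------
    try:
        bundle["pco_all"] = pco(mset_reduced)
        bundle["pco_individual"] = pco(mset_reduced.select("individual"))
        bundle["pco_fa"] = pco(mset_reduced.select("fa"))
    except Exception as exc:
        raise PipelineStageError("pco", exc) from exc
    if outdir:
        for key in ("pco_all", "pco_individual", "pco_fa"):
            emb = bundle[key]
            q = emb.coordinates.shape[1]
            df = pd.DataFrame(emb.coordinates, columns=[f"PCo{i + 1}" for i in range(q)])
            df.insert(0, "label", emb.labels)
            save(key, df)
            save(
                f"{key}_eigenvalues",
                pd.DataFrame({"eigenvalue": emb.eigenvalues}),
            )
    stage("pco")
    _finish(bundle, config, outdir)
    return bundle


def shape_pca_scores(tangent: np.ndarray, shape_dim: int) -> np.ndarray:
    """PCA scores of specimen-level tangent coordinates spanning the full
    shape space (the MANCOVA/CVA response variables)."""
    X = np.asarray(tangent, dtype=float)
    centred = X - X.mean(axis=0)
    _, s, Vt = np.linalg.svd(centred, full_matrices=False)
    return centred @ Vt[:shape_dim].T


def _finish(bundle: dict, config: RunConfig, outdir: Path | None) -> None:
    cfg_yaml = yaml.safe_dump(config.to_dict(), sort_keys=True)
    manifest = {
        "wingvar_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "seed": config.seed,
        "config_sha256": hashlib.sha256(cfg_yaml.encode()).hexdigest(),
        "stages_run": bundle["stages_run"],
    }
    bundle["manifest"] = manifest
    if outdir:
        (outdir / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=True))
        (outdir / "config.yaml").write_text(cfg_yaml)
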