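import numpy as np
import pandas as pd
import pytest

import wingvar as wv
from wingvar.mean_models import _pillai_f, sequential_linear_model

from conftest import clean_layer_config


def _toy_design(rng, n_per_cell=6, treat_effect=0.0, fam_sd=0.0, noise=1.0, families=4):
    rows = []
    for t in ("control", "treated"):
        for f in range(families):
            fam_eff = fam_sd * rng.normal()
            for _ in range(n_per_cell):
                rows.append(
                    {
                        "treatment": t,
                        "family": f + 1,
                        "y": (treat_effect if t == "treated" else 0.0)
                        + fam_eff
                        + noise * rng.normal(),
                    }
                )
    return pd.DataFrame(rows)


# --- size ANOVA ------------------------------------------------------------


def test_zero_between_group_differences_give_zero_treatment_ss():
    df = _toy_design(np.random.default_rng(0), noise=0.0)
    tab = wv.size_anova(df.y.to_numpy(), df.treatment.to_numpy(), df.family.to_numpy())
    assert tab.loc[tab.effect == "Treatment", "SS"].iloc[0] == pytest.approx(0.0, abs=1e-12)


def test_anova_df_and_ss_additivity(rng):
    df = _toy_design(rng, treat_effect=1.0, fam_sd=0.5)
    tab = wv.size_anova(df.y.to_numpy(), df.treatment.to_numpy(), df.family.to_numpy())
    n = len(df)
    assert tab.df.sum() == n - 1
    total = ((df.y - df.y.mean()) ** 2).sum()
    assert tab.SS.sum() == pytest.approx(total, rel=1e-10)
    assert np.allclose(tab.MS, tab.SS / tab.df)


@pytest.mark.parametrize("balanced", [True, False])
def test_sequential_ss_matches_statsmodels_type_one(rng, balanced):
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = _toy_design(rng, treat_effect=0.7, fam_sd=0.4)
    if not balanced:
        df = df.drop(index=df.sample(n=9, random_state=1).index).reset_index(drop=True)
    tab = wv.size_anova(df.y.to_numpy(), df.treatment.to_numpy(), df.family.to_numpy())
    fit = smf.ols("y ~ C(treatment) + C(family) + C(treatment):C(family)", data=df).fit()
    oracle = sm.stats.anova_lm(fit, typ=1)
    for mine, theirs in zip(
        ["Treatment", "Full-sib family", "Treatment x full-sib family"],
        ["C(treatment)", "C(family)", "C(treatment):C(family)"],
    ):
        row = tab[tab.effect == mine].iloc[0]
        assert row.SS == pytest.approx(oracle.loc[theirs, "sum_sq"], rel=1e-8)
        assert row.df == oracle.loc[theirs, "df"]
        assert row.F == pytest.approx(oracle.loc[theirs, "F"], rel=1e-8)
    if balanced:
        # on a balanced design sequential and marginal SS coincide
        oracle3 = sm.stats.anova_lm(
            smf.ols(
                "y ~ C(treatment, Sum) * C(family, Sum)", data=df
            ).fit(),
            typ=3,
        )
        row = tab[tab.effect == "Treatment"].iloc[0]
        assert row.SS == pytest.approx(oracle3.loc["C(treatment, Sum)", "sum_sq"], rel=1e-8)


def test_anova_f_invariant_to_affine_cs_rescaling(rng):
    df = _toy_design(rng, treat_effect=0.5, fam_sd=0.3)
    t1 = wv.size_anova(df.y.to_numpy(), df.treatment.to_numpy(), df.family.to_numpy())
    t2 = wv.size_anova(
        (3.7 * df.y + 11.0).to_numpy(), df.treatment.to_numpy(), df.family.to_numpy()
    )
    assert np.allclose(t1.F[:3], t2.F[:3], rtol=1e-10)


def test_empty_cell_is_named_in_error(rng):
    df = _toy_design(rng)
    df = df[~((df.treatment == "treated") & (df.family == 2))]
    with pytest.raises(ValueError, match="treated.*2|2.*treated"):
        wv.size_anova(df.y.to_numpy(), df.treatment.to_numpy(), df.family.to_numpy())


def test_by_sex_returns_one_table_per_sex(rng):
    df = _toy_design(rng)
    df["sex"] = np.where(np.arange(len(df)) % 2 == 0, "F", "M")
    out = wv.size_anova(
        df.y.to_numpy(), df.treatment.to_numpy(), df.family.to_numpy(),
        sex=df.sex.to_numpy(), by_sex=True,
    )
    assert set(out) == {"F", "M"}


# --- MANCOVA ---------------------------------------------------------------


def test_pillai_single_response_equals_univariate_f(rng):
    df = _toy_design(rng, treat_effect=0.8, fam_sd=0.3)
    cs = rng.normal(size=len(df))
    uni = wv.size_anova(df.y.to_numpy(), df.treatment.to_numpy(), df.family.to_numpy())
    man = wv.shape_mancova(
        df.y.to_numpy()[:, None], df.treatment.to_numpy(), df.family.to_numpy(), cs
    )
    # the univariate model has no covariate, so compare against a Pillai
    # model where the covariate enters last: earlier sequential rows match
    effects, E, df_e = sequential_linear_model(
        df.y.to_numpy()[:, None],
        [
            ("Treatment", (df.treatment.to_numpy() == "treated").astype(float)[:, None]),
        ],
    )
    name, q, H = effects[0]
    V = H[0, 0] / (H[0, 0] + E[0, 0])
    f, df1, df2, p = _pillai_f(V, q, 1, df_e)
    # for one response Pillai V is the partial R-squared and its F is the ANOVA F
    f_direct = (H[0, 0] / q) / (E[0, 0] / df_e)
    assert f == pytest.approx(f_direct, rel=1e-8)
    row = man[man.effect == "Treatment"].iloc[0]
    urow = uni[uni.effect == "Treatment"].iloc[0]
    assert row.df == urow.df


def test_pillai_zero_when_group_means_identical(rng):
    n = 80
    Y = rng.normal(size=(n, 3))
    treatment = np.repeat(["control", "treated"], n // 2)
    family = np.tile([1, 2], n // 2)
    Y -= np.stack([Y[treatment == t].mean(axis=0) for t in treatment])  # identical means
    tab = wv.shape_mancova(Y, treatment, family, rng.normal(size=n))
    assert tab.loc[tab.effect == "Treatment", "pillai"].iloc[0] == pytest.approx(0.0, abs=1e-10)


def test_mancova_matches_statsmodels_pillai_on_balanced_design(rng):
    from statsmodels.multivariate.manova import MANOVA

    n_cell, fams = 8, 3
    rows, Y = [], []
    for t in ("control", "treated"):
        for f in range(fams):
            mu = rng.normal(size=4) * 0.5
            for _ in range(n_cell):
                rows.append({"treatment": t, "family": f + 1})
                Y.append(mu + rng.normal(size=4))
    df = pd.DataFrame(rows)
    Y = np.stack(Y)
    effects, E, df_e = sequential_linear_model(
        Y,
        [
            ("treatment", (df.treatment == "treated").to_numpy(float)[:, None]),
            ("family", pd.get_dummies(df.family, drop_first=True).to_numpy(float)),
            (
                "interaction",
                pd.get_dummies(df.family, drop_first=True).to_numpy(float)
                * (df.treatment == "treated").to_numpy(float)[:, None],
            ),
        ],
    )
    data = df.copy()
    for i in range(4):
        data[f"y{i}"] = Y[:, i]
    mv = MANOVA.from_formula(
        "y0 + y1 + y2 + y3 ~ C(treatment, Sum) * C(family, Sum)", data=data
    ).mv_test()
    keys = {
        "treatment": "C(treatment, Sum)",
        "family": "C(family, Sum)",
        "interaction": "C(treatment, Sum):C(family, Sum)",
    }
    for name, q, H in effects:
        V = np.trace(H @ np.linalg.inv(H + E))
        stat = mv.results[keys[name]]["stat"]
        assert V == pytest.approx(stat.loc["Pillai's trace", "Value"], rel=1e-8)


def test_mancova_invariant_to_rotation_of_response_basis(rng):
    df = _toy_design(rng, treat_effect=0.5, fam_sd=0.3, families=3, n_per_cell=10)
    Y = rng.normal(size=(len(df), 5)) + df.y.to_numpy()[:, None] * 0.3
    cs = rng.normal(size=len(df))
    t1 = wv.shape_mancova(Y, df.treatment.to_numpy(), df.family.to_numpy(), cs)
    Q, _ = np.linalg.qr(rng.normal(size=(5, 5)))
    t2 = wv.shape_mancova(Y @ Q, df.treatment.to_numpy(), df.family.to_numpy(), cs)
    assert np.allclose(t1.pillai[:4], t2.pillai[:4], atol=1e-8)
    assert np.allclose(t1.F[:4], t2.F[:4], rtol=1e-6)


def test_mancova_rejects_undersized_samples(rng):
    Y = rng.normal(size=(10, 8))
    treatment = np.repeat(["control", "treated"], 5)
    family = np.tile([1, 2], 5)
    with pytest.raises(ValueError, match="too small"):
        wv.shape_mancova(Y, treatment, family, rng.normal(size=10))


# --- CVA -------------------------------------------------------------------


def test_cva_axis_aligns_with_separation_direction(rng):
    sep = np.array([1.0, 2.0, -1.0]) / np.sqrt(6)
    X = np.vstack(
        [rng.normal(size=(400, 3)) * 0.5, rng.normal(size=(400, 3)) * 0.5 + 6 * sep]
    )
    groups = np.repeat(["a", "b"], 400)
    res = wv.cva(X, groups)
    cv1 = res.loadings[:, 0] / np.linalg.norm(res.loadings[:, 0])
    assert abs(cv1 @ sep) > 0.99


def test_cva_identical_group_means_gives_null_eigenvalues(rng):
    X = rng.normal(size=(40, 3))
    groups = np.repeat(["a", "b"], 20)
    X[groups == "a"] -= X[groups == "a"].mean(axis=0)
    X[groups == "b"] -= X[groups == "b"].mean(axis=0)
    res = wv.cva(X, groups)
    assert (res.eigenvalues < 1e-10).all()


def test_cva_matches_generalized_eigenproblem_oracle(rng):
    X = np.vstack(
        [
            rng.normal(size=(30, 2)) + [0, 0],
            rng.normal(size=(30, 2)) + [3, 1],
            rng.normal(size=(30, 2)) + [1, 4],
        ]
    )
    groups = np.repeat(["a", "b", "c"], 30)
    res = wv.cva(X, groups)
    # brute-force oracle: eigenvalues of W^-1 B
    means = np.stack([X[groups == g].mean(axis=0) for g in "abc"])
    grand = X.mean(axis=0)
    B = (30 * (means - grand).T @ (means - grand)) / 2
    W = sum(
        (X[groups == g] - means[i]).T @ (X[groups == g] - means[i])
        for i, g in enumerate("abc")
    ) / (90 - 3)
    evals = np.sort(np.real(np.linalg.eigvals(np.linalg.inv(W) @ B)))[::-1]
    assert np.allclose(res.eigenvalues, evals[:2], atol=1e-8)


def test_cva_scores_have_unit_within_group_variance(small_gpa):
    res = small_gpa
    from wingvar.pipeline import shape_pca_scores, specimen_table

    spec = specimen_table(res)
    tang = spec[[c for c in spec.columns if c.startswith("t") and c[1:].isdigit()]].to_numpy()
    scores = shape_pca_scores(tang, res.shape_dim)
    groups = spec.family.astype(str) + ":" + spec.treatment
    out = wv.cva(scores, groups.to_numpy())
    uniq = np.unique(out.groups)
    pooled = np.zeros(out.scores.shape[1])
    n = 0
    for g in uniq:
        sub = out.scores[out.groups == g]
        pooled += ((sub - sub.mean(axis=0)) ** 2).sum(axis=0)
        n += len(sub)
    within_var = pooled / (n - len(uniq))
    assert np.allclose(within_var, 1.0, atol=1e-6)
    assert len(out.eigenvalues) <= min(len(uniq) - 1, scores.shape[1])


# --- reaction norms --------------------------------------------------------


def test_parallel_reaction_norms_have_zero_parallelism_variance():
    family = np.repeat([1, 2, 3], 4)
    treatment = np.tile(["control", "control", "treated", "treated"], 3)
    base = np.array([10.0, 10.0, 12.5, 12.5])
    values = np.concatenate([base, base + 1, base + 2])  # same +2.5 shift per family
    table, summary = wv.reaction_norms(values, family, treatment)
    assert np.allclose(table.difference, 2.5)
    assert summary.parallelism_variance.iloc[0] == pytest.approx(0.0, abs=1e-12)


def test_reaction_norm_toy_numbers_match_hand_arithmetic():
    family = np.array([1, 1, 1, 2, 2, 2, 2])
    treatment = np.array(
        ["control", "control", "treated", "control", "treated", "treated", "treated"]
    )
    values = np.array([4.0, 6.0, 9.0, 10.0, 7.0, 8.0, 12.0])
    table, _ = wv.reaction_norms(values, family, treatment)
    f1 = table[table.family == 1].iloc[0]
    assert f1.control_mean == 5.0 and f1.treated_mean == 9.0 and f1.difference == 4.0
    f2 = table[table.family == 2].iloc[0]
    assert f2.control_mean == 10.0 and f2.treated_mean == 9.0 and f2.difference == -1.0


def test_family_missing_a_treatment_excluded_with_warning():
    family = np.array([1, 1, 2])
    treatment = np.array(["control", "treated", "control"])
    values = np.array([1.0, 2.0, 3.0])
    with pytest.warns(UserWarning, match="family 2"):
        table, _ = wv.reaction_norms(values, family, treatment)
    assert set(table.family) == {1}


def test_gxt_increases_reaction_norm_spread():
    """Genetic variation for plasticity shows up as non-parallel norms."""
    spreads = {0.0: [], 0.02: []}
    for seed in range(6):
        for gxt in spreads:
            cfg = clean_layer_config(
                n_families=10, n_per_cell=(12, 12), sigma_GxT=gxt, sigma_I=0.005,
                size_noise_factor=1.0, seed=100 + seed,
            )
            sets, meta, _ = wv.generate_dataset(cfg)
            cs = np.array([wv.centroid_size(s.coords) for s in sets])
            df = meta.copy()
            df["cs"] = cs
            spec = df.groupby(["specimen_id", "family", "treatment"]).cs.mean().reset_index()
            _, summary = wv.reaction_norms(
                spec.cs.to_numpy(), spec.family.to_numpy(), spec.treatment.to_numpy()
            )
            spreads[gxt].append(summary.parallelism_variance.iloc[0])
    assert np.mean(spreads[0.02]) > np.mean(spreads[0.0])
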