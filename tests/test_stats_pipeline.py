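"""Statistical battery: rank tests, effect sizes, PCA, correlations, slopes."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from raftscape.stats_pipeline import (
    cohens_d,
    cohens_f2,
    compare_slopes,
    correlation_heatmap,
    forest_table,
    mann_whitney,
    pca_signature,
    simple_regression,
    subject_table,
)


def enumeration_p_value(x, y):
    """Independent oracle: exact two-sided Mann-Whitney p by full enumeration.

    Enumerates every assignment of the pooled values into an |x|-subset,
    computes U for each, and counts assignments at least as extreme as
    the observed U on either tail.
    """
    x, y = list(x), list(y)
    pooled = x + y
    n1 = len(x)

    def u_stat(sub):
        rest = list(pooled)
        for v in sub:
            rest.remove(v)
        return sum(1 for a in sub for b in rest if a > b)

    u_obs = u_stat(x)
    mean_u = n1 * len(y) / 2.0
    dev = abs(u_obs - mean_u)
    total = extreme = 0
    for combo in itertools.combinations(range(len(pooled)), n1):
        sub = [pooled[i] for i in combo]
        total += 1
        if abs(u_stat(sub) - mean_u) >= dev - 1e-12:
            extreme += 1
    return extreme / total


def test_mann_whitney_small_sample_example():
    u, p, method = mann_whitney([1, 2], [3, 4])
    assert u == 0
    assert method == "exact"
    assert p == pytest.approx(1 / 3)


def test_mann_whitney_identical_samples_degenerate():
    with pytest.warns(UserWarning, match="identical"):
        u, p, _ = mann_whitney([2.0, 2.0, 2.0], [2.0, 2.0, 2.0])
    assert p == 1.0
    assert u == 9 / 2


def test_mann_whitney_equal_distributions_symmetric():
    x = [1.0, 4.0, 7.0]
    y = [2.0, 5.0, 8.0]
    u, p, _ = mann_whitney(x, y)
    uy, _, _ = mann_whitney(y, x)
    assert u + uy == len(x) * len(y)


@given(
    st.lists(st.integers(0, 50), min_size=2, max_size=5),
    st.lists(st.integers(0, 50), min_size=2, max_size=5),
)
def test_mann_whitney_u_identity(xs, ys):
    """U_x + U_y = n1*n2 whenever a U statistic is defined."""
    ux, _, _ = mann_whitney(xs, ys)
    uy, _, _ = mann_whitney(ys, xs)
    assert ux + uy == pytest.approx(len(xs) * len(ys))


@pytest.mark.parametrize("n", [2, 3, 4])
def test_mann_whitney_exact_agrees_with_enumeration(n):
    """Exact branch equals the full-enumeration oracle on a value grid."""
    grid = list(range(1, 2 * n + 1))
    for combo in itertools.combinations(grid, n):
        x = list(combo)
        y = [v for v in grid if v not in x]
        _, p, method = mann_whitney(x, y)
        assert method == "exact"
        assert p == pytest.approx(enumeration_p_value(x, y), abs=1e-12)


def test_cohens_d_hand_example():
    res = cohens_d([1, 2, 3], [4, 5, 6])
    assert res.d == pytest.approx(-3.0)
    assert res.ci_low < res.d < res.ci_high
    assert res.large_effect


def test_cohens_d_antisymmetry_and_affine_invariance():
    x = [1.0, 2.5, 3.1, 4.0]
    y = [2.0, 3.0, 5.5, 6.1]
    a = cohens_d(x, y)
    b = cohens_d(y, x)
    assert b.d == pytest.approx(-a.d)
    assert (b.ci_low, b.ci_high) == pytest.approx((-a.ci_high, -a.ci_low))
    scaled = cohens_d([3 * v + 7 for v in x], [3 * v + 7 for v in y])
    assert scaled.d == pytest.approx(a.d)


def test_cohens_d_zero_spread_flagged():
    res = cohens_d([2.0, 2.0], [2.0, 2.0])
    assert res.undefined


@pytest.mark.parametrize("r2, expected", [(0.0, 0.0), (0.5, 1.0), (0.847, 0.847 / 0.153)])
def test_cohens_f2(r2, expected):
    assert cohens_f2(r2) == pytest.approx(expected)


def test_cohens_f2_edges():
    assert cohens_f2(1.0) == np.inf
    with pytest.raises(ValueError):
        cohens_f2(1.2)


def test_pca_two_collinear_variables():
    rng = np.random.default_rng(0)
    x = rng.normal(size=30)
    df = pd.DataFrame({"a": x, "b": 2 * x + 1})
    res = pca_signature(df, ["G1"] * 15 + ["G2"] * 15, n_components=1)
    assert res.variance_fraction[0] == pytest.approx(1.0)
    assert res.eigenvalues.sum() == pytest.approx(2.0)


def test_pca_recovers_planted_two_factor_structure():
    """Two orthogonal latent factors on disjoint variable blocks."""
    rng = np.random.default_rng(1)
    n = 100
    f1, f2 = rng.normal(size=n), rng.normal(size=n)
    cols = {}
    for k in range(4):
        cols[f"a{k}"] = f1 + 0.1 * rng.normal(size=n)
    for k in range(4):
        cols[f"b{k}"] = f2 + 0.1 * rng.normal(size=n)
    df = pd.DataFrame(cols)
    res = pca_signature(df, ["G1"] * 50 + ["G2"] * 50, n_components=2)
    assert res.variance_fraction.sum() > 0.95
    # varimax loads each block on its own component
    load = res.loadings
    a_comp = load.loc[[f"a{k}" for k in range(4)]].abs().idxmax(axis=1)
    b_comp = load.loc[[f"b{k}" for k in range(4)]].abs().idxmax(axis=1)
    assert len(set(a_comp)) == 1 and len(set(b_comp)) == 1
    assert set(a_comp) != set(b_comp)


def test_pca_group_shift_detected_on_single_factor():
    """A group offset planted on one latent factor shows up in that factor's ANOVA."""
    rng = np.random.default_rng(2)
    n = 50
    groups = np.array(["G1"] * n + ["G2"] * n)
    f1 = rng.normal(size=2 * n)
    f2 = rng.normal(size=2 * n) + np.where(groups == "G2", 2.0, 0.0)
    cols = {}
    for k in range(4):
        cols[f"a{k}"] = f1 + 0.15 * rng.normal(size=2 * n)
    for k in range(4):
        cols[f"b{k}"] = f2 + 0.15 * rng.normal(size=2 * n)
    res = pca_signature(pd.DataFrame(cols), groups, n_components=2)
    shifted = res.loadings.loc[[f"b{k}" for k in range(4)]].abs().mean().idxmax()
    quiet = [c for c in res.loadings.columns if c != shifted][0]
    comp = {c: i for i, c in enumerate(res.loadings.columns)}
    assert res.anova_p[comp[shifted]] < 0.01
    assert res.anova_p[comp[quiet]] > 0.1


def test_pca_rotation_preserves_retained_variance():
    rng = np.random.default_rng(3)
    df = pd.DataFrame(rng.normal(size=(40, 6)), columns=list("abcdef"))
    res = pca_signature(df, ["G1"] * 20 + ["G2"] * 20, n_components=2)
    retained = res.eigenvalues[:2].sum()
    assert (res.loadings.to_numpy() ** 2).sum() == pytest.approx(retained, rel=1e-8)
    assert res.eigenvalues.sum() / 6 == pytest.approx(1.0)
    assert np.abs(res.scores.mean(axis=0)).max() < 1e-8


def test_pca_drops_constant_variable():
    rng = np.random.default_rng(4)
    df = pd.DataFrame({"a": rng.normal(size=20), "b": rng.normal(size=20), "c": 1.0})
    with pytest.warns(UserWarning, match="constant"):
        res = pca_signature(df, ["G1"] * 10 + ["G2"] * 10, n_components=2)
    assert res.dropped == ("c",)


def test_correlation_heatmap_exact_line(small_cohort):
    heat = correlation_heatmap(small_cohort, ["PE"], ["20:4n-6", "22:6n-3"])
    for g, mat in heat.r.items():
        assert np.all(np.abs(mat.to_numpy()) <= 1.0)
        assert heat.r_squared[g].to_numpy() == pytest.approx(mat.to_numpy() ** 2)


def test_correlation_heatmap_perfect_and_independent():
    rng = np.random.default_rng(5)
    n = 500
    df = pd.DataFrame({
        "group": ["A"] * n + ["B"] * n,
        "x": np.concatenate([rng.normal(size=n), rng.normal(size=n)]),
    })
    df["y"] = 2 * df["x"]
    z = np.concatenate([rng.normal(size=n), rng.normal(size=n)])
    df["z"] = z
    heat = correlation_heatmap([], ["x"], ["y", "z"], value_frame=df)
    for g in heat.groups:
        assert heat.r[g].loc["x", "y"] == pytest.approx(1.0)
        assert abs(heat.r[g].loc["x", "z"]) < 0.1  # independent at n=500
    assert heat.difference_q.loc["x", "z"] < 0.3


def test_correlation_heatmap_sign_pattern_matches_groups(recovery_cohort):
    """PE row: positive with arachidonate in controls, negative in ALS."""
    heat = correlation_heatmap(recovery_cohort, ["PE"], ["20:4n-6"])
    assert heat.r["NSL"].loc["PE", "20:4n-6"] > 0.5
    assert heat.r["ALS"].loc["PE", "20:4n-6"] < -0.8
    assert heat.difference_q.loc["PE", "20:4n-6"] > 1.0


def test_simple_regression_f2():
    rng = np.random.default_rng(6)
    x = rng.normal(size=50)
    y = 2 * x + 0.1 * rng.normal(size=50)
    res = simple_regression(x, y)
    assert res.beta == pytest.approx(2.0, rel=0.05)
    assert res.f_squared == pytest.approx(res.r_squared / (1 - res.r_squared))


def test_compare_slopes_identical_groups_null():
    rng = np.random.default_rng(7)
    x = rng.normal(size=20)
    y = 1.5 * x + 0.2 * rng.normal(size=20)
    res = compare_slopes(np.tile(x, 2), np.tile(y, 2), ["A"] * 20 + ["B"] * 20)
    assert res.f_stat == pytest.approx(0.0, abs=1e-12)
    assert res.p_value == pytest.approx(1.0, abs=1e-9)


def test_compare_slopes_recovers_planted_heterogeneity():
    """Planted slopes -2.59 vs -0.07 are recovered and flagged."""
    rng = np.random.default_rng(8)
    n = 20
    x = np.concatenate([rng.uniform(30, 45, n), rng.uniform(30, 45, n)])
    groups = np.array(["ALS"] * n + ["NSL"] * n)
    slopes = np.where(groups == "ALS", -2.59, -0.07)
    y = 10 + slopes * x + 0.8 * rng.normal(size=2 * n)
    res = compare_slopes(x, y, groups)
    assert res.beta_by_group["ALS"] == pytest.approx(-2.59, rel=0.10)
    assert res.beta_by_group["NSL"] == pytest.approx(-0.07, abs=0.26)
    assert res.p_value < 0.01
    assert res.df == (1, 2 * n - 4)


def test_compare_slopes_scale_equivariance():
    rng = np.random.default_rng(9)
    x = rng.normal(size=30)
    y = np.concatenate([2 * x[:15], -1 * x[15:]]) + 0.1 * rng.normal(size=30)
    g = ["A"] * 15 + ["B"] * 15
    a = compare_slopes(x, y, g)
    b = compare_slopes(x, 2 * y, g)
    assert b.beta_by_group["A"] == pytest.approx(2 * a.beta_by_group["A"])
    assert b.f_stat == pytest.approx(a.f_stat)
    assert b.p_value == pytest.approx(a.p_value)


def test_compare_slopes_singular_design_names_group():
    with pytest.raises(ValueError, match="no variance"):
        compare_slopes(
            [1.0, 1.0, 1.0, 0.0, 1.0, 2.0],
            [1.0, 2.0, 3.0, 1.0, 2.0, 3.0],
            ["A", "A", "A", "B", "B", "B"],
        )


def test_forest_table_single_token_null(small_cohort):
    table = forest_table(small_cohort, tokens=["16:0"])
    assert set(table.index) == {"16:0"}
    assert {"d", "ci_low", "ci_high", "u_stat", "p_value", "pct_change"} <= set(table.columns)


def test_forest_table_null_config_rarely_flags():
    """With no planted effects, few tokens reach |d| > 0.8 at n=20/group."""
    import raftscape as rs

    cfg = rs.default_config(n_nsl=20, n_als=20, seed=11)
    als = cfg.groups[1]
    als.mean_fatty_acids = dict(cfg.groups[0].mean_fatty_acids)
    als.mean_lipid_classes = dict(cfg.groups[0].mean_lipid_classes)
    als.correlation_plan = list(cfg.groups[0].correlation_plan)
    table = forest_table(rs.generate_cohort(cfg))
    assert table["large_effect"].mean() <= 0.10


def test_forest_table_fdr_option(small_cohort):
    table = forest_table(small_cohort, fdr=True)
    ok = table["p_adjusted"].notna()
    assert (table.loc[ok, "p_adjusted"] >= table.loc[ok, "p_value"] - 1e-12).all()
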