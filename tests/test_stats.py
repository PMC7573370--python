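"""Evaluation statistics: Friedman ranks, correlation, clustering, PCA,
kNN grading, color grading charts and line fits."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from phenopot.datasets import lettuce_dynamic_traits
from phenopot.stats import (build_cgc, cluster_traits, correlation_matrix,
                            fit_line, friedman_test, knn_grading, pca_traits,
                            pooled_rank_report)


# ----------------------------------------------------------- Friedman

def test_friedman_on_geometric_dynamic_traits():
    geo, _ = lettuce_dynamic_traits()
    res = friedman_test(geo.T)          # 16 blocks × 3 varieties
    assert np.round(res.mean_ranks, 2).tolist() == [2.06, 2.38, 1.56]
    assert res.chi2 == pytest.approx(6.143, abs=5e-4)
    assert res.chi2_uncorrected == pytest.approx(5.375, abs=5e-4)
    assert res.pvalue == pytest.approx(0.046, abs=5e-3)


def test_friedman_on_color_dynamic_traits():
    _, col = lettuce_dynamic_traits()
    res = friedman_test(col.T)          # 14 blocks × 3 varieties
    assert np.round(res.mean_ranks, 2).tolist() == [1.82, 1.50, 2.68]
    assert res.chi2 == pytest.approx(10.582, abs=5e-4)
    assert res.pvalue == pytest.approx(0.005, abs=5e-3)


def test_friedman_complete_ties_are_degenerate():
    x = np.tile([[3.0, 3.0, 3.0]], (5, 1))
    res = friedman_test(x)
    assert res.degenerate
    assert res.chi2 == 0.0 and res.pvalue == 1.0
    assert np.allclose(res.mean_ranks, 2.0)


def test_friedman_without_ties_equals_uncorrected_and_scipy(rng):
    x = rng.normal(size=(12, 4))
    res = friedman_test(x)
    assert res.chi2 == pytest.approx(res.chi2_uncorrected, rel=1e-12)
    ref_stat, ref_p = sps.friedmanchisquare(*x.T)
    assert res.chi2 == pytest.approx(ref_stat, rel=1e-10)
    assert res.pvalue == pytest.approx(ref_p, rel=1e-10)


def test_friedman_rank_sums_match_brute_force_on_random_matrices(rng):
    """Exhaustive comparison-count ranking oracle on 4×3 matrices."""
    for _ in range(20):
        x = rng.integers(0, 5, size=(4, 3)).astype(float)  # ties likely
        res = friedman_test(x)
        oracle = np.zeros(3)
        for row in x:
            for j, v in enumerate(row):
                smaller = np.sum(row < v)
                equal = np.sum(row == v)
                oracle[j] += smaller + (equal + 1) / 2.0   # average ranks
        assert np.allclose(res.rank_sums, oracle)


def test_friedman_invariant_under_monotone_block_transforms(rng):
    x = rng.uniform(1.0, 2.0, size=(10, 3))
    res = friedman_test(x)
    warped = np.vstack([np.exp(row) if i % 2 else row**3
                        for i, row in enumerate(x)])
    res2 = friedman_test(warped)
    assert res2.chi2 == pytest.approx(res.chi2, rel=1e-12)


def test_friedman_mean_ranks_average_to_half_k_plus_one(rng):
    x = rng.normal(size=(9, 5))
    res = friedman_test(x)
    assert res.mean_ranks.mean() == pytest.approx((5 + 1) / 2.0)


def test_friedman_input_validation():
    with pytest.raises(ValueError):
        friedman_test(np.zeros((1, 3)))
    with pytest.raises(ValueError):
        friedman_test(np.array([[1.0, np.nan], [2.0, 3.0]]))


def test_pooled_rank_report_on_bundled_tables():
    geo, col = lettuce_dynamic_traits()
    ranks = pooled_rank_report([geo, col])
    # AC-CA is the largest of the 30 pooled columns in every variety row
    assert ranks["AC-CA"] == 30.0
    # AC-PA and AC-AXS are duplicated columns → tied average ranks
    assert ranks["AC-PA"] == pytest.approx(28.5)
    assert ranks["AC-AXS"] == pytest.approx(28.5)
    assert ((ranks >= 1.0) & (ranks <= 30.0)).all()


# -------------------------------------------------------- correlations

def test_correlation_matrix_basics(rng):
    x = rng.normal(size=100)
    df = pd.DataFrame({"x": x, "y2": 2 * x + 1.0,
                       "z": rng.normal(size=100)})
    r, p, stars = correlation_matrix(df)
    assert r.loc["x", "x"] == 1.0
    assert r.loc["x", "y2"] == pytest.approx(1.0)
    assert stars.loc["x", "y2"] == "**"
    assert abs(r.loc["x", "z"]) < 0.3


def test_correlation_against_direct_formula():
    df = pd.DataFrame({"a": [1.0, 2.0, 4.0, 4.5, 7.0],
                       "b": [0.5, 1.9, 3.1, 5.2, 6.0]})
    r, _p, _ = correlation_matrix(df)
    a, b = df["a"], df["b"]
    manual = (((a - a.mean()) * (b - b.mean())).sum() / (len(a) - 1)
              / (a.std(ddof=1) * b.std(ddof=1)))
    assert r.loc["a", "b"] == pytest.approx(manual, abs=1e-12)


def test_zero_variance_column_yields_nan():
    df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "c": [5.0, 5.0, 5.0]})
    r, _p, _ = correlation_matrix(df)
    assert np.isnan(r.loc["a", "c"])


# ---------------------------------------------------------- clustering

def test_duplicated_columns_merge_first_at_zero_distance(rng):
    x = rng.normal(size=50)
    df = pd.DataFrame({"a": x, "a_copy": x, "b": rng.normal(size=50)})
    res = cluster_traits(df)
    first = res.linkage[0]
    merged = {res.columns[int(first[0])], res.columns[int(first[1])]}
    assert merged == {"a", "a_copy"}
    assert first[2] == pytest.approx(0.0, abs=1e-20)


def test_correlated_pair_merges_before_independent_column(rng):
    x = rng.normal(size=200)
    df = pd.DataFrame({"a": x, "b": x + 0.1 * rng.normal(size=200),
                       "c": rng.normal(size=200)})
    res = cluster_traits(df)
    first = res.linkage[0]
    assert {res.columns[int(first[0])], res.columns[int(first[1])]} == \
        {"a", "b"}


def test_engineered_five_block_table_recovers_five_clusters(rng):
    """15 traits built from 5 latent factors, 3 traits each."""
    n = 300
    factors = rng.normal(size=(n, 5))
    cols = {}
    for f in range(5):
        for j in range(3):
            cols[f"T{f}{j}"] = factors[:, f] + 0.05 * rng.normal(size=n)
    df = pd.DataFrame(cols)
    res = cluster_traits(df)
    labels = res.cut_k(5)
    per_factor = {f: {labels[f"T{f}{j}"] for j in range(3)} for f in range(5)}
    assert all(len(v) == 1 for v in per_factor.values())
    assert len({v.pop() for v in per_factor.values()}) == 5


def test_constant_column_dropped_with_warning(rng):
    df = pd.DataFrame({"a": rng.normal(size=20),
                       "b": rng.normal(size=20),
                       "flat": np.ones(20)})
    with pytest.warns(UserWarning, match="flat"):
        res = cluster_traits(df)
    assert "flat" in res.dropped
    assert "flat" not in res.columns


# ----------------------------------------------------------------- PCA

def test_pca_eigenvalues_sum_to_column_count(rng):
    df = pd.DataFrame(rng.normal(size=(500, 6)),
                      columns=list("abcdef"))
    res = pca_traits(df)
    assert res.eigenvalues.sum() == pytest.approx(6.0, rel=1e-9)
    assert res.cumulative[-1] == pytest.approx(100.0, rel=1e-9)
    # independent columns at large n: all eigenvalues near 1
    assert np.all(np.abs(res.eigenvalues - 1.0) < 0.35)


def test_pca_two_perfectly_correlated_columns(rng):
    x = rng.normal(size=100)
    res = pca_traits(pd.DataFrame({"a": x, "b": 3 * x + 2}))
    assert res.eigenvalues == pytest.approx([2.0, 0.0], abs=1e-9)
    assert res.contributions[0] == pytest.approx(100.0)
    assert res.n_retained == 1


def test_pca_matches_independent_eigensolver(rng):
    from scipy.linalg import eigh
    df = pd.DataFrame(rng.normal(size=(120, 15)))
    df.iloc[:, 1] = df.iloc[:, 0] * 0.9 + 0.1 * df.iloc[:, 1]
    res = pca_traits(df)
    ref = np.sort(eigh(df.corr().to_numpy())[0])[::-1]
    assert np.allclose(res.eigenvalues, np.clip(ref, 0, None), atol=1e-8)


# --------------------------------------------------------- kNN grading

def _separable(rng, n_per=20):
    feats, labels = [], []
    for cls, centre in enumerate((0.0, 10.0, 20.0)):
        feats.append(centre + 0.1 * rng.normal(size=n_per))
        labels += [cls] * n_per
    return pd.DataFrame({"G": np.concatenate(feats)}), np.array(labels)


def test_knn_perfect_on_separated_classes(rng):
    features, labels = _separable(rng)
    for k in (1, 3, 5):
        res = knn_grading(features, labels, {"G": ["G"]}, k=k, seed=0)
        assert res[0].mean_accuracy == 1.0
        assert res[0].fold_accuracies == (1.0,) * 4


def test_knn_chance_level_on_shuffled_labels(rng):
    # structureless feature cloud, so no residual cluster-majority signal
    features = pd.DataFrame({"G": rng.normal(size=150)})
    shuffled = rng.permutation(np.repeat([0, 1, 2], 50))
    res = knn_grading(features, shuffled, {"G": ["G"]}, k=5, seed=1)
    assert res[0].mean_accuracy == pytest.approx(1.0 / 3.0, abs=0.1)


def test_knn_leave_one_out_on_duplicated_points():
    features = pd.DataFrame({"a": [0.0] * 6 + [5.0] * 6,
                             "b": [1.0] * 6 + [4.0] * 6})
    labels = [0] * 6 + [1] * 6
    res = knn_grading(features, labels, {"ab": ["a", "b"]},
                      k=1, folds=len(labels), seed=0)
    assert res[0].mean_accuracy == 1.0


def test_knn_hand_traced_nearest_neighbours():
    """6 points in 2 clusters: every held-out point's nearest neighbour is a
    same-class point, so k=1 must be perfect in every fold."""
    features = pd.DataFrame({
        "x": [0.0, 0.1, 0.0, 5.0, 5.1, 5.0],
        "y": [0.0, 0.0, 0.1, 5.0, 5.0, 5.1],
    })
    labels = [0, 0, 0, 1, 1, 1]
    res = knn_grading(features, labels, {"xy": ["x", "y"]},
                      k=1, folds=3, seed=2)
    assert res[0].fold_accuracies == (1.0, 1.0, 1.0)


def test_knn_requires_enough_members_per_class():
    features = pd.DataFrame({"x": [0.0, 1.0, 2.0, 3.0, 10.0]})
    with pytest.raises(ValueError, match="at least 4"):
        knn_grading(features, [0, 0, 0, 0, 1], {"x": ["x"]}, folds=4)


def test_knn_runs_the_ten_standard_combinations(rng):
    n = 40
    features = pd.DataFrame(
        rng.normal(size=(3 * n, 7)),
        columns=["R", "G", "B", "H", "S", "V", "ExG"])
    labels = np.repeat([0, 1, 2], n)
    features.loc[:, "G"] += labels * 5.0
    combos = {c: [c] for c in features.columns}
    combos["RGB"] = ["R", "G", "B"]
    combos["HSV"] = ["H", "S", "V"]
    combos["color traits"] = list(features.columns)
    res = knn_grading(features, labels, combos, k=5, seed=3)
    assert len(res) == 10
    by_name = {r.combo: r.mean_accuracy for r in res}
    assert by_name["G"] > 0.9                      # informative channel
    assert all(0.0 <= a <= 1.0 for a in by_name.values())


# ------------------------------------------------- color grading charts

def test_cgc_boundaries_at_every_fifth_rank():
    values = pd.Series(np.arange(1.0, 11.0),
                       index=[f"V{i}" for i in range(10)])
    chart = build_cgc(values, trait="G")
    assert [b[0] for b in chart.boundaries] == [2, 4, 6, 8, 10]
    assert (chart.vmin, chart.vmax) == (1.0, 10.0)
    assert not chart.degenerate


def test_cgc_all_equal_values_flagged_degenerate():
    values = pd.Series([7.0] * 6, index=[f"V{i}" for i in range(6)])
    chart = build_cgc(values)
    assert chart.degenerate
    assert chart.vmin == chart.vmax == 7.0


def test_cgc_range_tracks_uniform_green_channel(rng):
    values = pd.Series(rng.uniform(49.62, 147.63, size=100),
                       index=[f"V{i}" for i in range(100)])
    chart = build_cgc(values, trait="G")
    # order statistics of 100 uniforms: expected edge gap (b−a)/101 ≈ 1
    assert 49.62 <= chart.vmin <= 49.62 + 4.5
    assert 147.63 - 4.5 <= chart.vmax <= 147.63


def test_cgc_is_permutation_invariant(rng):
    values = pd.Series(rng.uniform(0, 1, 20),
                       index=[f"V{i}" for i in range(20)])
    shuffled = values.sample(frac=1.0, random_state=1)
    assert build_cgc(values) == build_cgc(shuffled)


def test_cgc_requires_five_varieties():
    with pytest.raises(ValueError):
        build_cgc(pd.Series([1.0, 2.0], index=["a", "b"]))


def test_cgc_renders_png(tmp_path, rng):
    values = pd.Series(rng.uniform(40, 150, 25),
                       index=[f"V{i}" for i in range(25)])
    from phenopot.stats import plot_cgc
    out = tmp_path / "cgc.png"
    plot_cgc(build_cgc(values, trait="G"), str(out))
    assert out.stat().st_size > 0


# ------------------------------------------------------------ line fit

def test_fit_line_exact():
    x = np.arange(10.0)
    slope, intercept, r2 = fit_line(x, 3.0 * x)
    assert (slope, intercept, r2) == pytest.approx((3.0, 0.0, 1.0))


def test_fit_line_independent_noise_has_near_zero_r2(rng):
    x = rng.normal(size=2000)
    _s, _i, r2 = fit_line(x, rng.normal(size=2000))
    assert r2 < 0.01


def test_fit_line_against_normal_equations():
    x = np.array([0.0, 1.0, 2.0, 4.0])
    y = np.array([1.0, 2.9, 5.2, 8.9])
    slope, intercept, r2 = fit_line(x, y)
    A = np.vstack([x, np.ones_like(x)]).T
    beta = np.linalg.solve(A.T @ A, A.T @ y)
    assert slope == pytest.approx(beta[0], abs=1e-12)
    assert intercept == pytest.approx(beta[1], abs=1e-12)
    resid = y - A @ beta
    r2_ref = 1 - (resid**2).sum() / ((y - y.mean())**2).sum()
    assert r2 == pytest.approx(r2_ref, abs=1e-12)


def test_fit_line_rejects_degenerate_input():
    with pytest.raises(ValueError):
        fit_line([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
    with pytest.raises(ValueError):
        fit_line([1.0, 2.0], [1.0, 2.0])
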