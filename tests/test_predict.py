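"""Prediction suite: PCA scores, R^2 curves, greedy selection, resampling,
and elastic-net LOOCV."""

import itertools

import numpy as np
import pandas as pd
import pytest

from wormexpress.predict import (GreedyForwardRegressor, cumulative_pc_r2,
                                 elastic_net_loocv, greedy_forward_selection,
                                 pca_scores, train_test_resampling)


def frame(X, prefix_g="g", prefix_w="w"):
    return pd.DataFrame(X, index=[f"{prefix_g}{i:03d}" for i in range(X.shape[0])],
                        columns=[f"{prefix_w}{j:03d}" for j in range(X.shape[1])])


# -- PCA ---------------------------------------------------------------

def test_rank_one_matrix_pc1_explains_everything():
    u = np.arange(1, 7, dtype=float)
    v = np.array([2.0, -1.0, 0.5, 3.0])
    expr = frame(np.outer(v, u))  # 4 genes x 6 worms, rank 1 after centering
    scores = pca_scores(expr)
    total = (scores.values ** 2).sum()
    assert (scores["PC1"] ** 2).sum() / total == pytest.approx(1.0, abs=1e-10)


def test_scores_orthogonal_and_variance_ordered():
    rng = np.random.default_rng(0)
    expr = frame(rng.normal(size=(30, 20)))
    S = pca_scores(expr).values
    G = S.T @ S
    off = G - np.diag(np.diag(G))
    assert np.abs(off).max() < 1e-8
    assert (np.diff(np.diag(G)) <= 1e-8).all()


def test_two_block_design_matches_direct_eigendecomposition():
    rng = np.random.default_rng(1)
    n = 40
    block1 = rng.normal(0, 3, n)   # strong shared factor
    block2 = rng.normal(0, 1, n)   # weaker shared factor
    genes = np.vstack([np.outer(np.ones(5), block1) + rng.normal(0, .01, (5, n)),
                       np.outer(np.ones(5), block2) + rng.normal(0, .01, (5, n))])
    expr = frame(genes)
    S = pca_scores(expr).values
    # oracle: eigenvalues of the worm-covariance of the centered matrix
    Xc = (genes - genes.mean(axis=1, keepdims=True)).T
    evals = np.sort(np.linalg.eigvalsh(Xc.T @ Xc))[::-1]
    got = (S ** 2).sum(axis=0)
    assert np.allclose(got[:2], evals[:2], rtol=1e-8)


def test_pca_deterministic_sign_convention():
    rng = np.random.default_rng(2)
    expr = frame(rng.normal(size=(15, 12)))
    a = pca_scores(expr)
    b = pca_scores(expr * 1.0)
    pd.testing.assert_frame_equal(a, b)


# -- cumulative PC R^2 -------------------------------------------------

def test_trait_equal_to_pc1_gives_r2_one_at_k1():
    rng = np.random.default_rng(3)
    expr = frame(rng.normal(size=(25, 30)))
    scores = pca_scores(expr)
    trait = pd.Series(scores["PC1"].values, index=scores.index)
    curve = cumulative_pc_r2(scores, trait, k_max=3, n_perm=10, seed=0)
    assert curve["observed_r2"].iloc[0] == pytest.approx(1.0, abs=1e-10)


def test_curves_monotone_and_saturate_at_full_rank():
    rng = np.random.default_rng(4)
    n = 20
    expr = frame(rng.normal(size=(40, n)))
    scores = pca_scores(expr)
    trait = pd.Series(rng.normal(size=n), index=scores.index)
    curve = cumulative_pc_r2(scores, trait, k_max=n - 1, n_perm=20, seed=1)
    assert (np.diff(curve["observed_r2"]) >= -1e-12).all()
    # with k = n - 1 even shuffled traits are fit perfectly
    assert curve["observed_r2"].iloc[-1] == pytest.approx(1.0, abs=1e-8)
    assert curve["null_mean_r2"].iloc[-1] == pytest.approx(1.0, abs=1e-8)


def test_null_mean_matches_k_over_n_minus_1():
    rng = np.random.default_rng(5)
    n = 60
    expr = frame(rng.normal(size=(80, n)))
    scores = pca_scores(expr)
    trait = pd.Series(rng.normal(size=n), index=scores.index)
    n_perm = 300
    curve = cumulative_pc_r2(scores, trait, k_max=10, n_perm=n_perm, seed=2)
    for k in (1, 5, 10):
        row = curve[curve["k"] == k].iloc[0]
        se = row["null_sd_r2"] / np.sqrt(n_perm)
        assert abs(row["null_mean_r2"] - k / (n - 1)) < 3 * se


# -- greedy selection --------------------------------------------------

def test_gene_identical_to_trait_selected_first():
    rng = np.random.default_rng(6)
    X = rng.normal(size=(20, 30))
    expr = frame(X)
    trait = pd.Series(X[7], index=expr.columns)
    sel = greedy_forward_selection(expr, trait, k_max=3)
    assert sel["gene"].iloc[0] == "g007"
    assert sel["cumulative_r2"].iloc[0] == pytest.approx(1.0, abs=1e-10)


def exhaustive_best(X, y, fixed=()):
    """Oracle: enumerate all candidate genes for the next position."""
    n, G = X.shape
    best = (-np.inf, None)
    for j in range(G):
        if j in fixed:
            continue
        cols = list(fixed) + [j]
        A = np.column_stack([np.ones(n)] + [X[:, c] for c in cols])
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        resid = y - A @ coef
        r2 = 1 - resid @ resid / ((y - y.mean()) @ (y - y.mean()))
        if r2 > best[0] + 1e-12:
            best = (r2, j)
    return best


@pytest.mark.parametrize("seed", range(5))
def test_greedy_matches_exhaustive_best_subset_for_two_steps(seed):
    rng = np.random.default_rng(100 + seed)
    n, G = 30, 8
    X = rng.normal(size=(n, G))
    y = X[:, 2] - 0.8 * X[:, 5] + rng.normal(0, 0.5, n)
    model = GreedyForwardRegressor(k=2).fit(X, y)
    r2_1, j1 = exhaustive_best(X, y)
    r2_2, j2 = exhaustive_best(X, y, fixed=(j1,))
    assert model.selected_idx_ == [j1, j2]
    assert model.r2_path_[0] == pytest.approx(r2_1, abs=1e-10)
    assert model.r2_path_[1] == pytest.approx(r2_2, abs=1e-10)


def test_duplicated_gene_never_selected():
    rng = np.random.default_rng(7)
    n = 40
    g0 = rng.normal(size=n)
    X = np.column_stack([g0, g0.copy()] + [rng.normal(size=n) for _ in range(6)])
    y = g0 + 0.3 * X[:, 4] + rng.normal(0, 0.2, n)
    model = GreedyForwardRegressor(k=5).fit(X, y)
    first = model.selected_idx_[0]
    assert first in (0, 1)
    dup = 1 - first
    assert dup not in model.selected_idx_
    assert (np.diff(model.r2_path_) >= -1e-12).all()


def test_greedy_tie_break_lexicographic():
    n = 24
    rng = np.random.default_rng(8)
    g = rng.normal(size=n)
    X = np.column_stack([g, g])
    y = g.copy()
    model = GreedyForwardRegressor(k=1).fit(X, y, feature_names=["zzz", "aaa"])
    assert model.selected_ == ["aaa"]


# -- resampling --------------------------------------------------------

def test_resampling_deterministic_and_disjoint():
    rng = np.random.default_rng(9)
    expr = frame(rng.normal(size=(30, 40)))
    trait = pd.Series(rng.normal(size=40), index=expr.columns)
    a = train_test_resampling(expr, trait, n_iter=5, k=3, seed=11)
    b = train_test_resampling(expr, trait, n_iter=5, k=3, seed=11)
    pd.testing.assert_frame_equal(a, b)
    for _, row in a.iterrows():
        train = set(row["train_worms"].split(";"))
        assert len(train) == 20


def test_resampling_perfect_signal_limit():
    rng = np.random.default_rng(10)
    n = 60
    X = rng.normal(size=(30, n))
    expr = frame(X)
    trait = pd.Series(2 * X[0] - X[1] + 0.5 * X[2], index=expr.columns)
    res = train_test_resampling(expr, trait, n_iter=20, k=5, seed=3)
    assert res["test_r2"].median() >= 0.99


# -- elastic net -------------------------------------------------------

def test_elastic_net_strong_signal_and_dropped_constant_gene():
    rng = np.random.default_rng(12)
    n = 40
    X = rng.normal(size=(20, n))
    X[5] = 1.0  # constant gene: must be dropped, not crash
    expr = frame(X)
    trait = pd.Series(X[2] + 0.05 * rng.normal(size=n), index=expr.columns)
    out = elastic_net_loocv(expr, trait, seed=0)
    assert out.attrs["r2"] >= 0.95
    assert len(out) == n


def test_elastic_net_loocv_no_leakage():
    rng = np.random.default_rng(13)
    n = 24
    expr = frame(rng.normal(size=(15, n)))
    trait = pd.Series(rng.normal(size=n), index=expr.columns)
    base = elastic_net_loocv(expr, trait, seed=1)
    bumped = trait.copy()
    bumped.iloc[5] += 1000.0
    pert = elastic_net_loocv(expr, bumped, seed=1)
    assert base["predicted"].iloc[5] == pert["predicted"].iloc[5]
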