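"""CPM normalization, gene filters, log transform, and IO round trips."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from wormexpress.preprocess import (ExpressionMatrix, cpm_normalize,
                                    filter_genes, log_transform_for_pca,
                                    read_counts_mtx, read_counts_tsv,
                                    validate_phenotypes, write_counts_mtx,
                                    write_counts_tsv)


def make_expr(values, genes=None, worms=None):
    values = np.atleast_2d(values)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    worms = worms or [f"w{j}" for j in range(values.shape[1])]
    return cpm_normalize(pd.DataFrame(values, index=genes, columns=worms))


def test_cpm_single_gene_whole_library():
    expr = make_expr([[10]])
    assert expr.cpm.iloc[0, 0] == pytest.approx(1e6)


def test_cpm_two_genes_one_library():
    expr = make_expr([[2], [8]])
    assert list(expr.cpm.iloc[:, 0]) == [pytest.approx(2e5), pytest.approx(8e5)]


def test_cpm_columns_sum_to_a_million():
    rng = np.random.default_rng(0)
    expr = make_expr(rng.integers(0, 500, size=(50, 20)) + 1)
    assert np.allclose(expr.cpm.sum(axis=0), 1e6)


def test_cpm_zero_library_names_worm():
    counts = pd.DataFrame([[5, 0], [5, 0]], index=["a", "b"],
                          columns=["good", "empty"])
    with pytest.raises(ValueError, match="empty"):
        cpm_normalize(counts)


def test_negative_counts_rejected():
    with pytest.raises(ValueError, match="negative"):
        ExpressionMatrix(pd.DataFrame([[-1]], index=["g"], columns=["w"]))


# -- filters -----------------------------------------------------------

def test_filter_any_gt_keeps_single_high_library():
    expr = make_expr([[0, 0, 11], [1, 1, 1]])
    # per-library CPM of gene 0 in library w2: 11/12 of a million > 10
    kept = filter_genes(expr, "any_gt", 10).genes
    assert "g0" in kept


def test_filter_strict_inequality_at_threshold():
    counts = pd.DataFrame([[10, 10], [999990, 999990]],
                          index=["edge", "rest"], columns=["w0", "w1"])
    expr = cpm_normalize(counts)
    assert expr.cpm.loc["edge"].max() == pytest.approx(10.0)
    assert "edge" not in filter_genes(expr, "any_gt", 10).genes


def test_any_set_contains_all_set():
    rng = np.random.default_rng(1)
    expr = make_expr(rng.integers(0, 2000, size=(100, 15)))
    any_set = set(filter_genes(expr, "any_gt", 10).genes)
    # brute-force recomputation of both rules
    all_set = {g for g in expr.genes if (expr.cpm.loc[g] > 10).all()}
    assert all_set <= any_set
    assert all_set == set(filter_genes(expr, "all_gt", 10).genes)


def test_unknown_rule_rejected():
    expr = make_expr([[1]])
    with pytest.raises(ValueError, match="unknown"):
        filter_genes(expr, "median_gt", 1)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(0, 2 ** 31 - 1), st.floats(0.1, 50), st.floats(0.1, 50))
def test_filter_monotone_in_threshold(seed, t1, t2):
    rng = np.random.default_rng(seed)
    expr = make_expr(rng.integers(0, 300, size=(30, 8)) + 1)
    lo, hi = sorted([t1, t2])
    assert set(filter_genes(expr, "any_gt", hi).genes) <= \
        set(filter_genes(expr, "any_gt", lo).genes)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(0, 2 ** 31 - 1), st.integers(2, 9))
def test_cpm_invariant_to_library_scaling(seed, factor):
    rng = np.random.default_rng(seed)
    counts = pd.DataFrame(rng.integers(1, 100, size=(12, 4)),
                          index=[f"g{i}" for i in range(12)],
                          columns=[f"w{j}" for j in range(4)])
    scaled = counts.copy()
    scaled["w1"] = scaled["w1"] * factor
    a = cpm_normalize(counts).cpm["w1"]
    b = cpm_normalize(scaled).cpm["w1"]
    assert np.allclose(a, b)


# -- log transform -----------------------------------------------------

def test_log_transform_constant_gene_is_zero():
    expr = make_expr([[7, 7, 7], [3, 3, 3]])
    lt = log_transform_for_pca(expr)
    assert np.allclose(lt.values, 0.0)


def test_log_transform_hand_computed_example():
    # cpm pattern (1, 4) with eps = 0: log2(1/2.5), log2(4/2.5)
    counts = pd.DataFrame([[1, 4], [999999, 999996]],
                          index=["g", "rest"], columns=["w0", "w1"])
    expr = cpm_normalize(counts)
    lt = log_transform_for_pca(expr, gene_set=["g"], pseudocount=0.0)
    assert lt.loc["g", "w0"] == pytest.approx(np.log2(1 / 2.5))
    assert lt.loc["g", "w1"] == pytest.approx(np.log2(4 / 2.5))


def test_log_transform_scale_invariance_per_gene():
    rng = np.random.default_rng(2)
    base = rng.integers(1, 50, size=(5, 6))
    e1 = make_expr(base)
    e2 = make_expr(base * 2)  # doubles every library: same CPM, same transform
    a = log_transform_for_pca(e1)
    b = log_transform_for_pca(e2)
    assert np.allclose(a.values, b.values)


def test_log_transform_reconstruction_identity():
    rng = np.random.default_rng(3)
    expr = make_expr(rng.integers(1, 400, size=(10, 8)))
    eps = 0.5
    lt = log_transform_for_pca(expr, pseudocount=eps)
    shifted = expr.cpm + eps
    recon = (2.0 ** lt).mul(shifted.mean(axis=1), axis=0)
    assert np.allclose(recon.values, shifted.values, rtol=1e-9)


def test_log_transform_empty_gene_set_rejected():
    expr = make_expr([[1, 2]])
    with pytest.raises(ValueError, match="empty"):
        log_transform_for_pca(expr, gene_set=[])


# -- IO ----------------------------------------------------------------

def test_counts_tsv_round_trip_bit_exact(tmp_path):
    rng = np.random.default_rng(4)
    expr = make_expr(rng.integers(0, 10_000, size=(25, 6)))
    path = tmp_path / "counts.tsv"
    write_counts_tsv(expr, path)
    back = read_counts_tsv(path)
    assert back.counts.equals(expr.counts)


def test_counts_mtx_round_trip(tmp_path):
    rng = np.random.default_rng(5)
    expr = make_expr(rng.integers(0, 100, size=(8, 5)))
    prefix = tmp_path / "m"
    write_counts_mtx(expr, prefix)
    back = read_counts_mtx(prefix)
    assert np.array_equal(back.counts.values, expr.counts.values)
    assert list(back.genes) == list(expr.genes)


def test_phenotype_validation_catches_problems():
    ok = pd.DataFrame({
        "worm_id": ["a", "b"], "replicate": [1, 2],
        "parental_age": [0, 1], "early_temp": [1, 0],
        "elo_hours": [68, 72], "early_brood": [100, 130]})
    validate_phenotypes(ok)
    dup = ok.copy()
    dup.loc[1, "worm_id"] = "a"
    with pytest.raises(ValueError, match="duplicate"):
        validate_phenotypes(dup)
    bad_bin = ok.copy()
    bad_bin.loc[0, "parental_age"] = 3
    with pytest.raises(ValueError, match="binary"):
        validate_phenotypes(bad_bin)
    bad_elo = ok.copy()
    bad_elo.loc[0, "elo_hours"] = 99
    with pytest.raises(ValueError, match="window"):
        validate_phenotypes(bad_elo)


def test_filter_worms_library_size_gate():
    from wormexpress.preprocess import filter_worms

    counts = pd.DataFrame([[100, 2], [100, 1]], index=["a", "b"],
                          columns=["big", "small"])
    expr = cpm_normalize(counts)
    assert list(filter_worms(expr, min_library_size=10).worms) == ["big"]
    # default gate is off
    assert list(filter_worms(expr).worms) == ["big", "small"]
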