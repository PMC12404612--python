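"""Enrichment analyses: ANOVA against a sums-of-squares oracle, the
regulated-proportion KS comparison, and the variance-by-domain test."""

import numpy as np
import pandas as pd
import pytest

from wormexpress import simulate_chromatin_annotation
from wormexpress.enrich import (regulated_proportion_test,
                                set_regulated_proportions,
                                tissue_domain_anova, variance_by_domain_test)


def balanced_annotation(n_per_cell):
    rows = []
    i = 0
    for t in ("soma", "germline"):
        for d in ("active", "regulated"):
            for _ in range(n_per_cell):
                rows.append((f"g{i:04d}", d, t))
                i += 1
    return pd.DataFrame(rows, columns=["gene", "domain", "tissue"])


def anova_oracle_balanced(y, a, b):
    """Textbook balanced two-way ANOVA from explicit sums of squares."""
    n = len(y)
    mu = y.mean()
    ss_total = ((y - mu) ** 2).sum()
    ss_a = sum(len(y[a == l]) * (y[a == l].mean() - mu) ** 2 for l in np.unique(a))
    ss_b = sum(len(y[b == l]) * (y[b == l].mean() - mu) ** 2 for l in np.unique(b))
    cell_means = {}
    ss_resid = 0.0
    for la in np.unique(a):
        for lb in np.unique(b):
            cell = y[(a == la) & (b == lb)]
            cell_means[(la, lb)] = cell.mean()
            ss_resid += ((cell - cell.mean()) ** 2).sum()
    ss_ab = ss_total - ss_a - ss_b - ss_resid
    df_resid = n - 4
    f = {
        "tissue": (ss_a / 1) / (ss_resid / df_resid),
        "domain": (ss_b / 1) / (ss_resid / df_resid),
        "tissue:domain": (ss_ab / 1) / (ss_resid / df_resid),
    }
    return f, (ss_total, ss_a, ss_b, ss_ab, ss_resid)


def test_constant_effects_give_zero_f_and_p_one():
    ann = balanced_annotation(5)
    eff = pd.Series(0.7, index=ann["gene"])
    rep = tissue_domain_anova(eff, ann)
    assert (rep.anova["F"] == 0).all()
    assert (rep.anova["pvalue"] == 1).all()


def test_anova_matches_textbook_sums_of_squares():
    rng = np.random.default_rng(0)
    ann = balanced_annotation(50)
    y = rng.normal(0, 0.1, len(ann))
    # shift the germline/regulated cell
    mask = ((ann["tissue"] == "germline") & (ann["domain"] == "regulated")).values
    y[mask] -= 0.3
    eff = pd.Series(y, index=ann["gene"])
    rep = tissue_domain_anova(eff, ann)
    f_oracle, ss = anova_oracle_balanced(y, ann["tissue"].values,
                                         ann["domain"].values)
    got = dict(zip(rep.anova["term"], rep.anova["F"]))
    for term in ("tissue", "domain", "tissue:domain"):
        assert got[term] == pytest.approx(f_oracle[term], rel=1e-8)
    # balanced decomposition identity
    ss_total, ss_a, ss_b, ss_ab, ss_resid = ss
    assert ss_total == pytest.approx(ss_a + ss_b + ss_ab + ss_resid, abs=1e-8)


def test_shifted_cell_detected_by_interaction_and_ttest():
    rng = np.random.default_rng(1)
    ann = balanced_annotation(50)
    y = rng.normal(0, 0.1, len(ann))
    mask = ((ann["tissue"] == "soma") & (ann["domain"] == "regulated")).values
    y[mask] -= 0.3
    rep = tissue_domain_anova(pd.Series(y, index=ann["gene"]), ann)
    p_int = float(rep.anova.set_index("term").loc["tissue:domain", "pvalue"])
    assert p_int < 1e-6
    tt = rep.cell_ttests.set_index("cell")
    assert tt.loc["soma_regulated", "pvalue"] < 1e-10
    assert tt.loc["soma_regulated", "mean"] < 0
    for cell in ("soma_active", "germline_active", "germline_regulated"):
        assert tt.loc[cell, "pvalue"] > 0.01
    # Tukey adjusted p-values live in [0, 1] and cover all 6 pairs
    assert len(rep.tukey) == 6
    assert rep.tukey["adj_pvalue"].between(0, 1).all()


def test_empty_cell_raises_with_cell_name():
    ann = balanced_annotation(4)
    ann = ann[~((ann["tissue"] == "soma") & (ann["domain"] == "active"))]
    eff = pd.Series(np.arange(len(ann), dtype=float).tolist(),
                    index=ann["gene"])
    with pytest.raises(ValueError, match="soma.*active"):
        tissue_domain_anova(eff, ann)


# -- regulated proportions ---------------------------------------------

def test_proportion_rule_drops_other_and_unannotated():
    ann = pd.DataFrame({
        "gene": ["a", "b", "c", "d"],
        "domain": ["regulated", "active", "other", "regulated"],
        "tissue": ["soma"] * 4,
    })
    sets = [["a", "b", "c", "unknown"],   # 1 regulated of 2 annotated
            ["c", "unknown"],             # no annotated member: excluded
            ["a", "d"]]                   # 2 of 2
    props = set_regulated_proportions(sets, ann)
    assert list(props) == [0.5, 1.0]


def test_identical_collections_have_zero_ks_statistic():
    genes = [f"g{i}" for i in range(200)]
    ann = simulate_chromatin_annotation(genes, p_regulated=0.5, seed=0)
    rng = np.random.default_rng(1)
    sets = [list(rng.choice(genes, 10, replace=False)) for _ in range(50)]
    from wormexpress.enrich import _ks_statistic_tied
    d, *_ = _ks_statistic_tied(set_regulated_proportions(sets, ann),
                               set_regulated_proportions(sets, ann))
    assert d == 0.0


def test_maximal_separation_gives_tiny_pvalue():
    genes = [f"g{i}" for i in range(400)]
    ann = simulate_chromatin_annotation(genes, p_regulated=0.5, seed=2)
    reg = list(ann.loc[ann["domain"] == "regulated", "gene"])
    rng = np.random.default_rng(3)
    sets = [list(rng.choice(reg, 10, replace=False)) for _ in range(100)]
    rep = regulated_proportion_test(sets, genes, ann, n_random=100, seed=4,
                                    n_ks_perm=1999)
    assert rep.ks_pvalue < 0.001
    assert 0 <= rep.ks_statistic <= 1
    assert np.all((rep.observed_proportions >= 0) & (rep.observed_proportions <= 1))


def test_proportion_test_deterministic_given_seed():
    genes = [f"g{i}" for i in range(150)]
    ann = simulate_chromatin_annotation(genes, seed=5)
    rng = np.random.default_rng(6)
    sets = [list(rng.choice(genes, 10, replace=False)) for _ in range(40)]
    a = regulated_proportion_test(sets, genes, ann, n_random=40, seed=7)
    b = regulated_proportion_test(sets, genes, ann, n_random=40, seed=7)
    assert a.ks_statistic == b.ks_statistic and a.ks_pvalue == b.ks_pvalue


# -- variance by domain ------------------------------------------------

def test_wilcoxon_shift_detected_and_symmetric():
    rng = np.random.default_rng(8)
    n = 200
    genes = [f"g{i}" for i in range(2 * n)]
    ann = pd.DataFrame({"gene": genes,
                        "domain": ["regulated"] * n + ["active"] * n,
                        "tissue": ["soma"] * 2 * n})
    z = np.concatenate([rng.normal(1.0, 1.0, n), rng.normal(0.0, 1.0, n)])
    vs = pd.DataFrame({"gene": genes, "variance_z": z})
    rep = regulated = variance_by_domain_test(vs, ann)
    assert rep.wilcoxon_pvalue < 1e-10
    # swapping the group labels leaves the two-sided p unchanged
    ann_sw = ann.copy()
    ann_sw["domain"] = np.where(ann["domain"] == "regulated", "active",
                                "regulated")
    rep_sw = variance_by_domain_test(vs, ann_sw)
    assert rep_sw.wilcoxon_pvalue == pytest.approx(rep.wilcoxon_pvalue, rel=1e-9)


def test_wilcoxon_requires_both_groups():
    ann = pd.DataFrame({"gene": ["a", "b"], "domain": ["active", "active"],
                        "tissue": ["soma", "soma"]})
    vs = pd.DataFrame({"gene": ["a", "b"], "variance_z": [0.1, -0.2]})
    with pytest.raises(ValueError, match="nonempty"):
        variance_by_domain_test(vs, ann)
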