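"""Chromatin-domain and tissue enrichment analyses.

Three analyses ask whether expression-trait effects and expression
variability are structured by chromatin state (H3K27me3-marked
"regulated" domains versus broadly expressed "active" domains) and
tissue (soma versus germline):

* a 2x2 two-way ANOVA with interaction on per-gene effect sizes,
  followed by Tukey HSD on the four tissue x domain cell means and
  one-sample t-tests of each cell mean against zero;
* a comparison of the proportion of regulated genes in resampled
  predictive gene sets against random same-size sets from the expressed
  background, by a two-sample Kolmogorov-Smirnov test;
* a two-sided Wilcoxon rank-sum test of variance Z-scores between
  regulated and active genes.

Genes labelled "other" for domain never enter proportion denominators;
unannotated genes are dropped per set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["EnrichmentReport", "tissue_domain_anova",
           "regulated_proportion_test", "variance_by_domain_test",
           "read_annotation", "set_regulated_proportions"]

log = logging.getLogger("wormexpress")

DOMAINS = ("active", "regulated", "other")
TISSUES = ("soma", "germline", "other")


@dataclass
class EnrichmentReport:
    anova: pd.DataFrame | None = None          # term, F, p
    tukey: pd.DataFrame | None = None          # cell pair, adjusted p
    cell_ttests: pd.DataFrame | None = None    # cell, mean, t, p
    ks_statistic: float | None = None
    ks_pvalue: float | None = None
    observed_proportions: np.ndarray | None = None
    control_proportions: np.ndarray | None = None
    wilcoxon_statistic: float | None = None
    wilcoxon_pvalue: float | None = None


def read_annotation(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    need = {"gene", "domain", "tissue"}
    if not need <= set(df.columns):
        raise ValueError(f"annotation must have columns {sorted(need)}")
    bad_d = set(df["domain"]) - set(DOMAINS)
    bad_t = set(df["tissue"]) - set(TISSUES)
    if bad_d or bad_t:
        raise ValueError(f"unknown labels: domain {bad_d}, tissue {bad_t}")
    return df


def _ols_rss(X: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    return float(resid @ resid), int(rank)


def tissue_domain_anova(effects: pd.Series, annotation: pd.DataFrame,
                        min_per_cell: int = 3) -> EnrichmentReport:
    """Two-way ANOVA (tissue x domain, with interaction) on gene effect sizes.

    ``effects`` is indexed by gene (e.g. standardized beta1 per gene);
    the analysis is restricted to soma/germline tissues and
    active/regulated domains.  Type II sums of squares via nested OLS
    model comparisons; Tukey HSD over the four cells; one-sample t-tests
    of each cell mean against zero.
    """
    ann = annotation.set_index("gene")
    common = effects.index.intersection(ann.index)
    df = pd.DataFrame({"y": effects.loc[common],
                       "tissue": ann.loc[common, "tissue"],
                       "domain": ann.loc[common, "domain"]})
    df = df[df["tissue"].isin(["soma", "germline"])
            & df["domain"].isin(["active", "regulated"])]
    cells = {(t, d): df[(df["tissue"] == t) & (df["domain"] == d)]["y"].values
             for t in ("soma", "germline") for d in ("active", "regulated")}
    for cell, vals in cells.items():
        if len(vals) < min_per_cell:
            raise ValueError(f"cell {cell} has {len(vals)} genes "
                             f"(need >= {min_per_cell})")

    y = df["y"].values.astype(float)
    n = len(y)
    a = (df["tissue"] == "germline").values.astype(float)  # tissue main effect
    b = (df["domain"] == "regulated").values.astype(float)
    ab = a * b
    ones = np.ones(n)
    sst = float(((y - y.mean()) ** 2).sum())
    rss_full, rank_full = _ols_rss(np.column_stack([ones, a, b, ab]), y)
    df_resid = n - rank_full
    ms_resid = rss_full / df_resid
    scale = n * max(1.0, float(y.mean()) ** 2)
    degenerate = sst <= 1e-12 * scale or rss_full <= 1e-12 * max(sst, 1e-300)

    def f_term(cols_reduced, cols_bigger, df_term):
        if degenerate:
            # constant response or an exact fit: F = 0, p = 1 by convention
            return 0.0, 1.0
        rss_r, _ = _ols_rss(np.column_stack(cols_reduced), y)
        rss_b, _ = _ols_rss(np.column_stack(cols_bigger), y)
        F = ((rss_r - rss_b) / df_term) / ms_resid
        p = float(stats.f.sf(F, df_term, df_resid))
        return float(max(F, 0.0)), p

    # Type II: main effects adjusted for each other (not the interaction);
    # the interaction adjusted for both main effects
    f_t, p_t = f_term([ones, b], [ones, a, b], 1)
    f_d, p_d = f_term([ones, a], [ones, a, b], 1)
    f_i, p_i = f_term([ones, a, b], [ones, a, b, ab], 1)
    anova = pd.DataFrame({
        "term": ["tissue", "domain", "tissue:domain"],
        "F": [f_t, f_d, f_i],
        "pvalue": [p_t, p_d, p_i],
    })

    labels = [f"{t}_{d}" for t in ("soma", "germline") for d in ("active", "regulated")]
    groups = [cells[(t, d)] for t in ("soma", "germline") for d in ("active", "regulated")]
    if np.ptp(np.concatenate(groups)) == 0:
        tukey = pd.DataFrame({"cell_a": [], "cell_b": [], "adj_pvalue": []})
    else:
        res = stats.tukey_hsd(*groups)
        rows = []
        for i in range(4):
            for j in range(i + 1, 4):
                rows.append((labels[i], labels[j], float(res.pvalue[i, j])))
        tukey = pd.DataFrame(rows, columns=["cell_a", "cell_b", "adj_pvalue"])

    trows = []
    for lab, vals in zip(labels, groups):
        if np.std(vals, ddof=1) == 0:
            t, p = (0.0, 1.0) if np.mean(vals) == 0 else (np.inf, 0.0)
        else:
            t, p = stats.ttest_1samp(vals, 0.0)
        trows.append((lab, float(np.mean(vals)), float(t), float(p)))
    ttests = pd.DataFrame(trows, columns=["cell", "mean", "t", "pvalue"])

    return EnrichmentReport(anova=anova, tukey=tukey, cell_ttests=ttests)


def set_regulated_proportions(gene_sets, annotation: pd.DataFrame) -> np.ndarray:
    """Per-set proportion of regulated genes among active+regulated members.

    Genes missing from the annotation or labelled 'other' are dropped
    from the denominator; sets with no annotated member are excluded
    (logged).
    """
    dom = annotation.set_index("gene")["domain"]
    props = []
    n_dropped = 0
    for genes in gene_sets:
        labs = [dom.get(g) for g in genes]
        labs = [l for l in labs if l in ("active", "regulated")]
        if not labs:
            n_dropped += 1
            continue
        props.append(sum(l == "regulated" for l in labs) / len(labs))
    if n_dropped:
        log.info("proportion test excluded %d sets with no annotated genes",
                 n_dropped)
    return np.asarray(props)


def _ks_statistic_tied(obs: np.ndarray, ctl: np.ndarray):
    """Two-sample KS statistic via per-unique-value counts (tie-aware)."""
    pooled = np.concatenate([obs, ctl])
    uniq, inv = np.unique(pooled, return_inverse=True)
    c1 = np.bincount(inv[:len(obs)], minlength=len(uniq))
    ctot = np.bincount(inv, minlength=len(uniq))
    f1 = np.cumsum(c1) / len(obs)
    f2 = np.cumsum(ctot - c1) / len(ctl)
    return float(np.max(np.abs(f1 - f2))), ctot, len(obs), len(ctl)


def _perm_ks_pvalue(obs: np.ndarray, ctl: np.ndarray, n_perm: int,
                    rng: np.random.Generator) -> tuple[float, float]:
    """Permutation p-value of the two-sample KS statistic.

    Set proportions are heavily tied (a 10-gene set can only take a few
    dozen proportion values), which makes the classical KS null
    distribution conservative; permuting group labels calibrates the
    test exactly under ties.  Label permutations reduce to multivariate
    hypergeometric splits of the per-value counts, so the whole null
    ensemble is vectorized.
    """
    d_obs, ctot, n1, n2 = _ks_statistic_tied(obs, ctl)
    draws = rng.multivariate_hypergeometric(ctot, n1, size=n_perm)
    f1 = np.cumsum(draws, axis=1) / n1
    f2 = np.cumsum(ctot[None, :] - draws, axis=1) / n2
    d_null = np.max(np.abs(f1 - f2), axis=1)
    p = (1.0 + np.sum(d_null >= d_obs - 1e-12)) / (n_perm + 1.0)
    return d_obs, float(p)


def regulated_proportion_test(predictive_sets, background_genes,
                              annotation: pd.DataFrame, n_random: int = 500,
                              set_size: int | None = None, seed: int = 0,
                              ks_method: str = "permutation",
                              n_ks_perm: int = 999) -> EnrichmentReport:
    """KS comparison of regulated-gene proportions: predictive vs random sets.

    ``predictive_sets`` is an iterable of gene lists (typically the 500
    top-10 sets from train/test resampling).  Random control sets of the
    same size are drawn uniformly from ``background_genes``.

    ``ks_method``: "permutation" (default) computes the KS statistic's
    p-value by label permutation, which stays calibrated on the heavily
    tied proportion values; "asymp" and "exact" delegate to the
    classical (continuity-assuming, hence conservative here) null.
    """
    predictive_sets = [list(s) for s in predictive_sets]
    if set_size is None:
        set_size = len(predictive_sets[0])
    background = list(background_genes)
    rng = np.random.default_rng(seed)
    random_sets = [list(rng.choice(background, size=set_size, replace=False))
                   for _ in range(n_random)]
    obs = set_regulated_proportions(predictive_sets, annotation)
    ctl = set_regulated_proportions(random_sets, annotation)
    if len(obs) == 0 or len(ctl) == 0:
        raise ValueError("no annotated sets to compare")
    if ks_method == "permutation":
        stat, pval = _perm_ks_pvalue(obs, ctl, n_ks_perm, rng)
    else:
        ks = stats.ks_2samp(obs, ctl, alternative="two-sided", method=ks_method)
        stat, pval = float(ks.statistic), float(ks.pvalue)
    return EnrichmentReport(ks_statistic=stat,
                            ks_pvalue=pval,
                            observed_proportions=obs,
                            control_proportions=ctl)


def variance_by_domain_test(var_scores: pd.DataFrame,
                            annotation: pd.DataFrame) -> EnrichmentReport:
    """Two-sided rank-sum test of variance Z-scores: regulated vs active."""
    dom = annotation.set_index("gene")["domain"]
    z = var_scores.set_index("gene")["variance_z"]
    common = z.index.intersection(dom.index)
    reg = z.loc[[g for g in common if dom.loc[g] == "regulated"]].values
    act = z.loc[[g for g in common if dom.loc[g] == "active"]].values
    if len(reg) == 0 or len(act) == 0:
        raise ValueError("both domain groups must be nonempty")
    res = stats.mannwhitneyu(reg, act, alternative="two-sided")
    return EnrichmentReport(wilcoxon_statistic=float(res.statistic),
                            wilcoxon_pvalue=float(res.pvalue))
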