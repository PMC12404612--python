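"""Per-gene model scans: trait association, environmental DE, variance
Z-scores, and the RNAi-effect test.

All scans share the random-intercept engine in :mod:`wormexpress.lmm`.
The trait scan regresses each trait on one gene's expression (CPM by
default) with biological replicate as the random intercept, and flags
genes by a Bonferroni-corrected Wald p-value.  The environment scan fits
a negative-binomial mixed model per gene to the raw counts, with
parental age and early-life temperature as fixed effects, replicate as
the random intercept, and log library size as an offset (library sizes
span an order of magnitude, so an offset is statistically necessary
even though plain counts are modelled).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .lmm import fit_lmm
from .nb import NegativeBinomialMixedModel
from .smoothing import loess_fit

__all__ = [
    "bonferroni_threshold", "scan_trait_associations", "scan_environment_de",
    "variance_zscores", "rnai_effect_test",
]

log = logging.getLogger("wormexpress")


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Nominal per-test threshold alpha / G (e.g. 0.05 / 8824 = 5.67e-6)."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


def _align(trait: pd.Series, cpm: pd.DataFrame, replicates: pd.Series):
    worms = cpm.columns
    if not set(worms) <= set(trait.index) or not set(worms) <= set(replicates.index):
        raise ValueError("trait/replicate tables do not cover the expression worms")
    return trait.loc[worms].values.astype(float), replicates.loc[worms].values


def scan_trait_associations(trait: pd.Series, cpm: pd.DataFrame,
                            replicates: pd.Series, alpha: float = 0.05,
                            predictor: str = "cpm") -> pd.DataFrame:
    """One LMM per gene: trait ~ expression + (1 | replicate).

    Parameters
    ----------
    trait : per-worm trait values indexed by worm id
    cpm : genes x worms CPM layer (already filtered, e.g. any CPM > 10)
    replicates : per-worm replicate labels indexed by worm id
    predictor : "cpm" (default) or "logcpm" (log2 of CPM + 0.5)

    Returns a frame with raw and standardized effects, p-values, the
    Bonferroni flag at threshold ``alpha / n_scanned`` and the effect
    sign.  Genes whose fit does not converge are excluded (logged).
    """
    y, groups = _align(trait, cpm, replicates)
    X = cpm.values.astype(float)
    if predictor == "logcpm":
        X = np.log2(X + 0.5)
    elif predictor != "cpm":
        raise ValueError(f"unknown predictor {predictor!r}")
    sd_y = y.std(ddof=1)
    rows, skipped = [], []
    for k, gene in enumerate(cpm.index):
        x = X[k]
        sd_x = x.std(ddof=1)
        if sd_x == 0:
            skipped.append(gene)
            continue
        fit = fit_lmm(y, x[:, None], groups=groups, names=["expr"])
        if not fit.converged:
            skipped.append(gene)
            continue
        b = fit.coef("expr")
        rows.append((gene, b, b * sd_x / sd_y, fit.pvalue("expr")))
    if skipped:
        log.info("trait scan skipped %d genes (constant or non-converged)",
                 len(skipped))
    res = pd.DataFrame(rows, columns=["gene", "effect", "std_effect", "pvalue"])
    n_scanned = len(res)
    thr = bonferroni_threshold(alpha, max(n_scanned, 1))
    res["significant"] = res["pvalue"] < thr
    res["sign"] = np.where(res["effect"] >= 0, "positive", "negative")
    res.attrs["n_scanned"] = n_scanned
    res.attrs["nominal_threshold"] = thr
    res.attrs["skipped"] = skipped
    return res


def scan_environment_de(counts: pd.DataFrame, pheno: pd.DataFrame,
                        alpha: float = 0.05, use_offset: bool = True,
                        theta_init: float = 10.0) -> pd.DataFrame:
    """Per-gene NB mixed model: counts ~ age + temp + (1 | replicate) + offset.

    ``counts`` are raw integer counts over the stringent (all CPM > 1)
    gene set; ``pheno`` is indexed or keyed by worm_id with replicate,
    parental_age, early_temp columns.  Returns per-gene coefficients and
    p-values for both environment factors, dispersion, mean CPM, and the
    log-scale unexplained (residual) variance used for variance
    Z-scores.  Bonferroni flags are per factor at alpha / n_scanned.
    """
    ph = pheno.set_index("worm_id") if "worm_id" in pheno.columns else pheno
    worms = counts.columns
    ph = ph.loc[worms]
    X = np.column_stack([ph["parental_age"].values.astype(float),
                         ph["early_temp"].values.astype(float)])
    groups = ph["replicate"].values
    lib = counts.sum(axis=0).values.astype(float)
    offset = np.log(lib / lib.mean()) if use_offset else None
    cpm = counts.values * 1e6 / lib

    rows, skipped = [], []
    for k, gene in enumerate(counts.index):
        y = counts.iloc[k].values.astype(float)
        try:
            m = NegativeBinomialMixedModel(theta_init=theta_init).fit(
                X, y, groups=groups, offset=offset)
        except (ValueError, np.linalg.LinAlgError):
            skipped.append(gene)
            continue
        if not m.converged_:
            skipped.append(gene)
            continue
        rows.append((gene, m.params_[1], m.pvalues_[1], m.params_[2],
                     m.pvalues_[2], m.theta_, m.unexplained_variance_,
                     float(cpm[k].mean())))
    if skipped:
        log.info("environment scan skipped %d genes", len(skipped))
    res = pd.DataFrame(rows, columns=[
        "gene", "age_coef", "age_pvalue", "temp_coef", "temp_pvalue",
        "dispersion", "unexplained_variance", "mean_cpm"])
    thr = bonferroni_threshold(alpha, max(len(res), 1))
    res["age_significant"] = res["age_pvalue"] < thr
    res["temp_significant"] = res["temp_pvalue"] < thr
    res.attrs["nominal_threshold"] = thr
    res.attrs["skipped"] = skipped
    return res


def variance_zscores(env_de: pd.DataFrame, span: float = 0.75) -> pd.DataFrame:
    """Z-scores of log10 unexplained variance against its loess trend on
    log10 mean CPM.

    Variance grows with expression, so a gene's variability must be
    judged relative to genes of similar abundance: the loess fit is that
    abundance trend and Z = (observed - fitted) / SD(residuals).
    """
    df = env_de[env_de["unexplained_variance"] > 0].copy()
    dropped = len(env_de) - len(df)
    if dropped:
        log.info("variance z-scores: dropped %d genes with zero variance", dropped)
    if len(df) < 50:
        raise ValueError("need >= 50 genes with positive unexplained variance")
    lx = np.log10(df["mean_cpm"].values)
    ly = np.log10(df["unexplained_variance"].values)
    fitted = loess_fit(lx, ly, span=span, degree=2)
    resid = ly - fitted
    resid = resid - resid.mean()  # z-score the residuals: mean exactly 0
    sd = resid.std(ddof=1)
    if sd < 1e-10 * max(1.0, float(np.abs(ly).max())):
        sd = 0.0  # all genes on the trend: no residual spread, Z = 0
    df["log10_mean_cpm"] = lx
    df["log10_unexplained_variance"] = ly
    df["loess_fitted"] = fitted
    df["variance_z"] = resid / sd if sd > 0 else 0.0
    return df[["gene", "log10_mean_cpm", "log10_unexplained_variance",
               "loess_fitted", "variance_z"]]


def rnai_effect_test(brood: pd.Series, treatment: pd.Series,
                     replicates: pd.Series, control: str = "ev",
                     min_obs: int = 3) -> pd.DataFrame:
    """Early-brood effect of each RNAi treatment against the control.

    One mixed model with treatment dummy coding (control as baseline)
    and replicate random intercept; treatments with fewer than
    ``min_obs`` observations are excluded (logged).
    """
    df = pd.DataFrame({"brood": brood, "treatment": treatment,
                       "replicate": replicates}).dropna()
    if control not in set(df["treatment"]):
        raise ValueError(f"control label {control!r} not present")
    counts = df["treatment"].value_counts()
    small = [t for t in counts.index if counts[t] < min_obs and t != control]
    if small:
        log.info("rnai test excluded treatments with < %d observations: %s",
                 min_obs, small)
        df = df[~df["treatment"].isin(small)]
    levels = [t for t in pd.unique(df["treatment"]) if t != control]
    X = np.column_stack([(df["treatment"] == t).astype(float) for t in levels])
    fit = fit_lmm(df["brood"].values.astype(float), X,
                  groups=df["replicate"].values, names=levels)
    rows = [(t, fit.coef(t), fit.se(t), fit.pvalue(t)) for t in levels]
    return pd.DataFrame(rows, columns=["treatment", "estimate", "se", "pvalue"])
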