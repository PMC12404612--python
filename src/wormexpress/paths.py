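"""Standardized path decomposition of expression-trait associations.

For each trait-associated gene k, three random-intercept models are fit:

    Model 1:  trait = b0 + b1 * expr_k                      + u_rep + e
    Model 2:  trait = b0 + b2 * expr_k + b3 * age + b4 * temp + u_rep + e
    Model E:  expr_k = b0 + b5 * age + b6 * temp              + u_rep + e

Every coefficient is standardized as b * sd(x) / sd(y) so that beta_n is
the shift in the dependent variable, in its own SDs, per one-SD change
of the predictor (binary environment variables included — they are
standardized by their sample SD so beta_3..beta_6 are comparable across
genes).  beta_1 is the total expression->trait effect; beta_2 the effect
after adjusting for historical environment ("noise" component); beta_5,
beta_6 the environment->expression paths.  p-values come from the
unstandardized fits.  Intercepts are computed but not reported.

Genes are then classified by whether their beta_2 survives a Bonferroni
cut and whether parental age significantly perturbs their expression
(from the NB environment scan): "noise", "parental_age", "both", or
"neither".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .lmm import fit_lmm

__all__ = ["PathCoefficients", "decompose_gene", "decompose_genes",
           "classify_gene", "classify_genes", "effect_in_trait_units"]

log = logging.getLogger("wormexpress")


@dataclass
class PathCoefficients:
    gene: str
    beta1: float
    p1: float
    beta2: float
    p2: float
    beta3: float
    p3: float
    beta4: float
    p4: float
    beta5: float
    p5: float
    beta6: float
    p6: float
    group: str = "unclassified"

    def as_row(self) -> dict:
        return {
            "gene": self.gene,
            "beta1": self.beta1, "p1": self.p1,
            "beta2": self.beta2, "p2": self.p2,
            "beta3": self.beta3, "p3": self.p3,
            "beta4": self.beta4, "p4": self.p4,
            "beta5": self.beta5, "p5": self.p5,
            "beta6": self.beta6, "p6": self.p6,
            "group": self.group,
        }


def _std_beta(raw: float, x: np.ndarray, y: np.ndarray) -> float:
    sx, sy = x.std(ddof=1), y.std(ddof=1)
    if sx == 0 or sy == 0:
        raise ValueError("degenerate (constant) predictor or response")
    return raw * sx / sy


def decompose_gene(gene: str, trait: pd.Series, cpm: pd.DataFrame,
                   parental_age: pd.Series, early_temp: pd.Series,
                   replicates: pd.Series) -> PathCoefficients:
    """Standardized beta1-beta6 for one gene (see module docstring)."""
    if gene not in cpm.index:
        raise ValueError(f"gene {gene!r} not in expression matrix")
    worms = cpm.columns
    y = trait.loc[worms].values.astype(float)
    x = cpm.loc[gene].values.astype(float)
    age = parental_age.loc[worms].values.astype(float)
    temp = early_temp.loc[worms].values.astype(float)
    groups = replicates.loc[worms].values

    m1 = fit_lmm(y, x[:, None], groups=groups, names=["expr"])
    m2 = fit_lmm(y, np.column_stack([x, age, temp]), groups=groups,
                 names=["expr", "age", "temp"])
    me = fit_lmm(x, np.column_stack([age, temp]), groups=groups,
                 names=["age", "temp"])

    return PathCoefficients(
        gene=gene,
        beta1=_std_beta(m1.coef("expr"), x, y), p1=m1.pvalue("expr"),
        beta2=_std_beta(m2.coef("expr"), x, y), p2=m2.pvalue("expr"),
        beta3=_std_beta(m2.coef("age"), age, y), p3=m2.pvalue("age"),
        beta4=_std_beta(m2.coef("temp"), temp, y), p4=m2.pvalue("temp"),
        beta5=_std_beta(me.coef("age"), age, x), p5=me.pvalue("age"),
        beta6=_std_beta(me.coef("temp"), temp, x), p6=me.pvalue("temp"),
    )


def decompose_genes(genes, trait, cpm, parental_age, early_temp,
                    replicates) -> pd.DataFrame:
    rows = []
    for g in genes:
        try:
            rows.append(decompose_gene(g, trait, cpm, parental_age,
                                       early_temp, replicates).as_row())
        except ValueError as exc:
            log.info("path decomposition skipped %s: %s", g, exc)
    return pd.DataFrame(rows)


def classify_gene(beta2_pvalue: float, beta2_significant: bool,
                  age_de_significant: bool | None) -> str:
    """Noise / parental-age / both / neither classification.

    noise: beta2 survives the Bonferroni cut but parental age does not
    perturb the gene's expression — the trait association is expression
    noise.  parental_age: the converse.  both: both hold.  A gene with
    no environment-scan record cannot be classified (treated as
    age-not-significant, with a warning upstream).
    """
    b2 = bool(beta2_significant)
    age = bool(age_de_significant) if age_de_significant is not None else False
    if b2 and not age:
        return "noise"
    if age and not b2:
        return "parental_age"
    if b2 and age:
        return "both"
    return "neither"


def classify_genes(path_df: pd.DataFrame, env_de: pd.DataFrame,
                   alpha: float = 0.05, family: str = "significant_set"
                   ) -> pd.DataFrame:
    """Attach group labels to a path-decomposition table.

    ``family`` controls the Bonferroni family for beta2: the default
    "significant_set" divides alpha by the number of classified
    (trait-significant) genes; "scan" uses the environment-scan gene
    count instead.
    """
    n_family = len(path_df) if family == "significant_set" else len(env_de)
    thr = alpha / max(n_family, 1)
    age_sig = env_de.set_index("gene")["age_significant"] if len(env_de) else pd.Series(dtype=bool)
    out = path_df.copy()
    labels = []
    for _, row in out.iterrows():
        gene = row["gene"]
        if gene in age_sig.index:
            age_flag = bool(age_sig.loc[gene])
        else:
            log.warning("no environment-scan record for %s; treating as "
                        "age-not-significant", gene)
            age_flag = None
        labels.append(classify_gene(row["p2"], row["p2"] < thr, age_flag))
    out["beta2_significant"] = out["p2"] < thr
    out["group"] = labels
    out.attrs["beta2_threshold"] = thr
    return out


def effect_in_trait_units(std_beta: float, trait_sd: float) -> float:
    """Convert a standardized beta to trait units (beta * SD of trait).

    E.g. a standardized effect of 0.39 on early brood with SD 20.3
    corresponds to 7.917 progeny.
    """
    if trait_sd <= 0:
        raise ValueError("trait_sd must be > 0")
    return std_beta * trait_sd
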