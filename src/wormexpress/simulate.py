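"""Synthetic single-worm cohorts with the study's statistical structure.

Emulates the design of the real experiment: 180 isogenic worms in 5
biological replicates, a 2x2 historical-environment design (parental age
x early-life temperature, each binarized and assigned Bernoulli(0.5)),
negative-binomial counts with replicate random intercepts and
environment effects on a planted gene subset, and two reproductive
traits — early brood (integer, target SD 20.3) and egg-laying onset
(integer hours on a 66-74 h observation window) — generated from direct
standardized gene effects plus environment, replicate, and residual
noise.

The generator exists so every downstream stage (scans, path
decomposition, prediction, enrichment, isogenicity) is testable with
known ground truth and no external download.  What it deliberately does
not emulate: read-level sequencing artifacts, gene-gene co-expression
networks beyond shared replicate/environment structure, and the
wet-lab time course.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .preprocess import ExpressionMatrix, cpm_normalize

__all__ = [
    "SimulationSpec", "GroundTruth", "simulate_design", "simulate_expression",
    "simulate_traits", "simulate_sitecalls", "simulate_chromatin_annotation",
    "simulate_dataset",
]


@dataclass
class SimulationSpec:
    """Parameters of a synthetic cohort.

    Defaults mirror the study design: 180 worms, 5 replicates, early
    brood SD 20.3.  ``frac_env_genes`` (parental-age responsive, ~2.3%
    of expressed genes in the real data) and ``frac_trait_genes`` are
    fractions of the gene universe; effect sizes are standardized
    (per-SD-of-expression) trait effects drawn N(0, effect_size_sd^2).
    ``nb_dispersion`` is theta in Var = mu + mu^2/theta.
    """

    n_worms: int = 180
    n_replicates: int = 5
    n_genes: int = 2000
    frac_env_genes: float = 0.025
    frac_trait_genes: float = 0.02
    effect_size_sd: float = 0.15
    replicate_sd: float = 0.1
    nb_dispersion: float = 10.0
    mean_libsize: float = 2e6
    trait_sd_brood: float = 20.3
    mean_brood: float = 120.0
    trait_env_effects: dict = field(default_factory=lambda: {
        "early_brood": (0.3, 0.0),   # (parental_age, early_temp), standardized
        "elo_hours": (0.2, 0.2),
    })
    env_logfc_sd: float = 0.35      # SD of planted log-scale environment effects
    seed: int = 0

    def __post_init__(self):
        for name in ("frac_env_genes", "frac_trait_genes"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        for name in ("n_worms", "n_replicates", "n_genes"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")


@dataclass
class GroundTruth:
    """Planted parameters, kept for parameter-recovery tests."""

    genes: list = field(default_factory=list)
    beta_trait: dict = field(default_factory=dict)        # trait -> {gene: standardized beta}
    env_effects: dict = field(default_factory=dict)       # gene -> (b_age, b_temp) log scale
    replicate_intercepts: np.ndarray | None = None        # log-expression scale
    trait_causal_genes: dict = field(default_factory=dict)  # trait -> [genes]
    env_responsive_genes: list = field(default_factory=list)
    planted_variants: list = field(default_factory=list)  # (chrom, pos, worm, kind)

    def to_json(self, path) -> None:
        d = asdict(self)
        if d["replicate_intercepts"] is not None:
            d["replicate_intercepts"] = list(map(float, d["replicate_intercepts"]))
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1, default=str)


def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


def simulate_design(spec: SimulationSpec) -> pd.DataFrame:
    """Worms, balanced replicate labels, and Bernoulli(0.5) environments.

    Traits are left unset (NaN); ``simulate_traits`` fills them.
    """
    if spec.n_worms < 2 * spec.n_replicates:
        raise ValueError("need n_worms >= 2 * n_replicates to estimate "
                         "replicate variance")
    rng = _rng(spec.seed)
    base, extra = divmod(spec.n_worms, spec.n_replicates)
    counts = [base + (1 if j < extra else 0) for j in range(spec.n_replicates)]
    replicate = np.repeat(np.arange(1, spec.n_replicates + 1), counts)
    design = pd.DataFrame({
        "worm_id": [f"worm{n:04d}" for n in range(1, spec.n_worms + 1)],
        "replicate": replicate,
        "parental_age": rng.integers(0, 2, spec.n_worms),
        "early_temp": rng.integers(0, 2, spec.n_worms),
        "elo_hours": np.nan,
        "early_brood": np.nan,
    })
    return design


def simulate_expression(design: pd.DataFrame, spec: SimulationSpec,
                        truth: GroundTruth | None = None
                        ) -> tuple[ExpressionMatrix, GroundTruth]:
    """NB counts with replicate intercepts and planted environment effects.

    log-mean for gene g, worm i:
        baseline_g + b_age,g * age_i + b_temp,g * temp_i + u_rep(i)
                   + log(libsize_i / mean_libsize)
    with dispersion ``spec.nb_dispersion``.  Baselines span a realistic
    abundance range (roughly 1-3000 CPM, log-uniform).  The stored
    library sizes of the returned matrix are its column sums.
    """
    for col in ("replicate", "parental_age", "early_temp"):
        if col not in design.columns:
            raise ValueError(f"design lacks column {col!r}")
    rng = _rng(spec.seed + 1)
    n, g = len(design), spec.n_genes
    genes = [f"gene{k:05d}" for k in range(1, g + 1)]
    truth = truth or GroundTruth()
    truth.genes = genes

    # baseline abundance: log-uniform CPM in [1, 3000]
    cpm_base = 10 ** rng.uniform(0.0, np.log10(3000.0), g)
    baseline = np.log(cpm_base * spec.mean_libsize / 1e6)
    if not np.all(np.isfinite(baseline)):
        raise ValueError("non-finite baseline log-means")

    b_age = np.zeros(g)
    b_temp = np.zeros(g)
    if truth.env_effects:
        # caller supplied explicit per-gene environment effects
        for gene, (ba, bt) in truth.env_effects.items():
            k = genes.index(gene) if isinstance(gene, str) else int(gene)
            b_age[k], b_temp[k] = ba, bt
    else:
        # temperature effects are rare in the real data (2 of 7938 genes);
        # plant age effects only by default
        n_env = int(round(spec.frac_env_genes * g))
        env_idx = rng.choice(g, size=n_env, replace=False)
        b_age[env_idx] = rng.normal(0.0, spec.env_logfc_sd, n_env)
    env_idx = np.where((b_age != 0) | (b_temp != 0))[0]
    truth.env_effects = {genes[k]: (float(b_age[k]), float(b_temp[k]))
                         for k in env_idx}
    truth.env_responsive_genes = [genes[k] for k in sorted(env_idx)]

    rep_levels, rep_codes = np.unique(design["replicate"].values, return_inverse=True)
    u = rng.normal(0.0, spec.replicate_sd, len(rep_levels))
    truth.replicate_intercepts = u

    libsize = rng.lognormal(np.log(spec.mean_libsize), 0.3, n)
    age = design["parental_age"].values.astype(float)
    temp = design["early_temp"].values.astype(float)
    log_mu = (baseline[:, None]
              + b_age[:, None] * age[None, :]
              + b_temp[:, None] * temp[None, :]
              + u[rep_codes][None, :]
              + np.log(libsize / spec.mean_libsize)[None, :])
    mu = np.exp(log_mu)
    theta = spec.nb_dispersion
    counts = rng.poisson(mu * rng.gamma(theta, 1.0 / theta, size=mu.shape))
    expr = ExpressionMatrix(pd.DataFrame(counts, index=genes,
                                         columns=design["worm_id"].values))
    return cpm_normalize(expr), truth


def simulate_traits(design: pd.DataFrame, expr: ExpressionMatrix,
                    spec: SimulationSpec, truth: GroundTruth) -> pd.DataFrame:
    """Fill traits from direct gene effects + environment + replicate + noise.

    On a standardized latent scale, trait_z = sum_causal beta_g z(cpm_g)
    + env effects + replicate intercept + N(0,1) noise.  Early brood is
    an affine map of its latent with SD calibrated to
    ``spec.trait_sd_brood`` then rounded to nonnegative integers; ELO is
    mapped onto the integer 66-74 h observation window.
    """
    rng = _rng(spec.seed + 2)
    n = len(design)
    out = design.copy()
    rep_levels, rep_codes = np.unique(design["replicate"].values, return_inverse=True)
    age = design["parental_age"].values.astype(float)
    temp = design["early_temp"].values.astype(float)
    cpm = expr.cpm

    for trait in ("early_brood", "elo_hours"):
        betas = dict(truth.beta_trait.get(trait, {}))
        if not betas:
            n_causal = int(round(spec.frac_trait_genes * spec.n_genes))
            causal = rng.choice(expr.genes, size=n_causal, replace=False)
            betas = {g: float(rng.normal(0.0, spec.effect_size_sd))
                     for g in causal}
        missing = [g for g in betas if g not in expr.genes]
        if missing:
            raise ValueError(f"causal genes absent from expression matrix: {missing[:5]}")
        truth.beta_trait[trait] = betas
        truth.trait_causal_genes[trait] = sorted(betas)

        z = np.zeros(n)
        for gene, b in betas.items():
            x = cpm.loc[gene].values
            sd = x.std(ddof=1)
            if sd > 0:
                z += b * (x - x.mean()) / sd
        b_age_t, b_temp_t = spec.trait_env_effects.get(trait, (0.0, 0.0))
        z += b_age_t * age + b_temp_t * temp
        z += rng.normal(0.0, spec.replicate_sd, len(rep_levels))[rep_codes]
        z += rng.normal(0.0, 1.0, n)

        zc = (z - z.mean()) / z.std(ddof=1)
        if trait == "early_brood":
            vals = np.round(spec.mean_brood + spec.trait_sd_brood * zc)
            out[trait] = np.maximum(vals, 0).astype(int)
        else:
            vals = np.round(70.0 + 1.8 * zc)
            out[trait] = np.clip(vals, 66, 74).astype(int)
    return out


def simulate_dataset(spec: SimulationSpec):
    """Design -> expression -> traits in one call; returns (pheno, expr, truth)."""
    design = simulate_design(spec)
    expr, truth = simulate_expression(design, spec)
    pheno = simulate_traits(design, expr, spec, truth)
    return pheno, expr, truth


def simulate_chromatin_annotation(genes, p_regulated: float = 0.35,
                                  p_germline: float = 0.4, seed: int = 0,
                                  p_other_domain: float = 0.0,
                                  p_other_tissue: float = 0.0) -> pd.DataFrame:
    """Random domain/tissue labels (synthetic stand-in for the published
    chromatin-domain annotation consumed by the enrichment stage)."""
    for name, p in (("p_regulated", p_regulated), ("p_germline", p_germline),
                    ("p_other_domain", p_other_domain), ("p_other_tissue", p_other_tissue)):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{name} must be in [0, 1]")
    rng = _rng(seed)
    genes = list(genes)
    domain = rng.choice(["regulated", "active", "other"], size=len(genes),
                        p=[p_regulated * (1 - p_other_domain),
                           (1 - p_regulated) * (1 - p_other_domain),
                           p_other_domain])
    tissue = rng.choice(["germline", "soma", "other"], size=len(genes),
                        p=[p_germline * (1 - p_other_tissue),
                           (1 - p_germline) * (1 - p_other_tissue),
                           p_other_tissue])
    return pd.DataFrame({"gene": genes, "domain": domain, "tissue": tissue})


def simulate_sitecalls(n_worms: int, n_sites: int, depth_mean: float,
                       error_rate: float = 0.0,
                       planted: GroundTruth | None = None,
                       seed: int = 0, chrom: str = "I",
                       as_frame: bool = True):
    """Per-worm, per-site base counts around planted genotypes.

    Depth ~ Poisson(depth_mean); reads are multinomial around the worm's
    genotype (hom ref by default; planted hom-alt or het at expected
    allele fraction 0.5) with symmetric per-read error_rate.  With
    ``as_frame=False`` returns the raw (worms, sites, 4) count array and
    the site positions — the memory-lean path used for large runs.
    """
    if not 0.0 <= error_rate <= 0.1:
        raise ValueError("error_rate must be in [0, 0.1]")
    if depth_mean <= 0:
        raise ValueError("depth_mean must be > 0")
    rng = _rng(seed)
    bases = np.array(["A", "C", "G", "T"])
    ref = rng.integers(0, 4, n_sites)

    # per-(worm, site) genotype: -1 hom ref, 0..3 hom alt base, 10+alt het
    geno = np.full((n_worms, n_sites), -1, dtype=np.int8)
    planted_records = []
    if planted is not None:
        for chrom_p, pos, worm, kind in planted.planted_variants:
            site = int(pos) - 1
            alt = int((ref[site] + 1) % 4)
            geno[int(worm), site] = alt if kind == "hom" else 10 + alt
            planted_records.append((chrom_p, int(pos), int(worm), kind, alt))

    depth = rng.poisson(depth_mean, size=(n_worms, n_sites))
    counts = np.zeros((n_worms, n_sites, 4), dtype=np.int32)
    err_off = error_rate / 3.0

    def probs_for(true_base_probs):
        # true_base_probs: (4,) genotype base mix; apply symmetric error
        return true_base_probs * (1 - error_rate - err_off) + err_off

    # vectorize by genotype class
    for w in range(n_worms):
        for cls in np.unique(geno[w]):
            idx = np.where(geno[w] == cls)[0]
            if cls == -1:
                true_base = ref[idx]
                p = np.full((len(idx), 4), err_off)
                p[np.arange(len(idx)), true_base] = 1 - error_rate
            elif cls < 10:
                p = np.full((len(idx), 4), err_off)
                p[:, cls] = 1 - error_rate
            else:
                alt = cls - 10
                p = np.full((len(idx), 4), err_off)
                p[np.arange(len(idx)), ref[idx]] += 0.5 * (1 - error_rate - 3 * err_off)
                p[:, alt] += 0.5 * (1 - error_rate - 3 * err_off)
                p += err_off * 0  # keep shape; error already in base level
            p = p / p.sum(axis=1, keepdims=True)
            counts[w, idx] = _multinomial_rows(rng, depth[w, idx], p)

    positions = np.arange(1, n_sites + 1)
    if not as_frame:
        return counts, positions, ref
    frames = []
    for w in range(n_worms):
        frames.append(pd.DataFrame({
            "worm_id": f"worm{w:04d}",
            "chrom": chrom,
            "pos": positions,
            "depth": counts[w].sum(axis=1),
            "A": counts[w, :, 0], "C": counts[w, :, 1],
            "G": counts[w, :, 2], "T": counts[w, :, 3],
        }))
    return pd.concat(frames, ignore_index=True)


def _multinomial_rows(rng, n_arr, p_mat):
    """Row-wise multinomial draws (counts_i ~ Multinomial(n_i, p_i))."""
    out = np.zeros((len(n_arr), p_mat.shape[1]), dtype=np.int32)
    remaining = n_arr.astype(np.int64).copy()
    acc = np.zeros(len(n_arr))
    for k in range(p_mat.shape[1] - 1):
        denom = np.maximum(1.0 - acc, 1e-12)
        draw = rng.binomial(remaining, np.clip(p_mat[:, k] / denom, 0, 1))
        out[:, k] = draw
        remaining -= draw
        acc += p_mat[:, k]
    out[:, -1] = remaining
    return out
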