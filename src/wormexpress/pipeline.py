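"""End-to-end orchestration: simulate -> preprocess -> scan -> decompose ->
predict -> enrich -> isogenicity, with seeded stages and a run manifest.

A single global seed fans out to per-stage seeds through
``numpy.random.SeedSequence(seed).spawn``, so any stage can be rerun in
isolation with an identical stream.  The manifest records the config,
per-stage seeds, and SHA-256 digests of every written output; rerunning
with the same config reproduces the digests bit for bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import simulate as sim
from .preprocess import (ExpressionMatrix, cpm_normalize, filter_genes,
                         log_transform_for_pca, read_counts_tsv,
                         read_phenotypes, write_counts_tsv, write_phenotypes)
from .scans import scan_trait_associations, scan_environment_de, variance_zscores
from .paths import decompose_genes, classify_genes
from .predict import (pca_scores, cumulative_pc_r2, greedy_forward_selection,
                      train_test_resampling, elastic_net_loocv)
from .enrich import (tissue_domain_anova, regulated_proportion_test,
                     variance_by_domain_test)
from .isogenicity import run_isogenicity_check
from .simulate import SimulationSpec, GroundTruth

__all__ = ["RunConfig", "run_pipeline", "stage_seed"]

log = logging.getLogger("wormexpress")

STAGES = ("simulate", "preprocess", "scan", "pathdecomp", "predict",
          "enrich", "isocheck")


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31 from the global seed."""
    h = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2 ** 31)


@dataclass
class RunConfig:
    """Validated configuration of a pipeline run (YAML round-trippable)."""

    outdir: str = "run"
    seed: int = 0
    counts_path: str | None = None       # None -> simulate
    pheno_path: str | None = None
    annotation_path: str | None = None
    sitecalls_path: str | None = None
    simulation: dict = field(default_factory=dict)  # SimulationSpec overrides
    alpha: float = 0.05
    any_gt_threshold: float = 10.0
    all_gt_threshold: float = 1.0
    traits: tuple = ("early_brood", "elo_hours")
    n_perm: int = 100
    k_max_pcs: int = 30
    n_iter: int = 100
    k_genes: int = 10
    alpha_enet: float = 0.5
    run_enet: bool = False               # LOOCV elastic net is the slow stage
    n_random_sets: int = 500
    min_depth: int = 20
    min_worms: int = 10
    stages: tuple = STAGES

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.n_perm < 1 or self.n_iter < 1 or self.k_genes < 1:
            raise ValueError("n_perm, n_iter and k_genes must be >= 1")
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "traits" in data:
            data["traits"] = tuple(data["traits"])
        if "stages" in data:
            data["stages"] = tuple(data["stages"])
        return cls(**data)

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["traits"] = list(d["traits"])
        d["stages"] = list(d["stages"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> Path:
    """Execute the configured stages; returns the run directory.

    Stage failures raise with the stage named; outputs written before
    the failure are left in place.
    """
    from . import __version__

    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    manifest = {"version": __version__, "seed": config.seed,
                "stages": {}, "inputs": {}, "outputs": {}}
    for label in ("counts_path", "pheno_path", "annotation_path",
                  "sitecalls_path"):
        p = getattr(config, label)
        if p is not None and Path(p).is_file():
            manifest["inputs"][label] = _sha256(Path(p))
    t_start = time.time()

    state: dict = {}
    for stage in STAGES:
        if stage not in config.stages:
            manifest["stages"][stage] = {"skipped": True}
            log.info("stage %s skipped by config", stage)
            continue
        t0 = time.time()
        try:
            _run_stage(stage, config, state, out)
        except Exception as exc:
            manifest["stages"][stage] = {"failed": str(exc)}
            (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        manifest["stages"][stage] = {
            "seed": stage_seed(config.seed, stage),
            "seconds": round(time.time() - t0, 3),
        }
        log.info("stage %s done in %.1fs", stage, time.time() - t0)

    for p in sorted(out.rglob("*")):
        if p.is_file() and p.name != "manifest.json":
            manifest["outputs"][str(p.relative_to(out))] = _sha256(p)
    manifest["total_seconds"] = round(time.time() - t_start, 3)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out


def _run_stage(stage: str, config: RunConfig, state: dict, out: Path) -> None:
    seed = stage_seed(config.seed, stage)

    if stage == "simulate":
        if config.counts_path is not None:
            state["expr"] = cpm_normalize(read_counts_tsv(config.counts_path))
            state["pheno"] = read_phenotypes(config.pheno_path)
            state["truth"] = None
            return
        spec = SimulationSpec(**{**config.simulation, "seed": seed})
        pheno, expr, truth = sim.simulate_dataset(spec)
        state.update(pheno=pheno, expr=expr, truth=truth, spec=spec)
        write_counts_tsv(expr, out / "counts.tsv")
        write_phenotypes(pheno, out / "phenotypes.csv")
        truth.to_json(out / "ground_truth.json")
        if config.annotation_path is None:
            ann = sim.simulate_chromatin_annotation(expr.genes, seed=seed + 1)
            ann.to_csv(out / "annotation.tsv", sep="\t", index=False)
            state["annotation"] = ann

    elif stage == "preprocess":
        expr = state["expr"]
        state["any_set"] = filter_genes(expr, "any_gt", config.any_gt_threshold).genes
        state["all_set"] = filter_genes(expr, "all_gt", config.all_gt_threshold).genes
        state["log_all"] = log_transform_for_pca(expr, state["all_set"])
        pd.Series(state["any_set"]).to_csv(out / "genes_any_gt.txt",
                                           index=False, header=False)
        pd.Series(state["all_set"]).to_csv(out / "genes_all_gt.txt",
                                           index=False, header=False)

    elif stage == "scan":
        expr, pheno = state["expr"], state["pheno"]
        ph = pheno.set_index("worm_id")
        cpm_any = expr.cpm.loc[state["any_set"]]
        for trait in config.traits:
            res = scan_trait_associations(ph[trait], cpm_any, ph["replicate"],
                                          alpha=config.alpha)
            res.to_csv(out / f"scan_{trait}.tsv", sep="\t", index=False)
            state[f"scan_{trait}"] = res
        env = scan_environment_de(expr.counts.loc[state["all_set"]], pheno,
                                  alpha=config.alpha)
        env.to_csv(out / "scan_envde.tsv", sep="\t", index=False)
        state["env_de"] = env
        vz = variance_zscores(env)
        vz.to_csv(out / "variance_zscores.tsv", sep="\t", index=False)
        state["var_z"] = vz

    elif stage == "pathdecomp":
        expr, pheno = state["expr"], state["pheno"]
        ph = pheno.set_index("worm_id")
        cpm_any = expr.cpm.loc[state["any_set"]]
        for trait in config.traits:
            scan = state[f"scan_{trait}"]
            sig = list(scan.loc[scan["significant"], "gene"])
            if not sig:
                log.info("no significant genes for %s; path stage skipped", trait)
                continue
            pc = decompose_genes(sig, ph[trait], cpm_any, ph["parental_age"],
                                 ph["early_temp"], ph["replicate"])
            pc = classify_genes(pc, state["env_de"], alpha=config.alpha)
            pc.to_csv(out / f"path_{trait}.tsv", sep="\t", index=False)
            state[f"path_{trait}"] = pc

    elif stage == "predict":
        expr, pheno = state["expr"], state["pheno"]
        ph = pheno.set_index("worm_id")
        scores = pca_scores(state["log_all"])
        log_all = state["log_all"]
        for trait in config.traits:
            y = ph[trait]
            k_max = min(config.k_max_pcs, scores.shape[1], len(scores) - 2)
            curve = cumulative_pc_r2(scores, y, k_max,
                                     n_perm=config.n_perm, seed=seed)
            curve.to_csv(out / f"pc_r2_{trait}.tsv", sep="\t", index=False)
            greedy = greedy_forward_selection(log_all, y, config.k_genes)
            greedy.to_csv(out / f"greedy_{trait}.tsv", sep="\t", index=False)
            resamp = train_test_resampling(log_all, y, n_iter=config.n_iter,
                                           k=config.k_genes, seed=seed)
            resamp.to_csv(out / f"resampling_{trait}.tsv", sep="\t", index=False)
            state[f"resampling_{trait}"] = resamp
            if config.run_enet:
                enet = elastic_net_loocv(log_all, y, alpha=config.alpha_enet,
                                         seed=seed)
                enet.to_csv(out / f"enet_loocv_{trait}.tsv", sep="\t", index=False)
                state[f"enet_{trait}"] = enet

    elif stage == "enrich":
        from .enrich import read_annotation
        ann = state.get("annotation")
        if ann is None:
            if config.annotation_path is None:
                raise ValueError("no annotation available for enrichment")
            ann = read_annotation(config.annotation_path)
        reports = {}
        trait = config.traits[0]
        path_df = state.get(f"path_{trait}")
        if path_df is not None and len(path_df) >= 12:
            try:
                rep = tissue_domain_anova(
                    path_df.set_index("gene")["beta1"], ann)
                reports["anova"] = rep.anova.to_dict("records")
                reports["tukey"] = rep.tukey.to_dict("records")
                reports["cell_ttests"] = rep.cell_ttests.to_dict("records")
            except ValueError as exc:
                log.info("tissue/domain ANOVA skipped: %s", exc)
        resamp = state.get(f"resampling_{trait}")
        if resamp is not None and len(resamp):
            sets = [s.split(";") for s in resamp["genes"]]
            rep = regulated_proportion_test(sets, state["all_set"], ann,
                                            n_random=config.n_random_sets,
                                            seed=seed)
            reports["ks"] = {"statistic": rep.ks_statistic,
                             "pvalue": rep.ks_pvalue}
        if "var_z" in state:
            rep = variance_by_domain_test(state["var_z"], ann)
            reports["wilcoxon"] = {"statistic": rep.wilcoxon_statistic,
                                   "pvalue": rep.wilcoxon_pvalue}
        (out / "enrichment.json").write_text(json.dumps(reports, indent=1))
        state["enrichment"] = reports

    elif stage == "isocheck":
        if config.sitecalls_path is not None:
            from .isogenicity import read_sitecalls
            table = read_sitecalls(config.sitecalls_path)
        else:
            truth = GroundTruth(planted_variants=[("I", 101, 0, "het")])
            table = sim.simulate_sitecalls(
                n_worms=20, n_sites=2000, depth_mean=40.0, error_rate=0.0,
                planted=truth, seed=seed)
        report, hom, het = run_isogenicity_check(
            table, min_depth=config.min_depth,
            min_worms_covered=config.min_worms)
        (out / "isogenicity.json").write_text(
            json.dumps(report.to_dict(), indent=1))
        bed_rows = []
        for df, kind in ((hom, "hom"), (het, "het")):
            for _, r in df.iterrows():
                chrom, pos = str(r["site"]).split(":")
                bed_rows.append((chrom, int(pos) - 1, int(pos), kind))
        pd.DataFrame(bed_rows, columns=["chrom", "start", "end", "class"]) \
            .to_csv(out / "variant_candidates.bed", sep="\t",
                    index=False, header=False)
        state["isogenicity"] = report
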