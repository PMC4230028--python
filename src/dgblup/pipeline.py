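"""End-to-end orchestration: simulate -> qc -> matrices -> reml/gibbs -> cv
-> mate, with a reproducibility manifest.

Every randomized stage consumes a child seed spawned deterministically from
the global seed via ``numpy.random.SeedSequence(global_seed).spawn``; the
manifest records the config snapshot, per-stage seeds and a SHA-256 checksum
of every artifact, which suffices to reproduce a run bit for bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as dio
from .containers import VarianceComponents
from .cv import cross_validate, make_folds
from .gibbs import geweke_diagnostic, gibbs_animal
from .mating import (
    allocate_matings,
    gain_summary,
    mating_score_matrices,
    snp_blup_effects,
)
from .qc import QCThresholds, apply_qc
from .relmat import build_D, build_G, pedigree_A
from .simulate import SimConfig, simulate_phenotypes, simulate_population, assign_effects
from .varcomp import ModelSpec, animal_to_marker_variance, mixture_lrt, reml_fit

__all__ = ["RunConfig", "run_pipeline"]

_ALL_STAGES = ("simulate", "qc", "matrices", "reml", "gibbs", "cv", "mate")


@dataclass
class RunConfig:
    out_dir: str
    seed: int = 0
    stages: tuple = _ALL_STAGES
    sim: dict = field(default_factory=dict)
    qc: dict = field(default_factory=dict)
    blend_weight: float = 0.95
    gibbs: dict = field(default_factory=lambda: {"n_iter": 20000, "burn_in": 2000, "thin": 10})
    cv_folds: int = 10
    n_bulls: int = 50
    mating_cap: int = 200

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the selected stages and return the run manifest.

    A stage failure aborts with the failing stage named; artifacts written
    by earlier stages are retained.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage_seeds = {
        name: int(child.generate_state(1)[0] % (2**31))
        for name, child in zip(
            _ALL_STAGES, np.random.SeedSequence(config.seed).spawn(len(_ALL_STAGES))
        )
    }
    manifest: dict = {
        "config": {
            **dataclasses.asdict(config),
            "stages": list(config.stages),
        },
        "stage_seeds": stage_seeds,
        "artifacts": {},
        "stages_run": [],
    }

    def record(name: str, path: Path) -> None:
        manifest["artifacts"][name] = {
            "path": str(path),
            "sha256": _sha256(path),
        }

    state: dict = {}
    for stage in config.stages:
        t0 = time.time()
        try:
            if stage == "simulate":
                sim_cfg = SimConfig(**{"seed": stage_seeds["simulate"], **config.sim})
                pedigree, genotypes = simulate_population(sim_cfg)
                effects = assign_effects(genotypes, sim_cfg)
                offspring = pedigree.loc[pedigree["generation"] > 0, "id"].to_numpy()
                phenotypes = simulate_phenotypes(genotypes, effects, sim_cfg, ids=offspring)
                dio.write_pedigree(pedigree, out / "pedigree.csv")
                dio.write_genotypes(genotypes, out / "genotypes.tsv")
                dio.write_phenotypes(phenotypes, out / "phenotypes.csv")
                dio.write_effects(effects, genotypes.locus_ids, out / "true_effects.tsv")
                for name in ("pedigree.csv", "genotypes.tsv", "phenotypes.csv", "true_effects.tsv"):
                    record(name, out / name)
                state.update(pedigree=pedigree, genotypes=genotypes, phenotypes=phenotypes)
            elif stage == "qc":
                geno = state.get("genotypes") or dio.read_genotypes(out / "genotypes.tsv")
                clean, report = apply_qc(geno, QCThresholds(**config.qc))
                dio.write_genotypes(clean, out / "genotypes_qc.tsv")
                (out / "qc_report.json").write_text(json.dumps(report.to_dict(), indent=2))
                record("genotypes_qc.tsv", out / "genotypes_qc.tsv")
                record("qc_report.json", out / "qc_report.json")
                state["genotypes_qc"] = clean
            elif stage == "matrices":
                clean = state.get("genotypes_qc") or dio.read_genotypes(out / "genotypes_qc.tsv")
                pedigree = state.get("pedigree")
                if pedigree is None:
                    pedigree = dio.read_pedigree(out / "pedigree.csv")
                pheno = state.get("phenotypes")
                if pheno is None:
                    pheno = dio.read_phenotypes(out / "phenotypes.csv")
                A_full = pedigree_A(pedigree)
                cohort = list(pheno["id"])
                index = {v: i for i, v in enumerate(clean.ids)}
                rows = np.array([index[i] for i in cohort])
                geno_cohort = clean.subset(rows=rows)
                A = A_full.subset(cohort)
                G = build_G(geno_cohort, A, config.blend_weight)
                D = build_D(geno_cohort, config.blend_weight)
                for name, M in (("A", A), ("G", G), ("D", D)):
                    dio.write_matrix(M, out / f"{name}.tsv")
                    record(f"{name}.tsv", out / f"{name}.tsv")
                state.update(A=A, G=G, D=D, geno_cohort=geno_cohort, phenotypes=pheno)
            elif stage in ("reml", "gibbs", "cv", "mate"):
                pheno = state["phenotypes"]
                y = pheno["yd"].to_numpy()
                eop = pheno["eop"].to_numpy()
                mats = {"A": state["A"], "G": state["G"], "D": state["D"]}
                if stage == "reml":
                    fits = {}
                    for model in ("MA", "MG", "MGD"):
                        spec = ModelSpec(model=model, y=y, eop=eop)
                        fits[model] = reml_fit(spec, mats)
                    lrt = mixture_lrt(fits["MG"].neg2logL, fits["MGD"].neg2logL)
                    summary = {
                        m: {
                            "sigma_A2": f.components.sigma_A2,
                            "sigma_D2": f.components.sigma_D2,
                            "sigma_E2": f.components.sigma_E2,
                            "dominance_ratio": f.components.dominance_ratio,
                            "neg2logL": f.neg2logL,
                            "converged": f.converged,
                        }
                        for m, f in fits.items()
                    }
                    summary["lrt_MG_vs_MGD"] = {"chi2": lrt.chi2, "p": lrt.p_value}
                    (out / "reml.json").write_text(json.dumps(summary, indent=2))
                    record("reml.json", out / "reml.json")
                    state["fits"] = fits
                elif stage == "gibbs":
                    spec = ModelSpec(model="MGD", y=y, eop=eop)
                    g = config.gibbs
                    chain = gibbs_animal(
                        spec, mats, n_iter=g.get("n_iter", 20000),
                        burn_in=g.get("burn_in", 2000), thin=g.get("thin", 10),
                        seed=stage_seeds["gibbs"],
                    )
                    summ = {
                        k: {"mean": mean, "sd": sd}
                        for k, (mean, sd) in chain.summary().items()
                    }
                    summ["geweke_z"] = geweke_diagnostic(chain)
                    (out / "gibbs.json").write_text(json.dumps(summ, indent=2))
                    record("gibbs.json", out / "gibbs.json")
                    state["chain"] = chain
                elif stage == "cv":
                    folds = make_folds(pheno["id"].to_numpy(), config.cv_folds,
                                       seed=stage_seeds["cv"])
                    rows = {}
                    for model in ("MA", "MG", "MGD"):
                        spec = ModelSpec(model=model, y=y, eop=eop)
                        comp = state["fits"][model].components
                        res = cross_validate(spec, comp, mats, folds)
                        rows[model] = {
                            "mean": res.mean.to_dict(),
                            "se": res.se.to_dict(),
                        }
                    (out / "cv.json").write_text(json.dumps(rows, indent=2))
                    record("cv.json", out / "cv.json")
                elif stage == "mate":
                    comp = state["fits"]["MGD"].components
                    geno = state["geno_cohort"]
                    p = geno.allele_freq()
                    sa2, sd2 = animal_to_marker_variance(
                        comp.sigma_A2, comp.sigma_D2, p
                    )
                    comp_m = VarianceComponents(
                        sigma_A2=comp.sigma_A2, sigma_D2=comp.sigma_D2,
                        sigma_E2=comp.sigma_E2, sigma_a2=sa2, sigma_d2=sd2,
                    )
                    effects = snp_blup_effects(y, geno, comp_m, eop=eop)
                    # bulls: top-B cohort individuals by predicted breeding value
                    ubv = (geno.codes - 2 * p) @ effects.alpha(p)
                    top = np.argsort(-ubv)[: config.n_bulls]
                    cows = np.setdiff1d(np.arange(geno.n), top)
                    scores = mating_score_matrices(
                        geno.subset(rows=top), geno.subset(rows=cows), effects, p
                    )
                    result = {}
                    for crit in ("g", "u"):
                        plan = allocate_matings(scores, crit, cap=config.mating_cap)
                        result[crit] = gain_summary(plan, scores)
                    (out / "mate.json").write_text(json.dumps(result, indent=2))
                    record("mate.json", out / "mate.json")
        except Exception as err:
            raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err
        manifest["stages_run"].append({"stage": stage, "seconds": round(time.time() - t0, 3)})

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
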