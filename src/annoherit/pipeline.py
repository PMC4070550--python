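"""End-to-end orchestration: simulate -> gwas -> enrich -> logit -> grm ->
reml -> report, driven by one YAML config and one master seed.

Every stage writes its outputs as TSV/JSON into the run directory and the
manifest records a SHA-256 checksum per output plus per-stage wall time, so
a rerun under the same config can be verified byte-for-byte (wall times
aside).  Stages communicate only through their declared files.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io_tables as iot
from ._seeds import derive_seed
from .data import ValidationError, build_design
from .enrichment import DEFAULT_TAV_THRESHOLD, DEFAULT_THRESHOLDS, status_matrix, threshold_sweep
from .grm import compute_grm, distance_heatmap
from .gwas import run_gwas
from .logistic import fit_trait
from .reml import fit_reml, per_snp_variance, random_intergenic_comparison
from .simulate import ClassSpec, FixedEffectSpec, SimScenario, assign_annotations, simulate_genotypes, simulate_phenotypes

logger = logging.getLogger(__name__)

__version__ = "0.1.0"


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    master_seed: int = 0
    scenario: SimScenario | None = None
    genotypes: str | None = None
    genotype_format: str = "tsv"
    annotations: str | None = None
    gwas: str | None = None
    phenotypes: str | None = None
    trait: str = "trait"
    covariates: list[str] = field(default_factory=list)
    tav_threshold: float = DEFAULT_TAV_THRESHOLD
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS
    n_perm: int = 1000
    n_reps: int = 5
    variance_classes: list[str] | None = None
    drop_classes: list[str] = field(default_factory=list)
    write_grms: bool = True
    min_class_snps: int = 10  # smallest class size worth a GRM/REML fit

    def validate(self) -> None:
        if self.scenario is None:
            if self.genotypes is None or self.annotations is None:
                raise ValidationError(
                    "config needs either a simulation scenario or genotype + "
                    "annotation input paths"
                )
            if self.gwas is None and self.phenotypes is None:
                raise ValidationError(
                    "config needs either a GWAS p-value table or phenotypes"
                )
            for name in ("genotypes", "annotations", "gwas", "phenotypes"):
                path = getattr(self, name)
                if path is not None and not Path(path).exists():
                    raise ValidationError(f"{name} file not found: {path}")
        if self.n_perm < 1 or self.n_reps < 1:
            raise ValidationError("n_perm and n_reps must be positive")
        if not 0 < self.tav_threshold <= 1:
            raise ValidationError("tav_threshold must be in (0, 1]")


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return config_from_dict(raw)


def config_from_dict(raw: dict) -> PipelineConfig:
    raw = dict(raw)
    scenario = None
    if "scenario" in raw:
        s = dict(raw.pop("scenario"))
        if "class_spec" in s:
            s["class_spec"] = tuple(
                ClassSpec(c["name"], float(c["proportion"]), c.get("parent"))
                for c in s["class_spec"]
            )
        if "fixed_effects" in s:
            s["fixed_effects"] = tuple(
                FixedEffectSpec(f["name"], tuple(float(v) for v in f["effects"]))
                for f in s["fixed_effects"]
            )
        if "maf_range" in s:
            s["maf_range"] = tuple(float(v) for v in s["maf_range"])
        scenario = SimScenario(**s)
    if "thresholds" in raw:
        raw["thresholds"] = tuple(float(t) for t in raw["thresholds"])
    known = set(PipelineConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ValidationError(f"unknown config keys: {sorted(unknown)}")
    cfg = PipelineConfig(scenario=scenario, **raw)
    cfg.validate()
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Run all stages; returns (and writes) the manifest."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "master_seed": config.master_seed,
        "stages": [],
    }

    def record(stage: str, outputs: list[Path], t0: float) -> None:
        manifest["stages"].append(
            {
                "name": stage,
                "outputs": {p.name: _sha256(p) for p in outputs},
                "wall_time_s": round(time.perf_counter() - t0, 3),
            }
        )

    def run_stage(stage, fn):
        t0 = time.perf_counter()
        try:
            outputs = fn()
        except Exception as exc:  # halt with the failing stage named
            _write_manifest(manifest, outdir)
            raise PipelineError(stage, str(exc)) from exc
        record(stage, outputs, t0)
        logger.info("stage %s done (%d outputs)", stage, len(outputs))

    state: dict = {}

    # ---- stage 1: simulate or load -------------------------------------
    def stage_data() -> list[Path]:
        if config.scenario is not None:
            scenario = config.scenario
            genotypes = simulate_genotypes(scenario)
            annotations = assign_annotations(scenario, genotypes)
            design, truth = simulate_phenotypes(scenario, genotypes, annotations)
            paths = [
                outdir / "genotypes.tsv",
                outdir / "annotations.tsv",
                outdir / "phenotypes.tsv",
                outdir / "truth.json",
            ]
            iot.write_genotypes(genotypes, paths[0])
            iot.write_annotations(annotations, paths[1])
            iot.write_phenotypes(design.pheno_frame, paths[2])
            iot.write_truth(truth.as_dict(), paths[3])
        else:
            genotypes = iot.read_genotypes(config.genotypes, config.genotype_format)
            annotations = iot.read_annotations(config.annotations)
            design = None
            if config.phenotypes is not None:
                pheno = iot.read_phenotypes(config.phenotypes)
                design = build_design(pheno, config.trait, config.covariates)
            paths = []
        annotations = annotations.reordered(list(genotypes.snp_ids))
        state["genotypes"] = genotypes
        state["annotations"] = annotations
        state["design"] = design
        return paths

    run_stage("data", stage_data)

    # ---- stage 2: gwas --------------------------------------------------
    def stage_gwas() -> list[Path]:
        if config.scenario is None and config.gwas is not None:
            gwas = iot.read_gwas(config.gwas).reordered(list(state["genotypes"].snp_ids))
        else:
            res = run_gwas(state["genotypes"], state["design"], config.trait)
            gwas = res.gwas
        state["gwas"] = gwas
        path = outdir / "gwas.tsv"
        iot.write_gwas(gwas, path)
        return [path]

    run_stage("gwas", stage_gwas)

    # ---- stage 3: enrichment -------------------------------------------
    def stage_enrich() -> list[Path]:
        sweep = threshold_sweep(
            state["gwas"],
            state["annotations"],
            thresholds=config.thresholds,
            n_perm=config.n_perm,
            master_seed=derive_seed(config.master_seed, "enrichment"),
        )
        state["sweep"] = sweep
        path = outdir / "enrichment.tsv"
        sweep.to_csv(path, sep="\t", index=False, float_format="%.10g")
        return [path]

    run_stage("enrich", stage_enrich)

    # ---- stage 4: logistic ----------------------------------------------
    def stage_logit() -> list[Path]:
        rows = []
        for trait in state["gwas"].traits:
            for tag, drops in [("full", None), *(
                [("drop:" + ",".join(config.drop_classes), config.drop_classes)]
                if config.drop_classes
                else []
            )]:
                fit = fit_trait(
                    state["gwas"], state["annotations"], trait,
                    threshold=config.tav_threshold, drop_classes=drops,
                )
                for cname in fit.classes:
                    rows.append(
                        {
                            "trait": trait,
                            "model": tag,
                            "class": cname,
                            "coefficient": fit.coefficient(cname),
                            "neglog10_p": fit.neglog10_p(cname),
                            "converged": fit.converged,
                        }
                    )
        path = outdir / "logistic.tsv"
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.10g")
        return [path]

    run_stage("logit", stage_logit)

    # ---- stage 5: GRMs ---------------------------------------------------
    def stage_grm() -> list[Path]:
        annotations = state["annotations"]
        classes = config.variance_classes or [
            c for c in annotations.class_names
            if annotations.n_members(c) >= config.min_class_snps
        ]
        grms = {}
        paths = []
        for cname in classes:
            grms[cname] = compute_grm(
                state["genotypes"], annotations.members(cname), cname
            )
            if config.write_grms:
                p = outdir / f"grm_{cname}.tsv"
                iot.write_grm(grms[cname], p)
                paths.append(p)
        state["grms"] = grms
        dmat = distance_heatmap(list(grms.values()))
        p = outdir / "grm_distances.tsv"
        pd.DataFrame(
            dmat.distances, index=dmat.class_names, columns=dmat.class_names
        ).to_csv(p, sep="\t", float_format="%.10g")
        paths.append(p)
        return paths

    run_stage("grm", stage_grm)

    # ---- stage 6: REML + random-intergenic comparison --------------------
    def stage_reml() -> list[Path]:
        design = state["design"]
        if design is None:
            raise ValidationError("variance analysis needs phenotypes")
        annotations = state["annotations"]
        grms = state["grms"]
        rows = []
        for cname, grm in grms.items():
            fit = fit_reml(design, grm)
            comp = None
            if (
                cname != "intergenic"
                and annotations.n_members("intergenic") >= annotations.n_members(cname)
                and "intergenic" in annotations.class_names
            ):
                comp = random_intergenic_comparison(
                    design, state["genotypes"], annotations, cname,
                    trait=config.trait, n_reps=config.n_reps,
                    master_seed=derive_seed(config.master_seed, "randint", cname),
                    class_fit=fit,
                )
            rows.append(
                {
                    "class": cname,
                    "trait": config.trait,
                    "n_snps": grm.n_snps,
                    "h2": fit.h2[cname],
                    "se": fit.se_h2[cname],
                    "random_h2": comp.mean_random_h2 if comp else float("nan"),
                    "random_se": comp.random_se if comp else float("nan"),
                    "difference": comp.difference if comp else float("nan"),
                    "flag": comp.significant if comp else "NA",
                    "converged": fit.converged,
                }
            )
        path = outdir / "variance.tsv"
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.10g")

        # joint multi-GRM fit over disjoint-enough classes -> per-SNP variance
        joint_classes = [c for c in grms if c not in ("intergenic",)]
        paths = [path]
        if joint_classes:
            joint = fit_reml(design, [grms[c] for c in joint_classes])
            jrows = []
            for cname in joint_classes:
                jrows.append(
                    {
                        "class": cname,
                        "trait": config.trait,
                        "n_snps": grms[cname].n_snps,
                        "h2_joint": joint.h2[cname],
                        "se": joint.se_h2[cname],
                        "per_snp_variance": per_snp_variance(
                            joint.h2[cname], grms[cname].n_snps
                        ),
                        "converged": joint.converged,
                    }
                )
            jpath = outdir / "joint_variance.tsv"
            pd.DataFrame(jrows).to_csv(jpath, sep="\t", index=False, float_format="%.10g")
            paths.append(jpath)
        return paths

    run_stage("reml", stage_reml)

    # ---- stage 7: report --------------------------------------------------
    def stage_report() -> list[Path]:
        return report(outdir, tav_threshold=config.tav_threshold)

    run_stage("report", stage_report)

    _write_manifest(manifest, outdir)
    return manifest


def _write_manifest(manifest: dict, outdir: Path) -> None:
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")


def report(run_dir: str | Path, tav_threshold: float = DEFAULT_TAV_THRESHOLD) -> list[Path]:
    """Summary tables from a completed run directory.

    Writes: the class x trait '+ / - / ns' enrichment matrix, the logistic
    table with '-log10 p (coefficient)' cells, and the variance comparison
    table with a '*' marker on differences beyond +-2 SE.
    """
    run_dir = Path(run_dir)
    outputs: list[Path] = []

    sweep_path = run_dir / "enrichment.tsv"
    if sweep_path.exists():
        sweep = pd.read_csv(sweep_path, sep="\t")
        mat = status_matrix(sweep, tav_threshold)
        p = run_dir / "report_enrichment_matrix.tsv"
        mat.to_csv(p, sep="\t")
        outputs.append(p)

    logit_path = run_dir / "logistic.tsv"
    if logit_path.exists():
        logit = pd.read_csv(logit_path, sep="\t")
        full = logit[logit["model"] == "full"].copy()
        if len(full):
            full["cell"] = [
                f"{nl:.2f} ({c:.3f})"
                for nl, c in zip(full["neglog10_p"], full["coefficient"])
            ]
            mat = full.pivot(index="class", columns="trait", values="cell")
            p = run_dir / "report_logistic_matrix.tsv"
            mat.to_csv(p, sep="\t")
            outputs.append(p)

    var_path = run_dir / "variance.tsv"
    if var_path.exists():
        var = pd.read_csv(var_path, sep="\t")
        var["significance"] = np.where(
            var["flag"].isin(["increase", "decrease"]), "*", ""
        )
        p = run_dir / "report_variance.tsv"
        var.to_csv(p, sep="\t", index=False, float_format="%.10g")
        outputs.append(p)

    return outputs
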