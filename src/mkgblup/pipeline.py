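"""Configuration-driven end-to-end pipeline with a provenance manifest.

Stages run in dependency order: simulate (or ingest) -> marker QC ->
phenotype processing -> kernels -> cross-validation of the six models ->
response to selection -> trait importance.  Every stochastic stage receives
a seed derived deterministically from the global seed, so individual stages
are reproducible in isolation.  Re-runs skip stages whose outputs already
exist under an unchanged configuration unless forced.
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

from . import evaluate, genotype, importance, kernels, phenotype, simulate
from .predict import MODEL_NAMES, ChainConfig, ModelSpec

logger = logging.getLogger(__name__)

STAGES = ["simulate", "qc", "pheno", "kernels", "cv", "rts", "importance"]


class PipelineError(RuntimeError):
    pass


def derive_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed: low 31 bits of SHA-256(global_seed:stage)."""
    h = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


@dataclass
class PipelineConfig:
    out_dir: str = "pipeline_out"
    seed: int = 0
    # data source: either a simulation, or paths to genotype + plot tables
    simulation: simulate.SimulationConfig | None = None
    genotype_csv: str | None = None
    genotype_vcf: str | None = None
    plots_csv: str | None = None
    # stage parameters
    max_missing: float = 0.80
    min_maf: float = 0.05
    fisher_filter: bool = False
    impute_method: str = "column_mean"
    dth_covariate: bool = False
    physio_traits: list[str] = field(default_factory=lambda: list(phenotype.PHYSIO_TRAITS))
    models: list[str] = field(default_factory=lambda: list(MODEL_NAMES))
    k_groups: int = 10
    cv_folds: int = 5
    n_iter: int = 4000
    burn_in: int = 1000
    thin: int = 5
    selection_intensity: float = 0.10
    importance_repeats: int = 5
    stages: list[str] = field(default_factory=lambda: list(STAGES))
    force: bool = False

    def validate(self) -> None:
        if self.simulation is None and self.genotype_csv is None and self.genotype_vcf is None:
            raise PipelineError("no genotype source: set simulation or a genotype path")
        if self.simulation is None and self.plots_csv is None:
            raise PipelineError("no phenotype source: set simulation or plots_csv")
        for s in self.stages:
            if s not in STAGES:
                raise PipelineError(f"unknown stage {s!r}")
        for path_attr in ("genotype_csv", "genotype_vcf", "plots_csv"):
            p = getattr(self, path_attr)
            if p is not None and not Path(p).exists():
                raise PipelineError(f"{path_attr} does not exist: {p}")

    def fingerprint(self) -> str:
        payload = {k: v for k, v in self.__dict__.items() if k != "force"}
        if self.simulation is not None:
            payload["simulation"] = self.simulation.__dict__.copy()
            payload["simulation"]["physio_loadings"] = dict(self.simulation.physio_loadings)
        return hashlib.sha256(
            json.dumps(payload, default=str, sort_keys=True).encode()
        ).hexdigest()


def _file_hash(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages; returns the run manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.json"
    fingerprint = config.fingerprint()
    old = {}
    if manifest_path.exists():
        old = json.loads(manifest_path.read_text())
        if old.get("fingerprint") != fingerprint:
            old = {}
    manifest: dict = {"fingerprint": fingerprint, "stages": dict(old.get("stages", {}))}

    def done(stage: str, outputs: list[Path]) -> bool:
        return (
            not config.force
            and stage in manifest["stages"]
            and all(Path(p).exists() for p in manifest["stages"][stage]["outputs"])
        ) and all(o.exists() for o in outputs)

    def record(stage: str, outputs: list[Path], t0: float) -> None:
        manifest["stages"][stage] = {
            "outputs": [str(o) for o in outputs],
            "hashes": {o.name: _file_hash(o) for o in outputs},
            "elapsed_s": round(time.time() - t0, 2),
        }
        manifest_path.write_text(json.dumps(manifest, indent=2))

    state: dict = {}

    def load_markers_raw() -> genotype.MarkerMatrix:
        if "markers_raw" in state:
            return state["markers_raw"]
        if (out / "markers_raw.csv").exists():
            m = genotype.MarkerMatrix.from_csv(out / "markers_raw.csv")
        elif config.genotype_csv:
            m = genotype.MarkerMatrix.from_csv(config.genotype_csv)
        else:
            m = genotype.MarkerMatrix.from_vcf(config.genotype_vcf)
        state["markers_raw"] = m
        return m

    def load_plots() -> pd.DataFrame:
        if "plots" in state:
            return state["plots"]
        path = out / "plots.csv" if (out / "plots.csv").exists() else config.plots_csv
        state["plots"] = pd.read_csv(path)
        return state["plots"]

    try:
        # ---------------------------------------------------------- simulate
        if "simulate" in config.stages and config.simulation is not None:
            outputs = [out / "markers_raw.csv", out / "plots.csv", out / "truth.csv", out / "weather.csv"]
            if not done("simulate", outputs):
                t0 = time.time()
                sim = config.simulation
                markers, plots, weather, truth = simulate.simulate_dataset(sim)
                markers.to_csv(outputs[0])
                plots.to_csv(outputs[1], index=False)
                truth.to_csv(outputs[2])
                weather.to_csv(outputs[3], index=False)
                state["markers_raw"] = markers
                state["plots"] = plots
                record("simulate", outputs, t0)
            else:
                logger.info("simulate: outputs present, skipping")

        # ---------------------------------------------------------------- qc
        if "qc" in config.stages:
            outputs = [out / "markers_qc.csv", out / "qc_report.json"]
            if not done("qc", outputs):
                t0 = time.time()
                m = load_markers_raw()
                m = genotype.filter_markers(m, config.max_missing, config.min_maf)
                if config.fisher_filter:
                    m = genotype.fisher_allelic_filter(m)
                m = genotype.impute_markers(m, config.impute_method)
                m.to_csv(outputs[0])
                outputs[1].write_text(json.dumps(genotype.qc_report(m), indent=2))
                state["markers"] = m
                record("qc", outputs, t0)
            else:
                state["markers"] = genotype.MarkerMatrix.from_csv(outputs[0])

        # ------------------------------------------------------------- pheno
        if "pheno" in config.stages:
            outputs = [out / "lsmeans.csv", out / "heritability.csv", out / "correlations.csv"]
            if not done("pheno", outputs):
                t0 = time.time()
                plots = phenotype.derive_traits(load_plots())
                lsm_frames = [
                    phenotype.compute_lsmeans(plots, "GY", dth_covariate=config.dth_covariate)
                ]
                for trait in config.physio_traits:
                    if trait in plots.columns and plots[trait].notna().any():
                        lsm_frames.append(phenotype.compute_lsmeans(plots, trait))
                lsm = pd.concat(lsm_frames, ignore_index=True)
                lsm.to_csv(outputs[0], index=False)
                h2 = phenotype.heritability_all(plots, "GY")
                pd.Series(h2, name="H2").rename_axis("environment").to_csv(outputs[1])
                corr = pd.concat(
                    [
                        phenotype.trait_yield_correlations(lsm, env).assign(environment=env)
                        for env in sorted(plots["environment"].unique())
                    ],
                    ignore_index=True,
                )
                corr.to_csv(outputs[2], index=False)
                state["lsmeans"], state["h2"] = lsm, h2
                record("pheno", outputs, t0)
            else:
                state["lsmeans"] = pd.read_csv(outputs[0])
                state["h2"] = pd.read_csv(outputs[1], index_col=0)["H2"].to_dict()

        # ----------------------------------------------------------- kernels
        if "kernels" in config.stages:
            outputs = [out / "grm.csv", out / "pkernel.csv", out / "design.csv"]
            if not done("kernels", outputs):
                t0 = time.time()
                markers = state.get("markers") or genotype.MarkerMatrix.from_csv(out / "markers_qc.csv")
                lsm = state["lsmeans"]
                grm = genotype.compute_grm(markers)
                gy = lsm[lsm["trait"] == "GY"]
                design = kernels.RecordDesign.from_lsmeans(gy)
                physio = kernels.compute_physio_kernel(
                    lsm[lsm["trait"] != "GY"],
                    traits=[t for t in config.physio_traits],
                    line_ids=design.line_levels,
                )
                grm.to_csv(outputs[0])
                physio.to_csv(outputs[1])
                design.to_frame().to_csv(outputs[2], index=False)
                state.update(grm=grm, physio=physio, design=design)
                record("kernels", outputs, t0)
            else:
                state["grm"] = genotype.GenomicKernel.from_csv(outputs[0])
                lsm = state["lsmeans"]
                state["design"] = kernels.RecordDesign.from_lsmeans(lsm[lsm["trait"] == "GY"])
                state["physio"] = kernels.compute_physio_kernel(
                    lsm[lsm["trait"] != "GY"], line_ids=state["design"].line_levels
                )

        # ---------------------------------------------------------------- cv
        needs_cv = {"cv", "rts"} & set(config.stages)
        if needs_cv:
            outputs = [out / "cv_accuracy.csv", out / "cv_gebv.csv", out / "folds.csv"]
            if not done("cv", outputs):
                t0 = time.time()
                markers = state.get("markers") or genotype.MarkerMatrix.from_csv(out / "markers_qc.csv")
                design = state["design"]
                lsm = state["lsmeans"]
                gy = lsm[lsm["trait"] == "GY"].sort_values(["environment", "genotype"])
                y = gy["lsmean"].to_numpy()
                groups = evaluate.stratify_lines(
                    markers, k_groups=config.k_groups, seed=derive_seed(config.seed, "strat")
                )
                folds = evaluate.assign_folds(
                    groups, f=config.cv_folds, seed=derive_seed(config.seed, "folds")
                )
                expanded = kernels.build_model_kernels(state["grm"], state["physio"], design)
                chain = ChainConfig(
                    n_iter=config.n_iter,
                    burn_in=config.burn_in,
                    thin=config.thin,
                    seed=derive_seed(config.seed, "gibbs"),
                )
                results, gebv_table = evaluate.cross_validate(
                    y,
                    design,
                    [ModelSpec(mn) for mn in config.models],
                    expanded,
                    folds,
                    state["h2"],
                    chain,
                    dth_corrected=config.dth_covariate,
                    return_gebv=True,
                )
                evaluate.cv_table(results).to_csv(outputs[0], index=False)
                gebv_table.to_csv(outputs[1], index=False)
                folds.folds.rename("fold").rename_axis("genotype").to_csv(outputs[2])
                state["gebv_table"] = gebv_table
                record("cv", outputs, t0)
            else:
                state["gebv_table"] = pd.read_csv(outputs[1])

        # --------------------------------------------------------------- rts
        if "rts" in config.stages:
            outputs = [out / "rts.csv"]
            if not done("rts", outputs):
                t0 = time.time()
                rts = evaluate.rts_from_cv(
                    state["gebv_table"], state["h2"], config.selection_intensity
                )
                rts.to_csv(outputs[0], index=False)
                record("rts", outputs, t0)

        # -------------------------------------------------------- importance
        if "importance" in config.stages:
            outputs = [out / "importance.csv"]
            if not done("importance", outputs):
                t0 = time.time()
                lsm = state["lsmeans"]
                frames = []
                for env in sorted(set(lsm["environment"])):
                    sub = lsm[lsm["environment"] == env]
                    wide = sub.pivot_table(index="genotype", columns="trait", values="lsmean")
                    traits = [t for t in config.physio_traits if t in wide.columns]
                    data = wide[traits + ["GY"]].dropna()
                    if len(data) < 2 * config.cv_folds or len(traits) < 2:
                        continue
                    res = importance.tune_and_rank(
                        data[traits],
                        data["GY"].to_numpy(),
                        importance.ImportanceConfig(
                            cv_repeats=config.importance_repeats,
                            seed=derive_seed(config.seed, f"imp:{env}"),
                        ),
                    )
                    frames.append(
                        res.importance.rename("importance")
                        .rename_axis("trait")
                        .reset_index()
                        .assign(environment=env, alpha=res.alpha, lam=res.lam)
                    )
                if frames:
                    pd.concat(frames, ignore_index=True).to_csv(outputs[0], index=False)
                    record("importance", outputs, t0)
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001 - annotate failing stage
        raise PipelineError(f"pipeline failed: {exc}") from exc

    return manifest
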