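"""End-to-end pipeline driver.

Stages run in the order preprocess -> SOM -> spots -> annotate -> diffexp ->
perturbation time -> eQTL enrichment, consuming either file inputs or a
synthetic cohort, writing every artifact as tab-separated text / JSON (plus
PNG figures) under one run directory together with a manifest.  All
randomness flows from the single config seed through stage-specific derived
seeds, so re-running an identical config reproduces all non-image outputs
bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from chronosom import io as cio
from chronosom.annotate import annotate_spots, correlate_celltypes, geneset_zscore
from chronosom.diffexp import deg_counts_by_age, spot_diff
from chronosom.enrichment import eqtl_enrichment, select_perturbed_enriched
from chronosom.perturbation_time import PerturbationResult, TimeCoursePair, analyze_spot
from chronosom.preprocess import adjust_covariates, assign_age_groups, center_genes
from chronosom.som_portrait import Portrait, SOMModel, group_portrait, sample_portrait, train_som
from chronosom.spots import segment_spots, spot_profiles, summary_maps
from chronosom.synthetic_data import (
    CohortConfig,
    generate_cohort,
    generate_eqtl_table,
    generate_genesets,
)

logger = logging.getLogger("chronosom")

STAGES = (
    "simulate",
    "preprocess",
    "som",
    "spots",
    "annotate",
    "diffexp",
    "perturb",
    "enrich",
)


@dataclass
class PipelineConfig:
    """Everything a run needs; exactly one of (real inputs, synthetic) set."""

    out_dir: str = "chronosom_run"
    seed: int = 0
    # inputs: either file paths ...
    matrix_path: str | None = None
    metadata_path: str | None = None
    gmt_path: str | None = None
    eqtl_path: str | None = None
    # ... or a synthetic cohort
    synthetic: CohortConfig | None = None
    # stage knobs
    nuisance: list[str] = field(default_factory=lambda: ["batch", "sex", "ph", "pmi"])
    som_k: int = 20
    som_epochs: int = 40
    spot_quantile: float = 0.80
    spot_min_size: int = 3
    spot_similarity: float = 0.90
    adjacency: int = 8
    tau_grid_size: int = 50
    gp_restarts: int = 5
    min_arm_size: int = 3
    lr_cutoff: float = 1.0
    extra_random_sets: int = 5
    eqtl_enriched_pairs: list[tuple[str, str]] = field(default_factory=list)
    make_plots: bool = True

    def validate(self) -> None:
        has_real = self.matrix_path is not None or self.metadata_path is not None
        has_synth = self.synthetic is not None
        if has_real and has_synth:
            raise ValueError("config mixes real inputs and a synthetic cohort; choose one")
        if not has_real and not has_synth:
            raise ValueError("config provides neither real inputs nor a synthetic cohort")
        if has_real and (self.matrix_path is None or self.metadata_path is None):
            raise ValueError("real inputs need both matrix_path and metadata_path")
        if not 0 < self.spot_quantile < 1:
            raise ValueError("spot_quantile must be in (0, 1)")
        if self.adjacency not in (4, 8):
            raise ValueError("adjacency must be 4 or 8")
        if self.som_k < 1 or self.som_epochs < 1 or self.tau_grid_size < 2:
            raise ValueError("som_k, som_epochs >= 1 and tau_grid_size >= 2 required")

    def to_dict(self) -> dict:
        d = asdict(self)
        if self.synthetic is not None:
            synth = d["synthetic"]
            synth.pop("trajectories", None)
            synth.pop("perturbations", None)
        return d

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        synth = raw.pop("synthetic", None)
        cfg = cls(**raw)
        if synth is not None:
            cfg.synthetic = CohortConfig(**synth)
        return cfg


def _stage_seed(seed: int, stage: str) -> int:
    """Stable derived seed per stage, below 2**31."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def build_time_course(
    spot_expr_row: pd.Series, meta: pd.DataFrame, disease: str
) -> TimeCoursePair:
    """Assemble the two-arm time course of one spot for one disease."""
    ctrl = meta.index[meta["diagnosis"] == "CNTRL"]
    dis = meta.index[meta["diagnosis"] == disease]
    return TimeCoursePair(
        t_ctrl=meta.loc[ctrl, "age"].to_numpy(float),
        y_ctrl=spot_expr_row[ctrl].to_numpy(float),
        t_dis=meta.loc[dis, "age"].to_numpy(float),
        y_dis=spot_expr_row[dis].to_numpy(float),
    )


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute all stages; returns the run directory.

    A stage failure aborts the run with the stage name; the manifest written
    so far is persisted as ``manifest.partial.json``.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)

    import chronosom

    manifest: dict = {
        "config": config.to_dict(),
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "versions": {
            "chronosom": chronosom.__version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "stages": [],
        "artifacts": [],
    }

    def record(stage: str, paths: list[Path]) -> None:
        manifest["stages"].append(stage)
        manifest["artifacts"].extend(str(p.relative_to(out)) for p in paths)

    current_stage = "simulate"
    try:
        # ------------------------------------------------------------ inputs
        truth = None
        genesets = None
        eqtl = None
        if config.synthetic is not None:
            synth_cfg = config.synthetic
            X_raw, meta, truth = generate_cohort(synth_cfg)
            genesets = generate_genesets(
                truth,
                extra_random_sets=config.extra_random_sets,
                seed=_stage_seed(config.seed, "genesets"),
            )
            pairs = config.eqtl_enriched_pairs or [
                (next(iter(truth.modules)), "Brain_Cortex")
            ]
            eqtl = generate_eqtl_table(
                truth,
                enriched_pairs=pairs,
                seed=_stage_seed(config.seed, "eqtl"),
            )
            cio.write_matrix(X_raw, out / "expression_raw.tsv")
            cio.write_metadata(meta, out / "metadata.tsv")
            truth.to_json(out / "truth.json")
            cio.write_gmt(genesets, out / "genesets.gmt")
            cio.write_eqtl_table(eqtl, out / "eqtl_flags.tsv")
            record("simulate", [out / "expression_raw.tsv", out / "metadata.tsv",
                                out / "truth.json", out / "genesets.gmt",
                                out / "eqtl_flags.tsv"])
        else:
            X_raw = cio.read_matrix(config.matrix_path)
            meta = cio.read_metadata(config.metadata_path)
            if config.gmt_path:
                genesets = cio.read_gmt(config.gmt_path)
            if config.eqtl_path:
                eqtl = cio.read_eqtl_table(config.eqtl_path)
            record("simulate", [])

        # -------------------------------------------------------- preprocess
        current_stage = "preprocess"
        t0 = time.perf_counter()
        nuisance = [n for n in config.nuisance if n in meta.columns]
        X = adjust_covariates(X_raw, meta, nuisance) if nuisance else X_raw
        X = center_genes(X)
        meta = meta.copy()
        meta["age_group"] = assign_age_groups(meta).astype(str)
        cio.write_matrix(X, out / "expression_centered.tsv")
        cio.write_metadata(meta, out / "metadata_annotated.tsv")
        record("preprocess", [out / "expression_centered.tsv", out / "metadata_annotated.tsv"])
        logger.info("preprocess done in %.1fs", time.perf_counter() - t0)

        # --------------------------------------------------------------- som
        current_stage = "som"
        t0 = time.perf_counter()
        model = train_som(
            X, k=config.som_k, epochs=config.som_epochs,
            seed=_stage_seed(config.seed, "som"),
        )
        som_dir = out / "som"
        som_dir.mkdir(exist_ok=True)
        cio.write_matrix(model.metagene_matrix(), som_dir / "metagene_weights.tsv")
        pd.Series(model.assignment, index=model.gene_ids, name="metagene").to_csv(
            som_dir / "gene_assignment.tsv", sep="\t"
        )
        (som_dir / "model.json").write_text(json.dumps(
            {"k": model.k, "epochs": config.som_epochs,
             "quantization_errors": model.quantization_errors}, indent=1))
        som_paths = [som_dir / "metagene_weights.tsv", som_dir / "gene_assignment.tsv",
                     som_dir / "model.json"]
        meta = meta.loc[list(model.sample_ids)]
        group_key = meta["diagnosis"].astype(str) + "_" + meta["age_group"].astype(str)
        if config.make_plots:
            from chronosom import plotting

            portraits = []
            for g in pd.unique(group_key):
                members = [sample_portrait(model, s) for s in meta.index[group_key == g]]
                portraits.append(group_portrait(members, label=g))
            plotting.plot_portraits(portraits, out / "group_portraits.png")
            som_paths.append(out / "group_portraits.png")
        record("som", som_paths)
        logger.info("som done in %.1fs", time.perf_counter() - t0)

        # ------------------------------------------------------------- spots
        current_stage = "spots"
        t0 = time.perf_counter()
        maps = summary_maps(model, group_key)
        spots = segment_spots(
            maps.variance,
            quantile=config.spot_quantile,
            min_size=config.spot_min_size,
            adjacency=config.adjacency,
            model=model,
            similarity_threshold=config.spot_similarity,
        )
        spot_expr = spot_profiles(spots, model)
        pd.DataFrame(maps.variance).to_csv(out / "variance_map.tsv", sep="\t")
        pd.DataFrame(maps.overexpression).to_csv(out / "overexpression_map.tsv", sep="\t")
        pd.DataFrame(
            [
                {
                    "spot": s.label,
                    "n_metagenes": s.size,
                    "n_genes": len(s.genes),
                    "metagenes": ",".join(map(str, s.metagenes)),
                    "genes": ",".join(s.genes),
                }
                for s in spots
            ]
        ).to_csv(out / "spots.tsv", sep="\t", index=False)
        spot_expr.to_csv(out / "spot_expression.tsv", sep="\t")
        spot_paths = [out / "variance_map.tsv", out / "overexpression_map.tsv",
                      out / "spots.tsv", out / "spot_expression.tsv"]
        if config.make_plots:
            plotting.plot_summary_map(maps.variance, spots, out / "variance_map.png")
            spot_paths.append(out / "variance_map.png")
        record("spots", spot_paths)
        logger.info("spots done in %.1fs (%d spots)", time.perf_counter() - t0, len(spots))

        # ---------------------------------------------------------- annotate
        current_stage = "annotate"
        t0 = time.perf_counter()
        annot_paths = []
        if genesets is not None and len(spots):
            enr = annotate_spots(spots, genesets, universe=list(X.index))
            enr.to_csv(out / "geneset_enrichment.tsv", sep="\t", index=False)
            annot_paths.append(out / "geneset_enrichment.tsv")
            sig_z = pd.DataFrame(
                {name: geneset_zscore(X, genes) for name, genes in genesets.items()}
            ).T
            r_matrix, edges = correlate_celltypes(spot_expr, sig_z)
            r_matrix.to_csv(out / "signature_correlations.tsv", sep="\t")
            edges.to_csv(out / "celltype_edges.tsv", sep="\t", index=False)
            annot_paths += [out / "signature_correlations.tsv", out / "celltype_edges.tsv"]
        record("annotate", annot_paths)
        logger.info("annotate done in %.1fs", time.perf_counter() - t0)

        # ----------------------------------------------------------- diffexp
        current_stage = "diffexp"
        t0 = time.perf_counter()
        diseases = [d for d in meta["diagnosis"].unique() if d != "CNTRL"]
        counts = deg_counts_by_age(X, meta, diseases)
        counts.to_csv(out / "deg_counts.tsv", sep="\t", index=False)
        sdiff = pd.concat(
            [spot_diff(spot_expr, meta, d) for d in diseases], ignore_index=True
        ) if len(spot_expr) else pd.DataFrame(columns=["spot", "disease", "coefficient", "p"])
        sdiff.to_csv(out / "spot_diff.tsv", sep="\t", index=False)
        de_paths = [out / "deg_counts.tsv", out / "spot_diff.tsv"]
        if config.make_plots and len(counts):
            plotting.plot_deg_counts(counts, out / "deg_counts.png")
            de_paths.append(out / "deg_counts.png")
        record("diffexp", de_paths)
        logger.info("diffexp done in %.1fs", time.perf_counter() - t0)

        # ----------------------------------------------------------- perturb
        current_stage = "perturb"
        t0 = time.perf_counter()
        results: list[PerturbationResult] = []
        posteriors = {}
        for spot_label, row in spot_expr.iterrows():
            for disease in diseases:
                n_dis = int((meta["diagnosis"] == disease).sum())
                n_ctl = int((meta["diagnosis"] == "CNTRL").sum())
                if min(n_dis, n_ctl) < config.min_arm_size:
                    continue
                pair = build_time_course(row, meta, disease)
                res = analyze_spot(
                    pair,
                    restarts=config.gp_restarts,
                    seed=_stage_seed(config.seed, f"gp:{spot_label}:{disease}"),
                    n_grid=config.tau_grid_size,
                    spot=str(spot_label),
                    disease=disease,
                )
                results.append(res)
                posteriors[f"{spot_label}:{disease}"] = {
                    "tau_grid": res.tau_grid.tolist(),
                    "posterior": res.posterior.tolist(),
                }
                if config.make_plots:
                    plotting.plot_perturbation(
                        pair, res, out / f"perturbation_{spot_label}_{disease}.png",
                        title=f"spot {spot_label} / {disease}",
                    )
        pert_df = pd.DataFrame(
            [
                {
                    "spot": r.spot,
                    "disease": r.disease,
                    "map_tau": r.map_tau,
                    "likelihood_ratio": r.likelihood_ratio,
                    "posterior_entropy": r.posterior_entropy,
                    "signal_var": r.params.signal_var,
                    "lengthscale": r.params.lengthscale,
                    "noise_var": r.params.noise_var,
                }
                for r in results
            ]
        )
        pert_df.to_csv(out / "perturbation_results.tsv", sep="\t", index=False)
        (out / "perturbation_posteriors.json").write_text(json.dumps(posteriors))
        record("perturb", [out / "perturbation_results.tsv",
                           out / "perturbation_posteriors.json"])
        logger.info("perturb done in %.1fs (%d results)", time.perf_counter() - t0, len(results))

        # ------------------------------------------------------------ enrich
        current_stage = "enrich"
        t0 = time.perf_counter()
        enrich_paths = []
        if eqtl is not None and len(spots):
            eqtl_records = eqtl_enrichment(spots, eqtl, universe=list(X.index))
            eqtl_records.to_csv(out / "eqtl_enrichment.tsv", sep="\t", index=False)
            timeline = select_perturbed_enriched(
                results, eqtl_records, lr_cutoff=config.lr_cutoff,
                spot_diff_records=sdiff,
            )
            timeline.to_csv(out / "timeline.tsv", sep="\t", index=False)
            enrich_paths = [out / "eqtl_enrichment.tsv", out / "timeline.tsv"]
        record("enrich", enrich_paths)
        logger.info("enrich done in %.1fs", time.perf_counter() - t0)

    except Exception:
        (out / "manifest.partial.json").write_text(json.dumps(manifest, indent=1))
        logger.exception("pipeline failed in stage %s", current_stage)
        logger.removeHandler(handler)
        handler.close()
        raise RuntimeError(f"pipeline failed in stage {current_stage!r}") from None
    finally:
        for h in list(logger.handlers):
            if h is handler:
                logger.removeHandler(handler)
                handler.close()

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out
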