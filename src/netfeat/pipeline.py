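"""End-to-end orchestration: simulate or ingest, build networks, compute
features, screen, score robustness, evaluate — with a manifest of
checksummed outputs so reruns are verifiable.

Every stage is a pure function of (inputs, config, seed); rerunning a
pipeline with an identical config reproduces identical output checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import data_io, features, network, robustness, significance
from .data_io import ValidationError
from .evaluation import CVConfig, SubsampleConfig, evaluate_feature_type, subsample_experiment
from .features import FEATURE_TYPE_NAMES
from .network import CoexpressionConfig
from .robustness import RobustnessConfig
from .significance import SignificanceConfig
from .simulate import SimulationConfig, generate_study

logger = logging.getLogger(__name__)

DEFAULT_EVAL_TYPES = ("Gene", "CEMEAN", "PPIMEAN", "CNF")


@dataclass
class PipelineConfig:
    """One config for a full run; stages read only their own section."""

    output_dir: str
    seed: int = 0
    # inputs: either simulate=True or the three file paths
    simulate: bool = True
    simulation: SimulationConfig = field(
        default_factory=SimulationConfig
    )
    expression_path: Optional[str] = None
    phenotype_path: Optional[str] = None
    ppi_path: Optional[str] = None
    coexpression: CoexpressionConfig = field(default_factory=CoexpressionConfig)
    significance: SignificanceConfig = field(default_factory=SignificanceConfig)
    robustness: RobustnessConfig = field(default_factory=RobustnessConfig)
    cv: CVConfig = field(default_factory=CVConfig)
    subsample: Optional[SubsampleConfig] = None
    feature_types: tuple[str, ...] = FEATURE_TYPE_NAMES
    evaluate_types: tuple[str, ...] = DEFAULT_EVAL_TYPES
    run_robustness: bool = True
    run_evaluation: bool = True

    def validate(self) -> None:
        unknown = set(self.feature_types) - set(FEATURE_TYPE_NAMES)
        if unknown:
            raise ValidationError(f"unknown feature type(s): {sorted(unknown)}")
        unknown = set(self.evaluate_types) - set(FEATURE_TYPE_NAMES) - {"CNF"}
        if unknown:
            raise ValidationError(f"unknown evaluation type(s): {sorted(unknown)}")
        if not self.simulate:
            for name in ("expression_path", "phenotype_path", "ppi_path"):
                path = getattr(self, name)
                if path is None or not Path(path).exists():
                    raise ValidationError(f"{name} missing or does not exist: {path}")


def load_pipeline_config(path: str | Path) -> PipelineConfig:
    """Build a PipelineConfig from a YAML file of nested key-value sections."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    sections = {
        "simulation": SimulationConfig,
        "coexpression": CoexpressionConfig,
        "significance": SignificanceConfig,
        "robustness": RobustnessConfig,
        "cv": CVConfig,
        "subsample": SubsampleConfig,
    }
    kwargs = {}
    for key, value in raw.items():
        if key in sections and isinstance(value, dict):
            if key == "simulation" and "cohorts" in value:
                value["cohorts"] = tuple(tuple(c) for c in value["cohorts"])
            if key == "subsample" and "percentages" in value:
                value["percentages"] = tuple(value["percentages"])
            kwargs[key] = sections[key](**value)
        else:
            if key in ("feature_types", "evaluate_types") and value is not None:
                value = tuple(value)
            kwargs[key] = value
    return PipelineConfig(**kwargs)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all requested stages in dependency order.

    Returns the run manifest: stage log plus every output file path with its
    SHA-256 content checksum. The manifest is also written to
    ``<output_dir>/manifest.json``.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"stages": [], "outputs": {}}

    def record(path: Path) -> None:
        manifest["outputs"][path.name] = _sha256(path)

    def stage(name: str):
        t0 = time.perf_counter()
        manifest["stages"].append(name)
        logger.info("stage %s", name)
        return t0

    try:
        # -- inputs ---------------------------------------------------------
        t0 = stage("inputs")
        if config.simulate:
            study = generate_study(
                SimulationConfig(
                    **{**asdict(config.simulation), "seed": config.seed}
                )
            )
            dataset, ppi = study.dataset, study.true_network
            data_io.write_expression(dataset, out / "expression.tsv")
            data_io.write_phenotype(dataset, out / "phenotype.tsv")
            network.write_edge_list(ppi, out / "true_network.tsv")
            (out / "differential_genes.tsv").write_text(
                "gene_id\n" + "".join(f"{g}\n" for g in sorted(study.differential_genes))
            )
            for name in (
                "expression.tsv",
                "phenotype.tsv",
                "true_network.tsv",
                "differential_genes.tsv",
            ):
                record(out / name)
        else:
            dataset = data_io.read_expression(config.expression_path)
            dataset = data_io.join_phenotype(
                dataset, data_io.read_phenotype(config.phenotype_path)
            )
            ppi = network.load_edge_list(config.ppi_path, dataset.gene_ids)
        logger.info(
            "dataset: %d genes x %d patients (%.1fs)",
            dataset.n_genes,
            dataset.n_patients,
            time.perf_counter() - t0,
        )

        # -- networks -------------------------------------------------------
        t0 = stage("networks")
        ce_config = config.coexpression
        if ce_config.target_edges is None:
            ce_config = CoexpressionConfig(
                k=ce_config.k, ranking=ce_config.ranking, target_edges=ppi.n_edges
            )
        ce = network.build_mutual_knn(dataset, ce_config)
        networks = {"CE": ce, "PPI": ppi}
        network.write_edge_list(ce, out / "coexpression_network.tsv")
        record(out / "coexpression_network.tsv")
        logger.info(
            "CE: %d edges (k=%s); PPI: %d edges (%.1fs)",
            ce.n_edges,
            ce.provenance.get("k"),
            ppi.n_edges,
            time.perf_counter() - t0,
        )

        # -- features + significance ---------------------------------------
        t0 = stage("features+significance")
        sig_tables: dict[str, pd.DataFrame] = {}
        provenances: dict[str, dict] = {}
        counts = []
        for name in config.feature_types:
            net = None
            if name != "Gene":
                net = networks["CE" if name.startswith("CE") else "PPI"]
            fm = features.compute_features(dataset, name, net)
            provenances[name] = fm.provenance
            features.write_feature_matrix(fm, out / f"features_{name}.tsv")
            record(out / f"features_{name}.tsv")
            table = significance.compute_significance(fm, dataset.outcome.to_numpy())
            sig_tables[name] = table
            significance.write_significance_table(
                table, out / f"significance_{name}.tsv"
            )
            record(out / f"significance_{name}.tsv")
            counts.append(
                (name, significance.count_significant(table, config.significance))
            )
        pd.DataFrame(counts, columns=["feature_type", "n_significant"]).to_csv(
            out / "significant_counts.tsv", sep="\t", index=False
        )
        record(out / "significant_counts.tsv")
        logger.info("%d feature types screened (%.1fs)", len(counts), time.perf_counter() - t0)

        # -- robustness -----------------------------------------------------
        cohorts = dataset.cohorts()
        if config.run_robustness and len(cohorts) >= 2:
            t0 = stage("robustness")
            results = []
            for name in config.feature_types:
                net = None
                if name != "Gene":
                    net = networks["CE" if name.startswith("CE") else "PPI"]
                per_cohort = {}
                for cname, cset in cohorts.items():
                    fm = features.compute_features(cset, name, net)
                    table = significance.compute_significance(
                        fm, cset.outcome.to_numpy()
                    )
                    per_cohort[cname] = robustness.select_top_genes(
                        table, name, fm.provenance, config.robustness
                    )
                results.append(
                    robustness.robustness_summary(
                        per_cohort,
                        dataset.n_genes,
                        net,
                        config.robustness,
                        feature_type=name,
                    )
                )
            robustness.write_robustness_report(results, out / "robustness_pairs.tsv")
            record(out / "robustness_pairs.tsv")
            summary = pd.DataFrame(
                [(r.feature_type, r.geometric_mean_fold) for r in results],
                columns=["feature_type", "geometric_mean_fold"],
            )
            summary.to_csv(out / "robustness_summary.tsv", sep="\t", index=False)
            record(out / "robustness_summary.tsv")
            diag = pd.concat(
                [
                    r.degree_diagnostics.assign(feature_type=r.feature_type)
                    for r in results
                    if len(r.degree_diagnostics)
                ],
                ignore_index=True,
            ) if any(len(r.degree_diagnostics) for r in results) else pd.DataFrame()
            if len(diag):
                diag.to_csv(out / "robustness_degree_diag.tsv", sep="\t", index=False)
                record(out / "robustness_degree_diag.tsv")
            logger.info("robustness over %d cohorts (%.1fs)", len(cohorts), time.perf_counter() - t0)

        # -- evaluation -----------------------------------------------------
        if config.run_evaluation:
            t0 = stage("evaluation")
            cv = CVConfig(**{**asdict(config.cv), "seed": config.seed})
            frames, summary_rows = [], []
            for name in config.evaluate_types:
                res = evaluate_feature_type(dataset, name, networks, cv)
                frames.append(res.to_frame())
                summary_rows.append((name, res.mean_auc))
                logger.info("%s mean AUC %.3f", name, res.mean_auc)
            pd.concat(frames, ignore_index=True).to_csv(
                out / "evaluation_folds.tsv", sep="\t", index=False
            )
            record(out / "evaluation_folds.tsv")
            pd.DataFrame(summary_rows, columns=["feature_type", "mean_auc"]).to_csv(
                out / "evaluation_summary.tsv", sep="\t", index=False
            )
            record(out / "evaluation_summary.tsv")
            if config.subsample is not None:
                t0 = stage("subsample")
                curve = subsample_experiment(
                    dataset, networks, cv, config.subsample, config.evaluate_types
                )
                curve.to_csv(out / "subsample_curve.tsv", sep="\t", index=False)
                record(out / "subsample_curve.tsv")
    except Exception as exc:
        failed = manifest["stages"][-1] if manifest["stages"] else "config"
        raise RuntimeError(f"pipeline stage {failed!r} failed: {exc}") from exc

    meta = {
        "seed": config.seed,
        "feature_types": list(config.feature_types),
        "evaluate_types": list(config.evaluate_types),
    }
    (out / "run_metadata.json").write_text(json.dumps(meta, indent=2) + "\n")
    record(out / "run_metadata.json")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest


__all__ = ["PipelineConfig", "load_pipeline_config", "run_pipeline", "DEFAULT_EVAL_TYPES"]
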