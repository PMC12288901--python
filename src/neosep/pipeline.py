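"""End-to-end pipeline orchestration with an auditable run manifest.

``run_pipeline`` executes preprocess → diffabund → modeling → classify-ps
on the configured inputs, writes every stage's outputs as CSV/TSV, and
records a manifest (config echo, per-file SHA-256 hashes, log of every
data-driven decision taken — missing pooled anchors, skipped tests,
redrawn splits).  A rerun with the same config and seed reproduces every
output byte for byte.

``cluster_order`` computes the deterministic row/column ordering that a
hierarchically clustered heatmap of the imputed matrix would display;
rendering itself is out of scope.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import asdict, dataclass, fields

import numpy as np
import pandas as pd
import yaml
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist

from . import diffabund, io, modeling, preprocess
from .datamodel import (
    ConfigurationError,
    PipelineStageError,
    ProteinAbundanceMatrix,
    ValidationError,
)


def cluster_order(matrix, linkage_method: str = "average",
                  distance: str = "euclidean"):
    """Leaf orders of agglomerative clusterings of rows and columns.

    Requires a complete (imputed) matrix.  scipy's linkage is
    deterministic; ties resolve by input index.  Returns
    ``(row_order, col_order)`` as integer index arrays.
    """
    values = matrix.values if isinstance(matrix, ProteinAbundanceMatrix) else \
        pd.DataFrame(matrix)
    arr = np.asarray(values, dtype=float)
    if np.isnan(arr).any():
        raise ValidationError("matrix has missing entries; impute before ordering")

    def order(data):
        if data.shape[0] < 2:
            return np.arange(data.shape[0])
        return leaves_list(linkage(pdist(data, metric=distance),
                                   method=linkage_method))

    return order(arr), order(arr.T)


@dataclass
class PipelineConfig:
    """Flat, versioned configuration of one end-to-end run."""

    matrix: str = ""
    samples: str = ""
    biomarkers: str = ""
    out_dir: str = "neosep_out"
    seed: int = 0
    config_version: int = 1
    dialect: str = "plain_matrix"
    reference_batch: int = 1
    detect_threshold: float = 0.20
    missing_threshold: float = 0.30
    impute_decile: float = 0.10
    alpha: float = 0.05
    sensitivity_ga: float = 37.0
    presence_margin: float = 0.15
    rf_runs: int = 10
    rf_test_fraction: float = 0.5
    class_weight_eos: float = 10.0
    cv_folds: int = 3
    permutation_repeats: int = 20
    log_biomarkers: bool = True
    auto_flag_outliers: bool = False
    exclude_outlier_ids: tuple = ()
    run_preprocess: bool = True
    run_diffabund: bool = True
    run_modeling: bool = True
    run_classify: bool = True

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        if "exclude_outlier_ids" in data and data["exclude_outlier_ids"]:
            data["exclude_outlier_ids"] = tuple(data["exclude_outlier_ids"])
        return cls(**data)

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["exclude_outlier_ids"] = list(self.exclude_outlier_ids)
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage_seed(master: int, stage_index: int) -> int:
    return int(np.random.SeedSequence([int(master), stage_index])
               .generate_state(1, dtype=np.uint64)[0] % (2 ** 31))


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages; returns (and writes) the run manifest.

    On a stage failure the outputs already written by that stage are
    renamed with a ``.partial`` suffix and a :class:`PipelineStageError`
    naming the stage is raised.
    """
    os.makedirs(config.out_dir, exist_ok=True)
    manifest: dict = {"config": {**asdict(config),
                                 "exclude_outlier_ids":
                                 list(config.exclude_outlier_ids)},
                      "stages": [], "log": [], "outputs": {}}
    state: dict = {}
    stage_files: list[str] = []

    def out(name):
        path = os.path.join(config.out_dir, name)
        stage_files.append(path)
        return path

    def finish_stage(name):
        for path in stage_files:
            manifest["outputs"][os.path.basename(path)] = _sha256(path)
        manifest["stages"].append(name)
        stage_files.clear()

    def run_stage(name, fn):
        try:
            fn()
        except Exception as exc:
            for path in stage_files:
                if os.path.exists(path):
                    os.replace(path, path + ".partial")
            raise PipelineStageError(name, exc) from exc
        finish_stage(name)

    def stage_preprocess():
        matrix = io.read_lfq_matrix(config.matrix, dialect=config.dialect)
        samples = io.read_sample_metadata(config.samples)
        manifest["log"].extend(samples.warnings)
        log2 = preprocess.log2_transform(matrix)
        filtered, excluded = preprocess.exclude_single_batch_proteins(log2, samples)
        manifest["log"].append(f"excluded {len(excluded)} single-batch proteins")
        normalized, report = preprocess.batch_normalize(
            filtered, samples, reference_batch=config.reference_batch)
        for p, b in report.missing_anchor:
            manifest["log"].append(
                f"missing pooled anchor for protein {p} in batch {b}; offset 0")
        spec_matrix, spec_samples = preprocess.average_technical_replicates(
            normalized, samples)
        partition = preprocess.detection_filter(spec_matrix,
                                                threshold=config.detect_threshold)
        imputed, imp_log = preprocess.impute_two_step(
            partition.kept, spec_samples,
            missing_threshold=config.missing_threshold,
            decile=config.impute_decile, seed=_stage_seed(config.seed, 1))
        manifest["log"].extend(imp_log)
        complete = imputed.values.dropna(axis=0, how="any")
        row_order, col_order = cluster_order(
            ProteinAbundanceMatrix(complete, "log2"))
        io.write_matrix(normalized, out("normalized_matrix.tsv"))
        io.write_matrix(spec_matrix, out("specimen_matrix.tsv"))
        io.write_matrix(partition.kept, out("kept_matrix.tsv"))
        io.write_matrix(partition.rare, out("rare_matrix.tsv"))
        io.write_matrix(imputed, out("imputed_matrix.tsv"))
        report.offsets.to_csv(out("batch_offsets.csv"), index_label="protein_id")
        io.write_table(spec_samples, out("specimen_samples.csv"))
        pd.DataFrame({"row_order": pd.Series(complete.index[row_order]),
                      "col_order": pd.Series(complete.columns[col_order])}
                     ).to_csv(out("cluster_order.csv"), index=False)
        state.update(samples=samples, spec_matrix=spec_matrix,
                     spec_samples=spec_samples, partition=partition)

    def stage_diffabund():
        partition, spec_samples = state["partition"], state["spec_samples"]
        da = diffabund.differential_abundance(partition.kept, spec_samples,
                                              alpha=config.alpha)
        da.to_csv(out("da_results.csv"))
        subset = diffabund.sensitivity_subset(spec_samples,
                                              ga_cutoff=config.sensitivity_ga)
        sub_matrix = partition.kept.subset_samples(
            [s for s in partition.kept.samples
             if s in set(subset.df["sample_id"])])
        da_sens = diffabund.differential_abundance(sub_matrix, subset,
                                                   alpha=config.alpha)
        da_sens.to_csv(out("da_sensitivity.csv"))
        pres = diffabund.presence_absence(partition.rare, spec_samples,
                                          margin=config.presence_margin)
        pres.to_csv(out("presence_absence.csv"), index_label="protein_id")
        demo, demo_log = diffabund.demographics_table(
            spec_samples,
            continuous_vars=("gestational_age", "plasma_protein_conc"),
            categorical_vars=("sex", "chorioamnionitis", "prom", "preeclampsia",
                              "multiple_gestation", "delivery_route", "labor"))
        manifest["log"].extend(demo_log)
        demo.to_csv(out("demographics.csv"), index=False)
        state["da"] = da

    def stage_modeling():
        samples = state.get("samples") or io.read_sample_metadata(config.samples)
        biomarkers = io.read_biomarker_table(config.biomarkers)
        excluded = tuple(config.exclude_outlier_ids)
        if config.auto_flag_outliers and not excluded:
            flagged, flag_log = modeling.flag_biomarker_outliers(biomarkers)
            manifest["log"].extend(flag_log)
            manifest["log"].append(f"auto-flagged outliers: {flagged}")
            excluded = tuple(flagged)
        manifest["log"].append(f"excluded {len(excluded)} outlier infants "
                               f"from modeling")
        logit = modeling.logistic_comparison(samples, biomarkers,
                                             outlier_ids=excluded,
                                             log_biomarkers=config.log_biomarkers)
        logit.to_csv(out("logistic_comparison.csv"), index=False)
        seed = _stage_seed(config.seed, 3)
        common = dict(n_runs=config.rf_runs,
                      test_fraction=config.rf_test_fraction,
                      class_weight_eos=config.class_weight_eos,
                      cv_folds=config.cv_folds,
                      n_permutation_repeats=config.permutation_repeats,
                      seed=seed)
        spec_bio = modeling.FeatureSpec(outlier_ids_excluded=excluded,
                                        log_biomarkers=config.log_biomarkers)
        spec_clin = spec_bio.replace(biomarkers=())
        eval_bio = modeling.rf_protocol(spec_bio, samples, biomarkers, **common)
        eval_clin = modeling.rf_protocol(spec_clin, samples, biomarkers, **common)
        manifest["log"].extend(eval_bio.redraw_events + eval_clin.redraw_events)
        eval_bio.runs.assign(model="biomarker").to_csv(
            out("rf_runs_biomarker.csv"), index=False)
        eval_clin.runs.assign(model="clinical").to_csv(
            out("rf_runs_clinical.csv"), index=False)
        eval_bio.importances.to_csv(out("rf_importances_biomarker.csv"),
                                    index=False)
        eval_clin.importances.to_csv(out("rf_importances_clinical.csv"),
                                     index=False)
        state.update(eval_bio=eval_bio, spec_bio=spec_bio, samples=samples,
                     biomarkers=biomarkers)

    def stage_classify():
        if "eval_bio" not in state:
            raise ConfigurationError("classify stage requires the modeling stage")
        result = modeling.classify_presumed(
            state["samples"], state["biomarkers"], state["spec_bio"],
            hyperparameters=state["eval_bio"].modal_params(),
            class_weight_eos=config.class_weight_eos,
            seed=_stage_seed(config.seed, 4))
        result.predictions.to_csv(out("ps_predictions.csv"), index=False)
        result.comparison.to_csv(out("ps_biomarker_comparison.csv"), index=False)
        result.pca_scores.to_csv(out("ps_pca.csv"), index=False)
        manifest["log"].append(result.summary())

    if config.run_preprocess:
        run_stage("preprocess", stage_preprocess)
    if config.run_diffabund:
        if "partition" not in state:
            raise ConfigurationError("diffabund stage requires preprocess")
        run_stage("diffabund", stage_diffabund)
    if config.run_modeling:
        run_stage("modeling", stage_modeling)
    if config.run_classify:
        run_stage("classify_ps", stage_classify)

    manifest_path = os.path.join(config.out_dir, "manifest.json")
    with open(manifest_path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
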