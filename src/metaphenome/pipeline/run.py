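"""End-to-end orchestration: simulate -> preprocess -> scan -> preonset ->
ageing -> metrs, each stage consuming only on-disk outputs of prior stages."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .. import __version__
from ..ageingwaves import (
    age_adjusted_curves,
    cluster_age_curves,
    deswan_scan,
    deswan_to_frame,
    detect_wave_peaks,
)
from ..assocscan import (
    DEFAULT_COVARIATES,
    build_analysis_sets,
    records_to_frame,
    scan_associations,
)
from ..metrs import cross_validated_metrs, evaluate
from ..preonset import (
    backward_screen,
    cluster_trajectories,
    profiles_to_frame,
    propensity_match,
    timeframe_profile,
)
from ..preprocess import impute_covariates, qc_transform
from ..synthcohort import SimulationConfig, read_cohort, simulate_cohort, write_cohort
from .config import PipelineConfig
from .io import checksum, read_table, write_table

logger = logging.getLogger(__name__)


class MissingArtifactError(FileNotFoundError):
    pass


@dataclass
class RunArtifacts:
    out_dir: Path
    manifest: dict = field(default_factory=dict)  # relative path -> sha256
    seed: int = 0
    version: str = __version__
    skipped_stages: list = field(default_factory=list)

    def register(self, path: Path) -> None:
        rel = str(Path(path).relative_to(self.out_dir))
        self.manifest[rel] = checksum(path)

    def write_manifest(self) -> Path:
        path = self.out_dir / "manifest.json"
        path.write_text(
            json.dumps(
                {
                    "version": self.version,
                    "seed": self.seed,
                    "skipped_stages": self.skipped_stages,
                    "files": self.manifest,
                },
                indent=2,
                sort_keys=True,
            )
        )
        return path


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise MissingArtifactError(
            f"missing artifact {path.name}; run the {stage!r} stage first"
        )
    return path


def run_pipeline(config: PipelineConfig) -> RunArtifacts:
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.yaml").write_text(config.to_yaml())
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("metaphenome")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    logger.info("resolved config:\n%s", config.to_yaml())

    artifacts = RunArtifacts(out_dir=out, seed=config.seed)
    try:
        cohort_dir = out / "cohort"
        if config.stages.simulate:
            sim_cfg = config.simulate
            sim_cfg.seed = config.seed
            bundle = simulate_cohort(sim_cfg)
            for path in write_cohort(bundle, cohort_dir):
                artifacts.register(path)
        else:
            cohort_dir = Path(config.cohort_dir)
            artifacts.skipped_stages.append("simulate")

        if config.stages.preprocess:
            _run_preprocess(cohort_dir, out, artifacts)
        else:
            artifacts.skipped_stages.append("preprocess")

        if config.stages.scan:
            _run_scan(cohort_dir, out, config, artifacts)
        else:
            artifacts.skipped_stages.append("scan")

        if config.stages.preonset:
            _run_preonset(cohort_dir, out, config, artifacts)
        else:
            artifacts.skipped_stages.append("preonset")
            logger.info("preonset stage disabled: emergence tables omitted")

        if config.stages.ageing:
            _run_ageing(out, config, artifacts)
        else:
            artifacts.skipped_stages.append("ageing")

        if config.stages.metrs:
            _run_metrs(cohort_dir, out, config, artifacts)
        else:
            artifacts.skipped_stages.append("metrs")

        artifacts.write_manifest()
    finally:
        root.removeHandler(handler)
        handler.close()
    return artifacts


def _run_preprocess(cohort_dir: Path, out: Path, artifacts: RunArtifacts) -> None:
    bundle = read_cohort(_require(cohort_dir, "simulate").resolve())
    z, report = qc_transform(bundle.metabolites)
    imputed, imp_report = impute_covariates(bundle.participants)
    artifacts.register(write_table(z, out / "z_metabolites.tsv"))
    artifacts.register(write_table(imputed, out / "covariates_imputed.tsv"))
    report.covariates = imp_report.covariates
    report.notes.extend(imp_report.notes)
    path = out / "transform_report.json"
    path.write_text(report.to_json())
    artifacts.register(path)


def _load_processed(cohort_dir: Path, out: Path):
    z = read_table(_require(out / "z_metabolites.tsv", "preprocess"), index_col="participant_id")
    cov = read_table(
        _require(out / "covariates_imputed.tsv", "preprocess"), index_col="participant_id"
    )
    bundle = read_cohort(cohort_dir)
    return z, cov, bundle


def _run_scan(cohort_dir: Path, out: Path, config: PipelineConfig, artifacts: RunArtifacts) -> None:
    z, cov, bundle = _load_processed(cohort_dir, out)
    sets = build_analysis_sets(
        bundle.registry,
        traits=bundle.traits if len(bundle.traits.columns) else None,
        min_cases=config.scan.min_cases,
        trait_min_n=config.scan.trait_min_n,
        binary_min_cell=config.scan.binary_min_cell,
    )
    if config.scan.kinds:
        wanted = set(config.scan.kinds)
        sets = [
            s for s in sets
            if s.kind in wanted or ("traits" in wanted and s.kind.startswith("trait_"))
        ]
    covariate_names = list(DEFAULT_COVARIATES)
    if config.scan.include_egfr:
        covariate_names.append("egfr")
    records = scan_associations(
        z, sets, cov, covariate_names=covariate_names, alpha=config.scan.alpha
    )
    artifacts.register(write_table(records_to_frame(records), out / "associations.tsv", index=False))
    excl = pd.DataFrame(
        [
            {"phenotype_id": s.phenotype_id, "kind": s.kind, "included": s.included, "reason": s.reason}
            for s in sets
        ]
    )
    artifacts.register(write_table(excl, out / "analysis_sets.tsv", index=False))


def _run_preonset(cohort_dir: Path, out: Path, config: PipelineConfig, artifacts: RunArtifacts) -> None:
    z, cov, bundle = _load_processed(cohort_dir, out)
    params = config.preonset
    profiles_all = []
    calls = []
    matched_rows = []
    matrices = {}
    registry = bundle.registry
    for disease_id, sub in registry.groupby("disease_id", sort=True):
        sub = sub.set_index("participant_id")
        case_ids = sub.index[sub["status"] == "incident"]
        pool_ids = sub.index[sub["status"] == "never"]
        if len(case_ids) < params.min_cases:
            logger.info("preonset: %s skipped (<%d cases)", disease_id, params.min_cases)
            continue
        onset = sub.loc[case_ids, "onset_time"]
        sets = propensity_match(
            cov.loc[case_ids], cov.loc[pool_ids], onset, ratio=params.ratio, seed=config.seed
        )
        for ms in sets:
            matched_rows.append(
                {
                    "disease_id": disease_id,
                    "case_id": ms.case_id,
                    "control_ids": ",".join(ms.control_ids),
                    "proxy_time": ms.proxy_time,
                }
            )
        profiles = timeframe_profile(
            sets, z, cov, disease_id=str(disease_id), n_bins=params.bins,
            min_cases_per_bin=params.min_cases_per_bin,
        )
        profiles_all.extend(profiles)
        matrices[str(disease_id)] = np.vstack([p.z for p in profiles])
        for p in profiles:
            if p.available.any():
                call = backward_screen(p, alpha=params.alpha, convention=params.convention)
                calls.append(
                    {
                        "disease_id": call.disease_id,
                        "metabolite_id": call.metabolite_id,
                        "emergence_bin": call.emergence_bin,
                        "convention": call.convention,
                    }
                )
    artifacts.register(write_table(pd.DataFrame(matched_rows), out / "matched_sets.tsv", index=False))
    artifacts.register(
        write_table(profiles_to_frame(profiles_all), out / "timeframe_profiles.tsv", index=False)
    )
    artifacts.register(write_table(pd.DataFrame(calls), out / "emergence_calls.tsv", index=False))
    if len(matrices) >= 3:
        result = cluster_trajectories(matrices)
        clusters = pd.DataFrame({"disease_id": result.disease_ids, "cluster": result.labels})
        artifacts.register(write_table(clusters, out / "clusters.tsv", index=False))


def _run_ageing(out: Path, config: PipelineConfig, artifacts: RunArtifacts) -> None:
    z = read_table(_require(out / "z_metabolites.tsv", "preprocess"), index_col="participant_id")
    cov = read_table(
        _require(out / "covariates_imputed.tsv", "preprocess"), index_col="participant_id"
    )
    params = config.ageing
    curves = age_adjusted_curves(z, cov, span=params.span)
    curve_frame = pd.DataFrame(
        {c.metabolite_id: c.fitted for c in curves}, index=curves[0].grid.astype(int)
    )
    curve_frame.index.name = "age"
    artifacts.register(write_table(curve_frame, out / "age_curves.tsv"))
    if len(curves) >= 3:
        labels, scores, k = cluster_age_curves(
            curves, k_range=range(params.k_min, params.k_max + 1)
        )
        cl = pd.DataFrame({"metabolite_id": [c.metabolite_id for c in curves], "cluster": labels})
        artifacts.register(write_table(cl, out / "age_clusters.tsv", index=False))
    result = deswan_scan(z, cov, width=params.width, min_parcel=params.min_parcel)
    artifacts.register(write_table(deswan_to_frame(result), out / "deswan_long.tsv", index=False))
    counts = pd.DataFrame({"centre": result.centres})
    for thr, series in result.counts.items():
        counts[f"q<{thr}"] = series
    artifacts.register(write_table(counts, out / "deswan_counts.tsv", index=False))
    peaks = detect_wave_peaks(result)
    path = out / "peaks.json"
    path.write_text(
        json.dumps(
            {"q_threshold": peaks.q_threshold, "peak_ages": peaks.peak_ages, "peak_counts": peaks.peak_counts},
            indent=2,
        )
    )
    artifacts.register(path)


def _run_metrs(cohort_dir: Path, out: Path, config: PipelineConfig, artifacts: RunArtifacts) -> None:
    z, cov, bundle = _load_processed(cohort_dir, out)
    params = config.metrs
    panels = []
    evals = []
    registry = bundle.registry
    for disease_id, sub in registry.groupby("disease_id", sort=True):
        sub = sub.set_index("participant_id")
        for task, case_status in (("prevalent", "prevalent"), ("incident", "incident")):
            cases = sub.index[sub["status"] == case_status]
            controls = sub.index[sub["status"] == "never"]
            if len(cases) < params.min_cases:
                continue
            ids = cases.union(controls)
            labels = pd.Series(0, index=ids)
            labels.loc[cases] = 1
            top_k = min(params.top_k, z.shape[1])
            model = cross_validated_metrs(
                z.loc[ids],
                labels,
                cov.loc[ids, "assessment_centre"],
                disease_id=str(disease_id),
                task=task,
                k=params.k_folds,
                top_k=top_k,
                seed=config.seed,
                ranking_params={"max_iter": params.max_iter},
            )
            ok = ~model.oof_scores.isna()
            report = evaluate(
                model.oof_scores[ok].to_numpy(),
                labels[ok].to_numpy(),
                n_bootstrap=params.n_bootstrap,
                seed=config.seed,
            )
            for rank, met in enumerate(model.selected_metabolites, start=1):
                panels.append(
                    {
                        "disease_id": disease_id,
                        "task": task,
                        "rank": rank,
                        "metabolite_id": met,
                        "mean_fold_rank": model.mean_ranks[met],
                    }
                )
            evals.append(
                {
                    "disease_id": disease_id,
                    "task": task,
                    "auc": report.auc,
                    "ci_low": report.ci95[0],
                    "ci_high": report.ci95[1],
                    "n": int(ok.sum()),
                    "n_cases": int(labels[ok].sum()),
                }
            )
    artifacts.register(write_table(pd.DataFrame(panels), out / "metrs_panels.tsv", index=False))
    artifacts.register(write_table(pd.DataFrame(evals), out / "metrs_eval.tsv", index=False))
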