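"""End-to-end orchestration: seeded runs, report assembly, and a manifest.

A run executes the stages in analysis order — cohort (read or simulate) →
EV features → univariate stats with FDR → correlation groups → PCA /
subject clustering → enrichment + random forest — writing one directory of
CSV/JSON outputs plus ``manifest.json`` (config echo, seed, package
versions, per-file checksums).

Randomness policy: every stage draws from its own seed, derived from the
master seed as ``master_seed + stage index`` (cohort sim 0, EV sim 1,
stats 2, groups 3, cluster 4, RF 5), so each stage is independently
reproducible.  No global RNG state is used anywhere.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import (
    CohortTable,
    complete_case_filter,
    read_cohort,
    read_descriptors,
    write_cohort,
    z_score,
)
from .enrichment import (
    RFProtocolConfig,
    feature_importance_summary,
    run_protocol,
    write_rf_report,
)
from .ev import (
    MARKERS,
    cohort_ev_features,
    read_particles,
    size_gate,
    subpopulation_profile,
    write_particles,
)
from .grouping import (
    cluster_variables,
    correlation_matrix,
    group_correlogram_export,
    write_assignment,
)
from .simulate import generate_cohort, generate_ev_particles, koa_scenario_presets
from .stats import run_univariate
from .unsupervised import cluster_subjects, linkage_to_newick, pca_subjects

logger = logging.getLogger(__name__)

STAGE_OFFSETS = {"cohort": 0, "ev": 1, "stats": 2, "groups": 3, "cluster": 4, "rf": 5}


class PipelineError(RuntimeError):
    """A pipeline stage failed; partial outputs are preserved."""


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one of ``preset`` (simulation scenario name) or ``cohort_csv``
    must be set.  Stage toggles switch whole stages off; per-stage parameter
    blocks mirror the underlying module parameters.
    """

    preset: str | None = None
    cohort_csv: str | None = None
    descriptors_csv: str | None = None
    particles_csv: str | None = None
    samples_csv: str | None = None
    seed: int = 0
    run_stats: bool = True
    run_groups: bool = True
    run_cluster: bool = True
    run_rf: bool = True
    alpha: float = 0.05
    drop_variables: tuple[str, ...] = ()
    k: int = 5
    residual_threshold: float = 0.4
    n_clusters: int = 2
    rf_protocols: tuple[str, ...] = ("enrich_before_split", "enrich_after_split")
    rf: RFProtocolConfig = field(default_factory=RFProtocolConfig)

    def validate(self) -> None:
        if (self.preset is None) == (self.cohort_csv is None):
            raise PipelineError("exactly one of preset / cohort_csv must be set")


def load_config(path) -> RunConfig:
    """Load a RunConfig from a TOML file; the ``[rf]`` table maps onto
    :class:`RFProtocolConfig`."""
    import tomllib

    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    rf_raw = raw.pop("rf", {})
    known = {f.name for f in dataclasses.fields(RunConfig)} - {"rf"}
    unknown = set(raw) - known
    if unknown:
        raise PipelineError(f"unknown config keys: {sorted(unknown)}")
    for key in ("drop_variables", "rf_protocols"):
        if key in raw:
            raw[key] = tuple(raw[key])
    return RunConfig(**raw, rf=RFProtocolConfig(**rf_raw))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage_seed(config: RunConfig, stage: str) -> int:
    return config.seed + STAGE_OFFSETS[stage]


def simulate_ev_stage(table: CohortTable, preset, seed: int):
    """Generate per-subject EV particle tables from the preset's
    per-diagnosis profiles and summarize them into cohort columns."""
    profiles_by_subject: dict = {}
    particle_tables = []
    for i, subject in enumerate(table.subjects):
        diag = table.diagnosis.loc[subject]
        ev_profiles = preset.ev_profiles[diag]
        sev_profiles = {c: p for c, p in ev_profiles.items() if c in MARKERS}
        particles = generate_ev_particles(
            sev_profiles, 1, seed=seed + i, sample_ids=[subject]
        )
        gated = size_gate(particles, "sEV")
        profiles_by_subject[subject] = {
            capture: subpopulation_profile(gated, capture) for capture in sev_profiles
        }
        particle_tables.append(particles)
    features, descriptors = cohort_ev_features(profiles_by_subject, table.subjects)
    return features, descriptors, particle_tables


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Execute the configured stages and write the report bundle.

    Returns the manifest dict.  Any stage failure raises
    :class:`PipelineError` naming the stage; outputs written so far stay on
    disk.
    """
    config.validate()
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "config": _config_echo(config),
        "versions": {
            "python": sys.version.split()[0],
            "evcohort": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "stages": {},
        "checksums": {},
    }
    stage = "cohort"
    try:
        if config.preset is not None:
            presets = koa_scenario_presets()
            if config.preset not in presets:
                raise PipelineError(
                    f"unknown preset {config.preset!r}; available: {sorted(presets)}"
                )
            preset = presets[config.preset]
            sim_config = dataclasses.replace(preset.cohort, seed=_stage_seed(config, "cohort"))
            table, truth = generate_cohort(sim_config)
            stage = "ev"
            features, ev_descriptors, particle_tables = simulate_ev_stage(
                table, preset, _stage_seed(config, "ev")
            )
            table = CohortTable(
                data=pd.concat([table.data, features], axis=1),
                diagnosis=table.diagnosis,
                sex=table.sex,
                descriptors={**table.descriptors, **ev_descriptors},
            )
            (out / "planted_truth.json").write_text(
                json.dumps(
                    {"group_ids": truth.group_ids,
                     "effect_sizes": list(truth.effect_sizes), "seed": truth.seed},
                    indent=2,
                )
            )
            merged = particle_tables[0]
            for t in particle_tables[1:]:
                merged = type(merged)(
                    particles=pd.concat([merged.particles, t.particles], ignore_index=True),
                    samples=pd.concat([merged.samples, t.samples]),
                )
            write_particles(merged, out / "ev_particles.csv", out / "ev_samples.csv")
            manifest["stages"]["ev"] = {"n_particles": int(len(merged.particles))}
        else:
            schema = (
                read_descriptors(config.descriptors_csv) if config.descriptors_csv else None
            )
            table = read_cohort(config.cohort_csv, schema)
            if config.particles_csv and config.samples_csv:
                stage = "ev"
                particles = read_particles(config.particles_csv, config.samples_csv)
                gated = size_gate(particles, "sEV")
                profiles = {
                    sid: {
                        c: subpopulation_profile(gated, c, sample_id=sid)
                        for c in MARKERS
                        if len(
                            gated.particles[
                                (gated.particles["sample_id"] == sid)
                                & (gated.particles["capture"] == c)
                            ]
                        )
                    }
                    for sid in gated.particles["sample_id"].unique()
                }
                features, ev_descriptors = cohort_ev_features(profiles, table.subjects)
                table = CohortTable(
                    data=pd.concat([table.data, features], axis=1),
                    diagnosis=table.diagnosis,
                    sex=table.sex,
                    descriptors={**table.descriptors, **ev_descriptors},
                )
        write_cohort(table, out / "cohort.csv", out / "descriptors.csv")
        manifest["stages"]["cohort"] = {
            "n_subjects": table.n_subjects, "n_variables": len(table.variables)
        }

        if config.run_stats:
            stage = "stats"
            results = run_univariate(table, config.alpha)
            results.to_csv(out / "stats.csv", index=False)
            report = results.attrs["fdr_report"]
            (out / "fdr.json").write_text(
                json.dumps(
                    {"alpha": report.alpha, "m": len(report.p_values),
                     "k_star": report.k_star, "critical_value": report.critical_value,
                     "threshold_met": report.threshold_met,
                     "rejected": [v for v, rej in report.reject.items() if rej]},
                    indent=2,
                )
            )
            manifest["stages"]["stats"] = {
                "n_tests": int(len(results)), "n_rejected": report.k_star
            }

        analysis = complete_case_filter(table, list(config.drop_variables))
        ztable = z_score(analysis)

        assignment = None
        if config.run_groups:
            stage = "groups"
            corr = correlation_matrix(ztable)
            assignment = cluster_variables(corr, config.k, config.residual_threshold)
            write_assignment(assignment, out / "groups.csv")
            group_correlogram_export(
                corr, assignment, alpha=config.alpha,
                matrix_path=out / "correlation.csv", stars_path=out / "correlation_stars.csv",
            )
            manifest["stages"]["groups"] = {
                "k": assignment.k,
                "n_residual": sum(
                    1 for g in assignment.assignment.values() if g == "residual"
                ),
            }

        if config.run_cluster:
            stage = "cluster"
            pca = pca_subjects(ztable)
            pca.scores.to_csv(out / "pca_scores.csv")
            pca.loadings.to_csv(out / "pca_loadings.csv")
            clustering = cluster_subjects(ztable, config.n_clusters)
            (out / "subject_tree.nwk").write_text(linkage_to_newick(clustering))
            (out / "subject_clusters.json").write_text(
                json.dumps(
                    {"labels": {str(k): v for k, v in clustering.labels.items()},
                     "ari": clustering.ari, "purity": clustering.purity},
                    indent=2,
                )
            )
            manifest["stages"]["cluster"] = {
                "ari": clustering.ari, "purity": clustering.purity,
                "explained_variance_pc1_pc2": float(
                    pca.explained_variance_ratio[:2].sum()
                ),
            }

        if config.run_rf:
            stage = "rf"
            if assignment is None:
                corr = correlation_matrix(ztable)
                assignment = cluster_variables(corr, config.k, config.residual_threshold)
            rf_config = dataclasses.replace(config.rf, seed=_stage_seed(config, "rf"))
            reports = {}
            for protocol in config.rf_protocols:
                report = run_protocol(ztable, assignment, rf_config, protocol)
                write_rf_report(report, out / f"rf_{protocol}.json")
                reports[protocol] = report
                if report.importance_reliable:
                    feature_importance_summary([report]).to_csv(
                        out / f"rf_{protocol}_importance.csv", index=False
                    )
            manifest["stages"]["rf"] = {
                p: {"mean_accuracy": r.mean_accuracy,
                    "importance_reliable": r.importance_reliable}
                for p, r in reports.items()
            }
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    for path in sorted(out.iterdir()):
        if path.is_file() and path.name != "manifest.json":
            manifest["checksums"][path.name] = _sha256(path)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def _config_echo(config: RunConfig) -> dict:
    echo = dataclasses.asdict(config)
    echo["drop_variables"] = list(config.drop_variables)
    echo["rf_protocols"] = list(config.rf_protocols)
    return echo


__all__ = ["PipelineError", "RunConfig", "load_config", "run_pipeline", "STAGE_OFFSETS"]
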