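"""Group-sampling data enrichment and random-forest classification.

A 16-subject cohort is too small to train a classifier on ~38 variables,
but the variables form a handful of strongly intra-correlated groups whose
members carry largely redundant information.  The enrichment step exploits
this redundancy: each replicate draws one variable per group (the same
choice for every subject, so the replicate has a coherent feature meaning)
and every original subject contributes one pseudo-subject with the sampled
values and its inherited diagnosis label.  Repeating 1000× yields a dataset
of 1000 × n pseudo-subjects over k features (one per group, residual group
included).

Two split protocols bracket the classifier's meaning:

* ``enrich_before_split`` — enrich first, then split pseudo-subjects 80/20.
  Train and test then share source subjects, so near-perfect accuracy is a
  *structural leakage* result: it certifies within-group information
  redundancy, not generalization to new subjects.
* ``enrich_after_split`` — split the original subjects 80/20 first, then
  enrich each side with independent variable samplings.  Accuracy here is
  an honest estimate of predicting new subjects.

Feature relevance is scored by the forest's mean decrease in impurity
(MDI), averaged over repeated fits.  MDI is only meaningful when the model
predicts well, so reports carry a reliability flag gated on accuracy.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import train_test_split

from .cohort import ZScoreTable
from .grouping import RESIDUAL, GroupAssignment

PROTOCOLS = ("original_features", "enrich_before_split", "enrich_after_split", "ev_only")


class EnrichmentError(ValueError):
    """Invalid input to enrichment or an RF protocol."""


@dataclass
class EnrichedTable:
    """Pseudo-subjects × one-feature-per-group matrix with provenance.

    ``data`` rows are pseudo-subjects (n_subjects × n_replicates of them);
    columns are group features (``group_1``..``group_k`` plus ``residual``).
    ``provenance`` records, per pseudo-subject, the source subject, the
    replicate id, and the variable sampled for each group feature.
    """

    data: pd.DataFrame
    labels: pd.Series
    provenance: pd.DataFrame
    feature_groups: dict  # feature name -> group id


@dataclass(frozen=True)
class RFProtocolConfig:
    """Random-forest protocol configuration.

    Tree hyperparameters follow the fixed recipe used throughout: 100 trees,
    entropy splits, up to 6 candidate features per split, bootstrap
    resampling, unlimited depth.  ``n_replicates`` is the enrichment factor,
    ``n_repeats`` the number of independent fit/split repetitions averaged
    in the report, ``train_fraction`` the subject (or pseudo-subject) share
    used for training.  MDI importances are flagged unreliable when mean
    accuracy falls below ``importance_accuracy_gate``.
    """

    n_trees: int = 100
    criterion: str = "entropy"
    max_features: int = 6
    bootstrap: bool = True
    max_depth: int | None = None
    min_samples_split: int = 2
    min_samples_leaf: int = 1
    n_repeats: int = 100
    train_fraction: float = 0.8
    n_replicates: int = 1000
    seed: int = 0
    importance_accuracy_gate: float = 0.7
    max_retries: int = 10

    def validate(self) -> None:
        if self.n_trees < 1:
            raise EnrichmentError("n_trees must be >= 1")
        if not 0.0 < self.train_fraction < 1.0:
            raise EnrichmentError("train_fraction must be in (0, 1)")
        if self.n_replicates < 1:
            raise EnrichmentError("n_replicates must be >= 1")
        if self.n_repeats < 1:
            raise EnrichmentError("n_repeats must be >= 1")


@dataclass
class RFReport:
    """Averaged outcome of one RF protocol.

    ``accuracies`` holds the per-repeat test accuracies;
    ``importances`` the per-repeat MDI scores (rows sum to 1 when sklearn
    normalizes them); ``importance_reliable`` is False when mean accuracy
    sits below the configured gate, in which case the MDI ranking should
    not be interpreted.
    """

    protocol: str
    feature_names: tuple[str, ...]
    accuracies: np.ndarray
    importances: np.ndarray  # n_repeats × n_features
    config: RFProtocolConfig
    seed: int

    @property
    def mean_accuracy(self) -> float:
        return float(self.accuracies.mean())

    @property
    def importance_mean(self) -> dict:
        return dict(zip(self.feature_names, self.importances.mean(axis=0)))

    @property
    def importance_sd(self) -> dict:
        sd = self.importances.std(axis=0, ddof=1) if len(self.importances) > 1 else np.zeros(
            self.importances.shape[1]
        )
        return dict(zip(self.feature_names, sd))

    @property
    def importance_reliable(self) -> bool:
        return self.mean_accuracy > self.config.importance_accuracy_gate


def _group_features(groups: GroupAssignment, variables) -> dict:
    """Ordered mapping feature name → sorted member variables."""
    members: dict = {}
    for var in variables:
        gid = groups.assignment.get(var)
        if gid is None:
            raise EnrichmentError(f"variable {var!r} has no group assignment")
        members.setdefault(gid, []).append(var)
    out = {}
    for gid in sorted(g for g in members if g != RESIDUAL):
        out[f"group_{gid}"] = sorted(members[gid])
    if RESIDUAL in members:
        out[RESIDUAL] = sorted(members[RESIDUAL])
    if not out:
        raise EnrichmentError("no groups cover the table's variables")
    return out


def _enrich_frame(
    data: pd.DataFrame, labels: pd.Series, features: dict, n_replicates: int,
    rng: np.random.Generator,
) -> EnrichedTable:
    n = len(data)
    feature_names = list(features)
    blocks, prov_rows = [], []
    for rep in range(n_replicates):
        picks = {f: features[f][rng.integers(len(features[f]))] for f in feature_names}
        blocks.append(data[[picks[f] for f in feature_names]].to_numpy(dtype=float))
        for subject in data.index:
            prov_rows.append(
                {"source_subject": subject, "replicate": rep,
                 **{f"{f}_variable": picks[f] for f in feature_names}}
            )
    index = pd.Index(
        [f"{s}_r{rep:04d}" for rep in range(n_replicates) for s in data.index],
        name="pseudo_subject",
    )
    enriched = pd.DataFrame(np.vstack(blocks), index=index, columns=feature_names)
    lab = pd.Series(np.tile(labels.to_numpy(), n_replicates), index=index, name="diagnosis")
    provenance = pd.DataFrame(prov_rows, index=index)
    groups_of = {f: (RESIDUAL if f == RESIDUAL else int(f.split("_")[1])) for f in feature_names}
    return EnrichedTable(data=enriched, labels=lab, provenance=provenance,
                         feature_groups=groups_of)


def enrich_dataset(
    table: ZScoreTable, groups: GroupAssignment, n_replicates: int = 1000, seed: int = 0
) -> EnrichedTable:
    """Enrich a complete-case standardized table ``n_replicates``-fold.

    Per replicate, one variable is drawn uniformly from each group — the
    same draw for all subjects, so every pseudo-subject of a replicate
    carries values of the same variables — and each subject contributes one
    pseudo-subject with its inherited diagnosis label.  Deterministic under
    ``seed``.
    """
    if n_replicates < 1:
        raise EnrichmentError(f"n_replicates must be >= 1, got {n_replicates}")
    if table.data.isna().any().any():
        raise EnrichmentError("enrichment requires a complete-case table")
    features = _group_features(groups, table.variables)
    rng = np.random.default_rng(seed)
    return _enrich_frame(table.data, table.diagnosis, features, n_replicates, rng)


def _stratified_split(X, y, train_fraction, seed, max_retries):
    """80/20 split stratified by label, retried (bounded) if a side is
    single-class — cannot happen with stratification, kept as a guard."""
    for attempt in range(max_retries):
        Xtr, Xte, ytr, yte = train_test_split(
            X, y, train_size=train_fraction, stratify=y, random_state=int(seed + attempt)
        )
        if len(np.unique(ytr)) == 2 and len(np.unique(yte)) == 2:
            return Xtr, Xte, ytr, yte
    raise EnrichmentError(
        f"could not draw a two-class train/test split in {max_retries} attempts"
    )


def _fit_forest(Xtr, ytr, Xte, yte, config: RFProtocolConfig, rf_seed: int):
    rf = RandomForestClassifier(
        n_estimators=config.n_trees,
        criterion=config.criterion,
        max_features=min(config.max_features, Xtr.shape[1]),
        bootstrap=config.bootstrap,
        max_depth=config.max_depth,
        min_samples_split=config.min_samples_split,
        min_samples_leaf=config.min_samples_leaf,
        n_jobs=1,
        random_state=int(rf_seed),
    )
    rf.fit(Xtr, ytr)
    return float(rf.score(Xte, yte)), rf.feature_importances_


def run_protocol(
    table: ZScoreTable,
    groups: GroupAssignment | None,
    config: RFProtocolConfig,
    protocol: str,
) -> RFReport:
    """Run one classification protocol, averaging over ``config.n_repeats``.

    ``enrich_before_split`` / ``enrich_after_split`` need a group
    assignment; ``original_features`` trains on all variables of the
    original subjects; ``ev_only`` restricts to ``ev_marker``-category
    columns.  Splits are stratified by diagnosis (an 8+8 design makes plain
    random splits frequently single-class).  MDI importances are computed on
    the training data of each repeat.  Deterministic under ``config.seed``.
    """
    config.validate()
    if protocol not in PROTOCOLS:
        raise EnrichmentError(f"unknown protocol {protocol!r}; expected one of {PROTOCOLS}")
    if table.data.isna().any().any():
        raise EnrichmentError("protocols require a complete-case table")
    y_all = table.diagnosis.to_numpy()
    if len(np.unique(y_all)) != 2:
        raise EnrichmentError("need both diagnosis classes present")

    if protocol in ("enrich_before_split", "enrich_after_split"):
        if groups is None:
            raise EnrichmentError(f"{protocol} requires a group assignment")
        features = _group_features(groups, table.variables)
        feature_names = tuple(features)
    elif protocol == "ev_only":
        cols = table.variables_in_category("ev_marker")
        if not cols:
            raise EnrichmentError("ev_only: table has no ev_marker variables")
        feature_names = tuple(cols)
    else:
        feature_names = tuple(table.variables)

    accuracies = np.empty(config.n_repeats)
    importances = np.empty((config.n_repeats, len(feature_names)))
    for rep in range(config.n_repeats):
        ss = np.random.SeedSequence([config.seed, rep]).generate_state(4) % (2**31 - 1)
        if protocol == "enrich_before_split":
            enriched = _enrich_frame(
                table.data, table.diagnosis, features, config.n_replicates,
                np.random.default_rng(int(ss[0])),
            )
            Xtr, Xte, ytr, yte = _stratified_split(
                enriched.data.to_numpy(), enriched.labels.to_numpy(),
                config.train_fraction, ss[1], config.max_retries,
            )
        elif protocol == "enrich_after_split":
            tr_idx, te_idx = _stratified_split(
                np.arange(len(table.data)), y_all, config.train_fraction,
                ss[1], config.max_retries,
            )[:2]
            tr_enr = _enrich_frame(
                table.data.iloc[tr_idx], table.diagnosis.iloc[tr_idx], features,
                config.n_replicates, np.random.default_rng(int(ss[0])),
            )
            te_enr = _enrich_frame(
                table.data.iloc[te_idx], table.diagnosis.iloc[te_idx], features,
                config.n_replicates, np.random.default_rng(int(ss[3])),
            )
            Xtr, ytr = tr_enr.data.to_numpy(), tr_enr.labels.to_numpy()
            Xte, yte = te_enr.data.to_numpy(), te_enr.labels.to_numpy()
        else:
            X = table.data[list(feature_names)].to_numpy()
            Xtr, Xte, ytr, yte = _stratified_split(
                X, y_all, config.train_fraction, ss[1], config.max_retries
            )
        accuracies[rep], importances[rep] = _fit_forest(
            Xtr, ytr, Xte, yte, config, ss[2]
        )
    return RFReport(
        protocol=protocol,
        feature_names=feature_names,
        accuracies=accuracies,
        importances=importances,
        config=config,
        seed=config.seed,
    )


def feature_importance_summary(reports: list[RFReport]) -> pd.DataFrame:
    """Average MDI importance across reports, with dispersion and rank.

    All reports must share the same feature space; the result is invariant
    to report order (rows sorted by descending mean importance, ties broken
    by feature name).
    """
    if not reports:
        raise EnrichmentError("no reports supplied")
    names = reports[0].feature_names
    for rep in reports[1:]:
        if rep.feature_names != names:
            raise EnrichmentError(
                f"mismatched feature spaces: {names} vs {rep.feature_names}"
            )
    stacked = np.vstack([rep.importances for rep in reports])
    mean = stacked.mean(axis=0)
    sd = stacked.std(axis=0, ddof=1) if stacked.shape[0] > 1 else np.zeros(len(names))
    out = pd.DataFrame({"feature": names, "importance_mean": mean, "importance_sd": sd})
    out = out.sort_values(
        ["importance_mean", "feature"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def write_rf_report(report: RFReport, path) -> None:
    """Serialize an RFReport as JSON (config echo, seed, per-repeat
    accuracies, importance mean/sd, reliability flag)."""
    payload = {
        "protocol": report.protocol,
        "seed": report.seed,
        "config": asdict(report.config),
        "feature_names": list(report.feature_names),
        "accuracies": report.accuracies.tolist(),
        "mean_accuracy": report.mean_accuracy,
        "importance_mean": {k: float(v) for k, v in report.importance_mean.items()},
        "importance_sd": {k: float(v) for k, v in report.importance_sd.items()},
        "importance_reliable": report.importance_reliable,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def write_enriched(table: EnrichedTable, path) -> None:
    """Write the enriched table CSV with provenance columns."""
    out = pd.concat([table.provenance, table.labels, table.data], axis=1)
    out.to_csv(path)


__all__ = [
    "PROTOCOLS",
    "EnrichmentError",
    "EnrichedTable",
    "RFProtocolConfig",
    "RFReport",
    "enrich_dataset",
    "run_protocol",
    "feature_importance_summary",
    "write_rf_report",
    "write_enriched",
]
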