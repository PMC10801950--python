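"""Per-subject multimodal cohort table: data model, CSV I/O, and preprocessing.

The cohort table holds one row per subject (diagnosis label, sex, and a set
of named numeric variables: cartilage thicknesses, functional and pain
scores, EV subpopulation counts).  Missing values are represented as NaN and
are never imputed; analyses that need complete cases call
:func:`complete_case_filter` explicitly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DIAGNOSES = ("control", "KOA")
SEXES = ("M", "F")
CATEGORIES = (
    "demographic",
    "cartilage",
    "objective_function",
    "subjective_function",
    "objective_pain",
    "subjective_pain",
    "ev_marker",
)


class CohortError(ValueError):
    """Base class for cohort-table validation failures."""


class DuplicateSubjectError(CohortError):
    """Two rows share a subject id."""


class UnknownLabelError(CohortError):
    """A diagnosis or sex label is outside the allowed set."""


class SchemaMismatchError(CohortError):
    """Table columns do not match the supplied descriptor schema."""


class ConstantVariableError(CohortError):
    """A variable has zero sample variance and cannot be standardized."""


class EmptyDiagnosisGroupError(CohortError):
    """A filtering step removed every subject of one diagnosis group."""


@dataclass(frozen=True)
class VariableDescriptor:
    """Metadata for one cohort variable.

    Parameters
    ----------
    name : str
        Unique variable name (column header in the cohort CSV).
    category : str
        One of :data:`CATEGORIES` — the variable grouping used for
        category-ordered correlogram exports.
    units : str
        Free-text units (e.g. ``"mm"``, ``"particles/ml"``, ``"%"``).
    higher_is_worse : bool
        Reporting direction flag: True when larger values indicate worse
        clinical status.
    """

    name: str
    category: str
    units: str = ""
    higher_is_worse: bool = False

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise SchemaMismatchError(
                f"unknown category {self.category!r} for variable {self.name!r}; "
                f"expected one of {CATEGORIES}"
            )


@dataclass
class CohortTable:
    """Subjects × variables numeric table with diagnosis and sex labels.

    ``data`` is indexed by subject id; NaN marks missing values.  The
    descriptor dict carries one :class:`VariableDescriptor` per column.
    """

    data: pd.DataFrame
    diagnosis: pd.Series
    sex: pd.Series
    descriptors: dict[str, VariableDescriptor] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.data.index.duplicated().any():
            dupes = self.data.index[self.data.index.duplicated()].tolist()
            raise DuplicateSubjectError(f"duplicate subject ids: {dupes}")
        for name, series, allowed in (
            ("diagnosis", self.diagnosis, DIAGNOSES),
            ("sex", self.sex, SEXES),
        ):
            if not series.index.equals(self.data.index):
                raise SchemaMismatchError(f"{name} labels do not cover all subjects")
            bad = series[~series.isin(allowed)]
            if len(bad):
                raise UnknownLabelError(
                    f"unknown {name} label {bad.iloc[0]!r} for subject {bad.index[0]!r}"
                )
        if not self.descriptors:
            self.descriptors = {
                c: VariableDescriptor(c, "subjective_function") for c in self.data.columns
            }
        if set(self.descriptors) != set(self.data.columns):
            missing = set(self.data.columns) - set(self.descriptors)
            extra = set(self.descriptors) - set(self.data.columns)
            raise SchemaMismatchError(
                f"descriptor/column mismatch: missing={sorted(missing)}, extra={sorted(extra)}"
            )

    @property
    def subjects(self) -> list:
        return list(self.data.index)

    @property
    def variables(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_subjects(self) -> int:
        return len(self.data)

    def mask(self) -> pd.DataFrame:
        """Boolean missingness mask (True = missing)."""
        return self.data.isna()

    def variables_in_category(self, category: str) -> list[str]:
        return [v for v in self.variables if self.descriptors[v].category == category]


@dataclass
class ZScoreTable(CohortTable):
    """Cohort table standardized per variable; normalization parameters kept.

    ``norm_params`` has one row per variable with the mean and sample
    standard deviation (n−1 denominator) used for the transform, so raw
    values can be recovered.
    """

    norm_params: pd.DataFrame = field(default_factory=pd.DataFrame)


def read_descriptors(path) -> list[VariableDescriptor]:
    """Read the descriptor sidecar CSV: ``name,category,units,higher_is_worse``."""
    df = pd.read_csv(path, dtype={"name": str, "category": str, "units": str})
    return [
        VariableDescriptor(
            name=row["name"],
            category=row["category"],
            units="" if pd.isna(row.get("units")) else str(row["units"]),
            higher_is_worse=bool(int(row.get("higher_is_worse", 0))),
        )
        for _, row in df.iterrows()
    ]


def write_descriptors(descriptors: dict[str, VariableDescriptor], path) -> None:
    pd.DataFrame(
        [
            {
                "name": d.name,
                "category": d.category,
                "units": d.units,
                "higher_is_worse": int(d.higher_is_worse),
            }
            for d in descriptors.values()
        ]
    ).to_csv(path, index=False)


def read_cohort(path, schema: list[VariableDescriptor] | None = None) -> CohortTable:
    """Read a tidy cohort CSV: ``subject_id,diagnosis,sex,<var1>,...``.

    Empty numeric fields become missing values (NaN in the table, True in
    the mask); nothing is imputed.  ``schema``, when given, must cover the
    variable columns exactly.
    """
    df = pd.read_csv(path, dtype={"subject_id": str, "diagnosis": str, "sex": str})
    required = ["subject_id", "diagnosis", "sex"]
    if df.columns[: len(required)].tolist() != required:
        raise SchemaMismatchError(
            f"expected leading columns {required}, got {df.columns[:3].tolist()}"
        )
    var_cols = [c for c in df.columns if c not in required]
    values = df[var_cols].apply(pd.to_numeric, errors="raise")
    values.index = pd.Index(df["subject_id"], name="subject_id")
    descriptors = None
    if schema is not None:
        descriptors = {d.name: d for d in schema}
        if set(descriptors) != set(var_cols):
            raise SchemaMismatchError(
                f"schema names {sorted(descriptors)} do not match CSV variable "
                f"columns {sorted(var_cols)}"
            )
    return CohortTable(
        data=values,
        diagnosis=pd.Series(df["diagnosis"].values, index=values.index),
        sex=pd.Series(df["sex"].values, index=values.index),
        descriptors=descriptors or {},
    )


def write_cohort(table: CohortTable, path, descriptor_path=None) -> None:
    """Write the tidy cohort CSV (and optionally the descriptor sidecar)."""
    out = table.data.copy()
    out.insert(0, "sex", table.sex)
    out.insert(0, "diagnosis", table.diagnosis)
    out.index.name = "subject_id"
    # 17 significant digits: round-trips float64 exactly
    out.to_csv(path, float_format="%.17g")
    if descriptor_path is not None:
        write_descriptors(table.descriptors, descriptor_path)


def z_score(table: CohortTable) -> ZScoreTable:
    """Standardize each variable to mean 0, sample SD 1 across subjects.

    Uses the n−1 (sample) standard deviation.  Missing entries remain
    missing.  Raises :class:`ConstantVariableError` for any variable with
    zero sample variance, naming it.
    """
    means = table.data.mean(axis=0, skipna=True)
    sds = table.data.std(axis=0, ddof=1, skipna=True)
    n_obs = table.data.notna().sum(axis=0)
    if (n_obs < 2).any():
        bad = n_obs.index[n_obs < 2].tolist()
        raise CohortError(f"variables with <2 non-missing values: {bad}")
    if (sds == 0).any():
        bad = sds.index[sds == 0].tolist()
        raise ConstantVariableError(f"constant variables cannot be standardized: {bad}")
    z = (table.data - means) / sds
    return ZScoreTable(
        data=z,
        diagnosis=table.diagnosis.copy(),
        sex=table.sex.copy(),
        descriptors=dict(table.descriptors),
        norm_params=pd.DataFrame({"mean": means, "sd": sds}),
    )


def complete_case_filter(
    table: CohortTable, drop_variables: list[str] = (), *, require_both_groups: bool = True
) -> CohortTable:
    """Drop the listed variables, then any subject still missing a value.

    Mirrors the exclusion strategy of small-cohort clinical analyses: a
    variable observed in too few subjects is removed wholesale, and the
    remaining table is reduced to complete cases.  The removals are logged.
    Raises :class:`EmptyDiagnosisGroupError` if a diagnosis group is emptied.
    """
    unknown = [v for v in drop_variables if v not in table.data.columns]
    if unknown:
        raise SchemaMismatchError(f"drop_variables not in table: {unknown}")
    data = table.data.drop(columns=list(drop_variables))
    keep = data.notna().all(axis=1)
    dropped_subjects = data.index[~keep].tolist()
    if drop_variables:
        logger.info("complete_case_filter: dropped variables %s", list(drop_variables))
    if dropped_subjects:
        logger.info("complete_case_filter: dropped subjects %s", dropped_subjects)
    data = data.loc[keep]
    diagnosis = table.diagnosis.loc[keep]
    if require_both_groups:
        for d in DIAGNOSES:
            if (diagnosis == d).sum() == 0:
                raise EmptyDiagnosisGroupError(
                    f"complete-case filtering removed every {d!r} subject"
                )
    return CohortTable(
        data=data,
        diagnosis=diagnosis,
        sex=table.sex.loc[keep],
        descriptors={v: d for v, d in table.descriptors.items() if v in data.columns},
    )


def lici_percent(first_meps, second_meps) -> float:
    """Long-interval cortical inhibition, in percent.

    LICI = 100 × mean(second MEP amplitudes) / mean(first MEP amplitudes),
    from paired-pulse TMS trials.  Values below 100 indicate inhibition of
    the second response.
    """
    first = np.asarray(first_meps, dtype=float)
    second = np.asarray(second_meps, dtype=float)
    if first.size == 0 or second.size == 0:
        raise CohortError("MEP amplitude lists must be non-empty")
    if first.mean() <= 0:
        raise CohortError(
            f"mean first-pulse MEP amplitude must be positive, got {first.mean()}"
        )
    return 100.0 * second.mean() / first.mean()


def average_bilateral(left, right):
    """Average left- and right-knee measurements into one per-subject value."""
    return (np.asarray(left, dtype=float) + np.asarray(right, dtype=float)) / 2.0


__all__ = [
    "CATEGORIES",
    "DIAGNOSES",
    "SEXES",
    "CohortError",
    "DuplicateSubjectError",
    "UnknownLabelError",
    "SchemaMismatchError",
    "ConstantVariableError",
    "EmptyDiagnosisGroupError",
    "VariableDescriptor",
    "CohortTable",
    "ZScoreTable",
    "read_cohort",
    "write_cohort",
    "read_descriptors",
    "write_descriptors",
    "z_score",
    "complete_case_filter",
    "lici_percent",
    "average_bilateral",
]
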