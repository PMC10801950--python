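"""Single-EV accounting: size gating, tetraspanin co-localization profiles,
and per-mL concentrations.

Chip-based single-particle imaging (SP-IRIS) captures individual small EVs
on antibody spots (CD41, CD63, CD81, CD9) and reads per-particle positivity
for the other markers; high-sensitivity flow cytometry sizes large EVs
(CD61 scatter channel).  This module turns per-particle detection tables
into subpopulation counts, per-capture percentages, and particles-per-mL
concentrations.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import pandas as pd

logger = logging.getLogger(__name__)

MARKERS = ("CD41", "CD63", "CD81", "CD9")
CAPTURE_CHANNELS = MARKERS + ("CD61-scatter",)

#: Size gates in nm: small EVs [50, 200] (closed), large EVs (200, 1000]
#: (open lower bound — a particle at exactly 200 nm belongs to the sEV gate).
SIZE_GATES_NM = {"sEV": (50.0, 200.0), "lEV": (200.0, 1000.0)}


class EVTableError(ValueError):
    """Validation failure in an EV particle table."""


class NoCapturedParticlesError(EVTableError):
    """No particles on the requested capture channel (no data — distinct from
    an all-negative co-localization profile, which is a valid observation)."""


@dataclass
class EVParticleTable:
    """Per-particle detections plus per-sample metadata.

    ``particles`` columns: ``sample_id, capture, CD41, CD63, CD81, CD9,
    diameter_nm`` (marker columns boolean).  ``samples`` is indexed by
    sample_id with ``dilution_factor`` (≥1) and ``analyzed_volume_ml`` (>0).
    A particle captured on a tetraspanin channel is positive for that marker
    by construction (enforced at ingest).
    """

    particles: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["sample_id", "capture", *MARKERS, "diameter_nm"]
        missing = [c for c in required if c not in self.particles.columns]
        if missing:
            raise EVTableError(f"particle table missing columns: {missing}")
        bad_capture = set(self.particles["capture"]) - set(CAPTURE_CHANNELS)
        if bad_capture:
            raise EVTableError(f"unknown capture channels: {sorted(bad_capture)}")
        if (self.particles["diameter_nm"] <= 0).any():
            raise EVTableError("particle diameters must be positive")
        for m in MARKERS:
            on_channel = self.particles["capture"] == m
            if on_channel.any() and not self.particles.loc[on_channel, m].all():
                raise EVTableError(
                    f"particle captured on {m} must be {m}-positive (self-positivity)"
                )
        meta_missing = [
            c for c in ("dilution_factor", "analyzed_volume_ml") if c not in self.samples.columns
        ]
        if meta_missing:
            raise EVTableError(f"sample metadata missing columns: {meta_missing}")
        if (self.samples["dilution_factor"] < 1).any():
            raise EVTableError("dilution_factor must be >= 1")
        if (self.samples["analyzed_volume_ml"] <= 0).any():
            raise EVTableError("analyzed_volume_ml must be positive")
        unknown = set(self.particles["sample_id"]) - set(self.samples.index)
        if unknown:
            raise EVTableError(f"particles reference unknown samples: {sorted(unknown)}")

    @property
    def sample_ids(self) -> list:
        return list(self.samples.index)


@dataclass
class SubpopulationProfile:
    """Co-localization profile of particles captured on one marker.

    ``table`` is indexed by the 8 positivity patterns over the three
    non-capture markers ("single" plus every double/triple/quadruple
    combination), with columns ``count``, ``percentage`` and
    ``concentration`` (particles/ml of original sample).
    """

    capture: str
    sample_id: object
    table: pd.DataFrame
    total_count: int
    total_concentration: float


def pattern_labels(capture: str) -> list[str]:
    """The 8 positivity patterns over the non-capture tetraspanins.

    "single" means positive for the capture marker only; other labels name
    the additional positive markers in canonical order, joined by "+".
    """
    others = [m for m in MARKERS if m != capture]
    labels = ["single"]
    for k in (1, 2, 3):
        labels.extend("+".join(combo) for combo in itertools.combinations(others, k))
    return labels


def read_particles(particle_csv, sample_csv) -> EVParticleTable:
    """Read the particle CSV (booleans as 0/1) and sample-metadata CSV.

    Capture-channel self-positivity is enforced here: a particle on a
    tetraspanin capture spot is set positive for that marker.
    """
    particles = pd.read_csv(particle_csv, dtype={"sample_id": str, "capture": str})
    for m in MARKERS:
        particles[m] = particles[m].astype(int).astype(bool)
    for m in MARKERS:
        particles.loc[particles["capture"] == m, m] = True
    samples = pd.read_csv(sample_csv, dtype={"sample_id": str}).set_index("sample_id")
    return EVParticleTable(particles=particles, samples=samples)


def write_particles(table: EVParticleTable, particle_csv, sample_csv) -> None:
    out = table.particles.copy()
    for m in MARKERS:
        out[m] = out[m].astype(int)
    out.to_csv(particle_csv, index=False)
    table.samples.to_csv(sample_csv)


def size_gate(table: EVParticleTable, regime: str) -> EVParticleTable:
    """Keep particles inside the named diameter gate.

    sEV keeps diameters in [50, 200] nm; lEV keeps (200, 1000] nm.  The two
    gates partition (50, 1000]: no particle passes both.  An empty result is
    permitted.
    """
    if regime not in SIZE_GATES_NM:
        raise EVTableError(f"unknown size regime {regime!r}; expected one of "
                           f"{sorted(SIZE_GATES_NM)}")
    lo, hi = SIZE_GATES_NM[regime]
    d = table.particles["diameter_nm"]
    keep = (d >= lo) & (d <= hi) if regime == "sEV" else (d > lo) & (d <= hi)
    logger.info("size_gate(%s): kept %d / %d particles", regime, int(keep.sum()), len(keep))
    return EVParticleTable(
        particles=table.particles.loc[keep].reset_index(drop=True),
        samples=table.samples.copy(),
    )


def concentration_per_ml(count: int, dilution_factor: float, analyzed_volume_ml: float) -> float:
    """Back-calculate original-sample concentration from gated event counts.

    concentration = count × dilution_factor / analyzed_volume_ml.
    """
    if dilution_factor < 1:
        raise EVTableError(f"dilution_factor must be >= 1, got {dilution_factor}")
    if analyzed_volume_ml <= 0:
        raise EVTableError(f"analyzed_volume_ml must be positive, got {analyzed_volume_ml}")
    if count < 0:
        raise EVTableError(f"count must be non-negative, got {count}")
    return count * dilution_factor / analyzed_volume_ml


def subpopulation_profile(
    table: EVParticleTable, capture: str, sample_id=None
) -> SubpopulationProfile:
    """Tally the co-localization patterns of particles captured on one marker.

    For each of the 8 positivity patterns over the three non-capture
    tetraspanins: particle count, percentage of all captured particles
    (per-capture denominator — each capture spot sums to 100%), and
    concentration per mL of original sample.
    """
    if capture not in MARKERS:
        raise EVTableError(
            f"co-localization profiles are defined for tetraspanin captures {MARKERS}; "
            f"got {capture!r}"
        )
    p = table.particles
    if sample_id is None:
        ids = p["sample_id"].unique()
        if len(ids) > 1:
            raise EVTableError(
                f"table holds {len(ids)} samples; pass sample_id to select one"
            )
        if len(ids) == 0:
            raise NoCapturedParticlesError("particle table is empty (no data)")
        sample_id = ids[0]
    if sample_id not in table.samples.index:
        raise EVTableError(f"unknown sample {sample_id!r}")
    sub = p[(p["sample_id"] == sample_id) & (p["capture"] == capture)]
    if len(sub) == 0:
        raise NoCapturedParticlesError(
            f"no particles captured on {capture} for sample {sample_id!r} "
            "(no data, not an all-negative profile)"
        )
    others = [m for m in MARKERS if m != capture]
    labels = pattern_labels(capture)
    pos = sub[others].to_numpy(dtype=bool)
    observed = [
        "single" if not row.any() else "+".join(m for m, flag in zip(others, row) if flag)
        for row in pos
    ]
    counts = pd.Series(observed).value_counts().reindex(labels, fill_value=0)
    meta = table.samples.loc[sample_id]
    dilution, volume = float(meta["dilution_factor"]), float(meta["analyzed_volume_ml"])
    total = int(counts.sum())
    out = pd.DataFrame(
        {
            "count": counts.astype(int),
            "percentage": 100.0 * counts / total,
            "concentration": [concentration_per_ml(int(c), dilution, volume) for c in counts],
        },
        index=pd.Index(labels, name="pattern"),
    )
    return SubpopulationProfile(
        capture=capture,
        sample_id=sample_id,
        table=out,
        total_count=total,
        total_concentration=concentration_per_ml(total, dilution, volume),
    )


def cohort_ev_features(
    profiles: dict, subjects: list, captures: tuple[str, ...] = MARKERS
) -> tuple[pd.DataFrame, dict]:
    """Bridge particle accounting to the subject-level cohort table.

    ``profiles`` maps subject id → {capture → SubpopulationProfile}; a
    subject absent from the mapping (no SP-IRIS run) gets all-missing
    columns.  Emits, per capture marker: one total-count column, 8 pattern
    count columns and 8 pattern percentage columns, all tagged with the
    ``ev_marker`` category.

    Returns the feature frame (indexed by subject) and a descriptor dict.
    """
    from .cohort import VariableDescriptor

    unknown = set(profiles) - set(subjects)
    if unknown:
        raise EVTableError(f"profiles reference subjects not in cohort: {sorted(unknown)}")
    columns: dict[str, dict] = {}
    descriptors: dict[str, VariableDescriptor] = {}
    for capture in captures:
        total_col = f"{capture}_total_count"
        columns[total_col] = {}
        descriptors[total_col] = VariableDescriptor(total_col, "ev_marker", "particles")
        for label in pattern_labels(capture):
            for kind, units in (("count", "particles"), ("pct", "%")):
                col = f"{capture}_{label}_{kind}"
                columns[col] = {}
                descriptors[col] = VariableDescriptor(col, "ev_marker", units)
    for subject in subjects:
        per_capture = profiles.get(subject, {})
        for capture in captures:
            prof = per_capture.get(capture)
            if prof is None:
                continue
            columns[f"{capture}_total_count"][subject] = prof.total_count
            for label, row in prof.table.iterrows():
                columns[f"{capture}_{label}_count"][subject] = row["count"]
                columns[f"{capture}_{label}_pct"][subject] = row["percentage"]
    frame = pd.DataFrame(columns, index=pd.Index(subjects, name="subject_id"), dtype=float)
    return frame, descriptors


__all__ = [
    "MARKERS",
    "CAPTURE_CHANNELS",
    "SIZE_GATES_NM",
    "EVTableError",
    "NoCapturedParticlesError",
    "EVParticleTable",
    "SubpopulationProfile",
    "pattern_labels",
    "read_particles",
    "write_particles",
    "size_gate",
    "concentration_per_ml",
    "subpopulation_profile",
    "cohort_ev_features",
]
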