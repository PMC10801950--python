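import dataclasses

import pytest

import evcohort as ec


@pytest.fixture(scope="session")
def presets():
    return ec.koa_scenario_presets()


@pytest.fixture(scope="session")
def strong_cohort(presets):
    """Strong-structure synthetic cohort (16 subjects, 5 planted groups at
    r = 0.8 with |effect| = 2, 8 residual variables)."""
    table, truth = ec.generate_cohort(presets["strong-structure"].cohort)
    return table, truth


@pytest.fixture(scope="session")
def strong_ztable(strong_cohort):
    table, _ = strong_cohort
    return ec.z_score(table)


@pytest.fixture(scope="session")
def big_strong_cohort(presets):
    """Strong-structure covariance at n = 2000 subjects: sampling noise in
    the correlation matrix is negligible, so structure recovery is exact."""
    cfg = dataclasses.replace(presets["strong-structure"].cohort, n_per_group=1000, seed=0)
    return ec.generate_cohort(cfg)


def truth_assignment(truth):
    """GroupAssignment built from planted truth (for tests that isolate a
    downstream property from grouping-recovery noise)."""
    return ec.GroupAssignment(
        assignment=dict(truth.group_ids),
        k=len({g for g in truth.group_ids.values() if g != "residual"}),
        mean_within_r={v: float("nan") for v in truth.group_ids},
    )
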