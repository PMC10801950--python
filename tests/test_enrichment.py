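"""Group-sampling enrichment and random-forest protocols."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import evcohort as ec
from conftest import truth_assignment
from evcohort.enrichment import EnrichmentError


@pytest.fixture(scope="module")
def strong_setup(presets):
    table, truth = ec.generate_cohort(presets["strong-structure"].cohort)
    return ec.z_score(table), truth_assignment(truth)


class TestEnrichDataset:
    def test_shape_16000_by_6(self, strong_setup):
        ztable, groups = strong_setup
        enriched = ec.enrich_dataset(ztable, groups, n_replicates=1000, seed=0)
        assert enriched.data.shape == (16000, 6)
        assert list(enriched.data.columns) == [
            "group_1", "group_2", "group_3", "group_4", "group_5", "residual"
        ]
        assert len(enriched.labels) == 16000

    def test_labels_inherited(self, strong_setup):
        ztable, groups = strong_setup
        enriched = ec.enrich_dataset(ztable, groups, n_replicates=5, seed=1)
        for pseudo, src in enriched.provenance["source_subject"].items():
            assert enriched.labels[pseudo] == ztable.diagnosis[src]

    def test_sampled_variables_belong_to_group(self, strong_setup):
        ztable, groups = strong_setup
        enriched = ec.enrich_dataset(ztable, groups, n_replicates=20, seed=2)
        for feature, gid in enriched.feature_groups.items():
            sampled = set(enriched.provenance[f"{feature}_variable"])
            for v in sampled:
                assert groups.assignment[v] == gid

    def test_values_come_from_source_subject(self, strong_setup):
        ztable, groups = strong_setup
        enriched = ec.enrich_dataset(ztable, groups, n_replicates=3, seed=3)
        prov = enriched.provenance
        for pseudo in enriched.data.index[:50]:
            src = prov.loc[pseudo, "source_subject"]
            for feature in enriched.data.columns:
                var = prov.loc[pseudo, f"{feature}_variable"]
                assert enriched.data.loc[pseudo, feature] == ztable.data.loc[src, var]

    def test_singleton_groups_identity(self, strong_setup):
        ztable, _ = strong_setup
        singles = {"g1_v1": 1, "g2_v1": 2}
        groups = ec.GroupAssignment(assignment=singles, k=2, mean_within_r={})
        sub = ec.ZScoreTable(
            data=ztable.data[list(singles)],
            diagnosis=ztable.diagnosis, sex=ztable.sex,
            descriptors={v: ztable.descriptors[v] for v in singles},
        )
        enriched = ec.enrich_dataset(sub, groups, n_replicates=1, seed=0)
        np.testing.assert_array_equal(
            enriched.data.to_numpy(), sub.data[["g1_v1", "g2_v1"]].to_numpy()
        )

    def test_uniform_sampling_frequency(self, strong_setup):
        ztable, groups = strong_setup
        enriched = ec.enrich_dataset(ztable, groups, n_replicates=10000, seed=4)
        picks = enriched.provenance.drop_duplicates("replicate")["group_1_variable"]
        freqs = picks.value_counts(normalize=True)
        assert len(freqs) == 6  # group 1 holds 6 variables
        # each of the 6 variables drawn with frequency 1/6 ± 3 SE
        se = np.sqrt((1 / 6) * (5 / 6) / 10000)
        assert np.abs(freqs - 1 / 6).max() < 3 * se + 1e-12

    def test_determinism(self, strong_setup):
        ztable, groups = strong_setup
        e1 = ec.enrich_dataset(ztable, groups, n_replicates=50, seed=7)
        e2 = ec.enrich_dataset(ztable, groups, n_replicates=50, seed=7)
        pd.testing.assert_frame_equal(e1.data, e2.data)
        pd.testing.assert_frame_equal(e1.provenance, e2.provenance)

    def test_bad_replicates_error(self, strong_setup):
        ztable, groups = strong_setup
        with pytest.raises(EnrichmentError):
            ec.enrich_dataset(ztable, groups, n_replicates=0, seed=0)


class TestRunProtocol:
    def test_leakage_makes_before_split_near_perfect(self, strong_setup):
        ztable, groups = strong_setup
        config = ec.RFProtocolConfig(n_repeats=5, n_replicates=200, seed=0)
        report = ec.run_protocol(ztable, groups, config, "enrich_before_split")
        assert report.mean_accuracy >= 0.999

    def test_null_preset_chance_level(self, presets):
        accs = []
        for seed in range(10):
            cfg = dataclasses.replace(presets["null"].cohort, seed=seed)
            table, truth = ec.generate_cohort(cfg)
            ztable = ec.z_score(table)
            config = ec.RFProtocolConfig(n_repeats=4, n_replicates=50, seed=seed)
            report = ec.run_protocol(
                ztable, truth_assignment(truth), config, "enrich_after_split"
            )
            accs.append(report.mean_accuracy)
        assert 0.35 <= np.mean(accs) <= 0.65

    def test_separating_feature_dominates_importance(self):
        rng = np.random.default_rng(0)
        n = 16
        idx = pd.Index([f"S{i:02d}" for i in range(n)], name="subject_id")
        diagnosis = pd.Series(["control"] * 8 + ["KOA"] * 8, index=idx)
        data = pd.DataFrame(
            {"signal": np.r_[rng.normal(-3, 0.3, 8), rng.normal(3, 0.3, 8)],
             "noise1": rng.normal(size=n), "noise2": rng.normal(size=n),
             "noise3": rng.normal(size=n)},
            index=idx,
        )
        ztable = ec.ZScoreTable(
            data=(data - data.mean()) / data.std(ddof=1),
            diagnosis=diagnosis, sex=pd.Series(["M"] * n, index=idx),
        )
        config = ec.RFProtocolConfig(n_repeats=10, seed=1)
        report = ec.run_protocol(ztable, None, config, "original_features")
        imp = report.importance_mean
        assert imp["signal"] > 0.5
        assert imp["signal"] == max(imp.values())

    def test_ev_only_uses_ev_columns(self, presets):
        table, truth = ec.generate_cohort(presets["strong-structure"].cohort)
        ztable = ec.z_score(table)
        config = ec.RFProtocolConfig(n_repeats=2, seed=0)
        report = ec.run_protocol(ztable, None, config, "ev_only")
        assert set(report.feature_names) == {
            v for v, d in ztable.descriptors.items() if d.category == "ev_marker"
        }

    def test_determinism_bit_for_bit(self, strong_setup):
        ztable, groups = strong_setup
        config = ec.RFProtocolConfig(n_repeats=3, n_replicates=50, seed=11)
        r1 = ec.run_protocol(ztable, groups, config, "enrich_after_split")
        r2 = ec.run_protocol(ztable, groups, config, "enrich_after_split")
        np.testing.assert_array_equal(r1.accuracies, r2.accuracies)
        np.testing.assert_array_equal(r1.importances, r2.importances)

    def test_unknown_protocol_error(self, strong_setup):
        ztable, groups = strong_setup
        with pytest.raises(EnrichmentError, match="unknown protocol"):
            ec.run_protocol(ztable, groups, ec.RFProtocolConfig(), "bogus")


@pytest.fixture(scope="module")
def gap_reports(presets):
    """Before/after-split protocol pairs at moderate effects (|d| = 1)."""
    out = []
    for seed in range(10):
        cfg = dataclasses.replace(
            presets["strong-structure"].cohort,
            effect_sizes=(1.0, -1.0, 1.0, -1.0, 1.0), seed=seed,
        )
        table, truth = ec.generate_cohort(cfg)
        ztable = ec.z_score(table)
        groups = truth_assignment(truth)
        config = ec.RFProtocolConfig(n_repeats=4, n_replicates=100, seed=seed)
        before = ec.run_protocol(ztable, groups, config, "enrich_before_split")
        after = ec.run_protocol(ztable, groups, config, "enrich_after_split")
        out.append((before, after))
    return out


class TestLeakageContrast:
    def test_leakage_gap(self, gap_reports):
        gaps = [b.mean_accuracy - a.mean_accuracy for b, a in gap_reports]
        assert min(gaps) >= 0.0
        assert np.mean(gaps) >= 0.15

    def test_importance_ranking_concordance(self, gap_reports):
        rhos = []
        for before, after in gap_reports:
            b = [before.importance_mean[f] for f in before.feature_names]
            a = [after.importance_mean[f] for f in before.feature_names]
            rhos.append(sps.spearmanr(b, a).statistic)
        assert np.mean(rhos) > 0.7


class TestImportanceSummary:
    def test_identical_reports_zero_dispersion(self, strong_setup):
        ztable, groups = strong_setup
        config = ec.RFProtocolConfig(n_repeats=2, n_replicates=50, seed=3)
        r = ec.run_protocol(ztable, groups, config, "enrich_before_split")
        summary = ec.feature_importance_summary([r, r])
        single = ec.feature_importance_summary([r])
        pd.testing.assert_series_equal(
            summary["importance_mean"], single["importance_mean"]
        )

    def test_order_invariance(self, strong_setup):
        ztable, groups = strong_setup
        config = ec.RFProtocolConfig(n_repeats=2, n_replicates=50, seed=3)
        r1 = ec.run_protocol(ztable, groups, config, "enrich_before_split")
        r2 = ec.run_protocol(
            ztable, groups, dataclasses.replace(config, seed=4), "enrich_before_split"
        )
        s12 = ec.feature_importance_summary([r1, r2])
        s21 = ec.feature_importance_summary([r2, r1])
        pd.testing.assert_frame_equal(s12, s21)

    def test_mean_equals_direct_average(self, strong_setup):
        ztable, groups = strong_setup
        config = ec.RFProtocolConfig(n_repeats=3, n_replicates=50, seed=5)
        r = ec.run_protocol(ztable, groups, config, "enrich_before_split")
        summary = ec.feature_importance_summary([r])
        for _, row in summary.iterrows():
            i = r.feature_names.index(row["feature"])
            assert row["importance_mean"] == pytest.approx(
                r.importances[:, i].mean(), abs=1e-12
            )

    def test_mismatched_feature_spaces_error(self, strong_setup):
        ztable, groups = strong_setup
        config = ec.RFProtocolConfig(n_repeats=2, n_replicates=20, seed=0)
        r1 = ec.run_protocol(ztable, groups, config, "enrich_before_split")
        r2 = ec.run_protocol(ztable, None, config, "ev_only")
        with pytest.raises(EnrichmentError, match="mismatched"):
            ec.feature_importance_summary([r1, r2])

    def test_importances_normalized_per_repeat(self, strong_setup):
        ztable, groups = strong_setup
        config = ec.RFProtocolConfig(n_repeats=3, n_replicates=50, seed=6)
        r = ec.run_protocol(ztable, groups, config, "enrich_before_split")
        np.testing.assert_allclose(r.importances.sum(axis=1), 1.0, atol=1e-9)
        assert (r.importances >= 0).all()
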