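"""The synthetic-data generator: planted structure, calibration, determinism."""

import numpy as np
import pytest
from scipy import stats

from borutafc.connectome import assemble_feature_table, compute_fc_matrix
from borutafc.simulate import (
    SyntheticConfig,
    Truth,
    default_network_sizes,
    generate_atlas,
    generate_clinical,
    generate_dataset,
    generate_fc_features,
    generate_time_series,
    planted_feature_table,
)

SIZES_12 = {n: 2 for n in ("DMN", "FPN", "CON", "SMN", "ON", "CN")}


def small_cfg(**kw):
    base = dict(
        seed=0, n_rois=12, network_sizes=dict(SIZES_12), n_patients=20,
        n_controls=20, n_discriminative=6, n_clinical_linked=3, effect_size=1.0,
    )
    base.update(kw)
    return SyntheticConfig(**base)


class TestAtlas:
    def test_default_shape_is_study_shaped(self):
        atlas = generate_atlas(160)
        assert atlas.n_rois == 160
        assert len(set(atlas.networks)) == 6
        assert 160 * 159 // 2 == 12720

    def test_small_atlas(self):
        atlas = generate_atlas(12, SIZES_12, seed=1)
        assert atlas.n_rois == 12
        counts = {n: atlas.networks.count(n) for n in SIZES_12}
        assert counts == SIZES_12

    def test_size_mismatch_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            generate_atlas(12, {"DMN": 2, "FPN": 2, "CON": 2, "SMN": 2, "ON": 2, "CN": 1})

    def test_proportional_partition_sums_to_R(self):
        for R in (6, 40, 80, 159, 160):
            assert sum(default_network_sizes(R).values()) == R


class TestFcFeatures:
    def test_null_effect_gives_null_t_statistics(self):
        atlas = generate_atlas(12, SIZES_12, seed=0)
        table, truth = generate_fc_features(atlas, small_cfg(effect_size=0.0,
                                                             n_patients=40, n_controls=40))
        pat = table.labels == 1
        t = stats.ttest_ind(table.features[pat][:, truth.discriminative],
                            table.features[~pat][:, truth.discriminative]).statistic
        assert np.abs(t).mean() < 2.0  # consistent with the null expectation ~0.8

    def test_planted_shift_matches_effect_size(self):
        atlas = generate_atlas(12, SIZES_12, seed=0)
        cfg = small_cfg(effect_size=1.5, n_patients=120, n_controls=120)
        table, truth = generate_fc_features(atlas, cfg)
        pat = table.labels == 1
        sigma = np.hypot(cfg.latent_strength, cfg.noise_sd)
        diff = (table.features[pat][:, truth.discriminative].mean(0)
                - table.features[~pat][:, truth.discriminative].mean(0))
        observed = np.abs(diff)
        se = sigma * np.sqrt(2 / 120)
        assert np.all(np.abs(observed - 1.5 * sigma) < 2.5 * se)

    def test_deterministic_given_seed(self):
        atlas = generate_atlas(12, SIZES_12, seed=0)
        t1, tr1 = generate_fc_features(atlas, small_cfg(seed=5))
        t2, tr2 = generate_fc_features(atlas, small_cfg(seed=5))
        assert np.array_equal(t1.features, t2.features)
        assert np.array_equal(tr1.discriminative, tr2.discriminative)

    def test_within_network_feature_correlation_elevated(self):
        atlas = generate_atlas(12, SIZES_12, seed=0)
        cfg = small_cfg(effect_size=0.0, n_patients=100, n_controls=100,
                        latent_strength=0.3)
        table, _ = generate_fc_features(atlas, cfg)
        nets = atlas.network_of

        def block(k):
            i, j = table.connection_index[k]
            return tuple(sorted((nets[i], nets[j])))

        # connections in the same network-pair block share a subject latent
        same = [k for k in range(table.n_connections) if block(k) == ("DMN", "FPN")]
        other = [k for k in range(table.n_connections) if block(k) == ("ON", "SMN")]
        c_shared = np.corrcoef(table.features[:, same[:2]].T)[0, 1]
        c_cross = np.corrcoef(
            table.features[:, [same[0], other[0]]].T
        )[0, 1]
        # expected shared-block correlation = s^2/(s^2+sd^2) ~ 0.59 here
        assert c_shared > 0.35
        assert abs(c_cross) < 0.25


class TestTimeSeries:
    def test_shared_latent_raises_correlation_monotonically(self):
        rng = np.random.default_rng(0)
        T = 300
        shared = rng.normal(size=T)
        rs = []
        for a in (0.0, 0.5, 1.0):
            x = a * shared + rng.normal(size=T)
            y = a * shared + rng.normal(size=T)
            rs.append(np.corrcoef(x, y)[0, 1])
        assert rs[0] < rs[1] < rs[2]
        assert rs[2] > 0.4

    def test_derived_fc_carries_planted_group_difference(self):
        atlas = generate_atlas(12, SIZES_12, seed=0)
        cfg = small_cfg(n_patients=30, n_controls=30, n_timepoints=170)
        ts, truth = generate_time_series(atlas, cfg)
        labels = {t.subject_id: (1 if t.subject_id.startswith("ASD") else -1) for t in ts}
        table = assemble_feature_table(ts, atlas, labels)
        pat = table.labels == 1
        t_planted = np.abs(
            stats.ttest_ind(table.features[pat][:, truth.discriminative],
                            table.features[~pat][:, truth.discriminative]).statistic
        )
        others = np.setdiff1d(np.arange(table.n_connections), truth.discriminative)
        t_null = np.abs(
            stats.ttest_ind(table.features[pat][:, others],
                            table.features[~pat][:, others]).statistic
        )
        assert t_planted.mean() > 3 * t_null.mean()

    def test_fixed_seed_identical_series(self):
        atlas = generate_atlas(12, SIZES_12, seed=0)
        cfg = small_cfg(n_patients=3, n_controls=3, n_timepoints=60)
        ts1, _ = generate_time_series(atlas, cfg)
        ts2, _ = generate_time_series(atlas, cfg)
        assert np.array_equal(ts1[0].data, ts2[0].data)


class TestClinical:
    def test_null_linkage_gives_small_correlations(self):
        atlas = generate_atlas(12, SIZES_12, seed=0)
        cfg = small_cfg(r_clin=0.0, n_patients=48, n_controls=10)
        table, truth = generate_fc_features(atlas, cfg)
        clin = generate_clinical(table, truth, cfg)
        pat = table.labels == 1
        u = table.features[pat][:, truth.clinical_linked].mean(1)
        rs = [np.corrcoef(u, clin[c])[0, 1] for c in clin.columns if c != "subject_id"]
        assert np.abs(rs).max() < 0.45  # 95% bound ~2/sqrt(48) plus slack

    def test_strong_linkage_recovered_without_rounding(self):
        ok = 0
        for seed in range(20):
            atlas = generate_atlas(12, SIZES_12, seed=seed)
            cfg = small_cfg(seed=seed, r_clin=0.9, round_clinical=False,
                            n_patients=48, n_controls=10)
            table, truth = generate_fc_features(atlas, cfg)
            clin = generate_clinical(table, truth, cfg)
            pat = table.labels == 1
            Z = table.features[pat][:, truth.clinical_linked]
            u = ((Z - Z.mean(0)) / Z.std(0)).mean(1)
            r = np.corrcoef(u, clin["ADOS_total"])[0, 1]
            ok += int(abs(r - 0.9) <= 0.1)
        assert ok >= 18  # >= 90% of seeds

    def test_rounded_scales_stay_in_range(self):
        atlas = generate_atlas(12, SIZES_12, seed=0)
        cfg = small_cfg(n_patients=48, n_controls=10)
        table, truth = generate_fc_features(atlas, cfg)
        clin = generate_clinical(table, truth, cfg)
        assert clin["ADOS_total"].between(0, 24).all()
        assert clin["ADOS_communication"].between(0, 10).all()
        assert np.allclose(clin["ADI_R_social"], np.round(clin["ADI_R_social"]))

    def test_deterministic(self):
        atlas = generate_atlas(12, SIZES_12, seed=0)
        cfg = small_cfg()
        table, truth = generate_fc_features(atlas, cfg)
        c1 = generate_clinical(table, truth, cfg)
        c2 = generate_clinical(table, truth, cfg)
        assert c1.equals(c2)


class TestPlantedTable:
    def test_shape_and_truth(self):
        table, planted = planted_feature_table(48, 50, 300, 20, 1.5, seed=0)
        assert table.features.shape == (98, 300)
        assert planted.size == 20
        pat = table.labels == 1
        diff = table.features[pat][:, planted].mean(0) - table.features[~pat][:, planted].mean(0)
        assert np.all(np.abs(diff - 1.5) < 0.75)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SyntheticConfig(n_rois=12, network_sizes=SIZES_12, n_discriminative=100)
        with pytest.raises(ValueError):
            SyntheticConfig(r_clin=1.5)


class TestEndToEndRecovery:
    def test_pipeline_recovers_planted_structure(self):
        """Selection finds the planted set (high recall, few false positives)
        and the classifier separates the groups on the confirmed features."""
        from borutafc.boruta import BorutaConfig, run_boruta
        from borutafc.classify import SvmConfig, loocv_classify

        atlas = generate_atlas(12, SIZES_12, seed=3)
        cfg = small_cfg(seed=3, effect_size=1.5, n_patients=30, n_controls=30,
                        n_discriminative=8)
        table, truth = generate_fc_features(atlas, cfg)
        res = run_boruta(table, BorutaConfig(n_trees=100, max_iter=40, seed=3))
        recall = np.isin(truth.discriminative, res.confirmed_index).mean()
        n_false = np.setdiff1d(res.confirmed_index, truth.discriminative).size
        assert recall >= 0.8
        assert n_false <= max(1, 0.02 * (table.n_connections - 8) + 1)
        rep = loocv_classify(table.restrict(res.confirmed_index), SvmConfig())
        assert rep.accuracy >= 0.85

    def test_two_generation_paths_statistically_consistent(self):
        """Group-difference t statistics on planted connections agree between
        the direct-feature path and the time-series path at matched settings."""
        atlas = generate_atlas(12, SIZES_12, seed=1)
        cfg = small_cfg(seed=1, n_patients=60, n_controls=60, effect_size=1.2,
                        n_timepoints=170)
        table_f, truth = generate_fc_features(atlas, cfg)
        ts, _ = generate_time_series(atlas, cfg, truth=truth)
        labels = {t.subject_id: (1 if t.subject_id.startswith("ASD") else -1) for t in ts}
        table_t = assemble_feature_table(ts, atlas, labels)

        def tstats(tbl):
            pat = tbl.labels == 1
            return stats.ttest_ind(
                tbl.features[pat][:, truth.discriminative],
                tbl.features[~pat][:, truth.discriminative],
            ).statistic

        # planted connections stand out from the null background on both paths
        tf, tt = tstats(table_f), tstats(table_t)
        assert np.abs(tf).mean() > 4
        assert np.abs(tt).mean() > 4
        assert np.mean(np.sign(tf) == np.sign(tt)) >= 0.8
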