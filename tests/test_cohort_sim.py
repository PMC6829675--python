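"""Synthetic cohort generator: determinism, planted-effect realization,
type-I calibration, episode structure, motion and QC hooks."""

import numpy as np
import pytest

from connfuse import (
    CohortConfig,
    EdgeIndex,
    functional_network,
    simulate_cohort,
    simulate_motion,
)
from connfuse.cohort_sim import (
    DEFAULT_PLANTED_EDGES,
    MotionModel,
    cohort_arrays,
    null_config,
    read_cohort,
    write_cohort,
)
from connfuse.group_stats import pooled_ttest
from connfuse.ts_qc import framewise_displacement
from tests.conftest import small_planted_config


def _raw_planted_z(subjects, config, idx):
    pos = config.planted_positions(idx)
    z = np.vstack([functional_network(s.roi_timeseries, idx)[pos] for s in subjects])
    labels = np.array([s.group for s in subjects])
    return z, labels


class TestDeterminism:
    def test_identical_seed_is_bit_identical(self):
        cfg = small_planted_config(seed=42)
        a = simulate_cohort(cfg)
        b = simulate_cohort(small_planted_config(seed=42))
        for sa, sb in zip(a, b):
            assert sa.subject_id == sb.subject_id and sa.episode == sb.episode
            assert np.array_equal(sa.roi_timeseries, sb.roi_timeseries)
            assert np.array_equal(sa.roi_volumes, sb.roi_volumes)
            assert np.array_equal(sa.motion_params, sb.motion_params)
            assert sa.covariates == sb.covariates

    def test_different_seed_differs(self):
        a = simulate_cohort(small_planted_config(seed=1))
        b = simulate_cohort(small_planted_config(seed=2))
        assert not np.array_equal(a[0].roi_timeseries, b[0].roi_timeseries)


class TestDefaultCohort:
    @pytest.fixture(scope="class")
    @staticmethod
    def default_cohort():
        cfg = CohortConfig(seed=1)
        return cfg, simulate_cohort(cfg)

    def test_group_sizes_and_labels(self, default_cohort):
        _, subs = default_cohort
        assert sum(s.group == 1 for s in subs) == 83
        assert sum(s.group == -1 for s in subs) == 94

    def test_episode_counts(self, default_cohort):
        _, subs = default_cohort
        eps = [s.episode for s in subs if s.group == 1]
        assert eps.count("depressive") == 35
        assert eps.count("manic") == 19
        assert eps.count("remission") == 29
        assert all(s.episode is None for s in subs if s.group == -1)

    def test_planted_edge_group_means_match_targets(self):
        # covariate slopes off so the raw group means isolate the planted
        # targets; averaged over replicates to separate calibration bias
        # from single-draw noise
        from connfuse.cohort_sim import CovariateModel

        no_slopes = dict(
            edge_slopes={"age": 0.0, "sex": 0.0, "education": 0.0},
            volume_slopes={"age": 0.0, "sex": 0.0, "education": 0.0},
        )
        idx = EdgeIndex(90)
        mean_a, mean_b = [], []
        for seed in range(8):
            cfg = CohortConfig(seed=seed, covariate_model=CovariateModel(**no_slopes))
            subs = simulate_cohort(cfg)
            z, labels = _raw_planted_z(subs, cfg, idx)
            mean_a.append(z[labels > 0].mean(0))
            mean_b.append(z[labels <= 0].mean(0))
        targets_a = [e[2] for e in DEFAULT_PLANTED_EDGES]
        targets_b = [e[3] for e in DEFAULT_PLANTED_EDGES]
        assert np.abs(np.mean(mean_a, axis=0) - targets_a).max() < 0.03
        assert np.abs(np.mean(mean_b, axis=0) - targets_b).max() < 0.03

    def test_episode_summation_score_means(self, default_cohort):
        cfg, subs = default_cohort
        idx = EdgeIndex(90)
        z, labels = _raw_planted_z(subs, cfg, idx)
        score = z.sum(axis=1)
        episodes = np.array([s.episode or "control" for s in subs])
        # configured sum-score targets: patient mean -0.38 plus episode shift
        for episode, target in (("depressive", -0.55), ("manic", 0.046),
                                ("remission", -0.46), ("control", 0.32)):
            got = score[episodes == episode].mean()
            assert got == pytest.approx(target, abs=0.15)

    def test_clinical_scores_respect_episode_definitions(self, default_cohort):
        _, subs = default_cohort
        for s in subs:
            if s.group != 1:
                assert s.clinical_scores == {}
                continue
            hamd, ymrs = s.clinical_scores["HAMD"], s.clinical_scores["YMRS"]
            if s.episode == "depressive":
                assert hamd >= 17 and ymrs < 12
            elif s.episode == "manic":
                assert ymrs >= 12 and hamd < 17
            else:
                assert hamd < 17 and ymrs < 12


class TestCalibration:
    def test_null_cohorts_reject_at_nominal_rate(self):
        # pooled over cohorts: >= 4000 null edge t-tests at alpha = 0.05
        hits, total = 0, 0
        for seed in range(24):
            cfg = null_config(
                n_group_A=30, n_group_B=30, n_regions=20, n_volumes=80, seed=seed
            )
            subs = simulate_cohort(cfg)
            idx = EdgeIndex(20)
            feats = np.vstack(
                [functional_network(s.roi_timeseries, idx) for s in subs]
            )
            labels = np.array([s.group for s in subs])
            _, p, *_ = pooled_ttest(feats, labels)
            hits += int((p < 0.05).sum())
            total += p.size
        rate = hits / total
        assert 0.04 <= rate <= 0.06

    def test_planted_difference_converges_at_large_n(self):
        # grand mean over planted edges and seeds at n = 500/500
        from connfuse.cohort_sim import CovariateModel

        no_confounds = CovariateModel(
            edge_slopes={"age": 0.0, "sex": 0.0, "education": 0.0},
            volume_slopes={"age": 0.0, "sex": 0.0, "education": 0.0},
        )
        diffs = []
        # well-spread seeds: the per-cohort latent draw has SE ~ 0.012, so
        # the +/-0.01 check needs averaging over replicates
        for seed in range(0, 12 * 97, 97):
            cfg = small_planted_config(
                seed=seed, n_group_A=500, n_group_B=500, n_volumes=150,
                episode_counts={}, episode_effect={},
                covariate_model=no_confounds,
            )
            subs = simulate_cohort(cfg)
            idx = EdgeIndex(cfg.n_regions)
            z, labels = _raw_planted_z(subs, cfg, idx)
            diffs.append(z[labels > 0].mean(0) - z[labels <= 0].mean(0))
        target = -0.5  # mean_z_A - mean_z_B for every planted edge
        assert np.mean(diffs) == pytest.approx(target, abs=0.01)


class TestMotion:
    def test_no_drift_no_spikes_means_zero_fd(self):
        cfg = small_planted_config(
            motion_model=MotionModel(fd_scale={"A": 0.0, "B": 0.0}, spike_prob=0.0)
        )
        motion = simulate_motion(cfg, 0)
        assert np.allclose(motion, 0.0)
        assert np.allclose(framewise_displacement(motion), 0.0)

    def test_mean_fd_tracks_group_scale(self):
        cfg = CohortConfig(n_group_A=10, n_group_B=10, n_volumes=250,
                           episode_counts={}, episode_effect={}, seed=0)
        fd_a = np.mean([framewise_displacement(simulate_motion(cfg, i)).mean()
                        for i in range(10)])
        fd_b = np.mean([framewise_displacement(simulate_motion(cfg, 10 + i)).mean()
                        for i in range(10)])
        assert fd_a == pytest.approx(0.15, rel=0.25)
        assert fd_b == pytest.approx(0.13, rel=0.25)

    def test_spikes_exceed_scrub_threshold(self):
        cfg = small_planted_config(
            seed=5,
            motion_model=MotionModel(
                fd_scale={"A": 0.05, "B": 0.05}, spike_prob=0.1, spike_mm=1.0
            ),
        )
        motion = simulate_motion(cfg, 0)
        fd = framewise_displacement(motion)
        assert (fd > 0.5).sum() > 0

    def test_heavy_spiking_triggers_downstream_exclusion(self):
        from connfuse.ts_qc import preprocess_subject

        cfg = small_planted_config(
            seed=5, n_volumes=250,
            motion_model=MotionModel(
                fd_scale={"A": 0.1, "B": 0.1}, spike_prob=0.4, spike_mm=1.0
            ),
        )
        s = simulate_cohort(cfg)[0]
        res = preprocess_subject(
            s.roi_timeseries, s.motion_params, s.nuisance_signals, n_discard=10
        )
        assert res.report.n_scrubbed > 48
        assert res.report.excluded


class TestValidation:
    def test_episode_counts_must_sum_to_patients(self):
        with pytest.raises(ValueError, match="episode counts"):
            small_planted_config(episode_counts={"depressive": 3})

    def test_infeasible_structural_target_rejected(self):
        with pytest.raises(ValueError, match="infeasible"):
            small_planted_config(structural_effect=((3, 7, 1.2, 0.5),))

    def test_planted_edge_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="out of range"):
            small_planted_config(planted_edges=((3, 99, 0.1, 0.2, 0.2),))


class TestCohortIO:
    def test_write_read_roundtrip(self, tmp_path):
        cfg = small_planted_config(n_group_A=6, n_group_B=6, n_volumes=40,
                                   episode_counts={"depressive": 3, "remission": 3})
        subs = simulate_cohort(cfg)
        manifest = write_cohort(subs, tmp_path)
        back = read_cohort(manifest)
        assert len(back) == len(subs)
        for sa, sb in zip(subs, back):
            assert sa.subject_id == sb.subject_id
            assert sa.group == sb.group and sa.episode == sb.episode
            assert np.allclose(sa.roi_timeseries, sb.roi_timeseries)
            assert np.allclose(sa.motion_params, sb.motion_params)
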