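"""Cohort generator: planted structure, determinism, ground truth."""

import hashlib
from pathlib import Path

import numpy as np
import pytest

from modcog.community import Partition, louvain_once
from modcog.connectivity import correlation_matrix, prepare_for_modularity
from modcog.errors import ParameterError
from modcog.preprocess import compute_fd
from modcog.synthetic_data import (
    TASK_NAMES,
    CohortSpec,
    block_covariance,
    make_cohort,
    module_assignment,
    simulate_motion,
    simulate_task_scores,
    simulate_timeseries,
    write_cohort,
)


def offdiag_corr(values):
    c = np.corrcoef(values, rowvar=False)
    return c[~np.eye(c.shape[0], dtype=bool)]


class TestTimeseries:
    def test_independent_nodes_have_vanishing_correlation(self):
        ts = simulate_timeseries(module_assignment(6, 2), 5000, 0.0, 0.0, seed=0)
        assert np.abs(offdiag_corr(ts.values)).mean() < 0.02

    def test_within_module_correlation_matches_target(self):
        assign = module_assignment(6, 2)
        ts = simulate_timeseries(assign, 10000, 0.6, 0.1, seed=42)
        c = np.corrcoef(ts.values, rowvar=False)
        same = assign[:, None] == assign[None, :]
        off = ~np.eye(6, dtype=bool)
        assert c[same & off].mean() == pytest.approx(0.6, abs=0.05)
        assert c[~same].mean() == pytest.approx(0.1, abs=0.05)

    def test_single_node_degenerates_gracefully(self):
        ts = simulate_timeseries(np.zeros(1, dtype=int), 50, 0.5, 0.1, seed=1)
        assert ts.values.shape == (50, 1)

    def test_non_positive_definite_covariance_names_parameters(self):
        with pytest.raises(ParameterError, match="r_within=0.0.*r_between=0.9"):
            block_covariance(module_assignment(6, 2), 0.0, 0.9)

    def test_remainder_nodes_assigned_to_last_module(self):
        assign = module_assignment(7, 3)
        assert np.bincount(assign).tolist() == [2, 2, 3]


class TestMotion:
    def test_no_spikes_keeps_fd_below_baseline_bound(self):
        mot, spikes = simulate_motion(180, 0.0, seed=0)
        fd = compute_fd(mot)
        assert spikes.size == 0
        assert fd.max() < 0.1

    def test_saturated_spikes_flag_every_interior_frame(self):
        mot, spikes = simulate_motion(60, 1.0, spike_magnitude_mm=2.0, seed=0)
        fd = compute_fd(mot)
        assert np.all(fd[1:] > 0.5)
        assert set(spikes) == set(range(1, 60))

    def test_flagged_frames_equal_ground_truth_spikes(self):
        mot, spikes = simulate_motion(180, 0.05, spike_magnitude_mm=2.0, seed=7)
        fd = compute_fd(mot)
        flagged = set(np.flatnonzero(fd > 0.5))
        assert flagged == set(spikes)

    def test_negative_magnitude_rejected(self):
        with pytest.raises(ParameterError):
            simulate_motion(100, 0.1, spike_magnitude_mm=-1.0, seed=0)


class TestTaskScores:
    def test_null_cohort_has_centered_control_residuals(self):
        # all effects zero: AE post scores follow the control law, so the
        # group difference of post-on-pre residuals is centered on zero
        from modcog.discriminant import TaskTable, control_residualize

        diffs = []
        for seed in range(10):
            spec = CohortSpec(
                n_per_group=60, task_effect_sizes=(0.0,) * 7, seed=seed
            )
            pre, post = simulate_task_scores(spec)
            rt = control_residualize(
                TaskTable(groups=spec.groups, pre=pre, post=post)
            )
            is_ae = rt.groups == "AE"
            diffs.append(
                rt.residuals[is_ae].mean() - rt.residuals[~is_ae].mean()
            )
        mean_std = np.array(diffs).mean(axis=0) / np.array(diffs).std(axis=0)
        assert np.abs(mean_std).max() < 1.5  # ~z-scale over 10 replicates

    def test_perfect_autocorrelation_copies_pre_to_post(self):
        spec = CohortSpec(
            n_per_group=10,
            task_effect_sizes=(0.0,) * 7,
            prepost_autocorrelation=1.0,
            seed=3,
        )
        pre, post = simulate_task_scores(spec)
        np.testing.assert_allclose(pre.values, post.values, atol=1e-10)

    def test_invalid_intercorrelation_rejected(self):
        with pytest.raises(ParameterError):
            CohortSpec(task_intercorrelation=1.0)
        with pytest.raises(ParameterError):
            CohortSpec(task_intercorrelation=-0.1)

    def test_planted_effect_appears_in_ae_post_only(self):
        eff = tuple(1.0 if t == "two_back_rt" else 0.0 for t in TASK_NAMES)
        spec = CohortSpec(n_per_group=400, task_effect_sizes=eff, seed=5)
        pre, post = simulate_task_scores(spec)
        is_ae = spec.groups == "AE"
        sd = pre["two_back_rt"].std()
        gap_post = post.loc[is_ae, "two_back_rt"].mean() - post.loc[~is_ae, "two_back_rt"].mean()
        gap_pre = pre.loc[is_ae, "two_back_rt"].mean() - pre.loc[~is_ae, "two_back_rt"].mean()
        assert gap_post / sd == pytest.approx(1.0, abs=0.25)
        assert abs(gap_pre / sd) < 0.25


class TestCohortAssembly:
    @pytest.fixture
    def tiny_spec(self):
        return CohortSpec(
            n_per_group=2, n_nodes=12, n_modules=3, n_frames=40, seed=9
        )

    def test_same_seed_gives_byte_identical_files(self, tiny_spec, tmp_path):
        def digest(root: Path) -> dict:
            return {
                p.relative_to(root).as_posix(): hashlib.sha256(p.read_bytes()).hexdigest()
                for p in sorted(root.rglob("*"))
                if p.is_file()
            }

        d1 = write_cohort(make_cohort(tiny_spec), tmp_path / "a")
        d2 = write_cohort(make_cohort(tiny_spec), tmp_path / "b")
        assert digest(d1) == digest(d2)

    def test_subject_streams_survive_cohort_resizing(self, tiny_spec):
        big = CohortSpec(**{**tiny_spec.__dict__, "n_per_group": 3})
        c_small = make_cohort(tiny_spec)
        c_big = make_cohort(big)
        key = ("sub-AE-001", "pre")
        np.testing.assert_array_equal(
            c_small.timeseries[key].values, c_big.timeseries[key].values
        )

    def test_ae_post_gets_the_covariance_increment(self):
        spec = CohortSpec(
            n_per_group=1,
            n_nodes=12,
            n_modules=2,
            n_frames=4000,
            r_within_pre=0.3,
            delta_r_within_post_AE=0.3,
            seed=21,
        )
        cohort = make_cohort(spec)
        assign = cohort.assignment
        same = (assign[:, None] == assign[None, :]) & ~np.eye(12, dtype=bool)

        def within(key):
            c = np.corrcoef(cohort.timeseries[key].values, rowvar=False)
            return c[same].mean()

        assert within(("sub-AE-001", "post")) == pytest.approx(0.6, abs=0.06)
        assert within(("sub-AE-001", "pre")) == pytest.approx(0.3, abs=0.06)
        assert within(("sub-UAA-001", "post")) == pytest.approx(0.3, abs=0.06)

    def test_ground_truth_records_planted_structure(self, tiny_spec):
        cohort = make_cohort(tiny_spec)
        gt = cohort.ground_truth
        assert gt["module_assignment"] == cohort.assignment.tolist()
        assert len(gt["spike_frames"]) == 8  # 4 subjects x 2 sessions


class TestPlantedStructureRecovery:
    def test_louvain_recovers_planted_modules_at_strong_contrast(self):
        # contrast r_within - r_between >= 0.4 and n_frames >= 500:
        # recovery in at least 95% of stochastic runs
        assign = module_assignment(24, 4)
        ts = simulate_timeseries(assign, 600, 0.5, 0.1, seed=11)
        cm = prepare_for_modularity(correlation_matrix(ts))
        planted = Partition(assign)
        hits = sum(louvain_once(cm, 1.0, seed=s)[0] == planted for s in range(40))
        assert hits >= 38
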