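"""Study/trial machinery: fold partitions, trial scoring, search contracts."""

from __future__ import annotations

import math

import numpy as np
import pytest

from finmark.annotations import ImageAnnotation, Landmark, LandmarkDataset
from finmark.hpo import (
    DEFAULT_RANGES,
    ParamRange,
    SearchRanges,
    StudyResult,
    TrialRecord,
    deviation_cdf,
    finalize_model,
    fold_seed,
    kfold_split,
    run_study,
    run_trial,
)
from finmark.shape_model import mean_deviation, train_predictor

from .conftest import TINY_HP, TINY_RANGES


def _dummy_dataset(n):
    return LandmarkDataset(
        [
            ImageAnnotation(f"i{i}.png", (Landmark(0, 1, 1),), width=10, height=10)
            for i in range(n)
        ]
    )


class TestKFoldSplit:
    def test_balanced_partition_n50_k5(self):
        pairs = kfold_split(_dummy_dataset(50), k=5, seed=0)
        assert [len(val) for _, val in pairs] == [10] * 5
        assert [len(train) for train, _ in pairs] == [40] * 5

    def test_remainder_distribution_n52_k5(self):
        pairs = kfold_split(_dummy_dataset(52), k=5, seed=0)
        assert sorted(len(val) for _, val in pairs) == [10, 10, 10, 11, 11]

    def test_validation_folds_partition_dataset(self):
        ds = _dummy_dataset(23)
        pairs = kfold_split(ds, k=4, seed=3)
        all_val: list[str] = []
        for train, val in pairs:
            val_paths = set(val.file_paths())
            train_paths = set(train.file_paths())
            assert not val_paths & train_paths  # no leak
            assert val_paths | train_paths == set(ds.file_paths())
            all_val.extend(val.file_paths())
        assert sorted(all_val) == sorted(ds.file_paths())  # disjoint union

    def test_deterministic_given_seed(self):
        ds = _dummy_dataset(20)
        a = kfold_split(ds, k=5, seed=7)
        b = kfold_split(ds, k=5, seed=7)
        assert [v.file_paths() for _, v in a] == [v.file_paths() for _, v in b]
        c = kfold_split(ds, k=5, seed=8)
        assert [v.file_paths() for _, v in a] != [v.file_paths() for _, v in c]

    def test_k_larger_than_dataset_rejected(self):
        with pytest.raises(ValueError):
            kfold_split(_dummy_dataset(3), k=5, seed=0)

    def test_k_below_two_rejected(self):
        with pytest.raises(ValueError):
            kfold_split(_dummy_dataset(5), k=1, seed=0)


class TestSearchRanges:
    def test_sampled_hyperparameters_lie_in_ranges(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            hp = DEFAULT_RANGES.sample(rng)
            assert DEFAULT_RANGES.contains(hp)

    def test_invalid_range_rejected(self):
        with pytest.raises(ValueError):
            ParamRange(5, 2)
        with pytest.raises(ValueError):
            ParamRange(0, 1, scale="log")

    def test_dict_round_trip(self):
        assert SearchRanges.from_dict(TINY_RANGES.to_dict()) == TINY_RANGES


class TestRunTrial:
    def test_mean_is_arithmetic_mean_of_folds(self, clean_small):
        out_dir, dataset = clean_small
        rec = run_trial(dataset, TINY_HP, k=3, seed=1, trial_index=0, image_root=out_dir)
        assert len(rec.fold_deviations) == 3
        assert rec.mean_deviation == pytest.approx(float(np.mean(rec.fold_deviations)))
        assert not rec.failed

    def test_arithmetic_mean_example(self):
        rec = TrialRecord(0, TINY_HP, [4, 5, 6, 5, 5], float(np.mean([4, 5, 6, 5, 5])))
        assert rec.mean_deviation == 5.0

    def test_constant_dataset_near_zero(self, tmp_path):
        from finmark.fixtures import FixtureParams, generate_dataset

        params = FixtureParams(seed=2, translation_jitter=0.0, noise_sigma=0.0,
                               body_length_px=(180, 180))
        out, ds = generate_dataset(6, params, tmp_path / "const")
        rec = run_trial(ds, TINY_HP, k=3, seed=0, image_root=out)
        assert rec.mean_deviation < 0.001 * math.hypot(400, 300)

    def test_matches_independent_fold_loop(self, clean_small):
        # Oracle equivalence: an externally scripted loop over the same
        # folds and seeds reproduces the trial score exactly.
        out_dir, dataset = clean_small
        k, seed, trial_index = 3, 4, 2
        rec = run_trial(dataset, TINY_HP, k=k, seed=seed, trial_index=trial_index,
                        image_root=out_dir)
        expected = []
        for fold, (train, val) in enumerate(kfold_split(dataset, k, seed)):
            model = train_predictor(train, TINY_HP, fold_seed(seed, trial_index, fold),
                                    image_root=out_dir)
            expected.append(mean_deviation(model, val, image_root=out_dir))
        assert rec.fold_deviations == pytest.approx(expected)
        assert rec.mean_deviation == pytest.approx(float(np.mean(expected)))

    def test_training_failure_marks_trial_failed(self):
        ds = _dummy_dataset(6)  # images do not exist on disk
        rec = run_trial(ds, TINY_HP, k=2, seed=0)
        assert rec.failed
        assert math.isinf(rec.mean_deviation)
        assert rec.error is not None


class TestRunStudy:
    def test_single_trial_best_index_zero(self, clean_small):
        out_dir, dataset = clean_small
        study = run_study(dataset, 1, ranges=TINY_RANGES, k=2, seed=0,
                          image_root=out_dir)
        assert study.best_index == 0

    def test_running_minimum_non_increasing_and_hp_in_range(self, clean_small):
        out_dir, dataset = clean_small
        study = run_study(dataset, 4, ranges=TINY_RANGES, k=2, seed=1,
                          image_root=out_dir)
        rm = study.running_minimum()
        assert all(a >= b for a, b in zip(rm, rm[1:]))
        assert rm[-1] == study.best_trial.mean_deviation
        for trial in study.trials:
            assert TINY_RANGES.contains(trial.hyperparameters)

    def test_best_index_is_argmin_with_tie_to_lowest(self):
        trials = [
            TrialRecord(0, TINY_HP, [3.0], 3.0),
            TrialRecord(1, TINY_HP, [2.0], 2.0),
            TrialRecord(2, TINY_HP, [2.0], 2.0),
        ]
        study = StudyResult(trials=trials, k=1, seed=0, ranges=TINY_RANGES)
        assert study.best_index == 1

    def test_all_failed_raises(self):
        ds = _dummy_dataset(6)
        with pytest.raises(ValueError, match="failed"):
            run_study(ds, 2, ranges=TINY_RANGES, k=2, seed=0)

    def test_random_sampler_reproducible(self, clean_small):
        out_dir, dataset = clean_small
        a = run_study(dataset, 3, ranges=TINY_RANGES, k=2, seed=5, sampler="random",
                      image_root=out_dir)
        b = run_study(dataset, 3, ranges=TINY_RANGES, k=2, seed=5, sampler="random",
                      image_root=out_dir)
        assert [t.hyperparameters for t in a.trials] == [t.hyperparameters for t in b.trials]
        assert [t.mean_deviation for t in a.trials] == [t.mean_deviation for t in b.trials]

    def test_adaptive_sampler_runs_and_stays_in_range(self, clean_small):
        out_dir, dataset = clean_small
        study = run_study(dataset, 5, ranges=TINY_RANGES, k=2, seed=2,
                          sampler="adaptive", image_root=out_dir)
        assert len(study.trials) == 5
        for trial in study.trials:
            assert TINY_RANGES.contains(trial.hyperparameters)

    def test_unknown_sampler_rejected(self, clean_small):
        out_dir, dataset = clean_small
        with pytest.raises(ValueError):
            run_study(dataset, 4, ranges=TINY_RANGES, k=2, seed=0,
                      sampler="genetic", image_root=out_dir)


class TestStudySerialization:
    def test_json_round_trip_preserves_best_hyperparameters(self, tmp_path):
        trials = [
            TrialRecord(0, TINY_HP, [3.0, 4.0], 3.5),
            TrialRecord(1, DEFAULT_RANGES.sample(np.random.default_rng(0)), [1.0, 2.0], 1.5),
            TrialRecord(2, TINY_HP, [], math.inf, error="boom"),
        ]
        study = StudyResult(trials=trials, k=2, seed=9, ranges=TINY_RANGES,
                            sampler="adaptive")
        path = tmp_path / "study.json"
        study.to_json(path)
        loaded = StudyResult.from_json(path)
        assert loaded.best_index == study.best_index
        assert loaded.best_trial.hyperparameters == study.best_trial.hyperparameters
        assert loaded.k == 2 and loaded.seed == 9 and loaded.sampler == "adaptive"
        assert loaded.trials[2].failed


class TestFinalizeModel:
    def test_uses_best_trial_hyperparameters_and_records_provenance(self, clean_small):
        out_dir, dataset = clean_small
        study = run_study(dataset, 2, ranges=TINY_RANGES, k=2, seed=3,
                          image_root=out_dir)
        model = finalize_model(dataset, study, seed=3, image_root=out_dir)
        assert model.hyperparameters == study.best_trial.hyperparameters
        assert model.provenance["best_trial_index"] == study.best_trial.trial_index
        assert model.provenance["best_cv_deviation_px"] == study.best_trial.mean_deviation

    def test_finalized_model_within_sanity_band_of_cv_score(self, clean50):
        # Retraining on the full dataset should not be much worse than the
        # cross-validated estimate: held-out deviation <= 1.5x the best
        # trial's CV score.
        out_dir, dataset = clean50
        train_set = dataset.subset(range(30))
        held_out = dataset.subset(range(30, 50))
        study = run_study(train_set, 3, ranges=TINY_RANGES, k=3, seed=12,
                          image_root=out_dir)
        model = finalize_model(train_set, study, seed=12, image_root=out_dir)
        dev = mean_deviation(model, held_out, image_root=out_dir)
        assert dev <= 1.5 * study.best_trial.mean_deviation


class TestDeviationCdf:
    def test_counting_example(self):
        trials = [TrialRecord(i, TINY_HP, [s], float(s)) for i, s in enumerate([1, 2, 3, 4])]
        cdf = deviation_cdf(trials, normalizer=100.0)  # scores become 1..4%
        assert cdf(2.0) == 0.5

    def test_bounds(self):
        trials = [TrialRecord(i, TINY_HP, [s], float(s)) for i, s in enumerate([2, 5, 9])]
        cdf = deviation_cdf(trials, normalizer=100.0)
        assert cdf(1.9) == 0.0
        assert cdf(9.0) == 1.0
        assert cdf(100.0) == 1.0

    def test_monotone_non_decreasing(self):
        rng = np.random.default_rng(1)
        scores = rng.uniform(0.5, 20, size=25)
        trials = [TrialRecord(i, TINY_HP, [s], float(s)) for i, s in enumerate(scores)]
        cdf = deviation_cdf(trials, normalizer=500.0)
        xs = np.linspace(0, 5, 101)
        vals = [cdf(x) for x in xs]
        assert all(a <= b for a, b in zip(vals, vals[1:]))

    def test_failed_trials_excluded(self):
        trials = [
            TrialRecord(0, TINY_HP, [2.0], 2.0),
            TrialRecord(1, TINY_HP, [], math.inf, error="x"),
        ]
        cdf = deviation_cdf(trials, normalizer=100.0)
        assert cdf(2.0) == 1.0

    def test_no_successful_trials_raises(self):
        trials = [TrialRecord(0, TINY_HP, [], math.inf, error="x")]
        with pytest.raises(ValueError):
            deviation_cdf(trials, normalizer=100.0)

    def test_larger_training_size_majorizes_at_one_percent(self, tmp_path):
        # Statistical ordering over 3 seeds: a study on more fixtures has
        # at least the probability of reaching 1% deviation that a study
        # on fewer fixtures has.
        from finmark.fixtures import FixtureParams, generate_dataset

        diag = math.hypot(400, 300)
        probs = {16: [], 48: []}
        for seed in range(3):
            out, ds = generate_dataset(
                48, FixtureParams(seed=100 + seed), tmp_path / f"cdf{seed}"
            )
            for size in (16, 48):
                study = run_study(ds.subset(range(size)), 5, ranges=TINY_RANGES,
                                  k=2, seed=seed, image_root=out)
                cdf = deviation_cdf(study.trials, normalizer=diag)
                probs[size].append(cdf(1.0))
        assert float(np.mean(probs[48])) >= float(np.mean(probs[16]))
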