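"""Split scheme, grid search, fit/evaluate and aggregation contracts."""

import numpy as np
import pandas as pd
import pytest

from phasesleep.classify import (
    ClassifierConfig,
    ClassifierRun,
    aggregate,
    compare_metrics,
    fit_evaluate,
    grid_search,
    make_splits,
    run_classification,
)

STAGES = ("W", "N1", "N2", "N3")


def synthetic_features(rng, n_subjects=8, epochs_per_stage=8, n_features=12,
                       separation=3.0):
    """Cheap stand-in feature table: class means separated by ``separation``."""
    rows = []
    for s in range(n_subjects):
        for gi, stage in enumerate(STAGES):
            for e in range(epochs_per_stage):
                x = rng.standard_normal(n_features)
                x[:4] += separation * gi
                rows.append({"subject": f"S{s:02d}", "stage": stage, "epoch": e,
                             **{f"f{k}": x[k] for k in range(n_features)}})
    return pd.DataFrame(rows)


ONE_COMBO = ClassifierConfig(grid_mode="reduced", reduced_grid=((0.1, 50, 3),))


class TestMakeSplits:
    def test_reference_scheme_30_splits_11_3(self):
        subjects = [f"S{i:02d}" for i in range(14)]
        scheme = make_splits(subjects, n_splits=30, test_n=3, seed=0)
        assert scheme.n_splits == 30
        for train, test in scheme.splits:
            assert len(train) == 11 and len(test) == 3
            assert set(train) | set(test) == set(subjects)
            assert not set(train) & set(test)
        assert len({tuple(sorted(t)) for _, t in scheme.splits}) == 30

    def test_exhaustive_leave_one_out(self):
        subjects = ["a", "b", "c", "d"]
        scheme = make_splits(subjects, n_splits=4, test_n=1, seed=1)
        test_sets = {t for _, (t,) in scheme.splits}
        assert test_sets == set(subjects)

    def test_determinism(self):
        subjects = [f"S{i}" for i in range(14)]
        a = make_splits(subjects, 30, 3, seed=7)
        b = make_splits(subjects, 30, 3, seed=7)
        assert a.splits == b.splits

    def test_too_many_splits_rejected(self):
        with pytest.raises(ValueError):
            make_splits(["a", "b", "c", "d"], n_splits=5, test_n=1, seed=0)


class TestGridConfig:
    def test_full_grid_size(self):
        assert len(ClassifierConfig(grid_mode="full").grid) == 150

    def test_single_combo_grid_returned(self, rng):
        feats = synthetic_features(rng, n_subjects=4, epochs_per_stage=3)
        best = grid_search(feats, ONE_COMBO, seed=0)
        assert best == (0.1, 50, 3)

    def test_separable_data_tie_breaks_to_cheapest(self, rng):
        feats = synthetic_features(rng, n_subjects=4, epochs_per_stage=3,
                                   separation=20.0)
        config = ClassifierConfig(
            grid_mode="reduced",
            reduced_grid=((0.1, 100, 5), (0.1, 50, 3), (0.1, 50, 5)),
        )
        best = grid_search(feats, config, seed=0)
        assert best == (0.1, 50, 3)  # all perfect; cheapest model wins

    def test_single_class_rejected(self, rng):
        feats = synthetic_features(rng, n_subjects=3, epochs_per_stage=2)
        feats["stage"] = "W"
        with pytest.raises(ValueError):
            grid_search(feats, ONE_COMBO)


class TestFitEvaluate:
    def _split(self, feats, test_n=2):
        subjects = sorted(feats["subject"].unique())
        return tuple(subjects[test_n:]), tuple(subjects[:test_n])

    def test_contracts_on_separable_data(self, rng):
        feats = synthetic_features(rng, separation=8.0)
        split = self._split(feats)
        run = fit_evaluate(split, feats, (0.1, 50, 3), metric="PLV", seed=0)
        assert isinstance(run, ClassifierRun)
        assert run.accuracy > 0.9
        # confusion rows sum to per-stage test epoch counts
        test_counts = (
            feats[feats["subject"].isin(split[1])]["stage"]
            .value_counts().reindex(list(STAGES)).to_numpy()
        )
        assert np.array_equal(run.confusion.sum(axis=1), test_counts)
        assert np.trace(run.confusion) / run.confusion.sum() == pytest.approx(
            run.accuracy)
        assert run.importances.sum() == pytest.approx(1.0, abs=1e-6)
        assert np.all(run.importances >= 0)

    def test_overlapping_split_rejected(self, rng):
        feats = synthetic_features(rng, n_subjects=4, epochs_per_stage=2)
        with pytest.raises(ValueError):
            fit_evaluate((("S00", "S01"), ("S01",)), feats, (0.1, 50, 3))

    def test_schema_mismatch_rejected(self, rng):
        feats = synthetic_features(rng, n_subjects=4, epochs_per_stage=2)
        with pytest.raises(ValueError, match="schema"):
            fit_evaluate(self._split(feats, 1), feats, (0.1, 50, 3),
                         expected_n_features=1740)

    def test_missing_training_stage_rejected(self, rng):
        feats = synthetic_features(rng, n_subjects=4, epochs_per_stage=2)
        train_subj = ("S01", "S02", "S03")
        feats = feats[~((feats["subject"].isin(train_subj)) & (feats["stage"] == "N3"))]
        with pytest.raises(ValueError, match="N3"):
            fit_evaluate((train_subj, ("S00",)), feats, (0.1, 50, 3))

    def test_determinism_same_seed(self, rng):
        feats = synthetic_features(rng, n_subjects=5, epochs_per_stage=3,
                                   separation=1.0)
        split = self._split(feats, 1)
        r1 = fit_evaluate(split, feats, (0.1, 50, 3), seed=3)
        r2 = fit_evaluate(split, feats, (0.1, 50, 3), seed=3)
        assert r1.accuracy == r2.accuracy
        assert np.array_equal(r1.importances, r2.importances)


class TestAggregateAndCompare:
    def _runs(self, rng, n=5, accuracy=0.8):
        runs = []
        for k in range(n):
            conf = rng.integers(0, 10, (4, 4)).astype(float)
            imp = rng.uniform(0, 1, 12)
            runs.append(ClassifierRun(
                metric="PLV", split_index=k, best_hyperparams=(0.1, 50, 3),
                accuracy=accuracy, confusion=conf, importances=imp / imp.sum()))
        return runs

    def test_identical_runs_aggregate_to_single_run(self, rng):
        runs = self._runs(rng, n=1) * 5
        agg = aggregate(runs)
        assert agg.mean_accuracy == runs[0].accuracy
        assert np.allclose(agg.mean_confusion, runs[0].confusion)
        assert np.allclose(agg.mean_importances, runs[0].importances)

    def test_band_shares_sum_to_one(self, rng):
        agg = aggregate(self._runs(rng))
        assert sum(agg.band_shares.values()) == pytest.approx(1.0)
        assert set(agg.band_shares) == {"delta", "theta", "alpha", "beta"}

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            aggregate([])

    def test_identical_columns_give_zero_f(self, rng):
        col = rng.uniform(0.5, 0.9, 30)
        table = pd.DataFrame({m: col for m in ("a", "b", "c")})
        f_stat, p, _ = compare_metrics(table)
        assert f_stat == pytest.approx(0.0, abs=1e-20)

    def test_shifted_column_detected_by_tukey(self, rng):
        table = pd.DataFrame({
            "a": rng.normal(0.7, 0.02, 30),
            "b": rng.normal(0.7, 0.02, 30),
            "c": rng.normal(0.9, 0.02, 30),
        })
        f_stat, p, tukey = compare_metrics(table)
        assert p < 1e-6
        assert tukey.loc["a", "c"] < 1e-4
        assert tukey.loc["a", "b"] > 0.05

    def test_row_permutation_invariance(self, rng):
        table = pd.DataFrame(rng.uniform(0.4, 0.9, (30, 3)), columns=list("abc"))
        f1, p1, _ = compare_metrics(table)
        shuffled = table.sample(frac=1.0, random_state=0).reset_index(drop=True)
        f2, p2, _ = compare_metrics(shuffled)
        assert f1 == pytest.approx(f2)

    def test_missing_cells_rejected(self, rng):
        table = pd.DataFrame(rng.uniform(0, 1, (10, 3)), columns=list("abc"))
        table.iloc[0, 0] = np.nan
        with pytest.raises(ValueError):
            compare_metrics(table)


class TestLeakageAndChance:
    def test_no_subject_leakage_in_runs(self, rng):
        feats = synthetic_features(rng, n_subjects=6, epochs_per_stage=3)
        subjects = sorted(feats["subject"].unique())
        scheme = make_splits(subjects, n_splits=4, test_n=2, seed=0)
        runs = run_classification(feats, scheme, ONE_COMBO, metric="PLV", seed=0)
        assert len(runs) == 4
        for (train, test), run in zip(scheme.splits, runs):
            assert not set(train) & set(test)

    def test_label_shuffled_accuracy_at_chance(self, rng):
        """Mean held-out accuracy over >= 20 permutations is 0.25 +/- 0.05."""
        feats = synthetic_features(rng, n_subjects=8, epochs_per_stage=6,
                                   separation=3.0)
        from phasesleep.experiments import chance_level_accuracy

        accs = chance_level_accuracy(feats, n_permutations=20, seed=5,
                                     hyperparams=(0.1, 50, 3))
        assert 0.20 <= accs.mean() <= 0.30
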