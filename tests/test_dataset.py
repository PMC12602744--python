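"""Consolidation, preprocessing, augmentation and stratified splitting."""

import numpy as np
import pandas as pd
import pytest

from vocalmarkers.dataset import (
    augment_minority,
    consolidate,
    preprocess,
    stratified_split,
    write_feature_csv,
)
from vocalmarkers.errors import (
    DegenerateColumnError,
    EmptyDatasetError,
    ParameterError,
    StratificationError,
)
from vocalmarkers.features import FEATURE_NAMES
from vocalmarkers.synth import (
    PulseTrainSpec,
    generate_feature_table,
    FeatureTableSpec,
    generate_pulse_train,
)


def _dummy_table(class_sizes: dict, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for label, n in class_sizes.items():
        for i in range(n):
            rows.append(
                {"record_id": f"{label}-{i}", "class_label": label,
                 "augmented": False, "x": float(rng.normal())}
            )
    return pd.DataFrame(rows)


class TestStratifiedSplit:
    @pytest.mark.parametrize(
        "sizes,fraction,expect_test,expect_train",
        [
            ({0: 400, 1: 656}, 0.30, 317, 739),
            ({0: 224, 1: 223, 2: 223}, 0.20, 134, 536),
        ],
    )
    def test_study_split_arithmetic(self, sizes, fraction, expect_test, expect_train):
        table = _dummy_table(sizes)
        train, test = stratified_split(table, fraction, seed=0)
        assert len(test) == expect_test
        assert len(train) == expect_train

    def test_partition_and_proportions_over_random_configs(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            sizes = {c: int(rng.integers(10, 200)) for c in range(int(rng.integers(2, 4)))}
            fraction = float(rng.uniform(0.1, 0.5))
            table = _dummy_table(sizes, seed=int(rng.integers(0, 1000)))
            train, test = stratified_split(table, fraction, seed=int(rng.integers(0, 1000)))
            assert len(train) + len(test) == len(table)
            assert set(train.index).isdisjoint(test.index)
            for c, n in sizes.items():
                got = (test["class_label"] == c).sum()
                assert abs(got - fraction * n) < 1.0

    def test_augmented_rows_never_in_test(self):
        table = _dummy_table({0: 40, 1: 40})
        table.loc[table.index[:20], "augmented"] = True
        _train, test = stratified_split(table, 0.3, seed=1)
        assert not test["augmented"].any()

    def test_augmentation_exhausting_eligible_rows_rejected(self):
        table = _dummy_table({0: 40, 1: 40})
        table.loc[table.index[:35], "augmented"] = True  # 5 eligible < quota
        with pytest.raises(StratificationError):
            stratified_split(table, 0.3, seed=1)

    def test_small_class_rejected(self):
        with pytest.raises(StratificationError):
            stratified_split(_dummy_table({0: 50, 1: 1}), 0.3, seed=0)

    def test_zero_fraction_rejected(self):
        with pytest.raises(ParameterError):
            stratified_split(_dummy_table({0: 10, 1: 10}), 0.0, seed=0)


class TestPreprocess:
    def _table(self, column):
        t = generate_feature_table(FeatureTableSpec(n_per_class={0: 3}, seed=0))
        t[FEATURE_NAMES[0]] = column
        return t

    def test_exact_zscores_on_three_values(self):
        out, _ = preprocess(self._table([1.0, 2.0, 3.0]))
        got = out[FEATURE_NAMES[0]].to_numpy()
        assert got == pytest.approx([-1.2247448714, 0.0, 1.2247448714], abs=1e-9)

    def test_missing_cell_imputed_with_column_mean(self):
        out, params = preprocess(self._table([1.0, np.nan, 3.0]))
        assert params.impute_means[FEATURE_NAMES[0]] == pytest.approx(2.0)
        assert out[FEATURE_NAMES[0]].iloc[1] == pytest.approx(0.0)

    def test_constant_column_warns_and_yields_zeros(self):
        with pytest.warns(UserWarning, match="zero-variance"):
            out, _ = preprocess(self._table([5.0, 5.0, 5.0]))
        assert np.allclose(out[FEATURE_NAMES[0]], 0.0)

    def test_all_missing_column_rejected(self):
        with pytest.raises(DegenerateColumnError):
            preprocess(self._table([np.nan, np.nan, np.nan]))

    def test_idempotent_on_fitting_rows(self):
        table = generate_feature_table(
            FeatureTableSpec(n_per_class={0: 20, 1: 20}, missing_rate=0.05, seed=2)
        )
        once, params = preprocess(table)
        twice, _ = preprocess(once)
        assert np.allclose(
            once[list(FEATURE_NAMES)].to_numpy(),
            twice[list(FEATURE_NAMES)].to_numpy(),
            atol=1e-9,
        )

    def test_fit_on_train_leaves_test_uncentered(self):
        table = generate_feature_table(
            FeatureTableSpec(
                n_per_class={0: 50, 1: 50},
                class_means={0: np.zeros(28), 1: np.full(28, 2.0)},
                seed=3,
            )
        )
        fit_rows = table["class_label"].to_numpy() == 0
        out, _ = preprocess(table, fit_rows=fit_rows)
        train_means = out.loc[fit_rows, list(FEATURE_NAMES)].mean()
        test_means = out.loc[~fit_rows, list(FEATURE_NAMES)].mean()
        assert np.allclose(train_means, 0.0, atol=1e-9)
        assert np.abs(test_means).mean() > 0.5


class TestAugmentMinority:
    def _records(self, n0, n1):
        recs = []
        for label, n in ((0, n0), (1, n1)):
            for i in range(n):
                wave = generate_pulse_train(
                    PulseTrainSpec(f0=130.0, duration=0.25, seed=100 * label + i)
                )
                recs.append(wave.replace(subject_id=f"s{label}{i}", class_label=label))
        return recs

    def test_balances_to_majority_count(self):
        out = augment_minority(self._records(8, 4), seed=0)
        labels = [w.class_label for w in out]
        assert labels.count(0) == labels.count(1) == 8
        assert sum(w.augmented for w in out) == 4

    def test_duration_ratio_within_factor_range(self):
        records = self._records(6, 3)
        out = augment_minority(records, factor_range=(0.99, 1.01), seed=1)
        sources = {w.subject_id: w for w in records}
        for w in out:
            if w.augmented:
                ratio = w.samples.size / sources[w.subject_id].samples.size
                assert 1 / 1.011 <= ratio <= 1 / 0.989

    def test_deterministic(self):
        records = self._records(4, 2)
        a = augment_minority(records, seed=5)
        b = augment_minority(records, seed=5)
        assert all(np.array_equal(x.samples, y.samples) for x, y in zip(a, b))

    def test_excessive_factor_range_rejected(self):
        with pytest.raises(ParameterError):
            augment_minority(self._records(4, 2), factor_range=(0.5, 1.5), seed=0)


class TestConsolidate:
    def test_one_row_per_recording_with_28_features(self, cohort_dir, cohort_table):
        n_wavs = len(list(cohort_dir.glob("*/*.wav")))
        assert len(cohort_table) == n_wavs == 44
        assert [c for c in cohort_table.columns[-28:]] == list(FEATURE_NAMES)
        assert cohort_table["class_label"].isin([0, 1]).all()

    def test_rerun_produces_identical_csv_bytes(self, cohort_dir, tmp_path):
        a, b = tmp_path / "a.csv", tmp_path / "b.csv"
        write_feature_csv(consolidate(cohort_dir), a)
        write_feature_csv(consolidate(cohort_dir), b)
        assert a.read_bytes() == b.read_bytes()

    def test_corrupt_wav_is_skipped_with_remaining_rows_intact(
        self, cohort_dir, tmp_path, caplog
    ):
        import shutil

        root = tmp_path / "root"
        src = sorted(cohort_dir.glob("*"))[0]
        shutil.copytree(src, root / src.name)
        bad = root / src.name / "a_9.wav"
        bad.write_bytes(b"RIFFgarbage")
        table = consolidate(root)
        assert len(table) == 11

    def test_empty_root_rejected(self, tmp_path):
        with pytest.raises(EmptyDatasetError):
            consolidate(tmp_path)
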