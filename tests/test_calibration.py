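"""NIRS calibration stage: splitting, classification screen, PLSR blocks,
coefficient regions and the permutation test."""

import math

import numpy as np
import pandas as pd
import pytest
from sklearn.neighbors import KNeighborsClassifier

from chemocal.calibration import (
    calibrate_index,
    classify_screen,
    coefficient_profile,
    make_split,
    permutation_test,
)
from chemocal.pls import fit_pls1
from chemocal.preprocess import PreprocessSpec, state_checksum
from chemocal.synthetic import (
    Band,
    Component,
    SpectralGeneratorConfig,
    StudyDesign,
    generate_spectra,
)


@pytest.fixture(scope="module")
def full_spectra():
    design = StudyDesign(seed=2)
    return generate_spectra(design, SpectralGeneratorConfig.long_wave())


@pytest.fixture(scope="module")
def small_spectra():
    design = StudyDesign(n_subsamples=2, n_scans_per_subsample=3, seed=7)
    return generate_spectra(design, SpectralGeneratorConfig.long_wave())


@pytest.fixture(scope="module")
def separable_spectra():
    """Nearly noise-free acquisition: storage classes are cleanly separated."""
    design = StudyDesign(n_subsamples=2, n_scans_per_subsample=3, seed=7)
    cfg = SpectralGeneratorConfig.long_wave(
        noise_sd=0.0003, scatter_slope_sd=0.01, scatter_offset_sd=0.004
    )
    return generate_spectra(design, cfg)


class TestSplit:
    def test_stratified_counts(self, full_spectra):
        split = make_split(full_spectra, ratio=0.8, seed=0)
        assert split.train_idx.size == 280 and split.test_idx.size == 70
        labels = full_spectra.meta["sample"].to_numpy()
        train_counts = pd.Series(labels[split.train_idx]).value_counts()
        test_counts = pd.Series(labels[split.test_idx]).value_counts()
        assert (train_counts == 40).all() and (test_counts == 10).all()

    def test_deterministic(self, full_spectra):
        a = make_split(full_spectra, seed=3)
        b = make_split(full_spectra, seed=3)
        assert np.array_equal(a.train_idx, b.train_idx)

    def test_sample_grouped_mode_infeasible_for_singleton_classes(self, full_spectra):
        with pytest.raises(ValueError, match="sample-grouped"):
            make_split(full_spectra, mode="sample")


class TestClassificationScreen:
    def test_separable_spectra_classified_perfectly(self, separable_spectra):
        split = make_split(separable_spectra, seed=0)
        report, confusions = classify_screen(
            separable_spectra, [PreprocessSpec("SNVFD")], split, cv_k=3, seed=0
        )
        assert (report["test_accuracy"] == 1.0).all()
        assert set(report["algorithm"]) == {"SVM", "KNN", "RF"}
        cm = confusions[("", "SNVFD", "RF")]
        assert cm.sum() == split.test_idx.size
        labels = separable_spectra.meta["sample"].to_numpy()
        test_counts = (
            pd.Series(labels[split.test_idx]).value_counts().sort_index().to_numpy()
        )
        np.testing.assert_array_equal(cm.sum(axis=1), test_counts)

    def test_shuffled_labels_fall_to_chance(self, small_spectra):
        rng = np.random.default_rng(0)
        shuffled = small_spectra.subset(rng.permutation(small_spectra.n_spectra))
        shuffled.meta["sample"] = small_spectra.meta["sample"].to_numpy()
        split = make_split(shuffled, seed=0)
        report, _ = classify_screen(
            shuffled, [PreprocessSpec("RAW")], split,
            algorithms={"KNN": KNeighborsClassifier(3)}, cv_k=3, seed=0,
        )
        assert report["cv_accuracy"].iloc[0] < 0.45  # chance is 1/7

    def test_report_covers_method_algorithm_grid(self, small_spectra):
        specs = [PreprocessSpec(m) for m in ("RAW", "SGFD", "MSCFD", "SNVFD")]
        split = make_split(small_spectra, seed=0)
        report, _ = classify_screen(
            small_spectra, specs, split,
            algorithms={"KNN": KNeighborsClassifier(3)}, cv_k=3, seed=0,
        )
        assert len(report) == 4  # x1 algorithm; full screen = 2 ranges x 4 x 3
        metrics = report[[c for c in report.columns if c.endswith(("accuracy", "weighted"))]]
        assert ((metrics >= 0) & (metrics <= 1)).all().all()

    def test_accuracy_degrades_with_noise(self):
        accs = []
        for noise in (0.002, 0.05, 0.3):
            cfg = SpectralGeneratorConfig.long_wave(noise_sd=noise)
            sp = generate_spectra(
                StudyDesign(n_subsamples=2, n_scans_per_subsample=3, seed=3), cfg
            )
            split = make_split(sp, seed=0)
            report, _ = classify_screen(
                sp, [PreprocessSpec("SNVFD")], split,
                algorithms={"KNN": KNeighborsClassifier(3)}, cv_k=3, seed=0,
            )
            accs.append(report["test_accuracy"].iloc[0])
        assert accs[0] >= accs[1] >= accs[2]


@pytest.fixture(scope="module")
def block(full_spectra):
    months = full_spectra.meta.drop_duplicates("sample").set_index("sample")["months"]
    split = make_split(full_spectra, seed=0)
    specs = [PreprocessSpec(m) for m in ("RAW", "SG", "MSC", "SNV", "SGFD", "MSCFD", "SNVFD")]
    report, results = calibrate_index(
        full_spectra, months.astype(float), specs, split, seed=0
    )
    return report, results, split


class TestCalibrateIndex:
    def test_one_row_per_method_one_best_flag(self, block):
        report, _, _ = block
        assert len(report) == 7 and report["best"].sum() == 1
        best_row = report[report["best"]].iloc[0]
        assert best_row["Rp2"] == report["Rp2"].max()

    def test_lv_selection_within_grid(self, block):
        report, _, _ = block
        assert report["n_lv"].between(1, 10).all()

    def test_no_test_set_leakage_into_fitted_state(self, full_spectra):
        months = full_spectra.meta.drop_duplicates("sample").set_index("sample")["months"]
        split = make_split(full_spectra, seed=0)
        spec = PreprocessSpec("MSCFD")
        _, results = calibrate_index(full_spectra, months.astype(float), [spec], split, seed=0)
        # corrupt the held-out spectra; training statistics must not move
        corrupted = full_spectra.with_absorbance(full_spectra.absorbance.copy())
        corrupted.absorbance[split.test_idx] += 5.0
        _, results2 = calibrate_index(corrupted, months.astype(float), [spec], split, seed=0)
        assert state_checksum(results["MSCFD"].state) == state_checksum(results2["MSCFD"].state)

    def test_constant_index_rejected(self, full_spectra):
        flat = pd.Series(1.0, index=full_spectra.meta["sample"].unique())
        split = make_split(full_spectra, seed=0)
        with pytest.raises(ValueError, match="constant"):
            calibrate_index(full_spectra, flat, [PreprocessSpec("RAW")], split)


class TestCoefficientProfile:
    def test_planted_band_recovered(self, rng):
        # oxidation is the only component varying with months; the top
        # coefficient region must sit on its 1850-1950 nm band
        const = lambda m, p: 1.0
        rise = lambda m, p: 0.2 + 0.8 * m / 56.0
        comps = (
            Component("water", (Band(1440, 70, 0.42),), const),
            Component("oxidation", (Band(1900, 30, 0.15),), rise),
            Component("background", (Band(2100, 120, 0.34),), const),
        )
        cfg = SpectralGeneratorConfig(
            wavelengths=np.linspace(1300, 2500, 257), components=comps
        )
        sp = generate_spectra(StudyDesign(seed=4), cfg)
        sp = sp.subset(sp.meta["processed"].to_numpy(bool))
        model = fit_pls1(sp.absorbance, sp.meta["months"].to_numpy(float), 3)
        top = coefficient_profile(model, sp.wavelengths).iloc[0]
        assert top["start_nm"] <= 1950 and top["end_nm"] >= 1850

    def test_flat_profile_yields_no_regions(self):
        model = fit_pls1(
            np.random.default_rng(0).normal(size=(10, 5)),
            np.arange(10, dtype=float),
            1,
        )
        model.coef_ = np.ones(5)
        assert coefficient_profile(model, np.arange(5.0)).empty

    def test_zero_percentile_spans_full_grid(self, rng):
        model = fit_pls1(rng.normal(size=(10, 8)), np.arange(10, dtype=float), 2)
        regions = coefficient_profile(model, np.arange(8.0), percentile=0.0)
        assert len(regions) == 1
        assert regions.iloc[0]["start_nm"] == 0.0 and regions.iloc[0]["end_nm"] == 7.0


class TestPermutationTest:
    def test_report_arrays_sized_to_iterations(self, rng):
        X = rng.normal(size=(30, 10))
        y = X[:, 0] * 2 + rng.normal(scale=0.1, size=30)
        report = permutation_test(X, y, n_lv=2, n_iter=25, seed=0)
        assert report.r2_perm.size == report.q2_perm.size == report.corr_abs.size == 25

    def test_genuine_signal_passes(self, rng):
        X = rng.normal(size=(40, 15))
        y = X @ rng.normal(size=15) + rng.normal(scale=0.2, size=40)
        report = permutation_test(X, y, n_lv=4, n_iter=50, seed=0)
        assert report.q2_intercept < 0.05 and report.passed
        assert report.original_q2 > max(report.q2_perm)

    def test_pure_noise_original_inside_null_band(self, rng):
        X = rng.normal(size=(40, 30))
        y = rng.normal(size=40)
        report = permutation_test(X, y, n_lv=2, n_iter=100, seed=0)
        lo, hi = np.percentile(report.q2_perm, [2.5, 97.5])
        assert lo <= report.original_q2 <= hi

    def test_few_iterations_warn(self, rng):
        X = rng.normal(size=(20, 5))
        y = rng.normal(size=20)
        with pytest.warns(UserWarning, match="intercept"):
            permutation_test(X, y, n_lv=1, n_iter=10, seed=0)
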