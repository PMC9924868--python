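import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from plasmaftir.io import SpectraSet
from plasmaftir.preprocess import (
    PreprocessConfig,
    RegionSpec,
    average_replicates,
    class_mean_sd,
    cut_region,
    rubberband_baseline,
    run_preprocess,
    savgol_second_derivative,
    vector_normalize,
)
from plasmaftir.simulate import CohortConfig, generate_cohort

from conftest import noise_free_config


def brute_force_lower_hull(x, y):
    """O(n^2) gift-wrapping oracle for the lower convex hull indices."""
    idx = [0]
    while idx[-1] != len(x) - 1:
        i = idx[-1]
        slopes = (y[i + 1:] - y[i]) / (x[i + 1:] - x[i])
        best = np.min(slopes)
        # farthest point attaining the minimal slope keeps hull vertices minimal
        j = i + 1 + np.flatnonzero(np.isclose(slopes, best, rtol=0, atol=0)).max()
        idx.append(j)
    return np.array(idx)


class TestCutRegion:
    def test_fingerprint_cut_yields_621_points(self, default_cohort):
        cut = cut_region(default_cohort, "fingerprint")
        assert cut.wavenumbers.size == 621
        assert cut.wavenumbers[0] == pytest.approx(900.0)
        assert cut.wavenumbers[-1] == pytest.approx(1800.0)

    def test_full_grid_cut_is_identity(self, tiny_set):
        cut = cut_region(
            tiny_set, RegionSpec("custom", 1000.0, 1030.0)
        )
        np.testing.assert_array_equal(cut.intensities, tiny_set.intensities)

    def test_single_point_cut(self, tiny_set):
        cut = cut_region(tiny_set, RegionSpec("custom", 1010.0, 1010.0))
        assert cut.wavenumbers.size == 1

    def test_disjoint_region_raises(self, tiny_set):
        with pytest.raises(ValueError, match="does not intersect"):
            cut_region(tiny_set, RegionSpec("custom", 2000.0, 2100.0))


class TestRubberband:
    def test_straight_line_corrects_to_zero(self):
        x = np.linspace(900, 1800, 200)
        y = 0.003 * x + 1.0
        baseline, corrected = rubberband_baseline(x, y)
        np.testing.assert_allclose(corrected, 0.0, atol=1e-12)
        np.testing.assert_allclose(baseline, y, atol=1e-12)

    def test_line_plus_gaussian_recovers_line(self):
        x = np.linspace(1000, 1500, 50)
        line = -0.001 * x + 3.0
        peak = 0.5 * np.exp(-((x - 1250.0) / 40.0) ** 2)
        baseline, corrected = rubberband_baseline(x, line + peak)
        np.testing.assert_allclose(baseline, line, atol=1e-9)
        np.testing.assert_allclose(corrected, peak, atol=1e-9)

    def test_idempotence(self):
        rng = np.random.default_rng(3)
        x = np.linspace(900, 1800, 120)
        y = rng.normal(size=x.size).cumsum()
        _, corrected = rubberband_baseline(x, y)
        _, again = rubberband_baseline(x, corrected)
        np.testing.assert_allclose(again, corrected, atol=1e-12)

    def test_corrected_nonnegative_and_touches_zero(self):
        rng = np.random.default_rng(5)
        x = np.linspace(900, 1800, 80)
        y = np.sin(x / 50.0) + rng.normal(scale=0.1, size=x.size)
        _, corrected = rubberband_baseline(x, y)
        assert corrected.min() >= -1e-12
        assert np.sum(np.isclose(corrected, 0.0, atol=1e-12)) >= 2
        assert np.isclose(corrected[0], 0.0) and np.isclose(corrected[-1], 0.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(30, 101)
        x = np.sort(rng.uniform(900, 1800, size=n))
        x += np.arange(n) * 1e-6  # guarantee strict ascent
        y = rng.normal(size=n).cumsum() + rng.uniform(0, 2) * np.sin(x / 90)
        baseline, _ = rubberband_baseline(x, y)
        idx = brute_force_lower_hull(x, y)
        np.testing.assert_allclose(baseline, np.interp(x, x[idx], y[idx]),
                                   atol=1e-10)

    def test_fewer_than_two_points_raises(self):
        with pytest.raises(ValueError):
            rubberband_baseline(np.array([1000.0]), np.array([1.0]))


class TestVectorNormalize:
    def test_three_four_five(self):
        np.testing.assert_allclose(
            vector_normalize(np.array([3.0, 4.0])), [0.6, 0.8]
        )

    def test_unit_vector_fixed_point(self):
        v = np.array([0.6, 0.8])
        np.testing.assert_allclose(vector_normalize(v), v, atol=1e-15)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        scale=st.floats(min_value=1e-6, max_value=1e6),
        seed=st.integers(min_value=0, max_value=1000),
    )
    def test_scale_invariance(self, scale, seed):
        v = np.random.default_rng(seed).normal(size=20) + 0.01
        np.testing.assert_allclose(
            vector_normalize(scale * v), vector_normalize(v), atol=1e-12
        )

    def test_zero_vector_raises(self):
        with pytest.raises(ValueError, match="all-zero"):
            vector_normalize(np.zeros(5))


class TestSavitzkyGolay:
    def test_exact_on_quadratic_everywhere(self):
        x = np.arange(900.0, 1800.0, 1.45)
        d2 = savgol_second_derivative(x**2, spacing=1.45)
        np.testing.assert_allclose(d2, 2.0, atol=1e-9)

    def test_constant_maps_to_zero(self):
        d2 = savgol_second_derivative(np.full(100, 3.3), spacing=2.0)
        np.testing.assert_allclose(d2, 0.0, atol=1e-9)

    def test_linearity(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=(2, 80))
        lhs = savgol_second_derivative(2 * a - 3 * b, spacing=1.0)
        rhs = (2 * savgol_second_derivative(a, spacing=1.0)
               - 3 * savgol_second_derivative(b, spacing=1.0))
        np.testing.assert_allclose(lhs, rhs, atol=1e-10)

    def test_gaussian_minimum_at_band_center(self):
        x = np.arange(1500.0, 1800.0, 1.45)
        y = np.exp(-4 * np.log(2) * ((x - 1650.0) / 40.0) ** 2)
        d2 = savgol_second_derivative(y, spacing=1.45)
        assert abs(x[np.argmin(d2)] - 1650.0) <= 1.45

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            savgol_second_derivative(np.zeros(50), spacing=1.0, window=12)

    def test_window_longer_than_spectrum_rejected(self):
        with pytest.raises(ValueError):
            savgol_second_derivative(np.zeros(9), spacing=1.0, window=13)


class TestAveraging:
    def test_replicate_mean(self, tiny_set):
        avg = average_replicates(tiny_set)
        assert avg.n_spectra == 2
        np.testing.assert_allclose(avg.intensities[0], 1.0)
        assert "replicate" not in avg.meta.columns

    def test_single_replicate_unchanged(self, tiny_set):
        from plasmaftir.io import subset_by_meta

        one = subset_by_meta(tiny_set, "replicate == 1")
        avg = average_replicates(one)
        np.testing.assert_array_equal(avg.intensities, one.intensities)

    def test_cohort_collapses_to_85_rows(self, default_cohort):
        assert average_replicates(default_cohort).n_spectra == 85

    def test_conflicting_class_labels_raise(self, tiny_set):
        meta = tiny_set.meta.copy()
        meta["subject_id"] = ["s", "s", "s", "s"]
        meta["class_label"] = ["HC", "MS", "HC", "MS"]
        meta["edss"] = np.nan
        meta["replicate"] = [1, 2, 3, 4]
        bad = SpectraSet(tiny_set.wavenumbers, tiny_set.intensities, meta)
        with pytest.raises(ValueError, match="conflicting"):
            average_replicates(bad)


class TestClassMeanSd:
    def test_identical_spectra_have_zero_sd(self, tiny_set):
        _, sd = class_mean_sd(average_replicates(tiny_set), "MS")
        # MS001 is a single subject after averaging -> sd defined as 0
        np.testing.assert_allclose(sd, 0.0)

    def test_two_point_sample_sd(self):
        wn = np.array([1000.0, 1010.0])
        meta = pd.DataFrame(
            {"subject_id": ["a", "b"], "class_label": ["HC", "HC"],
             "edss": [np.nan] * 2, "onset_years": [np.nan] * 2}
        )
        data = SpectraSet(wn, np.array([[0.0, 0.0], [2.0, 2.0]]), meta)
        mean, sd = class_mean_sd(data, "HC")
        np.testing.assert_allclose(mean, 1.0)
        np.testing.assert_allclose(sd, np.sqrt(2.0))

    def test_noise_free_class_sd_zero(self, noise_free_cohort):
        avg = average_replicates(noise_free_cohort)
        _, sd = class_mean_sd(avg, "HC")
        np.testing.assert_allclose(sd, 0.0, atol=1e-12)

    def test_empty_class_raises(self, tiny_set):
        from plasmaftir.io import subset_by_meta

        only_hc = subset_by_meta(tiny_set, "class_label == 'HC'")
        with pytest.raises(ValueError):
            class_mean_sd(only_hc, "MS")


class TestRunPreprocess:
    def test_absorbance_track_unit_norms(self, default_cohort):
        out = run_preprocess(
            default_cohort, PreprocessConfig(derivative="none")
        )
        np.testing.assert_allclose(
            np.linalg.norm(out.intensities, axis=1), 1.0, atol=1e-12
        )

    def test_derivative_track_unit_norms_and_621_columns(self, default_cohort):
        out = run_preprocess(default_cohort, PreprocessConfig())
        assert out.intensities.shape == (85, 621)
        np.testing.assert_allclose(
            np.linalg.norm(out.intensities, axis=1), 1.0, atol=1e-12
        )
        assert any("savgol" in step for step in out.provenance)

    def test_invariant_to_replicate_order(self, default_cohort):
        shuffled = SpectraSet(
            default_cohort.wavenumbers,
            default_cohort.intensities[::-1],
            default_cohort.meta.iloc[::-1].reset_index(drop=True),
        )
        a = run_preprocess(default_cohort, PreprocessConfig())
        b = run_preprocess(shuffled, PreprocessConfig())
        order = [list(b.meta["subject_id"]).index(s)
                 for s in a.meta["subject_id"]]
        np.testing.assert_allclose(
            a.intensities, b.intensities[order], atol=1e-12
        )

    def test_deterministic(self, default_cohort):
        a = run_preprocess(default_cohort, PreprocessConfig())
        b = run_preprocess(default_cohort, PreprocessConfig())
        np.testing.assert_array_equal(a.intensities, b.intensities)
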