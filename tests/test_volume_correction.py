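"""Spearman screen, binned profiles, the 8-form fit engine and inversion."""

import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone

from oracles import spearman_brute
from radrobust.phantom import PlantedDependencySpec, generate_planted_feature_table
from radrobust.volume_correction import (
    FIT_FORMS,
    VolumeDependencyCorrector,
    bin_measurements,
    classify_volume_dependent,
    correct_feature,
    fit_and_correct,
    fit_candidates,
    pairwise_feature_correlations,
    select_best_fit,
    spearman_rs,
)


def conditioned_p1(form_id, lo=300.0, hi=53141.0):
    """A slope keeping the signal term comparable to the offset p0."""
    g = FIT_FORMS[form_id][1]
    return 10.0 / abs(g(hi) - g(lo))


class TestSpearman:
    def test_monotone_sequences(self):
        x = np.array([1.0, 2.0, 5.0, 9.0])
        assert spearman_rs(x, x**2)[0] == pytest.approx(1.0)
        assert spearman_rs(x, -np.sqrt(x))[0] == pytest.approx(-1.0)

    def test_tied_sample_matches_rank_oracle(self):
        x = [1.0, 2.0, 2.0, 3.0, 4.0, 4.0, 4.0, 5.0]
        y = [2.0, 1.0, 3.0, 3.0, 5.0, 4.0, 6.0, 6.0]
        assert spearman_rs(x, y)[0] == pytest.approx(spearman_brute(x, y), rel=1e-12)

    def test_constant_input_undefined(self):
        with pytest.raises(ValueError, match="constant"):
            spearman_rs([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestClassifyVolumeDependent:
    def test_median_across_configs_thresholded_and_shape_exempt(self):
        rs = pd.DataFrame(
            {
                "firstorder_Energy": [0.9, 0.95, 0.85],
                "glcm_Imc2": [0.2, 0.6, 0.1],
                "shape_MeshVolume": [1.0, 1.0, 1.0],
            }
        )
        flags = classify_volume_dependent(rs, threshold=0.5)
        assert bool(flags["firstorder_Energy"]) is True
        assert bool(flags["glcm_Imc2"]) is False  # median 0.2 < 0.5
        assert bool(flags["shape_MeshVolume"]) is False

    def test_negative_correlations_count_by_magnitude(self):
        rs = pd.DataFrame({"ngtdm_Coarseness": [-0.9, -0.8, -0.95]})
        assert bool(classify_volume_dependent(rs)["ngtdm_Coarseness"]) is True


class TestBinMeasurements:
    def test_ten_points_make_five_divisions_of_two(self):
        x = np.arange(10, dtype=float)
        prof = bin_measurements(x, x, target_bins=5)
        assert prof.n_divisions == 5
        assert list(prof.counts) == [2, 2, 2, 2, 2]

    def test_duplicate_x_never_straddles_a_boundary(self):
        x = np.array([1.0, 2.0, 3.0, 3.0, 3.0, 3.0, 4.0, 5.0, 6.0, 7.0])
        prof = bin_measurements(x, np.arange(10.0), target_bins=5)
        for members in prof.x_members:
            inside = members == 3.0
            if inside.any():
                assert inside.sum() in (0, 4)  # the tie block stays together
        assert sum(np.sum(m == 3.0) for m in prof.x_members) == 4

    def test_random_sample_occupancy_near_uniform(self, rng):
        x = rng.uniform(10, 1000, size=43)
        prof = bin_measurements(x, rng.normal(size=43))
        assert prof.n_divisions == 10
        assert prof.counts.min() >= 2
        assert int(prof.counts.sum()) == 43
        assert prof.counts.max() - prof.counts.min() <= 2

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            bin_measurements([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])


class TestFitEngine:
    @pytest.mark.parametrize("form_id", list(FIT_FORMS))
    def test_noiseless_planted_form_recovered_exactly(self, form_id):
        p1 = conditioned_p1(form_id)
        spec = PlantedDependencySpec(form_id, p0=5.0, p1=p1, noise_sd=0.0, n_points=43, seed=form_id)
        t = generate_planted_feature_table(spec)
        best = select_best_fit(
            fit_candidates(bin_measurements(t["n_voxels"].to_numpy(), t["value"].to_numpy()))
        )
        assert best.form_id == form_id
        assert best.p0 == pytest.approx(5.0, rel=1e-6)
        assert best.p1 == pytest.approx(p1, rel=1e-6)

    def test_noiseless_log_model_example(self):
        x = np.linspace(10, 5000, 40)
        y = 3.0 * np.log(x) + 1.0
        best = select_best_fit(fit_candidates(bin_measurements(x, y)))
        assert best.form_id == 7
        assert best.p0 == pytest.approx(1.0, abs=1e-9)
        assert best.p1 == pytest.approx(3.0, rel=1e-12)
        assert best.chi2 == pytest.approx(0.0, abs=1e-12)

    def test_noiseless_reciprocal_model_example(self):
        x = np.linspace(1.0, 50.0, 24)
        y = 2.0 / x + 5.0
        best = select_best_fit(fit_candidates(bin_measurements(x, y)))
        assert best.form_id == 4
        assert best.p0 == pytest.approx(5.0, rel=1e-9)
        assert best.p1 == pytest.approx(2.0, rel=1e-9)

    def test_selected_fit_has_minimal_chi2(self, rng):
        x = rng.uniform(300, 5000, size=40)
        y = 4.0 * np.log(x) + rng.normal(0, 0.5, size=40)
        candidates = fit_candidates(bin_measurements(x, y))
        best = select_best_fit(candidates)
        assert all(best.reduced_chi2 <= c.reduced_chi2 + 1e-9 for c in candidates)

    def test_undefined_bases_skipped_with_zero_crossing(self):
        x = np.linspace(-5.0, 5.0, 20)  # log undefined, 1/x undefined at 0
        y = 2.0 * x + 1.0
        forms = {c.form_id for c in fit_candidates(bin_measurements(x, y))}
        assert 7 not in forms and 8 not in forms
        assert 1 in forms

    def test_poor_fits_discarded_as_uncorrectable(self, rng):
        # a sharp step is badly described by every smooth candidate
        x = np.linspace(1, 100, 40)
        y = np.where(x < 50, 0.0, 100.0) + rng.normal(0, 0.01, size=40)
        best = select_best_fit(fit_candidates(bin_measurements(x, y)), max_reduced_chi2=10.0)
        assert best is None

    def test_single_valid_candidate_returned(self):
        cands = fit_candidates(bin_measurements(np.linspace(1, 9, 12), np.linspace(0, 1, 12)))
        only = [c for c in cands if c.form_id == 1]
        assert select_best_fit(only).form_id == 1

    def test_near_tied_candidates_resolve_to_lowest_form_id(self):
        from radrobust.volume_correction import FitCandidate

        c1 = FitCandidate(3, "x^3", 0.0, 1.0, 1.0, 5)
        c2 = FitCandidate(1, "x", 0.0, 1.0, 1.0 + 1e-12, 5)
        assert select_best_fit([c1, c2]).form_id == 1


class TestCorrection:
    def test_noiseless_log_model_corrects_to_constant_p1(self):
        x = np.linspace(10, 5000, 30)
        y = 3.0 * np.log(x) + 1.0
        corrected, best = fit_and_correct(x, y)
        assert best.form_id == 7
        assert np.allclose(corrected, 3.0, atol=1e-9)

    def test_linear_model_at_two_points_inverts_exactly(self):
        from radrobust.volume_correction import FitCandidate

        fit = FitCandidate(1, "x", 1.0, 2.0, 0.0, 1)
        out = correct_feature(np.array([21.0, 201.0]), np.array([10.0, 100.0]), fit)
        assert np.allclose(out, [2.0, 2.0])

    def test_zero_basis_points_flagged_nan(self):
        from radrobust.volume_correction import FitCandidate

        fit = FitCandidate(7, "log(x)", 0.0, 2.0, 0.0, 1)
        out = correct_feature(np.array([3.0, 2.0]), np.array([1.0, 10.0]), fit)
        assert np.isnan(out[0]) and np.isfinite(out[1])

    def test_correction_idempotent_on_exact_model(self):
        x = np.linspace(300, 5000, 43)
        y = 2.0 * x + 7.0
        corrected, best = fit_and_correct(x, y)
        assert np.allclose(corrected, 2.0)
        # corrected values have no residual x dependence: refit slope ~ 0
        refit = select_best_fit(fit_candidates(bin_measurements(x, corrected)))
        if refit is not None:
            assert abs(refit.p1 * (np.ptp(FIT_FORMS[refit.form_id][1](x)))) < 1e-6

    def test_planted_noisy_dependency_decorrelates(self, rng):
        spec = PlantedDependencySpec(1, p0=10.0, p1=2.0, noise_sd=800.0, n_points=43, seed=4)
        t = generate_planted_feature_table(spec)
        x, y = t["n_voxels"].to_numpy(), t["value"].to_numpy()
        assert spearman_rs(x, y)[0] > 0.9
        corrected, best = fit_and_correct(x, y)
        assert abs(spearman_rs(x, corrected)[0]) < 0.5


class TestPairwiseCorrelations:
    def test_identical_and_negated_features(self, rng):
        f = rng.normal(size=10)
        table = pd.DataFrame({"a": f, "b": f.copy(), "c": -f})
        m = pairwise_feature_correlations(table)
        assert m.loc["a", "b"] == pytest.approx(1.0)
        assert m.loc["a", "c"] == pytest.approx(-1.0)
        assert (m.to_numpy().diagonal() == 1.0).all()

    def test_constant_feature_flagged_undefined(self, rng):
        table = pd.DataFrame({"a": rng.normal(size=6), "b": np.full(6, 2.0)})
        m = pairwise_feature_correlations(table)
        assert np.isnan(m.loc["b", "a"])
        assert m.loc["a", "a"] == 1.0

    def test_volume_correction_reduces_mean_intercorrelation(self, rng):
        # features sharing a common voxel-count factor decorrelate once the
        # factor is fitted out
        x = np.exp(rng.uniform(np.log(300), np.log(50_000), size=40))
        table = pd.DataFrame(
            {
                "f1": 2.0 * x + rng.normal(0, 2000, 40),
                "f2": 0.5 * x + rng.normal(0, 500, 40),
                "f3": 30.0 * np.log(x) + rng.normal(0, 6, 40),
            }
        )
        before = pairwise_feature_correlations(table).abs().to_numpy()
        corrected = {}
        for col in table:
            corrected[col], _ = fit_and_correct(x, table[col].to_numpy())
        after = pairwise_feature_correlations(pd.DataFrame(corrected)).abs().to_numpy()
        off = ~np.eye(3, dtype=bool)
        assert after[off].mean() < before[off].mean()


class TestCorrectorTransformer:
    @pytest.fixture
    def planted_table(self, rng):
        x = np.exp(rng.uniform(np.log(300), np.log(50_000), size=40))
        return pd.DataFrame(
            {
                "n_voxels": x,
                "firstorder_Energy": 3.0 * x + rng.normal(0, 3000, 40),
                "glcm_Imc2": rng.normal(0.5, 0.05, 40),
                "shape_MeshVolume": 1.2 * x,
            }
        )

    def test_sklearn_contract_clone_and_params(self):
        est = VolumeDependencyCorrector(rs_threshold=0.6)
        est2 = clone(est)
        assert est2.get_params()["rs_threshold"] == 0.6

    def test_fit_screens_and_corrects_planted_energy(self, planted_table):
        est = VolumeDependencyCorrector().fit(planted_table)
        assert "firstorder_Energy" in est.fits_
        assert "glcm_Imc2" not in est.correlated_
        out = est.transform(planted_table)
        rs, _ = spearman_rs(planted_table["n_voxels"], out["firstorder_Energy"])
        assert abs(rs) < 0.5
        # untouched columns pass through
        assert np.array_equal(out["glcm_Imc2"], planted_table["glcm_Imc2"])

    def test_shape_features_never_corrected(self, planted_table):
        est = VolumeDependencyCorrector().fit(planted_table)
        assert "shape_MeshVolume" not in est.fits_
        out = est.transform(planted_table)
        assert np.array_equal(out["shape_MeshVolume"], planted_table["shape_MeshVolume"])

    def test_fit_report_schema(self, planted_table):
        est = VolumeDependencyCorrector().fit(planted_table)
        report = est.fit_report()
        assert {"feature", "r_s", "corrected", "form_id", "p0", "p1"} <= set(report.columns)
        assert (report[report["corrected"]]["reduced_chi2"] >= 0).all()

    def test_transform_before_fit_raises(self, planted_table):
        from sklearn.exceptions import NotFittedError

        with pytest.raises(NotFittedError):
            VolumeDependencyCorrector().transform(planted_table)
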