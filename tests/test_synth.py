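"""Generator: log-normal calibration, rendering, and measurement inversion."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats as sps

from libs_tissue import (
    DEFAULT_COUNTS,
    DatasetSpec,
    LogNormalParams,
    TissueClass,
    ValidationError,
    calibrate_lognormal,
    default_model,
    electrolyte_sums,
    features_table,
    generate_dataset,
    preprocess_all,
    sample_features,
    sample_spectrum,
)
from libs_tissue.synth import Z75


class TestCalibration:
    def test_published_nerve_calcium_pair(self):
        p = calibrate_lognormal(63.64, 15.07)
        assert p.mu == pytest.approx(4.1533, abs=1e-4)
        assert p.sigma == pytest.approx(0.1751, abs=1e-4)

    def test_sinh_identity_collapses_to_unit_sigma(self):
        p = calibrate_lognormal(1.0, 2.0 * math.sinh(Z75))
        assert p.sigma == pytest.approx(1.0, rel=1e-12)

    @given(
        median=st.floats(0.5, 100.0),
        ratio=st.floats(0.05, 3.0),
    )
    def test_quantile_function_recovers_median_and_iqr(self, median, ratio):
        iqr = ratio * median
        p = calibrate_lognormal(median, iqr)
        dist = sps.lognorm(s=p.sigma, scale=math.exp(p.mu))
        assert dist.ppf(0.5) == pytest.approx(median, rel=1e-9)
        assert dist.ppf(0.75) - dist.ppf(0.25) == pytest.approx(iqr, rel=1e-9)

    @pytest.mark.parametrize("median, iqr", [(0.0, 1.0), (-1.0, 1.0), (1.0, 0.0)])
    def test_degenerate_inputs_rejected(self, median, iqr):
        with pytest.raises(ValidationError):
            calibrate_lognormal(median, iqr)


class TestDefaultModel:
    def test_published_medians_enter_the_model(self, model):
        assert model.classes[TissueClass.CELL_RICH_TUMOR].k.median == pytest.approx(6.498)
        assert model.classes[TissueClass.NERVE].ca.median == pytest.approx(63.64)
        assert model.classes[TissueClass.TUMOR_STROMA].ca.iqr == pytest.approx(40.46)
        assert default_model().to_dict() == model.to_dict()

    def test_weight_vectors_sum_to_one(self, model, catalog):
        for cls in TissueClass:
            for element in ("Ca", "K", "Na"):
                w = model.weight_vector(cls, element, len(catalog.bins_for(element)))
                assert w.sum() == pytest.approx(1.0)
                assert np.all(w >= 0)

    def test_truncation_quantile_in_documented_range(self, model):
        assert 0.9 < model.truncation_quantile <= 1.0


class TestSampleSpectrum:
    def test_measurement_inversion_noise_free(self, quiet_model, grid_wl, catalog):
        """With noise off, preprocessing recovers the drawn sums exactly."""
        for cls in TissueClass:
            s = sample_spectrum(
                quiet_model, cls, np.random.default_rng(5),
                grid_wl=grid_wl, catalog=catalog, gain=3.7,
            )
            f = electrolyte_sums(preprocess_all([s], catalog)[0], catalog)
            assert f.ca_sum == pytest.approx(s.meta["target_ca_sum"], rel=1e-6)
            assert f.k_sum == pytest.approx(s.meta["target_k_sum"], rel=1e-6)
            assert f.na_sum == pytest.approx(s.meta["target_na_sum"], rel=1e-6)

    def test_same_seed_same_spectrum(self, model, grid_wl, catalog):
        a = sample_spectrum(model, TissueClass.NERVE, np.random.default_rng(11),
                            grid_wl=grid_wl, catalog=catalog)
        b = sample_spectrum(model, TissueClass.NERVE, np.random.default_rng(11),
                            grid_wl=grid_wl, catalog=catalog)
        assert a.allclose(b)

    def test_reference_bone_class_is_calcium_dominated(self, model, grid_wl, catalog):
        for seed in range(5):
            s = sample_spectrum(model, TissueClass.HEALTHY_BONE_REF,
                                np.random.default_rng(seed), grid_wl=grid_wl, catalog=catalog)
            assert s.meta["target_ca_sum"] > s.meta["target_k_sum"]

    def test_lines_stay_below_reference_peak(self, model, grid_wl, catalog):
        """Even the winsorization bound keeps analyte lines below the base peak."""
        for cls in TissueClass:
            for seed in range(10):
                s = sample_spectrum(model, cls, np.random.default_rng(seed),
                                    grid_wl=grid_wl, catalog=catalog, gain=1.0)
                ref_idx = np.argmin(np.abs(s.wavelengths - model.reference_peak_nm))
                assert s.intensities.max() == pytest.approx(float(s.intensities[ref_idx]), rel=1e-6)


class TestGenerateDataset:
    def test_default_counts_sum_to_published_total(self, model, grid_wl, catalog):
        spec = DatasetSpec()
        assert sum(spec.counts.values()) == 3049
        assert spec.counts[TissueClass.NERVE] == 516

    def test_zero_counts_give_empty_dataset(self, model, grid_wl, catalog):
        spec = DatasetSpec(counts={cls: 0 for cls in TissueClass}, seed=1)
        assert generate_dataset(model, spec, grid_wl=grid_wl, catalog=catalog) == []

    def test_same_seed_same_dataset(self, model, grid_wl, catalog):
        spec = DatasetSpec(counts={TissueClass.NERVE: 3, TissueClass.FIBROSIS: 2}, seed=9)
        d1 = generate_dataset(model, spec, grid_wl=grid_wl, catalog=catalog)
        d2 = generate_dataset(model, spec, grid_wl=grid_wl, catalog=catalog)
        assert len(d1) == len(d2) == 5
        assert all(a.allclose(b) for a, b in zip(d1, d2))

    def test_changing_one_class_count_leaves_others_untouched(self, model, grid_wl, catalog):
        base = generate_dataset(
            model, DatasetSpec(counts={TissueClass.NERVE: 3, TissueClass.FIBROSIS: 2}, seed=9),
            grid_wl=grid_wl, catalog=catalog,
        )
        more = generate_dataset(
            model, DatasetSpec(counts={TissueClass.NERVE: 3, TissueClass.FIBROSIS: 4}, seed=9),
            grid_wl=grid_wl, catalog=catalog,
        )
        nerve_base = [s for s in base if s.tissue is TissueClass.NERVE]
        nerve_more = [s for s in more if s.tissue is TissueClass.NERVE]
        assert all(a.allclose(b) for a, b in zip(nerve_base, nerve_more))


class TestDistributionalProperties:
    def test_pipeline_recovers_calibration_median(self, model, grid_wl, catalog):
        """Measured nerve-class medians match the calibrated values within 5%."""
        spec = DatasetSpec(counts={TissueClass.NERVE: 500}, seed=3)
        spectra = generate_dataset(model, spec, grid_wl=grid_wl, catalog=catalog)
        feats = features_table(preprocess_all(spectra, catalog), catalog)
        ca = np.median([f.ca_sum for f in feats])
        k = np.median([f.k_sum for f in feats])
        assert ca == pytest.approx(model.classes[TissueClass.NERVE].ca.median, rel=0.05)
        assert k == pytest.approx(model.classes[TissueClass.NERVE].k.median, rel=0.05)

    def test_feature_level_medians_recover_all_classes(self, model):
        """Large feature-level samples reproduce every calibration median."""
        counts = {cls: 20_000 for cls in TissueClass}
        feats = sample_features(model, counts, seed=17)
        for cls in TissueClass:
            values = [(f.ca_sum, f.k_sum) for f in feats if f.tissue is cls]
            ca = np.median([v[0] for v in values])
            k = np.median([v[1] for v in values])
            assert ca == pytest.approx(model.classes[cls].ca.median, rel=0.05)
            assert k == pytest.approx(model.classes[cls].k.median, rel=0.05)

    def test_winsorization_leaves_median_unchanged(self, model):
        """Clipping the top 2.5% cannot move the median of the draws."""
        params = model.classes[TissueClass.TUMOR_STROMA].ca
        rng = np.random.default_rng(23)
        raw = params.sample(rng, 50_000, clip_quantile=None)
        clipped = np.minimum(raw, params.quantile(model.truncation_quantile))
        assert np.median(clipped) == np.median(raw)

    def test_measured_sum_monotone_in_calibration_median(self, model, grid_wl, catalog):
        boosted = dataclasses.replace(
            model,
            classes={
                **model.classes,
                TissueClass.NERVE: dataclasses.replace(
                    model.classes[TissueClass.NERVE],
                    ca=calibrate_lognormal(2 * 63.64, 15.07),
                ),
            },
        )
        spec = DatasetSpec(counts={TissueClass.NERVE: 200}, seed=3)
        base = features_table(preprocess_all(
            generate_dataset(model, spec, grid_wl=grid_wl, catalog=catalog), catalog), catalog)
        high = features_table(preprocess_all(
            generate_dataset(boosted, spec, grid_wl=grid_wl, catalog=catalog), catalog), catalog)
        assert np.mean([f.ca_sum for f in high]) > np.mean([f.ca_sum for f in base])
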