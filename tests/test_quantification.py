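"""Pattern metrics, body temperatures, block summaries and rates."""

import numpy as np
import pandas as pd
import pytest

from melanotherm.quantification import (
    PatternMetrics,
    block_summaries,
    body_temperature,
    pattern_metrics,
    prepare_thermal_table,
    summarize_individual,
    thermal_rates,
)
from melanotherm.segmentation import SegmentationConfig, segment_pattern
from melanotherm.synthetic import ImageGenParams, ThermalGenParams, generate_image, generate_thermal_cohort


class TestPatternMetrics:
    def test_against_generator_truth(self, spotted_image):
        seg = segment_pattern(spotted_image.record, SegmentationConfig(seed=0))
        m = pattern_metrics(spotted_image.record, seg)
        assert m.melanistic_proportion == pytest.approx(
            spotted_image.true_proportion, abs=0.035)
        px = spotted_image.record.pixels
        w = np.array([0.299, 0.587, 0.114])
        true_mel = (px[spotted_image.truth_mask] @ w).mean()
        true_non = (px[spotted_image.true_body_mask
                       & ~spotted_image.truth_mask] @ w).mean()
        assert m.mean_lum_mel == pytest.approx(true_mel, abs=0.02)
        assert m.mean_lum_nonmel == pytest.approx(true_non, abs=0.02)
        assert m.mean_lum_mel < m.mean_lum_nonmel

    def test_low_contrast_has_undefined_mel_luminance(self):
        si = generate_image(ImageGenParams(target_proportion=0.0, seed=1))
        seg = segment_pattern(si.record, SegmentationConfig(seed=0))
        m = pattern_metrics(si.record, seg)
        assert m.melanistic_proportion == 0.0
        assert m.mean_lum_mel is None

    def test_rejected_image_refused(self, spotted_image):
        seg = segment_pattern(spotted_image.record, SegmentationConfig(seed=0))
        seg.qc_accepted = False
        with pytest.raises(ValueError, match="rejected"):
            pattern_metrics(spotted_image.record, seg)

    def test_proportion_invariant_to_rescaling(self, spotted_image):
        from skimage.transform import rescale
        from melanotherm.imaging import ImageRecord
        rec = spotted_image.record
        px2 = np.clip(rescale(rec.pixels, 2, channel_axis=2, order=1), 0, 1)
        roi2 = rescale(rec.roi.astype(float), 2, order=0) > 0.5
        r0, c0, r1, c1 = rec.ref_region
        rec2 = ImageRecord(rec.individual_id, rec.seq_index, rec.block, px2,
                           (2 * r0, 2 * c0, 2 * r1, 2 * c1), roi2)
        p1 = segment_pattern(rec, SegmentationConfig(seed=0)).melanistic_proportion
        p2 = segment_pattern(rec2, SegmentationConfig(seed=0)).melanistic_proportion
        assert p2 == pytest.approx(p1, abs=0.01)


class TestSummarizeIndividual:
    def _metrics(self, props):
        return [PatternMetrics("g", i + 1, 1, p, 0.2, 0.6) for i, p in enumerate(props)]

    def test_mean_and_sample_sd(self):
        s = summarize_individual(self._metrics([0.1, 0.2, 0.3]))
        assert s.mean_proportion == pytest.approx(0.2)
        assert s.sd_proportion == pytest.approx(0.1)
        assert s.log_mean_proportion == pytest.approx(np.log(0.2))

    def test_constant_and_zero_cases(self):
        s = summarize_individual(self._metrics([0.2, 0.2, 0.2]))
        assert s.sd_proportion == pytest.approx(0.0, abs=1e-12)
        z = summarize_individual(self._metrics([0.0, 0.0]))
        assert z.log_mean_proportion is None

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize_individual([])


class TestBodyTemperature:
    def test_eye_average(self):
        assert body_temperature({"eye_L": 30.0, "eye_R": 30.4}) == pytest.approx(30.2)

    def test_snout_fallback(self):
        assert body_temperature({"eye_R": None, "eye_L": None, "snout": 29.8}) == 29.8
        assert body_temperature({"eye_L": np.nan, "eye_R": 31.0, "snout": 29.8}) == 29.8

    def test_all_missing(self):
        with pytest.raises(ValueError):
            body_temperature({"eye_L": np.nan, "eye_R": np.nan, "snout": np.nan})

    def test_table_body_temp_is_exact_eye_mean(self, null_cohort_params):
        cohort = generate_thermal_cohort(null_cohort_params)
        th = prepare_thermal_table(cohort.thermal)
        both = th.dropna(subset=["eye_L", "eye_R"])
        np.testing.assert_allclose(
            both["body_temp"], (both["eye_L"] + both["eye_R"]) / 2.0)


class TestBlocksAndRates:
    def test_simple_block_mean(self):
        df = pd.DataFrame({
            "individual_id": ["a"] * 15,
            "seq_index": range(1, 16),
            "block": [(t - 1) // 3 + 1 for t in range(1, 16)],
            "eye_L": [25.0] * 15,
            "eye_R": [25.0] * 15,
        })
        th = prepare_thermal_table(df)
        bs = block_summaries(th)
        assert (bs["mean_body_temp"] == 25.0).all()
        assert (bs["n_points"] == 3).all()

    def test_study_shaped_filter_counts(self, null_cohort_params):
        cohort = generate_thermal_cohort(null_cohort_params)
        th = prepare_thermal_table(cohort.thermal)
        # 12 individuals x 15 frames with 2 unusable IR frames -> 178 points
        assert th["body_temp"].notna().sum() == 178
        # 180 scheduled logger readings with one zero-flagged -> 179 usable
        loggers = th[["logger_cold", "logger_warm", "logger_hide"]]
        assert int(loggers.notna().all(axis=1).sum()) == 179
        assert th.attrs["n_logger_invalid"] == 1

    def test_rate_arithmetic(self):
        bs = pd.DataFrame({
            "individual_id": ["a"] * 5,
            "block": [1, 2, 3, 4, 5],
            "mean_body_temp": [24.8, 20.0, 16.0, 20.0, 24.2],
        })
        (r,) = thermal_rates(bs)
        assert r.cooling_rate == pytest.approx(8.8)
        assert r.heating_rate == pytest.approx(8.2)
        assert r.start_end_change == pytest.approx(-0.6)
        # conservation: start-end change is the difference of the two rates
        assert r.start_end_change == pytest.approx(r.heating_rate - r.cooling_rate)
        assert r.log_heating == pytest.approx(np.log(8.2))

    def test_flat_profile_rates(self):
        bs = pd.DataFrame({
            "individual_id": ["a"] * 5,
            "block": [1, 2, 3, 4, 5],
            "mean_body_temp": [25.0, 20.0, 15.0, 20.0, 25.0],
        })
        (r,) = thermal_rates(bs)
        assert r.cooling_rate == 10.0 and r.heating_rate == 10.0
        assert r.start_end_change == 0.0

    def test_non_positive_rate_flagged(self):
        bs = pd.DataFrame({
            "individual_id": ["a"] * 5,
            "block": [1, 2, 3, 4, 5],
            "mean_body_temp": [25.0, 25.0, 25.5, 25.0, 25.0],
        })
        (r,) = thermal_rates(bs)
        assert r.log_cooling is None and r.log_heating is None

    def test_missing_block_rejected(self):
        bs = pd.DataFrame({
            "individual_id": ["a"] * 2,
            "block": [1, 5],
            "mean_body_temp": [25.0, 25.0],
        })
        with pytest.raises(ValueError, match="missing block"):
            thermal_rates(bs)

    def test_recovered_proportion_tracks_truth(self):
        # per-individual mean over short image series vs generator truth
        from melanotherm.imaging import LightnessStandardizer
        from melanotherm.synthetic import generate_image_series
        truths, recovered = [], []
        for i, target in enumerate([0.02, 0.08, 0.15, 0.25, 0.35, 0.44]):
            series = generate_image_series(
                ImageGenParams(target_proportion=target, seed=600 + i), T=4,
                individual_id=f"g{i}")
            st = LightnessStandardizer().fit(series[0].record)
            props = []
            for f in series:
                rec = st.transform(f.record)
                props.append(segment_pattern(
                    rec, SegmentationConfig(seed=0)).melanistic_proportion)
            truths.append(np.mean([f.true_proportion for f in series]))
            recovered.append(np.mean(props))
        r = np.corrcoef(truths, recovered)[0, 1]
        assert r > 0.99
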