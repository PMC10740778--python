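"""Ingestion, robust outlier filtering, smoothing and daily alignment."""

import io
import warnings

import numpy as np
import pandas as pd
import pytest

import foragebudget as fb
from foragebudget.weights import WeightFormatError, filter_spurious_weights


def _csv(text: str) -> io.StringIO:
    return io.StringIO(text.strip() + "\n")


class TestIngestion:
    def test_well_formed_rows_become_records(self):
        df = fb.read_weight_records(
            _csv("animal_id,day,weight_kg\nA,0,240\nA,1,250\nB,0,245")
        )
        assert len(df) == 3
        assert df["weight_kg"].tolist() == [240.0, 250.0, 245.0]

    def test_non_positive_weight_dropped_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            df = fb.read_weight_records(
                _csv("animal_id,day,weight_kg\nA,0,240\nA,1,-5\nA,2,oops")
            )
        assert len(df) == 1
        assert "dropped 2" in caplog.text

    def test_dates_become_zero_based_day_offsets(self):
        df = fb.read_weight_records(
            _csv("animal_id,date,weight_kg\nA,2021-11-01,240\nA,2021-11-03,244")
        )
        assert df["day"].tolist() == [0, 2]

    def test_missing_columns_is_format_error(self):
        with pytest.raises(WeightFormatError):
            fb.read_weight_records(_csv("animal_id,weight_kg\nA,240"))
        with pytest.raises(WeightFormatError):
            fb.read_weight_records(_csv("id,day,kg\nA,0,240"))


def _records(days, weights, animal="A"):
    return pd.DataFrame(
        {"animal_id": animal, "day": list(days), "weight_kg": list(weights)}
    )


class TestSpuriousFilter:
    def test_single_spike_on_flat_series_is_flagged(self):
        """One 450 kg reading in a flat 300 kg month; cross-check with a
        brute-force median/MAD oracle on the residuals."""
        weights = [300.0] * 30
        weights[12] = 450.0
        rec = _records(range(30), weights)
        flagged = filter_spurious_weights(rec, residual_cutoff=3.0)
        assert flagged["flag"].tolist() == ["kept"] * 12 + ["outlier"] + ["kept"] * 17

        # oracle: residuals from the median, scaled by MAD of the clean part
        resid = np.abs(np.array(weights) - np.median(weights))
        oracle_outlier = resid > 3.0 * max(1.4826 * np.median(resid), 1e-6)
        assert (flagged["flag"].to_numpy() == "outlier").tolist() == oracle_outlier.tolist()

    def test_exact_linear_growth_has_no_flags(self):
        days = np.arange(40)
        rec = _records(days, 240 + 0.8 * days)
        assert (filter_spurious_weights(rec)["flag"] == "kept").all()

    def test_seeded_spikes_are_caught_without_many_false_positives(
        self, synthetic_run, cleaned_run
    ):
        """>=90% of injected +/-60 kg spikes flagged, <=2% of clean records."""
        _, _, _, truth = synthetic_run
        _, flagged = cleaned_run
        merged = flagged.merge(truth, on=["animal_id", "day", "weight_kg"])
        assert len(merged) == len(flagged)
        spikes = merged[merged["is_spurious"]]
        clean = merged[~merged["is_spurious"]]
        assert (spikes["flag"] == "outlier").mean() >= 0.90
        assert (clean["flag"] == "outlier").mean() <= 0.02

    def test_flags_are_permutation_invariant(self):
        rng = np.random.default_rng(7)
        days = np.arange(50)
        weights = 250 + 0.7 * days + rng.normal(0, 4, 50)
        weights[[5, 30]] += 80
        rec = _records(days, weights)
        base = filter_spurious_weights(rec).set_index("day")["flag"]
        shuffled = rec.sample(frac=1.0, random_state=3).reset_index(drop=True)
        perm = filter_spurious_weights(shuffled).set_index("day")["flag"]
        assert base.sort_index().equals(perm.sort_index())

    def test_too_few_records_pass_through_with_warning(self):
        rec = _records(range(4), [240, 241, 400, 243])
        with pytest.warns(fb.DataQualityWarning):
            flagged = filter_spurious_weights(rec)
        assert (flagged["flag"] == "kept").all()

    def test_all_records_same_day_falls_back_to_location_scale(self):
        rec = _records([3] * 10, [300, 301, 299, 300, 302, 298, 300, 301, 299, 420])
        flagged = filter_spurious_weights(rec)
        assert flagged.loc[flagged["weight_kg"] == 420, "flag"].item() == "outlier"
        assert (flagged["flag"] == "kept").sum() == 9


class TestSmoothing:
    def test_window_one_is_identity(self):
        x = np.array([100.0, 130.0, 100.0])
        np.testing.assert_array_equal(fb.smooth_weights(x, 1), x)

    def test_three_day_mean(self):
        out = fb.smooth_weights([100.0, 130.0, 100.0], 3)
        assert out[1] == pytest.approx(110.0)
        assert out[0] == pytest.approx(115.0)  # truncated edge window

    def test_constant_series_unchanged(self):
        np.testing.assert_allclose(fb.smooth_weights([5.0] * 9, 5), [5.0] * 9)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            fb.smooth_weights([1.0, 2.0], 2)


class TestAlignDaily:
    def test_interior_gap_linearly_interpolated(self):
        rec = _records([0, 2], [240.0, 244.0])
        series = fb.align_daily(rec, fb.GrazingPeriod(3))
        np.testing.assert_allclose(series.daily_bw, [240.0, 242.0, 244.0])
        assert series.day_flags.tolist() == ["kept", "imputed", "kept"]

    def test_same_day_visits_are_averaged(self):
        rec = _records([0, 0], [240.0, 244.0])
        series = fb.align_daily(rec, fb.GrazingPeriod(1))
        assert series.daily_bw[0] == pytest.approx(242.0)

    def test_long_trailing_gap_warns_and_carries_value(self):
        rec = _records([0], [240.0])
        with pytest.warns(fb.DataQualityWarning, match="1-4"):
            series = fb.align_daily(rec, fb.GrazingPeriod(5), max_gap_days=2)
        np.testing.assert_allclose(series.daily_bw, [240.0] * 5)
        assert series.day_flags.tolist() == ["kept"] + ["imputed"] * 4

    def test_zero_kept_records_is_hard_error(self):
        rec = _records([0, 1], [240.0, 241.0])
        rec["flag"] = "outlier"
        with pytest.raises(ValueError, match="A"):
            fb.align_daily(rec, fb.GrazingPeriod(3))

    def test_output_always_positive_and_complete(self, cleaned_run):
        herd, _ = cleaned_run
        assert np.isfinite(herd.values).all()
        assert (herd.values > 0).all()


class TestAssembleAndPipeline:
    def test_two_by_three_assembly_sorted_by_id(self):
        s1 = fb.CleanWeightSeries("b", [2.0, 2.0, 2.0], ["kept"] * 3)
        s2 = fb.CleanWeightSeries("a", [1.0, 1.0, 1.0], ["kept"] * 3)
        herd = fb.assemble_herd([s1, s2], fb.GrazingPeriod(3))
        assert herd.values.shape == (2, 3)
        assert herd.animal_ids == ("a", "b")
        assert herd.values[0, 0] == 1.0

    def test_empty_collection_rejected(self):
        with pytest.raises(ValueError):
            fb.assemble_herd([], fb.GrazingPeriod(3))

    def test_mismatched_lengths_rejected(self):
        s = fb.CleanWeightSeries("a", [1.0, 1.0], ["kept"] * 2)
        with pytest.raises(ValueError):
            fb.assemble_herd([s], fb.GrazingPeriod(3))

    def test_synthetic_heifer_herd_has_case_study_shape(self, cleaned_run):
        herd, _ = cleaned_run
        assert herd.values.shape == (60, 167)

    def test_clean_pipeline_is_identity_on_noise_free_linear_growth(self):
        days = np.arange(30)
        parts = []
        for animal, (b0, adg) in {"a": (240.0, 0.8), "b": (260.0, 0.5)}.items():
            parts.append(_records(days, b0 + adg * days, animal=animal))
        records = pd.concat(parts, ignore_index=True)
        herd, flagged = fb.clean_herd(records, fb.GrazingPeriod(30))
        assert (flagged["flag"] == "kept").all()
        expected = np.vstack([240.0 + 0.8 * days, 260.0 + 0.5 * days])
        # interior exactly; smoothing edges average a linear ramp asymmetrically
        np.testing.assert_allclose(herd.values[:, 1:-1], expected[:, 1:-1], rtol=1e-12)
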