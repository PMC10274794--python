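"""Cytoplasmic-marker normalization, regression and inversion."""

import math

import numpy as np
import pytest

from turgorkit import io as io_mod
from turgorkit import synth
from turgorkit.core import OsmoticCondition
from turgorkit.intensity import (
    IntensityCalibration,
    IntensityLinearFit,
    IntensityRecord,
    correct_and_normalize,
    fit_intensity_vs_concentration,
    invert_intensity,
    predict_intensity,
)


def _record(roi, bg, slide="s1", c=0.2):
    return IntensityRecord(
        condition=OsmoticCondition("x", c, 0.3),
        slide_id=slide,
        cell_id="cell",
        roi_mean=roi,
        background_mean=bg,
    )


CAL = {"s1": IntensityCalibration("s1", intact_mean=500.0)}


class TestNormalize:
    def test_background_correction_and_scaling(self):
        out = correct_and_normalize([_record(1100.0, 100.0)], CAL)
        assert out[0] == pytest.approx(2.0)

    def test_intact_population_self_normalizes_to_one(self, rng):
        intact = 500.0 + rng.normal(0, 25.0, 200)
        records = [_record(100.0 + v, 100.0) for v in intact]
        cal = {"s1": IntensityCalibration("s1", intact_mean=float(intact.mean()))}
        out = correct_and_normalize(records, cal)
        assert out.mean() == pytest.approx(1.0, rel=1e-12)

    def test_gain_invariance_per_slide(self):
        """Scaling roi, background and calibration of one slide by a common
        gain leaves normalized values unchanged."""
        base = correct_and_normalize([_record(1100.0, 100.0)], CAL)
        gained = correct_and_normalize(
            [_record(3.7 * 1100.0, 3.7 * 100.0)],
            {"s1": IntensityCalibration("s1", intact_mean=3.7 * 500.0)},
        )
        assert gained[0] == pytest.approx(base[0], rel=1e-12)

    def test_missing_calibration_rejected(self):
        with pytest.raises(ValueError, match="calibration"):
            correct_and_normalize([_record(1100.0, 100.0, slide="s9")], CAL)

    def test_nonpositive_corrected_flagged(self, caplog):
        with caplog.at_level("WARNING"):
            out = correct_and_normalize(
                [_record(90.0, 100.0), _record(1100.0, 100.0)], CAL
            )
        assert np.isnan(out[0]) and out[1] == pytest.approx(2.0)
        assert "excluded 1/2" in caplog.text

    def test_slide_factors_cancel_in_generator(self):
        """Slide calibration removes multiplicative slide factors: per-slide
        normalized condition means agree closely."""
        scen = synth.StudyScenario(
            true_internal_osmolarity=0.67,
            slide_factors=(0.8, 1.2),
            n_cells_per_condition=400,
            seed=7,
        )
        df = synth.gen_intensity_dataset(scen)
        df["normalized"] = np.nan
        for slide, group in df.groupby("slide_id"):
            intact = group[~group["is_protoplast"]]
            cal = (intact["roi_mean"] - intact["background_mean"]).mean()
            df.loc[group.index, "normalized"] = (
                group["roi_mean"] - group["background_mean"]
            ) / cal
        proto = df[df["is_protoplast"]]
        means = proto.groupby(["sorbitol_mol_per_L", "slide_id"])["normalized"].mean()
        for c in proto["sorbitol_mol_per_L"].unique():
            per_slide = means.loc[c].to_numpy()
            assert per_slide.max() / per_slide.min() < 1.02


class TestFit:
    def test_exact_line(self):
        c = np.array([0.1, 0.2, 0.3, 0.4])
        fit = fit_intensity_vs_concentration(c, 0.5 + 2.0 * c)
        assert fit.slope == pytest.approx(2.0, rel=1e-12)
        assert fit.intercept == pytest.approx(0.5, rel=1e-12)
        assert predict_intensity(fit, 0.25) == pytest.approx(1.0)

    def test_window_restricts_conditions(self):
        c = np.array([0.1, 0.2, 0.3, 0.4])
        fit = fit_intensity_vs_concentration(c, 0.5 + 2.0 * c, window=(0.15, 0.35))
        assert fit.fit_window == (0.2, 0.3)
        assert fit.n_points == 2
        with pytest.raises(ValueError):
            fit_intensity_vs_concentration(c, 0.5 + 2.0 * c, window=(0.35, 0.45))

    def test_per_cell_points_averaged_per_condition(self):
        c = np.array([0.1, 0.1, 0.3, 0.3])
        y = np.array([0.6, 0.8, 1.0, 1.2])
        fit = fit_intensity_vs_concentration(c, y)
        assert fit.slope == pytest.approx((1.1 - 0.7) / 0.2)

    def test_noisy_slope_within_errors(self, rng):
        c = np.repeat([0.1, 0.2, 0.3, 0.4, 0.5, 0.6], 100)
        y = 0.5 + 1.2 * c + rng.normal(0, 0.05, c.size)
        fit = fit_intensity_vs_concentration(c, y)
        se = math.sqrt(fit.param_covariance[0, 0])
        assert abs(fit.slope - 1.2) < 3 * se


class TestInvert:
    fit = IntensityLinearFit(
        slope=2.0, intercept=0.5, param_covariance=np.zeros((2, 2)),
        fit_window=(0.1, 0.4),
    )

    def test_algebra(self):
        est = invert_intensity(self.fit, 1.0)
        assert est.c_iso == pytest.approx(0.25)
        assert est.method == "intensity"
        assert est.note is None

    def test_target_at_intercept_gives_zero(self):
        assert invert_intensity(self.fit, 0.5).c_iso == 0.0

    def test_round_trip(self):
        for c in (0.12, 0.27, 0.39):
            y = predict_intensity(self.fit, c)
            assert invert_intensity(self.fit, y).c_iso == pytest.approx(c, rel=1e-12)

    def test_zero_slope_rejected(self):
        flat = IntensityLinearFit(0.0, 0.5, np.zeros((2, 2)), (0.1, 0.4))
        with pytest.raises(ValueError):
            invert_intensity(flat)

    def test_extrapolation_noted(self):
        est = invert_intensity(self.fit, 2.0)  # c_iso = 0.75, beyond window
        assert est.note is not None and "window" in est.note

    def test_error_terms(self):
        cov = np.diag([0.04, 0.0025])  # var(slope), var(intercept)
        fit = IntensityLinearFit(2.0, 0.5, cov, (0.1, 0.4))
        est = invert_intensity(fit, 1.0, intact_var=0.01)
        expected = math.sqrt(
            0.04 * (0.25 / 2.0) ** 2 + 0.0025 / 4.0 + 0.01 / 4.0
        )
        assert est.c_iso_err == pytest.approx(expected)


class TestSyntheticPipeline:
    def test_normalized_intensity_monotone_in_sorbitol(self):
        df = synth.gen_intensity_dataset(synth.default_intensity_scenario(3))
        est, fit = io_mod.run_intensity_method(df)
        proto = df[df["is_protoplast"]]
        corrected = proto["roi_mean"] - proto["background_mean"]
        means = corrected.groupby(proto["sorbitol_mol_per_L"]).mean()
        assert np.all(np.diff(means.to_numpy()) > 0)
        assert fit.slope > 0

    def test_noiseless_scenario_is_exact_at_isotonic(self):
        """With no noise and unit slide factors, the normalized intensity at
        the isotonic condition is exactly 1, and a condition at half the
        intact volume reads exactly 2 (inverse-volume law)."""
        scen = synth.StudyScenario(
            true_internal_osmolarity=0.70,
            sorbitol_grid=(0.2, 0.40, 2.15),  # 2.15 mol/L halves the volume
            intensity_noise_cv=0.0,
            slide_factors=(1.0,),
            n_cells_per_condition=10,
        )
        df = synth.gen_intensity_dataset(scen)
        corrected = df["roi_mean"] - df["background_mean"]
        intact_mean = corrected[~df["is_protoplast"]].mean()
        norm = corrected / intact_mean
        at_iso = norm[df["sorbitol_mol_per_L"] == 0.40]
        assert np.allclose(at_iso, 1.0, rtol=1e-9)
        half_volume_c = scen.m0 / (scen.intact_median_volume_um3 / 2 - scen.b0)
        assert half_volume_c - scen.medium_baseline_conc == pytest.approx(2.15)
        at_half = norm[df["sorbitol_mol_per_L"] == 2.15]
        assert np.allclose(at_half, 2.0, rtol=1e-9)

    def test_default_scenario_recovery(self):
        """Mean recovered isotonic concentration over 10 seeds is within 5%
        of the generating truth (0.37 mol/L sorbitol)."""
        recovered = []
        for seed in range(1, 11):
            df = synth.gen_intensity_dataset(synth.default_intensity_scenario(seed))
            est, _ = io_mod.run_intensity_method(df, window=(0.18, 0.52))
            recovered.append(est.c_iso)
        assert np.mean(recovered) == pytest.approx(0.37, rel=0.05)
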