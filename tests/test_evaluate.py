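"""Metrics, lift ratios, ideal image, artifact isolation, sweep analysis."""

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

from cavipact import evaluate as ev
from cavipact.acoustics import SensorArray, SensorData
from cavipact.fields import FieldMap, centered_origin
from cavipact.phantom import UNIFORM_MEDIA, build_arrangement
from cavipact.recon import ReconSpec


def _ssim_oracle(a, b):
    """Windowed SSIM from its defining moments (Gaussian window 11, s=1.5)."""
    k1, k2, L = 0.01, 0.03, 1.0
    c1, c2 = (k1 * L) ** 2, (k2 * L) ** 2
    f = lambda x: gaussian_filter(x, sigma=1.5, truncate=3.5)
    mu_a, mu_b = f(a), f(b)
    va = f(a * a) - mu_a**2
    vb = f(b * b) - mu_b**2
    cov = f(a * b) - mu_a * mu_b
    s = ((2 * mu_a * mu_b + c1) * (2 * cov + c2)) / (
        (mu_a**2 + mu_b**2 + c1) * (va + vb + c2))
    pad = 5  # skimage crops the filter radius
    return s[pad:-pad, pad:-pad].mean()


class TestMetrics:
    def test_identity_pair(self, rng):
        img = rng.random((16, 16))
        m = ev.metrics(img, img)
        assert m.mse == 0 and m.nae == 0
        assert m.ssim == pytest.approx(1.0)
        assert np.isinf(m.psnr)

    def test_unit_contrast_pair(self):
        ones, zeros = np.ones((8, 8)), np.zeros((8, 8))
        m = ev.metrics(ones, zeros)
        assert m.mse == pytest.approx(1.0)
        assert m.psnr == pytest.approx(0.0)
        assert m.nae == pytest.approx(1.0)

    def test_mse_nae_match_bruteforce(self, rng):
        a, b = rng.random((8, 8)), rng.random((8, 8))
        m = ev.metrics(a, b)
        mse = sum((a[i, j] - b[i, j]) ** 2 for i in range(8)
                  for j in range(8)) / 64
        nae = sum(abs(a[i, j] - b[i, j]) for i in range(8)
                  for j in range(8)) / np.abs(a).sum()
        assert m.mse == pytest.approx(mse, abs=1e-15)
        assert m.nae == pytest.approx(nae, abs=1e-15)
        assert m.psnr == pytest.approx(10 * np.log10(1 / mse), abs=1e-9)

    def test_ssim_matches_windowed_oracle(self, rng):
        a = gaussian_filter(rng.random((48, 48)), 1.0)
        b = np.clip(a + 0.05 * rng.standard_normal((48, 48)), 0, 1)
        assert ev.metrics(a, b).ssim == pytest.approx(_ssim_oracle(a, b),
                                                      abs=1e-6)

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            ev.metrics(np.zeros((4, 4)), np.ones((4, 4)))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            ev.metrics(np.ones((4, 4)), np.ones((5, 5)))


class TestLiftRatio:
    def test_no_change_is_zero(self):
        assert ev.lift_ratio(10.0, 10.0) == 0.0

    def test_twenty_percent_gain(self):
        assert ev.lift_ratio(12.0, 10.0) == pytest.approx(0.20)

    def test_error_metric_sign_convention(self):
        # halving the MSE reports -50%
        assert ev.lift_ratio(0.25, 0.50) == pytest.approx(-0.50)

    def test_scale_consistency(self, rng):
        f, o = 3.7, 2.9
        assert ev.lift_ratio(5 * f, 5 * o) == pytest.approx(
            ev.lift_ratio(f, o))

    def test_epsilon_guard(self):
        with pytest.raises(ValueError, match="baseline"):
            ev.lift_ratio(1.0, 1e-15)

    def test_build_report_flags_undefined(self):
        ga = np.zeros((12, 12))
        ga[5, 5] = 1.0
        rep = ev.build_report(ga, ga, ga, gf_id="identity")
        # identical images: PSNR baseline infinite -> lift flagged
        assert rep.lift_ratios["psnr"] is None
        assert any("psnr" in f for f in rep.flags)
        assert rep.lift_ratios["ssim"] == pytest.approx(0.0)


class TestIdealImage:
    SPEC = ReconSpec(grid_shape=(200, 200), pitch=0.5)

    def test_s4_renders_single_blood_disk(self):
        model = build_arrangement("s4")
        ga = ev.ideal_image(model, self.SPEC)
        assert ga.values.max() == 1.0
        # one disk of radius 0.5 mm around (-10, 0)
        X, Y = ga.pixel_centers()
        on = ga.values > 0
        assert np.all(np.hypot(X[on] + 10.0, Y[on]) <= 0.5 + 1e-9)
        area = on.sum() * self.SPEC.pitch**2
        assert area == pytest.approx(np.pi * 0.25, rel=0.35)  # coarse disk

    def test_S5_renders_three_blood_disks(self):
        model = build_arrangement("S5")
        ga = ev.ideal_image(model, self.SPEC)
        X, Y = ga.pixel_centers()
        on = ga.values > 0
        expected = model.positions_of("blood")
        for x, y in zip(X[on], Y[on]):
            assert min(np.hypot(x - bx, y - by) for bx, by in expected) <= 0.5 + 1e-9
        # every blood position is represented
        for bx, by in expected:
            assert np.any(np.hypot(X[on] - bx, Y[on] - by) <= 0.5 + 1e-9)

    def test_no_absorber_rejected(self):
        model = build_arrangement("s1")  # air-only control
        with pytest.raises(ValueError, match="absorb"):
            ev.ideal_image(model, self.SPEC)


class TestIsolateArtifacts:
    def _field(self, values):
        return FieldMap(np.asarray(values, dtype=float), 1.0,
                        centered_origin(np.asarray(values).shape, 1.0))

    def test_identical_fields_cancel_exactly(self, rng):
        f = self._field(rng.random((20, 20)))
        out = ev.isolate_artifacts(f, f)
        assert np.all(out.values == 0)

    def test_additive_linearity(self, rng):
        a = self._field(rng.random((10, 10)))
        b = self._field(rng.random((10, 10)))
        ab = self._field(a.values + b.values)
        np.testing.assert_allclose(ev.isolate_artifacts(ab, a).values,
                                   b.values, atol=1e-14)

    def test_grid_mismatch_rejected(self, rng):
        a = self._field(rng.random((10, 10)))
        b = FieldMap(rng.random((10, 10)), 0.5, a.origin)
        with pytest.raises(ValueError, match="grid"):
            ev.isolate_artifacts(a, b)

    def test_sensor_data_difference(self, rng):
        arr = SensorArray(n_elements=4)
        a = SensorData(traces=rng.random((4, 64)), dt=1e-8, array=arr)
        b = SensorData(traces=rng.random((4, 64)), dt=1e-8, array=arr)
        out = ev.isolate_artifacts(a, b)
        np.testing.assert_allclose(out.traces, a.traces - b.traces)

    def test_mixed_types_rejected(self, rng):
        arr = SensorArray(n_elements=4)
        a = SensorData(traces=rng.random((4, 64)), dt=1e-8, array=arr)
        with pytest.raises(TypeError):
            ev.isolate_artifacts(a, self._field(rng.random((4, 4))))


class TestFitSemicircle:
    def _arc_image(self, radius, center=(0.0, 0.0), span=(0, 180)):
        shape = (201, 201)
        origin = centered_origin(shape, 0.5)
        img = np.zeros(shape)
        theta = np.deg2rad(np.linspace(*span, 500))
        x = center[0] + radius * np.cos(theta)
        y = center[1] + radius * np.sin(theta)
        col = np.round((x - origin[0]) / 0.5).astype(int)
        row = np.round((origin[1] - y) / 0.5).astype(int)
        img[row, col] = 1.0
        return FieldMap(img, 0.5, origin)

    def test_half_circle_recovered(self):
        prof = ev.fit_semicircle(self._arc_image(20.0), threshold=0.5)
        assert np.hypot(*prof.center_xy) <= 1.0
        assert prof.radius == pytest.approx(20.0, abs=0.5)
        assert 150 <= prof.arc_span <= 210

    def test_full_circle_recovered(self):
        prof = ev.fit_semicircle(self._arc_image(15.0, span=(0, 360)))
        assert prof.arc_span >= 350
        assert prof.radius == pytest.approx(15.0, abs=0.5)

    def test_offcentre_circle(self):
        prof = ev.fit_semicircle(self._arc_image(10.0, center=(5.0, -3.0)))
        assert abs(prof.center_xy[0] - 5.0) <= 1.0
        assert abs(prof.center_xy[1] + 3.0) <= 1.0

    def test_too_few_pixels_rejected(self):
        shape = (50, 50)
        img = np.zeros(shape)
        img[25, 25] = 1.0
        field = FieldMap(img, 1.0, centered_origin(shape, 1.0))
        with pytest.raises(ValueError, match="10 pixels"):
            ev.fit_semicircle(field)


class TestSweepAnalysis:
    def _rows(self, waists, adf, nlm):
        rows = []
        for w, a, n in zip(waists, adf, nlm):
            row = {"waist_mm": float(w), "unstable": w < 8.0}
            for metric in ev.METRIC_NAMES:
                sign = 1.0 if metric in ev.POSITIVE_METRICS else -1.0
                row[f"adf_{metric}_lift"] = sign * a
                row[f"nlm_{metric}_lift"] = sign * n
                row[f"ratio_{metric}"] = a / n
            rows.append(row)
        return rows

    def test_constructed_crossover_located_between_16_and_18(self):
        waists = [10, 12, 14, 16, 18, 20]
        ratios = np.array([0.7, 0.8, 0.9, 0.95, 1.1, 1.2])
        found = ev.find_crossovers(waists, ratios, smooth_window=1)
        assert len(found) == 1
        assert 16 < found[0] < 18

    def test_no_crossing_returns_empty(self):
        assert ev.find_crossovers([1, 2, 3], [1.2, 1.4, 1.3]) == []

    def test_nan_segments_skipped(self):
        found = ev.find_crossovers([1, 2, 3, 4], [0.5, np.nan, 1.5, 1.6],
                                   smooth_window=1)
        assert found == []

    def test_trend_crossover_from_shapes(self):
        # ADF's improvement peaks late, NLM's peaks mid-sweep: normalised
        # trends must cross in between
        waists = [5, 8, 11, 14, 17, 20]
        adf = [0.001, 0.002, 0.003, 0.005, 0.008, 0.010]
        nlm = [0.004, 0.010, 0.012, 0.011, 0.009, 0.007]
        rows = self._rows(waists, adf, nlm)
        crossings = ev.trend_crossovers(rows)
        for metric in ev.METRIC_NAMES:
            assert len(crossings[metric]) >= 1
            assert 8 < crossings[metric][0] < 20

    def test_normalized_trends_span_unit_interval(self):
        rows = self._rows([5, 10, 15], [0.01, 0.02, 0.03], [0.3, 0.2, 0.1])
        trends = ev.normalized_trends(rows)
        for metric in ev.METRIC_NAMES:
            for f in ("adf", "nlm"):
                assert trends[metric][f].min() == 0.0
                assert trends[metric][f].max() == 1.0

    def test_empty_waist_list_rejected(self):
        with pytest.raises(ValueError, match="waist"):
            ev.waist_sweep("s4", [])


class TestUniformPipeline:
    def test_case_products_are_consistent(self, s4_case):
        go, ga = s4_case["go"], s4_case["ga"]
        assert go.values.shape == ga.values.shape
        assert 0.0 <= go.values.min() and go.values.max() == 1.0
        assert s4_case["sensor"].traces.shape == (128, 4096)
        # P0 under uniform light: only the blood tube emits
        p0 = s4_case["p0"]
        labels = s4_case["labels"]
        from cavipact.phantom import LABELS
        assert np.all((p0.values > 0) == (labels.values == LABELS["blood"]))

    def test_artifact_profile_matches_air_geometry(self, s4_paired):
        prof = s4_paired["profile"]
        (ax, ay), = s4_paired["air_positions"]
        assert np.hypot(prof.center_xy[0] - ax, prof.center_xy[1] - ay) <= 2.0
        d = np.hypot(s4_paired["blood_positions"][0][0] - ax,
                     s4_paired["blood_positions"][0][1] - ay)
        assert abs(prof.radius - d) / d <= 0.15

    def test_frozen_params_recorded(self):
        assert ev.FROZEN_ADF_PARAMS.coefficient == "exponential"
        assert ev.FROZEN_NLM_PARAMS.search_radius >= ev.FROZEN_NLM_PARAMS.patch_radius
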