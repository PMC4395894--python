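"""Biomechanical parameter extraction and unit conversion."""

import numpy as np
import pytest

from corvispy.contours import ContourSet
from corvispy.decomposition import (
    DeformationField,
    compute_deformation_field,
    fft_amplitude_map,
    highpass_vibration,
    split_eyeball_cornea,
)
from corvispy.parameters import (
    ParameterConfig,
    asymmetry_and_side,
    amplitude_metrics,
    build_report,
    compute_ratios,
    convert_units,
    corneal_length_change,
    detect_applanations,
    highest_concavity,
    max_flat_run,
    vibration_metrics,
)

from conftest import contours_from_truth, small_scene
from corvispy.synthetic import compute_ground_truth


def make_contours(outer: np.ndarray, thickness: float = 12.0, height: int = 200) -> ContourSet:
    t, w = outer.shape
    ones = np.ones((t, w), dtype=bool)
    return ContourSet(outer=outer, inner=outer + thickness, valid_outer=ones,
                      valid_inner=ones.copy(), height=height, width=w, n_frames=t)


def decomposed(outer: np.ndarray, baseline_frames=3, margin=20) -> tuple:
    cs = make_contours(outer)
    field = compute_deformation_field(cs, baseline_frames=baseline_frames)
    split_eyeball_cornea(field, scleral_margin=margin)
    highpass_vibration(field, 100.0)
    return cs, field, fft_amplitude_map(field)


class TestApplanations:
    def test_static_flat_contour_applanates_at_first_frame(self):
        outer = np.full((20, 300), 80.0)
        cs, field, _ = decomposed(outer)
        cfg = ParameterConfig(applanation_halfwidth=120)
        app1, _, _ = detect_applanations(field, cs, cfg)
        assert app1.time_frames == 0
        assert app1.velocity_px_per_frame == 0.0
        assert app1.length_px >= cfg.min_applanation_len_px

    def test_rigid_translation_of_curved_contour_never_applanates(self):
        cols = np.arange(300.0)
        arc = 40 + (cols - 150) ** 2 / 150  # strongly curved everywhere
        outer = arc[None, :] + np.linspace(0, 10, 20)[:, None]
        cs, field, _ = decomposed(outer)
        app1, app2, diag = detect_applanations(field, cs, ParameterConfig(applanation_halfwidth=120))
        assert app1 is None and app2 is None
        assert diag["n_flat_frames"] == 0

    def test_flat_run_length_and_location(self):
        cols = np.arange(300.0)
        y = (cols - 150) ** 2 / 100
        y[120:181] = y[120]  # 61 flat columns
        length, start = max_flat_run(y, tol=0.4, min_len=50)
        assert length >= 61
        assert start <= 120 <= start + length

    def test_no_flat_run_returns_zero(self):
        cols = np.arange(300.0)
        y = (cols - 150) ** 2 / 100
        assert max_flat_run(y, tol=0.1, min_len=50) == (0, None)


class TestHighestConcavity:
    def test_circular_arc_radius_within_one_percent(self):
        # deepest frame: exact circular arc of radius 180 between two crests
        cols = np.arange(400.0)
        r_true = 180.0
        x = cols - 200
        deformed = np.where(
            np.abs(x) <= 120,
            150.0 - (r_true - np.sqrt(np.clip(r_true**2 - x * x, 0, None))),
            150.0 - (r_true - np.sqrt(r_true**2 - 120.0**2))
            + 0.004 * (np.abs(x) - 120) ** 2,
        )
        outer = np.full((6, 400), 100.0)
        outer[3] = deformed
        cs = make_contours(outer)
        field = compute_deformation_field(cs, baseline_frames=1)
        split_eyeball_cornea(field, scleral_margin=30)
        hc = highest_concavity(field, cs)
        assert hc.time_frames == 3
        assert hc.peak_cols is not None
        assert hc.radius_px == pytest.approx(r_true, rel=0.01)

    def test_straight_contour_radius_flagged_infinite(self):
        outer = np.full((5, 300), 90.0)
        outer[2] += 3.0
        cs = make_contours(outer)
        field = compute_deformation_field(cs, baseline_frames=1)
        split_eyeball_cornea(field, scleral_margin=30)
        hc = highest_concavity(field, cs)
        assert np.isinf(hc.radius_px)
        assert hc.peak_distance_px is None

    def test_peak_distance_between_constructed_crests(self):
        cols = np.arange(576.0)
        outer = np.full((4, 576), 100.0)
        bump = 40 * np.exp(-((cols - 288) ** 2) / (2 * 60**2))
        sag = (cols - 288) ** 2 / 4000.0
        outer[2] = 100 + sag + bump
        cs = make_contours(outer)
        field = compute_deformation_field(cs, baseline_frames=1)
        split_eyeball_cornea(field, scleral_margin=50)
        hc = highest_concavity(field, cs)
        # analytic crest columns: d/dx (x^2/800) = d/dx bump
        assert hc.peak_cols is not None
        lcol, rcol = hc.peak_cols
        assert hc.peak_distance_px == rcol - lcol
        assert abs((288 - lcol) - (rcol - 288)) <= 2  # symmetric
        assert 100 < hc.peak_distance_px < 400


class TestAmplitudes:
    def test_zero_field_gives_zero_metrics(self):
        field = DeformationField(baseline=np.zeros(100), full=np.zeros((10, 100)))
        split_eyeball_cornea(field, scleral_margin=20)
        m = amplitude_metrics(field)
        assert all(v == 0.0 for v in m.values())

    def test_mirrored_field_preserves_absolute_reaction(self):
        rng = np.random.default_rng(0)
        full = rng.normal(0, 5, (12, 100))
        f1 = DeformationField(baseline=np.zeros(100), full=full)
        split_eyeball_cornea(f1, 20)
        f2 = DeformationField(baseline=np.zeros(100), full=-full)
        split_eyeball_cornea(f2, 20)
        m1, m2 = amplitude_metrics(f1), amplitude_metrics(f2)
        assert m1["absolute_cornea_reaction_px"] == pytest.approx(
            m2["absolute_cornea_reaction_px"], abs=1e-12
        )


class TestCornealLength:
    def test_undeformed_contour_has_zero_change(self):
        cols = np.arange(300.0)
        arc = 40 + (cols - 150) ** 2 / 500
        outer = np.tile(arc, (8, 1))
        cs = make_contours(outer)
        dl = corneal_length_change(cs, arc)
        np.testing.assert_allclose(dl, 0.0, atol=1e-9)

    def test_rigid_translation_invariant(self):
        cols = np.arange(300.0)
        arc = 40 + (cols - 150) ** 2 / 500
        outer = arc[None, :] + np.linspace(0, 7, 8)[:, None]
        cs = make_contours(outer)
        dl = corneal_length_change(cs, arc)
        np.testing.assert_allclose(dl, 0.0, atol=1e-9)

    def test_gaussian_bump_matches_quadrature_oracle(self):
        from scipy.integrate import quad

        cols = np.arange(576.0)
        base = np.full(576, 100.0)
        a, sigma, c0 = 30.0, 50.0, 287.5

        def deriv(x):
            return -a * (x - c0) / sigma**2 * np.exp(-((x - c0) ** 2) / (2 * sigma**2))

        oracle, _ = quad(lambda x: np.sqrt(1 + deriv(x) ** 2) - 1.0, 0, 575, limit=400)
        outer = np.vstack([base, base + a * np.exp(-((cols - c0) ** 2) / (2 * sigma**2))])
        cs = make_contours(outer)
        dl = corneal_length_change(cs, base)
        assert dl[1] == pytest.approx(oracle, rel=0.01)


class TestRatios:
    def test_arithmetic(self):
        r1, _ = compute_ratios(60.0, np.array([1.0, 12.0, 3.0]), 100.0)
        assert r1 == pytest.approx(5.0)

    def test_zero_deformation_gives_zero_ratios(self):
        assert compute_ratios(0.0, np.zeros(5), 100.0) == (0.0, 0.0)

    def test_zero_denominator_flagged_undefined(self):
        r1, r2 = compute_ratios(10.0, np.zeros(5), 0.0)
        assert r1 is None and r2 is None


class TestVibrationMetrics:
    def test_zero_vibration(self):
        field = DeformationField(baseline=np.zeros(50), full=np.zeros((140, 50)))
        split_eyeball_cornea(field, 10)
        highpass_vibration(field, 100.0)
        assert vibration_metrics(field, 0.1) == (0.0, 0)

    def test_threshold_above_amplitude_gives_zero_duration(self):
        field = DeformationField(baseline=np.zeros(50), full=np.zeros((140, 50)))
        split_eyeball_cornea(field, 10)
        highpass_vibration(field, 100.0)
        field.vibration = 0.3 * np.sin(np.linspace(0, 40, 140))[:, None] * np.ones((1, 50))
        amp, dur = vibration_metrics(field, threshold_px=1.0)
        assert amp == pytest.approx(0.3, abs=0.01)
        assert dur == 0

    def test_gated_sinusoid_duration_near_envelope_crossing(self):
        # 300 Hz, 1 px, raised-cosine gate over frames 40-90, threshold 0.5 px
        from corvispy.synthetic import _gate

        t = np.arange(140.0)
        dt = 231e-6
        gate = _gate(t, 40.0, 90.0, 10.0)
        sig = gate * np.sin(2 * np.pi * 300 * t * dt)
        cornea = np.tile(sig[:, None], (1, 8))
        field = DeformationField(
            baseline=np.zeros(8), full=cornea.copy(),
            eyeball=np.zeros_like(cornea), cornea=cornea.copy(), scleral_margin=2,
        )
        highpass_vibration(field, 100.0)
        amp, dur = vibration_metrics(field, threshold_px=0.5)
        expected = int((gate > 0.5).sum())  # ground-truth envelope crossing
        assert abs(dur - expected) <= 4
        assert amp == pytest.approx(1.0, abs=0.15)


class TestAsymmetry:
    def test_symmetric_motion_is_undetermined(self):
        field = DeformationField(baseline=np.zeros(100), full=np.ones((10, 100)))
        split_eyeball_cornea(field, 20)
        score, label = asymmetry_and_side(field)
        assert score == pytest.approx(0.0, abs=1e-12)
        assert label == "undetermined"

    def test_tilt_scores_left_and_mirrors_to_right(self):
        # left scleral anchor 3 px, right anchor 1 px at peak
        tilt = np.interp(np.arange(100.0), [19, 80], [3.0, 1.0])
        tilt[:20] = 3.0
        tilt[80:] = 1.0
        full = np.tile(tilt, (10, 1)) * np.linspace(0, 1, 10)[:, None]
        field = DeformationField(baseline=np.zeros(100), full=full)
        split_eyeball_cornea(field, 20)
        score, label = asymmetry_and_side(field)
        assert score == pytest.approx(2.0, abs=0.05)
        assert label == "left"

        mirrored = DeformationField(baseline=np.zeros(100), full=full[:, ::-1].copy())
        split_eyeball_cornea(mirrored, 20)
        mscore, mlabel = asymmetry_and_side(mirrored)
        assert mscore == pytest.approx(-score, abs=1e-9)
        assert mlabel == "right"


class TestConvertUnits:
    @pytest.mark.parametrize(
        "value,axis,decimals,expected",
        [
            (29, "temporal", 1, 6.7),
            (96, "temporal", 1, 22.2),
            (323, "temporal", 1, 74.6),
            (66.6, "spatial", 1, 10.0),
            (20.7, "spatial", 1, 3.1),
            (0.2, "spatial", 2, 0.03),
            (0, "spatial", 1, 0.0),
            (0, "temporal", 1, 0.0),
        ],
    )
    def test_calibration_worked_examples(self, value, axis, decimals, expected):
        assert convert_units(value, axis, 0.15, 231.0, decimals) == expected

    def test_rounding_half_away_from_zero(self):
        assert convert_units(1.0, "spatial", 0.25, decimals=1) == 0.3
        assert convert_units(-1.0, "spatial", 0.25, decimals=1) == -0.3

    def test_unknown_axis_rejected(self):
        with pytest.raises(ValueError, match="axis"):
            convert_units(1.0, "radial")

    def test_nonpositive_calibration_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            convert_units(1.0, "spatial", pixel_pitch_mm=0.0)


@pytest.fixture(scope="module")
def scene_report():
    truth = compute_ground_truth(small_scene(bump_sigma_px=20.0, n_frames=60,
                                             bump_onset_frame=10, bump_peak_frame=30,
                                             bump_offset_frame=50,
                                             eyeball_peak_frame=35,
                                             eyeball_offset_frame=59,
                                             vibration_amplitude_px=0.3))
    cs = contours_from_truth(truth, height=80)
    field = compute_deformation_field(cs, baseline_frames=6)
    split_eyeball_cornea(field, scleral_margin=30)
    highpass_vibration(field, 100.0)
    spec = fft_amplitude_map(field)
    pconf = ParameterConfig(applanation_halfwidth=80, min_applanation_len_px=40)
    return truth, cs, field, spec, pconf


class TestReport:
    def test_event_ordering_invariant(self, scene_report):
        truth, cs, field, spec, pconf = scene_report
        report = build_report(cs, field, spec, pconf, baseline_frames=6)
        assert (
            report.applanation1_time_frames
            < report.highest_concavity_time_frames
            < report.applanation2_time_frames
        )

    def test_translation_changes_only_static_ratio(self, scene_report):
        truth, cs, field, spec, pconf = scene_report
        base = build_report(cs, field, spec, pconf, baseline_frames=6)

        shifted = contours_from_truth(truth, height=80)
        shifted.outer += 10.0
        shifted.inner += 10.0
        f2 = compute_deformation_field(shifted, baseline_frames=6)
        split_eyeball_cornea(f2, scleral_margin=30)
        highpass_vibration(f2, 100.0)
        moved = build_report(shifted, f2, fft_amplitude_map(f2), pconf, baseline_frames=6)

        assert moved.max_cornea_deformation_px == pytest.approx(
            base.max_cornea_deformation_px, abs=1e-9
        )
        assert moved.applanation1_time_frames == base.applanation1_time_frames
        assert moved.asymmetry_score_px == pytest.approx(base.asymmetry_score_px, abs=1e-9)
        assert moved.ratio_reaction_over_static != pytest.approx(
            base.ratio_reaction_over_static, abs=1e-6
        )

    def test_json_roundtrip_and_physical_units(self, scene_report, tmp_path):
        import json

        truth, cs, field, spec, pconf = scene_report
        report = build_report(cs, field, spec, pconf, baseline_frames=6)
        report.to_json(tmp_path / "r.json")
        data = json.loads((tmp_path / "r.json").read_text())
        assert data["physical"]["max_cornea_deformation_mm"] == pytest.approx(
            report.max_cornea_deformation_px * 0.15
        )
        assert data["physical"]["highest_concavity_time_ms"] == pytest.approx(
            report.highest_concavity_time_frames * 0.231
        )
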