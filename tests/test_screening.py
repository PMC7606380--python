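"""Single-event screening: derivative, alignment, event location, WLC, work."""

import numpy as np
import pytest

from smfe.curves import ForceDistanceCurve, ScreeningParams, ValidationError, kbt_pn_nm
from smfe.screening import (
    CurveRejected,
    align_baseline,
    detect_binding_minimum,
    detect_rupture,
    fit_wlc,
    integrate_work,
    locate_state_A,
    screen_curve,
    screen_dataset,
    significant_maxima,
    windowed_derivative,
    wlc_force,
)
from smfe.synthetic import gen_dataset, gen_fdc, wlc_work_kbt


def _plain_curve(force, spacing=0.1):
    z = spacing * np.arange(len(force))
    return ForceDistanceCurve(separation=z, force=np.asarray(force, float))


class TestDerivative:
    def test_step_gives_single_maximum_at_step(self):
        force = np.where(np.arange(300) < 120, -80.0, 0.0)
        curve = _plain_curve(force)
        deriv, r = windowed_derivative(curve)
        peaks = significant_maxima(deriv)
        assert peaks.size == 1
        assert abs(peaks[0] - 120) <= r

    def test_straight_line_has_no_significant_maxima(self):
        curve = _plain_curve(3.0 * 0.1 * np.arange(200))
        deriv, _ = windowed_derivative(curve)
        assert significant_maxima(deriv).size == 0
        assert np.allclose(deriv[10:-10], 3.0, atol=1e-8)

    def test_synthetic_rupture_located_within_radius(self):
        curve, ann = gen_fdc("single_event", work_target=150.0, noise_sd=6.0, seed=2)
        idx, n_events, r = detect_rupture(curve, ScreeningParams())
        assert n_events == 1
        assert abs(idx - ann["index_B"]) <= r

    def test_two_ruptures_farthest_wins(self):
        curve, ann = gen_fdc("double_rupture", noise_sd=4.0, seed=5)
        idx, n_events, r = detect_rupture(curve, ScreeningParams())
        assert n_events == 2
        assert abs(idx - ann["rupture_indices"][1]) <= r

    def test_flat_noise_is_rejected(self):
        curve, _ = gen_fdc("flat", noise_sd=6.0, seed=3)
        with pytest.raises(CurveRejected):
            detect_rupture(curve, ScreeningParams())

    def test_curve_too_short_for_derivative(self):
        # bypass dataclass length floor to probe the derivative guard directly
        z = np.linspace(0, 1, 4)
        curve = ForceDistanceCurve.__new__(ForceDistanceCurve)
        curve.separation, curve.force = z, np.zeros(4)
        curve.temperature, curve.label, curve.pulling_rate = 298.15, "", None
        with pytest.raises(ValidationError):
            windowed_derivative(curve)


class TestBaseline:
    def test_drift_removed_and_noise_recovered(self):
        rng = np.random.default_rng(11)
        n = 1000
        z = 0.1 * np.arange(n)
        noise_sd = 5.0
        force = 7.0 + 0.3 * z + rng.normal(0, noise_sd, n)
        curve = ForceDistanceCurve(separation=z, force=force)
        aligned, sigma = align_baseline(curve, rupture_index=n // 2, alpha_frac=0.5)
        tail = aligned.force[n // 2 + 5:]
        assert abs(np.mean(tail)) < 3 * noise_sd / np.sqrt(tail.size)
        assert sigma == pytest.approx(noise_sd, rel=0.15)

    def test_zero_noise_tail_gives_zero_sigma(self):
        z = 0.1 * np.arange(200)
        curve = ForceDistanceCurve(separation=z, force=np.zeros(200))
        _, sigma = align_baseline(curve, rupture_index=100, alpha_frac=0.5)
        assert sigma == pytest.approx(0.0, abs=1e-10)

    def test_too_few_baseline_points_is_error(self):
        z = 0.1 * np.arange(100)
        curve = ForceDistanceCurve(separation=z, force=np.zeros(100))
        with pytest.raises(CurveRejected):
            align_baseline(curve, rupture_index=95, alpha_frac=0.5)


class TestBindingMinimum:
    @staticmethod
    def _screened_steps(curve, params):
        rupture, _, r = detect_rupture(curve, params)
        width = 2 * r + 1
        aligned, sigma = align_baseline(curve, rupture, params.alpha_frac, margin=width)
        return rupture, width, aligned, sigma

    def test_deep_dip_detected_then_rejected_at_higher_lod(self):
        # rupture force ~8 sigma: visible at lod 5.5, invisible at lod 9
        curve, ann = gen_fdc("single_event", work_target=111.0, contour_length=50.0,
                             noise_sd=6.0, seed=21)
        params = ScreeningParams()
        rupture, width, aligned, sigma = self._screened_steps(curve, params)
        idx = detect_binding_minimum(aligned, rupture, sigma, lod=5.5, kernel_width=width)
        assert abs(idx - ann["index_B"]) <= 2 * width
        with pytest.raises(CurveRejected):
            detect_binding_minimum(aligned, rupture, sigma, lod=9.0, kernel_width=width)

    def test_all_positive_curve_is_rejected(self):
        rng = np.random.default_rng(0)
        z = 0.1 * np.arange(500)
        force = np.abs(rng.normal(0, 1.0, 500)) + 1.0
        curve = ForceDistanceCurve(separation=z, force=force)
        with pytest.raises(CurveRejected):
            detect_binding_minimum(curve, rupture_index=400, sigma=1.0, lod=3.0)


class TestStateA:
    @staticmethod
    def _upstream(curve, params):
        rupture, _, r = detect_rupture(curve, params)
        width = 2 * r + 1
        aligned, sigma = align_baseline(curve, rupture, params.alpha_frac, margin=width)
        binding = detect_binding_minimum(aligned, rupture, sigma, params.lod,
                                         kernel_width=width)
        return aligned, sigma, binding, width

    def test_noise_free_zero_crossing_found_near_true_anchor(self):
        curve, ann = gen_fdc("single_event", work_target=80.0, noise_sd=0.0, seed=1)
        params = ScreeningParams()
        aligned, sigma, binding, width = self._upstream(curve, params)
        idx = locate_state_A(aligned, binding, sigma, params.mul_base, kernel_width=width)
        assert abs(idx - ann["index_A"]) <= width

    def test_zero_band_on_noisy_data_rejects(self):
        curve, _ = gen_fdc("single_event", work_target=150.0, noise_sd=6.0, seed=4)
        params = ScreeningParams()
        aligned, sigma, binding, width = self._upstream(curve, params)
        with pytest.raises(CurveRejected):
            locate_state_A(aligned, binding, sigma, mul_base=1e-12, kernel_width=width)

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_widening_band_never_moves_anchor_away_from_rupture(self, seed):
        curve, _ = gen_fdc("single_event", work_target=150.0, noise_sd=6.0, seed=seed)
        params = ScreeningParams()
        aligned, sigma, binding, width = self._upstream(curve, params)
        indices = [
            locate_state_A(aligned, binding, sigma, mb, kernel_width=width)
            for mb in (1.0, 2.0, 3.0, 4.0)
        ]
        assert all(a <= b for a, b in zip(indices, indices[1:]))


class TestWLC:
    def test_zero_extension_gives_zero_force(self):
        assert wlc_force(0.0, 60.0) == 0.0

    def test_half_extension_reference_value(self):
        # (kbt/l_p) * 1.25 at T=298.15, l_p=0.37
        assert wlc_force(30.0, 60.0) == pytest.approx(13.91, rel=1e-3)

    def test_force_monotone_and_divergent(self):
        g = np.linspace(0, 59.9, 500)
        f = wlc_force(g, 60.0)
        assert np.all(np.diff(f) > 0)
        assert f[-1] > 1000.0

    def test_extension_beyond_contour_is_domain_error(self):
        with pytest.raises(ValidationError):
            wlc_force(60.0, 60.0)

    def test_noiseless_contour_recovered(self):
        L = 60.0
        g = np.linspace(0, 0.85 * L, 300)
        force = -wlc_force(g, L)  # attractive sign convention
        contour, residual = fit_wlc(g, force)
        assert contour == pytest.approx(L, rel=1e-3)
        assert residual < 1e-6

    def test_noisy_residual_tracks_noise_level(self):
        rng = np.random.default_rng(8)
        L, noise_sd = 60.0, 10.0
        g = np.linspace(0, 0.85 * L, 400)
        force = -(wlc_force(g, L) + rng.normal(0, noise_sd, g.size))
        contour, residual = fit_wlc(g, force)
        # mean |N(0, sd)| = sd*sqrt(2/pi) ~ 7.98
        assert residual == pytest.approx(noise_sd * np.sqrt(2 / np.pi), rel=0.2)
        assert residual <= 3.0 * noise_sd
        assert residual > 0.01 * noise_sd

    def test_linear_segment_fits_badly(self):
        g = np.linspace(0, 40, 200)
        force = -2.0 * g  # Hookean, not WLC
        _, residual = fit_wlc(g, force)
        assert residual > 1.0


class TestWork:
    def test_zero_force_gives_zero_work(self):
        z = 0.1 * np.arange(100)
        curve = ForceDistanceCurve(separation=z, force=np.zeros(100))
        assert integrate_work(curve, 0, 99) == 0.0

    def test_rectangular_pulse_is_exact(self):
        z = 0.1 * np.arange(200)
        force = np.zeros(200)
        force[50:151] = -20.0  # 20 pN over 10 nm
        curve = ForceDistanceCurve(separation=z, force=force)
        expected = 20.0 * 10.0 / kbt_pn_nm(298.15)
        assert integrate_work(curve, 50, 150) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("work_target", [40.0, 80.0, 300.0])
    def test_trapezoid_matches_wlc_closed_form(self, work_target):
        curve, ann = gen_fdc("single_event", work_target=work_target, noise_sd=0.0, seed=6)
        w = integrate_work(curve, ann["index_A"], ann["index_B"])
        assert w == pytest.approx(ann["work_kbt"], rel=1e-3)
        assert ann["work_kbt"] == pytest.approx(work_target, rel=1e-6)


class TestScreenDataset:
    def test_known_composition_recovered(self, mixed_screened, mixed_dataset):
        events, qc = mixed_screened
        _, annotations = mixed_dataset
        kind_by_label = {a["label"]: a["kind"] for a in annotations}
        # every accepted curve is a true single event
        assert all(kind_by_label[e.label] == "single_event" for e in events)
        # most of the 40 true events survive; boundary cases may drop out
        assert 30 <= len(events) <= 40
        rejected = qc[qc.disposition == "rejected"]
        assert set(rejected.step) <= {
            "rupture", "multiple_events", "baseline", "binding", "state_a", "wlc", "work",
        }
        # double-rupture curves are rejected, never split
        doubles = [a["label"] for a in annotations if a["kind"] == "double_rupture"]
        assert set(doubles) <= set(rejected.label)

    def test_raising_lod_never_gains_events(self, mixed_dataset):
        curves, _ = mixed_dataset
        counts = []
        for lod in (3.0, 5.5, 9.0):
            events, _ = screen_dataset(curves, ScreeningParams(lod=lod))
            counts.append(len(events))
        assert counts[0] >= counts[1] >= counts[2]

    def test_empty_input_gives_empty_output(self):
        events, qc = screen_dataset([], ScreeningParams())
        assert events == [] and len(qc) == 0

    def test_drift_invariance_of_recovered_work(self):
        rng = np.random.default_rng(17)
        works = rng.gamma(4.42, 1 / 0.023, size=15)
        compared = 0
        for i, target in enumerate(works):
            plain, _ = gen_fdc("single_event", work_target=float(target), seed=100 + i)
            drifted, _ = gen_fdc("single_event", work_target=float(target),
                                 drift_slope=0.05, seed=100 + i)
            params = ScreeningParams()
            try:
                w0 = screen_curve(plain, params).work_kbt
                w1 = screen_curve(drifted, params).work_kbt
            except CurveRejected:
                continue  # same stochastic boundary case either way
            compared += 1
            assert w1 == pytest.approx(w0, rel=0.02)
        assert compared >= 8

    def test_work_sample_mean_recovered(self, screened_single_events, single_event_dataset):
        events, _, annotations = screened_single_events
        _, anns = single_event_dataset
        generated = np.array([a["work_kbt"] for a in anns])
        recovered = np.array([e.work_kbt for e in events])
        assert len(events) >= 150
        assert recovered.mean() == pytest.approx(generated.mean(), rel=0.05)
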