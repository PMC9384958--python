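"""Replicate statistics, quadratic calibration, inversion, LOD and risk labels."""

import numpy as np
import pytest

from lfaquant import (
    CalibrationError,
    CalibrationPoint,
    RunConfig,
    StripMeasurement,
    analyze_strip,
    classify_risk,
    dilution_series,
    estimate_concentration,
    fit_calibration,
    lod_estimate,
    noise_free_ratio_fn,
    render_strip,
    replicate_stats,
)


def meas(tb, cb=0.6):
    """Minimal StripMeasurement carrying the given ratios."""
    return StripMeasurement(
        control_pos=150, control_value=120.0, test_pos=90, test_value=tb * 200,
        background_mean=200.0, background_sd=0.0,
        ratio_tb=tb, ratio_cb=cb, ratio_tc=tb / cb,
    )


def exact_points(a2, a1, a0, concs):
    return [
        CalibrationPoint(c, a2 * c**2 + a1 * c + a0, 0.0, 1) for c in concs
    ]


class TestReplicateStats:
    def test_constant_group(self):
        pts = replicate_stats([meas(0.6)] * 3, [100] * 3)
        assert pts[0].mean_ratio == 0.6
        assert pts[0].sd_ratio == 0.0
        assert pts[0].n_replicates == 3

    def test_two_replicates_hand_sd(self):
        pts = replicate_stats([meas(0.5), meas(0.7)], [100, 100])
        assert pts[0].mean_ratio == pytest.approx(0.6)
        assert pts[0].sd_ratio == pytest.approx(np.sqrt(0.02))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            replicate_stats([], [])

    def test_matches_brute_force_on_phantom_series(self, phantom_cfg, det_cfg):
        strips = dilution_series([0.0, 296.0], 5, phantom_cfg, seed=3)
        ms = [
            analyze_strip(img, phantom_cfg.roi, det_cfg, keep_audit=False)
            for img, _ in strips
        ]
        labels = [t.concentration for _, t in strips]
        pts = replicate_stats(ms, labels)
        for p in pts:
            vals = [m.ratio_tb for m, c in zip(ms, labels) if c == p.concentration]
            assert p.mean_ratio == pytest.approx(sum(vals) / len(vals))
            assert p.sd_ratio == pytest.approx(np.std(vals, ddof=1))


class TestFitCalibration:
    def test_exact_line_recovered(self):
        pts = exact_points(0.0, -0.001, 1.0, [0, 100, 250, 400, 600])
        curve = fit_calibration(pts)
        assert curve.coeffs == pytest.approx((0.0, -0.001, 1.0), abs=1e-12)
        assert curve.residual_rmse == pytest.approx(0.0, abs=1e-12)

    def test_coefficients_equal_normal_equations(self, rng):
        concs = np.array([0, 50, 150, 300, 450, 600], dtype=float)
        ratios = 1 - 0.001 * concs + rng.normal(0, 0.01, len(concs))
        pts = [CalibrationPoint(c, r, 0.0, 1) for c, r in zip(concs, ratios)]
        curve = fit_calibration(pts)
        # independent closed-form solution of the normal equations
        V = np.vander(concs, 3)
        beta = np.linalg.solve(V.T @ V, V.T @ ratios)
        assert curve.coeffs == pytest.approx(tuple(beta), rel=1e-6)

    def test_noise_free_phantom_ladder_near_quadratic(self, run_cfg):
        """The saturating band-darkness law is close to quadratic over the
        working range: the fit to noise-free ladder ratios is tight."""
        fn = noise_free_ratio_fn(run_cfg)
        pts = [
            CalibrationPoint(c, fn(c), 0.0, 1) for c in run_cfg.concentrations
        ]
        curve = fit_calibration(pts)
        assert curve.residual_rmse < 0.02

    def test_too_few_points_rejected(self):
        pts = exact_points(0.0, -0.001, 1.0, [0, 300])
        with pytest.raises(CalibrationError, match="3 distinct"):
            fit_calibration(pts)

    def test_increasing_fit_rejected(self):
        pts = [CalibrationPoint(c, 0.5 + 0.001 * c, 0.0, 1) for c in [0, 200, 500]]
        with pytest.raises(CalibrationError, match="non_monotone"):
            fit_calibration(pts)

    def test_vertex_inside_range_truncates_working_range(self):
        # parabola turning at c=500: usable range ends just below the vertex
        pts = exact_points(1e-6, -0.001, 1.0, [0, 100, 200, 350, 500, 600])
        curve = fit_calibration(pts)
        assert curve.working_hi == pytest.approx(499.0, abs=1e-6)
        assert curve.is_monotone_decreasing()
        with pytest.raises(CalibrationError, match="non_monotone"):
            fit_calibration(pts, clip_range_to_vertex=False)


@pytest.fixture(scope="module")
def curve():
    return fit_calibration(
        exact_points(5e-7, -0.0012, 1.0, [0, 100, 200, 300, 450, 600])
    )


class TestEstimateConcentration:

    def test_inversion_identity(self, curve):
        q = estimate_concentration(curve, curve(300.0))
        assert q.estimated_concentration == pytest.approx(300.0, abs=1.0)
        assert q.censoring == "none"

    def test_round_trip_across_interior(self, curve):
        for c in np.linspace(10, 590, 30):
            q = estimate_concentration(curve, curve(c))
            assert q.estimated_concentration == pytest.approx(c, abs=1.0)

    def test_above_blank_censored_low(self, curve):
        q = estimate_concentration(curve, 1.2)
        assert q.censoring == "below_working_range"
        assert q.estimated_concentration == curve.working_lo

    def test_below_saturation_censored_high(self, curve):
        q = estimate_concentration(curve, 0.05)
        assert q.censoring == "saturated"
        assert q.estimated_concentration == curve.working_hi

    def test_round_trip_on_noisy_phantoms_at_200(self, run_cfg):
        """Quantify 20 noisy strips at 200 ng/ml against a curve calibrated
        from an independent seed; median relative error within 10%.

        Uses the control-normalised (test-control) ratio, which cancels the
        common per-strip amplitude jitter."""
        strips = dilution_series(
            run_cfg.concentrations, run_cfg.replicates, run_cfg.phantom, 0
        )
        ms = [
            analyze_strip(img, run_cfg.phantom.roi, run_cfg.detection, keep_audit=False)
            for img, _ in strips
        ]
        labels = [t.concentration for _, t in strips]
        curve = fit_calibration(
            replicate_stats(ms, labels, "ratio_tc"), "ratio_tc"
        )
        seeds = np.random.SeedSequence(1).generate_state(20)
        errs = []
        for s in seeds:
            img, _ = render_strip(200.0, run_cfg.phantom, int(s % 2**31))
            m = analyze_strip(
                img, run_cfg.phantom.roi, run_cfg.detection, keep_audit=False
            )
            q = estimate_concentration(curve, m.ratio_tc)
            errs.append(abs(q.estimated_concentration - 200.0) / 200.0)
        assert np.median(errs) <= 0.10


class TestLodEstimate:
    def langmuir_ratio(self, c):
        return (200.0 - 160.0 * c / (c + 300.0)) / 200.0

    def test_default_rule_on_ideal_response(self):
        # gap at 50 ng/ml is 0.114 < 0.14; gap at 100 is 0.200 > 0.14
        assert lod_estimate(self.langmuir_ratio) == 100.0

    def test_tiny_sigma_gives_smallest_grid_point(self):
        assert lod_estimate(self.langmuir_ratio, sigma_r=1e-9) == 25.0

    def test_huge_k_not_reached(self):
        assert lod_estimate(self.langmuir_ratio, k=1e6) is None

    def test_grid_without_blank_rejected(self):
        with pytest.raises(ValueError, match="blank"):
            lod_estimate(self.langmuir_ratio, grid=(25, 100))

    def test_monotone_in_sigma_and_k(self):
        prev = 0.0
        for sig in [0.01, 0.04, 0.07, 0.12, 0.2]:
            lod = lod_estimate(self.langmuir_ratio, sigma_r=sig)
            lod = np.inf if lod is None else lod
            assert lod >= prev
            prev = lod
        prev = 0.0
        for k in [0.5, 1, 2, 4, 8]:
            lod = lod_estimate(self.langmuir_ratio, k=k)
            lod = np.inf if lod is None else lod
            assert lod >= prev
            prev = lod


class TestClassifyRisk:
    @pytest.mark.parametrize(
        "conc, risk, band",
        [
            (0.0, "negative", "negative"),
            (108.9, "negative", "negative"),
            (109.0, "low", "low"),
            (249.9, "low", "low"),
            (250.0, "high_risk", "low"),
            (370.0, "high_risk", "high"),
            (1000.0, "high_risk", "high"),
        ],
    )
    def test_thresholds(self, conc, risk, band):
        assert classify_risk(conc) == (risk, band)

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            classify_risk(-5.0)

    def test_risk_call_robust_away_from_boundary(self, run_cfg):
        """Across 200 noisy strips, the high-risk call agrees with the true
        concentration's side of 250 ng/ml in >= 90% of strips whose truth is
        outside the grey zone [200, 300]."""
        strips = dilution_series(run_cfg.concentrations, 20, run_cfg.phantom, 0)
        ms = [
            analyze_strip(img, run_cfg.phantom.roi, run_cfg.detection, keep_audit=False)
            for img, _ in strips
        ]
        labels = [t.concentration for _, t in strips]
        curve = fit_calibration(
            replicate_stats(ms, labels, "ratio_tc"), "ratio_tc"
        )
        agree = total = 0
        for m, c in zip(ms, labels):
            if 200 <= c <= 300:
                continue
            q = estimate_concentration(curve, m.ratio_tc)
            total += 1
            agree += (q.estimated_concentration >= 250) == (c >= 250)
        assert total >= 100
        assert agree / total >= 0.90
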