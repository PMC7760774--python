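"""Synthetic cohort generator: calibration, sampling, rendering contracts."""
import numpy as np
import pytest

from critspeed import GeneratorConfig, compute_allout, process_gxt, process_verification
from critspeed.qc import pacing_check
from critspeed.synthetic import (
    CalibrationError,
    calibrate_sex_cs_distributions,
    design_protocol_for,
    render_allout_trace,
    render_gxt_series,
    render_pacing_violation,
    sample_athletes,
)


def population_arrays(config, n):
    cfg = config.replace(n_athletes=n)
    athletes = sample_athletes(cfg)
    cs = np.array([a.true_cs for a in athletes])
    vo2 = np.array([a.true_vo2max for a in athletes])
    return athletes, cs, vo2


class TestCalibration:
    def test_reproduces_pooled_moments_and_correlation(self, calibrated_config):
        _, cs, vo2 = population_arrays(calibrated_config, 100_000)
        assert cs.mean() == pytest.approx(3.56, abs=0.02)
        assert cs.std(ddof=1) == pytest.approx(0.55, abs=0.02)
        r = np.corrcoef(cs, vo2)[0, 1]
        assert r == pytest.approx(0.819, abs=0.015)

    def test_same_seed_same_parameters(self):
        a = calibrate_sex_cs_distributions(GeneratorConfig(seed=5))
        b = calibrate_sex_cs_distributions(GeneratorConfig(seed=5))
        assert a == b

    def test_degenerate_noiseless_single_sex(self):
        cfg = GeneratorConfig(residual_sd=0.0, male_fraction=1.0)
        with pytest.raises(CalibrationError, match="degenerate"):
            calibrate_sex_cs_distributions(cfg)
        # the underlying population correlation really is exactly 1
        manual = cfg.replace(
            cs_mean_male=3.56, cs_sd_male=0.55, cs_mean_female=3.56, cs_sd_female=0.55
        )
        _, cs, vo2 = population_arrays(manual, 2_000)
        assert np.corrcoef(cs, vo2)[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_unreachable_target_raises_with_diagnostic(self):
        cfg = GeneratorConfig(r_target=0.99)
        with pytest.raises(CalibrationError, match="no gap"):
            calibrate_sex_cs_distributions(cfg)


class TestSampleAthletes:
    def test_empty_cohort(self, calibrated_config):
        assert sample_athletes(calibrated_config.replace(n_athletes=0)) == []

    def test_flags_first_pacing_then_vp(self, calibrated_config):
        cfg = calibrated_config.replace(
            n_athletes=37, n_pacing_violators=9, n_vp_violators=3
        )
        athletes = sample_athletes(cfg)
        assert sum(a.is_pacing_violator for a in athletes) == 9
        assert sum(a.is_vp_violator for a in athletes) == 3
        assert all(a.is_pacing_violator for a in athletes[:9])
        assert all(a.is_vp_violator for a in athletes[9:12])
        assert not any(
            a.is_pacing_violator or a.is_vp_violator for a in athletes[12:]
        )

    def test_too_many_violators_rejected(self, calibrated_config):
        cfg = calibrated_config.replace(
            n_athletes=5, n_pacing_violators=4, n_vp_violators=2
        )
        with pytest.raises(ValueError, match="violators"):
            sample_athletes(cfg)

    def test_noiseless_prediction_arithmetic(self):
        # CS = 1.0 m/s, male, no residual: 8.449 + 4.387 + 14.683
        cfg = GeneratorConfig(
            n_athletes=3,
            male_fraction=1.0,
            residual_sd=0.0,
            cs_mean_male=1.0,
            cs_sd_male=0.0,
            cs_mean_female=1.0,
            cs_sd_female=0.0,
        )
        athletes = sample_athletes(cfg)
        for a in athletes:
            assert a.true_vo2max == pytest.approx(27.519, abs=1e-12)

    def test_truncations_and_get_below_vo2max(self, calibrated_config):
        athletes, cs, vo2 = population_arrays(calibrated_config, 20_000)
        assert cs.min() > 1.0
        assert min(a.true_dprime for a in athletes) > 50.0
        assert all(a.true_get < a.true_vo2max for a in athletes)

    def test_same_seed_identical_athletes(self, calibrated_config):
        a = sample_athletes(calibrated_config.replace(n_athletes=10))
        b = sample_athletes(calibrated_config.replace(n_athletes=10))
        assert a == b


class TestPacingViolation:
    def test_violation_trips_screen_and_honest_does_not(self, calibrated_config):
        cfg = calibrated_config.replace(n_athletes=6, n_pacing_violators=3)
        athletes = sample_athletes(cfg)
        for athlete in athletes:
            proto = design_protocol_for(athlete)
            gxt = process_gxt(render_gxt_series(athlete, proto, cfg), proto)
            if athlete.is_pacing_violator:
                trace = render_pacing_violation(athlete, cfg)
            else:
                trace = render_allout_trace(athlete, cfg)
            res = compute_allout(trace)
            passed, dev = pacing_check(res.cs, gxt.fifty_delta)
            assert passed is not athlete.is_pacing_violator, (
                f"athlete {athlete.id}: deviation {dev:.3f}"
            )

    def test_zero_target_deviation_passes_screen(self, calibrated_config):
        cfg = calibrated_config.replace(n_athletes=1)
        athlete = sample_athletes(cfg)[0]
        proto = design_protocol_for(athlete)
        gxt = process_gxt(render_gxt_series(athlete, proto, cfg), proto)
        res = compute_allout(render_pacing_violation(athlete, cfg, 0.0))
        passed, _ = pacing_check(res.cs, gxt.fifty_delta)
        assert passed

    def test_negative_target_rejected(self, calibrated_config):
        athlete = sample_athletes(calibrated_config.replace(n_athletes=1))[0]
        with pytest.raises(ValueError):
            render_pacing_violation(athlete, calibrated_config, -0.01)


class TestGXTRender:
    def test_phases_contiguous_and_complete(self, calibrated_config):
        athlete = sample_athletes(calibrated_config.replace(n_athletes=1))[0]
        gas = render_gxt_series(athlete, design_protocol_for(athlete), calibrated_config)
        phases = [p for p, _ in __import__("itertools").groupby(gas.phase)]
        assert phases == ["rest", "warmup", "ramp", "recovery", "verification"]
        assert np.all(gas.grade[gas.phase == "ramp"] == 0.03)

    def test_noiseless_get_recovery_within_one_bin(self, calibrated_config):
        cfg = calibrated_config.replace(n_athletes=8)
        for athlete in sample_athletes(cfg):
            proto = design_protocol_for(athlete)
            gas = render_gxt_series(athlete, proto, cfg, noiseless=True)
            gxt = process_gxt(gas, proto)
            # one 15-s bin of VO2 along the ramp
            bin_step = np.diff(gxt.binned["vo2"].to_numpy()).max()
            assert abs(gxt.get_vo2 - athlete.true_get) <= bin_step

    def test_verification_pass_fail_by_injection(self, calibrated_config):
        cfg = calibrated_config.replace(n_athletes=4, n_vp_violators=2)
        for athlete in sample_athletes(cfg):
            proto = design_protocol_for(athlete)
            gas = render_gxt_series(athlete, proto, cfg)
            gxt = process_gxt(gas, proto)
            vp = process_verification(gxt.vo2max, gas)
            assert vp.accepted is not athlete.is_vp_violator

    def test_misdesigned_protocol_rejected(self, calibrated_config):
        from critspeed import GXTProtocol

        athlete = sample_athletes(calibrated_config.replace(n_athletes=1))[0]
        lazy = GXTProtocol(increment_per_min=0.01, start_speed=3.0)
        with pytest.raises(ValueError, match="26 min"):
            render_gxt_series(athlete, lazy, calibrated_config)

    def test_seeded_determinism(self, calibrated_config):
        athlete = sample_athletes(calibrated_config.replace(n_athletes=1))[0]
        proto = design_protocol_for(athlete)
        a = render_gxt_series(athlete, proto, calibrated_config)
        b = render_gxt_series(athlete, proto, calibrated_config)
        assert np.array_equal(a.vo2, b.vo2)
        assert np.array_equal(a.vco2, b.vco2)


class TestEndToEndStructure:
    def test_extraction_fidelity_median_cs_error(self, calibrated_config):
        cfg = calibrated_config.replace(n_athletes=2_000)
        athletes = sample_athletes(cfg)
        errors = []
        for athlete in athletes:
            res = compute_allout(render_allout_trace(athlete, cfg))
            errors.append(abs(res.cs - athlete.true_cs))
        assert np.median(errors) < 0.02
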