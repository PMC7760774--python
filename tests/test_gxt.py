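"""GXT processing: binning, VO2max rule, v-slope, speeds, verification."""
import numpy as np
import pandas as pd
import pytest

from critspeed import GasSeries, GXTProtocol
from critspeed.gxt import (
    InsufficientDataError,
    _hinge_fit,
    _smooth3,
    _vo2_axis,
    bin_15s,
    design_protocol,
    detect_get_vslope,
    flat_equivalent,
    invert_running_demand,
    lagged_speed_at,
    process_gxt,
    process_verification,
    running_demand,
    vo2max_two_highest,
)


def gas_series(vo2, phase="ramp", vco2=None, t0=0.0):
    vo2 = np.asarray(vo2, dtype=float)
    n = vo2.size
    if vco2 is None:
        vco2 = 0.9 * vo2
    return GasSeries(
        time=t0 + np.arange(n, dtype=float),
        vo2=vo2,
        vco2=np.asarray(vco2, dtype=float),
        speed=np.full(n, 5.0),
        grade=np.full(n, 0.03),
        phase=np.full(n, phase, dtype=object),
    )


def binned_frame(vo2, vco2, dt=15.0):
    vo2 = np.asarray(vo2, dtype=float)
    return pd.DataFrame(
        {
            "t_end": dt * (np.arange(vo2.size) + 1),
            "vo2": vo2,
            "vco2": np.asarray(vco2, dtype=float),
        }
    )


def piecewise_vco2(vo2, break_at=32.5, below=0.85, above=1.15):
    vo2 = np.asarray(vo2, dtype=float)
    return np.where(
        vo2 <= break_at,
        below * vo2,
        below * break_at + above * (vo2 - break_at),
    )


class TestBin15s:
    def test_constant_minute_gives_four_bins(self):
        b = bin_15s(gas_series(np.full(60, 40.0)), "ramp")
        assert len(b) == 4
        assert np.allclose(b["vo2"], 40.0)
        assert np.allclose(b["t_end"], [15, 30, 45, 60])

    def test_linear_signal_bin_means_match_closed_form(self):
        # vo2(t) = 30 + 0.2 t sampled at 1 Hz: bin mean = 30 + 0.2 * mean(t in bin)
        t = np.arange(60)
        b = bin_15s(gas_series(30.0 + 0.2 * t), "ramp")
        expected = [30 + 0.2 * np.arange(j * 15, (j + 1) * 15).mean() for j in range(4)]
        assert np.allclose(b["vo2"], expected)

    def test_missing_phase_errors(self):
        with pytest.raises(ValueError, match="verification"):
            bin_15s(gas_series(np.full(60, 40.0)), "verification")

    def test_partial_trailing_bin_dropped(self):
        b = bin_15s(gas_series(np.full(70, 40.0)), "ramp")
        assert len(b) == 4


class TestVo2maxTwoHighest:
    @pytest.mark.parametrize(
        "bins, expected",
        [([40, 45, 50, 48], 49.0), ([30, 35, 40, 45], 42.5)],
    )
    def test_worked_examples(self, bins, expected):
        vmax, _ = vo2max_two_highest(binned_frame(bins, bins))
        assert vmax == expected

    def test_time_is_end_of_later_bin_and_ties_break_early(self):
        vmax, t = vo2max_two_highest(binned_frame([50, 48, 48, 50], [0] * 4))
        assert vmax == 49.0
        assert t == 30.0  # earlier of the two tied pairs

    def test_matches_exhaustive_pair_scan(self, rng):
        for _ in range(50):
            vo2 = rng.normal(45, 3, size=rng.integers(2, 40))
            vmax, _ = vo2max_two_highest(binned_frame(vo2, vo2))
            oracle = max((vo2[i] + vo2[i + 1]) / 2 for i in range(vo2.size - 1))
            assert vmax == pytest.approx(oracle, abs=1e-12)

    def test_appending_lower_bins_never_changes_result(self, rng):
        vo2 = rng.normal(45, 3, size=20)
        vmax, t = vo2max_two_highest(binned_frame(vo2, vo2))
        extended = np.concatenate([vo2, np.full(5, vmax - 5)])
        vmax2, t2 = vo2max_two_highest(binned_frame(extended, extended))
        assert (vmax2, t2) == (vmax, t)

    def test_single_bin_errors(self):
        with pytest.raises(InsufficientDataError):
            vo2max_two_highest(binned_frame([40], [36]))


def naive_vslope_oracle(binned, min_segment=3, min_slope_gap=0.10):
    """Independent exhaustive reimplementation of the shipped detector."""
    x = _vo2_axis(binned)
    y = _smooth3(binned["vco2"].to_numpy(float))
    order = np.argsort(x, kind="stable")
    x, y = x[order], y[order]
    candidates = []
    for k in range(min_segment, x.size - min_segment + 1):
        xk = 0.5 * (x[k - 1] + x[k])
        h = np.maximum(0.0, x - xk)
        X = np.column_stack([np.ones_like(x), x, h])
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        if coef[2] < min_slope_gap:
            continue
        rss = float(((y - X @ coef) ** 2).sum())
        candidates.append((rss, xk))
    return min(candidates)[1] if candidates else None


class TestVslope:
    def test_noiseless_breakpoint_within_half_spacing(self):
        vo2 = np.linspace(25, 45, 41)
        b = binned_frame(vo2, piecewise_vco2(vo2))
        get = detect_get_vslope(b)
        assert get == pytest.approx(32.5, abs=0.5 * 0.5)

    def test_perfectly_linear_reports_no_breakpoint(self):
        vo2 = np.linspace(25, 45, 41)
        assert detect_get_vslope(binned_frame(vo2, 0.9 * vo2)) is None

    def test_insufficient_bins_error(self):
        vo2 = np.linspace(25, 45, 7)
        with pytest.raises(InsufficientDataError):
            detect_get_vslope(binned_frame(vo2, piecewise_vco2(vo2)))

    @pytest.mark.parametrize(
        "noise_sd, tolerance, min_hit_rate",
        [
            (0.25, 1.5, 0.95),  # generator's default bin noise
            (0.5, 3.0, 0.90),  # doubled noise: breakpoint info halves
        ],
    )
    def test_monte_carlo_accuracy_under_noise(self, rng, noise_sd, tolerance, min_hit_rate):
        """Breakpoint recovery accuracy across seeded noisy replicates."""
        vo2 = np.linspace(25, 45, 41)
        reps, hits = 200, 0
        for _ in range(reps):
            vco2 = piecewise_vco2(vo2) + rng.normal(0, noise_sd, vo2.size)
            get = detect_get_vslope(binned_frame(vo2, vco2))
            if get is not None and abs(get - 32.5) <= tolerance:
                hits += 1
        assert hits / reps >= min_hit_rate

    def test_matches_naive_exhaustive_oracle(self, rng):
        for i in range(30):
            n = int(rng.integers(10, 200))
            vo2 = np.sort(rng.uniform(20, 50, n))
            breakpoint = rng.uniform(28, 42)
            vco2 = piecewise_vco2(vo2, break_at=breakpoint) + rng.normal(0, 0.5, n)
            b = binned_frame(vo2, vco2)
            ours = detect_get_vslope(b)
            oracle = naive_vslope_oracle(b)
            if oracle is None:
                assert ours is None
            else:
                assert ours == pytest.approx(oracle, abs=1e-9)

    def test_hinge_fit_matches_lstsq(self, rng):
        x = np.sort(rng.uniform(20, 50, 30))
        y = piecewise_vco2(x) + rng.normal(0, 0.3, 30)
        a, b_, c, rss = _hinge_fit(x, y, 33.0)
        X = np.column_stack([np.ones_like(x), x, np.maximum(0, x - 33.0)])
        ref, *_ = np.linalg.lstsq(X, y, rcond=None)
        assert np.allclose([a, b_, c], ref, atol=1e-9)


class TestLaggedSpeed:
    def test_one_minute_lag_to_ramp_start(self):
        proto = GXTProtocol(increment_per_min=0.5)
        speed, clamped = lagged_speed_at(proto, 15.0 * 5)  # sample j=4
        assert speed == 5.0 and not clamped

    def test_quarter_stage_interpolation(self):
        proto = GXTProtocol(increment_per_min=0.5)
        speed, _ = lagged_speed_at(proto, 15.0 * 9)  # j=8 -> lagged j=4
        assert speed == pytest.approx(5.5)

    def test_lag_before_ramp_clamps_with_flag(self):
        proto = GXTProtocol(increment_per_min=0.5)
        speed, clamped = lagged_speed_at(proto, 15.0 * 3)  # j=2
        assert speed == 5.0 and clamped

    def test_after_ramp_end_errors(self):
        proto = GXTProtocol(increment_per_min=0.5)
        with pytest.raises(ValueError, match="after ramp end"):
            lagged_speed_at(proto, 700.0, ramp_duration=600.0)


class TestFlatEquivalent:
    def test_three_percent_grade_worked_example(self):
        # 5.0 mph at 3% -> 5.675 mph flat -> 2.537 m/s
        assert flat_equivalent(5.0, 0.03) == pytest.approx(2.537, abs=5e-4)

    def test_demand_equality_is_the_definition(self):
        inclined_m_per_min = 5.0 * 26.8224
        flat_m_per_min = flat_equivalent(5.0, 0.03) * 60.0
        assert running_demand(flat_m_per_min, 0.0) == pytest.approx(
            running_demand(inclined_m_per_min, 0.03), rel=1e-12
        )

    def test_zero_grade_identity_and_monotonicity(self):
        assert flat_equivalent(3.0, 0.0, unit="mps") == 3.0
        assert flat_equivalent(3.0, 0.05, unit="mps") > flat_equivalent(
            3.0, 0.02, unit="mps"
        )

    def test_negative_grade_rejected(self):
        with pytest.raises(ValueError):
            flat_equivalent(5.0, -0.01)


class TestDesignProtocol:
    def test_demand_at_target_duration_equals_prediction(self):
        proto = design_protocol(47.7, target_duration=10.0)
        peak_mph = proto.start_speed + proto.increment_per_min * 10.0
        assert running_demand(peak_mph * 26.8224, 0.03) == pytest.approx(47.7, rel=1e-9)

    def test_prediction_at_start_speed_demand_errors(self):
        start_demand = running_demand(5.0 * 26.8224, 0.03)
        with pytest.raises(ValueError, match="peak speed"):
            design_protocol(start_demand, target_duration=10.0)

    def test_increment_monotone_in_predicted_vo2max(self):
        inc = [design_protocol(v, 10.0).increment_per_min for v in (45, 55, 65)]
        assert inc[0] < inc[1] < inc[2]

    def test_inversion_consistency(self):
        s = invert_running_demand(50.0, 0.03)
        assert running_demand(s, 0.03) == pytest.approx(50.0, rel=1e-12)


class TestProcessVerification:
    def test_two_percent_accepted(self):
        vp = gas_series(np.full(120, 49.0), phase="verification")
        res = process_verification(50.0, vp)
        assert res.accepted and res.relative_difference == pytest.approx(0.02)

    def test_four_percent_rejected(self):
        vp = gas_series(np.full(120, 48.0), phase="verification")
        assert not process_verification(50.0, vp).accepted

    def test_symmetric_in_deviation_sign(self):
        lo = process_verification(50.0, gas_series(np.full(120, 49.0), "verification"))
        hi = process_verification(50.0, gas_series(np.full(120, 51.0), "verification"))
        assert lo.relative_difference == pytest.approx(hi.relative_difference)

    def test_missing_phase_errors(self):
        with pytest.raises(ValueError, match="verification"):
            process_verification(50.0, gas_series(np.full(60, 40.0), "ramp"))


class TestProcessGXT:
    def test_fifty_delta_is_exact_mean_of_speeds(self, calibrated_config):
        from critspeed.synthetic import design_protocol_for, render_gxt_series, sample_athletes

        athlete = sample_athletes(calibrated_config.replace(n_athletes=1))[0]
        proto = design_protocol_for(athlete)
        gxt = process_gxt(render_gxt_series(athlete, proto, calibrated_config), proto)
        assert gxt.fifty_delta == 0.5 * (gxt.speed_at_get + gxt.speed_at_vo2max)

    def test_noiseless_fifty_delta_near_truth(self, calibrated_config):
        from critspeed.synthetic import design_protocol_for, render_gxt_series, sample_athletes

        cfg = calibrated_config.replace(n_athletes=5)
        for athlete in sample_athletes(cfg):
            proto = design_protocol_for(athlete)
            gxt = process_gxt(render_gxt_series(athlete, proto, cfg, noiseless=True), proto)
            assert gxt.fifty_delta == pytest.approx(athlete.true_fifty_delta, abs=0.05)

    def test_missing_ramp_errors(self):
        with pytest.raises(ValueError, match="ramp"):
            process_gxt(
                gas_series(np.full(120, 40.0), phase="recovery"),
                GXTProtocol(increment_per_min=0.5),
            )
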