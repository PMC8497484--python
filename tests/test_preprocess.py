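"""Preprocessing chain: filters, baseline, rejection, reference,
interpolation, decimation, condition averages."""

import dataclasses

import numpy as np
import pytest

from frnkit.design import generate_schedule
from frnkit.epochs import EpochSet
from frnkit.preprocess import (PreprocConfig, baseline_correct,
                               condition_averages, downsample, filter_epochs,
                               filter_response, interpolate_channel,
                               preprocess, reject_artifacts, rejection_log,
                               rereference_mastoids)
from frnkit.synth import GroundTruthEffects, simulate_epochs

ZERO = GroundTruthEffects(rpe_amplitude=0.0, late_amplitude=0.0,
                          salience_gain=0.0, noise_rms=0.0, artifact_rates={})


def make_epochs(layout, n_trials=4, sfreq=500.0, conditions=None):
    dt = 1000.0 / sfreq
    times = np.arange(-300.0, 700.0, dt)
    data = np.zeros((n_trials, layout.n_channels, len(times)))
    conditions = conditions or (["LP", "LN", "HP", "HN"] * n_trials)[:n_trials]
    return EpochSet("p0", data, sfreq, times, list(conditions), layout)


class TestFilter:
    @pytest.fixture(scope="class")
    @staticmethod
    def carrier(layout):
        ep = make_epochs(layout, n_trials=1)
        return ep, ep.times / 1000.0

    def mid_ratio_db(self, x, y):
        mid = slice(100, 400)
        return 20 * np.log10(np.std(y[mid]) / np.std(x[mid]))

    @pytest.mark.parametrize("f0", [50.0, 60.0])
    def test_notch_stopband(self, carrier, f0):
        ep, t = carrier
        ep = ep.copy()
        x = np.sin(2 * np.pi * f0 * t)
        ep.data[0, 0] = x
        y = filter_epochs(ep).data[0, 0]
        assert self.mid_ratio_db(x, y) <= -20.0

    @pytest.mark.parametrize("f0", [1.0, 5.0, 10.0, 25.0])
    def test_passband_ripple_and_zero_phase(self, carrier, f0):
        ep, t = carrier
        ep = ep.copy()
        x = np.sin(2 * np.pi * f0 * t)
        ep.data[0, 0] = x
        y = filter_epochs(ep).data[0, 0]
        mid = slice(100, 400)
        assert abs(self.mid_ratio_db(x, y)) <= 1.0
        # zero phase: filtered passband sinusoid stays in phase
        assert np.corrcoef(x[mid], y[mid])[0, 1] > 0.999

    def test_white_noise_matches_designed_response(self, layout, rng):
        """Empirical transfer function equals the designed |H(f)|."""
        ep = make_epochs(layout, n_trials=60)
        ep.data = rng.standard_normal(ep.data.shape)
        out = filter_epochs(ep)
        f = np.fft.rfftfreq(ep.data.shape[-1], 1 / ep.sfreq)
        px = (np.abs(np.fft.rfft(ep.data, axis=-1)) ** 2).mean(axis=(0, 1))
        py = (np.abs(np.fft.rfft(out.data, axis=-1)) ** 2).mean(axis=(0, 1))
        emp = np.sqrt(py / px)
        design = filter_response(PreprocConfig(), ep.sfreq, f)
        sel = (f > 2) & (f < 45) & (np.abs(f - 50) > 3)
        assert np.abs(emp[sel] - design[sel]).max() < 0.05

    def test_too_short_epoch_rejected(self, layout):
        ep = make_epochs(layout)
        ep = EpochSet("p", ep.data[:, :, :16], ep.sfreq, ep.times[:16],
                      ep.conditions, layout)
        with pytest.raises(ValueError, match="short"):
            filter_epochs(ep)


class TestBaseline:
    def test_constant_offset_removed(self, layout):
        ep = make_epochs(layout)
        ep.data += 7.5
        out = baseline_correct(ep)
        assert np.abs(out.data).max() < 1e-12

    def test_ramp_keeps_shape_minus_window_mean(self, layout):
        ep = make_epochs(layout, n_trials=1)
        ramp = np.linspace(0, 10, ep.data.shape[-1])
        ep.data[0, 0] = ramp
        out = baseline_correct(ep)
        mask = ep.time_mask(-200, 0)
        assert np.allclose(out.data[0, 0], ramp - ramp[mask].mean())

    def test_window_mean_zero_after_correction(self, layout, rng):
        ep = make_epochs(layout)
        ep.data = rng.standard_normal(ep.data.shape)
        out = baseline_correct(ep)
        mask = ep.time_mask(-200, 0)
        assert np.abs(out.data[:, :, mask].mean(axis=-1)).max() < 1e-12

    def test_empty_window_rejected(self, layout):
        with pytest.raises(ValueError):
            baseline_correct(make_epochs(layout), (-900, -800))


class TestRejection:
    def test_absolute_rule(self, layout):
        ep = make_epochs(layout)
        ep.data[1, layout.index("Fz"), 250] = 120.0
        ep.data[0, layout.index("Fz"), 250] = 90.0  # below threshold
        out = reject_artifacts(_nonflat(ep))
        assert out.rejected[1] and out.reject_reason[1] == "absolute:Fz"
        assert not out.rejected[0]

    def test_gradient_rule_arithmetic_at_500hz(self, layout):
        # adjacent samples are 2 ms apart: a 60 uV step is 30 uV/ms (keep),
        # a 120 uV step is 60 uV/ms (reject); both stay under the 100 uV
        # absolute rule via a bipolar flip
        ep = _nonflat(make_epochs(layout))
        ci = layout.index("Cz")
        ep.data[0, ci, 300] -= 30.0
        ep.data[0, ci, 301] += 30.0
        ep.data[1, ci, 300] -= 60.0
        ep.data[1, ci, 301] += 60.0
        out = reject_artifacts(ep)
        assert not out.rejected[0]
        assert out.rejected[1] and out.reject_reason[1] == "gradient:Cz"

    def test_flatline_rule_requires_all_channels(self, layout):
        ep = make_epochs(layout)  # all-zero: every channel flat
        out = reject_artifacts(ep)
        assert out.rejected.all()
        assert out.reject_reason[0] == "flat:all"
        # one live channel rescues the trial under the all-channel rule
        ep2 = make_epochs(layout)
        ep2.data[:, layout.index("Pz"), :] = np.linspace(0, 20, ep2.data.shape[-1])
        assert not reject_artifacts(ep2).rejected.any()

    def test_per_channel_flat_variant(self, layout, rng):
        ep = make_epochs(layout)
        ep.data = rng.standard_normal(ep.data.shape) * 10
        ep.data[2, layout.index("P3"), :] = 0.0
        cfg = PreprocConfig(flat_rule="per_channel")
        out = reject_artifacts(ep, cfg)
        assert out.rejected[2] and out.reject_reason[2] == "flat:P3"

    def test_rule_outside_scan_window_ignored(self, layout):
        ep = _nonflat(make_epochs(layout))
        before = np.argmin(np.abs(ep.times - (-250.0)))
        ep.data[0, layout.index("Fz"), before] = 500.0
        assert not reject_artifacts(ep).rejected[0]


def _nonflat(ep):
    # keep every channel's range above the 12 uV flatline rule
    ramp = np.linspace(0, 15, ep.data.shape[-1])
    ep.data = ep.data + ramp
    return ep


class TestRereference:
    def test_zero_mastoids_leave_data_unchanged(self, layout, rng):
        ep = make_epochs(layout)
        ep.data = rng.standard_normal(ep.data.shape)
        ep.data[:, layout.index("M1"), :] = 0.0
        ep.data[:, layout.index("M2"), :] = 0.0
        out = rereference_mastoids(ep)
        assert np.allclose(out.data, ep.data)

    def test_constant_right_mastoid_shifts_all_channels(self, layout):
        ep = make_epochs(layout)
        ep.data[:, layout.index("M2"), :] = 2.0
        out = rereference_mastoids(ep)
        others = [i for i in range(layout.n_channels)
                  if layout.names[i] not in ("M2",)]
        assert np.allclose(out.data[:, others, :], -1.0)

    def test_mastoid_mean_zero_and_idempotent_property(self, layout, rng):
        ep = make_epochs(layout)
        ep.data = rng.standard_normal(ep.data.shape)
        ep.data[:, layout.index("M1"), :] = 0.0
        out = rereference_mastoids(ep)
        li, ri = layout.index("M1"), layout.index("M2")
        assert np.abs(out.data[:, li] + out.data[:, ri]).max() < 1e-12
        again = rereference_mastoids(out)
        assert np.allclose(again.data, out.data)

    def test_missing_mastoid_rejected(self, layout):
        sub = layout.subset([n for n in layout.names if n != "M2"])
        ep = make_epochs(sub)
        with pytest.raises(ValueError, match="M2"):
            rereference_mastoids(ep)


class TestInterpolation:
    def test_degree_one_harmonic_recovered(self, layout):
        ep = make_epochs(layout)
        ep.data[:] = (10.0 * layout.positions[:, 2])[None, :, None]
        out = interpolate_channel(ep, "Cz")
        ci = layout.index("Cz")
        true = 10.0 * layout.positions[ci, 2]
        assert out.data[0, ci, 0] == pytest.approx(true, rel=0.01)

    def test_self_prediction_residual_shrinks_with_smoothness(self, layout):
        def field(sharpness):
            center = layout.positions[layout.index("C4")]
            d = layout.positions @ center
            return np.exp(sharpness * (d - 1.0))

        residuals = []
        ci = layout.index("C3")
        for sharpness in (1.0, 4.0):
            ep = make_epochs(layout)
            ep.data[:] = field(sharpness)[None, :, None] * 20.0
            truth = ep.data[0, ci, 0]
            out = interpolate_channel(ep, "C3")
            residuals.append(abs(out.data[0, ci, 0] - truth))
        assert residuals[0] < residuals[1]
        assert residuals[0] < 0.5

    def test_zero_data_interpolates_to_zero(self, layout):
        out = interpolate_channel(make_epochs(layout), "Pz")
        assert np.abs(out.data).max() < 1e-12

    def test_other_channels_untouched(self, layout, rng):
        ep = make_epochs(layout)
        ep.data = rng.standard_normal(ep.data.shape)
        out = interpolate_channel(ep, "Oz")
        oi = layout.index("Oz")
        mask = np.arange(layout.n_channels) != oi
        assert np.array_equal(out.data[:, mask], ep.data[:, mask])

    def test_non_scalp_channel_rejected(self, layout):
        with pytest.raises(ValueError):
            interpolate_channel(make_epochs(layout), "SO2")


class TestDownsample:
    def test_counting_and_time_axis(self, layout):
        ep = make_epochs(layout)
        out = downsample(ep, 100.0)
        assert out.data.shape[-1] == 100
        assert out.sfreq == 100.0
        assert np.allclose(np.diff(out.times), 10.0)

    def test_dc_unchanged(self, layout):
        ep = make_epochs(layout)
        ep.data += 3.3
        assert np.allclose(downsample(ep, 100.0).data, 3.3)

    def test_tone_amplitude_preserved(self, layout):
        ep = make_epochs(layout, n_trials=1)
        t = ep.times / 1000.0
        x = np.sin(2 * np.pi * 10 * t)
        ep.data[0, 0] = x
        y = downsample(ep, 100.0).data[0, 0]
        db = 20 * np.log10(y.std() / x.std())
        assert abs(db) < 1.0

    def test_non_integer_factor_rejected(self, layout):
        with pytest.raises(ValueError):
            downsample(make_epochs(layout), 300.0)


class TestConditionAverages:
    def test_identical_trials_average_to_themselves(self, layout, rng):
        ep = make_epochs(layout, n_trials=2, conditions=["LP", "LP"])
        trial = rng.standard_normal(ep.data.shape[1:])
        ep.data[:] = trial
        avg, counts = condition_averages(ep)
        assert np.allclose(avg["LP"], trial)
        assert counts["LP"] == 2 and counts["HN"] == 0

    def test_rejected_trial_excluded(self, layout):
        ep = make_epochs(layout, n_trials=2, conditions=["HP", "HP"])
        ep.data[0] = 1.0
        ep.data[1] = 5.0
        ep.rejected[1] = True
        avg, counts = condition_averages(ep)
        assert np.allclose(avg["HP"], 1.0)
        assert counts["HP"] == 1

    def test_zero_noise_averages_equal_injected_components(self, layout):
        sched = generate_schedule(1, 8, 0.0, seed=3)
        eff = dataclasses.replace(ZERO, rpe_amplitude=2.0, salience_gain=0.5)
        ep = simulate_epochs(sched, eff, seed=0)
        single = simulate_epochs(sched, eff, seed=0)
        avg, _ = condition_averages(ep)
        for i, c in enumerate(sched.conditions):
            assert np.allclose(avg[c], single.data[i])


def test_full_chain_runs_and_logs(schedule):
    eff = GroundTruthEffects(noise_rms=3.0,
                             artifact_rates={"blink": 0.05, "jump": 0.0,
                                             "flat": 0.0})
    ep = simulate_epochs(generate_schedule(1, 20, 0.0, seed=2), eff, seed=9)
    out = preprocess(ep)
    assert out.sfreq == 100.0
    log = rejection_log(out)
    assert log["retained"] + log["total"] == out.n_trials
    # chain order: mastoid reference applied after rejection
    li, ri = out.layout.index("M1"), out.layout.index("M2")
    assert np.abs(out.data[:, li] + out.data[:, ri]).max() < 1e-9


def test_config_file_round_trip(tmp_path):
    path = tmp_path / "preproc.cfg"
    path.write_text(
        "lowpass_hz = 35\nnotch_hz = 50\nflat_rule = per_channel\n"
        "# comment\nfilter_order = 2\n"
    )
    cfg = PreprocConfig.from_file(path)
    assert cfg.lowpass_hz == 35.0
    assert cfg.notch_hz == (50.0,)
    assert cfg.flat_rule == "per_channel"
    assert cfg.filter_order == 2
    bad = tmp_path / "bad.cfg"
    bad.write_text("unknown_key = 1\n")
    with pytest.raises(ValueError, match="unknown"):
        PreprocConfig.from_file(bad)
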