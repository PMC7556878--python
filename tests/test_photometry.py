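"""Photometry correction chain: bleaching, attenuation, z-scoring, events."""

import math

import numpy as np
import pytest
from scipy.signal import lfilter

from vasopipe import synth
from vasopipe.behavior import segment_behavior
from vasopipe.errors import InvalidParameterError
from vasopipe.photometry import (
    AttenuationModel,
    CorrectedPhotometry,
    correct_hemoglobin,
    correct_session,
    debleach,
    debleach_and_normalize,
    estimate_attenuation,
    event_triggered_photometry,
    fit_bleach,
    minmax_normalize,
    signal_blood_correlation,
    zscore,
)

FS = 1200.0
T = 1200.0
N = int(FS * T)
BLEACH = (1.0, 20.0, 0.5, 120.0, 2.0)


def bout_response(seg, tau_s, scale, n=N, fs=FS):
    moving = seg.moving_mask_at(fs, n).astype(float)
    alpha = 1.0 - math.exp(-1.0 / (tau_s * fs))
    return scale * lfilter([alpha], [1, -(1 - alpha)], moving)


@pytest.fixture(scope="module")
def behavior_seg():
    bouts = [(t, t + 8.0 + (t % 13)) for t in np.arange(30.0, T - 60.0, 75.0)]
    trace = synth.make_locomotion_trace(
        bouts, duration=T, sample_rate=100.0, noise_sd=0.1, seed=11,
    )
    return segment_behavior(trace)


@pytest.fixture(scope="module")
def gcamp_session(behavior_seg):
    calcium = bout_response(behavior_seg, 1.0, 1.0)
    cbv = bout_response(behavior_seg, 4.0, 1.0)
    session = synth.make_photometry(calcium, cbv, BLEACH, 0.3,
                                    noise_sd=0.2, seed=21)
    session.behavior = behavior_seg
    return session


@pytest.fixture(scope="module")
def gfp_sessions(behavior_seg):
    sessions = []
    for k in range(3):
        cbv = bout_response(behavior_seg, 3.0 + k, 0.8)
        s = synth.make_photometry(np.zeros(N), cbv, BLEACH, 0.3,
                                  noise_sd=0.2, seed=31 + k)
        s.behavior = behavior_seg
        sessions.append(s)
    return sessions


@pytest.fixture(scope="module")
def attenuation(gfp_sessions):
    return estimate_attenuation(gfp_sessions)


class TestFitBleach:
    def test_pure_double_exponential_residual(self):
        t = np.arange(N) / FS
        a1, tau1, a2, tau2, c = BLEACH
        channel = a1 * np.exp(-t / tau1) + a2 * np.exp(-t / tau2) + c
        model = fit_bleach(channel, FS)
        rms = np.sqrt(np.mean((model(t) - channel) ** 2))
        assert rms < 0.01 * (a1 + a2)

    def test_parameter_recovery(self, gcamp_session, behavior_seg):
        model = fit_bleach(gcamp_session.green, FS, behavior_seg)
        assert model.a1 == pytest.approx(BLEACH[0], rel=0.1)
        assert model.tau1 == pytest.approx(BLEACH[1], rel=0.1)
        assert model.a2 == pytest.approx(BLEACH[2], rel=0.1)
        assert model.tau2 == pytest.approx(BLEACH[3], rel=0.1)

    def test_constant_channel_near_zero_amplitudes(self):
        model = fit_bleach(np.full(N, 5.0), FS)
        assert abs(model.a1) < 1e-3
        assert abs(model.a2) < 1e-3

    def test_too_little_quiet_data_rejected(self, behavior_seg):
        short = np.ones(int(30 * FS))
        with pytest.raises(InvalidParameterError):
            fit_bleach(short, FS)


class TestDebleachNormalize:
    def test_output_spans_unit_interval(self, gcamp_session, behavior_seg):
        model = fit_bleach(gcamp_session.green, FS, behavior_seg)
        out = debleach_and_normalize(gcamp_session.green, FS, model)
        assert out.min() == pytest.approx(0.0, abs=1e-12)
        assert out.max() == pytest.approx(1.0, abs=1e-12)

    def test_affine_invariance(self, gcamp_session, behavior_seg):
        model = fit_bleach(gcamp_session.green, FS, behavior_seg)
        base = debleach_and_normalize(gcamp_session.green, FS, model)
        # an affine-transformed channel with a matching affine bleach model
        from vasopipe.photometry import BleachModel

        scaled_model = BleachModel(
            a1=3.0 * model.a1, tau1=model.tau1, a2=3.0 * model.a2,
            tau2=model.tau2, offset=3.0 * model.offset + 7.0,
        )
        scaled = debleach_and_normalize(3.0 * gcamp_session.green + 7.0, FS, scaled_model)
        np.testing.assert_allclose(scaled, base, atol=1e-9)

    def test_monotone_decay_flattens(self):
        t = np.arange(N) / FS
        channel = 2.0 * np.exp(-t / 50.0) + 1.0
        model = fit_bleach(channel, FS)
        flat = debleach(channel, FS, model)
        assert np.ptp(flat) < 0.01 * 2.0


class TestAttenuation:
    def test_coefficient_recovered(self, attenuation):
        assert attenuation.magnitude == pytest.approx(0.3, rel=0.05)
        assert attenuation.coeff < 0  # more blood -> less green light

    def test_coeff_is_mean_of_slopes(self, attenuation):
        assert attenuation.coeff == pytest.approx(
            np.mean(attenuation.per_animal_slopes))

    def test_red_independent_green_gives_zero_slope(self, behavior_seg):
        session = synth.make_photometry(
            np.zeros(N), bout_response(behavior_seg, 3.0, 0.8),
            BLEACH, 0.0, noise_sd=0.2, seed=41,
        )
        session.behavior = behavior_seg
        model = estimate_attenuation([session])
        assert abs(model.coeff) < 0.02


class TestCorrection:
    def test_recovers_programmed_calcium(self, gcamp_session, attenuation, behavior_seg):
        corrected = correct_session(gcamp_session, attenuation)
        calcium = gcamp_session.ground_truth["calcium"]
        r = np.corrcoef(corrected.gcamp_z, calcium)[0, 1]
        assert r > 0.95

    def test_zero_coeff_ignores_red_channel(self, gcamp_session, behavior_seg):
        model_g = fit_bleach(gcamp_session.green, FS, behavior_seg)
        g = debleach(gcamp_session.green, FS, model_g)
        rng = np.random.default_rng(0)
        zero = AttenuationModel(0.0, (0.0,))
        out_a = correct_hemoglobin(g, np.zeros_like(g), zero, FS)
        out_b = correct_hemoglobin(g, rng.normal(size=g.size), zero, FS)
        # with a zero coefficient the red channel has no influence and the
        # result is the band-passed, z-scored green channel
        np.testing.assert_allclose(out_a, out_b, atol=1e-9)
        assert np.corrcoef(out_a, zscore(g))[0, 1] > 0.97

    def test_gfp_correction_removes_blood_coupling(self, gfp_sessions, attenuation):
        # uncorrected green tracks blood volume almost perfectly; after
        # correction only filter-residual correlation remains (the strict
        # |r| < 0.1 bound at full session length is asserted in the
        # acceptance suite)
        session = gfp_sessions[0]
        g = debleach(session.green, FS, fit_bleach(session.green, FS, session.behavior))
        r = debleach(session.red, FS, fit_bleach(session.red, FS, session.behavior))
        before = abs(np.corrcoef(g, r)[0, 1])
        corrected = correct_session(session, attenuation)
        after = abs(signal_blood_correlation(corrected))
        assert before > 0.9
        assert after < 0.2

    def test_zscore_contract(self, gcamp_session, attenuation):
        corrected = correct_session(gcamp_session, attenuation)
        for sig in (corrected.gcamp_z, corrected.cbv_z):
            assert abs(np.mean(sig)) < 1e-6
            assert np.std(sig) == pytest.approx(1.0, abs=1e-6)

    def test_no_bleach_no_attenuation_identity(self, behavior_seg):
        # calcium kinetics chosen inside the 0.001-1 Hz passband so the
        # correction chain is an identity up to z-scoring
        calcium = bout_response(behavior_seg, 3.0, 1.0)
        session = synth.make_photometry(
            calcium, np.zeros(N) + 0.5, (0.0, 1.0, 0.0, 1.0, 0.0), 0.0,
            noise_sd=0.0, seed=0,
        )
        session.behavior = behavior_seg
        # the debleach stage alone is an exact identity within the band
        from scipy.signal import butter, sosfiltfilt

        model = fit_bleach(session.green, FS, behavior_seg)
        g = debleach(session.green, FS, model)
        sos = butter(4, 1.0, btype="low", fs=FS, output="sos")
        reference = sosfiltfilt(sos, calcium)
        assert np.corrcoef(g, reference)[0, 1] > 0.999
        # the full chain adds the 0.001 Hz drift removal, which perturbs
        # the slowest components of a 20-minute record
        corrected = correct_session(session, AttenuationModel(0.0, (0.0,)))
        assert np.corrcoef(corrected.gcamp_z, zscore(reference))[0, 1] > 0.97


class TestEventTriggered:
    def test_duration_binning(self, behavior_seg):
        rng = np.random.default_rng(0)
        corrected = CorrectedPhotometry(
            gcamp_z=rng.normal(size=N), cbv_z=rng.normal(size=N),
            sample_rate=FS, behavior=behavior_seg,
        )
        out = event_triggered_photometry(corrected)
        durations = [off - on for on, off in behavior_seg.events]
        for (lo, hi), averages in out.items():
            expected_n = sum(1 for d in durations if lo <= d < hi)
            assert averages["gcamp"].n_events <= expected_n

    def test_constant_signal_zero_after_baseline(self, behavior_seg):
        corrected = CorrectedPhotometry(
            gcamp_z=np.full(N, 2.5), cbv_z=np.full(N, -1.0),
            sample_rate=FS, behavior=behavior_seg,
        )
        out = event_triggered_photometry(corrected)
        assert out  # at least one populated bin
        for averages in out.values():
            np.testing.assert_allclose(
                np.nan_to_num(averages["gcamp"].mean), 0.0, atol=1e-12)

    def test_step_response_amplitude(self, behavior_seg):
        # build the step from the true bout times: the binarized mask is
        # smeared around each bout and would leak into the baseline window
        bouts = [(t, t + 8.0 + (t % 13)) for t in np.arange(30.0, T - 60.0, 75.0)]
        moving = np.zeros(N, dtype=bool)
        for a, b in bouts:
            moving[int(a * FS) : int(b * FS)] = True
        z = np.where(moving, 2.0, 0.0)
        corrected = CorrectedPhotometry(
            gcamp_z=z, cbv_z=z, sample_rate=FS, behavior=behavior_seg,
        )
        out = event_triggered_photometry(corrected)
        plateaus = []
        for averages in out.values():
            lta = averages["gcamp"]
            sel = (lta.rel_time >= 2.0) & (lta.rel_time <= 5.0)
            plateaus.append(np.nanmean(lta.mean[sel]))
        assert np.mean(plateaus) == pytest.approx(2.0, rel=0.05)


class TestSignalBloodCorrelation:
    def test_identical_signals(self):
        x = np.sin(np.linspace(0, 40, 10000))
        c = CorrectedPhotometry(gcamp_z=x, cbv_z=x.copy(), sample_rate=FS)
        assert signal_blood_correlation(c) == pytest.approx(1.0)

    def test_independent_noise_uncorrelated(self):
        rng = np.random.default_rng(1)
        c = CorrectedPhotometry(
            gcamp_z=rng.normal(size=100_000), cbv_z=rng.normal(size=100_000),
            sample_rate=FS,
        )
        assert abs(signal_blood_correlation(c)) < 0.1

    def test_shared_drive_analytic_value(self):
        # x = s + e1, y = s + e2 with unit variances: r = 1/2
        rng = np.random.default_rng(2)
        s = rng.normal(size=200_000)
        c = CorrectedPhotometry(
            gcamp_z=s + rng.normal(size=s.size),
            cbv_z=s + rng.normal(size=s.size),
            sample_rate=FS,
        )
        assert signal_blood_correlation(c) == pytest.approx(0.5, abs=0.05)


class TestMinMaxAndZscore:
    def test_minmax_constant_rejected(self):
        with pytest.raises(InvalidParameterError):
            minmax_normalize(np.ones(10))

    def test_zscore_constant_rejected(self):
        with pytest.raises(InvalidParameterError):
            zscore(np.ones(10))
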