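"""PSTHs, evoked responses, hyperbolic-ratio fits, depth profiles, generator."""

import numpy as np
import pytest

from lickroc.neural import (
    CRFFit,
    SpikeRecord,
    TrialEvent,
    evoked_response,
    fit_crf,
    hyperbolic_ratio,
    psth,
    silencing_depth_profile,
    simulate_sc_activity,
)


def poisson_record(rate_hz=10.0, n_trials=200, seed=0, depth=400.0):
    rng = np.random.default_rng(seed)
    period = 2.0
    events, spikes = [], []
    for k in range(n_trials):
        onset = k * period + 1.0
        n = rng.poisson(rate_hz * period)
        spikes.append(np.sort(rng.uniform(k * period, (k + 1) * period, n)))
        events.append(TrialEvent(onset, 100.0, False))
    return SpikeRecord(depth, np.concatenate(spikes), tuple(events))


def test_psth_flat_for_constant_rate():
    rec = poisson_record(rate_hz=10.0)
    centers, rate = psth(rec, pre_s=0.5, post_s=0.5, bin_s=0.1)
    assert centers.size == 10
    se = np.sqrt(10.0 / (200 * 0.1))  # Poisson SE per bin
    assert np.all(np.abs(rate - 10.0) < 4 * se)


def test_psth_zero_spikes_and_bin_check():
    rec = SpikeRecord(300.0, np.empty(0), (TrialEvent(1.0, 100.0, False),))
    _, rate = psth(rec, 0.2, 0.2, 0.04)
    assert np.all(rate == 0)
    with pytest.raises(ValueError):
        psth(rec, 0.25, 0.25, 0.15)


def test_psth_standard_error_scales_with_trials():
    rates = []
    for n in (100, 400):
        rec = poisson_record(rate_hz=20.0, n_trials=n, seed=3)
        _, r = psth(rec, 0.5, 0.5, 0.05)
        rates.append(np.std(r))
    # quadrupling trials should roughly halve bin-to-bin scatter
    assert rates[1] < rates[0] * 0.75


def test_evoked_response_null_when_no_modulation():
    rec = poisson_record(rate_hz=15.0, n_trials=300)
    contrasts, resp = evoked_response(rec, normalize=False)
    assert contrasts.tolist() == [100.0]
    assert abs(resp[0]) < 3.0  # baseline-subtracted, should hover near zero


def test_evoked_response_recovers_linear_contrast_profile():
    rng = np.random.default_rng(7)
    events, spikes = [], []
    period, t = 2.0, 0.0
    contrasts = [25.0, 50.0, 75.0, 100.0]
    for c in contrasts:
        for _ in range(400):
            onset = t + 1.0
            for lo, hi, rate in ((t, onset, 5.0),
                                 (onset, onset + 0.1, 5.0 + 40.0 * c / 100.0),
                                 (onset + 0.1, t + period, 5.0)):
                n = rng.poisson(rate * (hi - lo))
                spikes.append(np.sort(rng.uniform(lo, hi, n)))
            events.append(TrialEvent(onset, c, False))
            t += period
    rec = SpikeRecord(500.0, np.sort(np.concatenate(spikes)), tuple(events))
    got_c, got_r = evoked_response(rec, normalize=True)
    expected = np.asarray(contrasts) / 100.0
    assert np.allclose(got_r, expected, atol=0.05)


def test_hyperbolic_ratio_identities():
    assert hyperbolic_ratio(20.0, 1.0, 2.0, 20.0) == pytest.approx(0.5)  # x = x50
    assert hyperbolic_ratio(1e9, 1.3, 2.0, 20.0) == pytest.approx(1.3, rel=1e-6)
    assert hyperbolic_ratio(0.0, 1.0, 2.0, 20.0) == 0.0


def test_crf_noiseless_recovery_and_dense_grid_oracle(rng):
    x = np.array([2, 4, 8, 16, 32, 64, 100], float)
    y = hyperbolic_ratio(x, 1.0, 2.0, 20.0)
    fit = fit_crf(x, y)
    for got, true in ((fit.r_max, 1.0), (fit.n_exp, 2.0), (fit.x50, 20.0)):
        assert abs(got - true) / true < 1e-3
    # dense-grid brute force on random problems: the optimizer should do at
    # least as well (within tolerance) as the best grid point
    grid_r = np.linspace(0.2, 1.6, 25)
    grid_n = np.linspace(0.5, 4.0, 25)
    grid_x = np.linspace(2.0, 80.0, 40)
    for _ in range(10):
        theta = (rng.uniform(0.4, 1.4), rng.uniform(0.8, 3.5), rng.uniform(5, 60))
        y = hyperbolic_ratio(x, *theta) + rng.normal(0, 0.03, x.size)
        fit = fit_crf(x, y)
        best = min(
            float(np.sum((hyperbolic_ratio(x, r, n, xx) - y) ** 2))
            for r in grid_r for n in grid_n for xx in grid_x
        )
        assert fit.rss <= best + 1e-6


def test_crf_monotone_prediction():
    x = np.array([4, 8, 16, 32, 64, 100], float)
    y = hyperbolic_ratio(x, 0.9, 1.7, 15.0)
    fit = fit_crf(x, y)
    dense = fit.predict(np.linspace(0, 100, 300))
    assert np.all(np.diff(dense) >= -1e-12)


def test_simulator_determinism_and_led_effect():
    kw = dict(depths_um=[200.0, 600.0], contrasts_pct=(25.0, 100.0),
              training_scale=1.0, n_trials=150, seed=42)
    a = simulate_sc_activity(**kw)
    b = simulate_sc_activity(**kw)
    assert all(np.array_equal(x.spike_times_s, y.spike_times_s)
               for x, y in zip(a, b))
    # at the cortico-recipient depth, silencing removes the cortical drive
    deep = a[1]
    c, off = evoked_response(deep, led_on=False, normalize=False)
    _, on = evoked_response(deep, led_on=True, normalize=False)
    top = int(np.argmax(c))
    expected_ratio = 0.35 / (0.35 + 0.6)  # retinal / (retinal + cortical)
    assert on[top] / off[top] == pytest.approx(expected_ratio, abs=0.12)


def test_training_scale_zero_removes_led_effect():
    recs = simulate_sc_activity([600.0], contrasts_pct=(100.0,),
                                training_scale=0.0, n_trials=300, seed=1)
    _, off = evoked_response(recs[0], led_on=False, normalize=False)
    _, on = evoked_response(recs[0], led_on=True, normalize=False)
    assert on[0] == pytest.approx(off[0], abs=3.0)


def test_depth_profile_localizes_cortical_dependence():
    depths = [100.0, 200.0, 600.0, 700.0]
    recs = simulate_sc_activity(depths, contrasts_pct=(100.0,),
                                training_scale=1.0, n_trials=200, seed=5)
    d, ctrl, sil = silencing_depth_profile(recs)
    assert np.all(ctrl == 1.0)
    superficial = sil[d < 300]
    deep = sil[d >= 500]
    assert np.all(superficial > 0.8)  # retino-recipient layers barely affected
    assert np.all(deep < 0.6)  # cortico-recipient layers strongly suppressed
    with pytest.raises(ValueError):
        silencing_depth_profile(recs[:1])


def test_pipeline_x50_recovery_within_20pct():
    recs = simulate_sc_activity(
        [600.0], contrasts_pct=(2.0, 4.0, 8.0, 16.0, 32.0, 64.0, 100.0),
        training_scale=1.0, n_trials=100, seed=9, crf_x50=20.0)
    c, resp = evoked_response(recs[0], led_on=False)
    fit = fit_crf(c, resp)
    assert abs(fit.x50 - 20.0) / 20.0 < 0.2
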