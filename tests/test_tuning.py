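"""HD tuning curves, bidirectionality, von Mises fits, modulation, waveforms."""

import numpy as np
import pytest
from scipy.special import iv

from egospace import (angular_tuning_curve, bidirectionality_from_frames,
                      fit_bidirectional_von_mises, fit_von_mises,
                      modulation_indices, synth_waveform, waveform_width)
from egospace.tuning import TuningCurve, classify_peak_trough, faces_cue
from egospace.session import wrap_deg

CENTERS = (np.arange(30) + 0.5) * 12.0


def _uniform_frames(n=36_000):
    # exactly uniform angular occupancy
    return np.tile(CENTERS, n // 30)


def _curve(rate):
    rate = np.asarray(rate, float)
    from egospace.tuning import _resultant
    mvl, pfd = _resultant(rate, CENTERS)
    return TuningCurve(CENTERS, rate, np.ones(30), mvl, pfd)


def test_mvl_limits():
    hd = _uniform_frames()
    uniform = angular_tuning_curve(hd, np.ones(len(hd)))
    assert uniform.mvl == pytest.approx(0.0, abs=1e-12)
    one_bin = angular_tuning_curve(hd, (np.abs(hd - 90.0) < 6.0).astype(float))
    assert one_bin.mvl == pytest.approx(1.0, abs=1e-9)
    two_opposite = angular_tuning_curve(
        hd, ((np.abs(hd - 90.0) < 6.0) | (np.abs(hd - 270.0) < 6.0)).astype(float))
    assert two_opposite.mvl == pytest.approx(0.0, abs=1e-9)


def test_zero_occupancy_bins_excluded():
    hd = np.tile(CENTERS[:15], 100)          # only half the circle visited
    curve = angular_tuning_curve(hd, np.ones(len(hd)))
    assert np.isnan(curve.rate[15:]).all()
    assert np.isfinite(curve.mvl)


def test_bidirectionality_ideal_and_unidirectional():
    hd = _uniform_frames()
    # ideal symmetric bidirectional input: BI -> 1
    counts = np.exp(4 * np.cos(np.radians(hd))) + np.exp(4 * np.cos(np.radians(hd - 180)))
    assert bidirectionality_from_frames(hd, counts) == pytest.approx(1.0, abs=0.02)
    # pure von Mises (kappa=4): Bessel-ratio closed form
    k = 4.0
    counts_u = np.exp(k * np.cos(np.radians(hd - 33.0)))
    r1, r2 = iv(1, k) / iv(0, k), iv(2, k) / iv(0, k)
    oracle = (r2 - r1) / (r2 + r1)
    assert bidirectionality_from_frames(hd, counts_u) == pytest.approx(oracle, abs=0.02)


def test_bidirectionality_rotation_invariance():
    rng = np.random.default_rng(5)
    hd = rng.uniform(0, 360, 50_000)
    counts = rng.poisson(0.2 * (1 + np.cos(np.radians(2 * hd))))
    b0 = bidirectionality_from_frames(hd, counts)
    b1 = bidirectionality_from_frames(wrap_deg(hd + 72.0), counts)   # bin-width multiple
    assert b1 == pytest.approx(b0, abs=1e-9)


def test_bidirectionality_untuned_missing():
    hd = _uniform_frames(3000)
    assert np.isnan(bidirectionality_from_frames(hd, np.ones(len(hd))))


def test_von_mises_fit_upright_and_trough():
    up_rate = 2.0 + 8.0 * np.exp(3.0 * (np.cos(np.radians(CENTERS - 140.0)) - 1))
    fit = fit_von_mises(_curve(up_rate), "upright")
    assert fit.r_squared > 0.99
    assert wrap_deg(fit.mu) == pytest.approx(140.0, abs=3.0)
    label, diff, _ = classify_peak_trough(_curve(up_rate))
    assert label == "peak" and diff > 0

    tr_rate = 10.0 - 8.0 * np.exp(3.0 * (np.cos(np.radians(CENTERS - 140.0)) - 1))
    label_t, diff_t, _ = classify_peak_trough(_curve(tr_rate))
    assert label_t == "trough" and diff_t < 0


def test_bidirectional_fit_amplitude_ratio():
    rate = (1.0 + 8.0 * np.exp(4.0 * (np.cos(np.radians(CENTERS - 60.0)) - 1))
            + 4.0 * np.exp(4.0 * (np.cos(np.radians(CENTERS - 240.0)) - 1)))
    fit = fit_bidirectional_von_mises(_curve(rate), "upright")
    a = sorted(fit.amplitudes, reverse=True)
    assert a[0] / a[1] == pytest.approx(2.0, rel=0.15)
    # lobes are exactly 180 degrees apart by construction: both lobe centers
    # are local maxima of the fitted curve, the saddle in between is lower
    for mu in (fit.mu, fit.mu + 180.0):
        assert fit.predict(mu) > fit.predict(mu + 90.0)
    assert fit.r_squared > 0.99


def test_bidirectional_fit_nests_unidirectional():
    rate = 1.0 + 8.0 * np.exp(4.0 * (np.cos(np.radians(CENTERS - 60.0)) - 1))
    fit = fit_bidirectional_von_mises(_curve(rate), "upright")
    a = sorted(fit.amplitudes)
    assert a[0] < 0.1 * a[1]
    assert fit.r_squared > 0.99


def test_faces_cue_sector():
    """Directions in (180, 360) point toward the south-wall cue card."""
    assert faces_cue(270.0) and faces_cue(181.0) and faces_cue(-1.0)
    assert not faces_cue(90.0) and not faces_cue(180.0) and not faces_cue(0.0)


def test_modulation_index_closed_forms():
    from egospace.tuning import VonMisesFit
    # curve max 10 Hz at mu, min 2 Hz, opposite lobe peak 6 Hz
    fit = VonMisesFit("upright", mu=0.0, kappa=8.0, amplitudes=(8.0, 4.0),
                      baseline=2.0, r_squared=1.0, bidirectional=True)
    mi_a, mi_b = modulation_indices(fit, pfd_a1=10.0)
    assert mi_a == pytest.approx(0.8, abs=0.02)
    assert mi_b == pytest.approx(0.4, abs=0.02)
    # A1 preference near the other lobe swaps the attribution
    mi_a2, mi_b2 = modulation_indices(fit, pfd_a1=175.0)
    assert mi_a2 == pytest.approx(mi_b, abs=1e-9)
    assert mi_b2 == pytest.approx(mi_a, abs=1e-9)


@pytest.mark.parametrize("peak,trough,expected_us,expected_class", [
    (8, 16, 250.0, "wide"),
    (8, 13, 156.25, "narrow"),
])
def test_waveform_width_sample_latencies(peak, trough, expected_us, expected_class):
    s = np.arange(32, dtype=float)
    wf = (np.exp(-0.5 * ((s - peak) / 1.1) ** 2)
          - 0.8 * np.exp(-0.5 * ((s - trough) / 1.2) ** 2))
    lat, klass = waveform_width(wf)
    assert lat == pytest.approx(expected_us, abs=0.3125)
    assert klass == expected_class


def test_waveform_width_monotonic_errors():
    with pytest.raises(ValueError):
        waveform_width(np.linspace(-1, 1, 32))


def test_waveform_synthesis_round_trip():
    for klass in ("narrow", "wide"):
        wf, true_lat = synth_waveform(klass, seed=3, noise_sd=0.01)
        lat, est_class = waveform_width(wf)
        assert est_class == klass
        assert abs(lat - true_lat) < 20.0       # noisy template, coarse check
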