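"""Wavelet peak extraction and the four peak filters."""

import numpy as np
import pytest

from xlpcp import profile_io
from xlpcp.peaks import (
    Peak,
    extract_peaks,
    filter_peaks,
    ricker,
)
from xlpcp.profile_io import fit_calibration
from xlpcp.synthetic import _gaussian, default_calibration_standards

CAL48 = fit_calibration(default_calibration_standards(48))


def _profile(*components, n=48):
    """Sum of (apex, sd, amp) Gaussians, smoothed and normalized."""
    v = np.zeros(n)
    for apex, sd, amp in components:
        v += amp * _gaussian(n, apex, sd)
    return profile_io.minmax_normalize(profile_io.smooth(v))


def test_flat_and_zero_profiles_yield_no_peaks():
    assert extract_peaks(np.zeros(48)) == []
    assert extract_peaks(np.full(48, 0.7)) == []


@pytest.mark.parametrize("apex", [12, 20, 33])
def test_single_gaussian_yields_one_peak_at_argmax(apex):
    v = _profile((apex, 1.5, 1.0))
    peaks = extract_peaks(v)
    assert len(peaks) == 1
    # oracle: the apex of the noiseless profile is its argmax
    assert abs(peaks[0].apex_fraction - (int(np.argmax(v)) + 1)) <= 1
    assert abs(peaks[0].apex_fraction - apex) <= 1


def test_two_separated_gaussians_yield_two_peaks():
    peaks = extract_peaks(_profile((10, 1.5, 1.0), (30, 1.5, 0.8)))
    assert [p.apex_fraction for p in peaks] == [10, 30]


def test_mirrored_profile_yields_mirrored_apexes():
    v = _profile((10, 1.5, 1.0), (31, 2.0, 0.7))
    fwd = [p.apex_fraction for p in extract_peaks(v)]
    rev = [49 - p.apex_fraction for p in extract_peaks(v[::-1])]
    assert sorted(fwd) == sorted(rev)


def test_window_spans_chosen_width_and_zeros_outside():
    (peak,) = extract_peaks(_profile((20, 1.5, 1.0)))
    assert peak.lo_fraction <= peak.apex_fraction <= peak.hi_fraction
    outside = np.ones(48, bool)
    outside[peak.lo_fraction - 1 : peak.hi_fraction] = False
    assert (peak.values[outside] == 0).all()
    assert peak.amplitude == peak.values.max() > 0


def test_agrees_with_scipy_ridge_picker_on_separated_peaks():
    from scipy.signal import find_peaks_cwt

    for apexes in ([10, 30], [8, 22, 40]):
        v = _profile(*[(a, 1.5, 1.0) for a in apexes])
        ours = [p.apex_fraction for p in extract_peaks(v)]
        scipys = [int(i) + 1 for i in find_peaks_cwt(v, np.arange(2, 9))]
        assert len(ours) == len(apexes)
        for a, b in zip(sorted(ours), sorted(scipys)):
            assert abs(a - b) <= 1


def test_ricker_kernel_shape():
    for w in (2, 4, 8):
        k = ricker(10 * w + 1, w)
        centre = 5 * w
        assert np.argmax(k) == centre
        # positive support spans (-w, w); side-lobe minima near sqrt(3)*w
        x = np.arange(len(k)) - centre
        assert (k[np.abs(x) < w] > 0).all()
        assert (k[np.abs(x) > w] <= 0).all()
        minima = sorted(abs(m - centre) for m in np.argsort(k)[:2])
        assert all(abs(m - np.sqrt(3) * w) <= 1 for m in minima)


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------


def _peak(apex, amp, gid="G", monomer=10.0, n=48, width=2):
    values = np.zeros(n)
    lo, hi = max(1, apex - width), min(n, apex + width)
    values[lo - 1 : hi] = amp
    return Peak(
        group_id=gid,
        source="mean",
        apex_fraction=apex,
        lo_fraction=lo,
        hi_fraction=hi,
        values=values,
        amplitude=amp,
        apex_mw_kda=CAL48.fraction_to_mw(apex),
        monomer_mw_kda=monomer,
    )


def test_noise_filter_drops_sub_15_percent_peaks():
    peaks = [_peak(20, 1.0), _peak(30, 0.10), _peak(40, 0.151, monomer=5.0)]
    kept = filter_peaks(peaks, profile_max=1.0)
    assert [p.apex_fraction for p in kept] == [20, 40]


def test_dimer_rule_drops_peaks_at_or_below_twice_monomer_mw():
    # apparent MW at fraction 30 is ~80 kDa
    mw30 = CAL48.fraction_to_mw(30)
    at_dimer = _peak(30, 1.0, monomer=mw30 / 2.0)
    below = _peak(30, 1.0, monomer=mw30 / 1.9)
    above = _peak(30, 1.0, monomer=mw30 / 2.5)
    assert filter_peaks([at_dimer], 1.0) == []  # "equal to" is dropped
    assert filter_peaks([below], 1.0) == []
    assert len(filter_peaks([above], 1.0)) == 1


def test_void_filter_drops_fractions_1_to_4():
    peaks = [_peak(a, 1.0) for a in (1, 4, 5, 20)]
    kept = filter_peaks(peaks, 1.0)
    assert [p.apex_fraction for p in kept] == [5, 20]


def test_apex_separation_keeps_larger_amplitude():
    kept = filter_peaks([_peak(10, 0.9), _peak(12, 0.4)], 1.0)
    assert [p.apex_fraction for p in kept] == [10]
    # tie broken toward the smaller apex
    kept = filter_peaks([_peak(12, 0.9), _peak(10, 0.9)], 1.0)
    assert [p.apex_fraction for p in kept] == [10]
    # 3 fractions apart is allowed
    kept = filter_peaks([_peak(10, 0.9), _peak(13, 0.4)], 1.0)
    assert [p.apex_fraction for p in kept] == [10, 13]


def test_filters_idempotent_and_nonincreasing():
    peaks = [
        _peak(3, 1.0), _peak(8, 0.05), _peak(20, 1.0), _peak(21, 0.8),
        _peak(40, 0.9, monomer=40.0),
    ]
    once = filter_peaks(peaks, 1.0)
    twice = filter_peaks(once, 1.0)
    assert len(once) <= len(peaks)
    assert [p.apex_fraction for p in once] == [p.apex_fraction for p in twice]


def test_retained_peaks_clear_void_and_dimer_bounds():
    rng = np.random.default_rng(0)
    for _ in range(20):
        peaks = [
            _peak(int(a), float(rng.uniform(0.05, 1.0)), monomer=float(m))
            for a, m in zip(rng.integers(1, 49, 12), rng.uniform(5, 200, 12))
        ]
        for p in filter_peaks(peaks, 1.0):
            assert p.apex_fraction >= 5
            assert p.apex_mw_kda > 2 * p.monomer_mw_kda


def test_planted_peak_recovery_on_small_noisy_batch():
    rng = np.random.default_rng(42)
    n_ok = 0
    for _ in range(60):
        apex = int(rng.integers(10, 40))
        sd = float(rng.uniform(2.0, 4.0))
        v = _gaussian(48, apex, sd)
        noise = rng.lognormal(0, 0.1, 48)
        prof = profile_io.minmax_normalize(profile_io.smooth(v * noise))
        kept = filter_peaks(
            extract_peaks(prof, calibration=CAL48, monomer_mw_kda=5.0),
            1.0, CAL48,
        )
        if len(kept) == 1 and abs(kept[0].apex_fraction - apex) <= 1:
            n_ok += 1
    assert n_ok >= 54  # >= 90% on the small batch
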