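"""HRV metric oracles: every index is checked against an independently
coded brute-force evaluation of its defining formula."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from thermohrv import hrv, synthetic as syn
from thermohrv.signals import DegenerateInputError, RRSeries

from conftest import random_rr_ms


# ---------------------------------------------------------------- oracles
def oracle_mean_hr(rr):
    return sum(60000.0 / x for x in rr) / len(rr)


def oracle_sdnn(rr):
    m = sum(rr) / len(rr)
    return (sum((x - m) ** 2 for x in rr) / (len(rr) - 1)) ** 0.5


def oracle_rmssd(rr):
    d = [rr[i + 1] - rr[i] for i in range(len(rr) - 1)]
    return (sum(x * x for x in d) / len(d)) ** 0.5


def oracle_pnn50(rr):
    nn50 = sum(1 for i in range(len(rr) - 1) if abs(rr[i + 1] - rr[i]) > 50.0)
    return 100.0 * nn50 / len(rr)


def oracle_tinn(rr, bin_ms=hrv.TINN_BIN_MS):
    """Exhaustive triangular fit, written independently with plain loops."""
    lo = np.floor(min(rr) / bin_ms) * bin_ms
    nbins = int(np.floor((max(rr) - lo) / bin_ms)) + 1
    edges = [lo + bin_ms * i for i in range(nbins + 1)]
    counts, _ = np.histogram(rr, bins=edges)
    centers = [e + bin_ms / 2 for e in edges[:-1]]
    occupied = [i for i, c in enumerate(counts) if c > 0]
    if occupied[0] == occupied[-1]:
        return 0.0
    i0, i1 = occupied[0], occupied[-1]
    apex = int(np.argmax(counts[i0 : i1 + 1])) + i0
    height = counts[apex]
    best = None
    for ni in range(i0, apex + 1):
        for mi in range(apex, i1 + 1):
            err = 0.0
            for j in range(i0, i1 + 1):
                c, n, m, a = centers[j], centers[ni], centers[mi], centers[apex]
                if c < n or c > m:
                    q = 0.0
                elif c <= a:
                    q = height if a == n else height * (c - n) / (a - n)
                else:
                    q = height * (m - c) / (m - a)
                err += (counts[j] - q) ** 2
            width = centers[mi] - centers[ni]
            if best is None or err < best[0] - 1e-12 or (
                abs(err - best[0]) <= 1e-12 and width > best[1]
            ):
                best = (err, width)
    return best[1]


# ----------------------------------------------------------------- tests
def test_time_domain_metrics_match_bruteforce_oracles(rng):
    """100 random series: each Table-style index equals its formula."""
    for _ in range(100):
        rr = random_rr_ms(rng)
        assert hrv.mean_hr(rr) == pytest.approx(oracle_mean_hr(rr), abs=1e-9)
        assert hrv.mean_rr(rr) == pytest.approx(np.mean(rr), abs=1e-9)
        assert hrv.sdnn(rr) == pytest.approx(oracle_sdnn(rr), abs=1e-9)
        assert hrv.rmssd(rr) == pytest.approx(oracle_rmssd(rr), abs=1e-9)
        assert hrv.pnn50(rr) == pytest.approx(oracle_pnn50(rr), abs=1e-9)
        assert hrv.tinn(rr) == pytest.approx(oracle_tinn(rr), abs=hrv.TINN_BIN_MS)


@pytest.mark.parametrize(
    "rr, expected",
    [
        ([1000, 1000, 1000], 60.0),
        ([500], 120.0),
    ],
)
def test_mean_hr_examples(rr, expected):
    assert hrv.mean_hr(np.array(rr, float)) == pytest.approx(expected)


def test_mean_hr_overall_mode_differs_for_nonconstant():
    rr = np.array([600.0, 1200.0])
    inst = hrv.mean_hr(rr)  # (100 + 50) / 2
    overall = hrv.mean_hr(rr, method="overall")  # 60000 / 900
    assert inst == pytest.approx(75.0)
    assert overall == pytest.approx(60000.0 / 900.0)


def test_rmssd_and_pnn50_hand_examples():
    rr = np.array([800.0, 810.0, 790.0, 800.0])
    assert hrv.rmssd(rr) == pytest.approx(np.sqrt((100 + 400 + 100) / 3))
    rr2 = np.array([800.0, 860.0, 870.0, 801.0])
    # diffs 60, 10, -69 -> two exceed 50 ms; denominator is len(rr) = 4
    assert hrv.pnn50(rr2) == pytest.approx(50.0)


def test_constant_series_has_zero_variability():
    rr = np.full(60, 1000.0)
    assert hrv.sdnn(rr) == 0.0
    assert hrv.rmssd(rr) == 0.0
    assert hrv.pnn50(rr) == 0.0
    assert hrv.tinn(rr) == 0.0


def test_tinn_symmetric_three_bin_triangle():
    """Counts (1, 2, 1) in adjacent bins -> base of two bin widths."""
    bw = hrv.TINN_BIN_MS
    centers = 800.0 + bw * np.arange(3) + bw / 2
    rr = np.repeat(centers, [1, 2, 1])
    assert hrv.tinn(rr) == pytest.approx(2 * bw)


def test_scale_behavior_of_time_domain_metrics(rng):
    rr = random_rr_ms(rng, 60)
    c = 1.7
    assert hrv.mean_rr(c * rr) == pytest.approx(c * hrv.mean_rr(rr))
    assert hrv.sdnn(c * rr) == pytest.approx(c * hrv.sdnn(rr))
    assert hrv.rmssd(c * rr) == pytest.approx(c * hrv.rmssd(rr))
    assert hrv.mean_hr(c * rr) == pytest.approx(hrv.mean_hr(rr) / c)
    # widening differences can only push more pairs over the 50 ms line
    assert hrv.pnn50(c * rr) >= hrv.pnn50(rr)


def test_permutation_invariance_and_rmssd_counterexample(rng):
    rr = random_rr_ms(rng, 50)
    perm = rng.permutation(rr)
    for f in (hrv.mean_rr, hrv.mean_hr, hrv.sdnn):
        assert f(perm) == pytest.approx(f(rr))
    # successive-difference metrics are order-sensitive (pNN50 only through
    # its numerator; its denominator is the permutation-invariant len(rr))
    rr_sorted = np.sort(rr)
    assert hrv.rmssd(rr_sorted) != pytest.approx(hrv.rmssd(rr))
    assert hrv.pnn50(rr_sorted) <= hrv.pnn50(rr)


@settings(deadline=None, max_examples=30, derandomize=True)
@given(st.lists(st.floats(min_value=400.0, max_value=1800.0), min_size=4, max_size=80))
def test_metric_bounds_hold_for_arbitrary_series(values):
    rr = np.asarray(values)
    assert hrv.mean_hr(rr) > 0
    assert hrv.sdnn(rr) >= 0
    assert hrv.rmssd(rr) >= 0
    assert 0.0 <= hrv.pnn50(rr) <= 100.0
    assert hrv.tinn(rr) >= 0


def test_lf_hf_ratio_separates_known_spectral_content():
    lf_only = syn.generate_rr_series(
        syn.SubjectParams(mean_rr=1000, lf_amp=40, hf_amp=0, duration=60)
    )
    hf_only = syn.generate_rr_series(
        syn.SubjectParams(mean_rr=1000, lf_amp=0, hf_amp=40, breath_freq=0.3, duration=60)
    )
    with pytest.warns(UserWarning, match="LF"):
        assert hrv.lf_hf_ratio(lf_only) > 5
    with pytest.warns(UserWarning, match="LF"):
        assert hrv.lf_hf_ratio(hf_only) < 0.2


def test_lf_hf_ratio_balanced_tones_near_unity():
    rr = syn.generate_rr_series(
        syn.SubjectParams(mean_rr=1000, lf_amp=40, hf_amp=40, breath_freq=0.3, duration=60)
    )
    with pytest.warns(UserWarning, match="LF"):
        ratio = hrv.lf_hf_ratio(rr)
    assert 0.5 <= ratio <= 2.0


def test_lf_hf_requires_30s_and_nonzero_hf_power():
    short = RRSeries(beat_times=np.arange(0, 20, 1.0))
    with pytest.raises(DegenerateInputError):
        hrv.lf_hf_ratio(short)
    constant = RRSeries(beat_times=np.arange(0, 61, 1.0))
    with pytest.raises(DegenerateInputError), pytest.warns(UserWarning):
        hrv.lf_hf_ratio(constant)


def test_compute_all_is_consistent_with_individual_operations(rng):
    rr_ms = random_rr_ms(rng, 70)
    beats = np.concatenate([[0.0], np.cumsum(rr_ms) / 1000.0])
    rr = RRSeries(beat_times=beats)
    with pytest.warns(UserWarning):
        m = hrv.compute_all(rr)
    assert m.hr == hrv.mean_hr(rr)
    assert m.rr_mean == hrv.mean_rr(rr)
    assert m.sdnn == hrv.sdnn(rr)
    assert m.rmssd == hrv.rmssd(rr)
    assert m.pnn50 == hrv.pnn50(rr)
    assert m.tinn == hrv.tinn(rr)
    with pytest.warns(UserWarning):
        assert m.lf_hf == hrv.lf_hf_ratio(rr)


def test_compute_all_flags_degenerate_spectrum():
    rr = RRSeries(beat_times=np.arange(0, 61, 1.0))
    with pytest.warns(UserWarning):
        m = hrv.compute_all(rr)
    assert m.hr == pytest.approx(60.0)
    assert m.rr_mean == pytest.approx(1000.0)
    assert m.sdnn == 0.0 and m.rmssd == 0.0 and m.pnn50 == 0.0 and m.tinn == 0.0
    assert np.isnan(m.lf_hf)
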