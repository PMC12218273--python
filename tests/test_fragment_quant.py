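"""Peak registration, the +/-5-position rule, and MT/WT ratios."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from hidyce import (
    AlleleSpec,
    BinningMode,
    DyeTrace,
    InstrumentConfig,
    PeakMeasurement,
    RegistrationError,
    RegistryEntry,
    SamplePlan,
    acquire,
    deconvolve,
    make_dye_spectra,
    measure_allele,
    register_alleles,
    relative_intensity,
    simulate_pixel_frames,
)

from conftest import gaussian


def dye_trace(channel_values, dye=0, saturated_scans=()):
    """Single-capillary DyeTrace with one channel populated."""
    n = len(channel_values)
    intensities = np.zeros((n, 1, 4))
    intensities[:, 0, dye] = channel_values
    sat = np.zeros((n, 1), dtype=bool)
    for s in saturated_scans:
        sat[s, 0] = True
    return DyeTrace(intensities=intensities, saturated=sat)


def gaussian_trace(positions, heights, sigma=3.0, n=600, dye=0):
    t = np.arange(n)
    y = np.zeros(n)
    for p, h in zip(positions, heights):
        y += h * gaussian(t, p, sigma)
    return dye_trace(y, dye=dye)


class TestRegistration:
    def test_noise_free_apexes_recovered_exactly(self):
        trace = gaussian_trace([400, 430, 460], [100, 80, 120])
        reg = register_alleles(trace, [("a", 0), ("b", 0), ("c", 0)])
        assert [reg[n].position for n in "abc"] == [400, 430, 460]

    def test_shifted_apex_registered_at_shifted_scan(self):
        trace = gaussian_trace([402], [50.0])
        reg = register_alleles(trace, [("a", 0)])
        assert reg["a"].position == 402

    def test_fewer_peaks_than_alleles_fails_naming_channel(self):
        trace = gaussian_trace([300], [50.0], dye=2)
        with pytest.raises(RegistrationError, match="channel 2"):
            register_alleles(trace, [("a", 2), ("b", 2)])

    def test_registry_rejects_duplicate_positions(self):
        from hidyce import AlleleRegistry

        with pytest.raises(ValueError, match="duplicate"):
            AlleleRegistry((
                RegistryEntry("a", 0, 100), RegistryEntry("b", 0, 100),
            ))


class TestWindowRule:
    def test_apex_at_registered_position(self):
        trace = gaussian_trace([100], [55.0])
        m = measure_allele(trace, RegistryEntry("a", 0, 100))
        assert m.intensity == pytest.approx(55.0)
        assert m.window == (95, 105)

    def test_drift_of_5_scans_still_captures_apex(self):
        trace = gaussian_trace([105], [55.0])
        m = measure_allele(trace, RegistryEntry("a", 0, 100))
        assert m.intensity == pytest.approx(55.0)

    def test_drift_of_6_scans_captures_flank(self):
        """Apex one scan beyond the window edge: the measured value is the
        Gaussian flank one scan from the apex, h * exp(-1/(2 sigma^2))."""
        trace = gaussian_trace([106], [55.0], sigma=2.0)
        m = measure_allele(trace, RegistryEntry("a", 0, 100))
        assert m.intensity == pytest.approx(
            55.0 * np.exp(-1.0 / 8.0), rel=1e-9
        )
        assert m.intensity == pytest.approx(0.8825 * 55.0, rel=1e-3)

    @given(seed=st.integers(0, 2000), pos=st.integers(5, 594))
    def test_window_max_matches_brute_force_oracle(self, seed, pos):
        rng = np.random.default_rng(seed)
        y = rng.normal(size=600)
        trace = dye_trace(y)
        m = measure_allele(trace, RegistryEntry("a", 0, pos))
        brute = max(y[max(pos - 5, 0): pos + 6])
        assert m.intensity == pytest.approx(max(brute, 0.0))

    def test_window_truncated_at_edges(self):
        y = np.linspace(1, 20, 20)
        m = measure_allele(dye_trace(y), RegistryEntry("a", 0, 2))
        assert m.window == (0, 7)
        assert m.intensity == pytest.approx(y[7])

    def test_window_outside_trace_rejected(self):
        with pytest.raises(ValueError, match="outside trace"):
            measure_allele(dye_trace(np.ones(20)), RegistryEntry("a", 0, 40))

    def test_all_negative_window_clamped_to_zero(self):
        m = measure_allele(
            dye_trace(-np.ones(50)), RegistryEntry("a", 0, 25)
        )
        assert m.intensity == 0.0

    def test_saturation_flag_is_or_over_window(self):
        trace = dye_trace(np.ones(50), saturated_scans=[27])
        assert measure_allele(trace, RegistryEntry("a", 0, 25)).saturated
        assert not measure_allele(trace, RegistryEntry("a", 0, 10)).saturated


class TestRelativeIntensity:
    def wt(self, intensity=100.0, saturated=False):
        return PeakMeasurement("WT", intensity, (0, 10), saturated)

    def test_equal_peaks_give_unity(self):
        mt = PeakMeasurement("MT", 100.0, (0, 10), False)
        assert relative_intensity(mt, self.wt()).value == pytest.approx(1.0)

    def test_small_ratio(self):
        mt = PeakMeasurement("MT", 0.5, (0, 10), False)
        assert relative_intensity(mt, self.wt()).value == pytest.approx(0.005)

    def test_saturated_wt_marks_unreliable(self):
        mt = PeakMeasurement("MT", 1.0, (0, 10), False)
        r = relative_intensity(mt, self.wt(saturated=True))
        assert r.unreliable

    def test_nonpositive_wt_rejected(self):
        mt = PeakMeasurement("MT", 1.0, (0, 10), False)
        with pytest.raises(ValueError, match="not positive"):
            relative_intensity(mt, self.wt(intensity=0.0))

    @given(scale=st.floats(1e-3, 1e3))
    def test_scale_invariance(self, scale):
        y = np.zeros(200)
        y[50], y[150] = 30.0, 900.0
        entries = [RegistryEntry("MT", 0, 50), RegistryEntry("WT", 0, 150)]
        rs = []
        for s in (1.0, scale):
            trace = dye_trace(y * s)
            mt, wt = (measure_allele(trace, e) for e in entries)
            rs.append(relative_intensity(mt, wt).value)
        assert rs[0] == pytest.approx(rs[1], rel=1e-12)


def test_end_to_end_noise_free_ratio_is_exact(quiet_config):
    """simulate -> acquire(hidy) -> deconvolve -> measure recovers the
    configured amplitude x VAF ratio exactly when noise and saturation
    are absent."""
    wt = AlleleSpec("K-WT", 1, 120, 3.0, 8000.0)
    mt = AlleleSpec("K-MT", 1, 80, 3.0, 8000.0)
    vaf = 0.02
    plan = SamplePlan(alleles=((wt, 1 - vaf), (mt, vaf)), seed=0)
    frames = simulate_pixel_frames(quiet_config, plan)
    trace = acquire(frames, BinningMode.hidy(), quiet_config, seed=None)
    dye = deconvolve(trace, make_dye_spectra())
    m_mt = measure_allele(dye, RegistryEntry("K-MT", 1, 80))
    m_wt = measure_allele(dye, RegistryEntry("K-WT", 1, 120))
    r = relative_intensity(m_mt, m_wt)
    assert not r.unreliable
    assert r.value == pytest.approx(vaf / (1 - vaf), rel=1e-9)
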