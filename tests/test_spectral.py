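"""Welch PSD, band powers, region aggregation and the theta/beta ratio."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qeegdep import (
    BandScheme,
    MontageConfig,
    SegmentLabel,
    band_powers,
    compute_psd,
    compute_tbr,
)
from qeegdep.exceptions import (
    DegenerateInputError,
    InsufficientDataError,
    ResolutionError,
    SelectionError,
)
from qeegdep.spectral import aggregate_region_means

from conftest import make_segment


def total_power(psd):
    return np.trapezoid(psd.power, psd.frequencies, axis=-1)


class TestComputePsd:
    def test_sinusoid_power_matches_closed_form(self, tone_segment):
        """A unit tone carries amplitude^2/2 = 0.5 uV^2, all near 10 Hz."""
        psd = compute_psd(tone_segment)
        p = total_power(psd)[0]
        assert p == pytest.approx(0.5, rel=0.05)
        assert p == pytest.approx(np.var(tone_segment.samples), rel=0.05)
        mask = np.abs(psd.frequencies - 10.0) <= 1.0
        near10 = np.trapezoid(psd.power[0, mask], psd.frequencies[mask])
        assert near10 >= 0.95 * p

    def test_zero_signal_gives_zero_psd(self):
        seg = make_segment(signal_fn=lambda t, rng: np.zeros_like(t))
        psd = compute_psd(seg)
        assert np.all(psd.power == 0)

    def test_white_noise_satisfies_parseval(self):
        sigma = 3.0
        seg = make_segment(duration=120.0,
                           signal_fn=lambda t, rng: rng.normal(0, sigma,
                                                               t.size))
        psd = compute_psd(seg)
        assert total_power(psd)[0] == pytest.approx(sigma**2, rel=0.05)

    def test_too_short_segment_raises(self):
        seg = make_segment(duration=3.0)
        with pytest.raises(InsufficientDataError):
            compute_psd(seg)


MULTITONE = {2.0: 1.0, 6.0: 1.0, 10.0: 1.0, 20.0: 2.0, 40.0: 0.5}


def multitone_segment():
    def f(t, rng):
        return sum(a * np.sin(2 * np.pi * fr * t)
                   for fr, a in MULTITONE.items())

    return make_segment(duration=60.0, signal_fn=f)


class TestBandPowers:
    def test_pure_alpha_tone_concentrates_in_alpha(self, tone_segment):
        abs_df, rel_df = band_powers(compute_psd(tone_segment))
        assert rel_df.loc["FZ-CZ", "alpha"] >= 0.95
        for band in ("delta", "theta", "beta", "gamma"):
            assert rel_df.loc["FZ-CZ", band] <= 0.02

    def test_multitone_relative_powers_match_analytic_ratios(self):
        """Tone powers a^2/2: alpha carries 0.5 of 3.625 total."""
        abs_df, rel_df = band_powers(compute_psd(multitone_segment()))
        expected = {"delta": 0.5, "theta": 0.5, "alpha": 0.5, "beta": 2.0,
                    "gamma": 0.125}
        total = sum(expected.values())  # 3.625
        for band, p in expected.items():
            assert rel_df.loc["FZ-CZ", band] == pytest.approx(p / total,
                                                              rel=0.05)
        assert rel_df.loc["FZ-CZ", "alpha"] == pytest.approx(0.1379, abs=0.01)

    def test_zero_denominator_raises_degenerate(self):
        seg = make_segment(signal_fn=lambda t, rng: np.zeros_like(t))
        with pytest.raises(DegenerateInputError):
            band_powers(compute_psd(seg))

    def test_unresolvable_band_raises_resolution_error(self, tone_segment):
        scheme = BandScheme(bands={"sliver": (10.0, 10.2),
                                   "rest": (10.2, 45.0)},
                            relative_denominator=(1.0, 45.0))
        with pytest.raises(ResolutionError):
            band_powers(compute_psd(tone_segment), scheme)

    def test_relative_powers_sum_to_one_when_bands_span_denominator(self):
        seg = make_segment(duration=60.0)
        _, rel_df = band_powers(compute_psd(seg))
        assert rel_df.sum(axis=1).iloc[0] == pytest.approx(1.0, abs=1e-9)

    def test_scaling_leaves_relative_powers_invariant(self):
        seg = multitone_segment()
        scaled = make_segment(duration=60.0,
                              signal_fn=lambda t, rng: 7.3 * sum(
                                  a * np.sin(2 * np.pi * fr * t)
                                  for fr, a in MULTITONE.items()))
        a1, r1 = band_powers(compute_psd(seg))
        a2, r2 = band_powers(compute_psd(scaled))
        np.testing.assert_allclose(a2.values, 7.3**2 * a1.values, rtol=1e-9)
        np.testing.assert_allclose(r2.values, r1.values, atol=1e-9)

    def test_adding_alpha_power_raises_alpha_and_lowers_other_relatives(self):
        base = multitone_segment()
        boosted = make_segment(duration=60.0,
                               signal_fn=lambda t, rng: sum(
                                   a * np.sin(2 * np.pi * fr * t)
                                   for fr, a in MULTITONE.items())
                               + 2.0 * np.sin(2 * np.pi * 11 * t))
        _, r1 = band_powers(compute_psd(base))
        _, r2 = band_powers(compute_psd(boosted))
        assert r2.loc["FZ-CZ", "alpha"] > r1.loc["FZ-CZ", "alpha"]
        for band in ("delta", "theta", "beta", "gamma"):
            assert r2.loc["FZ-CZ", band] <= r1.loc["FZ-CZ", band] + 1e-12


class TestTbr:
    @pytest.mark.parametrize(
        "theta, beta, expected",
        [(0.5, 1.0, 0.5), (0.07, 0.29, 0.07 / 0.29), (0.0, 0.2, 0.0)],
    )
    def test_ratio(self, theta, beta, expected):
        assert compute_tbr(theta, beta) == pytest.approx(expected)

    def test_group_mean_ratio_example(self):
        # ratio of hyperventilation group-mean relatives; distinct from a
        # mean of per-subject ratios
        assert compute_tbr(0.07, 0.29) == pytest.approx(0.241, abs=0.001)

    def test_zero_beta_is_an_error_not_infinity(self):
        with pytest.raises(DegenerateInputError):
            compute_tbr(0.5, 0.0)


class TestRegionAggregation:
    @staticmethod
    def _frames(values):
        """values: channel -> band -> relative power; absolute = 10x."""
        rel = pd.DataFrame(values).T
        return rel * 10.0, rel

    def test_mean_of_identical_channels_is_unchanged(self):
        row = dict(delta=0.1, theta=0.2, alpha=0.3, beta=0.3, gamma=0.1)
        abs_df, rel_df = self._frames({"FZ-CZ": row, "CZ-PZ": row})
        rec = aggregate_region_means(abs_df, rel_df, SegmentLabel.BACKGROUND)
        assert rec.relative == pytest.approx(row)
        assert rec.n_channels == 2

    def test_arithmetic_mean_of_two_channels(self):
        a = dict(delta=0.2, theta=0.2, alpha=0.1, beta=0.4, gamma=0.1)
        b = dict(delta=0.2, theta=0.2, alpha=0.3, beta=0.2, gamma=0.1)
        abs_df, rel_df = self._frames({"FZ-CZ": a, "CZ-PZ": b})
        rec = aggregate_region_means(abs_df, rel_df, SegmentLabel.BACKGROUND)
        assert rec.relative["alpha"] == pytest.approx(0.2)
        # aggregate TBR = ratio of mean theta to mean beta
        assert rec.tbr == pytest.approx(0.2 / 0.3)
        # per-channel mean kept alongside: (0.5 + 1.0)/2
        assert rec.tbr_channel_mean == pytest.approx(0.75)

    def test_empty_region_raises_selection_error(self):
        row = dict(delta=0.1, theta=0.2, alpha=0.3, beta=0.3, gamma=0.1)
        abs_df, rel_df = self._frames({"FZ-CZ": row})
        with pytest.raises(SelectionError):
            aggregate_region_means(abs_df, rel_df, SegmentLabel.BACKGROUND,
                                   region="frontal")


class TestBandScheme:
    def test_overlapping_bands_rejected(self):
        with pytest.raises(ValueError):
            BandScheme(bands={"a": (1.0, 10.0), "b": (8.0, 20.0)})

    def test_denominator_must_cover_bands(self):
        with pytest.raises(ValueError):
            BandScheme(relative_denominator=(1.0, 20.0))


@settings(deadline=None, max_examples=20)
@given(scale=st.floats(min_value=0.01, max_value=100.0),
       seed=st.integers(min_value=0, max_value=2**16))
def test_scale_invariance_property(scale, seed):
    """Scaling a signal scales absolute powers by c^2, relatives unchanged."""
    rng = np.random.default_rng(seed)
    base = rng.normal(0, 1, 250 * 20)
    seg1 = make_segment(duration=20.0, signal_fn=lambda t, r: base)
    seg2 = make_segment(duration=20.0, signal_fn=lambda t, r: scale * base)
    a1, r1 = band_powers(compute_psd(seg1))
    a2, r2 = band_powers(compute_psd(seg2))
    np.testing.assert_allclose(a2.values, scale**2 * a1.values, rtol=1e-9)
    np.testing.assert_allclose(r2.values, r1.values, atol=1e-9)
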