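"""Derived indices: ratios, categorical thresholds, NA propagation."""

import numpy as np
import pytest

from qeegdep import SegmentLabel, compute_indices, generate_feature_fixture
from qeegdep.indices import (
    NA,
    alpha_blocking,
    cortical_reactivity,
    dependence_pattern,
    homeostatic_recovery,
    hyperarousal,
    power_status,
    tbr_category,
)


class TestAlphaBlocking:
    @pytest.mark.parametrize(
        "ec, eo, ratio, intact",
        [
            (0.09, 0.07, 0.09 / 0.07, "no"),   # 1.286 < 1.3
            (0.1, 0.1, 1.0, "no"),
            (0.26, 0.13, 2.0, "yes"),
            (0.13, 0.10, 1.3, "yes"),          # boundary: >= is intact
        ],
    )
    def test_ratio_and_intact_flag(self, ec, eo, ratio, intact):
        r, flag = alpha_blocking(ec, eo)
        assert r == pytest.approx(ratio)
        assert flag == intact

    def test_zero_eyes_open_reports_capped_sentinel(self):
        with pytest.warns(UserWarning):
            r, flag = alpha_blocking(0.2, 0.0)
        assert r == 10.0 and flag == "yes"

    def test_both_zero_is_na(self):
        r, flag = alpha_blocking(0.0, 0.0)
        assert r is None and flag == NA


class TestPowerStatus:
    @pytest.mark.parametrize(
        "alpha, beta, expected",
        [
            (0.08, 0.22, ("low", "high")),
            (0.25, 0.20, ("normal", "normal")),  # strict comparators
            (0.30, 0.10, ("normal", "normal")),
        ],
    )
    def test_status(self, alpha, beta, expected):
        assert power_status(alpha, beta) == expected


class TestHyperarousal:
    @pytest.mark.parametrize(
        "beta, alpha, index, cat",
        [
            (0.22, 0.08, 2.75, "high"),
            (0.1, 0.1, 1.0, "normal"),
            (0.1, 0.2, 0.5, "low"),
            (0.2, 0.1, 2.0, "normal"),  # closed interval [1, 2]
        ],
    )
    def test_index_and_category(self, beta, alpha, index, cat):
        hri, c = hyperarousal(beta, alpha)
        assert hri == pytest.approx(index)
        assert c == cat

    def test_zero_alpha_caps_with_warning(self):
        with pytest.warns(UserWarning):
            hri, c = hyperarousal(0.2, 0.0)
        assert hri == 10.0 and c == "high"


class TestCorticalReactivity:
    def test_two_term_mean(self):
        cri, cat, single = cortical_reactivity(0.09, 0.07, 0.07, 0.08)
        assert cri == pytest.approx(0.005)
        assert cat == "normal" and not single

    def test_all_equal_is_zero_and_normal(self):
        cri, cat, _ = cortical_reactivity(0.1, 0.1, 0.1, 0.1)
        assert cri == 0.0 and cat == "normal"

    def test_missing_flash_uses_single_term_and_flags_it(self):
        cri, cat, single = cortical_reactivity(0.06, 0.09, None, None)
        assert cri == pytest.approx(-0.03)
        assert cat == "low" and single

    def test_no_terms_is_na(self):
        assert cortical_reactivity(None, None, None, None) == (None, NA, False)


class TestHomeostaticRecovery:
    @pytest.mark.parametrize(
        "after, during, score, cat",
        [
            (0.08, 0.09, 0.08 / 0.09, "normal"),  # 0.889
            (0.1, 0.1, 1.0, "normal"),
            (0.04, 0.08, 0.5, "low"),
            (0.12, 0.10, 1.2, "normal"),  # closed interval [0.8, 1.2]
        ],
    )
    def test_score_and_category(self, after, during, score, cat):
        s, c = homeostatic_recovery(after, during)
        assert s == pytest.approx(score)
        assert c == cat

    def test_missing_segment_is_na(self):
        assert homeostatic_recovery(None, 0.1) == (None, NA)


class TestTbrCategory:
    @pytest.mark.parametrize(
        "tbr, cat",
        [(0.63, "low"), (1.0, "normal"), (4.0, "normal"), (4.5, "high")],
    )
    def test_category(self, tbr, cat):
        assert tbr_category(tbr) == cat


class TestDependencePattern:
    @pytest.mark.parametrize(
        "alpha, beta, tbr, label",
        [
            ("low", "high", "low", "hyperaroused"),  # first rule wins
            ("normal", "high", "low", "disinhibited"),
            ("normal", "normal", "normal", "balanced"),
            ("low", "normal", "low", "balanced"),
        ],
    )
    def test_rule_order(self, alpha, beta, tbr, label):
        assert dependence_pattern(alpha, beta, tbr) == label


class TestCategoryPartition:
    """Category maps are exhaustive and mutually exclusive over a value grid."""

    GRID = np.round(np.arange(-0.5, 6.0, 0.01), 10)
    BOUNDARIES = [1.3, 0.25, 0.20, 1.0, 2.0, 4.0, 0.8, 1.2, 0.0, 0.05]

    def _check(self, fn, values, allowed):
        for v in values:
            out = fn(float(v))
            assert out in allowed, (v, out)

    def test_tbr_partition(self):
        self._check(tbr_category, np.abs(self.GRID),
                    {"low", "normal", "high"})
        assert tbr_category(1.0) == "normal"
        assert tbr_category(4.0) == "normal"
        assert np.nextafter(4.0, 5.0) and tbr_category(4.0000001) == "high"

    def test_hri_partition(self):
        for v in np.abs(self.GRID):
            _, cat = hyperarousal(float(v), 1.0)
            assert cat in {"low", "normal", "high"}
        assert hyperarousal(1.0, 1.0)[1] == "normal"
        assert hyperarousal(2.0, 1.0)[1] == "normal"
        assert hyperarousal(2.0001, 1.0)[1] == "high"

    def test_recovery_partition(self):
        for v in np.abs(self.GRID):
            _, cat = homeostatic_recovery(float(v), 1.0)
            assert cat in {"low", "normal", "high"}
        assert homeostatic_recovery(0.8, 1.0)[1] == "normal"
        assert homeostatic_recovery(1.2, 1.0)[1] == "normal"

    def test_cri_partition(self):
        for v in self.GRID:
            _, cat, _ = cortical_reactivity(float(v), 0.0)
            assert cat in {"low", "normal", "high"}
        assert cortical_reactivity(0.0, 0.0)[1] == "normal"
        assert cortical_reactivity(0.05, 0.0)[1] == "normal"
        assert cortical_reactivity(0.051, 0.0)[1] == "high"
        assert cortical_reactivity(-1e-9, 0.0)[1] == "low"

    def test_blocking_and_power_status_partitions(self):
        for v in np.abs(self.GRID):
            assert alpha_blocking(float(v), 1.0)[1] in {"yes", "no"}
        for v in np.clip(self.GRID, 0, 1):
            a, b = power_status(float(v), float(v))
            assert a in {"low", "normal"} and b in {"high", "normal"}


class TestComputeIndicesFromFeatures:
    def test_worked_background_profile(self):
        features = generate_feature_fixture(
            tbr=0.63, alpha_rel=0.08, beta_rel=0.22, hri=2.75,
            alpha_blocking_ratio=1.0,
        )
        idx = compute_indices(features)
        assert idx.tbr_background == pytest.approx(0.63)
        assert idx.tbr_category == "low"
        assert idx.hyperarousal_index == pytest.approx(2.75)
        assert idx.hri_category == "high"
        assert idx.alpha_power_status == "low"
        assert idx.beta_power_status == "high"
        assert idx.alpha_blocking_intact == "no"
        assert idx.dependence_pattern == "hyperaroused"

    def test_na_iff_segment_missing(self, dependent_session):
        """Flash/HV comparisons are NA exactly when their segments are absent."""
        from qeegdep import extract_features, generate_session

        session = generate_session(
            "healthy", seed=2, duration_scale=0.1,
            missing_segments=[SegmentLabel.POST_FLASH,
                              SegmentLabel.HYPERVENTILATION],
        )
        from qeegdep import derive_bipolar_channels

        idx = compute_indices(
            extract_features(derive_bipolar_channels(session))
        )
        assert idx.after_flash_alpha_rebound == NA
        assert idx.homeostatic_recovery_score is None
        assert idx.hr_category == NA
        assert idx.after_hv_delta_increase == NA
        # present comparisons are never NA
        assert idx.alpha_blocking_intact in {"yes", "no"}
        assert idx.flash_beta_reactivity in {"yes", "no"}

    def test_equality_ties_take_the_negative_outcome(self):
        features = generate_feature_fixture(tbr=0.5, alpha_rel=0.1,
                                            beta_rel=0.2)
        idx = compute_indices(features)
        # fixture copies background alpha/delta into HV and post-HV segments
        assert idx.after_hv_alpha_recovery == "low"
        assert idx.after_hv_delta_increase == "no"
        assert idx.after_flash_alpha_rebound == "no"

    def test_scaling_all_powers_leaves_indices_unchanged(self):
        f1 = generate_feature_fixture(tbr=0.7, alpha_rel=0.1, beta_rel=0.25,
                                      total_power=100.0)
        f2 = generate_feature_fixture(tbr=0.7, alpha_rel=0.1, beta_rel=0.25,
                                      total_power=4200.0)
        i1, i2 = compute_indices(f1), compute_indices(f2)
        assert i1.to_row() == i2.to_row()
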