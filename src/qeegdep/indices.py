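"""Derived qEEG indices: reactivity, arousal balance and recovery measures.

Every index is a ratio, difference or comparison of *relative* band powers,
so all of them are invariant to rescaling the raw signal.  Continuous
indices come with a categorical counterpart defined by fixed clinical
thresholds; strict inequalities are honoured exactly as printed, closed
category intervals are inclusive at both ends, and an index is NA if and
only if a segment it requires is absent from the session.

Division-by-zero policy: when a denominator power is exactly zero while the
numerator is not, the ratio is reported as a configurable cap (default 10)
with a warning, rather than failing, so degenerate synthetic inputs flow
through the pipeline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

from .session import SegmentLabel
from .spectral import SegmentFeatureTable

#: Sentinel category for indices whose input segments are missing.
NA = "na"


@dataclass(frozen=True)
class IndexThresholds:
    """Clinical thresholds for the categorical derived variables."""

    alpha_blocking_intact: float = 1.3   # eyes-closed/eyes-open alpha ratio
    alpha_low: float = 0.25              # background alpha relative power
    beta_high: float = 0.20              # background beta relative power
    hri_normal: tuple[float, float] = (1.0, 2.0)
    tbr_normal: tuple[float, float] = (1.0, 4.0)
    recovery_normal: tuple[float, float] = (0.8, 1.2)
    cri_normal: tuple[float, float] = (0.0, 0.05)
    ratio_cap: float = 10.0              # sentinel for zero denominators


def _capped_ratio(num: float, den: float, cap: float, what: str
                  ) -> Optional[float]:
    if den > 0:
        return num / den
    if num == 0:
        return None  # 0/0: genuinely undefined -> NA
    warnings.warn(
        f"{what}: zero denominator with non-zero numerator; "
        f"reporting capped ratio {cap}", stacklevel=3,
    )
    return cap


def _band_category(value: float, normal: tuple[float, float]) -> str:
    lo, hi = normal
    if value < lo:
        return "low"
    if value > hi:
        return "high"
    return "normal"


def alpha_blocking(
    ec_alpha_rel: float,
    eo_alpha_rel: float,
    thresholds: IndexThresholds | None = None,
) -> tuple[Optional[float], str]:
    """Alpha blocking ratio (eyes-closed / eyes-open relative alpha).

    Blocking is "intact" (yes) when the ratio is at least 1.3, i.e. alpha is
    suppressed by eye opening; lower ratios mark deficient cortical gating.
    """
    t = thresholds or IndexThresholds()
    if ec_alpha_rel < 0 or eo_alpha_rel < 0:
        raise ValueError("relative powers must be non-negative")
    ratio = _capped_ratio(ec_alpha_rel, eo_alpha_rel, t.ratio_cap,
                          "alpha blocking ratio")
    if ratio is None:
        return None, NA
    return ratio, "yes" if ratio >= t.alpha_blocking_intact else "no"


def power_status(
    background_alpha_rel: float,
    background_beta_rel: float,
    thresholds: IndexThresholds | None = None,
) -> tuple[str, str]:
    """Alpha status (low iff alpha < 0.25) and beta status (high iff > 0.20)."""
    t = thresholds or IndexThresholds()
    alpha_status = "low" if background_alpha_rel < t.alpha_low else "normal"
    beta_status = "high" if background_beta_rel > t.beta_high else "normal"
    return alpha_status, beta_status


def hyperarousal(
    background_beta_rel: float,
    background_alpha_rel: float,
    thresholds: IndexThresholds | None = None,
) -> tuple[Optional[float], str]:
    """Hyperarousal index: background beta/alpha relative power."""
    t = thresholds or IndexThresholds()
    index = _capped_ratio(background_beta_rel, background_alpha_rel,
                          t.ratio_cap, "hyperarousal index")
    if index is None:
        return None, NA
    return index, _band_category(index, t.hri_normal)


def tbr_category(
    tbr: float, thresholds: IndexThresholds | None = None
) -> str:
    t = thresholds or IndexThresholds()
    return _band_category(tbr, t.tbr_normal)


def cortical_reactivity(
    ec_alpha: Optional[float],
    eo_alpha: Optional[float],
    after_flash_alpha: Optional[float] = None,
    flash_alpha: Optional[float] = None,
    thresholds: IndexThresholds | None = None,
) -> tuple[Optional[float], str, bool]:
    """Cortical Reactivity Index: mean of the available alpha contrasts.

    The full form averages the eyes-closed-minus-open contrast with the
    after-flash-minus-flash contrast.  When the flash segments are missing
    the eyes contrast stands alone and the result is flagged single-term.
    Returns ``(index, category, single_term)``.
    """
    t = thresholds or IndexThresholds()
    terms = []
    if ec_alpha is not None and eo_alpha is not None:
        terms.append(ec_alpha - eo_alpha)
    if after_flash_alpha is not None and flash_alpha is not None:
        terms.append(after_flash_alpha - flash_alpha)
    if not terms:
        return None, NA, False
    cri = sum(terms) / len(terms)
    return cri, _band_category(cri, t.cri_normal), len(terms) == 1


def homeostatic_recovery(
    after_hv_alpha_rel: Optional[float],
    hv_alpha_rel: Optional[float],
    thresholds: IndexThresholds | None = None,
) -> tuple[Optional[float], str]:
    """After-hyperventilation / during-hyperventilation relative alpha."""
    t = thresholds or IndexThresholds()
    if after_hv_alpha_rel is None or hv_alpha_rel is None:
        return None, NA
    score = _capped_ratio(after_hv_alpha_rel, hv_alpha_rel, t.ratio_cap,
                          "homeostatic recovery score")
    if score is None:
        return None, NA
    return score, _band_category(score, t.recovery_normal)


def dependence_pattern(alpha_status: str, beta_status: str,
                       tbr_cat: str) -> str:
    """Hyperaroused / disinhibited / balanced, rules applied in order."""
    if alpha_status == "low" and beta_status == "high":
        return "hyperaroused"
    if tbr_cat == "low" and beta_status == "high":
        return "disinhibited"
    return "balanced"


@dataclass
class DerivedIndices:
    """All derived variables for one subject (region-aggregated powers)."""

    subject_id: str
    alpha_blocking_ratio: Optional[float]
    alpha_blocking_intact: str          # yes / no / na
    alpha_power_status: str             # low / normal
    beta_power_status: str              # high / normal
    hyperarousal_index: Optional[float]
    hri_category: str                   # low / normal / high / na
    tbr_background: Optional[float]
    tbr_category: str
    cortical_reactivity_index: Optional[float]
    cri_category: str
    cri_single_term: bool
    homeostatic_recovery_score: Optional[float]
    hr_category: str
    after_hv_alpha_recovery: str        # low / normal / na
    after_hv_delta_increase: str        # yes / no / na
    after_flash_alpha_rebound: str      # yes / no / na
    flash_beta_reactivity: str          # yes / no / na
    dependence_pattern: str             # hyperaroused / disinhibited / balanced
    background_alpha_rel: float = field(default=float("nan"))
    background_beta_rel: float = field(default=float("nan"))

    def to_row(self) -> dict[str, object]:
        """One flat row per subject, headed by the field names used in reports."""
        return {
            "subject_id": self.subject_id,
            "Alpha Blocking Ratio": self.alpha_blocking_ratio,
            "Alpha Blocking Intact": self.alpha_blocking_intact,
            "Alpha Power Status": self.alpha_power_status,
            "Beta Power Status": self.beta_power_status,
            "Hyperarousal Index": self.hyperarousal_index,
            "Hyperarousal Index Category": self.hri_category,
            "Theta/Beta Ratio": self.tbr_background,
            "Theta/Beta Ratio Category": self.tbr_category,
            "Cortical Reactivity Index": self.cortical_reactivity_index,
            "Cortical Reactivity Index Category": self.cri_category,
            "Homeostatic Recovery Score": self.homeostatic_recovery_score,
            "Homeostatic Recovery Category": self.hr_category,
            "After Hyperventilation Alpha Recovery": self.after_hv_alpha_recovery,
            "After Hyperventilation Delta Increase": self.after_hv_delta_increase,
            "After Flash Stimulation Alpha Rebound": self.after_flash_alpha_rebound,
            "Flash Stimulation Beta Reactivity": self.flash_beta_reactivity,
            "Dependence Pattern": self.dependence_pattern,
        }


def _rel(features: SegmentFeatureTable, segment: SegmentLabel,
         band: str, region: str) -> Optional[float]:
    rec = features.get(segment, region)
    return None if rec is None else rec.relative[band]


def compute_indices(
    features: SegmentFeatureTable,
    thresholds: IndexThresholds | None = None,
    region: str = "all",
) -> DerivedIndices:
    """Evaluate every derived variable from a subject's feature table.

    Comparisons involving a missing segment yield NA; exact ties at strict
    ">" comparisons take the negative outcome.
    """
    t = thresholds or IndexThresholds()
    L = SegmentLabel

    bg = features.get(L.BACKGROUND, region)
    if bg is None:
        raise ValueError("background segment is required for derived indices")

    ec_alpha = _rel(features, L.EYES_CLOSED, "alpha", region)
    eo_alpha = _rel(features, L.EYES_OPEN, "alpha", region)
    if ec_alpha is None or eo_alpha is None:
        abr, intact = None, NA
    else:
        abr, intact = alpha_blocking(ec_alpha, eo_alpha, t)

    alpha_status, beta_status = power_status(
        bg.relative["alpha"], bg.relative["beta"], t
    )
    hri, hri_cat = hyperarousal(bg.relative["beta"], bg.relative["alpha"], t)
    tbr = bg.tbr
    tbr_cat = tbr_category(tbr, t)

    cri, cri_cat, single = cortical_reactivity(
        ec_alpha, eo_alpha,
        _rel(features, L.POST_FLASH, "alpha", region),
        _rel(features, L.FLASH, "alpha", region),
        t,
    )

    hv_alpha = _rel(features, L.HYPERVENTILATION, "alpha", region)
    ahv_alpha = _rel(features, L.POST_HYPERVENTILATION, "alpha", region)
    hr, hr_cat = homeostatic_recovery(ahv_alpha, hv_alpha, t)

    # After-HV alpha recovery: "low" unless strictly increased.
    if hv_alpha is None or ahv_alpha is None:
        ahv_recovery = NA
    else:
        ahv_recovery = "normal" if ahv_alpha > hv_alpha else "low"

    hv_delta = _rel(features, L.HYPERVENTILATION, "delta", region)
    ahv_delta = _rel(features, L.POST_HYPERVENTILATION, "delta", region)
    if hv_delta is None or ahv_delta is None:
        delta_increase = NA
    else:
        delta_increase = "yes" if ahv_delta > hv_delta else "no"

    flash_alpha = _rel(features, L.FLASH, "alpha", region)
    aflash_alpha = _rel(features, L.POST_FLASH, "alpha", region)
    if flash_alpha is None or aflash_alpha is None:
        rebound = NA
    else:
        rebound = "yes" if aflash_alpha > flash_alpha else "no"

    flash_beta = _rel(features, L.FLASH, "beta", region)
    if flash_beta is None:
        beta_react = NA
    else:
        beta_react = "yes" if flash_beta > bg.relative["beta"] else "no"

    return DerivedIndices(
        subject_id=features.subject_id,
        alpha_blocking_ratio=abr,
        alpha_blocking_intact=intact,
        alpha_power_status=alpha_status,
        beta_power_status=beta_status,
        hyperarousal_index=hri,
        hri_category=hri_cat,
        tbr_background=tbr,
        tbr_category=tbr_cat,
        cortical_reactivity_index=cri,
        cri_category=cri_cat,
        cri_single_term=single,
        homeostatic_recovery_score=hr,
        hr_category=hr_cat,
        after_hv_alpha_recovery=ahv_recovery,
        after_hv_delta_increase=delta_increase,
        after_flash_alpha_rebound=rebound,
        flash_beta_reactivity=beta_react,
        dependence_pattern=dependence_pattern(alpha_status, beta_status,
                                              tbr_cat),
        background_alpha_rel=bg.relative["alpha"],
        background_beta_rel=bg.relative["beta"],
    )
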