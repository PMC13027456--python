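"""The composite dependence score and the rule-based likelihood.

Five background-activity features feed the classifier: the theta/beta ratio
(TBR), relative alpha and beta power, the hyperarousal index (HRI, beta/alpha),
and whether alpha blocking is intact.  Each continuous feature is min-capped
to [0, 1] against a physiological anchor (TBR/4, alpha/0.30, beta/0.25,
HRI/3) and combined as

    score = 0.25*(1 - tbr_norm) + 0.25*beta_norm + 0.25*hri_norm
          + 0.15*(1 - alpha_norm) + 0.10*blocking_deficit

so inhibitory deficits (low TBR, low alpha) and excitatory dominance (high
beta, high HRI) push the score toward 1.  An all-conditions rule flags the
fully hyperaroused-disinhibited profile, and the hybrid decision labels a
subject dependence-related when the score reaches 0.7 *or* the rule fires
(the rule branch is kept verbatim even though any rule-positive profile
already scores above 0.7), borderline for scores in [0.5, 0.7), and a
normal pattern below 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .exceptions import DomainError
from .indices import NA, DerivedIndices

#: Hybrid decision labels.
DEPENDENCE_RELATED = "dependence-related"
BORDERLINE = "borderline"
NORMAL_PATTERN = "normal pattern"
UNCLASSIFIABLE = "unclassifiable"


@dataclass(frozen=True)
class ScoringConfig:
    """Normalization caps, rule thresholds, weights and decision cut-offs."""

    tbr_cap: float = 4.0
    alpha_cap: float = 0.30
    beta_cap: float = 0.25
    hri_cap: float = 3.0
    weights: tuple[float, float, float, float, float] = (
        0.25, 0.25, 0.25, 0.15, 0.10
    )  # (1-tbr_norm), beta_norm, hri_norm, (1-alpha_norm), blocking deficit
    rule_tbr_below: float = 1.0
    rule_alpha_below: float = 0.30
    rule_beta_above: float = 0.25
    rule_hri_at_least: float = 2.0
    dependent_score: float = 0.7
    borderline_score: float = 0.5


@dataclass(frozen=True)
class RawScoringFeatures:
    """Background-activity inputs to the scoring framework."""

    tbr: float
    alpha_rel: float
    beta_rel: float
    hri: float
    alpha_blocking_intact: bool

    def __post_init__(self) -> None:
        if self.tbr < 0 or self.hri < 0:
            raise DomainError("tbr and hri must be non-negative")
        if not (0 <= self.alpha_rel <= 1 and 0 <= self.beta_rel <= 1):
            raise DomainError("relative powers must lie in [0, 1]")

    @classmethod
    def from_indices(cls, indices: DerivedIndices
                     ) -> Optional["RawScoringFeatures"]:
        """Extract the scoring inputs; None when blocking status is NA."""
        if indices.alpha_blocking_intact == NA:
            return None
        return cls(
            tbr=indices.tbr_background,
            alpha_rel=indices.background_alpha_rel,
            beta_rel=indices.background_beta_rel,
            hri=indices.hyperarousal_index,
            alpha_blocking_intact=indices.alpha_blocking_intact == "yes",
        )


@dataclass(frozen=True)
class NormalizedFeatures:
    tbr_norm: float
    alpha_norm: float
    beta_norm: float
    hri_norm: float
    alpha_blocking_def: int  # 1 iff blocking absent


@dataclass
class ScoreBreakdown:
    """Weighted component contributions and the resulting decision signals."""

    contributions: dict[str, float]
    dependence_score: float
    likelihood: str  # yes / no
    final_label: str

    def to_row(self) -> dict[str, object]:
        row = {f"contribution_{k}": v for k, v in self.contributions.items()}
        row["Dependence Score"] = self.dependence_score
        row["Dependence Likelihood"] = self.likelihood
        row["Dependence Likelihood Result"] = self.final_label
        return row


def normalize_features(
    raw: RawScoringFeatures, config: ScoringConfig | None = None
) -> NormalizedFeatures:
    """Min-capped scaling of each feature to [0, 1] (see module docstring)."""
    c = config or ScoringConfig()
    return NormalizedFeatures(
        tbr_norm=min(raw.tbr / c.tbr_cap, 1.0),
        alpha_norm=min(raw.alpha_rel / c.alpha_cap, 1.0),
        beta_norm=min(raw.beta_rel / c.beta_cap, 1.0),
        hri_norm=min(raw.hri / c.hri_cap, 1.0),
        alpha_blocking_def=0 if raw.alpha_blocking_intact else 1,
    )


def dependence_score(
    norm: NormalizedFeatures, config: ScoringConfig | None = None
) -> tuple[float, dict[str, float]]:
    """Weighted composite on [0, 1]; returns (score, component contributions)."""
    c = config or ScoringConfig()
    w = c.weights
    contributions = {
        "tbr": w[0] * (1.0 - norm.tbr_norm),
        "beta": w[1] * norm.beta_norm,
        "hri": w[2] * norm.hri_norm,
        "alpha": w[3] * (1.0 - norm.alpha_norm),
        "alpha_blocking": w[4] * norm.alpha_blocking_def,
    }
    return sum(contributions.values()), contributions


def dependence_likelihood(
    raw: RawScoringFeatures, config: ScoringConfig | None = None
) -> str:
    """All-conditions rule for the hyperaroused-disinhibited profile."""
    c = config or ScoringConfig()
    hit = (
        raw.tbr < c.rule_tbr_below
        and raw.alpha_rel < c.rule_alpha_below
        and raw.beta_rel > c.rule_beta_above
        and raw.hri >= c.rule_hri_at_least
        and not raw.alpha_blocking_intact
    )
    return "yes" if hit else "no"


def classify(
    score: float, likelihood: str, config: ScoringConfig | None = None
) -> str:
    """Hybrid three-way decision, rules applied in order."""
    c = config or ScoringConfig()
    if score >= c.dependent_score or likelihood == "yes":
        return DEPENDENCE_RELATED
    if score >= c.borderline_score:
        return BORDERLINE
    return NORMAL_PATTERN


def score_features(
    raw: RawScoringFeatures, config: ScoringConfig | None = None
) -> ScoreBreakdown:
    """Normalize, score, apply the rule and the hybrid decision."""
    norm = normalize_features(raw, config)
    score, contributions = dependence_score(norm, config)
    likelihood = dependence_likelihood(raw, config)
    return ScoreBreakdown(
        contributions=contributions,
        dependence_score=score,
        likelihood=likelihood,
        final_label=classify(score, likelihood, config),
    )


def score_indices(
    indices: DerivedIndices, config: ScoringConfig | None = None
) -> ScoreBreakdown:
    """Score a subject from their derived indices.

    When alpha-blocking intactness is NA (missing eyes segments) the score
    is not computed and the subject is labelled unclassifiable.
    """
    raw = RawScoringFeatures.from_indices(indices)
    if raw is None:
        return ScoreBreakdown(
            contributions={},
            dependence_score=float("nan"),
            likelihood=NA,
            final_label=UNCLASSIFIABLE,
        )
    return score_features(raw, config)
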