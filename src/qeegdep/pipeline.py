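"""Batch pipeline driver and cohort-level reporting.

``run_pipeline`` takes EDF files, in-memory sessions or a precomputed
feature table, carries every subject through band-power extraction, derived
indices and dependence scoring, and aggregates a cohort summary with counts
and percentages for each categorical variable and means for each continuous
index.  Individual subject failures are logged and skipped; only a run with
zero successful subjects is fatal.
"""

from __future__ import annotations

import glob
import logging
import os
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .exceptions import PipelineError, QEEGError
from .indices import NA, DerivedIndices, compute_indices
from .scoring import ScoreBreakdown, score_indices
from .session import (
    EEGSession,
    SegmentLabel,
    derive_bipolar_channels,
    read_edf_session,
    reject_artifacts,
)
from .spectral import SegmentFeatureTable, extract_features

logger = logging.getLogger(__name__)

#: Categorical variables reported in the cohort summary.
CATEGORICAL_VARIABLES = (
    "After Hyperventilation Delta Increase",
    "Alpha Blocking Intact",
    "Flash Stimulation Beta Reactivity",
    "Theta/Beta Ratio Category",
    "After Flash Stimulation Alpha Rebound",
    "Cortical Reactivity Index Category",
    "Homeostatic Recovery Category",
    "Dependence Pattern",
    "Alpha Power Status",
    "Beta Power Status",
    "Hyperarousal Index Category",
    "After Hyperventilation Alpha Recovery",
    "Dependence Likelihood",
    "Dependence Likelihood Result",
)

#: Continuous indices summarized by mean and standard deviation.
CONTINUOUS_VARIABLES = (
    "Alpha Blocking Ratio",
    "Theta/Beta Ratio",
    "Hyperarousal Index",
    "Cortical Reactivity Index",
    "Homeostatic Recovery Score",
    "Dependence Score",
)


@dataclass
class SubjectResult:
    subject_id: str
    features: SegmentFeatureTable
    indices: DerivedIndices
    score: ScoreBreakdown

    def to_row(self) -> dict[str, object]:
        row = self.indices.to_row()
        row.update(self.score.to_row())
        return row


def format_percent(value: float) -> str:
    """One decimal place with half-up rounding (report style)."""
    return str(Decimal(str(float(value))).quantize(Decimal("0.1"),
                                                   rounding=ROUND_HALF_UP))


@dataclass
class CohortSummary:
    n: int
    categorical: dict[str, dict[str, tuple[int, float]]]
    continuous: dict[str, tuple[float, float]]  # mean, sd
    segment_availability: dict[str, int]
    denominator_mode: str = "non_na"

    def to_dict(self) -> dict[str, object]:
        return {
            "n": self.n,
            "denominator_mode": self.denominator_mode,
            "categorical": {
                var: {cat: {"count": c, "percent": p}
                      for cat, (c, p) in cats.items()}
                for var, cats in self.categorical.items()
            },
            "continuous": {
                var: {"mean": m, "sd": s}
                for var, (m, s) in self.continuous.items()
            },
            "segment_availability": dict(self.segment_availability),
        }

    def to_markdown(self) -> str:
        lines = [f"# Cohort summary (n = {self.n})", "",
                 "| Variable | Value | n (%) / mean |",
                 "| --- | --- | --- |"]
        for var, cats in self.categorical.items():
            for cat, (count, pct) in cats.items():
                lines.append(
                    f"| {var} | {cat} | {count} ({format_percent(pct)}%) |"
                )
        for var, (mean, sd) in self.continuous.items():
            lines.append(f"| {var} | mean (sd) | {mean:.4g} ({sd:.4g}) |")
        lines.append("")
        lines.append("| Segment | available |")
        lines.append("| --- | --- |")
        for seg, count in self.segment_availability.items():
            lines.append(f"| {seg} | {count} |")
        return "\n".join(lines) + "\n"


def summarize_cohort(
    results: Sequence[SubjectResult], mode: str = "non_na"
) -> CohortSummary:
    """Counts/percentages per categorical variable, means per index.

    ``mode="non_na"`` computes percentages over subjects with a defined
    value; ``mode="all"`` keeps NA as its own category over the full n.
    """
    if not results:
        raise PipelineError("cannot summarize an empty cohort")
    if mode not in ("non_na", "all"):
        raise ValueError("mode must be 'non_na' or 'all'")
    rows = pd.DataFrame([r.to_row() for r in results])
    n = len(rows)

    categorical: dict[str, dict[str, tuple[int, float]]] = {}
    for var in CATEGORICAL_VARIABLES:
        values = rows[var].astype(str)
        if mode == "non_na":
            values = values[values != NA]
        denom = len(values)
        cats: dict[str, tuple[int, float]] = {}
        for cat, count in values.value_counts().sort_index().items():
            pct = 100.0 * count / denom if denom else float("nan")
            cats[str(cat)] = (int(count), pct)
        categorical[var] = cats

    continuous: dict[str, tuple[float, float]] = {}
    for var in CONTINUOUS_VARIABLES:
        vals = pd.to_numeric(rows[var], errors="coerce").dropna()
        continuous[var] = (
            float(vals.mean()) if len(vals) else float("nan"),
            float(vals.std(ddof=1)) if len(vals) > 1 else float("nan"),
        )

    availability = {lab.value: 0 for lab in SegmentLabel}
    for r in results:
        for seg in r.features.available_segments:
            availability[seg.value] += 1

    return CohortSummary(
        n=n,
        categorical=categorical,
        continuous=continuous,
        segment_availability=availability,
        denominator_mode=mode,
    )


def process_session(
    session: EEGSession, config: PipelineConfig | None = None
) -> SubjectResult:
    """One subject: montage -> (optional rejection) -> features -> score."""
    config = config or PipelineConfig()
    session = derive_bipolar_channels(session, config.montage)
    if config.artifact_rejection.enabled:
        ar = config.artifact_rejection
        session = EEGSession(
            subject_id=session.subject_id,
            segments={
                lab: reject_artifacts(seg, ar.amplitude_limit,
                                      ar.epoch_seconds,
                                      ar.max_bad_channel_fraction)
                for lab, seg in session.segments.items()
            },
        )
    features = extract_features(
        session, config.montage, config.bands, config.welch
    )
    return _score_from_features(features, config)


def _score_from_features(
    features: SegmentFeatureTable, config: PipelineConfig
) -> SubjectResult:
    indices = compute_indices(features, config.thresholds, config.region)
    score = score_indices(indices, config.scoring)
    logger.info(
        "subject %s: segments=%d score=%.3f label=%s",
        features.subject_id,
        len(features.available_segments),
        score.dependence_score,
        score.final_label,
    )
    return SubjectResult(
        subject_id=features.subject_id,
        features=features,
        indices=indices,
        score=score,
    )


@dataclass
class PipelineResult:
    results: list[SubjectResult]
    summary: CohortSummary
    failures: list[tuple[str, str]] = field(default_factory=list)

    @property
    def results_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.to_row() for r in self.results])

    @property
    def features_frame(self) -> pd.DataFrame:
        return pd.concat([r.features.to_frame() for r in self.results],
                         ignore_index=True)


def _iter_inputs(inputs) -> Iterable:
    if isinstance(inputs, (str, os.PathLike)):
        path = str(inputs)
        if os.path.isdir(path):
            yield from sorted(glob.glob(os.path.join(path, "*.edf")))
        else:
            yield path
    else:
        yield from inputs


def run_pipeline(
    inputs, config: PipelineConfig | None = None, output_dir=None
) -> PipelineResult:
    """Run the full pipeline over a directory, file list, sessions or a CSV.

    ``inputs`` may be a directory of EDF files, a single EDF path, a
    feature-table CSV (skipping signal processing), or an iterable mixing
    EDF paths and in-memory :class:`EEGSession` objects.  Per-subject
    failures are logged and collected; the run fails only if no subject
    succeeds.  With ``output_dir`` set, per-subject and summary tables are
    written as CSV/JSON plus a Markdown summary.
    """
    config = config or PipelineConfig()
    results: list[SubjectResult] = []
    failures: list[tuple[str, str]] = []

    for item in _iter_inputs(inputs):
        try:
            if isinstance(item, EEGSession):
                results.append(process_session(item, config))
            elif isinstance(item, SegmentFeatureTable):
                results.append(_score_from_features(item, config))
            elif str(item).lower().endswith(".csv"):
                frame = pd.read_csv(item)
                for table in SegmentFeatureTable.from_frame(frame):
                    results.append(_score_from_features(table, config))
            else:
                session = read_edf_session(
                    item,
                    montage=config.montage,
                    segment_map=config.segment_name_map,
                    bandpass=config.bandpass,
                )
                results.append(process_session(session, config))
        except QEEGError as exc:
            name = item.subject_id if isinstance(item, EEGSession) else str(item)
            logger.warning("skipping %s: %s", name, exc)
            failures.append((name, str(exc)))

    if not results:
        raise PipelineError("no subject processed successfully")

    summary = summarize_cohort(results, config.percent_denominator)
    out = PipelineResult(results=results, summary=summary, failures=failures)

    if output_dir is not None:
        os.makedirs(output_dir, exist_ok=True)
        out.features_frame.to_csv(
            os.path.join(output_dir, "features.csv"), index=False
        )
        out.results_frame.to_csv(
            os.path.join(output_dir, "subjects.csv"), index=False
        )
        import json

        with open(os.path.join(output_dir, "summary.json"), "w") as f:
            json.dump(summary.to_dict(), f, indent=2, sort_keys=True)
        with open(os.path.join(output_dir, "summary.md"), "w") as f:
            f.write(summary.to_markdown())
        config.to_yaml(os.path.join(output_dir, "config.yaml"))
    return out
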