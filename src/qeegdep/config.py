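"""Pipeline configuration: every clinical constant in one overridable place.

The defaults reproduce the printed thresholds, normalization caps, weights
and decision cut-offs of the scoring framework; a YAML file can override any
subset.  The configuration round-trips through serialization so a run can be
reproduced from its emitted config alone.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any, Mapping

import yaml

from .indices import IndexThresholds
from .scoring import ScoringConfig
from .session import (
    DEFAULT_DERIVATION_PAIRS,
    DEFAULT_REGION_MAP,
    DEFAULT_SEGMENT_NAME_MAP,
    MontageConfig,
    SegmentLabel,
)
from .spectral import DEFAULT_BANDS, BandScheme, WelchParams


@dataclass
class ArtifactRejection:
    """Amplitude-threshold rejection; off by default (manual review stands)."""

    enabled: bool = False
    amplitude_limit: float = 100.0  # uV
    epoch_seconds: float = 2.0
    max_bad_channel_fraction: float = 0.5


@dataclass
class PipelineConfig:
    montage: MontageConfig = field(default_factory=MontageConfig)
    segment_name_map: dict[str, SegmentLabel] = field(
        default_factory=lambda: dict(DEFAULT_SEGMENT_NAME_MAP)
    )
    bands: BandScheme = field(default_factory=BandScheme)
    welch: WelchParams = field(default_factory=WelchParams)
    bandpass: tuple[float, float] | None = (1.0, 45.0)
    thresholds: IndexThresholds = field(default_factory=IndexThresholds)
    scoring: ScoringConfig = field(default_factory=ScoringConfig)
    artifact_rejection: ArtifactRejection = field(
        default_factory=ArtifactRejection
    )
    region: str = "all"
    percent_denominator: str = "non_na"  # or "all"
    seed: int = 0

    def to_dict(self) -> dict[str, Any]:
        d: dict[str, Any] = {
            "montage": {
                "derivation_pairs": [list(p) for p in
                                     self.montage.derivation_pairs],
                "region_map": dict(self.montage.region_map),
            },
            "segment_name_map": {k: v.value for k, v in
                                 self.segment_name_map.items()},
            "bands": {
                "bands": {b: list(e) for b, e in self.bands.bands.items()},
                "relative_denominator": list(self.bands.relative_denominator),
            },
            "welch": dataclasses.asdict(self.welch),
            "bandpass": list(self.bandpass) if self.bandpass else None,
            "thresholds": dataclasses.asdict(self.thresholds),
            "scoring": dataclasses.asdict(self.scoring),
            "artifact_rejection": dataclasses.asdict(self.artifact_rejection),
            "region": self.region,
            "percent_denominator": self.percent_denominator,
            "seed": self.seed,
        }
        return d

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "PipelineConfig":
        cfg = cls()
        if "montage" in d:
            m = d["montage"]
            cfg.montage = MontageConfig(
                derivation_pairs=tuple(tuple(p) for p in
                                       m.get("derivation_pairs",
                                             DEFAULT_DERIVATION_PAIRS)),
                region_map=dict(m.get("region_map", DEFAULT_REGION_MAP)),
            )
        if "segment_name_map" in d:
            cfg.segment_name_map = {
                k: SegmentLabel(v) for k, v in d["segment_name_map"].items()
            }
        if "bands" in d:
            b = d["bands"]
            # serialization may alphabetize the mapping; restore spectral order
            items = sorted(b.get("bands", DEFAULT_BANDS).items(),
                           key=lambda kv: kv[1][0])
            cfg.bands = BandScheme(
                bands={k: tuple(v) for k, v in items},
                relative_denominator=tuple(
                    b.get("relative_denominator", (1.0, 45.0))
                ),
            )
        if "welch" in d:
            cfg.welch = WelchParams(**d["welch"])
        if "bandpass" in d:
            bp = d["bandpass"]
            cfg.bandpass = tuple(bp) if bp else None
        if "thresholds" in d:
            t = dict(d["thresholds"])
            for k in ("hri_normal", "tbr_normal", "recovery_normal",
                      "cri_normal"):
                if k in t:
                    t[k] = tuple(t[k])
            cfg.thresholds = IndexThresholds(**t)
        if "scoring" in d:
            s = dict(d["scoring"])
            if "weights" in s:
                s["weights"] = tuple(s["weights"])
            cfg.scoring = ScoringConfig(**s)
        if "artifact_rejection" in d:
            cfg.artifact_rejection = ArtifactRejection(
                **d["artifact_rejection"]
            )
        for key in ("region", "percent_denominator", "seed"):
            if key in d:
                setattr(cfg, key, d[key])
        return cfg

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            with open(path, "w") as f:
                f.write(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "PipelineConfig":
        """Load from a YAML file path or a YAML string."""
        import os

        if isinstance(source, str) and not os.path.exists(source) \
                and "\n" in source:
            data = yaml.safe_load(source)
        else:
            with open(source) as f:
                data = yaml.safe_load(f)
        return cls.from_dict(data or {})
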