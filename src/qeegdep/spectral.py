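"""Welch spectral estimation and band-power extraction.

Per derivation and segment, the power spectral density is estimated with
Welch's method (2 s Hann windows, 50% overlap by default, density scaling so
that the integral of the PSD recovers the signal variance).  Absolute band
powers are trapezoidal integrals of the PSD over half-open frequency bands;
relative powers divide by the integral over a configurable reference range
(1-45 Hz by default).  The theta/beta ratio (TBR) — low when fast beta
activity dominates slow theta, i.e. under cortical hyperarousal — is formed
from the band powers and aggregated over frontal and central derivations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import signal as _sig

from .exceptions import (
    DegenerateInputError,
    InsufficientDataError,
    ResolutionError,
    SelectionError,
)
from .session import MontageConfig, SegmentLabel, SegmentRecording

#: delta/theta/alpha/beta plus a gamma band covering the rest of the
#: analysed range.  Edges are half-open [low, high) so shared edges are
#: counted once.
DEFAULT_BANDS: dict[str, tuple[float, float]] = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
    "gamma": (30.0, 45.0),
}

BAND_NAMES = tuple(DEFAULT_BANDS)


@dataclass(frozen=True)
class BandScheme:
    """Ordered frequency bands and the reference range for relative power."""

    bands: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BANDS)
    )
    relative_denominator: tuple[float, float] = (1.0, 45.0)

    def __post_init__(self) -> None:
        edges = list(self.bands.values())
        for lo, hi in edges:
            if not lo < hi:
                raise ValueError(f"band edges must be ascending, got {lo}>{hi}")
        for (_, hi_prev), (lo_next, _) in zip(edges, edges[1:]):
            if lo_next < hi_prev:
                raise ValueError("bands must be non-overlapping and ascending")
        d_lo, d_hi = self.relative_denominator
        if d_lo > edges[0][0] or d_hi < edges[-1][1]:
            raise ValueError("relative denominator must cover all bands")


@dataclass
class WelchParams:
    """Welch settings: window length (s), overlap fraction, taper name."""

    window_seconds: float = 2.0
    overlap: float = 0.5
    taper: str = "hann"


@dataclass
class PSDEstimate:
    frequencies: np.ndarray
    power: np.ndarray  # channels x frequencies, uV^2/Hz
    channel_labels: list[str]
    welch_params: WelchParams

    def __post_init__(self) -> None:
        if np.any(self.power < 0):
            raise ValueError("PSD must be non-negative")


@dataclass
class BandPowerRecord:
    """Band powers for one segment, aggregated over a channel selection."""

    segment: SegmentLabel
    region: str
    absolute: dict[str, float]  # uV^2
    relative: dict[str, float]  # unitless, in [0, 1]
    tbr: float  # ratio of aggregated theta to aggregated beta
    tbr_channel_mean: float | None = None  # mean of per-channel ratios
    n_channels: int = 1


@dataclass
class SegmentFeatureTable:
    """Per-segment, per-region band powers for one subject."""

    subject_id: str
    records: dict[tuple[SegmentLabel, str], BandPowerRecord]

    def get(self, segment: SegmentLabel, region: str = "all"
            ) -> BandPowerRecord | None:
        return self.records.get((segment, region))

    @property
    def available_segments(self) -> set[SegmentLabel]:
        return {seg for seg, _ in self.records}

    def to_frame(self) -> pd.DataFrame:
        """Flat table: one row per segment x region, band columns."""
        rows = []
        for (seg, region), rec in sorted(
            self.records.items(), key=lambda kv: (kv[0][0].value, kv[0][1])
        ):
            row: dict[str, object] = {
                "subject_id": self.subject_id,
                "segment": seg.value,
                "region": region,
                "n_channels": rec.n_channels,
            }
            for band, val in rec.absolute.items():
                row[f"{band}_absolute"] = val
            for band, val in rec.relative.items():
                row[f"{band}_relative"] = val
            row["tbr"] = rec.tbr
            row["tbr_channel_mean"] = rec.tbr_channel_mean
            rows.append(row)
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> list["SegmentFeatureTable"]:
        """Rebuild feature tables (one per subject) from :meth:`to_frame` output."""
        tables = []
        for sid, grp in frame.groupby("subject_id", sort=False):
            records = {}
            for _, row in grp.iterrows():
                seg = SegmentLabel(row["segment"])
                region = str(row["region"])
                bands = [c[: -len("_absolute")] for c in frame.columns
                         if c.endswith("_absolute")]
                absolute = {b: float(row[f"{b}_absolute"]) for b in bands}
                relative = {b: float(row[f"{b}_relative"]) for b in bands}
                tcm = row.get("tbr_channel_mean")
                records[(seg, region)] = BandPowerRecord(
                    segment=seg, region=region, absolute=absolute,
                    relative=relative, tbr=float(row["tbr"]),
                    tbr_channel_mean=None if pd.isna(tcm) else float(tcm),
                    n_channels=int(row.get("n_channels", 1)),
                )
            tables.append(cls(subject_id=str(sid), records=records))
        return tables


def compute_psd(
    segment: SegmentRecording, params: WelchParams | None = None
) -> PSDEstimate:
    """Welch PSD per channel; density scaling so the integral ~ variance."""
    params = params or WelchParams()
    nperseg = int(round(params.window_seconds * segment.sampling_rate))
    if segment.n_samples < 2 * nperseg:
        raise InsufficientDataError(
            f"segment {segment.label.value}: {segment.duration:.1f} s is "
            f"shorter than two {params.window_seconds:g} s windows"
        )
    freqs, pxx = _sig.welch(
        segment.samples,
        fs=segment.sampling_rate,
        window=params.taper,
        nperseg=nperseg,
        noverlap=int(round(params.overlap * nperseg)),
        detrend="constant",
        scaling="density",
        axis=-1,
    )
    return PSDEstimate(
        frequencies=freqs,
        power=np.atleast_2d(pxx),
        channel_labels=list(segment.channel_labels),
        welch_params=params,
    )


def _integrate(freqs: np.ndarray, power: np.ndarray,
               lo: float, hi: float, what: str) -> np.ndarray:
    mask = (freqs >= lo) & (freqs <= hi)
    if mask.sum() < 2:
        raise ResolutionError(
            f"{what} [{lo}, {hi}) Hz resolved by {int(mask.sum())} bins; "
            "need at least 2"
        )
    return np.trapezoid(power[:, mask], freqs[mask], axis=-1)


def band_powers(
    psd: PSDEstimate, scheme: BandScheme | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Absolute and relative band power per channel.

    Returns ``(absolute, relative)`` DataFrames indexed by channel with one
    column per band.  Adjacent bands share edge frequencies; because powers
    are trapezoidal integrals over contiguous intervals, summing bands
    reproduces the integral over their union without double counting.
    """
    scheme = scheme or BandScheme()
    total = _integrate(psd.frequencies, psd.power,
                       *scheme.relative_denominator, "reference range")
    absolute = {
        band: _integrate(psd.frequencies, psd.power, lo, hi, f"band {band}")
        for band, (lo, hi) in scheme.bands.items()
    }
    abs_df = pd.DataFrame(absolute, index=psd.channel_labels)
    if np.any(total <= 0):
        raise DegenerateInputError(
            "zero total power in the reference range; relative powers "
            "undefined"
        )
    rel_df = abs_df.div(total, axis=0)
    return abs_df, rel_df


def compute_tbr(theta_power: float, beta_power: float) -> float:
    """Theta/beta ratio; identical on absolute or relative powers."""
    if beta_power == 0:
        raise DegenerateInputError("beta power is zero; TBR undefined")
    if theta_power < 0 or beta_power < 0:
        raise ValueError("band powers must be non-negative")
    return theta_power / beta_power


def aggregate_region_means(
    abs_df: pd.DataFrame,
    rel_df: pd.DataFrame,
    segment: SegmentLabel,
    montage: MontageConfig | None = None,
    region: str = "all",
) -> BandPowerRecord:
    """Arithmetic mean of band powers over the channels of one region.

    The reported TBR is the ratio of the region-mean theta to region-mean
    beta power; the mean of per-channel ratios is kept alongside it.
    """
    montage = montage or MontageConfig()
    wanted = [c for c in montage.channels_in_region(region)
              if c in abs_df.index]
    if not wanted:
        raise SelectionError(f"no channels available for region {region!r}")
    abs_mean = abs_df.loc[wanted].mean(axis=0)
    rel_mean = rel_df.loc[wanted].mean(axis=0)
    tbr = compute_tbr(rel_mean["theta"], rel_mean["beta"])
    per_channel = [
        compute_tbr(rel_df.loc[c, "theta"], rel_df.loc[c, "beta"])
        for c in wanted
    ]
    return BandPowerRecord(
        segment=segment,
        region=region,
        absolute=abs_mean.to_dict(),
        relative=rel_mean.to_dict(),
        tbr=tbr,
        tbr_channel_mean=float(np.mean(per_channel)),
        n_channels=len(wanted),
    )


def extract_features(
    session,
    montage: MontageConfig | None = None,
    scheme: BandScheme | None = None,
    welch: WelchParams | None = None,
    regions: Iterable[str] = ("all", "frontal", "central"),
) -> SegmentFeatureTable:
    """PSD -> band powers -> region means for every present segment."""
    montage = montage or MontageConfig()
    records: dict[tuple[SegmentLabel, str], BandPowerRecord] = {}
    for label, seg in session.segments.items():
        psd = compute_psd(seg, welch)
        abs_df, rel_df = band_powers(psd, scheme)
        for region in regions:
            records[(label, region)] = aggregate_region_means(
                abs_df, rel_df, label, montage, region
            )
    return SegmentFeatureTable(subject_id=session.subject_id, records=records)
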