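"""Reading and montaging multi-segment clinical EEG sessions.

A session is one subject's EDF recording split into up to seven standardized
phases (background activity, eyes open, eyes closed, hyperventilation, the
period after hyperventilation, flash stimulation, and the period after flash
stimulation).  Segment boundaries are taken from EDF+ annotations matched by
a configurable name map, or from an explicit start/stop table; no automatic
detection is attempted.

Signals are carried in microvolts.  EDF files are read through MNE, which
normalizes EEG channels to SI units regardless of the physical-dimension
field in the header, so the conversion back to microvolts is a fixed factor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Sequence

import numpy as np
from scipy import signal as _sig

from .exceptions import (
    EmptySegmentError,
    FormatError,
    MontageError,
    SessionError,
)

logger = logging.getLogger(__name__)


class SegmentLabel(str, Enum):
    """The seven standardized recording phases of a clinical EEG session."""

    BACKGROUND = "background"
    EYES_OPEN = "eyes_open"
    EYES_CLOSED = "eyes_closed"
    HYPERVENTILATION = "hyperventilation"
    POST_HYPERVENTILATION = "post_hyperventilation"
    FLASH = "flash"
    POST_FLASH = "post_flash"


#: Canonical acquisition order of the seven phases.
SEGMENT_ORDER: tuple[SegmentLabel, ...] = tuple(SegmentLabel)

#: Default mapping from annotation text to segment label.  Keys are compared
#: case-insensitively after stripping whitespace.
DEFAULT_SEGMENT_NAME_MAP: dict[str, SegmentLabel] = {
    **{lab.value: lab for lab in SegmentLabel},
    "background activity": SegmentLabel.BACKGROUND,
    "open eyes": SegmentLabel.EYES_OPEN,
    "close eyes": SegmentLabel.EYES_CLOSED,
    "after hyperventilation": SegmentLabel.POST_HYPERVENTILATION,
    "flash stimulation": SegmentLabel.FLASH,
    "after flash stimulation": SegmentLabel.POST_FLASH,
}

#: The ten frontal/central bipolar derivations analysed by default.
DEFAULT_DERIVATION_PAIRS: tuple[tuple[str, str], ...] = (
    ("FZ", "CZ"),
    ("FP1", "F3"),
    ("FP1", "F7"),
    ("FP2", "F4"),
    ("FP2", "F8"),
    ("F3", "C3"),
    ("F4", "C4"),
    ("C3", "P3"),
    ("C4", "P4"),
    ("CZ", "PZ"),
)

#: Region tag per derivation.  Fronto-polar/frontal chains are "frontal";
#: chains terminating on central/parietal electrodes are "central".
DEFAULT_REGION_MAP: dict[str, str] = {
    "FP1-F3": "frontal",
    "FP1-F7": "frontal",
    "FP2-F4": "frontal",
    "FP2-F8": "frontal",
    "FZ-CZ": "central",
    "F3-C3": "central",
    "F4-C4": "central",
    "C3-P3": "central",
    "C4-P4": "central",
    "CZ-PZ": "central",
}

_TEN_TWENTY = {
    "FP1", "FP2", "F7", "F3", "FZ", "F4", "F8", "T3", "C3", "CZ", "C4",
    "T4", "T5", "P3", "PZ", "P4", "T6", "O1", "O2", "A1", "A2",
}


def _norm_name(name: str) -> str:
    """Normalize a channel name: strip type prefixes, unify dashes, upper-case."""
    n = name.strip().upper()
    for prefix in ("EEG ", "EEG-"):
        if n.startswith(prefix):
            n = n[len(prefix):]
    return n.replace("–", "-").replace("—", "-").strip()


def derivation_name(anode: str, cathode: str) -> str:
    return f"{_norm_name(anode)}-{_norm_name(cathode)}"


@dataclass
class MontageConfig:
    """Bipolar derivation pairs and their frontal/central region tags."""

    derivation_pairs: tuple[tuple[str, str], ...] = DEFAULT_DERIVATION_PAIRS
    region_map: Mapping[str, str] = field(
        default_factory=lambda: dict(DEFAULT_REGION_MAP)
    )

    def __post_init__(self) -> None:
        for anode, cathode in self.derivation_pairs:
            for el in (anode, cathode):
                if _norm_name(el) not in _TEN_TWENTY:
                    raise MontageError(
                        f"electrode {el!r} is not in the 10-20 set"
                    )

    @property
    def derivation_names(self) -> list[str]:
        return [derivation_name(a, c) for a, c in self.derivation_pairs]

    def channels_in_region(self, region: str) -> list[str]:
        if region == "all":
            return list(self.derivation_names)
        return [d for d in self.derivation_names
                if self.region_map.get(d) == region]


@dataclass
class SegmentRecording:
    """One phase of a session: a channels x samples matrix in microvolts."""

    label: SegmentLabel
    sampling_rate: float
    channel_labels: list[str]
    samples: np.ndarray

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a channels x time matrix")
        if len(self.channel_labels) != self.samples.shape[0]:
            raise ValueError("one channel label per signal row required")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("non-finite samples in segment "
                             f"{self.label.value}")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        """Segment length in seconds."""
        return self.n_samples / self.sampling_rate


@dataclass
class EEGSession:
    """A subject's labelled segment recordings plus the set of absent phases."""

    subject_id: str
    segments: dict[SegmentLabel, SegmentRecording]

    def __post_init__(self) -> None:
        for required in (SegmentLabel.BACKGROUND, SegmentLabel.EYES_OPEN,
                         SegmentLabel.EYES_CLOSED):
            if required not in self.segments:
                logger.warning(
                    "session %s lacks the %s segment; several indices will "
                    "be unavailable", self.subject_id, required.value,
                )

    @property
    def missing_segments(self) -> set[SegmentLabel]:
        return set(SegmentLabel) - set(self.segments)


def bandpass_filter(
    samples: np.ndarray,
    sampling_rate: float,
    low_hz: float = 1.0,
    high_hz: float = 45.0,
    order: int = 4,
) -> np.ndarray:
    """Zero-phase Butterworth band-pass over the analysed frequency range."""
    nyq = sampling_rate / 2.0
    if not 0 < low_hz < high_hz < nyq:
        raise ValueError("band edges must satisfy 0 < low < high < Nyquist")
    sos = _sig.butter(order, [low_hz, high_hz], btype="bandpass",
                      fs=sampling_rate, output="sos")
    return _sig.sosfiltfilt(sos, samples, axis=-1)


def read_edf_session(
    path,
    montage: MontageConfig | None = None,
    segment_map: Mapping[str, SegmentLabel] | None = None,
    segment_table: Mapping[SegmentLabel, tuple[float, float]] | None = None,
    bandpass: tuple[float, float] | None = (1.0, 45.0),
    subject_id: str | None = None,
) -> EEGSession:
    """Read a multi-segment EDF session.

    Parameters
    ----------
    path
        EDF/EDF+ file.
    montage
        Derivation configuration; used only for validation here (the bipolar
        montage itself is applied by :func:`derive_bipolar_channels`).
    segment_map
        Mapping from annotation text (case-insensitive) to
        :class:`SegmentLabel`.  Defaults to the canonical names plus the
        common clinical aliases.
    segment_table
        Explicit ``label -> (start_s, stop_s)`` table used instead of
        annotations when the file carries none.
    bandpass
        ``(low, high)`` zero-phase band-pass applied to every segment, or
        ``None`` to keep raw signals.
    """
    import mne

    segment_map = dict(DEFAULT_SEGMENT_NAME_MAP if segment_map is None
                       else segment_map)
    segment_map = {k.strip().lower(): v for k, v in segment_map.items()}

    try:
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    except Exception as exc:  # mne raises bare ValueError/OSError on bad EDF
        raise FormatError(f"cannot read EDF file {path}: {exc}") from exc

    sfreq = float(raw.info["sfreq"])
    data_uv = raw.get_data() * 1e6  # MNE normalizes EEG channels to volts
    ch_names = [_norm_name(n) for n in raw.ch_names]

    windows: dict[SegmentLabel, tuple[float, float]] = {}
    if segment_table is not None:
        windows.update({SegmentLabel(k): (float(a), float(b))
                        for k, (a, b) in segment_table.items()})
    else:
        for onset, dur, desc in zip(raw.annotations.onset,
                                    raw.annotations.duration,
                                    raw.annotations.description):
            label = segment_map.get(desc.strip().lower())
            if label is None:
                continue
            if label in windows:
                logger.warning("duplicate %s annotation in %s; keeping first",
                               label.value, path)
                continue
            windows[label] = (float(onset), float(onset) + float(dur))

    if not windows:
        raise SessionError(f"no recognizable segments located in {path}")

    total = data_uv.shape[1]
    segments: dict[SegmentLabel, SegmentRecording] = {}
    for label, (t0, t1) in windows.items():
        i0 = int(round(t0 * sfreq))
        i1 = min(int(round(t1 * sfreq)), total)
        if i1 <= i0:
            logger.warning("segment %s has zero extent; skipped", label.value)
            continue
        sig = data_uv[:, i0:i1]
        if bandpass is not None:
            sig = bandpass_filter(sig, sfreq, *bandpass)
        segments[label] = SegmentRecording(
            label=label, sampling_rate=sfreq,
            channel_labels=list(ch_names), samples=sig,
        )

    if not segments:
        raise SessionError(f"no non-empty segments located in {path}")

    if montage is not None:
        available = set(ch_names)
        for anode, cathode in montage.derivation_pairs:
            name = derivation_name(anode, cathode)
            if name not in available and not (
                _norm_name(anode) in available
                and _norm_name(cathode) in available
            ):
                raise MontageError(
                    f"derivation {name} unavailable: electrodes missing and "
                    "no stored bipolar channel"
                )

    sid = subject_id
    if sid is None:
        import os

        sid = os.path.splitext(os.path.basename(str(path)))[0]
    return EEGSession(subject_id=sid, segments=segments)


def derive_bipolar_channels(
    session: EEGSession, montage: MontageConfig | None = None
) -> EEGSession:
    """Apply the bipolar montage: each derivation is anode minus cathode.

    When a file already stores a channel under the pair's name (either dash
    dialect) it is passed through unchanged; otherwise the derivation is
    computed sample-wise from the two referential channels.
    """
    montage = montage or MontageConfig()
    new_segments: dict[SegmentLabel, SegmentRecording] = {}
    for label, seg in session.segments.items():
        index = {name: i for i, name in enumerate(seg.channel_labels)}
        rows = []
        for anode, cathode in montage.derivation_pairs:
            name = derivation_name(anode, cathode)
            if name in index:
                rows.append(seg.samples[index[name]])
            elif _norm_name(anode) in index and _norm_name(cathode) in index:
                rows.append(seg.samples[index[_norm_name(anode)]]
                            - seg.samples[index[_norm_name(cathode)]])
            else:
                raise MontageError(
                    f"cannot derive {name}: electrode missing in segment "
                    f"{label.value}"
                )
        new_segments[label] = SegmentRecording(
            label=label,
            sampling_rate=seg.sampling_rate,
            channel_labels=list(montage.derivation_names),
            samples=np.vstack(rows),
        )
    return EEGSession(subject_id=session.subject_id, segments=new_segments)


def reject_artifacts(
    segment: SegmentRecording,
    amplitude_limit: float,
    epoch_seconds: float = 2.0,
    max_bad_channel_fraction: float = 0.5,
) -> SegmentRecording:
    """Amplitude-threshold epoch/channel rejection.

    The segment is cut into fixed non-overlapping epochs.  A channel whose
    peak amplitude exceeds ``amplitude_limit`` microvolts in more than
    ``max_bad_channel_fraction`` of epochs is excluded entirely; afterwards
    any epoch in which a surviving channel still exceeds the limit is
    dropped.  This is automated plumbing standing in for manual visual
    review, and is therefore off by default in the pipeline configuration.
    """
    if amplitude_limit <= 0:
        raise ValueError("amplitude_limit must be positive")
    n_epoch = int(epoch_seconds * segment.sampling_rate)
    n_full = segment.n_samples // n_epoch
    if n_full == 0:
        raise EmptySegmentError(
            f"segment {segment.label.value} shorter than one epoch"
        )
    x = segment.samples[:, : n_full * n_epoch]
    epochs = x.reshape(x.shape[0], n_full, n_epoch)
    peak = np.abs(epochs).max(axis=2)  # channels x epochs
    bad = peak > amplitude_limit

    bad_frac = bad.mean(axis=1)
    keep_ch = bad_frac <= max_bad_channel_fraction
    for name, frac, kept in zip(segment.channel_labels, bad_frac, keep_ch):
        if not kept:
            logger.info("channel %s excluded (%.0f%% epochs above %g uV)",
                        name, 100 * frac, amplitude_limit)
    if not keep_ch.any():
        raise EmptySegmentError(
            f"all channels of {segment.label.value} exceed {amplitude_limit} uV"
        )

    keep_ep = ~bad[keep_ch].any(axis=0)
    n_dropped = int((~keep_ep).sum())
    if n_dropped:
        logger.info("segment %s: dropped %d/%d epochs above %g uV",
                    segment.label.value, n_dropped, n_full, amplitude_limit)
    if not keep_ep.any():
        raise EmptySegmentError(
            f"every epoch of {segment.label.value} exceeds {amplitude_limit} uV"
        )

    cleaned = epochs[np.ix_(keep_ch.nonzero()[0], keep_ep.nonzero()[0])]
    cleaned = cleaned.reshape(int(keep_ch.sum()), -1)
    return SegmentRecording(
        label=segment.label,
        sampling_rate=segment.sampling_rate,
        channel_labels=[n for n, k in zip(segment.channel_labels, keep_ch) if k],
        samples=cleaned,
    )
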