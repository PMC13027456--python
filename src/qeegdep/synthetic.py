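"""Synthetic seven-segment EEG sessions with controllable band structure.

Each segment is a sum of band-centred sinusoidal tones (one per frequency
band, independent random phase per channel) over a band-limited 1/f (pink)
noise floor.  Tones make the analytic band powers exact (a^2/2 per tone), so
target relative powers can be dialled in per segment: the generator solves
for tone amplitudes that, together with the noise floor's logarithmic band
allocation, reproduce a requested relative-power profile.

Three phenotype presets span the decision space of the scoring framework:

``hyperaroused_dependent``
    suppressed alpha, dominant beta, TBR < 1, hyperarousal index >= 2 and no
    alpha blocking — satisfies every condition of the likelihood rule with
    margin and scores far above the 0.7 cut-off.
``healthy``
    prominent posterior-style alpha with intact blocking, moderate beta —
    scores well below 0.5.
``borderline``
    intermediate profile targeting a score near 0.6.

This module deliberately does not model dipoles, artifacts (beyond optional
injected spikes) or any other physiological realism: it exists so that the
full pipeline is testable without patient data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .exceptions import DomainError
from .session import (
    DEFAULT_REGION_MAP,
    EEGSession,
    SegmentLabel,
    SegmentRecording,
    SEGMENT_ORDER,
)
from .spectral import DEFAULT_BANDS, BandPowerRecord, SegmentFeatureTable

#: Tone frequency per band: the band centre (geometrically sensible midpoints).
BAND_CENTERS: dict[str, float] = {
    "delta": 2.5,
    "theta": 6.0,
    "alpha": 10.5,
    "beta": 21.5,
    "gamma": 37.5,
}

#: Mean clinical segment durations in seconds, in acquisition order.
DEFAULT_SEGMENT_DURATIONS: dict[SegmentLabel, float] = {
    SegmentLabel.BACKGROUND: 149.0,
    SegmentLabel.EYES_OPEN: 73.0,
    SegmentLabel.EYES_CLOSED: 222.0,
    SegmentLabel.HYPERVENTILATION: 172.0,
    SegmentLabel.POST_HYPERVENTILATION: 277.0,
    SegmentLabel.FLASH: 333.0,
    SegmentLabel.POST_FLASH: 473.0,
}

DEFAULT_CHANNELS: tuple[str, ...] = tuple(DEFAULT_REGION_MAP)

_NOISE_RANGE = (1.0, 45.0)


@dataclass(frozen=True)
class SegmentRecipe:
    """Tone amplitude (uV) per band plus the pink-noise RMS level (uV)."""

    amplitudes: Mapping[str, float]
    noise_rms: float = 0.0

    def __post_init__(self) -> None:
        if any(a < 0 for a in self.amplitudes.values()) or self.noise_rms < 0:
            raise DomainError("amplitudes and noise level must be >= 0")

    @property
    def tone_power(self) -> float:
        return sum(a * a / 2.0 for a in self.amplitudes.values())


@dataclass(frozen=True)
class SyntheticSubjectSpec:
    """Full per-segment recipe for one synthetic subject."""

    subject_id: str
    recipes: Mapping[SegmentLabel, SegmentRecipe]
    sampling_rate: float = 250.0
    durations: Mapping[SegmentLabel, float] = field(
        default_factory=lambda: dict(DEFAULT_SEGMENT_DURATIONS)
    )
    missing_segments: frozenset[SegmentLabel] = frozenset()
    seed: int = 0

    def __post_init__(self) -> None:
        if any(d <= 0 for d in self.durations.values()):
            raise DomainError("segment durations must be positive")


def _pink_noise(n: int, sampling_rate: float, rms: float,
                rng: np.random.Generator) -> np.ndarray:
    """Band-limited 1/f noise with the requested RMS amplitude."""
    if rms == 0:
        return np.zeros(n)
    freqs = np.fft.rfftfreq(n, 1.0 / sampling_rate)
    inband = (freqs >= _NOISE_RANGE[0]) & (freqs <= _NOISE_RANGE[1])
    spec = np.zeros(freqs.size, dtype=complex)
    k = int(inband.sum())
    spec[inband] = (rng.standard_normal(k) + 1j * rng.standard_normal(k)) \
        / np.sqrt(freqs[inband])
    x = np.fft.irfft(spec, n)
    x *= rms / np.sqrt(np.mean(x * x))
    return x


def generate_segment_signal(
    recipe: SegmentRecipe,
    label: SegmentLabel,
    duration: float,
    sampling_rate: float,
    channels: Sequence[str],
    rng: np.random.Generator,
) -> SegmentRecording:
    """Render one segment: per-channel random-phase tones plus pink noise."""
    n = int(round(duration * sampling_rate))
    t = np.arange(n) / sampling_rate
    out = np.zeros((len(channels), n))
    for ch in range(len(channels)):
        for band, amp in recipe.amplitudes.items():
            if amp == 0:
                continue
            phase = rng.uniform(0.0, 2.0 * math.pi)
            out[ch] += amp * np.sin(2.0 * math.pi * BAND_CENTERS[band] * t
                                    + phase)
        out[ch] += _pink_noise(n, sampling_rate, recipe.noise_rms, rng)
    return SegmentRecording(
        label=label,
        sampling_rate=sampling_rate,
        channel_labels=list(channels),
        samples=out,
    )


def generate_session_from_spec(
    spec: SyntheticSubjectSpec,
    channels: Sequence[str] = DEFAULT_CHANNELS,
) -> EEGSession:
    """Deterministically render every non-missing segment of a spec."""
    rng = np.random.default_rng(spec.seed)
    segments: dict[SegmentLabel, SegmentRecording] = {}
    for label in SEGMENT_ORDER:
        if label in spec.missing_segments or label not in spec.recipes:
            continue
        segments[label] = generate_segment_signal(
            spec.recipes[label], label, spec.durations[label],
            spec.sampling_rate, channels, rng,
        )
    return EEGSession(subject_id=spec.subject_id, segments=segments)


# ---------------------------------------------------------------------------
# Target-relative-power solver and phenotype presets
# ---------------------------------------------------------------------------

def _log_band_weights() -> dict[str, float]:
    lo0, hi0 = _NOISE_RANGE
    total = math.log(hi0 / lo0)
    return {b: math.log(hi / lo) / total for b, (lo, hi) in
            DEFAULT_BANDS.items()}


def recipe_for_relatives(
    target_relative: Mapping[str, float],
    total_power: float = 100.0,
    noise_fraction: float = 0.1,
) -> SegmentRecipe:
    """Solve tone amplitudes so measured relative powers hit the targets.

    ``target_relative`` must cover the five default bands and sum to 1; the
    pink-noise floor carries ``noise_fraction`` of the total tone power,
    split across bands proportionally to log-bandwidth (the 1/f law), and
    the tone powers absorb the difference.
    """
    r = {b: float(target_relative[b]) for b in DEFAULT_BANDS}
    s = sum(r.values())
    if any(v < 0 for v in r.values()) or abs(s - 1.0) > 1e-6:
        raise DomainError("target relative powers must be >= 0 and sum to 1")
    tone_total = total_power / (1.0 + noise_fraction)
    noise_power = noise_fraction * tone_total
    weights = _log_band_weights()
    amplitudes = {}
    for band, rel in r.items():
        p = rel * total_power - noise_power * weights[band]
        if p < 0:
            raise DomainError(
                f"band {band}: target {rel} infeasible under noise fraction "
                f"{noise_fraction}"
            )
        amplitudes[band] = math.sqrt(2.0 * p)
    return SegmentRecipe(amplitudes=amplitudes,
                         noise_rms=math.sqrt(noise_power))


@dataclass(frozen=True)
class PhenotypePreset:
    """Named per-segment relative-power targets expanding to a subject spec."""

    name: str
    segment_targets: Mapping[SegmentLabel, Mapping[str, float]]

    def expand(
        self,
        subject_id: str,
        seed: int,
        duration_scale: float = 1.0,
        amplitude_jitter: float = 0.05,
        missing_segments: Iterable[SegmentLabel] = (),
        sampling_rate: float = 250.0,
    ) -> SyntheticSubjectSpec:
        """Build a concrete subject spec, jittering tone amplitudes.

        Jitter is multiplicative Gaussian on each tone amplitude (default
        5%), giving a few percent of between-subject variability in band
        powers while keeping every preset comfortably inside its intended
        decision region.
        """
        rng = np.random.default_rng(seed)
        recipes = {}
        for label, targets in self.segment_targets.items():
            base = recipe_for_relatives(targets)
            amps = {
                b: a * max(0.0, 1.0 + amplitude_jitter * rng.standard_normal())
                for b, a in base.amplitudes.items()
            }
            recipes[label] = replace(base, amplitudes=amps)
        durations = {lab: d * duration_scale
                     for lab, d in DEFAULT_SEGMENT_DURATIONS.items()}
        return SyntheticSubjectSpec(
            subject_id=subject_id,
            recipes=recipes,
            sampling_rate=sampling_rate,
            durations=durations,
            missing_segments=frozenset(missing_segments),
            seed=int(rng.integers(0, 2**31 - 1)),
        )


_L = SegmentLabel

_HYPER = {
    _L.BACKGROUND: dict(delta=0.30, theta=0.10, alpha=0.06, beta=0.35, gamma=0.19),
    _L.EYES_OPEN: dict(delta=0.30, theta=0.10, alpha=0.07, beta=0.34, gamma=0.19),
    _L.EYES_CLOSED: dict(delta=0.29, theta=0.10, alpha=0.08, beta=0.34, gamma=0.19),
    _L.HYPERVENTILATION: dict(delta=0.28, theta=0.10, alpha=0.08, beta=0.35, gamma=0.19),
    _L.POST_HYPERVENTILATION: dict(delta=0.34, theta=0.10, alpha=0.06, beta=0.32, gamma=0.18),
    _L.FLASH: dict(delta=0.25, theta=0.09, alpha=0.08, beta=0.40, gamma=0.18),
    _L.POST_FLASH: dict(delta=0.28, theta=0.10, alpha=0.06, beta=0.37, gamma=0.19),
}

_HEALTHY = {
    _L.BACKGROUND: dict(delta=0.17, theta=0.25, alpha=0.35, beta=0.15, gamma=0.08),
    _L.EYES_OPEN: dict(delta=0.22, theta=0.25, alpha=0.15, beta=0.25, gamma=0.13),
    _L.EYES_CLOSED: dict(delta=0.12, theta=0.18, alpha=0.45, beta=0.17, gamma=0.08),
    _L.HYPERVENTILATION: dict(delta=0.20, theta=0.25, alpha=0.30, beta=0.17, gamma=0.08),
    _L.POST_HYPERVENTILATION: dict(delta=0.18, theta=0.24, alpha=0.32, beta=0.18, gamma=0.08),
    _L.FLASH: dict(delta=0.18, theta=0.24, alpha=0.30, beta=0.14, gamma=0.14),
    _L.POST_FLASH: dict(delta=0.15, theta=0.24, alpha=0.35, beta=0.14, gamma=0.12),
}

_BORDER = {
    _L.BACKGROUND: dict(delta=0.25, theta=0.25, alpha=0.12, beta=0.20, gamma=0.18),
    _L.EYES_OPEN: dict(delta=0.27, theta=0.25, alpha=0.12, beta=0.20, gamma=0.16),
    _L.EYES_CLOSED: dict(delta=0.23, theta=0.24, alpha=0.24, beta=0.15, gamma=0.14),
    _L.HYPERVENTILATION: dict(delta=0.25, theta=0.25, alpha=0.12, beta=0.20, gamma=0.18),
    _L.POST_HYPERVENTILATION: dict(delta=0.26, theta=0.25, alpha=0.13, beta=0.19, gamma=0.17),
    _L.FLASH: dict(delta=0.25, theta=0.24, alpha=0.12, beta=0.22, gamma=0.17),
    _L.POST_FLASH: dict(delta=0.25, theta=0.25, alpha=0.13, beta=0.20, gamma=0.17),
}

PRESETS: dict[str, PhenotypePreset] = {
    "hyperaroused_dependent": PhenotypePreset("hyperaroused_dependent", _HYPER),
    "healthy": PhenotypePreset("healthy", _HEALTHY),
    "borderline": PhenotypePreset("borderline", _BORDER),
}

#: Final label each preset is designed to produce.
PRESET_EXPECTED_LABEL: dict[str, str] = {
    "hyperaroused_dependent": "dependence-related",
    "healthy": "normal pattern",
    "borderline": "borderline",
}


def generate_session(
    preset: str | PhenotypePreset,
    subject_id: str = "synthetic",
    seed: int = 0,
    duration_scale: float = 1.0,
    missing_segments: Iterable[SegmentLabel] = (),
    amplitude_jitter: float = 0.05,
) -> EEGSession:
    """Render a full session for one phenotype preset."""
    if isinstance(preset, str):
        preset = PRESETS[preset]
    spec = preset.expand(
        subject_id, seed, duration_scale=duration_scale,
        amplitude_jitter=amplitude_jitter,
        missing_segments=missing_segments,
    )
    return generate_session_from_spec(spec)


def generate_cohort(
    n: int,
    mixture: Mapping[str, float],
    seed: int = 0,
    duration_scale: float = 1.0,
    amplitude_jitter: float = 0.05,
) -> list[tuple[EEGSession, str]]:
    """Generate ``n`` sessions with presets drawn from ``mixture``.

    Returns ``(session, preset_name)`` pairs; the assignment and every
    signal are pure functions of ``seed``.
    """
    if n <= 0:
        raise DomainError("cohort size must be positive")
    names = list(mixture)
    probs = np.array([mixture[k] for k in names], dtype=float)
    if np.any(probs < 0) or abs(probs.sum() - 1.0) > 1e-9:
        raise DomainError("mixture proportions must be >= 0 and sum to 1")
    unknown = set(names) - set(PRESETS)
    if unknown:
        raise DomainError(f"unknown presets: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    assignment = rng.choice(len(names), size=n, p=probs)
    out = []
    for i, k in enumerate(assignment):
        name = names[int(k)]
        session = generate_session(
            name, subject_id=f"syn{i:03d}",
            seed=int(rng.integers(0, 2**31 - 1)),
            duration_scale=duration_scale,
            amplitude_jitter=amplitude_jitter,
        )
        out.append((session, name))
    return out


# ---------------------------------------------------------------------------
# Feature-level fixture (bypasses signal synthesis)
# ---------------------------------------------------------------------------

def generate_feature_fixture(
    tbr: float,
    alpha_rel: float,
    beta_rel: float,
    hri: float | None = None,
    alpha_blocking_ratio: float = 1.0,
    subject_id: str = "fixture",
    total_power: float = 100.0,
) -> SegmentFeatureTable:
    """Build a feature table whose scoring inputs equal the given targets.

    The background record carries exactly the requested alpha/beta relative
    powers and TBR; the eyes segments realize the requested alpha-blocking
    ratio; hyperventilation and flash segments get neutral copies so every
    derived index is computable.  ``hri`` defaults to ``beta/alpha`` and, if
    supplied, must be consistent with it.
    """
    theta_rel = tbr * beta_rel
    if min(tbr, alpha_rel, beta_rel) < 0 or alpha_blocking_ratio < 0:
        raise DomainError("targets must be non-negative")
    if alpha_rel + beta_rel + theta_rel > 1.0 + 1e-9:
        raise DomainError("requested relative powers sum above 1")
    if hri is not None and alpha_rel > 0 and \
            abs(hri - beta_rel / alpha_rel) > 1e-9 * max(1.0, hri):
        raise DomainError("hri inconsistent with beta/alpha ratio")

    def record(label: SegmentLabel, alpha: float, beta: float,
               theta: float) -> BandPowerRecord:
        rest = max(0.0, 1.0 - alpha - beta - theta)
        rel = dict(delta=rest / 2.0, theta=theta, alpha=alpha, beta=beta,
                   gamma=rest / 2.0)
        return BandPowerRecord(
            segment=label, region="all",
            absolute={b: v * total_power for b, v in rel.items()},
            relative=rel,
            tbr=theta / beta if beta > 0 else 0.0,
            tbr_channel_mean=theta / beta if beta > 0 else 0.0,
            n_channels=10,
        )

    eo_alpha = min(alpha_rel if alpha_rel > 0 else 0.1, 0.2)
    ec_alpha = eo_alpha * alpha_blocking_ratio
    if ec_alpha > 0.9:
        raise DomainError("alpha blocking ratio infeasible for a relative power")

    records = {
        (SegmentLabel.BACKGROUND, "all"):
            record(SegmentLabel.BACKGROUND, alpha_rel, beta_rel, theta_rel),
        (SegmentLabel.EYES_OPEN, "all"):
            record(SegmentLabel.EYES_OPEN, eo_alpha, beta_rel, theta_rel),
        (SegmentLabel.EYES_CLOSED, "all"):
            record(SegmentLabel.EYES_CLOSED, ec_alpha, beta_rel, theta_rel),
        (SegmentLabel.HYPERVENTILATION, "all"):
            record(SegmentLabel.HYPERVENTILATION, alpha_rel, beta_rel, theta_rel),
        (SegmentLabel.POST_HYPERVENTILATION, "all"):
            record(SegmentLabel.POST_HYPERVENTILATION, alpha_rel, beta_rel, theta_rel),
        (SegmentLabel.FLASH, "all"):
            record(SegmentLabel.FLASH, alpha_rel, beta_rel, theta_rel),
        (SegmentLabel.POST_FLASH, "all"):
            record(SegmentLabel.POST_FLASH, alpha_rel, beta_rel, theta_rel),
    }
    return SegmentFeatureTable(subject_id=subject_id, records=records)


# ---------------------------------------------------------------------------
# Minimal EDF+C writer (16-bit, microvolt physical units, TAL annotations)
# ---------------------------------------------------------------------------

def _edf_field(value, width: int) -> bytes:
    b = str(value).encode("ascii")
    if len(b) > width:
        raise ValueError(f"EDF header field too long: {value!r}")
    return b.ljust(width)


def write_session_edf(session: EEGSession, path,
                      record_duration: float = 1.0) -> None:
    """Write a session as one continuous EDF+C file.

    Segments are concatenated in acquisition order; onsets and durations go
    into an ``EDF Annotations`` signal as time-stamped annotation lists, one
    annotation per segment, using the canonical segment names.  Signals are
    quantized to 16 bits over a symmetric physical range sized to the data,
    which keeps the quantization step well below thermal EEG noise.
    """
    order = [lab for lab in SEGMENT_ORDER if lab in session.segments]
    if not order:
        raise DomainError("cannot write a session with no segments")
    first = session.segments[order[0]]
    sfreq = first.sampling_rate
    ch_names = first.channel_labels
    for lab in order:
        seg = session.segments[lab]
        if seg.sampling_rate != sfreq or seg.channel_labels != ch_names:
            raise DomainError("all segments must share channels and rate")

    data = np.concatenate([session.segments[lab].samples for lab in order],
                          axis=1)
    annotations = []
    t = 0.0
    for lab in order:
        dur = session.segments[lab].duration
        annotations.append((t, dur, lab.value))
        t += dur

    n_ch, n_samp = data.shape
    spr = int(round(sfreq * record_duration))
    n_rec = int(np.ceil(n_samp / spr))
    if n_rec * spr > n_samp:
        data = np.pad(data, ((0, 0), (0, n_rec * spr - n_samp)))

    phys = float(max(1.0, 1.05 * np.abs(data).max()))
    pmin, pmax = -phys, phys
    dmin, dmax = -32768, 32767
    gain = (dmax - dmin) / (pmax - pmin)
    dig = np.clip(np.round((data - pmin) * gain + dmin), dmin, dmax
                  ).astype("<i2")

    tals = []
    for r in range(n_rec):
        tal = f"+{r * record_duration:g}\x14\x14\x00".encode("ascii")
        for onset, dur, text in annotations:
            if int(onset // record_duration) == r:
                tal += (f"+{onset:.4f}\x15{dur:.4f}\x14{text}\x14\x00"
                        .encode("ascii"))
        tals.append(tal)
    ann_bytes = max(len(x) for x in tals)
    ann_bytes += ann_bytes % 2
    ann_spr = ann_bytes // 2

    ns = n_ch + 1
    header_len = 256 * (ns + 1)
    hdr = b"".join([
        _edf_field("0", 8),
        _edf_field(f"X X X {session.subject_id}"[:80], 80),
        _edf_field("Startdate 01-JAN-2026 X X X", 80),
        _edf_field("01.01.26", 8),
        _edf_field("00.00.00", 8),
        _edf_field(header_len, 8),
        _edf_field("EDF+C", 44),
        _edf_field(n_rec, 8),
        _edf_field(f"{record_duration:g}", 8),
        _edf_field(ns, 4),
    ])
    labels = [n[:16] for n in ch_names] + ["EDF Annotations"]
    hdr += b"".join(_edf_field(l, 16) for l in labels)
    hdr += b"".join(_edf_field("", 80) for _ in range(ns))
    hdr += b"".join(_edf_field("uV", 8) for _ in range(n_ch))
    hdr += _edf_field("", 8)
    hdr += b"".join(_edf_field(f"{pmin:.6g}", 8) for _ in range(n_ch))
    hdr += _edf_field(-1, 8)
    hdr += b"".join(_edf_field(f"{pmax:.6g}", 8) for _ in range(n_ch))
    hdr += _edf_field(1, 8)
    hdr += b"".join(_edf_field(dmin, 8) for _ in range(ns))
    hdr += b"".join(_edf_field(dmax, 8) for _ in range(ns))
    hdr += b"".join(_edf_field("", 80) for _ in range(ns))
    hdr += b"".join(_edf_field(spr, 8) for _ in range(n_ch))
    hdr += _edf_field(ann_spr, 8)
    hdr += b"".join(_edf_field("", 32) for _ in range(ns))
    assert len(hdr) == header_len

    with open(path, "wb") as f:
        f.write(hdr)
        for r in range(n_rec):
            f.write(dig[:, r * spr:(r + 1) * spr].tobytes())
            f.write(tals[r].ljust(ann_bytes, b"\x00"))


def inject_spike(segment: SegmentRecording, at_seconds: float,
                 amplitude: float = 500.0,
                 width_seconds: float = 0.1) -> SegmentRecording:
    """Add a square transient to every channel (artifact-rejection fixture)."""
    i0 = int(at_seconds * segment.sampling_rate)
    i1 = min(i0 + int(width_seconds * segment.sampling_rate),
             segment.n_samples)
    samples = segment.samples.copy()
    samples[:, i0:i1] += amplitude
    return SegmentRecording(
        label=segment.label,
        sampling_rate=segment.sampling_rate,
        channel_labels=list(segment.channel_labels),
        samples=samples,
    )
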