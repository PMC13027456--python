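# Methods

## Session model

A session is one subject's EDF recording divided into up to seven
standardized phases: background activity, eyes open, eyes closed,
hyperventilation, after hyperventilation, flash stimulation and after flash
stimulation. Phase boundaries are taken from EDF+ annotations through a
configurable name map (with an explicit start/stop table as fallback);
boundaries are never detected automatically, matching clinical practice
where they are visually confirmed. Any phase may be absent — absence is
recorded, not fatal — but background and both eyes conditions are required
for scoring, and downstream indices that compare against a missing phase
are reported as NA rather than imputed.

Signals are carried in microvolts. MNE normalizes EDF channels to SI units
regardless of the header's physical-dimension field, so the package applies
one fixed conversion after reading. A zero-phase 4th-order Butterworth
band-pass over 1–45 Hz (the analysed range; configurable, disable with
`bandpass=None`) is applied per segment at read time.

## Montage

Ten frontal/central bipolar derivations are analysed: FZ–CZ, FP1–F3,
FP1–F7, FP2–F4, FP2–F8, F3–C3, F4–C4, C3–P3, C4–P4, CZ–PZ. Files may store
either referential 10–20 channels (the derivation is computed sample-wise
as anode − cathode) or ready-made bipolar channels under the pair's name
(passed through; both `-` and `–` dialects are accepted). The region map
tags the four fronto-polar chains as *frontal* and the six chains ending on
central/parietal electrodes as *central*; this assignment is a package
choice (the split is not fully determined by the electrode names) and is
configurable. Derived indices consume the mean over all ten derivations
("all") by default; per-region values are computed alongside.

## Spectral estimation

PSDs are estimated with Welch's method: 2 s Hann windows, 50% overlap,
constant detrend, density scaling. The 2 s window gives 0.5 Hz resolution —
at least six bins in the narrowest band — and ≥ 28 averaged windows for the
shortest clinical segment, at the cost of smearing spectral lines by
±0.5 Hz, which is irrelevant for band integrals. Both parameters are
configurable; a segment shorter than two windows is an error.

Band powers are trapezoidal integrals of the PSD over δ [1,4), θ [4,8),
α [8,13), β [13,30), γ [30,45) Hz. Band edges are treated as half-open so
shared edges are counted once; with contiguous bands the trapezoidal
integrals are exactly additive, and when the relative-power reference range
(default 1–45 Hz, configurable) coincides with the bands' union the five
relative powers sum to 1. The γ edges and the reference range are exposed
in configuration because different laboratories define both differently;
widening the reference range (e.g. to include sub-1 Hz or >45 Hz power)
uniformly deflates all relative powers without reordering them.

The TBR reported for a region is the ratio of the region-mean θ power to
the region-mean β power; the mean of per-channel ratios is stored alongside
(the two differ whenever band powers vary across channels — ratios of means
are not means of ratios). Cohort-level summaries always average per-subject
values.

## Derived indices

All indices are ratios, differences or comparisons of relative powers, so
every one of them is invariant to rescaling the raw signal. Categorical
thresholds: blocking intact iff EC/EO α ≥ 1.3; background α low iff
< 0.25; background β high iff > 0.20; HRI and recovery and TBR categories
use closed "normal" intervals ([1,2], [0.8,1.2], [1,4]); the CRI normal
interval is [0, 0.05]. Strict comparators are honoured exactly, which
fixes the tie-breaks: a value exactly at a strict boundary takes the
non-extreme category, and the yes/no comparisons ("after > during") treat
exact equality as the negative outcome.

Two intentionally literal quirks: HRI exactly 2.0 is category *normal*
while simultaneously satisfying the likelihood rule's "HRI ≥ 2.0" — both
definitions are applied as written; and the CRI uses available-term
averaging, falling back to the eyes contrast alone (flagged single-term)
when flash segments are missing, so subjects without flash data still
receive a CRI.

Zero denominators (e.g. eyes-open α exactly 0) yield a configurable capped
sentinel (default 10) plus a warning instead of failing; 0/0 is NA. This
keeps degenerate synthetic inputs flowing through the pipeline while
remaining visible in logs.

## Scoring and classification

Normalization caps (4.0, 0.30, 0.25, 3.0), weights (0.25, 0.25, 0.25,
0.15, 0.10), rule thresholds and decision cut-offs (0.7, 0.5) are all
configuration with the published defaults. The score is kept at full float
precision; the ≥ 0.7 comparison uses the unrounded score (rounding happens
only in reports). The hybrid rule's "or likelihood = yes" branch is
retained even though it is mathematically subsumed: with TBR < 1 the TBR
term exceeds 0.1875, β > 0.25 saturates its term at 0.25, HRI ≥ 2
contributes at least 1/6, the blocking deficit adds 0.10 and the α term is
positive, so every rule-positive profile scores > 0.70 (verified by
brute-force search as well). Both signals are reported separately because
they answer different questions (a conjunctive profile flag vs. a graded
composite). If blocking intactness is NA the score is not computed and the
subject is labelled *unclassifiable*.

## Synthetic cohort generator

Each segment is rendered as one sinusoidal tone per band — at 2.5, 6, 10.5,
21.5 and 37.5 Hz, independent uniform phase per channel — over a
band-limited (1–45 Hz) pink-noise floor. Tones were chosen over narrowband
noise because their band power is exactly a²/2, making parameter recovery
an analytic oracle. Given target relative powers, the generator solves for
tone amplitudes after allocating the noise floor (default 10% of total tone
power) across bands by the 1/f log-bandwidth law. Default segment durations
are the clinical means (149/73/222/172/277/333/473 s) at 250 Hz; the test
suite and the acceptance run scale them by 0.2, which keeps ≥ 28 Welch
windows in the shortest segment while holding the full-cohort runtime to
seconds.

Three presets target the decision regions: *hyperaroused_dependent*
(background α ≈ 0.06, β ≈ 0.35, TBR ≈ 0.29, HRI ≈ 5.8, blocking ratio
≈ 1.14 — every rule condition holds with margin, score ≈ 0.95), *healthy*
(α ≈ 0.35, blocking ratio ≈ 3, score ≈ 0.33) and *borderline* (score
≈ 0.59). Between-subject variability is multiplicative Gaussian jitter
(σ = 5%) on tone amplitudes; at that level each preset recovers its
intended label for ≈ 100% of seeds at 0.2× durations, with the borderline
preset the closest to a boundary (observed scores ≈ 0.51–0.68). Cohort
composition is drawn per subject from the mixture with the run's seed; all
outputs are pure functions of the seed.

What the generator does *not* emulate: 1/f slopes per segment, spectral
peaks with realistic bandwidth, non-stationarity, eye/muscle artifacts
(beyond an optional injected square transient used to exercise artifact
rejection), volume conduction or inter-channel correlation. Passing the
end-to-end tests therefore demonstrates that the pipeline's arithmetic and
decision logic are correct and that band-structured signals are recovered
through the EDF/PSD path — not that the scoring framework separates
clinical populations.

## EDF writing and artifact plumbing

EDF files are written by a minimal built-in EDF+C writer (16-bit samples,
microvolt physical range sized to the data, segment annotations as
time-stamped annotation lists); quantization error is below 0.01 µV for
typical amplitudes, and write→read round-trips preserve labels, rates and
durations to within one sample.

Amplitude-threshold artifact rejection (fixed epochs; drop epochs whose
peak exceeds the limit; drop channels that exceed it in more than a
configurable fraction of epochs) is provided as automated plumbing but is
**off by default**: the clinical procedure it stands in for is manual
visual review, and silent automatic rejection would change the measured
spectra.

## Cohort summaries

Categorical variables are summarized as counts with percentages (one
decimal, half-up rounding). Percentages are computed over non-NA subjects
by default; an "all" mode keeps NA as its own category over the full n —
both are provided because flash-dependent variables have a smaller natural
denominator whenever after-flash segments are missing. Continuous indices
are summarized as mean and SD of per-subject values.

## Limitations

The framework's thresholds and weights are fixed heuristics, not fitted
parameters; the package deliberately provides no machine-learning
re-weighting. Group-comparison statistics are out of scope. Only EDF input
is supported, and re-referencing beyond the bipolar pairs (average
reference, Laplacian) is not implemented.
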