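# Methods

This note records the model implemented by `earshot`, the parameter choices
that matter, what the simulator does and does not emulate, and the numerical
decisions taken where the design was genuinely open.

## Model

The system estimates, per frequency band *f* and world azimuth *α*, the
probability that a sound source occupies (*f*, *α*). Sensing is purely
interaural-time-difference (ITD) based: two omnidirectional point receivers
at spacing *d*, no level cues, no pinna cues, no envelope ITDs.

**Front end.** Each stereo frame (N_k = 4096 samples at f_s = 48 kHz) passes
through a bank of 4th-order gammatone filters, 50 centre frequencies linearly
spaced over 100–5000 Hz, bandwidth b = 1.019·ERB(f_c) with
ERB(f) = 24.7·(4.37·f/1000 + 1). Each filter is realized as a cascade of four
identical complex one-pole resonators (pole e^{−2πb/f_s}·e^{2πjf_c/f_s}),
whose real output has the analytic gammatone impulse response
t³·e^{−2πbt}·cos(2πf_c t). This all-pole formulation is used because a direct
8th-order transfer-function expansion of the same filter is numerically
unstable in double precision for f_c/f_s below roughly 1/160 — i.e. for most
of the low bands at 48 kHz. Filter state is carried across frames, so a
continuous input is filtered without boundary transients. An ERB-spaced
layout is available as an option.

**EPSP transform.** Each band signal is reduced to its positive-going zero
crossings (strictly-negative → non-negative between consecutive samples,
crossing assigned to the later sample, no sub-sample interpolation); the unit
impulse train is convolved with a Gaussian kernel. This idealizes the
phase-locked EPSP input to coincidence-detector neurons and has two
consequences exploited downstream: the signal is amplitude-invariant (only
crossing *times* matter), and beam responses become narrow with a width set
by the kernel, not by the stimulus wavelength.

**Beamforming.** Whole-sample interaural delays T_b = k/f_s,
k = −K..K, K = ⌊d·f_s/c⌋, define B = 2K+1 beams at θ_b = asin(c·T_b/d)
(asin argument clamped to [−1, 1] to absorb floating-point excess at the
endfire beams). For each beam the lagging channel is advanced by f_s·T_b
samples and the channels are averaged; samples shifted in from outside the
frame are zero. The per-band RMS over the frame gives the egocentric energy
image S_{f,b}. Edge effects are at most K ≈ 20 samples of 4096 (< 0.5% RMS
bias), accepted for simplicity. The sign convention, used everywhere:
positive egocentric angle = source on the side of the channel stored second
("right"), which then leads in time; a beam with T_b > 0 aligns such a
source by advancing the other ("left") channel.

**Fusion.** Each egocentric map is (i) cubic-spline interpolated from the 41
non-uniform beam angles onto 1° steps over [−90°, 90°] (negative spline
artifacts clipped to a relative 10⁻¹² floor), (ii) reflected across the
interaural axis, α → 180°−α, making the front/back redundancy of a
two-sensor array explicit and exact on the grid, (iii) normalized per band
to sum to one, (iv) circularly shifted by the (integer-degree) head
orientation into world coordinates, and (v) multiplied into the running
per-band posterior, which starts uniform ("array of ones"). Head
orientations are restricted to whole degrees so the rotation is an exact
shift with no second interpolation.

## Parameters

| parameter | default | meaning / rationale |
|---|---|---|
| mic spacing d | 0.145 m | array geometry; with f_s and c fixes K = 20, B = 41 beams |
| speed of sound c | 343 m/s | dry air at 20 °C; configurable, beam count depends on it |
| sample rate f_s | 48 000 Hz | one rate end-to-end (no playback/capture mismatch modelled) |
| frame length N_k | 4096 | ≈ 85 ms evidence window |
| bands | 50, linear, 100–5000 Hz | spectral axis of the map |
| EPSP kernel support | 1 ms | total width of the truncated Gaussian window |
| EPSP kernel σ | 0.05 ms | coincidence-window acuity; see below |
| schedule | 0°:20°:180° | 10 poses = 9 rotations |
| frames per pose | 12 | ≈ 1 s of audio per pose |
| fusion mode | multiply | every incoming frame map is one Bayes update |
| epsilon floor | 10⁻¹² | prevents a single zero from vetoing an angle forever |

**The EPSP kernel width** is the one genuinely underdetermined physiological
parameter, and it governs everything. The kernel's Fourier envelope
attenuates the pulse train's fundamental by e^{−2π²σ²f²}: with σ ≈ 0.4 ms
(a 1 ms FWHM) the EPSP signal at 2400 Hz is flat to one part in 10⁹ and
carries no usable ITD contrast at double precision, so no high-frequency
behavior of the system would exist at all. σ = 0.05 ms (kernel support 1 ms)
keeps phase structure through the top of the filter bank while still acting
as a graded coincidence window several samples wide. This single default
simultaneously yields the three signature behaviors of the method, none of
which was tuned independently: frequency-stable narrow beam profiles
(half-max widths at 500 and 2000 Hz within 20%), unambiguous high-frequency
localization after rotation, and the low-frequency resolution limit — a
300 Hz tone merges with broadband noise at 11° separation (the coincidence
peak is ~16–25° wide pre-fusion) yet is resolved at 22°.

**Fusion mode.** The update rule is a running product over incoming maps.
Multiplying each frame's evidence map (12 updates per pose) is the default:
suppression of a wandering phantom lobe compounds per *frame*, and after a
full scan the front/back ghost retains < 10⁻⁷ of the true peak's mass in the
tone band. Averaging the frames of a pose into a single evidence map before
updating (one update per pose) is available as `fusion_mode="average"`, but
with only ~9 effective multiplications the 180° ghost of a midline noise
source retains ~20–40% of its peak and can outrank a weak second source in
the collapsed profile; it is kept for comparison, not recommended.

**Renormalization.** The raw running product underflows after a handful of
updates; each band row is therefore renormalized to sum to one after every
multiplication. This changes nothing ordinal (per-band argmax, peak-shape
ratios) and makes the final map independent of update order to 10⁻⁹.

## The simulator

The scene simulator replaces a physical rotating microphone array. Each
source has one continuous master waveform for the whole run (tones and
complexes keep phase across frames; noise and WAV sources are seeded
streams), normalized to a configurable RMS level — co-presented targets are
equalized by construction. Per channel, the waveform is delayed by ±ITD/2
via an 81-tap Kaiser-windowed-sinc fractional delay; the world is *not*
sample-quantized (only the analyzer is). Sources behind the interaural axis
receive the ITD of their front mirror image through sin(α), which is exactly
the physical ambiguity the fusion stage must resolve. Background noise is
white Gaussian, independent per channel, at a configurable linear RMS
(default 0.02 re. unit-RMS targets in the canned scenarios). A single master
seed drives per-source and per-channel substreams, so runs repeat
bit-identically.

Not emulated: room reflections and reverberation, distance attenuation,
microphone directivity, interaural level differences, pinna filtering,
source motion, and playback/capture rate mismatch. Passing tests therefore
demonstrate the *computational* claim — that ITD plus rotation plus
multiplicative memory resolves spatial-spectral ambiguity — under clean
anechoic geometry; they do not establish robustness to reverberant rooms or
to cue conflicts, where the evidence maps would be materially noisier.
Two-talker scenes accept user-supplied mono WAV files; without them the
scenario substitutes synthetic vowel-like harmonic stacks (f₀ = 210 and
120 Hz), which exercise broadband periodic unmixing but are not speech.

## Metrics

The map is collapsed across frequency by the per-angle *mean* of the band
rows (rows are individually normalized, so mean and sum have identical peak
structure; mean keeps the profile a probability-like quantity). Peaks are
local maxima of the circular profile ranked by topographic prominence,
computed after unwrapping the circle at its global minimum so no peak
straddles the seam; ties break toward the smaller angle; peaks exactly on
the mirror axis are kept once. Each peak carries its half-prominence extent
(overlapping extents are truncated at the nearer-peak boundary) and full
width at half prominence. Localization error sums, over true sources, the
circular distance to the nearest peak. Spectral correlation is the Pearson
correlation between (S_B2 − S_B1) — per-band probability mass under the two
peak extents — and (S_T2 − S_T1), the per-band RMS of the original source
waveforms passed monaurally through the same filter bank; it is undefined
(NaN) while fewer than two distinct peaks exist. Pearson rather than rank
correlation is used; the difference-of-spectra construction makes the
measure exactly invariant to mass shared by both peaks.

A note on the analytic oracle: the closed form A(ψ, θ) describes the
*linear* delay-and-sum response to a tone, and the audio chain reproduces it
essentially exactly (r ≈ 1.000 at 500/1200/2400 Hz) when beams are driven by
the filtered band signals. EPSP-driven profiles match A where A itself is
narrow (r > 0.9 at 2400 Hz) but are deliberately much narrower than A at low
frequency (r ≈ 0.6–0.7 at 500–1200 Hz) — that reshaping, not agreement with
A, is the EPSP stage's purpose, and is what the width-stability test pins
down.

## Degenerate inputs and numerical details

Empty or silent scenes yield uniform evidence (a zero band row normalizes to
uniform), a flat final map, and NaN metrics rather than errors. Fewer than
4 beams cannot be spline-resampled and are rejected. Tone frequencies at or
above Nyquist, unreadable WAV paths, schedules outside [0°, 360°), and
frame indices beyond the scene duration raise typed errors. The Gaussian
EPSP kernel is truncated to its stated support and forced to odd length;
FFT-convolution round-off below zero is clipped. Cubic splines are evaluated
only inside [−90°, 90°], so no extrapolation occurs. All randomness flows
from `numpy.random.SeedSequence` spawns of one scene seed.

## Known limitations

Peak-width estimates at high map sharpness are grid-limited (the 1° grid
floors measurable widths). Sources that collide within a band produce a
single fused image there — no per-cell reliability weighting is implemented.
The system deliberately blurs world-moving sources; only allocentrically
stationary scenes are modelled. The egocentric-recursion (Kalman-style)
variant and ILD/envelope cues are out of scope.
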