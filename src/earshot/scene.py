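"""Binaural scene simulator.

Renders two-channel audio frames for a configured acoustic scene as heard by a
pair of omnidirectional microphones on a rotatable head. The only spatial cue
rendered is the interaural time difference (ITD): each source waveform is
delayed per channel by half the ITD appropriate for its angle relative to the
current head orientation. Level differences, distance attenuation and room
reflections are deliberately absent.

Angle conventions used throughout the package:

* Allocentric azimuths are degrees in [0, 360) in a fixed world frame;
  0 deg is the head's frontal midline when the head orientation is 0 deg,
  and angles increase towards the side whose microphone we call "right".
* The egocentric angle of a source is ``azimuth - head_orientation``.
* A positive egocentric angle puts the source on the right: the sound
  arrives at the right microphone first, so the ITD (left arrival time minus
  right arrival time) is positive.
* Sources behind the interaural axis (|egocentric angle| > 90 deg) carry the
  ITD of their front mirror image, because ``sin`` is symmetric about 90 deg.
  This realizes the physical front/back ambiguity that the fusion stage must
  resolve.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.io import wavfile
from scipy.signal import resample_poly

__all__ = [
    "ArrayGeometry",
    "SourceSpec",
    "SceneSpec",
    "StereoFrame",
    "SceneRenderer",
    "itd_for_source",
    "render_frame",
]

DEFAULT_FRAME_LENGTH = 4096


class SceneError(ValueError):
    """Invalid scene or source specification."""


@dataclass(frozen=True)
class ArrayGeometry:
    """Microphone-pair geometry governing the ITD-to-angle map.

    Parameters
    ----------
    mic_spacing_m : float
        Distance between the two microphones, metres.
    speed_of_sound_mps : float
        Speed of sound, m/s. Not a measured room property here; 343 m/s
        (dry air, 20 C) is the conventional default.
    sample_rate_hz : float
        Sampling rate of capture and of all rendered audio.
    """

    mic_spacing_m: float = 0.145
    speed_of_sound_mps: float = 343.0
    sample_rate_hz: float = 48000.0

    def __post_init__(self) -> None:
        if self.mic_spacing_m <= 0 or self.speed_of_sound_mps <= 0 or self.sample_rate_hz <= 0:
            raise SceneError("geometry parameters must be positive")
        if self.max_delay_samples < 1:
            raise SceneError(
                "mic spacing too small for the sample rate: the maximum "
                "interaural delay is below one sample"
            )

    @property
    def max_itd_s(self) -> float:
        """Largest physical interaural delay (endfire source), seconds."""
        return self.mic_spacing_m / self.speed_of_sound_mps

    @property
    def max_delay_samples(self) -> int:
        """K, the number of whole-sample delays per hemifield."""
        return int(np.floor(self.max_itd_s * self.sample_rate_hz))


@dataclass(frozen=True)
class SourceSpec:
    """One sound source at a fixed allocentric azimuth.

    ``level`` is the linear broadband RMS amplitude of the source waveform at
    the microphones; co-presented targets are equalized simply by giving them
    the same level (the default 1.0).
    """

    kind: str  # tone | tone_complex | broadband_noise | wav_file
    azimuth_deg: float
    level: float = 1.0
    freq_hz: float | None = None
    freqs_hz: tuple[float, ...] | None = None
    band_hz: tuple[float, float] | None = None
    path: str | None = None

    # -- convenience constructors -------------------------------------------------
    @classmethod
    def tone(cls, freq_hz: float, azimuth_deg: float, level: float = 1.0) -> "SourceSpec":
        return cls(kind="tone", azimuth_deg=azimuth_deg, level=level, freq_hz=freq_hz)

    @classmethod
    def tone_complex(
        cls, freqs_hz: tuple[float, ...], azimuth_deg: float, level: float = 1.0
    ) -> "SourceSpec":
        return cls(kind="tone_complex", azimuth_deg=azimuth_deg, level=level,
                   freqs_hz=tuple(freqs_hz))

    @classmethod
    def noise(
        cls,
        azimuth_deg: float,
        level: float = 1.0,
        band_hz: tuple[float, float] | None = None,
    ) -> "SourceSpec":
        return cls(kind="broadband_noise", azimuth_deg=azimuth_deg, level=level,
                   band_hz=band_hz)

    @classmethod
    def wav(cls, path: str, azimuth_deg: float, level: float = 1.0) -> "SourceSpec":
        return cls(kind="wav_file", azimuth_deg=azimuth_deg, level=level, path=path)

    def validate(self, sample_rate_hz: float) -> None:
        nyquist = sample_rate_hz / 2.0
        if self.kind == "tone":
            if self.freq_hz is None or not (0.0 < self.freq_hz < nyquist):
                raise SceneError(f"tone frequency {self.freq_hz} outside (0, {nyquist}) Hz")
        elif self.kind == "tone_complex":
            if not self.freqs_hz:
                raise SceneError("tone complex needs at least one component")
            for f in self.freqs_hz:
                if not (0.0 < f < nyquist):
                    raise SceneError(f"component frequency {f} outside (0, {nyquist}) Hz")
        elif self.kind == "broadband_noise":
            if self.band_hz is not None:
                lo, hi = self.band_hz
                if not (0.0 <= lo < hi <= nyquist):
                    raise SceneError(f"noise band {self.band_hz} invalid for fs={sample_rate_hz}")
        elif self.kind == "wav_file":
            if not self.path:
                raise SceneError("wav source requires a file path")
        else:
            raise SceneError(f"unknown source kind {self.kind!r}")


@dataclass(frozen=True)
class SceneSpec:
    """A full acoustic scene: sources, background noise, duration and seed."""

    sources: tuple[SourceSpec, ...]
    background_noise_level: float = 0.0
    duration_frames: int = 120
    frame_length: int = DEFAULT_FRAME_LENGTH
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "sources", tuple(self.sources))
        if self.duration_frames < 1 or self.frame_length < 2:
            raise SceneError("scene must span at least one frame of at least two samples")
        if self.background_noise_level < 0:
            raise SceneError("background noise level must be non-negative")

    def with_seed(self, seed: int) -> "SceneSpec":
        return replace(self, seed=int(seed))


@dataclass
class StereoFrame:
    """One two-channel block of samples captured at one head orientation."""

    samples: np.ndarray  # (2, frame_length)
    head_orientation_deg: float

    @property
    def frame_length(self) -> int:
        return self.samples.shape[1]


def itd_for_source(
    geometry: ArrayGeometry, source_azimuth_deg: float, head_orientation_deg: float
) -> float:
    """Signed interaural delay, seconds, for a source at a world azimuth.

    Positive means the sound reaches the right microphone first. Sources
    behind the interaural axis map onto their front mirror image through the
    sine, which is the physical front/back ambiguity.
    """
    ego = np.deg2rad(source_azimuth_deg - head_orientation_deg)
    return geometry.max_itd_s * float(np.sin(ego))


# ---------------------------------------------------------------------------
# fractional delay


def _fractional_delay_fir(frac: float, taps: int = 81, beta: float = 8.6) -> np.ndarray:
    """Windowed-sinc FIR realizing a delay of ``frac`` samples, |frac| <= 0.5."""
    n = np.arange(taps)
    centre = (taps - 1) / 2.0
    h = np.sinc(n - centre - frac) * np.kaiser(taps, beta)
    return h / h.sum()


class SceneRenderer:
    """Deterministic frame renderer for one scene/geometry pair.

    Each source gets a single continuous master waveform spanning the whole
    run (so tones keep phase continuity across frames), padded at both ends to
    absorb interaural shifts and the fractional-delay filter transient. A
    frame at head orientation ``h`` is rendered by sampling each master
    waveform at ``t -/+ itd/2`` per channel via a windowed-sinc fractional
    delay, then summing sources and adding independent per-channel white
    Gaussian background noise. Everything is a pure function of the scene
    seed, so runs repeat exactly.
    """

    _FIR_TAPS = 81

    def __init__(self, scene: SceneSpec, geometry: ArrayGeometry):
        for src in scene.sources:
            src.validate(geometry.sample_rate_hz)
        self.scene = scene
        self.geometry = geometry
        self._pad = geometry.max_delay_samples + self._FIR_TAPS  # per side
        self._total = scene.duration_frames * scene.frame_length
        seq = np.random.SeedSequence(scene.seed)
        src_seeds = seq.spawn(len(scene.sources) + 1)
        self._waveforms = [
            self._master_waveform(src, np.random.default_rng(s))
            for src, s in zip(scene.sources, src_seeds[:-1])
        ]
        # background noise, one stream per channel, full run length
        bg_rng = np.random.default_rng(src_seeds[-1])
        if scene.background_noise_level > 0:
            self._background = scene.background_noise_level * bg_rng.standard_normal(
                (2, self._total)
            )
        else:
            self._background = None
        self._fir_cache: dict[float, np.ndarray] = {}

    # -- master waveforms --------------------------------------------------------
    def _timebase(self) -> np.ndarray:
        fs = self.geometry.sample_rate_hz
        n = self._total + 2 * self._pad
        return (np.arange(n) - self._pad) / fs

    def _master_waveform(self, src: SourceSpec, rng: np.random.Generator) -> np.ndarray:
        fs = self.geometry.sample_rate_hz
        n = self._total + 2 * self._pad
        if src.kind == "tone":
            x = np.sin(2 * np.pi * src.freq_hz * self._timebase())
        elif src.kind == "tone_complex":
            t = self._timebase()
            x = np.zeros_like(t)
            for f in src.freqs_hz:
                x += np.sin(2 * np.pi * f * t)
        elif src.kind == "broadband_noise":
            x = rng.standard_normal(n)
            if src.band_hz is not None:
                from scipy.signal import butter, sosfiltfilt

                lo, hi = src.band_hz
                nyq = fs / 2.0
                if lo <= 0:
                    sos = butter(4, hi / nyq, btype="low", output="sos")
                else:
                    sos = butter(4, [lo / nyq, hi / nyq], btype="band", output="sos")
                x = sosfiltfilt(sos, x)
        elif src.kind == "wav_file":
            x = _load_mono_wav(src.path, fs)
            if x.size < n:  # loop short stimuli to fill the run
                x = np.tile(x, int(np.ceil(n / x.size)))
            x = x[:n]
        else:  # pragma: no cover - guarded by validate()
            raise SceneError(f"unknown source kind {src.kind!r}")
        rms = np.sqrt(np.mean(np.square(x)))
        if rms == 0:
            raise SceneError(f"source {src.kind} at {src.azimuth_deg} deg renders silence")
        return (src.level / rms) * x

    # -- rendering ----------------------------------------------------------------
    def source_waveform(self, index: int) -> np.ndarray:
        """Level-scaled master waveform of one source (run span, no padding)."""
        return self._waveforms[index][self._pad : self._pad + self._total]

    def _delayed_segment(self, wave: np.ndarray, shift_samples: float,
                         start: int, length: int) -> np.ndarray:
        """wave(t - shift) over [start, start+length), shift in samples."""
        int_shift = int(np.round(shift_samples))
        frac = shift_samples - int_shift
        half = (self._FIR_TAPS - 1) // 2
        i0 = start + self._pad - int_shift - half
        seg = wave[i0 : i0 + length + self._FIR_TAPS - 1]
        key = round(frac, 9)
        fir = self._fir_cache.get(key)
        if fir is None:
            fir = _fractional_delay_fir(frac, self._FIR_TAPS)
            self._fir_cache[key] = fir
        return np.convolve(seg, fir, mode="valid")

    def render_frame(self, head_orientation_deg: float, frame_index: int) -> StereoFrame:
        scene, geom = self.scene, self.geometry
        if not (0 <= frame_index < scene.duration_frames):
            raise SceneError(
                f"frame_index {frame_index} outside scene duration {scene.duration_frames}"
            )
        n = scene.frame_length
        start = frame_index * n
        out = np.zeros((2, n))
        fs = geom.sample_rate_hz
        for src, wave in zip(scene.sources, self._waveforms):
            tau = itd_for_source(geom, src.azimuth_deg, head_orientation_deg)
            half_shift = tau * fs / 2.0
            # positive tau: right leads -> left delayed by tau/2, right advanced
            out[0] += self._delayed_segment(wave, +half_shift, start, n)
            out[1] += self._delayed_segment(wave, -half_shift, start, n)
        if self._background is not None:
            out += self._background[:, start : start + n]
        return StereoFrame(samples=out, head_orientation_deg=float(head_orientation_deg))


def render_frame(
    scene: SceneSpec,
    geometry: ArrayGeometry,
    head_orientation_deg: float,
    frame_index: int,
) -> StereoFrame:
    """One-shot frame render (builds a fresh renderer; prefer SceneRenderer in loops)."""
    return SceneRenderer(scene, geometry).render_frame(head_orientation_deg, frame_index)


def _load_mono_wav(path: str, target_fs: float) -> np.ndarray:
    """Read a WAV file as float mono at the run's sample rate."""
    try:
        fs_in, data = wavfile.read(path)
    except (FileNotFoundError, OSError) as exc:
        raise SceneError(f"unreadable WAV input {path!r}: {exc}") from exc
    x = np.asarray(data, dtype=float)
    if x.ndim == 2:
        x = x.mean(axis=1)
    if np.issubdtype(np.asarray(data).dtype, np.integer):
        x = x / float(np.iinfo(np.asarray(data).dtype).max)
    if fs_in != target_fs:
        from fractions import Fraction

        ratio = Fraction(int(target_fs), int(fs_in)).limit_denominator(1000)
        x = resample_poly(x, ratio.numerator, ratio.denominator)
    return x
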