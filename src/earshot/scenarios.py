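"""Canned experiment configurations for the standard study scenarios."""

from __future__ import annotations

from .experiment import ExperimentConfig
from .scene import SceneSpec, SourceSpec

__all__ = [
    "tone_in_noise",
    "tone_complexes",
    "two_talkers",
    "single_tone",
    "COMPLEX_A_HZ",
    "COMPLEX_B_HZ",
]

# Two interleaved harmonic-like combs, 600 Hz steps, offset by 300 Hz:
# 200..4400 and 500..4700 Hz.
COMPLEX_A_HZ = tuple(range(200, 4401, 600))
COMPLEX_B_HZ = tuple(range(500, 4701, 600))

_BACKGROUND = 0.02  # room noise floor, linear RMS re. unit-RMS targets


def tone_in_noise(
    tone_hz: float = 2400.0,
    separation_deg: float = 11.0,
    noise_azimuth_deg: float = 0.0,
    seed: int = 0,
    **overrides,
) -> ExperimentConfig:
    """Broadband noise at one azimuth and a pure tone offset from it."""
    scene = SceneSpec(
        sources=(
            SourceSpec.noise(azimuth_deg=noise_azimuth_deg),
            SourceSpec.tone(tone_hz, azimuth_deg=(noise_azimuth_deg + separation_deg) % 360),
        ),
        background_noise_level=_BACKGROUND,
        seed=seed,
    )
    return ExperimentConfig(scene=scene, seed=seed, **overrides)


def tone_complexes(separation_deg: float = 22.0, seed: int = 0, **overrides) -> ExperimentConfig:
    """Two interleaved tone complexes at 0 deg and at ``separation_deg``."""
    scene = SceneSpec(
        sources=(
            SourceSpec.tone_complex(COMPLEX_A_HZ, azimuth_deg=0.0),
            SourceSpec.tone_complex(COMPLEX_B_HZ, azimuth_deg=separation_deg),
        ),
        background_noise_level=_BACKGROUND,
        seed=seed,
    )
    return ExperimentConfig(scene=scene, seed=seed, **overrides)


def two_talkers(
    wav_a: str | None = None,
    wav_b: str | None = None,
    separation_deg: float = 45.0,
    seed: int = 0,
    **overrides,
) -> ExperimentConfig:
    """Two talkers separated in azimuth.

    Real speech recordings can be supplied as mono WAV files; without them the
    scenario substitutes synthetic vowel-like stimuli (harmonic stacks on
    distinct fundamentals), which exercise the same spectral-spatial
    unmixing on broadband periodic sources.
    """
    if wav_a and wav_b:
        sources = (
            SourceSpec.wav(wav_a, azimuth_deg=0.0),
            SourceSpec.wav(wav_b, azimuth_deg=separation_deg),
        )
    else:
        # "female"/"male"-register fundamentals; disjoint low harmonics
        sources = (
            SourceSpec.tone_complex(tuple(210.0 * k for k in range(1, 16)), azimuth_deg=0.0),
            SourceSpec.tone_complex(tuple(120.0 * k for k in range(1, 26)),
                                    azimuth_deg=separation_deg),
        )
    scene = SceneSpec(sources=sources, background_noise_level=_BACKGROUND, seed=seed)
    return ExperimentConfig(scene=scene, seed=seed, **overrides)


def single_tone(
    tone_hz: float,
    azimuth_deg: float,
    seed: int = 0,
    background_noise_level: float = 0.0,
    **overrides,
) -> ExperimentConfig:
    """A lone pure tone; used for oracle checks against the analytic response."""
    scene = SceneSpec(
        sources=(SourceSpec.tone(tone_hz, azimuth_deg=azimuth_deg),),
        background_noise_level=background_noise_level,
        seed=seed,
    )
    return ExperimentConfig(scene=scene, seed=seed, **overrides)
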