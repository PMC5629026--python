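"""Frequency-tuned delay-and-sum beamforming over interaural delays.

Each whole-sample interaural delay that the microphone spacing supports
defines one beam; with spacing ``d``, sample rate ``fs`` and speed of sound
``c`` there are ``K = floor(d*fs/c)`` delays per hemifield, hence
``2K + 1`` beams spanning -90..+90 deg via ``theta = asin(c*T_b/d)``. A beam
is computed by advancing the lagging channel by the beam's characteristic
delay and averaging the two channels, so signals arriving from the beam's
angle add coherently. The per-beam RMS over a frame gives the egocentric
bands-by-beams energy map.

This bank of frequency-tuned beams is a signal-processing rendering of the
Jeffress delay-line/coincidence-detector circuit: every (band, delay) cell is
one coincidence detector. The closed-form response of an ideal two-sensor
delay-and-sum beam to a pure tone,

    A(psi, theta) = sqrt(2 + 2*cos(2*pi*f*d*(sin psi - sin theta)/c)) / 2,

is provided as ``analytic_response`` and serves as an independent oracle for
the audio-domain chain, including its spatial-aliasing lobes at high
frequency.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cochlea import BandSignals
from .scene import ArrayGeometry

__all__ = [
    "BeamSet",
    "EgoMap",
    "make_beam_set",
    "delay_and_sum",
    "beam_energy",
    "analytic_response",
]


class BeamformError(ValueError):
    """Invalid beamformer configuration."""


@dataclass(frozen=True)
class BeamSet:
    """Characteristic delays and arrival angles of the beam fan."""

    delays_s: np.ndarray  # (n_beams,) integer multiples of 1/fs, ascending
    angles_deg: np.ndarray  # (n_beams,) strictly increasing, -90..+90
    sample_rate_hz: float

    @property
    def n_beams(self) -> int:
        return self.delays_s.size

    @property
    def delay_samples(self) -> np.ndarray:
        return np.round(self.delays_s * self.sample_rate_hz).astype(int)


@dataclass
class EgoMap:
    """Egocentric bands-by-beams energy image for one frame (or frame average)."""

    energy: np.ndarray  # (n_bands, n_beams), >= 0
    band_centres_hz: np.ndarray
    beam_angles_deg: np.ndarray
    head_orientation_deg: float
    frame_length: int


def make_beam_set(geometry: ArrayGeometry) -> BeamSet:
    """Beam fan for a geometry: delays k/fs for k = -K..K, angles asin(c*T/d).

    The asin argument is clamped to [-1, 1] to absorb the floating-point
    excess at the endfire beams (taking the real part of the principal value).
    """
    K = geometry.max_delay_samples
    if K < 1:
        raise BeamformError("geometry supports no whole-sample interaural delay")
    k = np.arange(-K, K + 1)
    delays = k / geometry.sample_rate_hz
    arg = geometry.speed_of_sound_mps * delays / geometry.mic_spacing_m
    angles = np.rad2deg(np.arcsin(np.clip(arg, -1.0, 1.0)))
    return BeamSet(delays_s=delays, angles_deg=angles,
                   sample_rate_hz=geometry.sample_rate_hz)


def delay_and_sum(bands: BandSignals, beams: BeamSet) -> np.ndarray:
    """Steer every beam through every band: (n_bands, n_beams, n_samples).

    For a beam with delay ``T_b > 0`` (source right of midline, left channel
    lagging) the left channel is advanced by ``fs*T_b`` samples and averaged
    with the right channel; negative delays advance the right channel.
    Samples shifted in from beyond the frame are zero.
    """
    if bands.stage not in ("epsp", "filtered"):
        raise BeamformError(f"unexpected band stage {bands.stage!r}")
    left, right = bands.values[:, 0, :], bands.values[:, 1, :]
    n_bands, n = left.shape
    shifts = beams.delay_samples
    out = np.zeros((n_bands, beams.n_beams, n))
    for j, s in enumerate(shifts):
        if s >= 0:  # advance left by s
            out[:, j, : n - s] = left[:, s:]
            out[:, j, :] += right
        else:  # advance right by |s|
            out[:, j, : n + s] = right[:, -s:]
            out[:, j, :] += left
        out[:, j, :] *= 0.5
    return out


def beam_energy(
    beam_signals: np.ndarray,
    band_centres_hz: np.ndarray,
    beams: BeamSet,
    head_orientation_deg: float = 0.0,
) -> EgoMap:
    """RMS over the frame per (band, beam): S[f, b] = sqrt(mean_k Z[f,b,k]^2)."""
    energy = np.sqrt(np.mean(np.square(beam_signals), axis=-1))
    return EgoMap(
        energy=energy,
        band_centres_hz=np.asarray(band_centres_hz),
        beam_angles_deg=beams.angles_deg,
        head_orientation_deg=float(head_orientation_deg),
        frame_length=beam_signals.shape[-1],
    )


def analytic_response(
    freq_hz: float,
    arrival_deg: np.ndarray | float,
    steering_deg: np.ndarray | float,
    geometry: ArrayGeometry,
) -> np.ndarray | float:
    """Ideal two-sensor delay-and-sum amplitude response A(psi, theta) in [0, 1]."""
    psi = np.deg2rad(arrival_deg)
    theta = np.deg2rad(steering_deg)
    phase = (
        2 * np.pi * freq_hz * geometry.mic_spacing_m
        * (np.sin(psi) - np.sin(theta)) / geometry.speed_of_sound_mps
    )
    return np.sqrt(np.clip(2.0 + 2.0 * np.cos(phase), 0.0, None)) / 2.0


def ego_map_csv(ego: EgoMap) -> str:
    """Delimited export: header rows of band centres and beam angles, then energies."""
    lines = [
        "# beam_angles_deg," + ",".join(f"{a:.4f}" for a in ego.beam_angles_deg),
        "# band_centres_hz," + ",".join(f"{f:.2f}" for f in ego.band_centres_hz),
    ]
    for row in ego.energy:
        lines.append(",".join(f"{v:.8g}" for v in row))
    return "\n".join(lines) + "\n"
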