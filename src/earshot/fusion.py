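"""Recursive Bayesian fusion of egocentric evidence into an allocentric map.

A two-microphone array cannot tell front from back, and at high frequencies
spatial aliasing adds further phantom lobes, so a single egocentric energy
map is ambiguous. The resolution is active hearing: each egocentric map is
reflected across the interaural axis (making the front/back redundancy
explicit), resampled onto a 360-point 1-degree grid, normalized per band into
a probability row, rotated into world coordinates by the current head
orientation, and multiplied into a running allocentric posterior. Evidence
lobes that track a real world position reinforce each other across head
rotations; phantom lobes move and are multiplied away.

Each band row of the allocentric map is renormalized to sum to one after
every multiplicative update. The raw running product of the update rule is
equivalent up to a per-band scale factor (so peak positions and peak-shape
ratios are unchanged) but underflows after a handful of updates; the
normalized form is the numerically viable one, and makes update order
irrelevant. A floor of 1e-12 is applied before renormalization so that a
single zero in one evidence map cannot permanently veto an angle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline

from .beamform import BeamSet, EgoMap, beam_energy, delay_and_sum, make_beam_set
from .cochlea import (
    DEFAULT_EPSP_SIGMA_MS,
    DEFAULT_EPSP_WINDOW_MS,
    FilterbankSpec,
    GammatoneFilterbank,
    epsp_transform,
)
from .scene import ArrayGeometry, SceneRenderer, SceneSpec

__all__ = [
    "EgoEvidence",
    "AlloMap",
    "reflect_and_resample",
    "normalize_bands",
    "rotate_to_allocentric",
    "bayes_update",
    "run_scan",
    "ScanResult",
]

N_ANGLES = 360
EPSILON = 1e-12


class FusionError(ValueError):
    """Incompatible maps or unsupported grids."""


@dataclass
class EgoEvidence:
    """Per-band probability rows on the 360-degree grid (egocentric or world frame)."""

    pdf: np.ndarray  # (n_bands, 360), rows sum to 1
    band_centres_hz: np.ndarray


@dataclass
class AlloMap:
    """Allocentric spectral-spatial probability map, updated recursively."""

    pdf: np.ndarray  # (n_bands, 360), each row sums to 1, entries > 0
    band_centres_hz: np.ndarray
    n_updates: int = 0

    @classmethod
    def uniform(cls, band_centres_hz: np.ndarray) -> "AlloMap":
        """Flat prior: the all-ones initialization, normalized per band."""
        n_bands = len(band_centres_hz)
        return cls(
            pdf=np.full((n_bands, N_ANGLES), 1.0 / N_ANGLES),
            band_centres_hz=np.asarray(band_centres_hz),
            n_updates=0,
        )

    def copy(self) -> "AlloMap":
        return AlloMap(self.pdf.copy(), self.band_centres_hz, self.n_updates)


# mapping from the 360-degree grid onto the front half-circle [-90, 90]:
# angles behind the interaural axis take the value of their mirror image.
def _front_equivalent_angles() -> np.ndarray:
    grid = np.arange(N_ANGLES, dtype=float)
    front = np.where(grid <= 90, grid, np.where(grid < 270, 180.0 - grid, grid - 360.0))
    return front


_FRONT_ANGLES = _front_equivalent_angles()


def reflect_and_resample(ego: EgoMap) -> np.ndarray:
    """Spline-resample beam energies to 1-degree steps and mirror front to back.

    Returns raw (unnormalized) non-negative values of shape (n_bands, 360).
    The value at grid angle ``a`` behind the interaural axis equals the value
    at its front mirror image ``180 - a``, exactly.
    """
    angles = ego.beam_angles_deg
    if angles.size < 4:
        raise FusionError("spline interpolation needs at least 4 beams")
    out = np.empty((ego.energy.shape[0], N_ANGLES))
    for i, row in enumerate(ego.energy):
        spline = CubicSpline(angles, row)
        vals = spline(_FRONT_ANGLES)
        floor = EPSILON * max(float(row.max()), EPSILON)
        out[i] = np.clip(vals, floor, None)
    return out


def normalize_bands(values: np.ndarray, band_centres_hz: np.ndarray) -> EgoEvidence:
    """Divide each band row by its sum; an all-zero row becomes uniform."""
    values = np.asarray(values, dtype=float)
    sums = values.sum(axis=1, keepdims=True)
    pdf = np.where(sums > 0, values / np.where(sums > 0, sums, 1.0), 1.0 / values.shape[1])
    return EgoEvidence(pdf=pdf, band_centres_hz=np.asarray(band_centres_hz))


def rotate_to_allocentric(evidence: EgoEvidence, head_orientation_deg: float) -> EgoEvidence:
    """Circularly shift rows so egocentric angle a maps to world angle a + head.

    Head orientations are restricted to whole degrees so the rotation is an
    exact circular shift; non-integer orientations are rounded to the grid.
    """
    shift = int(round(head_orientation_deg)) % N_ANGLES
    return EgoEvidence(
        pdf=np.roll(evidence.pdf, shift, axis=1),
        band_centres_hz=evidence.band_centres_hz,
    )


def bayes_update(prior: AlloMap, evidence: EgoEvidence) -> AlloMap:
    """Multiply prior by evidence per (band, angle); renormalize each band row."""
    if prior.pdf.shape != evidence.pdf.shape:
        raise FusionError(
            f"incompatible maps: prior {prior.pdf.shape} vs evidence {evidence.pdf.shape}"
        )
    post = prior.pdf * evidence.pdf
    np.clip(post, EPSILON, None, out=post)
    post /= post.sum(axis=1, keepdims=True)
    return AlloMap(pdf=post, band_centres_hz=prior.band_centres_hz,
                   n_updates=prior.n_updates + 1)


@dataclass
class ScanResult:
    """Final allocentric map plus the map after each head pose."""

    final: AlloMap
    snapshots: list[AlloMap] = field(default_factory=list)
    schedule: list[float] = field(default_factory=list)
    evidence_maps: list[EgoEvidence] = field(default_factory=list)


def frame_ego_map(
    renderer: SceneRenderer,
    bank: GammatoneFilterbank,
    beams: BeamSet,
    head_orientation_deg: float,
    frame_index: int,
    epsp_window_ms: float = DEFAULT_EPSP_WINDOW_MS,
    epsp_sigma_ms: float = DEFAULT_EPSP_SIGMA_MS,
) -> EgoMap:
    """Render one frame and run it through filter bank, EPSP and beamformer."""
    fs = renderer.geometry.sample_rate_hz
    frame = renderer.render_frame(head_orientation_deg, frame_index)
    filtered = bank.process(frame)
    epsp = epsp_transform(filtered, fs, epsp_window_ms, epsp_sigma_ms)
    z = delay_and_sum(epsp, beams)
    return beam_energy(z, bank.band_centres_hz, beams, head_orientation_deg)


def evidence_from_ego(ego: EgoMap) -> EgoEvidence:
    """Reflect, resample, normalize and rotate one egocentric map into the world frame."""
    raw = reflect_and_resample(ego)
    evidence = normalize_bands(raw, ego.band_centres_hz)
    return rotate_to_allocentric(evidence, ego.head_orientation_deg)


def evidence_for_pose(
    renderer: SceneRenderer,
    bank: GammatoneFilterbank,
    beams: BeamSet,
    head_orientation_deg: float,
    frame_indices: range,
    epsp_window_ms: float = DEFAULT_EPSP_WINDOW_MS,
    epsp_sigma_ms: float = DEFAULT_EPSP_SIGMA_MS,
) -> EgoEvidence:
    """Average the egocentric energy maps of several frames at one pose, then
    reflect, resample, normalize and rotate into the world frame."""
    acc = None
    for idx in frame_indices:
        ego = frame_ego_map(
            renderer, bank, beams, head_orientation_deg, idx, epsp_window_ms, epsp_sigma_ms
        )
        acc = ego.energy if acc is None else acc + ego.energy
    mean_ego = EgoMap(
        energy=acc / len(frame_indices),
        band_centres_hz=bank.band_centres_hz,
        beam_angles_deg=beams.angles_deg,
        head_orientation_deg=head_orientation_deg,
        frame_length=renderer.scene.frame_length,
    )
    return evidence_from_ego(mean_ego)


def run_scan(
    scene: SceneSpec,
    geometry: ArrayGeometry,
    filterbank: FilterbankSpec,
    schedule: list[float],
    frames_per_pose: int = 12,
    epsp_window_ms: float = DEFAULT_EPSP_WINDOW_MS,
    epsp_sigma_ms: float = DEFAULT_EPSP_SIGMA_MS,
    fusion_mode: str = "multiply",
) -> ScanResult:
    """Run the full pipeline over a head-rotation schedule.

    For each pose: render ``frames_per_pose`` frames, filter (state carried
    across the whole run), apply the EPSP transform, beamform, and fuse the
    evidence into the allocentric posterior. With ``fusion_mode='multiply'``
    (the default) every incoming frame's evidence map is a separate Bayes
    update, which is what the recursive update rule describes; with
    ``'average'`` the frames at a pose are averaged into a single evidence
    map first, giving each pose equal weight but much weaker convergence.
    Returns the final map and a snapshot after each pose (the first snapshot
    is the pre-rotation map).
    """
    if not schedule:
        raise FusionError("head-pose schedule is empty")
    if fusion_mode not in ("multiply", "average"):
        raise FusionError(f"unknown fusion_mode {fusion_mode!r}")
    needed = len(schedule) * frames_per_pose
    if scene.duration_frames < needed:
        raise FusionError(
            f"scene has {scene.duration_frames} frames but the schedule needs {needed}"
        )
    renderer = SceneRenderer(scene, geometry)
    bank = GammatoneFilterbank(filterbank, geometry.sample_rate_hz, n_channels=2)
    beams = make_beam_set(geometry)
    allo = AlloMap.uniform(bank.band_centres_hz)
    result = ScanResult(final=allo, schedule=list(schedule))
    for pose_idx, head in enumerate(schedule):
        frames = range(pose_idx * frames_per_pose, (pose_idx + 1) * frames_per_pose)
        if fusion_mode == "average":
            evidence = evidence_for_pose(
                renderer, bank, beams, head, frames, epsp_window_ms, epsp_sigma_ms
            )
            allo = bayes_update(allo, evidence)
        else:
            for idx in frames:
                ego = frame_ego_map(
                    renderer, bank, beams, head, idx, epsp_window_ms, epsp_sigma_ms
                )
                evidence = evidence_from_ego(ego)
                allo = bayes_update(allo, evidence)
        result.snapshots.append(allo.copy())
        result.evidence_maps.append(evidence)
    result.final = allo
    return result
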