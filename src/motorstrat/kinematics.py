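"""Reach-to-drop kinematics: filtering, phase segmentation and motor noise.

The measurement chain mirrors a standard upper-limb motion-capture analysis:

1. marker trajectories (4 markers x 3 coordinates, 60 Hz) are low-pass
   filtered with a zero-phase 5th-order Butterworth at 8 Hz;
2. the tangential velocity of the ulnar ("medial") wrist marker defines the
   movement phases: the grasp is the speed minimum between the two principal
   speed peaks (reach and drop sub-movements), and the feedforward/feedback
   boundary is the first deceleration peak after the reach's peak velocity;
3. trial-to-trial repeatability is quantified with multivariate dynamic time
   warping (Euclidean local cost in 12-D, symmetric2 step pattern, endpoints
   forced to match, cumulative cost normalised by N+M);
4. a subject's motor noise on a segment is the median of the 45 pairwise
   normalised DTW distances across the 10 repeat trials.

Higher motor noise = less repeatable movement.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numba import njit
from scipy.signal import butter, filtfilt, find_peaks
from scipy.spatial.distance import cdist

logger = logging.getLogger(__name__)

#: Marker order used in every frames x 12 trajectory matrix.
MARKERS = ("elbow", "wrist_ulnar", "wrist_radial", "hand_dorsum")

#: Marker whose tangential velocity drives segmentation (anatomically medial
#: wrist in standard pose).
VELOCITY_MARKER = "wrist_ulnar"

SEGMENTS = ("whole", "reach_feedforward", "reach_feedback", "drop")


class UnsegmentableTrial(Exception):
    """Raised when no deceleration peak after peak velocity can be found."""


@dataclass
class TrialTrajectory:
    """One pre-segmented trial: movement start to movement end."""

    subject_id: str
    trial: int
    data: np.ndarray  # frames x 12 (MARKERS x x,y,z), mm
    sample_rate: float = 60.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[1] != 12:
            raise ValueError("trajectory must be frames x 12")
        if self.data.shape[0] < 10:
            raise ValueError("trial too short (< 10 frames)")
        if not np.isfinite(self.data).all():
            raise ValueError("trajectory contains missing frames")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    def marker(self, name: str) -> np.ndarray:
        i = MARKERS.index(name)
        return self.data[:, 3 * i : 3 * i + 3]


@dataclass
class VelocityProfile:
    speed: np.ndarray  # mm/s, tangential speed of the segmentation marker
    acceleration: np.ndarray  # mm/s^2, d(speed)/dt
    sample_rate: float


@dataclass
class SegmentBoundaries:
    """Frame indices splitting a trial into phases.

    feedforward = [0, deceleration_peak], feedback = [deceleration_peak,
    reach_end], drop = [reach_end, trial_end].
    """

    deceleration_peak_frame: int
    reach_end_frame: int
    trial_end_frame: int

    def __post_init__(self) -> None:
        if not (0 < self.deceleration_peak_frame < self.reach_end_frame < self.trial_end_frame):
            raise ValueError("boundaries must satisfy 0 < DP < grasp < end")


@dataclass
class MotorNoiseScore:
    subject_id: str
    segment: str
    value: float
    n_trials: int = 10


# ---------------------------------------------------------------------------
# filtering and velocity


def lowpass_filter(traj: TrialTrajectory, cutoff: float = 8.0, order: int = 5) -> TrialTrajectory:
    """Zero-phase (forward-backward) Butterworth low-pass of all 12 channels."""
    if traj.sample_rate <= 2 * cutoff:
        raise ValueError(f"sample rate {traj.sample_rate} must exceed 2x cutoff {cutoff}")
    b, a = butter(order, cutoff, btype="low", fs=traj.sample_rate)
    padlen = 3 * max(len(a), len(b))
    if traj.n_frames <= padlen:
        raise ValueError(f"trial of {traj.n_frames} frames shorter than filter warm-up ({padlen})")
    smoothed = filtfilt(b, a, traj.data, axis=0)
    return TrialTrajectory(traj.subject_id, traj.trial, smoothed, traj.sample_rate)


def tangential_velocity(traj: TrialTrajectory, marker: str = VELOCITY_MARKER) -> VelocityProfile:
    """Speed and its derivative via central differences (one-sided at ends)."""
    pos = traj.marker(marker)
    vel = np.gradient(pos, axis=0) * traj.sample_rate
    speed = np.linalg.norm(vel, axis=1)
    accel = np.gradient(speed) * traj.sample_rate
    return VelocityProfile(speed=speed, acceleration=accel, sample_rate=traj.sample_rate)


# ---------------------------------------------------------------------------
# phase segmentation

#: Minimum separation between the two principal speed peaks (reach, drop).
_PRINCIPAL_PEAK_SEPARATION_S = 0.25

#: Deceleration peaks below this fraction of the maximum deceleration are
#: treated as residual-noise micro-peaks and ignored.
_DP_PROMINENCE_FRACTION = 0.05


def segment_phases(vel: VelocityProfile, traj: TrialTrajectory) -> SegmentBoundaries:
    """Locate grasp (reach/drop split) and the deceleration peak.

    Raises
    ------
    UnsegmentableTrial
        If the speed profile has no two principal peaks, or no deceleration
        peak of sufficient prominence after the reach's peak velocity.
    """
    speed = vel.speed
    min_sep = max(1, int(round(_PRINCIPAL_PEAK_SEPARATION_S * vel.sample_rate)))
    peaks, props = find_peaks(speed, distance=min_sep, height=0.0)
    if len(peaks) < 2:
        raise UnsegmentableTrial(f"{traj.subject_id} trial {traj.trial}: fewer than two speed peaks")
    # two largest local maxima = reach and drop sub-movements
    top2 = peaks[np.argsort(props["peak_heights"])[-2:]]
    reach_peak, drop_peak = int(top2.min()), int(top2.max())
    reach_end = reach_peak + int(np.argmin(speed[reach_peak : drop_peak + 1]))

    # deceleration = -d(speed)/dt within the reach, after peak speed
    reach_speed = speed[: reach_end + 1]
    vmax = int(np.argmax(reach_speed))
    decel = -vel.acceleration[: reach_end + 1]
    max_dec = decel[vmax:].max(initial=0.0)
    if max_dec <= 0:
        raise UnsegmentableTrial(f"{traj.subject_id} trial {traj.trial}: no deceleration after peak speed")
    dp_candidates, _ = find_peaks(decel, prominence=_DP_PROMINENCE_FRACTION * max_dec)
    dp_candidates = dp_candidates[dp_candidates > vmax]
    if len(dp_candidates) == 0:
        raise UnsegmentableTrial(f"{traj.subject_id} trial {traj.trial}: no qualifying deceleration peak")
    dp = int(dp_candidates[0])
    return SegmentBoundaries(dp, reach_end, traj.n_frames - 1)


def extract_segment(traj: TrialTrajectory, bounds: SegmentBoundaries, segment: str) -> np.ndarray:
    """Slice the frames x 12 matrix for one named phase (bounds inclusive)."""
    if segment == "whole":
        return traj.data
    if segment == "reach_feedforward":
        return traj.data[: bounds.deceleration_peak_frame + 1]
    if segment == "reach_feedback":
        return traj.data[bounds.deceleration_peak_frame : bounds.reach_end_frame + 1]
    if segment == "drop":
        return traj.data[bounds.reach_end_frame :]
    raise ValueError(f"unknown segment {segment!r}; expected one of {SEGMENTS}")


# ---------------------------------------------------------------------------
# dynamic time warping


@njit(cache=False)
def _accumulate_symmetric2(local: np.ndarray) -> float:
    """Cumulative DTW cost under the symmetric2 step pattern, closed ends.

    D[0,0] = d(0,0); diagonal steps add 2*d(i,j), horizontal/vertical steps
    add d(i,j); the returned value is D[N-1, M-1] (both endpoints matched).
    """
    n, m = local.shape
    D = np.empty((n, m))
    D[0, 0] = local[0, 0]
    for i in range(1, n):
        D[i, 0] = D[i - 1, 0] + local[i, 0]
    for j in range(1, m):
        D[0, j] = D[0, j - 1] + local[0, j]
    for i in range(1, n):
        for j in range(1, m):
            best = D[i - 1, j - 1] + 2.0 * local[i, j]
            up = D[i - 1, j] + local[i, j]
            if up < best:
                best = up
            left = D[i, j - 1] + local[i, j]
            if left < best:
                best = left
            D[i, j] = best
    return D[n - 1, m - 1]


def dtw_distance(a: np.ndarray, b: np.ndarray, normalize: bool = True) -> float:
    """Multivariate DTW distance between two frames x d matrices.

    Local cost is the Euclidean distance between frames; the warping path is
    monotone with both endpoints matched; symmetric2 weighting (diagonal
    counts its local cost twice) makes the cumulative cost comparable to the
    summed series lengths, so the normalised distance is cost / (N + M).
    """
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    if a.shape[0] == 0 or b.shape[0] == 0:
        raise ValueError("empty segment")
    if a.shape[1] != b.shape[1]:
        raise ValueError("series dimensionality differs")
    local = cdist(a, b)
    cost = float(_accumulate_symmetric2(local))
    if normalize:
        return cost / (a.shape[0] + b.shape[0])
    return cost


def pairwise_dtw_matrix(segments: Sequence[np.ndarray]) -> np.ndarray:
    """Symmetric matrix of normalised DTW distances across trials."""
    n = len(segments)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = dtw_distance(segments[i], segments[j])
    return mat


def motor_noise(
    segments: Sequence[np.ndarray],
    subject_id: str = "",
    segment: str = "whole",
    n_required: int = 10,
) -> MotorNoiseScore:
    """Median pairwise normalised DTW distance across repeat trials.

    Subjects who did not complete all ``n_required`` trials are excluded
    rather than imputed.
    """
    if len(segments) < n_required:
        raise ValueError(
            f"subject {subject_id!r} completed {len(segments)} of {n_required} trials; excluded"
        )
    mat = pairwise_dtw_matrix(segments)
    iu = np.triu_indices(len(segments), k=1)
    return MotorNoiseScore(subject_id, segment, float(np.median(mat[iu])), len(segments))


# ---------------------------------------------------------------------------
# subject-level scoring


@dataclass
class SubjectNoiseResult:
    subject_id: str
    scores: dict = field(default_factory=dict)  # segment -> value
    excluded_segments: dict = field(default_factory=dict)  # segment -> reason


def score_subject(
    trials: Sequence[TrialTrajectory],
    segments: Sequence[str] = SEGMENTS,
    cutoff: float = 8.0,
    n_required: int = 10,
) -> SubjectNoiseResult:
    """Filter, segment and score one subject's trials on each named segment.

    The whole-movement score only needs complete trials; phase scores
    additionally need every trial to be segmentable — a subject with any
    unsegmentable trial is flagged and excluded from phase analysis only.
    """
    if not trials:
        raise ValueError("no trials")
    subject = trials[0].subject_id
    result = SubjectNoiseResult(subject_id=subject)
    if len(trials) < n_required:
        reason = f"only {len(trials)} of {n_required} trials"
        logger.warning("subject %s excluded: %s", subject, reason)
        result.excluded_segments = {s: reason for s in segments}
        return result

    filtered = [lowpass_filter(t, cutoff=cutoff) for t in trials]
    bounds: list[SegmentBoundaries | None] = []
    for t in filtered:
        try:
            bounds.append(segment_phases(tangential_velocity(t), t))
        except UnsegmentableTrial as exc:
            logger.warning("unsegmentable: %s", exc)
            bounds.append(None)
    phases_ok = all(b is not None for b in bounds)

    for seg in segments:
        if seg != "whole" and not phases_ok:
            bad = sum(b is None for b in bounds)
            result.excluded_segments[seg] = f"{bad} unsegmentable trial(s)"
            continue
        mats = [
            t.data if seg == "whole" else extract_segment(t, b, seg)
            for t, b in zip(filtered, bounds)
        ]
        result.scores[seg] = motor_noise(mats, subject, seg, n_required).value
    return result
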