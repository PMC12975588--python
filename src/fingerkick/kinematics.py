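"""From raw marker trajectories to the ten kinematic parameters.

Processing chain for one go trial:

1. zero-phase low-pass filtering of the 3-D positions (2nd-order Butterworth
   at 10 Hz, applied forward and backward — effective 4th order, no lag);
2. tangential speed = ‖central-difference derivative‖, and its derivative;
3. event detection: onset (speed above 5 mm/s sustained for 500 ms), kick
   (ball-marker speed threshold, or minimum finger-target distance as a
   fallback), offset (speed back below 5 mm/s after the kick);
4. the parameters: MH (peak vertical position), MDevLeft/MDevRight (signed
   extrema of the horizontal-plane deviation from the start-target line),
   MV (peak speed), MDec (peak deceleration after the speed peak), MT
   (onset-to-offset duration in ms), and the four event times normalized
   to MT.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .errors import DataError, NoMovementError
from .types import FilteredTraces, KinematicRecord, MovementSegment, TrialTrajectory

logger = logging.getLogger(__name__)

DEFAULT_CUTOFF_HZ = 10.0
DEFAULT_V_THRESH = 5.0       # mm/s
DEFAULT_PERSIST_S = 0.5      # s
KICK_PERSIST_SAMPLES = 3


@dataclass
class KinematicsOptions:
    cutoff_hz: float = DEFAULT_CUTOFF_HZ
    v_thresh: float = DEFAULT_V_THRESH
    persist_s: float = DEFAULT_PERSIST_S
    filter_order: int = 2
    # apparatus-calibrated start/target (mm); None = estimate from the data
    start_mm: tuple[float, float, float] | None = None
    target_mm: tuple[float, float, float] | None = None


def lowpass_filter(
    pos: np.ndarray, fs: float, cutoff: float = DEFAULT_CUTOFF_HZ, order: int = 2
) -> np.ndarray:
    """Zero-phase Butterworth low-pass (dual pass, reflective padding).

    DC is preserved exactly; features are not shifted in time.
    """
    if fs <= 2 * cutoff:
        raise DataError(f"fs={fs} must exceed twice the cutoff {cutoff}")
    pos = np.asarray(pos, dtype=float)
    b, a = signal.butter(order, cutoff / (fs / 2.0))
    padlen = 3 * max(len(a), len(b))
    if pos.shape[0] <= padlen:
        raise DataError(
            f"trace of {pos.shape[0]} samples too short for zero-phase filtering "
            f"(needs > {padlen})"
        )
    return signal.filtfilt(b, a, pos, axis=0, padtype="even")


def differentiate(pos: np.ndarray, fs: float) -> FilteredTraces:
    """Tangential speed and its signed derivative from filtered positions.

    Central differences in the interior, one-sided at the endpoints
    (``np.gradient`` semantics).
    """
    pos = np.asarray(pos, dtype=float)
    if pos.shape[0] < 3:
        raise DataError("need at least 3 samples to differentiate")
    vel = np.gradient(pos, 1.0 / fs, axis=0)
    speed = np.linalg.norm(vel, axis=1)
    accel = np.gradient(speed, 1.0 / fs)
    return FilteredTraces(pos=pos, speed=speed, accel=accel, fs=fs)


def _first_sustained_crossing(above: np.ndarray, n_required: int) -> int | None:
    """First index starting a run of >= n_required consecutive True values."""
    if above.size == 0:
        return None
    idx = np.flatnonzero(above)
    if idx.size == 0:
        return None
    # run-length encode the True positions
    splits = np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1)
    for run in splits:
        if run.size >= n_required:
            return int(run[0])
    return None


def detect_onset_offset(
    traces: FilteredTraces,
    ball_xyz: np.ndarray | None = None,
    target: np.ndarray | None = None,
    v_thresh: float = DEFAULT_V_THRESH,
    persist_s: float = DEFAULT_PERSIST_S,
    trial_id: str | None = None,
) -> MovementSegment:
    """Movement onset, kick, and offset from the speed trace.

    Onset: first sample whose speed exceeds ``v_thresh`` and stays above it
    for at least ``persist_s`` (strict inequality). Kick: ball-marker speed
    exceeding the same threshold for 3 consecutive samples; without ball
    data, the sample of minimum finger-target distance after onset; without
    either, the speed peak. Offset: first sample at/after the kick where
    finger speed drops below ``v_thresh``; if none, the last sample (with a
    warning).
    """
    fs = traces.fs
    speed = traces.speed
    n_req = math.ceil(persist_s * fs)
    onset = _first_sustained_crossing(speed > v_thresh, n_req)
    if onset is None:
        raise NoMovementError(trial_id)

    kick: int | None = None
    if ball_xyz is not None:
        ball_f = lowpass_filter(np.asarray(ball_xyz, float), fs)
        ball_speed = np.linalg.norm(np.gradient(ball_f, 1.0 / fs, axis=0), axis=1)
        rel = _first_sustained_crossing(ball_speed[onset + 1:] > v_thresh, KICK_PERSIST_SAMPLES)
        if rel is not None:
            kick = onset + 1 + rel
    if kick is None and target is not None:
        dist = np.linalg.norm(traces.pos[onset + 1:] - np.asarray(target, float), axis=1)
        kick = onset + 1 + int(np.argmin(dist))
    search_from = kick if kick is not None else onset + 1 + int(np.argmax(speed[onset + 1:]))

    below = np.flatnonzero(speed[search_from:] < v_thresh)
    if below.size:
        offset = search_from + int(below[0])
    else:
        offset = speed.size - 1
        logger.warning(
            "trial %s: speed never dropped below %.1f mm/s after the kick; "
            "offset set to last sample", trial_id, v_thresh
        )
    if kick is not None and kick > offset:
        kick = offset
    return MovementSegment(onset_idx=onset, offset_idx=offset, kick_idx=kick, fs=fs)


def lateral_deviation(
    pos: np.ndarray,
    segment: MovementSegment,
    start: np.ndarray,
    target: np.ndarray,
) -> tuple[float, float, int, int]:
    """Signed horizontal-plane deviation from the start-target line.

    Deviation is perpendicular distance in the X-Z plane, negative leftward.
    Returns ``(MDevLeft, MDevRight, idx_left, idx_right)`` with absolute
    sample indices. A side never visited contributes 0; its index is the
    segment sample closest to that side.
    """
    start = np.asarray(start, float)
    target = np.asarray(target, float)
    u = np.array([target[0] - start[0], target[2] - start[2]])
    norm = np.linalg.norm(u)
    if norm < 1e-9:
        raise DataError("degenerate start-target line (start == target in horizontal plane)")
    u = u / norm
    seg = pos[segment.onset_idx : segment.offset_idx + 1]
    dx = seg[:, 0] - start[0]
    dz = seg[:, 2] - start[2]
    signed = u[1] * dx - u[0] * dz  # leftward (−X when the line runs along +Z) is negative
    i_left = int(np.argmin(signed))
    i_right = int(np.argmax(signed))
    mdev_left = float(min(signed[i_left], 0.0))
    mdev_right = float(max(signed[i_right], 0.0))
    return mdev_left, mdev_right, segment.onset_idx + i_left, segment.onset_idx + i_right


def estimate_start_position(pos_filtered: np.ndarray, onset_idx: int) -> np.ndarray:
    """Start position = mean filtered index position over the pre-onset rest."""
    if onset_idx > 0:
        return pos_filtered[:onset_idx].mean(axis=0)
    return pos_filtered[0].copy()


def extract_parameters(
    traj: TrialTrajectory,
    start: np.ndarray | None = None,
    target: np.ndarray | None = None,
    options: KinematicsOptions | None = None,
) -> KinematicRecord:
    """Compute the full :class:`KinematicRecord` for one go trial.

    ``start`` defaults to the mean pre-onset index position; ``target``
    defaults to the ball's initial position projected to the start height.
    """
    opts = options or KinematicsOptions()
    if start is None and opts.start_mm is not None:
        start = np.asarray(opts.start_mm, float)
    if target is None and opts.target_mm is not None:
        target = np.asarray(opts.target_mm, float)
    pos_f = lowpass_filter(traj.index_xyz, traj.fs, opts.cutoff_hz, opts.filter_order)
    traces = differentiate(pos_f, traj.fs)

    # provisional target for the kick fallback when the ball marker is absent
    provisional_target = target
    segment = detect_onset_offset(
        traces,
        ball_xyz=traj.ball_xyz,
        target=provisional_target,
        v_thresh=opts.v_thresh,
        persist_s=opts.persist_s,
        trial_id=traj.trial_id,
    )

    if start is None:
        start = estimate_start_position(pos_f, segment.onset_idx)
    if target is None:
        if traj.ball_xyz is None:
            raise DataError(
                f"trial {traj.trial_id!r}: no ball marker and no explicit target"
            )
        # ball rest position, averaged over the pre-onset interval to beat noise
        rest_end = max(segment.onset_idx, 1)
        target = traj.ball_xyz[:rest_end].mean(axis=0)
        target[1] = start[1]  # project to start height: the line is horizontal

    on, off = segment.onset_idx, segment.offset_idx
    sl = slice(on, off + 1)

    mh = float(np.max(pos_f[sl, 1]))
    i_mv = on + int(np.argmax(traces.speed[sl]))
    mv = float(traces.speed[i_mv])
    # deceleration phase only: from the speed peak to offset
    dec_slice = slice(i_mv, off + 1)
    i_mdec = i_mv + int(np.argmin(traces.accel[dec_slice]))
    mdec = float(abs(min(traces.accel[i_mdec], 0.0)))
    mdev_left, mdev_right, i_left, i_right = lateral_deviation(pos_f, segment, start, target)

    duration = off - on
    mt_ms = duration / traj.fs * 1000.0

    def t_norm(idx: int) -> float:
        return (idx - on) / duration

    return KinematicRecord(
        participant_id=traj.participant_id,
        trial_id=traj.trial_id,
        group=traj.group,
        stimulus=traj.stimulus,
        MH=mh,
        MDevRight=mdev_right,
        MDevLeft=mdev_left,
        MV=mv,
        MDec=mdec,
        MT=mt_ms,
        TMV=t_norm(i_mv),
        TMDec=t_norm(i_mdec),
        TMDevRight=t_norm(i_right),
        TMDevLeft=t_norm(i_left),
        segment=segment,
    )
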