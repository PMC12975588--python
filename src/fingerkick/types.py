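"""Core domain types shared across the pipeline.

Coordinate frame convention (all modules): positions in mm with
X lateral (leftward negative), Y vertical (positive up), Z pointing from the
start position toward the target. Time in seconds, sampled at ``fs`` Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DataError, ValidationError

#: The ten kinematic parameters, in canonical order.
PARAMETER_NAMES: tuple[str, ...] = (
    "MH",
    "MDevRight",
    "MDevLeft",
    "MV",
    "MDec",
    "MT",
    "TMV",
    "TMDec",
    "TMDevRight",
    "TMDevLeft",
)

GROUPS: tuple[str, str] = ("preschool", "school")

#: Stimulus conditions; the first three are go conditions, dots5_nogo is the
#: response-inhibition condition and never enters the kinematic analysis.
STIMULI: tuple[str, ...] = ("baseline", "dots2", "dots8", "dots5_nogo")
GO_STIMULI: tuple[str, ...] = ("baseline", "dots2", "dots8")


@dataclass
class TrialTrajectory:
    """One trial's marker time series plus its design labels.

    ``index_xyz`` is the fingertip marker, ``ball_xyz`` the marker on the
    ball (optional: kick detection falls back to a distance criterion).
    """

    participant_id: str
    trial_id: str
    group: str
    stimulus: str
    fs: float
    t: np.ndarray
    index_xyz: np.ndarray
    ball_xyz: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.index_xyz = np.atleast_2d(np.asarray(self.index_xyz, dtype=float))
        if self.ball_xyz is not None:
            self.ball_xyz = np.atleast_2d(np.asarray(self.ball_xyz, dtype=float))
        self.validate()

    def validate(self) -> None:
        if self.fs <= 0:
            raise ValidationError(f"fs must be positive, got {self.fs}")
        if self.group not in GROUPS:
            raise ValidationError(f"unknown group {self.group!r}")
        if self.stimulus not in STIMULI:
            raise ValidationError(f"unknown stimulus {self.stimulus!r}")
        if self.index_xyz.shape != (self.t.size, 3):
            raise DataError(
                f"trial {self.trial_id!r}: index_xyz shape {self.index_xyz.shape} "
                f"does not match {self.t.size} time samples"
            )
        if self.ball_xyz is not None and self.ball_xyz.shape != (self.t.size, 3):
            raise DataError(f"trial {self.trial_id!r}: ball_xyz length mismatch")
        if self.t.size >= 2:
            dt = np.diff(self.t)
            if np.any(dt <= 0):
                raise DataError(f"trial {self.trial_id!r}: time vector not strictly increasing")
            if np.any(np.abs(dt - 1.0 / self.fs) > 1e-9 + 1e-9 * dt):
                raise DataError(
                    f"trial {self.trial_id!r}: time spacing inconsistent with fs={self.fs}"
                )

    @property
    def n_samples(self) -> int:
        return self.t.size


@dataclass
class MathScores:
    """Enumeration / addition / subtraction sub-scores and their composite.

    ET is the enumeration score, already reverse-coded by its definition
    (20 s minus the time taken, floored at 0), so the composite is a plain
    sum: MPI = ET + ACA + SCA, range 0-60.
    """

    ET: int
    ACA: int
    SCA: int
    MPI: int | None = None

    def __post_init__(self) -> None:
        for name in ("ET", "ACA", "SCA"):
            v = getattr(self, name)
            if not (0 <= v <= 20):
                raise ValidationError(f"{name}={v} outside range 0-20")
        if self.MPI is not None and not (0 <= self.MPI <= 60):
            raise ValidationError(f"MPI={self.MPI} outside range 0-60")


@dataclass
class ParticipantRecord:
    participant_id: str
    age_months: int
    group: str
    handedness: str = "right"
    math_scores: MathScores | None = None
    formal_math_education: bool | None = None

    def __post_init__(self) -> None:
        if self.age_months <= 0:
            raise ValidationError(f"age_months must be positive, got {self.age_months}")
        if self.group not in GROUPS:
            raise ValidationError(f"unknown group {self.group!r}")
        if self.handedness not in ("right", "left", "unknown"):
            raise ValidationError(f"unknown handedness {self.handedness!r}")


@dataclass
class FilteredTraces:
    """Low-pass filtered positions with tangential speed and its derivative."""

    pos: np.ndarray      # (n, 3) mm
    speed: np.ndarray    # (n,) mm/s, >= 0
    accel: np.ndarray    # (n,) mm/s^2, signed d(speed)/dt
    fs: float


@dataclass
class MovementSegment:
    """Sample indices of the detected movement and its duration."""

    onset_idx: int
    offset_idx: int
    kick_idx: int | None
    fs: float

    def __post_init__(self) -> None:
        if not self.onset_idx < self.offset_idx:
            raise ValidationError(
                f"onset {self.onset_idx} must precede offset {self.offset_idx}"
            )
        if self.kick_idx is not None and not (self.onset_idx < self.kick_idx <= self.offset_idx):
            raise ValidationError("kick_idx outside (onset, offset]")

    @property
    def mt_s(self) -> float:
        return (self.offset_idx - self.onset_idx) / self.fs


@dataclass
class KinematicRecord:
    """The ten kinematic parameters of one trial — the unit entering statistics.

    Spatial parameters in mm, MV in mm/s, MDec in mm/s^2 (absolute value),
    MT in ms, and the four event times as fractions of MT in [0, 1].
    """

    participant_id: str
    trial_id: str
    group: str
    stimulus: str
    MH: float
    MDevRight: float
    MDevLeft: float
    MV: float
    MDec: float
    MT: float
    TMV: float
    TMDec: float
    TMDevRight: float
    TMDevLeft: float
    segment: MovementSegment | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.MV <= 0:
            raise ValidationError(f"MV must be positive, got {self.MV}")
        if self.MT <= 0:
            raise ValidationError(f"MT must be positive, got {self.MT}")
        if self.MDec < 0:
            raise ValidationError("MDec is an absolute value, must be >= 0")
        if not (self.MDevLeft <= 0.0 <= self.MDevRight):
            raise ValidationError("require MDevLeft <= 0 <= MDevRight")
        for name in ("TMV", "TMDec", "TMDevRight", "TMDevLeft"):
            v = getattr(self, name)
            if not (-1e-12 <= v <= 1 + 1e-12):
                raise ValidationError(f"{name}={v} outside [0, 1]")

    def values(self) -> dict[str, float]:
        return {name: float(getattr(self, name)) for name in PARAMETER_NAMES}
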