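"""Seeded synthetic finger-kick experiments with analytic ground truth.

The generator emulates the study design: 7 preschool + 14 school-age
children, three go conditions (baseline picture, 2-dot and 8-dot arrays),
10 trials per condition at 70 Hz, with group and condition effects injected
on maximum trajectory height (MH), leftward deviation (MDevLeft), and peak
speed (MV).

A trial is a rest phase, a minimum-jerk transport toward the ball/goal, and
a rest tail. Writing τ for normalized movement time and s(τ) = 10τ³ − 15τ⁴
+ 6τ⁵ for minimum-jerk progress, the fingertip moves

    x(τ) = d · sin(π s(τ))           (lateral bow, d < 0 = leftward)
    y(τ) = y₀ + h · sin(π s(τ))      (vertical arc over the ball)
    z(τ) = A · s(τ)                  (transport toward the goal)

so the injected extremes are exactly d and y₀ + h. Parametrizing the arcs
by path progress (rather than raw time) keeps velocity zero at both
movement boundaries, which the onset/offset detector assumes. Marker noise
is temporally correlated Gaussian noise (white noise coloured below
~1.5 Hz, SD ``marker_noise_mm`` per axis), emulating the slowly varying
reconstruction error of an optical system; rest-phase speeds then stay
below the 5 mm/s onset threshold.

Every trial carries a :class:`TrialTruth` with threshold-based event
samples and all ten parameters evaluated on the noise-free analytic
profile, so recovery tests never re-derive expected values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal, stats

from .errors import ValidationError
from .types import GO_STIMULI, PARAMETER_NAMES, MathScores, ParticipantRecord, TrialTrajectory

V_THRESH = 5.0  # mm/s, shared with event detection

# Pooled per-condition summaries (mean, SD) of the ten parameters that the
# defaults reproduce; the 2-dot condition is the base cell.
_BASE_MEAN = {
    "MH": 73.646, "MDevRight": 2.333, "MDevLeft": -4.547, "MV": 224.495,
    "MDec": 3767.097, "MT": 458.218, "TMV": 0.614, "TMDec": 0.673,
    "TMDevRight": 0.443, "TMDevLeft": 0.543,
}
_BASE_SD = {
    "MH": 4.820, "MDevRight": 2.256, "MDevLeft": 4.077, "MV": 101.091,
    "MDec": 2183.816, "MT": 210.510, "TMV": 0.260, "TMDec": 0.258,
    "TMDevRight": 0.265, "TMDevLeft": 0.227,
}
# additive condition offsets relative to the 2-dot cell (gaussian-scale params)
_COND_OFFSETS = {
    "MH": {"dots2": 0.0, "dots8": 0.020, "baseline": 1.042},
    "MDevLeft": {"dots2": 0.0, "dots8": -0.397, "baseline": -0.835},
    "MDevRight": {"dots2": 0.0, "dots8": 0.214, "baseline": 0.579},
    "TMV": {"dots2": 0.0, "dots8": 0.019, "baseline": 0.006},
    "TMDec": {"dots2": 0.0, "dots8": 0.010, "baseline": 0.017},
    "TMDevRight": {"dots2": 0.0, "dots8": 0.056, "baseline": 0.068},
    "TMDevLeft": {"dots2": 0.0, "dots8": 0.018, "baseline": 0.006},
}
# multiplicative condition factors (positive, log-link params)
_COND_SCALES = {
    "MV": {"dots2": 1.0, "dots8": 1.024, "baseline": 1.105},
    "MDec": {"dots2": 1.0, "dots8": 1.030, "baseline": 1.123},
    "MT": {"dots2": 1.0, "dots8": 1.024, "baseline": 0.968},
}

_GAUSSIAN_PARAMS = ("MH", "MDevRight", "MDevLeft")
_POSITIVE_PARAMS = ("MV", "MDec", "MT")
_TIME_PARAMS = ("TMV", "TMDec", "TMDevRight", "TMDevLeft")

#: default family per parameter for direct table generation
DEFAULT_FAMILY_MAP = {
    "MH": "student_t", "MDevLeft": "student_t", "MDevRight": "gaussian",
    "MV": "gamma", "MDec": "gamma", "MT": "gamma",
    "TMV": "truncnorm", "TMDec": "truncnorm",
    "TMDevRight": "truncnorm", "TMDevLeft": "truncnorm",
}


@dataclass
class EffectConfig:
    """Study design and injected effects; defaults ARE the study conditions."""

    n_preschool: int = 7
    n_school: int = 14
    trials_per_condition: int = 10
    fs: float = 70.0
    mh_group_shift: float = 6.58          # mm, school minus preschool
    mdevleft_preschool_dots2_shift: float = -2.24  # mm, extra leftward bias
    mv_condition_scale: dict = field(
        default_factory=lambda: dict(_COND_SCALES["MV"])
    )
    sigma_participant: dict = field(default_factory=dict)
    sigma_trial: dict = field(default_factory=dict)
    marker_noise_mm: float = 0.2
    seed: int = 0
    t_nu: float = 8.0                     # df of the t-family trial noise
    include_nogo: bool = False
    family_map: dict = field(default_factory=lambda: dict(DEFAULT_FAMILY_MAP))
    start_height_mm: float = 62.0         # resting fingertip marker height
    # trajectory realizations need movements long enough that the speed stays
    # above the onset threshold for the full 500 ms persistence window; the
    # printed MT distribution is reproduced only by the direct
    # parameter-table generator
    traj_mt_median_s: float = 0.85
    traj_mt_sigma_log: float = 0.14
    traj_mt_min_s: float = 0.62

    def __post_init__(self) -> None:
        if min(self.n_preschool, self.n_school, self.trials_per_condition) < 1:
            raise ValidationError("participant and trial counts must be >= 1")
        if self.marker_noise_mm < 0:
            raise ValidationError("marker_noise_mm must be >= 0")
        # pooled SDs split evenly between participant and trial levels
        for name in PARAMETER_NAMES:
            if name in _GAUSSIAN_PARAMS or name in _TIME_PARAMS:
                split = _BASE_SD[name] / math.sqrt(2.0)
            else:  # log-link parameters: split the squared CV
                cv2 = (_BASE_SD[name] / _BASE_MEAN[name]) ** 2
                split = math.sqrt(math.log1p(cv2 / 2.0))
            self.sigma_participant.setdefault(name, split)
            self.sigma_trial.setdefault(name, split)
        if any(s < 0 for s in self.sigma_participant.values()):
            raise ValidationError("sigma_participant entries must be >= 0")
        if any(s < 0 for s in self.sigma_trial.values()):
            raise ValidationError("sigma_trial entries must be >= 0")

    @classmethod
    def null(cls, **overrides) -> "EffectConfig":
        """All Group/Stimulus effects zero (for type-I calibration)."""
        cfg = cls(
            mh_group_shift=0.0,
            mdevleft_preschool_dots2_shift=0.0,
            mv_condition_scale={c: 1.0 for c in GO_STIMULI},
            **overrides,
        )
        cfg._zero_condition_effects = True
        return cfg

    def cell_mean(self, param: str, group: str, stimulus: str) -> float:
        """Generating cell mean on the model's link scale (log for positive params)."""
        zero = getattr(self, "_zero_condition_effects", False)
        if param in _POSITIVE_PARAMS:
            mu = math.log(_BASE_MEAN[param])
            if not zero:
                if param == "MV":
                    mu += math.log(self.mv_condition_scale.get(stimulus, 1.0))
                else:
                    mu += math.log(_COND_SCALES[param][stimulus])
            return mu
        mu = _BASE_MEAN[param]
        if param == "MH":
            # the group shift is carried entirely by the school group
            mu -= self.mh_group_shift * self.n_school / (self.n_school + self.n_preschool)
            if group == "school":
                mu += self.mh_group_shift
        if not zero:
            mu += _COND_OFFSETS.get(param, {}).get(stimulus, 0.0)
            if param == "MDevLeft" and group == "preschool" and stimulus == "dots2":
                mu += self.mdevleft_preschool_dots2_shift
        return mu

    def true_effects(self, param: str) -> dict[str, float]:
        """Fixed-effect vector implied by the cell means (treatment coding,
        preschool / dots2 reference)."""
        mu = lambda g, s: self.cell_mean(param, g, s)
        eff = {"(Intercept)": mu("preschool", "dots2"),
               "group[school]": mu("school", "dots2") - mu("preschool", "dots2")}
        for s in ("dots8", "baseline"):
            eff[f"stimulus[{s}]"] = mu("preschool", s) - mu("preschool", "dots2")
            eff[f"group[school]:stimulus[{s}]"] = (
                mu("school", s) - mu("school", "dots2") - eff[f"stimulus[{s}]"]
            )
        return eff


@dataclass
class TrialTruth:
    """Noise-free ground truth for one simulated trial."""

    onset_idx: int
    offset_idx: int
    kick_idx: int | None
    values: dict[str, float]


@dataclass
class GroundTruth:
    config: EffectConfig
    trials: dict[str, TrialTruth] = field(default_factory=dict)
    effects: dict[str, dict[str, float]] = field(default_factory=dict)
    participant_intercepts: dict[str, dict[str, float]] = field(default_factory=dict)


def minimum_jerk(tau: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Progress s(τ) and its derivative s'(τ) of the minimum-jerk profile."""
    tau = np.asarray(tau, float)
    s = 10 * tau**3 - 15 * tau**4 + 6 * tau**5
    ds = 30 * tau**2 - 60 * tau**3 + 30 * tau**4
    return s, ds


_NOISE_BW_HZ = 1.5


def _noise_gain(fs: float) -> float:
    """Variance gain of the dual-pass colouring filter (so output SD is exact)."""
    b, a = signal.butter(2, _NOISE_BW_HZ / (fs / 2.0))
    w, h = signal.freqz(b, a, worN=4096)
    mag4 = np.abs(h) ** 4  # forward+backward pass
    return float(np.sqrt(np.trapezoid(mag4, w) / np.pi))


def correlated_noise(rng: np.random.Generator, n: int, sd: float, fs: float) -> np.ndarray:
    """(n, 3) low-frequency Gaussian marker noise with per-axis SD ``sd``."""
    if sd == 0.0:
        return np.zeros((n, 3))
    b, a = signal.butter(2, _NOISE_BW_HZ / (fs / 2.0))
    white = rng.normal(size=(n, 3))
    coloured = signal.filtfilt(b, a, white, axis=0, padtype="even")
    return coloured * (sd / _noise_gain(fs))


@dataclass
class TrialShape:
    """Injected deterministic knobs of one trial."""

    mh: float          # target maximum height (absolute Y, mm)
    dev: float         # lateral bow amplitude (mm, negative = leftward)
    mt_nominal: float  # nominal movement duration (s)
    mv: float          # target peak transport speed (mm/s)


def _analytic_truth(shape: TrialShape, start_y: float, ball_z: float,
                    fs: float, move_start_idx: int, n_move: int) -> TrialTruth:
    """Evaluate events and all ten parameters on the noise-free profile."""
    A = shape.mv * shape.mt_nominal / 1.875
    h = shape.mh - start_y
    d = shape.dev
    mt = shape.mt_nominal
    # dense oversampled grid of the movement
    dense = 20
    tau = np.linspace(0.0, 1.0, n_move * dense + 1)
    s, ds = minimum_jerk(tau)
    arc = np.pi * np.cos(np.pi * s)
    speed = (ds / mt) * np.sqrt(A**2 + arc**2 * (h**2 + d**2))
    t = tau * mt  # seconds since movement start
    accel = np.gradient(speed, t)

    above = speed > V_THRESH
    if not above.any():
        raise ValidationError("movement never exceeds the onset threshold")
    i_on = int(np.argmax(above))
    i_peak = int(np.argmax(speed))
    z = A * s
    contact = z >= ball_z
    i_kick = int(np.argmax(contact)) if contact.any() else None
    search = i_kick if i_kick is not None else i_peak
    rest = np.flatnonzero(speed[search:] < V_THRESH)
    i_off = search + int(rest[0]) if rest.size else speed.size - 1

    t_on, t_off = t[i_on], t[i_off]
    dur = t_off - t_on

    def tnorm(i: int) -> float:
        return float(np.clip((t[i] - t_on) / dur, 0.0, 1.0))

    seg = slice(i_on, i_off + 1)
    x = d * np.sin(np.pi * s)
    y = start_y + h * np.sin(np.pi * s)
    i_mdec = i_peak + int(np.argmin(accel[i_peak : i_off + 1]))
    i_left = i_on + int(np.argmin(x[seg]))
    i_right = i_on + int(np.argmax(x[seg]))
    values = {
        "MH": float(np.max(y[seg])),
        "MDevLeft": float(min(np.min(x[seg]), 0.0)),
        "MDevRight": float(max(np.max(x[seg]), 0.0)),
        "MV": float(speed[i_peak]),
        "MDec": float(abs(min(accel[i_mdec], 0.0))),
        "MT": dur * 1000.0,
        "TMV": tnorm(i_peak),
        "TMDec": tnorm(i_mdec),
        "TMDevLeft": tnorm(i_left),
        "TMDevRight": tnorm(i_right),
    }
    # events are "first sample satisfying the condition", hence ceil
    to_sample = lambda i: move_start_idx + int(math.ceil(t[i] * fs - 1e-9))
    kick_idx = to_sample(i_kick) if i_kick is not None else None
    return TrialTruth(
        onset_idx=to_sample(i_on),
        offset_idx=to_sample(i_off),
        kick_idx=kick_idx,
        values=values,
    )


def simulate_trial(
    shape: TrialShape,
    participant_id: str = "P01",
    trial_id: str = "T001",
    group: str = "preschool",
    stimulus: str = "dots2",
    fs: float = 70.0,
    marker_noise_mm: float = 0.2,
    start_y: float = 55.0,
    ball_z: float = 10.0,
    rest_pre_s: float = 1.0,
    rest_post_s: float = 0.6,
    rng: np.random.Generator | None = None,
) -> tuple[TrialTrajectory, TrialTruth]:
    """Generate one trial's finger and ball trajectories plus its ground truth."""
    rng = rng or np.random.default_rng(0)
    n_move = int(round(shape.mt_nominal * fs))
    if n_move < 4:
        raise ValidationError("movement duration shorter than 4 samples")
    n_pre = int(round(rest_pre_s * fs))
    n_post = int(round(rest_post_s * fs))
    n = n_pre + n_move + 1 + n_post

    A = shape.mv * shape.mt_nominal / 1.875
    h = shape.mh - start_y
    d = shape.dev
    tau = np.arange(n_move + 1) / n_move
    s, _ = minimum_jerk(tau)
    move = np.column_stack(
        [d * np.sin(np.pi * s), start_y + h * np.sin(np.pi * s), A * s]
    )
    start = np.array([0.0, start_y, 0.0])
    pos = np.concatenate(
        [np.tile(start, (n_pre, 1)), move, np.tile(move[-1], (n_post, 1))]
    )

    truth = _analytic_truth(shape, start_y, ball_z, fs, n_pre, n_move)

    # ball: stationary until finger contact, then a fast decaying roll forward
    ball = np.tile(np.array([0.0, 11.5, ball_z]), (n, 1))
    if truth.kick_idx is not None:
        k = truth.kick_idx
        t_after = (np.arange(n - k)) / fs
        roll_t = 0.35
        v0 = 600.0
        disp = np.where(
            t_after < roll_t,
            v0 * (t_after - t_after**2 / (2 * roll_t)),
            v0 * roll_t / 2,
        )
        ball[k:, 2] += disp

    pos = pos + correlated_noise(rng, n, marker_noise_mm, fs)
    ball = ball + correlated_noise(rng, n, marker_noise_mm, fs)

    traj = TrialTrajectory(
        participant_id=participant_id,
        trial_id=trial_id,
        group=group,
        stimulus=stimulus,
        fs=fs,
        t=np.arange(n) / fs,
        index_xyz=pos,
        ball_xyz=ball,
    )
    return traj, truth


def _participants(config: EffectConfig, rng: np.random.Generator) -> list[ParticipantRecord]:
    records = []
    for i in range(config.n_preschool):
        records.append(
            ParticipantRecord(
                participant_id=f"P{i + 1:02d}",
                age_months=int(rng.integers(58, 83)),
                group="preschool",
                formal_math_education=False,
            )
        )
    for i in range(config.n_school):
        scores = MathScores(
            ET=int(rng.integers(1, 13)), ACA=int(rng.integers(10, 21)), SCA=int(rng.integers(4, 21))
        )
        records.append(
            ParticipantRecord(
                participant_id=f"S{i + 1:02d}",
                age_months=int(rng.integers(90, 131)),
                group="school",
                math_scores=scores,
                formal_math_education=True,
            )
        )
    return records


def simulate_experiment(
    config: EffectConfig | None = None,
) -> tuple[list[TrialTrajectory], list[ParticipantRecord], GroundTruth]:
    """Full synthetic experiment: trajectories for every go trial.

    Per participant, random intercepts for the trajectory-driving parameters
    (MH, MDevLeft, MT, MV) are drawn with the configured between-participant
    SDs; per trial, the condition cell mean plus trial noise sets the
    injected shape. No-go (5-dot) trials carry no kick and are emitted only
    when ``config.include_nogo`` is set; they never enter the analysis.
    """
    config = config or EffectConfig()
    ss = np.random.SeedSequence(config.seed)
    rng_design, rng_noise = (np.random.default_rng(s) for s in ss.spawn(2))
    participants = _participants(config, rng_design)
    truth = GroundTruth(config=config)
    for p in ("MH", "MDevLeft", "MV", "MT"):
        truth.effects[p] = config.true_effects(p)
    trials: list[TrialTrajectory] = []
    driver_params = ("MH", "MDevLeft", "MV")
    for rec in participants:
        b = {p: rng_design.normal(0.0, config.sigma_participant[p]) for p in driver_params}
        b["MT"] = rng_design.normal(0.0, config.traj_mt_sigma_log)
        truth.participant_intercepts[rec.participant_id] = b
        for cond in GO_STIMULI:
            for k in range(config.trials_per_condition):
                mh = (config.cell_mean("MH", rec.group, cond) + b["MH"]
                      + rng_design.normal(0.0, config.sigma_trial["MH"]))
                dev = (config.cell_mean("MDevLeft", rec.group, cond) + b["MDevLeft"]
                       + rng_design.normal(0.0, config.sigma_trial["MDevLeft"]))
                zero = getattr(config, "_zero_condition_effects", False)
                mt_scale = 1.0 if zero else _COND_SCALES["MT"][cond]
                mt = (config.traj_mt_median_s * mt_scale
                      * math.exp(b["MT"] + rng_design.normal(0.0, config.traj_mt_sigma_log)))
                mt = float(np.clip(mt, config.traj_mt_min_s, 1.5))
                mv = math.exp(config.cell_mean("MV", rec.group, cond) + b["MV"]
                              + rng_design.normal(0.0, config.sigma_trial["MV"]))
                mh = max(mh, config.start_height_mm + 1.0)
                # keep the speed profile single-peaked: the arc-to-transport
                # ratio pi*sqrt(h^2+d^2)/A must stay below ~0.65 or the
                # tangential speed develops two tied symmetric maxima
                h = mh - config.start_height_mm
                a_min = np.pi * math.hypot(h, dev) / 0.55
                mv = max(mv, 1.875 * a_min / mt)
                shape = TrialShape(mh=mh, dev=dev, mt_nominal=mt, mv=mv)
                trial_id = f"{rec.participant_id}_{cond}_{k:02d}"
                traj, ttruth = simulate_trial(
                    shape,
                    participant_id=rec.participant_id,
                    trial_id=trial_id,
                    group=rec.group,
                    stimulus=cond,
                    fs=config.fs,
                    marker_noise_mm=config.marker_noise_mm,
                    start_y=config.start_height_mm,
                    rng=rng_noise,
                )
                trials.append(traj)
                truth.trials[trial_id] = ttruth
    return trials, participants, truth


def simulate_parameter_table(
    config: EffectConfig | None = None,
    parameters: tuple[str, ...] | list[str] | None = None,
) -> tuple["pd.DataFrame", GroundTruth]:
    """Draw the ten parameters directly from the mixed-model generating
    equations, bypassing trajectories (for testing QC and inference at scale).

    Families per parameter follow ``config.family_map``: gaussian or
    Student-t on the natural scale, Gamma on the log scale for the positive
    parameters, and a [0, 1]-truncated normal for the normalized times.
    ``parameters`` restricts generation to a subset (draws are reproducible
    for a given seed *and* parameter set).
    """
    import pandas as pd

    config = config or EffectConfig()
    params = tuple(parameters) if parameters is not None else PARAMETER_NAMES
    unknown = set(params) - set(PARAMETER_NAMES)
    if unknown:
        raise ValidationError(f"unknown parameter(s): {sorted(unknown)}")
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
    participants = _participants(config, rng)
    truth = GroundTruth(config=config)
    for p in params:
        truth.effects[p] = config.true_effects(p)
    rows = []
    for rec in participants:
        b = {p: rng.normal(0.0, config.sigma_participant[p]) for p in params}
        truth.participant_intercepts[rec.participant_id] = b
        for cond in GO_STIMULI:
            for k in range(config.trials_per_condition):
                trial_id = f"{rec.participant_id}_{cond}_{k:02d}"
                for param in params:
                    mu = config.cell_mean(param, rec.group, cond) + b[param]
                    st = config.sigma_trial[param]
                    fam = config.family_map.get(param, "gaussian")
                    if fam == "gaussian":
                        val = rng.normal(mu, st)
                    elif fam == "student_t":
                        nu = config.t_nu
                        scale = st * math.sqrt((nu - 2.0) / nu)
                        val = mu + scale * rng.standard_t(nu)
                    elif fam == "gamma":
                        shape_k = max(1.0 / (math.expm1(st**2)), 0.5)
                        val = rng.gamma(shape=shape_k, scale=math.exp(mu) / shape_k)
                    elif fam == "truncnorm":
                        a, bnd = (0.0 - mu) / st, (1.0 - mu) / st
                        val = stats.truncnorm.rvs(a, bnd, loc=mu, scale=st, random_state=rng)
                    else:
                        raise ValidationError(f"unknown generating family {fam!r}")
                    rows.append(
                        {
                            "participant_id": rec.participant_id,
                            "group": rec.group,
                            "stimulus": cond,
                            "trial_id": trial_id,
                            "parameter": param,
                            "value": float(val),
                            "z": np.nan,
                            "excluded": False,
                        }
                    )
    return pd.DataFrame(rows), truth


def with_seed(config: EffectConfig, seed: int) -> EffectConfig:
    """Copy of the config with a different seed (effects untouched)."""
    cfg = replace(config, seed=seed,
                  mv_condition_scale=dict(config.mv_condition_scale),
                  sigma_participant=dict(config.sigma_participant),
                  sigma_trial=dict(config.sigma_trial),
                  family_map=dict(config.family_map))
    if getattr(config, "_zero_condition_effects", False):
        cfg._zero_condition_effects = True
    return cfg
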