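"""CSV readers and writers for every tabular artifact in the pipeline.

The canonical trajectory dialect is a long CSV with one row per sample:
``trial_id, participant_id, group, stimulus, t_s, ix, iy, iz, bx, by, bz``
(ball columns optional), positions in mm, time in seconds. Other layouts are
accommodated through a :class:`TrajectoryDialect` (column renames and unit
declarations) rather than guesswork; a dialect can be loaded from YAML.

Parameter tables are long CSVs with one row per (trial, parameter)
observation, matching the layout of deposited processed datasets.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import DataError, FormatError
from .types import (
    PARAMETER_NAMES,
    KinematicRecord,
    MathScores,
    ParticipantRecord,
    TrialTrajectory,
)

_TIME_FACTORS = {"s": 1.0, "ms": 1e-3}
_POS_FACTORS = {"mm": 1.0, "cm": 10.0, "m": 1000.0}

#: Columns of a long-format parameter table.
PARAMETER_TABLE_COLUMNS = (
    "participant_id",
    "group",
    "stimulus",
    "trial_id",
    "parameter",
    "value",
    "z",
    "excluded",
)


@dataclass
class TrajectoryDialect:
    """Declares column names and units of a trajectory CSV."""

    time_unit: str = "s"
    position_unit: str = "mm"
    fs: float = 70.0
    columns: dict[str, str] = field(default_factory=dict)  # canonical -> file column

    def __post_init__(self) -> None:
        if self.time_unit not in _TIME_FACTORS:
            raise FormatError(f"unknown time unit {self.time_unit!r}")
        if self.position_unit not in _POS_FACTORS:
            raise FormatError(f"unknown position unit {self.position_unit!r}")

    def column(self, canonical: str) -> str:
        return self.columns.get(canonical, canonical)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "TrajectoryDialect":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


_INDEX_COLS = ("ix", "iy", "iz")
_BALL_COLS = ("bx", "by", "bz")


def read_trajectories(
    path: str | Path, dialect: TrajectoryDialect | None = None
) -> list[TrialTrajectory]:
    """Read a long trajectory CSV into one :class:`TrialTrajectory` per trial.

    Trial order in the file is preserved; samples are never reordered.
    """
    dialect = dialect or TrajectoryDialect()
    df = pd.read_csv(path)
    required = ["trial_id", "participant_id", "group", "stimulus", "t_s", *_INDEX_COLS]
    for canonical in required:
        if dialect.column(canonical) not in df.columns:
            raise FormatError(f"missing required column {dialect.column(canonical)!r}")
    has_ball = all(dialect.column(c) in df.columns for c in _BALL_COLS)

    tfac = _TIME_FACTORS[dialect.time_unit]
    pfac = _POS_FACTORS[dialect.position_unit]
    trials: list[TrialTrajectory] = []
    # preserve file order of trials
    for trial_id, g in df.groupby(dialect.column("trial_id"), sort=False):
        t = g[dialect.column("t_s")].to_numpy(dtype=float) * tfac
        if np.any(np.diff(t) <= 0):
            raise DataError(f"trial {trial_id!r}: time column not strictly increasing")
        index_xyz = g[[dialect.column(c) for c in _INDEX_COLS]].to_numpy(dtype=float) * pfac
        ball_xyz = None
        if has_ball:
            ball = g[[dialect.column(c) for c in _BALL_COLS]]
            if not ball.isna().any().any():
                ball_xyz = ball.to_numpy(dtype=float) * pfac
        trials.append(
            TrialTrajectory(
                participant_id=str(g[dialect.column("participant_id")].iloc[0]),
                trial_id=str(trial_id),
                group=str(g[dialect.column("group")].iloc[0]),
                stimulus=str(g[dialect.column("stimulus")].iloc[0]),
                fs=dialect.fs,
                t=t,
                index_xyz=index_xyz,
                ball_xyz=ball_xyz,
            )
        )
    return trials


def write_trajectories(trials: list[TrialTrajectory], path: str | Path) -> None:
    """Write trials to the canonical long CSV dialect (mm, seconds)."""
    frames = []
    for tr in trials:
        d = {
            "trial_id": tr.trial_id,
            "participant_id": tr.participant_id,
            "group": tr.group,
            "stimulus": tr.stimulus,
            "t_s": tr.t,
            "ix": tr.index_xyz[:, 0],
            "iy": tr.index_xyz[:, 1],
            "iz": tr.index_xyz[:, 2],
        }
        if tr.ball_xyz is not None:
            d["bx"], d["by"], d["bz"] = tr.ball_xyz.T
        frames.append(pd.DataFrame(d))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_participants(path: str | Path) -> list[ParticipantRecord]:
    """Read participant metadata; ET/ACA/SCA map to MathScores when all present."""
    df = pd.read_csv(path)
    for col in ("participant_id", "age_months", "group"):
        if col not in df.columns:
            raise FormatError(f"missing required column {col!r}")
    if df["participant_id"].duplicated().any():
        dupes = df.loc[df["participant_id"].duplicated(), "participant_id"].tolist()
        raise DataError(f"duplicated participant_id(s): {dupes}")
    records = []
    has_math = all(c in df.columns for c in ("ET", "ACA", "SCA"))
    for _, row in df.iterrows():
        scores = None
        if has_math and not any(pd.isna(row[c]) for c in ("ET", "ACA", "SCA")):
            scores = MathScores(ET=int(row["ET"]), ACA=int(row["ACA"]), SCA=int(row["SCA"]))
        fme = None
        if "formal_math_education" in df.columns and not pd.isna(row["formal_math_education"]):
            fme = bool(row["formal_math_education"])
        records.append(
            ParticipantRecord(
                participant_id=str(row["participant_id"]),
                age_months=int(row["age_months"]),
                group=str(row["group"]),
                handedness=str(row.get("handedness", "right")) if "handedness" in df.columns else "right",
                math_scores=scores,
                formal_math_education=fme,
            )
        )
    return records


def write_participants(records: list[ParticipantRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        row: dict = {
            "participant_id": r.participant_id,
            "age_months": r.age_months,
            "group": r.group,
            "handedness": r.handedness,
            "formal_math_education": r.formal_math_education,
        }
        if r.math_scores is not None:
            row.update(dataclasses.asdict(r.math_scores))
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def empty_parameter_table() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "participant_id": pd.Series(dtype=str),
            "group": pd.Series(dtype=str),
            "stimulus": pd.Series(dtype=str),
            "trial_id": pd.Series(dtype=str),
            "parameter": pd.Series(dtype=str),
            "value": pd.Series(dtype=float),
            "z": pd.Series(dtype=float),
            "excluded": pd.Series(dtype=bool),
        }
    )


def validate_parameter_table(df: pd.DataFrame) -> pd.DataFrame:
    """Check the parameter-table contract; returns the (typed) frame."""
    for col in ("participant_id", "group", "stimulus", "trial_id", "parameter", "value"):
        if col not in df.columns:
            raise FormatError(f"parameter table missing column {col!r}")
    unknown = set(df["parameter"]) - set(PARAMETER_NAMES)
    if unknown:
        raise FormatError(f"unknown parameter name(s): {sorted(unknown)}")
    if df.duplicated(subset=["trial_id", "parameter"]).any():
        raise DataError("duplicate (trial_id, parameter) rows")
    out = df.copy()
    if "z" not in out.columns:
        out["z"] = np.nan
    if "excluded" not in out.columns:
        out["excluded"] = False
    out["excluded"] = out["excluded"].astype(bool)
    out["value"] = out["value"].astype(float)
    return out[list(PARAMETER_TABLE_COLUMNS)]


def read_parameter_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        dtype={"participant_id": str, "trial_id": str, "group": str, "stimulus": str},
    )
    if df.empty and "parameter" in df.columns:
        return empty_parameter_table()
    return validate_parameter_table(df)


def write_parameter_table(df: pd.DataFrame, path: str | Path) -> None:
    validate_parameter_table(df) if len(df) else None
    cols = [c for c in PARAMETER_TABLE_COLUMNS if c in df.columns]
    # full float precision so the round trip is exact to 1e-9 relative
    df.to_csv(path, index=False, columns=cols, float_format="%.12g")


def records_to_table(records: list[KinematicRecord]) -> pd.DataFrame:
    """Flatten KinematicRecords into the long parameter-table layout."""
    rows = []
    for rec in records:
        for name, value in rec.values().items():
            rows.append(
                {
                    "participant_id": rec.participant_id,
                    "group": rec.group,
                    "stimulus": rec.stimulus,
                    "trial_id": rec.trial_id,
                    "parameter": name,
                    "value": value,
                    "z": np.nan,
                    "excluded": False,
                }
            )
    if not rows:
        return empty_parameter_table()
    return pd.DataFrame(rows)
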