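"""Mathematical proficiency scoring, group assignment, and z-score cleaning.

The Mathematical Proficiency Index (MPI) sums three timed sub-scores, each
on a 0-20 scale: enumeration (ET, already reverse-coded: 20 s minus the time
to recite 1-20 without errors), additions correct in 30 s (ACA), and
subtractions correct in 30 s (SCA). MPI therefore lives on 0-60.

Observation cleaning standardizes each kinematic parameter against its
pooled whole-sample mean and SD and drops single (trial, parameter)
observations with |z| above a threshold (default 3), leaving the trial's
other parameters in play.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .types import MathScores, ParticipantRecord


def compute_mpi(scores: MathScores) -> MathScores:
    """Fill in the composite: MPI = ET + ACA + SCA (ET already reverse-coded)."""
    return MathScores(
        ET=scores.ET, ACA=scores.ACA, SCA=scores.SCA, MPI=scores.ET + scores.ACA + scores.SCA
    )


@dataclass
class GroupCriterion:
    """How to resolve a participant's developmental group.

    A ``formal_math_education`` flag wins when present; otherwise a
    participant with math scores is school-age, unless ``mpi_threshold`` is
    set and their MPI falls below it.
    """

    mpi_threshold: int | None = None


def assign_group(
    record: ParticipantRecord, criterion: GroupCriterion | None = None
) -> str:
    criterion = criterion or GroupCriterion()
    if record.formal_math_education is False:
        return "preschool"
    if record.formal_math_education is True:
        return "school"
    if record.math_scores is not None:
        if criterion.mpi_threshold is not None:
            mpi = compute_mpi(record.math_scores).MPI
            return "school" if mpi >= criterion.mpi_threshold else "preschool"
        return "school"
    raise ValidationError(
        f"participant {record.participant_id!r}: group unresolvable "
        "(no education flag and no math scores)"
    )


@dataclass
class CleaningReport:
    n_input: int
    n_excluded: int
    per_parameter_bounds: dict[str, tuple[float, float]] = field(default_factory=dict)
    n_trials_input: int = 0
    n_trials_affected: int = 0

    @property
    def n_retained(self) -> int:
        return self.n_input - self.n_excluded

    @property
    def pct_excluded(self) -> float:
        """Exclusion rate over (trial, parameter) observations."""
        return 100.0 * self.n_excluded / self.n_input if self.n_input else 0.0

    @property
    def pct_trials_affected(self) -> float:
        """Exclusion rate counting trials with at least one excluded parameter."""
        return 100.0 * self.n_trials_affected / self.n_trials_input if self.n_trials_input else 0.0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["n_retained"] = self.n_retained
        d["pct_excluded"] = self.pct_excluded
        d["pct_trials_affected"] = self.pct_trials_affected
        return d


def zscore_clean(
    table: pd.DataFrame, threshold_sd: float = 3.0
) -> tuple[pd.DataFrame, CleaningReport]:
    """Standardize each parameter and mark |z| > threshold observations excluded.

    z-scores use the pooled mean/SD (ddof=1) over all non-missing
    observations of that parameter. Parameters with zero variance are left
    unstandardized with a warning. Returns a copy; the input is not mutated.
    """
    out = table.copy()
    out["z"] = np.nan
    out["excluded"] = False
    bounds: dict[str, tuple[float, float]] = {}
    for name, grp in out.groupby("parameter", sort=False):
        vals = grp["value"]
        ok = vals.notna()
        if ok.sum() < 2:
            warnings.warn(f"parameter {name!r}: fewer than 2 observations, skipped")
            continue
        mean = float(vals[ok].mean())
        sd = float(vals[ok].std(ddof=1))
        if sd == 0.0 or not np.isfinite(sd):
            warnings.warn(f"parameter {name!r} has zero variance; no exclusions applied")
            continue
        bounds[str(name)] = (mean, sd)
        z = (vals - mean) / sd
        out.loc[grp.index, "z"] = z
        out.loc[grp.index, "excluded"] = z.abs() > threshold_sd

    n_input = int(out["value"].notna().sum())
    n_excluded = int(out["excluded"].sum())
    trials = out.groupby("trial_id")["excluded"].any()
    report = CleaningReport(
        n_input=n_input,
        n_excluded=n_excluded,
        per_parameter_bounds=bounds,
        n_trials_input=int(trials.size),
        n_trials_affected=int(trials.sum()),
    )
    return out, report
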