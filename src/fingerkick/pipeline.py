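"""Pipeline orchestration: simulate → extract → qc → fit → report.

Every stage persists its outputs under the run directory; reruns with the
same config and seed are bit-identical. All randomness descends from the
single top-level seed through ``numpy.random.SeedSequence`` spawning
(simulation uses the seed itself; each model's residual diagnostics use a
child seed in model order).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, io
from .errors import FingerkickError, NoMovementError, ValidationError
from .inference import (
    correlation_matrix,
    emm_contrasts,
    fit_mixed_model,
    get_family,
    simulated_residuals,
    ModelSpec,
)
from .kinematics import KinematicsOptions, extract_parameters
from .scoring import CleaningReport, zscore_clean
from .simulate import EffectConfig, simulate_experiment

logger = logging.getLogger(__name__)

#: the study's models: response parameter and its declared family
DEFAULT_MODELS = [
    {"response": "MH", "family": "student_t"},
    {"response": "MDevLeft", "family": "student_t"},
    {"response": "MV", "family": "gamma_log"},
]


@dataclass
class PipelineConfig:
    seed: int = 0
    simulate: bool = True
    simulate_overrides: dict = field(default_factory=dict)
    trajectories_csv: str | None = None
    participants_csv: str | None = None
    cutoff_hz: float = 10.0
    v_thresh: float = 5.0
    persist_s: float = 0.5
    target_mm: tuple | None = (0.0, 0.0, 500.0)  # apparatus goal position
    cleaning_threshold_sd: float = 3.0
    models: list = field(default_factory=lambda: [dict(m) for m in DEFAULT_MODELS])
    contrast_m: int = 2
    n_sim_diagnostics: int = 250
    agq_nodes: int = 11

    def validate(self) -> None:
        for m in self.models:
            get_family(m["family"])  # raises on unknown family
            if "response" not in m:
                raise ValidationError(f"model entry missing 'response': {m}")
        if not self.simulate and not self.trajectories_csv:
            raise ValidationError("either enable simulate or provide trajectories_csv")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if d["target_mm"] is not None:
            d["target_mm"] = list(d["target_mm"])
        return d


@dataclass
class RunReport:
    config: dict
    fingerprint: str
    n_trials_simulated: int = 0
    n_trials_extracted: int = 0
    n_no_movement: int = 0
    cleaning: dict = field(default_factory=dict)
    models: list = field(default_factory=list)
    contrasts: list = field(default_factory=list)
    correlations: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _fingerprint(config: PipelineConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    h = hashlib.sha256(blob).hexdigest()[:12]
    return f"fingerkick {__version__} / config {h}"


def _fmt_p(p: float) -> str:
    return "<0.001" if p < 0.001 else f"{p:.3f}"


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> RunReport:
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = RunReport(config=config.to_dict(), fingerprint=_fingerprint(config))
    fail_marker = outdir / "FAILED"
    if fail_marker.exists():
        fail_marker.unlink()
    try:
        _run_stages(config, outdir, report)
    except FingerkickError:
        fail_marker.write_text("pipeline aborted; see logs\n")
        raise
    (outdir / "run_report.json").write_text(json.dumps(report.to_dict(), indent=2, default=float))
    render_report(report, outdir / "report.md")
    return report


def _run_stages(config: PipelineConfig, outdir: Path, report: RunReport) -> None:
    # --- simulate -----------------------------------------------------------
    if config.simulate:
        sim_cfg = EffectConfig(seed=config.seed, **config.simulate_overrides)
        trials, participants, truth = simulate_experiment(sim_cfg)
        report.n_trials_simulated = len(trials)
        io.write_trajectories(trials, outdir / "trajectories.csv")
        io.write_participants(participants, outdir / "participants.csv")
        truth_json = {
            "effects": truth.effects,
            "trials": {
                tid: {"onset_idx": t.onset_idx, "offset_idx": t.offset_idx,
                      "kick_idx": t.kick_idx, **t.values}
                for tid, t in truth.trials.items()
            },
        }
        (outdir / "ground_truth.json").write_text(json.dumps(truth_json, indent=2))
    else:
        trials = io.read_trajectories(config.trajectories_csv)

    # --- extract ------------------------------------------------------------
    opts = KinematicsOptions(
        cutoff_hz=config.cutoff_hz,
        v_thresh=config.v_thresh,
        persist_s=config.persist_s,
        target_mm=tuple(config.target_mm) if config.target_mm is not None else None,
    )
    records = []
    for tr in trials:
        if tr.stimulus == "dots5_nogo":
            continue
        try:
            records.append(extract_parameters(tr, options=opts))
        except NoMovementError:
            report.n_no_movement += 1
            logger.warning("no movement detected in trial %s", tr.trial_id)
    report.n_trials_extracted = len(records)
    table = io.records_to_table(records)
    io.write_parameter_table(table, outdir / "parameters.csv")

    # --- qc -----------------------------------------------------------------
    cleaned, cleaning = zscore_clean(table, config.cleaning_threshold_sd)
    io.write_parameter_table(cleaned, outdir / "parameters_cleaned.csv")
    report.cleaning = cleaning.to_dict()
    (outdir / "cleaning_report.json").write_text(
        json.dumps(cleaning.to_dict(), indent=2, default=float)
    )

    # --- fit ----------------------------------------------------------------
    ss = np.random.SeedSequence(config.seed)
    diag_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(len(config.models))]
    coef_rows = []
    for spec_dict, dseed in zip(config.models, diag_seeds):
        spec = ModelSpec(response=spec_dict["response"], family=spec_dict["family"])
        fit = fit_mixed_model(spec, cleaned, agq_nodes=config.agq_nodes)
        contrasts = emm_contrasts(fit, m=config.contrast_m) if fit.converged else []
        diag = (
            simulated_residuals(fit, n_sim=config.n_sim_diagnostics, seed=dseed)
            if fit.converged
            else None
        )
        summary = fit.summary_dict()
        summary["diagnostics"] = (
            {"ks_stat": diag.ks_stat, "ks_p": diag.ks_p,
             "dispersion_ratio": diag.dispersion_ratio, "n_sim": diag.n_sim}
            if diag
            else None
        )
        report.models.append(summary)
        for c in contrasts:
            report.contrasts.append(
                {"response": spec.response, "group": c.group, "pair": list(c.pair),
                 "estimate": c.estimate, "se": c.se, "z": c.z,
                 "p_raw": c.p_raw, "p_adj": c.p_adj, "m": c.m}
            )
        for row in summary["coefficients"]:
            coef_rows.append({"response": spec.response, "family": spec.family, **row})
    pd.DataFrame(coef_rows).to_csv(outdir / "coefficients.csv", index=False)
    (outdir / "models.json").write_text(json.dumps(report.models, indent=2, default=float))

    # --- correlations -------------------------------------------------------
    corr = correlation_matrix(cleaned)
    corr.r.to_csv(outdir / "correlations_r.csv")
    corr.p_adj.to_csv(outdir / "correlations_p_adj.csv")
    report.correlations = {
        "m": corr.m,
        "n_significant": int((corr.p_adj.to_numpy()[np.triu_indices(len(corr.parameters), 1)] < 0.05).sum()),
    }


def render_report(report: RunReport, path: str | Path) -> None:
    """Human-readable markdown summary of one pipeline run."""
    lines = [
        "# Finger-kick kinematics pipeline report",
        "",
        f"_{report.fingerprint}_",
        "",
        "## Stage counts",
        "",
        f"- trials simulated: {report.n_trials_simulated}",
        f"- trials extracted: {report.n_trials_extracted}",
        f"- trials with no detected movement: {report.n_no_movement}",
        "",
    ]
    if report.cleaning:
        c = report.cleaning
        lines += [
            "## Observation cleaning",
            "",
            f"- observations in: {c['n_input']}, excluded: {c['n_excluded']} "
            f"({c['pct_excluded']:.2f}% of observations; "
            f"{c['pct_trials_affected']:.2f}% of trials affected)",
            f"- observations retained: {c['n_retained']}",
            "",
        ]
    for m in report.models:
        lines += [f"## Model: {m['response']} ({m['family']})", ""]
        lines += ["| term | b | SE | z | p |", "|---|---|---|---|---|"]
        for row in m["coefficients"]:
            lines.append(
                f"| {row['term']} | {row['b']:.3f} | {row['SE']:.3f} "
                f"| {row['z']:.2f} | {_fmt_p(row['p'])} |"
            )
        lines += [
            "",
            f"random-intercept SD: {m['sigma_u']:.3f}; "
            f"R² marginal {m['r2_marginal']:.3f}, conditional {m['r2_conditional']:.3f}; "
            f"log-likelihood {m['loglik']:.2f}; converged: {m['converged']}",
            "",
        ]
        if m.get("diagnostics"):
            d = m["diagnostics"]
            lines += [
                f"simulation-based residuals (n_sim={d['n_sim']}): "
                f"KS={d['ks_stat']:.3f} (p={_fmt_p(d['ks_p'])}), "
                f"dispersion ratio {d['dispersion_ratio']:.2f}",
                "",
            ]
    lines += ["## Post-hoc contrasts (Bonferroni within group)", ""]
    if report.contrasts:
        lines += [
            "| response | group | pair | estimate | SE | z | p_adj |",
            "|---|---|---|---|---|---|---|",
        ]
        for c in report.contrasts:
            lines.append(
                f"| {c['response']} | {c['group']} | {c['pair'][0]} − {c['pair'][1]} "
                f"| {c['estimate']:.3f} | {c['se']:.3f} | {c['z']:.2f} | {_fmt_p(c['p_adj'])} |"
            )
    else:
        lines.append("none")
    lines.append("")
    if report.correlations:
        lines += [
            "## Correlations",
            "",
            f"Bonferroni m = {report.correlations['m']}; "
            f"{report.correlations['n_significant']} significant pairs at p_adj < 0.05.",
            "",
        ]
    Path(path).write_text("\n".join(lines))
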