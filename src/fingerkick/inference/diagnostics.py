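"""Simulation-based residual diagnostics for fitted mixed models.

For each observation, the scaled residual is its empirical CDF position
among ``n_sim`` responses simulated from the fitted model (fresh random
intercepts and observation noise each replicate), with random tie-breaking.
Under a correctly specified model the scaled residuals are uniform on
[0, 1]; a one-sample Kolmogorov–Smirnov test quantifies departures, and a
dispersion ratio compares observed to simulated residual variance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from ..errors import ValidationError
from .families import get_family


@dataclass
class ResidualDiagnostics:
    n_sim: int
    scaled_residuals: np.ndarray
    ks_stat: float
    ks_p: float
    dispersion_ratio: float


def simulate_response(fit, rng: np.random.Generator) -> np.ndarray:
    """One response vector drawn from the fitted model."""
    fam = get_family(fit.family)
    u = rng.normal(0.0, fit.sigma_u, size=fit.n_groups)
    eta = fit.X @ fit.beta + u[fit.group_codes]
    return fam.simulate(rng, eta, fit._disp_raw)


def simulated_residuals(fit, n_sim: int = 250, seed: int = 0) -> ResidualDiagnostics:
    if not fit.converged:
        raise ValidationError("diagnostics require a converged fit")
    if n_sim < 100:
        raise ValidationError("n_sim must be at least 100")
    rng = np.random.default_rng(seed)
    sims = np.stack([simulate_response(fit, rng) for _ in range(n_sim)])  # (n_sim, n)
    y = fit.y
    less = (sims < y).sum(axis=0)
    equal = (sims == y).sum(axis=0)
    jitter = rng.uniform(size=y.size)
    scaled = (less + jitter * (equal + 1)) / (n_sim + 1)
    ks = stats.kstest(scaled, "uniform")
    mean_sim = sims.mean(axis=0)
    var_obs = float(np.var(y - mean_sim, ddof=1))
    var_sim = float(np.mean(np.var(sims - mean_sim, axis=1, ddof=1)))
    ratio = var_obs / var_sim if var_sim > 0 else np.nan
    return ResidualDiagnostics(
        n_sim=n_sim,
        scaled_residuals=scaled,
        ks_stat=float(ks.statistic),
        ks_p=float(ks.pvalue),
        dispersion_ratio=ratio,
    )
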