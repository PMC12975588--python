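"""Estimated-marginal-mean contrasts with Bonferroni adjustment.

Cell means are linear combinations of the fixed effects at each
Group × Stimulus cell on the link scale; a contrast between two cells within
a group gets a delta-method standard error from the coefficient covariance,
a Wald z, and a Bonferroni-adjusted p over the declared family size m
(default 2: the two comparisons against the reference stimulus within one
group).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..errors import ValidationError
from .families import normal_p_two_sided

DEFAULT_M = 2


@dataclass
class ContrastResult:
    group: str
    pair: tuple[str, str]
    estimate: float
    se: float
    z: float
    p_raw: float
    p_adj: float
    m: int


def cell_vector(fit, group: str, stimulus: str) -> np.ndarray:
    """Fixed-effect combination defining the (group, stimulus) cell mean."""
    meta = fit.design_meta
    if not meta:
        raise ValidationError("fit has no design metadata; was it built via fit_mixed_model?")
    if group not in meta["group_levels"]:
        raise ValidationError(f"group level {group!r} not in the fitted design")
    if stimulus not in meta["stimulus_levels"]:
        raise ValidationError(f"stimulus level {stimulus!r} not in the fitted design")
    L = np.zeros(len(fit.terms))
    for i, term in enumerate(fit.terms):
        if term == "(Intercept)":
            L[i] = 1.0
        elif term == f"group[{group}]":
            L[i] = 1.0
        elif term == f"stimulus[{stimulus}]":
            L[i] = 1.0
        elif term == f"group[{group}]:stimulus[{stimulus}]":
            L[i] = 1.0
    return L


def estimated_marginal_means(fit) -> dict[tuple[str, str], float]:
    """Link-scale EMM for every Group × Stimulus cell."""
    meta = fit.design_meta
    return {
        (g, s): float(cell_vector(fit, g, s) @ fit.beta)
        for g in meta["group_levels"]
        for s in meta["stimulus_levels"]
    }


def emm_contrasts(
    fit,
    pairs: list[tuple[str, str, str]] | None = None,
    m: int | None = None,
) -> list[ContrastResult]:
    """Within-group stimulus contrasts on the link scale.

    ``pairs`` is a list of ``(group, stimulus_a, stimulus_b)``; the estimate
    is EMM(a) − EMM(b). Defaults to (reference stimulus − each other
    stimulus) within every group, the family over which the default
    Bonferroni m = 2 applies.
    """
    if not fit.converged:
        raise ValidationError("contrasts require a converged fit")
    meta = fit.design_meta
    if pairs is None:
        ref = meta["stimulus_levels"][0]
        pairs = [
            (g, ref, other)
            for g in meta["group_levels"]
            for other in meta["stimulus_levels"][1:]
        ]
    if m is None:
        m = DEFAULT_M
    results = []
    for group, stim_a, stim_b in pairs:
        L = cell_vector(fit, group, stim_a) - cell_vector(fit, group, stim_b)
        est = float(L @ fit.beta)
        var = float(L @ fit.vcov_beta @ L)
        if stim_a == stim_b:
            results.append(ContrastResult(group, (stim_a, stim_b), 0.0, 0.0, 0.0, 1.0, 1.0, m))
            continue
        se = float(np.sqrt(var))
        z = est / se if se > 0 else 0.0
        p_raw = float(normal_p_two_sided(np.asarray(z)))
        results.append(
            ContrastResult(
                group=group,
                pair=(stim_a, stim_b),
                estimate=est,
                se=se,
                z=z,
                p_raw=p_raw,
                p_adj=min(1.0, m * p_raw),
                m=m,
            )
        )
    return results
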