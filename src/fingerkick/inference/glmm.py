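"""Random-intercept generalized linear mixed models by marginal maximum likelihood.

The model for observation j of participant i is

    y_ij ~ family(η_ij, dispersion),   η_ij = x_ij' β + u_i,   u_i ~ N(0, σ_u²)

with a scalar random intercept per participant. The marginal likelihood
integrates u_i out with adaptive Gauss–Hermite quadrature: for each
participant the integrand's mode and curvature are located by Newton steps
and the quadrature grid is centred and scaled there (one node recovers the
Laplace approximation; the gaussian family is integrated exactly for any
node count). Estimation is plain maximum likelihood (no REML); Wald
standard errors come from the inverse observed information (numerical
Hessian at the optimum) and p-values from the normal reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.polynomial.hermite import hermgauss
from scipy import optimize

from ..errors import FitError, ValidationError
from ..types import GO_STIMULI, GROUPS
from .families import Family, get_family, normal_p_two_sided

DEFAULT_AGQ_NODES = 11


@dataclass
class ModelSpec:
    """Fixed Group × Stimulus design with a per-participant random intercept."""

    response: str
    family: str
    reference_group: str = "preschool"
    reference_stimulus: str = "dots2"
    interaction: bool = True

    def __post_init__(self) -> None:
        get_family(self.family)  # validates the name eagerly


def _levels(values: pd.Series, reference: str, canonical: tuple[str, ...]) -> list[str]:
    present = list(pd.unique(values))
    if reference not in present:
        raise ValidationError(f"reference level {reference!r} absent from data")
    ordered = [reference]
    ordered += [lvl for lvl in canonical if lvl in present and lvl != reference]
    ordered += sorted(set(present) - set(ordered))
    return ordered


def build_design(data: pd.DataFrame, spec: ModelSpec) -> tuple[np.ndarray, list[str], dict]:
    """Treatment-coded design matrix for Group * Stimulus.

    Reference levels (first in each factor's ordering) are absorbed in the
    intercept, so the Group coefficient is the school-minus-preschool
    difference at the reference stimulus on the link scale.
    """
    g_levels = _levels(data["group"], spec.reference_group, GROUPS)
    s_levels = _levels(data["stimulus"], spec.reference_stimulus, GO_STIMULI)
    cols = [np.ones(len(data))]
    names = ["(Intercept)"]
    g_dummies = {}
    for lvl in g_levels[1:]:
        d = (data["group"] == lvl).to_numpy(float)
        g_dummies[lvl] = d
        cols.append(d)
        names.append(f"group[{lvl}]")
    s_dummies = {}
    for lvl in s_levels[1:]:
        d = (data["stimulus"] == lvl).to_numpy(float)
        s_dummies[lvl] = d
        cols.append(d)
        names.append(f"stimulus[{lvl}]")
    if spec.interaction:
        for gl, gd in g_dummies.items():
            for sl, sd in s_dummies.items():
                cols.append(gd * sd)
                names.append(f"group[{gl}]:stimulus[{sl}]")
    X = np.column_stack(cols)
    meta = {"group_levels": g_levels, "stimulus_levels": s_levels}
    return X, names, meta


@dataclass
class ModelFit:
    spec: ModelSpec | None
    family: str
    terms: list[str]
    beta: np.ndarray
    se: np.ndarray
    z: np.ndarray
    p: np.ndarray
    vcov_beta: np.ndarray
    sigma_u: float
    dispersion: dict[str, float]
    loglik: float
    converged: bool
    n_obs: int
    n_groups: int
    agq_nodes: int
    r2_marginal: float | None = None
    r2_conditional: float | None = None
    design_meta: dict = field(default_factory=dict)
    # retained for post-hoc contrasts and simulation-based diagnostics
    X: np.ndarray | None = field(default=None, repr=False)
    y: np.ndarray | None = field(default=None, repr=False)
    group_codes: np.ndarray | None = field(default=None, repr=False)
    _disp_raw: np.ndarray | None = field(default=None, repr=False)

    def coef_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"term": self.terms, "b": self.beta, "SE": self.se, "z": self.z, "p": self.p}
        )

    def summary_dict(self) -> dict:
        return {
            "response": self.spec.response if self.spec else None,
            "family": self.family,
            "coefficients": self.coef_table().to_dict(orient="records"),
            "sigma_u": self.sigma_u,
            "dispersion": self.dispersion,
            "loglik": self.loglik,
            "r2_marginal": self.r2_marginal,
            "r2_conditional": self.r2_conditional,
            "converged": self.converged,
            "n_obs": self.n_obs,
            "n_groups": self.n_groups,
        }


class _MarginalNLL:
    """Negative marginal log-likelihood with adaptive Gauss–Hermite quadrature.

    Observations must be pre-sorted by group. The per-group mode search
    warm-starts from the previous evaluation, so repeated calls during
    optimization are cheap.
    """

    def __init__(self, y: np.ndarray, X: np.ndarray, codes: np.ndarray, family: Family,
                 nodes: int = DEFAULT_AGQ_NODES):
        order = np.argsort(codes, kind="stable")
        self.y = np.asarray(y, float)[order]
        self.X = np.asarray(X, float)[order]
        self.codes = np.asarray(codes)[order]
        self.order = order
        self.family = family
        self.n_groups = int(self.codes.max()) + 1
        self.counts = np.bincount(self.codes, minlength=self.n_groups)
        if np.any(self.counts == 0):
            raise ValidationError("every participant must contribute at least one observation")
        self.starts = np.concatenate([[0], np.cumsum(self.counts)[:-1]])
        gx, gw = hermgauss(nodes)
        self.gh_x = gx
        self.gh_logw = np.log(gw)
        self._u_warm = np.zeros(self.n_groups)

    def _gsum(self, x: np.ndarray) -> np.ndarray:
        return np.add.reduceat(x, self.starts)

    def _mode(self, eta0, sigma_u, disp):
        """Newton search for the per-group mode of the joint log-density in u."""
        u = self._u_warm.copy()
        inv_var = 1.0 / sigma_u**2
        y, fam = self.y, self.family
        rep = np.repeat
        g = None
        for _ in range(80):
            eta = eta0 + rep(u, self.counts)
            g1 = self._gsum(fam.dll(y, eta, disp)) - u * inv_var
            g2 = self._gsum(fam.d2ll(y, eta, disp)) - inv_var
            g2 = np.minimum(g2, -1e-10)
            step = -g1 / g2
            # trust region keeps the t-family's non-concave tails in check
            cap = 10.0 * sigma_u + 1.0
            step = np.clip(step, -cap, cap)
            u_new = u + step
            if g is None:
                g = self._g_value(eta0, u, sigma_u, disp)
            g_new = self._g_value(eta0, u_new, sigma_u, disp)
            worse = g_new < g - 1e-12
            for _halve in range(15):
                if not np.any(worse):
                    break
                u_new = np.where(worse, (u + u_new) / 2.0, u_new)
                g_new = self._g_value(eta0, u_new, sigma_u, disp)
                worse = g_new < g - 1e-12
            moved = np.max(np.abs(u_new - u))
            u, g = u_new, g_new
            if moved < 1e-10 * (sigma_u + 1e-12):
                break
        eta = eta0 + rep(u, self.counts)
        h = -(self._gsum(fam.d2ll(y, eta, disp)) - inv_var)
        h = np.maximum(h, 1e-10)
        self._u_warm = u
        return u, h

    def _g_value(self, eta0, u, sigma_u, disp):
        eta = eta0 + np.repeat(u, self.counts)
        ll = self._gsum(self.family.ll(self.y, eta, disp))
        return ll - 0.5 * u**2 / sigma_u**2 - 0.5 * np.log(2 * np.pi * sigma_u**2)

    def loglik(self, beta, sigma_u, disp) -> float:
        eta0 = self.X @ beta
        u_hat, h = self._mode(eta0, sigma_u, disp)
        sd_hat = 1.0 / np.sqrt(h)
        # nodes: (G, K)
        u_nodes = u_hat[:, None] + np.sqrt(2.0) * sd_hat[:, None] * self.gh_x[None, :]
        gvals = np.empty((self.n_groups, self.gh_x.size))
        for k in range(self.gh_x.size):
            gvals[:, k] = self._g_value(eta0, u_nodes[:, k], sigma_u, disp)
        expo = gvals + self.gh_x[None, :] ** 2 + self.gh_logw[None, :]
        m = expo.max(axis=1)
        li = m + np.log(np.exp(expo - m[:, None]).sum(axis=1)) + 0.5 * np.log(2.0) - 0.5 * np.log(h)
        return float(li.sum())

    def __call__(self, theta: np.ndarray) -> float:
        p = self.X.shape[1]
        beta = theta[:p]
        sigma_u = np.exp(theta[p])
        disp = theta[p + 1:]
        ll = self.loglik(beta, sigma_u, disp)
        if not np.isfinite(ll):
            return 1e12
        return -ll


def _numerical_gradient(fun, theta: np.ndarray, rel_step: float = 1e-6) -> np.ndarray:
    h = rel_step * np.maximum(1.0, np.abs(theta))
    g = np.empty_like(theta)
    for i in range(theta.size):
        e = np.zeros_like(theta); e[i] = h[i]
        g[i] = (fun(theta + e) - fun(theta - e)) / (2 * h[i])
    return g


def _numerical_hessian(fun, theta: np.ndarray, rel_step: float = 1e-4) -> np.ndarray:
    k = theta.size
    h = rel_step * np.maximum(1.0, np.abs(theta))
    H = np.empty((k, k))
    f0 = fun(theta)
    for i in range(k):
        ei = np.zeros(k); ei[i] = h[i]
        fpp = fun(theta + ei)
        fmm = fun(theta - ei)
        H[i, i] = (fpp - 2 * f0 + fmm) / h[i] ** 2
        for j in range(i + 1, k):
            ej = np.zeros(k); ej[j] = h[j]
            fa = fun(theta + ei + ej)
            fb = fun(theta + ei - ej)
            fc = fun(theta - ei + ej)
            fd = fun(theta - ei - ej)
            H[i, j] = H[j, i] = (fa - fb - fc + fd) / (4 * h[i] * h[j])
    return H


def fit_glmm(
    y: np.ndarray,
    X: np.ndarray,
    groups: np.ndarray,
    family: str | Family,
    terms: list[str] | None = None,
    spec: ModelSpec | None = None,
    design_meta: dict | None = None,
    agq_nodes: int = DEFAULT_AGQ_NODES,
    maxiter: int = 500,
) -> ModelFit:
    """Fit a random-intercept GLMM by maximum likelihood. Low-level entry point.

    ``groups`` may be any labels; they are factorized internally.
    """
    fam = get_family(family) if isinstance(family, str) else family
    y = np.asarray(y, float)
    X = np.atleast_2d(np.asarray(X, float))
    codes, levels = pd.factorize(np.asarray(groups))
    if len(levels) < 2:
        raise ValidationError("need at least 2 participants for a random intercept")
    fam.check_response(y)
    p = X.shape[1]
    terms = terms or [f"x{i}" for i in range(p)]

    # deterministic start: GLM ignoring the random effect, sigma_u at 10% of
    # the link-scale response SD
    eta_y = fam.init_eta(y)
    beta0, *_ = np.linalg.lstsq(X, eta_y, rcond=None)
    resid0 = eta_y - X @ beta0
    disp0 = fam.init_disp(resid0)
    scale_y = max(float(np.std(eta_y)), 1e-6)
    theta0 = np.concatenate([beta0, [np.log(0.1 * scale_y)], disp0])

    nll = _MarginalNLL(y, X, codes, fam, nodes=agq_nodes)
    bounds = [(None, None)] * p
    bounds.append((np.log(scale_y * 1e-5), np.log(scale_y * 1e3)))
    bounds.extend(fam.disp_bounds())

    res = optimize.minimize(
        nll, theta0, method="L-BFGS-B", bounds=bounds,
        options={"maxiter": maxiter, "maxfun": 20000, "ftol": 1e-12, "gtol": 1e-6},
    )
    theta = res.x
    # Newton polish: the quasi-Newton loop can stall ~1e-4 from the optimum,
    # which matters for the exact balanced-design identities
    H_polish = _numerical_hessian(nll, theta)
    f_cur = nll(theta)
    for _ in range(3):
        g = _numerical_gradient(nll, theta)
        try:
            step = np.linalg.solve(H_polish, g)
        except np.linalg.LinAlgError:
            break
        cand = theta - step
        for lo_hi, i in zip(bounds, range(theta.size)):
            lo, hi = lo_hi
            if lo is not None:
                cand[i] = max(cand[i], lo)
            if hi is not None:
                cand[i] = min(cand[i], hi)
        f_cand = nll(cand)
        if f_cand < f_cur - 1e-12:
            theta, f_cur = cand, f_cand
        else:
            break
    loglik = -float(f_cur)
    # projected gradient: components pointing into an active bound don't count
    grad = np.asarray(res.jac, float) if res.jac is not None else np.full_like(theta, np.inf)
    proj = grad.copy()
    for i, (lo, hi) in enumerate(bounds):
        if lo is not None and theta[i] <= lo + 1e-10 and grad[i] > 0:
            proj[i] = 0.0
        if hi is not None and theta[i] >= hi - 1e-10 and grad[i] < 0:
            proj[i] = 0.0
    grad_norm = float(np.linalg.norm(proj))
    converged = bool(res.success) and grad_norm < 1e-5 * max(1.0, abs(loglik))

    moved = float(np.max(np.abs(theta - res.x) / np.maximum(1.0, np.abs(theta))))
    H = _numerical_hessian(nll, theta) if moved > 1e-6 else H_polish
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError as exc:
        raise FitError(f"singular observed information matrix: {exc}") from exc
    diag = np.diag(cov)
    if np.any(~np.isfinite(diag)) or np.any(diag[:p] <= 0):
        raise FitError(
            "observed information not positive definite at the optimum; "
            f"diagonal of the inverse: {np.round(diag, 6)}"
        )
    se = np.sqrt(diag[:p])
    beta = theta[:p]
    z = beta / se
    pvals = normal_p_two_sided(z)

    fit = ModelFit(
        spec=spec,
        family=fam.name,
        terms=list(terms),
        beta=beta,
        se=se,
        z=z,
        p=pvals,
        vcov_beta=cov[:p, :p],
        sigma_u=float(np.exp(theta[p])),
        dispersion=fam.dispersion_dict(theta[p + 1:]),
        loglik=loglik,
        converged=converged,
        n_obs=y.size,
        n_groups=len(levels),
        agq_nodes=agq_nodes,
        design_meta=design_meta or {},
        X=X,
        y=y,
        group_codes=codes,
        _disp_raw=theta[p + 1:],
    )
    return fit


def prepare_response(table: pd.DataFrame, response: str) -> pd.DataFrame:
    """Retained observations of one parameter, one row per trial."""
    sub = table[(table["parameter"] == response) & (~table["excluded"].astype(bool))]
    sub = sub.dropna(subset=["value"])
    return sub.reset_index(drop=True)


def fit_mixed_model(
    spec: ModelSpec,
    data: pd.DataFrame,
    agq_nodes: int = DEFAULT_AGQ_NODES,
) -> ModelFit:
    """Fit one kinematic parameter's Group × Stimulus model.

    ``data`` is either a long cleaned parameter table (filtered to
    ``spec.response`` internally) or an already-prepared frame with columns
    participant_id, group, stimulus, value.
    """
    if "parameter" in data.columns:
        data = prepare_response(data, spec.response)
    if data.empty:
        raise ValidationError(f"no observations for response {spec.response!r}")
    X, terms, meta = build_design(data, spec)
    fit = fit_glmm(
        y=data["value"].to_numpy(float),
        X=X,
        groups=data["participant_id"].to_numpy(),
        family=spec.family,
        terms=terms,
        spec=spec,
        design_meta=meta,
        agq_nodes=agq_nodes,
    )
    from .r2 import r2_nakagawa  # local import to avoid a cycle

    fit.r2_marginal, fit.r2_conditional = r2_nakagawa(fit)
    return fit


def marginal_loglik(fit_or_args, beta=None, sigma_u=None, disp_raw=None) -> float:
    """Evaluate the marginal log-likelihood of a fitted model at given parameters.

    Used by the likelihood-sanity checks (e.g. comparing against the
    intercept-only, no-random-variation configuration).
    """
    fit = fit_or_args
    fam = get_family(fit.family)
    nll = _MarginalNLL(fit.y, fit.X, fit.group_codes, fam, nodes=fit.agq_nodes)
    return nll.loglik(np.asarray(beta, float), float(sigma_u), np.asarray(disp_raw, float))
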