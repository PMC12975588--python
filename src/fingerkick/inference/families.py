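"""Response families for the random-intercept mixed models.

Each family exposes the per-observation log-likelihood and its first two
derivatives with respect to the linear predictor η (identity link for the
gaussian and Student-t families, log link for the Gamma), plus simulation
and the observation/latent-scale residual variance used by the
variance-decomposition R².

Dispersion parameters are carried on an unconstrained optimizer scale
(logs; the t-family's degrees of freedom are additionally box-bounded).
"""

from __future__ import annotations

import numpy as np
from scipy import special, stats

from ..errors import ValidationError

NU_MIN, NU_MAX = 2.5, 100.0


class Family:
    name: str
    link: str
    n_disp: int
    disp_names: tuple[str, ...]

    def check_response(self, y: np.ndarray) -> None:
        pass

    def init_eta(self, y: np.ndarray) -> np.ndarray:
        return np.asarray(y, float)

    def init_disp(self, resid: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def disp_bounds(self) -> list[tuple[float | None, float | None]]:
        return [(None, None)] * self.n_disp

    def ll(self, y, eta, disp) -> np.ndarray:
        raise NotImplementedError

    def dll(self, y, eta, disp) -> np.ndarray:
        raise NotImplementedError

    def d2ll(self, y, eta, disp) -> np.ndarray:
        raise NotImplementedError

    def simulate(self, rng: np.random.Generator, eta, disp) -> np.ndarray:
        raise NotImplementedError

    def dispersion_dict(self, disp) -> dict[str, float]:
        raise NotImplementedError

    def residual_variance(self, disp) -> float:
        """Residual variance on the link (latent) scale."""
        raise NotImplementedError


class Gaussian(Family):
    name = "gaussian"
    link = "identity"
    n_disp = 1
    disp_names = ("sigma",)

    def init_disp(self, resid):
        return np.array([np.log(max(np.std(resid), 1e-8))])

    def ll(self, y, eta, disp):
        sigma = np.exp(disp[0])
        r = y - eta
        return -0.5 * np.log(2 * np.pi * sigma**2) - r**2 / (2 * sigma**2)

    def dll(self, y, eta, disp):
        return (y - eta) / np.exp(2 * disp[0])

    def d2ll(self, y, eta, disp):
        return np.full_like(np.asarray(eta, float), -np.exp(-2 * disp[0]))

    def simulate(self, rng, eta, disp):
        return eta + rng.normal(0.0, np.exp(disp[0]), size=np.shape(eta))

    def dispersion_dict(self, disp):
        return {"sigma": float(np.exp(disp[0]))}

    def residual_variance(self, disp):
        return float(np.exp(2 * disp[0]))


class StudentT(Family):
    """Student-t response on the identity link; scale and df jointly estimated."""

    name = "student_t"
    link = "identity"
    n_disp = 2
    disp_names = ("scale", "nu")

    def init_disp(self, resid):
        s = max(np.std(resid), 1e-8)
        return np.array([np.log(0.8 * s), np.log(10.0)])

    def disp_bounds(self):
        return [(None, None), (np.log(NU_MIN), np.log(NU_MAX))]

    def ll(self, y, eta, disp):
        s, nu = np.exp(disp[0]), np.exp(disp[1])
        r = (y - eta) / s
        return (
            special.gammaln((nu + 1) / 2)
            - special.gammaln(nu / 2)
            - 0.5 * np.log(nu * np.pi * s**2)
            - (nu + 1) / 2 * np.log1p(r**2 / nu)
        )

    def dll(self, y, eta, disp):
        s, nu = np.exp(disp[0]), np.exp(disp[1])
        r = (y - eta) / s
        return (nu + 1) * r / (s * (nu + r**2))

    def d2ll(self, y, eta, disp):
        s, nu = np.exp(disp[0]), np.exp(disp[1])
        r = (y - eta) / s
        return -(nu + 1) * (nu - r**2) / (s**2 * (nu + r**2) ** 2)

    def simulate(self, rng, eta, disp):
        s, nu = np.exp(disp[0]), np.exp(disp[1])
        return eta + s * rng.standard_t(nu, size=np.shape(eta))

    def dispersion_dict(self, disp):
        return {"scale": float(np.exp(disp[0])), "nu": float(np.exp(disp[1]))}

    def residual_variance(self, disp):
        s, nu = np.exp(disp[0]), np.exp(disp[1])
        if nu <= 2:
            return float("inf")
        return float(s**2 * nu / (nu - 2))


class GammaLog(Family):
    """Gamma response with log link, shape parametrization (mean = exp(η))."""

    name = "gamma_log"
    link = "log"
    n_disp = 1
    disp_names = ("shape",)

    def check_response(self, y):
        if np.any(np.asarray(y) <= 0):
            raise ValidationError("gamma_log requires strictly positive responses")

    def init_eta(self, y):
        return np.log(np.asarray(y, float))

    def init_disp(self, resid):
        # resid on the log scale; moment-match lognormal-ish: var(log y) ≈ trigamma(k)
        v = max(float(np.var(resid)), 1e-6)
        k = max(1.0 / v, 0.1)
        return np.array([np.log(k)])

    def ll(self, y, eta, disp):
        k = np.exp(disp[0])
        return k * np.log(k) - k * eta + (k - 1) * np.log(y) - k * y * np.exp(-eta) - special.gammaln(k)

    def dll(self, y, eta, disp):
        k = np.exp(disp[0])
        return -k + k * y * np.exp(-eta)

    def d2ll(self, y, eta, disp):
        k = np.exp(disp[0])
        return -k * y * np.exp(-eta)

    def simulate(self, rng, eta, disp):
        k = np.exp(disp[0])
        return rng.gamma(shape=k, scale=np.exp(eta) / k)

    def dispersion_dict(self, disp):
        return {"shape": float(np.exp(disp[0]))}

    def residual_variance(self, disp):
        # latent (log-link) scale variance, trigamma of the shape
        return float(special.polygamma(1, np.exp(disp[0])))


FAMILIES: dict[str, type[Family]] = {
    "gaussian": Gaussian,
    "student_t": StudentT,
    "gamma_log": GammaLog,
}


def get_family(name: str) -> Family:
    try:
        return FAMILIES[name]()
    except KeyError:
        raise ValidationError(
            f"unknown family {name!r}; choose from {sorted(FAMILIES)}"
        ) from None


def normal_p_two_sided(z: np.ndarray) -> np.ndarray:
    return 2 * stats.norm.sf(np.abs(z))
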