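"""Variance-decomposition R² for mixed models (marginal and conditional).

The marginal R² is the share of total latent-scale variance explained by the
fixed effects; the conditional R² adds the random-intercept variance to the
numerator:

    R²_m = var(Xβ) / (var(Xβ) + σ_u² + σ_e²)
    R²_c = (var(Xβ) + σ_u²) / (var(Xβ) + σ_u² + σ_e²)

σ_e² is the family's residual variance on the link scale: σ² for the
gaussian, s²·ν/(ν−2) for the Student-t (both identity link), and the
trigamma of the shape for the log-link Gamma.
"""

from __future__ import annotations

import numpy as np

from .families import get_family


def r2_nakagawa(fit) -> tuple[float, float]:
    fam = get_family(fit.family)
    eta_fixed = fit.X @ fit.beta
    var_f = float(np.var(eta_fixed, ddof=1)) if eta_fixed.size > 1 else 0.0
    var_u = fit.sigma_u**2
    var_e = fam.residual_variance(fit._disp_raw)
    total = var_f + var_u + var_e
    if not np.isfinite(total) or total <= 0:
        return 0.0, 0.0
    return var_f / total, (var_f + var_u) / total
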