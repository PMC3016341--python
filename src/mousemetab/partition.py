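"""The body-composition partition function alpha(FM) = dFFM/dFM.

In adult male C57BL/6 mice the change of fat-free mass accompanying a
change of fat mass follows a well-defined, time-invariant Forbes-type
relationship.  Its derivative,

    alpha(FM) = c + d * exp(k * FM),

with c = 0.1, d = 1.89e-4, and k = 0.45 1/g, was measured empirically on
adult mice and is treated here as a fixed constitutive function: it couples
the fat-free-mass rate to the fat-mass rate (dFFM/dt = alpha * dFM/dt) and
makes the single energy-balance equation resolvable into a pair of ODEs.

Because the function was measured on adult mice only, evaluation is
restricted to fat masses in [0.1, 60] g; values outside that range raise
rather than extrapolate.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import quad

from .core import ModelParameters

#: Fat-mass domain (g) on which the empirical partition function is trusted.
FM_MIN = 0.1
FM_MAX = 60.0

_DEFAULT = ModelParameters()


class PartitionDomainError(ValueError):
    """Fat mass outside the empirically supported range."""


def _check_domain(FM) -> None:
    arr = np.asarray(FM, dtype=float)
    if np.any(~np.isfinite(arr)) or np.any(arr < FM_MIN) or np.any(arr > FM_MAX):
        raise PartitionDomainError(
            f"FM must lie in [{FM_MIN}, {FM_MAX}] g, got {FM!r}"
        )


def alpha(FM, p: ModelParameters = _DEFAULT):
    """Evaluate alpha(FM) = c + d*exp(k*FM), the lean-per-fat coupling.

    Accepts a scalar or array of fat masses (g) within [0.1, 60] g and
    returns the dimensionless dFFM/dFM ratio.  The function is
    deterministic and time-invariant; with the default constants it is
    continuous, strictly increasing, and non-negative on its domain.
    """
    _check_domain(FM)
    FM = np.asarray(FM, dtype=float)
    out = p.alpha_c + p.alpha_d * np.exp(p.alpha_k * FM)
    return float(out) if out.ndim == 0 else out


def ffm_from_fm_path(
    FM_start: float,
    FM_end: float,
    FFM_start: float,
    p: ModelParameters = _DEFAULT,
) -> float:
    """Integrate the partition function along a fat-mass path.

    Returns FFM_start + integral of alpha(f) df from FM_start to FM_end,
    computed by adaptive quadrature (absolute tolerance 1e-10).  Because
    alpha depends only on FM, the result is path-independent: composing
    legs or reversing a path is exact up to quadrature tolerance.
    """
    _check_domain(FM_start)
    _check_domain(FM_end)
    dffm, _ = quad(
        lambda f: p.alpha_c + p.alpha_d * np.exp(p.alpha_k * f),
        FM_start,
        FM_end,
        epsabs=1e-10,
        epsrel=1e-12,
        limit=200,
    )
    if not np.isfinite(dffm):
        raise ArithmeticError("quadrature of alpha returned a non-finite value")
    return FFM_start + dffm
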