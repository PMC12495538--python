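"""Single-pole Cole-Cole / Debye dielectric dispersion.

The complex relative permittivity of a material is modeled as

    eps_r(f) = eps_inf + (eps_s - eps_inf) / (1 + (j w tau)^(1-alpha))
               - j sigma / (eps0 w),        w = 2 pi f,

under the ``e^{+j w t}`` time convention (lossy media have a negative
imaginary part).  ``alpha = 0`` is the Debye model; ``alpha`` in (0, 1)
broadens the relaxation.  This single relaxation plus a static-conductivity
term is the standard description of skin-tissue and tissue-simulant
dielectrics in the 10-110 GHz range.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares

from .constants import EPS_0

__all__ = [
    "DispersionParams",
    "complex_permittivity",
    "loss_tangent",
    "fit_debye_to_dispersion",
    "DebyeFitError",
]


class DebyeFitError(RuntimeError):
    """Raised when the Debye re-fit of a dispersive model fails to converge.

    Carries the last iterate (``params``) and its residual so callers can
    inspect how close the optimizer got.
    """

    def __init__(self, message, params=None, residual=None):
        super().__init__(message)
        self.params = params
        self.residual = residual


@dataclass(frozen=True)
class DispersionParams:
    """Parameters of a single-pole Cole-Cole (or Debye) dielectric model.

    Parameters
    ----------
    eps_inf : float
        Relative permittivity at infinite frequency, >= 1.
    eps_s : float
        Static relative permittivity.
    sigma : float
        Static conductivity in S/m, >= 0.
    tau : float
        Relaxation time in seconds, > 0.  A material with no relaxation
        (``eps_s == eps_inf``) may set ``tau = 0``; the dispersive term
        vanishes identically then.
    alpha : float
        Cole-Cole broadening exponent in [0, 1).  ``alpha = 0`` gives the
        Debye model.
    name : str
        Optional label used in registries and provenance metadata.
    """

    eps_inf: float
    eps_s: float
    sigma: float = 0.0
    tau: float = 0.0
    alpha: float = 0.0
    name: str = field(default="", compare=False)

    def __post_init__(self):
        if not (self.eps_inf >= 1.0):
            raise ValueError(f"eps_inf must be >= 1, got {self.eps_inf}")
        if self.sigma < 0:
            raise ValueError(f"sigma must be >= 0, got {self.sigma}")
        if not (0.0 <= self.alpha < 1.0):
            raise ValueError(f"alpha must be in [0, 1), got {self.alpha}")
        if self.tau < 0:
            raise ValueError(f"tau must be >= 0, got {self.tau}")
        if self.eps_s != self.eps_inf and self.tau == 0:
            raise ValueError("dispersive model (eps_s != eps_inf) needs tau > 0")

    @property
    def is_debye(self) -> bool:
        return self.alpha == 0.0

    def permittivity(self, f):
        return complex_permittivity(self, f)


#: Non-dispersive vacuum "material", used as the default incident medium.
VACUUM = DispersionParams(eps_inf=1.0, eps_s=1.0, sigma=0.0, tau=0.0, name="vacuum")


def _check_frequency(f):
    f = np.asarray(f, dtype=float)
    if not np.all(np.isfinite(f)) or np.any(f <= 0):
        raise ValueError("frequency must be finite and > 0 Hz")
    return f


def complex_permittivity(params: DispersionParams, f):
    """Complex relative permittivity at frequency ``f`` (Hz, scalar or array).

    Returns ``eps_inf + (eps_s - eps_inf)/(1 + (j w tau)^(1-alpha))
    - j sigma/(eps0 w)``; the imaginary part is <= 0 for passive media.
    The principal branch of the complex power is used; since ``w tau > 0``
    the argument stays away from the branch cut.
    """
    f = _check_frequency(f)
    w = 2.0 * math.pi * f
    eps = np.full_like(f, params.eps_inf, dtype=complex)
    if params.eps_s != params.eps_inf:
        jwt = 1j * w * params.tau
        eps = eps + (params.eps_s - params.eps_inf) / (1.0 + jwt ** (1.0 - params.alpha))
    if params.sigma != 0.0:
        eps = eps - 1j * params.sigma / (EPS_0 * w)
    return eps if eps.shape else complex(eps)


def loss_tangent(params: DispersionParams, f):
    """Loss tangent ``tan(delta) = -Im(eps)/Re(eps)`` at frequency ``f``.

    Raises ``ValueError`` if the real part of the permittivity is not
    positive (degenerate medium for which the ratio is meaningless).
    """
    eps = np.asarray(complex_permittivity(params, f))
    if np.any(eps.real <= 0):
        raise ValueError("loss tangent undefined: Re(eps) <= 0 at requested frequency")
    out = -eps.imag / eps.real
    return out if out.shape else float(out)


def debye_from_loss_tangent(eps_r: float, tan_delta: float, f_ref: float,
                            name: str = "") -> DispersionParams:
    """Non-dispersive material with conductivity chosen to give ``tan_delta``
    at ``f_ref``.  Convenience for low-loss foams/spacers characterized by a
    single (eps_r, tan d) pair."""
    sigma = tan_delta * eps_r * EPS_0 * 2.0 * math.pi * f_ref
    return DispersionParams(eps_inf=eps_r, eps_s=eps_r, sigma=sigma, tau=0.0, name=name)


def fit_debye_to_dispersion(source: DispersionParams, band, n_points: int = 50):
    """Fit a Debye model (``alpha = 0``) to a dispersive source over a band.

    The band ``(f_lo, f_hi)`` in Hz is sampled logarithmically at
    ``n_points`` frequencies; the objective is the summed squared deviation
    of the complex permittivity (real and imaginary parts weighted equally).
    Useful for FDTD-style solvers that accept Debye poles only.

    Returns a ``DispersionParams`` with ``alpha = 0``; the achieved maximum
    relative deviation is attached as ``fit_residual_rel`` on the returned
    object's ``name`` metadata companion tuple via the second return value.

    Returns
    -------
    (params, max_rel_deviation)
    """
    f_lo, f_hi = float(band[0]), float(band[1])
    if not (0 < f_lo < f_hi <= 110e9 * 10):
        raise ValueError("band must satisfy 0 < f_lo < f_hi")
    if f_hi / f_lo < 1.0 + 1e-9:
        raise ValueError("band is degenerate (single frequency)")
    if n_points < 4:
        raise ValueError("need n_points >= 4")

    f = np.geomspace(f_lo, f_hi, n_points)
    target = np.asarray(complex_permittivity(source, f))

    def unpack(x):
        eps_inf, d_eps, sigma, tau_ps = x
        return DispersionParams(
            eps_inf=eps_inf, eps_s=eps_inf + d_eps, sigma=sigma,
            tau=tau_ps * 1e-12, alpha=0.0)

    def resid(x):
        eps = np.asarray(complex_permittivity(unpack(x), f))
        d = eps - target
        return np.concatenate([d.real, d.imag])

    x0 = np.array([
        max(source.eps_inf, 1.0),
        max(source.eps_s - source.eps_inf, 0.0),
        source.sigma,
        max(source.tau * 1e12, 1e-3),
    ])
    sol = least_squares(
        resid, x0,
        bounds=([1.0, 0.0, 0.0, 1e-6], [np.inf, np.inf, np.inf, 1e6]),
        xtol=1e-14, ftol=1e-14, gtol=1e-14)
    fitted = unpack(sol.x)
    eps_fit = np.asarray(complex_permittivity(fitted, f))
    rel = np.abs(eps_fit - target) / np.abs(target)
    max_rel = float(rel.max())
    if not sol.success:
        raise DebyeFitError("Debye fit did not converge", params=fitted, residual=max_rel)
    return replace(fitted, name=(source.name + "_debye") if source.name else "debye_fit"), max_rel
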