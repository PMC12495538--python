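"""Plane-wave reflection of stratified dispersive media.

A :class:`LayerStack` is an ordered sequence of finite-thickness layers over
a terminal half-space, illuminated from an incident half-space (vacuum by
default).  Reflection is computed by recursive transmission-line impedance
transformation: each layer is a section of line whose characteristic
impedance and propagation constant follow from its complex permittivity at
the evaluation frequency.

The same recursion, expressed per transverse wavenumber ``kt`` instead of
per incidence angle, provides the spectral-domain TE/TM input admittance of
the stack that the open-waveguide mode-matching solver integrates over.

Sign conventions: ``e^{+j w t}`` time dependence; normal wavenumbers take the
branch with non-negative real part and non-positive imaginary part, so waves
decay into lossy media.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .constants import C_0, EPS_0, MU_0
from .dispersion import VACUUM, DispersionParams, complex_permittivity

__all__ = [
    "Layer",
    "LayerStack",
    "plane_wave_reflection",
    "reflectance_db",
    "absorbed_power_fraction",
    "normal_incidence_curve",
    "reflectance_db_curve",
    "spectral_admittance",
]

NEG_INF_DB = -math.inf  # sentinel for |Gamma| = 0 in reflectance_db


@dataclass(frozen=True)
class Layer:
    """One layer of a stratified medium.

    ``thickness`` is in meters; ``math.inf`` marks the terminal half-space.
    """
    material: DispersionParams
    thickness: float

    def __post_init__(self):
        if not (self.thickness > 0):
            raise ValueError("layer thickness must be > 0 (use math.inf for a half-space)")

    @property
    def is_halfspace(self) -> bool:
        return math.isinf(self.thickness)


@dataclass(frozen=True)
class LayerStack:
    """Ordered layers from the illuminated surface inward.

    The last layer must be the (single) terminal half-space.  The incident
    half-space defaults to vacuum.
    """
    layers: tuple
    incident_medium: DispersionParams = VACUUM
    name: str = field(default="", compare=False)

    def __init__(self, layers: Sequence[Layer], incident_medium: DispersionParams = VACUUM,
                 name: str = ""):
        layers = tuple(layers)
        if not layers:
            raise ValueError("stack needs at least a terminal half-space")
        if not layers[-1].is_halfspace:
            raise ValueError("stack must terminate in a half-space (infinite thickness)")
        if any(ly.is_halfspace for ly in layers[:-1]):
            raise ValueError("only the terminal layer may be a half-space")
        object.__setattr__(self, "layers", layers)
        object.__setattr__(self, "incident_medium", incident_medium)
        object.__setattr__(self, "name", name)

    @property
    def finite_layers(self):
        return self.layers[:-1]

    @property
    def terminal(self) -> Layer:
        return self.layers[-1]


def _kz_branch(kz2):
    """Normal wavenumber from its square: Re >= 0, Im <= 0 branch."""
    kz = np.sqrt(np.asarray(kz2, dtype=complex))
    flip = kz.imag > 0
    kz = np.where(flip, -kz, kz)
    return kz


def _char_impedance(pol, kz, eps, w):
    """TE/TM wave impedance (ratio of transverse E to transverse H)."""
    if pol == "TE":
        return w * MU_0 / kz
    elif pol == "TM":
        return kz / (w * EPS_0 * eps)
    raise ValueError(f"polarization must be 'TE' or 'TM', got {pol!r}")


# tan(kz*d) saturates to -1j once the layer is many skin depths thick; beyond
# this attenuation the layer is numerically a half-space and tan() would lose
# accuracy/overflow.
_OPAQUE_ATTENUATION = 300.0


def _input_impedance(stack: LayerStack, f: float, kt, pol: str):
    """Transverse input impedance of the stack at the first interface.

    ``kt`` is the (conserved) transverse wavenumber in rad/m; scalar or array.
    """
    kt = np.asarray(kt, dtype=float)
    w = 2.0 * math.pi * f
    k0 = w / C_0

    term = stack.terminal.material
    eps_t = complex_permittivity(term, f)
    kz_t = _kz_branch(eps_t * k0**2 - kt**2)
    z = _char_impedance(pol, kz_t, eps_t, w)

    for layer in reversed(stack.finite_layers):
        eps_l = complex_permittivity(layer.material, f)
        kz = _kz_branch(eps_l * k0**2 - kt**2)
        zc = _char_impedance(pol, kz, eps_l, w)
        kzd = kz * layer.thickness
        opaque = -kzd.imag > _OPAQUE_ATTENUATION
        t = np.tan(np.where(opaque, -1j * _OPAQUE_ATTENUATION, kzd))
        z_new = zc * (z + 1j * zc * t) / (zc + 1j * z * t)
        z = np.where(opaque, zc, z_new)
    return z


def plane_wave_reflection(stack: LayerStack, f: float, theta: float = 0.0,
                          pol: str = "TE"):
    """Complex field reflection coefficient Gamma at the first interface.

    Parameters
    ----------
    stack : LayerStack
    f : float
        Frequency in Hz, > 0.
    theta : float
        Incidence angle in radians from the surface normal, 0 <= theta < pi/2,
        measured in the incident half-space.
    pol : 'TE' | 'TM'
        Polarization; at normal incidence the two coincide.

    For passive stacks |Gamma| <= 1.
    """
    if not (f > 0 and np.isfinite(f)):
        raise ValueError("frequency must be finite and > 0")
    if not (0.0 <= theta < math.pi / 2):
        raise ValueError("incidence angle must satisfy 0 <= theta < 90 deg")
    w = 2.0 * math.pi * f
    k0 = w / C_0
    eps_i = complex_permittivity(stack.incident_medium, f)
    ki = _kz_branch(np.asarray(eps_i * k0**2))
    kt = float((ki * math.sin(theta)).real)  # lossless incident medium assumed for oblique
    kz_i = _kz_branch(np.asarray(eps_i * k0**2 - kt**2))
    z_i = _char_impedance(pol, kz_i, eps_i, w)
    z_in = _input_impedance(stack, f, kt, pol)
    gamma = (z_in - z_i) / (z_in + z_i)
    return complex(gamma)


def reflectance_db(stack: LayerStack, f: float, theta: float = 0.0, pol: str = "TE"):
    """``20 log10 |Gamma|`` in dB; <= 0 for passive stacks with a lossless
    incident medium.  A perfectly matched stack (|Gamma| = 0) returns the
    ``-inf`` sentinel."""
    mag = abs(plane_wave_reflection(stack, f, theta, pol))
    if mag == 0.0:
        return NEG_INF_DB
    return 20.0 * math.log10(mag)


def absorbed_power_fraction(stack: LayerStack, f: float, theta: float = 0.0,
                            pol: str = "TE"):
    """Fraction ``1 - |Gamma|^2`` of the incident power density entering the
    stack.  With a lossless incident medium and a lossy terminal half-space
    this equals the absorbed power fraction."""
    mag = abs(plane_wave_reflection(stack, f, theta, pol))
    return 1.0 - mag * mag


def normal_incidence_curve(stack: LayerStack, fgrid):
    """Complex Gamma at normal incidence, vectorized over a frequency grid.

    Fast path used by the fitter and the cohort generator; identical to
    :func:`plane_wave_reflection` with ``theta = 0`` at each frequency.
    """
    f = np.asarray(fgrid, dtype=float)
    if np.any(~np.isfinite(f)) or np.any(f <= 0):
        raise ValueError("frequencies must be finite and > 0")
    w = 2.0 * math.pi * f
    k0 = w / C_0

    def kz_and_z(material, pol="TE"):
        eps = np.asarray(complex_permittivity(material, f))
        kz = _kz_branch(eps * k0**2)
        return kz, w * MU_0 / kz  # TE == TM at normal incidence

    term = stack.terminal.material
    _, z = kz_and_z(term)
    for layer in reversed(stack.finite_layers):
        kz, zc = kz_and_z(layer.material)
        kzd = kz * layer.thickness
        opaque = -kzd.imag > _OPAQUE_ATTENUATION
        t = np.tan(np.where(opaque, -1j * _OPAQUE_ATTENUATION, kzd))
        z_new = zc * (z + 1j * zc * t) / (zc + 1j * z * t)
        z = np.where(opaque, zc, z_new)
    _, z_i = kz_and_z(stack.incident_medium)
    return (z - z_i) / (z + z_i)


def reflectance_db_curve(stack: LayerStack, fgrid):
    """``20 log10 |Gamma|`` at normal incidence over a frequency grid."""
    with np.errstate(divide="ignore"):
        return 20.0 * np.log10(np.abs(normal_incidence_curve(stack, fgrid)))


def spectral_admittance(stack: LayerStack, f: float, kt, pol: str):
    """TE/TM input admittance ``Y(kt) = 1/Z_in(kt)`` of the stack seen from
    its first interface, per transverse wavenumber ``kt`` (rad/m, array-ok).

    This is the layered-half-space response that the open-waveguide
    mode-matching solver weights each exterior plane-wave component with.
    The incident half-space of ``stack`` is ignored: the aperture plane feeds
    the first layer directly.
    """
    return 1.0 / _input_impedance(stack, f, kt, pol)
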