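"""Open-ended rectangular waveguide probe against a stratified medium.

Mode-matching forward model for the TE10 reflection coefficient of a
flanged open-ended rectangular waveguide pressed against a layered
dielectric (the quantity a VNA measures with a waveguide probe on skin or
on a gel phantom).  The flange is assumed infinite and perfectly
conducting; the reference plane is the flange/sample interface.

Formulation
-----------
The aperture tangential electric field is expanded in the waveguide-mode
basis.  The exterior field is written as a 2-D spectrum of TE/TM plane
waves over the layered half-space; each spectral component sees the input
admittance of the stack at its transverse wavenumber (supplied by
:func:`mmskin.layered.spectral_admittance`).  Enforcing continuity of the
tangential magnetic field over the aperture by Galerkin projection onto
the same mode basis yields the dense linear system

    (Y_ext + diag(Y_g)) R = (diag(Y_g) - Y_ext) e_1 ,

whose first component is the TE10 reflection coefficient.  The exterior
admittance matrix is

    Y_ext[q,p] = (1/4 pi^2) Int [ Y_TM(kt) v_q* v_p + Y_TE(kt) u_q* u_p ] d^2k

with u, v the TE/TM (with respect to the surface normal) projections of
the aperture-mode Fourier spectra.  The spectra of rectangular-guide modes
factor into closed-form 1-D sine/cosine transforms, so the only numerics
are the polar-coordinate spectral integrals, evaluated with panelized
Gauss-Legendre quadrature.  Because the terminal half-space is lossy, the
integrand has no singularities on the real kt axis.

Only modes with the symmetry of TE10 (m odd, n even) couple; the default
mode set retains exactly those.  A full (all-parity) mode set is available
as a consistency check - the extra modes must not change S11.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .constants import C_0, EPS_0, MU_0
from .layered import LayerStack, spectral_admittance
from .spectrum import ReflectionSpectrum

__all__ = [
    "RectWaveguideSpec",
    "ModeIndex",
    "MMSettings",
    "WAVEGUIDE_REGISTRY",
    "te10_reflection",
    "te10_transverse_resonance",
    "s11_spectrum",
    "CutoffError",
]


class CutoffError(ValueError):
    """Requested frequency is at or below the TE10 cutoff of the probe."""


@dataclass(frozen=True)
class RectWaveguideSpec:
    """Rectangular waveguide probe geometry and usable band.

    ``a`` and ``b`` are the broad and narrow inner dimensions in meters
    (``a > b > 0``); ``f_lo``/``f_hi`` the band in Hz over which the probe
    is operated.
    """
    name: str
    a: float
    b: float
    f_lo: float
    f_hi: float

    def __post_init__(self):
        if not (self.a > self.b > 0):
            raise ValueError("need a > b > 0")
        if not (0 < self.f_lo < self.f_hi):
            raise ValueError("need 0 < f_lo < f_hi")
        if self.f_lo <= self.te10_cutoff_hz:
            raise ValueError(
                f"{self.name}: f_lo {self.f_lo / 1e9:.2f} GHz is at or below the "
                f"TE10 cutoff {self.te10_cutoff_hz / 1e9:.2f} GHz")

    @property
    def te10_cutoff_hz(self) -> float:
        return C_0 / (2.0 * self.a)


#: EIA standard inner dimensions; bands as operated for skin probing.
#: The nominal quoted floors (14 GHz for WR42, 21 GHz for WR28) sit at or
#: below the air-filled TE10 cutoffs (14.05 / 21.08 GHz); the registry
#: floors are trimmed to usable single-mode frequencies.
WAVEGUIDE_REGISTRY = {
    "WR42": RectWaveguideSpec("WR42", 10.668e-3, 4.318e-3, 15e9, 28e9),
    "WR28": RectWaveguideSpec("WR28", 7.112e-3, 3.556e-3, 22e9, 42e9),
    "WR15": RectWaveguideSpec("WR15", 3.7592e-3, 1.8796e-3, 45e9, 75e9),
    "WR10": RectWaveguideSpec("WR10", 2.54e-3, 1.27e-3, 75e9, 110e9),
}


@dataclass(frozen=True)
class ModeIndex:
    """Rectangular-waveguide mode label: family TE/TM with indices (m, n)."""
    family: str
    m: int
    n: int

    def __post_init__(self):
        if self.family not in ("TE", "TM"):
            raise ValueError("family must be 'TE' or 'TM'")
        if self.m < 0 or self.n < 0:
            raise ValueError("mode indices must be non-negative")
        if self.family == "TE" and self.m == 0 and self.n == 0:
            raise ValueError("TE00 does not exist")
        if self.family == "TM" and (self.m < 1 or self.n < 1):
            raise ValueError("TM modes need m >= 1 and n >= 1")

    def cutoff_wavenumber(self, a: float, b: float) -> float:
        return math.hypot(self.m * math.pi / a, self.n * math.pi / b)


@dataclass(frozen=True)
class MMSettings:
    """Numerical controls of the mode-matching solver.

    ``n_modes`` retained aperture modes (sorted by cutoff); ``kmax_over_k0``
    truncation radius of the spectral integral in units of the free-space
    wavenumber (raised automatically to cover the most evanescent retained
    mode); ``n_radial`` Gauss points per radial panel; ``phi_min`` /
    ``phi_per_rad`` set the angular point count, which grows with the
    electrical radius of the panel to resolve the oscillatory mode spectra;
    ``tol`` is the self-convergence tolerance in dB used by convergence
    checks.
    """
    n_modes: int = 64
    kmax_over_k0: float = 30.0
    n_radial: int = 16
    phi_min: int = 24
    phi_per_rad: float = 0.8
    tol: float = 0.05
    mode_set: str = "coupled"  # 'coupled' (m odd, n even) or 'full'

    def doubled(self) -> "MMSettings":
        """Settings with doubled mode count and quadrature density."""
        return replace(self, n_modes=2 * self.n_modes, n_radial=2 * self.n_radial,
                       phi_min=2 * self.phi_min, phi_per_rad=2 * self.phi_per_rad)


DEFAULT_SETTINGS = MMSettings()


# ---------------------------------------------------------------------------
# mode sets and their aperture-field Fourier spectra

def _mode_list(wg: RectWaveguideSpec, n_modes: int, mode_set: str):
    cands = []
    # generous index search range; 60x60 covers far more than any sane n_modes
    for m in range(0, 61):
        for n in range(0, 61):
            if mode_set == "coupled" and (m % 2 == 0 or n % 2 == 1):
                continue
            if not (m == 0 and n == 0):
                if m >= 0 and n >= 0:
                    try:
                        cands.append(ModeIndex("TE", m, n))
                    except ValueError:
                        pass
            if m >= 1 and n >= 1:
                if mode_set == "coupled" and (m % 2 == 0 or n % 2 == 1):
                    continue
                cands.append(ModeIndex("TM", m, n))
    cands.sort(key=lambda md: (md.cutoff_wavenumber(wg.a, wg.b), md.family, md.m, md.n))
    modes = cands[:n_modes]
    first = modes[0]
    assert first.family == "TE" and first.m == 1 and first.n == 0, "TE10 must lead"
    return modes


def _fc(kappa, k, L):
    """Transform of cos(kappa x) over [-L/2, L/2] against e^{+jkx}; real, even."""
    return (0.5 * L * np.sinc((kappa - k) * L / (2.0 * np.pi))
            + 0.5 * L * np.sinc((kappa + k) * L / (2.0 * np.pi)))


def _gs(kappa, k, L):
    """(1/j) x transform of sin(kappa x) over [-L/2, L/2]; real, odd in k."""
    return (0.5 * L * np.sinc((kappa - k) * L / (2.0 * np.pi))
            - 0.5 * L * np.sinc((kappa + k) * L / (2.0 * np.pi)))


def _shifted_sin_transform(m, L, k):
    """Transform of sin(m pi (x + L/2)/L) on the centered aperture."""
    kappa = m * np.pi / L
    if m % 2 == 1:
        return ((-1.0) ** ((m - 1) // 2)) * _fc(kappa, k, L).astype(complex)
    return ((-1.0) ** (m // 2)) * 1j * _gs(kappa, k, L)


def _shifted_cos_transform(m, L, k):
    """Transform of cos(m pi (x + L/2)/L) on the centered aperture."""
    kappa = m * np.pi / L
    if m % 2 == 1:
        return -((-1.0) ** ((m - 1) // 2)) * 1j * _gs(kappa, k, L)
    return ((-1.0) ** (m // 2)) * _fc(kappa, k, L).astype(complex)


def _mode_spectra(modes, wg: RectWaveguideSpec, kx, ky):
    """Fourier spectra (Ex, Ey) of the orthonormal mode fields at (kx, ky).

    Returns two complex arrays of shape (n_modes, n_nodes).
    """
    a, b = wg.a, wg.b
    n_nodes = kx.size
    Ex = np.zeros((len(modes), n_nodes), dtype=complex)
    Ey = np.zeros_like(Ex)
    for i, md in enumerate(modes):
        kxm = md.m * math.pi / a
        kyn = md.n * math.pi / b
        kc = md.cutoff_wavenumber(a, b)
        if md.family == "TE":
            if md.n == 0:
                norm = math.sqrt(2.0 / (a * b)) / kxm
            elif md.m == 0:
                norm = math.sqrt(2.0 / (a * b)) / kyn
            else:
                norm = 2.0 / (math.sqrt(a * b) * kc)
            cex, cey = norm * kyn, -norm * kxm
        else:
            norm = 2.0 / (math.sqrt(a * b) * kc)
            cex, cey = norm * kxm, norm * kyn
        # e_x ~ cos_m(x') sin_n(y'),  e_y ~ sin_m(x') cos_n(y')
        if cex != 0.0:
            Ex[i] = cex * _shifted_cos_transform(md.m, a, kx) * _shifted_sin_transform(md.n, b, ky)
        Ey[i] = cey * _shifted_sin_transform(md.m, a, kx) * _shifted_cos_transform(md.n, b, ky)
    return Ex, Ey


def _guide_admittances(modes, wg, f):
    """Modal wave admittances of the air-filled guide (complex for
    evanescent modes; Re >= 0, reactive sign set by the branch Im(kz) <= 0)."""
    w = 2.0 * math.pi * f
    k0 = w / C_0
    y = np.empty(len(modes), dtype=complex)
    for i, md in enumerate(modes):
        kc = md.cutoff_wavenumber(wg.a, wg.b)
        kz = np.sqrt(complex(k0 * k0 - kc * kc))
        if kz.imag > 0:
            kz = -kz
        y[i] = kz / (w * MU_0) if md.family == "TE" else w * EPS_0 / kz
    return y


# ---------------------------------------------------------------------------
# spectral integration

def _radial_panels(k0, kmax):
    """Panel edges for the radial integral: fine near the visible region and
    the quasi-static knee, geometric growth outward."""
    edges = [e * k0 for e in (0.0, 0.5, 1.0, 1.5, 2.0, 3.0, 4.0, 6.0, 8.0) if e * k0 < kmax]
    e = 8.0 * k0
    while e < kmax:
        e = min(e * 1.6, kmax)
        edges.append(e)
    if edges[-1] < kmax:
        edges.append(kmax)
    return np.asarray(edges)


def _exterior_admittance_matrix(modes, wg, stack, f, settings: MMSettings):
    w = 2.0 * math.pi * f
    k0 = w / C_0
    kc_max = max(md.cutoff_wavenumber(wg.a, wg.b) for md in modes)
    kmax = max(settings.kmax_over_k0 * k0, 2.5 * kc_max)
    edges = _radial_panels(k0, kmax)
    xg, wg_ = np.polynomial.legendre.leggauss(settings.n_radial)

    uniform_parity = all(md.m % 2 == 1 and md.n % 2 == 0 for md in modes)
    sign_combos = [(1.0, 1.0)] if uniform_parity else [(1, 1), (-1, 1), (1, -1), (-1, -1)]
    quadrant_factor = 4.0 if uniform_parity else 1.0

    P = len(modes)
    Y = np.zeros((P, P), dtype=complex)
    dim = max(wg.a, wg.b)
    for lo, hi in zip(edges[:-1], edges[1:]):
        kt = 0.5 * (hi - lo) * xg + 0.5 * (hi + lo)
        wkt = 0.5 * (hi - lo) * wg_
        n_phi = settings.phi_min + int(settings.phi_per_rad * hi * dim / 2.0)
        xp, wp = np.polynomial.legendre.leggauss(n_phi)
        phi = 0.25 * math.pi * (xp + 1.0)
        wphi = 0.25 * math.pi * wp

        y_te = np.asarray(spectral_admittance(stack, f, kt, "TE"))
        y_tm = np.asarray(spectral_admittance(stack, f, kt, "TM"))

        # tensor nodes (radial x angular)
        KT = kt[:, None]
        KX0 = (KT * np.cos(phi)[None, :]).ravel()
        KY0 = (KT * np.sin(phi)[None, :]).ravel()
        WT = (kt * wkt)[:, None] * wphi[None, :]
        w_te = (y_te[:, None] * WT).ravel()
        w_tm = (y_tm[:, None] * WT).ravel()
        kt_nodes = np.repeat(kt, n_phi)

        for sx, sy in sign_combos:
            KX, KY = sx * KX0, sy * KY0
            Ex, Ey = _mode_spectra(modes, wg, KX, KY)
            cphi, sphi = KX / kt_nodes, KY / kt_nodes
            U = -sphi[None, :] * Ex + cphi[None, :] * Ey   # TE (w.r.t. z) projection
            V = cphi[None, :] * Ex + sphi[None, :] * Ey    # TM projection
            Y += (U.conj() * w_te[None, :]) @ U.T + (V.conj() * w_tm[None, :]) @ V.T

    return Y * (quadrant_factor / (4.0 * math.pi ** 2))


# ---------------------------------------------------------------------------
# public operations

def te10_reflection(wg: RectWaveguideSpec, stack: LayerStack, f: float,
                    settings: MMSettings = DEFAULT_SETTINGS) -> complex:
    """Complex TE10 reflection coefficient at the flange/sample plane.

    Raises :class:`CutoffError` below the TE10 cutoff.  The stack's
    ``incident_medium`` is ignored: the first layer starts at the aperture.
    For passive stacks ``|S11| <= 1``.
    """
    if not (f > 0 and np.isfinite(f)):
        raise ValueError("frequency must be finite and > 0")
    if f <= wg.te10_cutoff_hz:
        raise CutoffError(
            f"{f / 1e9:.3f} GHz is at or below the TE10 cutoff of {wg.name} "
            f"({wg.te10_cutoff_hz / 1e9:.3f} GHz)")
    modes = _mode_list(wg, settings.n_modes, settings.mode_set)
    y_g = _guide_admittances(modes, wg, f)
    y_ext = _exterior_admittance_matrix(modes, wg, stack, f, settings)
    A = y_ext + np.diag(y_g)
    rhs = -y_ext[:, 0].copy()
    rhs[0] += y_g[0]
    R = np.linalg.solve(A, rhs)
    return complex(R[0])


def te10_transverse_resonance(wg: RectWaveguideSpec, stack: LayerStack,
                              f: float) -> complex:
    """Single-mode approximation ignoring aperture (fringing-field) coupling.

    The exterior is collapsed to the layered TE input admittance at the
    TE10 transverse wavenumber pi/a.  Used as a reference to quantify how
    much the fringing fields, captured by the full mode-matching solution,
    matter.
    """
    if f <= wg.te10_cutoff_hz:
        raise CutoffError("below TE10 cutoff")
    w = 2.0 * math.pi * f
    k0 = w / C_0
    kc = math.pi / wg.a
    kz = np.sqrt(complex(k0 * k0 - kc * kc))
    if kz.imag > 0:
        kz = -kz
    y_g = kz / (w * MU_0)
    y_l = complex(np.asarray(spectral_admittance(stack, f, np.array([kc]), "TE"))[0])
    return complex((y_g - y_l) / (y_g + y_l))


def s11_spectrum(wg: RectWaveguideSpec, stack: LayerStack, fgrid,
                 settings: MMSettings = DEFAULT_SETTINGS) -> ReflectionSpectrum:
    """Vectorized :func:`te10_reflection` over a frequency grid."""
    fgrid = np.atleast_1d(np.asarray(fgrid, dtype=float))
    s11 = np.array([te10_reflection(wg, stack, f, settings) for f in fgrid])
    meta = {
        "probe": wg.name,
        "stack": stack.name or repr([ly.material.name for ly in stack.layers]),
        "solver": "mode-matching",
        "n_modes": settings.n_modes,
        "mode_set": settings.mode_set,
        "kmax_over_k0": settings.kmax_over_k0,
    }
    return ReflectionSpectrum(fgrid, s11, meta)
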