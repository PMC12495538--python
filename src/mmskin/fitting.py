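"""Recover dispersive skin-layer parameters from reflection spectra.

Two constrained least-squares problems, both solved by SQP (scipy's SLSQP)
with seeded multi-start to mitigate local minima:

* :func:`fit_layer_d` - the inner-skin half-space ("Layer D") Debye
  parameters, with a fixed thin stratum-corneum cover layer;
* :func:`fit_sc_thick` - the thick stratum-corneum thickness and Debye
  parameters, with Layer D held fixed.

The objective is the summed squared deviation of the *dB magnitude* of the
reflection coefficient from the target, all frequency points weighted
equally; population statistics and coverage curves are dB-magnitude
quantities, and measured phase is not available for cohort means.  The
forward model is either the open-waveguide mode-matching solver (the
physically faithful choice, matching how probe data are taken) or the
normal-incidence plane-wave solver as a fast approximation for screening
and large simulation studies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import minimize

from .dispersion import DispersionParams
from .layered import Layer, LayerStack, reflectance_db_curve
from .spectrum import ReflectionSpectrum
from .waveguide import DEFAULT_SETTINGS, MMSettings, WAVEGUIDE_REGISTRY, te10_reflection

__all__ = ["FitTarget", "FitResult", "fit_layer_d", "fit_sc_thick"]


@dataclass
class FitTarget:
    """Multi-band dB-magnitude fit target.

    ``bands`` is a sequence of ``(probe_name, f_hz, s11_db)`` tuples, one
    per waveguide band; overlapping frequencies across bands are kept (each
    point counts once per band it appears in, after nearest-grid merging of
    near-duplicates).  ``percentile_label`` records which population curve
    the target is ('mean', 'mean-1sd', 'mean-2sd', ...).
    """
    bands: Sequence[tuple]
    percentile_label: str = "mean"

    @classmethod
    def from_spectra(cls, spectra: Sequence[ReflectionSpectrum],
                     percentile_label: str = "mean") -> "FitTarget":
        bands = [(sp.meta.get("probe", ""), sp.f_hz.copy(), sp.magnitude_db.copy())
                 for sp in spectra]
        return cls(bands, percentile_label)

    def merged(self):
        """(probe_per_point, f, db) arrays with near-duplicate frequencies
        (within 0.1% relative) merged onto the first band's grid point."""
        probes, fs, dbs = [], [], []
        for probe, f, db in self.bands:
            f = np.asarray(f, dtype=float)
            db = np.asarray(db, dtype=float)
            if not np.all(np.isfinite(db)):
                raise ValueError("fit target contains non-finite dB values")
            probes.extend([probe] * f.size)
            fs.append(f)
            dbs.append(db)
        f = np.concatenate(fs)
        db = np.concatenate(dbs)
        probes = np.asarray(probes)
        order = np.argsort(f, kind="stable")
        f, db, probes = f[order], db[order], probes[order]
        keep = np.ones(f.size, dtype=bool)
        for i in range(1, f.size):
            if f[i] - f[i - 1] <= 1e-3 * f[i] and probes[i] == probes[i - 1]:
                keep[i] = False
        return probes[keep], f[keep], db[keep]


@dataclass
class FitResult:
    """Outcome of a layer-parameter fit."""
    params: DispersionParams
    thickness_m: Optional[float]
    residual_max_db: float
    residual_rms_db: float
    n_iter: int
    converged: bool
    bounds_active: list = field(default_factory=list)
    objective: float = math.nan
    n_starts: int = 1
    percentile_label: str = "mean"

    def __post_init__(self):
        if self.converged and not (self.residual_max_db >= self.residual_rms_db >= 0):
            raise ValueError("residuals must satisfy max >= rms >= 0")


# default box bounds, chosen to bracket reported skin-tissue values broadly
LAYER_D_BOUNDS = {"eps_inf": (1.0, 20.0), "eps_s": (5.0, 80.0),
                  "sigma": (0.0, 20.0), "tau_ps": (1.0, 30.0)}
SC_THICK_BOUNDS = {"d_um": (50.0, 600.0), "eps_inf": (1.0, 10.0),
                   "eps_s": (1.5, 25.0), "tau_ps": (0.2, 20.0)}


def _forward_db(stack: LayerStack, probes, f, forward: str, settings: MMSettings):
    if forward == "planewave":
        return reflectance_db_curve(stack, f)
    if forward == "mm":
        out = np.empty(f.size)
        for i, (p, fi) in enumerate(zip(probes, f)):
            wg = WAVEGUIDE_REGISTRY[p]
            out[i] = 20.0 * math.log10(abs(te10_reflection(wg, stack, fi, settings)))
        return out
    raise ValueError("forward must be 'planewave' or 'mm'")


def _check_bounds(bounds):
    for key, (lo, hi) in bounds.items():
        if not lo < hi:
            raise ValueError(f"empty bound interval for {key}")
    if "eps_s" in bounds and "eps_inf" in bounds:
        if bounds["eps_s"][1] <= bounds["eps_inf"][0]:
            raise ValueError("infeasible bounds: eps_s upper bound <= eps_inf lower bound")


def _multistart_sqp(objective, x0_list, bounds_arr, constraints, maxiter):
    best = None
    n_iter_total = 0
    for x0 in x0_list:
        sol = minimize(objective, x0, method="SLSQP",
                       bounds=list(map(tuple, bounds_arr)),
                       constraints=constraints,
                       options={"maxiter": maxiter, "ftol": 1e-16})
        n_iter_total += sol.nit
        if best is None or sol.fun < best.fun:
            best = sol
        if best.fun < 1e-16:
            break
    return best, n_iter_total


def _active_bounds(x, bounds_arr, names):
    act = []
    for xi, (lo, hi), nm in zip(x, bounds_arr, names):
        span = hi - lo
        if xi - lo < 1e-6 * span:
            act.append(f"{nm}:lower")
        elif hi - xi < 1e-6 * span:
            act.append(f"{nm}:upper")
    return act


def _seeded_starts(rng, init_x, bounds_arr, n_starts):
    starts = [np.asarray(init_x, dtype=float)]
    lo = bounds_arr[:, 0]
    hi = bounds_arr[:, 1]
    for _ in range(n_starts - 1):
        starts.append(lo + rng.random(lo.size) * (hi - lo))
    return starts


def fit_layer_d(target: FitTarget, sc_layer: Layer, *,
                init: Optional[DispersionParams] = None,
                bounds: Optional[dict] = None,
                forward: str = "planewave",
                settings: MMSettings = DEFAULT_SETTINGS,
                n_starts: int = 8, seed: int = 0,
                maxiter: int = 200) -> FitResult:
    """Fit Debye parameters of the inner-skin half-space below a fixed
    stratum-corneum cover layer to a multi-band dB reflection target.

    Free parameters: ``eps_inf, eps_s, sigma, tau`` (``alpha`` fixed to 0).
    Requires a target spanning at least two probe bands so the relaxation
    is constrained over a wide enough frequency range.
    """
    if len(target.bands) < 2:
        raise ValueError("target must cover at least two probe bands")
    bounds = dict(LAYER_D_BOUNDS, **(bounds or {}))
    _check_bounds(bounds)
    probes, f, db_t = target.merged()
    names = ["eps_inf", "eps_s", "sigma", "tau_ps"]
    bounds_arr = np.array([bounds[n] for n in names], dtype=float)

    def make_stack(x):
        eps_inf, eps_s, sigma, tau_ps = x
        d = DispersionParams(eps_inf=eps_inf, eps_s=max(eps_s, eps_inf), sigma=sigma,
                             tau=tau_ps * 1e-12, alpha=0.0)
        return LayerStack([sc_layer, Layer(d, math.inf)])

    def objective(x):
        db = _forward_db(make_stack(x), probes, f, forward, settings)
        r = db - db_t
        return float(r @ r)

    if init is None:
        init_x = [5.0, 40.0, 5.0, 9.0]
    else:
        init_x = [init.eps_inf, init.eps_s, init.sigma, init.tau * 1e12]
    rng = np.random.default_rng(seed)
    cons = [{"type": "ineq", "fun": lambda x: x[1] - x[0]}]  # eps_s >= eps_inf
    best, n_iter = _multistart_sqp(objective, _seeded_starts(rng, init_x, bounds_arr, n_starts),
                                   bounds_arr, cons, maxiter)
    resid = _forward_db(make_stack(best.x), probes, f, forward, settings) - db_t
    params = DispersionParams(best.x[0], max(best.x[1], best.x[0]), best.x[2],
                              best.x[3] * 1e-12, 0.0, name="layer_d_fit")
    return FitResult(
        params=params, thickness_m=None,
        residual_max_db=float(np.max(np.abs(resid))),
        residual_rms_db=float(np.sqrt(np.mean(resid ** 2))),
        n_iter=n_iter, converged=bool(best.success and np.isfinite(best.fun)),
        bounds_active=_active_bounds(best.x, bounds_arr, names),
        objective=float(best.fun), n_starts=n_starts,
        percentile_label=target.percentile_label)


def fit_sc_thick(target: FitTarget, layer_d: DispersionParams, *,
                 init: Optional[tuple] = None,
                 bounds: Optional[dict] = None,
                 forward: str = "planewave",
                 settings: MMSettings = DEFAULT_SETTINGS,
                 n_starts: int = 8, seed: int = 0,
                 maxiter: int = 200) -> FitResult:
    """Fit thick-stratum-corneum thickness and Debye parameters over a
    fixed inner-skin half-space.

    Free parameters: thickness (um), ``eps_inf, eps_s, tau``; the surface
    layer's conductivity is fixed at zero (the low-water stratum corneum is
    essentially non-conducting).  ``init`` is an optional
    ``(thickness_um, DispersionParams)`` pair.
    """
    bounds = dict(SC_THICK_BOUNDS, **(bounds or {}))
    _check_bounds(bounds)
    probes, f, db_t = target.merged()
    names = ["d_um", "eps_inf", "eps_s", "tau_ps"]
    bounds_arr = np.array([bounds[n] for n in names], dtype=float)

    def make_stack(x):
        d_um, eps_inf, eps_s, tau_ps = x
        sc = DispersionParams(eps_inf=eps_inf, eps_s=max(eps_s, eps_inf), sigma=0.0,
                              tau=tau_ps * 1e-12, alpha=0.0)
        return LayerStack([Layer(sc, d_um * 1e-6), Layer(layer_d, math.inf)])

    def objective(x):
        db = _forward_db(make_stack(x), probes, f, forward, settings)
        r = db - db_t
        return float(r @ r)

    if init is None:
        init_x = [220.0, 3.5, 8.0, 2.0]
    else:
        d0, p0 = init
        init_x = [d0, p0.eps_inf, p0.eps_s, p0.tau * 1e12]
    rng = np.random.default_rng(seed)
    cons = [{"type": "ineq", "fun": lambda x: x[2] - x[1]}]
    best, n_iter = _multistart_sqp(objective, _seeded_starts(rng, init_x, bounds_arr, n_starts),
                                   bounds_arr, cons, maxiter)
    resid = _forward_db(make_stack(best.x), probes, f, forward, settings) - db_t
    params = DispersionParams(best.x[1], max(best.x[2], best.x[1]), 0.0,
                              best.x[3] * 1e-12, 0.0, name="sc_thick_fit")
    return FitResult(
        params=params, thickness_m=float(best.x[0]) * 1e-6,
        residual_max_db=float(np.max(np.abs(resid))),
        residual_rms_db=float(np.sqrt(np.mean(resid ** 2))),
        n_iter=n_iter, converged=bool(best.success and np.isfinite(best.fun)),
        bounds_active=_active_bounds(best.x, bounds_arr, names),
        objective=float(best.fun), n_starts=n_starts,
        percentile_label=target.percentile_label)
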