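"""Recover skin-layer parameters from reflection spectra by SQP fitting.

Builds noise-free dB reflection targets from a known two-layer skin model
over the four probe bands, then refits (a) the inner-layer Debye
parameters under a fixed 20 um stratum corneum and (b) the thick
stratum-corneum thickness and parameters.  At zero noise the fit should
return the generating parameters essentially exactly.
"""

import math

import numpy as np

from mmskin import Layer, LayerStack, fit_layer_d, fit_sc_thick, reflectance_db_curve
from mmskin.fitting import FitTarget
from mmskin.io import default_registry

reg = default_registry()
GRIDS = {"WR42": np.linspace(15e9, 28e9, 14), "WR28": np.linspace(22e9, 42e9, 21),
         "WR15": np.linspace(45e9, 75e9, 16), "WR10": np.linspace(75e9, 110e9, 15)}


def target_from(stack):
    return FitTarget([(p, f, reflectance_db_curve(stack, f))
                      for p, f in GRIDS.items()])


truth = reg.material("layer_d_mean")
sc = Layer(reg.material("sc_thin"), 20e-6)
res = fit_layer_d(target_from(LayerStack([sc, Layer(truth, math.inf)])), sc, seed=1)
print("inner-layer fit (truth -> recovered):")
print(f"  eps_inf {truth.eps_inf:6.2f} -> {res.params.eps_inf:6.2f}")
print(f"  eps_s   {truth.eps_s:6.2f} -> {res.params.eps_s:6.2f}")
print(f"  sigma   {truth.sigma:6.2f} -> {res.params.sigma:6.2f} S/m")
print(f"  tau     {truth.tau * 1e12:6.2f} -> {res.params.tau * 1e12:6.2f} ps")
print(f"  worst residual {res.residual_max_db:.2e} dB over "
      f"{sum(len(g) for g in GRIDS.values())} points, {res.n_iter} iterations")

res_t = fit_sc_thick(target_from(reg.stack("skin_thick1")),
                     reg.material("layer_d_mean"), seed=1)
print(f"\nthick stratum-corneum fit: thickness {res_t.thickness_m * 1e6:.1f} um "
      f"(truth 227), residual {res_t.residual_max_db:.2e} dB")
print("\nResiduals at the numerical-noise floor mean the spectra identify "
      "the layer parameters uniquely over this bandwidth.")
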