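"""Plane-wave reflectance of the population-coverage skin models.

Computes the normal-incidence reflection coefficient of the mean, 68%- and
95%-coverage thin-skin models from 10 to 110 GHz and prints the band-edge
values.  The 95%-coverage model reflects less (absorbs more) than the mean
model everywhere - that margin is what makes it a conservative choice for
absorbed-power-density compliance assessment.
"""

import numpy as np

from mmskin import absorbed_power_fraction, reflectance_db, reflectance_db_curve
from mmskin.io import default_registry

reg = default_registry()
f = np.linspace(10e9, 110e9, 11)

print(f"{'f (GHz)':>8}", *(f"{n:>14}" for n in ("mean", "68% cov", "95% cov")))
curves = {n: reflectance_db_curve(reg.stack(f"skin_thin_{n}"), f)
          for n in ("mean", "p68", "p95")}
for i, fi in enumerate(f):
    print(f"{fi / 1e9:8.0f}", *(f"{curves[n][i]:12.2f} dB"
                                for n in ("mean", "p68", "p95")))

p95 = reg.stack("skin_thin_p95")
mean = reg.stack("skin_thin_mean")
for fi in (15e9, 110e9):
    r = reflectance_db(p95, fi)
    a = absorbed_power_fraction(p95, fi)
    margin = reflectance_db(mean, fi) - r
    print(f"\n95% coverage model at {fi / 1e9:.0f} GHz: {r:.2f} dB reflected "
          f"({a * 100:.0f}% of incident power absorbed); "
          f"{margin:.2f} dB more absorption than the mean model")

print("\nReflectance falls monotonically with frequency: the 20 um stratum "
      "corneum acts as an impedance-matching layer at millimeter waves.")
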