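"""Mode-matching reflection of an open waveguide probe on a gel phantom.

Simulates what a WR28 open-ended rectangular waveguide with an infinite
flange measures against a tissue-simulating gel covered by 100 um of PTFE,
and compares it with the naive single-mode shortcut that ignores the
fringing fields spilling past the aperture.  The difference shows why the
fringing contribution must be modeled for low-permittivity cover layers.
"""

import math

import numpy as np

from mmskin import MMSettings, WAVEGUIDE_REGISTRY, s11_spectrum, te10_transverse_resonance
from mmskin.io import default_registry

reg = default_registry()
wg = WAVEGUIDE_REGISTRY["WR28"]
stack = reg.stack("gel_ptfe100")
f = np.linspace(24e9, 42e9, 7)

spec = s11_spectrum(wg, stack, f)
print(f"{'f (GHz)':>8} {'MM |S11| (dB)':>14} {'single-mode (dB)':>17} {'diff':>7}")
for fi, s in zip(spec.f_hz, spec.s11):
    mm_db = 20 * math.log10(abs(s))
    tr_db = 20 * math.log10(abs(te10_transverse_resonance(wg, stack, fi)))
    print(f"{fi / 1e9:8.1f} {mm_db:14.3f} {tr_db:17.3f} {mm_db - tr_db:7.3f}")

print("\nThe mode-matching solution differs from the aperture-free "
      "single-mode estimate by several tenths of a dB: the reactive "
      "fringing fields load the aperture and cannot be neglected.")

doubled = MMSettings().doubled()
s1 = spec.s11[3]
s2 = s11_spectrum(wg, stack, [f[3]], doubled).s11[0]
print(f"\nSelf-convergence at {f[3] / 1e9:.0f} GHz: doubling the retained "
      f"modes and quadrature changes |S11| by "
      f"{abs(20 * math.log10(abs(s1)) - 20 * math.log10(abs(s2))):.4f} dB.")
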