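"""Physical constants (CODATA 2018) and the package-wide sign convention.

All field quantities follow the electrical-engineering time convention
``e^{+j omega t}``: lossy media have complex permittivity with a *negative*
imaginary part, and waves decaying in +z carry ``e^{-j k z}`` with
``Im(k) <= 0``.  Every solver in the package uses this convention.
"""

EPS_0 = 8.8541878128e-12  # vacuum permittivity, F/m
MU_0 = 1.25663706212e-6   # vacuum permeability, H/m
C_0 = 299792458.0         # speed of light in vacuum, m/s
ETA_0 = 376.730313668     # impedance of free space, ohm
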