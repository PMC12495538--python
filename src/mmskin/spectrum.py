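"""Reflection-spectrum container shared by solvers, I/O, and fitting."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ReflectionSpectrum"]


@dataclass
class ReflectionSpectrum:
    """Complex one-port reflection coefficient versus frequency.

    ``f_hz`` must be strictly increasing.  ``s11`` holds the complex field
    reflection coefficient; dB magnitude is derived on demand.  ``meta``
    records provenance (probe, stack, solver settings, seeds).
    """

    f_hz: np.ndarray
    s11: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.f_hz = np.asarray(self.f_hz, dtype=float)
        self.s11 = np.asarray(self.s11, dtype=complex)
        if self.f_hz.ndim != 1 or self.f_hz.shape != self.s11.shape:
            raise ValueError("f_hz and s11 must be 1-D arrays of equal length")
        if self.f_hz.size == 0:
            raise ValueError("empty spectrum")
        if np.any(np.diff(self.f_hz) <= 0):
            raise ValueError("frequencies must be strictly increasing")

    def __len__(self):
        return self.f_hz.size

    @property
    def magnitude_db(self) -> np.ndarray:
        with np.errstate(divide="ignore"):
            return 20.0 * np.log10(np.abs(self.s11))

    @property
    def phase_deg(self) -> np.ndarray:
        return np.degrees(np.angle(self.s11))
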