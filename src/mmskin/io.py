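"""Spectrum file formats and the dielectric model registry.

Touchstone 1.x one-port files (.s1p) and plain CSV are supported for
reflection spectra.  Dielectric models and layer stacks are described in
YAML with the file conventions of the printed parameter tables: relaxation
times in picoseconds, thicknesses in micrometers (``inf`` for a terminal
half-space); both are converted to SI exactly once, here.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from .dispersion import DispersionParams
from .layered import Layer, LayerStack
from .spectrum import ReflectionSpectrum

__all__ = [
    "read_spectrum",
    "write_spectrum",
    "ModelRegistry",
    "load_model_registry",
    "default_registry",
    "SpectrumParseError",
]


class SpectrumParseError(ValueError):
    """Malformed spectrum file; carries the offending line number."""

    def __init__(self, message, line_no=None):
        super().__init__(message if line_no is None else f"line {line_no}: {message}")
        self.line_no = line_no


_UNIT_HZ = {"HZ": 1.0, "KHZ": 1e3, "MHZ": 1e6, "GHZ": 1e9}


def _parse_touchstone(lines):
    unit = 1e9
    fmt = "MA"
    data = []
    option_seen = False
    for no, raw in enumerate(lines, start=1):
        line = raw.split("!", 1)[0].strip()
        if not line:
            continue
        if line.startswith("#"):
            if option_seen:
                raise SpectrumParseError("duplicate option line", no)
            option_seen = True
            toks = line[1:].upper().split()
            i = 0
            while i < len(toks):
                t = toks[i]
                if t in _UNIT_HZ:
                    unit = _UNIT_HZ[t]
                elif t in ("RI", "MA", "DB"):
                    fmt = t
                elif t == "S":
                    pass
                elif t == "R":
                    i += 1  # reference impedance value, ignored for S11
                else:
                    raise SpectrumParseError(f"unknown option token {t!r}", no)
                i += 1
            continue
        parts = line.split()
        if len(parts) < 3:
            raise SpectrumParseError("expected 'freq val1 val2'", no)
        try:
            f, a, b = (float(parts[0]), float(parts[1]), float(parts[2]))
        except ValueError:
            raise SpectrumParseError("non-numeric data", no) from None
        data.append((f * unit, a, b, no))
    if not data:
        raise SpectrumParseError("no data lines found")
    f = np.array([d[0] for d in data])
    if np.any(np.diff(f) <= 0):
        i = int(np.argmax(np.diff(f) <= 0))
        raise SpectrumParseError("frequencies not strictly increasing", data[i + 1][3])
    a = np.array([d[1] for d in data])
    b = np.array([d[2] for d in data])
    if fmt == "RI":
        s = a + 1j * b
    elif fmt == "MA":
        s = a * np.exp(1j * np.radians(b))
    else:  # DB
        s = 10.0 ** (a / 20.0) * np.exp(1j * np.radians(b))
    return f, s, fmt


def read_spectrum(path) -> ReflectionSpectrum:
    """Read a one-port spectrum from Touchstone .s1p or CSV.

    CSV files need a header with columns ``f_hz, re, im`` (or
    ``f_hz, mag_db, phase_deg``).  The dialect is chosen by file suffix.
    """
    path = Path(path)
    if path.suffix.lower() == ".s1p":
        f, s, fmt = _parse_touchstone(path.read_text().splitlines())
        meta = {"source": str(path), "dialect": "touchstone", "format": fmt}
        return ReflectionSpectrum(f, s, meta)
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        cols = [c.strip() for c in reader.fieldnames or []]
        rows = list(reader)
    if not rows:
        raise SpectrumParseError("empty CSV")
    if {"f_hz", "re", "im"} <= set(cols):
        f = np.array([float(r["f_hz"]) for r in rows])
        s = np.array([float(r["re"]) + 1j * float(r["im"]) for r in rows])
    elif {"f_hz", "mag_db", "phase_deg"} <= set(cols):
        f = np.array([float(r["f_hz"]) for r in rows])
        mag = 10.0 ** (np.array([float(r["mag_db"]) for r in rows]) / 20.0)
        ph = np.radians([float(r["phase_deg"]) for r in rows])
        s = mag * np.exp(1j * ph)
    else:
        raise SpectrumParseError(
            f"CSV needs columns (f_hz, re, im) or (f_hz, mag_db, phase_deg); got {cols}")
    return ReflectionSpectrum(f, s, {"source": str(path), "dialect": "csv"})


def write_spectrum(spectrum: ReflectionSpectrum, path, fmt: str = "RI") -> None:
    """Write Touchstone .s1p (RI/MA/DB, GHz) or CSV by file suffix."""
    path = Path(path)
    if path.suffix.lower() == ".s1p":
        if fmt not in ("RI", "MA", "DB"):
            raise ValueError("fmt must be RI, MA or DB")
        lines = [f"! {spectrum.meta.get('probe', 'one-port')} reflection spectrum",
                 f"# GHz S {fmt} R 50"]
        for f, s in zip(spectrum.f_hz, spectrum.s11):
            if fmt == "RI":
                a, b = s.real, s.imag
            elif fmt == "MA":
                a, b = abs(s), math.degrees(np.angle(s))
            else:
                a, b = 20.0 * math.log10(abs(s)), math.degrees(np.angle(s))
            lines.append(f"{f / 1e9:.12g} {a:.12e} {b:.12e}")
        path.write_text("\n".join(lines) + "\n")
        return
    with path.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["f_hz", "re", "im"])
        for f, s in zip(spectrum.f_hz, spectrum.s11):
            w.writerow([f"{f:.12g}", f"{s.real:.12e}", f"{s.imag:.12e}"])


# ---------------------------------------------------------------------------
# model registry

_MATERIAL_KEYS = {"name", "eps_inf", "eps_s", "sigma_S_per_m", "tau_ps", "alpha", "d_um"}


@dataclass
class ModelRegistry:
    """Named dielectric materials and layer stacks loaded from YAML."""
    materials: dict
    stacks: dict
    default_thickness_um: dict

    def material(self, name: str) -> DispersionParams:
        return self.materials[name]

    def stack(self, name: str) -> LayerStack:
        return self.stacks[name]


def _parse_material(entry, path):
    unknown = set(entry) - _MATERIAL_KEYS
    if unknown:
        raise ValueError(f"{path}: unknown material keys {sorted(unknown)}")
    missing = {"name", "eps_inf", "eps_s"} - set(entry)
    if missing:
        raise ValueError(f"{path}: material missing keys {sorted(missing)}")
    params = DispersionParams(
        eps_inf=float(entry["eps_inf"]),
        eps_s=float(entry["eps_s"]),
        sigma=float(entry.get("sigma_S_per_m", 0.0)),
        tau=float(entry.get("tau_ps", 0.0)) * 1e-12,
        alpha=float(entry.get("alpha", 0.0)),
        name=str(entry["name"]))
    d_um = entry.get("d_um")
    if d_um is not None:
        d_um = math.inf if str(d_um).lower() in ("inf", ".inf", "infinity") else float(d_um)
    return params, d_um


def load_model_registry(paths) -> ModelRegistry:
    """Load one or more YAML model files into a validated registry.

    Each file may hold a ``materials:`` list (printed-table conventions:
    ``tau_ps`` picoseconds, ``d_um`` micrometers or ``inf``) and a
    ``stacks:`` list whose layers reference materials by name, optionally
    overriding the material's default thickness.  Duplicate names raise.
    """
    if isinstance(paths, (str, Path)):
        paths = [paths]
    materials, stacks, default_d = {}, {}, {}
    stack_defs = []
    for path in paths:
        doc = yaml.safe_load(Path(path).read_text()) or {}
        for entry in doc.get("materials", []):
            params, d_um = _parse_material(entry, path)
            if params.name in materials:
                raise ValueError(f"duplicate material name {params.name!r}")
            materials[params.name] = params
            if d_um is not None:
                default_d[params.name] = d_um
        for entry in doc.get("stacks", []):
            stack_defs.append((entry, path))
    for entry, path in stack_defs:
        name = entry.get("name")
        if name is None or "layers" not in entry:
            raise ValueError(f"{path}: stack needs 'name' and 'layers'")
        if name in stacks:
            raise ValueError(f"duplicate stack name {name!r}")
        layers = []
        for ly in entry["layers"]:
            mat = materials.get(ly["material"])
            if mat is None:
                raise ValueError(f"{path}: stack {name!r} references unknown "
                                 f"material {ly['material']!r}")
            d_um = ly.get("d_um", default_d.get(ly["material"]))
            if d_um is None:
                raise ValueError(f"{path}: no thickness for {ly['material']!r} "
                                 f"in stack {name!r}")
            d_um = math.inf if str(d_um).lower() in ("inf", ".inf", "infinity") else float(d_um)
            thickness = d_um if math.isinf(d_um) else d_um * 1e-6
            layers.append(Layer(mat, thickness))
        stacks[name] = LayerStack(layers, name=name)
    return ModelRegistry(materials, stacks, default_d)


def default_registry() -> ModelRegistry:
    """Registry of the shipped gel-validation and skin model files."""
    base = resources.files("mmskin").joinpath("data")
    with resources.as_file(base) as d:
        return load_model_registry(sorted(Path(d).glob("*.yaml")))
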