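"""Stratified-media plane-wave reflection against closed forms and an
independent transfer-matrix oracle."""

import cmath
import math

import numpy as np
import pytest

from mmskin.constants import C_0, EPS_0, MU_0
from mmskin.dispersion import DispersionParams, complex_permittivity
from mmskin.layered import (Layer, LayerStack, absorbed_power_fraction,
                            normal_incidence_curve, plane_wave_reflection,
                            reflectance_db, reflectance_db_curve)

from conftest import random_stack


def transfer_matrix_reflection(stack, f, theta=0.0, pol="TE"):
    """Independent oracle: 2x2 ABCD cascade of transmission-line sections.

    Implemented from the textbook matrix form (not the recursive impedance
    transform used by the package).
    """
    w = 2 * math.pi * f
    k0 = w / C_0

    def kz_of(material):
        eps = complex_permittivity(material, f)
        kz = cmath.sqrt(eps * k0**2 - kt**2)
        if kz.imag > 0:
            kz = -kz
        return kz, eps

    eps_i = complex_permittivity(stack.incident_medium, f)
    kt = (cmath.sqrt(eps_i) * k0).real * math.sin(theta)

    def z_of(kz, eps):
        return w * MU_0 / kz if pol == "TE" else kz / (w * EPS_0 * eps)

    M = np.eye(2, dtype=complex)
    for layer in stack.finite_layers:
        kz, eps = kz_of(layer.material)
        z = z_of(kz, eps)
        kd = kz * layer.thickness
        M = M @ np.array([[np.cos(kd), 1j * z * np.sin(kd)],
                          [1j * np.sin(kd) / z, np.cos(kd)]])
    kz_t, eps_t = kz_of(stack.terminal.material)
    z_t = z_of(kz_t, eps_t)
    kz_i, _ = kz_of(stack.incident_medium)
    z_i = z_of(kz_i, eps_i)
    num = M[0, 0] * z_t + M[0, 1] - z_i * (M[1, 0] * z_t + M[1, 1])
    den = M[0, 0] * z_t + M[0, 1] + z_i * (M[1, 0] * z_t + M[1, 1])
    return num / den


class TestClosedForms:
    def test_single_interface_fresnel(self):
        for eps in (2.0, 4.0, 30.0):
            st = LayerStack([Layer(DispersionParams(eps, eps), math.inf)])
            got = plane_wave_reflection(st, 30e9)
            expect = (1 - math.sqrt(eps)) / (1 + math.sqrt(eps))
            assert got == pytest.approx(expect, abs=1e-12)

    def test_matched_halfspace_reflects_nothing(self):
        st = LayerStack([Layer(DispersionParams(1.0, 1.0), math.inf)])
        assert plane_wave_reflection(st, 30e9) == 0

    def test_halfwave_layer_is_transparent(self):
        # a lossless eps=4 layer exactly half a wavelength thick vanishes
        f, eps = 30e9, 4.0
        d = C_0 / (2 * f * math.sqrt(eps))
        st = LayerStack([Layer(DispersionParams(eps, eps), d),
                         Layer(DispersionParams(9.0, 9.0), math.inf)])
        bare = LayerStack([Layer(DispersionParams(9.0, 9.0), math.inf)])
        assert plane_wave_reflection(st, f) == pytest.approx(
            plane_wave_reflection(bare, f), abs=1e-10)

    def test_structural_validation(self):
        mat = DispersionParams(2.0, 2.0)
        with pytest.raises(ValueError):
            LayerStack([Layer(mat, 1e-3)])  # no terminal half-space
        with pytest.raises(ValueError):
            LayerStack([Layer(mat, math.inf), Layer(mat, math.inf)])
        with pytest.raises(ValueError):
            Layer(mat, 0.0)


class TestTransferMatrixOracle:
    def test_matches_oracle_on_random_stacks(self):
        rng = np.random.default_rng(2024)
        worst = 0.0
        for _ in range(100):
            st = random_stack(rng)
            f = rng.uniform(10e9, 110e9)
            theta = rng.uniform(0.0, math.radians(80.0))
            pol = "TE" if rng.random() < 0.5 else "TM"
            got = plane_wave_reflection(st, f, theta, pol)
            expect = transfer_matrix_reflection(st, f, theta, pol)
            worst = max(worst, abs(got - expect) / max(abs(expect), 1e-30))
        assert worst < 1e-10

    def test_vectorized_curve_matches_scalar_path(self, thin_mean_stack):
        f = np.linspace(10e9, 110e9, 21)
        curve = normal_incidence_curve(thin_mean_stack, f)
        for i, fi in enumerate(f):
            assert curve[i] == pytest.approx(
                plane_wave_reflection(thin_mean_stack, fi), abs=1e-14)


class TestPhysicalInvariants:
    def test_thin_layer_continuity(self, registry):
        # a 1 nm cover layer changes nothing measurable
        base = LayerStack([Layer(registry.material("layer_d_mean"), math.inf)])
        thin = LayerStack([Layer(registry.material("sc_thin"), 1e-9),
                           Layer(registry.material("layer_d_mean"), math.inf)])
        for f in (15e9, 60e9, 110e9):
            assert abs(plane_wave_reflection(thin, f)
                       - plane_wave_reflection(base, f)) < 1e-5

    def test_passivity_magnitude_below_one(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            st = random_stack(rng)
            f = rng.uniform(10e9, 110e9)
            theta = rng.uniform(0.0, math.radians(85.0))
            pol = "TE" if rng.random() < 0.5 else "TM"
            assert abs(plane_wave_reflection(st, f, theta, pol)) <= 1 + 1e-12

    def test_matching_layer_trend_with_frequency(self, registry):
        # the thin stratum corneum acts as a matching layer: reflectance of
        # the thin-skin models falls monotonically from 15 to 110 GHz
        for name in ("skin_thin_mean", "skin_thin_p68", "skin_thin_p95"):
            st = registry.stack(name)
            db = reflectance_db_curve(st, np.linspace(15e9, 110e9, 40))
            assert np.all(np.diff(db) < 0)

    def test_absorbed_fraction_complements_reflectance(self, thin_p95_stack):
        f = 110e9
        g = plane_wave_reflection(thin_p95_stack, f)
        a = absorbed_power_fraction(thin_p95_stack, f)
        assert a == pytest.approx(1 - abs(g) ** 2, abs=1e-14)
        assert 0 <= a <= 1

    def test_perfect_reflector_proxy_is_zero_db(self):
        pec = LayerStack([Layer(DispersionParams(1.0, 1.0, sigma=1e9), math.inf)])
        assert reflectance_db(pec, 30e9) == pytest.approx(0.0, abs=1e-3)


class TestCoverageModelCurves:
    """Reflectance of the shipped population-coverage skin models."""

    def test_p95_model_reflectance_at_band_edges(self, thin_p95_stack):
        assert reflectance_db(thin_p95_stack, 15e9) == pytest.approx(-2.9, abs=0.1)
        assert reflectance_db(thin_p95_stack, 110e9) == pytest.approx(-6.0, abs=0.1)

    def test_margin_between_mean_and_p95_models(self, registry):
        mean = registry.stack("skin_thin_mean")
        p95 = registry.stack("skin_thin_p95")
        d15 = reflectance_db(mean, 15e9) - reflectance_db(p95, 15e9)
        d110 = reflectance_db(mean, 110e9) - reflectance_db(p95, 110e9)
        assert d15 == pytest.approx(0.3, abs=0.1)
        assert d110 == pytest.approx(1.0, abs=0.1)
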