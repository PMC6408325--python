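"""Sequestration equilibrium and one-site ITC model against oracles."""

import io

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq

from bendkit.errors import FitError
from bendkit.thermo import (
    BindingParameters,
    BindingSystem,
    ITCGeometry,
    TitrationSeries,
    effective_free_tubulin,
    fit_one_site,
    free_species_1to1,
    heats_per_mole_injectant,
    predicted_heats,
    simulate_itc,
    thermo_derive,
)


def _free_species_oracle(t, a, kd):
    """Independent root-finding oracle on the mass-action equations."""
    if t == 0 or a == 0:
        return 0.0

    def f(c):
        return (t - c) * (a - c) - kd * c

    return brentq(f, 0.0, min(t, a), xtol=1e-24, rtol=1e-15)


class TestFreeSpecies:
    def test_no_ligand_means_no_complex(self):
        out = free_species_1to1(BindingSystem(20e-6, 0.0, 1e-7))
        assert out["complex"] == 0.0
        assert out["free_macromolecule"] == 20e-6

    def test_tight_binding_stoichiometric_limit(self):
        out = free_species_1to1(BindingSystem(20e-6, 5e-6, 1e-15))
        assert out["free_macromolecule"] == pytest.approx(15e-6, rel=1e-6)
        assert out["complex"] == pytest.approx(5e-6, rel=1e-6)

    @pytest.mark.parametrize(
        "t,a,kd",
        [
            (20e-6, 5e-6, 0.27e-6),
            (20e-6, 20e-6, 95e-9),
            (15e-6, 1e-6, 1e-6),
            (1e-9, 1e-9, 1e-6),
        ],
    )
    def test_matches_root_finding_oracle(self, t, a, kd):
        out = free_species_1to1(BindingSystem(t, a, kd))
        assert out["complex"] == pytest.approx(_free_species_oracle(t, a, kd),
                                               rel=1e-9)

    def test_paper_condition_free_tubulin(self):
        out = free_species_1to1(BindingSystem(20e-6, 5e-6, 0.27e-6))
        assert out["free_macromolecule"] == pytest.approx(15.09e-6, abs=0.01e-6)

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(
        t=st.floats(0, 1e-3),
        a=st.floats(0, 1e-3),
        kd=st.floats(1e-12, 1e-3),
    )
    def test_mass_conservation_exact(self, t, a, kd):
        out = free_species_1to1(BindingSystem(t, a, kd))
        assert out["free_macromolecule"] + out["complex"] == pytest.approx(
            t, rel=1e-12, abs=1e-18
        )
        assert out["free_ligand"] + out["complex"] == pytest.approx(
            a, rel=1e-12, abs=1e-18
        )
        assert 0 <= out["complex"] <= min(t, a)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            BindingSystem(-1e-6, 1e-6, 1e-7)
        with pytest.raises(ValueError):
            BindingSystem(1e-6, 1e-6, 0.0)

    def test_free_tubulin_monotone_in_ligand_and_kd(self):
        ligands = np.linspace(0, 40e-6, 20)
        frees = [effective_free_tubulin(20e-6, a, 0.27e-6) for a in ligands]
        assert all(x >= y - 1e-18 for x, y in zip(frees, frees[1:]))
        kds = np.logspace(-9, -5, 20)
        frees = [effective_free_tubulin(20e-6, 10e-6, kd) for kd in kds]
        assert all(x <= y + 1e-18 for x, y in zip(frees, frees[1:]))


class TestSequestrationPredictions:
    """Unbound tubulin under the turbidity-assay conditions."""

    @pytest.mark.parametrize(
        "arep_uM,expected_uM",
        [(5.0, 15.0), (10.0, 10.0)],
    )
    def test_rounds_to_control_equivalent(self, arep_uM, expected_uM):
        free = effective_free_tubulin(20e-6, arep_uM * 1e-6, 0.27e-6,
                                      round_to_uM=True)
        assert free * 1e6 == pytest.approx(expected_uM)

    def test_stoichiometric_addition_leaves_little_free(self):
        free = effective_free_tubulin(20e-6, 20e-6, 95e-9)
        assert free == pytest.approx(1.33e-6, abs=0.01e-6)


class TestThermoDerive:
    def test_unit_kd_gives_zero_dg(self):
        assert thermo_derive(1.0, -5.0)["dg"] == pytest.approx(0.0)

    def test_enthalpy_equal_dg_gives_zero_tds(self):
        out = thermo_derive(270e-9, -8.0, 293.15)
        dh = out["dg"]
        assert thermo_derive(270e-9, dh, 293.15)["tds"] == pytest.approx(0.0)

    def test_submicromolar_kd_values(self):
        out = thermo_derive(270e-9, -8.0, 293.15)
        assert out["dg"] == pytest.approx(-8.8, abs=0.5)
        assert out["tds"] == pytest.approx(0.8, abs=0.5)
        out = thermo_derive(95e-9, -16.0, 293.15)
        assert out["dg"] == pytest.approx(-9.0, abs=0.5)
        assert out["tds"] == pytest.approx(-7.0, abs=0.5)

    def test_nonpositive_kd_rejected(self):
        with pytest.raises(ValueError):
            thermo_derive(0.0, -8.0)


def _integration_oracle(params, geometry):
    """Independent mass-balance bookkeeping with root-finding per injection."""
    v0 = geometry.cell_volume
    x = m = prevb = 0.0
    m = geometry.cell_concentration
    heats = []
    for dv in geometry.injection_volumes:
        f = 1.0 - dv / v0
        x = x * f + geometry.syringe_concentration * dv / v0
        m = m * f
        b = _free_species_oracle(params.n * m, x, params.kd)
        heats.append(params.dh * v0 * (b - prevb * f) * 1e9)
        prevb = b
    return np.array(heats)


class TestSimulateITC:
    def test_zero_enthalpy_means_zero_heat(self):
        p = BindingParameters(n=1.0, kd=1e-7, dh=0.0)
        series = simulate_itc(p, ITCGeometry.standard())
        np.testing.assert_array_equal(series.heats_ucal, 0.0)

    def test_saturation_tail_near_zero(self):
        p = BindingParameters(n=1.0, kd=1e-9, dh=-16.0)  # tight: early saturation
        series = simulate_itc(p, ITCGeometry.standard(25))
        peak = np.abs(series.heats_ucal).max()
        assert abs(series.heats_ucal[-1]) < 0.02 * peak

    def test_matches_independent_integration_oracle(self):
        p = BindingParameters(n=1.0, kd=95e-9, dh=-16.0)
        geometry = ITCGeometry.standard()
        series = simulate_itc(p, geometry)
        np.testing.assert_allclose(
            series.heats_ucal, _integration_oracle(p, geometry), rtol=1e-9
        )

    def test_inflection_near_unit_molar_ratio(self):
        p = BindingParameters(n=1.0, kd=95e-9, dh=-16.0)
        series = simulate_itc(p, ITCGeometry.standard())
        ratios = series.molar_ratios()
        steps = np.abs(np.diff(series.heats_ucal))
        inflection_ratio = ratios[1 + int(np.argmax(steps))]
        assert 0.8 < inflection_ratio < 1.2

    def test_per_mole_conversion_plateau_equals_dh(self):
        p = BindingParameters(n=1.0, kd=1e-10, dh=-16.0)
        series = simulate_itc(p, ITCGeometry.standard())
        per_mole = heats_per_mole_injectant(series)
        # before saturation every injected molecule binds: q/mol = ΔH
        assert per_mole[0] == pytest.approx(-16.0, rel=1e-3)


class TestFitOneSite:
    def test_noise_free_recovery_exact(self):
        truth = BindingParameters(n=0.8, kd=270e-9, dh=-8.0)
        series = simulate_itc(truth, ITCGeometry.standard())
        fit = fit_one_site(series)
        assert fit.params.n == pytest.approx(truth.n, rel=1e-6)
        assert fit.params.kd == pytest.approx(truth.kd, rel=1e-6)
        assert fit.params.dh == pytest.approx(truth.dh, rel=1e-6)
        assert fit.dg == pytest.approx(thermo_derive(270e-9, -8.0)["dg"],
                                       rel=1e-6)
        assert fit.tds == pytest.approx(fit.params.dh - fit.dg, abs=1e-9)
        assert not fit.warnings

    @pytest.mark.parametrize("kd", [50e-9, 95e-9, 270e-9, 1e-6])
    def test_roundtrip_across_kd_range(self, kd):
        truth = BindingParameters(n=1.0, kd=kd, dh=-12.0)
        series = simulate_itc(truth, ITCGeometry.standard())
        fit = fit_one_site(series)
        assert fit.params.kd == pytest.approx(kd, rel=1e-5)
        assert 1.0 <= fit.c_value <= 1000.0

    def test_bias_vanishes_with_noise(self):
        truth = BindingParameters(n=1.0, kd=95e-9, dh=-16.0)
        geometry = ITCGeometry.standard()
        peak = np.abs(predicted_heats(truth, geometry)).max()
        spreads, biases = [], []
        for level in (0.04, 0.01, 0.0025):
            kds = []
            for seed in range(30):
                series = simulate_itc(truth, geometry, noise_sd=level * peak,
                                      seed=1000 + seed)
                kds.append(fit_one_site(series).params.kd)
            biases.append(abs(np.median(kds) - truth.kd) / truth.kd)
            spreads.append(np.std(kds) / truth.kd)
        # scatter shrinks with the noise and the bias stays within it
        assert spreads[2] < spreads[1] < spreads[0]
        assert all(b <= s for b, s in zip(biases, spreads))
        assert biases[2] < 0.01

    def test_flat_series_is_unidentifiable(self):
        geometry = ITCGeometry.standard()
        series = TitrationSeries(np.zeros(len(geometry.injection_volumes)),
                                 geometry)
        with pytest.raises(FitError):
            fit_one_site(series)

    def test_too_few_injections_rejected(self):
        geometry = ITCGeometry.standard(5)
        series = simulate_itc(BindingParameters(1.0, 95e-9, -16.0), geometry)
        with pytest.raises(FitError):
            fit_one_site(series)

    def test_low_c_value_attaches_warning(self):
        truth = BindingParameters(n=1.0, kd=1e-4, dh=-10.0)
        series = simulate_itc(truth, ITCGeometry.standard())
        fit = fit_one_site(series)
        assert fit.c_value < 1.0
        assert fit.warnings


def test_titration_series_csv_round_trip():
    series = simulate_itc(BindingParameters(1.0, 95e-9, -16.0),
                          ITCGeometry.standard())
    buf = io.StringIO()
    series.to_csv(buf)
    buf.seek(0)
    back = TitrationSeries.from_csv(buf)
    np.testing.assert_allclose(back.heats_ucal, series.heats_ucal, rtol=1e-12)
    assert back.geometry.injection_volumes == pytest.approx(
        series.geometry.injection_volumes
    )
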