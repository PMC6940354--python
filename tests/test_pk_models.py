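"""Compartmental PK: analytic oracles, superposition and derived quantities."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.linalg import expm

import pdepkpd as pk
from pdepkpd import published as pub

TIMES = np.array([0.0, 2.0, 5.0, 15.0, 30.0, 60.0, 90.0, 120.0])


class TestDoseRegimen:
    def test_validation(self):
        with pytest.raises(ValueError):
            pk.DoseRegimen("IV", -1.0)
        with pytest.raises(ValueError):
            pk.DoseRegimen("IV", 10.0, times=(0.0, 0.0))
        with pytest.raises(ValueError):
            pk.DoseRegimen("oral", 10.0)
        reg = pk.DoseRegimen("iv", 10.0)
        assert reg.route is pk.Route.IV

    def test_extravascular_needs_ka(self):
        params = pk.OneCompartmentParams(V=1.0, Cl_t=0.05)
        with pytest.raises(ValueError, match="absorption"):
            pk.simulate_pk("one_compartment", params, pk.DoseRegimen("IP", 10.0), [0, 10])


class TestOneCompartment:
    def test_initial_condition_is_dose_over_volume(self):
        params = pk.OneCompartmentParams(V=1.60, Cl_t=0.053)
        sim = pk.simulate_pk(
            "one_compartment", params, pk.DoseRegimen("IV", 20.0), [0.0]
        )["parent"]
        assert sim.conc[0] == pytest.approx(12.5, rel=1e-9)

    def test_matches_analytic_exponential(self):
        params = pk.OneCompartmentParams(V=1.60, Cl_t=0.053)
        sim = pk.simulate_pk(
            "one_compartment", params, pk.DoseRegimen("IV", 20.0), TIMES
        )["parent"]
        exact = 20.0 / 1.60 * np.exp(-(0.053 / 1.60) * TIMES)
        np.testing.assert_allclose(sim.conc, exact, rtol=1e-6)

    def test_profile_equals_ode_solution(self):
        variant, params = pub.PK_LEWIS["rolipram"]
        reg = pk.DoseRegimen("IP", 10.0)
        prof = pk.concentration_profile(variant, params, reg)["parent"]
        sim = pk.simulate_pk(variant, params, reg, TIMES[1:])["parent"]
        np.testing.assert_allclose(prof(TIMES[1:]), sim.conc, rtol=1e-6)

    @given(scale=st.floats(0.25, 4.0))
    @settings(deadline=None, max_examples=10, derandomize=True)
    def test_dose_proportionality(self, scale):
        """Linear kinetics: scaling the dose scales every concentration."""
        variant, params = pub.PK_LEWIS["GRMS-55"]
        base = pk.concentration_profile(variant, params, pk.DoseRegimen("IV", 20.0))
        scaled = pk.concentration_profile(
            variant, params, pk.DoseRegimen("IV", 20.0 * scale)
        )
        t = np.array([1.0, 10.0, 45.0, 100.0])
        np.testing.assert_allclose(
            scaled["parent"](t), scale * base["parent"](t), rtol=1e-8
        )


class TestTwoCompartment:
    def test_matches_matrix_exponential(self):
        """Biexponential IV disposition against the closed-form expm oracle."""
        variant, params = pub.PK_WISTAR["rolipram"]
        dose = 5.0
        k10 = params.Cl_t / params.V1
        k12 = params.Cl_d / params.V1
        k21 = params.Cl_d / params.V2
        M = np.array([[-(k10 + k12), k21], [k12, -k21]])
        sim = pk.simulate_pk(variant, params, pk.DoseRegimen("IV", dose), TIMES)
        exact = np.array([(expm(M * t) @ [dose, 0.0])[0] / params.V1 for t in TIMES])
        np.testing.assert_allclose(sim["parent"].conc, exact, rtol=1e-6)

    def test_repeated_doses_superpose(self):
        variant, params = pub.PK_WISTAR["rolipram"]
        single = pk.concentration_profile(variant, params, pk.DoseRegimen("IV", 5.0))
        double = pk.concentration_profile(
            variant, params, pk.DoseRegimen("IV", 5.0, times=(0.0, 60.0))
        )
        t = np.array([30.0, 90.0, 150.0])
        expected = single["parent"](t) + single["parent"](np.maximum(t - 60.0, -1.0)) * (
            t >= 60.0
        )
        np.testing.assert_allclose(double["parent"](t), expected, rtol=1e-8)


class TestInterconversion:
    def test_flip_flop_terminal_slope(self):
        """SC lisofylline shows flip-flop kinetics: the terminal log-slope is
        set by absorption (close to ka, far from the fast disposition kd)."""
        variant, params = pub.PK_LEWIS["LSF"]
        sim = pk.simulate_pk(
            variant, params, pk.DoseRegimen("SC", 80.0), np.array([300.0, 420.0])
        )["parent"]
        slope = -(np.log(sim.conc[1]) - np.log(sim.conc[0])) / 120.0
        # terminal slope near the absorption rate, an order of magnitude
        # below the parent disappearance rate
        assert slope == pytest.approx(params.ka_LSF, rel=0.15)
        assert slope < params.kd / 5
        # and reproduces the observed ~23 min terminal half-life
        assert np.log(2) / slope == pytest.approx(23.0, abs=2.0)

    def test_mass_balance_without_elimination(self):
        """With negligible metabolite elimination and an IV dose, the total
        parent+metabolite amount is conserved."""
        params = pk.LSFInterconversionParams(
            V_LSF=0.37, V_PTXm_over_fm=1.95, ka_LSF=0.032,
            kd=0.212, kem=1e-12, kconv=0.054,
        )
        sim = pk.simulate_pk(
            "lsf_interconversion", params, pk.DoseRegimen("IV", 40.0),
            np.array([0.0, 30.0, 120.0, 300.0]),
        )
        total = sim["parent"].conc * params.V_LSF + sim[
            "metabolite"
        ].conc * params.V_PTXm_over_fm
        np.testing.assert_allclose(total, 40.0, rtol=1e-6)


class TestMichaelisMenten:
    def test_reduces_to_linear_at_low_concentration(self):
        """For C << Km the saturable model is linear with Cl = Vmax/Km."""
        _, params = pub.PK_WISTAR["LSF"]
        dose = 0.01  # C0 ~ 0.008 mg/L << Km/100
        times = np.array([1.0, 30.0, 90.0, 180.0])
        sim = pk.simulate_pk(
            "lsf_michaelis_menten", params, pk.DoseRegimen("IV", dose), times
        )["parent"]
        linear = pk.OneCompartmentParams(V=params.V_LSF, Cl_t=params.Vmax / params.Km)
        ref = pk.simulate_pk(
            "one_compartment", linear, pk.DoseRegimen("IV", dose), times
        )["parent"]
        np.testing.assert_allclose(sim.conc, ref.conc, rtol=0.01)

    def test_metabolite_dosing_leaves_parent_at_zero(self):
        _, params = pub.PK_WISTAR["LSF"]
        sim = pk.simulate_pk(
            "lsf_michaelis_menten", params, pk.DoseRegimen("IV", 40.0),
            np.array([10.0, 60.0]), dose_into="metabolite",
        )
        assert np.all(sim["parent"].conc == 0.0)
        assert np.all(sim["metabolite"].conc > 0.0)


class TestDerivedQuantities:
    @pytest.mark.parametrize(
        "V,Cl,expected",
        [(1.60, 0.053, 20.9), (0.58, 0.037, 10.9), (1.0, 1.0, np.log(2))],
    )
    def test_half_life(self, V, Cl, expected):
        assert pk.half_life(V, Cl) == pytest.approx(expected, abs=0.05)

    def test_half_life_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            pk.half_life(0.0, 1.0)

    @pytest.mark.parametrize(
        "kd,ka,expected", [(0.212, 0.032, 6.6), (0.3, 0.3, 1.0), (0.1, 0.05, 2.0)]
    )
    def test_flip_flop_ratio(self, kd, ka, expected):
        assert pk.flip_flop_ratio(kd, ka) == pytest.approx(expected, abs=0.05)

    def test_nca_auc_trapezoid(self):
        const = pk.ConcentrationSeries("x", np.linspace(0, 100, 11), np.ones(11))
        assert pk.nca_auc(const) == pytest.approx(100.0)
        tri = pk.ConcentrationSeries("x", [0.0, 10.0], [2.0, 0.0])
        assert pk.nca_auc(tri) == pytest.approx(10.0)

    def test_nca_auc_excludes_censored(self):
        s = pk.ConcentrationSeries(
            "x", [0.0, 10.0, 20.0], [2.0, 1.0, np.nan],
            loq=0.1, censored=[False, False, True],
        )
        assert pk.nca_auc(s) == pytest.approx(15.0)
        with pytest.raises(ValueError):
            pk.nca_auc(
                pk.ConcentrationSeries("x", [0.0], [1.0])
            )

    def test_nca_auc_approaches_dose_over_clearance(self):
        params = pk.OneCompartmentParams(V=1.60, Cl_t=0.053)
        t = np.linspace(0, 400, 2001)  # >13 half-lives, dense grid
        sim = pk.simulate_pk("one_compartment", params, pk.DoseRegimen("IV", 20.0), t)
        assert pk.nca_auc(sim["parent"]) == pytest.approx(20.0 / 0.053, rel=0.001)

    def test_fraction_absorbed_identities(self):
        assert pk.fraction_absorbed(1.0, 1.0, 1.0, 1.0) == pytest.approx(1.0)
        assert pk.fraction_absorbed(1.0, 2.0, 2.0, 1.0) == pytest.approx(1.0)
        with pytest.raises(ValueError):
            pk.fraction_absorbed(0.0, 1.0, 1.0, 1.0)

    def test_fraction_absorbed_round_trip(self):
        """Dose-normalized AUC ratio recovers the generating bioavailability."""
        variant, params = pub.PK_LEWIS["GRMS-55"]
        t = np.linspace(0, 600, 1201)
        iv = pk.simulate_pk(variant, params, pk.DoseRegimen("IV", 20.0), t)["parent"]
        ip = pk.simulate_pk(variant, params, pk.DoseRegimen("IP", 40.0), t)["parent"]
        f = pk.fraction_absorbed(pk.nca_auc(ip), 20.0, pk.nca_auc(iv), 40.0)
        assert f == pytest.approx(params.F, rel=0.05)


def test_unknown_variant_rejected():
    with pytest.raises(ValueError, match="unknown model variant"):
        pk.simulate_pk("three_compartment", None, pk.DoseRegimen("IV", 1.0), [0.0])


def test_output_before_first_dose_rejected():
    params = pk.OneCompartmentParams(V=1.0, Cl_t=0.05)
    with pytest.raises(ValueError, match="before the first dose"):
        pk.simulate_pk(
            "one_compartment", params, pk.DoseRegimen("IV", 1.0, times=(10.0,)), [5.0]
        )
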