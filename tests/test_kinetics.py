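"""EMSA Hill fitting and BLI 1:1 / two-step kinetic models."""

import numpy as np
import pytest

from g4condense import kinetics as kin
from g4condense.errors import (
    FitFailureError,
    InvalidInputError,
    InvalidParameterError,
    UnidentifiableFitError,
)
from g4condense.synthetic import gen_hill_curve, gen_sensorgram


class TestBindingFraction:
    @pytest.mark.parametrize("free,total,expected", [
        (50, 100, 50.0),
        (100, 100, 0.0),
        (0, 100, 100.0),
    ])
    def test_formula(self, free, total, expected):
        assert kin.binding_fraction(free, total) == pytest.approx(expected)

    def test_overshoot_clipped_with_warning(self):
        with pytest.warns(UserWarning):
            assert kin.binding_fraction(110, 100) == 0.0

    def test_zero_total_rejected(self):
        with pytest.raises(InvalidInputError):
            kin.binding_fraction(10, 0)


class TestHill:
    def test_half_saturation_identity(self):
        curve, _ = gen_hill_curve(10e-9, 2.0, 1.0, [10e-9, 1e-9, 100e-9])
        at_kd = curve.fractions[curve.concentrations == 10e-9]
        assert at_kd == pytest.approx(0.5)

    def test_steepest_log_slope_equals_h(self):
        # numeric d log(B/(Bmax-B)) / d log X equals h for the Hill form
        kd, h = 19.1e-9, 4.42
        X = np.geomspace(0.5 * kd, 2 * kd, 101)
        curve, _ = gen_hill_curve(kd, h, 1.0, X)
        y = curve.fractions
        logit = np.log(y / (1 - y))
        slopes = np.diff(logit) / np.diff(np.log(X))
        assert np.max(slopes) == pytest.approx(h, rel=1e-6)

    @pytest.mark.parametrize("kd,h", [
        (19.1e-9, 4.42),       # G4-containing probe, KCl-annealed
        (148e-9, 1.5),         # no-KCl (unfolded) probe
        (24.5e-9, 3.53),       # intermolecular G4 probe
    ])
    def test_noiseless_recovery_within_one_percent(self, kd, h):
        curve, _ = gen_hill_curve(kd, h, 1.0, np.geomspace(1e-9, 500e-9, 12))
        fit = kin.fit_hill(curve)
        assert fit.converged
        assert fit.K_D == pytest.approx(kd, rel=0.01)
        assert fit.h == pytest.approx(h, rel=0.01)
        assert fit.B_max == pytest.approx(1.0, rel=0.01)
        assert not fit.extrapolated

    def test_hyperbolic_limit(self):
        curve, _ = gen_hill_curve(50e-9, 1.0, 1.0,
                                  np.geomspace(1e-9, 1e-6, 10))
        fit = kin.fit_hill(curve)
        assert fit.K_D == pytest.approx(50e-9, rel=0.01)
        assert fit.h == pytest.approx(1.0, rel=0.01)

    def test_too_few_concentrations_rejected(self):
        curve = kin.BindingCurve(np.array([1e-9, 2e-9, 4e-9]),
                                 np.array([0.1, 0.2, 0.4]))
        with pytest.raises(InvalidInputError):
            kin.fit_hill(curve)


class TestSensorgramPhases:
    def test_phase_order_enforced(self):
        with pytest.raises(InvalidInputError):
            kin.Sensorgram(time=[0, 1, 2], response=[0, 0, 0],
                           phase=["dissociation", "association",
                                  "association"],
                           analyte_concentration=1e-9)

    def test_noiseless_association_matches_closed_form(self):
        ka, kd, conc = 2.5e5, 5.9e-4, 457e-9
        traces, _ = gen_sensorgram("one_to_one", {"k_a": ka, "k_d": kd},
                                   [conc], t_assoc=200, t_dissoc=100, dt=1.0)
        (tr,) = traces
        t, y = tr.phase_slice("association")
        kobs = ka * conc + kd
        req = conc / (conc + kd / ka)
        assert np.allclose(y, req * (1 - np.exp(-kobs * t)), atol=1e-12)


class TestExponentialFits:
    def _trace(self, noise=0.0, seed=0):
        traces, _ = gen_sensorgram(
            "one_to_one", {"k_a": 2.5e5, "k_d": 5.9e-4}, [457e-9],
            t_assoc=300, t_dissoc=600, dt=1.0, noise_sd=noise, seed=seed)
        return traces[0]

    def test_association_recovery(self):
        fit = kin.fit_association(self._trace())
        assert fit.k_obs == pytest.approx(2.5e5 * 457e-9 + 5.9e-4, rel=1e-3)

    def test_dissociation_recovery_and_half_life(self):
        fit = kin.fit_dissociation(self._trace())
        assert fit.k_d == pytest.approx(5.9e-4, rel=1e-3)
        # half-life identity on the fitted decay
        assert np.log(2) / fit.k_d == pytest.approx(np.log(2) / 5.9e-4,
                                                    rel=1e-3)

    def test_flat_trace_unidentifiable(self):
        t = np.arange(50.0)
        with pytest.raises(UnidentifiableFitError):
            kin.fit_association(t, np.ones_like(t))

    def test_fit_passes_through_Y0_at_t0(self):
        tr = self._trace()
        fit = kin.fit_association(tr)
        assert fit.Y0 == pytest.approx(0.0, abs=1e-6)

    def test_kobs_increases_with_concentration(self):
        traces, _ = gen_sensorgram(
            "one_to_one", {"k_a": 2.5e5, "k_d": 5.9e-4},
            [50e-9, 150e-9, 457e-9], t_assoc=300, t_dissoc=1, dt=1.0)
        kobs = [kin.fit_association(t).k_obs for t in traces]
        assert kobs == sorted(kobs)


class TestDerivedConstants:
    def test_derive_ka_arithmetic(self):
        assert kin.derive_ka(2.0e-3, 1.0e-3, 457e-9) == \
            pytest.approx(1.0e-3 / 457e-9)

    def test_ka_halves_when_analyte_doubles(self):
        assert kin.derive_ka(2e-3, 1e-3, 2 * 457e-9) == \
            pytest.approx(kin.derive_ka(2e-3, 1e-3, 457e-9) / 2)

    def test_kobs_below_kd_rejected(self):
        with pytest.raises(InvalidParameterError):
            kin.derive_ka(1e-3, 2e-3, 457e-9)

    def test_KD_ratio_and_scale_invariance(self):
        assert kin.derive_KD(5.4e-4, 2.29e5) == pytest.approx(2.36e-9,
                                                              rel=0.01)
        assert kin.derive_KD(0.0, 2.29e5) == 0.0
        assert kin.derive_KD(5.4e-4 * 7, 2.29e5 * 7) == \
            pytest.approx(kin.derive_KD(5.4e-4, 2.29e5))

    def test_one_to_one_fit_KD_identity(self):
        traces, _ = gen_sensorgram(
            "one_to_one", {"k_a": 2.5e5, "k_d": 5.9e-4}, [457e-9],
            t_assoc=300, t_dissoc=600, dt=1.0)
        fit = kin.fit_one_to_one(traces[0])
        assert fit.K_D == pytest.approx(fit.k_d / fit.k_a, rel=1e-12)


TWO_STEP = dict(k_on1=2.0e5, k_off1=2e-3, k_on2=5.0e4, k_off2=8e-3,
                R1=1.0, R2=2.0)


class TestTwoStep:
    def test_conservation(self):
        sim = kin.simulate_two_step(**TWO_STEP, g4_0=1.0, sp1=457e-9,
                                    times=np.arange(0, 900, 1.0),
                                    t_assoc=450)
        assert np.max(np.abs(sim.total - 1.0)) < 1e-9

    def test_reduces_to_one_to_one(self):
        times = np.arange(0, 300, 1.0)
        conc = 457e-9
        sim = kin.simulate_two_step(2.5e5, 5.9e-4, 0.0, 0.0, 1.0, 0.0,
                                    1.0, conc, times)
        kobs = 2.5e5 * conc + 5.9e-4
        req = conc / (conc + 5.9e-4 / 2.5e5)
        assert np.allclose(sim.response, req * (1 - np.exp(-kobs * times)),
                           atol=1e-12)
        assert np.all(sim.g4sp1_2 == 0)

    def test_equilibrium_matches_detailed_balance(self):
        # closed-form equilibrium: [G4P]/[G4] = K1, [G4P2]/[G4P] = K2
        conc = 457e-9
        K1 = TWO_STEP["k_on1"] * conc / TWO_STEP["k_off1"]
        K2 = TWO_STEP["k_on2"] * conc / TWO_STEP["k_off2"]
        z = 1 + K1 + K1 * K2
        sim = kin.simulate_two_step(**TWO_STEP, g4_0=1.0, sp1=conc,
                                    times=np.array([0.0, 1e6]))
        assert sim.g4[-1] == pytest.approx(1 / z, rel=1e-6)
        assert sim.g4sp1[-1] == pytest.approx(K1 / z, rel=1e-6)
        assert sim.g4sp1_2[-1] == pytest.approx(K1 * K2 / z, rel=1e-6)

    def test_full_mass_action_conserves_and_depletes(self):
        sim = kin.simulate_two_step(**TWO_STEP, g4_0=100e-9, sp1=457e-9,
                                    times=np.arange(0, 300, 1.0),
                                    full_mass_action=True)
        assert np.max(np.abs(sim.total - 100e-9)) < 1e-9 * 100e-9 * 10

    def test_global_fit_recovers_parameters(self):
        traces, _ = gen_sensorgram("two_step", TWO_STEP,
                                   [114e-9, 228e-9, 457e-9],
                                   t_assoc=300, t_dissoc=300, dt=2.0)
        fit = kin.fit_two_step(traces, seed=0)
        for name, true in TWO_STEP.items():
            attr = name if name.startswith("k") else name
            assert getattr(fit, attr) == pytest.approx(true, rel=0.05), name
        assert all(r2 > 0.999 for r2 in fit.r_squared.values())

    def test_single_flat_trace_fails(self):
        t = np.arange(0, 100, 1.0)
        flat = kin.Sensorgram(time=t, response=np.zeros_like(t),
                              phase=np.array(["association"] * t.size,
                                             dtype=object),
                              analyte_concentration=1e-9)
        with pytest.raises((FitFailureError, InvalidInputError)):
            kin.fit_two_step([flat, flat])


class TestCompareModels:
    def test_report_schema_and_nesting(self):
        traces, _ = gen_sensorgram("two_step", TWO_STEP,
                                   [114e-9, 457e-9],
                                   t_assoc=300, t_dissoc=300, dt=2.0)
        ones = [kin.fit_one_to_one(t) for t in traces]
        two = kin.fit_two_step(traces, seed=0)
        report = kin.compare_models(ones, two)
        assert len(report["per_concentration"]) == 2
        for row in report["per_concentration"]:
            assert set(row) >= {"concentration", "r2_one_to_one",
                                "r2_two_step", "delta_r2"}
            # two-step nests the 1:1 model: it cannot fit its own data worse
            assert row["r2_two_step"] >= row["r2_one_to_one"] - 1e-9

    def test_mismatched_concentrations_rejected(self):
        traces, _ = gen_sensorgram("two_step", TWO_STEP, [114e-9, 457e-9],
                                   t_assoc=100, t_dissoc=100, dt=2.0)
        ones = [kin.fit_one_to_one(traces[0])]
        two = kin.fit_two_step(traces, seed=0)
        with pytest.raises(InvalidInputError):
            kin.compare_models(ones, two)
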