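import numpy as np
import pytest
from scipy import optimize

from rnlcolour.contrast import (CatchSet, DegenerateBackgroundError,
                                NoiseModel, adaptation_coefficients,
                                catch_set, delta_S, delta_S_general,
                                michelson_contrast, quantum_catch,
                                receptor_contrast, relative_catches,
                                stimulus_contrast, weber_fractions)
from rnlcolour.receptors import RECEPTOR_ORDER
from rnlcolour.spectra import DEFAULT_GRID, Spectrum, UnitRoleError

REC = RECEPTOR_ORDER


def flat(value, role="quantum_radiance"):
    return Spectrum(DEFAULT_GRID, np.full_like(DEFAULT_GRID, value), role)


def rnl_distance_oracle(df, omega):
    """Independent oracle: numerically minimise sum_i (df_i - c)^2/w_i^2
    over the intensity shift c."""
    def obj(c):
        return float(np.sum(((df - c) / omega) ** 2))
    res = optimize.minimize_scalar(obj, bounds=(df.min() - 1, df.max() + 1),
                                   method="bounded",
                                   options={"xatol": 1e-14})
    return np.sqrt(res.fun)


class TestQuantumCatch:
    def test_zero_stimulus(self):
        R = flat(0.5, "sensitivity")
        assert quantum_catch(R, flat(0.0)) == 0.0

    def test_linearity_in_stimulus(self):
        R = flat(0.5, "sensitivity")
        L = flat(2.0)
        assert quantum_catch(R, L.scaled(2)) == pytest.approx(
            2 * quantum_catch(R, L))

    def test_closed_form_constant_integrand(self):
        # R=0.5, L=2 over 300-700 nm: trapezoid integral = 0.5*2*400
        assert quantum_catch(flat(0.5, "sensitivity"),
                             flat(2.0)) == pytest.approx(400.0)

    def test_unit_role_enforced(self):
        with pytest.raises(UnitRoleError):
            quantum_catch(flat(0.5, "sensitivity"),
                          flat(1.0, "energy_radiance"))


class TestAdaptation:
    def test_background_maps_to_unit_catches(self, vs, study):
        bg = study.backgrounds["grey"]
        cs = catch_set(vs, bg, adapt_to=bg)
        for r in REC:
            assert cs.Q[r] == pytest.approx(1.0, rel=1e-12)

    def test_coefficients_halve_when_background_doubles(self, vs, study):
        bg = study.backgrounds["grey"]
        k1 = adaptation_coefficients(vs, bg)
        k2 = adaptation_coefficients(vs, bg.scaled(2.0))
        for r in REC:
            assert k2[r] == pytest.approx(k1[r] / 2)

    def test_background_vs_itself_is_zero_jnd(self, vs, study):
        bg = study.backgrounds["grey"]
        assert stimulus_contrast(vs, bg, bg, bg) == pytest.approx(0.0,
                                                                  abs=1e-9)

    def test_dark_background_rejected(self, vs):
        with pytest.raises(DegenerateBackgroundError):
            adaptation_coefficients(vs, flat(0.0))


class TestChromaticity:
    def test_equal_catches_give_quarter_each(self):
        q = relative_catches(CatchSet({r: 3.0 for r in REC}))
        assert all(v == pytest.approx(0.25) for v in q.values())

    def test_scale_invariance(self):
        Q = dict(zip(REC, (0.5, 1.0, 1.5, 2.0)))
        q1 = relative_catches(CatchSet(Q))
        q2 = relative_catches(CatchSet({r: 7.3 * v for r, v in Q.items()}))
        for r in REC:
            assert q1[r] == pytest.approx(q2[r])

    def test_sums_to_one_and_arithmetic(self):
        q = relative_catches(CatchSet(dict(zip(REC, (0.0, 1.0, 1.0, 2.0)))))
        assert sum(q.values()) == pytest.approx(1.0)
        assert [q[r] for r in REC] == pytest.approx([0, 0.25, 0.25, 0.5])

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            relative_catches(CatchSet({r: 0.0 for r in REC}))


class TestReceptorContrast:
    def test_identity_and_antisymmetry(self):
        c1 = CatchSet(dict(zip(REC, (1.0, 2.0, 3.0, 4.0))))
        c2 = CatchSet(dict(zip(REC, (2.0, 2.0, 1.5, 4.0))))
        assert all(v == 0 for v in receptor_contrast(c1, c1).values())
        fwd = receptor_contrast(c1, c2)
        bwd = receptor_contrast(c2, c1)
        for r in REC:
            assert fwd[r] == pytest.approx(-bwd[r])

    def test_log_ratio_value(self):
        c1 = CatchSet(dict(zip(REC, (2.0, 1.0, 1.0, 1.0))))
        c2 = CatchSet(dict(zip(REC, (1.0, 1.0, 1.0, 1.0))))
        assert receptor_contrast(c1, c2)["UVS"] == pytest.approx(np.log(2))

    def test_zero_catch_rejected(self):
        c1 = CatchSet(dict(zip(REC, (0.0, 1.0, 1.0, 1.0))))
        with pytest.raises(ValueError):
            receptor_contrast(c1, c1)

    def test_mismatched_backgrounds_rejected(self):
        c1 = CatchSet(dict(zip(REC, (1, 1, 1, 1))), True, "grey")
        c2 = CatchSet(dict(zip(REC, (1, 1, 1, 1))), True, "green")
        with pytest.raises(ValueError):
            receptor_contrast(c1, c2)


class TestWeberFractions:
    def test_equal_abundances_all_equal_anchor(self):
        nm = weber_fractions(0.08, {r: 2.0 for r in REC})
        assert all(v == pytest.approx(0.08) for v in nm.omega.values())

    def test_standard_avian_ratios(self):
        # anchor 0.1 in LWS with abundance ratio 1:1.5:2:3 and sqrt pooling:
        # v = 0.1*sqrt(3), omega_i = v/sqrt(eta_i)
        nm = weber_fractions(0.1, dict(zip(REC, (1.0, 1.5, 2.0, 3.0))))
        expect = [0.1 * np.sqrt(3), 0.1 * np.sqrt(2),
                  0.1 * np.sqrt(1.5), 0.1]
        assert nm.as_array() == pytest.approx(expect, abs=1e-4)

    def test_quadrupled_abundance_halves_noise_at_fixed_v(self):
        # same single-cone noise v, 4x the cones per field -> half the
        # channel Weber fraction.  Holding v fixed under eta -> 4*eta
        # means restating the LWS anchor as v/sqrt(4*eta_LWS) = anchor/2.
        eta = dict(zip(REC, (1.0, 1.5, 2.0, 3.0)))
        a = weber_fractions(0.1, eta).as_array()
        b = weber_fractions(0.05, {r: 4 * v for r, v in eta.items()})
        assert np.allclose(b.as_array(), a / 2)

    def test_linear_scaling_variant(self):
        nm = weber_fractions(0.1, dict(zip(REC, (1.0, 1.5, 2.0, 3.0))),
                             scaling="linear")
        assert nm.omega["UVS"] == pytest.approx(0.3)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            weber_fractions(0.0, {r: 1.0 for r in REC})
        with pytest.raises(ValueError):
            weber_fractions(0.1, dict(zip(REC, (1, 1, 1, 0))))


class TestDeltaS:
    noise = weber_fractions(0.1, dict(zip(REC, (1.0, 1.5, 2.0, 3.0))))

    def test_pure_intensity_shift_is_invisible(self):
        df = {r: 0.37 for r in REC}
        assert delta_S(df, self.noise) == pytest.approx(0.0, abs=1e-12)

    def test_invariant_to_adding_constant(self, rng):
        df = dict(zip(REC, rng.normal(size=4)))
        shifted = {r: v + 1.234 for r, v in df.items()}
        assert delta_S(df, self.noise) == pytest.approx(
            delta_S(shifted, self.noise), rel=1e-10)

    def test_closed_form_equals_minimisation_oracle(self, rng):
        # 10^4 random draws: tetrachromatic closed form == the defining
        # minimisation over the intensity shift, to 1e-10
        for _ in range(10_000):
            df = rng.normal(scale=2.0, size=4)
            omega = rng.uniform(0.02, 0.5, size=4)
            nm = NoiseModel(dict(zip(REC, omega)))
            closed = delta_S(dict(zip(REC, df)), nm)
            assert abs(closed - delta_S_general(df, omega)) < 1e-10

    def test_oracle_spot_checks_against_scalar_minimiser(self, rng):
        for _ in range(50):
            df = rng.normal(scale=2.0, size=4)
            omega = rng.uniform(0.05, 0.5, size=4)
            nm = NoiseModel(dict(zip(REC, omega)))
            assert delta_S(dict(zip(REC, df)), nm) == pytest.approx(
                rnl_distance_oracle(df, omega), abs=1e-6)

    def test_noise_homogeneity(self, rng):
        df = dict(zip(REC, rng.normal(size=4)))
        omega = rng.uniform(0.05, 0.5, size=4)
        a = delta_S(df, NoiseModel(dict(zip(REC, omega))))
        b = delta_S(df, NoiseModel(dict(zip(REC, 3.0 * omega))))
        assert a == pytest.approx(3.0 * b, rel=1e-10)

    def test_pseudometric_on_random_triples(self, rng):
        # symmetry and triangle inequality for the induced distance on
        # adapted catch vectors
        for _ in range(300):
            logq = rng.normal(scale=0.5, size=(3, 4))
            def d(i, j):
                return delta_S(dict(zip(REC, logq[i] - logq[j])), self.noise)
            assert d(0, 1) == pytest.approx(d(1, 0), rel=1e-12)
            assert d(0, 2) <= d(0, 1) + d(1, 2) + 1e-9

    def test_wrong_receptor_count_rejected(self):
        with pytest.raises(ValueError):
            delta_S({"UVS": 0.1, "LWS": 0.2}, self.noise)


class TestMichelson:
    def test_equal_catches_zero(self):
        assert michelson_contrast(2.0, 2.0) == 0.0

    def test_three_to_one(self):
        assert michelson_contrast(3.0, 1.0) == pytest.approx(0.5)
        assert michelson_contrast(1.0, 3.0) == pytest.approx(0.5)  # symmetric

    def test_scale_invariant(self):
        assert michelson_contrast(3.0, 1.0) == pytest.approx(
            michelson_contrast(30.0, 10.0))

    def test_both_zero_rejected(self):
        with pytest.raises(ValueError):
            michelson_contrast(0.0, 0.0)
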