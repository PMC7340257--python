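import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import curve_fit

from midaskit import biophys as bp

SUBSTRATE_SERIES_MM = np.array([0.01, 0.05, 0.1, 0.25, 0.5, 0.75, 1.0, 2.0])


class TestHanesWoolf:
    def test_exact_on_noiseless_data(self):
        v = bp.michaelis_menten(SUBSTRATE_SERIES_MM, km=0.2, vmax=14.2)
        res = bp.hanes_woolf_fit(SUBSTRATE_SERIES_MM, v)
        assert res.km == pytest.approx(0.2, rel=1e-10)
        assert res.vmax == pytest.approx(14.2, rel=1e-10)
        assert res.r_squared == pytest.approx(1.0, abs=1e-12)

    @settings(max_examples=100, derandomize=True)
    @given(
        st.floats(min_value=0.01, max_value=10.0),
        st.floats(min_value=0.1, max_value=1000.0),
    )
    def test_exact_for_any_parameters(self, km, vmax):
        s = np.array([0.05, 0.1, 0.25, 0.5, 1.0, 2.0]) * km * 10
        v = bp.michaelis_menten(s, km, vmax)
        res = bp.hanes_woolf_fit(s, v)
        assert res.km == pytest.approx(km, rel=1e-8)
        assert res.vmax == pytest.approx(vmax, rel=1e-8)

    def test_saturated_limit_km_zero_with_warning(self):
        s = np.array([0.1, 0.5, 1.0, 2.0])
        v = np.full_like(s, 14.2)
        with pytest.warns(RuntimeWarning, match="Km -> 0"):
            res = bp.hanes_woolf_fit(s, v)
        assert res.km == pytest.approx(0.0, abs=1e-10)
        assert res.vmax == pytest.approx(14.2, rel=1e-10)

    def test_nonsaturating_data_rejected(self):
        s = np.array([0.1, 0.5, 1.0, 2.0])
        with pytest.raises(ValueError, match="no saturating fit"):
            bp.hanes_woolf_fit(s, s**2)  # superlinear: S/v decreasing

    def test_nonpositive_velocities_excluded(self):
        s = np.array([0.05, 0.1, 0.5, 1.0, 2.0])
        v = bp.michaelis_menten(s, 0.2, 14.2)
        v[0] = 0.0
        with pytest.warns(RuntimeWarning, match="v <= 0"):
            res = bp.hanes_woolf_fit(s, v)
        assert res.km == pytest.approx(0.2, rel=1e-8)

    def test_noisy_fit_matches_nonlinear_oracle(self):
        rng = np.random.default_rng(42)
        kms, kms_nls = [], []
        for _ in range(200):
            v = bp.michaelis_menten(SUBSTRATE_SERIES_MM, 0.2, 14.2)
            v_noisy = v * (1 + rng.normal(0, 0.05, v.size))
            res = bp.hanes_woolf_fit(SUBSTRATE_SERIES_MM, v_noisy)
            kms.append(res.km)
            (km_nls, _), _ = curve_fit(
                lambda s, km, vm: vm * s / (km + s),
                SUBSTRATE_SERIES_MM,
                v_noisy,
                p0=[0.3, 10.0],
            )
            kms_nls.append(km_nls)
        assert np.median(kms) == pytest.approx(0.2, rel=0.10)
        # linearised and direct nonlinear fits agree in the median
        assert np.median(kms) == pytest.approx(np.median(kms_nls), rel=0.10)


class TestBoltzmann:
    TEMPS = np.arange(25.0, 96.5, 0.5)

    def test_noiseless_self_fit(self):
        f = bp.boltzmann(self.TEMPS, 100, 1000, 52.0, 1.5)
        res = bp.boltzmann_fit(self.TEMPS, f)
        assert res.tm == pytest.approx(52.0, abs=1e-6)

    def test_wt_variant_shift(self):
        wt = bp.boltzmann_fit(self.TEMPS, bp.boltzmann(self.TEMPS, 100, 1000, 52.0, 1.5))
        var = bp.boltzmann_fit(self.TEMPS, bp.boltzmann(self.TEMPS, 100, 1000, 46.8, 1.5))
        assert bp.delta_tm(var, wt) == pytest.approx(-5.2, abs=1e-6)

    def test_aggregation_decay_excluded_from_window(self):
        f = bp.boltzmann(self.TEMPS, 100, 1000, 52.0, 1.5)
        f = f - np.where(self.TEMPS > 80, (self.TEMPS - 80) * 30, 0.0)
        res = bp.boltzmann_fit(self.TEMPS, f)
        assert res.tm == pytest.approx(52.0, abs=1e-3)
        assert res.window[1] <= 81.0

    def test_noisy_recovery_within_tenth_degree(self):
        rng = np.random.default_rng(7)
        truth = bp.boltzmann(self.TEMPS, 100, 1000, 52.0, 1.5)
        errors = [
            abs(bp.boltzmann_fit(self.TEMPS, truth + rng.normal(0, 18.0, truth.size)).tm - 52.0)
            for _ in range(100)
        ]  # noise SD = 2% of the 900-unit amplitude
        assert np.median(errors) < 0.1

    def test_monotone_decreasing_curve_rejected(self):
        f = np.linspace(1000, 100, self.TEMPS.size)
        with pytest.raises(ValueError, match="no rising transition"):
            bp.boltzmann_fit(self.TEMPS, f)

    def test_delta_tm_arithmetic(self, rng):
        f = bp.boltzmann(self.TEMPS, 100, 1000, 52.0, 1.5)
        res = bp.boltzmann_fit(self.TEMPS, f)
        assert bp.delta_tm(res, res) == 0.0
        tms = rng.uniform(35, 70, 10)
        for a_tm, b_tm in tms.reshape(5, 2):
            a = bp.boltzmann_fit(self.TEMPS, bp.boltzmann(self.TEMPS, 0, 1, a_tm, 2.0))
            b = bp.boltzmann_fit(self.TEMPS, bp.boltzmann(self.TEMPS, 0, 1, b_tm, 2.0))
            assert bp.delta_tm(a, b) == pytest.approx(a_tm - b_tm, abs=1e-4)
            assert bp.delta_tm(b, a) == pytest.approx(-(a_tm - b_tm), abs=1e-4)


class TestGuinier:
    Q = np.linspace(0.005, 0.4, 400)

    def test_gaussian_profile_exact(self):
        profile = 100.0 * np.exp(-(self.Q**2) * 20.0**2 / 3.0)
        res = bp.guinier_fit(self.Q, profile)
        assert res.rg == pytest.approx(20.0, rel=1e-9)
        assert res.i0 == pytest.approx(100.0, rel=1e-9)

    def test_solid_sphere_within_one_percent(self):
        radius = 30.0
        x = self.Q * radius
        form = (3.0 * (np.sin(x) - x * np.cos(x)) / x**3) ** 2
        res = bp.guinier_fit(self.Q, 50.0 * form)
        theory = radius * np.sqrt(3.0 / 5.0)
        assert res.rg == pytest.approx(theory, rel=0.01)
        assert res.q_max * res.rg <= 1.3 + 1e-9

    def test_aggregation_upturn_rejected(self):
        with pytest.raises(ValueError, match="no Guinier regime"):
            bp.guinier_fit(self.Q, 100.0 * np.exp(+(self.Q**2) * 50.0))


class TestMassAndStoichiometry:
    def test_glycine_masses(self):
        assert bp.mass_from_sequence("G") == pytest.approx(75.07, abs=0.01)
        # residue-table oracle: 2 glycine residues + one water
        assert bp.mass_from_sequence("GG") == pytest.approx(2 * 75.07 - 18.02, abs=0.02)

    def test_masses_from_fasta(self, tmp_path):
        path = tmp_path / "constructs.fasta"
        path.write_text(">a\nGG\n>b\nGGG\n")
        masses = bp.masses_from_fasta(path)
        assert masses["a"] == pytest.approx(bp.mass_from_sequence("GG"))
        assert masses["b"] > masses["a"]

    def test_empty_and_invalid_sequences(self):
        with pytest.raises(ValueError):
            bp.mass_from_sequence("")
        with pytest.raises(ValueError, match="position 2"):
            bp.mass_from_sequence("GGX")

    def test_complex_mass_arithmetic(self):
        comps = [
            bp.ComplexComponent("E1", 97_000, 16),
            bp.ComplexComponent("E2", 41_000, 24),
        ]
        assert bp.complex_mass(comps) == pytest.approx(2_536_000)
        assert bp.complex_mass([bp.ComplexComponent("x", 5.0, 0)]) == 0.0
        assert bp.complex_mass([bp.ComplexComponent("x", 123.0, 1)]) == 123.0

    @settings(max_examples=100, derandomize=True)
    @given(
        st.floats(min_value=1, max_value=1e6),
        st.integers(min_value=0, max_value=100),
        st.integers(min_value=1, max_value=5),
    )
    def test_complex_mass_linear_in_copies(self, mass, copies, factor):
        one = bp.complex_mass([bp.ComplexComponent("c", mass, copies)])
        many = bp.complex_mass([bp.ComplexComponent("c", mass, copies * factor)])
        assert many == pytest.approx(factor * one, rel=1e-12)

    def test_enumeration_matches_exhaustive_oracle(self):
        e1, e2, target = 97_000.0, 41_000.0, 2_536_000.0
        ranked = bp.enumerate_stoichiometry(e1, e2, target)
        # independent oracle: brute-force enumeration + sort in test code
        oracle = sorted(
            ((d, abs(24 * e2 + 2 * d * e1 - target)) for d in range(13)),
            key=lambda de: (de[1], de[0]),
        )
        got = [(m.components[0].copies // 2, err) for m, err in ranked]
        assert got == [(d, pytest.approx(err)) for d, err in oracle]
        assert ranked[0][0].components[0].copies == 16
        assert ranked[0][1] == 0.0

    def test_core_only_target(self):
        ranked = bp.enumerate_stoichiometry(97_000, 41_000, 24 * 41_000)
        assert ranked[0][0].components[0].copies == 0

    def test_tie_broken_toward_fewer_copies(self):
        # target exactly between the 0- and 1-dimer models
        ranked = bp.enumerate_stoichiometry(100.0, 10.0, 24 * 10.0 + 100.0)
        assert ranked[0][0].components[0].copies == 0
        assert ranked[0][1] == ranked[1][1] == 100.0

    def test_error_nondecreasing_down_ranking(self):
        ranked = bp.enumerate_stoichiometry(97_000, 41_000, 2_450_000)
        errs = [err for _, err in ranked]
        assert errs == sorted(errs)
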