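"""Composition arithmetic: electron density, Z_eff, mixing, basis expansion."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import dectissue as dt
from dectissue.composition import (
    CLOSURE_TOL,
    bragg_ionization_potential,
    electron_fractions,
)
from dectissue.elements import DEFAULT_ELEMENTS

WATER_EPG = 0.1119 * 1 / 1.008 + 0.8881 * 8 / 15.999  # mol e-/g


class TestRelativeElectronDensity:
    def test_water_is_unity(self):
        assert dt.relative_electron_density(dt.water()) == pytest.approx(1.0)

    def test_linear_in_mass_density(self):
        assert dt.relative_electron_density(
            dt.water(mass_density=2.0)
        ) == pytest.approx(2.0)

    def test_pmma_matches_hand_computation(self):
        # C5H8O2, M = 5*12.011 + 8*1.008 + 2*15.999 = 100.117 g/mol
        m = 5 * 12.011 + 8 * 1.008 + 2 * 15.999
        epg = (
            (5 * 12.011 / m) * 6 / 12.011
            + (8 * 1.008 / m) * 1 / 1.008
            + (2 * 15.999 / m) * 8 / 15.999
        )
        expected = 1.19 * epg / WATER_EPG
        assert dt.relative_electron_density(dt.pmma()) == pytest.approx(
            expected, rel=1e-12
        )

    def test_unknown_element_names_symbol(self):
        bad = dt.TissueComposition("odd", {"H": 0.1119, "Xx": 0.8881}, 1.0)
        with pytest.raises(KeyError, match="Xx"):
            dt.relative_electron_density(bad)


class TestEffectiveAtomicNumber:
    def test_single_element_is_its_z(self):
        oxy = dt.TissueComposition("o2", {"O": 1.0}, 1.33)
        for x in (1.0, 1.86, 3.62):
            assert dt.effective_atomic_number(oxy, x) == pytest.approx(8.0)

    def test_exponent_one_is_electron_weighted_mean(self):
        w = dt.water()
        lam = electron_fractions(w)
        expected = lam["H"] * 1 + lam["O"] * 8
        assert dt.effective_atomic_number(w, 1.0) == pytest.approx(expected)

    def test_water_power_mean_oracle(self):
        # brute-force scalar power mean at x = 3.62
        lam_h = (0.1119 * 1 / 1.008) / WATER_EPG
        lam_o = (0.8881 * 8 / 15.999) / WATER_EPG
        expected = (lam_h * 1**3.62 + lam_o * 8**3.62) ** (1 / 3.62)
        assert dt.effective_atomic_number(dt.water(), 3.62) == pytest.approx(
            expected, rel=1e-12
        )

    def test_bounded_by_present_elements(self):
        t = dt.load_reference_basis().get("cortical_bone")
        for x in (0.5, 1.86, 3.62, 6.0):
            z = dt.effective_atomic_number(t, x)
            assert 1.0 <= z <= 20.0

    def test_invalid_exponent(self):
        with pytest.raises(ValueError):
            dt.effective_atomic_number(dt.water(), 0.0)


class TestMixing:
    def test_single_component_identity(self):
        w = dt.water()
        out = dt.mix_by_mass([(w, 1.0)])
        assert out.weight_fractions == w.weight_fractions
        assert out.mass_density == pytest.approx(w.mass_density)

    def test_fifty_fifty_of_identical_is_identity(self):
        t = dt.pmma()
        out = dt.mix_by_mass([(t, 0.5), (t, 0.5)])
        assert out.fraction("C") == pytest.approx(t.fraction("C"))
        assert out.mass_density == pytest.approx(t.mass_density)

    def test_fraction_sum_violation(self):
        with pytest.raises(ValueError):
            dt.mix_by_mass([(dt.water(), 0.6), (dt.pmma(), 0.6)])

    def test_volume_mix_endpoints(self):
        basis = dt.load_reference_basis()
        lung, a = basis.get("lung"), dt.air()
        assert dt.mix_by_volume(lung, a, 1.0).fraction("C") == pytest.approx(
            lung.fraction("C")
        )
        assert dt.mix_by_volume(lung, a, 0.0).mass_density == pytest.approx(
            a.mass_density
        )

    def test_volume_mix_lung_air_oracle(self):
        # 50 vol% lung + 50 vol% air: density is the arithmetic mean and
        # mass fractions follow the density-weighted scalar formula.
        basis = dt.load_reference_basis()
        lung, a = basis.get("lung"), dt.air()
        mix = dt.mix_by_volume(lung, a, 0.5)
        rho = 0.5 * lung.mass_density + 0.5 * a.mass_density
        assert mix.mass_density == pytest.approx(rho)
        w_n = (
            0.5 * lung.mass_density * lung.fraction("N")
            + 0.5 * a.mass_density * a.fraction("N")
        ) / rho
        assert mix.fraction("N") == pytest.approx(w_n, rel=1e-12)
        # composition is mass-dominated by lung
        assert mix.fraction("C") > 0.99 * lung.fraction("C") * (
            0.5 * lung.mass_density / rho
        )

    @given(f=st.floats(0.01, 0.99))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_mass_and_volume_mix_agree_at_equal_density(self, f):
        basis = dt.load_reference_basis()
        a = basis.get("muscle").with_density(1.05)
        b = basis.get("adipose").with_density(1.05)
        by_vol = dt.mix_by_volume(a, b, f)
        by_mass = dt.mix_by_mass([(a, f), (b, 1.0 - f)])
        for sym in by_vol.weight_fractions:
            assert by_vol.fraction(sym) == pytest.approx(
                by_mass.fraction(sym), rel=1e-12, abs=1e-15
            )
        assert by_vol.mass_density == pytest.approx(
            by_mass.mass_density, rel=1e-12
        )

    @given(
        f1=st.floats(0.05, 0.9),
        f2=st.floats(0.05, 0.9),
    )
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_mixture_closure(self, f1, f2):
        basis = dt.load_reference_basis()
        total = f1 + f2
        mix = dt.mix_by_mass(
            [(basis.get("muscle"), f1 / total), (basis.get("adipose"), f2 / total)]
        )
        assert abs(sum(mix.weight_fractions.values()) - 1.0) <= CLOSURE_TOL


class TestRehydrate:
    def test_full_dry_fraction_is_identity(self):
        t = dt.pmma()
        assert dt.rehydrate(t, 1.0).fraction("C") == pytest.approx(t.fraction("C"))

    def test_limit_towards_water(self):
        t = dt.pmma()
        out = dt.rehydrate(t, 1e-9)
        assert out.fraction("O") == pytest.approx(0.8881, rel=1e-6)

    def test_pure_carbon_brain_style_dry_fraction(self):
        # a 13% dry-mass sample of pure carbon rehydrates to
        # w_C = 0.13, w_O = 0.87 * water's oxygen fraction
        carbon = dt.TissueComposition("dry_c", {"C": 1.0}, 2.0)
        out = dt.rehydrate(carbon, 0.13)
        assert out.fraction("C") == pytest.approx(0.13)
        assert out.fraction("O") == pytest.approx(0.87 * 0.8881)
        assert out.fraction("H") == pytest.approx(0.87 * 0.1119)

    def test_invalid_fraction(self):
        with pytest.raises(ValueError):
            dt.rehydrate(dt.pmma(), 0.0)


class TestHydroxyapatiteMixture:
    def test_p_ca_mass_ratio_independent_of_fraction(self):
        # stoichiometry fixes P/Ca at 6 A_P / (10 A_Ca) for any mixing
        expected = 6 * 30.974 / (10 * 40.078)
        for ca in (0.05, 0.1616, 0.30):
            mix = dt.hydroxyapatite_water_mixture(ca)
            assert mix.fraction("P") / mix.fraction("Ca") == pytest.approx(
                expected, rel=1e-12
            )

    def test_calcium_constraint_is_met(self):
        mix = dt.hydroxyapatite_water_mixture(0.1616)
        assert mix.fraction("Ca") == pytest.approx(0.1616, rel=1e-12)

    def test_cortical_recipe_reproduces_reported_fractions(self):
        """The bone-mimicking recipe: water + mineral at 16.16 wt% Ca."""
        mix = dt.hydroxyapatite_water_mixture(0.1616)
        assert round(mix.fraction("P") * 100, 2) == 7.49
        assert round(mix.fraction("O") * 100, 2) == 69.61
        assert round(mix.fraction("H") * 100, 2) == 6.74


class TestBasisExpansion:
    def test_noop_expansion(self, base_basis):
        out = dt.expand_basis(base_basis)
        assert out.names() == base_basis.names()

    def test_low_density_series_count_and_monotonicity(self, base_basis):
        out = dt.expand_basis(base_basis, n_low_density=9)
        added = [
            t for t, p in zip(out.tissues, out.provenance)
            if p == "lung-air-mixture"
        ]
        assert len(added) == 9
        dens = [t.mass_density for t in added]
        assert np.all(np.diff(dens) > 0)

    def test_paper_scale_augmentation_count(self, base_basis):
        spong = dt.spongiosa_series(base_basis, 50)
        out = dt.expand_basis(
            base_basis, spongiosa=spong, n_low_density=40,
            bone_series=dt.BoneSeriesSpec(n_mixtures=40),
        )
        assert len(out) - len(base_basis) >= 135

    def test_duplicate_names_rejected(self, base_basis):
        clash = dt.water(name="water")
        with pytest.raises(ValueError, match="duplicate"):
            dt.expand_basis(base_basis, spongiosa=[clash])

    def test_provenance_tags(self, base_basis):
        spong = dt.spongiosa_series(base_basis, 3)
        out = dt.expand_basis(
            base_basis, spongiosa=spong, n_low_density=2,
            bone_series=dt.BoneSeriesSpec(n_mixtures=2),
        )
        tags = set(out.provenance)
        assert {"base-set", "spongiosa-addition", "lung-air-mixture",
                "bone-series"} <= tags

    def test_all_generated_tissues_close(self, expanded_basis):
        for t in expanded_basis:
            assert abs(sum(t.weight_fractions.values()) - 1.0) <= CLOSURE_TOL


class TestIonizationPotential:
    def test_water_anchoring(self):
        assert bragg_ionization_potential(
            dt.water(), water_i_ev=78.0
        ) == pytest.approx(78.0, rel=1e-12)

    def test_unanchored_bragg_additivity_oracle(self):
        lam_h = (0.1119 * 1 / 1.008) / WATER_EPG
        lam_o = (0.8881 * 8 / 15.999) / WATER_EPG
        expected = math.exp(lam_h * math.log(19.2) + lam_o * math.log(95.0))
        assert bragg_ionization_potential(dt.water()) == pytest.approx(
            expected, rel=1e-12
        )


class TestTissueTableIO:
    @pytest.mark.parametrize("suffix", [".csv", ".json"])
    def test_round_trip(self, tmp_path, base_basis, suffix):
        path = tmp_path / f"tissues{suffix}"
        dt.write_tissue_table(base_basis, path)
        back = dt.read_tissue_table(path)
        assert back.names() == base_basis.names()
        for a, b in zip(back.tissues, base_basis.tissues):
            assert a.mass_density == pytest.approx(b.mass_density)
            assert a.category == b.category
            for sym in b.weight_fractions:
                assert a.fraction(sym) == pytest.approx(b.fraction(sym))

    def test_composition_invariants_enforced(self):
        with pytest.raises(ValueError):
            dt.TissueComposition("bad", {"H": 0.6, "O": 0.6}, 1.0)
        with pytest.raises(ValueError):
            dt.TissueComposition("bad", {"H": -0.1, "O": 1.1}, 1.0)
        with pytest.raises(ValueError):
            dt.TissueComposition("bad", {"H": 0.1119, "O": 0.8881}, 0.0)
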