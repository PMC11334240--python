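"""Voxelwise DECT conversion: assignment, rho_e, Z_eff, I, SPR, density."""

import math

import numpy as np
import pytest

import dectissue as dt
from dectissue.composition import bragg_ionization_potential
from dectissue.dect import (
    ELECTRON_REST_ENERGY_EV,
    ionization_potential,
    mass_density_map,
    spr_map,
    tissue_node_i_map,
    zeff_map,
)
from dectissue.stoichiometric import predict_hu


def single_voxel(hu_low, hu_high):
    return dt.DectVolume(
        np.full((1, 1, 1), float(hu_low)), np.full((1, 1, 1), float(hu_high))
    )


class TestAssignment:
    def test_exact_reference_point(self, basis_table):
        k = 5
        vol = single_voxel(basis_table.hu_low[k], basis_table.hu_high[k])
        idx = dt.assign_composition(vol, basis_table)
        assert idx[0, 0, 0] == k

    def test_tie_breaks_to_lowest_index(self):
        table = dt.BasisTable(
            names=("a", "b", "c"),
            hu_low=np.array([500.0, 100.0, 0.0]),
            hu_high=np.array([500.0, 0.0, 100.0]),
            compositions=(dt.water(name="a"), dt.water(name="b"), dt.water(name="c")),
        )
        # (50, 50) is equidistant to b (index 1) and c (index 2)
        idx = dt.assign_composition(single_voxel(50.0, 50.0), table)
        assert idx[0, 0, 0] == 1

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            dt.DectVolume(np.zeros((2, 2, 2)), np.zeros((2, 2, 3)))

    def test_permutation_invariance_without_ties(
        self, expanded_basis, fitted_scanner, scanner
    ):
        spec = dt.PhantomSpec(
            fills=(expanded_basis.get("muscle"),),
            outer_mm=(60.0, 60.0, 60.0), noise_sigma=(3.0, 3.0), seed=5,
        )
        vol, _ = dt.make_box_phantom(spec, *scanner, spacing=(3.0, 3.0, 3.0))
        table = dt.predict_basis_table(expanded_basis, *fitted_scanner)
        perm = np.random.default_rng(0).permutation(len(expanded_basis))
        permuted = dt.BasisTable(
            names=tuple(table.names[i] for i in perm),
            hu_low=table.hu_low[perm],
            hu_high=table.hu_high[perm],
            compositions=tuple(table.compositions[i] for i in perm),
        )
        names_a = np.array(table.names)[dt.assign_composition(vol, table)]
        names_b = np.array(permuted.names)[dt.assign_composition(vol, permuted)]
        assert (names_a == names_b).all()

    def test_noise_free_phantom_fully_recovered(
        self, expanded_basis, basis_table, scanner
    ):
        spec = dt.PhantomSpec(
            fills=(expanded_basis.get("liver"),),
            outer_mm=(60.0, 60.0, 60.0), noise_sigma=(0.0, 0.0), seed=1,
        )
        vol, truth = dt.make_box_phantom(spec, *scanner, spacing=(3.0, 3.0, 3.0))
        idx = dt.assign_composition(vol, basis_table)
        names = np.array(basis_table.names)
        assert (names[idx[truth.interior_mask]] == "liver").all()


class TestElectronDensityMap:
    def test_water_anchor(self):
        params = dt.SprModelParams(a=1.0, alpha=0.5, b=1.0)
        rho = dt.electron_density_map(single_voxel(0.0, 0.0), params)
        assert rho[0, 0, 0] == pytest.approx(1.0)

    def test_alpha_zero_depends_on_high_only(self):
        params = dt.SprModelParams(a=1.0, alpha=0.0, b=1.0)
        r1 = dt.electron_density_map(single_voxel(500.0, 100.0), params)
        r2 = dt.electron_density_map(single_voxel(-500.0, 100.0), params)
        assert r1[0, 0, 0] == pytest.approx(r2[0, 0, 0])

    def test_insert_recovery_on_noise_free_data(
        self, base_basis, spr_model, scanner
    ):
        for t in base_basis.tissues:
            if t.name == "air":
                continue
            vol = single_voxel(
                predict_hu(t, scanner[0]), predict_hu(t, scanner[1])
            )
            rho = dt.electron_density_map(vol, spr_model)[0, 0, 0]
            assert rho == pytest.approx(
                dt.relative_electron_density(t), rel=0.005
            )


class TestZeffMap:
    def test_water_voxel_gives_water_zeff(self, spr_model):
        z, flagged = zeff_map(
            np.array([1.0]), np.array([0.0]), spr_model
        )
        assert not flagged[0]
        assert z[0] == pytest.approx(spr_model.zeff_water, rel=1e-9)

    def test_low_density_flagged(self, spr_model):
        z, flagged = zeff_map(np.array([0.01]), np.array([-990.0]), spr_model)
        assert flagged[0] and np.isnan(z[0])

    def test_matches_direct_power_mean_on_noise_free_inserts(
        self, base_basis, spr_model, scanner
    ):
        for t in base_basis.tissues:
            if t.name == "air":
                continue
            hul = predict_hu(t, scanner[0])
            huh = predict_hu(t, scanner[1])
            rho = dt.electron_density_map(single_voxel(hul, huh), spr_model)
            z, flagged = zeff_map(rho, np.full((1, 1, 1), hul), spr_model)
            assert not flagged[0, 0, 0]
            direct = dt.effective_atomic_number(t, spr_model.n)
            assert z[0, 0, 0] == pytest.approx(direct, rel=0.02)


class TestIonizationPotential:
    def test_water_anchored_map_returns_water_i(self, spr_model):
        i = ionization_potential(
            np.array([spr_model.zeff_water]), spr_model
        )
        assert i[0] == pytest.approx(78.0, rel=1e-9)

    def test_single_segment_midpoint_is_geometric_mean(self):
        params = dt.SprModelParams(
            i_map=((6.0, math.log(60.0)), (10.0, math.log(240.0)))
        )
        i = ionization_potential(np.array([8.0]), params)
        assert i[0] == pytest.approx(math.sqrt(60.0 * 240.0), rel=1e-12)

    def test_extrapolation_clamps(self):
        params = dt.SprModelParams(
            i_map=((6.0, math.log(60.0)), (10.0, math.log(240.0)))
        )
        assert ionization_potential(np.array([2.0]), params)[0] == pytest.approx(60.0)
        assert ionization_potential(np.array([99.0]), params)[0] == pytest.approx(240.0)

    def test_empty_map_raises(self):
        with pytest.raises(ValueError):
            ionization_potential(np.array([7.0]), dt.SprModelParams())

    def test_reference_tissue_i_recovered(self, expanded_basis, spr_model):
        """Chain Z_eff -> I reproduces each reference tissue's Bragg I
        within 5% (fit-residual scale)."""
        for t in expanded_basis.tissues:
            rho = dt.relative_electron_density(t)
            if rho < spr_model.rho_e_floor:
                continue
            true_i = bragg_ionization_potential(t, water_i_ev=78.0)
            z = dt.effective_atomic_number(t, spr_model.n)
            est = ionization_potential(np.array([z]), spr_model)[0]
            assert est == pytest.approx(true_i, rel=0.05)


class TestSprMap:
    def test_water_identity(self, spr_model):
        spr = spr_map(np.array([1.0]), np.array([78.0]), spr_model)
        assert spr[0] == pytest.approx(1.0, rel=1e-12)

    def test_i_equal_water_collapses_to_rho_e(self, spr_model):
        spr = spr_map(np.array([1.37]), np.array([78.0]), spr_model)
        assert spr[0] == pytest.approx(1.37, rel=1e-12)

    def test_scalar_oracle(self):
        # independent evaluation of the Bethe ratio
        beta = dt.beta_from_energy(100.0)
        params = dt.SprModelParams(beta=beta, i_map=((7.0, math.log(78.0)),))
        rho_e, i_ev = 1.05, 70.0
        b2 = beta**2
        k = 2 * ELECTRON_REST_ENERGY_EV * b2 / (1 - b2)
        expected = rho_e * (math.log(k / i_ev) - b2) / (math.log(k / 78.0) - b2)
        got = spr_map(np.array([rho_e]), np.array([i_ev]), params)
        assert got[0] == pytest.approx(expected, rel=1e-12)

    def test_strictly_decreasing_in_i(self, spr_model):
        i_grid = np.linspace(40.0, 200.0, 33)
        spr = spr_map(np.ones_like(i_grid), i_grid, spr_model)
        assert np.all(np.diff(spr) < 0)

    def test_beta_kinematics(self):
        assert dt.beta_from_energy(100.0) == pytest.approx(0.4282, abs=2e-4)
        # the quoted literature value for comparison workflows
        assert dt.dect.BETA_LITERATURE_100MEV == 0.482


class TestMassDensityMap:
    def test_water_voxel(self, basis_table):
        widx = list(basis_table.names).index("water")
        rho_m = mass_density_map(
            np.array([1.0]), np.array([widx]), basis_table
        )
        assert rho_m[0] == pytest.approx(1.0, rel=1e-9)

    def test_linear_in_rho_e(self, basis_table):
        widx = list(basis_table.names).index("muscle")
        one = mass_density_map(np.array([1.0]), np.array([widx]), basis_table)
        two = mass_density_map(np.array([2.0]), np.array([widx]), basis_table)
        assert two[0] == pytest.approx(2 * one[0], rel=1e-12)

    def test_basis_tissue_nominal_density_recovered(
        self, expanded_basis, basis_table, spr_model, scanner
    ):
        for name in ("muscle", "liver", "cortical_bone", "adipose"):
            t = expanded_basis.get(name)
            vol = single_voxel(
                predict_hu(t, scanner[0]), predict_hu(t, scanner[1])
            )
            maps = dt.convert(vol, basis_table, spr_model)
            assert maps["rho_m"][0, 0, 0] == pytest.approx(
                t.mass_density, abs=max(1e-3, 5e-3 * t.mass_density)
            )


class TestFitSprModel:
    def test_exact_recovery_from_self_consistent_data(self):
        """HU pairs generated from a known parameter set are inverted
        back to that parameter set to 1e-6."""
        true = dt.SprModelParams(
            a=1.02, alpha=0.7, b=1.0, c=6.5, d=-5.5, n=3.62,
        )
        basis = dt.load_reference_basis()
        inserts = [t for t in basis.tissues if t.name != "air"]
        zw = dt.effective_atomic_number(dt.water(), true.n)
        hu_low, hu_high = [], []
        for t in inserts:
            rho = dt.relative_electron_density(t)
            z = dt.effective_atomic_number(t, true.n)
            radicand = rho * (z / zw) ** true.n
            u_low = (radicand - true.d * rho) / true.c - 1.0
            u_high = ((rho - true.b) / true.a + true.alpha * u_low) / (
                1 + true.alpha
            )
            hu_low.append(1000 * u_low)
            hu_high.append(1000 * u_high)
        fit = dt.fit_spr_model(inserts, hu_low, hu_high, n=true.n)
        assert fit.a == pytest.approx(true.a, rel=1e-6)
        assert fit.alpha == pytest.approx(true.alpha, rel=1e-6)
        assert fit.b == pytest.approx(true.b, rel=1e-6)
        assert fit.c == pytest.approx(true.c, rel=1e-6)
        assert fit.d == pytest.approx(true.d, rel=1e-6)

    def test_water_only_inserts_rejected(self):
        waters = [dt.water(mass_density=r, name=f"w{r}") for r in
                  (0.8, 0.9, 1.0, 1.1)]
        with pytest.raises(ValueError, match="rank-deficient"):
            dt.fit_spr_model(waters, [0.0] * 4, [0.0] * 4)

    def test_too_few_inserts_rejected(self):
        with pytest.raises(ValueError):
            dt.fit_spr_model([dt.water()] * 3, [0.0] * 3, [0.0] * 3)

    def test_noisy_holdout_rho_e_rmse_below_one_percent(
        self, base_basis, scanner
    ):
        rng = np.random.default_rng(13)
        # calibration spans the full HU range (lung through compact bone),
        # as physical insert sets do; held-out inserts interpolate
        cal_names = ["lung", "adipose", "muscle", "blood", "red_marrow",
                     "cortical_bone"]
        cal = [base_basis.get(n) for n in cal_names]
        holdout = [
            t for t in base_basis.tissues
            if t.name not in cal_names + ["air"]
        ]
        sigma = 2.0
        hu_l = [predict_hu(t, scanner[0]) + rng.normal(0, sigma) for t in cal]
        hu_h = [predict_hu(t, scanner[1]) + rng.normal(0, sigma) for t in cal]
        fit = dt.fit_spr_model(cal, hu_l, hu_h)
        errs = []
        for t in holdout:
            vol = single_voxel(
                predict_hu(t, scanner[0]), predict_hu(t, scanner[1])
            )
            rho = dt.electron_density_map(vol, fit)[0, 0, 0]
            errs.append(rho / dt.relative_electron_density(t) - 1.0)
        assert np.sqrt(np.mean(np.square(errs))) < 0.01

    def test_spr_model_io_round_trip(self, tmp_path, spr_model):
        path = tmp_path / "spr.json"
        dt.dect.write_spr_model(spr_model, path)
        back = dt.dect.read_spr_model(path)
        assert back.a == pytest.approx(spr_model.a)
        assert back.i_map == spr_model.i_map
        assert back.beta == pytest.approx(spr_model.beta)


class TestNodeIMap:
    def test_nodes_sorted_and_water_anchored(self, base_basis):
        nodes = tissue_node_i_map(list(base_basis.tissues), 3.62)
        zs = [z for z, _ in nodes]
        assert zs == sorted(zs)
        zw = dt.effective_atomic_number(dt.water(), 3.62)
        ln_at_water = np.interp(zw, zs, [l for _, l in nodes])
        assert math.exp(ln_at_water) == pytest.approx(78.0, rel=1e-6)
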