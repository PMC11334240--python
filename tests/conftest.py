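"""Shared fixtures: a small synthetic tissue set and a calibrated scanner."""

import numpy as np
import pytest

import dectissue as dt


@pytest.fixture(scope="session")
def scanner():
    """True generator coefficients of the simulated scanner (low, high)."""
    return (
        dt.StoichiometricParams(8e-5, 3e-3, "80kV"),
        dt.StoichiometricParams(3e-5, 1.5e-3, "140kV"),
    )


@pytest.fixture(scope="session")
def base_basis():
    return dt.load_reference_basis()


@pytest.fixture(scope="session")
def expanded_basis(base_basis):
    spong = dt.spongiosa_series(base_basis, 20)
    return dt.expand_basis(
        base_basis, spongiosa=spong, n_low_density=10,
        bone_series=dt.BoneSeriesSpec(n_mixtures=10),
    )


@pytest.fixture(scope="session")
def fitted_scanner(base_basis, scanner):
    """Noise-free calibration: recovered (low, high) stoichiometric params."""
    inserts = [t for t in base_basis.tissues if t.name != "air"]
    meas_low, meas_high = dt.make_calibration_set(inserts, *scanner, sigma_hu=0.0)
    fit_low, _ = dt.fit_params(meas_low, beam_label="low")
    fit_high, _ = dt.fit_params(meas_high, beam_label="high")
    return fit_low, fit_high


@pytest.fixture(scope="session")
def basis_table(expanded_basis, fitted_scanner):
    return dt.predict_basis_table(expanded_basis, *fitted_scanner)


@pytest.fixture(scope="session")
def spr_model(base_basis, expanded_basis, scanner, basis_table):
    """Self-consistent SPR conversion calibrated on noise-free inserts."""
    inserts = [t for t in base_basis.tissues if t.name != "air"]
    meas_low, meas_high = dt.make_calibration_set(inserts, *scanner, sigma_hu=0.0)
    return dt.fit_spr_model(
        inserts,
        [m.mean_hu for m in meas_low],
        [m.mean_hu for m in meas_high],
        reference_tissues=list(expanded_basis.tissues),
        reference_hu=(basis_table.hu_low, basis_table.hu_high),
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(20240812)
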