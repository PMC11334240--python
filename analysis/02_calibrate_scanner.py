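#!/usr/bin/env python
"""Calibrate the CT-number model and the DECT-to-SPR conversion.

Simulates ROI-mean readouts of tissue-equivalent calibration inserts at
both tube potentials (2 HU voxel noise, averaged over a cylindrical ROI),
fits the two stoichiometric coefficients per beam, then fits the
electron-density / effective-Z / ionization-potential conversion on the
expanded reference basis.  Writes the fitted parameters and a
calibration-residual report.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))

import numpy as np
import pandas as pd

import dectissue as dt
from common import (
    MASTER_SEED,
    RESULTS,
    TRUE_PARAMS_HIGH,
    TRUE_PARAMS_LOW,
    build_expanded_basis,
    calibration_inserts,
)


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    basis = build_expanded_basis()
    inserts = calibration_inserts(dt.load_reference_basis())

    meas_low, meas_high = dt.make_calibration_set(
        inserts, TRUE_PARAMS_LOW, TRUE_PARAMS_HIGH,
        sigma_hu=2.0, seed=MASTER_SEED, n_roi_voxels=400,
    )
    fit_low, rmse_low = dt.fit_params(meas_low, beam_label="80kV")
    fit_high, rmse_high = dt.fit_params(meas_high, beam_label="140kV")
    print(f"80 kV : k1 = {fit_low.k1:.3e} (true {TRUE_PARAMS_LOW.k1:.3e}), "
          f"k2 = {fit_low.k2:.3e}, residual RMSE {rmse_low:.3f} HU")
    print(f"140 kV: k1 = {fit_high.k1:.3e} (true {TRUE_PARAMS_HIGH.k1:.3e}), "
          f"k2 = {fit_high.k2:.3e}, residual RMSE {rmse_high:.3f} HU")
    dt.stoichiometric.write_params(
        {"low": fit_low, "high": fit_high},
        RESULTS / "stoichiometric_params.json",
    )

    table = dt.predict_basis_table(basis, fit_low, fit_high)
    model = dt.fit_spr_model(
        inserts,
        [m.mean_hu for m in meas_low],
        [m.mean_hu for m in meas_high],
        reference_tissues=list(basis.tissues),
        reference_hu=(table.hu_low, table.hu_high),
    )
    dt.dect.write_spr_model(model, RESULTS / "spr_model.json")
    print(f"electron density: a = {model.a:.4f}, alpha = {model.alpha:.4f}, "
          f"b = {model.b:.1f}")
    print(f"Z_eff: c = {model.c:.4f}, d = {model.d:.4f}, n = {model.n}; "
          f"i_map nodes: {len(model.i_map)}")

    rows = []
    for m_l, m_h, t in zip(meas_low, meas_high, inserts):
        rho_true = dt.relative_electron_density(t)
        vol = dt.DectVolume(
            np.full((1, 1, 1), m_l.mean_hu), np.full((1, 1, 1), m_h.mean_hu)
        )
        rho_est = float(dt.electron_density_map(vol, model)[0, 0, 0])
        rows.append({
            "insert": t.name,
            "hu_80": m_l.mean_hu, "hu_140": m_h.mean_hu,
            "rho_e_true": rho_true, "rho_e_est": rho_est,
            "rho_e_rel_err": rho_est / rho_true - 1.0,
        })
    report = pd.DataFrame(rows)
    report.to_csv(RESULTS / "calibration_report.csv", index=False)
    worst = report.rho_e_rel_err.abs().max()
    print(f"worst insert electron-density error: {100 * worst:.2f}%")
    print(f"wrote parameter files and {RESULTS / 'calibration_report.csv'}")


if __name__ == "__main__":
    main()
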