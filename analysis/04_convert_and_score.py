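#!/usr/bin/env python
"""Convert the simulated sample scans and score against ground truth.

Runs the dual-energy conversion (nearest-reference composition, electron
density, SPR, mass density) and the single-energy lookup-table comparator
on each simulated sample, evaluates the beam-path cylinder and target-box
ROIs, and reports mass-weighted compositions plus SPR/density errors and
soft/bony RMSE summaries.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))

import numpy as np
import pandas as pd

import dectissue as dt
from dectissue import volume_io
from dectissue.sect import build_hlut, sect_convert
from common import RESULTS, SCRATCH, SAMPLE_NOISE, build_expanded_basis, study_samples

REPORT_ELEMENTS = ("H", "C", "N", "O", "P", "Ca")
SOFT = ("muscle", "adipose", "brain", "liver")
BONY = ("spongiosa_sample", "cortical_sample")


def rois_for(shape, spacing):
    center = tuple(0.5 * n * s for n, s in zip(shape, spacing))
    extent = tuple(n * s for n, s in zip(shape, spacing))
    return {
        "roi_spr": dt.RoiSpec(
            "cylinder", center=center, axis=0, diameter=40.0,
            length=extent[0] - 24.0,
        ),
        "roi_target": dt.RoiSpec(
            "box",
            corner=tuple(c - 25.0 for c in center),
            extents=(50.0, 50.0, 50.0),
        ),
        "roi_sample": dt.RoiSpec(
            "box", corner=(12.0, 12.0, 12.0),
            extents=tuple(e - 24.0 for e in extent),
        ),
    }


def main() -> None:
    basis = build_expanded_basis()
    samples = study_samples(basis)
    fitted = dt.stoichiometric.read_params(RESULTS / "stoichiometric_params.json")
    model = dt.dect.read_spr_model(RESULTS / "spr_model.json")
    table = dt.predict_basis_table(basis, fitted["low"], fitted["high"])
    hlut = build_hlut(dt.load_reference_basis(), params_high=fitted["high"])

    comp_rows, spr_rows = [], []
    for name, tissue in samples.items():
        low, spacing = volume_io.read_volume(SCRATCH / name / "hu_low.nii.gz")
        high, _ = volume_io.read_volume(SCRATCH / name / "hu_high.nii.gz")
        vol = dt.DectVolume(low, high, spacing)
        maps = dt.convert(vol, table, model, symbols=REPORT_ELEMENTS)
        sect_density, sect_weights = sect_convert(high, hlut)
        rois = rois_for(vol.shape, spacing)

        cyl = dt.roi_mask(vol.shape, spacing, rois["roi_spr"])
        spr_rows.append({
            "sample": name,
            "spr_dect": float(maps["spr"][cyl].mean()),
            "spr_true": dt.bethe_spr(tissue, beta=model.beta),
            "rho_m_dect": float(maps["rho_m"][cyl].mean()),
            "rho_m_sect": float(sect_density[cyl].mean()),
            "rho_m_true": tissue.mass_density,
        })

        for roi_name in ("roi_target", "roi_sample"):
            mask = dt.roi_mask(vol.shape, spacing, rois[roi_name])
            est = dt.mass_weighted_composition(
                {s: maps[f"w_{s}"] for s in REPORT_ELEMENTS},
                maps["rho_m"], mask,
            )
            sect_est = dt.mass_weighted_composition(
                {s: sect_weights.get(s, np.zeros_like(sect_density))
                 for s in REPORT_ELEMENTS},
                sect_density, mask,
            )
            row = {"sample": name, "roi": roi_name}
            for s in REPORT_ELEMENTS:
                row[f"w_{s}_dect"] = 100 * est[s]
                row[f"w_{s}_sect"] = 100 * sect_est[s]
                row[f"w_{s}_true"] = 100 * tissue.fraction(s)
            comp_rows.append(row)

    comp = pd.DataFrame(comp_rows)
    spr = pd.DataFrame(spr_rows)
    comp.to_csv(RESULTS / "composition_report.csv", index=False)
    spr.to_csv(RESULTS / "spr_density_report.csv", index=False)

    # headline RMSE summary (whole-sample ROI, like a bulk assay)
    whole = comp[comp.roi == "roi_sample"].set_index("sample")
    summary = {}
    for method in ("dect", "sect"):
        for s in ("C", "O"):
            soft = whole.loc[list(SOFT)]
            summary[f"{method}_{s}_soft_rmse_wt_pct"] = dt.rmse(
                soft[f"w_{s}_{method}"], soft[f"w_{s}_true"]
            )
        bony = whole.loc[list(BONY)]
        for s in ("P", "Ca"):
            summary[f"{method}_{s}_bony_rmse_wt_pct"] = dt.rmse(
                bony[f"w_{s}_{method}"], bony[f"w_{s}_true"]
            )
    soft_spr = spr[spr["sample"].isin(SOFT)]
    bony_spr = spr[spr["sample"].isin(BONY)]
    summary["spr_soft_rmse_pct"] = 100 * dt.rmse(
        soft_spr.spr_dect, soft_spr.spr_true, relative=True
    )
    summary["spr_bony_rmse_pct"] = 100 * dt.rmse(
        bony_spr.spr_dect, bony_spr.spr_true, relative=True
    )
    summary["rho_m_soft_dect_rmse_pct"] = 100 * dt.rmse(
        soft_spr.rho_m_dect, soft_spr.rho_m_true, relative=True
    )
    summary["rho_m_soft_sect_rmse_pct"] = 100 * dt.rmse(
        soft_spr.rho_m_sect, soft_spr.rho_m_true, relative=True
    )
    pd.Series(summary).to_csv(RESULTS / "rmse_summary.csv", header=False)

    print(spr.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
    print()
    for k, v in summary.items():
        print(f"{k:32s} {v:6.2f}")
    print(f"wrote composition_report.csv, spr_density_report.csv, "
          f"rmse_summary.csv under {RESULTS}/")


if __name__ == "__main__":
    main()
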