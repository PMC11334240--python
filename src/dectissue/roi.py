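"""Region-of-interest definitions and the sample-level statistics.

The validation design evaluates three regions per sample: a 4 cm cylinder
along the proton beam path (SPR analysis), a 5x5x5 cm cube matching the
irradiated target, and the whole sample volume.  Statistics are computed
over voxel centers; ROI geometry lives in world millimetres with the
volume origin at the corner of voxel (0, 0, 0).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class RoiSpec:
    """A cylindrical or box ROI in world coordinates (mm).

    Cylinder: ``axis`` (0/1/2) is the grid axis of the cylinder axis,
    ``center`` its midpoint, ``diameter`` and ``length`` its size.
    Box: half-open [corner, corner + extents) in every dimension.
    """

    kind: str  # "cylinder" | "box"
    center: tuple[float, float, float] | None = None
    axis: int = 0
    diameter: float = 0.0
    length: float = 0.0
    corner: tuple[float, float, float] | None = None
    extents: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        if self.kind == "cylinder":
            if self.center is None:
                raise ValueError("cylinder ROI needs a center")
            if self.diameter <= 0 or self.length <= 0:
                raise ValueError("cylinder diameter/length must be > 0")
            if self.axis not in (0, 1, 2):
                raise ValueError(f"axis must be 0, 1 or 2, got {self.axis}")
        elif self.kind == "box":
            if self.corner is None or self.extents is None:
                raise ValueError("box ROI needs corner and extents")
            if any(e <= 0 for e in self.extents):
                raise ValueError("box extents must be > 0")
        else:
            raise ValueError(f"unknown ROI kind {self.kind!r}")

    def shifted(self, offset: Sequence[float]) -> "RoiSpec":
        off = tuple(float(o) for o in offset)
        if self.kind == "cylinder":
            c = tuple(a + b for a, b in zip(self.center, off))
            return RoiSpec("cylinder", center=c, axis=self.axis,
                           diameter=self.diameter, length=self.length)
        c = tuple(a + b for a, b in zip(self.corner, off))
        return RoiSpec("box", corner=c, extents=self.extents)


def voxel_centers(shape, spacing):
    """World coordinates (mm) of voxel centers along each axis."""
    return [
        (np.arange(n) + 0.5) * s for n, s in zip(shape, spacing)
    ]


def roi_mask(
    shape: Sequence[int], spacing: Sequence[float], roi: RoiSpec
) -> np.ndarray:
    """Boolean inclusion mask: voxel in ROI iff its center lies inside.

    Boxes use the half-open convention [corner, corner + extents);
    cylinders include centers with radial distance <= diameter/2 and
    axial offset within +- length/2.  An ROI that misses the grid
    entirely raises.
    """
    axes = voxel_centers(shape, spacing)
    grids = np.meshgrid(*axes, indexing="ij")
    if roi.kind == "box":
        mask = np.ones(tuple(shape), dtype=bool)
        for g, c, e in zip(grids, roi.corner, roi.extents):
            mask &= (g >= c) & (g < c + e)
    else:
        ax = roi.axis
        radial = [i for i in range(3) if i != ax]
        r2 = np.zeros(tuple(shape))
        for i in radial:
            r2 = r2 + (grids[i] - roi.center[i]) ** 2
        mask = r2 <= (roi.diameter / 2.0) ** 2
        mask &= np.abs(grids[ax] - roi.center[ax]) <= roi.length / 2.0
    if not mask.any():
        raise ValueError("ROI does not intersect the grid")
    return mask


def roi_hu_stats(hu_low: np.ndarray, hu_high: np.ndarray, mask: np.ndarray) -> dict:
    """Per-energy mean and population (N-divisor) std inside the mask."""
    if not np.any(mask):
        raise ValueError("empty ROI mask")
    return {
        "mean_low": float(np.mean(hu_low[mask])),
        "std_low": float(np.std(hu_low[mask])),
        "mean_high": float(np.mean(hu_high[mask])),
        "std_high": float(np.std(hu_high[mask])),
        "n_voxels": int(mask.sum()),
    }


def mass_weighted_composition(
    weights: Mapping[str, np.ndarray],
    density: np.ndarray,
    mask: np.ndarray,
) -> dict[str, float]:
    """Density-weighted mean weight fraction per element within the ROI.

    w^X = sum_i w_i^X rho_i^m / sum_i rho_i^m over the masked voxels —
    the mass-weighted mean composition, exactly as a bulk chemical assay
    of the region would see it.
    """
    if not np.any(mask):
        raise ValueError("empty ROI mask")
    rho = np.asarray(density, dtype=float)[mask]
    if np.any(rho <= 0):
        raise ValueError("non-positive density inside ROI")
    total = rho.sum()
    return {
        sym: float((np.asarray(vol, dtype=float)[mask] * rho).sum() / total)
        for sym, vol in weights.items()
    }


def rmse(
    predicted: Sequence[float],
    reference: Sequence[float],
    relative: bool = False,
) -> float:
    """Root-mean-square error; ``relative`` divides differences by reference."""
    p = np.asarray(predicted, dtype=float)
    r = np.asarray(reference, dtype=float)
    if p.shape != r.shape or p.size == 0:
        raise ValueError(f"length mismatch or empty: {p.shape} vs {r.shape}")
    d = p - r
    if relative:
        d = d / r
    return float(np.sqrt(np.mean(d**2)))


def roi_composition_stats(
    maps: Mapping[str, np.ndarray], mask: np.ndarray
) -> dict:
    """Mass-weighted composition + HU stats bundle for one ROI."""
    weights = {
        k[2:]: v for k, v in maps.items() if k.startswith("w_")
    }
    out = mass_weighted_composition(weights, maps["rho_m"], mask)
    out["mean_spr"] = float(np.mean(maps["spr"][mask]))
    out["mean_rho_m"] = float(np.mean(maps["rho_m"][mask]))
    out["n_voxels"] = int(mask.sum())
    return out


def shift_sensitivity(
    maps: Mapping[str, np.ndarray],
    spacing: Sequence[float],
    roi: RoiSpec,
    shifts_mm: Sequence[float] = (2.0, 5.0, 10.0),
) -> pd.DataFrame:
    """Re-evaluate ROI statistics under per-axis ROI displacements.

    For every axis and +-distance the ROI is shifted, statistics are
    recomputed, and the deviation from the unshifted baseline recorded.
    Shifted ROIs that miss the grid are flagged in the ``valid`` column
    rather than aborting the whole analysis.
    """
    shape = maps["rho_m"].shape
    baseline_mask = roi_mask(shape, spacing, roi)
    baseline = roi_composition_stats(maps, baseline_mask)
    rows = [{"axis": -1, "shift_mm": 0.0, "valid": True, **baseline}]
    for axis in range(3):
        for dist in shifts_mm:
            for sign in (+1.0, -1.0):
                off = [0.0, 0.0, 0.0]
                off[axis] = sign * dist
                row = {"axis": axis, "shift_mm": sign * dist}
                try:
                    m = roi_mask(shape, spacing, roi.shifted(off))
                    row.update(valid=True, **roi_composition_stats(maps, m))
                except ValueError:
                    row.update(valid=False)
                rows.append(row)
    frame = pd.DataFrame(rows)
    value_cols = [
        c for c in frame.columns
        if c not in ("axis", "shift_mm", "valid", "n_voxels")
    ]
    for c in value_cols:
        frame[f"dev_{c}"] = (frame[c] - baseline[c]).abs()
    return frame


def weights_from_densities(
    elemental_density: np.ndarray, mass_density: np.ndarray
) -> np.ndarray:
    """Elemental density (g/cm^3) over mass density -> weight fraction.

    Values above 1 are preserved (they diagnose inconsistent inputs from
    independent density estimates) rather than clipped.
    """
    rho = np.asarray(mass_density, dtype=float)
    if np.any(rho <= 0):
        raise ValueError("mass density must be > 0 everywhere")
    return np.asarray(elemental_density, dtype=float) / rho


def read_roi_specs(path: str | Path) -> dict[str, RoiSpec]:
    """Read named ROI specs from a JSON file."""
    payload = json.loads(Path(path).read_text())
    out = {}
    for name, d in payload.items():
        kind = d["kind"]
        if kind == "cylinder":
            out[name] = RoiSpec(
                "cylinder", center=tuple(d["center"]), axis=d["axis"],
                diameter=d["diameter"], length=d["length"],
            )
        else:
            out[name] = RoiSpec(
                "box", corner=tuple(d["corner"]), extents=tuple(d["extents"]),
            )
    return out
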