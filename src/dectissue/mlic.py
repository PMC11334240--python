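"""Range-based stopping-power-ratio ground truth.

A multi-layer ionization chamber (MLIC) records proton depth-dose curves.
The distal depth at 80% of the Bragg-peak maximum (R80) is the standard
range definition; measuring R80 with the beam path filled by the sample,
by water and by air turns three ranges into the sample's SPR through a
linear water/air interpolation formula.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class DepthDoseCurve:
    """Sampled depth-dose curve: strictly increasing depths (mm), dose >= 0."""

    depths: np.ndarray
    dose: np.ndarray

    def __post_init__(self) -> None:
        depths = np.asarray(self.depths, dtype=float)
        dose = np.asarray(self.dose, dtype=float)
        if depths.size < 3:
            raise ValueError("need at least 3 samples")
        if depths.shape != dose.shape:
            raise ValueError("depth/dose length mismatch")
        if not np.all(np.diff(depths) > 0):
            raise ValueError("depths must be strictly increasing")
        if np.any(dose < 0):
            raise ValueError("dose must be >= 0")
        object.__setattr__(self, "depths", depths)
        object.__setattr__(self, "dose", dose)


def r80_distal(curve: DepthDoseCurve, level: float = 0.8) -> float:
    """Distal depth at ``level`` x maximum dose, by linear interpolation.

    Only the falling edge beyond the global maximum is searched; with a
    noisy tail producing several crossings, the deepest one is returned.
    A curve whose tail never falls below the threshold is truncated and
    raises.
    """
    dose = curve.dose
    depths = curve.depths
    peak = int(np.argmax(dose))
    threshold = level * dose[peak]
    tail_dose = dose[peak:]
    tail_depth = depths[peak:]
    below = tail_dose < threshold
    if not below.any():
        raise ValueError("truncated curve: distal tail never falls below "
                         f"{level:.0%} of the maximum")
    # deepest downward crossing: last index where dose >= thr and next < thr
    crossings = np.nonzero((tail_dose[:-1] >= threshold) & below[1:])[0]
    i = int(crossings[-1])
    d0, d1 = tail_dose[i], tail_dose[i + 1]
    z0, z1 = tail_depth[i], tail_depth[i + 1]
    if d0 == d1:
        return float(z1)
    return float(z0 + (threshold - d0) * (z1 - z0) / (d1 - d0))


def spr_from_ranges(
    r_sample: float, r_water: float, r_air: float, spr_air: float
) -> float:
    """Sample SPR from the three R80 ranges.

    SPR = (R_sample - R_air)/(R_water - R_air) * (1 - SPR_air) + SPR_air,
    with SPR_air the (tiny) stopping-power ratio of dry air at the beam
    energy, supplied from tabulated stopping-power data.
    """
    if r_water == r_air:
        raise ValueError("water and air ranges coincide")
    if not 0.0 < spr_air < 0.01:
        raise ValueError(f"spr_air {spr_air} outside the physical (0, 0.01)")
    frac = (r_sample - r_air) / (r_water - r_air)
    return frac * (1.0 - spr_air) + spr_air


def read_curve(path: str | Path) -> DepthDoseCurve:
    """Two-column CSV (depth_mm, dose) -> curve."""
    frame = pd.read_csv(path)
    cols = list(frame.columns)
    return DepthDoseCurve(
        frame[cols[0]].to_numpy(dtype=float),
        frame[cols[1]].to_numpy(dtype=float),
    )


def write_curve(curve: DepthDoseCurve, path: str | Path) -> None:
    pd.DataFrame(
        {"depth_mm": curve.depths, "dose": curve.dose}
    ).to_csv(path, index=False)
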