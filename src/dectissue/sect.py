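"""Single-energy CT conversion via a piecewise-linear Hounsfield lookup.

The classic treatment-planning route: reference tissues are placed on the
HU axis (either by scanner-calibrated stoichiometric prediction or from a
published node table), and density plus elemental composition are linearly
interpolated in HU between consecutive nodes.  Interpolated weight
fractions are renormalised to restore closure; HU outside the node range
clamps to the end nodes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .composition import TissueBasis
from .elements import DEFAULT_ELEMENTS, ElementTable
from .stoichiometric import StoichiometricParams, predict_hu


@dataclass(frozen=True)
class HlutTable:
    """Sorted HU nodes with densities and per-element weight fractions."""

    hu: np.ndarray                  # (n,), strictly increasing
    density: np.ndarray             # (n,), g/cm^3
    symbols: tuple[str, ...]
    weights: np.ndarray             # (n, n_elements)
    names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        hu = np.asarray(self.hu, dtype=float)
        if hu.size < 2:
            raise ValueError("HLUT needs at least 2 nodes")
        if not np.all(np.diff(hu) > 0):
            raise ValueError("HLUT node HU must be strictly increasing")
        if np.any(np.asarray(self.density) <= 0):
            raise ValueError("HLUT densities must be > 0")

    def __len__(self) -> int:
        return len(self.hu)


def build_hlut(
    basis: TissueBasis,
    params_high: StoichiometricParams | None = None,
    node_hu: Sequence[float] | None = None,
    elements: ElementTable = DEFAULT_ELEMENTS,
    duplicate_tol: float = 1e-9,
) -> HlutTable:
    """Place basis tissues on the HU axis and assemble the lookup table.

    Calibrated flavor: node HU from the stoichiometric prediction at the
    high-energy beam.  Published-table (HLUT) flavor: node HU supplied
    verbatim via ``node_hu`` (one per basis tissue).  Nodes landing on
    the same HU (within ``duplicate_tol``) are collapsed by averaging
    density and composition; output is sorted by HU.
    """
    if len(basis) < 2:
        raise ValueError("need at least 2 tissues to build an HLUT")
    if node_hu is not None:
        hu = np.asarray(node_hu, dtype=float)
        if len(hu) != len(basis):
            raise ValueError("one node HU per basis tissue required")
    elif params_high is not None:
        hu = np.array([predict_hu(t, params_high, elements) for t in basis])
    else:
        raise ValueError("provide fitted parameters or explicit node HUs")

    symbols: list[str] = []
    for t in basis:
        for sym in t.weight_fractions:
            if sym not in symbols:
                symbols.append(sym)
    weights = np.array([[t.fraction(s) for s in symbols] for t in basis])
    density = np.array([t.mass_density for t in basis])
    names = np.array(basis.names())

    order = np.argsort(hu, kind="stable")
    hu, density, weights, names = hu[order], density[order], weights[order], names[order]

    # collapse duplicate-HU nodes by averaging
    keep_hu, keep_rho, keep_w, keep_names = [], [], [], []
    i = 0
    while i < len(hu):
        j = i
        while j + 1 < len(hu) and hu[j + 1] - hu[i] <= duplicate_tol:
            j += 1
        keep_hu.append(hu[i:j + 1].mean())
        keep_rho.append(density[i:j + 1].mean())
        keep_w.append(weights[i:j + 1].mean(axis=0))
        keep_names.append("+".join(names[i:j + 1]))
        i = j + 1
    if len(keep_hu) < 2:
        raise ValueError("fewer than 2 distinct HU nodes after collapsing")
    return HlutTable(
        hu=np.array(keep_hu),
        density=np.array(keep_rho),
        symbols=tuple(symbols),
        weights=np.vstack(keep_w),
        names=tuple(keep_names),
    )


def sect_convert(
    hu: np.ndarray, table: HlutTable
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Density and composition maps from a single-energy HU volume.

    Linear interpolation of density and each raw weight fraction in HU
    within consecutive-node intervals (clamped outside the table), then
    per-voxel renormalisation of the weight fractions to sum exactly 1.
    """
    hu = np.asarray(hu, dtype=float)
    density = np.interp(hu, table.hu, table.density)
    raw = {
        sym: np.interp(hu, table.hu, table.weights[:, k])
        for k, sym in enumerate(table.symbols)
    }
    total = np.zeros_like(hu)
    for vol in raw.values():
        total = total + vol
    weights = {sym: vol / total for sym, vol in raw.items()}
    return density, weights


def sect_interpolate_raw(
    hu: np.ndarray, table: HlutTable
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Like :func:`sect_convert` but without the closure renormalisation."""
    hu = np.asarray(hu, dtype=float)
    density = np.interp(hu, table.hu, table.density)
    weights = {
        sym: np.interp(hu, table.hu, table.weights[:, k])
        for k, sym in enumerate(table.symbols)
    }
    return density, weights


def write_hlut(table: HlutTable, path: str | Path) -> None:
    frame = pd.DataFrame({"hu": table.hu, "density_g_cm3": table.density})
    for k, sym in enumerate(table.symbols):
        frame[sym] = table.weights[:, k]
    frame.to_csv(path, index=False)


def read_hlut(path: str | Path) -> HlutTable:
    frame = pd.read_csv(path)
    symbols = [c for c in frame.columns if c not in ("hu", "density_g_cm3")]
    return HlutTable(
        hu=frame["hu"].to_numpy(dtype=float),
        density=frame["density_g_cm3"].to_numpy(dtype=float),
        symbols=tuple(symbols),
        weights=frame[symbols].to_numpy(dtype=float),
    )
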