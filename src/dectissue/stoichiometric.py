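"""Stoichiometric CT-number prediction and scanner calibration.

A CT scanner's response to a material at a given tube potential is modelled
with the classic three-term attenuation parametrization: photoelectric,
coherent-scatter and Compton contributions scale as Z^3.62, Z^1.86 and the
electron density respectively, leaving exactly two free coefficients (k1,
k2) per beam quality.  Fitting those coefficients to measured mean HU of a
handful of tissue-equivalent calibration inserts lets us predict the CT
number of *any* material of known composition at that beam quality — which
is what places reference tissues in the dual-energy HU plane.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from .composition import (
    TissueBasis,
    TissueComposition,
    effective_atomic_number,
    relative_electron_density,
    water,
)
from .elements import DEFAULT_ELEMENTS, ElementTable

#: Energy-dependence exponents of the photoelectric and coherent terms.
PHOTOELECTRIC_EXPONENT = 3.62
COHERENT_EXPONENT = 1.86


@dataclass(frozen=True)
class StoichiometricParams:
    """Fitted attenuation-model coefficients for one beam quality."""

    k1: float
    k2: float
    beam_label: str = ""

    def __post_init__(self) -> None:
        if self.k1 < 0 or self.k2 < 0:
            raise ValueError(
                f"k1/k2 must be >= 0, got ({self.k1}, {self.k2})"
            )


@dataclass(frozen=True)
class CalibrationMeasurement:
    """Mean HU of one calibration insert at one beam quality."""

    insert: TissueComposition
    mean_hu: float
    hu_std: float | None = None

    def __post_init__(self) -> None:
        if self.hu_std is not None and self.hu_std < 0:
            raise ValueError("hu_std must be >= 0")


@dataclass(frozen=True)
class BasisTable:
    """Reference tissues with their predicted (HU_low, HU_high) coordinates.

    This is the nearest-neighbour search space of the composition
    assignment: one entry per basis tissue, order preserved.
    """

    names: tuple[str, ...]
    hu_low: np.ndarray
    hu_high: np.ndarray
    compositions: tuple[TissueComposition, ...]

    def __post_init__(self) -> None:
        n = len(self.names)
        if n == 0:
            raise ValueError("empty basis table")
        if not (len(self.hu_low) == len(self.hu_high) == len(self.compositions) == n):
            raise ValueError("basis table field length mismatch")

    def __len__(self) -> int:
        return len(self.names)


def _attenuation_terms(
    comp: TissueComposition, elements: ElementTable
) -> tuple[float, float, float]:
    """(rho_e_hat, Z^3.62 power mean ** 3.62, Z^1.86 power mean ** 1.86)."""
    rho_e = relative_electron_density(comp, elements)
    z_pe = effective_atomic_number(comp, PHOTOELECTRIC_EXPONENT, elements)
    z_coh = effective_atomic_number(comp, COHERENT_EXPONENT, elements)
    return rho_e, z_pe ** PHOTOELECTRIC_EXPONENT, z_coh ** COHERENT_EXPONENT


def predict_hu(
    comp: TissueComposition,
    params: StoichiometricParams,
    elements: ElementTable = DEFAULT_ELEMENTS,
) -> float:
    """Predicted CT number (HU) of a material at a calibrated beam quality.

    HU = 1000 (u - 1) with u the attenuation ratio to water:
    u = rho_e_hat (1 + k1 Zpe^3.62 + k2 Zcoh^1.86) / (same for water).
    Water maps to 0 exactly by construction.
    """
    rho_e, zpe, zcoh = _attenuation_terms(comp, elements)
    _, zpe_w, zcoh_w = _attenuation_terms(water(), elements)
    u = rho_e * (1.0 + params.k1 * zpe + params.k2 * zcoh) / (
        1.0 + params.k1 * zpe_w + params.k2 * zcoh_w
    )
    return 1000.0 * (u - 1.0)


def fit_params(
    measurements: Sequence[CalibrationMeasurement],
    elements: ElementTable = DEFAULT_ELEMENTS,
    beam_label: str = "",
    weighted: bool = False,
) -> tuple[StoichiometricParams, float]:
    """Fit (k1, k2) to insert measurements; returns (params, RMSE in HU).

    Bounded least squares (k >= 0) on the residual predict_hu - mean_hu,
    optionally 1/sigma^2-weighted.  Requires at least three inserts
    spanning two distinct effective atomic numbers, otherwise the design
    is rank-deficient and the photoelectric/coherent terms cannot be
    separated from the electron-density scaling.
    """
    if len(measurements) < 3:
        raise ValueError("need at least 3 calibration measurements")
    terms = np.array(
        [_attenuation_terms(m.insert, elements) for m in measurements]
    )
    if np.ptp(terms[:, 1]) < 1e-9 * max(terms[:, 1].max(), 1.0):
        raise ValueError(
            "rank-deficient calibration: all inserts share one effective Z"
        )
    hu = np.array([m.mean_hu for m in measurements])
    if weighted:
        sig = np.array(
            [m.hu_std if m.hu_std else 1.0 for m in measurements], dtype=float
        )
        w = 1.0 / np.maximum(sig, 1e-12)
    else:
        w = np.ones(len(measurements))
    _, zpe_w, zcoh_w = _attenuation_terms(water(), elements)
    rho_e, zpe, zcoh = terms[:, 0], terms[:, 1], terms[:, 2]

    def residual(k):
        k1, k2 = k
        u = rho_e * (1.0 + k1 * zpe + k2 * zcoh) / (
            1.0 + k1 * zpe_w + k2 * zcoh_w
        )
        return w * (1000.0 * (u - 1.0) - hu)

    sol = least_squares(
        residual, x0=[1e-4, 1e-4], bounds=([0.0, 0.0], [np.inf, np.inf]),
        xtol=1e-14, ftol=1e-14, gtol=1e-14,
    )
    params = StoichiometricParams(sol.x[0], sol.x[1], beam_label)
    rmse = float(np.sqrt(np.mean((residual(sol.x) / w) ** 2)))
    return params, rmse


def predict_basis_table(
    basis: TissueBasis,
    params_low: StoichiometricParams,
    params_high: StoichiometricParams,
    elements: ElementTable = DEFAULT_ELEMENTS,
) -> BasisTable:
    """Place every basis tissue in the (HU_low, HU_high) plane."""
    hu_low = np.array([predict_hu(t, params_low, elements) for t in basis])
    hu_high = np.array([predict_hu(t, params_high, elements) for t in basis])
    return BasisTable(
        names=tuple(basis.names()),
        hu_low=hu_low,
        hu_high=hu_high,
        compositions=tuple(basis.tissues),
    )


# ---------------------------------------------------------------------------
# Parameter / measurement I/O
# ---------------------------------------------------------------------------

def write_params(params: dict[str, StoichiometricParams], path: str | Path) -> None:
    payload = {
        label: {"k1": p.k1, "k2": p.k2, "beam_label": p.beam_label or label}
        for label, p in params.items()
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_params(path: str | Path) -> dict[str, StoichiometricParams]:
    payload = json.loads(Path(path).read_text())
    return {
        label: StoichiometricParams(d["k1"], d["k2"], d.get("beam_label", label))
        for label, d in payload.items()
    }
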