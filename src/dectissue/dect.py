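"""Dual-energy CT to tissue-property maps.

Converts a co-registered pair of low/high-energy HU volumes into voxelwise
relative electron density, effective atomic number, mean excitation energy,
proton stopping-power ratio (SPR), mass density and elemental composition.

The electron-density and effective-Z parametrizations follow the
weighted-subtraction approach of Saito and Sagara: rho_e_hat is an affine
function of a weighted difference of the two CT numbers, and Z_eff follows
from rho_e_hat together with the low-energy image.  Z_eff is mapped to the
mean excitation energy I through a piecewise log-linear relation fitted on
reference tissues, and SPR is evaluated with the Bethe stopping-power
ratio at a fixed proton speed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .composition import (
    TissueComposition,
    air,
    bragg_ionization_potential,
    effective_atomic_number,
    electrons_per_gram,
    relative_electron_density,
    water,
)
from .elements import DEFAULT_ELEMENTS, ElementTable
from .stoichiometric import BasisTable

#: Electron rest energy in eV.
ELECTRON_REST_ENERGY_EV = 0.510999e6
#: Proton rest energy in MeV (for beta-from-energy kinematics).
PROTON_REST_ENERGY_MEV = 938.272
#: The conventional water mean excitation energy used here (Ziegler scale).
WATER_I_EV = 78.0
#: Proton speed ratio quoted alongside "100 MeV" in parts of the
#: literature; relativistic kinematics at 100 MeV actually gives 0.4282.
BETA_LITERATURE_100MEV = 0.482


def beta_from_energy(kinetic_mev: float) -> float:
    """Relativistic proton speed ratio v/c at a given kinetic energy."""
    if kinetic_mev <= 0:
        raise ValueError("kinetic energy must be > 0")
    gamma = 1.0 + kinetic_mev / PROTON_REST_ENERGY_MEV
    return math.sqrt(1.0 - 1.0 / gamma**2)


@dataclass(frozen=True)
class DectVolume:
    """Co-registered low/high-energy HU volumes with voxel spacing (mm)."""

    hu_low: np.ndarray
    hu_high: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        low = np.asarray(self.hu_low, dtype=float)
        high = np.asarray(self.hu_high, dtype=float)
        if low.shape != high.shape:
            raise ValueError(
                f"energy volumes differ in shape: {low.shape} vs {high.shape}"
            )
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be > 0, got {self.spacing}")
        object.__setattr__(self, "hu_low", low)
        object.__setattr__(self, "hu_high", high)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.hu_low.shape


@dataclass(frozen=True)
class SprModelParams:
    """Calibrated coefficients of the DECT-to-SPR conversion.

    rho_e_hat = a * [(1+alpha) u_high - alpha u_low] + b,   u = HU/1000
    Z_eff     = Z_eff,w * [(c (u_low + 1) + d rho_e_hat) / rho_e_hat]^(1/n)
    ln I      = piecewise-linear in Z_eff (i_map nodes), water anchored
                at I_w; SPR from the Bethe ratio at speed beta.

    The Z_eff radicand is affine in the reduced low-energy attenuation
    (u_low + 1) *and* the electron density: for a single-term
    photoelectric attenuation model with exponent n this inversion is
    exact, whereas a numerator affine in u_low alone leaves percent-level
    Z_eff residuals for soft tissues.  Water anchoring implies c + d = 1.
    """

    a: float = 1.0
    alpha: float = 0.0
    b: float = 1.0
    n: float = 3.3
    c: float = 1.0
    d: float = 0.0
    i_map: tuple[tuple[float, float], ...] = ()  # (Z_eff, ln I) nodes
    beta: float = field(default_factory=lambda: beta_from_energy(100.0))
    i_water_ev: float = WATER_I_EV
    zeff_water: float = 7.4776  # overwritten on fit for the chosen n
    rho_e_floor: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 < self.beta < 1.0:
            raise ValueError(f"beta must be in (0,1), got {self.beta}")
        if self.i_water_ev <= 0:
            raise ValueError("water I must be > 0")
        zs = [z for z, _ in self.i_map]
        if zs != sorted(zs):
            raise ValueError("i_map nodes must be sorted in Z_eff")


# ---------------------------------------------------------------------------
# Voxelwise maps
# ---------------------------------------------------------------------------

def assign_composition(
    dect: DectVolume, table: BasisTable, chunk: int = 262144
) -> np.ndarray:
    """Nearest-reference-tissue index per voxel, no interpolation.

    Each voxel is assigned the basis entry minimising the Euclidean
    distance in the raw (HU_low, HU_high) plane; exact ties go to the
    lowest entry index (``np.argmin`` first-occurrence semantics).
    """
    low = dect.hu_low.ravel()
    high = dect.hu_high.ravel()
    ref_low = np.asarray(table.hu_low)
    ref_high = np.asarray(table.hu_high)
    out = np.empty(low.size, dtype=np.int32)
    for start in range(0, low.size, chunk):
        sl = slice(start, min(start + chunk, low.size))
        d2 = (low[sl, None] - ref_low[None, :]) ** 2 + (
            high[sl, None] - ref_high[None, :]
        ) ** 2
        out[sl] = np.argmin(d2, axis=1)
    return out.reshape(dect.shape)


def electron_density_map(
    dect: DectVolume, params: SprModelParams
) -> np.ndarray:
    """Relative electron density from the weighted CT-number difference."""
    u_low = dect.hu_low / 1000.0
    u_high = dect.hu_high / 1000.0
    return params.a * ((1.0 + params.alpha) * u_high - params.alpha * u_low) + params.b


def zeff_map(
    rho_e: np.ndarray, hu_low: np.ndarray, params: SprModelParams
) -> tuple[np.ndarray, np.ndarray]:
    """Effective atomic number map plus an air/artifact flag mask.

    Voxels whose electron density falls below ``rho_e_floor`` or whose
    radicand is non-positive are flagged (True in the returned mask) and
    carry Z_eff = NaN; downstream steps substitute air properties there
    rather than raising.
    """
    rho_e = np.asarray(rho_e, dtype=float)
    u_low = np.asarray(hu_low, dtype=float) / 1000.0
    flagged = rho_e < params.rho_e_floor
    radicand = np.full(rho_e.shape, np.nan)
    ok = ~flagged
    radicand[ok] = (
        params.c * (u_low[ok] + 1.0) + params.d * rho_e[ok]
    ) / rho_e[ok]
    bad = ok & ~(radicand > 0)
    flagged = flagged | bad
    zeff = np.full(rho_e.shape, np.nan)
    good = ~flagged
    zeff[good] = params.zeff_water * radicand[good] ** (1.0 / params.n)
    return zeff, flagged


def ionization_potential(
    zeff: np.ndarray, params: SprModelParams
) -> np.ndarray:
    """Mean excitation energy I (eV) from Z_eff via the fitted log-linear map.

    Piecewise-linear interpolation of ln I over the i_map nodes; Z_eff
    outside the node range clamps to the end segments' endpoint values.
    NaN Z_eff (flagged voxels) propagates to NaN I.
    """
    if not params.i_map:
        raise ValueError("i_map is empty; fit or supply an I(Z_eff) mapping")
    nodes_z = np.array([z for z, _ in params.i_map])
    nodes_ln = np.array([ln for _, ln in params.i_map])
    zeff = np.asarray(zeff, dtype=float)
    ln_i = np.interp(zeff, nodes_z, nodes_ln)
    ln_i = np.where(np.isnan(zeff), np.nan, ln_i)
    return np.exp(ln_i)


def spr_map(
    rho_e: np.ndarray, i_ev: np.ndarray, params: SprModelParams
) -> np.ndarray:
    """Proton stopping-power ratio via the Bethe ratio.

    SPR = rho_e_hat * [ln(2 me c^2 beta^2 / (I (1-beta^2))) - beta^2]
                    / [ln(2 me c^2 beta^2 / (I_w (1-beta^2))) - beta^2]

    Voxels with NaN I (air/artifact flags) fall back to the water
    stopping number, i.e. SPR = rho_e_hat, which is negligible at air
    densities.  I values driving the log argument below 1 are treated
    the same way.
    """
    rho_e = np.asarray(rho_e, dtype=float)
    i_ev = np.asarray(i_ev, dtype=float)
    beta2 = params.beta**2
    k = 2.0 * ELECTRON_REST_ENERGY_EV * beta2 / (1.0 - beta2)
    denom = math.log(k / params.i_water_ev) - beta2
    with np.errstate(invalid="ignore", divide="ignore"):
        numer = np.log(k / i_ev) - beta2
    bad = ~np.isfinite(numer) | (k / i_ev <= 1.0)
    numer = np.where(bad, denom, numer)
    return rho_e * numer / denom


def mass_density_map(
    rho_e: np.ndarray,
    assignment: np.ndarray,
    table: BasisTable,
    elements: ElementTable = DEFAULT_ELEMENTS,
    flagged: np.ndarray | None = None,
) -> np.ndarray:
    """Mass density (g/cm^3) from electron density and assigned composition.

    rho_m = rho_e_hat * (electrons per cm^3 of water) / (electrons per
    gram of the assigned tissue); flagged voxels get the air value.
    """
    water_epg = electrons_per_gram(water(), elements)
    per_tissue = np.array(
        [water_epg / electrons_per_gram(t, elements) for t in table.compositions]
    )
    rho_m = np.asarray(rho_e, dtype=float) * per_tissue[assignment]
    if flagged is not None:
        rho_m = np.where(flagged, air().mass_density, rho_m)
    return rho_m


def composition_maps(
    assignment: np.ndarray,
    table: BasisTable,
    symbols: Sequence[str],
    flagged: np.ndarray | None = None,
) -> dict[str, np.ndarray]:
    """Per-element weight-fraction volumes from the assignment map."""
    the_air = air()
    out = {}
    for sym in symbols:
        per_tissue = np.array([t.fraction(sym) for t in table.compositions])
        vol = per_tissue[assignment]
        if flagged is not None:
            vol = np.where(flagged, the_air.fraction(sym), vol)
        out[sym] = vol
    return out


# ---------------------------------------------------------------------------
# Closed-form per-material SPR (ground truth / oracle route)
# ---------------------------------------------------------------------------

def bethe_spr(
    comp: TissueComposition,
    beta: float | None = None,
    i_water_ev: float = WATER_I_EV,
    elements: ElementTable = DEFAULT_ELEMENTS,
) -> float:
    """Closed-form Bethe SPR of a material from its composition.

    Uses the Bragg-additivity I anchored so that water evaluates to
    ``i_water_ev``; this is the ground-truth route against which the
    voxelwise pipeline (fitted i_map) is validated.
    """
    if beta is None:
        beta = beta_from_energy(100.0)
    rho_e = relative_electron_density(comp, elements)
    i_ev = bragg_ionization_potential(comp, elements, water_i_ev=i_water_ev)
    beta2 = beta**2
    k = 2.0 * ELECTRON_REST_ENERGY_EV * beta2 / (1.0 - beta2)
    return rho_e * (math.log(k / i_ev) - beta2) / (
        math.log(k / i_water_ev) - beta2
    )


# ---------------------------------------------------------------------------
# Model calibration
# ---------------------------------------------------------------------------

def fit_i_map(
    tissues: Sequence[TissueComposition],
    n: float,
    elements: ElementTable = DEFAULT_ELEMENTS,
    i_water_ev: float = WATER_I_EV,
    split_zeff: float = 8.5,
) -> tuple[tuple[float, float], ...]:
    """Two-segment log-linear I(Z_eff) fit over reference tissues.

    The soft-tissue segment (Z_eff <= split) is constrained to pass
    exactly through the water point (Z_eff,w, ln I_w); the bone segment
    (Z_eff > split) is an ordinary least-squares line.  Returned as
    sorted (Z_eff, ln I) nodes with a linear bridge between segments and
    clamped extrapolation outside.
    """
    zw = effective_atomic_number(water(), n, elements)
    pts = []
    for t in tissues:
        z = effective_atomic_number(t, n, elements)
        i_ev = bragg_ionization_potential(t, elements, water_i_ev=i_water_ev)
        pts.append((z, math.log(i_ev)))
    soft = [(z, l) for z, l in pts if z <= split_zeff]
    bone = [(z, l) for z, l in pts if z > split_zeff]
    ln_iw = math.log(i_water_ev)

    nodes: list[tuple[float, float]] = []
    # soft segment through the water anchor
    dz = np.array([z - zw for z, _ in soft])
    dl = np.array([l - ln_iw for _, l in soft])
    slope_s = float(dz @ dl / (dz @ dz)) if np.any(dz != 0) else 0.0
    z_lo = min([z for z, _ in soft] + [zw])
    z_hi = max([z for z, _ in soft] + [zw])
    nodes.append((z_lo, ln_iw + slope_s * (z_lo - zw)))
    nodes.append((z_hi, ln_iw + slope_s * (z_hi - zw)))
    if len(bone) >= 2:
        zb = np.array([z for z, _ in bone])
        lb = np.array([l for _, l in bone])
        slope_b, icept_b = np.polyfit(zb, lb, 1)
        nodes.append((float(zb.min()), float(slope_b * zb.min() + icept_b)))
        nodes.append((float(zb.max()), float(slope_b * zb.max() + icept_b)))
    elif len(bone) == 1:
        nodes.append(bone[0])
    nodes.sort(key=lambda p: p[0])
    return tuple(nodes)


def tissue_node_i_map(
    tissues: Sequence[TissueComposition],
    n: float,
    elements: ElementTable = DEFAULT_ELEMENTS,
    i_water_ev: float = WATER_I_EV,
    collapse_dz: float = 1e-3,
) -> tuple[tuple[float, float], ...]:
    """Dense I(Z_eff) map interpolating through the reference tissues.

    One (Z_eff, ln I) node per reference tissue (Bragg-additivity I on
    the water-anchored scale), sorted by Z_eff with near-coincident
    nodes collapsed by averaging.  Because every reference tissue sits
    on a node, the map reproduces each tissue's own I exactly, which the
    coarser two-segment regression cannot; extrapolation clamps to the
    end nodes.
    """
    pts = []
    for t in tissues:
        z = effective_atomic_number(t, n, elements)
        i_ev = bragg_ionization_potential(t, elements, water_i_ev=i_water_ev)
        pts.append((z, math.log(i_ev)))
    zw = effective_atomic_number(water(), n, elements)
    pts.append((zw, math.log(i_water_ev)))
    pts.sort(key=lambda p: p[0])
    return _collapse_nodes(pts, collapse_dz)


def _collapse_nodes(
    pts: Sequence[tuple[float, float]], collapse_dz: float
) -> tuple[tuple[float, float], ...]:
    """Average groups of nodes closer than ``collapse_dz`` in Z_eff."""
    nodes: list[tuple[float, float]] = []
    i = 0
    while i < len(pts):
        j = i
        while j + 1 < len(pts) and pts[j + 1][0] - pts[i][0] <= collapse_dz:
            j += 1
        group = pts[i:j + 1]
        nodes.append(
            (sum(p[0] for p in group) / len(group),
             sum(p[1] for p in group) / len(group))
        )
        i = j + 1
    return tuple(nodes)


def fit_spr_model(
    inserts: Sequence[TissueComposition],
    hu_low: Sequence[float],
    hu_high: Sequence[float],
    reference_tissues: Sequence[TissueComposition] | None = None,
    reference_hu: tuple[Sequence[float], Sequence[float]] | None = None,
    n: float = 3.3,
    beta: float | None = None,
    i_water_ev: float = WATER_I_EV,
    anchor_water: bool = True,
    i_map_mode: str = "nodes",
    elements: ElementTable = DEFAULT_ELEMENTS,
) -> SprModelParams:
    """Calibrate the DECT conversion from insert scans of known composition.

    (a, alpha, b) come from a linear least-squares fit of the known
    relative electron densities on (u_high, u_low); (c, d) from a linear
    fit of (Z_eff/Z_eff,w)^n * rho_e_hat on (u_low + 1, rho_e_hat); the
    i_map over
    ``reference_tissues`` (defaulting to the inserts) either as a dense
    per-tissue node interpolation (``i_map_mode="nodes"``, default) or a
    two-segment soft/bone log-linear regression (``"two-segment"``).
    Requires at least 4 inserts spanning soft- and bone-like effective
    atomic numbers.

    With ``anchor_water`` (the default) both affine fits are constrained
    through the water point (HU = 0, rho_e_hat = 1, Z_eff = Z_eff,w), so
    b = d = 1 exactly: CT numbers are defined relative to water, and the
    anchor makes the whole chain exact for a water voxel by construction.
    """
    if len(inserts) < 4:
        raise ValueError("need at least 4 calibration inserts")
    if not (len(inserts) == len(hu_low) == len(hu_high)):
        raise ValueError("insert/measurement length mismatch")
    u_low = np.asarray(hu_low, dtype=float) / 1000.0
    u_high = np.asarray(hu_high, dtype=float) / 1000.0
    rho_e = np.array([relative_electron_density(t, elements) for t in inserts])
    zeff = np.array(
        [effective_atomic_number(t, n, elements) for t in inserts]
    )
    if np.ptp(zeff) < 0.5:
        raise ValueError(
            "rank-deficient calibration: inserts span too little Z_eff"
        )

    # rho_e_hat = p u_high + q u_low + b  with p = a(1+alpha), q = -a alpha
    if anchor_water:
        design = np.column_stack([u_high, u_low])
        (p, q), *_ = np.linalg.lstsq(design, rho_e - 1.0, rcond=None)
        b = 1.0
    else:
        design = np.column_stack([u_high, u_low, np.ones_like(u_low)])
        (p, q, b), *_ = np.linalg.lstsq(design, rho_e, rcond=None)
    a = p + q
    if abs(a) < 1e-12:
        raise ValueError("degenerate electron-density fit (a ~ 0)")
    alpha = -q / a

    zw = effective_atomic_number(water(), n, elements)
    # (zeff/zw)^n rho_e = c (u_low + 1) + d rho_e
    target = (zeff / zw) ** n * rho_e
    if anchor_water:
        # constrained through water: c + d = 1
        x = u_low + 1.0 - rho_e
        y = target - rho_e
        c = float(x @ y / (x @ x))
        d = 1.0 - c
    else:
        design2 = np.column_stack([u_low + 1.0, rho_e])
        (c, d), *_ = np.linalg.lstsq(design2, target, rcond=None)

    refs = list(reference_tissues) if reference_tissues is not None else list(inserts)
    if all(t.name != "water" for t in refs):
        refs.append(water())
    if i_map_mode == "nodes":
        if reference_hu is not None:
            # calibrate the I map in the pipeline's own Z_eff coordinate:
            # node abscissae are the *model-estimated* Z_eff of each
            # reference tissue at its (noise-free) HU pair, so the chain
            # reproduces reference I values exactly at reference points.
            ref_ul = np.asarray(reference_hu[0], dtype=float) / 1000.0
            ref_uh = np.asarray(reference_hu[1], dtype=float) / 1000.0
            rho_ref = a * ((1.0 + alpha) * ref_uh - alpha * ref_ul) + b
            z_nodes, ln_nodes = [], []
            for t, ul, rho_r in zip(refs, ref_ul, rho_ref):
                if rho_r < 0.05:
                    continue
                radicand = (c * (ul + 1.0) + d * rho_r) / rho_r
                if radicand <= 0:
                    continue
                z_nodes.append(zw * radicand ** (1.0 / n))
                ln_nodes.append(
                    math.log(
                        bragg_ionization_potential(
                            t, elements, water_i_ev=i_water_ev
                        )
                    )
                )
            z_nodes.append(zw)
            ln_nodes.append(math.log(i_water_ev))
            i_map = _collapse_nodes(
                sorted(zip(z_nodes, ln_nodes)), collapse_dz=1e-3
            )
        else:
            i_map = tissue_node_i_map(refs, n, elements, i_water_ev=i_water_ev)
    elif i_map_mode == "two-segment":
        i_map = fit_i_map(refs, n, elements, i_water_ev=i_water_ev)
    else:
        raise ValueError(f"unknown i_map_mode {i_map_mode!r}")

    kwargs = {}
    if beta is not None:
        kwargs["beta"] = beta
    return SprModelParams(
        a=float(a), alpha=float(alpha), b=float(b), n=n,
        c=float(c), d=float(d), i_map=i_map,
        i_water_ev=i_water_ev, zeff_water=zw, **kwargs,
    )


# ---------------------------------------------------------------------------
# End-to-end conversion and parameter I/O
# ---------------------------------------------------------------------------

def convert(
    dect: DectVolume,
    table: BasisTable,
    params: SprModelParams,
    symbols: Sequence[str] = ("H", "C", "N", "O", "P", "Ca"),
    elements: ElementTable = DEFAULT_ELEMENTS,
) -> dict[str, np.ndarray]:
    """Full DECT conversion: returns a dict of voxelwise maps.

    Keys: ``tissue_index``, ``flagged``, ``rho_e``, ``zeff``, ``i_ev``,
    ``spr``, ``rho_m``, and one ``w_<element>`` entry per requested symbol.
    """
    assignment = assign_composition(dect, table)
    rho_e = electron_density_map(dect, params)
    zeff, flagged = zeff_map(rho_e, dect.hu_low, params)
    i_ev = ionization_potential(zeff, params)
    spr = spr_map(rho_e, i_ev, params)
    rho_m = mass_density_map(rho_e, assignment, table, elements, flagged)
    out = {
        "tissue_index": assignment,
        "flagged": flagged,
        "rho_e": rho_e,
        "zeff": zeff,
        "i_ev": i_ev,
        "spr": spr,
        "rho_m": rho_m,
    }
    for sym, vol in composition_maps(assignment, table, symbols, flagged).items():
        out[f"w_{sym}"] = vol
    return out


def write_spr_model(params: SprModelParams, path: str | Path) -> None:
    payload = {
        "a": params.a, "alpha": params.alpha, "b": params.b,
        "n": params.n, "c": params.c, "d": params.d,
        "i_map": [list(p) for p in params.i_map],
        "beta": params.beta, "i_water_ev": params.i_water_ev,
        "zeff_water": params.zeff_water, "rho_e_floor": params.rho_e_floor,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_spr_model(path: str | Path) -> SprModelParams:
    d = json.loads(Path(path).read_text())
    d["i_map"] = tuple(tuple(p) for p in d["i_map"])
    return SprModelParams(**d)
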