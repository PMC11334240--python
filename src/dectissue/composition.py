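"""Elemental compositions of tissues and the reference-tissue basis.

A material is described by its elemental mass fractions and its mass
density.  This module provides the composition arithmetic that the rest of
the pipeline builds on: relative electron density, effective atomic number,
mass- and volume-weighted mixing, rehydration of dried samples, and the
expansion of a base set of published human tissues with spongiosa,
lung--air mixtures and a dense-bone series so that the dual-energy CT
number plane is densely covered.

All weight fractions are dimensionless mass fractions in [0, 1] that sum
to one; densities are in g/cm^3.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .elements import DEFAULT_ELEMENTS, ElementTable

CLOSURE_TOL = 1e-6

#: Permitted categories for a tissue entry.
CATEGORIES = ("soft", "spongiosa", "bone", "low_density", "other")

#: ICRU-style two-component water composition.
WATER_WEIGHT_FRACTIONS = {"H": 0.1119, "O": 0.8881}

#: Standard dry air (mass fractions) and its density at ~20 C, 1 atm.
AIR_WEIGHT_FRACTIONS = {"N": 0.755, "O": 0.232, "Ar": 0.013}
AIR_DENSITY = 1.205e-3


@dataclass(frozen=True)
class TissueComposition:
    """A named material: elemental mass fractions plus mass density.

    Parameters
    ----------
    name : str
        Unique identifier within a basis.
    weight_fractions : dict
        Element symbol -> mass fraction; fractions must be non-negative
        and sum to 1 within ``CLOSURE_TOL``.  Zero entries are dropped.
    mass_density : float
        Mass density in g/cm^3 (> 1e-4; a near-zero air entry is the only
        intentionally low value).
    category : str
        One of ``soft``, ``spongiosa``, ``bone``, ``low_density``, ``other``.
    """

    name: str
    weight_fractions: Mapping[str, float]
    mass_density: float
    category: str = "other"

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(
                f"category {self.category!r} not in {CATEGORIES}"
            )
        fracs = {
            sym: float(w)
            for sym, w in self.weight_fractions.items()
            if w != 0.0
        }
        if not fracs:
            raise ValueError(f"{self.name!r}: empty composition")
        if any(w < 0 for w in fracs.values()):
            raise ValueError(f"{self.name!r}: negative weight fraction")
        total = sum(fracs.values())
        if abs(total - 1.0) > CLOSURE_TOL:
            raise ValueError(
                f"{self.name!r}: weight fractions sum to {total:.8f}, "
                f"expected 1 within {CLOSURE_TOL}"
            )
        if self.mass_density <= 1e-4:
            raise ValueError(
                f"{self.name!r}: mass density {self.mass_density} g/cm^3 "
                "out of range (> 1e-4 required)"
            )
        object.__setattr__(self, "weight_fractions", fracs)

    def fraction(self, symbol: str) -> float:
        """Mass fraction of an element (0 if absent)."""
        return self.weight_fractions.get(symbol, 0.0)

    def renamed(self, name: str, category: str | None = None) -> "TissueComposition":
        return TissueComposition(
            name, dict(self.weight_fractions), self.mass_density,
            category if category is not None else self.category,
        )

    def with_density(self, mass_density: float) -> "TissueComposition":
        return TissueComposition(
            self.name, dict(self.weight_fractions), mass_density, self.category
        )


def composition_from_formula(
    name: str,
    formula: Mapping[str, int | float],
    mass_density: float,
    category: str = "other",
    elements: ElementTable = DEFAULT_ELEMENTS,
) -> TissueComposition:
    """Build a composition from a stoichiometric formula.

    ``formula`` maps element symbols to atom counts, e.g.
    ``{"C": 5, "H": 8, "O": 2}`` for PMMA.  Mass fractions follow from the
    standard atomic weights.
    """
    masses = {sym: n * elements[sym].A for sym, n in formula.items()}
    total = sum(masses.values())
    fracs = {sym: m / total for sym, m in masses.items()}
    return TissueComposition(name, fracs, mass_density, category)


def water(mass_density: float = 1.0, name: str = "water") -> TissueComposition:
    """Liquid water with the ICRU two-decimal composition."""
    return TissueComposition(name, dict(WATER_WEIGHT_FRACTIONS), mass_density, "soft")


def air(name: str = "air") -> TissueComposition:
    """Standard dry air (N/O/Ar 0.755/0.232/0.013, 1.205e-3 g/cm^3)."""
    return TissueComposition(name, dict(AIR_WEIGHT_FRACTIONS), AIR_DENSITY, "low_density")


def pmma(name: str = "pmma") -> TissueComposition:
    """Acrylic (C5H8O2, 1.19 g/cm^3), the phantom-wall material."""
    return composition_from_formula(name, {"C": 5, "H": 8, "O": 2}, 1.19)


def hydroxyapatite(mass_density: float = 3.16, name: str = "hydroxyapatite") -> TissueComposition:
    """Bone mineral Ca10(PO4)6(OH)2, the surrogate in bone-mimicking recipes."""
    return composition_from_formula(
        name, {"Ca": 10, "P": 6, "O": 26, "H": 2}, mass_density, "bone"
    )


# ---------------------------------------------------------------------------
# Composition arithmetic
# ---------------------------------------------------------------------------

def electrons_per_gram(
    comp: TissueComposition, elements: ElementTable = DEFAULT_ELEMENTS
) -> float:
    """Sum over elements of w_i * Z_i / A_i (mol electrons per gram)."""
    return sum(
        w * elements[sym].Z / elements[sym].A
        for sym, w in comp.weight_fractions.items()
    )


def relative_electron_density(
    comp: TissueComposition, elements: ElementTable = DEFAULT_ELEMENTS
) -> float:
    """Electron density relative to water at 1.0 g/cm^3.

    rho_e_hat = rho_m * sum(w_i Z_i / A_i) normalised by the same
    expression for water; linear in mass density at fixed composition.
    """
    water_epg = electrons_per_gram(water(), elements)
    return comp.mass_density * electrons_per_gram(comp, elements) / water_epg


def electron_fractions(
    comp: TissueComposition, elements: ElementTable = DEFAULT_ELEMENTS
) -> dict[str, float]:
    """Per-element electron fractions lambda_i = w_i Z_i/A_i / sum(...)."""
    contrib = {
        sym: w * elements[sym].Z / elements[sym].A
        for sym, w in comp.weight_fractions.items()
    }
    total = sum(contrib.values())
    return {sym: v / total for sym, v in contrib.items()}


def effective_atomic_number(
    comp: TissueComposition,
    exponent: float,
    elements: ElementTable = DEFAULT_ELEMENTS,
) -> float:
    """Electron-fraction power mean (sum lambda_i Z_i^x)^(1/x).

    With exponent 1 this is the electron-weighted mean Z; the
    stoichiometric CT-number model uses exponents 3.62 (photoelectric)
    and 1.86 (coherent scatter).
    """
    if exponent <= 0:
        raise ValueError(f"exponent must be > 0, got {exponent}")
    lam = electron_fractions(comp, elements)
    acc = sum(l * elements[sym].Z ** exponent for sym, l in lam.items())
    return acc ** (1.0 / exponent)


def bragg_ionization_potential(
    comp: TissueComposition,
    elements: ElementTable = DEFAULT_ELEMENTS,
    water_i_ev: float | None = None,
) -> float:
    """Mean excitation energy (eV) by Bragg additivity over electrons.

    ln I = sum lambda_i ln I_i.  If ``water_i_ev`` is given, the result is
    rescaled by the constant factor that anchors the water composition at
    that value, so all tissues share one consistent I-scale with water at
    the conventional I_w.
    """
    lam = electron_fractions(comp, elements)
    ln_i = sum(l * math.log(elements[sym].I_eV) for sym, l in lam.items())
    i_val = math.exp(ln_i)
    if water_i_ev is not None:
        lam_w = electron_fractions(water(), elements)
        ln_iw = sum(l * math.log(elements[sym].I_eV) for sym, l in lam_w.items())
        i_val *= water_i_ev / math.exp(ln_iw)
    return i_val


def mix_by_mass(
    components: Sequence[tuple[TissueComposition, float]],
    name: str = "mixture",
    category: str = "other",
) -> TissueComposition:
    """Mass-weighted mixture with volume-additive (inverse-density) density.

    w_i = sum_k f_k w_{i,k};  1/rho = sum_k f_k / rho_k.  Mass fractions
    ``f_k`` must be non-negative and sum to 1.
    """
    if not components:
        raise ValueError("no components")
    fracs = [f for _, f in components]
    if any(f < 0 for f in fracs):
        raise ValueError("negative mass fraction")
    if abs(sum(fracs) - 1.0) > CLOSURE_TOL:
        raise ValueError(f"mass fractions sum to {sum(fracs):.8f}, expected 1")
    weights: dict[str, float] = {}
    inv_rho = 0.0
    for comp, f in components:
        for sym, w in comp.weight_fractions.items():
            weights[sym] = weights.get(sym, 0.0) + f * w
        inv_rho += f / comp.mass_density
    return TissueComposition(name, weights, 1.0 / inv_rho, category)


def mix_by_volume(
    a: TissueComposition,
    b: TissueComposition,
    vol_fraction_a: float,
    name: str = "mixture",
    category: str = "other",
) -> TissueComposition:
    """Volumetric mixture: rho = f rho_a + (1-f) rho_b, mass-weighted w_i."""
    if not 0.0 <= vol_fraction_a <= 1.0:
        raise ValueError(f"volume fraction {vol_fraction_a} outside [0, 1]")
    f = vol_fraction_a
    rho = f * a.mass_density + (1.0 - f) * b.mass_density
    if rho <= 0:
        raise ValueError("mixture density is zero")
    weights: dict[str, float] = {}
    for sym in set(a.weight_fractions) | set(b.weight_fractions):
        weights[sym] = (
            f * a.mass_density * a.fraction(sym)
            + (1.0 - f) * b.mass_density * b.fraction(sym)
        ) / rho
    return TissueComposition(name, weights, rho, category)


def rehydrate(
    dry: TissueComposition,
    dry_mass_fraction: float,
    name: str | None = None,
) -> TissueComposition:
    """Re-add the water lost during sample drying.

    A dried sample making up ``dry_mass_fraction`` of the original wet mass
    is mixed with pure water for the remainder, reconstructing the wet
    composition under the assumption that all lost weight was H2O.
    """
    if not 0.0 < dry_mass_fraction <= 1.0:
        raise ValueError(
            f"dry mass fraction {dry_mass_fraction} outside (0, 1]"
        )
    if dry_mass_fraction == 1.0:
        return dry if name is None else dry.renamed(name)
    return mix_by_mass(
        [(dry, dry_mass_fraction), (water(), 1.0 - dry_mass_fraction)],
        name=name or f"{dry.name}_rehydrated",
        category=dry.category,
    )


def hydroxyapatite_water_mixture(
    ca_weight_fraction: float,
    name: str = "water_hydroxyapatite",
    mineral_density: float = 3.16,
) -> TissueComposition:
    """Water--hydroxyapatite binary mixture hitting a target Ca mass fraction.

    The bone-mimicking recipe: the hydroxyapatite mass fraction is solved
    from the requested calcium weight fraction (calcium enters only through
    the mineral), then the two components are mass-mixed.
    """
    ha = hydroxyapatite(mass_density=mineral_density)
    f_ha = ca_weight_fraction / ha.fraction("Ca")
    if not 0.0 < f_ha <= 1.0:
        raise ValueError(
            f"calcium fraction {ca_weight_fraction} not achievable "
            "with a water-hydroxyapatite binary"
        )
    return mix_by_mass(
        [(ha, f_ha), (water(), 1.0 - f_ha)], name=name, category="bone"
    )


# ---------------------------------------------------------------------------
# The reference-tissue basis
# ---------------------------------------------------------------------------

@dataclass
class TissueBasis:
    """Ordered collection of reference tissues with provenance tags.

    Order matters: downstream nearest-neighbour assignment breaks exact
    ties by the lowest basis index, so a basis is a list, not a set.
    """

    tissues: list[TissueComposition] = field(default_factory=list)
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.provenance:
            self.provenance = ["base-set"] * len(self.tissues)
        if len(self.provenance) != len(self.tissues):
            raise ValueError("provenance length mismatch")
        names = [t.name for t in self.tissues]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate tissue names: {dupes}")

    def __len__(self) -> int:
        return len(self.tissues)

    def __iter__(self):
        return iter(self.tissues)

    def names(self) -> list[str]:
        return [t.name for t in self.tissues]

    def get(self, name: str) -> TissueComposition:
        for t in self.tissues:
            if t.name == name:
                return t
        raise KeyError(f"no tissue named {name!r}")

    def add(self, tissue: TissueComposition, provenance: str = "base-set") -> None:
        if tissue.name in self.names():
            raise ValueError(f"duplicate tissue name {tissue.name!r}")
        self.tissues.append(tissue)
        self.provenance.append(provenance)

    def subset(self, names: Iterable[str]) -> "TissueBasis":
        wanted = list(names)
        idx = {t.name: i for i, t in enumerate(self.tissues)}
        tissues = [self.tissues[idx[n]] for n in wanted]
        prov = [self.provenance[idx[n]] for n in wanted]
        return TissueBasis(tissues, prov)


@dataclass(frozen=True)
class BoneSeriesSpec:
    """Parameters of the dense-bone augmentation series.

    ``n_mixtures`` cortical-bone/red-marrow volumetric mixtures span the
    spongiosa-to-bone gap; ``density_scales`` multiplies the densest base
    bone's density to populate the high-HU region beyond it.
    """

    n_mixtures: int = 10
    density_scales: tuple[float, ...] = (1.02, 1.04, 1.06, 1.08, 1.10)


def spongiosa_series(
    base: TissueBasis,
    n: int,
    bone_name: str = "cortical_bone",
    marrow_name: str = "red_marrow",
) -> list[TissueComposition]:
    """Trabecular-bone surrogates spanning the soft-tissue/bone HU gap.

    Spongiosa is trabecular bone interleaved with marrow; its CT numbers
    fall between the soft-tissue cluster and compact bone.  This helper
    returns ``n`` volumetric bone/marrow mixtures at evenly spaced bone
    volume fractions in (0, 1), a parametric stand-in for site-specific
    published spongiosa tables.
    """
    bone = base.get(bone_name)
    marrow = base.get(marrow_name)
    out = []
    for i in range(1, n + 1):
        f = i / (n + 1)
        out.append(
            mix_by_volume(
                bone, marrow, f,
                name=f"spongiosa_{f:.3f}", category="spongiosa",
            )
        )
    return out


def expand_basis(
    base: TissueBasis,
    spongiosa: Sequence[TissueComposition] = (),
    n_low_density: int = 0,
    bone_series: BoneSeriesSpec | None = None,
    lung_name: str = "lung",
    bone_name: str | None = None,
    marrow_name: str = "red_marrow",
) -> TissueBasis:
    """Augment a base tissue set to cover the whole DECT number plane.

    Appends, in order: (a) the supplied spongiosa compositions, (b)
    ``n_low_density`` lung--air volumetric mixtures at evenly spaced
    volume fractions strictly inside (0, 1), and (c) a dense-bone series
    built from volumetric mixtures of the densest base bone with red
    marrow plus a multiplicative density ramp on that bone.  Provenance
    tags record the origin of every appended entry.
    """
    out = TissueBasis(list(base.tissues), list(base.provenance))
    for t in spongiosa:
        out.add(t, provenance="spongiosa-addition")

    if n_low_density > 0:
        lung = out.get(lung_name)
        the_air = air()
        for i in range(1, n_low_density + 1):
            f_lung = i / (n_low_density + 1)
            mix = mix_by_volume(
                lung, the_air, f_lung,
                name=f"lung_air_{f_lung:.3f}",
                category="low_density",
            )
            out.add(mix, provenance="lung-air-mixture")

    if bone_series is not None:
        bones = [t for t in out.tissues if t.category == "bone"]
        if not bones:
            raise ValueError("bone series requested but basis has no bone")
        dense = max(bones, key=lambda t: t.mass_density)
        if bone_name is not None:
            dense = out.get(bone_name)
        marrow = out.get(marrow_name)
        for i in range(1, bone_series.n_mixtures + 1):
            f_bone = i / (bone_series.n_mixtures + 1)
            mix = mix_by_volume(
                dense, marrow, f_bone,
                name=f"bone_marrow_{f_bone:.3f}",
                category="spongiosa",
            )
            out.add(mix, provenance="bone-series")
        for scale in bone_series.density_scales:
            up = dense.with_density(dense.mass_density * scale).renamed(
                f"{dense.name}_x{scale:.2f}"
            )
            out.add(up, provenance="bone-series")
    return out


# ---------------------------------------------------------------------------
# Tissue-table I/O (CSV with one column per element; JSON mirror)
# ---------------------------------------------------------------------------

def basis_to_frame(basis: TissueBasis) -> pd.DataFrame:
    symbols: list[str] = []
    for t in basis:
        for sym in t.weight_fractions:
            if sym not in symbols:
                symbols.append(sym)
    rows = []
    for t, prov in zip(basis.tissues, basis.provenance):
        row = {"name": t.name, "category": t.category,
               "density_g_cm3": t.mass_density, "provenance": prov}
        for sym in symbols:
            row[sym] = t.fraction(sym)
        rows.append(row)
    return pd.DataFrame(rows)


def write_tissue_table(basis: TissueBasis, path: str | Path) -> None:
    path = Path(path)
    frame = basis_to_frame(basis)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(frame.to_dict(orient="records"), indent=1))
    else:
        frame.to_csv(path, index=False)


def read_tissue_table(path: str | Path) -> TissueBasis:
    path = Path(path)
    if path.suffix.lower() == ".json":
        frame = pd.DataFrame(json.loads(path.read_text()))
    else:
        frame = pd.read_csv(path)
    return _basis_from_frame(frame)


def _basis_from_frame(frame: pd.DataFrame) -> TissueBasis:
    meta = {"name", "category", "density_g_cm3", "provenance"}
    element_cols = [c for c in frame.columns if c not in meta]
    tissues, prov = [], []
    for _, row in frame.iterrows():
        fracs = {
            sym: float(row[sym])
            for sym in element_cols
            if pd.notna(row[sym]) and float(row[sym]) != 0.0
        }
        tissues.append(
            TissueComposition(
                str(row["name"]), fracs, float(row["density_g_cm3"]),
                str(row.get("category", "other")),
            )
        )
        prov.append(str(row.get("provenance", "base-set")))
    return TissueBasis(tissues, prov)


def load_reference_basis() -> TissueBasis:
    """Packaged table of representative published human-tissue compositions."""
    with resources.files("dectissue").joinpath(
        "data", "reference_tissues.csv"
    ).open("r") as fh:
        frame = pd.read_csv(fh)
    return _basis_from_frame(frame)
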